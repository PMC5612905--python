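"""Tracking codes: UUID-v4 identity, QR/barcode payloads, label sheets.

Every sample, reaction and analysis receives a random version-4 UUID
when it is coded.  The QR payload is the full UUID string; the
"truncated barcode" is the first 8 hex characters rendered in Code128.
A scanned string resolves back to its element: a full UUID uniquely,
an 8-character prefix to the list of candidates (usually one — on a
forced collision the resolver returns all of them rather than guessing).
Label sheets are emitted as SVG, one cell per code, each containing the
QR matrix, the 1-D barcode and the human-readable element label.
"""

from __future__ import annotations

import random
import uuid as uuid_module
from dataclasses import dataclass

from ._code128 import code128_widths
from ._qr import qr_matrix
from .errors import NotFoundError, ValidationError
from .store import Store

ELEMENT_KINDS = ("sample", "reaction", "analysis")

#: label-sheet size presets: (cell width, cell height, QR module size) in px
SIZE_PRESETS = {
    "small": (160, 80, 2),
    "medium": (240, 120, 3),
    "large": (320, 160, 4),
}


@dataclass(frozen=True)
class TrackingCode:
    uuid: str
    element_kind: str
    element_id: int

    def __post_init__(self):
        if self.element_kind not in ELEMENT_KINDS:
            raise ValidationError(
                f"element kind must be one of {ELEMENT_KINDS}")
        parsed = uuid_module.UUID(self.uuid)
        if parsed.version != 4:
            raise ValidationError("tracking codes are UUID version 4")


def assign_code(element_kind: str, element_id: int, store: Store,
                rng: random.Random | None = None) -> TrackingCode:
    """Assign (or return the existing) tracking code for an element.

    ``rng`` makes the UUID reproducible in tests; by default the module
    uses the system entropy source.  Assigning twice is idempotent.
    """
    if element_kind not in ELEMENT_KINDS:
        raise ValidationError(f"element kind must be one of {ELEMENT_KINDS}")
    row = store.one("SELECT uuid FROM codes WHERE kind=? AND element_id=?",
                    (element_kind, element_id))
    if row:
        return TrackingCode(row["uuid"], element_kind, element_id)
    if rng is None:
        value = uuid_module.uuid4()
    else:
        value = uuid_module.UUID(int=rng.getrandbits(128), version=4)
    store.execute("INSERT INTO codes(uuid, kind, element_id) VALUES(?,?,?)",
                  (str(value), element_kind, element_id))
    return TrackingCode(str(value), element_kind, element_id)


def qr_payload(code: TrackingCode) -> str:
    """QR codes carry the full UUID."""
    return code.uuid


BARCODE_PREFIX_LEN = 8


def barcode_payload(code: TrackingCode) -> str:
    """Truncated barcode: the first 8 hex characters, Code128 symbology."""
    return code.uuid.replace("-", "")[:BARCODE_PREFIX_LEN]


def resolve_code(scanned: str, store: Store) -> list[TrackingCode]:
    """Resolve a scanned payload to element references.

    A full UUID resolves to exactly one element; an 8-character prefix
    resolves to every element whose UUID starts with it (a list, so a
    collision can never route to the wrong element).
    """
    scanned = scanned.strip().lower()
    if len(scanned) == 36:
        rows = store.query("SELECT * FROM codes WHERE uuid=?", (scanned,))
    elif len(scanned) == BARCODE_PREFIX_LEN:
        rows = [r for r in store.query("SELECT * FROM codes ORDER BY uuid")
                if r["uuid"].replace("-", "").startswith(scanned)]
    else:
        raise ValidationError(
            f"scanned payload must be a full UUID or an "
            f"{BARCODE_PREFIX_LEN}-character prefix, got {len(scanned)} chars")
    if not rows:
        raise NotFoundError(f"no element matches code {scanned!r}")
    return [TrackingCode(r["uuid"], r["kind"], r["element_id"]) for r in rows]


# ---------------------------------------------------------------------------
# printable label sheet
# ---------------------------------------------------------------------------


def element_label(code: TrackingCode, store: Store) -> str:
    """Human-readable label printed beside the codes."""
    if code.element_kind == "sample":
        row = store.one("SELECT label FROM samples WHERE id=?",
                        (code.element_id,))
        if row:
            return row["label"]
    elif code.element_kind == "reaction":
        row = store.one("SELECT label FROM reactions WHERE id=?",
                        (code.element_id,))
        if row and row["label"]:
            return row["label"]
    else:
        row = store.one("SELECT kind, sample_id FROM analyses WHERE id=?",
                        (code.element_id,))
        if row:
            parent = store.one("SELECT label FROM samples WHERE id=?",
                               (row["sample_id"],))
            base = parent["label"] if parent else f"#{row['sample_id']}"
            return f"{base}/{row['kind']}"
    return f"{code.element_kind}-{code.element_id}"


def label_sheet(codes: list[TrackingCode], size_preset: str,
                store: Store) -> str:
    """Render one SVG label sheet: per code a QR code, a Code128 barcode
    and the element's label text.  Deterministic for fixed codes."""
    if not codes:
        raise ValidationError("label sheet needs at least one code")
    if size_preset not in SIZE_PRESETS:
        raise ValidationError(
            f"unknown size preset {size_preset!r}; "
            f"choose from {sorted(SIZE_PRESETS)}")
    cell_w, cell_h, module = SIZE_PRESETS[size_preset]
    parts = []
    for i, code in enumerate(codes):
        y0 = i * cell_h
        parts.append(f'<g class="label-cell" transform="translate(0,{y0})">')
        parts.append(_qr_svg(qr_payload(code), module))
        parts.append(_barcode_svg(barcode_payload(code), x=cell_w // 2,
                                  height=cell_h // 3))
        text = element_label(code, store)
        parts.append(
            f'<text x="{cell_w // 2}" y="{cell_h - 10}" '
            f'font-family="monospace" font-size="10">{_xml_escape(text)}'
            f'</text>')
        parts.append("</g>")
    height = len(codes) * cell_h
    body = "\n".join(parts)
    return (f'<svg xmlns="http://www.w3.org/2000/svg" width="{cell_w}" '
            f'height="{height}" viewBox="0 0 {cell_w} {height}">\n'
            f'<rect width="{cell_w}" height="{height}" fill="white"/>\n'
            f"{body}\n</svg>\n")


def _qr_svg(payload: str, module: int) -> str:
    matrix = qr_matrix(payload)
    rects = [f'<g class="qr" fill="black">']
    for r, row in enumerate(matrix):
        for c, dark in enumerate(row):
            if dark:
                rects.append(
                    f'<rect x="{4 + c * module}" y="{4 + r * module}" '
                    f'width="{module}" height="{module}"/>')
    rects.append("</g>")
    return "\n".join(rects)


def _barcode_svg(payload: str, x: int, height: int) -> str:
    widths = code128_widths(payload)
    rects = [f'<g class="barcode" fill="black">']
    pos = x
    for i, w in enumerate(widths):
        if i % 2 == 0:  # bars at even positions
            rects.append(f'<rect x="{pos}" y="8" width="{w}" '
                         f'height="{height}"/>')
        pos += w
    rects.append("</g>")
    return "\n".join(rects)


def _xml_escape(text: str) -> str:
    return (text.replace("&", "&amp;").replace("<", "&lt;")
            .replace(">", "&gt;"))
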