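"""Minimal QR encoder: byte mode, error-correction level L, versions 1-5.

Produces the module matrix for short payloads such as UUID strings
(36 bytes fits version 3-L).  Single error-correction block per symbol
(true for 1-L through 5-L), Reed-Solomon over GF(2^8) with the standard
0x11D polynomial, fixed mask pattern 0 with the matching BCH-protected
format information.  Returns a list of rows of booleans (True = dark).
"""

from __future__ import annotations

from .errors import CapacityError

# version -> (data codewords, error-correction codewords) at level L
_CAPACITY = {1: (19, 7), 2: (34, 10), 3: (55, 15), 4: (80, 20), 5: (108, 26)}

# version -> alignment pattern centre coordinates
_ALIGNMENT = {1: [], 2: [6, 18], 3: [6, 22], 4: [6, 26], 5: [6, 30]}

_MASK = 0  # (row + col) % 2 == 0


# -- GF(256) arithmetic ------------------------------------------------------

_EXP = [0] * 512
_LOG = [0] * 256
_x = 1
for _i in range(255):
    _EXP[_i] = _x
    _LOG[_x] = _i
    _x <<= 1
    if _x & 0x100:
        _x ^= 0x11D
for _i in range(255, 512):
    _EXP[_i] = _EXP[_i - 255]


def _gf_mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return _EXP[_LOG[a] + _LOG[b]]


def _rs_generator(degree: int) -> list[int]:
    poly = [1]
    for i in range(degree):
        poly = _poly_mul(poly, [1, _EXP[i]])
    return poly


def _poly_mul(p: list[int], q: list[int]) -> list[int]:
    out = [0] * (len(p) + len(q) - 1)
    for i, a in enumerate(p):
        for j, b in enumerate(q):
            out[i + j] ^= _gf_mul(a, b)
    return out


def _rs_encode(data: list[int], degree: int) -> list[int]:
    gen = _rs_generator(degree)
    rem = list(data) + [0] * degree
    for i in range(len(data)):
        coef = rem[i]
        if coef:
            for j in range(1, len(gen)):
                rem[i + j] ^= _gf_mul(gen[j], coef)
    return rem[len(data):]


# -- bit stream --------------------------------------------------------------


def _data_codewords(payload: bytes, version: int) -> list[int]:
    n_data, _ = _CAPACITY[version]
    bits: list[int] = []

    def put(value: int, width: int) -> None:
        bits.extend((value >> (width - 1 - k)) & 1 for k in range(width))

    put(0b0100, 4)               # byte mode
    put(len(payload), 8)         # count (8 bits for versions 1-9)
    for byte in payload:
        put(byte, 8)
    put(0, min(4, n_data * 8 - len(bits)))  # terminator
    while len(bits) % 8:
        bits.append(0)
    words = [int("".join(map(str, bits[i:i + 8])), 2)
             for i in range(0, len(bits), 8)]
    pads = (0xEC, 0x11)
    k = 0
    while len(words) < n_data:
        words.append(pads[k % 2])
        k += 1
    return words


def _pick_version(payload: bytes) -> int:
    for version, (n_data, _) in sorted(_CAPACITY.items()):
        if len(payload) + 2 <= n_data:  # mode + count = 12 bits ~ 2 bytes
            return version
    raise CapacityError(
        f"payload of {len(payload)} bytes exceeds version 5-L capacity")


# -- matrix ------------------------------------------------------------------


def _bch_format(mask: int) -> int:
    data = (0b01 << 3) | mask  # level L = 0b01
    rem = data << 10
    gen = 0b10100110111
    for shift in range(14, 9, -1):
        if rem & (1 << shift):
            rem ^= gen << (shift - 10)
    return ((data << 10) | rem) ^ 0b101010000010010


def qr_matrix(payload: str | bytes) -> list[list[bool]]:
    """Encode a payload and return the module matrix (True = dark)."""
    data = payload.encode() if isinstance(payload, str) else payload
    version = _pick_version(data)
    size = 17 + 4 * version
    n_data, n_ec = _CAPACITY[version]
    words = _data_codewords(data, version)
    codewords = words + _rs_encode(words, n_ec)

    matrix = [[False] * size for _ in range(size)]
    reserved = [[False] * size for _ in range(size)]

    def set_module(r: int, c: int, dark: bool) -> None:
        matrix[r][c] = dark
        reserved[r][c] = True

    def finder(r0: int, c0: int) -> None:
        for dr in range(-1, 8):
            for dc in range(-1, 8):
                r, c = r0 + dr, c0 + dc
                if not (0 <= r < size and 0 <= c < size):
                    continue
                inside = 0 <= dr <= 6 and 0 <= dc <= 6
                ring = inside and (dr in (0, 6) or dc in (0, 6))
                core = 2 <= dr <= 4 and 2 <= dc <= 4
                set_module(r, c, bool(ring or core))

    finder(0, 0)
    finder(0, size - 7)
    finder(size - 7, 0)

    for i in range(8, size - 8):  # timing
        set_module(6, i, i % 2 == 0)
        set_module(i, 6, i % 2 == 0)

    for cr in _ALIGNMENT[version]:  # alignment patterns
        for cc in _ALIGNMENT[version]:
            if reserved[cr][cc]:
                continue
            for dr in range(-2, 3):
                for dc in range(-2, 3):
                    dark = max(abs(dr), abs(dc)) != 1
                    set_module(cr + dr, cc + dc, dark)

    set_module(4 * version + 9, 8, True)  # dark module

    fmt = _bch_format(_MASK)
    fmt_bits = [(fmt >> (14 - i)) & 1 for i in range(15)]
    near = [(8, 0), (8, 1), (8, 2), (8, 3), (8, 4), (8, 5), (8, 7), (8, 8),
            (7, 8), (5, 8), (4, 8), (3, 8), (2, 8), (1, 8), (0, 8)]
    far = [(size - 1 - i, 8) for i in range(7)] \
        + [(8, size - 8 + i) for i in range(8)]
    for (r, c), bit in zip(near, fmt_bits):
        set_module(r, c, bool(bit))
    for (r, c), bit in zip(far, fmt_bits):
        set_module(r, c, bool(bit))

    # zigzag data placement with mask 0
    bit_stream = [(w >> (7 - k)) & 1 for w in codewords for k in range(8)]
    idx = 0
    col = size - 1
    upward = True
    while col > 0:
        if col == 6:
            col -= 1
        rows = range(size - 1, -1, -1) if upward else range(size)
        for row in rows:
            for c in (col, col - 1):
                if reserved[row][c]:
                    continue
                bit = bit_stream[idx] if idx < len(bit_stream) else 0
                idx += 1
                if (row + c) % 2 == 0:
                    bit ^= 1
                matrix[row][c] = bool(bit)
        upward = not upward
        col -= 2
    return matrix
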