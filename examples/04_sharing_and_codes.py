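"""Collections, snapshot vs synchronized sharing, and tracking codes."""

import random

from elnkit import (ShareGrant, Store, assign_code, barcode_payload,
                    create_collection, create_sample, graph_from_smiles,
                    label_sheet, qr_payload, register_molecule, resolve_code,
                    share_snapshot, sync_collection)
from elnkit.collections import add_elements, visible_elements

store = Store()
m = register_molecule(graph_from_smiles("CCO", "ethanol"), store)
s1 = create_sample(m, "PT", store)
s2 = create_sample(m, "PT", store)

proj = create_collection("anna", "project A", store)
add_elements(proj, "sample", [s1.id], store)

# snapshot: the recipient's element set is frozen at share time
snap = share_snapshot(proj, ShareGrant("bob", "read", detail_level=1), store)
# sync: the recipient follows the live collection
sync_collection(proj, ShareGrant("carol", "read"), store)

add_elements(proj, "sample", [s2.id], store)  # added AFTER sharing
print("bob (snapshot) sees:", sorted(visible_elements(store, "bob", snap.id)))
print("carol (synchronized) sees:",
      sorted(visible_elements(store, "carol", proj.id)))
# the snapshot kept 1 sample; the synchronized view shows both

# tracking codes: UUID v4 per element, QR = full uuid, barcode = 8-hex prefix
code = assign_code("sample", s1.id, store, rng=random.Random(42))
print(f"uuid: {qr_payload(code)}  barcode payload: {barcode_payload(code)}")
hit = resolve_code(barcode_payload(code), store)[0]
print(f"scanning the barcode resolves to: {hit.element_kind} "
      f"{hit.element_id} ({s1.rendered_label})")

svg = label_sheet([code], "small", store)
print(f"label sheet: SVG with {svg.count('label-cell')} cell(s), "
      f"{len(svg)} bytes (QR + Code128 + label text)")
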