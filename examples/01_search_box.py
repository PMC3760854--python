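"""Derive a docking search box from a receptor-peptide complex.

Builds a toy two-chain structure (receptor chain A, bound peptide chain B),
computes the padded axis-aligned box around the peptide, and strips the
peptide so the receptor is ready for docking.
"""

import tempfile
from pathlib import Path

from pepbind import compute_search_box, parse_pdb, strip_chain
from pepbind.synthetic import gen_toy_pdb

with tempfile.TemporaryDirectory() as tmp:
    pdb = Path(tmp) / "complex.pdb"
    # peptide CA atoms exactly span the (0,0,0)-(10,10,10) cube
    pdb.write_text(gen_toy_pdb(seed=0, peptide_length=5))
    model = parse_pdb(pdb)

print(f"chains in the complex: {model.chains}")

box = compute_search_box(model, peptide_chain="B", padding=5.0)
print(f"search box centre: {box.centre}")
print(f"search box dims (bounding box + 2 x 5 A padding): {box.dims}")

receptor = strip_chain(model, "B")
print(f"chains after stripping the peptide: {receptor.chains}")
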