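"""Parse a PSI-BLAST ASCII profile and extract the three descriptor blocks.

Builds a small synthetic PSSM, round-trips it through the on-disk format,
and prints the dimensions and first entries of each feature block. The
AAC values are per-column mean log-odds; COMPOSITION values are scaled to
[-1, 1]; RPSSM values are non-negative squared-deviation terms.
"""

import tempfile
from pathlib import Path

from dbpforest import (
    SimSpec,
    aadp_pssm,
    extract_features,
    parse_pssm,
    pssm_composition,
    rpssm,
    simulate,
    write_pssm,
)

ds = simulate(SimSpec(n_pos=1, n_neg=1, length_range=(60, 60), seed=0))
matrix = ds.pssms["pos_0000"]

with tempfile.TemporaryDirectory() as td:
    path = Path(td) / "example.pssm"
    write_pssm(matrix, path)
    matrix = parse_pssm(path)

print(f"protein length L = {matrix.length}, matrix shape = {matrix.scores.shape}")
for block in (aadp_pssm(matrix), pssm_composition(matrix), rpssm(matrix)):
    head = ", ".join(f"{n}={v:.3f}" for n, v in zip(block.names[:3], block.values[:3]))
    print(f"{block.block:12s} {len(block):4d} dims   first entries: {head}")
fused = extract_features(matrix)
print(f"{fused.block:12s} {len(fused):4d} dims  (420 AADP + 400 COMPOSITION + 110 RPSSM)")
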