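"""Compute a genomic signature: the FCGR k-mer matrix of one sequence.

The 2^k x 2^k grid cell (row, col) counts one specific k-mer; the matrix is
the sequence's composition fingerprint.  Standardization rescales it to sum
to 4^k so sequences of different lengths become comparable.
"""

from cgrphylo import compute_fcgr, random_sequence, standardize_fcgr
from cgrphylo.fcgr import cell_to_word

seq = random_sequence(20_000, gc=0.42, seed=5)
f = compute_fcgr(seq, k=3)
print(f"k=3 FCGR of a {len(seq)} nt sequence: {f.cells.shape[0]}x"
      f"{f.cells.shape[1]} grid, {f.n_cells} cells, "
      f"{f.total():.0f} counted 3-mers")

top = max(((r, c) for r in range(8) for c in range(8)),
          key=lambda rc: f.cells[rc])
print(f"most frequent 3-mer: {cell_to_word(*top, 3)} "
      f"({f.cells[top]} occurrences) at cell {top}")

s = standardize_fcgr(f)
print(f"standardized total: {s.total():.6f} (= 4^3 = 64; mean cell value 1, "
      "so values > 1 mark over-represented words)")
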