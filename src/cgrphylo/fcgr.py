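"""Chaos Game Representation (CGR) walks and frequency matrices (FCGR).

The CGR places a nucleotide sequence in the unit square with the four bases
at the corners — C top-left (0,0), G top-right (1,0), A bottom-left (0,1),
T bottom-right (1,1), in image coordinates where y grows downward.  Starting
from the center (0.5, 0.5), each base moves the current point halfway toward
its corner.  Overlaying a 2^k x 2^k grid and counting points per cell yields
the FCGR: cell (row, col) is exactly the occurrence count of one specific
k-mer, so the FCGR is a k-mer composition matrix arranged fractally.

FCGRs here are computed by exact k-mer counting (integer arithmetic, O(L))
rather than by binning floating-point walk coordinates; the two agree exactly
for every point whose suffix is a full k-mer, i.e. points i >= k (the first
k-1 walk points have no length-k suffix and are excluded from counts).

Standardization rescales an FCGR so its cells sum to 4^k (mean cell value 1),
removing sequence-length bias.  For EST data, poly-A tails left over from
cDNA library construction inflate the two homopolymer cells (the AA...A and
TT...T corners); those two cells can be zeroed before standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import lfilter

from .seqio import SequenceSet

__all__ = [
    "CGR_START",
    "CGRTrail",
    "FCGR",
    "cgr_walk",
    "word_to_cell",
    "cell_to_word",
    "compute_fcgr",
    "standardize_fcgr",
    "mask_homopolymer_cells",
    "render_cgr_svg",
    "render_fcgr_image",
    "write_fcgr_tsv",
    "read_fcgr_tsv",
]

MAX_K = 8
CGR_START = (0.5, 0.5)

# corner of each base in image coordinates (x right, y down)
_VERTEX = {"C": (0.0, 0.0), "G": (1.0, 0.0), "A": (0.0, 1.0), "T": (1.0, 1.0)}

# per-base bits: bx = 1 for the right half (G, T), by = 1 for the bottom half (A, T)
_BX = {"C": 0, "G": 1, "A": 0, "T": 1}
_BY = {"C": 0, "G": 0, "A": 1, "T": 1}

_BX_TABLE = np.full(256, 255, dtype=np.uint8)
_BY_TABLE = np.full(256, 255, dtype=np.uint8)
for _b in "ACGT":
    _BX_TABLE[ord(_b)] = _BX[_b]
    _BY_TABLE[ord(_b)] = _BY[_b]


@dataclass(frozen=True)
class CGRTrail:
    """Ordered CGR walk points, one per nucleotide, start excluded."""

    points: np.ndarray  # shape (L, 2), float64, columns (x, y)
    start: tuple[float, float] = CGR_START

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class FCGR:
    """A 2^k x 2^k k-mer count (or standardized frequency) matrix.

    ``cells[row, col]`` counts the k-mer mapped to that cell by
    :func:`word_to_cell`; row 0 is the top of the image.  ``masked_cells``
    records cells that were explicitly zeroed (EST homopolymer masking).
    """

    k: int
    cells: np.ndarray
    standardized: bool = False
    masked_cells: tuple[tuple[int, int], ...] = ()
    source_length: int = 0

    def __post_init__(self) -> None:
        side = 2**self.k
        if self.cells.shape != (side, side):
            raise ValueError(
                f"FCGR with k={self.k} needs a {side}x{side} matrix, "
                f"got {self.cells.shape}"
            )
        if np.any(self.cells < 0):
            raise ValueError("FCGR cells must be non-negative")

    @property
    def n_cells(self) -> int:
        return 4**self.k

    def total(self) -> float:
        return float(self.cells.sum())


def _encode(seq: str) -> tuple[np.ndarray, np.ndarray]:
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    bx = _BX_TABLE[raw]
    by = _BY_TABLE[raw]
    if bx.size and bx.max() == 255:
        bad = sorted({seq[i] for i in np.nonzero(bx == 255)[0][:5]})
        raise ValueError(f"sequence contains non-ACGT characters: {bad}")
    return bx, by


def cgr_walk(seq: str) -> CGRTrail:
    """Compute the CGR point trail of a cleaned A/C/G/T sequence.

    point_i = midpoint(point_{i-1}, vertex(seq_i)), point_0 = (0.5, 0.5).
    The recurrence x_i = 0.5*x_{i-1} + 0.5*vx_i is evaluated as a linear
    filter, which performs the identical floating-point halving steps.
    """
    bx, by = _encode(seq)
    if bx.size == 0:
        return CGRTrail(points=np.empty((0, 2), dtype=np.float64))
    vx = bx.astype(np.float64)
    vy = by.astype(np.float64)
    # y[n] = 0.5*v[n] + 0.5*y[n-1], seeded so that y[-1] = 0.5
    b, a = [0.5], [1.0, -0.5]
    xs, _ = lfilter(b, a, vx, zi=[0.5 * CGR_START[0]])
    ys, _ = lfilter(b, a, vy, zi=[0.5 * CGR_START[1]])
    return CGRTrail(points=np.column_stack([xs, ys]))


def word_to_cell(word: str) -> tuple[int, int]:
    """Map a k-mer to its (row, col) cell in the 2^k x 2^k FCGR grid.

    col = sum_i bx(w_i) * 2^(i-1) and row = sum_i by(w_i) * 2^(i-1) for
    i = 1..k, where bx is 1 for G/T (right half) and by is 1 for A/T (bottom
    half); later characters carry higher bits, so this is exactly the grid
    cell containing the CGR point reached after reading the word.
    """
    if not word:
        raise ValueError("word must have length >= 1")
    col = 0
    row = 0
    for i, ch in enumerate(word):
        try:
            col |= _BX[ch] << i
            row |= _BY[ch] << i
        except KeyError:
            raise ValueError(f"invalid character {ch!r} in k-mer {word!r}") from None
    return row, col


def cell_to_word(row: int, col: int, k: int) -> str:
    """Inverse of :func:`word_to_cell`: the k-mer counted by cell (row, col)."""
    chars = []
    for i in range(k):
        bx = (col >> i) & 1
        by = (row >> i) & 1
        chars.append("CGAT"[bx + 2 * by])
    return "".join(chars)


def compute_fcgr(ss: SequenceSet | str, k: int) -> FCGR:
    """Count all length-k windows of a sequence into the 2^k x 2^k grid.

    Accepts a :class:`~cgrphylo.seqio.SequenceSet` or a plain cleaned string.
    The total count equals L - k + 1.
    """
    seq = ss.sequence if isinstance(ss, SequenceSet) else ss
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in 1..{MAX_K}, got {k}")
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} is shorter than k={k}")
    bx, by = _encode(seq)
    weights = (1 << np.arange(k)).astype(np.int64)
    cols = sliding_window_view(bx, k).astype(np.int64) @ weights
    rows = sliding_window_view(by, k).astype(np.int64) @ weights
    ids = rows * (1 << k) + cols
    counts = np.bincount(ids, minlength=4**k).reshape(2**k, 2**k)
    return FCGR(k=k, cells=counts.astype(np.int64), source_length=len(seq))


def compute_fcgr_segments(segments: list[str], k: int) -> FCGR:
    """Count k-mers within each segment separately and sum the counts.

    This is the walk-reset-at-boundaries variant: no window spans a segment
    junction, so concatenation artifacts are excluded entirely.  Segments
    shorter than k contribute nothing.  Compared with counting the plain
    concatenation, at most (k-1) junction words per boundary differ.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in 1..{MAX_K}, got {k}")
    usable = [s for s in segments if len(s) >= k]
    if not usable:
        raise ValueError(f"no segment reaches length k={k}")
    total = np.zeros((2**k, 2**k), dtype=np.int64)
    for seg in usable:
        total += compute_fcgr(seg, k).cells
    return FCGR(k=k, cells=total, source_length=sum(len(s) for s in segments))


def standardize_fcgr(f: FCGR) -> FCGR:
    """Rescale so the cells sum to 4^k (mean cell value 1)."""
    if f.standardized:
        raise ValueError("FCGR is already standardized")
    total = f.total()
    if total <= 0:
        raise ValueError("cannot standardize empty FCGR (all cells zero)")
    cells = f.cells.astype(np.float64) * (4**f.k / total)
    return replace(f, cells=cells, standardized=True)


def mask_homopolymer_cells(f: FCGR) -> FCGR:
    """Zero the poly-A and poly-T cells (EST poly-A tail correction).

    The two cells holding the A^k and T^k homopolymer counts — the bottom-left
    and bottom-right corners of the grid — are set to zero on the raw counts,
    before standardization, so the remaining cells carry all the mass.
    Idempotent.
    """
    if f.standardized:
        raise ValueError("mask before standardization, not after")
    cells = f.cells.copy()
    targets = (word_to_cell("A" * f.k), word_to_cell("T" * f.k))
    for row, col in targets:
        cells[row, col] = 0
    return replace(f, cells=cells, masked_cells=targets)


def render_cgr_svg(trail: CGRTrail, point_size: float = 1.0) -> str:
    """Render a CGR trail as an SVG document (unit square, corner base labels).

    ``point_size`` is the marker radius in pixels of a 520x520 canvas.
    """
    if len(trail) == 0:
        raise ValueError("cannot render an empty CGR trail")
    size, margin = 520.0, 20.0
    scale = size - 2 * margin

    def px(x: float, y: float) -> tuple[float, float]:
        return margin + x * scale, margin + y * scale

    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{size:.0f}" '
        f'height="{size:.0f}" viewBox="0 0 {size:.0f} {size:.0f}">',
        f'<rect x="{margin}" y="{margin}" width="{scale}" height="{scale}" '
        'fill="white" stroke="black"/>',
    ]
    # corner labels, image orientation: C upper left, G upper right,
    # A lower left, T lower right
    labels = [("C", 0.0, 0.0, "end", -4), ("G", 1.0, 0.0, "start", -4),
              ("A", 0.0, 1.0, "end", 12), ("T", 1.0, 1.0, "start", 12)]
    for text, x, y, anchor, dy in labels:
        cx, cy = px(x, y)
        lines.append(
            f'<text x="{cx:.1f}" y="{cy + dy:.1f}" text-anchor="{anchor}" '
            f'font-family="sans-serif" font-size="16">{text}</text>'
        )
    for x, y in trail.points:
        cx, cy = px(float(x), float(y))
        lines.append(f'<circle cx="{cx:.3f}" cy="{cy:.3f}" r="{point_size}"/>')
    lines.append("</svg>")
    return "\n".join(lines)


def render_fcgr_image(f: FCGR, gamma: float = 1.0, invert: bool = False) -> np.ndarray:
    """Render an FCGR as an 8-bit grayscale raster (2^k x 2^k pixels).

    By default the maximum cell maps to black (0) and empty cells to white
    (255), matching the usual dense-regions-dark presentation; ``invert``
    flips the mapping.  ``gamma`` is applied to the max-normalized values, so
    the image is invariant under rescaling all counts.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    cells = f.cells.astype(np.float64)
    peak = cells.max()
    norm = cells / peak if peak > 0 else cells
    norm = norm**gamma
    intensity = norm if invert else 1.0 - norm
    return np.clip(np.rint(intensity * 255), 0, 255).astype(np.uint8)


def write_fcgr_tsv(f: FCGR) -> str:
    """Serialize an FCGR as TSV with a small metadata header."""
    header = [
        f"#k={f.k}",
        f"#standardized={'true' if f.standardized else 'false'}",
        f"#source_length={f.source_length}",
        f"#masked_cells={';'.join(f'{r},{c}' for r, c in f.masked_cells)}",
    ]
    fmt = "%.10g" if f.standardized else "%d"
    body = "\n".join("\t".join(fmt % v for v in row) for row in f.cells)
    return "\n".join(header) + "\n" + body + "\n"


def read_fcgr_tsv(text: str) -> FCGR:
    """Parse the TSV produced by :func:`write_fcgr_tsv`."""
    meta: dict[str, str] = {}
    rows = []
    for line in text.splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            meta[key] = value
        else:
            rows.append([float(v) for v in line.split("\t")])
    k = int(meta["k"])
    standardized = meta.get("standardized", "false") == "true"
    masked = tuple(
        tuple(int(x) for x in pair.split(","))
        for pair in meta.get("masked_cells", "").split(";")
        if pair
    )
    cells = np.asarray(rows, dtype=np.float64 if standardized else np.int64)
    return FCGR(
        k=k,
        cells=cells,
        standardized=standardized,
        masked_cells=masked,  # type: ignore[arg-type]
        source_length=int(meta.get("source_length", 0)),
    )
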