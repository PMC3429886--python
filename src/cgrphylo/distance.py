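"""Pairwise distances between FCGR signatures and distance-matrix I/O.

Two distances are provided.  The Euclidean distance operates on standardized
FCGRs and is the root-mean-square cell difference,

    d(A, B) = (2^k / 4^k) * sqrt( sum_ij (a_ij - b_ij)^2 ),

i.e. sqrt of the mean squared difference over the 4^k cells (any positive
prefactor leaves every distance-based topology unchanged; the RMS convention
makes d dimensionless and comparable across k).  The Pearson distance
operates on the raw (non-standardized) counts and is one minus a weighted
Pearson correlation in which each cell is weighted by the product of the two
profiles' values at that cell; it lies in [0, 2] for non-negative profiles.

Matrices are written either as PHYLIP square distance matrices (names padded
to 10 characters, for interoperability with classic phylogenetics tools) or
as lossless TSV with full-length labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fcgr import FCGR

__all__ = [
    "DistanceMatrix",
    "DegenerateProfileError",
    "euclidean_distance",
    "pearson_distance",
    "build_distance_matrix",
    "write_phylip",
    "read_phylip",
    "write_tsv",
    "read_tsv",
]


class DegenerateProfileError(ValueError):
    """The weighted Pearson distance is undefined for these profiles."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Labeled symmetric distance matrix with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray
    metric: str = ""
    k: int = 0

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"expected {n}x{n} matrix, got {self.values.shape}")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate taxon labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


def _check_pair(a: FCGR, b: FCGR, want_standardized: bool) -> None:
    if a.k != b.k:
        raise ValueError(f"FCGR resolutions differ: k={a.k} vs k={b.k}")
    if a.standardized != want_standardized or b.standardized != want_standardized:
        state = "standardized" if want_standardized else "raw (non-standardized)"
        raise ValueError(f"this metric requires {state} FCGRs")
    if want_standardized and set(a.masked_cells) != set(b.masked_cells):
        raise ValueError("FCGRs have different masked cells")


def euclidean_vec(x: np.ndarray, y: np.ndarray, k: int) -> float:
    """RMS difference over 4^k entries of two flattened standardized FCGRs."""
    diff = x - y
    return float(2**k / 4**k * np.sqrt(np.dot(diff, diff)))


def pearson_vec(x: np.ndarray, y: np.ndarray) -> float:
    """Weighted Pearson distance between two flattened raw count profiles.

    Weights w_i = x_i y_i / n_w with n_w = sum x_i y_i; the weighted means
    x_w = sum x_i^2 y_i / n_w (and symmetrically y_w), the weighted standard
    deviations s_x, s_y, and d = 1 - sum ((x-x_w)/s_x)((y-y_w)/s_y) w.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    wraw = x * y
    n_w = wraw.sum()
    if n_w <= 0:
        raise DegenerateProfileError("no shared support (sum of x_i*y_i is zero)")
    w = wraw / n_w
    xbar = np.dot(x, wraw) / n_w
    ybar = np.dot(y, wraw) / n_w
    dx = x - xbar
    dy = y - ybar
    sx = np.sqrt(np.dot(dx * dx, w))
    sy = np.sqrt(np.dot(dy * dy, w))
    if sx == 0 or sy == 0:
        raise DegenerateProfileError("degenerate profile (zero weighted variance)")
    corr = np.dot(dx * dy, w) / (sx * sy)
    # weighted Cauchy-Schwarz bounds |corr| by 1; clip float residue
    return float(max(1.0 - corr, 0.0))


def euclidean_distance(a: FCGR, b: FCGR) -> float:
    """Eq.-style RMS distance between two standardized FCGRs of equal k."""
    _check_pair(a, b, want_standardized=True)
    return euclidean_vec(a.cells.ravel(), b.cells.ravel(), a.k)


def pearson_distance(a: FCGR, b: FCGR) -> float:
    """Weighted Pearson distance between two raw-count FCGRs of equal k."""
    _check_pair(a, b, want_standardized=False)
    return pearson_vec(a.cells.ravel(), b.cells.ravel())


def build_distance_matrix(
    profiles: list[tuple[str, FCGR]],
    metric: str = "euclidean",
) -> DistanceMatrix:
    """All-pairs distance matrix over labeled FCGR profiles.

    ``metric`` is "euclidean" (requires standardized profiles) or "pearson"
    (requires raw profiles).  Each pair is computed once and mirrored, so the
    result is exactly symmetric.
    """
    if metric not in ("euclidean", "pearson"):
        raise ValueError(f"unknown metric {metric!r}")
    if len(profiles) < 3:
        raise ValueError("need at least 3 profiles for a distance matrix")
    labels = tuple(label for label, _ in profiles)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate taxon labels")
    ks = {f.k for _, f in profiles}
    if len(ks) != 1:
        raise ValueError(f"inconsistent FCGR resolutions: {sorted(ks)}")
    dist = euclidean_distance if metric == "euclidean" else pearson_distance
    n = len(profiles)
    values = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        for j in range(i + 1, n):
            d = dist(profiles[i][1], profiles[j][1])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=labels, values=values, metric=metric, k=ks.pop())


_PHYLIP_NAME_WIDTH = 10


def write_phylip(d: DistanceMatrix) -> str:
    """PHYLIP square distance format (names padded/truncated to 10 chars)."""
    short = [label[:_PHYLIP_NAME_WIDTH] for label in d.labels]
    seen: dict[str, str] = {}
    for full, s in zip(d.labels, short):
        if s in seen:
            raise ValueError(
                f"taxon names collide after 10-character truncation: "
                f"{seen[s]!r} and {full!r} both become {s!r}"
            )
        seen[s] = full
    lines = [f"{d.n}"]
    for name, row in zip(short, d.values):
        lines.append(
            name.ljust(_PHYLIP_NAME_WIDTH)
            + " ".join(f"{v:.6f}" for v in row)
        )
    return "\n".join(lines) + "\n"


def read_phylip(text: str) -> DistanceMatrix:
    """Parse a PHYLIP square distance matrix (one taxon per line)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty PHYLIP input")
    n = int(lines[0].split()[0])
    if len(lines) != n + 1:
        raise ValueError(f"expected {n} taxon rows, found {len(lines) - 1}")
    labels: list[str] = []
    values = np.zeros((n, n), dtype=np.float64)
    for i, line in enumerate(lines[1:]):
        name = line[:_PHYLIP_NAME_WIDTH].strip()
        fields = line[_PHYLIP_NAME_WIDTH:].split()
        if len(fields) != n:
            raise ValueError(f"row {i + 1}: expected {n} distances, got {len(fields)}")
        labels.append(name)
        values[i] = [float(v) for v in fields]
    values = 0.5 * (values + values.T)  # absorb last-digit rounding asymmetry
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(labels=tuple(labels), values=values)


def write_tsv(d: DistanceMatrix) -> str:
    """Lossless TSV alternative with full-length labels."""
    header = "\t".join(("taxon",) + d.labels)
    lines = [f"#metric={d.metric}", f"#k={d.k}", header]
    for label, row in zip(d.labels, d.values):
        lines.append(label + "\t" + "\t".join(f"{v:.12g}" for v in row))
    return "\n".join(lines) + "\n"


def read_tsv(text: str) -> DistanceMatrix:
    """Parse the TSV produced by :func:`write_tsv`."""
    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    for line in text.splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            meta[key] = value
        else:
            rows.append(line.split("\t"))
    labels = tuple(rows[0][1:])
    values = np.array([[float(v) for v in row[1:]] for row in rows[1:]])
    return DistanceMatrix(
        labels=labels,
        values=values,
        metric=meta.get("metric", ""),
        k=int(meta.get("k", 0) or 0),
    )
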