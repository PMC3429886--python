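"""End-to-end orchestration: FASTA sets to bootstrapped consensus trees.

The full method is: one cleaned concatenated sequence per taxon (reverse
complement appended), an FCGR per taxon at resolution k (with the two
homopolymer cells zeroed for EST data), a pairwise distance matrix
(Euclidean on standardized FCGRs or weighted Pearson on raw counts), a
point-estimate Neighbor-Joining tree, and a bootstrap: the 4^k FCGR cells
are treated as the characters of a taxon-by-character matrix and resampled
with replacement — one shared index vector per replicate, applied to every
taxon — giving B replicate trees, a strict majority-rule consensus with
percentage supports, and branch lengths fitted on the fixed consensus
topology by weighted least squares against the point distance matrix.

Randomness: replicate r of a run with master seed s draws from the
substream SeedSequence(entropy=s, spawn_key=(r, attempt)), so any replicate
is reproducible in isolation and a degenerate replicate (a Pearson profile
with zero weighted variance, or an all-zero resample) is redrawn from the
next attempt substream without disturbing the other replicates.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .distance import (
    DegenerateProfileError,
    DistanceMatrix,
    build_distance_matrix,
    euclidean_vec,
    pearson_vec,
    write_phylip,
    write_tsv,
)
from .fcgr import FCGR, compute_fcgr, mask_homopolymer_cells, standardize_fcgr
from .seqio import build_dataset_sequence, read_fasta
from .tree import (
    annotate_supports,
    fit_branch_lengths,
    majority_consensus,
    neighbor_joining,
    tree_to_newick,
)

__all__ = [
    "TaxonInput",
    "RunConfig",
    "BootstrapResult",
    "resample_cell_indices",
    "bootstrap_replicate",
    "bootstrap_analysis",
    "run_pipeline",
]

logger = logging.getLogger("cgrphylo")

DATATYPES = ("genome", "est", "mito")
_MAX_REDRAWS = 10


@dataclass(frozen=True)
class TaxonInput:
    """One taxon: display label, FASTA path, and data type.

    ``datatype`` is "genome", "est" or "mito"; EST data get the poly-A/T
    homopolymer cells of their FCGR zeroed.
    """

    label: str
    path: str
    datatype: str = "genome"

    def __post_init__(self) -> None:
        if self.datatype not in DATATYPES:
            raise ValueError(f"datatype must be one of {DATATYPES}")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full bootstrap run."""

    taxa: tuple[TaxonInput, ...]
    k: int = 6
    metric: str = "euclidean"
    replicates: int = 500
    seed: int = 0
    append_revcomp: bool = True
    consensus_threshold: float = 0.5

    def __post_init__(self) -> None:
        if len(self.taxa) < 3:
            raise ValueError("need at least 3 taxa")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 1 <= self.k <= 8:
            raise ValueError("k must be in 1..8")
        if self.metric not in ("euclidean", "pearson"):
            raise ValueError(f"unknown metric {self.metric!r}")


@dataclass
class BootstrapResult:
    """Everything a bootstrap run produces."""

    point_tree: "object"  # dendropy.Tree with bootstrap labels
    consensus: "object"  # dendropy.Tree with supports and fitted lengths
    replicate_trees: list
    point_distances: DistanceMatrix
    config: RunConfig | None = None
    n_redrawn: int = 0
    field_metadata: dict = field(default_factory=dict)


def resample_cell_indices(k: int, rng: np.random.Generator) -> np.ndarray:
    """Draw 4^k cell indices uniformly with replacement (one bootstrap
    replicate's shared character sample)."""
    if not 1 <= k <= 8:
        raise ValueError("k must be in 1..8")
    n = 4**k
    return rng.integers(0, n, size=n)


def bootstrap_replicate(
    profiles: list[tuple[str, FCGR]],
    indices: np.ndarray,
) -> list[tuple[str, np.ndarray]]:
    """Gather every taxon's flattened FCGR cells at one shared index vector."""
    ks = {f.k for _, f in profiles}
    if len(ks) != 1:
        raise ValueError(f"inconsistent FCGR resolutions: {sorted(ks)}")
    k = ks.pop()
    if len(indices) != 4**k:
        raise ValueError(f"index vector must have length {4**k}")
    return [(label, f.cells.ravel()[indices]) for label, f in profiles]


def _replicate_distance_matrix(
    resampled: list[tuple[str, np.ndarray]],
    k: int,
    metric: str,
) -> DistanceMatrix:
    labels = tuple(label for label, _ in resampled)
    vectors = [np.asarray(v, dtype=np.float64) for _, v in resampled]
    if metric == "euclidean":
        # re-standardize within the replicate so the RMS distance sees
        # mean-1 profiles, as in the point estimate
        standardized = []
        for v in vectors:
            total = v.sum()
            if total <= 0:
                raise DegenerateProfileError("resampled profile is all zero")
            standardized.append(v * (4**k / total))
        vectors = standardized
        dist = lambda x, y: euclidean_vec(x, y, k)  # noqa: E731
    else:
        dist = pearson_vec
    n = len(vectors)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = dist(vectors[i], vectors[j])
    return DistanceMatrix(labels=labels, values=values, metric=metric, k=k)


def point_distance_matrix(
    profiles: list[tuple[str, FCGR]],
    metric: str,
) -> DistanceMatrix:
    """Distance matrix of the unresampled profiles (raw counts in,
    standardization applied internally on the Euclidean path)."""
    if metric == "euclidean":
        prepared = [(label, standardize_fcgr(f)) for label, f in profiles]
    else:
        prepared = profiles
    return build_distance_matrix(prepared, metric=metric)


def bootstrap_analysis(
    profiles: list[tuple[str, FCGR]],
    metric: str = "euclidean",
    replicates: int = 500,
    seed: int = 0,
    consensus_threshold: float = 0.5,
    config: RunConfig | None = None,
) -> BootstrapResult:
    """Point tree, B replicate trees, consensus with supports, fitted lengths.

    ``profiles`` are raw-count FCGRs (already masked for EST data); the
    Euclidean path standardizes internally, per replicate.
    """
    ks = {f.k for _, f in profiles}
    if len(ks) != 1:
        raise ValueError(f"inconsistent FCGR resolutions: {sorted(ks)}")
    k = ks.pop()
    point_dm = point_distance_matrix(profiles, metric)
    point_tree = neighbor_joining(point_dm)

    replicate_trees = []
    n_redrawn = 0
    for r in range(replicates):
        for attempt in range(_MAX_REDRAWS):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(r, attempt))
            )
            indices = resample_cell_indices(k, rng)
            try:
                resampled = bootstrap_replicate(profiles, indices)
                dm = _replicate_distance_matrix(resampled, k, metric)
            except DegenerateProfileError:
                n_redrawn += 1
                continue
            replicate_trees.append(neighbor_joining(dm))
            break
        else:
            raise RuntimeError(
                f"replicate {r}: {_MAX_REDRAWS} consecutive degenerate "
                "resamples; aborting"
            )

    consensus = majority_consensus(replicate_trees, threshold=consensus_threshold)
    consensus = fit_branch_lengths(consensus, point_dm)
    point_tree = annotate_supports(point_tree, replicate_trees)
    return BootstrapResult(
        point_tree=point_tree,
        consensus=consensus,
        replicate_trees=replicate_trees,
        point_distances=point_dm,
        config=config,
        n_redrawn=n_redrawn,
    )


def load_profiles(cfg: RunConfig) -> list[tuple[str, FCGR]]:
    """Read each taxon's FASTA, build its cleaned sequence and raw FCGR
    (homopolymer cells masked for EST data)."""
    profiles = []
    for taxon in cfg.taxa:
        records = read_fasta(taxon.path)
        ss = build_dataset_sequence(
            records, taxon.label, append_revcomp=cfg.append_revcomp
        )
        f = compute_fcgr(ss, cfg.k)
        if taxon.datatype == "est":
            f = mask_homopolymer_cells(f)
        profiles.append((taxon.label, f))
        logger.info(
            "loaded %s: %d records, %d nt cleaned%s",
            taxon.label,
            ss.n_records,
            len(ss.sequence),
            " (+revcomp)" if ss.revcomp_appended else "",
        )
    return profiles


def run_pipeline(cfg: RunConfig, outdir: str | Path | None = None) -> BootstrapResult:
    """Run the full method on FASTA inputs; optionally write all artifacts.

    Artifacts (``outdir``): the point-estimate NJ tree with bootstrap labels,
    the consensus tree with supports and fitted branch lengths, all replicate
    trees, the point distance matrix (PHYLIP + TSV), and a MANIFEST echoing
    the configuration.  Identical configurations (including the seed) produce
    byte-identical outputs.
    """
    t0 = time.perf_counter()
    try:
        profiles = load_profiles(cfg)
    except Exception as exc:
        raise RuntimeError(f"[stage sequences+fcgr] {exc}") from exc
    logger.info("stage sequences+fcgr: %.2fs", time.perf_counter() - t0)

    t1 = time.perf_counter()
    try:
        result = bootstrap_analysis(
            profiles,
            metric=cfg.metric,
            replicates=cfg.replicates,
            seed=cfg.seed,
            consensus_threshold=cfg.consensus_threshold,
            config=cfg,
        )
    except Exception as exc:
        raise RuntimeError(f"[stage bootstrap] {exc}") from exc
    logger.info("stage bootstrap: %.2fs", time.perf_counter() - t1)

    if outdir is not None:
        write_artifacts(result, outdir)
    return result


def write_artifacts(result: BootstrapResult, outdir: str | Path) -> None:
    """Write the trees, matrices and a MANIFEST for a bootstrap run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "point_tree.nwk").write_text(
        tree_to_newick(result.point_tree, include_supports=True)
    )
    (outdir / "consensus.nwk").write_text(
        tree_to_newick(result.consensus, include_supports=True)
    )
    (outdir / "replicates.nwk").write_text(
        "".join(tree_to_newick(t) for t in result.replicate_trees)
    )
    (outdir / "distances.phy").write_text(write_phylip(result.point_distances))
    (outdir / "distances.tsv").write_text(write_tsv(result.point_distances))
    manifest = {
        "replicates": len(result.replicate_trees),
        "redrawn": result.n_redrawn,
        "metric": result.point_distances.metric,
        "k": result.point_distances.k,
        "taxa": list(result.point_distances.labels),
        "complete": True,
    }
    if result.config is not None:
        manifest["config"] = {
            "k": result.config.k,
            "metric": result.config.metric,
            "replicates": result.config.replicates,
            "seed": result.config.seed,
            "append_revcomp": result.config.append_revcomp,
            "consensus_threshold": result.config.consensus_threshold,
            "taxa": [
                {"label": t.label, "path": t.path, "datatype": t.datatype}
                for t in result.config.taxa
            ],
        }
    (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2) + "\n")
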