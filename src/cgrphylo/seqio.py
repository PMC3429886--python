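"""FASTA input and per-taxon sequence preparation.

Every downstream computation (CGR walks, FCGR counting, distances) consumes a
single cleaned nucleotide string per taxon.  This module produces it: all
records of a taxon's FASTA file are concatenated in file order, characters
outside {A, C, G, T} are removed (case-insensitively), and by default the
reverse complement of the concatenated sequence is appended so that k-mer
counts become strand-symmetric.

Deletions and record boundaries create a handful of junction k-mers; with the
sequence sizes this method targets their contribution is negligible, and the
walk is deliberately not reset at boundaries (``reset_at_boundaries`` exists
for comparison but is off by default).
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SequenceRecord",
    "SequenceSet",
    "FastaParseError",
    "read_fasta",
    "clean_sequence",
    "reverse_complement",
    "build_dataset_sequence",
    "shred_subsample",
    "write_fasta",
]


@dataclass(frozen=True)
class SequenceRecord:
    """One raw FASTA entry: header id (up to first whitespace) and sequence."""

    id: str
    seq: str


@dataclass(frozen=True)
class SequenceSet:
    """Cleaned, concatenated nucleotide string for one taxon.

    ``sequence`` contains only A/C/G/T.  If ``revcomp_appended`` is true the
    second half of ``sequence`` is the reverse complement of the first half.
    """

    label: str
    sequence: str
    n_records: int
    revcomp_appended: bool

    def __post_init__(self) -> None:
        if self.revcomp_appended and len(self.sequence) % 2 != 0:
            raise ValueError("revcomp_appended sequence must have even length")


class FastaParseError(ValueError):
    """Malformed FASTA input (reports the offending line number)."""


# translate table: keep upper-case A/C/G/T (folding case), delete everything else
_CLEAN_TABLE = {c: None for c in range(256)}
for _ch in "ACGT":
    _CLEAN_TABLE[ord(_ch)] = _ch
    _CLEAN_TABLE[ord(_ch.lower())] = _ch

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ACGT = frozenset("ACGT")


def _open_text(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "r")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (optionally gzip-compressed) FASTA file.

    Returns one :class:`SequenceRecord` per entry, in file order, with the id
    taken up to the first whitespace.  Sequences are returned verbatim
    (cleaning is a separate step).  A sequence line appearing before any
    header raises :class:`FastaParseError` naming the line number.
    """
    records: list[SequenceRecord] = []
    current_id: str | None = None
    chunks: list[str] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                if current_id is not None:
                    records.append(SequenceRecord(current_id, "".join(chunks)))
                current_id = line[1:].split(None, 1)[0] if line[1:].strip() else ""
                if not current_id:
                    raise FastaParseError(f"empty FASTA header at line {lineno}")
                chunks = []
            else:
                if current_id is None:
                    raise FastaParseError(
                        f"sequence data before any FASTA header at line {lineno}"
                    )
                chunks.append(line.strip())
    if current_id is not None:
        records.append(SequenceRecord(current_id, "".join(chunks)))
    return records


def clean_sequence(raw: str) -> str:
    """Uppercase ``raw`` and drop every character outside {A, C, G, T}.

    Ambiguity codes, N runs, gaps and whitespace are simply removed; the kept
    characters keep their relative order (no gap marker, no walk reset).
    Idempotent by construction.
    """
    return raw.translate(_CLEAN_TABLE)


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of a cleaned A/C/G/T string."""
    if not _ACGT.issuperset(seq):
        bad = sorted(set(seq) - _ACGT)
        raise ValueError(
            f"reverse_complement requires a cleaned A/C/G/T sequence; "
            f"found {bad} (run clean_sequence first)"
        )
    return seq.translate(_COMPLEMENT)[::-1]


def build_dataset_sequence(
    records: list[SequenceRecord],
    label: str,
    append_revcomp: bool = True,
) -> SequenceSet:
    """Concatenate, clean and (by default) append the reverse complement.

    Records are concatenated in file order; the reverse complement of the
    whole concatenated string is appended once at the end (not per record).
    """
    concatenated = clean_sequence("".join(r.seq for r in records))
    if not concatenated:
        raise ValueError(f"empty dataset: no A/C/G/T characters in '{label}'")
    if append_revcomp:
        concatenated = concatenated + reverse_complement(concatenated)
    return SequenceSet(
        label=label,
        sequence=concatenated,
        n_records=len(records),
        revcomp_appended=append_revcomp,
    )


def shred_subsample(
    records: list[SequenceRecord],
    target_length: int,
    seed: int,
    label: str = "subsample",
    append_revcomp: bool = True,
) -> SequenceSet:
    """Shuffle whole records, concatenate, and keep a length-limited prefix.

    This is the procedure for probing how sequence length influences the
    resulting trees: the records (contigs or EST reads) are permuted with a
    seeded RNG, concatenated and cleaned, and the first ``target_length``
    nucleotides are kept before the reverse complement is appended.  If the
    cleaned concatenation is shorter than ``target_length`` the full sequence
    is used and a warning is emitted.
    """
    if target_length < 1:
        raise ValueError(f"target_length must be >= 1, got {target_length}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    concatenated = clean_sequence("".join(records[i].seq for i in order))
    if not concatenated:
        raise ValueError(f"empty dataset: no A/C/G/T characters in '{label}'")
    if len(concatenated) < target_length:
        warnings.warn(
            f"'{label}': cleaned sequence ({len(concatenated)} nt) is shorter "
            f"than target_length ({target_length}); using the full sequence",
            stacklevel=2,
        )
    else:
        concatenated = concatenated[:target_length]
    if append_revcomp:
        concatenated = concatenated + reverse_complement(concatenated)
    return SequenceSet(
        label=label,
        sequence=concatenated,
        n_records=len(records),
        revcomp_appended=append_revcomp,
    )


def write_fasta(ss: SequenceSet, path: str | Path, width: int = 80) -> None:
    """Serialize a :class:`SequenceSet` as a single-record FASTA file."""
    with open(path, "w") as handle:
        handle.write(f">{ss.label}\n")
        for i in range(0, len(ss.sequence), width):
            handle.write(ss.sequence[i : i + width] + "\n")
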