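"""DNA sequence primitives for circular plasmids, plus FASTA/FASTQ I/O.

Plasmids are circular molecules, so an assembly of one has an arbitrary
start coordinate and strand.  Everything downstream (assembly evaluation,
read back-mapping) therefore needs rotation- and strand-invariant sequence
comparison, which this module provides via a canonical rotation (the
lexicographically least string over all rotations of a sequence and of its
reverse complement, computed with Booth's least-rotation algorithm).

Sequences are plain uppercase strings over {A, C, G, T, N}.  All offsets
are 0-based and half-open; only sequences cross module boundaries.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AlphabetError(ValueError):
    """A sequence contains characters outside {A, C, G, T, N}."""


class FastqFormatError(ValueError):
    """Malformed or inconsistent FASTQ input (pair counts, lengths...)."""


def _check_alphabet(s: str) -> str:
    if not DNA_ALPHABET.issuperset(s):
        bad = sorted(set(s) - DNA_ALPHABET)
        raise AlphabetError(f"invalid DNA characters: {bad!r}")
    return s


def revcomp(s: str) -> str:
    """Watson-Crick reverse complement; N maps to N."""
    _check_alphabet(s)
    return s.translate(_COMPLEMENT)[::-1]


def _least_rotation(s: str) -> int:
    """Index of the lexicographically least rotation of ``s`` (Booth)."""
    n = len(s)
    doubled = s + s
    f = [-1] * (2 * n)  # failure function over the doubled string
    k = 0  # least-rotation start candidate
    for j in range(1, 2 * n):
        sj = doubled[j]
        i = f[j - k - 1]
        while i != -1 and sj != doubled[k + i + 1]:
            if sj < doubled[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != doubled[k + i + 1]:
            if sj < doubled[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def canonical_rotation(s: str) -> str:
    """Canonical form of a circular sequence, invariant to rotation and strand.

    Returns the lexicographically smallest string among all rotations of
    ``s`` and all rotations of ``revcomp(s)``.  Rejects empty input and
    sequences containing N (a canonical form is undefined under ambiguity).
    """
    if not s:
        raise ValueError("cannot canonicalize an empty sequence")
    _check_alphabet(s)
    if "N" in s:
        raise ValueError("cannot canonicalize a sequence containing N")
    i = _least_rotation(s)
    fwd = s[i:] + s[:i]
    rc = revcomp(s)
    j = _least_rotation(rc)
    rev = rc[j:] + rc[:j]
    return fwd if fwd <= rev else rev


def circular_equal(a: str, b: str) -> bool:
    """True iff ``a`` and ``b`` are the same circular molecule.

    Equality ignores rotation (arbitrary assembly start) and strand.
    """
    if len(a) != len(b):
        return False
    return canonical_rotation(a) == canonical_rotation(b)


@dataclass
class PlasmidRecord:
    """A named plasmid sequence; ``circular`` is True for all plasmids."""

    id: str
    seq: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("plasmid id must be non-empty")
        if not self.seq:
            raise ValueError("plasmid sequence must be non-empty")
        _check_alphabet(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Contig:
    """An assembled sequence.

    Circular contigs are reported without the redundant (k-1)-base terminal
    overlap: each base of the circle appears exactly once.  ``mean_depth``
    is the mean k-mer depth (x) of the contig's constituent k-mers.
    """

    seq: str
    circular: bool
    mean_depth: float = 0.0

    def __post_init__(self) -> None:
        _check_alphabet(self.seq)
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be non-negative")

    def __len__(self) -> int:
        return len(self.seq)


def circular_match(read: str, contig: Contig) -> bool:
    """Exact substring match of a read (either strand) against a contig.

    For a circular contig the read may span the origin, so the search text
    is the contig sequence extended by its own first ``len(read) - 1``
    bases.  Reads containing N never match: matching is exact only.
    """
    if not read:
        raise ValueError("read must be non-empty")
    if "N" in read:
        return False
    if len(read) > len(contig.seq):
        return False
    if contig.circular:
        text = contig.seq + contig.seq[: len(read) - 1]
    else:
        text = contig.seq
    return read in text or revcomp(read) in text


# ---------------------------------------------------------------------------
# Read containers

PROVENANCE_PRIMARY = "primary"
PROVENANCE_CONTAMINANT = "contaminant"
PROVENANCE_UNKNOWN = "unknown"


@dataclass
class ReadPair:
    """One paired-end read with per-base Phred qualities.

    ``provenance`` records ground truth in simulations (primary vs spiked
    contaminant); real data is ``unknown``.
    """

    id: str
    r1_seq: str
    r2_seq: str
    r1_qual: np.ndarray
    r2_qual: np.ndarray
    provenance: str = PROVENANCE_UNKNOWN

    def __post_init__(self) -> None:
        self.r1_qual = np.asarray(self.r1_qual, dtype=np.int64)
        self.r2_qual = np.asarray(self.r2_qual, dtype=np.int64)
        if len(self.r1_qual) != len(self.r1_seq) or len(self.r2_qual) != len(self.r2_seq):
            raise FastqFormatError(
                f"quality/sequence length mismatch in read {self.id!r}"
            )


@dataclass
class ReadSet:
    """An ordered collection of read pairs from one library."""

    pairs: list[ReadPair] = field(default_factory=list)
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[ReadPair]:
        return iter(self.pairs)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# FASTA / FASTQ I/O (Phred+33; transparent gzip by filename suffix)


def _open_text(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fasta(path: str | Path) -> list[PlasmidRecord]:
    """Read plasmid records from a (possibly gzipped) FASTA file."""
    with _open_text(path, "r") as fh:
        return [
            PlasmidRecord(id=rec.id, seq=str(rec.seq).upper())
            for rec in SeqIO.parse(fh, "fasta")
        ]


def write_fasta(records: Iterable[PlasmidRecord | Contig], path: str | Path) -> None:
    """Write records as FASTA wrapped at 70 columns.

    Contigs get headers ``contig_<i> length=<n> circular=<bool>
    mean_depth=<x>`` so downstream tools can recover circularity.
    """
    seqrecords = []
    for i, rec in enumerate(records):
        if isinstance(rec, Contig):
            rid = f"contig_{i + 1}"
            desc = (
                f"length={len(rec.seq)} circular={str(rec.circular).lower()} "
                f"mean_depth={rec.mean_depth:.1f}"
            )
            seqrecords.append(SeqRecord(Seq(rec.seq), id=rid, description=desc))
        else:
            seqrecords.append(SeqRecord(Seq(rec.seq), id=rec.id, description=""))
    with _open_text(path, "w") as fh:
        FastaWriter(fh, wrap=70).write_file(seqrecords)


def read_fastq_pair(path_r1: str | Path, path_r2: str | Path) -> ReadSet:
    """Read synchronized paired FASTQ files (Phred+33) into a ReadSet."""
    with _open_text(path_r1, "r") as f1:
        recs1 = list(SeqIO.parse(f1, "fastq"))
    with _open_text(path_r2, "r") as f2:
        recs2 = list(SeqIO.parse(f2, "fastq"))
    if len(recs1) != len(recs2):
        raise FastqFormatError(
            f"R1 has {len(recs1)} records but R2 has {len(recs2)}"
        )
    pairs = []
    for r1, r2 in zip(recs1, recs2):
        pairs.append(
            ReadPair(
                id=r1.id,
                r1_seq=str(r1.seq).upper(),
                r2_seq=str(r2.seq).upper(),
                r1_qual=np.array(r1.letter_annotations["phred_quality"]),
                r2_qual=np.array(r2.letter_annotations["phred_quality"]),
            )
        )
    return ReadSet(pairs=pairs, source_id=str(path_r1))


def write_fastq_pair(rs: ReadSet, path_r1: str | Path, path_r2: str | Path) -> None:
    """Write a ReadSet as two synchronized FASTQ files (Phred+33)."""
    with _open_text(path_r1, "w") as f1, _open_text(path_r2, "w") as f2:
        for pair in rs:
            q1 = "".join(chr(q + 33) for q in pair.r1_qual)
            q2 = "".join(chr(q + 33) for q in pair.r2_qual)
            f1.write(f"@{pair.id}\n{pair.r1_seq}\n+\n{q1}\n")
            f2.write(f"@{pair.id}\n{pair.r2_seq}\n+\n{q2}\n")
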