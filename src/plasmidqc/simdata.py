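"""Synthetic plasmids, variants, Illumina-like paired reads, contamination spiking.

This module generates the study conditions the pipeline is validated
against: small circular plasmids (the experimental regime is 2.5-3.3 kb),
paired-end reads at very high raw coverage with a broad per-read quality
distribution, contaminant plasmids differing from the primary by 1-4 SNPs,
a 608 bp indel, or nothing at all (unrelated), and read libraries spiked
with a controlled fraction of contaminant read pairs (up to 50%).

Reads carry a provenance label (primary/contaminant) so simulation
outcomes can be scored against ground truth; the labels ride along through
filtering, subsampling and mixing.

Sequencing errors are substitutions only: the Illumina error profile is
substitution-dominated and the downstream exact-match statistic only needs
match/no-match.  Read quality is a two-class per-pair mixture (good/bad
mean Phred) that reproduces the broad observed distribution of per-read
mean qualities without modelling position-dependent decay.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .seqcore import (
    PROVENANCE_CONTAMINANT,
    PROVENANCE_PRIMARY,
    PlasmidRecord,
    ReadPair,
    ReadSet,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Smallest plasmid length accepted by the generator; anything shorter is
#: not a meaningful assembly target.
MIN_PLASMID_LENGTH = 200

#: Control-plasmid length of the experimental regime (bp).
DEFAULT_PLASMID_LENGTH = 2521

#: Size of the indel distinguishing the insert-less plasmid variant (bp).
DEFAULT_INDEL_LENGTH = 608


@dataclass
class ErrorModel:
    """Read-simulation parameters.

    ``frac_bad_reads`` is the probability that a read *pair* is drawn from
    the low-quality class (both mates share the class, as quality is
    strongly correlated within a cluster); per-base Phred is then normal
    around the class mean (sd 3, clamped to [2, 41]).  Substitutions occur
    per base with probability max(base_error_rate, 10^(-q/10)).
    """

    read_len: int = 150
    insert_mean: int = 300
    insert_sd: float = 30.0
    base_error_rate: float = 0.001
    qual_mean_good: int = 38
    qual_mean_bad: int = 20
    frac_bad_reads: float = 0.3

    def __post_init__(self) -> None:
        if self.insert_mean < self.read_len:
            raise ValueError("insert_mean must be >= read_len")
        if not 0 <= self.base_error_rate < 1:
            raise ValueError("base_error_rate must be in [0, 1)")
        if not 0 <= self.frac_bad_reads <= 1:
            raise ValueError("frac_bad_reads must be in [0, 1]")


@dataclass
class VariantSpec:
    """How a contaminant plasmid differs from the primary.

    kind 'snp' uses ``n_snps`` (1-4 in the experimental regime); 'deletion'
    and 'insertion' use ``length`` (default 608 bp); 'unrelated' generates a
    fresh random plasmid of the same length and GC.
    """

    kind: Literal["snp", "deletion", "insertion", "unrelated"]
    n_snps: int = 1
    length: int = DEFAULT_INDEL_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("snp", "deletion", "insertion", "unrelated"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.kind == "snp" and not 1 <= self.n_snps:
            raise ValueError("n_snps must be >= 1")
        if self.kind in ("deletion", "insertion") and self.length < 1:
            raise ValueError("indel length must be >= 1")


def generate_plasmid(
    length: int = DEFAULT_PLASMID_LENGTH,
    gc: float = 0.5,
    seed: int = 0,
    id: str = "plasmid",
) -> PlasmidRecord:
    """Generate a random circular plasmid with expected GC fraction ``gc``."""
    if length < MIN_PLASMID_LENGTH:
        raise ValueError(
            f"plasmid length {length} < {MIN_PLASMID_LENGTH}: too short to assemble"
        )
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    seq = _BASES[codes].tobytes().decode("ascii")
    return PlasmidRecord(id=id, seq=seq, circular=True)


def apply_variant(p: PlasmidRecord, v: VariantSpec) -> PlasmidRecord:
    """Derive a contaminant plasmid from ``p`` according to ``v``.

    Deterministic under ``v.seed``.  SNP positions are uniform without
    replacement; indel positions are uniform on the circle.
    """
    rng = np.random.default_rng(v.seed)
    n = len(p.seq)
    if v.kind == "snp":
        codes = np.frombuffer(p.seq.encode("ascii"), dtype=np.uint8).copy()
        positions = rng.choice(n, size=v.n_snps, replace=False)
        lookup = {ord(b): i for i, b in enumerate("ACGT")}
        for pos in positions:
            old = lookup[codes[pos]]
            new = (old + rng.integers(1, 4)) % 4
            codes[pos] = _BASES[new]
        seq = codes.tobytes().decode("ascii")
        return PlasmidRecord(id=f"{p.id}_snp{v.n_snps}", seq=seq, circular=True)
    if v.kind == "deletion":
        if v.length >= n:
            raise ValueError(f"deletion of {v.length} bp >= plasmid length {n}")
        start = int(rng.integers(0, n))
        doubled = p.seq + p.seq
        # remove [start, start+length) on the circle; keep the remainder
        seq = doubled[start + v.length : start + n]
        return PlasmidRecord(id=f"{p.id}_del{v.length}", seq=seq, circular=True)
    if v.kind == "insertion":
        start = int(rng.integers(0, n))
        block = _BASES[rng.choice(4, size=v.length)].tobytes().decode("ascii")
        seq = p.seq[:start] + block + p.seq[start:]
        return PlasmidRecord(id=f"{p.id}_ins{v.length}", seq=seq, circular=True)
    # unrelated: fresh random plasmid, same length, same (empirical) GC
    gc = (p.seq.count("G") + p.seq.count("C")) / n
    gc = min(max(gc, 0.01), 0.99)
    rec = generate_plasmid(length=n, gc=gc, seed=v.seed, id=f"{p.id}_unrelated")
    return rec


def simulate_reads(
    p: PlasmidRecord,
    n_pairs: int,
    m: ErrorModel | None = None,
    seed: int = 0,
) -> ReadSet:
    """Simulate FR paired-end reads from a circular plasmid.

    Fragment starts are uniform on the circle (so origin-spanning coverage
    is unbiased) with Gaussian insert length clamped to
    [read_len, len(p)].  R1 is the fragment's 5' prefix; R2 is the reverse
    complement of its 3' suffix.  All pairs are labelled primary.
    """
    m = m or ErrorModel()
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    L = len(p.seq)
    if m.read_len > L:
        raise ValueError(f"read_len {m.read_len} > plasmid length {L}")
    rng = np.random.default_rng(seed)

    starts = rng.integers(0, L, size=n_pairs)
    frags = np.clip(
        np.rint(rng.normal(m.insert_mean, m.insert_sd, size=n_pairs)).astype(np.int64),
        m.read_len,
        L,
    )
    codes2 = np.tile(
        np.frombuffer(p.seq.encode("ascii"), dtype=np.uint8), 2
    )  # doubled circle; frag <= L so start+frag < 2L
    idx = np.arange(m.read_len)
    r1 = codes2[starts[:, None] + idx]
    r2_fwd = codes2[(starts + frags - m.read_len)[:, None] + idx]
    # R2 reports the reverse strand of the fragment's 3' end
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGT", b"TGCA"):
        comp[a] = b
    r2 = comp[r2_fwd[:, ::-1]]

    bad = rng.random(n_pairs) < m.frac_bad_reads
    mean_q = np.where(bad, m.qual_mean_bad, m.qual_mean_good)
    q1 = np.clip(
        np.rint(rng.normal(mean_q[:, None], 3.0, size=r1.shape)), 2, 41
    ).astype(np.int64)
    q2 = np.clip(
        np.rint(rng.normal(mean_q[:, None], 3.0, size=r2.shape)), 2, 41
    ).astype(np.int64)

    def _apply_errors(codes: np.ndarray, q: np.ndarray) -> np.ndarray:
        if m.base_error_rate == 0:
            return codes  # error-free limit: base_error_rate is the master switch
        p_err = np.maximum(m.base_error_rate, 10.0 ** (-q / 10.0))
        hit = rng.random(codes.shape) < p_err
        if hit.any():
            base_idx = np.searchsorted(_BASES, codes[hit])
            shift = rng.integers(1, 4, size=int(hit.sum()))
            codes = codes.copy()
            codes[hit] = _BASES[(base_idx + shift) % 4]
        return codes

    r1 = _apply_errors(r1, q1)
    r2 = _apply_errors(r2, q2)

    pairs = [
        ReadPair(
            id=f"{p.id}_read{i}",
            r1_seq=r1[i].tobytes().decode("ascii"),
            r2_seq=r2[i].tobytes().decode("ascii"),
            r1_qual=q1[i],
            r2_qual=q2[i],
            provenance=PROVENANCE_PRIMARY,
        )
        for i in range(n_pairs)
    ]
    return ReadSet(pairs=pairs, source_id=p.id)


def mix_reads(
    primary: ReadSet,
    contaminant: ReadSet,
    fraction: float,
    total_pairs: int,
    seed: int = 0,
) -> ReadSet:
    """Spike contaminant pairs into a primary library at a set fraction.

    Exactly round(fraction * total_pairs) pairs (banker's rounding) are
    sampled without replacement from ``contaminant`` and relabelled
    contaminant; the remainder come from ``primary``.  Output order is
    shuffled.  Deterministic under ``seed``.
    """
    if not 0 <= fraction <= 0.5:
        raise ValueError("contaminant fraction must be in [0, 0.5]")
    n_contam = int(np.rint(fraction * total_pairs))  # round-half-even
    n_prim = total_pairs - n_contam
    if n_contam > len(contaminant) or n_prim > len(primary):
        raise ValueError(
            f"not enough input pairs: need {n_prim} primary (have {len(primary)}) "
            f"and {n_contam} contaminant (have {len(contaminant)})"
        )
    rng = np.random.default_rng(seed)
    ci = rng.choice(len(contaminant), size=n_contam, replace=False)
    pi = rng.choice(len(primary), size=n_prim, replace=False)

    def _relabel(pair: ReadPair, prov: str) -> ReadPair:
        return ReadPair(
            id=pair.id,
            r1_seq=pair.r1_seq,
            r2_seq=pair.r2_seq,
            r1_qual=pair.r1_qual,
            r2_qual=pair.r2_qual,
            provenance=prov,
        )

    pairs = [_relabel(contaminant.pairs[i], PROVENANCE_CONTAMINANT) for i in ci]
    pairs += [_relabel(primary.pairs[i], PROVENANCE_PRIMARY) for i in pi]
    order = rng.permutation(len(pairs))
    pairs = [pairs[i] for i in order]
    return ReadSet(pairs=pairs, source_id=f"{primary.source_id}+{contaminant.source_id}")


def coverage(n_pairs: int, read_len: int, plasmid_len: int) -> float:
    """Nominal fold coverage: n_pairs * 2 * read_len / plasmid_len."""
    return n_pairs * 2 * read_len / plasmid_len


def pairs_for_coverage(cov: float, read_len: int, plasmid_len: int) -> int:
    """Number of read pairs giving nominal coverage ``cov``."""
    return int(round(cov * plasmid_len / (2 * read_len)))


def write_truth_tsv(rs: ReadSet, path: str | Path) -> None:
    """Write the ground-truth provenance sidecar (read_id <TAB> provenance)."""
    with open(path, "w") as fh:
        fh.write("read_id\tprovenance\n")
        for pair in rs:
            fh.write(f"{pair.id}\t{pair.provenance}\n")
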