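"""Strict read-pair quality filtering and coverage capping.

Very deep short-read runs of small plasmids routinely exceed 1000x
coverage, which paradoxically *hurts* de Bruijn assembly; the pipeline
therefore keeps only a high-quality minority of read pairs and then caps
nominal coverage.  Filtering is whole-read (no trimming): a pair survives
only if BOTH mates meet the mean-quality and length thresholds, keeping
the R1/R2 files synchronized.  An alternative top-fraction mode keeps the
best ceil(fraction * n) pairs ranked by the weaker mate's mean quality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .seqcore import ReadSet


@dataclass
class FilterParams:
    """Filtering and subsampling parameters.

    Threshold mode (default) keeps pairs whose mates both have mean Phred
    >= ``min_mean_q`` and length >= ``min_len``.  If ``top_fraction`` is
    set, rank-based selection is used instead and the thresholds are
    ignored.  ``target_coverage``/``plasmid_len_estimate`` drive the
    coverage cap in :func:`subsample`.
    """

    min_mean_q: float = 36.0
    min_len: int = 125
    top_fraction: float | None = None
    target_coverage: float | None = 500.0
    plasmid_len_estimate: int | None = None

    def __post_init__(self) -> None:
        if self.top_fraction is not None and not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if self.target_coverage is not None and self.target_coverage <= 0:
            raise ValueError("target_coverage must be positive")


#: Coverage band in which plasmid assemblies were observed to be optimal;
#: outside it a warning is appropriate, not a hard failure.
OPTIMAL_COVERAGE_BAND = (113.0, 1030.0)


def mean_phred(qual: np.ndarray) -> float:
    """Arithmetic mean of per-base Phred scores (not error-probability mean)."""
    qual = np.asarray(qual)
    if qual.size == 0:
        raise ValueError("empty quality array")
    return float(qual.mean())


def filter_reads(rs: ReadSet, fp: FilterParams) -> ReadSet:
    """Keep only high-quality read pairs; original order is preserved."""
    if fp.top_fraction is not None:
        n = len(rs)
        if n == 0:
            return ReadSet(pairs=[], source_id=rs.source_id)
        keep_n = math.ceil(fp.top_fraction * n)
        scores = np.array(
            [min(mean_phred(p.r1_qual), mean_phred(p.r2_qual)) for p in rs]
        )
        # stable argsort on -score: ties broken by input order
        ranked = np.argsort(-scores, kind="stable")[:keep_n]
        keep = sorted(ranked)
        return ReadSet(pairs=[rs.pairs[i] for i in keep], source_id=rs.source_id)
    kept = [
        p
        for p in rs
        if len(p.r1_seq) >= fp.min_len
        and len(p.r2_seq) >= fp.min_len
        and mean_phred(p.r1_qual) >= fp.min_mean_q
        and mean_phred(p.r2_qual) >= fp.min_mean_q
    ]
    return ReadSet(pairs=kept, source_id=rs.source_id)


def subsample(
    rs: ReadSet,
    fp: FilterParams,
    seed: int = 0,
    n_pairs: int | None = None,
) -> ReadSet:
    """Cap coverage by sampling pairs without replacement.

    If nominal coverage (n * 2 * mean_read_len / plasmid_len_estimate)
    exceeds ``target_coverage`` the set is downsampled to
    floor(target_coverage * plasmid_len_estimate / (2 * mean_read_len));
    otherwise the input is returned unchanged.  An explicit ``n_pairs``
    overrides the coverage arithmetic.  Relative pair order is preserved.
    """
    if len(rs) == 0:
        return rs
    if n_pairs is None:
        if fp.target_coverage is None or fp.plasmid_len_estimate is None:
            raise ValueError(
                "subsample needs target_coverage and plasmid_len_estimate, "
                "or an explicit n_pairs"
            )
        if fp.plasmid_len_estimate <= 0:
            raise ValueError("plasmid_len_estimate must be positive")
        mean_len = float(
            np.mean([len(p.r1_seq) + len(p.r2_seq) for p in rs]) / 2.0
        )
        cov = len(rs) * 2 * mean_len / fp.plasmid_len_estimate
        if cov <= fp.target_coverage:
            return rs
        n_pairs = int(fp.target_coverage * fp.plasmid_len_estimate / (2 * mean_len))
    if n_pairs <= 0:
        raise ValueError("subsample target must be positive")
    if n_pairs >= len(rs):
        return rs
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(rs), size=n_pairs, replace=False))
    return ReadSet(pairs=[rs.pairs[i] for i in keep], source_id=rs.source_id)


def filter_summary(before: ReadSet, after: ReadSet) -> dict:
    """JSON-ready summary of a filtering step."""
    def _mean_q(rs: ReadSet) -> float | None:
        if len(rs) == 0:
            return None
        return float(
            np.mean([mean_phred(p.r1_qual) + mean_phred(p.r2_qual) for p in rs]) / 2.0
        )

    return {
        "input_pairs": len(before),
        "retained_pairs": len(after),
        "retained_pct": 100.0 * len(after) / len(before) if len(before) else 0.0,
        "mean_quality_before": _mean_q(before),
        "mean_quality_after": _mean_q(after),
    }
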