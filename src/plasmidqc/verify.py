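"""Assembly evaluation and reference-agnostic contamination detection.

Two complementary checks live here.  With a reference available, an
assembly is classified into one of five outcomes: correct (one contig,
circularly identical to the primary reference), matching a known
contaminant, matching neither, fragmented (more than one contig), or no
assembly at all.  Without a reference, the quality signal is the
*mismatch percentage*: the fraction of distinct filtered read sequences
that do not occur exactly anywhere in the assembly (either strand,
origin-spanning allowed).  Even clean libraries leave a baseline of
non-matching reads (sequencing errors survive mean-quality filtering),
but contaminated libraries leave more, so the statistic separates the two
and a one-feature logistic model turns it into a contamination
probability.

The simulation harness at the bottom reruns the full pipeline
(simulate -> spike -> filter -> cap -> assemble -> classify -> score)
across replicates and aggregates per-condition outcome percentages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.stats import mannwhitneyu

from . import qualfilter, simdata
from .assembler import AssemblyParams, AssemblyResult, assemble
from .qualfilter import FilterParams
from .seqcore import PlasmidRecord, ReadSet, circular_equal, circular_match
from .simdata import ErrorModel, VariantSpec


class AssemblyOutcome(Enum):
    CORRECT_PRIMARY = "correct_primary"
    MATCHES_CONTAMINANT = "matches_contaminant"
    MISMATCH = "mismatch"
    FRAGMENTED = "fragmented"
    NO_ASSEMBLY = "no_assembly"


def classify_assembly(
    ar: AssemblyResult,
    primary_ref: PlasmidRecord,
    contaminant_ref: PlasmidRecord | None = None,
) -> AssemblyOutcome:
    """Classify an assembly against references, rotation/strand-invariantly."""
    if ar.n_contigs == 0:
        return AssemblyOutcome.NO_ASSEMBLY
    if ar.n_contigs >= 2:
        return AssemblyOutcome.FRAGMENTED
    contig = ar.contigs[0]
    if circular_equal(contig.seq, primary_ref.seq):
        return AssemblyOutcome.CORRECT_PRIMARY
    if contaminant_ref is not None and circular_equal(contig.seq, contaminant_ref.seq):
        return AssemblyOutcome.MATCHES_CONTAMINANT
    return AssemblyOutcome.MISMATCH


def exact_match_stats(ar: AssemblyResult, filtered: ReadSet) -> tuple[int, int, float]:
    """Back-map distinct filtered reads onto the assembly by exact matching.

    Each mate counts separately; deduplication is on the literal read
    string (a read and its reverse complement are distinct strings —
    matching itself already checks both strands).  A read matches if it
    occurs exactly in ANY contig, circularly for circular contigs.
    Returns (n_distinct, n_matched, mismatch_pct).
    """
    if ar.n_contigs == 0:
        raise ValueError("cannot back-map reads onto an empty assembly")
    if len(filtered) == 0:
        raise ValueError("no filtered reads to back-map")
    distinct: set[str] = set()
    for pair in filtered:
        distinct.add(pair.r1_seq)
        distinct.add(pair.r2_seq)
    n_matched = sum(
        1
        for read in distinct
        if any(circular_match(read, contig) for contig in ar.contigs)
    )
    n_distinct = len(distinct)
    mismatch_pct = 100.0 * (1.0 - n_matched / n_distinct)
    return n_distinct, n_matched, mismatch_pct


@dataclass
class ContaminationReport:
    n_distinct_reads: int
    n_matched: int
    mismatch_pct: float
    probability: float
    calibration_id: str

    def to_dict(self) -> dict:
        return {
            "n_distinct_reads": self.n_distinct_reads,
            "n_matched": self.n_matched,
            "mismatch_pct": self.mismatch_pct,
            "contamination_probability": self.probability,
            "calibration_id": self.calibration_id,
        }


# ---------------------------------------------------------------------------
# Calibration: logistic model on the single mismatch_pct feature


class CalibrationError(ValueError):
    """Degenerate calibration input (empty or non-informative classes)."""


@dataclass
class CalibrationModel:
    """Logistic map from mismatch percentage to contamination probability.

    The slope is constrained non-negative so that a higher mismatch
    percentage can never lower the contamination probability.
    ``training_summary`` keeps the class score distributions for
    diagnostics; ``calibration_id`` names the model in reports.
    """

    intercept: float
    slope: float
    training_summary: dict = field(default_factory=dict)
    n_train: int = 0
    calibration_id: str = "custom"

    def __post_init__(self) -> None:
        if self.slope < 0:
            raise ValueError("slope must be >= 0")

    def probability(self, mismatch_pct: float) -> float:
        z = self.intercept + self.slope * mismatch_pct
        return float(1.0 / (1.0 + np.exp(-z)))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "intercept": self.intercept,
                    "slope": self.slope,
                    "training_summary": self.training_summary,
                    "n_train": self.n_train,
                    "calibration_id": self.calibration_id,
                },
                fh,
                indent=2,
            )
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def default_calibration() -> CalibrationModel:
    """The packaged calibration, trained on simulated clean vs contaminated runs."""
    path = Path(__file__).parent / "data" / "default_calibration.json"
    return CalibrationModel.from_json(path)


def calibrate(
    clean_scores: list[float],
    contam_scores: list[float],
    calibration_id: str = "custom",
    min_per_class: int = 20,
) -> CalibrationModel:
    """Maximum-likelihood logistic fit of contamination on mismatch_pct.

    A tiny ridge penalty keeps the fit finite under perfect separation;
    the slope is bounded below by zero.  Deterministic.
    """
    clean = np.asarray(clean_scores, dtype=float)
    contam = np.asarray(contam_scores, dtype=float)
    if clean.size < min_per_class or contam.size < min_per_class:
        raise CalibrationError(
            f"need at least {min_per_class} scores per class "
            f"(got {clean.size} clean, {contam.size} contaminated)"
        )
    x = np.concatenate([clean, contam])
    y = np.concatenate([np.zeros(clean.size), np.ones(contam.size)])
    if np.ptp(x) == 0 and not (np.ptp(clean) == 0 and np.ptp(contam) == 0):
        raise CalibrationError("constant scores with overlapping classes")
    ridge = 1e-4

    def nll(theta):
        b0, b1 = theta
        z = b0 + b1 * x
        # log(1+exp(z)) - y*z, numerically stable
        val = np.sum(np.logaddexp(0.0, z) - y * z) + ridge * (b0 * b0 + b1 * b1)
        p = 1.0 / (1.0 + np.exp(-z))
        g0 = np.sum(p - y) + 2 * ridge * b0
        g1 = np.sum((p - y) * x) + 2 * ridge * b1
        return val, np.array([g0, g1])

    res = minimize(
        nll,
        x0=np.array([0.0, 0.0]),
        jac=True,
        method="L-BFGS-B",
        bounds=[(None, None), (0.0, None)],
    )
    b0, b1 = res.x
    summary = {
        "clean_mean": float(clean.mean()),
        "clean_sd": float(clean.std(ddof=1)) if clean.size > 1 else 0.0,
        "contam_mean": float(contam.mean()),
        "contam_sd": float(contam.std(ddof=1)) if contam.size > 1 else 0.0,
        "auc": roc_auc(clean_scores, contam_scores),
    }
    return CalibrationModel(
        intercept=float(b0),
        slope=float(max(b1, 0.0)),
        training_summary=summary,
        n_train=int(x.size),
        calibration_id=calibration_id,
    )


def contamination_probability(mismatch_pct: float, cm: CalibrationModel) -> float:
    """Calibrated probability that a library is contaminated."""
    return cm.probability(mismatch_pct)


def roc_auc(clean_scores, contam_scores) -> float:
    """AUC as the rank statistic P(contaminated score > clean score).

    Ties count one half; computed from the Mann-Whitney U statistic.
    """
    clean = np.asarray(clean_scores, dtype=float)
    contam = np.asarray(contam_scores, dtype=float)
    if clean.size == 0 or contam.size == 0:
        raise ValueError("both score lists must be non-empty")
    u = mannwhitneyu(contam, clean, alternative="two-sided").statistic
    return float(u / (clean.size * contam.size))


# ---------------------------------------------------------------------------
# Simulation harness (machine twin of the contamination-spiking table)


@dataclass
class SimulationSummary:
    """Aggregated outcomes of one contamination condition."""

    variant_kind: str
    contamination_fraction: float
    n_reps: int
    pct_correct: float
    pct_fragmented: float
    pct_mismatch_reads: float  # mean mismatch_pct across replicates
    pct_matches_contaminant: float = 0.0
    pct_no_assembly: float = 0.0
    n_errors: int = 0

    def to_row(self) -> dict:
        return {
            "variant_type": self.variant_kind,
            "contamination_pct": 100.0 * self.contamination_fraction,
            "pct_correct": self.pct_correct,
            "pct_fragmented": self.pct_fragmented,
            "mean_mismatch_pct": self.pct_mismatch_reads,
            "n_reps": self.n_reps,
        }


@dataclass
class PipelineParams:
    """Bundled stage parameters for simulation replicates.

    ``raw_coverage`` is the nominal coverage of each simulated library
    before filtering; the experimental regime is >1000x raw, filtered
    down and then capped at ``filter.target_coverage``.  Plasmid lengths
    are drawn uniformly from ``plasmid_len_range`` (the 2521-3294 bp
    regime) unless pinned.
    """

    error_model: ErrorModel = field(default_factory=ErrorModel)
    filter: FilterParams = field(default_factory=FilterParams)
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    raw_coverage: float = 500.0
    plasmid_len_range: tuple[int, int] = (2521, 3294)
    gc: float = 0.5


def run_replicate(
    variant: VariantSpec | None,
    fraction: float,
    seed: int,
    pp: PipelineParams | None = None,
) -> tuple[AssemblyOutcome, float]:
    """One full pipeline replicate; returns (outcome, mismatch_pct).

    Generates a fresh primary plasmid from ``seed``, derives the
    contaminant via ``variant`` (ignored when ``fraction`` is 0),
    simulates both libraries, spikes, filters, caps coverage, assembles
    and classifies.  mismatch_pct is NaN when no contig was produced.
    """
    pp = pp or PipelineParams()
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=6)
    lo, hi = pp.plasmid_len_range
    length = int(rng.integers(lo, hi + 1))
    primary = simdata.generate_plasmid(
        length=length, gc=pp.gc, seed=int(sub_seeds[0]), id=f"primary_{seed}"
    )
    n_pairs = simdata.pairs_for_coverage(
        pp.raw_coverage, pp.error_model.read_len, length
    )
    reads_p = simdata.simulate_reads(
        primary, n_pairs, pp.error_model, seed=int(sub_seeds[1])
    )
    contaminant_ref = None
    if fraction > 0 and variant is not None:
        v = VariantSpec(
            kind=variant.kind,
            n_snps=variant.n_snps,
            length=variant.length,
            seed=int(sub_seeds[2]),
        )
        contaminant_ref = simdata.apply_variant(primary, v)
        n_contam = max(
            int(np.ceil(fraction * n_pairs)) + 10, 1
        )  # only the spiked subset is needed
        reads_c = simdata.simulate_reads(
            contaminant_ref, n_contam, pp.error_model, seed=int(sub_seeds[3])
        )
        mixed = simdata.mix_reads(
            reads_p, reads_c, fraction, n_pairs, seed=int(sub_seeds[4])
        )
    else:
        mixed = reads_p
    fp = FilterParams(
        min_mean_q=pp.filter.min_mean_q,
        min_len=pp.filter.min_len,
        top_fraction=pp.filter.top_fraction,
        target_coverage=pp.filter.target_coverage,
        plasmid_len_estimate=length,
    )
    filtered = qualfilter.filter_reads(mixed, fp)
    capped = qualfilter.subsample(filtered, fp, seed=int(sub_seeds[5]))
    if len(capped) == 0:
        return AssemblyOutcome.NO_ASSEMBLY, float("nan")
    ar = assemble(capped, pp.assembly)
    outcome = classify_assembly(ar, primary, contaminant_ref)
    if ar.n_contigs == 0:
        return outcome, float("nan")
    _, _, mismatch_pct = exact_match_stats(ar, capped)
    return outcome, mismatch_pct


def run_contamination_experiment(
    variant: VariantSpec | None,
    fraction: float,
    n_reps: int,
    base_seed: int,
    pp: PipelineParams | None = None,
) -> SimulationSummary:
    """Run ``n_reps`` independent replicates of one contamination condition.

    Replicates that raise in any stage are tallied separately as errors
    (counted in neither %correct nor %fragmented).  The mismatch column
    is the unweighted mean of per-replicate mismatch percentages.
    """
    if not 0 <= fraction <= 0.5:
        raise ValueError("fraction must be in [0, 0.5]")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    pp = pp or PipelineParams()
    seed_rng = np.random.default_rng(base_seed)
    rep_seeds = seed_rng.integers(0, 2**31 - 1, size=n_reps)
    tally = {o: 0 for o in AssemblyOutcome}
    mismatches: list[float] = []
    n_errors = 0
    for s in rep_seeds:
        try:
            outcome, mm = run_replicate(variant, fraction, int(s), pp)
        except Exception:
            n_errors += 1
            continue
        tally[outcome] += 1
        if np.isfinite(mm):
            mismatches.append(mm)
    kind = variant.kind if (variant is not None and fraction > 0) else "none"
    if kind == "snp":
        kind = f"{variant.n_snps}_snp"
    return SimulationSummary(
        variant_kind=kind,
        contamination_fraction=fraction,
        n_reps=n_reps,
        pct_correct=100.0 * tally[AssemblyOutcome.CORRECT_PRIMARY] / n_reps,
        pct_fragmented=100.0 * tally[AssemblyOutcome.FRAGMENTED] / n_reps,
        pct_mismatch_reads=float(np.mean(mismatches)) if mismatches else float("nan"),
        pct_matches_contaminant=100.0
        * tally[AssemblyOutcome.MATCHES_CONTAMINANT]
        / n_reps,
        pct_no_assembly=100.0 * tally[AssemblyOutcome.NO_ASSEMBLY] / n_reps,
        n_errors=n_errors,
    )


def summaries_to_tsv(summaries: list[SimulationSummary], path: str | Path) -> None:
    """Write condition summaries as a TSV mirroring the contamination table."""
    cols = [
        "variant_type",
        "contamination_pct",
        "pct_correct",
        "pct_fragmented",
        "mean_mismatch_pct",
        "n_reps",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for s in summaries:
            row = s.to_row()
            fh.write(
                "\t".join(
                    f"{row[c]:.2f}" if isinstance(row[c], float) else str(row[c])
                    for c in cols
                )
                + "\n"
            )
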