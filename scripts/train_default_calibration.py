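"""Regenerate the packaged default calibration model.

Trains the mismatch-percentage logistic on simulated cohorts (40 clean
and 40 SNP-contaminated libraries at 20% spiking, cycling 1-4 SNPs) under
a fixed seed, and writes src/plasmidqc/data/default_calibration.json.

Run from the repository root:

    python scripts/train_default_calibration.py
"""

from pathlib import Path

from plasmidqc.cli import simulate_calibration_cohorts
from plasmidqc.verify import calibrate

SEED = 20240901
N_REPS = 40

def main() -> None:
    clean, contam = simulate_calibration_cohorts(N_REPS, SEED)
    cm = calibrate(clean, contam, calibration_id=f"default_sim_seed{SEED}")
    out = Path(__file__).resolve().parent.parent / "src" / "plasmidqc" / "data" / "default_calibration.json"
    cm.to_json(out)
    print(f"wrote {out}")
    print(f"slope={cm.slope:.4f} intercept={cm.intercept:.4f} "
          f"AUC={cm.training_summary['auc']:.3f} "
          f"clean_mean={cm.training_summary['clean_mean']:.2f} "
          f"contam_mean={cm.training_summary['contam_mean']:.2f}")

if __name__ == "__main__":
    main()
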