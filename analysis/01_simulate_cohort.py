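"""Simulate the demonstration cohort.

Generates two synthetic cohorts under results/analysis/:
  * ``null/`` — the stated world (follow-up mean ~11.8 months, no planted
    phenotype-symptom slopes);
  * ``planted/`` — the same world with one planted effect: wake
    accelerometer motor activity predicting the negative dimension with
    slope -1.2 score units per energy unit, per-patient random slopes
    (SD 0.35) and AR(1) month-to-month errors (rho = 0.3).

Both use 12 patients instead of the cohort's 38 to keep the demo's raw
window tables small; the full-size world is exercised by
scripts/acceptance.py.  The planted cohort is the input for 03-05; the
null cohort calibrates the expected false-positive count of the screen.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from phenolmm.config import PipelineConfig
from phenolmm.pipeline import stage_simulate

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"

BASE = {"n_patients": 12}
PLANTED = {
    **BASE,
    "fixed_slopes": {"acc_ste_wake_mean::negative": -1.2},
    "random_slope_sd": 0.35,
    "clip_at_floor": False,
}


def main():
    for name, sim in (("null", dict(BASE)), ("planted", PLANTED)):
        cfg = PipelineConfig(seed=7, out_dir=str(OUT / name), simulate=dict(sim))
        bundle = stage_simulate(cfg, OUT / name)
        print(
            f"{name}: {bundle.truth.n_patients} patients, "
            f"{len(bundle.windows):,} five-minute windows, "
            f"{len(bundle.clinical)} monthly visits "
            f"(mean follow-up {bundle.clinical.groupby('patient_id')['month_index'].max().mean():.1f} months)"
        )


if __name__ == "__main__":
    main()
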