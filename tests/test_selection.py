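"""The 3-step selection driver, covariate screening and interactions."""

import numpy as np
import pandas as pd
import pytest

from phenolmm.exceptions import DataError, EligibilityError
from phenolmm.lmm import LmmSpec, fit_lmm
from phenolmm.selection import (
    SelectionTrace,
    format_p,
    interaction_analysis,
    run_model_selection,
    screen_covariates,
    select_best_model,
    step1_screen,
    table2_like,
)
from phenolmm.simulate import SimulationTruth, generate_monthly_panel

PHENO = "acc_ste_wake_mean"


@pytest.fixture(scope="module")
def planted_panel():
    """Cohort with a strong planted slope of wake motility on the negative
    dimension and nothing else."""
    truth = SimulationTruth(
        n_patients=38,
        fixed_slopes={(PHENO, "negative"): -1.2},
        random_slope_sd=0.0,
        ar1_rho=0.2,
        seed=41,
    )
    return generate_monthly_panel(truth)


class TestStep1Screen:
    def test_double_gate(self, planted_panel):
        traces = step1_screen(planted_panel, phenotypes=(PHENO,), dimensions=("negative", "positive"))
        by_dim = {t.dimension: t for t in traces}
        assert by_dim["negative"].retained
        assert not by_dim["positive"].retained

    def test_gate_reasons_are_recorded(self, planted_panel):
        traces = step1_screen(planted_panel, phenotypes=(PHENO,), dimensions=("positive",))
        (tr,) = traces
        assert tr.reasons  # why the null pair was dropped

    def test_all_missing_phenotype_skipped(self, planted_panel):
        tab = planted_panel.copy()
        tab["rmssd_wake_mean"] = np.nan
        traces = step1_screen(tab, phenotypes=("rmssd_wake_mean",), dimensions=("negative",))
        assert not traces[0].retained and "missing" in traces[0].reasons[0]

    def test_row_order_invariance(self, planted_panel):
        shuffled = planted_panel.sample(frac=1.0, random_state=7).reset_index(drop=True)
        t1 = step1_screen(planted_panel, phenotypes=(PHENO, "rmssd_sleep_mean"))
        t2 = step1_screen(shuffled, phenotypes=(PHENO, "rmssd_sleep_mean"))
        r1 = {(t.phenotype, t.dimension): t.retained for t in t1}
        r2 = {(t.phenotype, t.dimension): t.retained for t in t2}
        assert r1 == r2


class TestSelectBestModel:
    def test_requires_retained_trace(self, planted_panel):
        tr = SelectionTrace(phenotype=PHENO, dimension="positive", retained=False)
        with pytest.raises(DataError):
            select_best_model(tr, planted_panel)

    def test_planted_random_slope_truth_selects_random_slope(self):
        truth = SimulationTruth(
            n_patients=38,
            fixed_slopes={(PHENO, "negative"): -1.2},
            random_slope_sd=1.2, random_intercept_sd=1.0,
            residual_sd=1.0, ar1_rho=0.0, clip_at_floor=False, seed=43,
        )
        panel = generate_monthly_panel(truth)
        (tr,) = step1_screen(panel, phenotypes=(PHENO,), dimensions=("negative",))
        assert tr.retained
        select_best_model(tr, panel)
        assert tr.best_model in ("random_slope", "autocorrelation_plus_random_slope")
        assert tr.step3_lrt.p_value < 0.05

    def test_planted_ar1_only_truth_selects_autocorrelation(self):
        truth = SimulationTruth(
            n_patients=38,
            fixed_slopes={(PHENO, "negative"): -1.2},
            random_slope_sd=0.0, random_intercept_sd=1.0,
            residual_sd=1.5, ar1_rho=0.7, clip_at_floor=False, seed=44,
        )
        panel = generate_monthly_panel(truth)
        (tr,) = step1_screen(panel, phenotypes=(PHENO,), dimensions=("negative",))
        assert tr.retained
        select_best_model(tr, panel)
        assert tr.best_model == "autocorrelation"

    def test_audit_trail_is_complete(self, planted_panel):
        traces = run_model_selection(planted_panel, phenotypes=(PHENO,), dimensions=("negative",))
        (tr,) = traces
        d = tr.to_dict()
        assert d["step1"] and d["step2"] and d["step2_lrt"]
        assert d["best_model"] in (
            "random_intercept", "autocorrelation", "random_slope", "autocorrelation_plus_random_slope"
        )
        t2 = table2_like(traces)
        assert len(t2) == 1 and t2.loc[0, "best_model"] == tr.best_model


class TestCovariateScreen:
    def _panel_with_gender_effect(self):
        truth = SimulationTruth(n_patients=38, seed=47)
        panel = generate_monthly_panel(truth)
        panel[PHENO] = panel[PHENO] + 1.5 * panel["gender"]
        panel["negative"] = panel["negative"] + 2.5 * panel["gender"]
        return panel

    def test_planted_gender_shift_detected_on_both_sides(self):
        panel = self._panel_with_gender_effect()
        screen = screen_covariates(panel, {"gender": "factor"}, phenotypes=(PHENO,), dimensions=("negative",))
        assert screen.eligible("gender", PHENO, "negative")

    def test_null_covariate_rarely_passes(self):
        truth = SimulationTruth(n_patients=38, seed=48)
        panel = generate_monthly_panel(truth)
        rng = np.random.default_rng(0)
        panel["noise_cov"] = rng.normal(size=len(panel))
        screen = screen_covariates(
            panel, {"noise_cov": "continuous"},
            phenotypes=("acc_ste_wake_mean", "gyro_ste_wake_mean", "nn_count_wake_mean", "rmssd_wake_mean"),
        )
        n_tested = int((screen.records["skipped"].isna()).sum())
        n_passed = int(screen.records["passed"].fillna(False).sum())
        assert n_passed <= max(1, 0.2 * n_tested)

    def test_constant_covariate_skipped(self):
        truth = SimulationTruth(n_patients=10, seed=49)
        panel = generate_monthly_panel(truth)
        panel["constant"] = 3.0
        screen = screen_covariates(panel, {"constant": "continuous"}, phenotypes=(PHENO,))
        assert "degenerate" in screen.records.iloc[0]["skipped"]

    def test_three_level_factor_uses_f_test(self):
        truth = SimulationTruth(n_patients=30, seed=50)
        panel = generate_monthly_panel(truth)
        rng = np.random.default_rng(1)
        levels = {p: rng.integers(0, 3) for p in panel["patient_id"].unique()}
        panel["site"] = panel["patient_id"].map(levels)
        screen = screen_covariates(panel, {"site": "factor"}, phenotypes=(PHENO,), dimensions=())
        rec = screen.records.iloc[0]
        assert rec["skipped"] is None and isinstance(rec["df"], tuple)


class TestInteractions:
    def test_ineligible_covariate_raises(self, planted_panel):
        traces = step1_screen(planted_panel, phenotypes=(PHENO,), dimensions=("negative",))
        screen = screen_covariates(planted_panel, {"gender": "factor"},
                                   phenotypes=(PHENO,), dimensions=("negative",))
        if not screen.eligible("gender", PHENO, "negative"):
            with pytest.raises(EligibilityError, match="both"):
                interaction_analysis(traces[0], "gender", planted_panel, screen, kind="factor")

    def test_mediated_effect_is_labelled_confounded(self):
        # the phenotype-outcome link exists only through a shared time trend
        truth = SimulationTruth(n_patients=38, seed=51)
        panel = generate_monthly_panel(truth)
        panel[PHENO] = panel[PHENO] + 0.25 * panel["followup_month"]
        panel["negative"] = panel["negative"] + 0.30 * panel["followup_month"]
        traces = step1_screen(panel, phenotypes=(PHENO,), dimensions=("negative",))
        (tr,) = traces
        assert tr.retained  # the marginal association is real
        select_best_model(tr, panel)
        screen = screen_covariates(panel, {"followup_month": "continuous"},
                                   phenotypes=(PHENO,), dimensions=("negative",))
        assert screen.eligible("followup_month", PHENO, "negative")
        rep = interaction_analysis(tr, "followup_month", panel, screen, kind="continuous")
        assert rep["conclusion"] == "confounded"

    def test_direct_effect_is_labelled_robust(self):
        truth = SimulationTruth(
            n_patients=38, fixed_slopes={(PHENO, "negative"): -1.5},
            random_slope_sd=0.0, ar1_rho=0.0, seed=52,
        )
        panel = generate_monthly_panel(truth)
        panel[PHENO] = panel[PHENO] + 0.20 * panel["followup_month"]
        panel["negative"] = panel["negative"] - 1.5 * 0.20 * panel["followup_month"] + 0.25 * panel["followup_month"]
        traces = step1_screen(panel, phenotypes=(PHENO,), dimensions=("negative",))
        (tr,) = traces
        select_best_model(tr, panel)
        screen = screen_covariates(panel, {"followup_month": "continuous"},
                                   phenotypes=(PHENO,), dimensions=("negative",))
        if screen.eligible("followup_month", PHENO, "negative"):
            rep = interaction_analysis(tr, "followup_month", panel, screen, kind="continuous")
            assert rep["conclusion"] == "robust"


class TestFormatting:
    @pytest.mark.parametrize(
        "p, shown",
        [(0.53, ".53"), (0.0005, "<.001"), (0.005, ".005"), (0.03, ".03"), (0.2, ".20")],
    )
    def test_table_style_p(self, p, shown):
        assert format_p(p) == shown
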