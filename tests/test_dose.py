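"""Sigmoid fitting, the extra sum-of-squares test and the agonist call."""

import math

import numpy as np
import pytest

from orscreen import (
    AgonistCall,
    DoseResponseFit,
    SigmoidParams,
    call_agonist,
    ec50_table,
    extra_ss_test,
    fit_sigmoid,
    predict_sigmoid,
)
from orscreen.schema_io import OdorRecord, ReceptorRecord

LADDER = [-12.0] + list(np.arange(-8.0, -1.75, 0.5))


def _series(params, sigma=0.0, rng=None, reps=3, grid=LADDER):
    rng = rng or np.random.default_rng(0)
    pts = []
    for x in grid:
        y = predict_sigmoid(params, x)
        for _ in range(reps):
            pts.append((x, y + (rng.normal(0, sigma) if sigma else 0.0)))
    return pts


class TestPredictSigmoid:
    def test_midpoint_at_log_ec50(self):
        p = SigmoidParams(bottom=0.2, top=1.4, log_ec50=-5.0)
        assert predict_sigmoid(p, -5.0) == pytest.approx(0.8)

    def test_asymptotes(self):
        p = SigmoidParams(bottom=0.1, top=2.0, log_ec50=-6.0)
        assert predict_sigmoid(p, -40.0) == pytest.approx(0.1, abs=1e-12)
        assert predict_sigmoid(p, 40.0) == pytest.approx(2.0, abs=1e-12)

    def test_plug_in_value(self):
        # bottom 0, top 2, logEC50 -6, hill 1 at x=-5: 2 * 10/11
        p = SigmoidParams(bottom=0.0, top=2.0, log_ec50=-6.0)
        assert predict_sigmoid(p, -5.0) == pytest.approx(2.0 * 10.0 / 11.0, rel=1e-12)

    def test_monotone_and_bounded_for_positive_hill(self):
        p = SigmoidParams(bottom=0.0, top=1.0, log_ec50=-5.0, hill=2.0)
        xs = np.linspace(-12, -2, 101)
        ys = predict_sigmoid(p, xs)
        assert np.all(np.diff(ys) >= 0)
        assert np.all((ys >= 0.0) & (ys <= 1.0))


class TestFitSigmoid:
    def test_noiseless_recovery(self):
        truth = SigmoidParams(bottom=0.15, top=1.25, log_ec50=-5.3)
        fit = fit_sigmoid(_series(truth))
        assert fit.converged
        assert fit.params.bottom == pytest.approx(truth.bottom, abs=1e-6)
        assert fit.params.top == pytest.approx(truth.top, abs=1e-6)
        assert fit.params.log_ec50 == pytest.approx(truth.log_ec50, abs=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_seeded_noisy_recovery_within_tenth_log_unit(self):
        truth = SigmoidParams(bottom=0.0, top=1.0, log_ec50=-5.0)
        pts = _series(truth, sigma=0.02, rng=np.random.default_rng(42))
        fit = fit_sigmoid(pts)
        assert fit.converged
        assert abs(fit.params.log_ec50 - truth.log_ec50) < 0.1
        lo, hi = fit.ci95["log_ec50"]
        assert lo < fit.params.log_ec50 < hi
        assert fit.se["log_ec50"] >= 0.0
        assert fit.df == fit.n_points - 3

    def test_three_points_three_parameters_rejected(self):
        with pytest.raises(ValueError, match="degrees of freedom"):
            fit_sigmoid([(-8.0, 0.0), (-5.0, 0.5), (-2.0, 1.0)])

    def test_flat_data_converges_with_tiny_span(self):
        rng = np.random.default_rng(5)
        pts = [(x, 0.2 + rng.normal(0, 0.01)) for x in LADDER for _ in range(3)]
        fit = fit_sigmoid(pts)
        assert fit.converged
        assert abs(fit.params.span) < 0.2  # bounded by the data's own spread

    def test_variable_hill_mode_recovers_slope(self):
        truth = SigmoidParams(bottom=0.0, top=1.0, log_ec50=-5.0, hill=1.7)
        fit = fit_sigmoid(_series(truth), fix_hill=None)
        assert fit.free_names == ("bottom", "top", "log_ec50", "hill")
        assert fit.params.hill == pytest.approx(1.7, abs=1e-4)

    def test_solution_beats_brute_force_grid(self):
        """Optimizer RSS is <= the best of a 50^3 parameter grid."""
        truth = SigmoidParams(bottom=0.1, top=0.9, log_ec50=-5.5)
        pts = _series(truth, sigma=0.05, rng=np.random.default_rng(7), reps=1)
        fit = fit_sigmoid(pts)
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        bs = np.linspace(-0.5, 1.5, 50)
        ts = np.linspace(-0.5, 1.5, 50)
        es = np.linspace(-9.0, -2.0, 50)
        B, T, E = np.meshgrid(bs, ts, es, indexing="ij")
        occ = 1.0 / (1.0 + 10.0 ** (E[..., None] - x))
        pred = B[..., None] + (T - B)[..., None] * occ
        grid_rss = ((pred - y) ** 2).sum(axis=-1).min()
        assert fit.rss <= grid_rss + 1e-9


class TestExtraSS:
    def test_separated_series_reject(self):
        rng = np.random.default_rng(1)
        receptor = _series(SigmoidParams(0.0, 1.0, -5.0), sigma=0.01, rng=rng)
        vector = [(x, rng.normal(0.0, 0.01)) for x, _ in receptor]
        test = extra_ss_test(receptor, vector)
        assert test.p_value < 1e-6
        assert test.rejected
        assert test.receptor_span > test.vector_span

    def test_identical_duplicated_data_gives_f_zero(self):
        rng = np.random.default_rng(2)
        pts = _series(SigmoidParams(0.1, 0.9, -5.0), sigma=0.05, rng=rng)
        test = extra_ss_test(pts, list(pts))
        assert test.f_stat == pytest.approx(0.0, abs=1e-6)
        assert test.p_value > 0.999
        assert not test.rejected

    def test_degrees_of_freedom_bookkeeping(self):
        rng = np.random.default_rng(3)
        receptor = _series(SigmoidParams(0.0, 1.0, -5.0), sigma=0.05, rng=rng)
        vector = _series(SigmoidParams(0.0, 0.0, -5.0), sigma=0.05, rng=rng)
        test = extra_ss_test(receptor, vector)
        n = len(receptor) + len(vector)
        assert test.df_num == 3  # 6 free params in the split fits vs 3 shared
        assert test.df_den == n - 6

    def test_inverted_span_blocks_rejection(self):
        # the *vector* responds, the receptor does not: p may be small but
        # the one-sided span condition must veto the rejection
        rng = np.random.default_rng(4)
        receptor = [(x, rng.normal(0.0, 0.01)) for x in LADDER for _ in range(3)]
        vector = _series(SigmoidParams(0.0, 1.0, -5.0), sigma=0.01, rng=rng)
        test = extra_ss_test(receptor, vector)
        assert test.p_value < 0.05
        assert not test.rejected

    def test_flat_null_variant_runs(self):
        rng = np.random.default_rng(6)
        receptor = _series(SigmoidParams(0.0, 1.0, -5.0), sigma=0.02, rng=rng)
        vector = [(x, rng.normal(0.0, 0.02)) for x, _ in receptor]
        shared = extra_ss_test(receptor, vector, null_model="shared")
        flat = extra_ss_test(receptor, vector, null_model="flat")
        assert flat.df_num == 5
        assert shared.rejected and flat.rejected


def _fit_stub(bottom, top, log_ec50, se_ec50, ci_gap, converged=True):
    half = ci_gap / 2
    return DoseResponseFit(
        params=SigmoidParams(bottom, top, log_ec50),
        se={"bottom": 0.01, "top": 0.01, "log_ec50": se_ec50},
        ci95={
            "bottom": (bottom - half, bottom + half),
            "top": (top - half, top + half),
            "log_ec50": (log_ec50 - 2 * se_ec50, log_ec50 + 2 * se_ec50),
        },
        rss=0.1,
        df=36,
        n_points=39,
        converged=converged,
        free_names=("bottom", "top", "log_ec50"),
    )


def _test_stub(p_value, receptor_span=1.0, vector_span=0.0, alpha=0.05):
    from orscreen import ExtraSSTest

    return ExtraSSTest(
        f_stat=10.0,
        df_num=3,
        df_den=30,
        p_value=p_value,
        alpha=alpha,
        receptor_span=receptor_span,
        vector_span=vector_span,
    )


class TestCallAgonist:
    def test_all_three_criteria_make_an_agonist(self):
        call = call_agonist(
            _fit_stub(0.0, 1.0, -5.2, se_ec50=0.1, ci_gap=0.1),
            _test_stub(1e-8),
            receptor_id="1001",
            odor_id="2001",
        )
        assert call.is_agonist
        assert call.crit_ci_separation and call.crit_ec50_sd and call.crit_extra_ss
        assert call.reported_log_ec50 == -5

    def test_overlapping_cis_block_the_call(self):
        call = call_agonist(
            _fit_stub(0.0, 0.3, -5.0, se_ec50=0.1, ci_gap=1.0), _test_stub(1e-8)
        )
        assert not call.crit_ci_separation and not call.is_agonist

    def test_ec50_sd_criterion_is_strict(self):
        at_limit = call_agonist(
            _fit_stub(0.0, 1.0, -5.0, se_ec50=1.0, ci_gap=0.1), _test_stub(1e-8)
        )
        assert not at_limit.crit_ec50_sd and not at_limit.is_agonist
        below = call_agonist(
            _fit_stub(0.0, 1.0, -5.0, se_ec50=0.999, ci_gap=0.1), _test_stub(1e-8)
        )
        assert below.crit_ec50_sd

    def test_unconverged_fit_is_never_an_agonist(self):
        fit = _fit_stub(0.0, 1.0, -5.0, se_ec50=0.1, ci_gap=0.1, converged=False)
        call = call_agonist(fit, _test_stub(1e-8))
        assert not call.is_agonist and call.reason is not None

    def test_descending_curve_uses_mirrored_ci_rule(self):
        call = call_agonist(
            _fit_stub(1.0, 0.0, -5.0, se_ec50=0.1, ci_gap=0.1),
            _test_stub(1e-8, receptor_span=-1.0, vector_span=-2.0),
        )
        assert call.crit_ci_separation

    @pytest.mark.parametrize(
        "log_ec50, reported", [(-4.9, -5), (-4.5, -5), (-4.4, -4), (-7.49, -7)]
    )
    def test_reported_ec50_rounds_to_integer_log_units(self, log_ec50, reported):
        call = call_agonist(
            _fit_stub(0.0, 1.0, log_ec50, se_ec50=0.1, ci_gap=0.1), _test_stub(1e-8)
        )
        assert call.reported_log_ec50 == reported


class TestEc50Table:
    def test_no_passing_calls_gives_empty_table(self):
        frame = ec50_table([])
        assert list(frame.columns) == ["OR", "Odor", "EC50", "OdorName", "Gene"]
        assert frame.empty

    def test_passing_rows_join_metadata_and_keep_repeats(self):
        call = call_agonist(
            _fit_stub(0.0, 1.0, -7.8, se_ec50=0.1, ci_gap=0.1),
            _test_stub(1e-8),
            receptor_id="1120",
            odor_id="1309",
        )
        receptors = {"1120": ReceptorRecord("1120", "OR10G7", "ATG")}
        odors = {"1309": OdorRecord("1309", None, "eugenol", 3314, "C")}
        frame = ec50_table([call, call], receptors=receptors, odors=odors)
        assert len(frame) == 2  # independent repeats stay distinct rows
        row = frame.iloc[0]
        assert (row.OR, row.Odor, row.EC50, row.OdorName, row.Gene) == (
            "1120",
            "1309",
            -8,
            "eugenol",
            "OR10G7",
        )


def test_affine_response_equivariance():
    """y -> a*y + b maps (bottom, top) accordingly, leaves log EC50, the F
    statistic and all three criteria unchanged."""
    rng = np.random.default_rng(11)
    truth = SigmoidParams(0.1, 1.1, -5.5)
    receptor = _series(truth, sigma=0.03, rng=rng)
    vector = [(x, rng.normal(0.1, 0.03)) for x, _ in receptor]
    a, b = 2.5, 0.7
    receptor2 = [(x, a * y + b) for x, y in receptor]
    vector2 = [(x, a * y + b) for x, y in vector]

    fit1, fit2 = fit_sigmoid(receptor), fit_sigmoid(receptor2)
    assert fit2.params.bottom == pytest.approx(a * fit1.params.bottom + b, abs=1e-5)
    assert fit2.params.top == pytest.approx(a * fit1.params.top + b, abs=1e-5)
    assert fit2.params.log_ec50 == pytest.approx(fit1.params.log_ec50, abs=1e-5)

    t1 = extra_ss_test(receptor, vector)
    t2 = extra_ss_test(receptor2, vector2)
    assert t2.f_stat == pytest.approx(t1.f_stat, rel=1e-4)

    c1 = call_agonist(fit1, t1)
    c2 = call_agonist(fit2, t2)
    assert (c1.crit_ci_separation, c1.crit_ec50_sd, c1.crit_extra_ss) == (
        c2.crit_ci_separation,
        c2.crit_ec50_sd,
        c2.crit_extra_ss,
    )
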