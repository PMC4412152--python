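"""Sigmoidal dose-response fitting and the three-criterion agonist call.

The concentration-response model is the three-parameter log-logistic
("sigmoidal dose-response") curve in log10 molar units

    y(x) = bottom + (top - bottom) / (1 + 10**(hill * (log_ec50 - x)))

with the Hill slope fixed at 1 by default; a variable-slope four-parameter
mode is available.  No-odor wells enter the fit at x = -12, acting as a
far-left anchor.  Fitting is nonlinear least squares with deterministic
multi-start over candidate log EC50s; standard errors come from the
asymptotic covariance (RSS/df times the inverse Gauss-Newton normal
matrix) and 95% confidence intervals are t-based.

An odorant is called an agonist for a receptor when all three of the
following hold:

1. the 95% confidence intervals of the top and bottom parameters do not
   overlap,
2. the standard deviation (standard error) of the fitted log EC50 is
   strictly less than 1 log unit, and
3. an extra sum-of-squares F test shows the receptor series is activated
   significantly more than the matched empty-vector control series.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .schema_io import DoseWellRecord, OdorRecord, ReceptorRecord

__all__ = [
    "SigmoidParams",
    "DoseResponseFit",
    "ExtraSSTest",
    "AgonistCall",
    "predict_sigmoid",
    "fit_sigmoid",
    "extra_ss_test",
    "call_agonist",
    "ec50_table",
    "analyze_dose_table",
]

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of the log-logistic concentration-response curve."""

    bottom: float
    top: float
    log_ec50: float
    hill: float = 1.0

    @property
    def span(self) -> float:
        return self.top - self.bottom


def predict_sigmoid(params: SigmoidParams, x) -> np.ndarray | float:
    """Model response at log10-molar concentration(s) ``x``.

    Total on all real x: tends to ``bottom`` as x -> -inf and ``top`` as
    x -> +inf, and equals the midpoint at x = log_ec50.
    """
    x = np.asarray(x, dtype=float)
    occ = _occupancy(x, params.log_ec50, params.hill)
    out = params.bottom + (params.top - params.bottom) * occ
    return out if out.ndim else float(out)


def _occupancy(x: np.ndarray, log_ec50: float, hill: float) -> np.ndarray:
    # 1/(1 + 10^(h(e-x))) computed stably for large |e-x|
    z = hill * (log_ec50 - x) * _LN10
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(z))


@dataclass(frozen=True)
class DoseResponseFit:
    """A fitted curve with uncertainties and goodness-of-fit bookkeeping."""

    params: SigmoidParams
    se: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    rss: float
    df: int
    n_points: int
    converged: bool
    free_names: tuple[str, ...]


def _model_and_jac(theta: np.ndarray, x: np.ndarray, fix_hill: float | None):
    if fix_hill is None:
        b, t, e, h = theta
    else:
        b, t, e = theta
        h = fix_hill
    occ = _occupancy(x, e, h)
    y = b + (t - b) * occ
    docc_de = -_LN10 * h * occ * (1.0 - occ)
    cols = [1.0 - occ, occ, (t - b) * docc_de]
    if fix_hill is None:
        docc_dh = -_LN10 * (e - x) * occ * (1.0 - occ)
        cols.append((t - b) * docc_dh)
    return y, np.column_stack(cols)


def _fit_bounds(x: np.ndarray, y: np.ndarray, fix_hill: float | None):
    """Box constraints keeping the fit inside the tested region.

    Bottom and top stay within the observed response range widened by its
    spread, and log EC50 within the tested concentration range plus two
    log units: flat or one-sided data then yields a tame near-degenerate
    fit instead of an unbounded extrapolation.
    """
    spread = max(float(np.ptp(y)), 1e-8)
    lo_resp, hi_resp = float(y.min()) - spread, float(y.max()) + spread
    lo = [lo_resp, lo_resp, float(x.min()) - 2.0]
    hi = [hi_resp, hi_resp, float(x.max()) + 2.0]
    if fix_hill is None:
        lo.append(0.05)
        hi.append(10.0)
    return np.array(lo), np.array(hi)


def _starting_points(x: np.ndarray, y: np.ndarray, fix_hill: float | None, bounds):
    """Deterministic multi-start grid: extrema for bottom/top, log EC50 at
    each midpoint of consecutive observed concentrations."""
    lo, hi = bounds
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    ux = np.unique(xs)
    b0 = float(np.mean(ys[xs == ux[0]]))
    t0 = float(np.mean(ys[xs == ux[-1]]))
    if math.isclose(b0, t0):
        b0, t0 = float(np.min(ys)), float(np.max(ys))
    mids = (ux[:-1] + ux[1:]) / 2.0 if ux.size > 1 else ux
    for e0 in mids:
        theta = [b0, t0, float(e0)]
        if fix_hill is None:
            theta.append(1.0)
        yield np.clip(np.array(theta), lo + 1e-12, hi - 1e-12)


def fit_sigmoid(
    points: Sequence[tuple[float, float]] | tuple[np.ndarray, np.ndarray],
    fix_hill: float | None = 1.0,
) -> DoseResponseFit:
    """Least-squares fit of the sigmoid to (log10 M, response) points.

    ``fix_hill=1`` (default) fits the classic three-parameter curve;
    ``fix_hill=None`` frees the Hill slope (four parameters).  Requires at
    least free-parameters + 1 points over >= 2 distinct concentrations so
    the residual degrees of freedom are positive.  Non-convergence is
    reported through ``converged=False``, never as an exception.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (x, y)")
    x, y = pts[:, 0], pts[:, 1]
    n_free = 3 if fix_hill is not None else 4
    names = ("bottom", "top", "log_ec50") + (() if fix_hill is not None else ("hill",))
    n = x.size
    df = n - n_free
    if df < 1:
        raise ValueError(
            f"{n} points with {n_free} free parameters leaves no residual "
            "degrees of freedom"
        )
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct concentrations")

    def residuals(theta):
        return _model_and_jac(theta, x, fix_hill)[0] - y

    def jac(theta):
        return _model_and_jac(theta, x, fix_hill)[1]

    bounds = _fit_bounds(x, y, fix_hill)
    best = None
    for theta0 in _starting_points(x, y, fix_hill, bounds):
        res = optimize.least_squares(
            residuals,
            theta0,
            jac=jac,
            method="trf",
            bounds=bounds,
            max_nfev=200 * n_free,
        )
        if best is None or res.cost < best.cost:
            best = res
    assert best is not None
    theta = best.x
    rss = float(2.0 * best.cost)
    converged = bool(best.success) and bool(np.all(np.isfinite(theta)))

    jtj = best.jac.T @ best.jac
    sigma2 = rss / df
    with np.errstate(invalid="ignore"):
        cov = sigma2 * np.linalg.pinv(jtj)
        se_vec = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    tcrit = float(stats.t.ppf(0.975, df))
    se = {name: float(s) for name, s in zip(names, se_vec)}
    ci95 = {
        name: (float(est - tcrit * s), float(est + tcrit * s))
        for name, est, s in zip(names, theta, se_vec)
    }
    if fix_hill is None:
        params = SigmoidParams(*map(float, theta))
    else:
        params = SigmoidParams(*map(float, theta), hill=float(fix_hill))
    return DoseResponseFit(
        params=params,
        se=se,
        ci95=ci95,
        rss=rss,
        df=df,
        n_points=int(n),
        converged=converged,
        free_names=names,
    )


@dataclass(frozen=True)
class ExtraSSTest:
    """Extra sum-of-squares F test of receptor vs empty-vector series.

    The null model fits one shared sigmoid to the pooled points; the
    alternative fits separate sigmoids per condition.  Rejection is
    one-sided: besides p < alpha, the receptor fit's span (top - bottom)
    must exceed the vector fit's span, so a control responding *more*
    than the receptor never counts as activation.
    """

    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    alpha: float
    receptor_span: float
    vector_span: float
    degenerate: bool = False

    @property
    def rejected(self) -> bool:
        return self.p_value < self.alpha and self.receptor_span > self.vector_span


def extra_ss_test(
    receptor_points,
    vector_points,
    alpha: float = 0.05,
    fix_hill: float | None = 1.0,
    null_model: str = "shared",
) -> ExtraSSTest:
    """Compare receptor and empty-vector dose series via nested fits.

    ``null_model="shared"`` (default) pools both series under one sigmoid;
    ``null_model="flat"`` is a sensitivity variant whose null is a single
    constant response.
    """
    fit_r = fit_sigmoid(receptor_points, fix_hill=fix_hill)
    fit_v = fit_sigmoid(vector_points, fix_hill=fix_hill)
    k = len(fit_r.free_names)
    rss_alt = fit_r.rss + fit_v.rss
    n_total = fit_r.n_points + fit_v.n_points
    p_alt = 2 * k
    df_alt = n_total - p_alt

    pooled = np.vstack([np.asarray(receptor_points, float), np.asarray(vector_points, float)])
    if null_model == "shared":
        fit_null = fit_sigmoid(pooled, fix_hill=fix_hill)
        rss_null, p_null = fit_null.rss, k
    elif null_model == "flat":
        y = pooled[:, 1]
        rss_null, p_null = float(((y - y.mean()) ** 2).sum()), 1
    else:
        raise ValueError(f"unknown null_model {null_model!r}")

    df_num = p_alt - p_null
    if rss_alt <= 0.0:
        return ExtraSSTest(
            f_stat=float("inf"),
            df_num=df_num,
            df_den=df_alt,
            p_value=0.0,
            alpha=alpha,
            receptor_span=fit_r.params.span,
            vector_span=fit_v.params.span,
            degenerate=True,
        )
    f = max(0.0, (rss_null - rss_alt) / df_num / (rss_alt / df_alt))
    p = float(stats.f.sf(f, df_num, df_alt))
    return ExtraSSTest(
        f_stat=float(f),
        df_num=df_num,
        df_den=df_alt,
        p_value=p,
        alpha=alpha,
        receptor_span=fit_r.params.span,
        vector_span=fit_v.params.span,
    )


@dataclass(frozen=True)
class AgonistCall:
    receptor_id: str
    odor_id: str
    crit_ci_separation: bool
    crit_ec50_sd: bool
    crit_extra_ss: bool
    is_agonist: bool
    log_ec50: float | None
    reported_log_ec50: int | None
    reason: str | None = None


def _round_toward_negative(x: float) -> int:
    # nearest integer; exact halves go to the more negative (more potent) side
    return int(math.ceil(x - 0.5))


def call_agonist(
    fit: DoseResponseFit,
    test: ExtraSSTest,
    sd_limit: float = 1.0,
    receptor_id: str = "",
    odor_id: str = "",
) -> AgonistCall:
    """Apply the composite three-criterion agonist decision to one pair."""
    if not fit.converged:
        return AgonistCall(
            receptor_id=receptor_id,
            odor_id=odor_id,
            crit_ci_separation=False,
            crit_ec50_sd=False,
            crit_extra_ss=False,
            is_agonist=False,
            log_ec50=None,
            reported_log_ec50=None,
            reason="fit did not converge",
        )
    lo_b, hi_b = fit.ci95["bottom"]
    lo_t, hi_t = fit.ci95["top"]
    if fit.params.top >= fit.params.bottom:
        ci_sep = lo_t > hi_b
    else:
        ci_sep = lo_b > hi_t
    ec50_sd_ok = fit.se["log_ec50"] < sd_limit  # strictly less than 1 log unit
    extra_ok = test.rejected
    is_agonist = ci_sep and ec50_sd_ok and extra_ok
    return AgonistCall(
        receptor_id=receptor_id,
        odor_id=odor_id,
        crit_ci_separation=ci_sep,
        crit_ec50_sd=ec50_sd_ok,
        crit_extra_ss=extra_ok,
        is_agonist=is_agonist,
        log_ec50=fit.params.log_ec50,
        reported_log_ec50=_round_toward_negative(fit.params.log_ec50),
    )


def ec50_table(
    calls: Iterable[AgonistCall],
    receptors: dict[str, ReceptorRecord] | None = None,
    odors: dict[str, OdorRecord] | None = None,
) -> pd.DataFrame:
    """EC50 summary table: one row per passing call, integer log EC50s.

    Repeated experiments on the same pair stay as separate rows.  Odor
    names and gene labels are joined from the metadata records when given.
    """
    rows = []
    for c in calls:
        if not c.is_agonist:
            continue
        rows.append(
            {
                "OR": c.receptor_id,
                "Odor": c.odor_id,
                "EC50": c.reported_log_ec50,
                "OdorName": odors[c.odor_id].odor_name
                if odors and c.odor_id in odors
                else "",
                "Gene": receptors[c.receptor_id].gene_label
                if receptors and c.receptor_id in receptors
                else "",
            }
        )
    return pd.DataFrame(rows, columns=["OR", "Odor", "EC50", "OdorName", "Gene"])


def analyze_dose_table(
    records: Sequence[DoseWellRecord],
    vector_id: str = "vector",
    alpha: float = 0.05,
    sd_limit: float = 1.0,
    fix_hill: float | None = 1.0,
    null_model: str = "shared",
) -> list[tuple[AgonistCall, DoseResponseFit, ExtraSSTest]]:
    """Fit and call every receptor/odor pair in a dose-response table.

    For each odor, the empty-vector control series (rows whose receptor is
    ``vector_id``) is the comparison series for every receptor tested with
    that odor.  Pairs without a matched vector series are skipped with a
    warning.
    """
    by_pair: dict[tuple[str, str], list[DoseWellRecord]] = {}
    for r in records:
        by_pair.setdefault((r.receptor_id, r.odor_id), []).append(r)
    out = []
    for (receptor_id, odor_id) in sorted(by_pair):
        if receptor_id == vector_id:
            continue
        vec = by_pair.get((vector_id, odor_id))
        if not vec:
            warnings.warn(
                f"no empty-vector series for odor {odor_id!r}; "
                f"skipping {receptor_id}/{odor_id}",
                stacklevel=2,
            )
            continue
        rec_pts = [(r.concentration_log10M, r.normalized_luc) for r in by_pair[(receptor_id, odor_id)]]
        vec_pts = [(r.concentration_log10M, r.normalized_luc) for r in vec]
        fit = fit_sigmoid(rec_pts, fix_hill=fix_hill)
        test = extra_ss_test(
            rec_pts, vec_pts, alpha=alpha, fix_hill=fix_hill, null_model=null_model
        )
        call = call_agonist(
            fit, test, sd_limit=sd_limit, receptor_id=receptor_id, odor_id=odor_id
        )
        out.append((call, fit, test))
    return out
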