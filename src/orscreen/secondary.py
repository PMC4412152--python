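"""Secondary-screen concentration-effect filter.

Each receptor/odor pair selected from the primary screen is retested in
triplicate at no-odor, 1, 10 and 100 µM.  A one-way fixed-effects ANOVA
across the concentration groups (the no-odor control enters as a factor
level) asks whether the response depends on concentration at all; pairs
with p below alpha advance to dose-response characterization.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .schema_io import SecondaryWellRecord

__all__ = ["SecondaryResult", "anova_oneway", "secondary_pass", "filter_secondary"]


@dataclass(frozen=True)
class SecondaryResult:
    receptor_id: str
    odor_id: str
    groups: dict[float, tuple[float, ...]]
    f_stat: float
    p_value: float
    passed: bool
    degenerate: bool = False


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F and p across concentration groups.

    F = MS_between / MS_within with (k-1, N-k) degrees of freedom.  Two
    degenerate cases are defined rather than errors: all observations
    identical across all groups gives (F, p) = (0, 1); zero within-group
    variance with real between-group differences gives the limit
    (F, p) = (inf, 0).
    """
    if len(groups) < 2:
        raise ValueError(f"need >= 2 groups, got {len(groups)}")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 1 for a in arrays):
        raise ValueError("every group needs at least one observation")
    n_total = sum(a.size for a in arrays)
    if n_total - len(arrays) < 1:
        raise ValueError("no residual degrees of freedom for the within term")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_within == 0:
        return float("inf"), 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*arrays)
    # equal group means can give a tiny negative F (and NaN p) in floating
    # arithmetic; clamp to the F >= 0 domain
    f = max(float(f), 0.0)
    if np.isnan(p):
        p = stats.f.sf(f, len(arrays) - 1, n_total - len(arrays))
    return f, float(p)


def secondary_pass(
    pair_records: Sequence[SecondaryWellRecord], alpha: float = 0.05
) -> SecondaryResult:
    """Assemble one pair's wells into concentration groups and test them.

    All records must share a receptor and odor.  A missing no-odor group
    only triggers a warning; the ANOVA runs on whatever concentration
    groups are present (>= 2 required).
    """
    if not pair_records:
        raise ValueError("no records for pair")
    receptors = {r.receptor_id for r in pair_records}
    odors = {r.odor_id for r in pair_records}
    if len(receptors) != 1 or len(odors) != 1:
        raise ValueError(
            f"records mix pairs: receptors {sorted(receptors)}, odors {sorted(odors)}"
        )
    grouped: dict[float, list[float]] = defaultdict(list)
    for r in pair_records:
        grouped[r.concentration_uM].append(r.normalized_luc)
    if len(grouped) < 2:
        raise ValueError("need >= 2 distinct concentrations")
    if 0.0 not in grouped:
        warnings.warn(
            f"pair {receptors.copy().pop()}/{odors.copy().pop()} has no "
            "no-odor group; testing available concentrations only",
            stacklevel=2,
        )
    concs = sorted(grouped)
    f, p = anova_oneway([grouped[c] for c in concs])
    return SecondaryResult(
        receptor_id=receptors.pop(),
        odor_id=odors.pop(),
        groups={c: tuple(grouped[c]) for c in concs},
        f_stat=f,
        p_value=p,
        passed=p < alpha,
        degenerate=not np.isfinite(f),
    )


def filter_secondary(
    records: Sequence[SecondaryWellRecord],
    alpha: float = 0.05,
    correction: str | None = None,
) -> list[SecondaryResult]:
    """Run the ANOVA filter over every receptor/odor pair in a table.

    ``correction="fdr_bh"`` applies Benjamini-Hochberg across pairs before
    the pass decision; the default applies none, testing each pair at
    ``alpha`` on its own.
    """
    by_pair: dict[tuple[str, str], list[SecondaryWellRecord]] = defaultdict(list)
    for r in records:
        by_pair[(r.receptor_id, r.odor_id)].append(r)
    results = [
        secondary_pass(by_pair[key], alpha=alpha) for key in sorted(by_pair)
    ]
    if correction is None:
        return results
    from statsmodels.stats.multitest import multipletests

    reject, _, _, _ = multipletests(
        [r.p_value for r in results], alpha=alpha, method=correction
    )
    return [
        SecondaryResult(
            receptor_id=r.receptor_id,
            odor_id=r.odor_id,
            groups=r.groups,
            f_stat=r.f_stat,
            p_value=r.p_value,
            passed=bool(rej),
            degenerate=r.degenerate,
        )
        for r, rej in zip(results, reject)
    ]
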