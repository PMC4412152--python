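"""Cross-stage validation by ROC analysis, and the end-to-end pipeline.

Each screening stage should predict the next: primary-screen deltas for
secondary-screen passes, and secondary-screen F statistics for agonist
calls.  Both are summarised as ROC curves whose AUC equals the normalized
Mann-Whitney U statistic (tie-aware), so AUC 0.5 is chance and 1.0 is
perfect ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dose import AgonistCall, DoseResponseFit, ExtraSSTest, analyze_dose_table
from .normalize import (
    PlateStandardization,
    ScreenScore,
    rank_and_select,
    score_primary_screen,
)
from .schema_io import (
    DoseWellRecord,
    PlateLayout,
    PrimaryWellRecord,
    SecondaryWellRecord,
)
from .secondary import SecondaryResult, filter_secondary

__all__ = ["RocCurve", "roc_curve", "PipelineConfig", "PipelineResult", "run_screen_pipeline"]


@dataclass(frozen=True)
class RocCurve:
    """A tie-grouped ROC curve: one vertex per distinct score, plus (0,0)."""

    points: tuple[tuple[float, float], ...]
    auc: float
    n_pos: int
    n_neg: int


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> RocCurve:
    """ROC curve of a continuous score against a boolean outcome.

    Thresholds sweep the distinct score values from high to low; tied
    scores contribute a single vertex.  The AUC is the trapezoidal area,
    which for this construction equals U / (n_pos * n_neg) with the
    standard half-credit for ties.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")
    from sklearn.metrics import roc_curve as _sk_roc

    fpr, tpr, _ = _sk_roc(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(
        points=tuple((float(f), float(t)) for f, t in zip(fpr, tpr)),
        auc=auc,
        n_pos=n_pos,
        n_neg=n_neg,
    )


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the three-stage screen analysis."""

    layout: PlateLayout = field(default_factory=PlateLayout)
    fraction: float = 0.05
    per_receptor_cap: int = 10
    alpha_secondary: float = 0.05
    alpha_dose: float = 0.05
    sd_limit: float = 1.0
    vector_id: str = "vector"
    fix_hill: float | None = 1.0
    exclude_receptors: tuple[str, ...] = ("vector",)


@dataclass(frozen=True)
class PipelineResult:
    hits: tuple[ScreenScore, ...]
    failed_plates: tuple[PlateStandardization, ...]
    secondary_results: tuple[SecondaryResult, ...]
    dose_results: tuple[tuple[AgonistCall, DoseResponseFit, ExtraSSTest], ...]
    roc_primary_to_secondary: RocCurve | None
    roc_secondary_to_agonist: RocCurve | None

    @property
    def agonist_calls(self) -> tuple[AgonistCall, ...]:
        return tuple(c for c, _, _ in self.dose_results)


def run_screen_pipeline(
    raw_primary: Sequence[PrimaryWellRecord],
    raw_secondary: Sequence[SecondaryWellRecord],
    raw_dose: Sequence[DoseWellRecord],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run normalization -> ranking -> ANOVA filter -> dose-response calls.

    Stages execute in order on whatever records each stage's table
    provides; the two cross-stage ROC curves are computed where both a
    score and its downstream label exist for at least one positive and
    one negative pair (otherwise they are None).  Empty inputs yield
    empty outputs.
    """
    config = config or PipelineConfig()

    if raw_primary:
        scores, failed = score_primary_screen(
            raw_primary, config.layout, exclude_receptors=config.exclude_receptors
        )
        hits = rank_and_select(scores, config.fraction, config.per_receptor_cap)
    else:
        hits, failed = [], []

    secondary_results = (
        filter_secondary(raw_secondary, alpha=config.alpha_secondary)
        if raw_secondary
        else []
    )

    dose_results = (
        analyze_dose_table(
            raw_dose,
            vector_id=config.vector_id,
            alpha=config.alpha_dose,
            sd_limit=config.sd_limit,
            fix_hill=config.fix_hill,
        )
        if raw_dose
        else []
    )

    roc_a = _stage_roc(
        {(h.receptor_id, h.odor_id): h.delta for h in hits},
        {(r.receptor_id, r.odor_id): r.passed for r in secondary_results},
    )
    roc_c = _stage_roc(
        {(r.receptor_id, r.odor_id): r.f_stat for r in secondary_results},
        {(c.receptor_id, c.odor_id): c.is_agonist for c, _, _ in dose_results},
    )
    return PipelineResult(
        hits=tuple(hits),
        failed_plates=tuple(failed),
        secondary_results=tuple(secondary_results),
        dose_results=tuple(dose_results),
        roc_primary_to_secondary=roc_a,
        roc_secondary_to_agonist=roc_c,
    )


def _stage_roc(scores_by_pair: dict, labels_by_pair: dict) -> RocCurve | None:
    common = sorted(scores_by_pair.keys() & labels_by_pair.keys())
    if not common:
        return None
    scores = [scores_by_pair[k] for k in common]
    finite = [s for s in scores if np.isfinite(s)]
    cap = (max(finite) + 1.0) if finite else 1.0
    scores = [s if np.isfinite(s) else cap for s in scores]  # inf F beats all
    labels = [labels_by_pair[k] for k in common]
    if all(labels) or not any(labels):
        return None
    return roc_curve(scores, labels)
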