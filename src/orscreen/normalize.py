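"""Primary-screen normalization, plate standardization and hit selection.

Raw firefly luciferase counts are divided by the constitutive Renilla
counts of the same well, cancelling transfection-efficiency and viability
differences.  Each plate is then standardized by the on-plate Olfr544
standard: the scale factor is the mean standard-well ratio under its
agonist minus the mean under diluent, so after division that difference
is exactly 1 on every healthy plate and responses are comparable across
plates and days.  Each receptor's response on the no-odor baseline plate
of the run is subtracted from its response to every odor, and the
resulting deltas are ranked; the top fraction of receptor/odor pairs
(capped per receptor) moves on to the secondary screen.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .schema_io import PlateLayout, PrimaryWellRecord

__all__ = [
    "PlateStandardization",
    "ScreenScore",
    "normalized_luc",
    "plate_scale",
    "standardize_plate",
    "baseline_subtract",
    "rank_and_select",
    "score_primary_run",
    "score_primary_screen",
]


def normalized_luc(luc_counts: float, rl_counts: float) -> float:
    """Firefly/Renilla ratio for one well; the well-level normalization."""
    if luc_counts < 0:
        raise ValueError(f"luc_counts must be non-negative, got {luc_counts}")
    if rl_counts <= 0:
        raise ValueError(
            f"rl_counts must be positive (dead or failed well), got {rl_counts}"
        )
    return luc_counts / rl_counts


@dataclass(frozen=True)
class PlateStandardization:
    """Per-plate scale factor derived from the Olfr544 standard wells."""

    plate_id: str
    scale_s: float

    @property
    def failed(self) -> bool:
        """A non-positive scale means the standard did not respond."""
        return not self.scale_s > 0


def plate_scale(
    standard_agonist_wells: Sequence[float],
    standard_diluent_wells: Sequence[float],
    plate_id: str = "",
) -> PlateStandardization:
    """Scale factor: mean agonist-challenged minus mean diluent standard ratio.

    Dividing every ratio on the plate by this factor sets the standard
    difference to exactly 1.  A non-positive factor flags the plate as
    failed (to be excluded and logged), it is not an exception.
    """
    if not standard_agonist_wells or not standard_diluent_wells:
        raise ValueError("need at least one standard well in each arm")
    s = sum(standard_agonist_wells) / len(standard_agonist_wells) - sum(
        standard_diluent_wells
    ) / len(standard_diluent_wells)
    return PlateStandardization(plate_id=plate_id, scale_s=s)


def standardize_plate(
    ratios: Mapping[int, float], standardization: PlateStandardization
) -> dict[int, float]:
    """Divide every well ratio on a plate by the plate's scale factor."""
    if standardization.failed:
        raise ValueError(
            f"plate {standardization.plate_id!r} failed standardization "
            f"(scale {standardization.scale_s})"
        )
    s = standardization.scale_s
    return {w: r / s for w, r in ratios.items()}


@dataclass(frozen=True)
class ScreenScore:
    """A receptor x odor primary-screen result after the full normalization."""

    receptor_id: str
    odor_id: str
    standardized_response: float
    baseline_response: float
    rank: int | None = None
    selected: bool = False

    @property
    def delta(self) -> float:
        return self.standardized_response - self.baseline_response


def baseline_subtract(
    odor_plate_scores: Mapping[str, float],
    baseline_plate_scores: Mapping[str, float],
) -> tuple[dict[str, float], list[str]]:
    """Per-receptor odor-minus-baseline deltas for one plate pair.

    Returns ``(deltas, missing)`` where ``missing`` lists receptors present
    on only one of the two plates (reported, never silently dropped).
    """
    common = odor_plate_scores.keys() & baseline_plate_scores.keys()
    missing = sorted(
        (odor_plate_scores.keys() | baseline_plate_scores.keys()) - common
    )
    deltas = {
        r: odor_plate_scores[r] - baseline_plate_scores[r] for r in common
    }
    return deltas, missing


def _selection_key(score: ScreenScore) -> tuple:
    # delta descending, then lexicographic ids for reproducible ties
    return (-score.delta, score.receptor_id, score.odor_id)


def rank_and_select(
    scores: Sequence[ScreenScore],
    fraction: float = 0.05,
    per_receptor_cap: int = 10,
) -> list[ScreenScore]:
    """Rank pairs by delta and select the screen's hits.

    The budget is ``floor(fraction * N)`` pairs.  A pair is selected iff
    its overall rank is within the budget *and* it is among the top
    ``per_receptor_cap`` deltas for its receptor; pairs excluded by the
    cap are not backfilled by lower-ranked pairs.  Ties are broken by
    (delta descending, receptor id, odor id) so selection is deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if per_receptor_cap < 1:
        raise ValueError(f"per_receptor_cap must be >= 1, got {per_receptor_cap}")
    for s in scores:
        if not math.isfinite(s.delta):
            raise ValueError(f"non-finite delta for {s.receptor_id}/{s.odor_id}")
    n = len(scores)
    budget = math.floor(fraction * n)
    ordered = sorted(scores, key=_selection_key)
    per_receptor_rank: dict[str, int] = defaultdict(int)
    out = []
    for rank, score in enumerate(ordered, start=1):
        per_receptor_rank[score.receptor_id] += 1
        selected = (
            rank <= budget and per_receptor_rank[score.receptor_id] <= per_receptor_cap
        )
        out.append(replace(score, rank=rank, selected=selected))
    return out


# ---------------------------------------------------------------------------
# Scoring whole runs from raw well records
# ---------------------------------------------------------------------------


def _plate_ratios(records: Sequence[PrimaryWellRecord]) -> dict[int, float]:
    return {
        r.well_index: normalized_luc(r.luc_counts, r.rl_counts) for r in records
    }


def score_primary_run(
    records: Sequence[PrimaryWellRecord],
    layout: PlateLayout | None = None,
) -> tuple[list[ScreenScore], list[PlateStandardization]]:
    """Score one screening run (a 12-plate set sharing a transfection plate).

    The baseline plate is recognised by its test wells all carrying the
    no-odor sentinel.  Every plate — the baseline included — is
    standardized by its own standard wells.  Returns the per-pair scores
    and the standardizations of any failed plates (excluded from scoring).

    Raises if no baseline plate is present or if the baseline plate itself
    fails standardization (no other plate in the run can then be scored).
    """
    layout = layout or PlateLayout()
    by_plate: dict[str, list[PrimaryWellRecord]] = defaultdict(list)
    for r in records:
        by_plate[r.plate_id].append(r)

    test_set = set(layout.test_wells)
    baseline_scores: dict[str, float] | None = None
    odor_plates: list[tuple[str, str, dict[str, float]]] = []
    failed: list[PlateStandardization] = []

    for plate_id, plate_records in sorted(by_plate.items()):
        ratios = _plate_ratios(plate_records)
        std = plate_scale(
            [ratios[w] for w in layout.standard_agonist_wells if w in ratios],
            [ratios[w] for w in layout.standard_diluent_wells if w in ratios],
            plate_id=plate_id,
        )
        test_records = [r for r in plate_records if r.well_index in test_set]
        is_baseline = bool(test_records) and all(r.is_no_odor for r in test_records)
        if std.failed:
            failed.append(std)
            if is_baseline:
                raise ValueError(
                    f"baseline plate {plate_id!r} failed standardization; "
                    "run cannot be scored"
                )
            continue
        standardized = standardize_plate(ratios, std)
        receptor_scores = {
            r.receptor_id: standardized[r.well_index] for r in test_records
        }
        if is_baseline:
            if baseline_scores is not None:
                raise ValueError("run contains more than one baseline plate")
            baseline_scores = receptor_scores
        else:
            odors = {r.odor_id for r in test_records}
            if len(odors) != 1:
                raise ValueError(
                    f"plate {plate_id!r} mixes odors {sorted(odors)} in test wells"
                )
            odor_plates.append((plate_id, odors.pop(), receptor_scores))

    if baseline_scores is None:
        raise ValueError("run has no baseline (all no-odor) plate")

    scores: list[ScreenScore] = []
    for _plate_id, odor_id, receptor_scores in odor_plates:
        deltas, _missing = baseline_subtract(receptor_scores, baseline_scores)
        for receptor_id in receptor_scores.keys() & deltas.keys():
            scores.append(
                ScreenScore(
                    receptor_id=receptor_id,
                    odor_id=odor_id,
                    standardized_response=receptor_scores[receptor_id],
                    baseline_response=baseline_scores[receptor_id],
                )
            )
    return scores, failed


def score_primary_screen(
    records: Sequence[PrimaryWellRecord],
    layout: PlateLayout | None = None,
    exclude_receptors: Iterable[str] = (),
) -> tuple[list[ScreenScore], list[PlateStandardization]]:
    """Score a whole primary screen: one run per date, pooled across runs.

    Replicated receptor/odor measurements within a run are averaged before
    ranking; runs (dates) are scored independently and their pair scores
    pooled.  ``exclude_receptors`` removes e.g. empty-vector padding wells
    from the ranked output.
    """
    by_date: dict = defaultdict(list)
    for r in records:
        by_date[r.date].append(r)
    excluded = set(exclude_receptors)
    pooled: list[ScreenScore] = []
    failed_all: list[PlateStandardization] = []
    for date in sorted(by_date):
        scores, failed = score_primary_run(by_date[date], layout)
        failed_all.extend(failed)
        grouped: dict[tuple[str, str], list[ScreenScore]] = defaultdict(list)
        for s in scores:
            if s.receptor_id not in excluded:
                grouped[(s.receptor_id, s.odor_id)].append(s)
        for (receptor_id, odor_id), reps in grouped.items():
            pooled.append(
                ScreenScore(
                    receptor_id=receptor_id,
                    odor_id=odor_id,
                    standardized_response=sum(r.standardized_response for r in reps)
                    / len(reps),
                    baseline_response=sum(r.baseline_response for r in reps)
                    / len(reps),
                )
            )
    return pooled, failed_all
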