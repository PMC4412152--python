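"""Ground-truthed synthetic screens in the deposited data schemas.

The generator emulates the structure of the real screen so every pipeline
stage is testable without the deposit: runs of twelve 96-well plates
sharing one transfection layout (one all-diluent baseline plate plus
eleven odor plates), 85 test wells per plate, five broadly tuned control
receptors and six Olfr544 standard wells (three challenged with 10 µM
nonanedioic acid, three with diluent).

The generative model for a well is

    luc = plate_gain * well_efficiency * max(0, baseline_r
            + efficacy * occupancy(conc; EC50) + Gaussian noise)
    rl  = well_efficiency * rl_mean * (1 + Gaussian noise)

with receptor occupancy ``conc / (conc + EC50)`` (Hill slope 1, matching
the fitted model so recovery tests are well-posed).  Sparse receptor/odor
pairs carry a latent log EC50 and efficacy; all other pairs have zero
efficacy.  Plate gain and per-well transfection efficiency are lognormal
and cancel under the Renilla normalization and plate standardization —
which is exactly what the analysis relies on.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .schema_io import (
    NO_ODOR,
    DoseWellRecord,
    PlateLayout,
    PrimaryWellRecord,
    SecondaryWellRecord,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "make_truth",
    "simulate_primary_run",
    "simulate_primary_screen",
    "simulate_secondary",
    "simulate_dose_response",
    "write_truth",
    "read_truth",
]

#: Default dose ladder, log10 molar: 10 nM to 10 mM in half-log steps.
DOSE_GRID_LOG10M = tuple(np.arange(-8.0, -1.75, 0.5))


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the simulated screen.

    Defaults mirror the real screen: 511 receptors x 73 odorants, odors
    applied at 100 µM in the primary screen, a {no-odor, 1, 10, 100 µM}
    secondary ladder, a 10 nM - 10 mM dose ladder plus a no-odor anchor,
    and triplicate wells everywhere past the primary screen.
    """

    n_receptors: int = 511
    n_odors: int = 73
    odors_per_run: int = 11
    primary_concentration_uM: float = 100.0
    secondary_ladder_uM: tuple[float, ...] = (0.0, 1.0, 10.0, 100.0)
    dose_grid_log10M: tuple[float, ...] = DOSE_GRID_LOG10M
    replicates: int = 3
    agonist_density: float = 0.005
    # latent agonist parameters
    log_ec50_range: tuple[float, float] = (-8.0, -4.0)
    efficacy_range: tuple[float, float] = (0.8, 1.5)
    # noise model (response units unless noted)
    noise_sigma: float = 0.05
    well_efficiency_sigma: float = 0.15  # lognormal sigma, dimensionless
    plate_gain_sigma: float = 0.2  # lognormal sigma, dimensionless
    rl_noise_sigma: float = 0.03  # relative
    luc_gain_mean: float = 1e4  # photons per response unit
    rl_mean: float = 1e4  # photons
    # constitutive baselines (response units)
    baseline_mean: float = 0.2
    baseline_sigma: float = 0.3  # lognormal sigma across receptors
    vector_baseline: float = 0.05
    # on-plate controls
    standard_receptor_id: str = "Olfr544"
    standard_odor_id: str = "2999"  # nonanedioic (azelaic) acid
    standard_concentration_uM: float = 10.0
    standard_log_ec50: float = -6.0
    standard_efficacy: float = 1.2
    standard_baseline: float = 0.3
    broad_receptor_ids: tuple[str, ...] = (
        "Olfr1079",
        "OR2W1",
        "Olfr1377",
        "Olfr73",
        "Olfr1341",
    )
    broad_efficacy: float = 0.6
    broad_log_ec50: float = -5.0
    vector_id: str = "vector"
    layout: PlateLayout = field(default_factory=PlateLayout)
    start_date: _dt.date = _dt.date(2013, 1, 7)

    def __post_init__(self) -> None:
        if not 0.0 <= self.agonist_density <= 1.0:
            raise ValueError(
                f"agonist_density must be in [0, 1], got {self.agonist_density}"
            )

    @property
    def receptor_ids(self) -> list[str]:
        # deposit-style opaque integer IDs starting at 1001
        return [str(1001 + i) for i in range(self.n_receptors)]

    @property
    def odor_ids(self) -> list[str]:
        return [str(2001 + j) for j in range(self.n_odors)]


@dataclass
class SimTruth:
    """Latent state of a simulated screen, sufficient to score any output."""

    agonist_pairs: dict[tuple[str, str], tuple[float, float]]  # (logEC50, efficacy)
    receptor_baselines: dict[str, float]
    plate_gains: dict[str, float] = field(default_factory=dict)
    well_efficiencies: dict[tuple[str, int], float] = field(default_factory=dict)
    noise_sigma: float = 0.05

    def is_agonist(self, receptor_id: str, odor_id: str) -> bool:
        return (receptor_id, odor_id) in self.agonist_pairs


def make_truth(config: SimConfig, seed: int) -> SimTruth:
    """Draw the latent truth: sparse agonist pairs and receptor baselines."""
    rng = np.random.default_rng(seed)
    receptors = config.receptor_ids
    odors = config.odor_ids
    mask = rng.random((len(receptors), len(odors))) < config.agonist_density
    log_ec50 = rng.uniform(*config.log_ec50_range, size=mask.shape)
    efficacy = rng.uniform(*config.efficacy_range, size=mask.shape)
    pairs = {
        (receptors[i], odors[j]): (float(log_ec50[i, j]), float(efficacy[i, j]))
        for i, j in zip(*np.nonzero(mask))
    }
    baselines = {
        r: float(b)
        for r, b in zip(
            receptors,
            config.baseline_mean
            * np.exp(rng.normal(0.0, config.baseline_sigma, len(receptors))),
        )
    }
    baselines[config.standard_receptor_id] = config.standard_baseline
    for b in config.broad_receptor_ids:
        baselines[b] = config.baseline_mean
    baselines[config.vector_id] = config.vector_baseline
    return SimTruth(
        agonist_pairs=pairs,
        receptor_baselines=baselines,
        noise_sigma=config.noise_sigma,
    )


def _occupancy(conc_M: float, log_ec50: float) -> float:
    if conc_M <= 0:
        return 0.0
    ec50 = 10.0**log_ec50
    return conc_M / (conc_M + ec50)


def _pair_effect(
    config: SimConfig, truth: SimTruth, receptor_id: str, odor_id: str
) -> tuple[float, float]:
    """(efficacy, log_ec50) of a receptor/odor pair, controls included."""
    if receptor_id == config.standard_receptor_id:
        if odor_id == config.standard_odor_id:
            return config.standard_efficacy, config.standard_log_ec50
        return 0.0, 0.0
    if receptor_id in config.broad_receptor_ids:
        return config.broad_efficacy, config.broad_log_ec50
    if receptor_id == config.vector_id:
        return 0.0, 0.0
    le = truth.agonist_pairs.get((receptor_id, odor_id))
    if le is None:
        return 0.0, 0.0
    log_ec50, efficacy = le
    return efficacy, log_ec50


def _response(
    config: SimConfig,
    truth: SimTruth,
    rng: np.random.Generator,
    receptor_id: str,
    odor_id: str,
    conc_M: float,
) -> float:
    base = truth.receptor_baselines.get(receptor_id, config.baseline_mean)
    efficacy, log_ec50 = _pair_effect(config, truth, receptor_id, odor_id)
    resp = base + efficacy * _occupancy(conc_M, log_ec50)
    if config.noise_sigma > 0:
        resp += rng.normal(0.0, config.noise_sigma)
    return max(resp, 0.0)


def _counts(
    config: SimConfig,
    rng: np.random.Generator,
    gain: float,
    well_eff: float,
    resp: float,
) -> tuple[float, float]:
    luc = gain * well_eff * resp
    rl_noise = (
        rng.normal(0.0, config.rl_noise_sigma) if config.rl_noise_sigma > 0 else 0.0
    )
    rl = well_eff * config.rl_mean * (1.0 + rl_noise)
    return max(luc, 0.0), max(rl, 1.0)


def simulate_primary_run(
    config: SimConfig,
    truth: SimTruth,
    seed: int,
    receptors: Sequence[str] | None = None,
    odors: Sequence[str] | None = None,
    run_id: str = "R01",
    date: _dt.date | None = None,
) -> list[PrimaryWellRecord]:
    """Simulate one screening run: a baseline plate plus one plate per odor.

    All plates of the run share the receptor-to-well assignment (they come
    from the same transfection master plate).  Test wells left over when
    fewer than 85 receptors are supplied are padded with the empty-vector
    control.  The baseline plate's test wells carry the no-odor sentinel.
    """
    rng = np.random.default_rng(seed)
    layout = config.layout
    receptors = list(receptors if receptors is not None else config.receptor_ids)
    n_test = len(layout.test_wells)
    if len(receptors) > n_test:
        raise ValueError(f"at most {n_test} receptors per run, got {len(receptors)}")
    receptors = receptors + [config.vector_id] * (n_test - len(receptors))
    odors = list(odors if odors is not None else config.odor_ids[: config.odors_per_run])
    date = date or config.start_date

    # plate 0 is the baseline; odor plates follow in the given odor order
    plates: list[tuple[str, str | None]] = [(f"{run_id}-B", None)]
    plates += [(f"{run_id}-{odor}", odor) for odor in odors]

    records: list[PrimaryWellRecord] = []
    for plate_id, plate_odor in plates:
        gain = config.luc_gain_mean * (
            math.exp(rng.normal(0.0, config.plate_gain_sigma))
            if config.plate_gain_sigma > 0
            else 1.0
        )
        truth.plate_gains[plate_id] = gain
        for well in range(1, 97):
            well_eff = (
                math.exp(rng.normal(0.0, config.well_efficiency_sigma))
                if config.well_efficiency_sigma > 0
                else 1.0
            )
            truth.well_efficiencies[(plate_id, well)] = well_eff
            if well in layout.standard_agonist_wells:
                receptor = config.standard_receptor_id
                odor = config.standard_odor_id
                conc_uM: object = config.standard_concentration_uM
            elif well in layout.standard_diluent_wells:
                receptor = config.standard_receptor_id
                odor = config.standard_odor_id
                conc_uM = NO_ODOR
            elif well in layout.broad_wells:
                receptor = config.broad_receptor_ids[
                    layout.broad_wells.index(well) % len(config.broad_receptor_ids)
                ]
                odor = plate_odor if plate_odor is not None else "none"
                conc_uM = (
                    config.primary_concentration_uM if plate_odor is not None else NO_ODOR
                )
            else:  # test well
                receptor = receptors[layout.test_wells.index(well)]
                odor = plate_odor if plate_odor is not None else "none"
                conc_uM = (
                    config.primary_concentration_uM if plate_odor is not None else NO_ODOR
                )
            conc_M = 0.0 if conc_uM is NO_ODOR else conc_uM * 1e-6
            resp = _response(config, truth, rng, receptor, odor, conc_M)
            luc, rl = _counts(config, rng, gain, well_eff, resp)
            records.append(
                PrimaryWellRecord(
                    plate_id=plate_id,
                    well_index=well,
                    concentration_uM=conc_uM,
                    luc_counts=luc,
                    rl_counts=rl,
                    receptor_id=receptor,
                    odor_id=odor,
                    date=date,
                )
            )
    return records


def simulate_primary_screen(
    config: SimConfig, seed: int
) -> tuple[list[PrimaryWellRecord], SimTruth]:
    """Simulate the full primary screen.

    Receptors are split into blocks of 85 (one transfection layout each)
    and odors into blocks of 11; every receptor block is run against every
    odor block, each such run on its own date with its own baseline plate.
    """
    truth = make_truth(config, seed)
    rng = np.random.default_rng(seed + 1)
    receptors = config.receptor_ids
    odors = config.odor_ids
    n_test = len(config.layout.test_wells)
    receptor_blocks = [
        receptors[i : i + n_test] for i in range(0, len(receptors), n_test)
    ]
    odor_blocks = [
        odors[j : j + config.odors_per_run]
        for j in range(0, len(odors), config.odors_per_run)
    ]
    records: list[PrimaryWellRecord] = []
    run = 0
    for rb_idx, rblock in enumerate(receptor_blocks):
        for ob_idx, oblock in enumerate(odor_blocks):
            run += 1
            records.extend(
                simulate_primary_run(
                    config,
                    truth,
                    seed=int(rng.integers(2**31)),
                    receptors=rblock,
                    odors=oblock,
                    run_id=f"R{run:03d}",
                    date=config.start_date + _dt.timedelta(days=run - 1),
                )
            )
    return records, truth


def simulate_secondary(
    pairs: Iterable[tuple[str, str]],
    config: SimConfig,
    truth: SimTruth,
    seed: int,
    date: _dt.date | None = None,
) -> list[SecondaryWellRecord]:
    """Triplicate wells at the secondary ladder for each selected pair.

    No-odor rows carry concentration 0 together with the pair's odor id so
    controls pair with their matched experiments.  Pairs absent from the
    truth behave as non-agonists.
    """
    rng = np.random.default_rng(seed)
    date = date or (config.start_date + _dt.timedelta(days=60))
    records: list[SecondaryWellRecord] = []
    for receptor_id, odor_id in pairs:
        for conc_uM in config.secondary_ladder_uM:
            for _ in range(config.replicates):
                resp = _response(
                    config, truth, rng, receptor_id, odor_id, conc_uM * 1e-6
                )
                records.append(
                    SecondaryWellRecord(
                        date=date,
                        receptor_id=receptor_id,
                        odor_id=odor_id,
                        concentration_uM=conc_uM,
                        normalized_luc=resp,
                    )
                )
    return records


def simulate_dose_response(
    pairs: Iterable[tuple[str, str]],
    config: SimConfig,
    truth: SimTruth,
    seed: int,
    date: _dt.date | None = None,
) -> list[DoseWellRecord]:
    """Triplicate dose series plus a matched empty-vector series per odor.

    Concentrations span the dose ladder in log10 molar with the no-odor
    condition at -12; the vector series has zero efficacy by construction.
    """
    rng = np.random.default_rng(seed)
    date = date or (config.start_date + _dt.timedelta(days=90))
    grid = (-12.0,) + tuple(config.dose_grid_log10M)
    records: list[DoseWellRecord] = []
    vector_done: set[str] = set()
    for receptor_id, odor_id in pairs:
        series = [(receptor_id, odor_id)]
        if odor_id not in vector_done:
            series.append((config.vector_id, odor_id))
            vector_done.add(odor_id)
        for rid, oid in series:
            for x in grid:
                conc_M = 0.0 if x == -12.0 else 10.0**x
                for _ in range(config.replicates):
                    resp = _response(config, truth, rng, rid, oid, conc_M)
                    records.append(
                        DoseWellRecord(
                            concentration_log10M=x,
                            normalized_luc=resp,
                            receptor_id=rid,
                            odor_id=oid,
                            date=date,
                        )
                    )
    return records


# ---------------------------------------------------------------------------
# Truth round-trip
# ---------------------------------------------------------------------------


def write_truth(truth: SimTruth, path: str | Path) -> Path:
    """Write the planted agonist pairs as a tab-separated truth table."""
    frame = pd.DataFrame(
        [
            {"OR": r, "Odor": o, "LogEC50": le, "Efficacy": eff}
            for (r, o), (le, eff) in sorted(truth.agonist_pairs.items())
        ],
        columns=["OR", "Odor", "LogEC50", "Efficacy"],
    )
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_truth(path: str | Path) -> dict[tuple[str, str], tuple[float, float]]:
    """Read a truth table back into the agonist-pair mapping."""
    frame = pd.read_csv(path, sep="\t", dtype={"OR": str, "Odor": str})
    return {
        (row.OR, row.Odor): (float(row.LogEC50), float(row.Efficacy))
        for row in frame.itertuples(index=False)
    }
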