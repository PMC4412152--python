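"""Readers and writers for the five screen data-record dialects.

The screen deposits five tab-separated tables: raw primary-screen wells,
normalized secondary-screen wells, dose-response wells, receptor clone
metadata and odorant metadata.  Each table kind has a fixed column set
(order-insensitive on read) and uses sentinel concentration codes:

* primary screen: ``9999`` µM means no odor was applied,
* secondary screen: ``0`` µM means no odor (rows still carry an odor label
  so controls pair with their matched experiments),
* dose-response: concentration is log10 molarity and ``-12`` codes the
  no-odor condition.

Wells of a 96-well plate are numbered row-major, 1 at the upper-left
corner (A1) through 96 at the lower-right (H12), so well 85 is the
lower-left corner (H1).
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

__all__ = [
    "NO_ODOR",
    "SchemaError",
    "ParseError",
    "ValidationError",
    "PrimaryWellRecord",
    "SecondaryWellRecord",
    "DoseWellRecord",
    "ReceptorRecord",
    "OdorRecord",
    "PlateLayout",
    "RECORD_COLUMNS",
    "read_record_table",
    "write_record_table",
    "well_position",
    "well_index",
]


class SchemaError(ValueError):
    """Header of a record table does not match the expected column set."""


class ParseError(ValueError):
    """A cell could not be converted to the expected type."""


class ValidationError(ValueError):
    """A parsed value violates a record invariant (e.g. RL counts <= 0)."""


class _NoOdorType:
    """Singleton sentinel for the no-odor condition of the primary screen."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NO_ODOR"


#: Sentinel marking primary-screen wells challenged with diluent only.
NO_ODOR = _NoOdorType()

Concentration = Union[float, _NoOdorType]

#: Concentration (log10 M) coding the no-odor condition in dose tables.
DOSE_NO_ODOR_LOG10M = -12.0

#: Literal written for the primary-screen no-odor sentinel.
_PRIMARY_NO_ODOR_LITERAL = "9999"


@dataclass(frozen=True)
class PrimaryWellRecord:
    """One raw primary-screen well: identity plus dual-reporter counts."""

    plate_id: str
    well_index: int
    concentration_uM: Concentration
    luc_counts: float
    rl_counts: float
    receptor_id: str
    odor_id: str
    date: _dt.date

    @property
    def is_no_odor(self) -> bool:
        return self.concentration_uM is NO_ODOR


@dataclass(frozen=True)
class SecondaryWellRecord:
    """One secondary-screen well (already Luc/RL normalized)."""

    date: _dt.date
    receptor_id: str
    odor_id: str
    concentration_uM: float
    normalized_luc: float

    @property
    def is_no_odor(self) -> bool:
        return self.concentration_uM == 0.0


@dataclass(frozen=True)
class DoseWellRecord:
    """One dose-response well; concentration in log10 molar, -12 = no odor."""

    concentration_log10M: float
    normalized_luc: float
    receptor_id: str
    odor_id: str
    date: _dt.date

    @property
    def is_no_odor(self) -> bool:
        return self.concentration_log10M == DOSE_NO_ODOR_LOG10M


@dataclass(frozen=True)
class ReceptorRecord:
    """A receptor clone: ID, gene label with variants, nucleotide sequence."""

    receptor_id: str
    gene_label: str
    nucleotide_seq: str

    @property
    def length_divisible_by_3(self) -> bool:
        """Flag (not an error) for sequences that are not whole codons."""
        return len(self.nucleotide_seq) % 3 == 0


@dataclass(frozen=True)
class OdorRecord:
    """An odorant: ID, CAS number, common name, PubChem CID, SMILES."""

    odor_id: str
    cas_number: str | None
    odor_name: str
    cid: int | None
    smiles: str


# ---------------------------------------------------------------------------
# 96-well plate coordinates and layout
# ---------------------------------------------------------------------------

_ROWS = "ABCDEFGH"
_N_COLS = 12


def well_position(index: int) -> tuple[str, int]:
    """Map a 1-based well index to (row letter, column) on a 96-well plate.

    Enumeration is row-major: well 1 is A1 (upper left), well 12 is A12,
    well 85 is H1 (lower left) and well 96 is H12.
    """
    if not 1 <= index <= 96:
        raise ValueError(f"well index must be in 1..96, got {index}")
    r, c = divmod(index - 1, _N_COLS)
    return _ROWS[r], c + 1


def well_index(row: str, column: int) -> int:
    """Inverse of :func:`well_position`."""
    r = _ROWS.find(row.upper())
    if r < 0 or not 1 <= column <= _N_COLS:
        raise ValueError(f"invalid well position {(row, column)!r}")
    return r * _N_COLS + column


@dataclass(frozen=True)
class PlateLayout:
    """Which wells of a 96-well screen plate hold tests, standards, controls.

    The default layout reserves wells 1-85 for test receptors and wells
    86-96 for controls: five broadly tuned receptors, three Olfr544
    standard wells challenged with its agonist (10 µM nonanedioic acid)
    and three Olfr544 standard wells challenged with diluent.
    """

    test_wells: tuple[int, ...] = tuple(range(1, 86))
    broad_wells: tuple[int, ...] = (86, 87, 88, 89, 90)
    standard_agonist_wells: tuple[int, ...] = (91, 92, 93)
    standard_diluent_wells: tuple[int, ...] = (94, 95, 96)
    vector_wells: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        groups = [
            self.test_wells,
            self.broad_wells,
            self.standard_agonist_wells,
            self.standard_diluent_wells,
            self.vector_wells,
        ]
        flat = [w for g in groups for w in g]
        if len(set(flat)) != len(flat):
            raise ValueError("plate layout wells overlap between roles")
        for w in flat:
            if not 1 <= w <= 96:
                raise ValueError(f"layout well index {w} outside 1..96")
        if not self.standard_agonist_wells or not self.standard_diluent_wells:
            raise ValueError("layout needs at least one standard well per arm")

    @property
    def control_wells(self) -> dict[int, str]:
        """Mapping well index -> control role for the non-test wells."""
        roles: dict[int, str] = {}
        roles.update({w: "broad" for w in self.broad_wells})
        roles.update({w: "standard_agonist" for w in self.standard_agonist_wells})
        roles.update({w: "standard_diluent" for w in self.standard_diluent_wells})
        roles.update({w: "vector" for w in self.vector_wells})
        return roles


# ---------------------------------------------------------------------------
# Parsing helpers
# ---------------------------------------------------------------------------

RECORD_COLUMNS: dict[str, tuple[str, ...]] = {
    "primary": ("Plate", "Well", "Concentration", "Luc", "RL", "OR", "Odor", "Date"),
    "secondary": ("Date", "OR", "Odor", "Concentration", "NormalizedLuc"),
    "dose": ("Concentration", "NormLuc", "OR", "Odor", "Date"),
    "receptor": ("OR", "Gene", "NucleotideSeq"),
    "odor": ("Odor", "CASRegistryNum", "OdorName", "CID", "SMILES"),
}

_RECORD_TYPES = {
    "primary": PrimaryWellRecord,
    "secondary": SecondaryWellRecord,
    "dose": DoseWellRecord,
    "receptor": ReceptorRecord,
    "odor": OdorRecord,
}


def _to_float(text: str, *, row: int, column: str) -> float:
    # the deposit prints the Unicode minus sign for negative numbers
    cleaned = text.strip().replace("−", "-")
    try:
        return float(cleaned)
    except ValueError:
        raise ParseError(
            f"row {row}: column {column!r}: cannot parse {text!r} as a number"
        ) from None


def _to_date(text: str, *, row: int) -> _dt.date:
    """Parse MM/DD/YY (two-digit years mapped to 2000-2099) or MM/DD/YYYY."""
    parts = text.strip().split("/")
    if len(parts) != 3:
        raise ParseError(f"row {row}: cannot parse date {text!r} (expect MM/DD/YY)")
    try:
        m, d, y = (int(p) for p in parts)
    except ValueError:
        raise ParseError(f"row {row}: cannot parse date {text!r}") from None
    if y < 100:
        y += 2000
    try:
        return _dt.date(y, m, d)
    except ValueError as exc:
        raise ParseError(f"row {row}: invalid date {text!r}: {exc}") from None


def _fmt_date(date: _dt.date) -> str:
    return f"{date.month:02d}/{date.day:02d}/{date.year % 100:02d}"


def _fmt_num(x: float) -> str:
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def _parse_primary(cells: dict[str, str], row: int) -> PrimaryWellRecord:
    widx = int(_to_float(cells["Well"], row=row, column="Well"))
    if not 1 <= widx <= 96:
        raise ValidationError(f"row {row}: well index {widx} outside 1..96")
    conc_text = cells["Concentration"].strip()
    conc: Concentration
    if conc_text == _PRIMARY_NO_ODOR_LITERAL:
        conc = NO_ODOR
    else:
        conc = _to_float(conc_text, row=row, column="Concentration")
        if conc < 0:
            raise ValidationError(f"row {row}: negative concentration {conc}")
    luc = _to_float(cells["Luc"], row=row, column="Luc")
    rl = _to_float(cells["RL"], row=row, column="RL")
    if luc < 0:
        raise ValidationError(f"row {row}: negative Luc counts {luc}")
    if rl <= 0:
        raise ValidationError(f"row {row}: RL counts must be positive, got {rl}")
    return PrimaryWellRecord(
        plate_id=cells["Plate"].strip(),
        well_index=widx,
        concentration_uM=conc,
        luc_counts=luc,
        rl_counts=rl,
        receptor_id=cells["OR"].strip(),
        odor_id=cells["Odor"].strip(),
        date=_to_date(cells["Date"], row=row),
    )


def _parse_secondary(cells: dict[str, str], row: int) -> SecondaryWellRecord:
    conc = _to_float(cells["Concentration"], row=row, column="Concentration")
    if conc < 0:
        raise ValidationError(f"row {row}: negative concentration {conc}")
    norm = _to_float(cells["NormalizedLuc"], row=row, column="NormalizedLuc")
    return SecondaryWellRecord(
        date=_to_date(cells["Date"], row=row),
        receptor_id=cells["OR"].strip(),
        odor_id=cells["Odor"].strip(),
        concentration_uM=conc,
        normalized_luc=norm,
    )


def _parse_dose(cells: dict[str, str], row: int) -> DoseWellRecord:
    conc = _to_float(cells["Concentration"], row=row, column="Concentration")
    if not -12.0 <= conc <= -2.0:
        raise ValidationError(
            f"row {row}: dose concentration {conc} outside log10-M range [-12, -2]"
        )
    return DoseWellRecord(
        concentration_log10M=conc,
        normalized_luc=_to_float(cells["NormLuc"], row=row, column="NormLuc"),
        receptor_id=cells["OR"].strip(),
        odor_id=cells["Odor"].strip(),
        date=_to_date(cells["Date"], row=row),
    )


def _parse_receptor(cells: dict[str, str], row: int) -> ReceptorRecord:
    seq = cells["NucleotideSeq"].strip().upper()
    if not seq:
        raise ValidationError(f"row {row}: empty nucleotide sequence")
    if set(seq) - set("ACGT"):
        raise ValidationError(
            f"row {row}: nucleotide sequence has characters outside ACGT"
        )
    return ReceptorRecord(
        receptor_id=cells["OR"].strip(),
        gene_label=cells["Gene"].strip(),
        nucleotide_seq=seq,
    )


def _parse_odor(cells: dict[str, str], row: int) -> OdorRecord:
    cas = cells["CASRegistryNum"].strip() or None
    cid_text = cells["CID"].strip()
    cid: int | None = None
    if cid_text:
        cid = int(_to_float(cid_text, row=row, column="CID"))
        if cid <= 0:
            raise ValidationError(f"row {row}: CID must be positive, got {cid}")
    return OdorRecord(
        odor_id=cells["Odor"].strip(),
        cas_number=cas,
        odor_name=cells["OdorName"].strip(),
        cid=cid,
        smiles=cells["SMILES"].strip(),
    )


_PARSERS = {
    "primary": _parse_primary,
    "secondary": _parse_secondary,
    "dose": _parse_dose,
    "receptor": _parse_receptor,
    "odor": _parse_odor,
}


def read_record_table(
    path: str | Path,
    kind: str,
    *,
    column_map: dict[str, str] | None = None,
    collect_errors: bool = False,
):
    """Read one of the five record tables into typed records.

    Parameters
    ----------
    path
        Tab-separated file with a header row.
    kind
        One of ``primary``, ``secondary``, ``dose``, ``receptor``, ``odor``.
    column_map
        Optional mapping from the file's column names to the canonical
        names, for deposits whose headers differ from the documented
        field names.
    collect_errors
        If True return ``(records, errors)`` where ``errors`` is a list of
        ``(row_number, exception)`` for rows that failed, instead of
        raising on the first bad row.  Rows are never silently dropped:
        every input row is either a record or a reported error.
    """
    if kind not in RECORD_COLUMNS:
        raise ValueError(f"unknown record kind {kind!r}")
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if column_map:
        frame = frame.rename(columns=column_map)
    expected = set(RECORD_COLUMNS[kind])
    missing = expected - set(frame.columns)
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {sorted(missing)} for kind {kind!r}"
        )
    parser = _PARSERS[kind]
    records = []
    errors: list[tuple[int, Exception]] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        cells = dict(zip(frame.columns, row))
        try:
            records.append(parser(cells, i))
        except (ParseError, ValidationError) as exc:
            if collect_errors:
                errors.append((i, exc))
            else:
                raise
    if collect_errors:
        return records, errors
    return records


def write_record_table(records: Sequence, path: str | Path, kind: str) -> Path:
    """Write homogeneous typed records as a tab-separated table.

    Round-trips with :func:`read_record_table`: sentinels are re-encoded
    as their literals (``9999`` for the primary no-odor condition, ``-12``
    for the dose no-odor condition).
    """
    if kind not in RECORD_COLUMNS:
        raise ValueError(f"unknown record kind {kind!r}")
    expected_type = _RECORD_TYPES[kind]
    for r in records:
        if not isinstance(r, expected_type):
            raise TypeError(
                f"record {r!r} is not a {expected_type.__name__}; "
                "records must be homogeneous in kind"
            )
    rows = [_record_to_cells(r, kind) for r in records]
    frame = pd.DataFrame(rows, columns=list(RECORD_COLUMNS[kind]))
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False)
    return path


def _record_to_cells(record, kind: str) -> dict[str, str]:
    if kind == "primary":
        conc = (
            _PRIMARY_NO_ODOR_LITERAL
            if record.is_no_odor
            else _fmt_num(record.concentration_uM)
        )
        return {
            "Plate": record.plate_id,
            "Well": str(record.well_index),
            "Concentration": conc,
            "Luc": _fmt_num(record.luc_counts),
            "RL": _fmt_num(record.rl_counts),
            "OR": record.receptor_id,
            "Odor": record.odor_id,
            "Date": _fmt_date(record.date),
        }
    if kind == "secondary":
        return {
            "Date": _fmt_date(record.date),
            "OR": record.receptor_id,
            "Odor": record.odor_id,
            "Concentration": _fmt_num(record.concentration_uM),
            "NormalizedLuc": _fmt_num(record.normalized_luc),
        }
    if kind == "dose":
        return {
            "Concentration": _fmt_num(record.concentration_log10M),
            "NormLuc": _fmt_num(record.normalized_luc),
            "OR": record.receptor_id,
            "Odor": record.odor_id,
            "Date": _fmt_date(record.date),
        }
    if kind == "receptor":
        return {
            "OR": record.receptor_id,
            "Gene": record.gene_label,
            "NucleotideSeq": record.nucleotide_seq,
        }
    if kind == "odor":
        return {
            "Odor": record.odor_id,
            "CASRegistryNum": record.cas_number or "",
            "OdorName": record.odor_name,
            "CID": "" if record.cid is None else str(record.cid),
            "SMILES": record.smiles,
        }
    raise ValueError(f"unknown record kind {kind!r}")  # pragma: no cover
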