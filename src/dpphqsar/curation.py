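"""Bioactivity curation: from a heterogeneous assay table to (structure, pIC50) pairs.

The raw input is one row per assay record: a structure (SMILES and/or InChI),
an IC50 with units, a qualifier ("<", ">", ratio, or an exact number), free-text
assay description and assay time.  Curation proceeds in a fixed order:

1. assay-window filter (keyword match + assay time),
2. quantitative filter (only exact IC50s survive),
3. structure standardization (salt stripping, neutralization, stereo removal,
   canonicalization),
4. molecular-weight cut (small molecules only),
5. unit conversion to molar and the pIC50 transform,
6. duplicate reconciliation keyed on stereo-free InChI, then on canonical
   SMILES, using the coefficient of variation of replicate IC50s.

Every dropped record is accounted for in a :class:`CurationReport`, together
with the skewness of the activity distribution before and after the log
transform.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors as _Desc
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Qualifier",
    "RawActivityRecord",
    "StandardizedStructure",
    "CuratedCompound",
    "CurationReport",
    "CurationConfig",
    "CurationError",
    "SchemaError",
    "UnitError",
    "StructureParseError",
    "InorganicStructureError",
    "read_activity_table",
    "filter_assay_window",
    "filter_quantitative",
    "standardize_structure",
    "filter_small_molecules",
    "to_molar",
    "to_pic50",
    "coefficient_of_variation",
    "merge_duplicates",
    "skewness",
    "curate",
]


class CurationError(ValueError):
    """Base class for curation failures."""


class SchemaError(CurationError):
    """Input table is missing a mandatory column."""


class UnitError(CurationError):
    """Unknown or unusable IC50 unit token."""


class StructureParseError(CurationError):
    """SMILES/InChI failed to parse; carries the offending record id."""

    def __init__(self, message: str, record_id: Optional[str] = None):
        super().__init__(message)
        self.record_id = record_id


class InorganicStructureError(CurationError):
    """The structure has no organic (carbon-containing) fragment."""


class Qualifier(str, Enum):
    EXACT = "exact"
    LESS_THAN = "less_than"
    GREATER_THAN = "greater_than"
    RATIO = "ratio"
    UNKNOWN = "unknown"


# Accepted unit spellings.  Molar units map to a plain multiplier; mass units
# to a grams-per-litre multiplier (division by molecular weight happens in
# to_molar).  Unknown tokens are errors, never guesses.
_MOLAR_FACTORS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9}
_MASS_FACTORS_G_PER_L = {"g/L": 1.0, "mg/L": 1e-3, "ug/mL": 1e-3}

_UNIT_ALIASES = {
    "M": "M", "mol/L": "M", "mol/l": "M",
    "mM": "mM", "mmol/L": "mM",
    "uM": "uM", "µM": "uM", "μM": "uM", "umol/L": "uM",
    "nM": "nM", "nmol/L": "nM",
    "g/L": "g/L", "g/l": "g/L",
    "mg/L": "mg/L", "mg/l": "mg/L",
    "ug/mL": "ug/mL", "ug/ml": "ug/mL", "µg/mL": "ug/mL", "µg/ml": "ug/mL",
    "μg/mL": "ug/mL", "μg/ml": "ug/mL",
}

MASS_UNITS = frozenset(_MASS_FACTORS_G_PER_L)


def normalize_unit(token: str) -> str:
    token = token.strip()
    try:
        return _UNIT_ALIASES[token]
    except KeyError:
        raise UnitError(f"unknown IC50 unit token: {token!r}") from None


@dataclass
class RawActivityRecord:
    record_id: str
    smiles: str
    ic50_value: float  # NaN when the cell was unparseable
    ic50_units: str
    qualifier: Qualifier = Qualifier.EXACT
    inchi: Optional[str] = None
    assay_text: str = ""
    assay_time_min: Optional[float] = None
    doi: Optional[str] = None
    chembl_id: Optional[str] = None


@dataclass(frozen=True)
class StandardizedStructure:
    canonical_smiles: str
    inchi_no_stereo: str
    mol_weight: float


@dataclass
class CuratedCompound:
    structure: StandardizedStructure
    ic50_molar: float
    pic50: float
    n_merged: int = 1
    source_ids: list = field(default_factory=list)


@dataclass
class CurationReport:
    n_input: int = 0
    n_output: int = 0
    dropped_parse_failure: int = 0
    dropped_assay_window: int = 0
    needs_manual_check: int = 0
    dropped_qualifier: int = 0
    dropped_inorganic: int = 0
    dropped_mw: int = 0
    dropped_cv_inchi: int = 0
    dropped_cv_smiles: int = 0
    merged_away_inchi: int = 0
    merged_away_smiles: int = 0
    skewness_ic50: Optional[float] = None
    skewness_pic50: Optional[float] = None

    @property
    def total_dropped(self) -> int:
        return (
            self.dropped_parse_failure
            + self.dropped_assay_window
            + self.needs_manual_check
            + self.dropped_qualifier
            + self.dropped_inorganic
            + self.dropped_mw
            + self.dropped_cv_inchi
            + self.dropped_cv_smiles
        )

    @property
    def total_merged_away(self) -> int:
        return self.merged_away_inchi + self.merged_away_smiles

    def is_conserved(self) -> bool:
        """Rows in == compounds out + dropped + merged-away rows."""
        return self.n_input == self.n_output + self.total_dropped + self.total_merged_away

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class CurationConfig:
    assay_keyword: str = "DPPH"
    assay_window_min: float = 30.0
    max_mw: float = 1000.0
    cv_cutoff: float = 0.1


# --------------------------------------------------------------------------
# table ingestion

MANDATORY_COLUMNS = ("smiles", "ic50_value", "ic50_units")

_QUALIFIER_TOKENS = {
    "": Qualifier.EXACT, "=": Qualifier.EXACT, "exact": Qualifier.EXACT,
    "<": Qualifier.LESS_THAN, "<=": Qualifier.LESS_THAN, "less_than": Qualifier.LESS_THAN,
    ">": Qualifier.GREATER_THAN, ">=": Qualifier.GREATER_THAN, "greater_than": Qualifier.GREATER_THAN,
    "ratio": Qualifier.RATIO, "~": Qualifier.UNKNOWN,
}

_VALUE_RE = re.compile(r"^\s*(<=?|>=?)?\s*([0-9]*\.?[0-9]+(?:[eE][+-]?[0-9]+)?)\s*$")


def parse_value_cell(cell: str) -> tuple[float, Qualifier]:
    """Parse an IC50 cell; inline ``<``/``>`` prefixes set the qualifier.

    Ratio-style cells (``1:2``) and unparseable text yield ``(nan, RATIO)``
    and ``(nan, UNKNOWN)`` respectively so the row is flagged, not dropped.
    """
    cell = str(cell).strip()
    m = _VALUE_RE.match(cell)
    if m:
        sym, num = m.groups()
        value = float(num)
        if sym is None:
            return value, Qualifier.EXACT
        return value, (Qualifier.LESS_THAN if sym.startswith("<") else Qualifier.GREATER_THAN)
    if ":" in cell:
        return math.nan, Qualifier.RATIO
    return math.nan, Qualifier.UNKNOWN


def read_activity_table(path) -> list[RawActivityRecord]:
    """Read the raw bioactivity CSV into :class:`RawActivityRecord` objects.

    Rows with unparseable numeric values are flagged (qualifier ``unknown``,
    value NaN) rather than silently dropped; unknown unit tokens raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty and df.columns.size == 0:
        raise CurationError(f"empty input file: {path}")
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column: {col!r}")

    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        value, inline_qual = parse_value_cell(row["ic50_value"])
        qual_token = str(row.get("qualifier", "") or "").strip().lower()
        qual = _QUALIFIER_TOKENS.get(qual_token, Qualifier.UNKNOWN)
        # an inline < or > (or a ratio/garbage cell) overrides the column
        if inline_qual is not Qualifier.EXACT:
            qual = inline_qual
        time_cell = str(row.get("assay_time_min", "") or "").strip()
        try:
            assay_time = float(time_cell) if time_cell else None
        except ValueError:
            assay_time = None
        records.append(
            RawActivityRecord(
                record_id=str(row.get("record_id") or f"row{i}"),
                smiles=str(row.get("smiles", "")).strip(),
                inchi=str(row.get("inchi", "")).strip() or None,
                ic50_value=value,
                ic50_units=str(row["ic50_units"]).strip(),
                qualifier=qual,
                assay_text=str(row.get("assay_text", "")),
                assay_time_min=assay_time,
                doi=str(row.get("doi", "")).strip() or None,
                chembl_id=str(row.get("chembl_id", "")).strip() or None,
            )
        )
    return records


# --------------------------------------------------------------------------
# record-level filters

def filter_assay_window(
    records: Sequence[RawActivityRecord],
    keyword: str = "DPPH",
    window_minutes: float = 30.0,
) -> tuple[list[RawActivityRecord], list[RawActivityRecord], list[RawActivityRecord]]:
    """Keep records matching the assay keyword at the given incubation time.

    Returns ``(kept, dropped, needs_manual_check)``; records matching the
    keyword but missing a time are routed to the manual-check list (the
    curation pipeline counts them as excluded — no literature lookup here).
    """
    if not keyword:
        raise ValueError("assay keyword must be non-empty")
    kept, dropped, manual = [], [], []
    kw = keyword.lower()
    for r in records:
        if kw not in r.assay_text.lower():
            dropped.append(r)
        elif r.assay_time_min is None:
            manual.append(r)
        elif r.assay_time_min == window_minutes:
            kept.append(r)
        else:
            dropped.append(r)
    return kept, dropped, manual


def filter_quantitative(
    records: Sequence[RawActivityRecord],
) -> tuple[list[RawActivityRecord], list[RawActivityRecord]]:
    """Keep only exact-valued records; "<", ">", ratio and flagged rows go."""
    kept = [r for r in records if r.qualifier is Qualifier.EXACT and math.isfinite(r.ic50_value)]
    dropped = [r for r in records if not (r.qualifier is Qualifier.EXACT and math.isfinite(r.ic50_value))]
    return kept, dropped


# --------------------------------------------------------------------------
# structure standardization

_LARGEST_FRAGMENT = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
_UNCHARGER = rdMolStandardize.Uncharger()


def standardize_structure(smiles: str, record_id: Optional[str] = None) -> StandardizedStructure:
    """Canonicalize a structure: largest organic fragment, neutralized, stereo-free.

    Deterministic, and a fixed point: standardizing the output SMILES again
    returns the same structure.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureParseError(f"unparseable SMILES: {smiles!r}", record_id)
    mol = _LARGEST_FRAGMENT.choose(mol)
    if not any(a.GetAtomicNum() == 6 for a in mol.GetAtoms()):
        raise InorganicStructureError(f"no organic fragment in {smiles!r}")
    mol = _UNCHARGER.uncharge(mol)
    Chem.RemoveStereochemistry(mol)
    canonical = Chem.MolToSmiles(mol)
    # re-parse so MW and InChI come from the canonical form
    mol = Chem.MolFromSmiles(canonical)
    inchi = Chem.MolToInchi(mol)
    return StandardizedStructure(
        canonical_smiles=canonical,
        inchi_no_stereo=inchi,
        mol_weight=_Desc.MolWt(mol),
    )


def filter_small_molecules(compounds: Sequence, max_mw: float = 1000.0) -> tuple[list, list]:
    """Split into (kept, dropped) by molecular weight; the cap is inclusive.

    Accepts anything exposing ``.structure.mol_weight`` or ``.mol_weight``.
    """
    def _mw(c):
        return c.structure.mol_weight if hasattr(c, "structure") else c.mol_weight

    kept = [c for c in compounds if _mw(c) <= max_mw]
    dropped = [c for c in compounds if _mw(c) > max_mw]
    return kept, dropped


# --------------------------------------------------------------------------
# scalar transforms

def to_molar(value: float, units: str, mol_weight: Optional[float] = None) -> float:
    """Convert an IC50 to mol/L.  Mass-based units require the molecular weight."""
    if not (value > 0):
        raise ValueError(f"IC50 value must be positive, got {value}")
    unit = normalize_unit(units)
    if unit in _MOLAR_FACTORS:
        return value * _MOLAR_FACTORS[unit]
    grams_per_litre = value * _MASS_FACTORS_G_PER_L[unit]
    if mol_weight is None or not mol_weight > 0:
        raise UnitError(f"unit {unit!r} requires a positive molecular weight")
    return grams_per_litre / mol_weight


def to_pic50(ic50_molar: float) -> float:
    """pIC50 = −log10(IC50 in mol/L)."""
    if not (ic50_molar > 0):
        raise ValueError(f"IC50 must be positive, got {ic50_molar}")
    return -math.log10(ic50_molar)


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample standard deviation (n−1 denominator) divided by the mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("coefficient of variation needs at least two values")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("coefficient of variation requires a positive mean")
    return float(arr.std(ddof=1) / mean)


def skewness(values: Sequence[float]) -> float:
    """Adjusted Fisher–Pearson (bias-corrected) skewness; right tail positive."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError("skewness needs at least three values")
    if np.ptp(arr) == 0:
        raise ValueError("skewness undefined for zero-variance data")
    return float(_stats.skew(arr, bias=False))


# --------------------------------------------------------------------------
# duplicate reconciliation

def merge_duplicates(
    compounds: Sequence[CuratedCompound],
    key: str = "inchi_no_stereo",
    cv_cutoff: float = 0.1,
) -> tuple[list[CuratedCompound], int, int]:
    """Collapse replicate measurements of the same structure.

    Groups compounds by the chosen structure key.  Singletons pass through.
    Groups whose molar IC50s have CV ≤ ``cv_cutoff`` collapse to one compound
    at the group-mean IC50 (mean on the linear molar scale, then re-logged);
    groups with CV above the cutoff are discarded entirely as irreproducible.

    Returns ``(merged, n_rows_merged_away, n_rows_dropped_high_cv)``.
    """
    if key not in ("inchi_no_stereo", "canonical_smiles"):
        raise ValueError(f"unsupported merge key: {key!r}")
    if not cv_cutoff > 0:
        raise ValueError("cv_cutoff must be positive")

    groups: dict[str, list[CuratedCompound]] = {}
    order: list[str] = []
    for c in compounds:
        k = getattr(c.structure, key)
        if k not in groups:
            groups[k] = []
            order.append(k)
        groups[k].append(c)

    merged: list[CuratedCompound] = []
    merged_away = 0
    dropped_cv = 0
    for k in order:
        members = groups[k]
        if len(members) == 1:
            merged.append(members[0])
            continue
        values = [m.ic50_molar for m in members]
        if coefficient_of_variation(values) > cv_cutoff:
            dropped_cv += len(members)
            continue
        mean_molar = float(np.mean(values))
        merged.append(
            CuratedCompound(
                structure=members[0].structure,
                ic50_molar=mean_molar,
                pic50=to_pic50(mean_molar),
                n_merged=sum(m.n_merged for m in members),
                source_ids=[sid for m in members for sid in m.source_ids],
            )
        )
        merged_away += len(members) - 1
    return merged, merged_away, dropped_cv


# --------------------------------------------------------------------------
# orchestration

def curate(
    records: Sequence[RawActivityRecord],
    config: Optional[CurationConfig] = None,
) -> tuple[list[CuratedCompound], CurationReport]:
    """Run the full curation cascade in its fixed stage order."""
    cfg = config or CurationConfig()
    report = CurationReport(n_input=len(records))

    kept, dropped, manual = filter_assay_window(records, cfg.assay_keyword, cfg.assay_window_min)
    report.dropped_assay_window = len(dropped)
    report.needs_manual_check = len(manual)

    kept, dropped_q = filter_quantitative(kept)
    report.dropped_qualifier = len(dropped_q)

    precursors: list[CuratedCompound] = []
    standardized: list[tuple[RawActivityRecord, StandardizedStructure]] = []
    for r in kept:
        try:
            standardized.append((r, standardize_structure(r.smiles, r.record_id)))
        except StructureParseError:
            report.dropped_parse_failure += 1
        except InorganicStructureError:
            report.dropped_inorganic += 1

    small, heavy = filter_small_molecules([s for _, s in standardized], cfg.max_mw)
    report.dropped_mw = len(heavy)
    heavy_keys = {s.canonical_smiles for s in heavy}

    for r, s in standardized:
        if s.canonical_smiles in heavy_keys:
            continue
        molar = to_molar(r.ic50_value, r.ic50_units, s.mol_weight)
        precursors.append(
            CuratedCompound(
                structure=s,
                ic50_molar=molar,
                pic50=to_pic50(molar),
                source_ids=[r.record_id],
            )
        )

    if len(precursors) >= 3 and np.ptp([p.ic50_molar for p in precursors]) > 0:
        report.skewness_ic50 = skewness([p.ic50_molar for p in precursors])

    merged, away, dropped_cv = merge_duplicates(precursors, "inchi_no_stereo", cfg.cv_cutoff)
    report.merged_away_inchi = away
    report.dropped_cv_inchi = dropped_cv

    merged, away, dropped_cv = merge_duplicates(merged, "canonical_smiles", cfg.cv_cutoff)
    report.merged_away_smiles = away
    report.dropped_cv_smiles = dropped_cv

    if len(merged) >= 3 and np.ptp([c.pic50 for c in merged]) > 0:
        report.skewness_pic50 = skewness([c.pic50 for c in merged])

    report.n_output = len(merged)
    return merged, report


def compounds_to_frame(compounds: Iterable[CuratedCompound]) -> pd.DataFrame:
    """Tabulate curated compounds for CSV export / downstream featurization."""
    return pd.DataFrame(
        {
            "canonical_smiles": [c.structure.canonical_smiles for c in compounds],
            "inchi": [c.structure.inchi_no_stereo for c in compounds],
            "mol_weight": [c.structure.mol_weight for c in compounds],
            "ic50_molar": [c.ic50_molar for c in compounds],
            "pic50": [c.pic50 for c in compounds],
            "n_merged": [c.n_merged for c in compounds],
        }
    )
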