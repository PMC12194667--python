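"""Self-contained synthetic fixtures with known ground truth.

Everything downstream of the public bioactivity database is testable without
a download: a molecule generator built on a hand-curated fragment grammar of
phenolic/flavonoid-like scaffolds (the chemical space where DPPH-active
antioxidants live), a planted nonlinear activity function over computed
descriptors, and a "corruptor" that re-introduces exactly the dirt the
curation cascade must remove — salt forms, stereo decoration, replicate
measurements at controlled coefficients of variation, "<"/">" qualifiers,
off-window assay times, an overweight decoy, an inorganic salt and an
unparseable row.

Every generated artifact is deterministic per seed, and the accompanying
manifest records the expected outcome of each curation stage, so fixture
tests assert exact counts rather than plausible ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from rdkit import Chem
from rdkit.Chem import Descriptors as _Desc

from .curation import standardize_structure
from .descriptors import compute_descriptors

__all__ = [
    "FixtureManifest",
    "generate_molecule_library",
    "plant_activity",
    "corrupt_to_raw_table",
    "make_modeling_dataset",
]

# Fragment grammar: aromatic scaffolds with substituent slots ({i}) plus a
# substituent alphabet.  Slots sit on in-ring atoms, so any branch below is
# chemically valid; emptiness is allowed.  Several templates carry stereo
# (double-bond or tetrahedral) that standardization must strip.
SCAFFOLDS = [
    "Oc1cc{0}cc{1}c1",                      # phenols
    "Oc1c{0}cc{1}cc1O",                     # catechols
    "COc1cc{0}cc{1}c1O",                    # guaiacols
    "O=C(O)c1cc{0}c{1}cc1O",                # salicylic/benzoic acids
    "OC(=O)/C=C/c1cc{0}c{1}cc1",            # cinnamic acids (E-configured)
    "O=c1cc(-c2cc{0}c{1}cc2)oc2cc(O)cc(O)c12",  # flavones
    "O=c1ccc2cc{0}cc{1}c2o1",               # coumarins
    "C[C@H](O)c1cc{0}cc{1}c1",              # benzylic alcohols (chiral)
    "OCc1cc{0}c{1}cc1",                     # benzyl alcohols
    "Nc1cc{0}c{1}cc1O",                     # aminophenols
    "Oc1ccc2cc{0}ccc2c1",                   # naphthols
    "c1ccc2[nH]c{0}cc2c1",                  # indoles
]

SUBSTITUENTS = [
    "", "(O)", "(OC)", "(C)", "(CC)", "(CCC)", "(C(C)C)", "(Cl)", "(F)",
    "(Br)", "(N)", "(C(=O)O)", "(C=O)", "(OCC)", "(CO)", "(C#N)",
    "(OC(C)=O)", "(S)", "(CCO)", "(C(=O)OC)",
]

# planted activity: five named 2D descriptors drive pIC50 through a weighted
# sum, one pairwise interaction and one threshold term
INFORMATIVE_DESCRIPTORS = ("MolLogP", "TPSA", "NumHDonors", "MolWt", "NumAromaticRings")

UNIT_CHOICES = ("M", "mM", "uM", "nM", "g/L", "mg/L", "ug/mL")
_MOLAR_FACTOR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9}

RAW_COLUMNS = [
    "record_id", "smiles", "inchi", "ic50_value", "ic50_units", "qualifier",
    "assay_text", "assay_time_min", "doi", "chembl_id",
]

_ASSAY_TEXT = "DPPH radical scavenging assay, 30 min incubation"


@dataclass
class FixtureManifest:
    """Ground truth for a corrupted raw table: the oracle for curation tests."""

    seed: int
    n_clean: int
    n_rows: int
    expected_survivors: list  # dicts: canonical_smiles, pic50, ic50_molar, n_merged
    expected_counts: dict     # per curation-report field
    low_cv_pairs: list        # canonical SMILES merged from replicate pairs
    high_cv_pairs: list       # canonical SMILES removed for irreproducibility
    planted: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_clean": self.n_clean,
            "n_rows": self.n_rows,
            "expected_survivors": self.expected_survivors,
            "expected_counts": self.expected_counts,
            "low_cv_pairs": self.low_cv_pairs,
            "high_cv_pairs": self.high_cv_pairs,
            "planted": self.planted,
        }


def generate_molecule_library(n: int, seed: int = 1) -> list[str]:
    """Sample n unique, parseable, sub-1000-Da SMILES from the fragment grammar.

    Uniqueness is enforced on the *standardized* canonical form (so a stereo
    variant never duplicates a flat library member); rejected draws are simply
    resampled.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    library: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(library) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError("fragment grammar exhausted before reaching n unique molecules")
        template = SCAFFOLDS[rng.integers(len(SCAFFOLDS))]
        n_slots = template.count("{")
        subs = [SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))] for _ in range(n_slots)]
        smiles = template.format(*subs)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None or _Desc.MolWt(mol) > 1000:
            continue
        canonical = standardize_structure(smiles).canonical_smiles
        if canonical in seen:
            continue
        seen.add(canonical)
        library.append(smiles)
    return library


def plant_activity(
    library: Sequence[str], seed: int = 1, noise_sd: float = 0.35
) -> tuple[np.ndarray, dict]:
    """Plant a nonlinear descriptor-driven pIC50 on a molecule library.

    pIC50 = 4.5 + signal + ε, where the signal is a standardized combination
    of five named descriptors (weighted sum + one interaction + one threshold
    term) scaled to unit variance, and ε ~ N(0, noise_sd²).  The default
    noise level puts the cross-validated R² of an ensemble-tree fit in the
    0.6–0.9 band; values are clipped to the plausible assay window [2, 7]
    (IC50 of 10 mM down to 100 nM).
    """
    rng = np.random.default_rng(seed)
    desc = compute_descriptors([standardize_structure(s).canonical_smiles for s in library])
    cols = {name: desc.frame[name].to_numpy(dtype=float) for name in INFORMATIVE_DESCRIPTORS}
    z = {}
    for name, v in cols.items():
        sd = v.std()
        z[name] = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    weights = {"TPSA": 0.5, "MolLogP": 0.4, "NumHDonors": 0.4, "NumAromaticRings": 0.3}
    raw = sum(w * z[name] for name, w in weights.items())
    raw = raw + 1.0 * z["MolLogP"] * z["TPSA"]        # interaction term
    raw = raw + 1.2 * (z["MolWt"] > 0.5)              # threshold term
    raw = np.asarray(raw, dtype=float)
    raw_sd = raw.std()
    signal = (raw - raw.mean()) / raw_sd if raw_sd > 0 else np.zeros_like(raw)

    pic50 = 4.5 + signal + rng.normal(0.0, noise_sd, size=len(library))
    pic50 = np.clip(pic50, 2.0, 7.0)
    params = {
        "descriptors": list(INFORMATIVE_DESCRIPTORS),
        "weights": weights,
        "interaction": ["MolLogP", "TPSA", 0.6],
        "threshold": ["MolWt", 0.5, 0.8],
        "intercept": 4.5,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return pic50, params


def _format_value(molar: float, unit: str, mol_weight: float) -> float:
    if unit in _MOLAR_FACTOR:
        return molar / _MOLAR_FACTOR[unit]
    # mass units: g/L, mg/L, ug/mL (the latter two are numerically identical)
    grams_per_litre = molar * mol_weight
    return grams_per_litre if unit == "g/L" else grams_per_litre * 1000.0


def corrupt_to_raw_table(
    library: Sequence[str],
    pic50: Sequence[float],
    seed: int = 1,
    planted: Optional[dict] = None,
) -> tuple[pd.DataFrame, FixtureManifest]:
    """Turn clean (molecule, pIC50) pairs into a dirty raw activity table.

    Injections, all recorded in the manifest: replicate pairs at known CV
    (some mergeable, some above the 0.1 cutoff), salt-decorated duplicates,
    "<"/">"/ratio qualifier rows, off-window and missing assay times, one
    >1000 Da decoy, one inorganic salt and one unparseable structure.
    """
    library = list(library)
    pic50 = np.asarray(pic50, dtype=float)
    if len(library) != pic50.size:
        raise ValueError("library and pic50 lengths differ")
    n = len(library)
    rng = np.random.default_rng(seed)

    std = [standardize_structure(s) for s in library]
    molar = 10.0 ** (-pic50)

    n_low = max(3, n // 15)
    n_high = max(2, n // 20)
    n_qual = max(3, n // 20)
    n_offtime = max(2, n // 25)
    n_nonkw = max(2, n // 30)
    n_missing = max(2, n // 30)

    special = rng.choice(n, size=n_low + n_high, replace=False)
    low_idx = {int(i) for i in special[:n_low]}
    high_idx = {int(i) for i in special[n_low:]}

    rows: list[dict] = []
    rid = iter(f"R{i:05d}" for i in range(1, 100000))

    def emit(smiles, value, unit, *, qualifier="", value_cell=None, assay=_ASSAY_TEXT,
             time="30", inchi=""):
        rows.append({
            "record_id": next(rid),
            "smiles": smiles,
            "inchi": inchi,
            "ic50_value": value_cell if value_cell is not None else repr(float(value)),
            "ic50_units": unit,
            "qualifier": qualifier,
            "assay_text": assay,
            "assay_time_min": time,
            "doi": "",
            "chembl_id": "",
        })

    def pick_unit() -> str:
        return UNIT_CHOICES[rng.integers(len(UNIT_CHOICES))]

    # clean singleton rows (some as salt forms — stripped during curation)
    for i in range(n):
        if i in low_idx or i in high_idx:
            continue
        smiles = library[i]
        if rng.random() < 0.15:
            smiles = smiles + (".Cl" if rng.random() < 0.5 else ".[Na+].[Cl-]")
        unit = pick_unit()
        emit(smiles, _format_value(molar[i], unit, std[i].mol_weight), unit)

    # replicate pairs at controlled CV; the pair mean is exactly the planted
    # value, so mergeable pairs survive at the planted pIC50
    for i in low_idx:
        d = rng.uniform(0.01, 0.06)  # CV = d*sqrt(2) <= 0.085 < 0.1
        unit = pick_unit()
        emit(library[i], _format_value(molar[i] * (1 + d), unit, std[i].mol_weight), unit)
        emit(library[i] + ".Cl", _format_value(molar[i] * (1 - d), unit, std[i].mol_weight), unit)
    for i in high_idx:
        d = rng.uniform(0.15, 0.40)  # CV = d*sqrt(2) >= 0.21 > 0.1
        unit = pick_unit()
        emit(library[i], _format_value(molar[i] * (1 + d), unit, std[i].mol_weight), unit)
        emit(library[i], _format_value(molar[i] * (1 - d), unit, std[i].mol_weight), unit)

    # qualifier rows: inline "<"/">" cells, qualifier-column tokens, ratios
    for k in range(n_qual):
        i = int(rng.integers(n))
        unit = pick_unit()
        v = float(_format_value(molar[i], unit, std[i].mol_weight))
        style = k % 3
        if style == 0:
            emit(library[i], v, unit, value_cell=f"{'<' if rng.random() < 0.5 else '>'}{v!r}")
        elif style == 1:
            emit(library[i], v, unit, qualifier="<" if rng.random() < 0.5 else ">")
        else:
            emit(library[i], v, unit, value_cell="1:2", qualifier="ratio")

    # wrong incubation time / wrong assay / missing time
    for _ in range(n_offtime):
        i = int(rng.integers(n))
        unit = pick_unit()
        t = str(int(rng.choice([15, 60, 90, 120])))
        emit(library[i], _format_value(molar[i], unit, std[i].mol_weight), unit,
             assay=f"DPPH radical scavenging assay, {t} min incubation", time=t)
    for _ in range(n_nonkw):
        i = int(rng.integers(n))
        unit = pick_unit()
        emit(library[i], _format_value(molar[i], unit, std[i].mol_weight), unit,
             assay="ABTS radical cation decolorization, 30 min", time="30")
    for _ in range(n_missing):
        i = int(rng.integers(n))
        unit = pick_unit()
        emit(library[i], _format_value(molar[i], unit, std[i].mol_weight), unit, time="")

    # structural decoys: overweight, inorganic, unparseable
    emit("C" * 72, 10.0, "uM")                   # C72 alkane, MW 1010 Da
    emit("[Na+].[Cl-]", 5.0, "mM")               # no organic fragment
    emit("not-a-smiles((", 1.0, "uM")            # parse failure

    frame = pd.DataFrame(rows, columns=RAW_COLUMNS)
    frame = frame.iloc[rng.permutation(len(frame))].reset_index(drop=True)

    high_keys = {std[i].canonical_smiles for i in high_idx}
    survivors = [
        {
            "canonical_smiles": std[i].canonical_smiles,
            "pic50": float(pic50[i]),
            "ic50_molar": float(molar[i]),
            "n_merged": 2 if i in low_idx else 1,
        }
        for i in range(n)
        if std[i].canonical_smiles not in high_keys
    ]
    counts = {
        "n_input": len(frame),
        "n_output": len(survivors),
        "dropped_qualifier": n_qual,
        "dropped_assay_window": n_offtime + n_nonkw,
        "needs_manual_check": n_missing,
        "dropped_mw": 1,
        "dropped_inorganic": 1,
        "dropped_parse_failure": 1,
        "dropped_cv_inchi": 2 * n_high,
        "dropped_cv_smiles": 0,
        "merged_away_inchi": n_low,
        "merged_away_smiles": 0,
    }
    manifest = FixtureManifest(
        seed=seed,
        n_clean=n,
        n_rows=len(frame),
        expected_survivors=survivors,
        expected_counts=counts,
        low_cv_pairs=sorted(std[i].canonical_smiles for i in low_idx),
        high_cv_pairs=sorted(high_keys),
        planted=planted or {},
    )
    return frame, manifest


def make_modeling_dataset(
    n: int = 300, seed: int = 1, noise_sd: float = 0.35
) -> tuple[list[str], np.ndarray, dict]:
    """Convenience: library + planted activity in one call (shared seed)."""
    library = generate_molecule_library(n, seed)
    pic50, params = plant_activity(library, seed, noise_sd)
    return library, pic50, params
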