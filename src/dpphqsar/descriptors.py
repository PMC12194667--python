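"""Molecular descriptor featurization and z-scaling.

Descriptors are computed with RDKit's 2D descriptor set (~210 named numeric
descriptors: constitutional counts, topological indices, E-state sums,
logP/TPSA-type physicochemical properties).  2D-only is the default so the
matrix is fully deterministic; an opt-in 3D mode embeds a single seeded ETKDG
conformer and appends RDKit's 3D shape descriptors.

Scaling is the usual z-score: subtract the column mean, divide by the column
standard deviation (population, n-denominator convention — the same as
scikit-learn's StandardScaler).  Scaler parameters are fitted on training
rows only and applied unchanged to held-out rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors, Descriptors3D

from .curation import StandardizedStructure, StructureParseError

__all__ = [
    "DescriptorMatrix",
    "ScalerParams",
    "FeatureMismatchError",
    "compute_descriptors",
    "clean_matrix",
    "fit_scaler",
    "apply_scaler",
]

_PROVENANCE = f"rdkit-2d ({Chem.rdBase.rdkitVersion})"


class FeatureMismatchError(ValueError):
    """Descriptor names in the matrix do not match the scaler/model."""


@dataclass
class DescriptorMatrix:
    """Compounds × named descriptors, as a dense numeric DataFrame."""

    frame: pd.DataFrame  # index = compound ids, columns = descriptor names
    provenance: str = _PROVENANCE

    @property
    def compound_ids(self) -> list:
        return list(self.frame.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class ScalerParams:
    mean: pd.Series
    sd: pd.Series  # population (ddof=0) standard deviations, all > 0


def _as_smiles(compound) -> str:
    if isinstance(compound, StandardizedStructure):
        return compound.canonical_smiles
    return str(compound)


def compute_descriptors(
    compounds: Sequence[Union[str, StandardizedStructure]],
    ids: Optional[Sequence] = None,
    include_3d: bool = False,
    conformer_seed: int = 1,
) -> DescriptorMatrix:
    """Compute one descriptor row per compound.

    Descriptor values that the calculator cannot produce come back as NaN and
    are handled by :func:`clean_matrix`.  With ``include_3d`` a single ETKDGv3
    conformer (fixed ``conformer_seed``) is embedded per molecule before the
    3D descriptors are evaluated.
    """
    smiles = [_as_smiles(c) for c in compounds]
    if ids is None:
        ids = smiles
    rows = []
    for sm in smiles:
        mol = Chem.MolFromSmiles(sm)
        if mol is None:
            raise StructureParseError(f"unparseable SMILES in descriptor input: {sm!r}")
        with np.errstate(all="ignore"):
            row = Descriptors.CalcMolDescriptors(mol)
        if include_3d:
            molh = Chem.AddHs(mol)
            params = AllChem.ETKDGv3()
            params.randomSeed = conformer_seed
            if AllChem.EmbedMolecule(molh, params) == 0:
                AllChem.MMFFOptimizeMolecule(molh)
                row.update(Descriptors3D.CalcMolDescriptors3D(molh))
        rows.append(row)
    frame = pd.DataFrame(rows, index=list(ids), dtype=float)
    provenance = _PROVENANCE if not include_3d else _PROVENANCE + "+3d"
    return DescriptorMatrix(frame=frame, provenance=provenance)


def clean_matrix(m: DescriptorMatrix) -> DescriptorMatrix:
    """Drop descriptor columns with any non-finite value or zero variance.

    Column order is otherwise preserved.  Dropping (rather than imputing) keeps
    the matrix fully reproducible.
    """
    frame = m.frame
    finite = frame.columns[np.isfinite(frame.to_numpy(dtype=float)).all(axis=0)]
    frame = frame[finite]
    varying = frame.columns[frame.nunique() > 1]
    frame = frame[varying]
    if frame.shape[1] == 0:
        raise ValueError("all descriptor columns were dropped during cleaning")
    return DescriptorMatrix(frame=frame, provenance=m.provenance)


def fit_scaler(train: DescriptorMatrix) -> ScalerParams:
    """Fit per-descriptor mean/sd on training rows only (leakage guard)."""
    values = train.frame.to_numpy(dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    if np.any(sd <= 0):
        bad = [n for n, s in zip(train.descriptor_names, sd) if s <= 0]
        raise ValueError(f"zero-variance descriptors cannot be scaled: {bad[:5]}")
    names = train.frame.columns
    return ScalerParams(mean=pd.Series(mean, index=names), sd=pd.Series(sd, index=names))


def apply_scaler(m: DescriptorMatrix, p: ScalerParams) -> DescriptorMatrix:
    """Z-scale a matrix with previously fitted parameters."""
    missing = [n for n in m.descriptor_names if n not in p.mean.index]
    if missing:
        raise FeatureMismatchError(f"descriptors absent from scaler: {missing[:5]}")
    scaled = (m.frame - p.mean[m.frame.columns]) / p.sd[m.frame.columns]
    return DescriptorMatrix(frame=scaled, provenance=m.provenance + "|scaled")
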