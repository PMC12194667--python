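"""Two-filter univariate feature selection.

Descriptors are ranked twice: by the univariate linear-regression F statistic
(F = r²·(n−2)/(1−r²) with r the Pearson correlation against the target) and
by a Kraskov-style k-nearest-neighbour mutual-information estimate for a
continuous target.  Descriptors appearing in the top-k of *both* rankings are
retained for modeling — the F filter captures linear association, the MI
filter keeps nonlinear dependencies the F statistic misses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.feature_selection import mutual_info_regression

from .descriptors import DescriptorMatrix

__all__ = [
    "FeatureRanking",
    "SelectionResult",
    "EmptySelectionError",
    "f_score_ranking",
    "mutual_info_ranking",
    "select_consensus",
]


class EmptySelectionError(ValueError):
    """The two top-k sets share no descriptor; enlarge k_f / k_mi."""


@dataclass
class FeatureRanking:
    descriptor_names: list[str]
    scores: list[float]
    method: str  # "f_score" | "mutual_information"

    def top_k(self, k: int) -> list[str]:
        """Names of the k best-scoring descriptors (score desc, name asc)."""
        order = sorted(
            range(len(self.descriptor_names)),
            key=lambda i: (-self.scores[i], self.descriptor_names[i]),
        )
        return [self.descriptor_names[i] for i in order[:k]]


@dataclass
class SelectionResult:
    selected_names: list[str]
    k_f: int
    k_mi: int


def _check_xy(X: DescriptorMatrix, y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if len(X) != y.size:
        raise ValueError("X rows and y length differ")
    if y.size < 3:
        raise ValueError("need at least three samples")
    return y


def f_score_ranking(X: DescriptorMatrix, y) -> FeatureRanking:
    """Per-descriptor univariate regression F statistic against the target.

    F = r²·(n−2)/(1−r²) with r the Pearson correlation of the descriptor with
    the target (the statistic behind sklearn's ``f_regression``).  A
    descriptor perfectly correlated with y gets an infinite F and ranks
    first; zero-variance descriptors (impossible after cleaning) score 0.
    """
    y = _check_xy(X, y)
    values = X.values
    n = y.size
    xc = values - values.mean(axis=0)
    yc = y - y.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
        r2 = np.clip(r**2, 0.0, 1.0)
        f = r2 * (n - 2) / (1.0 - r2)
    f = np.where(np.isnan(f), 0.0, f)
    return FeatureRanking(descriptor_names=X.descriptor_names, scores=[float(v) for v in f], method="f_score")


def mutual_info_ranking(X: DescriptorMatrix, y, n_neighbors: int = 3, seed: int = 1) -> FeatureRanking:
    """k-NN entropy-based mutual information of each descriptor with the target.

    Estimates are clipped at zero.  The estimator jitters continuous features
    with seeded noise, so the ranking is deterministic for a given seed.
    """
    y = _check_xy(X, y)
    if n_neighbors >= y.size:
        raise ValueError("n_neighbors must be smaller than the sample count")
    mi = mutual_info_regression(X.values, y, n_neighbors=n_neighbors, random_state=seed)
    mi = np.clip(mi, 0.0, None)
    return FeatureRanking(
        descriptor_names=X.descriptor_names, scores=[float(v) for v in mi], method="mutual_information"
    )


def select_consensus(
    rank_f: FeatureRanking, rank_mi: FeatureRanking, k_f: int = 300, k_mi: int = 300
) -> SelectionResult:
    """Intersect the top-k_f F-score names with the top-k_mi MI names.

    The result is ordered by F-score rank.  Ties within either ranking break
    by (score descending, name ascending), so selection is invariant to the
    column order of the input matrix.
    """
    if set(rank_f.descriptor_names) != set(rank_mi.descriptor_names):
        raise ValueError("rankings cover different descriptor universes")
    top_f = rank_f.top_k(k_f)
    top_mi = set(rank_mi.top_k(k_mi))
    selected = [n for n in top_f if n in top_mi]
    if not selected:
        raise EmptySelectionError(
            f"no descriptor in both top-{k_f} (F) and top-{k_mi} (MI); increase k"
        )
    return SelectionResult(selected_names=selected, k_f=k_f, k_mi=k_mi)
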