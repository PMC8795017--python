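"""Feature standardization, PCA to 10 components, and loading-based
per-feature contribution scores.

Standardization and the decomposition are fitted on training rows only
(leakage-free); test rows reuse the training parameters.  The contribution
score of feature j is the mean absolute loading across the retained
components, max-normalized to [0, 1]; features scoring above 0.7 are flagged
as the most important contributors to the decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "Standardizer",
    "PCAModel",
    "ContributionReport",
    "fit_pca",
    "transform",
    "inverse_transform",
    "feature_contributions",
]

CONTRIBUTION_CUTOFF = 0.7
_SD_FLOOR = 1e-12


@dataclass
class Standardizer:
    """Per-feature mean/SD learned on training rows.

    Near-constant features (SD < 1e-12) get SD clamped to 1, which
    effectively zeroes them after centering.
    """

    mean: np.ndarray
    sd: np.ndarray
    columns: tuple[str, ...]

    def apply(self, table: pd.DataFrame) -> np.ndarray:
        if tuple(table.columns) != self.columns:
            raise ValueError("feature columns do not match the fitted standardizer")
        x = table.to_numpy(dtype=np.float64)
        return (x - self.mean) / self.sd


@dataclass
class PCAModel:
    """Retained-component loading matrix plus explained variances."""

    loadings: np.ndarray  # (n_features, k), orthonormal columns
    explained_variance: np.ndarray  # (k,), non-increasing
    mean_score_offset: np.ndarray  # (k,), zero for centered input
    n_train: int
    columns: tuple[str, ...]

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


@dataclass
class ContributionReport:
    """Normalized per-feature contribution scores and the selected set."""

    scores: pd.Series  # index = feature names, values in [0, 1]
    cutoff: float = CONTRIBUTION_CUTOFF
    selected: tuple[str, ...] = field(default_factory=tuple)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.scores.index,
                "score": self.scores.to_numpy(),
                "selected": [f in set(self.selected) for f in self.scores.index],
            }
        )

    def plot(self, path=None, top: int = 50):
        """Rank plot of contribution scores with the cutoff line."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        ranked = self.scores.sort_values(ascending=False)
        fig, ax = plt.subplots(figsize=(8, 4))
        ax.plot(np.arange(1, len(ranked) + 1), ranked.to_numpy(), lw=1)
        ax.axhline(self.cutoff, color="red", lw=1, label=f"cutoff {self.cutoff}")
        ax.scatter(
            np.arange(1, min(top, len(ranked)) + 1),
            ranked.to_numpy()[:top],
            s=8,
            color="tab:blue",
        )
        ax.set_xlabel("feature rank")
        ax.set_ylabel("mean contribution (normalized)")
        ax.set_title(f"{len(self.selected)} features above cutoff")
        ax.legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def fit_pca(train_table: pd.DataFrame, k: int = 10) -> tuple[Standardizer, PCAModel]:
    """Standardize the training table and fit a k-component PCA.

    Deterministic: a full SVD solver plus a sign convention (the
    largest-magnitude loading of each component is made positive).
    """
    x = train_table.to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("feature table contains non-finite entries")
    n, p = x.shape
    if n <= k:
        raise ValueError(f"fewer rows than components: n={n} <= k={k}")
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd < _SD_FLOOR, 1.0, sd)
    std = Standardizer(mean=mean, sd=sd, columns=tuple(train_table.columns))
    z = (x - mean) / sd

    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(z)
    loadings = pca.components_.T.copy()  # (p, k)
    for c in range(k):
        j = np.argmax(np.abs(loadings[:, c]))
        if loadings[j, c] < 0:
            loadings[:, c] = -loadings[:, c]
    model = PCAModel(
        loadings=loadings,
        explained_variance=pca.explained_variance_.copy(),
        mean_score_offset=np.zeros(k),
        n_train=n,
        columns=tuple(train_table.columns),
    )
    return std, model


def transform(table: pd.DataFrame, standardizer: Standardizer, model: PCAModel) -> np.ndarray:
    """Project samples onto the retained components (n x k score matrix)."""
    z = standardizer.apply(table)
    return z @ model.loadings


def inverse_transform(scores: np.ndarray, model: PCAModel) -> np.ndarray:
    """Map component scores back to standardized feature space."""
    return np.asarray(scores) @ model.loadings.T


def feature_contributions(model: PCAModel, cutoff: float = CONTRIBUTION_CUTOFF) -> ContributionReport:
    """Mean |loading| across components, max-normalized; select > cutoff."""
    raw = np.abs(model.loadings).mean(axis=1)
    peak = raw.max()
    scores = raw / peak if peak > 0 else raw
    series = pd.Series(scores, index=list(model.columns), name="contribution")
    selected = tuple(series.index[series > cutoff])
    return ContributionReport(scores=series, cutoff=cutoff, selected=selected)
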