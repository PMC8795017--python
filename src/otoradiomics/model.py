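"""Model/results objects tying the pipeline together.

:class:`RadiomicsClassifier` is built from a feature table (one row per ear:
id, label, center plus the 812 radiomic features); ``fit()`` standardizes,
projects onto 10 principal components, trains the MLP and evaluates, and
returns a :class:`RadiomicsResults` carrying the fitted stages, the metric
estimates with bootstrap confidence intervals, the PCA contribution report
and a ``summary()`` table.  ``cross_validate()`` runs the stratified 10-fold
protocol on the full table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluation as ev
from . import mlp as mlp_mod
from . import reduction
from .mlp import MLPConfig, TrainedModel

__all__ = ["RadiomicsClassifier", "RadiomicsResults", "CrossValidationResults"]

_META_COLS = ("id", "label", "center")


def _encode_labels(labels: pd.Series) -> np.ndarray:
    """Map patient -> 1, control -> 0 (integers pass through)."""
    vals = labels.to_numpy()
    if vals.dtype.kind in "iub":
        out = vals.astype(int)
    else:
        mapping = {"patient": 1, "control": 0}
        try:
            out = np.array([mapping[str(v)] for v in vals])
        except KeyError as exc:
            raise ValueError(f"unknown class label {exc.args[0]!r}") from None
    if not set(np.unique(out)) <= {0, 1}:
        raise ValueError("labels must be binary (patient=1, control=0)")
    return out


def _metrics_with_ci(y, proba, protocol, reps, seed) -> ev.MetricsReport:
    pred = (proba >= 0.5).astype(int)
    report = ev.compute_metrics(ev.confusion_from_predictions(y, pred), protocol=protocol)
    report.auc = 100.0 * ev.roc_auc(y, proba)
    if reps > 0 and len(y) >= 10:
        defs = {
            "accuracy_pct": lambda t, p: 100.0 * float((t == (p >= 0.5)).mean()),
            "sensitivity_pct": lambda t, p: 100.0 * float(((p >= 0.5) & (t == 1)).sum() / max((t == 1).sum(), 1)),
            "specificity_pct": lambda t, p: 100.0 * float(((p < 0.5) & (t == 0)).sum() / max((t == 0).sum(), 1)),
            "ppv_pct": lambda t, p: 100.0 * ((p >= 0.5) & (t == 1)).sum() / (p >= 0.5).sum(),
            "npv_pct": lambda t, p: 100.0 * ((p < 0.5) & (t == 0)).sum() / (p < 0.5).sum(),
            "auc_pct": lambda t, p: 100.0 * ev.roc_auc(t, p),
        }
        for i, (name, fn) in enumerate(defs.items()):
            try:
                report.ci[name] = ev.bootstrap_ci(y, proba, fn, reps=reps, seed=seed + i)
            except (ValueError, ZeroDivisionError):
                pass
    return report


class RadiomicsClassifier:
    """The diagnostic model: standardize -> PCA(k) -> 500-unit MLP.

    Parameters
    ----------
    feature_table : DataFrame
        Columns ``id, label, center`` plus the feature columns.
    n_components : int
        Principal components retained (study value: 10).
    mlp_config : MLPConfig, optional
        Classifier hyperparameters.
    """

    def __init__(
        self,
        feature_table: pd.DataFrame,
        n_components: int = 10,
        mlp_config: MLPConfig | None = None,
    ):
        missing = [c for c in _META_COLS if c not in feature_table.columns]
        if missing:
            raise ValueError(f"feature table lacks columns {missing}")
        self.table = feature_table.reset_index(drop=True)
        self.feature_cols = [c for c in self.table.columns if c not in _META_COLS]
        if not self.feature_cols:
            raise ValueError("no feature columns")
        self.n_components = n_components
        self.mlp_config = mlp_config or MLPConfig()
        self.y = _encode_labels(self.table["label"])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "RadiomicsClassifier":
        return cls(df, **kwargs)

    # -- helpers -----------------------------------------------------------
    def _rows_for(self, ids) -> np.ndarray:
        pos = {i: k for k, i in enumerate(self.table["id"])}
        try:
            return np.array([pos[i] for i in ids])
        except KeyError as exc:
            raise ValueError(f"unknown sample id {exc.args[0]!r}") from None

    def _fit_once(self, train_rows: np.ndarray, seed: int):
        feats = self.table[self.feature_cols]
        std, pca = reduction.fit_pca(feats.iloc[train_rows], k=self.n_components)
        scores_all = reduction.transform(feats, std, pca)
        cfg = MLPConfig(**{**self.mlp_config.__dict__, "seed": seed})
        net = mlp_mod.train(scores_all[train_rows], self.y[train_rows], cfg)
        proba_all = mlp_mod.predict_proba(net, scores_all)[:, 1]
        return std, pca, net, scores_all, proba_all

    # -- protocols ---------------------------------------------------------
    def fit(
        self,
        split: ev.SplitPlan | None = None,
        seed: int = 0,
        bootstrap_reps: int = 2000,
    ) -> "RadiomicsResults":
        """Fit on the training rows of ``split`` (or on all rows) and
        evaluate on both partitions.
        """
        if split is None:
            train_rows = np.arange(len(self.table))
            test_rows = np.array([], dtype=int)
        else:
            train_rows = self._rows_for(split.train_ids)
            test_rows = self._rows_for(split.test_ids)
        std, pca, net, scores_all, proba_all = self._fit_once(train_rows, seed)

        train_metrics = _metrics_with_ci(
            self.y[train_rows], proba_all[train_rows], "train", bootstrap_reps, seed
        )
        test_metrics = None
        if test_rows.size:
            test_metrics = _metrics_with_ci(
                self.y[test_rows], proba_all[test_rows], "test", bootstrap_reps, seed + 100
            )
        predictions = pd.DataFrame(
            {
                "id": self.table["id"],
                "label": self.y,
                "proba_patient": proba_all,
                "predicted": (proba_all >= 0.5).astype(int),
                "partition": np.where(
                    np.isin(np.arange(len(self.table)), train_rows), "train", "test"
                ),
            }
        )
        return RadiomicsResults(
            model=self,
            split=split,
            standardizer=std,
            pca=pca,
            contributions=reduction.feature_contributions(pca),
            network=net,
            train_metrics=train_metrics,
            test_metrics=test_metrics,
            predictions=predictions,
        )

    def cross_validate(
        self, k: int = 10, seed: int = 0, bootstrap_reps: int = 0
    ) -> "CrossValidationResults":
        """Stratified k-fold cross-validation over the whole table."""
        folds = ev.kfold_plan(self.table, k=k, seed=seed)
        rows = []
        proba_oof = np.full(len(self.table), np.nan)
        for f, (train_ids, test_ids) in enumerate(folds):
            tr = self._rows_for(train_ids)
            te = self._rows_for(test_ids)
            _, _, _, _, proba_all = self._fit_once(tr, seed + f)
            proba_oof[te] = proba_all[te]
            rep = _metrics_with_ci(self.y[te], proba_all[te], f"fold-{f}", bootstrap_reps, seed)
            rows.append(rep)
        return CrossValidationResults(model=self, folds=rows, proba_oof=proba_oof, k=k, seed=seed)


@dataclass
class RadiomicsResults:
    """Fitted pipeline + evaluation of one train/test protocol."""

    model: RadiomicsClassifier
    split: ev.SplitPlan | None
    standardizer: reduction.Standardizer
    pca: reduction.PCAModel
    contributions: reduction.ContributionReport
    network: TrainedModel
    train_metrics: ev.MetricsReport
    test_metrics: ev.MetricsReport | None
    predictions: pd.DataFrame

    def predict_proba(self, feature_table: pd.DataFrame) -> np.ndarray:
        """Class-1 (patient) probability for new feature rows."""
        scores = reduction.transform(
            feature_table[list(self.standardizer.columns)], self.standardizer, self.pca
        )
        return mlp_mod.predict_proba(self.network, scores)[:, 1]

    def summary(self) -> str:
        lines = [
            "Radiomics MLP classifier",
            "=" * 54,
            f"samples: {len(self.model.table)}   features: {len(self.model.feature_cols)}"
            f"   components: {self.pca.k}",
            f"explained variance (top {self.pca.k} PCs): "
            f"{self.pca.explained_variance.sum():.4g}",
            f"hidden units: {self.network.config.hidden_units}   "
            f"stop epoch: {self.network.stop_epoch}",
            f"features with contribution > {self.contributions.cutoff}: "
            f"{len(self.contributions.selected)}",
            "",
        ]
        for name, rep in (("Training", self.train_metrics), ("Test", self.test_metrics)):
            if rep is None:
                continue
            lines.append(f"{name} cohort")
            lines.append("-" * 54)
            lines.append(str(rep))
            lines.append("")
        return "\n".join(lines)


@dataclass
class CrossValidationResults:
    """Per-fold metric reports of the k-fold protocol."""

    model: RadiomicsClassifier
    folds: list[ev.MetricsReport]
    proba_oof: np.ndarray
    k: int
    seed: int

    def mean_metrics(self) -> dict[str, float]:
        keys = ("accuracy", "sensitivity", "specificity", "ppv", "npv", "f1", "mcc", "auc")
        out = {}
        for key in keys:
            vals = [getattr(f, key) for f in self.folds]
            vals = [v for v in vals if v is not None and np.isfinite(v)]
            out[key] = float(np.mean(vals)) if vals else float("nan")
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([f.as_dict() for f in self.folds])

    def summary(self) -> str:
        m = self.mean_metrics()
        return (
            f"{self.k}-fold cross-validation (mean over folds)\n"
            + "-" * 54
            + f"\naccuracy    {m['accuracy']:6.1f}%"
            + f"\nAUC         {m['auc']:6.1f}"
            + f"\nsensitivity {m['sensitivity']:6.1f}%"
            + f"\nspecificity {m['specificity']:6.1f}%"
            + f"\nPPV         {m['ppv']:6.1f}%"
            + f"\nNPV         {m['npv']:6.1f}%"
            + f"\nF1          {m['f1']:7.2f}"
            + f"\nMCC         {m['mcc']:7.2f}"
        )
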