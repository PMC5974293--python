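"""Model/Results interface for phosphosite prediction.

``PhosphoSitePredictor`` is constructed from curated site data plus the
feature providers (embedding model and per-residue profiles), builds the
per-site feature matrix once, and ``fit()`` returns a
``PhosphoSiteResults`` carrying the cross-validated AUCs, the selected SVM
configuration, the final fitted scorer, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .curation import SiteDataset, task_residues
from .embedding import EmbeddingModel, context2vec
from .evaluation import (
    CrossValResult,
    MetricsReport,
    SvmConfig,
    cross_validate,
    evaluate_scores,
    train_svm,
)
from .features import FeatureLayout, residue_level_features
from .seqio import ProteinRecord

ProfileProvider = Callable[[ProteinRecord], "object"]


def build_feature_matrix(
    dataset: SiteDataset,
    records: Sequence[ProteinRecord],
    embedding_model: EmbeddingModel | None,
    profile_provider: ProfileProvider,
    strategy: str = "add",
    m: int = 7,
    include_residue: bool = True,
    include_context: bool = True,
    n: int = 3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int, str]]]:
    """Assemble (X, y, sites) for every positive and negative in a dataset.

    Feature-group order per site is the fixed layout (residue-level groups
    then context); either block can be switched off for ablations.  The
    inference strategy derives one sub-seed per site from ``seed`` so rows
    are independent of evaluation order.
    """
    if not include_residue and not include_context:
        raise ValueError("at least one of residue/context feature blocks is required")
    if include_context and embedding_model is None:
        raise ValueError("context features requested but no embedding model given")
    rec_map = {r.accession: r for r in records}
    sites: list[tuple[str, int, str, int]] = []
    for p in dataset.positives:
        sites.append((p.accession, p.position, p.residue, 1))
    for acc, pos, res in dataset.negatives:
        sites.append((acc, pos, res, 0))

    profiles: dict[str, object] = {}
    rows, labels, keys = [], [], []
    for site_no, (acc, pos, res, label) in enumerate(sites):
        rec = rec_map.get(acc)
        if rec is None:
            raise KeyError(f"no sequence for accession {acc}")
        i = pos - 1
        parts = []
        if include_residue:
            if acc not in profiles:
                profiles[acc] = profile_provider(rec)
            parts.append(residue_level_features(rec, i, profiles[acc]))
        if include_context:
            parts.append(
                context2vec(
                    rec.sequence, i, m, embedding_model, strategy, n,
                    seed=(seed + site_no) % (2**31 - 1),
                )
            )
        rows.append(np.concatenate(parts))
        labels.append(label)
        keys.append((acc, pos, res))
    return np.vstack(rows), np.array(labels), keys


def feature_names(
    context_dim: int, include_residue: bool = True, include_context: bool = True
) -> list[str]:
    names = FeatureLayout(context_dim).names()
    if not include_residue:
        names = [n for n in names if n.startswith("context")]
    if not include_context:
        names = [n for n in names if not n.startswith("context")]
    return names


class PhosphoSitePredictor:
    """SVM phosphosite model over assembled per-site features.

    Parameters
    ----------
    X, y : feature matrix and binary labels (1 = phosphosite).
    task : task identifier, e.g. "general-S" or "kinase:AGC/PKA".
    names : optional column names matching X.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        task: str = "general-S",
        names: list[str] | None = None,
        sites: list[tuple[str, int, str]] | None = None,
    ) -> None:
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y disagree on the number of sites")
        self.task = task
        self.names = names
        self.sites = sites

    @classmethod
    def from_dataset(
        cls,
        dataset: SiteDataset,
        records: Sequence[ProteinRecord],
        embedding_model: EmbeddingModel | None,
        profile_provider: ProfileProvider,
        strategy: str = "add",
        m: int = 7,
        include_residue: bool = True,
        include_context: bool = True,
        seed: int = 0,
    ) -> "PhosphoSitePredictor":
        """Build the model straight from a curated SiteDataset."""
        X, y, keys = build_feature_matrix(
            dataset, records, embedding_model, profile_provider,
            strategy=strategy, m=m,
            include_residue=include_residue, include_context=include_context,
            seed=seed,
        )
        dim = embedding_model.dim if (include_context and embedding_model) else 0
        return cls(
            X, y, task=dataset.task,
            names=feature_names(dim, include_residue, include_context),
            sites=keys,
        )

    def fit(
        self,
        config: SvmConfig | None = None,
        k: int = 10,
        grid: list[SvmConfig] | None = None,
        seed: int = 0,
    ) -> "PhosphoSiteResults":
        """Cross-validate (grid search unless ``config`` pins one setting),
        then refit the selected configuration on all sites."""
        if config is not None:
            grid = [config]
        cv = cross_validate(self.X, self.y, k=k, grid=grid, seed=seed)
        scorer = train_svm(self.X, self.y, cv.best_config, seed=seed)
        return PhosphoSiteResults(self, cv, scorer, k=k, seed=seed)


@dataclass
class PhosphoSiteResults:
    """Fit results: selected configuration, per-fold AUCs, final scorer."""

    model: PhosphoSitePredictor
    cv: CrossValResult
    scorer: object
    k: int
    seed: int

    @property
    def config(self) -> SvmConfig:
        return self.cv.best_config

    @property
    def mean_auc(self) -> float:
        return self.cv.best_mean

    @property
    def sd_auc(self) -> float:
        return self.cv.best_sd

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Real-valued decision scores for new sites."""
        return self.scorer.decision_function(np.asarray(X, dtype=float))

    def evaluate(self, X: np.ndarray, y: np.ndarray) -> MetricsReport:
        """AUC/ROC plus Sens/Spec/MCC at the task's FPR anchors."""
        residue_class = "Y" if task_residues(self.model.task) == ("Y",) else "S"
        return evaluate_scores(self.predict_scores(X), y, residue_class)

    def summary(self) -> str:
        """Text table of the fit, statsmodels-style."""
        n_pos = int(np.sum(self.model.y == 1))
        n_neg = int(np.sum(self.model.y == 0))
        lines = [
            "Phosphosite SVM results",
            "=" * 54,
            f"Task:               {self.model.task}",
            f"Sites:              {n_pos} positives, {n_neg} negatives",
            f"Features:           {self.model.X.shape[1]}",
            f"CV folds:           {self.k}",
            f"Selected kernel/C:  {self.config.kernel}, C={self.config.C:g}",
            f"CV AUC:             {self.mean_auc:.3f} +/- {self.sd_auc:.3f}",
            "-" * 54,
            "grid results (mean AUC +/- sd):",
        ]
        for cfg in sorted(self.cv.mean_auc, key=lambda c: (c.kernel, c.C)):
            lines.append(
                f"  {cfg.kernel:<7} C={cfg.C:<4g} "
                f"{self.cv.mean_auc[cfg]:.3f} +/- {self.cv.sd_auc[cfg]:.3f}"
            )
        return "\n".join(lines)

    def fold_table(self) -> pd.DataFrame:
        """Per-fold AUCs for every grid configuration."""
        rows = []
        for cfg, aucs in self.cv.fold_aucs.items():
            for f, a in enumerate(aucs):
                rows.append({"kernel": cfg.kernel, "C": cfg.C, "fold": f, "auc": a})
        return pd.DataFrame(rows)
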