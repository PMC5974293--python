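"""End-to-end orchestration: configuration, pipeline runs, featurisation.

A ``RunConfig`` pins every stochastic stage to an explicit seed and
serialises to JSON next to the outputs, so a run directory is reproducible
from its own config snapshot.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import curation, synthetic
from .curation import SiteAnnotation, build_dataset, make_splits
from .embedding import EmbeddingHyperparams, EmbeddingModel, train_embedding
from .evaluation import TASK_PRESETS, SvmConfig, default_grid
from .model import PhosphoSitePredictor, build_feature_matrix, feature_names
from .seqio import ProteinRecord, build_corpus, read_fasta
from .synthetic import MotifSpec, generate_synthetic_proteome, synthetic_profile_provider

log = logging.getLogger("phosctx")


@dataclass
class RunConfig:
    """Complete configuration of one pipeline run."""

    task: str = "general-S"
    ngram: int = 3
    strategy: str = "add"
    window_size: int = 15  # total context window, 2m+1
    hyperparams: EmbeddingHyperparams = field(default_factory=EmbeddingHyperparams)
    svm: SvmConfig | None = None  # None -> grid search
    cv_folds: int = 10
    negative_ratio: float = 1.0
    # synthetic-data conditions (used when no FASTA/annotations given)
    num_proteins: int = 200
    length_range: tuple[int, int] = (80, 160)
    motif_fraction: float = 0.3
    # per-stage seeds
    seed_corpus: int = 1
    seed_embedding: int = 2
    seed_split: int = 3
    seed_sampling: int = 4
    seed_cv: int = 5

    def __post_init__(self) -> None:
        if self.window_size % 2 == 0 or self.window_size < 3:
            raise ValueError("window_size must be odd and >= 3")
        if isinstance(self.hyperparams, dict):
            self.hyperparams = EmbeddingHyperparams(**self.hyperparams)
        if isinstance(self.svm, dict):
            self.svm = SvmConfig(**self.svm)

    @property
    def m(self) -> int:
        return (self.window_size - 1) // 2

    @classmethod
    def from_preset(cls, task: str, **overrides) -> "RunConfig":
        """Config preconfigured with the task's published strategy/window/SVM."""
        preset = TASK_PRESETS.get(task)
        if preset is None:
            raise ValueError(f"no preset for task {task!r}; known: {sorted(TASK_PRESETS)}")
        kwargs = dict(
            task=task,
            strategy=preset["strategy"],
            window_size=preset["window_size"],
            svm=SvmConfig(preset["kernel"], preset["C"]),
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, default=str)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["length_range"] = tuple(d["length_range"])
        return cls(**d)


def run_pipeline(
    config: RunConfig,
    outdir: str | Path,
    records: Sequence[ProteinRecord] | None = None,
    annotations: Sequence[SiteAnnotation] | None = None,
) -> dict:
    """Execute the full pipeline and write models, metrics, and manifests.

    Without explicit inputs, a synthetic proteome with a planted PKA-like
    motif supplies sequences and annotations.  Stages: corpus and embedding
    training, annotation split, 1:1 negative sampling, feature assembly,
    cross-validated SVM fit, independent-style test on the held-out split,
    and a config snapshot sufficient to reproduce everything.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(config.to_json())

    if records is None:
        log.info("generating synthetic proteome (%d proteins)", config.num_proteins)
        records, annotations = generate_synthetic_proteome(
            config.num_proteins,
            config.length_range,
            MotifSpec(fraction=config.motif_fraction),
            seed=config.seed_corpus,
        )
    if not annotations:
        raise ValueError("pipeline needs site annotations (none given or generated)")
    annotations, rejected = curation.validate_annotations(annotations, records)
    if not annotations:
        raise ValueError("all annotations were rejected against the sequences")

    corpus = build_corpus(records, config.ngram)
    model = train_embedding(corpus, config.hyperparams, seed=config.seed_embedding)
    model.save(outdir / "embedding")

    task_pos = curation.select_task_positives(annotations, config.task)
    if not task_pos:
        raise ValueError(f"no positive annotations match task {config.task!r}")
    train_pos, test_pos = make_splits(task_pos, k=5, seed=config.seed_split)
    provider = lambda rec: synthetic_profile_provider(rec, seed=config.seed_corpus)

    train_ds = build_dataset(
        records, train_pos, config.task, "train",
        ratio=config.negative_ratio, seed=config.seed_sampling,
        known_positives=annotations,
    )
    test_ds = build_dataset(
        records, test_pos, config.task, "test",
        seed=config.seed_sampling, known_positives=annotations,
    )

    predictor = PhosphoSitePredictor.from_dataset(
        train_ds, records, model, provider,
        strategy=config.strategy, m=config.m, seed=config.seed_sampling,
    )
    results = predictor.fit(
        config=config.svm, k=config.cv_folds,
        grid=None if config.svm else default_grid(), seed=config.seed_cv,
    )
    (outdir / "summary.txt").write_text(results.summary() + "\n")
    results.fold_table().to_csv(outdir / "fold_aucs.tsv", sep="\t", index=False)

    Xte, yte, test_keys = build_feature_matrix(
        test_ds, records, model, provider,
        strategy=config.strategy, m=config.m, seed=config.seed_sampling,
    )
    report = results.evaluate(Xte, yte)

    manifest = pd.DataFrame(
        [(a, p, r, "train", 1) for a, p, r in (s.key + (s.residue,) for s in train_ds.positives)]
        + [(a, p, r, "train", 0) for a, p, r in train_ds.negatives]
        + [(a, p, r, "test", 1) for a, p, r in (s.key + (s.residue,) for s in test_ds.positives)]
        + [(a, p, r, "test", 0) for a, p, r in test_ds.negatives],
        columns=["accession", "position", "residue", "role", "label"],
    )
    manifest.to_csv(outdir / "site_manifest.tsv", sep="\t", index=False)

    metrics = {
        "task": config.task,
        "cv_mean_auc": results.mean_auc,
        "cv_sd_auc": results.sd_auc,
        "selected_kernel": results.config.kernel,
        "selected_C": results.config.C,
        "test_auc": report.auc,
        "test_at_fpr": {
            str(level): {
                "cutoff": d["cutoff"],
                "sensitivity": d["sensitivity"],
                "specificity": d["specificity"],
                "mcc": d["mcc"],
            }
            for level, d in report.at_threshold.items()
        },
        "n_train_pos": len(train_ds.positives),
        "n_train_neg": len(train_ds.negatives),
        "n_test_pos": len(test_ds.positives),
        "n_test_neg": len(test_ds.negatives),
        "n_rejected_annotations": len(rejected),
    }
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2))
    log.info("pipeline complete: CV AUC %.3f, test AUC %.3f", results.mean_auc, report.auc)
    return {
        "results": results,
        "test_report": report,
        "metrics": metrics,
        "records": records,
        "embedding": model,
        "train_dataset": train_ds,
        "test_dataset": test_ds,
    }


def featurize_sites(
    records: Sequence[ProteinRecord],
    sites: Sequence[tuple[str, int]],
    model: EmbeddingModel,
    config: RunConfig,
    site_mode: str = "phospho",
) -> pd.DataFrame:
    """Feature table (one named row per requested site).

    ``site_mode`` "phospho" skips, with a warning column, sites whose
    residue is not S/T/Y; "any" featurises every requested position.
    """
    rec_map = {r.accession: r for r in records}
    provider = lambda rec: synthetic_profile_provider(rec, seed=config.seed_corpus)
    rows, index = [], []
    for acc, pos in sites:
        rec = rec_map.get(acc)
        if rec is None:
            raise KeyError(f"unknown accession {acc}")
        res = rec.sequence[pos - 1]
        if site_mode == "phospho" and res not in curation.PHOSPHO_RESIDUES:
            log.warning("skipping %s@%d: residue %s is not S/T/Y", acc, pos, res)
            continue
        ds = curation.SiteDataset(
            positives=[], negatives=[(acc, pos, res)], task=config.task, role="test"
        )
        X, _, _ = build_feature_matrix(
            ds, [rec], model,
            provider, strategy=config.strategy, m=config.m, seed=config.seed_sampling,
        )
        rows.append(X[0])
        index.append((acc, pos, res))
    columns = feature_names(model.dim)
    df = pd.DataFrame(rows, columns=columns)
    meta = pd.DataFrame(index, columns=["accession", "position", "residue"])
    return pd.concat([meta, df], axis=1)


def load_inputs(fasta: str | Path, sites: str | Path | None):
    records = read_fasta(fasta)
    annotations = curation.read_annotations(sites) if sites else []
    return records, annotations
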