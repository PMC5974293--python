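"""Phosphosite dataset curation: merging, filtering, splitting, sampling.

Annotations are triple records (protein accession, 1-based site position,
kinase label).  Curation merges annotation sources, drops records inferred
by similarity, normalises kinase names against the hierarchical
group/family naming, collapses duplicates, and excludes kinases with fewer
than 20 records.  Benchmark kinase families are those with more than 500
records.  Training negatives are down-sampled 1:1 from unannotated S/T/Y
sites; test negatives are every unannotated site of the residue class the
task targets, without down-sampling.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .seqio import ProteinRecord

PHOSPHO_RESIDUES = ("S", "T", "Y")

Role = Literal["train", "test"]

# residue classes a task draws its candidate sites from
_TASK_RESIDUES = {
    "general-S": ("S",),
    "general-T": ("T",),
    "general-Y": ("Y",),
}

# of the five benchmarked families, TK/SRC phosphorylates Y; the rest S/T
KINASE_RESIDUES = {
    "AGC/PKA": ("S", "T"),
    "AGC/PKC": ("S", "T"),
    "CMGC/CK2": ("S", "T"),
    "CMGC/CDK": ("S", "T"),
    "TK/SRC": ("Y",),
}


def task_residues(task: str) -> tuple[str, ...]:
    """Residue letters (S/T/Y) that are candidate sites for a task."""
    if task in _TASK_RESIDUES:
        return _TASK_RESIDUES[task]
    if task.startswith("kinase:"):
        label = task.split(":", 1)[1]
        if label in KINASE_RESIDUES:
            return KINASE_RESIDUES[label]
        return ("S", "T", "Y")
    raise ValueError(f"unknown task {task!r}")


@dataclass(frozen=True)
class SiteAnnotation:
    """One triple-record annotation with provenance."""

    accession: str
    position: int  # 1-based
    residue: str
    kinase_label: str | None = None
    source: str = ""
    by_similarity: bool = False

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.accession}: site positions are 1-based (got {self.position})")
        if self.residue not in PHOSPHO_RESIDUES:
            raise ValueError(f"{self.accession}@{self.position}: residue must be S/T/Y, got {self.residue!r}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.accession, self.position)


@dataclass
class SiteDataset:
    """Positives and negatives for one prediction task and role."""

    positives: list[SiteAnnotation]
    negatives: list[tuple[str, int, str]]  # (accession, 1-based position, residue)
    task: str
    role: Role

    def __post_init__(self) -> None:
        pos_keys = {p.key for p in self.positives}
        neg_keys = {(a, p) for a, p, _ in self.negatives}
        overlap = pos_keys & neg_keys
        if overlap:
            raise ValueError(f"sites in both positives and negatives: {sorted(overlap)[:5]}")


def validate_annotations(
    annotations: Iterable[SiteAnnotation],
    records: Mapping[str, ProteinRecord] | Sequence[ProteinRecord],
) -> tuple[list[SiteAnnotation], list[SiteAnnotation]]:
    """Split annotations into (valid, rejected) against their sequences.

    An annotation is rejected when its accession is unknown, its position is
    out of bounds, or the residue letter disagrees with the sequence.
    """
    if not isinstance(records, Mapping):
        records = {r.accession: r for r in records}
    valid, rejected = [], []
    for a in annotations:
        rec = records.get(a.accession)
        if rec is None or a.position > len(rec.sequence) or rec.sequence[a.position - 1] != a.residue:
            rejected.append(a)
        else:
            valid.append(a)
    if rejected:
        warnings.warn(
            f"{len(rejected)} annotations rejected (unknown accession, out-of-range "
            "position, or residue mismatch)",
            stacklevel=2,
        )
    return valid, rejected


def merge_annotations(
    set_a: Iterable[SiteAnnotation],
    set_b: Iterable[SiteAnnotation] = (),
    rename_map: Mapping[str, str] | None = None,
    kinase_name_map: Mapping[str, str] | None = None,
    min_kinase_count: int = 20,
) -> list[SiteAnnotation]:
    """Merge two annotation sources under the curation rules.

    Records flagged by-similarity are dropped; accessions are renamed via
    ``rename_map``; kinase labels normalised via ``kinase_name_map``; exact
    duplicate triples collapse to one; kinases with fewer than
    ``min_kinase_count`` records are removed entirely (unlabelled records
    are never removed by the count filter).
    """
    rename_map = rename_map or {}
    kinase_name_map = kinase_name_map or {}
    merged: dict[tuple[str, int, str | None], SiteAnnotation] = {}
    for a in list(set_a) + list(set_b):
        if a.by_similarity:
            continue
        acc = rename_map.get(a.accession, a.accession)
        kin = kinase_name_map.get(a.kinase_label, a.kinase_label) if a.kinase_label else None
        a = replace(a, accession=acc, kinase_label=kin)
        merged.setdefault((acc, a.position, kin), a)
    counts: dict[str, int] = {}
    for a in merged.values():
        if a.kinase_label:
            counts[a.kinase_label] = counts.get(a.kinase_label, 0) + 1
    keep = {k for k, c in counts.items() if c >= min_kinase_count}
    return [a for a in merged.values() if a.kinase_label is None or a.kinase_label in keep]


def select_benchmark_kinases(
    annotations: Iterable[SiteAnnotation], min_count: int = 500
) -> list[str]:
    """Kinase labels with strictly more than ``min_count`` records,
    sorted by count descending (ties broken alphabetically)."""
    counts: dict[str, int] = {}
    for a in annotations:
        if a.kinase_label:
            counts[a.kinase_label] = counts.get(a.kinase_label, 0) + 1
    chosen = [k for k, c in counts.items() if c > min_count]
    return sorted(chosen, key=lambda k: (-counts[k], k))


def select_task_positives(
    annotations: Iterable[SiteAnnotation], task: str
) -> list[SiteAnnotation]:
    """Positives relevant to a task: residue class for general models,
    kinase label (within its residue class) for kinase-specific models."""
    res = task_residues(task)
    if task.startswith("kinase:"):
        label = task.split(":", 1)[1]
        return [a for a in annotations if a.kinase_label == label and a.residue in res]
    return [a for a in annotations if a.residue in res]


def make_splits(
    annotations: Sequence[SiteAnnotation], k: int = 5, seed: int = 0
) -> tuple[list[SiteAnnotation], list[SiteAnnotation]]:
    """Partition records into k near-equal subsets; k-1 train, 1 test.

    The partition is a seeded random permutation chopped into contiguous
    blocks; block sizes differ by at most one.  The last block is the test
    fold.
    """
    N = len(annotations)
    if N < k:
        raise ValueError(f"need at least k={k} records, got {N}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(N)
    sizes = np.full(k, N // k)
    sizes[: N % k] += 1
    bounds = np.cumsum(sizes)
    test_idx = set(order[bounds[-2]:].tolist()) if k > 1 else set()
    train = [annotations[j] for j in range(N) if j not in test_idx]
    test = [annotations[j] for j in sorted(test_idx)]
    return train, test


def enumerate_candidate_sites(
    records: Iterable[ProteinRecord], residues: Sequence[str] = PHOSPHO_RESIDUES
) -> list[tuple[str, int, str]]:
    """All (accession, 1-based position, residue) sites of the given classes."""
    out = []
    for r in records:
        for j, c in enumerate(r.sequence, start=1):
            if c in residues:
                out.append((r.accession, j, c))
    return out


def sample_negatives(
    records: Sequence[ProteinRecord],
    positives: Sequence[SiteAnnotation],
    task: str,
    role: Role,
    ratio: float = 1.0,
    seed: int = 0,
    known_positives: Iterable[SiteAnnotation] | None = None,
) -> list[tuple[str, int, str]]:
    """Select negative sites for a task.

    Sites annotated as phosphosites anywhere (``known_positives``, defaulting
    to ``positives``) are never negatives.  Training draws a seeded uniform
    sample of size ratio x |positives| from all unannotated S/T/Y sites;
    testing takes every unannotated site of the residue class(es) the task
    targets, without sampling.
    """
    excluded = {p.key for p in (known_positives if known_positives is not None else positives)}
    excluded |= {p.key for p in positives}
    if role == "test":
        pool = enumerate_candidate_sites(records, task_residues(task))
        return [s for s in pool if (s[0], s[1]) not in excluded]
    pool = [s for s in enumerate_candidate_sites(records) if (s[0], s[1]) not in excluded]
    want = int(round(ratio * len(positives)))
    if want > len(pool):
        raise ValueError(
            f"negative pool of {len(pool)} sites cannot supply {want} samples"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=want, replace=False)
    return [pool[j] for j in sorted(idx)]


def build_dataset(
    records: Sequence[ProteinRecord],
    positives: Sequence[SiteAnnotation],
    task: str,
    role: Role,
    ratio: float = 1.0,
    seed: int = 0,
    known_positives: Iterable[SiteAnnotation] | None = None,
) -> SiteDataset:
    """Positives plus task/role-appropriate negatives as one SiteDataset."""
    negatives = sample_negatives(records, positives, task, role, ratio, seed, known_positives)
    return SiteDataset(list(positives), negatives, task, role)


# -- annotation-table I/O ---------------------------------------------------

_COLUMNS = ["accession", "position", "residue", "kinase_label", "source"]


def read_annotations(path: str | Path) -> list[SiteAnnotation]:
    """Read a tab-separated annotation table (header optional).

    Columns: accession, position (1-based), residue, kinase_label
    (slash-separated hierarchy or empty), source.  A trailing
    ``by_similarity`` column with value 1/true marks inferred records.
    """
    out = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[0] == "accession":
                continue
            if len(row) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            row += [""] * (6 - len(row))
            out.append(
                SiteAnnotation(
                    accession=row[0],
                    position=int(row[1]),
                    residue=row[2],
                    kinase_label=row[3] or None,
                    source=row[4],
                    by_similarity=row[5].lower() in ("1", "true", "yes"),
                )
            )
    return out


def write_annotations(annotations: Iterable[SiteAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_COLUMNS + ["by_similarity"])
        for a in annotations:
            writer.writerow(
                [a.accession, a.position, a.residue, a.kinase_label or "", a.source,
                 "1" if a.by_similarity else "0"]
            )
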