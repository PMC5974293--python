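"""Residue-level feature groups and per-site feature-vector assembly.

Six residue-level groups are computed for each candidate phosphosite:

1. Shannon entropy (1) of the residue's evolutionary-profile row, measuring
   positional conservation.
2. Relative entropy (1) of that row against a background amino-acid
   distribution (BLOSUM62 marginals by default).
3. Predicted intrinsic disorder probability (1).
4. Predicted 3-state secondary-structure probabilities (3: helix, strand,
   coil).
5. Taylor overlapping physicochemical properties of the residue (10 bits).
6. Average cumulative hydrophobicity (10): mean Sweet–Eisenberg index over
   centred windows of sizes 3, 5, ..., 21.

Together with a 100-dimensional context embedding these stack into a
126-component feature vector per site.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .seqio import STANDARD_AA, ProteinRecord

AA_INDEX = {aa: k for k, aa in enumerate(STANDARD_AA)}

# Sweet & Eisenberg optimal matching hydrophobicity (AAindex SWER830101).
SWEET_EISENBERG = {
    "A": -0.40, "R": -0.59, "N": -0.92, "D": -1.31, "C": 0.17,
    "Q": -0.91, "E": -1.22, "G": -0.67, "H": -0.64, "I": 1.25,
    "L": 1.22, "K": -0.67, "M": 1.02, "F": 1.92, "P": -0.49,
    "S": -0.55, "T": -0.28, "W": 0.50, "Y": 0.81, "V": 0.91,
}

# BLOSUM62 background (marginal) amino-acid frequencies, 4 decimals.
BLOSUM62_BACKGROUND = {
    "A": 0.0740, "R": 0.0520, "N": 0.0450, "D": 0.0540, "C": 0.0250,
    "Q": 0.0340, "E": 0.0540, "G": 0.0740, "H": 0.0260, "I": 0.0680,
    "L": 0.0990, "K": 0.0580, "M": 0.0250, "F": 0.0470, "P": 0.0390,
    "S": 0.0570, "T": 0.0510, "W": 0.0130, "Y": 0.0320, "V": 0.0730,
}

# Taylor's overlapping physicochemical classes (Venn-diagram membership).
TAYLOR_CLASSES = (
    ("hydrophobic", set("ACFGHIKLMTVWY")),
    ("polar", set("CDEHKNQRSTWY")),
    ("small", set("ACDGNPSTV")),
    ("tiny", set("AGS")),
    ("aliphatic", set("ILV")),
    ("aromatic", set("FHWY")),
    ("positive", set("HKR")),
    ("negative", set("DE")),
    ("charged", set("DEHKR")),
    ("proline", set("P")),
)

ACH_WINDOW_SIZES = tuple(range(3, 22, 2))  # 3, 5, ..., 21


def background_vector(bg: dict[str, float] | None = None) -> np.ndarray:
    """Background distribution as a 20-vector in STANDARD_AA order."""
    bg = BLOSUM62_BACKGROUND if bg is None else bg
    v = np.array([bg[aa] for aa in STANDARD_AA], dtype=float)
    if np.any(v < 0) or not math.isclose(v.sum(), 1.0, abs_tol=1e-3):
        raise ValueError("background probabilities must be >= 0 and sum to 1")
    return v / v.sum()


@dataclass
class ResidueProfile:
    """Per-residue evolutionary and structural channels for one protein.

    wop: (L, 20) weighted-observed-percentage rows, normalised to sum 1;
    disorder: (L,) disorder probabilities in [0, 1];
    ss3: (L, 3) helix/strand/coil probabilities.
    """

    wop: np.ndarray
    disorder: np.ndarray
    ss3: np.ndarray

    def __post_init__(self) -> None:
        self.wop = np.asarray(self.wop, dtype=float)
        self.disorder = np.asarray(self.disorder, dtype=float)
        self.ss3 = np.asarray(self.ss3, dtype=float)
        L = self.wop.shape[0]
        if self.wop.shape != (L, 20):
            raise ValueError(f"wop must be (L, 20), got {self.wop.shape}")
        if self.disorder.shape != (L,) or self.ss3.shape != (L, 3):
            raise ValueError("disorder/ss3 length mismatch with wop")
        if np.any(self.wop < 0) or np.any(self.ss3 < 0):
            raise ValueError("wop and ss3 entries must be non-negative")
        sums = self.wop.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("wop rows must be normalised to sum 1")

    def __len__(self) -> int:
        return self.wop.shape[0]


def shannon_entropy(wop_row: np.ndarray, base: float = 2.0) -> float:
    """Shannon entropy H = -sum p log p of a normalised 20-way profile row.

    Zero components contribute zero.  In bits by default; 0 <= H <= log2(20).
    """
    p = np.asarray(wop_row, dtype=float)
    if p.shape != (20,):
        raise ValueError(f"expected a 20-vector, got shape {p.shape}")
    if np.any(p < 0):
        raise ValueError("profile row must be non-negative")
    total = p.sum()
    if total == 0:
        raise ValueError("profile row is all zero; entropy undefined")
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / math.log(base))


def relative_entropy(
    wop_row: np.ndarray, bg: np.ndarray | None = None, base: float = 2.0
) -> float:
    """Kullback–Leibler divergence KL(p || q) of the profile row vs background.

    Terms with p_a = 0 contribute zero; p_a > 0 where q_a = 0 is an error.
    """
    p = np.asarray(wop_row, dtype=float)
    if p.shape != (20,):
        raise ValueError(f"expected a 20-vector, got shape {p.shape}")
    total = p.sum()
    if total == 0:
        raise ValueError("profile row is all zero")
    p = p / total
    q = background_vector() if bg is None else np.asarray(bg, dtype=float)
    mask = p > 0
    if np.any(q[mask] == 0):
        raise ValueError("background has zero mass where the profile does not")
    return float((p[mask] * np.log(p[mask] / q[mask])).sum() / math.log(base))


def taylor_op(aa: str) -> np.ndarray:
    """10-bit Taylor overlapping-property encoding of one residue letter.

    Non-standard letters encode as all zeros (with a warning).
    """
    if aa not in AA_INDEX:
        warnings.warn(f"non-standard residue {aa!r} encoded as zeros", stacklevel=2)
        return np.zeros(10)
    return np.array([1.0 if aa in members else 0.0 for _, members in TAYLOR_CLASSES])


def ach(
    sequence: str,
    i: int,
    index: dict[str, float] | None = None,
    boundary: str = "truncate",
) -> np.ndarray:
    """Average cumulative hydrophobicity over windows of sizes 3..21.

    One value per window size: the mean index value over residues of the
    size-w window centred at i.  At sequence boundaries, "truncate" averages
    only in-bounds residues; "zero" treats out-of-bounds positions as zero
    contributions over the full window length.  Residues without an index
    value (ambiguity letters) contribute zero.
    """
    if not 0 <= i < len(sequence):
        raise IndexError(f"residue index {i} out of range for length {len(sequence)}")
    idx = SWEET_EISENBERG if index is None else index
    out = np.empty(len(ACH_WINDOW_SIZES))
    for k, w in enumerate(ACH_WINDOW_SIZES):
        m = w // 2
        lo, hi = max(0, i - m), min(len(sequence), i + m + 1)
        vals = [idx.get(c, 0.0) for c in sequence[lo:hi]]
        denom = len(vals) if boundary == "truncate" else w
        out[k] = sum(vals) / denom
    return out


def profile_from_psiblast(path) -> np.ndarray:
    """Parse the weighted-observed-percentage block of a PSI-BLAST ASCII PSSM.

    The standard -out_ascii_pssm file carries, per residue row, 20 log-odds
    columns followed by 20 percentage columns; the percentage columns are
    returned, reordered to STANDARD_AA order and normalised to sum 1.
    All-zero rows are replaced by the BLOSUM62 background with a warning.
    """
    rows: list[np.ndarray] = []
    header_order: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = line.split()
            if header_order is None:
                # column-header line lists the 20 letters twice
                if len(toks) == 40 and all(t in AA_INDEX for t in toks):
                    header_order = toks[20:]
                continue
            if not toks:
                continue
            if not toks[0].isdigit():
                break  # footer (statistics block)
            if len(toks) < 42:
                raise ValueError(f"{path}:{lineno}: expected 20+20 profile columns")
            try:
                perc = np.array([float(t) for t in toks[22:42]])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: non-numeric profile entry") from e
            rows.append(perc)
    if header_order is None or not rows:
        raise ValueError(f"{path}: no weighted-observed-percentage block found")
    wop = np.vstack(rows)
    order = [header_order.index(aa) for aa in STANDARD_AA]
    wop = wop[:, order]
    sums = wop.sum(axis=1)
    zero = sums == 0
    if np.any(zero):
        warnings.warn(
            f"{path}: {int(zero.sum())} all-zero profile rows replaced by background",
            stacklevel=2,
        )
        wop[zero] = background_vector() * 100.0
        sums = wop.sum(axis=1)
    return wop / sums[:, None]


def read_residue_table(path, num_columns: int) -> np.ndarray:
    """Read a whitespace-delimited per-residue table (disorder or ss3).

    Expected columns: position, residue letter, then ``num_columns`` numeric
    values.  Lines starting with '#' are skipped.  Returns (L, num_columns).
    """
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            toks = line.split()
            if len(toks) < 2 + num_columns:
                raise ValueError(f"{path}:{lineno}: expected {2 + num_columns} columns")
            rows.append([float(t) for t in toks[2 : 2 + num_columns]])
    return np.array(rows)


@dataclass(frozen=True)
class FeatureLayout:
    """Named offsets of the per-site feature groups within the flat vector."""

    context_dim: int = 100

    @property
    def groups(self) -> list[tuple[str, int]]:
        return [
            ("shannon", 1),
            ("rel_entropy", 1),
            ("diso", 1),
            ("pss", 3),
            ("op", 10),
            ("ach", 10),
            ("context", self.context_dim),
        ]

    @property
    def total(self) -> int:
        return sum(width for _, width in self.groups)

    def slices(self) -> dict[str, slice]:
        out, off = {}, 0
        for name, width in self.groups:
            out[name] = slice(off, off + width)
            off += width
        return out

    def names(self) -> list[str]:
        cols = []
        for name, width in self.groups:
            if width == 1:
                cols.append(name)
            else:
                cols.extend(f"{name}_{k}" for k in range(width))
        return cols


@dataclass
class FeatureVector:
    """The assembled per-site representation with its named-group layout."""

    values: np.ndarray
    layout: FeatureLayout = field(default_factory=FeatureLayout)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.layout.total,):
            raise ValueError(
                f"feature vector length {self.values.shape} != layout total {self.layout.total}"
            )

    def group(self, name: str) -> np.ndarray:
        return self.values[self.layout.slices()[name]]

    def __len__(self) -> int:
        return len(self.values)


def residue_level_features(
    record: ProteinRecord, i: int, profile: ResidueProfile
) -> np.ndarray:
    """The 26 residue-level components (all groups except context)."""
    if len(profile) != len(record.sequence):
        raise ValueError(
            f"{record.accession}: profile length {len(profile)} != sequence length"
        )
    row = profile.wop[i]
    return np.concatenate(
        [
            [shannon_entropy(row)],
            [relative_entropy(row)],
            [profile.disorder[i]],
            profile.ss3[i],
            taylor_op(record.sequence[i]),
            ach(record.sequence, i),
        ]
    )


def assemble_feature_vector(
    record: ProteinRecord,
    i: int,
    profile: ResidueProfile,
    context: np.ndarray,
) -> FeatureVector:
    """Stack the six residue-level groups with the context embedding.

    Group order is fixed: shannon, rel_entropy, diso, pss, op, ach, context;
    for a 100-dimensional context embedding the total length is 126.
    """
    context = np.asarray(context, dtype=float)
    layout = FeatureLayout(context_dim=len(context))
    values = np.concatenate([residue_level_features(record, i, profile), context])
    return FeatureVector(values, layout)
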