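"""Synthetic proteomes, phosphosite annotations, and residue profiles.

Stands in for database-derived sequence and annotation data and for
profile/disorder/secondary-structure predictor outputs, so the whole
pipeline can be exercised and tested without downloads or external runs.
Sequences are drawn i.i.d. from the BLOSUM62 background amino-acid
frequencies; a kinase-like local motif can be planted around a fraction of
S/T (or Y) sites, which then become the positive annotations.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .curation import SiteAnnotation
from .features import ResidueProfile, background_vector
from .seqio import STANDARD_AA, ProteinRecord


@dataclass(frozen=True)
class MotifSpec:
    """A planted local pattern anchoring positive sites.

    ``pattern`` maps signed offsets from the site to a fixed residue letter;
    the default, R at -3 and -2 relative to an S/T acceptor, emulates the
    basophilic R-R-x-[S/T] consensus of PKA-family kinases.
    """

    kinase_label: str = "AGC/PKA"
    center_residues: tuple[str, ...] = ("S", "T")
    pattern: dict[int, str] = field(default_factory=lambda: {-3: "R", -2: "R"})
    fraction: float = 0.3

    def matches(self, sequence: str, i: int) -> bool:
        """True when every pattern offset around 0-based index i agrees."""
        if sequence[i] not in self.center_residues:
            return False
        for off, letter in self.pattern.items():
            j = i + off
            if not 0 <= j < len(sequence) or sequence[j] != letter:
                return False
        return True


def generate_synthetic_proteome(
    num_proteins: int,
    length_range: tuple[int, int] = (80, 160),
    motif_spec: MotifSpec | None = None,
    seed: int = 0,
) -> tuple[list[ProteinRecord], list[SiteAnnotation]]:
    """Generate random proteins and, optionally, planted positive sites.

    Residues are sampled from the BLOSUM62 background.  With a motif_spec, a
    ``fraction`` of eligible acceptor sites per protein is selected (seeded)
    and the surrounding residues overwritten with the motif pattern; those
    sites are emitted as positive annotations carrying the motif's kinase
    label.  All other S/T/Y positions remain unannotated.
    """
    if num_proteins < 1:
        raise ValueError("num_proteins must be >= 1")
    lo, hi = length_range
    if lo < 21 or hi < lo:
        raise ValueError(f"invalid length range {length_range}; lengths must be >= 21")
    rng = np.random.default_rng(seed)
    letters = np.array(list(STANDARD_AA))
    probs = background_vector()
    records: list[ProteinRecord] = []
    annotations: list[SiteAnnotation] = []
    for p in range(num_proteins):
        L = int(rng.integers(lo, hi + 1))
        seq = rng.choice(letters, size=L, p=probs)
        if motif_spec is not None:
            margin = max(abs(o) for o in motif_spec.pattern) if motif_spec.pattern else 0
            eligible = [
                i for i in range(margin, L - margin)
                if seq[i] in motif_spec.center_residues
            ]
            n_plant = int(round(motif_spec.fraction * len(eligible)))
            chosen = rng.choice(len(eligible), size=n_plant, replace=False) if n_plant else []
            for ci in sorted(chosen):
                i = eligible[ci]
                for off, letter in motif_spec.pattern.items():
                    seq[i + off] = letter
        sequence = "".join(seq)
        accession = f"SYN{p:05d}"
        records.append(ProteinRecord(accession, sequence))
        if motif_spec is not None:
            # re-scan: planting can overwrite an earlier chosen site's pattern
            for i in range(L):
                if motif_spec.matches(sequence, i):
                    annotations.append(
                        SiteAnnotation(
                            accession=accession,
                            position=i + 1,
                            residue=sequence[i],
                            kinase_label=motif_spec.kinase_label,
                            source="synthetic",
                        )
                    )
    return records, annotations


def synthetic_profile_provider(
    record: ProteinRecord,
    seed: int = 0,
    mix: float = 0.7,
    disorder_shape: tuple[float, float] = (2.0, 5.0),
) -> ResidueProfile:
    """Deterministic stand-in for profile/disorder/secondary-structure runs.

    Each residue's 20-way profile row is ``mix`` x one-hot(residue) +
    (1 - mix) x BLOSUM62 background (background only, for ambiguity
    letters); disorder is Beta(a, b) per residue; the secondary-structure
    triple is Dirichlet(1, 1, 1).  The stream is keyed on (seed, accession)
    so per-protein profiles are stable regardless of call order.
    """
    if not 0 <= mix <= 1:
        raise ValueError("mix must lie in [0, 1]")
    key = zlib.crc32(record.accession.encode()) & 0x7FFFFFFF
    rng = np.random.default_rng((seed, key))
    L = len(record.sequence)
    bg = background_vector()
    wop = np.tile(bg, (L, 1)) * (1.0 - mix)
    for i, aa in enumerate(record.sequence):
        k = STANDARD_AA.find(aa)
        if k >= 0:
            wop[i, k] += mix
        else:
            wop[i] = bg  # ambiguity letter: background row
    wop /= wop.sum(axis=1, keepdims=True)
    disorder = rng.beta(*disorder_shape, size=L)
    ss3 = rng.dirichlet(np.ones(3), size=L)
    return ResidueProfile(wop=wop, disorder=disorder, ss3=ss3)
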