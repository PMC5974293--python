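"""Sequence I/O, n-gram biological words, and tagged corpora.

Protein sequences are tokenised into fixed-length "biological words"
(n-grams of residues) before embedding training.  An overlapping split of a
length-L sequence yields L - n + 1 words; a non-overlapping split yields
floor(L / n) words with the trailing remainder dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS_AA = "XBZUO"
PERMITTED_AA = frozenset(STANDARD_AA + AMBIGUOUS_AA)

SplitMode = Literal["overlapping", "non-overlapping"]


class FastaFormatError(ValueError):
    """Raised when a FASTA entry cannot be parsed or validated."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: an accession and its amino-acid sequence."""

    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.accession}: sequence must be non-empty")
        bad = set(self.sequence) - PERMITTED_AA
        if bad:
            raise ValueError(
                f"{self.accession}: illegal residue letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BioWordList:
    """Ordered n-gram words produced from one source sequence."""

    words: tuple[str, ...]
    n: int
    mode: SplitMode

    def __len__(self) -> int:
        return len(self.words)

    def __iter__(self):
        return iter(self.words)


@dataclass
class TaggedCorpus:
    """Documents for embedding training: (document-id, word list) pairs."""

    documents: list[tuple[str, BioWordList]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.documents)

    @property
    def doc_ids(self) -> list[str]:
        return [doc_id for doc_id, _ in self.documents]

    def vocabulary(self) -> set[str]:
        vocab: set[str] = set()
        for _, wl in self.documents:
            vocab.update(wl.words)
        return vocab


def read_fasta(path: str | Path, *, on_invalid: str = "error") -> list[ProteinRecord]:
    """Read a multi-record FASTA file into ProteinRecords.

    The accession is the header token before the first whitespace; sequences
    are uppercased.  ``on_invalid`` controls residues outside the permitted
    alphabet: "error" rejects the record, "mask" maps them to 'X'.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        accession = entry.id
        if not accession:
            raise FastaFormatError(f"{path}: FASTA entry with empty header")
        seq = str(entry.seq).upper()
        bad = set(seq) - PERMITTED_AA
        if bad:
            if on_invalid == "mask":
                seq = "".join(c if c in PERMITTED_AA else "X" for c in seq)
            else:
                raise FastaFormatError(
                    f"{path}: record {accession} has illegal letters {sorted(bad)}"
                )
        if accession in seen:
            raise FastaFormatError(f"{path}: duplicate accession {accession}")
        seen.add(accession)
        records.append(ProteinRecord(accession, seq))
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records to FASTA, wrapping sequence lines at ``width``."""
    entries = [
        SeqRecord(Seq(r.sequence), id=r.accession, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(entries)


def split_ngrams(sequence: str, n: int = 3, mode: SplitMode = "overlapping") -> BioWordList:
    """Split a sequence into n-gram biological words.

    Overlapping mode emits every contiguous window (L - n + 1 words);
    non-overlapping mode emits windows at 0, n, 2n, ... and drops any
    trailing remainder shorter than n.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if mode not in ("overlapping", "non-overlapping"):
        raise ValueError(f"unknown split mode {mode!r}")
    L = len(sequence)
    if L < n:
        warnings.warn(
            f"sequence of length {L} shorter than word length {n}; empty word list",
            stacklevel=2,
        )
        return BioWordList((), n, mode)
    if mode == "overlapping":
        words = tuple(sequence[i : i + n] for i in range(L - n + 1))
    else:
        words = tuple(sequence[i : i + n] for i in range(0, L - n + 1, n))
    return BioWordList(words, n, mode)


def build_corpus(records: Sequence[ProteinRecord], n: int = 3) -> TaggedCorpus:
    """Tag each protein's overlapping n-gram words with its accession."""
    if not records:
        raise ValueError("cannot build a corpus from an empty record collection")
    counts: dict[str, int] = {}
    for r in records:
        counts[r.accession] = counts.get(r.accession, 0) + 1
    dups = sorted(a for a, c in counts.items() if c > 1)
    if dups:
        raise ValueError(f"duplicate accessions in corpus input: {dups}")
    corpus = TaggedCorpus()
    for r in records:
        corpus.documents.append((r.accession, split_ngrams(r.sequence, n, "overlapping")))
    return corpus
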