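"""Basic sequence containers and nucleotide utilities.

Internal conventions used throughout the toolkit:

* coordinates are 0-based, half-open; conversion to 1-based happens only in
  VCF/GFF writers;
* sequences are uppercase strings over ``{A, C, G, T, N}``; ``N`` runs are
  legal input and never count as matches;
* accessions are effectively haploid (inbred lines), so one sequence per
  chromosome is the whole genotype.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

_VALID = set("ACGTN")
_NORMALIZE = {c: c for c in "ACGTN"}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NON_ACGTN = re.compile(r"[^ACGTN]")


def normalize_sequence(seq: str) -> str:
    """Uppercase and map every non-ACGTN symbol (IUPAC codes etc.) to N."""
    seq = seq.upper()
    return _NON_ACGTN.sub("N", seq)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSet:
    """One accession's assembly: an ordered set of named chromosomes.

    Parameters
    ----------
    accession_id
        Text label for the accession (inbred line).
    chromosomes
        Ordered ``(name, sequence)`` pairs. Names must be unique, sequences
        non-empty and restricted to ``ACGTN`` (callers normally go through
        :func:`normalize_sequence`).
    """

    accession_id: str
    chromosomes: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            dup = next(n for i, n in enumerate(names) if n in names[:i])
            raise ValueError(f"duplicate chromosome name {dup!r} in accession {self.accession_id!r}")
        for name, seq in self.chromosomes:
            if not seq:
                raise ValueError(f"empty sequence for chromosome {name!r} in {self.accession_id!r}")
            if not _VALID.issuperset(seq):
                bad = sorted(set(seq) - _VALID)
                raise ValueError(
                    f"invalid symbols {bad} in chromosome {name!r} of {self.accession_id!r}"
                )

    # -- accessors ---------------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> list[int]:
        return [len(s) for _, s in self.chromosomes]

    def seq(self, name: str) -> str:
        for n, s in self.chromosomes:
            if n == name:
                return s
        raise KeyError(f"no chromosome {name!r} in accession {self.accession_id!r}")

    def __len__(self) -> int:
        return len(self.chromosomes)


@dataclass
class TEElement:
    element_id: str
    superfamily: str
    sequence: str


@dataclass
class TEAnnotationSet:
    """A library of transposable-element sequences (consensus or extracted)."""

    elements: list[TEElement] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.element_id for e in self.elements]
        if len(set(ids)) != len(ids):
            dup = next(i for k, i in enumerate(ids) if i in ids[:k])
            raise ValueError(f"duplicate element_id {dup!r}")

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)
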