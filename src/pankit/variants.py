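"""SNP and structural-variant extraction from the pangenome alignment.

SNPs are gap-free polymorphic columns; "isolated" mode additionally requires
both immediate neighbour columns to be gap-free and monomorphic, which
suppresses differences that arise from local alignment ambiguity rather
than point mutation. SV loci are maximal runs of gap-containing columns;
the similarity threshold ``s`` splits them into simple bi-allelic
presence/absence variants (sSV: every allele is either shorter than
``(1 - s) * L`` or longer than ``s * L``, with ``L`` the longest allele) and
complex multi-allelic variants (cSV). Presence-allele frequency polarizes
simple indels: a presence allele carried by few accessions is a likely
insertion, an absence allele carried by few a likely deletion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .localalign import global_identity
from .multialign import GAP, PangenomeAlignment

_GAP_BYTE = ord("-")
_N_BYTE = ord("N")

DEFAULT_LENGTH_CLASS_EDGES = (1, 15, 100, 500, 1000, 5000, 20000)


@dataclass
class SNPRecord:
    chrom: str                 # pangenome chromosome name
    column: int                # pangenome column index
    bases: str                 # per-accession base, alignment row order
    isolated: bool
    # reference projection for VCF output (first accession by default)
    ref_pos: int = -1
    ref_base: str = "N"
    alt_bases: tuple[str, ...] = ()
    genotypes: tuple[int, ...] = ()


@dataclass
class SVLocus:
    sv_id: str
    chrom: str
    start: int                 # pangenome columns, half-open
    end: int
    alleles: list[str]         # per accession, row order; '' = absence
    terminal: bool = False
    sv_class: str | None = None          # 'sSV' | 'cSV'
    presence_set: frozenset[int] = frozenset()
    absence_set: frozenset[int] = frozenset()
    presence_frequency: float | None = None
    polarity: str | None = None          # likely_insertion | likely_deletion | unpolarized

    @property
    def allele_lengths(self) -> list[int]:
        return [len(a) for a in self.alleles]

    @property
    def L(self) -> int:
        return max(self.allele_lengths)


# ---------------------------------------------------------------------------
# SNPs
# ---------------------------------------------------------------------------

def call_snps(aln: PangenomeAlignment, mode: str = "all") -> list[SNPRecord]:
    """Extract SNPs from gap-free polymorphic columns.

    ``mode='all'``: every gap-free column with >= 2 distinct bases (N bases
    disqualify a column — N never counts as a match or a difference).
    ``mode='isolated'``: additionally both neighbour columns must be gap-free
    and monomorphic; chromosome ends count as conserved flanks.
    """
    if mode not in {"all", "isolated"}:
        raise ValueError(f"unknown SNP mode {mode!r}")
    out: list[SNPRecord] = []
    for chrom in aln.chromosomes:
        B = chrom.bases
        m = chrom.n_columns
        if m == 0:
            continue
        gapfree = ~((B == _GAP_BYTE) | (B == _N_BYTE)).any(axis=0)
        poly = gapfree & (B != B[0]).any(axis=0)
        mono = gapfree & ~(B != B[0]).any(axis=0)
        cols = np.nonzero(poly)[0]
        if mode == "isolated":
            ok_left = np.ones(m, dtype=bool)
            ok_right = np.ones(m, dtype=bool)
            ok_left[1:] = mono[:-1]
            ok_right[:-1] = mono[1:]
            cols = cols[ok_left[cols] & ok_right[cols]]
        for c in cols:
            bases = B[:, c].tobytes().decode()
            ref_base = bases[0]
            alts = []
            gts = []
            for b in bases:
                if b == ref_base:
                    gts.append(0)
                else:
                    if b not in alts:
                        alts.append(b)
                    gts.append(1 + alts.index(b))
            out.append(
                SNPRecord(
                    chrom=chrom.name,
                    column=int(c),
                    bases=bases,
                    isolated=bool(mode == "isolated"),
                    ref_pos=int(chrom.pos[0, c] - 1),
                    ref_base=ref_base,
                    alt_bases=tuple(alts),
                    genotypes=tuple(gts),
                )
            )
    return out


# ---------------------------------------------------------------------------
# SV loci
# ---------------------------------------------------------------------------

def extract_sv_loci(aln: PangenomeAlignment) -> list[SVLocus]:
    """Maximal runs of consecutive columns with at least one gap, flanked by
    gap-free columns or chromosome ends (then flagged ``terminal``)."""
    loci: list[SVLocus] = []
    counter = 0
    for chrom in aln.chromosomes:
        B = chrom.bases
        m = chrom.n_columns
        if m == 0:
            continue
        has_gap = (B == _GAP_BYTE).any(axis=0)
        j = 0
        while j < m:
            if not has_gap[j]:
                j += 1
                continue
            start = j
            while j < m and has_gap[j]:
                j += 1
            end = j
            alleles = [
                B[i, start:end][B[i, start:end] != _GAP_BYTE].tobytes().decode()
                for i in range(B.shape[0])
            ]
            loci.append(
                SVLocus(
                    sv_id=f"sv_{counter}",
                    chrom=chrom.name,
                    start=int(start),
                    end=int(end),
                    alleles=alleles,
                    terminal=bool(start == 0 or end == m),
                )
            )
            counter += 1
    return loci


def classify_sv(locus: SVLocus, s: float = 0.9) -> SVLocus:
    """Apply the allele-length similarity rule: a locus is a simple indel
    (sSV) iff every allele is shorter than ``(1-s)*L`` (absence) or longer
    than ``s*L`` (presence); otherwise it is complex (cSV)."""
    if not (0.5 < s <= 1.0):
        raise ValueError("s must lie in (0.5, 1]: below 0.5 the absence and "
                         "presence length intervals overlap")
    L = locus.L
    presence, absence = set(), set()
    simple = True
    for i, length in enumerate(locus.allele_lengths):
        if length < (1.0 - s) * L:
            absence.add(i)
        elif length > s * L:
            presence.add(i)
        else:
            simple = False
    locus.sv_class = "sSV" if simple else "cSV"
    if simple:
        locus.presence_set = frozenset(presence)
        locus.absence_set = frozenset(absence)
        locus.presence_frequency = len(presence) / len(locus.alleles)
    else:
        locus.presence_set = frozenset()
        locus.absence_set = frozenset()
        locus.presence_frequency = None
    return locus


def infer_polarity(locus: SVLocus, max_minor: int = 3) -> str:
    """Frequency polarity of a simple indel: presence in at most ``max_minor``
    accessions is a likely insertion, absence in at most ``max_minor`` a
    likely deletion, anything else unpolarized."""
    if locus.sv_class != "sSV":
        raise ValueError("polarity is defined for sSV loci only")
    n_p, n_a = len(locus.presence_set), len(locus.absence_set)
    if n_p <= max_minor and n_a > max_minor:
        locus.polarity = "likely_insertion"
    elif n_a <= max_minor and n_p > max_minor:
        locus.polarity = "likely_deletion"
    else:
        locus.polarity = "unpolarized"
    return locus.polarity


def consensus_allele(locus: SVLocus) -> str:
    """Representative presence allele: the medoid (maximal mean global
    identity to the other presence alleles); a lone allele returns itself."""
    seqs = [locus.alleles[i] for i in sorted(locus.presence_set)]
    if not seqs:
        raise ValueError("locus has no presence allele")
    if len(seqs) == 1:
        return seqs[0]
    mean_ident = []
    for i, a in enumerate(seqs):
        vals = [global_identity(a, b) for j, b in enumerate(seqs) if j != i]
        mean_ident.append(sum(vals) / len(vals))
    return seqs[int(np.argmax(mean_ident))]


def length_class(L: int, edges: tuple[int, ...] = DEFAULT_LENGTH_CLASS_EDGES) -> str:
    """Bin an SV length into the fixed length-class partition; edges are
    left-closed, the last class is open-ended."""
    for lo, hi in zip(edges, edges[1:]):
        if lo <= L < hi:
            return f"[{lo},{hi})"
    if L >= edges[-1]:
        return f">={edges[-1]}"
    return f"<{edges[0]}"


def classify_all(
    aln: PangenomeAlignment,
    s: float = 0.9,
    max_minor: int = 3,
    include_terminal: bool = False,
) -> list[SVLocus]:
    """Extract, classify and polarize every SV locus of an alignment.

    Terminal loci are flagged and, by default, excluded (their polarity is
    unresolvable at sequence ends).
    """
    loci = extract_sv_loci(aln)
    out = []
    for loc in loci:
        if loc.terminal and not include_terminal:
            continue
        classify_sv(loc, s=s)
        if loc.sv_class == "sSV":
            infer_polarity(loc, max_minor=max_minor)
        out.append(loc)
    return out
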