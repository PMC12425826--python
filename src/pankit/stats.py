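"""Pangenome summaries: pan/core saturation curves, coordinate dilation and
pairwise divergence decompositions.

Pan/core is computed on alignment columns ("sequence presence"): for a
subset of accessions, the pan length is the number of columns where at least
one member is aligned and the core length the number where all are. Up to
20 unique subsets are drawn per sample size and the spread reported.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .multialign import PangenomeAlignment
from .variants import DEFAULT_LENGTH_CLASS_EDGES, SVLocus, classify_all, length_class

_GAP_BYTE = ord("-")


# ---------------------------------------------------------------------------
# Saturation
# ---------------------------------------------------------------------------

def _presence_matrix(aln: PangenomeAlignment) -> np.ndarray:
    mats = [c.presence() for c in aln.chromosomes]
    return np.concatenate(mats, axis=1) if mats else np.zeros((len(aln.accessions), 0), bool)


def _unique_subsets(n: int, k: int, max_subsets: int, rng: np.random.Generator) -> list[tuple[int, ...]]:
    total = comb(n, k)
    if total <= max_subsets:
        return list(itertools.combinations(range(n), k))
    subsets: set[tuple[int, ...]] = set()
    while len(subsets) < max_subsets:
        subsets.add(tuple(sorted(rng.choice(n, size=k, replace=False).tolist())))
    return sorted(subsets)


def pan_core_curve(
    aln: PangenomeAlignment, max_subsets: int = 20, seed: int = 0
) -> pd.DataFrame:
    """Pan and core aligned-sequence length versus sample size.

    For each ``k`` in ``1..n`` at most ``max_subsets`` unique accession
    subsets are evaluated; the frame reports mean and sample standard
    deviation (0 for a single subset) of both lengths.
    """
    P = _presence_matrix(aln)
    n = P.shape[0]
    if n < 2:
        raise ValueError("saturation needs at least 2 accessions")
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(1, n + 1):
        subsets = _unique_subsets(n, k, max_subsets, rng)
        pans, cores = [], []
        for sub in subsets:
            sel = P[list(sub)]
            pans.append(int(sel.any(axis=0).sum()))
            cores.append(int(sel.all(axis=0).sum()))
        pans, cores = np.asarray(pans, float), np.asarray(cores, float)
        rows.append(
            {
                "k": k,
                "n_subsets": len(subsets),
                "pan_mean": pans.mean(),
                "pan_sd": pans.std(ddof=1) if len(pans) > 1 else 0.0,
                "core_mean": cores.mean(),
                "core_sd": cores.std(ddof=1) if len(cores) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Coordinate dilation
# ---------------------------------------------------------------------------

def dilation_curve(aln: PangenomeAlignment, reference_accession: str) -> pd.DataFrame:
    """(pangenome column, reference position) pairs for columns where the
    reference accession is aligned; the pangenome axis dilates wherever other
    accessions carry sequence the reference lacks."""
    if reference_accession not in aln.accessions:
        raise ValueError(f"unknown accession {reference_accession!r}")
    ai = aln.accessions.index(reference_accession)
    frames = []
    offset = 0
    for chrom in aln.chromosomes:
        row = chrom.pos[ai]
        cols = np.nonzero(row)[0]
        frames.append(
            pd.DataFrame(
                {
                    "pan_chrom": chrom.name,
                    "pan_column": cols + offset,
                    "ref_pos": row[cols] - 1,
                }
            )
        )
        offset += chrom.n_columns
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Pairwise divergence
# ---------------------------------------------------------------------------

@dataclass
class DivergenceSummary:
    accession_i: str
    accession_j: str
    snp_count: int
    ssv_counts: dict[str, int]
    ssv_total_bp: int

    @property
    def ssv_count(self) -> int:
        return sum(self.ssv_counts.values())


def pairwise_divergence(
    aln: PangenomeAlignment,
    i: str,
    j: str,
    length_class_edges: tuple[int, ...] = DEFAULT_LENGTH_CLASS_EDGES,
    s: float = 0.9,
    loci: list[SVLocus] | None = None,
) -> DivergenceSummary:
    """SNP and simple-SV differences between one accession pair.

    SNPs are counted over columns where both are aligned with differing
    (non-N) bases; sSVs where exactly one of the pair holds the presence
    allele, binned by presence-allele length; total bp sums those presence
    alleles. ``loci`` may carry pre-classified loci to avoid recomputation.
    """
    if i == j:
        raise ValueError("pairwise divergence needs two distinct accessions")
    ai, aj = aln.accessions.index(i), aln.accessions.index(j)
    snp_count = 0
    for chrom in aln.chromosomes:
        bi, bj = chrom.bases[ai], chrom.bases[aj]
        both = (bi != _GAP_BYTE) & (bj != _GAP_BYTE) & (bi != ord("N")) & (bj != ord("N"))
        snp_count += int((both & (bi != bj)).sum())
    if loci is None:
        loci = classify_all(aln, s=s)
    counts: dict[str, int] = {}
    total_bp = 0
    for loc in loci:
        if loc.sv_class != "sSV":
            continue
        i_pres = ai in loc.presence_set
        j_pres = aj in loc.presence_set
        i_abs = ai in loc.absence_set
        j_abs = aj in loc.absence_set
        if (i_pres and j_abs) or (j_pres and i_abs):
            plen = len(loc.alleles[ai if i_pres else aj])
            counts[length_class(plen, length_class_edges)] = (
                counts.get(length_class(plen, length_class_edges), 0) + 1
            )
            total_bp += plen
    return DivergenceSummary(
        accession_i=i, accession_j=j, snp_count=snp_count,
        ssv_counts=counts, ssv_total_bp=total_bp,
    )
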