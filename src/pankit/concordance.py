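"""Reference-bias auditing.

The SNP-call taxonomy compares a call set derived from read mapping against
whole-genome-alignment (WGA) truth: truth SNPs are TP if called, uncalled if
the site lacks read coverage, FN otherwise; calls are FP_het if heterozygous
(the accessions are completely inbred, so heterozygous calls are errors by
construction), TP if in the truth, FP_non_snp if the site is aligned in the
WGA, and FP_unaligned otherwise. Expression and methylation concordance
apply min/max ratio cuts between reference-mapped and own-genome-mapped
estimates, and quantile normalization equalizes the 20% and 80% quantiles
across samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Hashable, Sequence

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# SNP-call taxonomy
# ---------------------------------------------------------------------------

@dataclass
class CallTaxonomy:
    tp: int
    fn: int
    uncalled: int
    fp_non_snp: int
    fp_unaligned: int
    fp_het: int

    @property
    def n_truth(self) -> int:
        return self.tp + self.fn + self.uncalled

    @property
    def n_calls(self) -> int:
        return self.tp + self.fp_non_snp + self.fp_unaligned + self.fp_het

    @property
    def fdr(self) -> float | None:
        """False discovery rate; None (missing) when there are no calls."""
        if self.n_calls == 0:
            return None
        return (self.fp_non_snp + self.fp_unaligned + self.fp_het) / self.n_calls

    @property
    def fnr(self) -> float | None:
        """False negative rate over covered truth sites."""
        denom = self.tp + self.fn
        if denom == 0:
            return None
        return self.fn / denom


def classify_calls(
    truth_snps: Collection[Hashable],
    aligned_mask: Collection[Hashable],
    test_calls: Collection[Hashable],
    coverage_mask: Collection[Hashable],
    het_calls: Collection[Hashable] = (),
) -> CallTaxonomy:
    """Six-way taxonomy of SNP calls against WGA truth.

    All collections hold site keys in a shared (reference) coordinate
    system. ``het_calls`` is the subset of ``test_calls`` that is
    heterozygous; heterozygosity takes precedence over a truth match.
    """
    truth = set(truth_snps)
    aligned = set(aligned_mask)
    calls = set(test_calls)
    covered = set(coverage_mask)
    het = set(het_calls) & calls

    nonhet_calls = calls - het
    tp_sites = truth & nonhet_calls
    tp = len(tp_sites)
    uncalled = len({t for t in truth - tp_sites if t not in covered})
    fn = len(truth) - tp - uncalled

    fp_het = len(het)
    fp_sites = nonhet_calls - truth
    fp_non_snp = len(fp_sites & aligned)
    fp_unaligned = len(fp_sites - aligned)
    tax = CallTaxonomy(tp, fn, uncalled, fp_non_snp, fp_unaligned, fp_het)
    assert tax.n_truth == len(truth)
    assert tax.n_calls == len(calls)
    return tax


# ---------------------------------------------------------------------------
# Expression / methylation concordance
# ---------------------------------------------------------------------------

def expression_concordance(
    counts_ref: Sequence[float],
    counts_own: Sequence[float],
    min_count: float = 6,
    ratio_cut: float = 0.7,
) -> np.ndarray:
    """Per-gene concordance of expression counts between reference-mapped
    and own-genome-mapped quantification.

    ``excluded`` when neither estimate reaches ``min_count``; ``discordant``
    when min/max <= ``ratio_cut`` (estimates differ by more than 30% at the
    default); ``concordant`` otherwise.
    """
    r = np.asarray(counts_ref, dtype=float)
    o = np.asarray(counts_own, dtype=float)
    if r.shape != o.shape:
        raise ValueError("count vectors must align on the same gene universe")
    if (r < 0).any() or (o < 0).any():
        raise ValueError("negative counts")
    hi = np.maximum(r, o)
    lo = np.minimum(r, o)
    out = np.where(hi < min_count, "excluded",
                   np.where(lo <= ratio_cut * hi, "discordant", "concordant"))
    return out


def methylation_level(meth_reads: float, unmeth_reads: float) -> float:
    """Methylation level = methylated / (methylated + unmethylated) reads;
    NaN (missing) when no reads cover the context."""
    if meth_reads < 0 or unmeth_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = meth_reads + unmeth_reads
    if total == 0:
        return float("nan")
    return meth_reads / total


def methylation_concordance(
    level_ref: float, level_own: float, ratio_cut: float = 0.5
) -> str:
    """Concordance of one gene's methylation level between mappings:
    ``excluded`` if either level is missing, ``concordant`` when both are
    zero (equal), otherwise ``discordant`` iff min/max <= ``ratio_cut``."""
    if np.isnan(level_ref) or np.isnan(level_own):
        return "excluded"
    for lv in (level_ref, level_own):
        if not 0.0 <= lv <= 1.0:
            raise ValueError("methylation levels must lie in [0, 1]")
    hi, lo = max(level_ref, level_own), min(level_ref, level_own)
    if hi == 0:
        return "concordant"
    return "discordant" if lo / hi <= ratio_cut else "concordant"


# ---------------------------------------------------------------------------
# Quantile normalization (ChIP coverage)
# ---------------------------------------------------------------------------

def quantile_normalize(
    values: Sequence[float], q_low: float = 0.20, q_high: float = 0.80
) -> np.ndarray:
    """Equalize the ``q_low`` and ``q_high`` quantiles across samples:
    elementwise ``(x - q_low_value) / (q_high_value - q_low_value)`` with
    type-7 (linear-interpolation) quantiles. Raises on constant input."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    lo = np.quantile(x, q_low)
    hi = np.quantile(x, q_high)
    if hi <= lo:
        raise ValueError("q_high quantile must exceed q_low quantile (constant input?)")
    return (x - lo) / (hi - lo)


def taxonomy_frame(taxonomies: dict[str, CallTaxonomy]) -> pd.DataFrame:
    rows = []
    for name, t in taxonomies.items():
        rows.append(
            {
                "pairing": name, "TP": t.tp, "FN": t.fn, "uncalled": t.uncalled,
                "FP_non_snp": t.fp_non_snp, "FP_unaligned": t.fp_unaligned,
                "FP_het": t.fp_het,
                "FDR": t.fdr if t.fdr is not None else float("nan"),
                "FNR": t.fnr if t.fnr is not None else float("nan"),
            }
        )
    return pd.DataFrame(rows)
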