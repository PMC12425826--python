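"""Internal seed-and-extend local aligner.

The toolkit is self-contained: anchoring, gap filling and nestedness all run
on this module rather than an external aligner. The model is deliberately
simple — exact k-mer seeds (default k=15) grouped into runs on a single
diagonal, which tolerates substitutions (they only delete k seeds around the
mismatch, the diagonal is unchanged) while indels split a region into
separate runs on different diagonals; chaining and the gap-fill pass stitch
those back together. Base-level alignment of bounded gap regions uses
edit-distance alignment (edlib) with the CIGAR walked into position pairs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import numpy as np

from .seqs import revcomp

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class LocalHit:
    """An ungapped local match between query and target.

    Coordinates are 0-based half-open on the forward strands of both
    sequences; ``qe - qs == te - ts`` (single diagonal).
    """

    qs: int
    qe: int
    ts: int
    te: int
    strand: str  # '+' or '-', strand of the query relative to the target
    identity: float
    matches: int

    @property
    def length(self) -> int:
        return self.qe - self.qs

    @property
    def score(self) -> int:
        return self.matches


def kmer_index(seq: str, k: int = 15, max_occ: int = 64) -> dict[str, np.ndarray]:
    """Exact k-mer index: k-mer -> sorted positions. K-mers occurring more
    than ``max_occ`` times (satellite arrays, low-complexity runs) are
    dropped, the standard repeat-seed guard."""
    occ: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        lst = occ.setdefault(kmer, [])
        if len(lst) <= max_occ:
            lst.append(i)
    return {
        kmer: np.asarray(pos, dtype=np.int64)
        for kmer, pos in occ.items()
        if len(pos) <= max_occ and "N" not in kmer
    }


def _seed_matches(query: str, index: dict[str, np.ndarray], k: int) -> tuple[np.ndarray, np.ndarray]:
    qpos: list[int] = []
    tpos: list[np.ndarray] = []
    for i in range(len(query) - k + 1):
        hits = index.get(query[i : i + k])
        if hits is not None:
            qpos.extend([i] * len(hits))
            tpos.append(hits)
    if not qpos:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.asarray(qpos, dtype=np.int64), np.concatenate(tpos)


def _runs_on_diagonals(
    qpos: np.ndarray, tpos: np.ndarray, k: int, max_seed_gap: int
) -> list[tuple[int, int, int]]:
    """Group seeds into per-diagonal runs; returns (qs, qe, diag) spans."""
    diag = tpos - qpos
    order = np.lexsort((qpos, diag))
    qpos, diag = qpos[order], diag[order]
    runs: list[tuple[int, int, int]] = []
    start = 0
    for i in range(1, len(qpos) + 1):
        if (
            i == len(qpos)
            or diag[i] != diag[start]
            or qpos[i] - qpos[i - 1] > max_seed_gap
        ):
            runs.append((int(qpos[start]), int(qpos[i - 1]) + k, int(diag[start])))
            start = i
    return runs


def _identity_on_diagonal(query: str, target: str, qs: int, qe: int, diag: int) -> tuple[float, int]:
    q = np.frombuffer(query[qs:qe].encode(), dtype=np.uint8)
    t = np.frombuffer(target[qs + diag : qe + diag].encode(), dtype=np.uint8)
    n_mask = (q == ord("N")) | (t == ord("N"))
    matches = int(((q == t) & ~n_mask).sum())
    return matches / len(q), matches


def local_hits(
    query: str,
    target: str,
    k: int = 15,
    min_len: int = 100,
    min_identity: float = 0.85,
    max_seed_gap: int = 400,
    index: dict[str, np.ndarray] | None = None,
    both_strands: bool = False,
    max_occ: int = 64,
) -> list[LocalHit]:
    """All qualifying ungapped local matches of ``query`` in ``target``.

    A precomputed ``index`` of the target may be passed to amortize indexing
    across many queries. With ``both_strands`` the reverse complement of the
    query is also searched; hit coordinates stay on the forward query.
    """
    if index is None:
        index = kmer_index(target, k=k, max_occ=max_occ)
    hits: list[LocalHit] = []
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        q = query if strand == "+" else revcomp(query)
        qpos, tpos = _seed_matches(q, index, k)
        if len(qpos) == 0:
            continue
        for qs, qe, diag in _runs_on_diagonals(qpos, tpos, k, max_seed_gap):
            if qe - qs < min_len:
                continue
            ident, matches = _identity_on_diagonal(q, target, qs, qe, diag)
            if ident < min_identity:
                continue
            if strand == "+":
                fqs, fqe = qs, qe
            else:  # map back onto the forward query
                fqs, fqe = len(query) - qe, len(query) - qs
            hits.append(
                LocalHit(
                    qs=fqs, qe=fqe, ts=qs + diag, te=qe + diag,
                    strand=strand, identity=ident, matches=matches,
                )
            )
    hits.sort(key=lambda h: (-h.score, h.ts, h.qs))
    return hits


def merged_coverage(intervals: list[tuple[int, int]]) -> int:
    """Total length of the union of half-open intervals."""
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    total += cur_e - cur_s
    return total


# ---------------------------------------------------------------------------
# Base-level alignment of bounded regions (edlib-backed)
# ---------------------------------------------------------------------------

def _walk_cigar(cigar: str, q_off: int, t_off: int):
    """Yield (q_pos, t_pos, is_match) for every aligned base pair; q is the
    edlib query (consumes I), t the target (consumes D)."""
    qi, ti = q_off, t_off
    for n, op in _CIGAR_RE.findall(cigar):
        n = int(n)
        if op in "=XM":
            for _ in range(n):
                yield qi, ti, op == "="
                qi += 1
                ti += 1
        elif op == "I":
            qi += n
        elif op == "D":
            ti += n


def global_pairs(a: str, b: str) -> tuple[list[tuple[int, int]], float, float]:
    """Global alignment of ``a`` vs ``b``: matched position pairs, the
    identity over the full alignment length (gaps penalized), and the
    identity over aligned pairs only (indel-length-insensitive)."""
    if not a or not b:
        return [], 0.0, 0.0
    res = edlib.align(a, b, mode="NW", task="path")
    pairs = []
    matches = 0
    aln_len = 0
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        aln_len += int(n)
    for qi, ti, is_match in _walk_cigar(res["cigar"], 0, 0):
        pairs.append((qi, ti))
        matches += is_match
    identity = matches / aln_len if aln_len else 0.0
    pair_identity = matches / len(pairs) if pairs else 0.0
    return pairs, identity, pair_identity


def global_pairs_flagged(a: str, b: str) -> list[tuple[int, int, bool]]:
    """Global alignment of ``a`` vs ``b`` as (a_pos, b_pos, is_match) triples."""
    if not a or not b:
        return []
    res = edlib.align(a, b, mode="NW", task="path")
    return [(qi, ti, m) for qi, ti, m in _walk_cigar(res["cigar"], 0, 0)]


def global_identity(a: str, b: str) -> float:
    """Identity of the optimal global alignment (matches / alignment length)."""
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="path")
    matches = 0
    aln_len = 0
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n)
        aln_len += n
        if op == "=":
            matches += n
    return matches / aln_len if aln_len else 0.0


def infix_identity(a: str, b: str) -> float:
    """Identity of the best placement of ``a`` inside ``b`` (semi-global)."""
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="HW", task="distance")
    return max(0.0, 1.0 - res["editDistance"] / len(a))


def suffix_pairs(a: str, b: str) -> tuple[list[tuple[int, int]], float]:
    """Align ``a`` against a suffix of ``b`` (right ends anchored): matched
    pairs in forward coordinates of both strings, plus identity over ``a``."""
    if not a or not b:
        return [], 0.0
    res = edlib.align(a[::-1], b[::-1], mode="SHW", task="path")
    pairs = []
    matches = 0
    for qi, ti, is_match in _walk_cigar(res["cigar"], 0, 0):
        pairs.append((len(a) - 1 - qi, len(b) - 1 - ti))
        matches += is_match
    pairs.reverse()
    identity = matches / len(a)
    return pairs, identity


def prefix_pairs(a: str, b: str) -> tuple[list[tuple[int, int]], float]:
    """Align ``a`` against a prefix of ``b`` (left ends anchored)."""
    if not a or not b:
        return [], 0.0
    res = edlib.align(a, b, mode="SHW", task="path")
    pairs = []
    matches = 0
    for qi, ti, is_match in _walk_cigar(res["cigar"], 0, 0):
        pairs.append((qi, ti))
        matches += is_match
    identity = matches / len(a)
    return pairs, identity
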