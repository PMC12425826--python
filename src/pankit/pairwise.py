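"""Pairwise genome correspondence: block anchoring, proximity chaining and
gap filling.

The query genome is chopped into 5-kb blocks, each block is anchored to the
reference with exactly one best local hit, hits without a colinear neighbor
in close proximity (both genomes) are dropped, and the sequence between
consecutive kept hits is resolved by a second, bounded alignment pass.
Minus-strand chains are reported as inversions and excluded from the
base-level correspondence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import localalign as la
from .seqs import GenomeSet

DEFAULT_BLOCK_SIZE = 5000
MIN_PARTIAL_BLOCK = 100
DEFAULT_MAX_JOIN_GAP = 20000


@dataclass
class Block:
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnchorHit:
    q_chrom: str
    q_start: int
    q_end: int
    r_chrom: str
    r_start: int
    r_end: int
    strand: str
    identity: float
    score: float

    def __post_init__(self) -> None:
        if self.q_end <= self.q_start or self.r_end <= self.r_start:
            raise ValueError("anchor hit intervals must be non-empty")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity must lie in [0, 1]")


@dataclass
class Inversion:
    q_chrom: str
    q_start: int
    q_end: int
    r_chrom: str
    r_start: int
    r_end: int
    n_hits: int


@dataclass
class CorrespondenceMap:
    """Base-level query -> reference correspondence.

    For each query chromosome, ``ref_pos[qpos]`` holds the matched reference
    position (-1 if unmatched) and ``ref_chrom_idx[qpos]`` the index of the
    reference chromosome it lies on. Within a segment the mapping is strictly
    monotone; matched positions are injective.
    """

    query_id: str
    reference_id: str
    ref_chroms: list[str]
    ref_pos: dict[str, np.ndarray] = field(default_factory=dict)
    ref_chrom_idx: dict[str, np.ndarray] = field(default_factory=dict)
    inversions: list[Inversion] = field(default_factory=list)

    def matched_fraction(self, chrom: str) -> float:
        arr = self.ref_pos[chrom]
        return float((arr >= 0).sum() / len(arr))

    def lookup(self, chrom: str, pos: int) -> tuple[str, int] | None:
        rp = int(self.ref_pos[chrom][pos])
        if rp < 0:
            return None
        return self.ref_chroms[int(self.ref_chrom_idx[chrom][pos])], rp


# ---------------------------------------------------------------------------
# Step 1: chop the query into blocks
# ---------------------------------------------------------------------------

def chop_blocks(genome: GenomeSet, block_size: int = DEFAULT_BLOCK_SIZE) -> list[Block]:
    """Consecutive non-overlapping blocks per chromosome; a final partial
    block shorter than 100 nt is merged into the previous block."""
    if block_size < 100:
        raise ValueError("block_size must be >= 100")
    blocks: list[Block] = []
    for name, seq in genome.chromosomes:
        n = len(seq)
        starts = list(range(0, n, block_size))
        chrom_blocks = [Block(name, s, min(s + block_size, n)) for s in starts]
        if len(chrom_blocks) > 1 and chrom_blocks[-1].length < MIN_PARTIAL_BLOCK:
            tail = chrom_blocks.pop()
            chrom_blocks[-1] = Block(name, chrom_blocks[-1].start, tail.end)
        blocks.extend(chrom_blocks)
    return blocks


# ---------------------------------------------------------------------------
# Step 2: one best anchor hit per block
# ---------------------------------------------------------------------------

class ReferenceIndex:
    """Per-chromosome k-mer indexes of a reference genome, built once and
    shared across the queries anchored against it."""

    def __init__(self, reference: GenomeSet, k: int = 15, max_occ: int = 64):
        self.reference = reference
        self.k = k
        self.indexes = {
            name: la.kmer_index(seq, k=k, max_occ=max_occ)
            for name, seq in reference.chromosomes
        }


def anchor_blocks(
    blocks: list[Block],
    reference: GenomeSet | ReferenceIndex,
    query: GenomeSet,
    min_identity: float = 0.85,
    min_hit_len: int = 100,
    k: int = 15,
) -> list[AnchorHit]:
    """At most one hit per block: the highest-scoring local match over all
    reference chromosomes and strands; ties broken by lower reference
    chromosome index, then lower reference start."""
    if isinstance(reference, GenomeSet):
        if not reference.chromosomes:
            raise ValueError("reference genome is empty")
        reference = ReferenceIndex(reference, k=k)
    ref = reference.reference
    anchors: list[AnchorHit] = []
    for block in blocks:
        seq = query.seq(block.chrom)[block.start : block.end]
        best: tuple | None = None
        for ci, (rname, _) in enumerate(ref.chromosomes):
            hits = la.local_hits(
                seq,
                ref.seq(rname),
                k=reference.k,
                min_len=min_hit_len,
                min_identity=min_identity,
                index=reference.indexes[rname],
                both_strands=True,
            )
            for h in hits:
                key = (-h.score, ci, h.ts)
                if best is None or key < best[0]:
                    best = (key, ci, rname, h)
        if best is None:
            continue
        _, ci, rname, h = best
        anchors.append(
            AnchorHit(
                q_chrom=block.chrom,
                q_start=block.start + h.qs,
                q_end=block.start + h.qe,
                r_chrom=rname,
                r_start=h.ts,
                r_end=h.te,
                strand=h.strand,
                identity=h.identity,
                score=h.score,
            )
        )
    return anchors


# ---------------------------------------------------------------------------
# Step 3: proximity chaining and gap filling
# ---------------------------------------------------------------------------

MAX_GAP_DRIFT = 8000


def _build_chains(hits: list[AnchorHit], max_join_gap: int) -> list[list[AnchorHit]]:
    """Greedy colinear chaining within one (q_chrom, r_chrom, strand) group.

    Query-sorted hits join a chain when both-genome gaps are within
    ``max_join_gap``, the reference order is consistent with the strand, and
    the two gaps are consistent with each other (their difference is the
    net indel length between the hits, bounded by ``MAX_GAP_DRIFT``): a
    paralogous anchor — a block matched against another copy of a repeat
    family — shows a small query gap but a large reference jump, and must
    break the chain rather than drag it off-locus.
    """
    chains: list[list[AnchorHit]] = []
    cur: list[AnchorHit] = []
    for h in sorted(hits, key=lambda x: x.q_start):
        if not cur:
            cur = [h]
            continue
        prev = cur[-1]
        q_gap = h.q_start - prev.q_end
        if h.strand == "+":
            r_gap = h.r_start - prev.r_end
        else:
            r_gap = prev.r_start - h.r_end
        if (
            -100 <= q_gap <= max_join_gap
            and -100 <= r_gap <= max_join_gap
            and abs(r_gap - q_gap) <= MAX_GAP_DRIFT
        ):
            cur.append(h)
        else:
            chains.append(cur)
            cur = [h]
    if cur:
        chains.append(cur)
    return chains


def _fill_pairs(qseq: str, rseq: str, min_identity: float, depth: int = 0) -> list[tuple[int, int]]:
    """Correspondences for an inter-hit gap region (both sequences bounded).

    Small gap pairs are aligned globally and accepted if the alignment
    identity clears ``min_identity`` (this is what rejects the planted
    unalignable satellite blocks); larger or divergent pairs fall back to a
    local-hit chain with recursive fills between the local hits.
    """
    if not qseq or not rseq:
        return []
    if len(qseq) <= 1500 and len(rseq) <= 1500:
        pairs, identity, _ = la.global_pairs(qseq, rseq)
        if identity >= min_identity:
            return pairs
        if depth > 0:
            return []
    k = 13
    hits = la.local_hits(qseq, rseq, k=k, min_len=max(50, k + 1), min_identity=min_identity)
    # keep a colinear subset (greedy by score)
    hits.sort(key=lambda h: (-h.score, h.qs))
    kept: list[la.LocalHit] = []
    for h in hits:
        if h.strand != "+":
            continue
        ok = all(
            (h.qs >= kh.qe and h.ts >= kh.te) or (h.qe <= kh.qs and h.te <= kh.ts)
            for kh in kept
        )
        if ok:
            kept.append(h)
    kept.sort(key=lambda h: h.qs)
    pairs: list[tuple[int, int]] = []
    prev_q, prev_t = 0, 0
    for h in kept:
        if depth < 2:
            sub = _fill_pairs(qseq[prev_q : h.qs], rseq[prev_t : h.ts], min_identity, depth + 1)
            pairs.extend((q + prev_q, t + prev_t) for q, t in sub)
        pairs.extend(zip(range(h.qs, h.qe), range(h.ts, h.te)))
        prev_q, prev_t = h.qe, h.te
    if kept and depth < 2:
        sub = _fill_pairs(qseq[prev_q:], rseq[prev_t:], min_identity, depth + 1)
        pairs.extend((q + prev_q, t + prev_t) for q, t in sub)
    return pairs


def chain_and_fill(
    hits: list[AnchorHit],
    query: GenomeSet,
    reference: GenomeSet,
    max_join_gap: int = DEFAULT_MAX_JOIN_GAP,
    min_identity: float = 0.85,
) -> CorrespondenceMap:
    """Keep colinear anchor chains (singletons discarded), fill inter-hit
    gaps by a second bounded alignment pass, and merge everything into a
    base-level :class:`CorrespondenceMap`."""
    ref_chroms = reference.names
    ref_chrom_to_idx = {n: i for i, n in enumerate(ref_chroms)}
    cmap = CorrespondenceMap(
        query_id=query.accession_id,
        reference_id=reference.accession_id,
        ref_chroms=ref_chroms,
    )
    for name, seq in query.chromosomes:
        cmap.ref_pos[name] = np.full(len(seq), -1, dtype=np.int64)
        cmap.ref_chrom_idx[name] = np.full(len(seq), -1, dtype=np.int16)

    groups: dict[tuple[str, str, str], list[AnchorHit]] = {}
    for h in hits:
        groups.setdefault((h.q_chrom, h.r_chrom, h.strand), []).append(h)

    all_chains: list[list[AnchorHit]] = []
    singletons: list[AnchorHit] = []
    for group_hits in groups.values():
        for chain in _build_chains(group_hits, max_join_gap):
            if len(chain) < 2:
                # repeat-induced noise unless later found colinear with an
                # accepted chain (e.g. a lone anchor in a chromosome tail)
                if chain[0].strand == "+":
                    singletons.append(chain[0])
                continue
            all_chains.append(chain)

    # minus-strand chains: reported, not entered into the base-level map
    plus_chains = []
    for chain in all_chains:
        if chain[0].strand == "-":
            cmap.inversions.append(
                Inversion(
                    q_chrom=chain[0].q_chrom,
                    q_start=chain[0].q_start,
                    q_end=chain[-1].q_end,
                    r_chrom=chain[0].r_chrom,
                    r_start=min(h.r_start for h in chain),
                    r_end=max(h.r_end for h in chain),
                    n_hits=len(chain),
                )
            )
        else:
            plus_chains.append(chain)

    # accept chains greedily by total score; a chain whose query or ref span
    # is mostly covered already is a repeat-induced duplicate and is skipped,
    # while slight overlaps (chains broken at one event) are tolerated —
    # position-level first-come writing keeps the map injective on both sides
    plus_chains.sort(key=lambda c: -sum(h.score for h in c))
    used_q: dict[str, list[tuple[int, int]]] = {}
    used_r: dict[str, list[tuple[int, int]]] = {}

    def overlap_len(spans: list[tuple[int, int]], s: int, e: int) -> int:
        return sum(max(0, min(e, e2) - max(s, s2)) for s2, e2 in spans)

    accepted: dict[tuple[str, str], list[list[AnchorHit]]] = {}
    for chain in plus_chains:
        qc, rc = chain[0].q_chrom, chain[0].r_chrom
        qs, qe = chain[0].q_start, chain[-1].q_end
        rs, re_ = chain[0].r_start, chain[-1].r_end
        if (
            overlap_len(used_q.setdefault(qc, []), qs, qe) > 0.5 * (qe - qs)
            or overlap_len(used_r.setdefault(rc, []), rs, re_) > 0.5 * (re_ - rs)
        ):
            continue
        used_q[qc].append((qs, qe))
        used_r[rc].append((rs, re_))
        accepted.setdefault((qc, rc), []).append(chain)

    # rescue singleton anchors that are colinear with an accepted chain:
    # a lone hit in a chromosome tail (or between two chains broken at a
    # paralogous jump) is real sequence, not repeat noise
    for h in sorted(singletons, key=lambda x: -x.score):
        chains = accepted.get((h.q_chrom, h.r_chrom))
        if not chains:
            continue
        colinear = False
        for chain in chains:
            if h.q_start >= chain[-1].q_end - 100 and h.r_start >= chain[-1].r_end - 100:
                q_gap = h.q_start - chain[-1].q_end
                r_gap = h.r_start - chain[-1].r_end
                if (
                    q_gap <= max_join_gap
                    and r_gap <= max_join_gap
                    and abs(r_gap - q_gap) <= MAX_GAP_DRIFT
                ):
                    colinear = True
                    break
            if h.q_end <= chain[0].q_start + 100 and h.r_end <= chain[0].r_start + 100:
                q_gap = chain[0].q_start - h.q_end
                r_gap = chain[0].r_start - h.r_end
                if (
                    q_gap <= max_join_gap
                    and r_gap <= max_join_gap
                    and abs(r_gap - q_gap) <= MAX_GAP_DRIFT
                ):
                    colinear = True
                    break
        if not colinear:
            continue
        if (
            overlap_len(used_q.setdefault(h.q_chrom, []), h.q_start, h.q_end) > 0
            or overlap_len(used_r.setdefault(h.r_chrom, []), h.r_start, h.r_end) > 0
        ):
            continue
        used_q[h.q_chrom].append((h.q_start, h.q_end))
        used_r[h.r_chrom].append((h.r_start, h.r_end))
        accepted[(h.q_chrom, h.r_chrom)].append([h])

    ref_used = {name: np.zeros(len(seq), dtype=bool) for name, seq in reference.chromosomes}

    for (qc, rc), chains in accepted.items():
        chains.sort(key=lambda c: c[0].q_start)
        rc_idx = ref_chrom_to_idx[rc]
        qseq = query.seq(qc)
        rseq = reference.seq(rc)
        used = ref_used[rc]
        for chain in chains:
            _apply_chain(cmap, chain, qseq, rseq, rc_idx, used, min_identity)
        # fill between consecutive colinear chains (e.g. across a block that
        # broke the chain), then bounded terminal extensions at the ends
        for a, b in zip(chains, chains[1:]):
            if b[0].r_start >= a[-1].r_end - 100:
                gap_pairs = _fill_pairs(
                    qseq[a[-1].q_end : b[0].q_start],
                    rseq[a[-1].r_end : b[0].r_start],
                    min_identity,
                )
                _set_pairs(
                    cmap, qc, rc_idx, used,
                    ((p + a[-1].q_end, t + a[-1].r_end) for p, t in gap_pairs),
                )
        _terminal_extensions(
            cmap, chains[0], chains[-1], qseq, rseq, rc_idx, used,
            max_join_gap, min_identity,
        )
    return cmap


def _set_pairs(cmap, qc, rc_idx, used, pairs):
    rp = cmap.ref_pos[qc]
    ci = cmap.ref_chrom_idx[qc]
    for qpos, tpos in pairs:
        if rp[qpos] < 0 and not used[tpos]:
            rp[qpos] = tpos
            ci[qpos] = rc_idx
            used[tpos] = True


def _apply_chain(cmap, chain, qseq, rseq, rc_idx, used, min_identity):
    qc = chain[0].q_chrom
    # trim any small overlap between consecutive hits (shared diagonal ends)
    trimmed: list[AnchorHit] = []
    for h in chain:
        if trimmed:
            prev = trimmed[-1]
            cut = max(prev.q_end - h.q_start, prev.r_end - h.r_start, 0)
            if cut >= h.q_end - h.q_start:
                continue
            if cut:
                h = AnchorHit(
                    h.q_chrom, h.q_start + cut, h.q_end,
                    h.r_chrom, h.r_start + cut, h.r_end,
                    h.strand, h.identity, h.score,
                )
        trimmed.append(h)

    for i, h in enumerate(trimmed):
        # hits are single-diagonal: 1:1 position correspondence
        _set_pairs(
            cmap, qc, rc_idx, used,
            zip(range(h.q_start, h.q_end), range(h.r_start, h.r_end)),
        )
        if i + 1 < len(trimmed):
            nxt = trimmed[i + 1]
            gap_pairs = _fill_pairs(
                qseq[h.q_end : nxt.q_start], rseq[h.r_end : nxt.r_start], min_identity
            )
            _set_pairs(
                cmap, qc, rc_idx, used,
                ((q + h.q_end, t + h.r_end) for q, t in gap_pairs),
            )

def _terminal_extensions(cmap, first_chain, last_chain, qseq, rseq, rc_idx, used,
                         max_join_gap, min_identity):
    """Anchor the chromosome-end stubs outside the outermost hits.

    Extensions are capped at ``max_join_gap``: end stubs are short in
    colinear genomes, and an unbounded extension would re-align another
    chain's territory through diverged regions.
    """
    qc = first_chain[0].q_chrom
    first, last = first_chain[0], last_chain[-1]
    if first.q_start > 0 and first.r_start > 0:
        q_lo = max(0, first.q_start - max_join_gap)
        q_pre = qseq[q_lo : first.q_start]
        r_lo = max(0, first.r_start - len(q_pre) - max(200, len(q_pre) // 4))
        r_pre = rseq[r_lo : first.r_start]
        pairs, identity = la.suffix_pairs(q_pre, r_pre)
        if identity >= min_identity:
            _set_pairs(cmap, qc, rc_idx, used, ((q + q_lo, t + r_lo) for q, t in pairs))
    if last.q_end < len(qseq) and last.r_end < len(rseq):
        q_suf = qseq[last.q_end : last.q_end + max_join_gap]
        r_hi = min(len(rseq), last.r_end + len(q_suf) + max(200, len(q_suf) // 4))
        r_suf = rseq[last.r_end : r_hi]
        pairs, identity = la.prefix_pairs(q_suf, r_suf)
        if identity >= min_identity:
            _set_pairs(
                cmap, qc, rc_idx, used,
                ((q + last.q_end, t + last.r_end) for q, t in pairs),
            )


def align_pair(
    query: GenomeSet,
    reference: GenomeSet | ReferenceIndex,
    block_size: int = DEFAULT_BLOCK_SIZE,
    max_join_gap: int = DEFAULT_MAX_JOIN_GAP,
    min_identity: float = 0.85,
    min_hit_len: int = 100,
    k: int = 15,
) -> CorrespondenceMap:
    """End-to-end pairwise correspondence: chop, anchor, chain, fill."""
    ref = reference if isinstance(reference, ReferenceIndex) else ReferenceIndex(reference, k=k)
    blocks = chop_blocks(query, block_size=block_size)
    hits = anchor_blocks(
        blocks, ref, query, min_identity=min_identity, min_hit_len=min_hit_len, k=k
    )
    return chain_and_fill(
        hits, query, ref.reference, max_join_gap=max_join_gap, min_identity=min_identity
    )
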