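"""Reference-free multiple alignment: the matrix of corresponding positions.

Several accessions are rotated as references; each rotation yields a draft
reference-biased matrix from the pairwise correspondences. Columns whose
full correspondence tuple is identical in every draft form the skeleton; the
sequence left unplaced between consecutive skeleton columns is resolved by a
progressive multiple alignment and spliced in. Blocks where any accession
carries more than ``max_block`` (default 30 kb) unplaced sequence are deemed
highly diverged and retained as accession-private columns instead.

The resulting :class:`PangenomeAlignment` stores, per pangenome chromosome,
an ``(n_accessions, n_columns)`` matrix of genome positions (0 = gap,
``p + 1`` = forward-strand position ``p``) plus the corresponding base
matrix; columns are the pangenome coordinate system.
"""

from __future__ import annotations

import itertools
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import localalign as la
from .pairwise import CorrespondenceMap, ReferenceIndex, align_pair
from .seqs import GenomeSet

DEFAULT_MAX_BLOCK = 30000
GAP = 0  # positions are stored +1; 0 marks a gap
_GAP_BYTE = ord("-")


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class PanChromosome:
    name: str
    acc_chrom: list[str]          # per accession: source chromosome name
    pos: np.ndarray               # (n_acc, n_cols) int64, 0 = gap, p+1 otherwise
    bases: np.ndarray             # (n_acc, n_cols) uint8 ASCII, '-' at gaps

    @property
    def n_columns(self) -> int:
        return self.pos.shape[1]

    def presence(self) -> np.ndarray:
        return self.pos != GAP


@dataclass
class PangenomeAlignment:
    accessions: list[str]
    chromosomes: list[PanChromosome] = field(default_factory=list)
    _index: dict | None = None

    # -- construction ------------------------------------------------------
    @classmethod
    def from_gapped(
        cls,
        rows: dict[str, str],
        chrom_name: str = "chr1",
        acc_chrom: str | None = None,
    ) -> "PangenomeAlignment":
        """Build an alignment from MSA-style gapped strings (test helper and
        small-scale entry point). ``-`` marks gaps."""
        accessions = list(rows)
        m = len(next(iter(rows.values())))
        if any(len(r) != m for r in rows.values()):
            raise ValueError("gapped rows must have equal length")
        n = len(accessions)
        pos = np.zeros((n, m), dtype=np.int64)
        bases = np.full((n, m), _GAP_BYTE, dtype=np.uint8)
        for i, acc in enumerate(accessions):
            row = rows[acc]
            p = 0
            for j, ch in enumerate(row):
                if ch != "-":
                    pos[i, j] = p + 1
                    bases[i, j] = ord(ch)
                    p += 1
        keep = (pos != GAP).any(axis=0)
        chrom = PanChromosome(
            name=chrom_name,
            acc_chrom=[acc_chrom or chrom_name] * n,
            pos=pos[:, keep],
            bases=bases[:, keep],
        )
        return cls(accessions=accessions, chromosomes=[chrom])

    # -- invariants --------------------------------------------------------
    def assert_monotonic(self) -> None:
        """Per accession, non-gap positions strictly increase along columns,
        every position occurs once, and no column is all-gap."""
        for chrom in self.chromosomes:
            if chrom.n_columns and not (chrom.pos != GAP).any(axis=0).all():
                raise AssertionError(f"{chrom.name}: all-gap column present")
            for i, acc in enumerate(self.accessions):
                vals = chrom.pos[i][chrom.pos[i] != GAP]
                if len(vals) and not (np.diff(vals) > 0).all():
                    raise AssertionError(f"{chrom.name}/{acc}: positions not strictly increasing")

    # -- coordinate index --------------------------------------------------
    def build_index(self) -> None:
        index: dict[tuple[str, str], tuple[int, np.ndarray]] = {}
        for ci, chrom in enumerate(self.chromosomes):
            for ai, acc in enumerate(self.accessions):
                row = chrom.pos[ai]
                nz = np.nonzero(row)[0]
                if len(nz) == 0:
                    continue
                size = int(row[nz].max())
                lut = np.full(size, -1, dtype=np.int64)
                lut[row[nz] - 1] = nz
                index[(acc, chrom.acc_chrom[ai])] = (ci, lut)
        self._index = index

    def to_pangenome(self, acc: str, chrom: str, pos: int) -> tuple[int, int] | None:
        """Genome position -> (pangenome chromosome index, column) or None."""
        if self._index is None:
            self.build_index()
        entry = self._index.get((acc, chrom))
        if entry is None:
            return None
        ci, lut = entry
        if pos >= len(lut) or lut[pos] < 0:
            return None
        return ci, int(lut[pos])

    def from_pangenome(self, chrom_idx: int, col: int, acc: str) -> int | None:
        """(pangenome chromosome index, column) -> genome position or None."""
        ai = self.accessions.index(acc)
        v = int(self.chromosomes[chrom_idx].pos[ai, col])
        return None if v == GAP else v - 1

    @property
    def total_columns(self) -> int:
        return sum(c.n_columns for c in self.chromosomes)


# ---------------------------------------------------------------------------
# Draft reference-biased matrices
# ---------------------------------------------------------------------------

@dataclass
class DraftAlignment:
    """One reference rotation: columns are the reference's positions."""

    reference: str
    accessions: list[str]
    # per reference chromosome: (n_acc, L) position matrix (+1, 0=gap) and
    # (n_acc, L) int16 chromosome-index matrix (-1 at gaps), indexing into
    # each accession's own chromosome-name list
    pos: dict[str, np.ndarray] = field(default_factory=dict)
    chrom_idx: dict[str, np.ndarray] = field(default_factory=dict)
    acc_chrom_names: list[list[str]] = field(default_factory=list)


def _scatter_map(draft: DraftAlignment, row: int, cmap: CorrespondenceMap,
                 query: GenomeSet, ref_chrom: str, rc_index: int) -> None:
    q_chrom_names = query.names
    for qi, qname in enumerate(q_chrom_names):
        rp = cmap.ref_pos[qname]
        ci = cmap.ref_chrom_idx[qname]
        sel = (rp >= 0) & (ci == rc_index)
        qpos = np.nonzero(sel)[0]
        if len(qpos) == 0:
            continue
        tpos = rp[qpos]
        # enforce injectivity on the reference side: drop duplicated targets
        uniq, counts = np.unique(tpos, return_counts=True)
        if (counts > 1).any():
            bad = set(uniq[counts > 1].tolist())
            keep = np.array([t not in bad for t in tpos])
            qpos, tpos = qpos[keep], tpos[keep]
        draft.pos[ref_chrom][row, tpos] = qpos + 1
        draft.chrom_idx[ref_chrom][row, tpos] = qi


def build_reference_matrices(
    genomes: list[GenomeSet],
    references: list[str],
    pairwise_maps: dict[tuple[str, str], CorrespondenceMap] | None = None,
    **align_kwargs,
) -> dict[str, DraftAlignment]:
    """One draft reference-biased matrix per rotated reference.

    ``pairwise_maps`` may carry precomputed ``(query, reference)`` maps;
    missing pairs are aligned on the fly.
    """
    if len(references) < 2:
        raise ValueError("at least 2 rotation references are required")
    by_id = {g.accession_id: g for g in genomes}
    for r in references:
        if r not in by_id:
            raise ValueError(f"reference {r!r} not in genome set")
    accessions = [g.accession_id for g in genomes]
    pairwise_maps = dict(pairwise_maps or {})

    drafts: dict[str, DraftAlignment] = {}
    for ref_id in references:
        ref = by_id[ref_id]
        draft = DraftAlignment(
            reference=ref_id,
            accessions=accessions,
            acc_chrom_names=[g.names for g in genomes],
        )
        for rname, rseq in ref.chromosomes:
            L = len(rseq)
            draft.pos[rname] = np.zeros((len(genomes), L), dtype=np.int64)
            draft.chrom_idx[rname] = np.full((len(genomes), L), -1, dtype=np.int16)
        ref_row = accessions.index(ref_id)
        for rci, (rname, rseq) in enumerate(ref.chromosomes):
            draft.pos[rname][ref_row] = np.arange(1, len(rseq) + 1)
            draft.chrom_idx[rname][ref_row] = rci
        rindex = None
        for row, q in enumerate(genomes):
            if q.accession_id == ref_id:
                continue
            key = (q.accession_id, ref_id)
            if key not in pairwise_maps:
                if rindex is None:
                    rindex = ReferenceIndex(ref, k=align_kwargs.get("k", 15))
                pairwise_maps[key] = align_pair(q, rindex, **align_kwargs)
            cmap = pairwise_maps[key]
            for rci, (rname, _) in enumerate(ref.chromosomes):
                _scatter_map(draft, row, cmap, q, rname, rci)
        drafts[ref_id] = draft
    return drafts


# ---------------------------------------------------------------------------
# Intersection -> skeleton
# ---------------------------------------------------------------------------

@dataclass
class Skeleton:
    """Surviving all-accession columns, ordered along the base reference."""

    accessions: list[str]
    acc_chrom_names: list[list[str]]
    # per base-reference chromosome: (n_acc, m) positions (+1) and the
    # per-accession chromosome index of every entry
    pos: dict[str, np.ndarray] = field(default_factory=dict)
    chrom_idx: dict[str, np.ndarray] = field(default_factory=dict)


def intersect_matrices(drafts: dict[str, DraftAlignment]) -> Skeleton:
    """Columns that carry the identical correspondence tuple in every draft.

    Only columns where all accessions are non-gap can agree across every
    rotation (each draft is complete on its own reference row), so the
    skeleton is restricted to all-present columns; gap-containing regions are
    re-derived by :func:`resolve_unaligned_blocks`.
    """
    draft_list = list(drafts.values())
    if len(draft_list) < 2:
        raise ValueError("need at least 2 drafts to intersect")
    accessions = draft_list[0].accessions
    for d in draft_list[1:]:
        if d.accessions != accessions:
            raise ValueError("drafts cover different accession sets")
    base = draft_list[0]
    others = draft_list[1:]
    skeleton = Skeleton(accessions=accessions, acc_chrom_names=base.acc_chrom_names)

    for rname, mat in base.pos.items():
        chrom_mat = base.chrom_idx[rname]
        ok = (mat != GAP).all(axis=0)
        for other in others:
            orow = accessions.index(other.reference)
            opos = mat[orow] - 1          # base column's position of the other ref
            ochrom = chrom_mat[orow]      # ...and its chromosome index
            agree = np.zeros(mat.shape[1], dtype=bool)
            other_names = base.acc_chrom_names[orow]
            for oc_idx, oc_name in enumerate(other_names):
                if oc_name not in other.pos:
                    continue
                sel = ok & (ochrom == oc_idx) & (opos >= 0) & (opos < other.pos[oc_name].shape[1])
                cols = np.nonzero(sel)[0]
                if len(cols) == 0:
                    continue
                sub_pos = other.pos[oc_name][:, opos[cols]]
                sub_chrom = other.chrom_idx[oc_name][:, opos[cols]]
                same = (sub_pos == mat[:, cols]).all(axis=0) & (
                    sub_chrom == chrom_mat[:, cols]
                ).all(axis=0)
                agree[cols[same]] = True
            ok &= agree
        cols = np.nonzero(ok)[0]
        pos = mat[:, cols]
        cidx = chrom_mat[:, cols]
        pos, cidx = _enforce_monotonic(pos, cidx)
        skeleton.pos[rname] = pos
        skeleton.chrom_idx[rname] = cidx
    return skeleton


def _enforce_monotonic(pos: np.ndarray, cidx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Keep columns where every accession stays on its modal chromosome with
    strictly increasing positions.

    Columns whose position deviates strongly from a rolling median are
    dropped first: a single wrong-locus correspondence (one mobile-element
    copy matched against another copy of its family) that survived the
    intersection would otherwise poison a plain greedy scan, which would
    keep the jumped-ahead column and then discard every honest column after
    it until the jump target is passed.
    """
    from scipy.ndimage import median_filter

    n, m = pos.shape
    if m == 0:
        return pos, cidx
    modal = np.zeros(n, dtype=np.int16)
    for i in range(n):
        vals, counts = np.unique(cidx[i], return_counts=True)
        modal[i] = vals[np.argmax(counts)]
    ok = (cidx == modal[:, None]).all(axis=0)
    if m > 51:
        for i in range(n):
            med = median_filter(pos[i].astype(np.float64), size=51, mode="nearest")
            ok &= np.abs(pos[i] - med) <= 5000
    keep = []
    last = np.zeros(n, dtype=np.int64)
    for j in np.nonzero(ok)[0]:
        if (pos[:, j] > last).all():
            keep.append(j)
            last = pos[:, j]
    keep = np.asarray(keep, dtype=np.int64)
    return pos[:, keep], cidx[:, keep]


# ---------------------------------------------------------------------------
# Progressive resolution of unaligned blocks
# ---------------------------------------------------------------------------

def _end_walks(member: str, center: str) -> tuple[int, int]:
    """Lengths of the exactly matching prefix and suffix of two sequences
    (non-overlapping). MSA blocks are flanked by alignment anchors on both
    sides, so matching ends are homologous by construction — anchoring them
    first removes the gap-placement ambiguity of a free global alignment,
    under which a short member can tie-score almost anywhere."""
    n = min(len(member), len(center))
    p = 0
    while p < n and member[p] == center[p]:
        p += 1
    s = 0
    while s < n - p and member[len(member) - 1 - s] == center[len(center) - 1 - s]:
        s += 1
    return p, s


def _member_pairs(
    member: str,
    center: str,
    support: np.ndarray | None = None,
    min_identity: float = 0.85,
    nw_limit: int = 300,
) -> tuple[list[tuple[int, int]], float]:
    """Confident member->center position pairs plus an acceptance score.

    Short centers are aligned globally (edit distance is trustworthy there)
    and scored by aligned-pair identity. Long centers are anchored: exact-
    seed runs chained colinearly plus bounded global alignment between them,
    so a member and a center that carry *different* large private insertions
    keep their insertions unaligned instead of smearing one against the
    other (a single global alignment prefers that, since mismatches are
    cheaper than two long gap runs). When ``support`` (per-center-position
    match counts from previously aligned members) is given, candidate runs
    are weighted by it: where a truncated mobile-element copy could align
    either to the homologous flank or verbatim into a *different* full
    copy of its family carried by the center, the consensus of the other
    members decides. Anchored pairs are confident by construction; the
    score then reflects how much of the shorter sequence was matched,
    which keeps mutually diverged members (satellite arrays) out.
    """
    p, s = _end_walks(member, center)
    end_pairs = [(i, i) for i in range(p)] + [
        (len(member) - s + i, len(center) - s + i) for i in range(s)
    ]
    n_end = p + s
    mm = member[p : len(member) - s]
    cc = center[p : len(center) - s]
    if not mm or not cc:
        # pure indel: one side fully explained by the anchored ends
        return end_pairs, 1.0 if end_pairs else 0.0

    if max(len(mm), len(cc)) <= nw_limit:
        mid_pairs, mid_matches = _nw_middle(mm, cc)
        pairs = (
            end_pairs[:p]
            + [(q + p, t + p) for q, t in mid_pairs]
            + end_pairs[p:]
        )
        denom = n_end + len(mid_pairs)
        if denom == 0:
            return [], 0.0
        return pairs, (n_end + mid_matches) / denom

    sup = support[p : len(center) - s] if support is not None else None
    mid_pairs = _anchored_middle(mm, cc, sup, min_identity)
    pairs = (
        end_pairs[:p]
        + [(q + p, t + p) for q, t in mid_pairs]
        + end_pairs[p:]
    )
    if not pairs:
        return [], 0.0
    covered = len(pairs) / min(len(member), len(center))
    if covered >= 0.2 or n_end >= 20:
        return pairs, 1.0
    return pairs, 0.0


def _nw_middle(mm: str, cc: str) -> tuple[list[tuple[int, int]], int]:
    """Global alignment of two short middles, keeping only contiguous
    aligned runs: with free interior gaps a short sequence can scatter-match
    almost every base against any longer one, so isolated matched singletons
    are noise, not homology."""
    trip = la.global_pairs_flagged(mm, cc)
    runs: list[list[tuple[int, int, bool]]] = []
    for q, t, m in trip:
        if runs and runs[-1][-1][0] == q - 1 and runs[-1][-1][1] == t - 1:
            runs[-1].append((q, t, m))
        else:
            runs.append([(q, t, m)])
    kept_runs = [run for run in runs if len(run) >= 5]
    pairs = [(q, t) for run in kept_runs for q, t, _ in run]
    matches = sum(m for run in kept_runs for _, _, m in run)
    return pairs, matches


def _anchored_middle(
    mm: str,
    cc: str,
    support: np.ndarray | None,
    min_identity: float,
) -> list[tuple[int, int]]:
    """Seed-run chaining of two long middles, support-weighted."""
    hits = la.local_hits(mm, cc, k=13, min_len=30, min_identity=min_identity)
    if support is not None:
        def weight(h: la.LocalHit) -> float:
            return h.length * (1.0 + float(support[h.ts : h.te].mean()))
    else:
        def weight(h: la.LocalHit) -> float:
            return float(h.score)

    kept: list[la.LocalHit] = []
    for h in sorted(hits, key=lambda h: (-weight(h), h.qs, h.ts)):
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

    def nw_gap(qs: int, qe: int, ts: int, te: int) -> None:
        if qe <= qs or te <= ts or qe - qs > 2000 or te - ts > 2000:
            return
        sub, matches = _nw_middle(mm[qs:qe], cc[ts:te])
        if sub and matches / len(sub) >= min_identity:
            pairs.extend((q + qs, t + ts) for q, t in sub)

    prev_q, prev_t = 0, 0
    for h in kept:
        nw_gap(prev_q, h.qs, prev_t, h.ts)
        pairs.extend(zip(range(h.qs, h.qe), range(h.ts, h.te)))
        prev_q, prev_t = h.qe, h.te
    if kept:
        nw_gap(prev_q, len(mm), prev_t, len(cc))
    pairs.sort()
    return pairs


def _star_msa(
    seqs: dict[int, str], min_identity: float = 0.75
) -> tuple[list[dict[int, int]], list[int], float]:
    """Star progressive alignment against the longest member.

    Returns MSA columns (accession-row -> offset within its subsequence) and
    the rows whose acceptance score against the center falls below
    ``min_identity`` (these get private columns instead): a member that is
    merely much shorter than the center (a pure indel with a shared flank)
    is kept, while a genuinely diverged member (a satellite array) is not.
    """
    rows = sorted(seqs, key=lambda r: (-len(seqs[r]), r))
    center = rows[0]
    cseq = seqs[center]
    m = len(cseq)
    match_at: dict[int, np.ndarray] = {}
    ins_chunks: dict[int, dict[int, list[int]]] = {}
    private: list[int] = []
    support = np.zeros(m, dtype=np.float64)
    # members aligned shortest first: short members carry no mobile-element
    # copies of their own, so they vote for the homologous flank before the
    # ambiguous (repeat-carrying) members are placed
    for r in sorted(rows[1:], key=lambda r: (len(seqs[r]), r)):
        pairs, score = _member_pairs(seqs[r], cseq, support)
        if score < min_identity:
            private.append(r)
            continue
        for _, ti in pairs:
            support[ti] += 1.0
        arr = np.full(m, -1, dtype=np.int64)
        chunks: dict[int, list[int]] = {}
        matched_q = set()
        for qi, ti in pairs:
            arr[ti] = qi
            matched_q.add(qi)
        # unmatched query positions are insertions before the next matched
        # center position (or at the end)
        nxt = m
        ordered = sorted(pairs, key=lambda p: p[0])
        qi_to_ci = dict(ordered)
        pending: list[int] = []
        for qi in range(len(seqs[r])):
            if qi in qi_to_ci:
                ci = qi_to_ci[qi]
                if pending:
                    chunks.setdefault(ci, []).extend(pending)
                    pending = []
            else:
                pending.append(qi)
        if pending:
            chunks.setdefault(m, []).extend(pending)
        match_at[r] = arr
        ins_chunks[r] = chunks
    columns: list[dict[int, int]] = []
    aligned_rows = [r for r in rows[1:] if r not in private]
    for g in range(m + 1):
        n_ins = max((len(ins_chunks[r].get(g, [])) for r in aligned_rows), default=0)
        for j in range(n_ins):
            col = {}
            for r in aligned_rows:
                chunk = ins_chunks[r].get(g, [])
                if j < len(chunk):
                    col[r] = chunk[j]
            if col:
                columns.append(col)
        if g < m:
            col = {center: g}
            for r in aligned_rows:
                if match_at[r][g] >= 0:
                    col[r] = int(match_at[r][g])
            columns.append(col)
    total = sum(len(seqs[r]) for r in rows[1:])
    anchored = sum(
        sum(1 for v in match_at[r] if v >= 0) for r in aligned_rows
    )
    unanchored_frac = 1.0 - anchored / total if total else 0.0
    return columns, private, unanchored_frac


def _msa_mismatch_fraction(columns: list[dict[int, int]], seqs: dict[int, str]) -> float:
    """Fraction of bases disagreeing with their column majority: a correct
    alignment of indel-divergent genomes is mismatch-sparse, so a high value
    flags an alignment that smeared non-homologous sequence together."""
    mism = 0
    total = 0
    for col in columns:
        if len(col) < 2:
            continue
        counts: dict[str, int] = {}
        for r, off in col.items():
            b = seqs[r][off]
            counts[b] = counts.get(b, 0) + 1
        n = sum(counts.values())
        mism += n - max(counts.values())
        total += n
    return mism / total if total else 0.0


def _mafft_available() -> bool:
    return shutil.which("mafft") is not None


def _mafft_msa(seqs: dict[int, str]) -> list[dict[int, int]] | None:
    """Progressive multiple alignment of a block via MAFFT.

    Used for larger multi-member blocks, where member-to-member consistency
    matters (e.g. several accessions sharing a mobile-element insertion the
    chosen center lacks); the star alignment cannot see those agreements.
    Returns MSA columns as row -> offset maps, or None if MAFFT is missing
    or fails (the caller falls back to the star alignment).
    """
    if not _mafft_available():
        return None
    rows = sorted(seqs)
    with tempfile.TemporaryDirectory(prefix="pankit_mafft_") as tmp:
        fasta = Path(tmp) / "block.fa"
        with open(fasta, "w") as fh:
            for r in rows:
                fh.write(f">{r}\n{seqs[r]}\n")
        try:
            res = subprocess.run(
                ["mafft", "--quiet", "--retree", "2", str(fasta)],
                capture_output=True, text=True, timeout=600,
            )
        except (OSError, subprocess.TimeoutExpired):
            return None
        if res.returncode != 0 or not res.stdout:
            return None
    aligned: dict[int, str] = {}
    name = None
    chunks: list[str] = []
    for line in res.stdout.splitlines():
        if line.startswith(">"):
            if name is not None:
                aligned[name] = "".join(chunks)
            name = int(line[1:].strip())
            chunks = []
        else:
            chunks.append(line.strip().upper())
    if name is not None:
        aligned[name] = "".join(chunks)
    if set(aligned) != set(rows):
        return None
    width = len(next(iter(aligned.values())))
    if any(len(v) != width for v in aligned.values()):
        return None
    offsets = {r: 0 for r in rows}
    columns: list[dict[int, int]] = []
    for j in range(width):
        col: dict[int, int] = {}
        for r in rows:
            if aligned[r][j] != "-":
                col[r] = offsets[r]
                offsets[r] += 1
        if col:
            columns.append(col)
    if any(offsets[r] != len(seqs[r]) for r in rows):
        return None
    return columns


def resolve_unaligned_blocks(
    skeleton: Skeleton,
    genomes: list[GenomeSet],
    max_block: int = DEFAULT_MAX_BLOCK,
    min_member_identity: float = 0.75,
) -> PangenomeAlignment:
    """Splice progressive-MSA columns into every inter-skeleton block.

    Chromosome ends count as flanking anchors. Blocks where any accession's
    unplaced subsequence exceeds ``max_block`` are considered highly diverged
    and kept as accession-private columns.
    """
    by_id = {g.accession_id: g for g in genomes}
    accessions = skeleton.accessions
    n = len(accessions)
    aln = PangenomeAlignment(accessions=accessions)

    for rname, pos in skeleton.pos.items():
        cidx = skeleton.chrom_idx[rname]
        m = pos.shape[1]
        if m == 0:
            continue
        acc_chrom = [
            skeleton.acc_chrom_names[i][int(cidx[i, 0])] for i in range(n)
        ]
        seqs = [by_id[accessions[i]].seq(acc_chrom[i]) for i in range(n)]
        lens = np.array([len(s) for s in seqs], dtype=np.int64)

        out_pos: list[np.ndarray] = []
        out_base: list[np.ndarray] = []

        def emit(col_pos: np.ndarray) -> None:
            col_base = np.full(n, _GAP_BYTE, dtype=np.uint8)
            for i in range(n):
                if col_pos[i] != GAP:
                    col_base[i] = ord(seqs[i][col_pos[i] - 1])
            out_pos.append(col_pos)
            out_base.append(col_base)

        def emit_block(prev: np.ndarray, nxt: np.ndarray) -> None:
            # per-accession unplaced subsequence between two anchors
            starts = prev  # position+1 of last anchored base (0 at chromosome start)
            stops = nxt - 1  # 0-based position of next anchored base
            sub = {
                i: seqs[i][starts[i] : stops[i]]
                for i in range(n)
                if stops[i] > starts[i]
            }
            if not sub:
                return
            if any(len(s) > max_block for s in sub.values()):
                # highly diverged: private columns, one accession at a time
                for i in sorted(sub):
                    for p in range(starts[i], stops[i]):
                        col = np.zeros(n, dtype=np.int64)
                        col[i] = p + 1
                        emit(col)
                return
            columns, private, unanchored = _star_msa(
                sub, min_identity=min_member_identity
            )
            if (
                (private or unanchored > 0.1)
                and len(sub) >= 2
                and max(len(x) for x in sub.values()) > 300
            ):
                mcols = _mafft_msa(sub)
                if mcols is not None and _msa_mismatch_fraction(mcols, sub) <= 0.003:
                    columns, private = mcols, []
            for col in columns:
                col_pos = np.zeros(n, dtype=np.int64)
                for i, off in col.items():
                    col_pos[i] = starts[i] + off + 1
                emit(col_pos)
            for i in sorted(private):
                for p in range(starts[i], stops[i]):
                    col = np.zeros(n, dtype=np.int64)
                    col[i] = p + 1
                    emit(col)

        prev = np.zeros(n, dtype=np.int64)  # virtual anchor before position 0
        for j in range(m):
            emit_block(prev, pos[:, j])
            emit(pos[:, j])
            prev = pos[:, j]
        emit_block(prev, lens + 1)  # virtual anchor past the chromosome end

        chrom = PanChromosome(
            name=rname,
            acc_chrom=acc_chrom,
            pos=np.column_stack(out_pos) if out_pos else np.zeros((n, 0), dtype=np.int64),
            bases=np.column_stack(out_base) if out_base else np.zeros((n, 0), dtype=np.uint8),
        )
        aln.chromosomes.append(chrom)
    aln.assert_monotonic()
    return aln


# ---------------------------------------------------------------------------
# Sorting and orchestration
# ---------------------------------------------------------------------------

def sort_and_index(aln: PangenomeAlignment, anchor_order: list[str]) -> PangenomeAlignment:
    """Stable-sort columns to be increasing in the first anchor accession's
    positions (ties resolved by subsequent anchors, fill-forward keys for gap
    entries), then build the bidirectional coordinate index."""
    if not anchor_order:
        raise ValueError("anchor_order must be non-empty")
    rows = [aln.accessions.index(a) for a in anchor_order]
    new_chroms = []
    for chrom in aln.chromosomes:
        m = chrom.n_columns
        keys = []
        for r in reversed(rows):
            p = chrom.pos[r].astype(np.float64)
            filled = np.maximum.accumulate(np.where(p > 0, p, 0.0))
            key = np.where(p > 0, p, filled + 0.5)
            keys.append(key)
        keys.append(np.arange(m))  # stability
        order = np.lexsort(tuple([keys[-1]] + keys[:-1]))
        new_chroms.append(
            PanChromosome(
                name=chrom.name,
                acc_chrom=chrom.acc_chrom,
                pos=chrom.pos[:, order],
                bases=chrom.bases[:, order],
            )
        )
    out = PangenomeAlignment(accessions=aln.accessions, chromosomes=new_chroms)
    out.build_index()
    return out


def pick_references(genomes: list[GenomeSet], n_refs: int | None = None,
                    k: int = 13, sample: int = 2000, seed: int = 0) -> list[str]:
    """Choose rotation references spread out in k-mer distance (greedy
    max-dispersion seeded with the first accession)."""
    n_refs = n_refs if n_refs is not None else min(4, len(genomes))
    rng = np.random.default_rng(seed)
    profiles = []
    for g in genomes:
        kmers: set[str] = set()
        for _, seq in g.chromosomes:
            if len(seq) <= k:
                continue
            starts = rng.integers(0, len(seq) - k, size=min(sample, len(seq) - k))
            kmers.update(seq[s : s + k] for s in starts)
        profiles.append(kmers)

    def dist(i: int, j: int) -> float:
        a, b = profiles[i], profiles[j]
        union = len(a | b)
        return 1.0 - (len(a & b) / union if union else 0.0)

    chosen = [0]
    while len(chosen) < min(n_refs, len(genomes)):
        best, best_d = None, -1.0
        for i in range(len(genomes)):
            if i in chosen:
                continue
            d = min(dist(i, j) for j in chosen)
            if d > best_d:
                best, best_d = i, d
        chosen.append(best)
    return [genomes[i].accession_id for i in chosen]


def build_pangenome(
    genomes: list[GenomeSet],
    references: list[str] | None = None,
    max_block: int = DEFAULT_MAX_BLOCK,
    anchor_order: list[str] | None = None,
    **align_kwargs,
) -> PangenomeAlignment:
    """End-to-end reference-free multiple alignment."""
    if references is None:
        references = pick_references(genomes)
    drafts = build_reference_matrices(genomes, references, **align_kwargs)
    skeleton = intersect_matrices(drafts)
    aln = resolve_unaligned_blocks(skeleton, genomes, max_block=max_block)
    anchor_order = anchor_order or [g.accession_id for g in genomes]
    return sort_and_index(aln, anchor_order)
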