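"""Gene-group ancestry classification against an outgroup proteome.

A gene group (one annotation group across accessions, ordered by its rank in
the pangenome coordinate system) is assigned the outgroup homolog shared by
at least half of its members at >= 80% identity over >= 80% of the focal
coding sequence. Consecutive assigned groups whose outgroup homologs sit
fewer than six genes apart in the outgroup's own gene order join a colinear
segment; membership in a segment of at least two groups makes the ancestry
call "position + sequence" (ancestral), a homolog without such synteny makes
it "similar", and no qualifying homolog "non-ancestral".
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class HomologHit:
    member_id: str
    outgroup_gene_id: str
    identity: float
    coverage: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0 and 0.0 <= self.coverage <= 1.0):
            raise ValueError("identity and coverage must lie in [0, 1]")


@dataclass
class GeneGroup:
    group_id: str
    rank: int                     # order in the pangenome coordinate system
    n_members: int
    hits: list[HomologHit] = field(default_factory=list)
    assigned_homolog: str | None = None


@dataclass
class AncestryCall:
    group_id: str
    value: str                    # ancestral_position_and_sequence | similar | non_ancestral
    outgroup_gene: str | None
    segment_id: int | None


def assign_group_homolog(
    group: GeneGroup,
    min_share: float = 0.5,
    min_ident: float = 0.8,
    min_cov: float = 0.8,
) -> str | None:
    """The single best-supported outgroup homolog of a group, or None.

    A candidate outgroup gene qualifies when hit by at least ``min_share``
    of the group's members at identity >= ``min_ident`` and coverage >=
    ``min_cov``; ties break by higher member share, then higher mean
    identity, then gene id.
    """
    if group.n_members <= 0:
        raise ValueError("group has no members")
    by_gene: dict[str, list[HomologHit]] = {}
    for h in group.hits:
        if h.identity >= min_ident and h.coverage >= min_cov:
            by_gene.setdefault(h.outgroup_gene_id, []).append(h)
    best: tuple | None = None
    for gene, hits in by_gene.items():
        share = len({h.member_id for h in hits}) / group.n_members
        if share < min_share:
            continue
        mean_ident = sum(h.identity for h in hits) / len(hits)
        key = (-share, -mean_ident, gene)
        if best is None or key < best[0]:
            best = (key, gene)
    group.assigned_homolog = best[1] if best else None
    return group.assigned_homolog


def build_colinear_segments(
    groups: list[GeneGroup],
    outgroup_order: dict[str, int],
    max_outgroup_gap: int = 6,
) -> dict[str, int]:
    """Partition rank-ordered groups into colinear segments.

    Two consecutive assigned groups stay in one segment iff their outgroup
    homologs are separated by fewer than ``max_outgroup_gap`` genes in the
    outgroup order; unassigned groups break segments and get no segment id.
    """
    segment_of: dict[str, int] = {}
    seg = -1
    prev_rank: int | None = None
    for g in sorted(groups, key=lambda x: x.rank):
        if g.assigned_homolog is None:
            prev_rank = None
            continue
        rank = outgroup_order[g.assigned_homolog]
        if prev_rank is None or abs(rank - prev_rank) >= max_outgroup_gap:
            seg += 1
        segment_of[g.group_id] = seg
        prev_rank = rank
    return segment_of


def classify_ancestry(
    group: GeneGroup, segments: dict[str, int]
) -> AncestryCall:
    """Ancestry state of one group given the segment partition."""
    seg = segments.get(group.group_id)
    if seg is not None:
        size = sum(1 for s in segments.values() if s == seg)
        if size >= 2:
            return AncestryCall(
                group_id=group.group_id,
                value="ancestral_position_and_sequence",
                outgroup_gene=group.assigned_homolog,
                segment_id=seg,
            )
    if group.assigned_homolog is not None:
        return AncestryCall(
            group_id=group.group_id, value="similar",
            outgroup_gene=group.assigned_homolog, segment_id=None,
        )
    return AncestryCall(
        group_id=group.group_id, value="non_ancestral",
        outgroup_gene=None, segment_id=None,
    )


def classify_groups(
    groups: list[GeneGroup],
    outgroup_order: dict[str, int],
    min_share: float = 0.5,
    min_ident: float = 0.8,
    min_cov: float = 0.8,
    max_outgroup_gap: int = 6,
) -> list[AncestryCall]:
    """Full pipeline: homolog assignment, segment construction, per-group
    ancestry calls (returned in input order)."""
    for g in groups:
        assign_group_homolog(g, min_share=min_share, min_ident=min_ident, min_cov=min_cov)
    segments = build_colinear_segments(groups, outgroup_order, max_outgroup_gap=max_outgroup_gap)
    return [classify_ancestry(g, segments) for g in groups]
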