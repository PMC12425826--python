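"""Synthetic pangenomes with planted, machine-readable ground truth.

An ancestor genome is drawn uniformly over ACGT; per-accession genomes are
the ancestor with a lineage's planted events applied. Events are SNPs,
TE insertions (complete or truncated copies drawn from a generated TE
library), deletions, and unalignable satellite blocks (tandem arrays that
are independently re-randomized per accession, so no pair aligns). All
structural events are mutually non-overlapping on the ancestor with a
safety margin; SNP sites are globally unique and avoid structural
intervals. The truth ledger records every event and can re-apply itself to
the ancestor and project ancestor coordinates into any accession.

The default genealogy is a star: every accession is mutated independently
from the ancestor, the simplest model under which a presence allele carried
by a single accession really is an insertion. Carrier sets of structural
events are still drawn with (mostly small) sizes >= 1 so that shared derived
alleles — and hence the frequency-polarity logic — are exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .localalign import global_identity
from .seqs import GenomeSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

STRUCTURAL_MARGIN = 50  # nt between structural events on the ancestor


# ---------------------------------------------------------------------------
# TE library
# ---------------------------------------------------------------------------

@dataclass
class TEFamily:
    family_id: str
    superfamily: str
    consensus: str


@dataclass
class TELibrary:
    families: list[TEFamily] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.families)

    def __iter__(self):
        return iter(self.families)


_SUPERFAMILIES = ("Gypsy", "Copia", "LINE", "hAT", "Mutator", "CACTA", "Helitron")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def make_te_library(
    n_families: int,
    length_range: tuple[int, int] = (400, 6000),
    seed: int = 0,
    max_identity: float = 0.6,
    max_retries: int = 50,
) -> TELibrary:
    """Generate TE family consensuses with pairwise global identity below
    ``max_identity`` (enforced by rejection sampling)."""
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    lo, hi = length_range
    if lo < 300:
        raise ValueError("minimum family length is 300 nt")
    rng = np.random.default_rng(seed)
    families: list[TEFamily] = []
    for i in range(n_families):
        for attempt in range(max_retries):
            length = int(rng.integers(lo, hi + 1))
            cand = _random_seq(rng, length)
            if all(global_identity(cand, f.consensus) < max_identity for f in families):
                families.append(
                    TEFamily(
                        family_id=f"fam_{i}",
                        superfamily=_SUPERFAMILIES[i % len(_SUPERFAMILIES)],
                        consensus=cand,
                    )
                )
                break
        else:
            raise RuntimeError(
                f"could not draw family {i} below identity {max_identity} "
                f"after {max_retries} retries"
            )
    return TELibrary(families=families)


# ---------------------------------------------------------------------------
# Truth ledger
# ---------------------------------------------------------------------------

@dataclass
class PlantedSNP:
    chrom: str
    pos: int                    # ancestor coordinate
    ancestral: str
    derived: str
    carriers: frozenset[int]


@dataclass
class PlantedInsertion:
    chrom: str
    pos: int                    # insertion point: sequence goes before ancestor pos
    family_id: str
    sequence: str
    complete: bool
    carriers: frozenset[int]


@dataclass
class PlantedDeletion:
    chrom: str
    start: int
    end: int
    carriers: frozenset[int]


@dataclass
class SatelliteBlock:
    chrom: str
    start: int
    end: int
    unit: str


@dataclass
class PlantedTruth:
    n_accessions: int
    ancestor: GenomeSet
    snps: list[PlantedSNP] = field(default_factory=list)
    insertions: list[PlantedInsertion] = field(default_factory=list)
    deletions: list[PlantedDeletion] = field(default_factory=list)
    satellites: list[SatelliteBlock] = field(default_factory=list)
    # per accession, per chromosome: the accession's satellite replacement
    satellite_seqs: dict[tuple[int, str, int], str] = field(default_factory=dict)

    # -- applying the ledger ----------------------------------------------
    def _events_for(self, acc: int, chrom: str):
        """Events touching ``chrom`` in coordinate order, as (start, end,
        kind, payload); satellites apply to every accession."""
        evs: list[tuple[int, int, str, object]] = []
        for s in self.snps:
            if s.chrom == chrom and acc in s.carriers:
                evs.append((s.pos, s.pos + 1, "snp", s))
        for ins in self.insertions:
            if ins.chrom == chrom and acc in ins.carriers:
                evs.append((ins.pos, ins.pos, "ins", ins))
        for d in self.deletions:
            if d.chrom == chrom and acc in d.carriers:
                evs.append((d.start, d.end, "del", d))
        for si, sat in enumerate(self.satellites):
            if sat.chrom == chrom:
                evs.append((sat.start, sat.end, "sat", (si, sat)))
        evs.sort(key=lambda e: (e[0], e[1]))
        return evs

    def apply(self, acc: int) -> GenomeSet:
        """Reconstruct one accession's genome from the ancestor + ledger."""
        chroms: list[tuple[str, str]] = []
        for name, anc in self.ancestor.chromosomes:
            parts: list[str] = []
            cursor = 0
            for start, end, kind, payload in self._events_for(acc, name):
                parts.append(anc[cursor:start])
                if kind == "snp":
                    parts.append(payload.derived)
                elif kind == "ins":
                    parts.append(payload.sequence)
                elif kind == "del":
                    pass  # skip the interval
                else:  # satellite: accession-specific replacement
                    si, _ = payload
                    parts.append(self.satellite_seqs[(acc, name, si)])
                cursor = end
            parts.append(anc[cursor:])
            chroms.append((name, "".join(parts)))
        return GenomeSet(accession_id=f"acc{acc}", chromosomes=chroms)

    # -- coordinate projection --------------------------------------------
    def project(self, acc: int, chrom: str, pos: int) -> int | None:
        """Map an ancestor position into accession coordinates; None when
        the position was deleted or lies inside a satellite block."""
        offset = 0
        for start, end, kind, payload in self._events_for(acc, chrom):
            if pos < start:
                break
            if kind == "snp":
                continue
            if kind == "ins":
                if pos >= start:
                    offset += len(payload.sequence)
            elif kind == "del":
                if pos < end:
                    return None
                offset -= end - start
            else:
                si, sat = payload
                if pos < end:
                    return None
                offset += len(self.satellite_seqs[(acc, chrom, si)]) - (end - start)
        return pos + offset

    def insertion_interval(self, ins: PlantedInsertion, acc: int) -> tuple[int, int] | None:
        """Half-open interval the inserted sequence occupies in a carrier."""
        if acc not in ins.carriers:
            return None
        p = self.project(acc, ins.chrom, ins.pos)
        if p is None:
            return None
        return p - len(ins.sequence), p

    def deletion_interval(self, dele: PlantedDeletion, acc: int) -> tuple[int, int] | None:
        """Interval the deleted sequence occupies in a NON-carrier."""
        if acc in dele.carriers:
            return None
        s = self.project(acc, dele.chrom, dele.start)
        if s is None:
            return None
        return s, s + (dele.end - dele.start)

    def satellite_intervals(self, acc: int) -> list[tuple[str, int, int]]:
        """Per-accession intervals occupied by satellite replacements."""
        out = []
        for si, sat in enumerate(self.satellites):
            s = self.project(acc, sat.chrom, max(0, sat.start - 1))
            if s is None:
                continue
            if sat.start > 0:
                s += 1
            length = len(self.satellite_seqs[(acc, sat.chrom, si)])
            out.append((sat.chrom, s, s + length))
        return out


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    n_accessions: int = 8
    n_chromosomes: int = 2
    chrom_length: int = 300_000
    snp_rate: float = 5e-4            # per site per lineage
    n_insertions: int = 60
    n_deletions: int = 40
    deletion_length: tuple[int, int] = (15, 2000)
    n_satellites: int = 4
    satellite_unit_length: tuple[int, int] = (20, 180)
    satellite_copies: tuple[int, int] = (20, 60)
    te_families: int = 6
    te_length_range: tuple[int, int] = (400, 6000)
    complete_fraction: float = 0.7
    truncation_range: tuple[float, float] = (0.2, 0.8)
    carrier_geom_p: float = 0.5       # carrier-set size ~ 1 + Geometric
    genealogy: str = "star"


def _draw_carriers(rng: np.random.Generator, n: int, p: float) -> frozenset[int]:
    size = 1 + rng.geometric(p) - 1  # Geometric support starts at 1
    size = int(min(max(size, 1), n - 1))
    return frozenset(rng.choice(n, size=size, replace=False).tolist())


def _place_intervals(
    rng: np.random.Generator,
    lengths: list[int],
    chrom_lengths: dict[str, int],
    margin: int = STRUCTURAL_MARGIN,
    max_tries: int = 10_000,
) -> list[tuple[str, int, int]]:
    """Place intervals of the given lengths uniformly, non-overlapping with
    a margin, across chromosomes (proportional to length)."""
    names = list(chrom_lengths)
    weights = np.array([chrom_lengths[n] for n in names], dtype=float)
    weights /= weights.sum()
    placed: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    out: list[tuple[str, int, int]] = []
    for L in lengths:
        for _ in range(max_tries):
            chrom = names[int(rng.choice(len(names), p=weights))]
            limit = chrom_lengths[chrom] - L - margin
            if limit <= margin:
                continue
            start = int(rng.integers(margin, limit))
            end = start + L
            if all(
                end + margin <= s or e + margin <= start for s, e in placed[chrom]
            ):
                placed[chrom].append((start, end))
                out.append((chrom, start, end))
                break
        else:
            raise RuntimeError(
                "event density too high: cannot place non-overlapping events"
            )
    return out


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode()


def simulate_pangenome(
    config: SimulationConfig | None = None,
    seed: int = 0,
    te_library: TELibrary | None = None,
) -> tuple[list[GenomeSet], PlantedTruth]:
    """Simulate a pangenome under the configured study conditions.

    Returns the accession genomes (derived from a common random ancestor by
    applying each lineage's planted events) together with the truth ledger.
    """
    cfg = config or SimulationConfig()
    if cfg.genealogy != "star":
        raise NotImplementedError("only the star genealogy is implemented")
    rng = np.random.default_rng(seed)
    n = cfg.n_accessions

    ancestor = GenomeSet(
        accession_id="ancestor",
        chromosomes=[
            (f"chr{i + 1}", _random_seq(rng, cfg.chrom_length))
            for i in range(cfg.n_chromosomes)
        ],
    )
    chrom_lengths = {name: len(seq) for name, seq in ancestor.chromosomes}
    truth = PlantedTruth(n_accessions=n, ancestor=ancestor)

    if te_library is None and cfg.n_insertions > 0:
        te_library = make_te_library(
            cfg.te_families, cfg.te_length_range, seed=int(rng.integers(2**31))
        )

    # --- satellites (reserve space first: they are the longest events) ----
    sat_specs = []
    for _ in range(cfg.n_satellites):
        unit = _random_seq(rng, int(rng.integers(*cfg.satellite_unit_length)))
        copies = int(rng.integers(*cfg.satellite_copies))
        sat_specs.append((unit, copies))
    sat_spans = _place_intervals(
        rng, [len(u) * c for u, c in sat_specs], chrom_lengths
    )
    for (unit, copies), (chrom, start, end) in zip(sat_specs, sat_spans):
        truth.satellites.append(SatelliteBlock(chrom=chrom, start=start, end=end, unit=unit))
        # ancestor block itself is the clean tandem array
        name_to_idx = {nm: i for i, (nm, _) in enumerate(ancestor.chromosomes)}
        ci = name_to_idx[chrom]
        nm, seq = ancestor.chromosomes[ci]
        ancestor.chromosomes[ci] = (nm, seq[:start] + (unit * copies)[: end - start] + seq[end:])
    si_by_index = list(range(len(truth.satellites)))
    for acc in range(n):
        for si in si_by_index:
            sat = truth.satellites[si]
            copies = int(rng.integers(*cfg.satellite_copies))
            array = (sat.unit * copies)[: copies * len(sat.unit)]
            # heavy independent divergence makes every pair unalignable
            truth.satellite_seqs[(acc, sat.chrom, si)] = _mutate(rng, array, 0.25)

    occupied: dict[str, list[tuple[int, int]]] = {nm: [] for nm in chrom_lengths}
    for sat in truth.satellites:
        occupied[sat.chrom].append((sat.start, sat.end))

    # --- deletions --------------------------------------------------------
    del_lengths = [
        int(rng.integers(cfg.deletion_length[0], cfg.deletion_length[1] + 1))
        for _ in range(cfg.n_deletions)
    ]
    # --- insertions -------------------------------------------------------
    ins_seqs = []
    for _ in range(cfg.n_insertions):
        fam = te_library.families[int(rng.integers(len(te_library)))]
        complete = bool(rng.random() < cfg.complete_fraction)
        if complete:
            seq = fam.consensus
        else:
            frac = rng.uniform(*cfg.truncation_range)
            length = max(1, int(round(frac * len(fam.consensus))))
            start = int(rng.integers(0, len(fam.consensus) - length + 1))
            seq = fam.consensus[start : start + length]
        ins_seqs.append((fam.family_id, seq, complete))

    spans = _place_intervals(
        rng,
        del_lengths + [1] * cfg.n_insertions,  # insertion points need 1 free nt
        {nm: L for nm, L in chrom_lengths.items()},
    )
    # re-check against satellite occupancy; retry conflicting placements
    def conflict(chrom, s, e):
        return any(
            s < oe + STRUCTURAL_MARGIN and os_ < e + STRUCTURAL_MARGIN
            for os_, oe in occupied[chrom]
        )

    final_spans = []
    all_lengths = del_lengths + [1] * cfg.n_insertions
    for (chrom, s, e), L in zip(spans, all_lengths):
        tries = 0
        while conflict(chrom, s, e) or any(
            s < fe + STRUCTURAL_MARGIN and fs < e + STRUCTURAL_MARGIN
            for fc, fs, fe in final_spans
            if fc == chrom
        ):
            tries += 1
            if tries > 10_000:
                raise RuntimeError("event density too high near satellites")
            s = int(rng.integers(STRUCTURAL_MARGIN, chrom_lengths[chrom] - L - STRUCTURAL_MARGIN))
            e = s + L
        final_spans.append((chrom, s, e))

    for (chrom, s, e), L in zip(final_spans[: cfg.n_deletions], del_lengths):
        truth.deletions.append(
            PlantedDeletion(chrom=chrom, start=s, end=e,
                            carriers=_draw_carriers(rng, n, cfg.carrier_geom_p))
        )
    for (chrom, s, e), (fam_id, seq, complete) in zip(
        final_spans[cfg.n_deletions :], ins_seqs
    ):
        truth.insertions.append(
            PlantedInsertion(chrom=chrom, pos=s, family_id=fam_id, sequence=seq,
                             complete=complete,
                             carriers=_draw_carriers(rng, n, cfg.carrier_geom_p))
        )

    # --- SNPs: per-lineage Binomial counts, globally unique sites ---------
    structural = {nm: sorted(occupied[nm] + [(s, e) for c, s, e in final_spans if c == nm])
                  for nm in chrom_lengths}
    free_sites: dict[str, np.ndarray] = {}
    for nm, L in chrom_lengths.items():
        mask = np.ones(L, dtype=bool)
        for s, e in structural[nm]:
            mask[max(0, s - 1) : min(L, e + 1)] = False
        free_sites[nm] = np.nonzero(mask)[0]

    anc_by_name = dict(ancestor.chromosomes)
    used: dict[str, set[int]] = {nm: set() for nm in chrom_lengths}
    for acc in range(n):
        for nm, L in chrom_lengths.items():
            count = rng.binomial(L, cfg.snp_rate)
            pool = free_sites[nm]
            picks: list[int] = []
            while len(picks) < count:
                cand = pool[rng.integers(len(pool))]
                if cand not in used[nm]:
                    used[nm].add(int(cand))
                    picks.append(int(cand))
            for pos in sorted(picks):
                anc_base = anc_by_name[nm][pos]
                choices = [b for b in "ACGT" if b != anc_base]
                derived = choices[int(rng.integers(3))]
                truth.snps.append(
                    PlantedSNP(chrom=nm, pos=pos, ancestral=anc_base,
                               derived=derived, carriers=frozenset({acc}))
                )
    truth.snps.sort(key=lambda s: (s.chrom, s.pos))
    truth.insertions.sort(key=lambda i: (i.chrom, i.pos))
    truth.deletions.sort(key=lambda d: (d.chrom, d.start))

    genomes = [truth.apply(acc) for acc in range(n)]
    return genomes, truth


# ---------------------------------------------------------------------------
# Simulated read-mapping call sets (taxonomy exercises)
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCallSet:
    calls: set[int]
    het_calls: set[int]
    coverage_mask: set[int]
    aligned_mask: set[int]
    dropped: set[int]


def simulate_call_set(
    truth_snps: list[int],
    fdr_target: float,
    fnr_target: float,
    uncovered_fraction: float,
    het_count: int,
    seed: int = 0,
    n_sites: int | None = None,
) -> SimulatedCallSet:
    """Simulate a read-mapping SNP call set with planted error rates.

    Covered truth SNPs are dropped independently with probability
    ``fnr_target``; false calls are added at non-truth sites so the expected
    false-discovery rate equals ``fdr_target``; ``uncovered_fraction`` of
    truth sites lose coverage; ``het_count`` heterozygous calls (errors by
    construction in inbred lines) are injected at further non-truth sites.
    Sites are integers in ``[0, n_sites)`` (default: 4x the truth count,
    covering at least the truth sites).
    """
    if not 0.0 <= fdr_target < 1.0:
        raise ValueError("fdr_target must lie in [0, 1): a rate of 1 is unachievable")
    for name, rate in (("fnr_target", fnr_target), ("uncovered_fraction", uncovered_fraction)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    truth = set(int(t) for t in truth_snps)
    if n_sites is None:
        n_sites = max(4 * len(truth), (max(truth) + 1) if truth else 1)
    if truth and max(truth) >= n_sites:
        raise ValueError("n_sites must exceed every truth site")

    uncovered = {t for t in truth if rng.random() < uncovered_fraction}
    covered_truth = truth - uncovered
    dropped = {t for t in covered_truth if rng.random() < fnr_target}
    tp = covered_truth - dropped

    non_truth = np.setdiff1d(np.arange(n_sites), np.fromiter(truth, dtype=np.int64, count=len(truth)))
    n_fp = rng.binomial(int(round(len(tp) / (1.0 - fdr_target))), fdr_target) if tp else 0
    n_extra = n_fp + het_count
    if n_extra > len(non_truth):
        raise ValueError("not enough non-truth sites for the requested false calls")
    extra = rng.choice(non_truth, size=n_extra, replace=False)
    fp_sites = set(int(x) for x in extra[:n_fp])
    het_sites = set(int(x) for x in extra[n_fp:])

    return SimulatedCallSet(
        calls=tp | fp_sites | het_sites,
        het_calls=het_sites,
        coverage_mask=set(range(n_sites)) - uncovered,
        aligned_mask=set(range(n_sites)),
        dropped=dropped,
    )
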