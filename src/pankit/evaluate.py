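"""Scoring recovered variation against a planted truth ledger.

Planted SNPs and structural events live in ancestor coordinates; the ledger
projects them into each accession, and recovered calls are matched through
the first accession's genome coordinates (every planted SNP site exists in
all accessions because planted events never overlap on the ancestor).
"""

from __future__ import annotations

from dataclasses import dataclass

from sklearn.metrics import adjusted_rand_score

from .multialign import PangenomeAlignment
from .synthetic import PlantedTruth
from .variants import SNPRecord, SVLocus


@dataclass
class SNPPerformance:
    sensitivity: float
    precision: float
    n_truth: int
    n_called: int
    n_called_eval: int  # calls outside excluded (satellite) regions


def _satellite_lookup(truth: PlantedTruth, acc: int, pad: int = 30):
    intervals = [
        (chrom, max(0, s - pad), e + pad)
        for chrom, s, e in truth.satellite_intervals(acc)
    ]

    def inside(chrom: str, pos: int) -> bool:
        return any(c == chrom and s <= pos < e for c, s, e in intervals)

    return inside


def snp_performance(
    called: list[SNPRecord],
    truth: PlantedTruth,
    aln: PangenomeAlignment,
    anchor_acc: int = 0,
) -> SNPPerformance:
    """Sensitivity and precision of called SNPs against planted SNPs.

    A planted SNP is recovered when a called column sits at its projected
    position in the anchor accession and the carriers show the derived base
    there. Precision is evaluated outside the planted satellite blocks
    (plus a small pad), where alignment columns are well defined.
    """
    anchor_chrom = {c.acc_chrom[anchor_acc]: c.name for c in aln.chromosomes}
    truth_by_key: dict[tuple[str, int], list] = {}
    for s in truth.snps:
        p = truth.project(anchor_acc, s.chrom, s.pos)
        if p is None:
            continue
        truth_by_key.setdefault((anchor_chrom.get(s.chrom, s.chrom), p), []).append(s)

    in_sat = _satellite_lookup(truth, anchor_acc)
    sat_chrom_of = {c.name: c.acc_chrom[anchor_acc] for c in aln.chromosomes}

    called_keys: dict[tuple[str, int], SNPRecord] = {}
    for rec in called:
        called_keys[(rec.chrom, rec.ref_pos)] = rec

    hit = 0
    for key, planted in truth_by_key.items():
        rec = called_keys.get(key)
        if rec is None:
            continue
        ok = True
        for s in planted:
            for carrier in s.carriers:
                if rec.bases[carrier] != s.derived:
                    ok = False
        if ok:
            hit += 1

    n_eval = 0
    n_true = 0
    for key, rec in called_keys.items():
        chrom, pos = key
        if in_sat(sat_chrom_of.get(chrom, chrom), pos):
            continue
        n_eval += 1
        if key in truth_by_key:
            n_true += 1
    return SNPPerformance(
        sensitivity=hit / len(truth_by_key) if truth_by_key else 1.0,
        precision=n_true / n_eval if n_eval else 1.0,
        n_truth=len(truth_by_key),
        n_called=len(called_keys),
        n_called_eval=n_eval,
    )


@dataclass
class SVRecovery:
    recovered_fraction: float
    polarity_accuracy_singletons: float
    n_events: int
    n_recovered: int
    n_singletons_recovered: int
    matches: list[tuple[str, int, SVLocus]]  # (kind, truth index, locus)


def sv_recovery(
    loci: list[SVLocus],
    truth: PlantedTruth,
    aln: PangenomeAlignment,
    tol: int = 20,
) -> SVRecovery:
    """Match planted insertions/deletions to recovered sSV loci.

    A planted event is recovered when an sSV locus separates its carriers
    from the rest and the locus breakpoints, projected into a witness
    accession's coordinates, deviate from the planted interval by at most
    ``tol``. Polarity accuracy is scored on recovered singleton events.
    """
    ssv = [l for l in loci if l.sv_class == "sSV"]
    # index loci by (chrom, witness accession interval)
    matches: list[tuple[str, int, SVLocus]] = []
    n_events = len(truth.insertions) + len(truth.deletions)
    n_singletons = 0
    singleton_ok = 0

    def locus_interval(loc: SVLocus, acc: int) -> tuple[str, int, int] | None:
        """Presence-allele interval of a locus in one accession's genome."""
        ci = next(i for i, c in enumerate(aln.chromosomes) if c.name == loc.chrom)
        chrom = aln.chromosomes[ci]
        row = chrom.pos[acc, loc.start : loc.end]
        vals = row[row > 0]
        if len(vals) == 0:
            return None
        return chrom.acc_chrom[acc], int(vals.min() - 1), int(vals.max())

    for ti, ins in enumerate(truth.insertions):
        witness = min(ins.carriers)
        expected = truth.insertion_interval(ins, witness)
        if expected is None:
            continue
        es, ee = expected
        found = None
        for loc in ssv:
            if witness not in loc.presence_set:
                continue
            got = locus_interval(loc, witness)
            if got is None:
                continue
            chrom, gs, ge = got
            if chrom == ins.chrom and abs(gs - es) <= tol and abs(ge - ee) <= tol:
                found = loc
                break
        if found is not None:
            matches.append(("insertion", ti, found))
            if len(ins.carriers) == 1:
                n_singletons += 1
                if found.polarity == "likely_insertion":
                    singleton_ok += 1

    for ti, dele in enumerate(truth.deletions):
        witness = min(set(range(truth.n_accessions)) - dele.carriers)
        expected = truth.deletion_interval(dele, witness)
        if expected is None:
            continue
        es, ee = expected
        found = None
        for loc in ssv:
            if witness not in loc.presence_set:
                continue
            if not dele.carriers <= loc.absence_set:
                continue
            got = locus_interval(loc, witness)
            if got is None:
                continue
            chrom, gs, ge = got
            if chrom == dele.chrom and abs(gs - es) <= tol and abs(ge - ee) <= tol:
                found = loc
                break
        if found is not None:
            matches.append(("deletion", ti, found))
            if len(dele.carriers) == 1:
                n_singletons += 1
                if found.polarity == "likely_deletion":
                    singleton_ok += 1

    return SVRecovery(
        recovered_fraction=len(matches) / n_events if n_events else 1.0,
        polarity_accuracy_singletons=(
            singleton_ok / n_singletons if n_singletons else 1.0
        ),
        n_events=n_events,
        n_recovered=len(matches),
        n_singletons_recovered=n_singletons,
        matches=matches,
    )


def mobilome_family_ari(
    recovery: SVRecovery,
    truth: PlantedTruth,
    components: dict[str, int],
    loci_by_id: dict[str, SVLocus] | None = None,
) -> float:
    """Adjusted Rand index between planted TE family labels and nestedness
    components, over recovered insertion loci present in the graph."""
    fam_labels: list[str] = []
    comp_labels: list[int] = []
    for kind, ti, loc in recovery.matches:
        if kind != "insertion":
            continue
        if loc.sv_id not in components:
            continue
        fam_labels.append(truth.insertions[ti].family_id)
        comp_labels.append(components[loc.sv_id])
    if not fam_labels:
        return float("nan")
    return float(adjusted_rand_score(fam_labels, comp_labels))
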