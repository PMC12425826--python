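"""Readers and writers for the standard formats the toolkit touches.

All internal coordinates are 0-based half-open; the VCF writer converts to
1-based POS. Genotypes are haploid (the accessions are inbred lines). Every
TSV emitted here starts with a commented ``#`` header line.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqs import GenomeSet, TEAnnotationSet, TEElement, normalize_sequence, revcomp


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, accession_id: str | None = None) -> GenomeSet:
    """Read a FASTA file into a :class:`GenomeSet` (one chromosome per record).

    Lowercase is normalized to uppercase and non-ACGTN symbols become ``N``.
    Raises ``ValueError`` on an empty file or duplicate record names.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    seen: set[str] = set()
    chroms: list[tuple[str, str]] = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate record name {rec.id!r} in {path}")
        seen.add(rec.id)
        chroms.append((rec.id, normalize_sequence(str(rec.seq))))
    acc = accession_id if accession_id is not None else path.stem
    return GenomeSet(accession_id=acc, chromosomes=chroms)


def write_fasta(genome: GenomeSet, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.chromosomes
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_sequences_fasta(seqs: dict[str, str], path: str | Path) -> None:
    """Write a plain id -> sequence mapping (e.g. SV alleles, ORFs)."""
    records = [SeqRecord(Seq(s), id=k, description="") for k, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# TE annotation (FASTA library or GFF3 + genome)
# ---------------------------------------------------------------------------

_GFF_COLS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def _gff_attr(attrs: str, key: str) -> str | None:
    for field in attrs.split(";"):
        field = field.strip()
        if field.startswith(key + "="):
            return field[len(key) + 1:]
    return None


def _looks_like_gff(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if line.startswith("##gff"):
                return True
            if line.startswith(">"):
                return False
            if line.startswith("#"):
                continue
            return line.count("\t") >= 8
    return False


def read_te_annotation(path: str | Path, genome: GenomeSet | None = None) -> TEAnnotationSet:
    """Read a TE library: either a FASTA of element consensuses or a GFF3 of
    genomic intervals (requires ``genome`` to extract sequences; minus-strand
    features are reverse-complemented)."""
    path = Path(path)
    if not _looks_like_gff(path):
        lib = read_fasta(path, accession_id="library")
        elements = [
            TEElement(element_id=name, superfamily="unknown", sequence=seq)
            for name, seq in lib.chromosomes
        ]
        return TEAnnotationSet(elements=elements)

    if genome is None:
        raise ValueError("GFF3 TE annotation requires a genome to extract sequences from")
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=_GFF_COLS,
        dtype={"seqid": str, "attributes": str},
    )
    elements: list[TEElement] = []
    for i, row in df.iterrows():
        elem_id = _gff_attr(row.attributes, "ID") or f"{row.type}_{i}"
        superfam = (
            _gff_attr(row.attributes, "superfamily")
            or _gff_attr(row.attributes, "Classification")
            or str(row.type)
        )
        try:
            chrom_seq = genome.seq(str(row.seqid))
        except KeyError as exc:
            raise ValueError(f"feature {elem_id!r}: unknown chromosome {row.seqid!r}") from exc
        start, end = int(row.start) - 1, int(row.end)  # GFF3 is 1-based inclusive
        if start < 0 or end > len(chrom_seq) or start >= end:
            raise ValueError(
                f"feature {elem_id!r} interval [{row.start},{row.end}] out of bounds "
                f"for chromosome {row.seqid!r} (length {len(chrom_seq)})"
            )
        seq = chrom_seq[start:end]
        if row.strand == "-":
            seq = revcomp(seq)
        elements.append(TEElement(element_id=elem_id, superfamily=superfam, sequence=seq))
    return TEAnnotationSet(elements=elements)


# ---------------------------------------------------------------------------
# VCF (SNPs, haploid GT)
# ---------------------------------------------------------------------------

def write_snp_vcf(
    snps: Sequence,
    accessions: Sequence[str],
    path: str | Path,
    contigs: dict[str, int] | None = None,
) -> None:
    """Write SNP records as VCF v4.2 with haploid per-accession genotypes.

    ``snps`` are :class:`pankit.variants.SNPRecord`-like objects exposing
    ``chrom``, ``ref_pos`` (0-based), ``ref_base``, ``alt_bases`` and
    ``genotypes`` (per-accession allele index). POS is written 1-based.
    """
    header = pysam.VariantHeader()
    header.add_meta("source", "pankit")
    contigs = contigs or {}
    seen_contigs = dict(contigs)
    for s in snps:
        seen_contigs.setdefault(s.chrom, max(s.ref_pos + 1, 1))
    for name, length in seen_contigs.items():
        header.contigs.add(name, length=int(length))
    header.add_meta(
        "INFO", items=[("ID", "MODE"), ("Number", "1"), ("Type", "String"),
                       ("Description", "SNP calling mode")]
    )
    header.formats.add("GT", 1, "String", "Haploid genotype")
    for acc in accessions:
        header.add_sample(acc)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for s in sorted(snps, key=lambda r: (r.chrom, r.ref_pos)):
            rec = vcf.new_record(
                contig=s.chrom, start=s.ref_pos, stop=s.ref_pos + 1,
                alleles=(s.ref_base, *s.alt_bases),
            )
            for acc, gt in zip(accessions, s.genotypes):
                rec.samples[acc]["GT"] = (int(gt),)
            vcf.write(rec)


def read_snp_vcf(path: str | Path) -> pd.DataFrame:
    """Read a SNP VCF into a frame with 0-based ``pos`` and haploid genotypes."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            gts = [rec.samples[s]["GT"][0] for s in samples]
            rows.append((rec.contig, rec.start, rec.ref, ",".join(rec.alts or ()), gts))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "genotypes"])


# ---------------------------------------------------------------------------
# TSV writers (BED-like SV table, edge lists, curves, taxonomies)
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a frame as TSV with a single commented header line."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: expected commented '#' header line")
        cols = header[1:].rstrip("\n").split("\t")
        return pd.read_csv(fh, sep="\t", header=None, names=cols)


def sv_loci_frame(loci: Iterable) -> pd.DataFrame:
    """BED-like table of SV loci: 0-based half-open pangenome coordinates plus
    per-accession allele lengths."""
    rows = []
    for loc in loci:
        rows.append(
            {
                "pan_chrom": loc.chrom,
                "start_col": loc.start,
                "end_col": loc.end,
                "sv_id": loc.sv_id,
                "L": loc.L,
                "class": loc.sv_class or ".",
                "polarity": loc.polarity or ".",
                "presence_freq": (
                    round(loc.presence_frequency, 6) if loc.presence_frequency is not None else "."
                ),
                "terminal": int(loc.terminal),
                "allele_lengths": ",".join(str(l) for l in loc.allele_lengths),
            }
        )
    return pd.DataFrame(rows)


def write_edge_list(edges: Iterable[tuple[str, str, float]], path: str | Path) -> None:
    df = pd.DataFrame(edges, columns=["nested_id", "container_id", "coverage"])
    write_tsv(df, path)


def write_outputs(results: dict, out_dir: str | Path) -> dict[str, Path]:
    """Write a bundle of downstream results into ``out_dir``.

    Recognized keys: ``snps`` (+ ``accessions``, optional ``contigs``),
    ``sv_loci``, ``sv_alleles`` (id -> sequence), ``edges``, ``curves``
    (name -> DataFrame), ``tables`` (name -> DataFrame).
    Returns the mapping of logical name -> written path.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise ValueError(f"output directory {out_dir} is not writable: {exc}") from exc

    written: dict[str, Path] = {}
    if "snps" in results:
        p = out_dir / "snps.vcf"
        write_snp_vcf(results["snps"], results["accessions"], p,
                      contigs=results.get("contigs"))
        written["snps"] = p
    if "sv_loci" in results:
        p = out_dir / "sv_loci.tsv"
        write_tsv(sv_loci_frame(results["sv_loci"]), p)
        written["sv_loci"] = p
    if "sv_alleles" in results:
        p = out_dir / "sv_alleles.fasta"
        write_sequences_fasta(results["sv_alleles"], p)
        written["sv_alleles"] = p
    if "edges" in results:
        p = out_dir / "nestedness_edges.tsv"
        write_edge_list(results["edges"], p)
        written["edges"] = p
    for group in ("curves", "tables"):
        for name, df in results.get(group, {}).items():
            p = out_dir / f"{name}.tsv"
            write_tsv(df, p)
            written[name] = p
    return written


# ---------------------------------------------------------------------------
# Syntactic validators
# ---------------------------------------------------------------------------

def validate_vcf(path: str | Path) -> bool:
    """Parse the file with pysam and check POS sorted within each contig."""
    last: dict[str, int] = {}
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.contig in last and rec.start < last[rec.contig]:
                raise ValueError(f"{path}: unsorted record at {rec.contig}:{rec.pos}")
            last[rec.contig] = rec.start
    return True


def validate_tsv(path: str | Path) -> bool:
    """Check the commented header and a constant column count."""
    df = read_tsv(path)
    with open(path) as fh:
        ncol = len(fh.readline()[1:].rstrip("\n").split("\t"))
        for i, line in enumerate(fh, start=2):
            if line.strip() and line.rstrip("\n").count("\t") != ncol - 1:
                raise ValueError(f"{path}: line {i} has wrong column count")
    _ = df
    return True
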