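"""Readers and writers for the pipeline's file formats.

VCF 4.2 (per-bulk AD allelic depths, samples D_bulk / N_bulk, dwarf-
parent allele recorded in an INFO tag), TSV variant/genotype/phenotype/
marker-map/Ct tables, GFF3 gene models (read through gffutils), FASTA,
and BED region export.  All VCF/GFF coordinates are 1-based inclusive;
BED is 0-based half-open; the converters are exact inverses.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bsastats import CandidateRegion
from .candgene import GeneModel
from .simgen import VARIANT_COLUMNS, F2Cohort

log = logging.getLogger("bsamap")

__all__ = [
    "write_vcf",
    "read_variants",
    "write_sites_tsv",
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "write_phenotypes_tsv",
    "read_phenotypes_tsv",
    "write_marker_map_tsv",
    "read_marker_map_tsv",
    "interval_to_bed",
    "bed_to_interval",
    "write_regions_bed",
    "read_gene_models",
    "write_gene_models_gff3",
    "read_fasta",
    "write_fasta",
    "write_table_with_header",
]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(
    sites: pd.DataFrame,
    path: str | Path,
    metadata: dict | None = None,
    samples: tuple[str, str] = ("D_bulk", "N_bulk"),
    contigs: Sequence[str] | None = None,
) -> Path:
    """Write bulk allele counts as a minimal VCF 4.2 with AD FORMAT fields.

    INFO tag ``DWA`` records the dwarf-parent allele so polarity survives
    a round trip.  ``metadata`` key/values become ``##bsamap_<k>=<v>``
    header lines (config snapshot, seed).
    """
    path = Path(path)
    sites = sites.sort_values(["chrom", "pos"], kind="stable")
    if contigs is None:
        contigs = list(dict.fromkeys(sites["chrom"]))
    lines = ["##fileformat=VCFv4.2", "##source=bsamap"]
    for k, v in (metadata or {}).items():
        lines.append(f"##bsamap_{k}={v}")
    for c in contigs:
        lines.append(f"##contig=<ID={c}>")
    lines.append('##INFO=<ID=DWA,Number=1,Type=String,Description="Dwarf-parent allele">')
    lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for row in sites.itertuples(index=False):
        lines.append(
            f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
            f"DWA={row.parent_dw}\tAD\t{row.d_ref},{row.d_alt}\t{row.n_ref},{row.n_alt}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_variants(
    path: str | Path,
    dialect: str | None = None,
    samples: tuple[str, str] = ("D_bulk", "N_bulk"),
    multiallelic: str = "skip",
) -> pd.DataFrame:
    """Read a variant table with per-bulk allele depths.

    ``dialect`` is ``'vcf'`` or ``'tsv'`` (inferred from the extension
    when None).  VCF input must carry an AD FORMAT field for the two
    named bulk samples; multi-allelic records are skipped (with a
    warning) or rejected per ``multiallelic`` in {'skip', 'error'}.
    The TSV dialect needs columns chrom,pos,ref,alt,d_ref,d_alt,
    n_ref,n_alt (parental columns optional; alt is assumed to be the
    dwarf-parent allele when absent).
    """
    path = Path(path)
    if dialect is None:
        dialect = "vcf" if path.suffix.lower() in (".vcf", ".gz", ".bcf") else "tsv"
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#")
        required = ["chrom", "pos", "ref", "alt", "d_ref", "d_alt", "n_ref", "n_alt"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: TSV variant table missing columns {missing}")
        if "parent_dw" not in df.columns:
            log.warning("%s: no parental columns; assuming alt = dwarf-parent allele", path)
            df["parent_dw"] = df["alt"]
            df["parent_hi"] = df["ref"]
        return df[VARIANT_COLUMNS]
    if dialect != "vcf":
        raise ValueError(f"unknown dialect {dialect!r}")

    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_idx = {}
    for s in samples:
        if s not in vcf.samples:
            raise ValueError(f"{path}: sample {s!r} not in VCF (has {vcf.samples})")
        sample_idx[s] = vcf.samples.index(s)
    rows = []
    for i, v in enumerate(vcf):
        if len(v.ALT) != 1:
            if multiallelic == "error":
                raise ValueError(f"{path}: multi-allelic record at {v.CHROM}:{v.POS}")
            log.warning("%s: skipping multi-allelic record at %s:%d", path, v.CHROM, v.POS)
            continue
        ad = v.format("AD")
        if ad is None:
            raise ValueError(
                f"{path}: record {v.CHROM}:{v.POS} lacks the AD FORMAT field "
                f"for samples {samples}"
            )
        dwa = v.INFO.get("DWA")
        if dwa is None:
            dwa = v.ALT[0]
            if i == 0:
                log.warning("%s: no DWA INFO tag; assuming alt = dwarf-parent allele", path)
        d_ad = ad[sample_idx[samples[0]]]
        n_ad = ad[sample_idx[samples[1]]]
        rows.append((
            v.CHROM, v.POS, v.REF, v.ALT[0],
            v.REF if dwa != v.REF else v.ALT[0],  # parent_hi = the other allele
            dwa,
            max(int(d_ad[0]), 0), max(int(d_ad[1]), 0),
            max(int(n_ad[0]), 0), max(int(n_ad[1]), 0),
        ))
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_table_with_header(
    df: pd.DataFrame, path: str | Path, metadata: dict | None = None
) -> Path:
    """TSV with '#'-prefixed key=value comment header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def write_sites_tsv(sites: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> Path:
    return write_table_with_header(sites, path, metadata)


def write_genotypes_tsv(cohort: F2Cohort, path: str | Path) -> Path:
    """Genotype matrix: rows = individuals, columns = markers, AA/AB/BB."""
    codes = cohort.genotype_codes()
    df = pd.DataFrame(codes, index=cohort.ids, columns=cohort.marker_map["marker"])
    df.index.name = "id"
    path = Path(path)
    df.to_csv(path, sep="\t")
    return path


def read_genotypes_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")


def write_phenotypes_tsv(cohort: F2Cohort, path: str | Path) -> Path:
    df = pd.DataFrame({
        "id": cohort.ids,
        "phenotype": np.where(cohort.phenotypes, "dwarf", "normal"),
    })
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_phenotypes_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"id", "phenotype"} <= set(df.columns):
        raise ValueError(f"{path}: phenotype TSV needs columns id, phenotype")
    return df


def write_marker_map_tsv(marker_map: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    marker_map.to_csv(path, sep="\t", index=False)
    return path


def read_marker_map_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"marker", "chrom", "pos_bp"} <= set(df.columns):
        raise ValueError(f"{path}: marker map needs columns marker, chrom, pos_bp")
    return df


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def interval_to_bed(start_bp: int, end_bp: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    if start_bp < 1 or start_bp > end_bp:
        raise ValueError(f"bad 1-based interval ({start_bp}, {end_bp})")
    return start_bp - 1, end_bp


def bed_to_interval(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    if start < 0 or start >= end:
        raise ValueError(f"bad BED interval ({start}, {end})")
    return start + 1, end


def write_regions_bed(
    regions: Iterable[CandidateRegion], path: str | Path, metadata: dict | None = None
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}={v}\n")
        for r in regions:
            lo, hi = interval_to_bed(r.start_bp, r.end_bp)
            fh.write(
                f"{r.chrom}\t{lo}\t{hi}\t{r.statistic}\t{r.peak_value:.6g}\t.\n"
            )
    return path


# ---------------------------------------------------------------------------
# GFF3 / FASTA
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse gene models (gene + exon + CDS features) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True,
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons = [(f.start, f.end) for f in db.children(g, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(g, featuretype="CDS")]
        if not exons:
            exons = sorted(cds)
        note = g.attributes.get("Note", [""])[0] if g.attributes else ""
        genes.append(GeneModel(
            gene_id=g.id, chrom=g.seqid, strand=g.strand,
            exons=exons, cds=cds, annotation=note,
        ))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_gene_models_gff3(genes: Iterable[GeneModel], path: str | Path) -> Path:
    path = Path(path)
    lines = ["##gff-version 3"]
    for g in genes:
        lines.append(
            f"{g.chrom}\tbsamap\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
            f"ID={g.gene_id};Note={g.annotation}"
        )
        for i, (s, e) in enumerate(g.exons, 1):
            lines.append(
                f"{g.chrom}\tbsamap\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.exon{i};Parent={g.gene_id}"
            )
        for i, (s, e) in enumerate(g.cds, 1):
            lines.append(
                f"{g.chrom}\tbsamap\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                f"ID={g.gene_id}.cds{i};Parent={g.gene_id}"
            )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")
    return path
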