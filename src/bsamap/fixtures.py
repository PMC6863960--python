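"""Deterministic synthetic gene fixture for the candidate-gene layer.

Builds a toy ABC-transporter-like gene whose structure mirrors the
mapped dwarfing candidate: 10 exons / 9 introns, a spliced CDS of
exactly 3,753 bp encoding a 1,250-aa protein, a genomic span of
6,377 bp, and a planted set of parental variants — two exonic SNPs
(one missense, one synonymous), one intronic SNP, a 1-bp deletion in
exon 4 at spliced-CDS position 631 (a frameshift that truncates the
protein), and a 5-bp deletion wholly inside intron 8.

The fixture is synthetic: sequence content is random (seeded and
frozen), only the coordinate arithmetic and variant consequences are
meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .candgene import GeneModel, Variant

__all__ = ["GeneFixture", "build_dwarf_gene_fixture"]

_FIXTURE_SEED = 20190913  # frozen; the fixture is part of the package surface

# exon CDS lengths sum to 3,753; UTRs 50 bp (5') + 60 bp (3');
# intron lengths sum to 2,514 => genomic span 6,377 bp
_EXON_CDS = [200, 180, 220, 300, 450, 500, 400, 473, 530, 500]
_UTR5, _UTR3 = 50, 60
_INTRONS = [300, 280, 270, 260, 250, 300, 274, 290, 290]

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"

# 4-fold degenerate codon prefixes (any third base is synonymous)
_FOURFOLD = {"CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"}


@dataclass
class GeneFixture:
    gene: GeneModel
    chrom_seq: str
    seq_origin: int
    variants: dict[str, Variant]
    cds: str


def _random_codons(rng: np.random.Generator, n: int) -> list[str]:
    out = []
    while len(out) < n:
        codon = "".join(_BASES[i] for i in rng.integers(4, size=3))
        if codon not in _STOPS:
            out.append(codon)
    return out


def build_dwarf_gene_fixture(
    chrom: str = "chr9", gene_start: int = 30_396_000, flank: int = 300
) -> GeneFixture:
    """Construct the toy gene, its local chromosome sequence, and variants.

    ``gene_start`` is the genomic coordinate of the first transcribed
    base; the returned sequence covers the gene plus ``flank`` bp on each
    side (its first base has coordinate ``gene_start - flank``).
    """
    rng = np.random.default_rng(_FIXTURE_SEED)
    codons = ["ATG"] + _random_codons(rng, 1249) + ["TAA"]

    # the 1-bp deletion removes spliced-CDS base 631 (0-based 630, the
    # first base of codon 211); keep it distinct from base 630 so the
    # anchored representation is already left-aligned
    while True:
        cds = "".join(codons)
        if cds[629] != cds[630]:
            break
        codons[209] = _random_codons(rng, 1)[0]

    assert len(cds) == 3753

    # genomic layout
    exon_lens = list(_EXON_CDS)
    exon_lens[0] += _UTR5
    exon_lens[-1] += _UTR3
    exons: list[tuple[int, int]] = []
    cds_segs: list[tuple[int, int]] = []
    pos = gene_start
    for i, elen in enumerate(exon_lens):
        exons.append((pos, pos + elen - 1))
        cs = pos + (_UTR5 if i == 0 else 0)
        ce = pos + elen - 1 - (_UTR3 if i == len(exon_lens) - 1 else 0)
        cds_segs.append((cs, ce))
        pos += elen
        if i < len(_INTRONS):
            pos += _INTRONS[i]
    gene_end = exons[-1][1]
    assert gene_end - gene_start + 1 == 6377

    gene = GeneModel(
        gene_id="ClDWG01", chrom=chrom, strand="+", exons=exons, cds=cds_segs,
        annotation="synthetic ABC transporter-like dwarfing candidate (toy fixture)",
    )

    # assemble the genomic sequence: CDS bases from the codon string,
    # UTRs / introns / flanks random
    def rand_seq(n: int) -> str:
        return "".join(_BASES[i] for i in rng.integers(4, size=n))

    seq_origin = gene_start - flank
    chunks = [rand_seq(flank), rand_seq(_UTR5)]
    cds_cursor = 0
    for i, (cs, ce) in enumerate(cds_segs):
        seg_len = ce - cs + 1
        chunks.append(cds[cds_cursor: cds_cursor + seg_len])
        cds_cursor += seg_len
        if i < len(_INTRONS):
            chunks.append(rand_seq(_INTRONS[i]))
    chunks.append(rand_seq(_UTR3))
    chunks.append(rand_seq(flank))
    chrom_seq = "".join(chunks)
    assert len(chrom_seq) == 6377 + 2 * flank

    def genomic_of_cds(cpos: int) -> int:
        acc = 0
        for cs, ce in cds_segs:
            seg = ce - cs + 1
            if cpos <= acc + seg:
                return cs + (cpos - acc - 1)
            acc += seg
        raise AssertionError

    def base_at(gpos: int) -> str:
        return chrom_seq[gpos - seq_origin]

    variants: dict[str, Variant] = {}

    # synonymous SNP: third base of the first 4-fold codon at index >= 100
    for ci in range(100, 1250):
        if codons[ci][:2] in _FOURFOLD:
            cpos = 3 * ci + 3
            g = genomic_of_cds(cpos)
            old = base_at(g)
            new = next(b for b in _BASES if b != old)
            variants["exon_snp_synonymous"] = Variant(chrom, g, old, new)
            break

    # missense SNP: first-base change that alters the amino acid, no stop
    from Bio.Seq import Seq
    for ci in range(400, 1250):
        codon = codons[ci]
        aa = str(Seq(codon).translate())
        for b in _BASES:
            if b == codon[0]:
                continue
            alt_codon = b + codon[1:]
            if alt_codon in _STOPS:
                continue
            if str(Seq(alt_codon).translate()) != aa:
                cpos = 3 * ci + 1
                g = genomic_of_cds(cpos)
                variants["exon_snp_missense"] = Variant(chrom, g, codon[0], b)
                break
        if "exon_snp_missense" in variants:
            break

    # intronic SNP in the middle of intron 5
    introns = gene.introns()
    i5 = introns[4]
    g = (i5[0] + i5[1]) // 2
    old = base_at(g)
    variants["intron_snp"] = Variant(chrom, g, old, next(b for b in _BASES if b != old))

    # the causal 1-bp deletion at spliced-CDS position 631 (exon 4)
    g_del = genomic_of_cds(631)
    anchor = g_del - 1
    variants["exon4_del1"] = Variant(
        chrom, anchor, base_at(anchor) + base_at(g_del), base_at(anchor)
    )

    # 5-bp deletion wholly inside intron 8
    i8 = introns[7]
    a = (i8[0] + i8[1]) // 2
    removed = "".join(base_at(a + j) for j in range(6))
    variants["intron8_del5"] = Variant(chrom, a, removed, removed[0])

    return GeneFixture(
        gene=gene, chrom_seq=chrom_seq, seq_origin=seq_origin,
        variants=variants, cds=cds,
    )
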