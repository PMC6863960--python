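"""Candidate-gene triage inside a mapped interval.

Variant-to-gene intersection, exon/intron placement, coding-effect
prediction (synonymous / missense / frameshift / in-frame indel, with
truncation by translation to the first stop codon), and design of
CAPS/dCAPS and Indel genotyping markers from parental variants.

Coordinates are GFF3-style: 1-based, inclusive.  Indels are expected in
left-aligned, VCF-anchored form (ref and alt share their first base);
an indel is *placed* by its leftmost affected base, i.e. the base after
the anchor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

__all__ = [
    "Variant",
    "GeneModel",
    "VariantEffect",
    "MarkerDesign",
    "Enzyme",
    "load_enzymes",
    "genes_in_region",
    "place_variant",
    "splice_cds",
    "predict_effect",
    "select_indel_markers",
    "design_dcaps",
    "genotype_concordance",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class Variant:
    """A biallelic variant; indels are VCF-anchored and left-aligned."""

    chrom: str
    pos: int            # 1-based; anchor base for indels
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")
        if not self.ref or not self.alt:
            raise ValueError("empty allele string")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def length_change(self) -> int:
        return len(self.alt) - len(self.ref)

    @property
    def affected_start(self) -> int:
        """Leftmost genomic base actually changed by the variant."""
        return self.pos + 1 if self.is_indel else self.pos


@dataclass
class GeneModel:
    """A gene with exon/CDS structure (1-based inclusive coordinates)."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        last = 0
        for s, e in self.exons:
            if s > e or s <= last:
                raise ValueError(f"exons of {self.gene_id} unsorted or overlapping")
            last = e
        for cs, ce in self.cds:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise ValueError(f"CDS segment ({cs}, {ce}) of {self.gene_id} outside exons")
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"CDS of {self.gene_id} has length {self.cds_length}, not divisible by 3"
            )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        ]


@dataclass(frozen=True)
class VariantEffect:
    """Placement and predicted coding consequence of one variant."""

    variant: Variant
    gene_id: str | None
    placement: str      # intergenic | intron | exon_utr | exon_cds
    effect: str         # none | synonymous | missense | frameshift | inframe_indel | nonstop
    cds_position: int | None = None
    protein_before_aa: int | None = None
    protein_after_aa: int | None = None
    nonstop: bool = False


@dataclass(frozen=True)
class Enzyme:
    name: str
    site: str

    def __post_init__(self) -> None:
        bad = set(self.site.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"enzyme {self.name}: invalid site characters {bad}")


@dataclass(frozen=True)
class MarkerDesign:
    """A CAPS/dCAPS/Indel genotyping marker derived from a parental variant."""

    marker_class: str               # Indel | CAPS | dCAPS
    variant: Variant
    enzyme_name: str | None = None
    enzyme_site: str | None = None
    site_offset: int | None = None  # 0-based offset of the site in the flank
    strand: str = "+"
    primer_window: tuple[int, int, str] | None = None
    mismatch_offset: int | None = None  # 0-based offset of the introduced mismatch
    mismatch_base: str | None = None
    diagnostic_allele: str | None = None  # 'ref' or 'alt': the allele that is cut
    fragment_diff_bp: int | None = None


# ---------------------------------------------------------------------------
# gene / region intersection and variant placement
# ---------------------------------------------------------------------------

def genes_in_region(
    genes: Iterable[GeneModel], chrom: str, start_bp: int, end_bp: int
) -> list[GeneModel]:
    """Genes whose genomic span overlaps the region (any overlap counts)."""
    if start_bp > end_bp:
        raise ValueError("region start exceeds end")
    return [
        g for g in genes
        if g.chrom == chrom and g.start <= end_bp and g.end >= start_bp
    ]


def place_variant(variant: Variant, gene: GeneModel) -> str:
    """Classify a variant as exon_cds / exon_utr / intron / intergenic."""
    if variant.chrom != gene.chrom:
        raise ValueError(
            f"variant on {variant.chrom} vs gene {gene.gene_id} on {gene.chrom}"
        )
    p = variant.affected_start
    if p < gene.start or p > gene.end:
        return "intergenic"
    if any(s <= p <= e for s, e in gene.cds):
        return "exon_cds"
    if any(s <= p <= e for s, e in gene.exons):
        return "exon_utr"
    return "intron"


# ---------------------------------------------------------------------------
# CDS splicing and effect prediction
# ---------------------------------------------------------------------------

def _extract(chrom_seq: str, start: int, end: int, seq_origin: int) -> str:
    lo, hi = start - seq_origin, end - seq_origin + 1
    if lo < 0 or hi > len(chrom_seq):
        raise ValueError(
            f"segment ({start}, {end}) outside provided sequence "
            f"(origin {seq_origin}, length {len(chrom_seq)})"
        )
    return chrom_seq[lo:hi]


def splice_cds(gene: GeneModel, chrom_seq: str, seq_origin: int = 1) -> str:
    """Spliced CDS sequence (5'->3' of the mRNA), validated for ATG...stop.

    ``seq_origin`` is the 1-based genomic coordinate of ``chrom_seq[0]``,
    so sub-chromosomal sequences can be supplied.
    """
    parts = [_extract(chrom_seq, s, e, seq_origin) for s, e in gene.cds]
    cds = "".join(parts).upper()
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    if not cds.startswith("ATG"):
        warnings.warn(f"CDS of {gene.gene_id} does not start with ATG", stacklevel=2)
    if cds[-3:] not in ("TAA", "TAG", "TGA"):
        warnings.warn(f"CDS of {gene.gene_id} does not end with a stop codon", stacklevel=2)
    return cds


def _genomic_to_cds(gene: GeneModel, pos: int) -> int:
    """1-based position in the spliced CDS of a genomic base inside the CDS."""
    segs = gene.cds
    if gene.strand == "+":
        acc = 0
        for s, e in segs:
            if s <= pos <= e:
                return acc + (pos - s) + 1
            acc += e - s + 1
    else:
        acc = 0
        for s, e in reversed(segs):
            if s <= pos <= e:
                return acc + (e - pos) + 1
            acc += e - s + 1
    raise ValueError(f"position {pos} is not inside the CDS of {gene.gene_id}")


def _translate_to_stop(cds: str) -> tuple[int, bool]:
    """(residues before the first stop, nonstop flag) for an ATG-led frame."""
    prot = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    stop = prot.find("*")
    if stop == -1:
        return len(prot), True
    return stop, False


def predict_effect(
    variant: Variant, gene: GeneModel, chrom_seq: str, seq_origin: int = 1
) -> VariantEffect:
    """Predicted coding consequence of applying the alt allele to the gene.

    SNPs are classified by codon comparison; CDS indels with a length
    change not divisible by 3 are frameshifts, otherwise in-frame.  The
    mutant protein length is obtained by translating the mutant CDS from
    its ATG to the first stop; if no stop is reached the product is
    flagged nonstop.  A stop-gain SNP is reported as missense (the codon
    changes) with the truncation visible in ``protein_after_aa``.

    Limitation: indels must fall wholly within one CDS segment (or
    outside the CDS); splice-boundary-spanning indels are not modelled.
    """
    placement = place_variant(variant, gene)
    cds = splice_cds(gene, chrom_seq, seq_origin)
    protein_before = len(cds) // 3 - 1
    if placement != "exon_cds":
        return VariantEffect(
            variant=variant, gene_id=gene.gene_id, placement=placement,
            effect="none", protein_before_aa=protein_before,
            protein_after_aa=protein_before,
        )

    if not variant.is_indel:
        # SNP (only single-nucleotide substitutions are modelled)
        if len(variant.ref) != 1:
            raise ValueError("multi-nucleotide substitutions are not supported")
        cpos = _genomic_to_cds(gene, variant.pos)
        ref_base, alt_base = variant.ref.upper(), variant.alt.upper()
        if gene.strand == "-":
            ref_base = str(Seq(ref_base).reverse_complement())
            alt_base = str(Seq(alt_base).reverse_complement())
        if cds[cpos - 1] != ref_base:
            raise ValueError(
                f"reference mismatch at CDS position {cpos} of {gene.gene_id}: "
                f"sequence has {cds[cpos - 1]}, variant ref is {ref_base}"
            )
        mutant = cds[: cpos - 1] + alt_base + cds[cpos:]
        codon_i = (cpos - 1) // 3
        codon_ref = cds[3 * codon_i: 3 * codon_i + 3]
        codon_alt = mutant[3 * codon_i: 3 * codon_i + 3]
        aa_ref = str(Seq(codon_ref).translate())
        aa_alt = str(Seq(codon_alt).translate())
        effect = "synonymous" if aa_ref == aa_alt else "missense"
        after, nonstop = _translate_to_stop(mutant)
        return VariantEffect(
            variant=variant, gene_id=gene.gene_id, placement=placement,
            effect=effect, cds_position=cpos, protein_before_aa=protein_before,
            protein_after_aa=after, nonstop=nonstop,
        )

    # indel: map the affected genomic bases into spliced-CDS space
    delta = variant.length_change
    if delta < 0:  # deletion of -delta bases after the anchor
        del_lo = variant.pos + 1
        del_hi = variant.pos + len(variant.ref) - 1
        seg = next(((s, e) for s, e in gene.cds if s <= del_lo and del_hi <= e), None)
        if seg is None:
            raise ValueError(
                "indel spans a CDS boundary; splice-spanning indels are not modelled"
            )
        c_lo = _genomic_to_cds(gene, del_lo)
        c_hi = _genomic_to_cds(gene, del_hi)
        c_lo, c_hi = min(c_lo, c_hi), max(c_lo, c_hi)
        mutant = cds[: c_lo - 1] + cds[c_hi:]
        cpos = c_lo
    else:  # insertion of delta bases after the anchor
        ins = variant.alt[len(variant.ref):].upper()
        if gene.strand == "-":
            ins = str(Seq(ins).reverse_complement())
            c_anchor = _genomic_to_cds(gene, variant.pos)
            # on the minus strand the insertion lands 5' of the anchor base
            mutant = cds[: c_anchor - 1] + ins + cds[c_anchor - 1:]
            cpos = c_anchor
        else:
            c_anchor = _genomic_to_cds(gene, variant.pos)
            mutant = cds[:c_anchor] + ins + cds[c_anchor:]
            cpos = c_anchor + 1

    after, nonstop = _translate_to_stop(mutant)
    if delta % 3 != 0:
        effect = "nonstop" if nonstop else "frameshift"
    else:
        effect = "inframe_indel"
    return VariantEffect(
        variant=variant, gene_id=gene.gene_id, placement=placement,
        effect=effect, cds_position=cpos, protein_before_aa=protein_before,
        protein_after_aa=after, nonstop=nonstop,
    )


# ---------------------------------------------------------------------------
# marker design
# ---------------------------------------------------------------------------

def load_enzymes(path: str | Path | None = None) -> list[Enzyme]:
    """Load the enzyme table (name TAB recognition-site, '#' comments)."""
    if path is None:
        text = (resources.files("bsamap") / "data" / "enzymes.tsv").read_text()
    else:
        text = Path(path).read_text()
    enzymes = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, site = line.split("\t")
        enzymes.append(Enzyme(name=name, site=site.upper()))
    return enzymes


def select_indel_markers(
    variants: Iterable[Variant], min_indel_bp: int = 3, flank_bp: int = 150
) -> list[MarkerDesign]:
    """Indel markers for length polymorphisms resolvable on a gel.

    Only indels with an allele length difference of at least
    ``min_indel_bp`` (default 3, the practical gel-resolution limit that
    motivated the original >=3 bp rule) are selected; each is wrapped in
    a +/- ``flank_bp`` primer window.
    """
    out = []
    for v in variants:
        diff = abs(v.length_change)
        if v.is_indel and diff >= min_indel_bp:
            out.append(MarkerDesign(
                marker_class="Indel", variant=v,
                primer_window=(max(1, v.pos - flank_bp), v.pos + len(v.ref) - 1 + flank_bp, "+"),
                diagnostic_allele="alt" if v.length_change < 0 else "ref",
                fragment_diff_bp=diff,
            ))
    return out


def _iupac_match(pattern: str, seq: str) -> bool:
    return len(pattern) == len(seq) and all(
        b in IUPAC[p] for p, b in zip(pattern, seq)
    )


def _mismatch_offsets(pattern: str, seq: str) -> list[int]:
    return [i for i, (p, b) in enumerate(zip(pattern, seq)) if b not in IUPAC[p]]


def _revcomp(s: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A",
            "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
            "B": "V", "D": "H", "H": "D", "V": "B", "N": "N"}
    return "".join(comp[c] for c in reversed(s.upper()))


def _site_in_seq(site: str, seq: str) -> bool:
    """Does the sequence contain the recognition site on either strand?"""
    for pattern in {site, _revcomp(site)}:
        for off in range(len(seq) - len(pattern) + 1):
            if _iupac_match(pattern, seq[off: off + len(pattern)]):
                return True
    return False


def design_dcaps(
    variant: Variant,
    flank_seq: str,
    var_offset: int,
    enzymes: Sequence[Enzyme] | None = None,
    max_mismatch: int = 1,
    primer_len: int = 20,
    amplicon_tail: int = 80,
) -> MarkerDesign | None:
    """CAPS/dCAPS design for a SNP (or CAPS for an indel) on a local flank.

    ``flank_seq`` is the reference-allele local sequence and
    ``var_offset`` the 0-based offset of the variant (anchor) base in it.

    Strategy, mirroring the dCAPS idea: first look for a plain CAPS — an
    enzyme whose recognition site overlaps the variant and is present in
    exactly one allele with no engineering.  Failing that, search both
    strands and every site placement overlapping the variant for a single
    base change (never at the variant itself) lying within the
    ``primer_len`` bases adjacent to the variant (the primer-covered
    portion) that completes the recognition site for exactly one allele.
    The same introduced base appears in both alleles' amplicons, so the
    allele discrimination comes solely from the variant base.

    Every returned design is re-verified by scanning both full (primer-
    mutated) allele sequences: exactly one must contain the site.
    Deterministic tie-break: alphabetical enzyme name, then leftmost
    placement, then forward before reverse strand.  Returns None when no
    design exists.

    The reported fragment-length difference is nominal: the distance from
    the cut site to the nearer end of an amplicon modelled as the primer
    window plus ``amplicon_tail`` bases beyond the variant.
    """
    if enzymes is None:
        enzymes = load_enzymes()
    enzymes = sorted(enzymes, key=lambda e: e.name)
    flank_seq = flank_seq.upper()
    ref, alt = variant.ref.upper(), variant.alt.upper()
    if flank_seq[var_offset: var_offset + len(ref)] != ref:
        raise ValueError("flank sequence does not carry the ref allele at var_offset")
    seq_ref = flank_seq
    seq_alt = flank_seq[:var_offset] + alt + flank_seq[var_offset + len(ref):]
    var_len = max(len(ref), len(alt))  # footprint on the ref flank

    def site_placements(pattern: str, strand: str):
        lo = max(0, var_offset - len(pattern) + 1)
        hi = min(len(seq_ref) - len(pattern), var_offset + len(ref) - 1)
        for off in range(lo, hi + 1):
            yield off, strand

    def finish(marker_class, enz, pattern, off, strand, mm_off=None, mm_base=None,
               diagnostic=None):
        s_ref, s_alt = seq_ref, seq_alt
        if mm_off is not None:
            s_ref = s_ref[:mm_off] + mm_base + s_ref[mm_off + 1:]
            shift = len(alt) - len(ref) if mm_off > var_offset else 0
            s_alt = s_alt[:mm_off + shift] + mm_base + s_alt[mm_off + shift + 1:]
        cut_ref = _site_in_seq(enz.site, s_ref)
        cut_alt = _site_in_seq(enz.site, s_alt)
        if cut_ref == cut_alt:  # self-check: exactly one allele cuttable
            return None
        diag = "ref" if cut_ref else "alt"
        amp_lo = max(0, var_offset - primer_len)
        amp_hi = min(len(seq_ref) - 1, var_offset + var_len - 1 + amplicon_tail)
        cut_pos = off + len(pattern) // 2
        frag = min(abs(cut_pos - amp_lo), abs(amp_hi - cut_pos))
        primer = (amp_lo, var_offset - 1, "+") if (mm_off is None or mm_off < var_offset) \
            else (var_offset + var_len, min(len(seq_ref) - 1, var_offset + var_len - 1 + primer_len), "-")
        return MarkerDesign(
            marker_class=marker_class, variant=variant,
            enzyme_name=enz.name, enzyme_site=enz.site, site_offset=off,
            strand=strand, primer_window=primer,
            mismatch_offset=mm_off, mismatch_base=mm_base,
            diagnostic_allele=diag, fragment_diff_bp=frag,
        )

    # pass 1: CAPS (no introduced mismatch)
    for enz in enzymes:
        patterns = [(enz.site, "+")]
        rc = _revcomp(enz.site)
        if rc != enz.site:
            patterns.append((rc, "-"))
        for pattern, strand in patterns:
            for off, _ in site_placements(pattern, strand):
                hit_ref = _iupac_match(pattern, seq_ref[off: off + len(pattern)])
                # for indels the alt-side window shifts; just scan alt near variant
                if variant.is_indel:
                    hit_alt = any(
                        _iupac_match(pattern, seq_alt[o: o + len(pattern)])
                        for o in range(max(0, var_offset - len(pattern) + 1),
                                       min(len(seq_alt) - len(pattern), var_offset + len(alt)) + 1)
                    )
                else:
                    hit_alt = _iupac_match(pattern, seq_alt[off: off + len(pattern)])
                if hit_ref != hit_alt:
                    design = finish("CAPS", enz, pattern, off, strand)
                    if design is not None:
                        return design

    if variant.is_indel or max_mismatch < 1:
        return None

    # pass 2: dCAPS (one engineered mismatch in the primer-covered flank)
    primer_ok = set(range(max(0, var_offset - primer_len), var_offset)) | \
        set(range(var_offset + 1, min(len(seq_ref), var_offset + 1 + primer_len)))
    for enz in enzymes:
        patterns = [(enz.site, "+")]
        rc = _revcomp(enz.site)
        if rc != enz.site:
            patterns.append((rc, "-"))
        for pattern, strand in patterns:
            for off, _ in site_placements(pattern, strand):
                for allele_seq in (seq_ref, seq_alt):
                    window = allele_seq[off: off + len(pattern)]
                    mm = _mismatch_offsets(pattern, window)
                    if len(mm) != 1:
                        continue
                    mm_abs = off + mm[0]
                    if mm_abs == var_offset or mm_abs not in primer_ok:
                        continue
                    # choose a concrete base completing the site
                    for base in IUPAC[pattern[mm[0]]]:
                        if base == allele_seq[mm_abs]:
                            continue
                        design = finish("dCAPS", enz, pattern, off, strand,
                                        mm_off=mm_abs, mm_base=base)
                        if design is not None:
                            return design
                        break
    return None


# ---------------------------------------------------------------------------
# marker-phenotype concordance
# ---------------------------------------------------------------------------

def genotype_concordance(
    calls: Mapping[str, str], phenotypes: Mapping[str, str]
) -> tuple[float, list[str]]:
    """Fraction of individuals whose marker genotype implies their phenotype.

    Under the recessive model the diagnostic (dwarf-parent, B) allele
    predicts a dwarf plant iff homozygous (BB).  Returns the concordance
    fraction and the sorted ids of discordant individuals.
    """
    if not calls or not phenotypes:
        raise ValueError("empty marker calls or phenotype panel")
    if set(calls) != set(phenotypes):
        only_c = sorted(set(calls) - set(phenotypes))[:5]
        only_p = sorted(set(phenotypes) - set(calls))[:5]
        raise ValueError(
            f"id mismatch between calls and phenotypes (calls-only {only_c}, "
            f"phenotypes-only {only_p})"
        )
    discordant = []
    for ind in calls:
        predicted_dwarf = str(calls[ind]).upper() == "BB"
        observed_dwarf = str(phenotypes[ind]).lower() in ("dwarf", "d", "1", "true")
        if predicted_dwarf != observed_dwarf:
            discordant.append(ind)
    discordant.sort()
    return 1.0 - len(discordant) / len(calls), discordant
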