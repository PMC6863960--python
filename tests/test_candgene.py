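"""Gene intersection, variant placement, effect prediction, marker design."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bsamap import candgene
from bsamap.candgene import (
    Enzyme, GeneModel, Variant, design_dcaps, genes_in_region,
    genotype_concordance, load_enzymes, place_variant, predict_effect,
    select_indel_markers, splice_cds,
)


def _gene(gene_id, chrom, start, end, strand="+"):
    length = end - start + 1 - (end - start + 1) % 3
    return GeneModel(gene_id, chrom, strand,
                     exons=[(start, end)], cds=[(start, start + length - 1)])


class TestGenesInRegion:
    def test_six_inside_two_outside(self):
        inside = [_gene(f"g{i}", "chr9", 30_400_000 + 10_000 * i,
                        30_400_000 + 10_000 * i + 2999) for i in range(6)]
        outside = [_gene("o1", "chr9", 30_600_000, 30_602_999),
                   _gene("o2", "chr3", 30_420_000, 30_422_999)]
        got = genes_in_region(inside + outside, "chr9", 30_394_615, 30_501_700)
        assert [g.gene_id for g in got] == [g.gene_id for g in inside]

    def test_empty_region_at_gene_free_bp(self):
        genes = [_gene("g", "chr1", 1000, 1999)]
        assert genes_in_region(genes, "chr1", 5000, 5000) == []

    def test_straddling_gene_included(self):
        genes = [_gene("g", "chr1", 900, 1199)]
        assert len(genes_in_region(genes, "chr1", 1000, 2000)) == 1

    @given(st.lists(st.tuples(st.integers(1, 500), st.integers(3, 60)),
                    min_size=1, max_size=15),
           st.integers(1, 500), st.integers(1, 100))
    @settings(deadline=None, max_examples=40)
    def test_matches_bruteforce_overlap(self, spans, reg_start, reg_len):
        genes = [_gene(f"g{i}", "chr1", s, s + ln - ln % 3 + 2)
                 for i, (s, ln) in enumerate(spans)]
        reg_end = reg_start + reg_len
        got = {g.gene_id for g in genes_in_region(genes, "chr1", reg_start, reg_end)}
        brute = {g.gene_id for g in genes
                 if max(g.start, reg_start) <= min(g.end, reg_end)}
        assert got == brute


class TestPlacement:
    def test_cds_snp(self, gene_fixture):
        v = gene_fixture.variants["exon_snp_missense"]
        assert place_variant(v, gene_fixture.gene) == "exon_cds"

    def test_five_bp_deletion_in_intron8(self, gene_fixture):
        v = gene_fixture.variants["intron8_del5"]
        g = gene_fixture.gene
        assert place_variant(v, g) == "intron"
        i8 = g.introns()[7]
        assert i8[0] <= v.affected_start and v.pos + len(v.ref) - 1 <= i8[1]

    def test_upstream_base_is_intergenic(self, gene_fixture):
        g = gene_fixture.gene
        v = Variant(g.chrom, g.start - 1, "A", "G")
        assert place_variant(v, g) == "intergenic"

    def test_utr_base(self, gene_fixture):
        g = gene_fixture.gene
        v = Variant(g.chrom, g.start + 10, "A", "G")  # inside the 50 bp 5'UTR
        assert place_variant(v, g) == "exon_utr"

    def test_wrong_chromosome_errors(self, gene_fixture):
        with pytest.raises(ValueError):
            place_variant(Variant("chrX", 5, "A", "G"), gene_fixture.gene)


class TestSpliceCds:
    def test_single_exon_plus_strand(self):
        seq = "NNATGAAATAGNN"
        g = GeneModel("t", "c", "+", exons=[(3, 11)], cds=[(3, 11)])
        assert splice_cds(g, seq) == "ATGAAATAG"

    def test_two_exon_minus_strand_hand_computed(self):
        #      123456789012345
        seq = "NNTTANNNNAGCCAT"
        # minus-strand gene: genomic segments (3,5)=TTA and (10,15)=AGCCAT;
        # concatenated TTAAGCCAT, reverse complement -> ATGGCTTAA
        g = GeneModel("t", "c", "-", exons=[(3, 5), (10, 15)], cds=[(3, 5), (10, 15)])
        assert splice_cds(g, seq) == "ATGGCTTAA"

    def test_fixture_cds_length_3753(self, gene_fixture):
        cds = splice_cds(gene_fixture.gene, gene_fixture.chrom_seq,
                         gene_fixture.seq_origin)
        assert len(cds) == 3753
        assert cds == gene_fixture.cds
        assert cds.startswith("ATG") and cds.endswith("TAA")

    def test_out_of_bounds_errors(self):
        g = GeneModel("t", "c", "+", exons=[(1, 9)], cds=[(1, 9)])
        with pytest.raises(ValueError):
            splice_cds(g, "ATGAA")


class TestPredictEffect:
    def test_synonymous_snp_keeps_protein(self, gene_fixture):
        eff = predict_effect(gene_fixture.variants["exon_snp_synonymous"],
                             gene_fixture.gene, gene_fixture.chrom_seq,
                             gene_fixture.seq_origin)
        assert eff.effect == "synonymous"
        assert eff.protein_after_aa == eff.protein_before_aa == 1250

    def test_missense_snp(self, gene_fixture):
        eff = predict_effect(gene_fixture.variants["exon_snp_missense"],
                             gene_fixture.gene, gene_fixture.chrom_seq,
                             gene_fixture.seq_origin)
        assert eff.effect == "missense"
        assert eff.placement == "exon_cds"

    def test_intronic_variants_have_no_coding_effect(self, gene_fixture):
        for key in ("intron_snp", "intron8_del5"):
            eff = predict_effect(gene_fixture.variants[key], gene_fixture.gene,
                                 gene_fixture.chrom_seq, gene_fixture.seq_origin)
            assert eff.placement == "intron"
            assert eff.effect == "none"
            assert eff.protein_after_aa == 1250

    def test_causal_deletion_frameshift_truncates(self, gene_fixture):
        eff = predict_effect(gene_fixture.variants["exon4_del1"],
                             gene_fixture.gene, gene_fixture.chrom_seq,
                             gene_fixture.seq_origin)
        assert eff.cds_position == 631
        assert eff.effect in ("frameshift", "nonstop")
        assert eff.nonstop or eff.protein_after_aa < eff.protein_before_aa

    def test_toy_deletion_without_new_stop_flags_nonstop(self):
        # CDS ATG AAA TAG; deleting nucleotide 4 gives ATGAATAG: M N, no stop
        seq = "ATGAAATAG"
        g = GeneModel("t", "c", "+", exons=[(1, 9)], cds=[(1, 9)])
        v = Variant("c", 3, "GA", "G")
        eff = predict_effect(v, g, seq)
        assert eff.nonstop
        assert eff.effect == "nonstop"
        assert eff.protein_after_aa == 2

    @pytest.mark.parametrize("delta", range(1, 10))
    def test_frameshift_iff_length_not_multiple_of_three(self, gene_fixture, delta):
        g = gene_fixture.gene
        seq, origin = gene_fixture.chrom_seq, gene_fixture.seq_origin
        cs, ce = g.cds[4]  # exon 5: 450 bp of CDS, roomy
        anchor = cs + 50
        ref = "".join(seq[anchor - origin + j] for j in range(delta + 1))
        eff = predict_effect(Variant(g.chrom, anchor, ref, ref[0]), g, seq, origin)
        if delta % 3 == 0:
            assert eff.effect == "inframe_indel"
        else:
            assert eff.effect in ("frameshift", "nonstop")

    def test_insertion_frameshift(self, gene_fixture):
        g = gene_fixture.gene
        seq, origin = gene_fixture.chrom_seq, gene_fixture.seq_origin
        cs, _ = g.cds[2]
        anchor = cs + 10
        base = seq[anchor - origin]
        eff = predict_effect(Variant(g.chrom, anchor, base, base + "TT"),
                             g, seq, origin)
        assert eff.effect in ("frameshift", "nonstop")

    def test_minus_strand_snp(self):
        # gene on minus strand: genomic ATG..TAA read from revcomp
        # CDS (revcomp of genomic 3..11): ATGGCTTAA
        genomic = "NNTTAAGCCATNN"
        g = GeneModel("t", "c", "-", exons=[(3, 11)], cds=[(3, 11)])
        assert splice_cds(g, genomic) == "ATGGCTTAA"
        # genomic G at pos 7 is CDS base 5 (C on the coding strand)
        eff = predict_effect(Variant("c", 7, "G", "A"), g, genomic)
        assert eff.effect == "missense"
        assert eff.cds_position == 5


class TestIndelMarkers:
    def test_one_bp_deletion_excluded_by_default(self, gene_fixture):
        out = select_indel_markers([gene_fixture.variants["exon4_del1"]])
        assert out == []

    def test_five_bp_deletion_included(self, gene_fixture):
        out = select_indel_markers([gene_fixture.variants["intron8_del5"]])
        assert len(out) == 1
        assert out[0].marker_class == "Indel"
        assert out[0].fragment_diff_bp == 5

    def test_threshold_one_includes_all_indels(self, gene_fixture):
        variants = list(gene_fixture.variants.values())
        out = select_indel_markers(variants, min_indel_bp=1)
        n_indels = sum(v.is_indel for v in variants)
        assert len(out) == n_indels


def _bruteforce_dcaps(ref, alt, flank, var_offset, enzymes, primer_len=20):
    """Exhaustive independent search over (enzyme, offset, strand, mismatch)."""
    from bsamap.candgene import IUPAC, _iupac_match, _revcomp, _site_in_seq

    seq_ref = flank
    seq_alt = flank[:var_offset] + alt + flank[var_offset + 1:]

    def ok(enz, s_ref, s_alt):
        return _site_in_seq(enz.site, s_ref) != _site_in_seq(enz.site, s_alt)

    # CAPS
    for enz in sorted(enzymes, key=lambda e: e.name):
        patterns = [enz.site] + ([_revcomp(enz.site)] if _revcomp(enz.site) != enz.site else [])
        for pattern in patterns:
            for off in range(max(0, var_offset - len(pattern) + 1), var_offset + 1):
                if off + len(pattern) > len(flank):
                    continue
                if _iupac_match(pattern, seq_ref[off:off + len(pattern)]) != \
                        _iupac_match(pattern, seq_alt[off:off + len(pattern)]):
                    if ok(enz, seq_ref, seq_alt):
                        return ("CAPS", enz.name)
    # dCAPS
    primer_ok = set(range(max(0, var_offset - primer_len), var_offset)) | \
        set(range(var_offset + 1, min(len(flank), var_offset + 1 + primer_len)))
    for enz in sorted(enzymes, key=lambda e: e.name):
        patterns = [enz.site] + ([_revcomp(enz.site)] if _revcomp(enz.site) != enz.site else [])
        for pattern in patterns:
            for off in range(max(0, var_offset - len(pattern) + 1), var_offset + 1):
                if off + len(pattern) > len(flank):
                    continue
                for allele_seq in (seq_ref, seq_alt):
                    window = allele_seq[off:off + len(pattern)]
                    mism = [i for i, (p, b) in enumerate(zip(pattern, window))
                            if b not in IUPAC[p]]
                    if len(mism) != 1:
                        continue
                    m_abs = off + mism[0]
                    if m_abs == var_offset or m_abs not in primer_ok:
                        continue
                    for base in IUPAC[pattern[mism[0]]]:
                        if base == allele_seq[m_abs]:
                            continue
                        s_r = seq_ref[:m_abs] + base + seq_ref[m_abs + 1:]
                        s_a = seq_alt[:m_abs] + base + seq_alt[m_abs + 1:]
                        if ok(enz, s_r, s_a):
                            return ("dCAPS", enz.name)
                        break
    return None


class TestDcapsDesign:
    def test_caps_when_alt_creates_site(self):
        #                   0123456789...
        flank = "TTTTTTTTTTGAATCCTTTTTTTTTT"
        # C/T SNP at offset 14: alt T makes GAATTC (EcoRI) at offset 10
        lib = [Enzyme("EcoRI", "GAATTC"), Enzyme("HindIII", "AAGCTT")]
        design = design_dcaps(Variant("c", 15, "C", "T"), flank, 14, lib)
        assert design is not None
        assert design.marker_class == "CAPS"
        assert design.enzyme_name == "EcoRI"
        assert design.diagnostic_allele == "alt"

    def test_dcaps_with_single_introduced_mismatch(self):
        # no CAPS possible; a one-base primer change must complete a site
        flank = "ACACACACACACACACACACGCACACACACACACACACACA"
        var_offset = 20  # G/A SNP
        design = design_dcaps(Variant("c", 21, "G", "A"), flank, var_offset)
        if design is not None:
            assert design.marker_class in ("CAPS", "dCAPS")
            assert (design.mismatch_offset is None) == (design.marker_class == "CAPS")

    def test_agrees_with_bruteforce_on_random_flanks(self, rng):
        enzymes = load_enzymes()
        bases = "ACGT"
        for _ in range(60):
            flank = "".join(bases[i] for i in rng.integers(4, size=41))
            ref = flank[20]
            alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4]
            design = design_dcaps(Variant("c", 21, ref, alt), flank, 20, enzymes)
            brute = _bruteforce_dcaps(ref, alt, flank, 20, enzymes)
            if brute is None:
                assert design is None
            else:
                assert design is not None
                assert (design.marker_class, design.enzyme_name) == brute

    def test_self_check_postcondition(self, rng):
        from bsamap.candgene import _site_in_seq
        enzymes = load_enzymes()
        bases = "ACGT"
        for _ in range(40):
            flank = "".join(bases[i] for i in rng.integers(4, size=41))
            ref = flank[20]
            alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4]
            design = design_dcaps(Variant("c", 21, ref, alt), flank, 20, enzymes)
            if design is None:
                continue
            s_ref, s_alt = flank, flank[:20] + alt + flank[21:]
            if design.mismatch_offset is not None:
                m, b = design.mismatch_offset, design.mismatch_base
                s_ref = s_ref[:m] + b + s_ref[m + 1:]
                s_alt = s_alt[:m] + b + s_alt[m + 1:]
            cut_ref = _site_in_seq(design.enzyme_site, s_ref)
            cut_alt = _site_in_seq(design.enzyme_site, s_alt)
            assert cut_ref != cut_alt
            assert design.diagnostic_allele == ("ref" if cut_ref else "alt")

    def test_impossible_site_returns_none(self):
        # GC-only 8-cutter site on an AT-only flank: unreachable with 1 mismatch
        lib = [Enzyme("NotI", "GCGGCCGC")]
        flank = "AT" * 20 + "A"
        assert design_dcaps(Variant("c", 21, "A", "T"), flank, 20, lib) is None


class TestConcordance:
    def test_perfect_cosegregation(self):
        calls = {f"p{i}": ("BB" if i < 5 else "AB") for i in range(20)}
        pheno = {f"p{i}": ("dwarf" if i < 5 else "normal") for i in range(20)}
        frac, disc = genotype_concordance(calls, pheno)
        assert frac == 1.0 and disc == []

    def test_five_discordant_of_100(self):
        calls = {f"a{i:03d}": "BB" for i in range(100)}
        pheno = {f"a{i:03d}": ("normal" if i < 5 else "dwarf") for i in range(100)}
        frac, disc = genotype_concordance(calls, pheno)
        assert frac == pytest.approx(0.95)
        assert disc == [f"a{i:03d}" for i in range(5)]

    def test_empty_panel_errors(self):
        with pytest.raises(ValueError):
            genotype_concordance({}, {})

    def test_id_mismatch_errors(self):
        with pytest.raises(ValueError, match="id mismatch"):
            genotype_concordance({"x": "BB"}, {"y": "dwarf"})


def test_gene_model_invariants_enforced():
    with pytest.raises(ValueError):  # CDS outside exons
        GeneModel("g", "c", "+", exons=[(1, 9)], cds=[(5, 13)])
    with pytest.raises(ValueError):  # CDS not a multiple of 3
        GeneModel("g", "c", "+", exons=[(1, 10)], cds=[(1, 10)])
    with pytest.raises(ValueError):  # overlapping exons
        GeneModel("g", "c", "+", exons=[(1, 9), (5, 13)], cds=[(1, 9)])


def test_fixture_structure(gene_fixture):
    g = gene_fixture.gene
    assert g.n_introns == 9
    assert len(g.exons) == 10
    assert g.cds_length == 3753
    assert g.end - g.start + 1 == 6377
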