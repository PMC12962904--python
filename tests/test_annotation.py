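"""Gene models, SNP effect classification and the candidate table."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from bsascan.annotation import (
    CATEGORIES,
    GeneModel,
    ReferenceMismatchError,
    build_candidate_table,
    classify_variant_location,
    coding_effect,
    load_gene_models,
)
from bsascan.intervals import QTLInterval
from bsascan.stats import site_stats

from conftest import GFF_HEADER, gene_gff3_lines, make_variant, random_sequence


def variant_at(pos, ref, alt, chrom="chrT"):
    return make_variant(chrom=chrom, pos=pos, ref=ref, alt=alt)


class TestLoadGeneModels:
    def test_toy_models_loaded(self, toy_gene_models):
        models, _ = toy_gene_models
        by_id = {g.gene_id: g for g in models}
        assert set(by_id) == {"geneA", "geneB"}
        assert len(by_id["geneA"].exons) == 2
        assert by_id["geneA"].cds_length == 1200

    def test_minus_strand_spans_stored_ascending(self, toy_gene_models):
        models, _ = toy_gene_models
        b = next(g for g in models if g.gene_id == "geneB")
        assert b.strand == "-"
        assert all(s <= e for s, e in b.exons)
        assert list(b.cds) == sorted(b.cds)

    def test_cds_not_multiple_of_three_skipped(self, tmp_path, toy_genome):
        genome, _ = toy_genome
        gff = GFF_HEADER + "\n".join(
            gene_gff3_lines("bad", "chrT", "+", (1000, 2000),
                            exons=[(1000, 2000)], cds=[(1100, 1200)])  # 101 bp
        ) + "\n"
        path = tmp_path / "bad.gff3"
        path.write_text(gff)
        assert load_gene_models(path, genome) == []

    def test_missing_chromosome_is_error(self, tmp_path, toy_genome):
        genome, _ = toy_genome
        gff = GFF_HEADER + "\n".join(
            gene_gff3_lines("g", "chrZ", "+", (100, 400),
                            exons=[(100, 400)], cds=[(100, 399)])
        ) + "\n"
        path = tmp_path / "z.gff3"
        path.write_text(gff)
        with pytest.raises(ValueError, match="chrZ"):
            load_gene_models(path, genome)


class TestClassifyLocation:
    @pytest.mark.parametrize(
        "pos,expected",
        [
            (11_500, "INTRON"),          # between geneA exons
            (10_100, "UTR_5_PRIME"),     # exon before CDS start, + strand
            (12_500, "UTR_3_PRIME"),     # exon after CDS end, + strand
            (9_201, "UPSTREAM"),         # 800 bp 5' of geneA TSS
            (13_500, "DOWNSTREAM"),      # 500 bp 3' of geneA
            (100_000, "INTERGENIC"),     # 10+ kb from any gene
            (51_950, "UTR_5_PRIME"),     # geneB (-): exon above CDS end
            (50_050, "UTR_3_PRIME"),     # geneB (-): exon below CDS start
            (52_500, "UPSTREAM"),        # geneB (-): 500 bp beyond gene end
            (49_600, "DOWNSTREAM"),      # geneB (-): below gene start
        ],
    )
    def test_categories(self, toy_gene_models, pos, expected):
        models, genome = toy_gene_models
        eff = classify_variant_location(variant_at(pos, "A", "G"), models, genome, flank=5000)
        assert eff.category == expected

    def test_every_snp_gets_exactly_one_known_category(self, toy_gene_models):
        models, genome = toy_gene_models
        rng = np.random.default_rng(1)
        for pos in rng.integers(1, 200_000, size=200):
            ref = genome["chrT"][int(pos) - 1].upper()
            alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
            eff = classify_variant_location(
                variant_at(int(pos), ref, alt), models, genome
            )
            assert eff.category in CATEGORIES


def crafted_fixture():
    """Handcrafted genome with known codons on both strands.

    plusG: + strand CDS at 101-109 spelling ATG GCT TAA.
    minusG: - strand CDS at 201-209; genome TTAAGCCAT reverse-complements
    to ATG GCT TAA on the codon strand.
    """
    seq = list(random_sequence(np.random.default_rng(0), 400))
    seq[100:109] = list("ATGGCTTAA")
    seq[200:209] = list("TTAAGCCAT")
    genome = {"chrM": "".join(seq)}
    plus = GeneModel("plusG", "chrM", "+", 101, 109,
                     exons=((101, 109),), cds=((101, 109),))
    minus = GeneModel("minusG", "chrM", "-", 201, 209,
                      exons=((201, 209),), cds=((201, 209),))
    return genome, plus, minus


class TestCodingEffect:
    def test_nonsynonymous_plus_strand(self):
        genome, plus, _ = crafted_fixture()
        eff = coding_effect(variant_at(103, "G", "A", "chrM"), plus, genome)
        assert eff.category == "EXON:NON_SYNONYMOUS_CODING"
        assert eff.aa_change == "M/1/I"  # ATG -> ATA

    def test_synonymous_plus_strand(self):
        genome, plus, _ = crafted_fixture()
        eff = coding_effect(variant_at(106, "T", "C", "chrM"), plus, genome)
        assert eff.category == "EXON:SYNONYMOUS_CODING"
        assert eff.aa_change == "A/2/A"  # GCT -> GCC

    def test_minus_strand_effect_on_reverse_complement(self):
        genome, _, minus = crafted_fixture()
        # genome T->C at 209; codon-strand base A->G turns ATG into GTG
        eff = coding_effect(variant_at(209, "T", "C", "chrM"), minus, genome)
        assert eff.category == "EXON:NON_SYNONYMOUS_CODING"
        assert eff.aa_change == "M/1/V"

    def test_reference_mismatch_names_site(self):
        genome, plus, _ = crafted_fixture()
        with pytest.raises(ReferenceMismatchError, match="103"):
            coding_effect(variant_at(103, "C", "A", "chrM"), plus, genome)

    def test_agrees_with_whole_cds_translation_oracle(self):
        """Codon-level calls match translating the entire mutated CDS."""
        rng = np.random.default_rng(17)
        bases = "ACGT"
        for trial in range(50):
            n_codons = int(rng.integers(4, 40))
            cds_len = 3 * n_codons
            strand = "+" if rng.random() < 0.5 else "-"
            seq = random_sequence(rng, cds_len + 200)
            start = 101
            end = start + cds_len - 1
            gene = GeneModel(f"g{trial}", "chrR", strand, start, end,
                             exons=((start, end),), cds=((start, end),))
            genome = {"chrR": seq}
            pos = int(rng.integers(start, end + 1))
            ref = seq[pos - 1].upper()
            alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4]
            eff = coding_effect(variant_at(pos, ref, alt, "chrR"), gene, genome)

            mutated = seq[: pos - 1] + alt + seq[pos:]
            cds_ref = seq[start - 1 : end]
            cds_alt = mutated[start - 1 : end]
            if strand == "-":
                cds_ref = str(Seq(cds_ref).reverse_complement())
                cds_alt = str(Seq(cds_alt).reverse_complement())
            aa_ref = str(Seq(cds_ref.upper()).translate())
            aa_alt = str(Seq(cds_alt.upper()).translate())
            expected = (
                "EXON:SYNONYMOUS_CODING" if aa_ref == aa_alt
                else "EXON:NON_SYNONYMOUS_CODING"
            )
            assert eff.category == expected
            diffs = [i for i, (a, b) in enumerate(zip(aa_ref, aa_alt)) if a != b]
            if diffs:
                i = diffs[0]
                assert eff.aa_change == f"{aa_ref[i]}/{i + 1}/{aa_alt[i]}"

    def test_strand_mirror_symmetry(self):
        """Reverse-complementing the genome and flipping strands leaves
        every category and amino-acid change unchanged."""
        genome, plus, minus = crafted_fixture()
        L = len(genome["chrM"])
        mirrored_genome = {"chrM": str(Seq(genome["chrM"]).reverse_complement())}

        def mirror_gene(g):
            flip = {"+": "-", "-": "+"}
            spans = lambda ss: tuple(sorted((L + 1 - e, L + 1 - s) for s, e in ss))
            return GeneModel(g.gene_id, g.chrom, flip[g.strand],
                             L + 1 - g.end, L + 1 - g.start,
                             exons=spans(g.exons), cds=spans(g.cds))

        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        cases = [(103, "G", "A", plus), (106, "T", "C", plus), (209, "T", "C", minus)]
        for pos, ref, alt, gene in cases:
            eff = coding_effect(variant_at(pos, ref, alt, "chrM"), gene, genome)
            m_eff = coding_effect(
                variant_at(L + 1 - pos, comp[ref], comp[alt], "chrM"),
                mirror_gene(gene), mirrored_genome,
            )
            assert m_eff.category == eff.category
            assert m_eff.aa_change == eff.aa_change


class TestCandidateTable:
    def _effects_and_stats(self, toy_gene_models, specs):
        models, genome = toy_gene_models
        variants, effects = [], []
        for pos, green, purple in specs:
            ref = genome["chrT"][pos - 1].upper()
            alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
            v = make_variant(chrom="chrT", pos=pos, ref=ref, alt=alt,
                             green=green, purple=purple)
            variants.append(v)
            effects.append(classify_variant_location(v, models, genome))
        return effects, site_stats(variants)

    def test_rows_restricted_sorted_and_tie_broken(self, toy_gene_models):
        specs = [
            (11_500, (0, 40), (40, 0)),    # delta 1.0
            (11_600, (2, 38), (38, 2)),    # delta 0.9
            (12_500, (2, 38), (40, 0)),    # delta 0.95
            (10_100, (4, 36), (36, 4)),    # delta 0.8
            (150_000, (0, 40), (40, 0)),   # outside interval
        ]
        effects, stats = self._effects_and_stats(toy_gene_models, specs)
        interval = QTLInterval("chrT", 9_000, 60_000, "consensus")
        table = build_candidate_table(effects, stats, interval)
        assert len(table) == 4
        assert table["pos"].tolist() == [11_500, 12_500, 11_600, 10_100]
        assert table["type"].iloc[0] == "INTRON"

    def test_equal_delta_broken_by_ed4_magnitude(self, toy_gene_models):
        # identical |delta| from different depths -> identical ed4; use
        # differing deltas at 2 d.p. resolution instead via slight depth change
        specs = [
            (11_500, (0, 40), (40, 0)),   # delta 1.0, ed4 4.0
            (11_600, (0, 20), (19, 1)),   # delta 0.95, ed4 < 4
        ]
        effects, stats = self._effects_and_stats(toy_gene_models, specs)
        table = build_candidate_table(
            effects, stats, QTLInterval("chrT", 9_000, 60_000, "consensus")
        )
        assert table["pos"].tolist() == [11_500, 11_600]
        assert table["ed4"].iloc[0] > table["ed4"].iloc[1]

    def test_empty_effects_give_empty_table(self):
        table = build_candidate_table(
            [], pd.DataFrame(columns=["chrom", "pos", "delta", "ed4"]),
            QTLInterval("chrT", 1, 10, "consensus"),
        )
        assert table.empty
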