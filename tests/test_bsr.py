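"""BLAST-score-ratio values, homolog calls and category summaries."""

import math

import pytest

from genrelate.align import ScoringScheme, bit_score
from genrelate.bsr import (
    GeneNotFoundError,
    GeneRecord,
    HomologySummary,
    bsr,
    homology_matrix,
    percent_homologous,
    reference_scores,
)
from genrelate.seqs import GenomeSequence
from genrelate.simulate import (
    GeneFamilySimSpec,
    generate_ancestor,
    simulate_gene_families,
)


@pytest.fixture(scope="module")
def family():
    spec = GeneFamilySimSpec(
        n_genes_per_category={"exoenzyme": 8, "toxin": 6, "NRPS": 4, "PKS": 4},
        retention_prob_by_degree={1: 1.0, 2: 0.8, 3: 0.5, 4: 0.2, 5: 0.0},
        divergence_by_degree={1: 0.02, 2: 0.10, 3: 0.15, 4: 0.15, 5: 0.15},
        seed=42,
    )
    return simulate_gene_families(
        spec, {d: [f"g{d}"] for d in range(1, 6)}
    )


@pytest.fixture(scope="module")
def ref_scores(family):
    return reference_scores(family.genes, family.reference)


class TestReferenceScores:
    def test_verbatim_gene_scores_full_length_self_hsp(self, family,
                                                       ref_scores):
        scheme = ScoringScheme()
        for gene in family.genes[:5]:
            # self raw score of an exact match = match_reward * length
            expected = bit_score(
                scheme.match_reward * len(gene.sequence), scheme
            )
            assert ref_scores[gene.gene_id] == pytest.approx(expected)

    def test_identical_paralogs_get_equal_bits(self):
        seq = generate_ancestor(800, 0.5, seed=3, id="x").sequence
        spacer = generate_ancestor(300, 0.5, seed=4, id="sp").sequence
        genome = GenomeSequence.from_string(
            "para", spacer + seq + spacer + seq + spacer
        )
        genes = [
            GeneRecord("p1", "toxin", seq),
            GeneRecord("p2", "toxin", seq),
        ]
        scores = reference_scores(genes, genome)
        assert scores["p1"] == scores["p2"]

    def test_absent_gene_raises(self, family):
        alien = GeneRecord(
            "alien", "toxin",
            generate_ancestor(900, 0.5, seed=5, id="al").sequence,
        )
        with pytest.raises(GeneNotFoundError):
            reference_scores([alien], family.reference)


class TestBsrValues:
    def test_source_genome_ratio_is_one(self, family, ref_scores):
        gene = family.genes[0]
        val = bsr(gene, family.reference, ref_scores[gene.gene_id])
        assert val.ratio == 1.0
        assert val.homolog

    def test_no_hsp_gives_zero_and_not_homolog(self, ref_scores, family):
        gene = family.genes[0]
        target = GenomeSequence.from_string("empty", "A" * 2000)
        val = bsr(gene, target, ref_scores[gene.gene_id])
        assert val.ratio == 0.0
        assert not val.homolog

    def test_diverged_gene_between_threshold_and_one(self, family,
                                                     ref_scores):
        # degree-2 genome carries homologs at 10% divergence
        present = family.truth.query("genome_id == 'g2' and present")
        genome = family.genomes["g2"]
        hits = 0
        for gene_id in present["gene_id"]:
            gene = next(g for g in family.genes if g.gene_id == gene_id)
            val = bsr(gene, genome, ref_scores[gene_id])
            assert 0.4 < val.ratio < 1.0
            hits += 1
        assert hits > 0

    def test_reference_bits_must_be_positive(self, family):
        with pytest.raises(ValueError):
            bsr(family.genes[0], family.reference, 0.0)


@pytest.fixture(scope="module")
def matrix(family, ref_scores):
    genomes = [family.reference, *family.genomes.values()]
    return homology_matrix(family.genes, genomes, reference=ref_scores)


class TestHomologyMatrix:
    def test_source_column_all_one(self, matrix):
        assert (matrix["reference"] == 1.0).all()

    def test_zero_retention_column_all_zero(self, matrix):
        assert (matrix["g5"] == 0.0).all()

    def test_entries_match_recomputed_bsr(self, matrix, family, ref_scores):
        for gene in family.genes[::7]:
            for gid, genome in list(family.genomes.items())[:2]:
                val = bsr(gene, genome, ref_scores[gene.gene_id])
                assert matrix.loc[gene.gene_id, gid] == val.ratio

    def test_contig_duplication_does_not_change_ratios(self, family,
                                                       ref_scores):
        genome = family.genomes["g2"]
        doubled = GenomeSequence(
            id="g2x2",
            contigs={"c1": genome.sequence, "c2": genome.sequence},
        )
        for gene in family.genes[:4]:
            r1 = bsr(gene, genome, ref_scores[gene.gene_id]).ratio
            r2 = bsr(gene, doubled, ref_scores[gene.gene_id]).ratio
            assert r1 == r2

    def test_truth_table_agreement_at_low_divergence(self, matrix, family):
        calls = matrix > 0.4
        sub = family.truth.query("degree <= 4")  # divergence <= 15% here
        agree = sum(
            bool(calls.loc[r.gene_id, r.genome_id]) == r.present
            for r in sub.itertuples()
        )
        assert agree / len(sub) >= 0.95


class TestPercentHomologous:
    def test_arithmetic_16_of_20(self):
        s = HomologySummary("g", "toxin", n_genes=20, n_homologs=16)
        assert s.percent == 80

    def test_rounding_half_up(self):
        assert HomologySummary("g", "PKS", 8, 1).percent == 13  # 12.5 -> 13
        assert HomologySummary("g", "PKS", 3, 2).percent == 67

    def test_all_ratio_one_gives_100(self, family, ref_scores):
        mat = homology_matrix(
            family.genes, [family.reference], reference=ref_scores
        )
        for s in percent_homologous(mat, family.categories):
            assert s.percent == 100

    def test_permutation_invariance_in_gene_order(self, family, ref_scores):
        genomes = [family.genomes["g2"]]
        mat = homology_matrix(family.genes, genomes, reference=ref_scores)
        fwd = {
            (s.genome_id, s.category): s.percent
            for s in percent_homologous(mat, family.categories)
        }
        rev = {
            (s.genome_id, s.category): s.percent
            for s in percent_homologous(mat.iloc[::-1], family.categories)
        }
        assert fwd == rev

    def test_uncategorized_gene_rejected(self, family, ref_scores):
        mat = homology_matrix(
            family.genes, [family.reference], reference=ref_scores
        )
        with pytest.raises(ValueError, match="uncategorized"):
            percent_homologous(mat, {})

    def test_binomial_band_for_retention(self, family):
        """Retained counts track the retention probability: degree 3 with
        p = 0.5 over 22 genes stays within 3 binomial SD."""
        n = len(family.genes)
        kept = int(family.truth.query("genome_id == 'g3'")["present"].sum())
        sd = math.sqrt(n * 0.5 * 0.5)
        assert abs(kept - 0.5 * n) <= 3 * sd
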