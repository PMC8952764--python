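"""Determinism, calibration bands and invariants of the data generator."""

import hashlib
import math

import numpy as np
import pytest

from genrelate.simulate import (
    EvolutionParams,
    GeneFamilySimSpec,
    MortalitySimSpec,
    evolve_genome,
    generate_ancestor,
    simulate_gene_families,
    simulate_mortality,
)


class TestGenerateAncestor:
    def test_length_alphabet_and_gc_band(self):
        g = generate_ancestor(1000, 0.517, seed=1)
        seq = g.sequence
        assert len(seq) == 1000
        assert set(seq) <= set("ACGT")
        gc = (seq.count("G") + seq.count("C")) / 1000
        band = 2.576 * math.sqrt(0.517 * 0.483 / 1000)  # 99% binomial band
        assert abs(gc - 0.517) <= band

    def test_degenerate_length_one(self):
        g = generate_ancestor(1, 0.5, seed=0)
        assert len(g.sequence) == 1 and g.sequence in "ACGT"

    def test_seed_determinism(self):
        assert (
            generate_ancestor(500, 0.4, seed=7).sequence
            == generate_ancestor(500, 0.4, seed=7).sequence
        )

    @pytest.mark.parametrize("length,gc", [(0, 0.5), (10, 0.0), (10, 1.0)])
    def test_invalid_arguments(self, length, gc):
        with pytest.raises(ValueError):
            generate_ancestor(length, gc, seed=0)


class TestEvolveGenome:
    def test_identity_case(self):
        anc = generate_ancestor(2000, 0.5, seed=2)
        ev, d = evolve_genome(anc, EvolutionParams(seed=3))
        assert ev.sequence == anc.sequence
        assert d == 0.0

    def test_realized_divergence_binomial_band(self):
        anc = generate_ancestor(100_000, 0.5, seed=4)
        ev, d = evolve_genome(
            anc, EvolutionParams(substitution_rate=0.05, seed=5)
        )
        sd = math.sqrt(100_000 * 0.05 * 0.95) / 100_000
        assert abs(d - 0.05) <= 3 * sd

    def test_substitutions_never_write_the_original_base(self):
        anc = generate_ancestor(5000, 0.5, seed=6)
        ev, d = evolve_genome(
            anc, EvolutionParams(substitution_rate=0.2, seed=7)
        )
        diffs = sum(a != b for a, b in zip(anc.sequence, ev.sequence))
        assert diffs == round(d * 5000)

    def test_rearrangement_conserves_residue_multiset(self):
        anc = generate_ancestor(10_000, 0.5, seed=8)
        ev, _ = evolve_genome(
            anc,
            EvolutionParams(substitution_rate=0.02, rearrangement_count=1,
                            seed=9),
        )
        sub_only, _ = evolve_genome(
            anc, EvolutionParams(substitution_rate=0.02, seed=9)
        )
        assert sorted(ev.sequence) == sorted(sub_only.sequence)

    def test_indels_change_length(self):
        anc = generate_ancestor(10_000, 0.5, seed=10)
        ev, _ = evolve_genome(
            anc, EvolutionParams(indel_rate=5.0, seed=11)
        )
        assert len(ev.sequence) != len(anc.sequence)

    def test_same_seed_same_output(self):
        anc = generate_ancestor(3000, 0.5, seed=12)
        p = EvolutionParams(substitution_rate=0.1, indel_rate=2.0,
                            rearrangement_count=2, seed=13)
        e1, d1 = evolve_genome(anc, p)
        e2, d2 = evolve_genome(anc, p)
        assert e1.sequence == e2.sequence and d1 == d2

    def test_empty_ancestor_rejected(self):
        from genrelate.seqs import GenomeSequence

        with pytest.raises(ValueError):
            evolve_genome(GenomeSequence(id="e"), EvolutionParams())


class TestGeneFamilies:
    def spec(self, **kw):
        base = dict(
            n_genes_per_category={"exoenzyme": 10, "toxin": 5, "NRPS": 3,
                                  "PKS": 2},
            retention_prob_by_degree={1: 1.0, 2: 0.8, 5: 0.0},
            divergence_by_degree={1: 0.0, 2: 0.1, 5: 0.2},
            seed=21,
        )
        base.update(kw)
        return GeneFamilySimSpec(**base)

    def test_certain_retention_all_present(self):
        fam = simulate_gene_families(self.spec(), {1: ["g1"]})
        assert fam.truth["present"].all()
        assert fam.genomes["g1"].length > 0

    def test_zero_retention_no_homologs(self):
        fam = simulate_gene_families(self.spec(), {5: ["g5"]})
        assert not fam.truth["present"].any()

    def test_retained_count_binomial_band(self):
        fam = simulate_gene_families(self.spec(), {2: ["g2"]})
        kept = int(fam.truth["present"].sum())
        sd = math.sqrt(20 * 0.8 * 0.2)
        assert abs(kept - 16) <= 3 * sd

    def test_retention_must_be_non_increasing(self):
        with pytest.raises(ValueError, match="non-increasing"):
            self.spec(retention_prob_by_degree={1: 0.5, 2: 0.9})

    def test_empty_category_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            self.spec(n_genes_per_category={})

    def test_written_files_hash_equal_across_runs(self, tmp_path):
        for sub in ("a", "b"):
            fam = simulate_gene_families(self.spec(), {1: ["g1"], 2: ["g2"]})
            fam.write(tmp_path / sub)
        for name in ("genes.fasta", "categories.tsv", "truth.tsv",
                     "reference.fasta", "g1.fasta", "g2.fasta"):
            h = [
                hashlib.sha256((tmp_path / sub / name).read_bytes())
                .hexdigest()
                for sub in ("a", "b")
            ]
            assert h[0] == h[1]


class TestMortality:
    def test_zero_probability_all_alive(self):
        spec = MortalitySimSpec(
            doses=(0.0,), true_mortality_by_dose={0.0: 0.0}, seed=1
        )
        assert (simulate_mortality(spec)["dead"] == 0).all()

    def test_certain_death(self):
        spec = MortalitySimSpec(
            doses=(1.0,), true_mortality_by_dose={1.0: 1.0}, seed=1
        )
        df = simulate_mortality(spec)
        assert (df["dead"] == df["n_larvae"]).all()

    def test_pooled_mortality_within_3sd_of_truth(self):
        spec = MortalitySimSpec(
            doses=(7.0,), true_mortality_by_dose={7.0: 0.79},
            n_larvae_per_replicate=10, n_replicates=12, seed=5,
        )
        df = simulate_mortality(spec)
        pooled = df["dead"].sum() / df["n_larvae"].sum()
        sd = math.sqrt(0.79 * 0.21 / 120)
        assert abs(pooled - 0.79) <= 3 * sd

    def test_default_design_shape(self):
        df = simulate_mortality(MortalitySimSpec(seed=2))
        assert len(df) == 6 * 12
        assert set(df["experiment"]) == {1, 2, 3, 4}
        assert set(df["replicate"]) == {1, 2, 3}

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            MortalitySimSpec(
                doses=(1.0,), true_mortality_by_dose={1.0: 1.5}
            )

    def test_seed_determinism(self):
        a = simulate_mortality(MortalitySimSpec(seed=9))
        b = simulate_mortality(MortalitySimSpec(seed=9))
        assert a.equals(b)


class TestDownstreamMonotonicity:
    def test_anib_non_increasing_in_substitution_rate(self):
        """Median ANIb over 5 seeds is non-increasing across rising rates."""
        from statistics import median

        from genrelate.anib import anib

        medians = []
        for rate in (0.01, 0.05, 0.10, 0.20):
            vals = []
            for seed in range(5):
                anc = generate_ancestor(10_000, 0.5, seed=100 + seed,
                                        id=f"anc{seed}")
                ev, _ = evolve_genome(
                    anc, EvolutionParams(substitution_rate=rate,
                                         seed=200 + seed)
                )
                vals.append(anib(ev, anc).anib_percent)
            medians.append(median(vals))
        assert all(a >= b for a, b in zip(medians, medians[1:]))
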