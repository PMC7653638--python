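"""Synthetic family-exome generator: determinism, Mendelian structure, noise."""
import numpy as np
import pytest

from digenicscan import (
    classify_deleterious,
    de_novo_scan,
    evaluate_recovery,
    quartet_pedigree,
)
from digenicscan.digenic import CandidatePair
from digenicscan.records import ConfigError
from digenicscan.simulate import (
    SimConfig,
    SimTruth,
    sample_af_spectrum,
    simulate_cohort,
    simulate_founders,
    transmit,
    write_cohort,
)

AFFECTED = frozenset({"proband", "sibling"})


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = SimConfig(n_background=80, seed=42, genotype_error_rate=0.02)
        a = write_cohort(simulate_cohort(cfg), tmp_path / "a")
        b = write_cohort(simulate_cohort(cfg), tmp_path / "b")
        for key in a:
            assert a[key].read_bytes() == b[key].read_bytes(), key

    def test_different_seeds_differ(self, tmp_path):
        a = write_cohort(simulate_cohort(SimConfig(n_background=80, seed=1)), tmp_path / "a")
        b = write_cohort(simulate_cohort(SimConfig(n_background=80, seed=2)), tmp_path / "b")
        assert a["vcf"].read_bytes() != b["vcf"].read_bytes()


class TestFounders:
    def test_af_zero_all_homref(self):
        cfg = SimConfig(n_background=50, af_min=0.0, af_max=0.0, seed=1)
        _, founder_gts, afs = simulate_founders(cfg)
        assert all((g == 0).all() for g in founder_gts.values())
        assert (afs == 0).all()

    def test_af_one_all_homalt(self):
        cfg = SimConfig(n_background=50, af_min=1.0, af_max=1.0, seed=1)
        _, founder_gts, _ = simulate_founders(cfg)
        assert all((g == 2).all() for g in founder_gts.values())

    def test_record_count_and_spectrum_window(self):
        cfg = SimConfig(n_background=300, seed=4)
        records, _, afs = simulate_founders(cfg)
        assert len(records) == 300
        assert ((afs >= cfg.af_min) & (afs <= cfg.af_max)).all()
        assert len({r.variant_id for r in records}) == 300

    def test_spectrum_is_rare_skewed(self):
        cfg = SimConfig(seed=0)
        afs = sample_af_spectrum(cfg, np.random.default_rng(0), 20000)
        assert np.median(afs) < 0.01  # most variants below the rarity cutoff


class TestTransmit:
    def test_het_by_homref_child_het_half_the_time(self):
        ped = quartet_pedigree(children=("c",), children_affected=(True,))
        n = 10000
        founder = {
            "father": np.ones(n, dtype=np.int8),
            "mother": np.zeros(n, dtype=np.int8),
        }
        records, _, _ = simulate_founders(SimConfig(n_background=n, seed=8))
        table = transmit(ped, founder, records, np.random.default_rng(8))
        frac = (table.sample_column("c") == 1).mean()
        se = 0.5 / np.sqrt(n)
        assert abs(frac - 0.5) < 3 * se

    def test_homalt_parents_always_transmit(self):
        ped = quartet_pedigree(children=("c",), children_affected=(True,))
        founder = {
            "father": np.full(100, 2, dtype=np.int8),
            "mother": np.full(100, 2, dtype=np.int8),
        }
        records, _, _ = simulate_founders(SimConfig(n_background=100, seed=8))
        table = transmit(ped, founder, records, np.random.default_rng(0))
        assert (table.sample_column("c") == 2).all()


class TestPlanting:
    def test_planted_configuration(self):
        cohort = simulate_cohort(SimConfig(n_background=100, seed=3))
        truth = cohort.truth
        gts = cohort.genotypes
        assert truth.maternal_gene != truth.paternal_gene
        assert gts.code(truth.maternal_variant, "mother") == 1
        assert gts.code(truth.maternal_variant, "father") == 0
        assert gts.code(truth.paternal_variant, "father") == 1
        assert gts.code(truth.paternal_variant, "mother") == 0
        for child in ("proband", "sibling"):
            assert gts.code(truth.maternal_variant, child) == 1
            assert gts.code(truth.paternal_variant, child) == 1
        # planted genes belong to the designated pathway set
        pathway = cohort.genesets.sets[cohort.config.pathway_name]
        assert {truth.maternal_gene, truth.paternal_gene} <= pathway

    def test_planted_afs_pass_rarity(self):
        from digenicscan import rarity_pass

        cohort = simulate_cohort(SimConfig(n_background=50, seed=12))
        for vid in (cohort.truth.maternal_variant, cohort.truth.paternal_variant):
            assert cohort.profiles[vid].af_global <= 0.002
            assert rarity_pass(cohort.profiles[vid], max_af=0.01)

    def test_no_affected_children_is_an_error(self):
        ped = quartet_pedigree(children_affected=(False, False))
        with pytest.raises(ConfigError):
            simulate_cohort(SimConfig(n_background=10, seed=1, pedigree=ped))

    def test_unaffected_child_carries_at_most_one(self):
        ped = quartet_pedigree(
            children=("proband", "sibling", "healthy"),
            children_affected=(True, True, False),
        )
        for seed in range(10):
            cohort = simulate_cohort(SimConfig(n_background=5, seed=seed, pedigree=ped))
            carried = sum(
                cohort.genotypes.code(v, "healthy") >= 1
                for v in (cohort.truth.maternal_variant, cohort.truth.paternal_variant)
            )
            assert carried <= 1


class TestAnnotation:
    def test_degenerate_rates_are_noise_free(self):
        cfg = SimConfig(
            n_background=60,
            seed=6,
            p_predictor_sensitivity=1.0,
            p_predictor_false_damaging=0.0,
            p_missing_call=0.0,
        )
        cohort = simulate_cohort(cfg)
        causal = {cohort.truth.maternal_variant, cohort.truth.paternal_variant}
        for vid, profile in cohort.profiles.items():
            call = classify_deleterious(profile)
            assert call.n_informative == 7
            assert call.n_damaging == (7 if vid in causal else 0)

    def test_all_missing_blocks_every_verdict(self):
        cfg = SimConfig(n_background=40, seed=6, p_missing_call=1.0)
        cohort = simulate_cohort(cfg)
        for profile in cohort.profiles.values():
            call = classify_deleterious(profile)
            assert call.insufficient_evidence and not call.verdict


class TestMendelianConsistency:
    def test_clean_simulation_has_no_de_novo(self):
        cfg = SimConfig(n_background=2000, seed=17, plant_pair=False)
        cohort = simulate_cohort(cfg)
        assert de_novo_scan(cohort.records, cohort.genotypes, cohort.pedigree) == []

    def test_injected_violations_are_exactly_recovered(self):
        cfg = SimConfig(n_background=500, seed=19, n_transmission_violations=4)
        cohort = simulate_cohort(cfg)
        found = {
            r.variant_id
            for r in de_novo_scan(cohort.records, cohort.genotypes, cohort.pedigree)
        }
        assert found == set(cohort.truth.transmission_violations)
        assert len(found) == 4


class TestRecovery:
    def _pair(self, ga, gb, va="va", vb="vb"):
        return CandidatePair(va, vb, ga, gb, AFFECTED)

    def test_sole_candidate(self):
        truth = SimTruth("va", "vb", "A", "B")
        assert evaluate_recovery(truth, [self._pair("A", "B")]) == (1, 1.0, 1)

    def test_among_four(self):
        truth = SimTruth("va", "vb", "A", "B")
        pairs = [self._pair("A", "B")] + [
            self._pair(f"X{i}", f"Y{i}", f"v{i}", f"w{i}") for i in range(3)
        ]
        recall, precision, n = evaluate_recovery(truth, pairs)
        assert (recall, n) == (1, 4) and precision == pytest.approx(0.25)

    def test_absent(self):
        truth = SimTruth("va", "vb", "A", "B")
        assert evaluate_recovery(truth, [self._pair("C", "D")]) == (0, 0.0, 1)

    def test_gene_order_irrelevant(self):
        truth = SimTruth("va", "vb", "A", "B")
        recall, _, _ = evaluate_recovery(truth, [self._pair("B", "A")])
        assert recall == 1
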