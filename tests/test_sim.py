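"""Generator checks: founder draws, gene dropping, disease implanting,
missingness, panels and ortholog sets, each against an independent
statistical or constructional oracle."""

import numpy as np
import pytest

from pedmap.model import HET, MISSING, Individual, Pedigree, PedmapError
from pedmap.sim import (
    SimulationConfig,
    apply_missingness,
    drop_genes,
    generate_ortholog_set,
    implant_recessive_disease,
    simulate_founder_haplotypes,
    simulate_marker_map,
    simulate_panel,
    simulate_study_family,
)

from conftest import make_map


def nuclear_pedigree(n_kids: int = 2) -> Pedigree:
    inds = [Individual("F", sex="male"), Individual("M", sex="female")]
    inds += [Individual(f"K{i}", sire="F", dam="M") for i in range(n_kids)]
    return Pedigree(inds)


class TestFounderHaplotypes:
    def test_degenerate_frequency_fixes_allele(self):
        mm = make_map(50)
        with pytest.raises(PedmapError):
            simulate_founder_haplotypes(mm, 1.0, 4, seed=0)  # must be open interval
        haps = simulate_founder_haplotypes(mm, 1.0 - 1e-12, 4, seed=0)
        assert (haps == 0).all()  # allele1 everywhere

    def test_mean_frequency_within_binomial_error(self):
        mm = make_map(1000)
        haps = simulate_founder_haplotypes(mm, 0.5, 4, seed=7)
        n_draws = 4 * 2 * 1000
        frac_allele1 = (haps == 0).mean()
        sd = np.sqrt(0.25 / n_draws)
        assert abs(frac_allele1 - 0.5) < 3 * sd

    def test_same_seed_identical(self):
        mm = make_map(100)
        a = simulate_founder_haplotypes(mm, 0.3, 3, seed=42)
        b = simulate_founder_haplotypes(mm, 0.3, 3, seed=42)
        np.testing.assert_array_equal(a, b)


class TestGeneDropping:
    def test_no_recombination_transmits_whole_haplotypes(self):
        mm = make_map(200)
        ped = nuclear_pedigree(1)
        haps = {f: simulate_founder_haplotypes(mm, 0.5, 2, seed=i)[0] for i, f in
                enumerate(["F", "M"])}
        res = drop_genes(ped, haps, mm, recomb_rate_cm_per_mb=0.0, seed=3)
        for strand in res.truth["K0"].origins:
            assert len(set(strand.tolist())) == 1  # one unrecombined origin

    def test_mendelian_consistency_many_replicates(self):
        """Offspring genotypes are consistent with parental genotypes at
        every marker across replicates (descent-based oracle)."""
        mm = make_map(200)
        ped = nuclear_pedigree(3)
        for rep in range(50):
            haps = {f: simulate_founder_haplotypes(mm, 0.4, 2, seed=100 + rep + i)[0]
                    for i, f in enumerate(["F", "M"])}
            res = drop_genes(ped, haps, mm, recomb_rate_cm_per_mb=1.0, seed=rep)
            gm = res.genotypes
            f, m = gm.row("F"), gm.row("M")
            for kid in ("K0", "K1", "K2"):
                k = gm.row(kid)
                # a child allele-2 dosage never exceeds what parents can give
                pat_min = (f == 2).astype(int)
                pat_max = 1 - (f == 0).astype(int)
                mat_min = (m == 2).astype(int)
                mat_max = 1 - (m == 0).astype(int)
                assert (k >= pat_min + mat_min).all()
                assert (k <= pat_max + mat_max).all()

    def test_sib_ibd2_fraction_near_quarter(self):
        """Full sibs share both parental origins at ~25% of markers."""
        mm = make_map(3000, spacing=500_000)  # 1.5 Gb: many independent segments
        ped = nuclear_pedigree(2)
        haps = {f: simulate_founder_haplotypes(mm, 0.5, 2, seed=i)[0]
                for i, f in enumerate(["F", "M"])}
        res = drop_genes(ped, haps, mm, recomb_rate_cm_per_mb=1.0, seed=11)
        o0, o1 = res.truth["K0"].origins, res.truth["K1"].origins
        ibd2 = ((o0[0] == o1[0]) & (o0[1] == o1[1])).mean()
        assert 0.15 < ibd2 < 0.35

    def test_missing_founder_haplotypes_rejected(self):
        mm = make_map(10)
        ped = nuclear_pedigree(1)
        with pytest.raises(PedmapError, match="no assigned haplotypes"):
            drop_genes(ped, {"F": simulate_founder_haplotypes(mm, 0.5, 2, 0)[0]}, mm)


class TestDiseaseImplant:
    def _drop(self, seed, n_kids=4):
        mm = make_map(50)
        ped = nuclear_pedigree(n_kids)
        haps = {f: simulate_founder_haplotypes(mm, 0.5, 2, seed=i)[0]
                for i, f in enumerate(["F", "M"])}
        return mm, drop_genes(ped, haps, mm, seed=seed)

    def test_no_carrier_founders_no_affected(self):
        mm, res = self._drop(0)
        phen = implant_recessive_disease(res, "C2", 1_200_000, [])
        assert all(v == "unaffected" for v in phen.values())

    def test_both_parents_carriers_quarter_affected(self):
        """Across many litters the affected fraction follows Mendelian 1/4."""
        affected = total = 0
        for rep in range(300):
            mm, res = self._drop(rep)
            phen = implant_recessive_disease(res, "C2", 1_200_000, ["F", "M"])
            kids = [k for k in phen if k.startswith("K")]
            affected += sum(phen[k] == "affected" for k in kids)
            total += len(kids)
        sd = np.sqrt(0.25 * 0.75 / total)
        assert abs(affected / total - 0.25) < 4 * sd

    def test_single_carrier_parent_no_affected_offspring(self):
        for rep in range(20):
            mm, res = self._drop(rep)
            phen = implant_recessive_disease(res, "C2", 1_200_000, ["M"])
            assert all(phen[k] == "unaffected" for k in phen if k.startswith("K"))

    def test_affected_always_hom_by_descent(self):
        for rep in range(50):
            mm, res = self._drop(rep)
            phen = implant_recessive_disease(res, "C2", 1_200_000, ["F", "M"])
            for iid, status in phen.items():
                assert (status == "affected") == (res.truth[iid].carrier_status == "hom_mut")


class TestMissingness:
    def test_rate_zero_unchanged(self):
        _mm, res = TestDiseaseImplant()._drop(5)
        gm = res.genotypes
        out = apply_missingness(gm, 0.0, seed=1)
        np.testing.assert_array_equal(out.calls, gm.calls)

    def test_call_rate_above_95_with_default_rate(self):
        """rate=0.04 over many markers keeps call rates > 95% in the large
        majority of replicates (binomial oracle: P(rate<=0.95) ~ 0)."""
        mm = make_map(10_000)
        calls = np.zeros((7, 10_000), dtype=np.int8)
        from pedmap.model import GenotypeMatrix
        gm = GenotypeMatrix([f"i{k}" for k in range(7)], mm, calls)
        ok = 0
        for rep in range(20):
            out = apply_missingness(gm, 0.04, seed=rep)
            ok += int((out.call_rates() > 0.95).all())
        assert ok >= 19

    def test_missing_count_matches_expectation(self):
        mm = make_map(2000)
        from pedmap.model import GenotypeMatrix
        gm = GenotypeMatrix(["x"], mm, np.zeros((1, 2000), dtype=np.int8))
        counts = [
            int((apply_missingness(gm, 0.1, seed=rep).calls == MISSING).sum())
            for rep in range(100)
        ]
        expected = 0.1 * 2000
        sd = np.sqrt(2000 * 0.1 * 0.9 / 100)
        assert abs(np.mean(counts) - expected) < 4 * sd


class TestPanel:
    def test_zero_fraction_all_hom_ref(self):
        t = simulate_panel(211, 0.0, seed=0)
        assert t.counts() == {"hom_ref": 211, "het": 0, "hom_alt": 0, "missing": 0}

    def test_full_fraction_all_het(self):
        t = simulate_panel(50, 1.0, seed=0)
        assert t.counts()["het"] == 50

    def test_observed_fraction_within_3sd(self):
        t = simulate_panel(10_000, 0.037, seed=123)
        frac = t.counts()["het"] / 10_000
        sd = np.sqrt(0.037 * 0.963 / 10_000)
        assert abs(frac - 0.037) < 3 * sd

    def test_never_hom_alt(self):
        for rep in range(10):
            t = simulate_panel(500, 0.5, seed=rep)
            assert t.counts()["hom_alt"] == 0


class TestOrthologSet:
    def test_zero_divergence_identical(self):
        seqs = generate_ortholog_set(100, 5, [10, 20], 0.0, seed=0)
        assert len(set(seqs.values())) == 1

    def test_conserved_positions_never_mutated(self):
        seqs = generate_ortholog_set(200, 6, list(range(10, 110, 10)), 0.5, seed=1)
        for seq in seqs.values():
            for p in range(10, 110, 10):
                assert seq[p - 1] == "C"

    def test_exclusive_mode_pins_exactly_the_conserved_set(self):
        positions = [375, 381, 397, 400, 405, 412, 420, 430, 440, 451]
        seqs = generate_ortholog_set(455, 8, positions, 0.13, seed=2)
        arr = np.array([list(s) for s in seqs.values()])
        all_cys = np.flatnonzero((arr == "C").all(axis=0)) + 1
        assert sorted(all_cys.tolist()) == positions

    def test_divergence_rate_recovered(self):
        seqs = generate_ortholog_set(5000, 2, [1], 0.13, seed=3)
        ref, other = seqs.values()
        diff = sum(a != b for a, b in zip(ref, other)) / 4999
        sd = np.sqrt(0.13 * 0.87 / 4999)
        assert abs(diff - 0.13) < 3 * sd


class TestStudyFamily:
    def test_phenotype_pattern_and_obligate_carriers(self):
        fam = simulate_study_family(SimulationConfig(n_markers=2000, seed=9))
        status = {i: fam.truth[i].carrier_status for i in fam.truth}
        assert status["KID1"] == status["KID2"] == "hom_mut"
        assert status["SIRE"] == status["PGM"] == status["DAM"] == "carrier"
        assert status["KID3"] != "hom_mut"
        assert fam.pedigree["KID1"].phenotype == "affected"

    def test_determinism_under_fixed_seed(self):
        a = simulate_study_family(SimulationConfig(n_markers=1500, seed=4))
        b = simulate_study_family(SimulationConfig(n_markers=1500, seed=4))
        np.testing.assert_array_equal(a.genotypes.calls, b.genotypes.calls)
        assert a.genotypes.marker_map.table.equals(b.genotypes.marker_map.table)

    def test_config_guards(self):
        with pytest.raises(PedmapError, match="call-rate"):
            SimulationConfig(missing_rate=0.2)
        with pytest.raises(PedmapError, match="outside its chromosome"):
            SimulationConfig(causal_bp=10**10)


def test_marker_map_simulation_counts_and_order():
    cfg = SimulationConfig(n_markers=5000, seed=0)
    mm = simulate_marker_map(cfg, np.random.default_rng(0))
    assert len(mm) == 5000
    assert set(mm.chromosomes) == set(cfg.chromosome_lengths_mb)
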