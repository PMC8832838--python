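"""Generator-level checks: pedigree shape, inheritance rules, phenotype
moments and crossover counting against the simulator's own truth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xgrr import simdata
from xgrr.simdata import (
    QTL,
    GenotypeInconsistencyError,
    SimulationError,
    TruthConfig,
    count_crossovers,
    default_marker_map,
    drop_genomes,
    simulate_pedigree,
    simulate_phenotypes,
)


class TestSimulatePedigree:
    def test_founder_count_and_validity(self):
        ped = simulate_pedigree(2, 1, 3, 2, seed=0)
        founders = ped.table[ped.table["sire"] == "0"]
        assert len(founders) == 2
        assert set(ped.table["sex"]) == {"M", "F"}

    def test_same_seed_reproduces(self):
        a = simulate_pedigree(30, 3, 5, 2.0, seed=7)
        b = simulate_pedigree(30, 3, 5, 2.0, seed=7)
        pd.testing.assert_frame_equal(a.table, b.table)
        c = simulate_pedigree(30, 3, 5, 2.0, seed=8)
        assert not a.table.equals(c.table)

    def test_mean_offspring_per_sire(self):
        ped = simulate_pedigree(50, 5, 20.0, 2.4, seed=3)
        counts = ped.table[ped.table["sire"] != "0"].groupby("sire").size()
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - 20.0) <= 3 * se + 1.0  # +1 for rounding of cohorts

    def test_single_sex_founders_rejected(self):
        with pytest.raises(SimulationError):
            simulate_pedigree(1, 1)
        with pytest.raises(SimulationError):
            simulate_pedigree(3, 0)


class TestDropGenomes:
    def test_x_inheritance_rules(self, nuclear_family):
        mm = default_marker_map(n_x=60, n_par=10)
        panel = drop_genomes(nuclear_family, mm, 0.5, seed=5)
        xmask = mm.region_mask("X-specific")
        sire_x = panel.haps[panel.index_of("sire"), 0, xmask]
        for dau in ("dau1", "dau2"):
            # daughters: paternal X-specific haplotype equals the sire's
            pat = panel.haps[panel.index_of(dau), 1, xmask]
            assert np.array_equal(pat, sire_x)
        for son in ("son1", "son2"):
            # sons: no X-specific material from the sire (copy 1 masked)
            assert (
                panel.haps[panel.index_of(son), 1, xmask]
                == simdata.HaplotypePanel.INVALID
            ).all()

    def test_par_is_diploid_for_males(self, nuclear_family):
        mm = default_marker_map(n_x=20, n_par=10)
        panel = drop_genomes(nuclear_family, mm, 0.5, seed=6)
        par = mm.region_mask("PAR")
        son = panel.haps[panel.index_of("son1")][:, par]
        assert (son != simdata.HaplotypePanel.INVALID).all()

    def test_female_map_crossover_rate(self):
        # one dam, 5000 gametes on a 100 cM female map
        rows = [("s", "0", "0", "M"), ("d", "0", "0", "F")]
        rows += [(f"k{i}", "s", "d", "F") for i in range(5000)]
        ped = simdata.Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam", "sex"]))
        mm = default_marker_map(n_x=100, n_par=5, female_cm_x=95.0, female_cm_par=5.0)
        panel = drop_genomes(ped, mm, 0.5, seed=9)
        counts = [panel.origins[("d", f"k{i}")]["n_co"] for i in range(5000)]
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 1.0) <= 3 * se

    def test_founder_frequency_preserved(self):
        ped = simulate_pedigree(120, 4, 8, 2.2, seed=10)
        mm = default_marker_map(n_x=40, n_par=4)
        panel = drop_genomes(ped, mm, 0.3, seed=11, track_origins=False)
        freqs = panel.allele_frequencies()
        assert abs(freqs.mean() - 0.3) < 0.05

    def test_seed_reproducibility(self, nuclear_family):
        mm = default_marker_map(n_x=30, n_par=5)
        a = drop_genomes(nuclear_family, mm, 0.4, seed=1)
        b = drop_genomes(nuclear_family, mm, 0.4, seed=1)
        assert np.array_equal(a.haps, b.haps)

    def test_bad_frequencies_rejected(self, nuclear_family):
        mm = default_marker_map(n_x=10, n_par=2)
        with pytest.raises(SimulationError):
            drop_genomes(nuclear_family, mm, 1.0, seed=1)


class TestPhenotypes:
    def _records(self, ped, truth, n=1, panel=None):
        gametes = [(p, f"o{p}_{i}") for p in ped.ids for i in range(n)]
        return simulate_phenotypes(ped, panel, gametes, truth)

    def test_degenerate_generator(self, nuclear_family):
        truth = TruthConfig(
            mu=25.4, var_a=0, var_s=0, var_i=0, var_p=0, var_e=0, beta=(0, 0, 0, 0)
        )
        rec = self._records(nuclear_family, truth)
        assert (rec["co_count"] == 25.0).all()

    def test_residual_variance_with_and_without_rounding(self):
        rows = [(f"p{i}", "0", "0", "M") for i in range(10000)]
        ped = simdata.Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam", "sex"]))
        base = dict(mu=25, var_a=0, var_s=0, var_i=0, var_p=0, var_e=1.0, beta=(0, 0, 0, 0))
        rec = self._records(ped, TruthConfig(round_counts=False, seed=3, **base))
        v = rec["co_count"].var()
        se = np.sqrt(2.0 / len(rec)) * v
        assert abs(v - 1.0) <= 3 * se
        rec_r = self._records(ped, TruthConfig(round_counts=True, seed=3, **base))
        vr = rec_r["co_count"].var()
        assert abs(vr - (1.0 + 1.0 / 12.0)) <= 3 * se + 0.02

    def test_male_qtl_variance_is_pqa2(self):
        # a reported large-effect variant: frequency 0.241, effect +0.78 CO
        p_f, a = 0.241, 0.78
        n = 10000
        rows = [(f"p{i}", "0", "0", "M") for i in range(n)]
        ped = simdata.Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam", "sex"]))
        mm = simdata.default_marker_map(n_x=2, n_par=2)
        panel = drop_genomes(ped, mm, founder_freqs=p_f, seed=4, track_origins=False)
        truth = TruthConfig(
            mu=25, var_a=0, var_s=0, var_i=0, var_p=0, var_e=0,
            beta=(0, 0, 0, 0), round_counts=False,
            qtls=(QTL(mm.ids[0], a, "male"),),
        )
        rec = self._records(ped, truth, panel=panel)
        target = p_f * (1 - p_f) * a * a
        # variance of a scaled Bernoulli: 3-SE band from its fourth moment
        q = 1 - p_f
        m4 = (a**4) * p_f * q * (q**3 + p_f**3)
        se_var = np.sqrt((m4 - target**2) / n)
        assert abs(rec["co_count"].var() - target) <= 3 * se_var

    def test_negative_variance_rejected(self):
        with pytest.raises(SimulationError):
            TruthConfig(var_a=-1)

    def test_reproducible_records(self, nuclear_family):
        truth = TruthConfig(seed=11)
        a = self._records(nuclear_family, truth, n=3)
        b = self._records(nuclear_family, truth, n=3)
        pd.testing.assert_frame_equal(a, b)


class TestCountCrossovers:
    def test_single_switch(self):
        assert count_crossovers([0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 1, 0]) == 1

    def test_identical_to_parent_hap(self):
        assert count_crossovers([0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 0, 1]) == 0

    def test_inconsistent_gamete_raises(self):
        with pytest.raises(GenotypeInconsistencyError):
            count_crossovers([0, 0, 1], [0, 1, 1], [1, 0, 1])

    def test_matches_generator_truth_on_informative_parent(self, rng):
        # fully heterozygous parent: every switch is observable
        m = 60
        h0 = np.zeros(m, dtype=np.uint8)
        h1 = np.ones(m, dtype=np.uint8)
        sw = np.full(m - 1, 0.02)
        for _ in range(500):
            gam, origin, nco = simdata._meiosis(h0, h1, sw, rng)
            assert count_crossovers(h0, h1, gam) == nco

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_counts_bounded_by_informative_switches(self, seed):
        r = np.random.default_rng(seed)
        m = 30
        h0 = r.integers(0, 2, m).astype(np.uint8)
        h1 = r.integers(0, 2, m).astype(np.uint8)
        gam, origin, nco = simdata._meiosis(h0, h1, np.full(m - 1, 0.1), r)
        # unobservable switches at uninformative markers can only hide COs
        assert count_crossovers(h0, h1, gam) <= nco
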