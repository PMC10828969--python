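"""Synthetic-registry generator: determinism, parameter validation, and
convergence of empirical moments to the model they encode."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from sibace.bvn import orthant_upper
from sibace.descriptives import individual_prevalence
from sibace.pedigree import select_study_pairs, sibling_clusters
from sibace.simulate import (
    SimulationParams,
    simulate_pair_level,
    simulate_pair_phenotypes,
    simulate_registry,
    simulate_study_tables,
)


def mc_se(p, n):
    return np.sqrt(p * (1 - p) / n)


class TestSimulationParams:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(a2=-0.1),
            dict(a2=0.8, c2=0.3),
            dict(n_clusters=0),
            dict(baseline_prevalence=0.6),
            dict(baseline_prevalence=None),
            dict(baseline_prevalence=0.1, baseline_threshold=1.0),
            dict(paternal_half_fraction=1.5),
            dict(cluster_type_mix={"full_2": -1.0}),
            dict(birth_year_range=(2000, 1990)),
        ],
    )
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            SimulationParams(**kw)

    def test_threshold_from_prevalence(self):
        p = SimulationParams(baseline_prevalence=0.0017)
        assert p.threshold0 == pytest.approx(norm.isf(0.0017))
        assert p.e2 == pytest.approx(1 - p.a2 - p.c2)


class TestSimulateRegistry:
    def test_deterministic_given_seed(self, tmp_path):
        params = SimulationParams(n_clusters=300, seed=123)
        r1 = simulate_registry(params)
        r2 = simulate_registry(params)
        pd.testing.assert_frame_equal(r1, r2)
        from sibace.io import write_registry

        f1, f2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_registry(r1, f1)
        write_registry(r2, f2)
        assert f1.read_bytes() == f2.read_bytes()

    def test_no_twins_and_schema(self):
        reg = simulate_registry(SimulationParams(n_clusters=200, seed=0))
        assert (reg["is_twin"] == 0).all()
        assert reg["person_id"].is_unique
        assert (reg["mother_id"] != reg["father_id"]).all()
        lo, hi = 1950, 2010
        assert reg["birth_year"].between(lo, hi).all()
        assert set(reg["affected"].unique()) <= {0, 1}
        # parent ids never collide with person ids
        assert not set(reg["person_id"]) & (set(reg["mother_id"]) | set(reg["father_id"]))

    def test_median_threshold_gives_half_prevalence(self):
        params = SimulationParams(
            n_clusters=20000, a2=0.0, c2=0.0, birth_year_slope=0.0,
            baseline_prevalence=0.4999, seed=17,
        )
        reg = simulate_registry(params)
        n = len(reg)
        assert abs(reg["affected"].mean() - 0.5) < 3 * mc_se(0.5, n)

    def test_pure_additive_liability_correlations(self):
        """With a2=1 the liability correlation is 0.5 for full sibs and 0.25
        for half sibs, by Mendelian construction."""
        params = SimulationParams(
            n_clusters=40000, a2=1.0, c2=0.0, seed=21,
            cluster_type_mix={"full_2": 0.5, "mixed": 0.5},
        )
        reg = simulate_registry(params)
        clusters = sibling_clusters(reg)
        pairs = select_study_pairs(clusters, reg, seed=1)
        liab = reg.set_index("person_id")["liability"]
        by_rel = {}
        for rel in ("full", "paternal_half", "maternal_half"):
            sel = [p for p in pairs if p.relationship == rel]
            x = liab.loc[[p.index_id for p in sel]].to_numpy()
            y = liab.loc[[p.sibling_id for p in sel]].to_numpy()
            by_rel[rel] = (np.corrcoef(x, y)[0, 1], len(sel))
        r_full, n_full = by_rel["full"]
        assert abs(r_full - 0.5) < 3.0 / np.sqrt(n_full)
        for rel in ("paternal_half", "maternal_half"):
            r, n = by_rel[rel]
            assert abs(r - 0.25) < 3.0 / np.sqrt(n)

    def test_birth_year_slice_prevalence_tracks_threshold(self):
        params = SimulationParams(
            n_clusters=60000, a2=0.3, c2=0.1, baseline_prevalence=0.2,
            birth_year_slope=0.02, seed=33,
        )
        reg = simulate_registry(params)
        t0 = params.threshold0
        for lo, hi in [(1950, 1960), (1975, 1985), (2000, 2010)]:
            sl = reg[reg["birth_year"].between(lo, hi - 1)]
            mid_t = t0 + params.birth_year_slope * (sl["birth_year"] - 1980)
            expected = norm.sf(mid_t).mean()
            assert abs(sl["affected"].mean() - expected) < 3 * mc_se(expected, len(sl))


class TestSimulatePairPhenotypes:
    def test_independence_at_median_cut(self):
        n = 200000
        t = simulate_pair_phenotypes(0.0, (0.0, 0.0), n, seed=5)
        se = mc_se(0.25, n) * n
        assert abs(t.n11 - n / 4) < 3 * se
        assert abs(t.n10 - n / 2) < 3 * mc_se(0.5, n) * n

    def test_near_comonotone_discordance_vanishes(self):
        """As rho -> 1 with equal cutoffs the discordant fraction matches the
        (vanishing) orthant-based expectation."""
        n, rho = 50000, 0.999999
        t = simulate_pair_phenotypes(rho, (1.0, 1.0), n, seed=6)
        p10 = 2 * (norm.sf(1.0) - orthant_upper(1.0, 1.0, rho))
        assert p10 < 1e-3
        assert abs(t.n10 / n - p10) < 3 * mc_se(p10, n)

    def test_rare_trait_cell_fraction_matches_orthant(self):
        """n11/n converges to the upper orthant probability (rare trait)."""
        rho, q = 0.18, 0.0017
        thr = norm.isf(q)
        p11 = orthant_upper(thr, thr, rho)
        n = 10**7
        t = simulate_pair_phenotypes(rho, (thr, thr), n, seed=44)
        assert abs(t.n11 / n - p11) < 3 * mc_se(p11, n)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_pair_phenotypes(1.0, (0, 0), 10, seed=0)
        with pytest.raises(ValueError):
            simulate_pair_phenotypes(0.2, (0, 0), 0, seed=0)


def test_study_tables_structure_and_prevalence():
    sizes = {"full": 300000, "maternal_half": 40000, "paternal_half": 60000}
    tabs = simulate_study_tables(0.29, 0.0, 0.0017, sizes, seed=9)
    assert {t.relationship for t in tabs.values()} == set(sizes)
    for rel, tab in tabs.items():
        assert tab.total == sizes[rel]
        prev = individual_prevalence(tab)
        assert abs(prev - 0.0017) < 3 * mc_se(0.0017, 2 * sizes[rel])


def test_pair_level_year_effect():
    df = simulate_pair_level(0.2, norm.isf(0.1), -0.015, 150000, seed=3,
                             year_gap_sd=2.0)
    early = df[df["birth_year_1"] < 1970]["affected_1"].mean()
    late = df[df["birth_year_1"] >= 1990]["affected_1"].mean()
    assert late > early  # negative slope on the cutoff raises prevalence
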