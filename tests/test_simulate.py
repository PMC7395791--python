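"""Two-population simulator: divergence, LD structure, effects, phenotypes."""

import numpy as np
import pandas as pd
import pytest

from pgsra import simulate
from pgsra.genodata import allele_frequencies, hudson_fst_from_stats, _ld_profile
from pgsra.simulate import (
    SimulationConfig,
    sample_causal_effects,
    simulate_phenotype,
    simulate_two_populations,
)

TINY = SimulationConfig(
    n_variants=400,
    n_blocks=8,
    target_fst=0.10,
    n_discovery=300,
    n_targets={"pop1": 100, "pop2": 300},
    m_causal=30,
    seed=11,
)


def _fst(panels):
    return hudson_fst_from_stats(
        allele_frequencies(panels["pop1"]), allele_frequencies(panels["pop2"])
    )


class TestGenotypeSimulation:
    def test_seed_determinism(self):
        a = simulate_two_populations(TINY)
        b = simulate_two_populations(TINY)
        for pop in a:
            np.testing.assert_array_equal(a[pop].genotypes, b[pop].genotypes)
            pd.testing.assert_frame_equal(a[pop].variants, b[pop].variants)

    def test_zero_fst_gives_near_zero_divergence(self):
        cfg = SimulationConfig(
            n_variants=800,
            n_blocks=10,
            target_fst=0.0,
            n_discovery=800,
            n_targets={"pop1": 200, "pop2": 1000},
            m_causal=30,
            ld_scale_kb={"pop1": 100.0, "pop2": 100.0},
            seed=5,
        )
        vals = [_fst(simulate_two_populations(cfg.with_seed(s))) for s in range(5)]
        vals = np.array(vals)
        assert abs(vals.mean()) < 3 * vals.std(ddof=1) / np.sqrt(len(vals))

    def test_target_fst_realized_within_20pct(self):
        cfg = SimulationConfig(
            n_variants=2_000,
            n_blocks=20,
            target_fst=0.10,
            n_discovery=3_000,
            n_targets={"pop1": 1_000, "pop2": 4_000},
            m_causal=50,
        )
        realized = [
            _fst(simulate_two_populations(cfg.with_seed(s))) for s in range(1, 11)
        ]
        assert all(0.08 <= f <= 0.12 for f in realized), realized

    def test_maf_floor_enforced_in_both_populations(self):
        panels = simulate_two_populations(TINY)
        for pop in panels:
            p = allele_frequencies(panels[pop])["p"].to_numpy()
            assert (np.minimum(p, 1 - p) >= TINY.maf_floor).all()

    def test_ld_decays_with_distance(self):
        cfg = SimulationConfig(
            n_variants=1_000,
            n_blocks=10,
            target_fst=0.10,
            n_discovery=600,
            n_targets={"pop1": 100, "pop2": 700},
            m_causal=30,
            seed=7,
        )
        panels = simulate_two_populations(cfg)
        for pop, panel in panels.items():
            near, far = _mean_r2_near_far(panel, cfg)
            assert near > far, (pop, near, far)

    def test_ld_differs_between_populations(self):
        panels = simulate_two_populations(TINY)
        r1 = _adjacent_r(panels["pop1"])
        r2 = _adjacent_r(panels["pop2"])
        assert np.mean((r1 - r2) ** 2) > 0

    def test_positions_do_not_feed_back_into_genotypes(self):
        import dataclasses

        wide = dataclasses.replace(TINY, block_gap_kb=TINY.block_gap_kb * 3)
        a = simulate_two_populations(TINY)
        b = simulate_two_populations(wide)
        for pop in a:
            np.testing.assert_array_equal(a[pop].genotypes, b[pop].genotypes)
            assert not a[pop].variants["bp"].equals(b[pop].variants["bp"])

    def test_unattainable_fst_raises(self):
        with pytest.raises(ValueError):
            SimulationConfig(target_fst=1.5)


def _block_pairs(panel, max_gap_bp, min_gap_bp=0):
    bp = panel.variants["bp"].to_numpy()
    pairs = []
    for i in range(panel.n_variants - 1):
        for j in range(i + 1, panel.n_variants):
            gap = bp[j] - bp[i]
            if gap > max_gap_bp:
                break
            if gap >= min_gap_bp:
                pairs.append((i, j))
    return pairs


def _mean_r2_near_far(panel, cfg):
    span = cfg.block_span_kb * 1000
    near_pairs = _block_pairs(panel, max_gap_bp=span / 20)
    far_pairs = _block_pairs(panel, max_gap_bp=span, min_gap_bp=span / 2)
    rng = np.random.default_rng(0)

    def mean_r2(pairs):
        take = rng.choice(len(pairs), size=min(len(pairs), 300), replace=False)
        vals = []
        for k in take:
            i, j = pairs[k]
            r = _ld_profile(panel, i, np.array([j]))[0]
            if not np.isnan(r):
                vals.append(r * r)
        return float(np.mean(vals))

    return mean_r2(near_pairs), mean_r2(far_pairs)


def _adjacent_r(panel):
    vals = []
    for i in range(0, panel.n_variants - 1, 7):
        r = _ld_profile(panel, i, np.array([i + 1]))[0]
        vals.append(0.0 if np.isnan(r) else r)
    return np.array(vals)


class TestCausalEffects:
    @staticmethod
    def _freqs(rng, n):
        p = rng.uniform(0.05, 0.5, size=n)
        return pd.DataFrame(
            {"variant_id": [f"v{i}" for i in range(n)], "p": p, "n_obs": 1000}
        )

    def test_perfect_correlation_is_deterministic_rescaling(self, rng):
        cfg = SimulationConfig(
            n_variants=500, m_causal=200, rho_b=1.0, seed=2,
            h2={"pop1": 0.5, "pop2": 0.3},
        )
        f1, f2 = self._freqs(rng, 300), self._freqs(rng, 300)
        eff = sample_causal_effects(f1, f2, cfg)
        het1 = 2 * eff.p["pop1"] * (1 - eff.p["pop1"])
        het2 = 2 * eff.p["pop2"] * (1 - eff.p["pop2"])
        # S = -1: beta * sqrt(het) is the standardized effect; with rho_b = 1
        # the two populations agree after the deterministic h2 rescaling
        z1 = eff.beta["pop1"] * np.sqrt(het1) / np.sqrt(0.5)
        z2 = eff.beta["pop2"] * np.sqrt(het2) / np.sqrt(0.3)
        np.testing.assert_allclose(z1, z2, rtol=1e-12)
        # raw effects differ only by per-variant MAF rescaling, so their
        # correlation stays near (but not exactly at) 1
        assert np.corrcoef(eff.beta["pop1"], eff.beta["pop2"])[0, 1] > 0.9

    def test_s_minus_one_gives_constant_explained_variance(self, rng):
        cfg = SimulationConfig(n_variants=500, m_causal=150, seed=3)
        f1, f2 = self._freqs(rng, 300), self._freqs(rng, 300)
        eff = sample_causal_effects(f1, f2, cfg)
        het = 2 * eff.p["pop1"] * (1 - eff.p["pop1"])
        z2 = het * eff.beta["pop1"] ** 2
        # standardized squared effects are h2/M_C * chi2(1): independent of MAF
        assert abs(np.corrcoef(z2, het)[0, 1]) < 0.2
        assert z2.mean() == pytest.approx(0.5 / 150, rel=0.35)

    def test_cross_population_correlation_matches_rho(self, rng):
        cfg = SimulationConfig(
            n_variants=20_001, m_causal=10_000, rho_b=0.8, seed=4
        )
        f1, f2 = self._freqs(rng, 12_000), self._freqs(rng, 12_000)
        eff = sample_causal_effects(f1, f2, cfg)
        het1 = 2 * eff.p["pop1"] * (1 - eff.p["pop1"])
        het2 = 2 * eff.p["pop2"] * (1 - eff.p["pop2"])
        corr = np.corrcoef(
            eff.beta["pop1"] * np.sqrt(het1), eff.beta["pop2"] * np.sqrt(het2)
        )[0, 1]
        assert corr == pytest.approx(0.8, abs=3 / np.sqrt(10_000))

    def test_selection_exponent_shapes_variance(self, rng):
        cfg = SimulationConfig(
            n_variants=20_001, m_causal=10_000, seed=5,
            S={"pop1": -0.5, "pop2": -1.0},
        )
        f1, f2 = self._freqs(rng, 12_000), self._freqs(rng, 12_000)
        eff = sample_causal_effects(f1, f2, cfg)
        het = 2 * eff.p["pop1"] * (1 - eff.p["pop1"])
        # S = -0.5: explained variance rises with het, so corr > 0
        z2 = het * eff.beta["pop1"] ** 2
        lo = z2[het < np.median(het)].mean()
        hi = z2[het >= np.median(het)].mean()
        assert hi > lo
        # expected total explained variance still h2
        assert z2.sum() == pytest.approx(0.5, rel=0.1)

    def test_too_few_eligible_variants_raises(self, rng):
        cfg = SimulationConfig(n_variants=500, m_causal=200, seed=1)
        f = self._freqs(rng, 100)
        with pytest.raises(ValueError, match="eligible"):
            sample_causal_effects(f, f, cfg)


@pytest.fixture(scope="module")
def panel_and_effects():
    cfg = SimulationConfig(
        n_variants=500,
        n_blocks=10,
        target_fst=0.05,
        n_discovery=9_000,
        n_targets={"pop1": 1_000, "pop2": 500},
        m_causal=50,
        seed=9,
    )
    panels = simulate_two_populations(cfg)
    eff = sample_causal_effects(
        allele_frequencies(panels["pop1"]),
        allele_frequencies(panels["pop2"]),
        cfg,
    )
    return panels["pop1"], eff


class TestPhenotype:
    def test_h2_one_returns_genetic_value(self, panel_and_effects):
        panel, eff = panel_and_effects
        ph = simulate_phenotype(panel, eff, h2=1.0, seed=1)
        np.testing.assert_array_equal(ph.y, ph.g)

    def test_variance_partition(self, panel_and_effects):
        panel, eff = panel_and_effects
        ratios = [
            np.var(ph.g) / np.var(ph.y)
            for ph in (
                simulate_phenotype(panel, eff, h2=0.5, seed=s) for s in range(10)
            )
        ]
        assert 0.45 < np.mean(ratios) < 0.55

    def test_invalid_h2_rejected(self, panel_and_effects):
        panel, eff = panel_and_effects
        with pytest.raises(ValueError):
            simulate_phenotype(panel, eff, h2=0.0, seed=1)

    def test_missing_causal_raises(self, panel_and_effects):
        panel, eff = panel_and_effects
        bad = simulate.EffectTable(
            variant_ids=np.array(["absent"]),
            beta={"pop1": np.array([0.1])},
            p={"pop1": np.array([0.2])},
        )
        with pytest.raises(KeyError, match="absent"):
            simulate_phenotype(panel, bad, h2=0.5, seed=1)
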