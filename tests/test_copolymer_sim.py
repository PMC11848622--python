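"""Unit and property tests for the chain-composition simulator."""

import numpy as np
import pytest
from scipy import stats

from excipol.copolymer_sim import (
    ChainComposition,
    ChainLengthModel,
    MonomerSpec,
    ReactivityRatios,
    SimConfig,
    grow_chain,
    read_ensemble_csv,
    sample_chain_lengths,
    simulate_ensemble,
    write_ensemble_csv,
)

from conftest import make_moni_config


def mayo_lewis_f1(f1: float, r1: float, r2: float) -> float:
    """Closed-form instantaneous incorporated fraction of monomer 1."""
    f2 = 1.0 - f1
    return (r1 * f1**2 + f1 * f2) / (r1 * f1**2 + 2 * f1 * f2 + r2 * f2**2)


class TestSampleChainLengths:
    def test_fixed_family_is_degenerate(self):
        model = ChainLengthModel(mean_dp=100, dispersity=1.0, family="fixed")
        assert sample_chain_lengths(model, 5, seed=0).tolist() == [100] * 5

    def test_schulz_zimm_realized_dispersity(self):
        # Gamma-moment oracle: z = 1/(D-1) = 5 gives Mw/Mn -> 1.20 as n grows
        model = ChainLengthModel(mean_dp=157, dispersity=1.20)
        lengths = sample_chain_lengths(model, 50_000, seed=7).astype(float)
        mn = lengths.mean()
        mw = (lengths**2).sum() / lengths.sum()
        assert 1.17 <= mw / mn <= 1.23

    def test_schulz_zimm_sample_mean(self):
        model = ChainLengthModel(mean_dp=63, dispersity=1.11)
        lengths = sample_chain_lengths(model, 50_000, seed=11)
        assert 61.7 <= lengths.mean() <= 64.3

    def test_mean_within_two_percent_at_1e4(self):
        model = ChainLengthModel(mean_dp=94, dispersity=1.14)
        lengths = sample_chain_lengths(model, 10_000, seed=3)
        assert abs(lengths.mean() - 94) / 94 < 0.02

    def test_floor_one(self):
        model = ChainLengthModel(mean_dp=2, dispersity=2.5)
        lengths = sample_chain_lengths(model, 20_000, seed=5)
        assert lengths.min() >= 1

    def test_invalid_dispersity_rejected(self):
        with pytest.raises(ValueError):
            ChainLengthModel(mean_dp=100, dispersity=0.9)

    def test_unit_dispersity_degenerates(self):
        model = ChainLengthModel(mean_dp=63.4, dispersity=1.0)
        assert set(sample_chain_lengths(model, 100, seed=0).tolist()) == {63}


class TestGrowChain:
    def test_single_monomer_feed(self, rng):
        chain = grow_chain(10, (1.0, 0.0), ReactivityRatios(5.0, 0.1), rng)
        assert chain.counts == (10, 0)

    def test_mayo_lewis_closed_form(self, rng):
        chain = grow_chain(10**6, (0.5, 0.5), ReactivityRatios(2.0, 0.5), rng)
        f1_inc = chain.counts[0] / chain.length
        assert abs(f1_inc - 2 / 3) / (2 / 3) < 0.005

    def test_ideal_random_reduces_to_bernoulli(self, rng):
        chain = grow_chain(10**6, (0.77, 0.23), ReactivityRatios(), rng)
        assert abs(chain.counts[0] / chain.length - 0.77) / 0.77 < 0.005

    def test_counts_sum_to_length(self, rng):
        chain = grow_chain(137, (0.3, 0.7), ReactivityRatios(1.4, 0.6), rng)
        assert sum(chain.counts) == chain.length == 137

    def test_all_zero_feed_errors(self, rng):
        with pytest.raises(ValueError):
            grow_chain(10, (0.0, 0.0), ReactivityRatios(), rng)

    @pytest.mark.parametrize("r1", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("r2", [0.5, 1.0, 2.0])
    def test_mayo_lewis_grid(self, r1, r2):
        # closed-form agreement within Monte-Carlo error at moderate length
        rng = np.random.default_rng(42)
        f1 = 0.6
        chain = grow_chain(200_000, (f1, 1 - f1), ReactivityRatios(r1, r2), rng)
        expected = mayo_lewis_f1(f1, r1, r2)
        assert abs(chain.counts[0] / chain.length - expected) < 0.005


class TestChainComposition:
    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            ChainComposition((0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ChainComposition((-1, 5))


class TestSimulateEnsemble:
    def test_symmetry(self):
        config = make_moni_config(
            100, 1.0, n_chains=10_000, feed=(0.5, 0.5), family="fixed"
        )
        _, summary = simulate_ensemble(config)
        assert abs(summary.mean_fractions[0] - 0.5) < 0.005
        assert abs(summary.mean_fractions[1] - 0.5) < 0.005

    def test_seed_determinism(self):
        config = make_moni_config(63, 1.11, n_chains=2_000, seed=99)
        chains_a, summary_a = simulate_ensemble(config)
        chains_b, summary_b = simulate_ensemble(config)
        assert chains_a == chains_b
        assert summary_a == summary_b

    def test_different_seeds_differ(self):
        a, _ = simulate_ensemble(make_moni_config(63, 1.11, n_chains=500, seed=1))
        b, _ = simulate_ensemble(make_moni_config(63, 1.11, n_chains=500, seed=2))
        assert a != b

    def test_summary_invariants(self):
        _, summary = simulate_ensemble(make_moni_config(94, 1.14, n_chains=5_000))
        assert summary.mw_dp >= summary.mn_dp
        assert abs(sum(summary.mean_fractions) - 1.0) < 1e-12

    def test_vectorized_matches_grow_chain_law(self):
        # non-ideal ratios: ensemble mean composition matches single-chain law
        ratios = ReactivityRatios(2.0, 0.5)
        config = make_moni_config(
            200, 1.0, n_chains=5_000, feed=(0.5, 0.5), ratios=ratios, family="fixed"
        )
        _, summary = simulate_ensemble(config)
        assert abs(summary.mean_fractions[0] - mayo_lewis_f1(0.5, 2.0, 0.5)) < 0.01

    def test_binomial_chi_square_at_fixed_length(self):
        # ideal-random: counts | length ~ Binomial(length, f1)
        n, length, f1 = 10_000, 50, 0.77
        config = make_moni_config(length, 1.0, n_chains=n, family="fixed", seed=8)
        chains, _ = simulate_ensemble(config)
        counts = np.array([c.counts[0] for c in chains])
        ks = np.arange(length + 1)
        pmf = stats.binom.pmf(ks, length, f1)
        # bin tails so expected counts stay >= 5
        expected = pmf * n
        lo = np.argmax(np.cumsum(expected) >= 5)
        hi = length - np.argmax(np.cumsum(expected[::-1]) >= 5)
        edges = np.concatenate(([-0.5], np.arange(lo, hi) + 0.5, [length + 0.5]))
        observed, _ = np.histogram(counts, bins=edges)
        probs = np.concatenate(
            ([pmf[: lo + 1].sum()], pmf[lo + 1 : hi], [pmf[hi:].sum()])
        )
        chi2, p = stats.chisquare(observed, probs / probs.sum() * n)
        assert p > 0.01


class TestFinitePool:
    def test_pool_conservation_exact(self):
        config = make_moni_config(
            50,
            1.1,
            n_chains=300,
            ratios=ReactivityRatios(2.0, 0.5),
            feed=(0.5, 0.5),
            pool_mode="finite_pool",
            seed=4,
        )
        chains, summary = simulate_ensemble(config)
        total_units = config.n_chains * config.length_model.mean_dp / config.target_conversion
        initial = np.array(
            [round(total_units * f) for f in config.feed], dtype=np.int64
        )
        consumed = np.array(
            [sum(c.counts[0] for c in chains), sum(c.counts[1] for c in chains)]
        )
        assert summary.residual_pool is not None
        assert (consumed + np.array(summary.residual_pool) == initial).all()

    def test_finite_pool_deterministic(self):
        config = make_moni_config(
            30, 1.2, n_chains=100, pool_mode="finite_pool", seed=12,
            ratios=ReactivityRatios(1.5, 0.7), feed=(0.6, 0.4),
        )
        assert simulate_ensemble(config) == simulate_ensemble(config)

    def test_conversion_limits_growth(self):
        config = make_moni_config(
            40, 1.0, n_chains=200, pool_mode="finite_pool", family="fixed", seed=2
        )
        chains, _ = simulate_ensemble(config)
        total_units = 200 * 40 / 0.98
        consumed = sum(c.length for c in chains)
        assert consumed <= int(total_units * 0.98)


class TestConfigValidation:
    def test_feed_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(
                monomers=(
                    MonomerSpec("A", 100.0, 0.6),
                    MonomerSpec("B", 100.0, 0.6),
                ),
                ratios=ReactivityRatios(),
                length_model=ChainLengthModel(50, 1.1),
                n_chains=10,
            )

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            ReactivityRatios(-0.5, 1.0)

    def test_bad_pool_mode(self):
        with pytest.raises(ValueError, match="pool_mode"):
            make_moni_config(50, 1.1, pool_mode="bogus")


def test_ensemble_csv_round_trip(tmp_path):
    config = make_moni_config(30, 1.1, n_chains=50, seed=3)
    chains, _ = simulate_ensemble(config)
    path = tmp_path / "ensemble.csv"
    write_ensemble_csv(path, chains, config)
    header = path.read_text().splitlines()[0]
    assert header == "chain_id,count_Morph,count_Nipam,length"
    assert read_ensemble_csv(path) == chains
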