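import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import truncnorm

from flowdedup.flow_model import (
    LookupTableError,
    default_parametric_model,
    export_lookup_table,
    load_lookup_model,
    posterior_h,
    prob_equal,
)

# Independent oracle: the posterior computed directly from its definition
# with scipy's truncated normal, sharing nothing with the implementation.

_DEFAULTS = dict(
    degradation_rate=0.002, base_sigma=0.11, sigma_slope=0.02,
    zero_sigma=0.10, prior_decay=0.25, h_max=11,
)


def oracle_posterior(f, cycle, **params):
    p = {**_DEFAULTS, **params}
    weights = []
    for h in range(p["h_max"] + 1):
        base = p["zero_sigma"] if h == 0 else p["base_sigma"] + p["sigma_slope"] * h
        sd = base * (1.0 + p["degradation_rate"] * cycle)
        density = truncnorm.pdf(f, a=(0.0 - h) / sd, b=np.inf, loc=h, scale=sd)
        weights.append(density * p["prior_decay"] ** h)
    weights = np.array(weights)
    return weights / weights.sum()


def oracle_prob_equal(f_a, f_b, cycle):
    if f_a > 5.5 or f_b > 5.5 or (f_a > 2.5 and f_b > 2.5):
        return 1.0
    pa = oracle_posterior(f_a, cycle)
    pb = oracle_posterior(f_b, cycle)
    return float(sum(pa[h] * pb[h] for h in range(6)))


class TestPosterior:
    def test_matches_bruteforce_oracle(self, model):
        for f in [0.0, 0.02, 0.37, 1.0, 1.85, 2.5, 4.2, 5.5]:
            for cycle in [1, 10, 100]:
                np.testing.assert_allclose(
                    posterior_h(model, f, cycle),
                    oracle_posterior(f, cycle),
                    atol=1e-10,
                )

    def test_normalizes_on_dense_grid(self, model):
        grid = np.arange(0, 601) / 100.0
        for cycle in [1, 5, 25, 50, 100, 200]:
            sums = model.posterior_matrix(grid, cycle).sum(axis=1)
            np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_argmax_tracks_rounding(self, model):
        # away from the .5 decision boundaries (the decreasing prior
        # shifts the exact crossover by a few hundredths)
        for f in np.round(np.arange(0.2, 5.31, 0.1), 2):
            if abs(f - np.floor(f) - 0.5) < 0.06:
                continue
            argmax = int(np.argmax(posterior_h(model, f, 1)))
            assert argmax == int(np.floor(f + 0.5)), f

    def test_near_zero_mass_at_zero(self, model):
        assert posterior_h(model, 0.02, 1)[0] > 0.99

    def test_one_gives_argmax_one(self, model):
        assert int(np.argmax(posterior_h(model, 1.0, 1))) == 1

    def test_negative_flow_rejected(self, model):
        with pytest.raises(ValueError):
            posterior_h(model, -0.1, 1)

    def test_degradation_zero_is_cycle_independent(self):
        flat = default_parametric_model(degradation_rate=0.0)
        f = np.array([0.3, 1.2, 2.7])
        np.testing.assert_allclose(
            flat.posterior_matrix(f, 1), flat.posterior_matrix(f, 150)
        )

    def test_prior_normalized(self, model):
        assert np.isclose(model.prior.sum(), 1.0)

    def test_likelihood_integrates_to_one(self, model):
        grid = np.arange(0.0, 20.0, 0.001)
        densities = np.exp(model.log_likelihood(grid, 1))
        masses = np.trapezoid(densities, grid, axis=0)
        np.testing.assert_allclose(masses, 1.0, atol=1e-3)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            default_parametric_model(base_sigma=0.0)
        with pytest.raises(ValueError):
            default_parametric_model(sigma_slope=-0.1)


class TestProbEqual:
    def test_cap_single_high(self, model):
        assert prob_equal(model, 6.2, 0.1) == 1.0

    def test_cap_both_high(self, model):
        assert prob_equal(model, 2.6, 2.7) == 1.0

    def test_caps_on_grid(self, model):
        grid = np.round(np.arange(0.0, 8.01, 0.1), 2)
        for f_a in grid:
            for f_b in grid:
                if f_a > 5.5 or f_b > 5.5 or (f_a > 2.5 and f_b > 2.5):
                    assert prob_equal(model, f_a, f_b) == 1.0

    def test_mixed_case_uses_sum(self, model):
        # one value in (2.5, 5.5], other <= 2.5: the caps do not fire
        assert prob_equal(model, 3.0, 1.0) < 0.01

    def test_equal_ones_matches_oracle(self, model):
        expected = oracle_prob_equal(1.0, 1.0, 1)
        assert prob_equal(model, 1.0, 1.0, 1) == pytest.approx(expected, abs=1e-10)

    def test_matches_oracle_on_grid(self, model):
        rng = np.random.default_rng(0)
        for _ in range(50):
            f_a, f_b = np.round(rng.uniform(0, 6, size=2), 2)
            cycle = int(rng.integers(1, 100))
            assert prob_equal(model, f_a, f_b, cycle) == pytest.approx(
                oracle_prob_equal(f_a, f_b, cycle), abs=1e-9
            )

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(min_value=0, max_value=6).map(lambda x: round(x, 2)),
        st.floats(min_value=0, max_value=6).map(lambda x: round(x, 2)),
    )
    def test_symmetry(self, f_a, f_b):
        model = _session_model()
        assert prob_equal(model, f_a, f_b) == pytest.approx(
            prob_equal(model, f_b, f_a), abs=1e-12
        )

    def test_bounded(self, model):
        rng = np.random.default_rng(1)
        values = np.round(rng.uniform(0, 7, size=200), 2)
        for f_a, f_b in values.reshape(-1, 2):
            assert 0.0 <= prob_equal(model, f_a, f_b) <= 1.0

    def test_monotone_in_separation(self, model):
        # same side of the shared integer, both below 2.5
        for base in [0.1, 1.0, 2.0]:
            probs = [
                prob_equal(model, base, round(base + delta, 2))
                for delta in [0.0, 0.1, 0.2, 0.3, 0.4]
            ]
            assert all(x >= y - 1e-12 for x, y in zip(probs, probs[1:]))

    def test_cauchy_schwarz_bound(self, model):
        # the off-diagonal probability is bounded by the geometric mean of
        # the two diagonal probabilities (Cauchy-Schwarz on the posterior
        # product); a sharper posterior can exceed the broader diagonal,
        # so the diagonal itself is not a maximum in general
        for f_a in [0.3, 1.2, 2.1]:
            diag_a = prob_equal(model, f_a, f_a)
            for f_b in np.round(np.arange(0.0, 2.51, 0.05), 2):
                diag_b = prob_equal(model, float(f_b), float(f_b))
                cross = prob_equal(model, f_a, float(f_b))
                assert cross <= np.sqrt(diag_a * diag_b) + 1e-12

    def test_negative_rejected(self, model):
        with pytest.raises(ValueError):
            prob_equal(model, -0.5, 1.0)


def _session_model(_cache={}):
    if "m" not in _cache:
        _cache["m"] = default_parametric_model()
    return _cache["m"]


class TestGridLookup:
    def test_grid_agrees_with_direct_evaluation(self, model):
        rng = np.random.default_rng(2)
        f_a = np.round(rng.uniform(0, 5.5, size=300), 2)
        f_b = np.round(rng.uniform(0, 5.5, size=300), 2)
        cycles = rng.integers(1, 50, size=300)
        vectorized = model.pair_probabilities(f_a, f_b, cycles)
        for i in range(300):
            direct = prob_equal(model, f_a[i], f_b[i], int(cycles[i]))
            assert vectorized[i] == pytest.approx(direct, abs=1e-6)


class TestLookupTable:
    def test_export_import_consistency(self, model, tmp_path):
        path = tmp_path / "table.tsv"
        export_lookup_table(model, path, cycle_bins=(1, 50), f_max=8.0)
        loaded = load_lookup_model(path)
        for f in [0.1, 0.9, 2.1, 3.3, 4.2]:
            np.testing.assert_allclose(
                posterior_h(loaded, f, 1),
                posterior_h(model, f, 1),
                atol=1e-2,
            )
        # near an h decision boundary the posterior is very sensitive to
        # the 0.01 binning; only a loose agreement is meaningful there
        np.testing.assert_allclose(
            posterior_h(loaded, 1.5, 1), posterior_h(model, 1.5, 1), atol=0.1
        )

    def test_cycle_fallback_to_nearest_bin(self, model, tmp_path):
        path = tmp_path / "table.tsv"
        export_lookup_table(model, path, cycle_bins=(1, 50), f_max=8.0)
        loaded = load_lookup_model(path)
        np.testing.assert_allclose(
            posterior_h(loaded, 1.2, 500), posterior_h(loaded, 1.2, 50)
        )

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(LookupTableError):
            load_lookup_model(path)

    def test_truncated_h_support(self, model, tmp_path):
        path = tmp_path / "h5.tsv"
        small = default_parametric_model(h_max=5)
        export_lookup_table(small, path, cycle_bins=(1,), f_max=8.0)
        loaded = load_lookup_model(path)
        assert loaded.h_max == 5
        assert np.isclose(posterior_h(loaded, 1.0, 1).sum(), 1.0)

    def test_missing_h_rows(self, tmp_path):
        path = tmp_path / "gap.tsv"
        lines = ["prior\t0\t0.6", "prior\t1\t0.3", "prior\t2\t0.1"]
        for h in (0, 2):  # h = 1 missing
            lines += [f"likelihood\t1\t{h}\t{x/10:.1f}\t{(x+1)/10:.1f}\t1.0"
                      for x in range(10)]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(LookupTableError, match="missing h"):
            load_lookup_model(path)

    def test_non_normalizing_row(self, tmp_path):
        path = tmp_path / "bad.tsv"
        lines = ["prior\t0\t0.7", "prior\t1\t0.3"]
        for h in (0, 1):
            density = "1.0" if h == 0 else "0.5"  # h=1 integrates to 0.5
            lines += [f"likelihood\t1\t{h}\t{x/10:.1f}\t{(x+1)/10:.1f}\t{density}"
                      for x in range(10)]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(LookupTableError, match="integrates"):
            load_lookup_model(path)
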