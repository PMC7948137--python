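"""The adaptive regression filter: λ' estimation and trial-wise subtraction."""
import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

import lsafilter as lf
from lsafilter.lsa import estimate_lambda, lsa_filter, select_reference
from lsafilter.simulate import (
    NoiseSpec,
    SimulationConfig,
    SourceSpec,
    gaussian_field,
    single_local_config,
    simulate_epochs,
)

from conftest import make_epochs


def _two_channel(x, y):
    data = np.stack([np.asarray(x, float), np.asarray(y, float)], axis=1)[:, :, None]
    return make_epochs(data, ["ref", "other"])


class TestEstimateLambda:
    def test_exact_linear_dependence(self, rng):
        x = rng.normal(size=40)
        ep = _two_channel(x, 0.5 * x)
        lam = estimate_lambda(ep, "ref", 0)
        assert lam["other"] == pytest.approx(0.5, abs=1e-12)
        assert lam["ref"] == 1.0

    def test_hand_expanded_covariance_ratio(self):
        """cov([1,1,2,2],[1,2,3,4]) / var([1,2,3,4]) = (2/3)/(5/3) = 0.4."""
        ep = _two_channel([1, 2, 3, 4], [1, 1, 2, 2])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lam = estimate_lambda(ep, "ref", 0)
        assert lam["other"] == pytest.approx(0.4, abs=1e-14)

    def test_independence_limit(self, rng):
        x = rng.normal(size=20_000)
        y = rng.normal(size=20_000)
        lam = estimate_lambda(_two_channel(x, y), "ref", 0)
        assert abs(lam["other"]) < 0.03

    def test_matches_brute_force_ols_slope(self, rng):
        """λ' equals the slope of an independent least-squares fit with
        intercept (np.polyfit) on random instances."""
        for _ in range(200):
            n = rng.integers(20, 60)
            x = rng.normal(size=n)
            y = rng.normal(size=n) + rng.normal() * x
            lam = estimate_lambda(_two_channel(x, y), "ref", 0)
            slope = np.polyfit(x, y, 1)[0]
            assert lam["other"] == pytest.approx(slope, rel=1e-10, abs=1e-12)

    def test_zero_variance_reference(self):
        ep = _two_channel([1, 1, 1, 1], [1, 2, 3, 4])
        with pytest.raises(ZeroDivisionError, match="nothing to regress out"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                estimate_lambda(ep, "ref", 0)

    def test_too_few_trials(self):
        ep = _two_channel([1.0], [2.0])
        with pytest.raises(ValueError, match="at least 2 trials"):
            estimate_lambda(ep, "ref", 0)

    def test_few_trials_warning(self):
        ep = _two_channel(np.arange(10.0), np.arange(10.0))
        with pytest.warns(UserWarning, match="trials"):
            estimate_lambda(ep, "ref", 0)


class TestSelectReference:
    def test_widespread_simulation_prefers_vertex_region(self, montage):
        """On the default simulation the selected reference sits at (or
        within a couple of cm of) Cz, where the widespread field peaks."""
        ep = simulate_epochs(single_local_config(seed=2, montage=montage))
        ref = select_reference(ep, (0.0, 0.0))
        assert montage.scalp_distance(ref, "Cz") < 2.5

    def test_noise_free_simulation_selects_cz_exactly(self, montage):
        cfg = SimulationConfig(
            sources=[SourceSpec("Cz", -20.0, 0.5, "widespread"),
                     SourceSpec("C3", -1.0, 0.2)],
            noise=NoiseSpec(amp_sd=1.0, global_sd=0.0, conductance_sd=0.0),
            n_trials=40, seed=2, montage=montage)
        ep = simulate_epochs(cfg)
        assert select_reference(ep, (0.0, 0.0)) == "Cz"

    def test_all_zero_data(self, montage):
        ep = make_epochs(np.zeros((5, 120, 1)), montage.labels)
        with pytest.raises(ValueError, match="zero"):
            select_reference(ep, (0.0, 0.0))

    def test_single_channel(self):
        ep = make_epochs(np.ones((5, 1, 1)), ["Cz"])
        assert select_reference(ep, (0.0, 0.0)) == "Cz"

    def test_empty_window(self, random_epochs):
        with pytest.raises(ValueError):
            select_reference(random_epochs, (5.0, 6.0))


class TestLSAFilter:
    def test_reference_channel_zeroed(self, random_epochs):
        res = lsa_filter(random_epochs, "Cz")
        out = res.filtered.data[:, random_epochs.channel_index("Cz"), :]
        assert np.all(out == 0.0)
        assert np.all(res.lambda_map[random_epochs.channel_index("Cz"), :] == 1.0)

    def test_orthogonality_invariant(self, random_epochs):
        """Exact OLS property: the filtered output is uncorrelated with
        the reference across trials, for every channel and sample."""
        ref = "Cz"
        res = lsa_filter(random_epochs, ref)
        ri = random_epochs.channel_index(ref)
        x = random_epochs.data[:, ri, :]
        xc = x - x.mean(axis=0)
        scale = x.std(axis=0) * res.filtered.data.std(axis=(0, 1))
        for t in range(random_epochs.n_samples):
            cov = res.filtered.data[:, :, t].T @ xc[:, t] / (len(x) - 1)
            assert np.all(np.abs(cov) <= 1e-10 * max(scale[t], 1.0))

    def test_out_of_window_passthrough(self, random_epochs):
        res = lsa_filter(random_epochs, "Cz", window=(0.0, 0.0015))
        assert np.array_equal(res.filtered.data[:, :, 2], random_epochs.data[:, :, 2])
        assert np.all(np.isnan(res.lambda_map[:, 2]))
        assert not np.array_equal(res.filtered.data[:, :, 1],
                                  random_epochs.data[:, :, 1])

    def test_linearity_in_non_reference_channels(self, random_epochs):
        ref_i = random_epochs.channel_index("Cz")
        scaled = random_epochs.data.copy()
        mask = np.arange(random_epochs.n_channels) != ref_i
        scaled[:, mask, :] *= 3.0
        res_a = lsa_filter(random_epochs, "Cz")
        res_b = lsa_filter(random_epochs.copy_with(data=scaled), "Cz")
        assert np.allclose(res_b.filtered.data, 3.0 * res_a.filtered.data,
                           atol=1e-10)

    def test_noise_free_two_source_recovery(self, montage):
        """With only per-source amplitude variability and non-overlapping
        supports at the measurement channels, the filtered map equals the
        local field exactly."""
        # narrow, well-separated fields so neither overlaps the other's center
        wide = SourceSpec("Cz", -20.0, 0.08, "widespread")
        local = SourceSpec("P7", -1.0, 0.05)
        cfg = SimulationConfig(
            sources=[wide, local],
            noise=NoiseSpec(amp_sd=1.0, global_sd=0.0, conductance_sd=0.0),
            n_trials=40, seed=4, montage=montage)
        ep = simulate_epochs(cfg)
        res = lsa_filter(ep, "Cz")
        ga = res.filtered.data.mean(axis=0)[:, 0]
        truth = gaussian_field(montage, local).values
        # away from the widespread support, the grand average equals the
        # local field scaled by the mean trial amplitude — exactly
        support = np.abs(gaussian_field(montage, wide).values) < 1e-12
        amp_mean = ga[ep.channel_index("P7")] / truth[ep.channel_index("P7")]
        assert np.allclose(ga[support], amp_mean * truth[support], atol=1e-9)
        assert np.corrcoef(ga, truth)[0, 1] > 0.999

    def test_recovers_local_topography(self, montage):
        """Default seeded simulation: the filtered grand-average map is
        nearly identical to the true local field."""
        cfg = single_local_config(seed=0, montage=montage)
        ep = simulate_epochs(cfg)
        res = lsa_filter(ep, "Cz")
        ga = res.filtered.data.mean(axis=0)[:, 0]
        truth = gaussian_field(montage, cfg.sources[1]).values
        assert np.corrcoef(ga, truth)[0, 1] >= 0.9

    def test_widespread_only_residuals_small(self, montage):
        """No local source: after filtering, residual amplitudes are far
        below the -20 µV widespread peak."""
        cfg = SimulationConfig(
            sources=[SourceSpec("Cz", -20.0, 0.5, "widespread")],
            n_trials=40, seed=6, montage=montage)
        ep = simulate_epochs(cfg)
        res = lsa_filter(ep, "Cz")
        ga = res.filtered.data.mean(axis=0)[:, 0]
        assert np.abs(ga).max() < 2.0


@given(hnp.arrays(np.float64, (25, 4),
                  elements=st.floats(-50, 50, allow_nan=False)))
def test_lambda_matches_ols_slope_property(data):
    """Property: for any trial matrix with a non-degenerate reference,
    λ' is the OLS slope of each channel on the reference."""
    ep = make_epochs(data[:, :, None], ["ref", "a", "b", "c"])
    x = data[:, 0]
    if x.var(ddof=1) < 1e-6:
        return
    lam = estimate_lambda(ep, "ref", 0)
    for i, lab in enumerate(["a", "b", "c"], start=1):
        slope = np.polyfit(x, data[:, i], 1)[0]
        assert lam[lab] == pytest.approx(slope, rel=1e-8, abs=1e-8)
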