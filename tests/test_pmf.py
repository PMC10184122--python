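"""Jarzynski estimator, bootstrap, convergence and second-cumulant checks."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from glueforce.constants import rt
from glueforce.pmf import (
    PMFProfile,
    WorkProfile,
    WorkProfileSet,
    bootstrap_errors,
    build_pmf_profile,
    convergence_scan,
    endpoint_value,
    jarzynski_free_energy,
    second_cumulant_estimate,
)

RT298 = rt(298.0)

work_lists = st.lists(
    st.floats(min_value=-50, max_value=50, allow_nan=False), min_size=1, max_size=30
)


class TestJarzynski:
    def test_identical_works_return_that_work(self):
        assert jarzynski_free_energy([3.2, 3.2, 3.2]) == pytest.approx(3.2)

    def test_single_work_is_identity(self):
        assert jarzynski_free_energy([7.5]) == pytest.approx(7.5)

    def test_two_terms_with_negligible_exponential(self):
        # {0, huge}: the huge term's exponential vanishes, leaving RT ln 2
        est = jarzynski_free_energy([0.0, 1000.0], temperature=298.0)
        assert est == pytest.approx(RT298 * np.log(2.0), abs=1e-9)
        assert est == pytest.approx(0.4105, abs=1e-3)

    def test_huge_works_do_not_overflow(self):
        est = jarzynski_free_energy([5000.0, 6000.0])
        assert np.isfinite(est)
        assert est == pytest.approx(5000.0 + RT298 * np.log(2.0), abs=1e-6)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            jarzynski_free_energy([])

    @given(works=work_lists)
    def test_jensen_bound(self, works):
        est = jarzynski_free_energy(works)
        assert min(works) - 1e-9 <= est <= np.mean(works) + 1e-9

    @given(works=work_lists, shift=st.floats(min_value=-20, max_value=20))
    def test_gauge_invariance_under_constant_shift(self, works, shift):
        base = jarzynski_free_energy(works)
        shifted = jarzynski_free_energy(np.asarray(works) + shift)
        assert shifted == pytest.approx(base + shift, abs=1e-7)


class TestBuildProfile:
    @staticmethod
    def _two_profile_set():
        grid = np.array([2.5, 3.0, 4.0, 5.0])
        a = WorkProfile(grid, np.array([0.0, 1.0, 3.0, 6.0]), traj_id=0)
        b = WorkProfile(grid, np.array([0.0, 2.0, 2.5, 4.0]), traj_id=1)
        return WorkProfileSet.from_profiles([a, b])

    def test_identical_profiles_reproduced(self):
        grid = np.array([2.5, 3.5, 5.0])
        work = np.array([0.0, 2.0, 5.0])
        ws = WorkProfileSet.from_profiles(
            [WorkProfile(grid, work, traj_id=i) for i in range(4)]
        )
        profile = build_pmf_profile(ws)
        assert np.allclose(profile.pmf, work)

    def test_matches_scalar_oracle_per_grid_point(self):
        ws = self._two_profile_set()
        profile = build_pmf_profile(ws)
        for j in range(ws.grid.size):
            expected = jarzynski_free_energy(ws.works[:, j])
            assert profile.pmf[j] == pytest.approx(expected, abs=1e-12)
        assert profile.pmf[0] == 0.0

    def test_mismatched_grids_rejected(self):
        a = WorkProfile(np.array([2.5, 3.0, 5.0]), np.zeros(3), traj_id=0)
        b = WorkProfile(np.array([2.5, 3.5, 5.0]), np.zeros(3), traj_id=1)
        with pytest.raises(ValueError, match="grid"):
            WorkProfileSet.from_profiles([a, b])

    def test_nonmonotone_grid_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            WorkProfile(np.array([2.5, 2.4, 5.0]), np.zeros(3))


class TestBootstrap:
    def test_identical_profiles_give_zero_sd(self):
        grid = np.array([2.5, 3.5, 5.0])
        work = np.array([0.0, 2.0, 5.0])
        ws = WorkProfileSet.from_profiles(
            [WorkProfile(grid, work, traj_id=i) for i in range(5)]
        )
        profile = bootstrap_errors(ws, n_boot=10, seed=1)
        assert np.allclose(profile.sd, 0.0)

    def test_same_seed_gives_identical_sd(self, shielded_ensemble):
        a = bootstrap_errors(shielded_ensemble, n_boot=10, seed=3)
        b = bootstrap_errors(shielded_ensemble, n_boot=10, seed=3)
        assert np.array_equal(a.sd, b.sd)

    def test_two_profile_enumeration_oracle(self):
        # brute-force enumeration of the 4 equally likely ordered resamples
        # of {A, B}; the bootstrap sd must converge to the population sd of
        # the enumerated estimator distribution
        grid = np.array([2.5, 3.75, 5.0])
        a = np.array([0.0, 1.0, 2.0])
        b = np.array([0.0, 3.0, 7.0])
        ws = WorkProfileSet.from_profiles(
            [WorkProfile(grid, a, traj_id=0), WorkProfile(grid, b, traj_id=1)]
        )
        estimates = []
        for resample in itertools.product([a, b], repeat=2):
            estimates.append(
                [jarzynski_free_energy([w[j] for w in resample]) for j in range(3)]
            )
        enum_sd = np.std(np.asarray(estimates), axis=0, ddof=0)
        boot = bootstrap_errors(ws, n_boot=4000, seed=9)
        assert np.allclose(boot.sd[1:], enum_sd[1:], rtol=0.1)

    def test_too_few_resamples_rejected(self, shielded_ensemble):
        with pytest.raises(ValueError):
            bootstrap_errors(shielded_ensemble, n_boot=1)


class TestEndpoint:
    def test_accessor_contract(self):
        profile = PMFProfile(
            grid=np.array([2.5, 5.0]),
            pmf=np.array([0.0, 4.2]),
            sd=np.array([0.0, 0.3]),
        )
        assert endpoint_value(profile) == (4.2, 0.3)
        assert endpoint_value(profile, end=5.0) == (4.2, 0.3)

    def test_all_zero_profile(self):
        profile = PMFProfile(grid=np.array([2.5, 5.0]), pmf=np.zeros(2))
        assert endpoint_value(profile) == (0.0, 0.0)

    def test_truncated_profile_rejected(self):
        profile = PMFProfile(grid=np.array([2.5, 4.0]), pmf=np.zeros(2))
        with pytest.raises(ValueError, match="truncated"):
            endpoint_value(profile, end=5.0)


def _gaussian_work_set(works: np.ndarray) -> WorkProfileSet:
    """Wrap scalar endpoint works into two-point profiles."""
    grid = np.array([2.5, 5.0])
    return WorkProfileSet.from_profiles(
        [
            WorkProfile(grid, np.array([0.0, w]), traj_id=i)
            for i, w in enumerate(works)
        ]
    )


class TestConvergence:
    def test_full_size_equals_full_ensemble(self, shielded_ensemble):
        n = shielded_ensemble.n_traj
        table = convergence_scan(shielded_ensemble, sizes=(4, n), seed=2)
        full, _ = endpoint_value(build_pmf_profile(shielded_ensemble))
        assert table["endpoint_kcal_mol"].iloc[-1] == pytest.approx(full)
        assert table["drift_kcal_mol"].iloc[-1] == 0.0

    def test_identical_profiles_zero_drift(self):
        grid = np.array([2.5, 5.0])
        ws = WorkProfileSet.from_profiles(
            [WorkProfile(grid, np.array([0.0, 3.0]), traj_id=i) for i in range(20)]
        )
        table = convergence_scan(ws, sizes=(5, 10, 20), seed=4)
        assert np.allclose(table["drift_kcal_mol"], 0.0)

    def test_oversized_subsample_rejected(self, shielded_ensemble):
        with pytest.raises(ValueError):
            convergence_scan(shielded_ensemble, sizes=(shielded_ensemble.n_traj + 1,))

    def test_finite_sample_bias_shrinks_from_above(self, gaussian_works):
        # Jensen: E[estimate] >= true dF, decreasing toward it with N; average
        # many subsamples per size to expose the systematic part
        works, mu, sigma = gaussian_works
        true_df = mu - sigma**2 / (2 * RT298)
        rng = np.random.default_rng(8)
        means = []
        for size in (5, 25, 100):
            est = [
                jarzynski_free_energy(rng.choice(works, size=size, replace=False))
                for _ in range(60)
            ]
            means.append(np.mean(est))
        assert means[0] > means[1] > means[2]
        assert means[2] > true_df - 0.1


class TestSecondCumulant:
    def test_identical_works(self):
        assert second_cumulant_estimate([4.0, 4.0, 4.0]) == pytest.approx(4.0)

    def test_gaussian_closed_form(self):
        # N(5, 1) at 298 K: 5 - 1/(2 RT) ~ 4.156 kcal/mol
        rng = np.random.default_rng(17)
        works = rng.normal(5.0, 1.0, size=200_000)
        est = second_cumulant_estimate(works)
        assert est == pytest.approx(5.0 - 1.0 / (2 * RT298), abs=0.02)
        assert 5.0 - 1.0 / (2 * RT298) == pytest.approx(4.156, abs=1e-3)

    def test_agrees_with_jarzynski_within_bootstrap_sd_for_gaussian_work(self):
        rng = np.random.default_rng(23)
        works = rng.normal(5.0, 0.5, size=100)
        ws = _gaussian_work_set(works)
        profile = bootstrap_errors(ws, n_boot=50, seed=5)
        _, sd = endpoint_value(profile)
        gap = abs(second_cumulant_estimate(works) - jarzynski_free_energy(works))
        assert gap < max(sd, 1e-3)

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            second_cumulant_estimate([1.0])
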