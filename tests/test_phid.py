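"""PID / integrated information decomposition and emergence capacity."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from neuroemergence import phid
from neuroemergence.datatypes import RegionalTimeseries


def _xor_pmf():
    p = np.zeros((2, 2, 2))
    for s1 in (0, 1):
        for s2 in (0, 1):
            p[s1, s2, s1 ^ s2] = 0.25
    return p


def _copy_pmf():
    p = np.zeros((2, 2, 4))
    for s1 in (0, 1):
        for s2 in (0, 1):
            p[s1, s2, 2 * s1 + s2] = 0.25
    return p


class TestPid:
    @pytest.mark.parametrize("method", ["MMI", "CCS"])
    def test_xor_is_pure_synergy(self, method):
        res = phid.pid(_xor_pmf(), method)
        assert abs(res.redundancy) < 1e-9
        assert abs(res.unique_1) < 1e-9
        assert abs(res.unique_2) < 1e-9
        assert abs(res.synergy - 1.0) < 1e-9

    def test_copy_discriminates_methods(self):
        """The COPY target separates the two redundancy functions exactly."""
        mmi = phid.pid(_copy_pmf(), "MMI")
        ccs = phid.pid(_copy_pmf(), "CCS")
        assert abs(mmi.redundancy - 1.0) < 1e-9 and abs(mmi.synergy - 1.0) < 1e-9
        assert abs(ccs.redundancy) < 1e-9 and abs(ccs.synergy) < 1e-9
        assert abs(ccs.unique_1 - 1.0) < 1e-9 and abs(ccs.unique_2 - 1.0) < 1e-9

    @pytest.mark.parametrize("method", ["MMI", "CCS"])
    def test_independent_target_all_zero(self, method):
        p = np.full((2, 2, 2), 0.125)
        res = phid.pid(p, method)
        for v in (res.redundancy, res.unique_1, res.unique_2, res.synergy):
            assert abs(v) < 1e-9

    @pytest.mark.parametrize("method", ["MMI", "CCS"])
    def test_consistency_equations_on_random_pmfs(self, method, rng):
        for _ in range(50):
            p = rng.dirichlet(np.ones(8)).reshape(2, 2, 2)
            res = phid.pid(p, method)
            total = res.redundancy + res.unique_1 + res.unique_2 + res.synergy
            assert abs(total - res.total_mi) < 1e-9
            if method == "MMI":
                i1 = phid._mi_generic(p, (0,), (2,))
                i2 = phid._mi_generic(p, (1,), (2,))
                assert res.redundancy <= min(i1, i2) + 1e-12
                assert abs(res.redundancy - min(i1, i2)) < 1e-12
                assert min(res.unique_1, res.unique_2) >= -1e-12

    def test_rejects_unnormalised_pmf(self):
        with pytest.raises(ValueError):
            phid.pid(np.full((2, 2, 2), 0.2), "MMI")


class TestPhidAtoms:
    def test_independent_past_future_all_zero(self):
        probs = np.full((2, 2, 2, 2), 1 / 16)
        atoms = phid.phid_atoms(phid.JointPmf4(probs=probs, lag=1, sample_count=100))
        assert all(abs(v) < 1e-9 for v in atoms.atoms.values())

    def test_copy_chain_lattice(self):
        """Two independent copy chains under MMI double-redundancy.

        Values follow from the cumulative informations (min of subset MIs) and
        Moebius inversion, worked by hand from the analytic MIs; MMI assigns
        one bit of forward redundancy to independent copies, which propagates
        through the lattice.
        """
        probs = np.zeros((2, 2, 2, 2))
        for a in (0, 1):
            for b in (0, 1):
                probs[a, b, a, b] = 0.25
        atoms = phid.phid_atoms(phid.JointPmf4(probs=probs, lag=1, sample_count=100)).atoms
        expected = {
            ("Red", "Syn"): 1.0,
            ("Unq1", "Unq1"): 1.0,
            ("Unq1", "Syn"): -1.0,
            ("Unq2", "Unq2"): 1.0,
            ("Unq2", "Syn"): -1.0,
            ("Syn", "Red"): 1.0,
            ("Syn", "Unq1"): -1.0,
            ("Syn", "Unq2"): -1.0,
            ("Syn", "Syn"): 2.0,
        }
        for key, value in atoms.items():
            assert abs(value - expected.get(key, 0.0)) < 1e-9, key
        assert abs(sum(atoms.values()) - 2.0) < 1e-9  # TDMI of two copy bits

    def test_atom_sum_equals_tdmi(self, rng):
        for _ in range(100):
            probs = rng.dirichlet(np.ones(16)).reshape(2, 2, 2, 2)
            pmf = phid.JointPmf4(probs=probs, lag=1, sample_count=100)
            atoms = phid.phid_atoms(pmf)
            tdmi = phid._mi(probs[None], (0, 1), (0, 1))[0]
            assert abs(atoms.tdmi - tdmi) < 1e-9

    def test_future_marginal_reproduces_forward_pid(self, rng):
        """Summing atoms over the future index gives the MMI forward PID."""
        for _ in range(20):
            probs = rng.dirichlet(np.ones(16)).reshape(2, 2, 2, 2)
            pmf = phid.JointPmf4(probs=probs, lag=1, sample_count=100)
            table = phid.phid_atoms(pmf).atoms
            forward = phid._forward_pid_array(probs[None], "MMI")[0]
            for k, name in enumerate(("Red", "Unq1", "Unq2", "Syn")):
                row = sum(table[(name, b)] for b in ("Red", "Unq1", "Unq2", "Syn"))
                assert abs(row - forward[k]) < 1e-9


class TestPmfEstimation:
    def test_alternating_surrogate(self):
        x = np.tile([0.0, 1.0], 50)
        pmf = phid.binarize_and_estimate_pmf(x, x, lag=1)
        assert abs(pmf.probs.sum() - 1.0) < 1e-12
        assert (pmf.probs > 0).sum() == 2  # only the two alternating joint states

    def test_independent_series_approach_product_law(self, rng):
        x = rng.normal(size=100_000)
        y = rng.normal(size=100_000)
        pmf = phid.binarize_and_estimate_pmf(x, y, lag=1)
        assert np.abs(pmf.probs - 1 / 16).max() < 0.01

    def test_lag_equal_to_length_errors(self):
        x = np.random.default_rng(0).normal(size=50)
        with pytest.raises(ValueError):
            phid.binarize_and_estimate_pmf(x, x, lag=50)

    def test_constant_series_flagged(self):
        with pytest.raises(phid.ConstantSeriesError):
            phid.binarize(np.ones(100))


class TestEmergenceCapacity:
    def test_independent_pair_near_zero(self, rng):
        x = rng.normal(size=5000)
        y = rng.normal(size=5000)
        for estimator, method in (("discrete", "CCS"), ("discrete", "MMI"), ("gaussian", "MMI")):
            res = phid.emergence_capacity_pair(x, y, method=method, estimator=estimator)
            assert abs(res.capacity) < 0.01

    def test_noisy_xor_matches_analytic_synergy(self, rng):
        """X1_t = X1_{t-1} XOR X2_{t-1} with flip noise: synergy = 1 - H2(eps)."""
        eps = 0.1
        T = 200_000
        x2 = rng.integers(0, 2, T)
        flips = (rng.random(T) < eps).astype(np.int64)
        x1 = np.zeros(T, dtype=np.int64)
        x1[0] = rng.integers(0, 2)
        for t in range(1, T):
            x1[t] = x1[t - 1] ^ x2[t - 1] ^ flips[t]
        analytic = 1.0 - (-eps * np.log2(eps) - (1 - eps) * np.log2(1 - eps))
        res = phid.emergence_capacity_pair(
            x1.astype(float) + rng.normal(0, 1e-6, T),
            x2.astype(float) + rng.normal(0, 1e-6, T),
            method="MMI",
            estimator="discrete",
        )
        assert abs(res.capacity - analytic) < 0.05

    @pytest.mark.parametrize("method", ["MMI", "CCS"])
    def test_capacity_splits_into_downward_and_decoupling(self, method, rng):
        for _ in range(50):
            w = rng.uniform(-0.6, 0.6, size=(2, 2))
            x = _var2(w, 400, rng)
            res = phid.emergence_capacity_pair(x[0], x[1], method=method)
            assert abs(res.capacity - res.downward_causation - res.causal_decoupling) < 1e-9

    def test_capacity_symmetric_under_swap(self, rng):
        w = rng.uniform(-0.5, 0.5, size=(2, 2))
        x = _var2(w, 500, rng)
        r_ij = phid.emergence_capacity_pair(x[0], x[1], method="CCS")
        r_ji = phid.emergence_capacity_pair(x[1], x[0], method="CCS")
        assert abs(r_ij.capacity - r_ji.capacity) < 1e-9

    def test_discrete_and_gaussian_estimators_rank_agree(self, rng):
        """Across random VAR pairs the two estimators order capacities alike."""
        disc, gaus = [], []
        for _ in range(50):
            w = rng.uniform(-0.7, 0.7, size=(2, 2))
            w *= 0.9 / max(np.abs(np.linalg.eigvals(w)).max(), 0.9)
            x = _var2(w, 1500, rng)
            disc.append(phid.emergence_capacity_pair(x[0], x[1], method="MMI").capacity)
            gaus.append(
                phid.emergence_capacity_pair(
                    x[0], x[1], method="MMI", estimator="gaussian"
                ).capacity
            )
        rho = spearmanr(disc, gaus).statistic
        assert rho > 0.5

    def test_gaussian_requires_mmi(self, rng):
        x = rng.normal(size=500)
        with pytest.raises(ValueError):
            phid.emergence_capacity_pair(x, x + rng.normal(size=500), method="CCS",
                                         estimator="gaussian")


class TestGlobalEmergence:
    def test_two_regions_equal_single_pair(self, rng):
        data = rng.normal(size=(2, 400))
        ts = RegionalTimeseries(data=data, tr=2.0)
        global_res, matrix = phid.global_emergence(ts, method="CCS")
        pair = phid.emergence_capacity_pair(data[0], data[1], method="CCS")
        assert abs(global_res.capacity - pair.capacity) < 1e-12
        assert abs(matrix[0, 1] - pair.capacity) < 1e-12

    def test_identical_regions_give_constant_matrix(self, rng):
        base = rng.normal(size=400)
        data = np.tile(base, (4, 1))
        ts = RegionalTimeseries(data=data, tr=2.0)
        _, matrix = phid.global_emergence(ts, method="MMI")
        off = matrix[np.triu_indices(4, 1)]
        assert np.allclose(off, off[0])

    def test_vectorised_path_matches_pairwise_reference(self, rng):
        data = rng.normal(size=(5, 300))
        ts = RegionalTimeseries(data=data, tr=2.0)
        for method in ("CCS", "MMI"):
            _, matrix = phid.global_emergence(ts, method=method)
            for i in range(5):
                for j in range(i + 1, 5):
                    ref = phid.emergence_capacity_pair(data[i], data[j], method=method)
                    assert abs(matrix[i, j] - ref.capacity) < 1e-12

    def test_single_region_errors(self, rng):
        ts = RegionalTimeseries(data=rng.normal(size=(1, 100)), tr=2.0)
        with pytest.raises(ValueError):
            phid.global_emergence(ts)


class TestHrfDeconvolution:
    def test_zero_and_constant_signals_map_to_zero(self):
        ts = RegionalTimeseries(data=np.zeros((3, 100)), tr=2.0)
        out = phid.hrf_deconvolve(ts)
        assert np.allclose(out.data, 0.0)
        ts2 = RegionalTimeseries(data=np.full((2, 100), 7.5), tr=2.0)
        out2 = phid.hrf_deconvolve(ts2)
        assert np.allclose(out2.data, 0.0, atol=1e-10)

    def test_roundtrip_recovers_white_noise(self, rng):
        h = phid.canonical_hrf(2.0)
        noise = rng.normal(size=(4, 300))
        conv = np.apply_along_axis(lambda x: np.convolve(x, h)[:300], 1, noise)
        ts = RegionalTimeseries(data=conv, tr=2.0)
        recovered = phid.hrf_deconvolve(ts)
        for i in range(4):
            r = np.corrcoef(noise[i] - noise[i].mean(), recovered.data[i])[0, 1]
            assert r > 0.9

    def test_requires_positive_tr(self):
        with pytest.raises(ValueError):
            phid.canonical_hrf(0.0)


def _var2(w: np.ndarray, T: int, rng) -> np.ndarray:
    """Stable 2-node VAR(1) sample path used as a generic test signal."""
    lam = np.abs(np.linalg.eigvals(w)).max()
    if lam >= 0.95:
        w = w * (0.9 / lam)
    x = np.zeros((2, T))
    v = rng.normal(size=2)
    for t in range(T):
        v = w @ v + rng.normal(size=2)
        x[:, t] = v
    return x
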