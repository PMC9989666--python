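"""Causal emergence capacity from Integrated Information Decomposition.

The microscale is a pair of regional signals evolving jointly in time.  The
time-delayed mutual information (TDMI) between the pair's past and future,
I(X1_{t-tau}, X2_{t-tau}; X1_t, X2_t), is decomposed into 16 information
atoms indexed by a (past, future) combination of redundant, unique and
synergistic information.  A system's capacity to host causally emergent
macroscopic features equals the synergistic information its past carries
about its future: the sum of the four atoms whose past component is
synergy.  That sum splits into

* downward causation  — synergy in the past predicting redundant or unique
  (i.e. single-region) information in the future, and
* causal decoupling   — synergy predicting synergy: the macroscale acting on
  the macroscale above and beyond the parts.

Two redundancy functions are supported for the forward partial information
decomposition (PID): minimum mutual information (MMI) and common change in
surprisal (CCS).  The full 16-atom lattice uses MMI double-redundancy, the
only case with an agreed closed form.  Estimators: a discrete plug-in
estimator on mean-binarised signals, and a closed-form Gaussian estimator on
the raw signals.  All quantities are reported in bits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .datatypes import RegionalTimeseries

logger = logging.getLogger(__name__)

_ATOM_NAMES = ("Red", "Unq1", "Unq2", "Syn")

# Partial order of the two-source PID lattice:
# Red (= {1}{2}) < Unq1 (= {1}), Unq2 (= {2}) < Syn (= {12}).
_LEQ = np.array(
    [
        [1, 1, 1, 1],
        [0, 1, 0, 1],
        [0, 0, 1, 1],
        [0, 0, 0, 1],
    ],
    dtype=bool,
)

# Collections of past/future variables represented by each lattice node:
# node -> list of variable subsets over which MMI takes the minimum.
_NODE_COLLECTIONS = {0: ((0,), (1,)), 1: ((0,),), 2: ((1,),), 3: ((0, 1),)}


# ---------------------------------------------------------------------------
# containers


@dataclass
class JointPmf4:
    """Plug-in joint law of (X1_{t-tau}, X2_{t-tau}, X1_t, X2_t), all binary."""

    probs: np.ndarray  # shape (2, 2, 2, 2), axes (x1 past, x2 past, x1 future, x2 future)
    lag: int
    sample_count: int

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (2, 2, 2, 2):
            raise ValueError("JointPmf4 must have shape (2, 2, 2, 2)")
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        if (self.probs < 0).any() or abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must be non-negative and sum to 1")


@dataclass
class PIDResult:
    redundancy: float
    unique_1: float
    unique_2: float
    synergy: float
    total_mi: float
    method: str


@dataclass
class InfoAtoms:
    """The 16 atoms keyed by (past atom, future atom)."""

    atoms: dict[tuple[str, str], float]
    double_redundancy_method: str = "MMI"

    @property
    def tdmi(self) -> float:
        return float(sum(self.atoms.values()))

    def downward_causation(self) -> float:
        return (
            self.atoms[("Syn", "Red")]
            + self.atoms[("Syn", "Unq1")]
            + self.atoms[("Syn", "Unq2")]
        )

    def causal_decoupling(self) -> float:
        return self.atoms[("Syn", "Syn")]


@dataclass
class EmergenceResult:
    capacity: float
    downward_causation: float
    causal_decoupling: float
    tdmi: float
    normalized_capacity: float
    method: str = "CCS"
    estimator: str = "discrete"


# ---------------------------------------------------------------------------
# HRF deconvolution


def canonical_hrf(tr: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled at TR.

    Response peak at 6 s, undershoot peak at 16 s, peak/undershoot ratio 6,
    unit dispersions — the conventional parameterisation.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    t = np.arange(0.0, duration, tr)

    def gamma_pdf(x, shape, scale=1.0):
        x = np.maximum(x, 1e-12)
        return np.exp(
            (shape - 1) * np.log(x) - x / scale - gammaln(shape) - shape * np.log(scale)
        )

    h = gamma_pdf(t, 6.0) - gamma_pdf(t, 16.0) / 6.0
    return h / np.abs(h).sum()


def hrf_deconvolve(ts: RegionalTimeseries, noise_floor: float = 1e-3) -> RegionalTimeseries:
    """Wiener-deconvolve the canonical HRF from each regional signal.

    The regularised inverse filter ``conj(H) / (|H|^2 + k)`` is applied in the
    frequency domain, with ``k`` a fixed fraction of the peak HRF spectral
    power.  Output has the input's length and zero mean per region.
    """
    if ts.n_timepoints < 50:
        raise ValueError("need at least 50 timepoints for deconvolution")
    X = ts.data - ts.data.mean(axis=1, keepdims=True)
    n = ts.n_timepoints
    h = canonical_hrf(ts.tr)
    H = np.fft.rfft(h, n=n)
    power = np.abs(H) ** 2
    k = noise_floor * power.max()
    G = np.conj(H) / (power + k)
    out = np.fft.irfft(np.fft.rfft(X, axis=1) * G[None, :], n=n, axis=1)
    out -= out.mean(axis=1, keepdims=True)
    result = ts.copy_with(out)
    result.meta = {**ts.meta, "hrf_deconvolved": True}
    return result


# ---------------------------------------------------------------------------
# discrete pmf estimation


class ConstantSeriesError(ValueError):
    """A series with no variance cannot be mean-binarised."""


def binarize(x: np.ndarray) -> np.ndarray:
    """Binarise a 1-D series at its mean (strictly above the mean -> 1)."""
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ConstantSeriesError("constant series cannot be binarised")
    return (x > x.mean()).astype(np.int64)


def binarize_and_estimate_pmf(ts_i: np.ndarray, ts_j: np.ndarray, lag: int = 1) -> JointPmf4:
    """Empirical joint law of the binarised pair at the given lag."""
    ts_i = np.asarray(ts_i, dtype=float)
    ts_j = np.asarray(ts_j, dtype=float)
    if ts_i.shape != ts_j.shape or ts_i.ndim != 1:
        raise ValueError("the two series must be 1-D and of equal length")
    T = len(ts_i)
    if lag < 1 or T - lag < 1:
        raise ValueError(f"lag {lag} leaves no aligned samples for T={T}")
    bi, bj = binarize(ts_i), binarize(ts_j)
    code = 8 * bi[:-lag] + 4 * bj[:-lag] + 2 * bi[lag:] + bj[lag:]
    counts = np.bincount(code, minlength=16).astype(float)
    probs = (counts / counts.sum()).reshape(2, 2, 2, 2)
    return JointPmf4(probs=probs, lag=lag, sample_count=T - lag)


# ---------------------------------------------------------------------------
# vectorised information primitives
#
# Stacked pmfs of shape (P, 2, 2, 2, 2) are the working representation; every
# per-pair quantity is computed for all P pairs at once.


def _entropy(p: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    """Shannon entropy (bits) of the marginal over the given variable axes."""
    keep = tuple(a + 1 for a in axes)
    drop = tuple(a for a in range(1, 5) if a not in keep)
    marg = p.sum(axis=drop) if drop else p
    flat = marg.reshape(p.shape[0], -1)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(flat > 0, flat * np.log2(flat), 0.0)
    return -terms.sum(axis=1)


def _mi(p: np.ndarray, past: tuple[int, ...], future: tuple[int, ...]) -> np.ndarray:
    """I(past variables ; future variables), vectorised over stacked pmfs."""
    past_axes = tuple(past)
    fut_axes = tuple(f + 2 for f in future)
    return (
        _entropy(p, past_axes) + _entropy(p, fut_axes) - _entropy(p, past_axes + fut_axes)
    )


def _all_mis(p: np.ndarray) -> dict[tuple[tuple[int, ...], tuple[int, ...]], np.ndarray]:
    subsets = ((0,), (1,), (0, 1))
    return {(a, b): _mi(p, a, b) for a in subsets for b in subsets}


def _phid_atoms_array(p: np.ndarray) -> np.ndarray:
    """16 ΦID atoms (MMI double-redundancy) for stacked pmfs; shape (P, 4, 4)."""
    mis = _all_mis(p)
    P = p.shape[0]
    cumulative = np.empty((P, 4, 4))
    for a in range(4):
        for b in range(4):
            vals = [mis[(pa, fb)] for pa in _NODE_COLLECTIONS[a] for fb in _NODE_COLLECTIONS[b]]
            cumulative[:, a, b] = np.min(vals, axis=0)
    atoms = np.zeros((P, 4, 4))
    for a in range(4):
        for b in range(4):
            below = sum(
                atoms[:, a2, b2]
                for a2 in range(4)
                for b2 in range(4)
                if _LEQ[a2, a] and _LEQ[b2, b] and (a2, b2) != (a, b)
            )
            atoms[:, a, b] = cumulative[:, a, b] - below
    return atoms


def _forward_pid_array(p: np.ndarray, method: str) -> np.ndarray:
    """Forward PID (red, u1, u2, syn) with composite future target; shape (P, 4)."""
    i1 = _mi(p, (0,), (0, 1))
    i2 = _mi(p, (1,), (0, 1))
    i12 = _mi(p, (0, 1), (0, 1))
    if method == "MMI":
        red = np.minimum(i1, i2)
    elif method == "CCS":
        red = _ccs_redundancy_array(p)
    else:
        raise ValueError(f"unknown PID method {method!r}")
    u1 = i1 - red
    u2 = i2 - red
    syn = i12 - red - u1 - u2
    return np.stack([red, u1, u2, syn], axis=1)


def _ccs_redundancy_array(p: np.ndarray) -> np.ndarray:
    """CCS redundancy for sources (X1 past, X2 past), composite future target.

    Per joint state, the local co-information counts as redundancy only when
    the local informations i(s1;t), i(s2;t), i(s1,s2;t) and the co-information
    itself all share one strict sign; otherwise the state contributes zero.
    """
    P = p.shape[0]
    pj = p.reshape(P, 2, 2, 4)  # target = composite future state
    ps1 = pj.sum(axis=(2, 3), keepdims=True)
    ps2 = pj.sum(axis=(1, 3), keepdims=True)
    ps12 = pj.sum(axis=3, keepdims=True)
    pt = pj.sum(axis=(1, 2), keepdims=True)
    ps1t = pj.sum(axis=2, keepdims=True)
    ps2t = pj.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        i1 = np.log2(ps1t / (ps1 * pt))
        i2 = np.log2(ps2t / (ps2 * pt))
        i12 = np.log2(pj / (ps12 * pt))
    i1 = np.broadcast_to(i1, pj.shape)
    i2 = np.broadcast_to(i2, pj.shape)
    with np.errstate(invalid="ignore"):
        coinfo = i1 + i2 - i12
    pos = (i1 > 0) & (i2 > 0) & (i12 > 0) & (coinfo > 0)
    neg = (i1 < 0) & (i2 < 0) & (i12 < 0) & (coinfo < 0)
    coherent = (pos | neg) & (pj > 0)
    contrib = np.where(coherent, pj * np.nan_to_num(coinfo, nan=0.0, posinf=0.0, neginf=0.0), 0.0)
    return contrib.sum(axis=(1, 2, 3))


# ---------------------------------------------------------------------------
# public single-pmf operations


def _as_stacked(pmf: JointPmf4) -> np.ndarray:
    return pmf.probs[None, ...]


def pid(pmf: np.ndarray | JointPmf4, method: str = "CCS") -> PIDResult:
    """Partial information decomposition of I(S1, S2; T).

    ``pmf`` is either a :class:`JointPmf4` (target = the composite future) or
    a raw joint array ``p[s1, s2, t]`` with arbitrary finite alphabets.
    """
    if isinstance(pmf, JointPmf4):
        p3 = pmf.probs.reshape(2, 2, 4)
    else:
        p3 = np.asarray(pmf, dtype=float)
        if p3.ndim != 3:
            raise ValueError("pid expects p[s1, s2, t]")
    if (p3 < 0).any() or abs(p3.sum() - 1.0) > 1e-9:
        raise ValueError("pmf must be non-negative and normalised")
    i1 = _mi_generic(p3, (0,), (2,))
    i2 = _mi_generic(p3, (1,), (2,))
    i12 = _mi_generic(p3, (0, 1), (2,))
    if method == "MMI":
        red = min(i1, i2)
    elif method == "CCS":
        red = _ccs_redundancy_generic(p3)
    else:
        raise ValueError(f"unknown PID method {method!r}")
    u1, u2 = i1 - red, i2 - red
    syn = i12 - red - u1 - u2
    return PIDResult(
        redundancy=float(red),
        unique_1=float(u1),
        unique_2=float(u2),
        synergy=float(syn),
        total_mi=float(i12),
        method=method,
    )


def _entropy_generic(p: np.ndarray, axes: tuple[int, ...]) -> float:
    drop = tuple(a for a in range(p.ndim) if a not in axes)
    marg = p.sum(axis=drop) if drop else p
    flat = marg.ravel()
    nz = flat[flat > 0]
    return float(-(nz * np.log2(nz)).sum())


def _mi_generic(p: np.ndarray, a: tuple[int, ...], b: tuple[int, ...]) -> float:
    return (
        _entropy_generic(p, a) + _entropy_generic(p, b) - _entropy_generic(p, tuple(a) + tuple(b))
    )


def _ccs_redundancy_generic(p3: np.ndarray) -> float:
    ps1 = p3.sum(axis=(1, 2), keepdims=True)
    ps2 = p3.sum(axis=(0, 2), keepdims=True)
    ps12 = p3.sum(axis=2, keepdims=True)
    pt = p3.sum(axis=(0, 1), keepdims=True)
    ps1t = p3.sum(axis=1, keepdims=True)
    ps2t = p3.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        i1 = np.broadcast_to(np.log2(ps1t / (ps1 * pt)), p3.shape)
        i2 = np.broadcast_to(np.log2(ps2t / (ps2 * pt)), p3.shape)
        i12 = np.log2(p3 / (ps12 * pt))
        coinfo = i1 + i2 - i12
    pos = (i1 > 0) & (i2 > 0) & (i12 > 0) & (coinfo > 0)
    neg = (i1 < 0) & (i2 < 0) & (i12 < 0) & (coinfo < 0)
    coherent = (pos | neg) & (p3 > 0)
    contrib = np.where(
        coherent, p3 * np.nan_to_num(coinfo, nan=0.0, posinf=0.0, neginf=0.0), 0.0
    )
    return float(contrib.sum())


def phid_atoms(pmf: JointPmf4, double_redundancy: str = "MMI") -> InfoAtoms:
    """Solve the 16-atom integrated information decomposition of the TDMI.

    Double-redundancy (the bottom atom) is the minimum of the four
    single-variable cross mutual informations; the remaining atoms follow by
    Moebius inversion of the cumulative informations on the product lattice,
    equivalent to solving the linear system that relates the atoms to the
    Shannon mutual informations between all past and future variable subsets.
    """
    if double_redundancy != "MMI":
        raise ValueError("only MMI double-redundancy is supported")
    atoms = _phid_atoms_array(_as_stacked(pmf))[0]
    table = {
        (_ATOM_NAMES[a], _ATOM_NAMES[b]): float(atoms[a, b]) for a in range(4) for b in range(4)
    }
    return InfoAtoms(atoms=table, double_redundancy_method="MMI")


# ---------------------------------------------------------------------------
# Gaussian estimator


def _gaussian_pair_covariance(
    x: np.ndarray, y: np.ndarray, lag: int, ridge: float = 1e-9
) -> np.ndarray:
    """Sample covariance of (x_{t-lag}, y_{t-lag}, x_t, y_t)."""
    past = np.stack([x[:-lag], y[:-lag]])
    fut = np.stack([x[lag:], y[lag:]])
    Z = np.vstack([past, fut])
    cov = np.cov(Z)
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0 or logdet < 4 * np.log(1e-12):
        warnings.warn("near-singular covariance; applying ridge regularisation")
        cov = cov + ridge * np.eye(4)
    return cov


def _gaussian_mi(cov: np.ndarray, a: list[int], b: list[int]) -> float:
    """I(A;B) in bits for jointly Gaussian variables."""
    ia = np.ix_(a, a)
    ib = np.ix_(b, b)
    ab = a + b
    iab = np.ix_(ab, ab)
    det_a = np.linalg.det(cov[ia])
    det_b = np.linalg.det(cov[ib])
    det_ab = np.linalg.det(cov[iab])
    det_ab = max(det_ab, 1e-300)
    return float(0.5 * np.log2(max(det_a * det_b / det_ab, 1.0)))


def _gaussian_atoms(cov: np.ndarray) -> np.ndarray:
    """16 MMI ΦID atoms from a 4x4 lagged covariance; shape (4, 4)."""
    subsets = {(0,): [0], (1,): [1], (0, 1): [0, 1]}
    mis = {
        (a, b): _gaussian_mi(cov, subsets[a], [v + 2 for v in subsets[b]])
        for a in subsets
        for b in subsets
    }
    cumulative = np.empty((4, 4))
    for na in range(4):
        for nb in range(4):
            vals = [mis[(pa, fb)] for pa in _NODE_COLLECTIONS[na] for fb in _NODE_COLLECTIONS[nb]]
            cumulative[na, nb] = min(vals)
    atoms = np.zeros((4, 4))
    for na in range(4):
        for nb in range(4):
            below = sum(
                atoms[a2, b2]
                for a2 in range(4)
                for b2 in range(4)
                if _LEQ[a2, na] and _LEQ[b2, nb] and (a2, b2) != (na, nb)
            )
            atoms[na, nb] = cumulative[na, nb] - below
    return atoms


# ---------------------------------------------------------------------------
# emergence capacity


def _result_from_atoms(
    atoms: np.ndarray, capacity: float, tdmi: float, method: str, estimator: str
) -> EmergenceResult:
    syn_row = atoms[3, :].sum()
    decoupling_mmi = atoms[3, 3]
    if method == "MMI":
        downward = atoms[3, 0] + atoms[3, 1] + atoms[3, 2]
        decoupling = decoupling_mmi
        capacity = downward + decoupling
    else:
        # CCS aggregate capacity, split in the MMI lattice's proportions
        frac = decoupling_mmi / syn_row if syn_row > 1e-15 else 0.0
        decoupling = capacity * frac
        downward = capacity - decoupling
    norm = capacity / tdmi if tdmi > 1e-15 else float("nan")
    return EmergenceResult(
        capacity=float(capacity),
        downward_causation=float(downward),
        causal_decoupling=float(decoupling),
        tdmi=float(tdmi),
        normalized_capacity=float(norm),
        method=method,
        estimator=estimator,
    )


def emergence_capacity_pair(
    ts_i: np.ndarray,
    ts_j: np.ndarray,
    lag: int = 1,
    method: str = "CCS",
    estimator: str = "discrete",
) -> EmergenceResult:
    """Emergence capacity of one pair of regional signals.

    Capacity is the synergy of the forward PID whose sources are the two past
    states and whose target is the composite future state; downward causation
    and causal decoupling come from the 16-atom lattice.
    """
    ts_i = np.asarray(ts_i, dtype=float)
    ts_j = np.asarray(ts_j, dtype=float)
    if estimator == "discrete":
        pmf = binarize_and_estimate_pmf(ts_i, ts_j, lag=lag)
        stacked = _as_stacked(pmf)
        atoms = _phid_atoms_array(stacked)[0]
        forward = _forward_pid_array(stacked, method)[0]
        tdmi = float(_mi(stacked, (0, 1), (0, 1))[0])
        return _result_from_atoms(atoms, float(forward[3]), tdmi, method, estimator)
    if estimator == "gaussian":
        if method == "CCS":
            raise ValueError("the CCS redundancy is defined for discrete data; use MMI")
        cov = _gaussian_pair_covariance(ts_i, ts_j, lag)
        atoms = _gaussian_atoms(cov)
        tdmi = _gaussian_mi(cov, [0, 1], [2, 3])
        return _result_from_atoms(atoms, float(atoms[3, :].sum()), tdmi, method, estimator)
    raise ValueError(f"unknown estimator {estimator!r}")


def global_emergence(
    ts: RegionalTimeseries,
    lag: int = 1,
    method: str = "CCS",
    estimator: str = "discrete",
) -> tuple[EmergenceResult, np.ndarray]:
    """Average pairwise emergence capacity over all unordered region pairs.

    Returns the global result (mean over pairs of every component) and the
    symmetric region x region capacity matrix (NaN for skipped pairs).
    Constant-signal regions are excluded with a logged count.
    """
    n = ts.n_regions
    if n < 2:
        raise ValueError("need at least 2 regions")
    X = ts.data
    if estimator == "discrete":
        return _global_discrete(X, lag, method)
    results = []
    matrix = np.full((n, n), np.nan)
    skipped = 0
    for i in range(n):
        for j in range(i + 1, n):
            if np.ptp(X[i]) == 0 or np.ptp(X[j]) == 0:
                skipped += 1
                continue
            res = emergence_capacity_pair(X[i], X[j], lag=lag, method=method, estimator=estimator)
            results.append(res)
            matrix[i, j] = matrix[j, i] = res.capacity
    if skipped:
        logger.warning("skipped %d constant-signal pairs", skipped)
    if not results:
        raise ValueError("no usable region pairs")
    return _aggregate(results, method, estimator), matrix


def _global_discrete(X: np.ndarray, lag: int, method: str) -> tuple[EmergenceResult, np.ndarray]:
    n, T = X.shape
    if T - lag < 1:
        raise ValueError("lag leaves no aligned samples")
    variable = np.ptp(X, axis=1) > 0
    skipped_regions = int((~variable).sum())
    if skipped_regions:
        logger.warning("skipped %d constant-signal regions", skipped_regions)
    idx = np.flatnonzero(variable)
    if len(idx) < 2:
        raise ValueError("fewer than 2 usable regions")
    B = (X[idx] > X[idx].mean(axis=1, keepdims=True)).astype(np.int64)
    pairs = [(a, b) for k, a in enumerate(idx) for b in idx[k + 1 :]]
    codes = np.empty((len(pairs), 16))
    pos = {r: k for k, r in enumerate(idx)}
    for p, (i, j) in enumerate(pairs):
        bi, bj = B[pos[i]], B[pos[j]]
        code = 8 * bi[:-lag] + 4 * bj[:-lag] + 2 * bi[lag:] + bj[lag:]
        codes[p] = np.bincount(code, minlength=16)
    pmfs = (codes / codes.sum(axis=1, keepdims=True)).reshape(-1, 2, 2, 2, 2)
    atoms = _phid_atoms_array(pmfs)
    forward = _forward_pid_array(pmfs, method)
    tdmi = _mi(pmfs, (0, 1), (0, 1))
    per_pair = [
        _result_from_atoms(atoms[p], float(forward[p, 3]), float(tdmi[p]), method, "discrete")
        for p in range(len(pairs))
    ]
    matrix = np.full((n, n), np.nan)
    for p, (i, j) in enumerate(pairs):
        matrix[i, j] = matrix[j, i] = per_pair[p].capacity
    return _aggregate(per_pair, method, "discrete"), matrix


def _aggregate(results: list[EmergenceResult], method: str, estimator: str) -> EmergenceResult:
    cap = float(np.mean([r.capacity for r in results]))
    down = float(np.mean([r.downward_causation for r in results]))
    dec = float(np.mean([r.causal_decoupling for r in results]))
    tdmi = float(np.mean([r.tdmi for r in results]))
    norms = [r.normalized_capacity for r in results if np.isfinite(r.normalized_capacity)]
    norm = float(np.mean(norms)) if norms else float("nan")
    return EmergenceResult(
        capacity=cap,
        downward_causation=down,
        causal_decoupling=dec,
        tdmi=tdmi,
        normalized_capacity=norm,
        method=method,
        estimator=estimator,
    )
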