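"""Linear network controllability of structural connectomes.

The network model is the discrete-time linear system
x(t+1) = A x(t) + B_K u_K(t), with A the structural adjacency matrix
normalised to Schur stability by dividing by (largest singular value + 1).
Two node-level measures are computed with single-node control sets:

* average controllability — trace of the controllability Gramian
  W_i = sum_tau A^tau e_i e_i' A'^tau, the energy of the network impulse
  response from node i (easy-to-reach states);
* modal controllability — phi_i = sum_j (1 - lambda_j^2) v_ij^2 from the
  eigendecomposition A = V Lambda V', the ability of node i to control all
  dynamic modes (hard-to-reach states).

Whole-brain values are unweighted means over regions.  A group consensus
connectome keeps an edge only when more than half of the subjects possess it,
valued as the mean over the subjects that do.
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np
from scipy.linalg import eigh, solve_discrete_lyapunov

from .datatypes import StructuralConnectome


@dataclass
class ControllabilityProfile:
    average: np.ndarray
    modal: np.ndarray
    labels: list[str]

    @property
    def global_average(self) -> float:
        return float(self.average.mean())

    @property
    def global_modal(self) -> float:
        return float(self.modal.mean())


def normalize_connectome(conn: StructuralConnectome) -> StructuralConnectome:
    """Divide the adjacency matrix by (largest singular value + 1).

    The result is Schur stable (spectral radius < 1), which the Gramian and
    the modal measure both require.
    """
    A = conn.weights
    sigma_max = np.linalg.norm(A, 2)
    if sigma_max == 0:
        warn("all-zero connectome; normalization is a no-op")
        return StructuralConnectome(
            weights=A.copy(), labels=list(conn.labels), normalized=True, meta=dict(conn.meta)
        )
    A_norm = A / (sigma_max + 1.0)
    return StructuralConnectome(
        weights=A_norm, labels=list(conn.labels), normalized=True, meta=dict(conn.meta)
    )


def average_controllability(conn: StructuralConnectome) -> np.ndarray:
    """Per-node trace of the single-node controllability Gramian.

    For node i with input vector e_i, trace(W_i) = sum_tau (A'^tau A^tau)_ii,
    so one discrete Lyapunov solve M = A' M A + I yields every node's value as
    diag(M).  Equivalence with the truncated per-node Gramian sum is asserted
    in the test suite.
    """
    if not conn.normalized:
        raise ValueError("normalize_connectome must be applied first")
    A = conn.weights
    rho = np.max(np.abs(np.linalg.eigvalsh(A))) if A.any() else 0.0
    if rho >= 1:
        raise ValueError("unstable adjacency matrix; normalize first")
    M = solve_discrete_lyapunov(A.T, np.eye(A.shape[0]))
    return np.diag(M).copy()


def modal_controllability(conn: StructuralConnectome) -> np.ndarray:
    """Per-node phi_i = sum_j (1 - lambda_j^2) v_ij^2.

    Uses the symmetric eigendecomposition (orthonormal V, real lambda);
    eigenvalues are sorted descending.  For numerically degenerate eigenvalues
    the sum over the degenerate subspace is rotation invariant, so no special
    handling is needed beyond using a symmetric solver.
    """
    if not conn.normalized:
        raise ValueError("normalize_connectome must be applied first")
    A = conn.weights
    lam, V = eigh(A)
    order = np.argsort(lam)[::-1]
    lam, V = lam[order], V[:, order]
    return ((1.0 - lam**2)[None, :] * V**2).sum(axis=1)


def controllability_profile(conn: StructuralConnectome) -> ControllabilityProfile:
    """Average and modal controllability of a (raw or normalised) connectome."""
    if not conn.normalized:
        conn = normalize_connectome(conn)
    return ControllabilityProfile(
        average=average_controllability(conn),
        modal=modal_controllability(conn),
        labels=list(conn.labels),
    )


def consensus_connectome(connectomes: list[StructuralConnectome]) -> StructuralConnectome:
    """Group consensus matrix.

    An edge is kept when strictly more than half of the subjects have a
    non-zero weight there; its consensus weight is the mean over those
    subjects.  All other entries are zero.
    """
    if not connectomes:
        raise ValueError("need at least one connectome")
    shapes = {c.weights.shape for c in connectomes}
    if len(shapes) != 1:
        raise ValueError("all connectomes must share dimensions")
    labels = connectomes[0].labels
    for c in connectomes[1:]:
        if c.labels != labels:
            raise ValueError("all connectomes must share region labels and order")
    stack = np.stack([c.weights for c in connectomes])
    nonzero = stack > 0
    count = nonzero.sum(axis=0)
    majority = count > len(connectomes) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_present = np.where(count > 0, stack.sum(axis=0) / np.maximum(count, 1), 0.0)
    weights = np.where(majority, mean_present, 0.0)
    np.fill_diagonal(weights, 0.0)
    weights = (weights + weights.T) / 2.0
    return StructuralConnectome(weights=weights, labels=list(labels), meta={"consensus": True})
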