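"""Absorbing-CTMC algebra on top of a phase-type representation.

A phase-type pair (alpha, A) defines an absorbing CTMC.  This module exposes
the standard derived objects: the embedded (jump-chain) transition block Q,
the Green matrix U = -A^{-1} of expected occupation times, expected rewards
accrued before absorption, and -- when the single absorbing state is split
into m labelled absorbing states via a routing matrix C -- the absorption
(hitting) probabilities across those states.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from glct.phasetype import PhaseTypeRep, VALIDATION_TOL


def embedded_chain(ph: PhaseTypeRep):
    """Embedded jump chain of the absorbing CTMC.

    Returns ``(Q, q, r)`` where ``r = -diag(A)`` are the exponential dwell
    rates, ``Q = D_r^{-1} A + I`` (zero diagonal; row i sums to 1 - q_i) is
    the transient block of the jump-chain transition matrix, and
    ``q = D_r^{-1} a`` (entries a_i / r_i) are the per-state probabilities
    of jumping to absorption.  The rate matrix is recovered as
    ``-A = D_r (I - Q)``.
    """
    r = -np.diag(ph.A)
    if np.any(r <= VALIDATION_TOL):
        raise ValueError("degenerate dwell state: some rate r_i is zero")
    Q = ph.A / r[:, None] + np.eye(ph.k)
    np.fill_diagonal(Q, 0.0)
    q = ph.a / r
    return Q, q, r


def green_matrix(ph: PhaseTypeRep) -> np.ndarray:
    """Green matrix ``U = -A^{-1}``.

    Entry (i, j) is the expected time spent in transient state j before
    absorption given the chain starts in state i; all entries are >= 0.
    """
    return np.linalg.solve(-ph.A, np.eye(ph.k))


def expected_reward(ph: PhaseTypeRep, g) -> float:
    """Expected reward ``alpha^T (-A^{-1}) g`` accrued before absorption.

    ``g`` holds per-state reward rates; with g = 1 this is the mean
    absorption time (the first moment of the phase-type distribution).
    """
    g = np.asarray(g, dtype=float).ravel()
    if g.size != ph.k:
        raise ValueError(f"reward vector length {g.size} != k = {ph.k}")
    return float(ph.alpha @ np.linalg.solve(-ph.A, g))


class AbsorptionSplit:
    """A phase-type chain whose exit is routed over m labelled absorbing states.

    ``C`` is k x m; row i is the conditional distribution over absorbing
    states taken on exit from transient state i.  Rows are only constrained
    (sum to 1) where the exit rate ``a_i`` is positive -- rows with no
    direct exit are stored as uniform since they never matter.
    """

    __slots__ = ("ph", "C", "labels", "m")

    def __init__(
        self,
        ph: PhaseTypeRep,
        C,
        labels: Sequence[str] | None = None,
        *,
        tol: float = VALIDATION_TOL,
    ):
        C = np.asarray(C, dtype=float)
        if C.ndim != 2 or C.shape[0] != ph.k:
            raise ValueError(f"C must be k x m with k = {ph.k}, got {C.shape}")
        m = C.shape[1]
        if np.any((C < -tol) | (C > 1.0 + tol)):
            raise ValueError("entries of C must lie in [0, 1]")
        C = np.clip(C, 0.0, 1.0)
        active = ph.a > tol
        rowsum = C.sum(axis=1)
        if np.any(np.abs(rowsum[active] - 1.0) > tol):
            raise ValueError("rows of C must sum to 1 where the exit rate is positive")
        C[~active] = 1.0 / m
        if labels is not None and len(labels) != m:
            raise ValueError("need one label per absorbing state")
        self.ph = ph
        self.C = C
        self.labels = list(labels) if labels is not None else list(range(m))
        self.m = m

    def to_dict(self) -> dict:
        return {
            "ph": self.ph.to_dict(),
            "C": self.C.tolist(),
            "absorbing_labels": list(self.labels),
        }

    @classmethod
    def from_dict(cls, obj) -> "AbsorptionSplit":
        return cls(
            PhaseTypeRep.from_dict(obj["ph"]), obj["C"], obj.get("absorbing_labels")
        )


def absorption_probabilities(split: AbsorptionSplit, *, tol: float = VALIDATION_TOL):
    """Hitting probabilities over the m absorbing states.

    Returns ``(H, pi)``: ``H = (-A^{-1}) D_a C`` is k x m with entry (i, j)
    the probability of ending in absorbing state j from transient state i
    (rows sum to 1), and ``pi = alpha^T H`` averages over the initial
    distribution.  ``pi`` requires sum(alpha) = 1: with a defect the mass
    absorbed at time 0 has no defined destination, so we refuse.
    """
    ph = split.ph
    H = np.linalg.solve(-ph.A, split.C * ph.a[:, None])
    if abs(ph.alpha.sum() - 1.0) > tol:
        raise ValueError(
            "absorption probabilities require sum(alpha) = 1 (no defect); "
            f"got defect {ph.defect}"
        )
    pi = ph.alpha @ H
    return H, pi
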