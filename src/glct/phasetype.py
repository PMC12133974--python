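"""Continuous phase-type distributions.

A (continuous) phase-type distribution is the distribution of the time to
absorption in a finite-state continuous-time Markov chain (CTMC) with ``k``
transient states and one absorbing state.  It is parameterized by

* ``alpha`` -- the initial probability vector over the transient states
  (entries >= 0, sum <= 1; any *defect* ``1 - sum(alpha)`` is probability
  mass absorbed instantaneously at time 0), and
* ``A`` -- the ``k x k`` transient block of the CTMC rate matrix, with
  strictly negative diagonal, nonnegative off-diagonals, and nonpositive
  row sums.  The exit-rate vector to the absorbing state is ``a = -A @ 1``.

The family contains the exponential, Erlang, hypoexponential (generalized
Erlang), hyper-Erlang (Erlang mixture) and Coxian distributions, and is
closed under minima (Kronecker product/sum) and finite mixtures.  These
closure operations, plus the mortality-augmented representation
``G = A - mu*I`` (the minimum with an independent exponential clock), are
the building blocks used by the model-assembly and reproduction-number
modules.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm

#: absolute tolerance for sign/row-sum checks on constructed matrices
VALIDATION_TOL = 1e-9

#: condition-number bound beyond which A is treated as numerically singular
_COND_LIMIT = 1e12


class PhaseTypeError(ValueError):
    """Raised when (alpha, A) is not a valid phase-type representation."""


class PhaseTypeRep:
    """A validated phase-type representation ``(alpha, A)``.

    Attributes
    ----------
    alpha : ndarray, shape (k,)
        Initial probability vector over transient states.
    A : ndarray, shape (k, k)
        Transient rate block (1/time).
    a : ndarray, shape (k,)
        Exit-rate vector to the absorbing state, ``-A @ 1`` (clipped at 0).
    defect : float
        Point mass at zero, ``1 - sum(alpha)``, in [0, 1].
    k : int
        Number of transient states.
    """

    __slots__ = ("alpha", "A", "a", "defect", "k")

    def __init__(self, alpha, A, *, tol: float = VALIDATION_TOL):
        alpha = np.atleast_1d(np.asarray(alpha, dtype=float)).ravel()
        A = np.asarray(A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise PhaseTypeError(f"A must be square, got shape {A.shape}")
        k = A.shape[0]
        if alpha.shape[0] != k:
            raise PhaseTypeError(
                f"alpha length {alpha.shape[0]} does not match A dimension {k}"
            )
        if not (np.all(np.isfinite(alpha)) and np.all(np.isfinite(A))):
            raise PhaseTypeError("alpha and A must have finite entries")
        if np.any(np.diag(A) >= 0.0):
            raise PhaseTypeError("diagonal of A must be strictly negative")
        off = A - np.diag(np.diag(A))
        if np.any(off < -tol):
            raise PhaseTypeError("off-diagonal entries of A must be >= 0")
        a = -A @ np.ones(k)
        if np.any(a < -tol):
            raise PhaseTypeError(
                "row sums of A must be <= 0 (exit vector a = -A@1 has a "
                "negative entry beyond tolerance)"
            )
        if np.any(alpha < -tol) or np.any(alpha > 1.0 + tol):
            raise PhaseTypeError("alpha entries must lie in [0, 1]")
        s = float(alpha.sum())
        if s > 1.0 + tol:
            raise PhaseTypeError(f"alpha sums to {s} > 1")
        if np.linalg.cond(A) > _COND_LIMIT:
            raise PhaseTypeError(
                "A is singular or near-singular: some transient state "
                "cannot reach absorption"
            )
        self.alpha = np.clip(alpha, 0.0, 1.0)
        self.A = A
        self.a = np.clip(a, 0.0, None)
        self.defect = float(min(max(1.0 - s, 0.0), 1.0))
        self.k = k

    # -- basic descriptors -------------------------------------------------

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PhaseTypeRep(k={self.k}, defect={self.defect:.3g})"

    @property
    def mean(self) -> float:
        """Mean absorption time, ``alpha^T (-A)^{-1} 1``."""
        return ph_moment(self, 1)

    def pdf(self, t):
        return ph_density(self, t)[0]

    def cdf(self, t):
        return ph_density(self, t)[1]

    def moment(self, j: int) -> float:
        return ph_moment(self, j)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        """Dense JSON-serializable form; round-trips bit-exactly."""
        return {"alpha": self.alpha.tolist(), "A": self.A.tolist()}

    @classmethod
    def from_dict(cls, obj: Mapping) -> "PhaseTypeRep":
        """Build from either the dense form or a canonical-kind form.

        Accepts ``{"alpha": [...], "A": [[...]]}`` or
        ``{"kind": "erlang", "k": 3, "mean": 2.0}`` etc.
        """
        if "kind" in obj:
            params = {key: val for key, val in obj.items() if key != "kind"}
            return build_canonical_ph(obj["kind"], params)
        return cls(obj["alpha"], obj["A"])


def validate_phase_type(alpha, A) -> PhaseTypeRep:
    """Validate and wrap (alpha, A); see :class:`PhaseTypeRep`."""
    return PhaseTypeRep(alpha, A)


# ---------------------------------------------------------------------------
# canonical constructors
# ---------------------------------------------------------------------------


def exponential(rate: float) -> PhaseTypeRep:
    """Exponential distribution with the given rate (k = 1)."""
    if rate <= 0:
        raise PhaseTypeError("rate must be positive")
    return PhaseTypeRep([1.0], [[-float(rate)]])


def erlang(k: int, rate: float | None = None, mean: float | None = None) -> PhaseTypeRep:
    """Erlang distribution: sum of k iid exponentials with common rate.

    Either ``rate`` or ``mean`` must be given; with a mean tau the stage
    rate is ``r = k / tau``.  Mean k/r, variance k/r^2, CV 1/sqrt(k).
    """
    k = int(k)
    if k < 1:
        raise PhaseTypeError("Erlang shape k must be >= 1")
    if (rate is None) == (mean is None):
        raise PhaseTypeError("give exactly one of rate or mean")
    if rate is None:
        if mean <= 0:
            raise PhaseTypeError("mean must be positive")
        rate = k / float(mean)
    return hypoexponential([float(rate)] * k)


def hypoexponential(rates: Sequence[float]) -> PhaseTypeRep:
    """Generalized Erlang: sum of independent exponentials with given rates."""
    rates = np.asarray(rates, dtype=float).ravel()
    k = rates.size
    if k < 1:
        raise PhaseTypeError("need at least one rate")
    if np.any(rates <= 0):
        raise PhaseTypeError("rates must be positive")
    A = np.diag(-rates)
    A[np.arange(k - 1), np.arange(1, k)] = rates[:-1]
    alpha = np.zeros(k)
    alpha[0] = 1.0
    return PhaseTypeRep(alpha, A)


def coxian(rates: Sequence[float], probs: Sequence[float] = ()) -> PhaseTypeRep:
    """Coxian distribution.

    All mass starts in state 1; from stage i the chain advances to stage
    i+1 with probability ``probs[i]`` (rate ``rates[i] * probs[i]``) or
    exits straight to absorption otherwise.  With all probs equal to 1 this
    is the hypoexponential distribution.
    """
    rates = np.asarray(rates, dtype=float).ravel()
    probs = np.asarray(probs, dtype=float).ravel()
    k = rates.size
    if k < 1:
        raise PhaseTypeError("need at least one rate")
    if probs.size != k - 1:
        raise PhaseTypeError(f"need {k - 1} continuation probabilities, got {probs.size}")
    if np.any(rates <= 0):
        raise PhaseTypeError("rates must be positive")
    if np.any((probs < 0) | (probs > 1)):
        raise PhaseTypeError("continuation probabilities must lie in [0, 1]")
    A = np.diag(-rates)
    if k > 1:
        A[np.arange(k - 1), np.arange(1, k)] = rates[:-1] * probs
    alpha = np.zeros(k)
    alpha[0] = 1.0
    return PhaseTypeRep(alpha, A)


def mixture(components: Sequence[PhaseTypeRep], weights: Sequence[float]) -> PhaseTypeRep:
    """Finite mixture of phase-type distributions.

    ``A`` is block diagonal over the components; ``alpha`` concatenates the
    component alphas scaled by the mixing weights.  Components must carry no
    defect (any point mass at zero belongs at the top level only).
    """
    weights = np.asarray(weights, dtype=float).ravel()
    if len(components) != weights.size or len(components) == 0:
        raise PhaseTypeError("need one weight per component")
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > VALIDATION_TOL:
        raise PhaseTypeError("mixture weights must form a probability vector")
    for comp in components:
        if comp.defect > VALIDATION_TOL:
            raise PhaseTypeError("mixture components must have zero defect")
    from scipy.linalg import block_diag

    A = block_diag(*(comp.A for comp in components))
    alpha = np.concatenate([w * comp.alpha for comp, w in zip(components, weights)])
    return PhaseTypeRep(alpha, A)


_CANONICAL = {
    "exponential": lambda p: exponential(p.get("rate", p.get("r"))),
    "erlang": lambda p: erlang(p["k"], rate=p.get("rate", p.get("r")), mean=p.get("mean")),
    "hypoexponential": lambda p: hypoexponential(p["rates"]),
    "coxian": lambda p: coxian(p["rates"], p.get("probs", ())),
    "mixture": lambda p: mixture(
        [PhaseTypeRep.from_dict(c) for c in p["components"]], p["weights"]
    ),
    "dense": lambda p: PhaseTypeRep(p["alpha"], p["A"]),
}


def build_canonical_ph(kind: str, params: Mapping) -> PhaseTypeRep:
    """Dispatch to a canonical constructor by name.

    Kinds: ``exponential``, ``erlang``, ``hypoexponential``, ``coxian``,
    ``mixture``, ``dense``.
    """
    try:
        builder = _CANONICAL[kind]
    except KeyError:
        raise PhaseTypeError(
            f"unknown kind {kind!r}; choose from {sorted(_CANONICAL)}"
        ) from None
    return builder(dict(params))


# ---------------------------------------------------------------------------
# density, moments, closure operations
# ---------------------------------------------------------------------------


def ph_density(ph: PhaseTypeRep, t):
    """Density and CDF at time(s) t >= 0.

    pdf(t) = alpha^T exp(A t) a and F(t) = 1 - alpha^T exp(A t) 1.  At t = 0
    the CDF equals the defect (the instantaneous point mass).  Scalar or
    array t accepted; the matrix exponential is evaluated per time point.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    ones = np.ones(ph.k)
    pdf = np.empty_like(t_arr)
    cdf = np.empty_like(t_arr)
    for i, ti in enumerate(t_arr):
        w = ph.alpha @ expm(ph.A * ti)
        pdf[i] = w @ ph.a
        cdf[i] = 1.0 - w @ ones
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(pdf[0]), float(cdf[0])
    return pdf, cdf


def ph_moment(ph: PhaseTypeRep, j: int) -> float:
    """j-th raw moment, ``j! alpha^T (-A)^{-j} 1``.

    Computed by j successive linear solves against ``-A`` (never by an
    explicit inverse or matrix power), for conditioning.
    """
    j = int(j)
    if j < 1:
        raise ValueError("moment order j must be >= 1")
    w = np.ones(ph.k)
    for _ in range(j):
        w = np.linalg.solve(-ph.A, w)
    return float(math.factorial(j) * (ph.alpha @ w))


def ph_minimum(*phs: PhaseTypeRep) -> PhaseTypeRep:
    """Minimum of independent phase-type random variables.

    For two variables the representation is ``alpha1 (x) alpha2`` (Kronecker
    product) and ``A1 (+) A2`` (Kronecker sum); more arguments fold
    associatively.
    """
    if len(phs) < 2:
        raise ValueError("need at least two distributions")
    out = phs[0]
    for ph in phs[1:]:
        alpha = np.kron(out.alpha, ph.alpha)
        A = np.kron(out.A, np.eye(ph.k)) + np.kron(np.eye(out.k), ph.A)
        out = PhaseTypeRep(alpha, A)
    return out


def ph_with_defect_exit(ph: PhaseTypeRep, mu: float) -> PhaseTypeRep:
    """Mortality-augmented ("effective") representation ``(alpha, A - mu I)``.

    Equivalent to the minimum of ``ph`` with an independent exponential(mu)
    clock after dropping the trivial Kronecker factor: every transient state
    gains an extra exit rate mu, so the exit vector becomes ``a + mu``.
    With mu = 0 the representation is returned unchanged.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    if mu == 0:
        return ph
    return PhaseTypeRep(ph.alpha, ph.A - mu * np.eye(ph.k))
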