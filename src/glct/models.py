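"""Mean-field ODE models assembled from phase-type dwell-time blocks.

The generalized linear chain trick (GLCT) turns the assumption "time spent
in state X is phase-type with parameters (alpha, A)" into the linear system

    dx/dt = alpha * inflow(t) + A^T x,

where x partitions X into substates, per-substate outflow is (-A 1) o x and
total outflow is -1^T A^T x.  This module provides that generic stage plus
two assembled model families:

* a generalized SEIRS model with phase-type latent, infectious, and immune
  periods, constant recruitment Lambda, uniform per-capita mortality mu,
  and a transmission-rate vector beta over infectious substates; and
* a stage-structured Rosenzweig-MacArthur predator-prey model with
  phase-type predator maturation time and adult lifetime, logistic prey
  growth, and a Holling type-II functional response.

State vectors are flat numpy arrays: scalars first, then substate vectors
in model-declaration order (S, x, y, z for SEIRS; N, x, y for predator-prey).
"""

from __future__ import annotations

from typing import Callable, Mapping

import numpy as np

from glct.phasetype import PhaseTypeRep, VALIDATION_TOL


def glct_stage_rhs(ph: PhaseTypeRep, inflow: float, x):
    """Generic GLCT stage derivative.

    Returns ``(dx, outflow_by_substate, total_outflow)`` with
    ``dx = alpha * inflow + A^T x``, per-substate outflow ``a o x`` and
    total outflow ``a . x`` (= -1^T A^T x).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size != ph.k:
        raise ValueError(f"substate vector length {x.size} != k = {ph.k}")
    dx = ph.alpha * inflow + ph.A.T @ x
    outflow = ph.a * x
    return dx, outflow, float(ph.a @ x)


class SEIRSModel:
    """Generalized SEIRS model with phase-type E, I, and R dwell times.

    Parameters
    ----------
    ph_latent, ph_infectious, ph_immune : PhaseTypeRep
        Dwell-time blocks for the latent (E), infectious (I), and immune (R)
        states.  The latent block must have no defect (every new infection
        enters E).
    beta : float or array of length k_I
        Transmission rate(s) per infectious substate (1/(individuals*time)).
        A scalar is broadcast over all substates.
    Lambda : float
        Constant recruitment/birth rate (individuals/time).
    mu : float
        Uniform per-capita mortality rate (1/time).
    birth : callable, optional
        Override ``birth(S, x, y, z) -> rate`` for non-constant recruitment.
        Users supplying one must also supply their own equilibrium.
    S0 : float, optional
        Disease-free susceptible population for closed populations
        (Lambda = mu = 0), where the equilibrium S is not determined by
        the demography.
    """

    def __init__(
        self,
        ph_latent: PhaseTypeRep,
        ph_infectious: PhaseTypeRep,
        ph_immune: PhaseTypeRep,
        beta,
        Lambda: float = 0.0,
        mu: float = 0.0,
        birth: Callable[..., float] | None = None,
        S0: float | None = None,
    ):
        if ph_latent.defect > VALIDATION_TOL:
            raise ValueError(
                "latent block must satisfy sum(alpha_E) = 1: all newly "
                "infected individuals enter the exposed state"
            )
        beta = np.asarray(beta, dtype=float).ravel()
        if beta.size == 1:
            beta = np.full(ph_infectious.k, beta[0])
        if beta.size != ph_infectious.k:
            raise ValueError("beta must be scalar or length k_I")
        if np.any(beta < 0) or Lambda < 0 or mu < 0:
            raise ValueError("beta, Lambda, mu must be nonnegative")
        self.ph_latent = ph_latent
        self.ph_infectious = ph_infectious
        self.ph_immune = ph_immune
        self.beta = beta
        self.Lambda = float(Lambda)
        self.mu = float(mu)
        self.birth = birth
        self.S0 = S0

    @property
    def k_E(self) -> int:
        return self.ph_latent.k

    @property
    def k_I(self) -> int:
        return self.ph_infectious.k

    @property
    def k_R(self) -> int:
        return self.ph_immune.k

    @property
    def dim(self) -> int:
        return 1 + self.k_E + self.k_I + self.k_R

    def slices(self) -> dict:
        kE, kI, kR = self.k_E, self.k_I, self.k_R
        return {
            "S": slice(0, 1),
            "E": slice(1, 1 + kE),
            "I": slice(1 + kE, 1 + kE + kI),
            "R": slice(1 + kE + kI, 1 + kE + kI + kR),
        }

    def pack(self, S: float, E, I, R) -> np.ndarray:
        state = np.concatenate(
            [[S], np.atleast_1d(E), np.atleast_1d(I), np.atleast_1d(R)]
        ).astype(float)
        if state.size != self.dim:
            raise ValueError("state slice lengths do not match model dimensions")
        return state

    def unpack(self, state) -> dict:
        state = np.asarray(state, dtype=float).ravel()
        sl = self.slices()
        return {name: state[s] for name, s in sl.items()}

    def state_names(self) -> list[str]:
        return (
            ["S"]
            + [f"E{i + 1}" for i in range(self.k_E)]
            + [f"I{i + 1}" for i in range(self.k_I)]
            + [f"R{i + 1}" for i in range(self.k_R)]
        )

    def rhs(self, t: float, state) -> np.ndarray:
        return seirs_rhs(self, state, t)


def seirs_rhs(model: SEIRSModel, state, t: float = 0.0) -> np.ndarray:
    """Right-hand side of the generalized SEIRS mean-field ODEs.

    dS = Lambda - mu S - lambda(t) S + a_R . z
    dx = alpha_E lambda S + A_E^T x - mu x
    dy = alpha_I (a_E . x) + A_I^T y - mu y
    dz = alpha_R (a_I . y) + A_R^T z - mu z

    with force of infection lambda(t) = beta . y.
    """
    state = np.asarray(state, dtype=float).ravel()
    if state.size != model.dim:
        raise ValueError(f"state length {state.size} != model dimension {model.dim}")
    phE, phI, phR = model.ph_latent, model.ph_infectious, model.ph_immune
    S = state[0]
    x = state[1 : 1 + phE.k]
    y = state[1 + phE.k : 1 + phE.k + phI.k]
    z = state[1 + phE.k + phI.k :]
    lam = float(model.beta @ y)
    if model.birth is not None:
        births = float(model.birth(S, x, y, z))
    else:
        births = model.Lambda
    dS = births - model.mu * S - lam * S + float(phR.a @ z)
    dx = phE.alpha * (lam * S) + phE.A.T @ x - model.mu * x
    dy = phI.alpha * float(phE.a @ x) + phI.A.T @ y - model.mu * y
    dz = phR.alpha * float(phI.a @ y) + phR.A.T @ z - model.mu * z
    return np.concatenate([[dS], dx, dy, dz])


class PredPreyModel:
    """Stage-structured Rosenzweig-MacArthur predator-prey model.

    Prey N grow logistically (rate r, carrying capacity K) and are consumed
    via a Holling type-II response with maximum predation rate a and
    half-saturation h; immature predators consume at the relative rate eta.
    Prey consumed by mature predators convert to new immature predators with
    efficiency chi.  Maturation time (block x, k_i substates) and adult
    lifetime (block y, k_m substates) are phase-type.  A defect in the
    maturation block means that fraction of offspring dies before entering
    the immature stage.
    """

    def __init__(
        self,
        ph_maturation: PhaseTypeRep,
        ph_adult: PhaseTypeRep,
        r: float,
        K: float,
        a: float,
        h: float,
        chi: float,
        eta: float = 0.0,
    ):
        if min(r, K, a, h) <= 0 or chi <= 0:
            raise ValueError("r, K, a, h, chi must be positive")
        if eta < 0:
            raise ValueError("eta must be >= 0")
        self.ph_maturation = ph_maturation
        self.ph_adult = ph_adult
        self.r = float(r)
        self.K = float(K)
        self.a = float(a)
        self.h = float(h)
        self.chi = float(chi)
        self.eta = float(eta)

    @property
    def k_i(self) -> int:
        return self.ph_maturation.k

    @property
    def k_m(self) -> int:
        return self.ph_adult.k

    @property
    def dim(self) -> int:
        return 1 + self.k_i + self.k_m

    def slices(self) -> dict:
        return {
            "N": slice(0, 1),
            "immature": slice(1, 1 + self.k_i),
            "mature": slice(1 + self.k_i, self.dim),
        }

    def pack(self, N: float, immature, mature) -> np.ndarray:
        state = np.concatenate(
            [[N], np.atleast_1d(immature), np.atleast_1d(mature)]
        ).astype(float)
        if state.size != self.dim:
            raise ValueError("state slice lengths do not match model dimensions")
        return state

    def unpack(self, state) -> dict:
        state = np.asarray(state, dtype=float).ravel()
        return {name: state[s] for name, s in self.slices().items()}

    def state_names(self) -> list[str]:
        return (
            ["N"]
            + [f"x{i + 1}" for i in range(self.k_i)]
            + [f"y{i + 1}" for i in range(self.k_m)]
        )

    def rhs(self, t: float, state) -> np.ndarray:
        return predprey_rhs(self, state, t)


def predprey_rhs(model: PredPreyModel, state, t: float = 0.0) -> np.ndarray:
    """Right-hand side of the stage-structured predator-prey ODEs.

    dN = r N (1 - N/K) - a (P_m + eta P_imm) N / (h + N)
    dx = chi (a N / (h + N)) P_m alpha_x + A_x^T x
    dy = (a_x . x) alpha_y + A_y^T y

    with P_imm = sum(x) and P_m = sum(y).
    """
    state = np.asarray(state, dtype=float).ravel()
    if state.size != model.dim:
        raise ValueError(f"state length {state.size} != model dimension {model.dim}")
    phX, phY = model.ph_maturation, model.ph_adult
    N = state[0]
    x = state[1 : 1 + phX.k]
    y = state[1 + phX.k :]
    P_imm = float(x.sum())
    P_m = float(y.sum())
    response = model.a * N / (model.h + N)
    dN = model.r * N * (1.0 - N / model.K) - response * (P_m + model.eta * P_imm)
    dx = model.chi * response * P_m * phX.alpha + phX.A.T @ x
    dy = phY.alpha * float(phX.a @ x) + phY.A.T @ y
    return np.concatenate([[dN], dx, dy])


# ---------------------------------------------------------------------------
# equilibria and summaries
# ---------------------------------------------------------------------------


def disease_free_equilibrium(model: SEIRSModel) -> np.ndarray:
    """The disease-free equilibrium (S0, 0, 0, 0).

    With constant recruitment, S0 = Lambda / mu.  For a closed population
    (Lambda = mu = 0) the equilibrium S is whatever the user supplied as
    ``model.S0``.  mu = 0 with Lambda > 0 has no equilibrium.
    """
    if model.birth is not None:
        raise ValueError("custom birth function: supply the DFE explicitly")
    if model.mu > 0:
        S0 = model.Lambda / model.mu
    elif model.Lambda == 0:
        if model.S0 is None:
            raise ValueError("closed population: set model.S0 explicitly")
        S0 = float(model.S0)
    else:
        raise ValueError("mu = 0 with Lambda > 0: susceptibles grow without bound")
    state = np.zeros(model.dim)
    state[0] = S0
    return state


def prey_only_equilibrium(model: PredPreyModel) -> np.ndarray:
    """The predator-free equilibrium (K, 0, 0)."""
    state = np.zeros(model.dim)
    state[0] = model.K
    return state


def lump_totals(model, state) -> dict:
    """Compartment totals: S, E, I, R for SEIRS; N, P_imm, P_m for predator-prey."""
    parts = model.unpack(state)
    if isinstance(model, SEIRSModel):
        return {
            "S": float(parts["S"][0]),
            "E": float(parts["E"].sum()),
            "I": float(parts["I"].sum()),
            "R": float(parts["R"].sum()),
        }
    return {
        "N": float(parts["N"][0]),
        "P_imm": float(parts["immature"].sum()),
        "P_m": float(parts["mature"].sum()),
    }


# ---------------------------------------------------------------------------
# config I/O
# ---------------------------------------------------------------------------


def model_from_config(cfg: Mapping):
    """Build a model from a config mapping.

    Schema::

        {"model": "seirs",
         "blocks": {"latent": <ph>, "infectious": <ph>, "immune": <ph>},
         "params": {"beta": 0.001 | [...], "Lambda": 1.0, "mu": 0.01,
                    "S0": 100.0},
         "initial_state": {"S": 99, "E": [...], "I": [...], "R": [...]}}

        {"model": "predprey",
         "blocks": {"maturation": <ph>, "adult": <ph>},
         "params": {"r": .., "K": .., "a": .., "h": .., "chi": .., "eta": ..},
         "initial_state": {"N": .., "immature": [...], "mature": [...]}}

    where each ``<ph>`` is a phase-type block dict (dense or canonical kind;
    see :meth:`PhaseTypeRep.from_dict`).  Returns ``(model, initial_state)``
    with ``initial_state`` None when absent.
    """
    kind = cfg.get("model")
    blocks = cfg.get("blocks", {})
    params = dict(cfg.get("params", {}))
    if kind == "seirs":
        for name in ("latent", "infectious", "immune"):
            if name not in blocks:
                raise KeyError(f"blocks.{name} is required for a seirs model")
        model = SEIRSModel(
            PhaseTypeRep.from_dict(blocks["latent"]),
            PhaseTypeRep.from_dict(blocks["infectious"]),
            PhaseTypeRep.from_dict(blocks["immune"]),
            beta=params["beta"],
            Lambda=params.get("Lambda", 0.0),
            mu=params.get("mu", 0.0),
            S0=params.get("S0"),
        )
        init = cfg.get("initial_state")
        state = None
        if init is not None:
            state = model.pack(init["S"], init["E"], init["I"], init["R"])
    elif kind == "predprey":
        for name in ("maturation", "adult"):
            if name not in blocks:
                raise KeyError(f"blocks.{name} is required for a predprey model")
        model = PredPreyModel(
            PhaseTypeRep.from_dict(blocks["maturation"]),
            PhaseTypeRep.from_dict(blocks["adult"]),
            r=params["r"],
            K=params["K"],
            a=params["a"],
            h=params["h"],
            chi=params["chi"],
            eta=params.get("eta", 0.0),
        )
        init = cfg.get("initial_state")
        state = None
        if init is not None:
            state = model.pack(init["N"], init["immature"], init["mature"])
    else:
        raise ValueError(f"model must be 'seirs' or 'predprey', got {kind!r}")
    if state is not None and np.any(state < 0):
        raise ValueError("initial state must be nonnegative")
    return model, state
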