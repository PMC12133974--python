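"""Reproduction numbers via the next-generation matrix and in closed form.

For the generalized SEIRS model the next-generation operator at the
disease-free equilibrium gives R0 = rho(F V^{-1}) with

    F = [[0, alpha_E beta^T S0], [0, 0]]
    V = [[-G_E^T, 0], [alpha_I 1^T A_E^T, -G_I^T]],   G = A - mu I,

and the spectral radius factors into two interpretable pieces:

    R0 = R0_new * P_{E->I}
    R0_new   = alpha_I^T (-G_I^{-1}) (beta S0)     expected new infections
                                                   per infectious individual
    P_{E->I} = alpha_E . (-G_E^{-1}) (-A_E 1)      probability of surviving
                                                   the latent stage

For the stage-structured predator-prey model at the prey-only equilibrium
N = K the analogous factorization is

    R_pred = [chi a N / (h + N)] * [alpha_y^T (-A_y^{-1}) 1] * (1 - alpha_x*),

birth rate times mean adult lifespan times the fraction of offspring that
enter the immature stage.  Both routes (dense eigenvalues of F V^{-1} and
the factored closed form) are computed and cross-checked here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from glct.ctmc import AbsorptionSplit
from glct.models import PredPreyModel, SEIRSModel
from glct.phasetype import PhaseTypeRep, VALIDATION_TOL, ph_with_defect_exit

#: relative tolerance for the eigenvalue-route vs closed-form consistency check
CHECK_TOL = 1e-8


@dataclass
class NGMResult:
    """Next-generation-matrix computation with its factored closed form."""

    F: np.ndarray
    V: np.ndarray
    Vinv: np.ndarray
    FVinv: np.ndarray
    rho: float
    factors: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "R0": self.rho,
            "factors": dict(self.factors),
            "F": self.F.tolist(),
            "V": self.V.tolist(),
            "classification": classify_threshold(self.rho),
        }


def classify_threshold(rho: float, tol: float = 1e-9) -> str:
    """Stability verdict for the equilibrium from the reproduction number."""
    if rho < 1.0 - tol:
        return "stable"
    if rho > 1.0 + tol:
        return "unstable"
    return "marginal"


def rank_one_spectral_radius(u, v) -> float:
    """Spectral radius of the outer product u v^T, which is |u . v|."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.size != v.size:
        raise ValueError("u and v must have equal lengths")
    return abs(float(u @ v))


def block_lower_triangular_inverse(Ablk, Cblk, Dblk) -> np.ndarray:
    """Inverse of [[A, 0], [C, D]] via per-block linear solves.

    Returns [[A^{-1}, 0], [-D^{-1} C A^{-1}, D^{-1}]].
    """
    Ablk = np.atleast_2d(np.asarray(Ablk, dtype=float))
    Cblk = np.atleast_2d(np.asarray(Cblk, dtype=float))
    Dblk = np.atleast_2d(np.asarray(Dblk, dtype=float))
    n, m = Ablk.shape[0], Dblk.shape[0]
    Ainv = np.linalg.solve(Ablk, np.eye(n))
    Dinv = np.linalg.solve(Dblk, np.eye(m))
    return np.block(
        [[Ainv, np.zeros((n, m))], [-Dinv @ Cblk @ Ainv, Dinv]]
    )


def _spectral_radius(M: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(M))))


def _seirs_S0(model: SEIRSModel, S0: float | None) -> float:
    if S0 is not None:
        return float(S0)
    if model.mu > 0:
        return model.Lambda / model.mu
    if model.S0 is None:
        raise ValueError("closed population: supply S0 explicitly")
    return float(model.S0)


def seirs_ngm(model: SEIRSModel, S0: float | None = None, *, check_tol: float = CHECK_TOL) -> NGMResult:
    """Next-generation matrix for the generalized SEIRS model at the DFE.

    Builds the F and V blocks over the infected substates (x, y), inverts V
    by the block-triangular formula, and takes the spectral radius of
    F V^{-1} from its full eigenvalue set.  The result is cross-checked
    against the factored closed form and both factors are stored in
    ``factors`` (keys ``R0_new``, ``P_E_to_I``).
    """
    S0 = _seirs_S0(model, S0)
    phE, phI = model.ph_latent, model.ph_infectious
    kE, kI = phE.k, phI.k
    GE = phE.A - model.mu * np.eye(kE)
    GI = phI.A - model.mu * np.eye(kI)
    if np.linalg.cond(GE) > 1e12 or np.linalg.cond(GI) > 1e12:
        raise np.linalg.LinAlgError("G_E or G_I is singular")
    F = np.block(
        [
            [np.zeros((kE, kE)), np.outer(phE.alpha, model.beta) * S0],
            [np.zeros((kI, kE)), np.zeros((kI, kI))],
        ]
    )
    # 1^T A_E^T = (A_E 1)^T = -a_E^T, so the coupling block is -alpha_I a_E^T
    coupling = -np.outer(phI.alpha, phE.a)
    V = np.block([[-GE.T, np.zeros((kE, kI))], [coupling, -GI.T]])
    Vinv = block_lower_triangular_inverse(-GE.T, coupling, -GI.T)
    FVinv = F @ Vinv
    rho = _spectral_radius(FVinv)
    R0, R0_new, P_EI = r0_seirs_closed(model, S0)
    if abs(rho - R0) > check_tol * max(1.0, abs(R0)):
        raise ArithmeticError(
            f"eigenvalue route ({rho}) disagrees with closed form ({R0})"
        )
    return NGMResult(
        F=F,
        V=V,
        Vinv=Vinv,
        FVinv=FVinv,
        rho=rho,
        factors={"R0_new": R0_new, "P_E_to_I": P_EI, "S0": S0},
    )


def r0_seirs_closed(model: SEIRSModel, S0: float | None = None):
    """Closed-form R0 = R0_new * P_{E->I} for the generalized SEIRS model.

    Returns ``(R0, R0_new, P_E_to_I)``.  P_{E->I} lies in [0, 1] and equals
    1 when mu = 0 (no death during latency).
    """
    S0 = _seirs_S0(model, S0)
    phE, phI = model.ph_latent, model.ph_infectious
    GE = phE.A - model.mu * np.eye(phE.k)
    GI = phI.A - model.mu * np.eye(phI.k)
    R0_new = float(phI.alpha @ np.linalg.solve(-GI, model.beta * S0))
    P_EI = float(phE.alpha @ np.linalg.solve(-GE, phE.a))
    return R0_new * P_EI, R0_new, P_EI


def r0_erlang_seirs_closed(
    kE: int, kI: int, tauE: float, tauI: float, beta: float, S0: float, mu: float
) -> float:
    """Explicit R0 for Erlang latent/infectious SEIRS.

    With stage rates r_E = kE/tauE and r_I = kI/tauI,

        R0 = beta S0 * [sum_{j=0}^{kI-1} r_I^j / (r_I + mu)^{j+1}]
                     * (r_E / (r_E + mu))^{kE}.

    The bracket is the mean effective infectious period (the minimum of the
    Erlang infectious period and an exponential(mu) lifetime); the final
    power is the probability of surviving all kE latent substages.
    """
    kE, kI = int(kE), int(kI)
    if kE < 1 or kI < 1 or tauE <= 0 or tauI <= 0:
        raise ValueError("shapes must be >= 1 and means positive")
    rE = kE / tauE
    rI = kI / tauI
    mean_infectious = sum(rI**j / (rI + mu) ** (j + 1) for j in range(kI))
    survival = (rE / (rE + mu)) ** kE
    return beta * S0 * mean_infectious * survival


def predprey_ngm(
    model: PredPreyModel, N: float | None = None, *, check_tol: float = CHECK_TOL
) -> NGMResult:
    """Next-generation matrix for the predator-prey model.

    Evaluated at prey abundance N (default the prey-only equilibrium K).
    ``factors`` holds ``birth_rate`` (chi a N / (h + N)),
    ``mean_adult_time`` (alpha_y^T (-A_y^{-1}) 1) and
    ``survival_to_immature`` (1 - alpha_x*); their product is R_pred.
    The relative predation rate eta of immature predators does not enter:
    it affects neither adult fecundity nor maturation.
    """
    N = model.K if N is None else float(N)
    phX, phY = model.ph_maturation, model.ph_adult
    ki, km = phX.k, phY.k
    birth_rate = model.chi * model.a * N / (model.h + N)
    F = np.block(
        [
            [np.zeros((ki, ki)), np.outer(phX.alpha, np.ones(km)) * birth_rate],
            [np.zeros((km, ki)), np.zeros((km, km))],
        ]
    )
    coupling = -np.outer(phY.alpha, phX.a)  # alpha_y 1^T A_x^T
    V = np.block([[-phX.A.T, np.zeros((ki, km))], [coupling, -phY.A.T]])
    Vinv = block_lower_triangular_inverse(-phX.A.T, coupling, -phY.A.T)
    FVinv = F @ Vinv
    rho = _spectral_radius(FVinv)
    mean_adult = float(phY.alpha @ np.linalg.solve(-phY.A, np.ones(km)))
    survival = 1.0 - phX.defect
    closed = birth_rate * mean_adult * survival
    if abs(rho - closed) > check_tol * max(1.0, abs(closed)):
        raise ArithmeticError(
            f"eigenvalue route ({rho}) disagrees with closed form ({closed})"
        )
    return NGMResult(
        F=F,
        V=V,
        Vinv=Vinv,
        FVinv=FVinv,
        rho=rho,
        factors={
            "birth_rate": birth_rate,
            "mean_adult_time": mean_adult,
            "survival_to_immature": survival,
            "N": N,
        },
    )


def survival_split(ph: PhaseTypeRep, mu: float) -> AbsorptionSplit:
    """Two-absorbing-state split {next stage, dead} under mortality mu.

    Augments ``ph`` with a uniform extra exit rate mu (G = A - mu I) and
    routes the exit from state i to the "next stage" absorbing state with
    probability a_i / (a_i + mu) and to "dead" otherwise.  The first entry
    of the resulting absorption-probability vector is the probability of
    surviving the stage -- an independent route to P_{E->I}.
    """
    eff = ph_with_defect_exit(ph, mu)
    total = ph.a + mu
    C = np.zeros((ph.k, 2))
    active = total > VALIDATION_TOL
    C[active, 0] = ph.a[active] / total[active]
    C[active, 1] = mu / total[active]
    C[~active] = 0.5
    return AbsorptionSplit(eff, C, labels=["next", "dead"])
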