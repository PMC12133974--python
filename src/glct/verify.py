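"""Stochastic and dynamical cross-validation.

Three independent routes onto the same objects the rest of the package
computes analytically:

* draw absorption times and absorbing-state labels by simulating the
  underlying CTMC jump by jump (checks densities, moments, and absorption
  probabilities);
* integrate the assembled mean-field ODEs with a stiff-capable solver
  (checks conservation laws and the qualitative behaviour near equilibria);
* linearize at the disease-free / prey-only equilibrium and compare the
  sign of the leading Jacobian eigenvalue with the position of the
  reproduction number relative to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from glct.ctmc import AbsorptionSplit, embedded_chain
from glct.models import (
    PredPreyModel,
    SEIRSModel,
    disease_free_equilibrium,
    lump_totals,
    prey_only_equilibrium,
)
from glct.phasetype import VALIDATION_TOL
from glct.reproduction import classify_threshold, predprey_ngm, r0_seirs_closed


@dataclass
class SimulationConfig:
    """Knobs for sampling and integration runs."""

    n_samples: int = 20_000
    seed: int = 0
    t_max: float = 100.0
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be positive")


def sample_absorption(split: AbsorptionSplit, cfg: SimulationConfig):
    """Simulate the absorbing CTMC; returns (times, labels).

    Each sample starts in a transient state drawn from alpha (a defect is
    refused: mass at t = 0 has no transient path), accrues an exponential
    dwell at rate r_i per visited state, jumps according to the embedded
    chain, and exits to an absorbing state drawn from the corresponding row
    of C.  Bit-reproducible for a fixed seed.
    """
    ph = split.ph
    if ph.defect > VALIDATION_TOL:
        raise ValueError("sampling requires sum(alpha) = 1")
    rng = np.random.default_rng(cfg.seed)
    Q, q, r = embedded_chain(ph)
    times = np.empty(cfg.n_samples)
    labels = np.empty(cfg.n_samples, dtype=int)
    alpha = ph.alpha / ph.alpha.sum()
    for n in range(cfg.n_samples):
        state = rng.choice(ph.k, p=alpha)
        t = 0.0
        while True:
            t += rng.exponential(1.0 / r[state])
            if rng.random() < q[state]:
                labels[n] = rng.choice(split.m, p=split.C[state])
                break
            row = Q[state] / (1.0 - q[state])
            state = rng.choice(ph.k, p=row / row.sum())
        times[n] = t
    return times, labels


def integrate_model(model, initial, cfg: SimulationConfig, n_points: int = 201) -> pd.DataFrame:
    """Integrate the mean-field ODEs; returns a tidy trajectory table.

    Uses LSODA (stiff-capable) at the configured tolerances.  Columns are
    time, each named substate, and the lumped compartment totals.
    """
    initial = np.asarray(initial, dtype=float).ravel()
    if np.any(initial < 0):
        raise ValueError("initial state must be nonnegative")
    sol = solve_ivp(
        model.rhs,
        (0.0, cfg.t_max),
        initial,
        method="LSODA",
        rtol=cfg.rel_tol,
        atol=cfg.abs_tol,
        t_eval=np.linspace(0.0, cfg.t_max, n_points),
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    df = pd.DataFrame(sol.y.T, columns=model.state_names())
    df.insert(0, "time", sol.t)
    totals = pd.DataFrame([lump_totals(model, row) for row in sol.y.T])
    for col in totals.columns:
        if col not in df.columns:
            df[col] = totals[col].to_numpy()
    return df


def jacobian_fd(fun, x0, scale: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian of ``fun`` at ``x0``.

    Step per coordinate is ``scale * max(1, |x_i|)``; adequate for the
    smooth polynomial/rational right-hand sides assembled here.
    """
    x0 = np.asarray(x0, dtype=float).ravel()
    n = x0.size
    J = np.empty((n, n))
    for i in range(n):
        h = scale * max(1.0, abs(x0[i]))
        xp, xm = x0.copy(), x0.copy()
        xp[i] += h
        xm[i] -= h
        J[:, i] = (fun(xp) - fun(xm)) / (2.0 * h)
    return J


def equilibrium_jacobian(model) -> tuple[np.ndarray, np.ndarray]:
    """Equilibrium state and Jacobian there (DFE or prey-only)."""
    if isinstance(model, SEIRSModel):
        eq = disease_free_equilibrium(model)
    elif isinstance(model, PredPreyModel):
        eq = prey_only_equilibrium(model)
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    J = jacobian_fd(lambda s: model.rhs(0.0, s), eq)
    return eq, J


def stability_report(model, *, eig_tol: float = 1e-7) -> dict:
    """Reproduction number vs. local stability of the relevant equilibrium.

    Returns the reproduction number, the leading (largest real part)
    eigenvalue of the equilibrium Jacobian, the verdicts from both routes,
    and whether they agree.  Near the threshold both quantities pass
    through their critical values together, so "marginal" verdicts on
    either side are treated as concordant.
    """
    if isinstance(model, SEIRSModel):
        rho = r0_seirs_closed(model)[0]
    else:
        rho = predprey_ngm(model).rho
    _, J = equilibrium_jacobian(model)
    leading = float(np.max(np.real(np.linalg.eigvals(J))))
    r_verdict = classify_threshold(rho)
    if leading < -eig_tol:
        e_verdict = "stable"
    elif leading > eig_tol:
        e_verdict = "unstable"
    else:
        e_verdict = "marginal"
    concordant = (
        r_verdict == e_verdict or "marginal" in (r_verdict, e_verdict)
    )
    return {
        "reproduction_number": rho,
        "leading_eigenvalue": leading,
        "verdict_from_R": r_verdict,
        "verdict_from_eigenvalues": e_verdict,
        "concordant": bool(concordant),
    }


def bracket_sign_change(fun, lo: float, hi: float, tol: float, max_iter: int = 200):
    """Bisection: locate the sign change of ``fun`` on [lo, hi] to width tol.

    ``fun(lo)`` and ``fun(hi)`` must have opposite signs.  Returns the
    midpoint of the final bracket.
    """
    flo, fhi = fun(lo), fun(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if np.sign(flo) == np.sign(fhi):
        raise ValueError("no sign change on the bracket")
    for _ in range(max_iter):
        if hi - lo <= tol:
            break
        mid = 0.5 * (lo + hi)
        fmid = fun(mid)
        if fmid == 0.0:
            return mid
        if np.sign(fmid) == np.sign(flo):
            lo, flo = mid, fmid
        else:
            hi, fhi = mid, fmid
    return 0.5 * (lo + hi)
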