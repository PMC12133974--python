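"""Random, valid phase-type representations and model parameterizations.

These generators back the property tests and the `make-fixtures` command.
Parameter ranges are chosen to be epidemiologically / ecologically plausible
while exercising the full structural variety the theory covers: Erlang,
hypoexponential, and Coxian dwell-time blocks with 1-5 substates, dwell
rates spanning roughly two orders of magnitude around 1/time-unit, and
mortality rates small relative to dwell rates (as for human demography
against infection timescales).
"""

from __future__ import annotations

import numpy as np

from glct.models import PredPreyModel, SEIRSModel
from glct.phasetype import PhaseTypeRep, coxian, erlang, hypoexponential

KINDS = ("erlang", "hypoexponential", "coxian")


def random_phase_type(
    rng: np.random.Generator,
    k: int | None = None,
    kind: str | None = None,
    kmax: int = 5,
    max_defect: float = 0.0,
) -> PhaseTypeRep:
    """Draw a random valid phase-type block.

    Stage rates are log-uniform on [0.2, 5]; Coxian continuation
    probabilities uniform on [0.3, 1].  ``max_defect > 0`` scales alpha
    down by a uniform defect in [0, max_defect].
    """
    if kind is None:
        kind = KINDS[rng.integers(len(KINDS))]
    if k is None:
        k = int(rng.integers(1, kmax + 1))
    rates = np.exp(rng.uniform(np.log(0.2), np.log(5.0), size=k))
    if kind == "erlang":
        ph = erlang(k, rate=float(rates[0]))
    elif kind == "hypoexponential":
        ph = hypoexponential(rates)
    elif kind == "coxian":
        probs = rng.uniform(0.3, 1.0, size=k - 1)
        ph = coxian(rates, probs)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    if max_defect > 0.0:
        defect = rng.uniform(0.0, max_defect)
        ph = PhaseTypeRep(ph.alpha * (1.0 - defect), ph.A)
    return ph


def random_seirs(rng: np.random.Generator, kmax: int = 5) -> SEIRSModel:
    """Random SEIRS model with demography (mu > 0, so the DFE exists)."""
    phE = random_phase_type(rng, kmax=kmax)
    phI = random_phase_type(rng, kmax=kmax)
    phR = random_phase_type(rng, kmax=kmax)
    mu = float(rng.uniform(0.01, 0.3))
    Lambda = float(rng.uniform(1.0, 10.0))
    beta = rng.uniform(0.001, 0.05, size=phI.k)
    return SEIRSModel(phE, phI, phR, beta=beta, Lambda=Lambda, mu=mu)


def random_predprey(
    rng: np.random.Generator, kmax: int = 5, max_defect: float = 0.0
) -> PredPreyModel:
    """Random stage-structured predator-prey model."""
    phX = random_phase_type(rng, kmax=kmax, max_defect=max_defect)
    phY = random_phase_type(rng, kmax=kmax)
    return PredPreyModel(
        phX,
        phY,
        r=float(rng.uniform(0.5, 2.0)),
        K=float(rng.uniform(50.0, 500.0)),
        a=float(rng.uniform(0.5, 3.0)),
        h=float(rng.uniform(20.0, 200.0)),
        chi=float(rng.uniform(0.05, 0.8)),
        eta=float(rng.uniform(0.0, 1.0)),
    )


def random_model_config(rng: np.random.Generator, model_kind: str) -> dict:
    """A serializable config for a random model, for `make-fixtures`."""
    if model_kind == "seirs":
        m = random_seirs(rng)
        return {
            "model": "seirs",
            "blocks": {
                "latent": m.ph_latent.to_dict(),
                "infectious": m.ph_infectious.to_dict(),
                "immune": m.ph_immune.to_dict(),
            },
            "params": {
                "beta": m.beta.tolist(),
                "Lambda": m.Lambda,
                "mu": m.mu,
            },
            "initial_state": {
                "S": m.Lambda / m.mu * 0.99,
                "E": [0.0] * m.k_E,
                "I": [m.Lambda / m.mu * 0.01] + [0.0] * (m.k_I - 1),
                "R": [0.0] * m.k_R,
            },
        }
    if model_kind == "predprey":
        m = random_predprey(rng)
        return {
            "model": "predprey",
            "blocks": {
                "maturation": m.ph_maturation.to_dict(),
                "adult": m.ph_adult.to_dict(),
            },
            "params": {
                "r": m.r,
                "K": m.K,
                "a": m.a,
                "h": m.h,
                "chi": m.chi,
                "eta": m.eta,
            },
            "initial_state": {
                "N": m.K,
                "immature": [0.0] * m.k_i,
                "mature": [1.0] + [0.0] * (m.k_m - 1),
            },
        }
    raise ValueError(f"model_kind must be 'seirs' or 'predprey', got {model_kind!r}")
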