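"""Circular mixture models of continuous-report recall errors.

The standard mixture model (with bias) describes the distribution of
signed recall errors as

    (1 - P_u) * VM(e; mu, kappa) + P_u / 360

where VM is the von Mises density on degrees, ``mu`` the mean bias,
``kappa`` the concentration (reported as circular s.d. in degrees) and
``P_u`` the probability of a uniform random guess; ``P_m = 1 - P_u``
estimates the probability that the probed item was in memory.  The
three-component swap variant adds responses centered on the non-probed
items' feature values, sharing the target component's s.d.

Fitting is by maximum likelihood with multi-start bounded optimization,
deterministic for a given data set.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "MixtureFit",
    "sd_to_kappa",
    "kappa_to_sd",
    "vonmises_pdf_deg",
    "loglik_standard",
    "loglik_swap",
    "fit_standard_mixture",
    "fit_swap_mixture",
    "simulate_errors",
    "circular_sd_deg",
]

_DEG = np.pi / 180.0


def _A(kappa):
    """Mean resultant length of a von Mises: I1(kappa)/I0(kappa)."""
    return special.i1e(kappa) / special.i0e(kappa)


def sd_to_kappa(sd_deg: float) -> float:
    """Concentration kappa for a circular s.d. given in degrees.

    Uses the standard mapping sd = sqrt(-2 ln R) with R = A(kappa);
    inverted numerically.
    """
    if sd_deg <= 0:
        raise ValueError("sd must be positive")
    r = float(np.exp(-0.5 * (sd_deg * _DEG) ** 2))
    if r >= 1.0 - 1e-12:
        return 1e8
    if r < 1e-9:
        return 1e-9
    lo, hi = 1e-9, 1e9
    return float(optimize.brentq(lambda k: _A(k) - r, lo, hi, xtol=1e-12, rtol=1e-14))


def kappa_to_sd(kappa: float) -> float:
    """Circular s.d. in degrees of a von Mises with concentration kappa."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    r = float(_A(kappa))
    return float(np.sqrt(-2.0 * np.log(r)) / _DEG)


def vonmises_pdf_deg(e_deg, mu_deg: float, kappa: float):
    """Von Mises density per degree on the 360-degree circle."""
    z = np.cos((np.asarray(e_deg, dtype=float) - mu_deg) * _DEG)
    # exp(kappa cos) / (2 pi I0(kappa)), expressed with i0e for stability
    return np.exp(kappa * (z - 1.0)) / (2.0 * np.pi * special.i0e(kappa)) * _DEG


def circular_sd_deg(e_deg) -> float:
    """Empirical circular s.d. (degrees) of a sample of angles."""
    ang = np.asarray(e_deg, dtype=float) * _DEG
    r = np.abs(np.mean(np.exp(1j * ang)))
    return float(np.sqrt(-2.0 * np.log(r)) / _DEG)


def _check_params(mu, sd, p_uniform, p_nontarget=0.0):
    if not sd > 0:
        raise ValueError("sd must be > 0")
    if not (0.0 <= p_uniform <= 1.0) or not (0.0 <= p_nontarget <= 1.0):
        raise ValueError("mixture probabilities must lie in [0, 1]")
    if p_uniform + p_nontarget > 1.0 + 1e-12:
        raise ValueError("mixture probabilities must sum to <= 1")


def loglik_standard(errors, mu: float, sd: float, p_uniform: float) -> float:
    """Log likelihood (nats) of errors under the standard mixture model."""
    _check_params(mu, sd, p_uniform)
    e = np.asarray(errors, dtype=float)
    kappa = sd_to_kappa(sd)
    dens = (1.0 - p_uniform) * vonmises_pdf_deg(e, mu, kappa) + p_uniform / 360.0
    return float(np.sum(np.log(np.maximum(dens, 1e-300))))


def loglik_swap(
    errors, nontarget_offsets, mu: float, sd: float, p_uniform: float, p_nontarget: float
) -> float:
    """Log likelihood under the three-component swap model.

    ``nontarget_offsets`` is an (n_trials, n_nontargets) array of the
    non-probed items' signed offsets from the target; the non-target
    component is a von Mises (same s.d., same bias) centered on each
    offset, averaged over the non-targets of a trial.
    """
    _check_params(mu, sd, p_uniform, p_nontarget)
    e = np.asarray(errors, dtype=float)
    off = np.atleast_2d(np.asarray(nontarget_offsets, dtype=float))
    if off.shape[0] != e.size:
        raise ValueError("one row of non-target offsets required per error")
    kappa = sd_to_kappa(sd)
    p_target = 1.0 - p_uniform - p_nontarget
    dens = p_target * vonmises_pdf_deg(e, mu, kappa) + p_uniform / 360.0
    nt = vonmises_pdf_deg(e[:, None] - off, mu, kappa).mean(axis=1)
    dens = dens + p_nontarget * nt
    return float(np.sum(np.log(np.maximum(dens, 1e-300))))


@dataclass
class MixtureFit:
    mu: float
    sd: float
    p_uniform: float
    p_nontarget: float
    loglik: float
    converged: bool
    n: int

    @property
    def p_m(self) -> float:
        return 1.0 - self.p_uniform - self.p_nontarget

    def to_dict(self) -> dict:
        d = asdict(self)
        d["p_m"] = self.p_m
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


_START_MU = (-20.0, 0.0, 20.0)
_START_SD = (10.0, 25.0, 50.0)
_START_PU = (0.05, 0.3)

# sd capped at 100 deg: beyond that a von Mises is operationally
# indistinguishable from the uniform component (standard convention)
_BOUNDS = {"mu": (-180.0, 180.0), "sd": (1.0, 100.0), "p": (0.0, 1.0)}


def fit_standard_mixture(errors, min_n: int = 20) -> MixtureFit:
    """MLE of the standard mixture model (with bias).

    Multi-start L-BFGS-B over (mu, sd, P_u); deterministic for a given
    sample.  Requires at least ``min_n`` responses.
    """
    e = np.asarray(errors, dtype=float)
    if e.size < min_n:
        raise ValueError(f"need at least {min_n} responses, got {e.size}")
    if np.allclose(e, e[0]):
        warnings.warn("degenerate (constant) error sample: boundary fit")
        return MixtureFit(float(e[0]), _BOUNDS["sd"][0], 0.0, 0.0,
                          loglik_standard(e, float(e[0]), _BOUNDS["sd"][0], 0.0),
                          False, int(e.size))

    def nll(x):
        mu, sd, pu = x
        return -loglik_standard(e, mu, sd, pu)

    best = None
    for mu0, sd0, pu0 in itertools.product(_START_MU, _START_SD, _START_PU):
        res = optimize.minimize(
            nll,
            x0=[mu0, sd0, pu0],
            method="L-BFGS-B",
            bounds=[_BOUNDS["mu"], _BOUNDS["sd"], (0.0, 1.0 - 1e-9)],
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    mu, sd, pu = best.x
    mu = float(((mu + 180.0) % 360.0) - 180.0)  # wrap into [-180, 180)
    # boundary-degeneracy guard: a von Mises at the sd cap mimics the
    # uniform component; keep the mixture only if its likelihood gain
    # justifies the three extra parameters (AIC), else report guessing
    ll_fit = -float(best.fun)
    ll_unif = e.size * float(np.log(1.0 / 360.0))
    if sd >= _BOUNDS["sd"][1] - 1e-6 and 2.0 * (ll_fit - ll_unif) < 6.0:
        return MixtureFit(0.0, float(sd), 1.0, 0.0, ll_unif, True, int(e.size))
    return MixtureFit(mu, float(sd), float(pu), 0.0, ll_fit,
                      bool(best.success), int(e.size))


def fit_swap_mixture(
    errors, nontarget_offsets, fix_p_nontarget: Optional[float] = None, min_n: int = 20
) -> MixtureFit:
    """MLE of the three-component swap model.

    ``fix_p_nontarget`` pins the non-target probability (0 recovers the
    standard fit up to optimizer tolerance).
    """
    e = np.asarray(errors, dtype=float)
    if nontarget_offsets is None:
        raise ValueError("swap model requires per-trial non-target offsets")
    off = np.atleast_2d(np.asarray(nontarget_offsets, dtype=float))
    if e.size < min_n:
        raise ValueError(f"need at least {min_n} responses, got {e.size}")

    if fix_p_nontarget is not None:
        pn_fixed = float(fix_p_nontarget)

        def nll(x):
            mu, sd, pu = x
            if pu + pn_fixed > 1.0:
                return 1e12
            return -loglik_swap(e, off, mu, sd, pu, pn_fixed)

        best = None
        for mu0, sd0, pu0 in itertools.product(_START_MU, _START_SD, _START_PU):
            res = optimize.minimize(
                nll, x0=[mu0, sd0, pu0], method="L-BFGS-B",
                bounds=[_BOUNDS["mu"], _BOUNDS["sd"], (0.0, 1.0 - pn_fixed - 1e-9)],
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        mu, sd, pu = best.x
        return MixtureFit(float(mu), float(sd), float(pu), pn_fixed,
                          -float(best.fun), bool(best.success), int(e.size))

    def nll(x):
        mu, sd, pu, pn = x
        if pu + pn > 1.0:
            return 1e12
        return -loglik_swap(e, off, mu, sd, pu, pn)

    best = None
    for mu0, sd0, pu0 in itertools.product(_START_MU, _START_SD, _START_PU):
        for pn0 in (0.02, 0.15):
            res = optimize.minimize(
                nll, x0=[mu0, sd0, pu0, pn0], method="L-BFGS-B",
                bounds=[_BOUNDS["mu"], _BOUNDS["sd"], (0.0, 1.0), (0.0, 1.0)],
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
    mu, sd, pu, pn = best.x
    return MixtureFit(float(mu), float(sd), float(pu), float(pn),
                      -float(best.fun), bool(best.success), int(e.size))


def simulate_errors(
    mu: float,
    sd: float,
    p_m: float,
    n: int,
    rng: np.random.Generator,
    p_nontarget: float = 0.0,
    offsets: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """Sample signed errors (degrees) from the generative mixture model.

    With probability ``p_m`` the response comes from the target von
    Mises, with ``p_nontarget`` from a von Mises centered on a randomly
    chosen non-target offset, otherwise from the uniform guess
    distribution.
    """
    if not (0.0 <= p_m <= 1.0 and 0.0 <= p_nontarget <= 1.0 and p_m + p_nontarget <= 1.0):
        raise ValueError("invalid mixture probabilities")
    if p_nontarget > 0 and offsets is None:
        raise ValueError("offsets required when p_nontarget > 0")
    kappa = sd_to_kappa(sd)
    comp = rng.choice(3, size=n, p=[p_m, p_nontarget, 1.0 - p_m - p_nontarget])
    vm = rng.vonmises(0.0, kappa, size=n) / _DEG
    out = np.empty(n)
    target = comp == 0
    out[target] = mu + vm[target]
    nont = comp == 1
    if nont.any():
        offs = np.asarray(offsets, dtype=float)
        pick = rng.integers(offs.size, size=int(nont.sum()))
        out[nont] = mu + offs[pick] + vm[nont]
    guess = comp == 2
    out[guess] = rng.uniform(-180.0, 180.0, size=int(guess.sum()))
    return ((out + 180.0) % 360.0) - 180.0
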