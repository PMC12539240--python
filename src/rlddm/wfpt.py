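"""Wiener first-passage-time (WFPT) density and diffusion-path simulation.

The decision stage of the model is a one-dimensional Wiener diffusion with
unit diffusion coefficient, drift ``v``, absorbing boundaries at 0 and ``a``,
and relative start point ``z`` (absolute start ``z * a``).  Hitting the upper
boundary codes a *left* choice, the lower boundary a *right* choice.

Two complementary routes to the first-passage distribution are provided:

* :func:`wfpt_density` — the analytic infinite-series density, evaluated with
  adaptive truncation using whichever of the small-time or large-time series
  needs fewer terms at the requested tolerance.
* :func:`simulate_trial` / :func:`simulate_paths` — Euler–Maruyama simulation
  of the path itself, with a Brownian-bridge correction for boundary
  crossings inside a time step (removes the O(sqrt(dt)) absorption bias).

Keeping both routes independent lets each validate the other.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = [
    "wfpt_density",
    "wfpt_cdf",
    "prob_upper",
    "simulate_trial",
    "simulate_paths",
]

DEFAULT_TOL = 1e-10


@njit(cache=True)
def _density_lower(t: float, v: float, a: float, z: float, tol: float) -> float:
    """Density of first passage through the LOWER boundary at decision time t.

    Series selection follows the standard small-time / large-time expansions
    of the zero-drift density on normalized time tt = t / a**2, with the drift
    entering through the exponential prefactor exp(-v*a*z - v**2 * t / 2).
    """
    tt = t / (a * a)
    w = z
    lead = math.exp(-v * a * w - 0.5 * v * v * t)
    if lead <= 0.0 or tt <= 0.0:
        return 0.0
    # tolerance on the normalized density implied by an absolute tolerance on f
    eps = tol * a * a / lead
    if eps <= 0.0:
        eps = 1e-300

    # number of terms needed by each series (Navarro-Fuss style bounds)
    if math.pi * tt * eps < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tt * eps) / (math.pi * math.pi * tt))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(tt)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(tt))
    if 2.0 * math.sqrt(2.0 * math.pi * tt) * eps < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tt * math.log(2.0 * eps * math.sqrt(2.0 * math.pi * tt)))
        ks = max(ks, math.sqrt(tt) + 1.0)
    else:
        ks = 2.0

    if ks < kl:  # small-time expansion
        K = int(math.ceil(ks))
        half = (K - 1) // 2 + 1
        s = 0.0
        for k in range(-half, half + 1):
            wk = w + 2.0 * k
            s += wk * math.exp(-wk * wk / (2.0 * tt))
        p = s / math.sqrt(2.0 * math.pi * tt * tt * tt)
    else:  # large-time expansion
        K = int(math.ceil(kl))
        s = 0.0
        for k in range(1, K + 1):
            s += k * math.exp(-k * k * math.pi * math.pi * tt / 2.0) * math.sin(k * math.pi * w)
        p = math.pi * s
    f = p * lead / (a * a)
    return f if f > 0.0 else 0.0


@njit(cache=True)
def _density(t: float, v: float, a: float, z: float, upper: bool, tol: float) -> float:
    if upper:
        # reflection: upper-boundary passage of (v, z) equals lower-boundary
        # passage of (-v, 1 - z)
        return _density_lower(t, -v, a, 1.0 - z, tol)
    return _density_lower(t, v, a, z, tol)


def wfpt_density(
    t_dec,
    v: float,
    a: float,
    z: float = 0.5,
    boundary: str = "upper",
    tol: float = DEFAULT_TOL,
):
    """First-passage density (1/s) at decision time ``t_dec`` (scalar or array).

    Parameters
    ----------
    t_dec : float or array
        Decision time(s) in seconds, strictly positive (RT minus non-decision
        time).
    v : float
        Drift rate (evidence/s); positive drift favours the upper boundary.
    a : float
        Boundary separation (> 0).
    z : float
        Relative start point in (0, 1); 0.5 is unbiased.
    boundary : {"upper", "lower"}
        Which absorbing boundary the density refers to (upper = left choice).
    tol : float
        Absolute truncation tolerance of the series.
    """
    if a <= 0.0:
        raise ValueError("boundary separation a must be > 0")
    if not 0.0 < z < 1.0:
        raise ValueError("relative start point z must lie in (0, 1)")
    if boundary not in ("upper", "lower"):
        raise ValueError(f"unknown boundary {boundary!r}")
    upper = boundary == "upper"
    t_arr = np.asarray(t_dec, dtype=float)
    if np.any(t_arr <= 0.0):
        raise ValueError("decision time t_dec must be > 0")
    if t_arr.ndim == 0:
        return _density(float(t_arr), v, a, z, upper, tol)
    out = np.empty(t_arr.shape, dtype=float)
    flat = t_arr.ravel()
    oflat = out.ravel()
    for i in range(flat.size):
        oflat[i] = _density(flat[i], v, a, z, upper, tol)
    return out


def wfpt_cdf(
    t_dec: float,
    v: float,
    a: float,
    z: float = 0.5,
    boundary: str = "upper",
    tol: float = DEFAULT_TOL,
) -> float:
    """Defective CDF: probability of hitting ``boundary`` before ``t_dec``.

    Computed by adaptive quadrature of :func:`wfpt_density`; the limit as
    ``t_dec`` grows is the choice probability of that boundary.
    """
    from scipy.integrate import quad

    if t_dec <= 0.0:
        return 0.0
    val, _ = quad(
        lambda t: wfpt_density(t, v, a, z, boundary, tol),
        0.0,
        t_dec,
        limit=200,
    )
    return float(val)


def prob_upper(v: float, a: float, z: float = 0.5) -> float:
    """Closed-form probability of absorption at the upper boundary.

    For drift v, boundaries {0, a} and absolute start z*a:
    ``P(upper) = (1 - exp(-2 v z a)) / (1 - exp(-2 v a))`` with the zero-drift
    limit ``z``.
    """
    x = 2.0 * v * a
    if abs(x) < 1e-9:
        return z
    return float(np.expm1(-2.0 * v * z * a) / np.expm1(-x))


@njit(cache=True)
def _simulate_paths(
    n: int,
    v: float,
    a: float,
    z: float,
    dt: float,
    max_t: float,
    seed: int,
):
    """Euler-Maruyama first-passage sampling with Brownian-bridge crossing check.

    Returns (boundaries, times): boundary 1 = upper, 0 = lower, -1 = censored
    at max_t; times are decision times in seconds.
    """
    np.random.seed(seed)
    boundaries = np.empty(n, dtype=np.int8)
    times = np.empty(n, dtype=np.float64)
    sq = math.sqrt(dt)
    for i in range(n):
        x = z * a
        t = 0.0
        b = np.int8(-1)
        while t < max_t:
            xn = x + v * dt + sq * np.random.standard_normal()
            t += dt
            if xn >= a:
                b = np.int8(1)
                break
            if xn <= 0.0:
                b = np.int8(0)
                break
            # probability the continuous bridge crossed a boundary inside the
            # step; skip the draw when it is negligible (< exp(-30))
            eu = 2.0 * (a - x) * (a - xn) / dt
            if eu < 30.0 and np.random.random() < math.exp(-eu):
                b = np.int8(1)
                break
            el = 2.0 * x * xn / dt
            if el < 30.0 and np.random.random() < math.exp(-el):
                b = np.int8(0)
                break
            x = xn
        boundaries[i] = b
        times[i] = t
    return boundaries, times


def simulate_paths(
    n: int,
    v: float,
    a: float,
    z: float = 0.5,
    dt: float = 1e-4,
    max_t: float = 60.0,
    seed: int = 0,
):
    """Sample ``n`` first-passage outcomes; see :func:`_simulate_paths`."""
    if a <= 0.0 or not 0.0 < z < 1.0 or dt <= 0.0:
        raise ValueError("invalid diffusion parameters")
    return _simulate_paths(int(n), float(v), float(a), float(z), float(dt), float(max_t), int(seed))


def simulate_trial(
    v: float,
    a: float,
    tau: float,
    z: float = 0.5,
    response_window: float = 5.45,
    seed: int = 0,
    dt: float = 1e-3,
):
    """Simulate a single trial outcome.

    Returns ``(response, rt)`` with response in {"left", "right"} and rt in
    seconds from stimulus onset, or ``(None, None)`` for an omission (the
    decision did not complete within the response window).
    """
    if response_window <= tau:
        raise ValueError("response_window must exceed the non-decision time")
    b, t = _simulate_paths(1, float(v), float(a), float(z), float(dt), float(response_window - tau), int(seed))
    if b[0] < 0:
        return None, None
    rt = tau + float(t[0])
    if rt > response_window:
        return None, None
    return ("left" if b[0] == 1 else "right"), rt
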