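"""Equilibrium and kinetic RNA-binding fits: Hill isotherm (anisotropy
titrations and EMSA fraction-bound), single-exponential strand release, and
an exact mass-balance solver for competition equilibria.

The Hill fit deliberately neglects ligand depletion (labeled RNA is nM-scale
against uM-scale dissociation constants); the competition solver does not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .core import RibofateError

logger = logging.getLogger(__name__)

HILL_H_BOUNDS = (0.3, 4.0)
N_MULTISTART = 5


@dataclass
class FitResult:
    model: str  # 'hill' or 'exp_decay'
    params: dict[str, float]
    stderr: dict[str, float]
    converged: bool
    diagnostics: dict = field(default_factory=dict)

    @property
    def half_life(self) -> float:
        if self.model != "exp_decay":
            raise RibofateError("half_life defined only for exp_decay fits")
        return np.log(2) / self.params["k"]


def anisotropy_change(raw: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Convert raw anisotropy to changes relative to the zero-protein point.

    The baseline is the mean raw anisotropy at x == 0; its absence is fatal.
    Dips more than 0.02 below baseline are flagged (photophysics artifact).
    """
    raw = np.asarray(raw, dtype=float)
    x = np.asarray(x, dtype=float)
    zero = x == 0
    if not zero.any():
        raise RibofateError("no zero-protein baseline point in titration")
    baseline = raw[zero].mean()
    delta = raw - baseline
    if (delta < -0.02).any():
        logger.warning("anisotropy drops > 0.02 below baseline: possible artifact")
    return delta


def _hill(x, baseline, amplitude, kd, h):
    xh = np.power(x, h, where=x > 0, out=np.zeros_like(np.asarray(x, dtype=float)))
    return baseline + amplitude * xh / (kd**h + xh)


def _at_bound(value, lo, hi, rtol=1e-6):
    span = hi - lo if np.isfinite(hi - lo) else max(abs(value), 1.0)
    return (abs(value - lo) < rtol * max(span, 1e-300)) or (
        np.isfinite(hi) and abs(value - hi) < rtol * span
    )


def fit_hill(x, y, fix_h: float | None = None) -> FitResult:
    """Least-squares Hill fit y = baseline + amplitude * x^h / (KD^h + x^h).

    Multi-start from log-spaced KD guesses; h bounded to [0.3, 4] (or fixed).
    ``converged`` is False when the optimizer pins a parameter at a bound,
    when the fit fails, or when the data show no binding signal (maximum
    signal at the lowest concentration, or zero dynamic range).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x, kind="mergesort")
    x, y = x[order], y[order]
    if np.unique(x).size < 5:
        raise RibofateError("need >= 5 distinct concentrations")

    # per-concentration means for signal-shape diagnostics
    ux = np.unique(x)
    uy = np.array([y[x == v].mean() for v in ux])
    no_signal = np.ptp(uy) == 0 or np.argmax(uy) == 0

    xpos = x[x > 0]
    kd_guesses = np.geomspace(xpos.min(), xpos.max(), N_MULTISTART)
    amp0 = max(np.ptp(uy), 1e-12)
    kd_lo, kd_hi = xpos.min() * 1e-4, xpos.max() * 1e4
    if fix_h is None:
        lo = [-np.inf, 1e-12, kd_lo, HILL_H_BOUNDS[0]]
        hi = [np.inf, np.inf, kd_hi, HILL_H_BOUNDS[1]]
        names = ["baseline", "amplitude", "kd", "hill_h"]
        model = _hill
    else:
        lo = [-np.inf, 1e-12, kd_lo]
        hi = [np.inf, np.inf, kd_hi]
        names = ["baseline", "amplitude", "kd"]
        model = lambda xx, b, a, kd: _hill(xx, b, a, kd, fix_h)  # noqa: E731

    best = None
    for kd0 in kd_guesses:
        p0 = [uy[0], amp0, kd0] + ([] if fix_h is not None else [1.0])
        try:
            popt, pcov = optimize.curve_fit(
                model, x, y, p0=p0, bounds=(lo, hi), maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        ssr = float(np.sum((model(x, *popt) - y) ** 2))
        if best is None or ssr < best[2]:
            best = (popt, pcov, ssr)
    if best is None:
        return FitResult("hill", {}, {}, False, {"reason": "optimizer failed"})
    popt, pcov, ssr = best
    params = dict(zip(names, (float(v) for v in popt)))
    if fix_h is not None:
        params["hill_h"] = float(fix_h)
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    stderr = dict(zip(names, (float(v) for v in se)))
    at_bound = any(
        _at_bound(v, l, h) for v, l, h in zip(popt, lo, hi) if np.isfinite(l)
    )
    converged = not (no_signal or at_bound)
    return FitResult(
        "hill",
        params,
        stderr,
        converged,
        {"ssr": ssr, "no_signal": bool(no_signal), "at_bound": bool(at_bound)},
    )


def fit_exp_decay(t, y) -> FitResult:
    """Least-squares fit of y = plateau + amplitude * exp(-k t).

    Returns rate constant k and half-life ln2/k; ``converged`` is False for
    increasing signals or optimizer failure.  The plateau is left free.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(t, kind="mergesort")
    t, y = t[order], y[order]
    if np.unique(t).size < 5:
        raise RibofateError("need >= 5 time points")
    if t.min() > 0:
        raise RibofateError("t0 (time zero) point required")

    ut = np.unique(t)
    uy = np.array([y[t == v].mean() for v in ut])
    increasing = uy[-1] > uy[0]

    span = t.max() - t.min()
    amp0 = max(uy[0] - uy[-1], 1e-12)
    best = None
    for k0 in np.geomspace(0.1 / span, 50.0 / span, N_MULTISTART):
        try:
            popt, pcov = optimize.curve_fit(
                lambda tt, plateau, amp, k: plateau + amp * np.exp(-k * tt),
                t, y,
                p0=[uy[-1], amp0, k0],
                bounds=([-np.inf, 1e-12, 1e-12], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        ssr = float(np.sum((popt[0] + popt[1] * np.exp(-popt[2] * t) - y) ** 2))
        if best is None or ssr < best[2]:
            best = (popt, pcov, ssr)
    if best is None:
        return FitResult("exp_decay", {}, {}, False, {"reason": "optimizer failed"})
    popt, pcov, ssr = best
    names = ["plateau", "amplitude", "k"]
    params = dict(zip(names, (float(v) for v in popt)))
    params["t_half"] = float(np.log(2) / params["k"])
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    stderr = dict(zip(names, (float(v) for v in se)))
    return FitResult(
        "exp_decay", params, stderr, not increasing, {"ssr": ssr}
    )


def solve_competition_equilibrium(
    P_total: float,
    RL_total: float,
    RC_total: float,
    KD_L: float,
    KD_C: float,
) -> dict[str, float]:
    """Exact two-RNA competition equilibrium by free-protein mass balance.

    Solves P_total = P_free * (1 + RL_total/(KD_L + P_free)
    + RC_total/(KD_C + P_free)); the left side is strictly increasing in
    P_free, so the positive root is bracketed on [0, P_total].  Returns the
    bound fractions of both RNAs and the free concentrations.
    """
    for name, v in [("P_total", P_total), ("KD_L", KD_L), ("KD_C", KD_C)]:
        if v <= 0:
            raise RibofateError(f"{name} must be positive")
    if RL_total < 0 or RC_total < 0:
        raise RibofateError("RNA totals must be non-negative")

    def balance(pf):
        return (
            pf * (1.0 + RL_total / (KD_L + pf) + RC_total / (KD_C + pf)) - P_total
        )

    p_free, res = optimize.brentq(
        balance, 0.0, P_total, xtol=1e-300, rtol=8.9e-16, maxiter=300,
        full_output=True,
    )
    if not res.converged:
        raise RibofateError("competition equilibrium solver did not converge")
    frac_labeled = p_free / (KD_L + p_free)
    frac_comp = p_free / (KD_C + p_free)
    return {
        "P_free": p_free,
        "frac_labeled_bound": frac_labeled,
        "frac_competitor_bound": frac_comp,
        "RL_free": RL_total * (1 - frac_labeled),
        "RC_free": RC_total * (1 - frac_comp),
    }


def fit_competition(conc, fraction_bound) -> FitResult:
    """Apparent-KD Hill fit of fraction bound vs protein concentration at a
    fixed competitor excess."""
    y = np.asarray(fraction_bound, dtype=float)
    if ((y < -0.05) | (y > 1.05)).any():
        raise RibofateError("fraction bound outside the [0, 1] tolerance band")
    result = fit_hill(conc, y)
    if result.params:
        result.params["apparent_kd"] = result.params["kd"]
    return result
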