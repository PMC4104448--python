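"""Equilibrium binding analysis: one-site saturation fits of SPR series.

The steady-state response R at analyte concentration C follows the
one-site saturation isotherm R = Rmax * C / (Kd + C); Kd (the equilibrium
dissociation constant) is the concentration at half-maximal response.
Competition conditions (e.g. 2 mM mannose 6-phosphate in the running
buffer) are metadata labels on the series, each analyzed as an
independent saturation — or called not-detectable when no
concentration-dependent saturation rises above noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .sim import BindingSeries

__all__ = [
    "BindingFit",
    "one_site_model",
    "fit_one_site",
    "detectability_call",
]


@dataclass(frozen=True)
class BindingFit:
    """One-site saturation fit of a concentration-response series."""

    kd: float
    rmax: float
    kd_se: float
    rmax_se: float
    r_squared: float
    converged: bool
    flags: tuple[str, ...] = ()


def one_site_model(concentration, kd: float, rmax: float):
    """R = rmax * C / (kd + C): 0 at C = 0, rmax/2 at C = kd, -> rmax."""
    if kd <= 0:
        raise ValueError("kd must be > 0")
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0) or rmax < 0:
        raise ValueError("concentrations and rmax must be >= 0")
    return rmax * c / (kd + c)


def _initial_guess(c: np.ndarray, r: np.ndarray) -> tuple[float, float]:
    """Deterministic start: rmax at the maximal response, kd at the sampled
    concentration whose response is nearest half-maximal."""
    rmax0 = float(np.max(r))
    if rmax0 <= 0:
        rmax0 = 1.0
    pos = c > 0
    if pos.any():
        kd0 = float(c[pos][np.argmin(np.abs(r[pos] - rmax0 / 2.0))])
    else:
        kd0 = 1.0
    return max(kd0, 1e-9), rmax0


def fit_one_site(series: BindingSeries) -> BindingFit:
    """Nonlinear least-squares fit of the one-site saturation model.

    Deterministic given the series. Warns (via flags) when fewer than 4
    distinct concentrations are available or when they do not bracket the
    fitted Kd; a fitted Kd more than 10x outside the sampled concentration
    range, or a failed optimization, is flagged rather than raised.
    """
    c = series.concentrations
    r = series.responses
    flags: list[str] = []
    if np.unique(c).size < 4:
        flags.append("fewer than 4 distinct concentrations")
    kd0, rmax0 = _initial_guess(c, r)
    try:
        popt, pcov = curve_fit(
            lambda x, kd, rmax: rmax * x / (kd + x),
            c,
            r,
            p0=[kd0, rmax0],
            bounds=([1e-12, 0.0], [np.inf, np.inf]),
            maxfev=10000,
        )
        converged = bool(np.all(np.isfinite(popt)))
    except (RuntimeError, ValueError):
        return BindingFit(
            kd=float("nan"),
            rmax=float("nan"),
            kd_se=float("nan"),
            rmax_se=float("nan"),
            r_squared=float("nan"),
            converged=False,
            flags=tuple(flags + ["optimization failed"]),
        )
    kd, rmax = float(popt[0]), float(popt[1])
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    resid = r - rmax * c / (kd + c)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    cmax = float(c.max()) if c.size else 0.0
    cmin_pos = float(c[c > 0].min()) if (c > 0).any() else 0.0
    if cmax > 0 and (kd > 10 * cmax or (cmin_pos > 0 and kd < cmin_pos / 10)):
        flags.append("kd outside the sampled concentration range by >10x")
    elif cmax > 0 and not (c.min() <= kd <= cmax):
        flags.append("sampled concentrations do not bracket kd")
    return BindingFit(
        kd=kd,
        rmax=rmax,
        kd_se=float(se[0]),
        rmax_se=float(se[1]),
        r_squared=r2,
        converged=converged,
        flags=tuple(flags),
    )


def detectability_call(
    series: BindingSeries,
    threshold: float | None = None,
    alpha: float = 0.01,
) -> str:
    """Classify a series as ``"binding"`` or ``"not-detectable"``.

    A condition is not-detectable when the maximal response falls below
    ``threshold`` (if given), or when the one-site fit fails, or when it
    does not improve significantly on a zero-response model (extra-sum-of-
    squares F-test at level ``alpha``) — the situation of a competed or
    deglycosylation-ablated interaction whose response is flat noise.
    """
    r = series.responses
    if threshold is not None and float(np.max(np.abs(r))) < threshold:
        return "not-detectable"
    if np.allclose(r, 0.0):
        return "not-detectable"
    fit = fit_one_site(series)
    if not fit.converged or not math.isfinite(fit.kd):
        return "not-detectable"
    n = r.size
    if n <= 2:
        return "not-detectable"
    ss0 = float(np.sum(r**2))
    ss1 = float(np.sum((r - one_site_model(series.concentrations, fit.kd, fit.rmax)) ** 2))
    if ss1 <= 0:  # perfect fit
        return "binding"
    f_stat = ((ss0 - ss1) / 2.0) / (ss1 / (n - 2))
    p = float(stats.f.sf(max(f_stat, 0.0), 2, n - 2))
    return "binding" if p < alpha else "not-detectable"
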