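"""Whole-cell modulus estimation from micropipette aspiration traces.

The half-space punch model for micropipette aspiration relates the
normalized aspiration length L_n = (L_p - L_0)/R_p to the suction
pressure through the cell's Young's modulus:

    L_n = (3 Phi / 2 pi) * dP / E        (elastic, ramp experiment)

where Phi is the pipette wall function (about 2.1 for typical wall
thickness ratios).  Inverting a least-squares slope of dP against L_n
yields E.  For creep at constant suction the standard-linear-solid
extension gives an exponential approach

    L_n(t) = L_inf (1 - a exp(-t / tau)),

from which the long-time and instantaneous moduli and the apparent
viscosity follow:

    k1 = 3 Phi dP / (2 pi L_inf),  k2 = a k1 / (1 - a),
    mu = tau k1 k2 / (k1 + k2) = tau k1 a.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = ["ModulusEstimate", "theret_elastic", "theret_viscous", "DEFAULT_PHI"]

DEFAULT_PHI = 2.1


@dataclass
class ModulusEstimate:
    """Result of a Theret-model fit.

    ``elastic_modulus`` in the pressure units of the trace;
    ``viscous_modulus`` in pressure * time units; standard errors are
    propagated from the fit.  ``phi`` records the wall function used and
    ``window`` the L_p/R_p fit window.
    """

    elastic_modulus: float | None = None
    elastic_se: float | None = None
    viscous_modulus: float | None = None
    viscous_se: float | None = None
    phi: float = DEFAULT_PHI
    window: tuple | None = None
    details: dict = field(default_factory=dict)


def theret_elastic(trace, phi: float = DEFAULT_PHI, window=(0.2, 1.0)) -> ModulusEstimate:
    """Elastic modulus from a pressure-ramp aspiration trace.

    Fits dP versus L_n by ordinary least squares inside the window on
    L_p/R_p (pass ``window=None`` to use every sample) and returns
    E = (3 phi / 2 pi) * slope.
    """
    if not (2.0 <= phi <= 2.2):
        raise ValueError("wall function phi outside its admissible range [2.0, 2.2]")
    ln = np.asarray(trace.normalized_length())
    dp = np.asarray(trace.pressure)
    lp_over_rp = np.asarray(trace.aspiration_length) / trace.r_p
    if window is not None:
        sel = (lp_over_rp >= window[0]) & (lp_over_rp <= window[1])
    else:
        sel = np.ones_like(ln, dtype=bool)
    sel &= np.isfinite(ln) & np.isfinite(dp)
    if sel.sum() < 5:
        raise ValueError(
            f"only {int(sel.sum())} samples in the fit window; need at least 5"
        )
    fit = stats.linregress(ln[sel], dp[sel])
    factor = 3.0 * phi / (2.0 * np.pi)
    return ModulusEstimate(
        elastic_modulus=factor * fit.slope,
        elastic_se=factor * fit.stderr,
        phi=phi,
        window=window,
        details={"slope": fit.slope, "intercept": fit.intercept, "r2": fit.rvalue**2,
                 "n": int(sel.sum())},
    )


def _creep_model(t, l_inf, a, tau):
    return l_inf * (1.0 - a * np.exp(-t / tau))


def theret_viscous(trace, phi: float = DEFAULT_PHI) -> ModulusEstimate:
    """Apparent viscosity from a constant-pressure creep trace.

    Fits L_n(t) = L_inf (1 - a e^(-t/tau)) and reports
    mu = tau * k1 * a with k1 = 3 phi dP / (2 pi L_inf), the
    standard-linear-solid creep relation for the half-space model.
    """
    if not (2.0 <= phi <= 2.2):
        raise ValueError("wall function phi outside its admissible range [2.0, 2.2]")
    t = np.asarray(trace.time, dtype=float)
    t = t - t[0]  # clock starts at creep onset
    ln = np.asarray(trace.normalized_length(), dtype=float)
    dp = float(np.median(trace.pressure))
    if len(t) < 5:
        raise ValueError("need at least 5 creep samples")
    # creep must actually creep: late mean above early mean
    n3 = max(2, len(ln) // 3)
    if ln[-n3:].mean() <= ln[:n3].mean():
        raise ValueError("non-monotone trace: no creep response to fit")
    l_inf0 = max(ln[-n3:].mean(), 1e-9)
    a0 = min(0.95, max(0.05, 1.0 - max(ln[0], 1e-9) / l_inf0))
    tau0 = max((t[-1] - t[0]) / 5.0, np.finfo(float).tiny)
    popt, pcov = optimize.curve_fit(
        _creep_model, t, ln, p0=(l_inf0, a0, tau0),
        bounds=([1e-12, 1e-6, 1e-12], [np.inf, 1.0, np.inf]), maxfev=20_000,
    )
    l_inf, a, tau = popt
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    k1 = 3.0 * phi * dp / (2.0 * np.pi * l_inf)
    k2 = a * k1 / max(1.0 - a, 1e-12)
    mu = tau * k1 * a
    # first-order error propagation (tau dominates in practice)
    rel = np.sqrt(
        (perr[2] / tau) ** 2 + (perr[1] / a) ** 2 + (perr[0] / l_inf) ** 2
    )
    return ModulusEstimate(
        viscous_modulus=mu,
        viscous_se=mu * rel,
        elastic_modulus=k1,
        elastic_se=k1 * perr[0] / l_inf,
        phi=phi,
        details={"l_inf": l_inf, "a": a, "tau": tau, "k1": k1, "k2": k2,
                 "pressure": dp},
    )
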