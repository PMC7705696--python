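"""Sizing of flexible polymers (PEG) in solution from isotropic SANS.

Contrast matching of the large wood pores relies on PEG coils being
small enough to enter them; their radius of gyration in D2O solution is
measured here from isotropic 1D profiles by either

* the Guinier law, I(q) = I0 exp(-q^2 Rg^2 / 3) + bg, a model-free
  low-q expansion valid for q*Rg <~ 1.3, or
* the Debye function of an ideal Gaussian coil,
  I(q) = I0 * (2/x^2) (exp(-x) + x - 1) + bg with x = q^2 Rg^2,
  valid over the full coil regime and the default for PEG.

Both estimators co-fit a flat incoherent background, so the reported Rg
is independent of the solvent background level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .profiles import Profile1D

logger = logging.getLogger(__name__)

__all__ = ["PolymerSolutionFit", "fit_guinier", "fit_debye", "debye_function"]

#: Guinier validity ceiling on q_max * Rg
_GUINIER_QRG_MAX = 1.3


@dataclass(frozen=True)
class PolymerSolutionFit:
    """Result of a solution-polymer size fit.

    Rg in Å; ``method`` records which estimator produced it, since a
    Guinier Rg and a Debye Rg are not interchangeable outside the
    q*Rg < 1 regime.
    """

    Rg: float
    I0: float
    background: float
    method: str
    fit_window: tuple[float, float]
    n_points: int

    def __post_init__(self) -> None:
        if self.Rg <= 0:
            raise ValueError("Rg must be > 0")
        if self.method == "guinier":
            q_max = self.fit_window[1]
            if q_max * self.Rg > _GUINIER_QRG_MAX + 1e-9:
                raise ValueError(
                    f"Guinier fit outside validity: q_max*Rg = "
                    f"{q_max * self.Rg:.3g} > {_GUINIER_QRG_MAX}"
                )

    @property
    def Rg_nm(self) -> float:
        return self.Rg / 10.0


def _estimate_background(profile: Profile1D, tail_fraction: float = 0.15) -> float:
    """Flat background from the high-q tail (mean of the top q fraction)."""
    n_tail = max(int(tail_fraction * len(profile)), 3)
    return float(np.mean(profile.I[-n_tail:]))


def _guinier_pass(
    profile: Profile1D, q_lo: float, q_hi: float, bg: float
) -> tuple[float, float, tuple[float, float], int]:
    """One Guinier regression with window shrinking to q_max*Rg <= 1.3.

    Returns (Rg, I0, effective window, n_points).
    """
    for _ in range(40):
        sub = profile.restrict(q_lo, q_hi)
        if len(sub) < 8:
            raise ValueError(
                f"Guinier window [{q_lo:.4g}, {q_hi:.4g}] collapsed below "
                "8 points"
            )
        net = sub.I - bg
        usable = net > 0
        if usable.sum() < 8:
            raise ValueError(
                "fewer than 8 points above background in the Guinier window"
            )
        x = sub.q[usable] ** 2
        y = np.log(net[usable])
        # sigma_lnI = sigma / (I - bg); fall back to unit weights for
        # noise-free input
        sig = sub.sigma[usable]
        w = np.where(sig > 0, net[usable] / np.maximum(sig, 1e-300), 1.0)
        A = (np.column_stack([np.ones_like(x), x]).T * w**2)
        beta = np.linalg.solve(
            A @ np.column_stack([np.ones_like(x), x]), A @ y
        )
        intercept, slope = beta
        if slope >= 0:
            raise ValueError(
                "no Guinier decay: ln I is non-decreasing in q^2"
            )
        rg = float(np.sqrt(-3.0 * slope))
        q_max_eff = float(sub.q[usable][-1])
        if q_max_eff * rg < 0.3:
            # < ~3% intensity drop across the window: flat within noise
            raise ValueError(
                "no Guinier decay: q_max*Rg < 0.3, decay indistinguishable "
                "from a flat profile"
            )
        if q_max_eff * rg <= _GUINIER_QRG_MAX:
            return (
                rg,
                float(np.exp(intercept)),
                (float(sub.q[usable][0]), q_max_eff),
                int(usable.sum()),
            )
        new_hi = _GUINIER_QRG_MAX / rg
        if new_hi >= q_hi:  # no progress possible
            new_hi = 0.9 * q_hi
        logger.info(
            "Guinier window shrunk: q_max %.4g -> %.4g (Rg %.3g A)",
            q_hi, new_hi, rg,
        )
        q_hi = new_hi
    raise ValueError("Guinier window did not converge to q_max*Rg <= 1.3")


def fit_guinier(
    profile: Profile1D,
    window: tuple[float, float] | None = None,
    background: float | None = None,
) -> PolymerSolutionFit:
    """Guinier fit: weighted linear regression of ln(I - bg) on q^2.

    Rg = sqrt(-3 * slope).  The flat background defaults to the high-q
    tail estimate and is refined iteratively: after each regression the
    background is re-estimated as the mean tail residual above the
    fitted Guinier curve, which removes the bias of a tail that still
    carries signal.  (Pass ``background`` explicitly for data that do
    not extend beyond the decay.)  The validity condition
    q_max * Rg <= 1.3 is enforced by shrinking the window and refitting
    (logged); a non-decaying profile raises "no Guinier decay".
    """
    q_lo, q_hi = window if window is not None else \
        (profile.q[0], profile.q[-1])
    if background is not None:
        rg, i0, win, n = _guinier_pass(profile, q_lo, q_hi, background)
        return PolymerSolutionFit(
            Rg=rg, I0=i0, background=background, method="guinier",
            fit_window=win, n_points=n,
        )

    bg = _estimate_background(profile)
    n_tail = max(int(0.15 * len(profile)), 3)
    rg = i0 = None
    for _ in range(20):
        rg, i0, win, n = _guinier_pass(profile, q_lo, q_hi, bg)
        model_tail = i0 * np.exp(
            -(profile.q[-n_tail:] * rg) ** 2 / 3.0
        )
        bg_new = float(np.mean(profile.I[-n_tail:] - model_tail))
        if abs(bg_new - bg) < 1e-4 * max(i0, abs(bg), 1e-300):
            bg = bg_new
            break
        bg = bg_new
    rg, i0, win, n = _guinier_pass(profile, q_lo, q_hi, bg)
    return PolymerSolutionFit(
        Rg=rg, I0=i0, background=bg, method="guinier",
        fit_window=win, n_points=n,
    )


def debye_function(x):
    """Debye function of a Gaussian coil, D(x) = 2 (e^-x + x - 1) / x^2.

    x = q^2 Rg^2; the x -> 0 limit D = 1 is evaluated by series to
    avoid cancellation (D ~ 1 - x/3 + x^2/12 for small x).
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x < 1e-4
    xs = x[small]
    out[small] = 1.0 - xs / 3.0 + xs**2 / 12.0
    xl = x[~small]
    out[~small] = 2.0 * (np.exp(-xl) + xl - 1.0) / xl**2
    return out if out.ndim else float(out)


def fit_debye(
    profile: Profile1D,
    window: tuple[float, float] | None = None,
) -> PolymerSolutionFit:
    """Nonlinear fit of the Gaussian-coil Debye model with flat background.

    I(q) = I0 * D(q^2 Rg^2) + bg.  Starting values come from a Guinier
    pass (falling back to a crude moment estimate when the Guinier fit
    is impossible); raises on non-convergence with the optimizer
    diagnostics attached.
    """
    q_lo, q_hi = window if window is not None else (profile.q[0], profile.q[-1])
    sub = profile.restrict(q_lo, q_hi)
    if len(sub) < 8:
        raise ValueError("need >= 8 points in the Debye fit window")
    bg0 = _estimate_background(profile)
    try:
        g = fit_guinier(profile, window, background=bg0)
        rg0, i0 = g.Rg, g.I0
    except ValueError:
        rg0 = 2.0 / sub.q[len(sub) // 2]
        i0 = float(max(sub.I[0] - bg0, 1e-12))

    sig = np.where(sub.sigma > 0, sub.sigma, 1.0)

    def residuals(theta):
        i0_, rg_, bg_ = theta
        model = i0_ * debye_function((sub.q * rg_) ** 2) + bg_
        return (model - sub.I) / sig

    res = least_squares(
        residuals,
        x0=[i0, rg0, bg0],
        bounds=([0.0, 1e-3, -np.inf], [np.inf, np.inf, np.inf]),
        xtol=1e-12, ftol=1e-12,
    )
    if res.status <= 0 or not np.isfinite(res.cost):
        raise RuntimeError(
            f"Debye fit failed: status={res.status}, "
            f"message={res.message!r}, nfev={res.nfev}"
        )
    i0_f, rg_f, bg_f = res.x
    return PolymerSolutionFit(
        Rg=float(rg_f),
        I0=float(i0_f),
        background=float(bg_f),
        method="debye",
        fit_window=(float(sub.q[0]), float(sub.q[-1])),
        n_points=len(sub),
    )
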