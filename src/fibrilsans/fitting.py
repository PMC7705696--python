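"""Weighted least-squares fitting of the three-term equatorial model.

The low-q bundle Gaussian and the pore power law overlap strongly, so a
single local fit is not reliable; fitting therefore runs a seeded
multistart (Latin-hypercube starting points within the parameter
bounds) and keeps the best optimum.  Intensities are normalised
internally to the maximum of the fitted window, which makes the
optimisation landscape independent of the data's overall scale: the
fitted amplitudes are exactly equivariant under rescaling of (I, sigma)
while the shape parameters are invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .model import (
    DerivedStructure,
    WoodModelParams,
    bundle_diameter_from_sigma,
    intensity_terms,
    peak_position,
    total_intensity,
)
from .profiles import Profile1D

__all__ = [
    "FitConfig",
    "FitResult",
    "fit_equatorial",
    "derive_structure",
    "decompose_contributions",
    "bootstrap_uncertainty",
]

#: parameters sampled log-uniformly at start (amplitude-like, span decades)
_LOG_PARAMS = {"A_mf", "A_b", "B_pl", "C_bg"}

#: default bounds in *normalised* intensity units (amplitudes) / Å (lengths).
#: R_mean brackets the 2-3 nm microfibril thickness; sigma_b brackets the
#: q-window 0.01-0.05 Å^-1 where the bundle term dominates.
_DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "A_mf": (0.0, 10.0),
    "R_mean": (8.0, 20.0),
    "R_sd": (0.0, 6.0),
    "a_cc": (25.0, 60.0),
    "g_distortion": (0.05, 0.45),
    "A_b": (0.0, 10.0),
    "sigma_b": (0.005, 0.05),
    "B_pl": (0.0, 1.0),   # upper bound rescaled by q_min^alpha at fit time
    "alpha": (3.0, 4.0),
    "C_bg": (0.0, 2.0),
}

_PARAM_ORDER = list(_DEFAULT_BOUNDS)


@dataclass
class FitConfig:
    """Configuration of an equatorial fit.

    Attributes
    ----------
    q_range : tuple
        Fitted q-window in Å^-1 (default the instrument's full
        0.002-0.3 coverage).
    bounds : dict
        Per-parameter (lo, hi) overrides of the defaults; amplitude
        bounds are interpreted in normalised units (data maximum = 1).
    frozen : set
        Parameters held at their ``base_params`` value.  By default the
        radius dispersity, the number of lattice planes and the Porod
        exponent are frozen — they are poorly determined by a single
        equatorial profile.
    base_params : WoodModelParams
        Values of frozen parameters (and of N_planes, which is always
        integer and never optimised continuously).
    n_starts : int
        Multistart count (Latin hypercube), default 16.
    loss : str
        "linear": residuals (model - I)/sigma; "log": residuals on
        log-intensity for curves spanning many decades.
    seed : int
        Seed of the Latin-hypercube sampler; fits are bit-reproducible
        given identical inputs and seed.
    """

    q_range: tuple[float, float] = (0.002, 0.3)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    frozen: frozenset = frozenset({"R_sd", "N_planes", "alpha"})
    base_params: WoodModelParams = field(default_factory=WoodModelParams)
    n_starts: int = 16
    loss: str = "linear"
    seed: int = 0
    start_from_base: bool = False

    def __post_init__(self) -> None:
        if self.q_range[0] >= self.q_range[1]:
            raise ValueError("q_range must be (lo, hi) with lo < hi")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.loss not in ("linear", "log"):
            raise ValueError("loss must be 'linear' or 'log'")
        unknown = set(self.bounds) - set(_DEFAULT_BOUNDS)
        if unknown:
            raise ValueError(f"unknown parameters in bounds: {sorted(unknown)}")
        self.frozen = frozenset(self.frozen) | {"N_planes"}


@dataclass
class FitResult:
    """Outcome of ``fit_equatorial``.

    ``derived`` is recomputed from ``params`` (never stored
    independently); ``per_term_profiles`` are the four model terms on
    the fitted q-grid in data units.
    """

    params: WoodModelParams
    stderr: dict[str, float]
    chi2_reduced: float
    derived: DerivedStructure
    per_term_profiles: dict[str, np.ndarray]
    q: np.ndarray
    convergence: dict
    at_bounds: list[str]


def _resolve_bounds(config: FitConfig, q_min: float) -> dict:
    bounds = dict(_DEFAULT_BOUNDS)
    # a Porod term can rise to ~10 x data maximum at the window edge
    alpha_hi = config.bounds.get("alpha", bounds["alpha"])[1] \
        if "alpha" in config.bounds else bounds["alpha"][1]
    if "alpha" in config.frozen:
        alpha_hi = config.base_params.alpha
    bounds["B_pl"] = (0.0, 10.0 * q_min**alpha_hi)
    bounds.update(config.bounds)
    return bounds


def _pack(config: FitConfig):
    return [p for p in _PARAM_ORDER if p not in config.frozen]


#: amplitude-like parameters, linear in the data scale
_AMPLITUDE_PARAMS = ("A_mf", "A_b", "B_pl", "C_bg")


def _params_from_vector(
    x: np.ndarray, free: list[str], base_values: dict
) -> WoodModelParams:
    values = dict(base_values)
    for name, val in zip(free, x):
        values[name] = float(val)
    return WoodModelParams(**values)


def fit_equatorial(profile: Profile1D, config: FitConfig | None = None) -> FitResult:
    """Fit the three-term model to a merged equatorial profile.

    Runs ``config.n_starts`` local trust-region fits from seeded
    Latin-hypercube starting points and keeps the lowest weighted
    sum of squares.  Raises if fewer than 30 points fall in the fitted
    window or if every start fails; parameters that land on a bound are
    listed in ``FitResult.at_bounds``.
    """
    config = config or FitConfig()
    window = profile.restrict(*config.q_range)
    if len(window) < 30:
        raise ValueError(
            f"only {len(window)} points in q_range {config.q_range}; "
            "need >= 30"
        )
    q, I, sigma = window.q, window.I, window.sigma
    i_ref = float(np.max(np.abs(I)))
    if i_ref <= 0:
        raise ValueError("profile has no positive intensity in q_range")
    i_n = I / i_ref
    if np.all(sigma > 0):
        w = i_ref / sigma  # 1/sigma_normalised
    else:
        w = np.ones_like(I)

    # the optimisation runs in normalised intensity (data maximum = 1):
    # frozen amplitude-like parameters are normalised on the way in and
    # every amplitude is rescaled by i_ref on the way out
    base_values = config.base_params.to_dict()
    for name in _AMPLITUDE_PARAMS:
        base_values[name] = base_values[name] / i_ref

    bounds = _resolve_bounds(config, q.min())
    free = _pack(config)
    lo = np.array([bounds[p][0] for p in free])
    hi = np.array([bounds[p][1] for p in free])

    use_log = config.loss == "log"
    if use_log and np.any(i_n <= 0):
        raise ValueError("log loss requires strictly positive intensities")

    def residuals(x: np.ndarray) -> np.ndarray:
        params = _params_from_vector(x, free, base_values)
        model = total_intensity(q, params)
        if use_log:
            model = np.log(np.maximum(model, 1e-300))
            return (model - np.log(i_n)) * np.minimum(w * i_n, 1e6)
        return (model - i_n) * w

    # Latin-hypercube starts in [0,1]^d; amplitude-like axes mapped
    # log-uniformly so starts span the decades inside the bounds
    sampler = qmc.LatinHypercube(d=len(free), seed=config.seed)
    unit = sampler.random(config.n_starts)
    starts = np.empty_like(unit)
    for j, name in enumerate(free):
        a, b = lo[j], hi[j]
        if name in _LOG_PARAMS:
            a_log = max(a, 1e-6 * max(b, 1e-30))
            starts[:, j] = a_log * (b / a_log) ** unit[:, j]
        else:
            starts[:, j] = a + (b - a) * unit[:, j]
    if config.start_from_base:
        # first start at the (normalised) base parameters; used by the
        # bootstrap to restart from the full-data optimum
        for j, name in enumerate(free):
            starts[0, j] = np.clip(base_values[name], lo[j], hi[j])

    best = None
    diagnostics = []
    for k in range(config.n_starts):
        try:
            res = least_squares(
                residuals, starts[k], bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=4000,
            )
        except Exception as err:  # singular model, overflow in a start
            diagnostics.append({"start": k, "status": "exception",
                                "message": str(err)})
            continue
        diagnostics.append({"start": k, "status": int(res.status),
                            "cost": float(res.cost), "nfev": int(res.nfev)})
        if res.status > 0 and np.isfinite(res.cost):
            if best is None or res.cost < best[1].cost:
                best = (k, res)
    if best is None:
        raise RuntimeError(
            f"all {config.n_starts} starts failed to converge; "
            f"per-start diagnostics: {diagnostics}"
        )
    k_best, res = best

    n_free = len(free)
    dof = max(len(q) - n_free, 1)
    chi2_reduced = float(2.0 * res.cost / dof)

    # covariance from the Jacobian at the optimum, scaled by chi2;
    # columns are equilibrated first — parameter scales differ by many
    # orders of magnitude and an unscaled pseudo-inverse truncates the
    # small singular values that carry the weakly-determined directions
    try:
        jac = res.jac
        col = np.sqrt(np.sum(jac**2, axis=0))
        col[col == 0] = 1.0
        jtj_scaled = (jac / col).T @ (jac / col)
        cov = np.linalg.pinv(jtj_scaled) / np.outer(col, col) \
            * (2.0 * res.cost / dof)
        stderr_vec = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        stderr_vec = np.full(n_free, np.nan)

    span = hi - lo
    at_bounds = [
        name
        for name, xv, a, b, s in zip(free, res.x, lo, hi, span)
        if min(xv - a, b - xv) < 1e-6 * s
    ]

    params_n = _params_from_vector(res.x, free, base_values)
    # rescale every amplitude-like parameter back to data units
    values = params_n.to_dict()
    stderr = {}
    for name, err in zip(free, stderr_vec):
        factor = i_ref if name in _AMPLITUDE_PARAMS else 1.0
        stderr[name] = float(err * factor)
    for name in _AMPLITUDE_PARAMS:
        values[name] = values[name] * i_ref
    params = WoodModelParams(**values)

    derived = derive_structure(params)
    q_half = params.sigma_b * np.sqrt(2.0 * np.log(2.0))
    if q_half > derived.peak_q:
        warnings.warn(
            "identifiability: the bundle Gaussian's half-maximum q "
            f"({q_half:.3g}) exceeds the packing-peak position "
            f"({derived.peak_q:.3g}); bundle and microfibril terms "
            "overlap pathologically",
            stacklevel=2,
        )

    return FitResult(
        params=params,
        stderr=stderr,
        chi2_reduced=chi2_reduced,
        derived=derived,
        per_term_profiles=intensity_terms(q, params),
        q=q.copy(),
        convergence={
            "status": int(res.status),
            "n_eval": int(res.nfev),
            "best_start": k_best,
            "starts": diagnostics,
        },
        at_bounds=at_bounds,
    )


def derive_structure(
    params: WoodModelParams, convention: str = "cross_section"
) -> DerivedStructure:
    """Structural quantities (nm) from fitted model parameters.

    Bundle diameter via the Guinier mapping of sigma_b; interfibrillar
    distance is a_cc converted to nm; peak_q is the position of the
    microfibril packing maximum.
    """
    return DerivedStructure(
        bundle_diameter=bundle_diameter_from_sigma(
            params.sigma_b, convention
        ),
        interfibrillar_distance=params.a_cc / 10.0,
        peak_q=peak_position(params),
    )


def decompose_contributions(
    profile: Profile1D, result: FitResult
) -> dict:
    """Per-term model curves and data-minus-other-terms residuals.

    Returns the four model terms on the fitted grid, the total model,
    the plain residual (data - model), and ``data_from_bundles``: the
    experimental data minus the fitted microfibril, power-law and
    background terms — the construction used to isolate the bundle
    contribution in a decomposition plot.
    """
    window = profile.restrict(result.q.min(), result.q.max())
    if len(window) != len(result.q) or not np.allclose(
        window.q, result.q, rtol=1e-12, atol=0
    ):
        raise ValueError(
            "profile q-grid does not match the grid the fit was run on"
        )
    terms = result.per_term_profiles
    total = sum(terms.values())
    other = terms["microfibrils"] + terms["power_law"] + terms["background"]
    return {
        "q": result.q,
        "terms": terms,
        "total": total,
        "residual": window.I - total,
        "data_from_bundles": window.I - other,
        "sigma": window.sigma,
    }


def write_decomposition(decomposition: dict, path) -> None:
    """Write a ``decompose_contributions`` result as multi-column ASCII.

    Columns: q, data-from-bundles, each model term, total, residual —
    the layout needed for a decomposition plot of an equatorial fit.
    """
    from pathlib import Path

    terms = decomposition["terms"]
    names = list(terms)
    header = ["# fibrilsans decomposition",
              "# columns: q data_from_bundles "
              + " ".join(names) + " total residual"]
    rows = []
    for i, q in enumerate(decomposition["q"]):
        vals = [q, decomposition["data_from_bundles"][i]]
        vals += [terms[n][i] for n in names]
        vals += [decomposition["total"][i], decomposition["residual"][i]]
        rows.append(" ".join(f"{v:.8e}" for v in vals))
    Path(path).write_text("\n".join(header + rows) + "\n")


def bootstrap_uncertainty(
    profile: Profile1D,
    config: FitConfig | None = None,
    n_boot: int = 100,
    interval: float = 0.95,
) -> dict:
    """Residual-resampling bootstrap intervals for the free parameters.

    Fits once, then refits ``n_boot`` profiles built as (best model +
    resampled residuals).  Refits start from the full-data optimum
    (single start) for speed; seeded by ``config.seed``.  Raises if
    more than 20% of refits fail.

    Returns a dict: parameter -> (lo, hi) percentile interval, plus
    ``"samples"`` with the raw per-parameter bootstrap draws.
    """
    config = config or FitConfig()
    if n_boot < 50:
        raise ValueError("n_boot must be >= 50")
    base = fit_equatorial(profile, config)
    window = profile.restrict(*config.q_range)
    model = total_intensity(window.q, base.params)
    # standardised residuals: the profile is strongly heteroscedastic
    # (decades of intensity), so residuals are exchangeable only after
    # scaling by their sigma
    scale = np.where(window.sigma > 0, window.sigma, 1.0)
    resid = (window.I - model) / scale

    rng = np.random.default_rng(config.seed + 1)
    free = _pack(config)
    single = FitConfig(
        q_range=config.q_range, bounds=config.bounds, frozen=config.frozen,
        base_params=base.params, n_starts=1, loss=config.loss,
        seed=config.seed, start_from_base=True,
    )
    samples: dict[str, list[float]] = {p: [] for p in free}
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(resid), len(resid))
        boot = Profile1D(
            q=window.q, I=model + scale * resid[idx], sigma=window.sigma,
            meta=dict(window.meta),
        )
        try:
            res = fit_equatorial(boot, single)
        except (RuntimeError, ValueError):
            failures += 1
            continue
        for p in free:
            samples[p].append(getattr(res.params, p))
    if failures > 0.2 * n_boot:
        raise RuntimeError(
            f"bootstrap refit failure rate {failures}/{n_boot} exceeds 20%"
        )
    tail = 0.5 * (1.0 - interval)
    intervals = {
        p: (
            float(np.quantile(samples[p], tail)),
            float(np.quantile(samples[p], 1.0 - tail)),
        )
        for p in free
    }
    intervals["samples"] = {p: np.array(v) for p, v in samples.items()}
    intervals["n_failures"] = failures
    return intervals
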