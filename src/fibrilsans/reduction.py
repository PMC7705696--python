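"""Reduce 2D detector frames to the merged equatorial 1D profile.

For a vertically mounted wood sample, the lateral (cross-sectional)
structure of the cellulose microfibrils scatters into a horizontal
equatorial streak.  Reduction estimates, per q-bin, the mean intensity
in an azimuthal band around the equator and subtracts the isotropic
level estimated in a reference band far from the equator; the result is
the equatorial *anisotropic* profile that the three-term model is
fitted to.  Profiles from several detector distances are rescaled onto
a common reference in their overlap regions, concatenated and rebinned
on a log-q grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .frames import DetectorFrame, build_qmap, solid_angle_weight
from .profiles import Profile1D

logger = logging.getLogger(__name__)

__all__ = [
    "SectorSpec",
    "azimuthal_profile",
    "separate_anisotropic",
    "merge_profiles",
    "rebin_log",
    "reduce_frames",
]


@dataclass(frozen=True)
class SectorSpec:
    """Azimuthal sector layout for the equatorial separation.

    Angles are degrees from the horizontal equator, folded into
    [0, 180).  The equator band covers azimuths within
    ``half_width_equator`` of ``equator_azimuth`` (both streak halves,
    since azimuth is 180-periodic); the reference band, centred 90
    degrees away by default, estimates the isotropic component.
    """

    equator_azimuth: float = 0.0
    half_width_equator: float = 15.0
    reference_azimuth_band: tuple[float, float] = (60.0, 120.0)

    def __post_init__(self) -> None:
        if not 0 < self.half_width_equator < 90:
            raise ValueError("half_width_equator must be in (0, 90)")
        lo, hi = self.reference_azimuth_band
        if not 0 <= lo < hi <= 180:
            raise ValueError("reference band must satisfy 0 <= lo < hi <= 180")
        # reference band must not touch the equator band
        eq = self.equator_azimuth % 180.0
        hw = self.half_width_equator
        edges = np.linspace(lo, hi, 181)
        dist = np.abs((edges - eq + 90.0) % 180.0 - 90.0)
        if np.any(dist < hw):
            raise ValueError(
                "reference_azimuth_band overlaps the equator band"
            )

    def in_equator(self, azimuth: np.ndarray) -> np.ndarray:
        """Boolean mask: azimuth (deg, [0,180)) inside the equator band."""
        eq = self.equator_azimuth % 180.0
        dist = np.abs((azimuth - eq + 90.0) % 180.0 - 90.0)
        return dist <= self.half_width_equator

    def in_reference(self, azimuth: np.ndarray) -> np.ndarray:
        lo, hi = self.reference_azimuth_band
        return (azimuth >= lo) & (azimuth <= hi)


def _pixel_intensity_maps(frame: DetectorFrame):
    """Per-pixel intensity (counts / exposure / solid angle) and variance."""
    shape = frame.counts.shape
    weight = solid_angle_weight(frame.geometry, shape)
    norm = frame.exposure * weight
    intensity = frame.counts / norm
    variance = frame.counts / norm**2  # Poisson: Var[counts] = counts
    return intensity, variance


def _default_q_edges(
    q_valid: np.ndarray, bins_per_decade: int
) -> np.ndarray:
    """Log-spaced q-bin edges aligned to the decade grid."""
    q_lo, q_hi = q_valid.min(), q_valid.max()
    k_lo = np.floor(bins_per_decade * np.log10(q_lo))
    k_hi = np.ceil(bins_per_decade * np.log10(q_hi))
    return 10.0 ** (np.arange(k_lo, k_hi + 1) / bins_per_decade)


def azimuthal_profile(
    frame: DetectorFrame,
    q_bin: tuple[float, float],
    n_azimuth_bins: int = 36,
) -> dict:
    """Intensity versus azimuth for pixels with q in ``[q_lo, q_hi)``.

    Returns a dict with ``azimuth`` (bin centres, deg in [0, 180)),
    ``I``, ``sigma`` and a boolean ``gap`` flag marking empty bins
    (NaN intensity) instead of silently reporting zero.
    """
    q_lo, q_hi = q_bin
    if q_lo >= q_hi:
        raise ValueError("q_bin must satisfy q_lo < q_hi")
    q, azimuth = build_qmap(frame.geometry, frame.counts.shape)
    if q_lo > np.max(q[~frame.mask]):
        raise ValueError(
            f"q_bin {q_bin} outside frame coverage (q_max="
            f"{np.max(q[~frame.mask]):.4g})"
        )
    intensity, variance = _pixel_intensity_maps(frame)
    select = (~frame.mask) & (q >= q_lo) & (q < q_hi)

    edges = np.linspace(0.0, 180.0, n_azimuth_bins + 1)
    idx = np.clip(
        np.digitize(azimuth[select], edges) - 1, 0, n_azimuth_bins - 1
    )
    n = np.bincount(idx, minlength=n_azimuth_bins)
    s_i = np.bincount(idx, weights=intensity[select], minlength=n_azimuth_bins)
    s_v = np.bincount(idx, weights=variance[select], minlength=n_azimuth_bins)
    gap = n == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(gap, np.nan, s_i / np.maximum(n, 1))
        sigma = np.where(gap, np.nan, np.sqrt(s_v) / np.maximum(n, 1))
    return {
        "azimuth": 0.5 * (edges[:-1] + edges[1:]),
        "I": mean,
        "sigma": sigma,
        "gap": gap,
    }


def separate_anisotropic(
    frame: DetectorFrame,
    sectors: SectorSpec | None = None,
    bins_per_decade: int = 40,
    q_edges: np.ndarray | None = None,
) -> Profile1D:
    """Equatorial anisotropic profile: equator band minus isotropic level.

    Per q-bin, the isotropic component is estimated as the mean pixel
    intensity in the reference azimuth band and subtracted from the mean
    in the equator band; uncertainties combine in quadrature.  Negative
    values are noise and are retained.  q-bins where either band has no
    unmasked pixels are dropped (count logged and recorded in meta).
    """
    sectors = sectors or SectorSpec()
    q, azimuth = build_qmap(frame.geometry, frame.counts.shape)
    intensity, variance = _pixel_intensity_maps(frame)
    valid = (~frame.mask) & (q > 0)
    if not valid.any():
        raise ValueError("frame is fully masked")
    if q_edges is None:
        q_edges = _default_q_edges(q[valid], bins_per_decade)

    in_eq = sectors.in_equator(azimuth) & valid
    in_ref = sectors.in_reference(azimuth) & valid

    rows = []
    n_dropped = 0
    for lo, hi in zip(q_edges[:-1], q_edges[1:]):
        shell = (q >= lo) & (q < hi)
        eq = shell & in_eq
        ref = shell & in_ref
        n_eq, n_ref = eq.sum(), ref.sum()
        if n_eq == 0 or n_ref == 0:
            if (shell & valid).any():
                n_dropped += 1
            continue
        i_eq = intensity[eq].mean()
        i_ref = intensity[ref].mean()
        # floor each band's summed variance at the one-count level so
        # zero-count bands do not report zero uncertainty
        floor = 1.0 / frame.exposure**2
        v_eq = max(variance[eq].sum(), floor) / n_eq**2
        v_ref = max(variance[ref].sum(), floor) / n_ref**2
        rows.append(
            (q[eq].mean(), i_eq - i_ref, np.sqrt(v_eq + v_ref))
        )
    if n_dropped:
        logger.info(
            "separate_anisotropic: dropped %d q-bins with an empty "
            "equator or reference band", n_dropped,
        )
    if not rows:
        raise ValueError("no q-bin has pixels in both azimuth bands")
    arr = np.array(rows)
    order = np.argsort(arr[:, 0])
    return Profile1D(
        q=arr[order, 0],
        I=arr[order, 1],
        sigma=arr[order, 2],
        meta={
            "sectors": (
                f"equator {sectors.equator_azimuth}±"
                f"{sectors.half_width_equator} deg, reference "
                f"{sectors.reference_azimuth_band} deg"
            ),
            "dropped_bins": n_dropped,
            "sdd_mm": frame.geometry.sdd,
        },
    )


def _fit_scale(target: Profile1D, reference: Profile1D) -> float:
    """Weighted least-squares scalar mapping *target* onto *reference*.

    The reference is interpolated onto the target's q-points inside the
    overlap (linear in log q); the optimal c minimises
    sum_w (c I - I_ref)^2 with w = 1/sigma^2.
    """
    lo = max(target.q.min(), reference.q.min())
    hi = min(target.q.max(), reference.q.max())
    in_overlap = (target.q >= lo) & (target.q <= hi)
    if in_overlap.sum() < 3:
        raise ValueError(
            f"insufficient q-overlap between configurations: "
            f"[{target.q.min():.4g}, {target.q.max():.4g}] vs "
            f"[{reference.q.min():.4g}, {reference.q.max():.4g}]"
        )
    q_o = target.q[in_overlap]
    i_t = target.I[in_overlap]
    sig = target.sigma[in_overlap]
    i_r = np.interp(np.log(q_o), np.log(reference.q), reference.I)
    w = np.where(sig > 0, 1.0 / np.maximum(sig, 1e-300) ** 2, 1.0)
    denom = np.sum(w * i_t**2)
    if denom <= 0:
        raise ValueError("degenerate overlap: zero intensity in target")
    return float(np.sum(w * i_r * i_t) / denom)


def merge_profiles(
    profiles: list[Profile1D],
    scale_reference: int = 0,
    bins_per_decade: int = 40,
) -> Profile1D:
    """Rescale, concatenate and log-rebin profiles from several setups.

    Each profile is rescaled by a least-squares scalar onto the
    reference configuration.  Profiles that do not overlap the reference
    directly are chained through already-scaled neighbours (the standard
    multi-distance bridge).  Raises if some profile cannot be bridged.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    if not 0 <= scale_reference < len(profiles):
        raise IndexError("scale_reference out of range")
    if len(profiles) == 1:
        out = rebin_log(profiles[0], bins_per_decade)
        out.meta["scale_factors"] = [1.0]
        return out

    scaled: dict[int, Profile1D] = {scale_reference: profiles[scale_reference]}
    factors = {scale_reference: 1.0}
    pending = [i for i in range(len(profiles)) if i != scale_reference]
    while pending:
        progressed = False
        for i in list(pending):
            last_err = None
            for j, ref in sorted(scaled.items()):
                try:
                    c = _fit_scale(profiles[i], ref)
                except ValueError as err:
                    last_err = err
                    continue
                scaled[i] = profiles[i].scaled(c)
                factors[i] = c
                pending.remove(i)
                progressed = True
                break
            else:
                continue
        if not progressed:
            raise ValueError(
                f"profiles {pending} share no q-overlap with the scaled "
                f"set; cannot bridge the gap ({last_err})"
            )

    q = np.concatenate([scaled[i].q for i in sorted(scaled)])
    I = np.concatenate([scaled[i].I for i in sorted(scaled)])
    sigma = np.concatenate([scaled[i].sigma for i in sorted(scaled)])
    order = np.argsort(q, kind="stable")
    # strictly-increasing q requires nudging exact duplicates apart before
    # Profile1D validation; rebinning merges them anyway
    q_sorted = q[order]
    dup = np.diff(q_sorted) <= 0
    if dup.any():
        eps = np.finfo(float).eps
        for k in np.nonzero(dup)[0]:
            q_sorted[k + 1] = q_sorted[k] * (1 + 4 * eps)
    stacked = Profile1D(
        q=q_sorted, I=I[order], sigma=sigma[order],
        meta={"scale_factors": [factors[i] for i in sorted(factors)]},
    )
    out = rebin_log(stacked, bins_per_decade)
    out.meta.update(stacked.meta)
    return out


def rebin_log(profile: Profile1D, bins_per_decade: int = 40) -> Profile1D:
    """Inverse-variance-weighted rebinning on a log-q grid.

    Bin edges are aligned to the decade grid (10^(k / bins_per_decade)).
    Empty bins are dropped.  Points with sigma == 0 (noise-free model
    curves) fall back to unweighted averaging within their bin.
    """
    if bins_per_decade < 1:
        raise ValueError("bins_per_decade must be >= 1")
    edges = _default_q_edges(profile.q, bins_per_decade)
    idx = np.clip(np.digitize(profile.q, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in np.unique(idx):
        sel = idx == b
        q_b, i_b, s_b = profile.q[sel], profile.I[sel], profile.sigma[sel]
        if np.all(s_b > 0):
            w = 1.0 / s_b**2
            wsum = w.sum()
            rows.append(
                (
                    np.sum(w * q_b) / wsum,
                    np.sum(w * i_b) / wsum,
                    np.sqrt(1.0 / wsum),
                )
            )
        else:
            n = sel.sum()
            rows.append(
                (q_b.mean(), i_b.mean(), np.sqrt(np.sum(s_b**2)) / n)
            )
    arr = np.array(rows)
    return Profile1D(
        q=arr[:, 0], I=arr[:, 1], sigma=arr[:, 2],
        meta=dict(profile.meta, bins_per_decade=bins_per_decade),
    )


def reduce_frames(
    frames: list[DetectorFrame],
    sectors: SectorSpec | None = None,
    bins_per_decade: int = 40,
    scale_reference: int | None = None,
) -> Profile1D:
    """Full reduction: separate each frame, then merge across distances.

    The reference configuration defaults to the longest
    sample-to-detector distance (lowest q, longest exposure in typical
    practice).
    """
    profiles = [
        separate_anisotropic(f, sectors, bins_per_decade) for f in frames
    ]
    if scale_reference is None:
        scale_reference = int(
            np.argmax([f.geometry.sdd for f in frames])
        )
    return merge_profiles(profiles, scale_reference, bins_per_decade)
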