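"""Seeded synthetic SANS data with known ground truth.

Emulates a D11-like fiber-diffraction measurement of wood: three
detector distances at wavelength 6.0 Å jointly covering
q = 0.002-0.3 Å^-1, an equatorially concentrated anisotropic signal
(microfibril packing + bundle Gaussian + pore power law) smeared in
azimuth by a wrapped Gaussian (fiber misalignment), an isotropic
background, and Poisson counting noise.  Because the ground truth is
known, the reduction and fitting stages can be validated end to end
without any instrument data.

Seeding: one global seed expands to per-frame children via
``numpy.random.SeedSequence([seed, frame_index])`` — a documented
counter scheme with no hidden global RNG state.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .frames import DetectorFrame, Geometry, build_qmap, solid_angle_weight, \
    write_frame_hdf5
from .model import WoodModelParams, total_intensity
from .profiles import Profile1D
from .reduction import SectorSpec

__all__ = [
    "SyntheticSpec",
    "default_geometries",
    "generate_profile",
    "generate_frames",
    "write_fixture_set",
    "regenerate_from_manifest",
    "azimuthal_weight",
    "anisotropic_intensity",
    "sector_response_factor",
]


def default_geometries(
    n_pixels: int = 128,
    pixel_size: float = 7.5,
    wavelength: float = 6.0,
    sdds: tuple[float, ...] = (1500.0, 8000.0, 39000.0),
) -> list[Geometry]:
    """Three D11-like configurations covering q = 0.002-0.33 Å^-1.

    With 128 x 128 pixels of 7.5 mm and the beam centred on the frame,
    the 1.5 m / 8 m / 39 m distances give overlapping q ranges of about
    0.02-0.33, 0.004-0.063 and 0.0008-0.013 Å^-1.
    """
    center = ((n_pixels - 1) / 2.0, (n_pixels - 1) / 2.0)
    return [
        Geometry(
            wavelength=wavelength, sdd=sdd, beam_center=center,
            pixel_size=pixel_size,
        )
        for sdd in sdds
    ]


@dataclass
class SyntheticSpec:
    """Ground truth and instrument layout of a synthetic measurement.

    ``counts_scale`` is the expected number of counts produced by unit
    model intensity in a pixel at normal incidence (the reference
    pixel); Poisson noise follows from it.  ``orientation_spread`` is
    the std (degrees) of the wrapped-Gaussian azimuthal smearing of all
    anisotropic terms about the equator.
    """

    truth: WoodModelParams = field(default_factory=WoodModelParams)
    orientation_spread: float = 10.0
    isotropic_flat: float = 0.05
    isotropic_porod: float = 0.0
    geometries: list[Geometry] = field(default_factory=default_geometries)
    counts_scale: float = 100.0
    frame_shape: tuple[int, int] = (128, 128)
    beamstop_radius_px: float = 4.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.orientation_spread < 45:
            raise ValueError("orientation_spread must be in (0, 45) degrees")
        if self.counts_scale <= 0:
            raise ValueError("counts_scale must be > 0")
        if not self.geometries:
            raise ValueError("need at least one geometry")
        if self.isotropic_flat < 0 or self.isotropic_porod < 0:
            raise ValueError("isotropic components must be >= 0")

    def to_dict(self) -> dict:
        return {
            "truth": self.truth.to_dict(),
            "orientation_spread": self.orientation_spread,
            "isotropic_flat": self.isotropic_flat,
            "isotropic_porod": self.isotropic_porod,
            "geometries": [
                {
                    "wavelength": g.wavelength,
                    "sdd": g.sdd,
                    "beam_center": list(g.beam_center),
                    "pixel_size": g.pixel_size,
                }
                for g in self.geometries
            ],
            "counts_scale": self.counts_scale,
            "frame_shape": list(self.frame_shape),
            "beamstop_radius_px": self.beamstop_radius_px,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticSpec":
        return cls(
            truth=WoodModelParams.from_dict(data["truth"]),
            orientation_spread=data["orientation_spread"],
            isotropic_flat=data["isotropic_flat"],
            isotropic_porod=data["isotropic_porod"],
            geometries=[
                Geometry(
                    wavelength=g["wavelength"], sdd=g["sdd"],
                    beam_center=tuple(g["beam_center"]),
                    pixel_size=g["pixel_size"],
                )
                for g in data["geometries"]
            ],
            counts_scale=data["counts_scale"],
            frame_shape=tuple(data["frame_shape"]),
            beamstop_radius_px=data["beamstop_radius_px"],
            seed=data["seed"],
        )


def azimuthal_weight(azimuth_deg, spread_deg: float):
    """Wrapped-Gaussian azimuthal weight, 180-deg period, unit mean.

    W(phi) = 180 * sum_k N(phi; 180 k, spread); the normalisation makes
    the azimuthal average exactly 1, so the radial average of
    I_an(q) * W(phi) recovers I_an(q).
    """
    phi = np.asarray(azimuth_deg, dtype=float)
    dens = np.zeros_like(phi)
    norm = 1.0 / (np.sqrt(2.0 * np.pi) * spread_deg)
    for k in range(-3, 4):
        dens += norm * np.exp(-0.5 * ((phi - 180.0 * k) / spread_deg) ** 2)
    return 180.0 * dens


def anisotropic_intensity(q, truth: WoodModelParams):
    """The anisotropic part of the model: everything except C_bg."""
    return total_intensity(q, truth) - truth.C_bg


def sector_response_factor(
    spread_deg: float, sectors: SectorSpec | None = None, n: int = 20001
) -> float:
    """Expected scale factor linking truth to the reduced profile.

    ``separate_anisotropic`` reports (equator-band mean) minus
    (reference-band mean) of I_an(q) * W(phi), i.e. I_an(q) times

        <W>_equator - <W>_reference,

    evaluated here by dense numerical averaging of the wrapped
    Gaussian over the two bands.  Tests compare reduced output against
    ``anisotropic_intensity * sector_response_factor``.
    """
    sectors = sectors or SectorSpec()
    phi = np.linspace(0.0, 180.0, n)
    w = azimuthal_weight(phi, spread_deg)
    eq = sectors.in_equator(phi)
    ref = sectors.in_reference(phi)
    return float(w[eq].mean() - w[ref].mean())


def generate_profile(
    truth: WoodModelParams,
    q_grid: np.ndarray,
    noise_level: float,
    seed: int = 0,
) -> tuple[Profile1D, dict]:
    """Synthetic 1D profile with multiplicative Gaussian noise.

    I_obs = I_model * (1 + noise_level * eps), eps ~ N(0, 1), and
    sigma = noise_level * I_model.  noise_level = 0 returns the model
    exactly (sigma = 0).  Returns the profile and a truth record.
    """
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    q_grid = np.asarray(q_grid, dtype=float)
    i_model = total_intensity(q_grid, truth)
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    if noise_level == 0:
        i_obs = i_model.copy()
        sigma = np.zeros_like(i_model)
    else:
        eps = rng.standard_normal(q_grid.size)
        i_obs = i_model * (1.0 + noise_level * eps)
        sigma = noise_level * i_model
    profile = Profile1D(
        q=q_grid, I=i_obs, sigma=sigma,
        meta={"synthetic": True, "seed": seed, "noise_level": noise_level},
    )
    record = {"truth": truth.to_dict(), "noise_level": noise_level,
              "seed": seed}
    return profile, record


def _expected_counts(spec: SyntheticSpec, geometry: Geometry) -> tuple:
    """Noise-free expected-counts map and the beamstop mask."""
    shape = spec.frame_shape
    q, azimuth = build_qmap(geometry, shape)
    rows, cols = np.indices(shape)
    r_px = np.hypot(
        rows - geometry.beam_center[0], cols - geometry.beam_center[1]
    )
    mask = r_px <= spec.beamstop_radius_px

    q_safe = np.where(q > 0, q, np.inf)
    i_an = anisotropic_intensity(q_safe.ravel(), spec.truth).reshape(shape)
    w_az = azimuthal_weight(azimuth, spec.orientation_spread)
    i_iso = spec.isotropic_flat + spec.isotropic_porod * q_safe ** -4.0
    expected = (
        spec.counts_scale
        * (i_an * w_az + i_iso)
        * solid_angle_weight(geometry, shape)
    )
    expected = np.where(mask, 0.0, expected)
    return expected, mask


def expected_reduced_profile(
    spec: SyntheticSpec,
    geometry_index: int,
    sectors: SectorSpec | None = None,
    bins_per_decade: int = 40,
) -> Profile1D:
    """Exact expectation of ``separate_anisotropic`` on a generated frame.

    Reduction is linear in the counts, so reducing the noise-free
    expected-counts map yields the exact mean of the reduced profile,
    including the pixel-discretisation of the azimuth bands that a
    purely analytic I_an(q) * sector_response_factor misses at small
    radii.  This is the reference curve for chi-square checks of the
    noise propagation.
    """
    from .reduction import separate_anisotropic

    geometry = spec.geometries[geometry_index]
    expected, mask = _expected_counts(spec, geometry)
    frame = DetectorFrame(
        counts=expected, exposure=1.0, geometry=geometry, mask=mask,
        meta={"synthetic": True, "noise_free_expectation": True},
    )
    return separate_anisotropic(frame, sectors, bins_per_decade)


def generate_frames(spec: SyntheticSpec) -> tuple[list[DetectorFrame], dict]:
    """Poisson-sampled detector frames for every geometry in *spec*.

    Per pixel the expectation is
    ``counts_scale * (I_an(q) W(phi) + I_iso(q)) * cos^3(2theta)``,
    zeroed under the beamstop mask.  Frame i uses the child seed
    ``SeedSequence([seed, i])``.
    """
    frames = []
    child_seeds = []
    for i, geometry in enumerate(spec.geometries):
        expected, mask = _expected_counts(spec, geometry)
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, i]))
        counts = rng.poisson(expected).astype(float)
        frames.append(
            DetectorFrame(
                counts=counts, exposure=1.0, geometry=geometry, mask=mask,
                meta={"synthetic": True, "frame_index": i},
            )
        )
        child_seeds.append([spec.seed, i])
    record = dict(spec.to_dict(), child_seeds=child_seeds)
    return frames, record


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_set(spec: SyntheticSpec, out_dir: str | Path) -> dict:
    """Write frames (HDF5), ground truth and a hash manifest.

    The manifest embeds the full spec, so ``regenerate_from_manifest``
    reproduces every file bit-identically (HDF5 timestamps are
    disabled by the frame writer).  Returns the manifest dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames, record = generate_frames(spec)
    entries = []
    for i, frame in enumerate(frames):
        name = f"frame_{i:02d}_sdd{int(frame.geometry.sdd)}mm.h5"
        path = out_dir / name
        write_frame_hdf5(frame, path)
        entries.append({"file": name, "sha256": _sha256(path)})
    truth_path = out_dir / "ground_truth.json"
    truth_path.write_text(json.dumps(record, indent=2, sort_keys=True))
    entries.append(
        {"file": truth_path.name, "sha256": _sha256(truth_path)}
    )
    manifest = {
        "spec": spec.to_dict(),
        "files": entries,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest


def regenerate_from_manifest(
    manifest_path: str | Path, out_dir: str | Path
) -> dict:
    """Rebuild a fixture set from its manifest; returns the new manifest."""
    manifest = json.loads(Path(manifest_path).read_text())
    spec = SyntheticSpec.from_dict(manifest["spec"])
    return write_fixture_set(spec, out_dir)
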