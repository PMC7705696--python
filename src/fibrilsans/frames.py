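"""2D detector frames, instrument geometry and the pixel q/azimuth map.

The geometry convention follows a fiber-diffraction SANS setup: the
sample's fiber (cell) axis is vertical, so the equatorial streak carrying
the lateral microfibril structure runs horizontally across the detector.
Azimuth is measured in degrees from the horizontal equator, increasing
towards the top row of the frame as seen from the sample, and is treated
as periodic in 180 degrees wherever only orientation (not direction)
matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

__all__ = [
    "Geometry",
    "DetectorFrame",
    "build_qmap",
    "solid_angle_weight",
    "read_frame_hdf5",
    "write_frame_hdf5",
    "read_frame_text",
    "write_frame_text",
]


@dataclass(frozen=True)
class Geometry:
    """Instrument geometry needed to map pixels to (q, azimuth).

    Parameters
    ----------
    wavelength : float
        Neutron wavelength in Å (> 0); the study's setting was 6.0 Å.
    sdd : float
        Sample-to-detector distance in mm (> 0).
    beam_center : tuple
        (row, col) of the direct beam in pixel coordinates (fractional
        allowed).
    pixel_size : float
        Square pixel edge in mm (> 0).
    """

    wavelength: float
    sdd: float
    beam_center: tuple[float, float]
    pixel_size: float

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be > 0")
        if self.sdd <= 0:
            raise ValueError("sdd must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


@dataclass
class DetectorFrame:
    """Gridded detector counts with geometry and an exclusion mask."""

    counts: np.ndarray
    exposure: float
    geometry: Geometry
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2D array")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.exposure <= 0:
            raise ValueError("exposure must be > 0")
        if self.mask is None:
            self.mask = np.zeros(self.counts.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.counts.shape:
                raise ValueError("mask shape must match counts shape")


def build_qmap(
    geometry: Geometry, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel scattering vector magnitude and azimuth.

    For a pixel at radial distance r from the beam center the scattering
    angle is 2θ = arctan(r / sdd) and q = 4π sin(θ) / λ.  Azimuth is
    measured from the horizontal equator and folded into [0, 180).

    Returns
    -------
    q : ndarray
        Å^-1, zero at the beam-center pixel (masked downstream).
    azimuth : ndarray
        Degrees in [0, 180), 0 = equator (horizontal), 90 = meridian.
    """
    rows, cols = np.indices(shape)
    dy = (geometry.beam_center[0] - rows) * geometry.pixel_size  # up = +
    dx = (cols - geometry.beam_center[1]) * geometry.pixel_size
    r = np.hypot(dx, dy)
    two_theta = np.arctan2(r, geometry.sdd)
    q = 4.0 * np.pi * np.sin(two_theta / 2.0) / geometry.wavelength
    azimuth = np.degrees(np.arctan2(dy, dx)) % 180.0
    return q, azimuth


def solid_angle_weight(geometry: Geometry, shape: tuple[int, int]) -> np.ndarray:
    """Relative solid angle subtended per pixel, cos^3(2θ).

    A flat detector pixel at scattering angle 2θ subtends a solid angle
    reduced by cos^3(2θ) relative to a pixel at normal incidence (one
    cosine for the increased distance squared, one for the tilt).
    Expected counts are proportional to I(q, φ) times this weight;
    reduction divides it out.
    """
    rows, cols = np.indices(shape)
    dy = (geometry.beam_center[0] - rows) * geometry.pixel_size
    dx = (cols - geometry.beam_center[1]) * geometry.pixel_size
    r = np.hypot(dx, dy)
    two_theta = np.arctan2(r, geometry.sdd)
    return np.cos(two_theta) ** 3


# ---------------------------------------------------------------------------
# I/O: HDF5 layout /entry/data/counts + /entry/geometry/*, or text matrix
# with YAML sidecar geometry.

def write_frame_hdf5(frame: DetectorFrame, path: str | Path) -> None:
    with h5py.File(path, "w") as h5:
        data = h5.create_group("entry/data")
        data.create_dataset("counts", data=frame.counts, track_times=False)
        data.create_dataset("mask", data=frame.mask.astype(np.uint8), track_times=False)
        data.attrs["exposure_s"] = frame.exposure
        geo = h5.create_group("entry/geometry")
        geo.create_dataset("wavelength_A", data=frame.geometry.wavelength, track_times=False)
        geo.create_dataset("sdd_mm", data=frame.geometry.sdd, track_times=False)
        geo.create_dataset(
            "beam_center_px", data=np.asarray(frame.geometry.beam_center),
            track_times=False,
        )
        geo.create_dataset("pixel_size_mm", data=frame.geometry.pixel_size, track_times=False)


def read_frame_hdf5(path: str | Path) -> DetectorFrame:
    with h5py.File(path, "r") as h5:
        counts = h5["entry/data/counts"][()]
        mask = (
            h5["entry/data/mask"][()].astype(bool)
            if "entry/data/mask" in h5
            else None
        )
        exposure = float(h5["entry/data"].attrs.get("exposure_s", 1.0))
        geo = h5["entry/geometry"]
        geometry = Geometry(
            wavelength=float(geo["wavelength_A"][()]),
            sdd=float(geo["sdd_mm"][()]),
            beam_center=tuple(np.asarray(geo["beam_center_px"][()])),
            pixel_size=float(geo["pixel_size_mm"][()]),
        )
    return DetectorFrame(
        counts=counts, exposure=exposure, geometry=geometry, mask=mask
    )


def write_frame_text(frame: DetectorFrame, path: str | Path) -> None:
    """Counts as a whitespace matrix plus a ``.geom.yaml`` sidecar."""
    path = Path(path)
    np.savetxt(path, frame.counts, fmt="%.6g")
    sidecar = {
        "wavelength_A": frame.geometry.wavelength,
        "sdd_mm": frame.geometry.sdd,
        "beam_center_px": list(frame.geometry.beam_center),
        "pixel_size_mm": frame.geometry.pixel_size,
        "exposure_s": frame.exposure,
    }
    path.with_suffix(path.suffix + ".geom.yaml").write_text(
        yaml.safe_dump(sidecar)
    )
    if frame.mask.any():
        np.savetxt(
            path.with_suffix(path.suffix + ".mask"),
            frame.mask.astype(int),
            fmt="%d",
        )


def read_frame_text(path: str | Path) -> DetectorFrame:
    path = Path(path)
    counts = np.loadtxt(path)
    sidecar = yaml.safe_load(
        path.with_suffix(path.suffix + ".geom.yaml").read_text()
    )
    geometry = Geometry(
        wavelength=float(sidecar["wavelength_A"]),
        sdd=float(sidecar["sdd_mm"]),
        beam_center=tuple(float(x) for x in sidecar["beam_center_px"]),
        pixel_size=float(sidecar["pixel_size_mm"]),
    )
    mask_path = path.with_suffix(path.suffix + ".mask")
    mask = np.loadtxt(mask_path).astype(bool) if mask_path.exists() else None
    return DetectorFrame(
        counts=counts,
        exposure=float(sidecar.get("exposure_s", 1.0)),
        geometry=geometry,
        mask=mask,
    )
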