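"""1D scattering profiles (q, I, sigma) and their plain-text round trip."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["Profile1D", "read_profile", "write_profile"]


@dataclass
class Profile1D:
    """A 1D scattering curve I(q) with pointwise uncertainties.

    Attributes
    ----------
    q : ndarray
        Scattering-vector magnitudes in Å^-1, strictly increasing, > 0.
    I : ndarray
        Intensities; absolute (cm^-1) only if ``absolute_units`` is set,
        otherwise relative.  Negative values are allowed (an isotropic
        subtraction can undershoot within noise) and retained.
    sigma : ndarray
        1-sigma uncertainties, same units as I, all >= 0.
    meta : dict
        Provenance: sector specification, configurations merged, scale
        factors, flags.
    absolute_units : bool
        True when I is calibrated to cm^-1.
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray
    meta: dict = field(default_factory=dict)
    absolute_units: bool = False

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (self.q.shape == self.I.shape == self.sigma.shape):
            raise ValueError(
                f"q/I/sigma length mismatch: {self.q.shape}, "
                f"{self.I.shape}, {self.sigma.shape}"
            )
        if self.q.ndim != 1:
            raise ValueError("profile arrays must be 1D")
        if np.any(self.q <= 0):
            raise ValueError("all q must be > 0")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be >= 0")

    def __len__(self) -> int:
        return self.q.size

    def restrict(self, q_lo: float, q_hi: float) -> "Profile1D":
        """Sub-profile with q in [q_lo, q_hi]."""
        keep = (self.q >= q_lo) & (self.q <= q_hi)
        return replace(
            self, q=self.q[keep], I=self.I[keep], sigma=self.sigma[keep]
        )

    def scaled(self, factor: float) -> "Profile1D":
        """Profile with I and sigma multiplied by *factor* (> 0)."""
        if factor <= 0:
            raise ValueError("scale factor must be > 0")
        return replace(
            self, I=self.I * factor, sigma=self.sigma * factor
        )


def write_profile(profile: Profile1D, path: str | Path) -> None:
    """Write a 3-column ``q I sigma`` ASCII file with ``#`` metadata."""
    path = Path(path)
    lines = ["# fibrilsans 1D profile", "# columns: q[1/A] I sigma"]
    lines.append(f"# absolute_units: {profile.absolute_units}")
    for key, value in profile.meta.items():
        lines.append(f"# {key}: {value}")
    for q, i, s in zip(profile.q, profile.I, profile.sigma):
        lines.append(f"{q:.8e} {i:.8e} {s:.8e}")
    path.write_text("\n".join(lines) + "\n")


def read_profile(path: str | Path) -> Profile1D:
    """Read a 3-column ASCII profile; tolerates comments and blank lines."""
    path = Path(path)
    meta: dict = {}
    absolute = False
    rows = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                key, value = key.strip(), value.strip()
                if key == "absolute_units":
                    absolute = value.lower() == "true"
                elif key not in ("columns",):
                    meta[key] = value
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(
                f"{path}: expected 3 columns (q I sigma), got {line!r}"
            )
        rows.append([float(parts[0]), float(parts[1]), float(parts[2])])
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.array(rows)
    order = np.argsort(arr[:, 0])
    arr = arr[order]
    return Profile1D(
        q=arr[:, 0], I=arr[:, 1], sigma=arr[:, 2],
        meta=meta, absolute_units=absolute,
    )
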