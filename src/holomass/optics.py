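"""Physical quantities linking inline-hologram contrast to dry mass.

The dry mass of a cell is the mass of its non-water content,
``m = V (c_obj - c_med)``, with ``c`` the solute mass concentration.  Because
the refractive index of a dilute solution grows linearly with concentration
(slope dn/dc, the specific refractive-index increment), the same quantity is
encoded optically: ``m = V * Δn / (dn/dc)``.  Forward scattering at small
angles is proportional to the integrated index contrast ``V·Δn``, which is
why an inline hologram carries the dry mass of each scatterer.

Unit conventions used throughout the package: lengths in µm, masses in pg,
wavelengths in nm where explicitly noted, dn/dc in ml/g.  With those units
the conversion is numerically clean: 1 µm³ = 1e-12 ml and 1 g = 1e12 pg
cancel, so ``mass_pg = V_µm³ * Δn / dndc_mlg``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "OpticalConfig",
    "Particle",
    "dry_mass_from_optics",
    "refractive_index_from_dry_mass",
    "coherence_length",
    "pixel_pitch",
    "carbon_from_volume",
    "dry_mass_from_elemental",
    "DEFAULT_DN_DC",
]

#: Specific refractive-index increment of average planktonic solute
#: composition, ml/g.
DEFAULT_DN_DC = 0.21


def dry_mass_from_optics(
    radius: float, n_particle: float, n_medium: float, dn_dc: float = DEFAULT_DN_DC
) -> float:
    """Dry mass (pg) of a sphere from its refractive-index contrast.

    Parameters
    ----------
    radius : float
        Equivalent spherical radius in µm.
    n_particle, n_medium : float
        Refractive indices of the particle and the surrounding medium.
    dn_dc : float
        Specific refractive-index increment in ml/g.

    Returns
    -------
    float
        ``(4/3)π r³ (n_particle - n_medium) / (dn/dc)`` in pg.
    """
    radius = np.asarray(radius, dtype=float) if np.ndim(radius) else float(radius)
    if np.any(np.asarray(radius) <= 0):
        raise ValueError("radius must be strictly positive")
    if dn_dc <= 0:
        raise ValueError("dn_dc must be strictly positive")
    volume = 4.0 / 3.0 * math.pi * radius**3  # µm³ == 1e-12 ml
    return volume * (n_particle - n_medium) / dn_dc


def refractive_index_from_dry_mass(
    dry_mass: float, radius: float, n_medium: float, dn_dc: float = DEFAULT_DN_DC
) -> float:
    """Refractive index a sphere must have to carry ``dry_mass`` pg.

    Exact algebraic inverse of :func:`dry_mass_from_optics`.
    """
    if np.any(np.asarray(radius) <= 0):
        raise ValueError("radius must be strictly positive")
    if dn_dc <= 0:
        raise ValueError("dn_dc must be strictly positive")
    volume = 4.0 / 3.0 * math.pi * np.asarray(radius, dtype=float) ** 3
    out = n_medium + dry_mass * dn_dc / volume
    return float(out) if np.ndim(out) == 0 else out


def coherence_length(center_wavelength: float, bandwidth: float) -> float:
    """Temporal coherence length λ²/(2Δλ) in µm.

    Both arguments in nm.  Bounds the usable source-to-sensor path
    difference, hence the axial extent of the observation volume.  (The
    λ²/Δλ convention, twice this value, is also in circulation; the factor
    1/2 matches the quoted ~200 µm for a 632.8 nm source behind a 1 nm
    line filter.)
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be strictly positive")
    return center_wavelength**2 / (2.0 * bandwidth) * 1e-3  # nm -> µm


def pixel_pitch(sensor_extent_mm: float, n_pixels: int) -> float:
    """Sensor pixel pitch in µm from one sensor dimension (mm) and its pixel count."""
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")
    return sensor_extent_mm * 1e3 / n_pixels


def carbon_from_volume(volume: float, coefficients: tuple[float, float]) -> float:
    """Cellular carbon content (pg) from cell volume (µm³).

    Uses the log-log allometry ``log10 C = log_a + b log10 V`` with
    trophic-group-specific coefficients supplied by the caller (they are
    configuration, not constants of this package).
    """
    if np.any(np.asarray(volume) <= 0):
        raise ValueError("volume must be strictly positive")
    log_a, b = coefficients
    return 10.0 ** (log_a + b * np.log10(volume))


def dry_mass_from_elemental(carbon: float, stoichiometric_multiplier: float) -> float:
    """Total dry mass (pg) from carbon mass (pg).

    The multiplier extrapolates carbon to the full elemental composition
    (H, O, N, P) via an extended Redfield-ratio table; it is configuration
    with literature provenance, not a baked-in constant.
    """
    if stoichiometric_multiplier < 1:
        raise ValueError("stoichiometric_multiplier must be >= 1")
    if np.any(np.asarray(carbon) < 0):
        raise ValueError("carbon must be non-negative")
    return carbon * stoichiometric_multiplier


@dataclass(frozen=True)
class OpticalConfig:
    """Illumination, sensor geometry and medium for one instrument.

    Defaults describe a lensless inline holographic microscope: narrow-band
    red LED (632 nm center, 18 nm bandwidth) over a CMOS sensor of
    4.608 mm x 3.686 mm with 1280 x 1024 pixels (3.6 µm pitch), sample in
    seawater-like medium, 10 fps.
    """

    center_wavelength_nm: float = 632.0
    filter_bandwidth_nm: float = 18.0
    sensor_size_mm: tuple[float, float] = (4.608, 3.686)  # (width, height)
    sensor_pixels: tuple[int, int] = (1280, 1024)  # (cols, rows)
    medium_refractive_index: float = 1.33
    dn_dc_ml_g: float = DEFAULT_DN_DC
    frame_interval_s: float = 0.1

    def __post_init__(self) -> None:
        if self.center_wavelength_nm <= 0 or self.filter_bandwidth_nm <= 0:
            raise ValueError("wavelength and bandwidth must be positive")
        if any(s <= 0 for s in self.sensor_size_mm) or any(
            p < 1 for p in self.sensor_pixels
        ):
            raise ValueError("sensor geometry must be positive")
        if self.dn_dc_ml_g <= 0:
            raise ValueError("dn_dc must be positive")
        if self.medium_refractive_index < 1:
            raise ValueError("medium refractive index must be >= 1")
        if self.frame_interval_s <= 0:
            raise ValueError("frame interval must be positive")

    @property
    def pixel_pitch_um(self) -> float:
        """Pitch derived from sensor width / column count."""
        return pixel_pitch(self.sensor_size_mm[0], self.sensor_pixels[0])

    @property
    def wavelength_um(self) -> float:
        return self.center_wavelength_nm * 1e-3

    @property
    def medium_wavelength_um(self) -> float:
        """Wavelength inside the medium, which sets the fringe geometry."""
        return self.wavelength_um / self.medium_refractive_index

    @property
    def coherence_length_um(self) -> float:
        return coherence_length(self.center_wavelength_nm, self.filter_bandwidth_nm)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["sensor_size_mm"] = list(self.sensor_size_mm)
        d["sensor_pixels"] = list(self.sensor_pixels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown OpticalConfig keys: {sorted(unknown)}")
        d = dict(d)
        if "sensor_size_mm" in d:
            d["sensor_size_mm"] = tuple(d["sensor_size_mm"])
        if "sensor_pixels" in d:
            d["sensor_pixels"] = tuple(int(v) for v in d["sensor_pixels"])
        return cls(**d)


@dataclass
class Particle:
    """One spherical scatterer: 3D position, size, index and dry mass.

    ``z`` is the axial distance from the detector plane (positive above the
    sensor).  ``dry_mass`` is kept consistent with (radius, refractive
    index) through the dn/dc relation; use the constructors below rather
    than setting fields independently.
    """

    x: float
    y: float
    z: float
    radius: float
    refractive_index: float
    dry_mass: float = field(default=0.0)

    @classmethod
    def from_index(
        cls,
        x: float,
        y: float,
        z: float,
        radius: float,
        refractive_index: float,
        config: OpticalConfig,
    ) -> "Particle":
        m = dry_mass_from_optics(
            radius,
            refractive_index,
            config.medium_refractive_index,
            config.dn_dc_ml_g,
        )
        return cls(x, y, z, radius, refractive_index, m)

    @classmethod
    def from_dry_mass(
        cls,
        x: float,
        y: float,
        z: float,
        radius: float,
        dry_mass: float,
        config: OpticalConfig,
    ) -> "Particle":
        n = refractive_index_from_dry_mass(
            dry_mass, radius, config.medium_refractive_index, config.dn_dc_ml_g
        )
        return cls(x, y, z, radius, n, dry_mass)

    def validate(self, config: OpticalConfig) -> None:
        if self.radius <= 0:
            raise ValueError("particle radius must be positive")
        if self.z <= 0:
            raise ValueError("particle must sit above the detector plane (z > 0)")
        m = dry_mass_from_optics(
            self.radius,
            self.refractive_index,
            config.medium_refractive_index,
            config.dn_dc_ml_g,
        )
        if abs(m - self.dry_mass) > 1e-6:
            raise ValueError(
                f"dry_mass={self.dry_mass} inconsistent with optics-derived {m}"
            )
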