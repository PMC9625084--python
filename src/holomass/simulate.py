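"""Synthetic inline holograms with paired ground truth.

A scene of spherical scatterers above a bare sensor is rendered with a
first-order scattering model: each particle is a thin complex transmittance
(integrated phase = vacuum wavenumber x Δn x chord length through the
sphere), its scattered field is propagated to the detector plane with the
band-limited angular-spectrum transfer function for its own axial distance,
the per-particle fields are summed with the unit-amplitude plane wave, and
the intensity is normalized by the unscattered intensity so the empty
background is exactly 1.

The same module renders the per-pixel supervision targets used to train the
detection network (segmentation, z, dry mass, and the signed in-plane
offsets to the nearest particle center), samples random training scenes and
crop sequences, builds scripted feeding/division movies, and round-trips
datasets through HDF5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .optics import OpticalConfig, Particle

__all__ = [
    "Scene",
    "Hologram",
    "TruthMaps",
    "SequenceSample",
    "SceneParams",
    "SequenceParams",
    "aliasing_z_limit",
    "simulate_hologram",
    "render_truth_maps",
    "sample_runet_scene",
    "sample_wacnet_sequence",
    "make_feeding_movie",
    "make_division_movie",
    "write_dataset",
    "read_dataset",
    "DatasetFormatError",
]

#: offsets farther than this from any particle center are undefined (left 0)
OFFSET_RANGE_PX = 16


@dataclass
class Scene:
    """Ground-truth scatterers over one sensor frame."""

    particles: list[Particle]
    config: OpticalConfig
    image_shape: tuple[int, int] = (128, 128)  # (rows, cols)
    noise_sigma: float = 0.0  # additive Gaussian, intensity fraction
    gradient_amplitude: float = 0.0  # illumination gradient, intensity fraction

    @property
    def pitch(self) -> float:
        return self.config.pixel_pitch_um

    def z_limit(self) -> float:
        rows, cols = self.image_shape
        return aliasing_z_limit(
            min(rows, cols), self.pitch, self.config.medium_wavelength_um
        )

    def validate(self) -> None:
        rows, cols = self.image_shape
        pitch = self.pitch
        zlim = self.z_limit()
        for p in self.particles:
            xp, yp = p.x / pitch, p.y / pitch
            if not (1.0 <= xp <= cols - 2.0 and 1.0 <= yp <= rows - 2.0):
                raise ValueError(
                    f"particle at ({xp:.1f},{yp:.1f}) px outside field of view "
                    f"({rows}x{cols}, margin 1 px)"
                )
            if p.z <= 0:
                raise ValueError("particle z must be positive")
            if p.z > zlim:
                raise ValueError(
                    f"particle z={p.z:.0f} µm beyond the angular-spectrum "
                    f"anti-aliasing limit {zlim:.0f} µm for a "
                    f"{min(rows, cols)}-px grid at {pitch:.2f} µm pitch"
                )


@dataclass
class Hologram:
    """One normalized inline hologram (background == 1)."""

    pixels: np.ndarray  # (rows, cols) float
    pixel_pitch_um: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class TruthMaps:
    """Per-pixel supervision targets for one scene.

    ``dx``/``dy`` are the signed in-plane offsets (in px) from a pixel to
    the nearest particle center — positive when the center lies at larger
    x/y — defined only within ``OFFSET_RANGE_PX`` of a center
    (``offset_mask``); ``z``/``mass`` carry the owning particle's values on
    its segmentation disk and 0 elsewhere.
    """

    seg: np.ndarray  # float {0,1}
    z: np.ndarray  # µm
    mass: np.ndarray  # pg
    dx: np.ndarray  # px, signed
    dy: np.ndarray  # px, signed
    offset_mask: np.ndarray  # bool, where dx/dy are defined

    def stack(self) -> np.ndarray:
        return np.stack([self.seg, self.z, self.mass, self.dx, self.dy], axis=-1)


@dataclass
class SequenceSample:
    """A 15-frame crop sequence following one particle of constant mass."""

    frames: np.ndarray  # (n_frames, size, size)
    target_mass: float  # pg
    target_radius: float  # µm
    target_optical_volume: float  # V·Δn, pg·(ml/g) — dn/dc-free label
    distractors: list[dict] = field(default_factory=list)
    seed: int | None = None


def aliasing_z_limit(n_pixels: int, pitch_um: float, wavelength_medium_um: float) -> float:
    """Largest propagation distance the sampled angular-spectrum kernel supports.

    Beyond this distance the transfer-function phase gradient exceeds π per
    frequency sample at the Nyquist frequency and the kernel aliases.
    """
    f_nyq_sq = 1.0 / (4.0 * pitch_um**2)
    inv_lam_sq = 1.0 / wavelength_medium_um**2
    if f_nyq_sq >= inv_lam_sq:
        # pitch finer than half a wavelength: evanescent cutoff governs
        return np.inf
    return n_pixels * pitch_um**2 * math.sqrt(inv_lam_sq - f_nyq_sq)


def _angular_spectrum_kernel(
    shape: tuple[int, int], pitch: float, lam: float, z: float
) -> np.ndarray:
    """Band-limited scalar propagation kernel H(fx, fy; z) on the FFT grid."""
    rows, cols = shape
    fy = np.fft.fftfreq(rows, d=pitch)[:, None]
    fx = np.fft.fftfreq(cols, d=pitch)[None, :]
    f_sq = fx**2 + fy**2
    arg = 1.0 / lam**2 - f_sq
    prop = arg > 0  # drop evanescent components
    kz = np.sqrt(np.where(prop, arg, 0.0))
    H = np.where(prop, np.exp(2j * np.pi * z * kz), 0.0)
    # band limit against kernel aliasing (local frequency of H under π/sample)
    flim_x = 1.0 / (lam * math.sqrt((2.0 * z / (cols * pitch)) ** 2 + 1.0))
    flim_y = 1.0 / (lam * math.sqrt((2.0 * z / (rows * pitch)) ** 2 + 1.0))
    H *= (np.abs(fx) <= flim_x) & (np.abs(fy) <= flim_y)
    return H


def _render_transmittance_deviation(
    shape: tuple[int, int],
    particle: Particle,
    config: OpticalConfig,
    supersample: int | None = None,
) -> np.ndarray:
    """Area-averaged ``exp(iφ) - 1`` of one particle on the pixel grid.

    φ is the phase picked up through the sphere relative to the medium:
    2π Δn chord / λ_vacuum.  Pixels are supersampled so that sub-pixel
    particles contribute the correct integrated phase (which carries the
    dry mass).
    """
    rows, cols = shape
    pitch = config.pixel_pitch_um
    r_px = particle.radius / pitch
    if supersample is None:
        supersample = 16 if r_px < 1.5 else 8
    xc, yc = particle.x / pitch, particle.y / pitch
    half = int(math.ceil(r_px)) + 2
    x0, x1 = int(math.floor(xc)) - half, int(math.floor(xc)) + half + 1
    y0, y1 = int(math.floor(yc)) - half, int(math.floor(yc)) + half + 1
    x0c, x1c = max(x0, 0), min(x1, cols)
    y0c, y1c = max(y0, 0), min(y1, rows)
    if x0c >= x1c or y0c >= y1c:
        return np.zeros(shape, dtype=np.complex128)

    s = supersample
    sub = (np.arange(s) + 0.5) / s - 0.5
    xs = (np.arange(x0c, x1c)[:, None] + sub[None, :]).ravel()  # px
    ys = (np.arange(y0c, y1c)[:, None] + sub[None, :]).ravel()
    dx2 = ((xs - xc) * pitch) ** 2
    dy2 = ((ys - yc) * pitch) ** 2
    rho2 = dy2[:, None] + dx2[None, :]
    chord = 2.0 * np.sqrt(np.maximum(particle.radius**2 - rho2, 0.0))  # µm
    dn = particle.refractive_index - config.medium_refractive_index
    phi = (2.0 * np.pi / config.wavelength_um) * dn * chord
    t = np.exp(1j * phi) - 1.0
    # average the s x s subsamples of each pixel
    t = t.reshape(y1c - y0c, s, x1c - x0c, s).mean(axis=(1, 3))
    out = np.zeros(shape, dtype=np.complex128)
    out[y0c:y1c, x0c:x1c] = t
    return out


def simulate_hologram(scene: Scene, rng_seed: int | None = None) -> Hologram:
    """Render the normalized inline hologram of a scene.

    Deterministic for a given ``rng_seed``; with no noise configured the
    seed is irrelevant.  An empty scene yields an all-ones image.
    """
    scene.validate()
    shape = scene.image_shape
    lam = scene.config.medium_wavelength_um
    pitch = scene.pitch

    field_dev = np.zeros(shape, dtype=np.complex128)
    for p in scene.particles:
        t = _render_transmittance_deviation(shape, p, scene.config)
        H = _angular_spectrum_kernel(shape, pitch, lam, p.z)
        field_dev += np.fft.ifft2(np.fft.fft2(t) * H)

    intensity = np.abs(1.0 + field_dev) ** 2
    if scene.gradient_amplitude > 0 or scene.noise_sigma > 0:
        rng = np.random.default_rng(rng_seed)
        if scene.gradient_amplitude > 0:
            intensity = intensity + _illumination_gradient(
                shape, scene.gradient_amplitude, rng
            )
        if scene.noise_sigma > 0:
            intensity = intensity + rng.normal(0.0, scene.noise_sigma, size=shape)
    # unscattered intensity is 1 by construction; clamp sensor floor
    return Hologram(np.maximum(intensity, 0.0), pitch)


def _illumination_gradient(
    shape: tuple[int, int], amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean low-order polynomial shading of peak amplitude ``amplitude``."""
    rows, cols = shape
    y = np.linspace(-1, 1, rows)[:, None]
    x = np.linspace(-1, 1, cols)[None, :]
    basis = [x, y, x * y, x**2 - 1.0 / 3.0, y**2 - 1.0 / 3.0]
    coeffs = rng.normal(size=len(basis))
    g = sum(c * b for c, b in zip(coeffs, basis))
    peak = np.max(np.abs(g))
    return g * (amplitude / peak) if peak > 0 else np.zeros(shape)


# ---------------------------------------------------------------------------
# ground-truth maps
# ---------------------------------------------------------------------------


def render_truth_maps(scene: Scene) -> TruthMaps:
    """Per-pixel supervision targets for a scene (see :class:`TruthMaps`)."""
    rows, cols = scene.image_shape
    pitch = scene.pitch
    seg = np.zeros((rows, cols), dtype=np.float64)
    zmap = np.zeros((rows, cols))
    mmap = np.zeros((rows, cols))
    dxm = np.zeros((rows, cols))
    dym = np.zeros((rows, cols))
    mask = np.zeros((rows, cols), dtype=bool)
    if not scene.particles:
        return TruthMaps(seg, zmap, mmap, dxm, dym, mask)

    yy = np.arange(rows)[:, None]
    xx = np.arange(cols)[None, :]
    centers = np.array([[p.x / pitch, p.y / pitch] for p in scene.particles])
    # squared pixel distance to each center, (n_particles, rows, cols)
    d2 = (
        (xx[None] - centers[:, 0, None, None]) ** 2
        + (yy[None] - centers[:, 1, None, None]) ** 2
    )
    nearest = np.argmin(d2, axis=0)
    d2_near = np.take_along_axis(d2, nearest[None], axis=0)[0]

    # seg disk per particle; on overlap the nearest covering particle owns
    # the pixel's z/mass values
    disk_r = np.array([max(2.0, p.radius / pitch) for p in scene.particles])
    cover = d2 <= (disk_r**2)[:, None, None]
    seg = np.any(cover, axis=0).astype(np.float64)
    d2_covered = np.where(cover, d2, np.inf)
    owner = np.argmin(d2_covered, axis=0)
    z_vals = np.array([p.z for p in scene.particles])
    m_vals = np.array([p.dry_mass for p in scene.particles])
    zmap = np.where(seg > 0, z_vals[owner], 0.0)
    mmap = np.where(seg > 0, m_vals[owner], 0.0)

    mask = d2_near <= OFFSET_RANGE_PX**2
    cx = centers[nearest, 0]
    cy = centers[nearest, 1]
    dxm = np.where(mask, cx - xx, 0.0)
    dym = np.where(mask, cy - yy, 0.0)
    return TruthMaps(seg, zmap, mmap, dxm, dym, mask)


# ---------------------------------------------------------------------------
# random training scenes / sequences
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneParams:
    """Training-scene distribution for the detection network.

    Dry mass uniform on [1, 995] pg and equivalent spherical diameter
    uniform on [1.5, 10] µm; the refractive index of each draw follows from
    the dn/dc relation.  Axial positions uniform over ``z_range``; the
    default upper end is set by the 128-px grid's propagation limit (the
    observation well sits ~1.5 mm above the sensor).
    """

    n_particles: tuple[int, int] = (1, 8)
    mass_range_pg: tuple[float, float] = (1.0, 995.0)
    diameter_range_um: tuple[float, float] = (1.5, 10.0)
    z_range_um: tuple[float, float] = (500.0, 2000.0)
    image_shape: tuple[int, int] = (128, 128)
    margin_px: float = 6.0
    noise_sigma: float = 0.01
    gradient_amplitude: float = 0.02


@dataclass(frozen=True)
class SequenceParams:
    """Crop-sequence distribution for the mass-refinement network.

    The main particle stays laterally centered (the crop follows it; its
    global step is uniform in ±1 px) and walks axially by ±100 µm per
    frame.  Occasional distractor particles cross the crop with a fixed
    random heading at 1–7 px/frame.
    """

    n_frames: int = 15
    crop_size: int = 64
    mass_range_pg: tuple[float, float] = (1.0, 995.0)
    diameter_range_um: tuple[float, float] = (1.5, 10.0)
    z_range_um: tuple[float, float] = (500.0, 1500.0)
    lateral_step_px: float = 1.0
    z_step_um: float = 100.0
    distractor_prob: float = 0.3
    distractor_speed_px: tuple[float, float] = (1.0, 7.0)
    noise_sigma: float = 0.01
    gradient_amplitude: float = 0.0


def _draw_particle_properties(
    rng: np.random.Generator, config: OpticalConfig, params
) -> tuple[float, float, float]:
    """Draw (mass pg, radius µm, refractive index) for one training particle.

    Equivalent spherical diameter is uniform over the configured range and
    the index contrast Δn is uniform over the range implied by the mass
    endpoints (smallest mass at the smallest cell, largest at the largest),
    so cells of different sizes and refractive indices jointly span the
    configured dry-mass range with physically coupled size/contrast values.
    Draws that would require Δn < 0 are rejected and resampled (capped at
    1000 attempts).
    """
    from .optics import dry_mass_from_optics

    d_lo, d_hi = params.diameter_range_um
    m_lo, m_hi = params.mass_range_pg
    v_lo = 4.0 / 3.0 * np.pi * (d_lo / 2.0) ** 3
    v_hi = 4.0 / 3.0 * np.pi * (d_hi / 2.0) ** 3
    dn_lo = m_lo * config.dn_dc_ml_g / v_lo
    dn_hi = m_hi * config.dn_dc_ml_g / v_hi
    for _ in range(1000):
        diameter = rng.uniform(d_lo, d_hi)
        dn = rng.uniform(min(dn_lo, dn_hi), max(dn_lo, dn_hi))
        if dn < 0:
            continue
        radius = diameter / 2.0
        n = config.medium_refractive_index + dn
        mass = dry_mass_from_optics(radius, n, config.medium_refractive_index,
                                    config.dn_dc_ml_g)
        return mass, radius, n
    raise RuntimeError("could not draw a feasible particle in 1000 attempts")


def sample_runet_scene(
    rng: np.random.Generator | int, config: OpticalConfig, params: SceneParams
) -> Scene:
    """Draw one random training scene (reproducible given the generator state)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rows, cols = params.image_shape
    pitch = config.pixel_pitch_um
    n = int(rng.integers(params.n_particles[0], params.n_particles[1] + 1))
    particles = []
    for _ in range(n):
        mass, radius, nidx = _draw_particle_properties(rng, config, params)
        m = params.margin_px
        x = rng.uniform(m, cols - 1 - m) * pitch
        y = rng.uniform(m, rows - 1 - m) * pitch
        z = rng.uniform(*params.z_range_um)
        particles.append(Particle(x, y, z, radius, nidx, mass))
    return Scene(
        particles,
        config,
        image_shape=params.image_shape,
        noise_sigma=params.noise_sigma,
        gradient_amplitude=params.gradient_amplitude,
    )


def sample_wacnet_sequence(
    rng: np.random.Generator | int, config: OpticalConfig, params: SequenceParams
) -> SequenceSample:
    """Draw one crop sequence following a particle of constant mass and radius."""
    if not isinstance(rng, np.random.Generator):
        seed = int(rng)
        rng = np.random.default_rng(seed)
    else:
        seed = None
    size = params.crop_size
    pitch = config.pixel_pitch_um
    mass, radius, nidx = _draw_particle_properties(rng, config, params)

    # global lateral walk of the main particle, in px
    steps = rng.uniform(
        -params.lateral_step_px, params.lateral_step_px, size=(params.n_frames, 2)
    )
    pos_px = np.cumsum(steps, axis=0) + size / 2.0
    z0 = rng.uniform(*params.z_range_um)
    zs = np.empty(params.n_frames)
    zs[0] = z0
    for t in range(1, params.n_frames):
        zs[t] = np.clip(
            zs[t - 1] + rng.uniform(-params.z_step_um, params.z_step_um),
            *params.z_range_um,
        )

    distractors: list[dict] = []
    if rng.uniform() < params.distractor_prob:
        d_mass, d_radius, d_n = _draw_particle_properties(rng, config, params)
        heading = rng.uniform(0, 2 * np.pi)
        speed = rng.uniform(*params.distractor_speed_px)
        start = rng.uniform(8, size - 8, size=2)
        d_z0 = rng.uniform(*params.z_range_um)
        d_zs = np.empty(params.n_frames)
        d_zs[0] = d_z0
        for t in range(1, params.n_frames):
            d_zs[t] = np.clip(
                d_zs[t - 1] + rng.uniform(-params.z_step_um, params.z_step_um),
                *params.z_range_um,
            )
        d_pos = start[None, :] + speed * np.arange(params.n_frames)[:, None] * np.array(
            [np.cos(heading), np.sin(heading)]
        )
        distractors.append(
            {
                "mass_pg": d_mass,
                "radius_um": d_radius,
                "refractive_index": d_n,
                "speed_px": speed,
                "heading_rad": heading,
                "positions_px": d_pos,
                "z_um": d_zs,
            }
        )

    frames = np.empty((params.n_frames, size, size), dtype=np.float64)
    for t in range(params.n_frames):
        # crop re-centered on the rounded main-particle position: only the
        # sub-pixel residual (within ±1 px by construction) remains
        center = np.round(pos_px[t])
        residual = pos_px[t] - center
        parts = [
            Particle(
                (size / 2.0 + residual[0]) * pitch,
                (size / 2.0 + residual[1]) * pitch,
                zs[t],
                radius,
                nidx,
                mass,
            )
        ]
        for d in distractors:
            p_px = d["positions_px"][t] - center + size / 2.0
            if 1.0 <= p_px[0] <= size - 2.0 and 1.0 <= p_px[1] <= size - 2.0:
                parts.append(
                    Particle(
                        p_px[0] * pitch,
                        p_px[1] * pitch,
                        d["z_um"][t],
                        d["radius_um"],
                        d["refractive_index"],
                        d["mass_pg"],
                    )
                )
        scene = Scene(
            parts,
            config,
            image_shape=(size, size),
            noise_sigma=params.noise_sigma,
            gradient_amplitude=params.gradient_amplitude,
        )
        frames[t] = simulate_hologram(
            scene, rng_seed=int(rng.integers(0, 2**31 - 1))
        ).pixels

    dn = nidx - config.medium_refractive_index
    optical_volume = 4.0 / 3.0 * np.pi * radius**3 * dn
    return SequenceSample(frames, mass, radius, optical_volume, distractors, seed)


# ---------------------------------------------------------------------------
# scripted movies for trophic-event analyses
# ---------------------------------------------------------------------------


def make_feeding_movie(
    config: OpticalConfig,
    rng: np.random.Generator | int,
    *,
    n_frames: int = 220,
    image_shape: tuple[int, int] = (128, 128),
    predator_mass_pg: float = 300.0,
    prey_mass_pg: float = 30.0,
    predator_diameter_um: float = 8.0,
    prey_diameter_um: float = 3.0,
    contact_frame: int = 110,
    touch_separation_px: float = 4.0,
    z_um: float = 900.0,
    noise_sigma: float = 0.01,
    speed_px: float = 0.25,
) -> tuple[np.ndarray, dict]:
    """Scripted predator–prey encounter: prey approaches, is consumed, gone.

    The prey starts well outside the predator's analysis crop, closes in to
    ``touch_separation_px`` by ``contact_frame``, and is then ingested: its
    track terminates and the predator dry mass steps up by the prey mass.
    Returns the frame stack and a truth record with the programmed masses
    and paths.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rows, cols = image_shape
    pitch = config.pixel_pitch_um
    pred_xy = np.array([cols * 0.38, rows * 0.5])
    prey_start = np.array([cols * 0.90, rows * 0.34])
    start_sep = float(np.linalg.norm(prey_start - pred_xy))

    frames = np.empty((n_frames, rows, cols), dtype=np.float64)
    pred_path, prey_path = [], []
    pred_mass_series = []
    # ingestion conserves both dry mass and volume: the predator swells by
    # the prey's volume and gains its dry mass
    d_post = (predator_diameter_um**3 + prey_diameter_um**3) ** (1.0 / 3.0)
    for t in range(n_frames):
        jitter = rng.uniform(-speed_px, speed_px, size=2)
        pred_xy = np.clip(pred_xy + jitter, 8, [cols - 9, rows - 9])
        fed = t >= contact_frame
        pred_mass = predator_mass_pg + (prey_mass_pg if fed else 0.0)
        pred_diameter = d_post if fed else predator_diameter_um
        parts = [
            Particle.from_dry_mass(
                pred_xy[0] * pitch,
                pred_xy[1] * pitch,
                z_um,
                pred_diameter / 2,
                pred_mass,
                config,
            )
        ]
        pred_path.append(pred_xy.copy())
        pred_mass_series.append(pred_mass)
        if t < contact_frame:
            # separation shrinks linearly to the touch distance at ingestion
            frac = min(t / contact_frame, 1.0)
            sep = start_sep + (touch_separation_px - start_sep) * frac
            direction = (prey_start - pred_xy)
            direction /= np.linalg.norm(direction)
            prey_xy = pred_xy + direction * sep + rng.uniform(-0.1, 0.1, size=2)
            parts.append(
                Particle.from_dry_mass(
                    prey_xy[0] * pitch,
                    prey_xy[1] * pitch,
                    z_um - 20.0,
                    prey_diameter_um / 2,
                    prey_mass_pg,
                    config,
                )
            )
            prey_path.append(prey_xy.copy())
        scene = Scene(parts, config, image_shape=image_shape, noise_sigma=noise_sigma)
        frames[t] = simulate_hologram(scene, rng_seed=int(rng.integers(0, 2**31 - 1))).pixels

    truth = {
        "predator_mass_pg": predator_mass_pg,
        "prey_mass_pg": prey_mass_pg,
        "contact_frame": contact_frame,
        "predator_path_px": np.array(pred_path),
        "prey_path_px": np.array(prey_path),
        "predator_mass_series_pg": np.array(pred_mass_series),
    }
    return frames, truth


def make_division_movie(
    config: OpticalConfig,
    rng: np.random.Generator | int,
    *,
    n_frames: int = 200,
    image_shape: tuple[int, int] = (128, 128),
    parent_mass_pg: float = 420.0,
    daughter_fraction: float = 0.7,
    parent_diameter_um: float = 9.0,
    division_frame: int = 80,
    z_um: float = 900.0,
    separation_speed_px: float = 0.25,
    initial_separation_px: float = 20.0,
    noise_sigma: float = 0.01,
) -> tuple[np.ndarray, dict]:
    """Scripted mass-conserving division: one parent splits into two daughters.

    The daughters carry ``daughter_fraction`` and ``1 - daughter_fraction``
    of the parent dry mass (volume split in proportion), separate abruptly
    by ``initial_separation_px`` at the division frame (so the parent's
    track genuinely terminates), and then drift apart until the isolation
    criterion is satisfied.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rows, cols = image_shape
    pitch = config.pixel_pitch_um
    center = np.array([cols * 0.5, rows * 0.5])
    f = daughter_fraction
    d_masses = (parent_mass_pg * f, parent_mass_pg * (1 - f))
    d_radii = (
        parent_diameter_um / 2 * f ** (1 / 3),
        parent_diameter_um / 2 * (1 - f) ** (1 / 3),
    )
    sep_dir = np.array([1.0, 0.35])
    sep_dir /= np.linalg.norm(sep_dir)

    frames = np.empty((n_frames, rows, cols), dtype=np.float64)
    for t in range(n_frames):
        if t < division_frame:
            jit = rng.uniform(-0.15, 0.15, size=2)
            parts = [
                Particle.from_dry_mass(
                    (center[0] + jit[0]) * pitch,
                    (center[1] + jit[1]) * pitch,
                    z_um,
                    parent_diameter_um / 2,
                    parent_mass_pg,
                    config,
                )
            ]
        else:
            off = sep_dir * (
                initial_separation_px / 2.0
                + separation_speed_px * (t - division_frame)
            )
            parts = []
            for sgn, m, r in zip((1, -1), d_masses, d_radii):
                p_xy = np.clip(center + sgn * off, 6, [cols - 7, rows - 7])
                parts.append(
                    Particle.from_dry_mass(
                        p_xy[0] * pitch, p_xy[1] * pitch, z_um, r, m, config
                    )
                )
        scene = Scene(parts, config, image_shape=image_shape, noise_sigma=noise_sigma)
        frames[t] = simulate_hologram(scene, rng_seed=int(rng.integers(0, 2**31 - 1))).pixels

    truth = {
        "parent_mass_pg": parent_mass_pg,
        "daughter_masses_pg": d_masses,
        "division_frame": division_frame,
    }
    return frames, truth


# ---------------------------------------------------------------------------
# HDF5 datasets
# ---------------------------------------------------------------------------


class DatasetFormatError(RuntimeError):
    """Raised when a dataset file is missing, truncated or malformed."""


_TRUTH_CHANNELS = ("seg", "z", "mass", "dx", "dy", "offset_mask")


def write_dataset(samples, path, *, overwrite: bool = False, meta: dict | None = None):
    """Write holograms+truth pairs or crop sequences to one HDF5 file.

    ``samples`` is either a list of ``(Hologram, TruthMaps)`` pairs or a
    list of :class:`SequenceSample`.  Round trip through
    :func:`read_dataset` is lossless.
    """
    import os

    import h5py

    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    if not samples:
        raise ValueError("no samples to write")

    with h5py.File(path, "w") as f:
        f.attrs["format"] = "holomass-dataset-v1"
        for k, v in (meta or {}).items():
            f.attrs[k] = v
        if isinstance(samples[0], SequenceSample):
            g = f.create_group("sequences")
            g.create_dataset("frames", data=np.stack([s.frames for s in samples]))
            g.create_dataset("mass_pg", data=[s.target_mass for s in samples])
            g.create_dataset("radius_um", data=[s.target_radius for s in samples])
            g.create_dataset(
                "optical_volume", data=[s.target_optical_volume for s in samples]
            )
            g.create_dataset(
                "seed", data=[-1 if s.seed is None else s.seed for s in samples]
            )
        else:
            holos = [h.pixels for h, _ in samples]
            f.create_dataset("images", data=np.stack(holos))
            f.attrs["pixel_pitch_um"] = samples[0][0].pixel_pitch_um
            g = f.create_group("truth")
            for name in _TRUTH_CHANNELS:
                g.create_dataset(
                    name, data=np.stack([getattr(t, name) for _, t in samples])
                )


def read_dataset(path):
    """Read a dataset written by :func:`write_dataset`.

    Returns ``(samples, meta)`` with the same sample types that were
    written.
    """
    import h5py

    try:
        f = h5py.File(path, "r")
    except (OSError, IOError) as e:
        raise DatasetFormatError(f"cannot open dataset {path}: {e}") from e
    with f:
        if f.attrs.get("format") != "holomass-dataset-v1":
            raise DatasetFormatError(f"{path} is not a holomass dataset")
        meta = {k: f.attrs[k] for k in f.attrs if k != "format"}
        if "sequences" in f:
            g = f["sequences"]
            frames = g["frames"][...]
            mass = g["mass_pg"][...]
            radius = g["radius_um"][...]
            ov = g["optical_volume"][...]
            seeds = g["seed"][...]
            samples = [
                SequenceSample(
                    frames[i],
                    float(mass[i]),
                    float(radius[i]),
                    float(ov[i]),
                    seed=None if seeds[i] < 0 else int(seeds[i]),
                )
                for i in range(len(mass))
            ]
            return samples, meta
        if "images" not in f or "truth" not in f:
            raise DatasetFormatError(f"{path} is missing images/truth groups")
        pitch = float(f.attrs["pixel_pitch_um"])
        images = f["images"][...]
        truth = {name: f["truth"][name][...] for name in _TRUTH_CHANNELS}
        samples = [
            (
                Hologram(images[i], pitch),
                TruthMaps(*(truth[name][i] for name in _TRUTH_CHANNELS)),
            )
            for i in range(images.shape[0])
        ]
        return samples, meta
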