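"""Synthetic 4D cine phantoms of a fluid-filled intestinal tube.

The phantom emulates what the motility pipeline actually relies on in a
mannitol-prepared bFFE acquisition: a bright tubular lumen on a darker
background, carrying band-limited intensity texture that is advected
along the tube by a prescribed axial flow, optionally deformed by a
travelling contraction wave, translated rigidly by a breathing-like
common-mode motion, and corrupted by additive Gaussian noise.  Because
every frame is synthesised from an analytic continuous model, the exact
frame-to-frame displacement of every world point is known and returned
as a :class:`GroundTruthMotion` oracle.

Axial flow follows a Poiseuille-like profile ``v(r) = v0 (1 - (r/R)^2)``
(no-slip at the wall; ``flow_profile`` prescribes the peak/centerline
speed ``v0``), which is both the physically sensible model for luminal
content transport and the reason the common-mode-suppressed estimate at
the centerline slightly underestimates ``v0``: the 30 mm outer disc
still contains the moving lumen, contributing ``v0 R^2 / (2 R_out^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np

from ._tube import TubeFrame
from .errors import ConfigurationError
from .geometry import CineVolume, Centerline, resample_centerline

__all__ = [
    "PhantomConfig",
    "WallWave",
    "GroundTruthMotion",
    "generate_phantom",
    "preset_phantoms",
    "PRESET_KINDS",
]

PRESET_KINDS = ("motile_forward", "motile_backward", "non_motile", "bidirectional")


@dataclass(frozen=True)
class WallWave:
    """Travelling sinusoidal modulation of the lumen radius."""

    amplitude: float  # mm
    wavelength: float  # mm
    speed: float  # mm/s


@dataclass(frozen=True)
class PhantomConfig:
    """Full description of a synthetic acquisition.

    Defaults mimic the coronal bFFE protocol: 128 x 128 x 14 voxels at
    1.4 x 1.4 x 2.5 mm, 16 one-second frames (an 18 s breath-hold with
    the first two contrast-artifact frames already removed), and a
    7.5 mm lumen radius so the 30 mm outer suppression disc extends
    well beyond the lumen.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 14)
    spacing: tuple[float, float, float] = (1.4, 1.4, 2.5)
    n_frames: int = 16
    dt: float = 1.0
    tube_path: Optional[np.ndarray] = None  # (n, 3) world mm; None -> gentle S-curve
    lumen_radius: float = 7.5
    lumen_intensity: float = 1.0
    background_intensity: float = 0.2
    flow_profile: Optional[Callable[[np.ndarray, float], np.ndarray]] = None
    flow_radial_power: float = 1.0  # exponent of (1 - (r/R)^2); 0 = plug flow
    wall_wave: Optional[WallWave] = None
    common_mode: Optional[Callable[[float], Sequence[float]]] = None
    noise_sd: float = 0.02
    texture_wavelengths: tuple[float, float] = (7.0, 40.0)  # mm, band limits
    texture_contrast: float = 0.5
    background_texture_amplitude: float = 0.05  # intensity units, surrounding "tissue"
    background_wavelengths: tuple[float, float] = (10.0, 30.0)  # mm
    edge_width: float = 1.0  # mm, lumen/background transition
    seed: int = 0

    def world_extent(self) -> np.ndarray:
        return (np.array(self.grid_shape) - 1) * np.array(self.spacing)

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    def validate(self) -> None:
        extent = self.world_extent()
        if self.lumen_radius >= extent.min() / 4:
            raise ConfigurationError(
                f"lumen radius {self.lumen_radius} mm too large for grid extent {extent}"
            )
        if self.lumen_intensity <= self.background_intensity:
            raise ConfigurationError("lumen must be brighter than the background")
        if self.n_frames < 1 or self.dt <= 0:
            raise ConfigurationError("need n_frames >= 1 and dt > 0")


def _default_path(config: PhantomConfig) -> np.ndarray:
    """Gentle S-curve spanning the x extent at mid-depth."""
    extent = config.world_extent()
    margin = 10.0  # keeps the capped tube end inside the grid
    x = np.linspace(margin, extent[0] - margin, 200)
    u = (x - x[0]) / (x[-1] - x[0])
    amp = min(6.0, 0.1 * extent[1])
    y = extent[1] / 2 + amp * np.sin(2 * np.pi * u)
    z = np.full_like(x, extent[2] / 2)
    return np.column_stack([x, y, z])


def _interp_extrap(x: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """np.interp with linear extrapolation at both ends."""
    y = np.interp(x, xp, fp)
    lo = x < xp[0]
    hi = x > xp[-1]
    if lo.any():
        slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
        y[lo] = fp[0] + (x[lo] - xp[0]) * slope
    if hi.any():
        slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        y[hi] = fp[-1] + (x[hi] - xp[-1]) * slope
    return y


class _FlowMaps:
    """Discrete-time advection of material arc-length coordinates.

    ``F[i, j, :]`` is the arc position at frame ``i`` of material that
    started on the dense ``s`` grid, for radial shell ``j``; advection
    uses forward-Euler steps ``s_{i+1} = s_i + v(s_i, t_i) g(r_j) dt``,
    which is exactly the displacement the ground-truth oracle reports,
    so synthesis and oracle agree by construction.
    """

    def __init__(self, config: PhantomConfig, length: float, n_shells: int = 9):
        self.s_grid = np.arange(0.0, length + 0.25, 0.5)
        self.shells = np.linspace(0.0, config.lumen_radius, n_shells)
        g = np.maximum(0.0, 1.0 - (self.shells / config.lumen_radius) ** 2)
        self.g = g ** config.flow_radial_power if config.flow_radial_power != 0 else np.ones_like(g)
        self.config = config
        n, m = config.n_frames, len(self.shells)
        self.F = np.empty((n, m, len(self.s_grid)))
        self.F[0] = self.s_grid
        for i in range(n - 1):
            v = self.peak_speed(self.F[i].ravel(), config.times()[i]).reshape(m, -1)
            self.F[i + 1] = self.F[i] + v * self.g[:, None] * config.dt

    def peak_speed(self, s: np.ndarray, t: float) -> np.ndarray:
        if self.config.flow_profile is None:
            return np.zeros_like(s)
        return np.broadcast_to(
            np.asarray(self.config.flow_profile(s, t), dtype=float), s.shape
        ).copy()

    def radial_factor(self, r: np.ndarray) -> np.ndarray:
        g = np.maximum(0.0, 1.0 - (r / self.config.lumen_radius) ** 2)
        if self.config.flow_radial_power == 0:
            return np.ones_like(g)
        return g ** self.config.flow_radial_power

    def material_coordinate(self, s: np.ndarray, r: np.ndarray, frame: int) -> np.ndarray:
        """Inverse advection: material (frame-0) arc coordinate of (s, r) at ``frame``."""
        if self.config.flow_profile is None or frame == 0:
            return s
        m_per_shell = np.stack(
            [_interp_extrap(s, self.F[frame, j], self.s_grid) for j in range(len(self.shells))]
        )
        # linear interpolation across shells in r
        rc = np.clip(r, 0.0, self.shells[-1])
        step = self.shells[1] - self.shells[0]
        j0 = np.minimum((rc / step).astype(int), len(self.shells) - 2)
        w = (rc - self.shells[j0]) / step
        cols = np.arange(len(s))
        return (1 - w) * m_per_shell[j0, cols] + w * m_per_shell[j0 + 1, cols]


class GroundTruthMotion:
    """Exact frame-to-frame displacement field of a synthesised phantom."""

    def __init__(self, config: PhantomConfig, tube: TubeFrame, flow: _FlowMaps):
        self.config = config
        self.tube = tube
        self.flow = flow
        self.times = config.times()

    def common_mode_at(self, t: float) -> np.ndarray:
        if self.config.common_mode is None:
            return np.zeros(3)
        return np.asarray(self.config.common_mode(t), dtype=float)

    def wall_radius(self, s: np.ndarray, t: float) -> np.ndarray:
        r0 = np.full_like(np.asarray(s, dtype=float), self.config.lumen_radius)
        w = self.config.wall_wave
        if w is not None:
            r0 = r0 + w.amplitude * np.sin(2 * np.pi * (s - w.speed * t) / w.wavelength)
        return r0

    def displacement(self, points: np.ndarray, frame: int) -> np.ndarray:
        """World displacement mapping frame ``frame`` points to frame ``frame + 1``."""
        if not 0 <= frame < self.config.n_frames - 1:
            raise ConfigurationError(f"frame pair {frame}->{frame + 1} out of range")
        points = np.atleast_2d(np.asarray(points, dtype=float))
        t0, t1 = self.times[frame], self.times[frame + 1]
        base = points - self.common_mode_at(t0)
        s, r, foot, idx = self.tube.project(base)
        disp = np.zeros_like(points)
        inside = r <= self.wall_radius(s, t0)
        if inside.any():
            v = self.flow.peak_speed(s[inside], t0) * self.flow.radial_factor(r[inside])
            disp[inside] += (v * self.config.dt)[:, None] * self.tube.tangents[idx[inside]]
            if self.config.wall_wave is not None:
                rin = r[inside]
                ok = rin > 1e-9
                scale = np.zeros_like(rin)
                r_t0 = self.wall_radius(s[inside], t0)
                r_t1 = self.wall_radius(s[inside], t1)
                scale[ok] = (r_t1[ok] - r_t0[ok]) / r_t0[ok]
                radial_dir = np.zeros((ok.sum(), 3))
                radial_dir = (base[inside][ok] - foot[inside][ok]) / rin[ok, None]
                disp[np.flatnonzero(inside)[ok]] += (
                    (rin[ok] * scale[ok])[:, None] * radial_dir
                )
        disp += self.common_mode_at(t1) - self.common_mode_at(t0)
        return disp if len(disp) > 1 or np.ndim(points) == 2 else disp[0]

    def geometry_displacement_between(self, points: np.ndarray, i: int, j: int) -> np.ndarray:
        """Displacement of the tube *geometry* (common mode + wall wave) from frame i to j.

        This is what an ideal tube tracker recovers when registering a
        frame directly to the reference frame for centerline
        propagation: content flowing through a stationary tube does not
        move the tube itself.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        ti, tj = self.times[i], self.times[j]
        disp = np.zeros_like(points) + (self.common_mode_at(tj) - self.common_mode_at(ti))
        if self.config.wall_wave is not None:
            base = points - self.common_mode_at(ti)
            s, r, foot, _ = self.tube.project(base)
            inside = (r <= self.wall_radius(s, ti)) & (r > 1e-9)
            if inside.any():
                r_i = self.wall_radius(s[inside], ti)
                r_j = self.wall_radius(s[inside], tj)
                radial_dir = (base[inside] - foot[inside]) / r[inside, None]
                disp[inside] += ((r[inside] * (r_j - r_i) / r_i))[:, None] * radial_dir
        return disp

    def displacement_between(self, points: np.ndarray, i: int, j: int) -> np.ndarray:
        """Displacement mapping frame ``i`` points to frame ``j`` (stepwise composition)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if i == j:
            return np.zeros_like(points)
        if i < j:
            x = points.copy()
            for k in range(i, j):
                x = x + self.displacement(x, k)
            return x - points
        # backward: numerical inverse of the forward j -> i map (fixed point)
        y = points
        x = y.copy()
        for _ in range(100):
            x_new = y - self.displacement_between(x, j, i)
            if np.max(np.linalg.norm(x_new - x, axis=1)) < 1e-7:
                x = x_new
                break
            x = x_new
        return x - y


def _make_texture(config: PhantomConfig, length: float, rng: np.random.Generator):
    """Periodic band-limited speckle along the tube (period = segment length).

    The wavelength band is physical (mm): long enough that frame-to-frame
    advection (a few mm) stays well inside the texture correlation
    length, making intraluminal optical flow observable to registration.
    """
    lam_lo, lam_hi = config.texture_wavelengths
    k_lo = max(1, int(round(length / lam_hi)))
    k_hi = max(k_lo + 1, int(round(length / lam_lo)))
    k = np.arange(k_lo, k_hi + 1)
    amp = 1.0 / np.sqrt(k)
    phase = rng.uniform(0, 2 * np.pi, size=len(k))
    dense = np.linspace(0, length, 4096, endpoint=False)
    vals = (amp[:, None] * np.sin(2 * np.pi * np.outer(k, dense) / length + phase[:, None])).sum(0)
    norm = np.abs(vals).max()

    def texture(m: np.ndarray) -> np.ndarray:
        acc = np.zeros_like(m, dtype=float)
        for kk, aa, pp in zip(k, amp, phase):
            acc += aa * np.sin(2 * np.pi * kk * m / length + pp)
        return acc / norm

    return texture


def _make_background_texture(config: PhantomConfig, rng: np.random.Generator):
    """Smooth 3D speckle for the surrounding 'tissue'.

    The surroundings must be visible to the registration, otherwise
    common-mode motion (breathing) cannot be estimated outside the
    lumen and the differential suppression would have nothing to
    subtract.  Moves rigidly with the common-mode translation only.
    """
    amp = config.background_texture_amplitude
    if amp <= 0:
        return lambda x: 0.0
    lam_lo, lam_hi = config.background_wavelengths
    n_comp = 24
    lam = rng.uniform(lam_lo, lam_hi, size=n_comp)
    dirs = rng.normal(size=(n_comp, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    kvec = 2 * np.pi * dirs / lam[:, None]
    phase = rng.uniform(0, 2 * np.pi, size=n_comp)
    scale = amp / np.sqrt(n_comp / 2.0)

    def texture(x: np.ndarray) -> np.ndarray:
        return scale * np.sin(x @ kvec.T + phase).sum(axis=1)

    return texture


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def generate_phantom(
    config: PhantomConfig,
) -> tuple[list[CineVolume], Centerline, GroundTruthMotion]:
    """Synthesise a 4D phantom.

    Returns the frame sequence, the tube centerline at frame 0 (resampled
    at 1 mm), and the exact ground-truth motion oracle.
    """
    config = replace(config)
    config.validate()
    rng = np.random.default_rng(config.seed)
    path = config.tube_path if config.tube_path is not None else _default_path(config)
    tube = TubeFrame(np.asarray(path, dtype=float), step=0.25)
    flow = _FlowMaps(config, tube.length)
    truth = GroundTruthMotion(config, tube, flow)

    # feasibility: tube (plus wall excursion and edge) must stay inside the grid
    shifts = np.array([truth.common_mode_at(t) for t in config.times()])
    max_radius = config.lumen_radius + config.edge_width
    if config.wall_wave is not None:
        max_radius += abs(config.wall_wave.amplitude)
    lo = tube.points.min(axis=0) + shifts.min(axis=0) - max_radius
    hi = tube.points.max(axis=0) + shifts.max(axis=0) + max_radius
    extent = config.world_extent()
    if np.any(lo < -1e-6) or np.any(hi > extent + 1e-6):
        raise ConfigurationError(
            "tube leaves the image grid under the configured common-mode motion"
        )

    texture = _make_texture(config, tube.length, rng)
    bg_texture = _make_background_texture(config, rng)
    spacing = np.array(config.spacing, dtype=float)
    shape = tuple(config.grid_shape)
    axes = [np.arange(n) * d for n, d in zip(shape, spacing)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)

    frames: list[CineVolume] = []
    proj_cache: dict[tuple, tuple] = {}
    bg, lum, c = config.background_intensity, config.lumen_intensity, config.texture_contrast
    for i, t in enumerate(config.times()):
        shift = truth.common_mode_at(t)
        key = tuple(np.round(shift, 9))
        if key not in proj_cache:
            s, r, _, _ = tube.project(grid - shift)
            proj_cache[key] = (s, r)
        s, r = proj_cache[key]
        r_wall = truth.wall_radius(s, t)
        edge = _smoothstep((r_wall - r) / config.edge_width + 0.5)
        vox = np.full(len(grid), bg) + (1.0 - edge) * bg_texture(grid - shift)
        in_tube = edge > 0
        m = flow.material_coordinate(s[in_tube], r[in_tube], i)
        texfac = (1.0 + c * texture(m)) / (1.0 + c)
        vox[in_tube] += (lum - bg) * edge[in_tube] * texfac
        vox = vox.reshape(shape)
        if config.noise_sd > 0:
            vox = vox + rng.normal(0.0, config.noise_sd, size=shape)
        frames.append(CineVolume(vox, spacing, np.zeros(3), time_index=i, dt=config.dt))

    cl0 = resample_centerline(tube.points + truth.common_mode_at(config.times()[0]), 1.0, 0)
    return frames, cl0, truth


def _breathing(amplitude: float = 3.0, period: float = 10.0):
    """Slow breathing-like bulk drift: starts at rest, peak displacement ``amplitude``.

    The cosine phase (zero velocity at t = 0) models a subject settling
    during a breath-hold; the drift is slow relative to the 3 s
    temporal smoothing window used for centerline propagation, so an
    accurate tracker can follow it.
    """
    direction = np.array([0.36, 0.48, 0.8])  # oblique so no axis is spared

    def common_mode(t: float) -> np.ndarray:
        return 0.5 * amplitude * (1.0 - np.cos(2 * np.pi * t / period)) * direction

    return common_mode


def preset_phantoms(kind: str, seed: int, *, compact: bool = False) -> PhantomConfig:
    """Named study conditions mirroring the three observable motion patterns.

    ``motile_forward`` / ``motile_backward``: constant-sign axial flow at
    +/- 2 mm/s peak speed.  ``non_motile``: zero flow, breathing-like
    3 mm sinusoidal common-mode translation only.  ``bidirectional``:
    zero-mean oscillating flow (2.5 mm/s amplitude, 8 s period), i.e.
    content pushed back and forth with no net transport.

    ``compact=True`` shrinks the grid to 64 x 64 x 14 voxels and 8
    frames for desk-scale experiments; physics is unchanged.
    """
    if kind not in PRESET_KINDS:
        raise ConfigurationError(f"unknown phantom preset {kind!r}; choose from {PRESET_KINDS}")
    base = dict(seed=seed)
    if compact:
        base.update(grid_shape=(64, 64, 14), n_frames=8)
    if kind == "motile_forward":
        return PhantomConfig(flow_profile=lambda s, t: np.full_like(s, 2.0, dtype=float), **base)
    if kind == "motile_backward":
        return PhantomConfig(flow_profile=lambda s, t: np.full_like(s, -2.0, dtype=float), **base)
    if kind == "non_motile":
        return PhantomConfig(common_mode=_breathing(), **base)
    return PhantomConfig(
        flow_profile=lambda s, t: np.full_like(s, 2.5 * np.sin(2 * np.pi * t / 8.0), dtype=float),
        **base,
    )
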