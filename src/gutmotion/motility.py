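"""From deformation fields to motility metrics.

The deformation estimated around a segment mixes true intestinal
motility with spurious motion (breathing, cardiac, adjacent loops).
Since spurious motion affects the segment *and* its surroundings while
motility is confined to the lumen, a differential sampling scheme
analogous to common-mode rejection is used: at every centerline point
the mean displacement over a large disc (default 30 mm diameter,
larger than any small-intestinal lumen) is subtracted from the mean
over a small disc (0.5 mm) centred on the same point.  Both discs lie
in the plane orthogonal to the local tangent.  Projecting the
suppressed displacement onto the tangent and dividing by the frame
interval yields a signed local velocity in mm/s; positive values point
from the beginning of the centerline towards its end.

The centerline itself is carried through time by sampling each
frame's direct-to-reference deformation at the reference points and
smoothing the sampled displacement with an 8 mm moving average along
the centerline followed by a 3 s moving average across time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, PropagationError
from .geometry import Centerline, CineVolume, resample_centerline
from .registration import DeformationModel, build_tube_roi

__all__ = [
    "SamplingParams",
    "SpaceTimeVelocityMap",
    "SegmentMetrics",
    "disc_mean_displacement",
    "suppress_spurious",
    "propagate_centerline",
    "local_velocity",
    "compute_velocity_map",
    "aggregate_metrics",
]


@dataclass(frozen=True)
class SamplingParams:
    """Differential disc sampling settings.

    The outer diameter may be enlarged by the user for severely
    distended segments; it must stay within the registration tube.
    """

    inner_diameter: float = 0.5
    outer_diameter: float = 30.0
    samples_inner: int = 16
    samples_outer: int = 256

    def __post_init__(self):
        if not 0 < self.inner_diameter < self.outer_diameter:
            raise ConfigurationError(
                f"need 0 < inner ({self.inner_diameter}) < outer ({self.outer_diameter}) diameter"
            )


_PATTERN_CACHE: dict[int, np.ndarray] = {}


def _disc_pattern(n: int) -> np.ndarray:
    """Deterministic low-discrepancy unit-disc pattern, exactly point-symmetric.

    Half the points follow a sunflower (Fibonacci) spiral; the other
    half are their negations, so the pattern mean is exactly zero and
    any displacement field that is linear in position averages to its
    value at the disc centre.
    """
    n = max(2, n + (n % 2))
    if n not in _PATTERN_CACHE:
        half = n // 2
        i = np.arange(half)
        r = np.sqrt((i + 0.5) / half)
        theta = i * np.pi * (3.0 - np.sqrt(5.0))
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        _PATTERN_CACHE[n] = np.vstack([pts, -pts])
    return _PATTERN_CACHE[n]


def _disc_basis(tangents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal in-plane basis per tangent, identical for t and -t.

    The tangent is canonicalised by sign of its largest-magnitude
    component before building the basis, so reversing the centerline
    orientation reuses the exact same sample points and velocity signs
    flip without any resampling noise.
    """
    t = np.atleast_2d(tangents).copy()
    lead = np.argmax(np.abs(t), axis=1)
    sign = np.sign(t[np.arange(len(t)), lead])
    t *= sign[:, None]
    helper = np.zeros_like(t)
    helper[np.arange(len(t)), np.argmin(np.abs(t), axis=1)] = 1.0
    e1 = np.cross(t, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(t, e1)
    return e1, e2


def _disc_means(
    model: DeformationModel,
    points: np.ndarray,
    tangents: np.ndarray,
    diameter: float,
    n_samples: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean forward displacement over a disc at each centerline point.

    Returns ``(means (P, 3), coverage (P,))`` where coverage is the
    fraction of disc samples inside the model's trusted region; samples
    outside are clipped from the average.
    """
    points = np.atleast_2d(points)
    tangents = np.atleast_2d(tangents)
    pat = _disc_pattern(n_samples) * (diameter / 2.0)
    e1, e2 = _disc_basis(tangents)
    samples = (
        points[:, None, :]
        + pat[None, :, 0, None] * e1[:, None, :]
        + pat[None, :, 1, None] * e2[:, None, :]
    )  # (P, S, 3)
    p, s, _ = samples.shape
    flat = samples.reshape(-1, 3)
    valid = model.roi.contains(flat) if model.roi is not None else np.ones(len(flat), bool)
    disp = np.zeros_like(flat)
    if valid.any():
        disp[valid] = model.forward(flat[valid])
    disp = disp.reshape(p, s, 3)
    valid = valid.reshape(p, s)
    counts = valid.sum(axis=1)
    coverage = counts / s
    means = np.zeros((p, 3))
    ok = counts > 0
    means[ok] = (disp[ok] * valid[ok, :, None]).sum(axis=1) / counts[ok, None]
    return means, coverage


def disc_mean_displacement(
    model: DeformationModel,
    point: np.ndarray,
    tangent: np.ndarray,
    diameter: float,
    params: SamplingParams = SamplingParams(),
) -> tuple[np.ndarray, float]:
    """Area-normalised mean displacement over one circular ROI.

    Returns ``(mean displacement mm, coverage fraction)``; a coverage
    below 0.5 marks the point boundary-unreliable.
    """
    n = params.samples_outer if diameter > params.inner_diameter else params.samples_inner
    means, cov = _disc_means(model, point, tangent, diameter, n)
    return means[0], float(cov[0])


def suppress_spurious(
    model: DeformationModel,
    points: np.ndarray,
    tangents: np.ndarray,
    params: SamplingParams = SamplingParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Common-mode-rejected local displacement at centerline points.

    Inner-disc mean minus outer-disc mean; any spatially uniform
    component of the field cancels exactly.  Returns ``(displacement
    (P, 3), coverage (P,))`` with coverage the lesser of the two discs'.
    """
    inner, cov_in = _disc_means(model, points, tangents, params.inner_diameter, params.samples_inner)
    outer, cov_out = _disc_means(model, points, tangents, params.outer_diameter, params.samples_outer)
    return inner - outer, np.minimum(cov_in, cov_out)


def local_velocity(displacement: np.ndarray, tangent: np.ndarray, dt: float) -> np.ndarray:
    """Signed along-centerline velocity in mm/s: (displacement . tangent) / dt."""
    if dt <= 0:
        raise ConfigurationError(f"dt must be > 0, got {dt}")
    displacement = np.asarray(displacement, dtype=float)
    tangent = np.asarray(tangent, dtype=float)
    return np.einsum("...i,...i->...", displacement, tangent) / dt


def _moving_average(values: np.ndarray, taps: int, axis: int) -> np.ndarray:
    """Centered moving average, truncated (renormalised) at the ends."""
    values = np.moveaxis(values, axis, 0)
    taps = min(taps, len(values))
    if taps % 2 == 0:
        taps -= 1
    if taps <= 1:
        return np.moveaxis(values, 0, axis)
    kernel = np.ones(taps)
    flat = values.reshape(len(values), -1)
    counts = np.convolve(np.ones(len(values)), kernel, mode="same")
    out = np.empty_like(flat)
    for j in range(flat.shape[1]):
        out[:, j] = np.convolve(flat[:, j], kernel, mode="same") / counts
    return np.moveaxis(out.reshape(values.shape), 0, axis)


def _odd_taps(window: float, step: float) -> int:
    taps = max(1, int(round(window / step)))
    return taps + 1 if taps % 2 == 0 else taps


def propagate_centerline(
    ref: Centerline,
    models_to_ref: Sequence[Optional[DeformationModel]],
    spatial_window: float = 8.0,
    temporal_window: float = 3.0,
    dt: float = 1.0,
) -> list[Centerline]:
    """Carry the reference centerline to every frame.

    ``models_to_ref[k]`` must map the reference frame to frame ``k``
    (``None`` is allowed for the reference frame itself and means the
    identity).  Sampled displacements are smoothed along arc length
    (default 8 mm window) and then across time (default 3 s window)
    before being added to the reference points.
    """
    n_frames = len(models_to_ref)
    disp = np.zeros((n_frames, len(ref), 3))
    for k, model in enumerate(models_to_ref):
        if model is None:
            if k != ref.frame_index:
                raise PropagationError(f"missing deformation model for frame {k}")
            continue
        disp[k] = model.forward(ref.points)
    step = float(np.median(np.diff(ref.arc_lengths)))
    disp = _moving_average(disp, _odd_taps(spatial_window, step), axis=1)
    disp = _moving_average(disp, _odd_taps(temporal_window, dt), axis=0)
    return [ref.with_points(ref.points + disp[k], frame_index=k) for k in range(n_frames)]


@dataclass
class SpaceTimeVelocityMap:
    """Signed local velocity (mm/s) indexed by centerline position x frame pair."""

    values: np.ndarray  # (n_points, n_pairs)
    positions: np.ndarray  # arc length, mm
    times: np.ndarray  # start time of each frame pair, s
    reliable: np.ndarray  # bool, (n_points, n_pairs)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("velocity map contains non-finite values")
        if self.values.shape != (len(self.positions), len(self.times)):
            raise ConfigurationError("velocity map dimensions inconsistent")

    def to_dataframe(self):
        import pandas as pd

        pos, tim = np.meshgrid(self.positions, self.times, indexing="ij")
        return pd.DataFrame(
            {
                "position_mm": pos.ravel(),
                "time_s": tim.ravel(),
                "velocity_mm_per_s": self.values.ravel(),
                "reliable": self.reliable.ravel().astype(int),
            }
        )

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass(frozen=True)
class SegmentMetrics:
    """Global motility metrics of one segment.

    ``mean_velocity`` (signed) measures net peristaltic transport;
    ``mean_absolute_velocity`` measures motility magnitude irrespective
    of direction; opposing motions cancel only in the former.
    ``three_part_means`` holds per-frame-pair mean velocities for the
    first, middle and final thirds of the segment.
    """

    mean_velocity: float
    mean_absolute_velocity: float
    three_part_means: np.ndarray  # (3, n_pairs)

    def __post_init__(self):
        if abs(self.mean_velocity) > self.mean_absolute_velocity + 1e-12:
            raise ConfigurationError("|mean velocity| cannot exceed mean absolute velocity")


def aggregate_metrics(vmap: SpaceTimeVelocityMap, exclude_unreliable: bool = False) -> SegmentMetrics:
    """Grand means over position and time, plus begin/middle/end summaries."""
    if vmap.values.size == 0:
        raise ConfigurationError("empty velocity map")
    vals = vmap.values.astype(float)
    if exclude_unreliable:
        vals = np.where(vmap.reliable, vals, np.nan)
        if np.all(np.isnan(vals)):
            raise ConfigurationError("no reliable samples in velocity map")
    thirds = np.array_split(np.arange(vals.shape[0]), 3)
    # segments shorter than 3 samples cannot be subdivided; fall back to the whole
    thirds = [ix if len(ix) else np.arange(vals.shape[0]) for ix in thirds]
    three = np.vstack([np.nanmean(vals[ix], axis=0) for ix in thirds])
    return SegmentMetrics(
        mean_velocity=float(np.nanmean(vals)),
        mean_absolute_velocity=float(np.nanmean(np.abs(vals))),
        three_part_means=three,
    )


def plot_velocity_map(vmap: SpaceTimeVelocityMap, path=None, metrics: Optional[SegmentMetrics] = None):
    """Space-time heatmap (position x time) with begin/middle/end arrows.

    Arrow lengths encode the per-third average velocity; rightward
    arrows mean motion towards the end of the centerline.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if metrics is None:
        metrics = aggregate_metrics(vmap)
    fig, ax = plt.subplots(figsize=(6, 4))
    lim = max(1.0, np.abs(vmap.values).max())
    im = ax.pcolormesh(
        vmap.positions, vmap.times, vmap.values.T, cmap="RdBu_r", vmin=-lim, vmax=lim
    )
    fig.colorbar(im, ax=ax, label="velocity (mm/s)")
    thirds = np.array_split(vmap.positions, 3)
    for k, seg in enumerate(thirds):
        x0 = seg.mean()
        v = float(metrics.three_part_means[k].mean())
        ax.annotate(
            "",
            xy=(x0 + 3.0 * v, vmap.times[-1] + 0.06 * (vmap.times[-1] - vmap.times[0] + 1)),
            xytext=(x0, vmap.times[-1] + 0.06 * (vmap.times[-1] - vmap.times[0] + 1)),
            arrowprops=dict(arrowstyle="->", color="black"),
            annotation_clip=False,
        )
    ax.set_xlabel("position along centerline (mm)")
    ax.set_ylabel("time (s)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig


def compute_velocity_map(
    frames: Sequence[CineVolume],
    ref_centerline: Centerline,
    backend,
    sampling: SamplingParams = SamplingParams(),
    tube_diameter: float = 40.0,
    step: float = 1.0,
    spatial_window: float = 8.0,
    temporal_window: float = 3.0,
    propagate: bool = True,
) -> SpaceTimeVelocityMap:
    """Full per-segment analysis: register, propagate, suppress, project.

    For every consecutive frame pair the backend registers the two
    frames inside the 40 mm tube; the common-mode-suppressed
    displacement is sampled at the propagated centerline of the
    earlier frame and projected onto its local tangents.
    """
    if len(frames) < 2:
        raise ConfigurationError("need at least 2 frames")
    if sampling.outer_diameter > tube_diameter:
        raise ConfigurationError("outer sampling disc must fit inside the registration tube")
    dt = frames[0].dt
    ref = resample_centerline(ref_centerline.points, step, ref_centerline.frame_index)
    roi = build_tube_roi(ref, tube_diameter, volume=frames[0])

    ref_idx = ref.frame_index
    if not 0 <= ref_idx < len(frames):
        raise PropagationError(f"reference frame {ref_idx} outside the frame sequence")
    if propagate:
        models_to_ref = [
            None
            if k == ref_idx
            else backend.register(frames[ref_idx], frames[k], roi, purpose="propagation")
            for k in range(len(frames))
        ]
        propagated = propagate_centerline(ref, models_to_ref, spatial_window, temporal_window, dt)
    else:
        propagated = [ref.with_points(ref.points, frame_index=k) for k in range(len(frames))]

    n_pairs = len(frames) - 1
    values = np.zeros((len(ref), n_pairs))
    reliable = np.zeros((len(ref), n_pairs), dtype=bool)
    diagnostics = []
    for i in range(n_pairs):
        model = backend.register(frames[i], frames[i + 1], roi)
        cl = propagated[i]
        disp, cov = suppress_spurious(model, cl.points, cl.tangents, sampling)
        values[:, i] = local_velocity(disp, cl.tangents, dt)
        reliable[:, i] = cov >= 0.5
        diagnostics.append(model.diagnostics)

    times = np.array([frames[i].time_index * dt for i in range(n_pairs)])
    return SpaceTimeVelocityMap(
        values=values,
        positions=ref.arc_lengths.copy(),
        times=times,
        reliable=reliable,
        meta={
            "backend": getattr(backend, "name", type(backend).__name__),
            "tube_diameter_mm": tube_diameter,
            "sampling": sampling,
            "registration_diagnostics": diagnostics,
            "segment_length_mm": ref.length,
        },
    )
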