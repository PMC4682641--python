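"""Render molecule trajectories into synthetic microscopy data.

A focus is drawn as a 2-D Gaussian spot whose integrated intensity is
``gain x fluorescent molecule count x axial attenuation``; the
nucleoplasmic pool (FREE + RNA molecules) is a uniform background inside
the nucleus mask. Axial locus drift follows an Ornstein-Uhlenbeck process
started in focus (z = 0). Acquisition photobleaching is a per-frame
multiplicative loss; Poisson shot noise is applied last.

Pre/post z-stacks distribute each focus over planes with normalized
Gaussian weights, so the stack sum is drift-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ImagingConfig, NucleusGeometry
from .simulate import MoleculeTrajectory
from .stackio import ImageStack


def _grid(imaging: ImagingConfig):
    n = imaging.n_pixels
    # pixel-centre coordinates in micrometres, image centred on the nucleus
    coords = (np.arange(n) + 0.5) * imaging.pixel_size - imaging.fov / 2.0
    return coords


def um_to_px(u: float, imaging: ImagingConfig) -> float:
    """Map a micrometre coordinate (nucleus-centred) to a pixel index."""
    return u / imaging.pixel_size + (imaging.n_pixels - 1) / 2.0


def _nucleus_mask(geometry, imaging):
    c = _grid(imaging)
    yy, xx = np.meshgrid(c, c, indexing="ij")
    return yy**2 + xx**2 <= geometry.nucleus_radius**2


def _spot(imaging, geometry, focus_index):
    (cx, cy, _), r = geometry.foci[focus_index]
    c = _grid(imaging)
    yy, xx = np.meshgrid(c, c, indexing="ij")
    g = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * r**2))
    s = g.sum()
    return g / s if s > 0 else g


def ou_path(times: np.ndarray, sigma: float, tau: float, rng) -> np.ndarray:
    """Ornstein-Uhlenbeck sample path started at 0 (in focus)."""
    z = np.zeros(len(times))
    if sigma <= 0:
        return z
    for i in range(1, len(times)):
        dt = times[i] - times[i - 1]
        a = np.exp(-dt / tau)
        z[i] = z[i - 1] * a + sigma * np.sqrt(1.0 - a * a) * rng.normal()
    return z


@dataclass
class RenderedExperiment:
    """Synthetic acquisition: pre z-stack, planar time series, post z-stack."""

    timeseries: ImageStack
    prestack: ImageStack
    poststack: ImageStack
    focus_z: np.ndarray  # (n_frames, n_foci) axial drift paths


def _plane_image(
    focus_counts, pool_count, focus_z, z_plane, spots, mask, geometry, imaging, stack_mode
):
    img = np.zeros(mask.shape)
    sigma = imaging.psf_axial_sigma
    for k, count in enumerate(focus_counts):
        dz = focus_z[k] - z_plane
        if stack_mode:
            # normalized partition over planes: stack sum is drift-invariant
            atten = (
                np.exp(-(dz**2) / (2 * sigma**2))
                * imaging.zstack_spacing
                / (np.sqrt(2 * np.pi) * sigma)
            )
        else:
            atten = np.exp(-(dz**2) / (2 * sigma**2))
        img += imaging.gain * count * atten * spots[k]
    n_in = mask.sum()
    if n_in:
        pool = pool_count / imaging.zstack_planes if stack_mode else pool_count
        img[mask] += imaging.gain * pool / n_in
    return img


def _zstack(trajectory, t, geometry, imaging, spots, mask, focus_z, rng, role):
    counts = trajectory.fluorescent_counts([t])[0]
    pool = counts[0] + counts[1]
    planes = []
    offsets = (np.arange(imaging.zstack_planes) - (imaging.zstack_planes - 1) / 2.0) * (
        imaging.zstack_spacing
    )
    for zp in offsets:
        planes.append(
            _plane_image(
                counts[2:], pool, focus_z, zp, spots, mask, geometry, imaging, True
            )
        )
    data = np.stack(planes)
    if imaging.noise_model == "poisson":
        data = rng.poisson(np.clip(data, 0, None)).astype(float)
    return ImageStack(
        data=data,
        frame_interval=imaging.frame_interval,
        pixel_size=imaging.pixel_size,
        role=role,
        z_spacing=imaging.zstack_spacing,
    )


def render_timeseries(
    trajectory: MoleculeTrajectory,
    geometry: NucleusGeometry,
    imaging: ImagingConfig,
    seed: int = 0,
) -> RenderedExperiment:
    """Render a full acquisition from a (possibly bleached) trajectory.

    The pre-stack is taken at t = 0, the time series at the configured
    frame times, the post-stack at the final frame time. With zero noise
    and zero drift the integrated focus intensity of a frame equals
    gain x fluorescent count (x axial attenuation).
    """
    if imaging.fov < 2 * geometry.nucleus_radius:
        raise ValueError("pixel grid smaller than the nucleus; increase fov")
    times = imaging.frame_times()
    if times[-1] > trajectory.duration + 1e-9:
        raise ValueError("trajectory does not cover the imaging window")
    rng = np.random.default_rng(seed)
    mask = _nucleus_mask(geometry, imaging)
    spots = [_spot(imaging, geometry, k) for k in range(geometry.n_foci)]

    focus_z = np.column_stack(
        [
            ou_path(times, imaging.z_drift_sigma, imaging.z_drift_tau, rng)
            for _ in range(geometry.n_foci)
        ]
    )

    counts = trajectory.fluorescent_counts(times)
    frames = np.empty((imaging.n_frames, imaging.n_pixels, imaging.n_pixels))
    for i, t in enumerate(times):
        img = _plane_image(
            counts[i, 2:],
            counts[i, 0] + counts[i, 1],
            focus_z[i],
            0.0,
            spots,
            mask,
            geometry,
            imaging,
            False,
        )
        img *= (1.0 - imaging.acquisition_bleach_rate) ** i
        frames[i] = img
    if imaging.noise_model == "poisson":
        frames = rng.poisson(np.clip(frames, 0, None)).astype(float)

    pre = _zstack(
        trajectory, 0.0, geometry, imaging, spots, mask, focus_z[0], rng, "prestack"
    )
    post = _zstack(
        trajectory,
        float(times[-1]),
        geometry,
        imaging,
        spots,
        mask,
        focus_z[-1],
        rng,
        "poststack",
    )
    ts = ImageStack(
        data=frames,
        frame_interval=imaging.frame_interval,
        pixel_size=imaging.pixel_size,
        role="timeseries",
    )
    return RenderedExperiment(timeseries=ts, prestack=pre, poststack=post, focus_z=focus_z)
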