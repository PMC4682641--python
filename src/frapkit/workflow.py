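"""End-to-end synthetic experiments and their analysis.

These helpers wire the simulator to the analysis exactly the way a real
acquisition would be processed: simulate molecules, bleach, render
images, extract the ROI trace, subtract background, detect the bleach
frame, normalize, fit. They are what the command-line interface and the
validation studies run.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .config import ImagingConfig, KineticConfig, NucleusGeometry
from .fractions import MobileFractionResult, corrected_mobile_fraction
from .linescan import LineScanSeries
from .meanfield import BleachSpec, GroundTruth, ground_truth
from .render import RenderedExperiment, render_timeseries, um_to_px, ou_path
from .simulate import MoleculeTrajectory, apply_bleach, simulate_molecules
from .stackio import ROISpec
from .traces import (
    FrapTrace,
    extract_trace,
    mark_bleach,
    normalize_trace,
    subtract_background,
)

LOCUS_ROI_RADIUS_UM = 0.25


@dataclass
class FrapExperiment:
    """One simulated FRAP acquisition plus its ground truth."""

    trajectory: MoleculeTrajectory
    rendered: RenderedExperiment
    imaging: ImagingConfig
    geometry: NucleusGeometry
    kinetics: KineticConfig
    bleach_focus: int
    truth: GroundTruth

    def locus_roi(self) -> ROISpec:
        cx, cy, _ = self.geometry.foci[self.bleach_focus][0]
        return ROISpec(
            shape="circle",
            label="frap",
            center=(um_to_px(cy, self.imaging), um_to_px(cx, self.imaging)),
            radius=LOCUS_ROI_RADIUS_UM / self.imaging.pixel_size,
        )

    def focus_roi(self, focus: int, label: str = "flip") -> ROISpec:
        cx, cy, _ = self.geometry.foci[focus][0]
        return ROISpec(
            shape="circle",
            label=label,
            center=(um_to_px(cy, self.imaging), um_to_px(cx, self.imaging)),
            radius=LOCUS_ROI_RADIUS_UM / self.imaging.pixel_size,
        )

    def nucleus_roi(self) -> ROISpec:
        n = self.imaging.n_pixels
        return ROISpec(
            shape="circle",
            label="nucleus",
            center=((n - 1) / 2.0, (n - 1) / 2.0),
            radius=self.geometry.nucleus_radius / self.imaging.pixel_size + 1.0,
        )


def simulate_frap_experiment(
    kinetics: KineticConfig,
    geometry: NucleusGeometry,
    imaging: ImagingConfig,
    seed: int,
    bleach_focus: int = 0,
    bleach: bool = True,
) -> FrapExperiment:
    """Simulate, bleach (at the configured bleach frame) and render one
    FRAP acquisition; the bleach spot is centred on ``bleach_focus``."""
    center = geometry.foci[bleach_focus][0]
    imaging = dc_replace(imaging, bleach_center=tuple(center))
    duration = imaging.duration() + imaging.frame_interval
    traj = simulate_molecules(kinetics, geometry, duration, seed)
    if bleach:
        traj = apply_bleach(
            traj, geometry, imaging, imaging.bleach_time, kinetics, seed=seed + 1
        )
    rendered = render_timeseries(traj, geometry, imaging, seed=seed + 2)
    truth = ground_truth(
        kinetics, geometry, BleachSpec.from_imaging(imaging, kinetics), focus=bleach_focus
    )
    return FrapExperiment(
        trajectory=traj,
        rendered=rendered,
        imaging=imaging,
        geometry=geometry,
        kinetics=kinetics,
        bleach_focus=bleach_focus,
        truth=truth,
    )


def analyze_trace(exp: FrapExperiment, normalized: bool = True) -> FrapTrace:
    """Standard pipeline on the bleached-locus ROI: extract ->
    subtract_background -> detect bleach -> (normalize)."""
    trace = extract_trace(exp.rendered.timeseries, exp.locus_roi())
    trace = mark_bleach(subtract_background(trace))
    return normalize_trace(trace) if normalized else trace


def recovered_halftime_ms(exp: FrapExperiment, n_components: int = 1) -> float:
    """Fitted half-time (ms) of one simulated experiment."""
    from .recovery import ExponentialRecoveryModel, halftime_from_curve

    trace = analyze_trace(exp)
    fit = ExponentialRecoveryModel.from_trace(trace, n_components).fit()
    return halftime_from_curve(fit)


def mobile_fraction_of(exp: FrapExperiment, locus_source: str = "stacks") -> MobileFractionResult:
    trace = analyze_trace(exp, normalized=False)
    return corrected_mobile_fraction(
        trace,
        exp.rendered.prestack,
        exp.rendered.poststack,
        exp.locus_roi(),
        exp.nucleus_roi(),
        locus_source=locus_source,
    )


def simulate_linescan(
    kinetics: KineticConfig,
    geometry: NucleusGeometry,
    imaging: ImagingConfig,
    seed: int,
    bleach: bool = True,
    prebleach_time: float = 0.2,
):
    """Line-scan acquisition of a bleached and a control nucleus.

    The line runs along x through the nucleus centre; the bleach interval
    is the stretch of the line within the bleach radius of the bleached
    spot (itself centred on the first focus, which sits on the line). The
    control nucleus shares the configuration but has its own seed and no
    bleach event.

    Returns ``(frap_series, ctrl_series)``.
    """
    dt = imaging.linescan_interval
    n_t = imaging.linescan_n_samples
    duration = n_t * dt
    if bleach and not 0 < prebleach_time < duration:
        raise ValueError("prebleach_time must fall inside the scan")
    times = np.arange(n_t) * dt

    R = geometry.nucleus_radius
    n_pos = int(2 * R / imaging.pixel_size)
    positions = (np.arange(n_pos) + 0.5) * imaging.pixel_size - R
    if n_pos < 2:
        raise ValueError("line does not intersect the nucleus")

    spot_center = np.asarray(geometry.foci[0][0], dtype=float)
    imaging = dc_replace(imaging, bleach_center=tuple(spot_center))
    in_bleach = np.abs(positions - spot_center[0]) <= imaging.bleach_radius
    lo = int(np.argmax(in_bleach))
    hi = int(n_pos - np.argmax(in_bleach[::-1]))

    def render_one(traj, rng):
        counts = traj.fluorescent_counts(times)
        pool = counts[:, 0] + counts[:, 1]
        profile = np.zeros((n_pos, n_t))
        # uniform pool along the in-nucleus line
        profile += imaging.gain * pool[None, :] / n_pos
        sigma = geometry.foci[0][1]
        for k, ((fx, fy, fz), fr) in enumerate(geometry.foci):
            off2 = fy**2 + fz**2
            if off2 > (3 * fr) ** 2:
                continue  # focus too far from the line to contribute
            g = np.exp(-((positions - fx) ** 2) / (2 * sigma**2))
            g /= g.sum() if g.sum() > 0 else 1.0
            lateral = np.exp(-off2 / (2 * sigma**2))
            profile += imaging.gain * lateral * np.outer(g, counts[:, 2 + k])
        if imaging.noise_model == "poisson":
            profile = rng.poisson(np.clip(profile, 0, None)).astype(float)
        return profile

    traj = simulate_molecules(kinetics, geometry, duration, seed)
    if bleach:
        traj = apply_bleach(traj, geometry, imaging, prebleach_time, kinetics, seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    frap = LineScanSeries(
        positions=positions,
        times=times,
        intensities=render_one(traj, rng),
        bleach_interval=(lo, hi),
        bleach_time=prebleach_time if bleach else None,
        series_id="frap",
    )

    ctrl_seed = seed + 7919
    ctrl_traj = simulate_molecules(kinetics, geometry, duration, ctrl_seed)
    ctrl_rng = np.random.default_rng(ctrl_seed + 2)
    ctrl = LineScanSeries(
        positions=positions,
        times=times,
        intensities=render_one(ctrl_traj, ctrl_rng),
        bleach_interval=(lo, hi),
        bleach_time=None,
        series_id="ctrl",
    )
    return frap, ctrl
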