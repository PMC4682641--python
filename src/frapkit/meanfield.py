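"""Deterministic mean-field recovery oracle.

Because molecules are independent linear Markov chains, the expected
fluorescence at a focus after a bleach is given exactly by the matrix
exponential of the augmented generator. This closed-form curve is the
testing oracle for the stochastic simulator and the source of
ground-truth half-times and mobile fractions.

In the two-state reaction-dominant limit (free pool much larger than the
bound population) the normalized curve reduces to 1 - exp(-k_off * t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq

from .config import ImagingConfig, KineticConfig, NucleusGeometry
from .simulate import (
    augmented_generator,
    sphere_intersection_volume,
    stationary_distribution,
)


@dataclass
class BleachSpec:
    """Bleach pulse description for the mean-field path."""

    center: tuple
    radius: float
    duration: float = 0.020
    efficiency: float = 1.0

    @classmethod
    def from_imaging(cls, imaging: ImagingConfig, config: KineticConfig) -> "BleachSpec":
        return cls(
            center=imaging.bleach_center,
            radius=imaging.bleach_radius,
            duration=imaging.bleach_duration,
            efficiency=config.bleach_efficiency,
        )


def _bleach_geometry(geometry: NucleusGeometry, bleach: BleachSpec):
    """Per-augmented-state probability of sitting inside the bleach sphere."""
    center = np.asarray(bleach.center, dtype=float)
    if np.linalg.norm(center) > geometry.nucleus_radius:
        raise ValueError("bleach region lies outside the nucleus")
    v_nuc = 4.0 / 3.0 * np.pi * geometry.nucleus_radius**3
    v_in = sphere_intersection_volume(
        geometry.nucleus_radius, bleach.radius, float(np.linalg.norm(center))
    )
    pool_q = v_in / v_nuc
    q = np.full(2 + geometry.n_foci, pool_q)
    for k, (c, _) in enumerate(geometry.foci):
        d = np.linalg.norm(np.asarray(c) - center)
        q[2 + k] = 1.0 if d <= bleach.radius else 0.0
    return q


def _post_bleach_distribution(config, geometry, bleach, Q, pi):
    """Fluorescent-molecule state distribution just after the pulse.

    The pulse window [0, duration] catches a molecule if it is inside the
    bleach sphere at either end of the window (pool positions are sampled
    independently at the two instants), matching the stochastic
    implementation exactly:

        survive(i -> j) = (1 - eff) + eff * (1 - q_i) * (1 - q_j)
    """
    q = _bleach_geometry(geometry, bleach)
    T = expm(Q * bleach.duration) if bleach.duration > 0 else np.eye(Q.shape[0])
    eff = bleach.efficiency
    survive = (1.0 - eff) + eff * np.outer(1.0 - q, 1.0 - q)
    f = (pi[:, None] * T * survive).sum(axis=0)
    return f, q


@dataclass
class MeanfieldRecovery:
    """Expected focus fluorescence after a bleach.

    ``fraction`` is the per-molecule probability of being fluorescent and
    at the monitored focus (mobile and immobile contributions combined);
    ``normalized`` divides by the long-time plateau, which is the scale the
    trace-normalization step of the analysis works on.
    """

    times: np.ndarray
    fraction: np.ndarray
    plateau: float
    prebleach: float

    @property
    def normalized(self) -> np.ndarray:
        return self.fraction / self.plateau


def meanfield_recovery(
    config: KineticConfig,
    geometry: NucleusGeometry,
    bleach: BleachSpec,
    times,
    focus: int = 0,
) -> MeanfieldRecovery:
    """Exact expected recovery curve at ``focus``; times measured from the
    start of the bleach pulse."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    Q = augmented_generator(config, geometry.n_foci)
    pi = stationary_distribution(Q)
    f0, q = _post_bleach_distribution(config, geometry, bleach, Q, pi)

    phi = config.immobile_fraction
    w = np.asarray(config.focus_weights)
    imm_survive = 1.0 - config.bleach_efficiency * q[2 + focus]
    imm_signal = phi * w[focus] * imm_survive

    QT = Q.T
    frac = np.empty(len(times))
    for i, t in enumerate(times):
        dt = max(t - bleach.duration, 0.0)
        p = expm(QT * dt) @ f0
        frac[i] = (1.0 - phi) * p[2 + focus] + imm_signal

    plateau = (1.0 - phi) * f0.sum() * pi[2 + focus] + imm_signal
    prebleach = (1.0 - phi) * pi[2 + focus] + phi * w[focus]
    return MeanfieldRecovery(times=times, fraction=frac, plateau=plateau, prebleach=prebleach)


@dataclass
class GroundTruth:
    """Simulator-side truth the analysis pipeline should recover."""

    expected_t_half: float
    mobile_fraction: float
    occupancies: dict
    focus_exchange_rate: float
    bleach_depth: float

    def to_dict(self) -> dict:
        return {
            "expected_t_half_s": self.expected_t_half,
            "mobile_fraction": self.mobile_fraction,
            "occupancies": self.occupancies,
            "focus_exchange_rate_per_s": self.focus_exchange_rate,
            "bleach_depth": self.bleach_depth,
        }


def ground_truth(
    config: KineticConfig,
    geometry: NucleusGeometry,
    bleach: BleachSpec,
    focus: int = 0,
) -> GroundTruth:
    """Expected half-time, mobile fraction and occupancies for a bleach.

    The half-time is the time at which the mean-field curve crosses midway
    between its post-bleach floor and its plateau; the mobile fraction of
    the bleached focus is the share of its steady-state fluorescence held
    by exchanging molecules.
    """
    Q = augmented_generator(config, geometry.n_foci)
    R = config.rate_matrix
    k_exit = R[1, 0] + R[1, 2]  # CHROM exit rate (to FREE and to RNA)
    if np.allclose(Q, 0.0):
        # frozen system: no exchange, no recovery, nothing mobile
        q = _bleach_geometry(geometry, BleachSpec(bleach.center, bleach.radius))
        w = np.asarray(config.focus_weights)
        occ = {"FREE": 0.0, "RNA": 0.0, "CHROM": 1.0} if config.initial_state in (
            None,
            "CHROM",
        ) else {config.initial_state: 1.0}
        return GroundTruth(
            expected_t_half=float("inf"),
            mobile_fraction=0.0,
            occupancies=occ,
            focus_exchange_rate=0.0,
            bleach_depth=float(1.0 - config.bleach_efficiency * q[2 + focus]),
        )
    pi = stationary_distribution(Q)

    def curve(t):
        return meanfield_recovery(config, geometry, bleach, [t], focus).fraction[0]

    f_floor = curve(bleach.duration)
    mf = meanfield_recovery(config, geometry, bleach, [0.0], focus)
    plateau = mf.plateau
    target = 0.5 * (f_floor + plateau)
    t_half = np.nan
    if plateau - f_floor > 1e-12:
        hi = 1.0 / max(k_exit, 1e-6)
        while curve(bleach.duration + hi) < target and hi < 1e6:
            hi *= 2.0
        t_half = brentq(
            lambda t: curve(bleach.duration + t) - target, 0.0, hi, xtol=1e-6
        )

    phi = config.immobile_fraction
    w = np.asarray(config.focus_weights)
    mobile_signal = (1.0 - phi) * pi[2 + focus]
    immobile_signal = phi * w[focus]
    total = mobile_signal + immobile_signal
    f_m = mobile_signal / total if total > 0 else np.nan

    occ = {
        "FREE": float((1.0 - phi) * pi[0]),
        "RNA": float((1.0 - phi) * pi[1]),
        "CHROM": float((1.0 - phi) * pi[2:].sum() + phi),
    }
    depth = f_floor / mf.prebleach if mf.prebleach > 0 else np.nan
    return GroundTruth(
        expected_t_half=float(t_half),
        mobile_fraction=float(f_m),
        occupancies=occ,
        focus_exchange_rate=float(k_exit),
        bleach_depth=float(depth),
    )
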