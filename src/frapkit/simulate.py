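"""Stochastic simulation of protein exchange and photobleaching.

Molecules are independent continuous-time Markov chains on an augmented
state space: FREE, RNA, and CHROM at each focus (a molecule entering the
chromatin-bound state picks a focus from the configured binding weights).
Exchange is pseudo-first-order -- binding sites never saturate -- which
keeps the mean behaviour an exactly solvable linear system (see
:mod:`frapkit.meanfield`).

The bleach pulse removes fluorescence, with the configured efficiency,
from molecules located inside the bleach sphere during the pulse window:
chromatin-bound molecules sit at their focus centre, free and RNA-bound
molecules at a uniformly sampled nucleoplasmic position. Fluorescence
flags never recover.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.linalg import null_space

from .config import CHROM, FREE, RNA, ImagingConfig, KineticConfig, NucleusGeometry

# Augmented state codes: 0 = FREE, 1 = RNA, 2 + k = CHROM at focus k.
AUG_FREE, AUG_RNA = 0, 1


def augmented_generator(config: KineticConfig, n_foci: int) -> np.ndarray:
    """Generator matrix Q on (FREE, RNA, CHROM@0..CHROM@K-1).

    Q[i, j] for i != j is the rate i -> j; rows sum to zero.
    """
    R = config.rate_matrix
    w = np.asarray(config.focus_weights)
    if len(w) != n_foci:
        raise ValueError("focus_weights length must equal the number of foci")
    n = 2 + n_foci
    Q = np.zeros((n, n))
    Q[AUG_FREE, AUG_RNA] = R[FREE, RNA]
    Q[AUG_RNA, AUG_FREE] = R[RNA, FREE]
    for k in range(n_foci):
        Q[AUG_FREE, 2 + k] = R[FREE, CHROM] * w[k]
        Q[AUG_RNA, 2 + k] = R[RNA, CHROM] * w[k]
        Q[2 + k, AUG_FREE] = R[CHROM, FREE]
        Q[2 + k, AUG_RNA] = R[CHROM, RNA]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a CTMC generator via its null space.

    States that cannot be entered (no inflow from the rest of the chain)
    carry zero stationary mass and are pruned iteratively; this covers
    configurations with unused states, e.g. a zero RNA-binding rate or a
    focus with zero binding weight. The remaining chain must be
    irreducible.
    """
    if np.allclose(Q, 0.0):
        raise ValueError(
            "all-zero rate matrix has no stationary distribution; "
            "set initial_state explicitly"
        )
    n = Q.shape[0]
    keep = np.ones(n, dtype=bool)
    changed = True
    while changed:
        changed = False
        for j in np.flatnonzero(keep):
            inflow = sum(Q[i, j] for i in np.flatnonzero(keep) if i != j)
            if inflow <= 0:
                keep[j] = False
                changed = True
    if not keep.any():
        raise ValueError("rate matrix has no recurrent states")
    sub = Q[np.ix_(keep, keep)].copy()
    np.fill_diagonal(sub, 0.0)
    np.fill_diagonal(sub, -sub.sum(axis=1))
    ns = null_space(sub.T)
    if ns.shape[1] != 1:
        raise ValueError(
            "rate matrix has multiple closed classes; stationary distribution "
            "is ambiguous -- set initial_state explicitly"
        )
    pi_sub = np.abs(ns[:, 0])
    pi = np.zeros(n)
    pi[keep] = pi_sub / pi_sub.sum()
    return pi


@dataclass
class MoleculeTrajectory:
    """Event record of one simulation run.

    ``initial_states`` / ``event_*`` use augmented codes; events are
    sorted by time. ``fluorescent`` flags apply from ``bleach_time``
    onward (``None`` means no bleach has been applied).
    """

    n_molecules: int
    n_foci: int
    duration: float
    initial_states: np.ndarray
    event_times: np.ndarray
    event_mol: np.ndarray
    event_state: np.ndarray
    immobile: np.ndarray
    fluorescent: np.ndarray
    bleach_time: float | None = None

    @property
    def n_states(self) -> int:
        return 2 + self.n_foci

    def states_at(self, t: float) -> np.ndarray:
        """Augmented state of every molecule at time t."""
        idx = np.searchsorted(self.event_times, t, side="right")
        s = self.initial_states.copy()
        if idx:
            mols = self.event_mol[:idx][::-1]
            vals = self.event_state[:idx][::-1]
            uniq, first = np.unique(mols, return_index=True)
            s[uniq] = vals[first]
        return s

    def _count_sweep(self, times: np.ndarray, weights: np.ndarray) -> np.ndarray:
        """Weighted per-state molecule counts at each time (times sorted)."""
        s = self.initial_states.copy()
        counts = np.zeros(self.n_states)
        np.add.at(counts, s, weights)
        out = np.empty((len(times), self.n_states))
        j = 0
        ev_t, ev_m, ev_s = self.event_times, self.event_mol, self.event_state
        for i, t in enumerate(times):
            while j < len(ev_t) and ev_t[j] <= t:
                m = ev_m[j]
                counts[s[m]] -= weights[m]
                s[m] = ev_s[j]
                counts[s[m]] += weights[m]
                j += 1
            out[i] = counts
        return out

    def state_counts(self, times) -> np.ndarray:
        """(len(times), n_states) counts of all molecules."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        return self._count_sweep(times, np.ones(self.n_molecules))

    def fluorescent_counts(self, times) -> np.ndarray:
        """Per-state counts of fluorescent molecules.

        Before the bleach every molecule counts; from ``bleach_time`` on,
        only those whose flag survived the pulse.
        """
        times = np.atleast_1d(np.asarray(times, dtype=float))
        all_counts = self._count_sweep(times, np.ones(self.n_molecules))
        if self.bleach_time is None:
            return all_counts
        fluor = self._count_sweep(times, self.fluorescent.astype(float))
        pre = times < self.bleach_time
        fluor[pre] = all_counts[pre]
        return fluor

    def total_fluorescent(self, times) -> np.ndarray:
        return self.fluorescent_counts(times).sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        """Long event table: time, molecule, state, focus, fluorescent."""
        state_names = np.array(
            ["FREE", "RNA"] + [f"CHROM" for _ in range(self.n_foci)]
        )
        focus = np.where(self.event_state >= 2, self.event_state - 2, -1)
        return pd.DataFrame(
            {
                "time": self.event_times,
                "molecule": self.event_mol,
                "state": state_names[self.event_state],
                "focus": focus,
                "fluorescent": self.fluorescent[self.event_mol],
            }
        )


def _initial_states(config, n_foci, Q, rng):
    n = config.n_molecules
    n_imm = int(round(config.immobile_fraction * n))
    n_mob = n - n_imm
    states = np.empty(n, dtype=np.int64)
    immobile = np.zeros(n, dtype=bool)
    immobile[n_mob:] = True
    if config.initial_state is None:
        pi = stationary_distribution(Q)
        states[:n_mob] = rng.choice(Q.shape[0], size=n_mob, p=pi)
    elif config.initial_state == "FREE":
        states[:n_mob] = AUG_FREE
    elif config.initial_state == "RNA":
        states[:n_mob] = AUG_RNA
    else:  # CHROM, distributed over foci by binding weights
        w = np.asarray(config.focus_weights)
        states[:n_mob] = 2 + rng.choice(n_foci, size=n_mob, p=w)
    if n_imm:
        w = np.asarray(config.focus_weights)
        states[n_mob:] = 2 + rng.choice(n_foci, size=n_imm, p=w)
    return states, immobile


def simulate_molecules(
    config: KineticConfig,
    geometry: NucleusGeometry,
    duration: float,
    seed: int,
) -> MoleculeTrajectory:
    """Exact event-driven simulation of independent molecules.

    Molecules start from the stationary distribution (or the forced
    ``initial_state``); immobile molecules are placed at a focus and never
    move. Identical (config, geometry, duration, seed) gives bit-identical
    trajectories.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_foci = geometry.n_foci
    Q = augmented_generator(config, n_foci)
    rng = np.random.default_rng(seed)
    states, immobile = _initial_states(config, n_foci, Q, rng)

    rates_out = -np.diag(Q)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(rates_out[:, None] > 0, Q / rates_out[:, None], 0.0)
    np.fill_diagonal(P, 0.0)
    cumP = np.cumsum(P, axis=1)

    mobile_idx = np.flatnonzero(~immobile)
    t = np.zeros(mobile_idx.size)
    s = states[mobile_idx].copy()
    active = rates_out[s] > 0
    ev_t, ev_m, ev_s = [], [], []
    while np.any(active):
        ai = np.flatnonzero(active)
        dt = rng.exponential(1.0 / rates_out[s[ai]])
        t[ai] += dt
        alive = t[ai] < duration
        ai = ai[alive]
        if ai.size:
            u = rng.random(ai.size)
            new = (u[:, None] > cumP[s[ai]]).sum(axis=1)
            s[ai] = new
            ev_t.append(t[ai].copy())
            ev_m.append(mobile_idx[ai])
            ev_s.append(new)
        active = np.zeros_like(active)
        active[ai] = rates_out[s[ai]] > 0

    if ev_t:
        et = np.concatenate(ev_t)
        em = np.concatenate(ev_m)
        es = np.concatenate(ev_s)
        order = np.argsort(et, kind="stable")
        et, em, es = et[order], em[order], es[order]
    else:
        et = np.empty(0)
        em = np.empty(0, dtype=np.int64)
        es = np.empty(0, dtype=np.int64)

    return MoleculeTrajectory(
        n_molecules=config.n_molecules,
        n_foci=n_foci,
        duration=duration,
        initial_states=states,
        event_times=et,
        event_mol=em,
        event_state=es.astype(np.int64),
        immobile=immobile,
        fluorescent=np.ones(config.n_molecules, dtype=bool),
    )


def _sample_in_sphere(rng, n, radius):
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return pts * r[:, None]


def sphere_intersection_volume(r1: float, r2: float, d: float) -> float:
    """Volume of the intersection of two spheres with centre distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return 4.0 / 3.0 * np.pi * r**3
    return (
        np.pi
        * (r1 + r2 - d) ** 2
        * (d**2 + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2)
        / (12 * d)
    )


def apply_bleach(
    trajectory: MoleculeTrajectory,
    geometry: NucleusGeometry,
    imaging: ImagingConfig,
    bleach_time: float,
    config: KineticConfig,
    seed: int = 0,
) -> MoleculeTrajectory:
    """Photobleach molecules inside the bleach sphere during the pulse.

    Location during [bleach_time, bleach_time + bleach_duration] is the
    focus centre for chromatin-bound molecules and a uniform nucleoplasmic
    position for FREE/RNA. The pulse itself is instantaneous at the
    configured efficiency; its 20 ms duration only widens the window of
    states considered, catching molecules transiting the spot.
    """
    if not 0.0 <= bleach_time <= trajectory.duration:
        raise ValueError("bleach_time must lie within the simulated duration")
    center = np.asarray(imaging.bleach_center, dtype=float)
    if np.linalg.norm(center) > geometry.nucleus_radius:
        raise ValueError("bleach region lies outside the nucleus")

    rng = np.random.default_rng(seed)
    n = trajectory.n_molecules
    centers = geometry.focus_centers()

    in_region = np.zeros(n, dtype=bool)
    for t in (bleach_time, min(bleach_time + imaging.bleach_duration, trajectory.duration)):
        s = trajectory.states_at(t)
        bound = s >= 2
        if np.any(bound):
            d = np.linalg.norm(centers[s[bound] - 2] - center, axis=1)
            in_region[np.flatnonzero(bound)[d <= imaging.bleach_radius]] = True
        pool = ~bound
        if np.any(pool):
            pos = _sample_in_sphere(rng, int(pool.sum()), geometry.nucleus_radius)
            d = np.linalg.norm(pos - center, axis=1)
            in_region[np.flatnonzero(pool)[d <= imaging.bleach_radius]] = True

    hit = in_region & (rng.random(n) < config.bleach_efficiency)
    fluor = trajectory.fluorescent & ~hit
    return replace(trajectory, fluorescent=fluor, bleach_time=bleach_time)
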