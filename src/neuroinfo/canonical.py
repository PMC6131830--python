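"""Canonical-experiment simulators emitting rasters plus ground-truth labels.

Four classic preparations are modeled at the level of firing-rate rules:

* sensory habituation in *Aplysia* (a depressing synapse between a sensory
  and a motor cell, both regular-spiking units);
* ON-center / OFF-surround retinal ganglion cells responding to dot stimuli;
* direction-tuned motor-cortex cells with a pre-movement temporal profile;
* hippocampal place cells driven by a random-walk trajectory.

The probabilistic models emit spikes as Bernoulli draws on a 1-ms internal
step (p = rate x 1 ms, far below 1 for every stated rate); counts are then
aggregated into the coarser analysis bins (25/50/100 ms).  Every simulator
is deterministic for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .neurosim import Circuit, Neuron, SpikeRaster, Stimulus, Synapse, simulate_circuit, torus_distance

__all__ = [
    "HabituationSpec",
    "RGCSpec",
    "MotorSpec",
    "PlaceSpec",
    "TrialCounts",
    "simulate_aplysia",
    "simulate_rgc",
    "simulate_motor",
    "simulate_place",
    "grid_label",
]

_EMISSION_DT_MS = 1.0  # internal Bernoulli step


@dataclass
class TrialCounts:
    """Binned spike counts (trials x time bins x neurons) with labels."""

    counts: np.ndarray
    bin_width: float
    labels: dict = field(default_factory=dict)  # name -> per-trial array
    meta: dict = field(default_factory=dict)


def _bernoulli_counts(
    rate_hz: np.ndarray, bin_width_ms: float, rng: np.random.Generator
) -> np.ndarray:
    """Spike counts per analysis bin from per-bin rates (any array shape).

    Each analysis bin is composed of ``bin_width_ms`` 1-ms Bernoulli steps
    at p = rate/1000, i.e. counts ~ Binomial(bin_width_ms, rate/1000).
    """
    p = np.asarray(rate_hz, dtype=float) * (_EMISSION_DT_MS / 1000.0)
    if np.any(p > 1.0):
        warnings.warn("emission probability capped at 1 for some bins", stacklevel=2)
        p = np.minimum(p, 1.0)
    n_sub = int(round(bin_width_ms / _EMISSION_DT_MS))
    return rng.binomial(n_sub, p)


def grid_label(points: np.ndarray, n_side: int = 4) -> np.ndarray:
    """Discretize unit-torus points to an n_side x n_side grid, row-major."""
    pts = np.mod(np.asarray(points, dtype=float), 1.0)
    ix = np.minimum((pts[..., 0] * n_side).astype(np.int64), n_side - 1)
    iy = np.minimum((pts[..., 1] * n_side).astype(np.int64), n_side - 1)
    return ix * n_side + iy


# ---------------------------------------------------------------------------
# Aplysia habituation

@dataclass(frozen=True)
class HabituationSpec:
    """Depressing sensory->motor synapse: per-spike peak current decays
    exponentially in the presynaptic spike index from 200 pA (first spike
    of the session) to 30 pA (last spike)."""

    initial_peak: float = 200.0
    final_peak: float = 30.0
    stim_amplitude: float = 200.0
    trial_duration: float = 1500.0
    stim_on: float = 500.0
    stim_off: float = 1000.0
    bin_width: float = 50.0
    noise_amplitude: float = 100.0


def _habituation_circuit(spec: HabituationSpec, weight: float) -> Circuit:
    return Circuit(
        neurons=[Neuron("S"), Neuron("M")],
        synapses=[Synapse("S", "M", weight)],
        noise_amplitude=spec.noise_amplitude,
    )


def simulate_aplysia(
    spec: HabituationSpec | None = None,
    n_trials: int = 20,
    seed: int | None = None,
    habituate: bool = True,
) -> tuple[SpikeRaster, TrialCounts]:
    """Simulate repeated stimulation of the sensory->motor reflex circuit.

    Trials run sequentially; the synaptic weight of the k-th presynaptic
    spike (counted over the whole session) follows
    ``w_k = initial * (final/initial)^(k / (K-1))`` where K is the total
    sensory spike count — pinned exactly to the stated endpoints.  Because
    the sensory cell is feedforward, K is found in a first pass with
    identical noise, then the session is re-run with the calibrated
    schedule.  ``habituate=False`` keeps the synapse constant (control).
    """
    spec = spec or HabituationSpec()
    if n_trials < 2:
        raise ValueError("need at least two trials")
    from .neurosim import gamma_kernel, one_over_f_noise

    dt = 0.1
    n_steps = int(round(spec.trial_duration / dt))
    rng = np.random.default_rng(seed)
    # per-trial membrane noise for both cells, drawn up front so the
    # two feedforward stages see consistent streams
    noise = one_over_f_noise(
        n_steps, dt, spec.noise_amplitude, rng, shape=(n_trials, 2)
    )

    # stage 1: the sensory cell is feedforward, so all trials run in one batch
    s_circuit = Circuit([Neuron("S")], noise_amplitude=0.0)
    s_raster = simulate_circuit(
        s_circuit,
        [Stimulus("S", spec.stim_amplitude, spec.stim_on, spec.stim_off)],
        spec.trial_duration, n_trials=n_trials, seed=rng,
        external_current=noise[:, :1, :],
    )
    s_spikes = [np.asarray(s_raster.spike_times[t][0]) for t in range(n_trials)]
    K = max(sum(len(s) for s in s_spikes), 2)
    ratio = spec.final_peak / spec.initial_peak

    if habituate:
        def weight_of(k: int) -> float:
            return spec.initial_peak * ratio ** (min(k, K - 1) / (K - 1))
    else:
        def weight_of(k: int) -> float:
            return spec.initial_peak

    # stage 2: schedule the depressing synaptic current onto the motor cell
    # (spike index k counts over the whole session, trials in order)
    kernel = gamma_kernel(dt)
    L = len(kernel)
    m_current = np.zeros((n_trials, 1, n_steps))
    k = 0
    for t in range(n_trials):
        for t_ms in s_spikes[t]:
            i = int(round(t_ms / dt))
            stop = min(i + L, n_steps)
            if stop > i:
                m_current[t, 0, i:stop] += weight_of(k) * kernel[: stop - i]
            k += 1
    m_current += noise[:, 1:, :]
    m_circuit = Circuit([Neuron("M")], noise_amplitude=0.0)
    m_raster = simulate_circuit(
        m_circuit, [], spec.trial_duration, n_trials=n_trials, seed=rng,
        external_current=m_current,
    )

    all_trials = [
        [s_spikes[t], np.asarray(m_raster.spike_times[t][0])]
        for t in range(n_trials)
    ]
    raster = SpikeRaster(all_trials, spec.trial_duration, ["S", "M"])
    raster.trial_labels["trial_index"] = np.arange(n_trials)
    counts = TrialCounts(
        raster.binned_counts(spec.bin_width),
        spec.bin_width,
        labels={"trial_index": np.arange(n_trials)},
        meta={"stim_on": spec.stim_on, "stim_off": spec.stim_off,
              "total_sensory_spikes": K, "habituate": habituate},
    )
    return raster, counts


# ---------------------------------------------------------------------------
# retinal ganglion cells

@dataclass(frozen=True)
class RGCSpec:
    """ON-center/OFF-surround cells on the unit torus."""

    n_neurons: int = 300
    on_radius: float = 0.1
    surround_outer_radius: float = 0.3
    background_rate: float = 30.0
    center_rate: float = 100.0
    surround_rate: float = 1.0
    n_stimuli: int = 400
    bin_width: float = 25.0
    stim_duration: float = 250.0

    def __post_init__(self) -> None:
        if not 0 < self.on_radius < self.surround_outer_radius:
            raise ValueError("require 0 < on_radius < surround_outer_radius")
        if min(self.background_rate, self.center_rate, self.surround_rate) < 0:
            raise ValueError("rates must be non-negative")


def simulate_rgc(
    spec: RGCSpec | None = None, seed: int | None = None
) -> TrialCounts:
    """Present random dot stimuli and draw spike counts per analysis bin.

    Each of ``n_stimuli`` presentations is one trial: every neuron fires at
    ``center_rate`` if the dot lies in its ON disc, ``surround_rate`` in the
    annulus, else ``background_rate``, throughout the presentation window.
    Labels carry the dot position and its 4x4 grid square.
    """
    spec = spec or RGCSpec()
    rng = np.random.default_rng(seed)
    cells = rng.random((spec.n_neurons, 2))
    stims = rng.random((spec.n_stimuli, 2))
    d = torus_distance(stims[:, None, :], cells[None, :, :])  # (stim, neuron)
    rate = np.full(d.shape, spec.background_rate)
    rate[d < spec.surround_outer_radius] = spec.surround_rate
    rate[d < spec.on_radius] = spec.center_rate
    n_bins = int(round(spec.stim_duration / spec.bin_width))
    rates_tb = np.broadcast_to(rate[:, None, :], (spec.n_stimuli, n_bins, spec.n_neurons))
    counts = _bernoulli_counts(rates_tb, spec.bin_width, rng)
    return TrialCounts(
        counts, spec.bin_width,
        labels={"stim_xy": stims, "stim_grid": grid_label(stims)},
        meta={"cell_positions": cells, "spec": spec},
    )


# ---------------------------------------------------------------------------
# motor cortex direction tuning

@dataclass(frozen=True)
class MotorSpec:
    """Cosine direction tuning with a Gaussian pre-movement profile."""

    n_directions: int = 8
    n_strong: int = 20          # responsiveness r = 1
    n_random: int = 100         # r ~ uniform(0, 1)
    background_rate: float = 50.0
    profile_mean: float = -100.0  # ms relative to movement onset
    profile_sd: float = 100.0
    n_trials: int = 150
    bin_width: float = 25.0
    t_start: float = -400.0
    t_stop: float = 200.0


def simulate_motor(
    spec: MotorSpec | None = None, seed: int | None = None
) -> TrialCounts:
    """Simulate a center-out task with direction-tuned cells.

    Rate rule: ``rate = bg * (1 + r * cos(theta - theta_pref) * g(t))`` with
    ``g`` a unit-peak Gaussian at ``profile_mean``; an r = 1 cell thus spans
    0..2*bg (0..100 Hz) at the profile peak.  Movement directions are
    equiprobable among ``n_directions``.
    """
    spec = spec or MotorSpec()
    rng = np.random.default_rng(seed)
    n_neurons = spec.n_strong + spec.n_random
    r = np.concatenate([np.ones(spec.n_strong), rng.random(spec.n_random)])
    theta_pref = rng.uniform(0, 2 * np.pi, n_neurons)
    directions = rng.integers(0, spec.n_directions, spec.n_trials)
    theta = directions * (2 * np.pi / spec.n_directions)
    edges = np.arange(spec.t_start, spec.t_stop + spec.bin_width, spec.bin_width)
    t_mid = 0.5 * (edges[:-1] + edges[1:])
    g = np.exp(-0.5 * ((t_mid - spec.profile_mean) / spec.profile_sd) ** 2)
    tuning = np.cos(theta[:, None] - theta_pref[None, :]) * r[None, :]  # (trial, neuron)
    rate = spec.background_rate * (
        1.0 + tuning[:, None, :] * g[None, :, None]
    )  # (trial, bin, neuron)
    counts = _bernoulli_counts(rate, spec.bin_width, rng)
    return TrialCounts(
        counts, spec.bin_width,
        labels={"direction": directions},
        meta={"responsiveness": r, "preferred_angle": theta_pref,
              "bin_centers_ms": t_mid, "spec": spec},
    )


# ---------------------------------------------------------------------------
# hippocampal place cells

@dataclass(frozen=True)
class PlaceSpec:
    """Gaussian place fields on the unit torus sampled by a random walk."""

    n_neurons: int = 200
    n_nonplace: int = 50        # rate-matched location-blind controls
    field_sd: float = 0.15
    peak_rate: float = 100.0
    background_rate: float = 20.0
    duration_s: float = 200.0
    bin_width: float = 100.0
    step_sd: float = 0.05       # random-walk step per bin, spatial units
    grid_side: int = 4


def simulate_place(
    spec: PlaceSpec | None = None, seed: int | None = None
) -> TrialCounts:
    """Random-walk exploration with place-field-modulated firing.

    The trajectory takes Gaussian steps (sd ``step_sd`` per 100-ms bin)
    wrapped on the torus; each place cell fires at
    ``bg + (peak - bg) * exp(-d^2 / (2 sd^2))`` for torus distance d to its
    field center.  ``n_nonplace`` extra cells fire at a constant rate equal
    to a place cell's spatial mean (location-blind, rate-matched controls).
    Counts come back as a single-trial layout (1 x bins x neurons) with a
    per-bin 4x4 grid location label; unvisited grid squares trigger a
    warning because location information is undefined for unseen states.
    """
    spec = spec or PlaceSpec()
    rng = np.random.default_rng(seed)
    n_bins = int(round(spec.duration_s * 1000.0 / spec.bin_width))
    steps = rng.normal(0.0, spec.step_sd, (n_bins, 2))
    steps[0] = rng.random(2)  # random start
    traj = np.mod(np.cumsum(steps, axis=0), 1.0)
    centers = rng.random((spec.n_neurons, 2))
    d = torus_distance(traj[:, None, :], centers[None, :, :])  # (bin, neuron)
    rate = spec.background_rate + (spec.peak_rate - spec.background_rate) * np.exp(
        -0.5 * (d / spec.field_sd) ** 2
    )
    if spec.n_nonplace:
        # spatial mean of a field over the torus ~ uniform average of the rate map
        gx = np.linspace(0, 1, 50, endpoint=False)
        gpts = np.stack(np.meshgrid(gx, gx, indexing="ij"), axis=-1).reshape(-1, 2)
        dd = torus_distance(gpts[:, None, :], centers[None, :1, :])
        mean_rate = float(
            (spec.background_rate
             + (spec.peak_rate - spec.background_rate) * np.exp(-0.5 * (dd / spec.field_sd) ** 2)
             ).mean()
        )
        rate = np.concatenate(
            [rate, np.full((n_bins, spec.n_nonplace), mean_rate)], axis=1
        )
    counts = _bernoulli_counts(rate, spec.bin_width, rng)
    location = grid_label(traj, spec.grid_side)
    occupancy = np.bincount(location, minlength=spec.grid_side**2)
    if np.any(occupancy == 0):
        warnings.warn(
            f"{int((occupancy == 0).sum())} grid squares unvisited; location "
            "information is undefined for unseen states",
            stacklevel=2,
        )
    is_place = np.concatenate(
        [np.ones(spec.n_neurons, bool), np.zeros(spec.n_nonplace, bool)]
    )
    return TrialCounts(
        counts[None, :, :], spec.bin_width,
        labels={"location": location},
        meta={"trajectory": traj, "field_centers": centers,
              "is_place_cell": is_place, "occupancy": occupancy, "spec": spec},
    )
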