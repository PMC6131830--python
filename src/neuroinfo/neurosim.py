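"""Spiking-network simulators used as built-in data generators.

Two families of models are provided:

* Small circuits (one to four cells) of dimensional Izhikevich units — a
  regular-spiking (RS) excitatory cell and a fast-spiking interneuron
  (FSI) — coupled by gamma-kernel synaptic current pulses, driven by square
  stimulus pulses and 1/f membrane noise, integrated by forward Euler at
  0.1 ms.
* A 1000-neuron network (800 excitatory, 200 inhibitory) on the unit torus
  with distance-dependent connectivity, using the classic dimensionless
  heterogeneous-parameter formulation with 1-ms steps and instantaneous
  synaptic delivery.

Rasters come back as per-trial, per-neuron spike-time lists with helpers to
bin them into the spike-count matrices the analysis side consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "IzhikevichParams",
    "RS_PARAMS",
    "FSI_PARAMS",
    "Neuron",
    "Synapse",
    "Stimulus",
    "Circuit",
    "SpikeRaster",
    "NetworkSpec",
    "step_rs",
    "step_fsi",
    "gamma_psc",
    "gamma_kernel",
    "one_over_f_noise",
    "simulate_circuit",
    "simulate_circuit_experiment",
    "circuit_preset",
    "CIRCUIT_PRESETS",
    "build_distance_network",
    "simulate_network",
]


@dataclass(frozen=True)
class IzhikevichParams:
    """Two-variable quadratic integrate-and-reset neuron parameters.

    Units: C in pF, voltages in mV, currents in pA, a in 1/ms.  ``d`` (the
    post-spike recovery increment) applies to the RS cell only; ``vb`` (the
    recovery activation threshold) to the FSI only.
    """

    cell_class: str
    C: float
    vr: float
    vt: float
    vpeak: float
    k: float
    a: float
    b: float
    c: float
    d: float = 0.0
    vb: float = 0.0

    def __post_init__(self) -> None:
        if self.cell_class not in ("RS", "FSI"):
            raise ValueError("cell_class must be 'RS' or 'FSI'")
        if not (self.vr < self.vt < self.vpeak) or not self.c < self.vpeak:
            raise ValueError("require vr < vt < vpeak and c < vpeak")


#: Regular-spiking pyramidal-cell preset.
RS_PARAMS = IzhikevichParams(
    cell_class="RS", C=100.0, vr=-60.0, vt=-40.0, vpeak=35.0,
    k=0.7, b=-2.0, a=0.03, c=-50.0, d=100.0,
)

#: Fast-spiking interneuron preset (k raised to 3.5 for responsiveness).
FSI_PARAMS = IzhikevichParams(
    cell_class="FSI", C=20.0, vr=-55.0, vt=-40.0, vpeak=25.0,
    k=3.5, b=0.025, a=0.2, c=-45.0, vb=-55.0,
)


def step_rs(v, u, p: IzhikevichParams, I, dt: float = 0.1):
    """One forward-Euler step of the RS cell; returns (v, u, spiked).

    dv/dt = (k (v - vr)(v - vt) - u + I) / C,  du/dt = a (b (v - vr) - u);
    on reaching vpeak: v <- c, u <- u + d.
    """
    v = np.asarray(v, dtype=float)
    u = np.asarray(u, dtype=float)
    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(u))):
        raise FloatingPointError("non-finite neuron state")
    v_new = v + dt * (p.k * (v - p.vr) * (v - p.vt) - u + I) / p.C
    u_new = u + dt * p.a * (p.b * (v - p.vr) - u)
    spiked = v_new >= p.vpeak
    v_new = np.where(spiked, p.c, v_new)
    u_new = np.where(spiked, u_new + p.d, u_new)
    return v_new, u_new, spiked


def step_fsi(v, u, p: IzhikevichParams, I, dt: float = 0.1):
    """One forward-Euler step of the FSI cell; returns (v, u, spiked).

    Recovery drive is piecewise: U(v) = 0 below vb, b (v - vb)^3 above.
    The reset restores v only (no recovery increment).
    """
    v = np.asarray(v, dtype=float)
    u = np.asarray(u, dtype=float)
    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(u))):
        raise FloatingPointError("non-finite neuron state")
    U = np.where(v < p.vb, 0.0, p.b * (v - p.vb) ** 3)
    v_new = v + dt * (p.k * (v - p.vr) * (v - p.vt) - u + I) / p.C
    u_new = u + dt * p.a * (U - u)
    spiked = v_new >= p.vpeak
    v_new = np.where(spiked, p.c, v_new)
    return v_new, u_new, spiked


# Gamma synaptic kernel: mean 30 ms and sd 20 ms give shape 2.25 and
# scale 40/3 ms; the pulse is normalized so its extremum equals the synaptic
# weight ("max pA"), which occurs at the mode (shape-1)*scale ~ 16.7 ms.
_GAMMA_SHAPE = 2.25
_GAMMA_SCALE = 40.0 / 3.0
_GAMMA_MODE = (_GAMMA_SHAPE - 1.0) * _GAMMA_SCALE
#: kernel support, ms: mean + 5 sd; the tail beyond is < 1e-3 of the peak
KERNEL_CUTOFF_MS = 130.0


def gamma_psc(weight: float, t_since_spike) -> np.ndarray | float:
    """Postsynaptic current (pA) ``t_since_spike`` ms after a spike.

    Gamma-shaped pulse scaled so its peak equals ``weight`` (negative
    weights give inhibitory pulses of the same shape).
    """
    t = np.asarray(t_since_spike, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since_spike must be >= 0")
    with np.errstate(invalid="ignore"):
        shape = np.where(
            t > 0,
            (t / _GAMMA_MODE) ** (_GAMMA_SHAPE - 1)
            * np.exp((_GAMMA_MODE - t) / _GAMMA_SCALE),
            0.0,
        )
    out = weight * shape
    return float(out) if np.isscalar(t_since_spike) else out


def gamma_kernel(dt: float = 0.1) -> np.ndarray:
    """Unit-peak synaptic kernel sampled at ``dt`` ms up to the cutoff."""
    t = np.arange(dt, KERNEL_CUTOFF_MS + dt, dt)
    return np.asarray(gamma_psc(1.0, t))


def one_over_f_noise(
    n_samples: int,
    dt: float = 0.1,
    amplitude: float = 1.0,
    seed: int | np.random.Generator | None = None,
    shape: tuple[int, ...] = (),
) -> np.ndarray:
    """Zero-mean 1/f ("pink") noise traces with standard deviation ``amplitude``.

    Gaussian white noise is filtered in frequency space to a 1/f power
    spectrum (amplitude spectrum 1/sqrt(f)) and inverse-transformed; the
    log-log spectral slope is -1 across the resolved decades.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(shape + (n_samples,))
    if amplitude == 0:
        return np.zeros_like(white)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=dt / 1000.0)
    gain = np.zeros_like(freqs)
    gain[1:] = 1.0 / np.sqrt(freqs[1:])
    trace = np.fft.irfft(spec * gain, n=n_samples, axis=-1)
    sd = trace.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return amplitude * trace / sd


@dataclass(frozen=True)
class Neuron:
    name: str
    cell_class: str = "RS"
    params: IzhikevichParams | None = None

    def resolved_params(self) -> IzhikevichParams:
        if self.params is not None:
            return self.params
        return RS_PARAMS if self.cell_class == "RS" else FSI_PARAMS


@dataclass(frozen=True)
class Synapse:
    """Directed connection; ``weight`` is the kernel's peak current in pA.

    Excitatory (RS) sources must have weight >= 0, inhibitory (FSI) sources
    weight <= 0; checked at simulation time.
    """

    pre: str
    post: str
    weight: float


@dataclass(frozen=True)
class Stimulus:
    """Square current pulse into one neuron, optionally on a subset of trials."""

    neuron: str
    amplitude: float
    t_on: float
    t_off: float
    trials: tuple[int, ...] | None = None  # None = every trial


@dataclass
class Circuit:
    neurons: list[Neuron]
    synapses: list[Synapse] = field(default_factory=list)
    background: dict = field(default_factory=dict)  # name -> constant pA
    #: 1/f membrane-noise standard deviation, pA; the default produces a
    #: low spontaneous RS firing rate (~1-5 Hz) in an unstimulated cell
    noise_amplitude: float = 100.0

    def neuron_index(self, name: str) -> int:
        for i, n in enumerate(self.neurons):
            if n.name == name:
                return i
        raise KeyError(name)


@dataclass
class SpikeRaster:
    """Spike times (ms) per trial per neuron, plus binning helpers."""

    spike_times: list  # [trial][neuron] -> float array, ms
    duration: float
    neuron_names: list[str]
    dt: float = 0.1
    trial_labels: dict = field(default_factory=dict)  # label -> per-trial array

    @property
    def n_trials(self) -> int:
        return len(self.spike_times)

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_names)

    def binned_counts(self, bin_width: float) -> np.ndarray:
        """Spike counts, shape (n_trials, n_bins, n_neurons)."""
        n_bins = int(np.floor(self.duration / bin_width))
        out = np.zeros((self.n_trials, n_bins, self.n_neurons), dtype=np.int64)
        edges = np.arange(n_bins + 1) * bin_width
        for t, per_neuron in enumerate(self.spike_times):
            for j, times in enumerate(per_neuron):
                if len(times):
                    out[t, :, j] = np.histogram(times, bins=edges)[0]
        return out


def simulate_circuit(
    circuit: Circuit,
    stimuli: Sequence[Stimulus],
    duration: float,
    n_trials: int = 1,
    dt: float = 0.1,
    seed: int | np.random.Generator | None = None,
    external_current: np.ndarray | None = None,
    synapse_weight_fn: Callable[[Synapse, int], float] | None = None,
) -> SpikeRaster:
    """Simulate a small circuit for ``n_trials`` independent trials.

    Event-driven synaptic currents: each presynaptic spike adds a
    gamma-kernel pulse (peak = synapse weight) to the target's input from
    the next step on.  ``external_current`` (n_trials, n_neurons, n_steps)
    is added verbatim; ``synapse_weight_fn(synapse, k)`` may override the
    weight of the k-th spike through a synapse (used for habituation).
    Trials are statistically independent but integrated together.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_neurons = len(circuit.neurons)
    n_steps = int(round(duration / dt))
    params = [n.resolved_params() for n in circuit.neurons]
    rs_mask = np.array([p.cell_class == "RS" for p in params])

    for syn in circuit.synapses:
        pre_class = params[circuit.neuron_index(syn.pre)].cell_class
        if pre_class == "RS" and syn.weight < 0:
            raise ValueError(f"excitatory source {syn.pre} cannot have weight < 0")
        if pre_class == "FSI" and syn.weight > 0:
            raise ValueError(f"inhibitory source {syn.pre} cannot have weight > 0")

    # external drive: stimuli + constant background + 1/f noise
    I_ext = np.zeros((n_trials, n_neurons, n_steps))
    if external_current is not None:
        I_ext += external_current
    for name, amp in circuit.background.items():
        I_ext[:, circuit.neuron_index(name), :] += amp
    for stim in stimuli:
        j = circuit.neuron_index(stim.neuron)
        i0, i1 = int(round(stim.t_on / dt)), int(round(stim.t_off / dt))
        tr = slice(None) if stim.trials is None else list(stim.trials)
        I_ext[tr, j, i0:i1] += stim.amplitude
    if circuit.noise_amplitude:
        I_ext += one_over_f_noise(
            n_steps, dt, circuit.noise_amplitude, rng, shape=(n_trials, n_neurons)
        )

    kernel = gamma_kernel(dt)
    L = len(kernel)
    syn_current = np.zeros((n_trials, n_neurons, n_steps + L))
    spike_lists: list[list[list[float]]] = [
        [[] for _ in range(n_neurons)] for _ in range(n_trials)
    ]
    spike_counter = [0] * len(circuit.synapses)

    # integrate columns sharing a parameter set together
    groups: list[tuple[IzhikevichParams, list[int]]] = []
    for j, p in enumerate(params):
        for gp, cols in groups:
            if gp is p or gp == p:
                cols.append(j)
                break
        else:
            groups.append((p, [j]))

    v = np.full((n_trials, n_neurons), [p.vr for p in params])
    u = np.zeros((n_trials, n_neurons))
    spiked = np.zeros((n_trials, n_neurons), dtype=bool)
    for i in range(n_steps):
        I = I_ext[:, :, i] + syn_current[:, :, i]
        for p, cols in groups:
            stepper = step_rs if p.cell_class == "RS" else step_fsi
            v[:, cols], u[:, cols], spiked[:, cols] = stepper(
                v[:, cols], u[:, cols], p, I[:, cols], dt
            )
        if spiked.any():
            t_ms = (i + 1) * dt
            for tr, j in zip(*np.nonzero(spiked)):
                spike_lists[tr][j].append(t_ms)
            for s_idx, syn in enumerate(circuit.synapses):
                pre = circuit.neuron_index(syn.pre)
                post = circuit.neuron_index(syn.post)
                trs = np.nonzero(spiked[:, pre])[0]
                for tr in trs:
                    w = syn.weight
                    if synapse_weight_fn is not None:
                        w = synapse_weight_fn(syn, spike_counter[s_idx])
                    spike_counter[s_idx] += 1
                    stop = min(i + 1 + L, n_steps + L)
                    syn_current[tr, post, i + 1 : stop] += w * kernel[: stop - i - 1]

    spike_times = [
        [np.asarray(spike_lists[tr][j]) for j in range(n_neurons)]
        for tr in range(n_trials)
    ]
    return SpikeRaster(spike_times, duration, [n.name for n in circuit.neurons], dt)


# ---------------------------------------------------------------------------
# circuit presets (weights in pA at the kernel peak)

def _preset_feedforward_pair(**kw) -> Circuit:
    """E1 -> E2 excitatory pair; E1 receives the stimulus."""
    return Circuit(
        neurons=[Neuron("E1"), Neuron("E2")],
        synapses=[Synapse("E1", "E2", 200.0)],
    )


def _preset_inhibition_modulated(inhibition: float = -150.0, **kw) -> Circuit:
    """E1 drives E2 and an interneuron I1 that inhibits E2.

    ``inhibition`` is the I1 -> E2 peak current, scanned over [0, -150] pA.
    """
    if not -150.0 <= inhibition <= 0.0:
        raise ValueError("inhibition is scanned over [0, -150] pA")
    return Circuit(
        neurons=[Neuron("E1"), Neuron("E2"), Neuron("I1", "FSI")],
        synapses=[
            Synapse("E1", "E2", 200.0),
            Synapse("E1", "I1", 200.0),
            Synapse("I1", "E2", inhibition),
        ],
    )


def _preset_two_stimulus_unique(**kw) -> Circuit:
    """Two stimulated cells; only E1 projects to the readout E3."""
    return Circuit(
        neurons=[Neuron("E1"), Neuron("E2"), Neuron("E3")],
        synapses=[Synapse("E1", "E3", 200.0)],
    )


def _preset_xor_gate(**kw) -> Circuit:
    """Readout E3 fires when exactly one of two stimuli is on.

    Both inputs excite E3 and a shared interneuron; with both stimuli on
    the interneuron's inhibition (plus constant background inhibition)
    silences E3, yielding XOR-like, synergy-dominated encoding.
    """
    return Circuit(
        neurons=[Neuron("E1"), Neuron("E2"), Neuron("I1", "FSI"), Neuron("E3")],
        synapses=[
            Synapse("E1", "I1", 50.0),
            Synapse("E2", "I1", 50.0),
            Synapse("E1", "E3", 200.0),
            Synapse("E2", "E3", 200.0),
            Synapse("I1", "E3", -250.0),
        ],
        background={"E3": -100.0},
    )


def _preset_nor_gate(background_excitation: float = 200.0, **kw) -> Circuit:
    """Two stimulated interneurons inhibit E1, which may get tonic drive.

    With background excitation on, E1 fires only when neither stimulus is
    on (NOR-like); with it off, E1 is mostly silent.
    """
    if background_excitation not in (0.0, 200.0):
        raise ValueError("background excitation is either 0 or 200 pA")
    return Circuit(
        neurons=[Neuron("I1", "FSI"), Neuron("I2", "FSI"), Neuron("E1")],
        synapses=[Synapse("I1", "E1", -30.0), Synapse("I2", "E1", -30.0)],
        background={"E1": background_excitation},
    )


def _preset_correlated_inputs(**kw) -> Circuit:
    """Two stimulated cells converging on E3 (stimulus correlation external)."""
    return Circuit(
        neurons=[Neuron("E1"), Neuron("E2"), Neuron("E3")],
        synapses=[Synapse("E1", "E3", 100.0), Synapse("E2", "E3", 100.0)],
    )


CIRCUIT_PRESETS: dict[str, Callable[..., Circuit]] = {
    "feedforward_pair": _preset_feedforward_pair,
    "inhibition_modulated": _preset_inhibition_modulated,
    "two_stimulus_unique": _preset_two_stimulus_unique,
    "xor_gate": _preset_xor_gate,
    "nor_gate": _preset_nor_gate,
    "correlated_inputs": _preset_correlated_inputs,
}


def circuit_preset(name: str, **overrides) -> Circuit:
    """Build a named small-circuit preset (see :data:`CIRCUIT_PRESETS`)."""
    try:
        factory = CIRCUIT_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown circuit preset {name!r}; available: {sorted(CIRCUIT_PRESETS)}"
        ) from None
    return factory(**overrides)


def simulate_circuit_experiment(
    preset: str,
    n_trials: int = 40,
    seed: int | np.random.Generator | None = None,
    duration: float = 1500.0,
    stim_window: tuple[float, float] = (500.0, 1000.0),
    stim_amplitude: float | None = None,
    correlation: float = 0.0,
    **preset_overrides,
) -> SpikeRaster:
    """Run a preset circuit over a randomized trial design.

    Single-stimulus presets (feedforward_pair, inhibition_modulated) get a
    balanced on/off design labeled ``stim_A``; two-stimulus presets get the
    four on/off combinations, equiprobable except for correlated_inputs,
    where ``correlation`` in [-0.25, 0.25] shifts probability mass toward
    (or away from) the matching combinations.  The stimulus is a square
    pulse over ``stim_window`` into the input cell(s).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    circuit = circuit_preset(preset, **preset_overrides)
    if stim_amplitude is None:
        # the gate circuits need a drive strong enough to recruit the shared
        # interneuron only under co-stimulation; pairs use a moderate pulse
        stim_amplitude = {
            "xor_gate": 600.0,
            "nor_gate": 600.0,
            "inhibition_modulated": 300.0,
        }.get(preset, 200.0)
    single = {"feedforward_pair": "E1", "inhibition_modulated": "E1"}
    double = {
        "two_stimulus_unique": ("E1", "E2"),
        "xor_gate": ("E1", "E2"),
        "nor_gate": ("I1", "I2"),
        "correlated_inputs": ("E1", "E2"),
    }
    t_on, t_off = stim_window
    stimuli: list[Stimulus] = []
    labels: dict[str, np.ndarray] = {}
    if preset in single:
        on = rng.permutation(n_trials) < n_trials // 2
        stimuli.append(
            Stimulus(single[preset], stim_amplitude, t_on, t_off,
                     tuple(np.nonzero(on)[0]))
        )
        labels["stim_A"] = on.astype(np.int64)
    elif preset in double:
        if preset == "correlated_inputs":
            if not -0.25 <= correlation <= 0.25:
                raise ValueError("correlation must lie in [-0.25, 0.25]")
            p = np.array([
                0.25 + correlation,  # off/off
                0.25 - correlation,  # off/on
                0.25 - correlation,  # on/off
                0.25 + correlation,  # on/on
            ])
        else:
            p = np.full(4, 0.25)
        combo = rng.choice(4, size=n_trials, p=p)
        a_on = (combo // 2).astype(bool)
        b_on = (combo % 2).astype(bool)
        na, nb = double[preset]
        stimuli.append(Stimulus(na, stim_amplitude, t_on, t_off, tuple(np.nonzero(a_on)[0])))
        stimuli.append(Stimulus(nb, stim_amplitude, t_on, t_off, tuple(np.nonzero(b_on)[0])))
        labels["stim_A"] = a_on.astype(np.int64)
        labels["stim_B"] = b_on.astype(np.int64)
    else:
        raise ValueError(f"no experiment design for preset {preset!r}")
    raster = simulate_circuit(circuit, stimuli, duration, n_trials, seed=rng)
    raster.trial_labels.update(labels)
    raster.trial_labels["stim_window"] = np.array([t_on, t_off])
    return raster


# ---------------------------------------------------------------------------
# large distance-dependent network

@dataclass
class NetworkSpec:
    """1000-neuron torus network configuration and (after build) topology."""

    n_exc: int = 800
    n_inh: int = 200
    stim_lines: tuple[float, ...] = (0.5,)
    stim_magnitude: float = 50.0
    stim_duration: float = 100.0
    isi: float = 1000.0
    n_stim_targets: int = 40
    positions: np.ndarray | None = None
    adjacency: np.ndarray | None = None  # [target, source]
    stim_targets: list | None = None

    @property
    def n_total(self) -> int:
        return self.n_exc + self.n_inh


def connection_probability(r) -> np.ndarray | float:
    """Distance-dependent connection probability 0.513 * exp(-0.513 r)."""
    return 0.513 * np.exp(-0.513 * np.asarray(r, dtype=float))


def torus_distance(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Minimal wrap-around distance between points on the unit torus."""
    d = np.abs(p - q)
    d = np.minimum(d, 1.0 - d)
    return np.sqrt((d**2).sum(axis=-1))


def build_distance_network(
    spec: NetworkSpec | None = None, seed: int | np.random.Generator | None = None
) -> NetworkSpec:
    """Place neurons on the unit torus and wire them by distance.

    Each ordered pair connects with probability 0.513 exp(-0.513 r); raw
    weights are uniform(0, 0.5) for excitatory and uniform(-1, 0) for
    inhibitory sources, then rescaled class-wise so the total excitatory
    and inhibitory weight match the all-to-all reference totals (expected
    values of the same uniform draws over every ordered pair).
    """
    spec = replace(spec) if spec is not None else NetworkSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = spec.n_total
    pos = rng.random((n, 2))
    r = torus_distance(pos[:, None, :], pos[None, :, :])
    connected = rng.random((n, n)) < connection_probability(r)
    np.fill_diagonal(connected, False)
    w = np.zeros((n, n))
    exc = np.arange(spec.n_exc)
    inh = np.arange(spec.n_exc, n)
    w[:, exc] = rng.uniform(0.0, 0.5, (n, spec.n_exc))
    w[:, inh] = rng.uniform(-1.0, 0.0, (n, spec.n_inh))
    w[~connected] = 0.0
    # class-wise rescale to the all-to-all expected totals
    exc_ref = spec.n_exc * n * 0.25
    inh_ref = -(spec.n_inh * n * 0.5)
    exc_sum = w[:, exc].sum()
    inh_sum = w[:, inh].sum()
    if exc_sum > 0:
        w[:, exc] *= exc_ref / exc_sum
    if inh_sum < 0:
        w[:, inh] *= inh_ref / inh_sum
    spec.positions = pos
    spec.adjacency = w
    # per line: the excitatory neurons nearest to the ring x = x0
    targets = []
    for x0 in spec.stim_lines:
        dx = np.abs(pos[exc, 0] - x0)
        dx = np.minimum(dx, 1.0 - dx)
        targets.append(exc[np.argsort(dx)[: spec.n_stim_targets]])
    spec.stim_targets = targets
    return spec


def simulate_network(
    spec: NetworkSpec,
    n_stim_trials: int = 10,
    n_off_trials: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> SpikeRaster:
    """Run the large network over stimulated and unstimulated trials.

    Each trial spans one inter-stimulus interval; on stimulated trials every
    stimulus line's 40 nearest excitatory neurons receive a square pulse of
    the configured magnitude for the first ``stim_duration`` ms.  Dynamics
    follow the canonical heterogeneous two-population formulation at 1-ms
    resolution with per-ms stochastic thalamic drive.  The returned raster
    carries a boolean ``stimulus_on`` trial label.
    """
    if spec.adjacency is None:
        raise ValueError("call build_distance_network first")
    if not 1 <= len(spec.stim_lines) <= 2:
        raise ValueError("one or two stimulus lines supported")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_off_trials is None:
        n_off_trials = n_stim_trials
    n = spec.n_total
    n_exc, n_inh = spec.n_exc, spec.n_inh
    re = rng.random(n_exc)
    ri = rng.random(n_inh)
    a = np.concatenate([np.full(n_exc, 0.02), 0.02 + 0.08 * ri])
    b = np.concatenate([np.full(n_exc, 0.2), 0.25 - 0.05 * ri])
    c = np.concatenate([-65 + 15 * re**2, np.full(n_inh, -65.0)])
    d = np.concatenate([8 - 6 * re**2, np.full(n_inh, 2.0)])
    noise_scale = np.concatenate([np.full(n_exc, 5.0), np.full(n_inh, 2.0)])
    W = spec.adjacency

    trial_on = np.array([True] * n_stim_trials + [False] * n_off_trials)
    order = rng.permutation(len(trial_on))
    trial_on = trial_on[order]
    steps = int(round(spec.isi))
    stim_steps = int(round(spec.stim_duration))
    stim_vector = np.zeros(n)
    for tgt in spec.stim_targets:
        stim_vector[tgt] = spec.stim_magnitude

    v = np.full(n, -65.0)
    u = b * v
    spike_lists: list[list[list[float]]] = []
    for on in trial_on:
        per_neuron: list[list[float]] = [[] for _ in range(n)]
        for t in range(steps):
            I = noise_scale * rng.standard_normal(n)
            if on and t < stim_steps:
                I = I + stim_vector
            fired = np.nonzero(v >= 30.0)[0]
            if fired.size:
                t_ms = float(t)
                for j in fired:
                    per_neuron[j].append(t_ms)
                v[fired] = c[fired]
                u[fired] += d[fired]
                I = I + W[:, fired].sum(axis=1)
            for _ in range(2):  # two half-steps for numerical stability
                v = v + 0.5 * (0.04 * v**2 + 5 * v + 140 - u + I)
            u = u + a * (b * v - u)
            np.clip(v, -200.0, 40.0, out=v)
        spike_lists.append(per_neuron)

    spike_times = [
        [np.asarray(per_neuron[j]) for j in range(n)] for per_neuron in spike_lists
    ]
    names = [f"e{j}" for j in range(n_exc)] + [f"i{j}" for j in range(n_inh)]
    raster = SpikeRaster(spike_times, spec.isi, names, dt=1.0)
    raster.trial_labels["stimulus_on"] = trial_on.astype(np.int64)
    return raster
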