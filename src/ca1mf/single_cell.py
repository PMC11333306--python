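"""EGLIF point-neuron dynamics and conductance-based alpha synapses.

The extended generalized leaky integrate-and-fire (EGLIF) neuron extends the
classic LIF with two intrinsic currents: a slow adaptation current ``I_adap``
that is driven by the distance of the membrane potential from rest and decays
at rate ``k_2``, and a fast depolarizing current ``I_dep`` that is set to a
fixed amplitude at each spike and decays at rate ``k_1``.  Between spikes the
membrane evolves as

    C_m dV/dt = -(C_m/tau_m) (V - E_rev) - I_adap + I_dep + I_e + I_syn
    dI_adap/dt = k_adap (V - E_rev) - k_2 I_adap
    dI_dep/dt  = -k_1 I_dep

and at a spike the state is updated as ``V -> V_r``, ``I_adap += A_2``,
``I_dep = A_1``.  Synaptic interaction is conductance based,

    I_syn = G_e (E_e - V) + G_i (E_i - V),

where each presynaptic spike of type ``j`` contributes an alpha-shaped
conductance transient ``Q_j (t/tau_syn) exp(1 - t/tau_syn)`` peaking at the
quantal conductance ``Q_j`` at ``t = tau_syn``.

Units are millivolt, millisecond, picoampere, nanosiemens and picofarad
throughout (consistent: pA = nS * mV and pF/ms = nS).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellParams",
    "SynParams",
    "NeuronState",
    "SpikeRecord",
    "PYR_PARAMS",
    "FS_PARAMS",
    "DEFAULT_SYN",
    "eglif_derivatives",
    "apply_spike_reset",
    "alpha_kernel",
    "synaptic_current",
    "simulate_single_cell",
]

# Alpha-kernel peak factor: the conductance jump applied to the auxiliary
# variable so that the kernel peaks exactly at Q (see alpha_kernel).
ALPHA_JUMP = math.e


@dataclass(frozen=True)
class CellParams:
    """Constants of one EGLIF cell type.

    The spike threshold ``v_th``, reset potential ``v_r`` and refractory
    period ``t_ref`` are calibration parameters of this package (they are not
    part of the published EGLIF parameter set for CA1); the shipped defaults
    produce output rates in the 0.5-50 Hz range over the transfer-function
    input grid.
    """

    name: str
    c_m: float        # membrane capacitance (pF)
    tau_m: float      # membrane time constant (ms)
    e_rev: float      # leak/rest reversal potential (mV)
    k_adap: float     # adaptation coupling (pA / (mV ms))
    k_1: float        # I_dep decay rate (1/ms)
    k_2: float        # I_adap decay rate (1/ms)
    a_1: float        # I_dep post-spike amplitude (pA)
    a_2: float        # I_adap post-spike increment (pA)
    i_e: float        # endogenous current (pA)
    v_r: float        # reset potential (mV)
    v_th: float       # spike threshold (mV)
    t_ref: float      # absolute refractory period (ms)

    def __post_init__(self) -> None:
        if not (self.c_m > 0 and self.tau_m > 0):
            raise ValueError("C_m and tau_m must be positive")
        if self.k_1 < 0 or self.k_2 < 0:
            raise ValueError("decay rates k_1, k_2 must be non-negative")
        if self.v_r > self.v_th:
            raise ValueError("V_r must not exceed V_th")
        if self.t_ref < 0:
            raise ValueError("t_ref must be non-negative")

    @property
    def g_l(self) -> float:
        """Leak conductance C_m / tau_m (nS)."""
        return self.c_m / self.tau_m

    def replace(self, **kw) -> "CellParams":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class SynParams:
    """Conductance-based alpha-synapse constants (shared by both cell types)."""

    q_pyr: float = 1.5    # quantal conductance, pyramidal (excitatory) source (nS)
    q_fs: float = 8.0     # quantal conductance, fast-spiking (inhibitory) source (nS)
    tau_syn: float = 5.0  # synaptic time constant (ms)
    e_e: float = 0.0      # excitatory reversal potential (mV)
    e_i: float = -80.0    # inhibitory reversal potential (mV)

    def __post_init__(self) -> None:
        if self.q_pyr < 0 or self.q_fs < 0:
            raise ValueError("quantal conductances must be non-negative")
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be positive")
        if self.e_i >= self.e_e:
            raise ValueError("E_i must be below E_e")


# Published EGLIF parameters for CA1 pyramidal cells and fast-spiking
# interneurons; v_r/v_th/t_ref are package calibration defaults (v_r = E_rev).
PYR_PARAMS = CellParams(
    name="pyr", c_m=2877.83, tau_m=10955.36, e_rev=-70.07,
    k_adap=0.0084, k_1=0.0007, k_2=0.0042, a_1=26.0, a_2=170.0,
    i_e=0.0, v_r=-70.07, v_th=-55.0, t_ref=2.0,
)
FS_PARAMS = CellParams(
    name="fs", c_m=2939.66, tau_m=2169.40, e_rev=-74.01,
    k_adap=0.0616, k_1=0.0021, k_2=0.0098, a_1=92.0, a_2=5.0,
    i_e=0.0, v_r=-74.01, v_th=-45.0, t_ref=2.0,
)
DEFAULT_SYN = SynParams()


@dataclass
class NeuronState:
    """Dynamical variables of one EGLIF neuron.

    The synaptic conductances are tracked with the exact two-variable linear
    realization of the alpha kernel: ``z`` is the auxiliary (input) variable
    and ``g`` the conductance, with dz/dt = -z/tau and dg/dt = (z - g)/tau.
    A presynaptic spike adds ``Q * e`` to ``z``, which yields the alpha
    transient ``Q (t/tau) exp(1 - t/tau)`` on ``g``.
    """

    v_m: float
    i_adap: float = 0.0
    i_dep: float = 0.0
    g_e: float = 0.0
    z_e: float = 0.0
    g_i: float = 0.0
    z_i: float = 0.0
    t_last_spike: float = -np.inf


@dataclass
class SpikeRecord:
    """Event list of spikes: parallel arrays of times (ms) and neuron ids,
    plus a map from population name to the (lo, hi) id range it occupies."""

    times: np.ndarray
    ids: np.ndarray
    populations: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.times)

    def select(self, population: str) -> np.ndarray:
        """Spike times of one population (ms)."""
        lo, hi = self.populations[population]
        mask = (self.ids >= lo) & (self.ids < hi)
        return self.times[mask]

    def count(self, population: str | None = None) -> int:
        if population is None:
            return len(self.times)
        return len(self.select(population))


def eglif_derivatives(state: NeuronState, p: CellParams, i_syn: float,
                      printed_leak_sign: bool = False):
    """Right-hand sides (dV/dt, dI_adap/dt, dI_dep/dt) of the EGLIF equations.

    ``printed_leak_sign=True`` flips the leak term to the repulsive
    convention ``+(C_m/tau_m)(V - E_rev)``; that variant is unstable and is
    provided for inspection only.
    """
    if not (np.isfinite(state.v_m) and np.isfinite(state.i_adap)
            and np.isfinite(state.i_dep)):
        raise FloatingPointError("non-finite neuron state (integration blow-up)")
    leak = (p.c_m / p.tau_m) * (state.v_m - p.e_rev)
    if not printed_leak_sign:
        leak = -leak
    dv = (leak - state.i_adap + state.i_dep + p.i_e + i_syn) / p.c_m
    di_adap = p.k_adap * (state.v_m - p.e_rev) - p.k_2 * state.i_adap
    di_dep = -p.k_1 * state.i_dep
    return dv, di_adap, di_dep


def apply_spike_reset(state: NeuronState, p: CellParams,
                      t_spike: float = 0.0) -> NeuronState:
    """Post-spike update: V -> V_r, I_adap += A_2 (additive), I_dep = A_1."""
    return dataclasses.replace(
        state, v_m=p.v_r, i_adap=state.i_adap + p.a_2, i_dep=p.a_1,
        t_last_spike=t_spike,
    )


def alpha_kernel(t_since_spike, q: float, tau_syn: float):
    """Alpha-function conductance ``Q (t/tau) exp(1 - t/tau)`` (nS).

    Peaks at exactly ``q`` at ``t_since_spike == tau_syn``; superposition over
    spikes is additive.  Accepts scalars or arrays.
    """
    t = np.asarray(t_since_spike, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since_spike must be non-negative")
    out = q * (t / tau_syn) * np.exp(1.0 - t / tau_syn)
    return out if out.ndim else float(out)


def synaptic_current(v_m, g_e, g_i, syn: SynParams):
    """Conductance-based synaptic current G_e (E_e - V) + G_i (E_i - V) (pA)."""
    return g_e * (syn.e_e - v_m) + g_i * (syn.e_i - v_m)


def _events_to_step_counts(times, n_steps: int, dt: float) -> np.ndarray:
    """Bin event times (ms) into per-step delivery counts.

    An event in step ``k`` (i.e. t in [k dt, (k+1) dt)) is applied to the
    synaptic input at the start of step k, so its conductance effect begins
    within that step.
    """
    counts = np.zeros(n_steps, dtype=np.int64)
    if times is None or len(times) == 0:
        return counts
    steps = np.floor(np.asarray(times, dtype=float) / dt).astype(np.int64)
    steps = steps[(steps >= 0) & (steps < n_steps)]
    np.add.at(counts, steps, 1)
    return counts


def simulate_single_cell(p: CellParams, syn: SynParams,
                         exc_spike_times=None, inh_spike_times=None,
                         duration: float = 1000.0, dt: float = 0.1,
                         record: bool = True, threshold: bool = True,
                         init: NeuronState | None = None):
    """Fixed-step simulation of one EGLIF neuron under given input trains.

    Parameters
    ----------
    exc_spike_times, inh_spike_times
        Presynaptic event times (ms); excitatory events use ``q_pyr`` and
        inhibitory events ``q_fs``.
    threshold
        If False the spike mechanism is disabled (used for subthreshold
        moment measurements).

    Returns
    -------
    (SpikeRecord, traces) where traces is a dict of arrays over the time grid
    (t, v_m, i_adap, i_dep, g_e, g_i) when ``record`` else None.

    Notes
    -----
    V is advanced with explicit Euler; I_dep and the decay of I_adap use
    exact exponential propagators, so after a spike I_dep follows its closed
    form ``A_1 exp(-k_1 (t - t_spk))`` to machine precision.  A spike is
    emitted when V crosses V_th from below at the end of a step; the reset
    applies at the same step and starts the refractory clamp.
    """
    if dt <= 0 or duration <= 0:
        raise ValueError("dt and duration must be positive")
    n_steps = int(round(duration / dt))
    exc_counts = _events_to_step_counts(exc_spike_times, n_steps, dt)
    inh_counts = _events_to_step_counts(inh_spike_times, n_steps, dt)

    s = init if init is not None else NeuronState(v_m=p.e_rev)
    v, i_adap, i_dep = s.v_m, s.i_adap, s.i_dep
    g_e, z_e, g_i, z_i = s.g_e, s.z_e, s.g_i, s.z_i

    dec = math.exp(-dt / syn.tau_syn)
    r = dt / syn.tau_syn
    e_k1 = math.exp(-p.k_1 * dt)
    e_k2 = math.exp(-p.k_2 * dt)
    # exponential-Euler weight for the I_adap drive term
    w_adap = (1.0 - e_k2) / p.k_2 if p.k_2 > 0 else dt

    spike_times = []
    ref_until = -np.inf
    if record:
        tr = {k: np.empty(n_steps + 1) for k in
              ("t", "v_m", "i_adap", "i_dep", "g_e", "g_i")}
        for k, val in (("t", 0.0), ("v_m", v), ("i_adap", i_adap),
                       ("i_dep", i_dep), ("g_e", g_e), ("g_i", g_i)):
            tr[k][0] = val

    for k in range(n_steps):
        t_next = (k + 1) * dt
        # deliver this step's events, then propagate the synaptic state
        # exactly (the jump lands at the start of the step, so a spike at
        # t0 yields a kernel peaking exactly at t0 + tau_syn)
        if exc_counts[k]:
            z_e += exc_counts[k] * syn.q_pyr * ALPHA_JUMP
        if inh_counts[k]:
            z_i += inh_counts[k] * syn.q_fs * ALPHA_JUMP
        g_e, z_e = dec * (g_e + r * z_e), dec * z_e
        g_i, z_i = dec * (g_i + r * z_i), dec * z_i

        i_syn = g_e * (syn.e_e - v) + g_i * (syn.e_i - v)
        dv = (-p.g_l * (v - p.e_rev) - i_adap + i_dep + p.i_e + i_syn) / p.c_m
        drive = p.k_adap * (v - p.e_rev)
        i_adap = i_adap * e_k2 + drive * w_adap
        i_dep *= e_k1
        if t_next < ref_until:
            v = p.v_r
        else:
            v = v + dt * dv
        if not np.isfinite(v):
            raise FloatingPointError(
                f"membrane potential diverged at t = {t_next:.3f} ms")

        if threshold and v >= p.v_th and t_next >= ref_until:
            spike_times.append(t_next)
            v = p.v_r
            i_adap += p.a_2
            i_dep = p.a_1
            ref_until = t_next + p.t_ref

        if record:
            tr["t"][k + 1] = t_next
            tr["v_m"][k + 1] = v
            tr["i_adap"][k + 1] = i_adap
            tr["i_dep"][k + 1] = i_dep
            tr["g_e"][k + 1] = g_e
            tr["g_i"][k + 1] = g_i

    rec = SpikeRecord(times=np.asarray(spike_times, dtype=float),
                      ids=np.zeros(len(spike_times), dtype=np.int64),
                      populations={p.name: (0, 1)})
    return rec, (tr if record else None)
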