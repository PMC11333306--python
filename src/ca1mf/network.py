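"""CA1 microcircuit: topology, external CA3 drive, and network simulation.

The microcircuit consists of two populations of EGLIF neurons, pyramidal
cells (Pyr, excitatory, N = 5,000) and fast-spiking interneurons (FS,
inhibitory, N = 500), connected by independent Bernoulli draws with
probabilities p(Pyr->Pyr) = 0.01, p(FS->Pyr) = 0.3, p(Pyr->FS) = 0.2,
p(FS->FS) = 0.3.  External excitatory input from CA3 is modeled as 5,000
independent Poisson sources, each connecting to every Pyr (FS) cell with
probability 0.15 (0.3).

The network serves as the validation oracle for the mean-field model: its
population rates under constant and time-varying drives are what the
mean-field is checked against.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from . import _kernels
from .single_cell import (CellParams, SynParams, SpikeRecord,
                          PYR_PARAMS, FS_PARAMS, DEFAULT_SYN, ALPHA_JUMP)

__all__ = [
    "NetworkTopology", "ConnectivityGraph", "RateTrace",
    "build_network", "make_external_drive", "simulate_network",
    "population_rate", "stationary_rates",
]

POPULATIONS = ("pyr", "fs")


@dataclass(frozen=True)
class NetworkTopology:
    """Population sizes and pairwise Bernoulli connection probabilities."""

    n: dict = field(default_factory=lambda: {"pyr": 5000, "fs": 500})
    #: p[(src, dst)]: probability that a given src neuron contacts a given dst
    p: dict = field(default_factory=lambda: {
        ("pyr", "pyr"): 0.01, ("fs", "pyr"): 0.3,
        ("pyr", "fs"): 0.2, ("fs", "fs"): 0.3,
    })
    n_ext: int = 5000
    p_ext: dict = field(default_factory=lambda: {"pyr": 0.15, "fs": 0.3})

    def __post_init__(self) -> None:
        for pop, n in self.n.items():
            if n <= 0:
                raise ValueError(f"population size {pop} must be positive")
        for key, prob in list(self.p.items()) + list(self.p_ext.items()):
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"connection probability {key} = {prob} "
                                 "outside [0, 1]")
        if self.n_ext <= 0:
            raise ValueError("n_ext must be positive")

    def convergence(self, src: str, dst: str) -> float:
        """Mean synaptic convergence K = p * N_src (src may be 'ext')."""
        if src == "ext":
            return self.p_ext[dst] * self.n_ext
        return self.p[(src, dst)] * self.n[src]

    def scaled(self, factor: float) -> "NetworkTopology":
        """Topology with all population sizes scaled by ``factor`` (sizes
        rounded); connection probabilities are left untouched, so the
        convergences scale with the network."""
        n = {k: max(1, int(round(v * factor))) for k, v in self.n.items()}
        return dataclasses.replace(self, n=n,
                                   n_ext=max(1, int(round(self.n_ext * factor))))


@dataclass
class ConnectivityGraph:
    """One realized Bernoulli network: recurrent and external adjacency in
    CSR-by-source form over the combined neuron indexing (Pyr block first,
    then FS)."""

    topology: NetworkTopology
    seed: int
    indptr: np.ndarray
    indices: np.ndarray
    ext_indptr: np.ndarray
    ext_indices: np.ndarray
    populations: dict          # pop -> (lo, hi) id range
    is_inh: np.ndarray         # per-neuron inhibitory-source flag

    @property
    def n_total(self) -> int:
        return len(self.is_inh)

    def out_degree(self, neuron: int) -> int:
        return int(self.indptr[neuron + 1] - self.indptr[neuron])

    def in_degrees(self, src_pop: str, dst_pop: str) -> np.ndarray:
        """Realized in-degree of every dst_pop neuron from src_pop sources."""
        s_lo, s_hi = self.populations[src_pop]
        d_lo, d_hi = self.populations[dst_pop]
        deg = np.zeros(d_hi - d_lo, dtype=np.int64)
        for s in range(s_lo, s_hi):
            t = self.indices[self.indptr[s]:self.indptr[s + 1]]
            t = t[(t >= d_lo) & (t < d_hi)]
            np.add.at(deg, t - d_lo, 1)
        return deg

    def ext_in_degrees(self, dst_pop: str) -> np.ndarray:
        d_lo, d_hi = self.populations[dst_pop]
        deg = np.zeros(d_hi - d_lo, dtype=np.int64)
        for s in range(self.topology.n_ext):
            t = self.ext_indices[self.ext_indptr[s]:self.ext_indptr[s + 1]]
            t = t[(t >= d_lo) & (t < d_hi)]
            np.add.at(deg, t - d_lo, 1)
        return deg


@dataclass
class RateTrace:
    """Binned per-population instantaneous firing rate (Hz)."""

    time: np.ndarray           # bin centers (ms)
    rates: dict                # pop -> rate array (Hz)
    bin_ms: float
    smooth_ms: float = 0.0
    raw_counts: dict = field(default_factory=dict)   # pre-smoothing counts

    def mean_rate(self, pop: str, t_min: float = 0.0,
                  t_max: float = np.inf) -> float:
        mask = (self.time >= t_min) & (self.time <= t_max)
        return float(np.mean(self.rates[pop][mask]))


def _bernoulli_rows(rng, n_src, d_lo, d_hi, p, self_offset=None):
    """Target lists for n_src sources onto the id range [d_lo, d_hi)."""
    rows = []
    n_dst = d_hi - d_lo
    for s in range(n_src):
        hit = np.nonzero(rng.random(n_dst) < p)[0] + d_lo
        if self_offset is not None:
            hit = hit[hit != s + self_offset]
        rows.append(hit)
    return rows


def build_network(top: NetworkTopology, seed: int = 0) -> ConnectivityGraph:
    """Realize the Bernoulli connectivity (recurrent + external fan-out).

    Each ordered neuron pair (i, j), i != j, is connected independently with
    the probability of its population pair; external sources connect to each
    target neuron with the per-population external probability.  Fully
    reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    offsets, lo = {}, 0
    for pop in POPULATIONS:
        offsets[pop] = (lo, lo + top.n[pop])
        lo += top.n[pop]
    n_total = lo

    row_targets = [[] for _ in range(n_total)]
    for src in POPULATIONS:
        s_lo, s_hi = offsets[src]
        for dst in POPULATIONS:
            d_lo, d_hi = offsets[dst]
            p = top.p[(src, dst)]
            if p == 0.0:
                continue
            rows = _bernoulli_rows(rng, s_hi - s_lo, d_lo, d_hi, p,
                                   self_offset=s_lo if src == dst else None)
            for i, hit in enumerate(rows):
                row_targets[s_lo + i].append(hit)

    indptr = np.zeros(n_total + 1, dtype=np.int64)
    chunks = []
    for i, parts in enumerate(row_targets):
        row = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
        indptr[i + 1] = indptr[i] + len(row)
        chunks.append(row)
    indices = (np.concatenate(chunks) if chunks
               else np.empty(0, dtype=np.int64))

    ext_rows = []
    for dst in POPULATIONS:
        d_lo, d_hi = offsets[dst]
        ext_rows.append(_bernoulli_rows(rng, top.n_ext, d_lo, d_hi,
                                        top.p_ext[dst]))
    ext_indptr = np.zeros(top.n_ext + 1, dtype=np.int64)
    ext_chunks = []
    for s in range(top.n_ext):
        row = np.concatenate([ext_rows[0][s], ext_rows[1][s]])
        ext_indptr[s + 1] = ext_indptr[s] + len(row)
        ext_chunks.append(row)
    ext_indices = (np.concatenate(ext_chunks) if ext_chunks
                   else np.empty(0, dtype=np.int64))

    is_inh = np.zeros(n_total, dtype=np.bool_)
    f_lo, f_hi = offsets["fs"]
    is_inh[f_lo:f_hi] = True
    return ConnectivityGraph(topology=top, seed=seed, indptr=indptr,
                             indices=indices, ext_indptr=ext_indptr,
                             ext_indices=ext_indices, populations=offsets,
                             is_inh=is_inh)


def make_external_drive(rate_fn, n_ext: int, p_ext: float, n_targets: int,
                        duration: float, seed: int = 0, dt: float = 0.1):
    """Explicit per-target external event lists (reference construction).

    ``n_ext`` independent (inhomogeneous) Poisson sources with rate
    ``rate_fn(t)`` (Hz) each connect to each of ``n_targets`` neurons with
    probability ``p_ext``; a target's event list is the union of its
    connected sources' spike trains.  Statistically this uses the marking
    construction: merged events of total rate ``n_ext * rate_fn`` are tagged
    with uniform source ids.

    Intended for small problems and tests; the network simulator generates
    the same construction on the fly.
    """
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / dt))
    t_grid = (np.arange(n_steps) + 0.5) * dt
    lam = np.asarray([rate_fn(t) for t in t_grid], dtype=float) / 1000.0
    if np.any(lam < 0):
        raise ValueError("external drive rate must be non-negative")
    counts = rng.poisson(n_ext * lam * dt)
    times = np.repeat(t_grid, counts)
    sources = rng.integers(0, n_ext, size=len(times))

    fanout = [np.nonzero(rng.random(n_targets) < p_ext)[0]
              for _ in range(n_ext)]
    events = [[] for _ in range(n_targets)]
    for t, s in zip(times, sources):
        for tgt in fanout[s]:
            events[tgt].append(t)
    return [np.asarray(ev) for ev in events]


def _cell_arrays(graph: ConnectivityGraph, cells: dict):
    n_total = graph.n_total
    arrs = {k: np.empty(n_total) for k in
            ("cm", "gl", "erev", "kadap", "k1", "k2", "a1", "a2",
             "ie", "vr", "vth", "tref")}
    for pop, (lo, hi) in graph.populations.items():
        c: CellParams = cells[pop]
        vals = dict(cm=c.c_m, gl=c.g_l, erev=c.e_rev, kadap=c.k_adap,
                    k1=c.k_1, k2=c.k_2, a1=c.a_1, a2=c.a_2, ie=c.i_e,
                    vr=c.v_r, vth=c.v_th, tref=c.t_ref)
        for k, v in vals.items():
            arrs[k][lo:hi] = v
    return arrs


def simulate_network(graph: ConnectivityGraph, drive, duration: float,
                     dt: float = 0.1, seed: int = 0,
                     cells: dict | None = None,
                     syn: SynParams = DEFAULT_SYN,
                     ext_mode: str = "sources",
                     max_rate_cap: float = 500.0) -> SpikeRecord:
    """Simulate the microcircuit under an external Poisson drive.

    Parameters
    ----------
    drive : callable t (ms) -> rate (Hz), or a constant (Hz)
        Common rate of the external CA3 sources.
    ext_mode : 'sources' (exact independent-source realization through the
        realized fan-out) or 'merged' (approximate: independent per-target
        Poisson counts with the mean convergence; faster, no shared-source
        correlations).
    max_rate_cap : spike-buffer sizing assumption (Hz per neuron); exceeding
        it raises.
    """
    if cells is None:
        cells = {"pyr": PYR_PARAMS, "fs": FS_PARAMS}
    if ext_mode not in ("sources", "merged"):
        raise ValueError("ext_mode must be 'sources' or 'merged'")
    rate_fn = drive if callable(drive) else (lambda t, r=float(drive): r)
    n_steps = int(round(duration / dt))
    t_grid = (np.arange(n_steps) + 0.5) * dt
    ext_nu = np.asarray([rate_fn(t) for t in t_grid], dtype=float) / 1000.0
    if np.any(ext_nu < 0):
        raise ValueError("external drive rate must be non-negative")

    arrs = _cell_arrays(graph, cells)
    top = graph.topology
    ext_k_target = np.zeros(graph.n_total)
    for pop, (lo, hi) in graph.populations.items():
        ext_k_target[lo:hi] = top.p_ext[pop] * top.n_ext
    q_src = np.where(graph.is_inh, syn.q_fs, syn.q_pyr)

    max_spikes = int(graph.n_total * duration / 1000.0 * max_rate_cap) + 1000
    spike_t, spike_id, err, err_t, err_i = _kernels.run_network(
        n_steps, dt, _as_kernel_seed(seed),
        arrs["cm"], arrs["gl"], arrs["erev"], arrs["kadap"], arrs["k1"],
        arrs["k2"], arrs["a1"], arrs["a2"], arrs["ie"], arrs["vr"],
        arrs["vth"], arrs["tref"],
        syn.tau_syn, syn.e_e, syn.e_i,
        q_src, graph.is_inh, graph.indptr, graph.indices,
        top.n_ext, graph.ext_indptr, graph.ext_indices, syn.q_pyr, ext_nu,
        0 if ext_mode == "sources" else 1, ext_k_target,
        max_spikes)
    if err == 1:
        raise FloatingPointError(
            f"neuron {err_i} diverged at t = {err_t:.2f} ms")
    if err == 2:
        raise RuntimeError(
            f"spike buffer overflow at t = {err_t:.2f} ms "
            f"(population rate exceeded {max_rate_cap} Hz)")
    return SpikeRecord(times=spike_t, ids=spike_id,
                       populations=dict(graph.populations))


def _as_kernel_seed(seed) -> int:
    """Map an arbitrary seed to the 32-bit range accepted by the kernels."""
    return int(np.random.SeedSequence(seed).generate_state(1)[0] % (2 ** 31))


def population_rate(spikes: SpikeRecord, bin_ms: float, smooth_ms: float = 0.0,
                    duration: float | None = None) -> RateTrace:
    """Instantaneous population rates: counts / (N * bin), with optional
    Gaussian smoothing.  Before smoothing the trace conserves the spike
    count: sum(rate * N * bin) = total spikes of that population."""
    if bin_ms <= 0:
        raise ValueError("bin width must be positive")
    if duration is None:
        duration = float(spikes.times.max()) if len(spikes) else bin_ms
    n_bins = max(1, int(np.ceil(duration / bin_ms)))
    edges = np.arange(n_bins + 1) * bin_ms
    centers = 0.5 * (edges[:-1] + edges[1:])
    rates, raw = {}, {}
    for pop, (lo, hi) in spikes.populations.items():
        n_pop = hi - lo
        counts, _ = np.histogram(spikes.select(pop), bins=edges)
        raw[pop] = counts
        rate = counts / (n_pop * bin_ms / 1000.0)
        if smooth_ms > 0:
            rate = gaussian_filter1d(rate, smooth_ms / bin_ms, mode="nearest")
        rates[pop] = rate
    return RateTrace(time=centers, rates=rates, bin_ms=bin_ms,
                     smooth_ms=smooth_ms, raw_counts=raw)


def stationary_rates(spikes: SpikeRecord, duration: float,
                     transient_ms: float = 1000.0) -> dict:
    """Time-averaged population rates (Hz) after a transient discard.

    The default 1,000 ms discard accounts for the slow intrinsic timescales
    of the EGLIF cells (adaptation and leak)."""
    out = {}
    for pop, (lo, hi) in spikes.populations.items():
        t = spikes.select(pop)
        n_sp = np.count_nonzero(t >= transient_ms)
        out[pop] = n_sp / ((hi - lo) * (duration - transient_ms) / 1000.0)
    return out
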