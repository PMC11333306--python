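"""Numba inner loops for the spiking simulations.

Two fixed-step integrators share the neuron update of
:mod:`ca1mf.single_cell` (explicit Euler on V, exact exponential propagators
for I_dep, the I_adap decay and the two-variable alpha synapse):

* :func:`poisson_neurons` - a bank of uncoupled EGLIF neurons, each driven by
  merged excitatory/inhibitory Poisson event streams.  Used to estimate
  numerical transfer functions and subthreshold voltage moments.
* :func:`run_network` - the recurrent Pyr/FS microcircuit with an external
  population of independent Poisson sources and Bernoulli fan-out.

External drive in ``run_network``: the union of ``n_ext`` independent Poisson
sources of common rate nu(t) is realized by drawing the merged event count
Poisson(n_ext nu dt) per step and tagging each event with a uniformly random
source id (marking theorem), then delivering along that source's fixed target
list.  This is statistically exact for the source construction while keeping
the per-step cost proportional to the event count.

Error signalling: the kernels return ``(err_flag, err_time, err_index)``
with flag 0 = ok, 1 = non-finite membrane potential, 2 = spike buffer
overflow; the Python wrappers convert these to exceptions.
"""

import numpy as np
from numba import njit

#: jump applied to the alpha-synapse auxiliary variable per event (peak = Q)
_E = np.e


@njit(cache=True)
def poisson_neurons(n_steps, dt, seed,
                    cm, gl, erev, kadap, k1, k2, a1, a2, ie, vr, vth, tref,
                    tau_syn, ee, ei, q_e, q_i,
                    rate_e, rate_i, mod_e,
                    use_threshold, stats_from):
    """Simulate ``n`` independent EGLIF neurons under Poisson bombardment.

    rate_e, rate_i : per-neuron merged event rates (events per ms).
    mod_e : per-step multiplicative modulation of the excitatory rate.
    stats_from : step index from which spike counts and voltage statistics
        are accumulated (transient discard).

    Returns (counts, v_sum, v_sumsq, n_samples, err_flag, err_time, err_idx).
    """
    np.random.seed(seed)
    n = cm.shape[0]
    v = erev.copy()
    i_adap = np.zeros(n)
    i_dep = np.zeros(n)
    g_e = np.zeros(n)
    z_e = np.zeros(n)
    g_i = np.zeros(n)
    z_i = np.zeros(n)
    ref_until = np.full(n, -1e30)

    dec = np.exp(-dt / tau_syn)
    r = dt / tau_syn
    e_k1 = np.exp(-k1 * dt)
    e_k2 = np.exp(-k2 * dt)
    w_adap = np.empty(n)
    for i in range(n):
        w_adap[i] = (1.0 - e_k2[i]) / k2[i] if k2[i] > 0 else dt

    counts = np.zeros(n, np.int64)
    v_sum = np.zeros(n)
    v_sq = np.zeros(n)
    n_samples = 0

    for k in range(n_steps):
        t_next = (k + 1) * dt
        m = mod_e[k]
        if k >= stats_from:
            n_samples += 1
        for i in range(n):
            # deliver events first so the kernel onset is this step's start
            lam_e = rate_e[i] * dt * m
            if lam_e > 0.0:
                ne = np.random.poisson(lam_e)
                if ne > 0:
                    z_e[i] += ne * q_e * _E
            lam_i = rate_i[i] * dt
            if lam_i > 0.0:
                ni = np.random.poisson(lam_i)
                if ni > 0:
                    z_i[i] += ni * q_i * _E
            g_e[i] = dec * (g_e[i] + r * z_e[i])
            z_e[i] = dec * z_e[i]
            g_i[i] = dec * (g_i[i] + r * z_i[i])
            z_i[i] = dec * z_i[i]

            i_syn = g_e[i] * (ee - v[i]) + g_i[i] * (ei - v[i])
            dv = (-gl[i] * (v[i] - erev[i]) - i_adap[i] + i_dep[i]
                  + ie[i] + i_syn) / cm[i]
            i_adap[i] = i_adap[i] * e_k2[i] + kadap[i] * (v[i] - erev[i]) * w_adap[i]
            i_dep[i] *= e_k1[i]
            if t_next < ref_until[i]:
                v[i] = vr[i]
            else:
                v[i] += dt * dv
            if not np.isfinite(v[i]):
                return counts, v_sum, v_sq, n_samples, 1, t_next, i
            if use_threshold and v[i] >= vth[i] and t_next >= ref_until[i]:
                v[i] = vr[i]
                i_adap[i] += a2[i]
                i_dep[i] = a1[i]
                ref_until[i] = t_next + tref[i]
                if k >= stats_from:
                    counts[i] += 1
            if k >= stats_from:
                v_sum[i] += v[i]
                v_sq[i] += v[i] * v[i]
    return counts, v_sum, v_sq, n_samples, 0, 0.0, -1


@njit(cache=True)
def run_network(n_steps, dt, seed,
                cm, gl, erev, kadap, k1, k2, a1, a2, ie, vr, vth, tref,
                tau_syn, ee, ei,
                q_src, is_inh_src, indptr, indices,
                n_ext, ext_indptr, ext_indices, q_ext, ext_nu,
                ext_mode, ext_k_target,
                max_spikes):
    """Recurrent EGLIF network with external Poisson drive.

    q_src, is_inh_src : per-neuron presynaptic quantal conductance and
        inhibitory flag (conductance type is set by the source).
    indptr, indices : recurrent adjacency, CSR by source neuron.
    ext_nu : per-step external source rate (events per ms per source).
    ext_mode : 0 = exact independent-source realization via the external
        CSR fan-out; 1 = merged approximation with independent per-target
        Poisson counts of mean ``ext_k_target[i] * ext_nu[k] * dt``.

    Spikes detected in step k are delivered to their targets in step k+1
    (zero synaptic delay at the dt resolution).
    """
    np.random.seed(seed)
    n = cm.shape[0]
    v = erev.copy()
    i_adap = np.zeros(n)
    i_dep = np.zeros(n)
    g_e = np.zeros(n)
    z_e = np.zeros(n)
    g_i = np.zeros(n)
    z_i = np.zeros(n)
    ref_until = np.full(n, -1e30)

    dec = np.exp(-dt / tau_syn)
    r = dt / tau_syn
    e_k1 = np.exp(-k1 * dt)
    e_k2 = np.exp(-k2 * dt)
    w_adap = np.empty(n)
    for i in range(n):
        w_adap[i] = (1.0 - e_k2[i]) / k2[i] if k2[i] > 0 else dt

    spike_t = np.empty(max_spikes)
    spike_id = np.empty(max_spikes, np.int64)
    n_sp = 0
    prev = np.empty(n, np.int64)
    cur = np.empty(n, np.int64)
    n_prev = 0

    for k in range(n_steps):
        t_next = (k + 1) * dt

        # external drive (delivered before synaptic propagation)
        if ext_nu[k] > 0.0:
            if ext_mode == 0:
                n_ev = np.random.poisson(n_ext * ext_nu[k] * dt)
                for _ in range(n_ev):
                    s = np.random.randint(0, n_ext)
                    for jj in range(ext_indptr[s], ext_indptr[s + 1]):
                        z_e[ext_indices[jj]] += q_ext * _E
            else:
                for i in range(n):
                    lam = ext_k_target[i] * ext_nu[k] * dt
                    if lam > 0.0:
                        ne = np.random.poisson(lam)
                        if ne > 0:
                            z_e[i] += ne * q_ext * _E

        # recurrent delivery of last step's spikes
        for idx in range(n_prev):
            s = prev[idx]
            q = q_src[s] * _E
            if is_inh_src[s]:
                for jj in range(indptr[s], indptr[s + 1]):
                    z_i[indices[jj]] += q
            else:
                for jj in range(indptr[s], indptr[s + 1]):
                    z_e[indices[jj]] += q

        for i in range(n):
            g_e[i] = dec * (g_e[i] + r * z_e[i])
            z_e[i] = dec * z_e[i]
            g_i[i] = dec * (g_i[i] + r * z_i[i])
            z_i[i] = dec * z_i[i]

        n_cur = 0
        for i in range(n):
            i_syn = g_e[i] * (ee - v[i]) + g_i[i] * (ei - v[i])
            dv = (-gl[i] * (v[i] - erev[i]) - i_adap[i] + i_dep[i]
                  + ie[i] + i_syn) / cm[i]
            i_adap[i] = i_adap[i] * e_k2[i] + kadap[i] * (v[i] - erev[i]) * w_adap[i]
            i_dep[i] *= e_k1[i]
            if t_next < ref_until[i]:
                v[i] = vr[i]
            else:
                v[i] += dt * dv
            if not np.isfinite(v[i]):
                return spike_t[:n_sp], spike_id[:n_sp], 1, t_next, i
            if v[i] >= vth[i] and t_next >= ref_until[i]:
                v[i] = vr[i]
                i_adap[i] += a2[i]
                i_dep[i] = a1[i]
                ref_until[i] = t_next + tref[i]
                if n_sp >= max_spikes:
                    return spike_t[:n_sp], spike_id[:n_sp], 2, t_next, i
                spike_t[n_sp] = t_next
                spike_id[n_sp] = i
                n_sp += 1
                cur[n_cur] = i
                n_cur += 1
        prev, cur = cur, prev
        n_prev = n_cur

    return spike_t[:n_sp], spike_id[:n_sp], 0, 0.0, -1
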