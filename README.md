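# ca1mf — multiscale modeling of hippocampal CA1

`ca1mf` builds a population model of the hippocampal CA1 microcircuit
bottom-up, for computational neuroscientists who need CA1 dynamics at a
cost far below single-cell network simulation:

1. **Single cell** — EGLIF neurons (leaky integrate-and-fire with a slow
   adaptation current and a fast post-spike depolarizing current) with
   conductance-based alpha synapses, for CA1 pyramidal cells (Pyr) and
   fast-spiking interneurons (FS).
2. **Microcircuit** — a spiking network of 5,000 Pyr + 500 FS with
   Bernoulli connectivity and external CA3 Poisson drive; the ground
   truth the mean-field is validated against.
3. **Mean field** — a second-order moment closure over the two
   populations, built on semi-analytic transfer functions fitted to
   single-cell simulations.
4. **Macroscale** — a 1.5 x 1.5 mm slice tiled into 100 um mean-field
   compartments coupled through geometric axonal/dendritic overlap,
   reproducing the transversally directed (CA3 -> subiculum) propagation
   seen in disinhibited CA1 slices.

## The model in brief

Each cell type's stationary rate under Poisson input with rates
`(nu_e, nu_i)` and convergences `K` is written as

    F = 1 / (2 tau_V) * erfc( (V_eff - mu_V) / (sqrt(2) sigma_V) )

where `mu_V`, `sigma_V`, `tau_V` are closed-form shot-noise moments of the
membrane potential and the effective threshold `V_eff` is a fitted linear
expansion in `(mu_V, sigma_V, tau_V^N)` plus a `ln(mu_G/g_L)` term. The
population dynamics follow the master-equation moment expansion

    T dnu_mu/dt = (F_mu - nu_mu) + 1/2 c_le d2F_mu/dnu_l dnu_e
    T dc_le/dt  = delta_le F_l (1/T - F_e)/N_l + (F_l - nu_l)(F_e - nu_e)
                  + dF_l/dnu_m c_em + dF_e/dnu_m c_lm - 2 c_le

with `T = 5 ms`. Synaptic plasticity of the CA3 afferents is emulated by
the weight `W_e` (percent of baseline CA3->Pyr convergence). See
`docs/methods.md` for assumptions, calibration choices and limitations.

## Worked example

Fit the transfer functions, build the mean-field, and compare it against
the spiking network at a constant 5 Hz CA3 drive (a one-fifth circuit,
1,000 Pyr + 100 FS, keeps this at laptop scale — about half a minute):

```python
import ca1mf

top = ca1mf.reduced_topology()            # 1,000 Pyr + 100 FS, K = p N
cells = {"pyr": ca1mf.PYR_PARAMS, "fs": ca1mf.FS_PARAMS}

model = ca1mf.build_validated_model(top, cells, seeds=(10, 11))
graph = ca1mf.build_network(top, seed=5)

res = ca1mf.compare_constant_drive(model, graph, nu_ext=5.0, cells=cells,
                                   seed=21)
for pop in ("pyr", "fs"):
    print(f"{pop}: SNN {res.snn[pop]:6.2f} Hz | "
          f"MF {res.mf_first_order[pop]:6.2f} Hz "
          f"(2nd order {res.mf_second_order[pop]:6.2f}) | rel. err. "
          f"{100 * res.relative_error(pop):.1f}%")
```

prints

```
pyr: SNN   1.97 Hz | MF   2.20 Hz (2nd order   2.36) | rel. err. 11.7%
fs: SNN  11.91 Hz | MF  12.38 Hz (2nd order  12.54) | rel. err. 4.0%
```

i.e. the fitted mean-field reproduces the network's stationary pyramidal
and interneuron rates to within ~12% and ~4% here; the second-order
column adds the finite-size covariance correction, which slightly inflates
the low pyramidal rate (see the methods note for why).

A slice propagation experiment in three lines:

```python
coeffs = ca1mf.fit_slice_tf(ca1mf.NetworkTopology(), cells, seed=20)
movie, times, summary, grid, stim = ca1mf.slice_experiment(coeffs, cells)
print(summary.anisotropy_index)           # ~11: transversal-dominant
```

## Command line

`ca1mf` installs a CLI with subcommands `fit-tf`, `run-snn`, `run-mf`,
`compare-mf-snn`, `run-slice` and `make-fixtures`; every run writes its
outputs (spike text files, rate CSVs, movie arrays) together with a JSON
manifest holding the fully resolved configuration, seeds and output
checksums. Example configurations live in `configs/`.

```
ca1mf run-snn --config configs/reduced_microcircuit.yaml --seed 1 --out out/
```

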