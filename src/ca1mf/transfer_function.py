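"""Semi-analytic neuronal transfer functions for the mean-field model.

A population transfer function F(nu_e, nu_i) maps stationary excitatory and
inhibitory presynaptic rates onto the stationary output rate of one neuron.
Following the effective-threshold formalism, the rate is written as

    F = 1/(2 tau_V) * erfc( (V_eff - mu_V) / (sqrt(2) sigma_V) ),

where mu_V, sigma_V and tau_V are the mean, standard deviation and
autocorrelation decay time of the subthreshold membrane potential under
Poisson bombardment, computed in closed form from the cell, synapse and
convergence parameters (Campbell-theorem shot-noise moments of the alpha
conductance kernels).  The effective threshold V_eff is a phenomenological
linear expansion in the normalized moments plus a conductance term,

    V_eff = P_0 + sum_x P_x (x - x0)/dx0 + P_muG ln(mu_G / g_L),
    x in {mu_V, sigma_V, tau_V^N},    tau_V^N = tau_V g_L / C_m,

whose coefficients are fitted per cell type against a numerical transfer
function measured from single-cell spiking simulations.

Conventions
-----------
* The alpha kernel's time integral contributes a factor e
  (int Q (t/tau) e^(1-t/tau) dt = e Q tau), applied uniformly:
  mu_Gj = e Q_j tau_j nu_j K_j, and the voltage-jump factors enter as e U_j.
* Excitatory sources with identical (Q, tau, E) pool exactly: all moment
  sums are linear in the product K_j nu_j.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import erfc, erfcinv

from . import _kernels
from .network import _as_kernel_seed
from .single_cell import CellParams, SynParams, DEFAULT_SYN

__all__ = [
    "SubthresholdMoments", "TFSamples", "TFCoefficients",
    "subthreshold_moments", "moments_from_sources",
    "numerical_tf", "invert_tf", "effective_threshold",
    "fit_effective_threshold", "semi_analytic_tf", "tf_from_moments",
    "DEFAULT_NU_E_GRID", "DEFAULT_NU_I_GRID",
]

_E = math.e

# Default input-rate grids for numerical TF estimation (Hz, log-spaced).
DEFAULT_NU_E_GRID = np.geomspace(0.5, 30.0, 12)
DEFAULT_NU_I_GRID = np.geomspace(0.5, 20.0, 8)

# Default normalization constants of the effective-threshold expansion.
DEFAULT_NORMS = dict(mu_v0=-60.0, dmu_v0=10.0, sigma_v0=4.0, dsigma_v0=6.0,
                     tau_n0=0.5, dtau_n0=1.0)


@dataclass
class SubthresholdMoments:
    """Stationary subthreshold voltage statistics (array-valued fields
    broadcast over input-rate grids)."""

    mu_g: np.ndarray        # total mean conductance incl. leak (nS)
    mu_v: np.ndarray        # mean membrane potential (mV)
    sigma_v: np.ndarray     # SD of membrane potential (mV)
    tau_v: np.ndarray       # autocorrelation decay time (ms)
    tau_m_eff: np.ndarray   # effective membrane time C_m / mu_G (ms)
    mu_gj: list = field(default_factory=list)   # per-source mean conductance
    u_j: list = field(default_factory=list)     # per-source voltage jump (mV)
    degenerate: np.ndarray = None  # True where all input rates vanish


def moments_from_sources(sources, cell: CellParams) -> SubthresholdMoments:
    """Subthreshold moments for an arbitrary list of Poisson input sources.

    ``sources`` is an iterable of tuples ``(K, nu_Hz, Q, tau_syn, E_syn)``;
    ``nu_Hz`` entries may be numpy arrays (broadcast together).
    """
    gl = cell.g_l
    mu_gj, prepped = [], []
    for k, nu_hz, q, tau, e_syn in sources:
        if np.any(np.asarray(k) < 0) or np.any(np.asarray(nu_hz) < 0):
            raise ValueError("convergences and rates must be non-negative")
        nu = np.asarray(nu_hz, dtype=float) * 1e-3  # events per ms
        g = _E * q * tau * nu * k
        mu_gj.append(g)
        prepped.append((k, nu, q, tau, e_syn, g))

    mu_g = gl + sum(mu_gj)
    mu_v = (sum(g * e_syn for *_, e_syn, g in prepped)
            + gl * cell.e_rev) / mu_g
    tau_m_eff = cell.c_m / mu_g

    u_j, s2, num = [], 0.0, 0.0
    for k, nu, q, tau, e_syn, g in prepped:
        u = (q / mu_g) * (e_syn - mu_v)
        u_j.append(u)
        s2 = s2 + k * nu * (2 * tau_m_eff + tau) * (
            (_E * u * tau) / (2 * (tau_m_eff + tau))) ** 2
        num = num + k * nu * (_E * u * tau) ** 2
    s2 = np.asarray(s2, dtype=float)
    degenerate = s2 <= 0
    sigma_v = np.sqrt(np.maximum(s2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tau_v = np.where(degenerate, tau_m_eff, num / (2 * s2))
    return SubthresholdMoments(
        mu_g=np.asarray(mu_g, dtype=float), mu_v=np.asarray(mu_v, dtype=float),
        sigma_v=sigma_v, tau_v=np.asarray(tau_v, dtype=float),
        tau_m_eff=np.asarray(tau_m_eff, dtype=float),
        mu_gj=mu_gj, u_j=u_j, degenerate=degenerate)


def subthreshold_moments(nu_e, nu_i, k_e, k_i, cell: CellParams,
                         syn: SynParams = DEFAULT_SYN) -> SubthresholdMoments:
    """Moments under one excitatory and one inhibitory Poisson population."""
    return moments_from_sources(
        [(k_e, nu_e, syn.q_pyr, syn.tau_syn, syn.e_e),
         (k_i, nu_i, syn.q_fs, syn.tau_syn, syn.e_i)], cell)


@dataclass
class TFSamples:
    """Numerical transfer-function measurements on an input-rate grid."""

    nu_e: np.ndarray       # excitatory input rate (Hz)
    nu_i: np.ndarray       # inhibitory input rate (Hz)
    rate: np.ndarray       # measured output rate (Hz)
    k_e: float
    k_i: float
    duration: float        # measurement window per point (ms)
    seed: int = 0
    cell_name: str = ""

    def __len__(self) -> int:
        return len(self.rate)


def balanced_tf_points(nu_e_grid, ratios):
    """Explicit (nu_e, nu_i) sample list with inhibition scaled to
    excitation.

    In a recurrently balanced circuit the operating points lie along rays
    nu_i ~ r nu_e rather than on a rectangle; sampling along such rays keeps
    the cell fluctuation-driven (where the erfc transfer function is valid)
    while covering the rate range the mean-field visits.
    """
    nu_e_grid = np.asarray(nu_e_grid, dtype=float)
    ratios = np.asarray(ratios, dtype=float)
    ne = np.repeat(nu_e_grid, len(ratios))
    ni = (nu_e_grid[:, None] * ratios[None, :]).ravel()
    return ne, ni


def numerical_tf(cell: CellParams, syn: SynParams, k_e: float, k_i: float,
                 nu_e_grid=None, nu_i_grid=None, duration: float = 20000.0,
                 seed: int = 0, dt: float = 0.1, transient: float = 1000.0,
                 points=None, replicas: int = 1) -> TFSamples:
    """Measure the numerical transfer function from single-cell simulations.

    Every sample point drives one EGLIF neuron with stationary merged
    Poisson excitation of rate ``k_e * nu_e`` and inhibition ``k_i * nu_i``
    (the sum of K independent Poisson afferents at rate nu is itself
    Poisson); the output rate is the spike count over ``duration`` after a
    transient.  All points are integrated simultaneously as a bank of
    uncoupled neurons.

    Points are either the rectangular product of ``nu_e_grid`` x
    ``nu_i_grid`` or an explicit list ``points=(nu_e, nu_i)`` (e.g. from
    :func:`balanced_tf_points`).  ``replicas`` runs several independent
    neurons per point and averages their counts, reducing the counting
    noise of low-rate samples.
    """
    if points is not None:
        ne = np.asarray(points[0], dtype=float)
        ni = np.asarray(points[1], dtype=float)
    else:
        nu_e_grid = (DEFAULT_NU_E_GRID if nu_e_grid is None
                     else np.asarray(nu_e_grid, float))
        nu_i_grid = (DEFAULT_NU_I_GRID if nu_i_grid is None
                     else np.asarray(nu_i_grid, float))
        ne, ni = np.meshgrid(nu_e_grid, nu_i_grid, indexing="ij")
        ne, ni = ne.ravel(), ni.ravel()
    if np.any(ne < 0) or np.any(ni < 0):
        raise ValueError("input rates must be non-negative")
    n_pts = len(ne)
    ne = np.tile(ne, replicas)
    ni = np.tile(ni, replicas)
    n = len(ne)

    ones = np.ones(n)
    arrs = dict(cm=cell.c_m * ones, gl=cell.g_l * ones, erev=cell.e_rev * ones,
                kadap=cell.k_adap * ones, k1=cell.k_1 * ones,
                k2=cell.k_2 * ones, a1=cell.a_1 * ones, a2=cell.a_2 * ones,
                ie=cell.i_e * ones, vr=cell.v_r * ones, vth=cell.v_th * ones,
                tref=cell.t_ref * ones)
    n_steps = int(round((duration + transient) / dt))
    stats_from = int(round(transient / dt))
    counts, _, _, _, err, err_t, err_i = _kernels.poisson_neurons(
        n_steps, dt, _as_kernel_seed(seed),
        arrs["cm"], arrs["gl"], arrs["erev"], arrs["kadap"], arrs["k1"],
        arrs["k2"], arrs["a1"], arrs["a2"], arrs["ie"], arrs["vr"],
        arrs["vth"], arrs["tref"],
        syn.tau_syn, syn.e_e, syn.e_i, syn.q_pyr, syn.q_fs,
        k_e * ne / 1000.0, k_i * ni / 1000.0, np.ones(n_steps),
        True, stats_from)
    if err:
        raise FloatingPointError(
            f"grid neuron {err_i} diverged at t = {err_t:.2f} ms")
    counts = counts.reshape(replicas, n_pts).sum(axis=0)
    rate = counts / (replicas * duration / 1000.0)
    if np.any((rate > 0) & (counts < 10)):
        warnings.warn("some transfer-function grid points have < 10 spikes; "
                      "consider a longer duration", stacklevel=2)
    return TFSamples(nu_e=ne[:n_pts], nu_i=ni[:n_pts], rate=rate, k_e=k_e,
                     k_i=k_i, duration=replicas * duration, seed=seed,
                     cell_name=cell.name)


def measure_subthreshold(cell: CellParams, syn: SynParams, k_e, k_i,
                         nu_e, nu_i, duration: float = 10000.0,
                         seed: int = 0, dt: float = 0.1,
                         transient: float = 2000.0):
    """Monte-Carlo (mu_V, sigma_V) with the spike mechanism disabled; the
    brute-force check of the closed-form moment formulas."""
    nu_e = np.atleast_1d(np.asarray(nu_e, float))
    nu_i = np.atleast_1d(np.asarray(nu_i, float))
    n = len(nu_e)
    ones = np.ones(n)
    n_steps = int(round((duration + transient) / dt))
    stats_from = int(round(transient / dt))
    _, v_sum, v_sq, n_samp, err, err_t, err_i = _kernels.poisson_neurons(
        n_steps, dt, _as_kernel_seed(seed),
        cell.c_m * ones, cell.g_l * ones, cell.e_rev * ones,
        cell.k_adap * ones, cell.k_1 * ones, cell.k_2 * ones,
        cell.a_1 * ones, cell.a_2 * ones, cell.i_e * ones,
        cell.v_r * ones, cell.v_th * ones, cell.t_ref * ones,
        syn.tau_syn, syn.e_e, syn.e_i, syn.q_pyr, syn.q_fs,
        k_e * nu_e / 1000.0, k_i * nu_i / 1000.0, np.ones(n_steps),
        False, stats_from)
    if err:
        raise FloatingPointError(
            f"neuron {err_i} diverged at t = {err_t:.2f} ms")
    mu = v_sum / n_samp
    sd = np.sqrt(np.maximum(v_sq / n_samp - mu ** 2, 0.0))
    return mu, sd


@dataclass
class TFCoefficients:
    """Fitted effective-threshold coefficients (all in mV) with the
    normalization constants and fit diagnostics they were obtained under."""

    cell_name: str
    p0: float
    p_mu_v: float
    p_sigma_v: float
    p_tau_n: float
    p_mu_g: float                      # coefficient of ln(mu_G / g_L)
    norms: dict = field(default_factory=lambda: dict(DEFAULT_NORMS))
    second_order: dict = field(default_factory=dict)  # optional quadratic terms
    diagnostics: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def vector(self) -> np.ndarray:
        return np.asarray([self.p0, self.p_mu_v, self.p_sigma_v,
                           self.p_tau_n, self.p_mu_g])

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["diagnostics"] = {k: (v.tolist() if hasattr(v, "tolist") else v)
                            for k, v in d["diagnostics"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TFCoefficients":
        return cls(**d)

    def save(self, path) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "TFCoefficients":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


_TERM_NAMES = ("P_0", "P_muV", "P_sigmaV", "P_tauVN", "P_muG")


def _normalized_regressors(m: SubthresholdMoments, cell: CellParams,
                           norms: dict) -> np.ndarray:
    tau_n = m.tau_v * cell.g_l / cell.c_m
    cols = [np.ones_like(m.mu_v),
            (m.mu_v - norms["mu_v0"]) / norms["dmu_v0"],
            (m.sigma_v - norms["sigma_v0"]) / norms["dsigma_v0"],
            (tau_n - norms["tau_n0"]) / norms["dtau_n0"],
            np.log(m.mu_g / cell.g_l)]
    return np.column_stack([np.broadcast_to(c, m.mu_v.shape).ravel()
                            for c in cols])


def _second_order_regressors(x: np.ndarray) -> np.ndarray:
    """Quadratic and cross terms of the three normalized moment regressors."""
    a, b, c = x[:, 1], x[:, 2], x[:, 3]
    return np.column_stack([a * a, b * b, c * c, a * b, a * c, b * c])


def effective_threshold(m: SubthresholdMoments, coeffs: TFCoefficients,
                        cell: CellParams) -> np.ndarray:
    """Evaluate the fitted effective threshold V_eff (mV)."""
    x = _normalized_regressors(m, cell, coeffs.norms)
    v = x @ coeffs.vector
    if coeffs.second_order:
        q = np.asarray([coeffs.second_order[k] for k in
                        ("muV2", "sigmaV2", "tauVN2", "muV_sigmaV",
                         "muV_tauVN", "sigmaV_tauVN")])
        v = v + _second_order_regressors(x) @ q
    return v.reshape(np.shape(m.mu_v))


def tf_from_moments(m: SubthresholdMoments, coeffs: TFCoefficients,
                    cell: CellParams) -> np.ndarray:
    """Erfc-form rate (Hz) from moments and fitted threshold, clipped at 0.

    In the zero-variance (no-input) limit the fitted expansion is an
    extrapolation with no data behind it; there the exact deterministic
    rule applies instead: the membrane settles at mu_V and fires only if
    that reaches the cell's spike threshold.
    """
    veff = effective_threshold(m, coeffs, cell)
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = (veff - m.mu_v) / (np.sqrt(2.0) * m.sigma_v)
        f = 1000.0 / (2.0 * m.tau_v) * erfc(arg)   # tau_v ms -> Hz
    f = np.where(m.sigma_v > 0, f,
                 np.where(m.mu_v >= cell.v_th,
                          1000.0 / (2.0 * m.tau_v), 0.0))
    return np.maximum(f, 0.0)


def semi_analytic_tf(nu_e, nu_i, coeffs: TFCoefficients, cell: CellParams,
                     syn: SynParams, k_e: float, k_i: float) -> np.ndarray:
    """Semi-analytic transfer function F(nu_e, nu_i) in Hz."""
    m = subthreshold_moments(nu_e, nu_i, k_e, k_i, cell, syn)
    return tf_from_moments(m, coeffs, cell)


def invert_tf(f_hz, m: SubthresholdMoments) -> np.ndarray:
    """Exact inverse of the erfc relation: the V_eff that reproduces rate F.

    Valid for 0 < 2 tau_V F < 2; F = 0 points cannot be inverted and must be
    excluded from fitting.
    """
    f = np.asarray(f_hz, dtype=float) / 1000.0  # kHz
    x = 2.0 * m.tau_v * f
    if np.any(x <= 0) or np.any(x >= 2):
        raise ValueError("rate outside the invertible range (0, 1/tau_V)")
    return m.mu_v + np.sqrt(2.0) * m.sigma_v * erfcinv(x)


def fit_effective_threshold(samples: TFSamples, cell: CellParams,
                            syn: SynParams = DEFAULT_SYN,
                            norms: dict | None = None,
                            refine: bool = True,
                            second_order: bool = False) -> TFCoefficients:
    """Fit the effective-threshold expansion to numerical TF samples.

    Stage 1 maps every sample with F > 0 to a target V_eff through the exact
    inverse of the erfc relation and solves an ordinary least-squares problem
    in the expansion's regressors.  Stage 2 (``refine=True``) polishes the
    coefficients by nonlinear least squares on the rate-space residuals over
    all samples (including F = 0 ones), which weights the fit where the
    mean-field actually operates.
    """
    norms = dict(DEFAULT_NORMS) if norms is None else dict(norms)
    m_all = subthreshold_moments(samples.nu_e, samples.nu_i,
                                 samples.k_e, samples.k_i, cell, syn)
    pos = samples.rate > 0
    # keep strictly invertible points
    pos &= (2.0 * m_all.tau_v * samples.rate / 1000.0) < 2.0
    ols_feasible = np.count_nonzero(pos) >= 10
    if not ols_feasible and not (refine and np.count_nonzero(
            samples.rate > 0) >= 10):
        raise ValueError("need at least 10 samples with positive rate")
    n_coef = 11 if second_order else 5
    if ols_feasible:
        m_pos = subthreshold_moments(samples.nu_e[pos], samples.nu_i[pos],
                                     samples.k_e, samples.k_i, cell, syn)
        y = invert_tf(samples.rate[pos], m_pos)
        x = _normalized_regressors(m_pos, cell, norms)
        if second_order:
            x = np.hstack([x, _second_order_regressors(x)])

        rank = np.linalg.matrix_rank(x)
        if rank < x.shape[1]:
            for j in range(x.shape[1]):
                others = np.delete(x, j, axis=1)
                if np.linalg.matrix_rank(others) == rank:
                    name = (_TERM_NAMES[j] if j < len(_TERM_NAMES)
                            else f"second-order term {j - len(_TERM_NAMES)}")
                    raise ValueError(f"rank-deficient design matrix: "
                                     f"term {name} is collinear")
            raise ValueError("rank-deficient design matrix")

        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        dof = max(len(y) - x.shape[1], 1)
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(x.T @ x)
        se = np.sqrt(np.diag(cov))
    else:
        # saturated regime: no invertible points, seed the rate-space
        # refinement from a bare threshold at V_th
        beta = np.zeros(n_coef)
        beta[0] = cell.v_th
        resid = np.full(1, np.nan)
        se = np.full(n_coef, np.nan)

    def _make(vec) -> TFCoefficients:
        c = TFCoefficients(cell_name=samples.cell_name or cell.name,
                           p0=float(vec[0]), p_mu_v=float(vec[1]),
                           p_sigma_v=float(vec[2]), p_tau_n=float(vec[3]),
                           p_mu_g=float(vec[4]), norms=norms)
        if second_order:
            keys = ("muV2", "sigmaV2", "tauVN2", "muV_sigmaV", "muV_tauVN",
                    "sigmaV_tauVN")
            c.second_order = {k: float(v) for k, v in zip(keys, vec[5:])}
        return c

    coeffs = _make(beta)
    rmse_veff = float(np.sqrt(np.mean(resid ** 2)))

    if refine:
        scale = float(np.max(samples.rate)) or 1.0

        def rate_resid(vec):
            return (tf_from_moments(m_all, _make(vec), cell)
                    - samples.rate) / scale

        sol = least_squares(rate_resid, coeffs.vector if not second_order
                            else np.concatenate([coeffs.vector,
                                                 [coeffs.second_order[k] for k in
                                                  ("muV2", "sigmaV2", "tauVN2",
                                                   "muV_sigmaV", "muV_tauVN",
                                                   "sigmaV_tauVN")]]),
                            method="lm", max_nfev=2000)
        coeffs = _make(sol.x)

    pred = tf_from_moments(m_all, coeffs, cell)
    coeffs.diagnostics = dict(
        rmse_veff=rmse_veff,
        rmse_rate=float(np.sqrt(np.mean((pred - samples.rate) ** 2))),
        max_rate=float(np.max(samples.rate)),
        se=se, n_samples=int(np.count_nonzero(pos)), refined=bool(refine))
    coeffs.provenance = dict(k_e=samples.k_e, k_i=samples.k_i,
                             duration_ms=samples.duration, seed=samples.seed)
    return coeffs
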