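"""Second-order mean-field dynamics of the Pyr/FS microcircuit.

The population model follows the master-equation moment expansion for
networks of rate-coupled populations: with F_mu the per-population transfer
function evaluated at the instantaneous population rates, the mean rates
nu_mu and the rate covariances c_lam_eta obey

    T dnu_mu/dt = (F_mu - nu_mu) + 1/2 c_lam_eta d2F_mu/dnu_lam dnu_eta
    T dc_le/dt  = delta_le F_l (1/T - F_e) / N_l + (F_l - nu_l)(F_e - nu_e)
                  + dF_l/dnu_m c_em + dF_e/dnu_m c_lm - 2 c_le

with Einstein summation over the populations {Pyr, FS}, finite-size source
terms proportional to 1/N, and a relaxation time T = 5 ms tied to the
network's autocorrelation time.  External CA3 drive enters the transfer
functions through the excitatory input rate with its own convergence; since
all excitatory sources share (Q, tau_syn, E_e) they pool exactly through the
product K * nu.

Derivatives of F are evaluated by finite differences on the transfer
function (central where the rate permits, one-sided at the nu = 0 boundary).

Adaptation and post-spike depolarizing currents do not appear explicitly at
this level: their stationary effect is absorbed in the fitted transfer
function, whose underlying single-cell simulations contain the full EGLIF
dynamics.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import root

from .single_cell import CellParams, SynParams, DEFAULT_SYN
from .transfer_function import TFCoefficients, moments_from_sources, tf_from_moments

__all__ = [
    "POPS", "MeanFieldModel", "MeanFieldState", "DriveSignal",
    "PlasticityWeight", "make_drive", "mf_derivatives", "integrate_mf",
    "stationary_state", "apply_plasticity", "MFTrace",
]

POPS = ("pyr", "fs")


@dataclass(frozen=True)
class DriveSignal:
    """External (CA3) population rate nu_ext(t) >= 0 in Hz."""

    kind: str
    params: dict = field(default_factory=dict)

    def __call__(self, t):
        p = self.params
        if self.kind == "constant":
            return p["nu0_hz"] * np.ones_like(np.asarray(t, dtype=float))
        if self.kind == "sinusoid":
            return p["nu0_hz"] * (1.0 + p["depth"] * np.sin(
                2.0 * np.pi * p["f_hz"] * np.asarray(t, dtype=float) / 1000.0))
        if self.kind == "gaussian_pulse":
            t = np.asarray(t, dtype=float)
            return p["nu0_hz"] + p["amp_hz"] * np.exp(
                -0.5 * ((t - p["center_ms"]) / p["sigma_ms"]) ** 2)
        if self.kind == "samples":
            return np.interp(np.asarray(t, dtype=float),
                             p["times_ms"], p["values_hz"])
        raise ValueError(f"unknown drive kind {self.kind!r}")


def make_drive(kind: str, **params) -> DriveSignal:
    """Construct a validated drive signal.

    constant(nu0_hz); sinusoid(nu0_hz, f_hz, depth) with
    nu0 (1 + depth sin 2 pi f t); gaussian_pulse(nu0_hz, amp_hz, center_ms,
    sigma_ms); samples(times_ms, values_hz).
    """
    if kind == "sinusoid":
        if not 0.0 <= params["depth"] <= 1.0:
            raise ValueError("sinusoid depth must lie in [0, 1] "
                             "(the rate would go negative)")
    if kind == "constant" and params["nu0_hz"] < 0:
        raise ValueError("constant drive rate must be non-negative")
    if kind == "gaussian_pulse" and (params["nu0_hz"] < 0
                                     or params["amp_hz"] < 0):
        raise ValueError("pulse baseline and amplitude must be non-negative")
    if kind == "samples" and np.any(np.asarray(params["values_hz"]) < 0):
        raise ValueError("sampled drive must be non-negative")
    return DriveSignal(kind=kind, params=params)


@dataclass(frozen=True)
class PlasticityWeight:
    """Percent of baseline external (CA3 -> Pyr) synaptic convergence; 100
    is the unmodified circuit, values below/above emulate LTD/LTP."""

    w_e: float

    def __post_init__(self):
        if self.w_e <= 0:
            raise ValueError("W_e must be positive")


@dataclass
class MeanFieldState:
    """Population rates (Hz) and rate covariance matrix (Hz^2), ordered
    (Pyr, FS)."""

    nu: np.ndarray
    c: np.ndarray

    def __post_init__(self):
        self.nu = np.asarray(self.nu, dtype=float)
        self.c = np.asarray(self.c, dtype=float)

    @classmethod
    def zero(cls) -> "MeanFieldState":
        return cls(nu=np.zeros(2), c=np.zeros((2, 2)))


@dataclass
class MeanFieldModel:
    """Per-population transfer functions plus the network couplings.

    k[(src, dst)] holds the mean synaptic convergences, including the
    external rows ('ext', dst).  n holds the population sizes entering the
    finite-size covariance source.
    """

    cells: dict                 # pop -> CellParams
    coeffs: dict                # pop -> TFCoefficients
    k: dict                     # (src, dst) -> convergence
    n: dict                     # pop -> population size
    syn: SynParams = DEFAULT_SYN
    t_relax: float = 5.0        # relaxation time T (ms)
    fd_step_min: float = 0.1    # finite-difference floor (Hz)
    fd_step_rel: float = 0.01   # relative finite-difference step

    def __post_init__(self):
        if self.t_relax <= 0:
            raise ValueError("T must be positive")
        if any(v < 0 for v in self.k.values()):
            raise ValueError("convergences must be non-negative")

    def transfer_rates(self, nu_pyr, nu_fs, nu_ext):
        """F for both populations (Hz); inputs may be arrays."""
        out = []
        for pop in POPS:
            pooled_e = (self.k[("pyr", pop)] * np.asarray(nu_pyr, float)
                        + self.k[("ext", pop)] * np.asarray(nu_ext, float))
            inh = self.k[("fs", pop)] * np.asarray(nu_fs, float)
            m = moments_from_sources(
                [(1.0, pooled_e, self.syn.q_pyr, self.syn.tau_syn, self.syn.e_e),
                 (1.0, inh, self.syn.q_fs, self.syn.tau_syn, self.syn.e_i)],
                self.cells[pop])
            out.append(tf_from_moments(m, self.coeffs[pop], self.cells[pop]))
        return np.asarray(out)


def _stencil(model: MeanFieldModel, nu: np.ndarray, nu_ext: float):
    """Transfer function value, gradient and Hessian at ``nu`` by finite
    differences; one-sided at the nu >= 0 boundary."""
    h = np.maximum(model.fd_step_min, model.fd_step_rel * nu)
    pts = [(nu[0], nu[1])]
    per_dim = []
    for d in range(2):
        if nu[d] >= h[d]:
            lo, hi, extra = nu[d] - h[d], nu[d] + h[d], None
        else:
            lo, hi, extra = nu[d], nu[d] + h[d], nu[d] + 2 * h[d]
        per_dim.append((lo, hi, extra))
        if extra is None:
            pts += [_sub(nu, d, lo), _sub(nu, d, hi)]
        else:
            pts += [_sub(nu, d, hi), _sub(nu, d, extra)]
    lo0, hi0, _ = per_dim[0]
    lo1, hi1, _ = per_dim[1]
    corner_lo0 = lo0 if per_dim[0][2] is None else nu[0]
    corner_lo1 = lo1 if per_dim[1][2] is None else nu[1]
    corners = [(hi0, hi1), (hi0, corner_lo1), (corner_lo0, hi1),
               (corner_lo0, corner_lo1)]
    pts += corners

    arr = np.asarray(pts)
    f_all = model.transfer_rates(arr[:, 0], arr[:, 1], nu_ext)  # (2, npts)
    f0 = f_all[:, 0]

    jac = np.empty((2, 2))
    hess_diag = np.empty((2, 2))
    idx = 1
    for d in range(2):
        lo, hi, extra = per_dim[d]
        if extra is None:
            f_lo, f_hi = f_all[:, idx], f_all[:, idx + 1]
            jac[:, d] = (f_hi - f_lo) / (hi - lo)
            hess_diag[:, d] = (f_lo - 2 * f0 + f_hi) / h[d] ** 2
        else:
            f_hi, f_ex = f_all[:, idx], f_all[:, idx + 1]
            jac[:, d] = (-3 * f0 + 4 * f_hi - f_ex) / (2 * h[d])
            hess_diag[:, d] = (f0 - 2 * f_hi + f_ex) / h[d] ** 2
        idx += 2
    f_pp, f_pm, f_mp, f_mm = (f_all[:, idx], f_all[:, idx + 1],
                              f_all[:, idx + 2], f_all[:, idx + 3])
    span0 = hi0 - corner_lo0
    span1 = hi1 - corner_lo1
    cross = (f_pp - f_pm - f_mp + f_mm) / (span0 * span1)

    hess = np.empty((2, 2, 2))
    for mu in range(2):
        hess[mu] = np.array([[hess_diag[mu, 0], cross[mu]],
                             [cross[mu], hess_diag[mu, 1]]])
    return f0, jac, hess


def _sub(nu, d, val):
    out = [nu[0], nu[1]]
    out[d] = val
    return tuple(out)


def mf_derivatives(state: MeanFieldState, nu_ext: float,
                   model: MeanFieldModel, first_order: bool = False):
    """Time derivatives (dnu/dt in Hz/ms, dc/dt in Hz^2/ms).

    ``first_order=True`` drops the curvature term and freezes c (returns
    dc/dt = 0), reducing the rate equation to T dnu/dt = F - nu.
    """
    nu = np.asarray(state.nu, dtype=float)
    t_relax = model.t_relax
    if first_order:
        f0 = model.transfer_rates(nu[0], nu[1], nu_ext)
        _check_finite(f0, nu_ext)
        return (f0 - nu) / t_relax, np.zeros((2, 2))

    f0, jac, hess = _stencil(model, nu, nu_ext)
    _check_finite(f0, nu_ext)
    c = np.asarray(state.c, dtype=float)
    curv = 0.5 * np.einsum("le,mle->m", c, hess)
    dnu = (f0 - nu + curv) / t_relax

    n_vec = np.asarray([model.n[p] for p in POPS], dtype=float)
    # finite-size source: 1/T converted to Hz so the term carries Hz^2
    source = np.diag(f0 * (1000.0 / t_relax - f0) / n_vec)
    drift = np.outer(f0 - nu, f0 - nu)
    flow = jac @ c
    dc = (source + drift + flow + flow.T - 2.0 * c) / t_relax
    if not np.all(np.isfinite(dc)):
        raise FloatingPointError("non-finite covariance derivative")
    return dnu, dc


def _check_finite(f0, nu_ext):
    if not np.all(np.isfinite(f0)):
        raise FloatingPointError(
            f"non-finite transfer-function value at nu_ext = {nu_ext}")


@dataclass
class MFTrace:
    """Mean-field integration output on the recorded time grid."""

    time: np.ndarray            # ms
    nu: np.ndarray              # (nt, 2) Hz, columns (Pyr, FS)
    c: np.ndarray               # (nt, 2, 2) Hz^2
    clip_fraction: float = 0.0  # fraction of steps where nu was clipped at 0
    pops: tuple = POPS

    def rate(self, pop: str) -> np.ndarray:
        return self.nu[:, self.pops.index(pop)]

    def mean_rate(self, pop: str, t_min: float = 0.0,
                  t_max: float = np.inf) -> float:
        mask = (self.time >= t_min) & (self.time <= t_max)
        return float(np.mean(self.rate(pop)[mask]))

    def peak_time(self, pop: str, t_min: float = 0.0) -> float:
        mask = self.time >= t_min
        r = self.rate(pop)[mask]
        return float(self.time[mask][np.argmax(r)])


def integrate_mf(model: MeanFieldModel, drive, duration: float,
                 dt: float = 0.1, init: MeanFieldState | None = None,
                 method: str = "heun", first_order: bool = False,
                 record_stride: int = 1) -> MFTrace:
    """Fixed-step integration of the mean-field equations.

    ``drive`` is a DriveSignal (or any callable t -> Hz).  Negative rates
    produced by the explicit step are clipped at zero and counted;
    ``clip_fraction`` in the returned trace reports the fraction of steps
    affected.
    """
    if dt > model.t_relax / 10.0:
        warnings.warn(f"dt = {dt} ms exceeds T/10 = {model.t_relax / 10} ms; "
                      "integration may be inaccurate", stacklevel=2)
    if method not in ("heun", "euler"):
        raise ValueError("method must be 'heun' or 'euler'")
    rate_fn = drive if callable(drive) else (lambda t, r=float(drive): r)
    n_steps = int(round(duration / dt))
    state = init if init is not None else MeanFieldState.zero()
    nu = np.array(state.nu, dtype=float)
    c = np.array(state.c, dtype=float)

    n_rec = n_steps // record_stride + 1
    t_out = np.empty(n_rec)
    nu_out = np.empty((n_rec, 2))
    c_out = np.empty((n_rec, 2, 2))
    t_out[0], nu_out[0], c_out[0] = 0.0, nu, c
    i_rec = 1
    clipped = 0

    for k in range(n_steps):
        t = k * dt
        ext_0 = float(rate_fn(t))
        if ext_0 < 0:
            raise ValueError(f"negative drive rate at t = {t} ms")
        d_nu1, d_c1 = mf_derivatives(MeanFieldState(nu, c), ext_0, model,
                                     first_order)
        if method == "euler":
            nu_new = nu + dt * d_nu1
            c_new = c + dt * d_c1
        else:
            ext_1 = float(rate_fn(t + dt))
            pred = MeanFieldState(np.maximum(nu + dt * d_nu1, 0.0),
                                  c + dt * d_c1)
            d_nu2, d_c2 = mf_derivatives(pred, ext_1, model, first_order)
            nu_new = nu + 0.5 * dt * (d_nu1 + d_nu2)
            c_new = c + 0.5 * dt * (d_c1 + d_c2)
        if np.any(nu_new < 0):
            clipped += 1
            nu_new = np.maximum(nu_new, 0.0)
        if not np.all(np.isfinite(nu_new)):
            raise FloatingPointError(
                f"mean-field blow-up at t = {t + dt:.2f} ms")
        nu, c = nu_new, 0.5 * (c_new + c_new.T)
        if (k + 1) % record_stride == 0:
            t_out[i_rec] = (k + 1) * dt
            nu_out[i_rec] = nu
            c_out[i_rec] = c
            i_rec += 1
    return MFTrace(time=t_out[:i_rec], nu=nu_out[:i_rec], c=c_out[:i_rec],
                   clip_fraction=clipped / max(n_steps, 1))


def stationary_state(model: MeanFieldModel, nu_ext: float,
                     first_order: bool = False, tol: float = 1e-10,
                     max_iter: int = 20000):
    """Stationary mean-field state under a constant external drive.

    The first-order fixed point nu = F(nu, nu_ext) is found by damped
    iteration; the full second-order fixed point is then solved by root
    finding on (nu, c), falling back to a long integration (flagged in the
    returned info dict) if the root search does not converge.

    Returns (MeanFieldState, info).
    """
    if nu_ext < 0:
        raise ValueError("nu_ext must be non-negative")

    def res1(x):
        return model.transfer_rates(max(x[0], 0.0), max(x[1], 0.0),
                                    nu_ext) - x

    sol1 = root(res1, np.array([1.0, 10.0]), method="hybr", tol=1e-12)
    if sol1.success and np.max(np.abs(res1(sol1.x))) < tol * 100:
        nu = np.maximum(sol1.x, 0.0)
    else:
        # strongly damped fixed-point iteration as fallback
        nu = np.array([1.0, 1.0])
        alpha = 0.1
        for _ in range(max_iter):
            f = model.transfer_rates(nu[0], nu[1], nu_ext)
            nu_new = (1 - alpha) * nu + alpha * f
            if np.max(np.abs(nu_new - nu)) < tol:
                nu = nu_new
                break
            nu = nu_new
        else:
            raise RuntimeError(
                "first-order fixed point did not converge; residual "
                f"{np.max(np.abs(f - nu)):.3e} Hz")
        nu = np.maximum(nu, 0.0)
    info = {"first_order_residual": float(np.max(np.abs(
        model.transfer_rates(nu[0], nu[1], nu_ext) - nu)))}
    if first_order:
        return MeanFieldState(nu=nu, c=np.zeros((2, 2))), info

    def residual(x):
        st = MeanFieldState(nu=x[:2], c=np.array([[x[2], x[3]],
                                                  [x[3], x[4]]]))
        d_nu, d_c = mf_derivatives(st, nu_ext, model)
        return np.array([d_nu[0], d_nu[1], d_c[0, 0], d_c[0, 1], d_c[1, 1]])

    x0 = np.array([nu[0], nu[1], 0.0, 0.0, 0.0])
    sol = root(residual, x0, method="hybr", tol=1e-12)
    if sol.success and np.max(np.abs(residual(sol.x))) < 1e-6:
        st = MeanFieldState(nu=np.maximum(sol.x[:2], 0.0),
                            c=np.array([[sol.x[2], sol.x[3]],
                                        [sol.x[3], sol.x[4]]]))
        info["residual"] = float(np.max(np.abs(residual(sol.x))))
        info["method"] = "root"
        return st, info

    # fallback: relax by integration
    drive = make_drive("constant", nu0_hz=float(nu_ext))
    trace = integrate_mf(model, drive, duration=3000.0, dt=0.1,
                         init=MeanFieldState(nu=nu, c=np.zeros((2, 2))),
                         record_stride=100)
    st = MeanFieldState(nu=trace.nu[-1], c=trace.c[-1])
    res = residual(np.array([st.nu[0], st.nu[1], st.c[0, 0], st.c[0, 1],
                             st.c[1, 1]]))
    info["residual"] = float(np.max(np.abs(res)))
    info["method"] = "integration-fallback"
    if info["residual"] > 1e-3:
        raise RuntimeError(
            f"stationary state did not converge (residual {info['residual']:.3e})")
    return st, info


def model_from_topology(cells: dict, coeffs: dict, top,
                        syn: SynParams = DEFAULT_SYN,
                        t_relax: float = 5.0) -> MeanFieldModel:
    """Mean-field model whose convergences K = p N match a network topology
    (including the external CA3 rows)."""
    k = {}
    for src in POPS + ("ext",):
        for dst in POPS:
            k[(src, dst)] = top.convergence(src, dst)
    return MeanFieldModel(cells=cells, coeffs=coeffs, k=k,
                          n={p: top.n[p] for p in POPS}, syn=syn,
                          t_relax=t_relax)


def apply_plasticity(model: MeanFieldModel, w: PlasticityWeight | float
                     ) -> MeanFieldModel:
    """Model with the external CA3 -> Pyr convergence scaled to W_e percent
    of baseline; every other parameter is untouched."""
    w_e = w.w_e if isinstance(w, PlasticityWeight) else float(w)
    if w_e <= 0:
        raise ValueError("W_e must be positive")
    k = dict(model.k)
    k[("ext", "pyr")] = model.k[("ext", "pyr")] * (w_e / 100.0)
    return dataclasses.replace(model, k=k)
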