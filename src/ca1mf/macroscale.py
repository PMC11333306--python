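"""Macroscale CA1 slice: mean-field compartments coupled by geometry.

A 1.5 x 1.5 mm patch of the pyramidal/stratum-oriens layer is tiled into
100 x 100 um compartments (about 200 neurons each), every compartment hosting
one mean-field unit.  Excitatory Pyr -> Pyr coupling between compartments is
derived from the geometric probability volumes of the neurites: the axonal
cloud of a pyramidal cell projects as a pair of elliptical densities whose
centers are displaced downstream along the CA3 -> subiculum (transversal)
axis, while the basal dendritic cloud is a compact cone footprint that merely
broadens the kernel (the axonal geometry is the binding constraint).  The
displaced axonal clouds make the coupling asymmetric and produce the
experimentally observed transversally directed propagation when inhibition
is absent.

Coordinates are in micrometers with the origin at the CA3-side corner; x
increases toward the subiculum (transversal axis), y is the longitudinal
(medio-lateral) axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mean_field import MeanFieldModel, POPS

__all__ = [
    "GeometryParams", "CompartmentGrid", "StimulusSpec",
    "connection_probability", "build_connectivity", "make_grid",
    "simulate_slice", "propagation_summary", "PropagationSummary",
]


@dataclass(frozen=True)
class GeometryParams:
    """Smooth-density representation of the neurite probability volumes.

    ellipses : tuple of (weight, semi_x_um, semi_y_um, offset_um)
        Axonal cloud as a mixture of elliptical Gaussian densities; the
        offset displaces each center along the anisotropy direction (toward
        the subiculum).  Semi-axes are treated as 2-sigma extents.
    dendrite_radius_um : basal-dendrite cone footprint radius; folded into
        the kernel width (the footprint is taken flat within the cone, so
        the axonal cloud remains the dominant constraint).
    anisotropy : unit vector of the CA3 -> subiculum direction.
    """

    ellipses: tuple = ((0.5, 400.0, 150.0, 150.0),
                       (0.5, 250.0, 150.0, 400.0))
    dendrite_radius_um: float = 150.0
    anisotropy: tuple = (1.0, 0.0)

    def __post_init__(self):
        for w, ax, ay, _ in self.ellipses:
            if ax <= 0 or ay <= 0 or w < 0:
                raise ValueError("ellipse weights/semi-axes must be positive")
        norm = float(np.hypot(*self.anisotropy))
        if not np.isclose(norm, 1.0):
            raise ValueError("anisotropy direction must be a unit vector")

    @classmethod
    def isotropic(cls, radius_um: float = 300.0,
                  dendrite_radius_um: float = 150.0) -> "GeometryParams":
        """Symmetric control geometry: one centered circular cloud."""
        return cls(ellipses=((1.0, radius_um, radius_um, 0.0),),
                   dendrite_radius_um=dendrite_radius_um)


def connection_probability(src_pos, dst_pos, geom: GeometryParams):
    """Unnormalized Pyr -> Pyr connection weight between two positions (um).

    Overlap of the source's displaced axonal cloud with the destination's
    dendritic footprint; symmetric under src/dst exchange only when all
    axonal offsets vanish.  Accepts arrays of positions (broadcast on the
    leading axes).
    """
    src = np.asarray(src_pos, dtype=float)
    dst = np.asarray(dst_pos, dtype=float)
    delta = dst - src
    ux, uy = geom.anisotropy
    dx = delta[..., 0] * ux + delta[..., 1] * uy
    dy = -delta[..., 0] * uy + delta[..., 1] * ux
    rd2 = (geom.dendrite_radius_um / 2.0) ** 2
    w = 0.0
    for wk, ax, ay, off in geom.ellipses:
        sx2 = (ax / 2.0) ** 2 + rd2
        sy2 = (ay / 2.0) ** 2 + rd2
        w = w + wk * np.exp(-0.5 * ((dx - off) ** 2 / sx2 + dy ** 2 / sy2))
    return w


@dataclass
class CompartmentGrid:
    """Tiling of mean-field units over the slice."""

    nx: int
    ny: int
    side_um: float
    model: MeanFieldModel
    coords: np.ndarray                 # (n, 2) compartment centers (um)
    k_comp: np.ndarray | None = None   # (n, n), K[i, j]: Pyr_i -> Pyr_j
    neurons_per_compartment: int = 200

    @property
    def n_comp(self) -> int:
        return self.nx * self.ny

    def index(self, ix: int, iy: int) -> int:
        if not (0 <= ix < self.nx and 0 <= iy < self.ny):
            raise IndexError("compartment outside grid")
        return iy * self.nx + ix


def make_grid(model: MeanFieldModel, nx: int = 15, ny: int = 15,
              side_um: float = 100.0) -> CompartmentGrid:
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    coords = np.column_stack([(ix.ravel(order="F") + 0.5) * side_um,
                              (iy.ravel(order="F") + 0.5) * side_um])
    return CompartmentGrid(nx=nx, ny=ny, side_um=side_um, model=model,
                           coords=coords)


def build_connectivity(grid: CompartmentGrid, geom: GeometryParams,
                       baseline_k: float | None = None,
                       normalization: str = "center") -> np.ndarray:
    """Inter-compartment convergence matrix from the geometric kernel.

    normalization='center': one global constant is chosen so that the total
    recurrent excitatory convergence received by the central compartment
    equals ``baseline_k``; normalization='row' makes every compartment
    receive exactly ``baseline_k``.

    The default anchor extends the microcircuit's pairwise connection
    probability to the neuron population the slice actually represents:
    K = p(Pyr->Pyr) * N_slice with N_slice = n_comp * neurons_per_compartment
    (450 for the default 15 x 15 grid of ~200-neuron compartments).
    Anchoring instead to the 5,000-neuron microcircuit value K = 50 makes
    the recurrent loop gain of the disinhibited slice fall below one, and
    no traveling front can exist.
    """
    if baseline_k is None:
        p_pp = grid.model.k[("pyr", "pyr")] / grid.model.n["pyr"]
        baseline_k = p_pp * grid.n_comp * grid.neurons_per_compartment
    w = connection_probability(grid.coords[:, None, :],
                               grid.coords[None, :, :], geom)
    if not np.any(w > 0):
        raise ValueError("geometric kernel produced all-zero weights")
    if normalization == "center":
        center = grid.index(grid.nx // 2, grid.ny // 2)
        k = baseline_k * w / w[:, center].sum()
    elif normalization == "row":
        k = baseline_k * w / w.sum(axis=0, keepdims=True)
    else:
        raise ValueError("normalization must be 'center' or 'row'")
    grid.k_comp = k
    return k


@dataclass(frozen=True)
class StimulusSpec:
    """Extra external rate applied to a single compartment."""

    target: tuple              # (ix, iy)
    onset_ms: float
    duration_ms: float
    amplitude_hz: float        # added to the external drive rate

    def __post_init__(self):
        if self.amplitude_hz < 0:
            raise ValueError("stimulus amplitude must be non-negative")


def simulate_slice(grid: CompartmentGrid, stimulus: StimulusSpec | None,
                   baseline_hz: float, duration: float, dt: float = 0.1,
                   no_inhibition: bool = True, record_stride: int = 20):
    """Integrate all compartments' mean-field rate equations.

    Every compartment evolves T dnu/dt = F - nu (first-order closure; the
    inter-compartment covariances are not modeled, so the within-compartment
    curvature correction is dropped for consistency).  The excitatory input
    of compartment j pools the external drive with the geometric recurrent
    input sum_i K_comp[i, j] nu_Pyr_i.  With ``no_inhibition`` the FS
    populations and all inhibitory couplings are silenced, the regime in
    which CA1 slices show transversally directed propagation.

    Returns (movie, times) with movie of shape (nx, ny, nt).
    """
    if grid.k_comp is None:
        raise ValueError("grid has no connectivity; call build_connectivity")
    model = grid.model
    n = grid.n_comp
    if stimulus is not None:
        tgt = grid.index(*stimulus.target)
    n_steps = int(round(duration / dt))
    t_relax = model.t_relax
    syn = model.syn

    nu_p = np.zeros(n)
    nu_f = np.zeros(n)
    k_t = grid.k_comp  # K[i, j], input to j is K.T @ nu
    k_ext_p = model.k[("ext", "pyr")]
    k_ext_f = model.k[("ext", "fs")]
    k_fs_p = 0.0 if no_inhibition else model.k[("fs", "pyr")]
    k_p_fs = model.k[("pyr", "fs")]
    k_fs_fs = 0.0 if no_inhibition else model.k[("fs", "fs")]

    from .transfer_function import moments_from_sources, tf_from_moments

    def f_rates(nu_p, nu_f, t):
        ext = np.full(n, baseline_hz, dtype=float)
        if stimulus is not None and \
                stimulus.onset_ms <= t < stimulus.onset_ms + stimulus.duration_ms:
            ext[tgt] += stimulus.amplitude_hz
        pooled_e = k_ext_p * ext + k_t.T @ nu_p
        m = moments_from_sources(
            [(1.0, pooled_e, syn.q_pyr, syn.tau_syn, syn.e_e),
             (1.0, k_fs_p * nu_f, syn.q_fs, syn.tau_syn, syn.e_i)],
            model.cells["pyr"])
        f_p = tf_from_moments(m, model.coeffs["pyr"], model.cells["pyr"])
        if no_inhibition:
            f_f = np.zeros(n)
        else:
            pooled_e_f = k_ext_f * ext + k_p_fs * nu_p
            m_f = moments_from_sources(
                [(1.0, pooled_e_f, syn.q_pyr, syn.tau_syn, syn.e_e),
                 (1.0, k_fs_fs * nu_f, syn.q_fs, syn.tau_syn, syn.e_i)],
                model.cells["fs"])
            f_f = tf_from_moments(m_f, model.coeffs["fs"], model.cells["fs"])
        return f_p, f_f

    n_rec = n_steps // record_stride + 1
    movie = np.empty((n_rec, n))
    times = np.empty(n_rec)
    movie[0], times[0] = nu_p, 0.0
    i_rec = 1
    for k in range(n_steps):
        t = k * dt
        f_p1, f_f1 = f_rates(nu_p, nu_f, t)
        p_pred = np.maximum(nu_p + dt * (f_p1 - nu_p) / t_relax, 0.0)
        f_pred = np.maximum(nu_f + dt * (f_f1 - nu_f) / t_relax, 0.0)
        f_p2, f_f2 = f_rates(p_pred, f_pred, t + dt)
        nu_p = nu_p + 0.5 * dt * ((f_p1 - nu_p) + (f_p2 - p_pred)) / t_relax
        nu_f = nu_f + 0.5 * dt * ((f_f1 - nu_f) + (f_f2 - f_pred)) / t_relax
        nu_p = np.maximum(nu_p, 0.0)
        nu_f = np.maximum(nu_f, 0.0)
        if not np.all(np.isfinite(nu_p)):
            bad = int(np.nonzero(~np.isfinite(nu_p))[0][0])
            raise FloatingPointError(
                f"compartment {bad} diverged at t = {t + dt:.2f} ms")
        if (k + 1) % record_stride == 0:
            movie[i_rec] = nu_p
            times[i_rec] = (k + 1) * dt
            i_rec += 1
    # (n_rec, n) -> (nx, ny, nt); flat compartment index is iy * nx + ix
    movie = movie[:i_rec].T.reshape(grid.ny, grid.nx, i_rec).transpose(1, 0, 2)
    return movie, times[:i_rec]


@dataclass
class PropagationSummary:
    """Per-compartment latency/peak statistics of a stimulus response."""

    latency: np.ndarray          # (nx, ny) time to half-max (ms); NaN if none
    peak: np.ndarray             # (nx, ny) peak rate (Hz)
    anisotropy_index: float      # transversal vs longitudinal latency slope
    null: bool = False


def propagation_summary(movie: np.ndarray, times: np.ndarray,
                        stim_index: tuple,
                        baseline_window_ms: float = 20.0,
                        min_response_hz: float = 1.0) -> PropagationSummary:
    """Latency map and anisotropy index of a slice response.

    Latency is the time to half-maximum above each compartment's pre-stimulus
    baseline.  The anisotropy index is the ratio of the latency-vs-distance
    slope along the longitudinal (y) axis through the stimulated compartment
    to the slope along the transversal (x) axis; values above 1 indicate
    transversal-dominant propagation, and an isotropic kernel gives 1.
    """
    nx, ny, _ = movie.shape
    pre = times < baseline_window_ms
    if not np.any(pre):
        pre = slice(0, 1)
    base = movie[:, :, pre].mean(axis=2)
    peak = movie.max(axis=2)
    responded = (peak - base) > min_response_hz
    if not np.any(responded):
        return PropagationSummary(latency=np.full((nx, ny), np.nan),
                                  peak=peak, anisotropy_index=np.nan,
                                  null=True)
    latency = np.full((nx, ny), np.nan)
    for i in range(nx):
        for j in range(ny):
            if not responded[i, j]:
                continue
            half = base[i, j] + 0.5 * (peak[i, j] - base[i, j])
            k = int(np.argmax(movie[i, j] >= half))
            if k == 0:
                latency[i, j] = times[0]
            else:
                # linear interpolation of the half-max crossing between
                # frames (breaks frame-quantization ties)
                r0, r1 = movie[i, j, k - 1], movie[i, j, k]
                frac = (half - r0) / (r1 - r0) if r1 > r0 else 1.0
                latency[i, j] = times[k - 1] + frac * (times[k] - times[k - 1])

    sx, sy = stim_index
    lat_row = latency[:, sy]
    dist_row = np.abs(np.arange(nx) - sx)
    ok = np.isfinite(lat_row)
    slope_x = _slope(dist_row[ok], lat_row[ok])
    lat_col = latency[sx, :]
    dist_col = np.abs(np.arange(ny) - sy)
    ok = np.isfinite(lat_col)
    slope_y = _slope(dist_col[ok], lat_col[ok])
    if slope_x is None or slope_y is None or slope_x <= 0:
        index = np.nan
    else:
        index = slope_y / slope_x
    return PropagationSummary(latency=latency, peak=peak,
                              anisotropy_index=float(index))


def _slope(x, y):
    if len(x) < 3 or np.ptp(x) == 0:
        return None
    return float(np.polyfit(x, y, 1)[0])
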