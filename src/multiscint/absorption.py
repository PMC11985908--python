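"""Analytic absorption model and the incident->reconstructed energy map.

The depth-resolved absorption per unit length of a multilayer stack follows
Beer-Lambert attenuation,

    A(z, E) = mu(z, E) * exp(-integral_0^z mu(z', E) dz'),

with the optical depth integral evaluated exactly as the piecewise-linear sum
of mu_j * (path in layer j).  Normalizing A over depth gives the absorption
density p_abs(z, E_inc); normalizing over energy gives the depth-conditional
detected-energy density p_det(z, E_det).  Chaining the two through a common
absorption depth and weighting by the incident spectrum N(E) yields the joint
density of (incident, reconstructed) energy; integrating it over bin
rectangles produces the M x M proportion matrix p^(mn), whose diagonal sum is
the energy reconstruction accuracy eta (1/M for uniform guessing, 1 for a
perfect depth->energy map).

Quadrature is trapezoidal on fixed grids that carry layer boundaries and
K-edges as double points, so no panel ever straddles a discontinuity.
Defaults: dz = L/2000, dE = 0.25 keV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import DegenerateInputError, RangeError, ValidationError
from .materials import E_MAX, E_MIN, LayerStack

log = logging.getLogger(__name__)

DEFAULT_EDGES = (16.0, 33.0, 50.0, 67.0)
_EPS = 1e-9


@dataclass(frozen=True)
class EnergyBinning:
    """Partition of the working energy range into M contiguous bins.

    The default edges place the two interior boundaries at the iodine and
    gadolinium K-edges (33 and 50 keV), giving three 17 keV bins over
    16-67 keV.  ``weights`` is the prior over incident bins; by default it is
    proportional to bin width (a uniform incident spectrum).
    """

    edges: tuple[float, ...] = DEFAULT_EDGES
    weights: tuple[float, ...] | None = None

    def __post_init__(self):
        e = np.asarray(self.edges, dtype=float)
        if e.size < 2 or np.any(np.diff(e) <= 0):
            raise ValidationError("bin edges must be strictly increasing")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.size != self.n_bins or np.any(w < 0) or abs(w.sum() - 1) > 1e-9:
                raise ValidationError("weights must be a distribution over bins")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def widths(self) -> np.ndarray:
        return np.diff(np.asarray(self.edges, dtype=float))

    @property
    def bin_weights(self) -> np.ndarray:
        if self.weights is not None:
            return np.asarray(self.weights, dtype=float)
        return self.widths / self.widths.sum()

    def bin_of(self, e_kev) -> np.ndarray:
        """0-based bin index; interior edges belong to the upper bin."""
        e = np.asarray(e_kev, dtype=float)
        idx = np.searchsorted(np.asarray(self.edges), e, side="right") - 1
        return np.clip(idx, 0, self.n_bins - 1)


# ----------------------------------------------------------------- grids
def depth_grid(stack: LayerStack, n_z: int = 2000):
    """Per-layer composite-Simpson grid over [0, L] with boundary doubling.

    Returns (coords, eval_z, weights): quadrature coordinates, the depths at
    which integrands are evaluated (boundary points inset into their own
    layer so the discontinuous mu is sampled on the correct side), and the
    concatenated per-layer Simpson weights.  The integrand is smooth inside
    every layer, so Simpson converges fast despite the inter-layer jumps.
    """
    L = stack.total_thickness
    b = stack.boundaries
    coords, evals, weights = [], [], []
    for k, layer in enumerate(stack.layers):
        d = layer.thickness_mm
        n_k = max(3, int(round(n_z * d / L)) + 1)
        if n_k % 2 == 0:            # Simpson needs an even panel count
            n_k += 1
        z = np.linspace(b[k], b[k + 1], n_k)
        ev = z.copy()
        if k < len(stack.layers) - 1:
            ev[-1] = b[k + 1] - _EPS * max(L, 1.0)  # stay inside layer k
        h = z[1] - z[0]
        w = np.full(n_k, 2.0)
        w[1::2] = 4.0
        w[0] = w[-1] = 1.0
        w *= h / 3.0
        coords.append(z)
        evals.append(ev)
        weights.append(w)
    return (np.concatenate(coords), np.concatenate(evals),
            np.concatenate(weights))


def energy_grid(binning: EnergyBinning, de: float = 0.25):
    """Per-bin trapezoid grid with K-edges sampled on the correct branch.

    Returns (coords, eval_e, weights, bin_index).  An interior edge energy
    belongs to the upper bin (H(0)=1), so the closing point of the lower bin
    is evaluated just below the edge.
    """
    coords, evals, weights, bins = [], [], [], []
    for m in range(binning.n_bins):
        e1, e2 = binning.edges[m], binning.edges[m + 1]
        n_m = max(2, int(round((e2 - e1) / de)) + 1)
        e = np.linspace(e1, e2, n_m)
        ev = e.copy()
        if m < binning.n_bins - 1:
            ev[-1] = e2 - 1e-7  # pre-edge side of the next bin's K-edge
        w = np.full(n_m, e[1] - e[0])
        w[0] *= 0.5
        w[-1] *= 0.5
        coords.append(e)
        evals.append(ev)
        weights.append(w)
        bins.append(np.full(n_m, m, dtype=int))
    return (np.concatenate(coords), np.concatenate(evals),
            np.concatenate(weights), np.concatenate(bins))


# ------------------------------------------------------------- absorption
def optical_depth(stack: LayerStack, z, e_kev) -> np.ndarray:
    """Exact piecewise-linear optical depth integral_0^z mu dz' (dimensionless).

    Broadcasts to shape (len(z), len(E)).
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    e = np.atleast_1d(np.asarray(e_kev, dtype=float))
    mu = stack.mu_profile(e)                      # (n_layers, n_E)
    d = np.array([l.thickness_mm for l in stack.layers])
    cum = np.vstack([np.zeros(e.size), np.cumsum(mu * d[:, None], axis=0)])
    idx = stack.layer_index(z)                    # (n_z,)
    z0 = stack.boundaries[idx]
    return cum[idx] + mu[idx] * (z - z0)[:, None]


def absorption_per_length(stack: LayerStack, z, e_kev):
    """A(z, E) = mu(z, E) exp(-tau(z, E)) in 1/mm; broadcasts over z and E."""
    z_arr = np.atleast_1d(np.asarray(z, dtype=float))
    e_arr = np.atleast_1d(np.asarray(e_kev, dtype=float))
    if np.any(z_arr < -1e-12) or np.any(z_arr > stack.total_thickness + 1e-12):
        raise RangeError("depth outside [0, L]")
    mu = stack.mu_profile(e_arr)[stack.layer_index(z_arr)]   # (n_z, n_E)
    out = mu * np.exp(-optical_depth(stack, z_arr, e_arr))
    if np.isscalar(z) and np.isscalar(e_kev):
        return float(out[0, 0])
    return np.squeeze(out) if (np.isscalar(z) or np.isscalar(e_kev)) else out


def total_absorption(stack: LayerStack, e_kev):
    """Probability that an X-ray of energy E is absorbed anywhere in the stack."""
    e = np.atleast_1d(np.asarray(e_kev, dtype=float))
    tau_L = optical_depth(stack, [stack.total_thickness], e)[0]
    out = 1.0 - np.exp(-tau_L)
    return float(out[0]) if np.isscalar(e_kev) else out


def p_abs(stack: LayerStack, z, e_inc, n_z: int = 2000):
    """Absorption depth density p_abs(z, E_inc); integrates to 1 over [0, L]."""
    denom = total_absorption(stack, e_inc)
    if np.min(np.atleast_1d(denom)) < 1e-300:
        raise DegenerateInputError(
            "stack is totally transparent at the requested energy")
    return absorption_per_length(stack, z, e_inc) / denom


def p_det(stack: LayerStack, z, e_det, binning: EnergyBinning | None = None,
          de: float = 0.25):
    """Depth-conditional detected-energy density; integrates to 1 over the range.

    A uniform incident-energy measure over [E_low, E_high] is assumed; the
    normalization uses trapezoidal quadrature on the (edge-aware) energy grid.
    """
    binning = binning or EnergyBinning()
    _, ev_e, w_e, _ = energy_grid(binning, de)
    z_arr = np.atleast_1d(np.asarray(z, dtype=float))
    denom = absorption_per_length(stack, z_arr, ev_e) @ w_e      # (n_z,)
    if np.min(denom) < 1e-300:
        raise DegenerateInputError("no absorption at this depth")
    num = absorption_per_length(stack, z_arr, e_det)
    out = np.atleast_2d(num) / denom[:, None]
    if np.isscalar(z) and np.isscalar(e_det):
        return float(out[0, 0])
    return np.squeeze(out) if (np.isscalar(z) or np.isscalar(e_det)) else out


# ------------------------------------------------- reconstruction matrix
@dataclass(frozen=True)
class ReconstructionMatrix:
    """Joint proportions p^(mn): incident bin m -> reconstructed bin n.

    Entries are non-negative and sum to one; row sums equal the per-bin
    incident weights implied by the spectrum.
    """

    p: np.ndarray
    binning: EnergyBinning
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValidationError("p must be a square matrix")
        if np.any(p < -1e-12):
            raise ValidationError("matrix entries must be non-negative")
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValidationError("matrix entries must sum to 1")

    @property
    def row_sums(self) -> np.ndarray:
        return np.asarray(self.p).sum(axis=1)

    def conditional(self) -> np.ndarray:
        """Row-normalized map p(n | m), used by the spectral imaging model."""
        rows = self.row_sums
        return np.asarray(self.p) / rows[:, None]

    def to_csv(self, path) -> None:
        import pandas as pd
        e = self.binning.edges
        names = [f"{e[m]:g}-{e[m+1]:g}keV" for m in range(self.binning.n_bins)]
        pd.DataFrame(self.p, index=names, columns=names).to_csv(
            path, index_label="incident\\reconstructed")


def _spectrum_on_grid(spectrum, e_coords, w_e):
    if spectrum is None:
        n = np.full(e_coords.size, 1.0 / (e_coords[-1] - e_coords[0]))
    elif callable(spectrum):
        n = np.asarray(spectrum(e_coords), dtype=float)
    else:
        n = np.asarray(spectrum, dtype=float)
        if n.shape != e_coords.shape:
            raise ValidationError(
                "spectrum array must match the quadrature energy grid")
    if np.any(n < 0):
        raise ValidationError("incident spectrum must be non-negative")
    total = float(n @ w_e)
    if abs(total - 1.0) > 1e-6:
        log.warning("incident spectrum not normalized (integral %.6g); "
                    "auto-normalizing", total)
        n = n / total
    return n


def reconstruction_matrix(stack: LayerStack, spectrum=None,
                          binning: EnergyBinning | None = None,
                          n_z: int = 2000, de: float = 0.25
                          ) -> ReconstructionMatrix:
    """Build p^(mn) from the analytic absorption model.

    ``spectrum`` is the incident N(E): None for uniform, a callable of E, or
    an array on the quadrature grid.  The joint density
    N(E_inc) * integral p_abs(z, E_inc) p_det(z, E_det) dz is normalized
    globally so the matrix is a proper joint distribution.
    """
    binning = binning or EnergyBinning()
    _, ev_z, w_z = depth_grid(stack, n_z)
    e_coords, ev_e, w_e, bin_idx = energy_grid(binning, de)
    A = absorption_per_length(stack, ev_z, ev_e)          # (n_z, n_E)
    denom_e = A @ w_e                                     # (n_z,)
    denom_z = w_z @ A                                     # (n_E,)
    if np.min(denom_z) < 1e-300:
        raise DegenerateInputError("stack transparent on part of the range")
    n_spec = _spectrum_on_grid(spectrum, e_coords, w_e)
    pa = A / denom_z[None, :]                             # p_abs(z, E_inc)
    # depths no X-ray reaches (tau underflow in an opaque stack) carry zero
    # absorption weight; p_det is irrelevant there and set to 0
    safe = denom_e > 1e-300
    pd_ = np.where(safe[:, None], A / np.where(safe, denom_e, 1.0)[:, None],
                   0.0)
    joint = (n_spec[:, None]) * (pa.T * w_z[None, :]) @ pd_   # (E_inc, E_det)
    total = w_e @ joint @ w_e
    joint = joint / total
    M = binning.n_bins
    p = np.empty((M, M))
    for m in range(M):
        wm = w_e * (bin_idx == m)
        for n in range(M):
            wn = w_e * (bin_idx == n)
            p[m, n] = wm @ joint @ wn
    return ReconstructionMatrix(p / p.sum(), binning,
                                meta={"n_z": n_z, "de": de})


def eta(matrix: ReconstructionMatrix | np.ndarray) -> float:
    """Energy reconstruction accuracy: the diagonal mass of p^(mn)."""
    p = matrix.p if isinstance(matrix, ReconstructionMatrix) else np.asarray(matrix)
    return float(np.trace(p))


def analytic_eta(stack: LayerStack, spectrum=None,
                 binning: EnergyBinning | None = None,
                 n_z: int = 2000, de: float = 0.25) -> float:
    """Convenience: eta of the analytic reconstruction matrix."""
    return eta(reconstruction_matrix(stack, spectrum, binning, n_z, de))


# ------------------------------------------------------------ optimization
def optimize_thicknesses(stack: LayerStack, total_bound: float,
                         box: tuple[float, float] = (0.01, 3.5),
                         n_starts: int = 8, seed: int = 0,
                         n_z: int = 600, de: float = 0.5,
                         binning: EnergyBinning | None = None):
    """Maximize analytic eta over layer thicknesses, sum(d) <= total_bound.

    Multi-start SLSQP inside the box; deterministic for a fixed seed.
    Returns (thicknesses, eta_at_optimum).
    """
    n_layers = len(stack.layers)
    lo, hi = box
    if total_bound < n_layers * lo:
        raise ValidationError("total thickness bound infeasible for the box")
    rng = np.random.default_rng(seed)
    binning = binning or EnergyBinning()

    def neg_eta(d):
        return -analytic_eta(stack.with_thicknesses(np.clip(d, lo, hi)),
                             binning=binning, n_z=n_z, de=de)

    best_d, best_val = None, np.inf
    starts = [np.full(n_layers, min(hi, total_bound / n_layers))]
    while len(starts) < n_starts:
        d = rng.uniform(lo, hi, n_layers)
        if d.sum() > total_bound:
            d *= total_bound / d.sum()
        if np.all(d >= lo):
            starts.append(d)
    cons = [{"type": "ineq", "fun": lambda d: total_bound - np.sum(d)}]
    for d0 in starts:
        res = optimize.minimize(neg_eta, d0, method="SLSQP",
                                bounds=[(lo, hi)] * n_layers,
                                constraints=cons,
                                options={"maxiter": 60, "ftol": 1e-7})
        if res.fun < best_val:
            best_val, best_d = res.fun, np.clip(res.x, lo, hi)
    final = analytic_eta(stack.with_thicknesses(best_d), binning=binning,
                         n_z=max(n_z, 2000), de=min(de, 0.25))
    return best_d, final
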