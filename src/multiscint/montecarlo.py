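"""Desk-scale stochastic simulator of multicolor scintillation frames.

Event-level replacement for a full particle-transport code, with
deliberately simplified physics (documented in the methods note):

* X-ray interaction: photoelectric-style total absorption at a single point.
  The absorption depth is drawn from the piecewise-exponential survival law
  through the stack by inverse-CDF sampling; an X-ray passes through
  unabsorbed with probability exp(-sum mu_i d_i).
* Scintillation: the photon count is Poisson with mean (light yield x
  deposited energy x detection efficiency); emission is isotropic.  Only
  downward-going photons within the total-internal-reflection cutoff of the
  detector normal (default 25 deg) can reach the detector, so surviving
  directions are drawn directly from the spherical cap (thinned Poisson).
* Optical transport: straight rays.  A photon emitted at height h above the
  detector plane lands at lateral offset h * tan(theta) along its azimuth.
* Angular filter: an idealized nanophotonic cutoff that removes photons with
  polar angle >= theta_c (default 15 deg) emitted in the layers above the
  bottom scintillator.

All randomness flows through one numpy Generator; a fixed seed reproduces
frames bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import RangeError, ValidationError
from .materials import E_MAX, E_MIN, LayerStack

CHANNELS = ("R", "G", "B")


@dataclass(frozen=True)
class DetectorGeometry:
    """Square detector of side ``side_mm`` with pixel pitch ``pitch_um``."""

    side_mm: float = 12.8
    pitch_um: float = 25.0

    def __post_init__(self):
        if self.side_mm <= 0 or self.pitch_um <= 0:
            raise ValidationError("detector side and pixel pitch must be positive")

    @property
    def n_pixels(self) -> int:
        return int(round(self.side_mm * 1000.0 / self.pitch_um))


@dataclass(frozen=True)
class AngularFilterModel:
    """Idealized angular filter below the upper scintillator layers.

    ``kind`` is "none" or "ideal-cutoff".  The filter removes photons with
    polar angle >= ``cutoff_deg`` emitted in the layers it acts on (by
    default every layer above the bottom scintillator); photons beyond
    ``tir_deg`` never reach the detector in any case.
    """

    kind: str = "none"
    cutoff_deg: float = 15.0
    tir_deg: float = 25.0
    acts_above_layer: int | None = None   # default: n_layers - 1

    def __post_init__(self):
        if self.kind not in ("none", "ideal-cutoff"):
            raise ValidationError("filter kind must be 'none' or 'ideal-cutoff'")
        if not (0.0 < self.cutoff_deg <= self.tir_deg):
            raise ValidationError("need 0 < cutoff angle <= TIR cutoff")

    def max_angle_deg(self, layer: int, n_layers: int) -> float:
        """Largest polar angle that survives for a photon born in ``layer``."""
        if self.kind == "none":
            return self.tir_deg
        boundary = (n_layers - 1 if self.acts_above_layer is None
                    else self.acts_above_layer)
        return self.cutoff_deg if layer < boundary else self.tir_deg


def filtered_fraction(cutoff_deg: float, tir_deg: float = 25.0) -> float:
    """Fraction of detector-reaching photons removed by an ideal filter.

    Isotropic emission restricted to the downward TIR cap has solid angle
    proportional to (1 - cos theta_TIR); the filter keeps only the inner cap,
    so the removed fraction is 1 - (1 - cos theta_c) / (1 - cos theta_TIR).
    """
    if not (0.0 < cutoff_deg <= tir_deg):
        raise ValidationError("need 0 < cutoff angle <= TIR cutoff")
    tc, tt = np.radians(cutoff_deg), np.radians(tir_deg)
    return float(1.0 - (1.0 - np.cos(tc)) / (1.0 - np.cos(tt)))


def geometric_acceptance(max_angle_deg: float) -> float:
    """Fraction of isotropically emitted photons inside the downward cap."""
    return float((1.0 - np.cos(np.radians(max_angle_deg))) / 2.0)


# ------------------------------------------------------------- interaction
def sample_interaction(stack: LayerStack, energy, rng: np.random.Generator,
                       n: int | None = None):
    """Sample absorption depths for X-rays of the given energies.

    ``energy`` may be a scalar (with ``n`` copies) or an array of per-event
    energies.  Returns (layer_index, z): layer_index is -1 and z is NaN for
    passthrough events.
    """
    if n is not None:
        e = np.full(n, float(energy))
    else:
        e = np.atleast_1d(np.asarray(energy, dtype=float))
    if np.any(e < E_MIN) or np.any(e > E_MAX):
        raise RangeError(f"energy outside [{E_MIN}, {E_MAX}] keV")
    mu = stack.mu_profile(e)                          # (n_layers, n_ev)
    d = np.array([l.thickness_mm for l in stack.layers])
    tau_edges = np.vstack([np.zeros(e.size),
                           np.cumsum(mu * d[:, None], axis=0)])  # (L+1, n_ev)
    u = rng.random(e.size)
    target = -np.log1p(-u)                            # exponential optical depth
    tau_total = tau_edges[-1]
    passthrough = target >= tau_total
    layer = np.sum(target[None, :] >= tau_edges[1:], axis=0)  # first layer with
    layer = np.clip(layer, 0, len(stack.layers) - 1)          # tau_edge > target
    z0 = stack.boundaries[layer]
    with np.errstate(invalid="ignore"):
        z = z0 + (target - tau_edges[layer, np.arange(e.size)]) / \
            mu[layer, np.arange(e.size)]
    layer = np.where(passthrough, -1, layer)
    z = np.where(passthrough, np.nan, z)
    return layer, z


# --------------------------------------------------------------- emission
def emit_photons(stack: LayerStack, layer: int, z: float, energy: float,
                 x: float, y: float, rng: np.random.Generator,
                 filt: AngularFilterModel | None = None,
                 efficiency: float = 1.0):
    """Optical hits on the detector plane from one absorbed X-ray.

    Returns (hx, hy) arrays of hit coordinates; the emission channel is the
    layer's channel.  The Poisson photon budget (yield x E) is thinned by the
    geometric acceptance of the allowed angular cap before sampling, which is
    statistically identical to emitting isotropically and discarding.
    """
    filt = filt or AngularFilterModel()
    props = stack.layers[layer].props
    max_ang = filt.max_angle_deg(layer, len(stack.layers))
    lam = props.light_yield * energy * efficiency * geometric_acceptance(max_ang)
    k = rng.poisson(lam)
    cos_max = np.cos(np.radians(max_ang))
    cos_t = rng.uniform(cos_max, 1.0, k)
    tan_t = np.sqrt(1.0 - cos_t ** 2) / cos_t
    phi = rng.uniform(0.0, 2.0 * np.pi, k)
    h = stack.total_thickness - z
    r = h * tan_t
    return x + r * np.cos(phi), y + r * np.sin(phi)


def _emit_batch(stack, layers, z, energies, xs, ys, rng, filt, efficiency):
    """Vectorized emission for many absorbed events.

    Returns (hx, hy, channel_idx, event_idx) flat hit arrays.
    """
    filt = filt or AngularFilterModel()
    n_layers = len(stack.layers)
    yields = np.array([l.props.light_yield for l in stack.layers])
    max_ang = np.array([filt.max_angle_deg(i, n_layers)
                        for i in range(n_layers)])
    acc = (1.0 - np.cos(np.radians(max_ang))) / 2.0
    lam = yields[layers] * energies * efficiency * acc[layers]
    counts = rng.poisson(lam)
    total = int(counts.sum())
    ev_idx = np.repeat(np.arange(layers.size), counts)
    cos_max_ev = np.cos(np.radians(max_ang))[layers]
    cos_t = rng.uniform(np.repeat(cos_max_ev, counts), 1.0)
    tan_t = np.sqrt(np.clip(1.0 - cos_t ** 2, 0.0, None)) / cos_t
    phi = rng.uniform(0.0, 2.0 * np.pi, total)
    h = stack.total_thickness - z
    r = np.repeat(h, counts) * tan_t
    hx = np.repeat(xs, counts) + r * np.cos(phi)
    hy = np.repeat(ys, counts) + r * np.sin(phi)
    ch_by_layer = np.array([CHANNELS.index(l.props.channel)
                            for l in stack.layers])
    return hx, hy, ch_by_layer[layers][ev_idx], ev_idx


# ------------------------------------------------------------------ frames
@dataclass
class Frame:
    """One detector exposure: hits, rendered image, and ground truth."""

    geometry: DetectorGeometry
    hits: pd.DataFrame            # columns x_mm, y_mm, channel, event_id
    image: np.ndarray             # (npix, npix, 3) uint16 counts
    events: pd.DataFrame          # per event: x, y, energy, layer, z
    seed: int
    n_dropped: int = 0            # hits outside the detector bounds
    meta: dict = field(default_factory=dict)

    @property
    def channel_totals(self) -> np.ndarray:
        return self.image.sum(axis=(0, 1))


def render_frame(hit_xy: np.ndarray, hit_channel: np.ndarray,
                 geometry: DetectorGeometry):
    """Rasterize hits into per-channel pixel counts; out-of-bounds drop.

    Returns (image, inside_mask).
    """
    npix = geometry.n_pixels
    if npix <= 0:
        raise ValidationError("non-positive pixel count")
    side = geometry.side_mm
    x, y = hit_xy[:, 0], hit_xy[:, 1]
    inside = (x >= 0) & (x < side) & (y >= 0) & (y < side)
    ix = np.floor(x[inside] / side * npix).astype(int)
    iy = np.floor(y[inside] / side * npix).astype(int)
    img = np.zeros((npix, npix, 3), dtype=np.uint16)
    ch = np.asarray(hit_channel)[inside]
    np.add.at(img, (iy, ix, ch), 1)
    return img, inside


def simulate_frame(stack: LayerStack, n_xrays: int,
                   rng: np.random.Generator | int,
                   geometry: DetectorGeometry | None = None,
                   filt: AngularFilterModel | None = None,
                   efficiency: float = 1.0,
                   energies: np.ndarray | None = None,
                   positions: np.ndarray | None = None,
                   render: bool = True) -> Frame:
    """Simulate one frame with ``n_xrays`` incident photons.

    Energies default to uniform over 16-67 keV and lateral positions to
    uniform over the detector area.
    """
    seed = rng if isinstance(rng, (int, np.integer)) else -1
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    geometry = geometry or DetectorGeometry()
    if energies is None:
        energies = rng.uniform(E_MIN, E_MAX, n_xrays)
    else:
        energies = np.asarray(energies, dtype=float)
    if positions is None:
        positions = rng.uniform(0.0, geometry.side_mm, (n_xrays, 2))
    layer, z = sample_interaction(stack, energies, rng)
    absorbed = layer >= 0
    hx, hy, ch, ev_local = _emit_batch(
        stack, layer[absorbed], z[absorbed], energies[absorbed],
        positions[absorbed, 0], positions[absorbed, 1], rng, filt, efficiency)
    ev_ids = np.flatnonzero(absorbed)[ev_local]
    if render:
        img, inside = render_frame(np.column_stack([hx, hy]), ch, geometry)
    else:
        img = np.zeros((1, 1, 3), dtype=np.uint16)
        inside = np.ones(hx.size, dtype=bool)
    hits = pd.DataFrame({"x_mm": hx[inside], "y_mm": hy[inside],
                         "channel": ch[inside], "event_id": ev_ids[inside]})
    events = pd.DataFrame({"x_mm": positions[:, 0], "y_mm": positions[:, 1],
                           "energy_kev": energies, "layer": layer, "z_mm": z})
    return Frame(geometry=geometry, hits=hits, image=img, events=events,
                 seed=int(seed), n_dropped=int(np.count_nonzero(~inside)))


def write_frame(frame: Frame, tiff_path=None, csv_path=None) -> None:
    """Persist a frame as 16-bit 3-channel TIFF and/or a CSV hit table."""
    if tiff_path is not None:
        import tifffile
        tifffile.imwrite(tiff_path, frame.image)
    if csv_path is not None:
        frame.hits.to_csv(csv_path, index=False)
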