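"""Empirical energy reconstruction from spot color and radius.

The analytic depth-conditional energy distribution is not observable on a
real detector; what is observable is each spot's dominant color (which layer
absorbed the X-ray) and effective radius r_c (how far above the detector the
light was born).  The reconstruction therefore replaces depth with the pair
(color, r_c): labeled single-X-ray simulations, swept over the energy grid
in 1 keV steps, build an empirical conditional distribution
p(E_det | color, radius bin), and a measured spot is classified into the
energy bin with the largest posterior mass.

Radii are binned into 32 equal-width bins spanning [0, 99th percentile of
the calibration radii] with overflow into the last bin; counts receive
additive (+0.5) smoothing before normalization so that desk-scale sample
sizes never produce hard zero posteriors.  Events that yield no surviving
optical photon are invisible to the detector; they are excluded from
calibration and reported separately as unclassifiable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .absorption import EnergyBinning
from .clustering import ClusterFeatures
from .errors import ValidationError
from .materials import E_MAX, E_MIN, LayerStack
from .montecarlo import AngularFilterModel, _emit_batch, sample_interaction

log = logging.getLogger(__name__)

N_RADIUS_BINS = 32
FORMAT_VERSION = 1
CHANNELS = ("R", "G", "B")


@dataclass
class CalibrationTable:
    """Empirical counts N(channel, radius bin, energy) plus conditionals."""

    radius_edges: np.ndarray            # (N_RADIUS_BINS + 1,) in mm
    energies: np.ndarray                # keV grid, 1 keV steps
    counts: np.ndarray                  # (3, n_rbins, n_E) int64
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.counts.shape != (len(CHANNELS), len(self.radius_edges) - 1,
                                 len(self.energies)):
            raise ValidationError("counts shape inconsistent with axes")

    # -------------------------------------------------------------- access
    @property
    def cell_totals(self) -> np.ndarray:
        """Raw event counts per (channel, radius-bin) cell."""
        return self.counts.sum(axis=2)

    def conditionals(self, smoothing: float = 0.5) -> np.ndarray:
        """p(E | channel, radius bin) with additive smoothing; sums to 1."""
        sm = self.counts + smoothing
        return sm / sm.sum(axis=2, keepdims=True)

    def channel_marginals(self, smoothing: float = 0.5) -> np.ndarray:
        """Fallback p(E | channel) for empty (channel, radius) cells."""
        per_ch = self.counts.sum(axis=1) + smoothing
        return per_ch / per_ch.sum(axis=1, keepdims=True)

    def radius_bin(self, r_c) -> np.ndarray:
        """Radius-bin index with overflow clamped into the last bin."""
        idx = np.searchsorted(self.radius_edges, np.asarray(r_c), side="right") - 1
        return np.clip(idx, 0, len(self.radius_edges) - 2)

    # ----------------------------------------------------------------- I/O
    def to_json(self, path) -> None:
        doc = {"format_version": FORMAT_VERSION,
               "radius_edges_mm": self.radius_edges.tolist(),
               "energies_kev": self.energies.tolist(),
               "counts": self.counts.tolist(),
               "meta": self.meta}
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "CalibrationTable":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format_version") != FORMAT_VERSION:
            raise ValidationError("unsupported calibration table version")
        return cls(radius_edges=np.asarray(doc["radius_edges_mm"]),
                   energies=np.asarray(doc["energies_kev"]),
                   counts=np.asarray(doc["counts"], dtype=np.int64),
                   meta=doc.get("meta", {}))


# ------------------------------------------------------------- simulation
def _simulate_features(stack: LayerStack, energies: np.ndarray,
                       rng: np.random.Generator,
                       filt: AngularFilterModel | None,
                       efficiency: float):
    """Per-event (channel index, r_c, detected mask) for single-X-ray events.

    Each incident X-ray makes at most one spot, so features come straight
    from its own hits (the clustering step is an identity for single-photon
    frames).  Events with no absorbed X-ray or no surviving photon are
    flagged undetected.
    """
    n = energies.size
    layer, z = sample_interaction(stack, energies, rng)
    absorbed = layer >= 0
    idx_abs = np.flatnonzero(absorbed)
    zeros = np.zeros(idx_abs.size)
    hx, hy, ch, ev_local = _emit_batch(
        stack, layer[absorbed], z[absorbed], energies[absorbed],
        zeros, zeros, rng, filt, efficiency)
    k = np.bincount(ev_local, minlength=idx_abs.size).astype(float)
    detected_local = k > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        cx = np.bincount(ev_local, weights=hx, minlength=idx_abs.size) / k
        cy = np.bincount(ev_local, weights=hy, minlength=idx_abs.size) / k
        dist = np.hypot(hx - cx[ev_local], hy - cy[ev_local])
        r_c = np.bincount(ev_local, weights=dist, minlength=idx_abs.size) / k
    channel = np.full(n, -1, dtype=int)
    radius = np.full(n, np.nan)
    detected = np.zeros(n, dtype=bool)
    ch_of_layer = np.array([CHANNELS.index(l.props.channel)
                            for l in stack.layers])
    channel[idx_abs[detected_local]] = ch_of_layer[layer[absorbed]][detected_local]
    radius[idx_abs[detected_local]] = r_c[detected_local]
    detected[idx_abs[detected_local]] = True
    return channel, radius, detected


def calibrate(stack: LayerStack, n_per_energy: int = 2000,
              rng: np.random.Generator | int = 0,
              filt: AngularFilterModel | None = None,
              efficiency: float = 1.0,
              energies: np.ndarray | None = None,
              radius_edges: np.ndarray | None = None) -> CalibrationTable:
    """Build the (color, radius)-conditioned energy table from simulations.

    Runs ``n_per_energy`` single-X-ray simulations at every grid energy
    (default 16..67 keV in 1 keV steps), extracts each spot's channel and
    effective radius, and accumulates counts.  Radius-bin edges span
    [0, 99th percentile] of all calibration radii.
    """
    if n_per_energy < 100:
        raise ValidationError("n_per_energy must be at least 100")
    if not any(l.props.light_yield > 0 for l in stack.layers):
        raise ValidationError("stack has no optical yield")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    energies = (np.arange(E_MIN, E_MAX + 0.5, 1.0) if energies is None
                else np.asarray(energies, dtype=float))
    ch_all, r_all, e_all = [], [], []
    n_undetected = 0
    for e in energies:
        ch, r_c, det = _simulate_features(
            stack, np.full(n_per_energy, e), rng, filt, efficiency)
        n_undetected += int(np.count_nonzero(~det))
        ch_all.append(ch[det])
        r_all.append(r_c[det])
        e_all.append(np.full(np.count_nonzero(det), e))
    ch_all = np.concatenate(ch_all)
    r_all = np.concatenate(r_all)
    e_all = np.concatenate(e_all)
    if radius_edges is not None:
        edges = np.asarray(radius_edges, dtype=float)
    else:
        r_cap = float(np.percentile(r_all, 99.0)) if r_all.size else 1.0
        edges = np.linspace(0.0, max(r_cap, 1e-6), N_RADIUS_BINS + 1)
    n_rb = len(edges) - 1
    rbin = np.clip(np.searchsorted(edges, r_all, side="right") - 1, 0, n_rb - 1)
    e_idx = np.searchsorted(energies, e_all)
    counts = np.zeros((len(CHANNELS), n_rb, energies.size), dtype=np.int64)
    np.add.at(counts, (ch_all, rbin, e_idx), 1)
    empty = int(np.count_nonzero(counts.sum(axis=2) == 0))
    if empty:
        log.info("calibration left %d empty (channel, radius) cells", empty)
    meta = {"n_per_energy": int(n_per_energy),
            "n_undetected": int(n_undetected),
            "efficiency": float(efficiency),
            "layers": [l.name for l in stack.layers],
            "total_thickness_mm": stack.total_thickness}
    return CalibrationTable(radius_edges=edges, energies=energies,
                            counts=counts, meta=meta)


# ----------------------------------------------------------- classification
def bin_posteriors(table: CalibrationTable,
                   binning: EnergyBinning | None = None) -> np.ndarray:
    """Precomputed p(bin | channel, radius bin); shape (3, n_rbins, M)."""
    binning = binning or EnergyBinning()
    cond = table.conditionals()
    marg = table.channel_marginals()
    empty = table.cell_totals == 0
    if np.any(empty):
        cond = np.where(empty[:, :, None], marg[:, None, :], cond)
    bins = binning.bin_of(table.energies)
    M = binning.n_bins
    post = np.stack([cond[:, :, bins == m].sum(axis=2) for m in range(M)],
                    axis=2)
    return post / post.sum(axis=2, keepdims=True)


def classify(features: ClusterFeatures, table: CalibrationTable,
             binning: EnergyBinning | None = None):
    """Per-bin posterior probabilities and the MAP energy bin of one spot.

    Empty (channel, radius) cells fall back to the channel marginal with a
    logged warning; posterior ties resolve to the lower bin.
    """
    binning = binning or EnergyBinning()
    ch = CHANNELS.index(features.channel)
    rbin = int(table.radius_bin(features.radius))
    if table.cell_totals[ch, rbin] == 0:
        log.warning("empty calibration cell (channel=%s, radius bin %d); "
                    "falling back to channel marginal", features.channel, rbin)
    probs = bin_posteriors(table, binning)[ch, rbin]
    return probs, int(np.argmax(probs))


@dataclass(frozen=True)
class EmpiricalAccuracy:
    """MAP accuracy with its binomial standard error and diagnostics."""

    eta: float
    se: float
    confusion: np.ndarray        # (M, M) joint proportions over classified events
    soft_eta: float              # posterior mass on the true bin, averaged
    n_classified: int
    n_unclassified: int


def empirical_eta(stack: LayerStack, table: CalibrationTable,
                  n_test: int = 10_000,
                  rng: np.random.Generator | int = 0,
                  binning: EnergyBinning | None = None,
                  filt: AngularFilterModel | None = None,
                  efficiency: float = 1.0,
                  guess_uniform: bool = False) -> EmpiricalAccuracy:
    """Monte Carlo estimate of the energy reconstruction accuracy.

    Simulates ``n_test`` labeled events with energies uniform over the
    working range, classifies each detected spot, and returns the diagonal
    mass of the jointly normalized confusion matrix.  ``guess_uniform``
    replaces the classifier with a uniform random guess (the 1/M floor
    ablation).
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    binning = binning or EnergyBinning()
    M = binning.n_bins
    energies = rng.uniform(E_MIN, E_MAX, n_test)
    truth = binning.bin_of(energies)
    channel, radius, detected = _simulate_features(
        stack, energies, rng, filt, efficiency)
    truth_d = truth[detected]
    n_cls = int(truth_d.size)
    if guess_uniform:
        pred = rng.integers(0, M, n_cls)
        soft = np.full((n_cls, M), 1.0 / M)
    else:
        post = bin_posteriors(table, binning)
        rbin = table.radius_bin(radius[detected])
        soft = post[channel[detected], rbin]
        pred = np.argmax(soft, axis=1)
    raw = np.zeros((M, M))
    np.add.at(raw, (truth_d, pred), 1.0)
    # weight incident bins by the spectrum prior, as in the analytic map:
    # rows are conditioned on their own classified counts, then scaled so the
    # matrix is a joint distribution whose row sums equal the bin weights.
    row_n = raw.sum(axis=1)
    w = binning.bin_weights
    conf = np.where(row_n[:, None] > 0, raw / np.maximum(row_n, 1)[:, None],
                    0.0) * w[:, None]
    eta_hat = float(np.trace(conf))
    # binomial error propagated per row through the fixed weights
    diag_p = np.where(row_n > 0, np.diag(raw) / np.maximum(row_n, 1), 0.0)
    se = float(np.sqrt(np.sum(
        w ** 2 * diag_p * (1.0 - diag_p) / np.maximum(row_n, 1))))
    soft_eta = float(np.mean(soft[np.arange(n_cls), truth_d])) if n_cls else 0.0
    return EmpiricalAccuracy(eta=eta_hat, se=se, confusion=conf,
                             soft_eta=soft_eta, n_classified=n_cls,
                             n_unclassified=int(n_test - n_cls))
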