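"""Accuracy bounds for three-bin energy reconstruction.

The floor is uniform random guessing: 1/M (33.3% for three bins).  The
physically-constrained ceiling comes from optimizing the analytic accuracy
over a family of hypothetical scintillators whose attenuation follows the
photoelectric-like parametric form mu(E) = E^a exp[b + c H(E - E_K)] with
a < 0.  K-edge energies are fixed by the contrast-agent chemistry (33 keV
bottom, 50 keV middle; the top layer carries no edge in range), the three
layers share a common thickness, and the nine remaining parameters
(a, b, c per layer) are optimized for each thickness in a sweep
(0.01-3.5 mm by default) with multi-start bounded quasi-Newton searches.

Default parameter boxes are generous neighborhoods of the packaged surrogate
materials' parameters; fits to measured attenuation data can be supplied to
reproduce bounds for real material families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .absorption import EnergyBinning, analytic_eta
from .errors import ValidationError
from .materials import AttenuationModel, LayerStack, surrogate_stack

DEFAULT_BOXES = (
    # (a_lo, a_hi), (b_lo, b_hi), (c_lo, c_hi) per layer, top to bottom
    ((-3.5, -1.5), (6.0, 12.0), (0.0, 0.0)),
    ((-3.5, -1.5), (6.0, 12.0), (0.0, 2.5)),
    ((-3.5, -1.5), (6.0, 12.0), (0.0, 2.5)),
)
DEFAULT_EDGES = (None, 50.0, 33.0)   # K-edge per layer, top to bottom


def lower_bound(n_bins: int = 3) -> float:
    """Accuracy of uniformly random bin guessing: 1/M."""
    if n_bins < 1:
        raise ValidationError("number of bins must be at least 1")
    return 1.0 / n_bins


@dataclass(frozen=True)
class BoundSearchSpace:
    """Per-layer (a, b, c) boxes with fixed K-edges and a thickness sweep."""

    boxes: tuple = DEFAULT_BOXES
    k_edges: tuple = DEFAULT_EDGES
    thickness_sweep: tuple[float, ...] = tuple(np.linspace(0.01, 3.5, 8))

    def __post_init__(self):
        if len(self.boxes) != 3 or len(self.k_edges) != 3:
            raise ValidationError("exactly three layers are expected")
        for (a_box, _b_box, c_box) in self.boxes:
            if a_box[1] >= 0:
                raise ValidationError("a-boxes must be entirely negative")
            if c_box[0] < 0:
                raise ValidationError("c-boxes must be non-negative")
        if len(self.thickness_sweep) == 0:
            raise ValidationError("thickness sweep must not be empty")


def _stack_from_params(params: np.ndarray, k_edges, thickness: float
                       ) -> LayerStack:
    """Three-layer stack with parametric attenuation set from a 9-vector."""
    template = surrogate_stack(thickness)
    layers = []
    for i, layer in enumerate(template.layers):
        a, b, c = params[3 * i: 3 * i + 3]
        e_k = k_edges[i]
        model = AttenuationModel.parametric(
            a, b, c if e_k is not None else 0.0, e_k)
        layers.append(type(layer)(layer.name, model, layer.props,
                                  thickness))
    return LayerStack(tuple(layers))


@dataclass(frozen=True)
class UpperBoundResult:
    thicknesses: np.ndarray
    accuracies: np.ndarray
    parameters: np.ndarray       # (n_thickness, 9)
    best_accuracy: float = field(default=0.0)

    def to_csv(self, path) -> None:
        import pandas as pd
        cols = [f"{p}{i}" for i in (1, 2, 3) for p in ("a", "b", "c")]
        df = pd.DataFrame(self.parameters, columns=cols)
        df.insert(0, "thickness_mm", self.thicknesses)
        df.insert(1, "accuracy", self.accuracies)
        df.to_csv(path, index=False)


def upper_bound(space: BoundSearchSpace = BoundSearchSpace(),
                n_starts: int = 16, seed: int = 0,
                n_z: int = 400, de: float = 0.5,
                binning: EnergyBinning | None = None) -> UpperBoundResult:
    """Best analytic accuracy over the parametric space, per layer thickness.

    Multi-start L-BFGS-B with numeric gradients inside the parameter boxes;
    the problem is smooth in the parameters (the K-edge discontinuity lives
    on the energy axis only).  Deterministic for a fixed seed.
    """
    binning = binning or EnergyBinning()
    rng = np.random.default_rng(seed)
    lo = np.array([v for box in space.boxes for v in
                   (box[0][0], box[1][0], box[2][0])])
    hi = np.array([v for box in space.boxes for v in
                   (box[0][1], box[1][1], box[2][1])])
    free = hi > lo
    accs, params_out = [], []
    starts = rng.uniform(lo[None, :], np.where(free, hi, lo + 1)[None, :],
                         (n_starts, 9))
    starts = np.where(free[None, :], starts, lo[None, :])
    for d in space.thickness_sweep:

        def neg_eta(p):
            stack = _stack_from_params(np.clip(p, lo, hi), space.k_edges, d)
            return -analytic_eta(stack, binning=binning, n_z=n_z, de=de)

        best_val, best_p = np.inf, lo.copy()
        for p0 in starts:
            res = optimize.minimize(
                neg_eta, p0, method="L-BFGS-B",
                bounds=list(zip(lo, hi)),
                options={"maxiter": 40, "eps": 1e-4, "ftol": 1e-8})
            if res.fun < best_val:
                best_val, best_p = res.fun, np.clip(res.x, lo, hi)
        accs.append(-best_val)
        params_out.append(best_p)
    accs = np.asarray(accs)
    return UpperBoundResult(np.asarray(space.thickness_sweep, dtype=float),
                            accs, np.asarray(params_out),
                            best_accuracy=float(accs.max()))
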