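"""Materials and multilayer scintillator stacks.

Everything downstream (absorption analytics, Monte Carlo sampling, phantom
imaging) consumes materials through a single interface: the energy-dependent
linear attenuation coefficient ``mu(E)`` in 1/mm over the working X-ray range
16-67 keV.  Two representations are supported:

* **tabulated** -- a (energy, mass attenuation) table in keV and cm^2/g plus a
  density, interpolated log-log between grid points.  K-edges are carried as an
  explicit edge list and interpolation never bridges an edge: the grid is split
  into inter-edge segments and each query energy is resolved inside its own
  segment (the edge energy itself belongs to the post-edge branch).
* **parametric** -- the photoelectric-like closed form

      mu(E) = E**a * exp(b + c * H(E - E_K))

  with ``a < 0`` (power-law decay), an overall scale ``exp(b)`` and a
  multiplicative K-edge jump ``exp(c)`` switched on by the Heaviside step
  ``H`` (``H(0) = 1``: the edge energy starts the post-edge branch).

Units are fixed package-wide: energies in keV, lengths in mm, densities in
g/cm^3, linear attenuation in 1/mm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml

from .errors import RangeError, ValidationError

log = logging.getLogger(__name__)

E_MIN = 16.0  #: lower end of the working energy range (keV)
E_MAX = 67.0  #: upper end of the working energy range (keV)

#: half-width of the exclusion window around a K-edge used to build
#: double grid points (E_K - eps on the pre-edge branch, E_K on the post-edge)
EDGE_EPS = 1e-6


def _heaviside(x: np.ndarray | float) -> np.ndarray | float:
    """H(x) = 1 for x >= 0 else 0 (the edge energy is post-edge)."""
    return np.where(np.asarray(x, dtype=float) >= 0.0, 1.0, 0.0)


@dataclass(frozen=True)
class AttenuationModel:
    """Energy-dependent attenuation of one material.

    Exactly one of the two parameter sets is populated, selected by ``kind``
    (``"parametric"`` or ``"tabulated"``).  Use the :meth:`parametric` /
    :meth:`tabulated` constructors rather than filling fields by hand.
    """

    kind: str
    # parametric fields
    a: float = 0.0
    b: float = 0.0
    c: float = 0.0
    e_k: float | None = None
    # tabulated fields
    energy: np.ndarray | None = None          # keV, ascending
    mass_atten: np.ndarray | None = None      # cm^2/g
    density: float | None = None              # g/cm^3
    k_edges: tuple[float, ...] = ()

    # ------------------------------------------------------------- builders
    @classmethod
    def parametric(cls, a: float, b: float, c: float = 0.0,
                   e_k: float | None = None) -> "AttenuationModel":
        if c != 0.0 and e_k is None:
            raise ValidationError("a K-edge jump c != 0 requires an edge energy")
        return cls(kind="parametric", a=float(a), b=float(b), c=float(c),
                   e_k=None if e_k is None else float(e_k),
                   k_edges=() if e_k is None else (float(e_k),))

    @classmethod
    def tabulated(cls, energy: Sequence[float], mass_atten: Sequence[float],
                  density: float, k_edges: Sequence[float] = ()) -> "AttenuationModel":
        e = np.asarray(energy, dtype=float)
        m = np.asarray(mass_atten, dtype=float)
        if e.ndim != 1 or e.shape != m.shape or e.size < 2:
            raise ValidationError("energy and mass_atten must be matching 1-D arrays")
        if np.any(np.diff(e) <= 0):
            raise ValidationError("energy grid must be strictly increasing")
        if np.any(m <= 0):
            raise ValidationError("mass attenuation values must be positive")
        if density <= 0:
            raise ValidationError("density must be positive")
        return cls(kind="tabulated", energy=e, mass_atten=m,
                   density=float(density),
                   k_edges=tuple(sorted(float(k) for k in k_edges)))

    # ------------------------------------------------------------ evaluation
    def mu(self, e_kev, density: float | None = None):
        """Linear attenuation coefficient in 1/mm at energies ``e_kev``.

        ``density`` overrides the stored density for tabulated models; it is
        ignored for parametric models, whose parameters define mu directly.
        """
        e = np.asarray(e_kev, dtype=float)
        if np.any(e < E_MIN - 1e-9) or np.any(e > E_MAX + 1e-9):
            raise RangeError(
                f"energy outside working range [{E_MIN}, {E_MAX}] keV")
        if self.kind == "parametric":
            out = np.power(e, self.a) * np.exp(self.b)
            if self.e_k is not None and self.c != 0.0:
                out = out * np.exp(self.c * _heaviside(e - self.e_k))
            return out if out.ndim else float(out)
        rho = self.density if density is None else float(density)
        # log-log interpolation, segment-wise so no interpolation spans an edge
        out = np.empty_like(e, dtype=float)
        flat_e = np.atleast_1d(e)
        flat_o = np.atleast_1d(out)
        edges = [k for k in self.k_edges if self.energy[0] < k < self.energy[-1]]
        seg_bounds = [-np.inf] + edges + [np.inf]
        loge, logm = np.log(self.energy), np.log(self.mass_atten)
        for lo, hi in zip(seg_bounds[:-1], seg_bounds[1:]):
            # query energy E belongs to segment [lo, hi): edge energy post-edge
            qsel = (flat_e >= lo) & (flat_e < hi)
            if not np.any(qsel):
                continue
            gsel = (self.energy >= lo) & (self.energy < hi)
            if gsel.sum() < 2:
                raise ValidationError(
                    "tabulated grid has fewer than two points between edges "
                    f"[{lo}, {hi}); edges must be carried as double points")
            flat_o[qsel] = np.exp(
                np.interp(np.log(flat_e[qsel]), loge[gsel], logm[gsel]))
        mu_mm = flat_o * rho / 10.0  # cm^2/g * g/cm^3 = 1/cm -> 1/mm
        mu_mm = mu_mm.reshape(e.shape)
        return mu_mm if mu_mm.ndim else float(mu_mm)

    def to_tabulated(self, density: float = 1.0,
                     de: float = 0.25) -> "AttenuationModel":
        """Sample a parametric model onto a tabulated grid (with edge doubling)."""
        if self.kind == "tabulated":
            return self
        grid = [np.arange(E_MIN, E_MAX + de / 2, de)]
        if self.e_k is not None and E_MIN < self.e_k < E_MAX:
            grid.append(np.array([self.e_k - EDGE_EPS, self.e_k]))
        e = np.unique(np.concatenate(grid))
        mu = np.asarray(self.mu(e))
        # store mass attenuation so that mu/rho * rho reproduces mu (in 1/mm)
        return AttenuationModel.tabulated(e, mu * 10.0 / density, density,
                                          k_edges=self.k_edges)


def linear_attenuation(model: AttenuationModel, density: float | None,
                       e_kev) -> float | np.ndarray:
    """Functional wrapper around :meth:`AttenuationModel.mu`."""
    return model.mu(e_kev, density=density)


# ---------------------------------------------------------------- mixtures
@dataclass(frozen=True)
class MassAttenuationCurve:
    """A mu/rho(E) curve (cm^2/g) on an explicit energy grid with K-edges."""

    energy: np.ndarray
    values: np.ndarray
    k_edges: tuple[float, ...] = ()

    def interp(self, e: np.ndarray) -> np.ndarray:
        model = AttenuationModel.tabulated(self.energy, self.values, 1.0,
                                           self.k_edges)
        return np.asarray(model.mu(e)) * 10.0  # undo 1/mm conversion


def mixture_mass_attenuation(
        components: Sequence[tuple[float, MassAttenuationCurve]],
        tol: float = 1e-9) -> MassAttenuationCurve:
    """Mass attenuation of a mixture: the weighted sum of component curves.

    Weight fractions must be non-negative and sum to one.  Components on
    different grids are resampled (log-log) onto the union grid first, with a
    logged warning; the K-edge list of the result is the union of the
    component edge lists.
    """
    if not components:
        raise ValidationError("mixture needs at least one component")
    weights = np.array([w for w, _ in components], dtype=float)
    if np.any(weights < 0):
        raise ValidationError("weight fractions must be non-negative")
    if abs(weights.sum() - 1.0) > tol:
        raise ValidationError(
            f"weight fractions must sum to 1 (got {weights.sum()!r})")
    curves = [c for _, c in components]
    grids = [c.energy for c in curves]
    same_grid = all(g.shape == grids[0].shape and np.allclose(g, grids[0])
                    for g in grids[1:])
    edges = tuple(sorted({e for c in curves for e in c.k_edges}))
    if same_grid:
        grid = grids[0]
        values = sum(w * c.values for w, c in zip(weights, curves))
    else:
        log.warning("mixture components on mismatched energy grids; "
                    "resampling onto the union grid")
        grid = np.unique(np.concatenate(grids))
        values = sum(w * c.interp(grid) for w, c in zip(weights, curves))
    return MassAttenuationCurve(grid, np.asarray(values), edges)


# ------------------------------------------------------- scintillator stacks
@dataclass(frozen=True)
class ScintillatorProps:
    """Optical properties of one scintillating layer."""

    light_yield: float          # photons per keV of deposited energy
    decay_time_ns: float
    refractive_index: float
    channel: str                # one of "R", "G", "B"

    def __post_init__(self):
        if self.light_yield <= 0:
            raise ValidationError("light yield must be positive")
        if self.channel not in ("R", "G", "B"):
            raise ValidationError("channel must be one of R, G, B")


@dataclass(frozen=True)
class Layer:
    name: str
    attenuation: AttenuationModel
    props: ScintillatorProps
    thickness_mm: float

    def __post_init__(self):
        if self.thickness_mm <= 0:
            raise ValidationError("layer thickness must be positive")

    def mu(self, e_kev):
        return self.attenuation.mu(e_kev)


@dataclass(frozen=True)
class LayerStack:
    """Ordered scintillator layers, indexed from the X-ray entry side.

    The depth coordinate z runs from 0 at the top surface to the total
    thickness L at the detector side.
    """

    layers: tuple[Layer, ...]

    def __post_init__(self):
        if not self.layers:
            raise ValidationError("a stack needs at least one layer")
        channels = [l.props.channel for l in self.layers]
        if len(set(channels)) != len(channels):
            raise ValidationError("each layer must emit in a distinct channel")

    @property
    def total_thickness(self) -> float:
        return float(sum(l.thickness_mm for l in self.layers))

    @property
    def boundaries(self) -> np.ndarray:
        """Depths of the layer interfaces, [0, d_1, d_1+d_2, ..., L] in mm."""
        return np.concatenate(
            [[0.0], np.cumsum([l.thickness_mm for l in self.layers])])

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(l.props.channel for l in self.layers)

    def layer_index(self, z) -> np.ndarray:
        """Index of the layer containing depth z (boundary belongs below)."""
        b = self.boundaries
        z = np.asarray(z, dtype=float)
        if np.any(z < -1e-12) or np.any(z > self.total_thickness + 1e-12):
            raise RangeError("depth outside [0, L]")
        idx = np.clip(np.searchsorted(b, z, side="right") - 1,
                      0, len(self.layers) - 1)
        return idx

    def mu_profile(self, e_kev) -> np.ndarray:
        """mu_i(E) for every layer; shape (n_layers,) + shape(E)."""
        return np.stack([np.asarray(l.mu(e_kev), dtype=float)
                         for l in self.layers])

    def delta_mu(self, i: int, j: int, e_kev):
        """Pairwise attenuation contrast mu_i(E) - mu_j(E) (1-based indices)."""
        return (np.asarray(self.layers[i - 1].mu(e_kev))
                - np.asarray(self.layers[j - 1].mu(e_kev)))

    def with_thicknesses(self, thicknesses: Sequence[float]) -> "LayerStack":
        if len(thicknesses) != len(self.layers):
            raise ValidationError("one thickness per layer required")
        return LayerStack(tuple(replace(l, thickness_mm=float(d))
                                for l, d in zip(self.layers, thicknesses)))

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_yaml(cls, path) -> "LayerStack":
        """Load a stack description: a list of layers, top to bottom.

        Each layer entry carries ``material``, ``thickness_mm``,
        ``yield_per_keV``, ``channel`` and either a ``parametric`` block
        (a, b, c, e_k) or a ``table`` block (path to two-column ASCII,
        density, k_edges).
        """
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict) or "layers" not in doc:
            raise ValidationError(f"{path}: expected a mapping with a 'layers' list")
        layers = []
        for entry in doc["layers"]:
            if "parametric" in entry:
                p = entry["parametric"]
                model = AttenuationModel.parametric(
                    p["a"], p["b"], p.get("c", 0.0), p.get("e_k"))
            elif "table" in entry:
                t = entry["table"]
                e, m = load_attenuation_table(t["path"])
                model = AttenuationModel.tabulated(
                    e, m, t["density"], t.get("k_edges", ()))
            else:
                raise ValidationError(
                    f"layer {entry.get('material')}: needs 'parametric' or 'table'")
            props = ScintillatorProps(
                light_yield=entry["yield_per_keV"],
                decay_time_ns=entry.get("decay_time_ns", 100.0),
                refractive_index=entry.get("refractive_index", 1.8),
                channel=entry["channel"])
            layers.append(Layer(entry["material"], model, props,
                                entry["thickness_mm"]))
        return cls(tuple(layers))


def load_attenuation_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column ASCII attenuation table (keV, cm^2/g; '#' comments)."""
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValidationError(f"{path}: expected two columns (keV, cm^2/g)")
    return data[:, 0], data[:, 1]


# ------------------------------------------------------------------ presets
def surrogate_material_presets() -> dict[str, Layer]:
    """Parametric surrogate scintillators following the three-layer design rules.

    The presets emulate the qualitative attenuation structure of a real
    multicolor stack: the top layer has a large, monotonically decreasing mu
    with no K-edge in range (confines the 16-33 keV bin); the middle layer has
    a K-edge at 50 keV (captures 50-67 keV behind the top layer while passing
    33-50 keV); the bottom layer has a K-edge at 33 keV (absorbs the
    intermediate bin).  Emission blueshifts top to bottom (R -> G -> B) to
    minimize inter-layer self-absorption; yields and decay times mirror
    typical ZnSe:Te-, Gadox:Tb- and NaI:Tl-class materials.

    Thicknesses default to 0.1 mm and are meant to be overridden via
    :meth:`LayerStack.with_thicknesses`.
    """
    top = Layer(
        "surrogate_top",
        AttenuationModel.parametric(a=-2.55, b=10.0),
        ScintillatorProps(55.0, 5e4, 2.6, "R"),
        0.1)
    middle = Layer(
        "surrogate_middle",
        AttenuationModel.parametric(a=-2.60, b=9.2, c=np.log(4.5), e_k=50.0),
        ScintillatorProps(60.0, 1e6, 2.3, "G"),
        0.1)
    bottom = Layer(
        "surrogate_bottom",
        AttenuationModel.parametric(a=-2.60, b=9.0, c=np.log(5.5), e_k=33.0),
        ScintillatorProps(38.0, 230.0, 1.85, "B"),
        0.1)
    return {"surrogate_top": top, "surrogate_middle": middle,
            "surrogate_bottom": bottom}


def surrogate_stack(layer_thickness_mm: float = 0.1) -> LayerStack:
    """The default three-layer surrogate multicolor stack (equal thicknesses)."""
    presets = surrogate_material_presets()
    order = ("surrogate_top", "surrogate_middle", "surrogate_bottom")
    return LayerStack(tuple(
        replace(presets[k], thickness_mm=layer_thickness_mm) for k in order))


def single_layer_stack(preset: str = "surrogate_top",
                       thickness_mm: float = 0.3) -> LayerStack:
    """A single-color stack built from one surrogate preset (for comparisons)."""
    layer = surrogate_material_presets()[preset]
    return LayerStack((replace(layer, thickness_mm=thickness_mm),))
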