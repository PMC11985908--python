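# multiscint

Energy-resolved X-ray imaging with multilayer **multicolor scintillators**:
a simulation and reconstruction toolkit for detector physicists and medical
imaging researchers studying three-bin spectral detection with conventional
X-ray tubes and RGB cameras.

A stack of scintillating layers with distinct emission colors encodes X-ray
energy in space: low energies (16–33 keV) are absorbed in the top layer,
high energies (50–67 keV) behind it in a layer with a gadolinium-type K-edge
at 50 keV, and intermediate energies (33–50 keV) in a bottom layer with an
iodine-type K-edge at 33 keV. Each absorbed X-ray makes one colored spot on
the detector; the spot's **dominant color** identifies the absorbing layer
and its **effective radius** `r_c` (mean distance of the spot's photons to
their centroid) encodes the emission depth. A calibration of
`p(E | color, r_c)` then classifies every spot into one of the three energy
bins bounded by the K-edges of the iodine and gadolinium contrast agents the
system is designed to discriminate.

The package covers the full chain:

* **materials** — tabulated (NIST/XCOM-style ASCII) or parametric
  attenuation models `mu(E) = E^a exp[b + c·H(E−E_K)]`, the mass-weighted
  mixture rule, and layer-stack descriptions (YAML);
* **absorption** — Beer–Lambert depth profiles, the depth-conditional
  energy density, the incident→reconstructed bin matrix `p^(mn)` and the
  accuracy `eta = Σ_m p^(mm)`, plus thickness optimization;
* **montecarlo** — a seeded event-level simulator (absorption-depth
  sampling, isotropic emission with a 25° TIR acceptance, optional ideal
  15° nanophotonic angular filter, frame rendering);
* **clustering** — spot finding by G-means with Hartigan dip-test splits,
  spot features, and the Fowlkes–Mallows index;
* **reconstruction** — calibration tables, MAP bin classification, and
  empirical accuracy with confusion matrices;
* **bounds** — the 1/3 random-guess floor and a physically-constrained
  accuracy ceiling optimized over parametric scintillators;
* **phantom** — equal-contrast contrast-agent phantoms, spectral forward
  imaging with detector noise, per-bin effective attenuation, and material
  identification by clustering in attenuation space;
* **pipeline / CLI** — end-to-end runs from a config file, reproducible
  from a single seed.

Real material tables are not bundled; the package ships parametric
*surrogate* scintillators and tissues that follow the same design rules, so
everything builds and tests offline. Measured data drops in through the
same interfaces.

## Worked example

```python
import numpy as np
from multiscint import (surrogate_stack, single_layer_stack, analytic_eta,
                        calibrate, empirical_eta, lower_bound)

stack = surrogate_stack(0.1)          # three 0.1 mm layers, R/G/B top→bottom
print(f"analytic eta: {analytic_eta(stack):.3f}")

table = calibrate(stack, n_per_energy=2000, rng=np.random.default_rng(1))
acc = empirical_eta(stack, table, n_test=10_000, rng=np.random.default_rng(2))
print(f"empirical eta: {acc.eta:.3f} +- {acc.se:.3f}  (floor {lower_bound(3):.3f})")

single = single_layer_stack("surrogate_top", 0.3)   # same total thickness
t1 = calibrate(single, 2000, rng=np.random.default_rng(1))
acc1 = empirical_eta(single, t1, 10_000, rng=np.random.default_rng(2))
print(f"single-layer eta: {acc1.eta:.3f}")
```

prints

```
analytic eta: 0.413
empirical eta: 0.519 +- 0.007  (floor 0.333)
single-layer eta: 0.357
```

The analytic 0.413 is the accuracy of the probabilistic depth→energy map
for this stack; the empirical 0.519 is the MAP classifier's accuracy from
spot color and radius (MAP beats the soft assignment); 0.357 is the best a
single edge-free layer of the same total thickness manages, and 1/3 is
random guessing. The multicolor gain over the single layer — here about 16
percentage points on surrogate materials — is the design's point.

The same machinery runs from the shell:

```bash
multiscint calibrate --n-per-energy 2000 --seed 1 --out table.json
multiscint simulate --n-xrays 200 --seed 2 --csv hits.csv
multiscint cluster --frame hits.csv --out spots.csv
multiscint classify --table table.json --channel G --radius 0.03
multiscint bounds --thickness-sweep 0.1,0.3,1.0 --seed 0
multiscint phantom --noise 0.001 --png phantom.png
```

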