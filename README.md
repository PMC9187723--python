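# furrowshell

Embryo-scale mechanics of ventral furrow formation (VFF) at the onset of
*Drosophila* gastrulation, modelled as a pre-stressed thin elastic shell.

The apical surface of the blastoderm is a closed triangulated ovoid (AP axis
three times the DV axis, ventral side more curved) enclosing a fixed volume
and confined by the rigid vitelline membrane across a thin perivitelline
fluid layer. Apical actomyosin (MyoII) contractility is encoded purely as an
isotropic areal pre-strain: mesoderm facets are assigned a target area
`A_0 < A_i`, so each carries pre-strain

    eps_a = (A_i − A_0)/A_0      and pre-stress      sigma_a = chi_2D · eps_a,

graded with cell-row distance from the ventral midline and ramped in time
following the double-exponential MyoII intensity law

    I_myo(t) = I_c + I·(exp(exp((t − t0)/T) − 1) − 1),

with `I_c = 4` arb and `T = 20` min on the confocal time base. Quasi-static
equilibria along the pre-strain ramp are found by deterministic constrained
energy minimisation (constant-strain-triangle membrane + discrete-shells
bending, volume via augmented Lagrangian, frictionless vitelline contact).
The package also implements the downstream quantifications: per-facet stress
tensors and principal stresses, the midline AP:DV tension anisotropy,
three-point (circumcircle) curvature on sections, furrow depth and
propagation along AP, vitelline distance maps, pole displacement, tissue
shortening, LOESS-style recoil velocities, MyoII model fitting, row-profile
decomposition and the 20%-area-reduction time synchronisation — plus seeded
generators for synthetic cell-tracking tables so every estimator is testable
against known ground truth.

Who is this for: people modelling epithelial morphogenesis who want a tested,
scriptable implementation of an active-surface (apical pre-stress only) model
with a rigid-confinement volume constraint, and of the morphometric measures
used to compare such models with light-sheet/confocal data.

See `docs/methods.md` for the model, its assumptions, parameter meanings and
known limitations — including an honest account of which in vivo and in
silico behaviours of VFF this implementation does and does not reproduce.

## Worked example

Fit the MyoII intensity model to a synthetic midline series and build the
pre-stress schedule:

```python
import numpy as np
from furrowshell import IntensityModelParams, eval_intensity, fit_intensity

truth = IntensityModelParams(i_c=4.0, amplitude=1.0, t_onset=0.0, tau=20.0)
t = np.linspace(-30, 15, 60)                # minutes around gastrulation onset
fit, rss = fit_intensity(t, eval_intensity(truth, t))
print(f"I_c={fit.i_c:.3f} arb  I={fit.amplitude:.3f}  "
      f"t0={fit.t_onset:.3f} min  T={fit.tau:.3f} min")
```

prints

```
I_c=4.000 arb  I=1.000  t0=0.000 min  T=20.000 min
```

i.e. the bounded multi-start least-squares fit recovers the constant signal
(4 arb), amplitude, onset time and the 20-minute characteristic time of the
MyoII rise exactly from a noiseless series.

Simulate the shell and measure the midline stress anisotropy:

```python
from furrowshell import (ElasticParams, GaussianRowProfile, GeometryParams,
                         anisotropy_ratio, assign_prestrain, build_vitelline,
                         facet_stress, generate_embryo_mesh, minimize_energy)

mesh = generate_embryo_mesh(GeometryParams(subdivisions=4))   # 2048 facets
vitelline = build_vitelline(mesh, gap=0.004)                  # ~0.35 um
params = ElasticParams(chi_tilde=50.0, nu=0.0)
loaded = assign_prestrain(mesh, GaussianRowProfile(), eps_midline=0.43)
state = minimize_energy(mesh.vertices, loaded, params, vitelline, tolerance=1e-3)
field = facet_stress(state, loaded, params)
print(f"midline AP:DV stress ratio = {anisotropy_ratio(field, mesh):.2f}")
```

prints

```
midline AP:DV stress ratio = 6.14
```

— AP tension at the ventral midline stays close to the imposed pre-stress
while DV tension relaxes, so the isotropic contractility produces a strongly
anisotropic tension (see `docs/methods.md` for why the magnitude of this
ratio is calibration-sensitive).

From the shell:

```bash
furrowshell mesh --subdiv 4 --out embryo.ply
furrowshell run --preset furrowing --out furrow_run/
furrowshell synth tracking --seed 1 --out track.csv
furrowshell myofit --input track.csv --modality confocal --out fit.json
```

`furrowshell run` writes a reproducible bundle: the serialised config, one
VTK mesh per ramp step, CSV tables (trajectory manifest, per-facet stress,
strain profiles, midline curvature, furrow depth) and a SHA-256 manifest.

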