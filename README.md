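# coildeploy

Finite-element simulation of endovascular coil embolization of intracranial
aneurysms, for researchers modelling how embolic coils pack into an
aneurysm sac.

Embolic coils are multiscale devices: a platinum stock wire (diameter D1)
tightly wound into a helical secondary structure (outer diameter D2), which
is heat-set on a mandrel into a 3D pre-shape (envelope diameter D3).
`coildeploy` models the device and its treatment mechanics end to end:

* **Spring-equivalent beam properties** — the coil is a chain of tubular
  Timoshenko beam elements whose elastic moduli are calibrated by equating
  beam rigidity to the helical-spring rigidities of the secondary
  structure:

      D_compressive = Gw·D1⁴·l / (8·n·D2³)
      D_shearing    = Ew·D1⁴·l / (8·n·D2³)
      D_flexural    = Ew·Gw·D1⁴·l / (16·n·D2·(2Gw+Ew))

  with `Eb·Ab = D_compressive`, `λ·Gb·Ab = D_shearing`,
  `Eb·Ib = D_flexural` (tight winding, l = n·D1). The resulting moduli are
  ~5 orders of magnitude below platinum.
* **Virtual manufacturing** — pre-shapes are wound analytically on a
  mandrel (main cylinder of diameter D3 − 1.5 mm plus cross-axis cylinders
  of diameter D3), truncated to the coil length and discretized into the
  beam centerline; a parametric spherical-spiral baseline is included.
* **Explicit deployment dynamics** — central-difference integration of a
  discrete Cosserat rod with lumped masses, Rayleigh damping, smooth-step
  displacement drives, and penalty contact with Coulomb friction against
  the catheter tube, the sac, a neck-cover barrier, and the coil itself.
  The three clinical steps (packaging, advancement, deployment) run in
  sequence, with 9-rotation initial-condition ensembles.
* **Cross-section metrics** — deployed configurations are sliced on planes
  1 mm apart, rasterized to binary images, and scored by coil density (CD)
  and gliding-box lacunarity (L); ensembles are compared to a reference in
  standardized CD–L space by Euclidean distances
  (`d = sqrt(ΔCD² + ΔL²)`; dMin/dMax/dAvg) with Shapiro-Wilk/Levene/t-test
  statistics.

A synthetic geometry generator (spherical sac on a tubular parent artery,
sidewall or terminal, with analytic centerlines) makes every stage testable
without patient data; STL surfaces and centerline polylines can be supplied
for imported cases.

## Worked example

Coil properties for a bare platinum 5 mm × 10 cm coil
(D1 = 0.0381 mm, D2 = 0.2921 mm, Ew = 230 GPa, Gw = 82 GPa):

```bash
$ coildeploy coilprops --d3 5.0 --length-cm 10.0
coil: D1=0.0381 mm  D2=0.2921 mm  D3=5.0 mm  l=100.0 mm  (n=2624.7 loops)
  D_compressive = 3.3018e-02 N
  D_shearing    = 9.2612e-02 N
  D_flexural    = 8.2228e-04 N*mm^2
  E_b = 1.506e-03 GPa  (axial candidate 8.354e-04, flexural candidate 1.506e-03)
  G_b = 1.843e-03 GPa  (lambda=0.75)
  rho_eff = 16.847 mg/mm^3
```

The three rigidities are the helical-spring constants of the secondary
structure (axial, shearing, and flexural). `E_b` and `G_b` are the
equivalent beam moduli under the default calibration (flexural equation on
the annulus around D2; shear equation on a solid-D2 disc with λ = 0.75) —
note they are ~150 000× softer than the platinum wire, which is what makes
a coil floppy even though its material is stiff. `rho_eff` makes beam mass
per length equal the physical coil's (≈ 0.512 mg/mm).

Deploy a reduced coil into a synthetic 5 mm sidewall aneurysm and measure
its cross-section distribution:

```bash
coildeploy simulate --sac-diameter 5 --vessel-diameter 3 \
    --coil-d3 5 --coil-length-cm 2 --rotation-deg 0 --out deployment.json
coildeploy metrics deployment.json --sections 3
```

`simulate` prints the per-step strain energies (packaged ≫ deployed: the
coil stores energy when straightened and releases it while recovering its
pre-shape in the sac) and writes the final centerline; `metrics` prints CD
and L per section plus the aneurysm average. In Python the same pipeline is
`DeploymentSession(case, coil).full_deployment(rotation_deg)` followed by
`extract_sections` / `rasterize` / `coil_density` / `lacunarity`.

See `docs/methods.md` for the model, its assumptions, numerical choices,
and limitations.

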