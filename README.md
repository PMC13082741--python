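# stokescope

Full-Stokes polarimetric hyperspectral microscopy, in software: simulate a
dual-LCVR polarization microscope imaging stained blood smears, reconstruct
Stokes parameter cubes from its four analyzer measurements, derive
degree-of-polarization maps, render synthetic RGB views, and compare the
spectral signatures of white-blood-cell classes with per-band statistics.

The package is for researchers building or evaluating Stokes polarimetric
imagers for hematology: it provides the complete data-reduction chain of
such an instrument plus a phantom generator, so reconstruction code,
visualization and statistics can be developed and validated without hardware
or patient slides.

## The measurement model

The instrument conditions unpolarized illumination with a 45° polarizer
(the polarization state generator), passes it through the sample, and
analyzes the exiting light with two liquid-crystal variable retarders
(LCVR 1 fast axis 0°, LCVR 2 fast axis 45°) followed by a horizontal
polarizer. Four retardance settings — (0, 0), (0, π), (π/2, π/2) and
(0, π/2) — turn the fixed analyzer into a horizontal, vertical, 45°-linear
and right-circular analyzer, recording Ih, Iv, I45 and Irc. The Stokes
vector of the light leaving the sample follows from

    S0 = Ih + Iv
    S1 = Ih − Iv
    S2 = 2·I45 − (Ih + Iv)
    S3 = 2·Irc − (Ih + Iv)

and the degree-of-polarization parameters are

    DOP  = √(S1² + S2² + S3²) / S0
    DOLP = √(S1² + S2²) / S0
    DOCP = |S3| / S0

so DOP = √(DOLP² + DOCP²) identically. All optics are modeled in Mueller
calculus; the retarder handedness convention is pinned so that the (0, π/2)
setting analyzes right-circular light (+S3), and every element form is
cross-checked against a brute-force Jones-calculus oracle in the tests.

Samples are modeled per pixel and band as transmittance × isotropic partial
depolarizer diag(1, d, d, d) × optional weak linear retarder. The phantom
generator lays out granulocyte-like cells (granular, strongly depolarizing),
lymphocyte-like cells (dense nucleus, weak surface texture) and
monocyte-like cells (large lobed nucleus) with a stain-like transmission
minimum near 535 nm, on a 29-band grid from 470 to 750 nm.

## Worked example

```python
from stokescope import (NoiseModel, PhantomSpec, compute_derived,
                        compute_stokes, generate_phantom, simulate_acquisition)

scene = generate_phantom(PhantomSpec(seed=3))
stack = simulate_acquisition(scene, noise=NoiseModel(kind="gaussian", level=0.01), seed=11)
derived = compute_derived(compute_stokes(stack))
for rec in scene.cell_records:
    print(rec.class_label, round(float(derived.dop[:, scene.cell_mask(rec.cell_id)].mean()), 3))
```

prints (among the 8 cells of the default field)

```
granulocyte 0.542
granulocyte 0.547
granulocyte 0.506
lymphocyte 0.339
lymphocyte 0.325
lymphocyte 0.305
monocyte 0.438
monocyte 0.474
```

— the masked-mean DOP recovers each class's depolarization level
(granulocytes ≈ 0.5, lymphocytes ≈ 0.3, monocytes ≈ 0.4) through the full
simulate–reconstruct chain under 1% detector noise. The discrimination
study (`stokescope.experiments.two_class_study`, 15 cells per class) then
gives per-band Welch t-tests with

```
parameter      median p    bands with p<0.05
S0             1.15e-07         17 / 29
DOP             3.8e-11         29 / 29
DOLP           3.62e-11         29 / 29
```

— depolarization-based parameters separate the classes at every band, raw
intensity at far fewer: the reason a polarimetric channel helps at all.

More narrative scripts live in `examples/` (optical elements, phantom
acquisition, RGB rendering, spectra statistics, full pipeline). The same
stages are scriptable from a shell via the `stokescope` CLI
(`simulate`, `stokes`, `derive`, `rgb`, `extract`, `ttest`, `run`).

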