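# shgdir — local SHG emission directionality analysis

Second-harmonic generation (SHG) microscopy images fibrillar collagen with
intrinsic contrast.  The *creation ratio* F_SHG/B_SHG — how much of the
harmonic is emitted forward versus backward at the point of creation — is
set by fibril size and packing through phase matching: under relaxed phase
matching the harmonic field is

    E_2ω = κ E_ω² · sinc(Δk·L/2),      sinc(x) = sin(x)/x,

so smaller phase mismatch |Δk| gives both brighter and more
forward-directed SHG.  What a microscope measures, however, is the
*detected* F/B after the photons have diffused through scattering tissue.
`shgdir` decouples the two: it simulates photon transport through the
tissue slab by Monte Carlo (Henyey–Greenstein scattering, NA-limited
detection with Snell refraction at the faces), tabulates detected F/B as a
function of creation ratio and emission depth, and inverts measured
patch-wise F/B (30×30-pixel patches, per optical section) into local
F_SHG/B_SHG heat maps.

On top of the heat maps the package computes the statistics that separate
ovarian tissue classes (normal, benign tumor, endometrioid, low-grade
serous, high-grade serous): per-volume mean ratio and within-volume
heterogeneity, the per-section Pearson correlation between directionality
and intensity (high when the underlying Δk distribution is narrow), group
Welch t-tests, skeleton-based fiber/bundle width estimation, and GLCM
texture features as an intensity-only control.  Because the original
patient image stacks are not publicly deposited, the package includes a
first-class synthetic tissue generator with per-class fiber morphology and
Δk distributions calibrated to the published class statistics, giving
every pipeline stage a known ground truth.

Intended users: microscopists and image analysts working with paired
forward/backward SHG stacks, and methodologists studying directionality
inversion.

## Worked example

```python
import numpy as np
from shgdir import (OpticalProperties, DetectionGeometry, MCConfig,
                    build_lookup_table, extract_ratio_heatmaps)
from shgdir.phase_matching import DirectionalityMap
from shgdir.synthetic import default_profiles, generate_volume

optics = OpticalProperties(mu_s_reduced=2.0, anisotropy_g=0.9,
                           refractive_index=1.4, thickness=150.0)
config = MCConfig(photons_per_condition=10_000, rng_seed=7,
                  depth_grid=tuple(np.linspace(0, 80, 20)))
lut = build_lookup_table(optics, DetectionGeometry(), config)

dmap = DirectionalityMap()                    # |dk| -> creation ratio map
profile = default_profiles(dmap)["HGS"]       # high-grade serous preset
pair, truth = generate_volume(profile, lut, dmap,
                              shape=(256, 256), n_sections=64, seed=1)

hm = extract_ratio_heatmaps(pair, lut, patch_size=30,
                            min_total_intensity=10.0)
vals = hm.valid_ratios()
print(f"mean F_SHG/B_SHG = {vals.mean():.2f}  "
      f"(configured {profile.ratio_mean})")
print(f"within-volume SD = {vals.std():.2f}")
```

Output:

```
mean F_SHG/B_SHG = 2.81  (configured 2.7)
within-volume SD = 0.83
```

The recovered mean sits close to the configured class mean (2.7); the
patch SD is attenuated relative to the fiber-level SD because each
30×30-px patch averages several fibers (see `docs/methods.md`).  Running
the full five-class cohort (`shgdir analyze` or
`shgdir.pipeline.run_full_analysis`) reproduces the class ordering of
mean ratios — benign > LGS > normal > endometrioid > HGS — and a higher
directionality–intensity Pearson correlation for the uniform HGS class
than for the heterogeneous LGS class.

## Command line

```bash
shgdir simulate-lut --mus-reduced 2.0 --thickness 150 --photons 10000 \
       --seed 7 --out lut.h5
shgdir generate-synthetic --class HGS --n 3 --lut lut.h5 --seed 1 --out cohort/
shgdir extract-fb --forward f.tif --backward b.tif --lut lut.h5 \
       --patch-size 30 --out heatmaps/vol0
shgdir fiber-widths --input section.tif --pixel-size 0.332 --out widths.csv
shgdir analyze --seed 1 --out run/
shgdir report --run-dir run/
```

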