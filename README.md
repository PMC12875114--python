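# chromaflux

Quantification of chromatin fibers and single nucleosomes in 3D MINFLUX
localization data.

MINFLUX nanoscopy localizes individual fluorophores with ~1-nm precision,
and a spontaneously blinking minor-groove DNA dye (12-bp footprint,
AT-preferring) turns nuclear DNA into a sparse 3D point cloud — dense
enough, in condensed regions, to resolve ~30-nm chromatin fibers and even
the ~11-nm ring of DNA wrapped around single nucleosomes. `chromaflux`
is the analysis layer for such data: it clusters localization clouds,
fits cylinder models to extract per-segment fiber diameter, length and
DNA density, fits ring / cylinder / stacked-dimer models at the
nucleosome scale, classifies regions by nucleosome content, estimates
image resolution by Fourier ring correlation (FRC), splits dual-color
acquisitions by spectral ratio, and runs the group statistics for
treatment comparisons. A synthetic-scene generator with exact
ground-truth bookkeeping makes every stage testable without microscope
data.

## Core quantities

* **DNA density** of a fiber segment with `n` localizations in a
  cylinder of radius `R` and length `L`:
  `rho = (n * 12 bp / 0.8) / (pi R^2 L)` in Mbp/um^3 — each probe marks
  12 bp and can cover at most 80% of the DNA.
* **Cylinder / ring fits** minimize the variance of radial distances;
  the diameter is twice the mean point-to-axis distance under the
  optimal axis. Nucleosome fits constrain the radius to [4.5, 7] nm,
  cap the height at 8 nm, and count probes "attached" within a 1.5-nm
  radial tolerance; 5–10 attached probes are expected per nucleosome
  (the AT-content-limited occupancy of 140 bp of nucleosomal DNA).
* **FRC resolution**: odd/even half-set images are correlated over
  Fourier rings; the resolution is the first crossing of the smoothed
  curve below 1/7.
* **Classification**: per density cluster, nucleosomes are greedily
  extracted from 18-nm windows; clusters with 0 / 1–2 / >= 3 accepted
  fits contribute their localizations to the scattered /
  mono-di-nucleosome / nucleosome-polymer fractions.
* **Statistics**: per-cell fractions are compared by one-way ANOVA and
  Dunnett's many-to-one test (seeded Monte-Carlo equicoordinate null).

See `docs/methods.md` for the full model descriptions and numerical
choices.

## Worked example

Simulate one 200-nm chromatin fiber (35-nm diameter, 34 Mbp/um^3) with
the instrument's localization noise, then recover its geometry:

```python
import numpy as np
from chromaflux import dbscan, segment_fiber, dna_density
from chromaflux.simgen import (AcquisitionParams, SyntheticScene,
                               make_fiber, simulate_localizations)

rng = np.random.default_rng(0)
scene = SyntheticScene(box=((0, 800),) * 3)
fib = make_fiber(200.0, [(200.0, 35.0)], 0.001, rng,
                 target_density_mbp_um3=34.0, start=(300, 400, 400),
                 scene=scene)
scene.fibers.append(fib)
table = simulate_localizations(scene, AcquisitionParams(rng_seed=0))
print(f"{len(table)} localizations")

labeling = dbscan(table.coords(), eps=20.0, min_pts=5)
print(f"{labeling.n_clusters} cluster(s)")

fiber = segment_fiber(table.coords())
for seg in fiber.segments:
    print(f"segment: diameter {seg.diameter:.1f} nm, "
          f"length {seg.length:.1f} nm, {len(seg.member_indices)} locs, "
          f"density {dna_density(seg):.1f} Mbp/um^3")
```

Output:

```
436 localizations
1 cluster(s)
segment: diameter 33.8 nm, length 206.1 nm, 436 locs, density 35.4 Mbp/um^3
```

The 436 probe sites fall in one density cluster; the cylinder fit
recovers the constructed 35-nm diameter to ~1 nm (the length overshoots
the 200-nm centerline slightly because probes extend past its ends) and
the density estimate lands within ~4% of the generator's 34 Mbp/um^3
target.

A command-line interface mirrors the library:

```bash
chromaflux simulate --seed 1 --out scene/
chromaflux cluster scene/localizations.csv --eps 20 --min-pts 5 --out clustered.csv
chromaflux fibers clustered.csv --out-fibers fibers.csv --out-segments segments.csv
chromaflux frc scene/localizations.csv --pixel-nm 2 --out frc.csv
chromaflux pipeline scene/localizations.csv --out run/
```

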