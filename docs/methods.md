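# Methods

`chromaflux` quantifies chromatin ultrastructure in 3D MINFLUX
localization data of a blinking minor-groove DNA dye. A localization is
one estimated position of one fluorophore sighting, with ~1-nm precision
in the focal plane and sub-nm along the optic axis. The pipeline turns a
table of such sightings into fiber geometry, nucleosome fits, DNA
densities, a resolution estimate, and treatment-comparison statistics.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic scenes do and do not establish.

## Measurement model

Each probe molecule occupies a 12-bp footprint on AT-rich DNA and can
cover at most 80% of a stretch of DNA, so `n` localizations in a region
estimate `n x 12 / 0.8` base pairs. Localization error is modeled as
independent per-axis Gaussian noise with FWHM 1.08 / 0.96 / 0.63 nm
(x / y / z), i.e. sigma = FWHM / (2 sqrt(2 ln 2)). Because the dye blinks
spontaneously and exchanges, a molecule is rarely sighted twice; the
simulator therefore emits at most one sighting per bound probe by
default (`relocalization_rate` re-enables repeats for sensitivity
analysis). Acquisition is sequential at 93.7 us per 3D localization.

## Synthetic scenes

The generator builds ground truth and keeps an observation-to-truth link
for every simulated localization, so each analysis stage can be scored
against construction.

**Nucleosome.** 147 bp wrapped in a left-handed superhelix of 1.65 turns
with ~5.7 nm total rise; candidate probe footprints every 12 bp (12
sites); each bound independently with probability `at_fraction`
(AT-content surrogate), thinned to the steric cap of
`floor(147 x 0.8 / 12) = 9`. Fluorophores sit at radial distance uniform
in [4.2, 5.5] nm from the disk axis (minor-groove positions across the
2.5-nm DNA cross-section inside an ~11-nm outer envelope). A consequence
worth stating explicitly: the ring traced by the *fluorophores* has mean
diameter 2 x 4.85 = 9.7 nm (`NucleosomeTruth.probe_ring_diameter_nm`),
which is what an unbiased least-squares fit of the probe cloud should
return — not the 11-nm envelope. Recovery tests use 9.7 nm as truth.

**Fiber.** A smoothed random-walk centerline (bend limited per nm) with a
diameter profile per arc-length segment. Nucleosome centers sit on a ring
about the centerline whose radius is de-biased by E|u|^2 / (3c) (u = the
probe offset from the nucleosome center, c = half the segment diameter) so
that the expected probe distance from the fiber axis equals the nominal
radius; a least-squares cylinder fit then recovers the nominal diameter.
Per segment, exactly the number of bound probes implied by the target DNA
density (default 34 Mbp/um^3) is kept, making density recovery testable.

**Decompaction (HDAC-inhibitor treatment).** A severity fraction of
fibers dissolves: 70% of their probes re-scatter as free DNA, the rest
persist as mono-nucleosomes displaced 30–80 nm from their former
positions (decompacted chromatin disperses; without the displacement the
surviving neighbors would spuriously re-form polymer-like clusters).
Surviving fibers are truncated below 50 nm; segment diameters are left
unchanged. Dissolution draws one uniform per fiber *first*, so runs at
increasing severity with the same seed dissolve nested sets — the basis
of the monotonicity tests.

**Resolution target.** `make_stripe_pattern` renders parallel fiber-like
stripes: the projected cross-section of a 30-nm cylinder (semicircle
profile) at random positions. Its spectrum decays at the structure width,
so a 1/7-threshold FRC reads out ~30 nm. A grid of zero-width lines would
instead produce a comb spectrum and a meaningless first crossing, which
is why the generator models stripes of finite width.

What the scenes do **not** emulate: chromatin motion (only the
fixed/live detection-probability contrast), the iterative beam
positioning and photon statistics of the instrument, sequence-explicit
AT content, linker DNA/histones, and nuclear context (crowding,
heterochromatin compartments). Passing recovery tests therefore show the
estimators are unbiased under this noise and sampling model, not that
real nuclei meet the model.

## Clustering and fiber geometry

Condensed signals are found with DBSCAN on Euclidean 3D coordinates
(defaults eps = 20 nm, min_pts = 5 — one 30-nm fiber at realistic
densities forms one cluster while uniform background does not). The
implementation is deterministic: border points join the lowest-uid core
neighbor, so repeated runs are bit-identical; an O(n^2)
density-reachability oracle and scikit-learn's DBSCAN serve as
independent checks in the tests. Cluster geometry comes from the member
covariance eigendecomposition; the fiber length measure is the full
projection range along the first principal axis (no percentile trim —
at sigma < 0.5 nm the difference is negligible at fiber scale).

Cylinder fits minimize the variance of point-to-axis distances; the
radius is the mean radial distance under the optimal axis (so "diameter"
is a point-cloud RMS convention, not a FWHM). Because a disk-like
cylinder's axis is the *minor* principal direction, all three
eigenvectors are tried as initializations and the lowest-residual
solution wins. The axis sign is fixed toward +z (ties +y, then +x).

`r_squared` is the explained cross-section: 1 − SS_res / SS_tot with
SS_res = Σ(r_i − R)^2 and SS_tot the total in-plane scatter about the
perpendicular centroid. Exact surfaces give 1; a filled ball or disk
gives ~0.87–0.89 — use `rms_radial_residual` alongside it when screening
shell-like versus filled clusters.

**Segmentation.** The fiber's axis line (PCA direction, offset refined on
all points) is fitted once; points are windowed every 25 nm along it and
each window's diameter is twice the mean radial distance of its members
from that shared line. Two failure modes motivated this choice over
fully independent per-window fits: an end window with azimuthally
clumped points lets a free offset diverge (the circle-fit-to-arc
problem), and a free whole-fiber axis tilts on clusters whose diameter
varies (fitting a cone with a cylinder). Adjacent windows within 20%
relative diameter are merged; a single-window segment whose diameter
lies strictly between its neighbors' is treated as a transition window
straddling a diameter step and its points are divided between the
neighbors by radial proximity. Clusters that fold back under axial
projection (high curvature) are not split and will be mis-segmented;
this is a known limitation, acceptable at the curvature of the scenes
studied here.

**DNA density.** density = (n x footprint / coverage) / (pi R^2 L),
reported in Mbp/um^3. Worked example: 100 localizations in a 30-nm x
100-nm cylinder give 1500 bp / 7.07e4 nm^3 = 21.22 Mbp/um^3. Validation
sweeps 8.87–69.87 Mbp/um^3 with fiber length scaled inversely with
density (900 nm at the low end, 300 nm at the high end) so every fiber
carries comparable probe counts — a power consideration: at ~20
nucleosomes a single fiber's azimuthal coverage is too lumpy for a
20%-accurate radius.

## Nucleosome-scale fits

**Ring.** Points are projected onto their two leading principal axes and
a circle is fitted (algebraic start, Gauss–Newton refinement of the
center on radial residuals). `plane="xy"` instead projects onto the
instrument focal plane — the uncorrected variant, in which a tilted
nucleosome's rise and orientation leak into the apparent ring. In
simulation this produces a diameter histogram whose primary peak sits
below the face-on value with a secondary population of inflated arc-like
fits above it — the orientation-angle artifact invoked to explain
double-peaked ring-diameter histograms. `tilt_corrected=True` refines
the plane normal jointly with the circle.

**Constrained cylinder.** Radius search band [4.5, 7] nm, height cap
8 nm, attachment tolerance 1.5 nm (~3 localization sigmas — separates
on-cylinder probes from linker/neighbor probes). The offset is solved
with a soft-L1 first pass and then iteratively re-estimated on the
attached subset, so off-cylinder scatter cannot drag the fit; when the
PCA axis candidates attach fewer than half the points, a deterministic
16-direction hemisphere grid of axis candidates is tried. A fit is
accepted with >= 5 attached probes (the 5–10 a nucleosome's AT content
admits) and diameter in the 9–14 nm band; everything else is a
no-nucleosome result, not an error. A helix-phase refinement beyond the
cylinder is deliberately not implemented.

**Dimer.** A shared axis (each principal direction tried) splits the
axial coordinates by exact 1D two-means; both halves must accept as
nucleosomes with the axis fixed. The center-to-center offset is reported
along the shared axis.

**Classification.** Noise localizations are scattered signal. Within
each cluster, nucleosomes are extracted greedily: an 18-nm cubic window
centered on the densest unclaimed localization is fitted; accepted fits
claim their attached points; failed seeds are not revisited (a claimed
set only shrinks a failed window, so revisiting is almost never
productive, and skipping it bounds the runtime). Clusters with 0 / 1–2 /
>= 3 accepted fits contribute their localizations to the scattered /
mono-di / polymer fractions; fractions are localization-weighted, per
the reading that the reported percentages refer to localizations.

## Resolution and precision

FRC splits localizations into odd/even-uid half-sets (deterministic,
robust to density gradients; random split available), renders each as a
2-nm-pixel 2D histogram on a common grid, and correlates Fourier rings
one frequency bin wide. The curve is smoothed with a centered 3-bin
moving average; the resolution is the linearly interpolated first
crossing below 1/7, or the Nyquist limit (2 x pixel) with a not-crossed
flag. 3D data are projected to xy. Precision from repeated sightings is
the pooled within-group standard deviation per axis, converted with
FWHM = 2 sqrt(2 ln 2) sigma; the same constant is used by the simulator
(cross-checked in tests).

## Dual-color split and statistics

Dual-color localizations are assigned by the spectral fraction
ch1/(ch1+ch2): strictly above 0.415 is the DNA-dye channel (strict
inequality per the threshold's definition); zero-total records are
dropped and counted. Co-localization uses exact nearest-neighbor
distances with a 50-nm default radius, allowing for the size of an
antibody stack relative to a nucleosome.

Per-cell classification fractions are compared by one-way ANOVA
(between/within mean squares, F with (k−1, N−k) df) and Dunnett's
two-sided many-to-one test against the control. The Dunnett adjustment
samples the joint null of the correlated t statistics by seeded Monte
Carlo (default 1e5 draws; each p is reported with its
sqrt(p(1−p)/B) standard error), which handles arbitrary unbalanced
designs; it reduces to the two-sample t-test at k = 1 and matches
scipy's implementation within Monte-Carlo error (both checked in tests).
Fractions are analyzed untransformed; an arcsine-sqrt option exists in
principle via pre-transforming the table.

## Determinism and problem sizes

Every stochastic routine takes an explicit generator or seed; reports
and tables are byte-stable for fixed inputs. Validation problem sizes —
100-replicate geometry recoveries, 50 clustering oracle instances,
20 000-localization FRC scenes, ~800-localization classification scenes,
6 000-nucleosome orientation-bias histograms, 1e5 Monte-Carlo draws —
were chosen so each check has clear statistical margin while the whole
suite stays comfortably interactive.
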