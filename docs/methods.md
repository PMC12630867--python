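# Methods

`afmhelix` reconstructs the three-dimensional surface envelope of
individual helical filaments — amyloid fibrils in the motivating
application — from topographic AFM height images, and quantifies the
structural heterogeneity and polymorph composition of filament
populations. This note describes the models, the algorithms, the
numerical choices, and what the synthetic data do and do not emulate.

## The imaging model

A rigid filament resting on a flat substrate is scanned from above by a
tip idealized as a sphere-capped cone (apex radius *R*, default 2 nm
for scanning, 5.5 nm for cryo-EM comparison; cone half-angle 18°). The
recorded height at each pixel is the lowest apex position at which the
tip still clears the sample: mathematically, the image is the
morphological (grayscale) dilation of the sample surface by the
reflected tip. Simulation implements this definition exactly on a fine
grid (pixel size / 4, bounding the geometric error well below the
noise floor), followed by i.i.d. Gaussian background noise of sd
0.255 nm — the background noise level typical of gently-scanned
peak-force images. Contact is rigid-body: no cantilever dynamics,
adhesion or sample deformation are modelled, which matches imaging at
forces far below the deformation threshold of amyloid fibrils.

A ground-truth filament ("phantom") is a star-shaped cross-section
r(θ) on a 1° grid that rotates about the filament axis by
`handedness × 360° × z / pitch_360`. Azimuth is measured from the
substrate normal such that handedness +1 is a physically right-handed
screw. The filament rests with its axis at height max r(θ), so over a
full twist its widest azimuth touches both the substrate and the apex;
consequently the axis height is exactly half the apex height, a fact
the reconstruction exploits.

## Tracing, straightening, periodicity, handedness

The centerline is followed from a seed point along the local ridge
direction (structure tensor), re-centred perpendicular to the ridge
with parabolic sub-pixel refinement, and terminated at the filament
end, the image edge, or a sharp junction. Marching direction is
canonicalized (toward +x) because the apparent cross-section of a 3D
object mirrors when viewed from the opposite axial direction; a fixed
convention keeps envelopes comparable without a reflection term in the
structural distance. This convention is a genuine limitation for real
images: two traces of the same physical fibril scanned in opposite
orientations are only comparable after the convention is applied
consistently.

Straightening resamples the image perpendicular to the centerline at
one-pixel arc steps (bilinear interpolation). It happens twice: the
first pass follows the ridge crest and yields the cross-over distance
*cod* as the dominant non-DC peak of the detrended, Hann-windowed FFT
of the central profile (quadratic peak refinement; a peak must exceed
3× the median spectral magnitude, otherwise the filament is reported
untwisted). The crest of a twisted filament wanders laterally about
the helical axis with the twist period, so the centerline is then
low-passed with a least-squares spline whose knots are spaced 1.3
crossover repeats apart — wide enough that the crest oscillation
cannot be represented — and the second pass follows the axis.
Crossovers are counted as profile maxima with prominence ≥ 2× the
background sd separated by at least 0.6 cod.

Twist handedness is read from the 2D power spectrum of the
axis-straightened raster: the near-apex ridge of a right-handed screw
drifts toward −lateral with +axial, concentrating band power (axial
frequencies within a factor 2 of the crossover frequency) in the
quadrants where the two frequency signs agree. Quadrant sums are
compared after subtracting the per-bin noise power estimated from the
out-of-band spectrum; the result is indeterminate when the band excess
is insignificant or the quadrant ratio is below 1.2.

Filaments enter the population analysis only with ≥ 3 crossovers,
≥ 150 nm of uninterrupted contour, no overlap with another trace and
no breakage (profile dipping below 2× background sd) — the study's
inclusion rules, automated.

## Contact-point reconstruction (CPR)

Eroding the image by the same tip gives the certified surface
estimate: the tightest surface consistent with the recorded image.
For each filament pixel, the tip apex at the recorded height defines a
tip surface, and the contact point is the position on the eroded
surface that achieves the dilation maximum — the tangency point. The
raster is upsampled 4× (cubic, with an exact index↔coordinate mapping)
before erosion, recovering sub-pixel lateral sampling. The contact
height is taken as the smaller of (a) the tip-surface height at the
tangency offset and (b) the eroded surface there; each bound
individually carries a small upward interpolation bias, their minimum
does not. Tangencies whose gain profile is flat (several candidate
positions within 0.01 nm) are flagged ambiguous but kept.

Contact points are only geometrically reliable near the filament apex:
at lab azimuths beyond ~50° from vertical the tangency becomes grazing
and its localization error grows steeply (measured on phantoms: ~0.1 nm
at ±10°, ~1.3 nm at ±90°). Reconstruction therefore trusts contacts
within ±50° of vertical — the twist carries every azimuth through this
window along the filament — mirroring the established practice of
using only pixels near the central axis.

## Helical envelope reconstruction

With crossover repeat *p* (pixels) and cross-sectional symmetry *s*,
the twist per axial pixel is 360°/(p·s). Axial windows of half-length
covering 180° of twist are placed along the filament; within each
window points are rotated about the axis by their axial distance from
the centre times the twist rate (sign by handedness) and referred to
the common z=0 azimuthal frame — required so that windows average
without smearing, and making the union of window poolings equal to the
globally "unwound" cloud. Pooled radii are binned at 1°, outliers
rejected at 3× MAD across windows, averaged, and smoothed with a
closed least-squares periodic cubic spline (24 knots by default; the
fitted envelope is explicitly symmetrized to the assumed rotational
symmetry). The result is the tip-accessible mean cross-section r̄(θ)
at 360 samples — tip-accessible because concavities narrower than the
tip are bridged in the image itself and cannot be recovered.

The axis position is estimated from the cloud: height = half the
robust apex height (exact under the resting-filament geometry), and
lateral position by minimizing the within-bin variance of the unwound
radii (Nelder–Mead on one coordinate), which is sensitive because a
mis-placed axis adds twist-phase-correlated scatter.

Cross-sectional symmetry is chosen from candidates {1,2,3,4} by
back-simulation: for each candidate an envelope is reconstructed, a
noiseless AFM image of it re-simulated, and the twist pattern scored
against the observed straightened image by Pearson correlation after
axial phase alignment. Scores within 0.005 of each other mean the
section is effectively rotation-invariant; symmetry 1 is then reported
with a low-confidence flag.

Contact-point density maps use the bivariate normal kernel estimator
f(x) = (1/n) Σ K_H(x − x_i) with H = h²I on the unwound (x, z) points,
h from the Silverman rule (σ·n^(−1/6)) unless supplied, gridded at
0.5 Å. Exact kernel summation is used for small clouds and a
histogram-plus-Gaussian-filter evaluation (the same discretized sum)
for large ones.

## Morphometrics

Per filament: average crossover-peak height *h* (peak sampling of the
central ridge avoids twist-phase bias; the full-profile mean is also
exported), crossover distance *cod*, handedness *hnd* ∈ {−1, +1},
directional periodic frequency *dpf* = hnd/cod (1/nm; negative =
left-handed), and the polar integrals of the envelope: cross-sectional
area csa = ½∮r²dθ, mean radius csr = ⟨r⟩, and second polar moment
csjz = ¼∮r⁴dθ (the perpendicular-axis sum of the two in-plane second
moments). Note the published usage of "helical pitch" is ambiguous
between the 360° repeat and the crossover repeat; this package defines
dpf against the crossover repeat (matching the 10–40 repeats/µm axis
convention of the population maps) and additionally exports
dpf_360 = hnd/pitch_360. Population structure is visualized as 2D
Gaussian KDE maps of (dpf, h) or (dpf, csa) with per-axis Silverman
bandwidths and highest-density contours at 25/50/75% mass (levels are
a display choice).

## Structural distance, heterogeneity, clustering

The dissimilarity of two filaments is the L1 combination
d_ξ = d_cs + d_dpf, where d_cs is the RMSD between the two 360-point
envelopes minimized over cyclic azimuthal shifts at 1° steps (the
in-plane phase of a helical filament is arbitrary; reflection is *not*
searched, as it would flip chirality), standardized by σ_cs, and
d_dpf = |dpf_v − dpf_w|/σ_dpf. The σ values are sample SDs (n−1) of
the raw components over all pairs of the analyzed dataset and are
stored with the matrix so cross-dataset comparisons reuse them.

The heterogeneity index HI of a population is the quadratic mean of
its pairwise distances, with a standard error by leave-one-*filament*-
out jackknife (pairs sharing a filament are dependent, so pairs are
not the resampling unit). Clustering is agglomerative with the
unweighted average linkage (the mean of all cross-pair distances);
ties break deterministically by lowest member index. Matching against
a reference structure extracts the cluster of filaments with
d_ξ < 0.5 to the reference (seeds), extended by filaments with
d_ξ < 1.0 to the reference and to every accepted member.

## Cryo-EM references

Deposited filament maps (MRC/CCP4, read via gemmi) are thresholded at
the author-recommended contour, denoised by dropping connected
components below 5% of the largest, triangulated (marching cubes),
axis-aligned (helical depositions put the axis along box z; the
principal inertia axis corrects only small tilts, as PCA is unreliable
for stubby segments), and helically extended with the deposited screw
operation (twist per subunit, rise per subunit) to a target length.
The tip-accessible cross-section is the morphological closing of the
unwound mean cross-section with a disk of the tip radius (implemented
with Euclidean distance transforms; cross-checked in tests against an
independent polygon-buffer oracle), sampled at 1°. dpf follows from
(twist, rise, symmetry); because deposition handedness conventions
vary, a per-entry handedness override is supported. Simulated AFM
images of references reuse the same dilation contract as phantoms.

## Synthetic study conditions

The synthetic study emulates a four-condition in vitro assembly
experiment with 100 filaments per condition. Each filament is a lobed
phantom whose core radius, lobe depth, crossover repeat and symmetry
are drawn from condition-specific distributions; the conditions inject
increasing structural variance in the order HEPES < Tris < phosphate
pH 7.4 < phosphate pH 8.0 (phosphate analogues spread mostly in
filament width, the Tris analogue mostly in twist), reproducing the
qualitative heterogeneity ranking of in vitro Aβ42 populations.
Across the study 10.3% of filaments are right-handed, assigned by
fixed proportion per condition (population composition is a study
condition, not a coin flip; with equal condition sizes the realized
fraction rounds to 10.0%).

The 21 cryo-EM reference entries are represented by *synthetic
geometry stand-ins* (real maps are not redistributable): unions of
round protofilaments with deterministic per-entry convex "fold detail",
a shape family distinct from the population phantoms. Mirroring the
study's geometry, most stand-ins lie outside the population's
morphometric support; two patient-brain-type analogues sit at the
sparse edge of the cloud, where small planted sub-populations (9 and 5
of 400) of near-copies represent the rare in vitro species that match
ex vivo structures.

The randomized null set draws 4,000 specifications uniformly within
bounds spanning the observed morphometric ranges (radii 0.75–6 nm,
360° pitch 50–400 nm, symmetry 1–3, either handedness), with the single
hard rule r_min < r_max enforced by rejection; specs are realized as
cosine-lobe sections under the same tip closing. The measured
chance-match rate of this null against the synthetic stand-ins is of
order 0.1% — higher than the figure obtained with real atomic-detail
maps, because tip closing leaves the smooth stand-ins less individual
than real fold outlines. The corresponding acceptance check is
therefore expected to fail in this synthetic-reference setting; the
null-match machinery itself (bookkeeping, thresholds, seeding) is
exercised and the rate is reported as computed.

What passing tests show — and do not. The synthetic populations
demonstrate that the pipeline recovers known geometry through the full
imaging chain (envelope round trips within max(0.2 nm, 2%) at tip radii
up to 5.5 nm, cod within 5%, handedness across the pitch range) and
that the population statistics behave as designed. They do not
demonstrate robustness to real-image nuisances: surface contamination,
fibril bundling and crossing, scanner drift and scars, tip wear or
double tips, or height loss from sample deformation.

## Numerical choices and problem sizes

Scan simulation uses a 4× oversampled grid; phantom rasterization
samples the lateral axis at an additional 4× sub-resolution so that
cell maxima do not bias sloped surfaces upward. Deconvolution uses 4×
upsampling and cubic interpolation. The default test and acceptance
problem sizes — filaments of ~600–750 nm at 1.953125 nm/px (the 4 µm /
2048 px calibration), 400-filament populations, 4,000-spec nulls — were
chosen so the full analysis reproduces the study-scale pair counts
(79,800 / 8,400 / 84,000) while a complete run stays in the
minutes range on a single core.

Known limitations: symmetry estimation discriminates poorly for
near-circular sections (by construction it then reports 1 with a
low-confidence flag); azimuthal orientation of envelopes is defined
only up to the tracing-direction convention; the certified envelope
retains a genuine ~1-pixel lateral ambiguity at the occluded flanks
below a filament's equator; and planar (per-cross-section) tip closing
approximates the fully 3D helical accessibility, which is accurate for
twist rates where the axial opening of surface grooves is much wider
than the tip.
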