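# afmhelix

Individual-filament 3D structural analysis of amyloid fibrils from AFM
height images.

Amyloid fibrils assembled from one peptide are structurally
polymorphic: the same sequence forms filaments differing in
protofilament fold, number and packing. Ensemble methods (cryo-EM
class averaging, ssNMR) resolve the few dominant structures;
topographic AFM resolves *every individual filament* in a population.
`afmhelix` turns calibrated AFM height images into per-filament 3D
helical surface envelopes and population-level polymorphism
statistics, for researchers studying filament self-assembly and
structural heterogeneity.

The pipeline:

1. **Trace & straighten** — sub-pixel ridge tracing, digital
   straightening, crossover repeat (*cod*) by FFT of the central height
   profile, twist handedness (*hnd* = −1 left, +1 right) from the 2D
   Fourier spectrum, selection rules (≥ 3 crossovers, ≥ 150 nm).
2. **Contact-point reconstruction (CPR)** — an AFM image is the
   morphological dilation of the surface by the reflected tip; eroding
   with the tip and locating each pixel's tangency point undoes the
   lateral broadening and yields a sub-pixel contact-point cloud.
3. **Helical envelope** — moving-window helical averaging (window =
   180° of twist; twist/pixel = 360°/(periodicity × symmetry)) pools
   unwound contact points into the mean tip-accessible cross-section
   r̄(θ) at 1° sampling, plus bivariate-normal-KDE cross-section
   density maps.
4. **Morphometrics** — h, cod, hnd, dpf = hnd/cod, and the polar
   integrals csa = ½∮r²dθ, csr = ⟨r⟩, csjz = ¼∮r⁴dθ; 2D polymorph
   distribution maps of (dpf, h) and (dpf, csa).
5. **Population analysis** — the structural distance
   d_ξ(v,w) = d_cs + d_dpf, where d_cs is the azimuthally registered
   RMSD of the two envelopes standardized by σ_cs and
   d_dpf = |dpf_v − dpf_w|/σ_dpf; heterogeneity index HI = RMS of all
   pairwise d_ξ with jackknife SE; average-linkage hierarchical
   clustering; match-cluster extraction at d_ξ < 0.5 (seed) / < 1.0
   (member).
6. **Cryo-EM comparison** — MRC/CCP4 maps are contoured, denoised,
   axis-aligned and helically extended from deposited twist/rise; their
   tip-accessible cross-sections are matched against the AFM envelopes
   under shared σ constants, with a randomized-fibril null set for
   match significance.

A first-class synthetic-data module generates ground-truth twisted
phantoms, simulates scans by exact tip dilation with realistic noise
(background sd 0.255 nm), and samples the randomized null fibrils —
every algorithm is validated against known geometry.

## Worked example

```python
import numpy as np
from afmhelix import synthetic, pipeline, population

# a two-lobed, left-handed filament: crossover repeat 120/2 = 60 nm
phantom = synthetic.PhantomParams(cross_section=("lobed", 2.0, 3.2),
                                  symmetry=2, pitch_360=120.0,
                                  handedness=-1, length=620.0)
filament = synthetic.make_phantom(phantom)
grid = synthetic.ScanGrid(nx=340, ny=48, noise_sd=0.255)
image = synthetic.simulate_scan(filament, synthetic.TipModel(2.0),
                                grid, seed=7)

result = pipeline.analyze_filament(image, (170, 24))
rec = result.record
```

This prints (formatted):

```
cod  =   60.0 nm   crossover repeat
hnd  = -1         twist handedness
dpf  = -0.0167 1/nm
h    =   6.58 nm   average crossover-peak height
csa  =   20.8 nm^2 tip-accessible cross-sectional area
csr  =   2.55 nm   mean cross-sectional radius
csjz =   74.5 nm^4 second polar moment
```

The crossover repeat (60 nm), handedness (left) and apex height
(≈ 2 × 3.2 nm plus noise) recover the generator's ground truth; csa is
the area of the tip-accessible cross-section (slightly above the true
lobed section's 21 nm² because the 2 nm tip bridges the lobe grooves).

Population level — two condition analogues with different injected
structural variance:

```python
envs = (pipeline.render_population("hepes_ph7.4", 30, seed=1)
        + pipeline.render_population("naph_ph8.0", 30, seed=2))
dm = population.distance_matrix(envs)
hi_h = population.heterogeneity_index(dm, list(range(30)))
hi_p = population.heterogeneity_index(dm, list(range(30, 60)))
```

```
pairs = 1770
HI(HEPES analogue)     = 2.25 +/- 0.34
HI(phosphate analogue) = 3.26 +/- 0.27
```

The phosphate analogue, generated with a broader polymorph
distribution, scores a higher heterogeneity index — the population's
RMS pairwise structural distance.

A CLI wraps the same library (`afmhelix simulate / trace /
reconstruct / morphometrics / cluster / match / fixtures / report`);
see `afmhelix --help`.

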