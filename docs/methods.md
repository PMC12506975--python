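# Methods

This note documents the models implemented in duotomo, the assumptions they
make, the defaults that matter, and what the synthetic experiments do and do
not demonstrate.

## Coordinate and geometry conventions

The array is an arc of radius 130 mm centred on the origin, opening upward;
element angles are measured from the downward vertical and span the arc
symmetrically, so elements 0 and N−1 are the two topmost (and reserved)
elements. Element normals point at the arc centre. Imaging grids use
pixel-centre sampling, index (0,0) at the (−x, top) corner; depth is measured
downward from the image top, and depth *below the skin* from the detected
skin line. The default grid is 120 mm × 50 mm with its midpoint 5 mm below
the array centre (480 × 200 px at the 0.25-mm real-time pitch, 1200 × 500 at
the 0.1-mm offline pitch). The published element layout is nonuniform but
untabulated, so the default is uniform angular spacing with a
`custom-table` hook for per-element angles.

## Forward models

Both forward models are linear, single-speed (c = 1.52 mm/µs), straight-ray
models with band-limited pulses at the 3-MHz centre frequency:

* **Photoacoustic**: each absorbing pixel with amplitude
  `absorption × fluence(depth)` deposits an N-shaped pulse
  `−sin(2πf₀t)·exp(−t²/2σ²)` centred at `t = d/c` with 1/max(d, pitch)
  geometric decay. The Gaussian envelope SD is
  `σ = √(2 ln 2)/(π·b·f₀)` for fractional bandwidth `b` (default 0.7, a free
  choice; the transducer bandwidth is not published). The fluence profile is
  a parametric exponential `exp(−μ_eff z)` calibrated so the surface-to-50-mm
  ratio is 62 (dark field) or 220 (bright field); it replaces optical Monte
  Carlo simulation.
* **Pulse-echo**: tissue is represented by a deterministic set of discrete
  point scatterers drawn from the reflectivity map (sub-pixel jittered,
  reflectivity = local map value), which produces fully developed speckle
  under coherent summation. Each scatterer inside the emitter's transmit
  diffraction cone (half-angle 48°, the upper end of the published 38–48°
  interval) contributes a cosine tone burst at the two-leg delay with
  `1/(d₁·d₂)` decay. The tumor + halo region is sampled at ≥ 4 scatterers/mm²
  with amplitudes scaled by √(density ratio) so that expected envelope power
  is unchanged — without this, the intratumoral echo texture would simply
  not be sampled. Pulses are evaluated from an 8× oversampled lookup table
  (linear interpolation, ±3σ support; relative amplitude error ≲ 1e−3).

Not modelled: frequency-dependent attenuation, acoustic heterogeneity
(single speed end-to-end, matching the single-speed reconstruction
assumption), elevational focusing (strictly 2D), and nonlinear propagation.

## Reconstruction

**PACT DAS.** `pixel(x) = Σ_d w(d,x) · s_d(|r_d − x|/c)` over the receive
elements, delays linearly interpolated, delays outside the recorded window
contributing zero (counted and warned). The apodization weight is a function
of the detection angle θ between the element normal and the element→pixel
direction: `none` (1), `cosine` (cos θ, the default) or `hann` (cos²θ);
weights are zero beyond 90°. The unipolar variant combines each delayed
sample with its scaled time derivative, `s(τ) − κ·s′(τ)` with
`κ = deriv_scale/(2πf₀)` (default `deriv_scale` 1, which makes the
derivative term dimensionally matched at the centre frequency), and
rectifies the summed image at zero: the derivative term rotates the pulse
phase so the positive extreme sits at the true arrival time, and
rectification removes the remaining negative lobes, so point absorbers
reconstruct as clean nonnegative peaks at the bipolar peak location.
Outside the well-resolved elliptical field of view (82 × 63 mm) the image
can be replaced by a Gaussian-smoothed copy (σ = 2 px) to suppress
spatial-undersampling streaks; pixels inside the ellipse are never touched.

**URCT.** Per emitter frame: analytic (Hilbert) signal per channel, complex
two-leg DAS over the gated receivers (element axis within 90° of the emitter
axis), cosine receive-directivity weighting, and — mirroring the transmit
cone of the forward model — reconstruction only of pixels inside the
emitter's diffraction cone. The compound image is the mean of per-frame
envelopes normalised per pixel by the number of covering cones. Without the
cone gate, each frame smears echoes along entire ellipses into regions the
emitter never insonified, and with few emitters that clutter dominates the
image. Display conditioning is 20·log₁₀(env/max) clipped to a 50-dB dynamic
range and mapped to [0,1], optionally followed by CLAHE (8 × 8 tiles, clip
0.01). **Quantitative amplitude statistics are taken on the log-compressed
image, not the CLAHE output**: adaptive histogram equalisation forces every
neighbourhood toward a uniform histogram and thereby erases the cross-case
amplitude differences the features are supposed to measure. CLAHE is a
display stage.

## Vascular post-processing

* **Skin surface**: per-column first crossing of 25% of the robust (99.5th
  percentile) maximum, median-filtered over 5 columns, jumps clamped to
  5 px, gap columns interpolated.
* **Depth compensation**: per-depth gain = (first-band mean)/(band mean) in
  2.5-mm bands below the skin, clipped to [1, gain_cap] (default 20), made
  nondecreasing with depth (isotonic), empty bands carrying the previous
  gain. Gains never darken a pixel.
* **Vessel enhancement**: multiscale Frangi vesselness with σ = d/4 … d/2
  covering vessel diameters 2–7 px, blended onto the max-normalised image
  with weight 0.1.
* **Skeletonisation** (order: Gaussian smooth σ=1 px → Frangi → hysteresis
  threshold → remove small objects (<5 px) → fill small holes → thin →
  remove branch points → clear spurs → drop components <5 px): the
  hysteresis threshold is applied to the *product* of vesselness and the
  robustly normalised intensity (clipped at its 99th percentile), with
  absolute thresholds 0.15/0.40 on that [0,1] response. The product is
  essential: sparse-view DAS streaks are tubular, so vesselness alone
  saturates on artifacts, and any scale tied to the image maximum lets one
  bright vessel cluster suppress detection of everything else. Remaining
  pixels are traced into ordered, branch-free segments.
* **Volumes**: translation-only rigid registration of each slice to its
  predecessor (the described motion is bulk drift/heartbeat) using
  Hann-windowed cross-correlation with upsampled-DFT sub-pixel peak
  localisation (recovers injected shifts to <0.25 px RMS), then linear
  interpolation along the scan direction (step 0.71–1.0 mm) to cubic-ish
  voxels. Depth-encoded projections take the per-column maximum through a
  slab and colour it by the 3D Euclidean distance of the argmax voxel to the
  skin surface (distance transform, fixed turbo map over 0–50 mm).
* **CNR** is (mean vessel − mean background)/SD background on the raw,
  unfiltered reconstruction.

## Zones and features

The tumor zone is the (hypoechoic) mass mask; the boundary zone is a 3-mm
dilation band (the halo width is not published; 3 mm is a typical echogenic
halo); the reference zone is breast tissue in the tumor's depth band more
than 5 mm beyond the boundary's outer edge, so amplitude normalisation
compares tissue at comparable optical fluence. Eleven features per mass:

| feature | definition |
| --- | --- |
| v_count_tumor / v_count_boundary | skeleton segments intersecting the zone |
| v_density_tumor / v_density_boundary | skeleton px / zone px |
| amp_mean_tumor_rel, amp_p90_tumor_rel | mean / 90th-pct unipolar amplitude in tumor ÷ same statistic in reference |
| amp_hetero_sd_tumor / _boundary | SD of amplitude over skeleton px in the zone |
| form_factor | 4πA/P², P from a σ=1 px smoothed marching-squares contour |
| axis_ratio | major/minor axis of the second-moment ellipse |
| echo_sd_tumor | SD of the log-compressed URCT amplitude in the tumor |

These instantiate the four published feature families (vessel number/
density, single-wavelength amplitude, vascular heterogeneity, anatomical
shape/echo); the exact clinical feature table is unavailable, so the set is
frozen here and reproducible from these definitions. The relative amplitude
features are invariant to global rescaling of the photoacoustic image;
counts and the heterogeneity SDs are covariant, as tested. Breast-wide
metrics (angiogenesis occurrence in 4-mm tiles above 1.5× the breast mean,
vascular distance metric, 6-mm superficial exclusion) follow the published
definitions directly.

## Diagnostic model

Standardisation is zero-mean/unit-variance with the population SD (ddof=0)
fitted on training rows only. Selection: (1) Welch two-sided t-test,
keep p < 0.01; (2) for pairs with |Pearson r| > 0.85 keep the smaller-p
member (ties by name); (3) keep features whose class-conditional density
overlap (Gaussian KDE, Silverman bandwidth on the pooled sample, shared
512-point grid) is below 75%. An empty retained set is a valid result; the
pipeline then falls back to all scalable features and records that it did.

The classifier is a compact NumPy 1D CNN: four same-padded Conv1D layers
(channels 16/16/32/32, kernel 3) with ReLU, max-pooling after the second and
fourth convolutions, three dense layers (32/16/1) with ReLU and dropout 0.5,
sigmoid head. Full-batch Adam (lr 0.01, 200 epochs, binary cross-entropy);
every random draw (initialisation, dropout) flows from one seed, so
identical seed + data give bit-identical probabilities. The POM threshold is
the largest threshold whose sensitivity meets the target (default 0.95) on
the evaluated set; the published clinical threshold is cohort-specific and
not a reproducible target, so the toolkit always reports its own threshold
with provenance. Permutation importance is the mean AUC drop over seeded
column permutations; it should be read on held-out rows (on training rows a
flexible model credits even noise columns). Confidence intervals are exact
Clopper–Pearson (beta-quantile tail inversion; x=0 → lower 0, x=n → upper 1),
and paired-specificity comparisons use the exact McNemar binomial on
discordant pairs.

## The synthetic cohort: what it is and is not

The generator emulates the *contrast structure* that separates malignant
from benign masses: malignant archetypes have more and denser intra- and
peritumoral vessels (Poisson counts with a 3.0×/2.6× factor against
0.4×/0.4× benign), more tortuous short angiogenic vessels scaled to the
tumor radius, brighter and more variable vascular amplitude (×1.6 mean,
lognormal σ 0.45 vs 0.15), more irregular and elongated masses (boundary
perturbation 0.28 vs 0.07; axis ratio 1.5–2.8 vs 1.0–1.6), and
heterogeneous internal echoes modelled as discrete echogenic foci plus
smooth reflectivity texture (smooth texture alone at realistic contrast is
unrecoverable under speckle and sparse-aperture clutter, so the foci carry
the echo-heterogeneity contrast). Effect sizes were chosen once so that each
archetype-encoded direction survives the full imaging chain on the default
study acquisition; with these defaults every one of the 11 features
separates the arms (rank-sum p < 0.01 at 80 masses/arm) in the encoded
direction, which is a property of the generator + pipeline, not evidence
about clinical data. Passing tests show the pipeline preserves designed
contrasts end to end; they do not show that real tumors are this separable,
that the features match the clinical feature table, or that the reported
AUC transfers to patients.

## Study problem sizes

The default study simulates 160 masses (80/80, split half train / half test
at the mass level, all masses treated as independent observations) with a
reduced acquisition chosen as a deliberate compute/fidelity balance: 512
elements for photoacoustic reception, 4 ultrasound emitters with every
second receiver (the full system uses 30 emitters and all 480 receivers),
0.25-mm pixels, 20-MHz sampling, 1200 base scatterers, and quantitative
analysis confined to a central 80 × 36-mm field of view (the well-sampled
core of the 82 × 63-mm resolved ellipse). Fewer emitters mainly raise
speckle/clutter variance in the ultrasound arm; the analysis-FOV restriction
mirrors confining quantitative reading to the well-resolved region. One case
takes ~2.5 s on one CPU; a full study plus model fitting runs in minutes.

## Numerical choices and degenerate inputs

Delay interpolation is linear everywhere, matching the brute-force oracles.
Distances in the forward models are floored at one pixel pitch to avoid
singularities. All-zero images are defined outputs (zero image, empty
skeleton) except where a result would be meaningless (skin detection,
CNR with zero background variance, empty reference zones), which raise
typed errors. Closed skeleton loops get a vascular distance of exactly 0.
Zero-variance training features abort standardisation with the feature
named. The angiogenesis tiling uses only tiles fully inside the breast mask.

## Known limitations

No attenuation or dispersion; a single sound speed end to end; 2D only;
uniform element spacing instead of the unpublished nonuniform layout; the
super-resolution network along the scan direction is out of scope (volumes
are built without it); sO₂ is not computed (single-wavelength amplitude
only); the 11 features are a reconstruction of the published feature
*families*, not the clinical table; and the synthetic cohort cannot
reproduce clinical sensitivities/specificities — only the printed
count-derived statistics are reproduced exactly.
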