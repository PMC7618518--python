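# Methods

This note documents the models and estimators implemented in
`nanodomain`, the defaults and why they were chosen, the numerical
choices, and what the synthetic data can and cannot show about real
measurements.

## 1. Synthetic nanodomain fields (`nanodomain.simulate`)

The generator emulates the observables of surface nanoclusters imaged by
dSTORM: clusters of uniform size on a regular lattice with a bimodal
distribution of localizations per cluster.

**Geometry.** Cluster centres sit on a square lattice (triangular
available via `lattice="triangular"`) with i.i.d. Gaussian jitter applied
to each lattice point. The generative geometry of real nanodomain
"tessellation" is unknown; the lattice is a configurable modelling
assumption, not a claim about the underlying biology. Emitters are
uniform on a disk of the configured diameter around each centre, so the
ground-truth diameter is exactly the disk diameter. Background emitters
are a homogeneous Poisson field.

**Defaults** (the study conditions for all recovery tests):

| parameter | default | rationale |
|---|---|---|
| field | 10 × 10 µm | the imaged surface area of a ~12 µm leukemia cell |
| spacing | 315 nm | midpoint of the observed 300–330 nm centre spacing |
| jitter sd | 5 nm | small; keeps nearest-neighbour distances inside the observed 300–330 nm band. Because the NN distance is a minimum over ~4 lattice neighbours, its mean drops ≈ 1.03·√2·jitter below the spacing, so sd much above ~10 nm would push the mean NN below the band |
| diameter | 119 nm (HL60) / 165 nm (OCIAML3) | the two cell-line presets |
| counts/cluster | 0.5·N(65, 10) + 0.5·N(130, 10) | the two observed populations at 50–80 and 120–140 localizations |
| background | 2 µm⁻² | sparse non-specific binding |
| localization noise | Gaussian, sd 10 nm | typical dSTORM precision; well inside the 30 nm filter |

`field_to_localizations` is the table-level shortcut: each emitter
becomes one localization with Gaussian noise of sd equal to the nominal
uncertainty. This deliberately bypasses blinking/rendering/fitting so the
cluster pipeline can be tested at scale; the imaging stages have their
own end-to-end test at small scale (§2).

**Blinking** is a two-state model: per-frame Bernoulli activation
(`p_on`) with geometric on-times (mean `mean_on_frames`), the simplest
model that produces the multi-frame bursts the merging stage must
handle. Overlapping activations of one emitter emit once per frame.
Expected events per emitter ≈ `p_on · frames · mean_on_frames`; the
exact per-frame on-probability is 1 − Π_k (1 − p·qᵏ) with q = 1 − 1/mean,
which the tests use as the closed-form oracle. No photophysics beyond
two states (no triplet shelving, bleaching, or spectral models).

**Camera.** Events render as pixel-integrated 2D Gaussians (erf
differences, so photons are conserved to < 1% for ROIs ≥ ±5σ);
counts = sensitivity × (dark + gain × photons), with optional Poisson
shot noise and Gaussian read noise. Hot/cold pixels are multiplicative
sensitivity deviations, which is exactly the defect class the pixel
correction is designed to remove.

**Spectral counts** are negative binomial with var = µ + α·µ², α the
`dispersion` (the standard RNA-seq/proteomics convention), drawn
independently per replicate and condition. Planted hits have
target-condition mean = baseline × fold and are drawn only from proteins
that survive standard preprocessing (non-contaminant, ≥ 2 unique
peptides), so recovery statistics measure the hit caller rather than the
filters. Unique peptide counts are 1 + Poisson(3), independent of
abundance — a simplification; in real data the two correlate.

## 2. Localization chain (`nanodomain.localization`)

**Pixel correction.** The first 4,000 frames (or all, if fewer) are
averaged; a pixel whose mean deviates from the median of its 8-connected
neighbours by more than 3% is flagged and multiplied by
(neighbour median)/(mean) in every frame, then dark counts are
subtracted with a floor at zero. The premise is that blinking signals
average out of the temporal mean while sensitivity defects persist — so
the correction assumes a low duty cycle. At the compressed frame budgets
of some tests (hundreds of frames with high `p_on`) spot signal survives
the average and is flagged like a defect; this is a property of the
scaled test conditions, not of the method, and the idempotence property
(the mask rebuilt from corrected frames is empty) is therefore asserted
at a realistic ~0.3% duty cycle. Pixels whose neighbour median is zero
are skipped and logged.

**Detection.** À-trous B-spline wavelet decomposition; the smoothing
kernel is the sampled cardinal B-spline (order 3, scale 2 gives the
classic [1, 4, 6, 4, 1]/16 mask), with mirror boundaries. Candidates are
strict 8-connected local maxima of the second wavelet plane above
1.2 × sd of the first plane (1.1 selectable). The second plane carries
spot-scale structure; the first carries pixel noise, which is why its sd
sets the threshold.

**Fitting.** Odd-sized ROIs around candidates are fitted with a sampled
2D Gaussian (offset + N/(2πσ²)·exp(…)) by `scipy.optimize.least_squares`
after counts→photons conversion by the camera gain. Flat or
non-convergent ROIs are rejected with a reason code. Coordinates:
x = (column + subpixel offset + 0.5) × pixel size, origin at the sensor
top-left, all distances in nm. Localization precision uses the Thompson
formula √((σ² + a²/12)/N) with a the pixel size; the background term is
omitted by default (Mortensen-style ×2 variance selectable) since the
synthetic benchmarks are background-subtracted.

**Merging** is greedy in frame order against open chains: a localization
joins the nearest chain whose *running intensity-weighted centroid* is
within 30 nm and whose last detection is ≤ 5 off-frames old; there is no
on-frame limit, and a chain admits one detection per frame. Merged
records take the intensity-weighted centroid and sigma, summed
intensity, first frame, and a precision recomputed from the summed
photons. The reference point for "maximum distance" (first detection vs
running centroid) is not fixed by the workflow this reproduces; the
running centroid was chosen as the more stable option.

**Drift correction** splits the frame range into 5 equal temporal bins,
reconstructs each at 5× magnification (17.7 nm bins), and estimates each
bin's shift against the first from the FFT cross-correlation peak with
per-axis 3-point quadratic refinement. Per-frame drift is interpolated
linearly between bin centres and extrapolated linearly outside them.
The correction is defined only up to a global translation (the bin-1
frame); tests therefore compare per-bin shifts against injected drift
and residual spread after removing the constant offset.

**Filtering** keeps 60 ≤ σ ≤ 270 nm (inclusive), intensity < 37,800
photons (strict; rejects multi-emitter events and merge pile-ups), and
uncertainty < 30 nm (strict). It is a projection: idempotent and a
row-subset of its input. **Reconstruction** is a 2D count histogram at
pixel/5 = 17.7 nm bins; its sum equals the number of in-bounds
localizations exactly, with dropped out-of-bounds rows logged.

## 3. Cluster pipeline (`nanodomain.cluster`)

**Ripley estimators.** K(r) = A/(n(n−1)) Σ_{i≠j} 1(d_ij ≤ r) by exact
cKDTree pair counting, L = √(K/π), H = L − r. Without edge correction K
is negatively biased near boundaries, so the pipeline uses a guard-zone
variant: focal points are restricted to an inner window inset by the
largest radius, all points supply neighbours, and
K(r) = Σ_focal count(r)/(λ·n_focal) with λ = n/A — unbiased under CSR
(verified in tests), with an isotropic-correction-free simplicity that
matches the "three areas with well-separated clusters" workflow.
Coincident points are flagged as degenerate (K jumps at r → 0⁺).

**Analysis areas.** Three non-overlapping windows, inner side 2 µm plus
a 500 nm guard ring, chosen as the densest by localization count on a
half-side candidate grid (explicit origins can be supplied instead). The
H radius grid runs from 5 nm to the guard width (500 nm) in 5 nm steps:
a grid extending to half the window side would demand a guard ring that
consumes the whole window, so the guard width caps the grid.

**Preferential size and seeding.** The preferential cluster size is
argmaxᵣ H(r) (ties → smallest radius; boundary maxima warn). For disk
clusters of radius R the argmax empirically falls at 1.3–1.5 R. The
DBSCAN radius is 0.45 × the mean preferential size — the fixed
correction factor of the reference workflow, applied verbatim; whether
it was originally derived empirically or theoretically is unknown, and
its provenance is deliberately not reinterpreted here.

**No-signal guard.** Each area's max H is compared against a 19-replicate
Monte-Carlo CSR envelope of the same point count and geometry (a
standard spatial-statistics device, ≈ 95% envelope); the envelope is
evaluated on a 4× coarser radius grid, which is ample for the null's
max-H scale and 5× cheaper. An area below its envelope contributes no
preferential size; if all areas fail, the pipeline warns ("no interior H
maximum…") and returns an empty cluster set rather than clustering
noise.

**DBSCAN and metrics.** DBSCAN (scikit-learn; a core point has
≥ `min_samples` neighbours within ε, itself included) with
`min_samples = 4` by default — unstated in the reference workflow, so
the report includes a sensitivity sweep over {3, 5, 10}. Cluster
diameter is the disk-equivalent 4·√((varₓ + var_y)/2), exact in
expectation for a uniform disk (max-pairwise-extent available via
`diameter="max_extent"`); cluster-to-cluster distance is each centroid's
Euclidean distance to its nearest other centroid (undefined for a single
cluster); localizations per cell is the full table size.

**Antibodies per cell** = localizations per cell / `locs_per_antibody`,
rounded. The calibration constant (default 50) absorbs dye stoichiometry
and fluorophore re-blinking; it is configurable and cross-checkable
against the MESF module. Setting it to the lower per-cluster count mode
m₁ yields the algebraic identity estimate ≈ n_clusters·(w₁ + w₂·m₂/m₁),
which the tests verify.

**Determinism.** All randomness (CSR envelope) flows from
`random_state`; identical inputs and configuration give byte-identical
reports.

## 4. Proteomics hit calling (`nanodomain.proteomics`)

Preprocessing removes contaminant genes (packaged keratin/cRAP-style
list, case-insensitive; a user list can replace or extend it) and
proteins with < 2 unique peptides. Enrichment is mean(target
replicates)/mean(isotype replicates). Division by zero is resolved as:
zero isotype with positive target → +∞, flagged, and always a hit
(absence from the control is maximal enrichment); 0/0 → 0, flagged
undetected. A pseudocount mode (+0.5 to both means) is available. The
global capture ratio is Σ target counts / Σ isotype counts over all
proteins and replicates ("total protein isolated" read as summed
spectral counts; a per-replicate-mean variant is available). The hit
rule is enrichment ≥ max(2, ratio). Enrichments are invariant under
global count rescaling and replicate reordering, and raising a protein's
target counts can never remove it from the hit set at fixed ratio.

A structural limitation worth stating: with triplicate means of
low-count data, a ×2 ratio threshold has a per-protein false-positive
rate of several percent under realistic overdispersion (var = µ + 0.5µ²
at µ = 10 gives ≈ 16%), so when only a few percent of proteins are truly
enriched, precision is dominated by baseline noise even though recall is
essentially perfect. The threshold rule is reproduced faithfully rather
than "fixed" (e.g. by count-based tests), because the rule *is* the
procedure being characterized.

Intersections across ≥ 2 cell lines are exact set algebra (per-line
unique sets, every membership class, at-least-k unions); the RBP
fraction is 100·|hits ∩ RBP|/|hits| against a user-supplied annotation
list (no list is bundled — published RBP censuses differ, and the
choice materially changes the number). GO analysis is out of scope; hit
lists are exported ranked by enrichment for external tools.

## 5. MESF calibration (`nanodomain.mesf`)

Least-squares line on log₁₀(MFI) vs log₁₀(MESF) over ≥ 2 bead
populations, with optional blank subtraction; samples invert through the
line. The vendor tool's exact arithmetic is proprietary; a log-log
linear fit is the standard MESF practice and is exact on its published
example layouts. The slope must be positive (monotonicity: brighter is
never fewer molecules) and out-of-range samples are returned with an
extrapolation flag. Round-trips are exact on collinear calibration data.

## 6. What the tests do and do not show

The synthetic generator reproduces the *observables* used by the
pipeline (cluster size, spacing, count bimodality, defect pixels,
overdispersed counts) but not: inhomogeneous labeling efficiency,
antibody cross-linking, fluorophore photophysics beyond two states,
membrane curvature projected into 2D, structured (non-uniform)
background, or abundance-correlated peptide counts. Recovery results
therefore validate the estimators and their composition — not staining
or acquisition. Problem sizes in the default test run are chosen for
desk-scale execution: 5 fields of 10 × 10 µm per preset (~10⁵
localizations each, ~1,000 clusters) for recovery statistics, 48 px
sensors with 200–3,000 frames for the imaging chain, and 10 × 1,000
proteins for hit-calling recovery.
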