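# Methods

This note documents the models, geometry, parameter choices and known
limitations behind `popdcquant`. It describes what the code computes;
every empirical number referenced here is produced by the test suite or
`scripts/acceptance.py`, not asserted from memory.

## Fiber segmentation and compartment geometry

Muscle-fiber cross-sections are segmented from the membrane-marker (SGCA)
channel alone: the channel is thresholded (Otsu by default; a fixed
threshold can be supplied, since published protocols typically state only
that "a threshold limit" was used), and fiber interiors are the
sub-threshold connected components (4-connectivity). Components smaller
than `min_fiber_area_um2` (default 150 µm², well below any real fiber) are
dropped, and components touching the image border are dropped by default —
this also removes the background network in fields where fibers do not
tile completely.

The *outline* of a fiber is defined as the exterior boundary band of its
segmented interior — the pixels adjacent to, but outside, the interior,
which is where the bright marker sits; this matches the behaviour of
outlining a thresholded selection in FIJI-style workflows. The sarcolemmal
*ring* is every pixel within Euclidean distance `dilation_radius_px`
(default 2) of the outline. Squared distances are computed in exact integer
arithmetic from the nearest outline pixel (KD-tree lookup, integer
re-evaluation), so the ring is reproducible pixel-for-pixel against a
brute-force distance computation. A pixel reachable from two fibers'
outlines belongs to the nearer fiber; exact ties go to the lower fiber id.
The cytoplasmic *interior* is the fiber region minus all ring pixels, so
rings and interiors are disjoint within and across fibers by construction.
Fibers whose interior is consumed entirely by the ring are skipped and
logged.

Because the ring is a band centred near the fiber edge, it mixes
true-sarcolemma pixels with a margin of cytoplasm. Both channels are
averaged over the *same* band, so the SGCA normalization cancels the
geometry; what remains is a dilution of group effects on the ring
component by the cytoplasmic contribution. With the default synthetic
intensities (ring:interior contrast ≈ 17:1) this bias is ≈ +0.03 on a
simulated 50% reduction — visible in the acceptance output and discussed
below. Real analyses inherit the same property: ring-ROI fold changes are
slightly conservative.

Fiber cross-sectional area is the area of the full segmented fiber region
(not the ring-eroded interior), in µm² via the pixel size, so reported
areas match the anatomical cross-section.

Background subtraction is *not* applied to tissue images (it is applied to
cultured-cell images, below); a configurable flag exists but defaults off.

## Synthetic biopsy mosaics

Transverse muscle sections are emulated as a space partition: fiber areas
are drawn from a lognormal (default median 3000 µm², σ = 0.3, matching
healthy adult fiber calibers), seeds are placed by dart throwing and the
field is partitioned by an additively weighted power diagram, iterated
~12 times with (i) Lloyd-style centroid relaxation during the first sweeps
and (ii) feedback of each fiber's realized *interior* area onto its power
weight, so realized areas track their draws (sample median within a few
percent of the lognormal median; verified against an independent
Monte-Carlo oracle). Background pockets fully enclosed by fibers are
reassigned to the nearest cell, so fibers share straight borders like real
fascicles; the outer background remains where packing leaves room.

Each cell's outermost `ring_thickness_px` (default 3) band is the
sarcolemmal ring; the membrane-marker channel is bright only there. The
target channel carries `background + group_effect × ring_intensity` on the
ring and `background + interior_intensity` inside, each multiplied by a
per-fiber lognormal factor with CV `intensity_cv` (default 0.1) modelling
fiber-to-fiber expression heterogeneity; the factor multiplies both
compartments of the target channel and cancels in ratios. Noise is
additive Gaussian (default SD 5 a.u. against a ring signal of 200),
clipped at zero. Defaults: marker ring 150, target ring 200, target
interior 12, background 4 — a strongly sarcolemmal target over a dim
diffuse cytoplasmic pool.

What the generator does *not* emulate: point-spread blur, chromatic
misregistration, uneven illumination, connective tissue and freezing
artefacts, intensity gradients across sections, or non-convex fiber
shapes. Tests passing on these mosaics therefore validate the geometry,
normalization and statistics of the pipeline — not robustness to optical
artefacts.

## Transfected-cell fields and localization ratios

Cells are non-overlapping discs with a DiD-bright membrane annulus
(3 px), a nuclear disc, and reporter channels whose noise-free
membrane:cytoplasm ratio equals the requested value exactly (the nuclear
disc carries cytoplasm-level reporter so nuclear-mask errors cannot bias
either compartment). Quantification first subtracts a per-channel
background (median outside the cell masks; 5th percentile of the whole
image as fallback — idempotent on noise-free data), then segments each
cell either from an operator-supplied boundary polygon (dilated by a
2 px band; the faithful counterpart of manual outlining, takes precedence)
or automatically from the thresholded DiD ridge; the cytoplasm is the
enclosed area minus the membrane band and the nucleus. When no nucleus
channel is present the cytoplasm is the full enclosed interior minus the
membrane band. Cells touching the image border are excluded.

In automatic mode the thresholded ridge itself is the membrane mask (it
already spans the membrane; extra dilation would dilute the membrane mean
with background on one side and cytoplasm on the other). Recovered median
ratios over 30-cell groups are within 10% of truth across ratios 0.5–5,
with a mild compression at high ratios from edge pixels straddling the
annulus.

## BiFC quantification

Pixels expressing the transfection control above background — threshold =
median + 3×MAD of the non-cell region, since published protocols state
only "above-background" — are gated in, nuclei (Otsu on the nuclear
channel) are removed, and the per-image signal is median(Venus)/
median(mRFP) over the gate. The replication unit is the image: group means
of per-image signals are normalized to the wild-type pair (exactly 1 by
construction) and compared by one-way ANOVA with Dunnett's many-to-one
test. The generators tie the interaction channel to the control channel
per cell (Venus = efficiency × mRFP), so the per-image signal estimates
the interaction efficiency directly.

## Type-1 qBRET

Raw plates carry one dye well and one matched dye-free (DMSO) well per
condition; the background BRET is subtracted per condition
(`bret_corr = bret_raw − bret_background`), and luminescence/fluorescence
are placed on a common expression scale by user-supplied calibration
factors (default 1.0; published protocols normalize but do not report
factors). Total expression is donor + acceptor on that scale; the acceptor
fraction is f = acceptor/total.

The constant-total design is checked by a nested-model F-test of total
expression against the acceptor:donor ratio (horizontal vs straight-line
fit), restricted to points with ratio strictly greater than 2 where the
fluorescence readout is reliable; its type-I error is calibrated at the
nominal 5% in simulation.

Ideal curves: under random assembly of an n-mer from the donor/acceptor
pool, a donor's complex has n−1 partner slots, each acceptor-occupied with
probability f, so the saturable BRET is Bmax·[1−(1−f)^(n−1)]. The dimer
reduces to Bmax·f — hyperbolic, Bmax·ρ/(1+ρ), against the acceptor:donor
ratio ρ. A monomer produces only bystander BRET, which is non-specific,
non-saturating, and linear in the acceptor level, i.e. slope·ρ =
slope·f/(1−f). This parameterization is a reconstruction of the type-1
qBRET framework (the originating protocol's exact equations are not
restated here); its acceptance surface is simulator/fitter
self-consistency, and within that surface a dimer is classified correctly
in ≥ 95% of noisy 12-point titrations and a monomer rejected against
saturating models in ≥ 90%.

Each candidate model has one linear parameter, fit in closed form by least
squares; model selection is by AICc (small-sample correction; with equal
parameter counts it reduces to RSS comparison, but the AICc values are
reported for transparency). Classification is refused when the
acceptor-fraction span is below 0.4, and a rapid-saturation caveat is
flagged when the winning order is ≥ 3 with sparse coverage of the
saturating limb — higher-order curves saturate so fast that sparse
titrations cannot pin the exact order. The fitter is exposed as a
scikit-learn estimator (`StoichiometryModel`) so it composes with sklearn
model-selection tooling.

## Statistics

All tests are two-sided. Per-fiber and per-cell values are treated as
independent (fiber-within-image correlation is not modelled — a known
simplification). Control-median normalization divides by the matched
control median, making the control group's normalized median exactly 1;
it is idempotent and scale-invariant.

Median 95% CIs use the distribution-free order-statistic interval with
Hettmansperger–Sheather interpolation between adjacent orders, chosen over
the plain binomial interval because the latter over-covers at moderate n
(96.5% at n = 100) while the interpolated interval is near-nominal
(95.1% over 1000 simulated lognormal samples). Samples below n = 6 fall
back to a seeded percentile bootstrap with a width warning.

Mann–Whitney uses the exact null distribution for groups of ≤ 20 without
ties and the tie-corrected normal approximation otherwise. Kruskal–Wallis
uses the tie-corrected H; Dunn's post-hoc z statistics use the standard
rank formula with tie correction, and p-values are Holm-adjusted (chosen
over Bonferroni as uniformly more powerful; the originating analyses do
not name an adjustment). ANOVA's many-to-one follow-up uses Dunnett's test
(scipy), whose p-values are inherently familywise.

## Numerical and reproducibility choices

All randomness flows through `numpy.random.default_rng(seed)`; identical
spec + seed gives bit-identical images and tables. KD-tree queries run
single-threaded; distance comparisons in contested ring pixels use exact
integer arithmetic with ties broken to the lower fiber id. CSV output uses
a fixed float format and JSON is written with sorted keys, so same-seed
runs are byte-identical (hash-checked). Image export quantizes to 16-bit;
in-memory analysis is float64 throughout.

Problem sizes in the test suite and acceptance script — 150 fibers per
arm, 30-cell groups, 9 images per BiFC group, 200 titrations per
classification rate, 500–1000 replicates per calibration — were chosen as
the smallest designs at which the targeted effects are decisively
detectable on a single CPU in minutes.

## Known limitations

* The ring-ROI dilution bias described above makes fold-change estimates
  slightly conservative; it shrinks with increasing ring:cytoplasm
  contrast and is inherent to band-ROI quantification.
* Automatic cell segmentation expects closed, reasonably bright membrane
  ridges; fragmented dye staining requires the polygon path.
* The qBRET ideal curves assume ideal random assembly at fixed total
  expression; cooperative assembly, incomplete HaloTag labelling, or
  expression-dependent complex formation are outside the model.
* Statistical tests treat objects (fibers, cells, images) as independent
  replicates; hierarchical designs would need mixed models.
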