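# Methods

This note documents the models, defaults and numerical choices behind
saxsqc, what the synthetic data do and do not emulate, and the design
decisions taken where more than one reasonable option existed.

## The coin-toss run statistic

Two noisy measurements of the same curve, compared point by point, give
a sign sequence `sign(I₁(qᵢ) − I₂(qᵢ))` that under the null (identical
underlying curves, exchangeable noise) is a sequence of fair coin
tosses. The statistic is the length *L* of the longest *patch* — a
maximal run of consecutive identical signs — and the reported p-value
is the exact tail probability

    p = P(longest run ≥ L | n fair tosses)

over the 2ⁿ equiprobable ±1 sequences. It is computed by dynamic
programming over the trailing-run length (integer counting, exact
division at the end), which is O(n·L) and agrees with brute-force
enumeration for every n ≤ 16 (asserted in the test suite). With n at
most a few hundred points there is no reason to use an asymptotic
approximation.

Choices:

* **Runs of either symbol** are scored by default (a patch of −1 is as
  diagnostic as a patch of +1); the heads-only variant (runs of +1
  only) is available via `heads_only=True`. Both have exact nulls.
* **Exact ties are dropped** before run analysis. Floating-point ties
  carry no directional information and are vanishingly rare on real
  data; `n` is the post-drop count. A comparison in which *every*
  point ties is degenerate and raises, except inside the center scan
  where it is reported as maximally null-like (n = 0, p = 1).
* The test is **conservative**: because the null is discrete,
  P(p ≤ α) ≤ α. The suite checks this on 1000 iid-noise pairs.
* No multiple-testing correction is applied across the three shift
  comparisons of the center scan; p-values are reported per shift and
  only their ordering enters the decision rule.

## Beam-center verification

Solution scattering is isotropic, so the 2-D pattern must be
centro-symmetric about the true beam position. The check:

1. Take two opposing pie-slice cuts through the assumed center
   (vertical axis: azimuths 90°/270°; horizontal: 0°/180°), averaged on
   a uniform low-q grid whose bin width is the q-increment of one
   detector pixel, from just outside the beamstop (3 pixels) up to
   q = 0.05 Å⁻¹ — beyond that the azimuthal variation of typical
   patterns is too weak to be informative about the center.
2. Compare the two cuts with the run statistic at relative index
   offsets −1, 0, +1. A one-bin offset between the binned 1-D cuts is
   the cheap realization of nudging the center by one data point; no
   re-integration is needed.
3. Decision rule: **keep** if the aligned (offset 0) comparison has the
   largest p-value; otherwise recommend shifting toward the offset with
   the largest p-value (`shift_plus` = move the center toward
   increasing row/column by one bin). The verdict is **inconclusive**
   when all three p-values are ≥ 0.5 (nothing distinguishes the
   hypotheses), when fewer than 10 informative points survive, or when
   the two shifted comparisons tie. The rule is the package's own; the
   underlying signal is simply that mis-centering produces long
   same-sign stretches in the aligned comparison and an offset that
   compensates them.

Default pie-slice half-angle is 10°: narrow enough to stay directional,
wide enough to average a useful number of pixels per one-pixel q bin.
Geometry follows the common detector convention — 0-based fractional
pixel coordinates (col, row), q evaluated at pixel centers,
q = (4π/λ)·sin(θ/2) with tan θ = r·pixel/distance. Bins that receive no
pixels carry an explicit `empty` flag (not zeros) and are skipped by
comparisons.

A center displaced by δ bins shifts the two opposing cuts by ±δ,
i.e. 2δ *relative* bins, so the ±1 offsets only partially compensate a
one-bin planted displacement; what the decision needs is only the
*ordering* of the three p-values, which survives partial compensation
(verified on 100 planted patterns in the acceptance script).

## Buffer subtraction

`I_sub(q) = I_sample(q) − f·I_buffer(q)`, with uncertainties combined
in quadrature. The buffer is first scaled so that its water-peak
magnitude — the windowed **maximum** of I(q) over 1.8–2.2 Å⁻¹, chosen
over an integral for robustness to the baseline — matches the
sample's. Because the protein also scatters under the water peak,
matched buffers must then be scaled *down* slightly; the estimator
finds that factor automatically.

Search: starting at f = 0.9, grow f by 0.01 while the subtraction
passes both criteria; on a violation back off to the last accepted f
and divide the step by 10; stop when the step falls below the precision
(0.0001) or f reaches the cap (1.0 — a matched buffer is never scaled
up; cap termination is reported, not silent). Factors live on the
integer precision grid, so no float drift accumulates. A violation
already at f = 0.9 raises: a factor below 0.9 signals a pathological
pair that needs human attention.

Criterion 1 — over-subtraction of the water peak:

* any strictly negative intensity, or
* a significant interior minimum of `q·I_sub` inside the water window.
  The multiplication by q flattens the gentle high-q decay of the
  atomic scattering factors so a genuine dip stands out. The window is
  smoothed (3-point), rebinned into 9 coarse bins, and a violation
  requires an interior bin to fall below *both* edge bins by more than
  2 propagated bin-σ. The significance guard exists because a strict
  3-point minimum test fires on any noisy sequence near a flat top
  (probability ≈ 1/3 per interior point), which would abort every
  search at its first step; on noiseless data (σ absent) the guard is
  inert and the test reduces to a plain interior-minimum test.

Criterion 2 — dynamic-range growth: the log₁₀ span between the highest
and lowest *positive* intensities beyond q = 0.3 Å⁻¹ (where no
structural features exist) must not grow by more than 0.05 decades
**per accepted adjustment**. The reference span is the span at the last
accepted factor, not a fixed baseline: subtraction legitimately expands
the dynamic range as the buffer residual vanishes, and what marks
over-subtraction is the *rate* at which the span explodes when the
minimum positive value collapses toward zero. Near that collapse the
per-step growth stays large even for 0.0001 steps, so the criterion
localizes the stopping factor sharply; a uniform-grid brute-force
search with the same criteria lands within one grid step of the
coarse-to-fine search on every tested pair (asserted in tests and in
the acceptance script). A subtracted curve that is identically zero
(sample ≡ buffer at f = 1) preserves the span by definition and is not
a violation, so the identity pair runs to the cap; a tail with
negatives but no positives is a degenerate violation.

The 0.05-decade threshold, the dip significance (2σ), the coarse-bin
count (9) and the water window are all configuration on
`ScalingOptions` with the defaults above.

## Sample logistics

The hardware numbers are constants of the module: 18-position holders
(two rows of 9), 9 measured wells per 96-well-plate row (columns 10–12
are mixing stocks only), a buffer required for every 5 samples,
4-character holder names, storage for 20 holders (360 tubes), and OT2
transfer runs capped at 2 plates + 12 holders on 12 deck slots (one
reserved for the fixed trash bin; holders travel in 3-holder adaptors
with a plate footprint).

* Validation is pure (same sheet → same report) and never mutates its
  input; on success it returns an enriched copy with proposal/SAF
  embedded and a fresh version-4 UUID per holder (seedable for
  reproducibility).
* A plate row's wells in columns 1–9 are "measured wells": rows with a
  `buffer_ref` are samples, rows without are buffers, and a sample's
  buffer must itself be a measured well — a buffer parked in columns
  10–12 would never reach a holder and could not be measured.
* Transfer mapping: occupied plate row k (top-down, 0-based) → holder
  k // 2, holder row k % 2; column c → position c or 9 + c. The mapping
  is injective and total over validated wells, deterministic, and the
  emitted measurement sheet always re-validates cleanly (round-trip
  property). Mixing steps for a well precede its holder transfer,
  which carries the mix flag.
* Tip policy: one tip per distinct source well, shared across that
  well's steps; tip racks = ⌈tips / 96⌉. The policy is configurable in
  effect through the reported counts; deck planning takes the rack
  count as input.
* Labels: payload `proposal-SAF-plateid` with a two-digit plate id,
  parse-invertible; malformed ids raise.

## Synthetic data

The generators emulate just enough structure to exercise the
algorithms, with every truth planted and recoverable:

* **Buffer**: flat baseline (1.0, the intensity unit) + weak power law
  (0.002·q⁻¹, an empty-cell-like low-q term) + Gaussian water peak at
  2.0 Å⁻¹ (amplitude 1.0, σ 0.1 Å⁻¹).
* **Sample**: `i0·P_sphere(qR) + c·buffer`, with R = 20 Å and i0 = 5 —
  a small globular protein at high concentration — and planted buffer
  fraction c (default 0.995, the working value of the manual
  procedure). The sphere form factor has a closed form and known zeros
  (first at qR ≈ 4.493), which the tests use as oracles.
* **Noise**: Poisson on counts = intensity × counts-per-intensity,
  rescaled; σ = √counts / scale. 1-D profiles default to 10⁸ counts
  per unit intensity (≈ 10⁻⁴ relative noise at the baseline — the
  quietness of azimuthally averaged, frame-averaged synchrotron data,
  and the regime in which a ±0.001 scaling-factor change is
  detectable at all). 2-D patterns default to 10⁴ counts per unit
  intensity per pixel (~10⁵ counts in the bright low-q pixels), which
  makes the one-bin intensity increment comparable to the per-bin
  noise of a 10° wedge — the "moderate noise" regime where the center
  scan has something to decide.
* **Patterns** are synthesized isotropically about a true center =
  nominal + planted offset and carry the *nominal* geometry, exactly
  the situation the verification faces; truth lives in `pattern.meta`.
* **Spreadsheets**: clean sheets interleave buffers so every rule holds
  (each 9-well row is buffer + 5 samples + buffer + 2 samples);
  `n_samples` counts occupied measured wells, so 72 fills the plate
  and maps to 4 holders. Each plantable rule id mutates exactly one
  rule into violation, and the validators are required to report
  exactly the planted codes.

What the synthetic data do **not** emulate: real protein form/structure
factors (CRYSOL-class), inter-particle interference, radiation damage,
detector artifacts (flat field, polarization, solid angle, module
gaps), SEC elution, or vendor spreadsheet dialects. Passing tests
therefore demonstrate the correctness of the decision logic under the
stated noise model, not detector-specific robustness.

## Problem sizes and determinism

The test suite and the acceptance script use the sizes the guarantees
are stated for: exact-null enumeration to n = 16, 1000 null pairs of
100 points, 100 center-scan patterns per condition (320×320 pixels),
100 scaling pairs on a 638-point grid with a 0.0001-resolution oracle,
and full 72-well plates. Everything runs in well under a minute per
component on one CPU. All randomness flows from explicit seeds or
`numpy.random.Generator` instances; given a pattern or profile pair,
every verdict is deterministic.

## Known limitations

* The center scan tests one axis at a time and ±1-bin offsets only; it
  verifies, it does not refine. Sub-bin displacements blend into the
  "keep" outcome.
* The run statistic conditions on n after tie removal; heavily
  quantized data with many ties lose power.
* The scaling estimator assumes the criteria are (approximately)
  monotone in f along the search path; strongly non-monotone
  pathologies (e.g. oscillating mismatched grids) are out of scope and
  surface as `start-infeasible` or cap terminations.
* Spreadsheet parsing accepts the documented schema only; it does not
  attempt to guess arbitrary vendor layouts.
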