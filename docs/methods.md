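# Methods

## Whittaker smoothing as SOFI trend correction

Each pixel trace `y ∈ ℝⁿ` is fitted by the minimizer of
`||y − μ||² + λ ||Dμ||²`, where `D` is the `(n−d) × n` matrix of order-`d`
finite differences (signed binomial stencil, e.g. `[1, −2, 1]` for `d = 2`).
The normal equations give `μ̂ = (I + λ DᵀD)⁻¹ y`. `I + λ DᵀD` is banded
(bandwidth `d`) and symmetric positive definite; we factorize it once with a
banded Cholesky decomposition (`scipy.linalg.cholesky_banded`) and back-solve
all pixel columns of the unfolded stack against the same factor, so the cost
is `O(n · k)` for `k` pixels. Dense inversion is never used outside test
oracles.

Properties relied on throughout:

* `D` annihilates polynomials of degree `< d`; for `d = 2` the smoother's
  fixed points are exactly the straight lines, and as `λ → ∞` the fit tends
  to the least-squares line through the trace.
* `1ᵀ(y − μ̂) = λ (D1)ᵀ(Dμ̂) = 0`: the residual of every pixel sums to zero,
  so trend correction never changes a pixel's total recorded intensity.
* The smoother is linear in `y`.

`d = 2` is the default and is used everywhere; it is configurable.

## V-curve selection of λ

One global λ is chosen for the whole image. For each λ on a log-spaced grid
(default `10⁻²…10⁸`, 10 points per decade) all pixel columns are smoothed and
the image-aggregated norms `f(λ) = log₁₀ Σ_cols ||y − μ||²` and
`p(λ) = log₁₀ Σ_cols ||Dμ||²` recorded. The V-curve is the sequence of
Euclidean distances between consecutive `(f, p)` points; the selected λ is
the geometric mean of the grid pair at the minimum. Diagnostics (`f`, `p`,
`v` per λ) are returned and exportable as CSV for plotting.

Choices made where the procedure is underdetermined:

* **Aggregation** is by summation over pixel columns (a per-column mode is
  not offered; the correction is defined image-wide).
* **Subsampling:** for images larger than 64×64 pixels a seeded uniform
  subsample of 4096 columns bounds the selection cost; the corner location
  is stable under aggregation.
* **Edge handling:** a minimum at the first or last grid interval triggers a
  warning to widen the grid.
* **Degenerate input:** if every column lies in the penalty null space
  (constant or exactly linear traces) the V-curve is undefined and selection
  raises an error — except inside `detrend_stack("auto")`, where the fit
  equals the data for any λ and the corrected stack is exactly zero, so a
  nominal λ = 1 is used.

**Known limitation.** On *trend-free* blinking data the `(f, p)` curve has no
pronounced corner: two shallow minima of comparable depth appear (one at
λ ≈ 1, one at trend scale ≈ 10⁵), and the global minimum can land at small
λ, in which case auto-selection over-smooths and removes blinking signal.
On data that actually contains a slow trend — the method's use case — the
trend-scale corner wins clearly. When correcting data known to be
trend-free, pass an explicit trend-scale λ instead of `"auto"`.

## Second-order cumulants

At zero time lag the auto-cumulant of a pixel is the population variance
(1/n normalization) of its mean-subtracted trace; cross-cumulants of
neighboring pixels are the corresponding covariances. The output grid is
`(2h−1) × (2w−1)` with physical pixels at even/even positions; horizontal
and vertical virtual pixels take the covariance of the two flanking
neighbors, and diagonal virtual pixels average the two diagonal pair
covariances (both pairs carry the same geometric information; averaging uses
it symmetrically). No distance factor, flat-fielding, PSF equalization or
deconvolution is applied, and negative values are preserved.

Batching baseline: frames are cut into consecutive non-overlapping blocks
(default 50), each block is mean-subtracted and cumulated on its own, and
the per-block images are averaged unweighted. A trailing remainder shorter
than one block is dropped with a warning (the benchmark movie lengths divide
evenly, so this path is exercised only by unusual inputs).

## Simulator

The benchmark scene: `N` fluorophores placed uniformly along the chords of
`L` lines with uniform random orientation in `[0, π)` and uniform random
anchor inside the field of view, split across lines as evenly as possible.
Defaults: 32×32 pixels at 100 nm, 500 frames at 10 ms exposure, 20,000
fluorophores on 10 lines.

* **Blinking:** independent two-state Markov chains with exponential dwell
  times, means τ_on = 10 ms and τ_off = 100 ms (stationary duty cycle
  10/110 ≈ 9.09%). The initial state is drawn from the stationary
  distribution to avoid transient bias. Simulation is event-driven: exact
  dwell times are drawn until the horizon, and each frame's on-fraction is
  the exact overlap of on-intervals with the exposure window — no sub-frame
  discretization.
* **Photodestruction:** per-emitter absorbing time drawn from an exponential
  with mean τ_bl (settings of interest: 1.1, 5.5, 11, 33 s; `None` disables
  bleaching). On-intervals are truncated at the bleach time.
* **Optics:** isotropic Gaussian PSF with
  σ = FWHM / (2√(2 ln 2)), FWHM = λ_em / (2 NA) — 78.9 nm (≈ 0.79 px) at
  NA 1.4 and λ_em = 520 nm; σ is directly overridable. Emitter weights are
  Gaussian integrals over pixel areas (erf differences), truncated beyond a
  5σ window and at the detector edge without renormalization (off-sensor
  light is lost). A fixed sparse footprint matrix maps emitter amplitudes
  to pixels, so a whole movie renders as one sparse matrix product.
* **Photons:** expected photons per emitter per frame =
  30 photons/ms × 10 ms × on-fraction; a Poisson background of mean 10
  photons per pixel per frame is added; shot noise is Poisson on the total
  expected count.
* **Camera:** output = offset (1000) + Gamma(shape = photon count,
  scale = EM gain 50) + optional Gaussian read noise (default sd 0, i.e.
  off — no magnitude is asserted for it anywhere, so it is a documented
  switch rather than a default). The Gamma form is the standard model of
  the EM gain register; `camera_model="simple"` replaces it by exact
  multiplication for analytic tests. Mean output − offset equals
  gain × mean photons.

One seeded generator drives all stages of `simulate_dataset`, so a seed
fully determines the stack.

What the generator does **not** emulate: dipole orientation effects,
triplet/dark states beyond the two-state chain, spatially varying
illumination, detector pixel cross-talk, clock-induced charge, and 3D/
multiplane optics. Tests passing on this generator therefore demonstrate
correct trend removal and cumulant estimation under idealized blinking
statistics, not performance on every real-sample pathology.

## Evaluation protocol

* **SNR:** per pixel, mean across repetition images divided by the sample
  standard deviation (ddof = 1) across repetitions; summarized as the mean
  over a foreground mask (reference pixels above 10% of the reference
  maximum — a reference-driven mask avoids rewarding background suppression
  twice). Zero-spread pixels are flagged NaN and excluded.
* **RMSD:** both images are scaled to unit Euclidean norm (SOFI amplitudes
  differ between methods by arbitrary scale), then the root mean squared
  pixel difference is taken. Reported per condition as the mean of
  per-repetition RMSDs against the reference.
* **Reference:** the average of SOFI images from independent bleach-free
  simulations, geometry redrawn per repetition (full-scale protocol: 100
  repetitions × 5000 frames).

Problem sizes in the shipped tests are reduced: the method comparison runs
20 repetitions per survival-time condition on a 16×16 field over 300
frames — the emitter count is scaled with field area (5,000) to keep the
benchmark density of ≈ 20 emitters per pixel — with a reference from 10
bleach-free runs of 1000 frames. The qualitative ordering (Whittaker ≥
batching > none in SNR, Whittaker < none in RMSD under fast bleaching;
Whittaker within 20% of batching in SNR under slow bleaching) is stable
across seeds at this scale.

## Numerical notes

* Residual zero-sum holds to 1e−6 relative on double-precision banded solves
  up to `n ≈ 10⁴` frames.
* At λ = 10¹² the fit matches the closed-form least-squares line to better
  than 1e−4 relative; conditioning of `I + λ DᵀD` limits accuracy at larger
  λ and is the reason the linear-fixed-point tolerance is 1e−6 relative.
* Cumulant estimators use two-pass mean subtraction; no Welford updates are
  needed at these movie lengths.
* TIFF output is float32 for anything that may be negative (corrected
  stacks, cumulant images); uint16 output refuses negative data rather than
  clipping.
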