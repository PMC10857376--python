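# Methods

## Problem and overall approach

County-level crop-yield regression from satellite time series faces two
coupled difficulties: the input geometry is irregular (every county has a
different set of masked cropland pixels), and ground truth is scarce —
one observation per county per year, and far fewer in data-poor regions.
This package addresses both with a four-stage pipeline:

1. **Histogramization.** For each of 9 spectral bands (7 surface-reflectance
   bands, day and night land-surface temperature) and each 8-day composite,
   the masked pixel values of a county are reduced to a normalized 32-bin
   histogram. A county-season becomes a rectangular tensor
   `[9 × T × 32]` whose per-slice distributions — not individual pixels —
   carry the crop-state signal.
2. **A strided CNN regressor.** Six stride-2 convolutional blocks
   (batch norm, ReLU, dropout) and a two-layer dense head map the tensor to
   a yield in bu/ac. Pooling is deliberately absent: pooling would discard
   *where* probability mass sits along the bin axis, which is the signal.
3. **Transfer from a data-rich source region** to a small target region:
   source-weight initialization, freezing of the first `n` conv layers,
   and the penalties L2 (`α/2·‖w‖²`), L2-SP
   (`α/2·‖w_S − w_S0‖² + β/2·‖w_S̄‖²`, anchoring the conv stack at the
   source weights and L2-regularizing the re-initialized dense head) and
   BSS (`η·Σ σ₋ᵢ²` over the k smallest singular values of the per-batch
   penultimate feature matrix).
4. **A spatio-temporal GP correction**: `y(x) = f(x) + h(x)ᵀβ` with a
   squared-exponential kernel over county centroid and season year plus
   Kronecker noise, and a Gaussian prior on `β` centred at the trained
   output layer (GP regression with explicit basis functions). This
   recovers the part of the residual field that is correlated across
   neighbouring counties and adjacent seasons.

Evaluation follows a rolling-origin seasonal protocol: for every test
season, models in *both* domains are trained only on strictly earlier
seasons, and every configuration is averaged over four seeded runs.

## Design choices where the design was open

* **Timesteps.** `T` is derived from the calendar window: a 256-day window
  at 8-day composites gives 32 steps; the in-season ("short") variant keeps
  the first 14. `T` is a property of the calendar, not a constant.
* **Bin edges.** Per-band quantile (equal-probability) edges, estimated on
  a pooled sample of source-domain pixels and then frozen for both domains.
  Transfer requires one shared feature space; quantile edges maximize
  resolution where mass actually lies. Out-of-range values are clipped into
  the terminal bins so no probability mass is lost; a slice with no valid
  pixel is all-zero rather than dropped, keeping tensors rectangular.
* **Architecture defaults.** 3×3 kernels, channel widths doubling with
  depth `(16,16,32,32,64,64)`, a 64-unit penultimate dense layer. Input is
  treated as a 2-D image (timesteps × bins) with 9 channels, so kernels see
  local neighbourhoods in both time and value.
* **Training.** Adam at a fixed 3e-3 learning rate, batch 64, up to 150
  epochs (a plain-SGD option exists for analyses where the scale of penalty
  gradients must be preserved — Adam's preconditioning makes very strong
  anchoring penalties settle at a learning-rate-sized oscillation floor
  instead of the `∇MSE/α` optimum, which is reached in the deterministic
  full-batch limit), early stopping (patience 15) on a validation split that holds
  out the *last* training season — the split that respects temporal
  ordering. Targets are standardized during optimization and the scaling is
  folded back into the output layer afterwards, so the decomposition
  `prediction = h(x)ᵀw_last + b_last` holds in bu/ac; penalties therefore
  act on weights expressed in standardized-target units.
* **Freezing semantics.** "Unchanged" is read strictly: frozen layers keep
  weights, batch-norm affine parameters *and* batch-norm running statistics
  bit-identical, and they normalize with running statistics even during
  fine-tuning. This prevents silent adaptation through normalization state.
* **Penalty bookkeeping.** L2/L2-SP are evaluated on the current weight
  partitions and BSS on the current minibatch's feature matrix at every
  optimization step. Frozen layers contribute identically zero to L2-SP and
  are skipped; batch-norm parameters are not decayed. The "L2" mode of the
  ladder reuses α as the Eq.-1 strength on all trainable weights.
* **GP kernel and solve.** The standard squared-exponential form over
  (centroid, year) with Kronecker-delta noise on identical indices;
  centroids in degrees (planar approximation, adequate at regional scale).
  Defaults σ=1, σ_e=0.32, r_loc=0.5°, r_year=1.5 yr, σ_b=0.01, all
  overridable. The basis is augmented with a constant column so the output
  bias participates in the prior. Solves use Cholesky with escalating
  jitter (0 → 1e-8 → 1e-6 → 1e-4) rather than explicit inversion; the GP is
  refit per test season on that season's training set, matching the rolling
  protocol. Kernel hyperparameter optimization is out of scope.

## The synthetic benchmark

The generator produces the statistical structure the framework assumes,
at desk scale, with no download:

* **Two domains.** A source region of 150 counties × 11 seasons
  (2010–2020) and a target of 40 counties × 5 seasons (2016–2020) — the
  source roughly an order of magnitude richer, mirroring a
  data-rich→data-poor transfer setting. Crop calendars are shifted by 248
  days (opposite hemispheres), both 256-day windows.
* **Yields.** `y = base + trend·(year−2010) + county effect + ε`, with
  target base 30 bu/ac below the source's 42, trend +0.4 bu/ac/yr, county
  effects N(0, 3²), and ε a Gaussian field over (centroid, year) drawn by
  Cholesky from the same squared-exponential family the GP head assumes
  (sd 2 bu/ac, r_loc 0.5°, r_year 1.5 yr). The oracle predictor returns the
  noise-free part; its RMSE equals the injected noise scale and is the
  floor for any histogram-based model, while the GP can go below it by
  exploiting ε's correlation.
* **Pixels.** Reflectance pixels are logit-normal on (0,1): a per-band
  offset plus a seasonal bump profile scaled by a shared, mildly nonlinear
  function of the yield signal, plus per-pixel spread; the signal also
  widens/narrows the distribution, so histogram shape (not just location)
  is informative. Temperature bands are Gaussian in scaled sensor units
  with the same structure. A domain-specific distortion of opposite sign in
  the two domains, scaled by `domain_specific_weight` (default 0.2, small
  relative to the shared weight 1.0), controls how favourable transfer is.
* **Observation-condition nuisance.** Every composite receives a random
  band-coherent offset (sd 0.4 logit units) whose band loading *matches the
  signal direction*, plus an incoherent part. Separating signal from
  nuisance then hinges on the temporal response profile (signal follows the
  season bump, nuisance is white in time) — the part of the map that needs
  data to learn. This is what makes ~150 target records genuinely
  insufficient while ~1500 source records suffice, i.e. the regime in which
  transfer pays; it mimics atmospheric contamination of reflectance
  composites. Without it, the synthetic task is linearly learnable from
  the target data alone and transfer has nothing to add.
* **Cleansing exercise.** 5% of counties receive cropland-mask counts below
  the 2000-pixel threshold and are removed by the cleansing rules, which
  also drop unassignable counties and non-positive yields.

What the generator does **not** emulate: real spectral band correlations,
cloud/gap artefacts, mask drift across years, multimodal pixel
distributions within a county, non-stationary trends, and any real
geography beyond "counties scattered in a box". Passing benchmarks here
demonstrates that the machinery behaves as designed under its assumptions,
not that these hyperparameters transfer to real MODIS data.

## Numerical notes

* The CNN is implemented directly in NumPy (im2col convolutions, explicit
  backward passes) in double precision; gradients are verified against
  central finite differences in the test suite. Fixed seed + fixed data
  gives a bit-reproducible training trajectory on one device.
* Histogram normalization guarantees each nonempty slice sums to 1 within
  1e-9; counts are integers divided by the valid-pixel count, so mass is
  conserved exactly.
* Degenerate inputs: constant pixel samples make quantile edges collapse
  and raise; a constant ground-truth vector makes R² undefined and raises;
  non-finite training losses abort with the offending batch identified.
* Problem sizes in the shipped tests and the acceptance script (full
  default benchmark, four runs, last one or two test seasons) were chosen
  so the whole battery runs on a single CPU in minutes; they are small
  relative to the real-data setting but preserve every structural property
  being tested.

## Known limitations

* No real-data adapter is shipped; the reader contract (rasters + county
  polygons + yield CSV) is documented but only the synthetic implementation
  exists.
* GP hyperparameters are fixed, not optimized; the kernel assumes
  stationarity and a planar degree metric.
* The BSS penalty uses a full SVD per batch — fine at dense_dim ≤ 64 and
  batch ≤ 64, wasteful beyond.
* Training-time penalties act in standardized-target units, so quoted α, β,
  η values are not directly comparable across datasets with different yield
  variance.
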