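# Methods

## Model

The analysis treats one day's surveillance record as a draw from a
p-variate Gaussian. Dependence structure is read off the precision
(inverse covariance) matrix: variables i and j are conditionally
independent given the rest exactly when the precision entry — equivalently
the partial correlation `r_ij·rest = −rⁱʲ/√(rⁱⁱ rʲʲ)` — is zero. Because
every variable is standardized implicitly by working on the correlation
scale, the whole pipeline operates on the sample correlation matrix `R`,
never the covariance.

Causal direction is *not* estimated. It is supplied entirely by the
declared three-tier layer structure (cause → intermediate effect →
effect), which reflects temporal/physical ordering of the chilling
process: weather and throughput precede room settings and loading, which
precede the measured carcass temperatures. The graphical model itself is
undirected; the layers only orient the drawn edges.

## Data and preprocessing

The two layered datasets are daily records over one operating year; a
record with any omitted field is discarded wholesale ("missing data
unit"), leaving 44 complete units each for beef and pork. Loading
completion times are clock readings converted to continuous hours as
hh + mm/60. The monthly seasonal dataset aggregates the whole facility;
its throughput column converts beef to pork-equivalent head at 4:1.
Fixtures are plain ASCII CSV; blank cells are the only recognised missing
marker, and any other non-numeric token is a parse error with row/column
location. Sample identifiers are opaque text and are preserved exactly as
recorded, including a few date-like identifiers that are internally
inconsistent with the stated study window; no date arithmetic is ever
performed on them.

## Constrained MLE (covariance selection)

For a zero set Z of pairs, the reduced model's MLE `Π̂` is the unique
positive-definite matrix with `Π̂_ij = R_ij` on the diagonal and all free
pairs, and `(Π̂⁻¹)_ij = 0` for pairs in Z. It is computed by iterative
proportional scaling over pairwise constraints: visiting pair (i,j) with
current inverse `K`, the update

```
σ_ij ← σ_ij + k_ij / (k_ii k_jj − k_ij²)
```

zeroes `k_ij` exactly while touching no other entry of Σ, and cycling the
constrained pairs is coordinate ascent on the Gaussian log-likelihood.

Numerical choices: convergence when the largest absolute entry update in a
sweep falls below 1e-10; at most 10 000 sweeps (non-convergence raises,
reporting the final residual); constrained pairs are visited in
lexicographic variable-name order, making every fit deterministic. The
inverse is recomputed densely each visit — at p ≤ 10 this costs microseconds
and avoids accumulating rank-2 update error. The implementation is
cross-checked in the test suite against an independent oracle that
maximizes `log det K − tr(RK)` directly over the free precision entries
with a quasi-Newton solver; the two agree to 1e-6 entrywise on 50 random
3–4-variable instances, and the single-constraint case matches the
classical closed form `Dev = −n log(1 − r²_ij·rest)`.

Deviance uses the raw sample count, `Dev = n log(|Π̂|/|R|)` with n = 44
for the bundled data (no n−1 correction), and `NFI = 1 − Dev(RM)/Dev(NM)`
with the null-model deviance `Dev(NM) = −n log|R|`.

## Backward elimination

Defaults: partial-correlation thresholds (0.1, 0.2), NFI guard 0.9.
Within each threshold the procedure is stepwise-with-refit: fit the
current model, recompute partial correlations *of the fitted matrix*,
remove the eligible pair with the smallest |r·rest| below the threshold
(ties broken alphabetically), refit, and repeat. A removal that drops NFI
below the guard is undone and ends that threshold pass, so the final model
always satisfies the guard; elimination then restarts at the next, larger
threshold over all surviving pairs.

"Layer by layer" processing is implemented as an eligibility schedule and
was a genuinely open design point; three policies are provided:

* `layered` (default): within each threshold, stage k admits only pairs
  whose deeper endpoint lies in layer k, for k = 1, 2, 3 — the scan sweeps
  the structure from causes toward effects;
* `unrestricted`: all pairs eligible at once;
* `batch`: candidates are ranked once per threshold from the current fit
  and removed in that fixed ascending order without re-ranking.

On the bundled data the selection removes 17 of 28 beef edges (final
NFI 0.9209) and 29 of 45 pork edges (final NFI 0.9146); these structures
are outputs of the procedure, not externally validated ground truth, so
the tests assert the procedural contract (every removal below the active
threshold; final NFI ≥ 0.9; deviance monotone in nested zero sets;
bit-reproducible traces) rather than a specific edge list.

## Descriptive layer

Pearson correlations use the sample (n−1) normalization — immaterial on
the correlation scale. Marginal associations with |r| ≥ 0.5 are flagged
as strong. Scatterplot-panel probability ellipses are parameterized by
the eigendecomposition of the 2×2 sample covariance with semi-axes
`scale·√eigenvalue`; the default scale 2.0 is the conventional two-sigma
ellipse, with `CHI2_95_SCALE` (√5.991 ≈ 2.447) available for exact 95%
bivariate-normal coverage — the two are often conflated in practice and
both are exposed. Degenerate (collinear) panels raise rather than return
a zero-width ellipse.

## Synthetic data generator

`sample_dataset` draws n i.i.d. zero-mean Gaussians with covariance equal
to the inverse of a prescribed precision matrix, via a Cholesky factor
applied to a seeded `numpy` standard-normal stream — identical seeds give
identical data wherever the generator stream is identical.
`random_sparse_precision` places a chosen fraction of off-diagonal entries
(magnitudes uniform in [0.2, 0.6], random sign) and enforces positive
definiteness by strict diagonal dominance, so the zero pattern is exact by
construction.

The fixed recovery benchmark has 6 variables in layers (2, 2, 2), 5 true
zeros, and all 10 nonzero partial correlations equal to ±0.35 — above the
largest elimination threshold by a margin that separates procedure error
from estimation error (at n = 5000 the sampling noise of a partial
correlation is ≈ 0.014). Edge signs were chosen to keep the matrix well
conditioned (smallest eigenvalue ≈ 0.45). The recovery study runs 100
replicates at n = 5000; exact zero-set recovery is the success criterion.
The generator emulates none of the real data's non-Gaussian features —
bounded humidity percentages, integer head counts, clock-time supports —
so recovery results certify the machinery under its own assumptions, not
robustness to their violation.

## Known limitations and discrepancies

* The three seasonal correlations involving the monthly outside
  temperature computed from the bundled monthly table (0.9292, 0.0112,
  −0.6985) differ by up to 0.008 from the reference values for this
  dataset (0.9307, 0.0172, −0.7063); the reference analysis evidently used
  an unrounded temperature series, whereas the monthly table carries one
  decimal place. The bundled data is kept verbatim and the strict check is
  left failing to document the gap. All other reference entries — every
  entry of the six 8×8/10×10 matrices and the remaining seasonal entries —
  reproduce to within the 4-d.p. printed rounding.
* With n = 44 and up to 10 variables, the selected structures are
  exploratory; the NFI guard controls fit degradation, not error rates,
  and no significance testing is performed (none is defined for this
  procedure).
* Within-layer edges remain undirected in the path diagram; the method has
  no information to orient them, and arrows across layers encode the
  declared ordering only.
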