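# Methods

This note records the models implemented, the numerical conventions, the
defaults and why they were chosen, and what the synthetic benchmarks do
and do not establish.

## Codelength framework

All codelengths are bits.  For real-valued data the codelength of a
sample under a coding density `f` is `−log₂ f(x)` up to a quantization
constant that is common to all coders and cancels in every comparison; it
is therefore never represented.  Codelengths are only meaningful when the
implied code is sequentially decodable: every predictive density used here
depends only on already-decoded samples, so totals obey the Kraft
inequality and mixtures of coders are themselves valid coders.

Model identities are coded with the universal integer code,
`c + log* i = c + log₂ i + log₂ log₂ i + …`, with `c = log₂ 2.865064`
(the constant that makes the Kraft sum equal one).  The mixture over a
coder set is computed in the log domain (log-sum-exp) and never exceeds
the best single penalized coder.  The prior odds of a segment being
atypical are not modeled separately; they are absorbed into the scanner
threshold `τ`, which is exactly the bit length of the atypical-segment
header.

## Predictive densities

Two constructions supply predictive densities with parameter uncertainty
built in.

**Sufficient statistic method (SSM).**  If `t(x^n) = s(Y, θ)` for a
pivot `Y` independent of `θ`, solving for `θ = r(Y, t)` turns the sampling
distribution of the statistic into a distribution on the parameter; the
predictive density is the data model averaged over it.  The construction
is invariant to reparameterization (verified by quadrature in the test
suite: the `σ` and `σ²` parameterizations give the same predictive).
Implemented cases: unknown mean with known (co)variance — predictive
`N(μ̂_n, (1+1/n)Σ)`; unknown variance (zero mean), scalar and isotropic
vector; unknown covariance via the inverse-Wishart law of `Σ` given the
scatter; unknown mean and covariance via centered scatters.

**Normalized likelihood method (NLM).**  `f(x_{n+1}|x^n) =
C(x^{n+1})/C(x^n)` with `C(x^n) = ∫ f(x^n|θ) dθ`.  Implemented for the
scalar unknown-variance model, the vector unknown-covariance and unknown
mean/covariance models, and the order-M linear-prediction model.  No SSM
exists for AR models — the minimal sufficient statistic has dimension
three for the two parameters already at order 1 — so the LP coder is
NLM-only by design.

**Validity bounds.**  `C(x^n)` is finite only when every gamma argument
in its closed form is positive.  This yields: scalar NLM from `n ≥ 3`;
vector unknown-covariance NLM from `n ≥ 2M+1`; unknown mean/covariance
NLM from `n ≥ 2M+2`; order-M LP NLM from `n ≥ 2M+3`.  (Stated prose
bounds that disagree with the closed forms — e.g. "defined for
`n ≥ 2M+2`" while the formula contains `Γ((n−2M−2)/2)` — are resolved in
favor of the formula; the `M = 0` reduction then matches the scalar coder
exactly, which the tests pin.)  The unknown-mean-and-covariance forms
carry the factor `(n/(n+1))^{M/2}`; the `M = 1` reduction to the scalar
unknown-mean/variance density fixes the exponent, and 2-D quadrature
confirms normalization.

**Staging.**  Before a coder's validity bound is reached, simpler rungs
code the stream: the very first sample is charged to a default
distribution (in the scanner, the typical distribution — so no prior is
chosen); scalar streams then use the unknown-variance SSM and, from two
samples of history, the unknown-mean/variance SSM.  The LP ladder is:
default, unknown-variance SSM for histories 1–2, then the NLM predictor
of order `min(M_max, ⌊(n−3)/2⌋)`.  Vector streams code whole vectors
componentwise through the scalar ladder until the vector coder is
defined, so only the first scalar component of a vector stream ever
touches the default.  Degenerate prefixes (all-zero, or constant where a
centered statistic is needed) fall back one rung for that sample instead
of emitting infinite bits.

## Signal-processing coders

**Linear prediction.**  Statistics (`r̂(k)`, `p`, `R`, `τ̂ = r0 −
pᵀR⁻¹p`) update by one rank-1 term per sample.  The batch implementation
accumulates them as cumulative sums and evaluates the per-sample
determinants and solves on stacked matrices (chunked at 16384 samples to
bound memory at about 13 MB for order 10); samples where `R` is
numerically singular (relative residual below 1e−12) fall back to the
largest lower order that works.  The trainable typical coder fits
per-segment least-squares coefficients of order 10 and charges the
plug-in innovation codelength; segment length defaults to the whole
stream and the CLI maps it to five minutes when a sample rate is given.
Coefficients are fitted on the full segment including any atypical
content — appropriate only when atypical data are known to be rare and
short; pre-cleaned data should be used otherwise.

**Filterbank.**  Only orthonormal perfect-reconstruction pairs are used
(energy preservation is what makes codelength comparisons across a
transform fair; a non-orthonormal transform would change codelengths by
its log-Jacobian).  Each node's first `filter_length − 1` samples are
passed through verbatim — the startup transient would otherwise corrupt
the sub-band variance estimates — and coded by the node's own scalar
stream; the even-length remainder is analyzed with circular (periodized)
filtering, which keeps the per-node transform exactly orthonormal and
perfectly reconstructible for any even length (an odd trailing sample
joins the pass-through set).  Internal nodes mix "code here" and "split
further" with weight ½ each; at the depth limit the weight is dropped
since no choice exists.  The weighted codelength is bracketed by the best
single tree and the best tree plus one bit per decision, verified
exhaustively for depths up to 3.  Default pair: Daubechies `db4` (the
choice is free; Haar is used for exact unit tests).  The number of
decomposition trees with the root split is `g(D−1)²` with `g(0)=1`,
`g(d)=1+g(d−1)²` — 676 at depth 4; the convention excludes the no-split
tree, which the weighting handles anyway.

**Sparse transform.**  Blocks of M samples are rotated by an orthonormal
DCT-II (default; the real-DFT packing with `√2`-scaled cosine/sine pairs
is available, but the DCT avoids the DFT's conjugate-symmetry
bookkeeping).  The N strongest components by end-of-block average power —
a decoder-safe statistic — are coded as scalar unknown-mean/variance
streams (they may carry deterministic offsets); the complement is coded
by the isotropic SSM.  The selected set costs `M·H₂(N/M) + ½log₂ M` bits
(binary entropy in bits).  N is chosen greedily from 0 upward, stopping
at the first non-improvement; a full sweep exists for verification.

## Scanner

`dL(n) = max_l [L_T − L_A]` with `L_A` the coder-set mixture plus
`log* l`.  Defaults: `τ = 20` bits (about one false event per 10⁶ scored
positions under the typical model — the Kraft/no-hypercompression bound
gives `P(dL > τ) ≤ 2^{−τ}` per scored sequence); coarse block levels
`2⁶..2⁹`; fine-search expansion of one block per side; `l_max` four times
the largest coarse block.  The coarse stage codes each block repeated
twice, so that a pattern whose per-sample saving is too small at one
block length still surfaces (the repetition itself creates false
positives, which the fine stage eliminates).  The fine stage scores every
subsequence of each expanded window with the per-sample recursions of the
coders.  Segmentation — globally minimizing the total stream codelength —
is intractable, so a greedy surrogate is used: accept candidates in
decreasing `dL` (ties to the earlier start) subject to non-overlap.  The
accounting identity `total = all-typical − Σ(dL − τ)` holds exactly and
is tested, and detection sets shrink monotonically as `τ` grows.

The default atypical coder set is `(gauss, lp)`: these have O(1)
per-sample recursions as the exhaustive stage requires.  The filterbank
and sparse coders participate if configured, but are evaluated only at
dyadic prefix lengths (no cheap per-sample recursion exists for the tree
mixture or the greedy-N selection), which is a complexity choice, not a
modeling one.

## Synthetic data

The generators produce the study conditions end to end: white or AR
Gaussian backgrounds and planted events (variance bursts, power-matched
colored segments with innovation variance `σ²(1−a²)`, tones, mean
shifts, AR changes), seeded and bit-reproducible.  The flagship fixture
is the power-matched AR(0.9) anomaly: invisible to amplitude/energy
detectors, compressed by the LP coder at `½log₂(1/(1−a²)) ≈ 1.2`
bits/sample.  Benchmarks use desk-scale sizes — 10⁵ samples for the
false-alarm suite, 2048-sample events in 32768-sample streams, 4096
samples for the LP-gain check, 2000 length-8 sequences for the redundancy
comparison — chosen so the whole suite runs in minutes on one core.

What passing these tests shows: the coders are correct against
independent oracles, and the scanner finds the classes of structure the
models cover, at the stated false-alarm budget, on Gaussian synthetic
data.  What they do not show: performance on real hydrophone or Holter
recordings (non-Gaussian, nonstationary backgrounds, overlapping events),
calibration of `τ` for field data, or robustness to typical-model
mismatch beyond the AR fit.  The miniature "whale" scenario is
illustrative, not a fidelity claim.

## Numerical choices

Base-2 logs at the API, natural logs internally.  All densities are
evaluated in the log domain with `gammaln`/`multigammaln`; determinants
via Cholesky with diagonal jitter `1e−12·trace/M` on near-singular
scatters and a hard error beyond `1e−6·trace/M` (robustness must not
silently change the model).  Rank-1 determinant updates (matrix
determinant lemma) let every vector density broadcast over batches of
evaluation points.  Scatter statistics are treated as degenerate below a
relative threshold of 1e−12.  Ties in component selection break toward
the lower index; candidate ties in segmentation break toward the earlier
start.
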