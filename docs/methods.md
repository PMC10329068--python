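# Methods

## Model

`gradedcat` implements Samejima's graded response model (GRM) for ordered
polytomous items. Item *i* with slope *a_i* > 0 and strictly ordered
thresholds *b_{i1} < … < b_{i,m_i−1}* assigns a respondent at latent
position θ the cumulative response probabilities

    P*_{ik}(θ) = 1 / (1 + exp(−a_i (θ − b_{ik}))),   k = 1 … m_i − 1,

with P*_{i0} = 1 and P*_{i,m_i} = 0, so the probability of choosing
category *k* is P_{ik} = P*_{i,k−1} − P*_{ik}. The logistic metric is
used without the 1.7 scaling constant, matching the parameterization of
the bundled bank (slopes ≈ 1.3–3.5). The model assumes a unidimensional
trait, local independence given θ, and monotone item response functions
— exactly the assumptions the `psychometrics` battery screens.

The bundled bank is the published graded-response calibration of the
17-item Animated Activity Questionnaire (AAQ), an animated measure of
activity limitations in hip/knee osteoarthritis. Its θ metric was scaled
to mean 0, SD 1 in the calibration sample, with **higher θ = more
activity limitation**; category codes run 1…m_i with the "Not possible"
option highest. Reported scores use the instrument's 0–100 metric with
the orientation reversed (higher = fewer limitations): a raw summed
score *s* ∈ [17, 85] maps to 100·(85 − s)/68. The IRT-based 0–100 score
maps the EAP θ̂ through the test characteristic curve
E[S | θ] = Σ_i Σ_k k·P_{ik}(θ) and then the same linear transform. The
linear transform reproduces the instrument's printed score range
(0–100) exactly at the all-min/all-max response patterns.

## Scoring

Respondents are scored by expected a posteriori (EAP) estimation under a
standard normal prior: the posterior over a fixed quadrature grid is
prior × likelihood of the observed categories, θ̂ is the posterior mean
and the reported standard error is the posterior SD. EAP is used both as
the interim estimator inside the adaptive loop and for final scores; no
ML/WLE/MAP alternatives are offered.

**Quadrature.** 61 equally spaced nodes on [−6, 6], weights proportional
to the standard normal density and renormalized. The hull matters: a
[−4, 4] grid clips the posterior of extreme response patterns and moves
the all-highest-pattern 0–100 score from ≈ 2.3 to ≈ 4.0; with [−6, 6]
both extreme-pattern scores (98.6 and 2.3) reproduce the published
values, and they are insensitive to node count beyond ~61 (61, 81 and
121 nodes agree to 2 decimals). 61 on [−6, 6] is also the convention of
the common GRM estimation software family, which the bundled parameters
come from. Tests guard EAP against an independent 601-node integration
oracle to |Δθ|, |Δse| < 1e−3.

## Calibration

`calibrate_grm` fits the GRM by marginal maximum likelihood EM. The
E-step computes each respondent's posterior weights on the grid and
accumulates expected item-category counts; the M-step re-maximizes every
item's expected complete-data log-likelihood with L-BFGS-B on an
unconstrained reparameterization (log slope, first threshold, log
threshold spacings), which enforces threshold ordering by construction.
The previous parameter vector is kept whenever the optimizer fails to
improve, preserving the monotone-likelihood EM property (asserted in
tests). The latent metric is identified by the fixed N(0, 1) prior — no
post-hoc rescaling to the sample — so externally calibrated parameters
remain directly usable. Convergence: largest absolute parameter change
< 1e−4 (default) or 500 cycles. Missing responses are treated as
ignorable (the item is skipped in that respondent's likelihood); a
category never observed for an item aborts with a pointer to
`collapse_categories`. Start values: unit slopes and thresholds from
inverted observed cumulative proportions. Parameter recovery from
n = 2000 simulated respondents achieves slope RMSE ≈ 0.09 and threshold
RMSE ≈ 0.03 (|b| < 3), comfortably inside the 0.25 test bound. Note that
very small configurations can be unidentified marginally — a single
dichotomous item exposes only one observable proportion — so oracle
comparisons use at least three items.

## Adaptive algorithm

Each CAT session starts at θ = 0 (the prior mean), selects the unused
item with maximum Fisher information

    I_i(θ) = Σ_k (P′_{ik})² / P_{ik},
    P′_{ik} = a_i [P*_{i,k−1}(1 − P*_{i,k−1}) − P*_{ik}(1 − P*_{ik})]

at the current θ̂ (ties broken by bank order), elicits a response,
re-estimates by EAP, and stops once se ≤ 0.3 (checked after each
response) or the item cap (17/10/5 in the study configurations) is
reached. There is no forced minimum test length: with this bank the
se ≤ 0.3 criterion cannot be met in fewer than 4 items, and the observed
minimum of 4 emerges in every simulated cohort. No exposure control or
content balancing is applied. Inside cohort runs, item information is
pre-evaluated on a 0.01-resolution θ table and looked up by nearest
node; at this resolution the selected item matches the exact argmax.
Responses come from a provider: a stored complete pattern (post-hoc
simulation, fully deterministic) or a generative simulee drawing from
the GRM at a true θ (seed-reproducible).

## Validation battery

* **Mokken scalability / monotonicity.** Pairwise Loevinger
  H_ij = cov(X_i, X_j)/cov_max, with cov_max from the comonotone
  (sorted) coupling of the two margins, aggregated to item H_i and scale
  H; monotonicity counts item-step decreases above 0.03 across
  rest-score groups (default group size min(n/10, 50)). H = 1 on
  Guttman data and ≈ 0 under independence, verified against a
  permutation-enumeration oracle.
* **Local independence.** Q3-style residual correlations
  e_ri = x_ri − E[X_i | θ̂_r] about the full-pattern EAP estimate;
  pairs with |r| > 0.20 are flagged. This replaces factor-analytic
  residual correlations with an IRT-native proxy probing the same
  concern; it is single-pass and makes no WLSMV machinery necessary.
* **S-X² item fit.** Orlando–Thissen: observed vs model-implied
  item-category frequencies conditional on the summed score, with the
  generalized Lord–Wingersky recursion supplying with- and without-item
  summed-score distributions integrated over the quadrature prior.
  Sparse summed-score groups are merged (starting at 5 respondents per
  group and escalating until all pooled expected cells ≥ 1 and ≥ 80%
  ≥ 5) and near-empty category cells pooled within rows. Degrees of
  freedom count free cells, Σ_rows (cells − 1), minus the item's
  parameter count when the bank was calibrated on the same data
  (`params_estimated=True`, the default). With fixed true parameters
  the subtraction is skipped; in that regime the type-I rate at
  α = 0.05 is ≈ 0.045 across seeded replicates. Flag level 0.003, a
  Bonferroni-style threshold for a 17-item scale.
* **DIF.** Per item, nested proportional-odds models (M0: θ;
  M2: θ + group + θ×group, via `statsmodels` `OrderedModel`) with the
  full-pattern EAP θ as matching variable, single-pass (no iterative
  purification — a deliberate simplification; purification could
  slightly sharpen flags near the 2% boundary). McFadden pseudo-R²
  change (ll_M2 − ll_M0)/(−ll_null) ≥ 0.02 flags an item. A +1.0
  threshold shift injected in one group is reliably detected at
  700 + 700 respondents.
* **Disordered categories.** A category that is never the modal
  response anywhere on θ ∈ [−6, 6] (0.01 grid) signals crowded
  thresholds — the analytical analogue of eyeballing category response
  curves. On the bundled bank the scan flags exactly four items
  (AAQ_02, AAQ_03, AAQ_04, AAQ_17), matching the published count,
  though the published detection was visual and need not coincide
  item-for-item.

## Synthetic cohorts

`generate_cohort` draws true θ from N(0, 1) — the latent calibration of
the bundled bank, whose metric was standardized in the real sample — and
responses from the GRM, by default n = 1408 (the calibration-study
size). What the generator does *not* emulate: the real sample's mild
skew toward low limitation (original score mean 78.3), country/age/sex
structure, any residual multidimensionality or local dependence, and
response styles. Consequently, passing simulations demonstrate that the
engine reproduces the study's machinery and magnitudes under the model,
not that the instrument behaves this way in new clinical samples.
Despite this, the synthetic cohort lands close to the published
magnitudes: mean test lengths ≈ 8.2 / 6.8 / 4.9 (published: 8.0 / 6.6 /
4.8), CAT-original correlations ≥ 0.95, score mean/SD ≈ 78.9/16.6
(78.4/16.7), and the same six highest-exposure items (4, 6, 7, 12, 13,
14).

## Numerical choices and edge cases

* Probabilities are clipped at 1e−300 before logs; posteriors are
  normalized in log space.
* Evaluation grids for maxima/limits default to [−6, 6], step 0.01.
* Category collapsing never invents thresholds: the collapsed item
  carries NaN placeholders flagged `requires_recalibration`, and
  recalibration is the caller's job (refitting after a top-category
  merge reproduces the original θ's with r > 0.995 on simulated data).
* Zero-response respondents are flagged and left unscored by
  `score_respondents` (while `eap_estimate` on an empty pattern returns
  the prior, θ̂ = 0, se = 1).
* Post-hoc cohort runs skip incomplete rows with a warning; a provider
  failure mid-session yields a record flagged invalid.

## Known limitations

* One known red in the acceptance suite: the published claim that test
  information stays ≥ 10 across θ ∈ [−1, 4] does not hold at the right
  endpoint with the printed parameters — TI(4.0) = 9.33, and the exact
  TI ≥ 10 interval is [−1.01, 3.96], whose endpoints round to the
  published −1 and 4. The information formula itself is verified
  against a finite-difference oracle, so the discrepancy is attributed
  to endpoint rounding in the published prose, and the check is left
  failing rather than redefined.
* Unidimensional GRM only: no guessing, nominal, partial-credit or
  multidimensional models; two-group DIF only; no exposure control or
  content balancing; no CFA/bifactor indices.
* The original 0–100 scoring requires complete patterns (no proration
  of missing responses).
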