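# Methods

## Models

For each target gene/protein *i* and sample *n* the package fits two linear
models by ordinary least squares:

**Protein association.** `y_i(n) = Σ_{j∈candidates} a_ij · y_i(n) y_j(n) + h_i + v_i(n)`.
The regressor for partner *j* is the *product* of the two profiles, so the
association ability `a_ij` measures multiplicative co-variation; `h_i` is
the basal level and `v_i` Gaussian noise. The model is a consistency
relation: solving for the target gives `y_i = (h_i + v_i)/(1 − Σ_j a_ij y_j)`.

**Gene regulation.** `x_i(n) = Σ_j b_ij · y_j(n) − Σ_l c_il · mir_l(n) + k_i + w_i(n)`
with TF abilities `b_ij` (either sign), miRNA repression abilities `c_il`
(positive means repression; the design column is the negated miRNA profile,
so the fitted coefficient *is* `c_il`), basal level `k_i` and noise `w_i`.
The signed coefficient on `mir_l` is `−c_il`.

**Order detection and pruning.** Per target: fit the full candidate model;
repeatedly remove the non-intercept regressor with the smallest |t| and
refit (ties break toward the lexicographically last label, for
determinism); over the visited nested path select the model with minimal
`AIC = n·ln(RSS/n) + 2p` (ties toward the smaller model; RSS = 0 maps to
−∞); finally remove every remaining regressor with p ≥ 0.05 and refit once.
The intercept is never pruned. On candidate sets of ≤ 8 regressors this
backward path recovers the exhaustive all-subsets AIC optimum in ≈ 100 % of
random instances (checked in the acceptance suite against full
enumeration).

**Inference.** Classical normal theory: `SE` from `σ̂² (XᵀX)⁻¹` with
`σ̂² = RSS/(n−p)`, p-values from Student's t with `n−p` degrees of freedom.
Constant non-intercept columns and linearly dependent columns are dropped
deterministically (rightmost first) before fitting. The residual SD is
floored at 1e-8 of the response RMS so that on numerically perfect fits
(RSS ≈ machine zero) coefficients that are themselves numerical zeros do
not test significant.

**Principal network projection.** Surviving abilities populate
`H ∈ ℝ^{(2N+O)×N}`: rows 1..N hold `a_·i`, rows N+1..2N hold `b_·i`, rows
2N+1..2N+O hold `−c_·i`, columns index targets. Thin SVD `H = U D Vᵀ`;
eigen-expression fractions `E_m = d_m²/Σ d²`; *M* is minimal with
cumulative energy ≥ 0.85 (configurable). Row scores `S(k,m) = h_k · v_m`,
distances `D(k) = √Σ_m S(k,m)²`. `D` is non-decreasing in *M* and equals
the row norm at full energy. Core membership thresholds `th1/th2/th3`
attach to the association/TF/miRNA row blocks respectively; a node is core
if any of its rows passes, and rows with `D = 0` (no surviving content) are
never core, so zero thresholds select exactly the loaded rows. The core
subnetwork is the induced edge set (both endpoints core). The study this
package models chose its thresholds per cohort without a stated rule; they
are exposed as constants (`COHORT_THRESHOLDS`) and a quantile helper
(default: 0.9-quantile of the nonzero distances per row class) serves
synthetic runs.

**Differential comparison.** Core-node and core-edge sets intersect and
difference exactly (common vs cohort-specific core GENs). DNA-methylation
candidates: two-estimate z-test on the fitted basal levels,
`z = (k_A − k_B)/√(SE_A² + SE_B²)`, two-sided normal p, α = 0.05 (an
absolute-difference mode is also exposed). Mutation candidates:
pooled-variance two-sample t-test per node on the expression profiles.
Both are candidate annotations, not biological claims.

## Synthetic generator

The generator emulates the study design: two cohorts of unequal size
(default 30 young / 146 elderly), a candidate network containing all true
edges plus uniformly drawn decoys (default: half of the candidates false,
`n_decoy = n_true · fp/(1−fp)`), group-specific basal-level shifts on a
subset of genes (methylation surrogates, default 10 % of nodes shifted by
±1.0 in k), and planted differential expression (default 10 % of nodes,
+0.3 ≈ 3 residual SDs, added to the shifted cohort's profiles so it is
exogenous to the network parameters).

Forward model per sample: miRNA profiles are i.i.d. log-normal
(μ=0, σ=0.5 on the log scale — expression-like positivity; no distribution
is prescribed by the study). Protein profiles solve the association
consistency relation by Gauss–Seidel iteration of the solved form
(≤ 100 passes, tolerance 1e-8), rejecting draws whose denominator
`|1 − Σ a_ij y_j|` comes within 0.2 of zero. Gene profiles then follow the
regulatory model given the realized protein matrix. Ability magnitudes
default to |a| ∈ [0.01, 0.05] (small, keeping the fixed point
well-conditioned at PPI degrees up to 8), |b|, c ∈ [0.3, 1.0]; basal levels
h, k ∈ [0.5, 1.5]; noise SD 0.1. All randomness derives from a single seed;
runs are bit-reproducible, and expression tables are written with `%.17g`
and parsed with round-trip precision so stages rerun from files reproduce
in-memory results bit for bit.

A second, **regression-faithful** mode (`simulate_faithful_target`) draws
all regressor profiles freely and sets one target by the solved form, so
that target's two regressions hold exactly with noise independent of the
regressors — the design classical least-squares theory assumes. It exists
because the jointly simulated data cannot satisfy that assumption (next
section), and because zero-noise joint data is degenerate: with constant
basal levels and no noise the protein profiles are constant across
samples and carry no information. Noiseless support recovery is therefore
exact in faithful mode (verified in the acceptance suite) and undefined in
joint mode.

## Known limitations

**The association model is endogenous on jointly consistent data.** Every
candidate column `y_i·y_j` contains the response `y_i` as a factor, hence
also its noise `v_i`. On jointly simulated cohorts, where inter-sample
protein dispersion is noise-driven (CV ≈ noise_sd/h ≈ 0.1), each candidate
column is nearly proportional to the response, so decoy association
partners are retained at ≈ 0.5 instead of the nominal 0.05 and edge-level
FDR over all edge types is ≈ 0.29 (sensitivity ≈ 0.95). The TF/miRNA
regulatory model does not share the problem — its regressors do not contain
the response — and recovers support at near-nominal error (FDR ≈ 0.06,
sensitivity ≈ 0.99). This is a structural property of fitting the
association relation by OLS, not an implementation artifact; it would
afflict any data that actually follows the model, and it is measurable
here only because the synthetic benchmark has ground truth.

**Basal-level comparison inherits post-selection bias.** The methylation
z-test compares intercepts of independently pruned models. When a true
regulator survives pruning in one cohort but not the other (power differs
with n = 30 vs 146), the omitted term's mean contribution `b·E[y_j]` is
absorbed into that cohort's intercept, shifting `k̂` by a magnitude
comparable to a genuine methylation shift. Null genes are consequently
flagged at ≈ 0.2 instead of α = 0.05, while well-powered planted shifts
(|z| ≥ 5) are detected essentially always. Basal-level differences from
pruned two-stage fits should be read as screening candidates, not
calibrated tests.

**Other simplifications.** No probe-level simulation, normalization
artifacts or missing data; identity mapping between gene expression and
protein abundance; decoy edges are uniform over the complement (no
degree-biased database artifacts); per-target regulator counts are capped
(8 PPI partners, 6 TFs, 6 miRNAs) so all fits stay overdetermined at
n = 30. Problem sizes in the test and acceptance suites (N up to 300,
O up to 50, 20 recovery seeds, 100–500 Monte-Carlo replicates) were chosen
to estimate each rate to a few percent while keeping a full run in tens of
seconds.
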