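# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not establish.

## Curation

EC50 values are potencies from a T4-displacement assay against human
transthyretin, in μM. pEC50 = −log10(EC50/μM) is used directly (no
reference-compound normalization); the binder bands are weak
(pEC50 < −0.9), medium (−0.9 ≤ pEC50 ≤ 0.12, both boundaries inclusive)
and strong (pEC50 > 0.12). Salt forms are removed by normalized-name match
against a fixed list of seven; duplicates are detected by canonical-SMILES
equality (name equality when the structure does not parse) and resolved by
keeping the lowest EC50, on the rationale that assay interference usually
biases potency downward. Compounds without a usable EC50 are kept as
`inactive` and excluded from all fitting. Salt removal and deduplication
commute with input row order, which the tests verify.

## Descriptors

Structures are standardized at pH 7: counterions stripped, carboxylic and
sulfonic acids deprotonated (perfluorinated acid pKa values are far below
7; the rule uses conservative pKa bounds of 4.9 and 0). Atom and bond
counts default to the hydrogen-suppressed graph with a switch for
hydrogen-inclusive counting, since descriptor platforms differ on this
convention and the choice should be auditable.

Two descriptors are implemented from their definitions rather than taken
from a library. KierA1 = (A+α)(A+α−1)²/(P+α)² with A heavy atoms, P
heavy-heavy bonds and α the Hall–Kier covalent-radius correction; a linear
sp³-carbon chain of length n gives exactly n, which anchors the unit tests.
GCUT_SLOGP builds a Burden-type matrix with Crippen atomic logP
contributions on the diagonal and 0.1·(bond order), floored at 0.01, on
bonded off-diagonals; the four reported summaries are the sorted
eigenvalues at positions {0, ⅓, ⅔, 1} and GCUT_SLOGP_3 is the largest.
The off-diagonal convention is a common GCUT choice; it affects absolute
values, not the orderings the models rely on.

E_vdw is the MMFF94 van der Waals term of a conformer embedded with ETKDG
at a fixed seed and minimized with the full force field. It is
deterministic for a fixed seed and rank-order faithful across a homologous
series, but not numerically equal to values from other force-field
platforms (e.g. AMBER-family parameterizations); only rank fidelity is
claimed or tested.

## Tiered QSAR

Tier 1 is fit on all curated actives with nine descriptors (n_C, a_count,
b_single, TPSA, BalabanJ, a_nO, lip_violation, GCUT_SLOGP_3, KierA1);
Tier 2 refits the medium+strong subset with E_vdw replacing KierA1.
Descriptors are standardized to zero mean and unit variance before PLS
because their units are heterogeneous (counts, Å², kcal/mol). The latent
dimension is chosen by maximizing leave-one-out Q² over 1–5 components with
ties broken toward fewer; at full rank PLS coincides with ordinary least
squares, which the tests use as an oracle. Splits are stratified by binder
class; an explicit `test_size` reproduces fixed partitions such as 62/10
(the nominal "80/20" of 72 compounds), and an option pins the global pEC50
extremes to the training set so the model never extrapolates in response
space during validation.

The domain of applicability is PCA (2 axes) on the standardized training
descriptors of each tier; a query is in-domain when its scores fall inside
the axis-aligned bounding rectangle of the training scores, expanded by a
configurable margin (default 0). Rectangular bounds were chosen over convex
hulls for transparency and serialization; out-of-domain predictions are
returned with the flag set, never suppressed. In tandem prediction, Tier 2
reports only when Tier 1 places the compound in the medium/strong band and
the query is inside the Tier-2 domain.

## Docking-score calibration

Docking scores are inputs; no docking is performed. The calibration subset
is restricted to carboxylates with 4–8 carbons — outside that class the
score–potency relation degrades, so predictions are class-restricted by
construction and queries outside the calibrated score range are flagged
extrapolated. The fit is ordinary least squares of pEC50 on score, which is
exactly equivariant under score shifts (tested against a two-pass
covariance computation at 1e−10).

## Toxicokinetics

A one-compartment model with first-order elimination (ke = ln2/half-life),
optional first-order absorption, bioavailability F defaulting to 1 (oral
PFAS absorption is near-complete and no value is given in the source
parameter tables), and superposition over one gavage per interval for the
study duration. Serum is evaluated on a 1-hour grid over the full window
starting at the first dose. Cmax is the grid maximum; TWA the trapezoidal
average. The boundary ka = ke is rejected with instructions unless the
limiting form F·D·ke·t/V·e^(−ke·t) is explicitly enabled, because silently
switching forms would hide a parameterization problem. Closed forms
(C(0) = D/V, the geometric accumulation factor, AUC = F·D/(V·ke)) are the
test oracles; grid refinement changes the metrics by <1% for half-lives of
6 h and realistic absorption rates.

## Benchmark dose

Inputs are group summaries (dose metric in μM, n, mean, SD). Each suite
member — linear, power, Hill, exponential-3, exponential-5 — is fit by
maximum likelihood under a normal, constant-variance likelihood on the
sufficient statistics; positivity and shape constraints (exponents in
(1, 18], Hill asymptote signs matching the declared direction) are enforced
by smooth reparameterization, so every fitted curve is monotone in the
declared direction. Optimization is Nelder–Mead followed by a BFGS polish;
members that fail to converge are dropped with a warning.

The BMD solves |f(BMD) − f(0)| = BMR·σ by bisection on [0, 10·d_max] to
1e−8 relative tolerance (closed forms for the linear and unit-shape Hill
models are matched to 1e−6 in tests); no solution in range is reported as
an infinite BMD, flagged. σ is the modelled constant SD by default with a
switch to the sample control SD — both conventions exist in practice.
Model averaging uses BIC weights ∝ exp(−BIC/2) with parameters drawn from
each member's asymptotic normal distribution in proportion to weight; the
averaged BMD is the median of the pooled draws and BMDL/BMDU the 5th/95th
percentiles. This asymptotic approximation stands in for a full MCMC
treatment (as in dedicated BMD software); the interface also accepts
externally computed BMD tables. The geometric standard error of the draw
distribution is reported as the response-side uncertainty for the
downstream regression.

## Errors-in-variables regression

Per point, x_obs ~ N(x_true, sx) and y_obs ~ N(a + b·x_true, √(σ² + sy²))
("normal" mode), or log y_obs ~ N(log(a + b·x_true), √(σ² + ln(GSE)²))
("lognormal" mode, for responses whose uncertainties are geometric standard
errors; the mode is a config switch because the convention is ambiguous and
both are defensible). Slope and intercept priors are normal, centred on an
OLS pre-fit; by default the slope prior SD is the SD of the observed
predictor and the intercept prior SD the geometric-standard-error summary
of the response, with a `swap` option for the other assignment — the
source convention does not pin down the mapping, so both are exposed rather
than resolved. σ has a half-Cauchy prior scaled by the OLS residual SD.

The latent predictors follow a structural model x_true_i ~ N(μ_x, τ²) with
μ_x and τ estimated jointly (normal hyperprior on μ_x, half-Cauchy on τ
scaled by the observed predictor SD). This is a deliberate design choice
over a fixed diffuse latent prior: marginalizing a flat latent prior gives
y ~ N(a + b·x_obs, σ² + sy² + b²·sx²), whose b²·sx² variance term
penalizes large slopes — the classical attenuation inconsistency of
functional errors-in-variables — whereas the structural form estimates the
latent spread and disattenuates. The implementation was cross-checked
against an independent Gibbs-sampler implementation of the same model
(JAGS) on a fixed dataset; posterior means and 95% intervals agree to
within Monte Carlo error.

Sampling uses the affine-invariant ensemble sampler (emcee), seeded and
bit-reproducible, with at least 2·(dim)+2 walkers; a result is flagged
invalid unless the effective sample size exceeds 100 for intercept, slope
and σ. Bayesian R² is var(fitted)/(var(fitted)+var(residual)) averaged
over draws; RMSE is computed from the posterior-mean line. Points with
sx = 0 have their latent predictor pinned to the observation, which makes
the sx = sy = 0 case reduce exactly to ordinary regression (tested against
OLS at ±0.05 on the slope).

Frequentist coverage of the 95% credible interval for a fixed true slope
is close to, but not exactly, nominal in the study-like regime (n = 8,
predictor measurement SD ≈ 60% of the predictor spread): the empirical
prior centring (priors centred on estimates from the same data) and the
small sample leave the interval slightly narrow, with misses on the
attenuated side. The acceptance suite measures this at 50 seeded
replicates; users should treat slopes from n = 8 datasets as evidence of
direction and rough magnitude, not precise effect sizes.

## Synthetic data

Generators emulate the five input tables with known truth. The binding
table uses a roster of 72 structurally diverse PFAS (carboxylate,
sulfonate, ether, fluorotelomer alcohol, sulfonamide, ω-H and diiodo
series, chain lengths 3–17) with pEC50 linear in the standardized Model-1
descriptors plus Gaussian noise (default SD 0.3 pEC50 units), affinely
rescaled so the extremes hit the study's training range (−2.62, 1.17); the
rescale is folded into the recorded effective coefficients. Seven salt-form
rows and one duplicate pair are planted to exercise curation. Planted
coefficient signs encode the mechanistic picture (size up to the pocket
length helps, oxygens help, polarity and lipophilicity extremes hurt);
size-family descriptors are strongly collinear by construction, as in real
homologous series, so sign-recovery tests check only effects identifiable
above the design's OLS noise floor.

The docking stand-in for the carboxylate calibration is deterministic: the
line is fixed by the two published anchor predictions and the residual
vector is orthogonal to the design, scaled for a sample R² of exactly 0.70.
Dose–response tables come from a decreasing Hill truth (control mean 50,
drop 10, k = 5 μM, shape 2, SD 1, n = 10 per group, doses 0–20 μM), whose
closed-form BMD at one SD is 5/3 μM. AOP pairs are generated exactly under
the errors-in-variables observation model with scalar measurement SDs
(sx = 4 kcal/mol, the scale of replicate MD simulation SDs; sy = 15 μM,
the scale of BMD posterior standard errors) and zero residual SD, so that
sx = sy = 0 yields exactly collinear points.

What passing on these data shows: the estimators recover planted truths
under their own assumptions at realistic noise. What it does not show:
performance under assay heteroscedasticity, activity cliffs, descriptor
error, or model misspecification in real binding data; the soft comparison
of tier fit statistics to published values is report-only because the
descriptor platform differs.

## Problem sizes

Default test and acceptance runs use 72-compound binding tables, 5-group
dose–response designs, 8-point AOP datasets, 500–2000 BMD draws and
2000–6000 MCMC draws; coverage experiments use 50 seeded replicates. These
sizes keep every statistical check well-resolved while the full suite runs
in minutes on a single CPU.
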