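# Methods

## Scope

`soilqualkit` computes a composite Soil Quality Index (SQI) from a Minimum
Data Set (MDS) of soil indicators selected by principal-component analysis,
plus the stand-level structure and productivity metrics (CV and Gini of DBH,
allometric biomass, NPP, broadleaf biomass share) usually analysed alongside
it in plantation studies. A latent-factor generator supplies synthetic soil
tables and tree inventories with the statistical structure the pipeline
assumes, so every stage is testable without field data.

## The MDS–SQI model

**Inputs.** A complete samples × indicators table of non-negative
measurements, with each indicator declared *more-is-better* or
*less-is-better* (bulk density is the only less-is-better indicator in the
default 20-indicator suite). Missing cells are rejected, not imputed: the
selection chain and the scoring means assume complete cases.

**Factorability.** The overall Kaiser–Meyer–Olkin statistic is
Σr²/(Σr² + Σq²) over off-diagonal entries, with partial correlations *q*
taken from the inverse correlation matrix; Bartlett's sphericity statistic is
−(n − 1 − (2p+5)/6)·ln det(R) on p(p−1)/2 degrees of freedom. Both are
diagnostics only: values below the usual guidelines (KMO < 0.5, Bartlett
p ≥ 0.05) produce warnings and an audit entry, never a hard stop, because a
practitioner should see the index anyway and judge.

**PCA.** Eigendecomposition of the sample correlation matrix (equivalently,
PCA of z-scored data with ddof = 1 — the test suite cross-checks against
scikit-learn's decomposition). Components with eigenvalue ≥ 1 are retained;
ties at exactly 1.0 are kept. Loadings are eigenvectors scaled by
√eigenvalue; each column's sign is fixed so its largest-magnitude entry is
positive. The sign convention affects nothing downstream (norms,
communalities, groups and SQI are all even in the loading sign).

**Grouping.** Each indicator joins the retained component where its absolute
loading is largest (ties to the lower component index). A fixed ≥ 0.5
loading cut is *not* used: published groupings of this kind include
indicators whose best loading is below 0.5, and max-|loading| assignment
reproduces them while guaranteeing every indicator exactly one group.

**Norm values and retention.** The norm value
N_i = sqrt(Σ_k U_ik² e_k) is the eigenvalue-weighted length of the
indicator's loading vector over retained components — its overall
representational power. Within each group, indicators with
N_i ≥ 0.9 × (group maximum), boundary inclusive, are candidates.

**Correlation pruning.** Candidates are walked in descending norm order; one
is dropped iff it is significantly Pearson-correlated (two-sided p < 0.05 via
the t transformation with n − 2 df) with an already-kept higher-norm
indicator of the same group. The greedy descending order makes the outcome
deterministic. Correlation facts normally come from the data; they can be
supplied externally (e.g. replayed from a published correlation statement),
and a missing needed pair is an error rather than a silent keep.

**Scoring.** S(x) = 1/(1 + (x/x_m)^b), with a = 1 the maximum score,
b = −2.5 (more-is-better, increasing) or +2.5 (less-is-better, decreasing).
x_m is the indicator's mean over *all* samples in the run, giving every
pattern one shared reference so indices are comparable between patterns.
S(x_m) = 0.5 exactly, and the two orientations complement to 1 at equal x_m.
Limits at x = 0 are taken by convention (0 for increasing, 1 for
decreasing); negative measurements are errors.

**Index, classes, sensitivity.** SQI = Σ W_i S_i with W_i = C_i/ΣC_i over
the MDS (weights sum to 1, scores lie in (0,1), so the index is already on
the 0–1 scale; no additional min–max rescaling is applied and the audit
notes this). Class bounds: published ranges share their endpoints
("0.37–0.46" medium, "0.46–0.55" high, very high strictly > 0.55); each
shared endpoint is assigned to the class whose range starts there, so 0.46
is "high", 0.55 is "high" and anything above 0.55 "very high". The
sensitivity index SI = max(SQI)/min(SQI) is computed over the replicate
samples of each planting pattern (three plot-level replicates in the default
design); the grouping unit is configurable by passing any replicate
labelling.

## Stand metrics

* CV_D = 100 × sample (n−1) standard deviation of DBH / mean DBH. The
  sample estimator is chosen because plot inventories are samples used for
  inference across plots.
* Gini_D comes in two forms. `standard` is the true Gini
  (mean absolute pairwise difference / (2 × mean), computed by the sorted
  identity and clamped at 0 against floating cancellation), bounded in
  [0, 1) and scale-invariant. `paper_literal` is a variance-to-mean
  dispersion index, (1/n)Σ(DBH_i − mean)²/mean, which is what some field
  reports' printed formulas and value ranges (well above 1) actually
  correspond to; it is unbounded and linear in the DBH scale. The dispersion
  form is the default for comparability with such reports; the standard form
  is recommended for new work. Neither is silently rescaled.
* Biomass: W = a(D²H)^b per tree (kg), species-specific coefficients
  supplied by the user (they are stand- and region-specific); plot totals are
  converted to t ha⁻¹ by (Σkg)/1000 × 10000/area. Only live recorded stems
  enter; there is no mortality field.
* NPP = FB / stand age (default age 20 years, per-plot overridable). This is
  a mean-annual-increment proxy, not a flux measurement.
* PBS = broadleaf share of stand biomass (%), independent of plot area.

## The synthetic world

Soil tables are drawn from x = shift + Λf + ε with standard-normal factors
and diagonal Gaussian noise, the latent value standardized to unit sd and
mapped affinely to a positive measurement scale: value = mean × (1 + 0.2 z),
with per-indicator means set to typical field magnitudes for the 20-indicator
suite. The affine map preserves the designed correlation structure
ΛΛᵀ + Ψ exactly (verified to ±0.05 at n ≥ 5000 in the tests); a floor at 1%
of the mean keeps scoring defined and binds with probability ~3 × 10⁻⁷ per
cell. Pattern-level quality differences are mean shifts in latent sd units
applied to more-is-better indicators, so a designed gradient is a usable
ground truth for recovery tests.

The default design uses the published 20 × 6 loading matrix as Λ with
uniqueness² = 1 − communality, ten planting patterns and three plot-level
samples each (n = 30). What a green test on this world establishes: the
pipeline's algebra, selection logic, monotonicity and recovery behaviour
under a known second-moment structure. What it does not establish:
behaviour under skewed or heavy-tailed indicators, spatial autocorrelation
between plots, measurement error structure, or any temporal dynamics — the
generator has none of these.

**Identifiability caveat.** Three of the six published indicator groups
contain a single indicator. A block-structure emulation makes such an
indicator uncorrelated with all others, so the population eigenvalue of its
direction is exactly 1.0 — precisely the retention threshold — and whether
its component is retained at any sample size is essentially a coin flip.
Recovery guarantees in the tests are therefore stated for the
multi-indicator factors (always represented in the MDS in the measured
runs) and for the retained-component *count* (4–6 components in 50/50
measured runs at n = 60); per-singleton-factor recovery is not a property
any faithful emulation can promise.

Stand inventories: DBH ~ lognormal (default median 15 cm, σ = 0.3), heights
H = 1.5 D^0.8 × lognormal noise (σ = 0.1), Bernoulli broadleaf labels, 100
stems per 600 m² plot (≈1670 ha⁻¹, inside the reported 675–3450 range for
such stands). All generators are deterministic given (spec, seed); no global
random state is used or touched.

## Numerical conventions

* Standardization uses the sample (ddof = 1) standard deviation; a
  zero-variance indicator is an error naming the column.
* Eigenvalues are clipped at 0 (symmetric eigensolver round-off); retention
  uses a 10⁻¹² tolerance below the threshold so exact ties are kept.
* KMO refuses numerically singular correlation matrices (condition number
  > 10¹²) with a suggestion to remove a redundant indicator.
* Score validation in the index is strict: scores must lie inside (0,1).
* The Pearson p-value uses the t transformation with n − 2 df.

## Known limitations

* Allometric coefficients must be supplied; none are bundled beyond the two
  synthetic-species defaults used by the generator (labelled as such).
* The index is computed from the MDS only; no TDS-based variant, and no
  alternative (linear or fuzzy-membership) scoring functions.
* KMO/Bartlett reference values from any particular field dataset are not
  reproducible without that dataset; the implementations are verified against
  small-matrix oracles instead.
* The NPP proxy divides standing biomass by one stand age; stands with
  differing or uncertain ages need per-plot ages in the plot metadata.
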