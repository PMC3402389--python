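# Methods

## The analysis

`genemeta` implements the standard fixed/random-effects meta-analysis of a
biallelic SNP in a case-control design, applied here to the MDM2 SNP309
(rs2279744, T→G) polymorphism and lung-cancer risk. Each study contributes
genotype counts (GG, GT, TT) for a case arm and a control arm. Three
contrasts are analysed:

* **additive** — GG vs TT, heterozygotes excluded. This is the *homozygote
  contrast* convention, not the Cochran-Armitage per-allele trend test;
  no trend test is implemented because the source tables report only the
  homozygote contrast.
* **dominant** — (GG+GT) vs TT,
* **recessive** — GG vs (GT+TT).

Each collapsed 2×2 table `(a, b, c, d)` (exposed/unexposed cases,
exposed/unexposed controls) gives a per-study odds ratio `ad/bc` with the
Woolf log-scale standard error `sqrt(1/a + 1/b + 1/c + 1/d)` and a
log-symmetric 95% CI. The z multiplier is kept at 1.959964 internally;
report layers round ORs and CI bounds to 2 dp, heterogeneity statistics to
3 dp and I² to 1 dp, mirroring the conventional table format.

### Continuity correction

If any cell of a collapsed table is zero, 0.5 is added to **all four**
cells (Haldane-Anscombe), per table per model, and the table is flagged.
A table whose case or control *margin* is zero before correction (e.g. a
study with only heterozygotes under the additive contrast) is degenerate:
the study is excluded from that model only, with the reason logged in the
report, never silently dropped from the dataset. The packaged dataset
contains no zero cells, so none of the published numbers depend on this
policy.

### Heterogeneity

Cochran's Q is computed from inverse-variance weights `w_i = 1/se_i²` on
the Woolf log-OR estimates about the inverse-variance mean; its p-value is
the upper chi-square tail on k−1 df. Derived quantities:
`I² = max(0, (Q−df)/Q)·100` and the DerSimonian-Laird moment estimator
`τ² = max(0, (Q−df)/(Σw − Σw²/Σw))`. Q/I²/τ² come from these Woolf
weights even when the pooled point estimate is Mantel-Haenszel, matching
RevMan 5 behaviour.

### Pooling and model selection

* **Fixed effects** are Mantel-Haenszel:
  `OR_MH = Σ(a_i d_i/n_i) / Σ(b_i c_i/n_i)`, with the
  Robins-Breslow-Greenland variance estimator for the CI of its log (the
  RevMan standard; the inverse-variance CI is the natural fallback but was
  not needed — see Reproduction below).
* **Random effects** are DerSimonian-Laird: weights `1/(se_i² + τ²)` on
  the log-OR scale. With τ² = 0 this reduces exactly to inverse-variance
  fixed effects (tested).
* **Selection rule**: if the Q-test p-value is *strictly greater* than the
  threshold (default 0.1) the fixed-effect pool is used, otherwise random
  effects; ties at the threshold go to random. A single study "pools"
  trivially as fixed with the heterogeneity block absent (rendered as a
  dash). The rule can be overridden (`method = fixed | random`) for
  comparison analyses.
* Significance of the pooled log OR uses the Wald Z-test.

### Hardy-Weinberg QC

Control arms are tested for HWE two ways: the chi-square goodness-of-fit
statistic over the three genotype classes (1 df, no continuity correction,
allele frequency `p̂ = (2·GG + GT)/2n`) — the statistic genotyping-QC
tables print and the operative gate here — and the conditional exact test
on the heterozygote count given the allele counts, provided as a second
opinion. Studies violating HWE at `hwe_alpha` (default 0.05) are flagged
in the report, not excluded: exclusion would be a silent data change, and
all eleven packaged control arms satisfy HWE anyway. Monomorphic arms
return chi2 = 0 with a flag.

### Publication bias and sensitivity

Funnel coordinates are (log OR, SE(log OR)) per study, exported
untransformed (axis inversion is a plotting concern). Egger's test is the
classical variant: OLS of the standard normal deviate `θ_i/se_i` on the
precision `1/se_i`; t = intercept/SE(intercept) on k−2 df, two-sided p,
requiring k ≥ 3. The one-way sensitivity analysis re-pools each
leave-one-out subset with the full selection rule re-applied per subset.

## Reproduction of the published analysis

The packaged fixture transcribes the published genotype-distribution
table of eleven lung-cancer case-control studies (7196 cases, 8456
controls; the multi-ethnic US study split into African and Caucasian
strata). Two transcription/derivation notes:

* One study's characteristics table prints a control total of 1300 while
  its genotype triple sums to 1294; the triple is authoritative (the
  7196/8456 headline totals only check out with 1294).
* All eleven printed HWE chi-squares match the plain chi-square
  goodness-of-fit statistic, although the source's methods text names
  Fisher's exact test; the chi-square is therefore treated as the
  operative method.

With these data the pipeline reproduces, at printed precision: all eleven
HWE chi-squares; the single-study African ORs/CIs under all three models;
the overall pooled ORs 1.14 (0.95–1.37), 1.05 (0.92–1.19) and
1.12 (0.99–1.27) with I² = 67.5/66.7/48.7%; the Asian subgroup cells; and
the Egger t statistics −0.58/−0.14/−0.72.

**Caucasian subgroup cells.** The published Caucasian Q-test p-values
(0.106/0.218/0.183) all exceed 0.1, so the stated rule selects fixed
effects, yielding 1.02 (0.89–1.17), 0.95 (0.87–1.04), 1.06 (0.94–1.20).
The published cells — 1.05 (0.86–1.27), 0.96 (0.86–1.07), 1.08
(0.92–1.27) — are instead exactly the DerSimonian-Laird random-effects
results: the original analysis evidently carried the random-effects choice
made for the overall data into the ethnicity subgroups. The package
applies the rule as stated by default and exposes the forced-random
override that reproduces the printed cells; both are written by the
subgroup analysis driver.

**Leave-one-out stability.** The source claims no single-study omission
alters any significance call (data not shown). Recomputation disagrees,
marginally: omitting the largest null study (Li) makes the additive and
recessive random-effects CIs exclude 1 (lower bounds 1.003 and 1.011), as
does omitting Chua for the recessive contrast (1.018). These pools were
cross-checked against R's `metafor::rma(method="DL")` to full precision.
A fixed-effect sensitivity display flips other omissions instead. The
sensitivity table therefore reports the recomputed truth, and the
corresponding reproduction test documents the discrepancy by failing
against the published claim.

## Synthetic data

The generator emulates the structure of the study table with known truth.
Controls are multinomial draws from HWE proportions (p², 2pq, q²) at a
configurable variant-allele frequency; case probabilities are exposure
tilts `P_case(g) ∝ P_ctrl(g)·ψ^{e(g)}` with the exposure indicator of the
chosen inheritance model, so the model-matched collapsed 2×2 has
population OR exactly ψ. (Under the additive/homozygote contrast the
indicator tilts GG only, which leaves the GG:TT odds scaled by exactly ψ
with heterozygotes untouched.) Between-study heterogeneity is log-normal
on the OR — `log ψ_i ~ N(log ψ, τ²)` — the standard DL generative
assumption. Arm sizes are fixed per study (case-control design), not
cohort binomial. Randomness is stream-disciplined: one `SeedSequence` per
dataset spawned into per-study child streams, so output depends only on
(config, seed).

Defaults (k = 11 studies, 600/800 arms, p_g = 0.4) echo the shape of the
real table: eleven studies, median arm sizes of a few hundred, and a
control G-allele frequency in the 0.35–0.55 range the studies report.

What the generator does **not** emulate: linkage disequilibrium,
genotyping error, covariates, population stratification or
selection/publication bias. Tests passing on synthetic data therefore
validate the estimators under a correctly specified sampling model, not
robustness to those real-data complications.

### Validation harness sizes

`evaluate_recovery` scores bias, RMSE, 95% CI coverage of the true OR and
the Q-test rejection rate over seeded replicates. The reproduction suite
uses k = 30 studies of 2000/2000 at ψ = 1.5, τ = 0 over 200 replicates
for recovery/coverage, and k = 10 studies of 1000/1000 at ψ = 1, τ = 0
over 1000 replicates for the Q-test type-I rate at the 0.1 gate (moderate
arm sizes chosen so the Woolf-normal approximation underlying Q holds);
the analysis driver uses k = 15, 1000/1000, 200 replicates per scenario.
Monte-Carlo checks use 99% binomial bands around the nominal rates.

## Numerical notes and edge cases

* All pooling is done in log-OR space; point estimates are exponentiated
  at the end.
* `I²` is clipped to [0, 100) and `τ²` to ≥ 0; Q = 0 defines I² = 0.
* The exact HWE test enumerates heterozygote counts of the correct parity
  in log-space (log-gamma weights, max-subtracted), and counts
  configurations with probability ≤ observed × (1 + 1e-12) to absorb
  floating-point ties.
* Heterogeneity requires k ≥ 2, Egger k ≥ 3, leave-one-out k ≥ 2; each
  raises an informative error below its minimum.
* Reports serialize deterministically (sorted JSON keys, `repr` floats in
  TSV), so identical (dataset, config) yields byte-identical output.

## Known limitations

* No Peto OR, risk ratio/difference, Hartung-Knapp adjustment, or
  REML/Paule-Mandel τ² — only the MH + DL pair the analysis reproduces.
* No trim-and-fill or Begg rank correlation; Egger and funnel coordinates
  only.
* The per-stratum genotype counts behind the published smoking, gender
  and histology rows were never published; those rows cannot be
  recomputed from data. The stratification machinery is instead exercised
  on synthetic strata with known truth.
* Forest/funnel plot rendering is out of scope; coordinates are exported
  for external plotting.
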