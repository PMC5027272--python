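# Methods

This note records the statistical model, the numerical choices, and the known
limitations of the `embryomix` implementation.

## 1. Binomial mixture exclusion model

### Setup

A cohort of `N` embryos is nominally phenotype-I. Each embryo independently
belongs to a hidden phenotype-II subpopulation with probability ρ (the
admixture fraction), develops to term at rate `q2` if phenotype-II and `q1`
otherwise. `T` term offspring are observed. Separately, `k` embryos from the
same production process are assayed for their modification state and all
show the phenotype-I state; under the model's 100%-correlation assumption
each assayed embryo is phenotype-II with probability ρ, so the probability
of observing `k` concordant phenotype-I states is `(1 − ρ)^k`.

### The combined probability

Let `m ~ Binomial(N, ρ)` be the hidden phenotype-II count and let `X` be the
number of term offspring that derive from phenotype-II. The package computes
the distribution of `X` conditional on the observed total `T`:

```
P(X = n | T, ρ) ∝ Σ_m  Bin(m; N, ρ) · Bin(n; m, q2) · Bin(T − n; N − m, q1)
```

normalized over `n = 0 … T` (strategy `"total-conditioned"`, the default).
This marginal collapses analytically: conditional on a term birth, the
probability that it derives from phenotype-II is

```
r(ρ) = ρ·q2 / (ρ·q2 + (1 − ρ)·q1)
```

independently per offspring, so `X | T ~ Binomial(T, r(ρ))`. The test suite
verifies the numeric marginalization against this closed form to 1e-9 and
against a Monte-Carlo cohort simulator (conditional frequencies over 4×10⁵
simulated cohorts, 3 standard errors per support point).

The reported quantity is the worst case over the unknown ρ:

```
P_max(n, k) = max_{ρ ∈ [0,1]}  (1 − ρ)^Σk · P(X ≥ n | T, ρ)
```

`P_max ≤ α` excludes, at level α, the scenario that `n` or more of the term
offspring came from a hidden normally-developing subpopulation regardless of
the true admixture fraction. `min_excludable_n` returns the smallest such
`n` (bisection on the monotone tail); for the reference cohort
(`N = 232, T = 24, q1 = 24/232, q2 = 107/237`) it gives `n = 9` for
`k = 20`, `n = 14` for `k = 9`, and `n = 7` for `k = 29`.

A second strategy, `"literal-prose"`, keeps only the single `m = n` term of
the sum (every hidden phenotype-II embryo develops, no normalization). It
yields values around 1e-100 for mid-range `n` and is retained only to
document why it cannot be the model behind the published mid-tail bounds.

### Numerics

- All pmf/tail arithmetic is in log space (`gammaln`-based log binomial
  coefficients, `logsumexp` for sums); tails at the 1e-40 scale are exact.
- The ρ-free log-binomial tables for a given `(N, T, q1, q2)` are cached, so
  a full worst-case maximization runs in about one second.
- The maximization uses a 2001-point ρ grid followed by bounded scalar
  refinement around the grid argmax to |Δρ| ≤ 1e-6. The profile is smooth
  and unimodal in practice; the grid guards against missing a narrow peak.

### Known limitation: the published n = 24 bounds

The three published worst-case values for `n = T = 24`
(9.84e-17 for k = 20, 9.32e-17 for k = 29, 1.05e-16 for k = 9) are **not
reproducible** from the stated model. The exact conditional tail at
`n = 24` is `r(ρ)^24`, whose evidence-weighted maximum is 3.66e-8
(k = 20), 1.11e-9 (k = 29) and 1.38e-5 (k = 9) — 8 to 11 orders of
magnitude above the published numbers. The published trio is mutually
consistent only with a k-independent factorization `A · (1 − ρ*)^k` with
`A ≈ 1.1e-16` (the scale of double-precision epsilon) and `ρ* ≈ 0.006`;
fitting `A` and `ρ*` from two of the three values reproduces the third to
three digits. The natural explanation is a floating-point cancellation
artifact (a tail computed as `1 − cumulative` in double precision) in the
original analysis. This package reports the exactly-computed values and the
corresponding acceptance cases fail by design; the mid-tail bounds
(0.0465, 0.0493, 0.0465) and the exclusion thresholds 9/14/7 are reproduced
to four significant digits.

## 2. Differential-expression null by label re-assignment

### Pipeline

Per group assignment: log2 transform (raw positive intensities) → quantile
normalization (columns share the mean sorted profile; ties receive the mean
of the tied reference slots) → technical-replicate collapse (median across
probes sharing a platform replicate group) → two-group moderated *t* →
two-sided p from the t distribution → Benjamini–Hochberg FDR → ranked
adjusted-p curve. Probes mapping to the same gene symbol can be reduced to
the lowest-raw-p probe, with BH re-applied at the gene level by default.

### Moderated t

Gene-wise pooled variances `s_g²` (df `d_g`) are shrunk toward a prior
`s_0²` with prior df `d_0` estimated by method of moments on `log s_g²`
under a scaled-F model (digamma/trigamma moments; Newton inversion of the
trigamma function). The posterior variance is
`(d_0·s_0² + d_g·s_g²)/(d_0 + d_g)` and p-values use `d_0 + d_g` degrees of
freedom. `prior_df=0` gives the ordinary pooled two-sample *t* (verified to
1e-10 against `scipy.stats.ttest_ind`); `prior_df=inf` shrinks fully. An
optional test cross-checks hyperparameters and statistics against R/limma's
`eBayes` to 1e-4 / 1e-6. BH adjustment delegates to
`statsmodels.stats.multitest.multipletests("fdr_bh")`, verified against a
brute-force step-up oracle.

### Assignments

Two-group splits of `n` samples into sizes `g` and `n − g`. For equal sizes
the label swap yields the same test, so enumeration anchors one sample and
counts each partition once: 16 samples in two 8s give C(16,8)/2 = 6,435;
8 sibling pairs constrained to one member per group give 2⁷ = 128; choosing
8 of 24 samples gives C(24,8) = 735,471 (sampled rather than enumerated).
Sampling draws `k` distinct lexicographic combination ranks without
replacement and unranks them — exactly uniform and duplicate-free by
construction (default seed 20160913).

### Density summary

The ensemble of curves is summarized as a 2-D density over
(log10 rank, adjusted p): points are binned on a regular grid padded by
5 bandwidths and smoothed with a Gaussian product kernel (Silverman's
per-axis rule `n^{-1/6}·σ` unless overridden), normalized to integrate to 1
over the grid. Binning + `gaussian_filter` keeps the cost linear in the
~10⁵ curve points where a direct kernel sum would be quadratic.

## 3. Synthetic generators

### Cohorts

`simulate_cohort` draws per-embryo phenotype labels (`Bernoulli(ρ)`) and
term outcomes (`q1`/`q2`), plus `k` assayed embryos whose reported state is
concordant with the label with configurable probability (default 1.0,
matching the model assumption). `simulate_cohort_counts` is the vectorized
aggregate version (`m ~ Bin(N, ρ)`, term counts binomial per
subpopulation); a property test asserts distributional equivalence. These
are the Monte-Carlo oracle for the mixture module.

### Sibling-paired expression studies

Defaults emulate the target study design as this package's own choices:
8 control (ICSI) sibling blastomere pairs = 16 arrays plus 8 treatment
(phICSI) arrays, 44,000 probes with 5% of genes carried by duplicate
technical-replicate probes, and 73 truly differentially expressed genes
shifted by 2 residual standard deviations with random sign. On the log2
scale a sample value is

```
baseline_g  (Normal(8, 1.5), fixed per gene)
+ pair effect (shared by the two siblings of a pair; SD = residual_sd·√pair_rho)
+ group effect (declared DE genes, treatment samples only)
+ noise       (independent per probe and sample; SD = residual_sd·√(1 − pair_rho))
```

so `pair_rho` is exactly the within-pair correlation of the residual
(verified empirically in the tests at `pair_rho = 0.9` to ±0.05).

`pair_rho` defaults to 0.04: on single-blastomere arrays technical noise
dominates the shared embryo effect. This choice also makes the unpaired
moderated *t* honest under the true null — pairing-respecting
re-assignments cancel pair effects in the group-mean difference but leave
them in the variance estimate, so a large `pair_rho` would make the pooled
raw p-values conservative rather than uniform. With the default, the raw
p-values pooled over all 128 pairing-respecting assignments of a true-null
study pass a KS test against uniform at statistic < 0.02 with
5% ± 1% below 0.05 (an acceptance test).

### Limitations

- The expression generator is Gaussian on the log2 scale; it does not model
  intensity-dependent variance, background, or array spatial artifacts.
- Treatment samples carry an independent latent per-sample effect of the
  same SD as the pair effect, but no treatment-wide batch effect.
- The cohort generator implements exactly the model assumptions (independent
  embryos, perfectly correlated modifications); it cannot probe violations
  of those assumptions beyond the `state_concordance` knob.
- Acceptance checks that depend on generated data use reduced problem sizes
  (1,000–2,000 genes instead of 44,000) chosen for runtime, not for
  outcome; effect sizes and the 73-gene count are kept at their defaults.
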