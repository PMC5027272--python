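# embryomix

Statistical tools for two questions that arise when a reproductive-biology
experiment produces an unexpectedly successful embryo cohort:

1. **Could the successes have come from a hidden, normally-developing
   subpopulation?** `embryomix.mixture` computes a worst-case exclusion bound:
   the probability, maximized over an unknown admixture fraction ρ, that at
   least *n* of the *T* term offspring from an *N*-embryo cohort derive from a
   hidden phenotype-II subpopulation — multiplied by the evidence factor
   (1 − ρ)^k from *k* independently assayed embryos that all showed the
   phenotype-I modification state.
2. **How many "significant" genes does a differential-expression analysis
   produce when there is no real group difference?** `embryomix.denull` builds
   the empirical null by exhaustively (or uniformly sampling) re-assigning
   sample group labels, running a moderated-*t* + Benjamini–Hochberg FDR
   analysis per assignment, and summarizing the resulting ranked
   significance curves.

`embryomix.synthetic` provides seeded generators for both settings (mixed
embryo cohorts; sibling-paired two-condition expression studies with planted
differentially expressed genes) and is also the Monte-Carlo oracle used by
the test suite. `embryomix.io` and the `embryomix` console script cover TSV
exchange formats and a shell-level interface.

## The mixture model

A cohort of `N` embryos is nominally phenotype-I (term rate `q1`), but each
embryo is independently phenotype-II (term rate `q2`) with unknown
probability ρ. Conditional on observing `T` term offspring, the number that
derive from phenotype-II is Binomial(`T`, `r(ρ)`) with

```
r(ρ) = ρ·q2 / (ρ·q2 + (1 − ρ)·q1)
```

(the package computes this by exact log-space marginalization over the hidden
phenotype-II count `m ~ Binomial(N, ρ)`, and cross-checks the closed form in
its tests). Concordant modification states in `k` assayed embryos contribute
the factor `(1 − ρ)^k`, and the reported bound is

```
P_max = max over ρ in [0, 1] of  (1 − ρ)^Σk · P(X ≥ n | ρ)
```

computed on a dense ρ grid with local refinement. `P_max ≤ α` excludes the
scenario that `n` or more of the term offspring came from a hidden normal
subpopulation. A known limitation of published values at the extreme `n = T`
tail is discussed in [docs/methods.md](docs/methods.md).

## Worked example

For the cohort this package was built around — 232 transferred phenotype-I
embryos of which 24 developed to term (`q1 = 24/232 ≈ 0.103`), a 237-embryo
phenotype-II reference with 107 at term (`q2 = 107/237 ≈ 0.451`), and
`k = 20` concordant assayed embryos — the bound for `n = 9`:

```bash
embryomix exclude \
  --developed-a 24 --transferred-a 232 \
  --developed-b 107 --transferred-b 237 \
  --n 9 --k 20 --out exclusion.tsv
```

writes `exclusion.tsv`:

```
n	k_list	p_max	rho_argmax	excluded	strategy
9	20	0.04648797373885841	0.08000403559053795	True	total-conditioned
```

so "9 or more of the 24 term offspring came from a hidden normal
subpopulation" is excluded at α = 0.05. The same computation in Python:

```python
from embryomix.mixture import MixtureQuery, estimate_rate, worst_case

q1, q2 = estimate_rate(24, 232), estimate_rate(107, 237)
res = worst_case(MixtureQuery(N=232, T=24, q1=q1, q2=q2, k_list=(20,), n=9))
print(res.p_max)          # 0.046488
```

A null ensemble over the 128 pairing-respecting re-assignments of 8 sibling
blastomere pairs:

```bash
embryomix simulate expression --n-genes 1000 --seed 7 --out study/
embryomix de-null run \
  --expression study/expression.tsv --samples study/samples.tsv \
  --annotation study/annotation.tsv --probe-collapse --pairing \
  --out null_summary.tsv
```

## Layout

- `src/embryomix/mixture.py` — exclusion bounds (`worst_case`,
  `min_excludable_n`, `rho_profile`)
- `src/embryomix/denull/` — preprocessing (quantile normalization, replicate
  collapse), moderated *t* + BH-FDR, assignment enumeration/sampling, null
  ensembles and density summaries
- `src/embryomix/synthetic.py` — seeded cohort and expression generators
- `src/embryomix/io.py`, `src/embryomix/cli.py` — TSV I/O and the `embryomix`
  command
- `docs/methods.md` — model derivations, numerical choices, known limitations
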