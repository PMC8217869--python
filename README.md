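# assemblage

Community-assembly inference for microbiome OTU tables.

Amplicon surveys of host-associated microbiomes (the motivating system is
marine sponges sampled alongside seawater and sediment) routinely ask the
same chain of questions: how diverse is each community, do communities differ
between host species and environments, which taxa are habitat generalists or
specialists, and — most importantly — is the community assembled by
*deterministic* processes (host selection, species interactions) or by
*stochastic* ones (drift, dispersal, ecological equivalence)?  `assemblage`
implements this analysis chain as a tested, seed-reproducible library with a
CLI, together with a synthetic-community generator that provides ground truth
(known immigration rates, planted generalists/specialists, known host-trait
phylogenetic signal) so that every inference stage can be validated end to
end.

## What it computes

Given a taxa × samples count table, a sample → category design, and
optionally a taxonomy and a host phylogeny:

- **Rarefaction** to a common library depth (single seeded subsample without
  replacement), rarefaction curves, and the alpha-diversity panel: observed
  OTUs, bias-corrected Chao1, ACE, Shannon *H′* (nats), inverse Simpson
  *D₂*, Pielou's *J*.
- **Beta diversity**: Bray–Curtis dissimilarity
  *d(x, y) = Σ|xᵢ − yᵢ| / Σ(xᵢ + yᵢ)*, with one-way PERMANOVA (pseudo-F, R²)
  and ANOSIM (rank-based R), permutation p-values.
- **Levins' niche breadth** *B = 1/Σₕ p² * per OTU, classified against a null
  envelope from **quasiswap** randomizations (fixed row sums, column sums,
  and fill): observed *B* above the 95% envelope → habitat generalist, below
  → habitat specialist, otherwise neutral.
- **Modified stochasticity ratio (MST)**: for each within-category pair,
  observed dissimilarity *D* against its null expectation *E* under a
  richness- and depth-preserving stochastic-assembly null;
  *MST = D/E* if *D ≤ E*, else *(1 − D)/(1 − E)*.  Category means below 0.5
  are deterministic-dominated, above 0.5 stochastic-dominated.
- **Sloan neutral community model**: occurrence frequency *fᵢ* of each taxon
  regressed on its metacommunity abundance *pᵢ* through
  *f̂(p; m) = 1 − E_Beta[(1 − q)^N]* with *q ~ Beta(Nmp, Nm(1 − p))* — the
  stationary neutral distribution observed through per-read sampling.  The
  single free parameter *m* is the immigration rate; R² is compared against
  zero-parameter binomial and Poisson random-sampling fits to accept or
  reject neutrality, with a 1,000-replicate taxon bootstrap for the CI of
  *m*.
- **Blomberg's K** with a tip-permutation test for phylogenetic signal of a
  continuous trait (e.g. per-sample *H′*) on the host tree, with replicate
  samples attached as zero-length polytomies.
- **Biomarker screen** (LEfSe-style): per-million lineage aggregation,
  Kruskal–Wallis filter, bootstrapped one-vs-all LDA effect sizes on the
  log₁₀ scale.
- **Set algebra**: per-category detection sets, Venn regions, exclusive and
  core OTUs ("present in all categories, not necessarily all replicates"),
  and the reporting percentages.

## Worked example

Simulate a neutrally assembled community (immigration rate m = 0.3, three
host categories, five replicates each, 1,000 reads/sample), then ask the two
headline questions — does the neutral model fit, and what does MST say?

```python
import assemblage as a

spec = a.SimSpec(S=300, n_categories=3, n_samples_per_category=5,
                 depth=1000, regime="neutral", m=0.3, seed=42)
table, design, _ = a.simulate_community(spec)

print(a.SloanNCM(table).fit(n_boot=200, seed=0).summary())
print(a.StochasticityRatio(table, design).fit(n_null=200, seed=0).summary())
```

```
Sloan neutral community model
  taxa 240, samples 15, N (mean depth) 1000.0, detection limit 0.001
  m      0.3193
  N*m    319.3
  m 95% CI [0.2778, 0.3678]  (200 bootstraps)
  R^2    0.9379   (binomial 0.6924, Poisson 0.6927)
  verdict: neutral fit accepted
  partition: 2 above / 237 within / 1 below the 95% band

Modified stochasticity ratio (occurrence_abundance null, 200 randomizations; boundary 0.5)
  cat1         MST = 0.944  -> stochastic
  cat2         MST = 0.912  -> stochastic
  cat3         MST = 0.953  -> stochastic
```

The fitted immigration rate (0.32, CI [0.28, 0.37]) recovers the generating
value 0.3; the beta-model R² (0.94) clearly beats random metacommunity
sampling (0.69), so neutrality is accepted; and all three categories sit
well above the 0.5 MST boundary — a stochastic-dominated call, as simulated.
Rerunning with `regime="niche", sigma_sel=3.0` flips both verdicts.

The same stages are available from the shell:

```sh
assemblage simulate --seed 42 --out-dir run/ --regime neutral --m 0.3
assemblage ncm --table run/table.tsv --bootstraps 1000 --seed 0 --out-prefix run/ncm
assemblage mst --table run/table.tsv --design run/design.tsv --seed 0 --out-prefix run/mst
assemblage run-all --config run.toml     # full pipeline with a manifest
```

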