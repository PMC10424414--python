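# fmtforge

Recipient-independent prediction and design of fecal microbiota
transplantation (FMT) outcomes, from the **donor microbiome alone**.

Most FMT outcome models need the recipient's baseline microbiome, which
rules out off-the-shelf donor selection and banked transplants. `fmtforge`
implements the alternative: predict what a transplant will do to a recipient
*before* choosing the recipient, using only the donor's 16S composition
(plus donor demographics when available), and then invert the predictor to
*design* a transplant.

The toolkit covers four connected analyses:

1. **Donor-only outcome prediction.** Each donor composition is embedded as
   a *microbiome image*: a matrix whose bottom row is the preprocessed leaf
   (species) abundance vector and whose higher rows hold, for every leaf
   column, the mean abundance of that leaf's ancestor at each taxonomic
   rank. Leaves are ordered by an abundance-sorted depth-first traversal of
   the taxonomy, so related taxa form contiguous constant blocks that a
   small convolutional network can exploit. A bank of flat baselines
   (ridge, kNN, SVR, random forest, gradient boosting, dense net) consumes
   the identical design matrix for confounder-free comparison. Targets:
   post-FMT Shannon diversity H = −Σ pᵢ ln pᵢ, per-taxon relative abundance
   or presence, and binary clinical outcome.
2. **Donor-vs-background decomposition.** Distances between post-FMT
   recipients are grouped into SDSR (same donor, same recipient, across
   time), SDDR (same donor, different recipients, matched time) and DDDR
   (different donors, matched time). One-sided t-tests of
   SDSR < SDDR < DDDR quantify how much of the post-FMT microbiome the
   donor explains versus the recipient background.
3. **Donor ranking.** Candidate donors are ranked by predicted recipient
   outcome and split into predicted-high / predicted-low groups (optionally
   covariate-matched), plus per-donor clinical success fractions and a
   success-vs-failure comparison of predicted richness.
4. **Synthetic community design.** A generative genetic algorithm searches
   donor-profile space against the trained predictor with the
   sparsity-penalized fitness

   ```
   fitness_max(sᵢ, bᵢ) = sᵢ − sum(bᵢ)·γ
   ```

   where sᵢ is the predicted recipient outcome, bᵢ the binary support of
   candidate i (bᵢⱼ = 1 iff abundance > 0) and γ ≥ 0 prices each extra
   taxon in the cocktail. Each generation keeps the 30 fittest of 100
   candidates and refills by uniform crossover and toggling mutations
   (probability 0.3 each), so the best fitness never decreases.

Because real FMT cohorts cannot ship with a package, `fmtforge` includes a
first-class synthetic-cohort generator with a known donor→recipient
transfer model (tunable donor effect δ, recipient background ρ, time decay,
per-taxon engraftability, outcome labels). Every pipeline stage is tested
against it, including the four recipient regimes from germ-free mice to
untreated humans.

## Worked example

```python
from fmtforge import synth, predictor, eval_protocol, ga, similarity
from fmtforge.predictor import PredictionTask

# a cohort of 60 donors, 3 recipients each, sampled 7 days post-FMT
cfg = synth.SynthConfig(n_donors=60, recipients_per_donor=3, seed=42)
bundle = synth.generate_cohort(cfg)

# recipient-grouped cross-validation of a donor-only Shannon predictor
task = PredictionTask("shannon", horizon=7)
plan = eval_protocol.grouped_kfold(bundle, k=5, seed=0)
metrics = eval_protocol.cross_validate(task, bundle, "rf", plan, seed=0)
print(f"held-out Shannon SCC = {metrics.scc:.3f}, R2 = {metrics.r2:.3f}")

# donor effect vs recipient background
report = similarity.hierarchy_test(
    similarity.pairwise_distances(bundle, phase="post_fmt"))
c = report["SDDR<DDDR"]
print(f"SDDR < DDDR: mean {c['mean_low']:.3f} vs {c['mean_high']:.3f}, "
      f"p = {c['p']:.2e} {c['stars']}")

# design a sparse synthetic transplant against the trained predictor
model = predictor.fit(task, bundle, "imic_cnn", seed=0)
pool = ga.expand_pool(bundle.donors, 500, seed=1)
result = ga.run(ga.GAConfig(gamma=0.01, max_generations=25, seed=3), model, pool)
print(f"GA best fitness {result.best_fitness[0]:.3f} -> "
      f"{result.best_fitness[-1]:.3f} over {result.generations_run} generations")
print(f"mean elite community size: {result.mean_elite_nnz[-1]:.1f} taxa")
```

prints

```
held-out Shannon SCC = 0.907, R2 = 0.789
SDDR < DDDR: mean 0.051 vs 0.184, p = 2.22e-138 ***
GA best fitness 3.287 -> 3.404 over 25 generations
mean elite community size: 44.7 taxa
```

The cross-validated Spearman correlation of 0.91 says the donor composition
alone orders future recipient diversities almost perfectly in this
strong-donor-effect regime; the distance hierarchy (recipients of the same
donor are 3–4× closer than recipients of different donors) is the
model-free version of the same fact. The GA then finds a ~45-taxon
community predicted to induce higher recipient diversity than any donor in
its starting population, trading predicted outcome against cocktail size
through γ.

A command-line interface wraps the same operations
(`fmtforge simulate | preprocess | train | predict | evaluate | similarity |
rank-donors | ga`); run `fmtforge --help`.

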