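# crocokin

Close-kin identification and population connectivity analysis for
structured wildlife populations, built around the saltwater crocodile
(*Crocodylus porosus*) study system: a pedigree-tracked forward simulator
calibrates and validates structure-robust kinship estimation
(KING-robust → PC-AiR-style partition → PC-Relate) and kin-pair
classification on sparse SNP panels, alongside read-count quality
control for DArT-style genotyping and classical population-genetic
summaries (diversity indices, Weir-Cockerham F_ST, isolation by
distance).

## Why

Wildlife SNP panels carry a few thousand markers, not the hundreds of
thousands of human studies, and the populations are strongly structured —
both relatedness and shared ancestry inflate genetic similarity.
PC-Relate separates the two by estimating each pair's kinship coefficient
φ and IBD-sharing probabilities k(0), k(2) against individual-specific
allele frequencies predicted from ancestry principal components.  Whether
that machinery still identifies parent-offspring pairs (POP), full
siblings (FSP) and second-degree relatives (half siblings,
grandparent-grandchild, aunt/uncle-niece/nephew) at panel sizes of ~10³
SNPs is an empirical question — so the package ships a non-Wright-Fisher
forward simulator (overlapping generations, female maturity 15 y / male
16 y, Poisson clutches, migration-linked demes, survival min(1, K/N),
pedigree truth) and classifies simulated pairs three ways:

- nearest Euclidean center over the canonical (φ, k0, k2) expectations
  POP = (0.25, 0, 0), FSP = (0.25, 0.25, 0.25), 2nd° = (0.125, 0.5, 0),
  3rd° = (0.063, 0.75, 0), U = (0, 1, 0);
- the Manichaikul degree intervals φ ∈ (2^−(d+3/2), 2^−(d+1/2)) with the
  k(0) < 2^(−9/2) parent-offspring split;
- a linear-kernel SVM trained on simulated kinship statistics with
  pedigree-truth labels.

Performance is summarised per class (precision, recall, specificity) and
overall by F1_macro = 2·P_macro·R_macro/(P_macro + R_macro).

See `docs/methods.md` for the full model and estimator account.

## Worked example

Simulate two demes at carrying capacity 250 linked by 0.1% migration with
Poisson(15) clutches, estimate kinship, and score the Manichaikul
classifier against pedigree truth:

```python
import numpy as np
from crocokin import (SimConfig, run_simulation, sample_individuals,
                      enumerate_kin, kin_census, site_filter, king_robust,
                      pcair_partition, pcrelate, classify_manichaikul,
                      evaluate)

cfg = SimConfig(carrying_capacity=250, migration_rate=0.001,
                clutch_lambda=15.0, n_generations=150, pedigree_window=100,
                genome_length=100_000_000, n_founder_sites=20_000, seed=42)
pedigree, pop = run_simulation(cfg)
sample = sample_individuals(pop, int(pop.census(2).min()),
                            np.random.default_rng(42))
order = np.argsort(sample.ids)
ids, G = sample.ids[order], sample.genotypes[order].astype(float)

truth = enumerate_kin(pedigree, ids)
Gf = G[:, site_filter(G, maf_min=0.05, ld_r2=0.1, window=10)]
part = pcair_partition(Gf, king_robust(Gf), n_pcs=2)
triples = pcrelate(Gf, part.pcs, part.unrelated, ids=ids)
metrics = evaluate(classify_manichaikul(triples), truth["label"])
```

This prints (seed 42):

```
final census per deme: [244 256]
sampled 488 individuals x 8544 polymorphic sites
true kin pairs: {'POP': 428, 'FSP': 2101, 'DEG2': 10063, 'U': 106236}
sites after LD pruning + MAF filter: 1378
PC-AiR partition: 34 unrelated / 454 related
Manichaikul macro-F1 vs pedigree truth: 0.662
```

Reading: a whole-deme sample of a small clutch-breeding population is
~11% true kin pairs; after pruning to 1378 informative SNPs, the fixed
interval rule recovers three quarters of parent-offspring pairs
(recall 0.755) but with modest precision (0.543) — exactly the regime in
which the simulation-trained SVM earns its keep (cross-scenario F1_macro
≈ 0.85 versus ≈ 0.80 for the intervals and ≈ 0.77 for Euclidean
centers; see below).

The same steps are scriptable from the shell:

```bash
crocokin simulate --config sim.yaml --seed 42 --sample-n 250 --out-prefix run
crocokin truth --pedigree run.pedigree.tsv --samples run.samples.csv --out truth.tsv
crocokin kinship --genotypes run.vcf --ld-window 10 --n-pcs 2 --out kin.tsv
crocokin classify --triples kin.tsv --out classified.tsv
crocokin study --seed 1 --out study_out/          # the full scenario grid
crocokin empirical --genotypes g.csv --metadata meta.csv \
    --coastline coast.csv --svm-model study_out/svm_model.joblib --out out/
```

The `empirical` subcommand runs the field-data workflow: QC cascade →
diversity + pairwise F_ST (bootstrap p-values, FDR control) + Mantel test
of linearised F_ST against along-coast distance → PC-Relate kinship →
kin-pair report with within-region straight-line and between-region
coastal distances and the fraction of kin found within 50 km.

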