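# glunet

Functional brain-network analysis of regional glucose-uptake cohorts.

Given per-animal regional uptake ratios (regions × animals CSV) plus animal
metadata (genotype × treatment × sex), `glunet` builds group-wise
inter-regional Pearson correlation networks over a correlation-threshold
grid and runs the full downstream analysis battery:

- **uptake statistics** — factorial ANOVA (Type II, unbalanced-safe) with
  Benjamini–Hochberg-corrected post hoc pairwise t-tests;
- **network construction** — Pearson/Fisher-z matrices, inclusive signed
  thresholding, automatic grid selection (largest threshold keeping every
  group's network connected);
- **graph metrics** — mean degree, average path length, clustering;
  degree / betweenness (Brandes, unnormalized) / eigenvector (shifted power
  iteration) centrality;
- **null-model inference** — hub calling versus edge-count-matched
  Erdős–Rényi ensembles (mean z > 1.96 across the grid), permutation tests
  of group differences (pooled per-threshold null, +1-corrected two-sided
  p), and rich-club core detection versus degree-preserving rewiring nulls
  (flagged as an approximate algorithm in all outputs);
- **PLSR connectivity** — seed-region PLS1 (deterministic NIPALS), VIP with
  leave-one-animal-out jackknife 95% CIs, between-group VIP comparison with
  Bonferroni correction, and lost / gained / restored classification;
- **synthetic cohorts** — a generator with planted ground truth (hub club,
  densely interconnected block, background modules, lost edges, drug-restored
  edges, mean shifts) whose group correlation matrices are
  positive-semi-definite by construction, so every stage is testable without
  external data.

## Command line

All stages are subcommands of one CLI:

```bash
# simulate a default cohort (59 regions, 6 groups) with ground truth
glunet simulate --out cohort/ --seed 1

# per-region factorial ANOVA for the saline-vs-ketamine design
glunet metabolism --cohort cohort/ --design saline-vs-ketamine --out anova.csv

# correlation networks + adjacency stacks for the two saline groups
glunet network --cohort cohort/ --group WT,SAL --group HET,SAL \
    --t-min 0.49 --step 0.01 --out networks/

# graph metrics, hub calling, rich club
glunet metrics  --network networks/ --group WT,SAL --out metrics.csv
glunet hubs     --network networks/ --group WT,SAL --n-null 1000 --seed 2 --out hubs.csv
glunet richclub --network networks/ --group WT,SAL --n-null 1000 --seed 3 --out rc.csv

# permutation test of a global-metric group difference
glunet permute --cohort cohort/ --group-a WT,SAL --group-b HET,SAL \
    --statistic path_length --n-perm 5000 --seed 4 --out perm.json

# seed-region PLSR/VIP connectivity with lost/gained/restored labels
glunet plsr --cohort cohort/ --seed-region 17 \
    --groups WT,SAL --groups HET,SAL --groups HET,KET --out plsr/

# or run everything from one YAML config (fully seeded, bit-reproducible)
glunet run --config config.yaml
```

A minimal pipeline config:

```yaml
out_dir: results/run1
seed: 42
t_min: 0.49
t_step: 0.01
n_null: 1000        # ER graphs per threshold (11,000 over the default grid)
n_perm: 5000        # permutations per threshold (55,000 over the grid)
synthetic_spec: {}  # defaults; or set cohort_paths: {uptake: ..., metadata: ..., regions: ...}
```

Every stochastic stage derives its seed from the master seed and records it
in `run.log`; rerunning an identical config is bit-identical (timings live
only in the log).

## Input formats

- `uptake.csv` — first column `region` (abbreviations, one row per region),
  one column per animal; no missing cells (validation fails fast).
- `metadata.csv` — columns `animal_id,genotype,treatment,sex` with levels
  WT/HET, SAL/KET/AMPH, M/F.
- `regions.csv` — columns `abbreviation,name,system`; row order defines the
  region indexing used everywhere downstream. A 59-region default catalogue
  ships with the package (`glunet.default_regions()`), user-replaceable.

## Statistical conventions worth knowing

- Thresholding is signed and inclusive: an edge exists iff r ≥ T; negative
  correlations never create edges (an `--absolute` analysis is out of scope).
- Betweenness is unnormalized; eigenvector centrality is scaled to max 1.
- Hub rule: across-threshold mean z versus pooled G(n, m) node ensembles,
  z > 1.96.
- Permutation p-values use the +1 correction and are two-sided.
- VIP group comparisons default to a Welch t-test directly on the jackknife
  replicates. This matches the operating characteristics of published VIP
  comparisons at n = 8–13 but understates variance; the conservative,
  properly scaled pseudo-value test is available (`method="pseudo"`) and is
  deliberately used for the equivalence clause of the restoration rule. See
  the `compare_vip` docstring before interpreting p-values.
- The rich-club core detector is an approximate stand-in (φ(k) against
  degree-preserving rewiring nulls) and marks its outputs as such.
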