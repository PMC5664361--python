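# phyloprof

A tested, reusable pipeline for assessing whether binary phylogenetic
profiles carry metabolic-pathway information:

* **gene families** — connected components of an identity-thresholded
  pairwise homology network (families + singletons = "gene objects"),
  evaluated against EC-based function labels with the adjusted Rand index;
* **profiles** — per-object presence/absence bit vectors over a fixed
  species order, identical-profile grouping, and complete-linkage /
  Euclidean species clustering emitted as Newick;
* **pathway annotation** — two-level (class → map) hierarchy handling,
  primary/secondary metabolism classification (primary wins on conflict),
  presence and gene-count surveys;
* **enrichment** — the core statistic: within-pathway identical-profile
  fraction `F_pw`, background fraction `F_all` (within pairs plus
  pathway-vs-outside cross pairs), enrichment `E = F_pw / F_all`, empirical
  p-values from uniform redraws of gene objects (default 10,000 draws),
  Benjamini–Hochberg correction;
* **similarity** — pairwise profile Jaccard similarity `d_PP`, pathway-set
  overlap agreement `A_PW`, random object-pair sampling (default 100,000
  pairs) and a multi-start logistic fit of `A_PW = f(d_PP)`;
* **prediction** — a bagged multi-label decision-tree ensemble (50 trees)
  over profile bits with hierarchy-consistent scores, out-of-bag AUCPRC,
  and comparison against occurrence-preserving label shuffles (Wilcoxon
  rank-sum);
* **assoc** — expression preprocessing (log + quantile normalization +
  10% sample subsampling), profile-similarity vs co-expression statistics,
  and interacting vs non-interacting protein-pair `d_PP` comparison;
* **simulate** — a seeded generator of complete synthetic input bundles
  with planted, tunable signal (pathway coherence, profile flip noise,
  expression blocks, logistic PPI selection) plus a ground-truth record.

All interchange formats are plain TSV with headers (`;` separates in-cell
lists); see `src/phyloprof/core_io.py` for the exact schemas.

## CLI

Every stage is a subcommand of `phyloprof`; multi-stage commands read a
YAML `RunConfig` (defaults: 30% identity, 10,000 draws, 100,000 pairs,
50 trees, 100 class / 20 map shuffles).

```bash
# synthetic bundle with planted signal
phyloprof simulate --seed 7 --out data/

# individual stages
phyloprof families --homology data/homology.tsv --annotation data/annotation.tsv \
    --species data/species.tsv --min-identity 30 --out families.tsv
phyloprof enrich --config run.yaml --level map --draws 10000 --seed 17
phyloprof pairsim --config run.yaml --n 100000 --seed 7
phyloprof predict --config run.yaml --trees 50 --seed 3
phyloprof assoc --config run.yaml

# everything, with a reproducibility manifest (per-stage seeds + checksums)
phyloprof run-all --config run.yaml
```

Minimal `run.yaml`:

```yaml
species_path: data/species.tsv
annotation_path: data/annotation.tsv
homology_path: data/homology.tsv
expression_path: data/expression.tsv   # optional; stage skipped if absent
ppi_path: data/ppi.tsv                 # optional
out_dir: out/
seed: 17
secondary_classes: [C3]                # classes treated as secondary metabolism
```

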