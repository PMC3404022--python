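# yphylo

Haplogroup subclade discovery from haploid, low-coverage variant calls.

Given a VCF of haploid Y-chromosome genotype calls, `yphylo` screens samples
into cases and controls by an anchor SNP, pushes every candidate variant
through a four-stage filter cascade, collapses the survivors into
phylogenetically equivalent marker blocks, builds the rooted perfect
phylogeny of subclades, reconciles it against a scaffold of known markers
(keeping the data-derived placement when the two disagree), and places each
sample at its most derived node. A synthetic low-coverage call simulator
with complete ground truth makes every stage testable without any external
download.

## The filter cascade

| Stage | Rule | Failure label |
|---|---|---|
| F1 | every *observed* control call must be ancestral | `FAIL_CONTROL_DERIVED` |
| F2 | at least two case samples with observed derived calls | `FAIL_SINGLETON` |
| F3 | no more than `--max-ambiguous` heterozygous-looking calls (default 0) | `FAIL_AMBIGUOUS` |
| F4 | pairwise rooted compatibility (three-pattern test on jointly observed samples); greedy removal of max-conflict variants | `FAIL_INCONSISTENT` |

Outcomes use first-fail attribution and always partition the candidate set.
MISSING and AMBIGUOUS calls are never treated as evidence.

## CLI

```bash
# generate a synthetic fixture set (VCF, sample metadata, known-variant
# list, scaffold, ground truth) from a YAML config or defaults
yphylo simulate --out fixtures/ --seed 7

# screening + filter cascade only
yphylo filter --vcf fixtures/calls.vcf --anchor A1 \
    --samples fixtures/samples.tsv --known fixtures/known_variants.tsv \
    --max-ambiguous 0 --out results/

# full tree build with scaffold reconciliation
yphylo build --vcf fixtures/calls.vcf --anchor A1 \
    --scaffold fixtures/scaffold.tsv --out results/

# everything from a flat YAML config
yphylo run --config pipeline.yaml --out results/

# print the clade summary of a finished run
yphylo report --pipeline-out results/
```

A run writes eight outputs (`screen.tsv`, `variant_table.tsv`,
`conflict_graph.tsv`, `blocks.tsv`, `tree.nwk`, `reconciliation.tsv`,
`placements.tsv`, `summary.tsv`) plus `run.log` and
`pipeline_manifest.json`. All non-log outputs are byte-deterministic for
fixed inputs.

## Library use

```python
from yphylo import SimConfig, simulate_dataset, screen_samples, run_filters
from yphylo.tree import equivalence_blocks, build_tree, place_samples

config = SimConfig(per_read_error=0.0, missing_rate=0.0, mean_coverage=50.0)
matrix, truth = simulate_dataset(config)
screen = screen_samples(matrix, config.anchor_name)
report = run_filters(matrix, screen)
retained = [v for v in matrix.variants if v.key in report.retained_keys]
blocks = equivalence_blocks(matrix, retained, sorted(screen.cases))
tree = build_tree(blocks, sorted(screen.cases))
placements = place_samples(tree, matrix)
```
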