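# cosegscan

Pedigree-aware co-segregation scanning for family exome studies: a
reusable implementation of the classic autosomal-dominant rare-variant
discovery workflow — per-sample variant calls are reduced through a shared-
candidate scan (carried by every affected sequenced relative, absent from
every unaffected one), a rarity/consequence/brain-expression filter
cascade, orthogonal validation-genotype override, and a per-variant
co-segregation verdict on the full pedigree.  A gene-dropping simulator
generates pedigrees, genotypes and annotations with the statistical
structure the analysis assumes, so every stage is testable without any
external data.

## Layout

| module | role |
|---|---|
| `cosegscan.pedigree_io` | PED-dialect parsing (with codes for uncertain/untested phenotypes), validation, phenotype partitions |
| `cosegscan.variant_io` | VCF/TSV ingestion into a genotype table, multi-allelic splitting, deterministic VCF/report output |
| `cosegscan.candidate_scan` | adjacent-SNV → MNV merging, read-support thresholding, shared-candidate scan |
| `cosegscan.annotation_filters` | cohort-database, population-MAF, consequence and brain-expression filters |
| `cosegscan.segregation` | validation-genotype override, transmission-lineage confirmation, co-segregation verdicts |
| `cosegscan.synthetic_data` | gene-dropping simulator, penetrance/phenocopy model, background-variation generator, packaged worked-example fixture |
| `cosegscan.pipeline` / `cosegscan.cli` | config-driven orchestration, stage trace, recovery experiment, CLI |

## CLI

```sh
# emit the packaged worked-example dataset (pedigree, per-sample VCFs,
# annotations, validation genotypes, whitelist, ready-to-run config)
cosegscan fixture -o example/

# run the full cascade; writes surviving-variant VCF, a per-variant report
# with terminal reason codes, and the stage trace
cosegscan run -c example/config.yaml

# simulate a synthetic family exome dataset
cosegscan simulate --seed 7 -o simulated/

# recovery experiment: how often does the implanted causal variant
# survive the whole cascade?
cosegscan recover --seed 7 --reps 50 -o recovery.tsv
```

The worked example reproduces the expected outcome exactly: of five
validated candidates, one co-segregates (`3:134264558 GA>TT`, a two-base
substitution assembled by the MNV merge step), one is monomorphic on
re-sequencing, one fails ancestral-transmission confirmation for the
exception individual, and two are carried by unaffected relatives.

Pipeline configs are YAML with strict schema checking (unknown keys or
stage names fail before any computation); see `example/config.yaml` after
running `cosegscan fixture`.  Exit codes: 0 success, 1 user error, 2
internal error.  All outputs are deterministic — identical config and
inputs give byte-identical reports, and the simulator is byte-reproducible
from its seed.

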