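# aviqtl

QTL and eQTL mapping toolkit for advanced intercross lines (AILs), built
around the analysis design of a wild x domestic chicken bone study:

- **Cross I/O** — R/qtl-style rotated-header cross CSV, expression matrix +
  probe annotation tables, interval tables, BED export.
- **Genotype probabilities** — three-state HMM (Haldane map function, F2
  transition model) over markers and pseudomarkers, with optional
  genotyping-error emissions and map expansion for AIL data.
- **Phenotype QTL scans** — single- and two-locus Haley-Knott regression
  with covariates (sex, batch, body weight, egg production, genotype PCs),
  block-permutation significance thresholds, forward-selected multi-QTL
  models with epistatic pairs, and 1.8-LOD-drop support intervals expanded
  to flanking markers.
- **eQTL mapping** — local (cis) scans inside a 100 cM window around each
  probe (expanded to flanking markers spanning at least 50 cM per side) and
  genome-wide trans scans, with a dual permutation threshold that resamples
  individual identities and subsamples probesets.
- **Candidate genes** — QTL/eQTL support-interval overlap followed by a
  trait~expression association test, Bonferroni-corrected by the number of
  uncorrelated cis-eQTL in the interval (connected components of the
  correlation-link graph).
- **Trans-eQTL hotspots** — exact sweep-line coverage of eQTL intervals and
  an empirical null that places the observed interval lengths uniformly on
  a concatenated genome axis; regions above the 95th-percentile maximum
  coverage are called clusters.
- **Synthetic data** — a seeded advanced-intercross simulator (founder
  lines fixed for alternate alleles, Haldane meioses, random mating) with
  additive/dominance/epistatic trait effects, cis/trans/hotspot expression
  effects, expression-mediated trait effects, covariates and missing-data
  injection, plus a ground-truth sidecar for parameter-recovery tests.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: oracle
identities, statistical calibration, parameter recovery, and the
recomputation of the published interval-calculus counts from the study's
supplementary tables. The last test requires those tables (journal
supplements, not redistributable here) converted to TSV under
`data/supplementary/` — see its docstring for the layout — and fails until
they are supplied.

## CLI

```sh
aviqtl simulate --config sim.json --out demo --seed 1
aviqtl scanone  --cross demo_cross.csv --trait trait1 \
                --covariates sex,batch,body_weight --out scan.tsv
aviqtl permtest --cross demo_cross.csv --trait trait1 --n-perm 1000 --seed 1
aviqtl scantwo  --cross demo_cross.csv --trait trait1 --out pairs.tsv
aviqtl mqm      --cross demo_cross.csv --trait trait1 --threshold 3.8 --out model.json
aviqtl eqtl     --cross demo_cross.csv --expr demo_expression.tsv \
                --annot demo_annotation.tsv --out eqtl.tsv
aviqtl candidates --qtl qtl.tsv --eqtl eqtl.tsv --cross demo_cross.csv \
                  --expr demo_expression.tsv --out candidates.tsv
aviqtl hotspots --eqtl eqtl.tsv --genome chrom.sizes --n-iter 1000 --seed 1 --out hs.tsv
aviqtl run      --config run.json          # full pipeline, per-stage outputs
```

`run.json` / `sim.json` are plain JSON files whose keys mirror the
`RunConfig` / `SimConfig` dataclass fields.

## Library sketch

```python
from aviqtl import (SimConfig, simulate_dataset, calc_genoprob, scanone,
                    permutation_threshold, lod_support_interval)

cross, expr, truth = simulate_dataset(SimConfig(seed=1))
probs = calc_genoprob(cross, step_cM=1.0)
thr = permutation_threshold(probs, cross, "trait1",
                            ["sex", "batch", "body_weight"],
                            n_perm=1000, seed=1)
scan = scanone(probs, cross, "trait1", ["sex", "batch", "body_weight"])
interval = lod_support_interval(scan, cross.gmap, drop=1.8)
```
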