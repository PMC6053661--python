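# slamitseq

Cell-type-specific transcriptome quantification from SLAM-ITseq-style
metabolic RNA labelling, read out by 3′-end sequencing.

## Background

In a SLAM-ITseq experiment, the uracil analogue 4-thiouracil (4TU) is
supplied to an animal in which the *Toxoplasma gondii* enzyme UPRT is
expressed only in a Cre-defined cell type. Only cells expressing UPRT
salvage 4TU into nascent RNA, so newly transcribed RNA of that cell type —
and only that cell type — carries 4-thiouridine. Alkylation chemistry then
makes reverse transcriptase read each labelled uridine as a cytosine, so
labelling appears in sequencing reads as T>C mismatches against the
reference. Cre⁻ littermates receive 4TU identically but express no UPRT;
they measure the background conversion rate (sequencing error, SNPs,
spontaneous conversion).

This package implements the computational half of that assay:

1. **Conversion quantification** (`slamitseq.quant`) — stream 3′-end
   alignments (SAM/BAM), count, per gene, the number of sequenced
   reference-T observations in the gene's 3′UTR counting window
   (*T coverage*) and how many were read as C (*T>C count*). Positions are
   filtered by a 5′ read-end trim, a base-quality floor, a multimapper cap,
   and a pooled-pileup SNP mask that removes germline T>C variants (which
   convert in every animal of both genotypes, unlike labelling).
2. **Labelling statistics** (`slamitseq.stats`) — per gene, a beta-binomial
   likelihood-ratio test of the Cre⁺ replicates (n=4) against the Cre⁻
   replicates (n=3), capturing animal-to-animal overdispersion; genes are
   called labelled at Benjamini–Hochberg FDR < 0.05 when the Cre⁺
   conversion mean exceeds the Cre⁻ mean.
3. **Synthetic experiments** (`slamitseq.simulate`) — a first-class,
   ground-truthed generator: per-gene contigs with 3′UTR windows, two-level
   Bernoulli chemistry (a molecule is labelled with the group's labelled
   fraction *f*; each sense-strand T of a labelled molecule converts with
   probability *c*; every base can additionally be miscalled), homozygous
   genomic SNPs, and pre-aligned SAM output with a per-gene × sample truth
   table.
4. **Reporting** (`slamitseq.report`) — end-to-end pipeline orchestration
   with a reproducibility manifest, marker-panel sensitivity, labelled
   proportion by window T content, overlap with FACS-derived expression
   sets, and pseudo-counted plotting tables.

## Worked example

Simulate a 40-gene experiment in which 8 genes are labelled only in the
Cre⁺ animals, then run the whole pipeline:

```python
import pandas as pd
from slamitseq.report import run_pipeline

config = {
    "simulate": {
        "seed": 11,
        "n_genes": 40,
        "n_labelled": 8,          # genes labelled only in Cre+ animals
        "labelled_fraction_pos": 0.2,
        "conversion_rate": 0.025,
        "error_rate": 0.001,
        "snp_fraction": 0.1,
        "expression": 150.0,
    },
    "fdr": 0.05,
}
manifest = run_pipeline(config, "demo_run")
print(f"{manifest['genes']['labelled']} of {manifest['genes']['tested']} genes "
      f"called labelled; {manifest['n_snp_masked_sites']} SNP sites masked")

results = pd.read_csv("demo_run/results.tsv", sep="\t")
print(results.head(5).to_string(index=False))
```

Output:

```text
8 of 40 genes called labelled; 5 SNP sites masked
  gene   mu_pos   mu_neg  rho_hat  statistic      p_value  converged      q_value  direction  labelled
gene23 0.006629 0.000550      0.0  48.767927 2.881130e-12       True 1.152452e-10          1      True
gene02 0.007389 0.001025      0.0  45.650781 1.413297e-11       True 1.905085e-10          1      True
gene38 0.006971 0.000611      0.0  45.629392 1.428814e-11       True 1.905085e-10          1      True
gene18 0.006329 0.001206      0.0  41.792249 1.015050e-10       True 1.015050e-09          1      True
gene19 0.005300 0.001002      0.0  28.056273 1.178385e-07       True 9.427082e-07          1      True
```

All 8 truly labelled genes are recovered (the simulated effect — labelled
fraction 0.2 × conversion rate 0.025 ≈ a 6× rise over the 0.001 background
— is strong at this coverage), with the expected Cre⁺ > Cre⁻ direction,
and every simulated SNP site is masked rather than mistaken for labelling.

## Command-line interface

The same stages are exposed as the `slamit` CLI:

```sh
slamit simulate --config sim.yaml --out experiment/       # ground-truthed reads
slamit count --ref ref.fa --bed utr.bed --sam s1.sam --sam s2.sam ... --out counts.tsv
slamit test --counts counts.tsv --sheet samples.tsv --out results.tsv
slamit run --config run.yaml --out run/                   # everything at once
slamit report --results results.tsv --panel markers.txt \
              --fpkm fpkm.tsv --fpkm-target endothelial --out-dir report/
```

`slamit run` writes `counts.tsv`, `results.tsv`, a p-value-ranked gene
list for enrichment tools, a plotting table (group-mean T>C fractions with
a 1×10⁻⁵ display pseudo-count), a zero-coverage filter report and a
`manifest.json` recording every parameter, seed and per-stage read/gene
count; rerunning a config reproduces all outputs byte-for-byte.

## Testing

```sh
python -m pytest -q tests/
```

The suite contains unit, property and oracle tests (independent
re-implementations of the counting rules and of the binomial-limit
likelihood-ratio test) plus an acceptance suite, `tests/test_acceptance.py`.
Two acceptance clauses are mathematically unattainable under their own
stated conditions and are deliberately left failing rather than weakened;
the analysis is in that module's docstring and in `docs/methods.md`.

## Layout

```
src/slamitseq/     the package: simulate, quant, stats, report, cli
analysis/          numbered narrative drivers writing results/
scripts/           acceptance entry point
tests/             pytest suite (unit, property, oracle, acceptance)
docs/methods.md    models, estimation, numerical choices, limitations
```
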