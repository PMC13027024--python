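# rnaedit

Rapid quantification of ADAR-mediated A-to-I RNA editing from RNA-seq
alignments using a curated 24-site hotspot panel, plus the downstream
analysis layer that links the editing index to molecular features:
pathway activation levels, expression-based MSI / TMB / retroelement
scores, and a correlation–intersection–permutation association framework.

## What it computes

* **Weighted editing index** — pooled edited reads over pooled (ref+edited)
  reads across the panel, as a percentage. Coverage-weighted by design.
* **Mean editing index** — arithmetic mean of per-site editing percentages
  over sites with more than 5 informative reads.
* Counting uses bam-readcount-style filters (MAPQ ≥ 20, base quality ≥ 20,
  primary non-duplicate alignments only) and orients counts per site:
  A>G on the plus strand for plus-strand genes, T>C for minus-strand genes.
* Panel sites with a germline A/G (T/C) polymorphism in a matched VCF are
  excluded so DNA variants are not mistaken for editing.
* **PAL** — pathway activation level: activator/repressor-weighted mean of
  log10 case-to-normal expression ratios over a pathway's genes.
* **Instability scores** — MMR-deficiency and hypermutator composites with a
  configurable linear MSI classifier, TMB (mutations/Mb), and the
  L1Hs/L1PA2/TERT/APOBEC3B insertional signature.
* **Associations** — Spearman correlations with BH adjustment, significant
  positive/negative sets, multi-group intersections, and a size-preserving
  permutation test for intersection significance.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (panel fidelity,
metric hand-arithmetic and per-read oracle equivalence, binomial parameter
recovery, germline-exclusion exactness, PAL identities, BH/permutation
calibration, Fisher-z averaging).

## CLI

```sh
# editing indices from BAMs or a precomputed count table
rnaedit score --bam sample.bam --vcf matched_wes.vcf --out-dir results/
rnaedit score --counts-table counts.tsv --out-dir results/

# pathway activation levels
rnaedit pal --expr expression.tsv --pathways pathways.tsv \
    --groups metadata.tsv --out pal.tsv

# MSI / TMB / insertional signature (coefficients and boundary are
# mandatory user configuration — there are no built-in defaults)
rnaedit instability --expr expression.tsv --coefficients coeffs.tsv \
    --boundary boundary.yaml --variant-counts variants.tsv \
    --exome-mb 30 --out instability.tsv

# associations of the editing score with a feature matrix, then
# cross-group intersection with a permutation test
rnaedit correlate --scores scores.tsv --features expression.tsv \
    --label coad_experimental --out assoc_coad.tsv
rnaedit intersect --associations assoc_coad.tsv --associations assoc_luad.tsv \
    --n-perm 1000 --seed 1 --out intersection.json

# synthetic fixture bundle (counts, toy BAM, VCF, expression, truth tables)
rnaedit simulate --seed 1 --out-dir fixtures/
```

The default panel (24 GRCh38 exonic hotspot sites in 20 genes) ships with
the package; pass `--panel` to substitute your own TSV
(`gene  chrom  pos  ref_base_plus  label`).

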