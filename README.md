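# netpres

Cross-species weighted gene coexpression analysis as a tested, reusable
pipeline: build a coexpression network in a reference species, cut it into
modules, project the module memberships into a test species, score module
preservation by kME sign consistency with a permutation null, and scan SNP
dosages for cis/trans expression effects with a target-set trans-enrichment
test. A synthetic paired-species generator makes every stage testable
without any external data.

## Stages

| module | what it does |
| --- | --- |
| `netpres.synthetic_data` | paired two-species studies with planted modules, probe redundancy, outlier samples, covariates, and cis/trans dosage effects |
| `netpres.preprocess` | probe → gene collapse (max mean probe), ortholog harmonization, Euclidean-distance outlier-sample removal |
| `netpres.network` | biweight midcorrelation, soft-threshold power selection against scale-free topology, topological overlap, average-linkage clustering with dynamic hybrid tree cut, eigengene-based module merging |
| `netpres.module_summary` | module eigengenes (first principal component), variance explained, gene × module kME |
| `netpres.preservation` | consistent-gene fraction, joint-permutation p-values (default 10,000 iterations), composite Z-summary / median-rank statistics |
| `netpres.eqtl` | SNP QC (MAF / call rate / HWE / imputation r²), vectorized OLS dosage scan with covariates, 1-Mb cis/trans classification, conditional scan, Fisher trans-set enrichment |
| `netpres.enrichment` | hypergeometric gene-set over-representation with BH FDR (GMT input) |
| `netpres.fixtures` | packaged reference-table transcriptions plus exact summary operations |

## CLI

```sh
netpres simulate --seed 1 --out data/            # write synthetic inputs
netpres preprocess --in data/ --out pre/
netpres network --expression pre/ref_expression.tsv --out net/ --power 5
netpres summarize --expression pre/ref_expression.tsv --modules net/modules.tsv --out sum/
netpres preserve --ref-expression pre/ref_expression.tsv \
    --test-expression pre/test_expression.tsv \
    --modules net/modules.tsv --out preservation.tsv
netpres eqtl --expression pre/ref_expression.tsv --dosages data/dosages.tsv \
    --covariates data/covariates.tsv --snp-positions data/snp_positions.tsv \
    --gene-positions data/gene_positions.tsv --out eqtl.tsv
netpres run --seed 7 --out run/                  # full workflow in one step
netpres fixtures --table table1 --column Size --stat sum
```

`netpres run` accepts a JSON config (`--config`) and `--set key=value`
overrides; defaults are in `netpres.pipeline.DEFAULT_CONFIG`. All inputs and
outputs are plain TSV/JSON (GMT for gene sets, optional VCF with a `DS`
field for dosages).

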