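# scontact

Single-cell Hi-C contact analysis: extrachromosomal DNA (ecDNA)
detection, trans-contact statistics, multi-way chromatin hubs and
chromatin-based cell annotation.

## The problem

Droplet-based single-cell Hi-C assays yield barcoded chromatin contact
pairs for thousands of cells at once. In cancer samples they expose a
question bulk Hi-C cannot answer per cell: does a focally amplified
oncogene locus live on **ecDNA** — circular, highly amplified elements
dispersed through the nucleus — or in a chromosomal **homogeneously
staining region (HSR)**, a tandem amplification pinned to one place?
The two have identical copy number but opposite spatial behaviour:
ecDNA contacts all chromosomes roughly evenly, while an HSR's trans
contacts concentrate near its integration site.

`scontact` implements the computational core of this analysis for users
of barcoded (4DN-pairs-style) single-cell contact data: per-cell
metrics, two ecDNA/HSR callers, significance tests for ecDNA trans
partners, amplicon boundary refinement, multi-way hub calling, domain
boundary variability tests, and chromatin-based cell annotation — all
exercisable end to end on seeded synthetic cohorts.

## The statistics at the core

For a 1 Mb query bin *i* in one cell:

* **Hub index** — the Gini coefficient of the bin's trans contacts
  aggregated per chromosome (own chromosome and chrY excluded, zero
  chromosomes included):
  `G = Σᵢⱼ |xᵢ − xⱼ| / (2 n² x̄)`.
  Evenly dispersed trans contacts (ecDNA) give G near 0; concentration
  on few chromosomes (HSR) pushes G toward 1.
* **Trans-to-cis contacting-bin ratio** — `Rᵢ = N_T / N_C`, distinct
  trans partner bins over distinct cis partner bins; a trans-tendency
  measure that copy number does not confound.
* **Inferred copy number** — `CN = 2 × (coverage / median coverage)`
  from per-bin anchor coverage under a diploid assumption.

Callers: a multivariate **logistic regression** on the triplet
(CN, G, Rᵢ), and a small **convolutional network** over the binarized
5 Mb neighbourhood of each bin (a 5 × B matrix of cis + trans contacts;
two conv–batchnorm–ReLU–maxpool modules of 8 and 16 channels with 45-
wide kernels, dense layers of 223 and 64 units, 3-way softmax:
none / ecDNA / HSR), trained with AdamW and a hard bootstrapped
cross-entropy (β = 0.99) with class weights biased toward the negative
class. The network is implemented in pure numpy with hand-derived
gradients, so training is deterministic per seed and dependency-free.

Significant trans partners of an ecDNA locus are found per chromosome
with a copy-number-weighted binomial test: interval *i* with `Nᵢ` locus
contacts is tested against `X ~ Binomial(Σ N_g, Eᵢ)` where
`Eᵢ = CNᵢ / Σ CN_g`, Bonferroni-corrected genome-wide. Multi-way hubs
are 10 kb bins whose per-cell-type multi-way participation frequency
exceeds the background by z > 1.96. Cell annotation transfers labels
from a co-embedded RNA reference through standardized inverse-distance
k-NN scores, and glioma cellular states (OPC/NPC/AC/MES) are scored as
signature-minus-matched-control expression means projected onto a
(D, identity) plane.

## Worked example

Simulate a matched cohort — 100 cells each carrying a 20-copy ecDNA, a
20-copy HSR at the same locus, or plain diploid background — then
compute the feature triplet and run both callers:

```python
import scontact as sc
from scontact.callers import assemble_training_dataset, ConvolutionalEcDNACaller

spec = sc.ecdna_vs_hsr_spec(n_cells=100, depth=5000, seed=0)
pairs, truth = sc.simulate_cells(spec)
cells = sc.bin_contacts(pairs, spec.genome, 1_000_000)

genome = spec.genome
locus = genome.bins_in_region("chr1", 10_000_000, 11_000_000, 1_000_000)
cnv = {bc: sc.infer_cnv(cells.anchor_coverage(bc), genome, 1_000_000)
       for bc in cells.barcodes}
feats = sc.build_feature_table(cells, cnv, bins=locus)
feats["mode"] = feats["barcode"].map(
    truth.drop_duplicates("barcode").set_index("barcode")["mode"])
print(feats.groupby("mode")[["inferred_copy", "hub_index",
                             "trans_cis_ratio"]].median().round(3))

y = (feats["mode"] == "ecDNA").astype(int)
model, metrics = sc.fit_lr(feats, y, seed=0)
print({k: round(v, 3) for k, v in metrics.items()})

ds = assemble_training_dataset(cells, truth, locus)
cnn = ConvolutionalEcDNACaller(seed=0).fit(ds)
print("CNN ternary validation accuracy:",
      round(cnn.validation_report_["ternary_accuracy"], 3))
```

Output:

```
       inferred_copy  hub_index  trans_cis_ratio
mode
HSR           17.898      0.389            1.426
ecDNA         17.420      0.126            2.778
none           1.972      0.222            0.526
{'sensitivity': 1.0, 'specificity': 1.0, 'precision': 1.0, 'accuracy': 1.0}
CNN ternary validation accuracy: 1.0
```

Reading the table: both amplified populations recover an inferred copy
near the planted 20 while the background stays diploid (~2); at matched
copy the ecDNA population has the *lower* hub index (trans contacts
spread evenly) and the *higher* trans-to-cis bin ratio — exactly the
contrast the callers exploit. The held-out logistic metrics and the CNN
validation accuracy show both callers separate the classes on this
cohort.

The same pipeline is available from the shell:

```sh
scontact simulate --n-cells 100 --depth 5000 --seed 0 --out sim/
scontact qc --pairs sim/contacts.pairs.gz --genome sim/chrom.sizes --out qc.tsv
scontact features --pairs sim/contacts.pairs.gz --genome sim/chrom.sizes \
    --bins chr1:10000000-11000000 --out features.tsv
scontact train-cnn --pairs sim/contacts.pairs.gz --genome sim/chrom.sizes \
    --truth sim/truth.tsv --locus chr1:10000000-11000000 --out model.npz
scontact call-ecdna --model-file model.npz --pairs sim/contacts.pairs.gz \
    --genome sim/chrom.sizes --out calls
```

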