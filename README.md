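# rzscreen

Analysis pipeline for plate-based transcriptomic drug screens of the
L1000/Connectivity-Map lineage, built for screens that compare drug
responses across cell contexts — e.g. patient-derived neural progenitor
cells (NPCs from schizophrenia cases and controls) against cancer cell
lines (CCLs) — and ask which drugs *reverse* a disease expression
signature.

## Who this is for

Computational biologists running (or re-analysing) perturbational
expression screens in which every treated well sits on a plate next to
cell-matched vehicle (DMSO) wells. The package turns such a screen into
per-(drug, cell line) signatures and runs the downstream battery:
differential-expression accounting between cell groups, gene-set
enrichment, connectivity-based reversal screening, chemogenomic
(drug-annotation) enrichment, and RNA-motif/variant enrichment. A
synthetic-screen generator with planted ground truth makes every stage
testable without any external download.

## The statistics at the core

**Robust Z-score (RZS).** For gene *g* in a treated well, against the
vehicle wells of the same plate and cell line:

```
RZS_g = (treated_g − median(vehicle_g)) / MAD(vehicle_g)
```

with MAD the raw median absolute deviation (no 1.4826 constant; a flag
enables it). Because the vehicle statistics are plate-matched, additive
plate/batch offsets cancel exactly. Replicate plates collapse to the
per-gene median, giving one signature per (drug, cell line).

**DE and differential DE.** A drug–gene pair is differentially expressed
(DE) within a cell group when |median RZS| ≥ 2 across the group's lines;
differentially DE between two groups when the group medians differ by
≥ 2 in absolute value. Group responsiveness is compared with a
Cochran–Mantel–Haenszel test stratified by drug–gene pair.

**Set enrichment.** Per drug and gene set, cell lines are summarised to
their mean RZS over the set's (background-restricted) genes and the two
groups compared by Welch *t* (two-sided, BH-FDR per set family).

**Connectivity.** Genes are ranked by RZS; the disease signature's up-
and down-regulated tag sets are scored by the signed extremum of the
two-sample KS running sum; the connectivity score is
(es_up − es_down)/2 when the tails disagree, else 0, and lies in
[−1, 1]. A drug "reverses" the disease signature when its score is
negative at permutation FDR < 0.1 (random tag sets of matching sizes).

**Chemogenomics and motifs.** One-sided Fisher exact tests over
class-specific drug backgrounds (a feature's background is the screened
drugs carrying any annotation of that class), and degenerate IUPAC
RNA-motif scanning (e.g. the FMRP-binding pattern ACUK, K = G/U) with
per-kb density *t*-tests and variant-in-motif cohort enrichment.

## Worked example

```python
import rzscreen as rz

cfg = rz.ScreenConfig.scaled_down(seed=42)   # 20 drugs, 500 genes, 8 lines
screen, truth = rz.simulate_screen(cfg)
tensor = rz.build_signature_tensor(screen)

de = rz.call_de(tensor, "NPC_control")
counts, summary = rz.gene_drug_counts(de)
print(int(de["is_de"].sum()), summary)

disease = rz.DiseaseSignature(frozenset(truth.disease_up),
                              frozenset(truth.disease_down))
mat = rz.build_connectivity_matrix(tensor, disease, aggregate="by_group")
rev = rz.reversal_screen(mat, disease, n_genes=len(tensor.genes),
                         n_permutations=1000, seed=43)
print(sorted(rev[rev["reversing"]]["drug"].unique()))
```

prints

```
482 {'n_perturbed_genes': 280, 'mean_drugs_per_gene': 1.7178571428571427}
['DRUG_009', 'DRUG_016']
```

meaning: 482 of the 20 × 500 drug–gene pairs cross the DE threshold in
control NPC lines, 280 distinct genes are perturbed by 1.72 drugs on
average, and the reversal screen flags exactly the two drugs the
generator planted as signature reversers (`truth.reverser_drugs`),
each with connectivity score −1.0 at q ≈ 0.01.

The same flow is available from the shell:

```sh
rzscreen simulate --seed 42 --outdir out/
rzscreen signatures --gct out/expression.gct \
    --annotation out/annotation.tsv --out out/signatures.gct
rzscreen run --config pipeline.yaml     # all seven stages + manifest
```

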