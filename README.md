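# barcodegap

Analysis toolkit for COI DNA barcoding of insect communities: distance-based
species identification with the Kimura two-parameter (K2P) model,
neighbor-joining trees with bootstrap supports, per-codon-position
composition, numt/pseudogene quality control and barcoding-gap species
delimitation — plus a synthetic community generator with programmed ground
truth so every stage is testable without sequence downloads.

## Who this is for

Molecular taxonomists and vector-surveillance groups building barcode
reference libraries from ~650 bp COI fragments (e.g. mosquito surveys),
who need to (i) verify that sequences cluster by species, (ii) delimit
species with distance thresholds, (iii) screen out nuclear mitochondrial
pseudogene copies (numts) before they contaminate the library, and (iv)
flag cryptic-species and synonymy candidates for taxonomic follow-up.

## The model

For an aligned sequence pair, let L be the number of columns where both
members carry an unambiguous A/C/G/T (pairwise deletion), P the proportion
of transition differences (A↔G, C↔T) and Q the proportion of transversions.
The K2P distance and its components are

    d   = -1/2 ln[(1 - 2P - Q) √(1 - 2Q)]
    d_s = -1/2 ln(1 - 2P - Q) + 1/4 ln(1 - 2Q)     (transition distance)
    d_v = -1/2 ln(1 - 2Q)                           (transversion distance)

with d = d_s + d_v exactly. Saturated pairs (either log argument ≤ 0) are
flagged undefined, never raised, so community-scale pooling proceeds with
an audit count.

Delimitation uses two thresholds: conspecific total K2P divergence is
expected below θ = 2%, and transversion divergence below θ_tv = 1.1%.
Species whose maximum within-species distance exceeds the thresholds are
cryptic-species candidates; species pairs whose mean distance falls below
them are synonymy candidates (low transversion divergence marks
plesiomorphic pairs). Pseudogene screening relies on COI being intact
coding sequence under the invertebrate mitochondrial code (translation
table 5): any internal stop codon or indel is disqualifying, and a
codon-position substitution spectrum that departs from the functional
~5:1:18 profile (positions 1:2:3) is flagged "suspect" by an exact
multinomial test.

## Worked example

The numbered scripts under `analysis/` run the full study on simulated
communities and write their tables under `results/`:

```sh
python analysis/01_simulate_community.py
python analysis/02_distances_composition.py
python analysis/03_nj_tree_bootstrap.py
python analysis/04_pseudogene_qc.py
python analysis/05_barcoding_gap.py
```

Output (seed 42):

```
community: 80 sequences, 651 bp, 20 species, 5 genera
survey: 404 sequences with 3 injected numts (1 insertion, 1 deletion, 1 internal stop)
K2P pools: conspecific 0.0000-0.0140 (mean 0.0052), congeneric 0.0509-0.1037,
           intergeneric 0.1125-0.2015
R-value (mean ts/tv over 3144 pairs, 16 zero-tv pairs excluded): 0.652
A+T content: all positions 0.668, third positions 0.828
species monophyly: 100% of 20 species
species-clade bootstrap supports (B=100): min 100, max 100
screened 404 sequences: 3 failed (internal stop or indel), 0 suspect
congeneric/conspecific mean ratio: 14.6
conspecific pairs below 2%: 100.0%; congeneric pairs above 2%: 100.0%
cryptic candidates: 0; synonymy candidates: 0
```

Reading this: the three divergence pools are cleanly separated (every
conspecific pair under 2%, every congeneric pair above it — a perfect
barcoding gap at the programmed depths), every species forms a fully
supported clade in the bootstrapped NJ tree, the mean transition/
transversion count ratio R ≈ 0.65 reflects the κ = 1.4 substitution
process, and the QC screen catches exactly the three injected pseudogene
copies with no false alarms.

The same operations are exposed as a CLI (`barcodegap simulate|distances|
tree|composition|qc|gap|classify|run`) and as a library
(`import barcodegap`).

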