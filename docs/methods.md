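# Methods

## Distances

Pair counting uses pairwise deletion: a column is compared only when both
sequences carry an unambiguous A/C/G/T; gaps and IUPAC ambiguity codes are
excluded per pair, not per alignment (complete deletion is available by
flag). Transitions are purine↔purine or pyrimidine↔pyrimidine mismatches,
everything else is a transversion. The K2P closed forms are evaluated in
double precision; they were checked against a 20-digit symbolic evaluation
and the component identity d_s + d_v = d holds to 1e-12 across the domain.
Outside the domain (1−2P−Q ≤ 0 or 1−2Q ≤ 0) a pair is *saturated*: the
entry is carried as NaN, counted, and excluded from summaries — a survey
with thousands of pairs must not abort on a handful of saturated
comparisons. Note that the transition component d_s can be legitimately
slightly negative when transversions dominate (e.g. P = 0, Q = 0.05 gives
d_s ≈ −0.00069); no clamping is applied to per-pair distances.

The R-value is the unweighted mean of per-pair count ratios n_ts/n_tv,
with zero-transversion pairs excluded and counted. A site-pooled
alternative would weight deep pairs more; the per-pair mean was chosen
because the statistic is reported as an average over individuals.

Grouped summaries report, per species, the mean and the **maximum**
pairwise within-species distance (the maximum is what threshold flagging
uses: one divergent lineage inside a species is exactly the cryptic-species
signal) and, per species pair, the mean and minimum between-species
distance (the mean is what synonymy flagging uses). The three pools —
conspecific, congeneric-heterospecific, intergeneric — partition all
defined pairs.

## Neighbor joining

Classical Saitou–Nei NJ: Q(i,j) = (n−2)d(i,j) − Σ_k d(i,k) − Σ_k d(j,k),
join the argmin pair, standard divergence branch lengths, reduction
d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2. Ties in Q break to the smallest
(row, column) index pair, which makes the output deterministic given the
input order. Negative branch lengths are clamped to zero with the deficit
transferred to the sister branch, preserving the pair's total length.
On additive matrices the algorithm recovers the generating topology and
reproduces the input as tree path lengths to 1e-9 (verified against an
exhaustive least-squares topology search for n ≤ 6). Undefined distances
are a caller error: impute or drop saturated pairs before tree building.

Bootstrap supports resample alignment columns with replacement (the
single-column resampling of the conventional distance-bootstrap; a codon
bootstrap is a deliberate non-feature since the distances are
nucleotide-level). Replicate r draws from the deterministic substream
`default_rng([seed, r])`; replicates whose matrix saturates are dropped
and counted, with a warning beyond 10%. Supports are mapped onto the
full-data tree by bipartition counting, not onto a consensus tree. Both
the full-data tree and every replicate are built in canonical
(sorted-seq_id) order: identical conspecific sequences produce exact
Q-ties, so canonicalisation is what makes the reported supports invariant
to leaf input order.

## Composition

The codon position of alignment column c is ((c − frame_offset) mod 3) + 1;
gap/ambiguity characters are excluded from denominators, so frequencies
over {A,C,G,T} sum to one at every position. Dataset and genus scopes pool
counts by default; an unweighted per-sequence average is available because
both readings of a "mean composition" are defensible and they differ once
sequences have unequal amounts of missing data.

## Pseudogene (numt) screening

The genetic code is translation table 5 (invertebrate mitochondrial; TGA =
Trp, AGA/AGG = Ser), the code of Culicidae COI. Each record is screened
against a majority-rule consensus: per species when a species map is
available (the pipeline default), otherwise dataset-wide. Consensus ties
involving the gap state resolve to gap, so a column carried by a single
sequence is treated as an insertion. The reading frame is chosen to
minimise internal stops in the consensus, with ties resolved to the
configured frame offset.

Hard flags — an internal stop codon, a gap mismatch against the consensus,
or a degapped length not divisible by 3 — give verdict *fail*; these are
the disqualifying lesions of a nuclear copy. Codon positions for the
substitution spectrum are numbered along the consensus's degapped
sequence, so an insertion column does not shift the frame assigned to
downstream columns. Without hard flags, the spectrum (n1, n2, n3) is
tested against the functional expectation 5:1:18 with a two-sided exact
multinomial test (all compositions with probability ≤ the observed one are
summed; chi-square fallback above n = 500 draws) and verdict *suspect* is
issued at p < 0.01. The expectation applies to low-divergence comparisons:
against a distant reference, multiple hits at fast third positions flatten
the observed spectrum, which is why the per-species consensus is the
recommended reference.

Divergence times for nuclear-transfer events use a two-rate linear clock,
T = d / (r_mt + r_pseudo): divergence accumulates along both lineages at
their own rates. No default rates ship — the published mosquito numt
datings imply a combined rate near 2.2e-10 substitutions/site/year
(0.1093 / 2.186e-10 ≈ 5.0e8 years), but the constants are a user decision
and are configured explicitly.

## Barcoding-gap delimitation

Thresholds default to θ = 0.02 total K2P and θ_tv = 0.011 transversion
distance. Queries are assigned by nearest individual reference (best-close-
match practice; a species-centroid mode is a flag) iff the nearest distance
is below θ; exact ties across species give "ambiguous" with all tied
species reported, and candidates are sorted by (distance, seq_id) so the
result is invariant to reference order. Cryptic flagging uses within-
species maxima, synonymy flagging uses between-species means, as above.
A configurable exclusion list removes known-anomalous taxa (e.g. a
subgroup with suspected *Wolbachia*-swept barcodes) before pooling; the
shipped default set is {Culex mimulus, Culex mimeticus, Culex murrelli}.
Subspecies (trinomials) are distinct taxa by default with an option to
collapse to binomials.

The ts/tv curve bins per-pair transition and transversion distances by
total divergence and reports the first bin where the mean transversion
distance reaches the transition distance. Under a homogeneous process
this crossover is degenerate: d_s/d_v is constant in expectation
(≈ κ/2 at small distances), so with κ < 2 transversion distance leads
from the origin and with κ > 2 it never catches up. A mid-range crossover
requires divergence-dependent behaviour (e.g. transition saturation of a
large-κ process) that the homogeneous generator deliberately does not
model.

## Synthetic communities

The generator emulates a barcode survey's divergence structure with a
three-level star hierarchy (root → genus ancestors → species ancestors →
individuals). Depth parameters are expected pairwise distances and convert
exactly to branch lengths: b_ind = conspecific/2, b_sp = (congeneric −
conspecific)/2, b_gen = (intergeneric − congeneric)/2. Defaults are
conspecific 0.004 (within-species averages near 0.4% are typical of
mosquito COI), congeneric 0.08 and intergeneric 0.16 (inside the observed
2.3–21.8% congeneric and ≥10.9% intergeneric ranges), 5 genera × 4
species × 4 individuals, 651 bp (one whole codon frame; the ~650 bp
amplicon is approximate).

Substitution is a continuous-time K2P process applied site by site through
its exact transition probabilities, with per-codon-position rate
multipliers 5:1:18 (mean-normalised) and κ = α/β = 1.4, which yields a
transition/transversion count ratio R ≈ 0.7. The root sequence is drawn
from per-position equilibrium frequencies chosen to reproduce insect COI
composition (~69% A+T overall, ~93% at third positions, more A and less T
at first than second positions). Functional lineages reject mutations that
create in-frame stops (redraw per offending codon), so clean sequences are
guaranteed stop- and indel-free — a deliberate clean specificity surface
for the QC tests.

Two modelled quantities differ knowingly from their targets. First, the
symmetric K2P process erodes the root composition toward uniformity as
divergence accrues, so realized third-position A+T in a community sits
near 0.83 rather than the 0.93 equilibrium; the generator reproduces the
ordering and strength of the bias, not its exact stationary value (that
would need an asymmetric, composition-preserving process). Second,
codon-position rate heterogeneity makes the pooled K2P estimate of a deep
pair concave-biased low by about −0.01 at d = 0.15; `simulate_pair`
therefore defaults to uniform position rates so that estimator-recovery
tests measure the estimator, not the heterogeneity bias, while the
community generator keeps heterogeneous rates because its delimitation
surface (pool ordering against thresholds) is robust to the bias.

Numt injection applies background substitutions at position-uniform
relaxed rates (the nuclear copy escapes coding constraint, flattening the
spectrum toward 1:1:1) and then one lesion: a TAA stop at a chosen codon,
a single-base deletion, or a single-base insertion — the insertion adds a
gap column to every other community member, keeping the alignment valid.
All lesions are recorded in the truth table with 1-based degapped
coordinates. `split_species` grafts extra divergence onto half of one
species' individuals to create a cryptic-species scenario with known
identity.

## Problem sizes and numerical choices

The test suite runs desk-scale: communities of 80 sequences (404 for the
survey-scale screen), 100 random additive matrices up to n = 8 for NJ
exactness (exhaustive least-squares oracle up to n = 6), 200 replicate
pairs per true distance for estimator recovery (3-standard-error
criterion), B = 100 bootstrap replicates over 10 seeds for the support
checks. Symmetry of distance matrices is enforced to 1e-12, round-trips
to 1e-9. Matrix entries equal to −0.0 (from log 1) are normalised to +0.0.

## Limitations

Within-species genealogies are stars, not coalescents — realized
conspecific distances are narrower than real population samples. No indel
evolution beyond numt lesions; no gamma rate variation or model selection
for distances; no ML/Bayesian trees; alignment construction is out of
scope (input is assumed aligned and in frame, trimming left to the user).
Passing delimitation tests on these communities demonstrates correctness
of the method under its own model, not performance on real surveys where
the barcoding gap can genuinely close.
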