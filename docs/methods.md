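# Methods

This note documents the models, rules and numerical choices behind
markergenie, in the order data flows through the pipeline.

## Profile HMM and local scoring

Each marker-gene family is modelled as a classic profile HMM over the
20 standard amino acids: M match states with position-specific emission
distributions, one insert state per node, delete states between nodes,
and per-node transition triplets (M→{M,I,D}, I→{M,I}, D→{M,D}).
Parameters are stored as probabilities; every emission row, the
background vector and each transition group must sum to 1 within 1e-6.

Scoring is single-hit local Viterbi, computed entirely in log2 space:

* the alignment may begin at any match node, with uniform entry
  probability 1/M (a fixed −log2 M bits);
* it may end at any match node, with free exit;
* residues outside the aligned interval cost nothing;
* the reported bit score is
  log2 [ P(aligned residues, path | model) / P(aligned residues | background) ].

`score_local` returns the best hit only when this score is strictly
positive; the pipeline's internal scoring (`viterbi_raw`) keeps the raw
best score even when ≤ 0, because calibration needs finite scores for
non-members. Multi-hit (J-state) architecture, glocal modes and
E-value statistics are deliberately absent: screening gates on
calibrated bit-score cutoffs, and the inventory needs presence/absence
per ORF, not domain structure.

Numerical details: dynamic programming carries, per cell, the start
coordinates of the best path so that exact score ties resolve toward
the smallest `seq_start`, then smallest `node_start`, deterministically.
Unknown residues `X` contribute zero log-odds in every state. The
scorer is validated cell-for-cell against an exhaustive enumeration of
every (subsequence, node interval, state path) on small random models
(agreement within 1e-9 bits over ≥ 200 instances).

## Profile construction

`build_from_alignment` follows standard profile construction: alignment
columns whose non-gap fraction is ≥ `match_fraction` (default 0.5)
become match states; match emissions are Laplace-smoothed column counts
`(count + κ) / (total + 20κ)` with pseudocount κ = 1 by default;
transitions are smoothed counts over each sequence's observed
match/insert/delete path; the background is the smoothed overall
residue composition of the alignment. Insert states emit the
background, so insertions carry zero log-odds — this keeps the scoring
model interpretable and the enumeration oracle simple. Structural
zeros are respected at the last node (no downstream delete state).

## HMMER3 ASCII I/O

Profiles are read and written in the `HMMER3/f` dialect: parameters as
negative natural logs, `*` for probability zero, `GA`/`TC`/`NC` header
lines carrying the calibrated cutoffs. The writer emits eight decimals
(stock hmmbuild prints five), bounding the round-trip error per
probability below 1e-8. The parser renormalizes rows to absorb the
~1e-6 rounding of five-decimal files but rejects deviations beyond
1e-3. The background vector is stored as the node-0 insert emission
line, which is where HMMER files carry the null composition in
practice; files written here are parseable by independent HMMER3
implementations (verified against pyhmmer in the test suite).

## ORF calling

Transcript assemblies are fragmentary, so ORFs are called stop-to-stop
(sequence ends count as boundaries) in all six frames, without
requiring an initiator codon — requiring ATG would discard genuine gene
fragments. Translation uses NCBI table 11 (marine sedimentary Bacteria
and Archaea); codons containing `N` translate to `X`. Default minimum
length is 30 aa, configurable. Coordinates are always reported on the
forward strand as 0-based half-open intervals, and output ordering is
deterministic by (start, strand, frame).

## Cutoff calibration and decoy screening

Per profile, from labelled bit scores of curated true members (TP) and
curated non-target homologs (FP):

* `trusted = min(TP)` — the weakest accepted true member;
* `noise = max(FP)`, or −∞ with no FPs;
* if `trusted > noise` the sets separate: `gathering =
  (trusted + noise) / 2` (or `trusted` itself with no FPs);
* otherwise `separable = false` and the gathering cutoff is the
  threshold maximising classification accuracy over the labelled
  scores, ties resolved toward the larger (more conservative)
  threshold, with "reject everything" (max + 1) among the candidates.
  Non-separable profiles are allowed but flagged in the calibration
  report and logged as warnings.

Screening is competitive: every ORF is scored against *all* target and
decoy profiles in the registry; the ORF is assigned to a gene only if
that gene's profile achieves the overall best score and the score is ≥
the gathering cutoff (ties at the cutoff accepted; score ties between
models resolve in favour of decoys, then lexicographically). One ORF
never contributes to two genes. Adding decoy profiles can therefore
only remove acceptances, never add them — a property the tests check.

## Variant counting ("transcript copies")

Counts are distinct sequence variants, not read-depth abundance (read
mapping is out of scope). Accepted ORFs of one (sample, lineage, gene)
group are de-replicated greedily: sorted longest-first, each ORF joins
the first cluster whose representative it matches at ≥
`identity_threshold` identity, measured over the shorter sequence on
the best ungapped overlap. At the default threshold 1.0 this reduces
to exact duplicate/substring de-replication. The threshold is exposed
because what counts as "the same variant" (and whether the original
figures counted nucleotide- or protein-level variants) is a
user-visible choice, not a fact the method fixes.

Lineage assignment consumes an externally produced id → lineage mapping
(phylum level, class level for Proteobacteria); taxonomic
classification itself is not re-implemented. Unmapped ORFs are kept
under `unclassified` so that totals are conserved.

## Synthetic benchmark

The generator emulates the statistical structure of the target data at
toy scale: per-sample contig sets with (a) planted marker ORFs drawn
from simulated protein families attributed to named taxa, (b) decoy
ORFs from confounding families, (c) ORF-free random contigs.

* **Families** evolve by substitution only (no indels): each member
  substitutes every site independently with probability
  `substitution_rate` (default 0.05) to a uniformly chosen different
  residue. Identities are therefore closed-form (binomial), and family
  members double as a trivially aligned seed alignment. Decoy families
  copy a stated fraction (0.4 in the demo) of the target root's sites,
  making calibration genuinely discriminative.
* **Member partition**: 12 seed-alignment members, 20 calibration
  members, 20 held-out members, the rest a planting pool — sizes chosen
  so that profile construction, cutoff derivation and evaluation use
  disjoint sequences.
* **Planting** reverse-translates each variant with uniform synonymous
  codons (table 11), brackets it with in-frame stop codons and ≥ 30 nt
  of AT-rich random flank, and places it on a random strand, so
  recorded coordinates are exactly recoverable. Random contigs are
  rejection-sampled until they contain no ORF of the minimum length in
  any frame; the AT-rich composition (40% A, 40% T) makes stop codons
  frequent on both strands and rejection rare.
* **Seeding**: one global seed fans out to per-family and per-sample
  subseeds by stable SHA-256 hashing of identifiers, so adding a sample
  or family never perturbs existing ones. All outputs are
  byte-deterministic.

The demo study (three samples × ~64 contigs, six marker genes across
five categories, two decoy families, 150-residue roots) mirrors the
survey's structure: two sulfate-depleted Baltic-style samples at 12 and
42 mbsf, one sulfate-bearing Peru-Margin-style sample at 91 mbsf, and a
nitrate-reduction gene planted exclusively in the deep sample. Problem
sizes were chosen so the full build–calibrate–scan cycle completes in
about a minute on one CPU while every stage still exercises realistic
score separations (true members ~300+ bits, decoys ~10–110,
gathering cutoffs ~175–227).

What passing on this benchmark does *not* show: robustness to indels
and frameshifts, to assembly chimeras or rRNA contamination, to
families whose true and confounding members genuinely overlap in score,
or to real taxonomic assignment error — the generator does not model
these. It demonstrates the correctness of the machinery (scoring,
calibration, screening, counting, export), not field performance on
real sediment metatranscriptomes.

## Known limitations

* Single best local hit per ORF; a genuinely bi-domain ORF would be
  credited to one family only.
* Bit-score cutoffs are per-sequence, not per-domain.
* The midpoint gathering rule is this package's concrete definition;
  other reasonable rules (e.g. quantile-based) would shift cutoffs
  within the separation gap without changing demo results.
* `count_variants` is O(n²) in group size with an O(L²) identity
  computation — fine for inventories of tens of ORFs per group, not for
  thousands.
* Viterbi only: no forward-algorithm E-values, so scores are not
  comparable across profiles of very different lengths except through
  their calibrated cutoffs.
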