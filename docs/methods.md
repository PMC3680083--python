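# Methods

This note documents the models and procedures implemented in `genefam`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not establish
about real data.

## Gene structure model

All structure analysis is relative to a 14-exon / 13-intron ancestral
architecture. A gene's introns are located by their coding-sequence
coordinate (bases of coding sequence upstream of the splice junction) and
phase (that coordinate mod 3): phase 0 means splicing after a complete
codon, phase 1 after its first nucleotide, phase 2 after its second.
Coordinates are 0-based half-open internally; GFF3 (1-based closed) is
converted at the I/O boundary, and minus-strand genes are re-expressed in
transcription order immediately on read so intron indexing is strand-free.
When a GFF3 provides CDS features, the 5'-UTR offset inside the first exon
is derived from them; otherwise exons are treated as fully coding. This is
adequate because the analysis concerns coding-region introns only.

**Projection.** Deciding *which* ancestral intron a given intron is cannot
be done from coordinates alone once lengths diverge, so introns are
projected onto a reference protein alignment: an intron matches ancestral
slot *k* iff it interrupts the same aligned codon column as the reference
gene's intron *k* (within a column tolerance) with the same phase. The
tolerance defaults to 0 columns — an exact match — which keeps results
deterministic and is correct whenever the alignment is right around the
splice site; it can be widened to ±1 column for noisier alignments. An
unmatched intron falling between the reference's introns 1 and 2 (exon-2
territory) is recorded as the novel exon-2 gain; any other unmatched
intron flags the gene `unresolved`, and two introns claiming one slot is
an error rather than a silent choice. Projection is invariant to all-gap
columns and, because matching is column-based, to per-sequence insertions
that the alignment represents correctly.

**Event decomposition.** Lost-intron sets decompose into events by maximal
runs of consecutive losses: an isolated loss is one Type 1 exon fusion; an
adjacent pair is one Type 2 (three exons fused into one). Runs longer than
two exceed what the family's taxonomy anticipates; they are decomposed
greedily 5'→3' (pairs first, then a single) and flagged with a warning.
This greedy decomposition provably minimises the event count (each event
removes at most two adjacent introns, so a run of length r needs ⌈r/2⌉
events). A novel exon-2 intron adds one Type 3 gain.

**State coding.** Each gene becomes one 19-state character: `a` full
structure, `b`–`n` the thirteen single-loss types, `o` intronless, `p`
exon-2 insertion with all ancestral introns, `q`/`r` animal outgroup
architectures, `s` unknown. Structures outside the vocabulary — several
simultaneous losses, a gain combined with losses, unresolved projections —
are coded `s` rather than force-fit; the vocabulary has no states for
them, and inventing a mapping would smuggle an assumption into the
reconstruction.

## Ancestral reconstruction

The structure character is reconstructed by maximum parsimony under the
unordered model (every state change costs 1) on a rooted binary tree.
Polytomies are rejected, not silently resolved; a deterministic
ladderize-left resolver is available separately so the caller sees exactly
what tree is analysed.

Parsimony length uses the unit-cost dynamic programme (equivalent to
Fitch on binary trees, exact also for ambiguous leaves). To express
reconstruction uncertainty the package counts *all* most-parsimonious
reconstructions by an inside/outside dynamic programme: for each node and
state, the number of MPRs assigning that state is the product of minimal
inside and outside assignment counts whenever their combined cost attains
the global minimum. Per-node frequencies are exact rationals (converted to
float on output) and always sum to 1; a frequency of 1 is the "solid pie"
case. MPRs are counted with equal weight, which is the natural convention
when no model says otherwise. The DP state space is restricted to observed
states — on binary trees an unobserved state at an internal node is always
strictly suboptimal, so nothing is lost.

The unknown state `s` is by default a distinct 19th state, since the
vocabulary lists it as one; a flag treats it as missing data instead (the
leaf may take any observed state), which is the usual alternative when
`s` is read as "could not determine". Branch events are derived from the
majority-MPR state at each node, with ties broken toward the parent's
state so that a tie never fabricates a change; transitions that imply
intron regain or involve non-decodable states are reported but flagged
irregular rather than translated into events.

## Reconciliation

Standard LCA (lowest-common-ancestor) reconciliation of a rooted binary
gene tree with a rooted binary species tree: each gene node maps to the
species-tree LCA of its descendant species; a node is a duplication iff it
shares its image with at least one child. Losses per gene edge follow the
path-length rule — an edge whose endpoint images are d species edges apart
implies d−1 losses below a speciation and d below a duplication (the
duplicated lineage must still cross its own species' split) — and each
loss is attributed to the specific species branch it prunes. The LCA map
minimises duplications and losses simultaneously over all valid
embeddings, which the test suite verifies against exhaustive enumeration.

The summary score is `w_dup·D + w_loss·L` with defaults 1.5 and 1.0 —
the weights under which a 90-duplication, 29-loss history scores 164, and
the defaults of the classic reconciliation tools; both are exposed.
Rooting is the caller's responsibility, but a utility scans all rootings
and returns the minimum-score one (ties broken by a deterministic edge
order), for gene trees whose published rooting is unstated. Species labels
can be supplied explicitly or extracted from gene identifiers (default:
prefix before the first digit, e.g. `Gma`/`Ath`/`Osa`; the simulator's
`species_copy` convention is also recognised).

## Tandem arrays and copy-number statistics

No universal definition of "tandem duplicate" exists, so the detector
states its criterion and applies it symmetrically: family members on one
chromosome chain into an array when consecutive members are separated by
at most `max_intervening = 1` non-family genes (when gene ranks are
available) or by at most `max_gap_bp = 100 kb` otherwise. Arrays need at
least two members and partition the members they contain; detection is
order-invariant. Both thresholds are parameters, and reports always record
the criterion used.

Copy-number covariation uses the sample Pearson coefficient with the
two-tailed significance from `t = R·√(n−2)/√(1−R²)` on n−2 degrees of
freedom (as `scipy.stats.pearsonr` computes it). The per-species table
bundled for demonstration is synthetic — labelled as such — because the
real per-species covariate table is not redistributable; only the
statistic, not any published R/P pair, is reproduced.

## qPCR expression analysis

Relative expression follows the comparative-Ct method. Replicate i of the
target is paired with replicate i of the reference in the same sample
(ΔCt = Ct_target − Ct_reference); the pairing is a choice — plate layouts
usually justify it — and an unpaired mode (subtracting the reference mean)
is available. ΔΔCt is the sample's mean ΔCt minus the calibrator's, and
fold change is 2^−ΔΔCt, so the calibrator's fold is exactly 1 and adding
any constant to a sample's Ct values cancels. Significance tests are run
on replicate ΔCt values, not on fold changes: Ct noise is approximately
normal on the cycle scale, where the t-test's assumptions hold. Student's
equal-variance test is the default (Welch by flag); when both groups have
zero variance the test degenerates and p is reported as 0 or 1 (means
differing or not) with an explicit flag. No multiple-testing correction is
applied by default, matching common single-gene reporting practice; a
Benjamini–Hochberg option exists but is off. Primer efficiency
`E = 10^(−1/slope) − 1` from the dilution-series regression is reported
for quality control only — fold changes are pure 2^−ΔΔCt, never
efficiency-corrected (Pfaffl-style correction is out of scope).

## Synthetic data: what it emulates and what it does not

The generator produces every pipeline input with ground truth attached.

* **Species trees** are Yule (pure birth) trees scaled to unit depth,
  sampled by a small explicit-RNG routine so that identical
  (parameters, seed) give byte-identical Newick output.
* **Gene families** evolve by birth–death along the species tree from one
  root copy (defaults: duplication 0.3, loss 0.1 per unit branch length —
  a regime that yields the handful of surviving duplications typical of
  moderately expanding families). All events are logged per species
  branch; families extinct everywhere are resampled with the count
  reported.
* **Structures** descend from the 14-exon ancestor (exons of ~168 coding
  bp, 784-residue protein — inside the family's 753–817 aa range; phase
  vector mostly 0 with 1s and 2s interspersed). Event rates default to
  0.35/0.04/0.04 per unit branch for Types 1/2/3, echoing the roughly
  9:1:1 proportions seen in the family (243:28:29 across 215 genes), and
  gains are confined to one designated clade, emulating a gain restricted
  to a single lineage. Losses that would leave fewer than 7 introns are
  suppressed, keeping simulated genes inside the observed 7–14 intron
  range. By default no loss is placed adjacent to an already-lost intron
  (collision-free mode), making every leaf's decomposition unique — the
  property the exact-recovery tests rely on; switching it off stresses
  the greedy decomposition instead.
* **Alignments** are gap-free by default (exon lengths held constant), so
  projection is exact by construction; an indel mode adds per-leaf coding
  insertions of 1–3 codons to exercise the column-mapping machinery.
* **Ct tables** draw the reference Ct as Normal(20, sd) and the target as
  that Ct plus the calibrator ΔCt minus log2(fold) plus noise, in
  triplicate per sample — unbiased for the paired ΔΔCt estimator and
  exact at sd = 0. The default noise (0.15 cycles) and the stress-panel
  fold map (6–6.5-fold salt induction, mild osmotic repression) mirror a
  realistic stress experiment.
* **Tandem placements** plant arrays of 2–3 members at consecutive gene
  ranks among scattered members kept ≥3 ranks and ≫100 kb apart, so the
  planted truth is unambiguous under the default criterion.

What passing these tests shows: the event classifier, reconciliation
engine, parsimony machinery and ΔΔCt estimator are *internally correct* —
they invert the generative model exactly when its assumptions hold. What
they do not show: robustness to misalignment around splice sites,
annotation errors, intron sliding, non-Poisson event clustering, or
amplification-efficiency differences between primers — real-data effects
the generator deliberately omits.

## Numerical and calibration choices

* Problem sizes in the verification suite: oracle equivalence uses 200
  random trees of ≤7 leaves × ≤4 states (parsimony) and ≤6 gene leaves ×
  ≤4 species (reconciliation), the largest sizes exhaustive enumeration
  handles comfortably; event recovery uses 1000 leaf histories on 5-leaf
  trees; t-test calibration uses 10⁴ null replicates; the permutation
  oracle uses 10⁵ permutations at n = 30, where the t approximation is
  excellent.
* "Low event rate" for root-state recovery means ≈1.5 expected structural
  events per 20-leaf tree (total rate 0.20 per unit branch; the mean
  total branch length of a unit-depth 20-leaf Yule tree is ≈7.5).
  Parsimony root inference is intrinsically ambiguous when an event lands
  on a basal branch — common on Yule trees, whose basal branches are
  long — so recovery degrades smoothly as rates rise; at ≈1.5 expected
  events recovery is ~97–99%.
* MPR frequencies are computed as exact integer ratios (Python
  arbitrary-precision integers, `fractions.Fraction`) and converted to
  float only on output, so the sum-to-one invariant holds to 1e-12 by
  construction.
* Ties: majority-MPR branch labelling breaks ties toward the parent
  (never fabricating a change), then alphabetically at the root;
  `min_score_rooting` breaks ties by a deterministic edge enumeration;
  polytomy resolution folds children left-to-right.
* Degenerate inputs: single-exon genes have an empty intron profile (not
  an error); constant vectors and n < 3 are rejected by the correlation;
  zero-variance t-tests are flagged; a non-negative standard-curve slope
  warns and reports E as NaN rather than a misleading number.
* All simulation functions accept either a seed or a live NumPy
  `Generator`; the pipeline derives per-stage seeds from the top-level
  seed by hashing, keeping every stage reproducible independently.

## Known limitations

* Projection assumes the reference carries all 13 ancestral introns and
  that the alignment is correct at splice-site codons; there is no
  realignment or splice-site re-inference.
* The reconciliation model is duplication–loss only (no transfers, no
  incomplete lineage sorting) and requires binary rooted inputs.
* The 19-state character cannot express multi-loss combinations, so such
  genes enter the reconstruction as `s`/unknown; with many of them the
  default distinct-state treatment can distort ancestral inference
  (the missing-data flag is the escape hatch).
* Expression analysis assumes a single stable reference gene; no
  multi-reference normalisation is implemented.
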