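# Methods

`sigpevo` reconstructs the evolutionary dynamics of Sec-pathway signal
peptides (SPs) across clusters of orthologous bacterial proteins (COGs) and
relates gain/loss events to bacterial lifestyle. This note documents the
models, the synthetic-data generator, the numerical choices, and the known
limits of what the test suite demonstrates.

## Consensus secretion states

Each protein carries three predictor-style calls: a SignalP-like score/call,
a Phobius-like discrete call, and a TatP-like twin-arginine call. The
consensus has four outcomes: a Tat call rejects the whole cluster (the
analysis is restricted to Sec substrates); agreement of the two Sec
predictors yields POSITIVE or NEGATIVE; disagreement discards the protein
(DISCORDANT). Clusters keeping ≥ 3 members after discards are labelled
positive, negative, or mixed by their members' states; only mixed clusters
enter the event analysis.

The trained predictors themselves are out of scope. They are replaced by a
documented heuristic that scores the tripartite SP architecture directly:
for every candidate cleavage point within residues 15–40 it requires

* an n-region: ≥ 1 K/R and no D/E among the first five residues;
* an h-region: some window of 7–14 residues, ending 3–9 residues before the
  cleavage point, with mean Kyte–Doolittle hydropathy ≥ 2.0;
* a cleavage motif: small uncharged residues at −3 and −1 (canonical A-x-A
  scores higher than the degenerate variants).

The score is 0.5 plus bonuses for motif canonicity, hydropathy excess, and
n-region charge, so score > 0.5 iff some candidate is admissible; the
best-scoring (ties: most N-terminal) candidate supplies the cleavage
position. The hydropathy floor of 2.0 was set for specificity: at laxer
values random genomic-context translations and mature-protein interiors
score as SPs often enough to dominate the start-correction step with false
positives, which no trained predictor would do. The twin-arginine detector
matches the consensus (S/T)-R-R-x-F-L-K with degenerate flanks (sets
configurable in `secretome.TAT_PATTERN`) within the first 35 residues.

## Trees and parsimony

Cluster trees are accepted from outside (the real pipeline used ML trees) or
built by neighbor joining on 1 − identity distances as a stand-in; pairwise
identity divides identical aligned residues by the shorter ungapped sequence
length. Unrooted trees are midpoint-rooted: the root is placed halfway along
the longest leaf-to-leaf path (ties broken by lexicographic leaf-pair order;
a midpoint falling exactly on a node attaches the root there). Polytomies
are resolved deterministically (children ordered by smallest descendant leaf
label) with zero-length branches.

Ancestral SP states (binary) and lifestyles (free-living 0, endosymbiont 1,
commensal 2) are reconstructed with Fitch parsimony. Every non-root branch
is then classified: gain ({0}→{1}), loss ({1}→{0}), keep/stay for constant
singletons, and **uncertain** whenever either endpoint's final state set is
ambiguous. This uncertainty rule is one of several defensible readings of
"not resolved by parsimony"; counting over all minimal labelings would mark
more branches uncertain. Fitch final sets are a subset of the full
MPR summary, so a branch can be resolved-but-wrong when several equally
minimal histories exist — the recovery analysis below accounts for that.

The taxonomic position of an event is the lowest rank (species < genus <
family < order) at which all descendant genomes of the event's child node
agree. The lifestyle reconstruction assigns each branch a transition class
from the child's final set (singleton → that lifestyle, otherwise
uncertain); the event-by-transition contingency table counts every
mixed-cluster branch exactly once and reports within-column percentages.

## Gene start correction

Mis-annotated starts truncate SP-encoding regions and masquerade as loss
events. For every consensus-NEGATIVE member of a mixed cluster, the search
window is derived from the MSA: for each SP-bearing member, the signed
offset between first-residue alignment columns, measured in ungapped
residues (member residues for upstream offsets, target residues for
downstream), maximized per direction, plus 30 residues. Every in-frame
ATG/GTG/TTG in the window yields a candidate N-terminus (extensions crossing
an in-frame stop are discarded; the shift-0 candidate always exists), which
is re-predicted. Priorities: (1) a Tat-positive candidate deletes the
cluster; (2) any reliably positive candidate re-annotates the start — the
highest SignalP-like score wins, ties broken by smaller |shift|, then codon;
(3) if no start gives a reliable call the protein is deleted as discordant;
(4) otherwise the start stays. Rule 3 is interpreted conservatively: a
reliable negative at any start (including shift 0) keeps the protein.
Corrected clusters are re-filtered and a second parsimony round is run; the
two-round summary reports kept-event and kept-mixed-cluster fractions.

## Event mechanisms

Only leaf-nearest events are analysed (an event with another gain/loss
strictly below it is set aside; opposite-type ancestor–descendant pairs are
reported as reversals). For each event, extant descendants of the node
*above* it are compared: new-state leaves from the child subtree against
old-state leaves from the rest of that subtree. For each (SP leaf s, non-SP
leaf t) pair, lr = (residues of t within the alignment columns of s's
signal peptide) / (SP length of s); the event lr is the mean over pairs.
lr ≤ 0.1 is classified as whole-segment indel, 0.9–1.1 as substitution,
anything else intermediate. For near-length-conserving pairs the identity
over the three cleavage-site columns and over the remaining SP columns is
reported separately (shorter-length normalization throughout).

## Statistics

* Discrimination score d(a,b,g) = (a_sp − a_nosp)/(a_sp + a_nosp) −
  (b_sp − b_nosp)/(b_sp + b_nosp), bounded in [−2, 2], with a two-tailed
  Fisher test on the 2×2 counts per cluster.
* GO annotations are closed upward over is_a edges (part_of optional);
  enrichment is a one-sided Fisher test of each term in each group against
  the pooled background. No multiple-testing correction is applied by
  default (a Benjamini–Hochberg helper would be an extension, not used in
  the reported tables).
* Two-sample location tests use Kolmogorov–Smirnov; the multivariate
  comparison of (genome size, SP fraction) between lifestyles is an
  energy-distance permutation test (Székely–Rizzo statistic, label
  permutation, p = (1 + exceedances)/(1 + permutations)). The original
  analysis names a multivariate Cramér–von Mises test without specifying a
  construction; the energy test is this package's stand-in with the same
  permutation-null logic.

## Synthetic data generator

No generative model exists in the source analysis (it consumed real
genomes), so the generator's distributions are this package's own study
conditions, fixed as defaults in `SimulationConfig`:

* **Cohort**: 153 species in one order; lifestyle fractions 120:21:12
  (free-living : endosymbiont : commensal); genome sizes normal per
  lifestyle with means 3600/1066/3730 (SD 600/250/600), matching the
  reported per-lifestyle protein counts. Taxonomy (≈ n/4 genera, ≈ genera/3
  families) is monophyletic by construction; species enter families with
  probability proportional to genome size.
* **Sequences**: every protein is N-terminal blocks + mature body
  (80–200 aa). SP blocks are sampled tripartite (n-region 3–6 incl. the
  initiator M with ≥ 1 K/R and no adjacent basic pair; h-region 8–14 from
  {L,V,I,F,A,M,W}; c-region 3–6 polar ending A-x-A; total 15–40, typically
  20–30); non-SP segments are polar remnants. Bodies evolve by per-site
  substitutions (0.02 per branch, flat — branch lengths are not used to
  scale mutation, a deliberate simplification); segments change only
  through SP events, so the true alignment is known exactly.
* **Events**: per branch, loss with probability 0.04 on SP lineages
  (×4 on branches whose descendants are all endosymbionts) and gain with
  0.01 on SP-less lineages; the indel mechanism is drawn with probability
  0.7, else substitution (in-place rewrite conserving length; substitution
  gains require an existing segment of hostable length and otherwise fall
  back to indel). Root state is SP-positive with probability 0.12; 1% of
  families carry twin-arginine SPs.
* **Annotation errors**: 10% of SP-bearing members have their start moved
  to the next in-frame start past the SP (0–10 residues beyond the
  cleavage site, so shifts concentrate near the SP length); coding
  sequences sit in 300 nt of genomic context per side with a planted
  in-frame upstream stop 10–14 codons before the true start (as in real
  genomes) and an alternative start below it.
* **Predictor noise**: independent per-tool flips (SignalP-like 0.04,
  Phobius-like 0.04, TatP-like 0.001), giving a discordance rate near the
  ~8% seen in real consensus data; scores stay consistent with calls.
* Every family is rejected and resampled (new derived seed) unless the
  zero-noise heuristic readout of every leaf equals its planted state, the
  predicted cleavage matches the planted SP length, and no alternative
  in-frame start of a non-SP leaf exposes an SP-like window — without the
  last condition the "non-secreted" ground-truth label would be ambiguous.

What the generator does **not** emulate: realistic substitution matrices or
rate heterogeneity, indels outside the SP region, horizontal transfer,
clustering errors, paralogy, or predictor error structure beyond independent
flips. Green tests therefore certify the pipeline's logic and its behaviour
under the stated noise models — not predictor accuracy on real proteomes.

## Recovery measures and experiment design

* Event recovery (zero noise, no start errors) is scored against planted
  events per branch. Clusters where the planted change count exceeds the
  Fitch minimum are excluded — there the truth is not parsimony-
  identifiable and no reconstruction could recover it; planted events on
  branches the reconstruction marks uncertain are likewise excluded from
  the recall denominator. Precision and recall are ≥ 0.9 in the shipped
  experiment (40 species, 150 families).
* The loss:gain experiment plants loss rate = 4 × gain rate with a
  balanced root state (0.5). Because state occupancy drifts along the tree
  and event counts condition on cluster composition, the unbiased recovery
  target is the opportunity-normalized rate ratio: losses per branch with a
  confidently SP-positive parent over gains per branch with a confidently
  SP-negative parent, across all clusters. The simulated 4-fold asymmetry
  is recovered within three standard errors (500 families).
* Start-error recovery uses a root-SP probability of 0.3 so that planted
  errors are plentiful; ≥ 90% of planted errors are corrected to POSITIVE
  and round-2 losses drop strictly below round 1. Occasional false
  corrections (random context translating to an SP-like N-terminus) are
  retained as inherent to the procedure.
* Mechanism recovery uses mechanism_mix = 0.5 to test both categories;
  the shipped problem sizes (250 families) give ≥ 95% indel and ≥ 90%
  substitution category recovery.

Problem sizes throughout (30–150 species, 60–500 families) were chosen so a
full reproduction run completes in about half a minute on one CPU while
keeping every recovery estimate's sampling error well inside its acceptance
margin.

## Numerical and degenerate-input choices

Identity of a pair with zero shared aligned columns is 0. NJ branch lengths
are clamped at 0. A zero-diameter tree is rooted at an arbitrary internal
node with a warning. Fisher p-values are clipped to (0, 1]. The permutation
p-value uses the add-one rule, so it is never below 1/(n_permutations + 1).
Spearman on constant input returns NaN. Events on the (nonexistent) root
branch are never created. All randomness flows through
`numpy.random.Generator` seeded from explicit `SeedSequence` tuples, so a
`SimulationConfig` determines every output byte.
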