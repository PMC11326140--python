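# Methods

## Problem setting

The package reconstructs how a phosphorylation signal initiated at a
designated receptor (the source node) propagates through a background
network, using only the temporal order and direction of per-protein
fold-change responses, and then asks whether the reconstructed network is
informative about an independent phenotype. The pipeline has four
statistical/algorithmic stages — significance scoring, prize-collecting
subnetwork extraction, temporal pathway synthesis, and validation against
inhibitor and functional-screen data — plus randomization null models and
a synthetic-data generator that plants a recoverable ground truth.

## Significance scoring and discretization

Inputs are replicate × time matrices of fold changes normalized to time
zero (`normalize_blots` performs background subtraction, loading-control
division, and time-zero normalization; it is scale invariant in the raw
signal). For each protein and each t > 0 two paired Student's t-tests are
computed: against time zero (*firstscores*) and against the preceding
point (*prevscores*). The t statistic is the closed form
`mean(d) / (sd(d)/√n)` with the sample (n−1) standard deviation and df
n − 1; two-sided p-values come from the t distribution. Two degenerate
cases have fixed conventions: all differences exactly zero gives p = 1
(flagged `zero-diff`), and zero spread with a nonzero mean difference gives
p = 0, the limit of a diverging statistic (flagged `zero-sd`). The second
convention is what makes noiseless synthetic data maximally significant and
is why zero-noise recovery tests are exact. Significance means p ≤ 0.05
(the threshold is "above which measurements are non-significant", so the
boundary is inclusive); no multiple-testing correction is applied, matching
the upstream protocol this stage mirrors. A time point's state is
`activated`/`inhibited` by the direction of the mean fold change relative
to the reference point of whichever test fired (the smaller p wins), and
`inactive` otherwise.

Prizes are `−log10` of the smallest p-value over both tracks, floored at 0
and capped at 16 (the cap only matters for the exact-zero convention).
The transformation is monotone in evidence; unmeasured proteins simply have
no prize.

## Subnetwork extraction

The extraction minimizes, over source-rooted trees,

    β · Σ_{v excluded} prize(v)  +  Σ_{e included} (1 − confidence(e)),

with β = 10 (edge reliability), degree penalty 0, and a dummy edge weight
parameter of 10 that is accepted for interface compatibility but inert in a
single-rooted construction (the objective has no dummy term once the root
is fixed). The solver is a deliberate simplification of
message-passing prize-collecting Steiner forest tools: a greedy
construction repeatedly attaches the prized node with the largest
`β·prize − shortest-path cost` margin along its cheapest path, then prunes
unprofitable leaves. One hundred runs with multiplicative uniform ±10 %
prize jitter are aggregated; edges kept in ≥ 50 % of runs survive, pruned
to the source component. An exhaustive optimum (enumerate connected node
subsets containing the source; the optimal edge set for a fixed subset is
its minimum spanning tree on edge costs) serves as the reference on
instances of ≤ 12 nodes; the greedy result is within 5 % of it on the test
fixtures. Kinase→substrate edges are projected to undirected edges here
(confidence 0.5 when the pair has no PPI support); direction is re-imposed
during synthesis.

## Temporal pathway synthesis

Candidate events are all signed orientations of subnetwork edges,
restricted by the directed kinase→substrate prior: a one-way prior removes
the reverse orientation, a signed prior removes the opposite sign for its
direction. Path validity over measured nodes requires (i) non-decreasing
first-change times, (ii) a measured, responding terminal, and (iii) the
cumulative sign product from the source matching each measured node's first
change direction. Unmeasured intermediates impose no timing constraint but
contribute their edge sign. These semantics are a design decision: they
make direction mostly resolvable while signs rarely are — the behaviour
expected of sparse time courses — with a decidable, desk-scale procedure.
Two further decisions: paths may not *end* at unmeasured nodes, and
enumeration is restricted to simple paths of at most `max_path_len = 8`
edges (configurable; a fidelity limit relative to symbolic solvers, chosen
because the nine-point grid cannot order deeper chains anyway).

The summary network is the union of all valid paths. Consolidation is a
union and therefore order independent; output files sort edges
lexicographically for byte-reproducibility. The pruned depth-first
enumeration is exact, not heuristic: both constraints are monotone along a
path (a timing or sign violation can never be repaired by extension), so
pruning at the first violating node loses nothing. `brute_force_summary`
re-derives the summary by unpruned enumeration over all simple signed paths
and is held equal to the fast path on randomized instances.

Activity windows report, per node and time point, the admissible states:
the observed state for measured nodes, `{activated}` for the source at all
times, and all three states for unmeasured nodes (unconstrained). This
conservative treatment of unmeasured nodes reflects that with sparse
time courses path validity rarely pins down a Steiner node's state.

## Validation

*Inhibitor arm.* Cumulative inhibition of a compound over a kinase set is
the literal sum of `100 − residual activity` over the set's kinases present
in the biochemical matrix; unassayed pairs are skipped, and residuals above
100 (activation) contribute negatively unless `clamp_negative` is set. The
perturbation cutoff is `network_fraction · n · inhibition_threshold`
(0.25 · n · 50), and prediction requires strictly exceeding it. A compound
measurably perturbs the phenotype when the unpaired two-sample t-test on
normalized AUC replicates gives p < 0.05 **or** every replicate's percent
change against the mean control exceeds +10 % (all) or falls below −10 %
(all); mixed directions never satisfy the effect clause, and degenerate
variance falls back to the effect clause with a warning. The reference for
percent change is the mean of the control replicates; the test is unpaired
because screen replicates are not paired across conditions.

*Functional arm.* A kinase is predicted active at grid time t when any of
its pathway activity intervals intersects the closed window
[t − 5, t + 5] minutes. The measured counterpart is differential
phosphorylation at t: one-sample t-test against 1 with p < 0.05 **or** all
replicate fold changes ≥ 1.2 (or all ≤ 0.8, boundaries inclusive).

Both arms report precision over positive predictions — compounds or
(kinase, time) instances below the prediction rule are abstentions, not
negatives — together with a full confusion matrix over the assessed
universe.

## Randomization nulls

*Network arm.* Each of 100 iterations relabels the subnetwork's nodes by a
uniformly random injection into the background network's node universe
(source label fixed), permutes the partial-model node labels, globally
shuffles the time-series values (t > 0 cells) and, independently, the two
significance-score tracks, reruns synthesis from the fixed source, and
scores the resulting network's kinases with the inhibitor arm. Relabeling
from the full universe, rather than within the subnetwork's own labels, is
deliberate: at this scale the measured panel is enriched for
phenotype-coupled kinases, and a within-subnetwork permutation would leave
every null network with the true network's kinase composition, making the
null uninformative. The global value shuffle is the most destructive
(hence most conservative) reading of value shuffling; a per-protein variant
is available via `per_protein=True`. Iterations with no defined accuracy
(no surviving kinases, no positive prediction) are recorded as NaN, never
dropped.

*Functional arm.* Each iteration draws a degree-preserving directed
configuration-model realization of the background kinase→substrate network
(self-loops and parallel edges removed after generation by default — the
pre-collapse multigraph preserves every in/out degree exactly and is
available with `collapse=False`), shuffles kinases onto its nodes,
resamples per-time weakening/strengthening labels from the kinase pool with
the true model's per-time selection probabilities, assigns each selected
kinase uniformly to one of 36 clusters, and reconnects every same-cluster
kinase pair by all unweighted shortest paths in the random background (ties
are all kept, so the null is not seed-order dependent; unreachable pairs
are counted and skipped). Accuracy is evaluated exactly as for the true
model.

Ensemble summaries report mean, SD, percentiles, and the empirical p-value
(fraction of iterations with accuracy ≥ the true model's; undefined
iterations count as not exceeding).

## Synthetic study generator

The generator's defaults are the study conditions for every end-to-end
test. The sampling design copies the motivating experiment: nine time
points (0, 5, 15, 30, 60, 120, 180, 240, 360 min), three biological
replicates, 28 measured proteins, 29 screened compounds. The remaining
conditions were fixed once, on the following grounds:

- **Background network: 140 proteins, 70 kinases.** Large enough that the
  planted pathway's kinases (~10–15) are a small minority of the kinase
  universe, as a real pathway is within a kinome-scale background; this
  asymmetry is what the randomization nulls probe.
- **Cascade: 20 nodes, depth ≤ 4, growth weighted 3:1 toward kinases.**
  Signal relays predominantly through kinases; shallow-and-wide matches a
  receptor-proximal signaling burst and keeps activation times strictly
  increasing on the early grid points (depth d activates at grid point d).
  Cascade edges get PPI confidence 0.95–0.99 (true signaling edges are the
  well-supported ones); background edges 0.4–0.7.
- **Measured panel: all cascade nodes plus off-cascade kinases up to 28.**
  Kinase-dominated, mirroring a 25-kinase blot panel, and the
  non-responding kinases anchor the negative side of the time-resolved
  validation.
- **Response: sustained step to fold 2.0 (or 0.5 under net inhibition),
  beginning at the planted activation time; optional pulse shape.** A step
  makes "first significant change" unambiguous for recovery tests.
- **Noise: multiplicative lognormal, CV 0.1 by default, mean exactly 1.**
  Fold changes are ratio data, strictly positive; the mean-one
  parameterization avoids spurious drift at large replicate counts.
  Time-zero values are exactly 1 by construction (normalization, not
  measurement).
- **Inhibitor panel: five selectivity classes.** Broad hitters (strong on
  most phenotype-coupled "barrier" kinases, inert elsewhere — the true
  perturbers), selective decoys (near-complete inhibition of a few
  specific kinases, at most one barrier kinase held below the 50 %
  phenotype threshold), cluster decoys (~45 % on three specific barrier
  kinases, score-bounded so only small networks can be fooled),
  promiscuous binders (moderate inhibition across most non-barrier
  kinases), and inert controls. Real inhibitor panels span exactly this
  selectivity spectrum, and the class structure is what makes the
  randomization null informative: every regime of random network size and
  composition has a compound class that exposes it, while a full-size
  barrier-dominated network clears all of them. ~10 % of unplanted matrix
  cells are left unmeasured (NaN).
- **Permeability screen: AUC mean shifted by +6 % per barrier kinase a
  compound inhibits ≥ 50 %, replicate CV 3 %.** Cumulative coupling
  mirrors the validation arm's additive-inhibition logic, and a broad
  hitter (~10 barrier kinases hit) shifts far beyond the 10 % detection
  threshold in every replicate.
- **Functional model fixture: barrier kinases labelled functional over a
  three-grid-point window starting at their activation time** (weakening
  for net-activating responses, strengthening for net-inhibiting ones),
  uniform clusters in 1..36, background = the interactome's
  kinase→substrate layer.

What the generator does **not** emulate: feedback loops and cycles (the
planted cascade is a tree), missing bands, batch effects, autocorrelated
noise, partial-agonist dose response, or kinases measured on multiple
phosphosites. Passing the recovery and separation tests therefore shows
the pipeline is correct and informative under clean cascade-like signal
propagation, not that it is robust to every artefact of real blots.

## Numerical and reproducibility choices

- One global seed expands into per-stage streams through
  `numpy.random.SeedSequence` with a fixed spawn key per stage, so no
  stage's draws depend on another stage's draw count; reruns with the same
  configuration are byte-identical, including output files.
- All time is integer minutes; node identifiers are opaque strings.
- Output TSVs carry a `# stage=... / # seed=...` header; floats print with
  `%.10g` so write∘read is the identity on canonical files.
- Edge iteration is sorted everywhere a set is serialized.

## Known limitations

- The greedy prize-collector has no optimality guarantee beyond the small
  instances where it is checked against exhaustive enumeration; on
  adversarial cost structures it can miss the optimum.
- Path enumeration is exponential in the worst case; `max_path_len` bounds
  it but also bounds the depth of recoverable cascades.
- With three replicates and sixteen uncorrected tests per protein, flat
  proteins fire spuriously at a substantial rate; at noise CV 0.1–0.2 an
  early false change with the wrong direction can invalidate paths through
  a node and cost the edges below it. Noisy-data recovery is therefore
  reported (recall ~0.8–0.95 at CV 0.2) rather than guaranteed.
- A noisy fit can occasionally lose enough pathway kinases that the
  validation contrast against the null ensemble tightens to a tie; across
  a 26-seed sweep of the default conditions this occurred once.
- The functional-model null evaluates accuracy over measured kinases only;
  kinases without phospho data abstain rather than count against either
  model.
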