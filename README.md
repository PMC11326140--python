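# pathsynth

Reconstruction and validation of kinase phosphosignaling networks from
time-resolved phosphorylation data.

When a receptor such as the thrombin receptor PAR1 (gene `F2R`) is
stimulated, a wave of phosphorylation propagates through kinase cascades.
Western-blot (or phosphoproteomic) time courses tell you *which* proteins
respond and *when*, but not how the signal travels. `pathsynth` turns a set
of replicate fold-change trajectories plus a background interactome into a
directed — and where the data allow, signed — summary network of the
pathways that can explain the observed temporal order, and then quantifies
how much that network knows about an independent phenotype.

It is written for systems biologists who have (i) per-protein time courses
on a fixed sampling grid, (ii) a protein–protein interaction network with a
directed kinase→substrate layer, and optionally (iii) kinase-inhibitor
biochemistry and a phenotypic screen to validate against.

## The method

1. **Significance scoring.** For each protein, paired Student's t-tests
   compare every time point against time zero (*firstscores*) and against
   the preceding point (*prevscores*); p ≤ 0.05 counts as significant, with
   no multiple-testing correction. Per-time activity states
   (activated / inhibited / inactive) follow from the fired test's
   direction, and each protein receives a prize
   `−log10(min p)` for subnetwork extraction.

2. **Prize-collecting subnetwork.** From the interactome, an undirected
   subnetwork connecting the prized proteins to the source receptor is
   extracted by minimizing `β·Σ excluded prizes + Σ (1 − confidence)` over
   source-rooted trees (β = 10, degree penalty 0), aggregating 100
   randomized greedy runs with ±10 % prize jitter and keeping edges present
   in at least half of them.

3. **Temporal pathway synthesis.** Every subnetwork edge is considered in
   both orientations and both signs, restricted by the directed
   kinase→substrate prior. A signed, directed, source-rooted simple path is
   *valid* when first-change times never decrease along it, it ends at a
   measured responding protein, and the running product of edge signs
   matches each measured node's first change direction (+ activation,
   − inhibition). The union of all valid paths is the summary network:
   edges are directed; an edge is signed only when every valid path through
   that node pair agrees on one (direction, sign). Per-node activity
   windows report the admissible states over time.

4. **Validation.** For a kinase-inhibitor panel, a compound's *cumulative
   inhibition* is `Σ (100 − residual activity)` over the network's kinases;
   it is predicted to perturb the phenotype when that score exceeds the
   cutoff "a quarter of the network's kinases inhibited by half"
   (`0.25 · n · 50`). For a time-resolved functional kinase model,
   a kinase is predicted active at *t* when any of its pathway intervals
   meets the closed window [t − 5, t + 5] minutes. Both arms score
   agreement as precision over positive predictions and are compared
   against 100-iteration randomization nulls (node-label shuffles, global
   value shuffles, and a degree-preserving configuration model).

A fully synthetic study generator plants a ground-truth signaling cascade
(signed edges, activation times, phenotype-coupled "barrier" kinases) and
emulates every input — time courses, interactome, inhibitor selectivity
spectrum, permeability screen, functional kinase model — so the whole
pipeline is testable end to end without external data.

## Worked example

```python
import pathsynth as ps

study = ps.simulate_study(ps.SimulationConfig(seed=42))
model = ps.TemporalPathwayModel(
    study.dataset, study.interactome, study.source, study.partial_model
)
res = model.fit(seed=0)
print(res.summary_table())
```

```
Temporal Pathway Synthesis Results
==========================================
source node:            RCPT
measured proteins:      28
responding proteins:    24
subnetwork nodes:       32
subnetwork edges:       31
summary directed edges: 24
summary signed edges:   22
network kinases:        17
significance threshold: 0.05
max path length:        8
seed:                   0
```

28 proteins were measured on the nine-point grid (0–360 min); 24 responded
significantly. The extracted subnetwork (32 nodes) yields a summary network
of 24 directed edges, 22 of which could also be signed thanks to the signed
kinase→substrate priors. Against the planted truth this run recovers every
true edge (`res.recovery(study.truth)` → recall 1.0, 20/20 edges, no sign
errors) with precision 0.83.

```python
report = res.validate(study.inhibition, study.screen)
null = res.null_ensemble(study.inhibition, study.screen, n=100, base_seed=1)
```

Here the fitted network predicts 9 of 29 compounds to perturb the
phenotype, all 9 confirmed by the screen (accuracy 100 %, cumulative-
inhibition cutoff 212.5 percentage points), while the 100 randomized
networks average 54 % accuracy with a 95th percentile of 80 % — the fitted
network's accuracy is what randomization destroys.

The same pipeline runs from the shell:

```bash
pathsynth run --seed 42 --outdir out/        # full pipeline, all artifacts
pathsynth simulate --seed 7 --outdir data/   # synthetic inputs only
```

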