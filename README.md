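# ptim — probabilistic target inhibition maps

`ptim` models why tumor cells respond to targeted agents in a single-agent
drug screen, and turns that model into ranked two-drug combination plans. It
is aimed at functional precision-medicine workflows: a primary culture (or a
set of cultures from spatially distinct tumor regions) is screened against a
kinase-inhibitor panel with known drug–target EC50 profiles, and the goal is
to pick a clinically dosable drug pair that is synergistic, works across
heterogeneous tumor sites, or shuts down parallel survival pathways.

## The model

Cell survival is represented as a Boolean series/parallel circuit over
protein targets. A **block** is a set of 1–4 targets that must all be
inhibited together (logical AND) to stop proliferation; blocks combine in
series across the circuit (logical OR), so fully covering any one block is
predicted to kill. One-target blocks are *single points of failure*.

Per-drug IC50 values are mapped to sensitivities in [0, 1]:

```
y = 1                                                    if IC50 ≤ Cmax
y = (log10 maxDose − log10 IC50) / log10 maxDose         otherwise (clamped)
```

so a drug active at clinically achievable concentration scores 1, and a drug
that never reaches 50% inhibition at the max tested dose scores 0. Each drug
inhibits the Boolean set of targets whose EC50 lies at or below its Cmax. A
drug *supports* every block it fully covers; a block's score is the shrunk
mean of its supporters' sensitivities, (Σy + α·y0)/(n + α). The circuit
predicts ŷ(d) = max score over blocks drug *d* fully covers, and model
search minimizes Σ(ŷ − y)² — exactly on small instances, by seeded beam
search otherwise.

Secondary evidence constrains the search through per-target priors:
tumor/normal expression ratio < 1.5 excludes a target; tumor-only expression
below the first quartile excludes it; high-impact mutation plus copy gain
requires it; siRNA knockdown viability with viability + 2σ < 1.5 requires
it; concordant phospho z-ratios (P1 ≥ 1, |P1 − P2| ≤ 0.5) require it.

Combination design covers blocks with at most two drugs: **synergy** (two
drugs jointly covering one multi-target block), **consensus** (one pair
covering a block in every tumor-site circuit; the weakest site bounds the
plan score), and **resistance abrogation** (a pair covering two
pathway-independent blocks, with suggested doses of 1.5 × target EC50 only
when below Cmax). Chou–Talalay combination indices for validation use the
non-constant-ratio two-term form CI = d1/Dx1 + d2/Dx2, reported only inside
each drug's functional dosage range [target EC50, Cmax].

## Worked example

Simulate a screen from a planted circuit, fit it, and design combinations:

```
$ ptim simulate --seed 7 --sigma 0 --out demo/bundle
wrote synthetic bundle to demo/bundle

$ ptim model --drugs demo/bundle/drugs.tsv --profiles demo/bundle/profiles.tsv \
             --screen demo/bundle/screen.tsv --out demo/model
circuit: 3 block(s), objective 0.1528; 2 at/above reporting threshold 0.5

$ ptim design --mode consensus --circuit demo/model/circuit.json \
              --circuit demo/model/circuit.json --circuit demo/model/circuit.json \
              --drugs demo/bundle/drugs.tsv --profiles demo/bundle/profiles.tsv \
              --out demo/plans
559 consensus plan(s) written to demo/plans
```

The fitted circuit (`demo/model/circuit.json`) contains exactly the three
planted blocks — `{T01,T02}` at 0.583, `{T03}` at 0.500, `{T04,T05,T06}` at
0.417 — the planted 0.70/0.60/0.50 pulled toward zero by the default
shrinkage (α = 1: five supporters give 5s/6). The objective 0.1528 is the
residual sum of squares of those shrunk predictions against the noise-free
sensitivities of all 40 simulated drugs. The consensus plans each name a
drug set covering at least one block in every one of the three (here
identical) site circuits, ranked by the minimum over sites of the best
covered-block score; the simulated formulary is promiscuous, hence the long
ranked list.

In Python the same pipeline is:

```python
from ptim import (GroundTruth, simulate_screen, scale_screen, binarize_targets,
                  search_blocks, assemble_circuit, recovery_metrics)

gt = GroundTruth(seed=7, sigma_log10=0.0)
drugs, profiles, screen, truth = simulate_screen(gt)
y = scale_screen(screen, drugs)                      # IC50 -> [0,1]
matrix = binarize_targets(profiles, drugs)           # EC50 <= Cmax
blocks, sse = search_blocks(matrix, y, mode="beam", alpha=0.0)
circuit = assemble_circuit(blocks, objective=sse)
print(recovery_metrics(gt, circuit))
# {'block_match': 1.0, 'target_jaccard': 1.0, 'score_rmse': 0.0}
```

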