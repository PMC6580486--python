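# Methods

## Model

The package represents tumor-cell survival as a Boolean series/parallel
circuit over protein targets. A block B is a set of 1–4 targets; a drug d
with binarized inhibition set I(d) *covers* B when B ⊆ I(d). The circuit
predicts a drug's scaled sensitivity as

    ŷ(d) = max { score(B) : B ∈ model, B ⊆ I(d) },   ŷ(d) = 0 if no block covered,

i.e. AND within a block, OR across blocks. Model search minimizes
Σ_d (ŷ(d) − y(d))² over block sets.

Scaled sensitivity maps IC50 (nM) into [0, 1]: 1 when IC50 ≤ Cmax, otherwise
(log10 maxDose − log10 IC50)/log10 maxDose clamped to [0, 1]. The log base
point is 1 nM, so max tested doses at or below 1 nM are rejected. Note the
transform is intentionally discontinuous at the Cmax boundary: sensitivities
strictly between 1 − log10(Cmax)/log10(maxDose) and 1 are unrepresentable.

Drug–target EC50 matrices are binarized with inhibits(d, t) = [EC50(d,t) ≤
Cmax(d)], falling back to the max tested dose when Cmax is unknown; an
absolute nM threshold is available as an alternative rule. Missing pairs are
non-interactions.

### Block scoring

A block's supporters are all drugs covering it. Its score is the shrunk mean

    score(B) = (Σ_{d ∈ supporters} y(d) + α·y0) / (n + α)

with α = 1, y0 = 0 by default: an unsupported-prior estimator that pulls
low-support blocks toward zero and thereby resists one-drug flukes. α = 0
gives the plain mean, under which a noise-free planted instance admits a
model with objective exactly 0. Scores are model-independent, which is what
makes exact search tractable. The PTIM literature leaves the block-scoring
correction factors and the drug-to-block assignment underdetermined; this
scoring and the assignment rule (a drug supports every block it covers;
predictions take the max) are this package's own concrete instantiation,
labelled as such, and every piece is configurable.

### Search

`search_blocks` has two modes.

* **exhaustive** — enumerate every set of ≤ `max_blocks` supported candidate
  blocks (vectorized over coverage masks) and return the global optimum.
  Refused when the number of block sets exceeds `exhaustive_budget`
  (default 2·10⁶). A pure-Python `brute_force_fit` (≤ 12 targets, ≤ 3 blocks
  of ≤ 3 targets) re-derives the same optimum independently and serves as
  the test oracle; the two paths share no enumeration code.
* **beam** — deterministic forward selection with beam width 50. Candidate
  ordering is fixed (descending single-block score, then lexicographic
  target tuple), so results are reproducible without randomness. A depth is
  accepted only when its best state improves the objective by at least
  `min_gain_frac` (default 1%) of the empty-model sum of squares. This
  explained-variance cutoff is the model-selection rule: in the synthetic
  conditions below, true blocks each explain ~20% of the total sum of
  squares and noise-level blocks ~0.1%, so any cutoff between 0.5% and 10%
  separates them; 1% is used throughout. The exhaustive mode deliberately
  omits the cutoff so that its objective remains directly comparable to the
  brute-force oracle.

`mode="auto"` picks exhaustive when it fits the budget. Priors integrate as:
excluded targets are dropped before enumeration; seed targets pre-populate
the beam start state with their best-scoring block; required targets are
guaranteed a block in the final model (their best candidate block is added
if the optimizer left them out); sticky targets are never pruned (the beam
performs no pruning, so stickiness is currently a no-op kept for interface
stability).

Circuit assembly orders blocks by descending score with lexicographic
tie-breaks, and drops a block whose target set is a subset of an
equal-or-higher-scoring block. Blocks at or above a reporting threshold
(default 0.5) form the abbreviated view; the full list is always retained.

## Evidence integration

Rules produce per-target statuses excluded < neutral < seed < required plus
an independent sticky flag, each firing recorded in provenance:

| rule | condition | result |
|---|---|---|
| expression ratio | tumor/normal ≥ 1.5 | keep (else exclude) |
| expression quartile (tumor-only) | Tumor(x) ≥ Q1 | keep (else exclude) |
| exome | high impact ∧ copy gain | required |
| exome | med ∧ gain | seed (sticky) |
| exome | high alone | seed |
| exome | med ∨ gain | sticky only |
| siRNA | viability + 2σ < 1.5 | required |
| phospho | P1 ≥ 1 ∧ \|P1 − P2\| ≤ 0.5 | required |

Targets absent from a table stay neutral — absence of evidence never
excludes. Merging takes the strongest promotion; a neutral from one rule
never overrides another rule's exclusion, and an explicit
excluded-vs-seed/required conflict resolves by policy (default: the
promotion wins, logged). Two formulations of the siRNA cutoff circulate —
an absolute one (viability + 2σ < 1.5, the default) and a mean-centered one
("two standard deviations below the mean", viability < μ − 2σ) — and they
select different targets, so both are offered. The quartile
convention is linear interpolation, configurable, since none is prescribed.

## Dose–response and combination index

Single-agent curves are 4-parameter logistics fit in log10-dose with
`scipy.optimize.least_squares` (bounds: asymptotes in [−0.1, 1.2], slope in
[0.05, 10], midpoint within two decades of the tested range), initialized
from data quartiles with 5 seeded random restarts standing in for manual
curation; a `fixed` mapping pins parameters for manual re-fits. Data never
dropping below 50% viability yield an above-range IC50 sentinel (10× the max
tested dose) rather than an extrapolated number.

Two-point EC50 inference assumes a fixed-asymptote (0 → 1) Hill curve
bracketed at 100 nM and 10 µM. When both inhibitions are informative
(strictly within [0.05, 0.95]) slope and EC50 are solved exactly from the
two logit equations; with one informative point the slope defaults to 1;
with none (≈0% then ≈100%) only the bracket is known and its geometric
midpoint is reported. Both observations on one side of 50% produce
above-/below-range sentinels, and inhibition decreasing by more than 0.05
with dose is flagged non-monotone with no estimate.

The combination index uses the mutually nonexclusive two-term
Chou–Talalay form, CI = d1/Dx1 + d2/Dx2 with
Dx = Dm·(fa/(1 − fa))^(1/m) from each agent's median-effect line (ordinary
least squares on log10(fa/fu) vs log10 d; fa ∈ {0, 1} rows are dropped with
a warning). The third product term is omitted, matching the standard
non-constant-ratio convention (CompuSyn's default output).
CI values are computed for every row but displayed as "N/A" outside the
closed functional range [target EC50, Cmax] of either drug; filtering never
alters values. Functional ranges are taken as given constants, not derived
from pharmacokinetics.

## Combination design

Coverage re-uses the model's binarization rule, so design never disagrees
with the fitted circuit about what a drug inhibits, and every emitted plan
re-verifies its coverage against the inhibition matrix. Plans are capped at
two drugs (toxicity; a `max_drugs` flag allows more). Synergy plans rank by
block score, then coverage tightness (the worst relevant EC50 across the
set, ascending), then drug names — the last tie-break is arbitrary and
labelled as such. Consensus plans require a covered block in every site
circuit and score as the minimum over sites of the best covered block.
Resistance plans require two independent blocks — disjoint target sets by
default, disjoint pathway labels when a target→pathway map is supplied
(pathway independence is otherwise not inferable from screen data). Dose
suggestions are 1.5 × the drug's worst relevant block-target EC50, emitted
only at or below its Cmax.

## Synthetic conditions

The generator plants a known circuit and runs the forward model in reverse.
Default conditions: a 12-target universe; three blocks {T01,T02} at 0.70,
{T03} at 0.60, {T04,T05,T06} at 0.50; 40 drugs; max tested dose 10 µM and
Cmax 10 nM (so the Cmax-collapsed band starts at 0.75 and the planted scores
are representable); truncated-geometric targets-per-drug (mean ≈ 3, max 8),
echoing promiscuous kinase inhibitors; EC50s log-uniform in [1 nM, Cmax] for
inhibited targets; log-normal IC50 noise σ = 0.1 log10 units, applied
multiplicatively to match the log-scaled transform. Drugs covering no block
get IC50 = 10 × max dose (non-hits); true sensitivity 1 draws IC50 uniformly
in (0, Cmax].

Three structural guarantees make the planted circuit identifiable: each
block receives 5 dedicated supporters whose random extra targets complete no
other planted block (otherwise a block's own score can be expressed by no
drug); each multi-target block gets one decoy per member inhibiting the
block minus that member (so every strict sub-block has a zero-sensitivity
supporter and cannot impersonate the block); and null drugs cover no block.
Under these conditions recovery at σ = 0 is exact, and at σ = 0.1 the
recovered-vs-planted target Jaccard reaches 0.8 in 96–100% of 50-seed
windows.

Omics tables are generated so the rules reproduce the planted structure:
planted targets over-express (ratio ≥ 1.5) and pass the phospho rule;
single-point-of-failure targets pass the siRNA rule; off-circuit targets
fail each rule with configurable probability (default 1, deterministic).
The siRNA viability scale is chosen so the absolute threshold separates:
typical knockdowns draw from [1.4, 1.8] and lethal targets are pulled below
1.5 − 2σ by a short fixed-point pass (σ itself depends on the values being
set). On a control-normalized scale near 1 the fixed 1.5 threshold fires for
nearly every target; the threshold's scale is not standardized, and this
choice makes the rule discriminative rather than vacuous.

What the generator does not emulate: real kinome panel structure, correlated
drug-target promiscuity, plate effects, or dose-response curve shapes (IC50s
are generated directly). Passing recovery tests therefore show correctness
of the inference machinery under the stated forward model, not performance
on real screens.

## Numerical choices and limitations

* Search and generation use `numpy.random.default_rng` seeded explicitly;
  identical seeds give byte-identical outputs across runs (CLI manifests
  record config and input hashes for re-runs).
* Objective comparisons between the vectorized search and the pure-Python
  oracle use an absolute tolerance of 1e−9 (float summation order differs).
* Screen correlation treats pairwise coefficients as independent
  observations in a two-sample two-tailed Student's t-test, the convention
  in this kind of heterogeneity analysis; coefficients sharing a model are
  in fact dependent, so the p-values are anti-conservative and should be
  read as descriptive. Spearman is the default; Pearson is available as the
  common alternative and both are reported by the comparison CLI.
* Pairs sharing fewer than 3 drugs are flagged unusable (NaN), never
  silently dropped.
* Hit classification is a closed comparison (IC50 ≤ max tested dose), so
  boundary IC50s count as hits.
* Benchmarks in tests and the acceptance script use 20–40 drug screens,
  4–12-target universes, 50-seed windows, and 50–100 random oracle
  instances — sizes at which the exhaustive oracle remains exact while the
  whole suite runs in well under a minute per component.
* The beam search is a heuristic: it can return a suboptimal block set on
  adversarial instances (verified only lower-bounded by the exhaustive
  optimum). Uncertainty intervals on block scores are out of scope.
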