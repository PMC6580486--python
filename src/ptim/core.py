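"""PTIM model core: sensitivity scaling, block scoring, and circuit search.

The model represents tumor-cell survival as a Boolean series/parallel circuit
over protein targets.  A *block* is a set of 1-4 targets that must all be
inhibited together (AND) to stop proliferation; blocks combine in series (OR)
across the circuit, so covering any one block suffices.  Single-target blocks
are "single points of failure".

Per-drug IC50s are log-scaled into [0, 1] sensitivities:

    y = 1                                           if IC50 <= Cmax
    y = (log10(maxDose) - log10(IC50)) / log10(maxDose)   otherwise

(clamped to [0, 1]; IC50 at or above the max tested dose gives 0).  The drug-
target EC50 matrix is binarized (default: EC50 <= Cmax, falling back to the
max tested dose), every drug then inhibits a Boolean target set.  A drug
*supports* every block whose targets it fully inhibits; a block's score is a
shrunk mean of its supporters' sensitivities, (sum(y) + alpha*y0)/(n + alpha).
The circuit predicts yhat(d) = max score over blocks fully inhibited by d
(0 when none), and the search minimizes sum_d (yhat(d) - y(d))^2 over block
sets, either exactly (vectorized enumeration when the instance is small
enough) or by seeded beam search.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .integration import TargetPriorSet
from .screens import Drug, ScreenResult, TargetProfile, ValidationError

__all__ = [
    "InhibitionMatrix",
    "PtimBlock",
    "PtimCircuit",
    "scale_sensitivity",
    "inverse_scale_sensitivity",
    "scale_screen",
    "binarize_targets",
    "score_block",
    "enumerate_blocks",
    "search_blocks",
    "model_objective",
    "brute_force_fit",
    "assemble_circuit",
    "circuit_to_json",
    "circuit_to_dot",
]

MAX_BLOCK_SIZE = 4


# ---------------------------------------------------------------------------
# sensitivity scaling


def scale_sensitivity(
    ic50: float, max_tested_dose: float, cmax: float | None = None
) -> float:
    """Scale an IC50 (nM) to a [0, 1] sensitivity.

    1 when the IC50 is at or below the clinically achievable Cmax; otherwise
    the log-dose margin (log10 maxDose - log10 IC50) / log10 maxDose, clamped
    to [0, 1].  Lower IC50 means higher sensitivity.  The log base point is
    1 nM, so the max tested dose must exceed 1 nM.
    """
    if max_tested_dose <= 1.0:
        raise ValidationError(
            f"max_tested_dose must exceed 1 nM (log10 base), got {max_tested_dose}"
        )
    if ic50 <= 0:
        raise ValidationError(f"ic50 must be > 0, got {ic50}")
    if cmax is not None and ic50 <= cmax:
        return 1.0
    y = (math.log10(max_tested_dose) - math.log10(ic50)) / math.log10(max_tested_dose)
    return min(1.0, max(0.0, y))


def inverse_scale_sensitivity(y: float, max_tested_dose: float) -> float:
    """IC50 (nM) whose log-branch scaled sensitivity equals ``y`` in [0, 1]."""
    if not (0.0 <= y <= 1.0):
        raise ValidationError(f"sensitivity must be in [0, 1], got {y}")
    return 10.0 ** ((1.0 - y) * math.log10(max_tested_dose))


def scale_screen(screen: ScreenResult, drugs: Mapping[str, Drug]) -> dict[str, float]:
    """Per-drug scaled sensitivities for a whole screen."""
    return {
        d: scale_sensitivity(ic50, drugs[d].max_tested_dose, drugs[d].cmax)
        for d, ic50 in screen.ic50.items()
    }


# ---------------------------------------------------------------------------
# inhibition matrix


class InhibitionMatrix:
    """Binary drugs x targets inhibition matrix."""

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame.astype(bool)

    @property
    def drugs(self) -> list[str]:
        return list(self.frame.index)

    @property
    def targets(self) -> list[str]:
        return list(self.frame.columns)

    def inhibited(self, drug_id: str) -> frozenset[str]:
        row = self.frame.loc[drug_id]
        return frozenset(row.index[row])

    def restrict(self, targets: Iterable[str]) -> "InhibitionMatrix":
        keep = [t for t in self.targets if t in set(targets)]
        return InhibitionMatrix(self.frame[keep])

    def drop(self, targets: Iterable[str]) -> "InhibitionMatrix":
        gone = set(targets)
        return InhibitionMatrix(self.frame[[t for t in self.targets if t not in gone]])


def binarize_targets(
    profiles: Iterable[TargetProfile],
    drugs: Mapping[str, Drug],
    rule: str = "cmax",
    threshold: float | None = None,
) -> InhibitionMatrix:
    """Binarize measured EC50s into inhibits(drug, target) in {0, 1}.

    ``rule="cmax"`` (default): a drug inhibits a target iff its EC50 there is
    at or below the drug's Cmax (falling back to the max tested dose when
    Cmax is unknown).  ``rule="absolute"``: EC50 <= ``threshold`` nM.
    Missing (drug, target) pairs are 0.
    """
    if rule == "absolute" and threshold is None:
        raise ValueError("absolute binarization needs a threshold (nM)")
    targets = sorted({p.target_id for p in profiles})
    frame = pd.DataFrame(False, index=sorted(drugs), columns=targets)
    for p in profiles:
        if p.drug_id not in drugs:
            raise ValidationError(f"profile references unknown drug {p.drug_id!r}")
        drug = drugs[p.drug_id]
        if rule == "cmax":
            cut = drug.cmax if drug.cmax is not None else drug.max_tested_dose
        elif rule == "absolute":
            cut = float(threshold)  # type: ignore[arg-type]
        else:
            raise ValueError(f"unknown binarization rule {rule!r}")
        frame.loc[p.drug_id, p.target_id] = p.ec50 <= cut
    return InhibitionMatrix(frame)


# ---------------------------------------------------------------------------
# blocks and scoring


@dataclass(frozen=True)
class PtimBlock:
    """A 1-4-target AND-block with its shrunk-mean sensitivity score."""

    targets: frozenset[str]
    score: float
    supporting_drugs: frozenset[str]

    def __post_init__(self) -> None:
        if not (1 <= len(self.targets) <= MAX_BLOCK_SIZE):
            raise ValidationError(f"block must have 1-{MAX_BLOCK_SIZE} targets: {set(self.targets)}")
        if not (0.0 <= self.score <= 1.0):
            raise ValidationError(f"block score must be in [0, 1], got {self.score}")

    @property
    def block_kind(self) -> str:
        return "single_point_of_failure" if len(self.targets) == 1 else "parallel"

    @property
    def sorted_targets(self) -> tuple[str, ...]:
        return tuple(sorted(self.targets))


def score_block(
    block_targets: Iterable[str],
    matrix: InhibitionMatrix,
    y: Mapping[str, float],
    alpha: float = 1.0,
    y0: float = 0.0,
) -> PtimBlock | None:
    """Score one candidate block; None when no drug supports it.

    Supporters are the drugs whose inhibited target set contains the whole
    block.  The score is the shrunk mean (sum(y_supporters) + alpha*y0) /
    (n + alpha); alpha=0 reduces to the arithmetic mean.
    """
    targets = frozenset(block_targets)
    missing = targets - set(matrix.targets)
    if missing:
        raise ValidationError(f"block targets not in matrix: {sorted(missing)}")
    sub = matrix.frame[list(targets)]
    mask = sub.all(axis=1)
    supporters = frozenset(sub.index[mask])
    if not supporters:
        return None
    total = sum(y[d] for d in supporters)
    score = (total + alpha * y0) / (len(supporters) + alpha)
    return PtimBlock(targets=targets, score=score, supporting_drugs=supporters)


def _candidate_arrays(
    matrix: InhibitionMatrix,
    y: Mapping[str, float],
    max_block_size: int,
    alpha: float,
    y0: float,
) -> tuple[list[frozenset[str]], np.ndarray, np.ndarray]:
    """All supported blocks of size <= max_block_size, with scores and coverage masks."""
    drugs = matrix.drugs
    inh = matrix.frame.to_numpy()  # drugs x targets bool
    yv = np.array([y[d] for d in drugs])
    targets = matrix.targets
    blocks: list[frozenset[str]] = []
    scores: list[float] = []
    masks: list[np.ndarray] = []
    idx = range(len(targets))
    for k in range(1, min(max_block_size, len(targets)) + 1):
        for combo in itertools.combinations(idx, k):
            cover = inh[:, combo].all(axis=1)
            n = int(cover.sum())
            if n == 0:
                continue
            blocks.append(frozenset(targets[i] for i in combo))
            scores.append((float(yv[cover].sum()) + alpha * y0) / (n + alpha))
            masks.append(cover)
    return blocks, np.array(scores), (
        np.array(masks) if masks else np.zeros((0, len(drugs)), dtype=bool)
    )


def enumerate_blocks(
    matrix: InhibitionMatrix,
    y: Mapping[str, float],
    max_block_size: int = MAX_BLOCK_SIZE,
    alpha: float = 1.0,
    y0: float = 0.0,
) -> list[PtimBlock]:
    """All supported candidate blocks, scored."""
    blocks, scores, masks = _candidate_arrays(matrix, y, max_block_size, alpha, y0)
    drugs = np.array(matrix.drugs)
    return [
        PtimBlock(b, float(s), frozenset(drugs[m]))
        for b, s, m in zip(blocks, scores, masks)
    ]


def model_objective(
    blocks: Sequence[PtimBlock], matrix: InhibitionMatrix, y: Mapping[str, float]
) -> float:
    """Sum of squared residuals of the circuit's predictions on a screen."""
    sse = 0.0
    for d in matrix.drugs:
        inhibited = matrix.inhibited(d)
        yhat = max((b.score for b in blocks if b.targets <= inhibited), default=0.0)
        sse += (yhat - y[d]) ** 2
    return sse


def _sse_for_selection(
    sel: np.ndarray, scores: np.ndarray, masks: np.ndarray, yv: np.ndarray
) -> float:
    if sel.size == 0:
        return float((yv**2).sum())
    yhat = (scores[sel, None] * masks[sel]).max(axis=0)
    return float(((yhat - yv) ** 2).sum())


def _exhaustive_select(
    scores: np.ndarray, masks: np.ndarray, yv: np.ndarray, max_blocks: int,
    chunk: int = 200_000,
) -> tuple[tuple[int, ...], float]:
    """Global optimum over block sets of size <= max_blocks (vectorized)."""
    n = len(scores)
    best_sel: tuple[int, ...] = ()
    best_sse = float((yv**2).sum())  # empty model
    contrib = scores[:, None] * masks  # n_blocks x n_drugs
    for k in range(1, max_blocks + 1):
        if k > n:
            break
        combos = itertools.combinations(range(n), k)
        while True:
            idx = np.fromiter(
                itertools.chain.from_iterable(itertools.islice(combos, chunk)),
                dtype=np.int64,
            ).reshape(-1, k)
            if idx.size == 0:
                break
            yhat = contrib[idx[:, 0]]
            for j in range(1, k):
                yhat = np.maximum(yhat, contrib[idx[:, j]])
            sse = ((yhat - yv) ** 2).sum(axis=1)
            i = int(np.argmin(sse))
            if sse[i] < best_sse - 1e-15:
                best_sse = float(sse[i])
                best_sel = tuple(int(v) for v in idx[i])
            if idx.shape[0] < chunk:
                break
    return best_sel, best_sse


def _beam_select(
    scores: np.ndarray,
    masks: np.ndarray,
    yv: np.ndarray,
    max_blocks: int,
    beam_width: int,
    order: np.ndarray,
    forced_start: Sequence[int] = (),
    min_gain_frac: float = 0.0,
) -> tuple[tuple[int, ...], float]:
    """Seeded beam search: forward selection keeping the best ``beam_width`` states.

    A depth is only accepted when its best state improves the objective by at
    least ``min_gain_frac`` of the empty-model sum of squares — an explained-
    variance cutoff that stops noise-level blocks from piling onto the model.
    """
    gain_tol = max(min_gain_frac * float((yv**2).sum()), 1e-12)
    contrib = scores[:, None] * masks
    start = tuple(sorted(forced_start))
    start_yhat = (
        contrib[list(start)].max(axis=0) if start else np.zeros_like(yv)
    )
    beam: dict[tuple[int, ...], np.ndarray] = {start: start_yhat}
    best_sel, best_sse = start, float(((start_yhat - yv) ** 2).sum())
    for _ in range(len(start), max_blocks):
        candidates: dict[tuple[int, ...], np.ndarray] = {}
        for sel, yhat in beam.items():
            new_yhat = np.maximum(yhat[None, :], contrib)  # n_blocks x n_drugs
            sse = ((new_yhat - yv) ** 2).sum(axis=1)
            take = np.argsort(sse, kind="stable")[: beam_width]
            for b in take:
                b = int(b)
                if b in sel:
                    continue
                key = tuple(sorted(sel + (b,)))
                if key not in candidates:
                    candidates[key] = new_yhat[b]
        if not candidates:
            break
        ranked = sorted(
            candidates.items(),
            key=lambda kv: (float(((kv[1] - yv) ** 2).sum()), [order[i] for i in kv[0]]),
        )
        beam = dict(ranked[:beam_width])
        top_sel, top_yhat = ranked[0]
        top_sse = float(((top_yhat - yv) ** 2).sum())
        if top_sse < best_sse - gain_tol:
            best_sel, best_sse = top_sel, top_sse
        else:
            break  # no worthwhile improvement at this depth
    return best_sel, best_sse


def search_blocks(
    matrix: InhibitionMatrix,
    y: Mapping[str, float],
    priors: TargetPriorSet | None = None,
    max_block_size: int = MAX_BLOCK_SIZE,
    max_blocks: int = 4,
    mode: str = "auto",
    alpha: float = 1.0,
    y0: float = 0.0,
    beam_width: int = 50,
    exhaustive_budget: int = 2_000_000,
    min_gain_frac: float = 0.01,
) -> tuple[list[PtimBlock], float]:
    """Search for the block set minimizing the circuit's squared error.

    Excluded targets (from ``priors``) are removed before enumeration; seed
    targets pre-populate the beam's start state with their best-scoring block;
    required targets are guaranteed a block in the returned model (their best
    candidate block is force-added if the optimizer left them out).

    ``mode``: "exhaustive" enumerates every block set of <= ``max_blocks``
    supported blocks (refused over ``exhaustive_budget`` combinations);
    "beam" runs deterministic beam search; "auto" picks exhaustive when it
    fits the budget.  Returns (blocks, objective value).
    """
    work = matrix
    required: set[str] = set()
    seeds: set[str] = set()
    if priors is not None:
        work = matrix.drop(priors.excluded & set(matrix.targets))
        required = priors.required & set(work.targets)
        seeds = priors.seeds & set(work.targets)
    if not work.targets:
        raise ValidationError("candidate target set is empty after applying priors")

    blocks, scores, masks = _candidate_arrays(work, y, max_block_size, alpha, y0)
    drugs = np.array(work.drugs)
    yv = np.array([y[d] for d in work.drugs])
    if not blocks:
        return [], float((yv**2).sum())

    # deterministic candidate ordering: descending score, then lexicographic
    keys = sorted(
        range(len(blocks)), key=lambda i: (-scores[i], tuple(sorted(blocks[i])))
    )
    rank = np.empty(len(blocks), dtype=np.int64)
    rank[keys] = np.arange(len(blocks))

    n_sets = sum(comb(len(blocks), k) for k in range(1, max_blocks + 1))
    if mode == "auto":
        mode = "exhaustive" if n_sets <= exhaustive_budget else "beam"
    if mode == "exhaustive":
        if n_sets > exhaustive_budget:
            raise ValidationError(
                f"exhaustive search over {n_sets} block sets exceeds the budget "
                f"({exhaustive_budget}); use beam mode"
            )
        sel, sse = _exhaustive_select(scores, masks, yv, max_blocks)
    elif mode == "beam":
        forced = []
        for t in sorted(seeds):
            containing = [i for i, b in enumerate(blocks) if t in b]
            if containing:
                forced.append(min(containing, key=lambda i: (rank[i],)))
        sel, sse = _beam_select(
            scores, masks, yv, max_blocks, beam_width, rank,
            forced_start=sorted(set(forced)), min_gain_frac=min_gain_frac,
        )
    else:
        raise ValueError(f"unknown search mode {mode!r}")

    chosen = list(sel)
    covered = set().union(*(blocks[i] for i in chosen)) if chosen else set()
    for t in sorted(required - covered):
        containing = [i for i, b in enumerate(blocks) if t in b and i not in chosen]
        if containing:
            chosen.append(min(containing, key=lambda i: (rank[i],)))
            covered |= blocks[chosen[-1]]
    result = [
        PtimBlock(blocks[i], float(scores[i]), frozenset(drugs[masks[i]]))
        for i in chosen
    ]
    sse = _sse_for_selection(np.array(chosen, dtype=np.int64), scores, masks, yv)
    return result, float(sse)


def brute_force_fit(
    matrix: InhibitionMatrix,
    y: Mapping[str, float],
    max_blocks: int = 3,
    max_block_size: int = 3,
    alpha: float = 1.0,
    y0: float = 0.0,
    max_targets: int = 12,
) -> tuple[list[PtimBlock], float]:
    """Pure-Python exhaustive oracle over all block sets of <= max_blocks blocks.

    Independent of the vectorized search path: candidate blocks, scores,
    predictions and the objective are all recomputed with plain Python
    loops.  Refuses instances with more than ``max_targets`` targets.
    """
    targets = matrix.targets
    if len(targets) > max_targets:
        raise ValidationError(
            f"brute force refused: {len(targets)} targets > max_targets={max_targets}"
        )
    inhibited = {d: matrix.inhibited(d) for d in matrix.drugs}
    candidates: list[PtimBlock] = []
    for k in range(1, min(max_block_size, len(targets)) + 1):
        for combo in itertools.combinations(sorted(targets), k):
            supp = [d for d, s in inhibited.items() if set(combo) <= s]
            if not supp:
                continue
            score = (sum(y[d] for d in supp) + alpha * y0) / (len(supp) + alpha)
            candidates.append(PtimBlock(frozenset(combo), score, frozenset(supp)))
    best: list[PtimBlock] = []
    best_sse = sum(y[d] ** 2 for d in matrix.drugs)
    for k in range(1, max_blocks + 1):
        for subset in itertools.combinations(candidates, k):
            sse = 0.0
            for d in matrix.drugs:
                yhat = 0.0
                for b in subset:
                    if b.targets <= inhibited[d] and b.score > yhat:
                        yhat = b.score
                sse += (yhat - y[d]) ** 2
            if sse < best_sse - 1e-15:
                best_sse = sse
                best = list(subset)
    return best, best_sse


# ---------------------------------------------------------------------------
# circuit assembly and export


@dataclass
class PtimCircuit:
    """An ordered series of blocks (descending score) with provenance."""

    blocks: list[PtimBlock]
    objective: float = math.nan
    provenance: dict = field(default_factory=dict)

    @property
    def targets(self) -> set[str]:
        return set().union(*(b.targets for b in self.blocks)) if self.blocks else set()

    def predict(self, inhibited: Iterable[str]) -> float:
        """Predicted sensitivity of a drug inhibiting the given target set."""
        s = frozenset(inhibited)
        return max((b.score for b in self.blocks if b.targets <= s), default=0.0)

    def abbreviated(self, threshold: float = 0.5) -> list[PtimBlock]:
        """Reporting view: blocks at or above the emission threshold."""
        return [b for b in self.blocks if b.score >= threshold]


def assemble_circuit(
    blocks: Iterable[PtimBlock],
    priors: TargetPriorSet | None = None,
    objective: float = math.nan,
    provenance: dict | None = None,
) -> PtimCircuit:
    """Order, tie-break, and de-duplicate blocks into a circuit.

    Blocks sort by descending score, ties broken lexicographically on sorted
    target names.  A block is dropped when its target set is a subset of an
    equal-or-higher-scoring other block (it adds no information).  Excluded
    targets must not appear; required targets must appear in at least one
    block.
    """
    ordered = sorted(set(blocks), key=lambda b: (-b.score, b.sorted_targets))
    kept: list[PtimBlock] = []
    for b in ordered:
        redundant = any(
            b.targets <= other.targets and other.score >= b.score and b != other
            for other in ordered
        )
        if not redundant:
            kept.append(b)
    circuit = PtimCircuit(kept, objective=objective, provenance=provenance or {})
    if priors is not None:
        leaked = circuit.targets & priors.excluded
        if leaked:
            raise ValidationError(f"excluded targets present in circuit: {sorted(leaked)}")
        missing = priors.required - circuit.targets
        if missing:
            raise ValidationError(f"required targets missing from circuit: {sorted(missing)}")
    return circuit


def circuit_to_json(circuit: PtimCircuit) -> str:
    payload = {
        "blocks": [
            {
                "targets": list(b.sorted_targets),
                "score": b.score,
                "kind": b.block_kind,
                "supporting_drugs": sorted(b.supporting_drugs),
            }
            for b in circuit.blocks
        ],
        "targets": sorted(circuit.targets),
        "objective": None if math.isnan(circuit.objective) else circuit.objective,
        "provenance": circuit.provenance,
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def circuit_to_dot(circuit: PtimCircuit, name: str = "ptim") -> str:
    """Graphviz DOT for the series/parallel circuit diagram.

    Blocks are left-to-right in score order; targets within a block stack as
    a parallel group (record shape).
    """
    lines = [f"digraph {name} {{", "  rankdir=LR;", "  node [shape=record];"]
    prev = "IN"
    lines.append('  IN [shape=point, label=""];')
    for i, b in enumerate(circuit.blocks):
        label = "|".join(b.sorted_targets)
        lines.append(f'  block{i} [label="{{{label}}}|score {b.score:.3f}"];')
        lines.append(f"  {prev} -> block{i};")
        prev = f"block{i}"
    lines.append('  OUT [shape=point, label=""];')
    lines.append(f"  {prev} -> OUT;")
    lines.append("}")
    return "\n".join(lines) + "\n"
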