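"""Phenotypic adaptation from MIC trajectories.

A doubling-dilution MIC series read every 200 generations is a step
function; "reaching the maximum" is therefore defined on the sampled grid
with no interpolation.  Per replicate, the plateau is the maximum MIC ever
observed and the earliest generation attaining it.  The arm-level plateau
MIC is the modal replicate plateau (ties broken toward the lower MIC); two
rules date the arm-level plateau generation:

- ``"all"`` (default): the earliest sampled generation by which *every*
  replicate has attained the consensus plateau;
- ``"first"``: the earliest generation at which *any* replicate attains it.

Replicates can disagree (one tube can jump a dilution step early), so both
datings are always carried in the summary and surfaced in the report rather
than silently resolved.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .io_formats import MicTable

logger = logging.getLogger(__name__)

PLATEAU_RULES = ("all", "first")


@dataclass
class FitnessSummary:
    antibiotic: str
    initial_mic: float
    plateau_mic: float
    plateau_generation: int
    fold_change: float
    rule: str
    plateau_generation_by_rule: dict[str, int] = field(default_factory=dict)
    per_replicate_plateaus: dict[str, tuple[float, int]] = field(default_factory=dict)
    replicates_disagree: bool = False

    def __post_init__(self) -> None:
        if self.plateau_mic < self.initial_mic:
            raise ValueError("plateau MIC cannot be below the initial MIC")


def _modal_low(values: list[float]) -> float:
    """Mode, ties broken toward the lower value."""
    counts = Counter(values)
    best = max(counts.values())
    return min(v for v, c in counts.items() if c == best)


def plateau(table: MicTable, rule: str = "all") -> FitnessSummary:
    """Detect the MIC plateau of one arm.

    Missing cells are excluded per replicate; an all-missing replicate is
    dropped with a warning, and an error is raised if none remain.
    """
    if rule not in PLATEAU_RULES:
        raise ValueError(f"unknown plateau rule {rule!r}")
    gens = np.asarray(table.generations)
    per_rep: dict[str, tuple[float, int]] = {}
    cummax_by_rep: dict[str, np.ndarray] = {}
    initial_values: list[float] = []
    for j, rep in enumerate(table.replicate_ids):
        col = table.values[:, j]
        if np.all(np.isnan(col)):
            logger.warning("replicate %s has no MIC measurements; excluded", rep)
            continue
        filled = np.where(np.isnan(col), -np.inf, col)
        rep_max = float(np.nanmax(col))
        rep_gen = int(gens[int(np.argmax(filled == rep_max))])
        per_rep[rep] = (rep_max, rep_gen)
        cummax_by_rep[rep] = np.maximum.accumulate(filled)
        if not np.isnan(col[0]):
            initial_values.append(float(col[0]))
    if not per_rep:
        raise ValueError("no replicate with any MIC measurement")

    consensus = _modal_low([m for m, _ in per_rep.values()])
    initial = _modal_low(initial_values) if initial_values else consensus

    attained = {rep: cummax_by_rep[rep] >= consensus for rep in per_rep}
    gen_by_rule: dict[str, int] = {}
    all_mask = np.logical_and.reduce(list(attained.values()))
    any_mask = np.logical_or.reduce(list(attained.values()))
    for name, mask in (("all", all_mask), ("first", any_mask)):
        idx = np.flatnonzero(mask)
        # a replicate whose maximum stays below consensus never attains it;
        # fall back to the latest sampled generation in that degenerate case
        gen_by_rule[name] = int(gens[idx[0]]) if idx.size else int(gens[-1])

    disagree = len({g for _, g in per_rep.values()}) > 1
    return FitnessSummary(
        antibiotic=table.antibiotic, initial_mic=initial, plateau_mic=consensus,
        plateau_generation=gen_by_rule[rule], fold_change=consensus / initial,
        rule=rule, plateau_generation_by_rule=gen_by_rule,
        per_replicate_plateaus=per_rep, replicates_disagree=disagree)


def adaptation_ratio(fast: FitnessSummary, slow: FitnessSummary) -> float | None:
    """Relative adaptation rate, rate being 1 / time-to-plateau.

    Returns slow.plateau_generation / fast.plateau_generation; None
    (undefined) when the fast arm plateaus at generation 0.
    """
    if fast.plateau_generation == 0:
        return None
    if slow.plateau_generation <= 0:
        raise ValueError("slow arm plateau generation must be positive")
    return slow.plateau_generation / fast.plateau_generation
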