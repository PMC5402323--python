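"""Parameter-recovery experiments: simulate a known mutation-accumulation
regime, push it through the full calling -> filtering -> identification
chain, and measure how well the pipeline recovers the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calling import CallingThresholds, call_table
from .denovo import filter_shared, identify_denovo
from .simulate import (ArmSpec, SimulationConfig, generate_reference,
                       simulate_arm, simulate_pileup)


@dataclass(frozen=True)
class RecoveryResult:
    """Per-lineage identified de novo counts for the treated arm."""

    counts: list[int]
    expected: float  # rate x generations

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts))

    @property
    def se(self) -> float:
        return float(np.std(self.counts, ddof=1) / np.sqrt(len(self.counts)))


def denovo_recovery_experiment(n_lineages: int = 50, rate: float = 0.01,
                               generations: int = 2000,
                               genome_length: int = 200_000,
                               coverage: float = 200.0,
                               n_control_lineages: int = 2,
                               seed: int = 0) -> RecoveryResult:
    """Recover the per-lineage de novo count of an antibiotic regime.

    Simulates one selected arm at the given fixed-mutation rate plus a small
    control arm (so the cross-arm shared filter has something to work
    against), produces error-free pileups at every sampled generation, calls
    both tiers, filters shared/baseline variants and identifies de novo
    mutations; returns the identified count per treated lineage.
    """
    cfg = SimulationConfig(
        genome_length=genome_length, n_lineages=n_lineages,
        arms=(ArmSpec("T", rate, True), ArmSpec("C", 0.003, False)),
        generations_total=generations, sampling_interval=200,
        n_preexisting_snvs=25, coverage_mean=coverage,
        sequencing_error_rate=0.0, background_sites=10, seed=seed)
    ref = generate_reference(cfg)
    thresholds = CallingThresholds(error_rate=0.0)

    truth = dict(simulate_arm(ref, cfg, "T"))
    control = simulate_arm(ref, cfg, "C")
    for lid in list(control)[:n_control_lineages]:
        truth[lid] = control[lid]

    fixed, lenient = {}, {}
    for lid, recs in truth.items():
        fixed[lid], lenient[lid] = [], []
        for g in cfg.sampled_generations:
            pile = simulate_pileup(ref, recs, g, cfg)
            fixed[lid] += call_table(pile, thresholds, "fixed", lid, g)
            lenient[lid] += call_table(pile, thresholds, "lenient", lid, g)

    retained, _removed = filter_shared(fixed)
    muts = identify_denovo(retained, lenient)
    treated = cfg.lineage_ids("T")
    per_lineage = {lid: 0 for lid in treated}
    for m in muts:
        if m.lineage_id in per_lineage:
            per_lineage[m.lineage_id] += 1
    return RecoveryResult(counts=[per_lineage[lid] for lid in treated],
                          expected=rate * generations)
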