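"""End-to-end orchestration: simulate -> call -> denovo -> annotate -> stats
-> fitness -> report, as one reproducible run under a single YAML config.

Every stage writes its artifacts under the output directory and can be
resumed from them: ``run_all(..., start_stage="denovo")`` reloads the
upstream files instead of recomputing them, and produces byte-identical
downstream outputs to a fresh full run (all randomness is keyed by the
config seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate import annotate_denovo
from .calling import CallingThresholds, call_table
from .denovo import DeNovoMutation, filter_shared, identify_denovo
from .fitness import FitnessSummary, plateau
from .io_formats import (read_callsets, read_mic_table, read_pileup,
                         read_reference, write_callset_vcf, write_mic_table,
                         write_pileup, write_reference, write_report,
                         write_truth_vcf)
from .simulate import (SimulationConfig, generate_reference, simulate_arm,
                       simulate_mic_trajectory, simulate_pileup)
from .stats import EvolutionStats, summarize_arm

logger = logging.getLogger(__name__)

STAGES = ("simulate", "call", "denovo", "annotate", "stats", "fitness", "report")


@dataclass
class RunManifest:
    config_digest: str
    tool_version: str
    seed: int
    stage_outputs: dict[str, list[str]] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _now() -> str:
    return datetime.now(timezone.utc).isoformat()


def run_all(config: SimulationConfig | str, outdir,
            thresholds: CallingThresholds | None = None,
            start_stage: str = "simulate") -> RunManifest:
    """Execute the full pipeline; returns the run manifest.

    ``config`` may be a SimulationConfig or a path to its YAML form.
    ``start_stage`` resumes from a later stage, reloading prior outputs.
    """
    if not isinstance(config, SimulationConfig):
        config = SimulationConfig.from_yaml(config)
    if start_stage not in STAGES:
        raise ValueError(f"unknown stage {start_stage!r}")
    thresholds = thresholds or CallingThresholds(
        error_rate=max(config.sequencing_error_rate, 1e-6))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config_yaml = config.to_yaml()
    (outdir / "config.yaml").write_text(config_yaml)
    manifest = RunManifest(
        config_digest=hashlib.sha256(config_yaml.encode()).hexdigest(),
        tool_version=__version__, seed=config.seed, started=_now())
    start_idx = STAGES.index(start_stage)
    current_stage = start_stage
    sampled = config.sampled_generations
    arm_of = {lid: a.label for a in config.arms for lid in config.lineage_ids(a.label)}

    try:
        # -- simulate -------------------------------------------------------
        sim_dir = outdir / "simulate"
        if start_idx <= STAGES.index("simulate"):
            sim_dir.mkdir(exist_ok=True)
            ref = generate_reference(config)
            write_reference(ref, sim_dir / "reference.fasta", sim_dir / "reference.gff3")
            truth_by_arm = {}
            mic_tables = {}
            for arm in config.arms:
                truth = simulate_arm(ref, config, arm.label)
                truth_by_arm[arm.label] = truth
                for lineage, records in truth.items():
                    write_truth_vcf(records, ref.id, len(ref), sampled,
                                    sim_dir / f"truth_{lineage}.vcf")
                    for g in sampled:
                        pile = simulate_pileup(ref, records, g, config)
                        write_pileup(pile, sim_dir / f"pileup_{lineage}_g{g}.tsv")
                mic = simulate_mic_trajectory(truth, config, arm.label)
                mic_tables[arm.label] = mic
                write_mic_table(mic, sim_dir / f"mic_{arm.label}.csv")
            logger.info("simulate: %d arms x %d lineages, genome %d bp",
                        len(config.arms), config.n_lineages, len(ref))
        else:
            ref = read_reference(sim_dir / "reference.fasta", sim_dir / "reference.gff3")
        manifest.stage_outputs["simulate"] = sorted(
            str(p) for p in sim_dir.iterdir())

        # -- call -----------------------------------------------------------
        current_stage = "call"
        call_dir = outdir / "call"
        if start_idx <= STAGES.index("call"):
            call_dir.mkdir(exist_ok=True)
            n_calls = {"fixed": 0, "lenient": 0}
            for lineage, arm in arm_of.items():
                for g in sampled:
                    pile = read_pileup(sim_dir / f"pileup_{lineage}_g{g}.tsv")
                    for tier in ("fixed", "lenient"):
                        calls = call_table(pile, thresholds, tier, lineage, g)
                        n_calls[tier] += len(calls)
                        write_callset_vcf(calls, ref.id, len(ref),
                                          call_dir / f"{tier}_{lineage}_g{g}.vcf")
            logger.info("call: %d fixed-tier and %d lenient-tier calls",
                        n_calls["fixed"], n_calls["lenient"])
        manifest.stage_outputs["call"] = sorted(str(p) for p in call_dir.iterdir())

        # -- denovo ---------------------------------------------------------
        current_stage = "denovo"
        denovo_path = outdir / "denovo.tsv"
        removed_path = outdir / "removed_shared.tsv"
        if start_idx <= STAGES.index("denovo"):
            fixed_sets = {}
            lenient_sets = {}
            for lineage in arm_of:
                fixed_sets[lineage] = read_callsets(
                    [call_dir / f"fixed_{lineage}_g{g}.vcf" for g in sampled])
                lenient_sets[lineage] = read_callsets(
                    [call_dir / f"lenient_{lineage}_g{g}.vcf" for g in sampled])
            retained, removed = filter_shared(fixed_sets, arm_of)
            muts = identify_denovo(retained, lenient_sets)
            _write_denovo_tsv(muts, arm_of, denovo_path)
            pd.DataFrame(removed).to_csv(removed_path, sep="\t", index=False)
            logger.info("denovo: %d shared/baseline variant identities removed, "
                        "%d de novo mutations retained", len(removed), len(muts))
        else:
            muts = _read_denovo_tsv(denovo_path)
        manifest.stage_outputs["denovo"] = [str(denovo_path), str(removed_path)]

        # -- annotate -------------------------------------------------------
        current_stage = "annotate"
        annotated_path = outdir / "denovo_annotated.tsv"
        if start_idx <= STAGES.index("annotate"):
            annotate_denovo(muts, ref)
            _write_denovo_tsv(muts, arm_of, annotated_path)
        else:
            muts = _read_denovo_tsv(annotated_path)
        manifest.stage_outputs["annotate"] = [str(annotated_path)]

        # -- stats ----------------------------------------------------------
        current_stage = "stats"
        stats_path = outdir / "stats.json"
        denovo_by_arm = {a.label: [m for m in muts if arm_of[m.lineage_id] == a.label]
                         for a in config.arms}
        if start_idx <= STAGES.index("stats"):
            stats_by_arm = {}
            for a in config.arms:
                stats_by_arm[a.label] = summarize_arm(
                    a.label, denovo_by_arm[a.label], config.n_lineages,
                    config.generations_total, ref)
            with open(stats_path, "w") as fh:
                json.dump({arm: dataclasses.asdict(s)
                           for arm, s in stats_by_arm.items()},
                          fh, indent=2, sort_keys=True)
        else:
            stats_by_arm = _read_stats_json(stats_path)
        manifest.stage_outputs["stats"] = [str(stats_path)]

        # -- fitness --------------------------------------------------------
        current_stage = "fitness"
        fitness_path = outdir / "fitness.json"
        fitness_by_arm: dict[str, FitnessSummary] = {}
        for a in config.arms:
            mic = read_mic_table(sim_dir / f"mic_{a.label}.csv",
                                 antibiotic=a.antibiotic or a.label)
            fitness_by_arm[a.label] = plateau(mic)
        if start_idx <= STAGES.index("fitness"):
            doc = {arm: dataclasses.asdict(fs) for arm, fs in fitness_by_arm.items()}
            selected = [a.label for a in config.arms if a.selected]
            if len(selected) >= 2:
                by_first = {lab: fitness_by_arm[lab].plateau_generation_by_rule["first"]
                            for lab in selected}
                fast = min(by_first, key=by_first.get)
                slow = max(by_first, key=by_first.get)
                if by_first[fast] > 0:
                    doc["adaptation_ratio"] = {
                        "fast_arm": fast, "slow_arm": slow,
                        "ratio": by_first[slow] / by_first[fast]}
            with open(fitness_path, "w") as fh:
                json.dump(doc, fh, indent=2, sort_keys=True)
        manifest.stage_outputs["fitness"] = [str(fitness_path)]

        # -- report ---------------------------------------------------------
        current_stage = "report"
        report_dir = outdir / "report"
        write_report(stats_by_arm, report_dir, denovo_by_arm=denovo_by_arm,
                     fitness_by_arm=fitness_by_arm, sampled_generations=sampled)
        manifest.stage_outputs["report"] = sorted(str(p) for p in report_dir.iterdir())
        for arm, s in sorted(stats_by_arm.items()):
            logger.info(
                "arm %s: mean de novo %.2f/lineage, rate %.2e/bp/gen, Ti/Tv %s, "
                "Ka/Ks %s", arm, s.mean_denovo_count, s.rate_per_bp_per_generation,
                f"{s.ti_tv:.2f}" if s.ti_tv is not None else "undefined",
                f"{s.ka_ks:.2f}" if s.ka_ks is not None else "undefined")
    except Exception as exc:
        manifest.finished = _now()
        manifest.write(outdir / "manifest.json")  # partial manifest for audit
        raise RuntimeError(
            f"pipeline aborted in stage {current_stage!r}: {exc}") from exc

    manifest.finished = _now()
    manifest.write(outdir / "manifest.json")
    return manifest


_DENOVO_COLS = ["lineage_id", "arm", "position", "ref_allele", "alt_allele",
                "variant_type", "first_seen", "last_seen", "fixed_at",
                "consequence", "spectrum_class", "is_transition", "gene_id"]


def _write_denovo_tsv(muts, arm_of, path) -> None:
    rows = []
    for m in muts:
        r = dataclasses.asdict(m)
        r["arm"] = arm_of.get(m.lineage_id, "")
        rows.append(r)
    pd.DataFrame(rows, columns=_DENOVO_COLS).to_csv(path, sep="\t", index=False)


def _read_denovo_tsv(path) -> list[DeNovoMutation]:
    df = pd.read_csv(path, sep="\t")
    muts = []
    for _, r in df.iterrows():
        muts.append(DeNovoMutation(
            lineage_id=str(r.lineage_id), position=int(r.position),
            ref_allele=str(r.ref_allele), alt_allele=str(r.alt_allele),
            variant_type=str(r.variant_type), first_seen=int(r.first_seen),
            last_seen=int(r.last_seen),
            fixed_at=None if pd.isna(r.fixed_at) else int(r.fixed_at),
            consequence=None if pd.isna(r.consequence) else str(r.consequence),
            spectrum_class=None if pd.isna(r.spectrum_class) else str(r.spectrum_class),
            is_transition=None if pd.isna(r.is_transition) else bool(r.is_transition),
            gene_id=None if pd.isna(r.gene_id) else str(r.gene_id)))
    return muts


def _read_stats_json(path) -> dict[str, EvolutionStats]:
    with open(path) as fh:
        doc = json.load(fh)
    out = {}
    for arm, d in doc.items():
        d["site_counts"] = tuple(d["site_counts"])
        out[arm] = EvolutionStats(**d)
    return out
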