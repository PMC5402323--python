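"""Synthetic ALE (adaptive laboratory evolution) dataset generator.

Emulates the statistical structure of a serial-passage mutation-accumulation
experiment on an annotated bacterial genome: three arms (two antibiotic, one
control), several replicate lineages per arm, fixed de novo mutations
arising as a Poisson process per genome per generation, a set of
pre-existing SNVs shared by every lineage, Poisson-coverage pileups with
symmetric base-miscall noise, and MIC trajectories that double with each
resistance fixation and plateau at a cap.

Population genetics follow an origin-fixation picture: the sampled
population is monomorphic between events.  Neutral events fix instantly at
their origin generation; resistance events in selected arms optionally
sweep logistically from 1/N to 1 over a configurable number of generations.

Seeding: one master seed; every stream is a ``numpy`` ``default_rng`` keyed
by ``[seed, stream-tag, ...]`` counters (genome=101, pre-existing=202,
arm/lineage=303, pileup=404), so any lineage or timepoint can be
regenerated independently of the others.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

from .io_formats import MicTable, ReferenceGenome, CdsFeature, classify_variant_type

_BASES = ("A", "C", "G", "T")
_STOPS = ("TAA", "TAG", "TGA")

#: substitution-class weights over the six strand-collapsed classes,
#: ordered as annotate.SPECTRUM_LABELS (AT→CG, AT→GC, AT→TA, CG→AT, CG→GC, CG→TA)
SUBSTITUTION_PRESETS: dict[str, tuple[float, ...]] = {
    "uniform": (1, 1, 1, 1, 1, 1),
    # CG→AT-transversion-enriched profile of the kind seen in L. casei Zhang
    # mutation-accumulation data (dominant CG→AT and AT→CG transversions,
    # substantial CG→TA transitions)
    "lcasei_zhang": (0.262, 0.048, 0.024, 0.408, 0.044, 0.214),
}


@dataclass(frozen=True)
class ArmSpec:
    """One experimental arm: a label, a fixed-mutation supply rate
    (events per genome per generation) and whether selection acts
    (antibiotic arms sweep resistance mutations; the control does not)."""

    label: str
    rate: float
    selected: bool = False
    antibiotic: str | None = None

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"arm {self.label}: rate must be non-negative")


DEFAULT_ARMS = (
    ArmSpec("A", 0.01, True, "amoxicillin"),
    ArmSpec("G", 0.01, True, "gentamicin"),
    ArmSpec("C", 0.003, False, None),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic ALE run.

    Defaults mirror the experiment the analysis is built for: three arms
    sampled every 200 generations to 2000, fixed-mutation supply 0.01
    events/genome/generation under antibiotics vs 0.003 in the control,
    MIC starting at 2 ug/mL and doubling per resistance fixation up to a
    32 ug/mL plateau, ~200x sequencing depth with 0.3% base-call error.
    The genome is desk-scale (100 kb at 46.4% GC, ~80% coding) rather than
    the full 2.86 Mb chromosome; the supply rate is per genome, so event
    counts stay realistic at any length.
    """

    genome_length: int = 100_000
    gc_content: float = 0.464
    cds_fraction: float = 0.8
    n_lineages: int = 3
    arms: tuple[ArmSpec, ...] = DEFAULT_ARMS
    generations_total: int = 2000
    sampling_interval: int = 200
    n_preexisting_snvs: int = 25
    coverage_mean: float = 200.0
    sequencing_error_rate: float = 0.003
    mic_initial: float = 2.0
    mic_plateau_cap: float = 32.0
    resistance_mutation_targets: frozenset[str] = frozenset()
    indel_fraction: float = 0.05
    substitution_preset: str = "uniform"
    sweep_generations: int = 200
    population_size: float = 1e6
    min_cds_length: int = 300
    max_cds_length: int = 1500
    background_sites: int = 50
    seed: int = 42

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must lie in (0, 1)")
        if not 0 < self.cds_fraction < 1:
            raise ValueError("cds_fraction must lie in (0, 1)")
        if self.n_lineages < 1:
            raise ValueError("n_lineages must be >= 1")
        if self.generations_total <= 0 or self.sampling_interval <= 0:
            raise ValueError("generations and sampling interval must be positive")
        if self.generations_total % self.sampling_interval != 0:
            raise ValueError("sampling_interval must divide generations_total")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if not 0 <= self.sequencing_error_rate < 1:
            raise ValueError("sequencing_error_rate must lie in [0, 1)")
        if not 0 <= self.indel_fraction <= 1:
            raise ValueError("indel_fraction must lie in [0, 1]")
        if self.n_preexisting_snvs < 0 or self.background_sites < 0:
            raise ValueError("counts must be non-negative")
        if self.mic_initial <= 0 or self.mic_plateau_cap < self.mic_initial:
            raise ValueError("mic_initial must be positive and <= plateau cap")
        if self.substitution_preset not in SUBSTITUTION_PRESETS:
            raise ValueError(f"unknown substitution preset {self.substitution_preset!r}")
        labels = [a.label for a in self.arms]
        if len(set(labels)) != len(labels):
            raise ValueError("arm labels must be unique")

    @property
    def sampled_generations(self) -> list[int]:
        return list(range(0, self.generations_total + 1, self.sampling_interval))

    def arm(self, label: str) -> ArmSpec:
        for a in self.arms:
            if a.label == label:
                return a
        raise KeyError(f"arm {label!r} not defined in config")

    def lineage_ids(self, arm_label: str) -> list[str]:
        return [f"{arm_label}{i}" for i in range(1, self.n_lineages + 1)]

    # -- YAML round trip ----------------------------------------------------
    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["arms"] = [dataclasses.asdict(a) for a in self.arms]
        d["resistance_mutation_targets"] = sorted(self.resistance_mutation_targets)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text_or_path) -> "SimulationConfig":
        import os
        if isinstance(text_or_path, (str, bytes)) and "\n" not in str(text_or_path) \
                and os.path.exists(str(text_or_path)):
            with open(text_or_path) as fh:
                d = yaml.safe_load(fh)
        else:
            d = yaml.safe_load(text_or_path)
        d["arms"] = tuple(ArmSpec(**a) for a in d.get("arms", []))
        d["resistance_mutation_targets"] = frozenset(
            d.get("resistance_mutation_targets", ()))
        return cls(**d)


@dataclass
class TruthRecord:
    """Ground truth for one planted variant in one lineage."""

    lineage_id: str
    position: int
    ref_allele: str
    alt_allele: str
    origin_generation: int
    frequency_by_sample: dict[int, float]
    is_preexisting: bool = False
    confers_resistance: bool = False
    fixed_generation: int | None = None

    def __post_init__(self) -> None:
        for g, f in self.frequency_by_sample.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency {f} at generation {g} outside [0,1]")

    @property
    def variant_type(self) -> str:
        return classify_variant_type(self.ref_allele, self.alt_allele)

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref_allele, self.alt_allele)


# ---------------------------------------------------------------------------
# Reference genome generation

def _cds_base_gc(target_gc: float) -> float:
    """Per-base GC to use inside CDS so that codon sampling conditioned on
    not being a stop codon realises the target GC.

    Rejecting TAA/TAG/TGA removes AT-rich codons and would otherwise inflate
    realised GC by ~1.5% at GC 0.46, outside the 1% construction contract.
    """
    def conditional_gc(g: float) -> float:
        at = (1 - g) / 2  # probability of one specific A/T base
        gc = g / 2
        p_taa = at ** 3
        p_tag = at * at * gc
        p_tga = at * gc * at
        p_stop = p_taa + p_tag + p_tga
        expected_gc_bases = 3 * g - (p_tag + p_tga)  # stops carry 0 or 1 G/C
        return expected_gc_bases / (3 * (1 - p_stop)) - target_gc

    return brentq(conditional_gc, 1e-6, 1 - 1e-6)


def _sample_codons(n: int, base_gc: float, rng: np.random.Generator) -> str:
    """Sample n codons with per-base GC ``base_gc``, rejecting stop codons."""
    p = np.array([(1 - base_gc) / 2, base_gc / 2, base_gc / 2, (1 - base_gc) / 2])
    out = rng.choice(4, size=(n, 3), p=p)
    codes = np.array([[_BASES.index(b) for b in s] for s in _STOPS])
    while True:
        is_stop = (out[:, None, :] == codes[None, :, :]).all(axis=2).any(axis=1)
        bad = np.flatnonzero(is_stop)
        if bad.size == 0:
            break
        out[bad] = rng.choice(4, size=(bad.size, 3), p=p)
    return "".join(_BASES[i] for i in out.ravel())


def generate_reference(config: SimulationConfig) -> ReferenceGenome:
    """Generate an annotated genome: requested GC (within 1%), non-overlapping
    CDS on both strands covering ~cds_fraction, each a multiple of 3 starting
    ATG, ending in a stop codon, with no internal in-frame stops."""
    rng = np.random.default_rng([config.seed, 101])
    L = config.genome_length
    target_cds_bp = int(round(config.cds_fraction * L))
    if target_cds_bp < config.min_cds_length:
        raise ValueError(
            f"cds_fraction {config.cds_fraction} infeasible for genome_length {L}: "
            f"coding target {target_cds_bp} bp < minimum CDS length "
            f"{config.min_cds_length} bp")

    # plan CDS lengths (multiples of 3) summing to at most the coding target
    lengths: list[int] = []
    remaining = target_cds_bp
    while remaining >= config.min_cds_length:
        hi = min(config.max_cds_length, remaining)
        n = int(rng.integers(config.min_cds_length, hi + 1))
        n -= n % 3
        lengths.append(n)
        remaining -= n
    n_cds = len(lengths)

    # distribute the non-coding bp over the n_cds+1 gaps, >=1 bp per gap
    gap_total = L - sum(lengths)
    n_gaps = n_cds + 1
    if gap_total < n_gaps:
        raise ValueError("genome too small to separate the planned CDS")
    extra = rng.multinomial(gap_total - n_gaps, np.full(n_gaps, 1.0 / n_gaps))
    gaps = extra + 1

    base_gc = _cds_base_gc(config.gc_content)
    p_inter = np.array([(1 - config.gc_content) / 2, config.gc_content / 2,
                        config.gc_content / 2, (1 - config.gc_content) / 2])

    parts: list[str] = []
    features: list[CdsFeature] = []
    pos = 1
    for i, cds_len in enumerate(lengths):
        gap = int(gaps[i])
        parts.append("".join(_BASES[j] for j in rng.choice(4, size=gap, p=p_inter)))
        pos += gap
        n_codons = cds_len // 3
        body = _sample_codons(n_codons - 2, base_gc, rng) if n_codons > 2 else ""
        stop = _STOPS[rng.integers(0, 3)]
        cds_seq = "ATG" + body + stop
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
            cds_seq = "".join(comp[b] for b in reversed(cds_seq))
        parts.append(cds_seq)
        features.append(CdsFeature(gene_id=f"gene_{i + 1:04d}", start=pos,
                                   end=pos + cds_len - 1, strand=strand))
        pos += cds_len
    parts.append("".join(_BASES[j] for j in rng.choice(4, size=int(gaps[-1]), p=p_inter)))
    sequence = "".join(parts)
    assert len(sequence) == L
    return ReferenceGenome(id=f"sim_{config.seed}", sequence=sequence,
                           features=features)


# ---------------------------------------------------------------------------
# Mutation trajectories

# given the normalised (A-or-C) reference base, the alternate base realising
# each of the six classes; complemented when the actual ref base is T or G
_CLASS_ALT = {
    "A": {"AT→CG": "C", "AT→GC": "G", "AT→TA": "T"},
    "C": {"CG→AT": "A", "CG→GC": "G", "CG→TA": "T"},
}
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}
_LABELS = ("AT→CG", "AT→GC", "AT→TA", "CG→AT", "CG→GC", "CG→TA")


def _draw_alt_base(ref_base: str, class_probs: np.ndarray,
                   rng: np.random.Generator) -> str:
    """Draw an alternate base from the substitution-class distribution,
    restricted (and renormalised) to the classes compatible with the
    reference base's pair."""
    norm = ref_base if ref_base in ("A", "C") else _COMP[ref_base]
    idx = [i for i, lab in enumerate(_LABELS) if lab in _CLASS_ALT[norm]]
    w = class_probs[idx]
    lab = _LABELS[idx[int(rng.choice(len(idx), p=w / w.sum()))]]
    alt = _CLASS_ALT[norm][lab]
    return alt if ref_base in ("A", "C") else _COMP[alt]


def preexisting_variants(ref: ReferenceGenome,
                         config: SimulationConfig) -> list[tuple[int, str, str]]:
    """The (position, ref, alt) SNVs planted identically in every lineage,
    drawn once from the master seed."""
    rng = np.random.default_rng([config.seed, 202])
    class_probs = np.asarray(SUBSTITUTION_PRESETS[config.substitution_preset], float)
    positions = rng.choice(len(ref.sequence), size=config.n_preexisting_snvs,
                           replace=False) + 1
    out = []
    for pos in sorted(int(p) for p in positions):
        ref_base = ref.base_at(pos)
        out.append((pos, ref_base, _draw_alt_base(ref_base, class_probs, rng)))
    return out


def _sweep_frequency(g: int, origin: int, sweep: int, f0: float) -> float:
    """Logistic rise from f0 at the origin to ~1 after ``sweep`` generations."""
    if g <= origin:
        return 0.0
    if g >= origin + sweep:
        return 1.0
    s = (logit(0.999) - logit(f0)) / sweep
    return float(expit(logit(f0) + s * (g - origin)))


def simulate_arm(ref: ReferenceGenome, config: SimulationConfig,
                 arm_label: str) -> dict[str, list[TruthRecord]]:
    """Simulate every lineage of one arm; returns lineage_id -> truth records.

    De novo events arrive Poisson(rate x generations); positions uniform
    (resampled on collision within the lineage, bounded); alternate alleles
    follow the configured substitution-class distribution, with a fraction
    of events drawn as 1-3 bp indels.  Selected-arm events falling in a
    resistance target gene sweep logistically; everything else fixes
    instantly at its origin generation.
    """
    arm = config.arm(arm_label)
    arm_idx = [a.label for a in config.arms].index(arm_label)
    pre = preexisting_variants(ref, config)
    sampled = config.sampled_generations
    L = len(ref.sequence)
    class_probs = np.asarray(SUBSTITUTION_PRESETS[config.substitution_preset], float)
    f0 = 1.0 / config.population_size

    out: dict[str, list[TruthRecord]] = {}
    for li, lineage in enumerate(config.lineage_ids(arm_label)):
        rng = np.random.default_rng([config.seed, 303, arm_idx, li])
        records: list[TruthRecord] = []
        occupied: set[int] = set()
        for pos, rb, ab in pre:
            records.append(TruthRecord(
                lineage_id=lineage, position=pos, ref_allele=rb, alt_allele=ab,
                origin_generation=0, is_preexisting=True,
                frequency_by_sample={g: 1.0 for g in sampled},
                fixed_generation=0))
            occupied.add(pos)

        n_events = rng.poisson(arm.rate * config.generations_total)
        for _ in range(n_events):
            for _attempt in range(1000):
                pos = int(rng.integers(1, L + 1))
                if pos not in occupied:
                    break
            else:
                raise RuntimeError(
                    "could not place mutation: too many position collisions")
            occupied.add(pos)
            origin = int(rng.integers(1, config.generations_total + 1))
            ref_base = ref.base_at(pos)
            if rng.random() < config.indel_fraction:
                ilen = int(rng.integers(1, 4))
                if rng.random() < 0.5 or pos + ilen > L:  # insertion
                    inserted = "".join(_BASES[j] for j in rng.integers(0, 4, ilen))
                    ref_allele, alt_allele = ref_base, ref_base + inserted
                else:  # deletion of ilen bases after the anchor
                    ref_allele = ref.sequence[pos - 1: pos + ilen]
                    alt_allele = ref_base
            else:
                ref_allele = ref_base
                alt_allele = _draw_alt_base(ref_base, class_probs, rng)

            feature = ref.feature_at(pos)
            resist = (arm.selected and feature is not None
                      and feature.gene_id in config.resistance_mutation_targets)
            if resist:
                freqs = {g: _sweep_frequency(g, origin, config.sweep_generations, f0)
                         for g in sampled}
                fixed_gen = origin + config.sweep_generations
            else:
                freqs = {g: (1.0 if g >= origin else 0.0) for g in sampled}
                fixed_gen = origin
            records.append(TruthRecord(
                lineage_id=lineage, position=pos, ref_allele=ref_allele,
                alt_allele=alt_allele, origin_generation=origin,
                frequency_by_sample=freqs, confers_resistance=resist,
                fixed_generation=fixed_gen))
        records.sort(key=lambda r: r.position)
        out[lineage] = records
    return out


# ---------------------------------------------------------------------------
# Pileups

def _lineage_tag(lineage_id: str) -> int:
    return zlib.crc32(lineage_id.encode()) & 0x7FFFFFFF


def simulate_pileup(ref: ReferenceGenome, truth: Sequence[TruthRecord],
                    generation: int, config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-site allele counts for one lineage at one sampled generation.

    Coverage is Poisson(coverage_mean); each read reports the true local
    allele (at the truth frequency for that generation) and is then
    miscalled to a uniformly chosen other base with probability
    ``sequencing_error_rate``.  Sequencing error never fabricates indels.
    Besides the truth sites, ``background_sites`` variant-free positions are
    emitted.  Deterministic given the config seed, lineage and generation.
    """
    if generation not in config.sampled_generations:
        raise KeyError(f"generation {generation} is not a sampled timepoint")
    if rng is None:
        lineage = truth[0].lineage_id if truth else "background"
        rng = np.random.default_rng(
            [config.seed, 404, _lineage_tag(lineage), generation])

    e = config.sequencing_error_rate
    rows: list[dict] = []
    truth_positions = {t.position for t in truth}

    for t in sorted(truth, key=lambda t: t.position):
        freq = t.frequency_by_sample.get(generation, 0.0)
        cov = int(rng.poisson(config.coverage_mean))
        ref_base = ref.base_at(t.position)
        row = {"pos": t.position, "ref": ref_base, "A": 0, "C": 0, "G": 0, "T": 0,
               "ins": 0, "del": 0, "ins_allele": "", "del_allele": ""}
        if t.variant_type == "SNV":
            p = _obs_probs(ref_base, t.alt_allele, freq, e)
            counts = rng.multinomial(cov, p)
            for b, c in zip(_BASES, counts):
                row[b] = int(c)
        else:
            n_indel = rng.binomial(cov, freq)
            p = _obs_probs(ref_base, ref_base, 0.0, e)
            counts = rng.multinomial(cov - n_indel, p)
            for b, c in zip(_BASES, counts):
                row[b] = int(c)
            if t.variant_type == "insertion":
                row["ins"] = int(n_indel)
                row["ins_allele"] = t.alt_allele if n_indel else ""
            else:
                row["del"] = int(n_indel)
                row["del_allele"] = t.ref_allele if n_indel else ""
        rows.append(row)

    n_bg = config.background_sites
    if n_bg > 0:
        bg = _background_counts(ref, n_bg, truth_positions, config, rng)
        rows.extend(bg)

    df = pd.DataFrame(rows, columns=list(
        ("pos", "ref", "A", "C", "G", "T", "ins", "del", "ins_allele", "del_allele")))
    return df.sort_values("pos", kind="stable").reset_index(drop=True)


def _obs_probs(ref_base: str, alt_base: str, freq: float, e: float) -> np.ndarray:
    """Observed-base distribution: true allele mix then symmetric miscall."""
    p_true = np.zeros(4)
    p_true[_BASES.index(alt_base)] += freq
    p_true[_BASES.index(ref_base)] += 1.0 - freq
    obs = np.full(4, 0.0)
    for i in range(4):
        obs[i] = p_true[i] * (1 - e) + (1 - p_true[i]) * (e / 3.0)
    return obs / obs.sum()


def _background_counts(ref, n_bg, truth_positions, config, rng) -> list[dict]:
    """Vectorised variant-free sites (used for false-positive control)."""
    L = len(ref.sequence)
    pool = rng.choice(L, size=min(L, n_bg + len(truth_positions)), replace=False) + 1
    positions = np.array([p for p in pool if p not in truth_positions][:n_bg])
    cov = rng.poisson(config.coverage_mean, size=len(positions))
    e = config.sequencing_error_rate
    errs = rng.binomial(cov, e) if e > 0 else np.zeros(len(positions), dtype=int)
    split = rng.multinomial(errs, np.full(3, 1 / 3.0)) if len(positions) else np.zeros((0, 3), int)
    rows = []
    for i, pos in enumerate(positions):
        ref_base = ref.base_at(int(pos))
        row = {"pos": int(pos), "ref": ref_base, "A": 0, "C": 0, "G": 0, "T": 0,
               "ins": 0, "del": 0, "ins_allele": "", "del_allele": ""}
        others = [b for b in _BASES if b != ref_base]
        row[ref_base] = int(cov[i] - errs[i])
        for j, b in enumerate(others):
            row[b] = int(split[i, j])
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# MIC trajectories

def simulate_mic_trajectory(truth_by_lineage: Mapping[str, Sequence[TruthRecord]],
                            config: SimulationConfig, arm_label: str) -> MicTable:
    """MIC grid for one arm: each resistance fixation doubles the MIC, capped
    at the plateau; arms without resistance fixations give a constant row."""
    arm = config.arm(arm_label)
    sampled = config.sampled_generations
    reps = sorted(truth_by_lineage)
    values = np.zeros((len(sampled), len(reps)))
    for j, lineage in enumerate(reps):
        fix_gens = sorted(t.fixed_generation for t in truth_by_lineage[lineage]
                          if t.confers_resistance and t.fixed_generation is not None)
        for i, g in enumerate(sampled):
            k = sum(1 for fg in fix_gens if fg <= g)
            values[i, j] = min(config.mic_initial * 2 ** k, config.mic_plateau_cap)
    return MicTable(antibiotic=arm.antibiotic or arm.label, generations=list(sampled),
                    replicate_ids=reps, values=values)
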