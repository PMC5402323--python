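"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are 1-based inclusive, matching GFF3 and VCF.
The chromosome is treated linearly; features spanning the origin of a
circular chromosome are not supported.
"""

from __future__ import annotations

import bisect
import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID_BASES = frozenset("ACGT")

#: Column order of the pileup TSV.  The two trailing allele columns carry the
#: sequence of the dominant observed insertion/deletion so indel calls can be
#: matched back to a truth record by exact (pos, ref, alt) identity; files
#: written without them still load.
PILEUP_COLUMNS = ("pos", "ref", "A", "C", "G", "T", "ins", "del",
                  "ins_allele", "del_allele")


def classify_variant_type(ref_allele: str, alt_allele: str) -> str:
    """Classify a VCF-style ref/alt pair as SNV, insertion or deletion."""
    if len(ref_allele) == 1 and len(alt_allele) == 1:
        return "SNV"
    if len(alt_allele) > len(ref_allele):
        return "insertion"
    return "deletion"


@dataclass(frozen=True)
class CdsFeature:
    """A protein-coding feature (1-based inclusive coordinates, phase 0)."""

    gene_id: str
    start: int
    end: int
    strand: str
    phase: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"CDS {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"CDS {self.gene_id}: strand must be '+' or '-'")
        if self.length % 3 != 0:
            raise ValueError(
                f"CDS {self.gene_id}: length {self.length} not divisible by 3")
        if self.phase != 0:
            raise ValueError(f"CDS {self.gene_id}: only phase 0 is supported")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ReferenceGenome:
    """A genome sequence plus its (non-overlapping) CDS annotation.

    The coordinate and strand authority for all downstream consequence
    calling: positions are 1-based, features sorted by start, overlaps
    rejected so every position maps to at most one gene.
    """

    id: str
    sequence: str
    features: list[CdsFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("empty genome sequence")
        if set(self.sequence) - _VALID_BASES:
            bad = sorted(set(self.sequence) - _VALID_BASES)
            raise ValueError(f"sequence contains non-ACGT characters: {bad}")
        self.features = sorted(self.features, key=lambda f: f.start)
        prev: CdsFeature | None = None
        for f in self.features:
            if f.end > len(self.sequence) or f.start < 1:
                raise ValueError(
                    f"CDS {f.gene_id} [{f.start},{f.end}] outside genome "
                    f"bounds [1,{len(self.sequence)}]")
            if prev is not None and f.start <= prev.end:
                raise ValueError(
                    f"overlapping CDS {prev.gene_id} and {f.gene_id}")
            prev = f
        self._starts = [f.start for f in self.features]

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc_content(self) -> float:
        s = self.sequence
        return (s.count("G") + s.count("C")) / len(s)

    @property
    def cds_fraction(self) -> float:
        return sum(f.length for f in self.features) / len(self.sequence)

    def feature_at(self, position: int) -> CdsFeature | None:
        """Return the CDS containing a 1-based position, or None."""
        if not 1 <= position <= len(self.sequence):
            raise ValueError(f"position {position} outside genome bounds")
        i = bisect.bisect_right(self._starts, position) - 1
        if i >= 0 and self.features[i].end >= position:
            return self.features[i]
        return None

    def base_at(self, position: int) -> str:
        return self.sequence[position - 1]


@dataclass
class VariantCall:
    """One alternate allele at one site in one sample (lineage, generation)."""

    lineage_id: str
    generation: int
    position: int
    ref_allele: str
    alt_allele: str
    coverage: int
    alt_frequency: float
    call_tier: str  # "fixed" | "lenient"
    variant_type: str = ""

    def __post_init__(self) -> None:
        if not self.variant_type:
            self.variant_type = classify_variant_type(self.ref_allele, self.alt_allele)
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        if not 0.0 <= self.alt_frequency <= 1.0:
            raise ValueError("alt_frequency must lie in [0, 1]")
        if self.call_tier not in ("fixed", "lenient"):
            raise ValueError(f"unknown call tier {self.call_tier!r}")
        if (self.variant_type == "SNV") != (
                len(self.ref_allele) == 1 and len(self.alt_allele) == 1):
            raise ValueError("SNV iff both alleles are single bases")

    @property
    def key(self) -> tuple[int, str, str]:
        """Variant identity used for cross-sample matching."""
        return (self.position, self.ref_allele, self.alt_allele)


@dataclass
class MicTable:
    """Replicate x generation grid of MIC values for one antibiotic arm.

    Missing cells are carried as NaN (never silently dropped); all present
    values must be positive and generations strictly increasing.
    """

    antibiotic: str
    generations: list[int]
    replicate_ids: list[str]
    values: np.ndarray  # shape (n_generations, n_replicates); NaN = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.generations), len(self.replicate_ids)):
            raise ValueError("MIC grid shape does not match generations x replicates")
        gens = np.asarray(self.generations)
        if len(gens) == 0 or np.any(np.diff(gens) <= 0):
            raise ValueError("generations must be non-empty and strictly increasing")
        present = self.values[~np.isnan(self.values)]
        if np.any(present <= 0):
            raise ValueError("MIC values must be positive")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.generations, name="Generation"),
                            columns=self.replicate_ids)


# ---------------------------------------------------------------------------
# FASTA + GFF3

def write_reference(ref: ReferenceGenome, fasta_path: os.PathLike | str,
                    gff_path: os.PathLike | str) -> None:
    record = SeqRecord(Seq(ref.sequence), id=ref.id, description="")
    SeqIO.write([record], str(fasta_path), "fasta")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {ref.id} 1 {len(ref)}\n")
        for f in ref.features:
            fh.write("\t".join([
                ref.id, "alemut", "CDS", str(f.start), str(f.end), ".",
                f.strand, str(f.phase), f"ID={f.gene_id}",
            ]) + "\n")


def read_reference(fasta_path: os.PathLike | str, gff_path: os.PathLike | str,
                   allow_overlap: bool = False) -> ReferenceGenome:
    """Load and validate a reference genome from FASTA + GFF3.

    CDS features with length not divisible by 3 or outside the sequence are
    rejected.  Overlapping CDS are rejected unless ``allow_overlap`` is set,
    in which case the first (leftmost) feature wins and later overlapping
    features are dropped.
    """
    import gffutils

    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"{fasta_path}: no FASTA records found")
    rec = records[0]

    db = gffutils.create_db(str(gff_path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    feats = []
    for f in db.features_of_type("CDS", order_by="start"):
        gene_id = (f.attributes.get("ID") or f.attributes.get("gene_id")
                   or [f.id])[0]
        phase = 0 if f.frame in (".", None) else int(f.frame)
        feats.append(CdsFeature(gene_id=gene_id, start=f.start, end=f.end,
                                strand=f.strand, phase=phase))
    if allow_overlap:
        kept: list[CdsFeature] = []
        for f in sorted(feats, key=lambda f: f.start):
            if kept and f.start <= kept[-1].end:
                continue  # first-wins
            kept.append(f)
        feats = kept
    return ReferenceGenome(id=rec.id, sequence=str(rec.seq), features=feats)


# ---------------------------------------------------------------------------
# VCF

_VCF_CALLSET_HEADER = """\
##fileformat=VCFv4.2
##source=alemut
##contig=<ID={contig},length={length}>
##INFO=<ID=LINEAGE,Number=1,Type=String,Description="Lineage identifier">
##INFO=<ID=GENERATION,Number=1,Type=Integer,Description="Sampled generation">
##INFO=<ID=TIER,Number=1,Type=String,Description="Call tier (fixed or lenient)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_callset_vcf(calls: Sequence[VariantCall], contig: str, contig_length: int,
                      path: os.PathLike | str) -> None:
    """Write one sample's calls (one lineage, one generation, one tier)."""
    if calls:
        lineage = calls[0].lineage_id
        generation = calls[0].generation
        tier = calls[0].call_tier
        sample = f"{lineage}_g{generation}"
    else:
        lineage, generation, tier, sample = "NA", 0, "fixed", "NA"
    with open(path, "w") as fh:
        fh.write(_VCF_CALLSET_HEADER.format(contig=contig, length=contig_length,
                                            sample=sample))
        for c in sorted(calls, key=lambda c: c.key):
            info = f"LINEAGE={c.lineage_id};GENERATION={c.generation};TIER={c.call_tier}"
            fh.write("\t".join([
                contig, str(c.position), ".", c.ref_allele, c.alt_allele, ".",
                "PASS", info, "DP:AF", f"{c.coverage}:{c.alt_frequency:.6g}",
            ]) + "\n")


def read_callsets(vcf_paths: Iterable[os.PathLike | str],
                  tier: str | None = None,
                  lineage_id: str | None = None,
                  generation: int | None = None) -> list[VariantCall]:
    """Read variant calls from VCF v4.2 files.

    One VariantCall per sample-allele; multi-allelic records are split.  The
    tier/lineage/generation come from the LINEAGE/GENERATION/TIER INFO tags
    unless overridden per call.  Missing AF or DP is an error naming the
    offending record.
    """
    from cyvcf2 import VCF

    calls: list[VariantCall] = []
    for path in vcf_paths:
        vcf = VCF(str(path))
        for v in vcf:
            where = f"{path}:{v.CHROM}:{v.POS}"
            try:
                af = v.format("AF")
                dp = v.format("DP")
            except KeyError:  # tag absent from the header entirely
                af = dp = None
            if af is None or dp is None:
                raise ValueError(f"{where}: record lacks per-sample AF/DP")
            rec_tier = tier or v.INFO.get("TIER")
            rec_lineage = lineage_id or v.INFO.get("LINEAGE")
            rec_gen = generation if generation is not None else v.INFO.get("GENERATION")
            if rec_tier is None or rec_lineage is None or rec_gen is None:
                raise ValueError(
                    f"{where}: tier/lineage/generation neither tagged nor supplied")
            for s in range(len(vcf.samples)):
                for i, alt in enumerate(v.ALT):
                    calls.append(VariantCall(
                        lineage_id=str(rec_lineage), generation=int(rec_gen),
                        position=v.POS, ref_allele=v.REF, alt_allele=alt,
                        coverage=int(dp[s][0] if np.ndim(dp) > 1 else dp[s]),
                        alt_frequency=float(af[s][i]),
                        call_tier=str(rec_tier)))
        vcf.close()
    return calls


_VCF_TRUTH_HEADER = """\
##fileformat=VCFv4.2
##source=alemut-simulate
##contig=<ID={contig},length={length}>
##INFO=<ID=ORIGIN_GEN,Number=1,Type=Integer,Description="Generation the mutation arose">
##INFO=<ID=PREEXISTING,Number=0,Type=Flag,Description="Present in the ancestral stock">
##INFO=<ID=RESIST,Number=0,Type=Flag,Description="Confers antibiotic resistance">
##FORMAT=<ID=AF,Number=A,Type=Float,Description="True allele frequency at the sampled generation">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def write_truth_vcf(truth: Sequence, contig: str, contig_length: int,
                    sampled_generations: Sequence[int],
                    path: os.PathLike | str) -> None:
    """Write one lineage's ground-truth records; samples are the timepoints."""
    samples = "\t".join(f"g{g}" for g in sampled_generations)
    with open(path, "w") as fh:
        fh.write(_VCF_TRUTH_HEADER.format(contig=contig, length=contig_length,
                                          samples=samples))
        for t in sorted(truth, key=lambda t: (t.position, t.alt_allele)):
            info = [f"ORIGIN_GEN={t.origin_generation}"]
            if t.is_preexisting:
                info.append("PREEXISTING")
            if t.confers_resistance:
                info.append("RESIST")
            cols = [contig, str(t.position), ".", t.ref_allele, t.alt_allele,
                    ".", "PASS", ";".join(info), "AF"]
            cols += [f"{t.frequency_by_sample.get(g, 0.0):.6g}"
                     for g in sampled_generations]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Pileup TSV

def write_pileup(pileup: pd.DataFrame, path: os.PathLike | str) -> None:
    pileup.to_csv(path, sep="\t", index=False)


def read_pileup(path: os.PathLike | str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"ref": str})
    for col in ("ins_allele", "del_allele"):
        if col not in df.columns:
            df[col] = ""
    df["ins_allele"] = df["ins_allele"].fillna("").astype(str)
    df["del_allele"] = df["del_allele"].fillna("").astype(str)
    return df[list(PILEUP_COLUMNS)]


# ---------------------------------------------------------------------------
# MIC CSV

def write_mic_table(table: MicTable, path: os.PathLike | str) -> None:
    table.to_frame().to_csv(path)


def read_mic_table(csv_path: os.PathLike | str, antibiotic: str | None = None) -> MicTable:
    """Load a replicate x generation MIC grid.

    Layout: first column ``Generation``, remaining columns one per replicate
    (e.g. G1-G3 / A1-A3).  Non-numeric or empty cells become explicit missing
    flags (NaN); non-increasing generations are a validation error.
    """
    df = pd.read_csv(csv_path)
    if df.shape[1] < 2:
        raise ValueError(f"{csv_path}: need a generation column and >=1 replicate column")
    gen_col = df.columns[0]
    generations = df[gen_col].astype(int).tolist()
    reps = [str(c) for c in df.columns[1:]]
    values = df[df.columns[1:]].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    name = antibiotic if antibiotic is not None else Path(csv_path).stem
    return MicTable(antibiotic=name, generations=generations,
                    replicate_ids=reps, values=values)


# ---------------------------------------------------------------------------
# Run report

def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (presentation layer only)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def _display_stats(stats) -> dict:
    """Presentation-rounded view: rates to 2 s.f., ratios to 2 decimals."""
    d = {}
    d["arm"] = stats.arm
    d["mean_denovo_count"] = round(stats.mean_denovo_count, 1)
    d["rate_per_generation"] = round_sig(stats.rate_per_generation, 2)
    d["rate_per_bp_per_generation"] = round_sig(stats.rate_per_bp_per_generation, 2)
    d["spectrum_percent"] = {k: round(100 * v, 1)
                             for k, v in stats.spectrum_proportions.items()}
    d["ti_tv"] = None if stats.ti_tv is None else round(stats.ti_tv, 2)
    d["ka"] = None if stats.ka is None else round_sig(stats.ka, 2)
    d["ks"] = None if stats.ks is None else round_sig(stats.ks, 2)
    d["ka_ks"] = None if stats.ka_ks is None else round(stats.ka_ks, 2)
    d["nonsyn_percent"] = (None if stats.nonsyn_fraction is None
                           else round(100 * stats.nonsyn_fraction, 1))
    return d


def write_report(stats_by_arm: Mapping[str, object], outdir: os.PathLike | str,
                 denovo_by_arm: Mapping[str, Sequence] | None = None,
                 fitness_by_arm: Mapping[str, object] | None = None,
                 sampled_generations: Sequence[int] | None = None) -> dict:
    """Write the machine-readable run summary, per-arm tables and figures.

    Raw values are kept unrounded in the JSON under ``raw``; rounding (2
    significant figures for rates, 2 decimals for ratios) happens only in
    the ``display`` section.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"arms": {}}
    for arm, stats in stats_by_arm.items():
        summary["arms"][arm] = {
            "raw": dataclasses.asdict(stats),
            "display": _display_stats(stats),
        }
    if fitness_by_arm:
        summary["fitness"] = {arm: dataclasses.asdict(fs)
                              for arm, fs in fitness_by_arm.items()}
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)

    if denovo_by_arm is not None:
        rows = []
        for arm, muts in denovo_by_arm.items():
            for m in muts:
                r = dataclasses.asdict(m)
                r["arm"] = arm
                rows.append(r)
        cols = ["arm", "lineage_id", "position", "ref_allele", "alt_allele",
                "variant_type", "first_seen", "last_seen", "fixed_at",
                "consequence", "spectrum_class", "gene_id"]
        pd.DataFrame(rows, columns=cols).to_csv(outdir / "mutations.tsv",
                                                sep="\t", index=False)

    _write_figures(stats_by_arm, denovo_by_arm, sampled_generations, outdir)
    return summary


def _write_figures(stats_by_arm, denovo_by_arm, sampled_generations, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .annotate import SPECTRUM_LABELS
    from .denovo import accumulation_curve

    fig, ax = plt.subplots(figsize=(5, 3.5))
    labels = sorted(stats_by_arm)
    width = 0.8 / max(len(labels), 1)
    x = np.arange(len(SPECTRUM_LABELS))
    for i, arm in enumerate(labels):
        props = stats_by_arm[arm].spectrum_proportions
        ax.bar(x + i * width, [100 * props.get(c, 0.0) for c in SPECTRUM_LABELS],
               width, label=arm)
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(SPECTRUM_LABELS, rotation=45, ha="right")
    ax.set_ylabel("% of de novo SNVs")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "spectrum.png", dpi=120)
    plt.close(fig)

    if denovo_by_arm is not None and sampled_generations is not None:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for arm in sorted(denovo_by_arm):
            muts = denovo_by_arm[arm]
            lineages = sorted({m.lineage_id for m in muts}) or [arm]
            curve = accumulation_curve(muts, sampled_generations)
            mean = [curve[g] / len(lineages) for g in sampled_generations]
            ax.plot(sampled_generations, mean, marker="o", label=arm)
        ax.set_xlabel("generation")
        ax.set_ylabel("mean de novo mutations / lineage")
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / "accumulation.png", dpi=120)
        plt.close(fig)
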