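"""Two-tier variant calling on pileup allele counts.

The fixed (high-quality) tier re-embodies a haploid fixed-ploidy detector:
a site is called when coverage exceeds ``min_coverage`` (strict, i.e. >20
with the default) and the posterior probability that the haploid consensus
equals the top non-reference allele reaches ``fixed_probability``.  The
posterior is computed under a transparent two-hypothesis model — the true
allele is either the reference or the top alternate, reads are miscalled
symmetrically with probability ``error_rate`` (uniform over the three wrong
bases), and the prior is uniform — so the decision reduces to a likelihood
ratio driven by the ref/alt count difference.

The lenient tier is a low-frequency detector: same coverage bound, allele
frequency at least ``min_frequency``, and a one-sided binomial test that the
alternate count exceeds what sequencing error alone (rate ``error_rate``/3
per specific wrong base) would produce, at level ``significance``.

Indels are gated on the ins/del count columns: lenient uses the same
frequency/significance gates; the fixed tier requires the indel frequency to
reach ``fixed_probability`` (a frequency criterion standing in for the
posterior, which is defined only for base substitutions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

from .io_formats import VariantCall

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class CallingThresholds:
    """Detection thresholds for both call tiers.

    Defaults: coverage > 20 (exclusive), fixed-tier posterior 90%,
    lenient-tier minimum frequency 1% and significance 1%, assumed per-base
    sequencing error 0.3%.
    """

    min_coverage: int = 20
    fixed_probability: float = 0.90
    min_frequency: float = 0.01
    significance: float = 0.01
    error_rate: float = 0.003

    def __post_init__(self) -> None:
        if not 0 < self.fixed_probability <= 1:
            raise ValueError("fixed_probability must lie in (0, 1]")
        if not 0 < self.min_frequency < 1:
            raise ValueError("min_frequency must lie in (0, 1)")
        if not 0 < self.significance < 1:
            raise ValueError("significance must lie in (0, 1)")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must lie in [0, 1)")


DEFAULT_THRESHOLDS = CallingThresholds()


def _row_counts(row: Mapping) -> tuple[str, np.ndarray]:
    ref = str(row["ref"]).upper()
    counts = np.array([int(row[b]) for b in _BASES])
    return ref, counts


def _top_alt(ref: str, counts: np.ndarray) -> tuple[str, int, int, int]:
    """Return (alt_base, alt_count, ref_count, coverage) for the top non-ref allele."""
    coverage = int(counts.sum())
    ref_idx = _BASES.index(ref)
    masked = counts.copy()
    masked[ref_idx] = -1
    alt_idx = int(np.argmax(masked))
    return _BASES[alt_idx], int(counts[alt_idx]), int(counts[ref_idx]), coverage


def consensus_posterior(ref_count: int, alt_count: int, error_rate: float) -> float:
    """Posterior P(haploid consensus = alt) under the two-hypothesis model.

    Reads matching neither hypothesis have equal likelihood under both and
    cancel, so only the ref/alt count difference matters.
    """
    e = max(error_rate, 1e-12)  # e=0 handled as a limit
    llr = (alt_count - ref_count) * (np.log1p(-e) - np.log(e / 3.0))
    return float(expit(llr))


def error_tail_probability(alt_count: int, coverage: int, error_rate: float) -> float:
    """One-sided binomial tail P(X >= alt_count | n=coverage, p=error_rate/3)."""
    if alt_count <= 0:
        return 1.0
    return float(sps.binom.sf(alt_count - 1, coverage, error_rate / 3.0))


def call_fixed(row: Mapping, thresholds: CallingThresholds = DEFAULT_THRESHOLDS,
               lineage_id: str = "NA", generation: int = 0) -> VariantCall | None:
    """Fixed-tier call on one pileup row, or None (zero coverage is a no-call)."""
    ref, counts = _row_counts(row)
    alt, alt_count, ref_count, coverage = _top_alt(ref, counts)
    if coverage <= thresholds.min_coverage or alt_count == 0:
        return None
    if consensus_posterior(ref_count, alt_count, thresholds.error_rate) \
            < thresholds.fixed_probability:
        return None
    return VariantCall(lineage_id=lineage_id, generation=generation,
                       position=int(row["pos"]), ref_allele=ref, alt_allele=alt,
                       coverage=coverage, alt_frequency=alt_count / coverage,
                       call_tier="fixed")


def call_lenient(row: Mapping, thresholds: CallingThresholds = DEFAULT_THRESHOLDS,
                 lineage_id: str = "NA", generation: int = 0) -> VariantCall | None:
    """Lenient-tier call on one pileup row, or None."""
    ref, counts = _row_counts(row)
    alt, alt_count, ref_count, coverage = _top_alt(ref, counts)
    if coverage <= thresholds.min_coverage or alt_count == 0:
        return None
    if alt_count / coverage < thresholds.min_frequency:
        return None
    if error_tail_probability(alt_count, coverage, thresholds.error_rate) \
            > thresholds.significance:
        return None
    return VariantCall(lineage_id=lineage_id, generation=generation,
                       position=int(row["pos"]), ref_allele=ref, alt_allele=alt,
                       coverage=coverage, alt_frequency=alt_count / coverage,
                       call_tier="lenient")


def call_table(pileup: pd.DataFrame, thresholds: CallingThresholds,
               tier: str, lineage_id: str, generation: int,
               reference_sequence: str | None = None) -> list[VariantCall]:
    """Vectorised calling of a whole pileup table at one tier.

    Substitutions use the tier's SNV rule on the top non-reference base;
    ins/del columns are gated as described in the module docstring.  The
    reference sequence (when given) supplies the multi-base ref allele of
    deletions; otherwise the del_allele column must carry it.
    """
    if tier not in ("fixed", "lenient"):
        raise ValueError(f"unknown tier {tier!r}")
    if len(pileup) == 0:
        return []
    counts = pileup[list(_BASES)].to_numpy(dtype=np.int64)
    coverage = counts.sum(axis=1)
    ref_idx = pd.Series(pileup["ref"].str.upper()).map(
        {b: i for i, b in enumerate(_BASES)}).to_numpy()
    n = len(pileup)
    rows = np.arange(n)
    ref_count = counts[rows, ref_idx]
    masked = counts.copy()
    masked[rows, ref_idx] = -1
    alt_idx = masked.argmax(axis=1)
    alt_count = counts[rows, alt_idx]

    e = max(thresholds.error_rate, 1e-12)
    covered = coverage > thresholds.min_coverage
    nonzero = alt_count > 0
    if tier == "fixed":
        llr = (alt_count - ref_count) * (np.log1p(-e) - np.log(e / 3.0))
        ok = covered & nonzero & (expit(llr) >= thresholds.fixed_probability)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            freq = np.where(coverage > 0, alt_count / np.maximum(coverage, 1), 0.0)
        tail = sps.binom.sf(alt_count - 1, coverage, e / 3.0)
        ok = (covered & nonzero & (freq >= thresholds.min_frequency)
              & (tail <= thresholds.significance))

    calls: list[VariantCall] = []
    positions = pileup["pos"].to_numpy(dtype=np.int64)
    refs = pileup["ref"].str.upper().to_numpy()
    for i in np.flatnonzero(ok):
        calls.append(VariantCall(
            lineage_id=lineage_id, generation=generation,
            position=int(positions[i]), ref_allele=str(refs[i]),
            alt_allele=_BASES[alt_idx[i]], coverage=int(coverage[i]),
            alt_frequency=float(alt_count[i] / coverage[i]), call_tier=tier))

    calls.extend(_call_indels(pileup, thresholds, tier, lineage_id, generation,
                              coverage))
    calls.sort(key=lambda c: c.key)
    return calls


def _call_indels(pileup, thresholds, tier, lineage_id, generation, base_coverage):
    calls: list[VariantCall] = []
    ins = pileup["ins"].to_numpy(dtype=np.int64) if "ins" in pileup else np.zeros(len(pileup), int)
    dele = pileup["del"].to_numpy(dtype=np.int64) if "del" in pileup else np.zeros(len(pileup), int)
    for kind, cnt_arr, allele_col in (("insertion", ins, "ins_allele"),
                                      ("deletion", dele, "del_allele")):
        for i in np.flatnonzero(cnt_arr > 0):
            cov = int(base_coverage[i] + cnt_arr[i])
            if cov <= thresholds.min_coverage:
                continue
            freq = cnt_arr[i] / cov
            if tier == "fixed":
                if freq < thresholds.fixed_probability:
                    continue
            else:
                if freq < thresholds.min_frequency:
                    continue
                if error_tail_probability(int(cnt_arr[i]), cov,
                                          thresholds.error_rate) > thresholds.significance:
                    continue
            allele = str(pileup.iloc[i].get(allele_col, "") or "")
            ref_base = str(pileup.iloc[i]["ref"]).upper()
            if kind == "insertion":
                ref_allele, alt_allele = ref_base, allele if allele else ref_base + "N"
            else:
                ref_allele = allele if allele else ref_base + "N"
                alt_allele = ref_allele[0]
            calls.append(VariantCall(
                lineage_id=lineage_id, generation=generation,
                position=int(pileup.iloc[i]["pos"]), ref_allele=ref_allele,
                alt_allele=alt_allele, coverage=cov, alt_frequency=float(freq),
                call_tier=tier))
    return calls
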