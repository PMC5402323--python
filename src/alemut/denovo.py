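"""Cross-lineage identification and tracing of de novo mutations.

A variant in the high-quality (fixed) call set is accepted as de novo only
if it is private to its evolutionary history: variants shared by lineages
from different arms are treated as pre-existing natural polymorphism and
removed everywhere, and anything already present in a lineage's
generation-0 baseline is likewise removed.  Sharing between replicate
lineages of the *same* arm does not trigger removal — identical selection
can plausibly fix the same mutation twice, and that recurrence is signal.

Each retained variant is then traced through the lenient call set of its
own lineage to date its first and last observed presence; the earliest
fixed-tier call dates its fixation.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

from .io_formats import VariantCall, classify_variant_type

logger = logging.getLogger(__name__)

VariantKey = tuple[int, str, str]


@dataclass
class DeNovoMutation:
    """A cross-lineage-filtered variant with its observation history."""

    lineage_id: str
    position: int
    ref_allele: str
    alt_allele: str
    variant_type: str
    first_seen: int
    last_seen: int
    fixed_at: int | None
    consequence: str | None = None
    spectrum_class: str | None = None
    is_transition: bool | None = None
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.first_seen > self.last_seen:
            raise ValueError("first_seen must be <= last_seen")
        if self.fixed_at is not None and self.fixed_at < self.first_seen:
            raise ValueError("fixed_at must be >= first_seen")

    @property
    def key(self) -> VariantKey:
        return (self.position, self.ref_allele, self.alt_allele)


def _default_arm(lineage_id: str) -> str:
    m = re.match(r"[A-Za-z]+", lineage_id)
    return m.group(0) if m else lineage_id


def filter_shared(fixed_callsets: Mapping[str, Sequence[VariantCall]],
                  arm_of: Mapping[str, str] | None = None,
                  ) -> tuple[dict[str, list[VariantCall]], list[dict]]:
    """Remove shared and baseline variants from the fixed call sets.

    A variant identity (position, ref, alt) present in >=2 lineages from
    different arms is removed from every lineage; a variant present in a
    lineage's generation-0 sample is removed from that lineage.  Returns
    (retained per lineage, removed-audit records).
    """
    if len(fixed_callsets) < 2:
        raise ValueError("cross-lineage filtering requires >= 2 lineages")
    if arm_of is None:
        arm_of = {lid: _default_arm(lid) for lid in fixed_callsets}

    arms_with: dict[VariantKey, set[str]] = defaultdict(set)
    lineages_with: dict[VariantKey, set[str]] = defaultdict(set)
    for lid, calls in fixed_callsets.items():
        for c in calls:
            arms_with[c.key].add(arm_of[lid])
            lineages_with[c.key].add(lid)
    cross_arm = {k for k, arms in arms_with.items() if len(arms) >= 2}

    baseline: dict[str, set[VariantKey]] = {
        lid: {c.key for c in calls if c.generation == 0}
        for lid, calls in fixed_callsets.items()}

    retained: dict[str, list[VariantCall]] = {}
    removed: list[dict] = []
    audited: set[tuple[str, VariantKey]] = set()
    for lid, calls in fixed_callsets.items():
        kept = []
        for c in calls:
            if c.key in cross_arm:
                reason = "shared-across-arms"
            elif c.key in baseline[lid]:
                reason = "present-at-generation-0"
            else:
                kept.append(c)
                continue
            if (lid, c.key) not in audited:
                audited.add((lid, c.key))
                removed.append({"lineage_id": lid, "position": c.position,
                                "ref_allele": c.ref_allele,
                                "alt_allele": c.alt_allele, "reason": reason,
                                "lineages": sorted(lineages_with[c.key])})
        retained[lid] = kept
    return retained, removed


def identify_denovo(retained_calls: Mapping[str, Sequence[VariantCall]],
                    lenient_callsets: Mapping[str, Sequence[VariantCall]],
                    ) -> list[DeNovoMutation]:
    """Build one DeNovoMutation per retained fixed variant, dated from the
    lenient call set of the same lineage.

    first_seen/last_seen are the earliest/latest sampled generations with a
    matching lenient call; fixed_at is the earliest fixed-tier call.  A
    retained variant with no lenient support anywhere is kept with
    first_seen = fixed_at and a logged audit warning (detection dropout).
    """
    lenient_gens: dict[tuple[str, VariantKey], list[int]] = defaultdict(list)
    for lid, calls in lenient_callsets.items():
        for c in calls:
            lenient_gens[(lid, c.key)].append(c.generation)

    fixed_gens: dict[tuple[str, VariantKey], list[int]] = defaultdict(list)
    order: list[tuple[str, VariantKey]] = []
    for lid in sorted(retained_calls):
        for c in retained_calls[lid]:
            k = (lid, c.key)
            if k not in fixed_gens:
                order.append(k)
            fixed_gens[k].append(c.generation)

    out: list[DeNovoMutation] = []
    for lid, key in order:
        fg = sorted(fixed_gens[(lid, key)])
        lg = sorted(lenient_gens.get((lid, key), []))
        fixed_at = fg[0]
        if lg:
            first_seen, last_seen = lg[0], lg[-1]
            if fixed_at < first_seen:
                # a fixed call is also evidence of presence
                first_seen = fixed_at
            last_seen = max(last_seen, fg[-1])
        else:
            logger.warning(
                "variant %s in %s has no lenient support at any generation; "
                "using fixed-tier dates", key, lid)
            first_seen, last_seen = fixed_at, fg[-1]
        pos, ref_allele, alt_allele = key
        out.append(DeNovoMutation(
            lineage_id=lid, position=pos, ref_allele=ref_allele,
            alt_allele=alt_allele,
            variant_type=classify_variant_type(ref_allele, alt_allele),
            first_seen=first_seen, last_seen=last_seen, fixed_at=fixed_at))
    out.sort(key=lambda m: (m.lineage_id, m.position, m.alt_allele))
    return out


def accumulation_curve(denovo: Sequence[DeNovoMutation],
                       sampled_generations: Sequence[int]) -> dict[int, int]:
    """Cumulative number of mutations first seen by each sampled generation."""
    firsts = sorted(m.first_seen for m in denovo)
    curve = {}
    for g in sampled_generations:
        curve[g] = sum(1 for f in firsts if f <= g)
    return curve
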