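"""Panel sampling, verdict aggregation and multi-curator consensus.

Curators answer "Is this a real SV?" with Yes/Maybe/No on fixed-order
genotype panels.  Verdicts aggregate per curator into retained/rejected
sets; curators are ranked by stringency (number rejected) and consensus
callsets are intersections of the k most lenient curators' retained sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .svio import CurationScore, SVCall

logger = logging.getLogger(__name__)

DEFAULT_RETAIN_ANSWERS = frozenset({"YES", "MAYBE"})

#: genotype classes in fixed panel order
_PANEL_ORDER = (0, 1, 2)


@dataclass
class CuratorVerdicts:
    """One curator's partition of the curated subset."""

    curator: str
    retained: set
    rejected: set

    def __post_init__(self):
        if self.retained & self.rejected:
            raise ValueError(f"curator {self.curator}: retained and rejected sets overlap")

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def sample_panel(call: SVCall, n_per_class: int, seed: int) -> list:
    """Sample individuals for a review panel, with replacement, in the fixed
    class order hom-ref, het, hom-alt.

    Returns ``3 * n_per_class`` sample names.  The fixed order is what lets
    a curator compare expected depth/genotype signatures across classes at
    a glance.  Deterministic under ``seed``; repeats within a class are
    permitted (and expected for singleton classes).
    """
    if n_per_class not in (1, 2, 3):
        raise ValueError("n_per_class must be 1, 2 or 3")
    rng = np.random.default_rng(seed)
    panel = []
    for cls in _PANEL_ORDER:
        members = [s for s, g in zip(call.samples, call.genotypes) if g == cls]
        if not members:
            raise ValueError(f"call {call.id}: genotype class {cls} is empty")
        panel.extend(rng.choice(members, size=n_per_class, replace=True))
    return [str(s) for s in panel]


def aggregate_verdicts(scores: Sequence[CurationScore],
                       retain_answers=DEFAULT_RETAIN_ANSWERS) -> list:
    """Partition the curated subset into retained/rejected per curator.

    By default Yes and Maybe both count as retained (lenient reading); pass
    ``retain_answers={"YES"}`` for the stringent reading.  Every curator
    must have scored every SV in the curated subset.
    """
    retain_answers = frozenset(a.upper() for a in retain_answers)
    all_ids = {s.sv_id for s in scores}
    by_curator = {}
    for s in scores:
        by_curator.setdefault(s.curator, {})[s.sv_id] = s.answer
    verdicts = []
    for curator in sorted(by_curator):
        answers = by_curator[curator]
        missing = all_ids - set(answers)
        if missing:
            raise ValueError(
                f"curator {curator} is missing scores for {len(missing)} SVs "
                f"(e.g. {sorted(missing)[0]!r})")
        retained = {sv for sv, a in answers.items() if a in retain_answers}
        verdicts.append(CuratorVerdicts(curator=curator, retained=retained,
                                        rejected=all_ids - retained))
    return verdicts


def rank_by_stringency(verdicts: Sequence[CuratorVerdicts]) -> list:
    """Order curators from most lenient (fewest rejections) to most
    stringent; ties break lexicographically by name, with a warning."""
    if not verdicts:
        raise ValueError("no curator verdicts to rank")
    counts = {}
    for v in verdicts:
        counts.setdefault(v.n_rejected, []).append(v.curator)
    for n, names in counts.items():
        if len(names) > 1:
            logger.warning("stringency tie at %d rejections between %s; breaking lexicographically",
                           n, sorted(names))
    return sorted(verdicts, key=lambda v: (v.n_rejected, v.curator))


def consensus(ordered_verdicts: Sequence[CuratorVerdicts], k: int) -> set:
    """Intersection of the retained sets of the k most lenient curators.

    ``k = len(verdicts)`` reproduces the all-curator consensus callset;
    consensus size is non-increasing in k.
    """
    if not 1 <= k <= len(ordered_verdicts):
        raise ValueError(f"k={k} outside 1..{len(ordered_verdicts)}")
    result = set(ordered_verdicts[0].retained)
    for v in ordered_verdicts[1:k]:
        result &= v.retained
    return result


def agreement(lenient: CuratorVerdicts, others: Sequence[CuratorVerdicts]) -> Optional[float]:
    """Percent of the lenient curator's rejections co-rejected by every
    other curator; None (not applicable) when the lenient curator rejected
    nothing."""
    if not lenient.rejected:
        logger.warning("curator %s rejected nothing; agreement undefined", lenient.curator)
        return None
    co_rejected = set(lenient.rejected)
    for v in others:
        co_rejected &= v.rejected
    return 100.0 * len(co_rejected) / len(lenient.rejected)


def agreement_report(ordered_verdicts: Sequence[CuratorVerdicts]) -> list:
    """(k, consensus size, agreement-with-first-k) rows for k = 1..n."""
    rows = []
    lenient = ordered_verdicts[0]
    for k in range(1, len(ordered_verdicts) + 1):
        pct = agreement(lenient, ordered_verdicts[1:k]) if k > 1 else 100.0
        rows.append((k, len(consensus(ordered_verdicts, k)), pct))
    return rows
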