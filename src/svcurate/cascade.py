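"""The ordered confidence-filter cascade with full per-stage bookkeeping.

Stage order mirrors the recommended workflow: raw calls -> call quality
(DHFFC) -> genotype quality (MSHQ) -> genotype frequency -> curation.
Each stage consumes the previous stage's retained set; the ledger keeps
retained and rejected sets per stage so percentages can be reported
against any denominator convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .evidence import site_dhffc
from .svio import MSHQ_NO_HETS, SV_TYPES, SVCall

logger = logging.getLogger(__name__)

DEFAULT_DEL_THRESHOLD = 0.7
DEFAULT_DUP_THRESHOLD = 1.3
DEFAULT_MIN_MSHQ = 3.0
DEFAULT_MIN_PER_CLASS = 3


def dhffc_filter(calls: Sequence[SVCall], del_threshold: float = DEFAULT_DEL_THRESHOLD,
                 dup_threshold: float = DEFAULT_DUP_THRESHOLD,
                 mode: str = "median_carriers"):
    """Call-quality filter on the site-level depth fold-change.

    Deletions are retained iff DHFFC < del_threshold and duplications iff
    DHFFC > dup_threshold (both strict).  Depth fold-change carries no
    expectation for copy-neutral inversions, so INV calls always pass.
    Calls whose site DHFFC is undefined are retained with a warning.
    """
    if del_threshold <= 0 or dup_threshold <= 0:
        raise ValueError("DHFFC thresholds must be positive")
    retained, rejected = [], []
    for call in calls:
        if call.svtype == "INV":
            retained.append(call)
            continue
        value = site_dhffc(call, mode)
        if math.isnan(value):
            logger.warning("call %s: undefined site DHFFC, retained unjudged", call.id)
            retained.append(call)
        elif (call.svtype == "DEL" and value < del_threshold) or \
                (call.svtype == "DUP" and value > dup_threshold):
            retained.append(call)
        else:
            rejected.append(call)
    return retained, rejected


def mshq_filter(calls: Sequence[SVCall], min_mshq: float = DEFAULT_MIN_MSHQ):
    """Genotype-quality filter: retained iff MSHQ >= min_mshq or MSHQ == -1
    (the no-het sentinel, which carries no heterozygote evidence to judge)."""
    retained, rejected = [], []
    for call in calls:
        if call.mshq is None:
            raise ValueError(f"call {call.id}: MSHQ missing")
        if call.mshq >= min_mshq or call.mshq == MSHQ_NO_HETS:
            retained.append(call)
        else:
            rejected.append(call)
    return retained, rejected


def genotype_frequency_filter(calls: Sequence[SVCall],
                              min_per_class: int = DEFAULT_MIN_PER_CLASS):
    """Retain calls with at least ``min_per_class`` individuals in each of
    the three genotype classes (hom-ref, het, hom-alt); missing genotypes
    count toward no class.  This selects the common SVs whose fixed-order
    evidence panels make rapid visual curation possible."""
    if min_per_class < 1:
        raise ValueError("min_per_class must be >= 1")
    retained, rejected = [], []
    for call in calls:
        if min(call.genotype_counts()) >= min_per_class:
            retained.append(call)
        else:
            rejected.append(call)
    return retained, rejected


def curation_filter(calls: Sequence[SVCall], retained_ids: set):
    """Keep the calls whose ids are in a curation consensus set."""
    retained = [c for c in calls if c.id in retained_ids]
    rejected = [c for c in calls if c.id not in retained_ids]
    return retained, rejected


def external_rejection_filter(calls: Sequence[SVCall], rejected_ids: set):
    """Apply an externally supplied rejection list (e.g. an automated
    deep-learning curator run outside this package) by SV id."""
    retained = [c for c in calls if c.id not in rejected_ids]
    rejected = [c for c in calls if c.id in rejected_ids]
    return retained, rejected


_STAGES = {
    "dhffc": dhffc_filter,
    "mshq": mshq_filter,
    "genotype_frequency": genotype_frequency_filter,
    "curation": curation_filter,
    "external_rejection": external_rejection_filter,
}


@dataclass
class StageRecord:
    name: str
    input: list
    retained: list
    rejected: list

    def counts(self) -> list:
        rows = []
        for svtype in SV_TYPES:
            n_in = sum(1 for c in self.input if c.svtype == svtype)
            n_ret = sum(1 for c in self.retained if c.svtype == svtype)
            rows.append((self.name, svtype, n_in, n_ret, n_in - n_ret))
        return rows


@dataclass
class CascadeResult:
    """Ordered ledger of the filter cascade.

    ``denominators`` maps a stage name to the stage whose *input* set is the
    reference population for percentage reporting (by default each stage's
    own input).
    """

    input_calls: list
    stages: list = field(default_factory=list)
    denominators: dict = field(default_factory=dict)

    def stage(self, name: str) -> StageRecord:
        for rec in self.stages:
            if rec.name == name:
                return rec
        raise KeyError(f"no stage named {name!r} in cascade")

    @property
    def retained(self) -> list:
        return self.stages[-1].retained if self.stages else list(self.input_calls)

    def ledger(self) -> pd.DataFrame:
        rows = [row for rec in self.stages for row in rec.counts()]
        return pd.DataFrame(rows, columns=["stage", "svtype", "n_in", "n_retained", "n_rejected"])

    def write_ledger(self, path: str) -> None:
        self.ledger().to_csv(path, sep="\t", index=False)


def run_cascade(calls: Sequence[SVCall], stages: Sequence[str],
                parameters: Optional[dict] = None,
                denominators: Optional[dict] = None) -> CascadeResult:
    """Run named filter stages in order, each consuming the previous
    retained set, and return the full ledger.

    ``parameters`` maps stage name to keyword arguments for that filter
    (e.g. ``{"curation": {"retained_ids": ids}}``).  Conservation
    (retained + rejected = input, disjoint) is asserted at every stage.
    """
    parameters = parameters or {}
    result = CascadeResult(input_calls=list(calls))
    current = list(calls)
    prev_name = "raw"
    for name in stages:
        if name not in _STAGES:
            raise ValueError(f"unknown cascade stage {name!r}; known: {sorted(_STAGES)}")
        retained, rejected = _STAGES[name](current, **parameters.get(name, {}))
        ids_in = {c.id for c in current}
        ids_out = {c.id for c in retained} | {c.id for c in rejected}
        if ids_out != ids_in or len(retained) + len(rejected) != len(current):
            raise AssertionError(f"stage {name} violated conservation")
        result.stages.append(StageRecord(name=name, input=current,
                                         retained=retained, rejected=rejected))
        result.denominators[name] = (denominators or {}).get(name, name)
        logger.info("stage %s: %d in, %d retained, %d rejected (after %s)",
                    name, len(current), len(retained), len(rejected), prev_name)
        current = retained
        prev_name = name
    return result
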