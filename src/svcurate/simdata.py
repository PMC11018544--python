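"""Synthetic cohorts for exercising the SV confidence pipeline.

The generator emulates the statistical structure of a medium-coverage
(~10x) short-read resequencing study of a structured bird population:
33 diploid individuals drawn from four population clusters, three SV
classes (DEL/DUP/INV), a configurable fraction of false-positive calls
carrying neither a depth signature nor population structure, and a roster
of curators of varying stringency.

Population differentiation follows the Balding-Nichols model: a true SV
site has an ancestral allele frequency p ~ U(0.05, 0.95) and per-population
frequencies Beta(p(1-F)/F, (1-p)(1-F)/F), so the differentiation parameter
F equals the expected Weir-Cockerham F_ST and can be recovered by the
popgen module.  False calls draw every genotype independently from one
global frequency q ~ U(0.05, 0.5): no structure at all.

Read depth is per-base Poisson(coverage * m), where the copy-number
multiplier m inside a true deletion is 1/0.5/0 and inside a true
duplication 1/1.5/2 for genotype 0/1/2; inversions are copy-neutral
(m = 1), as are all false calls and all flanks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import evidence
from .svio import FALSE_CALL, TRUE_SV, CurationScore, SVCall

DEFAULT_POPULATIONS = ("Trondelag", "Pasvik", "Finland", "LekaVega")


@dataclass
class CuratorModel:
    """Bernoulli model of one curator's verdict behaviour.

    ``p_retain_true`` is the curator's sensitivity on panels of real SVs,
    ``p_retain_false`` their false-retention rate (1 - specificity) on
    panels of false calls; a retained verdict becomes MAYBE with
    probability ``p_maybe_given_retain`` when the curator uses the Maybe
    category at all.
    """

    name: str
    p_retain_true: float
    p_retain_false: float
    p_maybe_given_retain: float = 0.0
    uses_maybe: bool = True

    def __post_init__(self):
        for attr in ("p_retain_true", "p_retain_false", "p_maybe_given_retain"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"curator {self.name}: {attr}={v} outside [0, 1]")
        if not self.uses_maybe and self.p_maybe_given_retain != 0.0:
            raise ValueError(f"curator {self.name}: uses_maybe=False forces p_maybe_given_retain=0")


def default_curators() -> list:
    # Four curators in increasing stringency.  The stricter curators'
    # near-zero false-retention rates encode the near-complete co-rejection
    # of obvious false positives that multi-curator studies report; the
    # lenient curator deliberately lets half the false calls through while
    # almost never discarding a real SV.
    return [
        CuratorModel("lenient", 0.995, 0.50, 0.25, True),
        CuratorModel("moderate", 0.98, 0.01, 0.20, True),
        CuratorModel("strict", 0.96, 0.005, 0.15, True),
        CuratorModel("strictest", 0.93, 0.002, 0.0, False),
    ]


def _default_size_spectrum() -> dict:
    # log-uniform length ranges per class (bp); minima follow the smallest
    # raw calls per class in the study design, maxima are kept at desk
    # scale so per-base depth simulation stays cheap.
    return {"DEL": (23, 5000), "DUP": (79, 8000), "INV": (33, 2000)}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort, plus the master seed."""

    n_populations: int = 4
    samples_per_population: Sequence[int] = (9, 8, 8, 8)
    fst_param: float = 0.15
    n_true_sv: int = 100
    n_false_sv: int = 100
    size_spectrum: dict = field(default_factory=_default_size_spectrum)
    coverage: float = 10.0
    flank_bp: int = 1000
    shq_true_weights: Sequence[float] = (0.05, 0.05, 0.45, 0.45)
    shq_false_weights: Sequence[float] = (0.45, 0.45, 0.05, 0.05)
    curators: list = field(default_factory=default_curators)
    seed: int = 0

    def __post_init__(self):
        if self.n_populations < 1:
            raise ValueError("need at least one population")
        if len(self.samples_per_population) != self.n_populations:
            raise ValueError("samples_per_population length must equal n_populations")
        if not 0.0 <= self.fst_param < 1.0:
            raise ValueError("fst_param must lie in [0, 1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.n_true_sv < 0 or self.n_false_sv < 0:
            raise ValueError("SV counts must be non-negative")
        for cls, (lo, hi) in self.size_spectrum.items():
            if not (20 < lo <= hi):
                raise ValueError(f"{cls}: size range ({lo}, {hi}) must satisfy 20 < lo <= hi")

    @property
    def n_samples(self) -> int:
        return int(sum(self.samples_per_population))

    def sample_table(self) -> pd.DataFrame:
        pops = list(DEFAULT_POPULATIONS)[: self.n_populations]
        while len(pops) < self.n_populations:
            pops.append(f"pop{len(pops) + 1}")
        rows = []
        for pop, n in zip(pops, self.samples_per_population):
            rows += [(f"{pop}_{i + 1:02d}", pop) for i in range(n)]
        return pd.DataFrame(rows, columns=["sample", "population"])


def load_config(path: str) -> SimulationConfig:
    """Read a SimulationConfig from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "curators" in raw:
        raw["curators"] = [CuratorModel(**c) for c in raw["curators"]]
    if "size_spectrum" in raw:
        raw["size_spectrum"] = {k: tuple(v) for k, v in raw["size_spectrum"].items()}
    return SimulationConfig(**raw)


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["samples_per_population"] = list(config.samples_per_population)
    return d


# ---------------------------------------------------------------------------
# seeding: one master seed, named independent sub-streams

def _stream(config: SimulationConfig, *key) -> np.random.Generator:
    name_codes = tuple(ord(ch) for part in key for ch in str(part))
    return np.random.default_rng(np.random.SeedSequence((config.seed,) + name_codes))


# ---------------------------------------------------------------------------
# genotypes

def _true_site_genotypes(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols genotypes for one true SV site across the cohort."""
    F = config.fst_param
    p = rng.uniform(0.05, 0.95)
    genotypes = np.empty(config.n_samples, dtype=np.int8)
    offset = 0
    for n in config.samples_per_population:
        if F > 0:
            p_pop = rng.beta(p * (1 - F) / F, (1 - p) * (1 - F) / F)
        else:
            p_pop = p
        genotypes[offset:offset + n] = rng.binomial(2, p_pop, size=n)
        offset += n
    return genotypes


def _false_site_genotypes(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    q = rng.uniform(0.05, 0.5)
    return rng.binomial(2, q, size=config.n_samples).astype(np.int8)


def simulate_population(config: SimulationConfig):
    """Generate the cohort's SV callset with truth labels and its sample table.

    Calls are laid out non-overlapping (gaps wider than two flanks) on one
    chromosome per SV class; true and false calls are interleaved in random
    order.  Per-call depth profiles are produced separately by
    :func:`simulate_depth` so that the full cohort never has to hold
    per-base depth for every call at once.
    """
    table = config.sample_table()
    samples = tuple(table["sample"])
    calls = []
    for svtype, (lo, hi) in config.size_spectrum.items():
        rng = _stream(config, "genotypes", svtype)
        truths = [TRUE_SV] * config.n_true_sv + [FALSE_CALL] * config.n_false_sv
        rng.shuffle(truths)
        lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(truths)))
        lengths = np.maximum(np.round(lengths).astype(int), lo)
        pos = 10_000
        for i, (truth, length) in enumerate(zip(truths, lengths)):
            genotypes = (_true_site_genotypes(config, rng) if truth == TRUE_SV
                         else _false_site_genotypes(config, rng))
            calls.append(SVCall(
                id=f"{svtype.lower()}_{i + 1:05d}",
                chrom=f"chr_{svtype}", start=pos, end=pos + int(length),
                svtype=svtype, samples=samples, genotypes=genotypes, truth=truth,
            ))
            pos += int(length) + 2 * config.flank_bp + int(rng.integers(200, 1000))
    return calls, table


# ---------------------------------------------------------------------------
# evidence

_DEL_MULT = {0: 1.0, 1: 0.5, 2: 0.0}
_DUP_MULT = {0: 1.0, 1: 1.5, 2: 2.0}


def _copy_multiplier(call: SVCall, genotype: int) -> float:
    if call.truth == FALSE_CALL or call.svtype == "INV" or genotype < 0:
        return 1.0
    if call.svtype == "DEL":
        return _DEL_MULT[genotype]
    return _DUP_MULT[genotype]


def simulate_depth(call: SVCall, config: SimulationConfig,
                   rng: Optional[np.random.Generator] = None):
    """Per-base Poisson depth profiles over the call plus both flanks.

    Flank depth is always Poisson(coverage); inside the SV the rate is
    scaled by the carrier's copy-number multiplier (true DEL/DUP only).
    Deterministic per call under the config seed when no rng is passed.
    """
    if rng is None:
        rng = _stream(config, "depth", call.id)
    profiles = []
    svlen, flank = call.svlen, config.flank_bp
    for i, sample in enumerate(call.samples):
        m = _copy_multiplier(call, int(call.genotypes[i]))
        depth = np.empty(svlen + 2 * flank, dtype=np.int32)
        depth[:flank] = rng.poisson(config.coverage, flank)
        depth[flank:flank + svlen] = rng.poisson(config.coverage * m, svlen)
        depth[flank + svlen:] = rng.poisson(config.coverage, flank)
        profiles.append(evidence.DepthProfile(
            sample=sample, chrom=call.chrom, start=call.start - flank, depth=depth))
    return profiles


def simulate_shq(call: SVCall, config: SimulationConfig,
                 rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Draw SHQ (1-4) for each heterozygous sample; NaN for non-hets.

    True SVs concentrate SHQ mass on {3, 4}, false calls on {1, 2}
    (default 0.9 on the favoured pair).
    """
    if rng is None:
        rng = _stream(config, "shq", call.id)
    weights = (config.shq_true_weights if call.truth == TRUE_SV
               else config.shq_false_weights)
    shq = np.full(len(call.samples), np.nan)
    hets = np.flatnonzero(call.genotypes == 1)
    if hets.size:
        shq[hets] = rng.choice([1, 2, 3, 4], size=hets.size, p=weights)
    return shq


def simulate_dataset(config: SimulationConfig):
    """Full annotated cohort: calls with DHFFC/SHQ/MSHQ evidence plus the
    sample table.  Depth profiles are generated and reduced call-by-call."""
    calls, table = simulate_population(config)
    for call in calls:
        call.shq = simulate_shq(call, config)
        profiles = simulate_depth(call, config)
        evidence.annotate_call(call, profiles, config.flank_bp)
    return calls, table


# ---------------------------------------------------------------------------
# curators

def simulate_curators(calls: Sequence[SVCall], curators: Sequence[CuratorModel],
                      seed: int) -> list:
    """Score every call with every curator under the Bernoulli verdict model."""
    if not curators:
        raise ValueError("curator list is empty")
    for call in calls:
        if call.truth is None:
            raise ValueError(f"call {call.id} has no truth label; cannot simulate verdicts")
    scores = []
    for curator in curators:
        rng = np.random.default_rng(np.random.SeedSequence(
            (seed,) + tuple(ord(c) for c in curator.name)))
        for call in calls:
            p_retain = (curator.p_retain_true if call.truth == TRUE_SV
                        else curator.p_retain_false)
            if rng.random() < p_retain:
                maybe = curator.uses_maybe and rng.random() < curator.p_maybe_given_retain
                answer = "MAYBE" if maybe else "YES"
            else:
                answer = "NO"
            scores.append(CurationScore(sv_id=call.id, curator=curator.name, answer=answer))
    return scores
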