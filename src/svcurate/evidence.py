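"""Heuristic evidence annotations: depth fold-change (DHFFC) and mean
heterozygote quality (MSHQ).

DHFFC compares read depth inside a putative deletion/duplication with the
depth in 1 kb flanking windows: a real deletion carrier sits well below 1,
a real duplication carrier well above 1, and copy-neutral events (and false
calls) near 1.  MSHQ averages the per-heterozygote genotype quality (SHQ,
1-4) and takes the sentinel -1 when a variant has no het carrier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .svio import MSHQ_NO_HETS, SVCall

logger = logging.getLogger(__name__)

SITE_DHFFC_MODES = ("median_carriers", "any_carrier", "all_carriers")


@dataclass
class DepthProfile:
    """Per-base depth for one sample over an SV plus both flanks.

    ``start`` is the 0-based position of the first covered base, i.e.
    ``call.start - flank_bp``; ``depth[i]`` is the depth at ``start + i``.
    """

    sample: str
    chrom: str
    start: int
    depth: np.ndarray

    @property
    def end(self) -> int:
        return self.start + len(self.depth)


def compute_dhffc(profile: DepthProfile, call: SVCall, flank_bp: int = 1000) -> float:
    """Median depth inside [start, end) over the median depth of both flanks pooled.

    Returns NaN (undefined) when the pooled flank median is zero; such a
    call cannot be judged by depth and is retained downstream with a warning.
    """
    if flank_bp <= 0:
        raise ValueError("flank_bp must be positive")
    if profile.chrom != call.chrom or profile.start != call.start - flank_bp \
            or profile.end < call.end + flank_bp:
        raise ValueError(
            f"profile for {profile.sample} covers {profile.chrom}:{profile.start}-{profile.end}, "
            f"call {call.id} needs {call.chrom}:{call.start - flank_bp}-{call.end + flank_bp}")
    inside = profile.depth[flank_bp:flank_bp + call.svlen]
    flanks = np.concatenate([profile.depth[:flank_bp],
                             profile.depth[flank_bp + call.svlen:flank_bp + call.svlen + flank_bp]])
    flank_med = float(np.median(flanks))
    if flank_med == 0:
        logger.warning("call %s sample %s: zero flank median depth, DHFFC undefined",
                       call.id, profile.sample)
        return float("nan")
    return float(np.median(inside)) / flank_med


def compute_mshq(call: SVCall) -> float:
    """Arithmetic mean of SHQ over heterozygous samples; -1 if no sample is het."""
    hets = np.flatnonzero(call.genotypes == 1)
    if hets.size == 0:
        return MSHQ_NO_HETS
    if call.shq is None:
        raise ValueError(f"call {call.id}: SHQ absent but het samples present")
    vals = call.shq[hets]
    bad = np.flatnonzero(~np.isfinite(vals))
    if bad.size:
        raise ValueError(
            f"call {call.id}: het sample {call.samples[hets[bad[0]]]!r} has no SHQ")
    return float(np.mean(vals))


def site_dhffc(call: SVCall, mode: str = "median_carriers") -> float:
    """Reduce per-sample DHFFC to one site-level value over carrier samples.

    modes: ``median_carriers`` (default), ``any_carrier`` (minimum) and
    ``all_carriers`` (maximum).  Non-carriers (genotype 0 or missing) are
    excluded; with no carrier, or no finite carrier DHFFC, returns NaN.
    """
    if mode not in SITE_DHFFC_MODES:
        raise ValueError(f"unknown site DHFFC mode {mode!r}")
    if call.dhffc is None:
        raise ValueError(f"call {call.id}: per-sample DHFFC not set")
    vals = call.dhffc[call.carrier_mask()]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    if mode == "median_carriers":
        return float(np.median(vals))
    if mode == "any_carrier":
        return float(np.min(vals))
    return float(np.max(vals))


def annotate_call(call: SVCall, profiles, flank_bp: int = 1000) -> SVCall:
    """Fill ``call.dhffc`` from per-sample depth profiles and ``call.mshq``
    from per-sample SHQ (when genotypes include hets).  Mutates and returns
    the call."""
    by_sample = {p.sample: p for p in profiles}
    dhffc = np.full(len(call.samples), np.nan)
    for i, s in enumerate(call.samples):
        if s in by_sample:
            dhffc[i] = compute_dhffc(by_sample[s], call, flank_bp)
    call.dhffc = dhffc
    call.mshq = compute_mshq(call)
    return call


# ---------------------------------------------------------------------------
# Depth TSV interchange (sample, chrom, pos, depth)

def write_depth_tsv(profiles, path: str) -> None:
    frames = []
    for p in profiles:
        frames.append(pd.DataFrame({
            "sample": p.sample, "chrom": p.chrom,
            "pos": np.arange(p.start, p.end), "depth": p.depth,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_depth_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    if not {"sample", "chrom", "pos", "depth"}.issubset(df.columns):
        raise ValueError("depth TSV needs columns: sample, chrom, pos, depth")
    return df


def profiles_for_call(depth: pd.DataFrame, call: SVCall, flank_bp: int = 1000):
    """Extract one DepthProfile per sample for a call from a depth table."""
    lo, hi = call.start - flank_bp, call.end + flank_bp
    window = depth[(depth["chrom"] == call.chrom) & (depth["pos"] >= lo) & (depth["pos"] < hi)]
    if window.empty:
        raise ValueError(f"depth table has no coverage for {call.id} "
                         f"({call.chrom}:{lo}-{hi})")
    profiles = []
    for sample, grp in window.groupby("sample", sort=False):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        if len(pos) != hi - lo or pos[0] != lo:
            raise ValueError(f"depth table does not fully cover {call.id} for sample {sample}")
        profiles.append(DepthProfile(sample=str(sample), chrom=call.chrom, start=lo,
                                     depth=grp["depth"].to_numpy()))
    return profiles
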