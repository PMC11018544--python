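"""Domain types and readers/writers for the formats the pipeline touches.

Coordinates are 0-based half-open internally, 1-based in VCF, 0-based
half-open in BED, so ``svlen == end - start`` everywhere inside the package.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

SV_TYPES = ("DEL", "DUP", "INV")
ANSWERS = ("YES", "MAYBE", "NO")

#: missing genotype sentinel in dosage vectors
MISSING = -1

#: MSHQ sentinel for variants with no heterozygous carrier
MSHQ_NO_HETS = -1.0

TRUE_SV = "TRUE_SV"
FALSE_CALL = "FALSE_CALL"


@dataclass
class SVCall:
    """One structural-variant record across a cohort.

    genotypes are allele dosages per sample: 0 hom-ref, 1 het, 2 hom-alt,
    -1 missing.  ``dhffc`` (depth fold-change vs. flanks) and ``shq``
    (per-heterozygote quality, 1-4) are per-sample arrays with NaN where
    unset; ``mshq`` is the site-level mean heterozygote quality with the
    sentinel -1 when the variant has no het carrier.
    """

    id: str
    chrom: str
    start: int
    end: int
    svtype: str
    samples: tuple
    genotypes: np.ndarray
    dhffc: Optional[np.ndarray] = None
    shq: Optional[np.ndarray] = None
    mshq: Optional[float] = None
    truth: Optional[str] = None

    def __post_init__(self):
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unsupported SVTYPE {self.svtype!r} for call {self.id}")
        if self.end <= self.start:
            raise ValueError(f"call {self.id}: end ({self.end}) must exceed start ({self.start})")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if len(self.genotypes) != len(self.samples):
            raise ValueError(f"call {self.id}: {len(self.genotypes)} genotypes for {len(self.samples)} samples")
        if self.truth is not None and self.truth not in (TRUE_SV, FALSE_CALL):
            raise ValueError(f"call {self.id}: unknown truth label {self.truth!r}")

    @property
    def svlen(self) -> int:
        return self.end - self.start

    def genotype_counts(self) -> tuple:
        """(n_homref, n_het, n_homalt); missing genotypes count toward no class."""
        g = self.genotypes
        return (int(np.sum(g == 0)), int(np.sum(g == 1)), int(np.sum(g == 2)))

    def carrier_mask(self) -> np.ndarray:
        return (self.genotypes == 1) | (self.genotypes == 2)


@dataclass(frozen=True)
class CurationScore:
    """One curator's verdict on one SV panel."""

    sv_id: str
    curator: str
    answer: str

    def __post_init__(self):
        if self.answer not in ANSWERS:
            raise ValueError(f"invalid answer {self.answer!r} for {self.sv_id}/{self.curator}")


def _check_consistent_samples(calls: Sequence[SVCall]) -> tuple:
    samples = calls[0].samples
    for c in calls:
        if c.samples != samples:
            raise ValueError(f"inconsistent sample sets: call {c.id} differs from {calls[0].id}")
    return samples


# ---------------------------------------------------------------------------
# VCF

def _build_header(calls: Sequence[SVCall]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    chroms = {}
    for c in calls:
        chroms[c.chrom] = max(chroms.get(c.chrom, 0), c.end + 1)
    for chrom, length in chroms.items():
        header.contigs.add(chrom, length=length + 10_000)
    header.info.add("SVTYPE", 1, "String", "Structural variant class")
    header.info.add("END", 1, "Integer", "End position (1-based inclusive)")
    header.info.add("SVLEN", 1, "Integer", "Structural variant length in bp")
    header.info.add("MSHQ", 1, "Float", "Mean heterozygote quality (-1 when no het carrier)")
    header.info.add("TRUTH", 1, "String", "Simulation truth label (TRUE_SV/FALSE_CALL)")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DHFFC", 1, "Float", "Depth fold-change of the SV vs. 1 kb flanks")
    header.formats.add("SHQ", 1, "Integer", "Per-sample heterozygote quality (1-4)")
    for s in calls[0].samples:
        header.add_sample(s)
    return header


_GT_CODES = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}


def write_sv_vcf(calls: Sequence[SVCall], path: str) -> None:
    """Write calls to a VCF 4.2 file with symbolic ALT alleles.

    DHFFC values are rounded to 3 decimals and MSHQ to 2 on output.
    Raises on an empty call list or inconsistent sample sets; no file is
    created in either case.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("refusing to write a VCF with no records")
    samples = _check_consistent_samples(calls)
    header = _build_header(calls)
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for c in calls:
            rec = vcf.new_record(
                contig=c.chrom, start=c.start, stop=c.end,
                alleles=("N", f"<{c.svtype}>"), id=c.id,
            )
            rec.info["SVTYPE"] = c.svtype
            rec.info["SVLEN"] = c.svlen
            if c.mshq is not None:
                rec.info["MSHQ"] = round(float(c.mshq), 2)
            if c.truth is not None:
                rec.info["TRUTH"] = c.truth
            for i, s in enumerate(samples):
                rec.samples[s]["GT"] = _GT_CODES[int(c.genotypes[i])]
                if c.dhffc is not None and np.isfinite(c.dhffc[i]):
                    rec.samples[s]["DHFFC"] = round(float(c.dhffc[i]), 3)
                if c.shq is not None and np.isfinite(c.shq[i]):
                    rec.samples[s]["SHQ"] = int(c.shq[i])
            vcf.write(rec)


def read_sv_vcf(path: str) -> list:
    """Read SV records from a VCF into :class:`SVCall` objects.

    VCF 1-based POS becomes 0-based half-open ``start``.  Records whose
    SVTYPE is not DEL/DUP/INV are skipped with a warning.  Missing
    annotations stay unset (None / NaN), never defaulted.
    """
    calls = []
    with pysam.VariantFile(path) as vcf:
        samples = tuple(vcf.header.samples)
        n = len(samples)
        # pysam raises on .get() for fields absent from the header entirely
        has = {f: f in vcf.header.info for f in ("SVLEN", "MSHQ", "TRUTH")}
        has_fmt = {f: f in vcf.header.formats for f in ("DHFFC", "SHQ")}
        for rec in vcf:
            svtype = rec.info.get("SVTYPE")
            if svtype not in SV_TYPES:
                logger.warning("skipping record %s at %s:%d with SVTYPE=%s",
                               rec.id, rec.contig, rec.pos, svtype)
                continue
            # SVLEN is authoritative for the interval length when present
            # (htslib derives the record end as POS + SVLEN for symbolic
            # alleles); otherwise the END-derived stop is used directly.
            svlen = rec.info.get("SVLEN") if has["SVLEN"] else None
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            end = rec.start + abs(int(svlen)) if svlen is not None else rec.stop
            genotypes = np.full(n, MISSING, dtype=np.int8)
            dhffc = np.full(n, np.nan)
            shq = np.full(n, np.nan)
            saw_dhffc = saw_shq = False
            for i, s in enumerate(samples):
                fmt = rec.samples[s]
                gt = fmt.get("GT")
                if gt is not None and None not in gt:
                    genotypes[i] = sum(gt)
                if has_fmt["DHFFC"]:
                    v = fmt.get("DHFFC")
                    if v is not None:
                        dhffc[i] = v
                        saw_dhffc = True
                if has_fmt["SHQ"]:
                    v = fmt.get("SHQ")
                    if v is not None:
                        shq[i] = v
                        saw_shq = True
            mshq = rec.info.get("MSHQ") if has["MSHQ"] else None
            calls.append(SVCall(
                id=rec.id, chrom=rec.contig, start=rec.start, end=end,
                svtype=svtype, samples=samples, genotypes=genotypes,
                dhffc=dhffc if saw_dhffc else None,
                shq=shq if saw_shq else None,
                mshq=None if mshq is None else round(float(mshq), 2),
                truth=rec.info.get("TRUTH") if has["TRUTH"] else None,
            ))
    return calls


# ---------------------------------------------------------------------------
# BED

def write_bed(calls: Sequence[SVCall], path: str) -> None:
    """Write a BED5 (chrom, start, end, id, svtype) file, 0-based half-open."""
    calls = list(calls)
    if not calls:
        raise ValueError("refusing to write a BED with no records")
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.id}\t{c.svtype}\n")


def read_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "id", "svtype"])
    return df


# ---------------------------------------------------------------------------
# Curation-score reports (PlotCritic-style TSV)

def read_score_report(path: str) -> list:
    """Read a tab-separated curation report with columns sv_id, curator, answer.

    Answers are normalised case-insensitively to YES/MAYBE/NO.  Unknown
    answer tokens and duplicate (sv_id, curator) pairs raise, naming the row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sv_id", "curator", "answer"}
    if not required.issubset(df.columns):
        raise ValueError(f"score report must have columns {sorted(required)}, got {list(df.columns)}")
    scores = []
    seen = set()
    for idx, row in df.iterrows():
        answer = str(row["answer"]).strip().upper()
        if answer not in ANSWERS:
            raise ValueError(f"row {idx + 2} of {path}: unknown answer {row['answer']!r}")
        key = (row["sv_id"], row["curator"])
        if key in seen:
            raise ValueError(f"row {idx + 2} of {path}: duplicate score for {key}")
        seen.add(key)
        scores.append(CurationScore(sv_id=row["sv_id"], curator=row["curator"], answer=answer))
    return scores


def write_score_report(scores: Iterable[CurationScore], path: str) -> None:
    df = pd.DataFrame([(s.sv_id, s.curator, s.answer) for s in scores],
                      columns=["sv_id", "curator", "answer"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample tables

def read_sample_table(path: str) -> pd.DataFrame:
    """TSV with columns sample, population; sample names must be unique."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "population"}.issubset(df.columns):
        raise ValueError("sample table needs columns: sample, population")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ValueError(f"duplicate sample name {dup!r} in {path}")
    return df.reset_index(drop=True)


def write_sample_table(table: pd.DataFrame, path: str) -> None:
    table[["sample", "population"]].to_csv(path, sep="\t", index=False)
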