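"""Population-structure validation: genotype-matrix PCA, Weir-Cockerham
(1984) F_ST variance components, and a cluster-separation score.

The F_ST estimator decomposes allele-frequency variance at a biallelic
site into components a (among populations), b (among individuals within
populations) and c (within individuals), from per-population sample sizes
n_i, allele frequencies p_i and observed heterozygote frequencies h_i.
The per-site estimate is a/(a+b+c); the "weighted" genome-wide aggregate
is sum(a)/sum(a+b+c) and the "mean" aggregate averages per-site ratios.
Negative per-site estimates are legitimate small-sample behaviour and are
never clamped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA
from sklearn.metrics import silhouette_score

from .svio import MISSING, SVCall

logger = logging.getLogger(__name__)


@dataclass
class GenotypeMatrix:
    """Individuals x variants allele-dosage matrix with population labels.

    ``dosages`` entries are 0/1/2 or NaN for missing.
    """

    dosages: np.ndarray
    samples: list
    populations: list
    variant_ids: Optional[list] = None

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape[0] != len(self.samples):
            raise ValueError("row count must equal sample count")
        if len(self.populations) != len(self.samples):
            raise ValueError("population labels must cover all samples")

    @classmethod
    def from_calls(cls, calls: Sequence[SVCall], sample_table: pd.DataFrame) -> "GenotypeMatrix":
        samples = list(calls[0].samples)
        pop_of = dict(zip(sample_table["sample"], sample_table["population"]))
        unknown = [s for s in samples if s not in pop_of]
        if unknown:
            raise ValueError(f"samples missing from sample table: {unknown[:3]}")
        dosages = np.stack([c.genotypes.astype(float) for c in calls], axis=1)
        dosages[dosages == MISSING] = np.nan
        return cls(dosages=dosages, samples=samples,
                   populations=[pop_of[s] for s in samples],
                   variant_ids=[c.id for c in calls])


@dataclass
class FstComponents:
    """WC84 per-site variance components and their intermediates."""

    a: float
    b: float
    c: float
    nbar: float      # mean per-population sample size
    nc: float        # sample-size correction
    pbar: float      # weighted mean allele frequency
    s2: float        # sample variance of allele frequencies over populations
    hbar: float      # weighted mean heterozygote frequency
    defined: bool = True

    @property
    def fst(self) -> float:
        denom = self.a + self.b + self.c
        if not self.defined or denom == 0:
            return float("nan")
        return self.a / denom


def wc_components(dosages: Sequence[float], populations: Sequence[str]) -> FstComponents:
    """WC84 variance components for one biallelic site.

    ``dosages`` are per-individual alt-allele counts (0/1/2, NaN/-1
    missing); individuals with missing genotypes are excluded.  Sites
    monomorphic across all called individuals (or with a degenerate design,
    e.g. one individual per population) are returned flagged undefined and
    are excluded from aggregates.
    """
    d = np.asarray(dosages, dtype=float)
    pops = np.asarray(populations)
    called = np.isfinite(d) & (d != MISSING)
    d, pops = d[called], pops[called]
    labels = pd.unique(pops)
    if len(labels) < 2:
        raise ValueError("need at least two populations with called genotypes")
    r = len(labels)
    n = np.array([np.sum(pops == lab) for lab in labels], dtype=float)
    p = np.array([np.mean(d[pops == lab]) / 2.0 for lab in labels])
    h = np.array([np.mean(d[pops == lab] == 1) for lab in labels])

    nbar = n.mean()
    nsum = n.sum()
    pbar = float(np.sum(n * p) / nsum)
    hbar = float(np.sum(n * h) / nsum)
    nc = (nsum - np.sum(n ** 2) / nsum) / (r - 1)
    s2 = float(np.sum(n * (p - pbar) ** 2) / ((r - 1) * nbar))

    undefined = FstComponents(np.nan, np.nan, np.nan, nbar, nc, pbar, s2, hbar, defined=False)
    if pbar in (0.0, 1.0) and s2 == 0.0:   # monomorphic across all samples
        return undefined
    if nbar <= 1 or nc <= 0:               # degenerate design, estimator blows up
        return undefined

    a = (nbar / nc) * (s2 - (1.0 / (nbar - 1.0)) *
                       (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0))
    b = (nbar / (nbar - 1.0)) * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2
                                 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
    c = hbar / 2.0
    return FstComponents(float(a), float(b), float(c), nbar, float(nc), pbar, s2, hbar)


def fst_components(G: GenotypeMatrix) -> list:
    return [wc_components(G.dosages[:, j], G.populations)
            for j in range(G.dosages.shape[1])]


def fst_aggregate(components: Sequence[FstComponents]) -> tuple:
    """(mean_fst, weighted_fst) over defined sites.

    mean_fst averages per-site a/(a+b+c); weighted_fst is
    sum(a)/sum(a+b+c).  Returns (nan, nan) when no site is defined.
    """
    defined = [comp for comp in components
               if comp.defined and np.isfinite(comp.fst)]
    if not defined:
        logger.warning("no defined polymorphic sites; F_ST aggregates undefined")
        return float("nan"), float("nan")
    mean_fst = float(np.mean([comp.fst for comp in defined]))
    num = sum(comp.a for comp in defined)
    den = sum(comp.a + comp.b + comp.c for comp in defined)
    return mean_fst, float(num / den)


def pairwise_fst(G: GenotypeMatrix, pop_a: str, pop_b: str) -> tuple:
    """Two-population (mean, weighted) F_ST restricted to samples of the
    two named clusters, supporting the 2-individuals-per-cluster design."""
    mask = np.isin(G.populations, [pop_a, pop_b])
    sub = GenotypeMatrix(G.dosages[mask], list(np.array(G.samples)[mask]),
                         list(np.array(G.populations)[mask]), G.variant_ids)
    return fst_aggregate(fst_components(sub))


def per_site_fst_table(G: GenotypeMatrix) -> pd.DataFrame:
    comps = fst_components(G)
    ids = G.variant_ids or [f"site_{j}" for j in range(len(comps))]
    return pd.DataFrame({
        "variant": ids,
        "a": [c.a for c in comps],
        "b": [c.b for c in comps],
        "c": [c.c for c in comps],
        "fst": [c.fst for c in comps],
    })


# ---------------------------------------------------------------------------
# PCA

def pca(G: GenotypeMatrix, n_components: int = 2, scale: bool = False) -> tuple:
    """Principal components of the dosage matrix.

    Columns are centered at twice the site allele frequency (the column
    mean of called dosages); missing entries are mean-imputed, which is
    neutral after centering.  With ``scale`` each column is divided by its
    binomial standard deviation sqrt(2 p (1-p)).  Returns (coordinates,
    explained variance fractions).
    """
    X = G.dosages.copy()
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 variants")
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    inds = np.where(np.isnan(X))
    X[inds] = col_mean[inds[1]]
    X -= col_mean
    if scale:
        p = col_mean / 2.0
        sd = np.sqrt(np.clip(2.0 * p * (1.0 - p), 1e-12, None))
        X /= sd
    if not np.any(X):
        logger.warning("all-constant genotype matrix: zero covariance, coordinates all zero")
        k = min(n_components, *X.shape)
        return np.zeros((X.shape[0], k)), np.zeros(k)
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    model = _SKPCA(n_components=k, svd_solver="full")
    coords = model.fit_transform(X)
    return coords, model.explained_variance_ratio_


def separation_score(coordinates: np.ndarray, populations: Sequence[str]) -> float:
    """Mean silhouette score of the population labels on the first two
    principal components; in [-1, 1], higher = better-separated clusters."""
    labels = np.asarray(populations)
    if len(set(labels)) < 2:
        raise ValueError("separation score needs at least two population labels")
    coords = np.asarray(coordinates)[:, :2]
    return float(silhouette_score(coords, labels))


def plot_pca(coordinates: np.ndarray, populations: Sequence[str], path: str,
             variance_fractions=None, title: str = "") -> None:
    """Scatter the first two PCs coloured by population (PNG/SVG by suffix)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    pops = np.asarray(populations)
    for pop in pd.unique(pops):
        m = pops == pop
        ax.scatter(coordinates[m, 0], coordinates[m, 1], label=pop, s=24)
    if variance_fractions is not None and len(variance_fractions) >= 2:
        ax.set_xlabel(f"PC1 ({100 * variance_fractions[0]:.1f}%)")
        ax.set_ylabel(f"PC2 ({100 * variance_fractions[1]:.1f}%)")
    else:
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
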