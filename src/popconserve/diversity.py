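"""Per-locus and population-level genetic-diversity statistics.

For a biallelic locus with alt-allele frequency p (q = 1 - p):

* minor allele frequency  MAF = min(p, q)
* expected heterozygosity He = 1 - sum(p_i^2)   (definitional, no
  small-sample correction by default)
* observed heterozygosity Ho = (# heterozygous calls) / (# called)
* polymorphism information content (Botstein)
  PIC = 1 - sum_i p_i^2 - sum_{i<j} 2 p_i^2 p_j^2
* effective allele number Ae = 1 / sum(p_i^2)

The Hardy-Weinberg test is the exact conditional test (all het-count
outcomes with the observed allele counts, summing the probabilities of
outcomes no more probable than the observed one); it is computed in exact
integer arithmetic so p-values carry no accumulation error.

The effective population size is estimated from linkage disequilibrium
through Sved's relation E[r^2] = 1/(1 + 4Nc), applied pair-by-pair to
sample-size-adjusted r^2 between nearby loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


class DiversityError(ValueError):
    """Undefined statistic (e.g. no called genotypes at a locus)."""


# ---------------------------------------------------------------------------
# per-locus primitives
# ---------------------------------------------------------------------------

def locus_frequencies(dosages: np.ndarray) -> tuple[float, float, int]:
    """Alt-allele frequency, MAF and called count for one dosage column."""
    d = np.asarray(dosages)
    called = d[d != MISSING]
    if called.size == 0:
        raise DiversityError("allele frequency undefined: no called genotypes")
    p = float(called.sum()) / (2.0 * called.size)
    return p, min(p, 1.0 - p), int(called.size)


def _check_freqs(freqs: Sequence[float]) -> np.ndarray:
    f = np.asarray(freqs, dtype=float)
    if (f < 0).any():
        raise DiversityError("allele frequencies must be nonnegative")
    if abs(f.sum() - 1.0) > 1e-9:
        raise DiversityError(f"allele frequencies sum to {f.sum()}, not 1")
    return f


def pic(freqs: Sequence[float]) -> float:
    """Botstein polymorphism information content of one marker."""
    f = _check_freqs(freqs)
    sq = f ** 2
    cross = np.outer(sq, sq)
    off = np.triu(cross, k=1).sum()
    return float(1.0 - sq.sum() - 2.0 * off)


def expected_heterozygosity(
    freqs: Sequence[float], unbiased: bool = False, n: int | None = None
) -> float:
    """He = 1 - sum p_i^2; optional (2n)/(2n-1) small-sample correction."""
    f = _check_freqs(freqs)
    he = float(1.0 - (f ** 2).sum())
    if unbiased:
        if not n or n < 1:
            raise DiversityError("unbiased He needs the sample size n")
        he *= 2 * n / (2 * n - 1)
    return he


def observed_heterozygosity(dosages: np.ndarray) -> float:
    """Fraction of called genotypes that are heterozygous."""
    d = np.asarray(dosages)
    called = d[d != MISSING]
    if called.size == 0:
        raise DiversityError("Ho undefined: no called genotypes")
    return float((called == 1).sum()) / called.size


def effective_allele_number(freqs: Sequence[float]) -> float:
    """Ae = 1 / sum p_i^2 (reciprocal homozygosity)."""
    f = _check_freqs(freqs)
    return float(1.0 / (f ** 2).sum())


def proportion_polymorphic(mafs: Sequence[float], threshold: float = 0.05) -> float:
    """Fraction of loci whose MAF reaches the polymorphism threshold.

    At ``threshold == 0`` a locus counts as polymorphic iff its MAF is
    strictly positive.
    """
    if not 0.0 <= threshold <= 0.5:
        raise DiversityError("polymorphism threshold must lie in [0, 0.5]")
    m = np.asarray(mafs, dtype=float)
    if m.size == 0:
        return 0.0
    if threshold == 0.0:
        return float((m > 0).mean())
    return float((m >= threshold).mean())


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4096)
def _het_weights(n: int, na: int) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Exact counts of genotype configurations for each feasible het count.

    For n diploid individuals carrying ``na`` copies of allele A (and
    2n - na of B), the number of equally likely allele arrangements giving
    h heterozygotes is  n! / (nAA! h! nBB!) * 2^h.
    """
    hets, weights = [], []
    h0 = na % 2
    for h in range(h0, min(na, 2 * n - na) + 1, 2):
        naa = (na - h) // 2
        nbb = n - naa - h
        if naa < 0 or nbb < 0:
            continue
        w = (
            math.factorial(n)
            // (math.factorial(naa) * math.factorial(h) * math.factorial(nbb))
            * 2 ** h
        )
        hets.append(h)
        weights.append(w)
    return tuple(hets), tuple(weights)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided Hardy-Weinberg exact test p-value.

    Conditions on the observed allele counts; the p-value is the total
    probability of het-count outcomes no more probable than the observed
    one. Computed with exact integers, so ties are resolved exactly.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise DiversityError("genotype counts must be nonnegative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise DiversityError("HWE test undefined on zero genotypes")
    na = 2 * n_hom_alt + n_het  # alt-allele count
    hets, weights = _het_weights(n, na)
    w_obs = weights[hets.index(n_het)]
    num = sum(w for w in weights if w <= w_obs)
    return num / sum(weights)


# ---------------------------------------------------------------------------
# LD-based effective population size
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeEstimate:
    ne: float
    n_pairs: int


def sved_ne(r2_adj: float, c: float) -> float:
    """Invert Sved's E[r^2] = 1/(1 + 4Nc) for one locus pair."""
    if not 0.0 < c <= 0.5:
        raise DiversityError("recombination fraction c must lie in (0, 0.5]")
    return (1.0 / (4.0 * c)) * (1.0 / r2_adj - 1.0)


def ne_from_ld(
    gm: GenotypeMatrix,
    recomb_rate_per_bp: float = 1e-8,
    max_pair_dist: int = 500_000,
    maf_floor: float = 0.05,
    r2_epsilon: float = 1e-6,
    method: str = "per_pair",
) -> NeEstimate:
    """LD-based effective population size via Sved's relation.

    r^2 is the squared Pearson correlation of dosages (missing calls mean
    imputed per locus); r^2_adj = r^2 - 1/(2n) corrects the finite-sample
    inflation and is floored at ``r2_epsilon``. Each pair's recombination
    fraction is bp distance x ``recomb_rate_per_bp`` capped at 0.5.

    ``method="per_pair"`` averages the per-pair inversions
    (1/(4c))(1/r^2_adj - 1); ``method="pooled"`` inverts the relation once
    at the mean adjusted r^2 and mean c over pairs, which is far more
    stable when many pairs sit near the r^2_adj floor (weak LD).
    """
    if method not in ("per_pair", "pooled"):
        raise DiversityError(f"unknown Ne method {method!r}")
    n = gm.n_samples
    if n < 2:
        raise DiversityError("Ne estimation needs at least 2 samples")
    estimates: list[float] = []
    r2s: list[float] = []
    cs: list[float] = []
    for chrom in dict.fromkeys(gm.variants["chrom"]):
        mask = (gm.variants["chrom"] == chrom).to_numpy()
        pos = gm.variants.loc[mask, "pos"].to_numpy()
        dos = gm.dosage[:, mask].astype(float)
        dos[dos == MISSING] = np.nan
        p = np.nanmean(dos, axis=0) / 2.0
        maf = np.minimum(p, 1 - p)
        keep = maf >= maf_floor
        if keep.sum() < 2:
            continue
        pos, dos = pos[keep], dos[:, keep]
        col_mean = np.nanmean(dos, axis=0)
        filled = np.where(np.isnan(dos), col_mean, dos)
        sd = filled.std(axis=0)
        ok = sd > 0
        pos, filled = pos[ok], filled[:, ok]
        if filled.shape[1] < 2:
            continue
        corr = np.corrcoef(filled.T)
        m = filled.shape[1]
        ii, jj = np.triu_indices(m, k=1)
        dist = pos[jj] - pos[ii]
        near = dist <= max_pair_dist
        for i, j, d in zip(ii[near], jj[near], dist[near]):
            r2_adj = max(corr[i, j] ** 2 - 1.0 / (2 * n), r2_epsilon)
            c = min(d * recomb_rate_per_bp, 0.5)
            if c <= 0:
                continue
            estimates.append(sved_ne(r2_adj, c))
            r2s.append(r2_adj)
            cs.append(c)
    if not estimates:
        raise DiversityError("no eligible locus pairs for Ne estimation")
    if method == "pooled":
        ne = sved_ne(float(np.mean(r2s)), float(np.mean(cs)))
    else:
        ne = float(np.mean(estimates))
    return NeEstimate(ne=ne, n_pairs=len(estimates))


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationDiversity:
    """Population-level means of the per-locus diversity statistics."""

    mean_maf: float
    pn: float
    mean_ho: float
    mean_he: float
    mean_pic: float
    mean_ae: float
    ne_ld: float | None
    n_loci: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("Effective Population Size (Ne)", self.ne_ld),
            ("Proportion of Polymorphic Markers (PN)", self.pn),
            ("Expected Heterozygosity (He)", self.mean_he),
            ("Observed Heterozygosity (Ho)", self.mean_ho),
            ("Polymorphism Information Content (PIC)", self.mean_pic),
            ("Effective Numbers of Alleles", self.mean_ae),
            ("Minor Allele Frequency (MAF)", self.mean_maf),
        ]
        return pd.DataFrame(rows, columns=["statistic", "value"])


def locus_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus statistics table: chrom, pos, p, maf, ho, he, pic, ae, hwe_p."""
    rows = []
    for j in range(gm.n_variants):
        col = gm.dosage[:, j]
        called = col[col != MISSING]
        if called.size == 0:
            rows.append((np.nan,) * 7 + (0,))
            continue
        p, maf, n_called = locus_frequencies(col)
        freqs = (1 - p, p)
        n_het = int((called == 1).sum())
        n_alt = int((called == 2).sum())
        rows.append(
            (
                p,
                maf,
                observed_heterozygosity(col),
                expected_heterozygosity(freqs),
                pic(freqs),
                effective_allele_number(freqs),
                hwe_exact_test(n_called - n_het - n_alt, n_het, n_alt),
                n_called,
            )
        )
    out = pd.DataFrame(
        rows, columns=["p", "maf", "ho", "he", "pic", "ae", "hwe_p", "n_called"]
    )
    out.insert(0, "pos", gm.variants["pos"].to_numpy())
    out.insert(0, "chrom", gm.variants["chrom"].to_numpy())
    out.insert(2, "id", gm.variants["id"].to_numpy())
    return out


def population_diversity(
    gm: GenotypeMatrix,
    pn_threshold: float = 0.05,
    estimate_ne: bool = True,
    **ne_kwargs,
) -> PopulationDiversity:
    """Population-level diversity summary over all loci of ``gm``.

    The headline Ne uses the pooled Sved inversion (stable under weak
    LD); pass ``method="per_pair"`` through ``ne_kwargs`` to override.
    """
    per_locus = locus_stats(gm)
    ok = per_locus["n_called"] > 0
    stats = per_locus.loc[ok]
    ne = None
    if estimate_ne:
        ne_kwargs.setdefault("method", "pooled")
        try:
            ne = ne_from_ld(gm, **ne_kwargs).ne
        except DiversityError:
            ne = None
    return PopulationDiversity(
        mean_maf=float(stats["maf"].mean()),
        pn=proportion_polymorphic(stats["maf"].to_numpy(), pn_threshold),
        mean_ho=float(stats["ho"].mean()),
        mean_he=float(stats["he"].mean()),
        mean_pic=float(stats["pic"].mean()),
        mean_ae=float(stats["ae"].mean()),
        ne_ld=ne,
        n_loci=int(ok.sum()),
    )
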