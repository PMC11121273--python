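"""Genomic relationship matrix, IBS distances and PCA.

Two kinship flavors are provided:

* ``grm(gm)`` — VanRaden method-1 genomic relationship matrix
  G = ZZ' / (2 * sum p_j q_j) with Z the allele-frequency-centered dosage,
  the estimator family behind GCTA-style kinship analysis. For each pair
  the sum runs over the mutually called loci (the PLINK ``--make-rel`` /
  GCTA convention), so missing calls do not deflate kinship. The diagonal
  is approximately 1 + F. Allele frequencies default to the analyzed
  sample's own; base-population frequencies can be supplied when known
  (sample frequencies shift unrelated pairs by about -2/n).
* ``grm(gm, method="standardized")`` — per-locus variance-standardized
  kinship X X' / m, the matrix whose eigendecomposition principal
  component analysis of SNP data diagonalizes (smartpca scaling).

``ibs_distance`` is the PLINK-style identity-by-state genetic distance
D = 1 - (N_IBS2 + 0.5 N_IBS1) / N over mutually called loci, used for
neighbor-joining clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


class RelatednessError(ValueError):
    """Degenerate input (monomorphic panel, uncallable pair, bad k)."""


@dataclass
class KinshipMatrix:
    """Symmetric sample x sample matrix, flavor "G" or "IBS_distance"."""

    ids: list[str]
    values: np.ndarray
    flavor: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise RelatednessError("kinship matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0):
            raise RelatednessError("kinship matrix not symmetric")

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def off_diagonal(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]


@dataclass
class PCAResult:
    """Sample coordinates on the top-k principal components."""

    ids: list[str]
    coords: np.ndarray  # (n_samples, k), columns scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # nonincreasing, nonnegative
    variance_explained: np.ndarray
    eigenvectors: np.ndarray  # (n_samples, k), orthonormal columns

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coords,
            columns=[f"PC{i + 1}" for i in range(self.coords.shape[1])],
        )
        df.insert(0, "sample_id", self.ids)
        return df


# ---------------------------------------------------------------------------

def _freqs_and_centered(
    gm: GenotypeMatrix, allele_freqs: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus alt frequency, centered dosage (missing -> 0), called mask."""
    dos = gm.dosage.astype(float)
    dos[dos == MISSING] = np.nan
    if allele_freqs is None:
        with np.errstate(invalid="ignore"):
            p = np.nanmean(dos, axis=0) / 2.0
        p = np.where(np.isnan(p), 0.0, p)  # all-missing loci: treated monomorphic
    else:
        p = np.asarray(allele_freqs, dtype=float)
        if p.shape != (gm.n_variants,):
            raise RelatednessError("allele_freqs length mismatch")
    z = dos - 2.0 * p
    called = ~np.isnan(z)
    z[~called] = 0.0  # missing -> locus mean, contributes 0
    return p, z, called


def grm(
    gm: GenotypeMatrix,
    method: str = "vanraden",
    allele_freqs: np.ndarray | None = None,
) -> KinshipMatrix:
    """Genomic relationship matrix.

    ``method="vanraden"`` normalizes each pair by 2*sum(p q) over the
    pair's mutually called loci. ``method="standardized"`` divides the
    standardized cross-product by the fixed locus count, the matrix
    principal component analysis diagonalizes.
    """
    if gm.n_samples < 2:
        raise RelatednessError("GRM needs at least 2 samples")
    p, z, called = _freqs_and_centered(gm, allele_freqs)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise RelatednessError("all loci monomorphic: GRM denominator is zero")
    c = called[:, poly].astype(float)
    if method == "vanraden":
        zp = z[:, poly]
        w = 2.0 * p[poly] * (1.0 - p[poly])
        num = zp @ zp.T
        den = (c * w) @ c.T
        if not (den > 0).all():
            raise RelatednessError("a sample pair shares no called polymorphic loci")
        g = num / den
    elif method == "standardized":
        sd = np.sqrt(2.0 * p[poly] * (1.0 - p[poly]))
        x = z[:, poly] / sd
        g = x @ x.T / poly.sum()
    else:
        raise RelatednessError(f"unknown GRM method {method!r}")
    g = (g + g.T) / 2.0  # exact symmetry against float noise
    return KinshipMatrix(gm.sample_ids, g, "G")


def ibs_distance(gm: GenotypeMatrix) -> KinshipMatrix:
    """Pairwise IBS genetic distance over mutually called loci.

    With dosages a, b the per-locus IBS state is 2 - |a - b|, so
    D = mean(|a - b|) / 2.
    """
    n = gm.n_samples
    if n < 2:
        raise RelatednessError("IBS distance needs at least 2 samples")
    called = gm.dosage != MISSING
    dos = gm.dosage.astype(np.int16)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = called[i] & called[j]
            nb = int(both.sum())
            if nb == 0:
                raise RelatednessError(
                    f"samples {gm.sample_ids[i]!r} and {gm.sample_ids[j]!r} "
                    "share no called loci"
                )
            diff = np.abs(dos[i, both] - dos[j, both]).sum()
            d[i, j] = d[j, i] = diff / (2.0 * nb)
    return KinshipMatrix(gm.sample_ids, d, "IBS_distance")


def pca(gm: GenotypeMatrix, k: int = 2) -> PCAResult:
    """Principal components of the standardized genotype matrix.

    Loci are standardized to (d - 2p) / sqrt(2 p q) with missing calls
    contributing zero; the sample x sample matrix X X' / m is
    eigendecomposed and coordinates are eigenvectors scaled by the square
    root of their eigenvalues.
    """
    n = gm.n_samples
    if not 0 < k < n:
        raise RelatednessError(f"k must satisfy 0 < k < n_samples, got {k}")
    kin = grm(gm, method="standardized")
    evals, evecs = np.linalg.eigh(kin.values)
    order = np.argsort(evals)[::-1][:k]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    coords = evecs * np.sqrt(evals)
    total = float(np.clip(np.linalg.eigvalsh(kin.values), 0, None).sum())
    return PCAResult(
        ids=gm.sample_ids,
        coords=coords,
        eigenvalues=evals,
        variance_explained=evals / total if total > 0 else evals * 0.0,
        eigenvectors=evecs,
    )
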