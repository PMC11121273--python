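"""SNP- and sample-level quality control.

The filter cascade mirrors standard PLINK-style genotype QC for a small
population: drop samples with low genotype detection rate, then drop SNPs
that fail any of — low call rate, low minor allele frequency,
Hardy-Weinberg disequilibrium, or location on a sex chromosome.

Per-criterion counts in the report are *standalone*: each criterion is
evaluated on the full input SNP set (over the retained samples), so the
counts may overlap and need not sum to ``total - retained``; the set
actually removed is the union.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .diversity import hwe_exact_test
from .genotypes import DEFAULT_AUTOSOMES, MISSING, GenotypeMatrix


class QCError(ValueError):
    """QC cannot proceed (e.g. every sample removed)."""


@dataclass
class QCConfig:
    """Thresholds of the filter cascade.

    ``min_depth`` and ``min_q20`` describe read-level genotyping criteria
    upstream of a genotype matrix; they are accepted for provenance but
    not enforced here.
    """

    min_sample_call_rate: float = 0.90
    min_snp_call_rate: float = 0.90
    min_maf: float = 0.01
    hwe_p_threshold: float = 1e-6
    autosomes_only: bool = True
    autosomes: Sequence[str] = DEFAULT_AUTOSOMES
    x_label: str = "X"
    y_label: str = "Y"
    min_depth: float | None = None  # provenance only
    min_q20: float | None = None  # provenance only

    def validate(self) -> None:
        for name in ("min_sample_call_rate", "min_snp_call_rate", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise QCError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.hwe_p_threshold <= 1.0:
            raise QCError("hwe_p_threshold must lie in [0, 1]")


@dataclass
class QCReport:
    """Per-criterion QC accounting (standalone, possibly overlapping counts)."""

    total_snps: int
    maf_fail: int
    hwe_fail: int
    callrate_fail: int
    chrx: int
    chry: int
    snps_retained: int
    samples_removed: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("Total number of SNPs", self.total_snps),
            ("SNP with MAF below threshold", self.maf_fail),
            ("SNP not in Hardy-Weinberg equilibrium", self.hwe_fail),
            ("SNP with call rate below threshold", self.callrate_fail),
            ("SNPs on chromosome X", self.chrx),
            ("SNPs on chromosome Y", self.chry),
            ("SNPs used after quality control", self.snps_retained),
        ]
        return pd.DataFrame(rows, columns=["criterion", "count"])


# ---------------------------------------------------------------------------

def snp_call_rate(gm: GenotypeMatrix, variant_index: int) -> float:
    """Fraction of samples with a called genotype at one variant."""
    if gm.n_samples == 0:
        raise QCError("SNP call rate undefined with zero samples")
    col = gm.dosage[:, variant_index]
    return float((col != MISSING).mean())


def sample_call_rate(gm: GenotypeMatrix, sample_index: int) -> float:
    """Fraction of variants called in one sample."""
    if gm.n_variants == 0:
        raise QCError("sample call rate undefined with zero variants")
    row = gm.dosage[sample_index, :]
    return float((row != MISSING).mean())


def _per_snp_masks(
    gm: GenotypeMatrix, cfg: QCConfig
) -> dict[str, np.ndarray]:
    """Boolean fail-masks per criterion, evaluated over gm's samples."""
    called = gm.dosage != MISSING
    n_called = called.sum(axis=0)
    n_samples = max(gm.n_samples, 1)
    callrate_fail = (n_called / n_samples) < cfg.min_snp_call_rate

    alt = np.where(called, gm.dosage, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_called > 0, alt / (2.0 * np.maximum(n_called, 1)), 0.0)
    maf = np.minimum(p, 1.0 - p)
    maf_fail = maf < cfg.min_maf  # all-missing loci count as MAF 0

    chrom = gm.variants["chrom"].astype(str).to_numpy()
    is_x = chrom == cfg.x_label
    is_y = chrom == cfg.y_label
    autosomal = np.isin(chrom, list(cfg.autosomes))

    n_het = ((gm.dosage == 1) & called).sum(axis=0)
    n_alt_hom = ((gm.dosage == 2) & called).sum(axis=0)
    hwe_fail = np.zeros(gm.n_variants, dtype=bool)
    for j in np.nonzero(autosomal & (n_called > 0))[0]:
        p_val = hwe_exact_test(
            int(n_called[j] - n_het[j] - n_alt_hom[j]),
            int(n_het[j]),
            int(n_alt_hom[j]),
        )
        hwe_fail[j] = p_val < cfg.hwe_p_threshold

    return {
        "callrate_fail": callrate_fail,
        "maf_fail": maf_fail,
        "hwe_fail": hwe_fail,
        "chrx": is_x,
        "chry": is_y,
        "nonautosomal": ~autosomal,
    }


def apply_qc(gm: GenotypeMatrix, cfg: QCConfig | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Run the full cascade; returns the filtered matrix and its report.

    Order: (1) samples failing the sample call-rate threshold are removed;
    (2) on the remaining samples each SNP criterion is evaluated on the
    full input SNP set and the union of failing SNPs is dropped.
    """
    cfg = cfg or QCConfig()
    cfg.validate()
    if gm.n_variants == 0:
        raise QCError("QC undefined on an empty variant set")

    rates = (gm.dosage != MISSING).mean(axis=1)
    removed = [
        sid
        for sid, r in zip(gm.sample_ids, rates)
        if r < cfg.min_sample_call_rate
    ]
    kept_samples = [s for s in gm.sample_ids if s not in set(removed)]
    if not kept_samples:
        raise QCError("QC removed every sample")
    gm_s = gm.subset(sample_ids=kept_samples) if removed else gm

    masks = _per_snp_masks(gm_s, cfg)
    drop = masks["callrate_fail"] | masks["maf_fail"] | masks["hwe_fail"]
    if cfg.autosomes_only:
        drop = drop | masks["nonautosomal"]
    retained = gm_s.subset(variant_predicate=~drop)

    report = QCReport(
        total_snps=gm.n_variants,
        maf_fail=int(masks["maf_fail"].sum()),
        hwe_fail=int(masks["hwe_fail"].sum()),
        callrate_fail=int(masks["callrate_fail"].sum()),
        chrx=int(masks["chrx"].sum()),
        chry=int(masks["chry"].sum()),
        snps_retained=retained.n_variants,
        samples_removed=removed,
    )
    return retained, report
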