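"""Core genotype data model.

The common currency of every analysis stage is a :class:`GenotypeMatrix`:
an ordered set of samples, an ordered map of biallelic variants, and a
samples x variants dosage table counting copies of the alternate allele
(0, 1, 2) with ``MISSING`` (-1) for no-calls.

Coordinates are 1-based inclusive base pairs, the VCF / PLINK MAP
convention. Chromosome labels are strings; autosome labels are
configurable (donkey default "1".."30").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

#: Dosage code for a missing genotype call.
MISSING: int = -1

#: Default autosome label set (donkey karyotype usage, chromosomes 1-30).
DEFAULT_AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 31))

SEXES = ("male", "female", "unknown")


class GenotypeError(ValueError):
    """Invalid genotype data or inconsistent matrix dimensions."""


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNP: chromosome, 1-based position, name and alleles."""

    chrom: str
    pos: int
    id: str
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise GenotypeError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise GenotypeError(f"variant {self.id}: ref and alt alleles are equal")


@dataclass(frozen=True)
class SampleRecord:
    """One sample: unique id and sex label."""

    id: str
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise GenotypeError(f"sample {self.id}: sex must be one of {SEXES}")


@dataclass
class GenotypeMatrix:
    """Samples x variants alt-allele dosage matrix with metadata.

    Parameters
    ----------
    samples
        DataFrame with columns ``id`` and ``sex``, one row per sample, in
        matrix row order.
    variants
        DataFrame with columns ``chrom``, ``pos``, ``id``, ``ref``, ``alt``,
        one row per variant, in matrix column order. Within each chromosome
        positions must be strictly increasing.
    dosage
        int8 array of shape (n_samples, n_variants); entries in
        {0, 1, 2, MISSING}.
    provenance
        Free-form notes on how the matrix was produced (e.g. alt-allele
        polarity decisions made by a reader).
    """

    samples: pd.DataFrame
    variants: pd.DataFrame
    dosage: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.variants = self.variants.reset_index(drop=True)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(
        cls,
        samples: Sequence[SampleRecord],
        variants: Sequence[VariantRecord],
        dosage: np.ndarray,
        provenance: dict | None = None,
    ) -> "GenotypeMatrix":
        sdf = pd.DataFrame(
            {"id": [s.id for s in samples], "sex": [s.sex for s in samples]},
            dtype=object,
        )
        vdf = pd.DataFrame(
            {
                "chrom": [v.chrom for v in variants],
                "pos": [v.pos for v in variants],
                "id": [v.id for v in variants],
                "ref": [v.ref_allele for v in variants],
                "alt": [v.alt_allele for v in variants],
            }
        )
        return cls(sdf, vdf, dosage, provenance or {})

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        ns, nv = len(self.samples), len(self.variants)
        if self.dosage.shape != (ns, nv):
            raise GenotypeError(
                f"dosage shape {self.dosage.shape} != ({ns} samples, {nv} variants)"
            )
        if ns and self.samples["id"].duplicated().any():
            dup = self.samples["id"][self.samples["id"].duplicated()].iloc[0]
            raise GenotypeError(f"duplicate sample id {dup!r}")
        legal = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not legal.all():
            bad = self.dosage[~legal][0]
            raise GenotypeError(f"illegal dosage code {bad}; expected 0/1/2/{MISSING}")
        if nv:
            pos = self.variants["pos"].to_numpy()
            if (pos < 1).any():
                raise GenotypeError("variant positions must be 1-based (>= 1)")
            chrom = self.variants["chrom"].to_numpy()
            same = chrom[1:] == chrom[:-1]
            if np.any(same & (np.diff(pos) <= 0)):
                i = int(np.nonzero(same & (np.diff(pos) <= 0))[0][0])
                raise GenotypeError(
                    "variants not sorted by strictly increasing position within "
                    f"chromosome {chrom[i]!r} near index {i}"
                )

    # -- basic accessors --------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["id"].tolist()

    def sample_index(self, sample_id: str) -> int:
        idx = self.samples.index[self.samples["id"] == sample_id]
        if len(idx) == 0:
            raise KeyError(sample_id)
        return int(idx[0])

    def sample_records(self) -> list[SampleRecord]:
        return [SampleRecord(r.id, r.sex) for r in self.samples.itertuples()]

    def variant_records(self) -> list[VariantRecord]:
        return [
            VariantRecord(str(r.chrom), int(r.pos), str(r.id), str(r.ref), str(r.alt))
            for r in self.variants.itertuples()
        ]

    def called_mask(self) -> np.ndarray:
        """Boolean mask of non-missing entries."""
        return self.dosage != MISSING

    # -- subsetting -------------------------------------------------------

    def subset(
        self,
        sample_ids: Iterable[str] | None = None,
        variant_predicate: Callable | np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        """Restrict to the given samples and/or variants.

        ``sample_ids`` keeps the listed samples in their current matrix
        order. ``variant_predicate`` is either a boolean mask over variants
        or a callable applied to each variant row (a namedtuple with fields
        chrom, pos, id, ref, alt). Unknown sample ids raise ``KeyError``.
        """
        if sample_ids is None:
            srows = np.arange(self.n_samples)
        else:
            wanted = set(sample_ids)
            unknown = wanted - set(self.sample_ids)
            if unknown:
                raise KeyError(f"unknown sample id(s): {sorted(unknown)}")
            srows = np.array(
                [i for i, sid in enumerate(self.sample_ids) if sid in wanted],
                dtype=int,
            )
        if variant_predicate is None:
            vmask = np.ones(self.n_variants, dtype=bool)
        elif callable(variant_predicate):
            vmask = np.array(
                [bool(variant_predicate(row)) for row in self.variants.itertuples()],
                dtype=bool,
            )
        else:
            vmask = np.asarray(variant_predicate, dtype=bool)
            if vmask.shape != (self.n_variants,):
                raise GenotypeError("variant mask length mismatch")
        return GenotypeMatrix(
            self.samples.iloc[srows],
            self.variants.loc[vmask],
            self.dosage[np.ix_(srows, np.nonzero(vmask)[0])],
            dict(self.provenance),
        )

    def autosomal(self, autosomes: Sequence[str] = DEFAULT_AUTOSOMES) -> "GenotypeMatrix":
        """Keep only variants on the given autosome labels."""
        return self.subset(
            variant_predicate=self.variants["chrom"].isin(list(autosomes)).to_numpy()
        )

    # -- comparison -------------------------------------------------------

    def equals(self, other: "GenotypeMatrix") -> bool:
        """Equality of samples, variant map and dosage (provenance ignored)."""
        return (
            self.samples[["id", "sex"]].equals(other.samples[["id", "sex"]])
            and self.variants[["chrom", "pos", "id", "ref", "alt"]]
            .astype({"pos": np.int64})
            .equals(
                other.variants[["chrom", "pos", "id", "ref", "alt"]].astype(
                    {"pos": np.int64}
                )
            )
            and np.array_equal(self.dosage, other.dosage)
        )
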