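"""Pedigree-structured genotype simulator.

Generates a GBS-like diploid SNP matrix for a small conservation herd so
that every downstream stage (QC, diversity, ROH, kinship, family
partitioning) can be tested against known ground truth:

* founders drawn in Hardy-Weinberg proportions at allele frequencies from
  a uniform law on [maf_min, 0.5];
* a sire-family mating design (paternal half-sib daughters) realized by
  gene dropping with recombination — crossovers per chromosome are
  Poisson with mean equal to the map length in Morgans at a uniform
  1 cM/Mb, positions uniform, no interference (Haldane);
* autozygosity planted as explicit tracts: over each tract one parental
  haplotype is copied onto both chromatids, so every covered marker is
  homozygous and the autozygous fraction of the genome is known exactly;
* GBS-style missingness applied i.i.d. per genotype call.

Defaults mirror a herd of 4 males and 28 females genotyped at ~45,000
sparse markers over 30 autosomes totalling ~2.3 Gb, with 3 sire families.
All output is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


class SimConfigError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass
class SimConfig:
    """Study-design parameters of the simulated population."""

    n_males: int = 4
    n_females: int = 28
    n_chrom: int = 30
    chrom_length_bp: int = 76_755_490  # 30 autosomes ~ 2.3026 Gb total
    n_snps: int = 45_000
    maf_min: float = 0.05  # founder alt frequencies ~ U[maf_min, 0.5]
    n_sire_families: int = 3
    n_daughters: int = 3  # females sired within families; the rest founders
    target_froh: float = 0.003  # planted autozygous fraction per individual
    tract_length_bp: tuple[int, int] = (1_000_000, 11_000_000)
    tract_min_gap_bp: int = 2_000_000  # same-chromosome separation of tracts
    call_rate: float = 0.95
    per_sample_call_rate: Mapping[str, float] | None = None
    cm_per_mb: float = 1.0
    n_x_snps: int = 0
    n_y_snps: int = 0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_males, self.n_females, self.n_chrom, self.n_snps) < 0:
            raise SimConfigError("counts must be nonnegative")
        if self.n_snps < self.n_chrom:
            raise SimConfigError(
                f"n_snps ({self.n_snps}) must be >= n_chrom ({self.n_chrom})"
            )
        if not 0.0 <= self.target_froh <= 1.0:
            raise SimConfigError("target_froh must lie in [0, 1]")
        if not 0.0 < self.call_rate <= 1.0:
            raise SimConfigError("call_rate must lie in (0, 1]")
        if self.n_sire_families > self.n_males:
            raise SimConfigError("n_sire_families cannot exceed n_males")
        if not 0.0 <= self.maf_min < 0.5:
            raise SimConfigError("maf_min must lie in [0, 0.5)")

    @property
    def genome_bp(self) -> int:
        return self.n_chrom * self.chrom_length_bp

    @property
    def sample_ids(self) -> list[str]:
        return [f"M{i + 1}" for i in range(self.n_males)] + [
            f"F{i + 1}" for i in range(self.n_females)
        ]


@dataclass
class TruePedigree:
    """Ground truth behind a simulated matrix.

    parents maps sample id -> (sire id, dam id), both ``None`` for
    founders (unsampled founder dams appear as parent ids only).
    tracts maps sample id -> list of planted autozygous (chrom, start_bp,
    end_bp) intervals, non-overlapping within a sample. families lists the
    planted male family groups; paternity maps each sired female to her
    sire.
    """

    parents: dict[str, tuple[str | None, str | None]]
    tracts: dict[str, list[tuple[str, int, int]]]
    families: list[list[str]] = field(default_factory=list)
    paternity: dict[str, str] = field(default_factory=dict)
    founder_freqs: np.ndarray | None = None  # alt freq per emitted variant

    def planted_fraction(self, sample_id: str, genome_bp: int) -> float:
        """Fraction of the autosomal genome inside planted tracts."""
        return sum(e - s + 1 for _, s, e in self.tracts[sample_id]) / genome_bp


def plant_sire_families(cfg: SimConfig) -> tuple[dict, list[list[str]], dict]:
    """Build the mating design: who descends from whom.

    Males are split round-robin into ``n_sire_families`` families; the
    first male of each family is a founder and any further male in the
    family is his son (all sons by one unsampled founder dam), so
    within-family male kinship is pedigree 0.5 (father-son, or full sibs
    between sons) and sired daughters of one family head are paternal
    half-sibs (pedigree kinship 0.25). The first
    ``n_daughters`` females are assigned round-robin as daughters of the
    family heads; remaining females are unrelated founders.

    Returns ``(parents, families, paternity)`` in the
    :class:`TruePedigree` field shapes.
    """
    cfg.validate()
    males = [f"M{i + 1}" for i in range(cfg.n_males)]
    females = [f"F{i + 1}" for i in range(cfg.n_females)]
    parents: dict[str, tuple[str | None, str | None]] = {}
    paternity: dict[str, str] = {}
    dam_counter = 0

    def next_dam() -> str:
        nonlocal dam_counter
        dam_counter += 1
        return f"DAM{dam_counter}"

    if cfg.n_sire_families == 0:
        families: list[list[str]] = []
        for sid in males + females:
            parents[sid] = (None, None)
        return parents, families, paternity

    families = [[] for _ in range(cfg.n_sire_families)]
    for i, m in enumerate(males):
        families[i % cfg.n_sire_families].append(m)
    heads = [fam[0] for fam in families]
    for fam in families:
        parents[fam[0]] = (None, None)
        if len(fam) > 1:
            dam = next_dam()  # one dam per family: sons are full sibs
            for son in fam[1:]:
                parents[son] = (fam[0], dam)
    n_d = min(cfg.n_daughters, cfg.n_females)
    for i, f in enumerate(females):
        if i < n_d:
            sire = heads[i % len(heads)]
            parents[f] = (sire, next_dam())
            paternity[f] = sire
        else:
            parents[f] = (None, None)
    return parents, families, paternity


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------

def _gamete(haps: list[np.ndarray], pos: np.ndarray, chrom_bp: int,
            morgans: float, rng: np.random.Generator) -> np.ndarray:
    """One meiotic product over a chromosome's marker positions."""
    k = int(rng.poisson(morgans))
    start = int(rng.integers(2))
    if k == 0:
        return haps[start].copy()
    breaks = np.sort(rng.uniform(0, chrom_bp, size=k))
    seg = np.searchsorted(breaks, pos)
    pick = (seg + start) % 2
    return np.where(pick == 0, haps[0], haps[1]).astype(np.int8)


def _plant_tracts(rng: np.random.Generator, cfg: SimConfig,
                  chrom_names: Sequence[str]) -> list[tuple[str, int, int]]:
    """Draw separated autozygous tracts totalling target_froh exactly.

    Tract lengths are drawn uniformly from ``tract_length_bp``; the final
    remainder is folded into the last tract (or becomes a single short
    tract when the whole target is below the minimum length), so the
    planted fraction equals the target exactly. Tracts on one chromosome
    keep at least ``tract_min_gap_bp`` of normal sequence between them so
    each planted tract is individually identifiable.
    """
    target_bp = int(round(cfg.target_froh * cfg.genome_bp))
    if target_bp == 0:
        return []
    lo, hi = cfg.tract_length_bp
    lengths: list[int] = []
    remaining = target_bp
    while remaining > 0:
        length = min(int(rng.integers(lo, hi + 1)), cfg.chrom_length_bp)
        if remaining - length < lo:
            if remaining >= lo or not lengths:
                lengths.append(min(remaining, cfg.chrom_length_bp))
            else:
                lengths[-1] += remaining
            break
        lengths.append(length)
        remaining -= length

    gap = cfg.tract_min_gap_bp
    tracts: list[tuple[str, int, int]] = []
    for length in lengths:
        placed = False
        for _ in range(10_000):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            start = int(rng.integers(1, cfg.chrom_length_bp - length + 2))
            end = start + length - 1
            if all(
                c != chrom or end < s - gap or start > e + gap
                for c, s, e in tracts
            ):
                tracts.append((chrom, start, end))
                placed = True
                break
        if not placed:
            raise SimConfigError(
                "could not place planted tracts without overlap; "
                "lower target_froh or tract_min_gap_bp"
            )
    return sorted(tracts)


def simulate_population(cfg: SimConfig) -> tuple[GenotypeMatrix, TruePedigree]:
    """Simulate the genotype matrix and its ground-truth pedigree."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    chrom_names = [str(i + 1) for i in range(cfg.n_chrom)]

    # marker map: markers split evenly across chromosomes, positions uniform
    base, extra = divmod(cfg.n_snps, cfg.n_chrom)
    counts = [base + (1 if i < extra else 0) for i in range(cfg.n_chrom)]
    pos_by_chrom: dict[str, np.ndarray] = {}
    for name, n in zip(chrom_names, counts):
        pos = np.sort(rng.choice(cfg.chrom_length_bp, size=n, replace=False)) + 1
        pos_by_chrom[name] = pos.astype(np.int64)
    freqs_by_chrom = {
        name: rng.uniform(cfg.maf_min, 0.5, size=len(pos_by_chrom[name]))
        for name in chrom_names
    }

    parents, families, paternity = plant_sire_families(cfg)
    morgans = cfg.chrom_length_bp / 1e6 * cfg.cm_per_mb / 100.0

    haplos: dict[str, dict[str, list[np.ndarray]]] = {}

    def founder(ind: str) -> None:
        haplos[ind] = {
            c: [
                (rng.random(len(p)) < freqs_by_chrom[c]).astype(np.int8),
                (rng.random(len(p)) < freqs_by_chrom[c]).astype(np.int8),
            ]
            for c, p in pos_by_chrom.items()
        }

    def drop(ind: str) -> None:
        if ind in haplos:
            return
        sire, dam = parents.get(ind, (None, None))
        if sire is None:
            founder(ind)
            return
        for par in (sire, dam):
            drop(par)
        haplos[ind] = {
            c: [
                _gamete(haplos[sire][c], pos_by_chrom[c], cfg.chrom_length_bp,
                        morgans, rng),
                _gamete(haplos[dam][c], pos_by_chrom[c], cfg.chrom_length_bp,
                        morgans, rng),
            ]
            for c in chrom_names
        }

    sample_ids = cfg.sample_ids
    for sid in sample_ids:
        drop(sid)

    # plant autozygosity: copy haplotype 0 over both chromatids in each tract
    tracts: dict[str, list[tuple[str, int, int]]] = {}
    for sid in sample_ids:
        t = _plant_tracts(rng, cfg, chrom_names)
        tracts[sid] = t
        for chrom, start, end in t:
            pos = pos_by_chrom[chrom]
            inside = (pos >= start) & (pos <= end)
            haplos[sid][chrom][1][inside] = haplos[sid][chrom][0][inside]

    # assemble dosage in (chrom, pos) order
    dosage = np.concatenate(
        [
            np.stack(
                [haplos[sid][c][0] + haplos[sid][c][1] for sid in sample_ids]
            )
            for c in chrom_names
        ],
        axis=1,
    ).astype(np.int8)

    variants = pd.DataFrame(
        {
            "chrom": np.repeat(chrom_names, counts),
            "pos": np.concatenate([pos_by_chrom[c] for c in chrom_names]),
        }
    )

    all_freqs = [freqs_by_chrom[c] for c in chrom_names]

    # optional sex-linked markers (exercise the QC sex-chromosome filter)
    for label, n_sex in (("X", cfg.n_x_snps), ("Y", cfg.n_y_snps)):
        if n_sex <= 0:
            continue
        pos = np.sort(rng.choice(cfg.chrom_length_bp, size=n_sex, replace=False)) + 1
        p = rng.uniform(cfg.maf_min, 0.5, size=n_sex)
        all_freqs.append(p)
        g = (
            (rng.random((len(sample_ids), n_sex)) < p)
            .astype(np.int8)
            + (rng.random((len(sample_ids), n_sex)) < p).astype(np.int8)
        )
        dosage = np.concatenate([dosage, g], axis=1)
        variants = pd.concat(
            [variants, pd.DataFrame({"chrom": label, "pos": pos})],
            ignore_index=True,
        )

    variants["id"] = [
        f"snp_{c}_{p}" for c, p in zip(variants["chrom"], variants["pos"])
    ]
    variants["ref"] = "A"
    variants["alt"] = "G"

    # GBS missingness, i.i.d. per call
    rates = np.full(len(sample_ids), 1.0 - cfg.call_rate)
    if cfg.per_sample_call_rate:
        for i, sid in enumerate(sample_ids):
            if sid in cfg.per_sample_call_rate:
                rates[i] = 1.0 - cfg.per_sample_call_rate[sid]
    miss = rng.random(dosage.shape) < rates[:, None]
    dosage[miss] = MISSING

    samples = pd.DataFrame(
        {
            "id": sample_ids,
            "sex": ["male"] * cfg.n_males + ["female"] * cfg.n_females,
        },
        dtype=object,
    )
    gm = GenotypeMatrix(
        samples, variants, dosage, {"simulated": True, "seed": cfg.seed}
    )
    ped = TruePedigree(
        parents={sid: parents[sid] for sid in sample_ids},
        tracts=tracts,
        families=families,
        paternity=paternity,
        founder_freqs=np.concatenate(all_freqs),
    )
    return gm, ped
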