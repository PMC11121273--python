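"""Runs of homozygosity and the ROH-based inbreeding coefficient.

A run of homozygosity (ROH) is a contiguous stretch of homozygous
genotypes along one individual's autosomes, the footprint of a haplotype
inherited identically from both parents. Detection follows the PLINK
``--homozyg`` two-stage scheme:

1. a window of ``window_snps`` consecutive markers slides along each
   chromosome; a window is homozygosity-compatible when it holds at most
   ``window_het_allowance`` heterozygous and ``max_missing_in_run``
   missing calls; a marker is *eligible* when the fraction of windows
   covering it that are compatible exceeds ``window_hit_threshold``;
2. maximal runs of eligible markers (split wherever adjacent markers are
   more than ``max_gap_bp`` apart) become segments when they carry at
   least ``min_snps`` markers, span at least ``min_length_bp`` and
   contain at most ``max_het_in_run`` heterozygous calls; a run holding
   more heterozygotes than the allowance is split at its heterozygous
   markers into het-free sub-runs, each re-tested against the same
   criteria, and segment endpoints are always homozygous-compatible
   (leading/trailing heterozygotes are trimmed).

Defaults are tuned to GBS marker sparsity (roughly 20 markers per Mb):
``min_snps`` is 15 and ``window_snps`` 20 rather than the dense-array
conventions of 100 and 50, since at GBS density a 1 Mb run cannot carry
100 markers and a 50-marker window spans ~2.5 Mb — longer than many real
runs, which would leave them without a single compatible window. The
window missing allowance of 4/20 likewise reflects GBS call rates near
0.90-0.95 (a 20-marker window then carries 1-2 missing calls on average;
the array-data ratio of 1/10 would let chance missing clusters shatter
genuine runs).

The genomic inbreeding coefficient of an individual is

    F_ROH = sum_k length(ROH_k) / L

with L the autosomal genome length covered by the genotype data; the
default L is 2,302,664.694 Kb (donkey autosomes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import DEFAULT_AUTOSOMES, MISSING, GenotypeMatrix

#: Donkey autosomal genome length in Kb.
DONKEY_AUTOSOME_KB: float = 2_302_664.694


class ROHError(ValueError):
    """Invalid ROH input (unsorted variants, bad parameters)."""


@dataclass
class ROHParams:
    min_length_bp: int = 1_000_000
    min_snps: int = 15
    max_het_in_run: int = 1
    max_missing_in_run: int = 4
    max_gap_bp: int = 1_000_000
    window_snps: int = 20
    window_het_allowance: int = 1
    window_hit_threshold: float = 0.05
    autosome_length_kb: float = DONKEY_AUTOSOME_KB
    autosomes: Sequence[str] = DEFAULT_AUTOSOMES

    def validate(self) -> None:
        if self.min_length_bp <= 0:
            raise ROHError("min_length_bp must be positive")
        for name in (
            "min_snps",
            "max_het_in_run",
            "max_missing_in_run",
            "max_gap_bp",
            "window_snps",
            "window_het_allowance",
        ):
            if getattr(self, name) < 0:
                raise ROHError(f"{name} must be nonnegative")
        if self.autosome_length_kb <= 0:
            raise ROHError("autosome_length_kb must be positive")


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run (1-based inclusive bp interval)."""

    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1_000.0


@dataclass(frozen=True)
class InbreedingResult:
    sample_id: str
    total_roh_length_kb: float
    n_segments: int
    froh: float


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _eligible_markers(het: np.ndarray, miss: np.ndarray, p: ROHParams) -> np.ndarray:
    """Stage 1: marker eligibility from sliding-window compatibility."""
    n = het.size
    w = min(p.window_snps, n)
    if w == 0:
        return np.zeros(n, dtype=bool)
    het_c = np.concatenate([[0], np.cumsum(het)])
    mis_c = np.concatenate([[0], np.cumsum(miss)])
    starts = np.arange(n - w + 1)
    good = (
        (het_c[starts + w] - het_c[starts] <= p.window_het_allowance)
        & (mis_c[starts + w] - mis_c[starts] <= p.max_missing_in_run)
    )
    # windows covering marker i start in [i-w+1, i]; count good ones
    good_c = np.concatenate([[0], np.cumsum(good)])
    idx = np.arange(n)
    lo = np.clip(idx - w + 1, 0, len(starts) - 1 + 1)
    hi = np.clip(idx, 0, len(starts) - 1) + 1
    lo = np.minimum(lo, hi)  # guard degenerate ranges
    n_cover = hi - lo
    n_good = good_c[hi] - good_c[lo]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(n_cover > 0, n_good / np.maximum(n_cover, 1), 0.0)
    return frac > p.window_hit_threshold


def detect_roh(
    gm: GenotypeMatrix, sample_id: str, params: ROHParams | None = None
) -> list[ROHSegment]:
    """Detect the ROH segments of one sample over its autosomal markers."""
    params = params or ROHParams()
    params.validate()
    row = gm.dosage[gm.sample_index(sample_id), :]
    chrom = gm.variants["chrom"].astype(str).to_numpy()
    pos = gm.variants["pos"].to_numpy()

    segments: list[ROHSegment] = []
    for c in dict.fromkeys(chrom):
        if c not in set(params.autosomes):
            continue
        mask = chrom == c
        cpos = pos[mask]
        if np.any(np.diff(cpos) <= 0):
            raise ROHError(f"variants on chromosome {c} not sorted by position")
        d = row[mask]
        het = (d == 1).astype(np.int64)
        miss = (d == MISSING).astype(np.int64)
        eligible = _eligible_markers(het, miss, params)

        # maximal eligible runs, split at large inter-marker gaps
        i = 0
        n = d.size
        while i < n:
            if not eligible[i]:
                i += 1
                continue
            j = i
            while (
                j + 1 < n
                and eligible[j + 1]
                and cpos[j + 1] - cpos[j] <= params.max_gap_bp
            ):
                j += 1
            for a, b in _qualify_run(i, j, het, params):
                if cpos[b] - cpos[a] + 1 >= params.min_length_bp:
                    segments.append(
                        ROHSegment(
                            sample_id, c, int(cpos[a]), int(cpos[b]), b - a + 1
                        )
                    )
            i = j + 1
    return segments


def _qualify_run(
    i: int, j: int, het: np.ndarray, p: ROHParams
) -> list[tuple[int, int]]:
    """Stage 2 run qualification over marker index range [i, j].

    Heterozygous endpoints are trimmed; a run holding more heterozygotes
    than ``max_het_in_run`` is split at its het markers into het-free
    sub-runs, each re-tested. Qualifying (start, end) index pairs must
    carry >= min_snps markers; the bp-length test is applied by the
    caller's position lookup here for convenience.
    """
    while i <= j and het[i]:
        i += 1
    while j >= i and het[j]:
        j -= 1
    if i > j:
        return []
    n_het = int(het[i : j + 1].sum())
    if n_het <= p.max_het_in_run:
        candidates = [(i, j)]
    else:
        candidates = []
        start = i
        for k in range(i, j + 1):
            if het[k]:
                if k > start:
                    candidates.append((start, k - 1))
                start = k + 1
        if start <= j:
            candidates.append((start, j))
    return [(a, b) for a, b in candidates if b - a + 1 >= p.min_snps]


def detect_roh_all(
    gm: GenotypeMatrix, params: ROHParams | None = None
) -> list[ROHSegment]:
    """ROH segments for every sample in the matrix."""
    params = params or ROHParams()
    out: list[ROHSegment] = []
    for sid in gm.sample_ids:
        out.extend(detect_roh(gm, sid, params))
    return out


# ---------------------------------------------------------------------------
# inbreeding coefficient
# ---------------------------------------------------------------------------

def froh(
    segments: Sequence[ROHSegment],
    L_kb: float = DONKEY_AUTOSOME_KB,
    sample_id: str | None = None,
) -> InbreedingResult:
    """F_ROH = total ROH length / autosome length, in consistent Kb units."""
    if L_kb <= 0:
        raise ROHError("autosome length L must be positive")
    ids = {s.sample_id for s in segments}
    if len(ids) > 1:
        raise ROHError(f"segments belong to multiple samples: {sorted(ids)}")
    if sample_id is None:
        sample_id = next(iter(ids)) if ids else ""
    total_kb = float(sum(s.length_kb for s in segments))
    return InbreedingResult(
        sample_id=sample_id,
        total_roh_length_kb=total_kb,
        n_segments=len(segments),
        froh=total_kb / L_kb,
    )


def froh_all(
    gm: GenotypeMatrix,
    params: ROHParams | None = None,
    segments: Sequence[ROHSegment] | None = None,
) -> pd.DataFrame:
    """Per-sample F_ROH table (all samples, including segment-free ones)."""
    params = params or ROHParams()
    if segments is None:
        segments = detect_roh_all(gm, params)
    by_sample: dict[str, list[ROHSegment]] = {sid: [] for sid in gm.sample_ids}
    for s in segments:
        by_sample[s.sample_id].append(s)
    rows = [
        froh(segs, params.autosome_length_kb, sample_id=sid)
        for sid, segs in by_sample.items()
    ]
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in rows],
            "n_segments": [r.n_segments for r in rows],
            "total_roh_length_kb": [r.total_roh_length_kb for r in rows],
            "froh": [r.froh for r in rows],
        }
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def segments_frame(segments: Sequence[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in segments],
            "chrom": [s.chrom for s in segments],
            "start_bp": [s.start_bp for s in segments],
            "end_bp": [s.end_bp for s in segments],
            "n_snps": [s.n_snps for s in segments],
            "length_kb": [s.length_kb for s in segments],
        }
    )


def roh_summaries(
    segments: Sequence[ROHSegment],
    sample_ids: Sequence[str] | None = None,
    bin_edges_mb: Sequence[float] = (1.0, 5.0, 10.0, np.inf),
    indiv_bin_mb: float = 5.0,
    L_kb: float = DONKEY_AUTOSOME_KB,
) -> dict[str, pd.DataFrame]:
    """Population ROH summaries.

    Returns tables for: segment-length bins (counts and proportions),
    per-chromosome segment counts, per-individual total-length histogram
    (``indiv_bin_mb`` bins), and the per-individual F_ROH distribution.
    """
    edges = list(bin_edges_mb)
    lengths_mb = np.array([s.length_bp / 1e6 for s in segments])
    labels, counts = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        labels.append(f"[{lo:g}, {hi:g}) Mb")
        counts.append(int(((lengths_mb >= lo) & (lengths_mb < hi)).sum()))
    total = len(segments)
    length_bins = pd.DataFrame(
        {
            "bin": labels,
            "count": counts,
            "proportion": [c / total if total else 0.0 for c in counts],
        }
    )

    by_chrom: dict[str, int] = {}
    for s in segments:
        by_chrom[s.chrom] = by_chrom.get(s.chrom, 0) + 1
    per_chrom = pd.DataFrame(
        {"chrom": list(by_chrom), "count": list(by_chrom.values())}
    )

    if sample_ids is None:
        sample_ids = sorted({s.sample_id for s in segments})
    totals_kb = {sid: 0.0 for sid in sample_ids}
    nsegs = {sid: 0 for sid in sample_ids}
    for s in segments:
        totals_kb.setdefault(s.sample_id, 0.0)
        nsegs.setdefault(s.sample_id, 0)
        totals_kb[s.sample_id] += s.length_kb
        nsegs[s.sample_id] += 1
    per_indiv = pd.DataFrame(
        {
            "sample_id": list(totals_kb),
            "n_segments": [nsegs[s] for s in totals_kb],
            "total_length_kb": list(totals_kb.values()),
            "froh": [v / L_kb for v in totals_kb.values()],
        }
    )
    tot_mb = per_indiv["total_length_kb"].to_numpy() / 1e3
    max_bin = max(float(tot_mb.max()) if len(tot_mb) else 0.0, indiv_bin_mb)
    hist_edges = np.arange(0.0, max_bin + indiv_bin_mb, indiv_bin_mb)
    hist, _ = np.histogram(tot_mb, bins=hist_edges)
    indiv_hist = pd.DataFrame(
        {
            "bin": [
                f"[{lo:g}, {hi:g}) Mb"
                for lo, hi in zip(hist_edges[:-1], hist_edges[1:])
            ],
            "n_individuals": hist,
        }
    )
    return {
        "length_bins": length_bins,
        "per_chromosome": per_chrom,
        "per_individual": per_indiv,
        "individual_total_hist": indiv_hist,
    }
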