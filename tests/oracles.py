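"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (loops,
exact rational arithmetic, explicit enumeration) and shares no code with
the package implementations it cross-checks.
"""

from fractions import Fraction
from itertools import combinations

import numpy as np

MISSING = -1


# ---------------------------------------------------------------------------
# per-locus statistics by direct counting
# ---------------------------------------------------------------------------

def brute_locus_stats(column):
    """(p, maf, ho, he, pic, ae) by direct counting and direct formulas."""
    called = [int(x) for x in column if x != MISSING]
    n = len(called)
    alt = sum(called)
    p = alt / (2 * n)
    q = 1 - p
    maf = min(p, q)
    ho = sum(1 for x in called if x == 1) / n
    he = 1 - (p * p + q * q)
    pic = 1 - (p * p + q * q) - 2 * p * p * q * q
    ae = 1 / (p * p + q * q)
    return p, maf, ho, he, pic, ae


def brute_ibs_distance(a, b):
    """IBS distance by per-locus allele-sharing enumeration."""
    n_used = 0
    share = 0.0
    for x, y in zip(a, b):
        if x == MISSING or y == MISSING:
            continue
        n_used += 1
        gx = ("A" * (2 - x)) + ("B" * x)
        gy = ("A" * (2 - y)) + ("B" * y)
        if gx == gy:
            share += 1.0
        elif (gx[0] in gy) or (gx[1] in gy):
            share += 0.5
    return 1.0 - share / n_used


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_fraction(n_hom_ref, n_het, n_hom_alt):
    """Exact-rational HWE test via the het-count probability recurrence.

    ways(h+2) = ways(h) * 4 * nAA(h) * nBB(h) / ((h+1)(h+2)); p-value is
    the mass of het counts no more probable than the observed one.
    """
    n = n_hom_ref + n_het + n_hom_alt
    na = 2 * n_hom_alt + n_het
    nb = 2 * n - na
    h = na % 2
    if min(na, nb) < h:  # no feasible het count below the parity floor
        return 1.0
    weights = {h: Fraction(1)}
    while h + 2 <= min(na, nb):
        naa = (na - h) // 2  # alt homozygotes at het count h
        nbb = (nb - h) // 2
        weights[h + 2] = weights[h] * 4 * naa * nbb / ((h + 1) * (h + 2))
        h += 2
    w_obs = weights[n_het]
    p = sum(w for w in weights.values() if w <= w_obs) / sum(weights.values())
    return float(p)


def hwe_exact_slots(n_hom_ref, n_het, n_hom_alt):
    """HWE test by full enumeration of allele-slot assignments (tiny n).

    Distributes the observed alt alleles over the 2n ordered allele slots
    in every possible way and tallies heterozygote counts; feasible only
    for 2n <= ~14.
    """
    n = n_hom_ref + n_het + n_hom_alt
    na = 2 * n_hom_alt + n_het
    counts = {}
    for alt_slots in combinations(range(2 * n), na):
        genos = [0] * n
        for s in alt_slots:
            genos[s // 2] += 1
        h = sum(1 for g in genos if g == 1)
        counts[h] = counts.get(h, 0) + 1
    c_obs = counts[n_het]
    total = sum(counts.values())
    return sum(c for c in counts.values() if c <= c_obs) / total


def sample_null_hwe_pvalues(n, maf_low, maf_high, n_loci, rng):
    """Reference p-values drawn from the exact conditional null.

    For each locus an allele frequency is drawn, the allele count follows
    the binomial sampling of 2n gametes, and the het count is sampled
    from its exact conditional distribution given the allele count; the
    p-value of that outcome is computed with the rational oracle.
    """
    out = []
    for _ in range(n_loci):
        p = rng.uniform(maf_low, maf_high)
        na = int(rng.binomial(2 * n, p))
        h0 = na % 2
        hets, weights = [], []
        h = h0
        w = Fraction(1)
        while h <= min(na, 2 * n - na):
            hets.append(h)
            weights.append(w)
            naa = (na - h) // 2
            nbb = (2 * n - na - h) // 2
            if h + 2 > min(na, 2 * n - na):
                break
            w = w * 4 * naa * nbb / ((h + 1) * (h + 2))
            h += 2
        probs = np.array([float(w) for w in weights])
        probs = probs / probs.sum()
        h_draw = int(rng.choice(hets, p=probs))
        naa = (na - h_draw) // 2
        out.append(hwe_exact_fraction(n - naa - h_draw, h_draw, naa))
    return np.array(out)


# ---------------------------------------------------------------------------
# naive ROH scanner
# ---------------------------------------------------------------------------

def naive_roh_scan(dosages, positions, params):
    """Exhaustive single-chromosome ROH scan with pure-python loops.

    Returns (start_bp, end_bp, n_snps) tuples under the same two-stage
    semantics as the production detector.
    """
    d = list(dosages)
    pos = list(positions)
    n = len(d)
    w = min(params.window_snps, n)
    if w == 0:
        return []
    good = []
    for s in range(n - w + 1):
        win = d[s : s + w]
        het = sum(1 for x in win if x == 1)
        mis = sum(1 for x in win if x == MISSING)
        good.append(
            het <= params.window_het_allowance
            and mis <= params.max_missing_in_run
        )
    elig = []
    for i in range(n):
        cover = range(max(0, i - w + 1), min(i, n - w) + 1)
        n_good = sum(1 for s in cover if good[s])
        elig.append(n_good / len(cover) > params.window_hit_threshold)

    segments = []
    i = 0
    while i < n:
        if not elig[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and elig[j + 1]
            and pos[j + 1] - pos[j] <= params.max_gap_bp
        ):
            j += 1
        a, b = i, j
        while a <= b and d[a] == 1:
            a += 1
        while b >= a and d[b] == 1:
            b -= 1
        if a <= b:
            het_idx = [k for k in range(a, b + 1) if d[k] == 1]
            if len(het_idx) <= params.max_het_in_run:
                cands = [(a, b)]
            else:
                cands = []
                start = a
                for k in het_idx:
                    if k > start:
                        cands.append((start, k - 1))
                    start = k + 1
                if start <= b:
                    cands.append((start, b))
            for x, y in cands:
                if (
                    y - x + 1 >= params.min_snps
                    and pos[y] - pos[x] + 1 >= params.min_length_bp
                ):
                    segments.append((pos[x], pos[y], y - x + 1))
        i = j + 1
    return segments


# ---------------------------------------------------------------------------
# random additive trees
# ---------------------------------------------------------------------------

def random_additive_tree(rng, n_taxa, bl_low=0.1, bl_high=1.0):
    """Random binary tree over taxa t0..t{n-1} by pairwise accumulation.

    Returns (labels, distance matrix, set of non-trivial splits), where
    each split is the min(side, complement) frozenset under sorted-key
    order, matching TreeNode.splits() normalization.
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    all_leaves = frozenset(labels)
    nodes = [({lab}, {lab: 0.0}) for lab in labels]
    pair = {}
    splits = set()
    while len(nodes) > 1:
        if len(nodes) == 2:
            i, j = 0, 1
            bi = rng.uniform(bl_low, bl_high)
            bj = 0.0
        else:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            bi = rng.uniform(bl_low, bl_high)
            bj = rng.uniform(bl_low, bl_high)
        si, di = nodes[i]
        sj, dj = nodes[j]
        for x in si:
            for y in sj:
                pair[frozenset((x, y))] = di[x] + bi + dj[y] + bj
        merged = (
            si | sj,
            {**{k: v + bi for k, v in di.items()},
             **{k: v + bj for k, v in dj.items()}},
        )
        for side in (si, sj):
            if 1 < len(side) < n_taxa - 1:
                splits.add(
                    min(frozenset(side), all_leaves - frozenset(side), key=sorted)
                )
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(merged)
    d = np.zeros((n_taxa, n_taxa))
    for a in range(n_taxa):
        for b in range(n_taxa):
            if a != b:
                d[a, b] = pair[frozenset((labels[a], labels[b]))]
    return labels, d, splits
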