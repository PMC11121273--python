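"""Threshold-based family partitioning for conservation breeding.

Sire-anchored families are formed from genomic kinship: males whose
pairwise relationship reaches the threshold (default G >= 0.1) are linked
and each connected component of that graph is one family. Every female is
then assigned to the family containing her most-related male, provided
that best kinship also reaches the threshold; females unrelated to every
male at the threshold fall into the "other" class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import pandas as pd

from .relatedness import KinshipMatrix

DEFAULT_KINSHIP_THRESHOLD: float = 0.1


class FamilyError(ValueError):
    """Invalid family-partition input."""


@dataclass
class Family:
    family_id: int
    males: list[str]
    females: list[str] = field(default_factory=list)


@dataclass
class FamilyAssignment:
    """Partition of the herd into male-anchored families plus "other"."""

    families: list[Family]
    other: list[str]
    threshold: float

    def membership(self) -> dict[str, str]:
        out = {}
        for fam in self.families:
            for sid in fam.males + fam.females:
                out[sid] = f"family_{fam.family_id}"
        for sid in self.other:
            out[sid] = "other"
        return out

    def partition(self) -> set[frozenset]:
        """Order-free view: the set of family member sets (incl. other)."""
        parts = {frozenset(f.males + f.females) for f in self.families}
        if self.other:
            parts.add(frozenset(self.other))
        return parts

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fam in self.families:
            for m in fam.males:
                rows.append((f"family_{fam.family_id}", m, "male"))
            for f in fam.females:
                rows.append((f"family_{fam.family_id}", f, "female"))
        for f in self.other:
            rows.append(("other", f, "female"))
        return pd.DataFrame(rows, columns=["family", "sample_id", "sex"])


def cluster_males(
    kinship: KinshipMatrix,
    male_ids: Sequence[str],
    threshold: float = DEFAULT_KINSHIP_THRESHOLD,
) -> list[list[str]]:
    """Connected components of the male kinship graph at the threshold.

    Components are ordered by their smallest member index (matrix order);
    members within a component likewise.
    """
    male_ids = list(male_ids)
    if not male_ids:
        raise FamilyError("at least one male is required")
    unknown = set(male_ids) - set(kinship.ids)
    if unknown:
        raise FamilyError(f"male id(s) not in kinship matrix: {sorted(unknown)}")
    index = {sid: kinship.ids.index(sid) for sid in male_ids}
    g = nx.Graph()
    g.add_nodes_from(male_ids)
    for a in male_ids:
        for b in male_ids:
            if index[a] < index[b] and kinship.loc(a, b) >= threshold:
                g.add_edge(a, b)
    comps = [sorted(c, key=index.get) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: index[c[0]])


def assign_females(
    kinship: KinshipMatrix,
    male_families: Sequence[Sequence[str]],
    female_ids: Sequence[str],
    threshold: float = DEFAULT_KINSHIP_THRESHOLD,
) -> FamilyAssignment:
    """Assign each female to her best-related family, or to "other".

    A female's kinship to a family is her maximum kinship over that
    family's males; she joins the argmax family when that value reaches
    the threshold (ties resolved toward the lowest family id).
    """
    families = [
        Family(family_id=i + 1, males=list(males))
        for i, males in enumerate(male_families)
    ]
    other: list[str] = []
    for f in female_ids:
        best_fam, best_val = None, -float("inf")
        for fam in families:
            val = max(kinship.loc(f, m) for m in fam.males)
            if val > best_val:  # strict: ties keep the lowest family id
                best_fam, best_val = fam, val
        if best_fam is not None and best_val >= threshold:
            best_fam.females.append(f)
        else:
            other.append(f)
    return FamilyAssignment(families=families, other=other, threshold=threshold)


def build_families(
    kinship: KinshipMatrix,
    male_ids: Sequence[str],
    female_ids: Sequence[str],
    threshold: float = DEFAULT_KINSHIP_THRESHOLD,
) -> FamilyAssignment:
    """Cluster males into families, then assign females."""
    comps = cluster_males(kinship, male_ids, threshold)
    return assign_females(kinship, comps, female_ids, threshold)
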