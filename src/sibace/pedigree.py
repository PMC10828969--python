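"""Family clusters and randomized sibling-pair selection.

A family cluster is a connected component of the relation "shares at least
one parent".  The study design analyses exactly one sibling pair per
cluster: clusters containing only full siblings contribute a random
(index, full-sibling) pair; clusters that also contain half-siblings
contribute a half-sibling pair, with paternal half-siblings prioritized over
maternal ones (paternal half-siblings are the more numerous stratum in the
population, so this priority maximizes the half-sibling sample).

Expected additive-genetic sharing is 0.5 for full siblings and 0.25 for
half-siblings; shared environment is treated as fully shared for every
analysed pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "K_ADDITIVE",
    "RELATIONSHIPS",
    "SiblingPair",
    "FamilyCluster",
    "sibling_clusters",
    "classify_pair",
    "select_study_pairs",
]

RELATIONSHIPS = ("full", "maternal_half", "paternal_half")

#: Expected proportion of additive genetic factors shared, by relationship.
K_ADDITIVE = {"full": 0.5, "maternal_half": 0.25, "paternal_half": 0.25}


@dataclass(frozen=True)
class SiblingPair:
    """One analysed pair: index person plus the randomly assigned sibling."""

    index_id: object
    sibling_id: object
    relationship: str
    k_additive: float = field(default=None)  # type: ignore[assignment]
    k_shared_env: float = 1.0

    def __post_init__(self) -> None:
        if self.index_id == self.sibling_id:
            raise ValueError("a pair must consist of two distinct individuals")
        if self.relationship not in RELATIONSHIPS:
            raise ValueError(f"unknown relationship {self.relationship!r}")
        if self.k_additive is None:
            object.__setattr__(self, "k_additive", K_ADDITIVE[self.relationship])
        elif self.k_additive != K_ADDITIVE[self.relationship]:
            raise ValueError("k_additive inconsistent with relationship")
        if self.k_shared_env != 1.0:
            raise ValueError("shared environment is fully shared for sibling pairs")


@dataclass(frozen=True)
class FamilyCluster:
    """Connected set of individuals sharing at least one parent pairwise-transitively."""

    member_ids: tuple
    kind: str  # "full_only" | "mixed"

    def __post_init__(self) -> None:
        if len(self.member_ids) < 2:
            raise ValueError("a family cluster has at least two members")
        if self.kind not in ("full_only", "mixed"):
            raise ValueError(f"unknown cluster kind {self.kind!r}")


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = np.arange(n)

    def find(self, i: int) -> int:
        p = self.parent
        root = i
        while p[root] != root:
            root = p[root]
        while p[i] != root:
            p[i], i = root, p[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def sibling_clusters(records: pd.DataFrame) -> list[FamilyCluster]:
    """Group individuals into family clusters via shared parents.

    Parameters
    ----------
    records : DataFrame
        Registry table with ``person_id``, ``mother_id``, ``father_id``
        columns.  Missing parent ids (NaN) never link individuals.

    Returns
    -------
    list of FamilyCluster
        Connected components of size >= 2, each tagged ``full_only`` when
        every member has the same two parents, else ``mixed``.  Singletons
        are dropped; each individual appears in at most one cluster.
    """
    pid = records["person_id"].to_numpy()
    mid = records["mother_id"].to_numpy()
    fid = records["father_id"].to_numpy()
    self_parent = (pid == mid) | (pid == fid)
    if np.any(self_parent):
        bad = pid[self_parent][:3]
        raise ValueError(f"individual(s) listed as own parent: {bad.tolist()}")

    n = len(records)
    uf = _UnionFind(n)
    for parent in (mid, fid):
        notna = pd.notna(parent)
        rows = np.flatnonzero(notna)
        codes = pd.factorize(pd.Series(parent[notna]))[0]
        order = np.argsort(codes, kind="stable")
        rows, codes = rows[order], codes[order]
        # union adjacent rows sharing a parent code
        same = codes[1:] == codes[:-1]
        for a, b in zip(rows[:-1][same], rows[1:][same]):
            uf.union(a, b)

    roots = np.array([uf.find(i) for i in range(n)])
    order = np.argsort(roots, kind="stable")
    sorted_roots = roots[order]
    starts = np.flatnonzero(np.r_[True, sorted_roots[1:] != sorted_roots[:-1]])
    bounds = np.r_[starts, n]
    m_isna = pd.isna(mid)
    f_isna = pd.isna(fid)
    clusters: list[FamilyCluster] = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        rows = order[s:e]
        if len(rows) < 2:
            continue
        members = tuple(sorted(pid[rows].tolist()))
        full_only = (
            not m_isna[rows].any()
            and not f_isna[rows].any()
            and len(set(mid[rows])) == 1
            and len(set(fid[rows])) == 1
        )
        clusters.append(FamilyCluster(members, "full_only" if full_only else "mixed"))
    clusters.sort(key=lambda c: c.member_ids)
    return clusters


def classify_pair(a, b) -> str:
    """Relationship of two siblings from their parent ids.

    ``a`` and ``b`` are records (mappings or Series) with ``mother_id`` and
    ``father_id``.  Raises ``ValueError`` if no parent is shared.
    """
    same_mother = pd.notna(a["mother_id"]) and a["mother_id"] == b["mother_id"]
    same_father = pd.notna(a["father_id"]) and a["father_id"] == b["father_id"]
    if same_mother and same_father:
        return "full"
    if same_mother:
        return "maternal_half"
    if same_father:
        return "paternal_half"
    raise ValueError("individuals share no parent: not siblings")


def select_study_pairs(
    clusters: list[FamilyCluster],
    records: pd.DataFrame,
    seed: int,
) -> list[SiblingPair]:
    """Randomly select one analysed sibling pair per family cluster.

    Full-sibling-only clusters yield a (random index, random full sibling)
    pair.  In mixed clusters the index is drawn uniformly among members with
    at least one half-sibling, and the partner uniformly among the index's
    paternal half-siblings if any exist, otherwise among the maternal ones.
    Candidate partners that are twins of the index (``is_twin`` set and equal
    birth year) are excluded.  Clusters with no eligible pair are skipped.

    A single seeded generator is consumed in sorted-cluster order, so the
    selection is reproducible for a given seed and input; permuting the
    input records may change which pair a cluster yields.
    """
    idx = records.set_index("person_id")
    mother = idx["mother_id"].to_dict()
    father = idx["father_id"].to_dict()
    birth = idx["birth_year"].to_dict() if "birth_year" in idx.columns else {}
    twin = idx["is_twin"].to_dict() if "is_twin" in idx.columns else {}

    def rel(a, b):
        sm = pd.notna(mother.get(a)) and mother.get(a) == mother.get(b)
        sf = pd.notna(father.get(a)) and father.get(a) == father.get(b)
        if sm and sf:
            return "full"
        if sm:
            return "maternal_half"
        if sf:
            return "paternal_half"
        return None

    def twin_of(a, b):
        return bool(twin.get(b, False)) and birth.get(a) == birth.get(b)

    rng = np.random.default_rng(seed)
    pairs: list[SiblingPair] = []
    for cluster in sorted(clusters, key=lambda c: c.member_ids):
        members = list(cluster.member_ids)
        if cluster.kind == "full_only":
            index = members[rng.integers(len(members))]
            partners = [m for m in members if m != index and not twin_of(index, m)]
            if not partners:
                continue
            sib = partners[rng.integers(len(partners))]
            pairs.append(SiblingPair(index, sib, "full"))
        else:
            eligible = [
                m for m in members
                if any(rel(m, o) in ("maternal_half", "paternal_half")
                       for o in members if o != m)
            ]
            if not eligible:
                continue
            index = eligible[rng.integers(len(eligible))]
            pat = [m for m in members
                   if rel(index, m) == "paternal_half" and not twin_of(index, m)]
            mat = [m for m in members
                   if rel(index, m) == "maternal_half" and not twin_of(index, m)]
            pool, r = (pat, "paternal_half") if pat else (mat, "maternal_half")
            if not pool:
                continue
            sib = pool[rng.integers(len(pool))]
            pairs.append(SiblingPair(index, sib, r))
    return pairs
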