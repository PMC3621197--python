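"""Pedigree structure, kinship, relationship classes, household sharing.

A pedigree is a directed acyclic family structure read from a
LINKAGE/PLINK-style text file (``FID IID FATHER MOTHER SEX`` plus optional
``HOUSEHOLD`` and ``REGION`` columns).  From it we derive the kinship matrix
Phi by the standard recursion, the additive relationship matrix 2*Phi used by
the variance-component model, a census of named relative-pair classes
(parent-offspring, siblings, avuncular, ...), and the 0/1 household-sharing
matrix used for the shared-environment variance component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "KinshipMatrix",
    "RelationshipCensus",
    "PedigreeError",
    "load_pedigree",
    "write_pedigree",
    "kinship_matrix",
    "classify_relationships",
    "household_matrix",
    "RELATIONSHIP_CLASSES",
]

MISSING_PARENT = "0"

#: Named relative-pair classes, in classification priority order.
RELATIONSHIP_CLASSES = (
    "parent_offspring",
    "siblings",
    "half_siblings",
    "avuncular",
    "half_avuncular",
    "grand_avuncular",
    "double_first_cousins",
    "first_cousins",
    "half_first_cousins",
    "first_cousins_once_removed",
    "half_first_cousins_once_removed",
    "half_second_cousins",
    "other",
)


class PedigreeError(ValueError):
    """Structural, reference, or validation error in a pedigree."""


@dataclass(frozen=True)
class Pedigree:
    """Validated pedigree with founders-first topological order.

    Attributes
    ----------
    ids
        Individual tokens in file order.
    father, mother
        Integer index into ``ids`` of each parent, or -1 for founders.
    sex
        ``"male"`` / ``"female"`` per individual.
    household, region, family
        Optional per-individual tokens (``None`` entries where missing).
    """

    ids: tuple[str, ...]
    father: np.ndarray
    mother: np.ndarray
    sex: tuple[str, ...]
    household: tuple | None = None
    region: tuple | None = None
    family: tuple | None = None
    _topo: tuple[int, ...] = field(default=None, repr=False)

    def __post_init__(self):
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(self.ids)})
        if self._topo is None:
            object.__setattr__(self, "_topo", _topological_order(self))

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, token: str) -> int:
        return self._index[token]

    @property
    def n_founders(self) -> int:
        return int(np.sum(self.father < 0))

    @property
    def founders(self) -> np.ndarray:
        return np.flatnonzero(self.father < 0)

    @property
    def topological_order(self) -> tuple[int, ...]:
        """Indices ordered so that parents precede their children."""
        return self._topo

    def families(self) -> list[np.ndarray]:
        """Index arrays of connected components (independent families)."""
        g = nx.Graph()
        g.add_nodes_from(range(len(self)))
        for i in range(len(self)):
            for p in (self.father[i], self.mother[i]):
                if p >= 0:
                    g.add_edge(i, int(p))
        return [np.array(sorted(c)) for c in nx.connected_components(g)]

    def to_frame(self) -> pd.DataFrame:
        fam = self.family if self.family is not None else ["F1"] * len(self)
        df = pd.DataFrame(
            {
                "FID": fam,
                "IID": self.ids,
                "FATHER": [self.ids[f] if f >= 0 else MISSING_PARENT for f in self.father],
                "MOTHER": [self.ids[m] if m >= 0 else MISSING_PARENT for m in self.mother],
                "SEX": [1 if s == "male" else 2 for s in self.sex],
            }
        )
        if self.household is not None:
            df["HOUSEHOLD"] = self.household
        if self.region is not None:
            df["REGION"] = self.region
        return df


def _topological_order(ped: Pedigree) -> tuple[int, ...]:
    g = nx.DiGraph()
    g.add_nodes_from(range(len(ped)))
    for i in range(len(ped)):
        for p in (ped.father[i], ped.mother[i]):
            if p >= 0:
                g.add_edge(int(p), i)
    try:
        return tuple(nx.topological_sort(g))
    except nx.NetworkXUnfeasible:
        cycle = nx.find_cycle(g)
        loop = " -> ".join(ped.ids[a] for a, _ in cycle) + f" -> {ped.ids[cycle[0][0]]}"
        raise PedigreeError(f"pedigree contains an ancestry cycle: {loop}") from None


def build_pedigree(
    ids: Sequence[str],
    father: Sequence[str],
    mother: Sequence[str],
    sex: Sequence,
    household: Sequence | None = None,
    region: Sequence | None = None,
    family: Sequence | None = None,
) -> Pedigree:
    """Assemble and validate a :class:`Pedigree` from parallel columns.

    Parent tokens use ``"0"`` for missing; an individual with exactly one
    known parent is rejected as a data error.  Sex may be coded 1/2 or
    ``male``/``female``.
    """
    ids = [str(s) for s in ids]
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids)[pd.Series(ids).duplicated()].iloc[0]
        raise PedigreeError(f"duplicate individual id {dup!r}")
    index = {s: i for i, s in enumerate(ids)}
    sex_norm = []
    for s in sex:
        s = str(s).lower()
        if s in ("1", "m", "male"):
            sex_norm.append("male")
        elif s in ("2", "f", "female"):
            sex_norm.append("female")
        else:
            raise PedigreeError(f"unrecognized sex code {s!r}")

    def resolve(tok: str, child: str, which: str) -> int:
        tok = str(tok)
        if tok == MISSING_PARENT:
            return -1
        if tok not in index:
            raise PedigreeError(f"{which} {tok!r} of individual {child!r} not in pedigree")
        if tok == child:
            raise PedigreeError(f"pedigree contains an ancestry cycle: {child} -> {child}")
        return index[tok]

    fa = np.array([resolve(f, c, "father") for f, c in zip(father, ids)])
    mo = np.array([resolve(m, c, "mother") for m, c in zip(mother, ids)])
    half = (fa < 0) != (mo < 0)
    if half.any():
        bad = ids[int(np.flatnonzero(half)[0])]
        raise PedigreeError(
            f"individual {bad!r} has exactly one known parent; both or neither required"
        )
    for i in range(len(ids)):
        if fa[i] >= 0 and sex_norm[fa[i]] != "male":
            raise PedigreeError(f"father {ids[fa[i]]!r} of {ids[i]!r} is not male")
        if mo[i] >= 0 and sex_norm[mo[i]] != "female":
            raise PedigreeError(f"mother {ids[mo[i]]!r} of {ids[i]!r} is not female")

    ped = Pedigree(
        ids=tuple(ids),
        father=fa,
        mother=mo,
        sex=tuple(sex_norm),
        household=tuple(household) if household is not None else None,
        region=tuple(region) if region is not None else None,
        family=tuple(str(f) for f in family) if family is not None else None,
    )
    return ped


def load_pedigree(path) -> Pedigree:
    """Read a whitespace-delimited pedigree file.

    Columns: ``FID IID FATHER MOTHER SEX [HOUSEHOLD] [REGION]``, with or
    without a header row; sex 1=male 2=female; missing parent ``"0"``.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str, header=None, comment="#")
    first = [str(x).upper() for x in df.iloc[0]]
    if "IID" in first or "FID" in first:
        df.columns = first
        df = df.iloc[1:].reset_index(drop=True)
    else:
        names = ["FID", "IID", "FATHER", "MOTHER", "SEX", "HOUSEHOLD", "REGION"]
        df.columns = names[: df.shape[1]]
    if df.shape[1] < 5:
        raise PedigreeError("pedigree file needs at least FID IID FATHER MOTHER SEX")
    return build_pedigree(
        df["IID"],
        df["FATHER"],
        df["MOTHER"],
        df["SEX"],
        household=df["HOUSEHOLD"] if "HOUSEHOLD" in df else None,
        region=df["REGION"] if "REGION" in df else None,
        family=df["FID"],
    )


def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class KinshipMatrix:
    """Kinship coefficients Phi over an ordered id list.

    ``phi[i, j]`` is the probability that a random allele drawn from i is
    identical by descent with a random allele drawn from j; the additive
    relationship matrix of the polygenic model is ``2 * phi``.
    """

    ids: tuple[str, ...]
    phi: np.ndarray

    @property
    def relationship(self) -> np.ndarray:
        return 2.0 * self.phi


def kinship_matrix(ped: Pedigree) -> KinshipMatrix:
    """Kinship by the standard recursion over a founders-first ordering.

    phi(i, i) = (1 + phi(father(i), mother(i))) / 2 and, for j processed
    before i, phi(i, j) = (phi(father(i), j) + phi(mother(i), j)) / 2;
    founders are unrelated and non-inbred.
    """
    n = len(ped)
    phi = np.zeros((n, n))
    for i in ped.topological_order:
        f, m = int(ped.father[i]), int(ped.mother[i])
        if f < 0:
            phi[i, i] = 0.5
        else:
            phi[i, i] = 0.5 * (1.0 + phi[f, m])
            # valid for every already-processed j (parents precede children);
            # entries for unprocessed descendants get overwritten on their turn
            row = 0.5 * (phi[f, :] + phi[m, :])
            row[i] = phi[i, i]
            phi[i, :] = row
            phi[:, i] = row
    return KinshipMatrix(ids=ped.ids, phi=phi)


@dataclass
class RelationshipCensus:
    """Counts of related (phi > 0) non-identical pairs per named class."""

    counts: dict[str, int]

    def __getitem__(self, key: str) -> int:
        return self.counts.get(key, 0)

    def total(self) -> int:
        return sum(self.counts.values())

    def to_series(self) -> pd.Series:
        return pd.Series({k: self.counts.get(k, 0) for k in RELATIONSHIP_CLASSES})


def _parents(ped: Pedigree, i: int) -> tuple[int, int] | None:
    f = int(ped.father[i])
    return None if f < 0 else (f, int(ped.mother[i]))


def _full_sibs(ped, i, j):
    pi, pj = _parents(ped, i), _parents(ped, j)
    return pi is not None and pj is not None and i != j and pi == pj


def _half_sibs(ped, i, j):
    pi, pj = _parents(ped, i), _parents(ped, j)
    if pi is None or pj is None or i == j:
        return False
    shared = len(set(pi) & set(pj))
    return shared == 1


def _first_cousins_degree(ped, i, j):
    """Number of (parent-of-i, parent-of-j) pairs that are full sibs."""
    pi, pj = _parents(ped, i), _parents(ped, j)
    if pi is None or pj is None:
        return 0
    return sum(_full_sibs(ped, a, b) for a in pi for b in pj)


def _half_first_cousins(ped, i, j):
    pi, pj = _parents(ped, i), _parents(ped, j)
    if pi is None or pj is None:
        return False
    return any(_half_sibs(ped, a, b) for a in pi for b in pj)


def classify_relationship(ped: Pedigree, i: int, j: int) -> str:
    """Assign one named class to a related pair (first match in priority order)."""
    pi, pj = _parents(ped, i), _parents(ped, j)
    if (pj is not None and i in pj) or (pi is not None and j in pi):
        return "parent_offspring"
    if _full_sibs(ped, i, j):
        return "siblings"
    if _half_sibs(ped, i, j):
        return "half_siblings"
    # i aunt/uncle of j, or vice versa
    for a, b in ((i, j), (j, i)):
        pb = _parents(ped, b)
        if pb is not None and any(_full_sibs(ped, a, p) for p in pb):
            return "avuncular"
    for a, b in ((i, j), (j, i)):
        pb = _parents(ped, b)
        if pb is not None and any(_half_sibs(ped, a, p) for p in pb):
            return "half_avuncular"
    for a, b in ((i, j), (j, i)):
        pb = _parents(ped, b)
        if pb is not None:
            for p in pb:
                gp = _parents(ped, p)
                if gp is not None and any(_full_sibs(ped, a, g) for g in gp):
                    return "grand_avuncular"
    deg = _first_cousins_degree(ped, i, j)
    if deg >= 2:
        return "double_first_cousins"
    if deg == 1:
        return "first_cousins"
    if _half_first_cousins(ped, i, j):
        return "half_first_cousins"
    for a, b in ((i, j), (j, i)):
        pb = _parents(ped, b)
        if pb is not None and any(_first_cousins_degree(ped, a, p) >= 1 for p in pb):
            return "first_cousins_once_removed"
    for a, b in ((i, j), (j, i)):
        pb = _parents(ped, b)
        if pb is not None and any(_half_first_cousins(ped, a, p) for p in pb):
            return "half_first_cousins_once_removed"
    pi, pj = _parents(ped, i), _parents(ped, j)
    if pi is not None and pj is not None:
        if any(_half_first_cousins(ped, a, b) for a in pi for b in pj):
            return "half_second_cousins"
    return "other"


def classify_relationships(ped: Pedigree, kin: KinshipMatrix | None = None) -> RelationshipCensus:
    """Census of all related (phi > 0) non-identical pairs.

    Each pair is assigned exactly one class; related pairs matching none of
    the named patterns are tallied as ``"other"``.  The result is invariant
    to the input row order of the pedigree file.
    """
    if kin is None:
        kin = kinship_matrix(ped)
    counts: dict[str, int] = {}
    n = len(ped)
    ii, jj = np.triu_indices(n, k=1)
    related = kin.phi[ii, jj] > 0
    for i, j in zip(ii[related], jj[related]):
        cls = classify_relationship(ped, int(i), int(j))
        counts[cls] = counts.get(cls, 0) + 1
    return RelationshipCensus(counts=counts)


def household_matrix(ped: Pedigree) -> np.ndarray:
    """Symmetric 0/1 same-household indicator with unit diagonal."""
    if ped.household is None or any(
        h is None or str(h) in ("", "0", "nan", "None") for h in ped.household
    ):
        raise PedigreeError(
            "household tokens are required for the household variance component; "
            "disable the component or supply a HOUSEHOLD column"
        )
    h = np.asarray([str(x) for x in ped.household])
    mat = (h[:, None] == h[None, :]).astype(float)
    np.fill_diagonal(mat, 1.0)
    return mat
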