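"""Multipoint identity-by-descent estimation from STR genotypes.

An exact Lander-Green-style computation: the hidden state on each chromosome
is the inheritance vector (one bit per non-founder meiosis, bit = which
grandparental allele was transmitted), marker genotypes enter through a
founder-allele-graph likelihood summed over phase and founder allele
assignments, and transitions between positions use the Haldane map function
theta = (1 - exp(-2d/100)) / 2 for d in cM (no interference, sex-averaged
map).  Forward-backward over the markers of a chromosome yields the posterior
over inheritance vectors at any cM position, from which the locus-specific
IBD-sharing matrix pihat (expected proportion of alleles shared IBD per pair)
is the posterior expectation of allele-sharing / 2.

The state space is 2^m for m meioses, so pedigrees are limited to a
configurable meiosis count (default 16, i.e. 8 non-founders per family);
larger families raise :class:`CapabilityError` advising splitting.  This
replaces MCMC IBD samplers deliberately: at desk scale the exact computation
is deterministic and testable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Pedigree, kinship_matrix

__all__ = [
    "GeneticMap",
    "MarkerGenotypes",
    "IBDMatrix",
    "CapabilityError",
    "haldane_theta",
    "mendelian_check",
    "InheritanceHMM",
    "MultipointIBD",
    "multipoint_ibd",
    "load_map",
    "write_map",
    "load_genotypes",
    "write_genotypes",
]

DEFAULT_BIT_LIMIT = 16
MISSING = 0


class CapabilityError(RuntimeError):
    """Pedigree exceeds the exact-HMM meiosis budget."""


def haldane_theta(d_cm) -> float:
    """Haldane recombination fraction for a distance in cM."""
    d = np.asarray(d_cm, float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0")
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


@dataclass(frozen=True)
class GeneticMap:
    """Ordered STR markers with chromosome and sex-averaged cM position."""

    table: pd.DataFrame  # columns: chrom, marker, pos_cm

    def __post_init__(self):
        t = self.table
        for chrom, sub in t.groupby("chrom", sort=False):
            pos = sub["pos_cm"].to_numpy(float)
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"marker positions on chromosome {chrom} must be "
                                 "strictly increasing")

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chrom"]))

    def markers_on(self, chrom) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom].reset_index(drop=True)

    def spacing_summary(self) -> dict:
        gaps = np.concatenate([
            np.diff(self.markers_on(c)["pos_cm"].to_numpy(float))
            for c in self.chromosomes
            if len(self.markers_on(c)) > 1
        ])
        return {"n_markers": int(len(self.table)),
                "mean_spacing_cm": float(gaps.mean()),
                "min_spacing_cm": float(gaps.min()),
                "max_spacing_cm": float(gaps.max())}


def load_map(path) -> GeneticMap:
    """MAP-style file: chromosome, marker, position(cM); whitespace-delimited."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=["chrom", "marker", "pos_cm"])
    df["pos_cm"] = df["pos_cm"].astype(float)
    return GeneticMap(df)


def write_map(gmap: GeneticMap, path) -> None:
    gmap.table.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class MarkerGenotypes:
    """Unphased allele pairs per individual per marker; 0 codes missing."""

    ids: tuple
    data: dict  # marker name -> (n, 2) int array

    def __post_init__(self):
        n = len(self.ids)
        for m, arr in self.data.items():
            if arr.shape != (n, 2):
                raise ValueError(f"genotype array for {m} has shape {arr.shape}")
            if np.any(arr < 0):
                raise ValueError(f"negative allele code at marker {m}")

    def subset_rows(self, idx) -> dict:
        return {m: a[idx] for m, a in self.data.items()}

    def missing_rate(self) -> float:
        tot = sum(a.size for a in self.data.values())
        miss = sum(int((a == MISSING).sum()) for a in self.data.values())
        return miss / tot if tot else 0.0


def load_genotypes(path) -> MarkerGenotypes:
    df = pd.read_csv(path, sep=r"\s+")
    ids = tuple(str(s) for s in df["IID"])
    markers = []
    for c in df.columns:
        if c.endswith(".1"):
            markers.append(c[:-2])
    data = {m: np.column_stack([df[f"{m}.1"].to_numpy(int),
                                df[f"{m}.2"].to_numpy(int)])
            for m in markers}
    return MarkerGenotypes(ids=ids, data=data)


def write_genotypes(genos: MarkerGenotypes, path) -> None:
    df = pd.DataFrame({"IID": list(genos.ids)})
    for m, arr in genos.data.items():
        df[f"{m}.1"] = arr[:, 0]
        df[f"{m}.2"] = arr[:, 1]
    df.to_csv(path, sep="\t", index=False)


@dataclass
class IBDMatrix:
    """Expected proportion of alleles shared IBD at one genome position."""

    chrom: object
    pos_cm: float
    ids: tuple
    pihat: np.ndarray

    def to_triplets(self) -> pd.DataFrame:
        ii, jj = np.triu_indices(len(self.ids))
        return pd.DataFrame({
            "id1": [self.ids[i] for i in ii],
            "id2": [self.ids[j] for j in jj],
            "pihat": self.pihat[ii, jj],
        })


# ---------------------------------------------------------------------------
# Mendelian consistency audit


def mendelian_check(ped: Pedigree, genos: MarkerGenotypes):
    """List child-parent transmission violations and blank offending trios.

    Returns ``(inconsistencies, blanked_genotypes, report)`` where
    inconsistencies is a list of ``(marker, child_id)``, blanked_genotypes is
    a cleaned copy of the input (child and genotyped parents blanked at the
    offending marker), and report carries the overall blanking rate.
    """
    idx = {s: i for i, s in enumerate(genos.ids)}
    cleaned = {m: a.copy() for m, a in genos.data.items()}
    inconsistencies = []
    total_typed = sum(int((a != MISSING).all(axis=1).sum()) for a in genos.data.values())
    blanked = 0
    for marker, arr in genos.data.items():
        for ci, cid in enumerate(ped.ids):
            if cid not in idx or ped.father[ci] < 0:
                continue
            crow = idx[cid]
            child = arr[crow]
            if MISSING in child:
                continue
            ok = True
            parents = []
            for p in (int(ped.father[ci]), int(ped.mother[ci])):
                pid = ped.ids[p]
                if pid in idx and MISSING not in arr[idx[pid]]:
                    parents.append(idx[pid])
            if len(parents) == 2:
                fa, mo = arr[parents[0]], arr[parents[1]]
                ok = any(
                    {child[0], child[1]} == {a, b} or (child[0] == a and child[1] == b)
                    or (child[0] == b and child[1] == a)
                    for a in fa for b in mo
                )
            elif len(parents) == 1:
                pa = arr[parents[0]]
                ok = bool(set(child) & set(pa))
            if not ok:
                inconsistencies.append((marker, cid))
                for r in [crow] + parents:
                    if not np.all(cleaned[marker][r] == MISSING):
                        blanked += 1
                    cleaned[marker][r] = MISSING
    rate = blanked / total_typed if total_typed else 0.0
    report = {"n_inconsistencies": len(inconsistencies),
              "n_genotypes_blanked": blanked,
              "blanking_rate": rate}
    return inconsistencies, MarkerGenotypes(genos.ids, cleaned), report


# ---------------------------------------------------------------------------
# founder allele frequencies


def founder_allele_freqs(ped: Pedigree, genos: MarkerGenotypes) -> dict:
    """Per-marker allele frequencies counted from genotyped founders.

    Alleles seen only in non-founders receive a 0.5 pseudo-count so that no
    observed genotype has zero prior probability; with no genotyped founders
    at a marker the distribution is uniform over the alleles observed there.
    """
    idx = {s: i for i, s in enumerate(genos.ids)}
    founder_rows = [idx[ped.ids[i]] for i in ped.founders if ped.ids[i] in idx]
    freqs = {}
    for marker, arr in genos.data.items():
        observed = set(int(a) for a in arr.ravel() if a != MISSING)
        counts = {a: 0.0 for a in observed}
        for r in founder_rows:
            for a in arr[r]:
                if a != MISSING:
                    counts[int(a)] += 1.0
        if sum(counts.values()) == 0:
            counts = {a: 1.0 for a in observed} or {1: 1.0}
        else:
            counts = {a: c + 0.5 for a, c in counts.items()}
        tot = sum(counts.values())
        freqs[marker] = {a: c / tot for a, c in counts.items()}
    return freqs


# ---------------------------------------------------------------------------
# inheritance-vector HMM (one family)


class InheritanceHMM:
    """Exact inheritance-vector HMM for one connected family.

    Parameters
    ----------
    ped
        Full pedigree (the family is selected by ``members``).
    members
        Global indices of this family's individuals.
    bit_limit
        Maximum number of non-founder meioses (2 per non-founder).
    """

    def __init__(self, ped: Pedigree, members: np.ndarray,
                 bit_limit: int = DEFAULT_BIT_LIMIT):
        self.ped = ped
        self.members = np.asarray(members)
        self.local = {int(g): k for k, g in enumerate(self.members)}
        order = [i for i in ped.topological_order if int(i) in self.local]
        self.founder_local = [self.local[int(i)] for i in order if ped.father[i] < 0]
        self.nonfounders = [int(i) for i in order if ped.father[i] >= 0]
        self.m = 2 * len(self.nonfounders)
        if self.m > bit_limit:
            raise CapabilityError(
                f"family with {len(self.nonfounders)} non-founders needs "
                f"{self.m} meiosis bits (> limit {bit_limit}); split the pedigree "
                "or raise bit_limit"
            )
        self.V = 1 << self.m
        self._build_descent()

    def _build_descent(self):
        """Founder-allele label per (inheritance vector, member, allele)."""
        nloc = len(self.members)
        V, m = self.V, self.m
        bits = ((np.arange(V)[:, None] >> np.arange(max(m, 1))) & 1).astype(np.int8)
        A = np.zeros((V, nloc, 2), dtype=np.int16)
        for k, floc in enumerate(self.founder_local):
            A[:, floc, 0] = 2 * k
            A[:, floc, 1] = 2 * k + 1
        for t, gi in enumerate(self.nonfounders):
            i = self.local[gi]
            f = self.local[int(self.ped.father[gi])]
            mo = self.local[int(self.ped.mother[gi])]
            bp = bits[:, 2 * t]
            bm = bits[:, 2 * t + 1]
            A[:, i, 0] = np.where(bp == 0, A[:, f, 0], A[:, f, 1])
            A[:, i, 1] = np.where(bm == 0, A[:, mo, 0], A[:, mo, 1])
        self.descent = A
        self.n_founder_alleles = 2 * len(self.founder_local)
        self._pair_share_cache: dict = {}

    # -- emission -----------------------------------------------------------

    def emission(self, marker_genos: np.ndarray, freq: dict) -> np.ndarray:
        """P(observed genotypes | inheritance vector) for all vectors.

        ``marker_genos`` is the (n_local, 2) allele array for this family's
        members; the founder-allele-graph likelihood sums over consistent
        founder allele assignments weighted by population frequencies.
        """
        typed = [k for k in range(len(self.members))
                 if MISSING not in marker_genos[k]]
        if not typed:
            return np.ones(self.V)
        genos = [tuple(int(a) for a in marker_genos[k]) for k in typed]
        out = np.empty(self.V)
        cache: dict = {}
        sub = self.descent[:, typed, :]
        for v in range(self.V):
            key = sub[v].tobytes()
            val = cache.get(key)
            if val is None:
                val = _founder_graph_lik(sub[v], genos, freq)
                cache[key] = val
            out[v] = val
        return out

    # -- transitions --------------------------------------------------------

    def transport(self, x: np.ndarray, d_cm: float) -> np.ndarray:
        """Diffuse a state distribution across d_cm of Haldane map."""
        theta = float(haldane_theta(d_cm))
        if theta == 0.0 or self.m == 0:
            return x.copy()
        out = x.copy()
        for b in range(self.m):
            out = out.reshape(-1, 2, 1 << b)
            out = (1.0 - theta) * out + theta * out[:, ::-1, :]
        return out.reshape(-1)

    # -- forward-backward ---------------------------------------------------

    def run_chromosome(self, marker_genos: list[np.ndarray], positions: np.ndarray,
                       freqs: list[dict]):
        """Precompute scaled forward/backward vectors at each marker."""
        T = len(positions)
        emis = [self.emission(g, f) for g, f in zip(marker_genos, freqs)]
        V = self.V
        prior = np.full(V, 1.0 / V)
        fwd = []
        x = prior * emis[0]
        s = x.sum()
        if s == 0:
            raise ValueError("genotypes inconsistent with pedigree at first marker "
                             "(zero likelihood); run mendelian_check first")
        fwd.append(x / s)
        for t in range(1, T):
            x = self.transport(fwd[t - 1], positions[t] - positions[t - 1]) * emis[t]
            s = x.sum()
            if s == 0:
                raise ValueError(f"zero likelihood at marker index {t}; "
                                 "run mendelian_check first")
            fwd.append(x / s)
        # g[t] = P(markers t..T | state at t), scaled
        g = [None] * T
        x = emis[T - 1].copy()
        g[T - 1] = x / x.sum()
        for t in range(T - 2, -1, -1):
            x = emis[t] * self.transport(g[t + 1], positions[t + 1] - positions[t])
            g[t] = x / x.sum()
        self._fwd, self._g = fwd, g
        self._positions = np.asarray(positions, float)
        return self

    def posterior(self, pos_cm: float) -> np.ndarray:
        """Posterior over inheritance vectors at an arbitrary cM position."""
        pos = self._positions
        fwd, g = self._fwd, self._g
        if pos_cm <= pos[0]:
            w = np.full(self.V, 1.0 / self.V) * self.transport(g[0], pos[0] - pos_cm)
        elif pos_cm >= pos[-1]:
            w = self.transport(fwd[-1], pos_cm - pos[-1])
        else:
            t = int(np.searchsorted(pos, pos_cm, side="right") - 1)
            if pos_cm == pos[t]:
                # posterior at marker t: forward (incl. emission) x future
                right = self.transport(g[t + 1], pos[t + 1] - pos[t]) if t + 1 < len(pos) \
                    else np.ones(self.V)
                w = fwd[t] * right
            else:
                w = (self.transport(fwd[t], pos_cm - pos[t])
                     * self.transport(g[t + 1], pos[t + 1] - pos_cm))
        s = w.sum()
        return w / s

    def prior_posterior(self) -> np.ndarray:
        """Uniform prior (the no-marker-information limit)."""
        return np.full(self.V, 1.0 / self.V)

    # -- IBD ----------------------------------------------------------------

    def _pair_share(self, i: int, j: int) -> np.ndarray:
        key = (i, j)
        if key not in self._pair_share_cache:
            A = self.descent
            if i == j:
                share = 1.0 + (A[:, i, 0] == A[:, i, 1])
            else:
                share = 0.5 * (
                    (A[:, i, 0] == A[:, j, 0]).astype(float)
                    + (A[:, i, 0] == A[:, j, 1])
                    + (A[:, i, 1] == A[:, j, 0])
                    + (A[:, i, 1] == A[:, j, 1])
                )
            self._pair_share_cache[key] = share
        return self._pair_share_cache[key]

    def pihat(self, weights: np.ndarray) -> np.ndarray:
        """IBD matrix for this family under a posterior over vectors."""
        nloc = len(self.members)
        out = np.empty((nloc, nloc))
        for i in range(nloc):
            for j in range(i, nloc):
                out[i, j] = out[j, i] = float(weights @ self._pair_share(i, j))
        return out


def _founder_graph_lik(labels: np.ndarray, genos: list, freq: dict) -> float:
    """Sum over founder-allele assignments consistent with the genotypes.

    Each typed individual constrains its two founder-allele nodes to carry
    its unordered genotype; connected components admit at most two assignment
    orientations, and unconstrained nodes integrate to 1.
    """
    edges: dict[int, list] = {}
    for (u, w), (a, b) in zip(labels, genos):
        u, w = int(u), int(w)
        if u == w:
            if a != b:
                return 0.0
            edges.setdefault(u, []).append((u, (a, b)))
        else:
            edges.setdefault(u, []).append((w, (a, b)))
            edges.setdefault(w, []).append((u, (a, b)))
    visited: set[int] = set()
    lik = 1.0
    for start in edges:
        if start in visited:
            continue
        # candidate alleles for the start node from its first constraint
        first = edges[start][0][1]
        total = 0.0
        for cand in set(first):
            assign = {start: cand}
            stack = [start]
            okflag = True
            while stack and okflag:
                node = stack.pop()
                aval = assign[node]
                for other, (a, b) in edges[node]:
                    if other == node:
                        if aval != a:
                            okflag = False
                            break
                        continue
                    if aval == a:
                        forced = b
                    elif aval == b:
                        forced = a
                    else:
                        okflag = False
                        break
                    if other in assign:
                        if assign[other] != forced:
                            okflag = False
                            break
                    else:
                        assign[other] = forced
                        stack.append(other)
            if okflag:
                p = 1.0
                for node, al in assign.items():
                    p *= freq.get(al, 0.0)
                total += p
        if total == 0.0:
            return 0.0
        lik *= total
        # mark the whole component visited
        comp_stack = [start]
        visited.add(start)
        while comp_stack:
            node = comp_stack.pop()
            for other, _ in edges[node]:
                if other not in visited:
                    visited.add(other)
                    comp_stack.append(other)
    return lik


# ---------------------------------------------------------------------------
# multipoint IBD across families


class MultipointIBD:
    """Locus-specific IBD matrices for a whole (multi-family) pedigree.

    Builds one :class:`InheritanceHMM` per connected family and assembles
    block-diagonal pihat matrices; between-family entries are 0 and the
    expectation over positions with no marker information equals 2*Phi.
    """

    def __init__(self, ped: Pedigree, genos: MarkerGenotypes, gmap: GeneticMap,
                 bit_limit: int = DEFAULT_BIT_LIMIT):
        self.ped = ped
        self.genos = genos
        self.gmap = gmap
        self.freqs = founder_allele_freqs(ped, genos)
        self.geno_row = {s: i for i, s in enumerate(genos.ids)}
        self.hmms = [InheritanceHMM(ped, fam, bit_limit) for fam in ped.families()]
        self._ran: dict = {}
        kin = kinship_matrix(ped)
        self._relationship = kin.relationship

    def _family_genos(self, hmm: InheritanceHMM, marker: str) -> np.ndarray:
        arr = np.zeros((len(hmm.members), 2), dtype=int)
        data = self.genos.data[marker]
        for k, gi in enumerate(hmm.members):
            row = self.geno_row.get(self.ped.ids[int(gi)])
            if row is not None:
                arr[k] = data[row]
        return arr

    def prepare_chromosome(self, chrom) -> None:
        if chrom in self._ran:
            return
        sub = self.gmap.markers_on(chrom)
        if not len(sub):
            raise KeyError(f"no markers on chromosome {chrom!r}")
        markers = list(sub["marker"])
        positions = sub["pos_cm"].to_numpy(float)
        for hmm in self.hmms:
            fam_genos = [self._family_genos(hmm, m) for m in markers]
            freqs = [self.freqs[m] for m in markers]
            hmm.run_chromosome(fam_genos, positions, freqs)
        self._ran[chrom] = (markers, positions)

    def matrix(self, chrom, pos_cm: float) -> IBDMatrix:
        self.prepare_chromosome(chrom)
        n = len(self.ped)
        pihat = np.zeros((n, n))
        for hmm in self.hmms:
            w = hmm.posterior(pos_cm)
            block = hmm.pihat(w)
            pihat[np.ix_(hmm.members, hmm.members)] = block
        return IBDMatrix(chrom=chrom, pos_cm=float(pos_cm), ids=self.ped.ids,
                         pihat=pihat)

    def nearest_marker(self, chrom, pos_cm: float) -> str:
        markers, positions = self._ran[chrom]
        return markers[int(np.argmin(np.abs(positions - pos_cm)))]


def multipoint_ibd(ped: Pedigree, genos: MarkerGenotypes, gmap: GeneticMap,
                   chrom, pos_cm: float,
                   bit_limit: int = DEFAULT_BIT_LIMIT) -> IBDMatrix:
    """One-shot locus-specific IBD matrix (see :class:`MultipointIBD`)."""
    return MultipointIBD(ped, genos, gmap, bit_limit).matrix(chrom, pos_cm)
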