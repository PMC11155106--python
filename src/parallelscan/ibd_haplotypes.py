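"""Isolation by distance and gene-region haplotype analysis.

Genetic distance is identity-by-state (PLINK convention): for two diploid
genotypes with dosages a, b the shared-allele count is ``2 - |a - b|``, and
the pairwise distance is ``1 - shared/2`` averaged over co-genotyped sites.
Population-level distance averages over cross-population individual pairs.
Geographic distance is the haversine great circle (Earth radius 6,371 km),
and the association between the two matrices is tested with a one-sided
(positive) Mantel permutation test.

Haplotypes over a gene region are collapsed from IUPAC-coded per-sample
sequences after removing ambiguous columns, and related in a minimum
spanning network (epsilon-0 MSN over Hamming distances): the minimum
spanning tree plus every equal-weight alternative edge between components.
Median vectors are not inferred, so star-like data match a median-joining
network while reticulations are represented only by observed haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, PopulationMap

EARTH_RADIUS_KM = 6371.0

_AMBIGUOUS = set("MRWSYKN")


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must have zero diagonal")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        self.values = v

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def ibs_distance(gm: GenotypeMatrix, popmap: PopulationMap) -> DistanceMatrix:
    """Population-level 1-IBS distance: mean over cross-population
    individual pairs of the per-individual-pair allele-sharing distance."""
    pops = popmap.populations
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    popmap.validate_against(gm)
    d = gm.dosage.astype(float)
    d[gm.dosage == MISSING] = np.nan

    def indiv_dist(i: int, j: int) -> float:
        both = ~np.isnan(d[i]) & ~np.isnan(d[j])
        if not both.any():
            raise ValueError(
                f"samples {gm.samples[i]!r} and {gm.samples[j]!r} share no genotyped sites"
            )
        return float(np.abs(d[i, both] - d[j, both]).mean() / 2.0)

    idx = {p: gm.sample_indices(popmap.samples_in(p)) for p in pops}
    out = np.zeros((len(pops), len(pops)))
    for a, b in combinations(range(len(pops)), 2):
        pairs = [indiv_dist(i, j) for i in idx[pops[a]] for j in idx[pops[b]]]
        out[a, b] = out[b, a] = float(np.mean(pairs))
    return DistanceMatrix(labels=list(pops), values=out, units="1-IBS")


def geo_distance(coords: dict[str, tuple[float, float]]) -> DistanceMatrix:
    """Great-circle (haversine) distances in km between population
    coordinates given as (latitude, longitude) in degrees."""
    labels = list(coords)
    for pop, (lat, lon) in coords.items():
        if not -90 <= lat <= 90:
            raise ValueError(f"latitude out of range for {pop!r}: {lat}")
    lat = np.radians([coords[p][0] for p in labels])
    lon = np.radians([coords[p][1] for p in labels])
    out = np.zeros((len(labels), len(labels)))
    for a, b in combinations(range(len(labels)), 2):
        dlat = lat[b] - lat[a]
        dlon = lon[b] - lon[a]
        h = np.sin(dlat / 2) ** 2 + np.cos(lat[a]) * np.cos(lat[b]) * np.sin(dlon / 2) ** 2
        out[a, b] = out[b, a] = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))
    return DistanceMatrix(labels=labels, values=out, units="km")


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int


def mantel(dm1: DistanceMatrix, dm2: DistanceMatrix, n_perm: int = 9999, seed: int = 0) -> MantelResult:
    """One-sided Mantel test for positive association between two distance
    matrices on the same labels.

    r is the Pearson correlation over upper-triangle entries; p is the
    permutation fraction ``(1 + #{r_perm >= r}) / (n_perm + 1)`` under
    simultaneous row/column permutation of the second matrix.
    """
    if dm1.labels != dm2.labels:
        raise ValueError("distance matrices must share labels and order")
    n = len(dm1.labels)
    if n < 3:
        raise ValueError("need >= 3 populations for a Mantel test")
    x = dm1.upper_triangle()
    y = dm2.upper_triangle()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant distance matrix: correlation undefined")

    def corr(a: np.ndarray, b: np.ndarray) -> float:
        return float(np.corrcoef(a, b)[0, 1])

    r_obs = corr(x, y)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        y_perm = dm2.values[np.ix_(perm, perm)][iu]
        if corr(x, y_perm) >= r_obs:
            count += 1
    return MantelResult(r=r_obs, p_value=(1 + count) / (n_perm + 1), n_perm=n_perm)


# ---------------------------------------------------------------------------
# haplotypes
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeSet:
    """Distinct sequences with total and per-population counts."""

    haplotypes: list[str]
    counts: list[int]
    pop_counts: pd.DataFrame | None = None
    members: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.haplotypes)


def collapse_haplotypes(
    seqs: dict[str, str],
    popmap: PopulationMap | None = None,
    ambiguity_mode: str = "drop_columns",
) -> HaplotypeSet:
    """Collapse per-sample IUPAC sequences into distinct haplotypes.

    ``drop_columns`` (default) removes every column where any sequence
    carries an ambiguity code or N before collapsing — deterministic and
    phase-free; ``fifth_state`` keeps ambiguity codes as distinct states.
    """
    if not seqs:
        raise ValueError("no sequences")
    length = {len(s) for s in seqs.values()}
    if len(length) != 1:
        raise ValueError("sequences must be aligned (equal length)")
    names = list(seqs)
    arr = np.array([list(seqs[n]) for n in names])
    if ambiguity_mode == "drop_columns":
        keep = [
            j for j in range(arr.shape[1]) if not any(c in _AMBIGUOUS for c in arr[:, j])
        ]
        if not keep:
            raise ValueError("all columns removed: every column carries an ambiguity code")
        arr = arr[:, keep]
    elif ambiguity_mode != "fifth_state":
        raise ValueError(f"unknown ambiguity_mode {ambiguity_mode!r}")

    collapsed = ["".join(row) for row in arr]
    order: dict[str, list[str]] = {}
    for name, hap in zip(names, collapsed):
        order.setdefault(hap, []).append(name)
    haps = list(order)
    counts = [len(order[h]) for h in haps]
    pop_counts = None
    if popmap is not None:
        pops = popmap.populations
        tab = np.zeros((len(haps), len(pops)), dtype=int)
        for hi, h in enumerate(haps):
            for member in order[h]:
                tab[hi, pops.index(popmap.assignment[member])] += 1
        pop_counts = pd.DataFrame(tab, index=[f"H{i+1}" for i in range(len(haps))], columns=pops)
    return HaplotypeSet(
        haplotypes=haps,
        counts=counts,
        pop_counts=pop_counts,
        members={f"H{i+1}": order[h] for i, h in enumerate(haps)},
    )


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return sum(x != y for x, y in zip(a, b))


def haplotype_network(hapset: HaplotypeSet) -> nx.Graph:
    """Epsilon-0 minimum spanning network over pairwise Hamming distances.

    Edges are added in increasing weight; at each weight every pair of
    haplotypes in different components (as of the previous weight level)
    is connected, so all equally-minimal alternative connections are kept.
    Node attributes carry haplotype sequence and count; edge attribute
    ``weight`` is the mutation-step distance.
    """
    g = nx.Graph()
    labels = [f"H{i+1}" for i in range(len(hapset.haplotypes))]
    for lab, hap, count in zip(labels, hapset.haplotypes, hapset.counts):
        g.add_node(lab, sequence=hap, count=count)
    if len(labels) <= 1:
        return g
    dist = {
        (labels[i], labels[j]): hamming(hapset.haplotypes[i], hapset.haplotypes[j])
        for i, j in combinations(range(len(labels)), 2)
    }
    uf = nx.utils.UnionFind(labels)
    for w in sorted(set(dist.values())):
        level = [(a, b) for (a, b), d in dist.items() if d == w and uf[a] != uf[b]]
        for a, b in level:
            g.add_edge(a, b, weight=w)
        for a, b in level:
            uf.union(a, b)
    return g


def network_edge_table(g: nx.Graph) -> pd.DataFrame:
    rows = [(a, b, d["weight"]) for a, b, d in g.edges(data=True)]
    return pd.DataFrame(rows, columns=["hap_a", "hap_b", "steps"]).sort_values(
        ["steps", "hap_a", "hap_b"], kind="stable"
    ).reset_index(drop=True)
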