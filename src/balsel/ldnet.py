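"""Linkage disequilibrium, haplotype blocks, and median-joining networks.

Because the input is phased, two-locus gamete counts are exact and every
LD quantity (D, D', r^2) comes from direct counting; the D' confidence
interval used by the block finder is computed from the multinomial
likelihood of the four gamete counts over a grid of |D'| values, the
procedure of the confidence-interval ("strong LD") block definition:
a pair is in strong LD when the CI lower bound exceeds 0.70 and the upper
bound reaches 0.98; it shows strong recombination evidence when the upper
bound stays below 0.90; a block requires the outermost pair to be in
strong LD and at least 95% of informative pairs inside to be strong.

The median-joining network iterates minimum-spanning-network construction
with the addition of median (consensus-of-triplet) vectors and pruning of
obsolete unsampled nodes; with epsilon = 0 (default) it returns the
sparsest network.  On recombination-free infinite-sites data the result
is the haplotype tree with each segregating site labelling exactly one
edge.  Removing the heaviest bridge splits the network into the two
deepest clades, the genealogical signature of an ancient balanced
polymorphism.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from balsel.haplotypes import HaplotypeAlignment

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# Pairwise LD
# ----------------------------------------------------------------------

@dataclass
class LdPair:
    i: int
    j: int
    D: float
    Dprime: float
    r2: float
    counts: tuple[int, int, int, int]   # n11, n10, n01, n00


def _gamete_counts(aln: HaplotypeAlignment, i: int, j: int):
    a = aln.H[:, i]
    b = aln.H[:, j]
    ok = (a >= 0) & (b >= 0)
    a, b = a[ok], b[ok]
    n11 = int(np.sum((a == 1) & (b == 1)))
    n10 = int(np.sum((a == 1) & (b == 0)))
    n01 = int(np.sum((a == 0) & (b == 1)))
    n00 = int(np.sum((a == 0) & (b == 0)))
    return n11, n10, n01, n00


def ld_pair(aln: HaplotypeAlignment, i: int, j: int) -> LdPair:
    """D, D' and r^2 between sites i and j from phased gamete counts."""
    n11, n10, n01, n00 = _gamete_counts(aln, i, j)
    n = n11 + n10 + n01 + n00
    pa = (n11 + n10) / n
    pb = (n11 + n01) / n
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError(f"site {i if pa in (0,1) else j} is monomorphic")
    D = n11 / n - pa * pb
    if D >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    dprime = D / dmax if dmax > 0 else 0.0
    r2 = D * D / (pa * (1 - pa) * pb * (1 - pb))
    return LdPair(i=i, j=j, D=D, Dprime=dprime, r2=r2, counts=(n11, n10, n01, n00))


def dprime_ci(
    aln: HaplotypeAlignment,
    i: int,
    j: int,
    grid: int = 101,
    mass: float = 0.05,
) -> tuple[float, float]:
    """(lower, upper) bounds of |D'| from the gamete-count likelihood.

    The likelihood of the four gamete counts is evaluated on a grid of
    |D'| in [0, 1] with allele frequencies fixed at their sample values,
    normalised, and the 5th/95th cumulative points returned.
    """
    n11, n10, n01, n00 = _gamete_counts(aln, i, j)
    n = n11 + n10 + n01 + n00
    pa = (n11 + n10) / n
    pb = (n11 + n01) / n
    D_obs = n11 / n - pa * pb
    sign = 1.0 if D_obs >= 0 else -1.0
    if sign > 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    dp = np.linspace(0.0, 1.0, grid)
    D = sign * dp * dmax
    f11 = np.clip(pa * pb + D, 1e-12, 1.0)
    f10 = np.clip(pa * (1 - pb) - D, 1e-12, 1.0)
    f01 = np.clip((1 - pa) * pb - D, 1e-12, 1.0)
    f00 = np.clip((1 - pa) * (1 - pb) + D, 1e-12, 1.0)
    ll = (
        n11 * np.log(f11)
        + n10 * np.log(f10)
        + n01 * np.log(f01)
        + n00 * np.log(f00)
    )
    w = np.exp(ll - ll.max())
    cdf = np.cumsum(w) / w.sum()
    lower = float(dp[int(np.searchsorted(cdf, mass))])
    upper = float(dp[int(np.searchsorted(cdf, 1.0 - mass, side="left"))])
    return lower, min(upper, 1.0)


# ----------------------------------------------------------------------
# Confidence-interval haplotype blocks
# ----------------------------------------------------------------------

@dataclass
class Block:
    first_site: int
    last_site: int
    start_pos: int
    end_pos: int
    n_sites: int


def ci_blocks(
    aln: HaplotypeAlignment,
    maf_min: float = 0.05,
    ci_low: float = 0.70,
    ci_high: float = 0.98,
    recomb_high: float = 0.90,
    strong_frac: float = 0.95,
) -> list[Block]:
    """Haplotype blocks by the confidence-interval (strong LD) criterion.

    Sites below ``maf_min`` are ignored.  Candidate spans whose outermost
    pair is in strong LD and whose informative pairs are at least
    ``strong_frac`` strong become blocks; longest spans win, without
    overlap.  Returns an empty list (with a warning) when sample size
    leaves every CI too wide.
    """
    maf = aln.minor_counts() / np.maximum(aln.sample_sizes(), 1)
    usable = np.flatnonzero((maf >= maf_min) & aln.segregating())
    m = len(usable)
    if m < 2:
        return []

    strong = {}
    recomb = {}
    for a_i, b_i in itertools.combinations(range(m), 2):
        lo, hi = dprime_ci(aln, int(usable[a_i]), int(usable[b_i]))
        strong[(a_i, b_i)] = lo > ci_low and hi >= ci_high
        recomb[(a_i, b_i)] = hi < recomb_high

    candidates = []
    for a_i in range(m):
        for b_i in range(a_i + 1, m):
            if not strong[(a_i, b_i)]:
                continue
            n_strong = n_inform = 0
            for x, y in itertools.combinations(range(a_i, b_i + 1), 2):
                if strong[(x, y)]:
                    n_strong += 1
                    n_inform += 1
                elif recomb[(x, y)]:
                    n_inform += 1
            if n_inform == 0:
                continue
            if n_strong / n_inform >= strong_frac:
                span = aln.positions[usable[b_i]] - aln.positions[usable[a_i]]
                candidates.append((span, a_i, b_i))
    if not candidates:
        logger.warning("no haplotype blocks (CIs too wide or no strong LD)")
        return []

    candidates.sort(key=lambda t: (-t[0], t[1]))
    taken = np.zeros(m, dtype=bool)
    blocks = []
    for _, a_i, b_i in candidates:
        if taken[a_i : b_i + 1].any():
            continue
        taken[a_i : b_i + 1] = True
        blocks.append(
            Block(
                first_site=int(usable[a_i]),
                last_site=int(usable[b_i]),
                start_pos=int(aln.positions[usable[a_i]]),
                end_pos=int(aln.positions[usable[b_i]]),
                n_sites=int(b_i - a_i + 1),
            )
        )
    blocks.sort(key=lambda b: b.first_site)
    return blocks


# ----------------------------------------------------------------------
# Median-joining network
# ----------------------------------------------------------------------

def _distinct_haplotypes(aln: HaplotypeAlignment):
    """Collapse rows to distinct haplotypes with multiplicities."""
    haps: dict[tuple, dict] = {}
    labels = aln.pop_labels
    for idx, row in enumerate(aln.H):
        key = tuple(int(x) for x in row)
        rec = haps.setdefault(key, {"count": 0, "pops": {}, "samples": []})
        rec["count"] += 1
        rec["pops"][labels[idx]] = rec["pops"].get(labels[idx], 0) + 1
        rec["samples"].append(idx)
    return haps


def _msn(vectors: list[tuple], epsilon: int = 0) -> nx.Graph:
    """Minimum-spanning network: all links of every epsilon-relaxed MST."""
    V = len(vectors)
    G = nx.Graph()
    G.add_nodes_from(range(V))
    if V == 1:
        return G
    arr = np.asarray(vectors, dtype=np.int8)
    dist = np.zeros((V, V), dtype=np.int64)
    for i in range(V):
        dist[i] = np.sum(arr != arr[i], axis=1)
    pairs_by_d: dict[int, list[tuple[int, int]]] = {}
    for i in range(V):
        for j in range(i + 1, V):
            pairs_by_d.setdefault(int(dist[i, j]), []).append((i, j))

    parent = list(range(V))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    min_connect: dict[tuple[int, int], int] = {}
    for d in sorted(pairs_by_d):
        snapshot = {i: find(i) for i in range(V)}
        added = []
        for i, j in pairs_by_d[d]:
            ci, cj = snapshot[i], snapshot[j]
            if ci == cj:
                continue
            key = (min(ci, cj), max(ci, cj))
            first = min_connect.setdefault(key, d)
            if d <= first + epsilon:
                G.add_edge(i, j, weight=int(d))
                added.append((i, j))
        for i, j in added:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
    return G


def mj_network(
    aln: HaplotypeAlignment,
    epsilon: int = 0,
    attach_mrca: bool = False,
    max_rounds: int = 20,
) -> nx.Graph:
    """Median-joining haplotype network.

    Nodes carry ``hap`` (allele tuple), ``count`` (multiplicity, 0 for
    inferred median vectors), ``pops`` (per-population counts),
    ``samples`` (row indices of the alignment) and ``median`` /``mrca``
    flags; edges carry ``sites`` (differing site indices) and ``weight``.
    With ``attach_mrca`` the all-ancestral haplotype is added as the MRCA
    node (requires a polarized alignment).
    """
    haps = _distinct_haplotypes(aln)
    vectors = sorted(haps)           # lexicographic: deterministic order
    observed = set(vectors)
    mrca_key = None
    if attach_mrca:
        if not bool(np.all(aln.polarized)):
            raise ValueError("MRCA attachment requires a fully polarized alignment")
        mrca_key = tuple([0] * aln.n_sites)
        if mrca_key not in observed:
            vectors.append(mrca_key)

    vset = set(vectors)
    for _ in range(max_rounds):
        G = _msn(vectors, epsilon)
        new: set[tuple] = set()
        for u in G.nodes:
            nbrs = list(G.neighbors(u))
            for v, w in itertools.combinations(nbrs, 2):
                tri = np.asarray(
                    [vectors[u], vectors[v], vectors[w]], dtype=np.int8
                )
                med = tuple(int(x) for x in (tri.sum(axis=0) >= 2))
                if med not in vset:
                    new.add(med)
        if not new:
            break
        vectors.extend(sorted(new))
        vset |= new
    # prune obsolete median vectors: unsampled nodes of degree <= 2 that
    # sit on a geodesic (always true for binary medians), then rebuild
    while True:
        G = _msn(vectors, epsilon)
        drop = None
        for idx, vec in enumerate(vectors):
            if vec in observed or vec == mrca_key:
                continue
            if G.degree(idx) <= 2:
                drop = idx
                break
        if drop is None:
            break
        vectors.pop(drop)

    G = _msn(vectors, epsilon)
    out = nx.Graph()
    for idx, vec in enumerate(vectors):
        rec = haps.get(vec)
        out.add_node(
            idx,
            hap=vec,
            count=rec["count"] if rec else 0,
            pops=dict(rec["pops"]) if rec else {},
            samples=list(rec["samples"]) if rec else [],
            median=rec is None and vec != mrca_key,
            mrca=vec == mrca_key,
        )
    for i, j, data in G.edges(data=True):
        a = np.asarray(vectors[i], dtype=np.int8)
        b = np.asarray(vectors[j], dtype=np.int8)
        sites = [int(s) for s in np.flatnonzero(a != b)]
        out.add_edge(i, j, weight=int(data["weight"]), sites=sites)
    return out


@dataclass
class CladeSplit:
    clade_nodes: tuple[list[int], list[int]]
    clade_counts: tuple[int, int]
    pop_counts: tuple[dict, dict]
    clade_of_sample: dict[int, int]
    cut_sites: list[int]
    cut_weight: int
    weak: bool


def clade_split(net: nx.Graph) -> CladeSplit:
    """Bipartition the network at its heaviest bridge.

    The removed edge is the bridge carrying the most mutations (ties are
    broken towards the smallest leftmost site index on the edge label,
    and logged).  The larger clade is reported first.  A split is flagged
    weak when the cut carries a single mutation or strands a single
    chromosome.
    """
    if net.number_of_nodes() < 2:
        raise ValueError("cannot split a single-node network")
    bridges = list(nx.bridges(net))
    if not bridges:
        raise ValueError("network has no bridge to cut (fully reticulate)")

    def key(e):
        d = net.edges[e]
        left = min(d["sites"]) if d["sites"] else -1
        return (-d["weight"], left)

    bridges.sort(key=key)
    best = bridges[0]
    same = [e for e in bridges if net.edges[e]["weight"] == net.edges[best]["weight"]]
    if len(same) > 1:
        logger.info(
            "tie among %d max-weight bridges; cutting leftmost-labelled", len(same)
        )
    cut = net.edges[best]
    G = net.copy()
    G.remove_edge(*best)
    comps = sorted(nx.connected_components(G), key=len, reverse=True)
    parts = [sorted(comps[0]), sorted(comps[1])]

    def total(nodes):
        return sum(net.nodes[v]["count"] for v in nodes)

    if total(parts[1]) > total(parts[0]):
        parts = parts[::-1]
    counts = (total(parts[0]), total(parts[1]))
    pops: list[dict] = []
    assign: dict[int, int] = {}
    for c, nodes in enumerate(parts):
        agg: dict[str, int] = {}
        for v in nodes:
            for p, k in net.nodes[v]["pops"].items():
                agg[p] = agg.get(p, 0) + k
            for s in net.nodes[v]["samples"]:
                assign[s] = c
        pops.append(agg)
    weak = cut["weight"] <= 1 or min(counts) <= 1
    return CladeSplit(
        clade_nodes=(parts[0], parts[1]),
        clade_counts=counts,
        pop_counts=(pops[0], pops[1]),
        clade_of_sample=assign,
        cut_sites=list(cut["sites"]),
        cut_weight=int(cut["weight"]),
        weak=weak,
    )


def to_gml(net: nx.Graph, path: str) -> None:
    """Write the network as GML (haplotypes stringified for portability)."""
    G = nx.Graph()
    for v, d in net.nodes(data=True):
        G.add_node(
            v,
            hap="".join(str(x) for x in d["hap"]),
            count=d["count"],
            median=int(d["median"]),
            mrca=int(d.get("mrca", False)),
        )
    for i, j, d in net.edges(data=True):
        G.add_edge(i, j, weight=d["weight"], sites=",".join(map(str, d["sites"])))
    nx.write_gml(G, path)
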