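"""Overlapping-module discovery and gene-set enrichment.

A miRNA's *regulatory emphasis* is the dominant cohesive module among the
proteins its targets encode.  Modules are found with a cohesiveness-based
greedy clustering in the style of ClusterONE: the cohesiveness of a vertex
set V on a weighted graph is

    w_in / (w_in + w_bound + penalty * |V|)

where ``w_in`` is the total edge weight inside V, ``w_bound`` the total
weight on the boundary (exactly one endpoint in V), and ``penalty`` models
unobserved interactions.  Clusters are grown greedily from high-degree
seeds, near-duplicates merged by the overlap score
``omega(A, B) = |A ∩ B|^2 / (|A| |B|)``, and small or sparse clusters
discarded.  All tie-breaking is lexicographic on node identifier so results
are bit-stable.

Modules are scored against disease gene sets by the hypergeometric
upper-tail test with Benjamini–Hochberg adjustment across sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError, NotFoundError, ParameterError
from .network import PPINetwork

DEFAULT_PENALTY = 2.0
DEFAULT_MIN_SIZE = 3
DEFAULT_MIN_DENSITY = 0.5
DEFAULT_OVERLAP_MERGE = 0.8


@dataclass(frozen=True)
class EnrichmentResult:
    gene_set_id: str
    overlap: int
    p_value: float
    adjusted_p: float


@dataclass(frozen=True)
class FunctionalModule:
    """An overlapping cluster of proteins with its quality statistics."""

    members: frozenset[str]
    cohesiveness: float
    density: float
    enrichment: tuple[EnrichmentResult, ...] = ()

    @property
    def size(self) -> int:
        return len(self.members)


def _edge_weight(net: PPINetwork, a: str, b: str) -> float:
    return net.edges[a, b].get("confidence", 1.0)


def _in_bound_weights(net: PPINetwork, members: set[str]) -> tuple[float, float]:
    w_in = 0.0
    w_bound = 0.0
    for v in members:
        for u in net.neighbors(v):
            w = _edge_weight(net, v, u)
            if u in members:
                w_in += w / 2.0   # each internal edge visited twice
            else:
                w_bound += w
    return w_in, w_bound


def cohesiveness(net: PPINetwork, members: Iterable[str],
                 penalty: float = DEFAULT_PENALTY) -> float:
    """Weighted cohesiveness ``w_in / (w_in + w_bound + penalty*|V|)``."""
    members = set(members)
    if not members:
        raise ParameterError("cohesiveness of an empty member set")
    missing = members - set(net.nodes)
    if missing:
        raise NotFoundError(f"members not in network: {sorted(missing)[:5]}")
    w_in, w_bound = _in_bound_weights(net, members)
    denom = w_in + w_bound + penalty * len(members)
    return w_in / denom if denom > 0 else 0.0


def density(net: PPINetwork, members: Iterable[str]) -> float:
    """Internal weighted density: sum of internal edge confidences over the
    number of possible pairs.  1.0 for a singleton by convention."""
    members = set(members)
    n = len(members)
    if n == 0:
        raise ParameterError("density of an empty member set")
    if n == 1:
        return 1.0
    w_in, _ = _in_bound_weights(net, members)
    return w_in / (n * (n - 1) / 2.0)


def grow_cluster(net: PPINetwork, seed: str,
                 penalty: float = DEFAULT_PENALTY) -> set[str]:
    """Greedy local cohesiveness maximization from a singleton seed.

    At each step every boundary-node addition and every member removal is
    evaluated; the single move with the largest strict cohesiveness increase
    is applied (ties broken by preferring additions, then by lexicographic
    node identifier).  Stops when no move improves cohesiveness.
    """
    if seed not in net:
        raise NotFoundError(f"seed node {seed!r} not in network")
    members = {seed}
    current = cohesiveness(net, members, penalty)
    while True:
        candidates: list[tuple[float, int, str]] = []
        boundary = {u for v in members for u in net.neighbors(v)} - members
        for u in sorted(boundary):
            value = cohesiveness(net, members | {u}, penalty)
            candidates.append((value, 0, u))
        if len(members) > 1:
            for v in sorted(members):
                value = cohesiveness(net, members - {v}, penalty)
                candidates.append((value, 1, v))
        if not candidates:
            break
        # max cohesiveness; ties -> additions first, then smallest node id
        best_value, kind, node = max(candidates,
                                     key=lambda c: (c[0], -c[1],
                                                    _rev(c[2])))
        if best_value <= current + 1e-12:
            break
        if kind == 0:
            members.add(node)
        else:
            members.remove(node)
        current = best_value
    return members


class _Rev:
    """Reversed lexicographic comparison, so max() picks the smallest id."""

    __slots__ = ("s",)

    def __init__(self, s: str):
        self.s = s

    def __lt__(self, other: "_Rev") -> bool:
        return self.s > other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _Rev) and self.s == other.s


def _rev(s: str) -> _Rev:
    return _Rev(s)


def overlap_score(a: Iterable[str], b: Iterable[str]) -> float:
    """omega(A, B) = |A ∩ B|^2 / (|A| * |B|)."""
    a, b = set(a), set(b)
    if not a or not b:
        return 0.0
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def cluster_one(net: PPINetwork,
                penalty: float = DEFAULT_PENALTY,
                min_size: int = DEFAULT_MIN_SIZE,
                min_density: float = DEFAULT_MIN_DENSITY,
                overlap_merge: float = DEFAULT_OVERLAP_MERGE,
                ) -> list[FunctionalModule]:
    """Cohesiveness clustering of the whole network.

    Seeds are taken in decreasing degree order (ties lexicographic) over
    nodes not yet covered; a grown cluster covers its nodes only when it
    passes the ``min_size`` and ``min_density`` filters, so a degenerate
    growth does not block better seeds.  Retained clusters whose pairwise
    overlap score reaches ``overlap_merge`` are merged (union), and merged
    unions are re-filtered.  Output is sorted by size (largest first), then
    cohesiveness, then members.
    """
    order = sorted(net.nodes, key=lambda v: (-net.degree[v], v))
    covered: set[str] = set()
    raw: list[set[str]] = []
    for seed in order:
        if seed in covered:
            continue
        cluster = grow_cluster(net, seed, penalty)
        if len(cluster) < min_size or density(net, cluster) < min_density:
            continue
        raw.append(cluster)
        covered |= cluster

    # merge near-duplicates by union-find over omega >= overlap_merge
    parent = list(range(len(raw)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(raw)):
        for j in range(i + 1, len(raw)):
            if overlap_score(raw[i], raw[j]) >= overlap_merge:
                parent[find(j)] = find(i)
    merged: dict[int, set[str]] = {}
    for i, cluster in enumerate(raw):
        merged.setdefault(find(i), set()).update(cluster)

    modules = []
    for members in merged.values():
        if len(members) < min_size:
            continue
        d = density(net, members)
        if d < min_density:
            continue
        modules.append(FunctionalModule(frozenset(members),
                                        cohesiveness(net, members, penalty),
                                        d))
    modules.sort(key=lambda m: (-m.size, -m.cohesiveness,
                                tuple(sorted(m.members))))
    return modules


def largest_module(modules: Sequence[FunctionalModule]) -> FunctionalModule:
    """Module of maximal size; ties by cohesiveness then smallest member."""
    if not modules:
        raise NotFoundError("no functional module found")
    return min(modules, key=lambda m: (-m.size, -m.cohesiveness,
                                       tuple(sorted(m.members))))


def target_subnetwork(net: PPINetwork, targets: Iterable[str]) -> PPINetwork:
    """Subgraph induced by a miRNA's in-network target proteins."""
    present = [t for t in targets if t in net]
    return net.subgraph(present).copy()


# ---------------------------------------------------------------------------
# Gene sets and enrichment

@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise InputError(f"gene set {self.set_id!r} has no members")


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, gene_set: GeneSet) -> None:
        self.sets[gene_set.set_id] = gene_set

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    @classmethod
    def read_gmt(cls, path: str | Path) -> "GeneSetCollection":
        collection = cls()
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise InputError(f"{path}:{lineno}: GMT line needs at "
                                     f"least 3 fields")
                collection.add(GeneSet(parts[0], parts[1],
                                       frozenset(p for p in parts[2:] if p)))
        return collection

    def write_gmt(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            for gs in self.sets.values():
                members = "\t".join(sorted(gs.members))
                handle.write(f"{gs.set_id}\t{gs.description}\t{members}\n")


def enrich(module: FunctionalModule, sets: GeneSetCollection,
           universe: Iterable[str]) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail enrichment of a module in each gene set.

    The p-value is the probability of drawing at least the observed overlap
    when sampling ``|module|`` genes from ``universe`` containing
    ``|set ∩ universe|`` successes; Benjamini–Hochberg adjusted across sets.
    Results are sorted by p-value (ties by set id).
    """
    universe = set(universe)
    if not universe:
        raise ParameterError("empty enrichment universe")
    if not module.members <= universe:
        raise InputError("module members must be contained in the universe")
    results = []
    for gs in sets:
        in_universe = gs.members & universe
        overlap = len(module.members & in_universe)
        # P[X >= overlap], X ~ Hypergeom(|U|, |set|, |module|)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe),
                                     len(in_universe), module.size))
        results.append((gs.set_id, overlap, min(p, 1.0)))
    if not results:
        return []
    _, adjusted, _, _ = multipletests([r[2] for r in results],
                                      method="fdr_bh")
    out = [EnrichmentResult(set_id, overlap, p, float(adj))
           for (set_id, overlap, p), adj in zip(results, adjusted)]
    out.sort(key=lambda r: (r.p_value, r.gene_set_id))
    return out


def enrich_module(module: FunctionalModule, sets: GeneSetCollection,
                  universe: Iterable[str]) -> FunctionalModule:
    """Return the module with its enrichment field populated."""
    return replace(module, enrichment=tuple(enrich(module, sets, universe)))
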