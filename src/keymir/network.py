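"""Confidence-filtered PPI networks and static topological miRNA scoring.

The static score measures a miRNA's *regulatory capacity*: how central the
proteins encoded by its target genes sit in a protein–protein interaction
network.  For the set of in-network targets T of a miRNA,

    static = mean_deg(T)/mean_deg(V) + mean_nc(T)/mean_nc(V) - offset

where ``deg`` is the unweighted degree, ``nc`` the neighborhood connectivity
(mean degree of a node's neighbors), V the whole network, and ``offset`` a
fixed shift (default 3.3).  Scores above a cutoff (default 0.6) flag
*enhanced* regulation.  Edge confidences are used only to filter the network
(default threshold 0.7, inclusive); topology statistics are unweighted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import InputError, NotFoundError, ParameterError, UndefinedResultError

DEFAULT_CONFIDENCE_THRESHOLD = 0.7
DEFAULT_STATIC_OFFSET = 3.3
DEFAULT_ENHANCED_CUTOFF = 0.6
DEFAULT_TARGET_P_CUTOFF = 0.01

#: A PPINetwork is an undirected networkx Graph whose edges carry a
#: ``confidence`` attribute in [0, 1] and whose nodes may carry a
#: nonnegative ``abundance`` attribute (linear concentration units).
PPINetwork = nx.Graph


# ---------------------------------------------------------------------------
# Construction

def read_edge_tsv(path: str | Path) -> list[tuple[str, str, float]]:
    """Parse ``protein_a<TAB>protein_b<TAB>combined_score`` edge records.

    Raises :class:`InputError` with the offending line number on malformed
    lines.  A header line starting with ``protein_a`` is skipped.
    """
    records = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0] in ("protein_a", "protein1"):
                continue
            if len(parts) != 3:
                raise InputError(f"{path}:{lineno}: expected 3 tab-separated "
                                 f"fields, got {len(parts)}")
            a, b, raw = parts
            try:
                score = float(raw)
            except ValueError:
                raise InputError(f"{path}:{lineno}: confidence score "
                                 f"{raw!r} is not a number") from None
            if not a or not b:
                raise InputError(f"{path}:{lineno}: empty protein identifier")
            records.append((a, b, score))
    return records


def build_network(edges: Iterable[tuple[str, str, float]] | str | Path,
                  confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
                  ) -> PPINetwork:
    """Build the confidence-filtered PPI network from an edge list.

    Scores may be probabilities in [0, 1] or the STRING 0–999 integer
    dialect; the dialect is auto-detected (any score > 1 rescales the whole
    list by 1/1000).  Duplicate undirected edges collapse to the maximum
    confidence; self-loops are dropped.  The threshold is inclusive.

    Raises :class:`InputError` if no edge survives the filter.
    """
    if isinstance(edges, (str, Path)):
        edges = read_edge_tsv(edges)
    else:
        edges = list(edges)
    if not 0 <= confidence_threshold <= 1:
        raise ParameterError(f"confidence threshold must be in [0, 1], "
                             f"got {confidence_threshold}")
    scores = [e[2] for e in edges]
    if any(s < 0 for s in scores):
        raise InputError("negative confidence score in edge list")
    string_dialect = any(s > 1 for s in scores)
    if string_dialect and any(s > 999 for s in scores):
        raise InputError("confidence scores exceed the STRING 0-999 dialect")

    net = nx.Graph()
    for a, b, score in edges:
        if string_dialect:
            score = score / 1000.0
        if a == b:
            continue
        if score < confidence_threshold:
            continue
        if net.has_edge(a, b):
            score = max(score, net.edges[a, b]["confidence"])
        net.add_edge(a, b, confidence=score)
    if net.number_of_edges() == 0:
        raise InputError(f"empty network: no edge has confidence >= "
                         f"{confidence_threshold}")
    return net


def attach_abundance(net: PPINetwork, abundance: Mapping[str, float],
                     floor: float = 1e-6) -> int:
    """Attach linear-scale abundances as the ``abundance`` node attribute.

    Non-positive values are floored at ``floor``; nodes absent from the
    mapping also receive ``floor``.  Returns the number of nodes that
    received a measured (non-floored) value.
    """
    matched = 0
    for node in net.nodes:
        value = abundance.get(node)
        if value is None:
            net.nodes[node]["abundance"] = floor
        else:
            if value < 0:
                raise InputError(f"negative abundance for {node!r}: {value}")
            net.nodes[node]["abundance"] = max(float(value), floor)
            matched += 1
    return matched


def read_abundance_tsv(path: str | Path) -> dict[str, float]:
    """Read a ``gene_id<TAB>abundance`` table (linear scale)."""
    frame = pd.read_csv(path, sep="\t")
    if list(frame.columns[:2]) != ["gene_id", "abundance"]:
        frame.columns = ["gene_id", "abundance", *frame.columns[2:]]
    return dict(zip(frame["gene_id"].astype(str), frame["abundance"].astype(float)))


# ---------------------------------------------------------------------------
# Topology

def degree(net: PPINetwork, node: str) -> int:
    """Unweighted degree; raises :class:`NotFoundError` on unknown node."""
    if node not in net:
        raise NotFoundError(f"node {node!r} not in network")
    return net.degree[node]


def neighborhood_connectivity(net: PPINetwork, node: str) -> float:
    """Mean degree of a node's neighbors; 0 for an isolated node."""
    if node not in net:
        raise NotFoundError(f"node {node!r} not in network")
    neighbors = list(net.neighbors(node))
    if not neighbors:
        return 0.0
    return sum(net.degree[n] for n in neighbors) / len(neighbors)


def mean_degree(net: PPINetwork) -> float:
    n = net.number_of_nodes()
    return 2.0 * net.number_of_edges() / n if n else 0.0


def mean_neighborhood_connectivity(net: PPINetwork) -> float:
    n = net.number_of_nodes()
    if n == 0:
        return 0.0
    return sum(neighborhood_connectivity(net, v) for v in net.nodes) / n


# ---------------------------------------------------------------------------
# Static score

@dataclass(frozen=True)
class StaticScoreRecord:
    """Static topological score of one miRNA on one network.

    ``static_score`` is ``None`` (undefined) when no target gene is present
    in the network; ``enhanced`` is then ``None`` as well.
    """

    mirna_id: str
    network_id: str
    n_targets_in_network: int
    n_targets_missing: int
    norm_mean_degree: float | None
    norm_mean_neighborhood_connectivity: float | None
    static_score: float | None
    enhanced: bool | None

    @property
    def defined(self) -> bool:
        return self.static_score is not None


def static_score(net: PPINetwork, targets: Iterable[str],
                 offset: float = DEFAULT_STATIC_OFFSET,
                 cutoff: float = DEFAULT_ENHANCED_CUTOFF,
                 mirna_id: str = "", network_id: str = "") -> StaticScoreRecord:
    """Score a target set against the network-mean background.

    Targets absent from the network are excluded from the means and counted
    in ``n_targets_missing``.  With no in-network target the record carries
    an explicit undefined marker rather than a number.
    """
    targets = set(targets)
    in_net = sorted(t for t in targets if t in net)
    missing = len(targets) - len(in_net)
    if not in_net:
        return StaticScoreRecord(mirna_id, network_id, 0, missing,
                                 None, None, None, None)
    bg_deg = mean_degree(net)
    bg_nc = mean_neighborhood_connectivity(net)
    t_deg = sum(net.degree[t] for t in in_net) / len(in_net)
    t_nc = sum(neighborhood_connectivity(net, t) for t in in_net) / len(in_net)
    norm_deg = t_deg / bg_deg if bg_deg > 0 else 0.0
    norm_nc = t_nc / bg_nc if bg_nc > 0 else 0.0
    score = norm_deg + norm_nc - offset
    return StaticScoreRecord(mirna_id, network_id, len(in_net), missing,
                             norm_deg, norm_nc, score, score > cutoff)


def classify_enhanced(records_net1: Sequence[StaticScoreRecord],
                      records_net2: Sequence[StaticScoreRecord] | None,
                      cutoff: float = DEFAULT_ENHANCED_CUTOFF,
                      ) -> dict[str, dict[str, bool | None]]:
    """Combine per-network enhanced flags into per-miRNA verdicts.

    Returns ``{mirna: {enhanced_net1, enhanced_net2, enhanced_both,
    evaluable}}``.  A miRNA undefined on either network is flagged
    not-evaluable (``enhanced_both`` is ``None``).  With a single network,
    ``enhanced_both`` degrades to the single-network flag.
    """
    rec1 = {r.mirna_id: r for r in records_net1}
    rec2 = {r.mirna_id: r for r in records_net2} if records_net2 is not None else None

    def flag(rec: StaticScoreRecord | None) -> bool | None:
        if rec is None or not rec.defined:
            return None
        return rec.static_score > cutoff

    out: dict[str, dict[str, bool | None]] = {}
    for mirna in rec1:
        f1 = flag(rec1[mirna])
        if rec2 is None:
            out[mirna] = {"enhanced_net1": f1, "enhanced_net2": None,
                          "enhanced_both": f1, "evaluable": f1 is not None}
        else:
            f2 = flag(rec2.get(mirna))
            evaluable = f1 is not None and f2 is not None
            out[mirna] = {"enhanced_net1": f1, "enhanced_net2": f2,
                          "enhanced_both": (f1 and f2) if evaluable else None,
                          "evaluable": evaluable}
    return out


# ---------------------------------------------------------------------------
# Target maps

@dataclass(frozen=True)
class TargetRecord:
    """One miRNA→gene interaction: validated, or predicted with a p-value."""

    gene_id: str
    evidence: str                 # 'validated' | 'predicted'
    p_value: float | None = None  # prediction p-value; None for validated

    def __post_init__(self) -> None:
        if self.evidence not in ("validated", "predicted"):
            raise InputError(f"evidence must be 'validated' or 'predicted', "
                             f"got {self.evidence!r}")
        if self.evidence == "validated" and self.p_value is not None:
            raise InputError(f"validated target {self.gene_id!r} must not "
                             f"carry a prediction p-value")
        if self.evidence == "predicted":
            if self.p_value is None or not 0 <= self.p_value <= 1:
                raise InputError(f"predicted target {self.gene_id!r} needs a "
                                 f"p-value in [0, 1], got {self.p_value}")


@dataclass
class TargetMap:
    """miRNA → target-gene records."""

    entries: dict[str, list[TargetRecord]] = field(default_factory=dict)

    def genes(self, mirna_id: str) -> set[str]:
        return {r.gene_id for r in self.entries.get(mirna_id, [])}

    def all_genes(self) -> set[str]:
        return {r.gene_id for recs in self.entries.values() for r in recs}

    @property
    def mirnas(self) -> list[str]:
        return list(self.entries)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TargetMap":
        """Read ``mirna_id<TAB>gene_id<TAB>evidence<TAB>p_value`` records
        (p_value column empty for validated targets)."""
        entries: dict[str, list[TargetRecord]] = {}
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if lineno == 1 and parts[0] == "mirna_id":
                    continue
                if len(parts) not in (3, 4):
                    raise InputError(f"{path}:{lineno}: expected 3 or 4 "
                                     f"fields, got {len(parts)}")
                mirna, gene, evidence = parts[0], parts[1], parts[2]
                raw_p = parts[3] if len(parts) == 4 else ""
                p_value = float(raw_p) if raw_p else None
                try:
                    record = TargetRecord(gene, evidence, p_value)
                except InputError as err:
                    raise InputError(f"{path}:{lineno}: {err}") from None
                entries.setdefault(mirna, []).append(record)
        return cls(entries)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            handle.write("mirna_id\tgene_id\tevidence\tp_value\n")
            for mirna, records in self.entries.items():
                for r in records:
                    p = "" if r.p_value is None else f"{r.p_value:.6g}"
                    handle.write(f"{mirna}\t{r.gene_id}\t{r.evidence}\t{p}\n")


def target_confidence_summary(records: Sequence[TargetRecord],
                              p_cutoff: float = DEFAULT_TARGET_P_CUTOFF,
                              ) -> float:
    """Fraction of targets that are validated or confidently predicted
    (prediction p-value < ``p_cutoff``)."""
    if not records:
        raise UndefinedResultError("target confidence undefined for an "
                                   "empty target entry")
    credible = sum(1 for r in records
                   if r.evidence == "validated" or r.p_value < p_cutoff)
    return credible / len(records)


def static_records_to_frame(records: Sequence[StaticScoreRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "mirna_id": r.mirna_id,
            "network_id": r.network_id,
            "n_targets_in_network": r.n_targets_in_network,
            "n_targets_missing": r.n_targets_missing,
            "norm_mean_degree": math.nan if r.norm_mean_degree is None
                                else r.norm_mean_degree,
            "norm_mean_neighborhood_connectivity":
                math.nan if r.norm_mean_neighborhood_connectivity is None
                else r.norm_mean_neighborhood_connectivity,
            "static_score": math.nan if r.static_score is None else r.static_score,
            "enhanced": r.enhanced,
        })
    return pd.DataFrame(rows).set_index("mirna_id")
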