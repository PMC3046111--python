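"""Synthetic benchmark generator with planted key miRNAs.

Emulates the statistical shape of the study inputs so every pipeline stage
can be verified against a known ground truth without downloads:

* a scale-free (preferential-attachment) PPI network with confidence
  weights in [0.7, 1] and heavy-tailed (log-normal) abundances;
* planted dense modules (the "regulatory emphasis" ground truth);
* a target map in which key miRNAs preferentially hit planted-module
  members and hubs, and those target proteins are given abundances that
  dominate their neighborhoods — under the mass-action model only a
  source whose free concentration dominates its neighbors' binding can
  propagate a fold-change, so this is what plants a high dynamic score;
* a four-group pooled expression table with planted dysregulation
  (|effect| well above the 0.5 log2 call threshold) and drug reversal
  (reversal fold well above 1.5) for a chosen subset;
* one disease gene set concentrated in the planted modules plus uniform
  decoy sets.

All generators are pure functions of (config, seed): identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParameterError
from .expression import GROUPS, ExpressionTable
from .modules import GeneSet, GeneSetCollection
from .network import PPINetwork, TargetMap, TargetRecord


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth accompanying a generated bundle."""

    planted_dysregulated: dict[str, float]   # mirna -> signed log2 effect
    planted_prmirs: frozenset[str]
    planted_key_mirnas: frozenset[str]
    planted_modules: tuple[frozenset[str], ...]
    planted_disease_genes: frozenset[str]
    rng_seed: int

    def __post_init__(self) -> None:
        if not self.planted_prmirs <= set(self.planted_dysregulated):
            raise ParameterError("planted PRmiRs must be planted dysregulated")
        if not self.planted_key_mirnas <= self.planted_prmirs:
            raise ParameterError("planted key miRNAs must be planted PRmiRs")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_dysregulated": self.planted_dysregulated,
            "planted_prmirs": sorted(self.planted_prmirs),
            "planted_key_mirnas": sorted(self.planted_key_mirnas),
            "planted_modules": [sorted(m) for m in self.planted_modules],
            "planted_disease_genes": sorted(self.planted_disease_genes),
            "rng_seed": self.rng_seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_dysregulated=dict(payload["planted_dysregulated"]),
            planted_prmirs=frozenset(payload["planted_prmirs"]),
            planted_key_mirnas=frozenset(payload["planted_key_mirnas"]),
            planted_modules=tuple(frozenset(m)
                                  for m in payload["planted_modules"]),
            planted_disease_genes=frozenset(payload["planted_disease_genes"]),
            rng_seed=int(payload["rng_seed"]),
        )


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic benchmark.

    The miRNA counts scale the study's proportions (102 detected, 31
    dysregulated, 18 reversed, 3 key players) down to a size that keeps
    every stage exercised; the 500-node network preserves the heavy-tailed
    topology of the STRING-derived networks at desk scale.
    """

    n_mirnas: int = 40
    n_dysregulated: int = 12
    n_prmirs: int = 7
    n_key_mirnas: int = 3
    noise_sd: float = 0.1             # log2 units on every expression value

    n_nodes: int = 500
    attachment: int = 3
    n_modules: int = 3
    module_size: int = 8
    intra_p: float = 0.9

    n_targets_per_mirna: int = 25
    n_hub_targets: int = 15           # hubs targeted by each key miRNA
    validated_fraction: float = 0.4   # of target records
    confident_predicted_fraction: float = 1 / 3   # of predicted records
    abundance_mean_log: float = 2.0   # log-normal parameters, linear scale
    abundance_sigma_log: float = 1.0
    dominant_boost_log: float = 2.5   # key-target abundance shift (natural log)

    n_decoy_sets: int = 10


# ---------------------------------------------------------------------------
# Generators

def make_network(n_nodes: int = 500, attachment: int = 3, seed: int = 0,
                 abundance_mean_log: float = 2.0,
                 abundance_sigma_log: float = 1.0) -> PPINetwork:
    """Scale-free PPI network with confidences and log-normal abundances."""
    if n_nodes < attachment + 1:
        raise ParameterError(f"need n_nodes >= attachment + 1, got "
                             f"{n_nodes} and {attachment}")
    rng = np.random.default_rng(seed)
    graph = nx.barabasi_albert_graph(n_nodes, attachment,
                                     seed=int(rng.integers(2**31)))
    width = len(str(n_nodes - 1))
    net = nx.relabel_nodes(graph, {i: f"G{i:0{width}d}" for i in graph.nodes})
    for a, b in sorted(net.edges):
        net.edges[a, b]["confidence"] = float(rng.uniform(0.7, 1.0))
    for node in sorted(net.nodes):
        net.nodes[node]["abundance"] = float(
            rng.lognormal(abundance_mean_log, abundance_sigma_log))
    return net


def plant_modules(net: PPINetwork, n_modules: int = 3, module_size: int = 8,
                  intra_p: float = 0.9, seed: int = 0,
                  ) -> tuple[PPINetwork, list[frozenset[str]]]:
    """Densify disjoint random node sets into recoverable modules.

    Intra-member edges are added with probability ``intra_p`` at confidence
    drawn uniform [0.7, 1]; existing edges are kept.  Returns a copy of the
    network and the planted member sets.
    """
    if n_modules * module_size > net.number_of_nodes():
        raise ParameterError(f"cannot plant {n_modules} disjoint modules of "
                             f"size {module_size} in a "
                             f"{net.number_of_nodes()}-node network")
    rng = np.random.default_rng(seed)
    net = net.copy()
    chosen = rng.choice(sorted(net.nodes), size=n_modules * module_size,
                        replace=False)
    modules = []
    for k in range(n_modules):
        members = sorted(chosen[k * module_size:(k + 1) * module_size])
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                if rng.random() < intra_p and not net.has_edge(a, b):
                    net.add_edge(a, b, confidence=float(rng.uniform(0.7, 1.0)))
        modules.append(frozenset(members))
    return net, modules


def make_target_map(mirnas: Sequence[str], net: PPINetwork,
                    key_mirnas: Sequence[str], seed: int = 0,
                    planted_modules: Sequence[frozenset[str]] = (),
                    n_targets: int = 25, n_hub_targets: int = 15,
                    validated_fraction: float = 0.4,
                    confident_predicted_fraction: float = 1 / 3,
                    dominant_boost_log: float = 2.5,
                    abundance_mean_log: float = 2.0,
                    ) -> TargetMap:
    """Target map with planted key miRNAs.

    Each key miRNA targets one planted module (cycling through the list),
    the top-degree hubs, and random fill; background miRNAs target
    uniformly.  Key-target proteins are reassigned abundances around
    ``exp(abundance_mean_log + dominant_boost_log)`` so they dominate their
    binding neighborhoods and the perturbation can propagate (high dynamic
    score).  Evidence labels and prediction p-values are drawn so that
    about ``validated_fraction + (1-validated_fraction) *
    confident_predicted_fraction`` of records (~60% at defaults) are
    validated or confidently predicted.
    """
    key_mirnas = list(key_mirnas)
    if not set(key_mirnas) <= set(mirnas):
        raise ParameterError("key miRNAs must be a subset of the miRNA list")
    if n_targets < 1:
        raise ParameterError(f"each miRNA needs at least one target, "
                             f"got n_targets={n_targets}")
    rng = np.random.default_rng(seed)
    nodes = sorted(net.nodes)
    by_degree = sorted(nodes, key=lambda v: (-net.degree[v], v))
    hubs = by_degree[:n_hub_targets]

    entries: dict[str, list[TargetRecord]] = {}
    key_target_union: set[str] = set()
    for i, mirna in enumerate(mirnas):
        if mirna in key_mirnas and planted_modules:
            module = planted_modules[key_mirnas.index(mirna)
                                     % len(planted_modules)]
            picked = list(dict.fromkeys([*sorted(module), *hubs]))
            if len(picked) < n_targets:
                pool = [v for v in nodes if v not in picked]
                fill = rng.choice(pool, size=n_targets - len(picked),
                                  replace=False)
                picked.extend(fill)
            key_target_union.update(picked)
        else:
            picked = list(rng.choice(nodes, size=min(n_targets, len(nodes)),
                                     replace=False))
        records = []
        for gene in picked:
            if rng.random() < validated_fraction:
                records.append(TargetRecord(gene, "validated"))
            elif rng.random() < confident_predicted_fraction:
                records.append(TargetRecord(
                    gene, "predicted", float(rng.uniform(0.0, 0.0099))))
            else:
                records.append(TargetRecord(
                    gene, "predicted", float(rng.uniform(0.01, 1.0))))
        entries[mirna] = records

    # plant regulatory efficiency: key targets dominate their neighborhoods
    for gene in sorted(key_target_union):
        net.nodes[gene]["abundance"] = float(
            rng.lognormal(abundance_mean_log + dominant_boost_log, 0.5))
    return TargetMap(entries)


def make_expression(mirnas: Sequence[str], truth: SyntheticTruth,
                    noise_sd: float = 0.1, seed: int = 0) -> ExpressionTable:
    """Four-group pooled expression table realizing the planted truth.

    Control baselines are N(8, 1); planted dysregulated miRNAs carry their
    signed effect in the disease group; planted reversed miRNAs move back
    toward control in the disease+drug group by at least 0.85 log2 (linear
    fold >= 1.8); everything is jittered with i.i.d. N(0, noise_sd).
    """
    if noise_sd < 0:
        raise ParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    rows = {}
    for mirna in mirnas:
        base = float(rng.normal(8.0, 1.0))
        effect = truth.planted_dysregulated.get(mirna, 0.0)
        if mirna not in truth.planted_dysregulated:
            effect = float(rng.uniform(-0.15, 0.15))
        disease = base + effect
        if mirna in truth.planted_prmirs:
            reversal = float(rng.uniform(0.85, max(abs(effect), 0.851)))
            treated = disease - np.sign(effect) * reversal
        else:
            treated = disease + float(rng.uniform(-0.2, 0.2))
        drug_only = base + float(rng.uniform(-0.3, 0.3))
        noise = rng.normal(0.0, noise_sd, size=4) if noise_sd > 0 else np.zeros(4)
        rows[mirna] = {
            "control": base + noise[0],
            "disease": disease + noise[1],
            "disease_drug": treated + noise[2],
            "drug_only": drug_only + noise[3],
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")[list(GROUPS)]
    frame.index.name = "mirna_id"
    return ExpressionTable(frame)


def make_gene_sets(net: PPINetwork, planted_disease_genes: Sequence[str],
                   n_decoy_sets: int = 10, seed: int = 0) -> GeneSetCollection:
    """One disease set (the planted genes) plus size-matched uniform decoys."""
    planted = sorted(set(planted_disease_genes))
    missing = set(planted) - set(net.nodes)
    if missing:
        raise ParameterError(f"planted disease genes not in network: "
                             f"{sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    collection = GeneSetCollection()
    collection.add(GeneSet("DISEASE", "planted disease-associated genes",
                           frozenset(planted)))
    nodes = sorted(net.nodes)
    for k in range(n_decoy_sets):
        members = rng.choice(nodes, size=len(planted), replace=False)
        collection.add(GeneSet(f"DECOY{k:02d}", "size-matched random decoy",
                               frozenset(members.tolist())))
    return collection


# ---------------------------------------------------------------------------
# Bundle orchestration

@dataclass
class SyntheticBundle:
    """All in-memory inputs for one pipeline run plus the planted truth."""

    config: SyntheticConfig
    seed: int
    expression: ExpressionTable
    network: PPINetwork
    target_map: TargetMap
    gene_sets: GeneSetCollection
    truth: SyntheticTruth

    @property
    def abundance(self) -> dict[str, float]:
        return {v: self.network.nodes[v]["abundance"]
                for v in sorted(self.network.nodes)}


def generate(config: SyntheticConfig = SyntheticConfig(),
             seed: int = 0) -> SyntheticBundle:
    """Generate a full, internally consistent input bundle.

    Sub-generators receive independent child seeds spawned from ``seed``,
    so the bundle is a pure function of (config, seed).
    """
    if not (config.n_key_mirnas <= config.n_prmirs
            <= config.n_dysregulated <= config.n_mirnas):
        raise ParameterError("need n_key <= n_prmirs <= n_dysregulated "
                             "<= n_mirnas")
    child = [int(s.generate_state(1)[0] % (2**31))
             for s in np.random.SeedSequence(seed).spawn(6)]
    rng = np.random.default_rng(child[0])

    width = len(str(config.n_mirnas - 1))
    mirnas = [f"miR-{i:0{width}d}" for i in range(config.n_mirnas)]
    dysregulated = sorted(map(str, rng.choice(mirnas,
                                              size=config.n_dysregulated,
                                              replace=False)))
    prmirs = sorted(map(str, rng.choice(dysregulated, size=config.n_prmirs,
                                        replace=False)))
    keys = sorted(map(str, rng.choice(prmirs, size=config.n_key_mirnas,
                                      replace=False)))
    effects = {m: float(rng.uniform(0.9, 1.4) * rng.choice([-1.0, 1.0]))
               for m in dysregulated}

    net = make_network(config.n_nodes, config.attachment, seed=child[1],
                       abundance_mean_log=config.abundance_mean_log,
                       abundance_sigma_log=config.abundance_sigma_log)
    net, modules = plant_modules(net, config.n_modules, config.module_size,
                                 config.intra_p, seed=child[2])
    target_map = make_target_map(
        mirnas, net, keys, seed=child[3], planted_modules=modules,
        n_targets=config.n_targets_per_mirna,
        n_hub_targets=config.n_hub_targets,
        validated_fraction=config.validated_fraction,
        confident_predicted_fraction=config.confident_predicted_fraction,
        dominant_boost_log=config.dominant_boost_log,
        abundance_mean_log=config.abundance_mean_log)

    disease_genes = sorted(set().union(*modules))
    truth = SyntheticTruth(
        planted_dysregulated=effects,
        planted_prmirs=frozenset(prmirs),
        planted_key_mirnas=frozenset(keys),
        planted_modules=tuple(modules),
        planted_disease_genes=frozenset(disease_genes),
        rng_seed=seed,
    )
    table = make_expression(mirnas, truth, noise_sd=config.noise_sd,
                            seed=child[4])
    gene_sets = make_gene_sets(net, disease_genes,
                               n_decoy_sets=config.n_decoy_sets,
                               seed=child[5])
    return SyntheticBundle(config, seed, table, net, target_map, gene_sets,
                           truth)


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle as the pipeline's file formats; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "edges": out / "ppi_edges.tsv",
        "targets": out / "targets.tsv",
        "abundance": out / "abundance.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "truth": out / "truth.json",
        "metadata": out / "metadata.json",
    }
    bundle.expression.write_tsv(paths["expression"])
    with open(paths["edges"], "w") as handle:
        handle.write("protein_a\tprotein_b\tcombined_score\n")
        for a, b in sorted(bundle.network.edges):
            conf = bundle.network.edges[a, b]["confidence"]
            handle.write(f"{a}\t{b}\t{conf:.6f}\n")
    bundle.target_map.write_tsv(paths["targets"])
    with open(paths["abundance"], "w") as handle:
        handle.write("gene_id\tabundance\n")
        for gene, value in bundle.abundance.items():
            handle.write(f"{gene}\t{value:.6f}\n")
    bundle.gene_sets.write_gmt(paths["gene_sets"])
    bundle.truth.to_json(paths["truth"])
    paths["metadata"].write_text(json.dumps(
        {"seed": bundle.seed, "config": dataclasses.asdict(bundle.config)},
        indent=2, sort_keys=True))
    return paths
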