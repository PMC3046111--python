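"""Mass-action equilibrium perturbation of a weighted PPI network.

The dynamic score measures a miRNA's *regulatory efficiency*: how far a
concentration change imposed on its target proteins propagates through the
binding network before the network's robustness absorbs it.

Model.  Every retained PPI edge (i, j) is a reversible dimerization
``P_i + P_j <-> C_ij`` with one global association constant K (uniform
affinity; no per-edge affinities are available).  At equilibrium

    complex_ij = K * free_i * free_j
    free_i + sum_{j in N(i)} complex_ij = total_i,

so the free concentrations satisfy the fixed point

    free_i = total_i / (1 + K * sum_{j in N(i)} free_j),

solved by damped fixed-point iteration (deterministic; no randomness).

Perturbation.  The totals of a miRNA's in-network target proteins are
multiplied by a fold factor (default 0.5 for an over-expressed miRNA — more
miRNA, less protein — and 2.0 for an under-expressed one), the network is
re-equilibrated, and each non-source node's response is the fold change of
its free concentration, ``max(f'/f, f/f') >= 1``.  The *perturbed subgroup
size* at threshold t counts non-source nodes with response >= t; the dynamic
score is the ratio of subgroup sizes at the upper and lower thresholds
(defaults 2.0 and 1.2), i.e. the fraction of perturbed nodes that are
strongly perturbed.  It lies in [0, 1] and is 0 when nothing is perturbed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .errors import ConvergenceError, InputError, ParameterError, UndefinedResultError
from .network import PPINetwork

DEFAULT_ASSOCIATION_CONSTANT = 1.0
DEFAULT_TOLERANCE = 1e-10
DEFAULT_MAX_ITER = 10000
DEFAULT_DAMPING = 0.5
DEFAULT_FOLD_OVER = 0.5    # source fold for an over-expressed miRNA
DEFAULT_FOLD_UNDER = 2.0   # source fold for an under-expressed miRNA
DEFAULT_SUBGROUP_THRESHOLDS = (1.2, 2.0)
ABUNDANCE_FLOOR = 1e-6


@dataclass(frozen=True)
class EquilibriumState:
    """Converged equilibrium: free concentrations, complexes, diagnostics."""

    free: dict[str, float]
    complex: dict[tuple[str, str], float]
    residual: float       # max relative mass-balance violation
    iterations: int


@dataclass(frozen=True)
class PerturbationResult:
    """Response of the network to a source perturbation."""

    source_nodes: frozenset[str]
    response: dict[str, float]          # non-source node -> fold change >= 1
    subgroup_sizes: dict[float, int]    # threshold -> count
    dynamic_score: float
    fold: float = 1.0


def _adjacency(net: PPINetwork) -> tuple[list[str], sparse.csr_matrix, np.ndarray]:
    nodes = sorted(net.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    totals = np.empty(len(nodes))
    for v, i in index.items():
        t = net.nodes[v].get("abundance")
        if t is None:
            raise InputError(f"node {v!r} has no abundance attribute")
        if t < 0:
            raise InputError(f"negative abundance for node {v!r}: {t}")
        totals[i] = t
    rows, cols = [], []
    for a, b in net.edges:
        rows += [index[a], index[b]]
        cols += [index[b], index[a]]
    adj = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)),
                            shape=(len(nodes), len(nodes)))
    return nodes, adj, totals


def _solve(adj: sparse.csr_matrix, totals: np.ndarray, K: float,
           tol: float, max_iter: int, damping: float,
           warm_start: np.ndarray | None = None) -> tuple[np.ndarray, float, int]:
    """Damped fixed-point iteration on the free-concentration vector."""
    free = totals.copy() if warm_start is None else warm_start.copy()
    scale = np.maximum(totals, ABUNDANCE_FLOOR)
    residual = np.inf
    for iteration in range(1, max_iter + 1):
        bound = adj @ free
        target = totals / (1.0 + K * bound)
        free = (1.0 - damping) * free + damping * target
        # mass balance: free_i * (1 + K * sum_j free_j) == total_i
        residual = float(np.max(np.abs(free * (1.0 + K * (adj @ free)) - totals)
                                / scale))
        if residual < tol:
            return free, residual, iteration
    raise ConvergenceError(
        f"equilibrium solver did not reach tol={tol} after {max_iter} "
        f"iterations (residual {residual:.3e})",
        residual=residual, iterations=max_iter)


def equilibrate(net: PPINetwork, K: float = DEFAULT_ASSOCIATION_CONSTANT,
                tol: float = DEFAULT_TOLERANCE,
                max_iter: int = DEFAULT_MAX_ITER,
                damping: float = DEFAULT_DAMPING) -> EquilibriumState:
    """Solve the binding equilibrium on a network with abundances attached."""
    if K < 0:
        raise ParameterError(f"association constant must be >= 0, got {K}")
    nodes, adj, totals = _adjacency(net)
    free, residual, iterations = _solve(adj, totals, K, tol, max_iter, damping)
    free_map = dict(zip(nodes, free.tolist()))
    complexes = {(a, b): K * free_map[a] * free_map[b] for a, b in net.edges}
    return EquilibriumState(free_map, complexes, residual, iterations)


def _responses(free_before: np.ndarray, free_after: np.ndarray,
               eps: float = 0.0) -> np.ndarray:
    """Fold change max(f'/f, f/f') per node, 1 where both are 0."""
    both_zero = (free_before <= eps) & (free_after <= eps)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(both_zero, 1.0, free_after / free_before)
        inv = np.where(both_zero, 1.0, free_before / free_after)
    return np.maximum(ratio, inv)


def perturb(net: PPINetwork, baseline: EquilibriumState,
            sources: Iterable[str], fold: float = DEFAULT_FOLD_OVER,
            K: float = DEFAULT_ASSOCIATION_CONSTANT,
            tol: float = DEFAULT_TOLERANCE,
            max_iter: int = DEFAULT_MAX_ITER,
            damping: float = DEFAULT_DAMPING,
            thresholds: Sequence[float] = DEFAULT_SUBGROUP_THRESHOLDS,
            include_sources: bool = False) -> PerturbationResult:
    """Multiply source totals by ``fold``, re-equilibrate, score responses.

    Sources are by default excluded from subgroup counting so the score
    measures propagation, not the imposed change itself.
    """
    sources = frozenset(sources)
    if not sources:
        raise ParameterError("empty perturbation source set")
    unknown = sources - set(net.nodes)
    if unknown:
        raise ParameterError(f"source nodes not in network: "
                             f"{sorted(unknown)[:5]}")
    if fold <= 0:
        raise ParameterError(f"perturbation fold must be > 0, got {fold}")

    nodes, adj, totals = _adjacency(net)
    index = {v: i for i, v in enumerate(nodes)}
    free_before = np.array([baseline.free[v] for v in nodes])
    totals_after = totals.copy()
    for s in sources:
        totals_after[index[s]] *= fold
    free_after, _, _ = _solve(adj, totals_after, K, tol, max_iter, damping,
                              warm_start=free_before)
    resp = _responses(free_before, free_after)
    counted = [v for v in nodes if include_sources or v not in sources]
    response = {v: float(resp[index[v]]) for v in counted}
    sizes = {float(t): perturbed_subgroup_size(response, t) for t in thresholds}
    return PerturbationResult(sources, response, sizes,
                              dynamic_score_from_sizes(sizes), fold)


def perturbed_subgroup_size(responses: Mapping[str, float] | Sequence[float],
                            threshold: float) -> int:
    """Count responses at or above a fold-change threshold (>= 1)."""
    if threshold < 1:
        raise ParameterError(f"subgroup threshold must be >= 1, "
                             f"got {threshold}")
    values = (responses.values() if isinstance(responses, Mapping)
              else responses)
    return sum(1 for r in values if r >= threshold)


def dynamic_score_from_sizes(sizes: Mapping[float, int],
                             upper: float = 2.0, lower: float = 1.2) -> float:
    """size(upper) / size(lower); 0 by convention when the denominator is 0."""
    denom = sizes[lower]
    return sizes[upper] / denom if denom else 0.0


def dynamic_score(result: PerturbationResult,
                  upper: float = 2.0, lower: float = 1.2) -> float:
    return dynamic_score_from_sizes(result.subgroup_sizes, upper, lower)


@dataclass(frozen=True)
class MiRNAPerturbationRecord:
    """Dynamic score and target-abundance summary for one miRNA."""

    mirna_id: str
    n_targets_in_network: int
    fold: float
    dynamic_score: float | None          # None when no in-network target
    subgroup_sizes: dict[float, int] = field(default_factory=dict)
    mean_log2_target_abundance: float | None = None
    solver_iterations: int = 0


def score_all_mirnas(net: PPINetwork, target_map,
                     directions: Mapping[str, str] | None = None,
                     K: float = DEFAULT_ASSOCIATION_CONSTANT,
                     fold_over: float = DEFAULT_FOLD_OVER,
                     fold_under: float = DEFAULT_FOLD_UNDER,
                     thresholds: Sequence[float] = DEFAULT_SUBGROUP_THRESHOLDS,
                     tol: float = DEFAULT_TOLERANCE,
                     max_iter: int = DEFAULT_MAX_ITER,
                     mirnas: Sequence[str] | None = None,
                     ) -> list[MiRNAPerturbationRecord]:
    """Perturb each miRNA's in-network targets and collect dynamic scores.

    ``directions`` maps miRNA to its disease direction ('up' or 'down'); an
    up-regulated miRNA suppresses its targets (``fold_over``), a
    down-regulated one releases them (``fold_under``).  Unlisted miRNAs use
    ``fold_over``.  A miRNA with no in-network target gets an undefined
    record (``dynamic_score=None``).
    """
    baseline = equilibrate(net, K=K, tol=tol, max_iter=max_iter)
    records = []
    for mirna in (mirnas if mirnas is not None else target_map.mirnas):
        targets = sorted(t for t in target_map.genes(mirna) if t in net)
        if not targets:
            records.append(MiRNAPerturbationRecord(mirna, 0, float("nan"),
                                                   None))
            continue
        direction = (directions or {}).get(mirna, "up")
        fold = fold_under if direction == "down" else fold_over
        result = perturb(net, baseline, targets, fold=fold, K=K, tol=tol,
                         max_iter=max_iter, thresholds=thresholds)
        abundances = np.array([net.nodes[t]["abundance"] for t in targets])
        records.append(MiRNAPerturbationRecord(
            mirna_id=mirna,
            n_targets_in_network=len(targets),
            fold=fold,
            dynamic_score=result.dynamic_score,
            subgroup_sizes=dict(result.subgroup_sizes),
            mean_log2_target_abundance=float(np.mean(np.log2(abundances))),
        ))
    return records


def correlate(scores: Mapping[str, float], covariate: Mapping[str, float],
              ) -> tuple[float, float, int]:
    """Pearson r and two-sided t-test p between paired per-miRNA values.

    Pairs with an undefined (None/NaN) entry on either side are dropped;
    returns ``(r, p, n_used)``.  Raises on fewer than 3 defined pairs.
    """
    keys = [k for k in scores
            if k in covariate
            and scores[k] is not None and covariate[k] is not None
            and np.isfinite(scores[k]) and np.isfinite(covariate[k])]
    if len(keys) < 3:
        raise UndefinedResultError(
            f"correlation needs >= 3 defined pairs, got {len(keys)}")
    x = np.array([scores[k] for k in keys], dtype=float)
    y = np.array([covariate[k] for k in keys], dtype=float)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), len(keys)


def perturbation_records_to_frame(records: Sequence[MiRNAPerturbationRecord],
                                  ) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "mirna_id": r.mirna_id,
            "n_targets_in_network": r.n_targets_in_network,
            "fold": r.fold,
            "dynamic_score": (np.nan if r.dynamic_score is None
                              else r.dynamic_score),
            "mean_log2_target_abundance":
                (np.nan if r.mean_log2_target_abundance is None
                 else r.mean_log2_target_abundance),
        }
        for threshold, size in sorted(r.subgroup_sizes.items()):
            row[f"subgroup_size_{threshold:g}"] = size
        rows.append(row)
    return pd.DataFrame(rows).set_index("mirna_id")
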