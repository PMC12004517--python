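"""Self-consistency diagnostics over directional ΔΔG networks.

For a converged, thermodynamically consistent set of estimates the sum
of the two directions of a pair (hysteresis) and the sum of edges around
any closed cycle (cycle closure) are both zero; their residuals measure
the statistical quality of a free-energy network.

Cycle-counting convention: cycles are identified up to rotation of the
starting node but the two orientations of a cycle are counted as
distinct — for four ligands this yields 8 cycles of length 3 and 6 of
length 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
from scipy.stats import pearsonr

from .model import FreeEnergyNetwork, ValidationError


def hysteresis(ddg_ab: float, ddg_ba: float) -> float:
    """Sum of the two directional estimates of one pair."""
    return ddg_ab + ddg_ba


def enumerate_cycles(nodes, length: int) -> list[tuple[str, ...]]:
    """All directed cycles of the given length over a complete
    bidirectional graph on ``nodes``, up to rotation (both orientations
    kept)."""
    if length not in (3, 4):
        raise ValidationError(f"cycle length {length} unsupported (use 3 or 4)")
    nodes = list(nodes)
    if len(nodes) < length:
        return []
    graph = nx.complete_graph(nodes, create_using=nx.DiGraph)
    return [
        tuple(c) for c in nx.simple_cycles(graph, length_bound=length)
        if len(c) == length
    ]


def cycle_closure(network: FreeEnergyNetwork, cycle) -> float:
    """Sum of directed ΔΔG edges around the cycle, kcal/mol."""
    cycle = list(cycle)
    total = 0.0
    for a, b in zip(cycle, cycle[1:] + cycle[:1]):
        total += network.ddg(a, b)
    return total


@dataclass
class NetworkReport:
    n_nodes: int
    n_pairs: int
    mean_abs_hysteresis: float
    max_abs_hysteresis: float
    max_hysteresis_pair: tuple[str, str] | None
    mean_abs_closure: dict[int, float] = field(default_factory=dict)
    cycle_counts: dict[int, int] = field(default_factory=dict)
    rmsd_vs_comparison: float | None = None
    pearson_vs_comparison: float | None = None

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_pairs": self.n_pairs,
            "mean_abs_hysteresis": self.mean_abs_hysteresis,
            "max_abs_hysteresis": self.max_abs_hysteresis,
            "max_hysteresis_pair": (
                list(self.max_hysteresis_pair) if self.max_hysteresis_pair else None
            ),
            "mean_abs_closure": {str(k): v for k, v in self.mean_abs_closure.items()},
            "cycle_counts": {str(k): v for k, v in self.cycle_counts.items()},
            "rmsd_vs_comparison": self.rmsd_vs_comparison,
            "pearson_vs_comparison": self.pearson_vs_comparison,
        }


def network_summary(
    network: FreeEnergyNetwork,
    comparison: FreeEnergyNetwork | None = None,
    cycle_lengths: tuple[int, ...] = (3, 4),
) -> NetworkReport:
    """Hysteresis and cycle-closure summary of a directional network.

    Hysteresis statistics run over the unordered pairs with both
    directions present; closure statistics over all cycles of the
    requested lengths whose directed edges all exist.  When a comparison
    network is given, the RMSD and Pearson correlation over the shared
    directed edges are included.  No rounding is applied internally.
    """
    nodes = network.nodes
    pairs = [
        (a, b)
        for a, b in combinations(nodes, 2)
        if network.has_edge(a, b) and network.has_edge(b, a)
    ]
    if not pairs:
        import warnings

        warnings.warn("no bidirectional pair in the network; empty report")
        return NetworkReport(
            n_nodes=len(nodes),
            n_pairs=0,
            mean_abs_hysteresis=float("nan"),
            max_abs_hysteresis=float("nan"),
            max_hysteresis_pair=None,
        )
    h = {
        (a, b): hysteresis(network.ddg(a, b), network.ddg(b, a)) for a, b in pairs
    }
    abs_h = {p: abs(v) for p, v in h.items()}
    max_pair = max(abs_h, key=abs_h.get)
    mean_closure: dict[int, float] = {}
    counts: dict[int, int] = {}
    for length in cycle_lengths:
        closures = []
        for cycle in enumerate_cycles(nodes, length):
            edges = list(zip(cycle, cycle[1:] + cycle[:1]))
            if all(network.has_edge(a, b) for a, b in edges):
                closures.append(abs(cycle_closure(network, cycle)))
        if closures:
            mean_closure[length] = float(np.mean(closures))
            counts[length] = len(closures)
    rmsd = corr = None
    if comparison is not None:
        shared = [e for e in network.edges if e in comparison.edges]
        if len(shared) >= 2:
            x = np.array([network.edges[e][0] for e in shared])
            y = np.array([comparison.edges[e][0] for e in shared])
            rmsd = float(np.sqrt(np.mean((x - y) ** 2)))
            corr = float(pearsonr(x, y)[0]) if np.std(x) > 0 and np.std(y) > 0 else 1.0
    return NetworkReport(
        n_nodes=len(nodes),
        n_pairs=len(pairs),
        mean_abs_hysteresis=float(np.mean(list(abs_h.values()))),
        max_abs_hysteresis=float(abs_h[max_pair]),
        max_hysteresis_pair=max_pair,
        mean_abs_closure=mean_closure,
        cycle_counts=counts,
        rmsd_vs_comparison=rmsd,
        pearson_vs_comparison=corr,
    )
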