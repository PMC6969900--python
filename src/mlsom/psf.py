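"""Pathway Signal Flow: propagate fold changes from pathway inputs to sinks.

Each input node starts with its own linear fold change. A node's signal is
its fold change times the product of its parents' contributions, where an
activating edge contributes the parent's signal S and an inhibiting edge
contributes 1/S. Sink-node signals summarize overall pathway activity.
Multi-parent aggregation by product is the minimal consistent extension of
the pairwise multiply/reduce rule and is recorded in the result metadata;
a mean-aggregation variant is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .datamodel import PathwayGraph, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PSFResult:
    """Per-node signals (linear fold-change scale) and the sink summary."""

    node_signal: dict[str, float]
    sink_values: dict[str, float]
    converged: bool = True
    aggregation: str = "product"

    def __post_init__(self) -> None:
        if any(s <= 0 or not np.isfinite(s) for s in self.node_signal.values()):
            raise ValidationError("signals must be positive and finite")


def _contribution(parent_signal: float, sign: str) -> float:
    return parent_signal if sign == "activation" else 1.0 / parent_signal


def _node_update(graph: nx.DiGraph, node: str,
                 signal: dict[str, float], aggregation: str) -> float:
    parents = list(graph.predecessors(node))
    fc = graph.nodes[node]["fc"]
    if not parents:
        return fc
    contribs = [_contribution(signal[p], graph.edges[p, node]["sign"])
                for p in parents]
    if aggregation == "product":
        return fc * float(np.prod(contribs))
    if aggregation == "mean":
        return fc * float(np.mean(contribs))
    raise ValidationError(f"unknown aggregation {aggregation!r}")


def propagate(pathway: PathwayGraph, aggregation: str = "product",
              tol: float = 1e-6, max_iter: int = 100,
              damping: float = 0.5) -> PSFResult:
    """Evaluate signal flow over the pathway.

    Acyclic graphs are evaluated in one topological pass. Cyclic graphs are
    iterated from the node-fold-change initialization with damped updates in
    log space (geometric interpolation between the old and the recomputed
    signal; undamped sweeps oscillate on negative feedback loops) until the
    maximum absolute log-signal change drops below ``tol`` (or ``max_iter``
    sweeps, then the last state is reported with a warning).
    """
    g = pathway.graph
    if not pathway.input_nodes:
        raise ValidationError("pathway has no input nodes (fully cyclic)")
    signal: dict[str, float] = {n: g.nodes[n]["fc"] for n in g.nodes}
    converged = True
    if nx.is_directed_acyclic_graph(g):
        for node in nx.topological_sort(g):
            signal[node] = _node_update(g, node, signal, aggregation)
    else:
        order = sorted(g.nodes)
        converged = False
        for _ in range(max_iter):
            delta = 0.0
            for node in order:
                target = _node_update(g, node, signal, aggregation)
                step = damping * (np.log(target) - np.log(signal[node]))
                new = float(signal[node] * np.exp(step))
                delta = max(delta, abs(np.log(new) - np.log(signal[node])))
                signal[node] = new
            if delta < tol * damping:
                converged = True
                break
        if not converged:
            logger.warning("PSF iteration did not converge within %d sweeps "
                           "(last max log-change %.2e)", max_iter, delta)
    sinks = {n: signal[n] for n in pathway.sink_nodes}
    return PSFResult(node_signal=signal, sink_values=sinks,
                     converged=converged, aggregation=aggregation)
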