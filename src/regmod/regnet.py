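"""Generic regulator -> target network with per-source evidence weights.

The network is consumed as a weighted edge list distilled from ChIP/motif
resources.  Each (regulator, target) pair may be reported by several
sources; the aggregated edge score ``es`` is the sum of the per-source
weights, so evidence from independent resources accumulates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["RegulatoryNetwork", "read_network", "write_sif", "write_graphml"]


@dataclass
class RegulatoryNetwork:
    """Directed weighted TF -> target edges with aggregated edge scores."""

    edges: pd.DataFrame  # columns: regulator, target, source, weight
    es: dict[tuple[str, str], float] = field(default_factory=dict)
    _targets: dict[str, list[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if (self.edges["weight"] < 0).any():
            bad = self.edges.loc[self.edges["weight"] < 0]
            raise ValueError(f"negative edge weights:\n{bad}")
        self_edges = self.edges[self.edges["regulator"] == self.edges["target"]]
        if len(self_edges):
            logger.warning("network contains %d self-edges", len(self_edges))
        if not self.es:
            agg = self.edges.groupby(["regulator", "target"], sort=False)["weight"].sum()
            self.es = {pair: float(w) for pair, w in agg.items()}
        if not self._targets:
            for (r, t) in self.es:
                self._targets.setdefault(r, []).append(t)

    def edge_score(self, regulator: str, target: str) -> float:
        """Aggregated score for the directed pair; 0 when no source reports it."""
        return self.es.get((regulator, target), 0.0)

    def regulators(self) -> list[str]:
        return sorted(self._targets)

    def regulators_of(self, gene: str) -> list[str]:
        """All regulators with an edge onto ``gene``."""
        return sorted(r for (r, t) in self.es if t == gene)


def targets_of(
    net: RegulatoryNetwork, regulator: str, exclude: str | None = None
) -> list[tuple[str, float]]:
    """All targets of ``regulator`` with es > 0, minus ``exclude``.

    An unknown regulator yields an empty list (logged), not an error: absent
    evidence simply means the regulator has no usable activity.
    """
    if regulator not in net._targets:
        logger.info("regulator %r absent from network; no targets", regulator)
        return []
    return [
        (t, net.es[(regulator, t)])
        for t in net._targets[regulator]
        if t != exclude and net.es[(regulator, t)] > 0
    ]


def read_network(path: str | Path) -> RegulatoryNetwork:
    """Read a TSV with columns regulator, target, source, weight."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str, 2: str}, comment="#")
    expected = ["regulator", "target", "source", "weight"]
    if list(df.columns[:4]) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    df["weight"] = df["weight"].astype(float)
    return RegulatoryNetwork(df[expected])


def _as_graph(net: RegulatoryNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    for (r, t), w in net.es.items():
        g.add_edge(r, t, es=w)
    return g


def write_sif(net: RegulatoryNetwork, path: str | Path) -> None:
    """Simple-interaction-format export (regulator  regulates  target)."""
    with open(path, "w") as fh:
        for (r, t), w in sorted(net.es.items()):
            fh.write(f"{r}\tregulates\t{t}\n")


def write_graphml(net: RegulatoryNetwork, path: str | Path) -> None:
    nx.write_graphml(_as_graph(net), path)
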