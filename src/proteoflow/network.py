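"""Protein–protein interaction networks from local STRING-style edge lists.

A STRING protein-links file is whitespace-separated with columns
``protein1 protein2 combined_score`` (score on the 0–1000 confidence
scale).  Identifiers may carry a numeric species prefix (``9606.P04637``),
which is stripped, and matching is case-insensitive.  The graph is
undirected with no self-loops; an edge listed in both orientations keeps
the maximum score.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import networkx as nx

__all__ = ["load_network", "induced_subnetwork", "NetworkGraph"]

NetworkGraph = nx.Graph

_SPECIES_PREFIX = re.compile(r"^\d+\.")


def _norm(identifier: str) -> str:
    return _SPECIES_PREFIX.sub("", identifier).upper()


def load_network(path: str | Path, score_threshold: int = 400) -> nx.Graph:
    """Read a scored edge list, dropping edges below ``score_threshold``.

    Duplicate pairs (either orientation) are merged keeping the maximum
    score; self-loops are discarded.  Malformed lines raise with the line
    number.  A header line starting with 'protein1' is tolerated.
    """
    g = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if lineno == 1 and fields[0].lower() in ("protein1", "#protein1", "node1"):
                continue
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 'protein1 protein2 combined_score'")
            a, b = _norm(fields[0]), _norm(fields[1])
            try:
                score = int(float(fields[2]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad combined_score {fields[2]!r}") from exc
            if not 0 <= score <= 1000:
                raise ValueError(f"{path}:{lineno}: combined_score {score} outside 0..1000")
            if a == b:
                continue
            if score < score_threshold:
                continue
            if g.has_edge(a, b):
                g[a][b]["combined_score"] = max(g[a][b]["combined_score"], score)
            else:
                g.add_edge(a, b, combined_score=score)
    return g


def induced_subnetwork(g: nx.Graph, genes: Iterable[str]) -> nx.Graph:
    """Subgraph induced by a protein/gene list (case-insensitive match).

    Queried nodes present in the network but isolated within the selection
    are retained with degree 0; identifiers absent from the network are
    dropped silently (they simply have no known interactions).
    """
    wanted = {_norm(x) for x in genes}
    nodes = [n for n in g.nodes if n in wanted]
    return g.subgraph(nodes).copy()
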