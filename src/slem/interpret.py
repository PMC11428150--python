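"""Per-SNP impact scores and mediator-module extraction.

The impact of a SNP on the disease output is computed under the network's
linearization: each node's output is taken to be its outgoing weight times
the sum of its active inputs (activation functions deliberately ignored).
Under that additivity the total influence of a SNP equals the sum over all
unmasked paths SNP -> isoform -> marker -> phenotype -> disease of the
product of edge weights along the path, in absolute value — which is exactly
a row of the masked weight-matrix product |W1 W2 W3 w4|.  Both routes are
implemented; the path enumeration doubles as an independent check of the
matrix form.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .archinit import SlemModel
from .exceptions import InvalidArgumentError

__all__ = [
    "ImpactScoreTable",
    "MediatorModule",
    "impact_scores_paths",
    "impact_scores_matrix",
    "top_snps",
    "extract_module",
]


@dataclass
class ImpactScoreTable:
    """Non-negative per-SNP impact scores with a deterministic ranking."""

    scores: pd.Series  # index: SNP labels, values >= 0

    def __post_init__(self):
        self.scores = self.scores.astype(float)

    @property
    def ranking(self) -> list[str]:
        """SNP labels by descending score; ties break lexicographically."""
        order = sorted(self.scores.index, key=lambda s: (-self.scores[s], s))
        return order

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"snp": self.ranking})
        df["score"] = self.scores[df["snp"]].to_numpy()
        df["rank"] = np.arange(1, len(df) + 1)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def impact_scores_matrix(model: SlemModel) -> ImpactScoreTable:
    """|row of (W1*M1)(W2*M2)(W3*M3)(w4*m4)| per SNP."""
    W = model.masked_weights()
    v = W[0] @ W[1] @ W[2] @ W[3]
    return ImpactScoreTable(
        pd.Series(np.abs(v.ravel()), index=list(model.architecture.layer("snp")))
    )


def impact_scores_paths(model: SlemModel) -> ImpactScoreTable:
    """Explicit enumeration of every unmasked path to the disease node.

    For each SNP, sums the product of edge weights over all paths through
    surviving edges and takes the absolute value.  A SNP with no surviving
    path scores 0.  Agrees with :func:`impact_scores_matrix` to floating
    tolerance; kept as the independent route.
    """
    W = model.masked_weights()
    adj = []  # adjacency: adj[layer][i] = list of (j, weight)
    for Wl in W:
        layer_adj = {}
        rows, cols = np.nonzero(Wl)
        for i, j in zip(rows, cols):
            layer_adj.setdefault(int(i), []).append((int(j), float(Wl[i, j])))
        adj.append(layer_adj)

    snps = list(model.architecture.layer("snp"))
    totals = np.zeros(len(snps))
    for si in range(len(snps)):
        total = 0.0
        for i1, w1 in adj[0].get(si, ()):
            for i2, w2 in adj[1].get(i1, ()):
                for i3, w3 in adj[2].get(i2, ()):
                    for _, w4 in adj[3].get(i3, ()):
                        total += w1 * w2 * w3 * w4
        totals[si] = abs(total)
    return ImpactScoreTable(pd.Series(totals, index=snps))


def top_snps(table: ImpactScoreTable, k: int = 5) -> list[str]:
    """The k highest-impact SNP labels (ties lexicographic)."""
    if k <= 0:
        raise InvalidArgumentError("k must be positive")
    if k > len(table.scores):
        raise InvalidArgumentError("k exceeds the number of SNPs")
    return table.ranking[:k]


@dataclass
class MediatorModule:
    """The strong-edge subnetwork feeding chosen phenotype nodes.

    Every retained node lies on a retained directed path into an anchor;
    edges are (source label, target label, weight) triples.
    """

    nodes: dict[str, list[str]]  # layer name -> retained labels
    edges: list[tuple[str, str, float]]
    anchors: list[str]

    def to_dict(self) -> dict:
        return {
            "anchors": self.anchors,
            "nodes": self.nodes,
            "edges": [[s, t, w] for s, t, w in self.edges],
        }

    def to_edge_list(self, path: str | Path) -> None:
        """Tab-separated source/target/weight export for graph viewers."""
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for s, t, w in self.edges:
                fh.write(f"{s}\t{t}\t{w!r}\n")


def extract_module(
    model: SlemModel,
    anchor_phenotypes: list[str],
    weight_fraction: float = 0.10,
) -> MediatorModule:
    """Project the trained network onto anchor phenotype nodes.

    Keeps the top ``weight_fraction`` of |weights| globally over all unmasked
    edges of the model, then retains exactly the nodes and edges with a
    surviving directed path into one of the anchors.
    """
    if not 0 < weight_fraction <= 1:
        raise InvalidArgumentError("weight_fraction must lie in (0, 1]")
    phen = set(model.architecture.layer("phenotype"))
    unknown = [a for a in anchor_phenotypes if a not in phen]
    if unknown:
        raise KeyError(f"unknown anchor phenotype labels: {unknown}")

    layer_names = ("snp", "isoform", "marker", "phenotype", "disease")
    labels = [list(model.architecture.layer(n)) for n in layer_names]
    W = model.masked_weights()

    mags = np.concatenate([np.abs(Wl[model.masks[i] > 0]) for i, Wl in enumerate(W)])
    if mags.size == 0:
        return MediatorModule({n: [] for n in layer_names}, [], list(anchor_phenotypes))
    k = max(1, int(np.ceil(weight_fraction * mags.size)))
    threshold = np.sort(mags)[::-1][k - 1]

    g = nx.DiGraph()
    for li, Wl in enumerate(W[:3]):  # anchors sit in the phenotype layer
        rows, cols = np.nonzero(model.masks[li])
        for i, j in zip(rows, cols):
            if abs(Wl[i, j]) >= threshold and Wl[i, j] != 0:
                g.add_edge(labels[li][i], labels[li + 1][j], weight=float(Wl[i, j]))

    reach = set()
    for a in anchor_phenotypes:
        if a in g:
            reach |= nx.ancestors(g, a)
        reach.add(a)
    sub = g.subgraph(reach)
    edges = sorted(
        ((s, t, d["weight"]) for s, t, d in sub.edges(data=True)), key=lambda e: (e[0], e[1])
    )
    kept_nodes = {n for s, t, _ in edges for n in (s, t)} | set(anchor_phenotypes)
    nodes = {
        name: [lbl for lbl in labels[i] if lbl in kept_nodes]
        for i, name in enumerate(layer_names)
    }
    return MediatorModule(nodes=nodes, edges=edges, anchors=list(anchor_phenotypes))
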