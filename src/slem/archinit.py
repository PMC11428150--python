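"""Assembly of the sparse labelled network from association tables.

The five-layer architecture (SNPs → isoforms → markers → phenotypes →
disease) is derived from data, not from an ontology: intermediate nodes are
the features significantly associated with the input SNPs (FDR thresholds
0.1 / 0.05 / 0.05 by default), and edges between adjacent layers start from
weights obtained by mapping each pair's association p-value onto the Xavier
normal scale,

    w = sign * sigma * Phi^-1(1 - p/2),     sigma = sqrt(2 / (fan_in + fan_out)),

so that for uniformly distributed p the |w| population follows the
half-normal with the Xavier scale, and smaller p always means a stronger
edge.  Pairs whose nominal p fails a significance cutoff are zeroed, then
only the top fraction (default 35%) of surviving |w| per layer is kept; the
rest are masked to exactly zero and stay zero through training.  The final
phenotype→disease edges carry no association information and are drawn fresh
from the Xavier normal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import special, stats

from .assoc import AssociationTable
from .exceptions import ArchitectureError, InvalidArgumentError

__all__ = [
    "LayerArchitecture",
    "BuildConfig",
    "SlemModel",
    "select_nodes",
    "xavier_sigma",
    "pvalue_to_weight",
    "weight_to_pvalue",
    "mask_top_fraction",
    "build_model",
]

LAYER_NAMES = ("snp", "isoform", "marker", "phenotype", "disease")


@dataclass(frozen=True)
class LayerArchitecture:
    """Ordered node labels for the five layers plus the selection thresholds."""

    layer_nodes: tuple[tuple[str, ...], ...]
    selection_thresholds: tuple[float, float, float] = (0.1, 0.05, 0.05)

    def __post_init__(self):
        if len(self.layer_nodes) != 5:
            raise ArchitectureError("exactly 5 layers are required")
        if len(self.layer_nodes[-1]) != 1:
            raise ArchitectureError("the disease layer must have exactly 1 node")
        for name, nodes in zip(LAYER_NAMES, self.layer_nodes):
            if len(set(nodes)) != len(nodes):
                raise ArchitectureError(f"duplicate labels in {name} layer")

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(nodes) for nodes in self.layer_nodes)

    def layer(self, name: str) -> tuple[str, ...]:
        return self.layer_nodes[LAYER_NAMES.index(name)]


@dataclass(frozen=True)
class BuildConfig:
    """Thresholds controlling node selection and edge initialization."""

    fdr_thresholds: tuple[float, float, float] = (0.1, 0.05, 0.05)
    significance_cutoff: float = 0.05  # nominal-p zeroing before masking
    keep_fraction: float = 0.35
    seed: int = 0

    def __post_init__(self):
        for t in (*self.fdr_thresholds, self.significance_cutoff):
            if not 0 < t < 1:
                raise InvalidArgumentError("thresholds must lie in (0, 1)")
        if not 0 < self.keep_fraction <= 1:
            raise InvalidArgumentError("keep_fraction must lie in (0, 1]")


def select_nodes(table: AssociationTable, q_threshold: float) -> list[str]:
    """Targets whose best (minimum over sources) q-value beats the threshold.

    Order is the stable order of first appearance in the table; labels are
    deduplicated.  An empty table yields an empty list with a warning.
    """
    if not 0 < q_threshold < 1:
        raise InvalidArgumentError("q_threshold must lie in (0, 1)")
    if len(table) == 0:
        warnings.warn("empty association table: no nodes selected", stacklevel=2)
        return []
    min_q = table.min_q_per_target()
    return [t for t in table.targets if min_q[t] < q_threshold]


def xavier_sigma(fan_in: int, fan_out: int) -> float:
    """Glorot-normal standard deviation sqrt(2 / (fan_in + fan_out))."""
    if fan_in < 1 or fan_out < 1:
        raise InvalidArgumentError("fan_in and fan_out must be >= 1")
    return float(np.sqrt(2.0 / (fan_in + fan_out)))


def pvalue_to_weight(p, sign, sigma: float, log_p=None):
    """Map a two-sided p-value onto a signed Xavier-scale weight.

    ``w = sign * sigma * Phi^-1(1 - p/2)``: strictly decreasing in p for a
    fixed sign, zero at p = 1, and half-normal(sigma) distributed in |w| when
    p is uniform.  Accepts scalars or arrays.

    When ``log_p`` (= ln p) is given it is used instead of ``p``, evaluated
    in log space: p-values below the float64 minimum all collapse to the
    same floored value, and only the log-space route keeps the transform
    strictly decreasing across them.  Magnitudes are capped at 1000 sigma so
    an exactly-zero p (log_p = -inf) still yields a finite weight.
    """
    if log_p is None:
        p_arr = np.asarray(p, dtype=float)
        if np.any(p_arr <= 0) or np.any(p_arr > 1):
            raise InvalidArgumentError("p must lie in (0, 1]")
        with np.errstate(divide="ignore"):
            lp = np.log(p_arr)
    else:
        lp = np.asarray(log_p, dtype=float)
        if np.any(lp > 0):
            raise InvalidArgumentError("log_p must be <= 0")
    z = -special.ndtri_exp(lp - np.log(2.0))
    z = np.minimum(np.maximum(z, 0.0), 1e3)
    w = np.asarray(sign, dtype=float) * sigma * z
    return float(w) if w.ndim == 0 else w


def weight_to_pvalue(w, sigma: float):
    """Inverse of :func:`pvalue_to_weight` on magnitudes (sign discarded)."""
    return 2.0 * stats.norm.sf(np.abs(np.asarray(w, dtype=float)) / sigma)


def mask_top_fraction(weights: np.ndarray, keep_fraction: float) -> np.ndarray:
    """Binary mask keeping the ceil(frac * E) largest |weights| among the E
    nonzero entries; ties break by (row, column) lexicographic order."""
    if not 0 < keep_fraction <= 1:
        raise InvalidArgumentError("keep_fraction must lie in (0, 1]")
    W = np.asarray(weights, dtype=float)
    rows, cols = np.nonzero(W)
    if len(rows) == 0:
        warnings.warn("all-zero weight matrix: mask is all-zero", stacklevel=2)
        return np.zeros_like(W, dtype=np.int8)
    k = int(np.ceil(keep_fraction * len(rows)))
    mags = np.abs(W[rows, cols])
    # lexsort: last key is primary -> sort by -|w|, then row, then col
    order = np.lexsort((cols, rows, -mags))
    keep = order[:k]
    mask = np.zeros_like(W, dtype=np.int8)
    mask[rows[keep], cols[keep]] = 1
    return mask


@dataclass
class SlemModel:
    """The sparse labelled five-layer network: weights, masks, activations.

    ``weights[i]`` connects layer i to layer i+1 (shape fan_in x fan_out, the
    disease layer has fan_out 1); ``masks[i]`` is the binary edge mask of the
    same shape.  Intermediate layers use tanh, the output sigmoid; there are
    no bias terms, so the edge counts are exactly the mask sums.
    """

    architecture: LayerArchitecture
    weights: list[np.ndarray]
    masks: list[np.ndarray]
    activations: tuple[str, ...] = ("tanh", "tanh", "tanh", "sigmoid")
    training_state: dict = field(default_factory=dict)

    def __post_init__(self):
        sizes = self.architecture.sizes
        if len(self.weights) != 4 or len(self.masks) != 4:
            raise ArchitectureError("expected 4 weight and 4 mask matrices")
        for i, (W, M) in enumerate(zip(self.weights, self.masks)):
            want = (sizes[i], sizes[i + 1])
            if W.shape != want or M.shape != want:
                raise ArchitectureError(
                    f"layer {i} weight/mask shape {W.shape} != {want}"
                )
        self._enforce_masks()

    def _enforce_masks(self) -> None:
        for i in range(4):
            self.weights[i] = self.weights[i] * self.masks[i]

    def masked_weights(self) -> list[np.ndarray]:
        return [W * M for W, M in zip(self.weights, self.masks)]

    def n_edges(self) -> int:
        return int(sum(M.sum() for M in self.masks))

    def edge_counts(self) -> list[int]:
        return [int(M.sum()) for M in self.masks]

    def copy(self) -> "SlemModel":
        return SlemModel(
            architecture=self.architecture,
            weights=[W.copy() for W in self.weights],
            masks=[M.copy() for M in self.masks],
            activations=self.activations,
            training_state=dict(self.training_state),
        )

    # ---- lossless JSON round trip -------------------------------------
    def to_dict(self) -> dict:
        return {
            "layer_nodes": [list(nodes) for nodes in self.architecture.layer_nodes],
            "selection_thresholds": list(self.architecture.selection_thresholds),
            "weights": [W.tolist() for W in self.weights],
            "masks": [M.astype(int).tolist() for M in self.masks],
            "activations": list(self.activations),
            "training_state": self.training_state,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "SlemModel":
        arch = LayerArchitecture(
            tuple(tuple(nodes) for nodes in d["layer_nodes"]),
            tuple(d.get("selection_thresholds", (0.1, 0.05, 0.05))),
        )
        return cls(
            architecture=arch,
            weights=[np.asarray(W, dtype=float) for W in d["weights"]],
            masks=[np.asarray(M, dtype=np.int8) for M in d["masks"]],
            activations=tuple(d["activations"]),
            training_state=d.get("training_state", {}),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SlemModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _edge_matrix(
    table: AssociationTable,
    src_nodes: Sequence[str],
    tgt_nodes: Sequence[str],
    sigma: float,
    significance_cutoff: float,
) -> np.ndarray:
    src_pos = {s: i for i, s in enumerate(src_nodes)}
    tgt_pos = {t: j for j, t in enumerate(tgt_nodes)}
    W = np.zeros((len(src_nodes), len(tgt_nodes)))
    df = table.frame
    sel = df["source"].isin(src_pos) & df["target"].isin(tgt_pos)
    sig = sel & (df["p"] < significance_cutoff)
    sub = df[sig]
    if len(sub):
        rows = sub["source"].map(src_pos).to_numpy()
        cols = sub["target"].map(tgt_pos).to_numpy()
        with np.errstate(divide="ignore"):
            log_p = (
                sub["log_p"].to_numpy(float)
                if "log_p" in sub
                else np.log(sub["p"].to_numpy(float))
            )
        W[rows, cols] = pvalue_to_weight(
            sub["p"].to_numpy(), sub["sign"].to_numpy(), sigma, log_p=log_p
        )
    return W


def build_model(
    tables: Mapping[str, AssociationTable],
    config: BuildConfig = BuildConfig(),
    disease_label: str = "disease",
) -> SlemModel:
    """Assemble the initialized sparse network from association tables.

    ``tables`` must cover ``snp->isoform``, ``isoform->marker`` and
    ``marker->phenotype``; when ``snp->marker`` / ``snp->phenotype`` tables
    are present they drive marker/phenotype node selection (the
    SNP-association route), otherwise selection falls back on the edge
    tables.  Disease-layer weights are Xavier-normal draws from
    ``config.seed``; everything else is deterministic given the tables.
    """
    tables = {k.replace("→", "->"): v for k, v in tables.items()}
    for needed in ("snp->isoform", "isoform->marker", "marker->phenotype"):
        if needed not in tables:
            raise InvalidArgumentError(f"missing association table {needed!r}")

    t_si = tables["snp->isoform"]
    snps = t_si.sources
    isoforms = select_nodes(t_si, config.fdr_thresholds[0])
    markers = select_nodes(
        tables.get("snp->marker", tables["isoform->marker"]), config.fdr_thresholds[1]
    )
    phenotypes = select_nodes(
        tables.get("snp->phenotype", tables["marker->phenotype"]),
        config.fdr_thresholds[2],
    )
    for name, nodes in (("isoform", isoforms), ("marker", markers), ("phenotype", phenotypes)):
        if not nodes:
            raise ArchitectureError(f"{name} layer is empty after selection")

    arch = LayerArchitecture(
        (tuple(snps), tuple(isoforms), tuple(markers), tuple(phenotypes), (disease_label,)),
        config.fdr_thresholds,
    )
    pairs = [
        (t_si, snps, isoforms),
        (tables["isoform->marker"], isoforms, markers),
        (tables["marker->phenotype"], markers, phenotypes),
    ]
    weights, masks = [], []
    for table, src, tgt in pairs:
        sigma = xavier_sigma(len(src), len(tgt))
        W = _edge_matrix(table, src, tgt, sigma, config.significance_cutoff)
        M = mask_top_fraction(W, config.keep_fraction)
        weights.append(W * M)
        masks.append(M.astype(np.int8))

    rng = np.random.default_rng([37, config.seed])
    w_out = rng.normal(0, xavier_sigma(len(phenotypes), 1), size=(len(phenotypes), 1))
    weights.append(w_out)
    masks.append(np.ones((len(phenotypes), 1), dtype=np.int8))

    return SlemModel(
        architecture=arch,
        weights=weights,
        masks=masks,
        training_state={"seed": config.seed, "epochs_trained": 0},
    )
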