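"""Model/Results facade over the two-step pipeline.

:class:`SLEM` holds the association-derived initial network (step one:
architecture from precise multilevel data); its :meth:`SLEM.fit` trains the
masked network on a large end-to-end genotype/diagnosis cohort (step two)
and returns a :class:`SLEMResults` carrying the trained network, its
cross-validated discrimination, per-SNP impact scores and the downstream
interpretation tools (combination screening, mediator-module extraction).

    >>> dataset, truth = gen_multilevel(config)
    >>> model = SLEM.from_multilevel(dataset)
    >>> res = model.fit(e2e_data, TrainConfig(epochs=200), cross_validate=True)
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import interpret, screen as screenmod
from .archinit import BuildConfig, SlemModel, build_model
from .assoc import AssociationTable, batch_assoc
from .exceptions import InvalidArgumentError
from .network import (
    CVResult,
    TrainConfig,
    auroc,
    forward,
    fully_connected_baseline,
    train,
)
from .network import cross_validate as _cross_validate
from .synthdata import EndToEndDataset, MultilevelDataset

__all__ = ["SLEM", "SLEMResults"]


class SLEM:
    """The sparse labelled network model, built from multilevel associations.

    Parameters
    ----------
    tables
        Association tables keyed by layer pair (``snp->isoform``,
        ``isoform->marker``, ``marker->phenotype`` required; ``snp->marker``
        and ``snp->phenotype`` drive node selection when present).
    build_config
        Node-selection FDR thresholds, the pre-mask significance cutoff, the
        top-fraction mask rule and the output-layer init seed.
    """

    def __init__(
        self, tables: Mapping[str, AssociationTable], build_config: BuildConfig = BuildConfig()
    ):
        self.tables = dict(tables)
        self.build_config = build_config
        self.initial_model: SlemModel = build_model(self.tables, build_config)

    @classmethod
    def from_multilevel(
        cls,
        dataset: MultilevelDataset,
        build_config: BuildConfig = BuildConfig(),
        n_pcs: int | None = None,
    ) -> "SLEM":
        """Compute all five layer-pair association tables and assemble."""
        tables = {
            pair: batch_assoc(dataset, pair, n_pcs=n_pcs)
            for pair in (
                "snp->isoform",
                "snp->marker",
                "snp->phenotype",
                "isoform->marker",
                "marker->phenotype",
            )
        }
        return cls(tables, build_config)

    @property
    def architecture(self):
        return self.initial_model.architecture

    def baseline(self, seed: int | None = None) -> SlemModel:
        """The fully connected comparator over the same architecture."""
        return fully_connected_baseline(
            self.architecture, self.build_config.seed if seed is None else seed
        )

    def fit(
        self,
        data: EndToEndDataset,
        train_config: TrainConfig = TrainConfig(),
        cross_validate: bool = False,
    ) -> "SLEMResults":
        """Train the masked network on an end-to-end cohort.

        With ``cross_validate=True`` a stratified k-fold AUROC summary is
        computed alongside the final model (which is trained on all data).
        """
        cv = None
        if cross_validate:
            cv = _cross_validate(self.initial_model, data, train_config)
        trained = train(self.initial_model, data, train_config)
        return SLEMResults(
            model=self,
            network=trained,
            train_config=train_config,
            train_data=data,
            cv=cv,
        )


@dataclass
class SLEMResults:
    """Fitted network plus diagnostics and interpretation entry points."""

    model: SLEM
    network: SlemModel
    train_config: TrainConfig
    train_data: EndToEndDataset
    cv: CVResult | None = None
    _impact: interpret.ImpactScoreTable | None = field(default=None, repr=False)

    # ---- prediction & diagnostics -------------------------------------
    def predict_proba(self, genotypes) -> np.ndarray:
        return forward(self.network, genotypes).output

    def train_auroc(self) -> float:
        return auroc(self.predict_proba(self.train_data.genotypes), self.train_data.labels)

    # ---- interpretation -----------------------------------------------
    def impact_scores(self, on: str = "trained") -> interpret.ImpactScoreTable:
        """Per-SNP path-product impact scores ('trained' or 'initial')."""
        if on == "trained":
            if self._impact is None:
                self._impact = interpret.impact_scores_matrix(self.network)
            return self._impact
        if on == "initial":
            return interpret.impact_scores_matrix(self.model.initial_model)
        raise InvalidArgumentError("on must be 'trained' or 'initial'")

    def top_snps(self, k: int = 5) -> list[str]:
        return interpret.top_snps(self.impact_scores(), k)

    def screen(
        self,
        data: EndToEndDataset | None = None,
        snps: Sequence[str] | None = None,
        precision_threshold: float = 0.6,
        p_threshold: float = 0.05,
    ) -> list[screenmod.ScreenRecord]:
        """Screen all genotype combinations of the top-impact SNPs."""
        data = data if data is not None else self.train_data
        snps = snps if snps is not None else self.top_snps()
        return screenmod.screen(data, snps, precision_threshold, p_threshold)

    def evaluate_holdout(
        self, records: Sequence[screenmod.ScreenRecord], holdout: EndToEndDataset
    ) -> pd.DataFrame:
        return screenmod.evaluate_holdout(records, holdout)

    def extract_module(
        self, anchor_phenotypes: Sequence[str], weight_fraction: float = 0.10
    ) -> interpret.MediatorModule:
        return interpret.extract_module(self.network, list(anchor_phenotypes), weight_fraction)

    # ---- reporting -----------------------------------------------------
    def summary(self) -> str:
        arch = self.network.architecture
        sizes = arch.sizes
        fc_edges = sum(a * b for a, b in zip(sizes[:-1], sizes[1:]))
        counts = self.network.edge_counts()
        lines = [
            "Sparse labelled network (SLEM) results",
            "=" * 54,
            f"Layers (snp/isoform/marker/phenotype/disease): {'/'.join(map(str, sizes))}",
            f"Edges kept: {self.network.n_edges()}  (per layer: {counts};"
            f" fully connected would have {fc_edges})",
            f"Training: lr={self.train_config.learning_rate}"
            f" batch={self.train_config.batch_size} epochs={self.train_config.epochs}",
            f"Training-set AUROC: {self.train_auroc():.4f}",
        ]
        if self.cv is not None:
            lines.append(
                f"{len(self.cv.per_fold)}-fold CV AUROC: {self.cv.mean:.4f}"
                f" +/- {self.cv.sd:.4f}"
            )
        top = self.top_snps(min(5, sizes[0]))
        scores = self.impact_scores().scores
        lines.append("Top impact SNPs:")
        for s in top:
            lines.append(f"  {s}: {scores[s]:.4f}")
        return "\n".join(lines)
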