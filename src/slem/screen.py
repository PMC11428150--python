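"""Genotype-combination screening for multi-SNP disease markers.

A genotype combination assigns a specific state (0 homozygous reference,
1 heterozygous, 2 homozygous alternative) to each SNP in a subset of the
candidate SNPs; a sample *carries* the combination when its genotype matches
every assigned state.  Each combination is scored on a labelled genotype
cohort by

* precision — patients carrying the marker / all carriers of the marker, and
* the hypergeometric upper-tail probability of drawing at least that many
  patients among the carriers from the cohort,

and passes the screen when precision strictly exceeds the precision
threshold (default 0.6) and the enrichment p is strictly below the p
threshold (default 0.05).  Passing combinations are re-evaluated on an
independent holdout cohort; a marker whose holdout precision falls below the
holdout base rate is labelled de-enriched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations as subsets
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidArgumentError, ScreeningError
from .synthdata import EndToEndDataset

__all__ = [
    "GenotypeCombination",
    "ScreenRecord",
    "enumerate_combinations",
    "carriers",
    "precision",
    "hypergeom_upper",
    "screen",
    "screen_single_snps",
    "evaluate_holdout",
]

logger = logging.getLogger(__name__)

STATES = (0, 1, 2)


@dataclass(frozen=True)
class GenotypeCombination:
    """A joint genotype-state assignment over a subset of SNPs."""

    assignments: tuple[tuple[str, int], ...]  # (snp label, state), fixed order

    def __post_init__(self):
        if len(self.assignments) < 1:
            raise InvalidArgumentError("a combination needs at least one SNP")
        labels = [s for s, _ in self.assignments]
        if len(set(labels)) != len(labels):
            raise InvalidArgumentError("duplicate SNP in combination")
        if any(state not in STATES for _, state in self.assignments):
            raise InvalidArgumentError("states must be 0, 1 or 2")

    @property
    def order(self) -> int:
        return len(self.assignments)

    @property
    def snps(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.assignments)

    def __str__(self) -> str:
        return "".join(f"{s}{g}" for s, g in self.assignments)


@dataclass
class ScreenRecord:
    """One screened combination with its counts, precision and enrichment."""

    combination: GenotypeCombination
    positives: int
    true_positives: int
    precision: float  # nan when positives == 0
    p_value: float  # nan when positives == 0
    passed: bool
    no_carriers: bool = False

    def __post_init__(self):
        if self.true_positives > self.positives:
            raise InvalidArgumentError("true_positives cannot exceed positives")


def enumerate_combinations(
    snps: Sequence[str], min_order: int = 1, max_order: int | None = None
) -> list[GenotypeCombination]:
    """All subsets of sizes [min_order, max_order] crossed with all 3^k state
    assignments; subset order lexicographic by position, states odometer."""
    snps = list(snps)
    if not snps:
        raise InvalidArgumentError("snps must be non-empty")
    if max_order is None:
        max_order = len(snps)
    if not 1 <= min_order <= max_order <= len(snps):
        raise InvalidArgumentError("need 1 <= min_order <= max_order <= |snps|")
    out = []
    for k in range(min_order, max_order + 1):
        for subset in subsets(range(len(snps)), k):
            for states in product(STATES, repeat=k):
                out.append(
                    GenotypeCombination(
                        tuple((snps[i], g) for i, g in zip(subset, states))
                    )
                )
    return out


def _combo_match(genotypes: pd.DataFrame, combo: GenotypeCombination):
    """(carrier mask, valid mask): valid samples have no missing genotype at
    any assigned SNP; carriers match every assigned state."""
    missing_cols = [s for s, _ in combo.assignments if s not in genotypes.columns]
    if missing_cols:
        raise InvalidArgumentError(f"SNPs absent from genotype matrix: {missing_cols}")
    valid = np.ones(len(genotypes), dtype=bool)
    match = np.ones(len(genotypes), dtype=bool)
    for snp, state in combo.assignments:
        col = genotypes[snp].to_numpy(float)
        ok = ~np.isnan(col) & (col >= 0)
        valid &= ok
        match &= ok & (col == state)
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.info(
            "combination %s: %d samples excluded for missing genotypes", combo, n_excluded
        )
    return match & valid, valid


def carriers(genotypes: pd.DataFrame, combo: GenotypeCombination) -> list:
    """Sample index labels carrying the combination (exact match on every
    assigned SNP; samples with a missing assigned genotype are excluded)."""
    is_carrier, _ = _combo_match(genotypes, combo)
    return list(genotypes.index[is_carrier])


def precision(true_positives: int, positives: int) -> float:
    """Patients with the marker / all carriers of the marker."""
    if positives < true_positives or true_positives < 0:
        raise InvalidArgumentError("need positives >= true_positives >= 0")
    if positives == 0:
        return float("nan")
    return true_positives / positives


def hypergeom_upper(population: int, patients: int, n_carriers: int, carrier_patients: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N=population, K=patients, n=carriers)."""
    N, K, n, k = population, patients, n_carriers, carrier_patients
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise InvalidArgumentError("inconsistent hypergeometric counts")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def screen(
    data: EndToEndDataset,
    snps: Sequence[str],
    precision_threshold: float = 0.6,
    p_threshold: float = 0.05,
    min_order: int = 1,
    max_order: int | None = None,
) -> list[ScreenRecord]:
    """Score every genotype combination of the candidate SNPs on the cohort.

    The full record table is returned; ``passed`` flags combinations with
    precision strictly above the precision threshold and enrichment p
    strictly below the p threshold.  Samples missing a genotype at an
    assigned SNP are excluded from that combination's population.
    """
    for thr in (precision_threshold, p_threshold):
        if not 0 < thr < 1:
            raise InvalidArgumentError("thresholds must lie in (0, 1)")
    y = data.labels.to_numpy(int)
    if y.sum() == 0:
        raise ScreeningError("dataset contains zero patients")
    records = []
    for combo in enumerate_combinations(snps, min_order, max_order):
        is_carrier, valid = _combo_match(data.genotypes, combo)
        N = int(valid.sum())
        K = int(y[valid].sum())
        n = int(is_carrier.sum())
        k = int(y[is_carrier].sum())
        if n == 0:
            records.append(
                ScreenRecord(combo, 0, 0, float("nan"), float("nan"), False, no_carriers=True)
            )
            continue
        prec = precision(k, n)
        p = hypergeom_upper(N, K, n, k)
        passed = (prec > precision_threshold) and (p < p_threshold)
        records.append(ScreenRecord(combo, n, k, prec, p, passed))
    return records


def screen_single_snps(
    data: EndToEndDataset,
    snps: Sequence[str],
    precision_threshold: float = 0.6,
    p_threshold: float = 0.05,
) -> list[ScreenRecord]:
    """Control group: every single-SNP genotype-state marker over the model's
    input SNPs, screened with identical statistics."""
    return screen(data, snps, precision_threshold, p_threshold, min_order=1, max_order=1)


def records_to_frame(records: Sequence[ScreenRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "combination": [str(r.combination) for r in records],
            "order": [r.combination.order for r in records],
            "positives": [r.positives for r in records],
            "true_positives": [r.true_positives for r in records],
            "precision": [r.precision for r in records],
            "p": [r.p_value for r in records],
            "passed": [r.passed for r in records],
        }
    )


def evaluate_holdout(
    records: Sequence[ScreenRecord],
    data: EndToEndDataset,
    precision_threshold: float = 0.6,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Re-evaluate passing combinations on an independent cohort.

    Returns the paired training/holdout precision table (the scatter data for
    robustness comparison).  Combinations with no holdout carriers are
    flagged and their holdout precision omitted; markers whose holdout
    precision is below the holdout base rate are labelled de-enriched.
    """
    y = data.labels.to_numpy(int)
    rows = []
    for rec in records:
        if not rec.passed:
            continue
        is_carrier, valid = _combo_match(data.genotypes, rec.combination)
        N, K = int(valid.sum()), int(y[valid].sum())
        n, k = int(is_carrier.sum()), int(y[is_carrier].sum())
        base_rate = K / N if N else float("nan")
        if n == 0:
            rows.append(
                {
                    "combination": str(rec.combination),
                    "train_precision": rec.precision,
                    "train_p": rec.p_value,
                    "holdout_positives": 0,
                    "holdout_true_positives": 0,
                    "holdout_precision": float("nan"),
                    "holdout_p": float("nan"),
                    "no_carriers": True,
                    "de_enriched": False,
                }
            )
            continue
        prec = precision(k, n)
        rows.append(
            {
                "combination": str(rec.combination),
                "train_precision": rec.precision,
                "train_p": rec.p_value,
                "holdout_positives": n,
                "holdout_true_positives": k,
                "holdout_precision": prec,
                "holdout_p": hypergeom_upper(N, K, n, k),
                "no_carriers": False,
                "de_enriched": bool(prec < base_rate),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "combination",
            "train_precision",
            "train_p",
            "holdout_positives",
            "holdout_true_positives",
            "holdout_precision",
            "holdout_p",
            "no_carriers",
            "de_enriched",
        ],
    )


def write_screen_tsv(records: Sequence[ScreenRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)
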