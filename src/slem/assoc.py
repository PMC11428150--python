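"""Covariate-adjusted association engine for adjacent network layers.

Two test families are used, matching how each layer pair behaves:

* ``linear_assoc`` — OLS of a response on ``[1, x, covariates]`` with a
  two-sided t-test on the predictor coefficient; used for every SNP→*
  pair (the eQTL-style tests).
* ``kendall_assoc`` — Kendall tau-b rank correlation with tie correction;
  used for isoform→marker and marker→phenotype pairs, where neuropathology
  features are not normally distributed and a rank test is more robust.

Hidden expression confounders are adjusted with the top principal components
of the genotype-residualized isoform matrix (the standard desk-scale
surrogate for factor-based confounder estimation; residualizing first keeps
the factors from absorbing the genetic signal under test) via the
``"expression_pcs"`` covariate label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import (
    ConfigurationError,
    DegeneratePredictorError,
    InvalidArgumentError,
    SingularDesignError,
)
from .synthdata import MultilevelDataset

__all__ = [
    "AssociationRecord",
    "AssociationTable",
    "linear_assoc",
    "kendall_assoc",
    "bh_adjust",
    "batch_assoc",
    "LAYER_PAIRS",
]

LAYER_PAIRS = (
    "snp->isoform",
    "snp->marker",
    "snp->phenotype",
    "isoform->marker",
    "marker->phenotype",
)


@dataclass(frozen=True)
class AssociationRecord:
    """One source/target association: statistic, sign, p and FDR q.

    ``log_p`` carries ln(p) at full precision: two-sided p-values of very
    strong associations underflow float64 (``p_value`` is then floored at
    the smallest positive float), and only the log-space value preserves
    their relative ordering downstream.
    """

    source: str
    target: str
    statistic: float
    sign: int
    p_value: float
    q_value: float | None = None
    log_p: float | None = None

    def __post_init__(self):
        if self.sign not in (-1, 1):
            raise InvalidArgumentError("sign must be +1 or -1")
        if self.log_p is None:
            object.__setattr__(self, "log_p", float(np.log(self.p_value)))


def _sign(x: float) -> int:
    # Ties at exactly zero break positive.
    return -1 if x < 0 else 1


def linear_assoc(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    source: str = "x",
    target: str = "y",
) -> AssociationRecord:
    """OLS association of ``y`` on ``x`` adjusting for covariates.

    Fits ``y ~ 1 + x + covariates`` by least squares and reports the slope on
    ``x`` with its two-sided t-test p-value.  Rows with missing values in any
    variable are dropped (listwise deletion).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise InvalidArgumentError("x and y must have equal length")
    if covariates is None:
        C = np.empty((len(x), 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    keep = ~(np.isnan(x) | np.isnan(y) | np.isnan(C).any(axis=1))
    x, y, C = x[keep], y[keep], C[keep]
    n, q = len(x), C.shape[1]
    if n < q + 3:
        raise InvalidArgumentError(f"need n > rank(covariates) + 2, got n={n}, q={q}")
    if np.ptp(x) == 0:
        raise DegeneratePredictorError("predictor is constant (monomorphic)")
    X = np.column_stack([np.ones(n), x, C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise SingularDesignError("design matrix is rank-deficient")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - X.shape[1]
    sigma2 = resid @ resid / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    slope = beta[1]
    if se == 0:
        # Noiseless fit: below any representable p; log-space sentinel keeps
        # it ahead of every finite-t association.
        p, logp = np.finfo(float).tiny, -np.inf
    else:
        t = slope / se
        logp = float(np.log(2) + stats.t.logsf(abs(t), df))
        p = max(float(np.exp(logp)), np.finfo(float).tiny)
    return AssociationRecord(source, target, float(slope), _sign(slope), p, log_p=logp)


def kendall_assoc(
    x: np.ndarray, y: np.ndarray, source: str = "x", target: str = "y"
) -> AssociationRecord:
    """Kendall tau-b association with tie correction.

    The p-value is exact for n <= 10 when the data are tie-free, and the
    normal approximation otherwise (the small-cohort regime these tests run
    in uses the approximation anyway).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise InvalidArgumentError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise InvalidArgumentError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegeneratePredictorError("constant vector has no rank correlation")
    has_ties = len(np.unique(x)) < len(x) or len(np.unique(y)) < len(y)
    method = "exact" if (len(x) <= 10 and not has_ties) else "asymptotic"
    res = stats.kendalltau(x, y, method=method)
    tau, p = float(res.statistic), float(res.pvalue)
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return AssociationRecord(source, target, tau, _sign(tau), p)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any(p <= 0) or np.any(p > 1):
        raise InvalidArgumentError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class AssociationTable:
    """All pairwise associations between two adjacent layers.

    Stored as a DataFrame with columns ``source, target, statistic, sign,
    p, q``; ``q`` is Benjamini–Hochberg adjusted within the table.
    """

    COLUMNS = ["source", "target", "statistic", "sign", "p", "q", "log_p"]

    def __init__(self, records: pd.DataFrame | Iterable[AssociationRecord], layer_pair: str):
        if isinstance(records, pd.DataFrame):
            df = records.copy()
        else:
            df = pd.DataFrame(
                [
                    {
                        "source": r.source,
                        "target": r.target,
                        "statistic": r.statistic,
                        "sign": r.sign,
                        "p": r.p_value,
                        "q": r.q_value,
                        "log_p": r.log_p,
                    }
                    for r in records
                ]
            )
        if df.empty:
            df = pd.DataFrame(columns=self.COLUMNS)
        if df.duplicated(subset=["source", "target"]).any():
            raise InvalidArgumentError("(source, target) pairs must be unique")
        if "q" not in df or df["q"].isna().all():
            df["q"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
        if "log_p" not in df:
            with np.errstate(divide="ignore"):
                df["log_p"] = np.log(df["p"].to_numpy(float)) if len(df) else []
        self.frame = df.reset_index(drop=True)[self.COLUMNS]
        self.layer_pair = layer_pair

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def sources(self) -> list[str]:
        """Source labels in stable first-appearance order."""
        return list(dict.fromkeys(self.frame["source"]))

    @property
    def targets(self) -> list[str]:
        return list(dict.fromkeys(self.frame["target"]))

    def min_q_per_target(self) -> pd.Series:
        return self.frame.groupby("target", sort=False)["q"].min()

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, layer_pair: str) -> "AssociationTable":
        return cls(pd.read_csv(path, sep="\t"), layer_pair)


def _expression_pcs(dataset: MultilevelDataset, k: int) -> np.ndarray:
    """Top-k PC scores of the isoform matrix after projecting out genotype.

    The PCs stand in for hidden *non-genetic* expression confounders, so the
    isoform matrix is first residualized against the genotype matrix (when
    the sample count permits); otherwise factors extracted from raw
    expression capture broad genetic effects and adjusting for them removes
    the very associations being tested.  When there are too few samples to
    residualize, plain PCs are used.
    """
    X = dataset.isoforms.to_numpy(float)
    X = X - X.mean(axis=0)
    G = dataset.genotypes.to_numpy(float)
    if X.shape[0] > G.shape[1] + k + 10:
        G = np.where(np.isnan(G), np.nanmean(G, axis=0), G)
        G = G - G.mean(axis=0)
        Q, _ = np.linalg.qr(G)
        X = X - Q @ (Q.T @ X)
    # PCs via SVD; deterministic up to sign, which cancels in regression.
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    k = min(k, vt.shape[0])
    return X @ vt[:k].T


def _covariate_matrix(
    dataset: MultilevelDataset, covariate_spec: Sequence[str], n_pcs: int
) -> np.ndarray:
    cols = []
    for label in covariate_spec:
        if label == "expression_pcs":
            cols.append(_expression_pcs(dataset, n_pcs))
        elif label in dataset.covariates.columns:
            cols.append(dataset.covariates[label].to_numpy(float)[:, None])
        else:
            raise ConfigurationError(f"unknown covariate label {label!r}")
    if not cols:
        return np.empty((dataset.n_samples, 0))
    return np.column_stack(cols)


def _batch_linear(
    X: np.ndarray, Y: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs OLS slopes, p-values and log p-values via Frisch–Waugh
    residualization.

    Equivalent to fitting ``y ~ 1 + x + C`` separately for every (column of
    X, column of Y) pair; columns constant after residualization get slope 0
    and p 1.  The third return value is ln(p) computed in log space, which
    stays informative where the plain p-value underflows to the float64
    minimum.
    """
    n = X.shape[0]
    D = np.column_stack([np.ones(n), C])
    # Residualize both sides against [1, C].
    Q, _ = np.linalg.qr(D)
    Xr = X - Q @ (Q.T @ X)
    Yr = Y - Q @ (Q.T @ Y)
    sxx = np.einsum("ij,ij->j", Xr, Xr)  # per-SNP
    degenerate = sxx <= 1e-12 * n
    sxx_safe = np.where(degenerate, 1.0, sxx)
    cross = Xr.T @ Yr  # snps x targets
    slopes = cross / sxx_safe[:, None]
    syy = np.einsum("ij,ij->j", Yr, Yr)  # per-target
    rss = syy[None, :] - slopes**2 * sxx_safe[:, None]
    df = n - (2 + C.shape[1])
    if df <= 0:
        raise InvalidArgumentError("not enough samples for the covariate set")
    sigma2 = np.maximum(rss, 0) / df
    se = np.sqrt(sigma2 / sxx_safe[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, slopes / se, np.inf)
    logp = np.log(2) + stats.t.logsf(np.abs(tvals), df)
    logp = np.minimum(logp, 0.0)
    pvals = np.clip(np.exp(logp), np.finfo(float).tiny, 1.0)
    slopes[degenerate, :] = 0.0
    pvals[degenerate, :] = 1.0
    logp[degenerate, :] = 0.0
    return slopes, pvals, logp


def batch_assoc(
    dataset: MultilevelDataset,
    layer_pair: str,
    covariate_spec: Sequence[str] | None = None,
    n_pcs: int | None = None,
) -> AssociationTable:
    """One association record per source/target pair of an adjacent layer pair.

    SNP→* pairs use the covariate-adjusted linear test; isoform→marker and
    marker→phenotype pairs use Kendall tau-b.  q-values are BH-adjusted
    within the returned table.
    """
    layer_pair = layer_pair.replace("→", "->")
    if layer_pair not in LAYER_PAIRS:
        raise InvalidArgumentError(
            f"layer_pair must be one of {LAYER_PAIRS}, got {layer_pair!r}"
        )
    src_name, tgt_name = layer_pair.split("->")
    src = dataset.layer(src_name)
    tgt = dataset.layer(tgt_name)
    if n_pcs is None:
        # Confounder PCs must stay well below both the sample count and the
        # isoform count, or residualization absorbs the signal itself.
        n_pcs = min(15, max(dataset.n_samples - 10, 0), dataset.isoforms.shape[1] // 4)

    if src_name == "snp":
        if covariate_spec is None:
            covariate_spec = (
                ["age", "sex", "diagnosis", "expression_pcs"]
                if tgt_name == "isoform"
                else ["age", "sex", "diagnosis"]
            )
        C = _covariate_matrix(dataset, covariate_spec, n_pcs)
        X = src.to_numpy(float)
        Y = tgt.to_numpy(float)
        if np.isnan(X).any() or np.isnan(Y).any() or np.isnan(C).any():
            records = []
            for s in src.columns:
                for t in tgt.columns:
                    try:
                        r = linear_assoc(src[s], tgt[t], C, source=s, target=t)
                    except DegeneratePredictorError:
                        r = AssociationRecord(s, t, 0.0, 1, 1.0)
                    records.append(r)
            return AssociationTable(records, layer_pair)
        slopes, pvals, logp = _batch_linear(X, Y, C)
        frame = pd.DataFrame(
            {
                "source": np.repeat(src.columns, len(tgt.columns)),
                "target": np.tile(tgt.columns, len(src.columns)),
                "statistic": slopes.ravel(),
                "sign": np.where(slopes.ravel() < 0, -1, 1),
                "p": pvals.ravel(),
                "log_p": logp.ravel(),
            }
        )
        return AssociationTable(frame, layer_pair)

    records = []
    for s in src.columns:
        xs = src[s].to_numpy(float)
        for t in tgt.columns:
            try:
                r = kendall_assoc(xs, tgt[t].to_numpy(float), source=s, target=t)
            except DegeneratePredictorError:
                r = AssociationRecord(s, t, 0.0, 1, 1.0)
            records.append(r)
    return AssociationTable(records, layer_pair)
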