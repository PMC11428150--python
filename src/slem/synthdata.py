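"""Synthetic multilevel and end-to-end genotype datasets with planted structure.

Real five-layer training data of this kind (genotypes, transcript-isoform
expression, neuropathology protein markers, cellular phenotypes, diagnosis)
come from access-restricted brain collections and genotype repositories.  This
module emulates both kinds of input with a known planted ground truth so that
every downstream stage — association, architecture initialization, masked
training, impact scoring, combination screening — can be tested quantitatively.

The generative cascade is:

    genotypes  ~ Binomial(2, maf) per SNP                     (additive 0/1/2)
    isoforms   = z(genotypes) @ E1 + covariate effects + eps1
    markers    = tanh(z(isoforms)) @ E2 + eps2
    phenotypes = z(markers) @ E3 + eps3
    liability  = z(phenotypes) @ beta + intercept
    diagnosis  ~ Bernoulli(sigmoid(liability))

The marker layer passes isoform signal through a monotone nonlinearity (tanh)
before linear mixing, so rank-based (Kendall) edge detection is exercised on a
genuinely non-Gaussian dependency, mirroring the non-normal neuropathology
features the upper layers represent.  ``z`` denotes per-column
standardization, so planted effect entries are in per-SD units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError

__all__ = [
    "SynthConfig",
    "PlantedTruth",
    "MultilevelDataset",
    "EndToEndDataset",
    "gen_genotypes",
    "gen_multilevel",
    "gen_end_to_end",
    "dominant_chain_config",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (a - a.mean(axis=0)) / sd


@dataclass(frozen=True)
class SynthConfig:
    """Shape, effect and noise settings for the synthetic cohort.

    Defaults follow the desk-scale shape of the study the generator emulates:
    57 multilevel samples, 138 risk SNPs, 67/42/19 intermediate nodes and a
    7300-sample end-to-end genotype/diagnosis cohort.

    Parameters
    ----------
    maf
        Per-SNP minor-allele frequency in (0, 0.5]; a scalar is broadcast,
        ``None`` draws each SNP's frequency from Uniform(0.1, 0.5).
    effect_size
        Magnitude (per-SD units) of planted nonzero layer-to-layer effects.
    sparsity
        Fraction of entries of each effect matrix that are nonzero when the
        matrices are generated rather than supplied.
    noise_sd
        Per-layer Gaussian noise scale.
    liability_intercept
        Intercept of the disease liability; ``None`` calibrates it on the
        realized sample so the case fraction matches ``prevalence``.
    """

    n_samples_multilevel: int = 57
    n_samples_e2e: int = 7300
    n_snps: int = 138
    n_isoforms: int = 67
    n_markers: int = 42
    n_phenotypes: int = 19
    maf: float | Sequence[float] | None = None
    effect_size: float = 2.0
    sparsity: float = 0.05
    noise_sd: float = 1.0
    liability_scale: float = 1.5
    liability_intercept: float | None = None
    prevalence: float = 0.5
    seed: int = 0
    effect_matrices: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
    liability_weights: np.ndarray | None = None

    def __post_init__(self):
        for name in (
            "n_samples_multilevel",
            "n_samples_e2e",
            "n_snps",
            "n_isoforms",
            "n_markers",
            "n_phenotypes",
        ):
            if getattr(self, name) < 1:
                raise InvalidArgumentError(f"{name} must be >= 1")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")
        if not 0 < self.prevalence < 1:
            raise InvalidArgumentError("prevalence must be in (0, 1)")
        if self.effect_matrices is not None:
            e1, e2, e3 = self.effect_matrices
            shapes = (
                (self.n_snps, self.n_isoforms),
                (self.n_isoforms, self.n_markers),
                (self.n_markers, self.n_phenotypes),
            )
            for m, want in zip((e1, e2, e3), shapes):
                if np.asarray(m).shape != want:
                    raise InvalidArgumentError(
                        f"effect matrix shape {np.asarray(m).shape} != {want}"
                    )
        if self.liability_weights is not None and (
            np.asarray(self.liability_weights).shape != (self.n_phenotypes,)
        ):
            raise InvalidArgumentError("liability_weights length mismatch")

    # Labels are stable so matrices generated from the same config align.
    @property
    def snp_labels(self) -> list[str]:
        return [f"snp{i:04d}" for i in range(self.n_snps)]

    @property
    def isoform_labels(self) -> list[str]:
        return [f"iso{i:04d}" for i in range(self.n_isoforms)]

    @property
    def marker_labels(self) -> list[str]:
        return [f"mrk{i:04d}" for i in range(self.n_markers)]

    @property
    def phenotype_labels(self) -> list[str]:
        return [f"phe{i:04d}" for i in range(self.n_phenotypes)]


@dataclass
class PlantedTruth:
    """Ground truth of a generated cohort: the planted effect cascade."""

    e1: np.ndarray  # SNPs x isoforms
    e2: np.ndarray  # isoforms x markers
    e3: np.ndarray  # markers x phenotypes
    liability_weights: np.ndarray
    liability_intercept: float
    mafs: np.ndarray
    dominant_snp: str | None = None

    def planted_edges(self, layer: int) -> set[tuple[int, int]]:
        """(row, col) indices of nonzero planted effects for layer 1, 2 or 3."""
        m = (self.e1, self.e2, self.e3)[layer - 1]
        rows, cols = np.nonzero(m)
        return set(zip(rows.tolist(), cols.tolist()))


@dataclass
class MultilevelDataset:
    """Aligned genotype / isoform / marker / phenotype / covariate tables."""

    genotypes: pd.DataFrame
    isoforms: pd.DataFrame
    markers: pd.DataFrame
    phenotypes: pd.DataFrame
    covariates: pd.DataFrame
    diagnosis: pd.Series

    def __post_init__(self):
        idx = self.genotypes.index
        for tbl in (self.isoforms, self.markers, self.phenotypes, self.covariates):
            if not tbl.index.equals(idx):
                raise InvalidArgumentError("all layer tables must share a sample index")
            if tbl.empty:
                raise InvalidArgumentError("no layer table may be empty")

    @property
    def n_samples(self) -> int:
        return len(self.genotypes)

    def layer(self, name: str) -> pd.DataFrame:
        tables = {
            "snp": self.genotypes,
            "isoform": self.isoforms,
            "marker": self.markers,
            "phenotype": self.phenotypes,
        }
        if name not in tables:
            raise InvalidArgumentError(f"unknown layer {name!r}")
        return tables[name]


@dataclass
class EndToEndDataset:
    """Genotype matrix plus a binary diagnosis label per sample."""

    genotypes: pd.DataFrame
    labels: pd.Series

    def __post_init__(self):
        if len(self.genotypes) != len(self.labels):
            raise InvalidArgumentError("genotypes and labels disagree on sample count")
        vals = set(pd.unique(self.labels))
        if not vals <= {0, 1}:
            raise InvalidArgumentError("labels must be binary 0/1")


def _resolve_mafs(config: SynthConfig) -> np.ndarray:
    if config.maf is None:
        rng = np.random.default_rng([7, config.seed])
        return rng.uniform(0.1, 0.5, size=config.n_snps)
    mafs = np.broadcast_to(np.asarray(config.maf, dtype=float), (config.n_snps,))
    return np.array(mafs)


def gen_genotypes(
    n_samples: int,
    mafs: Sequence[float],
    seed: int | np.random.Generator,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Draw an additive-coded genotype matrix, one Binomial(2, maf) per SNP.

    Values are 0 (homozygous reference), 1 (heterozygous), 2 (homozygous
    alternative).  Identical seeds give bit-identical matrices.
    """
    if n_samples < 1:
        raise InvalidArgumentError("n_samples must be >= 1")
    mafs = np.asarray(mafs, dtype=float)
    if mafs.ndim != 1 or len(mafs) < 1:
        raise InvalidArgumentError("mafs must be a non-empty 1-D sequence")
    if np.any(mafs <= 0) or np.any(mafs > 0.5):
        raise InvalidArgumentError("minor-allele frequencies must lie in (0, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    geno = rng.binomial(2, mafs, size=(n_samples, len(mafs)))
    if labels is None:
        labels = [f"snp{i:04d}" for i in range(len(mafs))]
    index = pd.Index([f"S{i:05d}" for i in range(n_samples)], name="sample")
    return pd.DataFrame(geno, index=index, columns=list(labels))


def _effect_matrix(
    rng: np.random.Generator, shape: tuple[int, int], effect: float, sparsity: float
) -> np.ndarray:
    m = np.zeros(shape)
    n_entries = m.size
    k = max(1, int(round(sparsity * n_entries)))
    flat = rng.choice(n_entries, size=k, replace=False)
    signs = rng.choice([-1.0, 1.0], size=k)
    m.flat[flat] = signs * effect
    return m


def _planted_network(config: SynthConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if config.effect_matrices is not None:
        e1, e2, e3 = (np.asarray(m, dtype=float) for m in config.effect_matrices)
    else:
        rng = np.random.default_rng([11, config.seed])
        e1 = _effect_matrix(
            rng, (config.n_snps, config.n_isoforms), config.effect_size, config.sparsity
        )
        e2 = _effect_matrix(
            rng, (config.n_isoforms, config.n_markers), config.effect_size, config.sparsity
        )
        e3 = _effect_matrix(
            rng, (config.n_markers, config.n_phenotypes), config.effect_size, config.sparsity
        )
    if config.liability_weights is not None:
        beta = np.asarray(config.liability_weights, dtype=float)
    else:
        rng = np.random.default_rng([13, config.seed])
        beta = rng.normal(0, 1, size=config.n_phenotypes)
        beta *= config.liability_scale / max(np.linalg.norm(beta), 1e-12)
        beta *= np.sqrt(config.n_phenotypes)
    return e1, e2, e3, beta


def _cascade(
    geno: np.ndarray,
    e1: np.ndarray,
    e2: np.ndarray,
    e3: np.ndarray,
    beta: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
    cov_effects: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    n = geno.shape[0]
    iso = _zscore(geno) @ e1 + rng.normal(0, noise_sd, size=(n, e1.shape[1]))
    if cov_effects is not None:
        iso = iso + cov_effects
    mrk = np.tanh(_zscore(iso)) @ e2 + rng.normal(0, noise_sd, size=(n, e2.shape[1]))
    phe = _zscore(mrk) @ e3 + rng.normal(0, noise_sd, size=(n, e3.shape[1]))
    liab = _zscore(phe) @ beta
    return iso, mrk, phe, liab


def _calibrate_intercept(liab: np.ndarray, prevalence: float) -> float:
    """Intercept such that mean sigmoid(liability + c) equals the prevalence."""
    from scipy.optimize import brentq

    lo, hi = -50.0, 50.0
    f = lambda c: _sigmoid(liab + c).mean() - prevalence
    return float(brentq(f, lo, hi, xtol=1e-10))


def gen_multilevel(config: SynthConfig) -> tuple[MultilevelDataset, PlantedTruth]:
    """Generate an aligned multilevel cohort plus its planted ground truth.

    Diagnosis is drawn from a sigmoid liability on the phenotype layer and
    enters the covariate table, mirroring observational case/control designs
    in which diagnosis is both a label and an adjustment covariate.
    """
    mafs = _resolve_mafs(config)
    e1, e2, e3, beta = _planted_network(config)
    n = config.n_samples_multilevel

    geno_df = gen_genotypes(
        n, mafs, np.random.default_rng([17, config.seed]), labels=config.snp_labels
    )
    rng = np.random.default_rng([19, config.seed])
    age = rng.normal(50, 10, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    cov_coef = rng.normal(0, 0.3, size=(2, config.n_isoforms))
    cov_block = np.column_stack([_zscore(age[:, None])[:, 0], sex]) @ cov_coef

    iso, mrk, phe, liab = _cascade(
        geno_df.to_numpy(float), e1, e2, e3, beta, config.noise_sd, rng, cov_block
    )
    if config.liability_intercept is None:
        intercept = _calibrate_intercept(liab, config.prevalence)
    else:
        intercept = float(config.liability_intercept)
    diag = rng.binomial(1, _sigmoid(liab + intercept))

    idx = geno_df.index
    dataset = MultilevelDataset(
        genotypes=geno_df,
        isoforms=pd.DataFrame(iso, index=idx, columns=config.isoform_labels),
        markers=pd.DataFrame(mrk, index=idx, columns=config.marker_labels),
        phenotypes=pd.DataFrame(phe, index=idx, columns=config.phenotype_labels),
        covariates=pd.DataFrame(
            {"age": age, "sex": sex, "diagnosis": diag}, index=idx
        ),
        diagnosis=pd.Series(diag, index=idx, name="diagnosis"),
    )
    truth = PlantedTruth(
        e1=e1,
        e2=e2,
        e3=e3,
        liability_weights=beta,
        liability_intercept=intercept,
        mafs=mafs,
    )
    return dataset, truth


def gen_end_to_end(
    config: SynthConfig, truth: PlantedTruth | None = None, seed_offset: int = 0
) -> EndToEndDataset:
    """Generate a genotype + binary-diagnosis cohort from the planted network.

    Labels are Bernoulli draws from the sigmoid of the cascaded liability;
    when the intercept is left for calibration the case fraction matches the
    configured prevalence on the realized sample.  ``seed_offset`` yields
    independent cohorts (e.g. a training and a holdout set) from one truth.
    """
    if truth is None:
        _, truth = gen_multilevel(config)
    e1, e2, e3 = truth.e1, truth.e2, truth.e3
    if e1.shape != (config.n_snps, config.n_isoforms):
        raise InvalidArgumentError("truth layer dimensions inconsistent with config")
    n = config.n_samples_e2e
    geno_df = gen_genotypes(
        n,
        truth.mafs,
        np.random.default_rng([23, config.seed, seed_offset]),
        labels=config.snp_labels,
    )
    rng = np.random.default_rng([29, config.seed, seed_offset])
    _, _, _, liab = _cascade(
        geno_df.to_numpy(float), e1, e2, e3, truth.liability_weights, config.noise_sd, rng
    )
    if config.liability_intercept is None:
        intercept = _calibrate_intercept(liab, config.prevalence)
    else:
        intercept = float(config.liability_intercept)
    labels = rng.binomial(1, _sigmoid(liab + intercept))
    return EndToEndDataset(
        genotypes=geno_df,
        labels=pd.Series(labels, index=geno_df.index, name="diagnosis"),
    )


def dominant_chain_config(
    n_snps: int = 40,
    n_isoforms: int = 12,
    n_markers: int = 8,
    n_phenotypes: int = 4,
    effect_size: float = 2.0,
    background_sparsity: float = 0.08,
    seed: int = 0,
    **overrides,
) -> SynthConfig:
    """A config whose first SNP drives a strong explicit chain to disease.

    ``snp0000`` gets planted effects into the first three isoforms; those feed
    the first two markers, which feed the first phenotype, which dominates the
    liability.  Background effects at ``background_sparsity`` make recovery
    non-trivial.  Used for impact-score and screening recovery checks.
    """
    cfg = SynthConfig(
        n_snps=n_snps,
        n_isoforms=n_isoforms,
        n_markers=n_markers,
        n_phenotypes=n_phenotypes,
        effect_size=effect_size,
        seed=seed,
        **overrides,
    )
    rng = np.random.default_rng([31, seed])
    e1 = _effect_matrix(rng, (n_snps, n_isoforms), effect_size * 0.5, background_sparsity)
    e2 = _effect_matrix(rng, (n_isoforms, n_markers), effect_size * 0.5, background_sparsity)
    e3 = _effect_matrix(rng, (n_markers, n_phenotypes), effect_size * 0.5, background_sparsity)
    e1[0, :3] = effect_size
    e2[:3, :2] = effect_size
    e3[:2, 0] = effect_size
    beta = rng.normal(0, 0.3, size=n_phenotypes)
    beta[0] = 3.0
    return replace(cfg, effect_matrices=(e1, e2, e3), liability_weights=beta)
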