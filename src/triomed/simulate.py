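"""Synthetic genotype/expression/covariate data with known mediation structure.

The generator mirrors the generative form of the trio regressions:

    C = b1*G + g.Cov + lC.h + e1
    T = b3*C + b4*G + g.Cov + lT.h + e3

with Hardy-Weinberg genotypes (dosage ~ Binomial(2, f), allele frequency f
drawn uniformly from the MAF range), Gaussian noise, optional known
covariates, and optional hidden factors h loading on both transcripts (the
confounding scenario the adaptive adjustment is meant to absorb).  Each trio
carries a truth label (b3 = 0 or not) so type-I error and power of every
scheme/adjustment combination can be measured end to end.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CovariateMatrix, ExpressionVector, GenotypeVector


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate a bulk-brain eQTL cohort: ~300 donors, common variants
    (MAF 0.05-0.5), unit-variance Gaussian expression noise, moderate cis
    effect and mediation effect of half the noise scale.
    """

    n_samples: int = 300
    n_trios: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    beta1: float = 1.0          # cis eQTL effect G -> C
    beta3: float | tuple[float, float] = 0.5  # mediation effect C -> T (non-null trios)
    beta4: float = 0.3          # direct effect G -> T
    fraction_null: float = 0.5  # trios simulated with beta3 = 0
    n_known_covariates: int = 2
    covariate_effect: float = 0.3
    n_hidden: int = 0           # hidden factors loading on both C and T
    confounder_scale: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if not 0.0 <= self.fraction_null <= 1.0:
            raise ValueError("fraction_null must be in [0, 1]")


@dataclass
class SimulatedStudy:
    """A complete synthetic study plus its ground truth."""

    sample_ids: list[str]
    genotypes: pd.DataFrame            # samples x variants (0/1/2)
    expression: pd.DataFrame           # genes x samples
    covariates: pd.DataFrame           # samples x covariates
    hidden_factors: np.ndarray         # samples x n_hidden
    truth: pd.DataFrame                # per-trio true effects and null labels

    def trio_vectors(
        self, i: int
    ) -> tuple[GenotypeVector, ExpressionVector, ExpressionVector, CovariateMatrix]:
        row = self.truth.iloc[i]
        G = GenotypeVector(
            self.genotypes[row.variant_id].to_numpy(),
            self.sample_ids,
            row.variant_id,
        )
        C = ExpressionVector(
            self.expression.loc[row.cis_gene_id].to_numpy(),
            self.sample_ids,
            row.cis_gene_id,
        )
        T = ExpressionVector(
            self.expression.loc[row.trans_gene_id].to_numpy(),
            self.sample_ids,
            row.trans_gene_id,
        )
        Cov = CovariateMatrix(
            self.covariates.to_numpy(),
            list(self.covariates.columns),
            self.sample_ids,
        )
        return G, C, T, Cov


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Hardy-Weinberg dosages, one column per trio's variant.

    Monomorphic draws (possible at low MAF and small n) are regenerated so
    every variant is testable.
    """
    n, m = config.n_samples, config.n_trios
    lo, hi = config.maf_range
    out = np.empty((n, m), dtype=float)
    for j in range(m):
        while True:
            f = rng.uniform(lo, hi)
            g = rng.binomial(2, f, size=n).astype(float)
            if len(np.unique(g)) >= 2:
                out[:, j] = g
                break
    cols = [f"var{j + 1}" for j in range(m)]
    return pd.DataFrame(out, columns=cols)


def simulate_trio_data(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedStudy:
    """Generate a full study: genotypes, expression, covariates, truth table."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_trios
    sample_ids = [f"s{i + 1}" for i in range(n)]

    geno = simulate_genotypes(config, rng)
    geno.index = sample_ids

    n_cov = config.n_known_covariates
    cov = rng.normal(size=(n, n_cov))
    cov_names = [f"cov{j + 1}" for j in range(n_cov)]

    h = rng.normal(size=(n, config.n_hidden)) if config.n_hidden else np.empty((n, 0))

    is_null = rng.random(m) < config.fraction_null
    if isinstance(config.beta3, tuple):
        b3 = rng.uniform(*config.beta3, size=m)
    else:
        b3 = np.full(m, float(config.beta3))
    b3[is_null] = 0.0

    expr_rows = {}
    truth_rows = []
    for j in range(m):
        g = geno.iloc[:, j].to_numpy()
        gamma_c = rng.normal(0, config.covariate_effect, size=n_cov)
        gamma_t = rng.normal(0, config.covariate_effect, size=n_cov)
        lam_c = rng.normal(0, config.confounder_scale, size=config.n_hidden)
        lam_t = rng.normal(0, config.confounder_scale, size=config.n_hidden)
        c = (
            config.beta1 * g
            + cov @ gamma_c
            + h @ lam_c
            + rng.normal(0, config.noise_sd, size=n)
        )
        t = (
            b3[j] * c
            + config.beta4 * g
            + cov @ gamma_t
            + h @ lam_t
            + rng.normal(0, config.noise_sd, size=n)
        )
        expr_rows[f"cis{j + 1}"] = c
        expr_rows[f"trans{j + 1}"] = t
        truth_rows.append(
            {
                "trio_index": j,
                "variant_id": geno.columns[j],
                "cis_gene_id": f"cis{j + 1}",
                "trans_gene_id": f"trans{j + 1}",
                "beta1": config.beta1,
                "beta3": b3[j],
                "beta4": config.beta4,
                "is_null": bool(is_null[j]),
            }
        )

    expression = pd.DataFrame(expr_rows, index=sample_ids).T
    expression.index.name = "gene_id"
    covariates = pd.DataFrame(cov, index=sample_ids, columns=cov_names)
    covariates.index.name = "sample_id"
    return SimulatedStudy(
        sample_ids=sample_ids,
        genotypes=geno,
        expression=expression,
        covariates=covariates,
        hidden_factors=h,
        truth=pd.DataFrame(truth_rows),
    )


def simulate_single_trio(
    n_samples: int,
    rng: np.random.Generator,
    maf: float = 0.3,
    beta1: float = 1.0,
    beta3: float = 0.0,
    beta4: float = 0.3,
    noise_sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One (G, C, T) trio as plain arrays; handy for calibration loops."""
    while True:
        g = rng.binomial(2, maf, size=n_samples).astype(float)
        if len(np.unique(g)) >= 2:
            break
    c = beta1 * g + rng.normal(0, noise_sd, size=n_samples)
    t = beta3 * c + beta4 * g + rng.normal(0, noise_sd, size=n_samples)
    return g, c, t
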