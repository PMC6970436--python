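"""Fixed and per-trio adaptive selection of hidden expression confounders.

Hidden structure in expression data (batch, cell-type composition, technical
covariates) biases mediation estimates when it drives both the cis and the
trans transcript.  Two strategies are supported:

* fixed: every user-supplied hidden covariate (PCs, SVs, PEER factors) enters
  the model for every trio, alongside the known covariates;
* adaptive: a pool of candidate hidden covariates (user-supplied, or the top
  principal components of the expression matrix) is screened per trio, and
  only components correlated with the cis or trans transcript (BH-FDR on
  Pearson correlation tests) are adjusted for.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import CovariateMatrix, ExpressionVector
from .fdr import bh_fdr


@dataclass
class ConfounderPool:
    """Candidate hidden covariates: samples x components score matrix."""

    components: np.ndarray
    explained_variance: np.ndarray
    source: str  # {"user_supplied", "pca_auto"}
    sample_ids: list[str] | None = None
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.components = np.atleast_2d(np.asarray(self.components, dtype=float))
        if self.names is None:
            self.names = [f"PC{j + 1}" for j in range(self.components.shape[1])]

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


@dataclass
class AdjustmentSpec:
    """How covariates enter the trio regressions."""

    mode: str  # {"fixed", "adaptive"}
    known_covariates: CovariateMatrix
    pool: ConfounderPool | None = None
    selection_fdr: float = 0.05

    def __post_init__(self) -> None:
        if self.mode not in {"fixed", "adaptive"}:
            raise ValueError(f"unknown adjustment mode {self.mode!r}")
        if self.mode == "adaptive" and self.pool is None:
            raise ValueError("adaptive adjustment requires a confounder pool")


def build_pc_pool(expression: np.ndarray, n_pcs: int = 30,
                  sample_ids: list[str] | None = None) -> ConfounderPool:
    """Principal-component scores of a genes x samples expression matrix.

    Genes are the features: each gene's profile is centered across samples
    and the samples' scores on the top ``n_pcs`` components are returned.
    Sign convention: the loading with the largest magnitude on each component
    is made positive, so results are reproducible across runs and BLAS builds.
    """
    X = np.asarray(expression, dtype=float)
    n_samples = X.shape[1]
    if n_pcs >= n_samples:
        raise ValueError("n_pcs must be smaller than the number of samples")
    Xc = (X - X.mean(axis=1, keepdims=True)).T  # samples x genes
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float((s**2).sum())
    n_pcs = min(n_pcs, len(s))
    scores = U[:, :n_pcs] * s[:n_pcs]
    for j in range(n_pcs):
        load = Vt[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] = -scores[:, j]
    ev = (s[:n_pcs] ** 2) / total_var if total_var > 0 else np.zeros(n_pcs)
    return ConfounderPool(
        components=scores,
        explained_variance=ev,
        source="pca_auto",
        sample_ids=sample_ids,
    )


def select_confounders(
    pool: ConfounderPool,
    C: ExpressionVector | np.ndarray,
    T: ExpressionVector | np.ndarray,
    fdr: float = 0.05,
) -> np.ndarray:
    """Indices of pool components correlated with the cis OR trans transcript.

    Each component is Pearson-correlation tested against C and against T;
    Benjamini-Hochberg is applied across all 2 * n_components tests, and a
    component is kept if either of its two tests is significant at ``fdr``.
    Deterministic (no RNG); an empty selection is a valid outcome.
    """
    c = np.asarray(C.values if isinstance(C, ExpressionVector) else C, float)
    t = np.asarray(T.values if isinstance(T, ExpressionVector) else T, float)
    H = pool.components
    if H.shape[0] != len(c) or len(c) != len(t):
        raise ValueError("pool and expression vectors misaligned")
    pvals = np.empty(2 * H.shape[1])
    for j in range(H.shape[1]):
        pvals[2 * j] = _pearson_p(H[:, j], c)
        pvals[2 * j + 1] = _pearson_p(H[:, j], t)
    adj = bh_fdr(pvals)
    keep = (adj[0::2] <= fdr) | (adj[1::2] <= fdr)
    return np.flatnonzero(keep)


def _pearson_p(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 1.0
    return float(stats.pearsonr(x, y).pvalue)


def assemble_cov(
    spec: AdjustmentSpec,
    C: ExpressionVector | np.ndarray | None = None,
    T: ExpressionVector | np.ndarray | None = None,
) -> CovariateMatrix:
    """Build the Cov matrix entering the trio regressions.

    Fixed mode concatenates known covariates with every pool component;
    adaptive mode concatenates known covariates with the per-trio selection
    (which needs the trio's C and T).  Duplicate covariate names raise.
    """
    known = spec.known_covariates
    if spec.pool is None or spec.pool.n_components == 0:
        return known
    if spec.mode == "fixed":
        idx = np.arange(spec.pool.n_components)
    else:
        if C is None or T is None:
            raise ValueError("adaptive adjustment needs the trio's C and T")
        idx = select_confounders(spec.pool, C, T, fdr=spec.selection_fdr)
    if idx.size == 0:
        return known
    hidden_names = [spec.pool.names[j] for j in idx]
    clash = set(hidden_names) & set(known.covariate_names)
    if clash:
        raise ValueError(f"duplicate covariate names: {sorted(clash)}")
    values = np.column_stack([known.values, spec.pool.components[:, idx]]) \
        if known.values.shape[1] else spec.pool.components[:, idx]
    return CovariateMatrix(
        values, list(known.covariate_names) + hidden_names, known.sample_ids
    )
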