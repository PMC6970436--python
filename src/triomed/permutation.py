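"""Within-genotype-group permutation null and empirical p-values.

The permutation null for the mediation statistic is built by shuffling the
cis-transcript values *within* each genotype class (AA / AB / BB).  This
breaks any mediation of the trans gene by the cis transcript while leaving
both eQTL associations (genotype -> expression) intact, so the permuted
statistics characterize the null hypothesis of no mediation specifically.

Two estimators are provided on top of the null draws:

* fixed scheme:     p = (M + 1) / (N + 1) after exactly N permutations,
* adaptive scheme:  p = min(K+1, M+1) / min(G+1, N+1), stopping the stream
  at the first permutation index G at which M (the running count of null
  statistics at least as strong as the observed |z|) reaches the pruning
  threshold K = floor(alpha * N).

M counts ties as exceedances (|z0| >= |z|), the conservative choice.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    Z_CAP,
    CovariateMatrix,
    ExpressionVector,
    GenotypeVector,
    design_matrix,
)

_BATCH = 100


@dataclass(frozen=True)
class PermutationPlan:
    """Permutation budget and pruning rule for one run."""

    n_max: int
    alpha: float = 0.05
    seed: int = 0
    scheme: str = "adaptive+gpd"

    def __post_init__(self) -> None:
        if self.scheme not in {"fixed", "adaptive", "gpd", "adaptive+gpd"}:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 1 <= self.pruning_threshold < self.n_max:
            raise ValueError("need 1 <= K < N; increase n_max or alpha")

    @property
    def pruning_threshold(self) -> int:
        """K = floor(alpha * N), at least 1."""
        return max(1, math.floor(self.alpha * self.n_max))


@dataclass
class NullStats:
    """Absolute permutation statistics |z0| actually executed for one trio."""

    values: np.ndarray
    n_executed: int
    n_failed: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("null statistics must be absolute values")
        if len(self.values) != self.n_executed:
            raise ValueError("n_executed must equal the number of statistics")


@dataclass
class EmpiricalP:
    """A permutation p-value together with how it was obtained."""

    p_value: float
    scheme: str  # {"fixed", "adaptive", "gpd"}
    M: int
    n_executed: int
    early_stopped: bool = False
    gof_p: float | None = None
    beyond_support: bool = False
    p_upper_bound: float | None = None
    gpd_failed: bool = False
    notes: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

def genotype_strata(g: np.ndarray) -> list[np.ndarray]:
    """Index arrays of the samples sharing each genotype class."""
    g = np.asarray(g)
    return [np.flatnonzero(g == v) for v in np.unique(g)]


def permutation_index_matrix(
    g: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_perm, n_samples) index matrix of within-stratum permutations.

    Each row, applied to the cis-expression vector, is one independent
    within-genotype-group shuffle; strata of size <= 1 are fixed points.
    Implemented with random-key argsort so whole batches vectorize.
    """
    n = len(g)
    idx = np.tile(np.arange(n), (n_perm, 1))
    for stratum in genotype_strata(g):
        if len(stratum) < 2:
            continue
        keys = rng.random((n_perm, len(stratum)))
        order = np.argsort(keys, axis=1)
        idx[:, stratum] = stratum[order]
    return idx


def permute_within_genotype(
    C: ExpressionVector | np.ndarray,
    G: GenotypeVector | np.ndarray,
    rng: np.random.Generator,
) -> ExpressionVector | np.ndarray:
    """One within-genotype-group shuffle of the cis-expression values.

    The multiset of expression values inside each genotype class is preserved
    exactly; values never move between classes.
    """
    c = np.asarray(C.values if isinstance(C, ExpressionVector) else C, dtype=float)
    g = np.asarray(G.values if isinstance(G, GenotypeVector) else G, dtype=float)
    idx = permutation_index_matrix(g, 1, rng)[0]
    out = c[idx]
    if isinstance(C, ExpressionVector):
        return ExpressionVector(out, list(C.sample_ids), C.gene_id)
    return out


class TrioNullSampler:
    """Draws absolute null mediation statistics for one trio, fast.

    The mediation-model t statistic of the (permuted) cis transcript equals
    the slope t statistic of residual-on-residual regression after projecting
    both T and C off the reduced design [1, G, Cov] (Frisch-Waugh), with the
    full-model residual degrees of freedom.  The projection basis is computed
    once; each permutation then costs a few matrix-vector products, and whole
    batches of permutations are evaluated as one matrix product.
    """

    def __init__(
        self,
        G: GenotypeVector | np.ndarray,
        C: ExpressionVector | np.ndarray,
        T: ExpressionVector | np.ndarray,
        Cov: CovariateMatrix | None = None,
    ) -> None:
        g = np.asarray(G.values if isinstance(G, GenotypeVector) else G, float)
        c = np.asarray(C.values if isinstance(C, ExpressionVector) else C, float)
        t = np.asarray(T.values if isinstance(T, ExpressionVector) else T, float)
        if len(np.unique(g)) < 2:
            raise ValueError("monomorphic genotype, variant untestable")
        n = len(g)
        X, names, _ = design_matrix(n, [("G", g)], Cov)
        self.g = g
        self.c = c
        self.n = n
        # full mediation model has one extra parameter (the C column)
        self.dof = n - X.shape[1] - 1
        if self.dof <= 0:
            raise ValueError("unestimable mediation model: too few samples")
        self.Q, _ = np.linalg.qr(X)
        self.e_t = t - self.Q @ (self.Q.T @ t)
        self.tt = float(self.e_t @ self.e_t)

    def statistics(self, c_matrix: np.ndarray) -> np.ndarray:
        """Absolute mediation t statistics for rows of permuted C values."""
        E = c_matrix - (c_matrix @ self.Q) @ self.Q.T
        denom = np.einsum("ij,ij->i", E, E)
        num = E @ self.e_t
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = num / denom
            rss = np.maximum(self.tt - beta**2 * denom, 0.0)
            se = np.sqrt(rss / self.dof / denom)
            z = np.where(se > 0, beta / se, np.sign(beta) * Z_CAP)
        z = np.where(denom <= 1e-12 * max(self.tt, 1.0), np.nan, z)
        return np.abs(np.clip(z, -Z_CAP, Z_CAP))

    def nominal(self) -> float:
        """Signed nominal z for the unpermuted cis transcript."""
        E = self.c - self.Q @ (self.Q.T @ self.c)
        denom = float(E @ E)
        if denom <= 1e-12 * max(self.tt, 1.0):
            raise ValueError("cis transcript collinear with genotype/covariates")
        beta = float(E @ self.e_t) / denom
        rss = max(self.tt - beta**2 * denom, 0.0)
        se = math.sqrt(rss / self.dof / denom)
        if se == 0.0:
            return math.copysign(Z_CAP, beta)
        return max(min(beta / se, Z_CAP), -Z_CAP)

    def draw(self, n_perm: int, rng: np.random.Generator) -> np.ndarray:
        """n_perm absolute null statistics (NaN marks a failed permutation)."""
        idx = permutation_index_matrix(self.g, n_perm, rng)
        return self.statistics(self.c[idx])


def null_statistics(
    G: GenotypeVector | np.ndarray,
    C: ExpressionVector | np.ndarray,
    T: ExpressionVector | np.ndarray,
    Cov: CovariateMatrix | None,
    n: int,
    rng: np.random.Generator,
    max_failed_fraction: float = 0.10,
) -> NullStats:
    """Draw ``n`` within-genotype-group permutation null statistics.

    Permutations whose fit degenerates (e.g. the permuted transcript becomes
    collinear with the design) are recorded as failures and redrawn are NOT
    attempted; more than ``max_failed_fraction`` failures aborts the trio.
    """
    if n < 1:
        raise ValueError("need at least one permutation")
    sampler = TrioNullSampler(G, C, T, Cov)
    out = []
    n_failed = 0
    done = 0
    while done < n:
        b = min(_BATCH, n - done)
        z = sampler.draw(b, rng)
        bad = ~np.isfinite(z)
        n_failed += int(bad.sum())
        out.append(z[~bad])
        done += b
    if n_failed > max_failed_fraction * n:
        raise RuntimeError(
            f"{n_failed}/{n} permutations failed; trio aborted"
        )
    values = np.concatenate(out) if out else np.empty(0)
    return NullStats(values=values, n_executed=len(values), n_failed=n_failed)


# ---------------------------------------------------------------------------
# empirical p-values
# ---------------------------------------------------------------------------

def exceedance_count(z_abs: float, values: np.ndarray) -> int:
    """Number of null statistics at least as strong as |z| (ties count)."""
    return int(np.count_nonzero(np.asarray(values) >= z_abs))


def p_fixed(z_abs: float, null: NullStats) -> EmpiricalP:
    """Fixed-scheme empirical p-value (M + 1) / (N + 1)."""
    if null.n_executed < 1:
        raise ValueError("empty null distribution")
    M = exceedance_count(z_abs, null.values)
    return EmpiricalP(
        p_value=(M + 1) / (null.n_executed + 1),
        scheme="fixed",
        M=M,
        n_executed=null.n_executed,
        early_stopped=False,
    )


def adaptive_p_from_stream(
    z_abs: float, stream: np.ndarray, plan: PermutationPlan
) -> tuple[EmpiricalP, NullStats]:
    """Apply the adaptive stopping rule to an ordered null-statistic stream.

    Scans the running exceedance count element-wise; the executed count G is
    the exact index at which it first reaches K (or the stream length).  The
    returned NullStats contains exactly the executed prefix, so it can be
    reused for tail modeling.
    """
    stream = np.asarray(stream, dtype=float)
    K = plan.pruning_threshold
    N = plan.n_max
    exceed = stream >= z_abs
    cum = np.cumsum(exceed)
    hit = np.flatnonzero(cum >= K)
    if hit.size:
        gamma = int(hit[0]) + 1
        M = K
        early = True
    else:
        gamma = len(stream)
        M = int(cum[-1]) if gamma else 0
        early = False
    p = min(K + 1, M + 1) / min(gamma + 1, N + 1)
    executed = stream[:gamma]
    return (
        EmpiricalP(
            p_value=p,
            scheme="adaptive",
            M=M,
            n_executed=gamma,
            early_stopped=early,
        ),
        NullStats(values=executed, n_executed=gamma),
    )


def p_adaptive(
    G: GenotypeVector | np.ndarray,
    C: ExpressionVector | np.ndarray,
    T: ExpressionVector | np.ndarray,
    Cov: CovariateMatrix | None,
    plan: PermutationPlan,
    rng: np.random.Generator,
    z_abs: float | None = None,
) -> tuple[EmpiricalP, NullStats]:
    """Adaptive-scheme p-value with early stopping.

    Permutations run in batches of 100; after each batch the stopping rule is
    checked element-wise inside the batch, so the reported executed count is
    the exact permutation index at which the K-th exceedance occurred.
    """
    sampler = TrioNullSampler(G, C, T, Cov)
    if z_abs is None:
        z_abs = abs(sampler.nominal())
    K = plan.pruning_threshold
    N = plan.n_max
    chunks: list[np.ndarray] = []
    m_before = 0
    executed_before = 0
    n_failed = 0
    while executed_before < N:
        b = min(_BATCH, N - executed_before)
        z = sampler.draw(b, rng)
        bad = ~np.isfinite(z)
        n_failed += int(bad.sum())
        if n_failed > 0.10 * N:
            raise RuntimeError("too many failed permutations; trio aborted")
        z = z[~bad]
        chunks.append(z)
        cum = m_before + np.cumsum(z >= z_abs)
        hit = np.flatnonzero(cum >= K)
        if hit.size:
            stop_at = int(hit[0]) + 1
            chunks[-1] = z[:stop_at]
            break
        m_before = int(cum[-1]) if len(z) else m_before
        executed_before += len(z)
    stream = np.concatenate(chunks) if chunks else np.empty(0)
    result, null = adaptive_p_from_stream(z_abs, stream, plan)
    null.n_failed = n_failed
    return result, null


def adaptive_p_value(M: int, gamma: int, plan: PermutationPlan) -> float:
    """Closed-form adaptive estimator min(K+1, M+1) / min(G+1, N+1)."""
    K = plan.pruning_threshold
    return min(K + 1, M + 1) / min(gamma + 1, plan.n_max + 1)
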