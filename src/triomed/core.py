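"""Linear-model machinery for eQTL mediation trios.

A *trio* is an eQTL variant ``L``, the local gene ``C`` it regulates in cis,
and a distant gene ``T`` it is associated with in trans.  The mediation
hypothesis is that the trans effect of ``L`` on ``T`` is carried by the
transcript of ``C``.  Three nested ordinary-least-squares models are used:

    C = a1 + b1*G + Cov*g1 + e1        (cis association)
    T = a2 + b2*G + Cov*g2 + e2        (trans association)
    T = a3 + b3*C + b4*G + Cov*g3 + e3 (mediation model)

where ``G`` is the additive genotype dosage (0/1/2) of ``L``.  The nominal
mediation statistic is ``z = b3 / se(b3)``; the null hypothesis is b3 = 0.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: |z| reported when se(b3) underflows instead of returning infinity.
Z_CAP = 1e8

#: relative residual-norm threshold below which a design column is
#: considered collinear with the columns before it and dropped.
_COLLINEAR_TOL = 1e-10

_COND_WARN = 1e10


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenotypeVector:
    """Additive dosage codes (0/1/2 allele counts) for one variant."""

    values: np.ndarray
    sample_ids: list[str]
    variant_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.sample_ids):
            raise ValueError("genotype values and sample_ids must align")
        finite = self.values[np.isfinite(self.values)]
        if not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError(
                f"{self.variant_id}: genotype dosages must be 0/1/2 (or missing)"
            )

    @property
    def n_groups(self) -> int:
        return len(np.unique(self.values[np.isfinite(self.values)]))


@dataclass
class ExpressionVector:
    """Normalized expression levels for one gene, aligned to sample_ids."""

    values: np.ndarray
    sample_ids: list[str]
    gene_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.sample_ids):
            raise ValueError("expression values and sample_ids must align")


@dataclass
class CovariateMatrix:
    """Samples x covariates numeric matrix with named columns."""

    values: np.ndarray
    covariate_names: list[str]
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.covariate_names):
            raise ValueError("covariate matrix / names mismatch")
        if len(set(self.covariate_names)) != len(self.covariate_names):
            raise ValueError("duplicate covariate names")
        keep = []
        for j in range(self.values.shape[1]):
            if np.ptp(self.values[:, j]) == 0.0:
                warnings.warn(
                    f"dropping zero-variance covariate {self.covariate_names[j]!r}"
                )
            else:
                keep.append(j)
        if len(keep) != self.values.shape[1]:
            self.values = self.values[:, keep]
            self.covariate_names = [self.covariate_names[j] for j in keep]

    @classmethod
    def empty(cls, n_samples: int) -> "CovariateMatrix":
        return cls(np.empty((n_samples, 0)), [])

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class Trio:
    """One (variant, cis-gene, trans-gene) mediation test unit."""

    variant_id: str
    cis_gene_id: str
    trans_gene_id: str
    cis_assoc_p: float | None = None
    trans_assoc_p: float | None = None

    def __post_init__(self) -> None:
        if self.cis_gene_id == self.trans_gene_id:
            raise ValueError("cis and trans gene must differ in a trio")


@dataclass
class LinearFit:
    """Coefficients, standard errors and t statistics of one OLS fit."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_statistics: np.ndarray
    p_values: np.ndarray
    residuals: np.ndarray
    n_samples: int
    dof: int
    term_names: list[str]
    dropped_terms: list[str] = field(default_factory=list)
    condition_number: float = np.nan
    degenerate: bool = False

    def __getitem__(self, term: str) -> dict[str, float]:
        i = self.term_names.index(term)
        return {
            "coef": float(self.coefficients[i]),
            "se": float(self.standard_errors[i]),
            "t": float(self.t_statistics[i]),
            "p": float(self.p_values[i]),
        }


# ---------------------------------------------------------------------------
# OLS core
# ---------------------------------------------------------------------------

def _drop_collinear(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Keep a maximal full-rank prefix-ordered subset of columns.

    Columns are scanned left to right; a column whose residual against the
    already-kept columns is (relatively) null is dropped, so the first
    occurrence of any collinear group survives.
    """
    kept_cols: list[np.ndarray] = []
    kept_names: list[str] = []
    dropped: list[str] = []
    Q: np.ndarray | None = None
    for j in range(X.shape[1]):
        col = X[:, j]
        resid = col if Q is None else col - Q @ (Q.T @ col)
        scale = np.linalg.norm(col)
        if scale == 0.0 or np.linalg.norm(resid) <= _COLLINEAR_TOL * max(scale, 1.0):
            dropped.append(names[j])
            continue
        kept_cols.append(col)
        kept_names.append(names[j])
        q = resid / np.linalg.norm(resid)
        Q = q[:, None] if Q is None else np.column_stack([Q, q])
    if dropped:
        warnings.warn(f"dropping collinear design columns: {dropped}")
    return np.column_stack(kept_cols), kept_names, dropped


def design_matrix(
    n_samples: int,
    design_columns: list[tuple[str, np.ndarray]],
    covariates: CovariateMatrix | None,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Assemble [intercept | design columns | covariates] and prune collinearity."""
    cols = [np.ones(n_samples)]
    names = ["intercept"]
    for name, v in design_columns:
        v = np.asarray(v, dtype=float)
        if v.shape != (n_samples,):
            raise ValueError(f"design column {name!r} misaligned")
        cols.append(v)
        names.append(name)
    if covariates is not None and covariates.values.shape[1]:
        if covariates.values.shape[0] != n_samples:
            raise ValueError("covariates misaligned with response")
        cols.extend(covariates.values.T)
        names.extend(covariates.covariate_names)
    return _drop_collinear(np.column_stack(cols), names)


def fit_ols(
    response: ExpressionVector | np.ndarray,
    design_columns: list[tuple[str, np.ndarray]],
    covariates: CovariateMatrix | None = None,
) -> LinearFit:
    """QR-based least squares with intercept.

    Collinear columns are dropped deterministically (first occurrence kept).
    Raises if the model is unestimable (no residual degrees of freedom).
    """
    y = np.asarray(
        response.values if isinstance(response, ExpressionVector) else response,
        dtype=float,
    )
    n = y.shape[0]
    X, names, dropped = design_matrix(n, design_columns, covariates)
    p = X.shape[1]
    dof = n - p
    if dof <= 0:
        raise ValueError(f"unestimable model: n={n} samples, {p} parameters")

    Q, R = np.linalg.qr(X)
    rdiag = np.abs(np.diag(R))
    if rdiag.min() <= 0:
        raise ValueError("unestimable model: rank-deficient design after dropping")
    cond = rdiag.max() / rdiag.min()
    if cond > _COND_WARN:
        warnings.warn(f"ill-conditioned design (condition number ~{cond:.2e})")

    qty = Q.T @ y
    beta = np.linalg.solve(R, qty)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = rss / dof
    Rinv = np.linalg.solve(R, np.eye(p))
    se = np.sqrt(np.maximum(sigma2 * np.einsum("ij,ij->i", Rinv, Rinv), 0.0))

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.sign(beta) * Z_CAP)
    degenerate = bool((se <= 0).any() or (np.abs(tstat) >= Z_CAP).any())
    tstat = np.clip(tstat, -Z_CAP, Z_CAP)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)

    return LinearFit(
        coefficients=beta,
        standard_errors=se,
        t_statistics=tstat,
        p_values=pvals,
        residuals=resid,
        n_samples=n,
        dof=dof,
        term_names=names,
        dropped_terms=dropped,
        condition_number=float(cond),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# trio regressions
# ---------------------------------------------------------------------------

def _check_genotype(G: GenotypeVector | np.ndarray) -> np.ndarray:
    g = np.asarray(G.values if isinstance(G, GenotypeVector) else G, dtype=float)
    if len(np.unique(g)) < 2:
        vid = G.variant_id if isinstance(G, GenotypeVector) else "genotype"
        raise ValueError(f"{vid}: monomorphic genotype, variant untestable")
    return g


def cis_association(
    G: GenotypeVector | np.ndarray,
    C: ExpressionVector | np.ndarray,
    Cov: CovariateMatrix | None = None,
) -> LinearFit:
    """Fit C ~ 1 + G + Cov; the genotype slope is the cis-eQTL effect b1."""
    g = _check_genotype(G)
    return fit_ols(C, [("G", g)], Cov)


def trans_association(
    G: GenotypeVector | np.ndarray,
    T: ExpressionVector | np.ndarray,
    Cov: CovariateMatrix | None = None,
) -> LinearFit:
    """Fit T ~ 1 + G + Cov; the genotype slope is the trans-eQTL effect b2."""
    g = _check_genotype(G)
    return fit_ols(T, [("G", g)], Cov)


def mediation_fit(
    G: GenotypeVector | np.ndarray,
    C: ExpressionVector | np.ndarray,
    T: ExpressionVector | np.ndarray,
    Cov: CovariateMatrix | None = None,
) -> LinearFit:
    """Fit the mediation model T ~ 1 + C + G + Cov."""
    g = _check_genotype(G)
    c = np.asarray(C.values if isinstance(C, ExpressionVector) else C, dtype=float)
    return fit_ols(T, [("C", c), ("G", g)], Cov)


def mediation_statistic(
    G: GenotypeVector | np.ndarray,
    C: ExpressionVector | np.ndarray,
    T: ExpressionVector | np.ndarray,
    Cov: CovariateMatrix | None = None,
) -> float:
    """Nominal mediation statistic z = b3 / se(b3), sign preserved.

    |z| is capped at ``Z_CAP`` when the standard error underflows (perfect
    mediation on noiseless data) instead of returning infinity.
    """
    fit = mediation_fit(G, C, T, Cov)
    return fit["C"]["t"]


# ---------------------------------------------------------------------------
# sample alignment
# ---------------------------------------------------------------------------

def complete_cases(
    G: GenotypeVector,
    C: ExpressionVector,
    T: ExpressionVector,
    Cov: CovariateMatrix | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, CovariateMatrix | None, list[str]]:
    """Align on shared sample ids and drop samples missing any value.

    Sample order follows the genotype vector.  Returns plain aligned arrays
    plus the retained sample ids.
    """
    idx_c = {s: i for i, s in enumerate(C.sample_ids)}
    idx_t = {s: i for i, s in enumerate(T.sample_ids)}
    idx_v = (
        {s: i for i, s in enumerate(Cov.sample_ids)}
        if Cov is not None and Cov.sample_ids is not None
        else None
    )
    g_list, c_list, t_list, v_list, ids = [], [], [], [], []
    for i, s in enumerate(G.sample_ids):
        if s not in idx_c or s not in idx_t:
            continue
        if idx_v is not None and s not in idx_v:
            continue
        gv = G.values[i]
        cv = C.values[idx_c[s]]
        tv = T.values[idx_t[s]]
        row = None
        if Cov is not None and Cov.values.shape[1]:
            row = Cov.values[idx_v[s] if idx_v is not None else i]
            if not np.isfinite(row).all():
                continue
        if not (np.isfinite(gv) and np.isfinite(cv) and np.isfinite(tv)):
            continue
        g_list.append(gv)
        c_list.append(cv)
        t_list.append(tv)
        if row is not None:
            v_list.append(row)
        ids.append(s)
    cov_out = None
    if Cov is not None and Cov.values.shape[1]:
        cov_out = CovariateMatrix(np.array(v_list), list(Cov.covariate_names), ids)
    return (
        np.array(g_list),
        np.array(c_list),
        np.array(t_list),
        cov_out,
        ids,
    )


# ---------------------------------------------------------------------------
# candidate-trio construction
# ---------------------------------------------------------------------------

def build_candidate_trios(
    cis_table: pd.DataFrame,
    trans_table: pd.DataFrame,
    cis_fdr_threshold: float = 0.05,
    trans_p_threshold: float = 1e-8,
) -> list[Trio]:
    """Join significant cis and trans associations sharing a variant.

    One trio per (variant, cis gene, trans gene) combination where the cis
    association passes ``fdr <= cis_fdr_threshold`` and the trans association
    passes ``p < trans_p_threshold``.  A missing ``fdr`` column on the cis
    table is filled with Benjamini-Hochberg adjusted p-values.
    """
    cis = cis_table.copy()
    if "fdr" not in cis.columns:
        from .fdr import bh_fdr

        cis["fdr"] = bh_fdr(cis["p"].to_numpy())
    cis_sig = cis[cis["fdr"] <= cis_fdr_threshold]
    trans_sig = trans_table[trans_table["p"] < trans_p_threshold]
    merged = cis_sig.merge(
        trans_sig, on="variant_id", suffixes=("_cis", "_trans")
    )
    merged = merged[merged["gene_id_cis"] != merged["gene_id_trans"]]
    if merged.empty:
        warnings.warn("no candidate trios pass the cis/trans thresholds")
        return []
    merged = merged.sort_values(
        ["variant_id", "gene_id_cis", "gene_id_trans"], kind="mergesort"
    )
    return [
        Trio(
            variant_id=r.variant_id,
            cis_gene_id=r.gene_id_cis,
            trans_gene_id=r.gene_id_trans,
            cis_assoc_p=float(r.p_cis),
            trans_assoc_p=float(r.p_trans),
        )
        for r in merged.itertuples(index=False)
    ]


def best_trio_per_gene_pair(
    trio_table: pd.DataFrame, p_column: str = "cis_assoc_p"
) -> pd.DataFrame:
    """Keep, per unique (cis gene, trans gene) pair, the trio minimizing a p-value.

    ``p_column`` selects the criterion: the cis-association p-value (pick the
    strongest cis-eQTL for the mediator) or the nominal mediation p-value
    (pick the strongest mediation signal).  Ties break on lexicographic
    variant id.
    """
    required = {"variant_id", "cis_gene_id", "trans_gene_id", p_column}
    missing = required - set(trio_table.columns)
    if missing:
        raise ValueError(f"trio table missing columns: {sorted(missing)}")
    ordered = trio_table.sort_values(
        [p_column, "variant_id"], kind="mergesort"
    )
    best = ordered.groupby(
        ["cis_gene_id", "trans_gene_id"], sort=True, as_index=False
    ).head(1)
    return best.sort_values(
        ["cis_gene_id", "trans_gene_id"], kind="mergesort"
    ).reset_index(drop=True)
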