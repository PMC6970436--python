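"""File readers/writers and the end-to-end mediation run.

Formats (all plain text):

* genotype TSV — header ``sample_id`` then variant ids, one row per sample,
  dosages 0/1/2 (blank/NA = missing);
* genotype VCF — standard VCF 4.x, GT field only, biallelic sites required;
* expression TSV — genes x samples, first column ``gene_id``;
* covariates TSV — samples x covariates, first column ``sample_id``;
* trio list TSV — columns ``variant_id``, ``cis_gene_id``, ``trans_gene_id``;
* association TSV — columns ``variant_id``, ``gene_id``, ``beta``, ``se``,
  ``p`` (cis tables may carry ``fdr``).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gpd as gpd_mod
from . import permutation as perm_mod
from .confounders import AdjustmentSpec, ConfounderPool, assemble_cov, build_pc_pool
from .core import (
    CovariateMatrix,
    ExpressionVector,
    GenotypeVector,
    Trio,
    best_trio_per_gene_pair,
    cis_association,
    complete_cases,
    mediation_fit,
    trans_association,
)
from .fdr import storey_tibshirani_qvalues
from .permutation import PermutationPlan

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "variant_id", "cis_gene_id", "trans_gene_id", "n_samples", "z",
    "nominal_p", "scheme", "n_perm_executed", "M", "p_perm", "p_source",
    "gof_p", "q_value", "status",
]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_genotypes(path: str, fmt: str = "tsv") -> pd.DataFrame:
    """Samples x variants dosage table from TSV or VCF."""
    if fmt == "tsv":
        return read_genotypes_tsv(path)
    if fmt == "vcf":
        return read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def read_genotypes_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "sample_id":
        raise ValueError(
            f"{path}: first genotype column must be 'sample_id', got {df.columns[0]!r}"
        )
    df = df.set_index("sample_id")
    values = df.to_numpy(dtype=float)
    finite = values[np.isfinite(values)]
    if not np.isin(finite, (0.0, 1.0, 2.0)).all():
        raise ValueError(f"{path}: dosages must be 0/1/2 or missing")
    return df.astype(float)


def read_genotypes_vcf(path: str) -> pd.DataFrame:
    """Parse GT fields of a VCF into 0/1/2 dosages (missing -> NaN).

    Multi-allelic records are rejected; split them upstream (e.g. with
    ``bcftools norm -m-``) before loading.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            raise ValueError(
                f"{path}: record {i + 1} ({rec.CHROM}:{rec.POS}) is multi-allelic; "
                "split it before loading"
            )
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        # rec.genotypes rows are [allele1, allele2, phased]; -1 marks missing
        dosage = np.array(
            [gt[0] + gt[1] if gt[0] >= 0 and gt[1] >= 0 else np.nan
             for gt in rec.genotypes],
            dtype=float,
        )
        cols[vid] = dosage
    df = pd.DataFrame(cols, index=samples)
    df.index.name = "sample_id"
    return df


def read_expression(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene_id":
        raise ValueError(f"{path}: first expression column must be 'gene_id'")
    return df.set_index("gene_id").astype(float)


def read_covariates(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "sample_id":
        raise ValueError(f"{path}: first covariate column must be 'sample_id'")
    return df.set_index("sample_id").astype(float)


def read_trios(path: str) -> list[Trio]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"variant_id", "cis_gene_id", "trans_gene_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: trio list needs columns {sorted(required)}")
    return [
        Trio(r.variant_id, r.cis_gene_id, r.trans_gene_id)
        for r in df.itertuples(index=False)
    ]


def read_association_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"variant_id", "gene_id", "p"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: association table needs columns {sorted(required)}")
    return df


# ---------------------------------------------------------------------------
# writers (simulation round trip)
# ---------------------------------------------------------------------------

def write_genotypes_tsv(df: pd.DataFrame, path: str) -> None:
    out = df.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def write_expression_tsv(df: pd.DataFrame, path: str) -> None:
    out = df.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def write_covariates_tsv(df: pd.DataFrame, path: str) -> None:
    out = df.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def write_trios_tsv(truth: pd.DataFrame, path: str) -> None:
    truth[["variant_id", "cis_gene_id", "trans_gene_id"]].to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# run configuration and driver
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything one mediation run needs (paths or preloaded frames)."""

    genotypes: pd.DataFrame
    expression: pd.DataFrame
    trios: list[Trio]
    covariates: pd.DataFrame | None = None
    hidden_covariates: pd.DataFrame | None = None  # user-supplied pool
    scheme: str = "adaptive+gpd"
    n_perm: int = 10000
    alpha: float = 0.05
    alpha_gpd: float = 0.01
    adjustment: str = "none"  # {"none", "fixed", "adaptive"}
    n_pcs: int = 30
    selection_fdr: float = 0.05
    seed: int = 0
    compute_qvalues: bool = True
    best_by: str = "nominal_p"
    verify_associations: bool = False
    cis_p_threshold: float = 0.05
    trans_p_threshold: float = 1e-8


def _trio_rng(seed: int, trio_index: int) -> np.random.Generator:
    """Per-trio RNG substream; serial and parallel runs agree."""
    return np.random.default_rng(np.random.SeedSequence((seed, trio_index)))


def _build_pool(config: RunConfig) -> ConfounderPool | None:
    if config.adjustment == "none":
        return None
    if config.hidden_covariates is not None:
        hc = config.hidden_covariates
        return ConfounderPool(
            components=hc.to_numpy(dtype=float),
            explained_variance=np.full(hc.shape[1], np.nan),
            source="user_supplied",
            sample_ids=list(hc.index),
            names=list(hc.columns),
        )
    n_pcs = min(config.n_pcs, config.expression.shape[1] - 1)
    return build_pc_pool(
        config.expression.to_numpy(dtype=float),
        n_pcs=n_pcs,
        sample_ids=list(config.expression.columns),
    )


def run_mediate(config: RunConfig) -> pd.DataFrame:
    """Run every trio through the configured scheme; one result row per trio.

    Trio-level failures (monomorphic genotype after complete-case filtering,
    unestimable models, too many failed permutations) are recorded in the
    row's ``status`` and the run continues.
    """
    plan = PermutationPlan(
        n_max=config.n_perm, alpha=config.alpha, seed=config.seed,
        scheme=config.scheme,
    )
    pool = _build_pool(config)
    known_cov = (
        CovariateMatrix(
            config.covariates.to_numpy(dtype=float),
            list(config.covariates.columns),
            list(config.covariates.index),
        )
        if config.covariates is not None
        else None
    )
    expr_samples = list(config.expression.columns)
    rows = []
    source_counts: dict[str, int] = {}
    for idx, trio in enumerate(config.trios):
        row: dict = {
            "variant_id": trio.variant_id,
            "cis_gene_id": trio.cis_gene_id,
            "trans_gene_id": trio.trans_gene_id,
        }
        try:
            rows.append(row | _run_one_trio(
                config, plan, pool, known_cov, expr_samples, trio, idx
            ))
            source_counts[rows[-1]["p_source"]] = (
                source_counts.get(rows[-1]["p_source"], 0) + 1
            )
        except (ValueError, RuntimeError, KeyError) as e:
            logger.warning("trio %s/%s/%s failed: %s",
                           trio.variant_id, trio.cis_gene_id, trio.trans_gene_id, e)
            row |= {c: np.nan for c in RESULT_COLUMNS if c not in row}
            row["status"] = f"failed: {e}"
            rows.append(row)
        if (idx + 1) % 1000 == 0:
            logger.info("processed %d/%d trios", idx + 1, len(config.trios))
    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    logger.info("p-value sources: %s", source_counts)
    if config.compute_qvalues:
        results = append_qvalues(results, best_by=config.best_by)
    return results


def _run_one_trio(
    config: RunConfig,
    plan: PermutationPlan,
    pool: ConfounderPool | None,
    known_cov: CovariateMatrix | None,
    expr_samples: list[str],
    trio: Trio,
    idx: int,
) -> dict:
    geno = config.genotypes
    expr = config.expression
    G = GenotypeVector(
        geno[trio.variant_id].to_numpy(dtype=float),
        list(geno.index), trio.variant_id,
    )
    C = ExpressionVector(
        expr.loc[trio.cis_gene_id].to_numpy(dtype=float), expr_samples,
        trio.cis_gene_id,
    )
    T = ExpressionVector(
        expr.loc[trio.trans_gene_id].to_numpy(dtype=float), expr_samples,
        trio.trans_gene_id,
    )
    # fold the hidden pool into the alignment step, then split it back out
    combined = known_cov
    n_known = known_cov.values.shape[1] if known_cov is not None else 0
    if pool is not None:
        pool_cov = CovariateMatrix(
            pool.components, list(pool.names), pool.sample_ids or expr_samples
        )
        if known_cov is not None:
            shared = [s for s in known_cov.sample_ids if s in set(pool_cov.sample_ids)]
            kidx = [known_cov.sample_ids.index(s) for s in shared]
            pidx = [pool_cov.sample_ids.index(s) for s in shared]
            combined = CovariateMatrix(
                np.column_stack([known_cov.values[kidx], pool_cov.values[pidx]]),
                list(known_cov.covariate_names) + list(pool_cov.covariate_names),
                shared,
            )
        else:
            combined = pool_cov
    g, c, t, cov_aligned, ids = complete_cases(G, C, T, combined)
    n = len(g)
    if len(np.unique(g)) < 2:
        raise ValueError("monomorphic genotype after complete-case filtering")

    if cov_aligned is None:
        cov_final = None
    elif pool is None:
        cov_final = cov_aligned
    else:
        known_part = CovariateMatrix(
            cov_aligned.values[:, :n_known],
            cov_aligned.covariate_names[:n_known], ids,
        ) if n_known else CovariateMatrix.empty(n)
        pool_part = ConfounderPool(
            components=cov_aligned.values[:, n_known:],
            explained_variance=np.full(
                cov_aligned.values.shape[1] - n_known, np.nan
            ),
            source=pool.source,
            sample_ids=ids,
            names=cov_aligned.covariate_names[n_known:],
        )
        spec = AdjustmentSpec(
            mode=config.adjustment, known_covariates=known_part,
            pool=pool_part, selection_fdr=config.selection_fdr,
        )
        cov_final = assemble_cov(spec, c, t)
        if cov_final.values.shape[1] == 0:
            cov_final = None

    status = "ok"
    if config.verify_associations:
        cis_p = cis_association(g, c, cov_final)["G"]["p"]
        trans_p = trans_association(g, t, cov_final)["G"]["p"]
        if cis_p > config.cis_p_threshold or trans_p > config.trans_p_threshold:
            status = "ok; upstream association not verified"

    fit = mediation_fit(g, c, t, cov_final)
    z = fit["C"]["t"]
    nominal_p = fit["C"]["p"]
    z_abs = abs(z)
    rng = _trio_rng(plan.seed, idx)

    if plan.scheme == "fixed":
        null = perm_mod.null_statistics(g, c, t, cov_final, plan.n_max, rng)
        ep = perm_mod.p_fixed(z_abs, null)
    elif plan.scheme == "adaptive":
        ep, _ = perm_mod.p_adaptive(g, c, t, cov_final, plan, rng, z_abs=z_abs)
    elif plan.scheme == "gpd":
        null = perm_mod.null_statistics(g, c, t, cov_final, plan.n_max, rng)
        ep = gpd_mod.p_hybrid(z_abs, null, plan, alpha_gpd=config.alpha_gpd)
    else:  # adaptive+gpd
        ep_a, null = perm_mod.p_adaptive(g, c, t, cov_final, plan, rng, z_abs=z_abs)
        ep = gpd_mod.p_hybrid(
            z_abs, null, plan, alpha_gpd=config.alpha_gpd, adaptive_result=ep_a
        )

    return {
        "n_samples": n,
        "z": z,
        "nominal_p": nominal_p,
        "scheme": plan.scheme,
        "n_perm_executed": ep.n_executed,
        "M": ep.M,
        "p_perm": ep.p_value if not ep.beyond_support else 0.0,
        "p_source": ep.scheme,
        "gof_p": ep.gof_p if ep.gof_p is not None else np.nan,
        "q_value": np.nan,
        "status": status if not ep.gpd_failed else status + "; gpd_failed",
        "_p_for_fdr": ep.p_upper_bound if ep.beyond_support else ep.p_value,
    }


def append_qvalues(results: pd.DataFrame, best_by: str = "nominal_p") -> pd.DataFrame:
    """Storey-Tibshirani q-values across unique gene pairs.

    The best trio per (cis gene, trans gene) pair is selected by ``best_by``
    (nominal mediation p by default); q-values are computed on those trios'
    permutation p-values (exact zeros from beyond-support GPD fits replaced
    by their recorded upper bounds) and merged back; non-best rows keep NaN.
    """
    results = results.copy()
    ok = results[results["p_perm"].notna()].copy()
    if ok.empty:
        return results
    if "_p_for_fdr" in ok.columns:
        ok["_p"] = ok["_p_for_fdr"].fillna(ok["p_perm"])
    else:
        ok["_p"] = ok["p_perm"]
    ok["_p"] = ok["_p"].clip(lower=np.finfo(float).tiny, upper=1.0)
    best = best_trio_per_gene_pair(ok, p_column=best_by)
    q, pi0 = storey_tibshirani_qvalues(best["_p"].to_numpy())
    logger.info("pi0 estimate across %d gene pairs: %.3f", len(best), pi0)
    key = ["variant_id", "cis_gene_id", "trans_gene_id"]
    qmap = best[key].assign(q_value=q)
    results = results.drop(columns=["q_value"]).merge(qmap, on=key, how="left")
    if "_p_for_fdr" in results.columns:
        results = results.drop(columns=["_p_for_fdr"])
    return results[RESULT_COLUMNS]


def write_results(results: pd.DataFrame, path: str, config: RunConfig | None = None) -> None:
    """Write the results TSV, with the run configuration echoed as # headers."""
    with open(path, "w") as fh:
        if config is not None:
            fh.write(
                f"# scheme={config.scheme} n_perm={config.n_perm} "
                f"alpha={config.alpha} alpha_gpd={config.alpha_gpd} "
                f"adjustment={config.adjustment} n_pcs={config.n_pcs} "
                f"seed={config.seed}\n"
            )
        cols = [c for c in RESULT_COLUMNS if c in results.columns]
        results.to_csv(fh, sep="\t", index=False, columns=cols)
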