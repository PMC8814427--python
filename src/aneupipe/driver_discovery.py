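"""Differential testing and the multi-omics intersection that nominates
aneuploidy driver genes.

A driver gene here is one whose promoter methylation is (a) differentially
altered in tumors versus normals and (b) associated with the aneuploidy
score, and whose expression passes the same two gates in the opposite
direction — promoter hyper-methylation with down-regulated expression or
the reverse, reflecting repressive promoter methylation.  The mutation
layer is handled by intersecting an externally supplied recurrent-mutation
list with the AS-associated mutated genes.

Differential testing uses per-gene Welch t-tests on each layer's working
scale (beta values for methylation, log2-normalized counts for
expression) with a fold-change gate and BH-adjusted p-values; the
intersection logic, not the test engine, carries the scientific content,
and the thresholds are explicit parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_adjust, spearman_matrix
from .clinical_survival import cox_univariable
from .enrichment import RankedList, gsea_permutation

logger = logging.getLogger(__name__)


def differential_test(matrix: pd.DataFrame, group_labels: pd.Series,
                      lfc_cut: float, q_cut: float,
                      layer: str = "methylation",
                      fc_matrix: pd.DataFrame | None = None,
                      pseudocount: float = 0.0) -> pd.DataFrame:
    """Per-gene Welch two-sample test of tumor versus normal.

    ``group_labels`` maps sample -> "tumor"/"normal".  The test statistic
    is computed on the matrix as given (its working scale: beta values,
    or log2-normalized counts).  The fold change is
    log2(mean_tumor / mean_normal) of positive-scale values — ``matrix``
    itself for beta values, or ``fc_matrix`` (e.g. normalized counts)
    when the working scale is already logarithmic — plus ``pseudocount``
    where zeros can occur.  A gene receives direction "up"/"down" only
    when |log2fc| > lfc_cut AND q < q_cut; otherwise "none".
    """
    labels = group_labels.reindex(matrix.columns)
    t_cols = labels.index[labels == "tumor"]
    n_cols = labels.index[labels == "normal"]
    if len(t_cols) < 3 or len(n_cols) < 3:
        raise ValueError("differential_test: need >= 3 samples per group")
    T = matrix[t_cols].to_numpy(dtype=float)
    N = matrix[n_cols].to_numpy(dtype=float)
    if (T.std(axis=1) == 0).all() and (N.std(axis=1) == 0).all():
        raise ValueError("differential_test: zero variance in every gene")
    fc_source = matrix if fc_matrix is None else fc_matrix.loc[matrix.index]
    Tf = fc_source[t_cols].to_numpy(dtype=float)
    Nf = fc_source[n_cols].to_numpy(dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        stat, p = stats.ttest_ind(T, N, axis=1, equal_var=False)
        log2fc = np.log2((Tf.mean(axis=1) + pseudocount)
                         / (Nf.mean(axis=1) + pseudocount))
    p = np.where(np.isfinite(p), p, np.nan)
    q = bh_adjust(p)
    direction = np.where(
        (np.abs(log2fc) > lfc_cut) & (q < q_cut),
        np.where(log2fc > 0, "up", "down"), "none")
    out = pd.DataFrame({
        "layer": layer, "log2fc": log2fc, "t_stat": stat, "p": p, "q": q,
        "direction": direction,
    }, index=matrix.index.copy())
    out.index.name = "gene"
    return out


def intersect_mutation_layer(recurrent_genes: set[str] | list[str],
                             as_related_mut_genes: set[str] | list[str]
                             ) -> set[str]:
    """Recurrently mutated genes that are also AS-associated.

    Plain set intersection; in prostate cancer this is typically empty —
    recurrent hotspot mutations and aneuploidy-associated mutations are
    disjoint gene lists.
    """
    return set(recurrent_genes) & set(as_related_mut_genes)


def intersect_layer(differential: pd.DataFrame,
                    as_related: set[str]) -> pd.DataFrame:
    """Genes both differentially altered (direction != none) and
    AS-related, retaining the direction annotation."""
    hits = differential[(differential["direction"] != "none")
                        & differential.index.isin(as_related)]
    return hits.copy()


@dataclass
class DriverCall:
    """One nominated driver with its full evidence trail."""

    gene: str
    meth_direction: str
    expr_direction: str
    meth_log2fc: float
    expr_log2fc: float
    meth_q_diff: float
    expr_q_diff: float
    meth_q_model: float
    expr_q_model: float
    meth_rho: float
    expr_rho: float
    meth_q_rho: float
    expr_q_rho: float
    reverse_consistent: bool = field(default=False)


def call_drivers(meth_intersection: pd.DataFrame,
                 expr_intersection: pd.DataFrame,
                 meth_records: pd.DataFrame,
                 expr_records: pd.DataFrame,
                 require_reverse: bool = True) -> pd.DataFrame:
    """Nominate drivers from the methylation and expression intersections.

    A gene qualifies when it appears in both intersections; with
    ``require_reverse`` (the default) the two directions must additionally
    be opposite (hyper-methylated & down-expressed, or hypo-methylated &
    up-expressed).  The association records supply the per-layer evidence
    values recorded in the output.
    """
    shared = meth_intersection.index.intersection(expr_intersection.index)
    rows = []
    for g in shared:
        md = str(meth_intersection.loc[g, "direction"])
        ed = str(expr_intersection.loc[g, "direction"])
        reverse = (md == "up" and ed == "down") or (md == "down" and ed == "up")
        if require_reverse and not reverse:
            continue
        rows.append(DriverCall(
            gene=g, meth_direction=md, expr_direction=ed,
            meth_log2fc=float(meth_intersection.loc[g, "log2fc"]),
            expr_log2fc=float(expr_intersection.loc[g, "log2fc"]),
            meth_q_diff=float(meth_intersection.loc[g, "q"]),
            expr_q_diff=float(expr_intersection.loc[g, "q"]),
            meth_q_model=float(meth_records.loc[g, "q_model"]),
            expr_q_model=float(expr_records.loc[g, "q_model"]),
            meth_rho=float(meth_records.loc[g, "rho"]),
            expr_rho=float(expr_records.loc[g, "rho"]),
            meth_q_rho=float(meth_records.loc[g, "q_rho"]),
            expr_q_rho=float(expr_records.loc[g, "q_rho"]),
            reverse_consistent=reverse,
        ))
    cols = list(DriverCall.__dataclass_fields__)
    out = pd.DataFrame([vars(r) for r in rows], columns=cols)
    return out.set_index("gene")


def discover(gene_meth: pd.DataFrame, expr_log: pd.DataFrame,
             expr_norm: pd.DataFrame, as_values: pd.Series,
             group_labels: pd.Series,
             covariates: pd.DataFrame | None = None,
             thresholds=None,
             dm_lfc: float = 0.3, dm_q: float = 0.01,
             de_lfc: float = 1.0, de_q: float = 0.01,
             require_reverse: bool = True) -> dict:
    """Run the methylation/expression arm of driver discovery in one call.

    Tumor samples (those with an AS value) feed the association models;
    all samples labelled tumor/normal feed the differential tests.
    Returns the driver table plus every intermediate (association records,
    differential tables, AS-related sets) for inspection.
    """
    from .association import Thresholds, associate_layer, select_as_related
    thresholds = thresholds or Thresholds()
    tumor = [s for s in gene_meth.columns if s in as_values.index]
    rec_meth = associate_layer(gene_meth[tumor], as_values.loc[tumor],
                               covariates=covariates, layer="methylation")
    rec_expr = associate_layer(expr_log[tumor], as_values.loc[tumor],
                               covariates=covariates, layer="expression")
    as_meth = select_as_related(rec_meth, thresholds)
    as_expr = select_as_related(rec_expr, thresholds)
    diff_meth = differential_test(gene_meth, group_labels, lfc_cut=dm_lfc,
                                  q_cut=dm_q, layer="methylation")
    diff_expr = differential_test(expr_log, group_labels, lfc_cut=de_lfc,
                                  q_cut=de_q, layer="expression",
                                  fc_matrix=expr_norm, pseudocount=1.0)
    drivers = call_drivers(intersect_layer(diff_meth, as_meth),
                           intersect_layer(diff_expr, as_expr),
                           rec_meth, rec_expr,
                           require_reverse=require_reverse)
    return {"drivers": drivers, "rec_meth": rec_meth, "rec_expr": rec_expr,
            "as_meth": as_meth, "as_expr": as_expr,
            "diff_meth": diff_meth, "diff_expr": diff_expr}


def recurrent_by_frequency(mutation: pd.DataFrame, top_k: int = 10
                           ) -> list[str]:
    """Frequency-rank fallback for a recurrent-mutation list (synthetic
    runs only; real cohorts should supply a hotspot-clustering result)."""
    freq = mutation.sum(axis=1).sort_values(ascending=False)
    return list(freq.index[:top_k])


def validate_drivers(driver_genes: list[str],
                     expr_log_matrix: pd.DataFrame,
                     gene_meth: pd.DataFrame,
                     cell_cycle_sets: dict[str, list[str]],
                     clinical: pd.DataFrame,
                     nperm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Per-driver validation: co-expression enrichment and prognosis.

    For each driver, every other gene is ranked by its Spearman
    correlation with the driver's expression and the ranking is tested
    against the supplied cell-cycle sets by permutation GSEA (the most
    significant set is reported).  Univariable Cox fits of the driver's
    methylation and expression against each available endpoint complete
    the record.  Drivers missing from the expression matrix, or with
    constant values, are flagged and skipped.
    """
    rows = []
    endpoints = [(e, f"{e}_time", f"{e}_event") for e in ("pfi", "dfs")
                 if f"{e}_time" in clinical.columns]
    for g in driver_genes:
        row: dict = {"gene": g, "flag": ""}
        if g not in expr_log_matrix.index:
            row["flag"] = "absent_from_expression"
            rows.append(row)
            continue
        y = expr_log_matrix.loc[g]
        if float(y.std()) == 0:
            row["flag"] = "constant_expression"
            rows.append(row)
            continue
        others = expr_log_matrix.drop(index=g)
        rho, _ = spearman_matrix(others.to_numpy(dtype=float),
                                 y.to_numpy(dtype=float))
        order = np.lexsort((np.asarray(others.index, dtype=object), -rho))
        ranked = RankedList([others.index[i] for i in order], rho[order])
        enr = gsea_permutation(ranked, cell_cycle_sets, nperm=nperm,
                               seed=seed)
        evaluated = enr[enr["flag"] == ""]
        if len(evaluated):
            best = evaluated["q"].idxmin()
            row.update(best_set=best,
                       es=float(evaluated.loc[best, "es"]),
                       nes=float(evaluated.loc[best, "nes"]),
                       enrichment_q=float(evaluated.loc[best, "q"]))
        for name, tcol, ecol in endpoints:
            for layer, matrix in (("expr", expr_log_matrix),
                                  ("meth", gene_meth)):
                if g not in matrix.index:
                    continue
                samples = [s for s in clinical.index
                           if s in matrix.columns]
                try:
                    fit = cox_univariable(
                        clinical.loc[samples, tcol],
                        clinical.loc[samples, ecol],
                        matrix.loc[g, samples], endpoint=name)
                except ValueError as exc:
                    row[f"{layer}_{name}_flag"] = str(exc)
                    continue
                row[f"{layer}_{name}_hr"] = fit.hr
                row[f"{layer}_{name}_ci_low"] = fit.ci_low
                row[f"{layer}_{name}_ci_high"] = fit.ci_high
                row[f"{layer}_{name}_p"] = fit.p
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")
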