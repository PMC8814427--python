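"""Cohort and probe filtering, promoter methylation aggregation, expression
normalization, and derived per-sample scores (TMB, stroma fractions, SCNA).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEX_CHROM_LABELS = {"X", "Y", "chrX", "chrY", "23", "24"}


def filter_cohort(layer_samples: Mapping[str, Iterable[str]],
                  clinical: pd.DataFrame,
                  min_days: float = 30,
                  time_col: str = "pfi_time") -> list[str]:
    """Samples present in every required omics layer with survival > min_days.

    ``layer_samples`` maps a layer name to the sample ids it covers.  The
    survival comparison is strict, so a sample at exactly ``min_days`` is
    dropped.  Order follows the clinical table.
    """
    keep = set(clinical.index)
    for layer, ids in layer_samples.items():
        ids = set(ids)
        dropped = keep - ids
        if dropped:
            logger.info("filter_cohort: %d sample(s) missing layer %s",
                        len(dropped), layer)
        keep &= ids
    out = [s for s in clinical.index
           if s in keep and clinical.loc[s, time_col] > min_days]
    if not out:
        raise ValueError("filter_cohort: no samples retained")
    return out


def filter_probes(manifest: pd.DataFrame) -> pd.Index:
    """Drop SNP-flagged, multi-hit and sex-chromosome probes."""
    chrom = manifest["chrom"].astype(str)
    bad = (manifest["snp_flag"].astype(int) != 0) \
        | (manifest["multihit_flag"].astype(int) != 0) \
        | chrom.isin(SEX_CHROM_LABELS)
    logger.info("filter_probes: removed %d of %d probes",
                int(bad.sum()), len(manifest))
    return manifest.index[~bad]


def gene_methylation(beta: pd.DataFrame, manifest: pd.DataFrame,
                     window: int = 1000) -> pd.DataFrame:
    """Gene-level promoter methylation: per gene, the mean beta over probes
    whose absolute TSS distance is at most ``window`` bp (inclusive).

    Genes with no in-window probe are absent from the output.  Only probes
    present in both the beta matrix and the manifest contribute.
    """
    m = manifest.loc[manifest.index.intersection(beta.index)]
    in_window = m["tss_distance_bp"].abs() <= window
    m = m[in_window]
    if m.empty:
        return pd.DataFrame(columns=beta.columns)
    sub = beta.loc[m.index]
    out = sub.groupby(m["gene"].to_numpy()).mean()
    out.index.name = "gene"
    return out


def normalize_counts(counts: pd.DataFrame
                     ) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame]:
    """Median-of-ratios size factors, the normalized matrix and its
    log2(x + 1) transform.

    Size factor of a sample = median over reference genes of
    count / geometric-mean(count across samples); genes whose count is zero
    in any sample are excluded from the reference (their geometric mean on
    the raw scale is zero).
    """
    if counts.shape[1] < 2:
        raise ValueError("normalize_counts: need at least 2 samples")
    if (counts < 0).to_numpy().any():
        raise ValueError("normalize_counts: negative counts")
    if (counts.sum(axis=0) == 0).any():
        bad = counts.columns[counts.sum(axis=0) == 0].tolist()
        raise ValueError(f"normalize_counts: all-zero sample(s) {bad}")
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError("normalize_counts: no gene positive in all samples")
    ref = arr[positive]
    log_geo_mean = np.mean(np.log(ref), axis=1)
    ratios = np.log(ref) - log_geo_mean[:, None]
    size_factors = pd.Series(np.exp(np.median(ratios, axis=0)),
                             index=counts.columns, name="size_factor")
    normalized = counts / size_factors
    log2 = np.log2(normalized + 1.0)
    return size_factors, normalized, log2


def compute_tmb(mutation_matrix: pd.DataFrame,
                denominator_mb: float = 38.0) -> pd.Series:
    """Tumor mutational burden: mutations per megabase of captured exome.

    The denominator defaults to 38 Mb, a pan-exome capture size.
    """
    if (mutation_matrix.to_numpy() < 0).any():
        raise ValueError("compute_tmb: negative entries")
    if denominator_mb <= 0:
        raise ValueError("compute_tmb: denominator must be positive")
    tmb = mutation_matrix.sum(axis=0) / denominator_mb
    tmb.name = "TMB"
    return tmb


def derive_fractions(purity: pd.Series,
                     leukocyte: pd.Series | None = None) -> pd.DataFrame:
    """Stroma fraction (1 - purity) and non-leukocyte stroma fraction
    (stroma - leukocyte, clamped at 0 with a logged warning)."""
    p = purity.astype(float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("derive_fractions: purity outside [0, 1]")
    stroma = 1.0 - p
    out = pd.DataFrame({"purity": p, "stroma": stroma})
    if leukocyte is not None:
        l = leukocyte.reindex(p.index).astype(float)
        if ((l < 0) | (l > 1)).any():
            raise ValueError("derive_fractions: leukocyte outside [0, 1]")
        nl = stroma - l
        clamped = nl < 0
        if clamped.any():
            logger.warning(
                "derive_fractions: leukocyte exceeds stroma for %d sample(s); "
                "non-leukocyte fraction clamped to 0", int(clamped.sum()))
        out["leukocyte"] = l
        out["non_leukocyte_stroma"] = nl.clip(lower=0.0)
    return out


def gene_cna_calls(arm_calls: pd.DataFrame,
                   gene_arms: pd.Series) -> pd.DataFrame:
    """Gene-level CNA calls inherited from the arm each gene lies on.

    ``arm_calls`` is samples x arms; ``gene_arms`` maps gene -> arm name.
    Returns genes x samples in {-1, 0, +1} (NaN where the arm call is
    missing).
    """
    known = gene_arms[gene_arms.isin(arm_calls.columns)]
    missing = len(gene_arms) - len(known)
    if missing:
        logger.warning("gene_cna_calls: %d gene(s) on arms without calls",
                       missing)
    out = arm_calls.T.reindex(known.to_numpy())
    out.index = pd.Index(known.index, name="gene")
    return out


def scna_score(gene_cna: pd.DataFrame,
               recurrent_genes: Sequence[str]) -> pd.Series:
    """Per-sample count of recurrent genes carrying a non-zero CNA call.

    Recurrent genes absent from the call matrix are skipped with a warning.
    """
    if len(recurrent_genes) == 0:
        raise ValueError("scna_score: recurrent gene list is empty")
    present = [g for g in recurrent_genes if g in gene_cna.index]
    absent = sorted(set(recurrent_genes) - set(present))
    if absent:
        logger.warning("scna_score: %d recurrent gene(s) absent from the "
                       "CNA matrix: %s", len(absent), ", ".join(absent[:10]))
    if not present:
        return pd.Series(0, index=gene_cna.columns, name="SCNA_score")
    sub = gene_cna.loc[present].fillna(0)
    score = (sub != 0).sum(axis=0)
    score.name = "SCNA_score"
    return score


def sample_scores(as_table: pd.DataFrame,
                  mutation: pd.DataFrame,
                  gene_cna: pd.DataFrame | None = None,
                  recurrent_genes: Sequence[str] | None = None,
                  leukocyte: pd.Series | None = None,
                  tmb_denominator_mb: float = 38.0) -> pd.DataFrame:
    """Assemble the per-sample score table: AS, purity, stroma fractions,
    TMB and (when inputs allow) the SCNA score."""
    out = as_table.copy()
    fr = derive_fractions(out["purity"], leukocyte)
    out = out.join(fr.drop(columns="purity"))
    out = out.join(compute_tmb(mutation, tmb_denominator_mb))
    if gene_cna is not None and recurrent_genes is not None:
        out = out.join(scna_score(gene_cna, recurrent_genes))
    return out
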