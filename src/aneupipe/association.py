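"""Per-gene covariate-adjusted association of omics layers with the
aneuploidy score (AS).

Continuous layers (promoter methylation, log-normalized expression) are
modeled by ordinary least squares::

    y_gene ~ intercept + covariates + AS

and the binary mutation layer by maximum-likelihood logistic regression on
the same design.  The reported coefficient and p-value always refer to the
AS term.  A Spearman screen and Benjamini-Hochberg adjustment complete the
record; genes pass the AS-related gate only when the regression q-value,
|rho| and the Spearman q-value all clear their thresholds (the mutation
layer uses the regression q-value alone).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    """Selection thresholds for AS-related genes."""

    q_model_max: float = 0.01
    rho_min: float = 0.3
    q_rho_max: float = 0.01


def _design(as_values: np.ndarray, covariates: pd.DataFrame | None
            ) -> np.ndarray:
    n = len(as_values)
    cols = [np.ones(n)]
    if covariates is not None and covariates.shape[1] > 0:
        cols.extend(covariates.to_numpy(dtype=float).T)
    cols.append(np.asarray(as_values, dtype=float))
    return np.column_stack(cols)


def fit_linear_matrix(Y: np.ndarray, as_values: np.ndarray,
                      covariates: pd.DataFrame | None = None
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS of every row of Y on [1, covariates, AS]; returns the AS
    coefficient, its standard error and the two-sided t-test p-value.

    The design matrix is shared across genes, so the normal equations are
    solved once.  Raises on a rank-deficient design.
    """
    X = _design(as_values, covariates)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"fit_linear: need >= {p + 2} samples, got {n}")
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("collinear design matrix")
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    xtx_inv = np.linalg.inv(X.T @ X)
    betas = Y @ X @ xtx_inv.T                     # genes x p
    resid = Y - betas @ X.T
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=1) / dof
    se = np.sqrt(np.outer(sigma2, np.diag(xtx_inv)))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = betas / se
    pvals = 2.0 * stats.t.sf(np.abs(t[:, -1]), dof)
    return betas[:, -1], se[:, -1], pvals


def fit_linear(y: np.ndarray, as_values: np.ndarray,
               covariates: pd.DataFrame | None = None
               ) -> tuple[float, float, float]:
    """AS coefficient, SE and p for a single gene (see fit_linear_matrix)."""
    b, se, p = fit_linear_matrix(np.asarray(y, float)[None, :],
                                 as_values, covariates)
    return float(b[0]), float(se[0]), float(p[0])


def fit_logistic(y_binary: np.ndarray, as_values: np.ndarray,
                 covariates: pd.DataFrame | None = None,
                 min_mutated: int = 3) -> dict:
    """Logistic fit of a binary gene profile on [1, covariates, AS].

    Returns a record with the AS coefficient, Wald SE and p, and a ``flag``
    that is non-empty when the gene was skipped (frequency gate, perfect
    separation or non-convergence) — flagged genes are excluded from
    downstream selection.
    """
    y = np.asarray(y_binary, dtype=float)
    n_mut, n_wt = int(y.sum()), int((1 - y).sum())
    if n_mut < min_mutated or n_wt < min_mutated:
        return {"beta2": np.nan, "se": np.nan, "p_model": np.nan,
                "flag": "low_frequency"}
    X = _design(as_values, covariates)
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", False):
            return {"beta2": np.nan, "se": np.nan, "p_model": np.nan,
                    "flag": "no_convergence"}
        beta2 = float(res.params[-1])
        se = float(res.bse[-1])
        if not np.isfinite(se) or se > 1e3:
            return {"beta2": np.nan, "se": np.nan, "p_model": np.nan,
                    "flag": "separation"}
        return {"beta2": beta2, "se": se,
                "p_model": float(res.pvalues[-1]), "flag": ""}
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError,
            ValueError):
        return {"beta2": np.nan, "se": np.nan, "p_model": np.nan,
                "flag": "separation"}


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho: float) -> float:
    """Exact permutation p for |rho| by enumerating all orderings (n <= 10)."""
    n = len(rx)
    denom = np.sqrt(np.sum((rx - rx.mean()) ** 2)
                    * np.sum((ry - ry.mean()) ** 2))
    count = total = 0
    target = abs(rho) - 1e-12
    xc = rx - rx.mean()
    yc = ry - ry.mean()
    for perm in itertools.permutations(range(n)):
        r = np.dot(xc, yc[list(perm)]) / denom
        count += abs(r) >= target
        total += 1
    return count / total


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman correlation with average-rank ties.

    The p-value uses the t approximation for n > 10 and an exact
    permutation enumeration for n <= 10.  Zero variance in either input
    raises (callers flag such genes instead of selecting them).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("spearman: need n >= 4")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise ValueError("spearman: zero variance input")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 10:
        p = _spearman_exact_p(rx, ry, rho)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((n - 2) / max(1.0 - rho ** 2, 1e-300))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, min(p, 1.0)


def spearman_matrix(Y: np.ndarray, x: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Spearman of Y against x (t approximation; n > 10)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    rx = stats.rankdata(x)
    rY = stats.rankdata(Y, axis=1)
    rxc = rx - rx.mean()
    rYc = rY - rY.mean(axis=1, keepdims=True)
    denom = np.sqrt((rYc ** 2).sum(axis=1) * (rxc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rYc @ rxc) / denom
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return rho, p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaN entries pass through as NaN and do not count toward the family
    size.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p[~np.isnan(p)] < 0) | (p[~np.isnan(p)] > 1)):
        raise ValueError("bh_adjust: p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def associate_layer(matrix: pd.DataFrame, as_values: pd.Series,
                    covariates: pd.DataFrame | None = None,
                    layer: str = "expression", kind: str = "linear",
                    covariate_set: str = "none",
                    min_mutated: int = 3) -> pd.DataFrame:
    """Per-gene association records for one omics layer.

    ``matrix`` is genes x samples and must share sample ids with
    ``as_values`` (and ``covariates`` if given).  Continuous layers get an
    OLS fit plus a Spearman screen; the mutation layer gets a logistic fit
    (no Spearman, matching the selection rule).  BH adjustment is applied
    within this layer/covariate-set family.
    """
    samples = [s for s in matrix.columns if s in as_values.index]
    if len(samples) < len(matrix.columns):
        logger.info("associate_layer(%s): %d sample(s) lack AS, dropped",
                    layer, len(matrix.columns) - len(samples))
    Y = matrix[samples].to_numpy(dtype=float)
    a = as_values.loc[samples].to_numpy(dtype=float)
    cov = covariates.loc[samples] if covariates is not None else None

    records = pd.DataFrame(index=matrix.index.copy())
    records.index.name = "gene"
    records["layer"] = layer
    records["covariate_set"] = covariate_set

    if np.std(a) == 0:
        # degenerate cohort (e.g. no aneuploidy at all): no association is
        # estimable; flag every record rather than fitting a singular model
        logger.warning("associate_layer(%s): AS is constant; all records "
                       "flagged", layer)
        for col in ("beta2", "p_model", "rho", "p_rho", "q_model", "q_rho"):
            records[col] = np.nan
        records["flag"] = "constant_AS"
        return records[["layer", "covariate_set", "beta2", "p_model",
                        "q_model", "rho", "p_rho", "q_rho", "flag"]]

    if kind == "logistic":
        rows = [fit_logistic(Y[i], a, cov, min_mutated=min_mutated)
                for i in range(Y.shape[0])]
        sub = pd.DataFrame(rows, index=records.index)
        records[["beta2", "p_model", "flag"]] = sub[["beta2", "p_model",
                                                     "flag"]]
        records["rho"] = np.nan
        records["p_rho"] = np.nan
    elif kind == "linear":
        constant = Y.std(axis=1) == 0
        beta2, _, p_model = fit_linear_matrix(Y, a, cov)
        rho, p_rho = spearman_matrix(Y, a)
        records["beta2"] = beta2
        records["p_model"] = p_model
        records["rho"] = rho
        records["p_rho"] = p_rho
        records["flag"] = np.where(constant, "zero_variance", "")
        records.loc[constant, ["beta2", "p_model", "rho", "p_rho"]] = np.nan
    else:
        raise ValueError(f"unknown model kind {kind!r}")

    records["q_model"] = bh_adjust(records["p_model"])
    records["q_rho"] = bh_adjust(records["p_rho"])
    return records[["layer", "covariate_set", "beta2", "p_model", "q_model",
                    "rho", "p_rho", "q_rho", "flag"]]


def select_as_related(records: pd.DataFrame,
                      thresholds: Thresholds = Thresholds(),
                      mutation_layer: bool = False) -> set[str]:
    """Genes associated with AS.

    Continuous layers require all three gates: regression q below
    ``q_model_max``, |rho| above ``rho_min`` and Spearman q below
    ``q_rho_max``.  The mutation layer uses the logistic q-value gate
    alone.  Flagged records never pass.
    """
    ok = (records["flag"] == "") & records["q_model"].notna()
    ok &= records["q_model"] < thresholds.q_model_max
    if not mutation_layer:
        ok &= records["rho"].abs() > thresholds.rho_min
        ok &= records["q_rho"] < thresholds.q_rho_max
    return set(records.index[ok])
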