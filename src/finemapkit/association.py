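"""Case-control single-variant association with imputation QC.

Implements the classical fine-mapping toolkit for a disease locus typed or
imputed in unrelated cases and controls:

* Cochran-Armitage trend test on 2x3 genotype count tables (1 df), and its
  dosage-based score-test generalisation used when genotypes are imputed;
* maximum-likelihood logistic regression (Newton-Raphson) giving per-allele
  log-odds, Wald tests and covariate adjustment;
* conditional analysis: re-testing every variant in a region with the lead
  SNP's dosage as a covariate, to ask whether any independent signal remains;
* the IMPUTE-style information measure ("info score") quantifying imputation
  certainty, and the MAF / info / significance filters used to define the
  credible risk-SNP set.

Conditional analysis is ordinary (unconditional-likelihood) logistic
regression with the lead dosage as covariate; there are no matched strata in
a population-based case-control design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .genotypes import GenotypeTable

__all__ = [
    "AssociationResult",
    "TrendResult",
    "LogisticFit",
    "InfoScore",
    "cochran_armitage_trend",
    "trend_test_dosage",
    "logistic_fit",
    "impute_info_score",
    "associate",
    "conditional_scan",
    "filter_variants",
]

RESULT_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "beta",
    "se",
    "or_",
    "chi2_trend",
    "p_trend",
    "p_wald",
    "maf",
    "info",
    "passed_qc",
]


@dataclass
class AssociationResult:
    """Per-variant association summary (one row of :func:`associate`)."""

    variant_id: str
    beta: float
    se: float
    or_: float
    chi2_trend: float
    p_trend: float
    p_wald: float
    maf: float
    info: float
    passed_qc: bool


class TrendResult(NamedTuple):
    chi2: float
    p: float
    degenerate: bool


class LogisticFit(NamedTuple):
    beta: np.ndarray
    se: np.ndarray
    wald_p: np.ndarray
    converged: bool
    n_iter: int


class InfoScore(NamedTuple):
    info: float
    degenerate: bool


def cochran_armitage_trend(counts) -> TrendResult:
    """Cochran-Armitage trend test with additive scores (0, 1, 2).

    Parameters
    ----------
    counts
        2x3 table of genotype counts: row 0 cases, row 1 controls; columns
        are copies of the counted allele (0, 1, 2 heterozygote/homozygote).

    Returns
    -------
    TrendResult
        1-df chi-square statistic and upper-tail p-value.  A table whose
        score variance is zero (e.g. a monomorphic variant) is flagged
        degenerate with ``chi2 = 0`` and ``p = 1``.
    """
    c = np.asarray(counts, dtype=float)
    if c.shape != (2, 3):
        raise ValueError("counts must be a 2x3 case/control by genotype table")
    if np.any(c < 0) or not np.allclose(c, np.round(c)):
        raise ValueError("counts must be nonnegative integers")
    if c[0].sum() == 0 or c[1].sum() == 0:
        raise ValueError("both case and control rows must be nonzero")
    w = np.array([0.0, 1.0, 2.0])
    n_j = c.sum(axis=0)
    r_j = c[0]
    N = c.sum()
    R = r_j.sum()
    num = N * (w * r_j).sum() - R * (w * n_j).sum()
    var = R * (N - R) * (N * (w**2 * n_j).sum() - (w * n_j).sum() ** 2)
    if var <= 0:
        return TrendResult(0.0, 1.0, True)
    chi2 = N * num**2 / var
    return TrendResult(float(chi2), float(stats.chi2.sf(chi2, df=1)), False)


def trend_test_dosage(dosage, phenotype) -> TrendResult:
    """Score-test form of the trend test, valid for fractional dosages.

    On hard 0/1/2 calls this coincides with :func:`cochran_armitage_trend`
    (it is the logistic-regression score statistic for the additive model).
    """
    g = np.asarray(dosage, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    ybar = y.mean()
    gc = g - g.mean()
    u = float(gc @ y)
    v = float(ybar * (1.0 - ybar) * (gc @ gc))
    if v <= 0 or ybar in (0.0, 1.0):
        return TrendResult(0.0, 1.0, True)
    chi2 = u * u / v
    return TrendResult(chi2, float(stats.chi2.sf(chi2, df=1)), False)


def logistic_fit(
    dosage,
    phenotype,
    covariates=None,
    *,
    max_iter: int = 25,
    score_tol: float = 1e-8,
) -> LogisticFit:
    """Newton-Raphson ML fit of a logistic model with intercept.

    Term order in the returned arrays: intercept, dosage (if given), then
    covariate columns.  ``dosage=None`` fits an intercept-only (or
    covariates-only) model.  Non-convergence — including quasi-complete
    separation, which drives coefficients to infinity — is reported via
    ``converged=False``; estimates are returned as-is, never silently.
    """
    y = np.asarray(phenotype, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("phenotype must be binary 0/1")
    cols = [np.ones_like(y)]
    if dosage is not None:
        cols.append(np.asarray(dosage, dtype=float))
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] == len(y) and cov.shape[1] != len(y):
            cov = cov.T
        cols.extend(list(cov))
    X = np.column_stack(cols)
    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = expit(X @ beta)
        score = X.T @ (y - p)
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        w = p * (1.0 - p)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        beta = beta + step
        if np.max(np.abs(beta)) > 40.0:  # heading to separation
            converged = False
            break
    if np.max(np.abs(beta)) > 15.0:
        # log-odds this extreme indicate (quasi-)complete separation: the
        # score can vanish numerically while the MLE is at infinity
        converged = False
    p = expit(X @ beta)
    w = p * (1.0 - p)
    H = (X * w[:, None]).T @ X
    try:
        cov_beta = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov_beta), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
        converged = False
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    wald_p = 2.0 * stats.norm.sf(np.abs(z))
    return LogisticFit(beta, se, wald_p, converged, it)


def impute_info_score(probabilities) -> InfoScore:
    """IMPUTE-style ratio-of-variances information measure.

    With per-sample triples ``(p0, p1, p2)``, ``e_i = p1 + 2 p2`` and
    ``f_i = p1 + 4 p2``::

        Is = 1 - sum_i(f_i - e_i^2) / (2 N theta (1 - theta)),  theta = sum e_i / 2N

    Hard calls give 1; a flat HWE-prior posterior gives 0.  Negative values
    are clamped to 0, values above 1 to 1.  ``theta`` of exactly 0 or 1
    (monomorphic) is degenerate and reported as 0.
    """
    p = np.asarray(probabilities, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("probabilities must be an (N, 3) array")
    if np.any(p < -1e-9) or not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("each probability triple must be nonnegative and sum to 1")
    e = p[:, 1] + 2.0 * p[:, 2]
    f = p[:, 1] + 4.0 * p[:, 2]
    n = p.shape[0]
    theta = e.sum() / (2.0 * n)
    if theta <= 0.0 or theta >= 1.0:
        return InfoScore(0.0, True)
    value = 1.0 - (f - e**2).sum() / (2.0 * n * theta * (1.0 - theta))
    return InfoScore(float(min(max(value, 0.0), 1.0)), False)


def _variant_info(table: GenotypeTable, j: int) -> float:
    if table.probabilities is None:
        return 1.0
    return impute_info_score(table.probabilities[:, j, :]).info


def associate(
    table: GenotypeTable,
    phenotype,
    *,
    maf_min: float = 0.01,
    info_min: float = 0.80,
) -> pd.DataFrame:
    """Single-variant association scan over all variants of a table.

    For each variant: allele frequency / MAF pooled over cases and controls,
    info score (1.0 when no probabilities are attached), dosage trend test,
    and a logistic fit giving per-allele log-odds, SE, OR and Wald p.
    ``passed_qc`` records the MAF/info QC only (``maf > maf_min`` and
    ``info >= info_min``); significance filtering is a separate step
    (:func:`filter_variants`).
    """
    y = np.asarray(phenotype, dtype=float)
    if len(y) != table.n_samples:
        raise ValueError("phenotype length does not match table")
    rows = []
    for j in range(table.n_variants):
        g = table.dosages[:, j]
        af = g.mean() / 2.0
        maf = min(af, 1.0 - af)
        info = _variant_info(table, j)
        trend = trend_test_dosage(g, y)
        if trend.degenerate:
            beta = se = np.nan
            p_wald = 1.0
        else:
            fit = logistic_fit(g, y)
            beta, se, p_wald = fit.beta[1], fit.se[1], fit.wald_p[1]
            if not fit.converged:
                beta = se = np.nan
                p_wald = np.nan
        var = table.variants.iloc[j]
        rows.append(
            {
                "variant_id": var["variant_id"],
                "chrom": var["chrom"],
                "pos": int(var["pos"]),
                "beta": beta,
                "se": se,
                "or_": math.exp(beta) if np.isfinite(beta) else np.nan,
                "chi2_trend": trend.chi2,
                "p_trend": trend.p,
                "p_wald": p_wald,
                "maf": maf,
                "info": info,
                "passed_qc": bool(maf > maf_min and info >= info_min),
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def filter_variants(
    results: pd.DataFrame,
    maf_min: float = 0.01,
    info_min: float = 0.80,
    p_max: float = 5.0e-7,
    *,
    p_column: str = "p_trend",
) -> pd.DataFrame:
    """Apply the risk-SNP filters: ``maf > maf_min``, ``info >= info_min``,
    ``p < p_max`` (strict inequalities on MAF and p), preserving input order.
    """
    keep = (
        (results["maf"] > maf_min)
        & (results["info"] >= info_min)
        & (results[p_column] < p_max)
    )
    return results.loc[keep].reset_index(drop=True)


def conditional_scan(
    table: GenotypeTable,
    phenotype,
    lead_id: str,
    region: tuple[str, int, int] | None = None,
) -> pd.DataFrame:
    """Re-test every variant in ``region`` with the lead SNP as covariate.

    ``region`` is ``(chrom, start, end)`` in 1-based inclusive coordinates;
    ``None`` scans the whole table.  The lead itself is excluded.  Variants
    (near-)collinear with the lead cannot be conditioned on it and are
    flagged ``collinear`` with NaN statistics.  Residual significant signal
    after conditioning indicates an independent second variant.
    """
    y = np.asarray(phenotype, dtype=float)
    lead = table.dosage_of(lead_id)
    if np.var(lead) == 0:
        raise ValueError(f"lead variant {lead_id!r} is monomorphic")
    mask = table.variants["variant_id"] != lead_id
    if region is not None:
        chrom, start, end = region
        mask &= (
            (table.variants["chrom"] == chrom)
            & (table.variants["pos"] >= start)
            & (table.variants["pos"] <= end)
        )
    idx = np.flatnonzero(mask.to_numpy())
    if len(idx) == 0:
        raise ValueError("region contains no variants besides the lead")
    rows = []
    for j in idx:
        g = table.dosages[:, j]
        var = table.variants.iloc[j]
        row = {
            "variant_id": var["variant_id"],
            "chrom": var["chrom"],
            "pos": int(var["pos"]),
            "beta": np.nan,
            "se": np.nan,
            "p": np.nan,
            "converged": False,
            "collinear": False,
        }
        if np.var(g) == 0:
            row["collinear"] = False  # monomorphic: untestable, left NaN
            rows.append(row)
            continue
        r = np.corrcoef(g, lead)[0, 1]
        if 1.0 - r**2 < 1e-8:
            row["collinear"] = True
            rows.append(row)
            continue
        fit = logistic_fit(g, y, covariates=lead[None, :].T)
        if fit.converged:
            row.update(beta=fit.beta[1], se=fit.se[1], p=fit.wald_p[1], converged=True)
        rows.append(row)
    return pd.DataFrame(rows)
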