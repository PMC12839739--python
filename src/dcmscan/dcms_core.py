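"""The DCMS composite: rank p-values, robust correlation, scoring, FDR.

The De-Correlated Composite of Multiple Signals combines one-tailed
empirical p-values of several per-SNP statistics into a single score,

    DCMS_l = sum_t  logit(1 - p_lt) / w_t ,      w_t = sum_s |r_st| ,

where r is the statistic-by-statistic correlation matrix estimated
robustly (Minimum Covariance Determinant) so that a statistic highly
correlated with the others is down-weighted. Absolute correlations are
used in the weights, which keeps w_t >= 1 and avoids sign cancellation.
The composite is then calibrated against a robust (Huber) normal fit to
give right-tailed p-values, and Storey q-values control the FDR.

Tail conventions: left-tailed for pi and Tajima's D (sweeps depress
both); right-tailed for |iHS| and |nSL| by default. The default takes
absolute standardized haplotype scores because reference-based
polarization makes their sign uninformative about sweeps; set
``signed_tails=True`` in the pipeline to right-tail the signed scores
instead (the two conventions give materially different scans).

Missing statistics (Tajima's D in windows with a single SNP, skipped
iHS cores) follow the policy: a SNP with two or more of the four
statistics missing is dropped from scoring; with exactly one missing,
the composite is the sum over the available terms with their own
weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import MinCovDet

STAT_COLUMNS = ("pi", "tajimas_d", "ihs_std", "nsl_std")
PVAL_COLUMNS = ("p_pi", "p_d", "p_ihs", "p_nsl")
TAILS = {"pi": "left", "tajimas_d": "left", "ihs_std": "right", "nsl_std": "right"}

DEFAULT_MCD_SEED = 20260119


@dataclass
class CorrelationModel:
    """Robust 4x4 correlation among the statistics plus the DCMS weights."""

    matrix: np.ndarray  # (4, 4) correlation
    column_weights: np.ndarray  # (4,) w_t = sum_s |r_st|
    mcd_alpha: float = 0.75
    mcd_nsamp: int = 50_000
    seed: int = DEFAULT_MCD_SEED

    def __post_init__(self) -> None:
        r = np.asarray(self.matrix, dtype=float)
        if r.shape[0] != r.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(r, r.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-10):
            raise ValueError("correlation matrix diagonal must be 1")
        if np.any(np.abs(r) > 1 + 1e-10):
            raise ValueError("correlations must lie in [-1, 1]")
        self.matrix = r
        self.column_weights = np.asarray(self.column_weights, dtype=float)


def stat_to_pvalue(values: np.ndarray, tail: str) -> np.ndarray:
    """Empirical one-tailed p-values, rank / (N + 1), ties sharing a p.

    Right tail: ``p_i = #{j : v_j >= v_i} / (N + 1)``; left tail uses
    ``<=``. N counts the non-missing entries; missing entries propagate
    as NaN. The N + 1 denominator keeps every p strictly inside (0, 1).
    """
    if tail not in ("right", "left"):
        raise ValueError("tail must be 'right' or 'left'")
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if not finite.any():
        raise ValueError("all values missing; cannot rank")
    n = int(finite.sum())
    out = np.full(v.shape, np.nan)
    sub = v[finite]
    # rankdata(..., 'max') of x counts #{j : x_j <= x_i}
    if tail == "right":
        counts = stats.rankdata(-sub, method="max")
    else:
        counts = stats.rankdata(sub, method="max")
    out[finite] = counts / (n + 1.0)
    return out


def robust_correlation(stat_matrix: np.ndarray, alpha: float = 0.75,
                       nsamp: int = 50_000, seed: int = DEFAULT_MCD_SEED,
                       classical_fallback: bool = False) -> CorrelationModel:
    """MCD-robust correlation among the statistics (complete rows only).

    Backed by the FAST-MCD estimator (`sklearn.covariance.MinCovDet`)
    with support fraction ``alpha``; deterministic given ``seed``.
    ``nsamp`` is recorded for provenance (the estimator controls its own
    subset sampling). Rows with any missing statistic are excluded; at
    least 50 complete rows are required. A rank-deficient robust fit
    raises unless ``classical_fallback`` is set, in which case the
    classical Pearson correlation is used instead.
    """
    x = np.asarray(stat_matrix, dtype=float)
    complete = np.isfinite(x).all(axis=1)
    xc = x[complete]
    if xc.shape[0] < 50:
        raise ValueError(
            f"need >= 50 complete rows for the MCD fit, got {xc.shape[0]}"
        )
    try:
        mcd = MinCovDet(support_fraction=alpha, random_state=seed).fit(xc)
        cov = mcd.covariance_
        d = np.sqrt(np.diag(cov))
        if np.any(d <= 0) or not np.all(np.isfinite(d)):
            raise np.linalg.LinAlgError("degenerate robust covariance")
        corr = cov / np.outer(d, d)
    except (np.linalg.LinAlgError, ValueError) as err:
        if not classical_fallback:
            raise ValueError(
                "MCD fit is rank deficient; jitter the statistics or pass "
                "classical_fallback=True"
            ) from err
        corr = np.corrcoef(xc, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    weights = np.abs(corr).sum(axis=0)
    return CorrelationModel(matrix=corr, column_weights=weights,
                            mcd_alpha=alpha, mcd_nsamp=nsamp, seed=seed)


def dcms_score(pvals: np.ndarray, model: CorrelationModel,
               max_missing: int = 1, formula: str = "per-stat") -> np.ndarray:
    """Composite DCMS score per SNP from the one-tailed p-value matrix.

    ``formula='per-stat'`` divides each statistic's logit by that
    statistic's summed absolute correlation (the de-correlating reading);
    ``'ratio-of-sums'`` divides the summed logits by the total weight, a
    sensitivity-analysis alternative. SNPs with more than ``max_missing``
    missing p-values score NaN; otherwise only available terms enter.
    """
    if formula not in ("per-stat", "ratio-of-sums"):
        raise ValueError("formula must be 'per-stat' or 'ratio-of-sums'")
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 2 or p.shape[1] != model.column_weights.size:
        raise ValueError("pvals must be N x n_stats matching the model")
    finite = np.isfinite(p)
    inside = (p > 0) & (p < 1)
    if np.any(finite & ~inside):
        raise ValueError("p-values must lie strictly inside (0, 1)")

    with np.errstate(invalid="ignore"):
        logits = np.log((1.0 - p) / p)
    w = model.column_weights
    terms = np.where(finite, logits, 0.0)
    if formula == "per-stat":
        scores = (terms / w).sum(axis=1)
    else:
        avail_w = (finite * w).sum(axis=1)
        scores = terms.sum(axis=1) / avail_w
    n_missing = (~finite).sum(axis=1)
    scores = np.where(n_missing > max_missing, np.nan, scores)
    scores = np.where(n_missing == p.shape[1], np.nan, scores)
    return scores


def huber_location_scale(x: np.ndarray, c: float = 1.345, tol: float = 1e-8,
                         max_iter: int = 50) -> tuple[float, float]:
    """Intercept-only Huber M-estimate of location with MAD-based scale.

    IRLS on the Huber psi with tuning constant ``c``; the scale is
    re-estimated each iteration as ``MAD / 0.6745`` of the residuals
    about the current location (the normal-consistent MAD). Convergence
    when the location shift falls below ``tol`` or after ``max_iter``
    iterations. Raises on zero MAD (degenerate sample).
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite values")
    mu = float(np.median(x))
    for _ in range(max_iter):
        resid = x - mu
        scale = float(np.median(np.abs(resid))) / 0.6745
        if scale == 0.0:
            raise ValueError("zero MAD: degenerate distribution, cannot calibrate")
        au = np.abs(resid / scale)
        w = np.ones_like(au)
        big = au > c
        w[big] = c / au[big]
        mu_new = float(np.sum(w * x) / np.sum(w))
        if abs(mu_new - mu) < tol:
            mu = mu_new
            break
        mu = mu_new
    resid = x - mu
    scale = float(np.median(np.abs(resid))) / 0.6745
    if scale == 0.0:
        raise ValueError("zero MAD: degenerate distribution, cannot calibrate")
    return mu, scale


def calibrate_pvalues(dcms: np.ndarray, min_n: int = 100) -> tuple[float, float, np.ndarray]:
    """Robust-normal calibration of DCMS to right-tailed p-values.

    Fits location mu and scale sigma by the Huber M-estimator and returns
    ``p_l = 1 - Phi((DCMS_l - mu) / sigma)``; NaN scores give NaN p.
    """
    d = np.asarray(dcms, dtype=float)
    finite = np.isfinite(d)
    if finite.sum() < min_n:
        raise ValueError(f"need >= {min_n} finite DCMS values, got {int(finite.sum())}")
    mu, sigma = huber_location_scale(d[finite])
    p = np.full(d.shape, np.nan)
    p[finite] = stats.norm.sf((d[finite] - mu) / sigma)
    return mu, sigma, p


def _storey_pi0(p: np.ndarray) -> float:
    """Storey's pi0: proportion of true nulls, smoothed over lambda."""
    lambdas = np.arange(0.05, 0.96, 0.05)
    n = p.size
    pi0_lambda = np.array([(p > lam).sum() / (n * (1.0 - lam)) for lam in lambdas])
    # cubic smoother evaluated at the largest lambda (qvalue-package style)
    coeffs = np.polyfit(lambdas, pi0_lambda, deg=3)
    pi0 = float(np.polyval(coeffs, lambdas[-1]))
    return min(max(pi0, 1e-8), 1.0)


def qvalues(p: np.ndarray, method: str = "storey") -> np.ndarray:
    """FDR q-values from p-values; ``storey`` (estimated pi0) or ``bh`` (pi0 = 1).

    ``q_(i) = min_{j >= i} pi0 * N * p_(j) / j`` over the ordered p-values;
    monotone non-decreasing in p and bounded by 1. NaN p-values propagate
    and do not enter N.
    """
    if method not in ("storey", "bh"):
        raise ValueError("method must be 'storey' or 'bh'")
    p = np.asarray(p, dtype=float)
    finite = np.isfinite(p)
    sub = p[finite]
    if sub.size == 0:
        raise ValueError("no finite p-values")
    if np.any(sub <= 0) or np.any(sub > 1):
        raise ValueError("p-values must lie in (0, 1]")
    n = sub.size
    pi0 = _storey_pi0(sub) if method == "storey" else 1.0
    order = np.argsort(sub, kind="mergesort")
    ranked = sub[order]
    raw = pi0 * n * ranked / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    out = np.full(p.shape, np.nan)
    out[finite] = q
    return out


def score_table(snp_frame: pd.DataFrame, mcd_alpha: float = 0.75,
                mcd_nsamp: int = 50_000, mcd_seed: int = DEFAULT_MCD_SEED,
                signed_tails: bool = False, max_missing: int = 1,
                fdr_method: str = "storey",
                formula: str = "per-stat",
                classical_fallback: bool = False) -> tuple[pd.DataFrame, CorrelationModel, float, float]:
    """Full composite scoring on a per-SNP statistics frame.

    ``snp_frame`` needs columns chrom, pos, pi, tajimas_d, ihs_std,
    nsl_std (NaN where missing); the rank transform is applied jointly
    over all rows (genome-wide). Returns the augmented frame (p_pi, p_d,
    p_ihs, p_nsl, dcms, p_dcms, q), the correlation model and the
    calibration (mu, sigma).
    """
    df = snp_frame.copy()
    hap_transform = (lambda v: v) if signed_tails else np.abs
    stat_values = {
        "pi": df["pi"].to_numpy(float),
        "tajimas_d": df["tajimas_d"].to_numpy(float),
        "ihs_std": hap_transform(df["ihs_std"].to_numpy(float)),
        "nsl_std": hap_transform(df["nsl_std"].to_numpy(float)),
    }
    pmat = np.column_stack([
        stat_to_pvalue(stat_values[c], TAILS[c]) for c in STAT_COLUMNS
    ])
    for col, name in zip(PVAL_COLUMNS, STAT_COLUMNS):
        df[col] = pmat[:, list(STAT_COLUMNS).index(name)]

    model = robust_correlation(
        np.column_stack([stat_values[c] for c in STAT_COLUMNS]),
        alpha=mcd_alpha, nsamp=mcd_nsamp, seed=mcd_seed,
        classical_fallback=classical_fallback,
    )
    df["dcms"] = dcms_score(pmat, model, max_missing=max_missing, formula=formula)
    mu, sigma, p_dcms = calibrate_pvalues(df["dcms"].to_numpy(float))
    df["p_dcms"] = p_dcms
    df["q"] = qvalues(p_dcms, method=fdr_method)
    return df, model, mu, sigma
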