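"""Correlation of texture features with a continuous covariate (age).

Association is measured by the Spearman rank correlation coefficient (SRCC,
Pearson correlation of tie-averaged ranks).  Significance comes from a
two-sided permutation test (the covariate is shuffled; the p-value is the
fraction of permutations whose absolute SRCC reaches the observed absolute
SRCC, with the same counting conventions as the group analysis), corrected
over the feature family with Holm-Bonferroni.  A bootstrap lower confidence
bound on |SRCC| — the empirical 5th percentile over resampled cohorts — is
reported as a stability check, and features with |rho| > 0.4 are flagged as
moderate-to-high correlations for reporting.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .group_stats import count_to_pvalue, feature_rng, holm_correct
from .volume_io import is_feature_column, parse_feature_column

logger = logging.getLogger(__name__)


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def spearman_rho(x, y) -> float:
    """Tie-aware Spearman rank correlation; NaN (with warning) if degenerate."""
    x, y = _paired(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("constant input: Spearman correlation undefined")
        return np.nan
    return float(stats.spearmanr(x, y).statistic)


def _rank_normalize(v: np.ndarray) -> np.ndarray | None:
    """Centered, unit-norm average ranks; None if degenerate."""
    r = stats.rankdata(v)
    r = r - r.mean()
    norm = np.sqrt((r**2).sum())
    if norm == 0:
        return None
    return r / norm


def correlation_permutation_p(
    x,
    y,
    n_permutations: int = 100_000,
    seed: int = 0,
    tie_rule: str = "ge",
    rng: np.random.Generator | None = None,
) -> float:
    """Two-sided permutation p for the SRCC (covariate values shuffled).

    Counts permutations whose |SRCC| reaches the observed |SRCC|; by default
    tie-inclusive with the +1 validity correction, as in the group analysis.
    """
    x, y = _paired(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    u = _rank_normalize(x)
    w = _rank_normalize(y)
    if u is None or w is None:
        logger.warning("constant input: permutation p undefined")
        return np.nan
    obs = abs(float(u @ w))
    if rng is None:
        rng = np.random.default_rng(seed)
    n = x.size
    count = 0
    remaining = n_permutations
    chunk_max = max(1, int(4_000_000 // n))
    base = np.arange(n)
    while remaining > 0:
        c = min(remaining, chunk_max)
        idx = np.tile(base, (c, 1))
        rng.permuted(idx, axis=1, out=idx)
        rho = np.abs(w[idx] @ u)
        count += int((rho >= obs).sum() if tie_rule == "ge" else (rho > obs).sum())
        remaining -= c
    return count_to_pvalue(count, n_permutations, tie_rule)


def bootstrap_srcc_lower_bound(
    x,
    y,
    n_samples: int = 100,
    sample_size: int = 100,
    seed: int = 0,
    percentile: float = 5.0,
    rng: np.random.Generator | None = None,
) -> float:
    """Bootstrap lower bound on |SRCC|: the empirical 5th percentile.

    Subjects are resampled with replacement ``n_samples`` times; |SRCC| is
    computed per resample and the bound is the order statistic at
    ``ceil(percentile/100 * B)`` of the sorted values (inverted-CDF
    convention; with B = 100 and the default percentile this is the 5th
    smallest value).  Degenerate resamples (a constant variable) are skipped
    with a warning, up to a 20% budget.
    """
    x, y = _paired(x, y)
    if sample_size < 3:
        raise ValueError("sample_size must be >= 3")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if rng is None:
        rng = np.random.default_rng(seed)
    vals: list[float] = []
    skipped = 0
    for _ in range(n_samples):
        sel = rng.integers(0, x.size, size=sample_size)
        xs, ys = x[sel], y[sel]
        if np.all(xs == xs[0]) or np.all(ys == ys[0]):
            skipped += 1
            continue
        vals.append(abs(float(stats.spearmanr(xs, ys).statistic)))
    if skipped:
        logger.warning("skipped %d degenerate bootstrap resample(s)", skipped)
    if skipped > 0.2 * n_samples:
        raise ValueError("more than 20% of bootstrap resamples were degenerate")
    vals.sort()
    k = int(np.ceil(percentile / 100.0 * len(vals)))
    return vals[max(k, 1) - 1]


def run_correlation_analysis(
    features: pd.DataFrame,
    metadata: pd.DataFrame,
    covariate: str = "age",
    n_permutations: int = 100_000,
    bootstrap_samples: int = 100,
    bootstrap_size: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    rho_flag_threshold: float = 0.4,
    compute_bootstrap_bound: bool = True,
) -> pd.DataFrame:
    """SRCC screen of every feature against a continuous covariate.

    The cohort is expected to be pre-filtered by the caller (e.g. controls
    only).  Per feature: SRCC, permutation p (Holm-corrected over all
    features), the bootstrap lower bound on |SRCC|, and a
    ``flagged_moderate`` marker for |rho| > ``rho_flag_threshold``.
    """
    if covariate not in metadata.columns:
        raise ValueError(f"metadata has no column {covariate!r}")
    meta = metadata.set_index(metadata["subject_id"].astype(str))
    common = features.index.astype(str).intersection(meta.index).sort_values()
    if len(common) < 3:
        raise ValueError("need at least 3 subjects with features and metadata")
    feats = features.loc[common]
    cov = pd.to_numeric(meta.loc[common, covariate]).to_numpy(dtype=np.float64)

    rows = []
    for col in feats.columns:
        v = feats[col].to_numpy(dtype=np.float64)
        xv, yv = _paired(cov, v)
        if is_feature_column(col):
            region, sigma, quant = parse_feature_column(col)
        else:
            region, sigma, quant = col, np.nan, ""
        rec = {
            "feature": col, "region": region, "sigma_mm": sigma,
            "quantifier": quant, "n": int(xv.size),
        }
        if xv.size < 3 or np.all(yv == yv[0]) or np.all(xv == xv[0]):
            logger.warning("feature %s: degenerate or too small; skipped", col)
            rec.update(rho=np.nan, p_raw=np.nan, ci_lower_abs=np.nan)
            rows.append(rec)
            continue
        rec["rho"] = spearman_rho(xv, yv)
        rng = feature_rng(seed, col, "corr-perm")
        rec["p_raw"] = correlation_permutation_p(
            xv, yv, n_permutations=n_permutations, rng=rng
        )
        if compute_bootstrap_bound:
            brng = feature_rng(seed, col, "corr-boot")
            rec["ci_lower_abs"] = bootstrap_srcc_lower_bound(
                xv, yv, n_samples=bootstrap_samples,
                sample_size=bootstrap_size, rng=brng,
            )
        else:
            rec["ci_lower_abs"] = np.nan
        rows.append(rec)

    result = pd.DataFrame(rows)
    result["p_holm"] = holm_correct(result["p_raw"].to_numpy())
    result["significant"] = result["p_holm"] < alpha
    result["flagged_moderate"] = result["rho"].abs() > rho_flag_threshold
    return result


def export_correlation_heatmaps(
    results: pd.DataFrame, rho_path, p_path=None, bound_path=None
) -> pd.DataFrame:
    """Export region x (scale, quantifier) matrices: rho, -log10 p, bound."""
    df = results.dropna(subset=["sigma_mm"]).copy()
    df["col"] = [f"{s:.3f}__{q}" for s, q in zip(df["sigma_mm"], df["quantifier"])]
    rho = df.pivot_table(index="region", columns="col", values="rho", sort=False)
    rho.to_csv(rho_path)
    if p_path is not None:
        heat = df.pivot_table(
            index="region", columns="col", values="p_raw", sort=False
        ).apply(lambda c: -np.log10(c))
        heat.to_csv(p_path)
    if bound_path is not None:
        df.pivot_table(
            index="region", columns="col", values="ci_lower_abs", sort=False
        ).to_csv(bound_path)
    return rho
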