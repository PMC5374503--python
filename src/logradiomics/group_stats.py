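"""Two-group analysis of texture features.

The primary test is a two-sided permutation test on the absolute difference
of group medians (ABM): group labels are randomly permuted many times
(default 100,000) and the p-value is the fraction of permutations whose ABM
reaches the observed one.  By default the tie-inclusive, validity-corrected
count ``p = (b + 1) / (N + 1)`` is used so that p can never be 0; the
literal "strictly greater" rule is available as ``tie_rule="gt"``.

As a complementary screen, balanced bootstrap resamples (equal numbers drawn
from each group, with replacement) are each scored by a Wilcoxon rank-sum
test and the per-resample p-values aggregated with Fisher's method.  Because
resample p-values are correlated, the aggregate is *relative-ranking only*
and intentionally not entered into the corrected-significance decision.

All raw p-values of one analysis family are corrected simultaneously with
the Holm-Bonferroni step-down procedure; features are declared significant
at corrected p < alpha (default 0.05).
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .volume_io import is_feature_column, parse_feature_column

logger = logging.getLogger(__name__)

_EXHAUSTIVE_MAX_N = 12


@dataclass(frozen=True)
class PermutationConfig:
    n_permutations: int = 100_000
    seed: int = 0
    tie_rule: str = "ge"  # "ge": tie-inclusive + validity correction; "gt": literal

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.tie_rule not in ("ge", "gt"):
            raise ValueError("tie_rule must be 'ge' or 'gt'")


@dataclass(frozen=True)
class BootstrapFisherConfig:
    n_samples: int = 100
    size_per_group: int = 100
    with_replacement: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.size_per_group < 1:
            raise ValueError("size_per_group must be >= 1")


def _clean(values) -> np.ndarray:
    v = np.asarray(values, dtype=np.float64).ravel()
    return v[~np.isnan(v)]


def feature_rng(master_seed: int, feature_name: str, salt: str = "") -> np.random.Generator:
    """Deterministic per-feature random stream, independent of analysis order."""
    key = zlib.crc32((feature_name + "|" + salt).encode("utf-8"))
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, key])
    return np.random.default_rng(ss)


def count_to_pvalue(n_reaching: int, n_permutations: int, tie_rule: str = "ge") -> float:
    """Permutation p from the count of permutations reaching the observed statistic."""
    if tie_rule == "ge":
        return (n_reaching + 1) / (n_permutations + 1)
    return n_reaching / n_permutations


# ---------------------------------------------------------------------------
# statistics


def abm_statistic(values_a, values_b) -> float:
    """Absolute difference of group medians (missing values dropped)."""
    a, b = _clean(values_a), _clean(values_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("a group is empty after missing-value removal")
    return float(abs(np.median(a) - np.median(b)))


def _two_groups(values, group_labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    v = np.asarray(values, dtype=np.float64).ravel()
    g = np.asarray(group_labels).ravel()
    if v.shape != g.shape:
        raise ValueError("values and group_labels must have equal length")
    keep = ~np.isnan(v)
    v, g = v[keep], g[keep]
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 group labels, got {list(levels)}")
    mask_a = g == levels[0]
    if mask_a.sum() == 0 or (~mask_a).sum() == 0:
        raise ValueError("one group is empty")
    return v, mask_a, levels


def permutation_test(
    values,
    group_labels,
    config: PermutationConfig = PermutationConfig(),
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo permutation p for the ABM statistic.

    Group sizes are preserved in every permutation; the relabelings are
    sampled uniformly at random.  Deterministic given the config seed (or an
    explicit generator, which takes precedence).
    """
    v, mask_a, _ = _two_groups(values, group_labels)
    n = v.size
    n_a = int(mask_a.sum())
    obs = abm_statistic(v[mask_a], v[~mask_a])
    if rng is None:
        rng = np.random.default_rng(config.seed)
    count = 0
    remaining = config.n_permutations
    chunk_max = max(1, int(4_000_000 // max(n, 1)))
    base = np.arange(n)
    while remaining > 0:
        c = min(remaining, chunk_max)
        idx = np.tile(base, (c, 1))
        rng.permuted(idx, axis=1, out=idx)
        va = v[idx[:, :n_a]]
        vb = v[idx[:, n_a:]]
        abm = np.abs(np.median(va, axis=1) - np.median(vb, axis=1))
        if config.tie_rule == "ge":
            count += int((abm >= obs).sum())
        else:
            count += int((abm > obs).sum())
        remaining -= c
    return count_to_pvalue(count, config.n_permutations, config.tie_rule)


def exhaustive_permutation_test(values, group_labels) -> float:
    """Exact permutation p by enumerating all group-size-preserving splits.

    Tie-inclusive counting (fraction of splits with ABM >= observed).  Only
    feasible for small cohorts (n <= 12); used as the oracle for the
    Monte-Carlo test.
    """
    v, mask_a, _ = _two_groups(values, group_labels)
    n = v.size
    if n > _EXHAUSTIVE_MAX_N:
        raise ValueError(f"exhaustive enumeration limited to n <= {_EXHAUSTIVE_MAX_N}")
    n_a = int(mask_a.sum())
    obs = abm_statistic(v[mask_a], v[~mask_a])
    total = 0
    reached = 0
    all_idx = frozenset(range(n))
    for combo in combinations(range(n), n_a):
        sel = np.fromiter(combo, dtype=int)
        rest = np.fromiter(sorted(all_idx - set(combo)), dtype=int)
        abm = abs(float(np.median(v[sel])) - float(np.median(v[rest])))
        total += 1
        if abm >= obs:
            reached += 1
    return reached / total


def wilcoxon_rank_sum(values_a, values_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration for small tie-free samples (n_a + n_b <= 20), tie-
    corrected normal approximation otherwise.
    """
    a, b = _clean(values_a), _clean(values_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def fisher_combine(p_values: Sequence[float]) -> tuple[float, float]:
    """Fisher's method: ``X = -2 sum(ln p)`` referred to chi-square(2k).

    Zero p-values are clamped to the smallest positive float with a warning
    (a zero would make X infinite).
    """
    p = np.asarray(p_values, dtype=np.float64).ravel()
    if p.size == 0:
        raise ValueError("fisher_combine needs at least one p-value")
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("p = 0 input(s) clamped to the smallest positive float")
        p = np.maximum(p, np.nextafter(0.0, 1.0))
    x = float(-2.0 * np.log(p).sum())
    p_comb = float(stats.chi2.sf(x, df=2 * p.size))
    return x, p_comb


def balanced_bootstrap_fisher(
    feature_values,
    group_labels,
    config: BootstrapFisherConfig = BootstrapFisherConfig(),
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Balanced-bootstrap Wilcoxon screen aggregated with Fisher's method.

    Draws ``n_samples`` resamples of ``size_per_group`` subjects from each
    group (with replacement by default), computes a Wilcoxon rank-sum p per
    resample, and combines them.  The aggregate is overly optimistic (the
    resample p-values are correlated) and is meant for relative ranking of
    features, never as a calibrated significance level.
    """
    v, mask_a, _ = _two_groups(feature_values, group_labels)
    va, vb = v[mask_a], v[~mask_a]
    if not config.with_replacement and config.size_per_group > min(va.size, vb.size):
        raise ValueError("size_per_group exceeds a group size (without replacement)")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ps = []
    for _ in range(config.n_samples):
        sa = rng.choice(va, size=config.size_per_group, replace=config.with_replacement)
        sb = rng.choice(vb, size=config.size_per_group, replace=config.with_replacement)
        ps.append(wilcoxon_rank_sum(sa, sb))
    return fisher_combine(ps)


def holm_correct(p_raw) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values.

    ``p~_(i) = min(1, max_{j<=i} (m - j + 1) p_(j))`` over the sorted raw
    p-values, mapped back to input order.  Missing (NaN) entries are excluded
    from the family size m and returned as NaN.
    """
    p = np.asarray(p_raw, dtype=np.float64).ravel()
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum() == 0:
        return out
    if np.any(p[mask] < 0) or np.any(p[mask] > 1):
        raise ValueError("p-values must lie in [0, 1]")
    out[mask] = multipletests(p[mask], method="holm")[1]
    return out


# ---------------------------------------------------------------------------
# cohort-level analysis


def run_group_analysis(
    features: pd.DataFrame,
    metadata: pd.DataFrame,
    grouping_variable: str = "group",
    perm_config: PermutationConfig = PermutationConfig(),
    bootstrap_config: BootstrapFisherConfig | None = None,
    alpha: float = 0.05,
    min_group_n: int = 10,
) -> pd.DataFrame:
    """Permutation-test every feature for a two-level grouping variable.

    ``features`` is a subjects x features table indexed by subject_id;
    ``metadata`` must contain ``subject_id`` and the grouping column with
    exactly two levels on the analyzed cohort.  Missing feature values are
    dropped pairwise per feature; features with fewer than ``min_group_n``
    subjects in a group are still tested but flagged ``low_n``.  Holm
    correction is applied simultaneously over all tested features.

    Per-feature random substreams are derived from the master seed and the
    feature name, so results do not depend on column order.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    meta = metadata.set_index(metadata["subject_id"].astype(str))
    # canonical subject order, so results are invariant to input row order
    common = features.index.astype(str).intersection(meta.index).sort_values()
    if len(common) < 4:
        raise ValueError("need at least 4 subjects with features and metadata")
    feats = features.loc[common]
    groups = meta.loc[common, grouping_variable].to_numpy()
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(
            f"grouping variable {grouping_variable!r} must be binary, got {list(levels)}"
        )
    for lev in levels:
        if (groups == lev).sum() < 2:
            raise ValueError(f"fewer than 2 subjects in group {lev!r}")

    rows = []
    for col in feats.columns:
        v = feats[col].to_numpy(dtype=np.float64)
        keep = ~np.isnan(v)
        vv, gg = v[keep], groups[keep]
        rec: dict = {"feature": col}
        if is_feature_column(col):
            region, sigma, quant = parse_feature_column(col)
        else:
            region, sigma, quant = col, np.nan, ""
        rec.update(region=region, sigma_mm=sigma, quantifier=quant)
        n_a = int((gg == levels[0]).sum())
        n_b = int((gg == levels[1]).sum())
        rec.update(n_a=n_a, n_b=n_b, low_n=min(n_a, n_b) < min_group_n)
        if n_a == 0 or n_b == 0:
            logger.warning("feature %s skipped: a group is empty after NaN removal", col)
            rec.update(abm=np.nan, p_raw=np.nan, fisher_chi2=np.nan, p_fisher=np.nan)
            rows.append(rec)
            continue
        rec["abm"] = abm_statistic(vv[gg == levels[0]], vv[gg == levels[1]])
        rng = feature_rng(perm_config.seed, col, "perm")
        rec["p_raw"] = permutation_test(vv, gg, perm_config, rng=rng)
        if bootstrap_config is not None:
            brng = feature_rng(bootstrap_config.seed, col, "bootstrap")
            chi2, p_f = balanced_bootstrap_fisher(vv, gg, bootstrap_config, rng=brng)
            rec.update(fisher_chi2=chi2, p_fisher=p_f)
        else:
            rec.update(fisher_chi2=np.nan, p_fisher=np.nan)
        rows.append(rec)

    result = pd.DataFrame(rows)
    result["p_holm"] = holm_correct(result["p_raw"].to_numpy())
    result["significant"] = result["p_holm"] < alpha
    return result


def export_heatmap_csvs(
    results: pd.DataFrame, p_path, mask_path=None
) -> pd.DataFrame:
    """Export a -log10 raw-p heatmap matrix (regions x scale/quantifier).

    Columns are ``<sigma mm>__<quantifier>``; an optional parallel 0/1 mask
    marks Holm-significant cells.  Returns the heatmap frame.
    """
    df = results.dropna(subset=["sigma_mm"]).copy()
    df["col"] = [
        f"{s:.3f}__{q}" for s, q in zip(df["sigma_mm"], df["quantifier"])
    ]
    heat = df.pivot_table(
        index="region", columns="col", values="p_raw", sort=False
    ).apply(lambda c: -np.log10(c))
    heat.to_csv(p_path)
    if mask_path is not None:
        mask = df.pivot_table(
            index="region", columns="col", values="significant",
            aggfunc="first", sort=False,
        ).astype(float)
        mask.to_csv(mask_path)
    return heat
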