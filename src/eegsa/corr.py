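"""Permutation-based group comparison of band-ratio metrics.

For every (metric, region) pair the two situation-awareness groups are
compared on their subject-level metric means with Welch's t statistic,

    t = (mean(a) - mean(b)) / sqrt(s_a²/n_a + s_b²/n_b),

and a two-sided permutation p-value obtained by shuffling group labels
across the pooled subjects:

    p = (1 + #{ |t*| >= |t_obs| }) / (n_perm + 1).

Subjects (not epochs) are the permutation units, since epochs within a
subject are strongly dependent.  Pairs significant at the lenient 0.1
level within the frontal/central regions define the selected feature set:
each selected (metric, region) contributes its mean and its median
sliding-window feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectral import METRICS, CORRELATED_METRICS, feature_name, parse_feature_name


@dataclass
class GroupComparison:
    metric: str
    region: str
    mean_high: float
    std_high: float
    mean_low: float
    std_low: float
    t: float
    p: float


def welch_t(a: np.ndarray, b: np.ndarray) -> float:
    """Welch's unequal-variance t statistic (sample variances, n-1).

    Degenerate case: both variances zero -> 0 if the means agree, signed
    infinity otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t needs >= 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    num = a.mean() - b.mean()
    den = np.sqrt(va / a.size + vb / b.size)
    if den == 0:
        return 0.0 if num == 0 else float(np.sign(num) * np.inf)
    return float(num / den)


def permutation_p(
    a: np.ndarray, b: np.ndarray, n_perm: int = 10_000, seed: int | None = None
) -> float:
    """Two-sided permutation p-value for Welch's t via label shuffling.

    Uses the additive-one correction, so p >= 1/(n_perm+1) and p <= 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    t_obs = abs(welch_t(a, b))
    pooled = np.concatenate([a, b])
    n_a = a.size
    rng = np.random.default_rng(seed)
    # vectorized shuffles: argsort of uniforms gives independent permutations
    u = rng.random((n_perm, pooled.size))
    order = np.argsort(u, axis=1)
    shuffled = pooled[order]
    ga, gb = shuffled[:, :n_a], shuffled[:, n_a:]
    va = ga.var(axis=1, ddof=1)
    vb = gb.var(axis=1, ddof=1)
    num = ga.mean(axis=1) - gb.mean(axis=1)
    den = np.sqrt(va / n_a + vb / gb.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t_star = np.where(den > 0, np.abs(num) / den, np.where(num == 0, 0.0, np.inf))
    exceed = int(np.sum(t_star >= t_obs - 1e-12))
    return (1 + exceed) / (n_perm + 1)


def subject_means(
    features: pd.DataFrame, metrics: tuple[str, ...] = METRICS
) -> pd.DataFrame:
    """Subject-level means of the window-mean (``M``) feature columns.

    Returns a tidy frame with columns subject_id, group, metric, region,
    value — the permutation units for :func:`evaluate_correlations`.
    """
    meta = {"subject_id", "group", "epoch_index", "start_s"}
    rows = []
    for col in features.columns:
        if col in meta:
            continue
        region, stat, metric = parse_feature_name(col)
        if stat != "mean" or metric not in metrics:
            continue
        per_subj = features.groupby(["subject_id", "group"], sort=True)[col].mean()
        for (sid, grp), val in per_subj.items():
            rows.append(
                {"subject_id": sid, "group": grp, "metric": metric, "region": region, "value": val}
            )
    return pd.DataFrame(rows)


def evaluate_correlations(
    subject_table: pd.DataFrame,
    metrics: tuple[str, ...] = METRICS,
    regions: tuple[str, ...] = ("F", "C", "P", "O"),
    n_perm: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """One group comparison per (metric, region): the correlation table.

    ``subject_table`` is the tidy output of :func:`subject_means`.  Returns
    a DataFrame with columns metric, region, mean_high, std_high, mean_low,
    std_low, t, p (metric-major, then region order as given).
    """
    rng = np.random.default_rng(seed)
    out: list[dict] = []
    for metric in metrics:
        for region in regions:
            sel = subject_table[
                (subject_table["metric"] == metric) & (subject_table["region"] == region)
            ]
            a = sel.loc[sel["group"] == "high", "value"].to_numpy()
            b = sel.loc[sel["group"] == "low", "value"].to_numpy()
            if a.size < 2 or b.size < 2:
                raise ValueError(f"missing subject data for region {region!r} ({metric})")
            t = welch_t(a, b)
            p = permutation_p(a, b, n_perm=n_perm, seed=int(rng.integers(2**31)))
            out.append(
                {
                    "metric": metric,
                    "region": region,
                    "mean_high": a.mean(),
                    "std_high": a.std(ddof=1),
                    "mean_low": b.mean(),
                    "std_low": b.std(ddof=1),
                    "t": t,
                    "p": p,
                }
            )
    df = pd.DataFrame(out)
    df["sig_0.05"] = df["p"] < 0.05
    df["sig_0.1"] = df["p"] < 0.1
    return df


def select_features(
    comparisons: pd.DataFrame,
    alpha_lenient: float = 0.1,
    regions_for_selection: tuple[str, ...] = ("F", "C"),
    metrics_for_selection: tuple[str, ...] = CORRELATED_METRICS,
) -> list[str]:
    """Feature names of the significant (metric, region) pairs.

    Every pair with p < ``alpha_lenient`` whose region lies in
    ``regions_for_selection`` (and metric in ``metrics_for_selection``)
    contributes its mean and median feature name, metric-major in the
    published ordering (FM1, FP1, CM1, CP1, FM2, ...).
    """
    names: list[str] = []
    for metric in metrics_for_selection:
        for region in regions_for_selection:
            sel = comparisons[
                (comparisons["metric"] == metric) & (comparisons["region"] == region)
            ]
            if sel.empty:
                continue
            if float(sel["p"].iloc[0]) < alpha_lenient:
                names.append(feature_name(region, "mean", metric))
                names.append(feature_name(region, "median", metric))
    return names
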