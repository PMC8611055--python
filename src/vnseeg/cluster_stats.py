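"""Cluster-based permutation tests and factorial models.

A cluster-based permutation test (CBPT) controls the family-wise error of
pointwise tests over time (or time x frequency) without assuming a
parametric null for the cluster statistic: samples whose pointwise statistic
exceeds a critical value are grouped into contiguous clusters, each
cluster's statistics are summed, and the summed values are compared with the
distribution of the *maximum* cluster sum under random relabelings of the
trials (or random per-trial sign flips for tests against baseline).

Cluster-forming statistics: deviation-coded Type III two-way ANOVA F traces
(frequency, amplitude, interaction), two-sample t, Wilcoxon rank-sum z, and
one-sample t against 0.  p-values use the add-one rule (b + 1)/(n + 1), so
the smallest reportable p with 1000 permutations is 1/1001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

STATISTICS = (
    "anova_frequency",
    "anova_amplitude",
    "anova_interaction",
    "two_sample_t",
    "rank_sum",
    "one_sample_baseline",
)

_SIGNED = {"two_sample_t", "rank_sum", "one_sample_baseline"}


@dataclass
class Cluster:
    """One suprathreshold cluster: boolean mask, summed statistic, p-value."""

    mask: np.ndarray
    cluster_sum: float
    p_value: float | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    observed_stat: np.ndarray
    critical_value: float
    n_permutations: int
    seed: int | None
    null_max: np.ndarray | None = None

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value is not None and c.p_value < alpha]


@dataclass
class AnovaTrace:
    """Pointwise Type III F statistics for the 2 x 2 factorial design."""

    F_frequency: np.ndarray
    F_amplitude: np.ndarray
    F_interaction: np.ndarray
    df_effect: int
    df_error: np.ndarray  # per time sample (NaN trials are dropped per sample)

    def trace(self, effect: str) -> np.ndarray:
        return getattr(self, f"F_{effect}")


# ---------------------------------------------------------------------------
# design handling
# ---------------------------------------------------------------------------

def _deviation_design(freq: np.ndarray, amp: np.ndarray) -> np.ndarray:
    """N x 4 deviation-coded (sum-to-zero) design: 1, f, a, f*a."""
    for name, lab in (("frequency", freq), ("amplitude", amp)):
        if len(np.unique(lab)) != 2:
            raise ValueError(f"{name} factor must have exactly 2 levels")
    f_levels = np.unique(freq)
    a_levels = np.unique(amp)
    for fl in f_levels:
        for al in a_levels:
            n_cell = int(np.sum((freq == fl) & (amp == al)))
            if n_cell < 2:
                raise ValueError(f"cell ({fl}, {al}) has {n_cell} trial(s); need >= 2")
    f = np.where(freq == f_levels[-1], 1.0, -1.0)
    a = np.where(amp == a_levels[-1], 1.0, -1.0)
    return np.column_stack([np.ones_like(f), f, a, f * a])


def _labels_to_arrays(labels) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(labels, pd.DataFrame):
        return labels.frequency_level.to_numpy(), labels.amplitude_level.to_numpy()
    freq, amp = labels
    return np.asarray(freq), np.asarray(amp)


def _anova_fit(Y: np.ndarray, D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS of each row of Y (n_times x N) on D (N x 4): returns (F 3 x n_times, df_err)."""
    n, k = D.shape
    DtD = D.T @ D
    inv = np.linalg.inv(DtD)
    beta = inv @ (D.T @ Y.T)  # 4 x n_times
    rss = np.sum(Y * Y, axis=1) - np.sum(beta * (DtD @ beta), axis=0)
    df = n - k
    mse = np.maximum(rss / df, 0.0)
    diag = np.diag(inv)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = beta[1:] ** 2 / (diag[1:, None] * mse[None, :])
    return F, np.full(Y.shape[0], df)


def pointwise_anova(values: np.ndarray, labels) -> AnovaTrace:
    """Type III two-way ANOVA (deviation coded) at each time sample.

    ``values`` is n_times x n_trials (a single time sample may be 1-D);
    ``labels`` is a DataFrame with frequency_level / amplitude_level columns
    or a (freq, amp) pair of arrays.  With a single-degree-of-freedom effect
    under sum-to-zero coding, the Type III F equals the squared Wald t of
    that coefficient in the full model; on balanced designs this coincides
    with the sequential (Type I) decomposition.  NaN trials are excluded
    per sample with the error degrees of freedom recomputed.
    """
    Y = np.atleast_2d(np.asarray(values, dtype=float))
    freq, amp = _labels_to_arrays(labels)
    if Y.shape[1] != len(freq):
        raise ValueError("values must be n_times x n_trials matching labels")
    D = _deviation_design(freq, amp)

    nan_rows = np.isnan(Y).any(axis=1)
    F = np.full((3, Y.shape[0]), np.nan)
    df_err = np.full(Y.shape[0], np.nan)
    if (~nan_rows).any():
        Fc, dfc = _anova_fit(Y[~nan_rows], D)
        F[:, ~nan_rows] = Fc
        df_err[~nan_rows] = dfc
    for t in np.flatnonzero(nan_rows):
        m = np.isfinite(Y[t])
        try:
            Dm = _deviation_design(freq[m], amp[m])
        except ValueError:
            continue  # a cell emptied out: leave NaN (treated subthreshold)
        Ft, dft = _anova_fit(Y[t : t + 1, m], Dm)
        F[:, t] = Ft[:, 0]
        df_err[t] = dft[0]
    return AnovaTrace(
        F_frequency=F[0], F_amplitude=F[1], F_interaction=F[2],
        df_effect=1, df_error=df_err,
    )


def critical_value(alpha: float = 0.05, df=None, kind: str = "F") -> float:
    """Cluster-forming threshold: upper-alpha quantile of the reference law.

    kind='F': F(df_num, df_den); kind='t': two-sided |t| at df (inf allowed);
    kind='z': two-sided |z|.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if kind == "F":
        d1, d2 = df
        if d1 < 1 or d2 < 1:
            raise ValueError("F degrees of freedom must be >= 1")
        return float(stats.f.ppf(1 - alpha, d1, d2))
    if kind == "t":
        if df is None or np.isinf(df):
            return float(stats.norm.ppf(1 - alpha / 2))
        if df < 1:
            raise ValueError("t degrees of freedom must be >= 1")
        return float(stats.t.ppf(1 - alpha / 2, df))
    if kind == "z":
        return float(stats.norm.ppf(1 - alpha / 2))
    raise ValueError(f"unknown reference distribution kind {kind!r}")


# ---------------------------------------------------------------------------
# cluster formation
# ---------------------------------------------------------------------------

def _runs_1d(supra: np.ndarray) -> list[np.ndarray]:
    """Boolean masks of maximal runs of True."""
    out = []
    d = np.diff(np.concatenate([[0], supra.astype(int), [0]]))
    for a, b in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
        m = np.zeros_like(supra)
        m[a:b] = True
        out.append(m)
    return out


def form_clusters(
    stat: np.ndarray,
    threshold: float,
    adjacency: str = "1d",
    signed: bool = False,
) -> list[Cluster]:
    """Maximal connected components of {stat > threshold}, with sums.

    NaN statistics are treated as subthreshold.  For signed statistics
    (signed=True) positive and negative clusters are formed separately on
    +-threshold and carry signed sums.  2-D adjacency is 4-connectivity
    (no diagonals).  Clusters are returned sorted by decreasing |sum|.
    """
    stat = np.asarray(stat, dtype=float)
    clean = np.where(np.isfinite(stat), stat, 0.0)
    sides = [1.0, -1.0] if signed else [1.0]
    clusters: list[Cluster] = []
    for sign in sides:
        s = sign * clean
        supra = s > threshold
        if stat.ndim == 1:
            masks = _runs_1d(supra)
        elif stat.ndim == 2:
            structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
            lab, n = ndimage.label(supra, structure=structure)
            masks = [lab == i for i in range(1, n + 1)]
        else:
            raise ValueError("stat must be 1-D or 2-D")
        for m in masks:
            clusters.append(Cluster(mask=m, cluster_sum=float(np.sum(clean[m]))))
    clusters.sort(key=lambda c: -abs(c.cluster_sum))
    return clusters


def _max_cluster_sums_1d(
    stat: np.ndarray, threshold: float, signed: bool
) -> np.ndarray:
    """Max cluster |sum| per row of a (n_perm, n_times) statistic array."""
    stat = np.where(np.isfinite(stat), stat, 0.0)
    best = np.zeros(stat.shape[0])
    sides = [stat, -stat] if signed else [stat]
    for s in sides:
        run = np.zeros(stat.shape[0])
        for i in range(stat.shape[1]):
            col = s[:, i]
            supra = col > threshold
            run = np.where(supra, run + col, 0.0)
            np.maximum(best, run, out=best)
    return best


def _max_cluster_sums_2d(
    stat: np.ndarray, threshold: float, signed: bool
) -> np.ndarray:
    """Max cluster |sum| per 2-D slice of a (n_perm, n_bands, n_times) array."""
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    stat = np.where(np.isfinite(stat), stat, 0.0)
    best = np.zeros(stat.shape[0])
    for p in range(stat.shape[0]):
        for s in ([stat[p], -stat[p]] if signed else [stat[p]]):
            supra = s > threshold
            if not supra.any():
                continue
            lab, n = ndimage.label(supra, structure=structure)
            if n:
                sums = ndimage.sum_labels(s, lab, index=np.arange(1, n + 1))
                best[p] = max(best[p], float(sums.max()))
    return best


# ---------------------------------------------------------------------------
# batched permutation statistics
# ---------------------------------------------------------------------------

def _anova_stat_batch(
    Y: np.ndarray, D: np.ndarray, perms: np.ndarray, effect_row: int
) -> np.ndarray:
    """F trace of one effect for a batch of label permutations.

    Y: n_times x N; D: N x 4 (deviation coded); perms: n_perm x N index
    arrays (labels permuted as D[perm]).  Returns (n_perm, n_times).
    Permuting rows leaves D'D unchanged, so only D'y is recomputed.
    """
    n, k = D.shape
    inv = np.linalg.inv(D.T @ D)
    n_perm = perms.shape[0]
    Dp = D[perms.reshape(-1)].reshape(n_perm, n, k)  # n_perm x N x 4
    # fold perms into columns so D'y for every permutation is one BLAS call
    Dp2 = np.transpose(Dp, (1, 0, 2)).reshape(n, n_perm * k)
    G = (Y @ Dp2).reshape(Y.shape[0], n_perm, k)  # n_times x n_perm x 4
    beta = G @ inv.T
    rss = np.sum(Y * Y, axis=1)[:, None] - np.sum(beta * G, axis=2)
    mse = np.maximum(rss / (n - k), 1e-300)
    j = effect_row
    F = beta[:, :, j] ** 2 / (inv[j, j] * mse)
    return F.T  # n_perm x n_times


def _two_sample_t_batch(Y: np.ndarray, member: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t for each membership column.

    Y: n_times x N; member: N x n_perm boolean (group 1).  Returns
    (n_perm, n_times) of t = (m1 - m0) / sqrt(sp2 (1/n1 + 1/n0)).
    """
    n = Y.shape[1]
    n1 = member[:, 0].sum()
    n0 = n - n1
    S = Y.sum(axis=1, keepdims=True)
    Q = (Y * Y).sum(axis=1, keepdims=True)
    M = member.astype(float)
    S1 = Y @ M
    Q1 = (Y * Y) @ M
    m1, m0 = S1 / n1, (S - S1) / n0
    v1 = (Q1 - n1 * m1**2) / (n1 - 1)
    v0 = (Q - Q1 - n0 * m0**2) / (n0 - 1)
    sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m0) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    return t.T


def _rank_sum_batch(Y: np.ndarray, member: np.ndarray) -> np.ndarray:
    """Tie-corrected rank-sum z for each membership column (group 1)."""
    n = Y.shape[1]
    n1 = member[:, 0].sum()
    n0 = n - n1
    R = stats.rankdata(Y, axis=1)
    W1 = R @ member.astype(float)
    mu = n1 * (n + 1) / 2.0
    tie = np.zeros(Y.shape[0])
    for t_idx in range(Y.shape[0]):
        _, counts = np.unique(Y[t_idx], return_counts=True)
        tie[t_idx] = np.sum(counts**3 - counts)
    var = n0 * n1 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (W1 - mu) / np.sqrt(var)[:, None]
    return z.T


def _one_sample_t_batch(Y: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """One-sample t vs 0 under per-trial sign flips (columns of signs)."""
    n = Y.shape[1]
    m = (Y @ signs) / n
    Q = (Y * Y).sum(axis=1, keepdims=True)
    v = (Q - n * m**2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(v / n)
    return t.T


# ---------------------------------------------------------------------------
# CBPT drivers
# ---------------------------------------------------------------------------

_EFFECT_ROW = {"anova_frequency": 1, "anova_amplitude": 2, "anova_interaction": 3}


def _observed_and_threshold(data, labels, statistic, alpha, threshold):
    n = data.shape[1]
    if statistic.startswith("anova"):
        trace = pointwise_anova(data, labels)
        obs = trace.trace(statistic.split("_", 1)[1])
        df_err = int(np.nanmin(trace.df_error))
        thr = critical_value(alpha, (1, df_err), "F") if threshold is None else threshold
        return obs, thr
    if statistic == "two_sample_t":
        g = np.asarray(labels)
        groups = np.unique(g)
        if len(groups) != 2:
            raise ValueError("two_sample_t requires exactly 2 groups")
        thr = critical_value(alpha, n - 2, "t") if threshold is None else threshold
        member = (g == groups[-1])[:, None]
        return _two_sample_t_batch(data, member)[0], thr
    if statistic == "rank_sum":
        g = np.asarray(labels)
        groups = np.unique(g)
        if len(groups) != 2:
            raise ValueError("rank_sum requires exactly 2 groups")
        thr = critical_value(alpha, None, "z") if threshold is None else threshold
        member = (g == groups[-1])[:, None]
        return _rank_sum_batch(data, member)[0], thr
    if statistic == "one_sample_baseline":
        thr = critical_value(alpha, n - 1, "t") if threshold is None else threshold
        return _one_sample_t_batch(data, np.ones((n, 1)))[0], thr
    raise ValueError(f"unknown statistic {statistic!r}; use one of {STATISTICS}")


def cbpt(
    data: np.ndarray,
    labels=None,
    statistic: str = "two_sample_t",
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    threshold: float | None = None,
    batch: int = 200,
) -> ClusterTestResult:
    """1-D cluster-based permutation test on a time x trials matrix.

    Between-condition statistics permute trial labels (for the ANOVA family,
    the joint (frequency, amplitude) label pairs are permuted without
    restriction); the one-sample baseline statistic flips trial signs.  The
    null is the maximum cluster sum per permutation (0 when a permutation
    has no suprathreshold cluster) and p = (b + 1)/(n_permutations + 1)
    where b counts null values >= the observed cluster sum (|sum| for
    signed statistics).
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; use one of {STATISTICS}")
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations: p-values will be coarse")
    if np.isnan(data).any():
        data, labels = _drop_nan_trials(data, labels, statistic)
    rng = np.random.default_rng(seed)
    n = data.shape[1]
    signed = statistic in _SIGNED

    if statistic.startswith("anova"):
        freq, amp = _labels_to_arrays(labels)
        D = _deviation_design(freq, amp)
    obs, thr = _observed_and_threshold(data, labels, statistic, alpha, threshold)
    clusters = form_clusters(obs, thr, adjacency="1d", signed=signed)

    null = np.empty(n_permutations)
    done = 0
    while done < n_permutations:
        b = min(batch, n_permutations - done)
        if statistic == "one_sample_baseline":
            signs = rng.choice([-1.0, 1.0], size=(n, b))
            traces = _one_sample_t_batch(data, signs)
        elif statistic.startswith("anova"):
            perms = np.array([rng.permutation(n) for _ in range(b)])
            traces = _anova_stat_batch(data, D, perms, _EFFECT_ROW[statistic])
        else:
            g = np.asarray(labels)
            groups = np.unique(g)
            member = np.empty((n, b), dtype=bool)
            base = g == groups[-1]
            for j in range(b):
                member[:, j] = base[rng.permutation(n)]
            fn = _two_sample_t_batch if statistic == "two_sample_t" else _rank_sum_batch
            traces = fn(data, member)
        null[done : done + b] = _max_cluster_sums_1d(traces, thr, signed)
        done += b

    for c in clusters:
        b_count = int(np.sum(null >= abs(c.cluster_sum) - 1e-12))
        c.p_value = (b_count + 1) / (n_permutations + 1)
    return ClusterTestResult(
        clusters=clusters, observed_stat=obs, critical_value=thr,
        n_permutations=n_permutations, seed=seed, null_max=null,
    )


def _drop_nan_trials(data, labels, statistic):
    """Drop trials containing any NaN sample (per-sample NaN handling is
    done by pointwise_anova for observed traces; for permutation nulls the
    trial is removed so the statistic stays exchangeable)."""
    keep = ~np.isnan(data).any(axis=0)
    if not keep.any():
        raise ValueError("all trials contain NaN")
    data = data[:, keep]
    if labels is None:
        return data, None
    if isinstance(labels, pd.DataFrame):
        return data, labels.loc[keep].reset_index(drop=True)
    if isinstance(labels, tuple):
        return data, tuple(np.asarray(l)[keep] for l in labels)
    return data, np.asarray(labels)[keep]


def cbpt_2d_baseline(
    trials: np.ndarray,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    band_centers: np.ndarray | None = None,
    time_axis: np.ndarray | None = None,
    batch: int = 100,
) -> ClusterTestResult:
    """2-D (frequency x time) CBPT of z-scored trials against baseline.

    ``trials`` is bands x time x trials of z-normalized amplitude.  The
    pointwise statistic is a one-sample t against 0; the null uses random
    per-trial sign flips; clusters are 4-connected.  Each cluster reports
    its spectral extent, temporal extent, and mean z (mean of the trial-mean
    map over the cluster cells) when band_centers / time_axis are given.
    """
    X = np.asarray(trials, dtype=float)
    if X.ndim != 3:
        raise ValueError("trials must be bands x time x trials")
    n_bands, n_times, n = X.shape
    rng = np.random.default_rng(seed)
    Y = X.reshape(n_bands * n_times, n)
    if np.isnan(Y).any():
        keep = ~np.isnan(Y).any(axis=0)
        if keep.sum() < 2:
            raise ValueError("fewer than 2 NaN-free trials")
        Y = Y[:, keep]
        n = Y.shape[1]
    thr = critical_value(alpha, n - 1, "t")
    obs = _one_sample_t_batch(Y, np.ones((n, 1)))[0].reshape(n_bands, n_times)
    clusters = form_clusters(obs, thr, adjacency="2d", signed=True)

    null = np.empty(n_permutations)
    done = 0
    while done < n_permutations:
        b = min(batch, n_permutations - done)
        signs = rng.choice([-1.0, 1.0], size=(n, b))
        traces = _one_sample_t_batch(Y, signs).reshape(b, n_bands, n_times)
        null[done : done + b] = _max_cluster_sums_2d(traces, thr, signed=True)
        done += b

    mean_map = Y.mean(axis=1).reshape(n_bands, n_times)
    for c in clusters:
        b_count = int(np.sum(null >= abs(c.cluster_sum) - 1e-12))
        c.p_value = (b_count + 1) / (n_permutations + 1)
        c.extra["mean_z"] = float(mean_map[c.mask].mean())
        rows, cols = np.nonzero(c.mask)
        if band_centers is not None:
            c.extra["band_range_hz"] = (
                float(band_centers[rows.min()]), float(band_centers[rows.max()]))
        if time_axis is not None:
            c.extra["time_range_s"] = (
                float(time_axis[cols.min()]), float(time_axis[cols.max()]))
    return ClusterTestResult(
        clusters=clusters, observed_stat=obs, critical_value=thr,
        n_permutations=n_permutations, seed=seed, null_max=null,
    )


# ---------------------------------------------------------------------------
# group-level factorial model
# ---------------------------------------------------------------------------

def group_factorial(
    window_stats: pd.DataFrame,
    response: str = "mean_z",
    bonferroni_alpha: float = 0.003,
) -> pd.DataFrame:
    """Deviation-coded Type III factorial ANOVA of window-averaged power.

    ``window_stats`` has one row per trial x unit with the response column
    and the factors frequency_level, amplitude_level, modality, band (any
    single-level factor is dropped).  Main effects and all two-way
    interactions between the retained factors are fitted with sum-to-zero
    contrasts.  This is a fixed-effects surrogate for a nested mixed model:
    no random intercepts or per-group variance structure are estimated.
    Returns a table of F, raw p, and significance at the Bonferroni-adjusted
    level (default 0.003).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = window_stats.copy()
    factors = [
        c for c in ("frequency_level", "amplitude_level", "modality", "band")
        if c in df.columns and df[c].nunique() > 1
    ]
    if not factors:
        raise ValueError("no factor with >= 2 levels present")
    terms = [f"C({f}, Sum)" for f in factors]
    inter = [
        f"{a}:{b}" for i, a in enumerate(terms) for b in terms[i + 1 :]
    ]
    formula = f"{response} ~ " + " + ".join(terms + inter)
    model = smf.ols(formula, data=df)
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        _, r = np.linalg.qr(exog)
        aliased = [
            model.exog_names[i]
            for i in range(exog.shape[1])
            if abs(r[i, i]) < 1e-8
        ]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    fit = model.fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = anova_lm(fit, typ=3)
    table = table.drop(index=[i for i in ("Intercept", "Residual") if i in table.index])
    out = pd.DataFrame(
        {
            "F": table["F"],
            "p": table["PR(>F)"],
            "df": table["df"],
            "significant": table["PR(>F)"] < bonferroni_alpha,
        }
    )
    out.attrs["bonferroni_alpha"] = bonferroni_alpha
    return out
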