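"""Independent brute-force reference implementations used only by tests.

These are deliberately slow and explicit (loops, full enumeration) so they
share nothing with the library's vectorized implementations.
"""

import itertools

import numpy as np
from scipy import stats


def brute_force_clusters(trace, threshold):
    """Enumerate maximal runs of trace > threshold with their sums."""
    clusters = []
    current = []
    for i, v in enumerate(trace):
        if np.isfinite(v) and v > threshold:
            current.append(i)
        else:
            if current:
                clusters.append((list(current), sum(trace[j] for j in current)))
            current = []
    if current:
        clusters.append((list(current), sum(trace[j] for j in current)))
    return clusters


def brute_force_two_sample_t(data, groups):
    """Pooled two-sample t per sample, explicit loops."""
    out = []
    g = np.asarray(groups)
    levels = sorted(set(g))
    for row in data:
        a = [row[i] for i in range(len(g)) if g[i] == levels[1]]
        b = [row[i] for i in range(len(g)) if g[i] == levels[0]]
        na, nb = len(a), len(b)
        ma, mb = np.mean(a), np.mean(b)
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        out.append((ma - mb) / np.sqrt(sp2 * (1 / na + 1 / nb)))
    return np.array(out)


def brute_force_cbpt_two_sample(data, groups, n_permutations, alpha, seed):
    """Full CBPT with explicit loops; shares only the permutation seed."""
    rng = np.random.default_rng(seed)
    n = data.shape[1]
    thr = float(stats.t.ppf(1 - alpha / 2, n - 2))
    obs = brute_force_two_sample_t(data, groups)
    observed = []
    for sign in (1, -1):
        for idx, s in brute_force_clusters(sign * obs, thr):
            observed.append((idx, sum(obs[j] for j in idx)))
    null = []
    g = np.asarray(groups)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        t = brute_force_two_sample_t(data, g[perm])
        best = 0.0
        for sign in (1, -1):
            for idx, s in brute_force_clusters(sign * t, thr):
                best = max(best, abs(sum(t[j] for j in idx)))
        null.append(best)
    results = []
    for idx, csum in observed:
        b = sum(1 for v in null if v >= abs(csum) - 1e-12)
        results.append((idx, csum, (b + 1) / (n_permutations + 1)))
    return results, thr


def anova_2x2_cell_means(values, freq, amp):
    """Type III = Type I F statistics for a balanced 2 x 2 design, from the
    classical cell-mean sums of squares."""
    values = np.asarray(values, dtype=float)
    f_levels = sorted(set(freq))
    a_levels = sorted(set(amp))
    cells = {}
    for fl, al in itertools.product(f_levels, a_levels):
        cells[(fl, al)] = values[
            [i for i in range(len(values)) if freq[i] == fl and amp[i] == al]
        ]
    n_cell = {k: len(v) for k, v in cells.items()}
    assert len(set(n_cell.values())) == 1, "oracle assumes balanced cells"
    n = n_cell[f_levels[0], a_levels[0]]
    grand = values.mean()
    m = {k: v.mean() for k, v in cells.items()}
    mf = {fl: np.mean([m[fl, al] for al in a_levels]) for fl in f_levels}
    ma = {al: np.mean([m[fl, al] for fl in f_levels]) for al in a_levels}
    ss_f = 2 * n * sum((mf[fl] - grand) ** 2 for fl in f_levels)
    ss_a = 2 * n * sum((ma[al] - grand) ** 2 for al in a_levels)
    ss_i = n * sum(
        (m[fl, al] - mf[fl] - ma[al] + grand) ** 2
        for fl in f_levels for al in a_levels
    )
    ss_e = sum(((cells[k] - m[k]) ** 2).sum() for k in cells)
    df_e = len(values) - 4
    mse = ss_e / df_e
    return ss_f / mse, ss_a / mse, ss_i / mse, df_e


def rand_index_adjusted(a, b):
    """ARI from the pair-counting definition (all item pairs enumerated)."""
    n = len(a)
    ss = sd = ds = dd = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_a = a[i] == a[j]
            same_b = b[i] == b[j]
            if same_a and same_b:
                ss += 1
            elif same_a:
                sd += 1
            elif same_b:
                ds += 1
            else:
                dd += 1
    total = ss + sd + ds + dd
    expected = (ss + sd) * (ss + ds) / total
    max_index = ((ss + sd) + (ss + ds)) / 2
    if max_index == expected:
        return 1.0
    return (ss - expected) / (max_index - expected)
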