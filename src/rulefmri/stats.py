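"""Group-level inference: fully-within repeated-measures ANOVA with
Greenhouse-Geisser correction, marginal-mean post-hoc comparisons adjusted
via the multivariate t distribution, one-sample tests, and sign-flip
permutation cluster correction for subject-wise maps.

The ANOVA follows the classical univariate approach: each within-subject
effect is an orthonormal contrast of the cell means; sphericity violations
are corrected by the Box/Greenhouse-Geisser epsilon computed from the
covariance of the contrast scores.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sp_stats

__all__ = [
    "rm_anova",
    "emm_posthoc",
    "mvt_max_abs_p",
    "one_sample_t",
    "paired_t",
    "permutation_cluster",
    "ClusterResult",
]


class StatsError(ValueError):
    pass


class ZeroVarianceError(StatsError):
    pass


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA
# ---------------------------------------------------------------------------

def _orthonormal_contrast(k: int) -> np.ndarray:
    """Orthonormal basis of the (k-1)-dimensional contrast space (any such
    basis yields the same F and epsilon)."""
    helmert = np.zeros((k, k - 1))
    for j in range(1, k):
        helmert[:j, j - 1] = 1.0
        helmert[j, j - 1] = -j
    return helmert / np.linalg.norm(helmert, axis=0)


def _wide_table(
    data: pd.DataFrame, dv: str, within: list[str], subject: str
) -> tuple[np.ndarray, list[tuple], list[str], dict[str, list]]:
    levels = {f: list(pd.unique(data[f])) for f in within}
    cells = list(itertools.product(*(levels[f] for f in within)))
    subjects = list(pd.unique(data[subject]))
    index = {}
    for _, row in data.iterrows():
        key = (row[subject], tuple(row[f] for f in within))
        if key in index:
            raise StatsError(f"duplicate cell for subject {key[0]}: {key[1]}")
        index[key] = row[dv]
    missing = [
        (s, c) for s in subjects for c in cells if (s, c) not in index
    ]
    if missing:
        raise StatsError(f"unbalanced design; missing subject x cell entries: {missing[:10]}")
    wide = np.array([[index[(s, c)] for c in cells] for s in subjects], dtype=float)
    return wide, cells, subjects, levels


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str = "subject",
) -> pd.DataFrame:
    """Fully-within repeated-measures ANOVA.

    Returns one row per effect (the intercept — the grand-mean test — plus
    every main effect and interaction of the within factors) with F,
    uncorrected dfs, Greenhouse-Geisser epsilon and corrected p, MSE, and
    partial eta squared. Requires a balanced design (every subject observed
    exactly once in every cell).
    """
    wide, cells, subjects, levels = _wide_table(data, dv, within, subject)
    n = len(subjects)
    if n < 2:
        raise StatsError("need at least 2 subjects")
    k_per_factor = [len(levels[f]) for f in within]
    contrasts = {f: _orthonormal_contrast(k) for f, k in zip(within, k_per_factor)}
    units = {f: np.full((k, 1), 1.0 / np.sqrt(k)) for f, k in zip(within, k_per_factor)}

    effects: list[tuple[str, tuple[str, ...]]] = [("Intercept", ())]
    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(within, r):
            effects.append((" * ".join(combo), combo))

    rows = []
    for name, combo in effects:
        M = np.ones((1, 1))
        for f in within:
            M = np.kron(M, contrasts[f] if f in combo else units[f])
        Z = wide @ M  # subjects x q
        q = Z.shape[1]
        zbar = Z.mean(axis=0)
        ss_effect = n * float(zbar @ zbar)
        resid = Z - zbar
        E = resid.T @ resid
        df1, df2 = q, q * (n - 1)
        mse = float(np.trace(E)) / df2
        if mse <= 0:
            raise ZeroVarianceError(f"no error variance for effect {name!r}")
        F = (ss_effect / df1) / mse
        sigma = E / (n - 1)
        tr = float(np.trace(sigma))
        eps = 1.0 if q == 1 else tr**2 / (q * float(np.trace(sigma @ sigma)))
        eps = float(np.clip(eps, 1.0 / q, 1.0))
        p_unc = float(sp_stats.f.sf(F, df1, df2))
        p_gg = float(sp_stats.f.sf(F, df1 * eps, df2 * eps))
        rows.append(
            dict(
                effect=name,
                F=F,
                df1=df1,
                df2=df2,
                epsilon=eps,
                df1_gg=df1 * eps,
                df2_gg=df2 * eps,
                MSE=mse,
                p_uncorrected=p_unc,
                p_gg=p_gg,
                partial_eta_sq=ss_effect / (ss_effect + float(np.trace(E))),
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Post-hoc marginal-mean comparisons
# ---------------------------------------------------------------------------

def mvt_max_abs_p(
    tvals: np.ndarray,
    R: np.ndarray,
    df: int,
    n_mc: int = 100_000,
    seed: int = 20_201_109,
) -> np.ndarray:
    """Equicoordinate max-|t| adjusted p values.

    For each observed statistic returns P(max_i |T_i| >= |t|) where T follows
    the multivariate t distribution with ``df`` degrees of freedom and
    correlation ``R``, evaluated by Monte Carlo with a fixed seed. Under an
    identity correlation and large df this converges to the Sidak adjustment
    1 - (1 - p_unadjusted)^m.
    """
    tvals = np.atleast_1d(np.asarray(tvals, dtype=float))
    R = np.asarray(R, dtype=float)
    m = R.shape[0]
    # eigen square root tolerates the singular correlation structures that
    # arise among k(k-1)/2 pairwise differences
    w, V = np.linalg.eigh(R)
    root = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_mc, m)) @ root.T
    s = np.sqrt(rng.chisquare(df, n_mc) / df)
    max_abs_t = np.abs(Z / s[:, None]).max(axis=1)
    return np.array([(max_abs_t >= abs(t)).mean() for t in tvals])


def emm_posthoc(
    data: pd.DataFrame,
    dv: str,
    factor: str,
    subject: str = "subject",
    adjust: str = "mvt",
    n_mc: int = 100_000,
    seed: int = 20_201_109,
) -> pd.DataFrame:
    """Pairwise comparisons of a factor's estimated marginal means.

    Marginal means are per-subject averages over the other cells; each pair
    is tested with a within-subject (paired) t. Under ``adjust="mvt"`` the
    p-values are corrected for the family of k tests by Monte-Carlo
    evaluation of the joint multivariate t distribution of the comparisons
    (equicoordinate max-|t| adjustment) with a fixed internal seed. Adjusted
    p-values are constrained to the valid [unadjusted, k x unadjusted]
    bracket.
    """
    if adjust not in ("mvt", "none"):
        raise StatsError(f"unknown adjustment {adjust!r}")
    levels = list(pd.unique(data[factor]))
    if len(levels) < 2:
        raise StatsError("need at least 2 levels to compare")
    marg = (
        data.groupby([subject, factor], sort=False)[dv].mean().unstack(factor)[levels]
    )
    n = marg.shape[0]
    df = n - 1
    pairs = list(itertools.combinations(levels, 2))
    diffs = np.column_stack([marg[a] - marg[b] for a, b in pairs])
    means = diffs.mean(axis=0)
    sds = diffs.std(axis=0, ddof=1)
    if np.any(sds == 0):
        raise ZeroVarianceError("a pairwise difference has zero variance")
    tvals = means / (sds / np.sqrt(n))
    p_unadj = 2 * sp_stats.t.sf(np.abs(tvals), df)
    m = len(pairs)
    if adjust == "none" or m == 1:
        p_adj = p_unadj.copy()
    else:
        R = np.corrcoef(diffs, rowvar=False)
        p_adj = mvt_max_abs_p(tvals, R, df, n_mc=n_mc, seed=seed)
        p_adj = np.clip(p_adj, p_unadj, np.minimum(1.0, m * p_unadj))
    return pd.DataFrame(
        dict(
            level_a=[a for a, _ in pairs],
            level_b=[b for _, b in pairs],
            estimate=means,
            t=tvals,
            df=df,
            p_unadjusted=p_unadj,
            p_adjusted=p_adj,
            n_tests=m,
        )
    )


# ---------------------------------------------------------------------------
# Simple tests
# ---------------------------------------------------------------------------

def one_sample_t(
    values: np.ndarray, mu0: float = 0.0, alternative: str = "two-sided"
) -> tuple[float, int, float]:
    """One-sample t test of the mean against ``mu0``; returns (t, df, p)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise StatsError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError("sample has zero variance")
    res = sp_stats.ttest_1samp(x, mu0, alternative=alternative)
    return float(res.statistic), x.size - 1, float(res.pvalue)


def paired_t(
    a: np.ndarray, b: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, int, float]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise StatsError("paired samples must have equal length")
    return one_sample_t(a - b, 0.0, alternative)


# ---------------------------------------------------------------------------
# Permutation cluster correction
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    cluster_forming_t: float
    clusters: list[dict]  # size, peak index, corrected p
    null_max_sizes: np.ndarray
    n_perm: int
    seed: int
    labels: np.ndarray = field(default=None, repr=False)


def _t_map(flip: np.ndarray, data: np.ndarray, ss: np.ndarray, n: int) -> np.ndarray:
    m = (flip @ data) / n
    var = (ss - n * m**2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(var > 0, m / np.sqrt(var / n), 0.0)


def _max_cluster_size(
    tflat: np.ndarray, t_crit: float, mask: np.ndarray, structure: np.ndarray
) -> int:
    vol = np.zeros(mask.shape)
    vol[mask] = tflat
    labels, nlab = ndimage.label((vol > t_crit) & mask, structure=structure)
    if nlab == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def permutation_cluster(
    maps: np.ndarray,
    cluster_forming_p: float = 0.001,
    n_perm: int = 1000,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> ClusterResult:
    """Cluster-level family-wise error correction by sign-flip permutation.

    ``maps`` is a (subjects, x, y, z) stack. A voxelwise one-sample t map is
    thresholded at the (one-sided, positive) cluster-forming p; observed
    26-connected clusters are compared against the permutation null
    distribution of the maximum cluster size obtained by randomly flipping
    each subject's map sign. Corrected p = (1 + #{null >= size}) / (n_perm + 1).
    """
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    if n < 8:
        raise StatsError("need at least 8 subjects for sign-flip permutation")
    if n_perm < 100:
        raise StatsError("need at least 100 permutations")
    if mask is None:
        mask = np.ones(maps.shape[1:], dtype=bool)
    data = maps[:, mask]
    valid = np.isfinite(data).all(axis=0)
    mask = mask.copy()
    mask[mask] = valid
    data = data[:, valid]
    ss = (data**2).sum(axis=0)
    t_crit = float(sp_stats.t.isf(cluster_forming_p, n - 1))
    structure = np.ones((3, 3, 3), dtype=int)

    t_obs = _t_map(np.ones(n), data, ss, n)
    vol = np.zeros(mask.shape)
    vol[mask] = t_obs
    labels, nlab = ndimage.label((vol > t_crit) & mask, structure=structure)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=int)
    for p in range(n_perm):
        flip = rng.choice([-1.0, 1.0], size=n)
        null[p] = _max_cluster_size(_t_map(flip, data, ss, n), t_crit, mask, structure)

    clusters = []
    for k in range(1, nlab + 1):
        cmask = labels == k
        size = int(cmask.sum())
        peak = np.unravel_index(np.argmax(np.where(cmask, vol, -np.inf)), vol.shape)
        p_corr = (1 + int((null >= size).sum())) / (n_perm + 1)
        clusters.append(dict(size=size, peak_index=tuple(int(i) for i in peak), p_corrected=p_corr))
    clusters.sort(key=lambda c: -c["size"])
    return ClusterResult(
        cluster_forming_t=t_crit,
        clusters=clusters,
        null_max_sizes=null,
        n_perm=n_perm,
        seed=seed,
        labels=labels,
    )
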