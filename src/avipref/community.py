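"""Community dissimilarity and group-difference statistics.

Bray-Curtis dissimilarity (optionally on square-root-transformed counts),
a permutation analysis of similarities (ANOSIM) with pairwise
Bonferroni-adjusted contrasts, one-way ANOVA / Kruskal-Wallis omnibus tests
with multiple-comparison letters, and a Spearman rank correlation with a
permutation p-value.

ANOSIM is rank based: with ``M = n(n-1)/2`` pairwise dissimilarities ranked
with midranks,

    R = (mean between-group rank - mean within-group rank) / (M / 2)

so R ranges over [-1, 1]; values near 0 mean the grouping does not
structure the dissimilarities, and R = 1 means every between-group pair is
more dissimilar than every within-group pair.  The permutation p-value uses
the add-one estimator ``(1 + #{R_perm >= R_obs}) / (n_perm + 1)``, which is
never smaller than ``1/(n_perm + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "bray_curtis",
    "anosim",
    "AnosimResult",
    "one_way_anova",
    "kruskal_wallis",
    "pairwise_contrasts",
    "compact_letters",
    "spearman_rho",
]


def bray_curtis(counts, transform: str = "sqrt") -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between rows of a count matrix.

    ``d(x, y) = sum|x - y| / sum(x + y)`` on the (optionally square-root
    transformed) abundance vectors.  Two all-zero rows are defined to have
    dissimilarity 0.

    Parameters
    ----------
    counts : DataFrame or array-like
        Non-negative abundances, one row per sample (route), one column per
        species.
    transform : {"sqrt", "none"}
        Transform applied to counts before the dissimilarity.

    Returns
    -------
    DataFrame
        Square symmetric matrix with zero diagonal, labelled by row index.
    """
    if isinstance(counts, pd.DataFrame):
        labels = list(counts.index)
        x = counts.to_numpy(dtype=float)
    else:
        x = np.asarray(counts, dtype=float)
        labels = list(range(x.shape[0]))
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("counts must be finite and non-negative")
    if transform == "sqrt":
        x = np.sqrt(x)
    elif transform != "none":
        raise ValueError("transform must be 'sqrt' or 'none'")
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=labels, columns=labels)


@dataclass
class AnosimResult:
    """Result of an ANOSIM test."""

    r: float
    p: float
    n_perm: int
    n_samples: int
    groups: list
    pairwise: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        out = {
            "R": self.r,
            "p": self.p,
            "n_perm": self.n_perm,
            "n_samples": self.n_samples,
            "groups": [str(g) for g in self.groups],
        }
        if self.pairwise is not None:
            out["pairwise"] = self.pairwise.to_dict(orient="records")
        return out


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = ranks.size
    r_w = ranks[within].mean()
    r_b = ranks[~within].mean()
    return (r_b - r_w) / (m / 2.0)


def anosim(
    d,
    groups,
    n_perm: int = 999,
    seed=None,
    pairwise: bool = True,
    alpha: float = 0.05,
) -> AnosimResult:
    """One-way analysis of similarities on a dissimilarity matrix.

    Parameters
    ----------
    d : DataFrame or square array
        Symmetric dissimilarity matrix with zero diagonal (e.g. from
        :func:`bray_curtis`).
    groups : sequence
        Group label per row of ``d``; at least two groups with at least two
        members each.
    n_perm : int
        Number of Monte Carlo label permutations.
    seed : int or numpy Generator, optional
        Randomness source for the permutations.
    pairwise : bool
        Also test each pair of groups on the corresponding submatrix, with
        a Bonferroni-adjusted alpha of ``alpha / n_pairs``.
    """
    dm = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d, float)
    g = np.asarray(list(groups))
    n = dm.shape[0]
    if dm.shape != (n, n) or g.size != n:
        raise ValueError("dissimilarity matrix and groups have inconsistent shapes")
    if not np.allclose(dm, dm.T) or not np.allclose(np.diag(dm), 0.0):
        raise ValueError("dissimilarity matrix must be symmetric with zero diagonal")
    labels, counts = np.unique(g, return_counts=True)
    if labels.size < 2:
        raise ValueError("need at least two groups")
    if np.any(counts < 2):
        raise ValueError("every group needs at least two members")

    iu, ju = np.triu_indices(n, k=1)
    cond = dm[iu, ju]
    if np.allclose(cond, cond[0]):
        raise ValueError("constant dissimilarities: R is undefined")
    ranks = stats.rankdata(cond)  # midranks
    within = g[iu] == g[ju]
    r_obs = _anosim_r(ranks, within)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(int(n_perm)):
        perm = rng.permutation(g)
        w = perm[iu] == perm[ju]
        if _anosim_r(ranks, w) >= r_obs - 1e-12:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)

    pw = None
    if pairwise and labels.size > 2:
        pairs = list(combinations(labels, 2))
        alpha_adj = alpha / len(pairs)
        rows = []
        for a, b in pairs:
            mask = (g == a) | (g == b)
            sub = anosim(dm[np.ix_(mask, mask)], g[mask], n_perm=n_perm, seed=rng, pairwise=False)
            rows.append(
                {
                    "group_1": a,
                    "group_2": b,
                    "R": sub.r,
                    "p": sub.p,
                    "alpha_adj": alpha_adj,
                    "significant": sub.p <= alpha_adj,
                }
            )
        pw = pd.DataFrame(rows)
    return AnosimResult(
        r=float(r_obs), p=float(p), n_perm=int(n_perm), n_samples=n,
        groups=list(labels), pairwise=pw,
    )


def _split(values, groups):
    v = np.asarray(values, dtype=float)
    g = np.asarray(list(groups))
    if v.size != g.size:
        raise ValueError("values and groups differ in length")
    labels = list(pd.unique(g))
    return [v[g == lab] for lab in labels], labels


def one_way_anova(values, groups):
    """Classical one-way ANOVA.

    Returns ``(F, df1, df2, p)``.  Requires at least two groups, positive
    residual degrees of freedom, and non-zero within-group variance.
    """
    samples, labels = _split(values, groups)
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    n = sum(s.size for s in samples)
    df1, df2 = len(samples) - 1, n - len(samples)
    if df2 < 2:
        raise ValueError("need at least 2 residual degrees of freedom")
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    if ssw == 0:
        raise ValueError("zero within-group variance: F is undefined")
    f, p = stats.f_oneway(*samples)
    return float(f), df1, df2, float(p)


def kruskal_wallis(values, groups):
    """Kruskal-Wallis rank test with tie correction.

    Returns ``(H, df, p)`` with a chi-square(k-1) p-value.
    """
    samples, _ = _split(values, groups)
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if np.ptp(np.concatenate(samples)) == 0:
        raise ValueError("all values tied: H is undefined")
    h, p = stats.kruskal(*samples)
    return float(h), len(samples) - 1, float(p)


def compact_letters(labels, different_pairs) -> dict:
    """Assign compact letter display codes (A, B, ...).

    Groups that are *not* significantly different share a letter.  Letters
    are the maximal cliques of the not-different graph, found by subset
    enumeration (group counts here are small), ordered by first member.
    """
    labels = list(labels)
    k = len(labels)
    diff = {frozenset(p) for p in different_pairs}
    cliques = []
    for size in range(k, 0, -1):
        for combo in combinations(range(k), size):
            if any(frozenset((labels[i], labels[j])) in diff for i, j in combinations(combo, 2)):
                continue
            if any(set(combo) <= set(c) for c in cliques):
                continue
            cliques.append(combo)
    cliques.sort(key=lambda c: c[0])
    letters = {lab: "" for lab in labels}
    for letter, clique in zip("ABCDEFGHIJKLMNOPQRSTUVWXYZ", cliques):
        for i in clique:
            letters[labels[i]] += letter
    return letters


def pairwise_contrasts(
    values, groups, method: str = "tukey", alpha: float = 0.05
) -> pd.DataFrame:
    """Post-hoc pairwise comparisons after an omnibus test.

    ``method="tukey"`` uses Tukey's HSD (studentized-range quantiles);
    ``method="rank"`` uses pairwise Wilcoxon rank-sum tests.  In both
    branches significance is judged against a Bonferroni-adjusted alpha of
    ``alpha / n_pairs``, matching a three-group design tested at 0.05/3.
    The result carries a ``letters`` attribute (compact letter display).
    """
    samples, labels = _split(values, groups)
    if any(s.size < 2 for s in samples):
        raise ValueError("every group needs at least two observations")
    pairs = list(combinations(range(len(labels)), 2))
    alpha_adj = alpha / len(pairs)
    rows = []
    if method == "tukey":
        res = stats.tukey_hsd(*samples)
        for i, j in pairs:
            rows.append((labels[i], labels[j], float(res.pvalue[i, j])))
    elif method == "rank":
        for i, j in pairs:
            stat, p = stats.mannwhitneyu(samples[i], samples[j], alternative="two-sided")
            rows.append((labels[i], labels[j], float(p)))
    else:
        raise ValueError("method must be 'tukey' or 'rank'")
    out = pd.DataFrame(rows, columns=["group_1", "group_2", "p"])
    out["alpha_adj"] = alpha_adj
    out["significant"] = out["p"] <= alpha_adj
    different = [
        (r.group_1, r.group_2) for r in out.itertuples() if r.significant
    ]
    out.attrs["letters"] = compact_letters(labels, different)
    return out


def spearman_rho(x, y, n_perm: int = 10_000, seed=None):
    """Spearman rank correlation with a permutation p-value.

    rho is the Pearson correlation of midranks; the two-sided p-value
    permutes one variable ``n_perm`` times (add-one estimator).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    rx_c = rx - rx.mean()
    denom = np.sqrt((rx_c**2).sum())
    for _ in range(int(n_perm)):
        perm = rng.permutation(ry)
        r = float(np.dot(rx_c, perm - perm.mean()) / (denom * np.sqrt(((perm - perm.mean()) ** 2).sum())))
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return rho, float(p)
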