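"""Diversity indices, distance-based group tests, and time-trend fits.

Covers the community-level statistics used around the network analysis:
Shannon alpha diversity, Bray-Curtis beta diversity with PERMANOVA (single
factor and sequential two-factor), within-group dispersion comparisons,
the top-k Kruskal-Wallis abundance screen, and least-squares quadratic
trend fits over ordered cohort timepoints (R00=0 ... R05=5), whose sign
classifies a trajectory as U-shaped (convex) or inverse-U (concave).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kruskal

from .tables import AbundanceTable, to_relative
from .sparcc import bh_adjust

__all__ = [
    "DistanceMatrix",
    "TrendFit",
    "PermanovaResult",
    "shannon_index",
    "bray_curtis",
    "within_group_dispersion",
    "permanova",
    "permanova_two_factor",
    "kruskal_wallis_screen",
    "fit_trend",
]


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample distances with zero diagonal."""

    sample_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.sample_ids):
            raise ValueError("distance matrix shape does not match sample_ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(v) != 0).any():
            raise ValueError("distance matrix diagonal must be zero")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        self.values = v

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class TrendFit:
    """Least-squares time-trend fit over integer group ranks."""

    coefficients: tuple  # quadratic: (intercept, linear, quadratic); exponential: (a, b, c)
    rss: float
    fitted_values: np.ndarray
    ranks: np.ndarray
    convex: bool
    shape: str  # "convex" | "concave" | "flat"
    vertex: float | None
    vertex_in_range: bool
    model: str = "quadratic"

    def predict(self, ranks) -> np.ndarray:
        r = np.asarray(ranks, float)
        if self.model == "exponential":
            a, b, c = self.coefficients
            return a + b * np.exp(c * r)
        c0, c1, c2 = self.coefficients
        return c0 + c1 * r + c2 * r * r


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p: float
    n_perm: int
    df_between: int
    df_within: int


def shannon_index(composition) -> float:
    """Shannon entropy H = -sum p_i ln p_i (natural log), scale-invariant."""
    x = np.asarray(composition, float)
    if (x < 0).any():
        raise ValueError("composition entries must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("composition must have positive sum")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples (columns).

    d(u, v) = 1 - 2 sum_i min(u_i, v_i) / (sum u + sum v); a pair of
    all-zero samples gets distance 0 with a warning.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    x = table.values().T  # samples x features
    with np.errstate(invalid="ignore", divide="ignore"):
        condensed = pdist(x, metric="braycurtis")
    if np.isnan(condensed).any():
        warnings.warn("distance between all-zero samples defined as 0", stacklevel=2)
        condensed = np.nan_to_num(condensed, nan=0.0)
    return DistanceMatrix(sample_ids=list(table.sample_ids), values=squareform(condensed))


def _group_arrays(groups, sample_ids) -> pd.Series:
    if isinstance(groups, pd.Series):
        return groups.reindex(sample_ids)
    return pd.Series([groups[s] for s in sample_ids], index=sample_ids)


def within_group_dispersion(d: DistanceMatrix, groups) -> tuple[dict, float, float]:
    """Within-group pairwise distances per group, compared by Kruskal-Wallis.

    Groups with fewer than 2 samples are excluded with a warning.  Returns
    ``(distances_by_group, H, p)``; a degenerate comparison (all distances
    identical) reports ``p = nan``.
    """
    labels = _group_arrays(groups, d.sample_ids)
    by_group: dict = {}
    idx_of = {s: i for i, s in enumerate(d.sample_ids)}
    for group, samples in labels.groupby(labels).groups.items():
        samples = list(samples)
        if len(samples) < 2:
            warnings.warn(f"group {group!r} has <2 samples; excluded", stacklevel=2)
            continue
        vals = []
        for a in range(len(samples)):
            for b in range(a + 1, len(samples)):
                vals.append(d.values[idx_of[samples[a]], idx_of[samples[b]]])
        by_group[group] = np.asarray(vals)
    if len(by_group) < 2:
        raise ValueError("need at least 2 groups with >= 2 samples")
    try:
        h, p = kruskal(*by_group.values())
    except ValueError:  # all values identical
        warnings.warn("within-group distances are all identical; test degenerate", stacklevel=2)
        h, p = 0.0, float("nan")
    return by_group, float(h), float(p)


def _permanova_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and integer group codes."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    return ss_total, ss_within


def permanova(
    d: DistanceMatrix, groups, n_perm: int = 999, seed: int | None = 0
) -> PermanovaResult:
    """One-factor PERMANOVA: pseudo-F, R^2 and a label-permutation p-value.

    Partitions the total sum of squared distances into between- and
    within-group components (the Gower-centering identity); p is the
    add-one-corrected fraction of unrestricted label permutations with
    pseudo-F at least as large as observed.
    """
    labels = _group_arrays(groups, d.sample_ids)
    codes, uniques = pd.factorize(labels)
    a = len(uniques)
    n = len(d.sample_ids)
    if a < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if a >= n:
        raise ValueError("all-distinct group labels leave no residual degrees of freedom")
    if n_perm < 99:
        warnings.warn(f"n_perm={n_perm} is low; p-value resolution is coarse", stacklevel=2)
    d2 = d.values**2
    ss_total, ss_within = _permanova_ss(d2, codes, a)
    ss_between = ss_total - ss_within
    df_b, df_w = a - 1, n - a
    f_obs = (ss_between / df_b) / (ss_within / df_w)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        sst, ssw = _permanova_ss(d2, perm, a)
        f_perm = ((sst - ssw) / df_b) / (ssw / df_w)
        if f_perm >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r2=float(ss_between / ss_total),
        p=float(p),
        n_perm=n_perm,
        df_between=df_b,
        df_within=df_w,
    )


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ (d**2) @ j


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x.T @ x) @ x.T


def permanova_two_factor(
    d: DistanceMatrix,
    factor_a,
    factor_b,
    n_perm: int = 999,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Sequential (type-I-like) two-factor PERMANOVA on a distance matrix.

    Factor A is fitted first, B after A; each row reports SS, R^2, pseudo-F
    and an unrestricted-permutation p-value.  The sequential order means the
    factor R^2 values are order-dependent — the order fitted is the order
    given and is stated in the output index.
    """
    la = _group_arrays(factor_a, d.sample_ids)
    lb = _group_arrays(factor_b, d.sample_ids)
    n = len(d.sample_ids)
    g = _gower_center(d.values)
    xa = pd.get_dummies(la).to_numpy(float)
    xab = np.hstack([xa, pd.get_dummies(lb).to_numpy(float)])
    ha = _hat(xa)
    hab = _hat(xab)
    df_a = np.linalg.matrix_rank(xa) - 1
    df_ab = np.linalg.matrix_rank(xab) - 1
    df_b = df_ab - df_a
    df_res = n - 1 - df_ab
    if df_a < 1 or df_b < 1 or df_res < 1:
        raise ValueError("insufficient degrees of freedom for two-factor PERMANOVA")

    def partition(gm):
        ss_total = np.trace(gm)
        ss_a = np.trace(ha @ gm)
        ss_ab = np.trace(hab @ gm)
        return ss_total, ss_a, ss_ab - ss_a, ss_total - ss_ab

    ss_total, ss_a, ss_b, ss_res = partition(g)
    f_a = (ss_a / df_a) / (ss_res / df_res)
    f_b = (ss_b / df_b) / (ss_res / df_res)
    rng = np.random.default_rng(seed)
    count_a = count_b = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        _, sa, sb, sr = partition(gp)
        if (sa / df_a) / (sr / df_res) >= f_a:
            count_a += 1
        if (sb / df_b) / (sr / df_res) >= f_b:
            count_b += 1
    rows = [
        {
            "factor": "A (fitted first)",
            "ss": ss_a,
            "df": df_a,
            "r2": ss_a / ss_total,
            "pseudo_f": f_a,
            "p": (1 + count_a) / (1 + n_perm),
        },
        {
            "factor": "B (after A)",
            "ss": ss_b,
            "df": df_b,
            "r2": ss_b / ss_total,
            "pseudo_f": f_b,
            "p": (1 + count_b) / (1 + n_perm),
        },
        {
            "factor": "residual",
            "ss": ss_res,
            "df": df_res,
            "r2": ss_res / ss_total,
            "pseudo_f": np.nan,
            "p": np.nan,
        },
    ]
    return pd.DataFrame(rows).set_index("factor")


def kruskal_wallis_screen(
    table: AbundanceTable, groups, alpha: float = 0.05, adjust: str | None = None
) -> pd.DataFrame:
    """Per-feature Kruskal-Wallis test across groups; retain p < alpha.

    Unadjusted by default; ``adjust="bh"`` screens on BH-adjusted q instead.
    Constant features are degenerate: H = 0, p = 1, never retained.
    """
    labels = _group_arrays(groups, table.sample_ids)
    codes, uniques = pd.factorize(labels)
    if len(uniques) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for feature in table.feature_ids:
        x = table.data.loc[feature].to_numpy(float)
        by_group = [x[codes == gi] for gi in range(len(uniques))]
        if np.ptp(x) == 0:
            rows.append({"feature": feature, "H": 0.0, "p": 1.0, "degenerate": True})
            continue
        h, p = kruskal(*by_group)
        rows.append({"feature": feature, "H": float(h), "p": float(p), "degenerate": False})
    out = pd.DataFrame(rows, columns=["feature", "H", "p", "degenerate"])
    if adjust == "bh":
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["retained"] = (out["q"] < alpha) & ~out["degenerate"]
    else:
        out["retained"] = (out["p"] < alpha) & ~out["degenerate"]
    return out


def fit_trend(values, ranks, model: str = "quadratic") -> TrendFit:
    """Least-squares trend fit over integer group ranks.

    The default model is quadratic, y = c0 + c1 r + c2 r^2: the quadratic
    sign classifies the trajectory as convex (c2 > 0, "first decreasing and
    then increasing" when the vertex falls inside the rank range) or
    concave.  ``model="exponential"`` fits the asymptotic alternative
    y = a + b exp(c r) by nonlinear least squares; there the sign of b
    classifies curvature (y'' = b c^2 exp(c r)).  Requires at least 3
    distinct ranks.
    """
    y = np.asarray(values, float)
    r = np.asarray(ranks, float)
    if y.shape != r.shape:
        raise ValueError("values and ranks must have equal length")
    if len(np.unique(r)) < 3:
        raise ValueError("need at least 3 distinct ranks for a quadratic fit")
    if model == "exponential":
        return _fit_exponential(y, r)
    if model != "quadratic":
        raise ValueError(f"model must be 'quadratic' or 'exponential', got {model!r}")
    x = np.column_stack([np.ones_like(r), r, r * r])
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ coef
    rss = float(((y - fitted) ** 2).sum())
    c0, c1, c2 = (float(c) for c in coef)
    tol = 1e-12 * max(1.0, abs(c0), abs(c1))
    if c2 > tol:
        shape = "convex"
    elif c2 < -tol:
        shape = "concave"
    else:
        shape = "flat"
    vertex = float(-c1 / (2 * c2)) if shape != "flat" else None
    vertex_in_range = bool(vertex is not None and r.min() < vertex < r.max())
    return TrendFit(
        coefficients=(c0, c1, c2),
        rss=rss,
        fitted_values=fitted,
        ranks=r,
        convex=bool(shape == "convex"),
        shape=shape,
        vertex=vertex,
        vertex_in_range=vertex_in_range,
    )


def _fit_exponential(y: np.ndarray, r: np.ndarray) -> TrendFit:
    from scipy.optimize import curve_fit

    def f(rr, a, b, c):
        return a + b * np.exp(c * rr)

    slope = np.polyfit(r, y, 1)[0]
    p0 = (float(y.mean()), float(y[r == r.min()].mean() - y.mean()), -0.5 if slope < 0 else 0.5)
    try:
        popt, _ = curve_fit(f, r, y, p0=p0, maxfev=20_000)
    except RuntimeError as err:
        raise ValueError(f"exponential trend fit did not converge: {err}") from err
    a, b, c = (float(v) for v in popt)
    fitted = f(r, a, b, c)
    rss = float(((y - fitted) ** 2).sum())
    tol = 1e-12 * max(1.0, abs(a))
    curvature = b  # sign of y'' = b c^2 exp(c r)
    shape = "convex" if curvature > tol else "concave" if curvature < -tol else "flat"
    return TrendFit(
        coefficients=(a, b, c),
        rss=rss,
        fitted_values=fitted,
        ranks=r,
        convex=bool(shape == "convex"),
        shape=shape,
        vertex=None,
        vertex_in_range=False,
        model="exponential",
    )
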