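"""SparCC: compositionally robust correlation inference.

Relative abundances are compositions, so naive Pearson correlations between
taxa are distorted by closure.  SparCC instead works from the variances of
pairwise log-ratios,

    t_ij = Var_s[ log(x_is / x_js) ],

which are invariant to the closure, and estimates each taxon's latent
("basis") log-abundance variance w_i by solving the linear system obtained
under the sparsity assumption that most basis correlations are near zero:

    sum_j t_ij  ~=  (D - 2) * w_i + sum_j w_j .

Basis correlations follow as rho_ij = (w_i + w_j - t_ij) / (2 sqrt(w_i w_j)),
clamped to [-1, 1].  Strongly correlated pairs violate the sparsity
assumption, so the strongest pair above a threshold is iteratively excluded
from the row sums and the system re-solved.  For count input the whole
estimate is averaged over Dirichlet-posterior resamples of the underlying
fractions; significance comes from a permutation bootstrap with
Benjamini-Hochberg FDR control over the pair family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import lapack
from statsmodels.stats.multitest import multipletests

from .tables import AbundanceTable, to_relative

__all__ = [
    "LogRatioVarianceMatrix",
    "CorrelationResult",
    "log_ratio_variances",
    "basis_correlations",
    "sparcc_estimate",
    "bootstrap_pvalues",
    "bh_adjust",
    "edge_filter",
    "run_sparcc",
    "SparCC",
]

_OMEGA_FLOOR = 1e-10


@dataclass
class LogRatioVarianceMatrix:
    """Symmetric matrix of log-ratio variances t_ij with zero diagonal."""

    t: np.ndarray
    feature_ids: list

    def __post_init__(self) -> None:
        t = np.asarray(self.t, float)
        if t.ndim != 2 or t.shape[0] != t.shape[1]:
            raise ValueError("t must be square")
        if not np.allclose(t, t.T, atol=1e-12):
            raise ValueError("t must be symmetric")
        if not np.isfinite(t).all():
            raise ValueError("t must be finite")
        np.fill_diagonal(t, 0.0)
        self.t = t


@dataclass
class CorrelationResult:
    """SparCC correlations with bootstrap significance."""

    feature_ids: list
    rho: np.ndarray  # basis correlations, diag exactly 1
    omega: np.ndarray  # basis variances
    p: np.ndarray | None = None  # bootstrap pseudo-p, symmetric
    q: np.ndarray | None = None  # BH-adjusted over the pair family
    n_resamples: int = 0
    n_bootstrap: int = 0
    seed: int | None = None

    def rho_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.feature_ids, columns=self.feature_ids)


def log_ratio_variances(
    table: AbundanceTable, pseudocount: float = 1e-6
) -> LogRatioVarianceMatrix:
    """Sample variance of log((x_i + pc) / (x_j + pc)) for every feature pair.

    Computed through the log-scale covariance identity
    t_ij = v_i + v_j - 2 c_ij, which equals the per-pair variance exactly.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    values = table.values()
    all_zero = np.flatnonzero((values == 0).all(axis=1))
    if all_zero.size:
        raise ValueError(
            f"feature {table.feature_ids[all_zero[0]]!r} is zero in every sample; "
            "apply a prevalence filter before SparCC"
        )
    logs = np.log(values + pseudocount)  # features x samples
    cov = np.cov(logs, ddof=1)
    cov = np.atleast_2d(cov)
    v = np.diag(cov)
    t = v[:, None] + v[None, :] - 2.0 * cov
    t = np.maximum(0.5 * (t + t.T), 0.0)  # exact symmetry; clip -0.0 noise
    np.fill_diagonal(t, 0.0)
    return LogRatioVarianceMatrix(t=t, feature_ids=list(table.feature_ids))


def _rho_from_omega(t: np.ndarray, omega: np.ndarray) -> np.ndarray:
    # exactly symmetric by construction: every elementwise operation below
    # acts on symmetric operands
    sq = np.sqrt(omega)
    rho = (omega[:, None] + omega[None, :] - t) / (2.0 * np.outer(sq, sq))
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def basis_correlations(
    lrv: LogRatioVarianceMatrix,
    exclusion_threshold: float = 0.1,
    exclusion_iterations: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Basis correlations rho and variances omega from log-ratio variances.

    After the initial solve, the most strongly correlated pair whose |rho|
    exceeds ``exclusion_threshold`` is removed from the row sums and the
    system re-solved — strongly coupled pairs are exactly the ones that
    break the sparsity assumption.  By default this repeats until no
    eligible pair exceeds the threshold (a cap of one round per pair
    guarantees termination); pass an integer to bound the rounds instead.
    One round per strong pair is essential when correlated pairs are not
    rare: with block structure covering ~20% of pairs, a small fixed round
    budget leaves the basis variances biased low and drags uncorrelated
    pairs to spuriously negative estimates.
    """
    t = lrv.t
    d = t.shape[0]
    if d < 4:
        raise ValueError(f"SparCC needs at least 4 features, got {d}")
    if exclusion_iterations is None:
        exclusion_iterations = d * (d - 1) // 2
    # incremental state: the system matrix, its row sums, and an eligibility
    # mask, all updated in place as pairs are excluded
    m = np.ones((d, d)) + np.eye(d) * (d - 2)
    t_row = t.sum(axis=1).copy()
    eligible = ~np.eye(d, dtype=bool)
    exclusion_count = np.zeros(d, dtype=int)
    negative_omega = False

    def solve(mat, rhs):
        # the system starts positive definite, so a Cholesky solve is the
        # fast path; the exclusion path can make it singular (e.g. two
        # equal blocks with every within pair excluded, where only the
        # total basis variance is identified), in which case min-norm
        # least squares resolves the unidentified direction symmetrically
        _, sol, info = lapack.dposv(mat, rhs)
        if info != 0:  # not positive definite
            sol, *_ = np.linalg.lstsq(mat, rhs, rcond=1e-8)
        return sol

    dropped = np.zeros(d, dtype=bool)

    def estimate(mat, rhs):
        nonlocal negative_omega
        omega = solve(mat, rhs)
        if (omega <= 0).any():
            negative_omega = True
            omega = np.maximum(omega, _OMEGA_FLOOR)
        rho = _rho_from_omega(t, omega)
        # a collapsed basis variance (orders of magnitude below the bulk)
        # or a dropped component carries no usable pairwise signal: its
        # pairs would clamp to +-1 purely through the tiny denominator;
        # report no correlation for them
        degenerate = dropped | (omega < 1e-3 * omega.mean())
        if degenerate.any():
            rho[degenerate, :] = 0.0
            rho[:, degenerate] = 0.0
            np.fill_diagonal(rho, 1.0)
        return omega, rho

    def exclude_pair(i, j):
        eligible[i, j] = eligible[j, i] = False
        m[i, i] -= 1.0
        m[j, j] -= 1.0
        m[i, j] = m[j, i] = 0.0
        t_row[i] -= t[i, j]
        t_row[j] -= t[i, j]

    omega, rho = estimate(m, t_row)
    for _ in range(exclusion_iterations):
        masked = np.where(eligible, np.abs(rho), 0.0)
        idx = int(np.argmax(masked))
        i, j = divmod(idx, d)
        if masked[i, j] <= exclusion_threshold:
            break
        exclude_pair(i, j)
        exclusion_count[i] += 1
        exclusion_count[j] += 1
        # a component excluded from nearly every pair no longer constrains
        # the system usefully: drop it entirely (its remaining pairs are
        # excluded too and its equation pinned to the last estimate)
        for k in (i, j):
            if exclusion_count[k] >= d - 3 and not dropped[k]:
                for other in np.flatnonzero(eligible[k]):
                    exclude_pair(k, int(other))
                dropped[k] = True
                m[k, :] = 0.0
                m[:, k] = 0.0
                m[k, k] = 1.0
                t_row[k] = omega[k]
        omega, rho = estimate(m, t_row)
    if negative_omega:
        warnings.warn(
            "negative basis variance estimate clipped to tolerance "
            "(degenerate sparsity approximation)",
            stacklevel=2,
        )
    return rho, omega


def sparcc_estimate(
    table: AbundanceTable,
    n_resamples: int = 20,
    seed: int | None = 0,
    pseudocount: float = 1e-6,
    exclusion_threshold: float = 0.1,
    exclusion_iterations: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Full SparCC point estimate for a count or relative table.

    Count input: fractions are drawn ``n_resamples`` times from the
    per-sample Dirichlet posterior (counts + 1) and the basis-correlation
    estimates averaged.  Relative input: a single deterministic pass, exactly
    ``basis_correlations(log_ratio_variances(table))``.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    if table.kind == "relative":
        lrv = log_ratio_variances(table, pseudocount=pseudocount)
        return basis_correlations(lrv, exclusion_threshold, exclusion_iterations)
    return _estimate_from_counts(
        table.values(),
        n_resamples=n_resamples,
        seed=seed,
        exclusion_threshold=exclusion_threshold,
        exclusion_iterations=exclusion_iterations,
    )


def _lrv_from_positive(fractions: np.ndarray) -> LogRatioVarianceMatrix:
    """t matrix from a strictly positive features x samples matrix."""
    logs = np.log(fractions)
    cov = np.atleast_2d(np.cov(logs, ddof=1))
    v = np.diag(cov)
    t = np.maximum(v[:, None] + v[None, :] - 2.0 * cov, 0.0)
    np.fill_diagonal(t, 0.0)
    return LogRatioVarianceMatrix(t=0.5 * (t + t.T), feature_ids=list(range(t.shape[0])))


def _estimate_from_counts(
    values: np.ndarray,
    n_resamples: int,
    seed,
    exclusion_threshold: float,
    exclusion_iterations,
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    counts = values.T  # samples x features
    rho_sum = None
    omega_sum = None
    for _ in range(n_resamples):
        # per-sample Dirichlet(counts + 1) draws, vectorised through gammas
        gammas = rng.standard_gamma(counts + 1.0)
        fractions = gammas / gammas.sum(axis=1, keepdims=True)
        lrv = _lrv_from_positive(fractions.T)
        rho, omega = basis_correlations(lrv, exclusion_threshold, exclusion_iterations)
        rho_sum = rho if rho_sum is None else rho_sum + rho
        omega_sum = omega if omega_sum is None else omega_sum + omega
    rho = np.clip(rho_sum / n_resamples, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho, omega_sum / n_resamples


def bootstrap_pvalues(
    table: AbundanceTable,
    rho_observed: np.ndarray,
    n_bootstrap: int = 100,
    seed: int | None = 0,
    n_resamples: int = 20,
    **sparcc_kwargs,
) -> np.ndarray:
    """Two-sided permutation-bootstrap pseudo-p-values for SparCC correlations.

    Each bootstrap permutes every feature's values independently across
    samples (destroying association while preserving marginals) and re-runs
    the full estimate; p = (1 + #{|rho_boot| >= |rho_obs|}) / (1 + B), so p
    is bounded below by 1/(1+B) and never exactly zero.
    """
    if n_bootstrap < 20:
        raise ValueError("n_bootstrap must be >= 20")
    rng = np.random.default_rng(seed)
    values = table.values()
    d, n = values.shape
    abs_obs = np.abs(np.asarray(rho_observed))
    exceed = np.zeros((d, d))
    pseudocount = sparcc_kwargs.pop("pseudocount", 1e-6)
    exclusion_threshold = sparcc_kwargs.pop("exclusion_threshold", 0.1)
    exclusion_iterations = sparcc_kwargs.pop("exclusion_iterations", None)
    if sparcc_kwargs:
        raise TypeError(f"unexpected arguments: {sorted(sparcc_kwargs)}")
    for _ in range(n_bootstrap):
        permuted = np.empty_like(values)
        for i in range(d):
            permuted[i] = values[i, rng.permutation(n)]
        if table.kind == "relative":
            # a per-feature permutation is no longer a composition; the
            # log-ratio statistic only needs strictly positive entries
            lrv = _lrv_from_positive(permuted + pseudocount)
            rho_b, _ = basis_correlations(lrv, exclusion_threshold, exclusion_iterations)
        else:
            rho_b, _ = _estimate_from_counts(
                permuted,
                n_resamples=n_resamples,
                seed=int(rng.integers(0, 2**31 - 1)),
                exclusion_threshold=exclusion_threshold,
                exclusion_iterations=exclusion_iterations,
            )
        exceed += np.abs(rho_b) >= abs_obs
    p = (1.0 + exceed) / (1.0 + n_bootstrap)
    p = 0.5 * (p + p.T)
    np.fill_diagonal(p, 0.0)
    return p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    For a square symmetric p matrix the family is the set of unordered
    off-diagonal pairs; a 1-D array is adjusted as-is.  Empty input passes
    through.
    """
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if p.ndim == 1:
        return multipletests(p, method="fdr_bh")[1]
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("p must be 1-D or square")
    d = p.shape[0]
    iu = np.triu_indices(d, k=1)
    if iu[0].size == 0:
        return np.zeros_like(p)
    q_flat = multipletests(p[iu], method="fdr_bh")[1]
    q = np.zeros((d, d))
    q[iu] = q_flat
    q = q + q.T
    return q


def edge_filter(
    result: CorrelationResult,
    r_threshold: float = 0.7,
    q_threshold: float = 0.05,
    signed_mode: bool = False,
) -> pd.DataFrame:
    """Edges surviving the correlation-strength and FDR cuts.

    Default mode keeps pairs with |rho| > r_threshold and q < q_threshold,
    retaining the correlation sign as an edge attribute; ``signed_mode``
    keeps only rho > r_threshold (positive correlations), the literal
    reading of an unsigned "R > 0.7" rule.
    """
    if not 0.0 <= r_threshold <= 1.0:
        raise ValueError("r_threshold must lie in [0, 1]")
    if not 0.0 <= q_threshold <= 1.0:
        raise ValueError("q_threshold must lie in [0, 1]")
    if result.q is None or result.p is None:
        raise ValueError("CorrelationResult lacks p/q values; run the bootstrap first")
    ids = result.feature_ids
    rows = []
    d = len(ids)
    for i in range(d):
        for j in range(i + 1, d):
            rho = float(result.rho[i, j])
            strong = rho > r_threshold if signed_mode else abs(rho) > r_threshold
            if strong and result.q[i, j] < q_threshold:
                rows.append(
                    {
                        "feature_a": ids[i],
                        "feature_b": ids[j],
                        "rho": rho,
                        "p": float(result.p[i, j]),
                        "q": float(result.q[i, j]),
                        "sign": 1 if rho >= 0 else -1,
                    }
                )
    return pd.DataFrame(rows, columns=["feature_a", "feature_b", "rho", "p", "q", "sign"])


def run_sparcc(
    table: AbundanceTable,
    n_resamples: int = 20,
    n_bootstrap: int = 100,
    seed: int | None = 0,
    pseudocount: float = 1e-6,
    exclusion_threshold: float = 0.1,
    exclusion_iterations: int | None = None,
) -> CorrelationResult:
    """Point estimate + bootstrap significance + BH FDR in one call."""
    kwargs = dict(
        pseudocount=pseudocount,
        exclusion_threshold=exclusion_threshold,
        exclusion_iterations=exclusion_iterations,
    )
    seeds = np.random.SeedSequence(seed).spawn(2)
    est_seed = int(seeds[0].generate_state(1)[0] % (2**31 - 1))
    boot_seed = int(seeds[1].generate_state(1)[0] % (2**31 - 1))
    rho, omega = sparcc_estimate(table, n_resamples=n_resamples, seed=est_seed, **kwargs)
    p = bootstrap_pvalues(
        table, rho, n_bootstrap=n_bootstrap, seed=boot_seed, n_resamples=n_resamples, **kwargs
    )
    q = bh_adjust(p)
    return CorrelationResult(
        feature_ids=list(table.feature_ids),
        rho=rho,
        omega=omega,
        p=p,
        q=q,
        n_resamples=n_resamples,
        n_bootstrap=n_bootstrap,
        seed=seed,
    )


class SparCC:
    """scikit-learn-style wrapper around the SparCC pipeline.

    ``fit`` takes a samples x features array (the sklearn orientation) or an
    :class:`AbundanceTable` and exposes ``correlation_``, ``basis_variance_``,
    ``pvalues_`` and ``qvalues_``.
    """

    def __init__(
        self,
        kind: str = "counts",
        n_resamples: int = 20,
        n_bootstrap: int = 100,
        seed: int | None = 0,
        pseudocount: float = 1e-6,
        exclusion_threshold: float = 0.1,
        exclusion_iterations: int | None = None,
    ):
        self.kind = kind
        self.n_resamples = n_resamples
        self.n_bootstrap = n_bootstrap
        self.seed = seed
        self.pseudocount = pseudocount
        self.exclusion_threshold = exclusion_threshold
        self.exclusion_iterations = exclusion_iterations

    def get_params(self, deep: bool = True) -> dict:
        return {
            "kind": self.kind,
            "n_resamples": self.n_resamples,
            "n_bootstrap": self.n_bootstrap,
            "seed": self.seed,
            "pseudocount": self.pseudocount,
            "exclusion_threshold": self.exclusion_threshold,
            "exclusion_iterations": self.exclusion_iterations,
        }

    def set_params(self, **params) -> "SparCC":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y=None) -> "SparCC":
        if isinstance(X, AbundanceTable):
            table = X
        else:
            X = np.asarray(X, float)
            ids = [f"f{i}" for i in range(X.shape[1])]
            samples = [f"s{i}" for i in range(X.shape[0])]
            df = pd.DataFrame(X.T, index=ids, columns=samples)
            table = AbundanceTable(df, kind=self.kind)
        if table.kind == "counts":
            table_rel = to_relative(table)
        else:
            table_rel = table
        result = run_sparcc(
            table if table.kind == "counts" else table_rel,
            n_resamples=self.n_resamples,
            n_bootstrap=self.n_bootstrap,
            seed=self.seed,
            pseudocount=self.pseudocount,
            exclusion_threshold=self.exclusion_threshold,
            exclusion_iterations=self.exclusion_iterations,
        )
        self.result_ = result
        self.feature_names_in_ = list(result.feature_ids)
        self.correlation_ = result.rho
        self.basis_variance_ = result.omega
        self.pvalues_ = result.p
        self.qvalues_ = result.q
        return self

    def transform(self, X=None) -> np.ndarray:
        if not hasattr(self, "correlation_"):
            raise ValueError("SparCC instance is not fitted yet")
        return self.correlation_
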