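"""Synthetic compositional metagenomes with planted guild structure.

The generative model is the one under which SparCC's estimand is well
defined: per-sample latent log-abundances are multivariate normal with a
block covariance (the planted modules), exponentiated and closed to a
composition, and observed as multinomial counts at a fixed sequencing depth,
optionally with additional structural zeros.  Every generator records its
ground truth (:class:`SyntheticTruth`) so downstream recovery can be scored,
and all randomness flows through one explicit integer seed per call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import AbundanceTable, ClinicalTable

__all__ = [
    "CovarianceSpec",
    "SyntheticTruth",
    "CohortDesign",
    "CohortBundle",
    "build_covariance",
    "simulate_counts",
    "simulate_clinical",
    "simulate_cohort",
    "simulate_ko_table",
]

_PSD_TOL = 1e-8


@dataclass
class CovarianceSpec:
    """Latent log-scale covariance with disjoint equicorrelated blocks.

    ``module_sizes`` carve the first ``sum(module_sizes)`` taxa into planted
    modules with pairwise correlation ``within_r``; pairs straddling blocks
    (and pairs involving leftover "background" taxa) get ``between_r``.
    ``log_mean``/``log_sd`` default to 0 and 1 per taxon.
    """

    n_taxa: int
    module_sizes: list = field(default_factory=list)
    within_r: float = 0.8
    between_r: float = 0.0
    log_mean: np.ndarray | None = None
    log_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be positive")
        if any(s < 1 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if sum(self.module_sizes) > self.n_taxa:
            raise ValueError(
                f"module sizes sum to {sum(self.module_sizes)} > n_taxa={self.n_taxa}"
            )
        for name in ("within_r", "between_r"):
            r = getattr(self, name)
            if not -1.0 < r < 1.0:
                raise ValueError(f"{name} must lie in (-1, 1), got {r}")
        self.log_mean = (
            np.zeros(self.n_taxa) if self.log_mean is None else np.asarray(self.log_mean, float)
        )
        self.log_sd = (
            np.ones(self.n_taxa) if self.log_sd is None else np.asarray(self.log_sd, float)
        )
        if self.log_mean.shape != (self.n_taxa,) or self.log_sd.shape != (self.n_taxa,):
            raise ValueError("log_mean and log_sd must have length n_taxa")
        if (self.log_sd <= 0).any():
            raise ValueError("log_sd entries must be positive")
        # validate PSD at construction
        build_covariance(self, _validated=True)

    def taxon_ids(self) -> list:
        width = max(3, len(str(self.n_taxa)))
        return [f"t{i:0{width}d}" for i in range(1, self.n_taxa + 1)]

    def module_of_taxon(self) -> dict:
        out = {}
        ids = self.taxon_ids()
        pos = 0
        for b, size in enumerate(self.module_sizes, start=1):
            for _ in range(size):
                out[ids[pos]] = f"block{b}"
                pos += 1
        for i in range(pos, self.n_taxa):
            out[ids[i]] = "background"
        return out


@dataclass
class SyntheticTruth:
    """Ground-truth record for recovery tests."""

    covariance_spec: CovarianceSpec
    module_of_taxon: dict
    clinical_coefficients: dict = field(default_factory=dict)
    ko_links: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path) -> None:
        spec = self.covariance_spec
        payload = {
            "seed": self.seed,
            "module_of_taxon": self.module_of_taxon,
            "clinical_coefficients": {
                k: [[f, float(e)] for f, e in v] for k, v in self.clinical_coefficients.items()
            },
            "ko_links": self.ko_links,
            "covariance_spec": {
                "n_taxa": spec.n_taxa,
                "module_sizes": list(spec.module_sizes),
                "within_r": spec.within_r,
                "between_r": spec.between_r,
                "log_mean": np.asarray(spec.log_mean).tolist(),
                "log_sd": np.asarray(spec.log_sd).tolist(),
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


@dataclass
class CohortDesign:
    """Ordered cohort groups with per-attribute quadratic time trends.

    ``trend_profile`` maps an attribute name to quadratic coefficients
    ``(c0, c1, c2)`` over integer group rank (first group = rank 0), plus an
    optional per-sample Gaussian noise sd (defaults to 0.1):
    ``{"shannon": {"coefficients": [3.0, -0.8, 0.15], "noise_sd": 0.1}}``.
    """

    groups: list
    samples_per_group: list
    trend_profile: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.groups) != len(self.samples_per_group):
            raise ValueError("groups and samples_per_group must have equal length")
        if any(n < 1 for n in self.samples_per_group):
            raise ValueError("every group needs at least one sample")
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("group labels must be unique")


@dataclass
class CohortBundle:
    """Everything one synthetic cohort produces."""

    table: AbundanceTable
    metadata: pd.DataFrame  # sample_id index; columns: group, rank
    attributes: pd.DataFrame  # sample_id index; one column per trend attribute
    truth: SyntheticTruth


def build_covariance(spec: CovarianceSpec, _validated: bool = False) -> np.ndarray:
    """Latent covariance matrix implied by a :class:`CovarianceSpec`.

    Entries are ``r * sd_i * sd_j`` with ``r`` = within_r inside a block,
    between_r otherwise, and ``sd_i**2`` on the diagonal.  Rejected if not
    positive semi-definite.
    """
    n = spec.n_taxa
    corr = np.full((n, n), spec.between_r)
    pos = 0
    for size in spec.module_sizes:
        corr[pos : pos + size, pos : pos + size] = spec.within_r
        pos += size
    np.fill_diagonal(corr, 1.0)
    sd = np.asarray(spec.log_sd, float)
    cov = corr * np.outer(sd, sd)
    min_eig = float(np.linalg.eigvalsh(cov).min())
    if min_eig < -_PSD_TOL * max(1.0, float(sd.max()) ** 2):
        raise ValueError(
            f"covariance is not positive semi-definite (min eigenvalue {min_eig:.3g}); "
            "reduce |between_r| or block sizes"
        )
    return cov


def simulate_counts(
    spec: CovarianceSpec,
    n_samples: int,
    depth: int = 100_000,
    zero_inflation: float = 0.1,
    seed: int = 0,
) -> tuple[AbundanceTable, SyntheticTruth]:
    """Draw a count table from the log-normal -> composition -> multinomial model.

    Structural zeros are applied after the multinomial draw as independent
    Bernoulli masking at rate ``zero_inflation``.  Identical seeds reproduce
    the table bit-for-bit.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2 (downstream variance undefined)")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0.0 <= zero_inflation < 1.0:
        raise ValueError("zero_inflation must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    cov = build_covariance(spec)
    logs = rng.multivariate_normal(
        np.asarray(spec.log_mean, float), cov, size=n_samples, method="eigh"
    )
    basis = np.exp(logs)  # samples x taxa
    fractions = basis / basis.sum(axis=1, keepdims=True)
    counts = rng.multinomial(depth, fractions)  # samples x taxa
    if zero_inflation > 0:
        mask = rng.random(counts.shape) < zero_inflation
        counts = np.where(mask, 0, counts)
    ids = spec.taxon_ids()
    sample_ids = [f"s{i:04d}" for i in range(1, n_samples + 1)]
    table = AbundanceTable(
        pd.DataFrame(counts.T.astype(float), index=ids, columns=sample_ids), kind="counts"
    )
    truth = SyntheticTruth(
        covariance_spec=spec, module_of_taxon=spec.module_of_taxon(), seed=seed
    )
    return table, truth


def simulate_clinical(
    truth: SyntheticTruth,
    module_abundances: pd.DataFrame,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> ClinicalTable:
    """Clinical indicators as linear functions of named features plus noise.

    ``truth.clinical_coefficients`` maps each indicator name to a list of
    ``(feature_name, effect_size)`` pairs; features are rows of
    ``module_abundances`` (module x sample).  Coefficients stay recorded in
    ``truth`` so a refit can be scored against them.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    samples = list(module_abundances.columns)
    out = {}
    for indicator, effects in truth.clinical_coefficients.items():
        y = np.zeros(len(samples))
        for feature, effect in effects:
            if feature not in module_abundances.index:
                raise ValueError(
                    f"clinical indicator {indicator!r} references unknown feature {feature!r}"
                )
            y = y + float(effect) * module_abundances.loc[feature].to_numpy(float)
        y = y + rng.normal(0.0, noise_sd, size=len(samples))
        out[indicator] = y
    return ClinicalTable(pd.DataFrame(out, index=pd.Index(samples, name="sample_id")))


def _quadratic(coeffs, rank: float) -> float:
    c0, c1, c2 = coeffs
    return c0 + c1 * rank + c2 * rank * rank


def simulate_cohort(
    design: CohortDesign,
    spec: CovarianceSpec,
    seed: int = 0,
    depth: int = 100_000,
    zero_inflation: float = 0.1,
) -> CohortBundle:
    """Longitudinal cohort: per-group count tables plus trended attributes.

    Each attribute in ``design.trend_profile`` has expectation
    ``c0 + c1*rank + c2*rank**2`` at integer group rank (first group = 0)
    with i.i.d. Gaussian noise per sample; group sizes in the metadata honour
    ``samples_per_group`` exactly.
    """
    rng = np.random.default_rng(seed)
    tables = []
    meta_rows = []
    attr_rows = []
    truth = None
    for rank, (group, n_g) in enumerate(zip(design.groups, design.samples_per_group)):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        table_g, truth_g = simulate_counts(
            spec, max(n_g, 2), depth=depth, zero_inflation=zero_inflation, seed=sub_seed
        )
        # simulate_counts needs >=2 samples; trim back to the designed size
        cols = table_g.sample_ids[:n_g]
        df = table_g.data[cols]
        df.columns = [f"{group}_{i:03d}" for i in range(1, n_g + 1)]
        tables.append(df)
        if truth is None:
            truth = truth_g
        for sample in df.columns:
            meta_rows.append({"sample_id": sample, "group": group, "rank": rank})
            row = {"sample_id": sample}
            for attr, profile in design.trend_profile.items():
                mu = _quadratic(profile["coefficients"], rank)
                noise = profile.get("noise_sd", 0.1)
                row[attr] = mu + rng.normal(0.0, noise)
            attr_rows.append(row)
    merged = pd.concat(tables, axis=1)
    table = AbundanceTable(merged, kind="counts")
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    attributes = pd.DataFrame(attr_rows).set_index("sample_id")
    truth.seed = seed
    return CohortBundle(table=table, metadata=metadata, attributes=attributes, truth=truth)


def simulate_ko_table(
    truth: SyntheticTruth,
    module_abundances: pd.DataFrame,
    n_kos: int,
    linked_fraction: float = 0.2,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> AbundanceTable:
    """KO x sample table with a known fraction of module-coupled functions.

    ``round(linked_fraction * n_kos)`` KOs are noisy monotone (log-linear)
    functions of a planted module's abundance, assigned round-robin over the
    rows of ``module_abundances``; the rest are independent log-normal noise.
    Links are recorded in ``truth.ko_links`` (KO id -> module id).
    """
    if not 0.0 <= linked_fraction <= 1.0:
        raise ValueError("linked_fraction must lie in [0, 1]")
    if n_kos < 0:
        raise ValueError("n_kos must be non-negative")
    samples = list(module_abundances.columns)
    ko_ids = [f"K{i:05d}" for i in range(1, n_kos + 1)]
    if n_kos == 0:
        return AbundanceTable(
            pd.DataFrame(index=pd.Index([], name="feature_id"), columns=samples, dtype=float),
            kind="counts",
        )
    rng = np.random.default_rng(seed)
    n_linked = int(round(linked_fraction * n_kos))
    modules = list(module_abundances.index)
    if n_linked > 0 and not modules:
        raise ValueError("linked KOs requested but module_abundances has no rows")
    values = np.empty((n_kos, len(samples)))
    truth.ko_links = {}
    for i, ko in enumerate(ko_ids):
        if i < n_linked:
            module = modules[i % len(modules)]
            base = module_abundances.loc[module].to_numpy(float)
            noise = rng.normal(0.0, noise_sd, size=len(samples)) if noise_sd > 0 else 0.0
            values[i] = base * np.exp(noise)  # monotone in base when noise-free
            truth.ko_links[ko] = module
        else:
            values[i] = np.exp(rng.normal(0.0, 1.0, size=len(samples)))
    return AbundanceTable(
        pd.DataFrame(values, index=pd.Index(ko_ids, name="feature_id"), columns=samples),
        kind="counts",
    )
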