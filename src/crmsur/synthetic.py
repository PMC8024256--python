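"""Synthetic plantation data with the statistical structure the CRM assumes.

The generator emulates a single even-aged broadleaf plantation: a census of
trees spread over 5-cm diameter classes, a small stratified destructive
sample, and per-tree component biomasses whose ratios follow linear-in-dbh
means with cross-component residual correlation.  Defaults reproduce the
reference study conditions: a 921-tree census with class counts
167/518/208/25/3, a 12-tree destructive sample allocated 2/4/3/3/0, ratio
means and residual correlation/scale taken from the packaged reference fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import reference
from .records import COMPONENTS, SYSTEM_COMPONENTS, BiomassRecord, FieldSample, TreeRecord


def _default_true_beta() -> dict[str, tuple[float, float]]:
    return reference.reference_params()


def _default_error_corr() -> np.ndarray:
    return reference.reference_error_correlation()


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic plantation generator.

    Attributes
    ----------
    n_census : int
        Number of census trees (default 921).
    class_edges : tuple of float
        Diameter-class boundaries in cm, length ``n_classes + 1``; dbh is
        drawn uniformly within a tree's class interval.
    class_probs : tuple of float
        Probability of each diameter class; must sum to one.
    sample_allocation : tuple of int
        Destructive-sample size per class (default 2/4/3/3/0, total 12).
    true_beta : dict
        Per-component ``(beta0, beta1)`` of the linear-in-dbh ratio means
        for stem, branch and twig.
    error_corr : ndarray
        3x3 cross-component residual correlation (symmetric PD, unit
        diagonal).
    error_sd : tuple of float
        Residual standard deviation per modeled component.
    agb_coef : tuple of float
        ``(a, b)`` of the aboveground-biomass allometry AGB = a * dbh**b
        (kg, dbh in cm).  Only sets the mass scale; ratios are unaffected.
    ht_coef : tuple of float
        ``(c, d)`` of the mean height curve ht = c * dbh**d (m); default
        fitted through the reference diameter-class means.
    ht_cv : tuple of float
        Per-class coefficient of variation of the multiplicative lognormal
        height noise.
    moisture_ratio : dict
        Dry:fresh weight ratio per component, in (0, 1].
    subsample_fraction : float
        Fraction of each component's fresh weight taken as the subsample.
    max_redraws : int
        Cap on rejection redraws of the residual triple per tree.
    seed : int
        Default random seed for functions not given an explicit rng.
    """

    n_census: int = 921
    class_edges: tuple[float, ...] = reference.CLASS_EDGES
    class_probs: tuple[float, ...] = tuple(
        c / sum(reference.CENSUS_COUNTS) for c in reference.CENSUS_COUNTS
    )
    sample_allocation: tuple[int, ...] = reference.SAMPLE_ALLOCATION
    true_beta: dict[str, tuple[float, float]] = field(default_factory=_default_true_beta)
    error_corr: np.ndarray = field(default_factory=_default_error_corr)
    error_sd: tuple[float, ...] = (0.0658, 0.0711, 0.0243)
    agb_coef: tuple[float, float] = (0.10, 2.40)
    ht_coef: tuple[float, float] | None = None
    ht_cv: tuple[float, ...] = reference.CLASS_HT_CV
    moisture_ratio: dict[str, float] = field(
        default_factory=lambda: {"stem": 0.5, "branch": 0.5, "twig": 0.5, "foliage": 0.35}
    )
    subsample_fraction: float = 0.1
    max_redraws: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ht_coef is None:
            self.ht_coef = reference.fit_height_curve()
        self.error_corr = np.asarray(self.error_corr, dtype=float)
        self.validate()

    @property
    def n_classes(self) -> int:
        return len(self.class_probs)

    @property
    def class_labels(self) -> tuple[str, ...]:
        if self.n_classes == len(reference.CLASS_LABELS):
            return reference.CLASS_LABELS
        return tuple(
            f"{self.class_edges[i]:g}-{self.class_edges[i + 1]:g}"
            for i in range(self.n_classes)
        )

    def validate(self) -> None:
        if self.n_census < 0:
            raise ValueError("n_census must be non-negative")
        if len(self.class_edges) != self.n_classes + 1:
            raise ValueError("class_edges must have one more entry than class_probs")
        if np.any(np.diff(self.class_edges) <= 0):
            raise ValueError("class_edges must be strictly increasing")
        probs = np.asarray(self.class_probs, dtype=float)
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0, atol=1e-9):
            raise ValueError("class_probs must be non-negative and sum to one")
        if len(self.sample_allocation) != self.n_classes:
            raise ValueError("sample_allocation must have one entry per class")
        expected = self.n_census * probs
        for k, alloc in enumerate(self.sample_allocation):
            if alloc < 0:
                raise ValueError("sample_allocation entries must be non-negative")
            if alloc > expected[k]:
                raise ValueError(
                    f"allocation of {alloc} exceeds expected count "
                    f"{expected[k]:.1f} in class {self.class_labels[k]!r}"
                )
        corr = self.error_corr
        if corr.shape != (3, 3) or not np.allclose(corr, corr.T, atol=1e-12):
            raise ValueError("error_corr must be a symmetric 3x3 matrix")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise ValueError("error_corr must have a unit diagonal")
        if np.linalg.eigvalsh(corr)[0] <= 0:
            raise ValueError("error_corr must be positive definite")
        if any(sd < 0 for sd in self.error_sd) or len(self.error_sd) != 3:
            raise ValueError("error_sd must be three non-negative values")
        for c, m in self.moisture_ratio.items():
            if not 0 < m <= 1:
                raise ValueError(f"moisture ratio for {c!r} must lie in (0, 1]")
        if len(self.ht_cv) not in (1, self.n_classes):
            raise ValueError("ht_cv must be scalar-like or one value per class")
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must lie in (0, 1]")

    def error_cov(self) -> np.ndarray:
        d = np.diag(self.error_sd)
        return d @ self.error_corr @ d

    def rng(self, seed: int | None = None) -> np.random.Generator:
        return np.random.default_rng(self.seed if seed is None else seed)


def _class_cv(config: SyntheticConfig, k: int) -> float:
    return config.ht_cv[0] if len(config.ht_cv) == 1 else config.ht_cv[k]


def generate_census(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> list[TreeRecord]:
    """Generate the tree census.

    Each tree's diameter class is drawn from ``class_probs``, its dbh
    uniformly within the class interval, and its height from the power
    mean curve with multiplicative lognormal noise at the class CV.
    """
    config.validate()
    rng = config.rng() if rng is None else rng
    n = config.n_census
    if n == 0:
        return []
    classes = rng.choice(config.n_classes, size=n, p=np.asarray(config.class_probs))
    edges = np.asarray(config.class_edges)
    dbh = rng.uniform(edges[classes], edges[classes + 1])
    c, d = config.ht_coef
    mean_ht = c * dbh**d
    cv = np.array([_class_cv(config, k) for k in classes])
    sigma = np.sqrt(np.log1p(cv**2))
    ht = mean_ht * np.exp(rng.normal(-0.5 * sigma**2, sigma))
    labels = config.class_labels
    return [
        TreeRecord(f"T{i + 1:04d}", float(dbh[i]), float(ht[i]), labels[classes[i]])
        for i in range(n)
    ]


def sample_biomass_trees(
    census: Sequence[TreeRecord],
    allocation: Sequence[int],
    rng: np.random.Generator | None = None,
    *,
    seed: int | None = None,
) -> list[TreeRecord]:
    """Stratified simple random sample without replacement within classes.

    ``allocation`` aligns with the census's diameter classes ordered by
    increasing dbh.  Raises when a class holds fewer trees than allocated,
    naming the class.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    groups: dict[str, list[TreeRecord]] = {}
    for t in census:
        groups.setdefault(t.diam_class or "", []).append(t)
    ordered = sorted(groups, key=lambda lbl: min(t.dbh for t in groups[lbl]))
    if len(allocation) < len(ordered) and any(
        a > 0 for a in allocation[len(ordered):]
    ):
        raise ValueError("allocation has positive entries beyond the last class")
    chosen: list[TreeRecord] = []
    for k, count in enumerate(allocation):
        if count == 0:
            continue
        if k >= len(ordered):
            raise ValueError(
                f"allocation requests {count} trees from class index {k}, "
                "but the census has no such class"
            )
        pool = groups[ordered[k]]
        if len(pool) < count:
            raise ValueError(
                f"class {ordered[k]!r} holds {len(pool)} trees, "
                f"fewer than the {count} allocated"
            )
        idx = rng.choice(len(pool), size=count, replace=False)
        chosen.extend(pool[i] for i in sorted(idx))
    return chosen


def generate_component_biomass(
    trees: Sequence[TreeRecord],
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> list[tuple[BiomassRecord, FieldSample]]:
    """Draw component biomasses and field weights for each tree.

    Ratios follow ``R_c = beta0_c + beta1_c * dbh + eps_c`` with the error
    triple drawn from a zero-mean trivariate normal (covariance from
    ``error_sd`` and ``error_corr``), redrawn until every modeled ratio
    exceeds 0.01 and their sum stays below 0.98; foliage is the
    complement.  AGB follows the power allometry, component masses are
    ``R_c * AGB``, and fresh/subsample weights are consistent with the
    configured moisture ratios.
    """
    config.validate()
    rng = config.rng() if rng is None else rng
    cov = config.error_cov()
    a, b = config.agb_coef
    out: list[tuple[BiomassRecord, FieldSample]] = []
    for t in trees:
        mean = np.array(
            [config.true_beta[c][0] + config.true_beta[c][1] * t.dbh
             for c in SYSTEM_COMPONENTS]
        )
        for _ in range(config.max_redraws):
            r = mean + rng.multivariate_normal(np.zeros(3), cov)
            if np.all(r > 0.01) and r.sum() < 0.98:
                break
        else:
            raise RuntimeError(
                f"no admissible ratio draw for tree {t.tree_id!r} (dbh "
                f"{t.dbh:.2f} cm) within {config.max_redraws} redraws; "
                "the configured means/SDs are inconsistent with the ratio bounds"
            )
        ratios = dict(zip(SYSTEM_COMPONENTS, r))
        ratios["foliage"] = 1.0 - r.sum()
        agb = a * t.dbh**b
        dry = {c: ratios[c] * agb for c in COMPONENTS}
        fresh = {c: dry[c] / config.moisture_ratio[c] for c in COMPONENTS}
        sample_fresh = {c: config.subsample_fraction * fresh[c] for c in COMPONENTS}
        sample_dry = {
            c: config.moisture_ratio[c] * sample_fresh[c] for c in COMPONENTS
        }
        out.append(
            (
                BiomassRecord(dry["stem"], dry["branch"], dry["twig"], dry["foliage"]),
                FieldSample(fresh, sample_fresh, sample_dry),
            )
        )
    return out


def census_frame(trees: Sequence[TreeRecord]) -> pd.DataFrame:
    """Census/sample table with columns tree_id, dbh_cm, ht_m, diam_class."""
    return pd.DataFrame(
        {
            "tree_id": [t.tree_id for t in trees],
            "dbh_cm": [t.dbh for t in trees],
            "ht_m": [np.nan if t.ht is None else t.ht for t in trees],
            "diam_class": [t.diam_class for t in trees],
        }
    )


def biomass_frame(
    trees: Sequence[TreeRecord],
    records: Sequence[tuple[BiomassRecord, FieldSample]],
) -> pd.DataFrame:
    """Biomass table: tree columns plus dry, fresh and subsample weights."""
    df = census_frame(trees)
    for c in COMPONENTS:
        df[f"b_{c}_kg"] = [rec.component(c) for rec, _ in records]
    for c in COMPONENTS:
        df[f"fw_{c}_kg"] = [fs.fresh_field[c] for _, fs in records]
    for c in COMPONENTS:
        df[f"sf_{c}_kg"] = [fs.sample_fresh[c] for _, fs in records]
        df[f"sd_{c}_kg"] = [fs.sample_dry[c] for _, fs in records]
    return df


def simulate_dataset(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the full generator: census, destructive sample, biomass table.

    A single rng seeded from ``seed`` (or ``config.seed``) drives all three
    stages, so a fixed seed yields bit-identical output.
    """
    rng = config.rng(seed)
    census = generate_census(config, rng)
    sample = sample_biomass_trees(census, config.sample_allocation, rng)
    records = generate_component_biomass(sample, config, rng)
    return census_frame(census), census_frame(sample), biomass_frame(sample, records)
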