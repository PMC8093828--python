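"""Class-separability diagnostics.

Why do some classification tasks keep working at 50 reads per sample while
others need 5000?  These diagnostics probe the properties of a labelled ASV
table that predict the answer:

* **class_gini** — Gini coefficient of the class-frequency distribution
  (training-data imbalance; 0 = perfectly balanced);
* **feature_cv** — per-ASV coefficient of variation of the class-mean
  relative abundances (high-CV features are class-discriminating);
* **shared_feature_fractions** — fraction of features present in every
  class versus exclusive to one (Venn-style class specificity), computed
  both per-ASV and read-weighted;
* **ordination_overlap** — Bray-Curtis NMDS ordination with per-class
  normal-theory confidence ellipses; the pairwise ellipse-overlap fraction
  measures how hard the class boundaries are.

Hard, well-separated class boundaries (high CV, low shared fraction, low
ellipse overlap) are the conditions under which very few reads per sample
already achieve the full-depth classification performance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2, gaussian_kde
from sklearn.manifold import MDS

from .tables import AsvTable, ParameterError, RelativeAbundanceTable

__all__ = [
    "class_gini",
    "feature_cv",
    "FeatureCvResult",
    "shared_feature_fractions",
    "SharedFeatureResult",
    "ordination_overlap",
    "OrdinationResult",
    "SeparabilityReport",
    "separability_report",
]

# covariance inflation for collinear classes, relative to coordinate scale
_ELLIPSE_EPS = 1e-6


def class_gini(class_counts) -> float:
    """Gini coefficient of a class-frequency distribution.

    ``G = sum_ij |x_i - x_j| / (2 n sum(x))`` over all ordered pairs; 0 for
    perfect balance, < 1 always.  Invariant under class reordering and under
    scaling all counts by a constant.
    """
    x = np.asarray(list(class_counts), dtype=float)
    if x.size < 2:
        raise ParameterError("need >= 2 classes")
    if np.any(x <= 0):
        raise ParameterError("all class counts must be positive")
    n = x.size
    diff_sum = np.abs(x[:, None] - x[None, :]).sum()
    return float(diff_sum / (2.0 * n * x.sum()))


@dataclass
class FeatureCvResult:
    """Per-feature CV of class means, plus the count of undefined features."""

    cv: pd.Series  # indexed by ASV id; grand-mean-zero features excluded
    n_excluded: int

    @property
    def median(self) -> float:
        return float(self.cv.median())

    def density(self, grid_size: int = 200) -> pd.DataFrame:
        """Gaussian kernel density of the CV distribution on a regular grid."""
        vals = self.cv.to_numpy()
        if vals.size < 2 or np.allclose(vals, vals[0]):
            # degenerate distribution: return a point mass marker
            return pd.DataFrame({"cv": [float(vals[0]) if vals.size else 0.0],
                                 "density": [np.inf]})
        kde = gaussian_kde(vals)
        grid = np.linspace(0.0, float(vals.max()) * 1.05, grid_size)
        return pd.DataFrame({"cv": grid, "density": kde(grid)})


def feature_cv(rel_table: RelativeAbundanceTable, labels=None) -> FeatureCvResult:
    """CV of each feature's class means: sd(class means) / grand mean.

    The class means are the mean relative abundances of the feature within
    each class; the standard deviation uses the n-1 denominator.  Features
    whose grand mean is zero (absent everywhere) have no defined CV and are
    excluded, with their count reported.
    """
    labels = rel_table.labels if labels is None else pd.Series(labels, index=rel_table.values.index)
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ParameterError("need >= 2 classes for a between-class CV")
    class_means = pd.DataFrame(
        {c: rel_table.values.loc[labels == c].mean(axis=0) for c in classes}
    )
    grand = class_means.mean(axis=1)
    defined = grand > 0
    sd = class_means.loc[defined].std(axis=1, ddof=1)
    cv = sd / grand[defined]
    return FeatureCvResult(cv=cv, n_excluded=int((~defined).sum()))


@dataclass
class SharedFeatureResult:
    shared_fraction: float  # present in every class
    exclusive_fractions: dict  # class -> fraction present only there
    weighting: str  # "asv" or "reads"

    @property
    def partial_fraction(self) -> float:
        """Features present in >1 but not all classes."""
        return 1.0 - self.shared_fraction - sum(self.exclusive_fractions.values())


def shared_feature_fractions(
    table: AsvTable,
    presence_min_count: int = 1,
    weighting: str = "asv",
) -> SharedFeatureResult:
    """Venn-style class-specificity fractions of the feature set.

    An ASV is *present* in a class when its pooled count over that class's
    samples is >= ``presence_min_count``.  ``weighting="asv"`` counts ASVs;
    ``weighting="reads"`` weights each ASV by its total read count, which
    answers "what fraction of sequences is common to all classes".  ASVs
    absent from every class (possible after rarefying) are ignored.
    """
    if weighting not in ("asv", "reads"):
        raise ParameterError(f"weighting must be 'asv' or 'reads', got {weighting!r}")
    classes = sorted(table.labels.unique())
    if len(classes) < 2:
        raise ParameterError("need >= 2 classes")
    pooled = pd.DataFrame(
        {c: table.counts.loc[table.labels == c].sum(axis=0) for c in classes}
    )
    present = pooled >= presence_min_count
    n_present = present.sum(axis=1)
    observed = n_present > 0
    if weighting == "asv":
        weights = observed.astype(float)
    else:
        weights = table.counts.sum(axis=0).astype(float) * observed
    total = float(weights.sum())
    if total == 0:
        raise ParameterError("no feature is present in any class")
    shared = float(weights[n_present == len(classes)].sum()) / total
    exclusive = {}
    for c in classes:
        only_c = present[c] & (n_present == 1)
        exclusive[c] = float(weights[only_c].sum()) / total
    return SharedFeatureResult(shared, exclusive, weighting)


@dataclass
class ClassEllipse:
    """Normal-theory confidence ellipse of one class's 2-D ordination cloud."""

    mean: np.ndarray
    cov: np.ndarray
    confidence: float
    inflated: bool = False  # true when a degenerate covariance was regularized

    @property
    def radius2(self) -> float:
        """Squared Mahalanobis radius of the ellipse boundary."""
        return float(chi2.ppf(self.confidence, df=2))

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = points - self.mean
        inv = np.linalg.inv(self.cov)
        md2 = np.einsum("ij,jk,ik->i", d, inv, d)
        return md2 <= self.radius2

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform points inside the ellipse (unit-disk transform)."""
        theta = rng.uniform(0, 2 * np.pi, n)
        r = np.sqrt(rng.uniform(0, 1, n))
        disk = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        chol = np.linalg.cholesky(self.cov)
        return self.mean + np.sqrt(self.radius2) * disk @ chol.T

    def boundary(self, n: int = 200) -> np.ndarray:
        theta = np.linspace(0, 2 * np.pi, n)
        circle = np.column_stack([np.cos(theta), np.sin(theta)])
        chol = np.linalg.cholesky(self.cov)
        return self.mean + np.sqrt(self.radius2) * circle @ chol.T


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x (axis1, axis2), labels attached
    stress: float
    ellipses: dict  # class -> ClassEllipse
    overlap: pd.DataFrame  # symmetric class x class overlap fractions

    @property
    def mean_pairwise_overlap(self) -> float:
        classes = list(self.overlap.index)
        vals = [
            self.overlap.loc[a, b]
            for i, a in enumerate(classes)
            for b in classes[i + 1 :]
        ]
        return float(np.mean(vals))


def _confidence_ellipse(points: np.ndarray, confidence: float) -> ClassEllipse:
    mean = points.mean(axis=0)
    cov = np.cov(points, rowvar=False, ddof=1)
    inflated = False
    scale = max(float(np.abs(points).max()), 1.0)
    # regularize collinear / coincident classes so the ellipse stays a region
    eps = _ELLIPSE_EPS * scale**2
    if np.linalg.matrix_rank(cov) < 2 or np.linalg.det(cov) <= eps**2:
        cov = cov + np.eye(2) * eps
        inflated = True
        warnings.warn(
            "degenerate class covariance in ordination; ellipse inflated",
            stacklevel=3,
        )
    return ClassEllipse(mean, cov, confidence, inflated)


def _ellipse_overlap(
    a: ClassEllipse, b: ClassEllipse, rng: np.random.Generator, n_points: int
) -> float:
    """Symmetrized Monte-Carlo overlap: mean of area-fraction A-in-B and B-in-A."""
    frac_ab = float(b.contains(a.sample(n_points, rng)).mean())
    frac_ba = float(a.contains(b.sample(n_points, rng)).mean())
    return 0.5 * (frac_ab + frac_ba)


def ordination_overlap(
    rel_table: RelativeAbundanceTable,
    n_dims: int = 2,
    confidence: float = 0.95,
    seed: int = 0,
    n_restarts: int = 8,
    n_mc_points: int = 20_000,
) -> OrdinationResult:
    """Bray-Curtis NMDS ordination with per-class confidence-ellipse overlap.

    Non-metric MDS is run with ``n_restarts`` random initializations and the
    lowest-stress embedding kept.  Each class gets a normal-theory ellipse
    (chi-square radius on its 2-D sample mean and covariance at
    ``confidence``); pairwise overlap is the seeded Monte-Carlo estimate of
    the mutual area fraction, symmetrized by averaging both directions.
    """
    labels = rel_table.labels
    classes = sorted(labels.unique())
    sizes = labels.value_counts()
    small = [c for c in classes if sizes[c] < 3]
    if small:
        raise ParameterError(f"need >= 3 samples per class, too few in: {small}")
    dist = squareform(pdist(rel_table.values.to_numpy(), metric="braycurtis"))
    best = None
    for i in range(n_restarts):
        mds = MDS(
            n_components=n_dims,
            metric="precomputed",
            metric_mds=False,
            init="random",
            random_state=int(seed) + i,
            n_init=1,
            normalized_stress=True,
            max_iter=300,
        )
        coords = mds.fit_transform(dist)
        if best is None or mds.stress_ < best[1]:
            best = (coords, float(mds.stress_))
    coords, stress = best
    frame = pd.DataFrame(
        coords[:, :2], index=rel_table.values.index, columns=["axis1", "axis2"]
    )
    frame["label"] = labels
    ellipses = {
        c: _confidence_ellipse(coords[(labels == c).to_numpy(), :2], confidence)
        for c in classes
    }
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2_000_003]))
    overlap = pd.DataFrame(np.eye(len(classes)), index=classes, columns=classes)
    for i, a in enumerate(classes):
        for b in classes[i + 1 :]:
            o = _ellipse_overlap(ellipses[a], ellipses[b], rng, n_mc_points)
            overlap.loc[a, b] = overlap.loc[b, a] = o
    return OrdinationResult(frame, stress, ellipses, overlap)


@dataclass
class SeparabilityReport:
    """Bundle of all separability diagnostics for one labelled table."""

    gini: float
    feature_cv: FeatureCvResult
    shared_asv: SharedFeatureResult
    shared_reads: SharedFeatureResult
    ordination: OrdinationResult

    def to_dict(self) -> dict:
        return {
            "class_gini": self.gini,
            "median_feature_cv": self.feature_cv.median,
            "n_features_cv_undefined": self.feature_cv.n_excluded,
            "shared_fraction_asv": self.shared_asv.shared_fraction,
            "exclusive_fractions_asv": self.shared_asv.exclusive_fractions,
            "shared_fraction_reads": self.shared_reads.shared_fraction,
            "exclusive_fractions_reads": self.shared_reads.exclusive_fractions,
            "nmds_stress": self.ordination.stress,
            "mean_ellipse_overlap": self.ordination.mean_pairwise_overlap,
            "ellipse_overlap": {
                a: {b: float(self.ordination.overlap.loc[a, b])
                    for b in self.ordination.overlap.columns}
                for a in self.ordination.overlap.index
            },
        }


def separability_report(
    table: AsvTable, seed: int = 0, confidence: float = 0.95
) -> SeparabilityReport:
    """Compute every diagnostic for a labelled count table."""
    from .preprocess import to_relative_abundance

    rel = to_relative_abundance(table)
    sizes = table.class_sizes()
    return SeparabilityReport(
        gini=class_gini(sizes.to_numpy()),
        feature_cv=feature_cv(rel),
        shared_asv=shared_feature_fractions(table, weighting="asv"),
        shared_reads=shared_feature_fractions(table, weighting="reads"),
        ordination=ordination_overlap(rel, seed=seed, confidence=confidence),
    )
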