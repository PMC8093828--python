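"""Random-forest depth sweep: the core benchmarking procedure.

For each dataset a "full model" grid is trained on the complete
relative-abundance matrix, then the same grid is retrained on each rarefied
table of the depth ladder.  The grid holds 21 configurations under defaults:
seven ``mtry`` values (the floor-square-root default plus offsets -3..+3,
clipped to the feature range) times three repeat seeds.  Every model is
scored by its out-of-bag (OOB) error — an unbiased stand-in for N-fold
cross-validation — and by Cohen's kappa computed on the OOB predictions.

Kappa values are banded:

* ``almost_perfect``  kappa > 0.8
* ``moderate``        0.6 <= kappa <= 0.8
* ``poor``            kappa < 0.6

The full model's summary band is the benchmark ("targeted RF prediction
performance"); walking the ladder from deepest to shallowest, the minimum
depth is the smallest level such that every level at or above it still meets
the benchmark band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .preprocess import to_relative_abundance
from .tables import AsvTable, ParameterError, RelativeAbundanceTable

__all__ = [
    "RfConfig",
    "ModelRecord",
    "ModelGridResult",
    "DepthDecision",
    "KAPPA_BANDS",
    "BAND_ORDER",
    "default_mtry",
    "build_model_grid",
    "cohen_kappa",
    "kappa_band",
    "train_rf_oob",
    "evaluate_level",
    "min_depth_for_target",
]

#: Band names from worst to best agreement.
BAND_ORDER: tuple[str, ...] = ("poor", "moderate", "almost_perfect")
KAPPA_BANDS = {"poor": "kappa < 0.6", "moderate": "0.6 <= kappa <= 0.8",
               "almost_perfect": "kappa > 0.8"}


@dataclass(frozen=True)
class RfConfig:
    """One random-forest configuration of the grid."""

    n_trees: int = 6000
    mtry: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ParameterError("n_trees must be >= 1")
        if self.mtry < 1:
            raise ParameterError("mtry must be >= 1")


@dataclass(frozen=True)
class ModelRecord:
    """Scores of one trained grid configuration."""

    mtry: int
    seed: int
    oob_error: float
    kappa: float

    @property
    def accuracy(self) -> float:
        return 1.0 - self.oob_error


@dataclass
class ModelGridResult:
    """All grid records at one depth level, plus their summary statistics."""

    depth_level: int | str  # a ladder depth, or "full"
    records: list[ModelRecord]

    @property
    def median_kappa(self) -> float:
        return float(np.median([r.kappa for r in self.records]))

    @property
    def mean_oob_error(self) -> float:
        return float(np.mean([r.oob_error for r in self.records]))

    @property
    def mean_accuracy(self) -> float:
        return 1.0 - self.mean_oob_error

    @property
    def band(self) -> str:
        """Band of the level's median kappa (the default gating summary)."""
        return kappa_band(self.median_kappa)

    @property
    def best(self) -> ModelRecord:
        """Best single model: max kappa, ties to lower OOB error then lower mtry."""
        return min(self.records, key=lambda r: (-r.kappa, r.oob_error, r.mtry))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "depth": self.depth_level,
                "mtry": r.mtry,
                "seed": r.seed,
                "oob_error": r.oob_error,
                "accuracy": r.accuracy,
                "kappa": r.kappa,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)


def default_mtry(n_features: int) -> int:
    """Default number of candidate features per split: floor(sqrt(p)), >= 1."""
    if n_features < 1:
        raise ParameterError("n_features must be >= 1")
    return max(1, int(np.floor(np.sqrt(n_features))))


def build_model_grid(
    n_features: int,
    offsets=range(-3, 4),
    n_runs: int = 3,
    base_seed: int = 0,
    n_trees: int = 6000,
) -> list[RfConfig]:
    """Build the per-level model grid: mtry offsets x repeat seeds.

    Under defaults, seven mtry values (default mtry -3..+3) times three seeds
    give 21 configurations.  Offsets falling outside [1, n_features] are
    clipped; duplicates after clipping are dropped with a warning.
    """
    m0 = default_mtry(n_features)
    mtry_values = []
    clipped = False
    for off in offsets:
        m = min(max(m0 + int(off), 1), n_features)
        if m != m0 + int(off):
            clipped = True
        if m not in mtry_values:
            mtry_values.append(m)
        else:
            clipped = True
    if clipped:
        warnings.warn(
            f"mtry grid clipped/deduplicated to {mtry_values} "
            f"(default {m0}, {n_features} features)",
            stacklevel=2,
        )
    # distinct seeds per repeat run, shared across mtry values
    seeds = [int(base_seed) + run for run in range(n_runs)]
    return [
        RfConfig(n_trees=n_trees, mtry=m, seed=s)
        for m in sorted(mtry_values)
        for s in seeds
    ]


def cohen_kappa(y_true, y_pred) -> float:
    """Cohen's chance-corrected agreement between two label vectors.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with ``p_o`` the observed agreement
    fraction and ``p_e`` the chance agreement from the marginal label
    frequencies.  Returns exactly 1.0 on perfect agreement (including the
    degenerate both-constant-and-equal case, where chance agreement is 1).
    Invariant under any bijective relabeling applied to both vectors.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ParameterError("empty label vectors")
    if y_true.shape != y_pred.shape:
        raise ParameterError("label vectors differ in length")
    n = y_true.size
    if np.array_equal(y_true, y_pred):
        return 1.0
    labels = np.unique(np.concatenate([y_true, y_pred]))
    p_o = float(np.mean(y_true == y_pred))
    p_e = 0.0
    for lab in labels:
        p_e += float(np.mean(y_true == lab)) * float(np.mean(y_pred == lab))
    return (p_o - p_e) / (1.0 - p_e)


def kappa_band(kappa: float) -> str:
    """Map a kappa value to its agreement band.

    Boundaries are inclusive-moderate: exactly 0.8 is ``moderate`` (the
    almost-perfect rule is strictly > 0.8) and exactly 0.6 is ``moderate``
    (the poor rule is strictly < 0.6).
    """
    if not np.isfinite(kappa):
        raise ParameterError(f"kappa must be finite, got {kappa}")
    if kappa > 0.8:
        return "almost_perfect"
    if kappa >= 0.6:
        return "moderate"
    return "poor"


@dataclass
class OobResult:
    predictions: pd.Series  # OOB-predicted class per scored sample
    oob_error: float
    kappa: float
    n_excluded: int  # samples with zero OOB trees

    @property
    def accuracy(self) -> float:
        return 1.0 - self.oob_error


def train_rf_oob(
    features: RelativeAbundanceTable, config: RfConfig
) -> OobResult:
    """Fit one random forest and score it on its out-of-bag predictions.

    Each sample's OOB prediction aggregates only the trees whose bootstrap
    did not contain it.  ``oob_error`` is the misclassification fraction
    among samples with at least one OOB tree; kappa is computed on the same
    samples.  Samples with zero OOB trees (possible at very small
    ``n_trees``) are excluded with a warning.
    """
    y = features.labels.to_numpy()
    if len(np.unique(y)) < 2:
        raise ParameterError("need >= 2 classes to train a classifier")
    X = features.values.to_numpy()
    if not np.all(np.isfinite(X)):
        raise ParameterError("features must be finite")
    mtry = min(config.mtry, X.shape[1])
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=mtry,
        oob_score=True,
        bootstrap=True,
        random_state=int(config.seed),
        n_jobs=1,
    )
    with warnings.catch_warnings():
        # sklearn warns about samples without OOB trees; we handle them below
        warnings.filterwarnings(
            "ignore", message="Some inputs do not have OOB scores"
        )
        warnings.filterwarnings("ignore", message="invalid value encountered")
        forest.fit(X, y)
    proba = forest.oob_decision_function_
    scored = ~np.isnan(proba).any(axis=1) & (proba.sum(axis=1) > 0)
    n_excluded = int((~scored).sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} sample(s) had no out-of-bag tree and were "
            "excluded from OOB scoring; increase n_trees",
            stacklevel=2,
        )
    if not scored.any():
        raise ParameterError("no sample has an out-of-bag prediction")
    pred = forest.classes_[np.argmax(proba[scored], axis=1)]
    truth = y[scored]
    oob_error = float(np.mean(pred != truth))
    kappa = cohen_kappa(truth, pred)
    predictions = pd.Series(
        pred, index=np.asarray(features.sample_ids)[scored], name="oob_prediction"
    )
    return OobResult(predictions, oob_error, kappa, n_excluded)


def evaluate_level(
    table: AsvTable, grid: list[RfConfig], depth_level: int | str = "full"
) -> ModelGridResult:
    """Train every grid configuration on one (possibly rarefied) table.

    The table is transformed to relative abundances once; each configuration
    is fit independently, so results do not depend on evaluation order.
    """
    rel = to_relative_abundance(table)
    records = []
    for cfg in grid:
        res = train_rf_oob(rel, cfg)
        records.append(
            ModelRecord(
                mtry=cfg.mtry, seed=cfg.seed,
                oob_error=res.oob_error, kappa=res.kappa,
            )
        )
    return ModelGridResult(depth_level=depth_level, records=records)


@dataclass
class DepthDecision:
    """Outcome of the sweep: benchmark band and minimum sufficient depth."""

    benchmark_band: str
    benchmark_kappa: float
    benchmark_accuracy: float
    min_depth: int | None  # None = "not reached"
    levels: pd.DataFrame = field(repr=False)  # one row per ladder level

    @property
    def reached(self) -> bool:
        return self.min_depth is not None

    def to_dict(self) -> dict:
        return {
            "benchmark_band": self.benchmark_band,
            "benchmark_kappa": self.benchmark_kappa,
            "benchmark_accuracy": self.benchmark_accuracy,
            "min_depth": self.min_depth if self.reached else "not reached",
            "levels": self.levels.to_dict(orient="records"),
        }


def _band_rank(band: str) -> int:
    return BAND_ORDER.index(band)


def min_depth_for_target(
    full_result: ModelGridResult,
    ladder_results: list[ModelGridResult],
    gate: str = "median",
) -> DepthDecision:
    """Extract the minimum depth still meeting the full model's band.

    ``gate`` selects the level summary that is banded: ``"median"`` bands the
    median kappa of the grid (robust to the grid's worst configurations),
    ``"best"`` bands the single best model.  The benchmark is the same
    summary of the full model.  Walking the ladder from deepest to
    shallowest, the minimum depth is the last level of the initial contiguous
    run of levels whose band is >= the benchmark band; ``min_depth=None``
    ("not reached") if even the deepest level fails.
    """
    if not ladder_results:
        raise ParameterError("no ladder results")
    depths = [r.depth_level for r in ladder_results]
    if any(a <= b for a, b in zip(depths, depths[1:])):
        raise ParameterError("ladder results must be ordered by decreasing depth")
    if gate == "median":
        level_kappa = lambda r: r.median_kappa
    elif gate == "best":
        level_kappa = lambda r: r.best.kappa
    else:
        raise ParameterError(f"unknown gate {gate!r}; use 'median' or 'best'")
    benchmark_kappa = level_kappa(full_result)
    benchmark_band = kappa_band(benchmark_kappa)
    target_rank = _band_rank(benchmark_band)

    rows = []
    min_depth: int | None = None
    contiguous = True
    for res in ladder_results:
        k = level_kappa(res)
        band = kappa_band(k)
        passes = _band_rank(band) >= target_rank
        if contiguous and passes:
            min_depth = int(res.depth_level)
        else:
            contiguous = False
        rows.append(
            {
                "depth": res.depth_level,
                "median_kappa": res.median_kappa,
                "mean_oob_error": res.mean_oob_error,
                "mean_accuracy": res.mean_accuracy,
                "best_kappa": res.best.kappa,
                "band": band,
                "meets_benchmark": passes,
            }
        )
    levels = pd.DataFrame(rows)
    return DepthDecision(
        benchmark_band=benchmark_band,
        benchmark_kappa=benchmark_kappa,
        benchmark_accuracy=full_result.mean_accuracy,
        min_depth=min_depth,
        levels=levels,
    )
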