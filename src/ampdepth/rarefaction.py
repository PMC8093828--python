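"""Exact without-replacement downsampling, rarefaction curves and Chao1 coverage.

Rarefying a sample to depth ``d`` draws a uniform random subset of ``d`` of
its reads without replacement, i.e. a multivariate-hypergeometric draw over
its ASV counts.  The depth ladder used for the model sweep starts at the
shallowest retained sample's depth (capped, default 15,000) and descends
through a fixed tail of twelve levels down to 50 reads.

Saturation is quantified against the bias-corrected Chao1 richness estimate
(treated as 100% ASV coverage): ``coverage = 100 * S_obs / Chao1``.  The
expected rarefaction curve is computed by the exact hypergeometric formula

    E[S_d] = sum_a [ 1 - C(N - n_a, d) / C(N, d) ]

evaluated through log-gamma for overflow safety; a Monte-Carlo cross-check
is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .tables import AsvTable, ParameterError

__all__ = [
    "DEFAULT_LADDER_TAIL",
    "DepthLadder",
    "build_ladder",
    "rarefy_sample",
    "rarefy_table",
    "chao1",
    "coverage_fraction",
    "rarefaction_curve",
    "rarefaction_curve_mc",
    "dataset_coverage",
]

#: Fixed tail of the depth ladder (levels below the dataset-specific first level).
DEFAULT_LADDER_TAIL: tuple[int, ...] = (
    12_500, 10_000, 7_500, 5_000, 2_500, 1_000, 500, 400, 300, 200, 100, 50
)


@dataclass(frozen=True)
class DepthLadder:
    """Strictly decreasing per-sample target depths for the downsampling sweep."""

    levels: tuple[int, ...]
    includes_full_model: bool = True

    def __post_init__(self) -> None:
        if not self.levels:
            raise ParameterError("ladder has no levels")
        if any(d <= 0 for d in self.levels):
            raise ParameterError("ladder depths must be positive")
        if any(a <= b for a, b in zip(self.levels, self.levels[1:])):
            raise ParameterError(f"ladder not strictly decreasing: {self.levels}")

    def __iter__(self):
        return iter(self.levels)

    def __len__(self) -> int:
        return len(self.levels)


def build_ladder(
    table: AsvTable, cap: int = 15_000, cap_ratio: float = 1.5
) -> DepthLadder:
    """Build the standard 13-level ladder for a depth-filtered table.

    The first level is the shallowest sample's total depth; the remaining
    levels are the fixed tail.  When the shallowest sample lies *well above*
    ``cap`` (by more than ``cap_ratio``-fold) the first level is pulled down
    to ``cap`` so that deeply sequenced datasets stay comparable with ones
    whose minimum sits just above the cap — a minimum only slightly above
    the cap is kept as-is.  Duplicate levels (first level colliding with a
    tail level) are collapsed.
    """
    min_depth = int(table.sample_depths.min())
    if min_depth < DEFAULT_LADDER_TAIL[-1]:
        raise ParameterError(
            f"shallowest sample has {min_depth} reads; ladder tail unreachable"
        )
    first = int(cap) if min_depth > cap * cap_ratio else min_depth
    levels = (first,) + tuple(d for d in DEFAULT_LADDER_TAIL if d < first)
    return DepthLadder(levels)


def rarefy_sample(
    counts: np.ndarray, depth: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Downsample one sample's counts to ``depth`` reads without replacement.

    Returns an integer vector summing exactly to ``depth`` with every entry
    bounded by the original count (multivariate-hypergeometric draw).
    """
    counts = np.asarray(counts)
    if counts.ndim != 1 or (counts.size and counts.min() < 0):
        raise ParameterError("counts must be a non-negative 1-D integer vector")
    total = int(counts.sum())
    if depth < 0:
        raise ParameterError("depth must be non-negative")
    if depth > total:
        raise ParameterError(
            f"cannot draw {depth} reads without replacement from {total}"
        )
    if depth == total:
        return counts.astype(np.int64, copy=True)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    return rng.multivariate_hypergeometric(counts.astype(np.int64), depth)


def rarefy_table(table: AsvTable, depth: int, seed: int) -> AsvTable:
    """Rarefy every sample of ``table`` to ``depth`` reads.

    Each sample uses an independent stream derived from ``(seed, sample
    index)``; labels and the ASV axis are preserved (all-zero ASV columns are
    allowed).
    """
    out = np.empty_like(table.counts.to_numpy())
    for i, (_, row) in enumerate(table.counts.iterrows()):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), i]))
        out[i] = rarefy_sample(row.to_numpy(), depth, rng)
    frame = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return AsvTable(frame, table.labels)


def chao1(abundances: np.ndarray) -> float:
    """Bias-corrected Chao1 richness estimate from an abundance vector.

    ``S_obs + f1*(f1-1) / (2*(f2+1))`` where ``f1``/``f2`` count singleton
    and doubleton ASVs.  The ``f2+1`` denominator keeps the estimator defined
    when no doubletons are observed.  Always >= the observed richness.
    """
    abundances = np.asarray(abundances)
    if abundances.size == 0:
        raise ParameterError("empty abundance vector")
    if abundances.min() < 0:
        raise ParameterError("abundances must be non-negative")
    s_obs = int((abundances > 0).sum())
    f1 = int((abundances == 1).sum())
    f2 = int((abundances == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def coverage_fraction(observed_richness: int, chao1_estimate: float) -> float:
    """Percent of the Chao1-estimated richness that was actually observed."""
    if observed_richness <= 0:
        raise ParameterError("observed richness must be positive")
    if chao1_estimate < observed_richness:
        raise ParameterError(
            f"Chao1 estimate {chao1_estimate} below observed {observed_richness}"
        )
    return 100.0 * observed_richness / chao1_estimate


def rarefaction_curve(counts: np.ndarray, probe_depths) -> np.ndarray:
    """Expected observed richness at each probe depth (exact formula).

    For a sample with total ``N`` and per-ASV counts ``n_a``, the expected
    richness of a uniform without-replacement subsample of size ``d`` is
    ``sum_a [1 - C(N-n_a, d) / C(N, d)]``; the binomial ratio is evaluated in
    log space.
    """
    counts = np.asarray(counts)
    counts = counts[counts > 0]
    total = int(counts.sum())
    depths = np.asarray(list(probe_depths), dtype=np.int64)
    if depths.size and depths.max() > total:
        raise ParameterError(
            f"probe depth {depths.max()} exceeds sample total {total}"
        )
    if depths.size and depths.min() < 0:
        raise ParameterError("probe depths must be non-negative")
    out = np.empty(depths.size, dtype=float)
    for k, d in enumerate(depths):
        if d == 0:
            out[k] = 0.0
            continue
        rest = total - counts  # reads not belonging to each ASV
        # P(ASV absent from the subsample) = C(rest, d) / C(total, d)
        log_absent = np.full(counts.shape, -np.inf)
        feasible = rest >= d
        r = rest[feasible].astype(float)
        log_absent_f = (
            gammaln(r + 1) - gammaln(r - d + 1)
            - (gammaln(total + 1.0) - gammaln(total - d + 1.0))
        )
        log_absent[feasible] = log_absent_f
        out[k] = float(np.sum(1.0 - np.exp(log_absent)))
    return out


def rarefaction_curve_mc(
    counts: np.ndarray, probe_depths, seed: int, n_rep: int = 200
) -> np.ndarray:
    """Monte-Carlo estimate of the expected rarefaction curve (cross-check)."""
    counts = np.asarray(counts, dtype=np.int64)
    rng = np.random.default_rng(seed)
    depths = list(probe_depths)
    means = np.zeros(len(depths))
    for k, d in enumerate(depths):
        richness = [
            int((rarefy_sample(counts, int(d), rng) > 0).sum())
            for _ in range(n_rep)
        ]
        means[k] = float(np.mean(richness))
    return means


def dataset_coverage(table: AsvTable) -> dict:
    """Dataset-level (pooled) observed richness, Chao1 and percent coverage."""
    pooled = table.counts.sum(axis=0).to_numpy()
    est = chao1(pooled)
    s_obs = int((pooled > 0).sum())
    return {
        "observed_richness": s_obs,
        "chao1": est,
        "coverage_pct": coverage_fraction(s_obs, est),
    }
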