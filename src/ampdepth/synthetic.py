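"""Synthetic ASV community tables with controllable class structure.

The generator produces finished count tables (never reads or sequences) that
emulate the shapes of benthic 16S amplicon surveys: tens of samples, a few
thousand ASVs, 15,000-215,000 reads per sample, 3-5 classes.  Class signal is
injected by multiplying the expected relative abundance of a small set of
class-specific ASVs by ``effect_size`` in their home class; ``effect_size=1``
collapses the design to a null with no class signal.  Compositional noise is
Dirichlet-multinomial: a log-normal expected-abundance profile defines the
Dirichlet mean, ``overdispersion`` is the total Dirichlet concentration
(smaller = noisier compositions sample-to-sample).

Random streams are keyed by ``(seed, sample index)``: adding samples to a
spec never perturbs the counts of earlier samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import AsvTable, ParameterError

__all__ = ["SyntheticSpec", "generate_dataset", "specific_asv_ids"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic multi-class ASV dataset.

    Defaults emulate a Scottish-salmon-farm-style sediment survey: 3 classes
    of (25, 24, 27) samples, 2800 shared background ASVs plus 80 ASVs specific
    to each class (3040 features total), per-sample depth uniform on
    [15,000, 40,000] reads.
    """

    n_classes: int = 3
    samples_per_class: tuple[int, ...] = (25, 24, 27)
    n_background_asvs: int = 2800
    n_specific_asvs_per_class: int = 80
    effect_size: float = 8.0
    base_abundance_logmean: float = 0.0
    base_abundance_logsd: float = 1.5
    overdispersion: float = 150.0
    depth_range: tuple[int, int] = (15_000, 40_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ParameterError("n_classes must be >= 2")
        if len(self.samples_per_class) != self.n_classes:
            raise ParameterError(
                f"samples_per_class has {len(self.samples_per_class)} entries "
                f"for {self.n_classes} classes"
            )
        if any(n < 3 for n in self.samples_per_class):
            raise ParameterError("need >= 3 samples per class")
        if self.n_background_asvs < 0 or self.n_specific_asvs_per_class < 0:
            raise ParameterError("ASV counts must be non-negative")
        if self.n_background_asvs + self.n_specific_asvs_per_class == 0:
            raise ParameterError("spec defines zero ASVs")
        if self.effect_size <= 0:
            raise ParameterError("effect_size must be positive")
        if self.overdispersion <= 0:
            raise ParameterError("overdispersion must be positive")
        lo, hi = self.depth_range
        if lo <= 0 or hi < lo:
            raise ParameterError(f"bad depth_range {self.depth_range}")

    @property
    def n_samples(self) -> int:
        return int(sum(self.samples_per_class))

    @property
    def n_asvs(self) -> int:
        return self.n_background_asvs + self.n_classes * self.n_specific_asvs_per_class

    @property
    def class_names(self) -> list[str]:
        return [f"class_{c}" for c in range(self.n_classes)]


def _asv_ids(spec: SyntheticSpec) -> list[str]:
    ids = [f"ASV_bg{i:05d}" for i in range(spec.n_background_asvs)]
    for c in range(spec.n_classes):
        ids += [
            f"ASV_c{c}s{j:04d}" for j in range(spec.n_specific_asvs_per_class)
        ]
    return ids


def specific_asv_ids(spec: SyntheticSpec, class_index: int) -> list[str]:
    """IDs of the ASVs enriched in class ``class_index``."""
    return [
        f"ASV_c{class_index}s{j:04d}"
        for j in range(spec.n_specific_asvs_per_class)
    ]


def _class_profiles(spec: SyntheticSpec) -> np.ndarray:
    """Expected relative-abundance profile per class, shape (classes, ASVs).

    The base profile is log-normal over all ASVs and drawn from a stream
    keyed by the seed alone, so it is identical across classes and stable
    when samples are added.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0]))
    base = rng.lognormal(
        spec.base_abundance_logmean, spec.base_abundance_logsd, spec.n_asvs
    )
    profiles = np.tile(base, (spec.n_classes, 1))
    k = spec.n_specific_asvs_per_class
    for c in range(spec.n_classes):
        start = spec.n_background_asvs + c * k
        profiles[c, start : start + k] *= spec.effect_size
    profiles /= profiles.sum(axis=1, keepdims=True)
    return profiles


def generate_dataset(spec: SyntheticSpec) -> AsvTable:
    """Draw one synthetic :class:`~ampdepth.tables.AsvTable` from ``spec``.

    Each sample's counts are a Dirichlet-multinomial realization at its own
    depth (uniform integer on ``spec.depth_range``), with the Dirichlet mean
    given by the sample's class profile and total concentration
    ``spec.overdispersion``.  Fully reproducible from ``spec.seed``; row sums
    equal the drawn depths exactly.
    """
    profiles = _class_profiles(spec)
    lo, hi = spec.depth_range
    n = spec.n_samples
    counts = np.zeros((n, spec.n_asvs), dtype=np.int64)
    labels = []
    sample_ids = []
    class_of_sample = np.repeat(
        np.arange(spec.n_classes), spec.samples_per_class
    )
    for i in range(n):
        c = int(class_of_sample[i])
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 1, i]))
        depth = int(rng.integers(lo, hi + 1))
        alpha = spec.overdispersion * profiles[c]
        composition = rng.dirichlet(alpha)
        # dirichlet can underflow to an all-zero vector for tiny alphas;
        # fall back to the mean profile rather than emitting NaNs
        total = composition.sum()
        if not np.isfinite(total) or total <= 0:
            composition = profiles[c]
        else:
            composition = composition / total
        counts[i] = rng.multinomial(depth, composition)
        labels.append(spec.class_names[c])
        sample_ids.append(f"S{i:03d}")
    frame = pd.DataFrame(counts, index=sample_ids, columns=_asv_ids(spec))
    return AsvTable(frame, pd.Series(labels, index=sample_ids, name="label"))
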