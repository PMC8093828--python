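"""Filtering rules and the relative-abundance transform for ASV tables.

Two quality filters precede any model fitting, applied in this fixed order:

1. drop ASVs whose total read count summed over **all** samples is below a
   threshold (default 50 reads), removing ecologically uninformative noise;
2. drop samples whose total depth is below a threshold (default 15,000
   reads), removing samples too shallow to rarefy meaningfully.

Both filters are idempotent.  The ASV threshold is interpreted as a
dataset-wide total, not a per-sample minimum, matching common amplicon
practice.  Classification then runs on the relative-abundance matrix
(each count divided by its sample's total) so that remaining depth
differences between samples cannot act as a predictive artifact.
"""

from __future__ import annotations

import logging

from .tables import (
    AsvTable,
    ClassEliminationError,
    EmptyTableError,
    ParameterError,
    RelativeAbundanceTable,
)

logger = logging.getLogger(__name__)

__all__ = [
    "filter_low_abundance_asvs",
    "filter_shallow_samples",
    "to_relative_abundance",
    "preprocess",
]


def filter_low_abundance_asvs(table: AsvTable, min_total_reads: int = 50) -> AsvTable:
    """Retain ASVs with at least ``min_total_reads`` reads across all samples.

    The sample axis and the order of retained ASVs are unchanged.  Raises
    :class:`EmptyTableError` if no ASV survives.
    """
    if min_total_reads < 0:
        raise ParameterError("min_total_reads must be non-negative")
    totals = table.counts.sum(axis=0)
    keep = totals[totals >= min_total_reads].index
    if len(keep) == 0:
        raise EmptyTableError(
            f"no ASV reaches {min_total_reads} total reads "
            f"(max observed: {int(totals.max()) if len(totals) else 0})"
        )
    if len(keep) == table.n_asvs:
        return table
    logger.info(
        "ASV filter (>=%d total reads): %d of %d ASVs retained",
        min_total_reads, len(keep), table.n_asvs,
    )
    return AsvTable(table.counts[keep], table.labels)


def filter_shallow_samples(table: AsvTable, min_depth: int = 15_000) -> AsvTable:
    """Retain samples with at least ``min_depth`` total reads.

    Discarded sample ids are logged.  If the filter would eliminate every
    sample of some class, :class:`ClassEliminationError` is raised naming the
    class(es), because the classification task cannot proceed without them.
    """
    if min_depth < 0:
        raise ParameterError("min_depth must be non-negative")
    depths = table.sample_depths
    keep = depths[depths >= min_depth].index
    discarded = [s for s in table.sample_ids if s not in set(keep)]
    if discarded:
        logger.info(
            "sample depth filter (>=%d reads): discarded %d sample(s): %s",
            min_depth, len(discarded), ", ".join(map(str, discarded)),
        )
    if len(keep) == 0:
        raise EmptyTableError(f"no sample reaches depth {min_depth}")
    before = set(table.labels.unique())
    after = set(table.labels.loc[keep].unique())
    lost = sorted(before - after)
    if lost:
        raise ClassEliminationError(lost)
    if not discarded:
        return table
    return table.subset_samples(keep)


def to_relative_abundance(table: AsvTable) -> RelativeAbundanceTable:
    """Divide each sample's counts by its total; rows sum to 1.

    Raises :class:`ParameterError` on a zero-total sample (impossible after
    the depth filter, guarded anyway).
    """
    depths = table.sample_depths
    zero = depths[depths == 0]
    if len(zero):
        raise ParameterError(
            f"zero-total sample(s) cannot be normalized: {list(zero.index)[:5]}"
        )
    values = table.counts.div(depths, axis=0)
    return RelativeAbundanceTable(values, table.labels)


def preprocess(
    table: AsvTable,
    min_asv_total: int = 50,
    min_sample_depth: int = 15_000,
) -> AsvTable:
    """Apply the ASV filter then the sample-depth filter (the pipeline order)."""
    return filter_shallow_samples(
        filter_low_abundance_asvs(table, min_asv_total), min_sample_depth
    )
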