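"""Rank-based group classification capacity between two methods.

Subjects are ranked by a body-composition variable separately under each
method and partitioned into ordered groups of (near-)equal size — tertiles by
default.  The classification capacity of the test method is the distribution
of placement offsets (test group minus reference group): the share at offset
0 is the percent correctly classified, offsets +/-1 are near misses, and so
on up to +/-(g-1).

Because the procedure depends only on ranks, any strictly increasing
recalibration of either method leaves it unchanged: a pure calibration bias
costs nothing here, only rank scrambling does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, SchemaError


@dataclass(frozen=True)
class Partition:
    """Group assignment from ranking one variable."""

    groups: np.ndarray  # group index (0 = lowest) per subject, input order
    sizes: tuple[int, ...]
    bounds: tuple[tuple[float, float], ...]  # observed (min, max) per group


@dataclass(frozen=True)
class ClassificationTable:
    """Cross-method placement offsets for one variable."""

    n: int
    n_groups: int
    sizes_test: tuple[int, ...]
    sizes_ref: tuple[int, ...]
    bounds_test: tuple[tuple[float, float], ...]
    bounds_ref: tuple[tuple[float, float], ...]
    offset_counts: dict[int, int]  # offset -(g-1)..+(g-1) -> subject count
    pct_correct: float
    pct_within_one: float


def group_sizes(n: int, n_groups: int) -> tuple[int, ...]:
    """Sizes of ranked groups; any remainder goes one-per-group to the lowest
    groups, so n=40, g=3 gives (14, 13, 13)."""
    base, rem = divmod(n, n_groups)
    return tuple(base + (1 if i < rem else 0) for i in range(n_groups))


def rank_and_partition(values, n_groups: int) -> Partition:
    """Rank subjects by ``values`` ascending and cut into contiguous groups.

    Ties keep input order (stable sort), so subject order acts as the
    tie-break.  Returns per-subject group indices in the original input
    order, group sizes, and the observed value range of each group.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n_groups < 2:
        raise SchemaError("n_groups must be >= 2")
    if n < n_groups:
        raise InsufficientDataError(f"need at least {n_groups} subjects, got {n}")
    sizes = group_sizes(n, n_groups)
    order = np.argsort(values, kind="stable")
    groups = np.empty(n, dtype=int)
    bounds = []
    start = 0
    for g, size in enumerate(sizes):
        block = order[start : start + size]
        groups[block] = g
        bounds.append((float(values[block].min()), float(values[block].max())))
        start += size
    return Partition(groups=groups, sizes=sizes, bounds=tuple(bounds))


def classification_table(
    part_test: Partition, part_ref: Partition
) -> ClassificationTable:
    """Tabulate placement offsets (test group - reference group) per subject."""
    gt, gr = part_test.groups, part_ref.groups
    if gt.shape != gr.shape:
        raise SchemaError("group assignments must have equal length")
    if len(part_test.sizes) != len(part_ref.sizes):
        raise SchemaError("both partitions must use the same number of groups")
    n = len(gt)
    g = len(part_test.sizes)
    offsets = gt - gr
    counts = {k: int(np.sum(offsets == k)) for k in range(-(g - 1), g)}
    pct_correct = 100.0 * counts[0] / n
    within_one = counts[0] + counts.get(-1, 0) + counts.get(1, 0)
    return ClassificationTable(
        n=n,
        n_groups=g,
        sizes_test=part_test.sizes,
        sizes_ref=part_ref.sizes,
        bounds_test=part_test.bounds,
        bounds_ref=part_ref.bounds,
        offset_counts=counts,
        pct_correct=pct_correct,
        pct_within_one=100.0 * within_one / n,
    )


def classify(test_values, ref_values, n_groups: int = 3) -> ClassificationTable:
    """Rank-and-partition both methods and tabulate the cross-classification."""
    test_values = np.asarray(test_values, dtype=float)
    ref_values = np.asarray(ref_values, dtype=float)
    if test_values.shape != ref_values.shape:
        raise SchemaError("test and reference values must have equal length")
    return classification_table(
        rank_and_partition(test_values, n_groups),
        rank_and_partition(ref_values, n_groups),
    )


def format_table(table: ClassificationTable, variable: str = "value") -> str:
    """Plain-text report of a classification table."""
    lines = [
        f"Classification capacity ({variable}, {table.n_groups} groups, n={table.n})",
        f"  group sizes: test {table.sizes_test}, reference {table.sizes_ref}",
        "  group ranges (test / reference):",
    ]
    for g in range(table.n_groups):
        lo_t, hi_t = table.bounds_test[g]
        lo_r, hi_r = table.bounds_ref[g]
        lines.append(
            f"    group {g}: {lo_t:.1f}-{hi_t:.1f} / {lo_r:.1f}-{hi_r:.1f}"
        )
    lines.append("  placement offsets (test - reference):")
    for k in sorted(table.offset_counts):
        c = table.offset_counts[k]
        lines.append(f"    {k:+d}: {c} ({100.0 * c / table.n:.0f}%)")
    lines.append(f"  correctly classified: {table.pct_correct:.0f}%")
    lines.append(f"  within one group:     {table.pct_within_one:.0f}%")
    return "\n".join(lines)
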