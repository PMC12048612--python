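"""Repeat-count range classification, genotype-combination labels and
fragment-size calibration for HTT CAG alleles.

The analysed genotype is the integer CAG copy number of each of a
subject's two HTT alleles, ordered so that ``a1 <= a2``.  Repeat counts
are classified into five ranges:

====== =========== ==================================================
letter repeats     meaning
====== =========== ==================================================
a      7-12        short alleles
b      13-(s-1)    common range below the split point *s* (default 21)
c      s-26        common range at/above the split point
d      27-35       intergenerational-instability (anticipation) risk
e      36-39       reduced-penetrance Huntington's disease range
====== =========== ==================================================

Counts of 40 or more lie in the fully penetrant HD range, are absent
from the study population this package models, and are flagged as
``"hd_full"`` rather than silently binned into ``e``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

MIN_REPEAT = 7
MAX_REPEAT = 39
HD_FULL_LABEL = "hd_full"

#: valid positions for the movable boundary between ranges b and c
SPLIT_RANGE = range(14, 27)


class RepeatRangeError(ValueError):
    """Raised for repeat counts or split points outside the modelled domain."""


@dataclass(frozen=True)
class RangeScheme:
    """Partition of the repeat-count domain [7, 39] into ranges a-e.

    Only the boundary between ``b`` and ``c`` is movable: ``b`` spans
    ``13..split_bc-1`` and ``c`` spans ``split_bc..26``.  The canonical
    scheme uses ``split_bc = 21``.
    """

    split_bc: int = 21

    def __post_init__(self) -> None:
        if self.split_bc not in SPLIT_RANGE:
            raise RepeatRangeError(
                f"split point must lie in {SPLIT_RANGE.start}..{SPLIT_RANGE.stop - 1}, "
                f"got {self.split_bc}"
            )

    @property
    def bins(self) -> dict[str, tuple[int, int]]:
        """Mapping letter -> inclusive (low, high) repeat-count bounds."""
        return {
            "a": (7, 12),
            "b": (13, self.split_bc - 1),
            "c": (self.split_bc, 26),
            "d": (27, 35),
            "e": (36, 39),
        }


CANONICAL_SCHEME = RangeScheme(21)


def categorize_repeat(count: int, scheme: RangeScheme = CANONICAL_SCHEME) -> str:
    """Classify a single repeat count into its range letter.

    Counts >= 40 return the flag ``"hd_full"``; counts < 7 are outside
    the observable allele domain and raise :class:`RepeatRangeError`.
    """
    count = int(count)
    if count < MIN_REPEAT:
        raise RepeatRangeError(f"repeat count {count} below minimum of {MIN_REPEAT}")
    if count > MAX_REPEAT:
        return HD_FULL_LABEL
    for letter, (lo, hi) in scheme.bins.items():
        if lo <= count <= hi:
            return letter
    raise AssertionError("unreachable: bins partition 7..39")


def combine(a1: int, a2: int, scheme: RangeScheme = CANONICAL_SCHEME) -> str:
    """Label the unordered genotype combination of two alleles, e.g. ``"bc"``.

    Letters are sorted alphabetically, which coincides with nondecreasing
    repeat length, so ``combine(22, 17) == combine(17, 22) == "bc"``.
    If either allele is in the fully penetrant range the whole genotype
    is flagged ``"hd_full"``.
    """
    c1 = categorize_repeat(a1, scheme)
    c2 = categorize_repeat(a2, scheme)
    if HD_FULL_LABEL in (c1, c2):
        return HD_FULL_LABEL
    return "".join(sorted((c1, c2)))


def sweep_schemes(splits: Iterable[int]) -> list[RangeScheme]:
    """Build one :class:`RangeScheme` per requested b/c split point."""
    return [RangeScheme(int(s)) for s in splits]


@dataclass(frozen=True)
class Subject:
    """One cohort member."""

    id: str
    group: str  # MDD | ANX | CON
    sex: str  # female | male
    age: float
    a1: int
    a2: int
    phenotypes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.a1 > self.a2:
            raise ValueError(f"subject {self.id}: a1={self.a1} > a2={self.a2}")
        if self.a1 < MIN_REPEAT:
            raise RepeatRangeError(f"subject {self.id}: a1={self.a1} < {MIN_REPEAT}")


# ---------------------------------------------------------------------------
# Fragment-size calibration (toy-scale repeat calling)
# ---------------------------------------------------------------------------

#: calls above this repeat count require a concordant replicate
PATHOLOGIC_THRESHOLD = 35


class CalibrationError(ValueError):
    """Raised when the size standard cannot support a calibration."""


@dataclass(frozen=True)
class FragmentStandard:
    """Reference DNA fragments of predetermined repeat number.

    ``pairs`` holds (fragment_size_bp, repeat_count) tuples; repeat count
    must increase strictly with fragment size.
    """

    pairs: tuple[tuple[float, int], ...]

    def __post_init__(self) -> None:
        if len({s for s, _ in self.pairs}) < 2:
            raise CalibrationError("need at least 2 distinct standard fragments")
        ordered = sorted(self.pairs)
        repeats = [r for _, r in ordered]
        if any(r2 <= r1 for r1, r2 in zip(repeats, repeats[1:])):
            raise CalibrationError("repeat counts must increase strictly with size")


@dataclass(frozen=True)
class RepeatCall:
    fragment_size: float
    repeat_count: int
    status: str  # "called" | "confirmed" | "unconfirmed"


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def calibrate_fragments(
    standards: FragmentStandard,
    observed_sizes: Sequence[float],
    replicate_sizes: Optional[Sequence[Optional[float]]] = None,
) -> list[RepeatCall]:
    """Convert capillary fragment sizes (bp) into integer repeat counts.

    An ordinary-least-squares linear map from fragment size to repeat
    count is fitted on the standards and applied to the observed sizes,
    with half-up rounding.  Calls above :data:`PATHOLOGIC_THRESHOLD`
    repeats must be confirmed by a concordant replicate measurement;
    otherwise the call is reported with status ``"unconfirmed"``.
    """
    sizes = np.array([s for s, _ in standards.pairs], dtype=float)
    repeats = np.array([r for _, r in standards.pairs], dtype=float)
    slope, intercept = np.polyfit(sizes, repeats, 1)
    # sizes must map into the plausible repeat domain (short of absurd calls)
    lo_rep, hi_rep = MIN_REPEAT - 1, 60

    if replicate_sizes is None:
        replicate_sizes = [None] * len(observed_sizes)
    if len(replicate_sizes) != len(observed_sizes):
        raise CalibrationError("replicate_sizes length must match observed_sizes")

    calls: list[RepeatCall] = []
    for size, rep_size in zip(observed_sizes, replicate_sizes):
        mapped = slope * size + intercept
        if not (lo_rep <= mapped <= hi_rep):
            raise CalibrationError(
                f"fragment size {size} maps to {mapped:.1f} repeats, outside "
                f"the callable domain [{lo_rep}, {hi_rep}]"
            )
        count = _round_half_up(mapped)
        status = "called"
        if count > PATHOLOGIC_THRESHOLD:
            if rep_size is not None and _round_half_up(slope * rep_size + intercept) == count:
                status = "confirmed"
            else:
                status = "unconfirmed"
                logger.warning(
                    "pathologic call %d repeats (size %.1f bp) lacks a concordant "
                    "replicate; reported as unconfirmed",
                    count,
                    size,
                )
        calls.append(RepeatCall(fragment_size=float(size), repeat_count=count, status=status))
    return calls
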