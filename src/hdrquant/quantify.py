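"""Per-sample editing-outcome quantities and replicate aggregation.

From per-read outcome calls this module computes, per sample:

* % cells with indel — indel reads as a percentage of non-discarded reads;
* % indel-free cells with target mutation — HDR reads as a percentage of
  non-discarded, indel-free reads;
* % cells with target mutation — the population correction

      % cells with target = % indel-free with target × (100 − % cells with indel) / 100

  which rescales the indel-free HDR percentage back to the whole (non-
  discarded) population, since reads with indels are removed from the
  alignment before HDR is scored;
* HDR:indel ratio — corrected HDR % divided by indel %, reported only when
  the HDR frequency clears the mode's threshold: 1% for HDR-proficient
  HEK293T-style experiments, 0.1% for less HDR-amenable cell types.  Below
  threshold the ratio is NOT_REPORTED (a first-class value, never a silent
  zero); when replicate ratios are averaged, NOT_REPORTED entries may be
  zero-filled so site means are not inflated by unreported values.

All percentages refer to the whole non-discarded read population, not to
edited or modified reads; read % is equated with cell %.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence, Union

from .align import ReadCall

__all__ = [
    "NOT_REPORTED",
    "NotReported",
    "ThresholdMode",
    "STRICT_1PCT",
    "PERMISSIVE_0P1PCT",
    "THRESHOLD_MODES",
    "SampleQuant",
    "tabulate_sample",
    "quantify_sample",
    "correct_hdr",
    "hdr_indel_ratio",
    "aggregate_replicates",
]

logger = logging.getLogger(__name__)


class NotReported:
    """Sentinel for an HDR:indel ratio that is not reported."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NOT_REPORTED"


NOT_REPORTED = NotReported()

Ratio = Union[float, NotReported]


@dataclass(frozen=True)
class ThresholdMode:
    """Minimum HDR frequency below which no HDR:indel ratio is reported."""

    name: str
    min_hdr_for_ratio: float  # percent


STRICT_1PCT = ThresholdMode("strict_1pct", 1.0)
PERMISSIVE_0P1PCT = ThresholdMode("permissive_0p1pct", 0.1)
THRESHOLD_MODES = {m.name: m for m in (STRICT_1PCT, PERMISSIVE_0P1PCT)}


@dataclass(frozen=True)
class SampleQuant:
    """Class counts and derived percentages for one sample."""

    n_total: int
    n_discarded: int
    n_indel: int
    n_hdr: int
    n_unmodified: int
    pct_cells_with_indel: float = math.nan
    pct_indelfree_with_target: float = math.nan
    pct_cells_with_target: float = math.nan
    hdr_indel_ratio: Ratio = NOT_REPORTED
    threshold_mode: str = ""


def tabulate_sample(calls: Sequence[ReadCall]) -> SampleQuant:
    """Exact outcome-class counts for one sample (percentages unfilled).

    Raises ``ValueError`` on an empty call list or when every read was
    discarded (nothing quantifiable).
    """
    if not calls:
        raise ValueError("no reads to tabulate")
    counts = {"UNMODIFIED": 0, "HDR": 0, "INDEL": 0, "DISCARDED": 0}
    for call in calls:
        counts[call.outcome] += 1
    if counts["DISCARDED"] == len(calls):
        raise ValueError("all reads discarded; no quantifiable reads")
    return SampleQuant(
        n_total=len(calls),
        n_discarded=counts["DISCARDED"],
        n_indel=counts["INDEL"],
        n_hdr=counts["HDR"],
        n_unmodified=counts["UNMODIFIED"],
    )


def correct_hdr(pct_indelfree_with_target: float, pct_cells_with_indel: float) -> float:
    """Population correction: % cells with the target mutation.

    ``% indel-free cells with target × (100 − % cells with indel) / 100``.
    """
    for v in (pct_indelfree_with_target, pct_cells_with_indel):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"percentages must lie in [0, 100], got {v}")
    return pct_indelfree_with_target * (100.0 - pct_cells_with_indel) / 100.0


def hdr_indel_ratio(
    pct_cells_with_target: float,
    pct_cells_with_indel: float,
    mode: ThresholdMode,
) -> Ratio:
    """Corrected HDR % divided by indel %, subject to the reporting threshold.

    NOT_REPORTED when HDR % falls below ``mode.min_hdr_for_ratio``, and also
    when indel % is exactly zero with HDR above threshold (the ratio is
    undefined; logged).
    """
    for v in (pct_cells_with_target, pct_cells_with_indel):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"percentages must lie in [0, 100], got {v}")
    if pct_cells_with_target < mode.min_hdr_for_ratio:
        return NOT_REPORTED
    if pct_cells_with_indel == 0.0:
        logger.warning(
            "HDR %.3f%% above the %s threshold but indel %% is zero; "
            "ratio undefined, not reported",
            pct_cells_with_target,
            mode.name,
        )
        return NOT_REPORTED
    return pct_cells_with_target / pct_cells_with_indel


def quantify_sample(
    calls: Sequence[ReadCall], mode: ThresholdMode = STRICT_1PCT
) -> SampleQuant:
    """Tabulate calls and fill all derived percentages and the ratio.

    Percentages are computed over non-discarded reads and carried at full
    floating precision; rounding happens only at report time.
    """
    q = tabulate_sample(calls)
    n_kept = q.n_total - q.n_discarded
    pct_indel = 100.0 * q.n_indel / n_kept
    n_indelfree = n_kept - q.n_indel
    pct_ifree = 100.0 * q.n_hdr / n_indelfree if n_indelfree > 0 else 0.0
    pct_target = correct_hdr(pct_ifree, pct_indel)
    return replace(
        q,
        pct_cells_with_indel=pct_indel,
        pct_indelfree_with_target=pct_ifree,
        pct_cells_with_target=pct_target,
        hdr_indel_ratio=hdr_indel_ratio(pct_target, pct_indel, mode),
        threshold_mode=mode.name,
    )


def aggregate_replicates(
    values: Iterable[Union[float, NotReported]], zero_fill: bool = False
) -> tuple[float, float, int]:
    """Mean, sample (n−1) standard deviation and n over replicate values.

    With ``zero_fill`` (the convention for HDR:indel ratios), NOT_REPORTED
    entries contribute 0 to the mean and sd; without it they are an error,
    since percentages are always defined.
    """
    filled: list[float] = []
    for v in values:
        if isinstance(v, NotReported):
            if not zero_fill:
                raise ValueError(
                    "NOT_REPORTED among replicate values; use zero_fill for ratios"
                )
            filled.append(0.0)
        else:
            filled.append(float(v))
    n = len(filled)
    if n < 1:
        raise ValueError("need at least one replicate")
    mean = sum(filled) / n
    sd = (
        math.sqrt(sum((v - mean) ** 2 for v in filled) / (n - 1))
        if n > 1
        else math.nan
    )
    return mean, sd, n
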