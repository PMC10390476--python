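"""Bacterial-load quantification from serial-dilution plate counts.

Each sampled insect is homogenized and the homogenate plated undiluted and
at two serial dilutions (1e-2 and 1e-4 by default). Colonies are counted on
the least dilute plate whose count is countable (between 1 and a saturation
threshold, conventionally 300 colonies); the CFU per insect is that count
scaled back by the dilution factor and by the homogenate-to-plated volume
ratio. Per-cage load is the median over the sampled individuals (four by
convention), reported with the interquartile range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_DILUTIONS",
    "DEFAULT_COUNTABLE_MAX",
    "QuantificationError",
    "UnderSampledWarning",
    "PlateSet",
    "select_countable_plate",
    "cfu_per_mosquito",
    "pool_median",
    "plates_from_records",
]

DEFAULT_DILUTIONS = (1.0, 1e-2, 1e-4)
DEFAULT_COUNTABLE_MAX = 300


class QuantificationError(ValueError):
    """No plate in the dilution series yields a usable colony count."""


class UnderSampledWarning(UserWarning):
    """Fewer individuals pooled than the design expects."""


@dataclass
class PlateSet:
    """Colony counts across a dilution series for one homogenate.

    ``counts[i]`` is the colony count on the plate at ``dilutions[i]``;
    ``uncountable[i]`` flags a lawn/saturated plate whose count is not
    usable. Dilutions are ordered from least dilute (highest concentration,
    factor 1) to most dilute.
    """

    counts: tuple[int | None, ...]
    dilutions: tuple[float, ...] = DEFAULT_DILUTIONS
    uncountable: tuple[bool, ...] = ()
    homogenate_volume_ul: float = 150.0
    #: ratio of homogenate volume to plated volume; multiplies counts back
    #: to whole-insect CFU. Unknown plating volumes cancel in log-scale
    #: treatment contrasts, so 1 is a safe default.
    volume_scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.uncountable:
            self.uncountable = tuple(c is None for c in self.counts)
        if len(self.counts) != len(self.dilutions) or len(self.uncountable) != len(self.counts):
            raise ValueError("counts, dilutions and uncountable must have equal length")
        if any(d2 >= d1 for d1, d2 in zip(self.dilutions, self.dilutions[1:])):
            raise ValueError("dilutions must be strictly decreasing in concentration")
        for c, u in zip(self.counts, self.uncountable):
            if not u and (c is None or c < 0):
                raise ValueError("countable plates need a non-negative count")


def select_countable_plate(plates: PlateSet,
                           countable_max: int = DEFAULT_COUNTABLE_MAX) -> tuple[float, int]:
    """Pick the least dilute plate with a countable colony count.

    Countable means not flagged uncountable and count in ``[1, countable_max]``.
    If every non-flagged plate reads zero, the least dilute zero plate is
    returned (a cleared infection), otherwise a missing countable plate is a
    :class:`QuantificationError`.
    """
    zero_fallback: tuple[float, int] | None = None
    for dilution, count, unc in zip(plates.dilutions, plates.counts, plates.uncountable):
        if unc:
            continue
        if 1 <= count <= countable_max:
            return dilution, count
        if count == 0 and zero_fallback is None:
            zero_fallback = (dilution, 0)
    if zero_fallback is not None:
        return zero_fallback
    raise QuantificationError(
        f"no countable plate (counts={plates.counts}, max={countable_max})")


def cfu_per_mosquito(plates: PlateSet, countable_max: int = DEFAULT_COUNTABLE_MAX) -> float:
    """CFU per insect: selected count scaled by 1/dilution and volume ratio."""
    dilution, count = select_countable_plate(plates, countable_max)
    return count * (1.0 / dilution) * plates.volume_scale


def pool_median(cfus, n_expected: int = 4) -> tuple[float, float]:
    """Median and interquartile range of per-insect CFU values.

    Quantiles use linear interpolation, so the even-n median is the mean of
    the middle two values and IQR = Q3 - Q1 on the same convention (this is
    what the plotted error bars represent).
    """
    cfus = np.asarray(list(cfus), dtype=float)
    if cfus.size == 0:
        raise ValueError("cannot pool an empty CFU list")
    if cfus.size != n_expected:
        warnings.warn(
            f"pooled {cfus.size} individuals, expected {n_expected}",
            UnderSampledWarning, stacklevel=2)
    q1, med, q3 = np.quantile(cfus, [0.25, 0.5, 0.75])
    return float(med), float(q3 - q1)


def plates_from_records(records, **kwargs) -> PlateSet:
    """Build a PlateSet from (dilution, count, uncountable) triples.

    Convenience for the raw-plate CSV interface: rows with ``uncountable``
    truthy carry no usable count.
    """
    records = sorted(records, key=lambda r: -r[0])
    dilutions = tuple(float(r[0]) for r in records)
    counts = tuple(None if r[2] else int(r[1]) for r in records)
    uncountable = tuple(bool(r[2]) for r in records)
    return PlateSet(counts=counts, dilutions=dilutions, uncountable=uncountable, **kwargs)
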