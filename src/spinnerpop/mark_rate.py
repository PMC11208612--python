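"""Mark-rate estimation from group-sighting records.

Capture-recapture abundance estimates apply only to the distinctively marked
(identifiable) fraction of a population, so they are later scaled by the mark
rate θ — the proportion of animals bearing individually identifiable marks.
Two independent ratio estimators are used:

* method 1 ("images"): among large groups (> ``threshold`` animals) with full
  photographic coverage, the proportion of sufficient-quality images showing a
  distinctive fin;
* method 2 ("groups"): among small groups (≤ ``threshold``) with full coverage
  and reliable size counts, the total number of distinct individuals over the
  summed group sizes.

Both pool numerators and denominators across qualifying sightings (a ratio of
totals, equivalently an image-/animal-count-weighted mean of per-sighting
ratios).  SE(θ̂) = sqrt(θ̂(1−θ̂)/n) with n the pooled denominator.  The
final rate is the unweighted mean of the two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True)
class GroupSighting:
    """Tallies from one encountered group."""

    sighting_id: str
    group_size: int
    n_distinct_individuals: int
    n_quality_images_distinct: int
    n_quality_images_total: int
    full_photo_coverage: bool = True

    def __post_init__(self) -> None:
        if self.group_size < 1:
            raise ValueError("group size must be positive")
        if not (0 <= self.n_distinct_individuals <= self.group_size):
            raise ValueError("distinct individuals must be in [0, group size]")
        if not (0 <= self.n_quality_images_distinct
                <= self.n_quality_images_total):
            raise ValueError("distinct-image count exceeds total images")


@dataclass(frozen=True)
class MarkRateEstimate:
    theta_hat: float
    se: float
    n: int
    method: str  # "images" | "groups" | "combined"
    components: tuple = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_hat <= 1.0:
            raise ValueError("theta must be a probability")
        if self.se < 0:
            raise ValueError("SE must be non-negative")


def _binomial_se(theta: float, n: int) -> float:
    return math.sqrt(theta * (1.0 - theta) / n)


def partition_groups(
    sightings: Iterable[GroupSighting], threshold: int = 20
) -> tuple[list[GroupSighting], list[GroupSighting], list[GroupSighting]]:
    """Split sightings into (large full-coverage, small full-coverage, excluded).

    "Small" is inclusive of the threshold (group size ≤ threshold); sightings
    without full photographic coverage are excluded regardless of size.
    """
    large, small, excluded = [], [], []
    for s in sightings:
        if not s.full_photo_coverage:
            excluded.append(s)
        elif s.group_size > threshold:
            large.append(s)
        else:
            small.append(s)
    return large, small, excluded


def theta1(sightings: Sequence[GroupSighting]) -> MarkRateEstimate:
    """Image-proportion mark rate from large, fully photographed groups."""
    if not sightings:
        raise ValueError("no qualifying sightings for method 1")
    num = sum(s.n_quality_images_distinct for s in sightings)
    den = sum(s.n_quality_images_total for s in sightings)
    if den == 0:
        raise ValueError("zero quality images across qualifying sightings")
    theta = num / den
    return MarkRateEstimate(theta, _binomial_se(theta, den), den, "images")


def theta2(sightings: Sequence[GroupSighting]) -> MarkRateEstimate:
    """Distinct-individuals-per-animal mark rate from small groups."""
    if not sightings:
        raise ValueError("no qualifying sightings for method 2")
    num = sum(s.n_distinct_individuals for s in sightings)
    den = sum(s.group_size for s in sightings)
    theta = num / den
    return MarkRateEstimate(theta, _binomial_se(theta, den), den, "groups")


def combine_mark_rates(
    estimates: Sequence[MarkRateEstimate],
) -> MarkRateEstimate:
    """Unweighted mean of the component mark rates.

    A single input is returned unchanged.  The combined estimate carries its
    components for reporting; its ``se`` is the largest component SE (kept for
    display only — downstream total-abundance SEs use the binomial term of the
    delta-method formula directly, not this value).
    """
    if not estimates:
        raise ValueError("need at least one estimate to combine")
    if len(estimates) == 1:
        return estimates[0]
    theta = sum(e.theta_hat for e in estimates) / len(estimates)
    return MarkRateEstimate(
        theta_hat=theta,
        se=max(e.se for e in estimates),
        n=sum(e.n for e in estimates),
        method="combined",
        components=tuple(estimates),
    )
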