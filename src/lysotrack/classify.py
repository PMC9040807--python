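"""Threshold logic turning coverage statistics into an activity call.

Decision tree (all comparisons are closed bounds, so a ratio of exactly 2.0
passes the default cutoff):

1. If both the coverage ratio and Cohen's *d* reach their thresholds, the
   prophage is potentially active; it is called ``active`` if it also passes
   the minimum mean-coverage and breadth gates, else ``ambiguous``.
2. If the ratio/effect test fails and the prophage also fails the
   coverage/breadth minima, there is insufficient evidence the prophage is in
   the sample at all: ``not present``.
3. Otherwise the prophage is covered like its host and is ``dormant``
   (lysogenic).

An uncovered host region makes the ratio undefined; such prophages are
``ambiguous``, never ``active``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .coordinates import ProphageCoordinate
from .coverage import RegionSummary, coverage_ratio, effect_size

ACTIVE = "active"
AMBIGUOUS = "ambiguous"
DORMANT = "dormant"
NOT_PRESENT = "not present"

#: Reduced ratio cutoff for increased sensitivity; control tests show it
#: still yields accurate calls while the default 2.0 is deliberately
#: conservative.
SENSITIVE_RATIO = 1.75

#: CLI floor for --min-ratio unless explicitly forced.
MIN_SUPPORTED_RATIO = 1.5


@dataclass(frozen=True)
class Thresholds:
    """Complete tunable decision configuration (defaults as published).

    min_ratio
        Minimum prophage/host coverage ratio (default 2.0; 1.75 is the
        recommended sensitive setting).
    min_effect
        Minimum Cohen's *d* (default 0.70, a "medium" effect).
    min_prophage_mean
        Minimum mean prophage coverage (default 1.0x) — presence gate.
    min_breadth
        Minimum fraction of prophage positions covered (default 0.50).
    min_region_len
        Minimum prophage and host region length in nucleotides (1000).
    mask_len
        Positions masked from each scaffold end (150).
    min_identity
        Read alignment percent-identity filter (97).
    """

    min_ratio: float = 2.0
    min_effect: float = 0.70
    min_prophage_mean: float = 1.0
    min_breadth: float = 0.50
    min_region_len: int = 1000
    mask_len: int = 150
    min_identity: float = 97.0

    def __post_init__(self) -> None:
        if not self.min_ratio > 1:
            raise ValueError("min_ratio must be > 1")
        if self.min_effect < 0:
            raise ValueError("min_effect must be >= 0")
        if not 0 < self.min_breadth <= 1:
            raise ValueError("min_breadth must be in (0, 1]")
        if self.min_region_len <= 0:
            raise ValueError("min_region_len must be > 0")
        if self.mask_len < 0:
            raise ValueError("mask_len must be >= 0")
        if not 0 <= self.min_identity <= 100:
            raise ValueError("min_identity must be in [0, 100]")

    def sensitive(self) -> "Thresholds":
        """Copy with the ratio cutoff reduced to the sensitive setting."""
        return replace(self, min_ratio=SENSITIVE_RATIO)


@dataclass(frozen=True)
class ActivityResult:
    """Activity call plus the statistics it was made from, for one prophage."""

    prophage_id: str
    scaffold_id: str
    start: int
    stop: int
    category: str
    reason: str
    ratio: float = math.nan
    effect_size_d: float = math.nan
    prophage_summary: RegionSummary | None = None
    host_summary: RegionSummary | None = None


def classify_metrics(
    ratio: float,
    d: float,
    prophage_mean: float,
    breadth: float,
    t: Thresholds,
) -> tuple[str, str]:
    """Categorize one (ratio, effect size, coverage, breadth) quadruple.

    Returns ``(category, reason)``; the reason records which criteria passed
    or failed.  A NaN ratio means the host region was uncovered.
    """
    if math.isnan(ratio):
        return AMBIGUOUS, "host region uncovered; ratio undefined"
    present = prophage_mean >= t.min_prophage_mean and breadth >= t.min_breadth
    metrics = ratio >= t.min_ratio and d >= t.min_effect
    if metrics:
        if present:
            return ACTIVE, (
                f"ratio {ratio:.2f} >= {t.min_ratio} and d {d:.2f} >= "
                f"{t.min_effect}; coverage and breadth adequate"
            )
        return AMBIGUOUS, (
            f"ratio and effect size pass but prophage coverage "
            f"{prophage_mean:.2f} or breadth {breadth:.2f} below minimum"
        )
    if not present:
        return NOT_PRESENT, (
            f"prophage coverage {prophage_mean:.2f} or breadth {breadth:.2f} "
            f"below minimum; no evidence prophage is in the sample"
        )
    if ratio < t.min_ratio and d < t.min_effect:
        why = f"ratio {ratio:.2f} < {t.min_ratio} and d {d:.2f} < {t.min_effect}"
    elif ratio < t.min_ratio:
        why = f"ratio {ratio:.2f} < {t.min_ratio}"
    else:
        why = f"d {d:.2f} < {t.min_effect}"
    return DORMANT, why


def classify(
    prophage: RegionSummary,
    host: RegionSummary,
    t: Thresholds,
    *,
    coord: ProphageCoordinate | None = None,
) -> ActivityResult:
    """Full activity call for one prophage/host summary pair."""
    ratio = coverage_ratio(prophage, host)
    d = effect_size(host, prophage)
    category, reason = classify_metrics(
        ratio, d, prophage.mean_depth, prophage.breadth, t
    )
    return ActivityResult(
        prophage_id=coord.prophage_id if coord else "",
        scaffold_id=coord.scaffold_id if coord else "",
        start=coord.start if coord else 0,
        stop=coord.stop if coord else 0,
        category=category,
        reason=reason,
        ratio=ratio,
        effect_size_d=d,
        prophage_summary=prophage,
        host_summary=host,
    )


def classify_all(
    entries: list[tuple[ProphageCoordinate, RegionSummary | None, RegionSummary | None, str | None]],
    t: Thresholds,
) -> list[ActivityResult]:
    """Classify every admitted prophage, including unanalyzable ones.

    Each entry is ``(coordinate, prophage_summary, host_summary, flag)``;
    entries with a non-None ``flag`` were excluded upstream (region too
    short, scaffold masked out, ...) and are reported as ``not present`` with
    that reason.  Output order is deterministic: scaffold id, then start.
    """
    results: list[ActivityResult] = []
    for coord, psum, hsum, flag in entries:
        if flag is not None or psum is None or hsum is None:
            results.append(
                ActivityResult(
                    prophage_id=coord.prophage_id,
                    scaffold_id=coord.scaffold_id,
                    start=coord.start,
                    stop=coord.stop,
                    category=NOT_PRESENT,
                    reason=flag or "region statistics unavailable",
                )
            )
            continue
        results.append(classify(psum, hsum, t, coord=coord))
    results.sort(key=lambda r: (r.scaffold_id, r.start, r.prophage_id))
    return results
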