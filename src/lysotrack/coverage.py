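"""Region coverage statistics: end masking, host segmentation, summaries.

The activity signal is a comparison of per-nucleotide depth between a
prophage interval and the prophage-excluded remainder of its scaffold.  Two
statistics drive the decision:

* the prophage/host coverage ratio, ``mean(prophage) / mean(host)``, which
  is ~1 for a dormant (lysogenic) prophage replicating 1:1 with the host
  chromosome and rises above 1 when lytic replication adds phage genome
  copies; and
* Cohen's *d*, ``|mean_host - mean_prophage| / sqrt((sd_host^2 +
  sd_prophage^2) / 2)``, the standardized mean difference of the two depth
  distributions, used as the significance gate for the ratio.

A fixed number of positions (default 150 bp) is masked at each scaffold end
before any statistic is computed, because partial metagenomic scaffolds show
depressed coverage at their ends.  All non-prophage interior positions of a
scaffold form one cohesive host region shared by every co-resident prophage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alignment import DepthProfile
from .coordinates import ScaffoldRecord
from .errors import ComputationError

DEFAULT_MASK_LEN = 150


@dataclass(frozen=True)
class RegionSummary:
    """Depth summary over one region (prophage or segmented host)."""

    mean_depth: float
    median_depth: float
    sd_depth: float
    breadth: float          # fraction of positions with depth >= 1
    n_positions: int


@dataclass(frozen=True)
class HostSegmentation:
    """Boolean position mask of the cohesive host region of one scaffold.

    Identical for every prophage on the scaffold: co-resident prophages never
    interfere with each other's host comparison.
    """

    scaffold_id: str
    host_mask: np.ndarray  # bool, length == scaffold length


def mask_ends(profile: DepthProfile, mask_len: int = DEFAULT_MASK_LEN) -> np.ndarray:
    """Boolean mask of interior positions after masking both scaffold ends.

    Positions ``[0, mask_len)`` and ``[L - mask_len, L)`` are excluded from
    all downstream statistics; the underlying depths are unaltered.  Raises
    :class:`ComputationError` when no interior remains (scaffold
    unanalyzable).
    """
    if mask_len < 0:
        raise ValueError("mask_len must be >= 0")
    L = profile.length
    if L <= 2 * mask_len:
        raise ComputationError(
            f"{profile.scaffold_id}: scaffold length {L} leaves no interior "
            f"after masking {mask_len} bp from each end"
        )
    mask = np.zeros(L, dtype=bool)
    mask[mask_len: L - mask_len] = True
    return mask


def segment_host(scaffold: ScaffoldRecord, interior: np.ndarray) -> HostSegmentation:
    """Host region = interior positions minus the union of prophage intervals."""
    host = interior.copy()
    for p in scaffold.prophages:
        host[p.slice0] = False
    return HostSegmentation(scaffold.scaffold_id, host)


def summarize_region(profile: DepthProfile, positions: np.ndarray) -> RegionSummary:
    """Mean/median/SD/breadth of depth over the selected positions.

    ``positions`` is a boolean mask over the scaffold.  Zeros are included;
    the SD is the population standard deviation; the median uses the
    midpoint-of-two rule for even counts.
    """
    vals = profile.depth[positions]
    if vals.size == 0:
        raise ComputationError(f"{profile.scaffold_id}: empty region")
    return RegionSummary(
        mean_depth=float(vals.mean()),
        median_depth=float(np.median(vals)),
        sd_depth=float(vals.std(ddof=0)),
        breadth=float((vals > 0).mean()),
        n_positions=int(vals.size),
    )


def coverage_ratio(prophage: RegionSummary, host: RegionSummary) -> float:
    """Prophage/host mean-depth ratio; NaN when the host is uncovered."""
    if host.mean_depth == 0:
        return math.nan
    return prophage.mean_depth / host.mean_depth


def cohens_d(mean_a: float, sd_a: float, mean_b: float, sd_b: float) -> float:
    """Cohen's *d* magnitude: ``|mean_a - mean_b| / sqrt((sd_a^2 + sd_b^2)/2)``.

    Reported as a magnitude (the sign carries no decision information; a
    large *d* flags a significant coverage difference in either direction).
    Both SDs zero with equal means gives 0; with unequal means the limit of
    the formula is returned as ``inf``, which passes any finite threshold.
    """
    diff = abs(mean_a - mean_b)
    pooled = math.sqrt((sd_a * sd_a + sd_b * sd_b) / 2.0)
    if pooled == 0:
        return 0.0 if diff == 0 else math.inf
    return diff / pooled


def effect_size(host: RegionSummary, prophage: RegionSummary) -> float:
    """Cohen's *d* between the host and prophage depth distributions."""
    return cohens_d(host.mean_depth, host.sd_depth, prophage.mean_depth, prophage.sd_depth)
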