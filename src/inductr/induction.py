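"""Induction calling from binned coverage over predicted prophage regions.

A prophage that switches to lytic replication multiplies its copy number and
therefore its read coverage relative to the host chromosome. Three statistics
quantify that excess per region and sample:

* the average modified z-score of the region's bins against the host
  background, ``mean(0.6745 * (x_p - med(x_h)) / MAD(x_h))``;
* Cohen's d between host and phage bin depths,
  ``(mean(x_h) - mean(x_p)) / sqrt((s_h^2 + s_p^2) / 2)`` (negative when the
  region is elevated; the decision rule uses the magnitude);
* the coverage fold change, mean phage depth over the robust host baseline
  (median by default).

A region is called induced when the average modified z-score reaches 3.5, or
when coverage is at least twofold with |d| above 0.7. Called regions are then
boundary-refined by trimming flanking bins below 25% of the region's mean
coverage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from inductr.coverage import BinnedCoverage
from inductr.regions import ProphageRegion

#: MAD-to-sigma consistency constant for the modified z-score.
MAD_SCALE = 0.6745

#: Published minimum protein lengths (aa) for Caudoviricetes hallmark genes.
DEFAULT_HALLMARK_CUTOFFS: dict[str, float] = {
    "terminase_large": 265,
    "portal": 245,
    "major_head": 186,
}


@dataclass(frozen=True)
class InductionStatistics:
    """Per-region, per-sample induction evidence."""

    region_id: str
    sample_id: str = ""
    z_ave: float = math.nan
    cohens_d: float = math.nan
    fold_change: float = math.nan
    induced: bool = False


@dataclass(frozen=True)
class HallmarkHit:
    """A profile-search hit of a viral hallmark gene on a contig."""

    contig_id: str
    gene: str
    protein_length: float
    evalue: float = math.nan

    def __post_init__(self) -> None:
        if self.protein_length <= 0:
            raise ValueError("protein_length must be positive")


def zscore_ave(coverage: BinnedCoverage, region_id: str) -> float:
    """Average modified z-score of a region's bins against the host bins.

    Returns NaN when the host MAD is zero (flat background, statistic
    undefined); the decision then falls to the fold-change/Cohen's d clause.
    """
    x_p = coverage.region_depths(region_id)
    x_h = coverage.host_depths()
    if x_h.size < 2:
        raise ValueError("need at least 2 host bins to form a null")
    if x_p.size < 1:
        raise ValueError(f"region {region_id!r} maps to no bins")
    med = np.median(x_h)
    mad = np.median(np.abs(x_h - med))
    if mad == 0:
        return math.nan
    return float(np.mean(MAD_SCALE * (x_p - med) / mad))


def cohens_d(coverage: BinnedCoverage, region_id: str) -> float:
    """Signed Cohen's d of host versus phage bin depths.

    Pooled-SD form with sample standard deviations (ddof=1); negative for
    regions elevated over the host. NaN when both sides are constant.
    """
    x_p = coverage.region_depths(region_id)
    x_h = coverage.host_depths()
    if x_p.size < 2 or x_h.size < 2:
        raise ValueError("Cohen's d needs >= 2 bins on each side")
    s_h = np.std(x_h, ddof=1)
    s_p = np.std(x_p, ddof=1)
    pooled = math.sqrt((s_h**2 + s_p**2) / 2)
    if pooled == 0:
        return math.nan
    return float((np.mean(x_h) - np.mean(x_p)) / pooled)


def fold_change(
    coverage: BinnedCoverage, region_id: str, baseline: str = "median"
) -> float:
    """Mean phage bin depth over the host baseline (median by default).

    The median baseline is robust to other induced regions elsewhere on the
    genome; ``baseline='mean'`` is available. NaN when the baseline is zero.
    """
    x_p = coverage.region_depths(region_id)
    x_h = coverage.host_depths()
    if x_p.size < 1 or x_h.size < 1:
        raise ValueError("fold change needs phage and host bins")
    if baseline == "median":
        base = float(np.median(x_h))
    elif baseline == "mean":
        base = float(np.mean(x_h))
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    if base == 0:
        return math.nan
    return float(np.mean(x_p) / base)


def call_induction(
    stats: InductionStatistics,
    z_min: float = 3.5,
    fold_min: float = 2.0,
    d_min: float = 0.7,
) -> bool:
    """Retention rule: z_ave >= 3.5, or fold >= 2 with |d| > 0.7.

    An undefined (NaN) component fails only its own clause; NaN never
    satisfies a comparison, so the clauses degrade independently.
    """
    z_clause = stats.z_ave >= z_min
    fold_clause = stats.fold_change >= fold_min and abs(stats.cohens_d) > d_min
    return bool(z_clause or fold_clause)


def region_statistics(
    coverage: BinnedCoverage,
    region_id: str,
    sample_id: str = "",
    z_min: float = 3.5,
    fold_min: float = 2.0,
    d_min: float = 0.7,
    baseline: str = "median",
) -> InductionStatistics:
    """Compute all three statistics for one region and apply the call rule."""
    stats = InductionStatistics(
        region_id=region_id,
        sample_id=sample_id,
        z_ave=zscore_ave(coverage, region_id),
        cohens_d=cohens_d(coverage, region_id),
        fold_change=fold_change(coverage, region_id, baseline=baseline),
    )
    return replace(
        stats, induced=call_induction(stats, z_min=z_min, fold_min=fold_min, d_min=d_min)
    )


def refine_boundaries(
    coverage: BinnedCoverage,
    region: ProphageRegion,
    min_frac: float = 0.25,
) -> ProphageRegion | None:
    """Trim flanking bins with depth below ``min_frac`` of the region mean.

    The threshold is computed once from the initial region's bins and is not
    recomputed while trimming. Only flanking bins are removed — interior dips
    survive. Returns ``None`` if every bin is trimmed; the result never
    extends past the input region.
    """
    first = region.start // coverage.bin_size
    last = (region.end - 1) // coverage.bin_size
    bins = coverage.depths[first : last + 1]
    if bins.size == 0:
        raise ValueError("region maps to no bins")
    threshold = min_frac * float(np.mean(bins))
    lo, hi = 0, bins.size - 1
    while lo <= hi and bins[lo] < threshold:
        lo += 1
    while hi >= lo and bins[hi] < threshold:
        hi -= 1
    if lo > hi:
        return None
    new_start = max(region.start, (first + lo) * coverage.bin_size)
    new_end = min(region.end, (first + hi + 1) * coverage.bin_size)
    return replace(region, start=new_start, end=new_end)


def derive_length_cutoff(lengths: list[float]) -> float:
    """Hallmark length cut-off: half the mean of the middle 80% of lengths.

    Values below the 10th or above the 90th percentile (linear-interpolation
    convention) are dropped before averaging. Guards against fragmented
    profile hits being counted as hallmark genes.
    """
    arr = np.asarray(lengths, dtype=float)
    if arr.size < 5:
        raise ValueError("need at least 5 lengths to derive a cut-off")
    lo, hi = np.percentile(arr, [10, 90])
    middle = arr[(arr >= lo) & (arr <= hi)]
    if middle.size == 0:
        raise ValueError("no lengths remain inside the middle 80%")
    return 0.5 * float(np.mean(middle))


def filter_hallmarks(
    hits: list[HallmarkHit],
    cutoffs: dict[str, float] | None = None,
) -> set[str]:
    """Contigs retained as genuine phage: >= 1 hallmark hit above its cut-off.

    Hits of unknown gene classes are ignored with a warning.
    """
    cutoffs = DEFAULT_HALLMARK_CUTOFFS if cutoffs is None else cutoffs
    retained: set[str] = set()
    for hit in hits:
        cutoff = cutoffs.get(hit.gene)
        if cutoff is None:
            warnings.warn(
                f"hallmark class {hit.gene!r} has no cut-off; hit ignored",
                stacklevel=2,
            )
            continue
        if hit.protein_length >= cutoff:
            retained.add(hit.contig_id)
    return retained
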