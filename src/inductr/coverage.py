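"""Binned read-depth tracks over bacterial contigs.

A :class:`BinnedCoverage` tiles a contig into fixed-size bins (default
100 bp) holding the mean per-base depth of each bin, plus a per-bin label
separating host background bins from bins inside predicted prophage regions.
The last bin may be partial and carries the per-base mean over its actual
span, so it participates in every statistic on equal terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from inductr.regions import ProphageRegion

HOST_LABEL = "host"


@dataclass
class BinnedCoverage:
    contig_id: str
    bin_size: int
    contig_length: int
    depths: np.ndarray  # mean per-base depth per bin, float
    labels: np.ndarray | None = None  # "host" or a region_id per bin

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if np.any(self.depths < 0):
            raise ValueError("depths must be non-negative")
        n_bins = -(-self.contig_length // self.bin_size)
        if len(self.depths) != n_bins:
            raise ValueError(
                f"{len(self.depths)} bins do not tile a {self.contig_length} bp "
                f"contig at bin size {self.bin_size} (expected {n_bins})"
            )
        if self.labels is None:
            self.labels = np.full(len(self.depths), HOST_LABEL, dtype=object)
        else:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != len(self.depths):
                raise ValueError("labels and depths must have equal length")

    @property
    def n_bins(self) -> int:
        return len(self.depths)

    def bin_span(self, i: int) -> tuple[int, int]:
        """Half-open bp interval covered by bin *i*."""
        return i * self.bin_size, min((i + 1) * self.bin_size, self.contig_length)

    def host_depths(self) -> np.ndarray:
        return self.depths[self.labels == HOST_LABEL]

    def region_depths(self, region_id: str) -> np.ndarray:
        return self.depths[self.labels == region_id]

    def region_bin_indices(self, region_id: str) -> np.ndarray:
        return np.flatnonzero(self.labels == region_id)


def bin_depth(
    depth_table: pd.DataFrame,
    bin_size: int = 100,
    contig_length: int | None = None,
) -> dict[str, BinnedCoverage]:
    """Bin a per-base depth table (samtools-depth dialect) into mean depths.

    Parameters
    ----------
    depth_table
        Columns ``contig``, ``pos`` (1-based), ``depth``; sorted by contig
        then position, no duplicated positions. Absent positions count as
        depth 0.
    bin_size
        Bin width in bp.
    contig_length
        Length of every contig; if ``None`` the highest reported position of
        each contig is taken as its length.

    Returns
    -------
    dict mapping contig id to its :class:`BinnedCoverage`.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    required = {"contig", "pos", "depth"}
    if not required.issubset(depth_table.columns):
        raise ValueError(f"depth table needs columns {sorted(required)}")

    out: dict[str, BinnedCoverage] = {}
    for contig, sub in depth_table.groupby("contig", sort=False):
        pos = sub["pos"].to_numpy(dtype=np.int64)
        dep = sub["depth"].to_numpy(dtype=float)
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"depth table for {contig!r} unsorted or duplicated")
        if pos[0] < 1:
            raise ValueError("positions are 1-based; found position < 1")
        length = int(contig_length if contig_length is not None else pos[-1])
        if pos[-1] > length:
            raise ValueError(f"position {pos[-1]} beyond contig length {length}")
        n_bins = -(-length // bin_size)
        sums = np.zeros(n_bins)
        np.add.at(sums, (pos - 1) // bin_size, dep)
        spans = np.full(n_bins, bin_size, dtype=float)
        spans[-1] = length - (n_bins - 1) * bin_size
        out[str(contig)] = BinnedCoverage(
            contig_id=str(contig),
            bin_size=bin_size,
            contig_length=length,
            depths=sums / spans,
        )
    return out


def mask_regions(
    coverage: BinnedCoverage, regions: list[ProphageRegion]
) -> BinnedCoverage:
    """Label bins overlapping any prophage region as phage bins.

    A bin overlapping a region by >= 1 bp takes that region's label; host
    bins are all bins inside no region, so region statistics never use other
    candidate regions as background. Returns a new track.
    """
    labels = np.full(coverage.n_bins, HOST_LABEL, dtype=object)
    for idx, r in enumerate(regions):
        if r.contig_id != coverage.contig_id:
            continue
        if r.end > coverage.contig_length:
            raise ValueError(
                f"region {r.region_id or idx} [{r.start},{r.end}) exceeds contig "
                f"length {coverage.contig_length}"
            )
        rid = r.region_id or f"region_{idx}"
        first = r.start // coverage.bin_size
        last = (r.end - 1) // coverage.bin_size  # inclusive bin index
        labels[first : last + 1] = rid
    return BinnedCoverage(
        contig_id=coverage.contig_id,
        bin_size=coverage.bin_size,
        contig_length=coverage.contig_length,
        depths=coverage.depths.copy(),
        labels=labels,
    )
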