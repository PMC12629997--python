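"""Comparative genomics of induced versus non-induced prophages.

Two analyses: (1) functional gene-category enrichment between an induced
set and a comparison (high- or low-completeness predicted) set — per-category
two-sided Fisher's exact tests with Hochberg adjustment, reported alongside
the percent frequency change 100 * (f_cry - f_in) / f_in; and (2) gap-event
calling between high-similarity prophage pairs from their alignment blocks:
a syntenic inter-block stretch with >= 50 bp unaligned sequence on *both*
genomes is a homologous-gene-transfer (replacement) signature, a stretch
with >= 50 bp on exactly one genome is an insertion-deletion event, and
spans involving either sequence end are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, ranksums
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class GapEvent:
    """An unaligned stretch between adjacent syntenic alignment blocks."""

    pair_id: str
    type: str  # "HGT" or "indel"
    a_start: int  # 0-based half-open, genome A
    a_end: int
    b_start: int
    b_end: int

    @property
    def size_a(self) -> int:
        return self.a_end - self.a_start

    @property
    def size_b(self) -> int:
        return self.b_end - self.b_start


def frequency_change(f_in: float, f_cry: float) -> float:
    """Percent change of a category's frequency from the induced set.

    NaN when f_in is 0 (undefined, reported but excluded from testing).
    """
    if not (0 <= f_in <= 1 and 0 <= f_cry <= 1):
        raise ValueError("frequencies must be in [0, 1]")
    if f_in == 0:
        return math.nan
    return 100.0 * (f_cry - f_in) / f_in


def category_frequencies(
    annotations: pd.DataFrame, mode: str = "total"
) -> tuple[pd.Series, int]:
    """Category frequencies in one prophage set.

    ``annotations`` has columns (genome, gene_id, category). Mode ``total``
    counts genes per category over all annotated genes; mode ``presence``
    counts genomes containing the category over all genomes. Returns the
    per-category counts and the denominator.
    """
    if mode == "total":
        counts = annotations.groupby("category")["gene_id"].count()
        denom = len(annotations)
    elif mode == "presence":
        counts = annotations.groupby("category")["genome"].nunique()
        denom = annotations["genome"].nunique()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return counts, denom


def category_enrichment(
    annotations_in: pd.DataFrame,
    annotations_cry: pd.DataFrame,
    mode: str = "total",
) -> pd.DataFrame:
    """Per-category Fisher tests between induced and comparison sets.

    For each category a 2x2 table (in-category vs rest, induced set vs
    comparison set) is tested two-sided; p-values are Hochberg-adjusted
    across categories. Zero-margin tables give p = 1 and are flagged. The
    percent frequency change is attached per category.
    """
    if annotations_in.empty or annotations_cry.empty:
        raise ValueError("both annotation sets must be non-empty")
    c_in, n_in = category_frequencies(annotations_in, mode)
    c_cry, n_cry = category_frequencies(annotations_cry, mode)
    categories = sorted(set(c_in.index) | set(c_cry.index))
    rows = []
    for cat in categories:
        a = int(c_in.get(cat, 0))
        b = int(c_cry.get(cat, 0))
        table = np.array([[a, n_in - a], [b, n_cry - b]])
        degenerate = (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()
        p = 1.0 if degenerate else float(fisher_exact(table, alternative="two-sided")[1])
        rows.append(
            dict(
                category=cat,
                count_induced=a,
                count_comparison=b,
                f_in=a / n_in,
                f_cry=b / n_cry,
                frequency_change_pct=frequency_change(a / n_in, b / n_cry),
                p_value=p,
                degenerate=degenerate,
            )
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p_value"], method="simes-hochberg")[1]
    return out


def call_gap_events(
    blocks: pd.DataFrame,
    len_a: int,
    len_b: int,
    min_gap: int = 50,
    pair_id: str = "",
) -> list[GapEvent]:
    """Call HGT and indel events between adjacent alignment blocks.

    ``blocks`` holds 1-based inclusive coordinates (BLAST tabular). Blocks
    are ordered by query coordinate and must be collinear (subject
    coordinates also increasing) and non-overlapping; rearranged or
    overlapping pairs are rejected. Between each pair of adjacent blocks the
    unaligned span on A and on B is measured: both >= ``min_gap`` -> one HGT
    event, exactly one >= ``min_gap`` -> one indel event. Spans before the
    first or after the last block touch a sequence end and are never called.
    """
    if blocks.empty:
        return []
    df = blocks.sort_values("qstart").reset_index(drop=True)
    q0 = df["qstart"].to_numpy(np.int64) - 1
    q1 = df["qend"].to_numpy(np.int64)  # half-open
    s0 = df["sstart"].to_numpy(np.int64) - 1
    s1 = df["send"].to_numpy(np.int64)
    if np.any(np.diff(s0) < 0):
        raise ValueError("non-collinear block set (subject order violated)")
    if np.any(q0[1:] < q1[:-1]) or np.any(s0[1:] < s1[:-1]):
        raise ValueError("overlapping alignment blocks")
    if q1[-1] > len_a or s1[-1] > len_b:
        raise ValueError("blocks extend past genome lengths")
    events: list[GapEvent] = []
    for i in range(len(df) - 1):
        gap_a = int(q0[i + 1] - q1[i])
        gap_b = int(s0[i + 1] - s1[i])
        if gap_a >= min_gap and gap_b >= min_gap:
            etype = "HGT"
        elif gap_a >= min_gap or gap_b >= min_gap:
            etype = "indel"
        else:
            continue
        events.append(
            GapEvent(
                pair_id=pair_id,
                type=etype,
                a_start=int(q1[i]),
                a_end=int(q0[i + 1]),
                b_start=int(s1[i]),
                b_end=int(s0[i + 1]),
            )
        )
    return events


def compare_event_counts(
    events_by_pair: dict[str, list[GapEvent]],
) -> pd.DataFrame:
    """Per-pair event tallies for downstream rank-sum comparison."""
    rows = []
    for pair, events in events_by_pair.items():
        n_hgt = sum(1 for e in events if e.type == "HGT")
        n_indel = sum(1 for e in events if e.type == "indel")
        rows.append(dict(pair_id=pair, n_hgt=n_hgt, n_indel=n_indel, n_total=n_hgt + n_indel))
    return pd.DataFrame(rows, columns=["pair_id", "n_hgt", "n_indel", "n_total"])


def event_count_test(counts_a: list[int], counts_b: list[int]) -> tuple[float, float]:
    """Two-sided rank-sum comparison of per-pair event totals."""
    stat, p = ranksums(counts_a, counts_b)
    return float(stat), float(p)
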