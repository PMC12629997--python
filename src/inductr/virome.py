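"""Fractional abundance and prevalence of phages across viromes.

Fractional abundance of a genome in a virome is its read count normalized
by genome length and by total virome reads scaled to a 50,000-read
convention:

    raw = (reads_genome / length_genome) / (total_reads_virome / 50000)

Per virome the raw values are renormalized to sum to 1. A genome counts as
present in a virome when reads cover at least 70% of its length; prevalence
is the fraction of viromes in which it is present.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

READ_SCALE = 50_000.0


def fractional_abundance(
    mapping: pd.DataFrame, scale: float = READ_SCALE
) -> pd.DataFrame:
    """Raw and sum-to-1-normalized fractional abundances per virome.

    ``mapping`` has columns (virome, genome, reads, length, total_reads).
    Genomes with zero reads get normalized abundance 0; if every genome in
    a virome has zero reads its normalized values are NaN.
    """
    df = mapping.copy()
    if (df["total_reads"] <= 0).any():
        raise ValueError("total_reads must be positive")
    if (df["length"] <= 0).any():
        raise ValueError("genome lengths must be positive")
    df["raw"] = (df["reads"] / df["length"]) / (df["total_reads"] / scale)
    sums = df.groupby("virome")["raw"].transform("sum")
    df["normalized"] = np.where(sums > 0, df["raw"] / sums, np.nan)
    return df


def prevalence(
    mapping: pd.DataFrame, breadth_min: float = 0.70
) -> pd.DataFrame:
    """Detection count and frequency per genome across viromes.

    A genome absent from a virome's rows has breadth 0 and is absent.
    Frequency is detections divided by the number of distinct viromes.
    """
    n_viromes = mapping["virome"].nunique()
    present = mapping[mapping["breadth"] >= breadth_min]
    counts = present.groupby("genome").size()
    genomes = mapping["genome"].unique()
    out = pd.DataFrame(
        {
            "genome": genomes,
            "detections": [int(counts.get(g, 0)) for g in genomes],
        }
    )
    out["frequency"] = out["detections"] / n_viromes
    return out
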