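"""Study-level tallies from per-sample induction calls.

The induction ledger is a tidy table with one row per tested
(isolate, region, condition) triple: columns ``isolate_id``, ``phylum``,
``region_id``, ``species_cluster``, ``condition``, ``induced`` (bool) and
``quality`` ("high"/"low" from the prediction's completeness). The
operations here aggregate it into the headline quantities of an induction
screen: induced fractions at the isolate, prediction and species level,
per-condition counts with overlap against the standard-medium control, and
polylysogeny statistics.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

LEDGER_COLUMNS = [
    "isolate_id",
    "phylum",
    "region_id",
    "species_cluster",
    "condition",
    "induced",
    "quality",
]


def percent_half_up(numerator: int, denominator: int) -> int:
    """Integer percent with ties rounded half-up (so 31.5 -> 32)."""
    if denominator == 0:
        raise ValueError("empty denominator")
    return int(
        (Decimal(100 * numerator) / Decimal(denominator)).quantize(
            Decimal("1"), rounding=ROUND_HALF_UP
        )
    )


def _dedupe(ledger: pd.DataFrame) -> pd.DataFrame:
    return ledger.drop_duplicates(subset=["isolate_id", "region_id", "condition"])


def summarize_induction(
    ledger: pd.DataFrame, level: str = "prediction"
) -> tuple[int, int, int]:
    """Induced fraction at a given aggregation level.

    * ``isolate`` — isolates with >= 1 induced region over all isolates;
    * ``prediction`` — high-quality regions induced in >= 1 condition over
      all high-quality regions;
    * ``species`` — species clusters (of high-quality regions) with >= 1
      induced member over all such clusters.

    Returns (numerator, denominator, integer percent, half-up rounded).
    """
    df = _dedupe(ledger)
    if level == "isolate":
        denom = df["isolate_id"].nunique()
        num = df.loc[df["induced"], "isolate_id"].nunique()
    elif level == "prediction":
        hq = df[df["quality"] == "high"]
        denom = hq["region_id"].nunique()
        num = hq.loc[hq["induced"], "region_id"].nunique()
    elif level == "species":
        hq = df[df["quality"] == "high"]
        denom = hq["species_cluster"].nunique()
        num = hq.loc[hq["induced"], "species_cluster"].nunique()
    else:
        raise ValueError(f"unknown level {level!r}")
    return num, denom, percent_half_up(num, denom)


def condition_overlap(
    ledger: pd.DataFrame,
    standard_condition: str = "standard",
    conditions: list[str] | None = None,
) -> pd.DataFrame:
    """Per-condition induced counts and overlap with the standard medium.

    Overlap counts regions induced both in the condition and in the
    standard-medium control (spontaneous induction). If ``conditions`` is
    given it is the allowed vocabulary; unknown labels raise.
    """
    df = _dedupe(ledger)
    if conditions is not None:
        unknown = set(df["condition"]) - set(conditions)
        if unknown:
            raise ValueError(f"unknown condition labels: {sorted(unknown)}")
    induced = df[df["induced"]]
    by_condition = induced.groupby("condition")["region_id"].agg(set)
    standard = by_condition.get(standard_condition, set())
    rows = [
        dict(
            condition=cond,
            n_induced=len(regions),
            overlap_with_standard=len(regions & standard)
            if cond != standard_condition
            else len(regions),
        )
        for cond, regions in by_condition.items()
    ]
    return pd.DataFrame(rows, columns=["condition", "n_induced", "overlap_with_standard"])


def polylysogeny_table(
    ledger: pd.DataFrame, focal_phylum: str = "Bacteroidota"
) -> dict:
    """Polylysogeny statistics over isolates with >= 1 induced prophage.

    A lysogen here is an isolate with at least one experimentally induced
    prophage; a polylysogen has two or more. Returns the per-isolate
    inducible-prophage counts, the 2x2 (focal phylum vs rest) x (single vs
    poly) contingency, and per-prophage (prophages-in-isolate,
    conditions-induced) pairs for downstream rank correlation.
    """
    df = _dedupe(ledger)
    induced = df[df["induced"]]
    per_isolate = (
        induced.groupby("isolate_id")
        .agg(
            n_induced_prophages=("region_id", "nunique"),
            phylum=("phylum", "first"),
        )
        .reset_index()
    )
    per_isolate["polylysogen"] = per_isolate["n_induced_prophages"] >= 2
    focal = per_isolate["phylum"] == focal_phylum
    contingency = [
        [
            int((focal & per_isolate["polylysogen"]).sum()),
            int((focal & ~per_isolate["polylysogen"]).sum()),
        ],
        [
            int((~focal & per_isolate["polylysogen"]).sum()),
            int((~focal & ~per_isolate["polylysogen"]).sum()),
        ],
    ]
    counts = per_isolate.set_index("isolate_id")["n_induced_prophages"]
    per_prophage = (
        induced.groupby(["isolate_id", "region_id"])["condition"]
        .nunique()
        .reset_index(name="n_conditions_induced")
    )
    per_prophage["n_prophages_in_isolate"] = per_prophage["isolate_id"].map(counts)
    return dict(
        per_isolate=per_isolate,
        contingency=contingency,
        per_prophage=per_prophage[
            ["isolate_id", "region_id", "n_prophages_in_isolate", "n_conditions_induced"]
        ],
    )
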