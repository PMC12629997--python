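"""Community-scale induction calling from mapping and k-mer reports.

Within a defined bacterial community, an induced prophage shows up as a
free phage genome whose read coverage (or unique-k-mer duplicity) rises
clearly above its host chromosome's. Two callers implement that logic over
per-replicate report tables:

* the read-mapping rule — a prophage species is induced if at least one
  member genome is covered over >= 85% of its length at >= twice the host's
  length-normalized mean depth in >= 3 of 5 replicates;
* the k-mer rule — a prophage is induced if its k-mer duplicity is >= twice
  the host's length-normalized duplicity (host detected), or simply if it is
  detected (host undetected), again in >= 3 of 5 replicates.

Detection itself uses fixed report thresholds: phage — 0.25 k-mer coverage,
10 reads, 100 unique k-mers; host — 10 reads, 18,000 unique k-mers.
Unique k-mers (k = 21, canonical over strands) are counted against the whole
genome database, so near-identical genomes shadow each other.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Mapping

import numpy as np
import pandas as pd

PHAGE_KMER_COVERAGE_MIN = 0.25
PHAGE_READS_MIN = 10
PHAGE_UNIQUE_KMERS_MIN = 100
HOST_READS_MIN = 10
HOST_UNIQUE_KMERS_MIN = 18_000

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _canonical_kmers(sequence: str, k: int) -> set[str]:
    seq = sequence.upper()
    out: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        rc = kmer.translate(_COMPLEMENT)[::-1]
        out.add(min(kmer, rc))
    return out


def count_unique_kmers(
    genomes: Mapping[str, str], k: int = 21
) -> dict[str, int]:
    """Per-genome counts of canonical k-mers unique within the database.

    A k-mer counts for a genome only if its canonical form (lexicographic
    minimum of the k-mer and its reverse complement) occurs in no other
    genome of ``genomes``. Windows containing N are skipped; sequences
    shorter than k contribute nothing.
    """
    if k < 3 or k % 2 == 0:
        raise ValueError("k must be odd and >= 3")
    per_genome = {name: _canonical_kmers(seq, k) for name, seq in genomes.items()}
    occupancy: Counter[str] = Counter()
    for kmers in per_genome.values():
        occupancy.update(kmers)
    return {
        name: sum(1 for km in kmers if occupancy[km] == 1)
        for name, kmers in per_genome.items()
    }


def detect_genome(row: Mapping, kind: str) -> bool:
    """Detection call for one report row, per the fixed report thresholds."""
    if kind == "phage":
        return (
            row["kmer_coverage"] >= PHAGE_KMER_COVERAGE_MIN
            and row["reads"] >= PHAGE_READS_MIN
            and row["unique_kmers"] >= PHAGE_UNIQUE_KMERS_MIN
        )
    if kind == "host":
        return row["reads"] >= HOST_READS_MIN and row["unique_kmers"] >= HOST_UNIQUE_KMERS_MIN
    raise ValueError(f"unknown kind {kind!r}")


def _host_weighted(report: pd.DataFrame, column: str) -> pd.Series:
    """Length-normalized host statistic per (replicate, host_id)."""
    hosts = report[report["kind"] == "host"]
    def agg(sub: pd.DataFrame) -> float:
        return float(np.average(sub[column], weights=sub["length"]))
    return hosts.groupby(["replicate", "host_id"]).apply(agg, include_groups=False)


def call_readmap_induction(
    report: pd.DataFrame,
    species_clusters: Mapping[str, str] | None = None,
    breadth_min: float = 0.85,
    fold_min: float = 2.0,
    quorum: int = 3,
) -> pd.DataFrame:
    """Read-mapping induction rule over replicate mapping reports.

    A phage genome passes a replicate if breadth >= ``breadth_min`` and its
    mean depth is >= ``fold_min`` times the host's length-weighted mean
    depth (host absent from the replicate -> the replicate fails). A genome
    is induced when it passes in >= ``quorum`` replicates, and a species is
    induced when at least one member genome does so — passes are not pooled
    across members. Returns a per-genome table with the per-replicate pass
    count and the induced flag (plus the species call if clusters given).
    """
    host_depth = _host_weighted(report, "mean_depth")
    phages = report[report["kind"] == "phage"]
    rows = []
    for genome, sub in phages.groupby("genome_id"):
        passes = 0
        for _, r in sub.iterrows():
            key = (r["replicate"], r["host_id"])
            if key not in host_depth.index:
                continue  # fold undefined, replicate fails
            base = host_depth.loc[key]
            if base > 0 and r["breadth"] >= breadth_min and r["mean_depth"] >= fold_min * base:
                passes += 1
        rows.append(dict(genome_id=genome, replicates_passed=passes, induced=passes >= quorum))
    calls = pd.DataFrame(rows)
    if species_clusters is not None and not calls.empty:
        calls["species"] = calls["genome_id"].map(species_clusters)
        induced_species = set(calls.loc[calls["induced"], "species"].dropna())
        calls["species_induced"] = calls["species"].isin(induced_species)
    return calls


def call_kmer_induction(
    report: pd.DataFrame,
    fold_min: float = 2.0,
    quorum: int = 3,
) -> pd.DataFrame:
    """K-mer duplicity induction rule over replicate classification reports.

    Host detection aggregates the host's contigs per replicate (reads and
    unique k-mers summed, duplicity length-weighted). When the host is
    detected, a replicate counts iff the phage is detected and its duplicity
    is >= ``fold_min`` times the host duplicity; when the host is
    undetected, the replicate counts iff the phage is detected (the
    undetected-isolate clause). >= ``quorum`` counting replicates -> induced.
    """
    hosts = report[report["kind"] == "host"]
    host_stats = hosts.groupby(["replicate", "host_id"]).apply(
        lambda sub: pd.Series(
            dict(
                reads=sub["reads"].sum(),
                unique_kmers=sub["unique_kmers"].sum(),
                duplicity=float(np.average(sub["duplicity"], weights=sub["length"])),
            )
        ),
        include_groups=False,
    )
    phages = report[report["kind"] == "phage"]
    rows = []
    for genome, sub in phages.groupby("genome_id"):
        counting = 0
        for _, r in sub.iterrows():
            if not detect_genome(r, "phage"):
                continue
            key = (r["replicate"], r["host_id"])
            if key in host_stats.index and detect_genome(host_stats.loc[key], "host"):
                if r["duplicity"] >= fold_min * host_stats.loc[key, "duplicity"]:
                    counting += 1
            else:
                counting += 1  # undetected isolate: detection alone counts
        rows.append(dict(genome_id=genome, replicates_passed=counting, induced=counting >= quorum))
    return pd.DataFrame(rows)
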