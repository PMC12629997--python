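"""Synthetic lysogens, coverage tracks, community reports and alignments.

Every input the pipeline consumes can be generated here with known ground
truth: host genomes with embedded prophages, per-bin depth tracks with
negative-binomial noise and a controlled induction fold-enrichment,
per-replicate community detection reports, and pairwise alignment-block
fixtures with planted gap events. Identical seeds yield identical output.

The noise model is a negative binomial on per-bin depth (Poisson in the
infinite-dispersion limit): bacterial sequencing depth is overdispersed
relative to Poisson, and a single dispersion parameter is the standard way
to emulate that without simulating reads. Sequence composition is i.i.d.
with a specified GC fraction; repeats and mapping artefacts are out of
scope, since the pipeline's contract starts at depth tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from inductr.coverage import BinnedCoverage, mask_regions
from inductr.regions import ProphageRegion


@dataclass(frozen=True)
class LysogenSpec:
    """A host genome with prophages embedded at fixed host offsets."""

    host_length: int
    prophage_inserts: tuple[tuple[int, int, str], ...] = ()
    gc: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.host_length <= 0:
            raise ValueError("host_length must be positive")
        if not 0 <= self.gc <= 1:
            raise ValueError("gc must be in [0, 1]")
        prev = -1
        for pos, length, _label in self.prophage_inserts:
            if length <= 0:
                raise ValueError("prophage length must be positive")
            if not 0 <= pos <= self.host_length:
                raise ValueError(f"insert position {pos} outside host")
            if pos <= prev:
                raise ValueError("overlapping inserts: positions must strictly increase")
            prev = pos


@dataclass(frozen=True)
class CoverageSimSpec:
    """Parameters of the per-bin depth simulator."""

    base_depth: float = 30.0
    induction_fold: float = 1.0
    dispersion: float = 10.0
    bin_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_depth <= 0:
            raise ValueError("base_depth must be positive")
        if self.induction_fold < 0:
            raise ValueError("induction_fold must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")


_BASES = np.array(list("ACGT"))


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def gen_lysogen(spec: LysogenSpec) -> tuple[str, list[ProphageRegion]]:
    """Generate a lysogen genome and the truth table of its prophages.

    Inserts are given as offsets into the *host* sequence; each earlier
    insert shifts later coordinates by its own length, and the truth table
    records the exact half-open coordinates in the final genome.
    """
    rng = np.random.default_rng(spec.seed)
    host = _random_sequence(rng, spec.host_length, spec.gc)
    pieces: list[str] = []
    truth: list[ProphageRegion] = []
    cursor = 0
    offset = 0
    for pos, length, label in spec.prophage_inserts:
        pieces.append(host[cursor:pos])
        phage = _random_sequence(rng, length, spec.gc)
        pieces.append(phage)
        truth.append(
            ProphageRegion(
                contig_id="lysogen",
                start=pos + offset,
                end=pos + offset + length,
                region_id=label,
                source="synthetic",
            )
        )
        offset += length
        cursor = pos
    pieces.append(host[cursor:])
    return "".join(pieces), truth


def simulate_coverage(
    genome_length: int,
    truth: list[ProphageRegion],
    sim: CoverageSimSpec,
) -> BinnedCoverage:
    """Simulate a binned depth track with elevated coverage inside prophages.

    Per-bin depth ~ NegativeBinomial(mean = base_depth, dispersion r), with
    mean multiplied by ``induction_fold`` inside truth regions; a bin
    overlapping a region by >= 1 bp counts as a phage bin. ``dispersion`` of
    ``inf`` gives the Poisson limit. The final partial bin is drawn the same
    way (its per-base mean is unchanged by its shorter span).
    """
    rng = np.random.default_rng(sim.seed)
    n_bins = -(-genome_length // sim.bin_size)
    track = BinnedCoverage(
        contig_id=truth[0].contig_id if truth else "contig",
        bin_size=sim.bin_size,
        contig_length=genome_length,
        depths=np.zeros(n_bins),
    )
    track = mask_regions(track, truth)
    means = np.where(
        track.labels == "host",
        sim.base_depth,
        sim.base_depth * sim.induction_fold,
    ).astype(float)
    track.depths = _nb_draw(rng, means, sim.dispersion)
    return track


def _nb_draw(
    rng: np.random.Generator, means: np.ndarray, dispersion: float
) -> np.ndarray:
    out = np.zeros_like(means)
    pos = means > 0
    if np.isinf(dispersion):
        out[pos] = rng.poisson(means[pos])
    else:
        p = dispersion / (dispersion + means[pos])
        out[pos] = rng.negative_binomial(dispersion, p)
    return out.astype(float)


def simulate_community_report(
    n_genomes: int,
    induced_truth: set[str] | None = None,
    n_replicates: int = 5,
    seed: int = 0,
    pass_prob: float = 1.0,
    n_host_contigs: int = 2,
) -> pd.DataFrame:
    """Per-replicate community detection report with known induced phages.

    One bacterial host (split over ``n_host_contigs`` contigs) plus one
    prophage row per genome ``g0..g{n-1}``; prophage ids carry a ``_phage``
    suffix. Induced prophages draw breadth, depth and k-mer duplicity well
    above the detection and twofold-over-host thresholds in each replicate
    with probability ``pass_prob``; non-induced prophages draw well below.
    Hosts are always comfortably detected.
    """
    induced_truth = induced_truth or set()
    rng = np.random.default_rng(seed)
    genomes = [f"g{i}" for i in range(n_genomes)]
    unknown = induced_truth - {f"{g}_phage" for g in genomes} - set(genomes)
    if unknown:
        raise ValueError(f"induced_truth not in community: {sorted(unknown)}")
    rows = []
    for rep in range(1, n_replicates + 1):
        for g in genomes:
            host_depth = rng.uniform(20, 60)
            host_dup = rng.uniform(1.2, 2.0)
            for c in range(n_host_contigs):
                length = int(rng.uniform(1.5e6, 3e6))
                rows.append(
                    dict(
                        replicate=rep,
                        genome_id=g,
                        contig_id=f"{g}_c{c}",
                        kind="host",
                        host_id=g,
                        length=length,
                        reads=int(host_depth * length / 300),
                        breadth=rng.uniform(0.95, 1.0),
                        mean_depth=host_depth * rng.uniform(0.9, 1.1),
                        unique_kmers=int(rng.uniform(3e4, 8e4)),
                        kmer_coverage=rng.uniform(0.6, 0.95),
                        duplicity=host_dup * rng.uniform(0.9, 1.1),
                    )
                )
            phage = f"{g}_phage"
            induced = (phage in induced_truth or g in induced_truth) and (
                rng.random() < pass_prob
            )
            length = int(rng.uniform(3e4, 6e4))
            if induced:
                breadth = rng.uniform(0.92, 1.0)
                depth = host_depth * rng.uniform(4, 10)
                dup = host_dup * rng.uniform(4, 10)
                kcov = rng.uniform(0.6, 0.95)
                reads = int(depth * length / 300)
                kmers = int(rng.uniform(2e3, 1e4))
            else:
                breadth = rng.uniform(0.05, 0.4)
                depth = host_depth * rng.uniform(0.05, 0.4)
                dup = host_dup * rng.uniform(0.2, 0.6)
                kcov = rng.uniform(0.01, 0.1)
                reads = max(0, int(depth * length / 300))
                kmers = int(rng.uniform(0, 50))
            rows.append(
                dict(
                    replicate=rep,
                    genome_id=phage,
                    contig_id=phage,
                    kind="phage",
                    host_id=g,
                    length=length,
                    reads=reads,
                    breadth=breadth,
                    mean_depth=depth,
                    unique_kmers=kmers,
                    kmer_coverage=kcov,
                    duplicity=dup,
                )
            )
    return pd.DataFrame(rows)


def gen_alignment_fixture(
    length: int,
    planted_hgt: list[tuple[int, int]] | None = None,
    planted_indel: list[tuple[int, int]] | None = None,
    seed: int = 0,
    gc: float = 0.45,
) -> tuple[str, str, pd.DataFrame, pd.DataFrame]:
    """Two sequences and their alignment blocks with planted gap events.

    Sequence B is derived from A: each HGT at ``(pos, size)`` replaces
    ``A[pos:pos+size]`` with fresh random sequence (an unaligned stretch of
    equal size on both genomes), and each indel deletes ``A[pos:pos+size]``
    from B (a gap on A only). Events must be >= 50 bp from either end and
    non-overlapping with >= 1 bp between them. Returns (seq A, seq B, block
    table in BLAST tabular coordinates — 1-based inclusive — and the truth
    table of planted events).
    """
    events = [(p, s, "HGT") for p, s in (planted_hgt or [])] + [
        (p, s, "indel") for p, s in (planted_indel or [])
    ]
    events.sort()
    prev_end = 50
    for pos, size, _t in events:
        if size < 50:
            raise ValueError("planted events must be >= 50 bp")
        if pos < prev_end or pos + size > length - 50:
            raise ValueError(
                "planted events must be non-overlapping, separated, and "
                ">= 50 bp from either sequence end"
            )
        prev_end = pos + size + 1
    rng = np.random.default_rng(seed)
    seq_a = _random_sequence(rng, length, gc)
    b_parts: list[str] = []
    blocks = []
    truth = []
    cursor = 0  # position in A
    b_cursor = 0  # position in B
    for pos, size, etype in events:
        seg = seq_a[cursor:pos]
        blocks.append(
            dict(
                qstart=cursor + 1,
                qend=pos,
                sstart=b_cursor + 1,
                send=b_cursor + len(seg),
                pident=100.0,
            )
        )
        b_parts.append(seg)
        b_cursor += len(seg)
        if etype == "HGT":
            replacement = _random_sequence(rng, size, gc)
            truth.append(
                dict(
                    type="HGT",
                    a_start=pos,
                    a_end=pos + size,
                    b_start=b_cursor,
                    b_end=b_cursor + size,
                    size_a=size,
                    size_b=size,
                )
            )
            b_parts.append(replacement)
            b_cursor += size
        else:
            truth.append(
                dict(
                    type="indel",
                    a_start=pos,
                    a_end=pos + size,
                    b_start=b_cursor,
                    b_end=b_cursor,
                    size_a=size,
                    size_b=0,
                )
            )
        cursor = pos + size
    seg = seq_a[cursor:]
    blocks.append(
        dict(
            qstart=cursor + 1,
            qend=length,
            sstart=b_cursor + 1,
            send=b_cursor + len(seg),
            pident=100.0,
        )
    )
    b_parts.append(seg)
    block_df = pd.DataFrame(blocks)
    block_df.insert(0, "qid", "A")
    block_df.insert(1, "sid", "B")
    return seq_a, "".join(b_parts), block_df, pd.DataFrame(
        truth, columns=["type", "a_start", "a_end", "b_start", "b_end", "size_a", "size_b"]
    )
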