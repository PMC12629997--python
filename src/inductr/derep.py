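"""ANI/AF computation from alignment blocks and greedy dereplication.

ANI is the alignment-length-weighted mean identity over the blocks of a
genome pair after resolving overlapping query intervals (longest block
first, later blocks trimmed). AF is the merged aligned span divided by the
shorter genome's length — the anicalc convention. Clustering is greedy
representative-linkage over the length-descending genome order, matching
dRep/anicalc-style dereplication: deterministic, with length ties broken
lexicographically by id.

Thresholds in this pipeline: 99% ANI / 85% AF for dereplicating induced
phage contigs, 95% ANI / 85% AF for species-level grouping and for
selecting induced/non-induced comparison pairs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PairSimilarity:
    query_id: str
    subject_id: str
    ani: float  # %, NaN when no blocks
    af: float  # % of the shorter genome aligned

    def __post_init__(self) -> None:
        if not math.isnan(self.ani) and not 0 <= self.ani <= 100:
            raise ValueError("ANI out of [0, 100]")
        if not 0 <= self.af <= 100:
            raise ValueError("AF out of [0, 100]")


def compute_ani_af(
    blocks: pd.DataFrame,
    len_q: int,
    len_s: int,
    query_id: str = "q",
    subject_id: str = "s",
) -> PairSimilarity:
    """ANI and AF of one genome pair from its local alignment blocks.

    ``blocks`` has 1-based inclusive ``qstart``/``qend`` (orientation
    normalized so qstart <= qend) and ``pident``. Overlaps on the query are
    resolved longest-first with trimming; identity weights use the trimmed
    lengths. An empty block set gives NaN ANI and AF 0.
    """
    if len_q <= 0 or len_s <= 0:
        raise ValueError("genome lengths must be positive")
    if blocks.empty:
        return PairSimilarity(query_id, subject_id, math.nan, 0.0)
    qs = np.minimum(blocks["qstart"], blocks["qend"]).to_numpy(dtype=np.int64)
    qe = np.maximum(blocks["qstart"], blocks["qend"]).to_numpy(dtype=np.int64)
    ident = blocks["pident"].to_numpy(dtype=float)
    order = np.argsort(-(qe - qs + 1), kind="stable")

    claimed: list[tuple[int, int]] = []  # half-open, kept disjoint
    weighted = 0.0
    total = 0
    for i in order:
        pieces = [(int(qs[i]) - 1, int(qe[i]))]
        for cs, ce in claimed:
            nxt = []
            for ps, pe in pieces:
                if pe <= cs or ps >= ce:
                    nxt.append((ps, pe))
                else:
                    if ps < cs:
                        nxt.append((ps, cs))
                    if pe > ce:
                        nxt.append((ce, pe))
            pieces = nxt
            if not pieces:
                break
        for ps, pe in pieces:
            claimed.append((ps, pe))
            weighted += (pe - ps) * ident[i]
            total += pe - ps
    if total == 0:
        return PairSimilarity(query_id, subject_id, math.nan, 0.0)
    af = 100.0 * total / min(len_q, len_s)
    return PairSimilarity(query_id, subject_id, weighted / total, min(af, 100.0))


def cluster_dereplicate(
    pairs: list[PairSimilarity],
    lengths: dict[str, int],
    ani_min: float = 99.0,
    af_min: float = 85.0,
) -> pd.DataFrame:
    """Greedy length-descending clustering at ANI/AF thresholds.

    Each genome, visited longest-first, joins the first existing cluster
    whose *representative* it matches at >= both thresholds, else founds a
    new cluster; the representative is always the founding (longest) member.
    Returns a table (genome, cluster_id, representative, is_representative).
    """
    if not (0 < ani_min <= 100 and 0 < af_min <= 100):
        raise ValueError("thresholds must be in (0, 100]")
    sim: dict[frozenset[str], tuple[float, float]] = {}
    for p in pairs:
        key = frozenset((p.query_id, p.subject_id))
        ani = -math.inf if math.isnan(p.ani) else p.ani
        prev = sim.get(key)
        if prev is None or (ani, p.af) > prev:
            sim[key] = (ani, p.af)

    reps: list[str] = []
    assignment: dict[str, str] = {}
    for g in sorted(lengths, key=lambda g: (-lengths[g], g)):
        for rep in reps:
            ani, af = sim.get(frozenset((g, rep)), (-math.inf, 0.0))
            if ani >= ani_min and af >= af_min:
                assignment[g] = rep
                break
        else:
            reps.append(g)
            assignment[g] = g
    rep_ids = {rep: f"cluster_{i}" for i, rep in enumerate(reps)}
    return pd.DataFrame(
        {
            "genome": list(assignment),
            "cluster_id": [rep_ids[assignment[g]] for g in assignment],
            "representative": [assignment[g] for g in assignment],
            "is_representative": [g == assignment[g] for g in assignment],
        }
    )


def select_comparable_pairs(
    pairs: list[PairSimilarity],
    induction_table: pd.DataFrame,
    condition_table: pd.DataFrame,
    ani_min: float = 95.0,
    af_min: float = 85.0,
) -> pd.DataFrame:
    """Induced/non-induced prophage pairs eligible for cryptic-prophage analysis.

    A pair is retained when ANI >= 95 and AF >= 85 and the non-induced
    member's host was sequenced in at least one condition in which the
    induced member was actually induced — highly similar prophages are
    expected to respond to the same triggers, so only then is the partner's
    silence informative. ``induction_table`` has columns (genome, condition)
    listing induction events; ``condition_table`` has (genome, condition)
    listing sequenced conditions. Pairs without condition records are
    dropped with a warning.
    """
    induced_conditions: dict[str, set[str]] = (
        induction_table.groupby("genome")["condition"].agg(set).to_dict()
    )
    sequenced: dict[str, set[str]] = (
        condition_table.groupby("genome")["condition"].agg(set).to_dict()
    )
    rows = []
    for p in pairs:
        if math.isnan(p.ani) or p.ani < ani_min or p.af < af_min:
            continue
        a_ind = p.query_id in induced_conditions
        b_ind = p.subject_id in induced_conditions
        if a_ind == b_ind:
            continue  # induced-induced / neither: not an induced-vs-cryptic pair
        induced, other = (
            (p.query_id, p.subject_id) if a_ind else (p.subject_id, p.query_id)
        )
        if other not in sequenced:
            warnings.warn(
                f"no condition records for {other!r}; pair dropped", stacklevel=2
            )
            continue
        shared = induced_conditions[induced] & sequenced[other]
        if shared:
            rows.append(
                dict(
                    induced=induced,
                    non_induced=other,
                    ani=p.ani,
                    af=p.af,
                    shared_conditions=",".join(sorted(shared)),
                )
            )
    return pd.DataFrame(
        rows, columns=["induced", "non_induced", "ani", "af", "shared_conditions"]
    )
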