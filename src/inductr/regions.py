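"""Prophage region intervals and interval algebra.

Coordinates are 0-based, half-open everywhere in memory; BED-compatible on
disk. Completeness is the upstream predictor's completeness estimate in
percent; predictions above 50% are conventionally treated as high quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class ProphageRegion:
    """A candidate or called prophage interval on a host contig."""

    contig_id: str
    start: int
    end: int
    region_id: str = ""
    completeness: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid region [{self.start}, {self.end}): need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def quality(self) -> str:
        """'high' for completeness > 50%, 'low' otherwise (or unknown)."""
        if self.completeness is not None and self.completeness > 50:
            return "high"
        return "low"


def merge_overlapping(regions: list[ProphageRegion]) -> list[ProphageRegion]:
    """Merge overlapping prophage predictions on the same contig.

    Two regions merge only if they share at least 1 bp; half-open abutting
    intervals ([10,100) and [100,150)) do not merge. The merged region keeps
    the maximum completeness of its members and concatenates sources. The
    result is independent of input order and conserves the covered span.
    """
    if not regions:
        return []
    by_contig: dict[str, list[ProphageRegion]] = {}
    for r in regions:
        by_contig.setdefault(r.contig_id, []).append(r)

    merged: list[ProphageRegion] = []
    for contig in sorted(by_contig):
        rs = sorted(by_contig[contig], key=lambda r: (r.start, r.end))
        current = rs[0]
        members = [current]
        for r in rs[1:]:
            if r.start < current.end:  # >=1 bp overlap
                members.append(r)
                current = replace(
                    current,
                    end=max(current.end, r.end),
                    completeness=_max_completeness(members),
                    region_id=members[0].region_id,
                    source=";".join(
                        dict.fromkeys(m.source for m in members if m.source)
                    ),
                )
            else:
                merged.append(current)
                current = r
                members = [r]
        merged.append(current)
    return merged


def _max_completeness(members: list[ProphageRegion]) -> float | None:
    vals = [m.completeness for m in members if m.completeness is not None]
    return max(vals) if vals else None
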