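"""Splicing-reporter (minigene) constructs as ordered exon/intron segments.

A minigene such as pRHCglo is a compact three-exon / two-intron reporter:
the middle (test) exon can be replaced with an element of interest — a
T-box binding element, multimeric MS2 sites, or a genomic exon with its
intronic fragments — and the transcripts reveal how the insert is spliced.
This module models a construct as an alternating exon/intron segment list,
supports segment replacement, enumerates the observable splice outcomes
(unspliced, single-intron retention, full inclusion, cassette skipping of
each internal exon), and predicts RT-PCR product sizes.

Only whole-intron removal and cassette skipping are modelled; cryptic
splice sites are out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

__all__ = [
    "Segment",
    "ReporterConstruct",
    "SpliceOutcome",
    "StructuralError",
    "replace_segment",
    "enumerate_isoforms",
    "product_size",
    "construct_from_json",
    "construct_to_json",
]


class StructuralError(ValueError):
    """A segment edit that breaks exon/intron alternation."""


@dataclass(frozen=True)
class Segment:
    id: str
    role: str  # "exon" or "intron"
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.role not in {"exon", "intron"}:
            raise StructuralError(f"segment role must be exon or intron, got {self.role!r}")
        if self.length < 1:
            raise StructuralError(f"segment {self.id!r} length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise StructuralError(f"segment {self.id!r}: sequence length != declared length")


@dataclass(frozen=True)
class ReporterConstruct:
    name: str
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise StructuralError("construct needs at least one exon")
        roles = [s.role for s in self.segments]
        if roles[0] != "exon" or roles[-1] != "exon":
            raise StructuralError("construct must start and end with an exon")
        for a, b in zip(roles, roles[1:]):
            if a == b:
                raise StructuralError("exon and intron segments must alternate")
        ids = [s.id for s in self.segments]
        if len(set(ids)) != len(ids):
            raise StructuralError("segment ids must be unique")

    @property
    def exons(self) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if s.role == "exon")

    @property
    def introns(self) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if s.role == "intron")

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.segments)


@dataclass(frozen=True)
class SpliceOutcome:
    """One observable product: which segments the mature RNA retains."""

    name: str
    retained_segments: tuple[Segment, ...]
    removed_intron_ids: tuple[str, ...]

    @property
    def retained_segment_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.retained_segments)

    @property
    def product_length(self) -> int:
        return sum(s.length for s in self.retained_segments)


def replace_segment(
    construct: ReporterConstruct,
    segment_id: str,
    new_length: int,
    new_sequence: str | None = None,
) -> ReporterConstruct:
    """Swap one segment for an insert of a new length (0 deletes it).

    Deleting an internal exon merges its two flanking introns into one
    (and deleting an intron merges the flanking exons), preserving the
    alternation invariant.
    """
    idx = next((i for i, s in enumerate(construct.segments) if s.id == segment_id), None)
    if idx is None:
        raise KeyError(f"no segment {segment_id!r} in construct {construct.name!r}")
    old = construct.segments[idx]
    if new_length < 0:
        raise StructuralError("new_length must be >= 0")
    if new_length == 0:
        if idx == 0 or idx == len(construct.segments) - 1:
            raise StructuralError("cannot delete a terminal exon")
        left, right = construct.segments[idx - 1], construct.segments[idx + 1]
        merged = Segment(
            f"{left.id}+{right.id}",
            left.role,
            left.length + right.length,
            (left.sequence + right.sequence)
            if left.sequence is not None and right.sequence is not None
            else None,
        )
        segments = (
            construct.segments[: idx - 1] + (merged,) + construct.segments[idx + 2 :]
        )
    else:
        segments = (
            construct.segments[:idx]
            + (Segment(old.id, old.role, new_length, new_sequence),)
            + construct.segments[idx + 1 :]
        )
    return ReporterConstruct(construct.name, segments)


def enumerate_isoforms(construct: ReporterConstruct) -> list[SpliceOutcome]:
    """The observable splice outcomes of a reporter construct.

    Outcomes: the unspliced pre-mRNA; each partially spliced intermediate
    with one intron removed; the fully spliced mRNA retaining all exons
    (full inclusion); and, for each internal exon, the mature cassette-skip
    mRNA (all introns spliced out and the exon excluded together with its
    flanking introns).  Introns are only removable as whole units; exon
    order is preserved.  Duplicate products (e.g. for a two-exon construct
    where the single-intron removal is full splicing) are reported once.
    """
    segs = construct.segments
    outcomes: dict[tuple[str, ...], SpliceOutcome] = {}

    def add(name: str, removed_ids: set[str]) -> None:
        retained = tuple(s for s in segs if s.id not in removed_ids)
        removed_introns = tuple(s.id for s in segs if s.id in removed_ids and s.role == "intron")
        key = tuple(s.id for s in retained)
        outcomes.setdefault(key, SpliceOutcome(name, retained, removed_introns))

    add("unspliced", set())
    intron_ids = [s.id for s in construct.introns]
    for iid in intron_ids:
        add(f"spliced:{iid}", {iid})
    if intron_ids:
        add("full_inclusion", set(intron_ids))
    for i, seg in enumerate(segs):
        if seg.role == "exon" and 0 < i < len(segs) - 1:
            add(f"skip:{seg.id}", set(intron_ids) | {seg.id})
    return list(outcomes.values())


def product_size(outcome: SpliceOutcome, primer_offsets: tuple[int, int] = (0, 0)) -> int:
    """RT-PCR product size: outcome length minus the terminal overhangs
    outside the primers (5' offset into the first retained exon, 3' offset
    into the last)."""
    off5, off3 = primer_offsets
    if off5 < 0 or off3 < 0:
        raise ValueError("primer offsets must be >= 0")
    exons = [s for s in outcome.retained_segments if s.role == "exon"]
    if off5 >= exons[0].length or off3 >= exons[-1].length:
        raise ValueError("primer offsets exceed the terminal exon lengths")
    return outcome.product_length - off5 - off3


# -- JSON construct definitions ----------------------------------------------

def construct_from_json(path) -> ReporterConstruct:
    with open(path) as fh:
        data = json.load(fh)
    segments = tuple(
        Segment(s["id"], s["role"], int(s["length"]), s.get("sequence"))
        for s in data["segments"]
    )
    return ReporterConstruct(data["name"], segments)


def construct_to_json(construct: ReporterConstruct, path) -> None:
    data = {
        "name": construct.name,
        "segments": [
            {"id": s.id, "role": s.role, "length": s.length,
             **({"sequence": s.sequence} if s.sequence is not None else {})}
            for s in construct.segments
        ],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)
        fh.write("\n")
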