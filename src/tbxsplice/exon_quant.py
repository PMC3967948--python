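"""Exon-level quantification for cassette-exon splicing events.

Turns read intervals or raw counts into per-event exon/gene counts, RPKM
values and exon-usage ratios.  All genomic coordinates are 0-based,
half-open (BED convention); GTF input is converted on read.

The usage ratio (exon RPKM / gene RPKM, pseudocounted) is the working
estimate of the inclusion level (PSI) of the alternative exon: because RPKM
normalises by feature length, the ratio of the alternative-exon RPKM to the
whole-gene RPKM cancels the exon's length share and estimates the fraction
of transcripts that include the exon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpliceEventAnnotation",
    "ParseError",
    "DataIntegrityError",
    "COUNT_COLUMNS",
    "validate_counts",
    "count_reads",
    "rpkm",
    "rpkm_pseudocount",
    "usage_ratio",
    "read_bed_intervals",
    "events_to_bed",
    "events_from_gtf",
    "add_usage_columns",
]


class ParseError(ValueError):
    """Malformed interval or annotation input."""


class DataIntegrityError(ValueError):
    """Counts violating the exon <= gene <= library ordering."""


Interval = tuple[int, int]


@dataclass(frozen=True)
class SpliceEventAnnotation:
    """One cassette-exon event: a gene's exon chain plus its alternative exon(s).

    ``exons`` are sorted, pairwise-disjoint 0-based half-open intervals.
    ``alt_exon_indices`` point at the alternative (cassette) exon(s); they
    must be strictly internal (never the first or last exon) and, when there
    are two, adjacent — mirroring events where a pair of exons is included
    or skipped as a unit.  ``flank_up``/``flank_down`` are the intronic
    intervals adjacent to the alternative block, in transcript orientation
    (upstream = 5' of the alternative exon on the gene strand).
    """

    event_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    alt_exon_indices: tuple[int, ...]
    flank_up: Interval = (0, 0)
    flank_down: Interval = (0, 0)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ParseError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.exons) < 3:
            raise ParseError(
                f"{self.event_id}: cassette events need >= 3 exons, got {len(self.exons)}"
            )
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ParseError(f"{self.event_id}: empty exon interval [{start},{end})")
            if prev_end is not None and start < prev_end:
                raise ParseError(f"{self.event_id}: exons unsorted or overlapping")
            prev_end = end
        idx = self.alt_exon_indices
        if not idx:
            raise ParseError(f"{self.event_id}: no alternative exon index")
        if min(idx) < 1 or max(idx) > len(self.exons) - 2:
            raise ParseError(f"{self.event_id}: alternative exons must be internal")
        if list(idx) != sorted(idx) or any(b - a != 1 for a, b in zip(idx, idx[1:])):
            raise ParseError(f"{self.event_id}: alternative exon indices must be adjacent")
        for f in (self.flank_up, self.flank_down):
            for s, e in self.exons:
                if f[0] < e and f[1] > s:
                    raise ParseError(f"{self.event_id}: flank {f} overlaps an exon")

    # -- derived geometry ---------------------------------------------------

    @property
    def alt_exons(self) -> tuple[Interval, ...]:
        return tuple(self.exons[i] for i in self.alt_exon_indices)

    @property
    def alt_span(self) -> Interval:
        """Genomic span of the alternative block (first alt start, last alt end)."""
        return (self.alt_exons[0][0], self.alt_exons[-1][1])

    @property
    def alt_length(self) -> int:
        """Summed length of the alternative exon(s); the RPKM length."""
        return sum(e - s for s, e in self.alt_exons)

    @property
    def gene_length(self) -> int:
        """Summed exonic length of the gene; the gene RPKM length."""
        return sum(e - s for s, e in self.exons)

    @property
    def gene_span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @classmethod
    def cassette(
        cls,
        event_id: str,
        gene_id: str,
        chrom: str,
        strand: str,
        exons: Sequence[Interval],
        alt_exon_indices: Sequence[int],
    ) -> "SpliceEventAnnotation":
        """Build an event, deriving the intronic flanks from the exon chain.

        The flanks are the full introns between the alternative block and
        its neighbouring constitutive exons (callers clip to a window, e.g.
        1 kb, at scan time).
        """
        exons = tuple(tuple(e) for e in exons)
        idx = tuple(sorted(alt_exon_indices))
        if not idx or min(idx) < 1 or max(idx) > len(exons) - 2:
            raise ParseError(f"{event_id}: alternative exons must be internal")
        left_intron = (exons[idx[0] - 1][1], exons[idx[0]][0])
        right_intron = (exons[idx[-1]][1], exons[idx[-1] + 1][0])
        if strand == "+":
            up, down = left_intron, right_intron
        else:
            up, down = right_intron, left_intron
        return cls(event_id, gene_id, chrom, strand, exons, idx, up, down)


# -- count table schema -----------------------------------------------------

COUNT_COLUMNS = [
    "event_id",
    "sample_id",
    "condition",
    "compartment",
    "replicate",
    "exon_count",
    "gene_count",
    "library_size",
]


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check the count-table schema and the 0 <= exon <= gene <= library ordering."""
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise ParseError(f"count table lacks columns: {missing}")
    for col in ("exon_count", "gene_count", "library_size"):
        vals = counts[col].to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(np.equal(np.mod(vals, 1), 0)):
                raise DataIntegrityError(f"{col} contains non-integer values")
        if (vals < 0).any():
            raise DataIntegrityError(f"{col} contains negative values")
    if (counts["exon_count"] > counts["gene_count"]).any():
        bad = counts.loc[counts["exon_count"] > counts["gene_count"], "event_id"]
        raise DataIntegrityError(f"exon_count > gene_count for events {list(bad)[:5]}")
    if (counts["gene_count"] > counts["library_size"]).any():
        raise DataIntegrityError("gene_count exceeds library_size")
    return counts


# -- read counting ----------------------------------------------------------

def _reads_frame(read_intervals) -> pd.DataFrame:
    if isinstance(read_intervals, pd.DataFrame):
        df = read_intervals
    else:
        df = pd.DataFrame(list(read_intervals), columns=["chrom", "start", "end"])
    if (df["end"] <= df["start"]).any():
        bad = df[df["end"] <= df["start"]].iloc[0]
        raise ParseError(f"malformed read interval [{bad['start']},{bad['end']})")
    return df


def count_reads(
    read_intervals,
    annotation: Iterable[SpliceEventAnnotation],
    *,
    warn_unknown_chrom: bool = True,
) -> pd.DataFrame:
    """Count reads on the alternative exon(s) and on the whole gene per event.

    A read is assigned to an exon if it overlaps it by at least 1 bp under
    half-open semantics.  A read overlapping several exons of the same gene
    counts once toward ``gene_count``; ``exon_count`` is the number of reads
    overlapping any alternative exon.  Reads on chromosomes absent from the
    annotation are skipped (with a warning).

    Parameters
    ----------
    read_intervals : DataFrame with chrom/start/end columns, or iterable of
        (chrom, start, end) tuples (e.g. parsed from BED).
    annotation : the events to quantify.

    Returns a DataFrame with columns event_id, exon_count, gene_count.
    """
    import warnings

    events = list(annotation)
    reads = _reads_frame(read_intervals)
    known = {ev.chrom for ev in events}
    unknown = set(reads["chrom"]) - known
    if unknown and warn_unknown_chrom:
        warnings.warn(f"skipping reads on unknown chromosomes: {sorted(unknown)}")
    by_chrom = {
        chrom: (grp["start"].to_numpy(), grp["end"].to_numpy())
        for chrom, grp in reads.groupby("chrom")
        if chrom in known
    }
    rows = []
    for ev in events:
        starts, ends = by_chrom.get(ev.chrom, (np.empty(0, int), np.empty(0, int)))
        gene_hit = np.zeros(len(starts), dtype=bool)
        exon_hit = np.zeros(len(starts), dtype=bool)
        alt = set(ev.alt_exon_indices)
        for i, (s, e) in enumerate(ev.exons):
            ov = (starts < e) & (ends > s)
            gene_hit |= ov
            if i in alt:
                exon_hit |= ov
        rows.append((ev.event_id, int(exon_hit.sum()), int(gene_hit.sum())))
    return pd.DataFrame(rows, columns=["event_id", "exon_count", "gene_count"])


# -- RPKM and usage ratio ---------------------------------------------------

def rpkm(count, length_bp, library_size):
    """Reads per kilobase of feature per million mapped reads.

    value = count / ((length_bp / 1000) * (library_size / 1e6)).
    Accepts scalars or numpy arrays; length and library size must be >= 1.
    """
    length_bp = np.asarray(length_bp)
    library_size = np.asarray(library_size)
    if (length_bp < 1).any() if length_bp.ndim else length_bp < 1:
        raise ValueError("length_bp must be >= 1")
    if (library_size < 1).any() if library_size.ndim else library_size < 1:
        raise ValueError("library_size must be >= 1")
    value = np.asarray(count, dtype=float) / ((length_bp / 1e3) * (library_size / 1e6))
    return float(value) if value.ndim == 0 else value


def rpkm_pseudocount(library_size) -> float:
    """Half-read continuity correction expressed in RPKM units: 0.5/(library/1e6)."""
    return 0.5 / (np.asarray(library_size, dtype=float) / 1e6)


def usage_ratio(exon_rpkm, gene_rpkm, pseudocount):
    """Pseudocounted exon-usage ratio (exon RPKM + eps) / (gene RPKM + eps).

    With exon reads a subset of gene reads and a shared library the ratio
    stays near or below 1 and estimates the inclusion level.  A 0/0 input
    yields 1.0: an uninformative event the caller should flag.
    """
    exon_rpkm = np.asarray(exon_rpkm, dtype=float)
    gene_rpkm = np.asarray(gene_rpkm, dtype=float)
    eps = np.asarray(pseudocount, dtype=float)
    if (eps <= 0).any() if eps.ndim else eps <= 0:
        raise ValueError("pseudocount must be > 0")
    for name, arr in (("exon_rpkm", exon_rpkm), ("gene_rpkm", gene_rpkm)):
        if (arr < 0).any() if arr.ndim else arr < 0:
            raise ValueError(f"{name} must be non-negative")
    out = (exon_rpkm + eps) / (gene_rpkm + eps)
    return float(out) if out.ndim == 0 else out


def add_usage_columns(counts: pd.DataFrame, annotation: Iterable[SpliceEventAnnotation]) -> pd.DataFrame:
    """Append rpkm_exon, rpkm_gene and usage_ratio columns to a count table."""
    validate_counts(counts)
    lengths = {ev.event_id: (ev.alt_length, ev.gene_length) for ev in annotation}
    alt_len = counts["event_id"].map(lambda e: lengths[e][0])
    gene_len = counts["event_id"].map(lambda e: lengths[e][1])
    lib = counts["library_size"].clip(lower=1)
    out = counts.copy()
    out["rpkm_exon"] = rpkm(counts["exon_count"].to_numpy(), alt_len.to_numpy(), lib.to_numpy())
    out["rpkm_gene"] = rpkm(counts["gene_count"].to_numpy(), gene_len.to_numpy(), lib.to_numpy())
    out["usage_ratio"] = usage_ratio(
        out["rpkm_exon"].to_numpy(), out["rpkm_gene"].to_numpy(), rpkm_pseudocount(lib.to_numpy())
    )
    return out


# -- interval / annotation I/O ----------------------------------------------

def read_bed_intervals(path) -> pd.DataFrame:
    """Read BED intervals (>=3 columns) into a chrom/start/end[/name/score/strand] frame."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ParseError(f"{path}: BED needs >= 3 columns")
    df = df.iloc[:, : min(6, df.shape[1])]
    df.columns = names[: df.shape[1]]
    if (df["end"] <= df["start"]).any():
        raise ParseError(f"{path}: interval with end <= start")
    return df


def events_to_bed(events: Iterable[SpliceEventAnnotation], path) -> None:
    """Write one BED6 line per alternative exon, name=event_id."""
    with open(path, "w") as fh:
        for ev in events:
            for s, e in ev.alt_exons:
                fh.write(f"{ev.chrom}\t{s}\t{e}\t{ev.event_id}\t0\t{ev.strand}\n")


def events_to_json(events: Iterable[SpliceEventAnnotation], path) -> None:
    """Full event annotation (exon chains included) as JSON."""
    import json

    data = [
        {
            "event_id": ev.event_id,
            "gene_id": ev.gene_id,
            "chrom": ev.chrom,
            "strand": ev.strand,
            "exons": [list(e) for e in ev.exons],
            "alt_exon_indices": list(ev.alt_exon_indices),
        }
        for ev in events
    ]
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)
        fh.write("\n")


def events_from_json(path) -> list[SpliceEventAnnotation]:
    import json

    with open(path) as fh:
        data = json.load(fh)
    return [
        SpliceEventAnnotation.cassette(
            d["event_id"], d["gene_id"], d["chrom"], d["strand"],
            [tuple(e) for e in d["exons"]], d["alt_exon_indices"],
        )
        for d in data
    ]


def events_from_gtf(path) -> list[SpliceEventAnnotation]:
    """Derive cassette-exon events from a GTF gene model.

    Groups exon features by gene; an internal exon present in some but not
    all transcripts of its gene (the knownAlt notion of an annotated
    alternative splice form) becomes one cassette event against the union
    exon chain.  GTF 1-based inclusive coordinates are converted to 0-based
    half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_gene: dict[str, dict] = {}
    for ex in db.features_of_type("exon"):
        gene = ex.attributes.get("gene_id", ["?"])[0]
        tx = ex.attributes.get("transcript_id", ["?"])[0]
        rec = by_gene.setdefault(gene, {"chrom": ex.seqid, "strand": ex.strand, "tx": {}})
        rec["tx"].setdefault(tx, set()).add((ex.start - 1, ex.end))
    events: list[SpliceEventAnnotation] = []
    for gene, rec in by_gene.items():
        union = sorted(set().union(*rec["tx"].values()))
        if len(union) < 3:
            continue
        n_tx = len(rec["tx"])
        for i, exon in enumerate(union[1:-1], start=1):
            present = sum(exon in exons for exons in rec["tx"].values())
            if 0 < present < n_tx:
                events.append(
                    SpliceEventAnnotation.cassette(
                        f"{gene}_ex{i}", gene, rec["chrom"], rec["strand"], union, (i,)
                    )
                )
    return events
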