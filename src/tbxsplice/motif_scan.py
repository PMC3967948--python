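"""Degenerate-motif scanning of alternative exons and their intronic flanks.

T-box factors bind a degenerate DNA element (the T-box binding element,
TBE) whose core is GGTG (complement CACC); its RNA counterpart is UGGUGU.
This module counts fixed degenerate patterns — it does not do de-novo
motif discovery — over exon sequences and the 1 kb intronic flanks of
cassette events, computes expected-by-chance counts under an i.i.d.
background, and tests over-representation with an upper-tail binomial.

Patterns are written with bracketed alternative sets, e.g. "[TA]GGTG[TAG]";
"N" matches any base.  DNA patterns are scanned on both strands by default
(reverse-strand hits are reported in forward coordinates with strand "-");
RNA patterns are sense-only, RNA having one strand.  Overlapping matches
all count: motif multiplicity matters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .exon_quant import SpliceEventAnnotation

__all__ = [
    "MotifPattern",
    "MotifHit",
    "EnrichmentResult",
    "BUILTIN_MOTIFS",
    "get_motif",
    "scan_sequence",
    "expected_count",
    "enrichment_test",
    "extract_flanks",
    "presence_summary",
    "PresenceSummary",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_DNA = set("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _parse_pattern(spec: str) -> tuple[frozenset, ...]:
    """Parse "[TA]GGTG[TAG]" (U allowed, normalised to T; N = any base)."""
    positions: list[frozenset] = []
    i = 0
    spec = spec.upper().replace("U", "T")
    while i < len(spec):
        ch = spec[i]
        if ch == "[":
            j = spec.index("]", i)
            chars = set(spec[i + 1 : j])
            i = j + 1
        elif ch == "N":
            chars = set(_DNA)
            i += 1
        else:
            chars = {ch}
            i += 1
        if not chars or not chars <= _DNA:
            raise ValueError(f"invalid pattern characters in {spec!r}")
        positions.append(frozenset(chars))
    return tuple(positions)


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate motif: per-position allowed base sets.

    ``alphabet`` records whether the motif was defined over DNA or RNA
    (internally everything is stored as DNA; sequences are T/U-normalised
    on read).  ``strand_policy`` is "both" or "sense-only".
    """

    name: str
    pattern: str
    alphabet: str = "DNA"
    strand_policy: str = "both"

    def __post_init__(self) -> None:
        if self.alphabet not in {"DNA", "RNA"}:
            raise ValueError("alphabet must be DNA or RNA")
        if self.strand_policy not in {"both", "sense-only"}:
            raise ValueError("strand_policy must be 'both' or 'sense-only'")
        if len(self.positions) < 4:
            raise ValueError("pattern length must be >= 4")

    @property
    def positions(self) -> tuple[frozenset, ...]:
        return _parse_pattern(self.pattern)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def rc_positions(self) -> tuple[frozenset, ...]:
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        return tuple(
            frozenset(comp[c] for c in chars) for chars in reversed(self.positions)
        )

    @property
    def is_rc_closed(self) -> bool:
        """True when the match set equals its own reverse-complement set."""
        return self.positions == self.rc_positions

    def _regex(self, positions) -> re.Pattern:
        return re.compile(
            "(?=(" + "".join("[" + "".join(sorted(p)) + "]" for p in positions) + "))"
        )

    @property
    def regex(self) -> re.Pattern:
        return self._regex(self.positions)

    @property
    def rc_regex(self) -> re.Pattern:
        return self._regex(self.rc_positions)

    def words(self) -> list[str]:
        """All concrete words matching the pattern (DNA alphabet)."""
        import itertools

        return ["".join(w) for w in itertools.product(*(sorted(p) for p in self.positions))]


#: Built-in TBE-family motifs.  TBE_DNA is the conservative literature
#: definition (T/A)GGTG(T/A/G); TBE_CONSENSUS the longer (A/T)GGTGTG;
#: TBE_CORE the GGTG core (complement CACC, covered by both-strand
#: scanning); RNA_TBE the RNA element UGGUGU; RELAXED the less stringent
#: (G/T)(G/C)TGN core reported from ChIP data.
BUILTIN_MOTIFS: dict[str, MotifPattern] = {
    "TBE_DNA": MotifPattern("TBE_DNA", "[TA]GGTG[TAG]", "DNA", "both"),
    "TBE_CONSENSUS": MotifPattern("TBE_CONSENSUS", "[AT]GGTGTG", "DNA", "both"),
    "TBE_CORE": MotifPattern("TBE_CORE", "GGTG", "DNA", "both"),
    "RNA_TBE": MotifPattern("RNA_TBE", "UGGUGU", "RNA", "sense-only"),
    "RELAXED": MotifPattern("RELAXED", "[GT][GC]TGN", "DNA", "both"),
}


def get_motif(name: str) -> MotifPattern:
    try:
        return BUILTIN_MOTIFS[name]
    except KeyError:
        raise KeyError(f"unknown motif {name!r}; built-ins: {sorted(BUILTIN_MOTIFS)}") from None


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    start: int
    strand: str
    matched_text: str
    motif_name: str


@dataclass(frozen=True)
class EnrichmentResult:
    motif_name: str
    observed: int
    expected: float
    n_positions: int
    p: float


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def scan_sequence(sequence: str, motif: MotifPattern, sequence_id: str = "seq") -> list[MotifHit]:
    """All (possibly overlapping) matches of the motif in the sequence.

    Reverse-strand hits (both-strand motifs only) are reported at their
    forward-strand start coordinate with strand "-"; their matched_text is
    the minus-strand reading, which matches the pattern.
    """
    seq = _normalize(sequence)
    k = len(motif)
    hits: list[MotifHit] = []
    for m in motif.regex.finditer(seq):
        i = m.start()
        hits.append(MotifHit(sequence_id, i, "+", seq[i : i + k], motif.name))
    if motif.strand_policy == "both":
        for m in motif.rc_regex.finditer(seq):
            i = m.start()
            hits.append(
                MotifHit(sequence_id, i, "-", reverse_complement(seq[i : i + k]), motif.name)
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def _match_probability(positions, background: Mapping[str, float]) -> float:
    prob = 1.0
    for chars in positions:
        prob *= sum(background[c] for c in chars)
    return prob


UNIFORM_BACKGROUND = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}


def expected_count(
    motif: MotifPattern,
    sequence_length: int,
    background_freqs: Mapping[str, float] | None = None,
) -> float:
    """Expected number of hits in an i.i.d. background sequence.

    expected = (L - k + 1) * P(position matches); for both-strand motifs
    whose match set is not reverse-complement-closed the reverse-strand
    match probability is added (which doubles the count under a uniform or
    strand-symmetric background).  Returns 0 when L < k.
    """
    bg = dict(UNIFORM_BACKGROUND if background_freqs is None else background_freqs)
    bg = {k.upper().replace("U", "T"): v for k, v in bg.items()}
    if abs(sum(bg.values()) - 1.0) > 1e-9:
        raise ValueError("background frequencies must sum to 1")
    k = len(motif)
    n_pos = sequence_length - k + 1
    if n_pos <= 0:
        return 0.0
    prob = _match_probability(motif.positions, bg)
    if motif.strand_policy == "both" and not motif.is_rc_closed:
        prob += _match_probability(motif.rc_positions, bg)
    return n_pos * prob


def enrichment_test(
    observed: int, expected: float, n_positions: int, motif_name: str = ""
) -> EnrichmentResult:
    """Upper-tail binomial test of observed vs expected-by-chance counts.

    p = P(Binomial(n_positions, expected/n_positions) >= observed).
    """
    if n_positions < 1:
        raise ValueError("n_positions must be >= 1")
    if observed > n_positions:
        raise ValueError("observed count exceeds the number of scannable positions")
    rate = min(1.0, expected / n_positions)
    p = float(stats.binom.sf(observed - 1, n_positions, rate))
    p = min(1.0, max(p, float(np.nextafter(0.0, 1.0))))
    return EnrichmentResult(motif_name, int(observed), float(expected), int(n_positions), p)


def extract_flanks(
    event: SpliceEventAnnotation,
    genome: Mapping[str, str],
    flank_bp: int = 1000,
) -> tuple[str, str, str]:
    """(upstream, exon, downstream) sequences on the gene strand.

    Flanks are intronic: clipped at the neighbouring constitutive exons
    and at ``flank_bp``.  On the minus strand all three sequences are
    reverse-complemented so that "upstream" is 5' of the alternative
    exon(s) in transcript orientation.
    """
    if event.chrom not in genome:
        raise KeyError(f"chromosome {event.chrom!r} absent from genome")
    seq = _normalize(str(genome[event.chrom]))
    s, e = event.alt_span
    if e > len(seq):
        raise ValueError(
            f"{event.event_id}: alternative block [{s},{e}) beyond sequence end {len(seq)}"
        )
    left_intron = (event.exons[event.alt_exon_indices[0] - 1][1], s)
    right_intron = (e, event.exons[event.alt_exon_indices[-1] + 1][0])
    left = seq[max(left_intron[0], s - flank_bp) : s]
    right = seq[e : min(right_intron[1], e + flank_bp, len(seq))]
    exon_seq = "".join(seq[a:b] for a, b in event.alt_exons)
    if event.strand == "+":
        return left, exon_seq, right
    return (
        reverse_complement(right),
        reverse_complement(exon_seq),
        reverse_complement(left),
    )


@dataclass(frozen=True)
class PresenceSummary:
    """Which events carry >= 1 motif hit in their intronic flanks."""

    per_event: Mapping[str, bool]
    count: int
    n: int

    @property
    def fraction(self) -> float:
        return self.count / self.n

    @property
    def label(self) -> str:
        return f"{self.count}/{self.n}"


def presence_summary(
    events: Iterable[SpliceEventAnnotation],
    genome: Mapping[str, str],
    motif: MotifPattern,
    flank_bp: int = 1000,
) -> PresenceSummary:
    """Fraction of events with at least one hit in either intronic flank."""
    events = list(events)
    if not events:
        raise ValueError("presence_summary needs at least one event")
    per_event: dict[str, bool] = {}
    for ev in events:
        up, _, down = extract_flanks(ev, genome, flank_bp)
        hit = bool(scan_sequence(up, motif, ev.event_id)) or bool(
            scan_sequence(down, motif, ev.event_id)
        )
        per_event[ev.event_id] = hit
    return PresenceSummary(per_event, sum(per_event.values()), len(per_event))


# -- FASTA I/O ---------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
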