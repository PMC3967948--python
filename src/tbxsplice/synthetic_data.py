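"""Synthetic data with known ground truth for every pipeline stage.

Emulates the study design the caller targets: a 2-genotype (control vs
factor-ablated) x 2-compartment (anterior/posterior) bulk RNA-Seq design
with 2 replicates per group, negative-binomial gene counts with
binomially thinned alternative-exon counts whose inclusion level (PSI)
can differ between genotypes — including in opposite directions in the
two compartments — plus random genomes with TBE motifs planted at
recorded positions, and Bernoulli IP-MS detection matrices with labelled
true interactors.

Counts are simulated at the exon/gene level (the statistics downstream
operate on counts and RPKM, not on reads); an optional read-interval
emitter places uniform single-end reads over the exons for exercising the
read counter.  The exon's share of the gene count is proportional to exon
length, and inclusion modulates only the alternative-exon count, so the
RPKM usage ratio recovers PSI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exon_quant import COUNT_COLUMNS, SpliceEventAnnotation
from .interactome_filter import DetectionMatrix
from .motif_scan import BUILTIN_MOTIFS, MotifPattern, reverse_complement

__all__ = [
    "SimulationDesign",
    "PlantedEvent",
    "PlantedMotif",
    "InvalidDesignError",
    "PlantingError",
    "generate_annotation",
    "generate_genome",
    "plant_study_events",
    "simulate_counts",
    "simulate_reads",
    "simulate_detection_matrix",
    "write_run_manifest",
]


class InvalidDesignError(ValueError):
    """A simulation design violating its invariants."""


class PlantingError(ValueError):
    """A motif that does not fit in its designated region."""


@dataclass(frozen=True)
class SimulationDesign:
    """The simulated study layout (identical across compartments)."""

    n_genes: int
    conditions: tuple[str, str] = ("control", "mutant")
    compartments: tuple[str, ...] = ("anterior", "posterior")
    replicates_per_group: int = 2
    mean_gene_depth: float = 200.0
    dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise InvalidDesignError("n_genes must be >= 1")
        if self.replicates_per_group < 1:
            raise InvalidDesignError("replicates_per_group must be >= 1")
        if self.mean_gene_depth < 0:
            raise InvalidDesignError("mean_gene_depth must be >= 0")
        if self.dispersion < 0:
            raise InvalidDesignError("dispersion must be >= 0")
        if len(self.conditions) != 2:
            raise InvalidDesignError("exactly two conditions (control, mutant)")


@dataclass(frozen=True)
class PlantedEvent:
    """Ground truth for one event: per-group inclusion levels and motif plan.

    ``psi`` maps (condition, compartment) -> inclusion level in [0, 1];
    ``motif_plan`` lists (motif_name, region, copies) with region one of
    "upstream", "downstream", "exon".
    """

    gene_id: str
    event_id: str
    psi: Mapping[tuple[str, str], float]
    motif_plan: tuple[tuple[str, str, int], ...] = ()

    def __post_init__(self) -> None:
        for key, val in self.psi.items():
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"psi{key} = {val} outside [0, 1]")
        for name, region, copies in self.motif_plan:
            if region not in {"upstream", "downstream", "exon"}:
                raise ValueError(f"unknown planting region {region!r}")
            if copies < 0:
                raise ValueError("motif copies must be >= 0")


@dataclass(frozen=True)
class PlantedMotif:
    """Record of one planted motif instance, for truth checking."""

    event_id: str
    motif_name: str
    region: str
    chrom: str
    start: int  # forward-strand coordinate
    strand: str  # gene strand the instance reads on
    word: str  # the concrete instance, as read on the gene strand


# -- annotation --------------------------------------------------------------

_EXON_LEN = (80, 250)
_INTRON_LEN = (600, 1400)  # room for 1 kb flank scans and motif planting
_PAD = 200


def generate_annotation(
    design: SimulationDesign,
    exons_per_gene: tuple[int, int] = (3, 8),
    *,
    p_double_alt: float = 0.2,
) -> list[SpliceEventAnnotation]:
    """One cassette event per gene, each gene on its own chromosome chrS<i>.

    Exon counts are drawn uniformly from the inclusive ``exons_per_gene``
    range (minimum 3: two constitutive flanks plus the cassette).  With
    probability ``p_double_alt`` the event spans two adjacent internal
    exons included or skipped as a perfectly correlated unit.  Intervals
    are 0-based half-open, sorted and disjoint; determinism follows from
    the design seed.
    """
    lo, hi = exons_per_gene
    if lo < 3:
        raise InvalidDesignError("cassette genes need at least 3 exons")
    if hi < lo:
        raise InvalidDesignError("empty exons_per_gene range")
    rng = np.random.default_rng([design.seed, 101])
    events: list[SpliceEventAnnotation] = []
    for g in range(design.n_genes):
        n_exons = int(rng.integers(lo, hi + 1))
        pos = _PAD
        exons = []
        for i in range(n_exons):
            length = int(rng.integers(*_EXON_LEN))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(*_INTRON_LEN))
        double = n_exons >= 4 and rng.random() < p_double_alt
        if double:
            first = int(rng.integers(1, n_exons - 2))
            alt = (first, first + 1)
        else:
            alt = (int(rng.integers(1, n_exons - 1)),)
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"gS{g + 1:04d}"
        events.append(
            SpliceEventAnnotation.cassette(
                f"ev{g + 1:04d}", gene_id, f"chrS{g + 1}", strand, exons, alt
            )
        )
    return events


# -- genome ------------------------------------------------------------------

def _planting_interval(ev: SpliceEventAnnotation, region: str, flank_bp: int = 1000):
    """Genomic interval for a planting region, in transcript orientation."""
    s, e = ev.alt_span
    left_intron = (ev.exons[ev.alt_exon_indices[0] - 1][1], s)
    right_intron = (e, ev.exons[ev.alt_exon_indices[-1] + 1][0])
    left = (max(left_intron[0], s - flank_bp), s)
    right = (e, min(right_intron[1], e + flank_bp))
    if region == "exon":
        return ev.alt_exons[0]
    if (region == "upstream") == (ev.strand == "+"):
        return left
    return right


def generate_genome(
    annotation: Iterable[SpliceEventAnnotation],
    background_freqs: Mapping[str, float] | None = None,
    planted: Sequence[PlantedEvent] = (),
    seed: int = 0,
) -> tuple[dict[str, str], list[PlantedMotif]]:
    """Random background sequence per chromosome with motifs planted verbatim.

    Bases are i.i.d. from ``background_freqs`` (uniform by default).  Each
    planted motif instance is a concrete word of the named pattern written
    on the gene strand at a recorded, non-overlapping position inside its
    region (upstream/downstream intronic 1 kb flank, or the alternative
    exon).  Returns the genome and the planting record.
    """
    bg = dict({"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25} if background_freqs is None else background_freqs)
    total = sum(bg.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("background frequencies must sum to 1")
    bases = sorted(bg)
    probs = np.array([bg[b] for b in bases])
    rng = np.random.default_rng(seed)
    events = {ev.event_id: ev for ev in annotation}
    lengths: dict[str, int] = {}
    for ev in events.values():
        lengths[ev.chrom] = max(lengths.get(ev.chrom, 0), ev.gene_span[1] + _PAD)
    genome_arr = {
        chrom: rng.choice(list(bases), size=n, p=probs).astype("<U1")
        for chrom, n in sorted(lengths.items())
    }
    record: list[PlantedMotif] = []
    for pe in planted:
        ev = events.get(pe.event_id)
        if ev is None:
            raise KeyError(f"planted event {pe.event_id!r} not in annotation")
        occupied: list[tuple[int, int]] = []
        for motif_name, region, copies in pe.motif_plan:
            motif = BUILTIN_MOTIFS.get(motif_name)
            if motif is None:
                raise KeyError(f"unknown motif {motif_name!r}")
            lo, hi = _planting_interval(ev, region)
            k = len(motif)
            if hi - lo < k:
                raise PlantingError(
                    f"{pe.event_id}/{region}: region of {hi - lo} bp cannot hold a {k} bp motif"
                )
            words = motif.words()
            for _ in range(copies):
                for _attempt in range(200):
                    start = int(rng.integers(lo, hi - k + 1))
                    if all(start + k <= a or start >= b for a, b in occupied):
                        break
                else:
                    raise PlantingError(f"{pe.event_id}/{region}: could not place motif copies")
                occupied.append((start, start + k))
                word = words[int(rng.integers(len(words)))]
                written = word if ev.strand == "+" else reverse_complement(word)
                genome_arr[ev.chrom][start : start + k] = list(written)
                record.append(
                    PlantedMotif(pe.event_id, motif_name, region, ev.chrom, start, ev.strand, word)
                )
    genome = {chrom: "".join(arr) for chrom, arr in genome_arr.items()}
    return genome, record


# -- counts ------------------------------------------------------------------

def _nb_counts(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    if dispersion <= 0:
        return rng.poisson(mean, size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size)


def simulate_counts(
    annotation: Iterable[SpliceEventAnnotation],
    design: SimulationDesign,
    planted: Sequence[PlantedEvent] = (),
    *,
    baseline_psi: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample exon/gene counts plus a truth table.

    Gene counts are NegBin(mean_gene_depth, dispersion); the alternative
    exon count is Binomial(gene_count, length_share * psi), so exon <=
    gene always and the length share cancels in the RPKM usage ratio.
    Events without a planted PSI use ``baseline_psi`` in every group.
    Library size is the per-sample sum of gene counts.

    Returns (counts, truth); truth has one row per event x compartment
    with psi_ctl, psi_mut, delta_psi (mutant - control) and the true
    direction ("factor-promotes-inclusion" when the mutant loses the exon).
    """
    if not (0.0 <= baseline_psi <= 1.0):
        raise ValueError("baseline_psi must lie in [0, 1]")
    events = list(annotation)
    known = {ev.event_id for ev in events}
    psi_map: dict[tuple[str, str, str], float] = {}
    for pe in planted:
        if pe.event_id not in known:
            raise KeyError(f"planted event {pe.event_id!r} not in annotation")
        for (cond, comp), val in pe.psi.items():
            psi_map[(pe.event_id, cond, comp)] = val
    rng = np.random.default_rng([design.seed, 202])
    rows = []
    for comp in design.compartments:
        for cond in design.conditions:
            for rep in range(1, design.replicates_per_group + 1):
                sample_id = f"{cond}_{comp}_{rep}"
                gene_counts = _nb_counts(rng, design.mean_gene_depth, design.dispersion, len(events))
                lib = int(gene_counts.sum())
                for ev, gc in zip(events, gene_counts):
                    share = ev.alt_length / ev.gene_length
                    psi = psi_map.get((ev.event_id, cond, comp), baseline_psi)
                    ec = int(rng.binomial(int(gc), share * psi)) if gc > 0 else 0
                    rows.append(
                        (ev.event_id, sample_id, cond, comp, rep, ec, int(gc), lib)
                    )
    counts = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    ctl, mut = design.conditions
    truth_rows = []
    for ev in events:
        for comp in design.compartments:
            p_ctl = psi_map.get((ev.event_id, ctl, comp), baseline_psi)
            p_mut = psi_map.get((ev.event_id, mut, comp), baseline_psi)
            if p_mut < p_ctl:
                direction = "factor-promotes-inclusion"
            elif p_mut > p_ctl:
                direction = "factor-promotes-skipping"
            else:
                direction = "none"
            truth_rows.append((ev.event_id, comp, p_ctl, p_mut, p_mut - p_ctl, direction))
    truth = pd.DataFrame(
        truth_rows,
        columns=["event_id", "compartment", "psi_ctl", "psi_mut", "delta_psi", "direction"],
    )
    return counts, truth


def plant_study_events(
    annotation: Sequence[SpliceEventAnnotation],
    n_events: int = 30,
    psi_high: float = 0.75,
    psi_low: float = 0.25,
) -> list[PlantedEvent]:
    """The standard planted-effect layout used for recovery studies.

    Plants switch-like inclusion changes (PSI ``psi_high`` <-> ``psi_low``,
    modelling the validated in-vivo events, which are near-complete isoform
    switches) on the first ``n_events`` genes: anterior-only effects of
    alternating direction, except the first event, which flips direction
    between the anterior and posterior compartments — the hallmark
    compartment-reversal pattern.
    """
    if n_events > len(annotation):
        raise InvalidDesignError("more planted events than genes")
    planted = []
    for i, ev in enumerate(annotation[:n_events]):
        if i == 0:
            psi = {
                ("control", "anterior"): psi_high,
                ("mutant", "anterior"): psi_low,
                ("control", "posterior"): psi_low,
                ("mutant", "posterior"): psi_high,
            }
        elif i % 2:
            psi = {("control", "anterior"): psi_high, ("mutant", "anterior"): psi_low}
        else:
            psi = {("control", "anterior"): psi_low, ("mutant", "anterior"): psi_high}
        planted.append(PlantedEvent(ev.gene_id, ev.event_id, psi))
    return planted


def simulate_reads(
    event: SpliceEventAnnotation,
    n_reads: int,
    read_length: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Uniform single-end reads over a gene's exons (for the read counter).

    Read starts are uniform over exonic positions; reads run along the
    chromosome and may extend past an exon boundary into the intron.
    """
    rng = np.random.default_rng(seed)
    starts = []
    exon_lens = np.array([e - s for s, e in event.exons])
    choices = rng.choice(len(event.exons), size=n_reads, p=exon_lens / exon_lens.sum())
    for i in choices:
        s, e = event.exons[i]
        starts.append(int(rng.integers(s, e)))
    return pd.DataFrame(
        {"chrom": event.chrom, "start": starts, "end": [s + read_length for s in starts]}
    )


# -- IP-MS detection matrices ------------------------------------------------

def simulate_detection_matrix(
    n_proteins: int,
    n_experiments: int,
    n_controls: int,
    detection_probs: Mapping[str, float],
    seed: int = 0,
    *,
    frac_true: float = 0.3,
    species_split: int | None = None,
) -> tuple[DetectionMatrix, pd.Series]:
    """Bernoulli IP-MS detections with labelled true interactors.

    ``detection_probs`` keys: ``true_in_assay`` (a true interactor's
    detection probability per non-control experiment), ``true_in_control``
    (default 0), ``background_in_assay`` and ``background_in_control``
    (sticky contaminants detected in controls too).  Experiments split
    into mouse (first ``species_split``, default n//2) and human, echoing
    a multi-species screen.  Returns the matrix and a protein-indexed
    boolean truth series.
    """
    if n_experiments < 2:
        raise InvalidDesignError("need at least two non-control experiments")
    if n_controls < 0 or n_proteins < 1:
        raise InvalidDesignError("invalid matrix dimensions")
    probs = {
        "true_in_assay": detection_probs.get("true_in_assay", 0.8),
        "true_in_control": detection_probs.get("true_in_control", 0.0),
        "background_in_assay": detection_probs.get("background_in_assay", 0.05),
        "background_in_control": detection_probs.get("background_in_control", 0.5),
    }
    for key, val in probs.items():
        if not (0.0 <= val <= 1.0):
            raise ValueError(f"detection probability {key}={val} outside [0, 1]")
    if not (0.0 <= frac_true <= 1.0):
        raise ValueError("frac_true must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    proteins = [f"P{i + 1:04d}" for i in range(n_proteins)]
    is_true = pd.Series(rng.random(n_proteins) < frac_true, index=proteins, name="is_true_interactor")
    split = n_experiments // 2 if species_split is None else species_split
    labels, species, is_ctrl = [], [], []
    for i in range(n_experiments):
        labels.append(f"IP{i + 1}")
        species.append("mouse" if i < split else "human")
        is_ctrl.append(False)
    for i in range(n_controls):
        labels.append(f"CTRL{i + 1}")
        species.append("mouse" if i % 2 == 0 else "human")
        is_ctrl.append(True)
    det = np.zeros((n_proteins, len(labels)), dtype=bool)
    for j, ctrl in enumerate(is_ctrl):
        p_true = probs["true_in_control"] if ctrl else probs["true_in_assay"]
        p_bg = probs["background_in_control"] if ctrl else probs["background_in_assay"]
        p_col = np.where(is_true.to_numpy(), p_true, p_bg)
        det[:, j] = rng.random(n_proteins) < p_col
    matrix = DetectionMatrix(
        pd.DataFrame(det, index=proteins, columns=labels),
        pd.DataFrame({"species": species, "is_negative_control": is_ctrl}, index=pd.Index(labels, name="experiment")),
    )
    return matrix, is_true


def write_run_manifest(path, seed: int, **parameters) -> None:
    """JSON manifest recording the seed and generator parameters."""
    with open(path, "w") as fh:
        json.dump({"seed": seed, "parameters": parameters}, fh, indent=2, default=str)
        fh.write("\n")
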