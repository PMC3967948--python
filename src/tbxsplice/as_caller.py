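"""Four-filter caller for differential cassette-exon usage.

Each event is tested per compartment by pooling replicate counts into a
2x2 table (condition x {alternative-exon reads, gene-remainder reads}) and
applying four conjunctive filters:

* two-sided Fisher's exact test p <= 0.05,
* Bayesian error rate <= 0.1 (a q-value-style posterior error bound,
  computed across all events of the compartment),
* fold change of the exon-usage ratio >= 1.5,
* total reads supporting the event >= 15.

The direction of an event states what the ablated factor does in the
wild type: if the mutant inclusion level drops, the factor promotes
inclusion; if it rises, the factor promotes skipping.  Anterior and
posterior limb compartments are tested independently, so one event can be
called with opposite directions in the two compartments.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exon_quant import (
    DataIntegrityError,
    SpliceEventAnnotation,
    rpkm,
    rpkm_pseudocount,
    usage_ratio,
    validate_counts,
)

__all__ = [
    "ASThresholds",
    "ASCall",
    "Direction",
    "build_contingency",
    "fisher_exact_two_sided",
    "fold_change",
    "bayesian_error_rate",
    "classify_direction",
    "call_events",
    "calls_to_frame",
    "write_significant_bed",
]

#: relative tolerance for point-probability ties in the two-sided Fisher sum
FISHER_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ASThresholds:
    """Significance thresholds of the filter cascade (all overridable)."""

    p_max: float = 0.05
    ber_max: float = 0.1
    fc_min: float = 1.5
    min_support: int = 15

    def __post_init__(self) -> None:
        if not (0 < self.p_max <= 1) or not (0 < self.ber_max <= 1):
            raise ValueError("p_max and ber_max must lie in (0, 1]")
        if self.fc_min < 1:
            raise ValueError("fc_min must be >= 1")
        if self.min_support < 0:
            raise ValueError("min_support must be >= 0")


class Direction(str, enum.Enum):
    """What the factor does to the exon in the wild type."""

    INCLUSION = "factor-promotes-inclusion"
    SKIPPING = "factor-promotes-skipping"
    NONE = "none"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


@dataclass
class ASCall:
    event_id: str
    comparison: str
    p: float
    ber: float
    fc: float
    support: int
    psi_ctl: float
    psi_mut: float
    direction: Direction
    significant: bool
    pass_p: bool = False
    pass_ber: bool = False
    pass_fc: bool = False
    pass_support: bool = False
    informative: bool = True


def build_contingency(
    counts: pd.DataFrame,
    event_id: str,
    comparison: str,
    conditions: Sequence[str] = ("control", "mutant"),
) -> np.ndarray:
    """Pool replicates into the 2x2 table for one event in one compartment.

    Rows are the two conditions; columns are alternative-exon reads and
    gene-remainder reads (gene_count - exon_count).
    """
    sub = counts[(counts["event_id"] == event_id) & (counts["compartment"] == comparison)]
    table = np.zeros((2, 2), dtype=np.int64)
    for i, cond in enumerate(conditions):
        grp = sub[sub["condition"] == cond]
        if grp.empty:
            raise ValueError(f"{event_id}/{comparison}: no samples for condition {cond!r}")
        exon = int(grp["exon_count"].sum())
        gene = int(grp["gene_count"].sum())
        if gene < exon:
            raise DataIntegrityError(f"{event_id}: gene_count < exon_count in {cond}")
        table[i] = (exon, gene - exon)
    return table


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher's exact test by the point-probability rule.

    Sums, over all tables with the observed margins, the hypergeometric
    probabilities not exceeding that of the observed table (ties admitted
    within relative tolerance 1e-7).  Degenerate margins (an all-zero row
    or column) return p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be a non-negative 2x2 integer array")
    a = int(t[0, 0])
    r1, r2 = int(t[0].sum()), int(t[1].sum())
    c1 = int(t[:, 0].sum())
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[a - lo]
    mask = pmf <= p_obs * (1.0 + FISHER_TIE_RTOL)
    if mask.all():
        return 1.0
    p = float(pmf[mask].sum())
    return min(1.0, max(p, np.nextafter(0.0, 1.0)))


def fold_change(psi_ctl: float, psi_mut: float) -> float:
    """Symmetric fold change max(ctl/mut, mut/ctl); inputs must be > 0."""
    if psi_ctl <= 0 or psi_mut <= 0:
        raise ValueError("usage ratios must be positive (pseudocount upstream)")
    return max(psi_ctl / psi_mut, psi_mut / psi_ctl)


def bayesian_error_rate(p_values) -> np.ndarray:
    """Per-event error estimate from the compartment's p-value vector.

    A q-value-style posterior error bound: the null fraction pi0 is
    estimated from the upper half of the p distribution,
    pi0 = min(1, mean(p > 0.5) / 0.5), and the rate at event i is
    min over thresholds t >= p_i of pi0 * t * M / rank(t), capped at 1.
    Monotone non-decreasing in p.  This estimator stands in for the
    original study's per-event error rate, whose exact definition is not
    public; thresholding it at 0.1 behaves like a false-discovery bound.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    pi0 = min(1.0, float(np.mean(p > 0.5)) / 0.5)
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    q = pi0 * p[order] * m / ranks
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def classify_direction(psi_ctl: float, psi_mut: float, min_delta: float = 0.05) -> Direction:
    """Loss-of-function logic: mutant inclusion below control means the
    factor promotes inclusion; above control, it promotes skipping."""
    if psi_mut < psi_ctl - min_delta:
        return Direction.INCLUSION
    if psi_mut > psi_ctl + min_delta:
        return Direction.SKIPPING
    return Direction.NONE


def call_events(
    counts: pd.DataFrame,
    annotation: Iterable[SpliceEventAnnotation],
    thresholds: ASThresholds = ASThresholds(),
    *,
    conditions: Sequence[str] = ("control", "mutant"),
    min_delta: float = 0.05,
    raw_rpkm_fc: bool = False,
) -> list[ASCall]:
    """Run the full filter cascade on every event x compartment.

    Replicates are pooled by summation; the Bayesian error rate is computed
    across all events separately within each compartment.  Support is the
    total alternative-exon read count over all samples of the comparison.
    With ``raw_rpkm_fc`` the fold change is taken on raw exon RPKM instead
    of the usage ratio (so gene-level expression changes are not factored
    out); the default usage-ratio mode is recommended.
    """
    validate_counts(counts)
    events = {ev.event_id: ev for ev in annotation}
    missing = set(counts["event_id"]) - set(events)
    if missing:
        raise ValueError(f"count table has events absent from annotation: {sorted(missing)[:5]}")
    calls: list[ASCall] = []
    for comp, comp_counts in counts.groupby("compartment", sort=False):
        comp_calls: list[ASCall] = []
        for event_id, sub in comp_counts.groupby("event_id", sort=False):
            ev = events[event_id]
            table = build_contingency(comp_counts, event_id, comp, conditions)
            informative = table.sum() > 0 and table.sum(axis=1).min() > 0
            p = fisher_exact_two_sided(table)
            support = int(sub["exon_count"].sum())
            psis = []
            fc_inputs = []
            for cond in conditions:
                grp = sub[sub["condition"] == cond]
                lib = max(1, int(grp["library_size"].sum()))
                eps = rpkm_pseudocount(lib)
                r_ex = rpkm(int(grp["exon_count"].sum()), ev.alt_length, lib)
                r_gn = rpkm(int(grp["gene_count"].sum()), ev.gene_length, lib)
                psis.append(usage_ratio(r_ex, r_gn, eps))
                fc_inputs.append(r_ex + eps if raw_rpkm_fc else psis[-1])
            psi_ctl, psi_mut = psis
            fc = fold_change(*fc_inputs)
            direction = classify_direction(psi_ctl, psi_mut, min_delta)
            comp_calls.append(
                ASCall(
                    event_id=event_id,
                    comparison=str(comp),
                    p=p,
                    ber=1.0,  # filled below, once the compartment's p vector is complete
                    fc=fc,
                    support=support,
                    psi_ctl=psi_ctl,
                    psi_mut=psi_mut,
                    direction=direction,
                    significant=False,
                    informative=bool(informative),
                )
            )
        bers = bayesian_error_rate([c.p for c in comp_calls])
        for call, ber in zip(comp_calls, bers):
            call.ber = float(ber)
            call.pass_p = call.p <= thresholds.p_max
            call.pass_ber = call.ber <= thresholds.ber_max
            call.pass_fc = call.fc >= thresholds.fc_min
            call.pass_support = call.support >= thresholds.min_support
            call.significant = call.pass_p and call.pass_ber and call.pass_fc and call.pass_support
        calls.extend(comp_calls)
    return calls


def calls_to_frame(calls: Iterable[ASCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "event_id": c.event_id,
                "comparison": c.comparison,
                "p": c.p,
                "ber": c.ber,
                "fc": c.fc,
                "support": c.support,
                "psi_ctl": c.psi_ctl,
                "psi_mut": c.psi_mut,
                "direction": str(c.direction),
                "significant": c.significant,
                "pass_p": c.pass_p,
                "pass_ber": c.pass_ber,
                "pass_fc": c.pass_fc,
                "pass_support": c.pass_support,
                "informative": c.informative,
            }
        )
    return pd.DataFrame(rows)


def write_significant_bed(
    calls: Iterable[ASCall], annotation: Iterable[SpliceEventAnnotation], path
) -> None:
    """BED6 of significant alternative exons, for downstream motif scanning."""
    events = {ev.event_id: ev for ev in annotation}
    seen = set()
    with open(path, "w") as fh:
        for c in calls:
            if not c.significant or c.event_id in seen:
                continue
            seen.add(c.event_id)
            ev = events[c.event_id]
            for s, e in ev.alt_exons:
                fh.write(f"{ev.chrom}\t{s}\t{e}\t{ev.event_id}\t0\t{ev.strand}\n")
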