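"""IP-MS interactome filtering and category fold-enrichment.

Affinity-purification mass spectrometry (IP-MS) screens call a protein an
interactor when it is detected in at least two independent IP-MS datasets
and in no negative-control IP.  This module applies that presence-based
rule to a protein x experiment detection matrix, counts cross-species
(mouse/human) overlap of the retained set, and computes category
fold-enrichment against a proteome background with an upper-tail
hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DetectionMatrix",
    "CrossSpeciesOverlap",
    "filter_interactors",
    "cross_species_overlap",
    "fold_enrichment",
    "enrich_categories",
]


@dataclass
class DetectionMatrix:
    """Boolean protein x experiment detections plus experiment metadata.

    ``detections``: DataFrame indexed by protein identifier (unique,
    case-preserved), one boolean column per experiment label.
    ``experiments``: DataFrame indexed by experiment label with columns
    ``species`` (mouse/human) and ``is_negative_control``.
    """

    detections: pd.DataFrame
    experiments: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.detections.index.is_unique:
            raise ValueError("protein identifiers must be unique")
        if list(self.detections.columns) != list(self.experiments.index):
            raise ValueError("detection columns must match experiment metadata index")
        if not (~self.experiments["is_negative_control"]).any():
            raise ValueError("need at least one non-control experiment")
        self.detections = self.detections.astype(bool)

    @property
    def assay_labels(self) -> list[str]:
        return list(self.experiments.index[~self.experiments["is_negative_control"]])

    @property
    def control_labels(self) -> list[str]:
        return list(self.experiments.index[self.experiments["is_negative_control"]])

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame) -> "DetectionMatrix":
        """Build from long TSV rows: protein, experiment, species, is_control, detected."""
        wide = (
            df.pivot_table(index="protein", columns="experiment", values="detected",
                           aggfunc="max", fill_value=0)
            .astype(bool)
        )
        meta = (
            df[["experiment", "species", "is_control"]]
            .drop_duplicates("experiment")
            .set_index("experiment")
            .rename(columns={"is_control": "is_negative_control"})
        )
        meta["is_negative_control"] = meta["is_negative_control"].astype(bool)
        return cls(wide[list(meta.index)], meta)

    @classmethod
    def read_tsv(cls, path) -> "DetectionMatrix":
        return cls.from_long_frame(pd.read_csv(path, sep="\t"))

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for exp in self.detections.columns:
            meta = self.experiments.loc[exp]
            for protein, det in self.detections[exp].items():
                rows.append(
                    (protein, exp, meta["species"], bool(meta["is_negative_control"]), int(det))
                )
        return pd.DataFrame(rows, columns=["protein", "experiment", "species", "is_control", "detected"])


def filter_interactors(
    matrix: DetectionMatrix,
    min_datasets: int = 2,
    *,
    within_single_species: bool = False,
) -> list[str]:
    """Proteins detected in >= min_datasets non-control IP-MS experiments
    and in zero negative-control IPs.

    By default "independent datasets" pools experiments across species;
    with ``within_single_species`` the detection threshold must be met
    inside at least one species on its own.
    """
    if min_datasets < 1:
        raise ValueError("min_datasets must be >= 1")
    det = matrix.detections
    if det.empty:
        return []
    in_control = det[matrix.control_labels].any(axis=1) if matrix.control_labels else pd.Series(False, index=det.index)
    assays = matrix.experiments.loc[matrix.assay_labels]
    if within_single_species:
        enough = pd.Series(False, index=det.index)
        for _, grp in assays.groupby("species"):
            enough |= det[list(grp.index)].sum(axis=1) >= min_datasets
    else:
        enough = det[matrix.assay_labels].sum(axis=1) >= min_datasets
    keep = enough & ~in_control
    return sorted(det.index[keep])


@dataclass(frozen=True)
class CrossSpeciesOverlap:
    total: int
    in_both: int
    per_protein: Mapping[str, tuple[bool, bool]]  # (mouse, human) detection flags


def cross_species_overlap(interactors: Iterable[str], matrix: DetectionMatrix) -> CrossSpeciesOverlap:
    """How many interactors were detected (non-control) in both species.

    Cross-species identity is by shared identifier, compared
    case-insensitively (mouse and human gene symbols differ in case).
    """
    assays = matrix.experiments.loc[matrix.assay_labels]
    species = sorted(assays["species"].unique())
    if len(species) < 2:
        raise ValueError(f"need experiments from both species, found only {species}")
    det = matrix.detections
    flags: dict[str, tuple[bool, bool]] = {}
    interactors = list(interactors)
    index_by_fold = {p.lower(): p for p in det.index}
    for protein in interactors:
        key = index_by_fold.get(protein.lower())
        if key is None:
            flags[protein] = (False, False)
            continue
        per_species = []
        for sp in ("mouse", "human"):
            labels = list(assays.index[assays["species"] == sp])
            per_species.append(bool(det.loc[key, labels].any()) if labels else False)
        flags[protein] = tuple(per_species)
    in_both = sum(m and h for m, h in flags.values())
    return CrossSpeciesOverlap(len(interactors), in_both, flags)


def fold_enrichment(
    k_in_set: int, n_set: int, K_background: int, N_background: int
) -> tuple[float, float]:
    """Category fold-enrichment (k/n)/(K/N) and hypergeometric upper-tail p.

    p = P(X >= k) for X ~ Hypergeom drawing n_set from N_background with
    K_background category members.
    """
    if n_set <= 0 or N_background <= 0 or K_background <= 0:
        raise ValueError("set and background sizes must be positive")
    if not (0 <= k_in_set <= n_set) or K_background > N_background or k_in_set > K_background:
        raise ValueError("inconsistent counts: need k <= n, k <= K, K <= N")
    fold = (k_in_set / n_set) / (K_background / N_background)
    p = float(stats.hypergeom.sf(k_in_set - 1, N_background, K_background, n_set))
    return fold, min(1.0, max(p, float(np.nextafter(0.0, 1.0))))


def enrich_categories(
    interactors: Iterable[str],
    protein_categories: Mapping[str, set],
    background: Mapping[str, tuple[int, int]],
) -> pd.DataFrame:
    """Fold-enrichment per category term over an interactor set.

    ``protein_categories`` maps protein -> set of category terms (e.g. GO
    annotations supplied as input); ``background`` maps term -> (K members
    in proteome, N proteome size).
    """
    interactors = list(interactors)
    n = len(interactors)
    rows = []
    for term, (K, N) in background.items():
        k = sum(term in protein_categories.get(p, ()) for p in interactors)
        fold, p = fold_enrichment(k, n, K, N) if k > 0 else (0.0, 1.0)
        rows.append((term, k, n, K, N, fold, p))
    return pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "fold", "p"])
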