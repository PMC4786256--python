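"""16S-informed species-specificity classification of Lactobacillus proteins.

The Lactobacillus reference databases are redundant and highly homologous, so
a search-engine best match alone does not establish which species a shared
protein came from. The classifier therefore combines two criteria:

1. the search best match is the species itself or a "Lactobacillus
   multispecies" entry, and
2. the mean ion intensity in the species-dominated VMB cluster (the *target*
   group) is at least ``fold_threshold``-fold (default 2) higher than in
   women who are 16S-negative for that species (the *reference* group), and
   the median ion intensity is equal to or higher.

The reference group is defined purely by 16S negativity for the species,
across all clusters. A "multispecies"-matched protein is a candidate for
both species but may be assigned to at most one; if it passes both species'
criteria the larger fold change wins by default (an exact tie falls back to
nonspecific) — the published criteria never had to break such a tie.

Zero-intensity conventions: a positive target mean over a zero reference
mean is an infinite fold change and passes the fold criterion; two zero
means fail it (an entirely undetected protein is nonspecific).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data_model import (
    AbundanceMatrix,
    ClassificationDecision,
    ProteinRecord,
    SampleRecord,
    SpeciesEvaluation,
    SPECIES,
    ValidationError,
)

log = logging.getLogger(__name__)

#: The VMB cluster dominated by each species (its target cluster).
DOMINANT_GROUP = {"L_iners": "G2_iners", "L_crispatus": "G1_crispatus"}

TARGET_RULES = ("cluster_members", "cluster_members_16s_positive")
TIEBREAKS = ("higher_fold", "nonspecific")


class ClassificationError(RuntimeError):
    """Raised when target/reference groups cannot be constructed."""


@dataclass(frozen=True)
class ClassifierConfig:
    fold_threshold: float = 2.0
    target_rule: str = "cluster_members"
    multispecies_tiebreak: str = "higher_fold"

    def __post_init__(self) -> None:
        if not self.fold_threshold > 0:
            raise ValidationError("fold_threshold must be positive")
        if self.target_rule not in TARGET_RULES:
            raise ValidationError(f"target_rule must be one of {TARGET_RULES}")
        if self.multispecies_tiebreak not in TIEBREAKS:
            raise ValidationError(f"multispecies_tiebreak must be one of {TIEBREAKS}")


def candidate_species(protein: ProteinRecord) -> tuple[str, ...]:
    """Candidate species set from the search best match (criterion 1)."""
    if protein.best_match in SPECIES:
        return (protein.best_match,)
    if protein.best_match == "multispecies":
        return SPECIES
    return ()


def target_samples(
    species: str,
    samples: Sequence[SampleRecord],
    config: ClassifierConfig = ClassifierConfig(),
) -> list[SampleRecord]:
    """Target group: members of the species-dominated cluster, optionally
    restricted to those with a positive 16S result for the species."""
    if species not in SPECIES:
        raise ValueError(f"species must be one of {SPECIES}, got {species!r}")
    group = DOMINANT_GROUP[species]
    target = [s for s in samples if s.vmb_group == group]
    if config.target_rule == "cluster_members_16s_positive":
        target = [s for s in target if s.is_positive(species)]
    if not target:
        raise ClassificationError(f"no target samples for {species}")
    return target


def reference_samples(species: str, samples: Sequence[SampleRecord]) -> list[SampleRecord]:
    """Reference group: every sample 16S-negative for the species, regardless
    of cluster."""
    if species not in SPECIES:
        raise ValueError(f"species must be one of {SPECIES}, got {species!r}")
    reference = [s for s in samples if not s.is_positive(species)]
    if not reference:
        raise ClassificationError(f"no reference samples for {species}")
    return reference


def evaluate_species(
    row: Mapping[str, float],
    target: Sequence[SampleRecord],
    reference: Sequence[SampleRecord],
    config: ClassifierConfig = ClassifierConfig(),
    species: str = "",
    best_match_ok: bool = True,
) -> SpeciesEvaluation:
    """Evaluate the intensity criteria (criterion 2) for one protein row.

    ``row`` maps sample_id -> intensity. Means and medians are computed on
    the raw (untransformed) normalized intensities.
    """
    if not target or not reference:
        raise ClassificationError("target and reference sets must be non-empty")
    t = np.asarray([float(row[s.sample_id]) for s in target])
    r = np.asarray([float(row[s.sample_id]) for s in reference])
    if (t < 0).any() or (r < 0).any():
        raise ValidationError("negative intensities in abundance row")
    t_mean, r_mean = float(t.mean()), float(r.mean())
    t_med, r_med = float(np.median(t)), float(np.median(r))
    if r_mean == 0.0:
        if t_mean > 0.0:
            fold = float("inf")
            fold_ok = True
        else:
            fold = 0.0
            fold_ok = False
    else:
        fold = t_mean / r_mean
        fold_ok = fold >= config.fold_threshold
    return SpeciesEvaluation(
        species=species,
        target_mean=t_mean,
        reference_mean=r_mean,
        target_median=t_med,
        reference_median=r_med,
        fold_change=fold,
        best_match_ok=best_match_ok,
        fold_ok=fold_ok,
        median_ok=t_med >= r_med,
    )


def classify_protein(
    protein: ProteinRecord,
    matrix: AbundanceMatrix,
    samples: Sequence[SampleRecord],
    config: ClassifierConfig = ClassifierConfig(),
) -> ClassificationDecision:
    """Assign one protein to L. iners, L. crispatus, or nonspecific."""
    row = matrix.row(protein.accession)
    evaluations: list[SpeciesEvaluation] = []
    passing: list[SpeciesEvaluation] = []
    for species in candidate_species(protein):
        ev = evaluate_species(
            row,
            target_samples(species, samples, config),
            reference_samples(species, samples),
            config,
            species=species,
            best_match_ok=True,
        )
        evaluations.append(ev)
        if ev.passed:
            passing.append(ev)
    if not passing:
        assigned = "nonspecific"
    elif len(passing) == 1:
        assigned = passing[0].species
    else:
        # A multispecies protein passing both species' criteria.
        if config.multispecies_tiebreak == "nonspecific":
            assigned = "nonspecific"
        else:
            folds = [ev.fold_change for ev in passing]
            if folds[0] == folds[1]:
                assigned = "nonspecific"
            else:
                assigned = passing[int(np.argmax(folds))].species
    return ClassificationDecision(
        accession=protein.accession, assigned=assigned, evaluations=tuple(evaluations)
    )


def classify_all(
    proteins: Sequence[ProteinRecord],
    matrix: AbundanceMatrix,
    samples: Sequence[SampleRecord],
    config: ClassifierConfig = ClassifierConfig(),
) -> tuple[list[ClassificationDecision], dict]:
    """Classify every protein; return decisions and summary counts.

    The summary reports, per species, the number of candidate proteins
    (best match = species or multispecies) and the number assigned, plus the
    nonspecific count. Candidate counts overlap for multispecies proteins;
    assignment counts partition the input.
    """
    decisions = [classify_protein(p, matrix, samples, config) for p in proteins]
    candidates = {
        sp: sum(1 for p in proteins if sp in candidate_species(p)) for sp in SPECIES
    }
    assigned = {sp: sum(1 for d in decisions if d.assigned == sp) for sp in SPECIES}
    n_nonspecific = sum(1 for d in decisions if d.assigned == "nonspecific")
    summary = {
        "n_proteins": len(proteins),
        "candidates": candidates,
        "assigned": assigned,
        "nonspecific": n_nonspecific,
    }
    log.info("classification summary: %s", summary)
    return decisions, summary
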