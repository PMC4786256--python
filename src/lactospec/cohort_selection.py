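"""Analysis cohorts, vaginal pH categories, and S/B abundance strata.

Comparative protein analyses include only samples with a positive 16S result
for the species in question within each VMB group. Vaginal pH is binned into
three categories for the L. iners analyses (4-5, 5-6, >=6) and, because of
the smaller sample size, two for the L. crispatus analyses (4-5, >=5).
Bins are half-open on the left label's upper edge ("4-5" = [4, 5)): with a
cohort median pH of 5 and published bin sizes of 7/18/6, a reading of 5.0
must fall in the "5-6" bin. L. iners analyses are additionally stratified by
L. iners 16S abundance, either at the cohort median S/B ratio or at a fixed
threshold (published: S/B > 70), with the strict ">" on both rules so that
ties go to the low stratum.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import PH_MAX, SPECIES, VMB_GROUPS, SampleRecord, ValidationError

log = logging.getLogger(__name__)


class CohortError(RuntimeError):
    """Raised when a cohort or stratum cannot be constructed."""


@dataclass(frozen=True)
class CategoryScheme:
    """An ordered pH binning: label i covers [boundaries[i], boundaries[i+1]),
    the last bin is closed above at pH 9.0 (the top of the strip scale)."""

    name: str
    boundaries: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.boundaries) != len(self.labels):
            raise ValidationError("one boundary per label required")
        if len(self.boundaries) < 2:
            raise ValidationError("need at least two categories")
        if any(b >= c for b, c in zip(self.boundaries, self.boundaries[1:])):
            raise ValidationError("boundaries must be strictly increasing")
        if self.boundaries[-1] > PH_MAX:
            raise ValidationError("top boundary exceeds the pH scale")


#: Three pH categories used for the L. iners protein analyses.
PH_THREE_BIN = CategoryScheme("ph3_iners", (4.0, 5.0, 6.0), ("4-5", "5-6", ">=6"))
#: Two pH categories used for the L. crispatus protein analyses.
PH_TWO_BIN = CategoryScheme("ph2_crispatus", (4.0, 5.0), ("4-5", ">=5"))

#: Default scheme per species.
SCHEME_FOR_SPECIES = {"L_iners": PH_THREE_BIN, "L_crispatus": PH_TWO_BIN}


def ph_category_index(ph: float, scheme: CategoryScheme = PH_THREE_BIN) -> int:
    """0-based bin index of a pH reading; readings below the lowest boundary
    map to bin 0 with a logged warning (none occur in the published range)."""
    if ph < scheme.boundaries[0]:
        log.warning(
            "pH %.1f below the lowest %s boundary %.1f; assigned to bin %r",
            ph,
            scheme.name,
            scheme.boundaries[0],
            scheme.labels[0],
        )
        return 0
    return bisect_right(scheme.boundaries, ph) - 1


def ph_category(ph: float, scheme: CategoryScheme = PH_THREE_BIN) -> str:
    """Label of the pH bin containing ``ph`` under ``scheme``."""
    return scheme.labels[ph_category_index(ph, scheme)]


def analysis_cohort(
    species: str, samples: Sequence[SampleRecord]
) -> dict[str, list[SampleRecord]]:
    """Per-VMB-group analysis cohort for a species: the 16S-positive samples.

    All four groups appear as keys; groups without positive samples map to an
    empty list (they are reported with n = 0 and skipped in pairwise testing).
    """
    if species not in SPECIES:
        raise ValueError(f"species must be one of {SPECIES}, got {species!r}")
    cohort: dict[str, list[SampleRecord]] = {g: [] for g in VMB_GROUPS}
    for sample in samples:
        if sample.is_positive(species):
            cohort[sample.vmb_group].append(sample)
    return cohort


def cohort_members(cohort: dict[str, list[SampleRecord]]) -> list[SampleRecord]:
    """Flatten a per-group cohort in group order."""
    return [s for g in VMB_GROUPS for s in cohort.get(g, ())]


def abundance_strata(
    samples: Sequence[SampleRecord],
    species: str,
    mode: str = "median_split",
    threshold: float | None = None,
) -> tuple[list[SampleRecord], list[SampleRecord]]:
    """Split samples into (high, low) strata by the species' 16S S/B ratio.

    ``median_split``: high = S/B strictly above the median of the given
    samples (ties at the median go low). ``fixed_threshold``: high = S/B
    strictly above ``threshold``.
    """
    if not samples:
        raise CohortError("cannot stratify an empty sample set")
    if mode == "median_split":
        cut = float(np.median([s.sb(species) for s in samples]))
    elif mode == "fixed_threshold":
        if threshold is None:
            raise ValueError("fixed_threshold mode requires a threshold")
        cut = float(threshold)
    else:
        raise ValueError(f"unknown stratification mode {mode!r}")
    high = [s for s in samples if s.sb(species) > cut]
    low = [s for s in samples if s.sb(species) <= cut]
    return high, low
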