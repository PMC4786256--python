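"""Post-identification protein inclusion rules.

A bacterial protein identification is retained when it has at least one
unique peptide and at least two peptides overall (counting non-unique
peptides). A protein supported by exactly one unique peptide is additionally
required to show consistent differential abundance across microbiota groups
(quantification-software ANOVA p < 0.05, strict) and a series of at least
four continuous fragment ions on manual inspection of its MS/MS spectra.
Spectra themselves are out of scope here, so the fragment-ion criterion
enters as a boolean flag; a missing flag (or missing ANOVA p) fails the
rescue rule, which is the conservative choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .data_model import ProteinRecord

ANOVA_ALPHA = 0.05  # strict "<", per the published threshold

#: Reason codes, in the order the clauses are checked.
REASON_OK = "ok"
REASON_NO_UNIQUE = "no-unique-peptide"
REASON_TOO_FEW_PEPTIDES = "fewer-than-two-peptides"
REASON_MISSING_METADATA = "insufficient-evidence-metadata"
REASON_ANOVA = "rescue-anova-p"
REASON_FRAGMENT = "rescue-fragment-series"


@dataclass(frozen=True)
class InclusionDecision:
    accession: str
    included: bool
    reason: str


def passes_inclusion(protein: ProteinRecord) -> InclusionDecision:
    """Apply the inclusion rule to one protein record.

    Returns an :class:`InclusionDecision` whose ``reason`` names the first
    failed clause (``"ok"`` when the record is included).
    """
    if protein.unique_peptides < 1:
        return InclusionDecision(protein.accession, False, REASON_NO_UNIQUE)
    if protein.peptide_count < 2:
        return InclusionDecision(protein.accession, False, REASON_TOO_FEW_PEPTIDES)
    if protein.unique_peptides >= 2:
        return InclusionDecision(protein.accession, True, REASON_OK)
    # Rescue path: exactly one unique peptide.
    if protein.anova_p is None or protein.fragment_series_ok is None:
        return InclusionDecision(protein.accession, False, REASON_MISSING_METADATA)
    if not protein.anova_p < ANOVA_ALPHA:
        return InclusionDecision(protein.accession, False, REASON_ANOVA)
    if not protein.fragment_series_ok:
        return InclusionDecision(protein.accession, False, REASON_FRAGMENT)
    return InclusionDecision(protein.accession, True, REASON_OK)


def filter_proteins(
    proteins: Sequence[ProteinRecord],
) -> tuple[list[ProteinRecord], list[tuple[ProteinRecord, str]]]:
    """Partition records into (included, excluded-with-reason), keeping order."""
    included: list[ProteinRecord] = []
    excluded: list[tuple[ProteinRecord, str]] = []
    for protein in proteins:
        decision = passes_inclusion(protein)
        if decision.included:
            included.append(protein)
        else:
            excluded.append((protein, decision.reason))
    return included, excluded
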