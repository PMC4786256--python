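"""Box-plot figures of per-group and per-pH-category protein abundance."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .cohort_selection import SCHEME_FOR_SPECIES, analysis_cohort, cohort_members, ph_category
from .data_model import AbundanceMatrix, SampleRecord, TABLE1_ABBREVIATIONS, VMB_GROUPS

_GROUP_SHORT = {
    "G1_crispatus": "L. crispatus\ndominated",
    "G2_iners": "L. iners\ndominated",
    "G3_moderate": "moderate\ndysbiosis",
    "G4_severe": "severe\ndysbiosis",
}


def _boxes(ax, groups: Mapping[str, Sequence[float]], title: str) -> None:
    labels = [lbl for lbl, vals in groups.items() if len(vals)]
    data = [groups[lbl] for lbl in labels]
    ax.boxplot(data, tick_labels=labels, whis=1.5)
    ax.set_yscale("log")
    ax.set_title(title, fontsize=9)
    ax.tick_params(axis="x", labelsize=7)


def abundance_boxplots(
    matrix: AbundanceMatrix,
    samples: Sequence[SampleRecord],
    accessions: Sequence[str],
    species: str,
    by: str = "vmb_group",
    path=None,
):
    """Grid of box plots, one panel per protein, grouped by VMB group or pH
    category, over the species' analysis cohort. Returns the figure."""
    members = cohort_members(analysis_cohort(species, samples))
    scheme = SCHEME_FOR_SPECIES[species]
    n = len(accessions)
    ncols = min(4, max(1, n))
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.8 * nrows), squeeze=False)
    for k, accession in enumerate(accessions):
        ax = axes[k // ncols][k % ncols]
        row = matrix.row(accession)
        if by == "vmb_group":
            groups = {
                _GROUP_SHORT[g]: [row[s.sample_id] for s in members if s.vmb_group == g]
                for g in VMB_GROUPS
            }
        elif by == "ph_category":
            groups = {lbl: [] for lbl in scheme.labels}
            for s in members:
                groups[ph_category(s.vaginal_ph, scheme)].append(row[s.sample_id])
        else:
            raise ValueError(f"unknown grouping {by!r}")
        _boxes(ax, groups, TABLE1_ABBREVIATIONS.get(accession, accession))
    for k in range(n, nrows * ncols):
        axes[k // ncols][k % ncols].set_axis_off()
    fig.suptitle(f"{species} proteins, n={len(members)} 16S-positive samples", fontsize=10)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
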