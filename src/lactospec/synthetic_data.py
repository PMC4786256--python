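"""Synthetic cohorts, 16S abundances, and intensity matrices with planted truth.

The generator emulates the statistical structure the downstream analyses
assume, so every stage of the pipeline can be exercised with known ground
truth and no external data:

* a cohort of samples in the four VMB groups, each with a vaginal pH drawn
  from a group-specific distribution on the 0.5 strip grid (dysbiotic groups
  skew toward higher pH, mirroring the published pH/group association) and
  per-taxon 16S S/B ratios drawn log-normally for 16S-positive samples;
* a protein list with realistic peptide-evidence fields; species-specific
  proteins carry their true species as the search best match, or
  "multispecies" with configurable probability;
* an intensity matrix generated on the log10 scale:

  ``log10(value) = base + species_effect * 1[sample 16S-positive for the
  protein's true species] + dysbiosis_effect * 1[group in {G3, G4}] +
  ph_effect * (pH category index, three-bin scheme) + Normal(0, noise_sd)``

  Samples *negative* for a specific protein's species draw that protein from
  the pure background ``base + Normal(0, noise_sd)`` (the protein is simply
  absent there, so the group/pH terms do not apply). Nonspecific proteins
  omit the species term but keep the dysbiosis and pH terms for all samples,
  mimicking shared Lactobacillus proteins that track overall community state.

Randomness is split into three independent sub-streams (samples, proteins,
matrix) spawned from the single seed, so changing the number of proteins
does not perturb the generated cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .cohort_selection import PH_THREE_BIN, ph_category_index
from .data_model import (
    AbundanceMatrix,
    DYSBIOTIC_GROUPS,
    ProteinRecord,
    SampleRecord,
    SPECIES,
    VMB_GROUPS,
    check_ph,
)


class ConfigurationError(ValueError):
    """Raised for an invalid simulation configuration."""


def _default_n_per_group() -> dict[str, int]:
    # The study cohort: 7 / 11 / 14 / 18 women.
    return {
        "G1_crispatus": 7,
        "G2_iners": 11,
        "G3_moderate": 14,
        "G4_severe": 18,
    }


def _default_positivity() -> dict[str, dict[str, float]]:
    # Per-group probability of a positive 16S result per species; the default
    # rates reproduce the published per-group positivity fractions
    # (iners 0/11, 11/11, 12/14, 8/18; crispatus 5/7, 4/11, 2/14, 2/18).
    return {
        "L_iners": {
            "G1_crispatus": 0.0,
            "G2_iners": 1.0,
            "G3_moderate": 12 / 14,
            "G4_severe": 8 / 18,
        },
        "L_crispatus": {
            "G1_crispatus": 5 / 7,
            "G2_iners": 4 / 11,
            "G3_moderate": 2 / 14,
            "G4_severe": 2 / 18,
        },
    }


def _default_sb_lognormal() -> dict[str, dict[str, tuple[float, float]]]:
    # (mu, sigma) of log10 S/B for 16S-positive samples; dominated clusters
    # carry roughly tenfold higher microarray signal than dysbiotic ones.
    return {
        "L_iners": {
            "G1_crispatus": (1.0, 0.4),
            "G2_iners": (2.0, 0.35),
            "G3_moderate": (1.7, 0.45),
            "G4_severe": (1.5, 0.45),
        },
        "L_crispatus": {
            "G1_crispatus": (2.2, 0.35),
            "G2_iners": (1.3, 0.45),
            "G3_moderate": (1.0, 0.45),
            "G4_severe": (1.0, 0.45),
        },
    }


def _default_ph_distribution() -> dict[str, dict[float, float]]:
    # Group-specific pH distributions on the 0.5 grid; the mixture reproduces
    # the published overall picture (median pH 5, range 4-7, dysbiosis skewed
    # toward higher pH).
    return {
        "G1_crispatus": {4.0: 0.6, 4.5: 0.4},
        "G2_iners": {4.0: 0.15, 4.5: 0.25, 5.0: 0.4, 5.5: 0.2},
        "G3_moderate": {4.5: 0.1, 5.0: 0.35, 5.5: 0.3, 6.0: 0.15, 6.5: 0.1},
        "G4_severe": {5.0: 0.15, 5.5: 0.25, 6.0: 0.25, 6.5: 0.2, 7.0: 0.15},
    }


@dataclass(frozen=True)
class SimulationConfig:
    """All tunable knobs of the generator; defaults emulate the study design.

    Effect sizes are on the log10 intensity scale: ``species_effect`` is the
    mean uplift of a specific protein in its species-positive samples,
    ``dysbiosis_effect`` (<= 0) the shift in the dysbiotic groups, and
    ``ph_effect`` (<= 0) the shift per pH category step.
    """

    seed: int = 0
    n_per_group: Mapping[str, int] = field(default_factory=_default_n_per_group)
    n_specific_iners: int = 7
    n_specific_crispatus: int = 11
    n_nonspecific: int = 22
    log_intensity_base: float = 5.0
    species_effect: float = 1.5
    dysbiosis_effect: float = -0.5
    ph_effect: float = -0.3
    noise_sd: float = 0.25
    multispecies_prob: float = 0.2
    positivity: Mapping[str, Mapping[str, float]] = field(default_factory=_default_positivity)
    sb_lognormal: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=_default_sb_lognormal
    )
    ph_distribution: Mapping[str, Mapping[float, float]] = field(
        default_factory=_default_ph_distribution
    )

    def __post_init__(self) -> None:
        for group in VMB_GROUPS:
            if group not in self.n_per_group:
                raise ConfigurationError(f"n_per_group missing group {group!r}")
            if self.n_per_group[group] < 0:
                raise ConfigurationError("group sizes must be nonnegative")
        counts = (self.n_specific_iners, self.n_specific_crispatus, self.n_nonspecific)
        if any(c < 0 for c in counts):
            raise ConfigurationError("protein counts must be nonnegative")
        if sum(self.n_per_group.values()) == 0:
            raise ConfigurationError("at least one sample is required")
        if sum(counts) == 0:
            raise ConfigurationError("at least one protein is required")
        if not self.noise_sd > 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.dysbiosis_effect > 0 or self.ph_effect > 0:
            raise ConfigurationError("dysbiosis_effect and ph_effect must be <= 0")
        if not 0.0 <= self.multispecies_prob <= 1.0:
            raise ConfigurationError("multispecies_prob must be in [0, 1]")
        for group, dist in self.ph_distribution.items():
            for ph in dist:
                check_ph(ph, context=f"ph_distribution[{group}]")
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"ph_distribution[{group}] probabilities sum to {total}, not 1"
                )

    @property
    def n_samples(self) -> int:
        return sum(self.n_per_group[g] for g in VMB_GROUPS)

    @property
    def n_proteins(self) -> int:
        return self.n_specific_iners + self.n_specific_crispatus + self.n_nonspecific

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        """Build a config from a plain (e.g. JSON-loaded) dictionary."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown simulation config keys: {sorted(unknown)}")
        cleaned = dict(raw)
        if "ph_distribution" in cleaned:
            cleaned["ph_distribution"] = {
                g: {float(ph): p for ph, p in dist.items()}
                for g, dist in cleaned["ph_distribution"].items()
            }
        if "sb_lognormal" in cleaned:
            cleaned["sb_lognormal"] = {
                sp: {g: tuple(v) for g, v in groups.items()}
                for sp, groups in cleaned["sb_lognormal"].items()
            }
        return cls(**cleaned)

    def to_dict(self) -> dict:
        raw = dataclasses.asdict(self)
        raw["n_per_group"] = dict(self.n_per_group)
        return raw


@dataclass(frozen=True)
class SyntheticDataset:
    samples: list[SampleRecord]
    proteins: list[ProteinRecord]
    matrix: AbundanceMatrix
    truth: Mapping[str, dict]
    config: SimulationConfig

    def __post_init__(self) -> None:
        if set(self.truth) != {p.accession for p in self.proteins}:
            raise ConfigurationError("truth table must cover every generated protein")


def _draw_ph(rng: np.random.Generator, dist: Mapping[float, float]) -> float:
    values = sorted(dist)
    probs = np.array([dist[v] for v in values])
    return float(rng.choice(values, p=probs / probs.sum()))


def _generate_samples(config: SimulationConfig, rng: np.random.Generator) -> list[SampleRecord]:
    samples: list[SampleRecord] = []
    for group in VMB_GROUPS:
        n = config.n_per_group[group]
        for i in range(n):
            ph = _draw_ph(rng, config.ph_distribution[group])
            taxon_sb: dict[str, float] = {}
            taxon_positive: dict[str, bool] = {}
            for species in SPECIES:
                positive = rng.random() < config.positivity[species][group]
                if positive:
                    mu, sigma = config.sb_lognormal[species][group]
                    sb = float(10.0 ** rng.normal(mu, sigma))
                else:
                    sb = 0.0
                taxon_sb[species] = sb
                taxon_positive[species] = positive
            samples.append(
                SampleRecord(
                    sample_id=f"{group.split('_')[0]}_{i + 1:03d}",
                    vmb_group=group,
                    vaginal_ph=ph,
                    taxon_sb=taxon_sb,
                    taxon_positive=taxon_positive,
                )
            )
    return samples


def _generate_proteins(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[ProteinRecord], dict[str, dict]]:
    proteins: list[ProteinRecord] = []
    truth: dict[str, dict] = {}
    spec_plan = (
        [("L_iners", i) for i in range(config.n_specific_iners)]
        + [("L_crispatus", i) for i in range(config.n_specific_crispatus)]
        + [(None, i) for i in range(config.n_nonspecific)]
    )
    tag = {"L_iners": "INERS", "L_crispatus": "CRISP", None: "NONSPEC"}
    for true_species, i in spec_plan:
        accession = f"SYN_{tag[true_species]}_{i + 1:03d}"
        if true_species is None:
            best_match = rng.choice(["L_iners", "L_crispatus", "multispecies"], p=[0.35, 0.45, 0.2])
        else:
            best_match = (
                "multispecies" if rng.random() < config.multispecies_prob else true_species
            )
        unique = 1 + int(rng.poisson(2.0))
        total = unique + int(rng.poisson(1.5))
        if unique == 1:
            # Specific proteins carry rescue metadata consistent with a real
            # differential signal; nonspecific ones draw a flat ANOVA p.
            anova_p = float(rng.uniform(0.001, 0.04)) if true_species else float(rng.uniform(0, 1))
            flag: Optional[bool] = bool(rng.random() < 0.9)
        else:
            anova_p, flag = None, None
        proteins.append(
            ProteinRecord(
                accession=accession,
                best_match=str(best_match),
                peptide_count=total,
                unique_peptides=unique,
                confidence_score=float(np.round(10.0 ** rng.normal(2.3, 0.4), 2)),
                anova_p=anova_p,
                fragment_series_ok=flag,
            )
        )
        truth[accession] = {
            "true_species": true_species,
            "true_betas": {
                "species": config.species_effect if true_species else 0.0,
                "dysbiosis": config.dysbiosis_effect,
                "ph": config.ph_effect,
            },
        }
    return proteins, truth


def planted_log10_mean(
    config: SimulationConfig, sample: SampleRecord, true_species: Optional[str]
) -> float:
    """Noise-free log10 intensity of a protein in a sample under the model."""
    if true_species is not None and not sample.is_positive(true_species):
        return config.log_intensity_base  # background: protein absent
    mean = config.log_intensity_base
    if true_species is not None:
        mean += config.species_effect
    if sample.vmb_group in DYSBIOTIC_GROUPS:
        mean += config.dysbiosis_effect
    mean += config.ph_effect * ph_category_index(sample.vaginal_ph, PH_THREE_BIN)
    return mean


def generate(config: SimulationConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset; deterministic given ``config.seed``."""
    seq = np.random.SeedSequence(config.seed)
    rng_samples, rng_proteins, rng_matrix = (
        np.random.default_rng(child) for child in seq.spawn(3)
    )
    samples = _generate_samples(config, rng_samples)
    proteins, truth = _generate_proteins(config, rng_proteins)
    log_means = np.array(
        [
            [planted_log10_mean(config, s, truth[p.accession]["true_species"]) for s in samples]
            for p in proteins
        ]
    )
    noise = rng_matrix.normal(0.0, config.noise_sd, size=log_means.shape)
    values = 10.0 ** (log_means + noise)
    matrix = AbundanceMatrix(
        pd.DataFrame(
            values,
            index=[p.accession for p in proteins],
            columns=[s.sample_id for s in samples],
        )
    )
    return SyntheticDataset(samples=samples, proteins=proteins, matrix=matrix, truth=truth, config=config)


def truth_report(dataset: SyntheticDataset) -> pd.DataFrame:
    """Per-protein planted labels and effect sizes, for recovery tests."""
    rows = []
    for accession in sorted(dataset.truth):
        info = dataset.truth[accession]
        rows.append(
            {
                "accession": accession,
                "true_species": info["true_species"] or "nonspecific",
                "beta_species": info["true_betas"]["species"],
                "beta_dysbiosis": info["true_betas"]["dysbiosis"],
                "beta_ph": info["true_betas"]["ph"],
            }
        )
    return pd.DataFrame(rows)
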