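"""Comparison battery and multivariable log-linear regression.

Bivariable comparisons are two-sided Mann-Whitney U tests run pairwise over
VMB groups and over vaginal pH categories, within each species' analysis
cohort (its 16S-positive samples). L. iners batteries are additionally
stratified by L. iners 16S abundance (median split and a fixed S/B > 70
threshold) and repeated within the L. iners-dominated group for the pH
factor. P-values are exact for combined n <= 25 without ties, otherwise the
normal approximation with tie and continuity corrections is used — the
switch is deterministic so p-values reproduce bit-for-bit. No
multiple-testing adjustment is applied by default (raw pairwise p-values are
reported); Holm adjustment is available behind a flag.

For proteins associated with dysbiosis, an ordinary least-squares model of
log10 relative abundance on VMB group dummies (reference: the
species-dominated group), pH category dummies (reference: the lowest bin)
and log10 16S S/B ratio is fitted; confidence intervals come from the
t-distribution with residual degrees of freedom, and residual normality is
reported via the Shapiro-Wilk p-value (a logged warning, not a failure, when
below 0.05). Zeros are replaced by half the smallest positive value of the
protein (respectively of the cohort's S/B ratios) before the log transform.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .cohort_selection import (
    CategoryScheme,
    SCHEME_FOR_SPECIES,
    abundance_strata,
    analysis_cohort,
    cohort_members,
    ph_category,
)
from .data_model import (
    AnalysisResult,
    AbundanceMatrix,
    ClassificationDecision,
    CoefficientEstimate,
    Comparison,
    RegressionResult,
    SampleRecord,
    VMB_GROUPS,
)
from .species_classifier import DOMINANT_GROUP

log = logging.getLogger(__name__)

#: Largest combined sample size for which the exact Mann-Whitney null
#: distribution is enumerated (ties always force the asymptotic branch).
EXACT_MAX_COMBINED_N = 25


class StatsError(RuntimeError):
    """Raised when a statistical routine cannot be run on the given input."""


def _has_ties(pooled: np.ndarray) -> bool:
    return len(np.unique(pooled)) < len(pooled)


def mannwhitney_p(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of the first sample, p).

    Exact when the combined n is at most :data:`EXACT_MAX_COMBINED_N` and the
    pooled values have no ties; otherwise the normal approximation with tie
    correction and continuity correction. Two identical samples (zero
    pooled variance) give p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatsError("Mann-Whitney requires two non-empty samples")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(a.size * b.size / 2.0), 1.0
    if a.size + b.size <= EXACT_MAX_COMBINED_N and not _has_ties(pooled):
        method = "exact"
    else:
        method = "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def pairwise_mannwhitney(
    values: Mapping[str, Sequence[float]],
    factor: str = "vmb_group",
    stratum: Optional[str] = None,
    adjust: Optional[str] = None,
) -> list[Comparison]:
    """One two-sided Mann-Whitney test per unordered pair of levels.

    Levels with zero observations are skipped with a logged warning. When
    ``adjust="holm"`` the Holm-adjusted p-values are attached alongside the
    raw ones (raw p-values are always reported).
    """
    levels = [lvl for lvl in values]
    nonempty = []
    for lvl in levels:
        if len(values[lvl]) == 0:
            log.warning("factor %s: level %r has n=0, skipped", factor, lvl)
        else:
            nonempty.append(lvl)
    comparisons: list[Comparison] = []
    for lvl_a, lvl_b in itertools.combinations(nonempty, 2):
        a = np.asarray(values[lvl_a], dtype=float)
        b = np.asarray(values[lvl_b], dtype=float)
        u, p = mannwhitney_p(a, b)
        comparisons.append(
            Comparison(
                factor=factor,
                level_a=lvl_a,
                level_b=lvl_b,
                n_a=a.size,
                n_b=b.size,
                median_a=float(np.median(a)),
                median_b=float(np.median(b)),
                u_statistic=u,
                p_value=p,
                stratum=stratum,
            )
        )
    if adjust is not None:
        comparisons = adjust_pvalues(comparisons, method=adjust)
    return comparisons


def adjust_pvalues(comparisons: list[Comparison], method: str = "holm") -> list[Comparison]:
    """Attach multiplicity-adjusted p-values to a comparison list."""
    if not comparisons:
        return comparisons
    _, adjusted, _, _ = multipletests([c.p_value for c in comparisons], method=method)
    return [
        Comparison(**{**c.__dict__, "p_adjusted": float(p_adj)})
        for c, p_adj in zip(comparisons, adjusted)
    ]


def shapiro_wilk(residuals: Sequence[float]) -> float:
    """Shapiro-Wilk normality p-value; requires 3 <= n <= 5000.

    A constant vector has no scale and the statistic is undefined; this
    implementation raises :class:`StatsError` for that degenerate input.
    """
    x = np.asarray(residuals, dtype=float)
    if x.size < 3:
        raise StatsError(f"Shapiro-Wilk requires at least 3 observations, got {x.size}")
    if x.size > 5000:
        raise StatsError("Shapiro-Wilk supports at most 5000 observations")
    if np.all(x == x[0]):
        raise StatsError("Shapiro-Wilk is undefined for a constant vector")
    return float(scipy.stats.shapiro(x).pvalue)


@dataclass(frozen=True)
class RegressionSpec:
    """Design of the multivariable model for one protein.

    Terms: VMB group dummies (reference ``group_reference``), pH category
    dummies under ``ph_scheme`` (reference = lowest bin), and the log10 16S
    S/B ratio of ``sb_taxon``. ``group_levels`` / ``ph_levels``, when given
    explicitly, must all be present in the data (an absent level makes the
    design rank-deficient and is reported as such); by default the observed
    levels are used.
    """

    group_reference: str = "G2_iners"
    ph_scheme: Optional[CategoryScheme] = None  # default: three-bin
    sb_taxon: str = "L_iners"
    alpha: float = 0.05
    group_levels: Optional[tuple[str, ...]] = None
    ph_levels: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def _halfmin_log10(values: np.ndarray, what: str) -> np.ndarray:
    """log10 with zeros replaced by half the smallest positive value."""
    positive = values[values > 0]
    if positive.size == 0:
        raise StatsError(f"all {what} values are zero; cannot log-transform")
    floor = positive.min() / 2.0
    return np.log10(np.where(values > 0, values, floor))


def fit_regression(
    values: Mapping[str, float],
    samples: Sequence[SampleRecord],
    spec: RegressionSpec = RegressionSpec(),
) -> RegressionResult:
    """OLS of log10 intensity on group + pH category dummies + log10 S/B.

    ``values`` maps sample_id -> intensity; ``samples`` is the analysis
    cohort the model is fitted on. Raises :class:`StatsError` for a
    rank-deficient design, listing the aliased terms.
    """
    from .cohort_selection import PH_THREE_BIN

    scheme = spec.ph_scheme or PH_THREE_BIN
    if not samples:
        raise StatsError("regression cohort is empty")
    y_raw = np.asarray([float(values[s.sample_id]) for s in samples])
    if (y_raw < 0).any():
        raise StatsError("negative intensities in regression input")
    y = _halfmin_log10(y_raw, "intensity")
    sb_raw = np.asarray([s.sb(spec.sb_taxon) for s in samples])
    x_sb = _halfmin_log10(sb_raw, f"{spec.sb_taxon} S/B")

    groups = [s.vmb_group for s in samples]
    observed_groups = [g for g in VMB_GROUPS if g in set(groups)]
    group_levels = list(spec.group_levels) if spec.group_levels else observed_groups
    if spec.group_reference not in group_levels:
        raise StatsError(
            f"reference group {spec.group_reference!r} absent from the cohort"
        )
    ph_labels = [ph_category(s.vaginal_ph, scheme) for s in samples]
    observed_ph = [lbl for lbl in scheme.labels if lbl in set(ph_labels)]
    ph_levels = list(spec.ph_levels) if spec.ph_levels else observed_ph
    ph_reference = scheme.labels[0]
    if ph_reference not in ph_levels:
        raise StatsError(f"reference pH category {ph_reference!r} absent from the cohort")

    design: dict[str, np.ndarray] = {"intercept": np.ones(len(samples))}
    for lvl in group_levels:
        if lvl == spec.group_reference:
            continue
        design[f"vmb_group[{lvl}]"] = np.asarray([1.0 if g == lvl else 0.0 for g in groups])
    for lvl in ph_levels:
        if lvl == ph_reference:
            continue
        design[f"ph[{lvl}]"] = np.asarray([1.0 if lab == lvl else 0.0 for lab in ph_labels])
    design["log10_sb"] = x_sb
    X = pd.DataFrame(design, index=[s.sample_id for s in samples])

    aliased = _aliased_columns(X.to_numpy())
    if aliased:
        names = [X.columns[i] for i in aliased]
        raise StatsError(f"rank-deficient design; aliased terms: {names}")
    if len(samples) < X.shape[1] + 2:
        raise StatsError(
            f"need at least {X.shape[1] + 2} samples for {X.shape[1]} terms,"
            f" got {len(samples)}"
        )

    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=spec.alpha)
    coefficients = {
        term: CoefficientEstimate(
            term=term,
            beta=float(fit.params[term]),
            ci_low=float(ci.loc[term, 0]),
            ci_high=float(ci.loc[term, 1]),
        )
        for term in X.columns
    }
    shapiro_p = shapiro_wilk(fit.resid)
    if shapiro_p < 0.05:
        log.warning("regression residuals deviate from normality (Shapiro-Wilk p=%.3g)", shapiro_p)
    return RegressionResult(coefficients=coefficients, shapiro_p=shapiro_p, n=len(samples))


def _aliased_columns(X: np.ndarray) -> list[int]:
    """Indices of columns that do not increase the design rank (greedy scan)."""
    aliased: list[int] = []
    rank = 0
    kept = np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        candidate = np.column_stack([kept, X[:, j]])
        new_rank = np.linalg.matrix_rank(candidate)
        if new_rank > rank:
            kept = candidate
            rank = new_rank
        else:
            aliased.append(j)
    return aliased


@dataclass(frozen=True)
class BatteryConfig:
    """Options for the per-protein comparison battery."""

    strata_threshold: float = 70.0
    include_strata: bool = True  # L. iners only, mirroring the study
    include_dominated_ph: bool = True
    adjust: Optional[str] = None


def run_group_battery(
    decisions: Sequence[ClassificationDecision],
    matrix: AbundanceMatrix,
    samples: Sequence[SampleRecord],
    species: str,
    config: BatteryConfig = BatteryConfig(),
) -> list[AnalysisResult]:
    """Comparison battery for every protein assigned to ``species``.

    Per protein: pairwise Mann-Whitney tests across the non-empty VMB groups
    of the species' analysis cohort and across its pH categories; for
    L. iners, the group battery is repeated within 16S-abundance strata
    (median split and fixed S/B > ``strata_threshold``), and the pH battery
    within the species-dominated group only.
    """
    assigned = [d for d in decisions if d.assigned == species]
    if not assigned:
        return []
    cohort = analysis_cohort(species, samples)
    members = cohort_members(cohort)
    if not members:
        raise StatsError(f"analysis cohort for {species} is empty")
    scheme = SCHEME_FOR_SPECIES[species]
    dominated = DOMINANT_GROUP[species]

    results: list[AnalysisResult] = []
    for decision in assigned:
        row = matrix.row(decision.accession)
        comparisons: list[Comparison] = []

        group_values = {
            g: [row[s.sample_id] for s in cohort[g]] for g in VMB_GROUPS if cohort[g]
        }
        comparisons += pairwise_mannwhitney(group_values, factor="vmb_group")

        ph_values: dict[str, list[float]] = {lbl: [] for lbl in scheme.labels}
        for s in members:
            ph_values[ph_category(s.vaginal_ph, scheme)].append(row[s.sample_id])
        comparisons += pairwise_mannwhitney(ph_values, factor="ph_category")

        if config.include_strata and species == "L_iners":
            for mode, label_high, label_low in (
                ("median_split", "sb>median", "sb<=median"),
                ("fixed_threshold", f"sb>{config.strata_threshold:g}", f"sb<={config.strata_threshold:g}"),
            ):
                high, low = abundance_strata(
                    members, species, mode=mode, threshold=config.strata_threshold
                )
                for stratum_label, stratum_samples in ((label_high, high), (label_low, low)):
                    stratum_groups = {
                        g: [row[s.sample_id] for s in stratum_samples if s.vmb_group == g]
                        for g in VMB_GROUPS
                    }
                    stratum_groups = {g: v for g, v in stratum_groups.items() if v}
                    if len(stratum_groups) >= 2:
                        comparisons += pairwise_mannwhitney(
                            stratum_groups, factor="vmb_group", stratum=stratum_label
                        )

        if config.include_dominated_ph:
            dom_samples = cohort[dominated]
            dom_ph: dict[str, list[float]] = {lbl: [] for lbl in scheme.labels}
            for s in dom_samples:
                dom_ph[ph_category(s.vaginal_ph, scheme)].append(row[s.sample_id])
            if sum(1 for v in dom_ph.values() if v) >= 2:
                comparisons += pairwise_mannwhitney(
                    dom_ph, factor="ph_category", stratum=f"group={dominated}"
                )

        if config.adjust is not None:
            comparisons = adjust_pvalues(comparisons, method=config.adjust)
        results.append(
            AnalysisResult(
                accession=decision.accession,
                species=species,
                comparisons=tuple(comparisons),
            )
        )
    return results


def comparisons_frame(results: Sequence[AnalysisResult]) -> pd.DataFrame:
    """Flatten battery results into a tidy table (one row per comparison)."""
    rows = []
    for res in results:
        for c in res.comparisons:
            rows.append(
                {
                    "accession": res.accession,
                    "species": res.species,
                    "factor": c.factor,
                    "stratum": c.stratum or "",
                    "level_a": c.level_a,
                    "level_b": c.level_b,
                    "n_a": c.n_a,
                    "n_b": c.n_b,
                    "median_a": c.median_a,
                    "median_b": c.median_b,
                    "u_statistic": c.u_statistic,
                    "p_value": c.p_value,
                    "p_adjusted": "" if c.p_adjusted is None else c.p_adjusted,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "accession", "species", "factor", "stratum", "level_a", "level_b",
            "n_a", "n_b", "median_a", "median_b", "u_statistic", "p_value", "p_adjusted",
        ],
    )


def regression_frame(results: Sequence[AnalysisResult]) -> pd.DataFrame:
    """Flatten regression fits into a tidy table (one row per coefficient)."""
    rows = []
    for res in results:
        if res.regression is None:
            continue
        for term, est in res.regression.coefficients.items():
            rows.append(
                {
                    "accession": res.accession,
                    "term": term,
                    "beta": est.beta,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "shapiro_p": res.regression.shapiro_p,
                    "n": res.regression.n,
                }
            )
    return pd.DataFrame(
        rows, columns=["accession", "term", "beta", "ci_low", "ci_high", "shapiro_p", "n"]
    )
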