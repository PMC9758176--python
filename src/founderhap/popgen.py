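"""Cohort and population-level allele statistics.

Implements the homozygote-deficit arithmetic for a recessive founder
variant: the population allele frequency q estimated from a genotyped
cohort, the Hardy-Weinberg expected number of homozygotes N*q^2 in a
population of N persons, the detection rate (identified homozygous
patients divided by that expectation; values << 1 mean homozygotes mostly
never present as patients), per-variant allele shares within a patient
cohort, and rank/t tests for comparing group measurements such as onset
ages.

Raw values are kept at full precision; printed values use decimal half-up
rounding at fixed precision (frequencies 5 dp, percentages 1 dp, rates
3 dp) so reported numbers are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import format_fixed, round_half_up

#: Estimated number of Japanese residents older than the mean onset age
#: (~28 y) of GNE myopathy, from national population statistics. The default
#: N for expected-homozygote calculations; pass your own for other cohorts.
DEFAULT_POPULATION_N = 91_800_000


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class AlleleCount:
    """Alt-allele count over total genotyped alleles for one variant."""

    variant_label: str
    alt_alleles: int
    total_alleles: int

    def __post_init__(self) -> None:
        if self.total_alleles <= 0:
            raise ValueError("total_alleles must be positive")
        if not 0 <= self.alt_alleles <= self.total_alleles:
            raise ValueError("alt_alleles must be in [0, total_alleles]")


@dataclass(frozen=True)
class AlleleFrequency:
    """Exact allele frequency plus its 5-decimal display form."""

    value: Fraction
    display: str

    def __float__(self) -> float:
        return float(self.value)


@dataclass(frozen=True)
class HomozygoteEstimate:
    variant_label: str
    allele_freq: float
    population_n: int
    expected_homozygotes: float  # N * q^2, full precision
    observed_homozygotes: int
    detection_rate: float

    @property
    def expected_display(self) -> int:
        return int(round_half_up(self.expected_homozygotes, 0))

    @property
    def detection_display(self) -> str:
        return format_fixed(self.detection_rate, 3)


@dataclass(frozen=True)
class CohortAlleleTable:
    """Per-variant allele counts within a patient cohort.

    ``homozygous_alleles`` counts both alleles of each homozygote (so it is
    even: 92 homozygous patients contribute 184 alleles), and together with
    ``compound_het_alleles`` exhausts ``patient_alleles``.
    """

    rows: pd.DataFrame  # columns: variant_label, patient_alleles, homozygous_alleles, compound_het_alleles
    total_patient_alleles: int

    def __post_init__(self) -> None:
        required = {
            "variant_label",
            "patient_alleles",
            "homozygous_alleles",
            "compound_het_alleles",
        }
        missing = required - set(self.rows.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        r = self.rows
        if ((r.homozygous_alleles + r.compound_het_alleles) != r.patient_alleles).any():
            raise ValueError("homozygous + compound-het alleles must equal patient_alleles")
        if (r.homozygous_alleles % 2 != 0).any():
            raise ValueError("homozygous allele counts must be even (two per person)")
        if r.patient_alleles.sum() > self.total_patient_alleles:
            raise ValueError("per-variant allele counts exceed cohort total")

    @classmethod
    def from_tsv(cls, path, total_patient_alleles: int | None = None) -> "CohortAlleleTable":
        df = pd.read_csv(path, sep="\t")
        total = total_patient_alleles
        if total is None:
            total = int(df["patient_alleles"].sum())
        return cls(rows=df, total_patient_alleles=total)


@dataclass(frozen=True)
class MeasurementSet:
    """Labelled group of measurements (e.g. onset ages in years)."""

    group_label: str
    values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.size == 0:
            raise ValueError("measurement set must be non-empty")
        if not np.isfinite(self.values).all():
            raise ValueError("measurements must be finite")


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    p_value: float
    method: str


# ---------------------------------------------------------------------------
# operations


def allele_frequency(counts: AlleleCount) -> AlleleFrequency:
    """q = alt/total as an exact fraction, displayed to 5 decimals half-up."""
    q = Fraction(counts.alt_alleles, counts.total_alleles)
    return AlleleFrequency(value=q, display=format_fixed(q, 5))


def expected_homozygotes(q: float, population_n: int = DEFAULT_POPULATION_N) -> float:
    """Hardy-Weinberg expected homozygote count N * q**2."""
    q = float(q)
    if not 0.0 <= q <= 1.0:
        raise ValueError("allele frequency must be in [0, 1]")
    if population_n <= 0:
        raise ValueError("population size must be positive")
    return population_n * q * q


def detection_rate(observed: int, expected: float) -> float:
    """Identified homozygotes / HWE-expected homozygotes."""
    if expected <= 0:
        raise ValueError("expected homozygote count must be positive")
    if observed < 0:
        raise ValueError("observed count must be non-negative")
    return observed / expected


def estimate_homozygotes(
    variant_label: str,
    q: float,
    observed: int,
    population_n: int = DEFAULT_POPULATION_N,
    rate_from_rounded_expected: bool = True,
) -> HomozygoteEstimate:
    """Full estimate record for one variant.

    ``rate_from_rounded_expected`` divides the observed count by the
    rounded integer expectation (the form printed in cohort reports, e.g.
    3/238 -> 0.013); switch off to divide by the full-precision expectation.
    """
    exp = expected_homozygotes(q, population_n)
    denom = round_half_up(exp, 0) if rate_from_rounded_expected else exp
    return HomozygoteEstimate(
        variant_label=variant_label,
        allele_freq=float(q),
        population_n=population_n,
        expected_homozygotes=exp,
        observed_homozygotes=observed,
        detection_rate=detection_rate(observed, denom),
    )


def allele_shares(table: CohortAlleleTable) -> pd.DataFrame:
    """Per-variant share of cohort alleles and homozygous rate by allele.

    share = patient_alleles / total * 100; homozygous rate =
    homozygous_alleles / patient_alleles * 100 (NaN when the variant has no
    alleles). Both carry 1-decimal half-up display columns.
    """
    r = table.rows
    share = r.patient_alleles / table.total_patient_alleles * 100.0
    with np.errstate(invalid="ignore", divide="ignore"):
        hom_rate = np.where(
            r.patient_alleles > 0,
            r.homozygous_alleles / r.patient_alleles.replace(0, np.nan) * 100.0,
            np.nan,
        )
    out = pd.DataFrame(
        {
            "variant_label": r.variant_label,
            "share_pct": share,
            "homozygous_rate_pct": hom_rate,
        }
    )
    out["share_display"] = [round_half_up(x, 1) for x in out.share_pct]
    out["homozygous_rate_display"] = [
        round_half_up(x, 1) if np.isfinite(x) else np.nan
        for x in out.homozygous_rate_pct
    ]
    return out


def compare_groups(
    a: MeasurementSet,
    b: MeasurementSet,
    method: Literal["rank_test", "t_test"] = "rank_test",
    paired: bool = False,
) -> GroupComparison:
    """Two-sided comparison of two measurement groups.

    ``rank_test`` is the unpaired two-sample rank-sum (Mann-Whitney U)
    comparison, exact when samples are small and tie-free; ``paired=True``
    switches to the Wilcoxon signed-rank form for matched samples.
    ``t_test`` is Student's two-sample t (equal variances).
    """
    x, y = a.values, b.values
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if method == "t_test":
        res = stats.ttest_ind(x, y, equal_var=True)
        return GroupComparison(float(res.statistic), float(res.pvalue), "t_test")
    if method != "rank_test":
        raise ValueError(f"unknown method {method!r}")
    if paired:
        if x.size != y.size:
            raise ValueError("paired comparison needs equal group sizes")
        res = stats.wilcoxon(x, y)
        return GroupComparison(float(res.statistic), float(res.pvalue), "rank_test_paired")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    how = "exact" if (not ties and x.size + y.size <= 60) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=how)
    return GroupComparison(float(res.statistic), float(res.pvalue), "rank_test")


def cohort_report(
    counts: Sequence[AlleleCount],
    observed: dict[str, int],
    table: CohortAlleleTable | None = None,
    population_n: int = DEFAULT_POPULATION_N,
    freq_overrides: dict[str, float] | None = None,
    use_display_freq: bool = True,
) -> dict:
    """Per-variant JSON-ready summary: frequency, expectation, detection, shares.

    Expected homozygote counts are computed from the 5-decimal display
    frequency by default (the form printed in reports); set
    ``use_display_freq=False`` to use the exact allele fraction instead.
    ``freq_overrides`` substitutes an externally reported frequency for a
    variant in place of the one computed from its counts.
    """
    freq_overrides = freq_overrides or {}
    share_df = allele_shares(table) if table is not None else None
    report: dict[str, dict] = {}
    for ac in counts:
        f = allele_frequency(ac)
        default_q = float(f.display) if use_display_freq else float(f.value)
        q = freq_overrides.get(ac.variant_label, default_q)
        entry: dict = {
            "frequency": {"exact": float(f.value), "display": f.display},
            "population_n": population_n,
        }
        if ac.variant_label in observed:
            est = estimate_homozygotes(
                ac.variant_label, q, observed[ac.variant_label], population_n
            )
            entry["expected_homozygotes"] = {
                "exact": est.expected_homozygotes,
                "display": est.expected_display,
            }
            entry["observed_homozygotes"] = est.observed_homozygotes
            entry["detection_rate"] = {
                "exact": est.detection_rate,
                "display": float(est.detection_display),
            }
        if share_df is not None:
            row = share_df[share_df.variant_label == ac.variant_label]
            if len(row):
                entry["share_pct"] = float(row.share_display.iloc[0])
                hr = row.homozygous_rate_display.iloc[0]
                entry["homozygous_rate_pct"] = None if pd.isna(hr) else float(hr)
        report[ac.variant_label] = entry
    return report
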