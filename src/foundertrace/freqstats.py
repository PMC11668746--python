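"""Carrier-frequency estimation and Hardy-Weinberg incidence projection.

Estimates the frequency of a recessive disease allele from the number of
variant alleles observed in a population screening cohort, attaches an exact
(Clopper-Pearson) binomial confidence interval, and projects the expected
disease incidence under Hardy-Weinberg equilibrium as ``q**2`` on a
per-``scale``-persons basis.

All chained computations use unrounded values; rounding happens only at the
display boundary (:func:`format_frequency`, :func:`format_incidence`).
Carrier observations are *allele* counts, not carrier individuals: a
homozygous carrier contributes two alleles, so a cohort of ``n`` diploid
individuals provides ``2 * n`` Bernoulli trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from scipy.stats import beta as _beta

__all__ = [
    "CohortCount",
    "FrequencyEstimate",
    "IncidenceEstimate",
    "allele_frequency",
    "clopper_pearson",
    "hwe_incidence",
    "format_frequency",
    "format_incidence",
]


class DegenerateInputError(ValueError):
    """Raised when an estimator receives an input with no information (n=0)."""


@dataclass
class CohortCount:
    """Variant-allele count in a genotyped population sample.

    ``n_carrier_alleles`` counts observed variant *alleles* (a homozygote
    contributes ``ploidy``), out of ``ploidy * n_individuals`` trials.
    """

    population_label: str
    n_individuals: int
    n_carrier_alleles: int
    ploidy: int = 2

    def __post_init__(self) -> None:
        if self.n_individuals < 0:
            raise ValueError("n_individuals must be non-negative")
        if self.ploidy < 1:
            raise ValueError("ploidy must be a positive integer")
        if not 0 <= self.n_carrier_alleles <= self.ploidy * self.n_individuals:
            raise ValueError(
                f"n_carrier_alleles={self.n_carrier_alleles} outside "
                f"[0, {self.ploidy * self.n_individuals}] for "
                f"{self.n_individuals} individuals of ploidy {self.ploidy}"
            )

    @property
    def n_alleles(self) -> int:
        return self.ploidy * self.n_individuals


@dataclass
class FrequencyEstimate:
    """Point estimate of an allele frequency with optional exact CI."""

    q_hat: float
    n_alleles: int
    ci_lower: Optional[float] = None
    ci_upper: Optional[float] = None
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 <= self.q_hat <= 1.0:
            raise ValueError("q_hat must lie in [0, 1]")
        if self.ci_lower is not None and self.ci_upper is not None:
            if not (0.0 <= self.ci_lower <= self.q_hat <= self.ci_upper <= 1.0):
                raise ValueError(
                    "CI must satisfy 0 <= lower <= q_hat <= upper <= 1"
                )


@dataclass
class IncidenceEstimate:
    """Expected recessive-disease incidence q**2, per ``scale`` persons."""

    incidence: float
    ci_lower: float
    ci_upper: float
    scale: int = 100_000

    def __post_init__(self) -> None:
        if self.scale < 1:
            raise ValueError("scale must be a positive integer")
        if self.incidence < 0:
            raise ValueError("incidence must be non-negative")


def allele_frequency(cohort: CohortCount) -> FrequencyEstimate:
    """Point estimate of the allele frequency (CI fields left unset).

    q_hat = n_carrier_alleles / (ploidy * n_individuals).
    """
    if cohort.n_individuals == 0:
        raise DegenerateInputError(
            "cannot estimate a frequency from zero genotyped individuals"
        )
    return FrequencyEstimate(
        q_hat=cohort.n_carrier_alleles / cohort.n_alleles,
        n_alleles=cohort.n_alleles,
    )


def clopper_pearson(
    successes: int, trials: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Exact binomial (Clopper-Pearson) confidence interval.

    Computed from beta-distribution quantiles: the lower bound is the
    ``alpha/2`` quantile of ``Beta(x, n - x + 1)`` and the upper bound the
    ``1 - alpha/2`` quantile of ``Beta(x + 1, n - x)``, which invert the
    binomial tail sums exactly.  By convention the lower bound is 0 when
    ``x == 0`` and the upper bound is 1 when ``x == n``.
    """
    if trials == 0:
        raise DegenerateInputError("Clopper-Pearson interval undefined for 0 trials")
    if not 0 <= successes <= trials:
        raise ValueError("need 0 <= successes <= trials")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie strictly between 0 and 1")
    alpha = 1.0 - confidence
    if successes == 0:
        lower = 0.0
    else:
        lower = float(_beta.ppf(alpha / 2.0, successes, trials - successes + 1))
    if successes == trials:
        upper = 1.0
    else:
        upper = float(_beta.ppf(1.0 - alpha / 2.0, successes + 1, trials - successes))
    return lower, upper


def estimate_with_ci(cohort: CohortCount, confidence: float = 0.95) -> FrequencyEstimate:
    """Convenience: point estimate plus exact CI in one call."""
    est = allele_frequency(cohort)
    lo, hi = clopper_pearson(cohort.n_carrier_alleles, cohort.n_alleles, confidence)
    return FrequencyEstimate(
        q_hat=est.q_hat,
        n_alleles=est.n_alleles,
        ci_lower=lo,
        ci_upper=hi,
        confidence=confidence,
    )


def hwe_incidence(freq: FrequencyEstimate, scale: int = 100_000) -> IncidenceEstimate:
    """Hardy-Weinberg recessive incidence q**2, per ``scale`` persons.

    Squares the *unrounded* point estimate and CI bounds.  Because squaring
    is monotone on [0, 1], the squared CI bounds are an exact CI for q**2.
    """
    if freq.ci_lower is None or freq.ci_upper is None:
        raise ValueError("frequency estimate must carry a confidence interval")
    return IncidenceEstimate(
        incidence=freq.q_hat**2 * scale,
        ci_lower=freq.ci_lower**2 * scale,
        ci_upper=freq.ci_upper**2 * scale,
        scale=scale,
    )


# -- display rounding ---------------------------------------------------------
# frequencies print at 6 decimals, per-100k incidences at 5

def format_frequency(value: float, decimals: int = 6) -> float:
    return round(value, decimals)


def format_incidence(value: float, decimals: int = 5) -> float:
    return round(value, decimals)


def frequency_report(cohort: CohortCount, confidence: float = 0.95,
                     scale: int = 100_000) -> str:
    """Human-readable carrier-frequency / incidence report for one cohort."""
    est = estimate_with_ci(cohort, confidence)
    inc = hwe_incidence(est, scale)
    pct = int(round(confidence * 100))
    return (
        f"population       : {cohort.population_label}\n"
        f"individuals (n)  : {cohort.n_individuals}\n"
        f"alleles observed : {cohort.n_carrier_alleles}/{cohort.n_alleles}\n"
        f"allele frequency : {format_frequency(est.q_hat):.6f} "
        f"({pct}%CI: {format_frequency(est.ci_lower):.6f}"
        f"–{format_frequency(est.ci_upper):.6f})\n"
        f"HWE incidence    : {format_incidence(inc.incidence):.5f} "
        f"({pct}%CI: {format_incidence(inc.ci_lower):.5f}"
        f"–{format_incidence(inc.ci_upper):.5f}) per {scale:,}\n"
    )
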