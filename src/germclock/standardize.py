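"""Standardization of published parental-age regressions into mutation rate components.

Pedigree studies of de novo mutation report the parental-age effect in
heterogeneous parameterizations: sex-specific slopes and intercepts per diploid
genome, combined per-site slopes, or mean rates over a reproductive span.  This
module converts each reported form into a common decomposition,

* ``mu_E`` — the embryonic mutation rate: mutations per site per generation
  accumulated in the germline between the zygote and puberty, and
* ``mu_gam`` — the gamete mutation rate: mutations per site per **year** accruing
  in mature spermatocytes and oocytes after puberty (the sum of the oocyte and
  spermatocyte rates, which individual studies rarely resolve separately),

so that the per-generation rate at parental ages ``(A_P, A_M)`` is
``mu_E + (A_P - P) * mu_S + (A_M - P) * mu_O`` with ``P`` the age of puberty.

It also provides a trio-level regression (:class:`TrioRegressionModel`) that
estimates the same decomposition directly from per-offspring mutation counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "SexSpecificRegressionSpec",
    "SlopeInterceptPerSiteSpec",
    "MeanRateSpanSpec",
    "RateDecomposition",
    "TrioRecord",
    "StudySpecError",
    "NegativeRateWarning",
    "standardize_sex_specific",
    "standardize_slope_intercept",
    "standardize_mean_rate",
    "TrioRegressionModel",
    "TrioRegressionResults",
    "fit_trio_regression",
]


class StudySpecError(ValueError):
    """A study spec violates its invariants or lacks a required field."""


class NegativeRateWarning(UserWarning):
    """A standardized rate came out negative; reported as-is, never clamped."""


def _finite(*values: float) -> bool:
    return all(math.isfinite(v) for v in values)


@dataclass(frozen=True)
class RateDecomposition:
    """A species' standardized germline mutation rate components.

    Attributes
    ----------
    species : str
        Species label.
    mu_E : float
        Embryonic mutation rate, mutations per site per generation.
    mu_gam : float
        Post-puberty gamete mutation rate (oocyte + spermatocyte), mutations
        per site per year.
    puberty_age : float
        Age of puberty / first reproduction, years.
    generation_time : float
        Average parental age at reproduction, years.
    mu_E_bounds, mu_gam_bounds : tuple of float, optional
        95% (lower, upper) bounds where the source study supports them.
    """

    species: str
    mu_E: float
    mu_gam: float
    puberty_age: float
    generation_time: float
    mu_E_bounds: tuple[float, float] | None = None
    mu_gam_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not _finite(self.mu_E, self.mu_gam, self.puberty_age, self.generation_time):
            raise StudySpecError(f"{self.species}: non-finite rate components")
        if self.generation_time < self.puberty_age:
            raise StudySpecError(
                f"{self.species}: generation_time ({self.generation_time}) "
                f"< puberty_age ({self.puberty_age})"
            )
        if self.mu_E < 0:
            warnings.warn(
                f"{self.species}: negative embryonic rate mu_E={self.mu_E:.3g}",
                NegativeRateWarning,
                stacklevel=3,
            )


@dataclass(frozen=True)
class SexSpecificRegressionSpec:
    """Maternal/paternal slopes and intercepts of a parental-age regression.

    ``units`` says whether slopes and intercepts count mutations per diploid
    genome ('per_genome', requiring ``accessible_haploid_size``) or per site
    ('per_site').  Each intercept applies at its stated reference age (0 for
    studies that extrapolate to birth).
    """

    species: str
    maternal_slope: float
    paternal_slope: float
    maternal_intercept: float
    paternal_intercept: float
    puberty_age: float
    generation_time: float
    units: Literal["per_genome", "per_site"] = "per_genome"
    maternal_ref_age: float = 0.0
    paternal_ref_age: float = 0.0
    accessible_haploid_size: float | None = None
    #: optional lower/upper bound variants of the numeric fields, for CI
    #: propagation by re-applying the standardization formulas
    lower: dict[str, float] = field(default_factory=dict)
    upper: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.units not in ("per_genome", "per_site"):
            raise StudySpecError(f"{self.species}: unknown units {self.units!r}")
        if self.units == "per_genome":
            if self.accessible_haploid_size is None:
                raise StudySpecError(
                    f"{self.species}: per_genome units require accessible_haploid_size"
                )
            if self.accessible_haploid_size <= 0:
                raise StudySpecError(f"{self.species}: accessible_haploid_size must be > 0")
        if self.puberty_age < 0:
            raise StudySpecError(f"{self.species}: puberty_age must be >= 0")
        if not _finite(
            self.maternal_slope,
            self.paternal_slope,
            self.maternal_intercept,
            self.paternal_intercept,
        ):
            raise StudySpecError(f"{self.species}: slopes/intercepts must be finite")
        if max(self.maternal_ref_age, self.paternal_ref_age) > self.puberty_age:
            raise StudySpecError(
                f"{self.species}: intercept reference ages must not exceed puberty_age"
            )


@dataclass(frozen=True)
class SlopeInterceptPerSiteSpec:
    """A combined per-site parental-age slope and intercept.

    ``intercept_offset_years`` adds that many years of gamete accumulation to
    the intercept to obtain the load at puberty (some studies report the
    regression intercept one year before their definition of puberty).
    """

    species: str
    slope: float
    intercept: float
    puberty_age: float
    generation_time: float
    intercept_offset_years: float = 0.0

    def __post_init__(self) -> None:
        if self.slope < 0 or self.intercept < 0:
            raise StudySpecError(f"{self.species}: slope and intercept must be >= 0")


@dataclass(frozen=True)
class MeanRateSpanSpec:
    """Rate at puberty plus a mean rate over the observed reproductive span."""

    species: str
    rate_at_puberty: float
    mean_rate: float
    puberty_age: float
    mean_reproductive_age: float

    def __post_init__(self) -> None:
        if self.mean_reproductive_age <= self.puberty_age:
            raise StudySpecError(
                f"{self.species}: mean_reproductive_age must exceed puberty_age"
            )


@dataclass(frozen=True)
class TrioRecord:
    """One offspring's parental ages, DNM count and callable genome size."""

    paternal_age: float
    maternal_age: float
    dnm_count: int
    callable_diploid_sites: float

    def __post_init__(self) -> None:
        if self.dnm_count < 0:
            raise StudySpecError("dnm_count must be >= 0")
        if self.callable_diploid_sites <= 0:
            raise StudySpecError("callable_diploid_sites must be > 0")
        if self.paternal_age <= 0 or self.maternal_age <= 0:
            raise StudySpecError("parental ages must be > 0")


# ---------------------------------------------------------------------------
# standardization operations


def _sex_specific_point(
    ms: float,
    ps: float,
    mi: float,
    pi: float,
    m_ref: float,
    p_ref: float,
    P: float,
    denom: float,
) -> tuple[float, float]:
    mu_gam = (ms + ps) / denom
    mu_E = (mi + pi + (P - m_ref) * ms + (P - p_ref) * ps) / denom
    return mu_E, mu_gam


def standardize_sex_specific(spec: SexSpecificRegressionSpec) -> RateDecomposition:
    """Standardize a sex-specific slope/intercept regression.

    The gamete rate is the summed parental slopes; the embryonic rate is the
    summed intercepts advanced from each intercept's reference age to puberty
    along its own slope.  Per-genome counts are diploid, so the per-site
    denominator is twice the accessible haploid genome size.

    If ``spec.lower`` / ``spec.upper`` bound values are present, bounds on the
    outputs are obtained by plugging the bound values into the same formulas.
    """
    denom = 1.0 if spec.units == "per_site" else 2.0 * float(spec.accessible_haploid_size)

    def point(src: dict[str, float]) -> tuple[float, float]:
        get = lambda k, default: float(src.get(k, default))  # noqa: E731
        d = denom
        if spec.units == "per_genome" and "accessible_haploid_size" in src:
            d = 2.0 * float(src["accessible_haploid_size"])
        return _sex_specific_point(
            get("maternal_slope", spec.maternal_slope),
            get("paternal_slope", spec.paternal_slope),
            get("maternal_intercept", spec.maternal_intercept),
            get("paternal_intercept", spec.paternal_intercept),
            get("maternal_ref_age", spec.maternal_ref_age),
            get("paternal_ref_age", spec.paternal_ref_age),
            get("puberty_age", spec.puberty_age),
            d,
        )

    mu_E, mu_gam = point({})
    mu_E_bounds = mu_gam_bounds = None
    if spec.lower and spec.upper:
        lo_E, lo_g = point(spec.lower)
        hi_E, hi_g = point(spec.upper)
        mu_E_bounds = (min(lo_E, hi_E), max(lo_E, hi_E))
        mu_gam_bounds = (min(lo_g, hi_g), max(lo_g, hi_g))
    return RateDecomposition(
        species=spec.species,
        mu_E=mu_E,
        mu_gam=mu_gam,
        puberty_age=spec.puberty_age,
        generation_time=spec.generation_time,
        mu_E_bounds=mu_E_bounds,
        mu_gam_bounds=mu_gam_bounds,
    )


def standardize_slope_intercept(spec: SlopeInterceptPerSiteSpec) -> RateDecomposition:
    """Standardize a combined per-site slope/intercept report.

    ``mu_gam`` is the slope itself; ``mu_E`` is the intercept plus
    ``intercept_offset_years`` years of gamete accumulation.
    """
    return RateDecomposition(
        species=spec.species,
        mu_E=spec.intercept + spec.intercept_offset_years * spec.slope,
        mu_gam=spec.slope,
        puberty_age=spec.puberty_age,
        generation_time=spec.generation_time,
    )


def standardize_mean_rate(spec: MeanRateSpanSpec) -> RateDecomposition:
    """Standardize a (rate at puberty, mean rate over span) report.

    The gamete rate is the excess of the mean rate over the rate at puberty
    divided by the mean years elapsed since puberty.
    """
    span = spec.mean_reproductive_age - spec.puberty_age
    return RateDecomposition(
        species=spec.species,
        mu_E=spec.rate_at_puberty,
        mu_gam=(spec.mean_rate - spec.rate_at_puberty) / span,
        puberty_age=spec.puberty_age,
        generation_time=spec.mean_reproductive_age,
    )


# ---------------------------------------------------------------------------
# trio regression


class TrioRegressionModel:
    """OLS of per-trio mutation rate against mean parental age.

    Each trio contributes a per-site rate ``dnm_count / callable_diploid_sites``
    regressed on the mean of the paternal and maternal ages.  The fitted slope
    is the gamete rate per year; the embryonic rate is the fitted intercept
    advanced to the age of puberty.

    Parameters
    ----------
    trios : sequence of TrioRecord
    puberty_age : float
        Age (years) at which the pre-reproductive mutation load is evaluated.
    species : str
        Label for the resulting decomposition.
    """

    def __init__(
        self,
        trios: Sequence[TrioRecord],
        puberty_age: float,
        species: str = "trio_fit",
    ) -> None:
        if len(trios) < 3:
            raise StudySpecError("need at least 3 trios")
        self.trios = list(trios)
        self.puberty_age = float(puberty_age)
        self.species = species
        self.ages = np.array([(t.paternal_age + t.maternal_age) / 2.0 for t in self.trios])
        self.rates = np.array(
            [t.dnm_count / t.callable_diploid_sites for t in self.trios]
        )
        if np.ptp(self.ages) == 0:
            raise StudySpecError("singular design: all mean parental ages identical")

    def fit(self) -> "TrioRegressionResults":
        import statsmodels.api as sm

        X = sm.add_constant(self.ages)
        res = sm.OLS(self.rates, X).fit()
        return TrioRegressionResults(self, res)


class TrioRegressionResults:
    """Results of :class:`TrioRegressionModel`; exposes the decomposition."""

    def __init__(self, model: TrioRegressionModel, sm_results) -> None:
        self.model = model
        self.sm_results = sm_results
        self.intercept, self.slope = sm_results.params
        P = model.puberty_age
        self.mu_gam = float(self.slope)
        self.mu_E = float(self.intercept + P * self.slope)
        # var(mu_E) = var(a) + P^2 var(b) + 2 P cov(a, b)
        cov = np.asarray(sm_results.cov_params())
        self.mu_gam_se = float(np.sqrt(cov[1, 1]))
        self.mu_E_se = float(np.sqrt(cov[0, 0] + P**2 * cov[1, 1] + 2 * P * cov[0, 1]))
        self.df_resid = float(sm_results.df_resid)

    def conf_int(self, alpha: float = 0.05) -> dict[str, tuple[float, float]]:
        from scipy import stats

        t = stats.t.ppf(1 - alpha / 2.0, self.df_resid)
        return {
            "mu_E": (self.mu_E - t * self.mu_E_se, self.mu_E + t * self.mu_E_se),
            "mu_gam": (self.mu_gam - t * self.mu_gam_se, self.mu_gam + t * self.mu_gam_se),
        }

    @property
    def decomposition(self) -> RateDecomposition:
        ci = self.conf_int()
        g = float(np.mean(self.model.ages))
        return RateDecomposition(
            species=self.model.species,
            mu_E=self.mu_E,
            mu_gam=self.mu_gam,
            puberty_age=self.model.puberty_age,
            generation_time=max(g, self.model.puberty_age),
            mu_E_bounds=ci["mu_E"],
            mu_gam_bounds=ci["mu_gam"],
        )

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            f"Trio regression ({self.model.species}): n={len(self.model.trios)} trios",
            f"  mu_E    = {self.mu_E:.4g} /site/gen   95% CI "
            f"[{ci['mu_E'][0]:.4g}, {ci['mu_E'][1]:.4g}]",
            f"  mu_gam  = {self.mu_gam:.4g} /site/yr   95% CI "
            f"[{ci['mu_gam'][0]:.4g}, {ci['mu_gam'][1]:.4g}]",
            f"  puberty = {self.model.puberty_age} y",
        ]
        return "\n".join(lines)


def fit_trio_regression(
    trios: Sequence[TrioRecord], puberty_age: float, species: str = "trio_fit"
) -> RateDecomposition:
    """Functional wrapper: fit the trio regression, return the decomposition."""
    return TrioRegressionModel(trios, puberty_age, species=species).fit().decomposition
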