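"""Reproductive-longevity models of germline mutation rate versus generation time.

Two nested models are implemented.  The *fixed-rate* model holds the molecular
rates constant across species and attributes all variation in the per-generation
mutation rate u(g) to reproductive timing:

    u(g) = mu_E + g * (1 - p) * mu_gam,

where ``p = P/g`` is the puberty fraction (age at first reproduction over
generation time), empirically close to a cross-species constant.  The
*relaxed-clock* model lets both molecular rates scale as power laws of
generation time, ``mu_E(g) = mu_E(1) * g**alpha`` and
``mu_gam(g) = mu_gam(1) * g**beta``, giving

    u(g) = mu_E(1) * g**alpha + (1 - p) * mu_gam(1) * g**(beta + 1).

``alpha`` and ``beta`` are estimated by unweighted log-log linear regression of
the standardized per-species rates on generation time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .standardize import RateDecomposition

__all__ = [
    "FixedClockParams",
    "RelaxedClockParams",
    "total_generational_rate",
    "predict_fixed",
    "embryonic_rate_at",
    "gamete_rate_at",
    "predict_relaxed",
    "RelaxedClockModel",
    "RelaxedClockResults",
    "fit_relaxed_clock",
    "PubertyFractionModel",
    "PubertyFractionResults",
    "fit_puberty_fraction",
    "DEFAULT_PUBERTY_FRACTION",
]

logger = logging.getLogger(__name__)

#: cross-species puberty fraction p = P/g (through-origin regression over a
#: large vertebrate demographic compilation)
DEFAULT_PUBERTY_FRACTION = 0.42


@dataclass(frozen=True)
class FixedClockParams:
    """Parameters of the fixed-rate reproductive longevity model."""

    mu_E: float
    mu_gam: float
    p: float = DEFAULT_PUBERTY_FRACTION

    def __post_init__(self) -> None:
        if not 0 <= self.p < 1:
            raise ValueError("puberty fraction p must be in [0, 1)")
        if self.mu_E < 0 or self.mu_gam < 0:
            raise ValueError("rates must be >= 0")


@dataclass(frozen=True)
class RelaxedClockParams:
    """Parameters of the relaxed-clock reproductive longevity model.

    ``mu_E1`` and ``mu_gam1`` are the embryonic and gamete rates at a
    generation time of one year; ``alpha`` and ``beta`` are the log-log slopes
    of the two rates against generation time.
    """

    mu_E1: float
    alpha: float
    mu_gam1: float
    beta: float
    p: float = DEFAULT_PUBERTY_FRACTION

    def __post_init__(self) -> None:
        if self.mu_E1 <= 0 or self.mu_gam1 <= 0:
            raise ValueError("unit-generation rates must be > 0")
        if not 0 <= self.p < 1:
            raise ValueError("puberty fraction p must be in [0, 1)")


def total_generational_rate(dec: RateDecomposition) -> float:
    """Per-generation mutation rate mu = mu_E + (g - P) * mu_gam.

    The gamete rate only accrues over the g - P years between puberty and
    reproduction.
    """
    span = dec.generation_time - dec.puberty_age
    if span < 0:
        raise ValueError(f"{dec.species}: generation_time < puberty_age")
    return dec.mu_E + span * dec.mu_gam


def _check_g(g):
    g = np.asarray(g, dtype=float)
    if np.any(g <= 0):
        raise ValueError("generation time g must be > 0")
    return g


def predict_fixed(g, params: FixedClockParams):
    """Fixed-rate model prediction u(g) = mu_E + g * (1 - p) * mu_gam."""
    g = np.asarray(g, dtype=float)
    out = params.mu_E + g * (1.0 - params.p) * params.mu_gam
    return float(out) if out.ndim == 0 else out


def embryonic_rate_at(g, params: RelaxedClockParams):
    """Embryonic rate mu_E(g) = mu_E(1) * g**alpha."""
    g = _check_g(g)
    out = params.mu_E1 * g**params.alpha
    return float(out) if out.ndim == 0 else out


def gamete_rate_at(g, params: RelaxedClockParams):
    """Gamete rate per year mu_gam(g) = mu_gam(1) * g**beta."""
    g = _check_g(g)
    out = params.mu_gam1 * g**params.beta
    return float(out) if out.ndim == 0 else out


def predict_relaxed(g, params: RelaxedClockParams):
    """Relaxed-clock prediction u(g) = mu_E(1) g^alpha + (1-p) mu_gam(1) g^(beta+1)."""
    g = _check_g(g)
    out = params.mu_E1 * g**params.alpha + (1.0 - params.p) * params.mu_gam1 * g ** (
        params.beta + 1.0
    )
    return float(out) if out.ndim == 0 else out


class RelaxedClockModel:
    """Fit the relaxed-clock power laws to standardized species decompositions.

    ``alpha`` (and ``log mu_E1``) come from OLS of ``log mu_E`` on ``log g``;
    ``beta`` (and ``log mu_gam1``) from OLS of ``log mu_gam`` on ``log g``.
    Natural logarithms are used throughout; intercepts are exponentiated back
    to rate scale.  Species with a non-positive rate are excluded from the
    corresponding regression with a logged warning.  The puberty fraction
    ``p`` is supplied, not refit.
    """

    def __init__(
        self,
        decompositions: Sequence[RateDecomposition],
        p: float = DEFAULT_PUBERTY_FRACTION,
    ) -> None:
        self.decompositions = list(decompositions)
        self.p = float(p)

    @classmethod
    def from_dataframe(cls, df, p: float = DEFAULT_PUBERTY_FRACTION) -> "RelaxedClockModel":
        """Build from a table with columns species, mu_E, mu_gam, puberty_age, generation_time."""
        decs = [
            RateDecomposition(
                species=str(r["species"]),
                mu_E=float(r["mu_E"]),
                mu_gam=float(r["mu_gam"]),
                puberty_age=float(r["puberty_age"]),
                generation_time=float(r["generation_time"]),
            )
            for _, r in df.iterrows()
        ]
        return cls(decs, p=p)

    @staticmethod
    def _loglog(g: np.ndarray, y: np.ndarray, what: str) -> tuple[float, float, float, float]:
        """OLS of log y on log g -> (intercept, slope, se_intercept, se_slope)."""
        keep = y > 0
        if not np.all(keep):
            logger.warning(
                "%s: excluding %d species with non-positive rates", what, int((~keep).sum())
            )
        g, y = g[keep], y[keep]
        if len(np.unique(g)) < 3:
            raise ValueError(f"{what}: need >= 3 usable species with distinct g")
        X = np.column_stack([np.ones_like(g), np.log(g)])
        z = np.log(y)
        coef, *_ = np.linalg.lstsq(X, z, rcond=None)
        resid = z - X @ coef
        dof = len(z) - 2
        s2 = float(resid @ resid) / dof if dof > 0 else 0.0
        cov = s2 * np.linalg.inv(X.T @ X)
        return coef[0], coef[1], math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])

    def fit(self) -> "RelaxedClockResults":
        g = np.array([d.generation_time for d in self.decompositions], dtype=float)
        mu_E = np.array([d.mu_E for d in self.decompositions], dtype=float)
        mu_gam = np.array([d.mu_gam for d in self.decompositions], dtype=float)
        aE, alpha, seA_int, alpha_se = self._loglog(g, mu_E, "mu_E")
        aG, beta, seG_int, beta_se = self._loglog(g, mu_gam, "mu_gam")
        params = RelaxedClockParams(
            mu_E1=math.exp(aE), alpha=alpha, mu_gam1=math.exp(aG), beta=beta, p=self.p
        )
        return RelaxedClockResults(
            self, params, alpha_se=alpha_se, beta_se=beta_se,
            log_mu_E1_se=seA_int, log_mu_gam1_se=seG_int,
        )


class RelaxedClockResults:
    """Fitted relaxed-clock exponents with standard errors."""

    def __init__(
        self,
        model: RelaxedClockModel,
        params: RelaxedClockParams,
        alpha_se: float,
        beta_se: float,
        log_mu_E1_se: float,
        log_mu_gam1_se: float,
    ) -> None:
        self.model = model
        self.params = params
        self.alpha_se = alpha_se
        self.beta_se = beta_se
        self.log_mu_E1_se = log_mu_E1_se
        self.log_mu_gam1_se = log_mu_gam1_se

    def predict(self, g):
        return predict_relaxed(g, self.params)

    def embryonic_rate(self, g):
        return embryonic_rate_at(g, self.params)

    def gamete_rate(self, g):
        return gamete_rate_at(g, self.params)

    def summary(self) -> str:
        p = self.params
        return "\n".join(
            [
                f"Relaxed-clock fit on {len(self.model.decompositions)} species "
                f"(p = {p.p})",
                f"  mu_E(g)   = {p.mu_E1:.4g} * g^{p.alpha:+.4f}  "
                f"(alpha SE {self.alpha_se:.4f})",
                f"  mu_gam(g) = {p.mu_gam1:.4g} * g^{p.beta:+.4f}  "
                f"(beta SE {self.beta_se:.4f})",
            ]
        )


def fit_relaxed_clock(
    decs: Sequence[RateDecomposition], p: float = DEFAULT_PUBERTY_FRACTION
) -> RelaxedClockParams:
    """Functional wrapper returning only the fitted parameters."""
    return RelaxedClockModel(decs, p=p).fit().params


class PubertyFractionModel:
    """Through-origin regression of age at first reproduction on generation time.

    Estimates the puberty fraction ``p`` in ``P = p * g`` from (P, g) pairs,
    together with the Pearson correlation of the pairs.
    """

    def __init__(self, pairs: Sequence[tuple[float, float]]) -> None:
        arr = np.asarray(pairs, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
            raise ValueError("need >= 2 (P, g) pairs")
        if np.any(arr <= 0):
            raise ValueError("ages must be > 0")
        self.P = arr[:, 0]
        self.g = arr[:, 1]
        if np.ptp(self.g) == 0 and np.ptp(self.P) == 0:
            raise ValueError("degenerate input: a single repeated pair")

    def fit(self) -> "PubertyFractionResults":
        slope = float(self.P @ self.g / (self.g @ self.g))
        resid = self.P - slope * self.g
        dof = len(self.g) - 1
        se = math.sqrt(float(resid @ resid) / dof / float(self.g @ self.g))
        if np.ptp(self.g) > 0 and np.ptp(self.P) > 0:
            r = float(np.corrcoef(self.P, self.g)[0, 1])
        else:
            r = float("nan")
        return PubertyFractionResults(self, slope, se, r)


class PubertyFractionResults:
    def __init__(self, model: PubertyFractionModel, p_hat: float, se: float, r: float):
        self.model = model
        self.p_hat = p_hat
        self.se = se
        self.pearson_r = r

    def summary(self) -> str:
        return (
            f"Puberty fraction fit: P = {self.p_hat:.4f} * g "
            f"(SE {self.se:.4f}, Pearson r = {self.pearson_r:.3f}, "
            f"n = {len(self.model.g)})"
        )


def fit_puberty_fraction(pairs: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Functional wrapper: (through-origin slope, Pearson r) of P on g."""
    res = PubertyFractionModel(pairs).fit()
    return res.p_hat, res.pearson_r
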