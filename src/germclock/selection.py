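"""Drift-barrier selection theory for mutator alleles, and a Wright-Fisher check.

A mutator allele raises the germline mutation rate and thereby carries an
indirect fitness cost through the deleterious mutations it creates.  Two kinds
of mutator are distinguished:

* a *non-clocklike* (per-generation) mutator adds ``u`` extra mutations per
  site per generation regardless of reproductive timing; its selection
  coefficient is ``S = -2 u L E[s]`` with ``L`` the diploid genome length and
  ``E[s]`` the mean fitness cost per mutation;
* a *clocklike* mutator adds ``k`` extra mutations per diploid genome per year
  of post-puberty germline maintenance, so its per-generation cost scales with
  the reproductive span: ``S = -k g (1 - p) E[s]``.

Selection purges a mutator once ``|S| > 1/(2 Ne)``; below that drift barrier
it is effectively neutral.  For clocklike mutators the threshold depends on
``Ne`` and ``g`` only through the product ``g * Ne``, which is why long
generation times can sharpen selection against gamete mutators even as they
depress ``Ne``.  ``Ne`` is estimated from nucleotide diversity as
``pi / (4 mu)``, and its allometric decline with generation time is modeled
as ``Ne = C * g**gamma``.

A diploid Wright-Fisher simulator provides an independent empirical check of
the near-neutrality thresholds against Kimura's diffusion fixation
probability.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "MutatorSpec",
    "PopulationContext",
    "NeScaling",
    "selection_coefficient",
    "neutrality_threshold",
    "effective_popsize_from_diversity",
    "gNe_curve",
    "kimura_fixation_probability",
    "simulate_mutator_fate",
    "FixationEstimate",
]

logger = logging.getLogger(__name__)

MutatorMode = Literal["clocklike", "per_generation"]


@dataclass(frozen=True)
class MutatorSpec:
    """A mutator allele's mode and effect size.

    ``effect`` is ``k`` (extra mutations per diploid genome per year after
    puberty) in 'clocklike' mode, or ``u`` (extra mutations per site per
    generation) in 'per_generation' mode.
    """

    mode: MutatorMode
    effect: float

    def __post_init__(self) -> None:
        if self.mode not in ("clocklike", "per_generation"):
            raise ValueError(f"unknown mutator mode {self.mode!r}")
        if self.effect < 0:
            raise ValueError("mutator effect must be >= 0")


@dataclass(frozen=True)
class PopulationContext:
    """Population parameters entering the drift-barrier calculations."""

    Ne: float
    g: float
    p: float = 0.42
    E_s: float = 1e-3
    L: float = 6e9

    def __post_init__(self) -> None:
        if self.Ne < 1:
            raise ValueError("Ne must be >= 1")
        if self.g <= 0:
            raise ValueError("g must be > 0")
        if not 0 <= self.p < 1:
            raise ValueError("p must be in [0, 1)")
        if self.E_s < 0 or self.L <= 0:
            raise ValueError("E_s must be >= 0 and L > 0")


@dataclass(frozen=True)
class NeScaling:
    """Allometric scaling Ne = C * g**gamma."""

    C: float
    gamma: float

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")


def selection_coefficient(
    m: MutatorSpec, ctx: PopulationContext, per_genome_u: bool = False
) -> float:
    """Selection coefficient of a mutator allele (reported <= 0).

    In 'per_generation' mode, ``u`` is a per-site rate and the cost is
    ``-2 u L E[s]``; with ``per_genome_u=True`` the effect is instead read as
    a whole-genome load per generation and the cost is ``-u E[s]`` (an
    alternative reading some theory uses).  In 'clocklike' mode the cost is
    ``-k g (1 - p) E[s]``; both modes are normalized to negative values so
    magnitudes compare directly with the drift barrier 1/(2 Ne).
    """
    if m.mode == "per_generation":
        if per_genome_u:
            return -m.effect * ctx.E_s
        return -2.0 * m.effect * ctx.L * ctx.E_s
    return -m.effect * ctx.g * (1.0 - ctx.p) * ctx.E_s


def neutrality_threshold(
    mode: MutatorMode, ctx: PopulationContext, per_genome_u: bool = False
) -> float:
    """Smallest mutator effect whose cost exceeds the drift barrier 1/(2 Ne).

    'per_generation': ``u > 1 / (4 Ne L E[s])`` per site (or
    ``u > 1 / (2 Ne E[s])`` per genome with ``per_genome_u=True``);
    'clocklike': ``k > 1 / (2 Ne g (1 - p) E[s]) = 1 / (2 gNe (1 - p) E[s])``
    per year — the product ``g * Ne`` alone sets the clocklike barrier.
    """
    if ctx.E_s == 0:
        raise ValueError("E_s must be > 0 for a finite threshold")
    if mode == "per_generation":
        if per_genome_u:
            return 1.0 / (2.0 * ctx.Ne * ctx.E_s)
        return 1.0 / (4.0 * ctx.Ne * ctx.L * ctx.E_s)
    if mode == "clocklike":
        denom = 2.0 * ctx.Ne * ctx.g * (1.0 - ctx.p) * ctx.E_s
        if denom == 0:
            raise ValueError("g (1 - p) must be > 0 for a clocklike threshold")
        return 1.0 / denom
    raise ValueError(f"unknown mutator mode {mode!r}")


def effective_popsize_from_diversity(pi: float, mu: float) -> float:
    """Ne = pi / (4 mu) from pairwise nucleotide diversity."""
    if mu <= 0:
        raise ValueError("mu must be > 0")
    if pi < 0:
        raise ValueError("pi must be >= 0")
    return pi / (4.0 * mu)


def gNe_curve(g, s: NeScaling):
    """(Ne, g*Ne) at generation time g under Ne = C * g**gamma."""
    g = np.asarray(g, dtype=float)
    if np.any(g <= 0):
        raise ValueError("g must be > 0")
    Ne = s.C * g**s.gamma
    gNe = g * Ne
    if Ne.ndim == 0:
        return float(Ne), float(gNe)
    return Ne, gNe


# ---------------------------------------------------------------------------
# Wright-Fisher verification of the drift barrier


def kimura_fixation_probability(S: float, N: int, p0: float | None = None) -> float:
    """Diffusion fixation probability of an allele with genic coefficient S.

    Genotype fitnesses are 1, 1 + S/2, 1 + S (the heterozygous carrier pays
    half the full cost S); the standard diffusion result for initial
    frequency p0 (default a single copy, 1/(2N)) is

        u(p0) = (1 - exp(-2 N S p0 * 2)) / (1 - exp(-2 N S))
              = (1 - exp(-2 N S p0)) / (1 - exp(-2 N S)),

    written with the per-homozygote coefficient S so that u(1/(2N)) reduces to
    (1 - e^{-S}) / (1 - e^{-2NS}); S = 0 returns p0.
    """
    if p0 is None:
        p0 = 1.0 / (2.0 * N)
    if S == 0.0:
        return p0
    num = -math.expm1(-2.0 * N * S * p0)
    den = -math.expm1(-2.0 * N * S)
    return num / den


@dataclass(frozen=True)
class FixationEstimate:
    """Monte Carlo fixation probability with its binomial standard error."""

    prob: float
    se: float
    n_fixed: int
    n_lost: int
    n_unresolved: int
    reps: int


def simulate_mutator_fate(
    S: float,
    N: int,
    reps: int = 10_000,
    seed: int | np.random.Generator | None = None,
    p0: float | None = None,
) -> FixationEstimate:
    """Wright-Fisher fate of an allele with genic selection coefficient S.

    Simulates ``reps`` independent diploid populations of size N.  Each starts
    with one allele copy (frequency 1/(2N) unless ``p0`` is given) and evolves
    by binomial resampling of 2N copies around the post-selection frequency

        p* = p (1 + S/2 + p S/2) / (1 + p S)

    (genotype fitnesses 1, 1 + S/2, 1 + S under random mating) until loss or
    fixation.  Trajectories still segregating after 100 * 2N generations are
    counted as losses and logged.
    """
    if N < 10:
        raise ValueError("N must be >= 10")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    two_n = 2 * N
    if p0 is None:
        counts = np.ones(reps, dtype=np.int64)
    else:
        counts = np.full(reps, int(round(p0 * two_n)), dtype=np.int64)
    n_fixed = 0
    n_lost = 0
    cap = 100 * two_n
    s_half = S / 2.0
    for _ in range(cap):
        if counts.size == 0:
            break
        p = counts / two_n
        p_star = p * (1.0 + s_half + p * s_half) / (1.0 + p * S)
        counts = rng.binomial(two_n, p_star)
        lost = counts == 0
        fixed = counts == two_n
        n_lost += int(lost.sum())
        n_fixed += int(fixed.sum())
        counts = counts[~(lost | fixed)]
    n_unresolved = int(counts.size)
    if n_unresolved:
        logger.warning(
            "%d/%d trajectories unresolved after %d generations; counted as losses",
            n_unresolved,
            reps,
            cap,
        )
        n_lost += n_unresolved
    prob = n_fixed / reps
    se = math.sqrt(max(prob * (1.0 - prob), 1.0 / reps) / reps)
    return FixationEstimate(
        prob=prob, se=se, n_fixed=n_fixed, n_lost=n_lost,
        n_unresolved=n_unresolved, reps=reps,
    )
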