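"""Closed-form establishment and equilibrium results for a single diploid locus.

These are the analytic benchmarks the stochastic simulator is validated
against, plus the inverse problem: given an observed carrier prevalence of a
homozygous-lethal variant at equilibrium, estimate the heterozygous selective
advantage that sustains it.

Notation: ``s`` is the additive selection coefficient (carriers leave
``(1+s)``-fold as many offspring as wild type); ``p`` the variant-allele
frequency and ``q = 1 - p``; genotype fractions at a Fisher selection
equilibrium are Hardy-Weinberg, ``P = p^2`` (variant homozygotes),
``2Q = 2pq`` (carriers), ``R = q^2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .model_core import InvalidParameterError

__all__ = [
    "EquilibriumSolution",
    "establishment_probability",
    "haldane_approximation",
    "fisher_equilibrium",
    "approx_carrier_fraction",
    "solve_s_for_carrier",
    "generations_to_years",
]


@dataclass(frozen=True)
class EquilibriumSolution:
    """Polymorphic selection equilibrium of a single diploid locus.

    ``valid`` is False when no interior equilibrium exists (no heterozygote
    advantage); the frequency fields then describe the wild-type boundary
    state ``p = 0``.
    """

    p: float
    q: float
    carrier_fraction: float
    hom_fraction: float
    valid: bool


def establishment_probability(s: float) -> float:
    """Probability that a single beneficial allele survives genetic drift.

    Returns ``1 - exp(-2 s)`` for ``s > 0`` (the finite-population
    refinement of Haldane's classical ``2 s``, accurate also for large
    ``s``), and exactly 0 for ``s <= 0``: a neutral or deleterious variant
    present as a single copy is eventually lost.
    """
    if s < -1.0:
        raise InvalidParameterError("s must lie in [-1, inf), got %r" % (s,))
    if s <= 0.0:
        return 0.0
    return -math.expm1(-2.0 * s)


def haldane_approximation(s: float) -> float:
    """Haldane's small-``s`` linearization ``P ~ 2 s`` of the establishment probability."""
    if s < -1.0:
        raise InvalidParameterError("s must lie in [-1, inf), got %r" % (s,))
    return 2.0 * s if s > 0.0 else 0.0


def fisher_equilibrium(s_het: float, s_hom: float) -> EquilibriumSolution:
    """Fisher's random-mating selection equilibrium for arbitrary genotype fitnesses.

    With parental selection weights ``a : b : c`` proportional to
    ``1+s_hom : 1+s_het : 1`` applied to genotype fractions ``P : 2Q : R``,
    a stable interior equilibrium requires heterozygote advantage
    (``b > a`` and ``b > c``) and sits at the Hardy-Weinberg state with

    ``p* = (b - c) / (2b - a - c)``.

    For a lethal homozygote (``s_hom = -1``, so ``a = 0``) this reduces to
    the closed forms ``p = s/(1+2s)`` and carrier fraction
    ``2Q = 2 s (1+s) / (1+2s)^2`` with ``s = s_het``.

    Absent heterozygote advantage the polymorphism is not protected and the
    solution is flagged invalid (returned as the ``p = 0`` boundary).
    """
    if s_het < -1.0:
        raise InvalidParameterError("s_het must lie in [-1, inf), got %r" % (s_het,))
    if s_hom < -1.0:
        raise InvalidParameterError("s_hom must lie in [-1, inf), got %r" % (s_hom,))
    a = 1.0 + s_hom
    b = 1.0 + s_het
    c = 1.0
    if b > a and b > c:
        p = (b - c) / (2.0 * b - a - c)
        q = 1.0 - p
        return EquilibriumSolution(
            p=p, q=q, carrier_fraction=2.0 * p * q, hom_fraction=p * p, valid=True
        )
    return EquilibriumSolution(p=0.0, q=1.0, carrier_fraction=0.0, hom_fraction=0.0, valid=False)


def approx_carrier_fraction(s: float) -> float:
    """Small-``s`` approximation ``2Q ~ 2s / (1 + 4s)`` of the equilibrium carrier fraction.

    Valid for a homozygous-lethal variant with small heterozygous advantage
    ``s``; the relative error against the exact form grows roughly linearly
    in ``s``.
    """
    if s < 0.0:
        raise InvalidParameterError("s must be non-negative, got %r" % (s,))
    return 2.0 * s / (1.0 + 4.0 * s)


def solve_s_for_carrier(target_carrier: float) -> float:
    """Heterozygous advantage sustaining a given equilibrium carrier prevalence.

    Inverts the lethal-homozygote closed form
    ``2 s (1+s) / (1+2s)^2 = T``, i.e. solves the quadratic
    ``(2-4T) s^2 + (2-4T) s - T = 0`` for its positive root. Defined for
    ``T`` in ``(0, 1/2)``; the carrier fraction approaches 1/2 only as
    ``s -> inf``.
    """
    t = float(target_carrier)
    if not 0.0 < t < 0.5:
        raise InvalidParameterError(
            "target_carrier must lie in (0, 0.5), got %r" % (target_carrier,)
        )
    coeff = 2.0 - 4.0 * t
    return (-coeff + math.sqrt(coeff * coeff + 4.0 * coeff * t)) / (2.0 * coeff)


def generations_to_years(generations: float, years_per_generation: float = 29.0) -> float:
    """Convert a generation count to calendar years (nominal 29 years/generation)."""
    if years_per_generation <= 0:
        raise InvalidParameterError("years_per_generation must be positive")
    return generations * years_per_generation
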