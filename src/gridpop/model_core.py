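"""Per-generation stochastic update of a diploid population on a toroidal lattice.

The population lives on a square torus with exactly one individual per cell
(density ``d = 1``). Each generation is non-overlapping and proceeds in four
phases:

1. *Mortality* — every individual is independently marked dead with a
   probability set by its genotype's relative fitness,
   ``p_death(g) = 1 - w_g / w_max`` with ``w_wild = 1``,
   ``w_het = 1 + s_het``, ``w_hom = 1 + s_hom``.
2. *Parent sampling* — every cell of the next generation draws two distinct
   surviving parents by sampling isotropic Gaussian offsets (standard
   deviation ``sigma`` per axis) from itself, rounding to the nearest cell and
   wrapping on the torus. ``sigma`` realizes a Wright neighborhood of size
   ``N_n = 4 pi sigma^2 d``.
3. *Mendelian transmission* — each parent contributes one allele (wild-type
   homozygotes a wild allele, variant homozygotes a variant allele,
   heterozygotes a fair coin).
4. *De novo mutation* — each wild allele of the offspring independently
   converts to the variant with probability ``mu``.

Genotypes are encoded as small integers (``WILD=0, HET=1, HOM=2, DEAD=3``)
and the lattice state is a dense ``int8`` array; ``DEAD`` exists only
transiently between the mortality and reproduction phases.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import IntEnum
from typing import Dict, Optional, Tuple

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Genotype",
    "WILD",
    "HET",
    "HOM",
    "DEAD",
    "InvalidParameterError",
    "PopulationCollapseError",
    "SimulationParams",
    "PopulationGrid",
    "GenerationStats",
    "sigma_from_neighborhood",
    "neighborhood_size",
    "apply_mortality",
    "sample_parent_pair",
    "mendelian_offspring",
    "apply_de_novo",
    "step_generation",
]


class Genotype(IntEnum):
    """Single-locus diploid genotype state of one lattice cell."""

    WILD = 0
    HET = 1
    HOM = 2
    DEAD = 3


WILD: Genotype = Genotype.WILD
HET: Genotype = Genotype.HET
HOM: Genotype = Genotype.HOM
DEAD: Genotype = Genotype.DEAD


class InvalidParameterError(ValueError):
    """A parameter violates its documented constraint."""


class PopulationCollapseError(RuntimeError):
    """Fewer than two individuals survived mortality; no parent pair exists."""


def sigma_from_neighborhood(n_n: float, d: float = 1.0) -> float:
    """Dispersal-kernel standard deviation realizing a neighborhood of size ``n_n``.

    Inverts Wright's neighborhood relation ``N_n = 4 pi sigma^2 d``: the
    effective community an individual draws mates from is the population
    within a circle of radius ``2 sigma`` at density ``d``.

    Parameters
    ----------
    n_n : float
        Neighborhood (community) size, in individuals. Must be positive.
    d : float, optional
        Population density, individuals per cell. The lattice construction
        fixes this at 1.

    Returns
    -------
    float
        ``sqrt(n_n / (4 pi d))``, in cells.
    """
    if n_n <= 0:
        raise InvalidParameterError("n_n must be positive, got %r" % (n_n,))
    if d <= 0:
        raise InvalidParameterError("density d must be positive, got %r" % (d,))
    return math.sqrt(n_n / (4.0 * math.pi * d))


def neighborhood_size(sigma: float, d: float = 1.0) -> float:
    """Neighborhood size ``N_n = 4 pi sigma^2 d`` realized by kernel width ``sigma``."""
    if sigma <= 0:
        raise InvalidParameterError("sigma must be positive, got %r" % (sigma,))
    if d <= 0:
        raise InvalidParameterError("density d must be positive, got %r" % (d,))
    return 4.0 * math.pi * sigma * sigma * d


@dataclass(frozen=True)
class SimulationParams:
    """Full parameter set for one simulation scenario.

    Exactly one of ``init_het_fraction`` / ``init_copies`` must be given.
    The census size actually simulated is ``side**2`` with
    ``side = round(sqrt(N))`` (square torus); see :attr:`n_effective`.

    Attributes
    ----------
    N : int
        Requested census population size.
    n_n : float, optional
        Effective community (neighborhood) size; used to derive the kernel
        width via ``N_n = 4 pi sigma^2`` (density 1) when ``sigma`` is not
        given explicitly.
    sigma : float, optional
        Kernel standard deviation in cells. Overrides ``n_n`` if set.
    panmictic : bool
        Random mating over the whole grid (kernel at least as wide as the
        torus side).
    s_het, s_hom : float
        Selection coefficients of heterozygotes / variant homozygotes,
        constrained to ``[-1, inf)``; carriers have ``(1+s)``-fold expected
        offspring relative to wild type.
    init_het_fraction : float, optional
        Each individual starts heterozygous independently with this
        probability.
    init_copies : int, optional
        Exactly this many heterozygous founders at distinct random cells.
    mu : float
        De novo wild-to-variant mutation probability per transmitted allele.
    max_generations : int
        Generation cap for a run.
    seed : int, optional
        RNG seed recorded with every run.
    """

    N: int
    n_n: Optional[float] = None
    sigma: Optional[float] = None
    panmictic: bool = False
    s_het: float = 0.0
    s_hom: float = 0.0
    init_het_fraction: Optional[float] = None
    init_copies: Optional[int] = None
    mu: float = 0.0
    max_generations: int = 1000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.N < 4:
            raise InvalidParameterError("N must be at least 4, got %r" % (self.N,))
        if self.s_het < -1.0:
            raise InvalidParameterError(
                "s_het must lie in [-1, inf), got %r" % (self.s_het,)
            )
        if self.s_hom < -1.0:
            raise InvalidParameterError(
                "s_hom must lie in [-1, inf), got %r" % (self.s_hom,)
            )
        if not 0.0 <= self.mu <= 1.0:
            raise InvalidParameterError("mu must lie in [0, 1], got %r" % (self.mu,))
        if (self.init_het_fraction is None) == (self.init_copies is None):
            raise InvalidParameterError(
                "exactly one of init_het_fraction / init_copies must be set"
            )
        if self.init_het_fraction is not None and not 0.0 <= self.init_het_fraction <= 1.0:
            raise InvalidParameterError(
                "init_het_fraction must lie in [0, 1], got %r"
                % (self.init_het_fraction,)
            )
        if self.init_copies is not None and not 0 <= self.init_copies <= self.n_effective:
            raise InvalidParameterError(
                "init_copies must lie in [0, N], got %r" % (self.init_copies,)
            )
        if self.max_generations < 0:
            raise InvalidParameterError("max_generations must be non-negative")
        if self.n_n is not None:
            if self.n_n <= 0:
                raise InvalidParameterError("n_n must be positive, got %r" % (self.n_n,))
            if self.n_n > self.N:
                raise InvalidParameterError(
                    "n_n (%r) must not exceed N (%r)" % (self.n_n, self.N)
                )
        if self.sigma is not None and self.sigma <= 0:
            raise InvalidParameterError("sigma must be positive, got %r" % (self.sigma,))
        if not self.panmictic and self.sigma is None and self.n_n is None:
            raise InvalidParameterError(
                "provide sigma or n_n, or set panmictic=True"
            )
        _ = self.kernel_sigma  # force derivation errors now

    @property
    def side(self) -> int:
        """Torus side length ``L = round(sqrt(N))`` in cells."""
        return int(round(math.sqrt(self.N)))

    @property
    def n_effective(self) -> int:
        """Census size actually simulated, ``L**2``."""
        return self.side * self.side

    @property
    def kernel_sigma(self) -> float:
        """Resolved kernel standard deviation in cells."""
        if self.sigma is not None:
            return float(self.sigma)
        if self.panmictic:
            return float(self.side)
        return sigma_from_neighborhood(self.n_n)

    @property
    def is_panmictic(self) -> bool:
        """Whether the kernel is effectively uniform over the torus."""
        return self.panmictic or self.kernel_sigma >= self.side

    @property
    def fitness(self) -> np.ndarray:
        """Relative fitness ``(w_wild, w_het, w_hom) = (1, 1+s_het, 1+s_hom)``."""
        return np.array([1.0, 1.0 + self.s_het, 1.0 + self.s_hom])

    @property
    def death_probabilities(self) -> np.ndarray:
        """Per-genotype mortality ``p_death(g) = 1 - w_g / w_max``."""
        w = self.fitness
        return 1.0 - w / w.max()


@dataclass
class PopulationGrid:
    """Toroidal 2-D lattice of genotype states, one individual per cell.

    All distance and offset arithmetic wraps in both dimensions, so the grid
    has no edges. Cells are addressed as ``(row, col)``.
    """

    states: np.ndarray
    generation_index: int = 0

    def __post_init__(self) -> None:
        arr = np.ascontiguousarray(self.states, dtype=np.int8)
        if arr.ndim != 2:
            raise InvalidParameterError("grid states must be a 2-D array")
        if arr.size and (arr.min() < 0 or arr.max() > int(DEAD)):
            raise InvalidParameterError("grid states must be genotype codes 0..3")
        self.states = arr

    @property
    def height(self) -> int:
        return self.states.shape[0]

    @property
    def width(self) -> int:
        return self.states.shape[1]

    @property
    def n(self) -> int:
        """Census size (number of cells)."""
        return self.states.size

    @property
    def has_dead(self) -> bool:
        return bool((self.states == int(DEAD)).any())

    def counts(self) -> np.ndarray:
        """Living genotype counts ``(n_wild, n_het, n_hom)``."""
        return np.bincount(self.states.ravel(), minlength=4)[:3]

    @classmethod
    def initialize(cls, params: SimulationParams, rng: np.random.Generator) -> "PopulationGrid":
        """Generation-0 grid: wild background with heterozygous founders.

        ``init_het_fraction`` places each individual as heterozygous
        independently; ``init_copies`` places exactly that many founders at
        uniformly random distinct cells.
        """
        side = params.side
        states = np.zeros((side, side), dtype=np.int8)
        if params.init_het_fraction is not None:
            mask = rng.random(states.shape) < params.init_het_fraction
            states[mask] = int(HET)
        else:
            k = int(params.init_copies)
            if k > 0:
                flat = rng.choice(states.size, size=k, replace=False)
                states.ravel()[flat] = int(HET)
        return cls(states, generation_index=0)


@dataclass(frozen=True)
class GenerationStats:
    """Genotype census of one generation."""

    generation: int
    n_wild: int
    n_het: int
    n_hom: int

    @property
    def n(self) -> int:
        return self.n_wild + self.n_het + self.n_hom

    @property
    def allele_frequency(self) -> float:
        """Variant-allele frequency ``p = (n_het + 2 n_hom) / 2N``."""
        return (self.n_het + 2 * self.n_hom) / (2.0 * self.n)

    @property
    def carrier_fraction(self) -> float:
        """Fraction of individuals carrying at least one variant allele."""
        return (self.n_het + self.n_hom) / float(self.n)

    @property
    def het_fraction(self) -> float:
        return self.n_het / float(self.n)

    @property
    def hom_fraction(self) -> float:
        return self.n_hom / float(self.n)

    @classmethod
    def from_counts(cls, generation: int, counts: np.ndarray) -> "GenerationStats":
        return cls(generation, int(counts[0]), int(counts[1]), int(counts[2]))

    @classmethod
    def from_grid(cls, grid: PopulationGrid) -> "GenerationStats":
        return cls.from_counts(grid.generation_index, grid.counts())


def apply_mortality(
    grid: PopulationGrid, params: SimulationParams, rng: np.random.Generator
) -> PopulationGrid:
    """Mark individuals dead with genotype-dependent probability.

    Each individual of genotype ``g`` is independently marked ``DEAD`` with
    probability ``1 - w_g / w_max``; survivors are unchanged. Returns a new
    grid, leaving the input untouched.
    """
    if grid.has_dead:
        raise InvalidParameterError("apply_mortality requires a grid without DEAD cells")
    p_death = params.death_probabilities
    states = grid.states.copy()
    doomed = rng.random(states.shape) < p_death[states]
    states[doomed] = int(DEAD)
    return PopulationGrid(states, generation_index=grid.generation_index)


_COORD_CACHE: Dict[Tuple[int, int], Tuple[np.ndarray, np.ndarray]] = {}


def _cell_coords(h: int, w: int) -> Tuple[np.ndarray, np.ndarray]:
    key = (h, w)
    if key not in _COORD_CACHE:
        idx = np.arange(h * w, dtype=np.int32)
        _COORD_CACHE[key] = (idx // w, idx % w)
    return _COORD_CACHE[key]


def sample_parent_pair(
    grid: PopulationGrid,
    focal_cell: Tuple[int, int],
    sigma: float,
    rng: np.random.Generator,
    rejection_budget: int = 1000,
) -> Tuple[Tuple[int, int], Tuple[int, int]]:
    """Draw two distinct non-dead parent cells around ``focal_cell``.

    Each parent is drawn by sampling a continuous isotropic Gaussian offset
    (standard deviation ``sigma`` per axis), rounding to the nearest cell and
    wrapping on the torus. Draws landing on dead cells (or duplicating the
    first parent) are rejected and redrawn; after ``rejection_budget``
    consecutive rejections the kernel width is doubled (logged) so the draw
    always terminates while survivors exist. The focal cell itself is a
    legitimate parent.

    Raises
    ------
    PopulationCollapseError
        If fewer than two non-dead individuals exist on the whole grid.
    """
    if sigma <= 0:
        raise InvalidParameterError("sigma must be positive, got %r" % (sigma,))
    states = grid.states
    h, w = states.shape
    n_alive = int((states != int(DEAD)).sum())
    if n_alive < 2:
        raise PopulationCollapseError(
            "fewer than two survivors on the grid (%d alive)" % n_alive
        )
    fr, fc = int(focal_cell[0]) % h, int(focal_cell[1]) % w

    def draw(exclude: Optional[Tuple[int, int]]) -> Tuple[int, int]:
        cur = float(sigma)
        rejections = 0
        while True:
            dr = int(round(rng.normal(0.0, cur)))
            dc = int(round(rng.normal(0.0, cur)))
            cell = ((fr + dr) % h, (fc + dc) % w)
            if states[cell] != int(DEAD) and cell != exclude:
                return cell
            rejections += 1
            if rejections % rejection_budget == 0:
                cur *= 2.0
                logger.warning(
                    "parent sampling exhausted %d draws near cell %r; "
                    "widening kernel sigma to %.3g",
                    rejections,
                    (fr, fc),
                    cur,
                )

    first = draw(None)
    second = draw(first)
    return first, second


def mendelian_offspring(
    g1: int, g2: int, rng: np.random.Generator
) -> Genotype:
    """Offspring genotype from two parents under Mendelian transmission.

    Each parent contributes one allele: wild-type homozygotes a wild allele,
    variant homozygotes a variant allele, heterozygotes a variant allele with
    probability 1/2.
    """

    def allele(g: int) -> int:
        if g == int(HOM):
            return 1
        if g == int(HET):
            return int(rng.random() < 0.5)
        if g == int(WILD):
            return 0
        raise InvalidParameterError("parent genotype must be WILD/HET/HOM, got %r" % (g,))

    return Genotype(allele(int(g1)) + allele(int(g2)))


def apply_de_novo(g: int, mu: float, rng: np.random.Generator) -> Genotype:
    """Convert each wild allele of genotype ``g`` to the variant with probability ``mu``."""
    if not 0.0 <= mu <= 1.0:
        raise InvalidParameterError("mu must lie in [0, 1], got %r" % (mu,))
    g = int(g)
    if g not in (int(WILD), int(HET), int(HOM)):
        raise InvalidParameterError("genotype must be WILD/HET/HOM, got %r" % (g,))
    if mu == 0.0 or g == int(HOM):
        return Genotype(g)
    return Genotype(g + int(rng.binomial(2 - g, mu)))


# --- vectorized lattice engine -------------------------------------------------

def _batch_sample_parents(
    alive: np.ndarray,
    h: int,
    w: int,
    sigma: float,
    rng: np.random.Generator,
    taken: Optional[np.ndarray] = None,
    rejection_budget: int = 1000,
) -> np.ndarray:
    """One parent (flat index) per cell, Gaussian kernel with rejection redraw.

    ``alive`` is a flat boolean mask; ``taken`` (if given) holds the first
    parent of each cell, which the second draw must not duplicate. Pending
    cells that exhaust the rejection budget get a doubled kernel width, so
    the loop terminates whenever at least two survivors exist.
    """
    rows, cols = _cell_coords(h, w)
    cur = float(sigma)
    rounds = 0

    def candidates(frow: np.ndarray, fcol: np.ndarray) -> np.ndarray:
        m = frow.size
        off = rng.standard_normal(m, dtype=np.float32)
        off *= cur
        np.rint(off, out=off)
        rr = frow + off.astype(np.int32)
        rr %= h
        off = rng.standard_normal(m, dtype=np.float32)
        off *= cur
        np.rint(off, out=off)
        cc = fcol + off.astype(np.int32)
        cc %= w
        rr *= w
        rr += cc
        return rr

    # first pass over the full grid without indirection, then redraw rejects
    out = candidates(rows, cols)
    ok = alive[out]
    if taken is not None:
        ok &= out != taken
    pending = np.nonzero(~ok)[0].astype(np.int32)
    while pending.size:
        rounds += 1
        if rounds % rejection_budget == 0:
            cur *= 2.0
            logger.warning(
                "parent sampling: %d cells still unresolved after %d rounds; "
                "widening kernel sigma to %.3g",
                pending.size,
                rounds,
                cur,
            )
        cand = candidates(rows[pending], cols[pending])
        ok = alive[cand]
        if taken is not None:
            ok &= cand != taken[pending]
        out[pending[ok]] = cand[ok]
        pending = pending[~ok]
    return out


def _transmit(g: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorized gamete draw: one allele (0/1) from each parent genotype."""
    out = (g == int(HOM)).astype(np.int8)
    het = np.nonzero(g == int(HET))[0]
    if het.size:
        out[het] = rng.random(het.size) < 0.5
    return out


def _step_lattice(
    states: np.ndarray, params: SimulationParams, rng: np.random.Generator
) -> np.ndarray:
    h, w = states.shape
    flat = states.reshape(-1)
    doomed = rng.random(flat.size) < params.death_probabilities[flat]
    alive = ~doomed
    if int(alive.sum()) < 2:
        raise PopulationCollapseError("fewer than two survivors after mortality")
    sigma = params.kernel_sigma
    p1 = _batch_sample_parents(alive, h, w, sigma, rng)
    p2 = _batch_sample_parents(alive, h, w, sigma, rng, taken=p1)
    child = _transmit(flat[p1], rng) + _transmit(flat[p2], rng)
    if params.mu > 0.0:
        child = (child + rng.binomial((2 - child).astype(np.int64), params.mu)).astype(
            np.int8
        )
    return child.reshape(h, w)


# --- exact panmictic (genotype-count) engine -----------------------------------

# P(offspring = k | parents i, j): each parent passes the variant with
# probability (0, 1/2, 1) for (WILD, HET, HOM).
_ALLELE_P = np.array([0.0, 0.5, 1.0])
_MENDEL = np.empty((3, 3, 3))
_MENDEL[:, :, 2] = np.outer(_ALLELE_P, _ALLELE_P)
_MENDEL[:, :, 0] = np.outer(1.0 - _ALLELE_P, 1.0 - _ALLELE_P)
_MENDEL[:, :, 1] = 1.0 - _MENDEL[:, :, 0] - _MENDEL[:, :, 2]
_MENDEL.setflags(write=False)


def _mutation_matrix(mu: float) -> np.ndarray:
    """Genotype transition matrix of per-wild-allele de novo mutation."""
    return np.array(
        [
            [(1 - mu) ** 2, 2 * mu * (1 - mu), mu * mu],
            [0.0, 1 - mu, mu],
            [0.0, 0.0, 1.0],
        ]
    )


def _offspring_distribution(surv: np.ndarray, mu: float) -> np.ndarray:
    """Offspring genotype law given survivor counts, under uniform pair sampling.

    Parent pairs are ordered draws of two *distinct* survivors, exactly as in
    the lattice procedure's uniform-kernel limit.
    """
    a = int(surv.sum())
    pair = np.outer(surv, surv).astype(float)
    np.fill_diagonal(pair, pair.diagonal() - surv)
    pair /= a * (a - 1)
    probs = np.tensordot(pair, _MENDEL, axes=([0, 1], [0, 1]))
    if mu > 0.0:
        probs = probs @ _mutation_matrix(mu)
    return probs / probs.sum()


def _step_counts(
    counts: np.ndarray,
    params: SimulationParams,
    rng: np.random.Generator,
    n_offspring: int,
) -> np.ndarray:
    """One generation of the exact aggregated update for a panmictic population.

    Scalar closed form of :func:`_offspring_distribution` (same law, no
    3x3 temporaries): with survivor counts ``(w, h, m)``, transmission
    probabilities ``t = (0, 1/2, 1)`` and ``T = sum c_i t_i``, the chance
    that both parents of an ordered distinct pair transmit the variant is
    ``(T^2 - sum c_i t_i^2) / (A (A - 1))``, and symmetrically for neither.
    """
    surv = rng.binomial(counts, 1.0 - params.death_probabilities)
    w, h, m = (int(v) for v in surv)
    a = w + h + m
    if a < 2:
        raise PopulationCollapseError("fewer than two survivors after mortality")
    denom = a * (a - 1.0)
    t_sum = 0.5 * h + m
    u_sum = w + 0.5 * h
    p2 = (t_sum * t_sum - (0.25 * h + m)) / denom
    p0 = (u_sum * u_sum - (w + 0.25 * h)) / denom
    p1 = 1.0 - p0 - p2
    mu = params.mu
    if mu > 0.0:
        p0, p1, p2 = (
            p0 * (1.0 - mu) ** 2,
            p0 * 2.0 * mu * (1.0 - mu) + p1 * (1.0 - mu),
            p0 * mu * mu + p1 * mu + p2,
        )
    return rng.multinomial(n_offspring, (p0, p1, p2))


def step_generation(
    grid: PopulationGrid, params: SimulationParams, rng: np.random.Generator
) -> Tuple[PopulationGrid, GenerationStats]:
    """Advance the population by one non-overlapping generation.

    Applies mortality, then repopulates every cell of a fresh same-sized grid
    with a Mendelian offspring of two kernel-sampled survivors, then de novo
    mutation. The returned grid contains no dead cells and its census equals
    the input census exactly.

    For a panmictic kernel the offspring genotype counts are drawn from the
    exact aggregated law (spatial position carries no information in that
    limit) and placed uniformly at random on the grid.
    """
    if grid.has_dead:
        raise InvalidParameterError("step_generation requires a grid without DEAD cells")
    if params.is_panmictic:
        counts = grid.counts()
        new_counts = _step_counts(counts, params, rng, grid.n)
        flat = np.repeat(np.arange(3, dtype=np.int8), new_counts)
        rng.shuffle(flat)
        new_states = flat.reshape(grid.states.shape)
    else:
        new_states = _step_lattice(grid.states, params, rng)
    new_grid = PopulationGrid(new_states, generation_index=grid.generation_index + 1)
    return new_grid, GenerationStats.from_grid(new_grid)
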