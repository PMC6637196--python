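"""Monte Carlo drivers: trajectories, establishment rates, equilibria, sweeps.

Everything here is deterministic given a master seed: batch runs derive one
child RNG stream per trial from :class:`numpy.random.SeedSequence`, so a
sweep is reproducible cell-by-cell and bit-identical across reruns.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, replace
from enum import Enum
from typing import List, Optional, Sequence, Union

import numpy as np
from scipy.stats import binomtest

from .model_core import (
    GenerationStats,
    InvalidParameterError,
    PopulationCollapseError,
    PopulationGrid,
    SimulationParams,
    _step_counts,
    step_generation,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TerminalStatus",
    "Trajectory",
    "EstablishmentResult",
    "SweepResult",
    "run_trajectory",
    "estimate_establishment",
    "estimate_equilibrium",
    "sweep",
    "scenario_preset",
    "PRESET_NAMES",
]

SeedLike = Union[None, int, np.random.SeedSequence]


def _seed_sequence(master_seed: SeedLike) -> np.random.SeedSequence:
    if isinstance(master_seed, np.random.SeedSequence):
        return master_seed
    return np.random.SeedSequence(master_seed)


class TerminalStatus(str, Enum):
    """How a trajectory ended."""

    EXTINCT = "extinct"  # zero variant alleles
    FIXED = "fixed"  # zero wild alleles
    MAX_GENERATIONS = "max_generations"


@dataclass
class Trajectory:
    """Per-generation genotype census of one run plus its terminal status."""

    params: SimulationParams
    seed: Optional[int]
    stats: List[GenerationStats]
    terminal: TerminalStatus
    collapsed: bool = False

    @property
    def n_generations(self) -> int:
        """Index of the last recorded generation."""
        return self.stats[-1].generation

    def carrier_series(self, pad_to: Optional[int] = None) -> np.ndarray:
        """Carrier fraction per generation, optionally padded to a fixed length.

        Padding extends an extinct run with zeros and a fixed run with ones,
        the values the frozen population would keep holding.
        """
        return self._series([s.carrier_fraction for s in self.stats], pad_to)

    def het_series(self, pad_to: Optional[int] = None) -> np.ndarray:
        """Heterozygote fraction per generation; fixed runs pad with zero."""
        vals = [s.het_fraction for s in self.stats]
        return self._series(vals, pad_to, fixed_value=0.0)

    def allele_series(self, pad_to: Optional[int] = None) -> np.ndarray:
        return self._series([s.allele_frequency for s in self.stats], pad_to)

    def _series(
        self, vals: Sequence[float], pad_to: Optional[int], fixed_value: float = 1.0
    ) -> np.ndarray:
        arr = np.asarray(vals, dtype=float)
        if pad_to is None or arr.size >= pad_to + 1:
            return arr[: None if pad_to is None else pad_to + 1]
        out = np.zeros(pad_to + 1)
        out[: arr.size] = arr
        if self.terminal is TerminalStatus.FIXED:
            out[arr.size:] = fixed_value
        return out


@dataclass(frozen=True)
class EstablishmentResult:
    """Monte Carlo establishment-probability estimate with binomial uncertainty."""

    n_trials: int
    n_established: int
    p_hat: float
    ci_low: float
    ci_high: float
    mean_survival_generations: float
    mean_max_prevalence: float
    master_seed: Optional[int] = None
    params: Optional[SimulationParams] = None


@dataclass
class SweepResult:
    """Estimated quantity per (community size, selection coefficient) cell."""

    n_n_values: np.ndarray
    s_values: np.ndarray
    matrix: np.ndarray
    runs_per_cell: int
    generations_per_cell: int
    quantity: str
    seeds: np.ndarray
    master_seed: Optional[int] = None
    params_base: Optional[SimulationParams] = None


def run_trajectory(
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
    force_lattice: bool = False,
) -> Trajectory:
    """Simulate one run until extinction, fixation, or the generation cap.

    A panmictic kernel dispatches to the exact genotype-count engine (spatial
    position carries no information under uniform mating); pass
    ``force_lattice=True`` to run the explicit lattice procedure regardless.
    A total population collapse (everybody dead before reproduction) is
    recorded as extinction with ``collapsed=True``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.n_effective
    use_counts = params.is_panmictic and not force_lattice

    if use_counts:
        if params.init_copies is not None:
            counts = np.array([n - params.init_copies, params.init_copies, 0], dtype=np.int64)
        else:
            k = int(rng.binomial(n, params.init_het_fraction))
            counts = np.array([n - k, k, 0], dtype=np.int64)
    else:
        grid = PopulationGrid.initialize(params, rng)
        counts = grid.counts()

    stats = [GenerationStats.from_counts(0, counts)]
    terminal = TerminalStatus.MAX_GENERATIONS
    collapsed = False

    def finished(st: GenerationStats) -> Optional[TerminalStatus]:
        if st.n_het == 0 and st.n_hom == 0:
            return TerminalStatus.EXTINCT
        if st.n_wild == 0 and st.n_het == 0:
            return TerminalStatus.FIXED
        return None

    status = finished(stats[0])
    if status is not None and params.mu == 0.0:
        return Trajectory(params, params.seed, stats, status)

    for gen in range(1, params.max_generations + 1):
        try:
            if use_counts:
                counts = _step_counts(counts, params, rng, n)
                st = GenerationStats.from_counts(gen, counts)
            else:
                grid, st = step_generation(grid, params, rng)
        except PopulationCollapseError:
            terminal = TerminalStatus.EXTINCT
            collapsed = True
            break
        stats.append(st)
        status = finished(st)
        # with recurrent mutation an extinct/fixed census is not absorbing
        if status is TerminalStatus.EXTINCT and params.mu > 0.0:
            status = None
        if status is not None:
            terminal = status
            break

    return Trajectory(params, params.seed, stats, terminal, collapsed)


def _is_established(traj: Trajectory, params: SimulationParams) -> bool:
    if traj.terminal is TerminalStatus.FIXED:
        return True
    # a homozygous disadvantage makes fixation (essentially) unreachable;
    # persistent segregation to the generation cap counts as establishment
    if params.s_hom < 0.0 and traj.terminal is TerminalStatus.MAX_GENERATIONS:
        return True
    return False


def estimate_establishment(
    params: SimulationParams,
    n_trials: int,
    master_seed: SeedLike = None,
) -> EstablishmentResult:
    """Establishment probability of a rare variant, from independent trials.

    Runs ``n_trials`` trajectories with derived child seeds and counts a
    trial as established when it fixes, or — when ``s_hom < 0`` so fixation
    is impossible — when the variant is still segregating at the generation
    cap. Reports the rate with a Wilson 95% interval, the mean survival time
    of extinct trials, and the mean maximum carrier prevalence attained.
    """
    if n_trials < 1:
        raise InvalidParameterError("n_trials must be at least 1")
    if params.init_copies is None:
        raise InvalidParameterError(
            "estimate_establishment requires init_copies (a countable founding dose)"
        )
    ss = _seed_sequence(master_seed)
    n_established = 0
    survival: List[int] = []
    max_prev: List[float] = []
    for child in ss.spawn(n_trials):
        traj = run_trajectory(params, rng=np.random.default_rng(child))
        if _is_established(traj, params):
            n_established += 1
        elif traj.terminal is TerminalStatus.EXTINCT:
            survival.append(traj.n_generations)
        max_prev.append(max(s.carrier_fraction for s in traj.stats))
    ci = binomtest(n_established, n_trials).proportion_ci(
        confidence_level=0.95, method="wilson"
    )
    return EstablishmentResult(
        n_trials=n_trials,
        n_established=n_established,
        p_hat=n_established / n_trials,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        mean_survival_generations=float(np.mean(survival)) if survival else float("nan"),
        mean_max_prevalence=float(np.mean(max_prev)),
        master_seed=master_seed if isinstance(master_seed, (int, type(None))) else None,
        params=params,
    )


def estimate_equilibrium(
    params: SimulationParams,
    n_runs: int,
    averaging_window: float = 0.2,
    master_seed: SeedLike = None,
) -> float:
    """Equilibrium carrier prevalence, averaged over late generations and runs.

    Each run goes to the generation cap (or extinction, whose zero tail is
    included rather than censored — local die-outs genuinely depress the
    population-average prevalence). The estimate is the carrier fraction
    averaged over the final ``averaging_window`` portion of each padded run
    and across runs.
    """
    if params.init_het_fraction is None or params.init_het_fraction <= 0.0:
        raise InvalidParameterError(
            "estimate_equilibrium requires init_het_fraction > 0"
        )
    if not 0.0 < averaging_window <= 1.0:
        raise InvalidParameterError("averaging_window must lie in (0, 1]")
    if n_runs < 1:
        raise InvalidParameterError("n_runs must be at least 1")
    ss = _seed_sequence(master_seed)
    horizon = params.max_generations
    k = max(1, int(round(averaging_window * (horizon + 1))))
    tails = []
    for child in ss.spawn(n_runs):
        traj = run_trajectory(params, rng=np.random.default_rng(child))
        series = traj.carrier_series(pad_to=horizon)
        tails.append(series[-k:].mean())
    return float(np.mean(tails))


def sweep(
    params_base: SimulationParams,
    n_n_values: Sequence[float],
    s_values: Sequence[float],
    quantity: str = "equilibrium",
    runs_per_cell: int = 4,
    master_seed: SeedLike = None,
    averaging_window: float = 0.2,
) -> SweepResult:
    """Fill an (N_n, s_het) matrix of equilibrium or establishment estimates.

    Each cell gets its own deterministic seed derived from ``master_seed``;
    for ``quantity="establishment"`` ``runs_per_cell`` is the trial count per
    cell. Per-cell failures are logged and recorded as NaN without aborting
    the sweep.
    """
    if quantity not in ("equilibrium", "establishment"):
        raise InvalidParameterError(
            "quantity must be 'equilibrium' or 'establishment', got %r" % (quantity,)
        )
    nn = np.asarray(list(n_n_values), dtype=float)
    ss_ = np.asarray(list(s_values), dtype=float)
    if nn.size == 0 or ss_.size == 0:
        raise InvalidParameterError("sweep axes must be non-empty")
    seeds = (
        _seed_sequence(master_seed)
        .generate_state(nn.size * ss_.size, dtype=np.uint32)
        .astype(np.int64)
        % (2**31)
    ).reshape(nn.size, ss_.size)
    matrix = np.full((nn.size, ss_.size), np.nan)
    total = nn.size * ss_.size
    t0 = time.perf_counter()
    done = 0
    for i, nn_val in enumerate(nn):
        for j, s_val in enumerate(ss_):
            cell_params = replace(
                params_base,
                n_n=float(nn_val),
                sigma=None,
                panmictic=False,
                s_het=float(s_val),
            )
            cell_seed = int(seeds[i, j])
            try:
                if quantity == "equilibrium":
                    value = estimate_equilibrium(
                        cell_params, runs_per_cell, averaging_window, cell_seed
                    )
                else:
                    value = estimate_establishment(
                        cell_params, runs_per_cell, cell_seed
                    ).p_hat
                matrix[i, j] = value
            except Exception:
                logger.exception(
                    "sweep cell (n_n=%g, s=%g) failed; recording NaN", nn_val, s_val
                )
            done += 1
            elapsed = time.perf_counter() - t0
            eta = elapsed / done * (total - done)
            logger.info(
                "sweep cell %d/%d (n_n=%g, s=%g, seed=%d): value=%s [eta %.0fs]",
                done,
                total,
                nn_val,
                s_val,
                cell_seed,
                "%.5g" % matrix[i, j] if np.isfinite(matrix[i, j]) else "nan",
                eta,
            )
    return SweepResult(
        n_n_values=nn,
        s_values=ss_,
        matrix=matrix,
        runs_per_cell=runs_per_cell,
        generations_per_cell=params_base.max_generations,
        quantity=quantity,
        seeds=seeds,
        master_seed=master_seed if isinstance(master_seed, (int, type(None))) else None,
        params_base=params_base,
    )


PRESET_NAMES = ("cftr_panmictic", "cftr_dunbar", "lactase", "neutral_drift")


def scenario_preset(name: str, scale: float = 1.0) -> SimulationParams:
    """Standard scenario parameterizations, optionally shrunk for desk-scale runs.

    ``scale`` multiplies the census size (and any founder count) while
    leaving the community size, selection coefficients and generation caps
    untouched; the parameters actually used are carried on the returned
    object. Equilibrium levels depend mainly on ``N_n`` and ``s``, so
    shrinking ``N`` is legitimate for equilibrium questions, while timing in
    founder-seeded scenarios shifts with the founding prevalence.
    """
    if scale <= 0:
        raise InvalidParameterError("scale must be positive, got %r" % (scale,))

    def scaled(n0: float) -> int:
        return max(4, int(round(n0 * scale)))

    if name == "cftr_panmictic":
        # homozygous-lethal variant held at 4% carriers by a 2.132% het advantage
        return SimulationParams(
            N=scaled(9e6),
            panmictic=True,
            s_het=0.02132,
            s_hom=-1.0,
            init_het_fraction=0.04,
            max_generations=5000,
        )
    if name == "cftr_dunbar":
        # same 4% equilibrium but communities capped at Dunbar's number
        return SimulationParams(
            N=scaled(1e8),
            n_n=150.0,
            s_het=0.0295,
            s_hom=-1.0,
            init_het_fraction=0.04,
            max_generations=3000,
        )
    if name == "lactase":
        # purely beneficial allele spreading from a rare founding base; the
        # horizon covers the full arc of the spread (carrier saturation and
        # the transient heterozygote peak) at this founding density
        return SimulationParams(
            N=scaled(5e6),
            n_n=150.0,
            s_het=0.1,
            s_hom=0.1,
            init_copies=max(1, int(round(100 * scale))),
            mu=0.0,
            max_generations=600,
        )
    if name == "neutral_drift":
        return SimulationParams(
            N=scaled(1e4),
            panmictic=True,
            s_het=0.0,
            s_hom=0.0,
            init_het_fraction=0.1,
            mu=0.0,
            max_generations=1000,
        )
    raise InvalidParameterError(
        "unknown preset %r; available: %s" % (name, ", ".join(PRESET_NAMES))
    )
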