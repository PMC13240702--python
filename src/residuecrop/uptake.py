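"""Linear mass-balance model of pesticide fate in a wheat-environment system.

The system has eight physical compartments — four *source* compartments
that receive the spray directly (air, soil, leaf surface, grain surface)
and four *receiving* crop compartments (leaf, grain, stem, root) — plus
an explicit ninth *degraded* (sink) state that absorbs degradation and
permanent-loss fluxes so that total mass is conserved and assertable.

All inter-compartment processes are first order, so the mass vector m
(kg per kg applied) obeys a linear ODE system

    dm/dt = K m,        m(t) = expm(K t) m(0)

where K is a 9x9 rate matrix with non-negative off-diagonal entries and
zero column sums (every unit of mass leaving a compartment arrives
somewhere, possibly the sink).  Solving by matrix exponential is exact
for the linear system; an adaptive ODE integration of the same system is
used as an independent cross-check in the test-suite, never as the
implementation.

From the simulated trajectories the module derives the quantities used
in residue and exposure assessment: the harvest fraction hF (mass in a
harvested component at harvest per mass applied), the human intake
fraction iF = hF x processing factor, the root-to-shoot translocation
factor TF = (C_stem + C_leaf)/C_root, characteristic residence times
from the terminal log-linear slope, per-source contribution
decompositions (exact by linearity), and grain-mass fractions under
either an applied-mass or a whole-crop denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.linalg import expm

from .dissipation import ResidueSeries
from .errors import NumericalError, TooFewPointsError, ValidationError

__all__ = [
    "Compartment",
    "SOURCE_COMPARTMENTS",
    "CROP_COMPARTMENTS",
    "SINK",
    "ModelParameterization",
    "RateMatrix",
    "SimulationResult",
    "HarvestMetrics",
    "build_rate_matrix",
    "default_time_grid",
    "simulate",
    "source_contributions",
    "harvest_fraction",
    "intake_fraction",
    "translocation_factor",
    "residence_time",
    "grain_fraction",
    "to_concentration",
    "model_field_agreement",
    "harvest_metrics",
]


class Compartment(str, Enum):
    """The eight physical compartments of the wheat-environment system."""

    AIR = "air"
    SOIL = "soil"
    LEAF_SURFACE = "leaf_surface"
    GRAIN_SURFACE = "grain_surface"
    LEAF = "leaf"
    GRAIN = "grain"
    STEM = "stem"
    ROOT = "root"


SOURCE_COMPARTMENTS = (
    Compartment.AIR,
    Compartment.SOIL,
    Compartment.LEAF_SURFACE,
    Compartment.GRAIN_SURFACE,
)
CROP_COMPARTMENTS = (
    Compartment.LEAF,
    Compartment.GRAIN,
    Compartment.STEM,
    Compartment.ROOT,
)

#: Label of the explicit degraded/lost state (index 8 of the state vector).
SINK = "degraded"

_ORDER: list[Compartment] = list(Compartment)
_INDEX: dict[Compartment, int] = {c: i for i, c in enumerate(_ORDER)}
_N_STATES = len(_ORDER) + 1  # 8 compartments + sink
_SINK_IDX = _N_STATES - 1


def _as_compartment(c) -> Compartment:
    return c if isinstance(c, Compartment) else Compartment(str(c))


@dataclass
class ModelParameterization:
    """Named first-order process rates plus application and crop data.

    Parameters
    ----------
    degradation_rate
        Per-compartment loss to the degraded sink, day^-1.
    transfer_rate
        Map (from, to) -> rate (day^-1) for allowed inter-compartment
        edges.  No self-edges.
    dilution_rate
        Growth-dilution pseudo-loss on crop compartments, day^-1; routed
        to the sink (it removes *concentration-relevant* mass).
    biomass
        Crop-compartment biomass, kg m^-2, used for mass->concentration
        conversion.
    applied_dose_g_per_ha
        Application dose in g active ingredient per hectare.
    application_split
        Fraction of the dose initially deposited on each source
        compartment; must sum to 1.
    harvest_day
        Day of harvest (terminal residue sampling).
    """

    degradation_rate: dict[Compartment, float]
    transfer_rate: dict[tuple[Compartment, Compartment], float]
    dilution_rate: dict[Compartment, float] = field(default_factory=dict)
    biomass: dict[Compartment, float] = field(default_factory=dict)
    applied_dose_g_per_ha: float = 675.0
    application_split: dict[Compartment, float] = field(default_factory=dict)
    harvest_day: float = 63.0
    name: str = "unnamed"
    log_kow: float | None = None

    def __post_init__(self):
        self.degradation_rate = {
            _as_compartment(c): float(r) for c, r in self.degradation_rate.items()
        }
        self.transfer_rate = {
            (_as_compartment(a), _as_compartment(b)): float(r)
            for (a, b), r in self.transfer_rate.items()
        }
        self.dilution_rate = {
            _as_compartment(c): float(r) for c, r in self.dilution_rate.items()
        }
        self.biomass = {_as_compartment(c): float(v) for c, v in self.biomass.items()}
        self.application_split = {
            _as_compartment(c): float(v) for c, v in self.application_split.items()
        }

    def violations(self) -> list[str]:
        """Every violated invariant, as human-readable strings."""
        bad = []
        for c, r in self.degradation_rate.items():
            if r < 0:
                bad.append(f"degradation rate of {c.value} is negative ({r})")
        for (a, b), r in self.transfer_rate.items():
            if a == b:
                bad.append(f"self-transfer on {a.value}")
            if r < 0:
                bad.append(f"transfer rate {a.value}->{b.value} is negative ({r})")
        for c, r in self.dilution_rate.items():
            if r < 0:
                bad.append(f"dilution rate of {c.value} is negative ({r})")
            if c not in CROP_COMPARTMENTS:
                bad.append(f"dilution on non-crop compartment {c.value}")
        for c, v in self.biomass.items():
            if not v > 0:
                bad.append(f"biomass of {c.value} must be > 0 ({v})")
        if not self.applied_dose_g_per_ha > 0:
            bad.append(f"applied dose must be > 0 ({self.applied_dose_g_per_ha})")
        if self.application_split:
            for c, f in self.application_split.items():
                if c not in SOURCE_COMPARTMENTS:
                    bad.append(f"application split onto non-source {c.value}")
                if f < 0:
                    bad.append(f"application split fraction of {c.value} negative")
            total = sum(self.application_split.values())
            if abs(total - 1.0) > 1e-12:
                bad.append(f"application split sums to {total!r}, not 1")
        if not self.harvest_day > 0:
            bad.append(f"harvest day must be > 0 ({self.harvest_day})")
        return bad

    def validate(self) -> "ModelParameterization":
        bad = self.violations()
        if bad:
            raise ValidationError("invalid model parameterization", bad)
        return self


@dataclass(frozen=True)
class RateMatrix:
    """The assembled 9x9 system matrix K (8 compartments + degraded sink).

    Off-diagonal entries are >= 0; each diagonal entry equals minus the
    sum of that column's off-diagonals, so column sums vanish and total
    mass (including the sink) is conserved exactly.
    """

    K: np.ndarray
    labels: tuple[str, ...] = tuple(c.value for c in _ORDER) + (SINK,)

    def __post_init__(self):
        K = np.asarray(self.K, dtype=float)
        if K.shape != (_N_STATES, _N_STATES):
            raise ValidationError(f"K must be {_N_STATES}x{_N_STATES}, got {K.shape}")
        off = K.copy()
        np.fill_diagonal(off, 0.0)
        problems = []
        if np.any(off < 0):
            problems.append("negative off-diagonal rate(s)")
        colsums = K.sum(axis=0)
        if np.any(np.abs(colsums) > 1e-10):
            problems.append(f"column sums not zero (max |sum| {np.abs(colsums).max():g})")
        if problems:
            raise ValidationError("invalid rate matrix", problems)
        object.__setattr__(self, "K", K)

    def index(self, compartment) -> int:
        if compartment == SINK:
            return _SINK_IDX
        return _INDEX[_as_compartment(compartment)]


def build_rate_matrix(params: ModelParameterization) -> RateMatrix:
    """Assemble K from named process rates so that dm/dt = K m.

    Degradation, growth dilution and other irreversible losses route to
    the explicit sink state; transfers move mass between compartments.
    """
    params.validate()
    K = np.zeros((_N_STATES, _N_STATES))
    for c, r in params.degradation_rate.items():
        j = _INDEX[c]
        K[_SINK_IDX, j] += r
    for c, r in params.dilution_rate.items():
        j = _INDEX[c]
        K[_SINK_IDX, j] += r
    for (a, b), r in params.transfer_rate.items():
        K[_INDEX[b], _INDEX[a]] += r
    # diagonals balance the columns exactly
    for j in range(_N_STATES):
        K[j, j] = 0.0
        K[j, j] = -K[:, j].sum()
    return RateMatrix(K=K)


@dataclass
class SimulationResult:
    """Mass trajectories (kg per kg applied) on a time grid.

    ``mass`` has shape (9, n_times): the eight compartments in enum
    order followed by the degraded sink.  ``source_decomposition`` maps
    a source compartment to the trajectory attributable to mass applied
    there; by linearity the decomposition sums to ``mass``.
    """

    time_grid: np.ndarray
    mass: np.ndarray
    labels: tuple[str, ...] = tuple(c.value for c in _ORDER) + (SINK,)
    source_decomposition: dict[Compartment, np.ndarray] | None = None

    def index(self, compartment) -> int:
        if compartment == SINK:
            return _SINK_IDX
        return _INDEX[_as_compartment(compartment)]

    def trajectory(self, compartment) -> np.ndarray:
        """Mass trajectory of one compartment (or the sink)."""
        return self.mass[self.index(compartment)]

    def at(self, t: float) -> np.ndarray:
        """State vector at a grid time t (must be on the grid)."""
        i = _grid_index(self.time_grid, t)
        return self.mass[:, i]


def default_time_grid(t_max: float = 300.0, n: int = 400) -> np.ndarray:
    """Geometric grid from 0.01 to t_max days, with t=0 prepended.

    Geometric spacing resolves both the sub-day deposition/penetration
    transient and the multi-hundred-day tail with a modest grid.
    """
    return np.concatenate([[0.0], np.geomspace(0.01, t_max, n - 1)])


def _initial_vector(initial) -> np.ndarray:
    m0 = np.zeros(_N_STATES)
    if isinstance(initial, Mapping):
        for c, f in initial.items():
            m0[_INDEX[_as_compartment(c)]] = float(f)
    else:
        arr = np.asarray(initial, dtype=float)
        if arr.size == _N_STATES:
            m0[:] = arr
        elif arr.size == _N_STATES - 1:
            m0[:-1] = arr
        else:
            raise ValidationError(f"initial vector has wrong length {arr.size}")
    if np.any(m0 < 0):
        raise ValidationError("initial masses must be >= 0")
    return m0


def simulate(K: RateMatrix, initial, time_grid: Sequence[float]) -> SimulationResult:
    """Propagate the mass balance: m(t) = expm(K t) m(0) at each grid point.

    ``initial`` is an application split over source compartments (a
    mapping compartment -> fraction) or a full state vector.  Raises
    :class:`NumericalError` if the evaluation loses more than 1e-6 of
    the applied mass.
    """
    grid = np.asarray(time_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise ValidationError("time grid must be a 1-D sequence")
    if grid[0] != 0.0 or np.any(np.diff(grid) <= 0):
        raise ValidationError("time grid must start at 0 and increase strictly")
    m0 = _initial_vector(initial)
    total0 = m0.sum()

    mass = np.empty((_N_STATES, grid.size))
    mass[:, 0] = m0
    m = m0
    for i in range(1, grid.size):
        # step-wise propagation keeps each expm argument small
        m = expm(K.K * (grid[i] - grid[i - 1])) @ m
        mass[:, i] = m

    totals = mass.sum(axis=0)
    if np.any(np.abs(totals - total0) > 1e-6 * max(total0, 1.0)):
        raise NumericalError(
            f"mass conservation violated (max drift {np.abs(totals - total0).max():g})"
        )
    # clamp roundoff-level negatives; anything larger is a real failure
    if mass.min() < -1e-9:
        raise NumericalError(f"negative mass encountered ({mass.min():g})")
    np.clip(mass, 0.0, None, out=mass)
    return SimulationResult(time_grid=grid, mass=mass)


def source_contributions(
    K: RateMatrix,
    application_split: Mapping,
    time_grid: Sequence[float],
) -> SimulationResult:
    """Full simulation plus exact per-source decomposition.

    Each source compartment s contributes ``split(s) * expm(K t) e_s``;
    by linearity the contributions sum to the full solution.
    """
    split = {_as_compartment(c): float(f) for c, f in application_split.items()}
    decomposition: dict[Compartment, np.ndarray] = {}
    total = None
    grid = np.asarray(time_grid, dtype=float)
    for source, fraction in split.items():
        part = simulate(K, {source: 1.0}, grid).mass * fraction
        decomposition[source] = part
        total = part if total is None else total + part
    if total is None:
        raise ValidationError("application split is empty")
    return SimulationResult(
        time_grid=grid, mass=total, source_decomposition=decomposition
    )


def _grid_index(grid: np.ndarray, t: float) -> int:
    i = int(np.argmin(np.abs(grid - t)))
    if not np.isclose(grid[i], t, rtol=0, atol=1e-9):
        raise ValidationError(f"time {t} is not on the simulation grid")
    return i


def _mass_at(sim: SimulationResult, compartment, t: float) -> float:
    """Mass at an arbitrary time within the grid span, log-linear in mass."""
    grid = sim.time_grid
    if t < grid[0] or t > grid[-1]:
        raise ValidationError(
            f"time {t} outside simulated span [{grid[0]}, {grid[-1]}]"
        )
    traj = sim.trajectory(compartment)
    hi = int(np.searchsorted(grid, t))
    if hi < grid.size and grid[hi] == t:
        return float(traj[hi])
    lo = hi - 1
    m0, m1 = traj[lo], traj[hi]
    w = (t - grid[lo]) / (grid[hi] - grid[lo])
    if m0 > 0 and m1 > 0:
        return float(np.exp(np.log(m0) * (1 - w) + np.log(m1) * w))
    return float(m0 * (1 - w) + m1 * w)


def harvest_fraction(sim: SimulationResult, compartment, t_harvest: float) -> float:
    """hF: mass in a compartment at harvest, per kg applied.

    Interpolates log-linearly in mass between grid points, consistent
    with locally exponential dynamics.
    """
    return _mass_at(sim, compartment, t_harvest)


def intake_fraction(hf: float, processing_factor: float = 0.33) -> float:
    """iF = hF x processing factor (default 0.33, wheat grain to bread)."""
    if not 0.0 <= hf <= 1.0:
        raise ValidationError(f"harvest fraction must be in [0, 1], got {hf}")
    if not 0.0 < processing_factor <= 1.0:
        raise ValidationError(
            f"processing factor must be in (0, 1], got {processing_factor}"
        )
    return hf * processing_factor


def translocation_factor(
    sim: SimulationResult, params: ModelParameterization, t: float
) -> float:
    """TF(t) = (C_stem + C_leaf) / C_root, concentrations as mass/biomass.

    TF > 1 indicates preferential upward translocation from root to
    shoot.  Undefined (raises) when the root concentration is zero.
    """
    for c in (Compartment.LEAF, Compartment.STEM, Compartment.ROOT):
        if c not in params.biomass:
            raise ValidationError(f"biomass missing for {c.value}")
    c_leaf = _mass_at(sim, Compartment.LEAF, t) / params.biomass[Compartment.LEAF]
    c_stem = _mass_at(sim, Compartment.STEM, t) / params.biomass[Compartment.STEM]
    c_root = _mass_at(sim, Compartment.ROOT, t) / params.biomass[Compartment.ROOT]
    if c_root <= 0.0:
        raise ValidationError("translocation factor undefined: root concentration is 0")
    return (c_stem + c_leaf) / c_root


def tf_series(
    sim: SimulationResult, params: ModelParameterization, times: Iterable[float]
) -> np.ndarray:
    """TF evaluated on a sequence of times."""
    return np.array([translocation_factor(sim, params, t) for t in times])


def residence_time(
    sim: SimulationResult, compartment, window_fraction: float = 0.3
) -> float:
    """Characteristic residence time from the terminal log-linear slope.

    Fits a line to ln m(t) over the final ``window_fraction`` of the
    grid and returns tau = -1/slope — i.e. the e-folding time of the
    slowest decaying mode that dominates the tail.  Raises if the
    trajectory is not decreasing over that window.
    """
    if not 0.0 < window_fraction <= 1.0:
        raise ValidationError("window fraction must be in (0, 1]")
    grid = sim.time_grid
    traj = sim.trajectory(compartment)
    t_start = grid[-1] - window_fraction * (grid[-1] - grid[0])
    sel = grid >= t_start
    t_win, m_win = grid[sel], traj[sel]
    if t_win.size < 3:
        raise TooFewPointsError("terminal window holds fewer than 3 grid points")
    if np.any(m_win <= 0):
        raise ValidationError("terminal window contains zero mass; no decay slope")
    if np.any(np.diff(m_win) >= 0):
        raise ValidationError("terminal trajectory is not strictly decreasing")
    slope = np.polyfit(t_win, np.log(m_win), 1)[0]
    if slope >= 0:
        raise ValidationError("terminal slope is non-negative; residence time undefined")
    return float(-1.0 / slope)


def grain_fraction(
    sim: SimulationResult, t: float, denominator: str = "applied_mass"
) -> float:
    """Grain mass as a fraction of applied mass or of total crop residue.

    ``total_crop_residue`` sums the four crop interiors plus both
    surface compartments (residue physically on/in the standing crop).
    """
    i = _grid_index(sim.time_grid, t)
    grain = float(sim.mass[sim.index(Compartment.GRAIN), i])
    if denominator == "applied_mass":
        return grain  # applied mass is normalized to 1
    if denominator == "total_crop_residue":
        crop = CROP_COMPARTMENTS + (Compartment.LEAF_SURFACE, Compartment.GRAIN_SURFACE)
        total = float(sum(sim.mass[sim.index(c), i] for c in crop))
        if total <= 0.0:
            raise ValidationError("total crop residue is zero; fraction undefined")
        return grain / total
    raise ValidationError(f"unknown denominator {denominator!r}")


def to_concentration(
    mass_per_applied: float, applied_dose_g_per_ha: float, biomass_kg_per_m2: float
) -> float:
    """Convert normalized mass (kg per kg applied) to mg kg^-1 fresh weight.

    dose [g ha^-1] / 1e4 -> g m^-2; x 1000 -> mg m^-2; / biomass
    [kg m^-2] -> mg kg^-1.
    """
    if mass_per_applied < 0:
        raise ValidationError("mass must be >= 0")
    if not applied_dose_g_per_ha > 0 or not biomass_kg_per_m2 > 0:
        raise ValidationError("dose and biomass must be > 0")
    dose_mg_per_m2 = applied_dose_g_per_ha / 1e4 * 1000.0
    return mass_per_applied * dose_mg_per_m2 / biomass_kg_per_m2


def model_field_agreement(
    model_times: Sequence[float],
    model_concentrations: Sequence[float],
    measured: ResidueSeries,
    match_tolerance_days: float = 0.1,
) -> float:
    """Coefficient of determination of measured against modeled residues.

    Measured observations are matched to the nearest modeled time within
    ``match_tolerance_days``; at least 3 pairs are required.  R^2 is
    1 - SS_res/SS_tot with residuals measured - modeled, so a model that
    explains less variance than the measured mean yields R^2 <= 0.
    """
    mt = np.asarray(model_times, dtype=float)
    mc = np.asarray(model_concentrations, dtype=float)
    pairs_obs, pairs_mod = [], []
    for obs in measured.observations:
        i = int(np.argmin(np.abs(mt - obs.time_days)))
        if abs(mt[i] - obs.time_days) <= match_tolerance_days:
            pairs_obs.append(obs.concentration)
            pairs_mod.append(mc[i])
    if len(pairs_obs) < 3:
        raise TooFewPointsError(
            f"only {len(pairs_obs)} measured points matched the model grid"
        )
    observed = np.array(pairs_obs)
    predicted = np.array(pairs_mod)
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else float("-inf")
    return 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class HarvestMetrics:
    """Summary metrics of one simulation run."""

    hf: float
    intake_fraction: float
    processing_factor: float
    peak_mass: dict[str, tuple[float, float]]
    residence_time_days: dict[str, float]

    def __post_init__(self):
        if self.peak_mass.get(Compartment.GRAIN.value) is not None:
            peak, _ = self.peak_mass[Compartment.GRAIN.value]
            if peak + 1e-15 < self.hf:
                raise ValidationError("grain peak mass below mass at harvest")


def harvest_metrics(
    sim: SimulationResult,
    params: ModelParameterization,
    processing_factor: float = 0.33,
) -> HarvestMetrics:
    """hF/iF at the configured harvest day plus per-compartment peaks
    and residence times (where a terminal decay slope exists)."""
    hf = harvest_fraction(sim, Compartment.GRAIN, params.harvest_day)
    peaks: dict[str, tuple[float, float]] = {}
    taus: dict[str, float] = {}
    for c in Compartment:
        traj = sim.trajectory(c)
        i = int(np.argmax(traj))
        peaks[c.value] = (float(traj[i]), float(sim.time_grid[i]))
        try:
            taus[c.value] = residence_time(sim, c)
        except (ValidationError, TooFewPointsError):
            pass
    return HarvestMetrics(
        hf=hf,
        intake_fraction=intake_fraction(hf, processing_factor),
        processing_factor=processing_factor,
        peak_mass=peaks,
        residence_time_days=taus,
    )
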