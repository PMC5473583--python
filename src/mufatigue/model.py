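"""Motor-unit population model of isometric muscle fatigue.

The simulated muscle is a pool of ``n`` motor units (MUs) whose twitch
forces and recruitment thresholds are exponentially distributed, so that
the pool contains many weak, low-threshold, fatigue-resistant units and
few strong, high-threshold, highly fatigable ones.  All units receive a
common excitatory drive ``E``; a unit fires once ``E`` reaches its
recruitment threshold, its rate grows linearly with excess drive, and
saturates at a unit-specific maximum arranged in an "onion-skin"
pattern (low-threshold units saturate at the highest rates).  Firing
rate, normalized by twitch contraction time, maps through a common
linear/sigmoid force-frequency curve to the fraction of the unit's
force capacity actually produced.

Fatigue acts through two channels:

* **peripheral** -- each unit loses force capacity at a rate equal to
  its nominal fatigability scaled by its instantaneous normalized
  force, and its twitch contraction time slows in proportion to the
  percent capacity lost;
* **central** -- an exponentially rising intrinsic adaptation current
  is subtracted from each unit's firing rate, deeper for
  high-threshold units and for units driven well above their minimum
  rate.

A closed-loop controller raises excitation on a 0.01-unit grid every
0.1-s sample so that total muscle force meets a target-force protocol;
the endurance time is the first instant at which the whole pool, driven
at maximal excitation, can no longer reach the target.

The module is laid out in the order the method runs: parameters and
configuration, pool construction, rate/force transforms, peripheral
fatigue, central adaptation, the closed-loop engine, and trace
serialization.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("mufatigue")

__all__ = [
    "PoolParameters",
    "MotorUnitStatic",
    "MotorUnitPool",
    "Protocol",
    "SimulationTrace",
    "ConfigError",
    "build_pool",
    "firing_rate_unadapted",
    "normalized_rate",
    "force_frequency",
    "unit_force",
    "fatigability_from_fatigue_index",
    "instantaneous_fatigability",
    "step_capacity",
    "update_contraction_time",
    "adaptation_ceiling_q",
    "adaptation_current",
    "effective_rate",
    "solve_excitation",
    "total_capacity",
    "run_protocol",
    "endurance_curve",
    "load_config",
    "write_trace",
    "read_summary",
]

# Duration of the standard intermittent-stimulation fatigue test from
# which fatigue indices are defined (2 min), and the fold-increase in
# fatigue rate when going from that test's 33% duty cycle to a
# sustained contraction.
FATIGUE_TEST_DURATION_S = 120.0
SUSTAINED_DUTY_ADJUST = 3.0

SUMMARY_SCHEMA_VERSION = 1
CSV_FLOAT_FORMAT = "%.6g"


class ConfigError(ValueError):
    """Raised when a parameter configuration is invalid."""


# ---------------------------------------------------------------------------
# Parameters and configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PoolParameters:
    """Constants defining the motor-unit pool and its fatigue dynamics.

    Attributes
    ----------
    n : int
        Number of motor units in the pool.
    RP : float
        Fold-range of twitch forces across the pool: the strongest unit
        is ``RP`` times stronger than the weakest.
    RR : float
        Fold-range of recruitment threshold excitations.
    minR : float
        Firing rate at recruitment threshold, impulses/s.
    maxR_first, maxR_last : float
        Maximum firing rates of the first (weakest) and last
        (strongest) unit, impulses/s; intermediate units interpolate
        linearly in recruitment threshold ("onion-skin" arrangement).
    g : float
        Firing-rate gain, impulses/s per excitation unit.
    CT_max : float
        Twitch contraction time of the weakest (slowest) unit, seconds.
    CT_range : float
        Fold-range of contraction times (weakest/strongest).
    FAT_first : float
        Nominal fatigability of the weakest unit, percent of rested
        capacity lost per second at normalized force 1.
    RFR : float
        Fold-range of nominal fatigability across the pool.
    ct_slope : float
        Contraction-time slowing coefficient: percent CT increase per
        percent force-capacity loss.
    tau : float
        Time constant of firing-rate adaptation, seconds.
    phi : float
        Dimensionless scaling of the adaptation ceiling.
    d : float
        Allowance, impulses/s, by which an adapted firing rate may fall
        below the recruitment-threshold minimum rate.
    dt : float
        Sampling interval of the simulation, seconds.
    dE : float
        Step of the excitation grid searched by the controller.
    adaptation_enabled : bool
        If False, firing-rate adaptation is switched off entirely.
    """

    n: int = 120
    RP: float = 100.0
    RR: float = 50.0
    minR: float = 8.0
    maxR_first: float = 35.0
    maxR_last: float = 25.0
    g: float = 1.0
    CT_max: float = 0.090
    CT_range: float = 3.0
    FAT_first: float = 0.0125
    RFR: float = 180.0
    ct_slope: float = 0.379
    tau: float = 22.0
    phi: float = 0.67
    d: float = 2.0
    dt: float = 0.1
    dE: float = 0.01
    adaptation_enabled: bool = True

    def __post_init__(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 2):
            raise ConfigError(f"n must be an integer >= 2, got {self.n!r}")
        positive = (
            "RP", "RR", "minR", "maxR_first", "maxR_last", "g", "CT_max",
            "CT_range", "FAT_first", "RFR", "tau", "phi", "dt", "dE",
        )
        for name in positive:
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ConfigError(f"{name} must be finite and > 0, got {value!r}")
        for name in ("ct_slope", "d"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value >= 0):
                raise ConfigError(f"{name} must be finite and >= 0, got {value!r}")
        if not (self.maxR_first > self.maxR_last > self.minR):
            raise ConfigError(
                "require maxR_first > maxR_last > minR, got "
                f"{self.maxR_first}, {self.maxR_last}, {self.minR}"
            )
        if self.RR <= 1 or self.RP <= 1:
            raise ConfigError("RP and RR must exceed 1 (threshold/force ranges)")

    @property
    def E_max(self) -> float:
        """Excitation at which the last unit reaches its maximum rate.

        ``E_max = RTE(n) + (maxR(n) - minR)/g``; 67 with defaults.
        """
        return self.RR + (self.maxR_last - self.minR) / self.g

    def replace(self, **changes) -> "PoolParameters":
        return dataclasses.replace(self, **changes)


def load_config(path: str | Path) -> PoolParameters:
    """Read a YAML or JSON parameter file into :class:`PoolParameters`.

    Missing keys fall back to the defaults; unknown keys raise
    :class:`ConfigError` with the offending field named.  An empty file
    yields the full default parameter set.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json" and text.strip():
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping of parameter names, got {type(raw).__name__}")
    known = {f.name for f in dataclasses.fields(PoolParameters)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown parameter(s): {', '.join(sorted(unknown))}")
    try:
        return PoolParameters(**raw)
    except ConfigError as err:
        raise ConfigError(f"{path}: {err}") from err


# ---------------------------------------------------------------------------
# Pool construction
# ---------------------------------------------------------------------------


class MotorUnitStatic(NamedTuple):
    """Rested (pre-fatigue) properties of one motor unit."""

    index: int              # 1-based unit index
    P: float                # rested twitch/tetanic force capacity, force units
    CT_rested: float        # rested twitch contraction time, s
    RTE: float              # recruitment threshold excitation
    maxR: float             # maximum firing rate, imp/s
    FAT_nominal: float      # nominal fatigability, % of rested capacity per s


@dataclass(frozen=True)
class MotorUnitPool(Sequence):
    """The rested pool: per-unit property arrays plus derived scalars.

    Behaves as a sequence of :class:`MotorUnitStatic` (0-based Python
    indexing; ``unit(i)`` accepts the conventional 1-based index used
    in reports).
    """

    params: PoolParameters
    P: np.ndarray
    CT_rested: np.ndarray
    RTE: np.ndarray
    maxR: np.ndarray
    FAT_nominal: np.ndarray

    def __len__(self) -> int:
        return self.params.n

    def __getitem__(self, j):
        if isinstance(j, slice):
            return [self[k] for k in range(*j.indices(len(self)))]
        return MotorUnitStatic(
            index=int(j % len(self)) + 1 if j >= 0 else len(self) + j + 1,
            P=float(self.P[j]),
            CT_rested=float(self.CT_rested[j]),
            RTE=float(self.RTE[j]),
            maxR=float(self.maxR[j]),
            FAT_nominal=float(self.FAT_nominal[j]),
        )

    def __iter__(self) -> Iterator[MotorUnitStatic]:
        for j in range(len(self)):
            yield self[j]

    def unit(self, i: int) -> MotorUnitStatic:
        """Return unit ``i`` using 1-based indexing (MU1 ... MUn)."""
        if not 1 <= i <= len(self):
            raise IndexError(f"unit index must be in 1..{len(self)}, got {i}")
        return self[i - 1]

    @property
    def E_max(self) -> float:
        return self.params.E_max

    def rested_max_force(self) -> float:
        """Total rested force at maximal excitation (the model's MVC)."""
        R = np.minimum(self.params.g * (self.E_max - self.RTE) + self.params.minR, self.maxR)
        NF = force_frequency(normalized_rate(R, self.CT_rested))
        return float(np.sum(NF * self.P))


def build_pool(params: PoolParameters | None = None) -> MotorUnitPool:
    """Construct the rested pool from the parameter set.

    Twitch forces and recruitment thresholds follow exponential
    distributions over the unit index, P(i) = exp(ln(RP)(i-1)/(n-1))
    and RTE(i) = exp(ln(RR)(i-1)/(n-1)), giving many weak,
    low-threshold units and few strong, high-threshold ones.
    Contraction times fall as an inverse power of twitch force,
    CT(i) = CT_max * (1/P(i))^(1/c) with c = ln(RP)/ln(CT_range), so
    the weakest unit is the slowest (CT_max) and the strongest the
    fastest (CT_max/CT_range).  Maximum firing rates decrease
    uniformly with recruitment threshold, from ``maxR_first`` at
    RTE = 1 to ``maxR_last`` at RTE = RR (linear in threshold, not in
    unit index), and nominal fatigabilities grow exponentially over an
    ``RFR``-fold range.
    """
    p = params if params is not None else PoolParameters()
    i = np.arange(p.n, dtype=float)          # 0-based internally
    frac = i / (p.n - 1)
    P = np.exp(np.log(p.RP) * frac)
    RTE = np.exp(np.log(p.RR) * frac)
    c = np.log(p.RP) / np.log(p.CT_range)
    CT = p.CT_max * (1.0 / P) ** (1.0 / c)
    maxR = p.maxR_first + (p.maxR_last - p.maxR_first) * (RTE - 1.0) / (p.RR - 1.0)
    FAT = p.FAT_first * np.exp(np.log(p.RFR) * frac)
    return MotorUnitPool(params=p, P=P, CT_rested=CT, RTE=RTE, maxR=maxR, FAT_nominal=FAT)


# ---------------------------------------------------------------------------
# Rate and force transforms
# ---------------------------------------------------------------------------


def firing_rate_unadapted(E: float, unit: MotorUnitStatic, params: PoolParameters) -> float | None:
    """Steady firing rate of ``unit`` at excitation ``E``, before adaptation.

    Returns ``None`` when the unit is not recruited (``E < RTE``);
    otherwise ``min(maxR, g*(E - RTE) + minR)``.
    """
    if E < 0:
        raise ValueError(f"excitation must be >= 0, got {E}")
    if E < unit.RTE:
        return None
    return min(unit.maxR, params.g * (E - unit.RTE) + params.minR)


def normalized_rate(R, CT_current):
    """Firing rate normalized by contractile speed: ``NR = R * CT``.

    Dividing rate by 1/CT collapses all units onto a single
    force-frequency curve regardless of twitch speed.
    """
    return R * CT_current


def force_frequency(NR):
    """Normalized force from normalized firing rate.

    Linear at low rates (``0.3*NR`` for ``NR <= 0.4``) and sigmoidal
    above (``1 - exp(-2*NR**3)``); the two branches agree to ~1.5e-4
    at the seam.  Accepts scalars or arrays; negative input is
    rejected.
    """
    NR = np.asarray(NR, dtype=float)
    if np.any(NR < 0):
        raise ValueError("normalized rate must be >= 0")
    NF = np.where(NR <= 0.4, 0.3 * NR, -np.expm1(-2.0 * NR**3))
    return float(NF) if NF.ndim == 0 else NF


def unit_force(NF, capacity):
    """Force produced: normalized force times remaining capacity.

    Total muscle force is the plain sum of the per-unit forces.
    """
    return NF * capacity


# ---------------------------------------------------------------------------
# Peripheral fatigue: capacity loss and contraction-time slowing
# ---------------------------------------------------------------------------


def fatigability_from_fatigue_index(
    FI: float, duty_adjust: float = SUSTAINED_DUTY_ADJUST
) -> float:
    """Convert a 2-minute fatigue index into a fatigability in %/s.

    ``FI`` is the fraction of initial force remaining after the
    standard 2-minute intermittent-stimulation test; the mean loss rate
    ``(1 - FI)/2 min * 100`` is multiplied by ``duty_adjust`` (default
    3) to translate the test's 33% duty cycle to a sustained
    contraction.
    """
    if not 0.0 <= FI <= 1.0:
        raise ValueError(f"fatigue index must lie in [0, 1], got {FI}")
    if duty_adjust <= 0:
        raise ValueError(f"duty_adjust must be > 0, got {duty_adjust}")
    return (1.0 - FI) / FATIGUE_TEST_DURATION_S * 100.0 * duty_adjust


def instantaneous_fatigability(FAT_nominal, NF):
    """Instantaneous loss rate, %/s: nominal fatigability scaled by the
    normalized force currently produced (an unloaded unit does not
    fatigue)."""
    return FAT_nominal * NF


def step_capacity(PE, P_rested, FAT_inst, dt: float):
    """Advance force capacity one step: ``PE -= dt * FAT_inst% of P``.

    The percent loss is taken relative to the *rested* capacity, so
    capacity declines linearly under constant load and reaches zero
    (exhaustion) in finite time; exhausted units stay at zero.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    return np.maximum(0.0, PE - dt * FAT_inst / 100.0 * P_rested)


def update_contraction_time(CT_rested, PE, P_rested, ct_slope: float):
    """Slowed contraction time after fatigue.

    The percent increase in CT is ``ct_slope`` times the percent force
    loss, capping at ``(1 + ct_slope)`` times the rested CT when a unit
    is exhausted.
    """
    frac_lost = 1.0 - PE / P_rested
    return CT_rested * (1.0 + ct_slope * frac_lost)


# ---------------------------------------------------------------------------
# Central fatigue: firing-rate adaptation
# ---------------------------------------------------------------------------


def adaptation_ceiling_q(unit: MotorUnitStatic, R_unadapted: float, params: PoolParameters) -> float:
    """Asymptotic depth of firing-rate adaptation for one unit, imp/s.

    ``q = phi * (R - minR + d) * (RTE(i) - 1)/(RTE(n) - 1)``: adaptation
    deepens with drive above the minimum rate and with recruitment
    threshold, so the lowest-threshold unit (RTE = 1) never adapts.
    The rate fed in is the unadapted rate capped at maxR.
    """
    depth = (
        params.phi
        * (R_unadapted - params.minR + params.d)
        * (unit.RTE - 1.0)
        / (params.RR - 1.0)
    )
    return max(0.0, depth)


def adaptation_current(q: float, t: float, TR: float, tau: float) -> float:
    """Adaptation current at time ``t`` for a unit recruited at ``TR``:
    ``A = q * (1 - exp(-(t - TR)/tau))``, rising from 0 toward ``q``."""
    if t < TR:
        raise ValueError(f"t={t} precedes recruitment time TR={TR}")
    return q * -math.expm1(-(t - TR) / tau)


def effective_rate(R_unadapted_capped: float, A: float, params: PoolParameters) -> float:
    """Adapted firing rate: the maxR-capped rate minus the adaptation
    current, floored at ``minR - d`` (a unit may fall slightly below
    its recruitment minimum before derecruiting)."""
    return max(R_unadapted_capped - A, params.minR - params.d)


# ---------------------------------------------------------------------------
# Closed-loop engine
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Protocol:
    """A target-force task: what to track and when to stop.

    ``kind`` is one of ``sustained_target`` (hold a constant % MVC
    until the pool can no longer produce it), ``sustained_maximal``
    (drive at maximal excitation for ``max_duration``), ``staircase``
    (hold successively higher plateaus joined by linear ramps), or
    ``run_to_capacity_floor`` (hold a target while attainable, then
    pin excitation at maximum until produced force falls below
    ``capacity_floor_percent`` of MVC).
    """

    kind: str
    target_percent_mvc: float | None = None
    plateaus: tuple[float, ...] | None = None
    plateau_duration: float = 32.0
    ramp_duration: float = 5.0
    capacity_floor_percent: float | None = None
    max_duration: float = 3600.0

    KINDS = ("sustained_target", "sustained_maximal", "staircase", "run_to_capacity_floor")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.max_duration <= 0:
            raise ValueError("max_duration must be > 0")
        if self.kind in ("sustained_target", "run_to_capacity_floor"):
            t = self.target_percent_mvc
            if t is None or not 0 < t <= 100:
                raise ValueError(f"target_percent_mvc must lie in (0, 100], got {t!r}")
        if self.kind == "run_to_capacity_floor":
            f = self.capacity_floor_percent
            if f is None or not 0 < f <= 100:
                raise ValueError(f"capacity_floor_percent must lie in (0, 100], got {f!r}")
        if self.kind == "staircase":
            if not self.plateaus or any(p <= 0 or p > 100 for p in self.plateaus):
                raise ValueError("staircase plateaus must lie in (0, 100]")
            if list(self.plateaus) != sorted(set(self.plateaus)):
                raise ValueError("staircase plateaus must be strictly increasing")
            if self.plateau_duration <= 0 or self.ramp_duration <= 0:
                raise ValueError("plateau and ramp durations must be > 0")

    # -- constructors ------------------------------------------------------
    @classmethod
    def sustained(cls, target_percent_mvc: float, max_duration: float = 3600.0) -> "Protocol":
        return cls("sustained_target", target_percent_mvc=target_percent_mvc,
                   max_duration=max_duration)

    @classmethod
    def maximal(cls, duration: float = 200.0) -> "Protocol":
        return cls("sustained_maximal", target_percent_mvc=100.0, max_duration=duration)

    @classmethod
    def staircase_task(cls, plateaus: Sequence[float], plateau_duration: float = 32.0,
                       ramp_duration: float = 5.0, max_duration: float = 3600.0) -> "Protocol":
        return cls("staircase", plateaus=tuple(float(p) for p in plateaus),
                   plateau_duration=plateau_duration, ramp_duration=ramp_duration,
                   max_duration=max_duration)

    @classmethod
    def to_capacity_floor(cls, target_percent_mvc: float, floor_percent: float,
                          max_duration: float = 3600.0) -> "Protocol":
        return cls("run_to_capacity_floor", target_percent_mvc=target_percent_mvc,
                   capacity_floor_percent=floor_percent, max_duration=max_duration)

    # -- target time course ------------------------------------------------
    def target_fraction(self, t: float) -> float:
        """Target force at time ``t`` as a fraction of MVC."""
        if self.kind in ("sustained_target", "run_to_capacity_floor"):
            return self.target_percent_mvc / 100.0
        if self.kind == "sustained_maximal":
            return 1.0
        # staircase: plateaus joined by linear ramps; hold the last
        # plateau once the programme is exhausted
        assert self.plateaus is not None
        u = t
        for k, level in enumerate(self.plateaus):
            if u < self.plateau_duration or k == len(self.plateaus) - 1:
                return level / 100.0
            u -= self.plateau_duration
            nxt = self.plateaus[k + 1]
            if u < self.ramp_duration:
                return (level + (nxt - level) * u / self.ramp_duration) / 100.0
            u -= self.ramp_duration
        return self.plateaus[-1] / 100.0


def _pool_force(
    E: float,
    pool: MotorUnitPool,
    PE: np.ndarray,
    CT: np.ndarray,
    t: float,
    TR: np.ndarray,
    recruited: np.ndarray,
    params: PoolParameters,
    return_details: bool = False,
):
    """Total force (and optionally per-unit detail) at excitation ``E``.

    Units fire iff ``E >= RTE``.  Already-recruited units carry their
    adaptation state; units not yet recruited are evaluated as if
    recruited at ``t`` (zero adaptation current), which makes this the
    counterfactual evaluator used both by the excitation solver and by
    the force-capacity readout at ``E = E_max``.
    """
    fires = E >= pool.RTE
    R_u = np.minimum(params.g * (E - pool.RTE) + params.minR, pool.maxR)
    if params.adaptation_enabled:
        decay = np.where(recruited, -np.expm1(-(t - TR) / params.tau), 0.0)
        q = params.phi * (R_u - params.minR + params.d) * (pool.RTE - 1.0) / (params.RR - 1.0)
        A = np.maximum(q, 0.0) * decay
        R = np.maximum(R_u - A, params.minR - params.d)
    else:
        R = R_u
    R = np.where(fires, R, 0.0)
    NR = R * CT
    NF = np.where(NR <= 0.4, 0.3 * NR, -np.expm1(-2.0 * NR**3))
    F = NF * PE
    total = float(F.sum())
    if return_details:
        return total, R, NR, NF, F, fires
    return total


def solve_excitation(
    pool: MotorUnitPool,
    PE: np.ndarray,
    CT: np.ndarray,
    t: float,
    TR: np.ndarray,
    recruited: np.ndarray,
    target: float,
    params: PoolParameters,
) -> tuple[float, bool]:
    """Smallest grid excitation producing at least ``target`` force.

    The grid is {0} followed by E = 1, 1+dE, ..., E_max.  Total force
    is non-decreasing in E (the adaptation ceiling grows slower than
    the rate, since phi < 1), so a bisection over the grid finds the
    same excitation the specified bottom-up 0.01-increment search
    would.  Returns ``(E, attained)``; when even ``E_max`` cannot meet
    the target the flag is False and ``E_max`` is returned.
    """
    if target < 0:
        raise ValueError(f"target force must be >= 0, got {target}")
    if target == 0:
        return 0.0, True

    def force_at(E: float) -> float:
        return _pool_force(E, pool, PE, CT, t, TR, recruited, params)

    n_steps = int(round((params.E_max - 1.0) / params.dE))
    if force_at(params.E_max) < target:
        return params.E_max, False
    lo, hi = 0, n_steps           # grid index k -> E = 1 + k*dE
    if force_at(1.0) >= target:
        return 1.0, True
    # invariant: force(1 + lo*dE) < target <= force(1 + hi*dE)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if force_at(1.0 + mid * params.dE) >= target:
            hi = mid
        else:
            lo = mid
    return 1.0 + hi * params.dE, True


def total_capacity(
    pool: MotorUnitPool,
    PE: np.ndarray,
    CT: np.ndarray,
    t: float,
    TR: np.ndarray,
    recruited: np.ndarray,
    params: PoolParameters,
) -> float:
    """Force the pool could produce right now at maximal excitation.

    This is the counterfactual "force capacity" readout: current
    capacities, contraction times and adaptation states, evaluated at
    ``E = E_max`` (units not yet recruited enter with zero adaptation).
    Endurance is reached when this value falls below the target.
    """
    return _pool_force(params.E_max, pool, PE, CT, t, TR, recruited, params)


@dataclass
class SimulationTrace:
    """Sampled time course of a run plus its summary scalars.

    Per-step arrays are indexed ``[step]`` (muscle level) or
    ``[step, unit]`` (unit level, 0-based columns for MU1..MUn).
    ``endurance_time`` is None when the target never became
    unattainable within the run.
    """

    protocol: Protocol
    params: PoolParameters
    mvc: float
    time: np.ndarray
    excitation: np.ndarray
    target_force: np.ndarray
    total_force: np.ndarray
    capacity: np.ndarray
    rate: np.ndarray
    normalized_rate: np.ndarray
    normalized_force: np.ndarray
    force: np.ndarray
    PE: np.ndarray
    CT: np.ndarray
    recruited: np.ndarray
    endurance_time: float | None = None
    initial_excitation_fraction: float = 0.0

    @property
    def final_relative_capacity(self) -> np.ndarray:
        pool = build_pool(self.params)
        return self.PE[-1] / pool.P

    @property
    def exhausted_range(self) -> tuple[int, int] | None:
        """1-based (first, last) indices of fully exhausted units, or None."""
        if self.PE.size == 0:
            return None
        idx = np.flatnonzero(self.PE[-1] <= 0.0)
        if idx.size == 0:
            return None
        return int(idx[0]) + 1, int(idx[-1]) + 1

    def summary(self) -> dict:
        ex = self.exhausted_range
        return {
            "schema_version": SUMMARY_SCHEMA_VERSION,
            "protocol": {
                "kind": self.protocol.kind,
                "target_percent_mvc": self.protocol.target_percent_mvc,
                "plateaus": list(self.protocol.plateaus) if self.protocol.plateaus else None,
                "plateau_duration": self.protocol.plateau_duration,
                "ramp_duration": self.protocol.ramp_duration,
                "capacity_floor_percent": self.protocol.capacity_floor_percent,
                "max_duration": self.protocol.max_duration,
            },
            "mvc": self.mvc,
            "endurance_time": self.endurance_time,
            "initial_excitation_fraction": self.initial_excitation_fraction,
            "duration": float(self.time[-1]) if self.time.size else 0.0,
            "exhausted_unit_range": list(ex) if ex else None,
            "final_relative_capacity": [float(x) for x in self.final_relative_capacity]
            if self.time.size
            else [],
        }

    def muscle_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "excitation": self.excitation,
                "target_force": self.target_force,
                "total_force": self.total_force,
                "capacity": self.capacity,
            }
        )

    def unit_frame(self) -> pd.DataFrame:
        """Tidy per-unit table: one row per time step per unit."""
        n_steps, n = self.rate.shape
        return pd.DataFrame(
            {
                "time_s": np.repeat(self.time, n),
                "unit": np.tile(np.arange(1, n + 1), n_steps),
                "rate": self.rate.ravel(),
                "normalized_rate": self.normalized_rate.ravel(),
                "normalized_force": self.normalized_force.ravel(),
                "force": self.force.ravel(),
                "capacity": self.PE.ravel(),
                "contraction_time_s": self.CT.ravel(),
                "recruited": self.recruited.ravel().astype(int),
            }
        )


def run_protocol(
    protocol: Protocol,
    params: PoolParameters | None = None,
    record_units: bool = True,
) -> SimulationTrace:
    """Run the closed-loop simulation of one task.

    Each ``dt`` sample proceeds causally: (1) capacity loss is applied
    from the normalized forces accepted at the previous sample,
    (2) contraction times are slowed from the new percent loss,
    (3) excitation is solved on the grid for the current target
    (adaptation currents evaluated at the current time).  The first
    sample (t = 0) is fully rested.  ``record_units=False`` keeps only
    muscle-level series, for long parameter sweeps.
    """
    p = params if params is not None else PoolParameters()
    pool = build_pool(p)
    mvc = pool.rested_max_force()
    n = p.n

    PE = pool.P.copy()
    CT = pool.CT_rested.copy()
    recruited = np.zeros(n, dtype=bool)
    TR = np.zeros(n)
    prev_NF = np.zeros(n)

    rows_m: list[tuple] = []
    rows_u: list[tuple] = []
    endurance_time: float | None = None
    initial_fraction = 0.0
    pinned = False  # excitation pinned at E_max (maximal / post-endurance floor runs)

    n_max = int(math.ceil(protocol.max_duration / p.dt))
    for k in range(n_max + 1):
        t = k * p.dt
        if k > 0:
            FAT_inst = pool.FAT_nominal * prev_NF
            PE = step_capacity(PE, pool.P, FAT_inst, p.dt)
            CT = update_contraction_time(pool.CT_rested, PE, pool.P, p.ct_slope)

        target = protocol.target_fraction(t) * mvc
        if protocol.kind == "sustained_maximal" or pinned:
            E, attained = p.E_max, False
        else:
            E, attained = solve_excitation(pool, PE, CT, t, TR, recruited, target, p)
            if not attained:
                E = p.E_max

        newly = (~recruited) & (pool.RTE <= E)
        recruited = recruited | newly
        TR = np.where(newly, t, TR)

        total, R, NR, NF, F, fires = _pool_force(
            E, pool, PE, CT, t, TR, recruited, p, return_details=True
        )
        cap = total_capacity(pool, PE, CT, t, TR, recruited, p)
        if k == 0:
            initial_fraction = E / p.E_max

        rows_m.append((t, E, target, total, cap))
        if record_units:
            rows_u.append((R, NR, NF, F, PE.copy(), CT.copy(), recruited.copy()))
        prev_NF = NF * fires

        if endurance_time is None and cap < target and target > 0:
            endurance_time = t
        if protocol.kind in ("sustained_target", "staircase") and endurance_time is not None:
            break
        if protocol.kind == "run_to_capacity_floor":
            if endurance_time is not None:
                pinned = True
            floor = protocol.capacity_floor_percent / 100.0 * mvc
            if total < floor:
                break

    time, E_arr, tgt, tot, cap_arr = (np.array(x) for x in zip(*rows_m))
    if record_units:
        stack = lambda j: np.array([r[j] for r in rows_u])  # noqa: E731
        R2, NR2, NF2, F2, PE2, CT2, rec2 = (stack(j) for j in range(7))
    else:
        empty = np.empty((0, n))
        R2 = NR2 = NF2 = F2 = empty
        PE2 = np.vstack([PE]) if time.size else empty
        CT2 = np.vstack([CT]) if time.size else empty
        rec2 = np.vstack([recruited]) if time.size else np.empty((0, n), dtype=bool)

    return SimulationTrace(
        protocol=protocol,
        params=p,
        mvc=mvc,
        time=time,
        excitation=E_arr,
        target_force=tgt,
        total_force=tot,
        capacity=cap_arr,
        rate=R2,
        normalized_rate=NR2,
        normalized_force=NF2,
        force=F2,
        PE=PE2,
        CT=CT2,
        recruited=rec2,
        endurance_time=endurance_time,
        initial_excitation_fraction=initial_fraction,
    )


def endurance_curve(
    targets: Sequence[float],
    params: PoolParameters | None = None,
    max_duration: float = 3600.0,
) -> pd.DataFrame:
    """Endurance time for a set of sustained targets (% MVC).

    Returns a DataFrame with columns ``target_percent_mvc`` and
    ``endurance_time_s``; endurance must decrease with target, which is
    asserted.
    """
    rows = []
    for tgt in targets:
        trace = run_protocol(
            Protocol.sustained(tgt, max_duration=max_duration), params, record_units=False
        )
        rows.append((float(tgt), trace.endurance_time))
    frame = pd.DataFrame(rows, columns=["target_percent_mvc", "endurance_time_s"])
    et = frame["endurance_time_s"].to_numpy(dtype=float)
    order = np.argsort(frame["target_percent_mvc"].to_numpy())
    if np.any(np.diff(et[order]) >= 0):
        raise AssertionError("endurance time must strictly decrease with target force")
    return frame


# ---------------------------------------------------------------------------
# Trace serialization
# ---------------------------------------------------------------------------


def write_trace(trace: SimulationTrace, prefix: str | Path) -> dict[str, Path]:
    """Write a run to ``<prefix>_muscle.csv``, ``<prefix>_units.csv``
    and ``<prefix>_summary.json``.

    Floats in the CSVs carry 6 significant digits; the JSON summary is
    exact and versioned, and round-trips through
    :func:`read_summary`.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "muscle": prefix.with_name(prefix.name + "_muscle.csv"),
        "units": prefix.with_name(prefix.name + "_units.csv"),
        "summary": prefix.with_name(prefix.name + "_summary.json"),
    }
    trace.muscle_frame().to_csv(paths["muscle"], index=False, float_format=CSV_FLOAT_FORMAT)
    trace.unit_frame().to_csv(paths["units"], index=False, float_format=CSV_FLOAT_FORMAT)
    with open(paths["summary"], "w") as fh:
        json.dump(trace.summary(), fh, indent=1)
    logger.info("wrote trace to %s_{muscle,units}.csv and %s_summary.json", prefix, prefix)
    return paths


def read_summary(path: str | Path) -> dict:
    """Read back a JSON run summary written by :func:`write_trace`."""
    with open(path) as fh:
        summary = json.load(fh)
    version = summary.get("schema_version")
    if version != SUMMARY_SCHEMA_VERSION:
        raise ValueError(f"unsupported summary schema version {version!r}")
    return summary
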