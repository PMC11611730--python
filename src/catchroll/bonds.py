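"""Single-bond two-state/two-pathway kinetics.

The bond is modelled as a continuous-time Markov chain on the states
``{weak, strong, unbound}`` (``unbound`` absorbing).  Every transition obeys a
Kramers--Bell rate law

    k(F) = k0 * exp(F * x / kBT)

where ``k0`` is the zero-force rate (1/s), ``x`` the distance to the
transition state (nm, signed: positive means tension accelerates the
transition, negative means tension suppresses it) and ``F`` the tensile force
in pN.  A catch bond arises when the weak state can, under tension,
interconvert into a strong state whose dissociation barrier is higher: the
mean lifetime then increases with force over an intermediate force window.

Barrier energies and rates are linked through an Arrhenius-type relation
``E = -kBT ln(k0 / nu)`` with a configurable attempt frequency ``nu``; only
rate ratios matter for the dynamics, so ``nu`` is a bookkeeping constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence, Union

import numpy as np

from .environment import Environment

__all__ = [
    "BellTransition",
    "SlipBondParams",
    "CatchBondParams",
    "LandscapeEnergies",
    "BondState",
    "bell_rate",
    "rate_matrix",
    "mean_lifetime",
    "classify_mechanotype",
    "check_design_requirements",
    "DEFAULT_ATTEMPT_FREQUENCY",
]

#: Attempt frequency used to convert rates to barrier heights (1/s).
DEFAULT_ATTEMPT_FREQUENCY = 1.0e6


class BondState(str, Enum):
    """Kinetic state of a single tether."""

    UNBOUND = "unbound"
    SLIP_BOUND = "slip_bound"
    WEAK = "weak"
    STRONG = "strong"


@dataclass(frozen=True)
class BellTransition:
    """One barrier crossing with a Bell-type force dependence.

    Parameters
    ----------
    zero_force_rate : float
        k0, the transition rate at zero force (1/s, >= 0).
    force_scale_distance : float
        x, distance to the transition state (nm).  Positive: force
        accelerates the transition; negative: force suppresses it.
    """

    zero_force_rate: float
    force_scale_distance: float

    def __post_init__(self) -> None:
        if not (self.zero_force_rate >= 0 and math.isfinite(self.zero_force_rate)):
            raise ValueError(
                f"zero_force_rate must be finite and >= 0, got {self.zero_force_rate}"
            )
        if not math.isfinite(self.force_scale_distance):
            raise ValueError("force_scale_distance must be finite")


def bell_rate(t: BellTransition, force, env: Environment):
    """Force-dependent transition rate k(F) = k0 exp(F x / kBT).

    Parameters
    ----------
    t : BellTransition
    force : float or ndarray
        Tensile force in pN; must be >= 0 (compression is resolved upstream
        as slack, i.e. zero tension).
    env : Environment

    Returns
    -------
    float or ndarray
        Rate in 1/s; strictly increasing in F for x > 0, strictly
        decreasing for x < 0.
    """
    f = np.asarray(force, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("force must be finite")
    if np.any(f < 0):
        raise ValueError(
            "negative force passed to bell_rate; slack tethers must be "
            "clamped to zero tension upstream"
        )
    out = t.zero_force_rate * np.exp(f * t.force_scale_distance / env.thermal_energy)
    return float(out) if np.isscalar(force) or out.ndim == 0 else out


@dataclass(frozen=True)
class SlipBondParams:
    """A single-state bond that only weakens under tension.

    ``off.force_scale_distance`` must be positive: tension always accelerates
    dissociation (the defining property of a slip bond).  An ideal bond is the
    x -> 0 limit and is represented by a very small positive distance.
    """

    off: BellTransition
    on_rate: float = 10.0
    label: str = "slip"

    def __post_init__(self) -> None:
        if not self.off.force_scale_distance > 0:
            raise ValueError(
                "slip-bond off pathway must have force_scale_distance > 0"
            )
        if not self.on_rate >= 0:
            raise ValueError("on_rate must be >= 0")

    @property
    def ground_state(self) -> BondState:
        return BondState.SLIP_BOUND

    def to_energies(
        self,
        env: Environment,
        attempt_frequency: float = DEFAULT_ATTEMPT_FREQUENCY,
    ) -> "LandscapeEnergies":
        """Embed the slip bond in the two-state landscape picture.

        A slip bond has no strong state, so the embedding degenerates:
        E2 = E1 and deltaE0 = 0 (it fails design requirements I and IV by
        construction).
        """
        e1 = -math.log(self.off.zero_force_rate / attempt_frequency)
        x1 = self.off.force_scale_distance
        return LandscapeEnergies(
            E1=e1, E2=e1, EIC=math.inf, deltaE0=0.0,
            x1=x1, x2=x1, xIC=0.0,
        )


@dataclass(frozen=True)
class CatchBondParams:
    """Two-state/two-pathway catch bond.

    Transitions (all Bell-type):

    - ``off_weak``      weak -> unbound       (barrier E1)
    - ``interconvert``  weak -> strong        (barrier EIC)
    - ``revert``        strong -> weak
    - ``off_strong``    strong -> unbound     (barrier E2)

    Construction enforces the four thermodynamic design requirements of a
    functional catch bond:

    I.   the strong state dissociates more slowly at zero force
         (``off_strong.k0 < off_weak.k0``, i.e. E2 > E1);
    II.  at zero force, rupture beats interconversion
         (``interconvert.k0 < off_weak.k0``, i.e. EIC > E1 at low tension);
    III. interconversion is more force-susceptible than weak rupture
         (``interconvert.x > off_weak.x``), so EIC < E1 at high tension;
    IV.  the weak state is thermodynamically preferred at rest
         (``revert.k0 > interconvert.k0``, i.e. deltaE0 > 0).
    """

    off_weak: BellTransition
    interconvert: BellTransition
    revert: BellTransition
    off_strong: BellTransition
    on_rate: float = 10.0
    label: str = "catch"
    #: set False to bypass the requirement checks, e.g. to explore parameter
    #: sets that deliberately break the catch-bond design
    validate: bool = True

    def __post_init__(self) -> None:
        if not self.on_rate >= 0:
            raise ValueError("on_rate must be >= 0")
        if not self.validate:
            return
        if not self.off_strong.zero_force_rate < self.off_weak.zero_force_rate:
            raise ValueError(
                "requirement I violated: off_strong.k0 must be < off_weak.k0"
            )
        if not self.interconvert.zero_force_rate < self.off_weak.zero_force_rate:
            raise ValueError(
                "requirement II violated: interconvert.k0 must be < off_weak.k0"
            )
        if not (
            self.interconvert.force_scale_distance
            > self.off_weak.force_scale_distance
        ):
            raise ValueError(
                "requirement III violated: interconvert.x must exceed off_weak.x"
            )
        if not self.revert.zero_force_rate > self.interconvert.zero_force_rate:
            raise ValueError(
                "requirement IV violated: revert.k0 must exceed interconvert.k0"
            )

    @property
    def ground_state(self) -> BondState:
        return BondState.WEAK

    def to_energies(
        self,
        env: Environment,
        attempt_frequency: float = DEFAULT_ATTEMPT_FREQUENCY,
    ) -> "LandscapeEnergies":
        """Barrier heights (kBT units) implied by the zero-force rates."""

        def energy(k0: float) -> float:
            return math.inf if k0 == 0 else -math.log(k0 / attempt_frequency)

        return LandscapeEnergies(
            E1=energy(self.off_weak.zero_force_rate),
            E2=energy(self.off_strong.zero_force_rate),
            EIC=energy(self.interconvert.zero_force_rate),
            deltaE0=math.log(
                self.revert.zero_force_rate / self.interconvert.zero_force_rate
            ),
            x1=self.off_weak.force_scale_distance,
            x2=self.off_strong.force_scale_distance,
            xIC=self.interconvert.force_scale_distance,
        )


BondParams = Union[SlipBondParams, CatchBondParams]


@dataclass(frozen=True)
class LandscapeEnergies:
    """Barrier energies of the two-state landscape, in kBT units.

    ``x1``, ``x2``, ``xIC`` are the Bell tilt distances (nm) of the E1, E2
    and EIC barriers; under force F a barrier tilts linearly,
    ``E(F) = E(0) - F * x / kBT``.
    """

    E1: float
    E2: float
    EIC: float
    deltaE0: float
    x1: float = 0.0
    x2: float = 0.0
    xIC: float = 0.0

    def tilted(self, which: str, force: float, env: Environment) -> float:
        """Barrier height (kBT) under tensile force ``force`` (pN)."""
        e0, x = {
            "E1": (self.E1, self.x1),
            "E2": (self.E2, self.x2),
            "EIC": (self.EIC, self.xIC),
        }[which]
        return e0 - force * x / env.thermal_energy


#: canonical ordering of the generator-matrix states
_STATES = ("weak", "strong", "unbound")


def rate_matrix(p: CatchBondParams, force: float, env: Environment) -> np.ndarray:
    """Generator matrix over (weak, strong, unbound) at fixed tension.

    Off-diagonals are the four Bell rates; each row sums to zero and the
    absorbing ``unbound`` row is all zero.
    """
    k_w_off = bell_rate(p.off_weak, force, env)
    k_ic = bell_rate(p.interconvert, force, env)
    k_rev = bell_rate(p.revert, force, env)
    k_s_off = bell_rate(p.off_strong, force, env)
    q = np.array(
        [
            [0.0, k_ic, k_w_off],
            [k_rev, 0.0, k_s_off],
            [0.0, 0.0, 0.0],
        ]
    )
    # diagonal from the realized off-diagonal row sums, so conservation holds
    # to the last bit of the summation actually performed
    q[0, 0] = -(q[0, 1] + q[0, 2])
    q[1, 1] = -(q[1, 0] + q[1, 2])
    return q


def mean_lifetime(
    p: BondParams,
    force: float,
    env: Environment,
    start_state: BondState | str | None = None,
) -> float:
    """Mean first-passage time (s) from a bound state to ``unbound``.

    For a slip bond this is ``1 / k_off(F)``.  For a catch bond the MFPT
    vector tau solves ``-Q_t tau = 1`` on the transient (weak, strong) block
    of the generator matrix.

    Raises
    ------
    ValueError
        If every dissociation rate is zero (infinite lifetime), or if
        ``start_state`` is not a bound state of ``p``.
    """
    if isinstance(p, SlipBondParams):
        if start_state not in (None, BondState.SLIP_BOUND, "slip_bound", "bound"):
            raise ValueError(f"slip bond has a single bound state, got {start_state}")
        k = bell_rate(p.off, force, env)
        if k == 0:
            raise ValueError("all dissociation rates are zero: infinite lifetime")
        return 1.0 / k

    if start_state is None:
        start_state = BondState.WEAK
    state = BondState(start_state)
    if state not in (BondState.WEAK, BondState.STRONG):
        raise ValueError(f"start_state must be weak or strong, got {start_state}")
    q = rate_matrix(p, force, env)
    qt = q[:2, :2]
    if bell_rate(p.off_weak, force, env) == 0 and bell_rate(p.off_strong, force, env) == 0:
        raise ValueError("all dissociation rates are zero: infinite lifetime")
    tau = np.linalg.solve(-qt, np.ones(2))
    return float(tau[0] if state is BondState.WEAK else tau[1])


def classify_mechanotype(
    p: BondParams,
    env: Environment,
    force_grid: Sequence[float],
    rel_tol: float = 0.05,
) -> tuple[str, float]:
    """Classify the bond as ``slip``, ``ideal`` or ``catch`` on a force grid.

    - ``catch``: the lifetime curve has an interior maximum exceeding the
      zero-force lifetime by more than ``rel_tol`` (relative);
    - ``ideal``: relative lifetime variation across the grid below
      ``rel_tol``;
    - ``slip``: lifetime decreasing with force.

    Returns
    -------
    (mechanotype, force_of_max_lifetime)
    """
    grid = np.asarray(force_grid, dtype=float)
    if grid.size < 3:
        raise ValueError("force_grid needs at least 3 points")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("force_grid must be strictly increasing")
    if grid[0] != 0:
        raise ValueError("force_grid must start at 0")

    tau = np.array([mean_lifetime(p, f, env) for f in grid])
    imax = int(np.argmax(tau))
    f_max = float(grid[imax])

    if 0 < imax < grid.size - 1 and tau[imax] > tau[0] * (1.0 + rel_tol):
        return "catch", f_max
    if (tau.max() - tau.min()) <= rel_tol * tau[0]:
        return "ideal", f_max
    if np.all(np.diff(tau) < 0):
        return "slip", f_max
    # Remainder: no significant interior max and not flat.  Call it slip when
    # the curve ends significantly below tau(0), ideal otherwise.
    if tau[-1] < tau[0] * (1.0 - rel_tol):
        return "slip", f_max
    return "ideal", f_max


def check_design_requirements(
    e: LandscapeEnergies,
    low_force: float,
    high_force: float,
    env: Environment,
) -> tuple[bool, bool, bool, bool]:
    """Audit the four thermodynamic design requirements of a catch bond.

    I.   E2 > E1 (strong state mechanically stronger);
    II.  EIC(low_force) > E1(low_force) (rupture preferred at low tension);
    III. EIC(high_force) < E1(high_force) (activation preferred at high
         tension);
    IV.  deltaE0 > 0 (weak state thermodynamically preferred at rest).

    Each barrier tilts with its own Bell distance, E(F) = E(0) - F x / kBT.
    """
    if low_force > high_force:
        raise ValueError("low_force must not exceed high_force")
    req1 = e.E2 > e.E1
    req2 = e.tilted("EIC", low_force, env) > e.tilted("E1", low_force, env)
    req3 = e.tilted("EIC", high_force, env) < e.tilted("E1", high_force, env)
    req4 = e.deltaE0 > 0
    return req1, req2, req3, req4
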