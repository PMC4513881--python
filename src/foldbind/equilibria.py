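"""Three-state coupled binding-and-folding equilibrium.

An intrinsically disordered protein can bind its partner as a loose,
still-unfolded encounter complex and fold afterwards on the partner
surface (induced fit):

    F_U + R  <=>  B_U·R  <=>  B_F·R

with ``F_U`` the free unfolded protein, ``R`` the free RNA, ``B_U`` the
bound unfolded (encounter) complex and ``B_F`` the bound folded complex.
Two constants parameterize the scheme:

* ``kd1 = [F_U][R]/[B_U]`` — microscopic dissociation constant of the
  encounter step (µM);
* ``k2 = [B_F]/[B_U]`` — dimensionless folding equilibrium constant on
  the RNA.

Any readout that reports total bound material (e.g. the anisotropy of a
labeled nucleic acid) cannot distinguish B_U from B_F and sees an
apparent two-state constant

    kd_app = kd1 / (1 + k2)

so a tight macroscopic affinity is compatible with a weak encounter step
whenever folding on the partner is favorable.  The species solver
exploits this exactly: total bound follows the usual 1:1 quadratic with
``kd_app``, and the bound pool splits as ``b_f = k2 · b_u``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "GAS_CONSTANT_KJ",
    "ThreeStateModel",
    "SpeciesState",
    "apparent_kd",
    "microscopic_kd",
    "solve_species",
    "delta_g",
]

#: Gas constant in kJ/(mol·K).
GAS_CONSTANT_KJ = 8.314e-3


@dataclass(frozen=True)
class ThreeStateModel:
    """Parameters of the three-state binding-and-folding scheme.

    Parameters
    ----------
    kd1 : float
        Microscopic dissociation constant of the encounter step, µM.
    k2 : float
        Folding equilibrium constant [B_F]/[B_U] (dimensionless).
    temperature : float
        Absolute temperature in kelvin (default 298).
    """

    kd1: float
    k2: float
    temperature: float = 298.0

    def __post_init__(self) -> None:
        if not self.kd1 > 0:
            raise ValueError(f"kd1 must be positive, got {self.kd1}")
        if not self.k2 > 0:
            raise ValueError(f"k2 must be positive, got {self.k2}")
        if not self.temperature > 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")

    @property
    def kd_app(self) -> float:
        """Apparent (macroscopic) dissociation constant kd1/(1+k2), µM."""
        return self.kd1 / (1.0 + self.k2)

    def folding_delta_g(self) -> float:
        """ΔG of B_U -> B_F at the model temperature, kJ/mol."""
        return delta_g(self.k2, self.temperature)

    def solve(self, p_total: float, r_total: float) -> "SpeciesState":
        """Equilibrium species at the given totals; see :func:`solve_species`."""
        return solve_species(p_total, r_total, self)


@dataclass(frozen=True)
class SpeciesState:
    """Equilibrium concentrations (µM) at one titration point."""

    f_u: float
    r_free: float
    b_u: float
    b_f: float
    p_total: float
    r_total: float
    model: ThreeStateModel | None = field(default=None, compare=False)

    @property
    def bound_total(self) -> float:
        """Total complex concentration b_u + b_f, µM."""
        return self.b_u + self.b_f

    @property
    def unfolded_total(self) -> float:
        """Total unfolded-protein pool f_u + b_u, µM (the fast-exchange pool)."""
        return self.f_u + self.b_u

    @property
    def unfolded_bound_fraction(self) -> float:
        """Fraction of the unfolded pool that is RNA-bound, b_u/(f_u+b_u)."""
        tot = self.unfolded_total
        if tot == 0.0:
            return 0.0
        return self.b_u / tot


def apparent_kd(model: ThreeStateModel) -> float:
    """Apparent dissociation constant kd1/(1+k2) of the three-state scheme.

    Total-bound observables of the three-state system are exactly those of
    a two-state system with this constant.
    """
    return model.kd_app


def microscopic_kd(kd_app: float, k2: float) -> float:
    """Microscopic encounter-step Kd from the apparent Kd: kd_app·(1+k2).

    Exact inverse of :func:`apparent_kd`.
    """
    if not kd_app > 0:
        raise ValueError(f"kd_app must be positive, got {kd_app}")
    if not k2 > 0:
        raise ValueError(f"k2 must be positive, got {k2}")
    return kd_app * (1.0 + k2)


def _bound_two_state(p: float, r: float, kd: float) -> float:
    # Smaller root of B^2 - (p+r+kd) B + p r = 0 in the multiplication form
    # 2pr / (s + sqrt(s^2 - 4pr)): immune to cancellation when kd << totals.
    if p == 0.0 or r == 0.0:
        return 0.0
    s = p + r + kd
    disc = s * s - 4.0 * p * r
    disc = max(disc, 0.0)
    return 2.0 * p * r / (s + math.sqrt(disc))


def solve_species(p_total: float, r_total: float, model: ThreeStateModel) -> SpeciesState:
    """Solve the 1:1 mass-balance system of the three-state scheme.

    Returns the unique non-negative equilibrium state.  Total bound equals
    the two-state quadratic solution at ``model.kd_app`` and the bound pool
    satisfies ``b_f = k2 · b_u`` exactly.

    Parameters
    ----------
    p_total, r_total : float
        Total protein and RNA concentrations, µM (non-negative).
    """
    if p_total < 0:
        raise ValueError(f"p_total must be non-negative, got {p_total}")
    if r_total < 0:
        raise ValueError(f"r_total must be non-negative, got {r_total}")
    bound = _bound_two_state(p_total, r_total, model.kd_app)
    b_u = bound / (1.0 + model.k2)
    b_f = model.k2 * b_u
    f_u = max(p_total - bound, 0.0)
    r_free = max(r_total - bound, 0.0)
    return SpeciesState(
        f_u=f_u,
        r_free=r_free,
        b_u=b_u,
        b_f=b_f,
        p_total=p_total,
        r_total=r_total,
        model=model,
    )


def delta_g(k: float, temperature: float = 298.0) -> float:
    """Standard free-energy difference −R·T·ln(k) in kJ/mol.

    For the folding step on the RNA, ``k = [B_F]/[B_U]``; k = 5 at 298 K
    gives about −4 kJ/mol, i.e. the two bound forms are close in energy.
    """
    if not k > 0:
        raise ValueError(f"equilibrium constant must be positive, got {k}")
    if not temperature > 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return -GAS_CONSTANT_KJ * temperature * math.log(k)
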