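"""Concentration unit helpers.

All equilibrium code works in micromolar internally; these converters let
callers supply values in nM, µM or M.
"""

from __future__ import annotations

_FACTORS_TO_UM = {
    "nM": 1e-3,
    "uM": 1.0,
    "µM": 1.0,
    "M": 1e6,
    "mM": 1e3,
}


def to_micromolar(value: float, unit: str = "uM") -> float:
    """Convert a concentration to µM.

    Parameters
    ----------
    value : float
        Concentration in ``unit``.
    unit : str
        One of ``nM``, ``uM``/``µM``, ``mM``, ``M``.
    """
    try:
        return value * _FACTORS_TO_UM[unit]
    except KeyError:
        raise ValueError(
            f"unknown concentration unit {unit!r}; expected one of "
            f"{sorted(set(_FACTORS_TO_UM))}"
        ) from None


def from_micromolar(value_um: float, unit: str = "uM") -> float:
    """Convert a concentration in µM to ``unit``."""
    try:
        return value_um / _FACTORS_TO_UM[unit]
    except KeyError:
        raise ValueError(
            f"unknown concentration unit {unit!r}; expected one of "
            f"{sorted(set(_FACTORS_TO_UM))}"
        ) from None
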