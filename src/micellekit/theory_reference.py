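"""Reference scaling laws and evaluable mean-field formulas.

The free energy per molecule of a spherical micelle decomposes as

    F = F_corona + F_surface + F_core,

where only the core/corona interfacial term has a universal closed form,

    F_surface = gamma_surf * (NB / phi_B)**(2/3) * p**(-1/3),

with ``gamma_surf`` the interfacial free energy per unit area and
``phi_B ~ 1`` the core volume fraction (``F_core`` can be omitted within
the stability range of spherical micelles, and ``F_corona`` depends on the
corona model).  Minimizing ``F`` over ``p`` in the various corona models
yields the power-law predictions tabulated here; this module stores those
exponents (as exact rationals), evaluates the closed-form pieces, and
serves them as comparison lines for simulation sweeps.

Symbol note: ``gamma_surf`` (interfacial tension) is distinct from the
Langevin friction constant ``gamma`` of the integrator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

__all__ = [
    "TheoryParams",
    "ExponentEntry",
    "EXPONENT_TABLE",
    "ANCHORS",
    "surface_free_energy",
    "manning_parameter",
    "reference_exponent",
    "log_aggregation_law",
    "reference_line",
]


@dataclass(frozen=True)
class TheoryParams:
    """Constants entering the mean-field reference formulas.

    ``alpha_frac`` is the fraction of charged monomers of the corona block;
    ``alpha_const``/``beta_const`` are the fitting constants of the
    logarithmic aggregation law (set by the core surface tension, core
    density, Flory exponent and NB; they are free inputs here).
    """

    gamma_surf: float = 1.0
    phi_B: float = 1.0
    alpha_frac: float = 1.0
    alpha_const: float = 1.0
    beta_const: float = 1.0
    solvent_regime: str = "theta"          # or "good"
    charge_regime: str = "small_aggregation"  # or "large_aggregation"

    def __post_init__(self) -> None:
        if not 0.0 < self.phi_B <= 1.0:
            raise ValueError("phi_B must be in (0, 1]")
        if not 0.0 <= self.alpha_frac <= 1.0:
            raise ValueError("alpha_frac must be in [0, 1]")


@dataclass(frozen=True)
class ExponentEntry:
    exponent: Fraction
    anchor: str


def _e(num: int, den: int, anchor: str) -> ExponentEntry:
    return ExponentEntry(Fraction(num, den), anchor)


# keys: (block type, charge, regime, observable)
EXPONENT_TABLE: dict[tuple[str, str, str, str], ExponentEntry] = {
    # --- linear corona, neutral ---
    ("linear", "neutral", "scf", "peq_vs_NA"):
        _e(-3, 11, "p_eq ~ NA^(-3/11)  [SCF, linear neutral]"),
    ("linear", "neutral", "scf", "peq_vs_NB"):
        _e(10, 11, "p_eq ~ NB^(10/11)  [SCF, linear neutral, star-like]"),
    ("linear", "neutral", "scaling", "peq_vs_NB"):
        _e(4, 5, "p_eq ~ NB^(4/5)  [scaling theory, linear neutral]"),
    ("linear", "neutral", "theta", "Rcorona_vs_NA"):
        _e(1, 2, "R_corona ~ NA^(1/2)  [scaling, theta solvent]"),
    ("linear", "neutral", "good", "Rcorona_vs_NA"):
        _e(3, 5, "R_corona ~ NA^(3/5)  [scaling, good solvent]"),
    # --- linear corona, quenched ionic ---
    ("linear", "ionic", "small_aggregation", "peq_vs_NA"):
        _e(-1, 1, "p_eq ~ NA^(-1)  [scaling, ionic, small aggregation]"),
    ("linear", "ionic", "large_aggregation", "peq_vs_NA"):
        _e(-3, 1, "p_eq ~ NA^(-3)  [scaling, ionic, large aggregation]"),
    ("linear", "ionic", "charged_micelle", "R_vs_NA"):
        _e(2, 3, "R ~ NA^(2/3)  [scaling, effectively charged micelle]"),
    ("linear", "ionic", "small_aggregation", "peq_vs_NB"):
        _e(2, 3, "p_eq ~ NB^(2/3)  [SCF, ionic, small aggregation]"),
    ("linear", "ionic", "large_aggregation", "peq_vs_NB"):
        _e(2, 1, "p_eq ~ NB^2  [SCF, ionic, large aggregation/osmotic]"),
    ("linear", "ionic", "large_aggregation", "Rcore_vs_NB"):
        _e(1, 1, "R_core ~ NB  [SCF, ionic]"),
    # --- dendritic corona, neutral ---
    ("dendritic", "neutral", "scf", "Rcorona_vs_NB"):
        _e(2, 11, "R_corona ~ NB^(2/11)  [SCF, dendritic neutral]"),
    ("dendritic", "neutral", "scf", "Rcore_vs_NB"):
        _e(7, 11, "R_core ~ NB^(7/11)  [SCF, dendritic neutral]"),
    ("dendritic", "neutral", "scf", "Rcorona_vs_NA"):
        _e(6, 11, "R_corona ~ NA^(6/11)  [SCF, dendritic neutral]"),
}

#: bundled anchor list; every table entry round-trips to one of these
ANCHORS: tuple[str, ...] = tuple(
    entry.anchor for entry in EXPONENT_TABLE.values()
)


def surface_free_energy(
    gamma_surf: float, NB: int, phi_B: float, p: float
) -> float:
    """Interfacial free energy per molecule of the micellar core.

    ``gamma_surf * (NB / phi_B)**(2/3) * p**(-1/3)`` — the surface area
    per chain of a compact spherical core of ``p * NB / phi_B`` bead
    volumes, times the interfacial tension.
    """
    if gamma_surf <= 0 or NB <= 0 or phi_B <= 0 or p <= 0:
        raise ValueError("all arguments must be > 0")
    return gamma_surf * (NB / phi_B) ** (2.0 / 3.0) * p ** (-1.0 / 3.0)


def manning_parameter(lambda_B: float, l_charge: float) -> float:
    """Manning condensation parameter ``Gamma = lambda_B / l_charge``.

    ``Gamma > 1`` signals counterion condensation on a linear
    polyelectrolyte with charge spacing ``l_charge``.
    """
    if l_charge <= 0:
        raise ValueError("l_charge must be > 0")
    if lambda_B < 0:
        raise ValueError("lambda_B must be >= 0")
    return lambda_B / l_charge


def reference_exponent(
    block: str, charge: str, regime: str, observable: str
) -> ExponentEntry:
    """Look up a tabulated scaling exponent.

    Raises ``KeyError`` with the list of valid keys for combinations that
    have no stated prediction.
    """
    key = (block, charge, regime, observable)
    try:
        return EXPONENT_TABLE[key]
    except KeyError:
        valid = "\n  ".join(str(k) for k in sorted(EXPONENT_TABLE))
        raise KeyError(
            f"no tabulated exponent for {key}; valid keys:\n  {valid}"
        ) from None


def log_aggregation_law(
    NA: float, alpha_const: float, beta_const: float
) -> float:
    """Logarithmic aggregation law ``p_eq = (alpha ln(beta NA))**(-6/5)``.

    Valid for ``beta NA > 1`` (natural logarithm; the base only rescales
    ``alpha``).  Describes the flattening of ``p_eq(NA)`` for star-like
    neutral micelles beyond the SCF power-law regime.
    """
    x = beta_const * NA
    if x <= 1.0:
        raise ValueError("beta_const * NA must be > 1")
    if alpha_const <= 0:
        raise ValueError("alpha_const must be > 0")
    return (alpha_const * math.log(x)) ** (-6.0 / 5.0)


def reference_line(
    block: str, charge: str, regime: str, observable: str,
    x_min: float, x_max: float, n_points: int = 20, prefactor: float = 1.0,
):
    """Evaluate a tabulated power law on a log-spaced grid.

    Returns ``(x, y, entry)`` for overlay plotting against simulation
    sweeps; the prefactor is arbitrary (scaling laws fix only the slope).
    """
    import numpy as np

    entry = reference_exponent(block, charge, regime, observable)
    x = np.geomspace(x_min, x_max, n_points)
    y = prefactor * x ** float(entry.exponent)
    return x, y, entry
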