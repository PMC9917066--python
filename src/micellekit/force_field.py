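"""Interaction potentials and forces for the coarse-grained micelle model.

The model is a Kremer-Grest bead-spring system in implicit solvent:

* excluded volume between all bead pairs via the Weeks-Chandler-Andersen
  (WCA) potential, cut at ``2**(1/6)`` times the pair size parameter;
* FENE bonds along the chains (stiffness ``kbond``, divergence ``r_inf``);
* a solvent-induced hydrophobic attraction between B-B pairs only: a flat
  well of depth ``eps_attr`` inside the WCA cutoff with a ``cos**2`` tail of
  width ``wc``;
* bare Coulomb interactions between charged beads in Bjerrum-length units,
  ``V = kBT * lambda_B * z1 * z2 / r``.

Reduced units throughout: ``sigma_BB`` is the unit of length, ``epsilon``
the unit of energy, bead masses are 1.  Pair size parameters follow the
underlying membrane model: ``sigma_AA = sigma_AB = 0.95 sigma_BB``;
counterions use ``sigma = sigma_BB`` against every partner.  Bonded pairs
are *not* excluded from WCA (standard Kremer-Grest convention, keeping bond
lengths near 0.97 sigma).

Single-micelle runs use open boundaries; an optional stiff harmonic wall at
radius ``R_conf`` (``SystemState.R_conf``) confines the system, playing the
role of the finite simulation box for counterion partitioning.  Coulomb
energies are evaluated by direct summation; a standard Ewald sum under cubic
periodic boundaries is provided for cross-validation on small clusters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

import numpy as np
from numba import njit
from scipy.special import erfc

if TYPE_CHECKING:  # pragma: no cover
    from .md_engine import SystemState
    from .polymer_topology import Topology

__all__ = [
    "BondBreakError",
    "ForceFieldParams",
    "WCA_CUT_FACTOR",
    "wca_energy",
    "fene_energy",
    "attractive_energy",
    "coulomb_energy",
    "total_energy",
    "forces",
    "compute_forces_energies",
    "direct_coulomb_energy",
    "ewald_coulomb_energy",
]

#: WCA cutoff in units of the pair size parameter
WCA_CUT_FACTOR = 2.0 ** (1.0 / 6.0)


class BondBreakError(RuntimeError):
    """A FENE bond reached its divergence length ``r_inf``."""


@dataclass(frozen=True)
class ForceFieldParams:
    """All interaction constants of the model (reduced units).

    Defaults are the reference parameter set of the model: ``sigma_AA =
    sigma_AB = 0.95``, ``sigma_BB = 1``, ``kbond = 30``, ``r_inf = 1.5``,
    ``lambda_B = 2`` (water at room temperature), ``kBT = 1``.  The two
    free parameters are ``eps_attr`` (hydrophobicity strength) and ``wc``
    (attraction range); they control the equilibrium aggregation number.
    """

    epsilon: float = 1.0
    sigma_BB: float = 1.0
    sigma_AA: float = 0.95
    sigma_AB: float = 0.95
    sigma_ion: float = 1.0          # counterion pairs and counterion-monomer
    eps_attr: float = 1.0
    wc: float = 1.6
    kbond: float = 30.0
    r_inf: float = 1.5
    lambda_B: float = 2.0
    kBT: float = 1.0
    wall_k: float = 100.0           # harmonic confining-wall stiffness

    def __post_init__(self) -> None:
        for name in ("epsilon", "sigma_BB", "sigma_AA", "sigma_AB",
                     "sigma_ion", "kbond", "r_inf", "kBT"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("eps_attr", "wc", "lambda_B", "wall_k"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    # -- derived quantities -------------------------------------------------

    def sigma_matrix(self) -> np.ndarray:
        """3x3 pair size parameters indexed by (bead_type, bead_type)."""
        s = np.empty((3, 3))
        s[0, 0] = self.sigma_AA
        s[0, 1] = s[1, 0] = self.sigma_AB
        s[1, 1] = self.sigma_BB
        s[2, :] = s[:, 2] = self.sigma_ion
        return s

    def rc_matrix(self) -> np.ndarray:
        """Per-pair WCA cutoffs, ``2**(1/6)`` times the pair sigma."""
        return WCA_CUT_FACTOR * self.sigma_matrix()

    @property
    def rc_BB(self) -> float:
        """B-B WCA cutoff; inner edge of the hydrophobic attraction well."""
        return WCA_CUT_FACTOR * self.sigma_BB

    @property
    def attraction_range(self) -> float:
        """Outer edge of the B-B attraction, ``rc_BB + wc``."""
        return self.rc_BB + self.wc

    def with_(self, **kwargs) -> "ForceFieldParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "epsilon": self.epsilon, "sigma_BB": self.sigma_BB,
            "sigma_AA": self.sigma_AA, "sigma_AB": self.sigma_AB,
            "sigma_ion": self.sigma_ion, "eps_attr": self.eps_attr,
            "wc": self.wc, "kbond": self.kbond, "r_inf": self.r_inf,
            "lambda_B": self.lambda_B, "kBT": self.kBT,
            "wall_k": self.wall_k,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ForceFieldParams":
        return cls(**d)


# ---------------------------------------------------------------------------
# scalar reference potentials (validated, used directly by analyses/tests)
# ---------------------------------------------------------------------------

def wca_energy(r: float, sigma_pair: float, epsilon: float = 1.0) -> float:
    """Truncated-shifted Lennard-Jones (WCA) pair energy.

    ``4 eps [ (s/r)^12 - (s/r)^6 + 1/4 ]`` for ``r <= 2^(1/6) s``, else 0;
    continuous and non-negative everywhere.
    """
    if r <= 0:
        raise ValueError(f"r must be > 0, got {r}")
    if r > WCA_CUT_FACTOR * sigma_pair:
        return 0.0
    sr6 = (sigma_pair / r) ** 6
    return 4.0 * epsilon * (sr6 * sr6 - sr6 + 0.25)


def fene_energy(r: float, kbond: float = 30.0, r_inf: float = 1.5) -> float:
    """FENE bond energy ``-(1/2) k r_inf^2 ln(1 - (r/r_inf)^2)``.

    Monotonically increasing on ``(0, r_inf)``; a separation at or beyond
    the divergence length is a broken bond and raises ``BondBreakError``.
    """
    if r < 0:
        raise ValueError(f"r must be >= 0, got {r}")
    if r >= r_inf:
        raise BondBreakError(
            f"bond length r={r:g} >= divergence length r_inf={r_inf:g}"
        )
    x = r / r_inf
    return -0.5 * kbond * r_inf**2 * math.log1p(-x * x)


def attractive_energy(r: float, eps_attr: float, wc: float, rc: float) -> float:
    """Hydrophobic B-B attraction: flat well with a ``cos^2`` shoulder.

    ``-eps_attr`` for ``r < rc``; ``-eps_attr cos^2(pi (r-rc) / (2 wc))``
    on ``[rc, rc+wc]``; 0 beyond.  Continuous everywhere.
    """
    if r <= 0:
        raise ValueError(f"r must be > 0, got {r}")
    if r < rc:
        return -eps_attr
    if wc > 0 and r <= rc + wc:
        return -eps_attr * math.cos(math.pi * (r - rc) / (2.0 * wc)) ** 2
    return 0.0


def coulomb_energy(
    r: float, z1: float, z2: float,
    lambda_B: float = 2.0, kBT: float = 1.0,
) -> float:
    """Bare Coulomb pair energy ``kBT lambda_B z1 z2 / r``.

    The Bjerrum length ``lambda_B`` is the separation at which two unit
    charges interact with energy ``kBT``.
    """
    if r <= 0:
        raise ValueError(f"r must be > 0, got {r}")
    return kBT * lambda_B * z1 * z2 / r


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _nonbonded_kernel(pos, types, charges, sigma2, rc2, epsilon,
                      eps_attr, wc, rc_bb, attr_out2, coul_pref, f_out):
    """All-pairs nonbonded forces.  Returns (E_wca, E_attr, E_coul)."""
    n = pos.shape[0]
    e_wca = 0.0
    e_attr = 0.0
    e_coul = 0.0
    half_pi_over_wc = 0.0
    if wc > 0.0:
        half_pi_over_wc = math.pi / (2.0 * wc)
    for i in range(n):
        ti = types[i]
        qi = charges[i]
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        for j in range(i + 1, n):
            tj = types[j]
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dz = zi - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < 1e-18:
                r2 = 1e-18
            fs = 0.0  # scalar force / r; positive = repulsive
            # WCA
            if r2 < rc2[ti, tj]:
                sr2 = sigma2[ti, tj] / r2
                sr6 = sr2 * sr2 * sr2
                e_wca += 4.0 * epsilon * (sr6 * sr6 - sr6 + 0.25)
                fs += 24.0 * epsilon * (2.0 * sr6 * sr6 - sr6) / r2
            # hydrophobic B-B attraction
            if ti == 1 and tj == 1 and eps_attr > 0.0:
                if r2 < rc_bb * rc_bb:
                    e_attr -= eps_attr
                elif r2 < attr_out2:
                    r = math.sqrt(r2)
                    u = half_pi_over_wc * (r - rc_bb)
                    c = math.cos(u)
                    e_attr -= eps_attr * c * c
                    # dV/dr = eps * sin(2u) * pi/(2 wc); force = -dV/dr
                    fs -= eps_attr * math.sin(2.0 * u) * half_pi_over_wc / r
            # Coulomb
            if qi != 0.0 and charges[j] != 0.0:
                r = math.sqrt(r2)
                e = coul_pref * qi * charges[j] / r
                e_coul += e
                fs += e / r2
            if fs != 0.0:
                f_out[i, 0] += fs * dx
                f_out[i, 1] += fs * dy
                f_out[i, 2] += fs * dz
                f_out[j, 0] -= fs * dx
                f_out[j, 1] -= fs * dy
                f_out[j, 2] -= fs * dz
    return e_wca, e_attr, e_coul


@njit(cache=True)
def _bond_kernel(pos, bonds, kbond, r_inf, f_out):
    """FENE bond forces.  Returns (E_fene, first broken bond or -1)."""
    e = 0.0
    r_inf2 = r_inf * r_inf
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= r_inf2:
            return e, b
        x2 = r2 / r_inf2
        e += -0.5 * kbond * r_inf2 * math.log(1.0 - x2)
        fs = -kbond / (1.0 - x2)  # attractive
        f_out[i, 0] += fs * dx
        f_out[i, 1] += fs * dy
        f_out[i, 2] += fs * dz
        f_out[j, 0] -= fs * dx
        f_out[j, 1] -= fs * dy
        f_out[j, 2] -= fs * dz
    return e, -1


@njit(cache=True)
def _wall_kernel(pos, r_conf, wall_k, f_out):
    """Harmonic confining sphere beyond radius ``r_conf``.  Returns E."""
    e = 0.0
    for i in range(pos.shape[0]):
        x = pos[i, 0]
        y = pos[i, 1]
        z = pos[i, 2]
        d = math.sqrt(x * x + y * y + z * z)
        if d > r_conf:
            exc = d - r_conf
            e += 0.5 * wall_k * exc * exc
            fs = -wall_k * exc / d
            f_out[i, 0] += fs * x
            f_out[i, 1] += fs * y
            f_out[i, 2] += fs * z
    return e


# ---------------------------------------------------------------------------
# system-level evaluation
# ---------------------------------------------------------------------------

def compute_forces_energies(
    positions: np.ndarray,
    topo: "Topology",
    ff: ForceFieldParams,
    R_conf: float | None = None,
) -> tuple[np.ndarray, dict[str, float]]:
    """Forces and potential-energy decomposition for one configuration.

    Returns ``(forces, terms)`` with ``terms`` holding ``wca``, ``fene``,
    ``attractive``, ``coulomb``, ``wall`` and their sum ``potential``.
    Raises :class:`BondBreakError` if any bond reaches ``r_inf``.
    """
    pos = np.ascontiguousarray(positions, dtype=np.float64)
    if pos.shape != (topo.n_beads, 3):
        raise ValueError(
            f"positions shape {pos.shape} inconsistent with topology "
            f"({topo.n_beads} beads)"
        )
    f = np.zeros_like(pos)
    sig = ff.sigma_matrix()
    rc = ff.rc_matrix()
    attr_out = ff.attraction_range
    e_wca, e_attr, e_coul = _nonbonded_kernel(
        pos, topo.bead_type.astype(np.int64),
        topo.bead_charge.astype(np.float64),
        sig * sig, rc * rc, ff.epsilon, ff.eps_attr, ff.wc, ff.rc_BB,
        attr_out * attr_out, ff.kBT * ff.lambda_B, f,
    )
    e_fene, broken = _bond_kernel(
        pos, np.ascontiguousarray(topo.bonds, dtype=np.int64),
        ff.kbond, ff.r_inf, f,
    )
    if broken >= 0:
        i, j = topo.bonds[broken]
        r = float(np.linalg.norm(pos[i] - pos[j]))
        raise BondBreakError(
            f"bond {broken} ({i}-{j}) length {r:.4f} >= r_inf={ff.r_inf:g}"
        )
    e_wall = 0.0
    if R_conf is not None and R_conf > 0:
        e_wall = _wall_kernel(pos, float(R_conf), ff.wall_k, f)
    terms = {
        "wca": float(e_wca),
        "fene": float(e_fene),
        "attractive": float(e_attr),
        "coulomb": float(e_coul),
        "wall": float(e_wall),
    }
    terms["potential"] = sum(terms.values())
    return f, terms


def total_energy(
    state: "SystemState", topo: "Topology", ff: ForceFieldParams
) -> dict[str, float]:
    """Energy decomposition of a state, including kinetic energy.

    ``per_molecule`` is the total *potential* energy divided by the
    aggregation number ``p`` — the quantity the equilibration protocol
    monitors.
    """
    _, terms = compute_forces_energies(
        state.positions, topo, ff, R_conf=state.R_conf
    )
    terms["kinetic"] = float(0.5 * np.sum(state.velocities**2))
    terms["per_molecule"] = terms["potential"] / topo.p
    return terms


def forces(
    state: "SystemState", topo: "Topology", ff: ForceFieldParams
) -> np.ndarray:
    """Per-bead conservative force vectors (analytic gradients)."""
    f, _ = compute_forces_energies(
        state.positions, topo, ff, R_conf=state.R_conf
    )
    return f


# ---------------------------------------------------------------------------
# electrostatics cross-check: direct sum and Ewald
# ---------------------------------------------------------------------------

def direct_coulomb_energy(
    positions: np.ndarray,
    charges: np.ndarray,
    lambda_B: float = 2.0,
    kBT: float = 1.0,
) -> float:
    """Open-boundary all-pairs Coulomb energy (the production route)."""
    pos = np.asarray(positions, dtype=float)
    q = np.asarray(charges, dtype=float)
    d = pos[:, None, :] - pos[None, :, :]
    r = np.sqrt((d * d).sum(axis=-1))
    qq = np.outer(q, q)
    iu = np.triu_indices(len(q), k=1)
    return float(kBT * lambda_B * np.sum(qq[iu] / r[iu]))


def ewald_coulomb_energy(
    positions: np.ndarray,
    charges: np.ndarray,
    box_L: float,
    lambda_B: float = 2.0,
    kBT: float = 1.0,
    alpha: float | None = None,
    k_max: int = 8,
) -> float:
    """Standard Ewald Coulomb energy in a cubic periodic box.

    Real-space sum over minimum-image pairs with ``erfc`` screening,
    reciprocal-space sum over integer modes ``|n| <= k_max``, and the
    Gaussian self term; tin-foil (conducting) boundary conditions.  The
    Ewald splitting parameter ``alpha`` defaults to ``6/box_L``, which
    balances real- and reciprocal-space truncation errors below 1e-5 for
    ``k_max = 8``.  Used to validate the open-boundary direct sum on
    compact neutral clusters.
    """
    pos = np.asarray(positions, dtype=float)
    q = np.asarray(charges, dtype=float)
    n = len(q)
    L = float(box_L)
    if alpha is None:
        alpha = 6.0 / L
    # real space, minimum image
    d = pos[:, None, :] - pos[None, :, :]
    d -= L * np.round(d / L)
    r = np.sqrt((d * d).sum(axis=-1))
    iu = np.triu_indices(n, k=1)
    e_real = float(np.sum(np.outer(q, q)[iu] * erfc(alpha * r[iu]) / r[iu]))
    # reciprocal space
    rng = np.arange(-k_max, k_max + 1)
    nx, ny, nz = np.meshgrid(rng, rng, rng, indexing="ij")
    mask = (nx != 0) | (ny != 0) | (nz != 0)
    nvec = np.stack([nx[mask], ny[mask], nz[mask]], axis=-1)
    nvec = nvec[(nvec**2).sum(axis=1) <= k_max**2]
    kvec = 2.0 * np.pi / L * nvec
    k2 = (kvec**2).sum(axis=1)
    phase = pos @ kvec.T                        # (n, nk)
    S = (q[:, None] * np.exp(1j * phase)).sum(axis=0)
    V = L**3
    e_recip = float(
        (2.0 * np.pi / V)
        * np.sum(np.exp(-k2 / (4.0 * alpha**2)) / k2 * np.abs(S) ** 2)
    )
    e_self = -alpha / math.sqrt(math.pi) * float(np.sum(q * q))
    return kBT * lambda_B * (e_real + e_recip + e_self)
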