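"""Structural observables: gyration radii, shape, profiles, charge, scaling.

Shape analysis is based on the gyration tensor
``S = (1/n) sum (r - rbar)(r - rbar)^T`` with eigenvalues
``l1 >= l2 >= l3``.  The asphericity used throughout is the normalized,
size-independent form

    A = [(l1-l2)^2 + (l2-l3)^2 + (l3-l1)^2] / [2 (l1+l2+l3)^2],

which is 0 for a spherically symmetric eigenvalue spectrum and 1 in the rod
limit; algebraically it coincides with the standard relative shape
anisotropy ``kappa^2 = 1 - 3 (l1 l2 + l2 l3 + l3 l1) / (l1+l2+l3)^2``.
Being scale-free, it is comparable across aggregation numbers in a sweep.

Radial density profiles are shell-normalized number densities around the
center of mass of the hydrophobic beads of the largest cluster, so escaped
molecules or far counterions do not shift the micelle center.  Counterion
partitioning uses an operational corona boundary: the radius enclosing a
given percentile (default 95%) of the hydrophilic beads; ``Qin`` is the
fraction of counterions inside that boundary and the net micelle charge
follows exactly as ``Znet = (1 - Qin) * n_counterions`` for monovalent
ions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, TYPE_CHECKING

import numpy as np
from scipy import stats

from .polymer_topology import TYPE_A, TYPE_B, TYPE_CION

if TYPE_CHECKING:  # pragma: no cover
    from .polymer_topology import Topology

__all__ = [
    "ShapeDescriptors",
    "DensityProfile",
    "ChargePartition",
    "ScalingFit",
    "radius_of_gyration",
    "gyration_tensor",
    "shape_descriptors",
    "micelle_descriptors",
    "radial_density_profile",
    "charge_partition",
    "average_charge_partition",
    "fit_scaling",
]


@dataclass(frozen=True)
class ShapeDescriptors:
    """Gyration-tensor summary of one bead subset."""

    rg: float
    asphericity: float
    anisotropy: float
    eigenvalues: tuple[float, float, float]  # descending


@dataclass(frozen=True)
class DensityProfile:
    """Radial number-density profile per species around a micelle center."""

    bin_edges: np.ndarray                 # (n_bins + 1,)
    density: dict[str, np.ndarray]        # species label -> (n_bins,)
    counts: dict[str, np.ndarray]         # raw per-shell bead counts
    center: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def shell_volumes(self) -> np.ndarray:
        return 4.0 / 3.0 * np.pi * np.diff(self.bin_edges**3)


@dataclass(frozen=True)
class ChargePartition:
    """Counterion partitioning across the corona boundary."""

    Qin: float              # fraction of counterions inside the corona
    Znet: float             # uncompensated micelle charge, elementary units
    corona_radius: float
    percentile: float


@dataclass(frozen=True)
class ScalingFit:
    """Power-law exponent from OLS on (ln x, ln y)."""

    exponent: float
    intercept: float
    stderr: float

    @property
    def prefactor(self) -> float:
        return float(np.exp(self.intercept))


def _select(positions: np.ndarray, subset) -> np.ndarray:
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    if subset is None:
        return pos
    sel = pos[np.asarray(subset)]
    if sel.shape[0] == 0:
        raise ValueError("subset is empty")
    return sel


def radius_of_gyration(positions: np.ndarray, subset=None) -> float:
    """Root-mean-square distance from the subset centroid (unit masses)."""
    sel = _select(positions, subset)
    d = sel - sel.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def gyration_tensor(positions: np.ndarray, subset=None) -> np.ndarray:
    sel = _select(positions, subset)
    d = sel - sel.mean(axis=0)
    return d.T @ d / sel.shape[0]


def shape_descriptors(positions: np.ndarray, subset=None) -> ShapeDescriptors:
    """Rg, asphericity and relative shape anisotropy of a bead subset.

    Subsets with fewer than 3 beads return all-zero descriptors by
    convention (the tensor spectrum is degenerate there).
    """
    sel = _select(positions, subset)
    if sel.shape[0] < 3:
        return ShapeDescriptors(
            rg=radius_of_gyration(sel),
            asphericity=0.0, anisotropy=0.0,
            eigenvalues=(0.0, 0.0, 0.0),
        )
    S = gyration_tensor(sel)
    lam = np.linalg.eigvalsh(S)[::-1]           # descending
    lam = np.clip(lam, 0.0, None)
    tr = float(lam.sum())
    if tr <= 0.0:
        return ShapeDescriptors(0.0, 0.0, 0.0, (0.0, 0.0, 0.0))
    l1, l2, l3 = (float(v) for v in lam)
    asph = ((l1 - l2) ** 2 + (l2 - l3) ** 2 + (l3 - l1) ** 2) / (2.0 * tr**2)
    kappa2 = 1.0 - 3.0 * (l1 * l2 + l2 * l3 + l3 * l1) / tr**2
    return ShapeDescriptors(
        rg=float(np.sqrt(tr)),
        asphericity=float(asph),
        anisotropy=float(kappa2),
        eigenvalues=(l1, l2, l3),
    )


def micelle_descriptors(
    positions: np.ndarray,
    topo: "Topology",
    molecules: Iterable[int] | None = None,
) -> dict[str, float]:
    """Micelle- and core-level shape summary.

    ``Rg_micelle`` and the asphericity/anisotropy are computed over all
    copolymer beads (optionally restricted to the molecules of one
    cluster), ``Rg_core`` over the hydrophobic beads only.
    """
    pos = np.asarray(positions, dtype=float)
    in_mol = topo.molecule_id >= 0
    if molecules is not None:
        in_mol &= np.isin(topo.molecule_id, np.asarray(list(molecules)))
    poly = shape_descriptors(pos, np.flatnonzero(in_mol))
    core_idx = np.flatnonzero(in_mol & topo.is_B)
    return {
        "Rg_micelle": poly.rg,
        "Rg_core": radius_of_gyration(pos, core_idx),
        "asphericity": poly.asphericity,
        "anisotropy": poly.anisotropy,
    }


def _micelle_center(positions: np.ndarray, topo: "Topology") -> np.ndarray:
    """Center of mass of the B beads of the largest cluster."""
    from .micelle_protocol import detect_clusters  # deferred: avoids cycle

    res = detect_clusters(positions, topo)
    b_idx = np.flatnonzero(topo.is_B)
    largest = np.argmax(np.bincount(res.bead_labels))
    return positions[b_idx[res.bead_labels == largest]].mean(axis=0)


def radial_density_profile(
    positions: np.ndarray,
    topo: "Topology",
    species: Sequence[str] = ("A", "B", "CI"),
    n_bins: int = 50,
    r_max: float | None = None,
    center: np.ndarray | None = None,
) -> DensityProfile:
    """Shell-normalized radial number densities per species.

    ``center`` defaults to the core center of mass (largest hydrophobic
    cluster); ``r_max`` defaults to the largest bead distance so that every
    bead is counted and the integral invariant
    ``sum(rho * shell_volume) == species count`` holds exactly.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    pos = np.asarray(positions, dtype=float)
    if center is None:
        center = _micelle_center(pos, topo)
    center = np.asarray(center, dtype=float)
    r = np.linalg.norm(pos - center, axis=1)
    if r_max is None:
        r_max = float(r.max()) * (1.0 + 1e-9) + 1e-12
    if r_max <= 0:
        raise ValueError("r_max must be > 0")
    edges = np.linspace(0.0, r_max, n_bins + 1)
    volumes = 4.0 / 3.0 * np.pi * np.diff(edges**3)
    type_of = {"A": TYPE_A, "B": TYPE_B, "CI": TYPE_CION}
    density: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    for sp in species:
        mask = topo.bead_type == type_of[sp]
        c, _ = np.histogram(r[mask], bins=edges)
        counts[sp] = c.astype(float)
        density[sp] = counts[sp] / volumes
    return DensityProfile(
        bin_edges=edges, density=density, counts=counts, center=center
    )


def charge_partition(
    positions: np.ndarray,
    topo: "Topology",
    percentile: float = 0.95,
    center: np.ndarray | None = None,
) -> ChargePartition:
    """Single-frame counterion partitioning across the corona boundary."""
    if not topo.is_charged:
        raise ValueError("charge partitioning requires a charged system")
    if not 0.0 < percentile <= 1.0:
        raise ValueError("percentile must be in (0, 1]")
    pos = np.asarray(positions, dtype=float)
    if center is None:
        center = _micelle_center(pos, topo)
    center = np.asarray(center, dtype=float)
    r = np.linalg.norm(pos - center, axis=1)
    r_corona = float(np.quantile(r[topo.is_A], percentile))
    cions = r[topo.is_counterion]
    q_in = float(np.count_nonzero(cions <= r_corona) / cions.shape[0])
    z_net = (1.0 - q_in) * topo.n_counterions
    return ChargePartition(
        Qin=q_in, Znet=z_net, corona_radius=r_corona, percentile=percentile
    )


def average_charge_partition(
    frames: Iterable[np.ndarray],
    topo: "Topology",
    percentile: float = 0.95,
) -> ChargePartition:
    """Time-averaged ``Qin`` over frames; ``Znet`` via the exact identity."""
    qs, radii = [], []
    for pos in frames:
        cp = charge_partition(pos, topo, percentile=percentile)
        qs.append(cp.Qin)
        radii.append(cp.corona_radius)
    if not qs:
        raise ValueError("no frames supplied")
    q_in = float(np.mean(qs))
    return ChargePartition(
        Qin=q_in,
        Znet=(1.0 - q_in) * topo.n_counterions,
        corona_radius=float(np.mean(radii)),
        percentile=percentile,
    )


def fit_scaling(x, y) -> ScalingFit:
    """Least-squares power-law exponent: OLS of ln(y) on ln(x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points for a scaling fit")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("scaling fits require strictly positive data")
    res = stats.linregress(np.log(x), np.log(y))
    return ScalingFit(
        exponent=float(res.slope),
        intercept=float(res.intercept),
        stderr=float(res.stderr) if np.isfinite(res.stderr) else 0.0,
    )
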