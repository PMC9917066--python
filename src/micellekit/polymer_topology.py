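"""Topology builders for linear and linear-dendritic block copolymers.

A copolymer is a linear hydrophobic chain of ``NB`` beads (type B) bonded to
a hydrophilic block of ``NA`` beads (type A).  The hydrophilic block is a
regular dendron described by three parameters: the number of generations
``g``, the branching functionality ``q`` and the spacer length ``Ns`` (beads
per branch segment).  The dendron is a tree of spacers: one root spacer is
bonded to the hydrophobic chain end, and for ``g`` generations the terminal
bead of every spacer spawns ``q`` child spacers.  The total hydrophilic size
is then

    NA = Ns * (q**(g+1) - 1) / (q - 1)        (q > 1)
    NA = Ns * (g + 1)                          (q = 1, linear limit)

``g = 0`` or ``q = 1`` therefore reduce to an ordinary linear diblock.

Bead ordering inside a molecule is deterministic and documented: hydrophobic
chain first, from the free end (index 0) to the junction bead (index NB-1),
then the dendritic block depth-first starting at the root spacer.  Stable
indices let observables slice by block without bookkeeping.

Charged (quenched polyelectrolyte) coronas carry one fixed elementary charge
per A bead; electroneutrality is restored by explicit monovalent counterions
appended after all copolymer beads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import IO

import numpy as np

__all__ = [
    "TYPE_A",
    "TYPE_B",
    "TYPE_CION",
    "TYPE_LABELS",
    "ArchitectureSpec",
    "Topology",
    "dendritic_size",
    "build_copolymer",
    "assemble_system",
    "bond_graph_distances",
    "write_vtf",
]

#: integer bead-type codes used throughout the package
TYPE_A = 0   # hydrophilic (corona) bead
TYPE_B = 1   # hydrophobic (core) bead
TYPE_CION = 2  # counterion

TYPE_LABELS = {TYPE_A: "A", TYPE_B: "B", TYPE_CION: "CI"}


def _check_int(name: str, value, minimum: int) -> int:
    """Reject non-integral or out-of-range architecture parameters."""
    if isinstance(value, bool) or not isinstance(value, (int, np.integer)):
        raise TypeError(f"{name} must be an integer, got {value!r}")
    if value < minimum:
        raise ValueError(f"{name} must be >= {minimum}, got {value}")
    return int(value)


def dendritic_size(g: int, q: int, Ns: int) -> int:
    """Degree of polymerization NA of a regular dendron.

    Parameters
    ----------
    g : int
        Number of generations, ``g >= 0``.
    q : int
        Functionality of the branching points, ``q >= 1``.
    Ns : int
        Number of beads per spacer, ``Ns >= 1``.

    Returns
    -------
    int
        ``Ns * (q**(g+1) - 1) // (q - 1)`` for ``q > 1``; the analytic
        ``q -> 1`` limit ``Ns * (g + 1)`` for ``q = 1`` (a linear block).
    """
    g = _check_int("g", g, 0)
    q = _check_int("q", q, 1)
    Ns = _check_int("Ns", Ns, 1)
    if q == 1:
        return Ns * (g + 1)
    return Ns * (q ** (g + 1) - 1) // (q - 1)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Blueprint of one linear-dendritic block copolymer.

    Attributes
    ----------
    NB : int
        Beads in the linear hydrophobic block (>= 1).
    Ns : int
        Beads per spacer of the hydrophilic dendron (>= 1).
    g : int
        Dendron generations (>= 0); ``g = 0`` is a linear corona block.
    q : int
        Branching functionality (>= 1); ``q = 1`` is a linear corona block.
    charge_A, charge_B : int
        Fixed valence per hydrophilic / hydrophobic bead in elementary
        charges (quenched polyelectrolyte; 0 for neutral blocks).
    """

    NB: int
    Ns: int
    g: int = 0
    q: int = 1
    charge_A: int = 0
    charge_B: int = 0

    def __post_init__(self) -> None:
        _check_int("NB", self.NB, 1)
        _check_int("Ns", self.Ns, 1)
        _check_int("g", self.g, 0)
        _check_int("q", self.q, 1)
        for name in ("charge_A", "charge_B"):
            v = getattr(self, name)
            if isinstance(v, bool) or not isinstance(v, (int, np.integer)):
                raise TypeError(f"{name} must be a signed integer, got {v!r}")

    @property
    def NA(self) -> int:
        """Hydrophilic degree of polymerization from (g, q, Ns)."""
        return dendritic_size(self.g, self.q, self.Ns)

    @property
    def n_beads(self) -> int:
        return self.NA + self.NB

    @property
    def ZA(self) -> int:
        """Total hydrophilic-block charge per molecule."""
        return self.charge_A * self.NA

    @property
    def ZB(self) -> int:
        """Total hydrophobic-block charge per molecule."""
        return self.charge_B * self.NB

    @property
    def is_linear(self) -> bool:
        return self.g == 0 or self.q == 1

    def to_dict(self) -> dict:
        return {
            "NB": self.NB, "Ns": self.Ns, "g": self.g, "q": self.q,
            "charge_A": self.charge_A, "charge_B": self.charge_B,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        return cls(**d)


@dataclass
class Topology:
    """Concrete bead/bond graph for ``p`` copolymers plus counterions.

    Beads of molecule ``m`` occupy the contiguous index range
    ``[m * (NA+NB), (m+1) * (NA+NB))``; counterions follow at the end with
    ``molecule_id = -1``.
    """

    bead_type: np.ndarray      # (N,) int8, values in {TYPE_A, TYPE_B, TYPE_CION}
    bead_charge: np.ndarray    # (N,) int64, elementary charges
    bonds: np.ndarray          # (M, 2) int64, unordered bead-index pairs
    molecule_id: np.ndarray    # (N,) int64, -1 for counterions
    p: int = 1
    arch: ArchitectureSpec | None = None

    @property
    def n_beads(self) -> int:
        return int(self.bead_type.shape[0])

    @property
    def n_bonds(self) -> int:
        return int(self.bonds.shape[0])

    @property
    def is_A(self) -> np.ndarray:
        return self.bead_type == TYPE_A

    @property
    def is_B(self) -> np.ndarray:
        return self.bead_type == TYPE_B

    @property
    def is_counterion(self) -> np.ndarray:
        return self.bead_type == TYPE_CION

    @property
    def n_counterions(self) -> int:
        return int(np.count_nonzero(self.is_counterion))

    @property
    def n_copolymer_beads(self) -> int:
        return self.n_beads - self.n_counterions

    @property
    def total_charge(self) -> int:
        return int(self.bead_charge.sum())

    @property
    def is_charged(self) -> bool:
        return bool(np.any(self.bead_charge != 0))

    def to_dict(self) -> dict:
        """JSON-able structured serialization (lossless round trip)."""
        return {
            "bead_type": self.bead_type.tolist(),
            "bead_charge": self.bead_charge.tolist(),
            "bonds": self.bonds.tolist(),
            "molecule_id": self.molecule_id.tolist(),
            "p": self.p,
            "arch": None if self.arch is None else self.arch.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Topology":
        return cls(
            bead_type=np.asarray(d["bead_type"], dtype=np.int8),
            bead_charge=np.asarray(d["bead_charge"], dtype=np.int64),
            bonds=np.asarray(d["bonds"], dtype=np.int64).reshape(-1, 2),
            molecule_id=np.asarray(d["molecule_id"], dtype=np.int64),
            p=int(d["p"]),
            arch=None if d.get("arch") is None
            else ArchitectureSpec.from_dict(d["arch"]),
        )

    def dumps(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def loads(cls, s: str) -> "Topology":
        return cls.from_dict(json.loads(s))


def build_copolymer(arch: ArchitectureSpec) -> Topology:
    """Build the bead/bond graph of one copolymer molecule.

    Bead ordering: hydrophobic chain from free end (0) to junction
    (NB-1), then the dendron depth-first from the root spacer.  Exactly one
    bond links the junction bead to the first bead of the root spacer.
    """
    NB, Ns, g, q = arch.NB, arch.Ns, arch.g, arch.q
    NA = arch.NA
    n = NA + NB

    bead_type = np.empty(n, dtype=np.int8)
    bead_type[:NB] = TYPE_B
    bead_type[NB:] = TYPE_A

    bead_charge = np.empty(n, dtype=np.int64)
    bead_charge[:NB] = arch.charge_B
    bead_charge[NB:] = arch.charge_A

    bonds: list[tuple[int, int]] = [(i, i + 1) for i in range(NB - 1)]

    # depth-first dendron growth; each frame = (attachment bead, generation)
    next_idx = NB
    stack: list[tuple[int, int]] = [(NB - 1, 0)]
    while stack:
        attach, gen = stack.pop()
        first = next_idx
        bonds.append((attach, first))
        for k in range(1, Ns):
            bonds.append((first + k - 1, first + k))
        next_idx += Ns
        terminal = first + Ns - 1
        if gen < g:
            # children pushed in reverse so lower branch indices come first
            for _ in range(q):
                stack.append((terminal, gen + 1))
    assert next_idx == n, "dendron bead count mismatch"

    return Topology(
        bead_type=bead_type,
        bead_charge=bead_charge,
        bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
        molecule_id=np.zeros(n, dtype=np.int64),
        p=1,
        arch=arch,
    )


def assemble_system(arch: ArchitectureSpec, p: int) -> Topology:
    """Replicate ``p`` copolymers and append neutralizing counterions.

    Counterions are monovalent with valence ``-sign(ZA + ZB)``; their count
    is ``|ZA + ZB| * p`` so the total system charge is exactly zero.
    """
    p = _check_int("p", p, 1)
    frag = build_copolymer(arch)
    n = frag.n_beads

    bead_type = np.tile(frag.bead_type, p)
    bead_charge = np.tile(frag.bead_charge, p)
    bonds = np.concatenate(
        [frag.bonds + m * n for m in range(p)], axis=0
    )
    molecule_id = np.repeat(np.arange(p, dtype=np.int64), n)

    Z = arch.ZA + arch.ZB
    n_cions = abs(Z) * p
    if n_cions:
        cion_valence = -int(np.sign(Z))
        bead_type = np.concatenate(
            [bead_type, np.full(n_cions, TYPE_CION, dtype=np.int8)]
        )
        bead_charge = np.concatenate(
            [bead_charge, np.full(n_cions, cion_valence, dtype=np.int64)]
        )
        molecule_id = np.concatenate(
            [molecule_id, np.full(n_cions, -1, dtype=np.int64)]
        )

    topo = Topology(
        bead_type=bead_type,
        bead_charge=bead_charge,
        bonds=bonds,
        molecule_id=molecule_id,
        p=p,
        arch=arch,
    )
    if topo.total_charge != 0:
        raise ValueError(
            "monovalent counterions cannot neutralize the system: "
            f"residual charge {topo.total_charge}"
        )
    return topo


def bond_graph_distances(topo: Topology, source: int = 0) -> np.ndarray:
    """Graph (bond-count) distance of every bead from ``source``.

    Counterions and beads disconnected from ``source`` get -1.  Used for
    stretched initial conformations, where the spatial distance along the
    contour is the graph distance times the bond length.
    """
    n = topo.n_beads
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in topo.bonds:
        adj[int(i)].append(int(j))
        adj[int(j)].append(int(i))
    dist = np.full(n, -1, dtype=np.int64)
    dist[source] = 0
    queue = [source]
    while queue:
        nxt: list[int] = []
        for u in queue:
            for v in adj[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        queue = nxt
    return dist


def write_vtf(
    topo: Topology,
    fh: IO[str],
    positions: np.ndarray | None = None,
    precision: int = 5,
) -> None:
    """Write a VTF structure block (and optionally one timestep) to ``fh``.

    VTF is the VMD-compatible plain-text trajectory format: ``atom`` lines
    carry type/charge/residue metadata, ``bond`` lines the connectivity.
    """
    radius = {TYPE_A: 0.475, TYPE_B: 0.5, TYPE_CION: 0.5}
    for i in range(topo.n_beads):
        t = int(topo.bead_type[i])
        fh.write(
            f"atom {i} radius {radius[t]} name {TYPE_LABELS[t]} "
            f"charge {int(topo.bead_charge[i])} resid {int(topo.molecule_id[i])}\n"
        )
    for i, j in topo.bonds:
        fh.write(f"bond {int(i)}:{int(j)}\n")
    if positions is not None:
        fh.write("\ntimestep ordered\n")
        fmt = f"%.{precision}f"
        for r in np.asarray(positions, dtype=float):
            fh.write(" ".join(fmt % c for c in r) + "\n")
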