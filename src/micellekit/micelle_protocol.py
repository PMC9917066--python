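"""Single-micelle equilibration protocol and aggregation-number sweep.

Instead of simulating many copolymers in a box and waiting for the
aggregation-number distribution to equilibrate, the protocol prepares *one*
micelle of prescribed aggregation number ``p`` and asks whether it is
stable:

1.  **Stretched radial initialization.**  Each of the ``p`` molecules is
    laid out fully stretched (bond length 0.97 sigma along its contour,
    dendron pointing outward) along a random direction, and shifted
    radially by ``rshift = (2 p r0)**(2/3) * xi`` with ``xi ~ U(0, 1)`` and
    ``r0 = 1.1``.  Hydrophobic blocks always point inward.  Counterions
    (if any) are placed uniformly in the confining sphere.
2.  **Overlap removal** by steepest descent.
3.  **Two-stage relaxation:** Langevin dynamics with the hydrophilic beads
    frozen (core and counterions equilibrate inside the corona scaffold,
    preventing an early artificial split), then an unconstrained warmup.
    Between the two stages the protocol runs a *core-seeding* phase: a
    weak central drift force on the hydrophobic beads only, held until
    their cluster analysis reports a single core (with a step cap).  The
    stretched radial initialization scatters the hydrophobic blocks over
    a region much larger than the attraction range, and unbiased
    coarsening of the resulting sub-clusters is diffusion-limited (orders
    of magnitude beyond a desk-scale budget); the seeding force assembles
    the single micelle that the protocol is designed to interrogate and
    is switched off well before the measurement window, so the production
    dynamics is unbiased.
4.  **Production** with periodic sampling of the energy decomposition,
    cluster count, shape descriptors and (for ionic systems) counterion
    partitioning.

Repeating this over a list of ``p`` and several random realizations yields
the total potential energy per molecule as a function of ``p``; its minimum
defines the equilibrium aggregation number ``p_eq``, cross-checked against
the asphericity minimum.  Realizations whose core splits into several
clusters are flagged and excluded from the per-``p`` means (the split is
the signal that ``p`` exceeds stability, not data about the micelle).

All step counts below are desk-scale defaults chosen so that a full sweep
runs in minutes while the stationarity criterion is satisfied; they are
ordinary configuration knobs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from . import observables as obs
from .force_field import BondBreakError, ForceFieldParams
from .md_engine import (
    IntegratorParams,
    SystemState,
    maxwell_boltzmann_velocities,
    run_md,
    steepest_descent,
)
from .polymer_topology import (
    ArchitectureSpec,
    Topology,
    assemble_system,
    bond_graph_distances,
    build_copolymer,
)

__all__ = [
    "ProtocolError",
    "InitParams",
    "ProtocolParams",
    "ClusterResult",
    "RealizationResult",
    "SweepResult",
    "init_micelle",
    "relax_two_stage",
    "detect_clusters",
    "run_realization",
    "sweep_p",
]


class ProtocolError(RuntimeError):
    """Unrecoverable protocol failure (minimization, all-split p, ...)."""


@dataclass(frozen=True)
class InitParams:
    """Stretched-initialization parameters: shift scale ``r0`` and ``p``."""

    p: int
    r0: float = 1.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if self.r0 <= 0:
            raise ValueError("r0 must be > 0")


@dataclass(frozen=True)
class ProtocolParams:
    """Knobs of the single-micelle protocol (desk-scale defaults)."""

    r0: float = 1.1                  # initial-shift length scale
    conf_factor: float = 6.0         # R_conf = conf_factor * (2 p r0)^(2/3)
    init_bond_len: float = 0.97      # stretched-conformation bond length
    init_jitter: float = 0.01        # symmetry-breaking jitter at init
    sd_max_steps: int = 2000
    sd_force_tol: float = 10.0
    sd_max_disp: float = 0.01
    stage1_steps: int = 500          # core relaxation, corona frozen
    seed_bias_k: float = 0.15        # core-seeding central drift (0 = off)
    seed_min_steps: int = 1500
    seed_max_steps: int = 8000       # cap; unassembled realizations flagged
    seed_check_every: int = 500
    seed_consolidate_steps: int = 1000  # extra biased steps once connected
    stage2_steps: int = 2500         # unconstrained warmup after release
    prod_steps: int = 5000
    sample_stride: int = 50
    window_frac: float = 0.5         # stationary window = trailing fraction
    n_blocks: int = 5                # block count for stationarity check
    aspher_threshold: float = 0.1    # anisotropic-growth flag
    corona_percentile: float = 0.95  # Qin boundary definition
    cluster_cutoff: float | None = None  # default: attraction range
    detached_threshold: float = 2.0  # mean detached molecules => split

    def with_(self, **kwargs) -> "ProtocolParams":
        return replace(self, **kwargs)

    def confinement_radius(self, p: int) -> float:
        return self.conf_factor * (2.0 * p * self.r0) ** (2.0 / 3.0)


@dataclass
class ClusterResult:
    """Single-linkage clustering of the hydrophobic beads."""

    n_clusters: int
    bead_labels: np.ndarray       # per B bead, cluster id
    molecule_labels: np.ndarray   # per molecule (majority of its B beads)

    @property
    def largest_cluster(self) -> int:
        return int(np.argmax(np.bincount(self.bead_labels)))

    def molecules_in_largest(self) -> np.ndarray:
        return np.flatnonzero(self.molecule_labels == self.largest_cluster)


@dataclass
class RealizationResult:
    """One protocol realization at fixed ``p``."""

    p: int
    seed: int
    times: np.ndarray
    energy_per_molecule_trace: np.ndarray
    asphericity_trace: np.ndarray
    n_clusters_trace: np.ndarray
    final_state: SystemState
    split_flag: bool
    aniso_flag: bool
    stationary: bool
    observables_block: dict[str, float]
    charge: obs.ChargePartition | None = None


@dataclass
class SweepResult:
    """Per-``p`` statistics of a sweep and the detected ``p_eq``."""

    p_values: np.ndarray
    mean_energy_per_molecule: np.ndarray
    se_energy_per_molecule: np.ndarray
    mean_asphericity: np.ndarray
    se_asphericity: np.ndarray
    n_split: np.ndarray
    n_used: np.ndarray
    p_eq: int
    p_eq_asphericity: int
    boundary_warning: bool
    asphericity_disagrees: bool
    realizations: list = field(default_factory=list, repr=False)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "p": self.p_values,
                "e_per_mol": self.mean_energy_per_molecule,
                "e_se": self.se_energy_per_molecule,
                "asphericity": self.mean_asphericity,
                "asphericity_se": self.se_asphericity,
                "n_split": self.n_split,
                "n_used": self.n_used,
            }
        )
        df["is_p_eq"] = df["p"] == self.p_eq
        return df


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def init_micelle(
    topo: Topology,
    init: InitParams,
    rng: np.random.Generator,
    R_conf: float | None = None,
    bond_len: float = 0.97,
    jitter: float = 0.01,
) -> SystemState:
    """Stretched radial initial configuration for ``p`` molecules.

    Bead positions along a random unit vector ``u`` per molecule:
    ``(rshift + bond_len * (l_k - l_mid)) * u`` where ``l_k`` is the graph
    distance of bead ``k`` from the hydrophobic free end and ``l_mid`` that
    of the middle bead of the hydrophobic chain (the pivot of the random
    orientation).  ``rshift = (2 p r0)**(2/3) * xi``, ``xi ~ U(0,1)``.  A
    small isotropic jitter breaks the exact overlap of sibling dendron
    branches; overlaps are removed by the subsequent minimization, not
    here.  Counterions are distributed uniformly in the confining sphere.
    """
    if topo.arch is None:
        raise ValueError("topology must carry its ArchitectureSpec")
    arch = topo.arch
    p = topo.p
    n_mol_beads = arch.n_beads

    frag = build_copolymer(arch)
    contour = bond_graph_distances(frag, source=0).astype(float)
    l_mid = contour[arch.NB // 2]

    shift_scale = (2.0 * p * init.r0) ** (2.0 / 3.0)
    pos = np.empty((topo.n_beads, 3))
    for m in range(p):
        u = _random_unit_vector(rng)
        rshift = shift_scale * rng.uniform()
        coords = rshift + bond_len * (contour - l_mid)
        block = coords[:, None] * u[None, :]
        block += jitter * rng.uniform(-1.0, 1.0, size=block.shape)
        pos[m * n_mol_beads : (m + 1) * n_mol_beads] = block

    n_cions = topo.n_counterions
    if n_cions:
        radius = R_conf if R_conf is not None else shift_scale + bond_len * (
            contour.max() + 1.0
        )
        pos[topo.n_copolymer_beads :] = _uniform_in_sphere(
            n_cions, radius, rng
        )

    return SystemState(positions=pos, R_conf=R_conf)


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - essentially impossible
        v = rng.standard_normal(3)
        n = np.linalg.norm(v)
    return v / n


def _uniform_in_sphere(
    n: int, radius: float, rng: np.random.Generator
) -> np.ndarray:
    u = np.stack([_random_unit_vector(rng) for _ in range(n)])
    r = radius * rng.uniform(size=n) ** (1.0 / 3.0)
    return u * r[:, None]


# ---------------------------------------------------------------------------
# relaxation and clustering
# ---------------------------------------------------------------------------

def relax_two_stage(
    state: SystemState,
    topo: Topology,
    ff: ForceFieldParams,
    ip: IntegratorParams,
    stage1_steps: int,
    stage2_steps: int,
    rng: np.random.Generator | None = None,
    proto: ProtocolParams | None = None,
) -> SystemState:
    """Overlap removal plus the two-stage relaxation.

    Steepest descent, then Langevin dynamics with the hydrophilic beads
    frozen in space (hydrophobic beads and counterions relax), then the
    core-seeding phase (when ``proto.seed_bias_k > 0``), then an
    unconstrained warmup.  Returns the state at the start of the
    stationary window.  Aborts with :class:`ProtocolError` if the
    minimization leaves diverging overlaps.
    """
    proto = proto or ProtocolParams()
    if rng is None:
        rng = np.random.default_rng(ip.seed)
    state, info = steepest_descent(
        state, topo, ff,
        max_steps=proto.sd_max_steps,
        force_tol=proto.sd_force_tol,
        max_displacement=proto.sd_max_disp,
    )
    # dense initial packings may exhaust the step budget with residual
    # large forces; one more pass with a finer displacement cap keeps the
    # first thermal kick from snapping a bond
    if info["max_force"] > 1e3:
        state, info = steepest_descent(
            state, topo, ff,
            max_steps=proto.sd_max_steps,
            force_tol=proto.sd_force_tol,
            max_displacement=0.5 * proto.sd_max_disp,
        )
    # the descent must at least have removed diverging overlaps, even if
    # the force tolerance was not reached within the step budget
    if not np.isfinite(info["potential"]):
        raise ProtocolError(
            f"steepest descent failed to remove overlaps: {info}"
        )
    state.velocities = maxwell_boltzmann_velocities(
        state.n_beads, ip.kBT, rng
    )
    frozen = topo.is_A.copy()
    if frozen.any() and not frozen.all():
        # brief reduced-step ramp: lets any remaining tight contacts
        # unload before the full time step is applied
        for factor, steps in ((0.05, 300), (0.2, 300)):
            state, _ = run_md(
                state, topo, ff, ip.with_(dt=factor * ip.dt), steps,
                frozen_mask=frozen, rng=rng, sample_stride=0,
            )
        state, _ = run_md(
            state, topo, ff, ip, stage1_steps,
            frozen_mask=frozen, rng=rng, sample_stride=0,
        )
    if proto.seed_bias_k > 0.0:
        _seed_single_core(state, topo, ff, ip, rng, proto)
    state, _ = run_md(
        state, topo, ff, ip, stage2_steps, rng=rng, sample_stride=0
    )
    return state


def _seed_single_core(
    state: SystemState,
    topo: Topology,
    ff: ForceFieldParams,
    ip: IntegratorParams,
    rng: np.random.Generator,
    proto: ProtocolParams,
) -> int:
    """Core-seeding: weak central drift on B beads until one core forms.

    Runs in chunks of ``seed_check_every`` steps and stops as soon as the
    hydrophobic beads form a single cluster (after ``seed_min_steps``),
    or at ``seed_max_steps``.  Returns the steps spent.  The drift force
    ``-k r`` acts on hydrophobic beads only, leaving corona and
    counterion statistics untouched, and is removed before the warmup.
    """
    is_b = topo.is_B
    k = proto.seed_bias_k

    def bias(pos: np.ndarray) -> np.ndarray:
        f = np.zeros_like(pos)
        f[is_b] = -k * pos[is_b]
        return f

    cutoff = proto.cluster_cutoff or ff.attraction_range
    steps = 0
    while steps < proto.seed_max_steps:
        state_, _ = run_md(
            state, topo, ff, ip, proto.seed_check_every,
            rng=rng, extra_force=bias,
        )
        steps += proto.seed_check_every
        if steps >= proto.seed_min_steps:
            n = detect_clusters(
                state.positions, topo, cutoff=cutoff
            ).n_clusters
            if n == 1:
                break
    # connectivity is not compactness: hold the drift a little longer so
    # a freshly merged, string-like core can consolidate into a globule
    if proto.seed_consolidate_steps > 0:
        state_, _ = run_md(
            state, topo, ff, ip, proto.seed_consolidate_steps,
            rng=rng, extra_force=bias,
        )
        steps += proto.seed_consolidate_steps
    return steps


def detect_clusters(
    positions: np.ndarray,
    topo: Topology,
    cutoff: float | None = None,
    ff: ForceFieldParams | None = None,
) -> ClusterResult:
    """Single-linkage connected components of the hydrophobic beads.

    Two B beads are connected when closer than ``cutoff`` (default: the
    attraction range ``rc_BB + wc`` of ``ff``, or of the default force
    field if none is given).  Each molecule is assigned to the cluster
    holding the majority of its B beads.
    """
    if cutoff is None:
        cutoff = (ff or ForceFieldParams()).attraction_range
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    pos = np.asarray(positions, dtype=float)
    b_idx = np.flatnonzero(topo.is_B)
    nb = b_idx.size
    if nb == 0:
        raise ValueError("topology has no hydrophobic beads")
    tree = cKDTree(pos[b_idx])
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    adj = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(nb, nb)
    )
    n_clusters, labels = sparse.csgraph.connected_components(
        adj, directed=False
    )
    mol_of_b = topo.molecule_id[b_idx]
    n_mol = topo.p
    mol_labels = np.empty(n_mol, dtype=np.int64)
    for m in range(n_mol):
        lab = labels[mol_of_b == m]
        mol_labels[m] = np.bincount(lab).argmax() if lab.size else -1
    return ClusterResult(
        n_clusters=int(n_clusters),
        bead_labels=labels,
        molecule_labels=mol_labels,
    )


# ---------------------------------------------------------------------------
# realization and sweep
# ---------------------------------------------------------------------------

def _block_stationary(trace: np.ndarray, n_blocks: int) -> bool:
    """First vs last block means within 2 combined standard errors."""
    if trace.size < 2 * n_blocks:
        return False
    blocks = np.array_split(trace, n_blocks)
    first, last = blocks[0], blocks[-1]
    se = math.sqrt(
        np.var(first, ddof=1) / first.size + np.var(last, ddof=1) / last.size
    )
    if se == 0.0:
        return bool(np.isclose(first.mean(), last.mean()))
    return bool(abs(first.mean() - last.mean()) < 2.0 * se)


def run_realization(
    arch: ArchitectureSpec,
    p: int,
    seed: int,
    ff: ForceFieldParams | None = None,
    ip: IntegratorParams | None = None,
    proto: ProtocolParams | None = None,
) -> RealizationResult:
    """Assemble, initialize, relax and run one micelle realization.

    Deterministic for a fixed seed.  The stationary window is the trailing
    ``window_frac`` of production frames; within it the realization is
    flagged as split when the core forms more than one cluster in at least
    half of the frames, and as anisotropic when the mean asphericity
    exceeds the threshold.  Flagged realizations are retained, never
    dropped here.
    """
    ff = ff or ForceFieldParams()
    ip = (ip or IntegratorParams()).with_(seed=seed)
    proto = proto or ProtocolParams()

    topo = assemble_system(arch, p)
    R_conf = proto.confinement_radius(p)
    # a dense random initialization occasionally snaps a bond during the
    # early relaxation; such attempts are discarded and re-drawn (the
    # production stage is never retried)
    last_exc: Exception | None = None
    for attempt in range(3):
        attempt_seed = (seed + attempt * 0x9E3779B9) & 0x7FFFFFFF
        rng = np.random.default_rng(attempt_seed)
        state = init_micelle(
            topo,
            InitParams(p=p, r0=proto.r0, seed=attempt_seed),
            rng,
            R_conf=R_conf,
            bond_len=proto.init_bond_len,
            jitter=proto.init_jitter,
        )
        try:
            state = relax_two_stage(
                state, topo, ff, ip,
                proto.stage1_steps, proto.stage2_steps,
                rng=rng, proto=proto,
            )
            break
        except BondBreakError as exc:
            last_exc = exc
    else:
        raise ProtocolError(
            f"relaxation failed in 3 attempts at p={p}: {last_exc}"
        )
    state, traj = run_md(
        state, topo, ff, ip, proto.prod_steps,
        rng=rng, sample_stride=proto.sample_stride,
    )

    times = np.asarray(traj.times)
    e_per_mol = np.array(
        [t["potential"] / p for t in traj.energies]
    )
    cutoff = proto.cluster_cutoff or ff.attraction_range
    n_clusters = np.empty(len(traj), dtype=np.int64)
    n_detached = np.empty(len(traj), dtype=np.int64)
    aspher = np.empty(len(traj))
    rg_mic = np.empty(len(traj))
    rg_core = np.empty(len(traj))
    for k, pos in enumerate(traj.positions):
        cl = detect_clusters(pos, topo, cutoff=cutoff)
        n_clusters[k] = cl.n_clusters
        in_largest = cl.molecules_in_largest()
        n_detached[k] = p - in_largest.size
        desc = obs.micelle_descriptors(pos, topo, molecules=in_largest)
        aspher[k] = desc["asphericity"]
        rg_mic[k] = desc["Rg_micelle"]
        rg_core[k] = desc["Rg_core"]

    w0 = int(len(traj) * (1.0 - proto.window_frac))
    win = slice(w0, len(traj))
    # split = genuine multi-molecule breakup; transient single-molecule
    # evaporation near equilibrium is normal and not a split
    split_flag = bool(
        np.mean(n_detached[win]) >= proto.detached_threshold
    )
    aniso_flag = bool(np.mean(aspher[win]) > proto.aspher_threshold)
    stationary = _block_stationary(e_per_mol[win], proto.n_blocks)

    def _mean_se(x: np.ndarray) -> tuple[float, float]:
        return float(np.mean(x)), float(
            np.std(x, ddof=1) / math.sqrt(len(x)) if len(x) > 1 else 0.0
        )

    e_mean, e_se = _mean_se(e_per_mol[win])
    a_mean, a_se = _mean_se(aspher[win])
    observables_block = {
        "energy_per_molecule": e_mean,
        "energy_per_molecule_se": e_se,
        "asphericity": a_mean,
        "asphericity_se": a_se,
        "Rg_micelle": float(np.mean(rg_mic[win])),
        "Rg_core": float(np.mean(rg_core[win])),
        "n_clusters": float(np.mean(n_clusters[win])),
        "n_detached": float(np.mean(n_detached[win])),
    }

    charge = None
    if topo.is_charged:
        charge = obs.average_charge_partition(
            traj.positions[w0:], topo, percentile=proto.corona_percentile
        )

    return RealizationResult(
        p=p,
        seed=seed,
        times=times,
        energy_per_molecule_trace=e_per_mol,
        asphericity_trace=aspher,
        n_clusters_trace=n_clusters,
        final_state=state,
        split_flag=split_flag,
        aniso_flag=aniso_flag,
        stationary=stationary,
        observables_block=observables_block,
        charge=charge,
    )


def realization_seed(master_seed: int, p: int, index: int) -> int:
    """Documented counter scheme: independent, reproducible realization
    seeds derived from (master seed, p, realization index)."""
    ss = np.random.SeedSequence([int(master_seed), int(p), int(index)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def sweep_p(
    arch: ArchitectureSpec,
    p_list: Sequence[int],
    n_realizations: int,
    seed: int = 0,
    ff: ForceFieldParams | None = None,
    ip: IntegratorParams | None = None,
    proto: ProtocolParams | None = None,
    on_all_split: str = "raise",
) -> SweepResult:
    """Sweep the aggregation number and locate ``p_eq``.

    For every ``p`` the per-realization stationary-window means are
    averaged over non-split realizations; ``p_eq`` is the argmin of the
    mean energy per molecule.  When a neighboring smaller ``p`` lies
    within one combined standard error of the minimum, the smaller ``p``
    is preferred (cheaper, safely spherical).  A minimum at the end of the
    grid raises a boundary warning; a disagreement of more than one grid
    step with the asphericity minimum raises a cross-check warning.

    ``on_all_split`` controls what happens when every realization at some
    ``p`` splits: ``'raise'`` (default) or ``'drop'`` (that ``p`` is
    excluded from the argmin; recorded in ``n_used``).
    """
    if len(p_list) == 0:
        raise ValueError("p_list must be nonempty")
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    if on_all_split not in ("raise", "drop"):
        raise ValueError("on_all_split must be 'raise' or 'drop'")

    p_values = np.asarray(sorted(int(p) for p in p_list))
    all_results: list[list[RealizationResult]] = []
    for p in p_values:
        runs = [
            run_realization(
                arch, int(p), realization_seed(seed, int(p), r),
                ff=ff, ip=ip, proto=proto,
            )
            for r in range(n_realizations)
        ]
        all_results.append(runs)
        if all(r.split_flag for r in runs) and on_all_split == "raise":
            raise ProtocolError(
                f"all {n_realizations} realizations at p={p} split into "
                "multiple clusters; p is beyond the stable range"
            )

    mean_e = np.full(len(p_values), np.nan)
    se_e = np.zeros(len(p_values))
    mean_a = np.full(len(p_values), np.nan)
    se_a = np.zeros(len(p_values))
    n_split = np.zeros(len(p_values), dtype=np.int64)
    n_used = np.zeros(len(p_values), dtype=np.int64)
    for k, runs in enumerate(all_results):
        n_split[k] = sum(r.split_flag for r in runs)
        kept = [r for r in runs if not r.split_flag]
        n_used[k] = len(kept)
        if not kept:
            continue
        es = np.array([r.observables_block["energy_per_molecule"] for r in kept])
        as_ = np.array([r.observables_block["asphericity"] for r in kept])
        mean_e[k] = es.mean()
        mean_a[k] = as_.mean()
        if len(kept) > 1:
            se_e[k] = es.std(ddof=1) / math.sqrt(len(kept))
            se_a[k] = as_.std(ddof=1) / math.sqrt(len(kept))
        else:
            se_e[k] = kept[0].observables_block["energy_per_molecule_se"]
            se_a[k] = kept[0].observables_block["asphericity_se"]

    valid = np.flatnonzero(n_used > 0)
    if valid.size == 0:
        raise ProtocolError("no p in the sweep retained any realization")
    m = valid[np.nanargmin(mean_e[valid])]
    # tie-break toward the smaller p when the neighbor is within 1 SE
    while m > 0 and n_used[m - 1] > 0:
        combined = math.sqrt(se_e[m - 1] ** 2 + se_e[m] ** 2)
        if mean_e[m - 1] - mean_e[m] < combined:
            m = m - 1
        else:
            break
    p_eq = int(p_values[m])

    a_idx = valid[np.nanargmin(mean_a[valid])]
    p_eq_aspher = int(p_values[a_idx])
    grid = int(np.max(np.diff(p_values))) if len(p_values) > 1 else 0
    aspher_disagrees = abs(p_eq_aspher - p_eq) > grid
    boundary = m == len(p_values) - 1
    if boundary:
        warnings.warn(
            f"energy minimum at the sweep boundary p={p_eq}; "
            "extend p_list to bracket the true minimum",
            stacklevel=2,
        )
    if aspher_disagrees:
        warnings.warn(
            f"asphericity minimum (p={p_eq_aspher}) disagrees with the "
            f"energy minimum (p={p_eq}) by more than one grid step",
            stacklevel=2,
        )

    return SweepResult(
        p_values=p_values,
        mean_energy_per_molecule=mean_e,
        se_energy_per_molecule=se_e,
        mean_asphericity=mean_a,
        se_asphericity=se_a,
        n_split=n_split,
        n_used=n_used,
        p_eq=p_eq,
        p_eq_asphericity=p_eq_aspher,
        boundary_warning=bool(boundary),
        asphericity_disagrees=bool(aspher_disagrees),
        realizations=all_results,
    )
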