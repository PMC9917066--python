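"""Configuration files, fixtures, and result serialization.

Run configuration is a YAML file with five sections (``architecture``,
``force_field``, ``integrator``, ``protocol``, ``output``) plus a top-level
``seed``.  Every parameter has the model default, so an empty file is a
valid configuration; unknown keys are rejected with a list of offenders.
All I/O is in reduced units (sigma, epsilon, kBT); ``PHYSICAL_MAPPING``
records the optional correspondence to water at room temperature
(lambda_B = 0.71 nm => sigma = 0.355 nm) but is never applied silently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Any

import numpy as np
import yaml

from .force_field import WCA_CUT_FACTOR, ForceFieldParams
from .md_engine import IntegratorParams, SystemState
from .micelle_protocol import (
    InitParams,
    ProtocolParams,
    SweepResult,
    init_micelle,
)
from .observables import ChargePartition
from .polymer_topology import (
    TYPE_B,
    TYPE_LABELS,
    ArchitectureSpec,
    Topology,
    assemble_system,
)

__all__ = [
    "ConfigError",
    "OutputParams",
    "RunConfig",
    "PHYSICAL_MAPPING",
    "load_config",
    "save_config",
    "config_hash",
    "make_fixture",
    "FIXTURE_NAMES",
    "write_results",
    "write_xyz",
]

#: reduced-unit to physical-unit correspondence (metadata only)
PHYSICAL_MAPPING = {"lambda_B_nm": 0.71, "sigma_nm": 0.355}


class ConfigError(ValueError):
    """Schema violation; the message lists every offending key."""


@dataclass(frozen=True)
class OutputParams:
    out_dir: str = "results"
    trajectory_stride: int = 0       # 0 = no trajectory output
    trajectory_format: str = "xyz"   # or "vtf"
    float_precision: int = 6


@dataclass
class RunConfig:
    """Validated bundle of every knob a sweep needs."""

    architecture: ArchitectureSpec = field(
        default_factory=lambda: ArchitectureSpec(NB=5, Ns=25)
    )
    force_field: ForceFieldParams = field(default_factory=ForceFieldParams)
    integrator: IntegratorParams = field(default_factory=IntegratorParams)
    protocol: ProtocolParams = field(default_factory=ProtocolParams)
    output: OutputParams = field(default_factory=OutputParams)
    p_list: list[int] = field(default_factory=lambda: [10, 15, 20, 25, 30])
    n_realizations: int = 3
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "architecture": self.architecture.to_dict(),
            "force_field": self.force_field.to_dict(),
            "integrator": dataclasses.asdict(self.integrator),
            "protocol": dataclasses.asdict(self.protocol),
            "output": dataclasses.asdict(self.output),
            "p_list": list(self.p_list),
            "n_realizations": self.n_realizations,
            "seed": self.seed,
        }


_SECTIONS = {
    "architecture": ArchitectureSpec,
    "force_field": ForceFieldParams,
    "integrator": IntegratorParams,
    "protocol": ProtocolParams,
    "output": OutputParams,
}
_TOP_LEVEL = {"p_list", "n_realizations", "seed"}


def _build_section(cls, data: dict, section: str, errors: list[str]):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    for k in sorted(unknown):
        errors.append(f"{section}.{k}: unknown key")
    kwargs = {k: v for k, v in data.items() if k in valid}
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"{section}: {exc}")
        return None


def parse_config(data: dict | None) -> RunConfig:
    data = dict(data or {})
    errors: list[str] = []
    kwargs: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        section = data.pop(name, None) or {}
        if not isinstance(section, dict):
            errors.append(f"{name}: must be a mapping")
            section = {}
        if not section:
            continue  # absent/empty section: RunConfig defaults apply
        built = _build_section(cls, section, name, errors)
        if built is not None:
            kwargs[name] = built
    for name in _TOP_LEVEL & set(data):
        kwargs[name] = data.pop(name)
    for k in sorted(data):
        errors.append(f"{k}: unknown key")
    if errors:
        raise ConfigError(
            "invalid configuration:\n  " + "\n  ".join(errors)
        )
    cfg = RunConfig(**kwargs)
    if cfg.n_realizations < 1:
        raise ConfigError("n_realizations: must be >= 1")
    if not cfg.p_list or any(int(p) < 1 for p in cfg.p_list):
        raise ConfigError("p_list: must be a nonempty list of p >= 1")
    cfg.p_list = [int(p) for p in cfg.p_list]
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration (defaults applied)."""
    path = Path(path)
    with path.open() as fh:
        data = yaml.safe_load(fh)
    if data is not None and not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return parse_config(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    """Stable sha256 of the canonical configuration (for run logs)."""
    canon = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


# ---------------------------------------------------------------------------
# deterministic fixtures shared across tests and examples
# ---------------------------------------------------------------------------

def _bare_beads(n: int, bead_type: int = TYPE_B) -> Topology:
    return Topology(
        bead_type=np.full(n, bead_type, dtype=np.int8),
        bead_charge=np.zeros(n, dtype=np.int64),
        bonds=np.empty((0, 2), dtype=np.int64),
        molecule_id=np.arange(n, dtype=np.int64),
        p=n,
    )


def _compact_chain(n: int, center: np.ndarray) -> np.ndarray:
    # dense zigzag with ~0.97 bond lengths and < 2 sigma extent
    pos = np.zeros((n, 3))
    for k in range(1, n):
        pos[k] = pos[k - 1]
        pos[k, k % 3] += 0.97 * (1 if (k // 3) % 2 == 0 else -1)
    return pos - pos.mean(axis=0) + center


def _fixture_bb_pair():
    topo = _bare_beads(2)
    pos = np.array([[0.0, 0.0, 0.0], [WCA_CUT_FACTOR, 0.0, 0.0]])
    return topo, SystemState(positions=pos)

def _fixture_octet():
    topo = _bare_beads(8)
    corners = np.array(
        [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
        dtype=float,
    )
    return topo, SystemState(positions=corners)

def _fixture_split_micelle():
    arch = ArchitectureSpec(NB=4, Ns=1)
    topo = assemble_system(arch, 2)
    pos = np.vstack(
        [
            _compact_chain(5, np.zeros(3)),
            _compact_chain(5, np.array([10.0, 0.0, 0.0])),
        ]
    )
    return topo, SystemState(positions=pos)

def _fixture_half_shell():
    arch = ArchitectureSpec(NB=1, Ns=21, charge_A=1)
    topo = assemble_system(arch, 10)  # 210 counterions
    rng = np.random.default_rng(1234)
    pos = np.empty((topo.n_beads, 3))
    n_mol = arch.n_beads
    for m in range(10):
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        # B bead near the center, A beads spread to radius 4
        radii = np.concatenate([[0.2], np.linspace(0.9, 4.0, arch.NA)])
        pos[m * n_mol : (m + 1) * n_mol] = radii[:, None] * u[None, :]
    cions = pos[topo.n_copolymer_beads:]
    for k in range(210):
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        cions[k] = (3.0 if k < 105 else 50.0) * u
    return topo, SystemState(positions=pos, R_conf=60.0)

def _fixture_neutral_reference():
    arch = ArchitectureSpec(NB=5, Ns=25)
    p = 20
    proto = ProtocolParams()
    topo = assemble_system(arch, p)
    state = init_micelle(
        topo,
        InitParams(p=p, r0=proto.r0),
        np.random.default_rng(0),
        R_conf=proto.confinement_radius(p),
    )
    return topo, state


_FIXTURES = {
    "bb_pair_at_cutoff": _fixture_bb_pair,
    "unit_cube_octet": _fixture_octet,
    "split_micelle": _fixture_split_micelle,
    "half_shell_counterions": _fixture_half_shell,
    "neutral_reference": _fixture_neutral_reference,
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def make_fixture(name: str) -> tuple[Topology, SystemState]:
    """Deterministic small systems used across tests and examples."""
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    return builder()


# ---------------------------------------------------------------------------
# result serialization
# ---------------------------------------------------------------------------

def write_xyz(
    fh: IO[str],
    positions: np.ndarray,
    topo: Topology,
    comment: str = "",
    precision: int = 5,
) -> None:
    pos = np.asarray(positions, dtype=float)
    fh.write(f"{pos.shape[0]}\n{comment}\n")
    fmt = f"%.{precision}f"
    for i, r in enumerate(pos):
        label = TYPE_LABELS[int(topo.bead_type[i])]
        fh.write(label + " " + " ".join(fmt % c for c in r) + "\n")


def _sweep_to_csv(result: SweepResult, path: Path, precision: int) -> None:
    # fixed column order and float precision: byte-stable summaries
    df = result.to_frame()
    df.to_csv(path, index=False, float_format=f"%.{precision}f")


def _charge_to_json(cp: ChargePartition, path: Path) -> None:
    path.write_text(
        json.dumps(
            {
                "Qin": round(cp.Qin, 9),
                "Znet": round(cp.Znet, 9),
                "corona_radius": round(cp.corona_radius, 9),
                "percentile": cp.percentile,
            },
            indent=2,
        )
        + "\n"
    )


def write_results(results, path: str | Path, precision: int = 6) -> Path:
    """Serialize a result object by type: CSV for sweep tables, JSON for
    nested records.  Returns the written path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(results, SweepResult):
        _sweep_to_csv(results, path, precision)
    elif isinstance(results, ChargePartition):
        _charge_to_json(results, path)
    elif isinstance(results, dict):
        path.write_text(json.dumps(results, indent=2, default=_json_default) + "\n")
    else:
        raise TypeError(f"cannot serialize {type(results).__name__}")
    return path


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON-serializable: {type(obj).__name__}")


def realization_record(res) -> dict:
    """JSON-able summary of one realization (no trajectory payload)."""
    rec = {
        "p": res.p,
        "seed": res.seed,
        "split_flag": res.split_flag,
        "aniso_flag": res.aniso_flag,
        "stationary": res.stationary,
        "observables": res.observables_block,
        "energy_per_molecule_trace": res.energy_per_molecule_trace.tolist(),
        "asphericity_trace": res.asphericity_trace.tolist(),
        "n_clusters_trace": res.n_clusters_trace.tolist(),
    }
    if res.charge is not None:
        rec["charge"] = {
            "Qin": res.charge.Qin,
            "Znet": res.charge.Znet,
            "corona_radius": res.charge.corona_radius,
            "percentile": res.charge.percentile,
        }
    return rec


def write_run_metadata(out_dir: str | Path, cfg: RunConfig) -> Path:
    """Record seed, config hash and package version next to the results."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "seed": cfg.seed,
        "config_sha256": config_hash(cfg),
        "micellekit_version": __version__,
        "physical_mapping": PHYSICAL_MAPPING,
    }
    path = out / "run_metadata.json"
    path.write_text(json.dumps(meta, indent=2) + "\n")
    return path
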