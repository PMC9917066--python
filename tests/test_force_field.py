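"""Pair potentials, forces, and electrostatics cross-checks."""

import math

import numpy as np
import pytest

from micellekit.force_field import (
    WCA_CUT_FACTOR,
    BondBreakError,
    ForceFieldParams,
    attractive_energy,
    compute_forces_energies,
    coulomb_energy,
    direct_coulomb_energy,
    ewald_coulomb_energy,
    fene_energy,
    wca_energy,
)
from micellekit.md_engine import SystemState
from micellekit.polymer_topology import (
    ArchitectureSpec,
    Topology,
    assemble_system,
)

from conftest import random_bonded_system


# ---------------------------------------------------------------------------
# independent brute-force oracle (pure numpy, no shared code with the kernel)
# ---------------------------------------------------------------------------

def brute_force_potential(pos, topo, ff: ForceFieldParams, R_conf=None):
    sig = ff.sigma_matrix()
    total = {"wca": 0.0, "attractive": 0.0, "coulomb": 0.0, "fene": 0.0,
             "wall": 0.0}
    n = len(pos)
    for i in range(n):
        for j in range(i + 1, n):
            r = float(np.linalg.norm(pos[i] - pos[j]))
            s = sig[topo.bead_type[i], topo.bead_type[j]]
            total["wca"] += wca_energy(r, s, ff.epsilon)
            if topo.bead_type[i] == 1 and topo.bead_type[j] == 1:
                total["attractive"] += attractive_energy(
                    r, ff.eps_attr, ff.wc, ff.rc_BB
                )
            q1, q2 = topo.bead_charge[i], topo.bead_charge[j]
            if q1 and q2:
                total["coulomb"] += coulomb_energy(
                    r, q1, q2, ff.lambda_B, ff.kBT
                )
    for i, j in topo.bonds:
        r = float(np.linalg.norm(pos[i] - pos[j]))
        total["fene"] += fene_energy(r, ff.kbond, ff.r_inf)
    if R_conf is not None:
        d = np.linalg.norm(pos, axis=1)
        out = np.clip(d - R_conf, 0.0, None)
        total["wall"] = float(0.5 * ff.wall_k * np.sum(out**2))
    total["potential"] = sum(total.values())
    return total


class TestScalarPotentials:
    def test_wca_vanishes_at_cutoff_and_beyond(self):
        assert wca_energy(WCA_CUT_FACTOR, 1.0) == 0.0
        assert wca_energy(2.0, 1.0) == 0.0

    def test_wca_at_sigma_equals_epsilon(self):
        assert wca_energy(1.0, 1.0, 1.0) == pytest.approx(1.0, abs=1e-14)

    def test_wca_continuity_at_cutoff(self):
        for eps in np.linspace(-1e-7, 1e-7, 21):
            assert abs(wca_energy(WCA_CUT_FACTOR + eps, 1.0)) < 1e-5

    def test_wca_rejects_nonpositive_r(self):
        with pytest.raises(ValueError):
            wca_energy(0.0, 1.0)

    def test_fene_zero_at_origin_and_printed_value(self):
        assert fene_energy(0.0) == 0.0
        # closed form -33.75 ln(5/9) at r=1, k=30, r_inf=1.5
        assert fene_energy(1.0, 30.0, 1.5) == pytest.approx(
            -33.75 * math.log(5.0 / 9.0), abs=1e-12
        )
        assert fene_energy(1.0, 30.0, 1.5) == pytest.approx(19.84, abs=1e-2)

    def test_fene_monotone_and_divergent(self):
        rs = np.linspace(0.01, 1.49, 200)
        es = [fene_energy(r) for r in rs]
        assert np.all(np.diff(es) > 0)
        with pytest.raises(BondBreakError):
            fene_energy(1.5)
        with pytest.raises(BondBreakError):
            fene_energy(2.0)

    def test_attraction_plateau_midpoint_and_edge(self):
        eps_attr, wc = 0.8, 1.6
        rc = WCA_CUT_FACTOR
        assert attractive_energy(0.5, eps_attr, wc, rc) == -eps_attr
        assert attractive_energy(rc + wc / 2, eps_attr, wc, rc) == (
            pytest.approx(-eps_attr / 2, abs=1e-12)
        )
        assert attractive_energy(rc + wc, eps_attr, wc, rc) == (
            pytest.approx(0.0, abs=1e-12)
        )
        assert attractive_energy(rc + wc + 0.1, eps_attr, wc, rc) == 0.0

    def test_attraction_continuity_at_both_edges(self):
        eps_attr, wc, rc = 1.0, 1.6, WCA_CUT_FACTOR
        for r0 in (rc, rc + wc):
            vals = [
                attractive_energy(r0 + d, eps_attr, wc, rc)
                for d in np.linspace(-1e-7, 1e-7, 11)
            ]
            assert max(vals) - min(vals) < 1e-6

    def test_coulomb_bjerrum_definition(self):
        lb = 2.0
        assert coulomb_energy(lb, 1, 1, lb) == pytest.approx(1.0)
        assert coulomb_energy(lb, 1, -1, lb) == pytest.approx(-1.0)
        assert coulomb_energy(2 * lb, 1, 1, lb) == pytest.approx(0.5)

    def test_bb_combined_potential_minimum_is_minus_eps_attr(self):
        # repulsive core + flat well of depth eps_attr (the model's B-B law)
        eps_attr, wc, rc = 1.3, 1.6, WCA_CUT_FACTOR
        rs = np.append(np.linspace(0.85, rc + wc + 0.5, 4000), rc)
        v = np.array(
            [
                wca_energy(r, 1.0) + attractive_energy(r, eps_attr, wc, rc)
                for r in rs
            ]
        )
        assert v.min() == pytest.approx(-eps_attr, abs=1e-9)
        assert np.all(v >= -eps_attr - 1e-9)
        # the well floor is attained on the plateau, not in the core
        assert rs[np.argmin(v)] >= rc - 1e-6


class TestParams:
    def test_pair_cutoffs_scale_with_pair_sigma(self):
        ff = ForceFieldParams()
        rc = ff.rc_matrix()
        assert rc[0, 0] == pytest.approx(WCA_CUT_FACTOR * 0.95)
        assert rc[0, 1] == pytest.approx(WCA_CUT_FACTOR * 0.95)
        assert rc[1, 1] == pytest.approx(WCA_CUT_FACTOR)
        assert rc[2, 2] == pytest.approx(WCA_CUT_FACTOR)
        assert rc[0, 2] == pytest.approx(WCA_CUT_FACTOR)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ForceFieldParams(wc=-1.0)
        with pytest.raises(ValueError):
            ForceFieldParams(sigma_BB=0.0)


class TestSystemEnergies:
    def test_bb_pair_at_cutoff_plateau(self, ff_default):
        from micellekit.interface_io import make_fixture

        topo, state = make_fixture("bb_pair_at_cutoff")
        _, terms = compute_forces_energies(state.positions, topo, ff_default)
        assert terms["wca"] == pytest.approx(0.0, abs=1e-12)
        assert terms["attractive"] == pytest.approx(-ff_default.eps_attr)

    def test_neutral_molecule_has_zero_coulomb(self, ff_default):
        topo, pos = random_bonded_system(
            n_molecules=1, arch=ArchitectureSpec(NB=3, Ns=4), seed=3
        )
        _, terms = compute_forces_energies(pos, topo, ff_default)
        assert terms["coulomb"] == 0.0
        assert math.isfinite(terms["potential"])

    def test_matches_brute_force_oracle(self, ff_default):
        topo, pos = random_bonded_system(n_molecules=2, seed=11)
        _, terms = compute_forces_energies(
            pos, topo, ff_default, R_conf=12.0
        )
        ref = brute_force_potential(pos, topo, ff_default, R_conf=12.0)
        for key in ("wca", "fene", "attractive", "coulomb", "wall",
                    "potential"):
            assert terms[key] == pytest.approx(
                ref[key], rel=1e-10, abs=1e-10
            ), key

    def test_bond_break_is_fatal_with_diagnostic(self, ff_default):
        arch = ArchitectureSpec(NB=2, Ns=1)
        topo = assemble_system(arch, 1)
        pos = np.array([[0.0, 0, 0], [1.6, 0, 0], [2.5, 0, 0]])
        with pytest.raises(BondBreakError, match="r_inf"):
            compute_forces_energies(pos, topo, ff_default)


class TestForces:
    def test_isolated_bead_feels_nothing(self, ff_default):
        topo = assemble_system(ArchitectureSpec(NB=1, Ns=1), 1)
        pos = np.array([[0.0, 0, 0], [0.97, 0, 0]])
        f, _ = compute_forces_energies(pos, topo, ff_default)
        # far third bead: zero force
        topo2 = Topology(
            bead_type=np.array([1], dtype=np.int8),
            bead_charge=np.zeros(1, dtype=np.int64),
            bonds=np.empty((0, 2), dtype=np.int64),
            molecule_id=np.zeros(1, dtype=np.int64),
        )
        f2, _ = compute_forces_energies(np.zeros((1, 3)), topo2, ff_default)
        assert np.all(f2 == 0.0)

    def test_plateau_edge_exerts_no_force(self, ff_default):
        # at the WCA cutoff both the core repulsion and the flat well are
        # forceless: the B-B pair sits on the well floor
        from micellekit.interface_io import make_fixture

        topo, state = make_fixture("bb_pair_at_cutoff")
        f, _ = compute_forces_energies(state.positions, topo, ff_default)
        assert np.allclose(f, 0.0, atol=1e-10)

    def test_newtons_third_law(self, ff_default):
        from micellekit.md_engine import SystemState, steepest_descent

        topo, pos = random_bonded_system(n_molecules=3, seed=5)
        state, _ = steepest_descent(
            SystemState(positions=pos), topo, ff_default, max_steps=500,
            force_tol=30.0,
        )
        f, _ = compute_forces_energies(state.positions, topo, ff_default)
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-10)

    @pytest.mark.parametrize(
        "ff_kwargs, charged",
        [
            (dict(eps_attr=0.0), False),                 # WCA + FENE only
            (dict(eps_attr=1.3, wc=1.6), False),         # + attraction
            (dict(eps_attr=1.0, wc=1.6), True),          # + Coulomb
        ],
    )
    def test_forces_match_finite_differences(self, ff_kwargs, charged):
        arch = (
            ArchitectureSpec(NB=3, Ns=3, g=1, q=2, charge_A=1)
            if charged
            else ArchitectureSpec(NB=3, Ns=3, g=1, q=2)
        )
        topo, pos = random_bonded_system(n_molecules=3, arch=arch, seed=17)
        ff = ForceFieldParams(**ff_kwargs)
        # remove deep core overlaps first: the 12th-power core makes the
        # central difference truncation error blow past the tolerance there
        from micellekit.md_engine import SystemState, steepest_descent

        state, _ = steepest_descent(
            SystemState(positions=pos), topo, ff, max_steps=500,
            force_tol=30.0,
        )
        pos = state.positions
        f, _ = compute_forces_energies(pos, topo, ff, R_conf=15.0)
        h = 1e-6
        rng = np.random.default_rng(0)
        beads = rng.choice(topo.n_beads, size=12, replace=False)
        for i in beads:
            for k in range(3):
                pp = pos.copy()
                pp[i, k] += h
                ep = brute_force_potential(pp, topo, ff, 15.0)["potential"]
                pm = pos.copy()
                pm[i, k] -= h
                em = brute_force_potential(pm, topo, ff, 15.0)["potential"]
                fd = -(ep - em) / (2 * h)
                scale = max(1.0, abs(fd))
                assert abs(f[i, k] - fd) / scale < 1e-5


class TestElectrostaticsCrossCheck:
    @staticmethod
    def _zero_dipole_cluster(seed=3, n=10):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-1.5, 1.5, size=(n, 3))
        q = np.array([1.0, -1.0] * (n // 2))
        return np.vstack([pts, -pts]), np.concatenate([q, q])

    def test_ewald_agrees_with_direct_sum(self):
        pos, q = self._zero_dipole_cluster()
        e_direct = direct_coulomb_energy(pos, q)
        e_ewald = ewald_coulomb_energy(pos, q, box_L=35.0)
        assert e_ewald == pytest.approx(e_direct, rel=1e-4)

    def test_ewald_is_alpha_independent(self):
        pos, q = self._zero_dipole_cluster(seed=9)
        L = 30.0
        e1 = ewald_coulomb_energy(pos, q, L, alpha=6.0 / L)
        e2 = ewald_coulomb_energy(pos, q, L, alpha=8.0 / L, k_max=12)
        assert e1 == pytest.approx(e2, rel=1e-6)

    def test_kernel_coulomb_matches_direct_sum(self, ff_default):
        topo, pos = random_bonded_system(n_molecules=2, seed=21)
        _, terms = compute_forces_energies(pos, topo, ff_default)
        ref = direct_coulomb_energy(
            pos, topo.bead_charge, ff_default.lambda_B, ff_default.kBT
        )
        assert terms["coulomb"] == pytest.approx(ref, rel=1e-12)
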