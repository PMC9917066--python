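"""Initialization geometry, clustering, sweep statistics and p_eq logic."""

import numpy as np
import pytest

import micellekit.micelle_protocol as mp
from micellekit.force_field import ForceFieldParams
from micellekit.md_engine import IntegratorParams
from micellekit.micelle_protocol import (
    InitParams,
    ProtocolParams,
    RealizationResult,
    _block_stationary,
    detect_clusters,
    init_micelle,
    realization_seed,
    sweep_p,
)
from micellekit.polymer_topology import ArchitectureSpec, assemble_system


class TestInitMicelle:
    @staticmethod
    def _init(p=20, seed=0, arch=None, **kwargs):
        arch = arch or ArchitectureSpec(NB=5, Ns=25)
        topo = assemble_system(arch, p)
        rng = np.random.default_rng(seed)
        state = init_micelle(topo, InitParams(p=p), rng, **kwargs)
        return arch, topo, state

    def test_shift_bound_is_respected(self):
        # the middle hydrophobic bead of every molecule lies within the
        # initialization sphere (2 p r0)^(2/3), up to the jitter amplitude
        p = 20
        bound = (2 * p * 1.1) ** (2 / 3)
        assert bound == pytest.approx(12.46, abs=0.01)
        for seed in range(5):
            arch, topo, state = self._init(p=p, seed=seed)
            n = arch.n_beads
            mid = arch.NB // 2
            radii = [
                np.linalg.norm(state.positions[m * n + mid])
                for m in range(p)
            ]
            assert max(radii) <= bound + 0.05

    def test_shifts_actually_spread(self):
        arch, topo, state = self._init(p=30, seed=1)
        n = arch.n_beads
        mid = arch.NB // 2
        radii = [np.linalg.norm(state.positions[m * n + mid])
                 for m in range(30)]
        assert max(radii) > 6.0  # xi ~ U(0,1): large shifts do occur

    def test_hydrophobic_blocks_point_inward(self):
        for seed in range(4):
            arch, topo, state = self._init(p=15, seed=seed)
            n = arch.n_beads
            for m in range(15):
                block = state.positions[m * n:(m + 1) * n]
                center_b = block[: arch.NB].mean(axis=0)
                center_a = block[arch.NB:].mean(axis=0)
                assert np.linalg.norm(center_b) < np.linalg.norm(center_a)

    def test_stretched_contour_bond_lengths(self):
        arch, topo, state = self._init(p=3, seed=2)
        i, j = topo.bonds.T
        lengths = np.linalg.norm(
            state.positions[i] - state.positions[j], axis=1
        )
        assert np.all(np.abs(lengths - 0.97) < 0.05)

    def test_counterions_fill_the_confining_sphere(self):
        arch = ArchitectureSpec(NB=5, Ns=10, charge_A=1)
        _, topo, state = self._init(p=10, seed=3, arch=arch, R_conf=30.0)
        cions = state.positions[topo.is_counterion]
        r = np.linalg.norm(cions, axis=1)
        assert r.max() <= 30.0
        assert r.max() > 15.0  # uniform in the sphere, not clustered

    def test_same_seed_same_layout(self):
        a = self._init(p=8, seed=9)[2].positions
        b = self._init(p=8, seed=9)[2].positions
        assert np.array_equal(a, b)


class TestDetectClusters:
    def test_two_blobs_and_majority_assignment(self):
        from micellekit.interface_io import make_fixture

        topo, state = make_fixture("split_micelle")
        res = detect_clusters(state.positions, topo)
        assert res.n_clusters == 2
        assert sorted(np.bincount(res.molecule_labels)) == [1, 1]

    def test_single_blob(self):
        from micellekit.interface_io import make_fixture

        topo, state = make_fixture("split_micelle")
        pos = state.positions.copy()
        pos[5:] -= np.array([10.0, 0.0, 0.0])  # merge the blobs
        assert detect_clusters(pos, topo).n_clusters == 1

    def test_escaped_molecule_forms_its_own_cluster(self):
        arch = ArchitectureSpec(NB=4, Ns=1)
        p = 6
        topo = assemble_system(arch, p)
        ff = ForceFieldParams()
        rng = np.random.default_rng(0)
        n = arch.n_beads
        pos = np.empty((topo.n_beads, 3))
        for m in range(p):
            pos[m * n:(m + 1) * n] = (
                rng.normal(0, 0.4, (n, 3))  # compact blob at the origin
            )
        # move the last molecule far beyond the attraction range
        pos[(p - 1) * n:] += 5.0 * ff.attraction_range
        res = detect_clusters(pos, topo, ff=ff)
        assert res.n_clusters == 2
        sizes = np.bincount(res.molecule_labels)
        assert sorted(sizes) == [1, p - 1]
        assert res.molecules_in_largest().size == p - 1

    def test_cutoff_validation(self):
        from micellekit.interface_io import make_fixture

        topo, state = make_fixture("split_micelle")
        with pytest.raises(ValueError):
            detect_clusters(state.positions, topo, cutoff=0.0)


class TestStationarity:
    def test_flat_noise_is_stationary(self):
        rng = np.random.default_rng(0)
        assert _block_stationary(rng.normal(0, 1, 200), 5)

    def test_strong_trend_is_not(self):
        rng = np.random.default_rng(0)
        trace = np.linspace(0, 10, 200) + rng.normal(0, 0.5, 200)
        assert not _block_stationary(trace, 5)

    def test_tiny_traces_are_not_stationary(self):
        assert not _block_stationary(np.ones(5), 5)


class TestRealizationSeeds:
    def test_deterministic_and_distinct(self):
        s1 = realization_seed(7, 20, 0)
        assert s1 == realization_seed(7, 20, 0)
        others = {
            realization_seed(7, 20, 1),
            realization_seed(7, 25, 0),
            realization_seed(8, 20, 0),
        }
        assert s1 not in others
        assert 0 <= s1 < 2**31


def _fake_result(p, seed, energy, aspher=0.05, split=False):
    return RealizationResult(
        p=p,
        seed=seed,
        times=np.arange(4.0),
        energy_per_molecule_trace=np.full(4, energy),
        asphericity_trace=np.full(4, aspher),
        n_clusters_trace=np.ones(4, dtype=np.int64),
        final_state=None,
        split_flag=split,
        aniso_flag=False,
        stationary=True,
        observables_block={
            "energy_per_molecule": energy,
            "energy_per_molecule_se": 0.05,
            "asphericity": aspher,
            "asphericity_se": 0.005,
            "Rg_micelle": 5.0,
            "Rg_core": 2.0,
            "n_clusters": 1.0,
            "n_detached": 0.0,
        },
    )


class TestSweepLogic:
    """Sweep statistics exercised with injected synthetic realizations."""

    arch = ArchitectureSpec(NB=5, Ns=25)

    def _patch(self, monkeypatch, energy_of, aspher_of=None, split_of=None):
        def fake_run(arch, p, seed, ff=None, ip=None, proto=None):
            rng = np.random.default_rng(seed)
            e = energy_of(p) + rng.normal(0, 0.01)
            a = aspher_of(p) if aspher_of else 0.05
            s = split_of(p) if split_of else False
            return _fake_result(p, seed, e, aspher=a, split=s)

        monkeypatch.setattr(mp, "run_realization", fake_run)

    def test_interior_minimum_is_found(self, monkeypatch):
        self._patch(
            monkeypatch,
            energy_of=lambda p: 0.05 * (p - 25) ** 2 - 10.0,
            aspher_of=lambda p: 0.01 + 1e-4 * (p - 25) ** 2,
        )
        res = sweep_p(self.arch, [10, 15, 20, 25, 30, 35, 40], 3, seed=1)
        assert res.p_eq == 25
        assert res.p_eq_asphericity == 25
        assert not res.boundary_warning
        assert not res.asphericity_disagrees

    def test_monotone_curve_warns_at_boundary(self, monkeypatch):
        self._patch(monkeypatch, energy_of=lambda p: -0.5 * p)
        with pytest.warns(UserWarning, match="boundary"):
            res = sweep_p(self.arch, [10, 20, 30], 2, seed=1)
        assert res.p_eq == 30
        assert res.boundary_warning

    def test_near_tie_prefers_smaller_p(self, monkeypatch):
        # neighbor within one combined SE of the minimum: choose smaller p
        energies = {10: -9.98, 20: -10.0, 30: -8.0}
        self._patch(monkeypatch, energy_of=lambda p: energies[p])
        # single realization: the within-run SE (0.05) sets the tie scale
        res = sweep_p(self.arch, [10, 20, 30], 1, seed=2)
        assert res.p_eq == 10

    def test_split_realizations_are_excluded_but_counted(self, monkeypatch):
        self._patch(
            monkeypatch,
            energy_of=lambda p: 0.05 * (p - 20) ** 2 - 10.0,
            split_of=lambda p: p == 30,
        )
        with pytest.raises(mp.ProtocolError, match="split"):
            sweep_p(self.arch, [10, 20, 30], 2, seed=3)
        res = sweep_p(
            self.arch, [10, 20, 30], 2, seed=3, on_all_split="drop"
        )
        assert res.p_eq == 20
        assert res.n_split[-1] == 2
        assert res.n_used[-1] == 0

    def test_asphericity_cross_check_warns_on_disagreement(self, monkeypatch):
        self._patch(
            monkeypatch,
            energy_of=lambda p: 0.05 * (p - 20) ** 2 - 10.0,
            aspher_of=lambda p: 0.2 - 0.004 * p,  # argmin at the far end
        )
        with pytest.warns(UserWarning, match="asphericity"):
            res = sweep_p(self.arch, [10, 15, 20, 25, 30, 35, 40], 2, seed=4)
        assert res.asphericity_disagrees

    def test_input_validation(self):
        with pytest.raises(ValueError):
            sweep_p(self.arch, [], 3)
        with pytest.raises(ValueError):
            sweep_p(self.arch, [10], 0)
        with pytest.raises(ValueError):
            sweep_p(self.arch, [10], 1, on_all_split="ignore")
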