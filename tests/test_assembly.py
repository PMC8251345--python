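"""Ring assembly, superposition and self-avoiding tail growth."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from torusfit import assembly
from torusfit.assembly import (
    BeadChain,
    BeadModel,
    RigidTransform,
    TailSpec,
    build_partial_ring,
    grow_tails,
    infer_adjacent_transform,
    kabsch_superpose,
    ring_layout,
    ring_metrics,
)
from torusfit.errors import (
    DegenerateGeometryError,
    GrowthFailureError,
    InvalidArgumentError,
    ShapeMismatchError,
)


def random_rotation(seed):
    rng = np.random.default_rng(seed)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    return RigidTransform.about_axis(axis, rng.uniform(0.1, 3.0),
                                     point=rng.normal(size=3))


class TestKabsch:
    def test_identity(self):
        A = np.random.default_rng(0).normal(size=(10, 3))
        t, rmsd = kabsch_superpose(A, A)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(t.translation, 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_recovers_known_rotation(self, seed):
        A = np.random.default_rng(seed).normal(size=(20, 3))
        truth = random_rotation(seed + 100)
        t, rmsd = kabsch_superpose(A, truth.apply(A))
        assert rmsd < 1e-9
        assert np.allclose(t.rotation, truth.rotation, atol=1e-9)
        assert np.allclose(t.translation, truth.translation, atol=1e-8)

    def test_mirror_image_keeps_proper_rotation(self):
        A = np.random.default_rng(5).normal(size=(15, 3))
        B = A * np.array([-1.0, 1.0, 1.0])  # reflection
        t, rmsd = kabsch_superpose(A, B)
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)
        with pytest.raises(ShapeMismatchError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestRigidTransform:
    def test_rejects_improper_rotation(self):
        with pytest.raises(InvalidArgumentError):
            RigidTransform(np.diag([-1.0, 1.0, 1.0]), np.zeros(3))
        with pytest.raises(InvalidArgumentError):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))

    def test_angle_of_axis_rotation(self):
        t = RigidTransform.about_axis((0, 0, 1), np.radians(45.0))
        assert t.angle_deg == pytest.approx(45.0, abs=1e-9)


class TestRingBuilding:
    def test_closed_ring_transform_is_45_degrees(self, ring16):
        t = infer_adjacent_transform(ring16)
        assert t.angle_deg == pytest.approx(45.0, abs=0.1)

    def test_transform_power_eight_is_identity(self, ring16):
        t = infer_adjacent_transform(ring16)
        closure = t.power(8)
        ref = ring16.dimers[0].coords
        gap = np.sqrt(np.mean(np.sum((closure.apply(ref) - ref) ** 2, axis=1)))
        assert gap < 1e-3

    def test_construct_then_recover_round_trip(self, dimer):
        truth = random_rotation(42)
        ring = build_partial_ring(dimer, truth, 4)
        rec = infer_adjacent_transform(ring)
        assert np.allclose(rec.rotation, truth.rotation, atol=1e-6)
        assert np.allclose(rec.translation, truth.translation, atol=1e-6)

    @pytest.mark.parametrize("k", [1, 2, 5, 6, 8])
    def test_bead_counts_and_no_duplicates(self, dimer, k):
        ring = ring_layout(dimer, k)
        assert ring.k == k
        assert ring.n_chains == 2 * k
        coords = ring.coords
        assert coords.shape[0] == k * dimer.n_beads
        d = cdist(coords, coords)
        np.fill_diagonal(d, np.inf)
        assert d.min() > 1e-6  # no coordinate duplicated

    def test_closed_flag_only_at_eight(self, dimer):
        assert ring_layout(dimer, 8).closed
        assert not ring_layout(dimer, 6).closed

    def test_k_out_of_range(self, dimer):
        t = RigidTransform.identity()
        with pytest.raises(InvalidArgumentError):
            build_partial_ring(dimer, t, 0)
        with pytest.raises(InvalidArgumentError):
            build_partial_ring(dimer, t, 9)

    def test_adjacent_dimers_respect_clearance(self, ring16):
        a = ring16.dimers[0].coords
        b = ring16.dimers[1].coords
        assert cdist(a, b).min() >= 4.0 - 1e-6

    def test_all_seam_geometries_identical_in_closed_ring(self, ring16):
        """Every inter-dimer contact of the torus is the same interface."""
        spectra = []
        for i in range(8):
            a = ring16.dimers[i].coords
            b = ring16.dimers[(i + 1) % 8].coords
            spectra.append(np.sort(cdist(a, b), axis=None))
        for s in spectra[1:]:
            assert np.allclose(s, spectra[0], atol=1e-6)


class TestRingMetrics:
    def test_cylinder_closed_form(self):
        # beads on a circle of radius 20 -> hole = 2*(20 - r_bead) = 36
        ang = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        chains = []
        for j in range(3):
            coords = np.column_stack([
                20 * np.cos(ang[j::3]), 20 * np.sin(ang[j::3]),
                np.zeros(8),
            ])
            chains.append(BeadChain(f"C{j}", np.arange(1, 9), coords))
        model = assembly.OligomerModel(
            dimers=[BeadModel([chains[j]]) for j in range(3)], k=3,
            closed=True, ring_axis=(np.zeros(3), np.array([0.0, 0.0, 1.0])))
        m = ring_metrics(model, bead_radius=2.0)
        assert m["hole_diameter"] == pytest.approx(36.0, abs=1e-9)
        assert m["outer_diameter"] == pytest.approx(44.0, abs=1e-9)

    def test_hole_never_exceeds_outer(self, ring16):
        m = ring_metrics(ring16, bead_radius=1.9)
        assert 0.0 <= m["hole_diameter"] <= m["outer_diameter"]

    def test_degenerate_ring(self, dimer):
        ring = ring_layout(dimer, 2)
        with pytest.raises(DegenerateGeometryError):
            ring_metrics(ring)


class TestTailGrowth:
    def test_zero_length_gives_identical_copies(self, ring12):
        ens = grow_tails(ring12, TailSpec(tail_length=0), 4, seed=9)
        for conf in ens.conformers:
            assert np.array_equal(conf, ring12.coords)

    def test_reproducible_for_fixed_seed(self, ring12):
        spec = TailSpec(tail_length=15)
        a = grow_tails(ring12, spec, 3, seed=5)
        b = grow_tails(ring12, spec, 3, seed=5)
        for ca, cb in zip(a.conformers, b.conformers):
            assert np.array_equal(ca, cb)
        c = grow_tails(ring12, spec, 3, seed=6)
        assert not np.array_equal(a.conformers[0], c.conformers[0])

    def test_core_is_bit_identical_across_conformers(self, ring12):
        ens = grow_tails(ring12, TailSpec(tail_length=20), 5, seed=2)
        n_core = ring12.coords.shape[0]
        for conf in ens.conformers:
            assert np.array_equal(conf[:n_core], ring12.coords)

    def test_bond_lengths_exact(self, ring12):
        spec = TailSpec(tail_length=12)
        ens = grow_tails(ring12, spec, 2, seed=3)
        n_core = ring12.coords.shape[0]
        L = spec.tail_length
        chains = ring12.chains
        for conf in ens.conformers:
            tails = conf[n_core:]
            for j, chain in enumerate(chains):
                tail = tails[j * L:(j + 1) * L]
                full = np.vstack([chain.coords[-1], tail])
                bonds = np.linalg.norm(np.diff(full, axis=0), axis=1)
                assert np.allclose(bonds, spec.bond_length, atol=1e-6)

    def test_no_nonbonded_pair_below_cutoff(self, ring12):
        """Exhaustive O(N^2) verification of the self-avoidance contract."""
        spec = TailSpec(tail_length=30)
        ens = grow_tails(ring12, spec, 2, seed=11)
        n_core = ring12.coords.shape[0]
        L = spec.tail_length
        n_per = len(ring12.chains[0])
        for conf in ens.conformers:
            d = cdist(conf, conf)
            np.fill_diagonal(d, np.inf)
            # mask bonded pairs: consecutive core, consecutive tail, anchor
            for off in range(0, n_core, n_per):
                for i in range(n_per - 1):
                    d[off + i, off + i + 1] = d[off + i + 1, off + i] = np.inf
            for j in range(len(ring12.chains)):
                base = n_core + j * L
                for i in range(L - 1):
                    d[base + i, base + i + 1] = np.inf
                    d[base + i + 1, base + i] = np.inf
                anchor = (j + 1) * n_per - 1
                d[anchor, base] = d[base, anchor] = np.inf
            assert d.min() >= spec.clash_cutoff - 1e-9

    def test_self_avoiding_walks_swell_superlinearly(self):
        """Mean squared end-to-end distance grows faster than ideal-chain
        linear scaling and is monotone in tail length."""
        msd = {}
        for L in (10, 20, 30):
            spec = TailSpec(tail_length=L)
            walks = assembly.grow_isolated_tail(spec, seed=123,
                                                n_conformers=200)
            e2e = [np.sum((w[-1] - w[0]) ** 2) for w in walks]
            msd[L] = np.mean(e2e)
        assert msd[10] < msd[20] < msd[30]
        # super-linear: normalized by L, still increasing
        assert msd[20] / 20 > msd[10] / 10
        assert msd[30] / 30 > msd[20] / 20

    def test_growth_failure_names_chain_and_conformer(self, dimer):
        ring = ring_layout(dimer, 2)
        impossible = TailSpec(tail_length=5, clash_cutoff=10.0,
                              max_attempts=10, step_attempts=5)
        with pytest.raises(GrowthFailureError) as err:
            grow_tails(ring, impossible, 1, seed=0)
        assert err.value.conformer == 0
        assert err.value.chain_id


class TestBeadContainers:
    def test_chain_invariants(self):
        with pytest.raises(InvalidArgumentError):
            BeadChain("A", [1, 1], np.zeros((2, 3)))  # non-increasing index
        with pytest.raises(InvalidArgumentError):
            BeadChain("A", [1, 2, 3], np.zeros((2, 3)))  # count mismatch
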