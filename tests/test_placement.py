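"""Pose generation, complex minimization, and center scanning."""

import warnings

import numpy as np
import pytest

from pepadsorb.centers import AdsorptionCenter, ChargeWindow, CenterScanConfig, find_local_centers
from pepadsorb.energy import ClassicalModel, ClassicalParams
from pepadsorb.placement import (
    OptimizationSettings,
    PlacementError,
    apply_pose,
    binding_energy,
    dock_panel,
    generate_poses,
    minimize_complex,
    minimize_structures,
    scan_centers,
)
from pepadsorb.structures import Atom, InputError, Structure, min_intermolecular_distance
from pepadsorb.synthetic import SyntheticHostSpec, make_analyte, make_host

from conftest import random_structure


@pytest.fixture(scope="module")
def host_and_centers():
    host, wells = make_host(SyntheticHostSpec(n_wells=2, seed=7))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        centers = find_local_centers(host)
    return host, centers, wells


@pytest.fixture(scope="module")
def acetone():
    return make_analyte("acetone")


class TestGeneratePoses:
    def test_deterministic_for_fixed_seed(self, host_and_centers, acetone):
        host, centers, _ = host_and_centers
        p1 = generate_poses(centers[0], acetone, host, n_orientations=1, seed=9)
        p2 = generate_poses(centers[0], acetone, host, n_orientations=1, seed=9)
        np.testing.assert_array_equal(p1[0].rotation, p2[0].rotation)

    def test_different_seeds_differ(self, host_and_centers, acetone):
        host, centers, _ = host_and_centers
        p1 = generate_poses(centers[0], acetone, host, n_orientations=4, seed=1)
        p2 = generate_poses(centers[0], acetone, host, n_orientations=4, seed=2)
        assert not np.allclose(p1[0].rotation, p2[0].rotation)

    def test_no_pose_clashes(self, host_and_centers, acetone):
        host, centers, _ = host_and_centers
        for center in centers:
            for pose in generate_poses(center, acetone, host, n_orientations=12, seed=3):
                placed = apply_pose(pose, center, acetone)
                d, _ = min_intermolecular_distance(host, placed)
                assert d >= 0.8

    def test_all_clashing_raises(self, acetone):
        # a dense host shell all around the center leaves no room at 3 Å
        shell = [Atom("C", p, -0.02) for p in 3.0 * np.random.default_rng(0).normal(size=(300, 3))]
        host = Structure(shell, name="shell")
        center = AdsorptionCenter("a", -0.5, member_atoms=(0,), centroid=np.zeros(3))
        with pytest.raises(PlacementError):
            generate_poses(center, acetone, host, n_orientations=5, seed=0)


class TestMinimize:
    def test_start_at_minimum_stays(self, rng):
        s = random_structure(rng, 6, name="s")
        model = ClassicalModel([s])  # reference geometry = network minimum
        (out,), e, conv = minimize_structures([s], model)
        assert conv
        assert e == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(out.positions, s.positions, atol=1e-9)

    def test_single_spring_reaches_analytic_minimum(self):
        ref = Structure(
            [Atom("C", [0, 0, 0], 0.0), Atom("C", [1.5, 0, 0], 0.0)], name="spring"
        )
        params = ClassicalParams(spring_constant=2.0, network_cutoff=3.0)
        model = ClassicalModel([ref], params)
        stretched = ref.with_positions([[0, 0, 0], [2.4, 0, 0]])
        (out,), e, conv = minimize_structures(
            [stretched], model, OptimizationSettings(tolerance=1e-10)
        )
        assert conv
        d = np.linalg.norm(out.positions[1] - out.positions[0])
        assert d == pytest.approx(1.5, abs=1e-6)

    def test_monotone_descent_from_random_starts(self, host_and_centers, acetone):
        """Final energy never exceeds the initial energy (seeded starts)."""
        host, centers, _ = host_and_centers
        model = ClassicalModel([host, acetone])
        for seed in range(10):
            poses = generate_poses(centers[0], acetone, host, n_orientations=4, seed=seed)
            placed = apply_pose(poses[0], centers[0], acetone)
            e0 = model.evaluate([host, placed])
            _, _, e1, _ = minimize_complex(host, placed, model)
            assert e1 <= e0 + 1e-12


class TestBindingEnergy:
    def test_arithmetic(self):
        assert binding_energy(-10.0, -6.0, -3.0) == pytest.approx(-1.0)

    def test_separation_limit_zero(self, rng):
        a = random_structure(rng, 8, name="a")
        a = a.with_charges(a.charges - a.charges.mean())
        b = random_structure(rng, 5, name="b")
        b = b.with_charges(b.charges - b.charges.mean())
        b_far = b.with_positions(b.positions + 200.0)
        model = ClassicalModel([a, b_far])
        e_bind = binding_energy(
            model.evaluate([a, b_far]), model.evaluate([a]), model.evaluate([b_far])
        )
        assert abs(e_bind) < 1e-6

    def test_reference_energy_triple(self):
        """The stored CIHNP/acetone center-e energy triple differences to the
        published −0.71 eV binding energy."""
        from pepadsorb.synthetic import reference_table

        t = reference_table("synthetic_cihnp_acetone_e_energies").set_index("quantity")
        e = t["energy_ev"]
        assert binding_energy(e["e_complex"], e["e_host"], e["e_analyte"]) == pytest.approx(-0.71)


class TestScanAndPanel:
    def test_single_center_is_most_active(self, host_and_centers, acetone):
        host, centers, _ = host_and_centers
        model = ClassicalModel([host, acetone])
        report = scan_centers(host, acetone, centers[:1], model, seed=0, n_orientations=4)
        assert report.most_active == centers[0].label

    def test_scan_deterministic(self, host_and_centers, acetone):
        host, centers, _ = host_and_centers
        model = ClassicalModel([host, acetone])
        r1 = scan_centers(host, acetone, centers, model, seed=5, n_orientations=4)
        r2 = scan_centers(host, acetone, centers, model, seed=5, n_orientations=4)
        assert r1.most_active == r2.most_active
        for a, b in zip(r1.results, r2.results):
            assert a.e_bind == b.e_bind  # bit-identical

    def test_converged_binding_energies_nonpositive(self, host_and_centers, acetone):
        host, centers, _ = host_and_centers
        model = ClassicalModel([host, acetone])
        report = scan_centers(host, acetone, centers, model, seed=1, n_orientations=6)
        for r in report.results:
            if r.converged and not r.failed:
                assert r.e_bind <= 1e-9

    def test_panel_of_one_matches_scan(self, host_and_centers, acetone):
        host, centers, _ = host_and_centers
        model = ClassicalModel([host, acetone])
        scan = scan_centers(host, acetone, centers[:1], model, seed=3, n_orientations=4)
        panel = dock_panel(host, [acetone], centers[0], model, seed=3,
                           n_orientations=4, attach_metrics=False)
        assert panel[0].e_bind == pytest.approx(scan.results[0].e_bind, abs=1e-12)

    def test_empty_panel_rejected(self, host_and_centers):
        host, centers, _ = host_and_centers
        model = ClassicalModel([host])
        with pytest.raises(InputError):
            dock_panel(host, [], centers[0], model)

    def test_panel_attaches_metrics(self, host_and_centers, acetone):
        host, centers, _ = host_and_centers
        model = ClassicalModel([host, acetone])
        (res,) = dock_panel(host, [acetone], centers[0], model, seed=2, n_orientations=4)
        assert res.metrics is not None
        assert "delta_v_A3" in res.metrics
        assert res.metrics["min_distance_A"] > 0
        assert res.metrics["charge_transfer_e"] == 0.0  # classical: no polarization


def test_well_depth_monotonically_deepens_binding():
    """At fixed geometry, making the well charge more negative lowers the
    interaction energy with a polar analyte (5-point charge ladder)."""
    host, wells = make_host(SyntheticHostSpec(n_wells=1, well_sizes=(1,), seed=3))
    acetone = make_analyte("acetone")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        centers = find_local_centers(host)
    model = ClassicalModel([host, acetone])
    poses = generate_poses(centers[0], acetone, host, n_orientations=4, seed=0)
    placed = apply_pose(poses[0], centers[0], acetone)
    # relax once, then freeze the geometry and ladder the well charge
    h_opt, a_opt, _, _ = minimize_complex(host, placed, model)
    well_atom = wells[0][0]
    energies = []
    for q in (-0.1, -0.3, -0.5, -0.7, -0.9):
        charges = host.charges.copy()
        charges[well_atom] = q
        h_q = h_opt.with_charges(charges)
        m = ClassicalModel([h_q, a_opt])
        energies.append(
            binding_energy(m.evaluate([h_q, a_opt]), m.evaluate([h_q]), m.evaluate([a_opt]))
        )
    assert all(b < a for a, b in zip(energies, energies[1:]))
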