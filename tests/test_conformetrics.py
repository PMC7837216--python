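import numpy as np
import pytest

from eif2btools.conformetrics import (
    DegenerateAlignmentError,
    RigidTransform,
    axis_rotation,
    compare_complexes,
    helix_axis,
    kabsch_superpose,
    mean_displacement,
    pocket_displacement,
)
from eif2btools.synthetic import Motion, ideal_helix
from oracles import quaternion_superposition_rmsd


def _random_cloud(rng, n=10):
    return rng.normal(0.0, 5.0, size=(n, 3))


class TestKabsch:
    def test_identical_sets_give_identity(self):
        pts = _random_cloud(np.random.default_rng(0))
        res = kabsch_superpose(pts, pts)
        assert res.rmsd_fit < 1e-12
        assert np.allclose(res.transform.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(res.transform.translation, 0.0, atol=1e-12)

    def test_recovers_known_rotation_translation(self):
        pts = _random_cloud(np.random.default_rng(1))
        injected = RigidTransform.from_axis_angle((0, 0, 1), 25.0,
                                                  translation=(1.0, 2.0, 3.0))
        res = kabsch_superpose(pts, injected.apply(pts))
        assert res.rmsd_fit < 1e-10
        assert np.allclose(res.transform.rotation, injected.rotation, atol=1e-10)
        assert np.allclose(res.transform.translation, injected.translation, atol=1e-9)
        angle = np.degrees(np.arccos((np.trace(res.transform.rotation) - 1) / 2))
        assert angle == pytest.approx(25.0, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateAlignmentError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(DegenerateAlignmentError, match="collinear"):
            kabsch_superpose(line, line + 1.0)
        with pytest.raises(DegenerateAlignmentError, match="unpaired"):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_rmsd_matches_quaternion_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            p, q = _random_cloud(rng), _random_cloud(rng)
            ours = kabsch_superpose(p, q).rmsd_fit
            assert ours == pytest.approx(quaternion_superposition_rmsd(p, q),
                                         abs=1e-10)


class TestHelixAxis:
    def test_ideal_helix_axis_exact(self):
        geom = helix_axis(ideal_helix(21))
        assert np.degrees(np.arccos(abs(geom.axis[2]))) < 1e-6
        assert geom.axis[2] > 0  # oriented N→C

    def test_rotated_helix_axis_recovered(self):
        t = RigidTransform.from_axis_angle((1, 0, 0), 30.0)
        geom = helix_axis(t.apply(ideal_helix(21)))
        expected = t.rotation @ np.array([0.0, 0.0, 1.0])
        ang = np.degrees(np.arccos(np.clip(np.dot(geom.axis, expected), -1, 1)))
        assert ang < 0.5

    def test_noisy_axis_within_two_degrees(self):
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(100):
            pts = ideal_helix(21) + rng.normal(0.0, 0.3, size=(21, 3))
            axis = helix_axis(pts).axis
            worst = max(worst, np.degrees(np.arccos(np.clip(abs(axis[2]), -1, 1))))
        assert worst < 2.0

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError, match=">= 7"):
            helix_axis(ideal_helix(6))


class TestStructureMetrics:
    def test_self_comparison_is_zero(self, decamer):
        d = mean_displacement(decamer.model, decamer.model, decamer.assignment,
                              decamer.assignment, decamer.info.frame_specs,
                              decamer.info.probe_spec)
        assert d["mean_displacement_A"] == pytest.approx(0.0, abs=1e-9)
        r = axis_rotation(decamer.model, decamer.model, decamer.assignment,
                          decamer.assignment, decamer.info.frame_specs,
                          decamer.info.probe_spec)
        assert r["rotation_deg"] == pytest.approx(0.0, abs=1e-9)
        assert r["direction"] == "n/a"
        p = pocket_displacement(decamer.model, decamer.model, decamer.assignment,
                                decamer.assignment, decamer.info.shell_spec())
        assert p["displacement_A"] == pytest.approx(0.0, abs=1e-9)

    def test_pure_probe_translation_recovered(self, decamer, perturb):
        pert = perturb([Motion(chains=("D",), resnum_range=(247, 267),
                               translation=(2.0, 0.0, 0.0))])
        d = mean_displacement(decamer.model, pert.model, decamer.assignment,
                              pert.assignment, decamer.info.frame_specs,
                              decamer.info.probe_spec)
        assert d["per_protomer"]["unit1"]["displacement_A"] == pytest.approx(2.0, abs=1e-6)
        assert d["per_protomer"]["unit2"]["displacement_A"] == pytest.approx(0.0, abs=1e-9)
        assert d["rmsd_fit_A"] < 1e-9  # frame untouched

    def test_probe_rotation_angle_and_direction(self, decamer, perturb):
        centroid = tuple(decamer.info.chain_coords["D"][7:28].mean(axis=0))
        pert = perturb([Motion(chains=("D",), resnum_range=(247, 267),
                               rotation_axis=(0, 0, 1), rotation_deg=8.0,
                               pivot=centroid)])
        r = axis_rotation(decamer.model, pert.model, decamer.assignment,
                          pert.assignment, decamer.info.frame_specs,
                          decamer.info.probe_spec)
        assert r["per_protomer"]["unit1"]["rotation_deg"] == pytest.approx(8.0, abs=1e-6)
        assert r["per_protomer"]["unit2"]["rotation_deg"] == pytest.approx(0.0, abs=1e-6)
        # β sits at smaller x than δ in the fixture: +x moves the helix away
        away = perturb([Motion(chains=("D",), resnum_range=(247, 267),
                               translation=(3.0, 0.0, 0.0))])
        r_away = axis_rotation(decamer.model, away.model, decamer.assignment,
                               away.assignment, decamer.info.frame_specs,
                               decamer.info.probe_spec)
        assert r_away["per_protomer"]["unit1"]["direction"] == "away_from_beta"
        toward = perturb([Motion(chains=("D",), resnum_range=(247, 267),
                                 translation=(-2.0, 0.0, 0.0))])
        r_tow = axis_rotation(decamer.model, toward.model, decamer.assignment,
                              toward.assignment, decamer.info.frame_specs,
                              decamer.info.probe_spec)
        assert r_tow["per_protomer"]["unit1"]["direction"] == "toward_beta"

    def test_pocket_half_shell_translation_recovered(self, decamer, perturb):
        pert = perturb([Motion(chains=("H", "I"), translation=(0.9, -1.2, 0.0))])
        res = pocket_displacement(decamer.model, pert.model, decamer.assignment,
                                  pert.assignment, decamer.info.shell_spec(),
                                  align_unit="unit1")
        assert res["displacement_A"] == pytest.approx(1.5, abs=1e-6)
        assert res["rmsd_fit_A"] < 1e-9

    def test_metrics_invariant_under_global_motion_of_target(self, decamer, perturb):
        pert = perturb([Motion(chains=("D",), resnum_range=(247, 267),
                               rotation_axis=(1, 0, 0), rotation_deg=7.9,
                               translation=(1.0, 0.5, -0.2))])
        base_d = mean_displacement(decamer.model, pert.model, decamer.assignment,
                                   pert.assignment, decamer.info.frame_specs,
                                   decamer.info.probe_spec)
        base_r = axis_rotation(decamer.model, pert.model, decamer.assignment,
                               pert.assignment, decamer.info.frame_specs,
                               decamer.info.probe_spec)
        t = RigidTransform.from_axis_angle((0.3, -0.5, 0.8), 73.0,
                                           translation=(25.0, -40.0, 13.0))
        moved = pert.model.transformed(t.rotation, t.translation)
        d = mean_displacement(decamer.model, moved, decamer.assignment,
                              pert.assignment, decamer.info.frame_specs,
                              decamer.info.probe_spec)
        r = axis_rotation(decamer.model, moved, decamer.assignment,
                          pert.assignment, decamer.info.frame_specs,
                          decamer.info.probe_spec)
        assert d["per_protomer"]["unit1"]["displacement_A"] == pytest.approx(
            base_d["per_protomer"]["unit1"]["displacement_A"], abs=1e-6)
        assert r["per_protomer"]["unit1"]["rotation_deg"] == pytest.approx(
            base_r["per_protomer"]["unit1"]["rotation_deg"], abs=1e-6)


def test_compare_complexes_batch_continues_on_failure(decamer):
    models = {"SYN1": decamer.model}
    assigns = {"SYN1": decamer.assignment}
    comparisons = [
        {"id": "self", "ref": "SYN1", "target": "SYN1", "kind": "helix",
         "frame": decamer.info.frame_specs, "probe": decamer.info.probe_spec},
        {"id": "broken", "ref": "SYN1", "target": "MISSING", "kind": "helix",
         "frame": decamer.info.frame_specs, "probe": decamer.info.probe_spec},
    ]
    reports = compare_complexes(comparisons, models, assigns)
    assert len(reports) == 2
    assert reports[0].error == ""
    assert reports[0].mean_displacement_A == pytest.approx(0.0, abs=1e-9)
    assert reports[1].error != ""
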