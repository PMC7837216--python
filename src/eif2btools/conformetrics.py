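"""Rigid-body superposition and domain-motion metrics for eIF2B complexes.

Binding of phosphorylated eIF2 toggles eIF2B between conformations; the
readouts used to quantify that motion are (i) the mean Cα displacement and
helical-axis rotation of eIF2Bδ helix α3 (residues 247-267) after aligning two
entries on the C-terminal domains of the β/δ subunits, with a direction label
(toward/away from the same-protomer eIF2Bβ), and (ii) the relative shift of
the two βδ half-shells of the ISRIB-binding pocket, measured over the Cα atoms
within 10 Å of the ligand in a reference ISRIB-bound entry.

Superposition is least-squares rigid (Kabsch, SVD); the helix axis estimator
uses cross products of successive second-difference vectors of the Cα trace,
which is exact on an ideal helix of any length and degrades gracefully with
coordinate noise. All metrics are invariant under any global rigid motion of
either entry, because every comparison starts with a frame alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .structure_io import (
    AtomSet,
    SelectionSpec,
    StructureModel,
    SubunitAssignment,
    pair_atom_sets,
    resolve_many,
    resolve_selection,
)

#: a frame may be a single selection or a composite of several
FrameSpec = SelectionSpec | Sequence[SelectionSpec]

__all__ = [
    "RigidTransform",
    "SuperpositionResult",
    "HelixGeometry",
    "ConformationalMetricsReport",
    "DegenerateAlignmentError",
    "kabsch_superpose",
    "helix_axis",
    "mean_displacement",
    "axis_rotation",
    "pocket_displacement",
    "compare_complexes",
]


class DegenerateAlignmentError(ValueError):
    """Too few or geometrically degenerate alignment atoms."""


@dataclass
class RigidTransform:
    """Proper rigid motion x ↦ R x + t."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, float)
        self.translation = np.asarray(self.translation, float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthogonal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-9):
            raise ValueError("rotation matrix is not proper (det != +1)")

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(
        cls,
        axis: Sequence[float],
        angle_deg: float,
        pivot: Sequence[float] = (0.0, 0.0, 0.0),
        translation: Sequence[float] = (0.0, 0.0, 0.0),
    ) -> "RigidTransform":
        """Rotation by ``angle_deg`` about ``axis`` through ``pivot``, then a
        translation (Rodrigues construction)."""
        axis = np.asarray(axis, float)
        axis = axis / np.linalg.norm(axis)
        theta = np.deg2rad(angle_deg)
        k = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        rot = np.eye(3) + np.sin(theta) * k + (1 - np.cos(theta)) * (k @ k)
        pivot = np.asarray(pivot, float)
        t = pivot - rot @ pivot + np.asarray(translation, float)
        return cls(rot, t)


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd_fit: float  # Å over the alignment atoms
    n_atoms: int
    mobile_entry: str = ""
    reference_entry: str = ""


def kabsch_superpose(mobile: AtomSet | np.ndarray, reference: AtomSet | np.ndarray) -> SuperpositionResult:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    The two sets must be paired (equal length, matched order; see
    :func:`eif2btools.structure_io.pair_atom_sets`). Returns the rigid
    transform minimising the RMSD, which is the global optimum of the
    orthogonal Procrustes problem restricted to proper rotations.
    """
    p = mobile.xyz if isinstance(mobile, AtomSet) else np.asarray(mobile, float)
    q = reference.xyz if isinstance(reference, AtomSet) else np.asarray(reference, float)
    if p.shape != q.shape:
        raise DegenerateAlignmentError(
            f"unpaired sets: {p.shape[0]} vs {q.shape[0]} atoms"
        )
    n = p.shape[0]
    if n < 3:
        raise DegenerateAlignmentError(f"need >= 3 paired atoms, got {n}")
    p_mean, q_mean = p.mean(axis=0), q.mean(axis=0)
    pc, qc = p - p_mean, q - q_mean
    h = pc.T @ qc
    u, s, vt = np.linalg.svd(h)
    # collinear point sets leave the rotation about the line undetermined
    if s[1] <= 1e-8 * max(s[0], 1.0):
        raise DegenerateAlignmentError("degenerate (collinear) alignment atoms")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = q_mean - rot @ p_mean
    transform = RigidTransform(rot, t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(p) - q) ** 2, axis=1))))
    return SuperpositionResult(
        transform,
        rmsd,
        n,
        mobile_entry=mobile.entry_id if isinstance(mobile, AtomSet) else "",
        reference_entry=reference.entry_id if isinstance(reference, AtomSet) else "",
    )


@dataclass
class HelixGeometry:
    axis: np.ndarray  # unit vector, oriented N→C
    centroid: np.ndarray  # Å
    residue_span: tuple[int, int]

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, float)
        if not np.isclose(np.linalg.norm(self.axis), 1.0, atol=1e-9):
            raise ValueError("helix axis must be a unit vector")


def _complete_basis(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    seed = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = seed - np.dot(seed, a) * a
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(a, e1)


def _refine_helix_axis(pts: np.ndarray, a0: np.ndarray) -> np.ndarray:
    """Polish the axis by least-squares fitting an ideal helix model.

    Parameters: axis tilt (2), helix center (3), radius, phase, rise, twist.
    Initialised from the cross-product axis; on noiseless ideal helices the
    initial residual is already ~0, so the estimate stays exact, while under
    coordinate noise the parametric fit averages over all atoms.
    """
    from scipy.optimize import least_squares

    n = len(pts)
    k = np.arange(n) - (n - 1) / 2.0
    u, v = _complete_basis(a0)
    centroid = pts.mean(axis=0)
    rel = pts - centroid
    axial = rel @ a0
    radial = rel - np.outer(axial, a0)
    r0 = float(np.linalg.norm(radial, axis=1).mean())
    if r0 < 1e-9:
        return a0
    ang = np.unwrap(np.arctan2(radial @ v, radial @ u))
    omega0 = float(np.polyfit(k, ang, 1)[0])
    phi0 = float(np.mean(ang - omega0 * k))
    h0 = float(np.polyfit(k, axial, 1)[0])

    def residual(theta: np.ndarray) -> np.ndarray:
        alpha, beta, cx, cy, cz, r, phi, h, omega = theta
        a = a0 + alpha * u + beta * v
        a = a / np.linalg.norm(a)
        e1, e2 = _complete_basis(a)
        angles = omega * k + phi
        model = (
            np.array([cx, cy, cz])
            + np.outer(r * np.cos(angles), e1)
            + np.outer(r * np.sin(angles), e2)
            + np.outer(h * k, a)
        )
        return (model - pts).ravel()

    x0 = np.array([0.0, 0.0, *centroid, r0, phi0, h0, omega0])
    sol = least_squares(residual, x0, method="lm", xtol=1e-14, ftol=1e-14)
    a = a0 + sol.x[0] * u + sol.x[1] * v
    a /= np.linalg.norm(a)
    # rise sign convention: keep the axis pointing along increasing k (N→C)
    if sol.x[7] < 0:
        a = -a
    return a


def helix_axis(helix: AtomSet | np.ndarray, residue_span: tuple[int, int] | None = None) -> HelixGeometry:
    """Axis and centroid of an α-helical Cα trace (N→C orientation).

    Estimator, two stages: (1) for consecutive Cα positions p, the second
    differences d_k = p_{k-1} - 2 p_k + p_{k+1} point radially toward the
    helix axis, so each cross product d_k × d_l is parallel to the axis; the
    sign-aligned mean over all pairs gives a closed-form axis. (2) The axis
    is then polished by least-squares fitting an ideal helix (radius, rise,
    twist, phase, center, axis tilt) to the trace. Both stages are exact for
    an ideal helix; the parametric stage sets the noise performance.
    Requires ≥ 7 atoms.
    """
    pts = helix.xyz if isinstance(helix, AtomSet) else np.asarray(helix, float)
    n = pts.shape[0]
    if n < 7:
        raise ValueError(f"helix axis needs >= 7 consecutive Cα atoms, got {n}")
    d = pts[:-2] - 2 * pts[1:-1] + pts[2:]  # (n-2, 3) radial vectors
    cross = np.cross(d[:-1], d[1:])
    norms = np.linalg.norm(cross, axis=1)
    good = norms > 1e-12
    if not np.any(good):
        raise ValueError("degenerate trace: no curvature to define a helix axis")
    axis = (cross[good] / norms[good, None]).mean(axis=0)
    axis /= np.linalg.norm(axis)
    # second pass: average over *all* radial-vector pairs, sign-aligned with
    # the first-pass axis (more pairs → less noise; still exact when ideal)
    ii, jj = np.triu_indices(len(d), k=1)
    crosses = np.cross(d[ii], d[jj])
    cnorms = np.linalg.norm(crosses, axis=1)
    keep = cnorms > 0.2 * cnorms.max()
    units = crosses[keep] / cnorms[keep, None]
    signs = np.where(units @ axis >= 0, 1.0, -1.0)
    axis = (units * signs[:, None]).mean(axis=0)
    axis /= np.linalg.norm(axis)
    if np.dot(axis, pts[-1] - pts[0]) < 0:  # orient N→C
        axis = -axis
    axis = _refine_helix_axis(pts, axis)
    if np.dot(axis, pts[-1] - pts[0]) < 0:
        axis = -axis
    if residue_span is None and isinstance(helix, AtomSet) and len(helix):
        residue_span = (helix.records[0][3], helix.records[-1][3])
    return HelixGeometry(axis, pts.mean(axis=0), residue_span or (0, 0))


def _angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    cosang = float(np.clip(np.dot(a, b), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def _frame_superpose(
    ref: StructureModel,
    target: StructureModel,
    ref_assign: SubunitAssignment,
    target_assign: SubunitAssignment,
    frame: FrameSpec,
    shell_reference=None,
) -> SuperpositionResult:
    specs = [frame] if isinstance(frame, SelectionSpec) else list(frame)
    ref_frame = resolve_many(ref, ref_assign, specs, shell_reference=shell_reference)
    tgt_frame = resolve_many(target, target_assign, specs, shell_reference=shell_reference)
    tgt_paired, ref_paired = pair_atom_sets(tgt_frame, ref_frame)
    return kabsch_superpose(tgt_paired, ref_paired)


def mean_displacement(
    ref: StructureModel,
    target: StructureModel,
    ref_assign: SubunitAssignment,
    target_assign: SubunitAssignment,
    frame: FrameSpec,
    probe: SelectionSpec,
    protomers: Sequence[str] = ("unit1", "unit2"),
    shell_reference=None,
) -> dict:
    """Per-protomer mean Cα displacement of ``probe`` after frame alignment.

    The target entry is superposed onto the reference with the ``frame``
    atoms; the mean over paired probe atoms of the per-atom Euclidean
    displacement is then returned for each protomer, together with their mean,
    the probe RMSD, and the frame fit RMSD.
    """
    sup = _frame_superpose(ref, target, ref_assign, target_assign, frame, shell_reference)
    out: dict = {"rmsd_fit_A": sup.rmsd_fit, "n_frame": sup.n_atoms, "per_protomer": {}}
    disps, all_sq, n_tot = [], 0.0, 0
    for unit in protomers:
        ref_probe = resolve_selection(ref, ref_assign, probe, protomer=unit,
                                      shell_reference=shell_reference)
        tgt_probe = resolve_selection(target, target_assign, probe, protomer=unit,
                                      shell_reference=shell_reference)
        if len(ref_probe) == 0 or len(tgt_probe) == 0:
            continue
        tgt_paired, ref_paired = pair_atom_sets(tgt_probe, ref_probe)
        moved = sup.transform.apply(tgt_paired.xyz)
        per_atom = np.linalg.norm(moved - ref_paired.xyz, axis=1)
        out["per_protomer"][unit] = {
            "displacement_A": float(per_atom.mean()),
            "n_probe": len(per_atom),
        }
        disps.append(float(per_atom.mean()))
        all_sq += float(np.sum(per_atom**2))
        n_tot += len(per_atom)
    if not disps:
        raise ValueError("empty probe pairing: no probe atoms shared by both entries")
    out["mean_displacement_A"] = float(np.mean(disps))
    out["probe_rmsd_A"] = float(np.sqrt(all_sq / n_tot))
    return out


def axis_rotation(
    ref: StructureModel,
    target: StructureModel,
    ref_assign: SubunitAssignment,
    target_assign: SubunitAssignment,
    frame: FrameSpec,
    helix: SelectionSpec,
    beta_reference: str = "eIF2B_beta",
    protomers: Sequence[str] = ("unit1", "unit2"),
    direction_tol: float = 1e-6,
) -> dict:
    """Helix-axis rotation (degrees, in [0, 180]) between two entries.

    After frame superposition the angle between the N→C-oriented helix axes is
    reported per protomer. The direction label compares the internal distance
    from the helix centroid to the Cα centroid of the same-protomer eIF2Bβ
    chain in each entry ("toward_beta" if it shrinks, "away_from_beta" if it
    grows, "n/a" if unchanged within tolerance); being an internal distance it
    needs no alignment.
    """
    sup = _frame_superpose(ref, target, ref_assign, target_assign, frame)
    out: dict = {"rmsd_fit_A": sup.rmsd_fit, "per_protomer": {}}
    angles = []
    for unit in protomers:
        ref_h = resolve_selection(ref, ref_assign, helix, protomer=unit)
        tgt_h = resolve_selection(target, target_assign, helix, protomer=unit)
        if len(ref_h) == 0 or len(tgt_h) == 0:
            continue
        tgt_paired, ref_paired = pair_atom_sets(tgt_h, ref_h)
        geom_ref = helix_axis(ref_paired)
        moved = tgt_paired.subset(range(len(tgt_paired)))
        moved.xyz = sup.transform.apply(moved.xyz)
        geom_tgt = helix_axis(moved)
        angle = _angle_deg(geom_ref.axis, geom_tgt.axis)

        direction = "n/a"
        ref_beta = resolve_selection(
            ref, ref_assign, SelectionSpec(role=beta_reference), protomer=unit)
        tgt_beta = resolve_selection(
            target, target_assign, SelectionSpec(role=beta_reference), protomer=unit)
        if len(ref_beta) and len(tgt_beta):
            d_ref = float(np.linalg.norm(geom_ref.centroid - ref_beta.xyz.mean(axis=0)))
            d_tgt = float(np.linalg.norm(
                helix_axis(tgt_paired).centroid - tgt_beta.xyz.mean(axis=0)))
            if d_tgt < d_ref - direction_tol:
                direction = "toward_beta"
            elif d_tgt > d_ref + direction_tol:
                direction = "away_from_beta"
        out["per_protomer"][unit] = {"rotation_deg": angle, "direction": direction}
        angles.append(angle)
    if not angles:
        raise ValueError("helix not resolvable in both entries")
    out["rotation_deg"] = float(np.mean(angles))
    labels = {v["direction"] for v in out["per_protomer"].values()}
    out["direction"] = labels.pop() if len(labels) == 1 else "mixed"
    return out


def pocket_displacement(
    ref: StructureModel,
    target: StructureModel,
    ref_assign: SubunitAssignment,
    target_assign: SubunitAssignment,
    shell: SelectionSpec,
    align_unit: str = "unit1",
) -> dict:
    """Relative shift of the two βδ half-shells of the ligand pocket.

    The shell (defined in the reference entry, which must contain the ligand)
    is split by protomer; ``target`` is superposed on the reference using the
    ``align_unit`` half-shell, and the mean displacement of the *other*
    half-shell's Cα atoms is returned.
    """
    if shell.shell is None:
        raise ValueError("pocket_displacement needs a shell selection")
    other = "unit2" if align_unit == "unit1" else "unit1"
    shell_ref = (ref, ref_assign)
    ref_align = resolve_selection(ref, ref_assign, shell, protomer=align_unit,
                                  shell_reference=shell_ref)
    tgt_align = resolve_selection(target, target_assign, shell, protomer=align_unit,
                                  shell_reference=shell_ref)
    tgt_paired, ref_paired = pair_atom_sets(tgt_align, ref_align)
    n_shell_ref = len(ref_align)
    if len(tgt_paired) < 0.5 * n_shell_ref:
        raise ValueError(
            f"shell transfer covers {len(tgt_paired)}/{n_shell_ref} residues (< 50%)"
        )
    sup = kabsch_superpose(tgt_paired, ref_paired)

    ref_other = resolve_selection(ref, ref_assign, shell, protomer=other,
                                  shell_reference=shell_ref)
    tgt_other = resolve_selection(target, target_assign, shell, protomer=other,
                                  shell_reference=shell_ref)
    tgt_o, ref_o = pair_atom_sets(tgt_other, ref_other)
    per_atom = np.linalg.norm(sup.transform.apply(tgt_o.xyz) - ref_o.xyz, axis=1)
    return {
        "displacement_A": float(per_atom.mean()),
        "align_unit": align_unit,
        "probe_unit": other,
        "n_probe": len(per_atom),
        "rmsd_fit_A": sup.rmsd_fit,
        "n_frame": sup.n_atoms,
    }


@dataclass
class ConformationalMetricsReport:
    """One reference/target comparison: displacement, rotation, direction."""

    comparison_id: str
    ref_entry: str
    target_entry: str
    kind: str  # "helix" or "pocket"
    mean_displacement_A: float | None = None
    axis_rotation_deg: float | None = None
    direction: str = "n/a"
    probe_rmsd_A: float | None = None
    rmsd_fit_A: float | None = None
    per_protomer: dict = field(default_factory=dict)
    n_frame: int | None = None
    error: str = ""

    def to_row(self) -> dict:
        row = {
            "comparison": self.comparison_id,
            "ref": self.ref_entry,
            "target": self.target_entry,
            "kind": self.kind,
            "mean_displacement_A": self.mean_displacement_A,
            "axis_rotation_deg": self.axis_rotation_deg,
            "direction": self.direction,
            "probe_rmsd_A": self.probe_rmsd_A,
            "rmsd_fit_A": self.rmsd_fit_A,
            "n_frame": self.n_frame,
            "error": self.error,
        }
        for unit in sorted(self.per_protomer):
            for key, val in self.per_protomer[unit].items():
                row[f"{unit}_{key}"] = val
        return row


def compare_complexes(
    comparisons: Sequence[Mapping],
    models: Mapping[str, StructureModel],
    assignments: Mapping[str, SubunitAssignment],
) -> list[ConformationalMetricsReport]:
    """Run a batch of configured comparisons; per-comparison failures are
    recorded in the report (``error`` field) and the batch continues.

    Each comparison mapping needs: ``id``, ``ref``, ``target``, ``kind``
    ("helix" or "pocket"), plus for helix comparisons ``frame`` and ``probe``
    (:class:`SelectionSpec`), and for pocket comparisons ``shell``
    (shell SelectionSpec) and optionally ``align_unit``.
    """
    reports = []
    for comp in comparisons:
        cid, kind = comp["id"], comp.get("kind", "helix")
        ref_id, tgt_id = comp["ref"], comp["target"]
        report = ConformationalMetricsReport(cid, ref_id, tgt_id, kind)
        try:
            ref, tgt = models[ref_id], models[tgt_id]
            ra, ta = assignments[ref_id], assignments[tgt_id]
            if kind == "helix":
                disp = mean_displacement(ref, tgt, ra, ta, comp["frame"], comp["probe"])
                rot = axis_rotation(ref, tgt, ra, ta, comp["frame"], comp["probe"])
                report.mean_displacement_A = disp["mean_displacement_A"]
                report.probe_rmsd_A = disp["probe_rmsd_A"]
                report.rmsd_fit_A = disp["rmsd_fit_A"]
                report.n_frame = disp["n_frame"]
                report.axis_rotation_deg = rot["rotation_deg"]
                report.direction = rot["direction"]
                report.per_protomer = {
                    u: {**disp["per_protomer"].get(u, {}), **rot["per_protomer"].get(u, {})}
                    for u in set(disp["per_protomer"]) | set(rot["per_protomer"])
                }
            elif kind == "pocket":
                units = comp.get("align_units", ("unit1", "unit2"))
                per = {}
                for unit in units:
                    res = pocket_displacement(ref, tgt, ra, ta, comp["shell"], unit)
                    per[unit] = {
                        "displacement_A": res["displacement_A"],
                        "n_probe": res["n_probe"],
                        "rmsd_fit_A": res["rmsd_fit_A"],
                    }
                report.per_protomer = per
                report.mean_displacement_A = float(
                    np.mean([v["displacement_A"] for v in per.values()])
                )
                report.rmsd_fit_A = float(
                    np.mean([v["rmsd_fit_A"] for v in per.values()])
                )
            else:
                raise ValueError(f"unknown comparison kind {kind!r}")
        except Exception as exc:  # batch continues; failure recorded
            report.error = f"{type(exc).__name__}: {exc}"
        reports.append(report)
    return reports
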