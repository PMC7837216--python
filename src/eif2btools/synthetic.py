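"""Synthetic fixtures: toy decamer structures with a known motion ledger, and
signal traces drawn from the regression models.

The structural fixture is a deliberately non-physical stand-in for the eIF2B
decamer: ten ideal poly-Cα helices (two copies each of the α/β/γ/δ/ε roles)
arranged with two-fold pseudo-symmetry about z, a δ chain numbered so that
residues 247-267 form the "α3" probe helix, and a three-atom dummy ligand on
the symmetry axis between the β/δ chains of the two protomers. It exists to
exercise the real mmCIF parser, the role/protomer assignment, and the
geometry code against analytically known answers — not to resemble biology.

``perturb_fixture`` applies caller-specified rigid motions to chain groups
and returns a ledger whose expected displacement/rotation values are computed
in closed form from the injected transforms (never by the pipeline under
test). ``simulate_trace`` adds seeded Gaussian noise to exact model curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

from .binding_models import KineticTrace, evaluate
from .conformetrics import RigidTransform
from .structure_io import SelectionSpec, ShellSpec, StructureModel, load_structure

__all__ = [
    "FixtureInfo",
    "Motion",
    "MotionLedger",
    "TraceLedger",
    "ideal_helix",
    "make_decamer_fixture",
    "perturb_fixture",
    "simulate_trace",
    "default_trace_ledgers",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 2021

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}
_AA1 = list(_AA3)

#: chain layout: chain id → (role, protomer unit, first residue number, length)
_CHAIN_PLAN = {
    "A": ("eIF2B_alpha", "unit1", 1, 25),
    "B": ("eIF2B_beta", "unit1", 1, 40),
    "D": ("eIF2B_delta", "unit1", 240, 41),
    "G": ("eIF2B_gamma", "unit1", 1, 30),
    "E": ("eIF2B_eps", "unit1", 1, 30),
    "F": ("eIF2B_alpha", "unit2", 1, 25),
    "H": ("eIF2B_beta", "unit2", 1, 40),
    "I": ("eIF2B_delta", "unit2", 240, 41),
    "J": ("eIF2B_gamma", "unit2", 1, 30),
    "K": ("eIF2B_eps", "unit2", 1, 30),
}

#: unit1 placement: chain → (origin, direction); unit2 is the 180° rotation
#: about z. The β/δ chains pass within 10 Å of the ligand at the origin.
_UNIT1_GEOMETRY = {
    "A": ((12.0, 30.0, 6.0), (1.0, 0.0, 0.0)),
    "B": ((4.0, -25.0, 2.0), (0.0, 1.0, 0.0)),
    "D": ((7.0, -20.0, -4.0), (0.0, 1.0, 0.0)),
    "G": ((25.0, 12.0, 8.0), (1.0, 0.0, 0.0)),
    "E": ((25.0, 18.0, -8.0), (1.0, 0.0, 0.0)),
}

_LIGAND_XYZ = np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [-1.5, 0.0, 0.0]])

HELIX_RISE_A = 1.5
HELIX_TWIST_DEG = 100.0
HELIX_RADIUS_A = 2.3


def _rotation_to(direction: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping +z onto ``direction``."""
    z = np.array([0.0, 0.0, 1.0])
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    v = np.cross(z, d)
    c = float(np.dot(z, d))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    k = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + k + k @ k / (1.0 + c)


def ideal_helix(
    n: int,
    origin: Sequence[float] = (0, 0, 0),
    direction: Sequence[float] = (0, 0, 1),
    phase_deg: float = 0.0,
    rise: float = HELIX_RISE_A,
    twist_deg: float = HELIX_TWIST_DEG,
    radius: float = HELIX_RADIUS_A,
) -> np.ndarray:
    """Cα trace of an ideal α-helix advancing from ``origin`` along
    ``direction`` (N→C)."""
    k = np.arange(n)
    ang = np.deg2rad(phase_deg + twist_deg * k)
    local = np.stack([radius * np.cos(ang), radius * np.sin(ang), rise * k], axis=1)
    return local @ _rotation_to(direction).T + np.asarray(origin, float)


@dataclass
class FixtureInfo:
    """Ground truth for a generated decamer fixture."""

    entry_id: str
    seed: int
    sequences: dict[str, str]  # role → one-letter reference sequence
    chain_roles: dict[str, str]
    chain_units: dict[str, str]
    helix_directions: dict[str, np.ndarray]  # chain → construction axis (N→C)
    chain_coords: dict[str, np.ndarray]  # chain → (n, 3) Cα construction coords
    chain_resnums: dict[str, np.ndarray]
    ligand_xyz: np.ndarray

    @property
    def reference_library(self) -> dict[str, str]:
        return dict(self.sequences)

    @property
    def frame_specs(self) -> list[SelectionSpec]:
        """Alignment frame: the full β chains plus the δ segment C-terminal of
        the probe helix (stand-in for the β/δ C-terminal domains)."""
        return [
            SelectionSpec(role="eIF2B_beta", ranges=((1, 40),)),
            SelectionSpec(role="eIF2B_delta", ranges=((270, 280),)),
        ]

    @property
    def probe_spec(self) -> SelectionSpec:
        return SelectionSpec(role="eIF2B_delta", ranges=((247, 267),))

    def shell_spec(self, reference_entry: str | None = None) -> SelectionSpec:
        return SelectionSpec(
            shell=ShellSpec("ISRIB", 10.0, reference_entry or self.entry_id)
        )


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA1, size=length))


def _build_structure(entry_id: str, info: FixtureInfo) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = entry_id
    model = gemmi.Model("1")
    for cid, (role, _unit, start, _length) in _CHAIN_PLAN.items():
        chain = gemmi.Chain(cid)
        seq = info.sequences[role]
        for i, xyz in enumerate(info.chain_coords[cid]):
            res = gemmi.Residue()
            res.name = _AA3[seq[i]]
            res.seqid = gemmi.SeqId(int(info.chain_resnums[cid][i]), " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            atom.b_iso = 20.0
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    lig_chain = gemmi.Chain("X")
    res = gemmi.Residue()
    res.name = "ISR"
    res.seqid = gemmi.SeqId(1, " ")
    res.het_flag = "H"
    for j, xyz in enumerate(info.ligand_xyz):
        atom = gemmi.Atom()
        atom.name = f"C{j + 1}"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*xyz)
        atom.occ = 1.0
        atom.b_iso = 20.0
        res.add_atom(atom)
    lig_chain.add_residue(res)
    model.add_chain(lig_chain)
    st.add_model(model)
    st.setup_entities()
    return st


def make_decamer_fixture(
    seed: int = DEFAULT_SEED,
    directory: str | Path = ".",
    entry_id: str = "SYN1",
) -> tuple[Path, FixtureInfo]:
    """Write a toy two-protomer decamer fixture as mmCIF.

    The seed perturbs the chain placements (origins by ±2 Å, helix phases)
    and draws the per-role sequences; helices themselves stay ideal so that
    axis geometry has exact expected values. Returns the file path and the
    ground-truth :class:`FixtureInfo`.
    """
    rng = np.random.default_rng(seed)
    sequences = {}
    for cid, (role, unit, _start, length) in _CHAIN_PLAN.items():
        if unit == "unit1":  # one draw per role; both copies share it
            sequences[role] = _random_sequence(rng, length)

    flip = np.diag([-1.0, -1.0, 1.0])  # two-fold about z
    chain_coords, chain_resnums, helix_dirs = {}, {}, {}
    for cid, (role, unit, start, length) in _CHAIN_PLAN.items():
        unit1_cid = cid if unit == "unit1" else {
            "F": "A", "H": "B", "I": "D", "J": "G", "K": "E"}[cid]
        origin, direction = _UNIT1_GEOMETRY[unit1_cid]
        origin = np.asarray(origin, float) + rng.uniform(-2.0, 2.0, size=3)
        phase = float(rng.uniform(0.0, 360.0))
        coords = ideal_helix(length, origin, direction, phase_deg=phase)
        direction = np.asarray(direction, float)
        if unit == "unit2":
            coords = coords @ flip.T
            direction = flip @ direction
        chain_coords[cid] = coords
        chain_resnums[cid] = np.arange(start, start + length)
        helix_dirs[cid] = direction / np.linalg.norm(direction)

    info = FixtureInfo(
        entry_id=entry_id,
        seed=seed,
        sequences=sequences,
        chain_roles={c: plan[0] for c, plan in _CHAIN_PLAN.items()},
        chain_units={c: plan[1] for c, plan in _CHAIN_PLAN.items()},
        helix_directions=helix_dirs,
        chain_coords=chain_coords,
        chain_resnums=chain_resnums,
        ligand_xyz=_LIGAND_XYZ.copy(),
    )
    st = _build_structure(entry_id, info)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{entry_id}.cif"
    st.make_mmcif_document().write_file(str(path))
    return path, info


@dataclass(frozen=True)
class Motion:
    """One injected rigid motion applied to a chain group.

    ``resnum_range`` restricts the motion to a residue window within the
    chains (e.g. just the probe helix); ``pivot`` defaults to the centroid of
    the moved Cα atoms.
    """

    chains: tuple[str, ...]
    rotation_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    rotation_deg: float = 0.0
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    resnum_range: tuple[int, int] | None = None
    pivot: tuple[float, float, float] | None = None


@dataclass
class MotionLedger:
    """Analytic expectations for a perturbed fixture (generator-side truth)."""

    source_entry: str
    perturbed_entry: str
    motions: list[Motion]
    #: per-motion expected mean Cα displacement over the moved atoms, Å
    expected_mean_displacement: list[float]
    #: per-motion expected helix-axis rotation (°) for chains with a known
    #: construction axis; None when the motion touches no recorded helix
    expected_axis_rotation: list[float | None]
    details: list[dict] = field(default_factory=list)


def _motion_transform(motion: Motion, group_xyz: np.ndarray) -> RigidTransform:
    pivot = (np.asarray(motion.pivot, float) if motion.pivot is not None
             else group_xyz.mean(axis=0))
    return RigidTransform.from_axis_angle(
        motion.rotation_axis, motion.rotation_deg, pivot=pivot,
        translation=motion.translation,
    )


def perturb_fixture(
    source: str | Path,
    motions: Sequence[Motion],
    out_path: str | Path,
    info: FixtureInfo | None = None,
    entry_id: str | None = None,
) -> tuple[Path, MotionLedger]:
    """Apply rigid motions to chain groups of a fixture and write the result.

    Expected metric values in the returned ledger are closed-form functions of
    the injected transform and the pre-motion coordinates: the mean
    displacement is mean‖T(p) − p‖ over the moved Cα atoms, and the expected
    axis rotation is the angle between a moved helix's construction axis and
    its image under the injected rotation.
    """
    st = gemmi.read_structure(str(source))
    st.setup_entities()
    model = st[0]
    out_entry = entry_id or f"{st.name}P"
    st.name = out_entry

    expected_disp: list[float] = []
    expected_rot: list[float | None] = []
    details: list[dict] = []
    claimed: set[tuple[str, int]] = set()
    for motion in motions:
        group_xyz = []
        group_atoms = []
        for chain in model:
            if chain.name not in motion.chains:
                continue
            for res in chain:
                num = res.seqid.num
                if motion.resnum_range is not None:
                    lo, hi = motion.resnum_range
                    if not lo <= num <= hi:
                        continue
                key = (chain.name, num)
                if key in claimed:
                    raise ValueError(f"overlapping motion groups at {key}")
                claimed.add(key)
                for atom in res:
                    group_xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    group_atoms.append(atom)
        if not group_xyz:
            raise ValueError(f"motion group matched no atoms: {motion}")
        group_xyz = np.asarray(group_xyz)
        transform = _motion_transform(motion, group_xyz)
        moved = transform.apply(group_xyz)
        for atom, xyz in zip(group_atoms, moved):
            atom.pos = gemmi.Position(*xyz)
        expected_disp.append(float(np.linalg.norm(moved - group_xyz, axis=1).mean()))

        rot_expect: float | None = None
        if info is not None and motion.rotation_deg != 0.0:
            for cid in motion.chains:
                axis = info.helix_directions.get(cid)
                if axis is not None:
                    image = transform.rotation @ axis
                    cosang = float(np.clip(np.dot(axis, image), -1.0, 1.0))
                    rot_expect = float(np.degrees(np.arccos(cosang)))
                    break
        elif motion.rotation_deg == 0.0:
            rot_expect = 0.0
        expected_rot.append(rot_expect)
        details.append({
            "chains": motion.chains,
            "resnum_range": motion.resnum_range,
            "rotation_deg": motion.rotation_deg,
            "translation": motion.translation,
            "n_atoms": len(group_atoms),
        })

    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    st.make_mmcif_document().write_file(str(out_path))
    ledger = MotionLedger(
        source_entry=Path(source).stem,
        perturbed_entry=out_entry,
        motions=list(motions),
        expected_mean_displacement=expected_disp,
        expected_axis_rotation=expected_rot,
        details=details,
    )
    return out_path, ledger


def load_fixture(path: str | Path) -> StructureModel:
    """Convenience wrapper: read a fixture back through the real parser."""
    return load_structure(path)


# ---------------------------------------------------------------------------
# trace simulation


@dataclass(frozen=True)
class TraceLedger:
    """Generator record for one simulated trace."""

    model_id: str
    true_params: tuple[tuple[str, float], ...]
    noise_sd: float
    seed: int

    @property
    def params(self) -> dict[str, float]:
        return dict(self.true_params)


def simulate_trace(
    ledger: TraceLedger,
    x: Sequence[float],
    x_units: str = "",
    y_units: str = "",
) -> KineticTrace:
    """Y = model(X; true params) + Gaussian(0, σ), seeded.

    Regeneration with the same ledger is bit-identical; σ = 0 reproduces the
    model curve exactly.
    """
    x = np.asarray(x, float)
    y = evaluate(ledger.model_id, ledger.params, x)
    if ledger.noise_sd > 0:
        rng = np.random.default_rng(ledger.seed)
        y = y + rng.normal(0.0, ledger.noise_sd, size=y.shape)
    return KineticTrace(x, y, x_units=x_units, y_units=y_units,
                        meta={"ledger": ledger})


def default_trace_ledgers(seed: int = DEFAULT_SEED, noise_frac: float = 0.02) -> dict:
    """Study-condition trace generators for each model, keyed by model id.

    True parameter values are the ones the assays report: FAM-ISRIB
    displacement k_off 0.74 min⁻¹; eIF2(αP) competition IC50 0.25 µM with
    Hill slope 2.4; biphasic dissociation switching %Fast between 50 and 75;
    steady-state binding K_1/2max 15.2 nM (29.8 nM with ISRIB for the
    specific-binding plateau fit); %Fast dose response EC50 1.8 nM. Noise σ
    is ``noise_frac`` of the curve span (default 2%).
    """
    truths: dict[str, tuple[dict[str, float], np.ndarray]] = {
        "one_phase_decay": (
            {"Y0": 200.0, "Plateau": 50.0, "K": 0.74},
            np.linspace(0.0, 6.0, 25),
        ),
        "one_site_total": (
            {"Bmax": 180.0, "Kd": 15.2, "NS": 0.2, "Background": 40.0},
            np.linspace(0.0, 150.0, 25),
        ),
        "fourpl_inhibition": (
            {"Bottom": 40.0, "Top": 240.0, "LogIC50": float(np.log10(0.25)),
             "HillSlope": 2.4},
            np.linspace(-3.0, 1.5, 25),
        ),
        # biphasic traces sample the fast phase densely (as a biosensor does):
        # uniform spacing wider than the fast half-life leaves KFast and
        # PercentFast ill-determined
        "two_phase_association": (
            {"Y0": 0.0, "Plateau": 1.2, "PercentFast": 60.0, "KFast": 2.0,
             "KSlow": 0.15},
            np.concatenate([np.linspace(0.0, 2.0, 13), np.linspace(2.5, 30.0, 17)]),
        ),
        "two_phase_decay": (
            {"Y0": 1.2, "Plateau": 0.1, "PercentFast": 75.0, "KFast": 1.5,
             "KSlow": 0.05},
            np.concatenate([np.linspace(0.0, 3.0, 13), np.linspace(4.0, 60.0, 17)]),
        ),
        "one_site_specific": (
            {"Bmax": 1.5, "Kd": 29.8},
            np.linspace(0.0, 150.0, 25),
        ),
        "agonist_response": (
            {"Bottom": 50.0, "Top": 75.0, "EC50": 1.8},
            np.linspace(0.0, 30.0, 25),
        ),
    }
    ledgers = {}
    for offset, (model_id, (params, x)) in enumerate(truths.items()):
        span = float(np.ptp(evaluate(model_id, params, x)))
        ledgers[model_id] = (
            TraceLedger(model_id, tuple(params.items()), noise_frac * span,
                        seed + offset),
            x,
        )
    return ledgers
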