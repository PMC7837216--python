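"""Coordinate I/O, subunit-role assignment, and declarative atom selections.

eIF2B is a two-fold pseudo-symmetric decamer (two copies each of the α, β, γ,
δ and ε subunits); the structures handled here additionally carry eIF2 α/γ
chains and the small molecule ISRIB. Deposited mmCIF/PDB entries use arbitrary
chain identifiers, so downstream geometry never addresses chains directly:
chains are first mapped to biological *roles* by sequence identity against a
reference library, the β/δ/γ/ε chains are partitioned into the two protomers
("unit1"/"unit2"), and selections are expressed as (role, residue range) or as
a ligand shell and resolved to concrete coordinate arrays.

Residue addressing uses author numbering throughout (the numbering the
literature quotes, e.g. human eIF2Bδ helix α3 = residues 247-267); label
numbering is retained on every record as a fallback.
"""

from __future__ import annotations

import copy
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import gemmi
import numpy as np

__all__ = [
    "ROLES",
    "EIF2B_ROLES",
    "TETRAMER_ROLES",
    "StructureModel",
    "ChainRecord",
    "LigandRecord",
    "SubunitAssignment",
    "ShellSpec",
    "SelectionSpec",
    "AtomSet",
    "StructureError",
    "SelectionError",
    "AssignmentError",
    "load_structure",
    "structure_from_gemmi",
    "assign_subunits",
    "resolve_selection",
    "shell_residues",
    "pair_atom_sets",
    "fetch_structures",
]

EIF2B_ROLES = (
    "eIF2B_alpha",
    "eIF2B_beta",
    "eIF2B_gamma",
    "eIF2B_delta",
    "eIF2B_eps",
)
#: β/δ/γ/ε chains come in two copies, one per protomer
TETRAMER_ROLES = ("eIF2B_beta", "eIF2B_gamma", "eIF2B_delta", "eIF2B_eps")
ROLES = EIF2B_ROLES + ("eIF2_alpha", "eIF2_gamma", "ISRIB")

#: ligand component ids accepted as ISRIB (fixture id plus deposited het code)
ISRIB_COMPONENT_NAMES = frozenset({"ISR", "F6N", "EZB"})


class StructureError(ValueError):
    """Unreadable, empty, or otherwise malformed coordinate input."""


class AssignmentError(ValueError):
    """Chain-to-role assignment could not be completed consistently."""


class SelectionError(ValueError):
    """A selection could not be resolved against a structure."""


@dataclass
class ChainRecord:
    """One polymer chain: per-residue Cα coordinates with dual numbering."""

    chain_id: str
    sequence: str
    auth_num: np.ndarray  # (n,) int author residue numbers
    label_num: np.ndarray  # (n,) int label numbers (-1 where undefined)
    ca: np.ndarray  # (n, 3) float Cα coordinates, Å

    def __post_init__(self) -> None:
        self.auth_num = np.asarray(self.auth_num, dtype=int)
        self.label_num = np.asarray(self.label_num, dtype=int)
        self.ca = np.asarray(self.ca, dtype=float)
        if self.ca.shape != (len(self.auth_num), 3):
            raise StructureError(
                f"chain {self.chain_id}: {len(self.auth_num)} residues but "
                f"Cα array of shape {self.ca.shape}"
            )
        if not np.all(np.isfinite(self.ca)):
            raise StructureError(f"chain {self.chain_id}: non-finite Cα coordinates")

    def __len__(self) -> int:
        return len(self.auth_num)

    @property
    def centroid(self) -> np.ndarray:
        return self.ca.mean(axis=0)


@dataclass
class LigandRecord:
    """One non-polymer component (all atoms)."""

    comp_name: str
    chain_id: str
    atom_names: list[str]
    xyz: np.ndarray  # (n, 3) Å

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not np.all(np.isfinite(self.xyz)):
            raise StructureError(f"ligand {self.comp_name}: non-finite coordinates")


@dataclass
class StructureModel:
    """Parsed multi-chain coordinate set (Cα trace + ligands)."""

    entry_id: str
    chains: list[ChainRecord]
    ligands: list[LigandRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.entry_id:
            raise StructureError("entry_id must be nonempty")

    def chain(self, chain_id: str) -> ChainRecord:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in {self.entry_id}")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a copy with every coordinate rigidly transformed."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        out = copy.deepcopy(self)
        for c in out.chains:
            c.ca = c.ca @ rotation.T + translation
        for lig in out.ligands:
            lig.xyz = lig.xyz @ rotation.T + translation
        return out


def _residue_is_amino_acid(res: gemmi.Residue) -> bool:
    info = gemmi.find_tabulated_residue(res.name)
    if info is not None:
        return info.is_amino_acid()
    # unknown component: treat as polymer when it carries a CA atom
    return res.find_atom("CA", "*") is not None


def structure_from_gemmi(st: gemmi.Structure, entry_id: str | None = None) -> StructureModel:
    """Convert a gemmi Structure (first model) to a :class:`StructureModel`."""
    if len(st) == 0:
        raise StructureError(f"{st.name or 'structure'}: no models")
    st.setup_entities()
    model = st[0]
    chains: list[ChainRecord] = []
    ligands: list[LigandRecord] = []
    for chain in model:
        auth, label, ca, seq = [], [], [], []
        for res in chain:
            if gemmi.find_tabulated_residue(res.name) is not None and gemmi.find_tabulated_residue(
                res.name
            ).is_water():
                continue
            if _residue_is_amino_acid(res):
                atom = res.find_atom("CA", "*")
                if atom is None:
                    continue
                auth.append(res.seqid.num)
                label.append(res.label_seq if res.label_seq is not None else -1)
                ca.append([atom.pos.x, atom.pos.y, atom.pos.z])
                seq.append(gemmi.find_tabulated_residue(res.name).one_letter_code.upper()
                           if gemmi.find_tabulated_residue(res.name) is not None else "X")
            else:
                xyz = [[a.pos.x, a.pos.y, a.pos.z] for a in res]
                names = [a.name for a in res]
                if xyz:
                    ligands.append(LigandRecord(res.name, chain.name, names, np.array(xyz)))
        if auth:
            chains.append(
                ChainRecord(chain.name, "".join(seq), np.array(auth), np.array(label), np.array(ca))
            )
    if not chains:
        raise StructureError(f"{entry_id or st.name}: no polymer chains with Cα atoms")
    return StructureModel(entry_id or st.name or "UNKNOWN", chains, ligands)


def load_structure(source: str | Path, fmt: str | None = None) -> StructureModel:
    """Read an mmCIF or PDB file into a :class:`StructureModel`.

    Parameters
    ----------
    source:
        Path to a ``.cif``/``.cif.gz``/``.pdb``/``.ent`` file.
    fmt:
        Force ``"mmcif"`` or ``"pdb"``; by default inferred from the extension.
    """
    path = Path(source)
    if not path.exists():
        raise StructureError(f"coordinate file not found: {path}")
    try:
        if fmt is None:
            st = gemmi.read_structure(str(path))
        elif fmt.lower() in ("mmcif", "cif"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt.lower() == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        else:
            raise StructureError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"could not parse {path.name}: {exc}") from exc
    entry_id = st.name or path.stem.upper()
    return structure_from_gemmi(st, entry_id=entry_id)


# ---------------------------------------------------------------------------
# subunit assignment


@dataclass
class SubunitAssignment:
    """Chain → biological role map plus protomer tags for the βδγε chains."""

    role_to_chains: dict[str, list[str]]
    protomer: dict[str, str]  # chain_id -> "unit1" | "unit2" (βδγε chains only)
    identity: dict[str, float] = field(default_factory=dict)  # chain_id -> best identity
    unassigned: list[str] = field(default_factory=list)

    def role_of(self, chain_id: str) -> str | None:
        for role, ids in self.role_to_chains.items():
            if chain_id in ids:
                return role
        return None

    def chains_for(self, role: str, protomer: str = "both") -> list[str]:
        ids = self.role_to_chains.get(role, [])
        if protomer == "both" or role not in TETRAMER_ROLES:
            return list(ids)
        return [c for c in ids if self.protomer.get(c) == protomer]


def _identity(seq_a: str, seq_b: str) -> float:
    if not seq_a or not seq_b:
        return 0.0
    dist = edlib.align(seq_a, seq_b, mode="NW", task="distance")["editDistance"]
    return 1.0 - dist / max(len(seq_a), len(seq_b))


def assign_subunits(
    model: StructureModel,
    references: Mapping[str, str],
    min_identity: float = 0.6,
    ligand_names: Iterable[str] = ISRIB_COMPONENT_NAMES,
) -> SubunitAssignment:
    """Assign each chain the role whose reference sequence it matches best.

    ``references`` maps each role (see :data:`ROLES`, minus ``"ISRIB"``) to a
    one-letter reference sequence. Chains below ``min_identity`` against every
    reference are recorded in ``unassigned`` (a warning, not an error).
    Protomer tags for the βδγε chains are derived geometrically: each chain is
    grouped with the nearer of the two eIF2Bα chains (``unit1`` = the α chain
    with the lexicographically smaller chain id). ISRIB is assigned from
    ligand component names.
    """
    seq_roles = [r for r in ROLES if r != "ISRIB" and r in references]
    if not seq_roles:
        raise AssignmentError("reference library is empty")
    role_to_chains: dict[str, list[str]] = {r: [] for r in ROLES}
    identity: dict[str, float] = {}
    unassigned: list[str] = []
    for chain in model.chains:
        scores = {r: _identity(chain.sequence, references[r]) for r in seq_roles}
        best_role = max(sorted(scores), key=lambda r: scores[r])
        identity[chain.chain_id] = scores[best_role]
        if scores[best_role] >= min_identity:
            role_to_chains[best_role].append(chain.chain_id)
        else:
            unassigned.append(chain.chain_id)
    for role, ids in role_to_chains.items():
        if role != "ISRIB" and len(ids) > 2:
            raise AssignmentError(f"role {role} matched {len(ids)} chains: {ids}")

    ligand_names = set(ligand_names)
    for lig in model.ligands:
        if lig.comp_name in ligand_names:
            role_to_chains["ISRIB"].append(lig.chain_id)

    protomer = _tag_protomers(model, role_to_chains)
    return SubunitAssignment(role_to_chains, protomer, identity, unassigned)


def _tag_protomers(
    model: StructureModel, role_to_chains: Mapping[str, Sequence[str]]
) -> dict[str, str]:
    tetramer_ids = sorted(
        cid for role in TETRAMER_ROLES for cid in role_to_chains.get(role, [])
    )
    if not tetramer_ids:
        return {}
    alpha_ids = sorted(role_to_chains.get("eIF2B_alpha", []))
    centroids = {cid: model.chain(cid).centroid for cid in tetramer_ids}
    if len(alpha_ids) == 2:
        anchors = [model.chain(alpha_ids[0]).centroid, model.chain(alpha_ids[1]).centroid]
    else:
        # no α pair: seed two groups from the most distant βδγε chain pair
        ids = tetramer_ids
        best = (0.0, ids[0], ids[0])
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                d = float(np.linalg.norm(centroids[a] - centroids[b]))
                if d > best[0]:
                    best = (d, a, b)
        anchors = [centroids[best[1]], centroids[best[2]]]
    tags = {}
    for cid in tetramer_ids:
        d0 = np.linalg.norm(centroids[cid] - anchors[0])
        d1 = np.linalg.norm(centroids[cid] - anchors[1])
        tags[cid] = "unit1" if d0 <= d1 else "unit2"
    for role in TETRAMER_ROLES:
        ids = role_to_chains.get(role, [])
        if len(ids) == 2 and tags[ids[0]] == tags[ids[1]]:
            raise AssignmentError(
                f"both {role} chains ({ids}) fell into protomer {tags[ids[0]]}"
            )
    return tags


# ---------------------------------------------------------------------------
# selections


@dataclass(frozen=True)
class ShellSpec:
    """All-role Cα shell within ``radius_A`` of a ligand, defined in a
    designated reference entry and transferred by residue identity."""

    ligand_role: str
    radius_A: float
    reference_entry: str

    def __post_init__(self) -> None:
        if self.radius_A <= 0:
            raise SelectionError("shell radius must be > 0")


@dataclass(frozen=True)
class SelectionSpec:
    """Declarative atom selection: (role, residue ranges) or a ligand shell."""

    role: str | tuple[str, ...] = ()
    ranges: tuple[tuple[int, int], ...] = ()
    atom_name: str = "CA"
    shell: ShellSpec | None = None

    def __post_init__(self) -> None:
        if self.shell is None:
            if not self.role:
                raise SelectionError("selection needs a role (or a shell)")
            for lo, hi in self.ranges:
                if hi < lo:
                    raise SelectionError(f"empty residue range {lo}-{hi}")

    @property
    def roles(self) -> tuple[str, ...]:
        return (self.role,) if isinstance(self.role, str) else tuple(self.role)


@dataclass
class AtomSet:
    """Resolved selection: canonical-ordered atom records + coordinates.

    Records are ``(role, unit, chain_id, auth_resnum, atom_name)``; ``unit`` is
    the protomer tag for βδγε chains and ``"-"`` otherwise. Order is canonical
    (role, unit, residue number) so that two AtomSets resolved from the same
    spec in different entries pair positionally after :func:`pair_atom_sets`.
    """

    records: list[tuple[str, str, str, int, str]]
    xyz: np.ndarray  # (n, 3)
    entry_id: str
    spec: SelectionSpec | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        if len(self.records) != len(self.xyz):
            raise SelectionError("records/coordinates length mismatch")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def keys(self) -> list[tuple[str, str, int, str]]:
        """Identity keys used for cross-entry pairing (chain id excluded)."""
        return [(r[0], r[1], r[3], r[4]) for r in self.records]

    def subset(self, idx: Sequence[int]) -> "AtomSet":
        idx = list(idx)
        return AtomSet(
            [self.records[i] for i in idx],
            self.xyz[idx],
            self.entry_id,
            self.spec,
            list(self.warnings),
        )

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        rows = [
            dict(entry=self.entry_id, role=r, unit=u, chain=c, resnum=n, atom=a,
                 x=xyz[0], y=xyz[1], z=xyz[2])
            for (r, u, c, n, a), xyz in zip(self.records, self.xyz)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.3f")


def _sorted_atomset(records, xyz, entry_id, spec, warnings) -> AtomSet:
    order = sorted(range(len(records)), key=lambda i: records[i])
    return AtomSet([records[i] for i in order], np.asarray(xyz)[order] if records else
                   np.zeros((0, 3)), entry_id, spec, warnings)


def shell_residues(
    model: StructureModel,
    assignment: SubunitAssignment,
    ligand_role: str,
    radius_A: float,
) -> list[tuple[str, str, int]]:
    """(role, unit, resnum) of every Cα within ``radius_A`` of the ligand.

    Membership is a function of internal distances only, so it is invariant
    under any rigid transformation of the reference entry.
    """
    lig_chain_ids = assignment.role_to_chains.get(ligand_role, [])
    lig_xyz = [l.xyz for l in model.ligands if l.chain_id in lig_chain_ids]
    if not lig_xyz:
        raise SelectionError(
            f"ligand role {ligand_role!r} not present in {model.entry_id}"
        )
    lig = np.vstack(lig_xyz)
    members: list[tuple[str, str, int]] = []
    for chain in model.chains:
        role = assignment.role_of(chain.chain_id)
        if role is None:
            continue
        unit = assignment.protomer.get(chain.chain_id, "-")
        dmin = np.linalg.norm(chain.ca[:, None, :] - lig[None, :, :], axis=2).min(axis=1)
        for resnum in chain.auth_num[dmin <= radius_A]:
            members.append((role, unit, int(resnum)))
    return sorted(set(members))


def resolve_selection(
    model: StructureModel,
    assignment: SubunitAssignment,
    spec: SelectionSpec,
    protomer: str = "both",
    shell_reference: tuple[StructureModel, SubunitAssignment] | None = None,
) -> AtomSet:
    """Resolve a :class:`SelectionSpec` to concrete coordinates.

    Range selections return the residues of the requested role(s)/range(s)
    that are resolved in ``model``; if fewer than half of a requested range is
    resolved a low-coverage warning is carried in the AtomSet. Shell
    selections compute membership once in the reference entry and transfer it
    here by (role, unit, residue number) identity.
    """
    warnings: list[str] = []
    records: list[tuple[str, str, str, int, str]] = []
    xyz: list[np.ndarray] = []

    if spec.shell is not None:
        if shell_reference is None:
            raise SelectionError("shell selection needs shell_reference=(model, assignment)")
        ref_model, ref_assignment = shell_reference
        members = set(shell_residues(ref_model, ref_assignment, spec.shell.ligand_role,
                                     spec.shell.radius_A))
        for chain in model.chains:
            role = assignment.role_of(chain.chain_id)
            if role is None:
                continue
            unit = assignment.protomer.get(chain.chain_id, "-")
            if protomer != "both" and unit not in ("-", protomer):
                continue
            for i, resnum in enumerate(chain.auth_num):
                if (role, unit, int(resnum)) in members:
                    records.append((role, unit, chain.chain_id, int(resnum), spec.atom_name))
                    xyz.append(chain.ca[i])
        n_expected = len(members) if protomer == "both" else sum(
            1 for (_, u, _) in members if u in ("-", protomer))
        if n_expected and len(records) < 0.5 * n_expected:
            warnings.append(
                f"shell transfer covered {len(records)}/{n_expected} residues in "
                f"{model.entry_id}"
            )
        return _sorted_atomset(records, xyz, model.entry_id, spec, warnings)

    for role in spec.roles:
        chain_ids = assignment.chains_for(role, protomer)
        if not chain_ids and role in assignment.role_to_chains:
            if not assignment.role_to_chains[role]:
                raise SelectionError(f"role {role!r} not assigned in {model.entry_id}")
        for cid in chain_ids:
            chain = model.chain(cid)
            unit = assignment.protomer.get(cid, "-")
            ranges = spec.ranges or ((int(chain.auth_num.min()), int(chain.auth_num.max())),)
            for lo, hi in ranges:
                mask = (chain.auth_num >= lo) & (chain.auth_num <= hi)
                n_found = int(mask.sum())
                if n_found < 0.5 * (hi - lo + 1):
                    warnings.append(
                        f"{model.entry_id} {role} {cid} {lo}-{hi}: only "
                        f"{n_found}/{hi - lo + 1} residues resolved"
                    )
                for i in np.nonzero(mask)[0]:
                    records.append((role, unit, cid, int(chain.auth_num[i]), spec.atom_name))
                    xyz.append(chain.ca[i])
    return _sorted_atomset(records, xyz, model.entry_id, spec, warnings)


def resolve_many(
    model: StructureModel,
    assignment: SubunitAssignment,
    specs: Sequence[SelectionSpec],
    protomer: str = "both",
    shell_reference: tuple[StructureModel, SubunitAssignment] | None = None,
) -> AtomSet:
    """Resolve several selections and merge them into one canonical AtomSet
    (used for composite alignment frames spanning multiple roles/ranges)."""
    records, xyz, warnings = [], [], []
    for spec in specs:
        part = resolve_selection(model, assignment, spec, protomer, shell_reference)
        records.extend(part.records)
        xyz.extend(part.xyz)
        warnings.extend(part.warnings)
    return _sorted_atomset(records, xyz, model.entry_id, None, warnings)


def pair_atom_sets(a: AtomSet, b: AtomSet) -> tuple[AtomSet, AtomSet]:
    """Intersect two AtomSets on (role, unit, residue, atom) identity.

    Residues missing in either member are dropped (cryo-EM models have
    unmodelled loops); the result is a matched, equal-length, canonically
    ordered pair. Symmetric: ``pair(a, b)`` and ``pair(b, a)`` keep the same
    residue identities.
    """
    keys_a = {k: i for i, k in enumerate(a.keys)}
    keys_b = {k: i for i, k in enumerate(b.keys)}
    common = sorted(set(keys_a) & set(keys_b))
    if not common:
        raise SelectionError(
            f"no overlapping residues between {a.entry_id} and {b.entry_id}"
        )
    return a.subset([keys_a[k] for k in common]), b.subset([keys_b[k] for k in common])


_DESCRIPTION_KEYWORDS: list[tuple[tuple[str, ...], str]] = [
    (("2b", "alpha"), "eIF2B_alpha"),
    (("2b", "beta"), "eIF2B_beta"),
    (("2b", "gamma"), "eIF2B_gamma"),
    (("2b", "delta"), "eIF2B_delta"),
    (("2b", "epsilon"), "eIF2B_eps"),
    (("factor 2", "subunit 1"), "eIF2_alpha"),
    (("factor 2", "alpha"), "eIF2_alpha"),
    (("factor 2", "subunit 3"), "eIF2_gamma"),
    (("factor 2", "gamma"), "eIF2_gamma"),
]


def reference_library_from_entry(path: str | Path) -> dict[str, str]:
    """Derive a role → sequence reference library from an annotated mmCIF
    entry, using the deposited entity descriptions to name the roles.

    Useful for bootstrapping role assignment across a set of related entries
    from a single well-annotated one (e.g. the complex containing every
    subunit); entities whose description matches no known role are skipped.
    """
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()
    descriptions = dict(
        zip(
            (str(v) for v in block.find_values("_entity.id")),
            (gemmi.cif.as_string(v).lower() for v in block.find_values("_entity.pdbx_description")),
        )
    )
    chain_entity: dict[str, str] = {}
    table = block.find(["_atom_site.auth_asym_id", "_atom_site.label_entity_id"])
    for row in table:
        chain_entity.setdefault(row[0], row[1])
    model = load_structure(path)
    library: dict[str, str] = {}
    for chain in model.chains:
        desc = descriptions.get(chain_entity.get(chain.chain_id, ""), "")
        for keywords, role in _DESCRIPTION_KEYWORDS:
            if all(k in desc for k in keywords):
                if role not in library or len(chain.sequence) > len(library[role]):
                    library[role] = chain.sequence
                break
    return library


# ---------------------------------------------------------------------------
# retrieval

_RCSB_URL = "https://files.rcsb.org/download/{acc}.cif"


def fetch_structures(
    accessions: Iterable[str], directory: str | Path, timeout: float = 30.0
) -> list[Path]:
    """Download mmCIF files from the PDB into ``directory`` (cached: existing
    files are never re-downloaded)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for acc in accessions:
        acc = acc.upper()
        dest = directory / f"{acc}.cif"
        if not dest.exists():
            url = _RCSB_URL.format(acc=acc)
            with urllib.request.urlopen(url, timeout=timeout) as resp:
                data = resp.read()
            dest.write_bytes(data)
        paths.append(dest)
    return paths
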