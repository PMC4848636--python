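"""Per-residue solvent accessibility and interatomic contacts from coordinates.

Accessible surface area (ASA) is computed with the Shrake-Rupley rolling-probe
method: each heavy atom is covered with a deterministic golden-spiral point
set on a sphere of radius (r_vdw + probe); points buried inside any
neighbouring expanded sphere are removed, and the atom's ASA is the exposed
point fraction times the sphere area.  Residue ASA is the sum over its atoms.

Relative ASA follows the "residue in a vacuum" convention: the residue's ASA
in the full structure divided by the ASA of the very same residue extracted
alone in its observed conformation (not an extended Gly-X-Gly reference),
expressed in percent.  A residue is called fully exposed when relative
ASA > 50%, the criterion consumed by the motif exposure filter.

Contacts are unordered heavy-atom pairs from different residues within a
distance cutoff (default 4.0 A), labelled backbone-backbone, backbone-side
chain or side chain-side chain (backbone = N, CA, C, O).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "StructureModel",
    "ExposureTable",
    "Contact",
    "ContactList",
    "StructureError",
    "DEFAULT_RADII",
    "PROBE_RADIUS",
    "N_SPHERE_POINTS",
    "golden_spiral_points",
    "shrake_rupley_asa",
    "relative_asa",
    "relative_asa_table",
    "interatomic_contacts",
]


class StructureError(ValueError):
    """Invalid structural input."""


#: Van der Waals radii (A) by element; user-overridable per call.
DEFAULT_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}

PROBE_RADIUS = 1.4  # A, water probe
N_SPHERE_POINTS = 960

_BACKBONE_ATOMS = {"N", "CA", "C", "O"}


@dataclass(frozen=True)
class Atom:
    chain: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain, self.residue_number)

    @property
    def is_backbone(self) -> bool:
        return self.atom_name in _BACKBONE_ATOMS


@dataclass(frozen=True)
class StructureModel:
    """A list of (heavy) atoms with chain/residue bookkeeping."""

    atoms: tuple[Atom, ...]
    source: str = ""

    def __post_init__(self) -> None:
        for a in self.atoms:
            if not all(math.isfinite(v) for v in (a.x, a.y, a.z)):
                raise StructureError(
                    f"non-finite coordinates for atom {a.atom_name} "
                    f"{a.chain}/{a.residue_number}"
                )

    def coordinates(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def residues(self) -> list[tuple[str, int]]:
        seen: dict[tuple[str, int], None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_key)
        return list(seen)

    def residue_atoms(self, key: tuple[str, int]) -> "StructureModel":
        return StructureModel(
            atoms=tuple(a for a in self.atoms if a.residue_key == key),
            source=self.source,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "StructureModel":
        xyz = self.coordinates() @ np.asarray(rotation).T + translation
        atoms = tuple(
            Atom(a.chain, a.residue_number, a.residue_name, a.atom_name,
                 a.element, *map(float, p))
            for a, p in zip(self.atoms, xyz)
        )
        return StructureModel(atoms=atoms, source=self.source)


@dataclass(frozen=True)
class ExposureTable:
    """Per-residue absolute (A^2) and relative (%) ASA with method metadata."""

    absolute: Mapping[tuple[str, int], float]
    relative: Mapping[tuple[str, int], float]
    residue_names: Mapping[tuple[str, int], str]
    probe_radius: float
    n_points: int
    reference_convention: str = "isolated-residue-observed-conformation"

    def exposed(self, threshold: float = 50.0) -> list[tuple[str, int]]:
        return [k for k, v in self.relative.items() if v > threshold]


@dataclass(frozen=True)
class Contact:
    atom_a: Atom
    atom_b: Atom
    distance: float
    kind: str  # backbone-backbone | backbone-sidechain | sidechain-sidechain


@dataclass(frozen=True)
class ContactList:
    contacts: tuple[Contact, ...]
    cutoff: float

    def pair_keys(self) -> set[tuple]:
        keys = set()
        for c in self.contacts:
            a = (c.atom_a.chain, c.atom_a.residue_number, c.atom_a.atom_name)
            b = (c.atom_b.chain, c.atom_b.residue_number, c.atom_b.atom_name)
            keys.add(tuple(sorted((a, b))))
        return keys


# ---------------------------------------------------------------------------
# Shrake-Rupley
# ---------------------------------------------------------------------------


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic, nearly-uniform unit-sphere point set (golden spiral)."""
    if n < 1:
        raise StructureError("need at least one sphere point")
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = k * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _atom_radii(
    model: StructureModel, radii: Mapping[str, float]
) -> np.ndarray:
    out = np.empty(len(model.atoms))
    missing = []
    for i, a in enumerate(model.atoms):
        r = radii.get(a.element.upper())
        if r is None:
            missing.append(f"{a.atom_name} ({a.element}) "
                           f"{a.chain}/{a.residue_number}")
        else:
            out[i] = r
    if missing:
        raise StructureError(
            "no van der Waals radius for atoms: " + "; ".join(missing)
        )
    return out


def shrake_rupley_asa(
    model: StructureModel,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
    radii: Mapping[str, float] = DEFAULT_RADII,
) -> tuple[np.ndarray, dict[tuple[str, int], float]]:
    """Absolute solvent-accessible surface area, per atom and per residue.

    Deterministic for a fixed point count (the golden-spiral set has no
    random state).  Returns ``(per_atom_A2, per_residue_A2)``.
    """
    if not model.atoms:
        raise StructureError("empty structure model")
    if probe_radius < 0:
        raise StructureError("probe radius must be non-negative")
    xyz = model.coordinates()
    r_exp = _atom_radii(model, radii) + probe_radius
    sphere = golden_spiral_points(n_points)

    tree = cKDTree(xyz)
    max_reach = 2.0 * r_exp.max()
    per_atom = np.zeros(len(model.atoms))
    for i in range(len(model.atoms)):
        pts = xyz[i] + r_exp[i] * sphere
        neighbours = [j for j in tree.query_ball_point(xyz[i], max_reach)
                      if j != i]
        if neighbours:
            centers = xyz[neighbours]
            rads = r_exp[neighbours]
            d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (rads**2)[None, :]).any(axis=1)
            exposed_frac = 1.0 - buried.mean()
        else:
            exposed_frac = 1.0
        per_atom[i] = exposed_frac * 4.0 * math.pi * r_exp[i] ** 2

    per_residue: dict[tuple[str, int], float] = {}
    for a, asa in zip(model.atoms, per_atom):
        per_residue[a.residue_key] = per_residue.get(a.residue_key, 0.0) + asa
    return per_atom, per_residue


def relative_asa(
    model: StructureModel,
    residue: tuple[str, int],
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
    radii: Mapping[str, float] = DEFAULT_RADII,
) -> float:
    """Relative ASA (%) of one residue: in-structure over isolated reference.

    The reference is the same residue extracted alone in its observed
    conformation ("in a vacuum"); the ratio can exceed 100% only through
    sampling noise and is not clipped.
    """
    alone = model.residue_atoms(residue)
    if not alone.atoms:
        raise StructureError(f"residue {residue} not present in model")
    _, full = shrake_rupley_asa(model, probe_radius, n_points, radii)
    _, ref = shrake_rupley_asa(alone, probe_radius, n_points, radii)
    reference = ref[residue]
    if reference <= 0:
        raise StructureError(f"zero reference ASA for residue {residue}")
    return 100.0 * full[residue] / reference


def relative_asa_table(
    model: StructureModel,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
    radii: Mapping[str, float] = DEFAULT_RADII,
) -> ExposureTable:
    """Absolute and relative ASA for every residue of a model."""
    _, full = shrake_rupley_asa(model, probe_radius, n_points, radii)
    relative: dict[tuple[str, int], float] = {}
    names: dict[tuple[str, int], str] = {}
    for key in model.residues():
        alone = model.residue_atoms(key)
        _, ref = shrake_rupley_asa(alone, probe_radius, n_points, radii)
        relative[key] = 100.0 * full[key] / ref[key]
        names[key] = alone.atoms[0].residue_name
    return ExposureTable(
        absolute=dict(full),
        relative=relative,
        residue_names=names,
        probe_radius=probe_radius,
        n_points=n_points,
    )


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------


def interatomic_contacts(
    model: StructureModel, cutoff: float = 4.0
) -> ContactList:
    """All inter-residue heavy-atom pairs within ``cutoff`` A, labelled by
    backbone membership."""
    if cutoff <= 0:
        raise StructureError("cutoff must be positive")
    xyz = model.coordinates()
    tree = cKDTree(xyz)
    contacts: list[Contact] = []
    for i, j in sorted(tree.query_pairs(cutoff)):
        a, b = model.atoms[i], model.atoms[j]
        if a.residue_key == b.residue_key:
            continue
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        if a.is_backbone and b.is_backbone:
            kind = "backbone-backbone"
        elif a.is_backbone or b.is_backbone:
            kind = "backbone-sidechain"
        else:
            kind = "sidechain-sidechain"
        contacts.append(Contact(atom_a=a, atom_b=b, distance=d, kind=kind))
    return ContactList(contacts=tuple(contacts), cutoff=cutoff)
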