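"""Sequences, PDB structure I/O, nucleobase reference frames, and idealized
B-DNA / G-quadruplex fixture geometries.

The geometry builders produce *idealized* stacked-chromophore arrangements
(fiber-model rise/twist, square-planar G-tetrads) intended as controlled
inputs for exciton-model CD calculations, not as substitutes for MD-derived
ensembles.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile


class StructureError(ValueError):
    """Raised for malformed sequences, structures, or geometry recipes."""


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

_BASES = frozenset("ACGT")

#: complement map for duplex construction
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# characters stripped from decorated oligo strings: primes (ASCII and
# typographic), direction labels, digits 5/3 attached to them, dashes, spaces
_DECORATION = re.compile(r"5['′ʹ]?|3['′ʹ]?|[-‐‑–—\s]")


@dataclass(frozen=True)
class NucleicSequence:
    """A DNA sequence, 5'->3'."""

    id: str
    bases: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return "".join(self.bases)

    @property
    def complement(self) -> "NucleicSequence":
        """Watson-Crick complement, returned 5'->3'."""
        comp = tuple(COMPLEMENT[b] for b in reversed(self.bases))
        return NucleicSequence(self.id + "_comp", comp)


def parse_sequence(text: str, seq_id: str = "seq") -> NucleicSequence:
    """Parse a decorated oligonucleotide string such as
    ``5'-AAA GGG TTA GGG TTA GGG TTA GGG AA-3'``.

    Strips 5'/3' end labels, whitespace and hyphens; remaining characters
    must be A/C/G/T (case-insensitive).
    """
    stripped = _DECORATION.sub("", text).upper()
    if not stripped:
        raise StructureError(f"no base symbols found in {text!r}")
    for ch in stripped:
        if ch not in _BASES:
            raise StructureError(f"invalid base symbol {ch!r} in sequence {text!r}")
    return NucleicSequence(seq_id, tuple(stripped))


# ---------------------------------------------------------------------------
# Residues and models
# ---------------------------------------------------------------------------

# residue-name dialects accepted on input, normalized to one-letter
_RESNAME_MAP = {
    "A": "A", "DA": "A", "ADE": "A", "DA5": "A", "DA3": "A",
    "G": "G", "DG": "G", "GUA": "G", "DG5": "G", "DG3": "G",
    "C": "C", "DC": "C", "CYT": "C", "DC5": "C", "DC3": "C",
    "T": "T", "DT": "T", "THY": "T", "DT5": "T", "DT3": "T",
}

#: residue names treated as the ligand dummy chromophore
LIGAND_RESNAMES = {"LIG", "CHE"}

# ring atoms used for the plane fit, and the ordered hexagon cycle used to
# fix the normal's sign (counterclockwise circulation defines +z)
PURINE_RING = ("N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6")
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")
RING_CYCLE = ("N1", "C2", "N3", "C4", "C5", "C6")

PURINES = {"A", "G"}


@dataclass
class BaseResidue:
    """One residue: name (A/C/G/T or LIG), atoms and coordinates (Angstrom)."""

    name: str
    chain: str
    number: int
    atom_names: list[str]
    coords: np.ndarray  # (n_atoms, 3)
    glycosidic: str | None = None  # "anti" / "syn" for G4 fixtures

    @property
    def is_ligand(self) -> bool:
        return self.name in LIGAND_RESNAMES

    def coord(self, atom: str) -> np.ndarray:
        try:
            i = self.atom_names.index(atom)
        except ValueError:
            raise StructureError(
                f"atom {atom!r} not present in residue {self.name} {self.number}"
            ) from None
        return self.coords[i]

    def has_atom(self, atom: str) -> bool:
        return atom in self.atom_names

    def transformed(self, rot: np.ndarray, trans: np.ndarray) -> "BaseResidue":
        return BaseResidue(
            self.name, self.chain, self.number, list(self.atom_names),
            self.coords @ rot.T + trans, self.glycosidic,
        )


@dataclass
class StructureModel:
    """One MODEL of a (possibly multi-model) structure."""

    model_index: int
    residues: list[BaseResidue] = field(default_factory=list)

    @property
    def nucleic_residues(self) -> list[BaseResidue]:
        return [r for r in self.residues if not r.is_ligand]

    @property
    def ligand_residues(self) -> list[BaseResidue]:
        return [r for r in self.residues if r.is_ligand]

    def all_coords(self) -> np.ndarray:
        return np.concatenate([r.coords for r in self.residues])


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def read_pdb_models(path) -> list[StructureModel]:
    """Read a PDB file into one :class:`StructureModel` per MODEL record.

    Residue names are normalized across dialects (DA/ADE/A...); water, ions
    and unrecognized het groups are dropped, ligand dummy residues (LIG/CHE)
    are kept. Raises :class:`StructureError` if no nucleic residues remain.
    """
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    models: list[StructureModel] = []
    for m, atoms in enumerate(stack):
        model = StructureModel(model_index=m)
        for res in struc.residue_iter(atoms):
            raw = res.res_name[0].strip().upper()
            if raw in _RESNAME_MAP:
                name = _RESNAME_MAP[raw]
            elif raw in LIGAND_RESNAMES:
                name = raw
            else:
                continue
            model.residues.append(
                BaseResidue(
                    name=name,
                    chain=str(res.chain_id[0]),
                    number=int(res.res_id[0]),
                    atom_names=[str(a) for a in res.atom_name],
                    coords=np.asarray(res.coord, dtype=float),
                )
            )
        if not np.all(np.isfinite(model.all_coords() if model.residues else np.zeros(1))):
            raise StructureError(f"non-finite coordinates in model {m}")
        models.append(model)
    if all(not m.nucleic_residues for m in models):
        raise StructureError(f"no nucleic residues found in {path}")
    return models


def _element_of(atom_name: str) -> str:
    stripped = atom_name.strip("0123456789'")
    return stripped[0] if stripped else "C"


def write_pdb(path, models: list[StructureModel]) -> None:
    """Write models to a PDB file (multi-MODEL when more than one)."""
    arrays = []
    for model in models:
        n = sum(len(r.atom_names) for r in model.residues)
        atoms = struc.AtomArray(n)
        i = 0
        for res in model.residues:
            for name, xyz in zip(res.atom_names, res.coords):
                atoms.chain_id[i] = res.chain
                atoms.res_id[i] = res.number
                atoms.res_name[i] = res.name
                atoms.atom_name[i] = name
                atoms.element[i] = _element_of(name)
                atoms.hetero[i] = res.is_ligand
                atoms.coord[i] = xyz
                i += 1
        arrays.append(atoms)
    pdb = PDBFile()
    pdb.set_structure(struc.stack(arrays) if len(arrays) > 1 else arrays[0])
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Base reference frames
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BaseFrame:
    """Right-handed orthonormal frame attached to a nucleobase.

    origin: ring centroid; z: ring-plane normal with sign fixed by the
    circulation of the hexagon cycle; x: glycosidic direction (C1'->N9 for
    purines, C1'->N1 for pyrimidines) projected into the plane; y = z cross x.
    """

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray


def base_frame(residue: BaseResidue) -> BaseFrame:
    if residue.is_ligand:
        raise StructureError("base_frame is defined for nucleobases only")
    ring_names = PURINE_RING if residue.name in PURINES else PYRIMIDINE_RING
    ring = [residue.coord(a) for a in ring_names if residue.has_atom(a)]
    if len(ring) < 6:
        raise StructureError(
            f"residue {residue.name} {residue.number} has fewer than 6 ring atoms"
        )
    ring = np.array(ring)
    origin = ring.mean(axis=0)
    centered = ring - origin
    # least-squares plane normal = singular vector of smallest singular value
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-6:
        raise StructureError("degenerate (collinear) ring atom set")
    normal = vt[2]
    # fix sign from the circulation of the ordered hexagon cycle; this is
    # intrinsic to the atom geometry, hence equivariant under rotations
    cyc = np.array([residue.coord(a) for a in RING_CYCLE if residue.has_atom(a)])
    cyc = cyc - origin
    circ = np.cross(cyc, np.roll(cyc, -1, axis=0)).sum(axis=0)
    if np.dot(normal, circ) < 0:
        normal = -normal
    z = normal / np.linalg.norm(normal)

    attach = "N9" if residue.name in PURINES else "N1"
    x_raw = residue.coord(attach) - residue.coord("C1'")
    x = x_raw - np.dot(x_raw, z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-8:
        raise StructureError("glycosidic bond parallel to plane normal")
    x = x / nx
    y = np.cross(z, x)
    return BaseFrame(origin=origin, x_axis=x, y_axis=y, z_axis=z)


# ---------------------------------------------------------------------------
# Idealized geometry templates
# ---------------------------------------------------------------------------

_RING_BOND = 1.38  # aromatic ring bond length, Angstrom
_GLYCO_BOND = 1.47  # C1'-N bond length, Angstrom


def _regular_polygon_on_edge(p0: np.ndarray, p1: np.ndarray, n: int,
                             away_from: np.ndarray) -> list[np.ndarray]:
    """Vertices of a planar regular n-gon (in the xy-plane) whose first edge
    is p0->p1, bulging away from `away_from`. Returns all n vertices,
    starting with p0, p1."""
    s = np.linalg.norm(p1 - p0)
    mid = 0.5 * (p0 + p1)
    e = (p1 - p0) / s
    nrm = np.array([-e[1], e[0], 0.0])
    if np.linalg.norm(mid + nrm - away_from) < np.linalg.norm(mid - nrm - away_from):
        nrm = -nrm
    center = mid + (s / (2.0 * np.tan(np.pi / n))) * nrm
    ang = 2.0 * np.pi / n
    v0 = p0 - center
    sign = 1.0
    if np.linalg.norm(_rot_z(ang) @ v0 + center - p1) > np.linalg.norm(
        _rot_z(-ang) @ v0 + center - p1
    ):
        sign = -1.0
    return [center + _rot_z(sign * k * ang) @ v0 for k in range(n)]


def _base_template(base: str) -> tuple[list[str], np.ndarray]:
    """Planar template of a nucleobase in the xy-plane.

    Ring geometry is idealized (regular polygons, 1.38 A bonds); this is a
    fixture for exciton calculations, where only planarity, centroid and
    glycosidic direction matter. The template is positioned with ring
    centroid at the origin and the frame x-axis (C1'->N9 / C1'->N1) along +x.
    """
    # hexagon N1 C2 N3 C4 C5 C6, counterclockwise, radius = bond length
    hex_names = list(RING_CYCLE)
    ang = np.deg2rad(90 + 60 * np.arange(6))
    hexagon = np.stack(
        [_RING_BOND * np.cos(ang), _RING_BOND * np.sin(ang), np.zeros(6)], axis=1
    )
    names = list(hex_names)
    coords = [hexagon[i] for i in range(6)]
    if base in PURINES:
        # fuse pentagon on the C4-C5 edge: cycle C4-C5-N7-C8-N9
        c4, c5 = hexagon[3], hexagon[4]
        penta = _regular_polygon_on_edge(c4, c5, 5, away_from=np.zeros(3))
        names += ["N7", "C8", "N9"]
        coords += [penta[2], penta[3], penta[4]]
        attach_idx = names.index("N9")
    else:
        attach_idx = names.index("N1")
    ring_arr = np.array(coords)
    ring_centroid = ring_arr.mean(axis=0)
    # C1' radially outward from the ring centroid through the attachment atom
    v = ring_arr[attach_idx] - ring_centroid
    v = v / np.linalg.norm(v)
    c1p = ring_arr[attach_idx] + _GLYCO_BOND * v
    names.append("C1'")
    coords.append(c1p)
    arr = np.array(coords) - ring_centroid
    # orient so that C1'->attach (the frame x-axis) points along +x
    xdir = arr[attach_idx] - arr[-1]
    xdir = xdir / np.linalg.norm(xdir)
    theta = np.arctan2(xdir[1], xdir[0])
    arr = arr @ _rot_z(-theta).T
    # guarantee counterclockwise hexagon circulation (+z normal)
    cyc = arr[:6]
    circ = np.cross(cyc, np.roll(cyc, -1, axis=0)).sum(axis=0)
    if circ[2] < 0:
        arr = arr * np.array([1.0, -1.0, 1.0])
    return names, arr


def _ligand_template() -> tuple[list[str], np.ndarray]:
    """Planar dummy chromophore: a hexagonal ring plus one 'cationic-N'
    marker atom (NC) offset in-plane along +x."""
    ang = np.deg2rad(60 * np.arange(6))
    ring = np.stack([1.4 * np.cos(ang), 1.4 * np.sin(ang), np.zeros(6)], axis=1)
    names = [f"C{i+1}" for i in range(6)] + ["NC"]
    coords = np.vstack([ring, [2.8, 0.0, 0.0]])
    return names, coords


def _rot_z(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_x(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


# ---------------------------------------------------------------------------
# Recipes and builders
# ---------------------------------------------------------------------------

DUPLEX_POSES = {"none", "intercalated_left", "intercalated_right"}
G4_POSES = {"none", "end_stack_in", "end_stack_edge"}
TOPOLOGIES = ("parallel", "antiparallel", "hybrid")


@dataclass
class GeometryRecipe:
    """Recipe for an idealized structure.

    kind: "duplex" or "g4". For duplexes give `sequence` (strand 1, 5'->3');
    for G4 give `n_tetrads` (>= 2) and a `topology`. `rise` (A) and `twist`
    (deg) are the per-step helical parameters; defaults are fiber-model B-DNA
    and typical G4 stacking values.
    """

    kind: str
    sequence: str | NucleicSequence | None = None
    n_tetrads: int = 3
    topology: str = "parallel"
    rise: float | None = None
    twist: float | None = None
    ligand_pose: str = "none"

    def __post_init__(self):
        if self.kind not in ("duplex", "g4"):
            raise StructureError(f"unknown recipe kind {self.kind!r}")
        if self.rise is None:
            self.rise = 3.38 if self.kind == "duplex" else 3.3
        if self.twist is None:
            self.twist = 36.0 if self.kind == "duplex" else 30.0
        if self.rise <= 0:
            raise StructureError("rise must be positive")
        if not -180.0 < self.twist <= 180.0:
            raise StructureError("twist must lie in (-180, 180]")
        if self.kind == "g4":
            if self.n_tetrads < 2:
                raise StructureError("a G-quadruplex requires at least 2 tetrads")
            if self.topology not in TOPOLOGIES:
                raise StructureError(f"unknown topology {self.topology!r}")
            if self.ligand_pose not in G4_POSES:
                raise StructureError(
                    f"pose {self.ligand_pose!r} not supported for g4"
                )
        else:
            if self.ligand_pose not in DUPLEX_POSES:
                raise StructureError(
                    f"pose {self.ligand_pose!r} not supported for duplex"
                )


_PAIR_HALF_SPAN = 2.9  # base centroid distance from helix axis, Angstrom
_POCKET_LATERAL = 1.5  # ligand lateral offset in an intercalation pocket, A
_STACK_GAP = 3.4  # ligand stacking distance above a terminal tetrad, A


def build_ideal_duplex(recipe: GeometryRecipe) -> StructureModel:
    """Idealized B-form double helix along +z with the requested rise and
    twist; optional intercalated planar dummy chromophore.

    Chain A holds strand 1 (5'->3' bottom to top), chain B its complement.
    Successive base-pair origins (midpoints of the two ring centroids) sit on
    the helix axis, `rise` apart, rotated by `twist`. An intercalation pocket
    at the central step doubles the local rise and inserts a LIG residue at
    mid-gap with a left/right lateral offset; the two poses are exact mirror
    images of each other across the plane containing the helix axis and the
    pocket x-axis (DNA atoms identical).
    """
    if recipe.kind != "duplex":
        raise StructureError("recipe.kind must be 'duplex'")
    seq = recipe.sequence
    if seq is None:
        raise StructureError("duplex recipe requires a sequence")
    if isinstance(seq, str):
        seq = parse_sequence(seq)
    n = len(seq)
    twist = np.deg2rad(recipe.twist)
    pocket = None
    if recipe.ligand_pose in ("intercalated_left", "intercalated_right"):
        if n < 2:
            raise StructureError("intercalation requires at least 2 base pairs")
        pocket = n // 2 - 1  # pocket between steps pocket and pocket+1

    strand_a: list[BaseResidue] = []
    strand_b: list[BaseResidue] = []
    z = 0.0
    for i, base in enumerate(seq.bases):
        theta = i * twist
        rot = _rot_z(theta)
        names_a, tpl_a = _base_template(base)
        # glycosidic x-axis points toward the axis: centroid at +x, x to -x
        coords_a = (tpl_a @ _rot_z(np.pi).T + np.array([_PAIR_HALF_SPAN, 0, 0]))
        comp = COMPLEMENT[base]
        names_b, tpl_b = _base_template(comp)
        coords_b = (tpl_b @ _rot_z(np.pi).T + np.array([_PAIR_HALF_SPAN, 0, 0]))
        coords_b = coords_b @ _rot_y(np.pi).T  # pair dyad: antiparallel partner
        trans = np.array([0.0, 0.0, z])
        strand_a.append(
            BaseResidue(base, "A", i + 1, names_a, coords_a @ rot.T + trans)
        )
        strand_b.append(
            BaseResidue(comp, "B", n - i, names_b, coords_b @ rot.T + trans)
        )
        z += recipe.rise * (2.0 if pocket is not None and i == pocket else 1.0)

    model = StructureModel(model_index=0)
    model.residues = strand_a + list(reversed(strand_b))

    if pocket is not None:
        lig_names, lig_tpl = _ligand_template()
        theta_p = (pocket + 0.5) * twist
        z_lig = pocket * recipe.rise + recipe.rise  # mid-gap of the doubled step
        offset = np.array([0.0, _POCKET_LATERAL, 0.0])
        lig = lig_tpl + offset
        if recipe.ligand_pose == "intercalated_left":
            lig = lig * np.array([1.0, -1.0, 1.0])  # mirror across pocket plane
        rot = _rot_z(theta_p)
        lig = lig @ rot.T + np.array([0.0, 0.0, z_lig])
        model.residues.append(BaseResidue("LIG", "L", 1, lig_names, lig))
    return model


def base_pair_origins(model: StructureModel) -> np.ndarray:
    """Midpoints of paired ring centroids for a duplex built by
    :func:`build_ideal_duplex` (pairing by residue number on chains A/B)."""
    a = {r.number: r for r in model.nucleic_residues if r.chain == "A"}
    b = {r.number: r for r in model.nucleic_residues if r.chain == "B"}
    n = len(a)
    origins = []
    for i in sorted(a):
        ra, rb = a[i], b[n - i + 1]
        ca = base_frame(ra).origin
        cb = base_frame(rb).origin
        origins.append(0.5 * (ca + cb))
    return np.array(origins)


# glycosidic patterns around one quartet, by topology
_G4_PATTERNS = {
    "parallel": ("anti", "anti", "anti", "anti"),
    "antiparallel": ("anti", "syn", "anti", "syn"),
    "hybrid": ("anti", "anti", "syn", "anti"),
}

_QUARTET_RADIUS = 4.0  # guanine ring-centroid distance from the G4 axis, A


def build_ideal_g4(recipe: GeometryRecipe) -> StructureModel:
    """Idealized G-quadruplex: `n_tetrads` stacked square-planar guanine
    quartets along +z, inter-tetrad rise/twist per the recipe, glycosidic
    (syn/anti) pattern per topology, optional end-stacked dummy chromophore.

    Syn guanines are flipped 180 deg about their glycosidic x-axis and
    annotated via ``BaseResidue.glycosidic``. An end-stacked LIG residue sits
    one stacking distance above the top tetrad; pose "in" orients its NC
    marker toward the central axis, "edge" toward the periphery.
    """
    if recipe.kind != "g4":
        raise StructureError("recipe.kind must be 'g4'")
    pattern = _G4_PATTERNS[recipe.topology]
    twist = np.deg2rad(recipe.twist)
    chains = "ABCD"
    model = StructureModel(model_index=0)
    names_g, tpl_g = _base_template("G")
    for t in range(recipe.n_tetrads):
        z = t * recipe.rise
        for k in range(4):
            glyc = pattern[k]
            coords = tpl_g.copy()
            if glyc == "syn":
                coords = coords @ _rot_x(np.pi).T
            # Hoogsteen-like placement: glycosidic direction roughly
            # tangential, centroid at the quartet radius
            coords = coords @ _rot_z(np.deg2rad(135.0)).T
            coords = coords + np.array([_QUARTET_RADIUS, 0.0, 0.0])
            rot = _rot_z(t * twist + k * np.pi / 2)
            coords = coords @ rot.T + np.array([0.0, 0.0, z])
            model.residues.append(
                BaseResidue("G", chains[k], t + 1, names_g, coords, glycosidic=glyc)
            )
    if recipe.ligand_pose in ("end_stack_in", "end_stack_edge"):
        lig_names, lig_tpl = _ligand_template()
        z_top = (recipe.n_tetrads - 1) * recipe.rise + _STACK_GAP
        center = np.array([1.5, 0.0, z_top])
        # NC marker lies along the template +x from the ring; point it toward
        # the axis ("in") or away from it ("edge")
        if recipe.ligand_pose == "end_stack_in":
            lig = lig_tpl @ _rot_z(np.pi).T + center
        else:
            lig = lig_tpl + center
        model.residues.append(BaseResidue("LIG", "L", 1, lig_names, lig))
    return model


def build_from_recipe(recipe: GeometryRecipe) -> StructureModel:
    return build_ideal_duplex(recipe) if recipe.kind == "duplex" else build_ideal_g4(recipe)


# ---------------------------------------------------------------------------
# Ensemble fixtures
# ---------------------------------------------------------------------------

def jitter_model(model: StructureModel, rng: np.random.Generator,
                 rot_sd_deg: float = 3.0, trans_sd: float = 0.15) -> StructureModel:
    """Apply independent small rigid perturbations to every residue: a random
    rotation about the residue centroid (axis uniform, angle ~ N(0, rot_sd))
    and a Gaussian translation. Emulates thermal disorder of a snapshot
    ensemble without any molecular dynamics."""
    out = StructureModel(model_index=model.model_index)
    for res in model.residues:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = np.deg2rad(rng.normal(0.0, rot_sd_deg))
        K = np.array([
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ])
        rot = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
        centroid = res.coords.mean(axis=0)
        coords = (res.coords - centroid) @ rot.T + centroid
        coords = coords + rng.normal(0.0, trans_sd, size=3)
        out.residues.append(
            BaseResidue(res.name, res.chain, res.number, list(res.atom_names),
                        coords, res.glycosidic)
        )
    return out


def snapshot_ensemble(recipe: GeometryRecipe, n_snapshots: int,
                      seed: int, rot_sd_deg: float = 3.0,
                      trans_sd: float = 0.15) -> list[StructureModel]:
    """Generate a jittered ensemble from an ideal recipe (fixture stand-in
    for representative, uncorrelated MD snapshots)."""
    if n_snapshots < 1:
        raise StructureError("n_snapshots must be >= 1")
    rng = np.random.default_rng(seed)
    ideal = build_from_recipe(recipe)
    models = []
    for i in range(n_snapshots):
        m = jitter_model(ideal, rng, rot_sd_deg, trans_sd)
        m.model_index = i
        models.append(m)
    return models
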