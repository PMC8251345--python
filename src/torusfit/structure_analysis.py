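"""Crystal-structure analysis: surfaces, interfaces, solvent content.

Quantifies the claims one makes about a crystal form of a ring-forming
oligomer: how much surface an interface buries (total change in
solvent-accessible surface area over both partners), what stabilizes it
(hydrogen bonds, salt bridges, hydrophobic burial), and whether a given
chain length is compatible with the unit cell (Matthews coefficient and
solvent fraction).

Buried-area convention: TOTAL delta-SASA summed over both partners; divide
by two for the per-partner (interface-area) convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .assembly import RigidTransform
from .errors import InvalidArgumentError

__all__ = [
    "AtomStructure",
    "CrystalForm",
    "InterfaceReport",
    "read_structure",
    "write_structure",
    "shrake_rupley",
    "buried_surface",
    "interface_contacts",
    "matthews_solvent",
    "apply_symmetry",
]

# van der Waals radii, Angstrom
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_RADIUS = 1.70

HYDROPHILIC_SIDECHAIN_N = {"NE", "NH1", "NH2", "NZ", "ND1", "NE2", "ND2"}
ACIDIC_SIDECHAIN_O = {"OD1", "OD2", "OE1", "OE2"}
BASIC_RESIDUES = {"ARG", "LYS", "HIS"}
ACIDIC_RESIDUES = {"ASP", "GLU"}


@dataclass
class AtomStructure:
    """Flat atom table of a (possibly multi-chain) structure."""

    element: np.ndarray      # str
    atom_name: np.ndarray    # str
    res_name: np.ndarray     # str
    res_id: np.ndarray       # int
    chain_id: np.ndarray     # str
    coords: np.ndarray       # (n, 3) float, Angstrom
    occupancy: np.ndarray    # float
    source: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise InvalidArgumentError("coordinates must be finite")
        if any(not c for c in np.asarray(self.chain_id)):
            raise InvalidArgumentError("chain ids must be non-empty")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def select_chains(self, chains) -> np.ndarray:
        """Boolean mask of atoms belonging to the given chain ids."""
        chains = set(chains)
        return np.array([c in chains for c in self.chain_id])

    def subset(self, mask: np.ndarray) -> "AtomStructure":
        return AtomStructure(
            element=self.element[mask], atom_name=self.atom_name[mask],
            res_name=self.res_name[mask], res_id=self.res_id[mask],
            chain_id=self.chain_id[mask], coords=self.coords[mask],
            occupancy=self.occupancy[mask], source=self.source,
        )

    def radii(self, probe: float = 0.0) -> np.ndarray:
        return np.array([
            VDW_RADII.get(str(e).upper(), DEFAULT_RADIUS) + probe
            for e in self.element
        ])


@dataclass
class CrystalForm:
    """Unit cell plus asymmetric-unit content for solvent-content analysis."""

    cell_lengths: tuple[float, float, float]
    cell_angles: tuple[float, float, float] = (90.0, 90.0, 90.0)
    asu_multiplicity: int = 1        # space-group general positions
    chains_per_asu: int = 1
    chain_mass: float = 1.0          # Da
    partial_specific_volume: float = 0.742  # cm^3/g

    def __post_init__(self):
        if any(a <= 0 for a in self.cell_lengths) or self.asu_multiplicity < 1:
            raise InvalidArgumentError("cell lengths positive, multiplicity >= 1")
        if self.chain_mass <= 0:
            raise InvalidArgumentError("chain_mass must be positive")

    @property
    def cell_volume(self) -> float:
        a, b, c = self.cell_lengths
        al, be, ga = np.radians(self.cell_angles)
        cos = np.cos([al, be, ga])
        return a * b * c * float(np.sqrt(
            1 - cos[0]**2 - cos[1]**2 - cos[2]**2 + 2 * cos[0] * cos[1] * cos[2]
        ))


@dataclass
class InterfaceReport:
    """Buried surface and contact typing between two chain groups."""

    buried_total: float                       # A^2, total over both partners
    per_residue: dict[tuple[str, int, str], float]
    hbonds: list[tuple]
    salt_bridges: list[tuple]
    hydrophobic_fraction: float
    convention: str = "total delta-SASA over both partners"


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def _structure_from_gemmi(st: gemmi.Structure, source: str) -> AtomStructure:
    st.remove_alternative_conformations()  # keeps highest occupancy
    model = st[0]
    el, an, rn, ri, ci, xyz, occ = [], [], [], [], [], [], []
    for chain in model:
        for res in chain:
            for atom in res:
                el.append(atom.element.name.upper())
                an.append(atom.name)
                rn.append(res.name)
                ri.append(res.seqid.num)
                ci.append(chain.name)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                occ.append(atom.occ)
    if not xyz:
        raise InvalidArgumentError(f"no atoms parsed from {source!r}")
    return AtomStructure(
        element=np.array(el), atom_name=np.array(an), res_name=np.array(rn),
        res_id=np.array(ri, dtype=int), chain_id=np.array(ci),
        coords=np.array(xyz, dtype=float), occupancy=np.array(occ, dtype=float),
        source=source,
    )


def read_structure(path: str, fmt: str | None = None) -> AtomStructure:
    """Read a PDB or mmCIF file into an :class:`AtomStructure`.

    Alternative conformations are reduced to the highest-occupancy one.
    The format is taken from the extension unless ``fmt`` is given.
    """
    path = str(path)
    if fmt is None:
        fmt = "mmcif" if path.endswith((".cif", ".cif.gz", ".mmcif")) else "pdb"
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Mmcif)
        elif fmt == "pdb":
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Pdb)
        else:
            raise InvalidArgumentError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise InvalidArgumentError(f"cannot parse {path!r}: {exc}") from exc
    return _structure_from_gemmi(st, source=path)


def write_structure(structure: AtomStructure, path: str) -> None:
    """Write an :class:`AtomStructure` as PDB (or mmCIF for .cif paths)."""
    st = gemmi.Structure()
    st.name = "torusfit"
    model = gemmi.Model("1")
    current_chain = None
    chain = None
    res = None
    current_res = None
    for i in range(structure.n_atoms):
        cid = str(structure.chain_id[i])
        if cid != current_chain:
            chain = gemmi.Chain(cid)
            model.add_chain(chain)
            chain = model[-1]
            current_chain = cid
            current_res = None
        key = (cid, int(structure.res_id[i]), str(structure.res_name[i]))
        if key != current_res:
            res = gemmi.Residue()
            res.name = str(structure.res_name[i])
            res.seqid = gemmi.SeqId(int(structure.res_id[i]), " ")
            chain.add_residue(res)
            res = chain[-1]
            current_res = key
        atom = gemmi.Atom()
        atom.name = str(structure.atom_name[i])
        atom.element = gemmi.Element(str(structure.element[i]).capitalize())
        atom.occ = float(structure.occupancy[i])
        x, y, z = structure.coords[i]
        atom.pos = gemmi.Position(float(x), float(y), float(z))
        res.add_atom(atom)
    st.add_model(model)
    st.setup_entities()
    if str(path).endswith(".cif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


# --------------------------------------------------------------------------
# SASA
# --------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def shrake_rupley(structure: AtomStructure, probe: float = 1.4,
                  n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area (rolling-probe, numeric).

    Each atom's solvent-accessible sphere (vdW radius + probe) is sampled
    at ``n_points`` Fibonacci points; a point is accessible if it lies
    outside every neighbour's accessible sphere.  Deterministic for a
    fixed point count.
    """
    if structure.n_atoms == 0:
        raise InvalidArgumentError("structure has no atoms")
    radii = structure.radii(probe=probe)
    coords = structure.coords
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    rmax = radii.max()
    areas = np.empty(structure.n_atoms)
    for i in range(structure.n_atoms):
        neigh = tree.query_ball_point(coords[i], radii[i] + rmax)
        neigh = [j for j in neigh if j != i]
        pts = coords[i] + radii[i] * sphere
        if neigh:
            d2 = ((pts[:, None, :] - coords[neigh][None, :, :]) ** 2).sum(axis=2)
            buried = np.any(d2 < (radii[neigh] ** 2)[None, :], axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * frac
    return areas


# --------------------------------------------------------------------------
# interfaces
# --------------------------------------------------------------------------

def _check_groups(structure, group_a, group_b):
    group_a, group_b = set(group_a), set(group_b)
    if not group_a or not group_b:
        raise InvalidArgumentError("both chain groups must be non-empty")
    if group_a & group_b:
        raise InvalidArgumentError("chain groups must be disjoint")
    mask_a = structure.select_chains(group_a)
    mask_b = structure.select_chains(group_b)
    if not mask_a.any() or not mask_b.any():
        raise InvalidArgumentError("a chain group selected no atoms")
    return mask_a, mask_b


def buried_surface(
    structure: AtomStructure,
    group_a,
    group_b,
    probe: float = 1.4,
    n_points: int = 960,
    hbond_cutoff: float = 3.5,
    salt_cutoff: float = 4.0,
) -> InterfaceReport:
    """Interface between two chain groups: buried area and contact typing.

    ``buried_total = SASA(A alone) + SASA(B alone) - SASA(A union B)``,
    i.e. the total surface both partners lose on association; the
    per-residue map decomposes the same quantity, so its sum equals the
    total.  Hydrophobic fraction is the share of buried area on carbon
    and sulfur atoms.
    """
    mask_a, mask_b = _check_groups(structure, group_a, group_b)
    sub_a = structure.subset(mask_a)
    sub_b = structure.subset(mask_b)
    both = structure.subset(mask_a | mask_b)
    sasa_a = shrake_rupley(sub_a, probe=probe, n_points=n_points)
    sasa_b = shrake_rupley(sub_b, probe=probe, n_points=n_points)
    sasa_ab = shrake_rupley(both, probe=probe, n_points=n_points)

    alone = np.concatenate([sasa_a, sasa_b])
    # subset preserves order, and (mask_a | mask_b) concatenates A's atoms
    # and B's atoms in original atom order; rebuild the alone-vector in the
    # same order as `both`
    order = np.concatenate([np.flatnonzero(mask_a), np.flatnonzero(mask_b)])
    combined_order = np.flatnonzero(mask_a | mask_b)
    alone_in_both_order = np.empty_like(alone)
    alone_in_both_order[np.searchsorted(combined_order, order)] = alone

    datom = alone_in_both_order - sasa_ab  # buried area per atom, >= 0 up to noise
    per_residue: dict[tuple[str, int, str], float] = {}
    hydro = 0.0
    for i in range(both.n_atoms):
        key = (str(both.chain_id[i]), int(both.res_id[i]), str(both.res_name[i]))
        per_residue[key] = per_residue.get(key, 0.0) + float(datom[i])
        if str(both.element[i]).upper() in ("C", "S"):
            hydro += float(datom[i])
    buried_total = float(datom.sum())
    hydro_frac = float(np.clip(hydro / buried_total, 0.0, 1.0)) \
        if buried_total > 0 else 0.0
    hbonds, salts, _ = interface_contacts(
        structure, group_a, group_b,
        hbond_cutoff=hbond_cutoff, salt_cutoff=salt_cutoff,
        with_fraction=False)
    return InterfaceReport(
        buried_total=buried_total,
        per_residue=per_residue,
        hbonds=hbonds,
        salt_bridges=salts,
        hydrophobic_fraction=hydro_frac,
    )


def interface_contacts(
    structure: AtomStructure,
    group_a,
    group_b,
    hbond_cutoff: float = 3.5,
    salt_cutoff: float = 4.0,
    probe: float = 1.4,
    n_points: int = 480,
    with_fraction: bool = True,
) -> tuple[list, list, float]:
    """Distance-based contact typing across an interface.

    Hydrogen bonds: any N/O--N/O pair across the interface within
    ``hbond_cutoff`` (distance-only criterion, appropriate when hydrogens
    are absent).  Salt bridges: basic side-chain nitrogen against acidic
    side-chain oxygen within ``salt_cutoff``.  Also returns the
    hydrophobic fraction of the buried area (carbon/sulfur share).
    """
    mask_a, mask_b = _check_groups(structure, group_a, group_b)
    ia = np.flatnonzero(mask_a)
    ib = np.flatnonzero(mask_b)
    A, B = structure.coords[ia], structure.coords[ib]
    tree_b = cKDTree(B)

    def _tag(i):
        return (str(structure.chain_id[i]), int(structure.res_id[i]),
                str(structure.res_name[i]), str(structure.atom_name[i]))

    hbonds, salts = [], []
    if hbond_cutoff > 0 or salt_cutoff > 0:
        pairs = tree_b.query_ball_point(A, max(hbond_cutoff, salt_cutoff))
        for ja, neigh in enumerate(pairs):
            i = ia[ja]
            ei = str(structure.element[i]).upper()
            for jb in neigh:
                j = ib[jb]
                ej = str(structure.element[j]).upper()
                d = float(np.linalg.norm(structure.coords[i] - structure.coords[j]))
                if hbond_cutoff > 0 and d <= hbond_cutoff and \
                        ei in ("N", "O") and ej in ("N", "O"):
                    hbonds.append((_tag(i), _tag(j), round(d, 3)))
                if salt_cutoff > 0 and d <= salt_cutoff:
                    if _is_basic_n(structure, i) and _is_acidic_o(structure, j):
                        salts.append((_tag(i), _tag(j), round(d, 3)))
                    elif _is_basic_n(structure, j) and _is_acidic_o(structure, i):
                        salts.append((_tag(j), _tag(i), round(d, 3)))
    if not with_fraction:
        return hbonds, salts, 0.0
    # hydrophobic fraction from a coarse burial computation
    sub_a = structure.subset(mask_a)
    sub_b = structure.subset(mask_b)
    both = structure.subset(mask_a | mask_b)
    alone = np.concatenate([
        shrake_rupley(sub_a, probe=probe, n_points=n_points),
        shrake_rupley(sub_b, probe=probe, n_points=n_points),
    ])
    order = np.concatenate([ia, ib])
    combined_order = np.flatnonzero(mask_a | mask_b)
    alone_sorted = np.empty_like(alone)
    alone_sorted[np.searchsorted(combined_order, order)] = alone
    datom = alone_sorted - shrake_rupley(both, probe=probe, n_points=n_points)
    total = float(datom.sum())
    carbon = np.isin(np.char.upper(both.element.astype(str)), ("C", "S"))
    frac = float(np.clip(datom[carbon].sum() / total, 0, 1)) if total > 0 else 0.0
    return hbonds, salts, frac


def _is_basic_n(structure, i) -> bool:
    return (str(structure.res_name[i]) in BASIC_RESIDUES
            and str(structure.atom_name[i]) in HYDROPHILIC_SIDECHAIN_N)


def _is_acidic_o(structure, i) -> bool:
    return (str(structure.res_name[i]) in ACIDIC_RESIDUES
            and str(structure.atom_name[i]) in ACIDIC_SIDECHAIN_O)


# --------------------------------------------------------------------------
# solvent content / symmetry
# --------------------------------------------------------------------------

def matthews_solvent(form: CrystalForm, density_constant: float = 1.23) -> dict:
    """Matthews coefficient and solvent fraction of a crystal form.

    ``Vm = V_cell / (multiplicity * chains_per_asu * chain_mass)`` in
    cubic Angstrom per Dalton, and ``solvent = 1 - density_constant / Vm``
    with the conventional 1.23 constant (clamped to [0, 1] with a warning
    flag when Vm is below the protein close-packing bound).  A partial
    specific volume based estimate (``1.66054 * vbar * ...``) is reported
    alongside.
    """
    total_mass = form.asu_multiplicity * form.chains_per_asu * form.chain_mass
    Vm = form.cell_volume / total_mass
    raw = 1.0 - density_constant / Vm
    clamped = bool(raw < 0.0 or raw > 1.0)
    solvent = float(np.clip(raw, 0.0, 1.0))
    # alternative from the partial specific volume: protein volume per Da
    # = vbar[cm^3/g] * 1.66054 A^3 Da / (cm^3/g)
    vbar_solvent = float(np.clip(
        1.0 - (form.partial_specific_volume * 1.66054) / Vm, 0.0, 1.0))
    return {
        "Vm": float(Vm),
        "solvent_fraction": solvent,
        "solvent_fraction_vbar": vbar_solvent,
        "clamped": clamped,
    }


def apply_symmetry(structure: AtomStructure,
                   ops: list[RigidTransform]) -> AtomStructure:
    """Expand a structure by rigid symmetry operators, relabelling chains.

    The input chains are kept; each operator appends a transformed copy
    with chain ids suffixed by the operator index.  Zero operators return
    the structure unchanged.
    """
    if not ops:
        return structure
    parts = [structure]
    for k, op in enumerate(ops, start=1):
        parts.append(AtomStructure(
            element=structure.element.copy(),
            atom_name=structure.atom_name.copy(),
            res_name=structure.res_name.copy(),
            res_id=structure.res_id.copy(),
            chain_id=np.array([f"{c}{k}" for c in structure.chain_id]),
            coords=op.apply(structure.coords),
            occupancy=structure.occupancy.copy(),
            source=structure.source,
        ))
    return AtomStructure(
        element=np.concatenate([p.element for p in parts]),
        atom_name=np.concatenate([p.atom_name for p in parts]),
        res_name=np.concatenate([p.res_name for p in parts]),
        res_id=np.concatenate([p.res_id for p in parts]),
        chain_id=np.concatenate([p.chain_id for p in parts]),
        coords=np.concatenate([p.coords for p in parts]),
        occupancy=np.concatenate([p.occupancy for p in parts]),
        source=structure.source,
    )
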