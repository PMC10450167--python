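"""Atomic models and density maps: reading, writing, geometry primitives.

Models are read with gemmi (PDB/mmCIF auto-detected) and reduced to an
explicit polynucleotide view: ordered residues with named atoms, grouped
into chains and, where the sugar-phosphate backbone is broken, into
continuous fragments.  Density maps are wrapped in a small container that
carries the unit cell, the grid origin and a periodicity flag, with a
vectorized trilinear interpolation used throughout the package.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger("nucassign")

#: O3'(i)-P(i+1) distance (Angstrom) below which consecutive residues are
#: treated as covalently bonded.  The covalent bond is ~1.6 A; the default
#: is generous to tolerate poor geometry in preliminary models.
DEFAULT_BOND_CUTOFF = 2.5

# Residue codes recognised as standard nucleotides (name-based shortcut).
RNA_CODES = {"A", "G", "C", "U"}
DNA_CODES = {"DA", "DG", "DC", "DT"}
PURINE_CODES = {"A", "G", "DA", "DG"}
PYRIMIDINE_CODES = {"C", "U", "DC", "DT"}

BACKBONE_ATOMS = ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'", "C2'", "C1'", "O4'")


# ---------------------------------------------------------------------------
# model types
# ---------------------------------------------------------------------------

@dataclass
class AtomRecord:
    name: str
    element: str
    xyz: np.ndarray            # Cartesian, Angstrom
    occupancy: float = 1.0
    b_iso: float = 20.0
    altloc: str = ""

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    name: str
    seqid: int
    atoms: list[AtomRecord]
    chain_id: str = ""
    icode: str = ""

    def __post_init__(self):
        self._by_name = {a.name: a for a in self.atoms}

    def atom(self, name: str) -> AtomRecord | None:
        return self._by_name.get(name)

    def xyz(self, name: str) -> np.ndarray | None:
        a = self._by_name.get(name)
        return None if a is None else a.xyz

    def has(self, *names: str) -> bool:
        return all(n in self._by_name for n in names)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seqid, self.icode)

    def is_nucleotide(self) -> bool:
        return "C1'" in self._by_name and ("N9" in self._by_name or "N1" in self._by_name)

    def rebuild_index(self) -> None:
        self._by_name = {a.name: a for a in self.atoms}


@dataclass
class NucleicChain:
    chain_id: str
    residues: list[Residue]
    kind: str = "RNA"          # "RNA" | "DNA"

    def __post_init__(self):
        self.residues.sort(key=lambda r: (r.seqid, r.icode))

    def __len__(self) -> int:
        return len(self.residues)

    @staticmethod
    def infer_kind(residues: Sequence[Residue]) -> str:
        n_o2 = sum(1 for r in residues if r.has("O2'"))
        return "RNA" if n_o2 * 2 >= len(residues) else "DNA"


@dataclass
class Structure:
    chains: list[NucleicChain] = field(default_factory=list)
    cell: tuple[float, float, float, float, float, float] | None = None
    title: str = ""
    #: optional ground-truth metadata attached by the fixture generator
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate chain ids")

    def chain(self, chain_id: str) -> NucleicChain | None:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        return None

    def residue(self, key: tuple[str, int, str]) -> Residue | None:
        c = self.chain(key[0])
        if c is None:
            return None
        for r in c.residues:
            if (r.seqid, r.icode) == (key[1], key[2]):
                return r
        return None

    def all_residues(self) -> list[Residue]:
        return [r for c in self.chains for r in c.residues]


@dataclass
class Fragment:
    """Continuous polynucleotide run (chain_id, start seqid, residues)."""
    chain_id: str
    start_seqid: int
    residues: list[Residue]

    def __len__(self) -> int:
        return len(self.residues)


# ---------------------------------------------------------------------------
# structure I/O
# ---------------------------------------------------------------------------

def _pick_altloc(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep the highest-occupancy conformer per atom name (ties -> 'A')."""
    groups: dict[str, list[gemmi.Atom]] = {}
    for at in res:
        groups.setdefault(at.name, []).append(at)
    picked = []
    for name, group in groups.items():
        group.sort(key=lambda a: (-a.occ, a.altloc or "A"))
        picked.append(group[0])
    return picked


def read_structure(path: str | os.PathLike) -> Structure:
    """Read a PDB or mmCIF model into the polynucleotide view.

    Non-nucleic content (protein, water, ligands) is dropped from the chain
    list; a model with no nucleic chains yields an empty chain list.
    """
    try:
        st = gemmi.read_structure(os.fspath(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc
    st.setup_entities()
    chains: list[NucleicChain] = []
    model = st[0]
    for ch in model:
        residues = []
        for res in ch:
            atoms = []
            for at in _pick_altloc(res):
                if at.element.name == "H":
                    continue
                atoms.append(AtomRecord(
                    name=at.name, element=at.element.name,
                    xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=at.occ, b_iso=at.b_iso,
                    altloc=at.altloc or ""))
            r = Residue(name=res.name, seqid=res.seqid.num, atoms=atoms,
                        chain_id=ch.name, icode=res.seqid.icode.strip())
            if r.is_nucleotide():
                residues.append(r)
        if residues:
            chains.append(NucleicChain(chain_id=ch.name, residues=residues,
                                       kind=NucleicChain.infer_kind(residues)))
    cell = None
    if st.cell and st.cell.a > 1.0:
        cell = (st.cell.a, st.cell.b, st.cell.c,
                st.cell.alpha, st.cell.beta, st.cell.gamma)
    return Structure(chains=chains, cell=cell, title=st.name or "")


def write_structure(structure: Structure, path: str | os.PathLike) -> None:
    """Write the nucleic chains as PDB or mmCIF (by extension)."""
    st = gemmi.Structure()
    st.name = structure.title or "model"
    if structure.cell:
        st.cell = gemmi.UnitCell(*structure.cell)
    st.spacegroup_hm = "P 1"
    model = gemmi.Model("1")
    for chain in structure.chains:
        ch = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seqid, res.icode or " ")
            for a in res.atoms:
                gat = gemmi.Atom()
                gat.name = a.name
                gat.element = gemmi.Element(a.element)
                gat.pos = gemmi.Position(*a.xyz)
                gat.occ = a.occupancy
                gat.b_iso = a.b_iso
                gat.altloc = a.altloc or "\0"
                gres.add_atom(gat)
            ch.add_residue(gres)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    path = os.fspath(path)
    if path.endswith(".cif") or path.endswith(".mmcif"):
        st.make_mmcif_document().write_file(path)
    else:
        st.write_pdb(path)


# ---------------------------------------------------------------------------
# density maps
# ---------------------------------------------------------------------------

@dataclass
class DensityMap:
    """3-D scalar grid with cell geometry.

    ``values[i, j, k]`` is the density at fractional coordinate
    ``origin_frac + (i/nx, j/ny, k/nz)`` expressed in the (X, Y, Z) axis
    order (any file-level axis permutation is normalized on read).
    Crystallographic maps are periodic; simulated/EM box maps are not and
    interpolate to 0 outside the grid.
    """
    values: np.ndarray
    cell: tuple[float, float, float, float, float, float]
    origin_frac: np.ndarray = field(default_factory=lambda: np.zeros(3))
    periodic: bool = False
    axis_order: tuple[str, str, str] = ("X", "Y", "Z")

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("map grid must be 3-D with all dimensions >= 2")
        if min(self.cell[:3]) <= 0:
            raise ValueError("cell lengths must be positive")
        self.origin_frac = np.asarray(self.origin_frac, dtype=float)
        self._ucell = gemmi.UnitCell(*self.cell)
        self._orth = np.array(self._ucell.orth.mat.tolist())
        self._frac = np.array(self._ucell.frac.mat.tolist())

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape

    # -- coordinate transforms ------------------------------------------------
    def cart_to_frac(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, dtype=float) @ self._frac.T

    def frac_to_cart(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self._orth.T

    # -- interpolation --------------------------------------------------------
    def interpolate(self, xyz: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at Cartesian points, vectorized.

        Accepts a single point or an (N, 3) array.  Periodic maps wrap;
        non-periodic maps return 0 outside the grid.
        """
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        frac = self.cart_to_frac(xyz) - self.origin_frac
        shape = np.array(self.values.shape)
        g = frac * shape               # grid coordinates
        i0 = np.floor(g).astype(np.int64)
        t = g - i0
        vals = np.zeros(len(g))
        v = self.values
        if self.periodic:
            def node(di, dj, dk):
                return v[(i0[:, 0] + di) % shape[0],
                         (i0[:, 1] + dj) % shape[1],
                         (i0[:, 2] + dk) % shape[2]]
            acc = np.zeros(len(g))
            for di in (0, 1):
                for dj in (0, 1):
                    for dk in (0, 1):
                        w = (np.where(di, t[:, 0], 1 - t[:, 0])
                             * np.where(dj, t[:, 1], 1 - t[:, 1])
                             * np.where(dk, t[:, 2], 1 - t[:, 2]))
                        acc += w * node(di, dj, dk)
            vals = acc
        else:
            inside = np.all((g >= 0) & (g <= shape - 1), axis=1)
            if np.any(inside):
                ii = np.minimum(i0[inside], shape - 2)
                tt = g[inside] - ii
                acc = np.zeros(inside.sum())
                for di in (0, 1):
                    for dj in (0, 1):
                        for dk in (0, 1):
                            w = (np.where(di, tt[:, 0], 1 - tt[:, 0])
                                 * np.where(dj, tt[:, 1], 1 - tt[:, 1])
                                 * np.where(dk, tt[:, 2], 1 - tt[:, 2]))
                            acc += w * v[ii[:, 0] + di, ii[:, 1] + dj, ii[:, 2] + dk]
                vals[inside] = acc
        return vals if vals.size > 1 else vals[0]


def interpolate_density(density_map: DensityMap, xyz: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`DensityMap.interpolate`."""
    return density_map.interpolate(xyz)


def read_ccp4_map(path: str | os.PathLike) -> DensityMap:
    """Read a CCP4/MRC map; axis order is normalized to (X, Y, Z)."""
    try:
        m = gemmi.read_ccp4_map(os.fspath(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot read CCP4/MRC map {path}: {exc}") from exc
    if m.header_i32(4) not in (0, 1, 2):
        raise ValueError(f"unsupported CCP4 mode {m.header_i32(4)}")
    m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    grid = m.grid
    arr = np.array(grid, copy=True)
    nstart = np.array([m.header_i32(5), m.header_i32(6), m.header_i32(7)], dtype=float)
    # after reordering to XYZ the start words follow the axis order
    axis_pos = m.axis_positions()
    cell = grid.unit_cell
    shape = np.array(arr.shape, dtype=float)
    origin_frac = nstart / shape
    periodic = bool(grid.spacegroup) and np.allclose(nstart, 0) and (
        grid.nu == m.header_i32(8) and grid.nv == m.header_i32(9) and grid.nw == m.header_i32(10))
    return DensityMap(values=arr,
                      cell=(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma),
                      origin_frac=origin_frac, periodic=periodic)


def write_ccp4_map(density_map: DensityMap, path: str | os.PathLike) -> None:
    """Write a mode-2 CCP4/MRC map (grid start from origin_frac)."""
    grid = gemmi.FloatGrid(np.ascontiguousarray(density_map.values, dtype=np.float32))
    grid.set_unit_cell(gemmi.UnitCell(*density_map.cell))
    grid.spacegroup = gemmi.SpaceGroup("P1")
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    shape = np.array(density_map.values.shape)
    nstart = np.round(density_map.origin_frac * shape).astype(int)
    for k, v in zip((5, 6, 7), nstart):
        m.set_header_i32(k, int(v))
    m.write_ccp4_map(os.fspath(path))


def map_from_mtz(path: str | os.PathLike,
                 amp_label: str = "FWT",
                 phase_label: str = "PHWT") -> DensityMap:
    """Fourier synthesis of a real-space map from MTZ amplitudes + phases.

    The grid is sampled at least as finely as d_min/3 per dimension
    (sample_rate=3); the result is periodic over the unit cell.
    """
    mtz = gemmi.read_mtz_file(os.fspath(path))
    labels = [c.label for c in mtz.columns]
    for lbl in (amp_label, phase_label):
        if lbl not in labels:
            raise ValueError(f"column {lbl!r} not in MTZ; available: {labels}")
    grid = mtz.transform_f_phi_to_map(amp_label, phase_label, sample_rate=3.0)
    arr = np.array(grid, copy=True)
    cell = grid.unit_cell
    return DensityMap(values=arr,
                      cell=(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma),
                      origin_frac=np.zeros(3), periodic=True)


# ---------------------------------------------------------------------------
# chain continuity
# ---------------------------------------------------------------------------

def chain_fragments(chain: NucleicChain,
                    bond_cutoff: float = DEFAULT_BOND_CUTOFF) -> list[Fragment]:
    """Split a chain into maximal covalently continuous runs.

    Connectivity is decided by the O3'(i)-P(i+1) distance, not residue
    numbering.  Residues missing both P and O3' break the chain and are
    placed in their own fragment.
    """
    if not chain.residues:
        raise ValueError("empty chain")
    fragments: list[list[Residue]] = [[chain.residues[0]]]
    for prev, cur in zip(chain.residues, chain.residues[1:]):
        o3 = prev.xyz("O3'")
        p = cur.xyz("P")
        bonded = (o3 is not None and p is not None
                  and float(np.linalg.norm(o3 - p)) <= bond_cutoff)
        if not bonded and (o3 is None or p is None):
            logger.debug("continuity break at %s/%s: missing O3'/P",
                         prev.key, cur.key)
        if bonded:
            fragments[-1].append(cur)
        else:
            fragments.append([cur])
    return [Fragment(chain_id=chain.chain_id, start_seqid=f[0].seqid, residues=f)
            for f in fragments]
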