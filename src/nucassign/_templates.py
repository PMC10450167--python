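"""Idealized nucleotide templates and embedded helix reference geometry.

Monomer templates come from the Chemical Component Dictionary bundled with
biotite.  The A-RNA / B-DNA reference Watson-Crick pair conformers (one
nucleotide per strand, expressed in a frame whose z axis is the helix
axis) were fitted once against hydrogen-bond, backbone-continuity and
stacking-contact targets and are shipped as package data.
"""

from __future__ import annotations

import functools
from importlib import resources

import numpy as np
from scipy.spatial.transform import Rotation

import biotite.structure.info as _ccd_info

# fibre parameters: twist (deg) and rise (A) per base pair step
HELIX_PARAMS = {"A_RNA": (32.7, 2.81), "B_DNA": (36.0, 3.38)}

PURINE_LETTERS = {"A", "G"}
PYRIMIDINE_LETTERS = {"C", "U", "T"}

#: residue code per (letter, kind)
CODE_FOR_LETTER = {
    ("A", "RNA"): "A", ("G", "RNA"): "G", ("C", "RNA"): "C", ("U", "RNA"): "U",
    ("A", "DNA"): "DA", ("G", "DNA"): "DG", ("C", "DNA"): "DC", ("T", "DNA"): "DT",
}
LETTER_FOR_CODE = {v: k[0] for k, v in CODE_FOR_LETTER.items()}

WC_COMPLEMENT = {
    "RNA": {"A": "U", "U": "A", "G": "C", "C": "G"},
    "DNA": {"A": "T", "T": "A", "G": "C", "C": "G"},
}

# base (heavy) atoms per parent letter
BASE_ATOMS = {
    "A": ["N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"],
    "G": ["N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"],
    "C": ["N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"],
    "U": ["N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"],
    "T": ["N1", "C2", "O2", "N3", "C4", "O4", "C5", "C7", "C6"],
}
# base hydrogens of guanine (used by the descriptor sampling-cloud sweep)
GUANINE_BASE_H = ["H8", "H1", "H21", "H22"]

RIBOSE_RING = ["C1'", "C2'", "C3'", "C4'", "O4'"]

#: sugar-phosphate atoms kept when a base is rebuilt
NA_BACKBONE_SET = frozenset(
    ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'", "C2'", "C1'", "O4'", "O2'"])
ANCHOR_TRIPLE = ("C2'", "C1'", "O4'")


def glycosidic_nitrogen(letter_or_code: str) -> str:
    """'N9' for purines, 'N1' for pyrimidines (by parent letter)."""
    letter = LETTER_FOR_CODE.get(letter_or_code, letter_or_code)
    return "N9" if letter in PURINE_LETTERS else "N1"


def letter_class(letter: str) -> str:
    if letter in PURINE_LETTERS:
        return "PURINE"
    if letter in PYRIMIDINE_LETTERS:
        return "PYRIMIDINE"
    raise ValueError(f"unknown nucleotide letter {letter!r}")


@functools.lru_cache(maxsize=64)
def template_atoms(code: str, keep_h: bool = False) -> tuple[tuple[str, ...], np.ndarray]:
    """Idealized monomer coordinates for a residue code (CCD)."""
    res = _ccd_info.residue(code)
    if res is None:
        raise KeyError(f"no CCD template for residue {code!r}")
    if not keep_h:
        res = res[res.element != "H"]
    res = res[res.atom_name != "OP3"]
    names = tuple(str(n) for n in res.atom_name)
    coords = res.coord.astype(float).copy()
    coords.setflags(write=False)
    return names, coords


def template_dict(code: str, keep_h: bool = False) -> dict[str, np.ndarray]:
    names, coords = template_atoms(code, keep_h)
    return {n: c for n, c in zip(names, coords)}


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, target: np.ndarray,
              weights: np.ndarray | None = None):
    """Least-squares rigid superposition (Kabsch).

    Returns ``(rot, trans, rmsd)`` with ``rot @ x + trans`` mapping mobile
    onto target.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if weights is None:
        weights = np.ones(len(mobile))
    w = weights / weights.sum()
    mc = (mobile * w[:, None]).sum(0)
    tc = (target * w[:, None]).sum(0)
    H = ((mobile - mc) * w[:, None]).T @ (target - tc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    diff = (mobile @ R.T + t) - target
    rmsd = float(np.sqrt((w * (diff ** 2).sum(1)).sum()))
    return R, t, rmsd


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle in radians, IUPAC sign convention."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1n) * b1n
    w = b2 - (b2 @ b1n) * b1n
    x = v @ w
    y = np.cross(b1n, v) @ w
    return float(np.arctan2(y, x))


def ribose_plane_normal(get_xyz) -> np.ndarray:
    """Least-squares plane normal of the five-membered sugar ring.

    ``get_xyz`` maps an atom name to coordinates (or None).  The sign is
    chosen so the normal points towards C2' as seen from C1'.
    """
    pts = []
    for name in RIBOSE_RING:
        p = get_xyz(name)
        if p is not None:
            pts.append(p)
    if len(pts) < 4:
        raise ValueError("fewer than 4 sugar ring atoms")
    pts = np.asarray(pts, float)
    ctr = pts.mean(0)
    _, s, vt = np.linalg.svd(pts - ctr)
    if s[1] < 1e-6:        # degenerate (collinear) ring
        raise ValueError("degenerate ribose ring geometry")
    normal = vt[2]
    c1, c2 = get_xyz("C1'"), get_xyz("C2'")
    if c1 is not None and c2 is not None and normal @ (c2 - c1) < 0:
        normal = -normal
    return normal


# ---------------------------------------------------------------------------
# embedded helix reference pair
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=4)
def helix_reference(form: str) -> dict[str, dict[str, np.ndarray]]:
    """Reference WC pair conformers in the helix frame.

    Returns ``{"s1": {atom: xyz}, "s2": {...}}`` where s1 is a guanosine
    (dG for B-DNA) and s2 the paired cytidine; applying a rotation of
    ``i * twist`` about z plus a translation of ``i * rise`` along z
    generates base-pair step i.
    """
    if form not in HELIX_PARAMS:
        raise ValueError(f"unsupported helix form {form!r}")
    text = (resources.files("nucassign.data") / f"helix_{form}.tsv").read_text()
    out: dict[str, dict[str, np.ndarray]] = {"s1": {}, "s2": {}}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        strand, atom, x, y, z = line.split("\t")
        out[strand][atom] = np.array([float(x), float(y), float(z)])
    return out


def helix_step_transform(form: str, i: int):
    twist, rise = HELIX_PARAMS[form]
    R = Rotation.from_euler("z", i * twist, degrees=True).as_matrix()
    t = np.array([0.0, 0.0, i * rise])
    return R, t


# ---------------------------------------------------------------------------
# base replacement
# ---------------------------------------------------------------------------

def build_base_atoms(letter: str, kind: str, anchor_xyz: dict[str, np.ndarray],
                     chi: float | None = None) -> list[tuple[str, str, np.ndarray]]:
    """Idealized base atoms of `letter` grafted onto a ribose.

    The template is superposed on the (C2', C1', O4') anchors; when `chi`
    (the O4'-C1'-N-C4/C2 glycosidic torsion, radians) is given, the base is
    additionally rotated about the glycosidic bond to match it.  Returns
    ``(name, element, xyz)`` triples for the base heavy atoms.
    """
    code = CODE_FOR_LETTER[(letter, kind)]
    tmpl = template_dict(code)
    anchors = np.array([tmpl[a] for a in ANCHOR_TRIPLE])
    target = np.array([anchor_xyz[a] for a in ANCHOR_TRIPLE])
    R, t, _ = superpose(anchors, target)
    glyco = glycosidic_nitrogen(letter)
    base_names = BASE_ATOMS[letter]
    placed = {n: R @ tmpl[n] + t for n in base_names}
    c1 = R @ tmpl["C1'"] + t
    o4 = R @ tmpl["O4'"] + t
    if chi is not None:
        ref_atom = "C4" if letter in PURINE_LETTERS else "C2"
        cur = dihedral(o4, c1, placed[glyco], placed[ref_atom])
        ax = placed[glyco] - c1
        ax = ax / np.linalg.norm(ax)
        rot = Rotation.from_rotvec(ax * (chi - cur)).as_matrix()
        pivot = placed[glyco]
        placed = {n: rot @ (p - pivot) + pivot for n, p in placed.items()}
    out = []
    for n in base_names:
        elem = "N" if n.startswith("N") else ("O" if n.startswith("O") else "C")
        out.append((n, elem, placed[n]))
    return out


def residue_chi(get_xyz, letter: str) -> float | None:
    """Glycosidic torsion of an existing residue, or None if atoms missing."""
    glyco = glycosidic_nitrogen(letter)
    ref = "C4" if letter in PURINE_LETTERS else "C2"
    pts = [get_xyz(a) for a in ("O4'", "C1'", glyco, ref)]
    if any(p is None for p in pts):
        return None
    return dihedral(*pts)
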