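"""Per-nucleotide density descriptors in the glycosidic/ribose local frame.

A nucleotide is summarized by map values sampled on a fixed cloud of 403
grid points around its base region.  The cloud is built once by sweeping a
guanine base through all rotations about the glycosidic bond and keeping
regular 1-Angstrom grid nodes close to any swept atom position; at
prediction time the precomputed cloud is rigidly aligned to each residue
through its C2'/C1'/O4' sugar atoms.  Purine/pyrimidine labels for named
residues (including modified bases) follow the imidazole-ring geometry
rule: a base with both N1 and N9 roughly 4.1 Angstrom apart is a purine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from . import _templates as T
from .na_io import DensityMap, Residue

logger = logging.getLogger("nucassign")

CLOUD_SIZE = 403
GRID_SPACING = 1.0
CUTOFF_BOUNDS = (0.8, 1.2)
SD_FLOOR = 1e-6

PURINE = "PURINE"
PYRIMIDINE = "PYRIMIDINE"

# purine N1-N9 separation window around the ~4.1 A imidazole-ring geometry
N1_N9_RANGE = (3.6, 4.6)


# ---------------------------------------------------------------------------
# purine / pyrimidine classification of residue codes
# ---------------------------------------------------------------------------

def base_moiety_class(residue: Residue) -> str:
    """Classify a residue as PURINE or PYRIMIDINE.

    Standard codes short-circuit by name; anything else (modified bases)
    is decided by the presence of both N1 and N9 within bonding-consistent
    distance, i.e. by the presence of the imidazole ring.
    """
    if residue.name in T.LETTER_FOR_CODE:
        return PURINE if residue.name in {"A", "G", "DA", "DG"} else PYRIMIDINE
    n1, n9 = residue.xyz("N1"), residue.xyz("N9")
    if n1 is None and n9 is None:
        raise ValueError(f"residue {residue.name} {residue.key}: no base nitrogen atoms")
    if n1 is not None and n9 is not None:
        d = float(np.linalg.norm(n1 - n9))
        if N1_N9_RANGE[0] <= d <= N1_N9_RANGE[1]:
            return PURINE
    return PYRIMIDINE


# ---------------------------------------------------------------------------
# local frame
# ---------------------------------------------------------------------------

@dataclass
class BaseFrame:
    origin: np.ndarray      # glycosidic nitrogen position
    e_x: np.ndarray         # unit, along C1' -> glycosidic N
    e_y: np.ndarray         # unit, ribose plane normal (orthogonalized)
    e_z: np.ndarray         # e_x x e_y

    def apply_rigid(self, rot: np.ndarray, trans: np.ndarray) -> "BaseFrame":
        return BaseFrame(origin=rot @ self.origin + trans,
                         e_x=rot @ self.e_x, e_y=rot @ self.e_y, e_z=rot @ self.e_z)


def compute_frame(residue: Residue) -> BaseFrame:
    """Orthonormal local frame anchored at the glycosidic nitrogen."""
    cls = base_moiety_class(residue)
    glyco = "N9" if cls == PURINE else "N1"
    n = residue.xyz(glyco)
    c1 = residue.xyz("C1'")
    if n is None or c1 is None:
        raise ValueError(f"residue {residue.key}: missing {glyco} or C1'")
    e_x = n - c1
    nrm = np.linalg.norm(e_x)
    if nrm < 1e-9:
        raise ValueError("degenerate glycosidic bond")
    e_x = e_x / nrm
    normal = T.ribose_plane_normal(residue.xyz)
    e_y = normal - e_x * (normal @ e_x)
    nrm = np.linalg.norm(e_y)
    if nrm < 1e-9:
        raise ValueError("ribose normal parallel to glycosidic bond")
    e_y = e_y / nrm
    return BaseFrame(origin=n, e_x=e_x, e_y=e_y, e_z=np.cross(e_x, e_y))


# ---------------------------------------------------------------------------
# sampling cloud
# ---------------------------------------------------------------------------

@dataclass
class SamplingCloud:
    """403 sampling offsets in the guanine-template local frame.

    ``points`` are ordered lexicographically by integer grid index; the
    order is part of the classifier input contract.  ``anchor_local``
    holds the C2'/C1'/O4' template coordinates in the same frame, used to
    align the cloud to a model residue.
    """
    points: np.ndarray
    anchor_local: np.ndarray
    grid_spacing: float
    cutoff: float
    anchor_atoms: tuple[str, str, str] = T.ANCHOR_TRIPLE

    def __post_init__(self):
        self.points = np.asarray(self.points, float)
        if len(self.points) != CLOUD_SIZE:
            raise ValueError(f"cloud has {len(self.points)} points, expected {CLOUD_SIZE}")


def _guanine_local(template: dict[str, np.ndarray] | None = None):
    """Guanine template (with base H) in the N9-centred local frame."""
    tmpl = template if template is not None else T.template_dict("G", keep_h=True)
    for req in ("N9", "C1'", "C2'", "O4'"):
        if req not in tmpl:
            raise ValueError(f"guanine template missing atom {req}")
    n9, c1 = tmpl["N9"], tmpl["C1'"]
    e_x = n9 - c1
    e_x = e_x / np.linalg.norm(e_x)
    normal = T.ribose_plane_normal(lambda a: tmpl.get(a))
    e_y = normal - e_x * (normal @ e_x)
    e_y = e_y / np.linalg.norm(e_y)
    R = np.array([e_x, e_y, np.cross(e_x, e_y)])
    return {n: R @ (c - n9) for n, c in tmpl.items()}


def build_sampling_cloud(guanine_template: dict[str, np.ndarray] | None = None,
                         grid_spacing: float = GRID_SPACING,
                         cutoff: float = 1.0,
                         sweep_step_deg: float = 1.0) -> SamplingCloud:
    """Construct the canonical sampling cloud.

    Base atoms (hydrogens included) are swept about the glycosidic-bond
    axis in 1-degree steps; regular grid nodes centred at N9 within
    `cutoff` of any swept position are kept.  If the count differs from
    403 the cutoff is calibrated by binary search inside [0.8, 1.2] A.
    """
    loc = _guanine_local(guanine_template)
    base_names = [a for a in T.BASE_ATOMS["G"] + T.GUANINE_BASE_H if a in loc]
    base = np.array([loc[a] for a in base_names])
    angles = np.deg2rad(np.arange(0.0, 360.0, sweep_step_deg))
    axis = np.array([1.0, 0.0, 0.0])   # glycosidic bond is the local x axis
    swept = np.concatenate([Rotation.from_rotvec(axis * a).apply(base) for a in angles])

    reach = int(np.ceil((np.linalg.norm(swept, axis=1).max() + CUTOFF_BOUNDS[1]) / grid_spacing))
    rng1 = np.arange(-reach, reach + 1)
    idx = np.array(np.meshgrid(rng1, rng1, rng1, indexing="ij")).reshape(3, -1).T
    nodes = idx * grid_spacing
    dmin = cdist(nodes, swept).min(axis=1)

    def count(c):
        return int((dmin <= c).sum())

    c = cutoff
    if count(c) != CLOUD_SIZE:
        lo, hi = CUTOFF_BOUNDS
        if not (count(lo) <= CLOUD_SIZE <= count(hi)):
            raise ValueError("cannot reach 403 cloud points within cutoff bounds; "
                             "template geometry suspect")
        for _ in range(200):
            c = 0.5 * (lo + hi)
            n = count(c)
            if n == CLOUD_SIZE:
                break
            if n < CLOUD_SIZE:
                lo = c
            else:
                hi = c
        else:
            raise ValueError("cutoff calibration did not converge to 403 points")
    keep = dmin <= c
    kept_idx = idx[keep]
    order = np.lexsort((kept_idx[:, 2], kept_idx[:, 1], kept_idx[:, 0]))
    points = kept_idx[order] * grid_spacing
    anchor_local = np.array([loc[a] for a in T.ANCHOR_TRIPLE])
    return SamplingCloud(points=points, anchor_local=anchor_local,
                         grid_spacing=grid_spacing, cutoff=float(c))


_CANONICAL: SamplingCloud | None = None


def canonical_cloud() -> SamplingCloud:
    """The shipped, frozen sampling cloud (403 points)."""
    global _CANONICAL
    if _CANONICAL is None:
        text = (resources.files("nucassign.data") / "sampling_cloud.tsv").read_text()
        pts, anchors = [], {}
        spacing = cutoff = None
        for line in text.splitlines():
            if line.startswith("# spacing"):
                spacing = float(line.split()[-1])
            elif line.startswith("# cutoff"):
                cutoff = float(line.split()[-1])
            elif line.startswith("# anchor"):
                tok = line.split()
                anchors[tok[3]] = [float(v) for v in tok[4:7]]
            elif line and not line.startswith("#"):
                pts.append([float(v) for v in line.split()[-3:]])
        anchor_local = np.array([anchors[a] for a in T.ANCHOR_TRIPLE])
        _CANONICAL = SamplingCloud(points=np.array(pts), anchor_local=anchor_local,
                                   grid_spacing=spacing, cutoff=cutoff)
    return _CANONICAL


def save_cloud(cloud: SamplingCloud, path) -> None:
    lines = [f"# spacing {cloud.grid_spacing}", f"# cutoff {cloud.cutoff:.10f}"]
    for name, xyz in zip(cloud.anchor_atoms, cloud.anchor_local):
        lines.append(f"# anchor : {name} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}")
    lines.append("# x y z")
    for p in cloud.points:
        lines.append(f"{p[0]:.3f} {p[1]:.3f} {p[2]:.3f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# descriptor extraction
# ---------------------------------------------------------------------------

@dataclass
class ResidueDescriptor:
    residue_key: tuple[str, int, str]
    values: np.ndarray
    normalization: tuple[float, float] = (0.0, 1.0)   # (mean, sd) removed

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if len(self.values) != CLOUD_SIZE:
            raise ValueError(f"descriptor length {len(self.values)} != {CLOUD_SIZE}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite descriptor values")


def extract_descriptor(density_map: DensityMap, residue: Residue,
                       cloud: SamplingCloud | None = None) -> ResidueDescriptor:
    """Sample the map on the cloud aligned to one residue; z-score normalize."""
    if cloud is None:
        cloud = canonical_cloud()
    target = []
    for a in cloud.anchor_atoms:
        p = residue.xyz(a)
        if p is None:
            raise ValueError(f"residue {residue.key}: missing anchor atom {a}")
        target.append(p)
    R, t, _ = T.superpose(cloud.anchor_local, np.array(target))
    pts = cloud.points @ R.T + t
    raw = np.atleast_1d(density_map.interpolate(pts))
    mean = float(raw.mean())
    sd = float(raw.std())
    sd_used = max(sd, SD_FLOOR)
    values = (raw - mean) / sd_used
    return ResidueDescriptor(residue_key=residue.key, values=values,
                             normalization=(mean, sd_used))
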