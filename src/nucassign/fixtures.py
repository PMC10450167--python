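"""Synthetic structures, simulated maps, and labeled training data.

The generators emulate what the method assumes about real data: ideal
A-RNA/B-DNA duplexes with full-atom nucleotides built from idealized
monomer templates and fibre parameters, density maps simulated as
Gaussian atoms at a stated resolution with optional white noise, and
random sequences with controlled composition.  Every generator is
seed-deterministic.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from . import _templates as T
from .classifier import LabeledDescriptor
from .descriptor import extract_descriptor, canonical_cloud
from .na_io import AtomRecord, DensityMap, NucleicChain, Residue, Structure, write_structure, write_ccp4_map

#: simple atomic-number weights for the Gaussian-atom density
Z_EFF = {"C": 6.0, "N": 7.0, "O": 8.0, "P": 15.0}

#: Gaussian sd per resolution: Fourier amplitude falls to ~1/e at 1/resolution
SIGMA_PER_RESOLUTION = 0.225


@dataclass
class MapSimulationParams:
    resolution: float = 3.0
    grid_spacing: float | None = None     # default resolution / 3
    noise_sd: float = 0.0                 # fraction of map sd
    b_factor: float = 0.0                 # extra isotropic blur, A^2
    seed: int = 0

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def spacing(self) -> float:
        return self.grid_spacing if self.grid_spacing else self.resolution / 3.0


@dataclass
class DuplexSpec:
    sequence: str
    form: str = "A_RNA"                   # "A_RNA" | "B_DNA"
    include_complement: bool = True

    def __post_init__(self):
        kind = "RNA" if self.form == "A_RNA" else "DNA"
        alphabet = set("AGCU" if kind == "RNA" else "AGCT")
        if not self.sequence or not set(self.sequence) <= alphabet:
            raise ValueError(f"sequence must be non-empty over {sorted(alphabet)}")

    @property
    def kind(self) -> str:
        return "RNA" if self.form == "A_RNA" else "DNA"


def _element(name: str) -> str:
    return "P" if name == "P" else name[0]


def _strand_backbone(ref: dict[str, np.ndarray], kind: str) -> dict[str, np.ndarray]:
    base = set(T.BASE_ATOMS["G"]) | set(T.BASE_ATOMS["C"])
    bb = {n: c for n, c in ref.items() if n not in base}
    if kind == "DNA":
        bb.pop("O2'", None)
    return bb


def _reference_chis(form: str) -> tuple[float, float]:
    ref = T.helix_reference(form)
    chi_pur = T.residue_chi(lambda a: ref["s1"].get(a), "G")
    chi_pyr = T.residue_chi(lambda a: ref["s2"].get(a), "C")
    return chi_pur, chi_pyr


def _build_residue(bb: dict[str, np.ndarray], letter: str, kind: str,
                   chi_pur: float, chi_pyr: float,
                   rot: np.ndarray, trans: np.ndarray,
                   seqid: int, chain_id: str) -> Residue:
    atoms = [AtomRecord(name=n, element=_element(n), xyz=rot @ c + trans)
             for n, c in bb.items()]
    anchor = {a.name: a.xyz for a in atoms}
    chi = chi_pur if letter in T.PURINE_LETTERS else chi_pyr
    for n, elem, xyz in T.build_base_atoms(letter, kind, anchor, chi=chi):
        atoms.append(AtomRecord(name=n, element=elem, xyz=xyz))
    code = T.CODE_FOR_LETTER[(letter, kind)]
    return Residue(name=code, seqid=seqid, atoms=atoms, chain_id=chain_id)


def make_duplex(spec: DuplexSpec) -> Structure:
    """Ideal duplex (or single strand) with ground-truth pairing metadata."""
    form, kind = spec.form, spec.kind
    ref = T.helix_reference(form)
    chi_pur, chi_pyr = _reference_chis(form)
    bb1 = _strand_backbone(ref["s1"], kind)
    bb2 = _strand_backbone(ref["s2"], kind)
    n = len(spec.sequence)
    comp = T.WC_COMPLEMENT[kind]

    chain_a = []
    for i, letter in enumerate(spec.sequence):
        R, t = T.helix_step_transform(form, i)
        chain_a.append(_build_residue(bb1, letter, kind, chi_pur, chi_pyr,
                                      R, t, seqid=i + 1, chain_id="A"))
    chains = [NucleicChain(chain_id="A", residues=chain_a, kind=kind)]
    pairs = []
    seq_b = ""
    if spec.include_complement:
        chain_b = []
        # strand 2 runs 5'->3' with decreasing helical slot
        for j, slot in enumerate(range(n - 1, -1, -1)):
            letter = comp[spec.sequence[slot]]
            seq_b += letter
            R, t = T.helix_step_transform(form, slot)
            chain_b.append(_build_residue(bb2, letter, kind, chi_pur, chi_pyr,
                                          R, t, seqid=j + 1, chain_id="B"))
        chains.append(NucleicChain(chain_id="B", residues=chain_b, kind=kind))
        pairs = [(("A", i + 1, ""), ("B", n - i, "")) for i in range(n)]
    st = Structure(chains=chains, title=f"ideal {form} duplex")
    st.metadata = {"pairs": pairs,
                   "sequences": ({"A": spec.sequence, "B": seq_b}
                                 if spec.include_complement else {"A": spec.sequence}),
                   "form": form}
    return st


def make_hairpin(stem_seq: str, loop_len: int = 4, form: str = "A_RNA") -> Structure:
    """Single chain: stem (paired), loop (unpaired, non-helical), stem return.

    The loop backbone is laid along an arc with irregular orientations so
    it does not mimic double-helical geometry; ground-truth pairs cover
    the stem only.
    """
    duplex = make_duplex(DuplexSpec(sequence=stem_seq, form=form))
    kind = duplex.chains[0].kind
    m = len(stem_seq)
    ref = T.helix_reference(form)
    chi_pur, chi_pyr = _reference_chis(form)
    bb1 = _strand_backbone(ref["s1"], kind)

    residues = []
    for i, r in enumerate(duplex.chains[0].residues):
        residues.append(Residue(name=r.name, seqid=i + 1, atoms=r.atoms, chain_id="A"))
    # arc from the 3' end of strand 1 to the 5' end of the returning strand
    _, t_next = T.helix_step_transform(form, m)
    start = np.asarray(t_next) + np.array([6.0, 0.0, 0.0])
    end_res = duplex.chains[1].residues[0]
    end = end_res.atoms[0].xyz + np.array([6.0, 0.0, 3.0])
    mid = 0.5 * (start + end) + np.array([10.0, 4.0, 2.0])
    loop_letters = ("GAAA" * (loop_len // 4 + 1))[:loop_len]
    for k in range(loop_len):
        s = (k + 1) / (loop_len + 1)
        pos = ((1 - s) ** 2) * start + 2 * s * (1 - s) * mid + s ** 2 * end
        rot = Rotation.from_euler("zyx", [137.5 * k, 63.0 * k, 29.0 * k],
                                  degrees=True).as_matrix()
        letter = loop_letters[k]
        residues.append(_build_residue(bb1, letter, kind, chi_pur, chi_pyr,
                                       rot, pos, seqid=m + k + 1, chain_id="A"))
    for j, r in enumerate(duplex.chains[1].residues):
        residues.append(Residue(name=r.name, seqid=m + loop_len + j + 1,
                                atoms=r.atoms, chain_id="A"))
    st = Structure(chains=[NucleicChain(chain_id="A", residues=residues, kind=kind)],
                   title="hairpin")
    st.metadata = {
        "pairs": [(("A", i + 1, ""), ("A", 2 * m + loop_len - i, "")) for i in range(m)],
        "sequences": {"A": stem_seq + loop_letters
                      + "".join(T.WC_COMPLEMENT[kind][c] for c in stem_seq[::-1])},
        "form": form}
    return st


# ---------------------------------------------------------------------------
# map simulation
# ---------------------------------------------------------------------------

def simulate_map(structure: Structure, params: MapSimulationParams) -> DensityMap:
    """Gaussian-atom density on an orthogonal box grid padded 5 A.

    density = sum_atoms Z_eff * occupancy * exp(-|r - r_a|^2 / (2 sigma^2))
    with sigma = 0.225 * resolution (plus any b_factor blur), then seeded
    white noise of noise_sd * map_sd.
    """
    atoms = [(a.xyz, Z_EFF.get(a.element, 6.0) * a.occupancy)
             for c in structure.chains for r in c.residues for a in r.atoms]
    if not atoms:
        raise ValueError("structure has no atoms")
    coords = np.array([a[0] for a in atoms])
    weights = np.array([a[1] for a in atoms])
    sigma = SIGMA_PER_RESOLUTION * params.resolution
    if params.b_factor > 0:
        sigma = float(np.sqrt(sigma ** 2 + params.b_factor / (8 * np.pi ** 2)))
    spacing = params.spacing
    pad = 5.0
    # snap the origin to grid-spacing multiples so CCP4 NSTART stays exact
    box_min = np.floor((coords.min(0) - pad) / spacing) * spacing
    box_max = coords.max(0) + pad
    shape = np.ceil((box_max - box_min) / spacing).astype(int) + 1
    cell = tuple(shape * spacing) + (90.0, 90.0, 90.0)
    values = np.zeros(shape, dtype=np.float64)
    reach = int(np.ceil(3.5 * sigma / spacing))
    axes = [np.arange(s) * spacing + box_min[d] for d, s in enumerate(shape)]
    for xyz, w in zip(coords, weights):
        ijk0 = np.floor((xyz - box_min) / spacing).astype(int)
        sl = [slice(max(0, ijk0[d] - reach), min(shape[d], ijk0[d] + reach + 1))
              for d in range(3)]
        dx = axes[0][sl[0]] - xyz[0]
        dy = axes[1][sl[1]] - xyz[1]
        dz = axes[2][sl[2]] - xyz[2]
        g = np.exp(-(dx[:, None, None] ** 2 + dy[None, :, None] ** 2
                     + dz[None, None, :] ** 2) / (2 * sigma ** 2))
        values[sl[0], sl[1], sl[2]] += w * g
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        values = values + rng.normal(0.0, params.noise_sd * values.std(), values.shape)
    origin_frac = box_min / np.array(cell[:3])
    return DensityMap(values=values.astype(np.float32), cell=cell,
                      origin_frac=origin_frac, periodic=False)


# ---------------------------------------------------------------------------
# labeled training data
# ---------------------------------------------------------------------------

def training_set(n_per_class: int, resolutions=(3.0,), noise_sd: float = 0.0,
                 seed: int = 0, form: str = "A_RNA",
                 duplex_len: int = 10) -> list[LabeledDescriptor]:
    """Balanced purine/pyrimidine descriptors from simulated duplex maps."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    cloud = canonical_cloud()
    kind = "RNA" if form == "A_RNA" else "DNA"
    letters = "AGCU" if kind == "RNA" else "AGCT"
    by_class: dict[str, list[LabeledDescriptor]] = {"PURINE": [], "PYRIMIDINE": []}
    res_cycle = list(resolutions)
    i_map = 0
    while min(len(v) for v in by_class.values()) < n_per_class:
        seq = "".join(rng.choice(list(letters), duplex_len))
        st = make_duplex(DuplexSpec(sequence=seq, form=form))
        resolution = res_cycle[i_map % len(res_cycle)]
        params = MapSimulationParams(resolution=resolution, noise_sd=noise_sd,
                                     seed=int(rng.integers(0, 2 ** 31)))
        dmap = simulate_map(st, params)
        for chain in st.chains:
            for res in chain.residues:
                label = ("PURINE" if T.LETTER_FOR_CODE[res.name] in T.PURINE_LETTERS
                         else "PYRIMIDINE")
                if len(by_class[label]) >= n_per_class:
                    continue
                desc = extract_descriptor(dmap, res, cloud)
                by_class[label].append(LabeledDescriptor(descriptor=desc, label=label))
        i_map += 1
    out = []
    for a, b in zip(by_class["PURINE"], by_class["PYRIMIDINE"]):
        out.extend((a, b))
    return out


def random_rna_sequence(n: int, seed: int = 0, gc: float = 0.5):
    """Seeded i.i.d. RNA sequence with the stated GC fraction."""
    from .seqtools import TargetSequence
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    letters = np.array(list("GCAU"))
    p = np.array([gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2])
    seq = "".join(rng.choice(letters, size=n, p=p))
    return TargetSequence(id=f"random_{seed}", letters=seq, kind="RNA")


def write_bundle(outdir, sequence: str = "GGACUUCGGUCC" * 2, form: str = "A_RNA",
                 resolution: float = 3.0, noise_sd: float = 0.1, seed: int = 0) -> dict:
    """Emit a PDB + CCP4 map + FASTA + ground-truth JSON fixture bundle."""
    os.makedirs(outdir, exist_ok=True)
    st = make_duplex(DuplexSpec(sequence=sequence, form=form))
    dmap = simulate_map(st, MapSimulationParams(resolution=resolution,
                                                noise_sd=noise_sd, seed=seed))
    paths = {k: os.path.join(outdir, v) for k, v in
             (("model", "model.pdb"), ("map", "map.ccp4"),
              ("fasta", "target.fasta"), ("truth", "truth.json"))}
    write_structure(st, paths["model"])
    write_ccp4_map(dmap, paths["map"])
    with open(paths["fasta"], "w") as fh:
        for cid, seq in st.metadata["sequences"].items():
            fh.write(f">chain_{cid}\n{seq}\n")
    with open(paths["truth"], "w") as fh:
        json.dump({"pairs": st.metadata["pairs"],
                   "sequences": st.metadata["sequences"],
                   "form": form, "resolution": resolution,
                   "noise_sd": noise_sd, "seed": seed}, fh, indent=1)
    return paths
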