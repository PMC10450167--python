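"""Sequence-independent base-pair and stacking assignment.

Base pairs are inferred purely from sugar-phosphate backbone geometry:
small search fragments of known secondary structure (by default a
2-base-pair ideal double helix) are superposed onto the model.  Candidate
placements come from matching P-atom triplets by pairwise-distance
compatibility; each candidate is refined on all shared backbone atoms and
accepted below an RMSD cutoff.  A two-step protocol first finds
Watson-Crick pairs with the helical fragment, then (for RNA, when a
recurrent-motif library is supplied) matches motifs against what remains
after removing the interiors of stacked WC runs.
"""

from __future__ import annotations

import itertools
import logging
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from . import _templates as T
from .na_io import NucleicChain, Residue, Structure

logger = logging.getLogger("nucassign")

WC = "WC"
NONCANONICAL = "NONCANONICAL"
STACKING = "STACKING"

RMSD_CUTOFF = 1.0          # A, refined all-backbone acceptance threshold
TRIPLET_TOLERANCE = 1.0    # A, per-distance P-P compatibility window
P_MAP_CUTOFF = 3.0         # A, fragment-residue -> model-P mapping radius

BACKBONE_NAMES = ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'", "C2'", "C1'", "O4'")

# hydrogen-bond restraint targets per WC pair type (purine atom, pyrimidine atom)
WC_HBONDS = {
    ("G", "C"): [("O6", "N4"), ("N1", "N3"), ("N2", "O2")],
    ("A", "U"): [("N1", "N3"), ("N6", "O4")],
    ("A", "T"): [("N1", "N3"), ("N6", "O4")],
}
HBOND_TARGET = (2.9, 0.15)     # A, sigma
NN_TARGET = (8.9, 0.3)         # glycosidic-N to glycosidic-N fallback


@dataclass
class SearchFragment:
    id: str
    residues: list[Residue]
    annotated_pairs: list[tuple[int, int, str]]
    source: str = "HELIX"          # HELIX | MOTIF_LIBRARY

    def __post_init__(self):
        if len(self.residues) < 2:
            raise ValueError("search fragment needs >= 2 residues")
        for i, j, kind in self.annotated_pairs:
            if not (0 <= i < len(self.residues) and 0 <= j < len(self.residues)):
                raise ValueError("annotated pair index out of range")
        if any(r.xyz("P") is None for r in self.residues):
            raise ValueError("every fragment residue needs a P atom")


@dataclass
class FragmentMatch:
    fragment_id: str
    residue_mapping: dict[int, tuple[str, int, str]]   # fragment index -> residue key
    rmsd: float


@dataclass(frozen=True)
class BasePair:
    i: tuple[str, int, str]
    j: tuple[str, int, str]
    interaction: str
    best_rmsd: float
    step: int = 1

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("self-pair")
        if self.j < self.i:
            i0, j0 = self.i, self.j
            object.__setattr__(self, "i", j0)
            object.__setattr__(self, "j", i0)

    @property
    def key(self):
        return (self.i, self.j)


@dataclass
class SecondaryStructure:
    pairs: list[BasePair] = field(default_factory=list)
    model_ref: str = ""

    def wc_pairs(self) -> list[BasePair]:
        return [p for p in self.pairs if p.interaction == WC]

    def partner_of(self, key):
        for p in self.pairs:
            if p.interaction != WC:
                continue
            if p.i == key:
                return p.j
            if p.j == key:
                return p.i
        return None


# ---------------------------------------------------------------------------
# search fragments
# ---------------------------------------------------------------------------

def make_helical_fragment(form: str, n_bp: int = 2) -> SearchFragment:
    """Ideal 2- or 3-bp duplex fragment with annotated WC pairs/stackings."""
    if n_bp not in (2, 3):
        raise ValueError("n_bp must be 2 or 3")
    if form not in T.HELIX_PARAMS:
        raise ValueError(f"unsupported helix form {form!r}")
    from .fixtures import DuplexSpec, make_duplex   # deferred: avoids cycle at import
    seq = "G" * n_bp
    duplex = make_duplex(DuplexSpec(sequence=seq, form=form))
    residues = duplex.chains[0].residues + duplex.chains[1].residues
    pairs: list[tuple[int, int, str]] = []
    for i in range(n_bp):
        pairs.append((i, n_bp + (n_bp - 1 - i), WC))
    for i in range(n_bp - 1):
        pairs.append((i, i + 1, STACKING))
        pairs.append((n_bp + i, n_bp + i + 1, STACKING))
    return SearchFragment(id=f"{form}_{n_bp}bp", residues=residues,
                          annotated_pairs=pairs, source="HELIX")


def load_motif_library(directory) -> list[SearchFragment]:
    """Read a motif-library directory: PDB files + sidecar `.pairs` tables.

    Each `<name>.pdb` may have `<name>.pairs` with lines
    ``res_index_i res_index_j interaction`` (0-based indices into the
    residue list, interaction WC/NONCANONICAL/STACKING).
    """
    from .na_io import read_structure
    fragments = []
    for fn in sorted(os.listdir(directory)):
        if not fn.endswith(".pdb"):
            continue
        st = read_structure(os.path.join(directory, fn))
        residues = [r for c in st.chains for r in c.residues]
        pairs = []
        sidecar = os.path.join(directory, fn[:-4] + ".pairs")
        if os.path.exists(sidecar):
            with open(sidecar) as fh:
                for line in fh:
                    line = line.strip()
                    if not line or line.startswith("#"):
                        continue
                    i, j, kind = line.split()
                    pairs.append((int(i), int(j), kind))
        fragments.append(SearchFragment(id=fn[:-4], residues=residues,
                                        annotated_pairs=pairs,
                                        source="MOTIF_LIBRARY"))
    return fragments


# ---------------------------------------------------------------------------
# fragment matching
# ---------------------------------------------------------------------------

def _model_p_atoms(model: Structure):
    keys, coords = [], []
    for chain in model.chains:
        for res in chain.residues:
            p = res.xyz("P")
            if p is not None:
                keys.append(res.key)
                coords.append(p)
    return keys, np.array(coords) if coords else np.empty((0, 3))


def _shared_backbone(frag_res: Residue, model_res: Residue):
    a, b = [], []
    for name in BACKBONE_NAMES:
        pa, pb = frag_res.xyz(name), model_res.xyz(name)
        if pa is not None and pb is not None:
            a.append(pa)
            b.append(pb)
    return a, b


def match_fragment(fragment: SearchFragment, model: Structure,
                   rmsd_cutoff: float = RMSD_CUTOFF,
                   triplet_tolerance: float = TRIPLET_TOLERANCE) -> list[FragmentMatch]:
    """All placements of `fragment` on `model` below the RMSD cutoff.

    Candidate P-atom triplets are pre-filtered by pairwise distance
    compatibility, superposed, extended to a full residue mapping by
    nearest model P (within 3 A, injective), then refined on all shared
    backbone atoms.  Matches are deduplicated by residue mapping, keeping
    the lowest refined RMSD.
    """
    keys, P = _model_p_atoms(model)
    n = len(P)
    if n < 3:
        return []
    frag_P = np.array([r.xyz("P") for r in fragment.residues])
    nf = len(frag_P)
    model_res_by_key = {r.key: r for c in model.chains for r in c.residues}

    # all model triplets with sorted pairwise distances (vectorized prefilter)
    tri = np.array(list(itertools.combinations(range(n), 3)))
    D = squareform(pdist(P))
    d_tri = np.sort(np.stack([D[tri[:, 0], tri[:, 1]],
                              D[tri[:, 0], tri[:, 2]],
                              D[tri[:, 1], tri[:, 2]]], axis=1), axis=1)

    results: dict[frozenset, FragmentMatch] = {}
    frag_perms = list(itertools.permutations(range(3)))
    for fi in itertools.combinations(range(nf), 3):
        fpts = frag_P[list(fi)]
        fd = np.sort([np.linalg.norm(fpts[0] - fpts[1]),
                      np.linalg.norm(fpts[0] - fpts[2]),
                      np.linalg.norm(fpts[1] - fpts[2])])
        mask = np.all(np.abs(d_tri - fd) <= triplet_tolerance, axis=1)
        for t in tri[mask]:
            for perm in frag_perms:
                tgt = P[t]
                src = fpts[list(perm)]
                # per-correspondence distance check
                ok = all(abs(np.linalg.norm(src[a] - src[b]) - np.linalg.norm(tgt[a] - tgt[b]))
                         <= triplet_tolerance for a, b in ((0, 1), (0, 2), (1, 2)))
                if not ok:
                    continue
                R, tr, _ = T.superpose(src, tgt)
                moved = frag_P @ R.T + tr
                # map each fragment residue to nearest model P
                d2 = np.linalg.norm(moved[:, None, :] - P[None, :, :], axis=2)
                nearest = d2.argmin(axis=1)
                if np.any(d2[np.arange(nf), nearest] > P_MAP_CUTOFF):
                    continue
                if len(set(nearest)) != nf:
                    continue
                mapping = {k: keys[nearest[k]] for k in range(nf)}
                sig = frozenset(mapping.items())
                # refine on all shared backbone atoms
                src_bb, tgt_bb = [], []
                for k in range(nf):
                    a, b = _shared_backbone(fragment.residues[k],
                                            model_res_by_key[mapping[k]])
                    src_bb.extend(a)
                    tgt_bb.extend(b)
                _, _, rmsd = T.superpose(np.array(src_bb), np.array(tgt_bb))
                if rmsd >= rmsd_cutoff:
                    continue
                prev = results.get(sig)
                if prev is None or rmsd < prev.rmsd:
                    results[sig] = FragmentMatch(fragment_id=fragment.id,
                                                 residue_mapping=mapping, rmsd=rmsd)
    return sorted(results.values(), key=lambda m: m.rmsd)


# ---------------------------------------------------------------------------
# two-step assignment
# ---------------------------------------------------------------------------

def _pairs_from_matches(matches, fragment, step):
    best: dict = {}
    for m in matches:
        for i, j, kind in fragment.annotated_pairs:
            ki, kj = m.residue_mapping[i], m.residue_mapping[j]
            if ki == kj:
                continue
            pair = BasePair(i=ki, j=kj, interaction=kind, best_rmsd=m.rmsd, step=step)
            prev = best.get((pair.key, kind))
            if prev is None or pair.best_rmsd < prev.best_rmsd:
                best[(pair.key, kind)] = pair
    return list(best.values())


def _wc_runs(model: Structure, wc_pairs):
    """Runs of >= 3 consecutive WC pairs whose partners are consecutive too."""
    partner = {}
    for p in wc_pairs:
        partner[p.i] = p.j
        partner[p.j] = p.i
    runs = []
    for chain in model.chains:
        keys = [r.key for r in chain.residues]
        run = []
        for a, b in zip(keys, keys[1:]):
            if a in partner and b in partner:
                pa, pb = partner[a], partner[b]
                # partners consecutive (antiparallel) in the partner chain
                consecutive = pa[0] == pb[0] and abs(
                    _index_of(model, pa) - _index_of(model, pb)) == 1
                if consecutive:
                    if not run:
                        run = [a]
                    run.append(b)
                    continue
            if len(run) >= 3:
                runs.append(run)
            run = []
        if len(run) >= 3:
            runs.append(run)
    return runs


def _index_of(model: Structure, key):
    chain = model.chain(key[0])
    for i, r in enumerate(chain.residues):
        if r.key == key:
            return i
    return -1


def _resolve_wc(pairs):
    """Enforce one WC partner per residue, preferring step 2 then low RMSD."""
    out, used = [], set()
    for p in sorted(pairs, key=lambda p: (-p.step, p.best_rmsd)):
        if p.i in used or p.j in used:
            continue
        used.update((p.i, p.j))
        out.append(p)
    return out


def assign_base_pairs(model: Structure,
                      motif_library: list[SearchFragment] | None = None,
                      rmsd_cutoff: float = RMSD_CUTOFF) -> SecondaryStructure:
    """Two-step secondary-structure assignment.

    Step 1 matches the 2-bp ideal helix (A-RNA for RNA models, B-DNA for
    DNA) and yields WC pairs and stackings.  Step 2 (RNA with a motif
    library) removes the interiors of stacked WC runs and matches each
    library fragment against the remainder; step-2 assignments win
    conflicts, then lower RMSD.
    """
    if not model.chains:
        raise ValueError("model has no nucleic chains")
    kinds = [c.kind for c in model.chains]
    kind = "RNA" if kinds.count("RNA") >= kinds.count("DNA") else "DNA"
    helix = make_helical_fragment("A_RNA" if kind == "RNA" else "B_DNA", 2)
    matches = match_fragment(helix, model, rmsd_cutoff=rmsd_cutoff)
    step1 = _pairs_from_matches(matches, helix, step=1)

    step2: list[BasePair] = []
    if kind == "RNA" and motif_library:
        # resolve WC multiplicity first: spurious overlapping helix matches
        # must not distort the stacked-run detection
        wc = _resolve_wc([p for p in step1 if p.interaction == WC])
        partner = {}
        for p in wc:
            partner[p.i] = p.j
            partner[p.j] = p.i
        interior = set()
        for run in _wc_runs(model, wc):
            for key in run[1:-1]:
                interior.add(key)
                interior.add(partner[key])
        pruned_chains = []
        for chain in model.chains:
            kept = [r for r in chain.residues if r.key not in interior]
            if kept:
                pruned_chains.append(NucleicChain(chain_id=chain.chain_id,
                                                  residues=kept, kind=chain.kind))
        pruned = Structure(chains=pruned_chains, cell=model.cell, title=model.title)
        for frag in motif_library:
            mm = match_fragment(frag, pruned, rmsd_cutoff=rmsd_cutoff)
            step2.extend(_pairs_from_matches(mm, frag, step=2))

    # conflict resolution: step 2 wins, then lowest rmsd; WC multiplicity <= 1
    chosen: dict = {}
    for p in step1 + step2:
        prev = chosen.get(p.key)
        if prev is None or (p.step, -p.best_rmsd) > (prev.step, -prev.best_rmsd):
            if prev is None or p.interaction == prev.interaction or p.step > prev.step \
               or (p.step == prev.step and p.best_rmsd < prev.best_rmsd):
                chosen[p.key] = p
    final = _resolve_wc([p for p in chosen.values() if p.interaction == WC])
    final.extend(p for p in chosen.values() if p.interaction != WC)
    return SecondaryStructure(pairs=sorted(final, key=lambda p: p.key),
                              model_ref=model.title)


# ---------------------------------------------------------------------------
# restraint export
# ---------------------------------------------------------------------------

def _pair_letters(model, pair):
    ra = model.residue(pair.i)
    rb = model.residue(pair.j)
    la = T.LETTER_FOR_CODE.get(ra.name)
    lb = T.LETTER_FOR_CODE.get(rb.name)
    return ra, rb, la, lb


def _wc_atom_pairs(la, lb):
    for (pu, py), atoms in WC_HBONDS.items():
        if (la, lb) == (pu, py):
            return [(a, b) for a, b in atoms]
        if (lb, la) == (pu, py):
            return [(b, a) for a, b in atoms]
    return None


def write_restraints(ss: SecondaryStructure, model: Structure,
                     dialect: str = "REFMAC") -> str:
    """Base-pair restraints in REFMAC/PHENIX/ISOLDE/COOT/PYMOL dialects.

    WC pairs with known identities emit hydrogen-bond distance restraints
    (target 2.9 A, sigma 0.15); pairs with unknown/ambiguous identity emit
    one glycosidic-N-glycosidic-N restraint (8.9 A, sigma 0.3).
    """
    dialect = dialect.upper()
    if dialect not in ("REFMAC", "PHENIX", "ISOLDE", "COOT", "PYMOL"):
        raise ValueError(f"unknown restraint dialect {dialect!r}")
    entries = []   # (key_i, atom_i, key_j, atom_j, target, sigma)
    for pair in ss.wc_pairs():
        ra, rb, la, lb = _pair_letters(model, pair)
        atom_pairs = _wc_atom_pairs(la, lb) if la and lb else None
        if atom_pairs and all(ra.has(a) and rb.has(b) for a, b in atom_pairs):
            for a, b in atom_pairs:
                entries.append((pair.i, a, pair.j, b, *HBOND_TARGET))
        else:
            ga = "N9" if (la in T.PURINE_LETTERS if la else ra.has("N9")) else "N1"
            gb = "N9" if (lb in T.PURINE_LETTERS if lb else rb.has("N9")) else "N1"
            entries.append((pair.i, ga, pair.j, gb, *NN_TARGET))

    lines = []
    if dialect == "REFMAC":
        lines.append("# REFMAC5 external base-pair restraints")
        for ki, a, kj, b, tgt, sig in entries:
            lines.append(
                f"exte dist first chain {ki[0]} resi {ki[1]} ins {ki[2] or '.'} atom {a} "
                f"second chain {kj[0]} resi {kj[1]} ins {kj[2] or '.'} atom {b} "
                f"value {tgt} sigma {sig}")
    elif dialect == "PHENIX":
        lines.append("refinement.geometry_restraints.edits {")
        for ki, a, kj, b, tgt, sig in entries:
            lines.append("  bond {")
            lines.append(f"    atom_selection_1 = chain {ki[0]} and resid {ki[1]} and name {a}")
            lines.append(f"    atom_selection_2 = chain {kj[0]} and resid {kj[1]} and name {b}")
            lines.append(f"    distance_ideal = {tgt}")
            lines.append(f"    sigma = {sig}")
            lines.append("  }")
        lines.append("}")
    elif dialect in ("ISOLDE", "COOT"):
        lines.append(f"# {dialect} distance restraints (python)")
        for ki, a, kj, b, tgt, sig in entries:
            lines.append(
                f"add_distance_restraint(('{ki[0]}', {ki[1]}, '{a}'), "
                f"('{kj[0]}', {kj[1]}, '{b}'), {tgt}, {sig})")
    elif dialect == "PYMOL":
        lines.append("# PyMOL base-pair visualisation")
        lines.append("set dash_gap, 0.4")
        lines.append("set dash_radius, 0.1")
        seen_pairs = {}
        for ki, a, kj, b, tgt, sig in entries:
            seen_pairs.setdefault((ki, kj), []).append((a, b))
        for idx, ((ki, kj), atoms) in enumerate(sorted(seen_pairs.items())):
            a, b = atoms[0]
            lines.append(
                f"distance bp_{idx}, chain {ki[0]} and resi {ki[1]} and name {a}, "
                f"chain {kj[0]} and resi {kj[1]} and name {b}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# dot-bracket
# ---------------------------------------------------------------------------

def to_dotbracket(ss: SecondaryStructure, chain: NucleicChain) -> str:
    """One character per residue: maximal nested WC set as (), rest as []."""
    keys = [r.key for r in chain.residues]
    pos = {k: i for i, k in enumerate(keys)}
    pairs = []
    for p in ss.wc_pairs():
        if p.i in pos and p.j in pos:
            a, b = sorted((pos[p.i], pos[p.j]))
            pairs.append((a, b))
    pairs = sorted(set(pairs))
    n = len(keys)
    out = ["."] * n
    if pairs:
        nested = _max_nested(pairs, n)
        for a, b in nested:
            out[a], out[b] = "(", ")"
        for a, b in pairs:
            if (a, b) not in nested:
                out[a], out[b] = "[", "]"
    return "".join(out)


def _max_nested(pairs, n):
    """Maximum-cardinality non-crossing subset (interval DP)."""
    pairset = set(pairs)
    by_j: dict[int, list[int]] = {}
    for a, b in pairs:
        by_j.setdefault(b, []).append(a)
    dp = [[0] * n for _ in range(n)]
    choice = [[None] * n for _ in range(n)]
    for length in range(1, n):
        for i in range(0, n - length):
            j = i + length
            best, pick = dp[i][j - 1], None
            for a in by_j.get(j, []):
                if a < i:
                    continue
                cand = (dp[i][a - 1] if a > i else 0) + dp[a + 1][j - 1] + 1
                if cand > best:
                    best, pick = cand, a
            dp[i][j] = best
            choice[i][j] = pick
    out = set()

    def trace(i, j):
        while i < j:
            a = choice[i][j]
            if a is None:
                j -= 1
                continue
            out.add((a, j))
            if a + 1 < j:
                trace(a + 1, j - 1)
            j = a - 1
    trace(0, n - 1)
    return out
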