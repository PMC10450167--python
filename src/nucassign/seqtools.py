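"""Probabilistic sequence assignment, identification and validation.

A continuous model fragment is summarized by per-residue purine/pyrimidine
probabilities (from the density classifier).  Gapless alignments of the
fragment against a target sequence are scored by the product of per-residue
class probabilities; Watson-Crick pairs inside the fragment contribute a
0.1 correction factor when a tentative alignment puts two same-class bases
across a pair.  Significance is a p-value calibrated against alignment
scores on a long random sequence with a Gumbel (extreme-value) fit and a
1-(1-p)^m length correction.  For database identification the profile is
encoded as a Stockholm MSA whose column composition matches the predicted
probabilities, annotated with the base-pairing pattern, and queried with
covariance-model (INFERNAL) or profile-HMM tools.
"""

from __future__ import annotations

import logging
import math
import os
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from scipy.stats import genextreme

from . import _templates as T
from .classifier import ClassifierModel
from .descriptor import canonical_cloud, extract_descriptor
from .na_io import DensityMap, Fragment, Residue, Structure, chain_fragments
from .secstruct import SecondaryStructure, WC

logger = logging.getLogger("nucassign")

PROB_CLIP = 1e-3
PAIR_CORRECTION = 0.1          # same-class bases across a WC pair
BACKGROUND_SEQ_LEN = 10_000
DEFAULT_N_RANDOM = 200
EULER_GAMMA = 0.5772156649015329

PURINE_SET = frozenset("AG")
PYRIMIDINE_SET = frozenset("CUT")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TargetSequence:
    id: str
    letters: str
    kind: str = "RNA"

    def __post_init__(self):
        if not self.letters:
            raise ValueError("empty target sequence")
        self.letters = self.letters.upper()
        bad = set(self.letters) - set("ACGUTN")
        if bad:
            raise ValueError(f"invalid letters in target sequence: {sorted(bad)}")

    def __len__(self):
        return len(self.letters)

    @property
    def class_indices(self) -> np.ndarray:
        """0 purine, 1 pyrimidine, -1 unknown (N), per position."""
        out = np.empty(len(self.letters), dtype=np.int8)
        for i, c in enumerate(self.letters):
            out[i] = 0 if c in PURINE_SET else (1 if c in PYRIMIDINE_SET else -1)
        return out


@dataclass
class ProbabilityProfile:
    fragment: tuple[str, int, int]             # (chain_id, start seqid, length)
    probs: np.ndarray                          # (n, 2) purine/pyrimidine
    pairs_internal: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        p = np.asarray(self.probs, float)
        if p.ndim != 2 or p.shape[1] != 2:
            raise ValueError("probs must be (n, 2)")
        p = p / p.sum(axis=1, keepdims=True)
        p = np.clip(p, PROB_CLIP, 1 - PROB_CLIP)
        self.probs = p / p.sum(axis=1, keepdims=True)
        n = len(p)
        for i, j in self.pairs_internal:
            if not (0 <= i < n and 0 <= j < n and i != j):
                raise ValueError("internal pair index out of range")

    def __len__(self):
        return len(self.probs)


@dataclass
class AlignmentCandidate:
    offset: int
    log_score: float
    n_corrected_pairs: int = 0


@dataclass
class BackgroundModel:
    samples: np.ndarray          # block maxima of background placement scores
    gumbel_mu: float             # GEV location
    gumbel_beta: float           # GEV scale
    n_positions: int             # block size m (placements in the true target)
    gev_shape: float = 0.0


@dataclass
class AssignmentResult:
    profile: ProbabilityProfile
    best: AlignmentCandidate
    pvalue: float
    target_id: str
    assigned_letters: str
    background: BackgroundModel | None = None
    tied_offsets: list[int] = field(default_factory=list)


@dataclass
class SequenceHit:
    target_id: str
    e_value: float
    mode: str                                   # "CM" | "HMM"
    aligned_region: tuple[int, int] = (0, 0)
    score: float = 0.0


# ---------------------------------------------------------------------------
# alignment scoring
# ---------------------------------------------------------------------------

def _position_log_probs(profile: ProbabilityProfile, cls: np.ndarray) -> np.ndarray:
    """(n, L) per-residue log-probabilities against target class track."""
    logp = np.log(profile.probs)                     # (n, 2)
    L = len(cls)
    out = np.empty((len(profile), L))
    known = cls >= 0
    for i in range(len(profile)):
        out[i, known] = logp[i, cls[known]]
        out[i, ~known] = math.log(0.5)
    return out


def alignment_score(profile: ProbabilityProfile, target: TargetSequence,
                    offset: int) -> AlignmentCandidate:
    """Product-of-probabilities score of one gapless placement (log space)."""
    n = len(profile)
    if offset < 0 or offset + n > len(target):
        raise ValueError(f"window [{offset}, {offset + n}) outside target of "
                         f"length {len(target)}")
    cls = target.class_indices
    logp = np.log(profile.probs)
    score = 0.0
    for i in range(n):
        c = cls[offset + i]
        score += math.log(0.5) if c < 0 else logp[i, c]
    n_corr = 0
    for i, j in profile.pairs_internal:
        ci, cj = cls[offset + i], cls[offset + j]
        if ci >= 0 and cj >= 0 and ci == cj:
            score += math.log(PAIR_CORRECTION)
            n_corr += 1
    return AlignmentCandidate(offset=offset, log_score=score, n_corrected_pairs=n_corr)


def enumerate_alignments(profile: ProbabilityProfile,
                         target: TargetSequence) -> list[AlignmentCandidate]:
    """All gapless placements, sorted by score (desc), ties by offset."""
    n, L = len(profile), len(target)
    if n > L:
        raise ValueError("fragment longer than target")
    cls = target.class_indices
    pos_lp = _position_log_probs(profile, cls)
    m = L - n + 1
    scores = np.zeros(m)
    for i in range(n):
        scores += pos_lp[i, i:i + m]
    n_corr = np.zeros(m, dtype=int)
    for i, j in profile.pairs_internal:
        ci = cls[i:i + m]
        cj = cls[j:j + m]
        same = (ci >= 0) & (cj >= 0) & (ci == cj)
        scores[same] += math.log(PAIR_CORRECTION)
        n_corr[same] += 1
    order = np.lexsort((np.arange(m), -scores))
    return [AlignmentCandidate(offset=int(o), log_score=float(scores[o]),
                               n_corrected_pairs=int(n_corr[o])) for o in order]


# ---------------------------------------------------------------------------
# p-values
# ---------------------------------------------------------------------------

def estimate_pvalue(best: AlignmentCandidate, profile: ProbabilityProfile,
                    target_len: int, n_random: int = DEFAULT_N_RANDOM,
                    seed: int = 0,
                    background: BackgroundModel | None = None) -> tuple[float, BackgroundModel]:
    """Chance probability of a placement score at least as good as `best`.

    The background is built from the profile's gapless placement scores on
    a long seeded random sequence: consecutive scores are cut into
    contiguous blocks of m = target_len - n + 1 placements (so block
    maxima share the overlap correlation of the true target's best score)
    and a generalized extreme-value distribution is fitted to the block
    maxima.  The returned p-value is the fitted GEV survival probability
    at the best score.  With m = 1 this reduces to the single-placement
    tail probability.
    """
    if n_random < 200:
        raise ValueError("n_random must be >= 200")
    n = len(profile)
    m = max(1, target_len - n + 1)
    if background is None or background.n_positions != m:
        background = sample_background(profile, n_random=n_random, seed=seed, m=m)
    if background.gumbel_beta <= 0:
        logger.warning("degenerate background (zero variance); p-value set to 1")
        return 1.0, background
    p = genextreme.sf(best.log_score, background.gev_shape,
                      background.gumbel_mu, background.gumbel_beta)
    return float(min(max(float(p), 1e-300), 1.0)), background


def sample_background(profile: ProbabilityProfile, n_random: int = DEFAULT_N_RANDOM,
                      seed: int = 0, m: int = 1) -> BackgroundModel:
    """Block maxima of placement scores on a seeded uniform random sequence.

    `n_random` blocks of `m` consecutive placements are scored on one long
    random sequence; the per-block maxima are the background samples and a
    GEV is fitted to them (location/scale stored in gumbel_mu/gumbel_beta,
    shape in gev_shape).
    """
    n = len(profile)
    length = n_random * m + n
    rng = np.random.default_rng(seed)
    letters = rng.choice(list("AGCU"), size=length)
    target = TargetSequence(id="background", letters="".join(letters))
    cands = enumerate_alignments(profile, target)
    scores = np.empty(len(cands))
    for c in cands:
        scores[c.offset] = c.log_score
    nb = len(scores) // m
    maxima = scores[:nb * m].reshape(nb, m).max(axis=1)
    if maxima.std(ddof=1) <= 0:
        return BackgroundModel(samples=maxima, gumbel_mu=float(maxima.mean()),
                               gumbel_beta=0.0, n_positions=m)
    shape, loc, scale = genextreme.fit(maxima)
    return BackgroundModel(samples=maxima, gumbel_mu=float(loc),
                           gumbel_beta=float(scale), n_positions=m,
                           gev_shape=float(shape))


# ---------------------------------------------------------------------------
# profiles from models
# ---------------------------------------------------------------------------

def profile_from_fragment(density_map: DensityMap, fragment: Fragment,
                          classifier: ClassifierModel,
                          ss: SecondaryStructure | None = None) -> ProbabilityProfile:
    """Classifier probabilities + intra-fragment WC pairs for one fragment."""
    cloud = canonical_cloud()
    probs = []
    for res in fragment.residues:
        desc = extract_descriptor(density_map, res, cloud)
        lp = classifier.log_proba(desc.values[None, :])[0]
        probs.append(np.exp(lp))
    keys = {r.key: i for i, r in enumerate(fragment.residues)}
    pairs = []
    if ss is not None:
        for p in ss.wc_pairs():
            if p.i in keys and p.j in keys:
                pairs.append((keys[p.i], keys[p.j]))
    return ProbabilityProfile(
        fragment=(fragment.chain_id, fragment.start_seqid, len(fragment)),
        probs=np.array(probs), pairs_internal=pairs)


def _rebuild_base(residue: Residue, letter: str, kind: str) -> None:
    """Replace base atoms with an idealized template base (backbone untouched)."""
    cur_letter = T.LETTER_FOR_CODE.get(residue.name)
    chi = T.residue_chi(residue.xyz, cur_letter) if cur_letter else None
    kept = [a for a in residue.atoms if a.name in T.NA_BACKBONE_SET]
    anchor = {a.name: a.xyz for a in kept}
    from .na_io import AtomRecord
    new_atoms = list(kept)
    for n, elem, xyz in T.build_base_atoms(letter, kind, anchor, chi=chi):
        new_atoms.append(AtomRecord(name=n, element=elem, xyz=xyz))
    residue.atoms = new_atoms
    residue.name = T.CODE_FOR_LETTER[(letter, kind)]
    residue.rebuild_index()


def assign_fragment(model: Structure, density_map: DensityMap, fragment: Fragment,
                    target: TargetSequence, classifier: ClassifierModel,
                    ss: SecondaryStructure | None = None,
                    n_random: int = DEFAULT_N_RANDOM, seed: int = 0,
                    rebuild: bool = True) -> AssignmentResult:
    """Assign one continuous fragment to the target sequence.

    Builds the probability profile, scores all gapless placements, keeps
    the best (ties resolved to the smallest offset, logged), estimates its
    p-value, and rewrites residue identities/base atoms to the aligned
    target letters.
    """
    if len(fragment) > len(target):
        raise ValueError("fragment longer than target sequence")
    profile = profile_from_fragment(density_map, fragment, classifier, ss)
    cands = enumerate_alignments(profile, target)
    best = cands[0]
    tied = [c.offset for c in cands[1:] if c.log_score == best.log_score]
    if tied:
        logger.info("assignment tie at offsets %s; keeping smallest (%d)",
                    [best.offset] + tied, best.offset)
    pvalue, background = estimate_pvalue(best, profile, target_len=len(target),
                                         n_random=n_random, seed=seed)
    letters = target.letters[best.offset:best.offset + len(fragment)]
    kind = "RNA" if target.kind == "RNA" else "DNA"
    if rebuild:
        for res, letter in zip(fragment.residues, letters):
            if letter in ("N",):
                continue
            _rebuild_base(res, letter, kind)
    return AssignmentResult(profile=profile, best=best, pvalue=pvalue,
                            target_id=target.id, assigned_letters=letters,
                            background=background, tied_offsets=tied)


# ---------------------------------------------------------------------------
# Stockholm encoding / database identification
# ---------------------------------------------------------------------------

def stockholm_from_profile(profile: ProbabilityProfile, ss_string: str,
                           n_rows: int = 100, seed: int = 0,
                           rna: bool = True) -> str:
    """Encode class probabilities as an MSA in Stockholm 1.0.

    In each column, round(R * p_purine) rows carry purine letters (split
    as evenly as possible between A and G), the rest pyrimidine letters
    (split between C and U/T); rows are shuffled column-independently with
    a fixed seed so no artificial row-wise sequence is implied.
    """
    n = len(profile)
    if len(ss_string) != n:
        raise ValueError("secondary-structure string length != fragment length")
    rng = np.random.default_rng(seed)
    py = ("C", "U") if rna else ("C", "T")
    cols = []
    for i in range(n):
        k = int(round(n_rows * profile.probs[i, 0]))
        k = min(max(k, 0), n_rows)
        npy = n_rows - k
        col = (["A"] * ((k + 1) // 2) + ["G"] * (k // 2)
               + [py[0]] * ((npy + 1) // 2) + [py[1]] * (npy // 2))
        rng.shuffle(col)
        cols.append(col)
    rows = ["".join(cols[i][r] for i in range(n)) for r in range(n_rows)]
    width = len(f"profile_{n_rows - 1}")
    lines = ["# STOCKHOLM 1.0", ""]
    for r, row in enumerate(rows):
        lines.append(f"{f'profile_{r}':<{width}} {row}")
    ss = ss_string.replace("(", "<").replace(")", ">").replace("[", ".").replace("]", ".")
    lines.append(f"{'#=GC SS_cons':<{width}} {ss}")
    lines.append("//")
    return "\n".join(lines) + "\n"


def _which_or_raise(*programs: str):
    missing = [p for p in programs if shutil.which(p) is None]
    if missing:
        raise EnvironmentError(
            f"required search tool(s) not on PATH: {', '.join(missing)}. "
            "Install the INFERNAL suite (cmbuild/cmcalibrate/cmsearch) for CM "
            "queries, or HMMER (hmmbuild/nhmmer) for profile-HMM queries.")


def _run(cmd: list[str], **kw) -> subprocess.CompletedProcess:
    proc = subprocess.run(cmd, capture_output=True, text=True, **kw)
    if proc.returncode != 0:
        raise RuntimeError(f"{cmd[0]} failed (exit {proc.returncode}):\n{proc.stderr}")
    return proc


def infernal_available() -> bool:
    return all(shutil.which(p) for p in ("cmbuild", "cmcalibrate", "cmsearch"))


def hmmer_available() -> bool:
    return all(shutil.which(p) for p in ("hmmbuild", "nhmmer"))


def _parse_tblout(text: str, evalue_col: int, mode: str) -> list[SequenceHit]:
    hits = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split()
        try:
            e = float(f[evalue_col])
        except (IndexError, ValueError):
            continue
        if mode == "CM":
            region = (int(f[7]), int(f[8]))
            score = float(f[14])
        else:
            region = (int(f[6]), int(f[7]))
            score = float(f[13])
        hits.append(SequenceHit(target_id=f[0], e_value=e, mode=mode,
                                aligned_region=region, score=score))
    return hits


def _search_one(sto_text: str, db_path: str, mode: str, workdir: str,
                rna: bool) -> list[SequenceHit]:
    sto = os.path.join(workdir, "query.sto")
    with open(sto, "w") as fh:
        fh.write(sto_text)
    if infernal_available():
        cm = os.path.join(workdir, "query.cm")
        tbl = os.path.join(workdir, "hits.tbl")
        _run(["cmbuild", "-F", cm, sto])
        if mode == "CM":
            _run(["cmcalibrate", cm])
            _run(["cmsearch", "--tblout", tbl, cm, db_path])
        else:
            _run(["cmsearch", "--hmmonly", "--tblout", tbl, cm, db_path])
        with open(tbl) as fh:
            return _parse_tblout(fh.read(), evalue_col=15, mode=mode)
    if mode == "CM":
        _which_or_raise("cmbuild", "cmcalibrate", "cmsearch")
    _which_or_raise("hmmbuild", "nhmmer")
    # profile-HMM path via HMMER: DNA alphabet, so U -> T on both sides
    sto_dna = sto_text
    if rna:
        lines = []
        for line in sto_dna.splitlines():
            if line.startswith(("#", "//")) or not line.strip():
                lines.append(line)
            else:
                name, seq = line.rsplit(None, 1)
                lines.append(f"{name} {seq.replace('U', 'T')}")
        sto_dna = "\n".join(lines) + "\n"
    sto2 = os.path.join(workdir, "query_dna.sto")
    with open(sto2, "w") as fh:
        fh.write(sto_dna)
    db2 = os.path.join(workdir, "db_dna.fasta")
    with open(db2, "w") as out:
        for rec in SeqIO.parse(db_path, "fasta"):
            out.write(f">{rec.id}\n{str(rec.seq).upper().replace('U', 'T')}\n")
    hmm = os.path.join(workdir, "query.hmm")
    tbl = os.path.join(workdir, "hits.tbl")
    _run(["hmmbuild", "--dna", hmm, sto2])
    _run(["nhmmer", "--watson", "--tblout", tbl, hmm, db2])
    with open(tbl) as fh:
        return _parse_tblout(fh.read(), evalue_col=12, mode="HMM")


def identify_sequence(model: Structure, density_map: DensityMap, db_path,
                      classifier: ClassifierModel, mode: str = "CM",
                      top_n: int = 3, min_fragment: int = 20,
                      ss: SecondaryStructure | None = None,
                      stockholm_seed: int = 0) -> list[SequenceHit]:
    """Query a FASTA database with profiles of all fragments >= 20 nt.

    CM mode builds and calibrates a covariance model (base-pairing aware);
    HMM mode uses a profile HMM and ignores pairing.  Hits are merged
    across fragments (best E-value per target) and the `top_n` lowest
    E-values returned.
    """
    mode = mode.upper()
    if mode not in ("CM", "HMM"):
        raise ValueError("mode must be CM or HMM")
    if mode == "CM" and not infernal_available():
        _which_or_raise("cmbuild", "cmcalibrate", "cmsearch")
    records = list(SeqIO.parse(os.fspath(db_path), "fasta"))
    if not records:
        raise ValueError(f"sequence database {db_path} is empty")
    from .secstruct import assign_base_pairs, to_dotbracket
    if ss is None:
        ss = assign_base_pairs(model)
    rna = all(c.kind == "RNA" for c in model.chains)
    merged: dict[str, SequenceHit] = {}
    with tempfile.TemporaryDirectory(prefix="nucassign_") as workdir:
        for chain in model.chains:
            for frag in chain_fragments(chain):
                if len(frag) < min_fragment:
                    continue
                profile = profile_from_fragment(density_map, frag, classifier, ss)
                db = _dotbracket_for_fragment(ss, frag)
                sto = stockholm_from_profile(profile, db, seed=stockholm_seed, rna=rna)
                for hit in _search_one(sto, os.fspath(db_path), mode, workdir, rna):
                    prev = merged.get(hit.target_id)
                    if prev is None or hit.e_value < prev.e_value:
                        merged[hit.target_id] = hit
    hits = sorted(merged.values(), key=lambda h: (h.e_value, h.target_id))
    return hits[:top_n]


def _dotbracket_for_fragment(ss: SecondaryStructure, frag: Fragment) -> str:
    pos = {r.key: i for i, r in enumerate(frag.residues)}
    out = ["."] * len(frag)
    seen = set()
    for p in ss.wc_pairs():
        if p.i in pos and p.j in pos:
            a, b = sorted((pos[p.i], pos[p.j]))
            if a in seen or b in seen:
                continue
            ok = all(not (x < a < y < b or a < x < b < y)
                     for x, y in zip(*[iter(sorted(seen))] * 2))
            out[a], out[b] = "(", ")"
            seen.update((a, b))
    # drop crossing pairs for the consensus line (rare on fragments)
    return _uncross("".join(out))


def _uncross(db: str) -> str:
    stack, chars = [], list(db)
    for i, c in enumerate(chars):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if stack:
                stack.pop()
            else:
                chars[i] = "."
    for i in stack:
        chars[i] = "."
    return "".join(chars)


# ---------------------------------------------------------------------------
# model validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationFlag:
    chain_id: str
    start_seqid: int
    end_seqid: int
    deposited_offset: int
    suggested_offset: int
    deposited_pvalue: float
    suggested_pvalue: float

    @property
    def register_shift(self) -> int:
        return self.suggested_offset - self.deposited_offset


def validate_model(model: Structure, density_map: DensityMap,
                   sequences: dict[str, TargetSequence],
                   classifier: ClassifierModel,
                   window: int = 20, stride: int = 5,
                   n_random: int = DEFAULT_N_RANDOM, seed: int = 0,
                   ss: SecondaryStructure | None = None) -> list[ValidationFlag]:
    """Scan windows of each chain against its own deposited sequence.

    A window is flagged when the best alternative placement is at least
    two orders of magnitude more significant than the deposited one and
    itself below p = 0.05.
    """
    from .secstruct import assign_base_pairs
    if ss is None:
        ss = assign_base_pairs(model)
    flags = []
    for chain in model.chains:
        target = sequences.get(chain.chain_id)
        if target is None:
            logger.warning("chain %s has no matching sequence; skipped", chain.chain_id)
            continue
        index_in_chain = {r.key: i for i, r in enumerate(chain.residues)}
        for frag in chain_fragments(chain):
            if len(frag) < window:
                continue
            for w0 in range(0, len(frag) - window + 1, stride):
                sub = Fragment(chain_id=frag.chain_id,
                               start_seqid=frag.residues[w0].seqid,
                               residues=frag.residues[w0:w0 + window])
                deposited = index_in_chain[sub.residues[0].key]
                if deposited + window > len(target):
                    continue
                profile = profile_from_fragment(density_map, sub, classifier, ss)
                cands = enumerate_alignments(profile, target)
                background = sample_background(profile, n_random=n_random, seed=seed,
                                               m=len(target) - window + 1)
                dep_cand = next(c for c in cands if c.offset == deposited)
                p_dep, _ = estimate_pvalue(dep_cand, profile, len(target),
                                           n_random, seed, background)
                alt = next((c for c in cands if c.offset != deposited), None)
                if alt is None:
                    continue
                p_alt, _ = estimate_pvalue(alt, profile, len(target),
                                           n_random, seed, background)
                if p_alt < 0.05 and p_alt <= p_dep * 1e-2:
                    flags.append(ValidationFlag(
                        chain_id=chain.chain_id,
                        start_seqid=sub.residues[0].seqid,
                        end_seqid=sub.residues[-1].seqid,
                        deposited_offset=deposited,
                        suggested_offset=alt.offset,
                        deposited_pvalue=p_dep,
                        suggested_pvalue=p_alt))
    return flags


# ---------------------------------------------------------------------------
# sequence randomization
# ---------------------------------------------------------------------------

def randomize_sequence(model: Structure, fraction: float,
                       ss: SecondaryStructure | None = None,
                       seed: int = 0) -> Structure:
    """Class-swap a random subset of nucleobases, keeping WC complementarity.

    A seeded random subset of floor(fraction * N) nucleotides is mutated
    purine<->pyrimidine; when a mutated residue is WC-paired, the partner
    is co-mutated to the WC complement (and counted).  Base atoms are
    rebuilt from templates; the backbone is untouched.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    residues = model.all_residues()
    n_target = int(math.floor(fraction * len(residues)))
    if n_target == 0:
        return model
    partner = {}
    if ss is not None:
        for p in ss.wc_pairs():
            partner[p.i] = p.j
            partner[p.j] = p.i
    by_key = {r.key: r for r in residues}
    kind_by_key = {r.key: c.kind for c in model.chains for r in c.residues}
    order = rng.permutation(len(residues))
    mutated = set()
    count = 0
    for idx in order:
        if count >= n_target:
            break
        res = residues[idx]
        if res.key in mutated:
            continue
        letter = T.LETTER_FOR_CODE.get(res.name)
        if letter is None:
            continue
        kind = kind_by_key[res.key]
        if letter in T.PURINE_LETTERS:
            new = rng.choice(["C", "U" if kind == "RNA" else "T"])
        else:
            new = rng.choice(["A", "G"])
        _rebuild_base(res, str(new), kind)
        mutated.add(res.key)
        count += 1
        pk = partner.get(res.key)
        if pk is not None and pk not in mutated and pk in by_key:
            comp = T.WC_COMPLEMENT[kind_by_key[pk]][str(new)]
            _rebuild_base(by_key[pk], comp, kind_by_key[pk])
            mutated.add(pk)
            count += 1
    return model
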