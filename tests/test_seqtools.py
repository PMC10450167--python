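import math
import os
import shutil
import subprocess

import numpy as np
import pytest

from nucassign.fixtures import (DuplexSpec, MapSimulationParams, make_duplex,
                                random_rna_sequence, simulate_map)
from nucassign.na_io import chain_fragments
from nucassign.secstruct import BasePair, SecondaryStructure, WC, assign_base_pairs
from nucassign.seqtools import (AlignmentCandidate, ProbabilityProfile,
                                TargetSequence, alignment_score, assign_fragment,
                                enumerate_alignments, estimate_pvalue,
                                identify_sequence, infernal_available,
                                randomize_sequence, sample_background,
                                stockholm_from_profile, validate_model,
                                PROB_CLIP)


def certain_profile(classes, pairs=()):
    """Profile with probability 1 (clipped) on the given class per residue."""
    probs = np.array([[1.0, 0.0] if c == "R" else [0.0, 1.0] for c in classes])
    return ProbabilityProfile(fragment=("A", 1, len(classes)), probs=probs,
                              pairs_internal=list(pairs))


class TestAlignmentScore:
    def test_product_of_near_ones(self):
        prof = certain_profile("RRYY")
        target = TargetSequence(id="t", letters="AGCU")
        cand = alignment_score(prof, target, 0)
        assert cand.log_score == pytest.approx(4 * math.log(1 - PROB_CLIP), abs=1e-12)

    def test_pair_correction_factor_log10(self):
        prof_nopair = certain_profile("RYYR")
        prof_pair = certain_profile("RYYR", pairs=[(0, 3)])
        # G...C across the pair: purine-pyrimidine, correction 1
        ok = TargetSequence(id="t", letters="GCCC")
        s0 = alignment_score(prof_nopair, ok, 0).log_score
        s1 = alignment_score(prof_pair, ok, 0).log_score
        assert s1 == pytest.approx(s0, abs=1e-12)
        # G...G across the pair: same class, correction 0.1
        bad = TargetSequence(id="t", letters="GCCG")
        prof_pair2 = certain_profile("RYYR"[:3] + "R", pairs=[(0, 3)])
        s2_no = alignment_score(certain_profile("RYYR"[:3] + "R"), bad, 0).log_score
        s2 = alignment_score(prof_pair2, bad, 0).log_score
        assert s2 - s2_no == pytest.approx(math.log(0.1), abs=1e-12)
        assert alignment_score(prof_pair2, bad, 0).n_corrected_pairs == 1

    def test_uniform_profile_constant_score(self):
        n = 6
        prof = ProbabilityProfile(fragment=("A", 1, n), probs=np.full((n, 2), 0.5))
        target = random_rna_sequence(30, seed=1)
        for off in (0, 7, 24):
            s = alignment_score(prof, target, off).log_score
            assert s == pytest.approx(n * math.log(0.5), abs=1e-12)

    def test_n_letters_contribute_half(self):
        prof = certain_profile("RR")
        target = TargetSequence(id="t", letters="NN")
        s = alignment_score(prof, target, 0).log_score
        assert s == pytest.approx(2 * math.log(0.5), abs=1e-12)

    def test_out_of_range_raises(self):
        prof = certain_profile("RRR")
        target = TargetSequence(id="t", letters="AGC")
        with pytest.raises(ValueError):
            alignment_score(prof, target, 1)


class TestEnumerateAlignments:
    def test_candidate_count(self):
        prof = certain_profile("RYRY")
        target = random_rna_sequence(60, seed=2)
        cands = enumerate_alignments(prof, target)
        assert len(cands) == 60 - 4 + 1

    def test_matches_bruteforce_rescoring(self):
        rng = np.random.default_rng(3)
        for rep in range(100):
            n = int(rng.integers(2, 16))
            L = int(rng.integers(n, 61))
            probs = rng.uniform(0.01, 0.99, (n, 2))
            pairs = []
            if n >= 4 and rng.random() < 0.5:
                i, j = rng.choice(n, 2, replace=False)
                pairs = [(int(i), int(j))]
            prof = ProbabilityProfile(fragment=("A", 1, n), probs=probs,
                                      pairs_internal=pairs)
            target = random_rna_sequence(L, seed=1000 + rep)
            cands = enumerate_alignments(prof, target)
            for c in cands:
                direct = alignment_score(prof, target, c.offset)
                assert abs(direct.log_score - c.log_score) < 1e-12
            best_direct = max(range(L - n + 1),
                              key=lambda o: (alignment_score(prof, target, o).log_score, -o))
            assert cands[0].offset == best_direct

    def test_ties_broken_by_smaller_offset(self):
        prof = ProbabilityProfile(fragment=("A", 1, 2), probs=np.full((2, 2), 0.5))
        target = random_rna_sequence(10, seed=4)
        cands = enumerate_alignments(prof, target)
        assert [c.offset for c in cands] == list(range(9))

    def test_monotonicity_in_correct_class_probability(self):
        rng = np.random.default_rng(6)
        target = random_rna_sequence(40, seed=7)
        true_off = 11
        n = 8
        window = target.letters[true_off:true_off + n]
        cls = ["R" if c in "AG" else "Y" for c in window]
        probs = rng.uniform(0.3, 0.7, (n, 2))
        for k in range(n):
            base = ProbabilityProfile(fragment=("A", 1, n), probs=probs.copy())
            s0 = alignment_score(base, target, true_off).log_score
            boosted = probs.copy()
            ci = 0 if cls[k] == "R" else 1
            boosted[k, ci] = min(0.99, boosted[k, ci] + 0.2)
            boosted[k, 1 - ci] = 1 - boosted[k, ci]
            s1 = alignment_score(ProbabilityProfile(fragment=("A", 1, n),
                                                    probs=boosted),
                                 target, true_off).log_score
            assert s1 >= s0 - 1e-12


class TestPvalue:
    def test_score_below_background_minimum_gives_p_near_one(self):
        prof = certain_profile("RYRYRYRY")
        bg = sample_background(prof, n_random=300, seed=1, m=43)
        low = AlignmentCandidate(offset=0, log_score=float(bg.samples.min() - 50))
        p, _ = estimate_pvalue(low, prof, target_len=50, seed=1, background=bg)
        assert p > 0.99

    def test_m_equals_one_is_single_placement_tail(self):
        prof = certain_profile("RYRYRYRY")
        cand = AlignmentCandidate(offset=0, log_score=-5.0)
        p, bg = estimate_pvalue(cand, prof, target_len=len(prof), seed=2)
        assert bg.n_positions == 1
        from scipy.stats import genextreme
        expected = genextreme.sf(cand.log_score, bg.gev_shape, bg.gumbel_mu,
                                 bg.gumbel_beta)
        assert p == pytest.approx(float(expected))

    def test_n_random_floor(self):
        prof = certain_profile("RY")
        with pytest.raises(ValueError):
            estimate_pvalue(AlignmentCandidate(0, -1.0), prof, 10, n_random=50)

    def test_null_pvalues_are_uniform(self):
        """KS uniformity of p-values for random profiles vs random targets."""
        from scipy.stats import kstest
        rng = np.random.default_rng(42)
        n, L = 20, 120
        pvals = []
        for rep in range(150):
            conf = rng.uniform(0.7, 0.999, n)
            cls = rng.integers(0, 2, n)
            probs = np.where(cls[:, None] == np.arange(2)[None, :],
                             conf[:, None], 1 - conf[:, None])
            prof = ProbabilityProfile(fragment=("A", 1, n), probs=probs)
            target = random_rna_sequence(L, seed=10_000 + rep)
            best = enumerate_alignments(prof, target)[0]
            p, _ = estimate_pvalue(best, prof, L, seed=20_000 + rep)
            pvals.append(p)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestStockholm:
    def test_certain_column_splits_purines_evenly(self):
        prof = certain_profile("R")
        sto = stockholm_from_profile(prof, ".", n_rows=100, seed=0)
        rows = [l.split()[-1] for l in sto.splitlines()
                if l.startswith("profile_")]
        col = [r[0] for r in rows]
        assert col.count("A") == 50 and col.count("G") == 50

    def test_half_half_column(self):
        prof = ProbabilityProfile(fragment=("A", 1, 1), probs=np.array([[0.5, 0.5]]))
        sto = stockholm_from_profile(prof, ".", n_rows=100, seed=0)
        rows = [l.split()[-1] for l in sto.splitlines() if l.startswith("profile_")]
        col = [r[0] for r in rows]
        assert sum(c in "AG" for c in col) == 50

    def test_roundtrip_frequencies_match_probabilities(self):
        rng = np.random.default_rng(5)
        n, R = 12, 100
        probs = rng.uniform(0.05, 0.95, (n, 1))
        probs = np.hstack([probs, 1 - probs])
        prof = ProbabilityProfile(fragment=("A", 1, n), probs=probs)
        sto = stockholm_from_profile(prof, "." * n, n_rows=R, seed=1)
        rows = [l.split()[-1] for l in sto.splitlines() if l.startswith("profile_")]
        assert len(rows) == R
        for i in range(n):
            freq = sum(r[i] in "AG" for r in rows) / R
            assert abs(freq - prof.probs[i, 0]) <= 1.0 / R + 1e-9
        assert "#=GC SS_cons" in sto
        assert sto.startswith("# STOCKHOLM 1.0")

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            stockholm_from_profile(certain_profile("RY"), ".")

    def test_accepted_by_profile_builder_without_warnings(self, tmp_path):
        """hmmbuild (and cmbuild when present) accept the emitted Stockholm."""
        prof = certain_profile("RYRYGGRYRYRYGGRYRYRY"[:20])
        sto_text = stockholm_from_profile(prof, "((((....))))........", seed=0)
        sto = tmp_path / "q.sto"
        sto.write_text(sto_text)
        if infernal_available():
            out = subprocess.run(["cmbuild", "-F", str(tmp_path / "q.cm"), str(sto)],
                                 capture_output=True, text=True)
            assert out.returncode == 0
            assert "WARNING" not in out.stderr.upper()
        assert shutil.which("hmmbuild"), "hmmbuild expected on PATH"
        dna = "\n".join(l if l.startswith(("#", "//")) or not l.strip()
                        else l.replace("U", "T") for l in sto_text.splitlines())
        sto_dna = tmp_path / "q_dna.sto"
        sto_dna.write_text(dna + "\n")
        out = subprocess.run(["hmmbuild", "--dna", str(tmp_path / "q.hmm"),
                              str(sto_dna)], capture_output=True, text=True)
        assert out.returncode == 0
        assert "warning" not in (out.stdout + out.stderr).lower()


@pytest.fixture(scope="module")
def assigned_fixture(em_classifier):
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("AGCU"), 40))
    st = make_duplex(DuplexSpec(sequence=seq, form="A_RNA"))
    dmap = simulate_map(st, MapSimulationParams(resolution=3.0, noise_sd=0.1, seed=3))
    ss = assign_base_pairs(st)
    return st, dmap, ss, seq


class TestAssignFragment:
    def test_recovers_true_sequence(self, assigned_fixture, em_classifier):
        st, dmap, ss, seq = assigned_fixture
        decoy = random_rna_sequence(40, seed=9)
        target = TargetSequence(id="t", letters=decoy.letters[:20] + seq
                                + decoy.letters[20:])
        frag = chain_fragments(st.chains[0])[0]
        res = assign_fragment(st, dmap, frag, target, em_classifier, ss=ss,
                              seed=11, rebuild=False)
        assert res.best.offset == 20
        assert res.assigned_letters == seq
        assert res.pvalue < 0.01

    def test_rebuild_renames_and_preserves_backbone(self, assigned_fixture,
                                                    em_classifier):
        import copy
        st, dmap, ss, seq = assigned_fixture
        st = copy.deepcopy(st)
        target = TargetSequence(id="t", letters=seq)
        frag = chain_fragments(st.chains[0])[0]
        bb_before = {r.key: r.xyz("P").copy() for r in frag.residues}
        res = assign_fragment(st, dmap, frag, target, em_classifier, ss=ss, seed=1)
        assert "".join(r.name for r in frag.residues) == seq
        for r in frag.residues:
            assert np.array_equal(r.xyz("P"), bb_before[r.key])

    def test_ambiguous_purine_repeat_ties_to_smallest_offset(self, em_classifier):
        prof = certain_profile("RR")
        target = TargetSequence(id="t", letters="AGAGAG")
        cands = enumerate_alignments(prof, target)
        assert cands[0].offset == 0
        assert cands[0].log_score == cands[1].log_score

    def test_length_one_fragment_uninformative(self, assigned_fixture, em_classifier):
        st, dmap, ss, seq = assigned_fixture
        frag_all = chain_fragments(st.chains[0])[0]
        from nucassign.na_io import Fragment
        frag1 = Fragment(chain_id="A", start_seqid=1,
                         residues=frag_all.residues[:1])
        target = TargetSequence(id="t", letters=random_rna_sequence(50, seed=3).letters)
        res = assign_fragment(st, dmap, frag1, target, em_classifier, ss=ss,
                              seed=2, rebuild=False)
        assert res.pvalue > 0.2

    def test_fragment_longer_than_target_raises(self, assigned_fixture, em_classifier):
        st, dmap, ss, seq = assigned_fixture
        frag = chain_fragments(st.chains[0])[0]
        target = TargetSequence(id="t", letters="AGC")
        with pytest.raises(ValueError):
            assign_fragment(st, dmap, frag, target, em_classifier, ss=ss)


def _write_decoy_db(path, truth, n_decoys=50, include_truth=True, seed=0):
    with open(path, "w") as fh:
        if include_truth:
            fh.write(f">true_seq\n{truth}\n")
        for i in range(n_decoys):
            rng = np.random.default_rng(seed + i)
            fh.write(f">decoy_{i}\n{''.join(rng.permutation(list(truth)))}\n")


class TestIdentifySequence:
    def test_hmm_mode_ranks_true_sequence_first(self, assigned_fixture,
                                                em_classifier, tmp_path):
        st, dmap, ss, seq = assigned_fixture
        db = tmp_path / "db.fasta"
        _write_decoy_db(db, seq)
        hits = identify_sequence(st, dmap, db, em_classifier, mode="HMM",
                                 top_n=3, ss=ss)
        assert hits, "no hits returned"
        assert hits[0].target_id == "true_seq"
        assert hits[0].e_value < 0.1
        assert hits[0].mode == "HMM"

    def test_decoy_only_db_gives_no_confident_hit(self, assigned_fixture,
                                                  em_classifier, tmp_path):
        st, dmap, ss, seq = assigned_fixture
        db = tmp_path / "db.fasta"
        _write_decoy_db(db, seq, include_truth=False)
        hits = identify_sequence(st, dmap, db, em_classifier, mode="HMM",
                                 top_n=3, ss=ss)
        assert all(h.e_value >= 0.1 for h in hits)

    def test_cm_mode_contract(self, assigned_fixture, em_classifier, tmp_path):
        """CM mode runs the INFERNAL pipeline, or raises an actionable error."""
        st, dmap, ss, seq = assigned_fixture
        db = tmp_path / "db.fasta"
        _write_decoy_db(db, seq)
        if infernal_available():
            hits = identify_sequence(st, dmap, db, em_classifier, mode="CM",
                                     top_n=3, ss=ss)
            assert hits[0].target_id == "true_seq"
            assert hits[0].e_value < 0.1
        else:
            with pytest.raises(EnvironmentError, match="INFERNAL"):
                identify_sequence(st, dmap, db, em_classifier, mode="CM",
                                  top_n=3, ss=ss)

    def test_empty_db_raises(self, assigned_fixture, em_classifier, tmp_path):
        st, dmap, ss, seq = assigned_fixture
        db = tmp_path / "empty.fasta"
        db.write_text("")
        with pytest.raises(ValueError):
            identify_sequence(st, dmap, db, em_classifier, mode="HMM", ss=ss)


class TestValidateModel:
    def test_correct_model_yields_zero_flags(self, assigned_fixture, em_classifier):
        st, dmap, ss, seq = assigned_fixture
        seqs = {c.chain_id: TargetSequence(id=c.chain_id,
                                           letters=st.metadata["sequences"][c.chain_id])
                for c in st.chains}
        flags = validate_model(st, dmap, seqs, em_classifier, window=20,
                               stride=5, seed=4, ss=ss)
        assert flags == []

    def test_register_shift_is_flagged_with_correct_shift(self, assigned_fixture,
                                                          em_classifier):
        st, dmap, ss, seq = assigned_fixture
        # deposited sequence with one extra leading base: model is shifted +1
        seqs = {"A": TargetSequence(id="A", letters="G" + seq),
                "B": TargetSequence(id="B",
                                    letters=st.metadata["sequences"]["B"])}
        flags = validate_model(st, dmap, seqs, em_classifier, window=20,
                               stride=5, seed=4, ss=ss)
        a_flags = [f for f in flags if f.chain_id == "A"]
        assert a_flags
        assert all(f.register_shift == 1 for f in a_flags)

    def test_noise_map_produces_no_confident_flags(self, assigned_fixture,
                                                   em_classifier):
        st, dmap, ss, seq = assigned_fixture
        rng = np.random.default_rng(8)
        noise = type(dmap)(values=rng.normal(0, 1, dmap.grid_shape),
                           cell=dmap.cell, origin_frac=dmap.origin_frac)
        seqs = {c.chain_id: TargetSequence(id=c.chain_id,
                                           letters=st.metadata["sequences"][c.chain_id])
                for c in st.chains}
        flags = validate_model(st, noise, seqs, em_classifier, window=20,
                               stride=5, seed=4, ss=ss)
        assert flags == []

    def test_chain_without_sequence_is_skipped(self, assigned_fixture, em_classifier):
        st, dmap, ss, seq = assigned_fixture
        seqs = {"A": TargetSequence(id="A", letters=seq)}
        flags = validate_model(st, dmap, seqs, em_classifier, window=20,
                               stride=5, seed=4, ss=ss)
        assert all(f.chain_id == "A" for f in flags)


class TestRandomizeSequence:
    def test_fraction_zero_is_identity(self):
        import copy
        st = make_duplex(DuplexSpec(sequence="GAUCGAUC", form="A_RNA"))
        names = [r.name for c in st.chains for r in c.residues]
        randomize_sequence(st, 0.0, seed=1)
        assert [r.name for c in st.chains for r in c.residues] == names

    def test_fraction_one_unpaired_strand_swaps_every_class(self):
        st = make_duplex(DuplexSpec(sequence="GAUCGAUC", form="A_RNA",
                                    include_complement=False))
        before = [r.name for r in st.chains[0].residues]
        randomize_sequence(st, 1.0, seed=2)
        after = [r.name for r in st.chains[0].residues]
        pur = {"A", "G"}
        for b, a in zip(before, after):
            assert (b in pur) != (a in pur), f"{b} -> {a} not class-swapped"

    def test_duplex_stays_wc_complementary(self):
        st = make_duplex(DuplexSpec(sequence="GAUCGAUCGAUCGAUCGAUC", form="A_RNA"))
        ss = assign_base_pairs(st)
        randomize_sequence(st, 0.9, ss=ss, seed=3)
        comp = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
        for ka, kb in st.metadata["pairs"]:
            ra, rb = st.residue(tuple(ka)), st.residue(tuple(kb))
            assert (ra.name, rb.name) in comp

    def test_bad_fraction_raises(self):
        st = make_duplex(DuplexSpec(sequence="GAUC", form="A_RNA"))
        with pytest.raises(ValueError):
            randomize_sequence(st, 1.5, seed=0)
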