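"""Profile-HMM model, HMMER3 I/O, construction and local Viterbi scoring."""

import io
import math

import numpy as np
import pytest

from markergenie.errors import FormatError, HmmParseError, ValidationError
from markergenie.profilehmm import (
    AMINO_ACIDS,
    ProfileHMM,
    build_from_alignment,
    parse_hmm3,
    score_local,
    viterbi_raw,
    write_hmm3,
)
from markergenie.synthdata import FamilySpec, evolve_family

from .oracles import enumerate_local_score, random_profile_hmm

UNIFORM_RECORD = """\
HMMER3/f [3.4 | Aug 2023]
NAME  uni1
LENG  1
ALPH  amino
HMM          A        C        D        E        F        G        H        I        K        L        M        N        P        Q        R        S        T        V        W        Y
            m->m     m->i     m->d     i->m     i->i     d->m     d->d
""" + "  COMPO " + "  2.99573" * 20 + "\n" \
    + "        " + "  2.99573" * 20 + "\n" \
    + "          0.69315  1.38629  1.38629  0.69315  0.69315  0.69315  0.69315\n" \
    + "      1 " + "  2.99573" * 20 + "\n" \
    + "        " + "  2.99573" * 20 + "\n" \
    + "          0.69315  0.69315        *  0.69315  0.69315  0.00000        *\n//\n"


class TestParseHmm3:
    def test_uniform_single_node_record(self):
        """-ln(0.05) = 2.99573 decodes to emission probability 0.05 everywhere."""
        (hmm,) = parse_hmm3(io.StringIO(UNIFORM_RECORD))
        assert hmm.name == "uni1"
        assert hmm.length == 1
        assert np.allclose(hmm.match_emissions, 0.05, atol=1e-5)
        assert np.allclose(hmm.background, 0.05, atol=1e-5)
        # '*' decodes to probability zero
        assert hmm.transitions[1, 2] == 0.0
        assert hmm.transitions[1, 6] == 0.0

    def test_fasta_stream_is_rejected(self):
        with pytest.raises(FormatError, match="HMMER3"):
            parse_hmm3(io.StringIO(">seq1\nACDEF\n"))

    def test_empty_stream_is_rejected(self):
        with pytest.raises(FormatError):
            parse_hmm3(io.StringIO(""))

    def test_short_emission_row_names_node(self):
        broken = UNIFORM_RECORD.replace("      1 " + "  2.99573" * 20,
                                        "      1 " + "  2.99573" * 7)
        with pytest.raises(HmmParseError, match="node 1"):
            parse_hmm3(io.StringIO(broken))

    def test_non_numeric_token_is_rejected(self):
        broken = UNIFORM_RECORD.replace("0.69315  1.38629", "0.69315  oops1.3")
        with pytest.raises(HmmParseError, match="non-numeric"):
            parse_hmm3(io.StringIO(broken))


class TestWriteHmm3:
    @pytest.mark.parametrize("m", [1, 2, 5, 12])
    def test_roundtrip_random_models(self, m):
        """parse(write(h)) returns h's parameters within 1e-6."""
        rng = np.random.default_rng(100 + m)
        for rep in range(8):
            hmm = random_profile_hmm(rng, m, name=f"rt{m}_{rep}", sparse=(rep % 2 == 0))
            (back,) = parse_hmm3(io.StringIO(write_hmm3(hmm)))
            for a, b in (
                (hmm.match_emissions, back.match_emissions),
                (hmm.insert_emissions, back.insert_emissions),
                (hmm.transitions, back.transitions),
                (hmm.background, back.background),
            ):
                assert np.abs(a - b).max() < 1e-6

    def test_zero_probability_written_as_star(self):
        rng = np.random.default_rng(0)
        hmm = random_profile_hmm(rng, 2)
        hmm.transitions[1, 1] = 0.0  # zero out M->I at node 1
        hmm.transitions[1, 0] = 1.0 - hmm.transitions[1, 2]
        text = write_hmm3(hmm)
        node1_trans = text.splitlines()[-5]
        assert "*" in node1_trans

    def test_invalid_model_is_rejected(self):
        rng = np.random.default_rng(1)
        hmm = random_profile_hmm(rng, 2)
        hmm.match_emissions[0, 0] += 0.5  # break row normalization
        with pytest.raises(ValidationError, match="match_emissions"):
            write_hmm3(hmm)

    def test_multi_record_stream(self):
        rng = np.random.default_rng(2)
        h1 = random_profile_hmm(rng, 2, name="a")
        h2 = random_profile_hmm(rng, 3, name="b")
        models = parse_hmm3(io.StringIO(write_hmm3(h1) + write_hmm3(h2)))
        assert [h.name for h in models] == ["a", "b"]

    def test_cutoff_lines_roundtrip(self):
        from markergenie.profilehmm import CutoffPair

        rng = np.random.default_rng(3)
        hmm = random_profile_hmm(rng, 2).with_cutoffs(
            CutoffPair(trusted=50.0, noise=20.0, gathering=35.0, separable=True)
        )
        (back,) = parse_hmm3(io.StringIO(write_hmm3(hmm)))
        assert back.cutoffs is not None
        assert back.cutoffs.gathering == pytest.approx(35.0)
        assert back.cutoffs.trusted == pytest.approx(50.0)
        assert back.cutoffs.noise == pytest.approx(20.0)
        assert back.cutoffs.separable

    def test_pyhmmer_reads_written_files(self, tmp_path):
        """Written files are valid HMMER3/f for an independent parser."""
        pyhmmer = pytest.importorskip("pyhmmer")
        rng = np.random.default_rng(4)
        hmm = random_profile_hmm(rng, 6, name="xcheck")
        path = tmp_path / "xcheck.hmm"
        path.write_text(write_hmm3(hmm))
        with pyhmmer.plan7.HMMFile(str(path)) as fh:
            ph = fh.read()
        assert ph.M == hmm.length
        me = np.asarray(ph.match_emissions)[1:]  # pyhmmer row 0 is node 0
        assert np.abs(me - hmm.match_emissions).max() < 1e-6


class TestBuildFromAlignment:
    def test_laplace_smoothed_emissions(self):
        """Two identical 'ACD' sequences: P(A at node 1) = (2+1)/(2+20)."""
        hmm = build_from_alignment(["ACD", "ACD"], pseudocount=1.0, match_fraction=0.5)
        assert hmm.length == 3
        assert hmm.match_emissions[0, AMINO_ACIDS.index("A")] == pytest.approx(3 / 22)
        assert hmm.match_emissions[1, AMINO_ACIDS.index("C")] == pytest.approx(3 / 22)

    def test_gappy_column_is_not_a_match_state(self):
        seqs = ["AC", "A-", "A-", "A-"]  # column 2 non-gap fraction 0.25 < 0.5
        hmm = build_from_alignment(seqs, match_fraction=0.5)
        assert hmm.length == 1

    def test_no_match_column_raises(self):
        from markergenie.errors import ConstructionError

        with pytest.raises(ConstructionError):
            build_from_alignment(["--", "--", "AC", "AC"], match_fraction=0.9)

    def test_ragged_alignment_raises(self):
        with pytest.raises(ValidationError):
            build_from_alignment(["ACD", "AC"])

    def test_consensus_recovers_simulated_root(self):
        """20 members at substitution rate 0.05: consensus ~= root."""
        spec = FamilySpec("fam", root_length=120, n_members=20,
                          substitution_rate=0.05, seed=77)
        root, members = evolve_family(spec)
        hmm = build_from_alignment(members)
        cons = hmm.consensus()
        ident = sum(a == b for a, b in zip(cons, root)) / len(root)
        assert ident >= 0.95


class TestScoreLocal:
    def test_flat_model_yields_no_hit(self):
        """Match emissions equal to background: log-odds never positive."""
        bg = np.full(20, 0.05)
        m = 3
        trans = np.tile([0.8, 0.1, 0.1, 0.5, 0.5, 0.5, 0.5], (m + 1, 1))
        trans[m] = [0.9, 0.1, 0.0, 0.5, 0.5, 1.0, 0.0]
        hmm = ProfileHMM("flat", np.tile(bg, (m, 1)), np.tile(bg, (m, 1)), trans, bg)
        hmm.validate()
        assert score_local(hmm, "ACDEFGHIKL") is None

    def test_matches_bruteforce_enumeration(self):
        """DP equals exhaustive path enumeration on small random instances."""
        rng = np.random.default_rng(11)
        checked = 0
        for case in range(80):
            m = int(rng.integers(1, 4))
            hmm = random_profile_hmm(rng, m, sparse=(case % 3 == 0))
            prot = "".join(rng.choice(list("ACDEFGHX"), size=int(rng.integers(1, 5))))
            got = viterbi_raw(hmm, prot)
            exp = enumerate_local_score(hmm, prot)
            if exp is None:
                continue
            assert got[0] == pytest.approx(exp[0], abs=1e-9)
            checked += 1
        assert checked >= 60

    def test_peaked_consensus_beats_all_single_substitutions(self):
        """A sharply peaked profile prefers its consensus to any 1-sub variant."""
        m = 6
        cons = "ACDEFG"
        match = np.full((m, 20), 0.01 / 19)
        for k, aa in enumerate(cons):
            match[k, AMINO_ACIDS.index(aa)] = 0.99
        bg = np.full(20, 0.05)
        trans = np.tile([0.9, 0.05, 0.05, 0.5, 0.5, 0.5, 0.5], (m + 1, 1))
        trans[m] = [0.95, 0.05, 0.0, 0.5, 0.5, 1.0, 0.0]
        hmm = ProfileHMM("peak", match, np.tile(bg, (m, 1)), trans, bg)
        hmm.validate()
        s_cons = viterbi_raw(hmm, cons)[0]
        for k in range(m):
            for aa in AMINO_ACIDS:
                if aa == cons[k]:
                    continue
                variant = cons[:k] + aa + cons[k + 1:]
                assert viterbi_raw(hmm, variant)[0] < s_cons

    def test_score_never_decreases_under_extension(self):
        """Appending residues preserves all existing local alignments."""
        rng = np.random.default_rng(13)
        for _ in range(20):
            hmm = random_profile_hmm(rng, int(rng.integers(2, 6)))
            prot = "".join(rng.choice(list(AMINO_ACIDS), size=6))
            prev = viterbi_raw(hmm, prot)[0]
            for _ in range(4):
                prot += str(rng.choice(list(AMINO_ACIDS)))
                cur = viterbi_raw(hmm, prot)[0]
                assert cur >= prev - 1e-12
                prev = cur

    def test_scale_invariance_probability_vs_neglog(self):
        """Scores agree whether parameters arrive as probabilities or as
        exp(-neglog) round-tripped values (full float precision)."""
        rng = np.random.default_rng(17)
        for _ in range(10):
            hmm = random_profile_hmm(rng, int(rng.integers(1, 8)))
            prot = "".join(rng.choice(list(AMINO_ACIDS), size=12))

            def roundtrip(a):
                with np.errstate(divide="ignore"):
                    neglog = -np.log(a)
                return np.exp(-neglog)

            hmm2 = ProfileHMM(
                hmm.name,
                roundtrip(hmm.match_emissions),
                roundtrip(hmm.insert_emissions),
                roundtrip(hmm.transitions),
                roundtrip(hmm.background),
            )
            assert viterbi_raw(hmm2, prot)[0] == pytest.approx(
                viterbi_raw(hmm, prot)[0], abs=1e-9
            )

    def test_hit_coordinates_cover_consensus(self):
        rng = np.random.default_rng(19)
        spec = FamilySpec("f", root_length=50, n_members=10, seed=5)
        root, members = evolve_family(spec)
        hmm = build_from_alignment(members)
        hit = score_local(hmm, "MMMM" + root + "WWWW", orf_id="q")
        assert hit is not None
        assert hit.bit_score > 10
        assert (hit.seq_start, hit.seq_end) == (4, 4 + 50)
        assert (hit.node_start, hit.node_end) == (0, 50)

    def test_input_validation(self):
        rng = np.random.default_rng(23)
        hmm = random_profile_hmm(rng, 2)
        with pytest.raises(ValidationError):
            viterbi_raw(hmm, "")
        with pytest.raises(ValidationError):
            viterbi_raw(hmm, "AC1")
        # 'X' is allowed and contributes zero log-odds
        assert math.isfinite(viterbi_raw(hmm, "AXC")[0])
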