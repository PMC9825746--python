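"""Internal Viterbi aligner, hmmscan output parsing, external driver."""

import shutil

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codonlens.align import (
    parse_search_alignments,
    parse_search_output_files,
    read_segments,
    run_external_search,
    viterbi_align,
    write_segments,
)
from codonlens.codes import six_frame_translate, write_fasta
from codonlens.errors import (
    InvalidSequenceError,
    MissingExecutableError,
    TruncatedAlignmentError,
)
from codonlens.fixtures import FixtureSpec, make_fixture
from codonlens.profiles import ProfileHMM, build_profile_from_msa

from _oracle import brute_force_best_score, random_instance


class TestViterbiAligner:
    def test_exact_substring_maps_consecutively(self):
        p = build_profile_from_msa(["MKV"] * 4, name="toy")
        seg = viterbi_align(p, "GGMKVGG", min_score_bits=-10.0)
        assert seg is not None
        assert seg.column_map == [(1, 2), (2, 3), (3, 4)]
        oracle = brute_force_best_score(p, "GGMKVGG")
        assert seg.score == pytest.approx(oracle, abs=1e-9)

    def test_all_background_profile_scores_nonpositive(self):
        em = np.full((3, 20), 1 / 20)
        trans = np.tile([0.95, 0.03, 0.02, 0.7, 0.3, 0.7, 0.3], (4, 1))
        p = ProfileHMM(
            name="bg", length=3, match_emissions=em,
            background=np.full(20, 1 / 20), transitions=trans,
        )
        assert viterbi_align(p, "ACDEFGHIKLM", min_score_bits=0.0) is None

    def test_unalignable_residues_forced_outside_match(self):
        p = build_profile_from_msa(["MKV"] * 4, name="toy")
        seg = viterbi_align(p, "XXMKVX*", min_score_bits=-10.0)
        assert seg is not None
        assert seg.column_map == [(1, 2), (2, 3), (3, 4)]

    def test_shift_equivariance(self):
        """Prepending unalignable flanking residues shifts every mapped
        position by exactly k and leaves the score unchanged."""
        p = build_profile_from_msa(["MKVLH"] * 4, name="toy")
        base = viterbi_align(p, "MKVLH", min_score_bits=-10.0)
        for k in (1, 3, 7):
            shifted = viterbi_align(p, "X" * k + "MKVLH", min_score_bits=-10.0)
            assert shifted.score == pytest.approx(base.score, abs=1e-9)
            assert shifted.column_map == [
                (c, pos + k) for c, pos in base.column_map
            ]

    def test_column_map_strictly_increasing(self, small_bundle):
        from codonlens.codes import read_fasta

        profiles = small_bundle.profiles
        for sid, seq in read_fasta(small_bundle.genome_fasta_path)[:6]:
            for tr in six_frame_translate(seq, source_id=sid):
                for p in profiles:
                    seg = viterbi_align(p, tr.protein, min_score_bits=10.0)
                    if seg is None:
                        continue
                    cols = [c for c, _ in seg.column_map]
                    poss = [r for _, r in seg.column_map]
                    assert cols == sorted(set(cols))
                    assert poss == sorted(set(poss))
                    assert 1 <= cols[0] and cols[-1] <= p.length
                    assert 0 <= poss[0] and poss[-1] < len(tr.protein)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=150, deadline=None)
    def test_score_matches_exhaustive_enumeration(self, seed):
        """Viterbi optimum equals brute-force path enumeration on tiny
        random instances with per-node random transitions."""
        rng = np.random.default_rng(seed)
        profile, target = random_instance(rng)
        oracle = brute_force_best_score(profile, target)
        seg = viterbi_align(profile, target, min_score_bits=-np.inf)
        got = -np.inf if seg is None else seg.score
        if np.isinf(oracle):
            assert np.isinf(got)
        else:
            assert got == pytest.approx(oracle, abs=1e-6)


HMMSCAN_TEMPLATE = """\
Query:  tgt|+|0  [L=40]
Domain annotation for each model (and alignments):
>> prof1  synthetic
   #    score  bias  c-Evalue  i-Evalue  hmmfrom  hmm to    alifrom  ali to
   1 !   30.0   0.0   1.2e-10   2.4e-08 {hmm_from:>8} {hmm_to:>7} .. {ali_from:>8} {ali_to:>6} ..

  Alignments for each domain:
  == domain 1  score: 30.0 bits;  conditional E-value: 1.2e-10
      prof1 {hmm_from:>3} {hmm_seq} {hmm_to}
              {midline}
    tgt|+|0 {ali_from:>5} {tgt_seq} {ali_to}
              {pp} PP

Internal pipeline statistics summary:
"""


def _scan_text(hmm_seq, tgt_seq, hmm_from, ali_from):
    n_cols = sum(1 for c in hmm_seq if c != ".")
    n_res = sum(1 for c in tgt_seq if c != "-")
    return HMMSCAN_TEMPLATE.format(
        hmm_seq=hmm_seq, tgt_seq=tgt_seq,
        hmm_from=hmm_from, hmm_to=hmm_from + n_cols - 1,
        ali_from=ali_from, ali_to=ali_from + n_res - 1,
        midline=" " * len(hmm_seq), pp="9" * len(tgt_seq),
    )


class TestParseSearchAlignments:
    def test_gapless_walk(self):
        segs = parse_search_alignments(_scan_text("ACD", "ACD", 1, 8))
        assert len(segs) == 1
        s = segs[0]
        assert s.profile_name == "prof1"
        assert s.target_id == "tgt|+|0"
        assert s.score == pytest.approx(30.0)
        assert s.significance == pytest.approx(1.2e-10)
        assert s.column_map == [(1, 7), (2, 8), (3, 9)]

    def test_insert_advances_target_only(self):
        segs = parse_search_alignments(_scan_text("A.CD", "AxCD", 1, 8))
        assert segs[0].column_map == [(1, 7), (2, 9), (3, 10)]

    def test_delete_advances_profile_only(self):
        segs = parse_search_alignments(_scan_text("ACD", "A-D", 1, 8))
        assert segs[0].column_map == [(1, 7), (3, 8)]

    def test_truncated_block_raises(self):
        text = _scan_text("ACD", "ACD", 1, 8)
        text = text.replace("    tgt|+|0 ", "    nonsense ")
        with pytest.raises(TruncatedAlignmentError):
            parse_search_alignments(text)

    def test_coordinate_mismatch_raises(self):
        # declared hmm_to larger than the walked alignment supports
        text = HMMSCAN_TEMPLATE.format(
            hmm_seq="ACD", tgt_seq="ACD", hmm_from=1, hmm_to=5,
            ali_from=8, ali_to=10, midline="   ", pp="999",
        )
        with pytest.raises(TruncatedAlignmentError):
            parse_search_alignments(text)


class TestSegmentFile:
    def test_write_read_round_trip(self, tmp_path):
        p = build_profile_from_msa(["MKVLH"] * 4, name="toy")
        seg = viterbi_align(p, "GGMKVLHGG", min_score_bits=-10.0)
        path = tmp_path / "segments.tsv"
        write_segments([seg, seg], path)
        back = read_segments(path)
        assert len(back) == 2
        for b in back:
            assert b.profile_name == seg.profile_name
            assert b.target_id == seg.target_id
            assert b.column_map == seg.column_map
            assert b.score == pytest.approx(seg.score, abs=0.01)


@pytest.fixture(scope="module")
def scan_setup(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("scan")
    bundle = make_fixture(
        FixtureSpec(seed=3, n_families=2, family_length=40,
                    n_seqs_per_family=30, n_copies_per_family=3),
        tmp,
    )
    recs = []
    for sid, seq in bundle.genome:
        for tr in six_frame_translate(seq, source_id=sid):
            if len(tr.protein) >= 5:
                recs.append((tr.target_id, tr.protein.replace("*", "X")))
    fasta = tmp / "translations.faa"
    write_fasta(recs, fasta)
    return bundle, fasta, tmp


@pytest.mark.skipif(
    shutil.which("hmmscan") is None, reason="hmmer not installed"
)
class TestExternalSearch:

    def test_finds_every_encoded_gene(self, scan_setup):
        bundle, fasta, tmp = scan_setup
        outs = run_external_search(
            bundle.profile_db_path, fasta, tmp / "w1", n_workers=1
        )
        segs = parse_search_output_files(outs)
        found = {s.target_id.split("|")[0] for s in segs}
        expected = {pl.source_id for pl in bundle.placements}
        assert expected <= found

    def test_worker_fanout_is_deterministic(self, scan_setup):
        bundle, fasta, tmp = scan_setup
        one = parse_search_output_files(
            run_external_search(bundle.profile_db_path, fasta, tmp / "a", 1)
        )
        four = parse_search_output_files(
            run_external_search(bundle.profile_db_path, fasta, tmp / "b", 4)
        )
        key = lambda s: (s.target_id, s.profile_name, tuple(s.column_map))
        assert sorted(map(key, one)) == sorted(map(key, four))

    def test_empty_fasta_rejected_before_invocation(self, tmp_path):
        empty = tmp_path / "empty.faa"
        empty.write_text("")
        db = tmp_path / "db.hmm"
        db.write_text("")
        with pytest.raises(InvalidSequenceError):
            run_external_search(db, empty, tmp_path / "out")

    def test_missing_executable_names_alternative(self, scan_setup):
        bundle, fasta, tmp = scan_setup
        with pytest.raises(MissingExecutableError, match="internal"):
            run_external_search(
                bundle.profile_db_path, fasta, tmp / "x",
                executable="definitely-not-hmmscan",
            )
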