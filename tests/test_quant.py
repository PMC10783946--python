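"""Trimming, window scanning, UMI dedup and end-to-end quantification."""

import random

import pytest

from tagquant import (
    CountRecord,
    FixtureSpec,
    ReadLayout,
    ScanStatus,
    ValidationError,
    build_mismatch_map,
    correct_cell_barcode,
    deduplicate,
    extract_cell_umi,
    generate_fixture,
    quantify,
    read_matrix,
    scan_read,
    trim_tag_read,
    truth_matrix,
    write_matrix,
)
from conftest import make_whitelist, random_whitelist
from oracles import brute_scan


class TestTrim:
    def test_fixed_trim(self):
        layout = ReadLayout(cb_span=(0, 4), umi_span=(4, 8), trim5=4, trim3=4)
        assert trim_tag_read("AAAACGTACGTTTT", layout) == "CGTACG"

    def test_anchor_keep_after(self):
        layout = ReadLayout(cb_span=(0, 4), umi_span=(4, 8), anchor="TAGCAT", anchor_keep="after")
        assert trim_tag_read("GGGGTAGCATACGT", layout) == "ACGT"

    def test_anchor_keep_before(self):
        layout = ReadLayout(cb_span=(0, 4), umi_span=(4, 8), anchor="TAGCAT", anchor_keep="before")
        assert trim_tag_read("GGGGTAGCATACGT", layout) == "GGGG"

    def test_absent_anchor_discards(self):
        layout = ReadLayout(cb_span=(0, 4), umi_span=(4, 8), anchor="TAGCAT")
        assert trim_tag_read("GGGGACGTACGT", layout) is None

    def test_overtrimming_discards(self):
        layout = ReadLayout(cb_span=(0, 4), umi_span=(4, 8), trim5=5, trim3=5)
        assert trim_tag_read("ACGTACGTAC", layout) is None

    def test_anchor_first_then_fixed(self):
        layout = ReadLayout(cb_span=(0, 4), umi_span=(4, 8),
                            anchor="GG", anchor_keep="after", trim5=1, trim3=1)
        # "TTGGACGTA" -> after anchor "ACGTA" -> trim 1/1 -> "CGT"
        assert trim_tag_read("TTGGACGTA", layout) == "CGT"


class TestScanRead:
    def test_exact_hit_with_offset(self):
        mmap = build_mismatch_map(make_whitelist({"F1": "ACGT"}))
        status, hit = scan_read("TTACGTTT", mmap)
        assert status is ScanStatus.ASSIGNED
        assert (hit.parent_id, hit.offset, hit.n_mismatches) == ("F1", 2, 0)

    def test_variant_hit(self):
        mmap = build_mismatch_map(make_whitelist({"F1": "ACGT"}))
        status, hit = scan_read("TTACCTTT", mmap)
        assert status is ScanStatus.ASSIGNED
        assert (hit.parent_id, hit.offset, hit.n_mismatches) == ("F1", 2, 1)

    def test_two_parents_ambiguous(self):
        mmap = build_mismatch_map(make_whitelist({"F1": "AAAA", "F2": "TTTT"}))
        status, hit = scan_read("AAAATTTT", mmap)
        assert status is ScanStatus.AMBIGUOUS and hit is None

    def test_short_read_unassigned(self):
        mmap = build_mismatch_map(make_whitelist({"F1": "ACGTACGT"}))
        assert scan_read("ACGT", mmap)[0] is ScanStatus.UNASSIGNED

    def test_n_in_window_never_matches(self):
        mmap = build_mismatch_map(make_whitelist({"F1": "ACGT"}))
        # ACNT is at Hamming distance 1 only via the N position; N windows never match
        assert scan_read("ACNT", mmap)[0] is ScanStatus.UNASSIGNED

    def test_exact_window_preferred_over_earlier_variant(self):
        mmap = build_mismatch_map(make_whitelist({"F1": "AAAA"}))
        # offset 0 window "CAAA" is a variant; offset 1 "AAAA" is exact
        status, hit = scan_read("CAAAA", mmap)
        assert (hit.offset, hit.n_mismatches) == (1, 0)

    def test_revcomp_scanning(self):
        mmap = build_mismatch_map(make_whitelist({"F1": "AACCGG"}))
        from tagquant import revcomp as rc

        read = "TT" + rc("AACCGG") + "TT"
        assert scan_read(read, mmap, revcomp_flag=False)[0] is ScanStatus.UNASSIGNED
        status, hit = scan_read(read, mmap, revcomp_flag=True)
        assert status is ScanStatus.ASSIGNED
        assert hit.strand == "reverse"

    def test_fixed_offset_mode(self):
        mmap = build_mismatch_map(make_whitelist({"F1": "ACGT"}))
        assert scan_read("TTACGTTT", mmap, scan_offset=2)[0] is ScanStatus.ASSIGNED
        assert scan_read("TTACGTTT", mmap, scan_offset=0)[0] is ScanStatus.UNASSIGNED

    @pytest.mark.parametrize("revcomp_flag", [False, True])
    def test_oracle_agreement_random(self, revcomp_flag):
        """scan_read matches a per-window brute-force Hamming oracle."""
        rng = random.Random(7 if revcomp_flag else 5)
        for _ in range(50):
            n, L = rng.randint(1, 8), rng.randint(2, 8)
            wl = random_whitelist(rng, n=n, L=L)
            parents = dict(zip(wl.feature_ids, wl.sequences))
            mmap = build_mismatch_map(wl)
            for _ in range(40):
                read = "".join(rng.choice("ACGTN" if rng.random() < 0.1 else "ACGT")
                               for _ in range(rng.randint(L, 2 * L + 4)))
                expected = brute_scan(read, parents, revcomp_flag)
                status, hit = scan_read(read, mmap, revcomp_flag=revcomp_flag)
                if expected[0] == "assigned":
                    assert status is ScanStatus.ASSIGNED
                    assert (hit.parent_id, hit.offset, hit.n_mismatches) == expected[1:]
                else:
                    assert status.value == expected[0]


class TestExtractAndCorrect:
    def test_spans_sliced(self):
        layout = ReadLayout(cb_span=(0, 9), umi_span=(9, 13))
        assert extract_cell_umi("AAACCCGGGTTTNNNN", layout) == ("AAACCCGGG", "TTTN")

    def test_short_read_discarded(self):
        layout = ReadLayout(cb_span=(0, 16), umi_span=(16, 20))
        assert extract_cell_umi("ACGTACGT", layout) is None

    def test_n_in_cell_discarded_n_in_umi_kept(self):
        layout = ReadLayout(cb_span=(0, 4), umi_span=(4, 8))
        assert extract_cell_umi("AANAACGT", layout) is None
        assert extract_cell_umi("AAAAACNT", layout) == ("AAAA", "ACNT")

    def test_onlist_correction(self):
        onlist = frozenset({"AAAA", "TTTT"})
        assert correct_cell_barcode("AAAA", onlist) == "AAAA"
        assert correct_cell_barcode("AAAT", onlist) == "AAAA"  # unique distance-1
        assert correct_cell_barcode("AATT", onlist) is None  # distance 2 from both
        assert correct_cell_barcode("GGGG", onlist) is None

    def test_onlist_ambiguous_distance_one(self):
        onlist = frozenset({"AAAA", "AAGG"})
        assert correct_cell_barcode("AAAG", onlist) is None  # distance 1 from both

    def test_no_onlist_identity(self):
        assert correct_cell_barcode("ANYC", None) == "ANYC"


class TestDeduplicate:
    def test_duplicate_triple_collapses(self):
        recs = [CountRecord("c1", "u1", "F1")] * 2
        assert deduplicate(recs) == [CountRecord("c1", "u1", "F1")]

    def test_umi_conflict_dropped(self):
        recs = [CountRecord("c1", "u1", "F1"), CountRecord("c1", "u1", "F2")]
        assert deduplicate(recs) == []

    def test_distinct_umis_kept_sorted(self):
        recs = [CountRecord("c1", "u2", "F1"), CountRecord("c1", "u1", "F1")]
        assert deduplicate(recs) == [
            CountRecord("c1", "u1", "F1"),
            CountRecord("c1", "u2", "F1"),
        ]


def _fixture_layout(spec: FixtureSpec) -> ReadLayout:
    return ReadLayout(cb_span=(0, spec.cb_len),
                      umi_span=(spec.cb_len, spec.cb_len + spec.umi_len))


class TestQuantify:
    def test_error_free_fixture_recovers_truth(self, tmp_path, well_separated_whitelist):
        # poly-A filler mirrors Multiseq-style flanks and, for this whitelist,
        # provably creates no cross-parent window at error rate 0
        spec = FixtureSpec(whitelist=well_separated_whitelist, n_cells=3,
                           reads_per_cell_feature=5, error_rate=0.0,
                           filler_base="A", seed=11)
        paths = generate_fixture(spec, tmp_path)
        matrix, stats = quantify(paths["r1"], paths["r2"],
                                 well_separated_whitelist, _fixture_layout(spec))
        expected = truth_matrix(paths["truth"], well_separated_whitelist)
        assert stats.assigned == stats.pairs_read == 3 * 4 * 5
        assert matrix.cells == list(expected.index)
        assert (matrix.to_dense() == expected.values).all()

    def test_pcr_duplicates_do_not_inflate(self, tmp_path, well_separated_whitelist):
        base = FixtureSpec(whitelist=well_separated_whitelist, n_cells=2,
                           reads_per_cell_feature=4, seed=3)
        dup = FixtureSpec(whitelist=well_separated_whitelist, n_cells=2,
                          reads_per_cell_feature=4, seed=3, reads_per_molecule=3)
        m1, _ = quantify(*_run_paths(base, tmp_path / "a"),
                         well_separated_whitelist, _fixture_layout(base))
        m2, s2 = quantify(*_run_paths(dup, tmp_path / "b"),
                          well_separated_whitelist, _fixture_layout(dup))
        assert s2.pairs_read == 3 * 2 * 4 * 4
        assert m1 == m2

    def test_conservation(self, tmp_path, well_separated_whitelist):
        spec = FixtureSpec(whitelist=well_separated_whitelist, n_cells=2,
                           reads_per_cell_feature=6, error_rate=0.08, seed=42)
        paths = generate_fixture(spec, tmp_path)
        matrix, s = quantify(paths["r1"], paths["r2"],
                             well_separated_whitelist, _fixture_layout(spec))
        assert (s.assigned + s.unassigned + s.ambiguous
                + s.discarded_by_layout + s.discarded_by_onlist) == s.pairs_read
        assert matrix.total <= s.assigned

    def test_permutation_invariance(self, tmp_path, well_separated_whitelist):
        spec = FixtureSpec(whitelist=well_separated_whitelist, n_cells=3,
                           reads_per_cell_feature=4, error_rate=0.02, seed=9)
        paths = generate_fixture(spec, tmp_path / "orig")
        _shuffle_fastq_pair(paths["r1"], paths["r2"], tmp_path / "shuf", seed=1)
        layout = _fixture_layout(spec)
        m1, _ = quantify(paths["r1"], paths["r2"], well_separated_whitelist, layout)
        m2, _ = quantify(tmp_path / "shuf" / "R1.fastq", tmp_path / "shuf" / "R2.fastq",
                         well_separated_whitelist, layout)
        assert m1 == m2

    def test_onlist_correction_end_to_end(self, tmp_path, well_separated_whitelist):
        spec = FixtureSpec(whitelist=well_separated_whitelist, n_cells=2,
                           reads_per_cell_feature=3, filler_base="A", seed=5)
        paths = generate_fixture(spec, tmp_path)
        truth_cells = sorted({line.split("\t")[1]
                              for line in open(paths["truth"]).read().splitlines()[1:]})
        matrix, stats = quantify(paths["r1"], paths["r2"], well_separated_whitelist,
                                 _fixture_layout(spec), onlist=frozenset(truth_cells))
        assert stats.discarded_by_onlist == 0
        assert matrix.cells == truth_cells
        # an on-list missing one cell drops exactly that cell's reads
        matrix2, stats2 = quantify(paths["r1"], paths["r2"], well_separated_whitelist,
                                   _fixture_layout(spec), onlist=frozenset(truth_cells[:1]))
        assert matrix2.cells == truth_cells[:1]
        assert stats2.discarded_by_onlist == stats.pairs_read - stats2.assigned

    def test_mismatched_record_counts_error(self, tmp_path, well_separated_whitelist):
        spec = FixtureSpec(whitelist=well_separated_whitelist, n_cells=2,
                           reads_per_cell_feature=2, seed=0)
        paths = generate_fixture(spec, tmp_path)
        truncated = tmp_path / "R1_short.fastq"
        lines = open(paths["r1"]).read().splitlines(keepends=True)
        truncated.write_text("".join(lines[:-4]))
        with pytest.raises(ValidationError, match="different record counts"):
            quantify(truncated, paths["r2"], well_separated_whitelist, _fixture_layout(spec))

    def test_double_substitution_unassigned(self, tmp_path):
        wl = make_whitelist({"F1": "ACGTACGT"})
        spec = FixtureSpec(whitelist=wl, n_cells=1, reads_per_cell_feature=1,
                           tag_offset=0, r2_len=8, seed=0)
        paths = generate_fixture(spec, tmp_path)
        r2 = tmp_path / "R2_mut.fastq"
        rec = open(paths["r2"]).read().splitlines()
        assert rec[1] == "ACGTACGT"
        rec[1] = "TAGTACGT"  # two substitutions in the tag
        r2.write_text("\n".join(rec) + "\n")
        _, stats = quantify(paths["r1"], r2, wl, _fixture_layout(spec))
        assert stats.unassigned == 1 and stats.assigned == 0


class TestMatrixIO:
    def test_write_format_and_roundtrip(self, tmp_path):
        import numpy as np
        import scipy.sparse

        from tagquant import CountMatrix

        counts = scipy.sparse.csr_matrix(np.array([[1, 0], [0, 3]], dtype=np.int64))
        matrix = CountMatrix(cells=["AAAA", "CCCC"], features=["F1", "F2"], counts=counts)
        write_matrix(matrix, tmp_path)
        mtx_lines = (tmp_path / "matrix.mtx").read_text().splitlines()
        assert mtx_lines[0].startswith("%%MatrixMarket matrix coordinate integer general")
        data_lines = [l for l in mtx_lines if not l.startswith("%")]
        assert data_lines[0].split() == ["2", "2", "2"]
        assert ["1", "1", "1"] in [l.split() for l in data_lines[1:]]
        assert ["2", "2", "3"] in [l.split() for l in data_lines[1:]]
        assert read_matrix(tmp_path) == matrix

    def test_empty_matrix_roundtrip(self, tmp_path, well_separated_whitelist):
        from tagquant.quant import records_to_matrix

        matrix = records_to_matrix([], well_separated_whitelist)
        write_matrix(matrix, tmp_path)
        assert read_matrix(tmp_path) == matrix
        assert matrix.total == 0


def _run_paths(spec, out_dir):
    paths = generate_fixture(spec, out_dir)
    return paths["r1"], paths["r2"]


def _shuffle_fastq_pair(r1, r2, out_dir, seed):
    import os

    os.makedirs(out_dir, exist_ok=True)
    rng = random.Random(seed)
    for path, name in ((r1, "R1.fastq"), (r2, "R2.fastq")):
        lines = open(path).read().splitlines()
        records = [lines[i : i + 4] for i in range(0, len(lines), 4)]
        order = list(range(len(records)))
        rng2 = random.Random(seed)
        rng2.shuffle(order)
        with open(os.path.join(out_dir, name), "w") as fh:
            for i in order:
                fh.write("\n".join(records[i]) + "\n")
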