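import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from famdiverge.anchors_and_trim import (
    DomainAnchor,
    ProteinAlignment,
    degap,
    locate_anchor,
    locate_anchors,
    trim_alignment,
    ungapped_to_columns,
)
from famdiverge.conservation import consensus, domain_conservation, p_distance
from famdiverge.errors import ValidationError
from famdiverge.motif_scan import compile_pattern

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestLocateAnchor:
    def test_exact_substring(self):
        assert locate_anchor("MKVIVPGGRLL", "VIVPGGR", 0) == ((2, 9), 0)

    def test_one_mismatch_within_budget(self):
        assert locate_anchor("MKVIVPGGKLL", "VIVPGGR", 1) == ((2, 9), 1)

    def test_anchor_missing(self):
        assert locate_anchor("MKLLL", "VIVPGGR", 1) is None

    def test_gaps_are_transparent(self):
        interval, mm = locate_anchor("MK--VIV-PGGR--LL", "VIVPGGR", 0)
        assert (interval, mm) == ((2, 9), 0)  # interval on the degapped row

    def test_matches_brute_force_over_degapped_offsets(self):
        rng = np.random.default_rng(21)
        pattern = compile_pattern("DSKTFVDM")
        for _ in range(40):
            seq = "".join(rng.choice(list(AA + "--"), size=50))
            got = locate_anchor(seq, pattern, 2)
            plain = degap(seq)
            best = None
            for off in range(len(plain) - pattern.length + 1):
                mm = sum(
                    plain[off + j] not in pattern.positions[j]
                    for j in range(pattern.length)
                )
                if mm <= 2 and (best is None or mm < best[1]):
                    best = ((off, off + pattern.length), mm)
            assert got == best


class TestColumnMapping:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(alphabet="AC-", min_size=1, max_size=40))
    def test_nongap_count_left_of_mapped_column(self, aligned):
        plain = degap(aligned)
        if not plain:
            return
        for start in range(len(plain)):
            for end in range(start + 1, len(plain) + 1):
                c0, c1 = ungapped_to_columns(aligned, start, end)
                assert sum(ch != "-" for ch in aligned[:c0]) == start
                assert degap(aligned[c0:c1]) == plain[start:end]


def _alignment_with_anchors(width=30):
    # first anchor at columns [4,11), last at [20,27), on every row
    rows = []
    for i, pad in enumerate("ACD"):
        row = pad * 4 + "VIVPGGR" + pad * 9 + "DSKTFVD" + pad * 3
        rows.append((f"s{i}", row))
    return ProteinAlignment(tuple(rows))


class TestTrim:
    def test_trimmed_width_spans_outermost_anchors(self):
        msa = _alignment_with_anchors()
        anchors = locate_anchors(
            msa, [("a1", "VIVPGGR"), ("a2", "DSKTFVD")], max_mismatch=0
        )
        assert [a.column_interval for a in anchors] == [(4, 11), (20, 27)]
        trimmed = trim_alignment(msa, anchors)
        assert trimmed.width == 27 - 4
        assert trimmed.ids == msa.ids

    def test_full_width_anchors_make_trim_identity(self):
        msa = ProteinAlignment((("a", "VIVPGGRDD"), ("b", "VIVPGGRDD")))
        anchors = locate_anchors(msa, [("a1", "VIVPGGR"), ("a2", "RDD")], 0)
        assert trim_alignment(msa, anchors).rows == msa.rows

    def test_single_located_anchor_is_error(self):
        msa = _alignment_with_anchors()
        anchors = locate_anchors(msa, [("a1", "VIVPGGR"), ("a2", "WWWWWWW")], 0)
        with pytest.raises(ValidationError, match="inspect"):
            trim_alignment(msa, anchors)

    def test_trim_is_idempotent(self):
        msa = _alignment_with_anchors()
        specs = [("a1", "VIVPGGR"), ("a2", "DSKTFVD")]
        once = trim_alignment(msa, locate_anchors(msa, specs, 0))
        twice = trim_alignment(once, locate_anchors(once, specs, 0))
        assert twice.rows == once.rows

    def test_modal_interval_ignores_divergent_minority(self):
        rows = [(f"s{i}", "AAAA" + "VIVPGGR" + "AAAA") for i in range(3)]
        rows.append(("odd", "VIVPGGRAAAAAAAA"))  # anchor at different columns
        msa = ProteinAlignment(tuple(rows))
        (anchor,) = locate_anchors(msa, [("a1", "VIVPGGR")], 0)
        assert anchor.column_interval == (4, 11)
        assert anchor.per_sequence_hits["odd"] is not None


class TestConsensus:
    def test_majority(self):
        msa = ProteinAlignment((("a", "AC"), ("b", "AC"), ("c", "AT")))
        assert consensus(msa) == "AC"

    def test_gaps_do_not_vote(self):
        msa = ProteinAlignment((("a", "A-"), ("b", "-A")))
        assert consensus(msa) == "AA"

    def test_tie_breaks_lexicographically(self):
        msa = ProteinAlignment((("a", "A"), ("b", "C")))
        assert consensus(msa) == "A"

    def test_all_gap_column(self):
        msa = ProteinAlignment((("a", "A-"), ("b", "C-")))
        assert consensus(msa) == "A-"


class TestPDistance:
    def test_examples(self):
        assert p_distance("VIVPGGR", "VIVPGGK") == pytest.approx(1 / 7)
        assert p_distance("VIVPGGR", "VIVPGGR") == 0.0
        assert p_distance("VI-PGGR", "VIVPGGR") == 0.0  # pairwise deletion

    def test_x_is_non_information(self):
        assert p_distance("AXC", "AAC") == 0.0
        assert math.isnan(p_distance("XXX", "AAA"))

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValidationError):
            p_distance("AA", "AAA")

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_column_count_oracle_and_is_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 30))
        a = "".join(rng.choice(list(AA + "-X"), size=n))
        b = "".join(rng.choice(list(AA + "-X"), size=n))
        pairs = [
            (x, y) for x, y in zip(a, b)
            if x not in "-X" and y not in "-X"
        ]
        expected = (
            math.nan if not pairs else sum(x != y for x, y in pairs) / len(pairs)
        )
        got = p_distance(a, b)
        if math.isnan(expected):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(expected)
            assert p_distance(b, a) == got
            assert 0.0 <= got <= 1.0


class TestDomainConservation:
    def test_identical_to_consensus_gives_zero_row(self):
        msa = _alignment_with_anchors()
        anchors = locate_anchors(msa, [("a1", "VIVPGGR"), ("a2", "DSKTFVD")], 0)
        matrix = domain_conservation(msa, anchors)
        assert (matrix.table.loc["s0"] == 0.0).all()

    def test_single_mismatch_in_seven_column_anchor(self):
        rows = (
            ("a", "AAVIVPGGRAA"),
            ("b", "AAVIVPGGRAA"),
            ("c", "AAVIVPGGKAA"),
        )
        msa = ProteinAlignment(rows)
        anchors = locate_anchors(msa, [("a1", "VIVPGGR")], 1)
        matrix = domain_conservation(msa, anchors)
        assert matrix.table.loc["c", "a1"] == pytest.approx(1 / 7)

    def test_missing_anchor_gives_missing_cell(self):
        rows = (
            ("a", "AAVIVPGGRAA"),
            ("b", "AAVIVPGGRAA"),
            ("c", "AAWWWWWWWAA"),
        )
        msa = ProteinAlignment(rows)
        anchors = locate_anchors(msa, [("a1", "VIVPGGR")], 1)
        matrix = domain_conservation(msa, anchors)
        assert math.isnan(matrix.table.loc["c", "a1"])
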