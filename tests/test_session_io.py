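"""Recording parsing, session summaries and cohort standardization."""

from __future__ import annotations

import io
import zipfile

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from eeglatent.session_io import (
    CohortMatrix,
    DegenerateFeatureError,
    DialectError,
    EmptyCohortError,
    EmptyRecordingError,
    build_cohort_matrix,
    inverse_zscore,
    parse_recording,
    scan_archive,
    summarize_session,
    zscore_matrix,
)
from eeglatent.streams import Moment, STREAM_NAMES

NAME = "Patient1_Before_2024-01-05.txt"


def _rows_text(rows, header=None):
    lines = []
    if header is not None:
        lines.append("\t".join(header))
    for r in rows:
        lines.append("\t".join(str(v) for v in r))
    return "\n".join(lines) + "\n"


def _simple_rows(delta, fill=0.0):
    return [[d] + [fill] * 9 for d in delta]


class TestParseRecording:
    def test_headerless_canonical_order(self):
        rec = parse_recording(_rows_text(_simple_rows([1, 2, 3])), NAME)
        assert rec.samples.shape == (3, 10)
        assert rec.n_invalid_dropped == 0
        assert rec.patient_id == 1 and rec.moment is Moment.BEFORE
        np.testing.assert_array_equal(rec.samples[:, 0], [1, 2, 3])

    def test_invalid_token_dropped_per_token(self):
        text = _rows_text([[1] + [0] * 9, ["NaN"] + [0] * 9, [3] + [0] * 9])
        rec = parse_recording(text, NAME)
        assert rec.n_invalid_dropped == 1
        feats = summarize_session(rec).features
        assert feats[0] == 2.0  # mean of the retained {1, 3}
        assert np.all(feats[1:] == 0.0)

    def test_header_reordered_to_canonical(self):
        header = list(reversed(STREAM_NAMES))
        rows = [list(range(10, 0, -1))]  # delta last, value 1
        rec = parse_recording(_rows_text(rows, header=header), NAME)
        np.testing.assert_array_equal(rec.samples[0], np.arange(1, 11))

    def test_header_aliases(self):
        header = ["δ", "θ", "lowAlpha", "highAlpha", "lowBeta", "highBeta",
                  "lowGamma", "highGamma", "Attention", "Meditation"]
        rec = parse_recording(_rows_text([list(range(10))], header=header), NAME)
        np.testing.assert_array_equal(rec.samples[0], np.arange(10))

    def test_header_only_is_empty_recording(self):
        with pytest.raises(EmptyRecordingError):
            parse_recording("\t".join(STREAM_NAMES) + "\n", NAME)

    def test_wrong_column_count_is_dialect_error(self):
        with pytest.raises(DialectError):
            parse_recording("1 2 3\n", NAME)

    def test_comma_separated(self):
        rec = parse_recording("1,2,3,4,5,6,7,8,9,10\n", NAME)
        np.testing.assert_array_equal(rec.samples[0], np.arange(1, 11))

    def test_bad_name_rejected(self):
        with pytest.raises(DialectError):
            parse_recording("1 2 3\n", "notes.txt")


class TestSummarize:
    def test_mean_per_stream(self):
        rec = parse_recording(_rows_text(_simple_rows([1, 2, 3], fill=5)), NAME)
        np.testing.assert_array_equal(
            summarize_session(rec).features, [2] + [5] * 9
        )

    def test_single_row_identity(self):
        row = list(range(1, 11))
        rec = parse_recording(_rows_text([row]), NAME)
        np.testing.assert_array_equal(summarize_session(rec).features, row)

    def test_row_order_invariance(self, rng):
        rows = rng.normal(size=(7, 10))
        a = parse_recording(_rows_text(rows.tolist()), NAME)
        b = parse_recording(_rows_text(rows[::-1].tolist()), NAME)
        np.testing.assert_allclose(
            summarize_session(a).features, summarize_session(b).features, rtol=1e-12
        )

    def test_stream_with_no_values_is_error(self):
        text = _rows_text([["x"] + [0] * 9, ["y"] + [1] * 9])
        rec = parse_recording(text, NAME)
        with pytest.raises(EmptyRecordingError, match="delta"):
            summarize_session(rec)


class TestCohortMatrix:
    def test_rows_in_input_order(self):
        recs = [
            parse_recording(_rows_text([[float(k)] * 10]), f"Patient{k}_During_2023.txt")
            for k in (1, 2)
        ]
        m = build_cohort_matrix([summarize_session(r) for r in recs])
        assert m.values.shape == (2, 10)
        np.testing.assert_array_equal(m.values[:, 0], [1, 2])
        assert list(m.labels["patient_id"]) == [1, 2]

    def test_empty_list_is_error(self):
        with pytest.raises(EmptyCohortError):
            build_cohort_matrix([])

    def test_zscore_hand_values(self):
        values = np.tile([[1.0], [2.0], [3.0]], (1, 10))
        m = CohortMatrix(values, pd.DataFrame({"patient_id": [1, 1, 1],
                                               "moment": [Moment.BEFORE] * 3,
                                               "date": [None] * 3}))
        z = zscore_matrix(m)
        np.testing.assert_allclose(z.values[:, 0], [-1.224745, 0.0, 1.224745], atol=1e-6)
        np.testing.assert_allclose(z.norm_stats["sigma"][0], 0.816497, atol=1e-6)

    def test_zscore_unit_variance_fixed_point(self):
        values = np.tile([[-1.0], [1.0]], (1, 10))
        m = CohortMatrix(values, pd.DataFrame({"patient_id": [1, 1],
                                               "moment": [Moment.BEFORE] * 2,
                                               "date": [None] * 2}))
        np.testing.assert_allclose(zscore_matrix(m).values, values, atol=1e-12)

    def test_constant_column_degenerate(self):
        values = np.ones((3, 10))
        values[:, 1:] = np.random.default_rng(0).normal(size=(3, 9))
        m = CohortMatrix(values, pd.DataFrame({"patient_id": [1] * 3,
                                               "moment": [Moment.BEFORE] * 3,
                                               "date": [None] * 3}))
        with pytest.raises(DegenerateFeatureError, match="delta"):
            zscore_matrix(m)

    @given(st.integers(0, 2**31 - 1))
    def test_zscore_round_trip(self, seed):
        vals = np.random.default_rng(seed).normal(size=(6, 10), scale=3.0) + 5.0
        m = CohortMatrix(vals, pd.DataFrame({"patient_id": [1] * 6,
                                             "moment": [Moment.BEFORE] * 6,
                                             "date": [None] * 6}))
        back = inverse_zscore(zscore_matrix(m))
        np.testing.assert_allclose(back.values, vals, atol=1e-10)
        z = zscore_matrix(m)
        np.testing.assert_allclose(z.values.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(z.values.std(axis=0), 1.0, atol=1e-8)


def _make_zip(tmp_path, members, name="cohort.zip"):
    path = tmp_path / name
    with zipfile.ZipFile(path, "w") as zf:
        for member_name, text in members:
            zf.writestr(member_name, text)
    return path


ROW = "\t".join(["1"] * 10) + "\n"


class TestScanArchive:
    def test_counts_and_skipped(self, tmp_path):
        members = [(f"Patient1_Before_202{k}.txt", ROW) for k in range(3)]
        members.append(("Patient2_During_2024-01-01.txt", ROW))
        members.append(("README.md", "notes"))
        entries, manifest = scan_archive(_make_zip(tmp_path, members))
        assert manifest["total"] == 4
        assert manifest["by_moment"] == {"Before": 3, "During": 1, "After": 0}
        assert manifest["by_patient"] == {"1": 3, "2": 1}
        assert [s["name"] for s in manifest["skipped"]] == ["README.md"]

    def test_counts_permutation_invariant(self, tmp_path):
        members = [
            ("Patient1_Before_2022.txt", ROW),
            ("Patient2_During_2023.txt", ROW),
            ("Patient1_After_2024.txt", ROW),
        ]
        _, m1 = scan_archive(_make_zip(tmp_path, members, "a.zip"))
        _, m2 = scan_archive(_make_zip(tmp_path, members[::-1], "b.zip"))
        assert m1["by_moment"] == m2["by_moment"]
        assert m1["by_patient"] == m2["by_patient"]

    def test_count_totals_consistent(self, tmp_path):
        members = [
            (f"Patient{p}_{m}_20{20 + p}-0{s + 1}-01.txt", ROW)
            for p in (1, 2, 3)
            for m in ("Before", "During", "After")
            for s in range(p)
        ]
        _, manifest = scan_archive(_make_zip(tmp_path, members))
        assert sum(manifest["by_moment"].values()) == manifest["total"]
        assert sum(manifest["by_patient"].values()) == manifest["total"]

    def test_missing_archive(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            scan_archive(tmp_path / "nope.zip")

    def test_empty_cohort(self, tmp_path):
        with pytest.raises(EmptyCohortError):
            scan_archive(_make_zip(tmp_path, [("README.md", "x")]))
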