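import numpy as np
import pandas as pd
import pytest

from synercomb import (
    AnalysisReport,
    ResponseMatrix,
    normalize,
    read_checkerboard,
    read_report,
    write_checkerboard,
    write_report,
)
from synercomb.matrixio import SchemaError, ValidationError


def _long_csv(tmp_path, rows, name="board.csv"):
    path = tmp_path / name
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def _grid_rows(doses_r, doses_c, response_fn, time_h=72.0, replicate=1,
               scale="inhibition", block=1):
    return [
        {
            "block_id": block, "drug_row": "hdm201", "drug_col": "trametinib",
            "conc_r": r, "conc_c": c, "conc_unit": "nM",
            "response": response_fn(r, c), "response_scale": scale,
            "time_h": time_h, "replicate": replicate,
        }
        for r in doses_r
        for c in doses_c
    ]


MTS_R = [0.0, 12.5, 25.0, 50.0, 100.0, 200.0]
MTS_C = [0.0, 0.25, 0.5, 1.0, 2.0, 4.0]


class TestReadCheckerboard:
    def test_mts_grid_reads_to_one_sorted_matrix(self, tmp_path):
        rows = _grid_rows(MTS_R[::-1], MTS_C, lambda r, c: r + c)
        mats = read_checkerboard(_long_csv(tmp_path, rows))
        assert len(mats) == 1
        m = mats[0]
        assert m.doses_row.tolist() == MTS_R
        assert m.doses_col.tolist() == MTS_C
        assert m.response[3, 2] == 50.0 + 0.5

    def test_constant_viability_block(self, tmp_path):
        rows = _grid_rows([1, 2, 4, 8], [1, 2], lambda r, c: 100.0, scale="viability")
        (m,) = read_checkerboard(_long_csv(tmp_path, rows))
        assert np.all(m.response == 100.0)
        assert m.response_scale == "viability"

    def test_multiple_timepoints_split_into_matrices(self, tmp_path):
        times = [28, 32, 36, 48, 52, 56, 60, 72, 76, 80, 24]
        rows = []
        for t in times:
            rows += _grid_rows([0, 1, 2], [0, 1, 2], lambda r, c: r * c, time_h=t)
        mats = read_checkerboard(_long_csv(tmp_path, rows))
        assert len(mats) == len(times)
        assert sorted(m.timepoint_h for m in mats) == sorted(times)
        # all share the dose grid
        for m in mats:
            assert m.doses_row.tolist() == [0, 1, 2]

    def test_duplicate_cells_averaged(self, tmp_path):
        rows = _grid_rows([0, 1], [0, 1], lambda r, c: 10.0)
        rows.append(dict(rows[-1], response=30.0))  # duplicate (1, 1) cell
        (m,) = read_checkerboard(_long_csv(tmp_path, rows))
        assert m.response[1, 1] == 20.0

    def test_missing_column_is_schema_error(self, tmp_path):
        rows = _grid_rows([0, 1], [0, 1], lambda r, c: 0.0)
        df = pd.DataFrame(rows).drop(columns=["replicate"])
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="replicate"):
            read_checkerboard(path)

    def test_ragged_grid_is_validation_error(self, tmp_path):
        rows = _grid_rows([0, 1], [0, 1], lambda r, c: 0.0)
        rows = [r for r in rows if not (r["conc_r"] == 1 and r["conc_c"] == 1)]
        with pytest.raises(ValidationError, match="missing cells"):
            read_checkerboard(_long_csv(tmp_path, rows))

    def test_negative_concentration_rejected(self, tmp_path):
        rows = _grid_rows([-1, 1], [0, 1], lambda r, c: 0.0)
        with pytest.raises(ValidationError):
            read_checkerboard(_long_csv(tmp_path, rows))

    def test_write_read_roundtrip(self, tmp_path, bliss_null_matrix):
        path = tmp_path / "rt.csv"
        write_checkerboard([bliss_null_matrix], path)
        (back,) = read_checkerboard(path)
        np.testing.assert_allclose(back.response, bliss_null_matrix.response, atol=1e-9)
        np.testing.assert_allclose(back.doses_row, bliss_null_matrix.doses_row)


class TestNormalize:
    def _signal_matrix(self, signal):
        return ResponseMatrix(
            drug_row_name="a", drug_col_name="b",
            doses_row=[0.0, 1.0], doses_col=[0.0, 1.0],
            response=signal, response_scale="viability",
        )

    def test_half_signal_gives_half_inhibition(self):
        m = self._signal_matrix([[100.0, 100.0], [100.0, 50.0]])
        out = normalize(m, control="auto")
        assert out.response[1, 1] == 50.0
        assert out.response_scale == "inhibition"

    def test_signal_above_control_clips_to_zero_inhibition(self):
        m = self._signal_matrix([[100.0, 100.0], [100.0, 120.0]])
        with pytest.warns(UserWarning, match="clipped"):
            out = normalize(m)
        assert out.response[1, 1] == 0.0

    def test_all_signals_equal_control_gives_zero_inhibition(self):
        m = self._signal_matrix(np.full((2, 2), 80.0))
        out = normalize(m, control=80.0)
        assert np.all(out.response == 0.0)

    def test_nonpositive_control_rejected(self):
        m = self._signal_matrix(np.ones((2, 2)))
        with pytest.raises(ValidationError):
            normalize(m, control=0.0)

    def test_idempotent_on_inhibition_scale(self):
        m = self._signal_matrix([[100.0, 90.0], [80.0, 50.0]])
        once = normalize(m)
        with pytest.warns(UserWarning, match="identity"):
            twice = normalize(once)
        np.testing.assert_array_equal(once.response, twice.response)

    def test_inhibition_plus_viability_is_100_before_clipping(self):
        m = self._signal_matrix([[100.0, 90.0], [60.0, 30.0]])
        out = normalize(m)
        viability = 100.0 * m.response / 100.0
        np.testing.assert_allclose(out.response + viability, 100.0)


class TestReport:
    def test_report_roundtrip(self, tmp_path):
        rep = AnalysisReport(
            per_matrix=[{"deltas": {"bliss": {"mean_delta": 5.0}}}],
            aggregates={"models": {"bliss": {"mean_delta": 5.0, "sd": 0.1}}},
            classifications=[{"basis": "delta", "label": "synergism", "value": 5.0}],
            provenance={"seed": 1},
        )
        path = tmp_path / "report.json"
        write_report(rep, path)
        back = read_report(path)
        assert back.to_dict() == rep.to_dict()

    def test_empty_report_is_valid(self, tmp_path):
        path = tmp_path / "empty.json"
        write_report(AnalysisReport(), path)
        back = read_report(path)
        assert back.per_matrix == [] and back.aggregates == {}

    def test_nonfinite_values_roundtrip_via_null_flag(self, tmp_path):
        rep = AnalysisReport(aggregates={"r_squared": float("-inf"), "x": float("nan")})
        path = tmp_path / "nf.json"
        write_report(rep, path)
        text = path.read_text()
        assert "Infinity" not in text  # explicit flag, not bare JSON Infinity
        back = read_report(path)
        assert back.aggregates["r_squared"] == float("-inf")
        assert np.isnan(back.aggregates["x"])
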