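import math

import numpy as np
import pytest

from meltshift import (
    DEFAULT_GRADIENT,
    FormatError,
    MeltProfile,
    NormalizationError,
    RawProfile,
    TemperatureGradient,
    ValidationError,
    normalize_profile,
    read_quant_table,
    read_results,
    write_quant_table,
    write_results,
)
from meltshift.target_call import ShiftRecord, TargetCall


def _write_rows(path, header, rows):
    lines = ["\t".join(header)] + ["\t".join(str(v) for v in r) for r in rows]
    path.write_text("\n".join(lines) + "\n")


class TestTemperatureGradient:
    def test_rejects_non_increasing_temperatures(self):
        with pytest.raises(ValidationError):
            TemperatureGradient((37.0, 40.0, 40.0, 43.0), ("a", "b", "c", "d"))

    def test_rejects_mismatched_lengths_and_short_gradients(self):
        with pytest.raises(ValidationError):
            TemperatureGradient((37.0, 40.0, 43.0, 46.0), ("a", "b", "c"))
        with pytest.raises(ValidationError):
            TemperatureGradient((37.0, 40.0, 43.0), ("a", "b", "c"))


class TestReadQuantTable:
    def _toy_rows(self):
        base = [float(10 - i) for i in range(10)]
        return [
            ["P1", "vehicle", 1] + base,
            ["P1", "drug", 1] + [v * 2 for v in base],
            ["P2", "DMSO", 2] + base,       # alias, case-insensitive
            ["P2", "DA", 2] + base,          # alias for drug
        ]

    def test_toy_file_parses_in_gradient_order(self, tmp_path, gradient):
        path = tmp_path / "q.tsv"
        header = ["protein_id", "condition", "replicate"] + list(gradient.channel_labels)
        _write_rows(path, header, self._toy_rows())
        profiles = read_quant_table(path, gradient)
        assert len(profiles) == 4
        assert [p.protein_id for p in profiles] == ["P1", "P1", "P2", "P2"]
        assert profiles[0].intensities == tuple(float(10 - i) for i in range(10))
        assert profiles[2].condition == "vehicle" and profiles[3].condition == "drug"

    def test_shuffled_channel_columns_realign_by_header(self, tmp_path, gradient, rng):
        perm = rng.permutation(10)
        header = ["protein_id", "condition", "replicate"] + [
            gradient.channel_labels[i] for i in perm
        ]
        values = [float(v) for v in rng.uniform(1, 100, size=10)]
        row = ["P1", "vehicle", 1] + [values[i] for i in perm]
        path = tmp_path / "q.tsv"
        _write_rows(path, header, [row])
        (profile,) = read_quant_table(path, gradient)
        assert profile.intensities == pytest.approx(values)

    def test_missing_replicate_column_is_a_format_error(self, tmp_path, gradient):
        header = ["protein_id", "condition"] + list(gradient.channel_labels)
        path = tmp_path / "q.tsv"
        _write_rows(path, header, [["P1", "vehicle"] + [1.0] * 10])
        with pytest.raises(FormatError, match="replicate"):
            read_quant_table(path, gradient)

    def test_negative_intensity_names_the_protein(self, tmp_path, gradient):
        header = ["protein_id", "condition", "replicate"] + list(gradient.channel_labels)
        row = ["BADPROT", "vehicle", 1] + [1.0] * 9 + [-5.0]
        path = tmp_path / "q.tsv"
        _write_rows(path, header, [row])
        with pytest.raises(ValidationError, match="BADPROT"):
            read_quant_table(path, gradient)

    def test_malformed_row_reported_with_line_number(self, tmp_path, gradient):
        header = ["protein_id", "condition", "replicate"] + list(gradient.channel_labels)
        good = ["P1", "vehicle", 1] + [1.0] * 10
        bad = ["P2", "vehicle", "not_an_int"] + [1.0] * 10
        path = tmp_path / "q.tsv"
        _write_rows(path, header, [good, bad])
        with pytest.raises(FormatError, match="line 3"):
            read_quant_table(path, gradient)

    def test_na_tokens_become_missing_points(self, tmp_path, gradient):
        header = ["protein_id", "condition", "replicate"] + list(gradient.channel_labels)
        row = ["P1", "vehicle", 1, 5.0, "NA"] + [1.0] * 8
        path = tmp_path / "q.tsv"
        _write_rows(path, header, [row])
        (profile,) = read_quant_table(path, gradient)
        assert math.isnan(profile.intensities[1])

    def test_write_read_round_trip_is_exact(self, tmp_path, gradient, rng):
        profiles = [
            RawProfile(f"P{i}", "vehicle", 1,
                       tuple(float(v) for v in rng.uniform(1e3, 1e8, 10)))
            for i in range(5)
        ]
        path = tmp_path / "q.tsv"
        write_quant_table(profiles, gradient, path)
        back = read_quant_table(path, gradient)
        assert back == profiles


class TestNormalizeProfile:
    def test_divides_by_reference_intensity(self):
        raw = RawProfile("P1", "vehicle", 1,
                         (2.0e6, 1.0e6, 0.2e6) + (1e5,) * 7)
        prof = normalize_profile(raw)
        assert prof.rel_abundance[0] == 1.0
        assert prof.rel_abundance[1] == pytest.approx(0.5)
        assert prof.rel_abundance[2] == pytest.approx(0.1)

    def test_constant_profile_normalizes_to_ones(self):
        raw = RawProfile("P1", "vehicle", 1, (3.0,) * 10)
        assert normalize_profile(raw).rel_abundance == (1.0,) * 10

    def test_zero_reference_intensity_raises(self):
        raw = RawProfile("PZ", "vehicle", 1, (0.0,) + (1.0,) * 9)
        with pytest.raises(NormalizationError, match="PZ"):
            normalize_profile(raw)

    def test_idempotent_on_normalized_profiles(self, rng):
        values = (1.0,) + tuple(float(v) for v in rng.uniform(0.01, 1.2, 9))
        prof = MeltProfile("P1", "vehicle", 1, values)
        assert normalize_profile(prof) == prof

    def test_missing_points_counted(self):
        prof = MeltProfile("P1", "vehicle", 1,
                           (1.0, math.nan, 0.8) + (0.5,) * 7)
        assert prof.n_present == 9
        assert prof.missing_mask[1] is True


def _toy_calls():
    shift_full = ShiftRecord(
        protein_id="P1", dtm_1=-3.2, dtm_2=-2.8, dtm_ctrl=0.5,
        sign_concordant=True, exceeds_control=True, slope_pass=True,
        fc_profile=tuple(np.linspace(-0.3, 1.7, 10)), max_fc_score=1.7,
        tm_vehicle=(55.0, 54.5), tm_drug=(51.8, 51.7), min_abs_slope=0.21,
    )
    shift_nofit = ShiftRecord(
        protein_id="P2", dtm_1=None, dtm_2=None, dtm_ctrl=None,
        sign_concordant=None, exceeds_control=None, slope_pass=None,
        fc_profile=None, max_fc_score=None, tm_vehicle=(None, 52.0),
        tm_drug=(None, None), unfittable=True,
    )
    return [
        TargetCall("P1", "candidate_destabilized", "none", shift_full),
        TargetCall("P2", "excluded", "unfittable", shift_nofit),
    ]


class TestResultsRoundTrip:
    def test_round_trip_reproduces_records(self, tmp_path):
        calls = _toy_calls()
        path = tmp_path / "results.tsv"
        write_results(calls, path)
        assert read_results(path) == calls

    def test_empty_collection_gives_header_only_file(self, tmp_path):
        path = tmp_path / "results.tsv"
        write_results([], path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("protein_id\t")
        assert read_results(path) == []

    def test_undefined_tm_serialized_as_na(self, tmp_path):
        path = tmp_path / "results.tsv"
        write_results(_toy_calls(), path)
        row = path.read_text().splitlines()[2].split("\t")
        assert "NA" in row
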