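"""Domain containers and text I/O: round trips, sorting, missing data."""

import numpy as np
import pandas as pd
import pytest

from fusedcna import (
    AnnotationError,
    CNACall,
    FormatError,
    ProbeMap,
    ProfileMatrix,
    read_profiles,
    write_cna_calls,
    write_profiles,
)


def _cohort(probe_map_10):
    rng = np.random.default_rng(0)
    values = rng.normal(size=(3, 10)).round(6)
    return ProfileMatrix(["s1", "s2", "s3"], values, probe_map_10)


class TestReadWriteProfiles:
    def test_round_trip_is_lossless(self, tmp_path, probe_map_10):
        cohort = _cohort(probe_map_10)
        write_profiles(cohort, tmp_path / "m.tsv", tmp_path / "a.tsv",
                       provenance={"seed": 1})
        back = read_profiles(tmp_path / "m.tsv", tmp_path / "a.tsv")
        assert back.sample_ids == cohort.sample_ids
        np.testing.assert_array_equal(back.values, cohort.values)
        np.testing.assert_array_equal(back.probe_map.position, cohort.probe_map.position)

    def test_shuffled_input_columns_yield_identical_matrix(self, tmp_path, probe_map_10):
        cohort = _cohort(probe_map_10)
        write_profiles(cohort, tmp_path / "m.tsv", tmp_path / "a.tsv")
        frame = pd.read_csv(tmp_path / "m.tsv", sep="\t", index_col=0)
        ann = pd.read_csv(tmp_path / "a.tsv", sep="\t")
        rng = np.random.default_rng(3)
        perm = rng.permutation(10)
        frame.iloc[:, :] = frame.iloc[:, perm]
        frame.columns = frame.columns[perm]
        frame.to_csv(tmp_path / "m2.tsv", sep="\t")
        ann.iloc[rng.permutation(10)].to_csv(tmp_path / "a2.tsv", sep="\t", index=False)
        back = read_profiles(tmp_path / "m2.tsv", tmp_path / "a2.tsv")
        np.testing.assert_array_equal(back.values, cohort.values)
        np.testing.assert_array_equal(back.probe_map.probe_ids, cohort.probe_map.probe_ids)

    def test_probe_missing_everywhere_is_dropped(self, tmp_path, probe_map_10):
        cohort = _cohort(probe_map_10)
        write_profiles(cohort, tmp_path / "m.tsv", tmp_path / "a.tsv")
        frame = pd.read_csv(tmp_path / "m.tsv", sep="\t", index_col=0)
        frame["P00002"] = np.nan
        frame.to_csv(tmp_path / "m2.tsv", sep="\t")
        back = read_profiles(tmp_path / "m2.tsv", tmp_path / "a.tsv")
        assert back.n_probes == 9
        assert "P00002" not in back.probe_map.probe_ids

    def test_single_missing_entry_gets_probe_median(self, tmp_path, probe_map_10):
        # 1 missing entry in 6 samples (17%) is under the drop threshold
        rng = np.random.default_rng(5)
        cohort = ProfileMatrix(
            [f"s{i}" for i in range(6)], rng.normal(size=(6, 10)).round(6), probe_map_10
        )
        write_profiles(cohort, tmp_path / "m.tsv", tmp_path / "a.tsv")
        frame = pd.read_csv(tmp_path / "m.tsv", sep="\t", index_col=0)
        expected = float(np.median(frame.loc["s1":"s5", "P00001"]))
        frame.loc["s0", "P00001"] = np.nan
        frame.to_csv(tmp_path / "m2.tsv", sep="\t")
        back = read_profiles(tmp_path / "m2.tsv", tmp_path / "a.tsv")
        assert back.n_probes == 10
        j = list(back.probe_map.probe_ids).index("P00001")
        assert back.values[0, j] == pytest.approx(expected)

    def test_mismatched_probe_sets_raise(self, tmp_path, probe_map_10):
        cohort = _cohort(probe_map_10)
        write_profiles(cohort, tmp_path / "m.tsv", tmp_path / "a.tsv")
        ann = pd.read_csv(tmp_path / "a.tsv", sep="\t")
        ann.loc[0, "probe_id"] = "UNKNOWN"
        ann.to_csv(tmp_path / "a2.tsv", sep="\t", index=False)
        with pytest.raises(FormatError):
            read_profiles(tmp_path / "m.tsv", tmp_path / "a2.tsv")

    def test_error_policy_refuses_missing(self, tmp_path, probe_map_10):
        cohort = _cohort(probe_map_10)
        write_profiles(cohort, tmp_path / "m.tsv", tmp_path / "a.tsv")
        frame = pd.read_csv(tmp_path / "m.tsv", sep="\t", index_col=0)
        frame.loc["s1", "P00001"] = np.nan
        frame.to_csv(tmp_path / "m2.tsv", sep="\t")
        with pytest.raises(FormatError):
            read_profiles(tmp_path / "m2.tsv", tmp_path / "a.tsv", missing_policy="error")


class TestProbeMapValidation:
    def test_duplicate_positions_rejected(self):
        with pytest.raises(AnnotationError):
            ProbeMap(["A", "B"], ["1", "1"], [500, 500], ["p", "p"])

    def test_interleaved_arms_rejected(self):
        with pytest.raises(AnnotationError):
            ProbeMap(["A", "B", "C"], ["1", "1", "1"], [1, 2, 3], ["p", "q", "p"])

    def test_unknown_arm_label_rejected(self):
        with pytest.raises(AnnotationError):
            ProbeMap(["A"], ["1"], [1], ["x"])

    def test_natural_chromosome_order(self):
        pm = ProbeMap.from_frame(
            pd.DataFrame(
                {
                    "probe_id": ["a", "b", "c"],
                    "chromosome": ["10", "2", "X"],
                    "position": [5, 5, 5],
                    "arm": ["p", "p", "p"],
                }
            )
        )
        assert pm.chromosome.tolist() == ["2", "10", "X"]


class TestWriteCNACalls:
    CALL = CNACall("7", 3, 9, 100, 200, "gain", 0.8, node_id="7:r+", n_samples=12)

    def test_bed_is_zero_based_half_open(self, tmp_path):
        path = tmp_path / "calls.bed"
        write_cna_calls([self.CALL], path, format="bed")
        line = [l for l in path.read_text().splitlines() if not l.startswith("#")][0]
        fields = line.split("\t")
        assert fields[:3] == ["7", "99", "200"]

    def test_seg_is_one_based_inclusive_with_probe_count(self, tmp_path):
        path = tmp_path / "calls.seg"
        write_cna_calls([self.CALL], path, format="seg")
        lines = path.read_text().splitlines()
        assert lines[0].split("\t") == ["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]
        fields = lines[1].split("\t")
        assert fields[1:] == ["7", "100", "200", "7", "0.8"]

    def test_empty_call_list_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.seg"
        write_cna_calls([], path, format="seg")
        assert path.read_text().splitlines() == [
            "ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean"
        ]

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_cna_calls([], tmp_path / "x", format="gff")

    def test_direction_sign_consistency_enforced(self):
        with pytest.raises(ValueError):
            CNACall("1", 0, 1, 10, 20, "gain", -0.5)
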