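"""Profile CSV output, run reports and the shipped report schema."""

import json
from importlib import resources

import numpy as np
import pandas as pd
import pytest

from golgiflux import build_scenario, run_to_steady_state
from golgiflux.report import _monotonicity, summarize, write_profiles, write_report


@pytest.fixture(scope="module")
def small_result():
    species, params = build_scenario("single_snare_loss_only")
    return run_to_steady_state(species, params), species


class TestWriteProfiles:
    def test_row_count_and_header(self, small_result, tmp_path):
        result, species = small_result
        path = write_profiles(result, species, tmp_path / "p.csv", scenario="x")
        frame = pd.read_csv(path)
        assert list(frame.columns) == [
            "scenario",
            "species",
            "cisterna",
            "concentration",
            "normalized_concentration",
        ]
        assert len(frame) == len(species) * result.params.n_cisternae

    def test_normalization_peaks_at_one(self, small_result, tmp_path):
        result, species = small_result
        frame = pd.read_csv(write_profiles(result, species, tmp_path / "p.csv"))
        for _, group in frame.groupby("species"):
            assert group["normalized_concentration"].max() == pytest.approx(1.0)

    def test_round_trip_to_printed_precision(self, small_result, tmp_path):
        result, species = small_result
        frame = pd.read_csv(write_profiles(result, species, tmp_path / "p.csv"))
        for i, spec in enumerate(species):
            col = frame[frame.species == spec.name].sort_values("cisterna")
            np.testing.assert_allclose(
                col["concentration"].to_numpy(), result.profiles[i], rtol=1e-11
            )

    def test_deterministic_row_order(self, small_result, tmp_path):
        result, species = small_result
        f1 = (tmp_path / "a.csv", tmp_path / "b.csv")
        t1 = write_profiles(result, species, f1[0]).read_text()
        t2 = write_profiles(result, species, f1[1]).read_text()
        assert t1 == t2
        frame = pd.read_csv(f1[0])
        assert list(frame.species[:8]) == ["alpha_t"] * 8
        assert list(frame.cisterna[:8]) == list(range(1, 9))


class TestMonotonicity:
    @pytest.mark.parametrize(
        "profile, expected",
        [
            ([1.0, 1.0, 1.0], "constant"),
            ([1.0, 0.8, 0.5], "decreasing"),
            ([0.5, 0.8, 1.0], "increasing"),
            ([0.5, 1.0, 0.6], "unimodal"),
            ([1.0, 0.5, 1.0], "other"),
        ],
    )
    def test_shape_flags(self, profile, expected):
        assert _monotonicity(np.array(profile)) == expected


class TestSummarize:
    def test_summary_fields_recomputable_from_profiles(self, small_result):
        result, _ = small_result
        report = summarize(result, scenario="single_snare_loss_only")
        for summ in report.summaries:
            prof = result.profile(summ.name)
            assert summ.argmax_cisterna == int(np.argmax(prof)) + 1
            assert summ.peak_value == pytest.approx(float(prof.max()))
            assert summ.total == pytest.approx(float(prof.sum()))
            assert summ.monotonicity == "decreasing"

    def test_enzyme_summary_flags(self, enzymes_open_result):
        report = summarize(enzymes_open_result)
        flags = {s.name: s for s in report.summaries}
        assert flags["enz_med"].monotonicity == "unimodal"
        assert flags["enz_trans"].monotonicity == "unimodal"
        order = [
            flags["enz_cis"].argmax_cisterna,
            flags["enz_med"].argmax_cisterna,
            flags["enz_trans"].argmax_cisterna,
        ]
        assert order == sorted(order)

    def test_full_model_beta_v_flagged_rising(self, full_result):
        report = summarize(full_result)
        flags = {s.name: s.monotonicity for s in report.summaries}
        # rises across the stack, dips only in the trans-most cisterna
        assert flags["beta_v"] == "unimodal"
        assert flags["alpha_t"] == "decreasing"


def _check_schema(instance: dict, schema: dict) -> None:
    """Minimal structural validation against the shipped JSON schema
    (required keys, enums, primitive types); avoids a validator dependency."""
    types = {"object": dict, "string": str, "integer": int, "boolean": bool, "array": list}

    def check(node, sch, path="$"):
        if "enum" in sch:
            assert node in sch["enum"], f"{path}: {node!r} not in {sch['enum']}"
            return
        typ = sch.get("type")
        typs = typ if isinstance(typ, list) else [typ] if typ else []
        if typs:
            ok = any(
                (t == "null" and node is None)
                or (t == "number" and isinstance(node, (int, float)) and not isinstance(node, bool))
                or (t in types and isinstance(node, types[t]) and not (t == "integer" and isinstance(node, bool)))
                for t in typs
            )
            assert ok, f"{path}: {type(node)} does not match {typs}"
        if isinstance(node, dict) and "properties" in sch:
            for req in sch.get("required", []):
                assert req in node, f"{path}: missing required key {req}"
            if not sch.get("additionalProperties", True):
                extra = set(node) - set(sch["properties"])
                assert not extra, f"{path}: unexpected keys {extra}"
            for key, val in node.items():
                if key in sch["properties"]:
                    check(val, sch["properties"][key], f"{path}.{key}")
        if isinstance(node, list) and "items" in sch:
            for i, item in enumerate(node):
                check(item, sch["items"], f"{path}[{i}]")

    check(instance, schema)


class TestReportJson:
    def test_report_validates_against_shipped_schema(self, small_result, tmp_path):
        result, _ = small_result
        report = summarize(result, scenario="single_snare_loss_only")
        path = write_report(report, tmp_path / "report.json")
        instance = json.loads(path.read_text())
        schema = json.loads(
            resources.files("golgiflux").joinpath("schema/report.schema.json").read_text()
        )
        _check_schema(instance, schema)
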