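"""Structural-alert library and screening."""

import json

import pandas as pd
import pytest
from rdkit import Chem

from fdtox import load_alert_library, screen, screening_report
from fdtox.alerts import AlertLibrary, group_summary
from fdtox.errors import JoinError, LoadError

EXPECTED_ALERTS = {
    "TA662", "TA665", "TA642", "TA628", "TA11521", "TA667", "TA617",
    "TA626", "TA631", "TA1181", "TA1176", "TA659", "TA638", "TA634",
}


@pytest.fixture(scope="module")
def library():
    return load_alert_library()


class TestLibrary:
    def test_default_library_has_the_fourteen_named_alerts(self, library):
        assert {a.alert_id for a in library} == EXPECTED_ALERTS
        assert len(library) == 14

    def test_every_smarts_compiles(self, library):
        for alert in library:
            assert all(p is not None for p in alert.compiled())

    def test_roundtrip_through_serialization(self, library, tmp_path):
        path = tmp_path / "alerts.json"
        library.save(path)
        back = load_alert_library(path, include_defaults=False)
        assert {a.alert_id for a in back} == {a.alert_id for a in library}
        assert all(
            back.by_id[a.alert_id].smarts == a.smarts for a in library
        )

    def test_duplicate_alert_id_in_user_file_rejected(self, tmp_path):
        payload = {"alerts": [
            {"alert_id": "X1", "name": "a", "smarts": ["[CX4]"]},
            {"alert_id": "X1", "name": "b", "smarts": ["[OX2]"]},
        ]}
        path = tmp_path / "dup.json"
        path.write_text(json.dumps(payload))
        with pytest.raises(LoadError, match="X1"):
            load_alert_library(path, include_defaults=False)

    def test_invalid_smarts_named_in_error(self, tmp_path):
        payload = {"alerts": [{"alert_id": "BAD1", "name": "x", "smarts": ["[[["]}]}
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(payload))
        with pytest.raises(LoadError, match="BAD1"):
            load_alert_library(path, include_defaults=False)

    def test_empty_library_returns_no_hits(self):
        lib = AlertLibrary([])
        assert screen("CCN", lib) == []

    def test_user_file_extends_defaults(self, library, tmp_path):
        payload = {"alerts": [{"alert_id": "USR9", "name": "ether",
                               "smarts": ["[OX2]([CX4])[CX4]"]}]}
        path = tmp_path / "user.json"
        path.write_text(json.dumps(payload))
        lib = load_alert_library(path)
        assert len(lib) == 15
        assert "USR9" in lib.by_id


class TestScreen:
    def test_all_positive_and_negative_controls(self, library):
        """Each alert fires on its positive control and not on its paired
        negative control (28 control structures in total)."""
        failures = []
        for alert in library:
            pos = {h.alert_id for h in screen(alert.positive_control, library)}
            neg = {h.alert_id for h in screen(alert.negative_control, library)}
            if alert.alert_id not in pos:
                failures.append(f"{alert.alert_id} missed positive control")
            if alert.alert_id in neg:
                failures.append(f"{alert.alert_id} fired on negative control")
        assert not failures, failures

    @pytest.mark.parametrize(
        "smiles, present, absent",
        [
            ("CCCN", {"TA665"}, {"TA662"}),          # primary alkyl amine
            ("CCO", {"TA659"}, set()),                # aliphatic alcohol
            ("c1ccccc1", set(), EXPECTED_ALERTS),     # benzene: clean
            ("CCNCC", {"TA662"}, {"TA665"}),          # secondary amine
        ],
    )
    def test_named_examples(self, library, smiles, present, absent):
        hits = {h.alert_id for h in screen(smiles, library)}
        assert present <= hits
        assert not (absent & hits)

    def test_tetra_ammonium_counts_four_matches(self, library):
        smi = "C(C[NH3+])(C[NH3+])(C[NH3+])C[NH3+]"
        hit = {h.alert_id: h.match_count for h in screen(smi, library)}
        assert hit["TA642"] == 4

    def test_invariant_to_smiles_canonicalization(self, library):
        raw = "OCC(N)Cc1ccccc1"
        canon = Chem.CanonSmiles(raw)
        as_raw = {(h.alert_id, h.match_count) for h in screen(raw, library)}
        as_canon = {(h.alert_id, h.match_count) for h in screen(canon, library)}
        assert as_raw == as_canon


class TestScreeningReport:
    def test_report_row_count_and_review_flag(self, small_dataset, library):
        ds = small_dataset
        pred = ds.response_table["AverageBScore"]
        report = screening_report(ds, library, pred, concern_threshold=5000.0)
        assert len(report) == len(ds.ids)
        # review == high predicted score with zero alerts
        manual = (report.predicted_avg_bscore >= 5000.0) & (report.n_alerts == 0)
        assert (report.review == manual).all()

    def test_pristine_cores_are_alert_free(self, small_dataset, library):
        ds = small_dataset
        pristine = [c.cid for c in ds.compounds if not c.motif_counts]
        pred = ds.response_table["AverageBScore"]
        report = screening_report(ds, library, pred)
        assert (report.loc[pristine, "n_alerts"] == 0).all()

    def test_id_mismatch_raises_join_error(self, small_dataset, library):
        pred = small_dataset.response_table["AverageBScore"].iloc[:-2]
        with pytest.raises(JoinError):
            screening_report(small_dataset, library, pred)

    def test_group_summary_partitions_alerted_compounds(self, small_dataset, library):
        ds = small_dataset
        report = screening_report(ds, library, ds.response_table["AverageBScore"])
        groups = group_summary(report)
        assert groups.n_compounds.sum() == (report.alert_signature != "").sum()
        assert (groups.mean_score.diff().dropna() <= 1e-9).all()  # descending
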