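"""Ingestion, filtering, vocabulary and count-matrix assembly."""

import numpy as np
import pandas as pd
import pytest

import aefactor as af
from aefactor import ae_data

# The pooled three-study breast-cancer design: 10 periods (3 baseline),
# 5 treatments, 2 mechanisms (nucleic-acid-synthesis vs mitosis
# inhibition), with per-arm patient counts and cycle lengths.
DESIGN_ROWS = [
    # period, study, treatment, mechanism, cycles, baseline, n_patients
    (1, 1, None, None, None, True, 1625),
    (2, 1, 1, 1, 4, False, 1625),
    (3, 1, 5, 2, 4, False, 1583),
    (4, 2, 2, 1, 6, False, 731),
    (5, 3, None, None, None, True, 480),
    (6, 3, 3, 1, 4, False, 480),
    (7, 3, 4, 1, 3, False, 459),
    (8, 3, None, None, None, True, 481),
    (9, 3, 1, 1, 4, False, 481),
    (10, 3, 4, 1, 3, False, 472),
]


def _write_design(tmp_path, rows=DESIGN_ROWS, with_enrollment=True):
    design = pd.DataFrame(
        [r[:6] for r in rows],
        columns=[
            "period_id",
            "study_id",
            "treatment_id",
            "mechanism_id",
            "n_cycles",
            "is_baseline",
        ],
    )
    dpath = tmp_path / "design.csv"
    design.to_csv(dpath, index=False)
    epath = None
    if with_enrollment:
        # arms: periods 1-3 share patients; 4 own; 5-7 share; 8-10 share
        arm_of = {1: "a", 2: "a", 3: "a", 4: "b", 5: "c", 6: "c", 7: "c",
                  8: "d", 9: "d", 10: "d"}
        en = []
        for pid, *_rest, n in rows:
            arm = arm_of[pid]
            en += [
                {"period_id": pid, "patient_id": f"{arm}{i:05d}"}
                for i in range(n)
            ]
        epath = tmp_path / "enrollment.csv"
        pd.DataFrame(en).to_csv(epath, index=False)
    return dpath, epath


def _write_events(tmp_path, rows):
    df = pd.DataFrame(
        rows, columns=["patient_id", "period_id", "ae_name", "severity", "count"]
    )
    path = tmp_path / "events.csv"
    df.to_csv(path, index=False)
    return path


class TestReadEvents:
    def test_identity_parse(self, tmp_path):
        ev_path = _write_events(
            tmp_path,
            [
                ("a00000", 2, "NAUSEA", 1, 3),
                ("a00001", 2, "VOMIT", 2, 1),
                ("a00000", 3, "NAUSEA", 2, 2),
            ],
        )
        dpath, epath = _write_design(tmp_path)
        events, design = ae_data.read_events(ev_path, dpath, epath)
        assert len(events) == 3
        assert events[0] == af.AEEvent("a00000", 2, "NAUSEA", 1, 3)
        assert events[1].label == "VOMIT_2"

    def test_out_of_range_severity_names_row(self, tmp_path):
        ev_path = _write_events(tmp_path, [("a00000", 2, "NAUSEA", 5, 1)])
        dpath, epath = _write_design(tmp_path)
        with pytest.raises(ae_data.ValidationError, match="row 0"):
            ae_data.read_events(ev_path, dpath, epath)

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"patient_id": ["x"], "period_id": [1]}).to_csv(
            path, index=False
        )
        dpath, _ = _write_design(tmp_path, with_enrollment=False)
        with pytest.raises(ae_data.ValidationError, match="missing columns"):
            ae_data.read_events(path, dpath)

    def test_unknown_period_rejected(self, tmp_path):
        ev_path = _write_events(tmp_path, [("a00000", 99, "NAUSEA", 1, 1)])
        dpath, epath = _write_design(tmp_path)
        with pytest.raises(ae_data.ValidationError, match="period_id 99"):
            ae_data.read_events(ev_path, dpath, epath)

    def test_three_study_design_parses(self, tmp_path):
        ev_path = _write_events(tmp_path, [("a00000", 2, "NAUSEA", 1, 1)])
        dpath, epath = _write_design(tmp_path)
        _, design = ae_data.read_events(ev_path, dpath, epath)
        assert len(design) == 10
        assert sum(pm.is_baseline for pm in design) == 3
        treatments = {pm.treatment_id for pm in design if pm.treatment_id}
        assert treatments == {1, 2, 3, 4, 5}
        mech = {pm.treatment_id: pm.mechanism_id for pm in design
                if pm.treatment_id}
        assert mech == {1: 1, 2: 1, 3: 1, 4: 1, 5: 2}

    def test_inconsistent_mechanism_map_rejected(self, tmp_path):
        rows = [r if r[0] != 9 else (9, 3, 1, 2, 4, False, 481)
                for r in DESIGN_ROWS]
        ev_path = _write_events(tmp_path, [("a00000", 2, "NAUSEA", 1, 1)])
        dpath, epath = _write_design(tmp_path, rows)
        with pytest.raises(ae_data.ValidationError, match="mechanism"):
            ae_data.read_events(ev_path, dpath, epath)


class TestFilters:
    EVENTS = [
        af.AEEvent("p1", 1, "ALOPECIA", 2, 4),
        af.AEEvent("p1", 1, "NAUSEA", 1, 2),
        af.AEEvent("p2", 1, "ALOPECIA", 1, 1),
        af.AEEvent("p3", 1, "VOMIT", 3, 1),
    ]
    DESIGN = [
        af.PeriodMeta(1, 1, None, None, None, True,
                      enrolled_patients=["p1", "p2", "p3", "p4"]),
    ]

    def test_stopword_removes_all_severities(self):
        kept, _, report = ae_data.apply_filters(
            self.EVENTS, self.DESIGN, stopword_names={"ALOPECIA"}
        )
        assert all(ev.ae_name != "ALOPECIA" for ev in kept)
        assert report.removed_names == {"ALOPECIA": 2}

    def test_patient_with_only_stopword_events_is_dropped(self):
        kept, design, report = ae_data.apply_filters(
            self.EVENTS, self.DESIGN, stopword_names={"ALOPECIA"}
        )
        # p2 only had ALOPECIA; p4 never had an event
        assert set(report.removed_patients) == {"p2", "p4"}
        assert design[0].enrolled_patients == ["p1", "p3"]

    def test_no_stopwords_is_identity_on_events(self):
        kept, design, _ = ae_data.apply_filters(self.EVENTS[:3], self.DESIGN)
        assert kept == self.EVENTS[:3]

    def test_idempotent(self):
        kept1, design1, _ = ae_data.apply_filters(
            self.EVENTS, self.DESIGN, stopword_names={"ALOPECIA"}
        )
        kept2, design2, rep2 = ae_data.apply_filters(
            kept1, design1, stopword_names={"ALOPECIA"}
        )
        assert kept2 == kept1
        assert [pm.enrolled_patients for pm in design2] == [
            pm.enrolled_patients for pm in design1
        ]
        assert rep2.removed_names == {} and rep2.removed_patients == []

    def test_frequency_rule_drops_near_universal_names(self):
        # ALOPECIA hits 2 of 3 patients (67%) -> removed at a 50% floor
        kept, _, report = ae_data.apply_filters(
            self.EVENTS, self.DESIGN, max_patient_fraction=0.5
        )
        assert "ALOPECIA" in report.removed_names
        assert any(ev.ae_name == "NAUSEA" for ev in kept)


class TestIndex:
    def test_single_type_label(self):
        idx = ae_data.build_ae_type_index([af.AEEvent("p", 1, "VOMIT", 2, 1)])
        assert idx.labels == ["VOMIT_2"]

    def test_lexicographic_then_severity_order(self):
        events = [
            af.AEEvent("p", 1, "VOMIT", 2, 1),
            af.AEEvent("p", 1, "NAUSEA", 3, 1),
            af.AEEvent("p", 1, "NAUSEA", 1, 1),
            af.AEEvent("p", 1, "VOMIT", 1, 1),
            af.AEEvent("p", 1, "NAUSEA", 2, 1),
        ]
        idx = ae_data.build_ae_type_index(events)
        assert idx.J == 5
        assert idx.labels == [
            "NAUSEA_1", "NAUSEA_2", "NAUSEA_3", "VOMIT_1", "VOMIT_2",
        ]

    def test_empty_events_warns(self):
        with pytest.warns(UserWarning):
            idx = ae_data.build_ae_type_index([])
        assert idx.J == 0


class TestAdjacency:
    def _index(self, pairs):
        return ae_data.AETypeIndex(pairs)

    def test_consecutive_severities_chain(self):
        idx = self._index([("NAUSEA", 2), ("NAUSEA", 3)])
        adj = ae_data.build_adjacency(idx)
        assert adj.adj_pairs == [(0, 1)]
        assert adj.anchors == [0]

    def test_single_severity_has_anchor_only(self):
        idx = self._index([("VOMIT", 4)])
        adj = ae_data.build_adjacency(idx)
        assert adj.adj_pairs == [] and adj.anchors == [0]

    def test_gap_in_observed_grades_still_chains(self):
        # grades {1, 3} with 2 unobserved: the chain links 1 -> 3
        idx = self._index([("FEVER", 1), ("FEVER", 3)])
        adj = ae_data.build_adjacency(idx)
        assert adj.adj_pairs == [(0, 1)]
        assert adj.anchors == [idx.column("FEVER_1")]

    @pytest.mark.parametrize("seed", range(4))
    def test_chain_property_pairs_and_anchors_per_name(self, seed):
        rng = np.random.default_rng(seed)
        pairs = []
        n_names = int(rng.integers(2, 8))
        grades_of = {}
        for i in range(n_names):
            k = int(rng.integers(1, 5))
            grades = sorted(rng.choice(4, size=k, replace=False) + 1)
            grades_of[f"N{i}"] = grades
            pairs += [(f"N{i}", int(g)) for g in grades]
        idx = self._index(pairs)
        adj = ae_data.build_adjacency(idx)
        assert len(adj.anchors) == n_names
        assert len(adj.adj_pairs) == sum(
            len(g) - 1 for g in grades_of.values()
        )
        # each column is in at most two pairs
        from collections import Counter

        c = Counter([j for p in adj.adj_pairs for j in p])
        assert max(c.values(), default=0) <= 2


class TestAssemble:
    def test_single_event_maps_to_single_cell(self):
        design = [
            af.PeriodMeta(2, 1, 1, 1, 4, False, enrolled_patients=["A", "B"]),
        ]
        idx = ae_data.AETypeIndex([("NAUSEA", 1), ("VOMIT", 1)])
        data = ae_data.assemble_counts(
            [af.AEEvent("A", 2, "NAUSEA", 1, 3)], design, idx
        )
        Y = data.Y[2]
        assert Y[0, idx.column("NAUSEA_1")] == 3
        assert Y.sum() == 3
        assert np.all(data.C[2] == 4.0)

    def test_full_design_period_shapes_and_exposure(self, tmp_path):
        ev_path = _write_events(tmp_path, [("a00000", 2, "NAUSEA", 1, 1)])
        dpath, epath = _write_design(tmp_path)
        events, design = ae_data.read_events(ev_path, dpath, epath)
        idx = ae_data.build_ae_type_index(events)
        data = ae_data.assemble_counts(events, design, idx)
        assert data.Y[2].shape == (1625, 1)
        assert np.all(data.C[2] == 4.0)
        assert data.Y[4].shape == (731, 1) and np.all(data.C[4] == 6.0)
        # baseline exposure defaults to one pre-treatment interval
        assert np.all(data.C[1] == 1.0)

    def test_dropout_rows_absent_from_later_period(self):
        design = [
            af.PeriodMeta(2, 1, 1, 1, 4, False, enrolled_patients=["A", "B"]),
            af.PeriodMeta(3, 1, 5, 2, 4, False, enrolled_patients=["A"]),
        ]
        idx = ae_data.AETypeIndex([("NAUSEA", 1)])
        data = ae_data.assemble_counts([], design, idx)
        assert data.patients(2) == ["A", "B"]
        assert data.patients(3) == ["A"]

    def test_event_for_unenrolled_patient_rejected(self):
        design = [af.PeriodMeta(1, 1, 1, 1, 2, False, enrolled_patients=["A"])]
        idx = ae_data.AETypeIndex([("NAUSEA", 1)])
        with pytest.raises(ae_data.ValidationError, match="not covered"):
            ae_data.assemble_counts(
                [af.AEEvent("Z", 1, "NAUSEA", 1, 1)], design, idx
            )

    def test_exposure_override(self):
        design = [
            af.PeriodMeta(
                1, 1, 1, 1, 4, False,
                enrolled_patients=["A", "B"],
                exposure_overrides={"B": 2.5},
            )
        ]
        idx = ae_data.AETypeIndex([("NAUSEA", 1)])
        data = ae_data.assemble_counts([], design, idx)
        assert list(data.C[1]) == [4.0, 2.5]

    def test_total_count_roundtrip_and_row_order_invariance(self):
        rng = np.random.default_rng(7)
        design = [
            af.PeriodMeta(1, 1, None, None, None, True,
                          enrolled_patients=["A", "B", "C"]),
            af.PeriodMeta(2, 1, 1, 1, 3, False,
                          enrolled_patients=["C", "A", "B"]),
        ]
        names = ["N1", "N2"]
        events = [
            af.AEEvent(
                rng.choice(["A", "B", "C"]),
                int(rng.integers(1, 3)),
                rng.choice(names),
                int(rng.integers(1, 5)),
                int(rng.integers(0, 4)),
            )
            for _ in range(30)
        ]
        idx = ae_data.build_ae_type_index(events)
        data = ae_data.assemble_counts(events, design, idx)
        assert data.total_count == sum(ev.count for ev in events)
        shuffled = [events[i] for i in rng.permutation(len(events))]
        data2 = ae_data.assemble_counts(shuffled, design, idx)
        for p in data.Y:
            assert np.array_equal(data.Y[p], data2.Y[p])
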