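import json

import pytest

from saxsqc.exceptions import (
    CapacityError,
    DomainError,
    FormatError,
    UnknownHolderError,
    ValidationError,
)
from saxsqc.logistics import (
    HOLDER_POSITIONS,
    MAX_HOLDERS_PER_RUN,
    MeasurementRow,
    MeasurementSheet,
    PlateRow,
    PlateSheet,
    POSITIONS_PER_ROW,
    STORAGE_HOLDERS,
    STORAGE_SAMPLES,
    compile_manifest,
    generate_transfer_protocol,
    make_holder_uuids,
    make_label_payload,
    parse_label_payload,
    plan_deck,
    read_measurement_sheet,
    read_plate_sheet,
    validate_measurement_sheet,
    validate_plate_sheet,
    write_measurement_sheet,
    write_plate_sheet,
)
from saxsqc.synthetic import make_sheets


def minimal_measurement_sheet():
    return MeasurementSheet(
        [
            MeasurementRow("H1", 1, "buf1", "buffer"),
            MeasurementRow("H1", 2, "lysA", "sample", buffer_ref="buf1"),
        ],
        proposal_id="301111",
        saf_id="312222",
    )


class TestMeasurementValidation:
    def test_minimal_sheet_passes_and_gets_uuid(self):
        sheet = minimal_measurement_sheet()
        report = validate_measurement_sheet(sheet, rng=1)
        assert report.ok
        assert set(report.enriched.holder_uuids) == {"H1"}
        assert sheet.holder_uuids == {}  # input never mutated
        # idempotent re-validation, apart from the freshly drawn UUIDs
        again = validate_measurement_sheet(sheet, rng=2)
        assert again.ok and again.codes() == report.codes()
        assert again.enriched.holder_uuids != report.enriched.holder_uuids

    def test_six_samples_one_buffer_rejected(self):
        rows = [MeasurementRow("H1", 1, "buf1", "buffer")]
        rows += [
            MeasurementRow("H1", i + 2, f"s{i}", "sample", buffer_ref="buf1")
            for i in range(6)
        ]
        report = validate_measurement_sheet(MeasurementSheet(rows))
        assert report.codes() == ["buffer_every_5"]
        # the rule is an override-able default
        relaxed = validate_measurement_sheet(
            MeasurementSheet(rows), enforce_buffer_every=False
        )
        assert relaxed.ok and [w.code for w in relaxed.warnings] == ["buffer_every_5"]

    def test_holder_name_too_long(self):
        sheet = minimal_measurement_sheet()
        for r in sheet.rows:
            r.holder_name = "ABCDE"
        assert validate_measurement_sheet(sheet).codes() == ["holder_name_len"]

    @pytest.mark.parametrize(
        "mutate, code",
        [
            (lambda s: setattr(s.rows[1], "sample_name", "bad name!"), "name_rule"),
            (lambda s: setattr(s.rows[1], "buffer_ref", "ghost"), "missing_buffer"),
            (lambda s: setattr(s.rows[1], "position", 1), "dup_position"),
            (lambda s: setattr(s.rows[1], "position", 19), "position_range"),
            (lambda s: setattr(s.rows[1], "role", "blank"), "role_rule"),
            (lambda s: setattr(s.rows[1], "sample_name", "buf1"), "dup_name"),
        ],
    )
    def test_single_rule_violations(self, mutate, code):
        sheet = minimal_measurement_sheet()
        mutate(sheet)
        assert code in validate_measurement_sheet(sheet).codes()


class TestPlateValidation:
    def test_sample_in_column_10_rejected(self):
        sheet = PlateSheet([
            PlateRow("A1", "buf", 50.0),
            PlateRow("A10", "s1", 50.0, buffer_ref="buf"),
        ])
        assert validate_plate_sheet(sheet).codes() == ["well_rule"]

    def test_empty_sheet(self):
        assert "no_samples" in validate_plate_sheet(PlateSheet([])).codes()

    def test_four_occupied_rows_need_two_holders(self):
        rows = []
        for r in "ABCD":
            rows.append(PlateRow(f"{r}1", f"buf_{r}", 50.0))
            rows.append(PlateRow(f"{r}2", f"s_{r}", 50.0, buffer_ref=f"buf_{r}"))
        report = validate_plate_sheet(PlateSheet(rows))
        assert report.ok and report.info["holders_needed"] == 2

    def test_dangling_mixing_source(self):
        sheet = PlateSheet([
            PlateRow("A1", "buf", 50.0),
            PlateRow("A2", "s1", 50.0, buffer_ref="buf",
                     mixing_sources=[("H12", 10.0)]),
        ])
        assert validate_plate_sheet(sheet).codes() == ["dangling_mix_source"]


class TestTransferProtocol:
    def test_two_well_plate(self):
        plate = PlateSheet([
            PlateRow("A1", "buf", 50.0),
            PlateRow("A2", "s1", 50.0, buffer_ref="buf"),
        ], proposal_id="301111", saf_id="312222")
        proto, msheet = generate_transfer_protocol(plate, make_holder_uuids(1, 0))
        assert len(proto.steps) == 2
        assert [s.position for s in proto.steps] == [1, 2]
        assert validate_measurement_sheet(msheet).ok
        assert {r.sample_name for r in msheet.rows} == {"buf", "s1"}

    def test_full_plate_mapping(self):
        plate, _ = make_sheets(72)
        uuids = make_holder_uuids(4, 0)
        proto, msheet = generate_transfer_protocol(plate, uuids)
        assert len(proto.steps) == 72
        assert len(msheet.holders()) == 4
        # injective and total: 18 distinct positions per holder
        dests = {(s.holder_uuid, s.position) for s in proto.holder_steps}
        assert len(dests) == 72
        for hu in uuids:
            positions = sorted(p for u, p in dests if u == hu)
            assert positions == list(range(1, HOLDER_POSITIONS + 1))
        assert validate_measurement_sheet(msheet).ok

    def test_mixing_steps_precede_transfer(self):
        plate = PlateSheet([
            PlateRow("A1", "buf", 50.0),
            PlateRow("A2", "s1", 50.0, buffer_ref="buf",
                     mixing_sources=[("A10", 20.0), ("A11", 10.0)]),
            PlateRow("A10", "stockA", 200.0),
            PlateRow("A11", "stockB", 200.0),
        ])
        proto, _ = generate_transfer_protocol(plate, make_holder_uuids(1, 0))
        s1_steps = [s for s in proto.steps
                    if s.dest_well == "A2" or s.source_well == "A2"]
        assert len(s1_steps) == 3
        assert [s.mix for s in s1_steps] == [False, False, True]
        assert s1_steps[-1].holder_uuid is not None

    def test_insufficient_holders(self):
        plate, _ = make_sheets(72)
        with pytest.raises(CapacityError):
            generate_transfer_protocol(plate, make_holder_uuids(3, 0))

    def test_invalid_plate_rejected(self):
        plate, _ = make_sheets(18, planted_errors=["well_rule"])
        with pytest.raises(ValidationError):
            generate_transfer_protocol(plate, make_holder_uuids(1, 0))

    def test_protocol_json_round_trip(self, tmp_path):
        plate, _ = make_sheets(18)
        proto, _ = generate_transfer_protocol(plate, make_holder_uuids(1, 0))
        doc = json.loads(proto.to_json(tmp_path / "p.json"))
        assert len(doc["steps"]) == 18
        assert doc["labware"]["holder_adaptors"] == 1


class TestDeckPlanning:
    def test_operational_maximum_run_is_feasible(self):
        layout = plan_deck(2, 12, 2)
        assert not layout.empty
        assert layout.max_feasible_holders == MAX_HOLDERS_PER_RUN
        assert sum(1 for v in layout.slots.values() if v.startswith("holder")) == 4

    def test_empty_layout(self):
        assert plan_deck(0, 0, 0).empty

    def test_thirteen_holders_split_into_runs(self):
        with pytest.raises(CapacityError) as exc:
            plan_deck(2, 13, 2)
        runs = exc.value.suggestion
        assert sum(r["holders"] for r in runs) == 13
        assert all(r["holders"] <= MAX_HOLDERS_PER_RUN and r["plates"] <= 2 for r in runs)

    def test_negative_counts_rejected(self):
        with pytest.raises(DomainError):
            plan_deck(-1, 0, 0)


class TestManifest:
    def _registry(self, n_holders, owners):
        uuids = make_holder_uuids(n_holders, 0)
        registry = {}
        for i, hu in enumerate(uuids):
            sheet = minimal_measurement_sheet()
            sheet.holder_uuids = {"H1": hu}
            registry[hu] = {"owner": owners[i % len(owners)], "sheet": sheet}
        return uuids, registry

    def test_grouped_by_owner(self):
        uuids, registry = self._registry(3, [("301111", "1"), ("305555", "2")])
        man = compile_manifest(uuids, registry)
        assert len(man.groups) == 2 and man.n_holders == 3

    def test_duplicate_uuid_rejected(self):
        uuids, registry = self._registry(2, [("p", "s")])
        with pytest.raises(DomainError):
            compile_manifest([uuids[0], uuids[0]], registry)

    def test_unknown_uuid_rejected(self):
        uuids, registry = self._registry(2, [("p", "s")])
        with pytest.raises(UnknownHolderError):
            compile_manifest(uuids + ["deadbeef"], registry)

    def test_storage_capacity_enforced(self):
        uuids, registry = self._registry(STORAGE_HOLDERS + 1, [("p", "s")])
        with pytest.raises(CapacityError):
            compile_manifest(uuids, registry)


class TestLabelsAndUuids:
    def test_payload_round_trip(self):
        label, payload = make_label_payload(301111, 312222, "01")
        parsed = parse_label_payload(payload)
        assert parsed == {"proposal": "301111", "saf": "312222", "plate_id": "01"}
        for fieldval in ("301111", "312222", "01"):
            assert fieldval in label

    @pytest.mark.parametrize("plate_id", ["1", "001", "AB", ""])
    def test_bad_plate_id(self, plate_id):
        with pytest.raises(FormatError):
            make_label_payload(301111, 312222, plate_id)

    def test_bad_payload(self):
        with pytest.raises(FormatError):
            parse_label_payload("no-dash")

    def test_seeded_uuids_reproducible(self):
        assert make_holder_uuids(5, 7) == make_holder_uuids(5, 7)
        assert make_holder_uuids(5, 7) != make_holder_uuids(5, 8)
        # well-formed v4
        assert all(u[14] == "4" for u in make_holder_uuids(3, 0))


class TestSheetIO:
    @pytest.mark.parametrize("suffix", [".csv", ".xlsx"])
    def test_measurement_round_trip(self, tmp_path, suffix):
        _, sheet = make_sheets(18)
        sheet.holder_uuids = dict(zip(sheet.holders(), make_holder_uuids(1, 0)))
        path = tmp_path / f"meas{suffix}"
        write_measurement_sheet(sheet, path)
        back = read_measurement_sheet(path)
        assert back.proposal_id == sheet.proposal_id
        assert back.holder_uuids == sheet.holder_uuids
        assert [(r.holder_name, r.position, r.sample_name, r.role, r.buffer_ref)
                for r in back.rows] == [
            (r.holder_name, r.position, r.sample_name, r.role, r.buffer_ref)
            for r in sheet.rows
        ]

    @pytest.mark.parametrize("suffix", [".csv", ".xlsx"])
    def test_plate_round_trip(self, tmp_path, suffix):
        plate, _ = make_sheets(18)
        plate.rows[1].mixing_sources = [("A10", 20.0)]
        plate.rows.append(PlateRow("A10", "stock", 100.0))
        path = tmp_path / f"plate{suffix}"
        write_plate_sheet(plate, path)
        back = read_plate_sheet(path)
        assert back.plate_id == plate.plate_id
        assert [(r.well, r.sample_name, r.buffer_ref, r.mixing_sources)
                for r in back.rows] == [
            (r.well, r.sample_name, r.buffer_ref, r.mixing_sources)
            for r in plate.rows
        ]


def test_capacity_constants_are_consistent():
    assert HOLDER_POSITIONS == 2 * POSITIONS_PER_ROW == 18
    assert STORAGE_SAMPLES == STORAGE_HOLDERS * HOLDER_POSITIONS == 360
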