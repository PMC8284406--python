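"""Sample tracking for mail-in solution scattering.

Two spreadsheet dialects are handled:

* the **measurement sheet** for samples shipped pre-loaded in 18-position
  sample holders (two rows of nine 0.2 ml PCR tubes), naming each
  holder (<= 4 characters), each tube position, the sample it contains
  and the buffer paired with it for background subtraction;
* the **plate sheet** for samples shipped in 96-well plates, where only
  columns 1-9 of each row hold measured wells (matching the two
  9-position holder rows) and columns 10-12 hold buffer or other stock
  chemicals for mixing series.

Validation catches everything that would stall unattended data
collection — detector-unsafe names, duplicate names or positions within
a holder, samples without a buffer, buffers serving more than five
samples — and, on success, embeds the user identity (proposal + SAF
numbers) and a fresh UUID per holder.  From a validated plate sheet the
package generates the liquid-handler transfer protocol and the
measurement sheet the beamline will use, plans the robot deck, and
compiles the holder manifest consulted before a collection run.

Schema (CSV with ``# key: value`` metadata headers, or XLSX with a
``meta`` sheet):

===================  =====================================================
measurement sheet    holder_name, position, sample_name, role, buffer_ref,
                     volume_ul (optional), plate_origin (optional)
plate sheet          well, sample_name, volume_ul, buffer_ref,
                     mixing_sources (``"A10:20;B10:15"`` = well:volume)
===================  =====================================================
"""

from __future__ import annotations

import json
import math
import re
import uuid as uuid_mod
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .exceptions import CapacityError, DomainError, FormatError, UnknownHolderError, ValidationError

__all__ = [
    "MeasurementRow",
    "MeasurementSheet",
    "PlateRow",
    "PlateSheet",
    "ValidationIssue",
    "ValidationReport",
    "TransferStep",
    "TransferProtocol",
    "DeckLayout",
    "HolderManifest",
    "validate_measurement_sheet",
    "validate_plate_sheet",
    "generate_transfer_protocol",
    "plan_deck",
    "compile_manifest",
    "make_label_payload",
    "parse_label_payload",
    "make_holder_uuids",
    "read_measurement_sheet",
    "write_measurement_sheet",
    "read_plate_sheet",
    "write_plate_sheet",
    "HOLDER_POSITIONS",
    "POSITIONS_PER_ROW",
    "SAMPLE_COLUMNS",
    "PLATE_ROWS",
    "PLATE_COLUMNS",
    "BUFFER_EVERY",
    "MAX_HOLDER_NAME_LEN",
    "STORAGE_HOLDERS",
    "STORAGE_SAMPLES",
    "DECK_SLOTS",
    "USABLE_DECK_SLOTS",
    "HOLDERS_PER_ADAPTOR",
    "MAX_PLATES_PER_RUN",
    "MAX_HOLDERS_PER_RUN",
    "TIPS_PER_RACK",
]

# --- hard numbers of the LiX sample-handling hardware -----------------------
POSITIONS_PER_ROW = 9            #: tube positions per holder row
HOLDER_POSITIONS = 2 * POSITIONS_PER_ROW   #: 18 tubes per holder
SAMPLE_COLUMNS = range(1, POSITIONS_PER_ROW + 1)  #: plate columns 1-9 are measured
PLATE_ROWS = "ABCDEFGH"
PLATE_COLUMNS = range(1, 13)
BUFFER_EVERY = 5                 #: a buffer serves at most 5 samples
MAX_HOLDER_NAME_LEN = 4
STORAGE_HOLDERS = 20             #: sample-storage unit capacity (holders)
STORAGE_SAMPLES = STORAGE_HOLDERS * HOLDER_POSITIONS  #: 360 tubes
DECK_SLOTS = 12                  #: OT2 deck slots (standard plate footprint)
USABLE_DECK_SLOTS = DECK_SLOTS - 1  #: one slot is the fixed trash bin
HOLDERS_PER_ADAPTOR = 3          #: holders grouped per plate-footprint adaptor
MAX_PLATES_PER_RUN = 2           #: per-transfer-run operational caps
MAX_HOLDERS_PER_RUN = 12
TIPS_PER_RACK = 96

_NAME_RE = re.compile(r"^[A-Za-z0-9_-]+$")
_WELL_RE = re.compile(r"^([A-H])(\d{1,2})$")


def _safe_name(name) -> bool:
    """Detector-software-safe sample name: alphanumerics, '_' and '-'."""
    return isinstance(name, str) and bool(_NAME_RE.match(name))


def parse_well(well: str) -> tuple[str, int]:
    """Split 'C7' into ('C', 7); raise DomainError for malformed wells."""
    m = _WELL_RE.match(str(well).strip().upper())
    if not m or not (1 <= int(m.group(2)) <= 12):
        raise DomainError(f"malformed well {well!r} (expected A1-H12)")
    return m.group(1), int(m.group(2))


# ---------------------------------------------------------------------------
# sheet data model


@dataclass
class MeasurementRow:
    holder_name: str
    position: int
    sample_name: str
    role: str                    # 'sample' | 'buffer'
    buffer_ref: str | None = None
    volume_ul: float | None = None
    plate_origin: str | None = None


@dataclass
class MeasurementSheet:
    rows: list[MeasurementRow]
    proposal_id: str | None = None
    saf_id: str | None = None
    holder_uuids: dict[str, str] = field(default_factory=dict)

    def holders(self) -> list[str]:
        seen = []
        for r in self.rows:
            if r.holder_name not in seen:
                seen.append(r.holder_name)
        return seen

    def n_samples(self) -> int:
        return sum(1 for r in self.rows if r.role == "sample")


@dataclass
class PlateRow:
    well: str
    sample_name: str
    volume_ul: float
    buffer_ref: str | None = None        # None => buffer / stock chemical
    mixing_sources: list[tuple[str, float]] = field(default_factory=list)


@dataclass
class PlateSheet:
    rows: list[PlateRow]
    proposal_id: str | None = None
    saf_id: str | None = None
    plate_id: str = "01"


@dataclass
class ValidationIssue:
    code: str
    location: str
    message: str

    def __str__(self):
        return f"[{self.code}] {self.location}: {self.message}"


@dataclass
class ValidationReport:
    errors: list[ValidationIssue] = field(default_factory=list)
    warnings: list[ValidationIssue] = field(default_factory=list)
    enriched: MeasurementSheet | PlateSheet | None = None
    info: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors

    def codes(self) -> list[str]:
        return [e.code for e in self.errors]


# ---------------------------------------------------------------------------
# UUIDs and labels


def _as_rng(rng) -> np.random.Generator | None:
    if rng is None or isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def make_holder_uuids(n: int, rng=None) -> list[str]:
    """n holder UUIDs (version 4).  Pass an int seed or Generator for a
    reproducible sequence; default is the system entropy source."""
    rng = _as_rng(rng)
    out = []
    for _ in range(n):
        raw = bytes(rng.integers(0, 256, 16, dtype=np.uint8)) if rng is not None else None
        u = uuid_mod.UUID(bytes=raw, version=4) if raw is not None else uuid_mod.uuid4()
        out.append(str(u))
    return out


def make_label_payload(proposal, saf, plate_id: str) -> tuple[str, str]:
    """Plate-label text and the QR payload encoding the same information.

    The payload joins the proposal number, SAF number and a two-digit
    plate identifier with '-'; :func:`parse_label_payload` inverts it.
    """
    proposal = str(proposal)
    saf = str(saf)
    plate_id = str(plate_id)
    if not proposal.isdigit() or not saf.isdigit():
        raise FormatError("proposal and SAF numbers must be numeric")
    if not (len(plate_id) == 2 and plate_id.isdigit()):
        raise FormatError("plate_id must be exactly two digits")
    payload = f"{proposal}-{saf}-{plate_id}"
    label = f"proposal {proposal} / SAF {saf} / plate {plate_id}"
    return label, payload


def parse_label_payload(payload: str) -> dict:
    parts = str(payload).split("-")
    if len(parts) != 3:
        raise FormatError(f"malformed label payload {payload!r}")
    proposal, saf, plate_id = parts
    if not (proposal.isdigit() and saf.isdigit() and len(plate_id) == 2 and plate_id.isdigit()):
        raise FormatError(f"malformed label payload {payload!r}")
    return {"proposal": proposal, "saf": saf, "plate_id": plate_id}


# ---------------------------------------------------------------------------
# validation


def validate_measurement_sheet(
    sheet: MeasurementSheet,
    buffer_every: int = BUFFER_EVERY,
    enforce_buffer_every: bool = True,
    rng=None,
) -> ValidationReport:
    """Validate a measurement sheet against the collection-time rules.

    Checks, each yielding a located machine-readable error:

    - ``name_rule``: sample names must be detector-safe;
    - ``holder_name_len``: holder names at most 4 characters;
    - ``position_range`` / ``dup_position``: positions 1-18, unique per holder;
    - ``dup_name``: no duplicate sample names within a holder;
    - ``role_rule``: role must be 'sample' or 'buffer';
    - ``missing_buffer``: every sample resolves to a buffer row in its holder;
    - ``buffer_every_5``: no buffer serves more than ``buffer_every``
      samples (warning instead of error when ``enforce_buffer_every`` is
      False).

    On success the returned report carries an *enriched copy* of the
    sheet with a fresh UUID per holder (seedable through ``rng``);
    validation never mutates its input.
    """
    errors: list[ValidationIssue] = []
    warnings: list[ValidationIssue] = []

    if not sheet.rows:
        errors.append(ValidationIssue("no_samples", "sheet", "sheet contains no rows"))

    by_holder: dict[str, list[MeasurementRow]] = {}
    for r in sheet.rows:
        by_holder.setdefault(r.holder_name, []).append(r)

    for holder, rows in by_holder.items():
        loc = f"holder {holder!r}"
        if not isinstance(holder, str) or not (1 <= len(holder) <= MAX_HOLDER_NAME_LEN):
            errors.append(ValidationIssue(
                "holder_name_len", loc,
                f"holder name must be 1-{MAX_HOLDER_NAME_LEN} characters"))
        seen_pos: set[int] = set()
        seen_names: set[str] = set()
        buffer_names = {r.sample_name for r in rows if r.role == "buffer"}
        buffer_load: dict[str, int] = {}
        for r in rows:
            rloc = f"{loc} position {r.position}"
            if not _safe_name(r.sample_name):
                errors.append(ValidationIssue(
                    "name_rule", rloc,
                    f"sample name {r.sample_name!r} is not detector-safe "
                    "([A-Za-z0-9_-]+)"))
            if not (1 <= int(r.position) <= HOLDER_POSITIONS):
                errors.append(ValidationIssue(
                    "position_range", rloc,
                    f"position must be 1-{HOLDER_POSITIONS}"))
            if r.position in seen_pos:
                errors.append(ValidationIssue(
                    "dup_position", rloc, "duplicate position within holder"))
            seen_pos.add(r.position)
            if r.sample_name in seen_names:
                errors.append(ValidationIssue(
                    "dup_name", rloc,
                    f"duplicate sample name {r.sample_name!r} within holder"))
            seen_names.add(r.sample_name)
            if r.role not in ("sample", "buffer"):
                errors.append(ValidationIssue(
                    "role_rule", rloc, f"role must be 'sample' or 'buffer', got {r.role!r}"))
            elif r.role == "sample":
                if not r.buffer_ref or r.buffer_ref not in buffer_names:
                    errors.append(ValidationIssue(
                        "missing_buffer", rloc,
                        f"sample {r.sample_name!r} has no resolvable buffer"))
                else:
                    buffer_load[r.buffer_ref] = buffer_load.get(r.buffer_ref, 0) + 1
        for bname, load in buffer_load.items():
            if load > buffer_every:
                issue = ValidationIssue(
                    "buffer_every_5", f"{loc} buffer {bname!r}",
                    f"buffer serves {load} samples; a new buffer measurement "
                    f"is required for every {buffer_every} samples")
                (errors if enforce_buffer_every else warnings).append(issue)

    report = ValidationReport(errors, warnings)
    if report.ok:
        uuids = make_holder_uuids(len(by_holder), rng)
        enriched = MeasurementSheet(
            [replace(r) for r in sheet.rows],
            sheet.proposal_id,
            sheet.saf_id,
            dict(zip(by_holder.keys(), uuids)),
        )
        report.enriched = enriched
        report.info["holder_uuids"] = enriched.holder_uuids
    return report


def _tips_needed(rows: list[PlateRow]) -> int:
    """One tip per distinct source well (shared across that well's steps)."""
    sources: set[str] = set()
    for r in rows:
        _, col = parse_well(r.well)
        if col in SAMPLE_COLUMNS:
            sources.add(r.well.upper())
        for src, _vol in r.mixing_sources:
            sources.add(str(src).upper())
    return len(sources)


def validate_plate_sheet(sheet: PlateSheet, buffer_every: int = BUFFER_EVERY) -> ValidationReport:
    """Validate a 96-well plate sheet and report transfer requirements.

    Measured wells live in columns 1-9 (rows with a ``buffer_ref`` are
    samples, rows without are buffers); columns 10-12 may only hold
    buffer/chemical stocks for mixing.  Checks: ``bad_well``,
    ``dup_well``, ``name_rule``, ``well_rule`` (sample in columns
    10-12), ``missing_buffer`` (buffer_ref must resolve to a measured
    buffer well), ``dangling_mix_source``, ``buffer_every_5``,
    ``no_samples``.  ``report.info`` carries ``holders_needed``
    (ceil(occupied rows / 2): two 9-well plate rows fill one holder),
    ``tips_needed`` and ``tip_racks_needed``.
    """
    errors: list[ValidationIssue] = []
    warnings: list[ValidationIssue] = []

    wells_seen: set[str] = set()
    parsed: list[tuple[PlateRow, str, int]] = []
    all_wells: set[str] = set()
    for r in sheet.rows:
        try:
            wrow, wcol = parse_well(r.well)
        except DomainError:
            errors.append(ValidationIssue("bad_well", f"well {r.well!r}", "malformed well"))
            continue
        well = f"{wrow}{wcol}"
        if well in wells_seen:
            errors.append(ValidationIssue("dup_well", f"well {well}", "duplicate well"))
        wells_seen.add(well)
        all_wells.add(well)
        parsed.append((r, wrow, wcol))

    measured = [(r, wrow, wcol) for r, wrow, wcol in parsed if wcol in SAMPLE_COLUMNS]
    measured_buffers = {r.sample_name for r, _, c in measured if r.buffer_ref is None}
    n_samples = sum(1 for r, _, _ in parsed if r.buffer_ref is not None)
    if n_samples == 0:
        errors.append(ValidationIssue("no_samples", "sheet", "plate contains no samples"))

    buffer_load: dict[str, int] = {}
    for r, wrow, wcol in parsed:
        loc = f"well {wrow}{wcol}"
        if not _safe_name(r.sample_name):
            errors.append(ValidationIssue(
                "name_rule", loc,
                f"sample name {r.sample_name!r} is not detector-safe"))
        if r.buffer_ref is not None and wcol not in SAMPLE_COLUMNS:
            errors.append(ValidationIssue(
                "well_rule", loc,
                f"samples are restricted to columns 1-{POSITIONS_PER_ROW}; "
                "columns 10-12 hold buffer/chemical stocks only"))
        if r.buffer_ref is not None:
            if r.buffer_ref not in measured_buffers:
                errors.append(ValidationIssue(
                    "missing_buffer", loc,
                    f"buffer_ref {r.buffer_ref!r} does not resolve to a "
                    "measured buffer well (columns 1-9)"))
            else:
                buffer_load[r.buffer_ref] = buffer_load.get(r.buffer_ref, 0) + 1
        for src, vol in r.mixing_sources:
            try:
                srow, scol = parse_well(src)
            except DomainError:
                errors.append(ValidationIssue(
                    "dangling_mix_source", loc, f"malformed mixing source {src!r}"))
                continue
            if f"{srow}{scol}" not in all_wells:
                errors.append(ValidationIssue(
                    "dangling_mix_source", loc,
                    f"mixing source {src!r} is not on the plate"))
    for bname, load in buffer_load.items():
        if load > buffer_every:
            errors.append(ValidationIssue(
                "buffer_every_5", f"buffer {bname!r}",
                f"buffer serves {load} samples (limit {buffer_every})"))

    occupied_rows = sorted({wrow for _, wrow, wcol in measured})
    holders_needed = math.ceil(len(occupied_rows) / 2)
    tips = _tips_needed([r for r, _, _ in parsed])
    report = ValidationReport(errors, warnings)
    report.info.update(
        holders_needed=holders_needed,
        occupied_rows=occupied_rows,
        tips_needed=tips,
        tip_racks_needed=math.ceil(tips / TIPS_PER_RACK) if tips else 0,
        n_samples=n_samples,
        n_measured_wells=len(measured),
    )
    if report.ok:
        report.enriched = PlateSheet(
            [replace(r) for r in sheet.rows], sheet.proposal_id, sheet.saf_id, sheet.plate_id
        )
    return report


# ---------------------------------------------------------------------------
# transfer planning


@dataclass
class TransferStep:
    """One aspirate/dispense step.  ``dest_well`` is set for in-plate
    mixing steps, ``holder_uuid``/``position`` for holder transfers."""

    source_well: str
    volume_ul: float
    dest_well: str | None = None
    holder_uuid: str | None = None
    position: int | None = None
    mix: bool = False

    def to_dict(self) -> dict:
        d = {"source_well": self.source_well, "volume_ul": self.volume_ul, "mix": self.mix}
        if self.dest_well is not None:
            d["dest_well"] = self.dest_well
        else:
            d["holder_uuid"] = self.holder_uuid
            d["position"] = self.position
        return d


@dataclass
class TransferProtocol:
    steps: list[TransferStep]
    labware: dict = field(default_factory=dict)

    @property
    def holder_steps(self) -> list[TransferStep]:
        return [s for s in self.steps if s.holder_uuid is not None]

    def to_json(self, path=None) -> str:
        doc = {"labware": self.labware, "steps": [s.to_dict() for s in self.steps]}
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def generate_transfer_protocol(
    sheet: PlateSheet,
    holder_uuids: list[str],
    validate: bool = True,
) -> tuple[TransferProtocol, MeasurementSheet]:
    """Plan the plate -> holder transfer and emit the measurement sheet.

    Occupied plate row k (0-based, among occupied rows, top-down) maps to
    holder k // 2, holder row k % 2; well column c (1-9) maps to holder
    position c (row 0) or 9 + c (row 1).  Mixing steps for a well precede
    its transfer to the holder, which carries the mix flag.  The emitted
    measurement sheet records the plate of origin per tube and passes
    :func:`validate_measurement_sheet`.
    """
    report = validate_plate_sheet(sheet)
    if validate and not report.ok:
        raise ValidationError(report)
    occupied_rows: list[str] = report.info["occupied_rows"]
    holders_needed: int = report.info["holders_needed"]
    if len(holder_uuids) < holders_needed:
        raise CapacityError(
            f"{holders_needed} holders required, only {len(holder_uuids)} provided"
        )
    if len(set(holder_uuids)) != len(holder_uuids):
        raise DomainError("holder_uuids contains duplicates")

    row_ordinal = {wrow: k for k, wrow in enumerate(occupied_rows)}
    holder_names = [f"{sheet.plate_id}{chr(ord('A') + h)}" for h in range(holders_needed)]

    by_well: list[tuple[int, int, PlateRow]] = []
    for r in sheet.rows:
        wrow, wcol = parse_well(r.well)
        if wcol in SAMPLE_COLUMNS:
            by_well.append((row_ordinal[wrow], wcol, r))
    by_well.sort(key=lambda t: (t[0], t[1]))

    steps: list[TransferStep] = []
    mrows: list[MeasurementRow] = []
    for k, col, r in by_well:
        holder_idx = k // 2
        position = (k % 2) * POSITIONS_PER_ROW + col
        for src, vol in r.mixing_sources:
            steps.append(TransferStep(str(src).upper(), float(vol), dest_well=r.well.upper()))
        steps.append(TransferStep(
            r.well.upper(), float(r.volume_ul),
            holder_uuid=holder_uuids[holder_idx], position=position,
            mix=bool(r.mixing_sources),
        ))
        mrows.append(MeasurementRow(
            holder_name=holder_names[holder_idx],
            position=position,
            sample_name=r.sample_name,
            role="sample" if r.buffer_ref is not None else "buffer",
            buffer_ref=r.buffer_ref,
            volume_ul=float(r.volume_ul),
            plate_origin=f"{sheet.plate_id}:{r.well.upper()}",
        ))

    protocol = TransferProtocol(
        steps,
        labware={
            "plates": [sheet.plate_id],
            "holder_adaptors": math.ceil(holders_needed / HOLDERS_PER_ADAPTOR),
            "holders": list(holder_uuids[:holders_needed]),
            "tip_racks": report.info["tip_racks_needed"],
        },
    )
    msheet = MeasurementSheet(
        mrows,
        proposal_id=sheet.proposal_id,
        saf_id=sheet.saf_id,
        holder_uuids=dict(zip(holder_names, holder_uuids[:holders_needed])),
    )
    return protocol, msheet


@dataclass
class DeckLayout:
    """Slot assignment for one OT2 transfer run (slot 12 is the trash)."""

    slots: dict[int, str]
    n_plates: int
    n_holders: int
    tip_racks: int
    max_feasible_holders: int

    @property
    def empty(self) -> bool:
        return self.n_plates == 0 and self.n_holders == 0 and self.tip_racks == 0


def _max_feasible_holders(n_plates: int, tip_racks: int) -> int:
    free = USABLE_DECK_SLOTS - n_plates - tip_racks
    return max(0, min(MAX_HOLDERS_PER_RUN, HOLDERS_PER_ADAPTOR * free))


def plan_deck(n_plates: int, n_holders: int, tip_racks_needed: int) -> DeckLayout:
    """Allocate the 12 OT2 deck slots for one transfer run.

    One slot is the fixed trash; plates, three-holder adaptors and tip
    racks share the remaining 11.  Per-run operational caps: at most two
    full plates and 12 holders.  An infeasible demand raises
    :class:`CapacityError` whose ``suggestion`` lists a feasible split
    into multiple runs.
    """
    if min(n_plates, n_holders, tip_racks_needed) < 0:
        raise DomainError("counts must be non-negative")
    adaptors = math.ceil(n_holders / HOLDERS_PER_ADAPTOR)
    needed = n_plates + adaptors + tip_racks_needed
    if n_plates > MAX_PLATES_PER_RUN or n_holders > MAX_HOLDERS_PER_RUN or needed > USABLE_DECK_SLOTS:
        runs = []
        plates_left, holders_left = n_plates, n_holders
        while plates_left > 0 or holders_left > 0:
            p = min(plates_left, MAX_PLATES_PER_RUN)
            h = min(holders_left, MAX_HOLDERS_PER_RUN, _max_feasible_holders(p, tip_racks_needed))
            if p == 0 and h == 0:
                break
            runs.append({"plates": p, "holders": h})
            plates_left -= p
            holders_left -= h
        raise CapacityError(
            f"demand ({n_plates} plates, {n_holders} holders, "
            f"{tip_racks_needed} tip racks) exceeds one transfer run "
            f"(caps: {MAX_PLATES_PER_RUN} plates, {MAX_HOLDERS_PER_RUN} holders, "
            f"{USABLE_DECK_SLOTS} usable slots); split into runs",
            suggestion=runs,
        )
    slots: dict[int, str] = {}
    slot = 1
    for i in range(n_plates):
        slots[slot] = f"plate_{i + 1}"
        slot += 1
    for i in range(adaptors):
        slots[slot] = f"holder_adaptor_{i + 1}"
        slot += 1
    for i in range(tip_racks_needed):
        slots[slot] = f"tip_rack_{i + 1}"
        slot += 1
    slots[DECK_SLOTS] = "trash"
    return DeckLayout(
        slots, n_plates, n_holders, tip_racks_needed,
        max_feasible_holders=_max_feasible_holders(n_plates, tip_racks_needed),
    )


# ---------------------------------------------------------------------------
# holder manifest


@dataclass
class HolderManifest:
    """Collection-time correlation holder UUID <-> sheet <-> owner,
    grouped by owner (proposal, SAF)."""

    groups: dict[tuple[str, str], list[dict]]

    @property
    def n_holders(self) -> int:
        return sum(len(v) for v in self.groups.values())


def compile_manifest(holder_uuid_list: list[str], registry: dict[str, dict]) -> HolderManifest:
    """Verify that sample information exists for every holder in a run
    and group it by owner.

    ``registry`` maps holder UUID to a dict with keys ``owner``
    (``(proposal, saf)``), ``sheet`` (:class:`MeasurementSheet`) and
    optionally ``origin``.  Raises on duplicate or unknown UUIDs and
    when the run exceeds the storage unit (20 holders / 360 samples).
    """
    if len(set(holder_uuid_list)) != len(holder_uuid_list):
        raise DomainError("duplicate holder UUID in collection list")
    if len(holder_uuid_list) > STORAGE_HOLDERS:
        raise CapacityError(
            f"{len(holder_uuid_list)} holders exceed the storage capacity of "
            f"{STORAGE_HOLDERS} holders ({STORAGE_SAMPLES} samples)"
        )
    groups: dict[tuple[str, str], list[dict]] = {}
    total_tubes = 0
    for hu in holder_uuid_list:
        if hu not in registry:
            raise UnknownHolderError(
                f"no sample information registered for holder {hu}"
            )
        entry = registry[hu]
        owner = tuple(entry["owner"])
        sheet: MeasurementSheet = entry["sheet"]
        tubes = sum(1 for r in sheet.rows if sheet.holder_uuids.get(r.holder_name) == hu)
        total_tubes += tubes
        groups.setdefault(owner, []).append({
            "holder_uuid": hu,
            "owner": owner,
            "sheet": sheet,
            "origin": entry.get("origin"),
            "n_tubes": tubes,
        })
    if total_tubes > STORAGE_SAMPLES:
        raise CapacityError(
            f"{total_tubes} tubes exceed the storage capacity of {STORAGE_SAMPLES}"
        )
    return HolderManifest(groups)


# ---------------------------------------------------------------------------
# sheet I/O (CSV with '#' metadata headers, or XLSX with a 'meta' sheet)

_MEAS_COLS = ["holder_name", "position", "sample_name", "role", "buffer_ref",
              "volume_ul", "plate_origin"]
_PLATE_COLS = ["well", "sample_name", "volume_ul", "buffer_ref", "mixing_sources"]


def _encode_mix(sources: list[tuple[str, float]]) -> str:
    return ";".join(f"{w}:{v:g}" for w, v in sources)


def _decode_mix(text) -> list[tuple[str, float]]:
    if text is None or (isinstance(text, float) and math.isnan(text)) or str(text).strip() == "":
        return []
    out = []
    for part in str(text).split(";"):
        well, _, vol = part.partition(":")
        out.append((well.strip(), float(vol or 0)))
    return out


def _read_table(path) -> tuple["pandas.DataFrame", dict]:  # noqa: F821
    import pandas as pd

    path = Path(path)
    meta: dict = {}
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, sheet_name=0)
        try:
            mdf = pd.read_excel(path, sheet_name="meta", header=None, dtype=str)
            meta = {str(k): str(v) for k, v in zip(mdf[0], mdf[1])}
        except (ValueError, KeyError):
            meta = {}
    else:
        with path.open() as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, val = line.lstrip("#").partition(":")
                if _:
                    meta[key.strip()] = val.strip()
        df = pd.read_csv(path, comment="#")
    return df, meta


def _write_table(df, meta: dict, path) -> None:
    import pandas as pd

    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        with pd.ExcelWriter(path, engine="openpyxl") as xl:
            df.to_excel(xl, sheet_name="sheet", index=False)
            pd.DataFrame(list(meta.items())).to_excel(
                xl, sheet_name="meta", index=False, header=False)
    else:
        with path.open("w") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}: {v}\n")
            df.to_csv(fh, index=False)


def _opt(value):
    import pandas as pd

    if value is None or (isinstance(value, float) and math.isnan(value)) or pd.isna(value):
        return None
    return value


def read_measurement_sheet(path) -> MeasurementSheet:
    df, meta = _read_table(path)
    rows = []
    for _, rec in df.iterrows():
        rows.append(MeasurementRow(
            holder_name=str(rec["holder_name"]),
            position=int(rec["position"]),
            sample_name=str(rec["sample_name"]),
            role=str(rec["role"]),
            buffer_ref=None if _opt(rec.get("buffer_ref")) is None else str(rec["buffer_ref"]),
            volume_ul=None if _opt(rec.get("volume_ul")) is None else float(rec["volume_ul"]),
            plate_origin=None if _opt(rec.get("plate_origin")) is None else str(rec["plate_origin"]),
        ))
    uuids = json.loads(meta["holder_uuids"]) if "holder_uuids" in meta else {}
    return MeasurementSheet(rows, meta.get("proposal_id"), meta.get("saf_id"), uuids)


def write_measurement_sheet(sheet: MeasurementSheet, path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [[r.holder_name, r.position, r.sample_name, r.role, r.buffer_ref,
          r.volume_ul, r.plate_origin] for r in sheet.rows],
        columns=_MEAS_COLS,
    )
    meta = {}
    if sheet.proposal_id:
        meta["proposal_id"] = sheet.proposal_id
    if sheet.saf_id:
        meta["saf_id"] = sheet.saf_id
    if sheet.holder_uuids:
        meta["holder_uuids"] = json.dumps(sheet.holder_uuids)
    _write_table(df, meta, path)


def read_plate_sheet(path) -> PlateSheet:
    df, meta = _read_table(path)
    rows = []
    for _, rec in df.iterrows():
        rows.append(PlateRow(
            well=str(rec["well"]),
            sample_name=str(rec["sample_name"]),
            volume_ul=float(rec["volume_ul"]),
            buffer_ref=None if _opt(rec.get("buffer_ref")) is None else str(rec["buffer_ref"]),
            mixing_sources=_decode_mix(rec.get("mixing_sources")),
        ))
    return PlateSheet(rows, meta.get("proposal_id"), meta.get("saf_id"),
                      meta.get("plate_id", "01"))


def write_plate_sheet(sheet: PlateSheet, path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [[r.well, r.sample_name, r.volume_ul, r.buffer_ref, _encode_mix(r.mixing_sources)]
         for r in sheet.rows],
        columns=_PLATE_COLS,
    )
    meta = {"plate_id": sheet.plate_id}
    if sheet.proposal_id:
        meta["proposal_id"] = sheet.proposal_id
    if sheet.saf_id:
        meta["saf_id"] = sheet.saf_id
    _write_table(df, meta, path)
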