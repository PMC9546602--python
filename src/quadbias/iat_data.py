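"""Data model and I/O for trial-level IAT sessions.

The atomic unit is a :class:`SessionRecord`: one participant's ordered
trials from a seven-block IAT plus group metadata and optional feeling
thermometers.  Sessions reduce to a :class:`ResponseCountTable`, the
correct/incorrect counts per (stimulus category x pairing) cell that the
Quad likelihood consumes.

Pairing is stored per trial as a *semantic* label — which target group
currently shares a response key with "pleasant" — never as a physical key
side, because the order of the critical block pairs is randomized between
participants.
"""

from __future__ import annotations

import csv
import enum
import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "StimulusCategory",
    "Pairing",
    "BlockOrder",
    "StatusRole",
    "TrialRecord",
    "SessionRecord",
    "ResponseCountTable",
    "BlockDesign",
    "DESIGN_STANDARD",
    "DESIGN_SHORT_CRITICAL",
    "FormatError",
    "ValidationError",
    "read_sessions",
    "write_sessions",
    "tabulate_counts",
    "validate_design",
    "CELLS",
]


class StimulusCategory(str, enum.Enum):
    INGROUP_TARGET = "ingroup_target"
    OUTGROUP_TARGET = "outgroup_target"
    PLEASANT_WORD = "pleasant_word"
    UNPLEASANT_WORD = "unpleasant_word"


class Pairing(str, enum.Enum):
    """Which target group shares a key with "pleasant" in a critical block."""

    INGROUP_PLEASANT = "ingroup_pleasant_shared"
    OUTGROUP_PLEASANT = "outgroup_pleasant_shared"


class BlockOrder(str, enum.Enum):
    INGROUP_PLEASANT_FIRST = "ingroup_pleasant_first"
    OUTGROUP_PLEASANT_FIRST = "outgroup_pleasant_first"


class StatusRole(str, enum.Enum):
    LOWER = "lower"
    HIGHER = "higher"


#: The 8 cells of the Quad likelihood, in canonical order.
CELLS: tuple[tuple[StimulusCategory, Pairing], ...] = tuple(
    (cat, pairing) for cat in StimulusCategory for pairing in Pairing
)

CRITICAL_BLOCKS = frozenset({3, 4, 6, 7})
PRACTICE_BLOCKS = frozenset({1, 2, 5})


class FormatError(ValueError):
    """A file is structurally unreadable (missing columns, bad header)."""


class ValidationError(ValueError):
    """A row or record violates a domain invariant."""


@dataclass(frozen=True)
class TrialRecord:
    block_index: int
    trial_index: int
    stimulus_category: StimulusCategory
    pairing: Pairing | None
    first_response_correct: bool
    latency_ms: float

    def __post_init__(self) -> None:
        if not 1 <= self.block_index <= 7:
            raise ValidationError(f"block_index must be 1-7, got {self.block_index}")
        if self.trial_index < 1:
            raise ValidationError(f"trial_index must be >= 1, got {self.trial_index}")
        if not self.latency_ms > 0:
            raise ValidationError(f"latency_ms must be positive, got {self.latency_ms}")
        if self.block_index in CRITICAL_BLOCKS and self.pairing is None:
            raise ValidationError(
                f"critical block {self.block_index} trial requires a pairing"
            )
        if self.block_index in PRACTICE_BLOCKS and self.pairing is not None:
            raise ValidationError(
                f"practice block {self.block_index} trial must not carry a pairing"
            )

    @property
    def is_critical(self) -> bool:
        return self.block_index in CRITICAL_BLOCKS


@dataclass(frozen=True)
class BlockDesign:
    """Expected number of trials per block, indexed 1..7."""

    block_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.block_lengths) != 7:
            raise ValueError("a block design names exactly 7 blocks")


#: Standard Project-Implicit-style design: 20/20/20/40/20/20/40.
DESIGN_STANDARD = BlockDesign((20, 20, 20, 40, 20, 20, 40))
#: Variant with 20-trial critical blocks throughout (confirmatory sexuality IATs).
DESIGN_SHORT_CRITICAL = BlockDesign((20, 20, 20, 20, 20, 20, 20))


@dataclass
class SessionRecord:
    participant_id: str
    group_membership: str
    status_role: StatusRole
    iat_variant: str
    critical_block_order: BlockOrder
    trials: list[TrialRecord] = field(default_factory=list)
    gender: str | None = None
    thermometer_ingroup: int | None = None
    thermometer_outgroup: int | None = None

    def __post_init__(self) -> None:
        for name in ("thermometer_ingroup", "thermometer_outgroup"):
            value = getattr(self, name)
            if value is not None and not 0 <= value <= 10:
                raise ValidationError(f"{name} must be in 0-10, got {value}")

    def critical_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.is_critical]

    def trials_in_pairing(self, pairing: Pairing) -> list[TrialRecord]:
        return [t for t in self.critical_trials() if t.pairing is pairing]


@dataclass(frozen=True)
class ResponseCountTable:
    """Correct/incorrect counts for the 8 (category, pairing) cells."""

    counts: Mapping[tuple[StimulusCategory, Pairing], tuple[int, int]]

    def __post_init__(self) -> None:
        missing = [c for c in CELLS if c not in self.counts]
        if missing:
            raise ValidationError(f"count table missing cells: {missing}")
        for cell, (nc, ni) in self.counts.items():
            if nc < 0 or ni < 0:
                raise ValidationError(f"negative count in cell {cell}")

    @property
    def n_total(self) -> int:
        return sum(nc + ni for nc, ni in self.counts.values())

    def cell(self, category: StimulusCategory, pairing: Pairing) -> tuple[int, int]:
        return self.counts[(category, pairing)]

    def as_arrays(self):
        """(n_correct, n_incorrect) arrays in canonical :data:`CELLS` order."""
        import numpy as np

        nc = np.array([self.counts[c][0] for c in CELLS], dtype=float)
        ni = np.array([self.counts[c][1] for c in CELLS], dtype=float)
        return nc, ni

    def __add__(self, other: "ResponseCountTable") -> "ResponseCountTable":
        merged = {
            c: (
                self.counts[c][0] + other.counts[c][0],
                self.counts[c][1] + other.counts[c][1],
            )
            for c in CELLS
        }
        return ResponseCountTable(merged)


# ---------------------------------------------------------------------------
# I/O

#: Canonical column names for trial files.
DEFAULT_COLUMNS = {
    "participant_id": "participant_id",
    "block": "block",
    "trial": "trial",
    "category": "category",
    "pairing": "pairing",
    "correct": "correct",
    "latency_ms": "latency_ms",
    # session-level metadata, repeated per row
    "group": "group",
    "status": "status",
    "variant": "variant",
    "block_order": "block_order",
    "gender": "gender",
    "thermo_ingroup": "thermo_ingroup",
    "thermo_outgroup": "thermo_outgroup",
}

_TRUE_TOKENS = {"1", "true", "t", "yes", "y"}
_FALSE_TOKENS = {"0", "false", "f", "no", "n"}
_MISSING_TOKENS = {"", "na", "nan", "none", "null"}


def _parse_bool(token: str, row_no: int) -> bool:
    t = token.strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    raise ValidationError(f"row {row_no}: unparseable correct flag {token!r}")


def _sniff_delimiter(sample: str) -> str:
    return "\t" if sample.count("\t") >= sample.count(",") else ","


def read_sessions(
    path,
    column_map: Mapping[str, str] | None = None,
) -> list[SessionRecord]:
    """Read a delimited trial file into sessions grouped by participant.

    The file is UTF-8 text, comma- or tab-delimited (auto-detected), with a
    header row.  ``column_map`` maps the logical field names of
    :data:`DEFAULT_COLUMNS` to the file's actual column names; omitted
    entries fall back to the canonical names.  Trials are ordered by
    (block, trial) within each session; unparseable rows raise a
    :class:`ValidationError` naming the row number.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)

    with open(path, "r", encoding="utf-8", newline="") as fh:
        text = fh.read()
    delim = _sniff_delimiter(text.splitlines()[0] if text else "")
    reader = csv.DictReader(io.StringIO(text), delimiter=delim)
    if reader.fieldnames is None:
        raise FormatError(f"{path}: empty file, header row required")
    mandatory = ["participant_id", "block", "trial", "category", "correct", "latency_ms"]
    for logical in mandatory:
        if cols[logical] not in reader.fieldnames:
            raise FormatError(f"{path}: missing mandatory column {cols[logical]!r}")

    by_pid: dict[str, dict] = {}
    for row_no, row in enumerate(reader, start=2):  # header is line 1
        pid = row[cols["participant_id"]].strip()
        try:
            block = int(row[cols["block"]])
            trial = int(row[cols["trial"]])
            cat_token = row[cols["category"]].strip()
            try:
                category = StimulusCategory(cat_token)
            except ValueError:
                raise ValidationError(f"unknown category token {cat_token!r}")
            pairing_token = (row.get(cols["pairing"]) or "").strip()
            pairing = (
                None
                if pairing_token.lower() in _MISSING_TOKENS
                else Pairing(pairing_token)
            )
            latency = float(row[cols["latency_ms"]])
            correct = _parse_bool(row[cols["correct"]], row_no)
            rec = TrialRecord(block, trial, category, pairing, correct, latency)
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: row {row_no}: {exc}") from exc

        entry = by_pid.setdefault(pid, {"trials": [], "meta": {}})
        entry["trials"].append(rec)
        if not entry["meta"]:
            meta = {}
            for logical in ("group", "status", "variant", "block_order", "gender",
                            "thermo_ingroup", "thermo_outgroup"):
                token = (row.get(cols[logical]) or "").strip()
                meta[logical] = None if token.lower() in _MISSING_TOKENS else token
            entry["meta"] = meta

    sessions = []
    for pid, entry in by_pid.items():
        meta = entry["meta"]
        trials = sorted(entry["trials"], key=lambda t: (t.block_index, t.trial_index))
        order_token = meta.get("block_order")
        if order_token is None:
            # derive from the first critical trial seen
            first_crit = next((t for t in trials if t.is_critical), None)
            if first_crit is None or first_crit.pairing is None:
                order = BlockOrder.INGROUP_PLEASANT_FIRST
            else:
                order = (
                    BlockOrder.INGROUP_PLEASANT_FIRST
                    if first_crit.pairing is Pairing.INGROUP_PLEASANT
                    else BlockOrder.OUTGROUP_PLEASANT_FIRST
                )
        else:
            order = BlockOrder(order_token)
        sessions.append(
            SessionRecord(
                participant_id=pid,
                group_membership=meta.get("group") or "unknown",
                status_role=StatusRole(meta.get("status") or "lower"),
                iat_variant=meta.get("variant") or "unknown",
                critical_block_order=order,
                trials=trials,
                gender=meta.get("gender"),
                thermometer_ingroup=(
                    int(meta["thermo_ingroup"]) if meta.get("thermo_ingroup") else None
                ),
                thermometer_outgroup=(
                    int(meta["thermo_outgroup"]) if meta.get("thermo_outgroup") else None
                ),
            )
        )
    return sessions


def write_sessions(sessions: Sequence[SessionRecord], path, delimiter: str = ",") -> None:
    """Write sessions as a delimited trial file readable by :func:`read_sessions`."""
    header = list(DEFAULT_COLUMNS.values())
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(header)
        for s in sessions:
            for t in s.trials:
                writer.writerow(
                    [
                        s.participant_id,
                        t.block_index,
                        t.trial_index,
                        t.stimulus_category.value,
                        t.pairing.value if t.pairing else "",
                        int(t.first_response_correct),
                        repr(t.latency_ms),
                        s.group_membership,
                        s.status_role.value,
                        s.iat_variant,
                        s.critical_block_order.value,
                        s.gender or "",
                        "" if s.thermometer_ingroup is None else s.thermometer_ingroup,
                        "" if s.thermometer_outgroup is None else s.thermometer_outgroup,
                    ]
                )


def tabulate_counts(
    sessions: Iterable[SessionRecord] | SessionRecord,
    critical_only: bool = True,
) -> ResponseCountTable:
    """Aggregate trials into the 8-cell correct/incorrect count table.

    With several sessions the result is the cell-wise sum over sessions
    (group-level aggregation).  Practice-block trials are dropped when
    ``critical_only`` is set; they carry no pairing and cannot enter the
    table otherwise.
    """
    if isinstance(sessions, SessionRecord):
        sessions = [sessions]
    counts = {c: [0, 0] for c in CELLS}
    for s in sessions:
        for t in s.trials:
            if not t.is_critical:
                if critical_only:
                    continue
                raise ValidationError(
                    f"participant {s.participant_id}: practice trial has no pairing; "
                    "tabulation requires critical_only=True"
                )
            if t.pairing is None:
                raise ValidationError(
                    f"participant {s.participant_id}: critical trial without pairing"
                )
            cell = counts[(t.stimulus_category, t.pairing)]
            cell[0 if t.first_response_correct else 1] += 1
    return ResponseCountTable({c: (v[0], v[1]) for c, v in counts.items()})


def write_counts(table: ResponseCountTable, path, delimiter: str = ",") -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["category", "pairing", "n_correct", "n_incorrect"])
        for (cat, pairing) in CELLS:
            nc, ni = table.counts[(cat, pairing)]
            writer.writerow([cat.value, pairing.value, nc, ni])


def read_counts(path) -> ResponseCountTable:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        delim = _sniff_delimiter(fh.readline())
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        counts = {}
        for row in reader:
            cell = (StimulusCategory(row["category"]), Pairing(row["pairing"]))
            counts[cell] = (int(row["n_correct"]), int(row["n_incorrect"]))
    return ResponseCountTable(counts)


def validate_design(
    session: SessionRecord, design: BlockDesign = DESIGN_STANDARD
) -> list[str]:
    """Check block lengths and pairing assignments against a declared design.

    Returns a list of human-readable violations; an empty list means the
    session conforms.  Nothing is raised.
    """
    violations: list[str] = []
    by_block: dict[int, list[TrialRecord]] = {}
    for t in session.trials:
        by_block.setdefault(t.block_index, []).append(t)

    for block in range(1, 8):
        expected = design.block_lengths[block - 1]
        got = len(by_block.get(block, []))
        if block not in by_block:
            violations.append(f"block {block}: missing (expected {expected} trials)")
        elif got != expected:
            violations.append(f"block {block}: {got} trials, expected {expected}")

    first = (
        Pairing.INGROUP_PLEASANT
        if session.critical_block_order is BlockOrder.INGROUP_PLEASANT_FIRST
        else Pairing.OUTGROUP_PLEASANT
    )
    second = (
        Pairing.OUTGROUP_PLEASANT
        if first is Pairing.INGROUP_PLEASANT
        else Pairing.INGROUP_PLEASANT
    )
    expected_pairing = {3: first, 4: first, 6: second, 7: second}
    for block, pairing in expected_pairing.items():
        for t in by_block.get(block, []):
            if t.pairing is not pairing:
                violations.append(
                    f"block {block}: pairing {t.pairing and t.pairing.value} "
                    f"inconsistent with declared order (expected {pairing.value})"
                )
                break
    seen_pairings = {t.pairing for t in session.critical_trials()}
    for pairing in Pairing:
        if pairing not in seen_pairings:
            violations.append(f"pairing {pairing.value} absent from critical blocks")
    return violations
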