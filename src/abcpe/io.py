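"""Sweep and cohort I/O.

Data containers for longitudinal two-port transmission measurements
(|S21| amplitude in dB versus frequency in Hz) plus readers/writers for
the two interchange formats a VNA workflow produces:

* Touchstone v1 ``.s2p`` files, one sweep per file (formats RI, MA, DB);
* a long-format cohort CSV (``subject,group,time_h,freq_hz,amp_db``)
  with an optional JSON manifest mapping subject -> group.

Frequencies are stored internally in Hz; amplitudes in dB.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SweepRecord",
    "CohortDataset",
    "TimeWindow",
    "DEFAULT_WINDOWS",
    "ValidationError",
    "TouchstoneFormatError",
    "read_touchstone",
    "write_touchstone",
    "read_cohort_csv",
    "write_cohort_csv",
]

EXPERIMENTAL = "Exp"
CONTROL = "Con"

#: dB written into the unused S-parameter slots of an exported .s2p file.
PLACEHOLDER_DB = -100.0


class ValidationError(ValueError):
    """Input data violates a structural invariant."""


class TouchstoneFormatError(ValidationError):
    """Malformed Touchstone file (option line, port count, grid)."""


@dataclass(frozen=True)
class SweepRecord:
    """One amplitude-frequency sweep of a subject at one time point.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier.
    time_h : float
        Hours since the first measurement; the ``time_h == 0`` record is
        the baseline against which characteristic parameters are formed.
    freq_hz : ndarray
        Strictly increasing frequency grid in Hz.
    amp_db : ndarray
        |S21| transmission amplitude in dB, one value per grid point.
    """

    subject_id: str
    time_h: float
    freq_hz: np.ndarray
    amp_db: np.ndarray

    def __post_init__(self) -> None:
        freq = np.asarray(self.freq_hz, dtype=float)
        amp = np.asarray(self.amp_db, dtype=float)
        object.__setattr__(self, "freq_hz", freq)
        object.__setattr__(self, "amp_db", amp)
        if freq.ndim != 1 or amp.ndim != 1:
            raise ValidationError("freq_hz and amp_db must be 1-D")
        if freq.size != amp.size:
            raise ValidationError(
                f"grid/amplitude length mismatch: {freq.size} vs {amp.size}"
            )
        if freq.size < 8:
            raise ValidationError(f"sweep needs >= 8 points, got {freq.size}")
        if not np.all(np.diff(freq) > 0):
            raise ValidationError("frequency grid must be strictly increasing")
        if not np.all(np.isfinite(amp)):
            raise ValidationError("amplitude values must be finite")
        if not np.all(np.isfinite(freq)):
            raise ValidationError("frequency values must be finite")
        if self.time_h < 0:
            raise ValidationError(f"time_h must be >= 0, got {self.time_h}")

    @property
    def n_points(self) -> int:
        return int(self.freq_hz.size)

    @property
    def is_baseline(self) -> bool:
        return self.time_h == 0


@dataclass(frozen=True)
class TimeWindow:
    """Half-open-on-the-left time window (lo, hi] in hours."""

    name: str
    lo_h: float
    hi_h: float

    def contains(self, time_h: float) -> bool:
        return self.lo_h < time_h <= self.hi_h


#: Analysis windows. t0 is excluded everywhere: all characteristic
#: parameters are identically zero there by construction. A record at
#: exactly 6 h belongs to the acute window.
DEFAULT_WINDOWS: dict[str, TimeWindow] = {
    "full": TimeWindow("full", 0.0, 24.0),
    "early": TimeWindow("early", 0.0, 1.0),
    "acute": TimeWindow("acute", 0.0, 6.0),
    "chronic": TimeWindow("chronic", 6.0, 24.0),
}


@dataclass
class CohortDataset:
    """Labeled longitudinal cohort of sweep records.

    Every subject must have exactly one baseline (``time_h == 0``) record
    and all records of one subject must share an identical frequency grid.
    """

    records: list[SweepRecord]
    group_of: dict[str, str]
    windows: dict[str, TimeWindow] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS)
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        by_subject: dict[str, list[SweepRecord]] = {}
        for rec in self.records:
            by_subject.setdefault(rec.subject_id, []).append(rec)
        for sid, recs in by_subject.items():
            n_base = sum(1 for r in recs if r.is_baseline)
            if n_base == 0:
                raise ValidationError(f"subject {sid!r} has no time_h == 0 baseline record")
            if n_base > 1:
                raise ValidationError(f"subject {sid!r} has {n_base} baseline records")
            grid = recs[0].freq_hz
            for r in recs[1:]:
                if r.freq_hz.size != grid.size or not np.array_equal(r.freq_hz, grid):
                    raise ValidationError(
                        f"subject {sid!r}: frequency grid at t={r.time_h} h "
                        "differs from the subject's baseline grid"
                    )
            if sid not in self.group_of:
                raise ValidationError(f"subject {sid!r} missing from group map")
            if self.group_of[sid] not in (EXPERIMENTAL, CONTROL):
                raise ValidationError(
                    f"subject {sid!r} has unknown group {self.group_of[sid]!r}"
                )

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.subject_id, None)
        return sorted(seen)

    def records_of(self, subject_id: str) -> list[SweepRecord]:
        recs = [r for r in self.records if r.subject_id == subject_id]
        return sorted(recs, key=lambda r: r.time_h)

    def baseline_of(self, subject_id: str) -> SweepRecord:
        for rec in self.records:
            if rec.subject_id == subject_id and rec.is_baseline:
                return rec
        raise KeyError(f"no baseline record for subject {subject_id!r}")

    def in_window(self, window: str | TimeWindow) -> list[SweepRecord]:
        win = self.windows[window] if isinstance(window, str) else window
        return [r for r in self.records if win.contains(r.time_h)]

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# Touchstone v1
# ---------------------------------------------------------------------------

_FREQ_UNITS = {"HZ": 1.0, "KHZ": 1e3, "MHZ": 1e6, "GHZ": 1e9}
_FORMATS = ("RI", "MA", "DB")


def _parse_option_line(line: str) -> tuple[float, str]:
    """Return (frequency multiplier to Hz, numeric format) from a '#' line."""
    tokens = line.lstrip("#").split()
    unit_mult = 1e9  # Touchstone default unit is GHz
    fmt = "MA"  # Touchstone default format
    i = 0
    while i < len(tokens):
        tok = tokens[i].upper()
        if tok in _FREQ_UNITS:
            unit_mult = _FREQ_UNITS[tok]
        elif tok in _FORMATS:
            fmt = tok
        elif tok == "S":
            pass
        elif tok == "R":
            i += 1  # skip reference resistance value
            if i >= len(tokens):
                raise TouchstoneFormatError("option line: 'R' without resistance value")
            try:
                float(tokens[i])
            except ValueError as exc:
                raise TouchstoneFormatError(
                    f"option line: bad resistance {tokens[i]!r}"
                ) from exc
        elif tok in ("Y", "Z", "H", "G"):
            raise TouchstoneFormatError(
                f"only S-parameter files are supported, got parameter type {tok!r}"
            )
        else:
            raise TouchstoneFormatError(f"unrecognized option-line token {tokens[i]!r}")
        i += 1
    return unit_mult, fmt


def _pair_to_db(x: float, y: float, fmt: str) -> float:
    """Convert one Touchstone value pair to amplitude in dB."""
    if fmt == "DB":
        return x
    if fmt == "MA":
        mag = x
    else:  # RI
        mag = math.hypot(x, y)
    if mag <= 0:
        raise TouchstoneFormatError("non-positive magnitude cannot be expressed in dB")
    return 20.0 * math.log10(mag)


def read_touchstone(
    path: str | Path,
    port_pair: tuple[int, int] = (2, 1),
    subject_id: str = "",
    time_h: float = 0.0,
) -> SweepRecord:
    """Read a 2-port Touchstone v1 file and return the requested S-parameter
    amplitude sweep (default S21) in dB with frequency in Hz.

    Parameters
    ----------
    path : path
        ``.s2p`` file with an option line such as ``# HZ S DB R 50``.
    port_pair : (int, int)
        (output port, input port); ``(2, 1)`` selects S21.
    subject_id, time_h :
        Metadata attached to the returned record (Touchstone files carry
        neither; callers supply them, e.g. from the file path).
    """
    path = Path(path)
    out_port, in_port = port_pair
    if out_port not in (1, 2) or in_port not in (1, 2):
        raise ValidationError(f"port_pair must index a 2-port network, got {port_pair}")
    # 2-port row order is S11 S21 S12 S22: pair index = 2*(in-1) + (out-1)
    pair_idx = 2 * (in_port - 1) + (out_port - 1)

    option: tuple[float, str] | None = None
    values: list[float] = []
    for raw in path.read_text().splitlines():
        line = raw.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("#"):
            if option is None:
                option = _parse_option_line(line)
            continue
        if option is None:
            raise TouchstoneFormatError(f"{path}: data before option line")
        for tok in line.split():
            try:
                values.append(float(tok))
            except ValueError as exc:
                raise TouchstoneFormatError(f"{path}: bad numeric token {tok!r}") from exc
    if option is None:
        raise TouchstoneFormatError(f"{path}: missing '#' option line")
    if not values:
        raise TouchstoneFormatError(f"{path}: no data")
    if len(values) % 9 != 0:
        raise TouchstoneFormatError(
            f"{path}: token count {len(values)} is not a multiple of 9; "
            "not a 2-port (freq + 4 complex pairs) file"
        )
    unit_mult, fmt = option
    data = np.asarray(values, dtype=float).reshape(-1, 9)
    freq_hz = data[:, 0] * unit_mult
    if not np.all(np.diff(freq_hz) > 0):
        raise ValidationError(f"{path}: frequency column is not strictly increasing")
    col = 1 + 2 * pair_idx
    amp_db = np.array(
        [_pair_to_db(x, y, fmt) for x, y in zip(data[:, col], data[:, col + 1])]
    )
    return SweepRecord(
        subject_id=subject_id or path.stem, time_h=time_h, freq_hz=freq_hz, amp_db=amp_db
    )


def write_touchstone(record: SweepRecord, path: str | Path) -> None:
    """Write ``record`` as a 2-port Touchstone v1 file, option line
    ``# HZ S DB R 50``, with the S21 slot carrying ``amp_db`` at phase 0.

    The other three S-parameters are placeholders (``-100`` dB, phase 0);
    only the S21 amplitude survives a round trip.
    """
    path = Path(path)
    lines = [
        f"! subject={record.subject_id} time_h={record.time_h}",
        "! S21 amplitude export; S11/S12/S22 are placeholders",
        "# HZ S DB R 50",
    ]
    for f, a in zip(record.freq_hz, record.amp_db):
        lines.append(
            f"{f:.6f} {PLACEHOLDER_DB:.1f} 0 {a:.9f} 0 {PLACEHOLDER_DB:.1f} 0 {PLACEHOLDER_DB:.1f} 0"
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Cohort CSV / manifest
# ---------------------------------------------------------------------------

_COHORT_COLUMNS = ["subject", "group", "time_h", "freq_hz", "amp_db"]


def read_cohort_csv(
    path: str | Path, windows: Mapping[str, TimeWindow] | None = None
) -> CohortDataset:
    """Read a long-format cohort table into a validated :class:`CohortDataset`.

    Expected header: ``subject,group,time_h,freq_hz,amp_db``; one row per
    (subject, time point, frequency).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    records: list[SweepRecord] = []
    group_of: dict[str, str] = {}
    for (sid, t), chunk in df.groupby(["subject", "time_h"], sort=True):
        chunk = chunk.sort_values("freq_hz")
        groups = chunk["group"].unique()
        if len(groups) != 1:
            raise ValidationError(f"subject {sid!r} has inconsistent group labels")
        group_of[str(sid)] = str(groups[0])
        records.append(
            SweepRecord(
                subject_id=str(sid),
                time_h=float(t),
                freq_hz=chunk["freq_hz"].to_numpy(dtype=float),
                amp_db=chunk["amp_db"].to_numpy(dtype=float),
            )
        )
    win = dict(windows) if windows is not None else dict(DEFAULT_WINDOWS)
    return CohortDataset(records=records, group_of=group_of, windows=win)


def write_cohort_csv(dataset: CohortDataset, path: str | Path) -> None:
    """Write a :class:`CohortDataset` as the long-format cohort table."""
    frames = []
    for rec in sorted(dataset.records, key=lambda r: (r.subject_id, r.time_h)):
        frames.append(
            pd.DataFrame(
                {
                    "subject": rec.subject_id,
                    "group": dataset.group_of[rec.subject_id],
                    "time_h": rec.time_h,
                    "freq_hz": rec.freq_hz,
                    "amp_db": rec.amp_db,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_manifest(dataset: CohortDataset, path: str | Path) -> None:
    """Write the subject -> group map as a JSON manifest."""
    Path(path).write_text(json.dumps(dataset.group_of, indent=2, sort_keys=True) + "\n")


def read_manifest(path: str | Path) -> dict[str, str]:
    mapping = json.loads(Path(path).read_text())
    if not isinstance(mapping, dict):
        raise ValidationError(f"{path}: manifest must be a JSON object")
    return {str(k): str(v) for k, v in mapping.items()}
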