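"""Amplitude-based characteristic parameter extraction (Ab-CPE).

From each |S21| amplitude-frequency sweep the algorithm extracts, relative
to the subject's own t0 baseline sweep:

* ``alpha`` — fractional change of the peak amplitude A (dB),
  ``(A_i - A0) / A0``;
* ``beta``  — fractional shift of the characteristic frequency f (peak
  location), ``(f_i - f0) / f0``;
* ``gamma`` — fractional change of the 3 dB (half-power) bandwidth F,
  ``(F_i - F0) / F0``;
* ``delta`` — fractional change of the mean amplitude over the *baseline*
  band F0, ``(a_i - a0) / a0``;
* ``rho``   — fractional change of the mean amplitude over the *current*
  band F_i ("followed" band), ``(a_i' - a0) / a0``.

All ratios are formed literally on the dB values. Since transmission
amplitudes are typically negative in dB, denominators are negative: an
amplitude *increase* therefore yields a *negative* alpha/delta/rho. The
downstream classification is sign-agnostic (scores are magnitudes after
mapping to [-1, 1]), so this sign convention is harmless, but consumers of
the raw parameters should keep it in mind.

The -3 dB band edges are located by linear interpolation between the
bracketing grid samples (an exact-equality crossing cannot occur on a
discrete grid); the point count N is taken on the raw grid. When the curve
re-crosses the level (side lobes), the crossings nearest the peak are used
so the band is the contiguous half-power region around the characteristic
frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CohortDataset, SweepRecord

__all__ = [
    "PARAMETER_NAMES",
    "Peak",
    "BandSummary",
    "BaselineReference",
    "CharacteristicParameters",
    "ExtractionError",
    "DegenerateCurveError",
    "BandIncompleteError",
    "DegenerateBaselineError",
    "find_peak",
    "find_3db_band",
    "band_mean",
    "extract_baseline",
    "extract_parameters",
    "extract_series",
    "parameters_to_frame",
]

#: Canonical ordering of the five characteristic parameters.
PARAMETER_NAMES = ("alpha", "beta", "gamma", "delta", "rho")

#: Half-power band definition: level is peak amplitude minus 3 dB.
BAND_DROP_DB = 3.0


class ExtractionError(ValueError):
    """Base class for extraction failures on a single sweep."""


class DegenerateCurveError(ExtractionError):
    """Sweep amplitude is flat; no peak is defined."""


class BandIncompleteError(ExtractionError):
    """The -3 dB level is not crossed on one side within the sweep range."""

    def __init__(self, side: str, message: str | None = None):
        self.side = side
        super().__init__(message or f"-{BAND_DROP_DB} dB level never crossed on the {side} side")


class DegenerateBaselineError(ExtractionError):
    """A baseline quantity used as a denominator is zero."""


@dataclass(frozen=True)
class Peak:
    """Sweep maximum: amplitude (dB), its frequency (Hz), grid index, and
    whether it sits on a sweep boundary (band extraction will fail there)."""

    amp_db: float
    freq_hz: float
    index: int
    at_boundary: bool


@dataclass(frozen=True)
class BandSummary:
    """3 dB (half-power) band around the sweep peak.

    ``f_lower_hz``/``f_upper_hz`` are the interpolated -3 dB crossings
    bracketing the peak; ``n_points`` counts raw grid points inside
    ``[f_lower_hz, f_upper_hz]``.
    """

    peak_amp_db: float
    peak_freq_hz: float
    f_lower_hz: float
    f_upper_hz: float
    n_points: int

    @property
    def bandwidth_hz(self) -> float:
        return self.f_upper_hz - self.f_lower_hz

    def __post_init__(self) -> None:
        if not (self.f_lower_hz < self.peak_freq_hz < self.f_upper_hz):
            raise ExtractionError("band edges must bracket the peak frequency")
        if self.n_points < 1:
            raise ExtractionError("band must contain at least one grid point")


@dataclass(frozen=True)
class BaselineReference:
    """Baseline (t0) band and its mean amplitude a0 over the N0 grid
    points inside [f0', f0'']."""

    band: BandSummary
    mean_amp_db: float


@dataclass(frozen=True)
class CharacteristicParameters:
    """The five-parameter vector of one measurement relative to baseline."""

    subject_id: str
    time_h: float
    alpha: float
    beta: float
    gamma: float
    delta: float
    rho: float

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma, self.delta, self.rho])


def find_peak(record: SweepRecord) -> Peak:
    """Locate the sweep maximum (the characteristic frequency).

    Ties are broken toward the lowest frequency; a peak at either grid
    boundary is returned with ``at_boundary=True``. A flat curve raises
    :class:`DegenerateCurveError`.
    """
    amp = record.amp_db
    if np.ptp(amp) == 0:
        raise DegenerateCurveError("flat amplitude curve has no defined peak")
    idx = int(np.argmax(amp))  # argmax returns the first (lowest-f) maximum
    return Peak(
        amp_db=float(amp[idx]),
        freq_hz=float(record.freq_hz[idx]),
        index=idx,
        at_boundary=idx == 0 or idx == amp.size - 1,
    )


def _cross_toward(
    freq: np.ndarray, amp: np.ndarray, peak_idx: int, level: float, step: int
) -> float:
    """Interpolated frequency of the innermost ``level`` crossing, walking
    from the peak in direction ``step`` (-1 lower side, +1 upper side)."""
    n = amp.size
    i = peak_idx
    while True:
        j = i + step
        if j < 0 or j >= n:
            raise BandIncompleteError("lower" if step < 0 else "upper")
        if amp[j] <= level:
            break
        i = j
    if amp[j] == level:
        return float(freq[j])
    # linear interpolation between inner point i (amp > level) and outer j
    frac = (amp[i] - level) / (amp[i] - amp[j])
    return float(freq[i] + frac * (freq[j] - freq[i]))


def find_3db_band(record: SweepRecord, peak: Peak | None = None) -> BandSummary:
    """Extract the half-power band around the peak.

    The band edges are the innermost crossings of ``peak - 3 dB`` below and
    above the peak frequency, each linearly interpolated between the
    bracketing grid samples. Raises :class:`BandIncompleteError` naming the
    side if the level is never reached within the sweep span.
    """
    if peak is None:
        peak = find_peak(record)
    level = peak.amp_db - BAND_DROP_DB
    f_lo = _cross_toward(record.freq_hz, record.amp_db, peak.index, level, -1)
    f_hi = _cross_toward(record.freq_hz, record.amp_db, peak.index, level, +1)
    n_points = int(np.count_nonzero((record.freq_hz >= f_lo) & (record.freq_hz <= f_hi)))
    return BandSummary(
        peak_amp_db=peak.amp_db,
        peak_freq_hz=peak.freq_hz,
        f_lower_hz=f_lo,
        f_upper_hz=f_hi,
        n_points=n_points,
    )


def band_mean(record: SweepRecord, f_lo: float, f_hi: float) -> float:
    """Arithmetic mean of ``amp_db`` over grid points with
    ``f_lo <= f_n <= f_hi`` (discrete mean, no interpolation)."""
    if not f_lo < f_hi:
        raise ValueError(f"need f_lo < f_hi, got [{f_lo}, {f_hi}]")
    mask = (record.freq_hz >= f_lo) & (record.freq_hz <= f_hi)
    if not mask.any():
        raise ExtractionError(f"no grid point inside band [{f_lo}, {f_hi}] Hz")
    return float(record.amp_db[mask].mean())


def extract_baseline(record: SweepRecord) -> BaselineReference:
    """Build the baseline reference (A0, f0, F0 band, N0, a0) from the
    t0 sweep. Requires ``record.time_h == 0``."""
    if record.time_h != 0:
        raise ValueError(
            f"baseline must be the time_h == 0 record, got time_h={record.time_h}"
        )
    band = find_3db_band(record)
    mean = band_mean(record, band.f_lower_hz, band.f_upper_hz)
    return BaselineReference(band=band, mean_amp_db=mean)


def extract_parameters(
    record: SweepRecord, baseline: BaselineReference
) -> CharacteristicParameters:
    """Compute the five characteristic parameters of one sweep relative to
    the baseline reference.

    ``delta`` averages the current sweep over the frozen baseline band F0;
    ``rho`` averages it over the sweep's own (followed) band F_i. Both are
    referenced to the baseline band mean a0.
    """
    b = baseline.band
    if b.peak_amp_db == 0 or baseline.mean_amp_db == 0:
        raise DegenerateBaselineError("baseline amplitude of exactly 0 dB cannot normalize")
    if b.peak_freq_hz == 0 or b.bandwidth_hz == 0:
        raise DegenerateBaselineError("zero baseline frequency or bandwidth")

    band_i = find_3db_band(record)
    a_i = band_mean(record, b.f_lower_hz, b.f_upper_hz)  # baseline band, current sweep
    a_i_followed = band_mean(record, band_i.f_lower_hz, band_i.f_upper_hz)

    return CharacteristicParameters(
        subject_id=record.subject_id,
        time_h=record.time_h,
        alpha=(band_i.peak_amp_db - b.peak_amp_db) / b.peak_amp_db,
        beta=(band_i.peak_freq_hz - b.peak_freq_hz) / b.peak_freq_hz,
        gamma=(band_i.bandwidth_hz - b.bandwidth_hz) / b.bandwidth_hz,
        delta=(a_i - baseline.mean_amp_db) / baseline.mean_amp_db,
        rho=(a_i_followed - baseline.mean_amp_db) / baseline.mean_amp_db,
    )


def extract_series(
    dataset: CohortDataset,
) -> tuple[list[CharacteristicParameters], list[dict]]:
    """Extract parameters for every non-baseline record of the cohort,
    each against its subject's own t0 baseline.

    Returns ``(parameters, errors)``: output is ordered deterministically
    by (subject, time); records that fail band extraction are collected
    into per-record error dicts rather than aborting the run.
    """
    params: list[CharacteristicParameters] = []
    errors: list[dict] = []
    for sid in dataset.subjects:
        recs = dataset.records_of(sid)
        try:
            baseline = extract_baseline(dataset.baseline_of(sid))
        except ExtractionError as exc:
            errors.append({"subject": sid, "time_h": 0.0, "error": str(exc)})
            continue
        for rec in recs:
            if rec.is_baseline:
                continue
            try:
                params.append(extract_parameters(rec, baseline))
            except ExtractionError as exc:
                errors.append({"subject": sid, "time_h": rec.time_h, "error": str(exc)})
    return params, errors


def parameters_to_frame(
    params: list[CharacteristicParameters], group_of: dict[str, str] | None = None
) -> pd.DataFrame:
    """Tabulate parameter vectors as a DataFrame
    (subject, [group,] time_h, alpha..rho)."""
    rows = []
    for p in params:
        row = {"subject": p.subject_id, "time_h": p.time_h}
        if group_of is not None:
            row["group"] = group_of[p.subject_id]
        row.update({name: getattr(p, name) for name in PARAMETER_NAMES})
        rows.append(row)
    cols = ["subject"] + (["group"] if group_of is not None else []) + ["time_h", *PARAMETER_NAMES]
    return pd.DataFrame(rows, columns=cols)
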