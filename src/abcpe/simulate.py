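"""Synthetic longitudinal cohort generator.

Emulates the measurement protocol of an electromagnetic-induction edema
monitoring study: a vector network analyzer sweeps 1-100 MHz over 1060
frequency points once every 30 minutes for 24 hours (49 sweeps per
subject), on an experimental group of 10 edema subjects and a control
group of 4 sham subjects.

Each subject's sensor-head coupling is modeled as a single resonance:
Lorentzian in linear power over a flat off-resonance floor,

    P(f) = P_floor + (P_peak - P_floor) / (1 + (2 (f - f_c) / W)^2),

returned as 10 log10 P so the emitted curve peaks at ``a_peak_db`` and
its half-power full width equals ``fwhm_hz`` (up to the vanishing floor
contribution). Edema is modeled as a slow drift of the resonance
descriptors (peak amplitude, characteristic frequency, half-power width):
piecewise-linear in time with a fast acute segment on (0, 6] h and a
slower chronic segment on (6, 24] h. Controls carry no drift, only noise.

Default effect sizes are generator choices, not measured values: the
endpoint fractional changes (amplitude +8 % of |A0| in dB, center
frequency +1.5 %, bandwidth +25 %, with 70 % of each realized by 6 h)
encode the qualitative fast-then-slow trajectory the method is designed
to detect. A ground-truth sidecar records the noise-free descriptors per
subject and time point so recovery can be audited.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import (
    CONTROL,
    EXPERIMENTAL,
    CohortDataset,
    SweepRecord,
    ValidationError,
    write_cohort_csv,
    write_manifest,
    write_touchstone,
)

__all__ = [
    "ResonanceModel",
    "EffectConfig",
    "TrajectoryModel",
    "GridSpec",
    "resonance_curve",
    "make_trajectory",
    "generate_cohort",
    "write_cohort_tree",
    "DEFAULT_GRID",
    "DEFAULT_EFFECT",
]


@dataclass(frozen=True)
class GridSpec:
    """Sweep frequency grid: ``n_points`` linearly spaced over
    [f_start_hz, f_stop_hz]."""

    f_start_hz: float = 1e6
    f_stop_hz: float = 100e6
    n_points: int = 1060

    def build(self) -> np.ndarray:
        if not (self.f_start_hz < self.f_stop_hz and self.n_points >= 8):
            raise ValidationError("grid needs f_start < f_stop and >= 8 points")
        return np.linspace(self.f_start_hz, self.f_stop_hz, self.n_points)

    @property
    def step_hz(self) -> float:
        return (self.f_stop_hz - self.f_start_hz) / (self.n_points - 1)


DEFAULT_GRID = GridSpec()


@dataclass(frozen=True)
class ResonanceModel:
    """Single-resonance transmission curve descriptors.

    a_peak_db : peak |S21| amplitude in dB (typically negative)
    f_center_hz : characteristic (resonance) frequency, Hz
    fwhm_hz : half-power full width, Hz
    floor_db : off-resonance floor amplitude, dB (must lie below the peak)
    """

    a_peak_db: float
    f_center_hz: float
    fwhm_hz: float
    floor_db: float = -60.0

    def __post_init__(self) -> None:
        if self.fwhm_hz <= 0:
            raise ValidationError(f"fwhm_hz must be > 0, got {self.fwhm_hz}")
        if self.a_peak_db <= self.floor_db:
            raise ValidationError("peak amplitude must exceed the floor")


def resonance_curve(model: ResonanceModel, grid: np.ndarray) -> np.ndarray:
    """Evaluate the Lorentzian-in-power resonance on a frequency grid,
    returning amplitude in dB.

    At ``f_center`` the curve equals ``a_peak_db`` exactly; at
    ``f_center +/- fwhm/2`` the power above the floor is halved (about
    -3.01 dB from the peak once the floor is negligible).
    """
    grid = np.asarray(grid, dtype=float)
    if not np.all(np.diff(grid) > 0):
        raise ValidationError("grid must be strictly increasing")
    if not (grid[0] <= model.f_center_hz <= grid[-1]):
        raise ValidationError(
            f"f_center {model.f_center_hz:.4g} Hz outside grid span "
            f"[{grid[0]:.4g}, {grid[-1]:.4g}]"
        )
    if model.fwhm_hz >= grid[-1] - grid[0]:
        raise ValidationError("fwhm wider than the grid span")
    p_peak = 10.0 ** (model.a_peak_db / 10.0)
    p_floor = 10.0 ** (model.floor_db / 10.0)
    x = 2.0 * (grid - model.f_center_hz) / model.fwhm_hz
    p = p_floor + (p_peak - p_floor) / (1.0 + x**2)
    return 10.0 * np.log10(p)


@dataclass(frozen=True)
class EffectConfig:
    """Endpoint effect sizes and noise levels of the edema trajectory.

    Fractional endpoint changes (at 24 h) for experimental subjects:
    ``amp_change`` is the dB increase of the peak as a fraction of |A0|;
    ``freq_change`` and ``fwhm_change`` are relative shifts of the center
    frequency and half-power width. ``acute_fraction`` of each change is
    realized by 6 h (the acute phase), the rest linearly over 6-24 h.

    Noise has two components with distinct roles. Per-time-point jitter of
    the three descriptors models physiological fluctuation (both groups;
    i.i.d. across time points, so control observations of one subject stay
    exchangeable with those of another). Per-point measurement noise on
    the emitted amplitudes models VNA trace noise and is kept an order of
    magnitude below the physiological jitter: noise on the single baseline
    sweep propagates into every one of a subject's parameter vectors as a
    shared offset, and if it rivaled the per-time-point jitter the cohort
    would cluster by subject rather than by class.
    """

    amp_change: float = 0.08
    freq_change: float = 0.015
    fwhm_change: float = 0.25
    acute_fraction: float = 0.70
    acute_end_h: float = 6.0
    total_h: float = 24.0
    amp_jitter_db: float = 0.05
    freq_jitter_hz: float = 3e5
    fwhm_jitter_hz: float = 3e5
    measurement_noise_db: float = 0.01

    def __post_init__(self) -> None:
        for name in ("amp_jitter_db", "freq_jitter_hz", "fwhm_jitter_hz",
                     "measurement_noise_db"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 <= self.acute_fraction <= 1:
            raise ValidationError("acute_fraction must be in [0, 1]")

    def zeroed(self) -> "EffectConfig":
        """Copy with all drift effects set to zero (null cohort)."""
        return EffectConfig(
            amp_change=0.0,
            freq_change=0.0,
            fwhm_change=0.0,
            acute_fraction=self.acute_fraction,
            acute_end_h=self.acute_end_h,
            total_h=self.total_h,
            amp_jitter_db=self.amp_jitter_db,
            freq_jitter_hz=self.freq_jitter_hz,
            fwhm_jitter_hz=self.fwhm_jitter_hz,
            measurement_noise_db=self.measurement_noise_db,
        )


DEFAULT_EFFECT = EffectConfig()


@dataclass(frozen=True)
class TrajectoryModel:
    """Noise-free drift of one subject's resonance descriptors over time.

    ``drift_fraction(t)`` rises piecewise-linearly from 0 at t=0 to
    ``acute_fraction`` at the acute-phase end and to 1 at ``total_h``;
    controls have identically zero drift.
    """

    group: str
    baseline: ResonanceModel
    config: EffectConfig

    def drift_fraction(self, time_h: float) -> float:
        if self.group == CONTROL:
            return 0.0
        c = self.config
        if time_h <= 0:
            return 0.0
        if time_h <= c.acute_end_h:
            return c.acute_fraction * time_h / c.acute_end_h
        if time_h >= c.total_h:
            return 1.0
        return c.acute_fraction + (1.0 - c.acute_fraction) * (
            (time_h - c.acute_end_h) / (c.total_h - c.acute_end_h)
        )

    def at(self, time_h: float) -> ResonanceModel:
        """Noise-free resonance descriptors at ``time_h``."""
        g = self.drift_fraction(time_h)
        b = self.baseline
        c = self.config
        return ResonanceModel(
            # amplitude drifts upward (toward 0 dB) by amp_change * |A0|
            a_peak_db=b.a_peak_db + g * c.amp_change * abs(b.a_peak_db),
            f_center_hz=b.f_center_hz * (1.0 + g * c.freq_change),
            fwhm_hz=b.fwhm_hz * (1.0 + g * c.fwhm_change),
            floor_db=b.floor_db,
        )


def make_trajectory(
    group: str,
    baseline: ResonanceModel,
    config: EffectConfig = DEFAULT_EFFECT,
) -> TrajectoryModel:
    """Build a subject trajectory. Controls get zero drift regardless of
    the configured effect sizes."""
    if group not in (EXPERIMENTAL, CONTROL):
        raise ValidationError(f"unknown group {group!r}")
    return TrajectoryModel(group=group, baseline=baseline, config=config)


#: Subject-to-subject variation of the baseline resonance (normal priors).
BASELINE_PRIORS = {
    "a_peak_db": (-15.0, 1.0),
    "f_center_mhz": (56.0, 1.5),
    "fwhm_mhz": (8.0, 0.8),
}


def _draw_baseline(rng: np.random.Generator) -> ResonanceModel:
    a = rng.normal(*BASELINE_PRIORS["a_peak_db"])
    f = rng.normal(*BASELINE_PRIORS["f_center_mhz"]) * 1e6
    w = abs(rng.normal(*BASELINE_PRIORS["fwhm_mhz"])) * 1e6
    return ResonanceModel(a_peak_db=a, f_center_hz=f, fwhm_hz=max(w, 1e6))


def generate_cohort(
    n_exp: int = 10,
    n_con: int = 4,
    n_timepoints: int = 49,
    grid_spec: GridSpec = DEFAULT_GRID,
    effect_config: EffectConfig = DEFAULT_EFFECT,
    seed: int = 0,
    return_truth: bool = False,
):
    """Simulate a full longitudinal cohort.

    Defaults reproduce the reference protocol: 10 experimental + 4 control
    subjects, 49 time points (0-24 h every 30 min), 1060-point sweeps over
    1-100 MHz. Per subject, a baseline resonance is drawn from
    :data:`BASELINE_PRIORS`, the group trajectory is applied, per-time
    descriptor jitter and per-point measurement noise are added, and one
    :class:`~abcpe.io.SweepRecord` is emitted per time point. Fully
    reproducible from ``seed`` (per-subject child seeds are spawned from
    the master ``numpy`` SeedSequence).

    Returns the :class:`~abcpe.io.CohortDataset`; with
    ``return_truth=True``, also a list of ground-truth dicts (noise-free
    descriptors per subject and time point).
    """
    if n_exp < 1 or n_con < 1:
        raise ValidationError("need at least one subject per group")
    if n_timepoints < 2:
        raise ValidationError("need at least baseline plus one follow-up")
    grid = grid_spec.build()
    times = np.linspace(0.0, effect_config.total_h, n_timepoints)

    subjects = [(f"Exp{i + 1:02d}", EXPERIMENTAL) for i in range(n_exp)]
    subjects += [(f"Con{i + 1:02d}", CONTROL) for i in range(n_con)]

    master = np.random.SeedSequence(seed)
    child_seqs = master.spawn(len(subjects))

    records: list[SweepRecord] = []
    group_of: dict[str, str] = {}
    truth: list[dict] = []
    for (sid, group), seq in zip(subjects, child_seqs):
        rng = np.random.default_rng(seq)
        group_of[sid] = group
        baseline = _draw_baseline(rng)
        traj = make_trajectory(group, baseline, effect_config)
        for t in times:
            clean = traj.at(float(t))
            if t == 0:
                noisy = clean  # baseline defines the reference: no descriptor jitter
            else:
                noisy = ResonanceModel(
                    a_peak_db=clean.a_peak_db
                    + rng.normal(0.0, effect_config.amp_jitter_db),
                    f_center_hz=clean.f_center_hz
                    + rng.normal(0.0, effect_config.freq_jitter_hz),
                    fwhm_hz=max(
                        clean.fwhm_hz + rng.normal(0.0, effect_config.fwhm_jitter_hz),
                        grid_spec.step_hz,
                    ),
                    floor_db=clean.floor_db,
                )
            amp = resonance_curve(noisy, grid)
            if effect_config.measurement_noise_db > 0:
                amp = amp + rng.normal(0.0, effect_config.measurement_noise_db, grid.size)
            records.append(
                SweepRecord(subject_id=sid, time_h=float(t), freq_hz=grid, amp_db=amp)
            )
            truth.append(
                {
                    "subject": sid,
                    "group": group,
                    "time_h": float(t),
                    "a_peak_db": clean.a_peak_db,
                    "f_center_hz": clean.f_center_hz,
                    "fwhm_hz": clean.fwhm_hz,
                    "drift_fraction": traj.drift_fraction(float(t)),
                }
            )
    dataset = CohortDataset(records=records, group_of=group_of)
    if return_truth:
        return dataset, truth
    return dataset


def write_cohort_tree(
    dataset: CohortDataset,
    outdir: str | Path,
    truth: list[dict] | None = None,
    config: dict | None = None,
    touchstone: bool = False,
) -> None:
    """Write a cohort to disk: cohort CSV + JSON manifest, optionally one
    ``.s2p`` per (subject, time point) under ``touchstone/``, plus the
    ground-truth sidecar and generating config when provided."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_cohort_csv(dataset, outdir / "cohort.csv")
    write_manifest(dataset, outdir / "manifest.json")
    if touchstone:
        ts_dir = outdir / "touchstone"
        ts_dir.mkdir(exist_ok=True)
        for rec in dataset.records:
            fname = f"{rec.subject_id}_t{rec.time_h:05.1f}h.s2p".replace(" ", "0")
            write_touchstone(rec, ts_dir / fname)
    if truth is not None:
        (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1) + "\n")
    if config is not None:
        (outdir / "config.json").write_text(json.dumps(config, indent=2, sort_keys=True) + "\n")
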