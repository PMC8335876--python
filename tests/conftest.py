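"""Shared fixtures: analytic Lorentzian sweeps and small simulated cohorts."""

import numpy as np
import pytest

from abcpe.io import SweepRecord
from abcpe.simulate import EffectConfig, GridSpec, generate_cohort


def lorentzian_db(
    grid: np.ndarray,
    peak_db: float = -15.0,
    f_center: float = 50e6,
    fwhm: float = 4e6,
    floor_db: float = -300.0,
) -> np.ndarray:
    """Reference Lorentzian-in-power curve in dB, written independently of
    the package (used as ground truth in tests).

    With a negligible floor this is peak_db - 10*log10(1 + (2(f-fc)/W)^2),
    whose half-power full width is exactly ``fwhm``.
    """
    p_peak = 10.0 ** (peak_db / 10.0)
    p_floor = 10.0 ** (floor_db / 10.0)
    x = 2.0 * (grid - f_center) / fwhm
    return 10.0 * np.log10(p_floor + (p_peak - p_floor) / (1.0 + x * x))


@pytest.fixture
def dense_grid() -> np.ndarray:
    """1-100 MHz, 1060 points: the reference sweep protocol grid."""
    return np.linspace(1e6, 100e6, 1060)


@pytest.fixture
def lorentzian_sweep(dense_grid) -> SweepRecord:
    """Baseline-like Lorentzian sweep: peak -15 dB at 50 MHz, FWHM 4 MHz."""
    return SweepRecord(
        subject_id="S1",
        time_h=0.0,
        freq_hz=dense_grid,
        amp_db=lorentzian_db(dense_grid),
    )


#: Small simulation geometry for structure-only tests (fast).
SMALL_GRID = GridSpec(f_start_hz=30e6, f_stop_hz=90e6, n_points=200)


@pytest.fixture(scope="session")
def small_cohort():
    """2 Exp + 2 Con subjects, 9 time points, coarse grid: fast, valid cohort."""
    return generate_cohort(
        n_exp=2, n_con=2, n_timepoints=9, grid_spec=SMALL_GRID, seed=7
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The full default cohort (10 Exp + 4 Con, 49 x 1060-point sweeps)."""
    return generate_cohort(seed=11)


@pytest.fixture(scope="session")
def null_effect() -> EffectConfig:
    return EffectConfig().zeroed()
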