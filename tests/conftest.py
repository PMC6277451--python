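"""Shared fixtures: small synthetic studies reused across test modules.

Heavier simulated objects are session-scoped so their cost is paid once.
"""

from __future__ import annotations

import numpy as np
import pytest

from chromalib.demultiplex import demultiplex_run
from chromalib.models import Spectrum
from chromalib.synthetic_data import simulate_library, simulate_run

# interior precursor range for span (400, 600) / 24 m/z windows: precursors
# below first_low + width/2 (412) or above last_low + width/2 (580) sit in a
# window half that no neighboring window re-isolates, so they cannot be
# demultiplexed
SPAN = (400.0, 600.0)
MZ_INTERIOR = (415.0, 575.0)


def make_spectrum(mzs, intensities, rt=1.0, ms_level=2, center=500.0, width=24.0,
                  scan_id="s"):
    order = np.argsort(mzs)
    return Spectrum(
        scan_id=scan_id,
        ms_level=ms_level,
        rt=rt,
        mzs=np.asarray(mzs, dtype=float)[order],
        intensities=np.asarray(intensities, dtype=float)[order],
        isolation_center=center if ms_level == 2 else None,
        isolation_width=width if ms_level == 2 else None,
    )


@pytest.fixture(scope="session")
def small_library():
    lib, truth = simulate_library(
        120, seed=11, gradient=(0.5, 4.0), mz_range=MZ_INTERIOR
    )
    return lib, truth


@pytest.fixture(scope="session")
def wide_run(small_library):
    """One noisy overlapped wide-window run of the 120-peptide library,
    demultiplexed."""
    _, truth = small_library
    run = simulate_run(
        truth, scheme="overlapped_wide", span=SPAN, noise=0.02, seed=12,
        chemical_noise_peaks=10, background_peaks=60,
        background_intensity=8000.0, cycle_time_s=2.0, run_id="wide1",
    )
    return demultiplex_run(run)


@pytest.fixture(scope="session")
def searched_wide_run(small_library, wide_run):
    from chromalib.pipeline import StudyConfig, search_run_two_pass

    lib, _ = small_library
    matches, report = search_run_two_pass(wide_run, lib, StudyConfig(seed=11))
    return matches, report
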