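"""Deconvolution of 50%-overlapped DIA spectra into half-width pseudo-spectra.

Each MS2 spectrum S(T,i) of an overlapped scheme co-isolates precursors from
the lower and upper halves of its window. The lower half is re-isolated by
window i-1 in the previous/next half cycles, the upper half by window i+1.
Fragment peaks are routed accordingly:

* matched only in the lower neighbors  -> lower half-window bin
* matched only in the upper neighbors  -> upper half-window bin
* matched in both                      -> split proportionally to the summed
  neighbor intensities L/(L+U) and U/(L+U)
* matched in neither                   -> dropped as noise

Only three half cycles are needed at a time, so the transform streams with a
look-ahead bounded by one full cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .models import DIARun, Spectrum

logger = logging.getLogger(__name__)

DEFAULT_TOL_PPM = 10.0


@dataclass
class OverlapContext:
    """One MS2 spectrum plus its four (or fewer) overlap neighbors."""

    current: Spectrum
    lower_prev: Optional[Spectrum] = None
    lower_next: Optional[Spectrum] = None
    upper_prev: Optional[Spectrum] = None
    upper_next: Optional[Spectrum] = None
    match_tolerance: float = DEFAULT_TOL_PPM


def _matched_intensities(
    mzs: np.ndarray, spec: Optional[Spectrum], tol_ppm: float
) -> np.ndarray:
    """Per query m/z, the intensity of the nearest peak within tol_ppm else 0."""
    if spec is None or spec.mzs.size == 0 or mzs.size == 0:
        return np.zeros(mzs.size)
    j = np.searchsorted(spec.mzs, mzs)
    left = np.clip(j - 1, 0, spec.mzs.size - 1)
    right = np.clip(j, 0, spec.mzs.size - 1)
    take = np.where(
        np.abs(spec.mzs[right] - mzs) < np.abs(spec.mzs[left] - mzs), right, left
    )
    ok = np.abs(spec.mzs[take] - mzs) <= mzs * tol_ppm * 1e-6
    return np.where(ok, spec.intensities[take], 0.0)


def demultiplex_spectrum(ctx: OverlapContext) -> tuple[Spectrum, Spectrum]:
    """Split one overlapped MS2 spectrum into lower and upper half spectra."""
    s = ctx.current
    lo, hi = s.window
    mid = (lo + hi) / 2.0
    has_lower = ctx.lower_prev is not None or ctx.lower_next is not None
    has_upper = ctx.upper_prev is not None or ctx.upper_next is not None

    lower_mz, lower_int = [], []
    upper_mz, upper_int = [], []

    if not has_lower and not has_upper:
        # run boundary with no overlap information: pass through unsplit
        logger.warning(
            "scan %s has no overlap neighbors; passed through unsplit", s.scan_id
        )
        half = (hi - lo) / 2.0
        low_half = Spectrum(
            s.scan_id + ".L", 2, s.rt, s.mzs.copy(), s.intensities.copy(),
            isolation_center=lo + half / 2, isolation_width=half,
        )
        up_half = Spectrum(
            s.scan_id + ".U", 2, s.rt, s.mzs.copy(), s.intensities.copy(),
            isolation_center=mid + half / 2, isolation_width=half,
        )
        return low_half, up_half

    tol = ctx.match_tolerance
    L = _matched_intensities(s.mzs, ctx.lower_prev, tol) + _matched_intensities(
        s.mzs, ctx.lower_next, tol
    )
    U = _matched_intensities(s.mzs, ctx.upper_prev, tol) + _matched_intensities(
        s.mzs, ctx.upper_next, tol
    )
    for mz, inten, l, u in zip(s.mzs, s.intensities, L, U):
        if l <= 0 and u <= 0:
            continue  # noise
        if not has_upper:
            frac_low = 1.0 if l > 0 else 0.0
        elif not has_lower:
            frac_low = 0.0
        elif l > 0 and u > 0:
            frac_low = l / (l + u)
        else:
            frac_low = 1.0 if l > 0 else 0.0
        if frac_low > 0:
            lower_mz.append(mz)
            lower_int.append(inten * frac_low)
        if frac_low < 1:
            upper_mz.append(mz)
            upper_int.append(inten * (1.0 - frac_low))

    half = (hi - lo) / 2.0
    lower = Spectrum(
        s.scan_id + ".L", 2, s.rt,
        np.array(lower_mz), np.array(lower_int),
        isolation_center=lo + half / 2.0, isolation_width=half,
    )
    upper = Spectrum(
        s.scan_id + ".U", 2, s.rt,
        np.array(upper_mz), np.array(upper_int),
        isolation_center=mid + half / 2.0, isolation_width=half,
    )
    return lower, upper


def is_overlapped_scheme(scheme: list[tuple[float, float]], rel_tol: float = 0.05) -> bool:
    """True when consecutive windows are staggered by half their width."""
    if len(scheme) < 2:
        return False
    for (lo1, hi1), (lo2, _) in zip(scheme, scheme[1:]):
        width = hi1 - lo1
        if width <= 0 or abs((lo2 - lo1) - width / 2.0) > rel_tol * width:
            return False
    return True


def demultiplex_run(run: DIARun, tol_ppm: float = DEFAULT_TOL_PPM) -> DIARun:
    """Replace every MS2 spectrum by its two half-width pseudo-spectra.

    Non-overlapping schemes are returned unchanged with a warning. At run
    boundaries only the single available previous/next half cycle is used.
    """
    if not is_overlapped_scheme(run.window_scheme):
        logger.warning("run %s has no 50%%-overlapped scheme; identity", run.run_id)
        return run

    # index MS2 spectra by (cycle, window index)
    by_cw: dict[tuple[int, int], Spectrum] = {}
    for s, (cyc, wi) in zip(run.spectra, run.cycle_index):
        if s.ms_level == 2:
            by_cw[(cyc, wi)] = s

    new_spectra: list[Spectrum] = []
    for s, (cyc, wi) in zip(run.spectra, run.cycle_index):
        if s.ms_level != 2:
            new_spectra.append(s)
            continue
        ctx = OverlapContext(
            current=s,
            lower_prev=by_cw.get((cyc - 1, wi - 1)),
            lower_next=by_cw.get((cyc + 1, wi - 1)),
            upper_prev=by_cw.get((cyc - 1, wi + 1)),
            upper_next=by_cw.get((cyc + 1, wi + 1)),
            match_tolerance=tol_ppm,
        )
        lower, upper = demultiplex_spectrum(ctx)
        new_spectra.extend([lower, upper])

    new_scheme = sorted(
        {
            (round(lo, 6), round((lo + hi) / 2.0, 6))
            for lo, hi in run.window_scheme
        }
        | {
            (round((lo + hi) / 2.0, 6), round(hi, 6))
            for lo, hi in run.window_scheme
        }
    )
    # keep cycle numbers; each half spectrum inherits its parent's cycle
    cycles = []
    i = 0
    for s, (cyc, wi) in zip(run.spectra, run.cycle_index):
        if s.ms_level != 2:
            cycles.append((cyc, -1))
        else:
            lo, hi = run.window_scheme[wi]
            mid = (lo + hi) / 2.0
            li = new_scheme.index((round(lo, 6), round(mid, 6)))
            ui = new_scheme.index((round(mid, 6), round(hi, 6)))
            cycles.extend([(cyc, li), (cyc, ui)])
        i += 1
    return DIARun(
        run_id=run.run_id,
        spectra=new_spectra,
        window_scheme=new_scheme,
        cycle_index=cycles,
    )
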