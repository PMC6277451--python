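"""Peptide-centric scoring of library entries against DIA runs.

For every library entry (target or decoy) the engine scans all MS2 spectra of
the isolation-window column containing the entry's precursor, computes the
primary score at each retention-time point, keeps the argmax, and evaluates
15 auxiliary features there.

Primary score: log10 of the correlation-weighted dot product of acquired (I)
and library (P) fragment intensities, multiplied by n! where n is the number
of matched fragments. Both intensity vectors are square-root transformed and
max-normalized before the product (configurable; the transform choice is an
implementation decision, not prescribed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import masses
from .library_builder import BackgroundDistribution
from .models import FEATURE_NAMES, DIARun, LibraryEntry, ScoredMatch, Spectrum

logger = logging.getLogger(__name__)

NEG_INF = float("-inf")


@dataclass
class FragmentMatches:
    """Aligned arrays of matched fragment observations for one spectrum."""

    acquired: np.ndarray  # I, raw acquired intensities
    library: np.ndarray  # P, raw library intensities
    correlations: np.ndarray  # C
    ppm: np.ndarray  # signed fragment mass errors, ppm
    delta_da: np.ndarray  # signed fragment mass errors, Da
    fragment_index: np.ndarray  # index into entry.fragment_mzs

    @property
    def n(self) -> int:
        return int(self.acquired.size)


def match_fragments(
    spec: Spectrum, entry: LibraryEntry, tol_ppm: float = 10.0
) -> FragmentMatches:
    """Match each library fragment to at most one acquired peak (nearest
    within ``tol_ppm``); unmatched fragments are excluded."""
    mzs = spec.mzs
    fmz = entry.fragment_mzs
    empty = np.array([])
    if mzs.size == 0 or fmz.size == 0:
        return FragmentMatches(empty, empty, empty, empty, empty, np.array([], dtype=int))
    j = np.searchsorted(mzs, fmz)
    left = np.clip(j - 1, 0, mzs.size - 1)
    right = np.clip(j, 0, mzs.size - 1)
    take = np.where(np.abs(mzs[right] - fmz) < np.abs(mzs[left] - fmz), right, left)
    delta = mzs[take] - fmz
    ok = np.abs(delta) <= fmz * tol_ppm * 1e-6
    idx = np.nonzero(ok)[0]
    return FragmentMatches(
        acquired=spec.intensities[take[ok]],
        library=entry.fragment_intensities[idx],
        correlations=entry.fragment_correlations[idx],
        ppm=delta[ok] / fmz[ok] * 1e6,
        delta_da=delta[ok],
        fragment_index=idx,
    )


def _transform(v: np.ndarray, transform: str, ref_max: float | None = None) -> np.ndarray:
    """sqrt (optional) then max-normalize; ``ref_max`` supplies an external
    normalization reference (the spectrum base peak) so that weak matches in
    a tall spectrum score lower than the same pattern at its apex."""
    if transform == "sqrt":
        v = np.sqrt(np.maximum(v, 0.0))
        if ref_max is not None:
            ref_max = math.sqrt(max(ref_max, 0.0))
    m = ref_max if ref_max else (v.max() if v.size else 0.0)
    return v / m if m > 0 else v


def primary_score(
    acquired: np.ndarray,
    library: np.ndarray,
    correlations: np.ndarray,
) -> float:
    """log10((sum_i I_i * P_i * C_i) * n!), or -inf when the sum is zero.

    Operates on the vectors as given; any normalization happens upstream.
    """
    acquired = np.asarray(acquired, dtype=float)
    n = acquired.size
    if n == 0:
        return NEG_INF
    s = float(np.sum(acquired * np.asarray(library) * np.asarray(correlations)))
    if s <= 0:
        return NEG_INF
    return math.log10(s) + math.lgamma(n + 1) / math.log(10)


def score_spectrum(
    spec: Spectrum, entry: LibraryEntry, tol_ppm: float = 10.0, transform: str = "sqrt"
) -> tuple[float, FragmentMatches]:
    m = match_fragments(spec, entry, tol_ppm)
    if m.n == 0:
        return NEG_INF, m
    base = float(spec.intensities.max()) if spec.intensities.size else None
    I = _transform(m.acquired, transform, ref_max=base)
    P = _transform(m.library, transform)
    return primary_score(I, P, m.correlations), m


def find_best_rt(
    run: DIARun,
    entry: LibraryEntry,
    masked: Optional[list[float]] = None,
    tol_ppm: float = 10.0,
    transform: str = "sqrt",
) -> ScoredMatch:
    """Highest-scoring retention-time point for an entry in a run.

    Spectra whose RT is within one cycle time of a masked RT are excluded.
    Ties go to the earlier RT.
    """
    masked = masked or []
    windows = run.window_index_for_mz(entry.precursor_mz)
    spectra: list[Spectrum] = []
    for wi in windows:
        spectra.extend(run.ms2_in_window(wi))
    spectra.sort(key=lambda s: s.rt)
    if not spectra:
        return ScoredMatch(
            entry.peptide_modseq, entry.charge, entry.is_decoy, run.run_id,
            apex_rt=None, n_matching=0, primary_score=NEG_INF,
            masked_rts=list(masked), out_of_range=True,
        )
    cycle = run.cycle_time() or 0.0
    scores = np.full(len(spectra), NEG_INF)
    ns = np.zeros(len(spectra), dtype=int)
    for i, spec in enumerate(spectra):
        if any(abs(spec.rt - m) <= cycle for m in masked):
            continue
        s, mm = score_spectrum(spec, entry, tol_ppm, transform)
        scores[i] = s
        ns[i] = mm.n
    if not np.any(np.isfinite(scores)):
        return ScoredMatch(
            entry.peptide_modseq, entry.charge, entry.is_decoy, run.run_id,
            apex_rt=None, n_matching=0, primary_score=NEG_INF,
            masked_rts=list(masked),
            candidate_scores=scores, candidate_rts=np.array([s.rt for s in spectra]),
            out_of_range=len(masked) > 0 and all(
                any(abs(sp.rt - m) <= cycle for m in masked) for sp in spectra
            ),
        )
    best = int(np.argmax(scores))  # argmax returns first (earliest RT) on ties
    return ScoredMatch(
        entry.peptide_modseq, entry.charge, entry.is_decoy, run.run_id,
        apex_rt=float(spectra[best].rt),
        n_matching=int(ns[best]),
        primary_score=float(scores[best]),
        masked_rts=list(masked),
        candidate_scores=scores,
        candidate_rts=np.array([s.rt for s in spectra]),
    )


# ---------------------------------------------------------------------------
# Feature scores
# ---------------------------------------------------------------------------

def _xcorr(obs_mz, obs_int, ref_mz, ref_int, bin_width=1.0005, max_offset=75):
    """Sequest-style cross-correlation: dot product at zero offset minus the
    mean dot product over +/-max_offset bins."""
    if len(obs_mz) == 0 or len(ref_mz) == 0:
        return 0.0
    top = max(float(np.max(obs_mz)), float(np.max(ref_mz)))
    nbins = int(top / bin_width) + max_offset + 2
    a = np.zeros(nbins)
    b = np.zeros(nbins)
    np.add.at(a, (np.asarray(obs_mz) / bin_width).astype(int), obs_int)
    np.add.at(b, (np.asarray(ref_mz) / bin_width).astype(int), ref_int)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    a /= na
    b /= nb
    full = np.correlate(a, b, mode="full")
    zero = a.size - 1
    window = full[zero - max_offset: zero + max_offset + 1]
    return float(full[zero] - (window.sum() - full[zero]) / (window.size - 1))


def _isotope_features(
    run: DIARun, entry: LibraryEntry, apex_rt: float, tol_ppm: float
) -> tuple[float, float, float]:
    """(isotopeDotProduct, averagePPM, averageAbsPPM) from the nearest MS1."""
    ms1 = run.ms1_spectra()
    if not ms1:
        return 0.0, 0.0, 0.0
    spec = min(ms1, key=lambda s: abs(s.rt - apex_rt))
    neutral = (entry.precursor_mz - masses.PROTON) * entry.charge
    expected = masses.averagine_isotopes(neutral, n=4)
    obs, ppms = [], []
    for k in range(4):
        mz = entry.precursor_mz + k * masses.NEUTRON / entry.charge
        j = int(np.searchsorted(spec.mzs, mz))
        best, best_d = -1, mz * tol_ppm * 1e-6
        for cand in (j - 1, j):
            if 0 <= cand < spec.mzs.size:
                d = abs(spec.mzs[cand] - mz)
                if d <= best_d:
                    best, best_d = cand, d
        if best >= 0:
            obs.append(float(spec.intensities[best]))
            ppms.append(masses.ppm_error(float(spec.mzs[best]), mz))
        else:
            obs.append(0.0)
    obs_a = np.array(obs)
    exp_a = np.array(expected)
    if obs_a.sum() <= 0:
        idp = 0.0
    else:
        idp = float(
            np.dot(obs_a, exp_a) / (np.linalg.norm(obs_a) * np.linalg.norm(exp_a))
        )
    avg_ppm = float(np.mean(ppms)) if ppms else 0.0
    avg_abs = float(np.mean(np.abs(ppms))) if ppms else 0.0
    return idp, avg_ppm, avg_abs


def feature_scores(
    run: DIARun,
    entry: LibraryEntry,
    match: ScoredMatch,
    bg: Optional[BackgroundDistribution] = None,
    rt_model=None,
    tol_ppm: float = 10.0,
    transform: str = "sqrt",
) -> dict[str, float]:
    """The 15 auxiliary features at the match's apex retention time.

    With no background distribution the weighted variants fall back to their
    unweighted counterparts; deltaRT is 0 until an RT model is available.
    """
    f = dict.fromkeys(FEATURE_NAMES, 0.0)
    if match.apex_rt is None or not np.isfinite(match.primary_score):
        return f

    # locate the apex spectrum again
    spectra = []
    for wi in run.window_index_for_mz(entry.precursor_mz):
        spectra.extend(run.ms2_in_window(wi))
    spec = min(spectra, key=lambda s: abs(s.rt - match.apex_rt))
    m = match_fragments(spec, entry, tol_ppm)
    base = float(spec.intensities.max()) if spec.intensities.size else None
    I = _transform(m.acquired, transform, ref_max=base)
    P = _transform(m.library, transform)

    s1 = match.primary_score
    if match.candidate_scores is not None:
        finite = match.candidate_scores[np.isfinite(match.candidate_scores)]
        others = np.sort(finite)[::-1]
        s2 = others[1] if others.size > 1 else NEG_INF
        f["deltaCN"] = (s1 - s2) / s1 if np.isfinite(s2) and s1 != 0 else 1.0
        # eValue stand-in: z-score of the apex score against the candidate
        # score distribution over all retention-time points
        if finite.size > 2 and np.std(finite) > 0:
            f["eValue"] = float((s1 - np.mean(finite)) / np.std(finite))
    else:
        f["deltaCN"] = 1.0

    dot = float(np.sum(I * P))
    f["logDotProduct"] = math.log10(dot) if dot > 0 else -10.0
    if bg is not None:
        w = np.array([bg.weight(entry.fragment_mzs[k]) for k in m.fragment_index])
    else:
        w = np.ones(m.n)
    wdot = float(np.sum(I * P * w))
    f["logWeightedDotProduct"] = math.log10(wdot) if wdot > 0 else -10.0

    f["xCorrLib"] = _xcorr(
        spec.mzs, np.sqrt(np.maximum(spec.intensities, 0)),
        entry.fragment_mzs, np.sqrt(np.maximum(entry.fragment_intensities, 0)),
    )
    theo = masses.theoretical_fragments(entry.peptide_modseq, entry.charge)
    f["xCorrModel"] = _xcorr(
        spec.mzs, np.sqrt(np.maximum(spec.intensities, 0)),
        [t[1] for t in theo], np.ones(len(theo)),
    )

    nI = np.linalg.norm(I)
    nP = np.linalg.norm(P)
    Ih = I / nI if nI > 0 else I
    Ph = P / nP if nP > 0 else P
    f["sumOfSquaredErrors"] = float(np.sum((Ih - Ph) ** 2))
    f["weightedSumOfSquaredErrors"] = float(np.sum(w * (Ih - Ph) ** 2))
    f["numberOfMatchingPeaks"] = float(m.n)
    if m.n:
        f["averageFragmentDeltaMass"] = float(np.mean(m.delta_da))
        f["averageAbsFragDeltaMass"] = float(np.mean(np.abs(m.delta_da)))

    idp, avg_ppm, avg_abs = _isotope_features(run, entry, match.apex_rt, tol_ppm)
    f["isotopeDotProduct"] = idp
    f["averagePPM"] = avg_ppm
    f["averageAbsPPM"] = avg_abs

    if rt_model is not None:
        f["deltaRT"] = abs(match.apex_rt - rt_model.predict(entry.library_rt))
    return f


def modified_form_gate(
    run: DIARun,
    match: ScoredMatch,
    entry: LibraryEntry,
    unmod_entry: LibraryEntry,
    tol_ppm: float = 10.0,
    transform: str = "sqrt",
    min_fraction: float = 0.25,
    n_isotopes: int = 4,
) -> bool:
    """Require >=25% of the score contribution of a modified peptide to come
    from fragments exclusive to the modification, when the modified and
    unmodified precursors (any of up to 4 isotope peaks) co-occur in one
    isolation window. Returns True when accepted (or when the gate does not
    apply)."""
    windows = run.window_index_for_mz(entry.precursor_mz)
    shared_window = False
    for wi in windows:
        lo, hi = run.window_scheme[wi]
        for k in range(n_isotopes):
            iso = unmod_entry.precursor_mz + k * masses.NEUTRON / unmod_entry.charge
            if lo <= iso < hi:
                shared_window = True
    if not shared_window:
        return True
    if match.apex_rt is None:
        return False
    spectra = []
    for wi in windows:
        spectra.extend(run.ms2_in_window(wi))
    spec = min(spectra, key=lambda s: abs(s.rt - match.apex_rt))
    m = match_fragments(spec, entry, tol_ppm)
    if m.n == 0:
        return False
    I = _transform(m.acquired, transform)
    P = _transform(m.library, transform)
    contrib = I * P * m.correlations
    unmod_mzs = unmod_entry.fragment_mzs
    exclusive = np.ones(m.n, dtype=bool)
    for i, k in enumerate(m.fragment_index):
        fmz = entry.fragment_mzs[k]
        j = int(np.searchsorted(unmod_mzs, fmz))
        for cand in (j - 1, j):
            if 0 <= cand < unmod_mzs.size:
                if abs(unmod_mzs[cand] - fmz) <= fmz * tol_ppm * 1e-6:
                    exclusive[i] = False
    if not exclusive.any():
        logger.info("%s: no modification-exclusive fragments; rejected", entry.peptide_modseq)
        return False
    total = float(contrib.sum())
    if total <= 0:
        return False
    return float(contrib[exclusive].sum()) >= min_fraction * total


def search_run(
    run: DIARun,
    lib,
    bg_by_window: Optional[dict[int, BackgroundDistribution]] = None,
    rt_model=None,
    tol_ppm: float = 10.0,
    transform: str = "sqrt",
    masked: Optional[dict[tuple, list[float]]] = None,
) -> list[ScoredMatch]:
    """Score every library entry (targets and decoys) against one run."""
    results = []
    masked = masked or {}
    for entry in lib:
        m = find_best_rt(
            run, entry, masked.get(entry.key), tol_ppm=tol_ppm, transform=transform
        )
        bg = None
        if bg_by_window is not None:
            wis = run.window_index_for_mz(entry.precursor_mz)
            if wis:
                bg = bg_by_window.get(wis[0])
        m.features = feature_scores(
            run, entry, m, bg=bg, rt_model=rt_model, tol_ppm=tol_ppm, transform=transform
        )
        results.append(m)
    return results
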