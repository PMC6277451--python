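"""Fragment-ion chromatogram extraction, transition refinement against the
median peak shape, background-subtracted integration, and study-level
peptide/protein quantification."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.stats import pearsonr

from .masses import FragmentAnnotation
from .models import DIARun, LibraryEntry, ProteinGroup, ScoredMatch

logger = logging.getLogger(__name__)

R_QUANT = 0.9
R_DETECT = 0.75
INTERFERENCE_MAX = 0.2
MIN_TRANSITIONS = 3
MAX_TRANSITIONS = 5
CV_MAX = 0.20
SAVGOL_WINDOW = 7
SAVGOL_ORDER = 2


@dataclass
class TransitionTrace:
    """Extracted chromatogram of one fragment ion around a detection apex."""

    fragment_id: FragmentAnnotation | tuple
    rts: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray = field(default_factory=lambda: np.array([]))
    unit_norm: np.ndarray = field(default_factory=lambda: np.array([]))
    correlation: float = np.nan
    status: str = "interfered"

    def __post_init__(self) -> None:
        self.rts = np.asarray(self.rts, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)


@dataclass
class PeakBoundaries:
    left_rt: float
    right_rt: float
    median_shape: np.ndarray
    left_idx: int = 0
    right_idx: int = 0


@dataclass
class QuantRecord:
    modseq: str
    charge: int
    run_id: str
    transition_ids: list
    areas: np.ndarray  # I_t,s per transition
    correlations: np.ndarray  # C_t,s per transition
    peptide_area: float = 0.0
    quantitative: bool = True


def extract_traces(
    run: DIARun,
    match: ScoredMatch,
    entry: LibraryEntry,
    rt_halfwidth: float = 0.5,
    tol_ppm: float = 10.0,
) -> list[TransitionTrace]:
    """Per library fragment, the nearest-peak intensity in every MS2 spectrum
    of the matching window column within apex +/- halfwidth (0 if absent)."""
    spectra = []
    for wi in run.window_index_for_mz(entry.precursor_mz):
        spectra.extend(run.ms2_in_window(wi))
    spectra = sorted(
        (s for s in spectra if abs(s.rt - match.apex_rt) <= rt_halfwidth),
        key=lambda s: s.rt,
    )
    if not spectra:
        return []
    rts = np.array([s.rt for s in spectra])
    traces = []
    for k, fmz in enumerate(entry.fragment_mzs):
        vals = np.zeros(len(spectra))
        for i, s in enumerate(spectra):
            if s.mzs.size == 0:
                continue
            j = int(np.searchsorted(s.mzs, fmz))
            best, best_d = -1, fmz * tol_ppm * 1e-6
            for cand in (j - 1, j):
                if 0 <= cand < s.mzs.size:
                    d = abs(s.mzs[cand] - fmz)
                    if d <= best_d:
                        best, best_d = cand, d
            if best >= 0:
                vals[i] = s.intensities[best]
        fid = (
            entry.fragment_annotations[k]
            if entry.fragment_annotations is not None
            and entry.fragment_annotations[k] is not None
            else ("mz", round(float(fmz), 4), 1)
        )
        traces.append(TransitionTrace(fragment_id=fid, rts=rts, raw=vals))
    return traces


def _smooth(raw: np.ndarray) -> np.ndarray:
    n = raw.size
    if n < 3:
        return raw.copy()
    window = min(SAVGOL_WINDOW, n if n % 2 == 1 else n - 1)
    order = min(SAVGOL_ORDER, window - 1)
    return np.maximum(savgol_filter(raw, window, order), 0.0)


def _trace_boundaries(shape: np.ndarray) -> tuple[int, int]:
    """Descend from the maximum on both sides; stop at the minimum before the
    trace rises for >2 consecutive points, or where it drops below 1% of the
    maximum."""
    apex = int(np.argmax(shape))
    floor = 0.01 * shape[apex]

    def descend(step: int) -> int:
        i = apex
        local_min = apex
        rises = 0
        while 0 <= i + step < shape.size:
            nxt = i + step
            if shape[nxt] <= floor:
                return nxt
            if shape[nxt] > shape[i]:
                rises += 1
                if rises > 2:
                    return local_min
            else:
                rises = 0
                if shape[nxt] < shape[local_min]:
                    local_min = nxt
            i = nxt
        return i

    return descend(-1), descend(+1)


def refine_transitions(
    traces: list[TransitionTrace],
) -> tuple[Optional[PeakBoundaries], list[TransitionTrace]]:
    """Smooth, unit-area normalize, find boundaries on the median shape, and
    classify each trace by Pearson correlation to the median peak shape
    (>=0.9 quantitative, >=0.75 detection, else interfered).

    Returns (None, traces) when fewer than two traces carry signal.
    """
    for tr in traces:
        tr.smoothed = _smooth(tr.raw)
        total = np.trapezoid(tr.smoothed, tr.rts) if tr.rts.size > 1 else tr.smoothed.sum()
        tr.unit_norm = tr.smoothed / total if total > 0 else tr.smoothed.copy()

    with_signal = [tr for tr in traces if tr.raw.sum() > 0]
    if len(with_signal) < 2:
        logger.info("fewer than 2 transitions with signal: non-quantifiable")
        return None, traces

    stack = np.vstack([tr.unit_norm for tr in with_signal])
    median_shape = np.median(stack, axis=0)
    li, ri = _trace_boundaries(median_shape)
    rts = with_signal[0].rts
    boundaries = PeakBoundaries(
        left_rt=float(rts[li]), right_rt=float(rts[ri]),
        median_shape=median_shape, left_idx=li, right_idx=ri,
    )

    sl = slice(li, ri + 1)
    ref = median_shape[sl]
    for tr in traces:
        seg = tr.unit_norm[sl]
        if ri - li + 1 <= 3 or np.std(seg) == 0 or np.std(ref) == 0:
            tr.correlation = np.nan  # undefined on <=3 points -> interfered
        else:
            tr.correlation = float(pearsonr(seg, ref)[0])
        if np.isfinite(tr.correlation) and tr.correlation >= R_QUANT:
            tr.status = "quantitative"
        elif np.isfinite(tr.correlation) and tr.correlation >= R_DETECT:
            tr.status = "detection"
        else:
            tr.status = "interfered"
    return boundaries, traces


def integrate(
    trace: np.ndarray | TransitionTrace,
    rts: np.ndarray | None = None,
    boundaries: PeakBoundaries | tuple[int, int] | None = None,
) -> float:
    """Trapezoidal area between the boundaries minus a background rectangle
    whose height is the larger boundary-edge intensity; floored at zero."""
    if isinstance(trace, TransitionTrace):
        values = trace.smoothed if trace.smoothed.size else trace.raw
        rts = trace.rts
    else:
        values = np.asarray(trace, dtype=float)
        rts = np.asarray(rts, dtype=float) if rts is not None else np.arange(values.size, dtype=float)
    if isinstance(boundaries, PeakBoundaries):
        li, ri = boundaries.left_idx, boundaries.right_idx
    elif boundaries is None:
        li, ri = 0, values.size - 1
    else:
        li, ri = boundaries
    if ri <= li:
        return 0.0
    seg = values[li:ri + 1]
    seg_rt = rts[li:ri + 1]
    area = float(np.trapezoid(seg, seg_rt))
    rect = (seg_rt[-1] - seg_rt[0]) * max(seg[0], seg[-1])
    return max(area - rect, 0.0)


def quantify_match(
    run: DIARun,
    match: ScoredMatch,
    entry: LibraryEntry,
    rt_halfwidth: float = 0.5,
    tol_ppm: float = 10.0,
) -> Optional[QuantRecord]:
    """Extract, refine and integrate one peptide detection in one run."""
    traces = extract_traces(run, match, entry, rt_halfwidth, tol_ppm)
    if not traces:
        return None
    boundaries, refined = refine_transitions(traces)
    if boundaries is None:
        return QuantRecord(
            modseq=match.modseq, charge=match.charge, run_id=run.run_id,
            transition_ids=[tr.fragment_id for tr in refined],
            areas=np.zeros(len(refined)),
            correlations=np.full(len(refined), np.nan),
            quantitative=False,
        )
    areas = np.array([integrate(tr, boundaries=boundaries) for tr in refined])
    corrs = np.array(
        [tr.correlation if np.isfinite(tr.correlation) else -1.0 for tr in refined]
    )
    return QuantRecord(
        modseq=match.modseq, charge=match.charge, run_id=run.run_id,
        transition_ids=[tr.fragment_id for tr in refined],
        areas=areas, correlations=corrs,
    )


def interference_score(
    intensities: np.ndarray, correlations: np.ndarray, r_quant: float = R_QUANT
) -> float:
    """Sum of intensities in runs where the transition shows interference
    (C < 0.9) over runs where it does not (C >= 0.9)."""
    bad = float(np.sum(intensities[correlations < r_quant]))
    good = float(np.sum(intensities[correlations >= r_quant]))
    if good <= 0:
        return np.inf if bad > 0 else 0.0
    return bad / good


def select_transitions_study(
    records: list[QuantRecord],
    min_transitions: int = MIN_TRANSITIONS,
    max_transitions: int = MAX_TRANSITIONS,
    interference_max: float = INTERFERENCE_MAX,
) -> dict[tuple[str, int], dict[str, float]]:
    """Study-wide transition choice and peptide quantities.

    Transitions are ranked by the sum of their correlation scores over runs
    where they are quantitative; transitions with interference score > 0.2
    are dropped study-wide; each peptide's per-run quantity is the sum of its
    top-5 surviving transitions, and peptides with fewer than 3 quantitative
    transitions are dropped. Returns {(modseq, charge): {run_id: quantity}}.
    """
    by_pep: dict[tuple[str, int], list[QuantRecord]] = {}
    for r in records:
        if r.quantitative:
            by_pep.setdefault((r.modseq, r.charge), []).append(r)

    out: dict[tuple[str, int], dict[str, float]] = {}
    for key, recs in by_pep.items():
        tids: list = []
        for r in recs:
            for t in r.transition_ids:
                if t not in tids:
                    tids.append(t)
        n_t = len(tids)
        inten = np.zeros((n_t, len(recs)))
        corr = np.full((n_t, len(recs)), -1.0)
        for s, r in enumerate(recs):
            for t_local, t in enumerate(r.transition_ids):
                g = tids.index(t)
                inten[g, s] = r.areas[t_local]
                corr[g, s] = r.correlations[t_local]
        quant_mask = corr >= R_QUANT
        rank_score = np.where(quant_mask, corr, 0.0).sum(axis=1)
        iscores = np.array(
            [interference_score(inten[t], corr[t]) for t in range(n_t)]
        )
        surviving = [
            t for t in range(n_t)
            if iscores[t] <= interference_max and quant_mask[t].any()
        ]
        if len(surviving) < min_transitions:
            continue
        surviving.sort(key=lambda t: -rank_score[t])
        chosen = surviving[:max_transitions]
        out[key] = {
            recs[s].run_id: float(inten[chosen, s].sum())
            for s in range(len(recs))
        }
    return out


def study_filters(
    quantities: dict[tuple[str, int], dict[str, float]],
    design: dict[str, str],
    cv_max: float = CV_MAX,
    backfill: Optional[dict[tuple[str, int], dict[str, float]]] = None,
) -> pd.DataFrame:
    """Keep peptides measured in every replicate of at least one condition
    with study-wide CV (after per-condition median centering) below 20%.

    ``design`` maps run_id -> condition. ``backfill`` optionally supplies
    quantities recovered through cross-run RT alignment before filtering.
    Returns a peptides x runs matrix.
    """
    runs = sorted(design)
    conditions: dict[str, list[str]] = {}
    for rid, cond in design.items():
        conditions.setdefault(cond, []).append(rid)

    rows = {}
    for key, per_run in quantities.items():
        vals = dict(per_run)
        if backfill and key in backfill:
            for rid, v in backfill[key].items():
                vals.setdefault(rid, v)
        complete = any(
            all(rid in vals and vals[rid] > 0 for rid in rids)
            for rids in conditions.values()
        )
        if not complete:
            continue
        obs = np.array([vals.get(rid, np.nan) for rid in runs])
        # per-condition median centering before the CV estimate
        centered = obs.copy()
        for rids in conditions.values():
            idx = [runs.index(r) for r in rids]
            med = np.nanmedian(obs[idx])
            grand = np.nanmedian(obs)
            if med > 0 and grand > 0:
                centered[idx] = obs[idx] * (grand / med)
        finite = centered[np.isfinite(centered)]
        if finite.size >= 2 and finite.mean() > 0:
            cv = finite.std(ddof=1) / finite.mean()
            if cv >= cv_max:
                continue
        rows[key] = obs
    df = pd.DataFrame.from_dict(rows, orient="index", columns=runs)
    df.index = pd.MultiIndex.from_tuples(rows.keys(), names=["modseq", "charge"]) if rows else df.index
    return df


def protein_quant(
    peptide_matrix: pd.DataFrame, groups: list[ProteinGroup]
) -> pd.DataFrame:
    """Per protein group, the sum of quantities of peptides unique to it.

    Peptides shared between groups contribute to none.
    """
    if peptide_matrix.empty:
        return pd.DataFrame()
    pep_counts: dict[str, int] = {}
    for g in groups:
        for p in g.peptides:
            pep_counts[p] = pep_counts.get(p, 0) + 1
    rows = {}
    for g in groups:
        unique_peps = [p for p in g.peptides if pep_counts[p] == 1]
        sel = peptide_matrix.index.get_level_values("modseq").isin(unique_peps)
        if not sel.any():
            logger.info("group %s has no unique quantified peptides", sorted(g.accessions))
            continue
        rows["/".join(sorted(g.accessions))] = peptide_matrix[sel].sum(
            axis=0, skipna=True
        )
    return pd.DataFrame.from_dict(rows, orient="index")
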