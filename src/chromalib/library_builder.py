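"""Decoy generation, per-window background ion frequencies, and
DIA-derived chromatogram library construction."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import masses
from .masses import FragmentAnnotation
from .models import DIARun, Library, LibraryEntry, ScoredMatch

logger = logging.getLogger(__name__)

MAX_BACKGROUND_MZ = 4000


# ---------------------------------------------------------------------------
# Decoys
# ---------------------------------------------------------------------------

def reverse_modseq(modseq: str) -> str:
    """Reverse the peptide keeping the C-terminal (enzymatic) residue fixed."""
    tokens = masses.tokenize(modseq)
    return "".join(reversed(tokens[:-1])) + tokens[-1]


def annotate_fragments(entry: LibraryEntry, tol_ppm: float = 10.0) -> LibraryEntry:
    """Fill missing fragment annotations by matching theoretical B/Y ions."""
    if entry.fragment_annotations is not None and all(
        a is not None for a in entry.fragment_annotations
    ):
        return entry
    theo = masses.theoretical_fragments(entry.peptide_modseq, entry.charge)
    anns: list[FragmentAnnotation | None] = (
        list(entry.fragment_annotations)
        if entry.fragment_annotations is not None
        else [None] * entry.fragment_mzs.size
    )
    for i, mz in enumerate(entry.fragment_mzs):
        if anns[i] is not None:
            continue
        best, best_ppm = None, tol_ppm
        for ann, tmz in theo:
            d = abs(masses.ppm_error(mz, tmz))
            if d <= best_ppm:
                best, best_ppm = ann, d
        anns[i] = best
    entry.fragment_annotations = anns
    return entry


def make_decoy(entry: LibraryEntry, tol_ppm: float = 10.0) -> LibraryEntry:
    """Reversed-sequence decoy carrying the target's annotated fragments.

    Fragment ions annotatable as B/Y on the target are transferred to the
    decoy m/z for the same ion type/index/charge; the per-fragment ppm error
    of the target observation is preserved. Unannotated peaks are omitted.
    A decoy identical to its target is flagged ``degenerate_decoy``.
    """
    entry = annotate_fragments(entry, tol_ppm)
    decoy_seq = reverse_modseq(entry.peptide_modseq)
    degenerate = decoy_seq == entry.peptide_modseq

    mzs, intens, corrs, anns = [], [], [], []
    for mz, inten, corr, ann in zip(
        entry.fragment_mzs,
        entry.fragment_intensities,
        entry.fragment_correlations,
        entry.fragment_annotations,
    ):
        if ann is None:
            continue
        if ann.charge > 1 and entry.charge <= 2:
            continue  # +2 fragments only for precursors above +2
        target_theo = masses.fragment_mz(entry.peptide_modseq, ann)
        decoy_theo = masses.fragment_mz(decoy_seq, ann)
        ppm_err = masses.ppm_error(mz, target_theo)
        mzs.append(decoy_theo * (1.0 + ppm_err * 1e-6))
        intens.append(inten)
        corrs.append(corr)
        anns.append(ann)

    order = np.argsort(mzs) if mzs else np.array([], dtype=int)
    return LibraryEntry(
        peptide_modseq=decoy_seq,
        charge=entry.charge,
        precursor_mz=entry.precursor_mz,  # reversal preserves mass exactly
        library_rt=entry.library_rt,
        fragment_mzs=np.array(mzs)[order],
        fragment_intensities=np.array(intens)[order],
        fragment_correlations=np.array(corrs)[order],
        fragment_annotations=[anns[i] for i in order],
        is_decoy=True,
        source=entry.source,
        degenerate_decoy=degenerate,
    )


def add_decoys(lib: Library, tol_ppm: float = 10.0) -> Library:
    """Add exactly one decoy per target entry (in place)."""
    for entry in list(lib.targets()):
        lib.add(make_decoy(entry, tol_ppm))
    return lib


# ---------------------------------------------------------------------------
# Background ion frequencies
# ---------------------------------------------------------------------------

@dataclass
class BackgroundDistribution:
    """Per-window frequency of nominal fragment m/z values among library
    entries, with a pseudocount so no bin has zero frequency."""

    window: tuple[float, float]
    freq: np.ndarray  # index = trunc(m/z), length MAX_BACKGROUND_MZ + 1
    pseudocount: float = 1.0

    def weight(self, mz: float) -> float:
        """-log10 frequency: rarer ions weigh more."""
        b = min(int(mz), MAX_BACKGROUND_MZ)
        return -np.log10(self.freq[b])


def build_background(
    lib: Library, window: tuple[float, float], pseudocount: float = 1.0
) -> BackgroundDistribution:
    """Frequency of each nominal m/z bin among target entries whose precursor
    falls in ``window`` (half-open). Counting is per entry: duplicate peaks
    within one entry count once."""
    lo, hi = window
    entries = [e for e in lib.targets() if lo <= e.precursor_mz < hi]
    counts = np.zeros(MAX_BACKGROUND_MZ + 1)
    for e in entries:
        bins = {min(int(mz), MAX_BACKGROUND_MZ) for mz in e.fragment_mzs}
        for b in bins:
            counts[b] += 1
    if not entries:
        logger.warning("no library entries in window %s; uniform background", window)
    freq = (counts + pseudocount) / (len(entries) + pseudocount)
    return BackgroundDistribution(window=window, freq=freq, pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# Chromatogram library construction
# ---------------------------------------------------------------------------

def build_chromatogram_library(
    narrow_results: list[ScoredMatch],
    runs: list[DIARun],
    source_lib: Library,
    min_fragments: int = 3,
    detect_corr: float = 0.75,
    tol_ppm: float = 10.0,
    rt_halfwidth: float = 0.5,
) -> Library:
    """Build a chromatogram library from FDR-passing narrow-window matches.

    For each passing peptide only the highest-scoring charge state is kept;
    only +1H/+2H B/Y fragments survive; each fragment's correlation to the
    median peak shape (measured on the narrow-window data) becomes its C
    vector; peptides left with fewer than ``min_fragments`` fragments are
    excluded.
    """
    from .quantification import extract_traces, refine_transitions

    runs_by_id = {r.run_id: r for r in runs}

    # best charge state per peptide
    best: dict[str, ScoredMatch] = {}
    for m in narrow_results:
        if m.is_decoy or m.apex_rt is None:
            continue
        cur = best.get(m.modseq)
        if cur is None or m.primary_score > cur.primary_score:
            best[m.modseq] = m

    out = Library()
    for modseq, match in best.items():
        src = source_lib.entries.get((modseq, match.charge, False))
        if src is None:
            continue
        src = annotate_fragments(src, tol_ppm)
        run = runs_by_id[match.run_id]
        keep = [
            i
            for i, ann in enumerate(src.fragment_annotations)
            if ann is not None and ann.charge in (1, 2)
        ]
        if len(keep) < min_fragments:
            logger.info("%s: <%d usable B/Y fragments; excluded", modseq, min_fragments)
            continue
        sub = LibraryEntry(
            peptide_modseq=modseq,
            charge=match.charge,
            precursor_mz=src.precursor_mz,
            library_rt=match.apex_rt,
            fragment_mzs=src.fragment_mzs[keep],
            fragment_intensities=src.fragment_intensities[keep],
            fragment_annotations=[src.fragment_annotations[i] for i in keep],
            source="chromatogram_library",
        )
        traces = extract_traces(run, match, sub, rt_halfwidth=rt_halfwidth, tol_ppm=tol_ppm)
        if len(traces) < 2:
            continue
        boundaries, refined = refine_transitions(traces)
        if boundaries is None:
            continue
        mzs, intens, corrs, anns = [], [], [], []
        for i, tr in enumerate(refined):
            if not np.isfinite(tr.correlation) or tr.correlation < detect_corr:
                continue
            apex_idx = int(np.argmin(np.abs(np.asarray(tr.rts) - match.apex_rt)))
            mzs.append(sub.fragment_mzs[i])
            intens.append(max(float(tr.smoothed[apex_idx]), 0.0))
            corrs.append(float(tr.correlation))
            anns.append(sub.fragment_annotations[i])
        if len(mzs) < min_fragments:
            logger.info("%s passed FDR but has <%d fragments; excluded", modseq, min_fragments)
            continue
        order = np.argsort(mzs)
        out.add(
            LibraryEntry(
                peptide_modseq=modseq,
                charge=match.charge,
                precursor_mz=sub.precursor_mz,
                library_rt=match.apex_rt,
                fragment_mzs=np.array(mzs)[order],
                fragment_intensities=np.array(intens)[order],
                fragment_correlations=np.array(corrs)[order],
                fragment_annotations=[anns[i] for i in order],
                source="chromatogram_library",
            )
        )
    kept = {e.peptide_modseq for e in out}
    out.protein_map = {
        pep: set(accs)
        for pep, accs in source_lib.protein_map.items()
        if pep in kept
    }
    return out
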