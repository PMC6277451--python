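"""Shared domain types used across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .masses import FragmentAnnotation, precursor_mz as _theoretical_precursor_mz

#: The 15 auxiliary feature names computed at the best retention-time point.
FEATURE_NAMES = (
    "deltaCN",
    "eValue",
    "logDotProduct",
    "logWeightedDotProduct",
    "xCorrLib",
    "xCorrModel",
    "sumOfSquaredErrors",
    "weightedSumOfSquaredErrors",
    "numberOfMatchingPeaks",
    "averageAbsFragDeltaMass",
    "averageFragmentDeltaMass",
    "isotopeDotProduct",
    "averageAbsPPM",
    "averagePPM",
    "deltaRT",
)


@dataclass
class Spectrum:
    """A single centroided mass spectrum.

    ``mzs`` must be strictly increasing and aligned with ``intensities``;
    retention time is in minutes. MS2 spectra additionally carry their
    precursor isolation window center and full width.
    """

    scan_id: str
    ms_level: int
    rt: float
    mzs: np.ndarray
    intensities: np.ndarray
    isolation_center: Optional[float] = None
    isolation_width: Optional[float] = None

    def __post_init__(self) -> None:
        self.mzs = np.asarray(self.mzs, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.mzs.shape != self.intensities.shape:
            raise ValueError("mzs and intensities must have equal length")
        if self.mzs.size > 1 and not np.all(np.diff(self.mzs) > 0):
            raise ValueError(f"mzs must be strictly increasing (scan {self.scan_id})")
        if self.rt < 0:
            raise ValueError("rt must be non-negative")

    @property
    def window(self) -> Optional[tuple[float, float]]:
        if self.isolation_center is None or self.isolation_width is None:
            return None
        h = self.isolation_width / 2.0
        return (self.isolation_center - h, self.isolation_center + h)


@dataclass
class DIARun:
    """Time-ordered spectra of one DIA acquisition plus its window scheme.

    ``window_scheme`` lists (low, high) isolation windows sorted by low m/z.
    ``cycle_index`` holds one (cycle number, window index) pair per spectrum;
    MS1 spectra have window index -1. m/z window membership uses half-open
    intervals [low, high).
    """

    run_id: str
    spectra: list[Spectrum]
    window_scheme: list[tuple[float, float]]
    cycle_index: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.cycle_index:
            self.cycle_index = assign_cycles(self.spectra, self.window_scheme)
        if len(self.cycle_index) != len(self.spectra):
            raise ValueError("cycle_index must align with spectra")

    def window_index_for_mz(self, mz: float) -> list[int]:
        """Indices of all scheme windows containing mz (half-open)."""
        return [
            i for i, (lo, hi) in enumerate(self.window_scheme) if lo <= mz < hi
        ]

    def ms2_in_window(self, window_index: int) -> list[Spectrum]:
        cache = getattr(self, "_ms2_cache", None)
        if cache is None:
            cache = {}
            for s, (_, wi) in zip(self.spectra, self.cycle_index):
                if s.ms_level == 2:
                    cache.setdefault(wi, []).append(s)
            self._ms2_cache = cache
        return cache.get(window_index, [])

    def ms1_spectra(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 1]

    def cycle_time(self) -> float:
        """Median time between successive spectra of the same window column."""
        cached = getattr(self, "_cycle_time", None)
        if cached is not None:
            return cached
        by_window: dict[int, list[float]] = {}
        for s, (_, wi) in zip(self.spectra, self.cycle_index):
            if s.ms_level == 2:
                by_window.setdefault(wi, []).append(s.rt)
        gaps = []
        for rts in by_window.values():
            if len(rts) > 1:
                gaps.extend(np.diff(sorted(rts)))
        self._cycle_time = float(np.median(gaps)) if gaps else 0.0
        return self._cycle_time


def match_window_index(
    scheme: list[tuple[float, float]], center: float, width: float, tol: float = 1e-6
) -> int:
    for i, (lo, hi) in enumerate(scheme):
        if abs((lo + hi) / 2 - center) <= tol and abs((hi - lo) - width) <= tol:
            return i
    raise ValueError(f"isolation window {center}+/-{width / 2} not in scheme")


def assign_cycles(
    spectra: list[Spectrum], scheme: list[tuple[float, float]]
) -> list[tuple[int, int]]:
    """Assign (cycle, window index) to each spectrum.

    A new cycle starts at each MS1 spectrum; in runs without MS1 scans a new
    cycle starts whenever the window index fails to increase.
    """
    out: list[tuple[int, int]] = []
    cycle = -1
    prev_wi = None
    has_ms1 = any(s.ms_level == 1 for s in spectra)
    for s in spectra:
        if s.ms_level == 1:
            cycle += 1
            out.append((cycle, -1))
            prev_wi = None
            continue
        wi = match_window_index(scheme, s.isolation_center, s.isolation_width)
        if not has_ms1 and (prev_wi is None or wi <= prev_wi):
            cycle += 1
        if has_ms1 and cycle < 0:
            cycle = 0
        out.append((cycle, wi))
        prev_wi = wi
    return out


@dataclass
class LibraryEntry:
    """A peptide fragment template: what to look for and how much it weighs."""

    peptide_modseq: str
    charge: int
    precursor_mz: float
    library_rt: float
    fragment_mzs: np.ndarray
    fragment_intensities: np.ndarray
    fragment_correlations: np.ndarray = None  # the C vector; defaults to 1.0
    fragment_annotations: Optional[list[Optional[FragmentAnnotation]]] = None
    is_decoy: bool = False
    source: str = "spectrum_library"
    degenerate_decoy: bool = False

    def __post_init__(self) -> None:
        self.fragment_mzs = np.asarray(self.fragment_mzs, dtype=np.float64)
        self.fragment_intensities = np.asarray(
            self.fragment_intensities, dtype=np.float64
        )
        if self.fragment_correlations is None:
            self.fragment_correlations = np.ones_like(self.fragment_mzs)
        self.fragment_correlations = np.asarray(
            self.fragment_correlations, dtype=np.float64
        )
        n = self.fragment_mzs.size
        if self.fragment_intensities.size != n or self.fragment_correlations.size != n:
            raise ValueError("fragment arrays must have equal length")
        if self.fragment_annotations is not None and len(self.fragment_annotations) != n:
            raise ValueError("fragment_annotations must align with fragment_mzs")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")

    @property
    def key(self) -> tuple[str, int, bool]:
        return (self.peptide_modseq, self.charge, self.is_decoy)

    def check_precursor(self, tol_ppm: float = 50.0) -> bool:
        if self.is_decoy:
            return True  # decoy modseq is the reversed sequence; mass matches target
        theo = _theoretical_precursor_mz(self.peptide_modseq, self.charge)
        return abs(self.precursor_mz - theo) / theo * 1e6 <= tol_ppm


@dataclass
class Library:
    """Collection of library entries plus the peptide-to-protein map."""

    entries: dict[tuple[str, int, bool], LibraryEntry] = field(default_factory=dict)
    protein_map: dict[str, set[str]] = field(default_factory=dict)

    def add(self, entry: LibraryEntry) -> None:
        self.entries[entry.key] = entry

    def targets(self) -> list[LibraryEntry]:
        return [e for e in self.entries.values() if not e.is_decoy]

    def decoys(self) -> list[LibraryEntry]:
        return [e for e in self.entries.values() if e.is_decoy]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.values())


@dataclass
class ScoredMatch:
    """Best retention-time point of one library entry in one run."""

    modseq: str
    charge: int
    is_decoy: bool
    run_id: str
    apex_rt: Optional[float]
    n_matching: int
    primary_score: float
    features: dict[str, float] = field(default_factory=dict)
    masked_rts: list[float] = field(default_factory=list)
    candidate_scores: Optional[np.ndarray] = None
    candidate_rts: Optional[np.ndarray] = None
    out_of_range: bool = False
    rt_outlier: bool = False

    @property
    def entry_ref(self) -> tuple[str, int, bool]:
        return (self.modseq, self.charge, self.is_decoy)


@dataclass
class ValidatedPeptide:
    modseq: str
    charge: int
    run_id: str
    is_decoy: bool
    svm_score: float
    q_value: float
    pep: float


@dataclass
class ProteinGroup:
    accessions: frozenset[str]
    peptides: set[str]
    score: float
    best_pep: float
    q_value: float = 1.0
    is_decoy: bool = False
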