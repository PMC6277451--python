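"""Ground-truth-labeled synthetic libraries, DIA runs, and multi-run studies.

The generator produces tryptic-like peptides with B/Y fragment ions at
log-normal relative intensities, Gaussian elution peaks, 50%-overlapped (or
fixed) isolation-window cycles, injected coeluting interference, monotone
retention-time warps, and condition-level fold changes — everything needed to
exercise the pipeline without external data.

Pipeline modules never read :class:`GroundTruth`; only tests do.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from . import masses
from .models import DIARun, Library, LibraryEntry, Spectrum

# I excluded so reversed decoys never collide through I/L mass degeneracy
ALPHABET = "ACDEFGHLMNPQSTVWY"

PEAK_SD_MIN = 0.1  # ~6 s elution peak standard deviation


@dataclass
class TruthPeptide:
    modseq: str
    charge: int
    base_rt: float
    abundance: float
    fragment_mzs: np.ndarray
    fragment_rel: np.ndarray
    fragment_annotations: list
    protein: str


@dataclass
class InterferenceEvent:
    """A coeluting foreign peak on top of one target fragment."""

    modseq: str
    fragment_index: int
    rt_offset: float  # minutes relative to the peptide's apex
    magnitude: float  # relative to the fragment's own apex height


@dataclass
class GroundTruth:
    peptides: list[TruthPeptide]
    seed: int
    gradient: tuple[float, float]
    interference: list[InterferenceEvent] = field(default_factory=list)
    warps: dict[str, Callable[[float], float]] = field(default_factory=dict)
    abundance_scales: dict[str, dict[str, float]] = field(default_factory=dict)

    def by_modseq(self) -> dict[str, TruthPeptide]:
        return {p.modseq: p for p in self.peptides}

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "gradient": self.gradient,
                "peptides": [
                    {
                        "modseq": p.modseq,
                        "charge": p.charge,
                        "base_rt": p.base_rt,
                        "abundance": p.abundance,
                        "protein": p.protein,
                        "fragment_mzs": p.fragment_mzs.tolist(),
                        "fragment_rel": p.fragment_rel.tolist(),
                    }
                    for p in self.peptides
                ],
            },
            indent=1,
        )


def _random_tryptic(rng: np.random.Generator, min_len=7, max_len=14) -> str:
    n = int(rng.integers(min_len, max_len + 1))
    body = "".join(rng.choice(list(ALPHABET), size=n - 1))
    return body + ("K" if rng.random() < 0.5 else "R")


def simulate_library(
    n_peptides: int,
    seed: int = 0,
    gradient: tuple[float, float] = (0.5, 9.5),
    mz_range: tuple[float, float] = (400.0, 1000.0),
    peptides_per_protein: int = 3,
) -> tuple[Library, GroundTruth]:
    """Random tryptic-like library with ground truth.

    Sequences are unique, end in K/R, avoid I entirely (so reversal decoys
    are never mass-degenerate via I/L), and their precursors fall inside
    ``mz_range`` at charge 2 or 3. Fragment relative intensities are
    log-normal; retention times are uniform over the gradient.
    """
    rng = np.random.default_rng(seed)
    lib = Library()
    peptides: list[TruthPeptide] = []
    seen: set[str] = set()
    attempts = 0
    while len(peptides) < n_peptides and attempts < n_peptides * 200 + 1000:
        attempts += 1
        seq = _random_tryptic(rng)
        if seq in seen or seq[:-1] == seq[:-1][::-1]:  # skip palindromic bodies
            continue
        charge = None
        for z in (2, 3):
            mz = masses.precursor_mz(seq, z)
            if mz_range[0] <= mz < mz_range[1]:
                charge = z
                break
        if charge is None:
            continue
        seen.add(seq)
        frags = [
            (ann, fmz)
            for ann, fmz in masses.theoretical_fragments(seq, charge)
            if 200.0 <= fmz <= 1800.0 and ann.index >= 2
        ]
        if len(frags) < 6:
            continue
        rel = rng.lognormal(mean=0.0, sigma=0.7, size=len(frags))
        rel /= rel.max()
        order = np.argsort([f[1] for f in frags])
        rt = float(rng.uniform(*gradient))
        abundance = float(rng.lognormal(mean=np.log(1000.0), sigma=0.8))
        idx = len(peptides)
        protein = f"PROT{idx // peptides_per_protein:05d}"
        tp = TruthPeptide(
            modseq=seq,
            charge=charge,
            base_rt=rt,
            abundance=abundance,
            fragment_mzs=np.array([frags[i][1] for i in order]),
            fragment_rel=rel[order],
            fragment_annotations=[frags[i][0] for i in order],
            protein=protein,
        )
        peptides.append(tp)
        lib.add(
            LibraryEntry(
                peptide_modseq=seq,
                charge=charge,
                precursor_mz=masses.precursor_mz(seq, charge),
                library_rt=rt,
                fragment_mzs=tp.fragment_mzs.copy(),
                fragment_intensities=tp.fragment_rel.copy(),
                fragment_annotations=list(tp.fragment_annotations),
                source="spectrum_library",
            )
        )
        lib.protein_map.setdefault(seq, set()).add(protein)
    truth = GroundTruth(peptides=peptides, seed=seed, gradient=gradient)
    return lib, truth


# ---------------------------------------------------------------------------
# Acquisition schemes
# ---------------------------------------------------------------------------

def make_scheme(
    span: tuple[float, float] = (400.0, 1000.0),
    width: float = 24.0,
    overlapped: bool = True,
) -> list[tuple[float, float]]:
    """Isolation windows covering ``span``; 50%-staggered when overlapped."""
    step = width / 2.0 if overlapped else width
    lows = []
    lo = span[0]
    while lo + width <= span[1] + 1e-9:
        lows.append(lo)
        lo += step
    return [(lo, lo + width) for lo in lows]


SCHEME_PRESETS: dict[str, dict] = {
    "overlapped_narrow": {"width": 4.0, "overlapped": True},
    "overlapped_wide": {"width": 24.0, "overlapped": True},
    "fixed": {"width": 24.0, "overlapped": False},
}


def _gauss(t: float, mu: float, sd: float) -> float:
    return math.exp(-0.5 * ((t - mu) / sd) ** 2)


def simulate_run(
    truth: GroundTruth,
    scheme: str | Sequence[tuple[float, float]] = "overlapped_wide",
    warp: Optional[Callable[[float], float]] = None,
    noise: float = 0.0,
    seed: int = 0,
    run_id: str = "run",
    span: tuple[float, float] = (400.0, 1000.0),
    cycle_time_s: float = 3.0,
    peak_sd_min: float = PEAK_SD_MIN,
    abundance_scale: Optional[dict[str, float]] = None,
    interference: Sequence[InterferenceEvent] = (),
    chemical_noise_peaks: int = 0,
    background_peaks: int = 0,
    background_intensity: float | None = None,
    with_ms1: bool = True,
) -> DIARun:
    """Simulate one DIA acquisition of the ground-truth peptides.

    ``noise`` is the relative shot-noise level; ``chemical_noise_peaks`` adds
    that many uniform random peaks per MS2 spectrum. ``background_peaks``
    adds per-window peaks at fixed m/z with time-constant intensity — the
    coeluting backdrop that real wide windows always contain. With
    ``noise=0``, no interference, and no background, every fragment peak
    equals the analytic Gaussian elution value at the scan time.
    """
    rng = np.random.default_rng(seed)
    if isinstance(scheme, str):
        windows = make_scheme(span=span, **SCHEME_PRESETS[scheme])
        overlapped = SCHEME_PRESETS[scheme]["overlapped"]
    else:
        windows = list(scheme)
        overlapped = True
    warp = warp or (lambda t: t)
    scale = abundance_scale or {}

    # index peptides and interference by window
    pep_windows: dict[int, list[TruthPeptide]] = {}
    for p in truth.peptides:
        mz = masses.precursor_mz(p.modseq, p.charge)
        for wi, (lo, hi) in enumerate(windows):
            if lo <= mz < hi:
                pep_windows.setdefault(wi, []).append(p)
    intf_by_pep: dict[str, list[InterferenceEvent]] = {}
    for ev in interference:
        intf_by_pep.setdefault(ev.modseq, []).append(ev)

    # background species: time-constant peaks tied to a precursor position so
    # they appear consistently in every window covering that precursor (and
    # therefore survive overlap deconvolution)
    bg_by_window: dict[int, tuple[list[float], list[float]]] = {}
    if background_peaks:
        if background_intensity is None:
            abunds = [p.abundance for p in truth.peptides] or [1000.0]
            background_intensity = float(np.median(abunds))
        for _ in range(background_peaks):
            bg_pmz = float(rng.uniform(span[0], span[1]))
            bg_fmz = float(rng.uniform(200.0, 1800.0))
            bg_int = float(background_intensity * rng.lognormal(0.0, 0.5))
            for wi, (lo, hi) in enumerate(windows):
                if lo <= bg_pmz < hi:
                    mzl, inl = bg_by_window.setdefault(wi, ([], []))
                    mzl.append(bg_fmz)
                    inl.append(bg_int)

    if overlapped:
        halves = [list(range(0, len(windows), 2)), list(range(1, len(windows), 2))]
    else:
        halves = [list(range(len(windows)))]
    half_dur = cycle_time_s / 60.0 / len(halves)

    t0, t1 = truth.gradient
    n_half = int((t1 - t0) / half_dur)
    spectra: list[Spectrum] = []
    cycles: list[tuple[int, int]] = []
    scan = 0
    by_modseq = truth.by_modseq()

    for h in range(n_half):
        t_start = t0 + h * half_dur
        half_windows = halves[h % len(halves)]
        n_scans = len(half_windows) + (1 if with_ms1 else 0)
        dt = half_dur / n_scans

        def elution(p: TruthPeptide, t: float) -> float:
            apex = warp(p.base_rt)
            a = p.abundance * scale.get(p.modseq, 1.0)
            return a * _gauss(t, apex, peak_sd_min)

        if with_ms1:
            t = t_start
            mzvals: list[float] = []
            intens: list[float] = []
            for p in truth.peptides:
                amp = elution(p, t)
                if amp <= 1e-6:
                    continue
                pmz = masses.precursor_mz(p.modseq, p.charge)
                iso = masses.averagine_isotopes(masses.peptide_mass(p.modseq))
                for k, frac in enumerate(iso):
                    mzvals.append(pmz + k * masses.NEUTRON / p.charge)
                    intens.append(amp * frac * 3.0)
            spectra.append(_build_spectrum(f"scan={scan}", 1, t, mzvals, intens, rng, noise))
            cycles.append((h, -1))
            scan += 1

        for j, wi in enumerate(half_windows):
            t = t_start + (j + (1 if with_ms1 else 0)) * dt
            lo, hi = windows[wi]
            mzvals, intens = [], []
            for p in pep_windows.get(wi, []):
                amp = elution(p, t)
                events = intf_by_pep.get(p.modseq, ())
                if amp <= 1e-6 and not events:
                    continue
                apex = warp(p.base_rt)
                a = p.abundance * scale.get(p.modseq, 1.0)
                for k, (fmz, rel) in enumerate(zip(p.fragment_mzs, p.fragment_rel)):
                    v = amp * rel
                    for ev in events:
                        if ev.fragment_index == k:
                            v += (
                                a * rel * ev.magnitude
                                * _gauss(t, apex + ev.rt_offset, peak_sd_min)
                            )
                    if v > 1e-6:
                        mzvals.append(fmz)
                        intens.append(v)
            if wi in bg_by_window:
                bg_mz, bg_int = bg_by_window[wi]
                mzvals.extend(bg_mz)
                intens.extend(bg_int)
            if chemical_noise_peaks:
                for _ in range(chemical_noise_peaks):
                    mzvals.append(float(rng.uniform(200.0, 1800.0)))
                    intens.append(float(rng.exponential(2.0)))
            spectra.append(
                _build_spectrum(
                    f"scan={scan}", 2, t, mzvals, intens, rng, noise,
                    center=(lo + hi) / 2.0, width=hi - lo,
                )
            )
            cycles.append((h, wi))
            scan += 1

    truth.warps[run_id] = warp
    truth.abundance_scales[run_id] = dict(scale)
    return DIARun(
        run_id=run_id, spectra=spectra, window_scheme=windows, cycle_index=cycles
    )


def _build_spectrum(
    scan_id, ms_level, rt, mzvals, intens, rng, noise, center=None, width=None
) -> Spectrum:
    mz = np.asarray(mzvals, dtype=float)
    it = np.asarray(intens, dtype=float)
    if noise > 0 and it.size:
        it = np.maximum(it * (1.0 + noise * rng.standard_normal(it.size)), 0.0)
    # merge coinciding m/z values so the spectrum is strictly increasing
    if mz.size:
        order = np.argsort(mz)
        mz, it = mz[order], it[order]
        key = np.round(mz, 6)
        uniq, inv = np.unique(key, return_inverse=True)
        merged = np.zeros(uniq.size)
        np.add.at(merged, inv, it)
        mz, it = uniq, merged
        keep = it > 0
        mz, it = mz[keep], it[keep]
    return Spectrum(
        scan_id=scan_id, ms_level=ms_level, rt=rt, mzs=mz, intensities=it,
        isolation_center=center, isolation_width=width,
    )


# ---------------------------------------------------------------------------
# Warps and studies
# ---------------------------------------------------------------------------

def monotone_cubic_warp(a: float = 0.3, b: float = 1.05, c: float = 0.004):
    """y = a + b*x + c*x^3 — strictly monotone for b, c >= 0."""

    def warp(x: float) -> float:
        return a + b * x + c * x**3

    return warp


def random_monotone_warp(rng: np.random.Generator, scale: float = 0.3):
    a = float(rng.uniform(-scale, scale))
    b = float(rng.uniform(0.95, 1.05))
    c = float(rng.uniform(0.0, 0.002))
    return monotone_cubic_warp(a, b, c)


def simulate_study(
    truth: GroundTruth,
    n_conditions: int,
    n_replicates: int,
    fold_changes: Optional[dict[str, list[float]]] = None,
    seed: int = 0,
    scheme: str | Sequence[tuple[float, float]] = "overlapped_wide",
    noise: float = 0.0,
    span: tuple[float, float] = (400.0, 1000.0),
    cycle_time_s: float = 3.0,
    chemical_noise_peaks: int = 0,
    identity_warps: bool = False,
    **run_kwargs,
) -> tuple[list[DIARun], dict[str, str]]:
    """Multi-run study with per-condition fold changes and per-run warps.

    ``fold_changes`` maps protein accession -> one factor per condition
    (default: all 1.0). Returns (runs, design) where design maps
    run_id -> condition name.
    """
    rng = np.random.default_rng(seed)
    fold_changes = fold_changes or {}
    runs = []
    design = {}
    for ci in range(n_conditions):
        for ri in range(n_replicates):
            run_id = f"cond{ci}_rep{ri}"
            scale = {
                p.modseq: fold_changes.get(p.protein, [1.0] * n_conditions)[ci]
                for p in truth.peptides
            }
            warp = (lambda t: t) if identity_warps else random_monotone_warp(rng)
            runs.append(
                simulate_run(
                    truth,
                    scheme=scheme,
                    warp=warp,
                    noise=noise,
                    seed=int(rng.integers(0, 2**31)),
                    run_id=run_id,
                    span=span,
                    cycle_time_s=cycle_time_s,
                    abundance_scale=scale,
                    chemical_noise_peaks=chemical_noise_peaks,
                    **run_kwargs,
                )
            )
            design[run_id] = f"cond{ci}"
    return runs, design


def unshared_fragments(
    truth: GroundTruth,
    windows: Sequence[tuple[float, float]],
    tol_ppm: float = 10.0,
) -> dict[str, np.ndarray]:
    """Per peptide, mask of fragments that no other peptide with an
    overlapping or adjacent isolation-window footprint shares within
    tolerance. Deliberately conservative: any such shared fragment can be
    split by the deconvolution, so only unshared ones have a deterministic
    half-window destination. Used as the demultiplexing oracle."""
    width = windows[0][1] - windows[0][0] if windows else 24.0
    out = {}
    pmzs = {q.modseq: masses.precursor_mz(q.modseq, q.charge) for q in truth.peptides}
    for p in truth.peptides:
        pmz = pmzs[p.modseq]
        competitors = [
            q
            for q in truth.peptides
            if q.modseq != p.modseq and abs(pmzs[q.modseq] - pmz) < 1.5 * width
        ]
        mask = np.ones(p.fragment_mzs.size, dtype=bool)
        for k, fmz in enumerate(p.fragment_mzs):
            for q in competitors:
                if np.any(np.abs(q.fragment_mzs - fmz) <= fmz * tol_ppm * 1e-6):
                    mask[k] = False
                    break
        out[p.modseq] = mask
    return out
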