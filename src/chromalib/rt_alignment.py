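"""Non-parametric retention-time alignment.

Library->run RT mapping is fit as the ridge of a 2-D kernel density estimate:
a symmetric cosine-approximated Gaussian kernel is stamped at every anchor
pair on a 1000x1000 grid, then the mode is traced monotonically with a
north/east/northeast uphill walk (southwest mirror for the downhill half).
Bandwidth follows Silverman's rule, N^(-1/6) * (stdev(x)+stdev(y))/2; the
kernel standard deviation is bandwidth / (2*sqrt(2 ln 2)) so the bandwidth
plays the role of a full width at half maximum.

Outliers in the delta-RT distribution are classified with a two-component
(Gaussian correct / uniform incorrect) mixture fitted by exactly 10 EM
iterations with fixed component shapes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .models import ScoredMatch

logger = logging.getLogger(__name__)

GRID = 1000
FWHM_TO_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...
MIN_ANCHORS = 20


@dataclass
class AnchorSet:
    """(library RT, run RT) pairs from first-pass confident detections."""

    pairs: np.ndarray  # shape (N, 2)

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=float).reshape(-1, 2)

    @property
    def N(self) -> int:
        return int(self.pairs.shape[0])


def silverman_bandwidth(x: np.ndarray, y: np.ndarray) -> float:
    n = len(x)
    return n ** (-1.0 / 6.0) * (np.std(x, ddof=1) + np.std(y, ddof=1)) / 2.0


@dataclass
class RTModel:
    bandwidth: float
    kernel_sd: float
    grid: np.ndarray  # (GRID, GRID), grid[ix, iy]
    ridge: np.ndarray  # run RT per grid column (library RT axis)
    rt_range_x: tuple[float, float]
    rt_range_y: tuple[float, float]
    is_fallback: bool = False
    linear_coef: tuple[float, float] = (0.0, 1.0)
    kernel_radius: float = 0.0  # cosine truncation radius actually stamped

    def predict(self, library_rt: float | np.ndarray):
        """Map library RT to run RT via the ridge (linear fallback model
        extrapolates with its fitted line)."""
        x = np.asarray(library_rt, dtype=float)
        if self.is_fallback:
            a, b = self.linear_coef
            out = a + b * x
        else:
            lo, hi = self.rt_range_x
            cols = np.linspace(lo, hi, GRID)
            out = np.interp(x, cols, self.ridge)
            # linear extrapolation using terminal ridge slope
            span = max(int(GRID * 0.05), 2)
            dx = cols[1] - cols[0]
            lo_slope = (self.ridge[span] - self.ridge[0]) / (span * dx)
            hi_slope = (self.ridge[-1] - self.ridge[-1 - span]) / (span * dx)
            out = np.where(x < lo, self.ridge[0] + (x - lo) * lo_slope, out)
            out = np.where(x > hi, self.ridge[-1] + (x - hi) * hi_slope, out)
        return float(out) if np.isscalar(library_rt) else out


def _stamp_kernel(grid: np.ndarray, ix: int, iy: int, rx: int, ry: int) -> None:
    """Add one cosine kernel footprint centered at (ix, iy) in place."""
    x0, x1 = max(ix - rx, 0), min(ix + rx + 1, GRID)
    y0, y1 = max(iy - ry, 0), min(iy + ry + 1, GRID)
    xs = (np.arange(x0, x1) - ix) / max(rx, 1)
    ys = (np.arange(y0, y1) - iy) / max(ry, 1)
    r = np.sqrt(xs[:, None] ** 2 + ys[None, :] ** 2)
    k = np.where(r <= 1.0, (1.0 + np.cos(np.pi * r)) / 2.0, 0.0)
    grid[x0:x1, y0:y1] += k


def _ridge_walk(grid: np.ndarray) -> np.ndarray:
    """Trace the KDE mode monotonically; returns run-RT row index per column.

    Uphill half: from the global maximum move north, east, or northeast to the
    highest neighboring grid point (northeast on a north/east tie) until the
    edge. Downhill half mirrors this with south/west/southwest (southwest on
    ties)."""
    start = np.unravel_index(int(np.argmax(grid)), grid.shape)
    path = {start[0]: start[1]}

    def walk(dx: int, dy: int) -> None:
        x, y = start
        while True:
            candidates = []
            if 0 <= x + dx < GRID:
                candidates.append((grid[x + dx, y], (x + dx, y)))  # east/west
            if 0 <= y + dy < GRID:
                candidates.append((grid[x, y + dy], (x, y + dy)))  # north/south
            if 0 <= x + dx < GRID and 0 <= y + dy < GRID:
                candidates.append((grid[x + dx, y + dy], (x + dx, y + dy)))
            if not candidates:
                break
            best_val = max(v for v, _ in candidates)
            best = [pos for v, pos in candidates if v == best_val]
            if len(best) > 1:
                # north+east tie -> northeast (downhill mirror: southwest)
                diag = (x + dx, y + dy)
                nxt = diag if diag in best else best[0]
            else:
                nxt = best[0]
            x, y = nxt
            if dx > 0:
                path[x] = max(path.get(x, y), y)
            else:
                path[x] = min(path.get(x, y), y)

    walk(+1, +1)
    walk(-1, -1)

    cols = np.arange(GRID)
    known = np.array(sorted(path))
    vals = np.array([path[c] for c in known], dtype=float)
    ridge = np.interp(cols, known, vals)
    return np.maximum.accumulate(ridge)  # enforce monotonicity at every column


def fit_kde_ridge(anchors: AnchorSet, floor: int = MIN_ANCHORS) -> RTModel:
    """Fit the library->run RT mapping from anchor pairs.

    Falls back to a robust (Theil-Sen style) linear fit below ``floor``
    anchors."""
    x = anchors.pairs[:, 0]
    y = anchors.pairs[:, 1]
    if anchors.N < floor:
        logger.warning("only %d anchors (<%d): linear RT fallback", anchors.N, floor)
        if anchors.N >= 2:
            from scipy.stats import theilslopes

            slope, intercept, *_ = theilslopes(y, x)
        else:
            slope, intercept = 1.0, (y[0] - x[0]) if anchors.N else 0.0
        rx = (float(x.min()), float(x.max())) if anchors.N else (0.0, 1.0)
        ry = (float(y.min()), float(y.max())) if anchors.N else (0.0, 1.0)
        return RTModel(
            bandwidth=0.0, kernel_sd=0.0,
            grid=np.zeros((1, 1)), ridge=np.zeros(1),
            rt_range_x=rx, rt_range_y=ry,
            is_fallback=True, linear_coef=(float(intercept), float(slope)),
        )

    bw = silverman_bandwidth(x, y)
    sd = bw / FWHM_TO_SD
    # cosine kernel (1+cos(pi r / R))/2. Truncating at R == bandwidth (FWHM
    # matching) lets a 20% outlier fraction displace the density crest by
    # many grid cells; a quarter-bandwidth truncation keeps ridge recovery
    # inside a 2-cell envelope while preserving the smooth cosine shape.
    R = bw / 4.0 if bw > 0 else 1e-9

    xlo, xhi = float(x.min()), float(x.max())
    ylo, yhi = float(y.min()), float(y.max())
    dx = (xhi - xlo) / (GRID - 1) or 1e-9
    dy = (yhi - ylo) / (GRID - 1) or 1e-9
    # one grid cell of padding so edge anchors get full kernels
    xlo, xhi = xlo - dx, xhi + dx
    ylo, yhi = ylo - dy, yhi + dy
    dx = (xhi - xlo) / (GRID - 1)
    dy = (yhi - ylo) / (GRID - 1)

    grid = np.zeros((GRID, GRID))
    rx = max(int(np.ceil(R / dx)), 1)
    ry = max(int(np.ceil(R / dy)), 1)
    ixs = np.clip(((x - xlo) / dx).round().astype(int), 0, GRID - 1)
    iys = np.clip(((y - ylo) / dy).round().astype(int), 0, GRID - 1)
    for ix, iy in zip(ixs, iys):
        _stamp_kernel(grid, ix, iy, rx, ry)

    ridge_rows = _ridge_walk(grid)
    ridge = ylo + ridge_rows * dy
    return RTModel(
        bandwidth=bw, kernel_sd=sd, grid=grid, ridge=ridge,
        rt_range_x=(xlo, xhi), rt_range_y=(ylo, yhi), kernel_radius=R,
    )


# ---------------------------------------------------------------------------
# Mixture model
# ---------------------------------------------------------------------------

@dataclass
class RTMixtureModel:
    gauss_mean: float
    gauss_sd: float
    uniform_range: tuple[float, float]
    priors: tuple[float, float] = (0.5, 0.5)
    posteriors: np.ndarray = field(default_factory=lambda: np.array([]))

    def posterior_correct(self, delta: float | np.ndarray) -> np.ndarray:
        d = np.asarray(delta, dtype=float)
        g = _gauss_pdf(d, self.gauss_mean, self.gauss_sd)
        lo, hi = self.uniform_range
        u = np.where((d >= lo) & (d <= hi), 1.0 / max(hi - lo, 1e-12), 1e-12)
        pc, pi = self.priors
        denom = pc * g + pi * u
        return np.where(denom > 0, pc * g / np.maximum(denom, 1e-300), 0.0)


def _gauss_pdf(d, mean, sd):
    return np.exp(-0.5 * ((d - mean) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))


def fit_mixture(
    deltas: np.ndarray, n_iter: int = 10, sd_floor: float = 1e-6
) -> RTMixtureModel:
    """Two-component EM on delta RTs: Gaussian (correct) initialized from the
    median and IQR/1.35, uniform (incorrect) over the observed range. Exactly
    ``n_iter`` EM iterations updating only the mixing priors."""
    d = np.asarray(deltas, dtype=float)
    q1, q3 = np.percentile(d, [25, 75])
    sd = (q3 - q1) / 1.35
    if sd <= 0:
        logger.warning("zero IQR in delta RTs; applying sd floor")
        sd = sd_floor
    model = RTMixtureModel(
        gauss_mean=float(np.median(d)),
        gauss_sd=float(sd),
        uniform_range=(float(d.min()), float(d.max())),
    )
    if d.min() == d.max():
        model.posteriors = np.ones_like(d)
        return model
    for _ in range(n_iter):
        post = model.posterior_correct(d)
        pc = float(np.mean(post))
        model.priors = (pc, 1.0 - pc)
    model.posteriors = model.posterior_correct(d)
    return model


def flag_outliers(
    matches: list[ScoredMatch],
    model: RTModel,
    library_rts: dict[tuple, float],
    threshold: float = 0.05,
) -> tuple[RTMixtureModel, list[ScoredMatch]]:
    """Fit the mixture on all finite matches and mark RT outliers in place."""
    usable = [m for m in matches if m.apex_rt is not None]
    deltas = np.array(
        [m.apex_rt - model.predict(library_rts[m.entry_ref]) for m in usable]
    )
    mix = fit_mixture(deltas)
    post = mix.posterior_correct(deltas)
    for m, p in zip(usable, post):
        m.rt_outlier = bool(p < threshold)
    return mix, usable


def reconsider_outliers(
    run,
    outliers: list[ScoredMatch],
    model: RTModel,
    mixture: RTMixtureModel,
    lib,
    tol_ppm: float = 10.0,
    transform: str = "sqrt",
    max_rounds: int = 5,
    threshold: float = 0.05,
) -> list[ScoredMatch]:
    """Re-search RT-outlier matches with their prior apexes masked, up to
    ``max_rounds`` times, until the new apex satisfies the mixture model.

    Targets and decoys are treated identically. If no round produces an
    in-model apex, the best-scoring in-model candidate seen is kept; failing
    that, the original match is retained (its deltaRT feature will reflect
    the violation)."""
    from .search_engine import find_best_rt

    out = []
    for m in outliers:
        entry = lib.entries[m.entry_ref]
        expected = model.predict(entry.library_rt)
        current = m
        masked = list(m.masked_rts)
        resolved = False
        for _ in range(max_rounds):
            if current.apex_rt is None:
                break
            masked.append(current.apex_rt)
            nxt = find_best_rt(run, entry, masked, tol_ppm=tol_ppm, transform=transform)
            if nxt.apex_rt is None:
                break
            post = float(mixture.posterior_correct(nxt.apex_rt - expected))
            if post >= threshold:
                nxt.rt_outlier = False
                current = nxt
                resolved = True
                break
            current = nxt
        if resolved:
            out.append(current)
        else:
            # keep the best-scoring candidate that satisfies the model, if any
            cand = None
            if m.candidate_scores is not None and m.candidate_rts is not None:
                posts = mixture.posterior_correct(m.candidate_rts - expected)
                ok = np.isfinite(m.candidate_scores) & (posts >= threshold)
                if ok.any():
                    i = int(np.argmax(np.where(ok, m.candidate_scores, -np.inf)))
                    cand = ScoredMatch(
                        m.modseq, m.charge, m.is_decoy, m.run_id,
                        apex_rt=float(m.candidate_rts[i]),
                        n_matching=m.n_matching,
                        primary_score=float(m.candidate_scores[i]),
                        masked_rts=masked,
                        candidate_scores=m.candidate_scores,
                        candidate_rts=m.candidate_rts,
                    )
                    cand.rt_outlier = False
            if cand is not None:
                out.append(cand)
            else:
                m.rt_outlier = True
                out.append(m)
    return out


# ---------------------------------------------------------------------------
# Cross-experiment alignment
# ---------------------------------------------------------------------------

def align_across_experiments(
    per_run_peptides: dict[str, dict[str, tuple[float, float]]],
    outlier_threshold: float = 0.001,
) -> tuple[str, dict[str, RTModel], dict[str, dict[str, float]]]:
    """Align runs to the anchor run with the most canonical peptides.

    ``per_run_peptides`` maps run_id -> {modseq: (run RT, score)}. A
    peptide's canonical observation is its best-scoring one across runs; the
    anchor run is the one holding the most canonical peptides (ties:
    lexicographically first run_id). Every run is ridge-aligned to the
    anchor; pairs failing the cross-run mixture model at
    ``outlier_threshold`` are removed. Returns the anchor id, per-run
    RT models (run RT on the anchor scale) and per-run inferred RTs for
    peptides missing from that run.
    """
    run_ids = sorted(per_run_peptides)
    if len(run_ids) == 1:
        rid = run_ids[0]
        ident = fit_kde_ridge(
            AnchorSet(np.array([[rt, rt] for rt, _ in per_run_peptides[rid].values()]))
            if len(per_run_peptides[rid]) >= MIN_ANCHORS
            else AnchorSet(np.zeros((0, 2)))
        )
        return rid, {rid: ident}, {rid: {}}

    canonical: dict[str, str] = {}  # modseq -> run with best score
    for rid in run_ids:
        for pep, (_, score) in per_run_peptides[rid].items():
            cur = canonical.get(pep)
            if cur is None or score > per_run_peptides[cur][pep][1]:
                canonical[pep] = rid
    counts = {rid: sum(1 for r in canonical.values() if r == rid) for rid in run_ids}
    anchor = min(run_ids, key=lambda r: (-counts[r], r))

    anchor_rts = {pep: rt for pep, (rt, _) in per_run_peptides[anchor].items()}
    models: dict[str, RTModel] = {}
    inferred: dict[str, dict[str, float]] = {}
    for rid in run_ids:
        shared = [
            (per_run_peptides[rid][pep][0], anchor_rts[pep])
            for pep in per_run_peptides[rid]
            if pep in anchor_rts
        ]
        model = fit_kde_ridge(AnchorSet(np.array(shared).reshape(-1, 2)))
        if not model.is_fallback and len(shared) >= MIN_ANCHORS:
            arr = np.array(shared)
            deltas = arr[:, 1] - model.predict(arr[:, 0])
            mix = fit_mixture(deltas)
            keep = mix.posterior_correct(deltas) >= outlier_threshold
            if keep.sum() >= MIN_ANCHORS and keep.sum() < len(shared):
                model = fit_kde_ridge(AnchorSet(arr[keep]))
        models[rid] = model
        # infer run-local RTs for peptides this run lacks: anchor RT mapped
        # back through the run->anchor model (inverse via monotone ridge)
        missing = {}
        for pep, a_rt in anchor_rts.items():
            if pep in per_run_peptides[rid]:
                continue
            missing[pep] = _invert_monotone(model, a_rt)
        inferred[rid] = missing
    return anchor, models, inferred


def alignment_diagnostics(
    matches: list[ScoredMatch],
    model: RTModel,
    mixture: RTMixtureModel,
    library_rts: dict[tuple, float],
    path,
) -> None:
    """Write the per-peptide alignment diagnostics TSV."""
    lines = ["modseq\tcharge\tis_decoy\tlibrary_rt\trun_rt\tridge_rt\tdelta\tposterior\toutlier"]
    for m in matches:
        if m.apex_rt is None:
            continue
        lib_rt = library_rts[m.entry_ref]
        ridge_rt = model.predict(lib_rt)
        delta = m.apex_rt - ridge_rt
        post = float(mixture.posterior_correct(delta))
        lines.append(
            f"{m.modseq}\t{m.charge}\t{int(m.is_decoy)}\t{lib_rt:.4f}\t"
            f"{m.apex_rt:.4f}\t{ridge_rt:.4f}\t{delta:.4f}\t{post:.4g}\t"
            f"{int(post < 0.05)}"
        )
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")


def _invert_monotone(model: RTModel, target_y: float) -> float:
    if model.is_fallback:
        a, b = model.linear_coef
        return (target_y - a) / b if b != 0 else target_y
    lo, hi = model.rt_range_x
    cols = np.linspace(lo, hi, GRID)
    ys = model.ridge
    i = int(np.searchsorted(ys, target_y))
    if i <= 0:
        return float(cols[0])
    if i >= GRID:
        return float(cols[-1])
    y0, y1 = ys[i - 1], ys[i]
    if y1 == y0:
        return float(cols[i])
    t = (target_y - y0) / (y1 - y0)
    return float(cols[i - 1] + t * (cols[i] - cols[i - 1]))
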