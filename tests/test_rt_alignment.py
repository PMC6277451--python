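import numpy as np
import pytest

from chromalib.models import Library, LibraryEntry, ScoredMatch
from chromalib.rt_alignment import (
    GRID,
    AnchorSet,
    align_across_experiments,
    fit_kde_ridge,
    fit_mixture,
    flag_outliers,
    reconsider_outliers,
    silverman_bandwidth,
)
from chromalib.synthetic_data import monotone_cubic_warp


def scaled_to_std(rng, n, std):
    v = rng.normal(size=n)
    return v / v.std(ddof=1) * std


class TestBandwidth:
    def test_closed_form(self):
        rng = np.random.default_rng(0)
        x = scaled_to_std(rng, 64, 2.0)
        y = scaled_to_std(rng, 64, 2.0)
        assert silverman_bandwidth(x, y) == pytest.approx(1.0, abs=1e-12)

    def test_kernel_sd_relation(self):
        rng = np.random.default_rng(1)
        x = scaled_to_std(rng, 64, 2.0) + 5
        y = scaled_to_std(rng, 64, 2.0) + 5
        model = fit_kde_ridge(AnchorSet(np.c_[x, y]))
        assert model.bandwidth == pytest.approx(1.0, abs=1e-12)
        assert model.kernel_sd == pytest.approx(1.0 / 2.35482, abs=1e-4)


class TestRidge:
    def test_identity_line(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, 200)
        model = fit_kde_ridge(AnchorSet(np.c_[x, x]))
        cols = np.linspace(*model.rt_range_x, GRID)
        cell = (model.rt_range_y[1] - model.rt_range_y[0]) / (GRID - 1)
        inner = (cols > 0.5) & (cols < 9.5)
        err = np.abs(model.ridge[inner] - cols[inner])
        assert np.max(err) <= 3 * cell

    def test_monotone_everywhere(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 10, 150)
            y = np.sort(rng.uniform(0, 8, 150))[np.argsort(np.argsort(x))]
            model = fit_kde_ridge(AnchorSet(np.c_[x, y]))
            assert np.all(np.diff(model.ridge) >= 0)

    def test_cubic_warp_with_outliers(self):
        rng = np.random.default_rng(3)
        warp = monotone_cubic_warp(0.3, 1.0, 0.001)
        n = 500
        x = np.sort(rng.uniform(0, 10, n))
        y = np.array([warp(v) for v in x])
        out_idx = rng.choice(n, n // 5, replace=False)  # 20% outliers
        y[out_idx] = rng.uniform(y.min(), y.max(), n // 5)
        model = fit_kde_ridge(AnchorSet(np.c_[x, y]))
        cols = np.linspace(*model.rt_range_x, GRID)
        cell = (model.rt_range_y[1] - model.rt_range_y[0]) / (GRID - 1)
        truth = np.array([warp(v) for v in cols])
        ok = np.abs(model.ridge - truth) <= 2 * cell
        assert ok.mean() >= 0.95
        assert np.all(np.diff(model.ridge) >= 0)

    def test_mass_conservation(self):
        """Grid mass ~= N x single-kernel mass; edge truncation tolerated."""
        rng = np.random.default_rng(4)
        # interior anchors plus two extremes that define the range
        x = np.concatenate([[0.0, 10.0], rng.uniform(3, 7, 200)])
        y = np.concatenate([[0.0, 10.0], rng.uniform(3, 7, 200)])
        model = fit_kde_ridge(AnchorSet(np.c_[x, y]))
        # recompute one centered kernel on the same grid geometry
        from chromalib.rt_alignment import _stamp_kernel

        g = np.zeros((GRID, GRID))
        dx = (model.rt_range_x[1] - model.rt_range_x[0]) / (GRID - 1)
        dy = (model.rt_range_y[1] - model.rt_range_y[0]) / (GRID - 1)
        rx = max(int(np.ceil(model.kernel_radius / dx)), 1)
        ry = max(int(np.ceil(model.kernel_radius / dy)), 1)
        _stamp_kernel(g, GRID // 2, GRID // 2, rx, ry)
        expected = len(x) * g.sum()
        assert model.grid.sum() == pytest.approx(expected, rel=0.01)

    def test_fallback_below_floor(self, caplog):
        x = np.array([1.0, 2.0, 3.0])
        y = 2 * x + 1
        with caplog.at_level("WARNING"):
            model = fit_kde_ridge(AnchorSet(np.c_[x, y]))
        assert model.is_fallback
        assert model.predict(4.0) == pytest.approx(9.0, abs=1e-9)

    def test_extrapolation_continues_linearly(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(2, 8, 300)
        model = fit_kde_ridge(AnchorSet(np.c_[x, x]))
        lo = model.predict(0.0)
        hi = model.predict(10.0)
        assert lo == pytest.approx(0.0, abs=0.5)
        assert hi == pytest.approx(10.0, abs=0.5)


class TestMixture:
    def test_sd_closed_form(self):
        deltas = np.array([-0.675] * 50 + [0.675] * 50)
        model = fit_mixture(deltas)
        assert model.gauss_sd == pytest.approx(1.35 / 1.35, abs=1e-9)

    def test_identical_deltas_no_outliers(self, caplog):
        with caplog.at_level("WARNING"):
            model = fit_mixture(np.full(100, 0.25))
        assert np.all(model.posteriors >= 0.05)

    def test_prior_initial_and_iterations(self):
        rng = np.random.default_rng(6)
        d = rng.normal(0, 0.1, 500)
        model = fit_mixture(d)
        assert model.priors[0] + model.priors[1] == pytest.approx(1.0)

    def test_recovery_80_20(self):
        sens, spec, pis = [], [], []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            n = 1000
            correct = rng.random(n) < 0.8
            d = np.where(
                correct, rng.normal(0, 0.1, n), rng.uniform(-10, 10, n)
            )
            model = fit_mixture(d)
            flagged = model.posteriors < 0.05
            # an outlier drawn inside the tight central band is
            # indistinguishable by construction; exclude |d| < 3 sd
            amb = (~correct) & (np.abs(d) < 0.3)
            sens.append(flagged[~correct & ~amb].mean())
            spec.append((~flagged[correct]).mean())
            pis.append(model.priors[0])
        assert np.mean(sens) >= 0.9
        assert np.mean(spec) >= 0.9
        assert abs(np.mean(pis) - 0.8) <= 0.05


class TestReconsider:
    def _setup(self):
        """Entry whose top score is an off-ridge interference point; the
        true (in-model) peak is second best."""
        from conftest import make_spectrum
        from chromalib import masses
        from chromalib.models import DIARun

        seq = "LNDQEGFTK"
        mzs = sorted(
            masses.fragment_mz(seq, masses.FragmentAnnotation("Y", i, 1))
            for i in (3, 4, 5, 6)
        )
        e = LibraryEntry(
            seq, 2, masses.precursor_mz(seq, 2), library_rt=2.0,
            fragment_mzs=np.array(mzs), fragment_intensities=np.ones(4),
        )
        spectra = []
        # true peak at rt 2.0 (height 50), interference at rt 5.0 (height 500)
        for i, rt in enumerate(np.arange(0.5, 6.5, 0.1)):
            h = 50 * np.exp(-0.5 * ((rt - 2.0) / 0.1) ** 2) + 500 * np.exp(
                -0.5 * ((rt - 5.0) / 0.1) ** 2
            )
            peaks = list(mzs) + [700.0]
            heights = [h, h, h, h, 1000.0]
            spectra.append(
                make_spectrum(peaks, heights, rt=rt, center=e.precursor_mz,
                              width=24.0, scan_id=f"s{i}")
            )
        run = DIARun(
            "r", spectra, [(e.precursor_mz - 12, e.precursor_mz + 12)]
        )
        lib = Library()
        lib.add(e)
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 6, 100)
        model = fit_kde_ridge(AnchorSet(np.c_[x, x]))  # identity ridge
        mixture = fit_mixture(rng.normal(0, 0.05, 400))
        return run, lib, e, model, mixture

    def test_interference_corrected_to_true_apex(self):
        from chromalib.search_engine import find_best_rt

        run, lib, e, model, mixture = self._setup()
        m = find_best_rt(run, e)
        assert abs(m.apex_rt - 5.0) < 0.2  # fooled by interference
        m.rt_outlier = True
        out = reconsider_outliers(run, [m], model, mixture, lib)
        assert abs(out[0].apex_rt - 2.0) < 0.2

    def test_absent_peptide_stays_unmatched(self):
        from chromalib.search_engine import find_best_rt
        from chromalib import masses

        run, lib, e, model, mixture = self._setup()
        ghost = LibraryEntry(
            "GHSTWNPEK", 2, e.precursor_mz + 1.0, library_rt=2.0,
            fragment_mzs=np.array([345.6, 456.7, 567.8]),
            fragment_intensities=np.ones(3),
        )
        lib.add(ghost)
        m = find_best_rt(run, ghost)
        assert m.apex_rt is None or not np.isfinite(m.primary_score)
        m.rt_outlier = True
        out = reconsider_outliers(run, [m], model, mixture, lib)
        assert out[0].apex_rt is None

    def test_decoys_processed_identically(self):
        run, lib, e, model, mixture = self._setup()
        matches = [
            ScoredMatch(e.peptide_modseq, 2, False, "r", 5.0, 4, 1.0),
            ScoredMatch(e.peptide_modseq, 2, False, "r", 5.0, 4, 1.0),
        ]
        matches[1].is_decoy = False
        lib.add(e)
        out = reconsider_outliers(run, matches, model, mixture, lib)
        assert len(out) == len(matches)


def test_alignment_diagnostics_tsv(tmp_path):
    from chromalib.rt_alignment import alignment_diagnostics

    rng = np.random.default_rng(11)
    x = rng.uniform(0, 10, 100)
    model = fit_kde_ridge(AnchorSet(np.c_[x, x]))
    mixture = fit_mixture(rng.normal(0, 0.05, 200))
    matches = [
        ScoredMatch("AAAPEPK", 2, False, "r", apex_rt=3.0, n_matching=5,
                    primary_score=4.0),
        ScoredMatch("CCCPEPK", 2, True, "r", apex_rt=8.0, n_matching=5,
                    primary_score=1.0),
    ]
    lib_rts = {m.entry_ref: 3.0 for m in matches}
    p = tmp_path / "diag.tsv"
    alignment_diagnostics(matches, model, mixture, lib_rts, p)
    lines = p.read_text().strip().splitlines()
    assert lines[0].split("\t") == [
        "modseq", "charge", "is_decoy", "library_rt", "run_rt", "ridge_rt",
        "delta", "posterior", "outlier",
    ]
    assert len(lines) == 3
    on_ridge = lines[1].split("\t")
    off_ridge = lines[2].split("\t")
    assert on_ridge[-1] == "0"  # apex == ridge prediction: not an outlier
    assert off_ridge[-1] == "1"  # 5 min off a tight model: outlier


class TestAcrossExperiments:
    def test_single_run_identity(self):
        rng = np.random.default_rng(8)
        peps = {f"P{i}K": (float(rng.uniform(1, 9)), 1.0) for i in range(50)}
        anchor, models, inferred = align_across_experiments({"run1": peps})
        assert anchor == "run1"
        assert inferred == {"run1": {}}

    def test_anchor_identity_ridge(self):
        rng = np.random.default_rng(9)
        base = {f"P{i}K": float(rng.uniform(1, 9)) for i in range(120)}
        warp2 = monotone_cubic_warp(0.5, 1.05, 0.002)
        runs = {
            "a": {p: (rt, 10.0) for p, rt in base.items()},
            "b": {p: (warp2(rt), 5.0) for p, rt in base.items()},
        }
        anchor, models, inferred = align_across_experiments(runs)
        assert anchor == "a"  # holds all canonical peptides
        for p, rt in list(base.items())[:20]:
            assert models["a"].predict(rt) == pytest.approx(rt, abs=0.1)

    def test_tie_lexicographic(self):
        runs = {
            "b": {f"P{i}K": (1.0 + i * 0.1, 1.0) for i in range(30)},
            "a": {f"Q{i}K": (1.0 + i * 0.1, 1.0) for i in range(30)},
        }
        anchor, _, _ = align_across_experiments(runs)
        assert anchor == "a"

    def test_inferred_rts_recover_truth(self):
        rng = np.random.default_rng(10)
        base = {f"P{i}K": float(rng.uniform(0.5, 9.5)) for i in range(300)}
        warps = {
            "a": lambda t: t,
            "b": monotone_cubic_warp(0.3, 1.02, 0.003),
            "c": monotone_cubic_warp(-0.2, 0.98, 0.005),
        }
        runs = {}
        held_out = {}
        for rid, warp in warps.items():
            obs = {}
            for j, (p, rt) in enumerate(base.items()):
                if j % 5 == (ord(rid) % 5):  # hold out 20% per run
                    held_out.setdefault(rid, {})[p] = warp(rt)
                else:
                    obs[p] = (warp(rt), float(rng.uniform(1, 10)))
            runs[rid] = obs
        anchor, models, inferred = align_across_experiments(runs)
        total, good = 0, 0
        for rid, missing in held_out.items():
            rt_span = 10.0
            tol = 3 * rt_span / GRID + 0.05
            for p, true_rt in missing.items():
                if p in inferred[rid]:
                    total += 1
                    if abs(inferred[rid][p] - true_rt) <= tol:
                        good += 1
        assert total >= 100
        assert good / total >= 0.95
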