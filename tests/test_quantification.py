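import numpy as np
import pytest

from chromalib import masses
from chromalib.models import DIARun, LibraryEntry, ProteinGroup, ScoredMatch
from chromalib.quantification import (
    PeakBoundaries,
    QuantRecord,
    TransitionTrace,
    extract_traces,
    integrate,
    interference_score,
    protein_quant,
    quantify_match,
    refine_transitions,
    select_transitions_study,
    study_filters,
)

from conftest import make_spectrum


def gauss_trace(rts, mu, sd, height, fid=("Y", 3, 1)):
    vals = height * np.exp(-0.5 * ((rts - mu) / sd) ** 2)
    return TransitionTrace(fragment_id=fid, rts=rts, raw=vals)


class TestIntegrate:
    def test_triangle_closed_form(self):
        assert integrate(np.array([0.0, 1, 2, 1, 0])) == pytest.approx(4.0)

    def test_background_rectangle_removed(self):
        # same peak on a pedestal of 1: trapezoid 8, rectangle 4*1 -> 4
        assert integrate(np.array([1.0, 2, 3, 2, 1])) == pytest.approx(4.0)

    def test_flat_trace_zero(self):
        assert integrate(np.array([1.0, 1, 1, 1, 1])) == 0.0

    def test_negative_floored(self):
        assert integrate(np.array([5.0, 1, 1, 1, 5.0])) == 0.0

    def test_linearity(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 10, 21)
        a = integrate(v)
        assert integrate(7.0 * v) == pytest.approx(7.0 * a, rel=1e-12)

    def test_rt_spacing_respected(self):
        v = np.array([0.0, 1, 2, 1, 0])
        rts = np.arange(5) * 2.0
        assert integrate(v, rts=rts) == pytest.approx(8.0)


class TestRefine:
    def test_identical_traces_all_quantitative(self):
        rts = np.linspace(0, 1, 31)
        traces = [gauss_trace(rts, 0.5, 0.1, h, fid=("Y", i, 1))
                  for i, h in enumerate([10, 20, 30, 40, 50], start=3)]
        boundaries, refined = refine_transitions(traces)
        assert boundaries is not None
        for tr in refined:
            assert tr.correlation == pytest.approx(1.0, abs=1e-9)
            assert tr.status == "quantitative"
        # boundaries symmetric about the apex
        assert 0.5 - boundaries.left_rt == pytest.approx(
            boundaries.right_rt - 0.5, abs=0.05
        )

    def test_interfered_trace_flagged(self):
        rts = np.linspace(0, 1, 31)
        traces = [gauss_trace(rts, 0.5, 0.1, 30, fid=("Y", i, 1)) for i in range(3, 7)]
        bad = gauss_trace(rts, 0.5, 0.1, 30, fid=("Y", 9, 1))
        bad.raw = bad.raw + gauss_trace(rts, 0.75, 0.1, 30).raw  # coeluting bump
        traces.append(bad)
        boundaries, refined = refine_transitions(traces)
        statuses = {tr.fragment_id: tr.status for tr in refined}
        assert statuses[("Y", 9, 1)] != "quantitative"
        for i in range(3, 7):
            assert statuses[("Y", i, 1)] == "quantitative"

    def test_one_percent_floor_sets_boundary(self):
        from chromalib.quantification import _trace_boundaries

        shape = np.array([0.004, 0.3, 1.0, 0.3, 0.004, 0.2, 0.4])
        li, ri = _trace_boundaries(shape)
        assert li == 0  # 0.004 < 1% of max
        assert ri == 4

    def test_rise_over_two_spectra_sets_boundary(self):
        from chromalib.quantification import _trace_boundaries

        shape = np.array([0.9, 0.8, 0.7, 0.2, 1.0, 0.7, 0.6, 0.5])
        li, ri = _trace_boundaries(shape)
        assert li == 3  # minimum before >2 consecutive rises going left
        assert ri == 7  # right side falls monotonically to the edge

    def test_fewer_than_two_signals_non_quantifiable(self):
        rts = np.linspace(0, 1, 11)
        traces = [
            gauss_trace(rts, 0.5, 0.1, 10),
            TransitionTrace(("Y", 4, 1), rts, np.zeros(11)),
        ]
        boundaries, _ = refine_transitions(traces)
        assert boundaries is None

    def test_permutation_invariant(self):
        rts = np.linspace(0, 1, 31)
        traces = [gauss_trace(rts, 0.5, 0.08 + 0.01 * i, 10 + i, fid=("Y", i, 1))
                  for i in range(3, 9)]
        _, ref1 = refine_transitions([t for t in traces])
        shuffled = [traces[i] for i in (3, 0, 5, 1, 4, 2)]
        _, ref2 = refine_transitions(shuffled)
        s1 = {t.fragment_id: t.status for t in ref1}
        s2 = {t.fragment_id: t.status for t in ref2}
        assert s1 == s2


class TestInterferenceScore:
    def test_kept_at_tenth(self):
        s = interference_score(np.array([10.0, 100.0]), np.array([0.5, 0.95]))
        assert s == pytest.approx(0.1)
        assert s <= 0.2

    def test_dropped_at_three_tenths(self):
        s = interference_score(np.array([30.0, 100.0]), np.array([0.5, 0.95]))
        assert s == pytest.approx(0.3)
        assert s > 0.2


def record(modseq, run_id, tids, areas, corrs, charge=2):
    return QuantRecord(
        modseq=modseq, charge=charge, run_id=run_id, transition_ids=tids,
        areas=np.asarray(areas, dtype=float),
        correlations=np.asarray(corrs, dtype=float),
    )


class TestSelectTransitions:
    TIDS = [("Y", i, 1) for i in range(3, 9)]

    def test_interfered_transition_dropped_study_wide(self):
        recs = [
            record("AAAPEPK", "r1", self.TIDS[:4], [100, 100, 100, 30],
                   [0.95, 0.95, 0.95, 0.5]),
            record("AAAPEPK", "r2", self.TIDS[:4], [100, 100, 100, 100],
                   [0.95, 0.95, 0.95, 0.95]),
        ]
        out = select_transitions_study(recs)
        # interference score of last transition = 30/100 = 0.3 > 0.2: dropped
        assert out[("AAAPEPK", 2)]["r1"] == pytest.approx(300.0)
        assert out[("AAAPEPK", 2)]["r2"] == pytest.approx(300.0)

    def test_mild_interference_kept(self):
        recs = [
            record("AAAPEPK", "r1", self.TIDS[:4], [100, 100, 100, 10],
                   [0.95, 0.95, 0.95, 0.5]),
            record("AAAPEPK", "r2", self.TIDS[:4], [100, 100, 100, 100],
                   [0.95, 0.95, 0.95, 0.95]),
        ]
        out = select_transitions_study(recs)
        assert out[("AAAPEPK", 2)]["r2"] == pytest.approx(400.0)

    def test_top_five_rule(self):
        recs = [
            record("AAAPEPK", "r1", self.TIDS, [10, 20, 30, 40, 50, 60],
                   [0.99, 0.98, 0.97, 0.96, 0.95, 0.94])
        ]
        out = select_transitions_study(recs)
        # five highest rank scores: the first five by correlation sum
        assert out[("AAAPEPK", 2)]["r1"] == pytest.approx(10 + 20 + 30 + 40 + 50)

    def test_fewer_than_three_quantitative_excluded(self):
        recs = [
            record("AAAPEPK", "r1", self.TIDS[:3], [100, 100, 100],
                   [0.95, 0.95, 0.5]),
        ]
        out = select_transitions_study(recs)
        assert ("AAAPEPK", 2) not in out


class TestStudyFilters:
    DESIGN = {"c0r0": "c0", "c0r1": "c0", "c1r0": "c1", "c1r1": "c1"}

    def test_high_cv_dropped(self):
        q = {("AAAPEPK", 2): {"c0r0": 100, "c0r1": 300, "c1r0": 100, "c1r1": 300}}
        df = study_filters(q, self.DESIGN)
        assert df.empty

    def test_low_cv_kept(self):
        q = {("AAAPEPK", 2): {"c0r0": 100, "c0r1": 102, "c1r0": 200, "c1r1": 205}}
        # per-condition centering removes the condition effect before the CV
        df = study_filters(q, self.DESIGN)
        assert len(df) == 1

    def test_missing_replicate_everywhere_dropped(self):
        q = {("AAAPEPK", 2): {"c0r0": 100, "c1r0": 100}}
        df = study_filters(q, self.DESIGN)
        assert df.empty

    def test_backfill_rescues(self):
        q = {("AAAPEPK", 2): {"c0r0": 100, "c1r0": 99}}
        backfill = {("AAAPEPK", 2): {"c0r1": 101}}
        assert study_filters(q, self.DESIGN).empty
        assert len(study_filters(q, self.DESIGN, backfill=backfill)) == 1


class TestProteinQuant:
    def _matrix(self):
        import pandas as pd

        idx = pd.MultiIndex.from_tuples(
            [("AAAK", 2), ("CCCK", 2), ("DDDK", 2), ("SHAREDK", 2)],
            names=["modseq", "charge"],
        )
        return pd.DataFrame(
            {"r1": [100.0, 200.0, 300.0, 50.0]}, index=idx
        )

    def test_sum_of_unique_peptides(self):
        groups = [
            ProteinGroup(frozenset({"A"}), {"AAAK", "CCCK", "DDDK"}, 3.0, 0.01),
        ]
        out = protein_quant(self._matrix(), groups)
        assert out.loc["A", "r1"] == pytest.approx(600.0)

    def test_shared_peptide_contributes_to_neither(self):
        groups = [
            ProteinGroup(frozenset({"A"}), {"AAAK", "SHAREDK"}, 2.0, 0.01),
            ProteinGroup(frozenset({"B"}), {"CCCK", "SHAREDK"}, 2.0, 0.01),
        ]
        out = protein_quant(self._matrix(), groups)
        assert out.loc["A", "r1"] == pytest.approx(100.0)
        assert out.loc["B", "r1"] == pytest.approx(200.0)

    def test_group_without_unique_peptides_absent(self):
        groups = [
            ProteinGroup(frozenset({"A"}), {"SHAREDK"}, 1.0, 0.01),
            ProteinGroup(frozenset({"B"}), {"SHAREDK"}, 1.0, 0.01),
        ]
        out = protein_quant(self._matrix(), groups)
        assert out.empty


class TestExtractTraces:
    def _run_with_peak(self, mu=2.0, sd=0.1):
        seq = "LNDQEGFTK"
        mzs = sorted(
            masses.fragment_mz(seq, masses.FragmentAnnotation("Y", i, 1))
            for i in (3, 4, 5)
        )
        e = LibraryEntry(
            seq, 2, masses.precursor_mz(seq, 2), 2.0,
            fragment_mzs=np.array(mzs), fragment_intensities=np.ones(3),
        )
        spectra = [
            make_spectrum(
                mzs, [100 * np.exp(-0.5 * ((rt - mu) / sd) ** 2)] * 3,
                rt=rt, center=e.precursor_mz, width=24.0, scan_id=f"s{i}",
            )
            for i, rt in enumerate(np.arange(1.0, 3.0, 0.05))
        ]
        run = DIARun("r", spectra, [(e.precursor_mz - 12, e.precursor_mz + 12)])
        return run, e

    def test_apex_recovered(self):
        run, e = self._run_with_peak()
        m = ScoredMatch(e.peptide_modseq, 2, False, "r", apex_rt=2.0,
                        n_matching=3, primary_score=5.0)
        traces = refine_transitions(extract_traces(run, m, e))[1]
        for tr in traces:
            assert tr.rts[np.argmax(tr.raw)] == pytest.approx(2.0, abs=0.051)

    def test_absent_fragment_all_zero(self):
        run, e = self._run_with_peak()
        e2 = LibraryEntry(
            e.peptide_modseq, 2, e.precursor_mz, 2.0,
            fragment_mzs=np.array([777.777]),
            fragment_intensities=np.ones(1),
        )
        m = ScoredMatch(e.peptide_modseq, 2, False, "r", apex_rt=2.0,
                        n_matching=1, primary_score=5.0)
        traces = extract_traces(run, m, e2)
        assert np.all(traces[0].raw == 0.0)

    def test_two_bumps_visible(self):
        run, e = self._run_with_peak()
        # add a second elution bump of a shared fragment at rt 2.4
        for s in run.spectra:
            bump = 80 * np.exp(-0.5 * ((s.rt - 2.4) / 0.1) ** 2)
            s.intensities = s.intensities + bump
        m = ScoredMatch(e.peptide_modseq, 2, False, "r", apex_rt=2.0,
                        n_matching=3, primary_score=5.0)
        traces = extract_traces(run, m, e, rt_halfwidth=0.6)
        raw = traces[0].raw
        rts = traces[0].rts
        assert raw[np.argmin(np.abs(rts - 2.4))] > raw[np.argmin(np.abs(rts - 2.2))]

    def test_no_spectra_in_range_empty(self):
        run, e = self._run_with_peak()
        m = ScoredMatch(e.peptide_modseq, 2, False, "r", apex_rt=9.0,
                        n_matching=3, primary_score=5.0)
        assert extract_traces(run, m, e) == []


class TestQuantifyMatch:
    def test_areas_scale_with_abundance(self):
        rts = np.linspace(0, 1, 31)
        base = [gauss_trace(rts, 0.5, 0.1, h, fid=("Y", i, 1))
                for i, h in enumerate([10, 20, 30], start=3)]
        b1, r1 = refine_transitions([TransitionTrace(t.fragment_id, t.rts, t.raw)
                                     for t in base])
        b2, r2 = refine_transitions([TransitionTrace(t.fragment_id, t.rts, 3 * t.raw)
                                     for t in base])
        a1 = np.array([integrate(t, boundaries=b1) for t in r1])
        a2 = np.array([integrate(t, boundaries=b2) for t in r2])
        np.testing.assert_allclose(a2, 3 * a1, rtol=1e-9)
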