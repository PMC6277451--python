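"""End-to-end workflows: chromatogram-library building, two-pass search with
retention-time reconsideration, and study-level quantification."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .library_builder import (
    add_decoys,
    build_background,
    build_chromatogram_library,
)
from .models import DIARun, Library, ScoredMatch
from .rt_alignment import (
    AnchorSet,
    MIN_ANCHORS,
    fit_kde_ridge,
    flag_outliers,
    reconsider_outliers,
)
from .search_engine import feature_scores, search_run
from .validation import (
    global_peptide_fdr,
    parsimonious_proteins,
    rescore,
)
from .quantification import (
    quantify_match,
    select_transitions_study,
    study_filters,
    protein_quant,
)

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Tolerances and thresholds for one study; defaults follow the engine's
    standard settings (10 ppm tolerances, 1% FDRs, 0.9/0.75 correlation
    gates, 0.2 interference ceiling, 20% CV, 3-5 transitions)."""

    precursor_tol_ppm: float = 10.0
    fragment_tol_ppm: float = 10.0
    library_tol_ppm: float = 10.0
    peptide_fdr: float = 0.01
    protein_fdr: float = 0.01
    r_quant: float = 0.9
    r_detect: float = 0.75
    interference_max: float = 0.2
    cv_max: float = 0.20
    min_transitions: int = 3
    max_transitions: int = 5
    score_transform: str = "sqrt"
    rt_reconsider_rounds: int = 5
    backfill: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("peptide_fdr", "protein_fdr", "r_quant", "r_detect", "cv_max"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass
class SearchReport:
    entries_scored: int = 0
    anchors: int = 0
    outliers_reconsidered: int = 0
    passing_pass1: int = 0
    passing_pass2: int = 0
    stage_counts: dict = field(default_factory=dict)


def _backgrounds(run: DIARun, lib: Library):
    return {
        wi: build_background(lib, window)
        for wi, window in enumerate(run.window_scheme)
    }


def search_run_two_pass(
    run: DIARun, lib: Library, cfg: StudyConfig
) -> tuple[list[ScoredMatch], SearchReport]:
    """The two-pass loop: score everything, validate, fit the RT model on 1%
    FDR anchors, reconsider RT outliers (up to five times), refresh deltaRT,
    and hand the curated features back for final validation."""
    report = SearchReport()
    if not any(not e.is_decoy for e in lib) or not run.spectra:
        return [], report
    if not lib.decoys():
        add_decoys(lib)
    bgs = _backgrounds(run, lib)

    matches = search_run(
        run, lib, bg_by_window=bgs,
        tol_ppm=cfg.fragment_tol_ppm, transform=cfg.score_transform,
    )
    report.entries_scored = len(matches)

    validated = rescore(matches, seed=cfg.seed)
    q_by_key = {(v.modseq, v.charge, v.is_decoy): v.q_value for v in validated}
    anchors = [
        (lib.entries[m.entry_ref].library_rt, m.apex_rt)
        for m in matches
        if not m.is_decoy
        and m.apex_rt is not None
        and q_by_key.get(m.entry_ref, 1.0) <= cfg.peptide_fdr
    ]
    report.passing_pass1 = len(anchors)

    rt_model = None
    if len(anchors) >= 3:
        rt_model = fit_kde_ridge(AnchorSet(np.array(anchors)))
        library_rts = {m.entry_ref: lib.entries[m.entry_ref].library_rt for m in matches}
        mixture, usable = flag_outliers(matches, rt_model, library_rts)
        outliers = [m for m in usable if m.rt_outlier]
        report.anchors = len(anchors)
        report.outliers_reconsidered = len(outliers)
        changed_refs = set()
        if outliers:
            fixed = reconsider_outliers(
                run, outliers, rt_model, mixture, lib,
                tol_ppm=cfg.fragment_tol_ppm, transform=cfg.score_transform,
                max_rounds=cfg.rt_reconsider_rounds,
            )
            by_ref = {m.entry_ref: m for m in fixed}
            new_matches = []
            for m in matches:
                repl = by_ref.get(m.entry_ref, m)
                if repl is not m and repl.apex_rt != m.apex_rt:
                    changed_refs.add(m.entry_ref)
                new_matches.append(repl)
            matches = new_matches
        # deltaRT is now defined for everyone; full feature refresh is only
        # needed where the apex moved
        for m in matches:
            entry = lib.entries[m.entry_ref]
            if m.entry_ref in changed_refs:
                wis = run.window_index_for_mz(entry.precursor_mz)
                bg = bgs.get(wis[0]) if wis else None
                m.features = feature_scores(
                    run, entry, m, bg=bg, rt_model=rt_model,
                    tol_ppm=cfg.fragment_tol_ppm, transform=cfg.score_transform,
                )
            elif m.apex_rt is not None and m.features:
                m.features["deltaRT"] = abs(
                    m.apex_rt - rt_model.predict(entry.library_rt)
                )
    return matches, report


def run_build_library(
    narrow_runs: list[DIARun], seed_lib: Library, cfg: StudyConfig
) -> tuple[Library, dict]:
    """Narrow-window runs -> validated detections -> chromatogram library."""
    all_matches: list[list[ScoredMatch]] = []
    per_run: dict[str, list[ScoredMatch]] = {}
    for run in narrow_runs:
        matches, _ = search_run_two_pass(run, seed_lib, cfg)
        all_matches.append(matches)
        per_run[run.run_id] = matches
    if not all_matches or not any(all_matches):
        logger.error("no narrow-window matches; empty library")
        return Library(), {"peptides": 0}
    validated = global_peptide_fdr(all_matches, seed=cfg.seed)
    passing_keys = {
        (v.modseq, v.charge)
        for v in validated
        if not v.is_decoy and v.q_value <= cfg.peptide_fdr
    }
    passing_matches = [
        m
        for matches in all_matches
        for m in matches
        if not m.is_decoy and (m.modseq, m.charge) in passing_keys
    ]
    chroma = build_chromatogram_library(
        passing_matches, narrow_runs, seed_lib,
        min_fragments=cfg.min_transitions,
        detect_corr=cfg.r_detect,
        tol_ppm=cfg.fragment_tol_ppm,
    )
    chroma.protein_map = dict(seed_lib.protein_map)
    return chroma, {"peptides": len(chroma.targets()), "passing_keys": len(passing_keys)}


def run_search(
    runs: list[DIARun], lib: Library, cfg: StudyConfig
) -> tuple[dict[str, list[ScoredMatch]], list, dict]:
    """Search every quantitative run and validate globally."""
    per_run: dict[str, list[ScoredMatch]] = {}
    reports = {}
    for run in runs:
        matches, rep = search_run_two_pass(run, lib, cfg)
        per_run[run.run_id] = matches
        reports[run.run_id] = rep
    validated = global_peptide_fdr(list(per_run.values()), seed=cfg.seed)
    return per_run, validated, reports


def run_quantify(
    runs: list[DIARun],
    lib: Library,
    per_run: dict[str, list[ScoredMatch]],
    validated,
    design: dict[str, str],
    cfg: StudyConfig,
) -> dict:
    """Global FDR -> protein groups -> extract/refine/integrate -> study
    transition selection and filters -> peptide and protein matrices."""
    passing = {
        (v.modseq, v.charge)
        for v in validated
        if not v.is_decoy and v.q_value <= cfg.peptide_fdr
    }
    groups, unmapped = parsimonious_proteins(
        validated, lib.protein_map,
        peptide_q=cfg.peptide_fdr, protein_q=cfg.protein_fdr,
    )
    runs_by_id = {r.run_id: r for r in runs}
    records = []
    quantified: set[tuple[str, str]] = set()  # (modseq, run_id)
    for run_id, matches in per_run.items():
        run = runs_by_id[run_id]
        for m in matches:
            if m.is_decoy or m.apex_rt is None:
                continue
            if (m.modseq, m.charge) not in passing:
                continue
            entry = lib.entries[m.entry_ref]
            rec = quantify_match(run, m, entry, tol_ppm=cfg.fragment_tol_ppm)
            if rec is not None:
                records.append(rec)
                quantified.add((m.modseq, run_id))

    if cfg.backfill and len(runs) > 1:
        # cross-run RT alignment recovers quantities for peptides that were
        # detected in some runs but not others
        from .rt_alignment import MIN_ANCHORS, align_across_experiments

        charge_of = {ms: ch for ms, ch in passing}
        per_run_pep: dict[str, dict[str, tuple[float, float]]] = {}
        for run_id, matches in per_run.items():
            d: dict[str, tuple[float, float]] = {}
            for m in matches:
                if m.is_decoy or m.apex_rt is None:
                    continue
                if (m.modseq, m.charge) not in passing:
                    continue
                cur = d.get(m.modseq)
                if cur is None or m.primary_score > cur[1]:
                    d[m.modseq] = (m.apex_rt, m.primary_score)
            per_run_pep[run_id] = d
        if all(len(d) >= MIN_ANCHORS for d in per_run_pep.values()):
            _, _, inferred = align_across_experiments(per_run_pep)
            for run_id, missing in inferred.items():
                run = runs_by_id[run_id]
                for modseq, rt in missing.items():
                    if (modseq, run_id) in quantified or modseq not in charge_of:
                        continue
                    pseudo = ScoredMatch(
                        modseq, charge_of[modseq], False, run_id,
                        apex_rt=rt, n_matching=0, primary_score=float("nan"),
                    )
                    entry = lib.entries[(modseq, charge_of[modseq], False)]
                    rec = quantify_match(run, pseudo, entry, tol_ppm=cfg.fragment_tol_ppm)
                    if rec is not None:
                        records.append(rec)
    quantities = select_transitions_study(
        records,
        min_transitions=cfg.min_transitions,
        max_transitions=cfg.max_transitions,
        interference_max=cfg.interference_max,
    )
    peptide_matrix = study_filters(quantities, design, cv_max=cfg.cv_max)
    protein_matrix = protein_quant(peptide_matrix, groups)
    return {
        "peptides": peptide_matrix,
        "proteins": protein_matrix,
        "groups": groups,
        "unmapped": unmapped,
        "quantities": quantities,
        "records": records,
    }


def matches_to_frame(matches: list[ScoredMatch]) -> pd.DataFrame:
    from .models import FEATURE_NAMES

    rows = []
    for m in matches:
        row = {
            "modseq": m.modseq, "charge": m.charge, "is_decoy": m.is_decoy,
            "run_id": m.run_id, "apex_rt": m.apex_rt,
            "primary_score": m.primary_score, "n_matching": m.n_matching,
        }
        row.update({k: m.features.get(k, 0.0) for k in FEATURE_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)
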