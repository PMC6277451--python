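"""Target/decoy validation: semi-supervised linear re-scoring, q-values and
posterior error probabilities, and parsimonious protein grouping with
protein-level FDR.

The re-scorer is a self-contained stand-in for an external SVM validator:
3-fold cross-validated, 3 iterations of semi-supervised training (decoys vs
targets passing a provisional 1% FDR), linear decision function. q-values use
the (+1)-corrected decoy/target ratio, monotonized; PEPs come from an
isotonic fit of the local decoy probability.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LogisticRegression

from .models import FEATURE_NAMES, ProteinGroup, ScoredMatch, ValidatedPeptide

logger = logging.getLogger(__name__)

DECOY_PREFIX = "DECOY_"


def feature_matrix(matches: list[ScoredMatch]) -> np.ndarray:
    """Rows of [primary_score, 15 features]; -inf scores mapped to a floor."""
    rows = np.zeros((len(matches), 1 + len(FEATURE_NAMES)))
    finite = [m.primary_score for m in matches if np.isfinite(m.primary_score)]
    floor = (min(finite) - 1.0) if finite else -1.0
    for i, m in enumerate(matches):
        s = m.primary_score if np.isfinite(m.primary_score) else floor
        rows[i, 0] = s
        for j, name in enumerate(FEATURE_NAMES):
            rows[i, 1 + j] = m.features.get(name, 0.0)
    return rows


def qvalues_from_scores(
    scores: np.ndarray, is_decoy: np.ndarray
) -> np.ndarray:
    """q(s) = (#decoys >= s + 1) / max(1, #targets >= s), monotonized."""
    order = np.argsort(-scores, kind="stable")
    d_cum = np.cumsum(is_decoy[order])
    t_cum = np.cumsum(~is_decoy[order])
    fdr = (d_cum + 1) / np.maximum(t_cum, 1)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return np.minimum(q, 1.0)


def peps_from_scores(scores: np.ndarray, is_decoy: np.ndarray) -> np.ndarray:
    """PEP via isotonic regression of decoy probability against score."""
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip", y_min=0.0, y_max=1.0)
    p_decoy = iso.fit_transform(scores, is_decoy.astype(float))
    # with ~equal target/decoy counts, local false-positive fraction among
    # targets is p/(1-p); clip to [0, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        pep = p_decoy / np.maximum(1.0 - p_decoy, 1e-9)
    return np.clip(pep, 0.0, 1.0)


def rescore(
    matches: list[ScoredMatch],
    n_folds: int = 3,
    n_iter: int = 3,
    train_fdr: float = 0.01,
    min_decoys: int = 50,
    seed: int = 0,
) -> list[ValidatedPeptide]:
    """Semi-supervised re-scoring of target/decoy feature rows.

    Falls back to primary-score-only ranking when fewer than ``min_decoys``
    decoy rows are available.
    """
    X = feature_matrix(matches)
    is_decoy = np.array([m.is_decoy for m in matches])
    n = len(matches)
    if is_decoy.sum() < min_decoys:
        logger.warning(
            "%d decoys (<%d): primary-score-only ranking", int(is_decoy.sum()), min_decoys
        )
        scores = X[:, 0].copy()
    else:
        mu = X.mean(axis=0)
        sig = X.std(axis=0)
        sig[sig == 0] = 1.0
        Xs = (X - mu) / sig
        rng = np.random.default_rng(seed)
        folds = rng.integers(0, n_folds, size=n)
        scores = Xs[:, 0].copy()
        for fold in range(n_folds):
            train = folds != fold
            test = ~train
            if test.sum() == 0 or train.sum() == 0:
                continue
            s_train = Xs[train, 0].copy()
            for _ in range(n_iter):
                q = qvalues_from_scores(s_train, is_decoy[train])
                pos = (~is_decoy[train]) & (q <= train_fdr)
                neg = is_decoy[train]
                if pos.sum() < 5 or neg.sum() < 5:
                    break
                sel = pos | neg
                clf = LogisticRegression(max_iter=1000)
                clf.fit(Xs[train][sel], pos[sel].astype(int))
                s_train = clf.decision_function(Xs[train])
                scores[test] = clf.decision_function(Xs[test])
        # guard against a learned direction that performs worse than the
        # primary score alone (small-sample overfitting)
        def accepted(s: np.ndarray) -> int:
            q = qvalues_from_scores(s, is_decoy)
            return int(((~is_decoy) & (q <= train_fdr)).sum())

        if accepted(scores) < accepted(Xs[:, 0]):
            logger.warning("re-scorer underperforms primary score; falling back")
            scores = Xs[:, 0].copy()

    q = qvalues_from_scores(scores, is_decoy)
    pep = peps_from_scores(scores, is_decoy)
    return [
        ValidatedPeptide(
            modseq=m.modseq, charge=m.charge, run_id=m.run_id,
            is_decoy=m.is_decoy, svm_score=float(s),
            q_value=float(qq), pep=float(pp),
        )
        for m, s, qq, pp in zip(matches, scores, q, pep)
    ]


def global_peptide_fdr(
    per_run_results: list[list[ScoredMatch]], seed: int = 0, **kwargs
) -> list[ValidatedPeptide]:
    """Concatenate feature rows across runs, re-score once, then keep the
    best observation per (modseq, charge, is_decoy) to define study-level q."""
    allm = [m for run in per_run_results for m in run]
    validated = rescore(allm, seed=seed, **kwargs)
    best: dict[tuple, ValidatedPeptide] = {}
    for v in validated:
        key = (v.modseq, v.charge, v.is_decoy)
        cur = best.get(key)
        if cur is None or v.svm_score > cur.svm_score:
            best[key] = v
    out = list(best.values())
    scores = np.array([v.svm_score for v in out])
    is_decoy = np.array([v.is_decoy for v in out])
    q = qvalues_from_scores(scores, is_decoy)
    pep = peps_from_scores(scores, is_decoy)
    for v, qq, pp in zip(out, q, pep):
        v.q_value = float(qq)
        v.pep = float(pp)
    return out


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def write_pin(matches: list[ScoredMatch], path, protein_map=None) -> None:
    """Percolator PIN-compatible export (tab-separated): SpecId, Label,
    ScanNr, primary score + the 15 features, Peptide, Proteins."""
    from pathlib import Path

    cols = ["SpecId", "Label", "ScanNr", "primaryScore", *FEATURE_NAMES,
            "Peptide", "Proteins"]
    lines = ["\t".join(cols)]
    X = feature_matrix(matches)
    for i, m in enumerate(matches):
        prots = "\t".join(sorted((protein_map or {}).get(m.modseq, {"-"})))
        lines.append("\t".join([
            f"{m.modseq}_{m.charge}_{m.run_id}",
            "-1" if m.is_decoy else "1",
            str(i),
            *(f"{v:.6g}" for v in X[i]),
            f"-.{m.modseq}.-",
            prots,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_peptides_tsv(validated: list[ValidatedPeptide], path) -> None:
    from pathlib import Path

    lines = ["modseq\tcharge\trun_id\tis_decoy\tscore\tq_value\tpep"]
    for v in validated:
        lines.append(
            f"{v.modseq}\t{v.charge}\t{v.run_id}\t{int(v.is_decoy)}\t"
            f"{v.svm_score:.6g}\t{v.q_value:.6g}\t{v.pep:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_proteins_tsv(groups: list[ProteinGroup], path) -> None:
    from pathlib import Path

    lines = ["accessions\tn_peptides\tscore\tbest_pep\tq_value"]
    for g in groups:
        lines.append(
            f"{'/'.join(sorted(g.accessions))}\t{len(g.peptides)}\t"
            f"{g.score:.6g}\t{g.best_pep:.6g}\t{g.q_value:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Protein inference
# ---------------------------------------------------------------------------

def protein_score(peps: list[float]) -> float:
    """N - sum of peptide PEPs for the N peptides assigned to a protein."""
    return len(peps) - sum(peps)


def parsimonious_proteins(
    peptides: list[ValidatedPeptide],
    protein_map: dict[str, set[str]],
    peptide_q: float = 0.01,
    protein_q: float = 0.01,
) -> tuple[list[ProteinGroup], list[str]]:
    """Greedy parsimony: each peptide goes to the candidate group with the
    highest protein score; groups with identical peptide sets are merged.

    Decoy peptides map to ``DECOY_``-prefixed accessions of their target's
    proteins; all-decoy groups serve as protein decoys for FDR. Returns
    (groups passing protein FDR, unmapped peptide modseqs).
    """
    passing = [p for p in peptides if p.q_value <= peptide_q]
    pep_info: dict[tuple[str, bool], float] = {}
    for p in passing:
        key = (p.modseq, p.is_decoy)
        pep_info[key] = min(pep_info.get(key, 1.0), p.pep)

    # candidate accession -> peptide keys
    acc_peps: dict[str, set[tuple[str, bool]]] = defaultdict(set)
    unmapped: list[str] = []
    for (modseq, is_decoy) in pep_info:
        target_seq = modseq
        accs = protein_map.get(target_seq)
        if accs is None and is_decoy:
            # decoy peptide: map through its target's reversed sequence
            from .library_builder import reverse_modseq

            accs = protein_map.get(reverse_modseq(modseq))
            accs = {DECOY_PREFIX + a for a in accs} if accs else None
        if not accs:
            unmapped.append(modseq)
            continue
        for a in accs:
            acc_peps[a].add((modseq, is_decoy))

    # merge indistinguishable accessions
    by_pepset: dict[frozenset, set[str]] = defaultdict(set)
    for acc, peps in acc_peps.items():
        by_pepset[frozenset(peps)].add(acc)

    candidates = [
        (frozenset(accs), set(pepset)) for pepset, accs in by_pepset.items()
    ]
    assigned: dict[tuple[str, bool], frozenset] = {}
    remaining = dict(pep_info)
    group_peps: dict[frozenset, set[tuple[str, bool]]] = {}
    while remaining:
        best_group, best_score, best_set = None, -np.inf, None
        for accs, pepset in candidates:
            avail = pepset & remaining.keys()
            if not avail:
                continue
            score = protein_score([remaining[k] for k in avail])
            if score > best_score:
                best_group, best_score, best_set = accs, score, avail
        if best_group is None:
            break
        group_peps[best_group] = set(best_set)
        for k in best_set:
            assigned[k] = best_group
            del remaining[k]

    groups = []
    for accs, pepkeys in group_peps.items():
        peps = [pep_info[k] for k in pepkeys]
        is_decoy_group = all(k[1] for k in pepkeys)
        groups.append(
            ProteinGroup(
                accessions=accs,
                peptides={k[0] for k in pepkeys},
                score=protein_score(peps),
                best_pep=min(peps),
                is_decoy=is_decoy_group,
            )
        )
    # protein q-values: rank by lowest member PEP
    groups.sort(key=lambda g: g.best_pep)
    scores = -np.array([g.best_pep for g in groups])
    is_d = np.array([g.is_decoy for g in groups])
    if groups:
        q = qvalues_from_scores(scores, is_d)
        for g, qq in zip(groups, q):
            g.q_value = float(qq)
    kept = [g for g in groups if not g.is_decoy and g.q_value <= protein_q]
    return kept, unmapped
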