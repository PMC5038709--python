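"""Diagnostic evaluation of window-level state predictions.

Per-class one-vs-rest confusion counts feed the usual screening metrics —
sensitivity, specificity, F-measure, accuracy, false positive/negative
rates, the diagnostic odds ratio DOR = (TP x TN)/(FP x FN) with a
log-normal 95% confidence interval, and rank-based one-vs-rest AUC.
Cross-validation is stratified at the subject level (a subject's windows
never straddle the train/test split) so within-subject signal cannot leak
into the test folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import rankdata

from .features import FEATURE_GROUPS
from .hmm import quantize_observations, svi_train, vpc_train, viterbi_decode
from .pipeline import PipelineModel
from .predict import PredictionResult, predict_window
from .states import STATES, dominant_state

__all__ = [
    "confusion_counts",
    "rates",
    "diagnostic_odds_ratio",
    "roc_auc_ovr",
    "DiagnosticReport",
    "report_from_predictions",
    "stratified_subject_folds",
    "cross_validate",
]

Z_95 = 1.959963984540054


# ---------------------------------------------------------------------------
# confusion counts and rates


def confusion_counts(
    true: list[str], predicted: list[str]
) -> dict[str, dict[str, int]]:
    """One-vs-rest TP/FP/TN/FN per class."""
    if len(true) != len(predicted):
        raise ValueError("true and predicted must have equal length")
    t = np.asarray(true)
    p = np.asarray(predicted)
    out = {}
    for c in STATES:
        tp = int(np.sum((t == c) & (p == c)))
        fp = int(np.sum((t != c) & (p == c)))
        fn = int(np.sum((t == c) & (p != c)))
        tn = int(np.sum((t != c) & (p != c)))
        out[c] = {"TP": tp, "FP": fp, "TN": tn, "FN": fn}
    return out


def rates(counts: dict[str, int]) -> dict[str, float]:
    """Sen/Spe/FM/Acc/FPR/FNR from one class's counts.

    Undefined ratios (zero denominators) are reported as NaN, never
    silently as 0 or 1.
    """
    tp, fp, tn, fn = counts["TP"], counts["FP"], counts["TN"], counts["FN"]
    total = tp + fp + tn + fn

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else np.nan

    sen = ratio(tp, tp + fn)
    spe = ratio(tn, tn + fp)
    precision = ratio(tp, tp + fp)
    fm = (
        2 * precision * sen / (precision + sen)
        if np.isfinite(precision) and np.isfinite(sen) and (precision + sen) > 0
        else np.nan
    )
    return {
        "Sen": sen,
        "Spe": spe,
        "FM": fm,
        "Acc": ratio(tp + tn, total),
        "FPR": ratio(fp, fp + tn),
        "FNR": ratio(fn, fn + tp),
    }


def diagnostic_odds_ratio(
    counts: dict[str, int],
) -> tuple[float, tuple[float, float], bool]:
    """DOR = (TP x TN)/(FP x FN) with a log-normal 95% CI.

    A zero cell triggers the Haldane 0.5 continuity correction; the third
    return value flags that the correction was applied.
    """
    tp, fp, tn, fn = (
        float(counts["TP"]),
        float(counts["FP"]),
        float(counts["TN"]),
        float(counts["FN"]),
    )
    corrected = min(tp, fp, tn, fn) == 0
    if corrected:
        tp, fp, tn, fn = tp + 0.5, fp + 0.5, tn + 0.5, fn + 0.5
    dor = (tp * tn) / (fp * fn)
    se = np.sqrt(1 / tp + 1 / fp + 1 / tn + 1 / fn)
    ci = (float(np.exp(np.log(dor) - Z_95 * se)), float(np.exp(np.log(dor) + Z_95 * se)))
    return float(dor), ci, corrected


def roc_auc_ovr(
    true: list[str], scores: dict[str, np.ndarray]
) -> dict[str, float]:
    """One-vs-rest AUC per class by the Mann-Whitney rank statistic."""
    t = np.asarray(true)
    out = {}
    for c, s in scores.items():
        s = np.asarray(s, dtype=float)
        pos = t == c
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            out[c] = np.nan
            continue
        ranks = rankdata(s)
        out[c] = float(
            (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        )
    return out


# ---------------------------------------------------------------------------
# report


@dataclass
class DiagnosticReport:
    """Per-class and macro diagnostic metrics over pooled predictions."""

    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    accuracy: float
    n_windows: int
    fold_subjects: dict[int, list[str]] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        def clean(v):
            if isinstance(v, dict):
                return {k: clean(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [clean(x) for x in v]
            if isinstance(v, (np.floating, float)):
                return None if not np.isfinite(v) else float(v)
            if isinstance(v, (np.integer,)):
                return int(v)
            return v

        payload = {
            "per_class": clean(self.per_class),
            "macro": clean(self.macro),
            "accuracy": clean(self.accuracy),
            "n_windows": self.n_windows,
            "fold_subjects": self.fold_subjects,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def report_from_predictions(
    true: list[str],
    predicted: list[str],
    scores: dict[str, np.ndarray] | None = None,
    fold_subjects: dict[int, list[str]] | None = None,
) -> DiagnosticReport:
    """Assemble the full diagnostic report from pooled window predictions."""
    counts = confusion_counts(true, predicted)
    aucs = roc_auc_ovr(true, scores) if scores is not None else {}
    per_class = {}
    for c in STATES:
        r = rates(counts[c])
        dor, ci, corrected = diagnostic_odds_ratio(counts[c])
        per_class[c] = {
            **counts[c],
            **r,
            "AUC": aucs.get(c, np.nan),
            "DOR": dor,
            "DOR_CI": ci,
            "DOR_corrected": corrected,
        }
    macro = {
        key: float(np.mean([per_class[c][key] for c in STATES]))
        for key in ("Sen", "Spe", "FM", "Acc", "FPR", "FNR", "AUC")
    }
    accuracy = float(np.mean(np.asarray(true) == np.asarray(predicted)))
    return DiagnosticReport(
        per_class=per_class,
        macro=macro,
        accuracy=accuracy,
        n_windows=len(true),
        fold_subjects=fold_subjects or {},
    )


# ---------------------------------------------------------------------------
# cross-validation


def stratified_subject_folds(
    subjects: list[str], labels: list[str], k: int, seed: int
) -> dict[int, list[str]]:
    """Assign subjects to k folds, stratified by dominant label."""
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds: dict[int, list[str]] = {i: [] for i in range(k)}
    by_label: dict[str, list[str]] = {}
    for s, lab in zip(subjects, labels):
        by_label.setdefault(lab, []).append(s)
    for lab in sorted(by_label):
        members = sorted(by_label[lab])
        rng.shuffle(members)
        for i, s in enumerate(members):
            folds[i % k].append(s)
    for i, members in folds.items():
        present = {labels[subjects.index(s)] for s in members}
        if present != set(by_label):
            raise ValueError(
                f"fold {i} is missing a class; use a smaller k than {k}"
            )
    return folds


def _subject_sequences(
    table: pd.DataFrame, symbols: np.ndarray
) -> dict[str, tuple[np.ndarray, list[str]]]:
    """Per-subject (symbol sequence, true slot labels) in slot order."""
    out = {}
    sym = pd.Series(symbols, index=table.index)
    for subject, grp in table.groupby("subject", sort=True):
        grp = grp.sort_values("slot")
        out[subject] = (
            sym.loc[grp.index].to_numpy(dtype=int),
            grp["true_state"].tolist(),
        )
    return out


def _align_states(decoded_paths, true_paths) -> dict[str, str]:
    """Map latent state labels to clinical labels by maximal overlap."""
    overlap = np.zeros((len(STATES), len(STATES)))
    for dec, tru in zip(decoded_paths, true_paths):
        for d, t in zip(dec, tru):
            overlap[STATES.index(d), STATES.index(t)] += 1
    row, col = linear_sum_assignment(-overlap)
    return {STATES[r]: STATES[c] for r, c in zip(row, col)}


def _feature_columns(table: pd.DataFrame, groups: list[str] | None) -> list[str]:
    cols = [c for c in table.columns if c in FEATURE_GROUPS]
    if groups is None:
        return cols
    return [c for c in cols if FEATURE_GROUPS[c] in groups]


def cross_validate(
    table: pd.DataFrame,
    k: int = 5,
    window_w: int = 60,
    algo: str = "vpc",
    K: int = 16,
    k_features: int | None = 30,
    feature_groups: list[str] | None = None,
    seed: int = 0,
    svi_iterations: int = 200,
) -> DiagnosticReport:
    """Subject-level stratified k-fold evaluation of the full method.

    For each fold the normalization / mRMR / PCA / GDA pipeline and the
    HMM (VPC supervised on slot labels, or SVI followed by
    overlap-based state alignment) are fitted on training subjects only;
    held-out subjects are cut into non-overlapping ``window_w``-slot
    windows, decoded, and summarized by the candidate ensemble.  The
    pooled windows yield one :class:`DiagnosticReport`.
    """
    if algo not in {"vpc", "svi"}:
        raise ValueError("algo must be 'vpc' or 'svi'")
    subjects = sorted(table["subject"].unique())
    dominant = {
        s: dominant_state(table.loc[table["subject"] == s, "true_state"].tolist())
        for s in subjects
    }
    folds = stratified_subject_folds(
        subjects, [dominant[s] for s in subjects], k, seed
    )
    cols = _feature_columns(table, feature_groups)
    if not cols:
        raise ValueError("feature mask leaves no feature columns")

    all_true: list[str] = []
    all_pred: list[str] = []
    all_scores: dict[str, list[float]] = {c: [] for c in STATES}
    for fold_id in sorted(folds):
        test_subjects = set(folds[fold_id])
        train_mask = ~table["subject"].isin(test_subjects)
        train = table[train_mask]
        test = table[~train_mask]
        model = PipelineModel.fit(
            train[cols], train["true_state"].to_numpy(), k_features=k_features
        )
        train_scores = model.transform(train[cols])
        symbols, codebook = quantize_observations(train_scores, K, seed)
        seqs = _subject_sequences(train, symbols)
        sequences = [seqs[s][0] for s in sorted(seqs)]
        labels = [seqs[s][1] for s in sorted(seqs)]
        if algo == "vpc":
            params = vpc_train(sequences, labels=labels, K=codebook.K)
            relabel = {s: s for s in STATES}
        else:
            params = svi_train(
                sequences,
                K=codebook.K,
                batch_size=min(11, len(sequences)),
                n_iterations=svi_iterations,
                seed=seed,
            )
            decoded_train = [viterbi_decode(params, s)[0] for s in sequences]
            relabel = _align_states(decoded_train, labels)

        test_scores = model.transform(test[cols])
        test_seqs = _subject_sequences(test, codebook.assign(test_scores))
        for subject in sorted(test_seqs):
            sym, true_slots = test_seqs[subject]
            n_windows = len(sym) // window_w
            for wi in range(n_windows):
                lo, hi = wi * window_w, (wi + 1) * window_w
                result: PredictionResult = predict_window(params, sym[lo:hi])
                predicted = relabel[result.predicted]
                all_true.append(dominant_state(true_slots[lo:hi]))
                all_pred.append(predicted)
                scores = {relabel[c]: v for c, v in result.class_scores().items()}
                for c in STATES:
                    all_scores[c].append(scores.get(c, 0.0))
    score_arrays = {c: np.asarray(v) for c, v in all_scores.items()}
    return report_from_predictions(all_true, all_pred, score_arrays, folds)
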