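"""In-silico antimicrobial-peptide (AMP) screen over a proteome.

The screen has four stages:

1. **Corpus curation** — labelled AMP / background sequences are restricted
   to 5–100 residues and de-redundified at <90% pairwise identity by a
   greedy, length-descending pass (identity = matches / shorter length under
   the best ungapped offset alignment).
2. **Classifier training** — four support vector machines (RBF, linear,
   polynomial, sigmoid kernels) on PseAAC + physicochemical features, each
   tuned by exhaustive grid search under 3-fold stratified cross-validation;
   the best kernel is chosen by CV accuracy (ties: AUC, then a fixed kernel
   order).  Feature standardisation is fit inside each training fold.
3. **Sliding-window digestion and scoring** — every 8–15-mer window of every
   protein is scored; decision values are mapped to [0, 1] by a monotone
   empirical-CDF calibration built from out-of-fold decision values.
4. **Synthesis filtering** — declared proxies for "high water solubility and
   chemical stability": soluble iff hydrophobic-residue fraction < 0.45 and
   |net charge| above a floor; stable iff instability index < 40, no
   Asp-Pro bond and at most one Met.  All four thresholds are configurable.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.isotonic import IsotonicRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import (
    compute_features,
    feature_matrix,
    hydrophobic_fraction,
)
from .io import ProteinRecord

KERNEL_ORDER = ("rbf", "linear", "polynomial", "sigmoid")

#: default hyperparameter grids per kernel (exhaustively enumerated)
DEFAULT_GRID: dict[str, dict[str, list]] = {
    "rbf": {"C": [0.1, 1, 10, 100], "gamma": [0.001, 0.01, 0.1, 1]},
    "linear": {"C": [0.1, 1, 10, 100]},
    "polynomial": {"C": [0.1, 1, 10, 100], "degree": [2, 3]},
    "sigmoid": {"C": [0.1, 1, 10, 100], "gamma": [0.001, 0.01, 0.1, 1]},
}


# ---------------------------------------------------------------------------
# corpus curation


def _as_codes(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def _best_matches(short: np.ndarray, long_: np.ndarray,
                  min_overlap: int = 1) -> int:
    """Max match count over all ungapped offsets with >= min_overlap overlap."""
    ns, nl = len(short), len(long_)
    best = 0
    for off in range(-(ns - min_overlap), nl - min_overlap + 1):
        lo_s, hi_s = max(0, -off), min(ns, nl - off)
        m = int(np.count_nonzero(short[lo_s:hi_s] ==
                                 long_[lo_s + off:hi_s + off]))
        if m > best:
            best = m
    return best


def ungapped_identity(a: str, b: str) -> float:
    """Best ungapped-offset identity: matches / length of the shorter sequence.

    All relative offsets of the two sequences are tried; the maximal match
    count is divided by the shorter length.  Cheap, deterministic, and
    redundancy-removal-like in spirit.
    """
    if not a or not b:
        return 0.0
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    return _best_matches(_as_codes(short), _as_codes(long_)) / len(short)


def _is_redundant(short: np.ndarray, long_: np.ndarray, cutoff: float) -> bool:
    """Exactly ungapped_identity >= cutoff, but cheaper.

    A qualifying offset needs matches >= cutoff*ns, and matches never exceed
    the overlap, so offsets with smaller overlap cannot qualify and are
    skipped without changing the decision.
    """
    ns = len(short)
    need = int(np.ceil(cutoff * ns))
    return _best_matches(short, long_, min_overlap=max(1, need)) >= need


@dataclass(frozen=True)
class Corpus:
    """Curated labelled training sequences (label 1 = AMP, 0 = background)."""

    sequences: tuple[str, ...]
    labels: np.ndarray
    ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.labels):
            raise ValueError("sequences and labels differ in length")


def curate_corpus(
    sequences: Sequence[tuple[str, str, int]],
    min_len: int = 5,
    max_len: int = 100,
    identity_cut: float = 0.90,
) -> Corpus:
    """Length-filter and de-redundify a labelled corpus.

    ``sequences`` is (id, sequence, label) triples.  Sequences outside
    [min_len, max_len] are dropped; the survivors are visited longest-first
    (ties by sequence then id, so the pass is deterministic) and a sequence
    is discarded when its identity to any already-retained sequence is
    >= ``identity_cut``.  An empty surviving class is a hard error.
    """
    in_range = [(sid, s, y) for sid, s, y in sequences
                if min_len <= len(s) <= max_len]
    ordered = sorted(in_range, key=lambda t: (-len(t[1]), t[1], t[0]))
    kept: list[tuple[str, str, int]] = []
    kept_codes: list[np.ndarray] = []
    for sid, s, y in ordered:
        codes = _as_codes(s)
        # kept sequences are never shorter than s (length-descending order)
        if any(_is_redundant(codes, kc, identity_cut) for kc in kept_codes):
            continue
        kept.append((sid, s, y))
        kept_codes.append(codes)
    labels = np.array([y for _, _, y in kept], dtype=int)
    for cls in (0, 1):
        if not np.any(labels == cls):
            raise ValueError(
                f"curation left no sequences with label {cls}; "
                "both classes are required for training"
            )
    return Corpus(
        sequences=tuple(s for _, s, _ in kept),
        labels=labels,
        ids=tuple(sid for sid, _, _ in kept),
    )


# ---------------------------------------------------------------------------
# training


@dataclass(frozen=True)
class KernelReport:
    kernel: str
    params: Mapping[str, float]
    cv_accuracy: float
    auc: float


@dataclass
class TrainedClassifier:
    """Best SVM with its calibration data and per-kernel comparison report."""

    kernel: str
    hyperparameters: dict
    cv_accuracy: float
    auc: float
    seed: int
    lam: int
    weight: float
    pipeline: Pipeline = field(repr=False)
    calibration_decisions: np.ndarray = field(repr=False)
    calibration_probs: np.ndarray = field(repr=False)
    per_kernel: tuple[KernelReport, ...] = ()

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return self.pipeline.decision_function(X)

    def probabilities(self, X: np.ndarray) -> np.ndarray:
        """Monotone class-probability calibration of decision values.

        An isotonic fit of held-out decision values against their labels
        gives P(AMP | decision); between knots the map is interpolated
        linearly, so it stays monotone.
        """
        return self.calibrate(self.decision_values(X))

    def calibrate(self, d: np.ndarray) -> np.ndarray:
        return np.interp(d, self.calibration_decisions,
                         self.calibration_probs)

    def score_sequences(self, sequences: Sequence[str]) -> np.ndarray:
        X = feature_matrix(sequences, lam=self.lam, weight=self.weight)
        return self.probabilities(X)


def _svc(kernel: str, params: Mapping, seed: int) -> SVC:
    sk_kernel = "poly" if kernel == "polynomial" else kernel
    return SVC(kernel=sk_kernel, random_state=seed, **params)


def _grid_points(grid: Mapping[str, list]) -> list[dict]:
    keys = sorted(grid)
    return [dict(zip(keys, combo))
            for combo in itertools.product(*(grid[k] for k in keys))]


def train_classifiers(
    corpus: Corpus,
    grid: Mapping[str, Mapping[str, list]] | None = None,
    cv_folds: int = 3,
    seed: int = 0,
    lam: int = 4,
    weight: float = 0.05,
) -> TrainedClassifier:
    """Grid-search four SVM kernels under stratified cross-validation.

    Every (kernel, hyperparameter) combination is scored by mean CV accuracy
    with features standardised on the training folds only.  Per kernel the
    best combination is reported with its out-of-fold AUC; the overall
    winner is the kernel with highest CV accuracy (ties broken by AUC, then
    by the fixed order rbf, linear, polynomial, sigmoid).

    Because the maximum over a grid is optimistically biased, the winning
    configuration's reported ``cv_accuracy`` and ``auc`` are re-estimated on
    a fresh cross-validation split that played no part in the selection;
    the same fresh out-of-fold decision values drive the probability
    calibration.  The winner is finally refit on the full corpus.
    """
    grid = dict(DEFAULT_GRID) if grid is None else grid
    y = corpus.labels
    if len(np.unique(y)) < 2:
        raise ValueError("training corpus must contain both classes")
    X = feature_matrix(corpus.sequences, lam=lam, weight=weight)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    eval_skf = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                               random_state=seed + 1)
    eval_splits = list(eval_skf.split(X, y))

    def evaluate(kernel: str, params: dict,
                 splits: list) -> tuple[float, float, np.ndarray]:
        accs = []
        oof_decision = np.empty(len(y))
        for train_idx, test_idx in splits:
            pipe = Pipeline([
                ("scale", StandardScaler()),
                ("svm", _svc(kernel, params, seed)),
            ])
            pipe.fit(X[train_idx], y[train_idx])
            accs.append(pipe.score(X[test_idx], y[test_idx]))
            oof_decision[test_idx] = pipe.decision_function(X[test_idx])
        auc = float(roc_auc_score(y, oof_decision))
        return float(np.mean(accs)), auc, oof_decision

    reports: list[KernelReport] = []
    best_by_kernel: dict[str, tuple[dict, float, float, np.ndarray]] = {}
    for kernel in KERNEL_ORDER:
        if kernel not in grid:
            continue
        best = None
        for params in _grid_points(grid[kernel]):
            acc, auc, oof = evaluate(kernel, params, splits)
            cand = (acc, auc, params, oof)
            if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                best = cand
        assert best is not None, f"empty grid for kernel {kernel}"
        acc, auc, params, oof = best
        reports.append(KernelReport(kernel, params, acc, auc))
        best_by_kernel[kernel] = (params, acc, auc, oof)

    order = {k: i for i, k in enumerate(KERNEL_ORDER)}
    winner = max(
        best_by_kernel,
        key=lambda k: (best_by_kernel[k][1], best_by_kernel[k][2], -order[k]),
    )
    params, _, _, _ = best_by_kernel[winner]
    # selection-free estimate of the winner's performance and calibration
    acc, auc, oof = evaluate(winner, params, eval_splits)
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True,
                             out_of_bounds="clip")
    iso.fit(oof, y)
    cal_x = np.sort(np.unique(oof))
    cal_p = iso.predict(cal_x)
    final = Pipeline([
        ("scale", StandardScaler()),
        ("svm", _svc(winner, params, seed)),
    ])
    final.fit(X, y)
    return TrainedClassifier(
        kernel=winner,
        hyperparameters=dict(params),
        cv_accuracy=acc,
        auc=auc,
        seed=seed,
        lam=lam,
        weight=weight,
        pipeline=final,
        calibration_decisions=cal_x,
        calibration_probs=cal_p,
        per_kernel=tuple(reports),
    )


# ---------------------------------------------------------------------------
# sliding-window digestion


@dataclass(frozen=True)
class PeptideWindow:
    """One sliding window; ``occurrences`` lists every (parent, start) locus."""

    parent_id: str
    start: int  # 0-based offset into the parent
    length: int
    sequence: str
    occurrences: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if len(self.sequence) != self.length:
            raise ValueError("window length does not match its sequence")


def window_count(lengths: Iterable[int], window_min: int = 8,
                 window_max: int = 15) -> int:
    """Closed-form pre-deduplication window count over protein lengths."""
    return sum(
        max(0, L - k + 1)
        for L in lengths
        for k in range(window_min, window_max + 1)
    )


def window_digest(
    proteome: Sequence[ProteinRecord],
    window_min: int = 8,
    window_max: int = 15,
) -> list[PeptideWindow]:
    """All 8–15-mer windows at step 1, deduplicated by sequence.

    The first occurrence of each distinct sequence defines the reported
    (parent, start); all other occurrences are recorded on the window.
    """
    if window_min > window_max:
        raise ValueError(
            f"window_min ({window_min}) > window_max ({window_max})"
        )
    first: dict[str, int] = {}
    windows: list[PeptideWindow] = []
    occ: list[list[tuple[str, int]]] = []
    for rec in proteome:
        seq = rec.sequence
        L = len(seq)
        for k in range(window_min, window_max + 1):
            for start in range(0, L - k + 1):
                s = seq[start:start + k]
                idx = first.get(s)
                if idx is None:
                    first[s] = len(windows)
                    windows.append(
                        PeptideWindow(rec.id, start, k, s)
                    )
                    occ.append([(rec.id, start)])
                else:
                    occ[idx].append((rec.id, start))
    return [replace(w, occurrences=tuple(o)) for w, o in zip(windows, occ)]


# ---------------------------------------------------------------------------
# scanning and filtering


@dataclass(frozen=True)
class AmpCandidate:
    window: PeptideWindow
    score: float           # raw SVM decision value
    probability: float     # calibrated to [0, 1]
    soluble: bool = False
    stable: bool = False
    selected: bool = False


@dataclass(frozen=True)
class FilterRules:
    """Configurable proxies for synthesis-friendly solubility/stability."""

    max_hydrophobic_fraction: float = 0.45
    min_abs_charge: float = 0.5
    max_instability: float = 40.0
    max_methionines: int = 1
    forbid_asp_pro: bool = True


def scan_proteome(
    windows: Sequence[PeptideWindow],
    classifier: TrainedClassifier,
    threshold: float = 0.8,
    batch_size: int = 50_000,
) -> list[AmpCandidate]:
    """Score windows and keep those with calibrated probability >= threshold.

    Windows containing non-standard residues (X) cannot be featurised and
    are skipped.  Raising the threshold never increases the candidate count.
    """
    scorable = [w for w in windows
                if all(c in "ACDEFGHIKLMNPQRSTVWY" for c in w.sequence)]
    candidates: list[AmpCandidate] = []
    for lo in range(0, len(scorable), batch_size):
        chunk = scorable[lo:lo + batch_size]
        X = feature_matrix([w.sequence for w in chunk],
                           lam=classifier.lam, weight=classifier.weight)
        d = classifier.decision_values(X)
        p = classifier.calibrate(d)
        for w, di, pi in zip(chunk, d, p):
            if pi >= threshold:
                candidates.append(AmpCandidate(w, float(di), float(pi)))
    return candidates


def filter_candidates(
    candidates: Sequence[AmpCandidate],
    rules: FilterRules = FilterRules(),
    lam: int = 4,
    weight: float = 0.05,
) -> list[AmpCandidate]:
    """Apply the solubility and stability proxies; selected = both pass."""
    out = []
    for c in candidates:
        s = c.window.sequence
        fv = compute_features(s, lam=min(lam, len(s) - 1), weight=weight)
        soluble = (
            hydrophobic_fraction(s) < rules.max_hydrophobic_fraction
            and abs(fv.net_charge) >= rules.min_abs_charge
        )
        stable = (
            fv.instability < rules.max_instability
            and s.count("M") <= rules.max_methionines
            and not (rules.forbid_asp_pro and "DP" in s)
        )
        out.append(replace(c, soluble=soluble, stable=stable,
                           selected=soluble and stable))
    return out


def assess_peptide(sequence: str, rules: FilterRules = FilterRules(),
                   lam: int = 4, weight: float = 0.05) -> tuple[bool, bool]:
    """(soluble, stable) verdict for a bare sequence under the proxies."""
    fv = compute_features(sequence, lam=min(lam, len(sequence) - 1),
                          weight=weight)
    soluble = (
        hydrophobic_fraction(sequence) < rules.max_hydrophobic_fraction
        and abs(fv.net_charge) >= rules.min_abs_charge
    )
    stable = (
        fv.instability < rules.max_instability
        and sequence.count("M") <= rules.max_methionines
        and not (rules.forbid_asp_pro and "DP" in sequence)
    )
    return soluble, stable


# ---------------------------------------------------------------------------
# model serialisation (documented JSON)


def save_model(clf: TrainedClassifier, path: str | Path) -> None:
    """Serialise a trained classifier to a documented JSON file.

    Stores kernel, hyperparameters, scaler constants, support vectors and
    coefficients, calibration decision values and feature settings — enough
    to reproduce ``decision_function`` exactly without pickling.
    """
    svm: SVC = clf.pipeline.named_steps["svm"]
    scale: StandardScaler = clf.pipeline.named_steps["scale"]
    payload = {
        "format": "glandscreen-svm-1",
        "kernel": clf.kernel,
        "hyperparameters": clf.hyperparameters,
        "cv_accuracy": clf.cv_accuracy,
        "auc": clf.auc,
        "seed": clf.seed,
        "lam": clf.lam,
        "weight": clf.weight,
        "scaler": {
            "mean": scale.mean_.tolist(),
            "scale": scale.scale_.tolist(),
        },
        "svm": {
            "reference_decision": float(
                svm.decision_function(svm.support_vectors_[:1])[0]),
            "support_vectors": svm.support_vectors_.tolist(),
            "dual_coef": svm.dual_coef_.tolist(),
            "intercept": svm.intercept_.tolist(),
            "gamma": float(svm._gamma),
            "degree": int(svm.degree),
            "coef0": float(svm.coef0),
            "classes": svm.classes_.tolist(),
            "n_support": svm.n_support_.tolist(),
        },
        "calibration_decisions": clf.calibration_decisions.tolist(),
        "calibration_probs": clf.calibration_probs.tolist(),
        "per_kernel": [
            {"kernel": r.kernel, "params": dict(r.params),
             "cv_accuracy": r.cv_accuracy, "auc": r.auc}
            for r in clf.per_kernel
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_model(path: str | Path) -> TrainedClassifier:
    """Rebuild a classifier from :func:`save_model` output.

    The SVC is reconstructed by refitting on its own support vectors with
    fixed dual coefficients replaced — sklearn has no public constructor for
    a bare kernel machine, so we restore the fitted attributes directly.
    """
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "glandscreen-svm-1":
        raise ValueError(f"{path}: not a recognised model file")
    scale = StandardScaler()
    scale.mean_ = np.array(payload["scaler"]["mean"])
    scale.scale_ = np.array(payload["scaler"]["scale"])
    scale.var_ = scale.scale_ ** 2
    scale.n_features_in_ = len(scale.mean_)
    svm_meta = payload["svm"]
    svm = _svc(payload["kernel"], payload["hyperparameters"], payload["seed"])
    svm.support_vectors_ = np.array(svm_meta["support_vectors"])
    svm.dual_coef_ = np.array(svm_meta["dual_coef"])
    svm.intercept_ = np.array(svm_meta["intercept"])
    svm._gamma = svm_meta["gamma"]
    svm.classes_ = np.array(svm_meta["classes"])
    svm._n_support = np.array(svm_meta["n_support"], dtype=np.int32)
    svm.support_ = np.arange(len(svm.support_vectors_), dtype=np.int32)
    svm._dual_coef_ = svm.dual_coef_
    svm._intercept_ = svm.intercept_
    svm.fit_status_ = 0
    svm._sparse = False
    svm.shape_fit_ = (len(svm.support_vectors_),
                      svm.support_vectors_.shape[1])
    svm._probA = np.empty(0)
    svm._probB = np.empty(0)
    svm.n_features_in_ = svm.support_vectors_.shape[1]
    # libsvm's decision sign depends on the label order seen at fit time,
    # which attribute surgery cannot restore; a stored reference decision
    # value disambiguates it
    ref = svm_meta["reference_decision"]
    got = float(svm.decision_function(svm.support_vectors_[:1])[0])
    if not np.isclose(got, ref, rtol=1e-6, atol=1e-9):
        svm.dual_coef_ = -svm.dual_coef_
        svm._dual_coef_ = svm.dual_coef_
        svm.intercept_ = -svm.intercept_
        svm._intercept_ = svm.intercept_
        got = float(svm.decision_function(svm.support_vectors_[:1])[0])
        if not np.isclose(got, ref, rtol=1e-6, atol=1e-9):
            raise ValueError(f"{path}: cannot reproduce stored decision values")
    pipe = Pipeline([("scale", scale), ("svm", svm)])
    return TrainedClassifier(
        kernel=payload["kernel"],
        hyperparameters=dict(payload["hyperparameters"]),
        cv_accuracy=payload["cv_accuracy"],
        auc=payload["auc"],
        seed=payload["seed"],
        lam=payload["lam"],
        weight=payload["weight"],
        pipeline=pipe,
        calibration_decisions=np.array(payload["calibration_decisions"]),
        calibration_probs=np.array(payload["calibration_probs"]),
        per_kernel=tuple(
            KernelReport(r["kernel"], r["params"], r["cv_accuracy"], r["auc"])
            for r in payload["per_kernel"]
        ),
    )
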