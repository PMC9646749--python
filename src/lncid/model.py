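"""Feature assembly, preprocessing, balancing, feature selection, model
training/prediction, and evaluation.

The classifier is a gradient-boosted decision-tree ensemble (XGBoost)
trained on z-scored features, with SMOTE oversampling to balance the
classes and an optional recursive feature elimination step driven by
gain importance. lncRNA is the positive class; prediction reports the
lncRNA probability and a thresholded label (ties at the 0.5 threshold
go to lncRNA). A trained model is persisted as a self-contained bundle:
probability tables, scaler statistics, selected feature list, and the
serialized classifier.
"""

from __future__ import annotations

import itertools
import json
import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import NearestNeighbors
import xgboost
from xgboost import XGBClassifier

from . import schema
from .orf import find_typed_orfs, orf_length_coverage_features
from .protein_features import protein_features_for_orfset
from .seq_features import (HexamerTable, fickett_score, gc_content,
                           hexamer_score_orf, hexamer_score_transcript,
                           relative_codon_bias)
from .seqio import POSITIVE_LABEL, TranscriptRecord
from .struct_features import (SASS_KS, SassTable, gc_content_paired,
                              loop_features, paired_ratio, parse_dotbracket,
                              sass_score)

BUNDLE_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# feature assembly

def compute_record_features(
    record: TranscriptRecord,
    hexamer_table: HexamerTable,
    sass_tables: Optional[dict[int, SassTable]],
    with_structure: bool,
) -> dict[str, float]:
    """All features of one transcript, keyed by schema name.

    SSF columns are zero when structure handling is off; the structure
    itself must be present when it is on.
    """
    seq = record.sequence
    orfs = find_typed_orfs(seq)
    feats: dict[str, float] = {
        "gc_content": gc_content(seq),
        "fickett_score": fickett_score(seq),
        "hexamer_score": hexamer_score_transcript(seq, hexamer_table),
    }
    feats.update(orf_length_coverage_features(orfs, len(seq)))
    feats.update(hexamer_score_orf(orfs, hexamer_table))
    for t in ("t0", "t1", "t2", "t3"):
        orf = orfs.get(t)
        feats[f"rcb_{t}"] = relative_codon_bias(orf.sequence) if orf else 0.0
    if with_structure:
        if record.structure is None:
            raise ValueError(f"record {record.id!r} has no structure")
        pt = parse_dotbracket(record.structure)
        feats["mfe"] = record.mfe if record.mfe is not None else 0.0
        feats["paired_ratio"] = paired_ratio(pt)
        feats["gc_content_paired"] = gc_content_paired(seq, pt)
        feats.update(loop_features(pt, len(seq)))
        for k in SASS_KS:
            feats[f"sass_k{k}_score"] = (
                sass_score(seq, record.structure, k, sass_tables[k])
                if sass_tables and k in sass_tables else 0.0
            )
    else:
        for name in schema.SSF_FEATURES:
            feats[name] = 0.0
    feats.update(protein_features_for_orfset(orfs))
    return feats


def assemble_features(
    records: Sequence[TranscriptRecord],
    hexamer_table: HexamerTable,
    sass_tables: Optional[dict[int, SassTable]] = None,
    features: Sequence[str] = schema.FULL_57,
    with_structure: bool = True,
    threads: int = 1,
) -> pd.DataFrame:
    """One feature row per record, columns in schema order.

    When structure handling is on, every record must carry a structure;
    the ids of offenders are listed in the error. Extraction is
    per-record independent, so the threaded path merges results in input
    order and is bit-identical to the sequential one.
    """
    if with_structure:
        missing = [rec.id for rec in records if rec.structure is None]
        if missing:
            raise ValueError(
                f"{len(missing)} record(s) lack structures: {missing[:10]}"
            )

    def one(rec: TranscriptRecord) -> dict[str, float]:
        return compute_record_features(rec, hexamer_table, sass_tables, with_structure)

    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            rows = list(pool.map(one, records))
    else:
        rows = [one(rec) for rec in records]
    frame = pd.DataFrame(rows, index=[rec.id for rec in records])
    return frame.reindex(columns=list(features))


# ---------------------------------------------------------------------------
# standardization

@dataclass
class ScalerStats:
    """Per-feature training mean and population standard deviation."""

    feature_names: list[str]
    mean: np.ndarray
    std: np.ndarray

    def subset(self, names: Sequence[str]) -> "ScalerStats":
        idx = [self.feature_names.index(n) for n in names]
        return ScalerStats(list(names), self.mean[idx], self.std[idx])


def zscore_fit(matrix: pd.DataFrame) -> ScalerStats:
    values = matrix.to_numpy(dtype=float)
    return ScalerStats(
        list(matrix.columns),
        values.mean(axis=0),
        values.std(axis=0, ddof=0),
    )


def zscore_apply(matrix: pd.DataFrame, stats: ScalerStats) -> pd.DataFrame:
    if list(matrix.columns) != stats.feature_names:
        raise ValueError("feature columns do not match scaler statistics")
    values = matrix.to_numpy(dtype=float) - stats.mean
    safe = np.where(stats.std > 0, stats.std, 1.0)
    values = values / safe
    values[:, stats.std == 0] = 0.0  # constant training column -> 0
    return pd.DataFrame(values, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# SMOTE balancing

def smote_balance(
    matrix: np.ndarray,
    labels: np.ndarray,
    k_neighbors: int = 5,
    seed: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling to equal class counts.

    Each synthetic row lies on the segment between a randomly chosen
    minority instance and one of its k nearest minority neighbors:
    x_new = x + u * (x_nn - x) with u uniform on [0, 1]. Original rows
    of both classes are preserved verbatim. If the minority class has at
    most ``k_neighbors`` members, k is reduced with a warning.
    """
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError("smote_balance expects exactly two classes")
    minority = classes[np.argmin(counts)]
    n_needed = int(abs(counts[0] - counts[1]))
    if n_needed == 0:
        return matrix, labels
    minority_rows = matrix[labels == minority]
    k = k_neighbors
    if len(minority_rows) <= k:
        import warnings

        k = len(minority_rows) - 1
        warnings.warn(
            f"minority class of {len(minority_rows)} <= k_neighbors; using k={k}"
        )
    if k < 1:
        raise ValueError("minority class too small for SMOTE")
    rng = np.random.default_rng(seed)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(minority_rows)
    neighbor_idx = nn.kneighbors(minority_rows, return_distance=False)[:, 1:]
    base = rng.integers(0, len(minority_rows), size=n_needed)
    pick = rng.integers(0, k, size=n_needed)
    u = rng.uniform(0.0, 1.0, size=n_needed)
    x = minority_rows[base]
    x_nn = minority_rows[neighbor_idx[base, pick]]
    synthetic = x + u[:, None] * (x_nn - x)
    out_matrix = np.vstack([matrix, synthetic])
    out_labels = np.concatenate([labels, np.full(n_needed, minority, dtype=labels.dtype)])
    return out_matrix, out_labels


# ---------------------------------------------------------------------------
# classifier construction and tuning

#: Documented default hyperparameter grid for the boosted-tree model.
DEFAULT_GRID: dict[str, list] = {
    "n_estimators": [100, 300, 500],
    "max_depth": [4, 6, 8],
    "learning_rate": [0.05, 0.1, 0.3],
}

#: Reduced grid for fixture-scale runs (tests, worked examples).
SMALL_GRID: dict[str, list] = {
    "n_estimators": [200],
    "max_depth": [4, 6],
    "learning_rate": [0.1],
}


def make_classifier(seed: int = 0, **params) -> XGBClassifier:
    defaults = dict(
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        eval_metric="logloss",
        importance_type="gain",
    )
    defaults.update(params)
    return XGBClassifier(**defaults)


def tune_and_train(
    matrix,
    labels,
    folds: int = 10,
    grid: Optional[dict[str, list]] = None,
    seed: int = 0,
) -> tuple[XGBClassifier, list[dict]]:
    """Select hyperparameters by mean stratified k-fold CV accuracy, then
    refit on the full training matrix. Returns the fitted classifier and
    the CV table; a fixed seed yields an identical model."""
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    grid = grid or DEFAULT_GRID
    names = sorted(grid)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    results: list[dict] = []
    best: Optional[dict] = None
    for combo in itertools.product(*(grid[n] for n in names)):
        params = dict(zip(names, combo))
        clf = make_classifier(seed=seed, **params)
        scores = cross_val_score(clf, X, y, cv=cv, scoring="accuracy")
        entry = {**params, "cv_accuracy": float(scores.mean())}
        results.append(entry)
        if best is None or entry["cv_accuracy"] > best["cv_accuracy"]:
            best = entry
    assert best is not None
    params = {k: v for k, v in best.items() if k != "cv_accuracy"}
    clf = make_classifier(seed=seed, **params)
    clf.fit(X, y)
    return clf, results


def rfecv_select(
    matrix: pd.DataFrame,
    labels,
    folds: int = 10,
    step: int = 1,
    seed: int = 0,
    estimator_params: Optional[dict] = None,
) -> tuple[list[str], list[tuple[int, float]]]:
    """Recursive feature elimination with cross-validated accuracy.

    Repeatedly records the mean stratified k-fold CV accuracy of the
    current feature subset, then drops the ``step`` features with the
    lowest gain importance (from a fit on the full data). Returns the
    subset at the accuracy peak (ties favor the smaller subset) plus the
    full (size, accuracy) trace.
    """
    y = np.asarray(labels)
    params = estimator_params or {"n_estimators": 100, "max_depth": 4, "learning_rate": 0.3}
    current = list(matrix.columns)
    trace: list[tuple[int, float]] = []
    subsets: dict[int, list[str]] = {}
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    while current:
        X = matrix[current].to_numpy(dtype=float)
        clf = make_classifier(seed=seed, **params)
        acc = float(cross_val_score(clf, X, y, cv=cv, scoring="accuracy").mean())
        trace.append((len(current), acc))
        subsets[len(current)] = list(current)
        if len(current) == 1:
            break
        clf.fit(X, y)
        importance = clf.feature_importances_
        order = np.argsort(importance, kind="stable")
        drop = {current[i] for i in order[:step]}
        current = [f for f in current if f not in drop]
    # peak accuracy; ties -> smaller subset
    best_size, _ = min(trace, key=lambda t: (-t[1], t[0]))
    return subsets[best_size], trace


# ---------------------------------------------------------------------------
# metrics

@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    f_score: float
    mcc: float
    degenerate: bool = False  # a zero denominator was reported as 0

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "precision": self.precision, "accuracy": self.accuracy,
            "f_score": self.f_score, "mcc": self.mcc,
        }


def _as_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        return (arr == POSITIVE_LABEL).astype(int)
    return arr.astype(int)


def compute_metrics(true_labels, predicted_labels) -> MetricsReport:
    """Sn, Sp, Prec, Acc, F-score, and MCC with lncRNA as positive class.

    Ratios with a zero denominator are reported as 0 and flagged.
    """
    y = _as_binary(true_labels)
    p = _as_binary(predicted_labels)
    if len(y) == 0:
        raise ValueError("empty input")
    if len(y) != len(p):
        raise ValueError("label vectors differ in length")
    tp = int(((y == 1) & (p == 1)).sum())
    fp = int(((y == 0) & (p == 1)).sum())
    tn = int(((y == 0) & (p == 0)).sum())
    fn = int(((y == 1) & (p == 0)).sum())
    degenerate = False

    def ratio(num: float, den: float) -> float:
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    sn = ratio(tp, tp + fn)
    sp = ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    acc = (tp + tn) / len(y)
    f = ratio(2 * prec * sn, prec + sn)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ratio(tp * tn - fp * fn, mcc_den)
    return MetricsReport(tp, fp, tn, fn, sn, sp, prec, acc, f, mcc, degenerate)


def roc_auc(true_labels, scores) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points by threshold sweep and the trapezoid AUC.

    Equivalent to the Mann-Whitney rank formulation of the AUC.
    """
    y = _as_binary(true_labels)
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, dtype=float))
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


# ---------------------------------------------------------------------------
# model bundle

@dataclass
class ModelBundle:
    """Everything needed to predict: tables, scaler, features, classifier."""

    subset_name: str
    feature_names: list[str]
    scaler: ScalerStats
    hexamer_table: HexamerTable
    sass_tables: Optional[dict[int, SassTable]]
    booster: xgboost.Booster
    with_structure: bool
    threshold: float = 0.5
    metadata: dict = field(default_factory=dict)

    def save(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format_version": BUNDLE_FORMAT_VERSION,
            "subset_name": self.subset_name,
            "feature_names": self.feature_names,
            "with_structure": self.with_structure,
            "threshold": self.threshold,
            "scaler": {
                "feature_names": self.scaler.feature_names,
                "mean": self.scaler.mean.tolist(),
                "std": self.scaler.std.tolist(),
            },
            "sass_ks": sorted(self.sass_tables) if self.sass_tables else [],
            "metadata": self.metadata,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
        self.hexamer_table.to_tsv(directory / "hexamer.tsv")
        if self.sass_tables:
            for k, table in self.sass_tables.items():
                table.to_tsv(directory / f"sass_k{k}.tsv")
        self.booster.save_model(str(directory / "classifier.json"))
        return directory

    @classmethod
    def load(cls, directory) -> "ModelBundle":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        if manifest.get("format_version") != BUNDLE_FORMAT_VERSION:
            raise ValueError(
                f"bundle format version {manifest.get('format_version')} is not "
                f"supported (expected {BUNDLE_FORMAT_VERSION})"
            )
        scaler = ScalerStats(
            manifest["scaler"]["feature_names"],
            np.asarray(manifest["scaler"]["mean"], dtype=float),
            np.asarray(manifest["scaler"]["std"], dtype=float),
        )
        hexamer = HexamerTable.from_tsv(directory / "hexamer.tsv")
        sass: Optional[dict[int, SassTable]] = None
        if manifest["sass_ks"]:
            sass = {k: SassTable.from_tsv(directory / f"sass_k{k}.tsv")
                    for k in manifest["sass_ks"]}
        booster = xgboost.Booster()
        booster.load_model(str(directory / "classifier.json"))
        return cls(
            subset_name=manifest["subset_name"],
            feature_names=list(manifest["feature_names"]),
            scaler=scaler,
            hexamer_table=hexamer,
            sass_tables=sass,
            booster=booster,
            with_structure=manifest["with_structure"],
            threshold=manifest["threshold"],
            metadata=manifest.get("metadata", {}),
        )


def predict(
    bundle: ModelBundle,
    records: Sequence[TranscriptRecord],
    threads: int = 1,
) -> tuple[np.ndarray, list[str]]:
    """lncRNA probability and thresholded label per record (input order).

    A structure-free bundle ignores any structures the records carry.
    """
    if not records:
        return np.empty(0), []
    X = assemble_features(
        records,
        bundle.hexamer_table,
        bundle.sass_tables,
        features=bundle.feature_names,
        with_structure=bundle.with_structure,
        threads=threads,
    )
    Xz = zscore_apply(X, bundle.scaler)
    probs = bundle.booster.inplace_predict(Xz.to_numpy(dtype=float))
    labels = [POSITIVE_LABEL if p >= bundle.threshold else "mRNA" for p in probs]
    return probs, labels


# ---------------------------------------------------------------------------
# end-to-end training

def train_pipeline(
    records: Sequence[TranscriptRecord],
    subset: str = "top28",
    with_structure: bool = True,
    seed: int = 0,
    folds: int = 10,
    grid: Optional[dict[str, list]] = None,
    run_rfecv: bool = False,
    smote_k: int = 5,
    threads: int = 1,
) -> tuple[ModelBundle, dict]:
    """Tables -> features -> z-score -> SMOTE -> (RFECV) -> tune/train.

    Records must be pre-filtered and labeled; mRNA records need CDS
    intervals (the hexamer table's coding counts come from them). The
    returned report logs per-stage counts, CV results, and the
    training-set confusion.
    """
    from .struct_features import build_sass_tables

    mrnas = [r for r in records if r.label == "mRNA"]
    lncrnas = [r for r in records if r.label == POSITIVE_LABEL]
    if not mrnas or not lncrnas:
        raise ValueError("training data must contain both classes")
    missing_cds = [r.id for r in mrnas if r.cds is None]
    if missing_cds:
        raise ValueError(
            f"{len(missing_cds)} mRNA record(s) lack CDS annotations: "
            f"{missing_cds[:10]}"
        )
    if subset == "no-ssf22":
        with_structure = False  # subset carries no SSF columns
    elif not with_structure and subset == "top28":
        subset = "no-ssf22"

    hexamer = build_hexamer_table_from_records(mrnas, lncrnas)
    sass = build_sass_tables(mrnas, lncrnas) if with_structure else None

    feature_names = list(schema.subset_features(subset))
    X = assemble_features(records, hexamer, sass, features=feature_names,
                          with_structure=with_structure, threads=threads)
    y = np.array([1 if r.label == POSITIVE_LABEL else 0 for r in records])

    scaler = zscore_fit(X)
    Xz = zscore_apply(X, scaler)

    Xb, yb = smote_balance(Xz.to_numpy(dtype=float), y, k_neighbors=smote_k, seed=seed)
    report: dict = {
        "n_input": len(records),
        "n_mrna": len(mrnas),
        "n_lncrna": len(lncrnas),
        "n_after_smote": len(yb),
        "subset": subset,
        "with_structure": with_structure,
    }

    selected = feature_names
    if run_rfecv:
        Xb_df = pd.DataFrame(Xb, columns=feature_names)
        selected, trace = rfecv_select(Xb_df, yb, folds=folds, seed=seed)
        report["rfecv_trace"] = trace
        report["rfecv_selected"] = selected
        Xb = Xb_df[selected].to_numpy(dtype=float)

    clf, cv_results = tune_and_train(Xb, yb, folds=folds, grid=grid, seed=seed)
    report["cv_results"] = cv_results
    report["best_params"] = max(cv_results, key=lambda e: e["cv_accuracy"])

    bundle = ModelBundle(
        subset_name=subset,
        feature_names=list(selected),
        scaler=scaler.subset(selected),
        hexamer_table=hexamer,
        sass_tables=sass,
        booster=clf.get_booster(),
        with_structure=with_structure,
        metadata={
            "class_counts": {"mRNA": len(mrnas), "lncRNA": len(lncrnas)},
            "structure_mode": "on" if with_structure else "off",
            "seed": seed,
        },
    )
    # training-set confusion for the report
    probs, labels = predict(bundle, records, threads=threads)
    train_metrics = compute_metrics([r.label for r in records], labels)
    report["train_confusion"] = {
        "TP": train_metrics.tp, "FP": train_metrics.fp,
        "TN": train_metrics.tn, "FN": train_metrics.fn,
    }
    report["train_accuracy"] = train_metrics.accuracy
    return bundle, report


def build_hexamer_table_from_records(
    mrnas: Sequence[TranscriptRecord],
    lncrnas: Sequence[TranscriptRecord],
) -> HexamerTable:
    """Hexamer table from mRNA CDS sequences and lncRNA full sequences."""
    from .seq_features import build_hexamer_table

    coding = [r.cds_sequence for r in mrnas if r.cds_sequence]
    noncoding = [r.sequence for r in lncrnas]
    return build_hexamer_table(coding, noncoding)
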