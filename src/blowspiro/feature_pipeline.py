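"""Feature-table assembly and prescreening.

Each recording yields 42 features: gender, the three spirometer-like
features, and the 38 time-frequency features.  Before classification the
table passes through a fixed chain:

1. correlation filter — of any feature pair with |Pearson r| above the
   threshold (default 0.9), the later column in canonical order is dropped;
2. PCA-based feature selection — fit PCA on standardized columns, score
   each original feature by sum_c EVR_c * loading_c^2, and keep the
   smallest prefix of features (descending score) reaching the target share
   (default 99.9%) of the total score;
3. SMOTE oversampling — minority classes are topped up with convex
   interpolations between same-class nearest neighbours until all classes
   match the majority count.

Age is the label and never enters prescreening except as SMOTE's class
labels; gender is a feature but is never dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .audio_io import AudioSignal, validate_exhalation
from .cwd_core import CWDConfig
from .spiro_features import extract_spiro_features
from .tf_features import TF_FEATURE_NAMES, BandSet, extract_tf_features

#: Canonical feature-column order of the 42-feature table.
FEATURE_COLUMNS = ["gender", "total_dec", "total_dec_1st_sec", "max_peak", *TF_FEATURE_NAMES]

#: Full CSV header: id + features + label.
CSV_COLUMNS = ["sample_id", *FEATURE_COLUMNS, "age"]


@dataclass(frozen=True)
class PrescreenReport:
    dropped_by_correlation: list[str]
    pca_kept: list[str]
    evr_cum: float
    smote_added: dict = field(default_factory=dict)


def assemble(
    samples: list[tuple[AudioSignal, float, int]],
    cwd_cfg: CWDConfig | None = None,
    bands: BandSet | None = None,
    n_fft: int = 2048,
    hop: int = 512,
    validate: bool = True,
) -> pd.DataFrame:
    """Build the 42-feature table from (signal, age, gender) samples.

    Samples failing validation are excluded (a warning names them).
    Deterministic given the inputs and configs.
    """
    if not samples:
        raise ValueError("empty sample list")
    cwd_cfg = cwd_cfg or CWDConfig()
    rows = []
    for i, (sig, age, gender) in enumerate(samples):
        if validate:
            report = validate_exhalation(sig, min_s=0.5, max_s=30.0)
            if not report.ok:
                warnings.warn(f"sample {i} excluded: {'; '.join(report.messages)}")
                continue
        spiro = extract_spiro_features(sig, n_fft=n_fft, hop=hop)
        tf = extract_tf_features(sig, cwd_cfg, bands)
        row = {"sample_id": f"s{i:04d}", "gender": float(gender),
               "total_dec": spiro.total_dec,
               "total_dec_1st_sec": spiro.total_dec_1st_sec,
               "max_peak": spiro.max_peak,
               **dict(zip(TF_FEATURE_NAMES, tf.as_array())),
               "age": float(age)}
        rows.append(row)
    if not rows:
        raise ValueError("no sample passed validation")
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def correlation_filter(
    table: pd.DataFrame, threshold: float = 0.9
) -> tuple[pd.DataFrame, list[str]]:
    """Drop the later member of every feature pair with |Pearson r| > threshold.

    ``gender`` is never dropped.  Constant columns have undefined r and are
    treated as |r| = 0 (with a warning).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    feats = [c for c in table.columns if c in FEATURE_COLUMNS]
    if len(table) < 3:
        raise ValueError("need >= 3 rows for correlation screening")
    sub = table[feats]
    constant = [c for c in feats if sub[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant feature columns treated as uncorrelated: {constant}")
    corr = sub.corr().abs().fillna(0.0)
    dropped: list[str] = []
    for j, cj in enumerate(feats):
        if cj == "gender" or cj in dropped:
            continue
        for ci in feats[:j]:
            if ci in dropped:
                continue
            if corr.loc[ci, cj] > threshold:
                dropped.append(cj)
                break
    kept = [c for c in table.columns if c not in dropped]
    return table[kept], dropped


def pca_select(
    table: pd.DataFrame, evr_target: float = 0.999
) -> tuple[pd.DataFrame, list[str]]:
    """Keep the original features that carry ``evr_target`` of the variance.

    PCA is fitted on standardized columns; components are retained until
    their cumulative explained-variance ratio reaches the target, each
    feature is scored by sum_c EVR_c * loading_{c,feature}^2, and the
    smallest prefix of features (by descending score) whose cumulative
    score reaches ``evr_target`` of the total score is kept.  ``gender`` is
    always kept.
    """
    feats = [c for c in table.columns if c in FEATURE_COLUMNS and c != "gender"]
    X = table[feats].to_numpy(dtype=np.float64)
    if X.shape[0] < X.shape[1] + 1:
        warnings.warn("fewer rows than features + 1; PCA restricted to available rank")
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    nonzero = std > 0
    Xs = np.zeros_like(X)
    Xs[:, nonzero] = (X[:, nonzero] - mean[nonzero]) / std[nonzero]
    pca = PCA()
    pca.fit(Xs)
    evr = pca.explained_variance_ratio_
    n_comp = int(np.searchsorted(np.cumsum(evr), evr_target) + 1)
    n_comp = min(n_comp, len(evr))
    scores = np.einsum("c,cf->f", evr[:n_comp], pca.components_[:n_comp] ** 2)
    order = np.argsort(-scores, kind="stable")
    cum = np.cumsum(scores[order])
    total = scores.sum()
    n_keep = int(np.searchsorted(cum, evr_target * total) + 1) if total > 0 else len(feats)
    n_keep = min(n_keep, len(feats))
    kept_feats = [feats[i] for i in sorted(order[:n_keep])]
    kept = ["gender"] + kept_feats
    cols = [c for c in table.columns if c not in FEATURE_COLUMNS or c in kept]
    return table[cols], kept


def smote_balance(
    table: pd.DataFrame,
    labels: np.ndarray,
    k: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Equalize class counts by SMOTE interpolation.

    Every synthetic row is u + lam * (v - u) for a real row u of the class,
    v one of u's k nearest same-class neighbours (k reduced for tiny
    classes) and lam ~ U[0, 1].  Returns the augmented table, labels, and
    per-class added counts; synthetic rows get sample_id suffix ``_syn``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    labels = np.asarray(labels)
    feats = [c for c in table.columns if c in FEATURE_COLUMNS]
    classes, counts = np.unique(labels, return_counts=True)
    singletons = classes[counts < 2]
    if singletons.size:
        raise ValueError(f"cannot interpolate singleton class(es): {singletons.tolist()}")
    target = counts.max()
    rng = np.random.default_rng(seed)
    new_rows, new_labels = [], []
    added = {}
    for cls, count in zip(classes, counts):
        n_add = int(target - count)
        added[cls] = n_add
        if n_add == 0:
            continue
        members = table.loc[labels == cls, feats].to_numpy(dtype=np.float64)
        k_eff = min(k, count - 1)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(members)
        _, idx = nn.kneighbors(members)
        for j in range(n_add):
            u_i = int(rng.integers(0, count))
            v_i = int(idx[u_i, 1 + rng.integers(0, k_eff)])
            lam = rng.uniform()
            synth = members[u_i] + lam * (members[v_i] - members[u_i])
            row = {c: v for c, v in zip(feats, synth)}
            row["sample_id"] = f"{cls}_syn{j:04d}"
            if "age" in table.columns:
                row["age"] = np.nan
            new_rows.append(row)
            new_labels.append(cls)
    if not new_rows:
        return table, labels, added
    aug = pd.concat([table, pd.DataFrame(new_rows)], ignore_index=True)
    aug = aug.reindex(columns=table.columns)
    return aug, np.concatenate([labels, np.array(new_labels)]), added


def prescreen(
    table: pd.DataFrame,
    corr_threshold: float = 0.9,
    evr_target: float = 0.999,
) -> tuple[pd.DataFrame, PrescreenReport]:
    """Correlation filter then PCA selection (SMOTE is applied at
    evaluation time, inside or before cross-validation)."""
    filtered, dropped = correlation_filter(table, corr_threshold)
    selected, kept = pca_select(filtered, evr_target)
    return selected, PrescreenReport(
        dropped_by_correlation=dropped, pca_kept=kept, evr_cum=evr_target
    )
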