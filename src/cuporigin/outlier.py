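"""Density-based outlier scoring against the fitted tumor classes.

A sample's outlier score is OS = -log p(x) (natural log), where p(x)
is the mixture density of the fitted class-conditional Gaussians
weighted by their priors.  A low density — a sample resembling none of
the training classes — gives a high score.  Classes here use QDA
(per-class covariance), because dispersion differences between classes
are exactly what the score should be sensitive to.  Scores for samples
of known class are computed leave-one-out, so a sample never supports
its own density; samples of unknown class (CUPs) are scored against
the full model.

The score-to-error-rate relationship is summarized by ranking the
scored samples into equal-frequency bins and fitting a low-order
polynomial of per-bin error rate on per-bin median score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .classify import DiscriminantModel, _fit_gaussian
from .simulate import UNKNOWN_CLASS

log = logging.getLogger(__name__)

_LOG_2PI = np.log(2.0 * np.pi)


def fit_qda(
    matrix: pd.DataFrame,
    classes: pd.Series,
    mode: str = "diagonal",
    shrinkage: float = 0.1,
    var_floor: float = 1e-6,
) -> DiscriminantModel:
    """Maximum-likelihood QDA: one covariance per class (ML, divide by
    the class size), variances floored at ``var_floor``."""
    return _fit_gaussian(matrix, classes, "qda", mode, shrinkage, var_floor)


def outlier_score(model: DiscriminantModel, x) -> float:
    """OS = -log sum_c p(x|c) p(c), natural log, via log-sum-exp."""
    ll = model.log_likelihoods(x)[:, 0]
    return float(-logsumexp(ll + np.log(model.priors)))


def loocv_outlier_scores(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    var_floor: float = 1e-6,
    include_normal: bool = True,
) -> pd.DataFrame:
    """Score every sample against held-out QDA class models.

    Samples whose ``class_label`` is known form the training pool; each
    is scored by a diagonal QDA fitted on all the *other* training
    samples, and its predicted class (argmax posterior under the same
    held-out model) and correctness are recorded.  Unknown-class
    samples (CUPs) are scored against the full model.  Set
    ``include_normal=False`` to drop the pooled-normal class from the
    model entirely.

    Returns a table indexed by sample with columns ``os``,
    ``predicted_class``, ``correct`` (NaN where truth is unknown) and
    ``group``.
    """
    samples = samples.loc[matrix.columns]
    known = samples["class_label"] != UNKNOWN_CLASS
    if not include_normal:
        known &= samples["class_label"] != "normal"
    train_classes = samples.loc[known, "class_label"]
    counts = train_classes.value_counts()
    if (counts < 3).any():
        bad = counts.index[int(np.argmin(counts.to_numpy()))]
        raise ValueError(f"class {bad!r} has {counts.min()} samples; need at least 3")

    X = matrix.to_numpy(dtype=float)
    n_probes = X.shape[0]
    labels = list(train_classes.unique())
    k = len(labels)
    col_of = {s: j for j, s in enumerate(matrix.columns)}
    train_cols = np.array([col_of[s] for s in train_classes.index])
    y = np.array([labels.index(lab) for lab in train_classes])

    sums = np.zeros((n_probes, k))
    sumsq = np.zeros((n_probes, k))
    n_c = np.zeros(k)
    for c in range(k):
        j = train_cols[y == c]
        sums[:, c] = X[:, j].sum(axis=1)
        sumsq[:, c] = (X[:, j] ** 2).sum(axis=1)
        n_c[c] = len(j)
    n_train = int(n_c.sum())

    def score_vector(xi, sums_, sumsq_, n_c_):
        mean_c = sums_ / n_c_
        var_c = np.maximum(sumsq_ / n_c_ - mean_c**2, var_floor)  # ML per class
        d = xi[:, None] - mean_c
        ll = -0.5 * (n_probes * _LOG_2PI + np.log(var_c).sum(axis=0) + (d * d / var_c).sum(axis=0))
        log_joint = ll + np.log(n_c_ / n_c_.sum())
        return float(-logsumexp(log_joint)), int(np.argmax(log_joint))

    os_values = pd.Series(index=matrix.columns, dtype=float)
    pred = pd.Series(index=matrix.columns, dtype=object)
    for idx, sample_id in enumerate(train_classes.index):
        ci = y[idx]
        xi = X[:, train_cols[idx]]
        sums[:, ci] -= xi
        sumsq[:, ci] -= xi * xi
        n_c[ci] -= 1
        score, best = score_vector(xi, sums, sumsq, n_c)
        sums[:, ci] += xi
        sumsq[:, ci] += xi * xi
        n_c[ci] += 1
        os_values[sample_id] = score
        pred[sample_id] = labels[best]

    unknown_ids = samples.index[~known]
    for sample_id in unknown_ids:
        xi = X[:, col_of[sample_id]]
        score, best = score_vector(xi, sums, sumsq, n_c)
        os_values[sample_id] = score
        pred[sample_id] = labels[best]

    table = pd.DataFrame(
        {
            "os": os_values,
            "predicted_class": pred,
            "correct": np.where(
                known, (pred == samples["class_label"]).astype(float), np.nan
            ),
            "group": samples["group"] if "group" in samples.columns else "unknown",
        }
    )
    table.index.name = "sample_id"
    log.info("scored %d held-out and %d unknown samples", n_train, len(unknown_ids))
    return table


def bin_error_rates(
    table: pd.DataFrame,
    n_bins: int = 10,
    exclude_normal: bool = True,
) -> pd.DataFrame:
    """Equal-frequency bins of samples by outlier score, with per-bin
    error rate.

    Only samples with known correctness enter; normals are excluded by
    default (their pooled class is too heterogeneous for the score to
    be comparable).  When n is not divisible, the remainder goes one
    sample each to the lowest-score bins.
    """
    rows = table.dropna(subset=["correct"])
    if exclude_normal and "group" in rows.columns:
        rows = rows[rows["group"] != "normal"]
    n = len(rows)
    if n < n_bins:
        raise ValueError(f"{n} scored samples cannot fill {n_bins} bins")
    rows = rows.sort_values("os", kind="mergesort")
    base, rem = divmod(n, n_bins)
    sizes = [base + 1 if b < rem else base for b in range(n_bins)]
    records, start = [], 0
    for b, size in enumerate(sizes):
        chunk = rows.iloc[start : start + size]
        start += size
        records.append(
            {
                "bin": b + 1,
                "n": size,
                "os_median": float(chunk["os"].median()),
                "os_min": float(chunk["os"].min()),
                "os_max": float(chunk["os"].max()),
                "error_rate": float(1.0 - chunk["correct"].mean()),
            }
        )
    return pd.DataFrame(records).set_index("bin")


@dataclass(frozen=True)
class ErrorCurve:
    """Polynomial fit of bin error rate on bin median outlier score."""

    coefficients: np.ndarray  # highest power first (numpy convention)
    degree: int

    def predict(self, os_values) -> np.ndarray:
        """Expected error rate at given outlier scores, clipped to [0, 1]."""
        return np.clip(np.polyval(self.coefficients, np.asarray(os_values, dtype=float)), 0.0, 1.0)


def fit_error_curve(bins: pd.DataFrame, degree: int = 2) -> ErrorCurve:
    """Least-squares polynomial of error rate on median OS per bin."""
    if len(bins) < degree + 1:
        raise ValueError(f"{len(bins)} bins cannot support degree {degree}")
    coef = np.polyfit(bins["os_median"].to_numpy(), bins["error_rate"].to_numpy(), degree)
    return ErrorCurve(coefficients=coef, degree=degree)
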