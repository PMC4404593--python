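"""Gaussian discriminant classification of tumor expression profiles.

The classifier is the textbook Bayes rule with Gaussian
class-conditional densities: p(c|x) = p(x|c) p(c) / p(x), with
p(x) = sum_c p(x|c) p(c).  Class densities and priors are maximum
likelihood fits; LDA shares one covariance across classes, QDA (in
:mod:`cuporigin.outlier`) fits one per class.  Because probe counts
exceed class sizes by orders of magnitude, the default covariance is
diagonal (probe-wise variances, floored); a shrunken full covariance is
available for low-dimensional inputs.  Feature selection is a one-way
ANOVA F-test per probe, with the p-value cutoff chosen by grid search
over leave-one-out cross-validation accuracy, re-running the selection
inside every split so the reported accuracy is honest.

Sex-specific classes (by default ovary and cervix female-only,
prostate male-only) are handled at prediction time by zeroing their
priors for the wrong sex and renormalizing the rest.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import f as f_dist

log = logging.getLogger(__name__)

DEFAULT_SEX_MAP = {"ovary": "F", "cervix": "F", "prostate": "M"}
DEFAULT_CUTOFF_GRID = tuple(10.0 ** -k for k in range(2, 13))  # 1e-2 .. 1e-12

_LOG_2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def _check_classes(classes: pd.Series, min_per_class: int = 2) -> pd.Series:
    counts = classes.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 classes")
    small = counts[counts < min_per_class]
    if len(small):
        raise ValueError(
            f"class {small.index[0]!r} has {small.iloc[0]} sample(s); "
            f"need at least {min_per_class}"
        )
    return classes


def f_statistics(matrix: pd.DataFrame, classes: pd.Series) -> pd.DataFrame:
    """Per-probe one-way ANOVA F statistic and p-value across classes.

    Returns a DataFrame indexed by probe with columns ``F`` and ``p``
    (p from the F distribution with (K-1, N-K) degrees of freedom).
    Constant probes get F = 0, p = 1.
    """
    classes = pd.Series(classes, index=matrix.columns)
    _check_classes(classes)
    X = matrix.to_numpy(dtype=float)
    X = X - X.mean(axis=1, keepdims=True)  # center: SST = sum of squares
    n_total = X.shape[1]
    labels = classes.unique()
    k = len(labels)
    ssb = np.zeros(X.shape[0])
    for label in labels:
        j = np.flatnonzero((classes == label).to_numpy())
        ssb += len(j) * X[:, j].mean(axis=1) ** 2
    sst = (X**2).sum(axis=1)
    ssw = np.maximum(sst - ssb, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = (ssb / (k - 1)) / (ssw / (n_total - k))
    constant = sst <= 0
    f_stat[constant] = 0.0
    f_stat[np.isnan(f_stat)] = 0.0  # 0/0: no between- or within-class variation
    p = np.where(np.isinf(f_stat), 0.0, f_dist.sf(np.where(np.isinf(f_stat), 0, f_stat), k - 1, n_total - k))
    p[constant] = 1.0
    return pd.DataFrame({"F": f_stat, "p": p}, index=matrix.index)


def select_probes(stats: pd.DataFrame, cutoff: float) -> pd.Index:
    """Probes whose F-test p-value falls below the cutoff."""
    return stats.index[stats["p"] < cutoff]


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class DiscriminantModel:
    """Per-class Gaussian parameters and priors.

    ``kind`` is ``"lda"`` (shared covariance) or ``"qda"`` (per-class);
    ``mode`` is ``"diagonal"`` (probe-wise variances, the default) or
    ``"full_shrunk"`` (full covariance shrunk toward a scaled identity
    with intensity ``shrinkage``).  Diagonal variances are floored at
    ``var_floor``.
    """

    class_labels: tuple[str, ...]
    probe_ids: tuple[str, ...]
    means: np.ndarray  # K x P
    priors: np.ndarray  # K
    kind: str = "lda"
    mode: str = "diagonal"
    variances: np.ndarray | None = None  # K x P (diagonal mode)
    covariances: list[np.ndarray] | None = None  # K of P x P (full mode)
    shrinkage: float = 0.1
    var_floor: float = 1e-6

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def _as_matrix(self, x) -> np.ndarray:
        """Coerce a vector/Series/DataFrame to a P x n array aligned to the model."""
        if isinstance(x, pd.DataFrame):
            missing = set(self.probe_ids) - set(x.index)
            if missing:
                raise ValueError(f"input lacks {len(missing)} model probe(s)")
            return x.loc[list(self.probe_ids)].to_numpy(dtype=float)
        if isinstance(x, pd.Series):
            missing = set(self.probe_ids) - set(x.index)
            if missing:
                raise ValueError(f"input lacks {len(missing)} model probe(s)")
            return x.loc[list(self.probe_ids)].to_numpy(dtype=float)[:, None]
        arr = np.asarray(x, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.shape[0] != self.n_probes:
            raise ValueError(
                f"input has {arr.shape[0]} features, model expects {self.n_probes}"
            )
        return arr

    def log_likelihoods(self, x) -> np.ndarray:
        """log p(x|c) for every class: K x n array."""
        X = self._as_matrix(x)
        out = np.empty((self.n_classes, X.shape[1]))
        if self.mode == "diagonal":
            assert self.variances is not None
            for c in range(self.n_classes):
                v = self.variances[c]
                d = X - self.means[c][:, None]
                out[c] = -0.5 * (
                    self.n_probes * _LOG_2PI + np.log(v).sum() + (d * d / v[:, None]).sum(axis=0)
                )
        else:
            assert self.covariances is not None
            for c in range(self.n_classes):
                cov = self.covariances[c]
                chol = np.linalg.cholesky(cov)
                d = X - self.means[c][:, None]
                z = np.linalg.solve(chol, d)
                logdet = 2.0 * np.log(np.diag(chol)).sum()
                out[c] = -0.5 * (self.n_probes * _LOG_2PI + logdet + (z * z).sum(axis=0))
        return out

    # --- plain-text serialization ------------------------------------
    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "class_labels": list(self.class_labels),
            "probe_ids": list(self.probe_ids),
            "means": self.means.tolist(),
            "priors": self.priors.tolist(),
            "kind": self.kind,
            "mode": self.mode,
            "variances": None if self.variances is None else self.variances.tolist(),
            "covariances": None
            if self.covariances is None
            else [c.tolist() for c in self.covariances],
            "shrinkage": self.shrinkage,
            "var_floor": self.var_floor,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "DiscriminantModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            class_labels=tuple(payload["class_labels"]),
            probe_ids=tuple(payload["probe_ids"]),
            means=np.asarray(payload["means"], dtype=float),
            priors=np.asarray(payload["priors"], dtype=float),
            kind=payload["kind"],
            mode=payload["mode"],
            variances=None
            if payload["variances"] is None
            else np.asarray(payload["variances"], dtype=float),
            covariances=None
            if payload["covariances"] is None
            else [np.asarray(c, dtype=float) for c in payload["covariances"]],
            shrinkage=payload["shrinkage"],
            var_floor=payload["var_floor"],
        )


def _fit_gaussian(
    matrix: pd.DataFrame,
    classes: pd.Series,
    kind: str,
    mode: str,
    shrinkage: float,
    var_floor: float,
) -> DiscriminantModel:
    classes = pd.Series(classes, index=matrix.columns)
    _check_classes(classes)
    X = matrix.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("expression matrix contains non-finite values")
    labels = tuple(classes.unique())
    n_probes, n_total = X.shape
    means = np.empty((len(labels), n_probes))
    priors = np.empty(len(labels))
    members = []
    for c, label in enumerate(labels):
        j = np.flatnonzero((classes == label).to_numpy())
        members.append(j)
        means[c] = X[:, j].mean(axis=1)
        priors[c] = len(j) / n_total

    model = DiscriminantModel(
        class_labels=labels,
        probe_ids=tuple(matrix.index),
        means=means,
        priors=priors,
        kind=kind,
        mode=mode,
        shrinkage=shrinkage,
        var_floor=var_floor,
    )
    if mode == "diagonal":
        if kind == "lda":
            ssw = np.zeros(n_probes)
            for c, j in enumerate(members):
                d = X[:, j] - means[c][:, None]
                ssw += (d * d).sum(axis=1)
            pooled = np.maximum(ssw / n_total, var_floor)  # ML: divide by N
            model.variances = np.tile(pooled, (len(labels), 1))
        else:
            variances = np.empty((len(labels), n_probes))
            for c, j in enumerate(members):
                d = X[:, j] - means[c][:, None]
                variances[c] = (d * d).sum(axis=1) / len(j)  # ML: divide by n_c
            model.variances = np.maximum(variances, var_floor)
    elif mode == "full_shrunk":
        covs = []
        if kind == "lda":
            s = np.zeros((n_probes, n_probes))
            for c, j in enumerate(members):
                d = X[:, j] - means[c][:, None]
                s += d @ d.T
            s /= n_total
            covs = [_shrink(s, shrinkage, var_floor)] * len(labels)
        else:
            for c, j in enumerate(members):
                d = X[:, j] - means[c][:, None]
                covs.append(_shrink(d @ d.T / len(j), shrinkage, var_floor))
        model.covariances = covs
    else:
        raise ValueError(f"unknown covariance mode {mode!r}")
    return model


def _shrink(cov: np.ndarray, shrinkage: float, var_floor: float) -> np.ndarray:
    """Shrink toward the scaled identity (Ledoit-Wolf-style target)."""
    p = cov.shape[0]
    target = (np.trace(cov) / p) * np.eye(p)
    out = (1.0 - shrinkage) * cov + shrinkage * target
    out[np.diag_indices_from(out)] = np.maximum(np.diag(out), var_floor)
    return out


def fit_lda(
    matrix: pd.DataFrame,
    classes: pd.Series,
    mode: str = "diagonal",
    shrinkage: float = 0.1,
    var_floor: float = 1e-6,
) -> DiscriminantModel:
    """Maximum-likelihood LDA: class means, class-frequency priors, one
    covariance pooled across classes."""
    return _fit_gaussian(matrix, classes, "lda", mode, shrinkage, var_floor)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PosteriorResult:
    """Bayes posterior p(c|x) together with the model evidence p(x)."""

    posterior: pd.Series  # indexed by class label, sums to 1
    log_evidence: float  # log p(x) = log sum_c p(x|c) p(c)

    @property
    def predicted_class(self) -> str:
        return str(self.posterior.idxmax())


def posterior(model: DiscriminantModel, x) -> PosteriorResult:
    """p(c|x) = p(x|c) p(c) / p(x), evaluated in log space."""
    ll = model.log_likelihoods(x)[:, 0]
    log_joint = ll + np.log(model.priors)
    log_evidence = float(logsumexp(log_joint))
    post = np.exp(log_joint - log_evidence)
    return PosteriorResult(
        posterior=pd.Series(post, index=list(model.class_labels)),
        log_evidence=log_evidence,
    )


@dataclass(frozen=True)
class Prediction:
    """A classified sample: full posterior, argmax class, sex-mask flag."""

    posterior: pd.Series
    predicted_class: str
    log_evidence: float
    sex_mask_applied: bool


def _masked_priors(
    model: DiscriminantModel, sex: str, sex_specific_map: dict[str, str]
) -> tuple[np.ndarray, bool]:
    priors = model.priors.copy()
    applied = False
    if sex in ("M", "F"):
        for c, label in enumerate(model.class_labels):
            required = sex_specific_map.get(label)
            if required is not None and required != sex:
                priors[c] = 0.0
                applied = True
    total = priors.sum()
    if total == 0:
        raise ValueError(f"sex mask for {sex!r} removed every class")
    return priors / total, applied


def predict(
    model: DiscriminantModel,
    x,
    sex: str = "unknown",
    sex_specific_map: dict[str, str] | None = None,
) -> Prediction:
    """Classify one sample, zeroing priors of classes impossible for its
    sex and renormalizing the remainder."""
    if sex_specific_map is None:
        sex_specific_map = DEFAULT_SEX_MAP
    priors, applied = _masked_priors(model, sex, sex_specific_map)
    ll = model.log_likelihoods(x)[:, 0]
    with np.errstate(divide="ignore"):
        log_joint = ll + np.log(priors)
    log_evidence = float(logsumexp(log_joint[priors > 0]))
    post = np.where(priors > 0, np.exp(log_joint - log_evidence), 0.0)
    best = int(np.argmax(post))
    ties = np.flatnonzero(post == post[best])
    if len(ties) > 1:
        log.warning(
            "posterior tie between classes %s; keeping %s",
            [model.class_labels[t] for t in ties],
            model.class_labels[best],
        )
    return Prediction(
        posterior=pd.Series(post, index=list(model.class_labels)),
        predicted_class=model.class_labels[best],
        log_evidence=log_evidence,
        sex_mask_applied=applied,
    )


def predict_matrix(
    model: DiscriminantModel,
    matrix: pd.DataFrame,
    samples: pd.DataFrame | None = None,
    sex_specific_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Classify every column of a matrix; returns a table with the
    predicted class and per-class posteriors."""
    rows = {}
    for sample_id in matrix.columns:
        sex = "unknown"
        if samples is not None and "sex" in samples.columns:
            sex = samples.loc[sample_id, "sex"]
        pred = predict(model, matrix[sample_id], sex=sex, sex_specific_map=sex_specific_map)
        rows[sample_id] = pd.concat(
            [pd.Series({"predicted_class": pred.predicted_class}), pred.posterior]
        )
    out = pd.DataFrame(rows).T
    out.index.name = "sample_id"
    return out


def evaluate(predicted: pd.Series, truth: pd.Series) -> tuple[float, pd.DataFrame]:
    """Accuracy and a truth x predicted confusion table."""
    predicted, truth = pd.Series(predicted), pd.Series(truth)
    if set(predicted.index) != set(truth.index):
        raise ValueError("predicted and truth sample sets differ")
    predicted = predicted.loc[truth.index]
    accuracy = float((predicted == truth).mean())
    labels = sorted(set(truth) | set(predicted))
    confusion = pd.crosstab(truth, predicted).reindex(
        index=labels, columns=labels, fill_value=0
    )
    confusion.index.name, confusion.columns.name = "truth", "predicted"
    return accuracy, confusion


# ---------------------------------------------------------------------------
# LOOCV grid search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSearchResult:
    """Outcome of the cutoff grid search."""

    best_cutoff: float
    accuracies: pd.Series  # indexed by cutoff
    best_predictions: pd.Series  # LOOCV predictions at the best cutoff

    @property
    def best_accuracy(self) -> float:
        return float(self.accuracies.loc[self.best_cutoff])


def loocv_grid_search(
    matrix: pd.DataFrame,
    classes: pd.Series,
    cutoff_grid: tuple[float, ...] = DEFAULT_CUTOFF_GRID,
    var_floor: float = 1e-6,
) -> GridSearchResult:
    """Choose the F-test p-value cutoff by leave-one-out accuracy.

    For every left-out sample the F statistics and the (diagonal) LDA
    fit use only the remaining samples, so selection bias cannot leak
    into the accuracy estimate.  Ties between cutoffs break toward the
    stricter (smaller) one.  If a split selects no probe, that sample
    falls back to the largest-prior class.
    """
    if len(cutoff_grid) == 0:
        raise ValueError("cutoff grid is empty")
    classes = pd.Series(classes, index=matrix.columns)
    _check_classes(classes)
    X = matrix.to_numpy(dtype=float)
    n_probes, n_total = X.shape
    labels = list(classes.unique())
    k = len(labels)
    label_of = {lab: c for c, lab in enumerate(labels)}
    y = np.array([label_of[lab] for lab in classes])
    counts = np.bincount(y, minlength=k).astype(float)
    if (counts < 2).any():
        bad = labels[int(np.argmin(counts))]
        raise ValueError(f"class {bad!r} would be emptied by a LOOCV split")

    # per-class running sums: P x K
    sums = np.zeros((n_probes, k))
    sumsq = np.zeros((n_probes, k))
    for c in range(k):
        j = np.flatnonzero(y == c)
        sums[:, c] = X[:, j].sum(axis=1)
        sumsq[:, c] = (X[:, j] ** 2).sum(axis=1)

    grid = sorted(set(cutoff_grid))
    correct = {cut: 0 for cut in grid}
    predictions = {cut: [] for cut in grid}
    log_counts = {}

    for i in range(n_total):
        xi, ci = X[:, i], y[i]
        sums[:, ci] -= xi
        sumsq[:, ci] -= xi * xi
        counts[ci] -= 1
        n_eff = n_total - 1

        mean_c = sums / counts  # P x K
        ssw = np.maximum((sumsq - sums * mean_c).sum(axis=1), 0.0)
        grand = sums.sum(axis=1) / n_eff
        ssb = np.maximum((counts * (mean_c - grand[:, None]) ** 2).sum(axis=1), 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_stat = (ssb / (k - 1)) / (ssw / (n_eff - k))
        f_stat[~np.isfinite(f_stat)] = np.inf  # ssw == 0 with signal
        f_stat[(ssb + ssw) <= 0] = 0.0
        pvals = np.where(
            np.isinf(f_stat), 0.0, f_dist.sf(np.where(np.isinf(f_stat), 0, f_stat), k - 1, n_eff - k)
        )
        pooled_all = np.maximum(ssw / n_eff, var_floor)  # ML pooled variance
        log_prior = np.log(counts / n_eff)

        for cut in grid:
            sel = pvals < cut
            if not sel.any():
                pred = int(np.argmax(counts))
                log_counts[cut] = log_counts.get(cut, 0) + 1
            else:
                mu = mean_c[sel]  # p x K
                v = pooled_all[sel][:, None]
                d = xi[sel][:, None] - mu
                ll = -0.5 * (np.log(v).sum(axis=0) + (d * d / v).sum(axis=0))
                pred = int(np.argmax(ll + log_prior))
            predictions[cut].append(labels[pred])
            if pred == ci:
                correct[cut] += 1

        sums[:, ci] += xi
        sumsq[:, ci] += xi * xi
        counts[ci] += 1

    for cut, n_empty in log_counts.items():
        log.info("cutoff %.1e: %d split(s) selected no probe; used prior fallback", cut, n_empty)
    accuracies = pd.Series({cut: correct[cut] / n_total for cut in grid}).sort_index()
    best_acc = accuracies.max()
    best_cutoff = min(c for c, a in accuracies.items() if a == best_acc)
    return GridSearchResult(
        best_cutoff=float(best_cutoff),
        accuracies=accuracies,
        best_predictions=pd.Series(predictions[best_cutoff], index=matrix.columns),
    )
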