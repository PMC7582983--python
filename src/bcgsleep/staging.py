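"""Five-stage logistic sleep-stage model and its evaluation.

Each sleep stage S in {WAKE, REM, N1, N2, N3} has its own logistic
probability

    sigma_S = 1 / (1 + exp(-(A + B*RR + C*RRstd + D*VLF + E*LF/HF)))

over the per-epoch HRV features.  The five logistics are independent
one-vs-rest models — their probabilities need not sum to one — and an
epoch is assigned the argmax stage, ties broken in the fixed order
WAKE, REM, N1, N2, N3.

Fitting is full-batch gradient descent on the cross-entropy of each
one-vs-rest problem (the single-layer special case of backpropagation),
with features z-scored internally; the standardization is stored with
the coefficients, because coefficients of order one are only meaningful
on standardized inputs (raw VLF power is orders of magnitude smaller
than mean RR).

A published reference coefficient set and a published evaluation
confusion matrix ship with the package (``load_reference_params``,
``load_reference_confusion_matrix``).  The feature scaling under which
the reference coefficients were estimated was not published, so they
reproduce the model's functional form but cannot be validated against
real probabilities; treat them as illustrative defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from bcgsleep.features import FEATURE_COLUMNS, FeatureVector

__all__ = [
    "STAGES",
    "STAGES_MERGED",
    "StageParams",
    "Hypnogram",
    "ConfusionMatrix",
    "SleepStageModel",
    "SleepStageResults",
    "stage_probability",
    "classify_epoch",
    "fit_params",
    "loso_evaluate",
    "merge_light_sleep",
    "accuracy",
    "load_reference_params",
    "load_reference_confusion_matrix",
]

STAGES = ("WAKE", "REM", "N1", "N2", "N3")
STAGES_MERGED = ("WAKE", "REM", "LIGHT", "N3")
MODEL_FEATURES = ("rr_mean", "rr_std", "vlf", "lf_hf")
COEF_NAMES = ("A", "B", "C", "D", "E")


@dataclass
class StageParams:
    """Per-stage logistic coefficients with optional feature standardization.

    ``coefficients`` maps each stage to the array (A, B, C, D, E):
    intercept plus one weight per model feature (rr_mean, rr_std, vlf,
    lf_hf).  ``feature_means``/``feature_sds``, when present, are applied
    to the features before the logistic; they record the z-scoring under
    which the coefficients were estimated.
    """

    coefficients: dict[str, np.ndarray]
    feature_means: Optional[np.ndarray] = None
    feature_sds: Optional[np.ndarray] = None
    degenerate_stages: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        missing = [s for s in STAGES if s not in self.coefficients]
        if missing:
            raise ValueError(f"missing stage(s) {missing} in parameters")
        self.coefficients = {
            s: np.asarray(self.coefficients[s], dtype=float) for s in STAGES
        }
        for s, c in self.coefficients.items():
            if c.shape != (5,) or not np.all(np.isfinite(c)):
                raise ValueError(f"stage {s}: coefficients must be 5 finite values")
        if (self.feature_means is None) != (self.feature_sds is None):
            raise ValueError("feature_means and feature_sds must be given together")
        if self.feature_means is not None:
            self.feature_means = np.asarray(self.feature_means, dtype=float)
            self.feature_sds = np.asarray(self.feature_sds, dtype=float)
            if self.feature_means.shape != (4,) or self.feature_sds.shape != (4,):
                raise ValueError("standardization must give mean and sd per model feature")
            if np.any(self.feature_sds <= 0):
                raise ValueError("standardization sds must be positive")

    def standardize(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.feature_means is None:
            return x
        return (x - self.feature_means) / self.feature_sds

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[s, *self.coefficients[s]] for s in STAGES],
            columns=["stage", *COEF_NAMES],
        )

    def write_csv(self, path: str | Path, standardization_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(path, index=False)
        if standardization_path is not None and self.feature_means is not None:
            pd.DataFrame(
                {
                    "feature": MODEL_FEATURES,
                    "mean": self.feature_means,
                    "sd": self.feature_sds,
                }
            ).to_csv(standardization_path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, standardization_path: str | Path | None = None
    ) -> "StageParams":
        df = pd.read_csv(path)
        coef = {
            str(row["stage"]): np.array([row[c] for c in COEF_NAMES], dtype=float)
            for _, row in df.iterrows()
        }
        means = sds = None
        if standardization_path is not None:
            sdf = pd.read_csv(standardization_path).set_index("feature")
            means = sdf.loc[list(MODEL_FEATURES), "mean"].to_numpy(dtype=float)
            sds = sdf.loc[list(MODEL_FEATURES), "sd"].to_numpy(dtype=float)
        return cls(coefficients=coef, feature_means=means, feature_sds=sds)


@dataclass
class Hypnogram:
    """One stage label per scoring epoch."""

    stages: Sequence[str]
    tau: float = 30.0

    def __post_init__(self) -> None:
        self.stages = list(self.stages)
        allowed = set(STAGES) | set(STAGES_MERGED)
        bad = sorted({s for s in self.stages if s not in allowed})
        if bad:
            raise ValueError(f"unknown stage label(s) {bad}")

    def __len__(self) -> int:
        return len(self.stages)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, s in enumerate(self.stages, start=1):
                fh.write(f"{i}\t{s}\n")

    @classmethod
    def read_tsv(cls, path: str | Path, tau: float = 30.0) -> "Hypnogram":
        stages: list[str] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}: expected 'epoch<TAB>stage' at line {lineno}")
                idx, stage = int(parts[0]), parts[1]
                if idx != len(stages) + 1:
                    raise ValueError(f"{path}: epoch indices must be contiguous from 1 (line {lineno})")
                stages.append(stage)
        return cls(stages=stages, tau=tau)


@dataclass
class ConfusionMatrix:
    """Epoch-count confusion matrix; rows are true stages, columns predicted."""

    counts: np.ndarray
    labels: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k} for labels {self.labels}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def row_totals(self) -> np.ndarray:
        """Epoch count per true stage."""
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))
        df["Epoch Count"] = self.row_totals
        return df

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def read_csv(cls, path: str | Path) -> "ConfusionMatrix":
        """Read a confusion-matrix CSV, validating the Epoch Count column.

        The stated per-stage epoch counts must equal the row sums of the
        cells; a mismatch means a corrupted or mistranscribed table.
        """
        df = pd.read_csv(path, index_col=0)
        labels = tuple(str(c) for c in df.columns if c != "Epoch Count")
        counts = df[list(labels)].to_numpy(dtype=int)
        cm = cls(counts=counts, labels=labels)
        if "Epoch Count" in df.columns:
            stated = df["Epoch Count"].to_numpy(dtype=int)
            if not np.array_equal(stated, cm.row_totals):
                raise ValueError(
                    f"{path}: Epoch Count column {stated.tolist()} does not match "
                    f"row sums {cm.row_totals.tolist()}"
                )
        return cm


def _feature_array(features: "FeatureVector | np.ndarray | Sequence[float]") -> np.ndarray:
    if isinstance(features, FeatureVector):
        return features.as_array()
    return np.asarray(features, dtype=float)


def stage_probability(
    features: "FeatureVector | np.ndarray", params: StageParams, stage: str
) -> float:
    """Logistic probability that an epoch with these features is in ``stage``."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    x = _feature_array(features)
    if x.shape != (4,) or not np.all(np.isfinite(x)):
        raise ValueError("features must be 4 finite values (rr_mean, rr_std, vlf, lf_hf)")
    z = params.standardize(x)
    c = params.coefficients[stage]
    return float(1.0 / (1.0 + np.exp(-(c[0] + z @ c[1:]))))


def classify_epoch(features: "FeatureVector | np.ndarray", params: StageParams) -> str:
    """Argmax over the five stage probabilities; ties go to the earlier stage."""
    probs = [stage_probability(features, params, s) for s in STAGES]
    return STAGES[int(np.argmax(probs))]  # np.argmax returns the first maximum


def _fit_binary_logistic(
    X: np.ndarray, y: np.ndarray, learning_rate: float, n_iterations: int
) -> np.ndarray:
    """Full-batch gradient descent on mean cross-entropy, zero initialization.

    ``X`` already includes the intercept column.  Deterministic: no
    randomness enters a zero-initialized full-batch descent.
    """
    w = np.zeros(X.shape[1])
    n = X.shape[0]
    for _ in range(n_iterations):
        p = 1.0 / (1.0 + np.exp(-(X @ w)))
        w -= learning_rate * (X.T @ (p - y)) / n
    return w


def fit_params(
    features: "pd.DataFrame | np.ndarray",
    labels: "Hypnogram | Sequence[str]",
    learning_rate: float = 0.1,
    n_iterations: int = 5000,
    seed: int | None = None,
) -> StageParams:
    """Fit the five one-vs-rest logistics by gradient descent.

    ``features`` is an (n, 4) array of (rr_mean, rr_std, vlf, lf_hf) or
    a feature table containing those columns.  Features are z-scored
    over the training set and the transform stored in the result.  A
    stage absent from the labels is flagged degenerate (its one-vs-rest
    problem has no positive examples).

    ``seed`` is accepted for interface stability; the default
    zero-initialized full-batch descent is deterministic without it.
    """
    if isinstance(features, pd.DataFrame):
        X = features[list(MODEL_FEATURES)].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != 4:
        raise ValueError("features must be an (n, 4) array or table")
    stages = list(labels.stages) if isinstance(labels, Hypnogram) else list(labels)
    if len(stages) != X.shape[0]:
        raise ValueError("one label per feature row required")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite (inf LF/HF epochs must be excluded)")
    if len(set(stages)) < 2:
        raise ValueError("need at least 2 distinct stage labels to fit")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    sds = np.where(sds > 0, sds, 1.0)
    Z = (X - means) / sds
    Xd = np.column_stack([np.ones(Z.shape[0]), Z])
    y_all = np.asarray(stages)
    coef: dict[str, np.ndarray] = {}
    degenerate = set()
    for s in STAGES:
        y = (y_all == s).astype(float)
        if y.sum() == 0 or y.sum() == y.size:
            degenerate.add(s)
        coef[s] = _fit_binary_logistic(Xd, y, learning_rate, n_iterations)
    return StageParams(
        coefficients=coef,
        feature_means=means,
        feature_sds=sds,
        degenerate_stages=frozenset(degenerate),
    )


class SleepStageModel:
    """One-vs-rest logistic sleep-stage model over per-epoch HRV features.

    Parameters
    ----------
    features
        (n, 4) array or feature table with columns rr_mean, rr_std, vlf,
        lf_hf — one row per scored epoch.
    labels
        Stage label per epoch (five-stage set), as a sequence or
        :class:`Hypnogram`.

    Examples
    --------
    >>> model = SleepStageModel(features_df, hypnogram)   # doctest: +SKIP
    >>> res = model.fit()                                 # doctest: +SKIP
    >>> print(res.summary())                              # doctest: +SKIP
    """

    def __init__(
        self,
        features: "pd.DataFrame | np.ndarray",
        labels: "Hypnogram | Sequence[str]",
    ) -> None:
        if isinstance(features, pd.DataFrame):
            self.exog = features[list(MODEL_FEATURES)].to_numpy(dtype=float)
        else:
            self.exog = np.asarray(features, dtype=float)
        self.labels = list(labels.stages) if isinstance(labels, Hypnogram) else list(labels)
        if self.exog.ndim != 2 or self.exog.shape[1] != 4:
            raise ValueError("features must be (n, 4)")
        if len(self.labels) != self.exog.shape[0]:
            raise ValueError("one label per feature row required")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_column: str = "stage"
    ) -> "SleepStageModel":
        """Build from a single table carrying both features and labels."""
        return cls(df, df[label_column].tolist())

    @property
    def nobs(self) -> int:
        return self.exog.shape[0]

    def fit(
        self,
        learning_rate: float = 0.1,
        n_iterations: int = 5000,
        seed: int | None = None,
    ) -> "SleepStageResults":
        params = fit_params(
            self.exog, self.labels, learning_rate=learning_rate,
            n_iterations=n_iterations, seed=seed,
        )
        return SleepStageResults(self, params)


class SleepStageResults:
    """Fitted sleep-stage model: coefficients, diagnostics and prediction."""

    def __init__(self, model: SleepStageModel, params: StageParams) -> None:
        self.model = model
        self.params = params

    def predict_proba(self, features: "pd.DataFrame | np.ndarray") -> pd.DataFrame:
        """Per-stage probabilities, one row per epoch (columns need not sum to 1)."""
        if isinstance(features, pd.DataFrame):
            X = features[list(MODEL_FEATURES)].to_numpy(dtype=float)
        else:
            X = np.atleast_2d(np.asarray(features, dtype=float))
        return pd.DataFrame(
            {s: [stage_probability(x, self.params, s) for x in X] for s in STAGES}
        )

    def predict(self, features: "pd.DataFrame | np.ndarray") -> list[str]:
        probs = self.predict_proba(features)
        return [STAGES[i] for i in probs.to_numpy().argmax(axis=1)]

    @property
    def training_accuracy(self) -> float:
        pred = self.predict(self.model.exog)
        truth = self.model.labels
        return float(np.mean([p == t for p, t in zip(pred, truth)]))

    def confusion(self) -> ConfusionMatrix:
        """In-sample confusion matrix (rows true, columns predicted)."""
        pred = self.predict(self.model.exog)
        return _confusion_from_labels(self.model.labels, pred)

    def summary(self) -> str:
        lines = [
            "One-vs-rest logistic sleep-stage model",
            "=" * 62,
            f"Epochs: {self.model.nobs}    Features: {', '.join(MODEL_FEATURES)}",
            f"Training accuracy (5-stage argmax): {self.training_accuracy:.3f}",
            "",
            f"{'stage':<6}" + "".join(f"{c:>10}" for c in COEF_NAMES),
        ]
        for s in STAGES:
            c = self.params.coefficients[s]
            flag = "  (degenerate)" if s in self.params.degenerate_stages else ""
            lines.append(f"{s:<6}" + "".join(f"{v:>10.4f}" for v in c) + flag)
        if self.params.feature_means is not None:
            lines.append("")
            lines.append("Feature standardization (applied before the logistic):")
            for name, m, sd in zip(
                MODEL_FEATURES, self.params.feature_means, self.params.feature_sds
            ):
                lines.append(f"  {name:<8} mean {m:>12.6g}   sd {sd:>12.6g}")
        return "\n".join(lines)


def _confusion_from_labels(
    truth: Sequence[str], predicted: Sequence[str], labels: tuple[str, ...] = STAGES
) -> ConfusionMatrix:
    index = {s: i for i, s in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(truth, predicted):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, labels=labels)


def loso_evaluate(
    dataset: Mapping[str, tuple["pd.DataFrame | np.ndarray", "Hypnogram | Sequence[str]"]],
    learning_rate: float = 0.1,
    n_iterations: int = 5000,
) -> tuple[ConfusionMatrix, float, float]:
    """Leave-one-subject-out evaluation.

    For each subject the model is fitted on all other subjects' epochs
    and applied to the held-out subject; per-fold confusion counts are
    summed into one matrix.  Returns the combined matrix, the five-stage
    accuracy (trace/total), and the four-stage accuracy after merging N1
    and N2 into LIGHT.
    """
    subjects = list(dataset)
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")

    def _xy(entry):
        feats, labels = entry
        if isinstance(feats, pd.DataFrame):
            feats = feats[list(MODEL_FEATURES)].to_numpy(dtype=float)
        else:
            feats = np.asarray(feats, dtype=float)
        labels = list(labels.stages) if isinstance(labels, Hypnogram) else list(labels)
        return feats, labels

    combined = np.zeros((5, 5), dtype=int)
    for held_out in subjects:
        train_X, train_y = [], []
        for s in subjects:
            if s == held_out:
                continue
            X, y = _xy(dataset[s])
            train_X.append(X)
            train_y.extend(y)
        params = fit_params(
            np.vstack(train_X), train_y,
            learning_rate=learning_rate, n_iterations=n_iterations,
        )
        X_test, y_test = _xy(dataset[held_out])
        pred = [classify_epoch(x, params) for x in X_test]
        combined += _confusion_from_labels(y_test, pred).counts
    cm = ConfusionMatrix(combined, STAGES)
    acc5 = accuracy(cm)
    acc4 = accuracy(merge_light_sleep(cm))
    return cm, acc5, acc4


def merge_light_sleep(cm: ConfusionMatrix) -> ConfusionMatrix:
    """Sum the N1 and N2 rows/columns into a single LIGHT stage.

    Total epoch count is conserved; the merged trace gains the N1<->N2
    cross terms, which stop counting as errors once light sleep is one
    category.
    """
    if "N1" not in cm.labels or "N2" not in cm.labels:
        raise ValueError("matrix is already merged (no N1/N2 stages)")
    i1, i2 = cm.labels.index("N1"), cm.labels.index("N2")
    keep = [i for i in range(len(cm.labels)) if i not in (i1, i2)]
    new_labels = []
    rows = []
    merged_row = cm.counts[i1] + cm.counts[i2]
    inserted = False
    for i in range(len(cm.labels)):
        if i in (i1, i2):
            if not inserted:
                new_labels.append("LIGHT")
                rows.append(merged_row)
                inserted = True
            continue
        new_labels.append(cm.labels[i])
        rows.append(cm.counts[i])
    counts = np.vstack(rows)
    j1, j2 = i1, i2
    light_pos = new_labels.index("LIGHT")
    merged_col = counts[:, j1] + counts[:, j2]
    keep_cols = [j for j in range(counts.shape[1]) if j not in (j1, j2)]
    out = np.zeros((len(new_labels), len(new_labels)), dtype=int)
    col_src = iter(keep_cols)
    for j in range(len(new_labels)):
        if j == light_pos:
            out[:, j] = merged_col
        else:
            out[:, j] = counts[:, next(col_src)]
    return ConfusionMatrix(out, tuple(new_labels))


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall agreement: trace / total epoch count."""
    if cm.total == 0:
        raise ValueError("accuracy undefined for an empty matrix")
    return float(np.trace(cm.counts) / cm.total)


def load_reference_params() -> StageParams:
    """Published reference coefficients for the five-stage model.

    The feature scaling used when these were estimated was not published;
    they reproduce the functional form, not calibrated probabilities.
    """
    with resources.files("bcgsleep.data").joinpath("reference_stage_params.csv").open() as fh:
        df = pd.read_csv(fh)
    coef = {
        str(r["stage"]).upper(): np.array([r[c] for c in COEF_NAMES], dtype=float)
        for _, r in df.iterrows()
    }
    return StageParams(coefficients=coef)


def load_reference_confusion_matrix() -> ConfusionMatrix:
    """Published leave-one-subject-out evaluation matrix (five stages)."""
    path = resources.files("bcgsleep.data").joinpath("reference_confusion_matrix.csv")
    with resources.as_file(path) as p:
        return ConfusionMatrix.read_csv(p)
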