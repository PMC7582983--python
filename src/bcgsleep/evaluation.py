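"""Agreement between estimated and reference RR-interval series.

Estimated intervals (from the bed sensors) are paired one-to-one with
reference intervals (from the reference pulse channel) by nearest
timestamp.  A paired interval deviating by more than 10% of the
reference value counts as incorrect; precision is the fraction of paired
intervals that are correct.  RMSE and MAE are reported in milliseconds
over the paired values, and overall concordance is summarized by
Bland–Altman bias/limits of agreement and Lin's concordance correlation
coefficient.  Reference intervals that attract no estimate are tracked
separately through ``detection_rate`` — a missed beat and a mistimed
beat are different failure modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from bcgsleep.beats import RrSeries

__all__ = [
    "MatchResult",
    "EvalReport",
    "match_rr",
    "precision",
    "rmse",
    "mae",
    "bland_altman",
    "lin_ccc",
    "segment_rr",
    "evaluate_rr",
]

DEFAULT_REL_TOLERANCE = 0.10


@dataclass
class MatchResult:
    """One-to-one pairing of estimated (x) and reference (y) RR intervals."""

    pairs: np.ndarray  # shape (n, 2): columns (estimated, reference), seconds
    n_correct: int
    n_incorrect: int
    n_reference: int

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=float).reshape(-1, 2)
        if self.n_correct + self.n_incorrect != self.pairs.shape[0]:
            raise ValueError("correct + incorrect must equal the number of pairs")

    @property
    def n_pairs(self) -> int:
        return int(self.pairs.shape[0])

    @property
    def x(self) -> np.ndarray:
        """Estimated RR values (seconds)."""
        return self.pairs[:, 0]

    @property
    def y(self) -> np.ndarray:
        """Reference RR values (seconds)."""
        return self.pairs[:, 1]

    @property
    def detection_rate(self) -> float:
        """Fraction of reference intervals that attracted an estimate."""
        return self.n_pairs / self.n_reference if self.n_reference else 0.0


@dataclass
class EvalReport:
    """Flat summary of one agreement analysis."""

    precision: float
    rmse_ms: float
    mae_ms: float
    bias: float
    loa_low: float
    loa_high: float
    ccc: Optional[float]
    detection_rate: float
    n_pairs: int
    n_reference: int

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "rmse_ms": self.rmse_ms,
            "mae_ms": self.mae_ms,
            "bias": self.bias,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "ccc": self.ccc if self.ccc is not None else float("nan"),
            "detection_rate": self.detection_rate,
            "n_pairs": self.n_pairs,
            "n_reference": self.n_reference,
        }

    def write_csv(self, path: str | Path) -> None:
        """Serialize as flat key,value CSV."""
        with open(path, "w") as fh:
            fh.write("key,value\n")
            for k, v in self.to_dict().items():
                fh.write(f"{k},{v}\n")


def match_rr(
    est: RrSeries, ref: RrSeries, rel_tolerance: float = DEFAULT_REL_TOLERANCE
) -> MatchResult:
    """Pair estimated with reference intervals and apply the 10% criterion.

    Pairing is one-to-one by nearest timestamp, assigned greedily in
    ascending order of time gap (deterministic and order-independent).
    A candidate pairing whose time gap exceeds half the local reference
    RR is left unmatched — it is closer to a different beat than to the
    one it would be scored against.  A pair is correct when
    ``|x - y| / y <= rel_tolerance``.
    """
    if len(ref) == 0:
        raise ValueError("reference series is empty")
    te, xe = est.times, est.rr
    tr, yr = ref.times, ref.rr
    if len(est) == 0:
        return MatchResult(np.empty((0, 2)), 0, 0, len(ref))
    # all candidate (gap, est index, ref index), sorted by gap then indices
    gaps = np.abs(te[:, None] - tr[None, :])
    order = np.argsort(gaps, axis=None, kind="stable")
    used_e = np.zeros(te.size, dtype=bool)
    used_r = np.zeros(tr.size, dtype=bool)
    pairs: list[tuple[float, float]] = []
    for flat in order:
        i, j = divmod(int(flat), tr.size)
        if used_e[i] or used_r[j]:
            continue
        if gaps[i, j] > 0.5 * yr[j]:
            continue
        used_e[i] = used_r[j] = True
        pairs.append((xe[i], yr[j]))
        if used_r.all() or used_e.all():
            break
    arr = np.asarray(pairs, dtype=float).reshape(-1, 2)
    if arr.shape[0]:
        correct = np.abs(arr[:, 0] - arr[:, 1]) / arr[:, 1] <= rel_tolerance
        n_correct = int(correct.sum())
    else:
        n_correct = 0
    return MatchResult(arr, n_correct, arr.shape[0] - n_correct, len(ref))


def precision(match: MatchResult) -> float:
    """Fraction of paired intervals within tolerance: correct / (correct + incorrect)."""
    total = match.n_correct + match.n_incorrect
    if total == 0:
        raise ValueError("precision undefined: no paired intervals")
    return match.n_correct / total


def rmse(match: MatchResult) -> float:
    """Root mean squared error of paired intervals, in milliseconds."""
    if match.n_pairs == 0:
        raise ValueError("rmse undefined: no pairs")
    d = match.y - match.x
    return float(np.sqrt(np.mean(d * d)) * 1000.0)


def mae(match: MatchResult) -> float:
    """Mean absolute error of paired intervals, in milliseconds."""
    if match.n_pairs == 0:
        raise ValueError("mae undefined: no pairs")
    return float(np.mean(np.abs(match.y - match.x)) * 1000.0)


def bland_altman(
    pairs: np.ndarray,
) -> tuple[float, float, float, np.ndarray]:
    """Bland–Altman bias and 1.96-SD limits of agreement.

    Differences are estimate minus reference.  Returns
    ``(bias, loa_low, loa_high, coords)`` where ``coords`` holds the
    per-pair (mean, difference) plotting coordinates.
    """
    pairs = np.asarray(pairs, dtype=float).reshape(-1, 2)
    if pairs.shape[0] < 2:
        raise ValueError("Bland-Altman requires at least 2 pairs")
    d = pairs[:, 0] - pairs[:, 1]
    m = pairs.mean(axis=1)
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    coords = np.column_stack([m, d])
    return bias, bias - 1.96 * sd, bias + 1.96 * sd, coords


def lin_ccc(pairs: np.ndarray) -> float:
    """Lin's concordance correlation coefficient.

    ``CCC = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2)``
    with biased (1/n) moment estimators, following the original
    definition.  Measures agreement with the identity line, not just
    linear association.
    """
    pairs = np.asarray(pairs, dtype=float).reshape(-1, 2)
    if pairs.shape[0] < 2:
        raise ValueError("CCC requires at least 2 pairs")
    x, y = pairs[:, 0], pairs[:, 1]
    mx, my = x.mean(), y.mean()
    vx = np.mean((x - mx) ** 2)
    vy = np.mean((y - my) ** 2)
    cov = np.mean((x - mx) * (y - my))
    denom = vx + vy + (mx - my) ** 2
    if denom == 0.0:
        raise ValueError("CCC undefined: zero variance and equal means")
    return float(2.0 * cov / denom)


def segment_rr(rr: RrSeries, segment_length: float = 30.0) -> list[RrSeries]:
    """Split an RR series into consecutive fixed-length time segments.

    Intervals are assigned to segments by their timestamp.  Empty
    segments are omitted; segments are returned in time order.
    """
    if segment_length <= 0:
        raise ValueError("segment_length must be positive")
    if len(rr) == 0:
        return []
    bins = np.floor(rr.times / segment_length).astype(int)
    return [
        RrSeries(rr.times[bins == b], rr.rr[bins == b])
        for b in np.unique(bins)
    ]


def evaluate_rr(
    est: RrSeries, ref: RrSeries, rel_tolerance: float = DEFAULT_REL_TOLERANCE
) -> EvalReport:
    """Full agreement report for one estimated-vs-reference comparison."""
    match = match_rr(est, ref, rel_tolerance=rel_tolerance)
    if match.n_pairs == 0:
        raise ValueError("no estimated interval could be paired with the reference")
    prec = precision(match)
    if match.n_pairs >= 2:
        bias, lo, hi, _ = bland_altman(match.pairs)
        try:
            ccc = lin_ccc(match.pairs)
        except ValueError:
            ccc = None
    else:
        d = float(match.x[0] - match.y[0])
        bias, lo, hi, ccc = d, d, d, None
    return EvalReport(
        precision=prec,
        rmse_ms=rmse(match),
        mae_ms=mae(match),
        bias=bias,
        loa_low=lo,
        loa_high=hi,
        ccc=ccc,
        detection_rate=match.detection_rate,
        n_pairs=match.n_pairs,
        n_reference=match.n_reference,
    )
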