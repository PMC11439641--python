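"""Evaluation metrics: concordance index and mean squared error.

The concordance index (CI) is the fraction of record pairs with differing
true affinity that the predictions rank in the same order; a predicted tie
counts half.  0.5 is random ranking, 1.0 perfect.  Pairs whose true
affinities are equal are not compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class EvaluationResult:
    ci: float
    mse: float
    n_pairs_compared: int

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("ci,mse,n_pairs_compared\n")
            fh.write(f"{self.ci:.6f},{self.mse:.6f},{self.n_pairs_compared}\n")


def _validate(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    yt = np.asarray(y_true, dtype=np.float64).ravel()
    yp = np.asarray(y_pred, dtype=np.float64).ravel()
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    return yt, yp


def concordance_index(y_true, y_pred) -> float:
    """CI over all ordered pairs with y_true[i] > y_true[j]: 1 point if the
    prediction agrees, 0.5 if the predictions tie, 0 otherwise."""
    yt, yp = _validate(y_true, y_pred)
    if yt.size < 2:
        raise ValueError("concordance index needs at least 2 observations")
    # vectorized O(n^2) pair comparison
    dt = yt[:, None] - yt[None, :]
    dp = yp[:, None] - yp[None, :]
    pos = dt > 0
    n_pairs = int(pos.sum())
    if n_pairs == 0:
        raise ValueError("concordance index undefined: all true values tied")
    score = np.where(dp > 0, 1.0, np.where(dp == 0, 0.5, 0.0))
    return float((score * pos).sum() / n_pairs)


def n_comparable_pairs(y_true) -> int:
    yt = np.asarray(y_true, dtype=np.float64).ravel()
    return int((yt[:, None] > yt[None, :]).sum())


def mean_squared_error(y_true, y_pred) -> float:
    yt, yp = _validate(y_true, y_pred)
    if yt.size == 0:
        raise ValueError("mean squared error of empty vectors is undefined")
    return float(np.mean((yt - yp) ** 2))


def evaluate(y_true, y_pred) -> EvaluationResult:
    return EvaluationResult(
        ci=concordance_index(y_true, y_pred),
        mse=mean_squared_error(y_true, y_pred),
        n_pairs_compared=n_comparable_pairs(y_true),
    )
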