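"""Leave-one-participant-out prediction of weight change from connectivity.

For each participant i the model

    dw = beta0 + beta_roi * z + eps

is fitted by ordinary least squares on the other n-1 (z, dw) pairs and
used to predict dw_i from z_i.  Agreement between predicted and observed
weight change is summarized by Pearson r with (i) a parametric two-tailed
t-transform p-value and (ii) a nonparametric chance interval: percentile
bounds of r over random permutations of the observed vector against the
fixed predictions.

A caution documented in the methods note: under the null (feature
carries no information) the LOOCV predicted-observed correlation is
*negatively* biased, because when the training slope is near zero the
predictions collapse to the leave-one-out training means, which
correlate -1 with the observations.  Predictive skill is therefore a
directional question, and ``PredictionResult.detected`` compares r to
the *upper* chance bound only.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "LoocvFit",
    "PredictionResult",
    "CorrelationInference",
    "weight_change",
    "parametric_p",
    "loocv_predict",
    "correlation_inference",
    "predict_weight_change_pipeline",
]


@dataclasses.dataclass(frozen=True)
class LoocvFit:
    """OLS coefficients of one training fold (n-1 participants)."""

    beta0: float
    beta_roi: float
    residual_sd: float
    left_out: str


@dataclasses.dataclass
class PredictionResult:
    """Observed vs LOOCV-predicted weight change with inference."""

    observed: np.ndarray
    predicted: np.ndarray
    participants: list[str]
    fits: list[LoocvFit]
    roi: str = ""
    r: float | None = None
    p_parametric: float | None = None
    perm_low: float | None = None
    perm_high: float | None = None
    n_perm: int = 0

    @property
    def detected(self) -> bool:
        """Predictive skill: r above the upper chance bound."""
        if self.r is None or self.perm_high is None:
            raise ValueError("inference not yet computed")
        return self.r > self.perm_high


class CorrelationInference(NamedTuple):
    r: float
    p_parametric: float
    perm_low: float
    perm_high: float
    n_perm: int


def weight_change(records: Sequence) -> np.ndarray:
    """Weight at T8 minus weight at T0 per record, kg (negative = loss)."""
    out = np.empty(len(records))
    for k, rec in enumerate(records):
        w0, w8 = rec.weight_T0_kg, rec.weight_T8_kg
        if w0 is None or w8 is None or not (np.isfinite(w0) and np.isfinite(w8)):
            raise ValueError(f"record {getattr(rec, 'id', k)} missing a weight")
        out[k] = w8 - w0
    return out


def parametric_p(r: float, n: int) -> float:
    """Two-tailed p of t = r sqrt(n-2) / sqrt(1-r^2) on n-2 df."""
    if n < 4:
        raise ValueError("need n >= 4")
    if not abs(r) < 1:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def _ols(z: np.ndarray, dw: np.ndarray, intercept: bool) -> tuple[float, float]:
    if intercept:
        X = np.column_stack([np.ones_like(z), z])
    else:
        X = z[:, None]
    beta, *_ = np.linalg.lstsq(X, dw, rcond=None)
    return (float(beta[0]), float(beta[1])) if intercept else (0.0, float(beta[0]))


def loocv_predict(z: np.ndarray, dw: np.ndarray,
                  participants: Sequence[str] | None = None,
                  intercept: bool = True, roi: str = "") -> PredictionResult:
    """Fold-by-fold OLS prediction of each held-out participant.

    ``intercept=False`` reproduces the literal slope-only prediction
    form; the default applies the trained intercept (standard OLS
    prediction).
    """
    z = np.asarray(z, dtype=float)
    dw = np.asarray(dw, dtype=float)
    n = z.size
    if n < 4:
        raise ValueError("need at least 4 participants")
    if dw.shape != z.shape:
        raise ValueError("feature and weight-change vectors must align")
    ids = list(participants) if participants is not None else [str(i) for i in range(n)]

    predicted = np.empty(n)
    fits = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        zt, yt = z[mask], dw[mask]
        if np.ptp(zt) == 0:
            raise ValueError(f"constant feature in training fold leaving out {ids[i]}")
        b0, b1 = _ols(zt, yt, intercept)
        resid = yt - (b0 + b1 * zt)
        dof = max(1, zt.size - (2 if intercept else 1))
        fits.append(LoocvFit(beta0=b0, beta_roi=b1,
                             residual_sd=float(np.sqrt((resid @ resid) / dof)),
                             left_out=ids[i]))
        predicted[i] = b0 + b1 * z[i]
    return PredictionResult(observed=dw, predicted=predicted,
                            participants=ids, fits=fits, roi=roi)


def _permutation_r(a: np.ndarray, b: np.ndarray, n_perm: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Pearson r between a and n_perm random shuffles of b, vectorized."""
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.linalg.norm(ac) * np.linalg.norm(bc)
    perms = rng.permuted(np.tile(bc, (n_perm, 1)), axis=1)
    return (perms @ ac) / denom


def correlation_inference(a: np.ndarray, b: np.ndarray, n_perm: int = 10_000,
                          seed: int | np.random.Generator | None = None,
                          percentiles: tuple[float, float] = (5.0, 95.0)
                          ) -> CorrelationInference:
    """Pearson r with parametric p and permutation chance bounds.

    The chance interval is the (5th, 95th) percentile pair of r over
    ``n_perm`` random shuffles of ``b`` against fixed ``a`` — the
    convention matching printed chance bounds of ~+/-1.65/sqrt(n-1);
    other percentile pairs are configurable.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be aligned 1D vectors")
    n = a.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant input vector")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    r = float(np.corrcoef(a, b)[0, 1])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r_perm = _permutation_r(a, b, n_perm, rng)
    lo, hi = np.percentile(r_perm, percentiles)
    return CorrelationInference(r=r, p_parametric=parametric_p(r, n),
                                perm_low=float(lo), perm_high=float(hi),
                                n_perm=n_perm)


def predict_weight_change_pipeline(features: dict[str, np.ndarray],
                                   records: Sequence,
                                   n_perm: int = 10_000,
                                   seed: int | None = 0,
                                   intercept: bool = True
                                   ) -> dict[str, PredictionResult]:
    """LOOCV prediction and inference for each ROI's feature vector.

    ``features`` maps ROI name -> per-participant feature (aligned with
    ``records``).  Each ROI gets an independent permutation stream
    derived from ``seed``.
    """
    dw = weight_change(records)
    ids = [rec.id for rec in records]
    results = {}
    for k, (roi, z) in enumerate(sorted(features.items())):
        res = loocv_predict(np.asarray(z, float), dw, ids,
                            intercept=intercept, roi=roi)
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2, k)))
        inf = correlation_inference(res.predicted, res.observed,
                                    n_perm=n_perm, seed=rng)
        res.r, res.p_parametric = inf.r, inf.p_parametric
        res.perm_low, res.perm_high = inf.perm_low, inf.perm_high
        res.n_perm = inf.n_perm
        results[roi] = res
    return results
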