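"""Hormone-connectivity linkage and simple change tests.

The obese group's ratio statistic

    x = (leptin_T0 - leptin_T8) / (fat_T0 - fat_T8)      [ng/ml per kg]

— serum leptin lost per kilogram of body fat lost — is correlated with
the change in seed-ROI connectivity y = z_T8 - z_T0.  Because leptin is
secreted by white adipose tissue, raw leptin change tracks fat change;
the ratio removes that dependency so the correlation isolates leptin
regulation beyond fat loss.  Inference reuses the permutation machinery
of the prediction module.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import ConnectivityFeature
from .prediction import correlation_inference

__all__ = [
    "HormoneStats",
    "leptin_per_fat_ratio",
    "connectivity_change",
    "hormone_connectivity_correlation",
    "hormone_dataset",
    "change_tests",
]

#: |fat change| below this is treated as an undefined ratio
FAT_CHANGE_EPS_KG = 0.01


@dataclasses.dataclass
class HormoneStats:
    """Ratio statistic x, connectivity change y, and their correlation."""

    x: np.ndarray
    y: np.ndarray
    participants: list[str]
    rho: float
    p_parametric: float
    perm_low: float
    perm_high: float
    n_perm: int


def leptin_per_fat_ratio(leptin_T0: float, leptin_T8: float,
                         fat_T0: float, fat_T8: float,
                         eps_kg: float = FAT_CHANGE_EPS_KG) -> float:
    """(leptin_T0 - leptin_T8) / (fat_T0 - fat_T8), ng/ml per kg."""
    dfat = fat_T0 - fat_T8
    if abs(dfat) < eps_kg:
        raise ValueError(f"fat change {dfat:.3g} kg below {eps_kg} kg: "
                         "ratio undefined")
    return (leptin_T0 - leptin_T8) / dfat


def connectivity_change(z_T0: ConnectivityFeature,
                        z_T8: ConnectivityFeature) -> float:
    """Fisher-z connectivity change z_T8 - z_T0 for one participant/ROI."""
    if z_T0 is None or z_T8 is None:
        raise ValueError("both sessions required for a connectivity change")
    if z_T0.roi != z_T8.roi:
        raise ValueError(f"ROI mismatch: {z_T0.roi!r} vs {z_T8.roi!r}")
    if z_T0.participant != z_T8.participant:
        raise ValueError("connectivity change must pair one participant")
    return z_T8.value - z_T0.value


def hormone_dataset(records: Sequence, y_by_id: dict[str, float],
                    eps_kg: float = FAT_CHANGE_EPS_KG
                    ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Aligned (x, y) vectors over obese participants with complete data.

    Participants whose fat change falls below ``eps_kg`` are excluded
    with a warning rather than producing unstable ratios.
    """
    xs, ys, ids = [], [], []
    for rec in records:
        if rec.group != "obese" or rec.id not in y_by_id:
            continue
        try:
            x = leptin_per_fat_ratio(rec.leptin_T0, rec.leptin_T8,
                                     rec.body_fat_T0_kg, rec.body_fat_T8_kg,
                                     eps_kg)
        except ValueError as err:
            warnings.warn(f"excluding {rec.id}: {err}")
            continue
        xs.append(x)
        ys.append(y_by_id[rec.id])
        ids.append(rec.id)
    return np.asarray(xs), np.asarray(ys), ids


def hormone_connectivity_correlation(x: np.ndarray, y: np.ndarray,
                                     participants: Sequence[str] | None = None,
                                     n_perm: int = 10_000,
                                     seed: int | np.random.Generator | None = 0
                                     ) -> HormoneStats:
    """Pearson rho between the leptin ratio and connectivity change."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 complete obese participants")
    inf = correlation_inference(x, y, n_perm=n_perm, seed=seed)
    ids = list(participants) if participants is not None else [str(i) for i in range(x.size)]
    return HormoneStats(x=x, y=y, participants=ids, rho=inf.r,
                        p_parametric=inf.p_parametric, perm_low=inf.perm_low,
                        perm_high=inf.perm_high, n_perm=inf.n_perm)


def _paired_rows(records: Sequence, measure: str, getter) -> tuple[np.ndarray, np.ndarray]:
    t0, t8 = [], []
    for rec in records:
        if rec.group != "obese":
            continue
        a, b = getter(rec, "T0"), getter(rec, "T8")
        if a is None or b is None:
            continue
        t0.append(a)
        t8.append(b)
    return np.asarray(t0), np.asarray(t8)


_MEASURES = {
    "weight_kg": lambda r, s: r.weight_T0_kg if s == "T0" else r.weight_T8_kg,
    "bmi": lambda r, s: r.bmi(s),
    "body_fat_pct": lambda r, s: r.body_fat_pct(s),
    "body_fat_kg": lambda r, s: r.body_fat_T0_kg if s == "T0" else r.body_fat_T8_kg,
    "leptin_ngml": lambda r, s: r.leptin_T0 if s == "T0" else r.leptin_T8,
    "insulin_mUl": lambda r, s: r.insulin_T0 if s == "T0" else r.insulin_T8,
}


def change_tests(records: Sequence) -> pd.DataFrame:
    """Paired obese T0-vs-T8 t-tests and lean-vs-obese baseline t-tests.

    Returns one row per (measure, test) with t, df and two-tailed p.
    Paired tests are two-tailed on obese participants with both
    sessions; between-group tests compare the groups at T0 where both
    carry the measure.
    """
    rows = []
    for measure, getter in _MEASURES.items():
        t0, t8 = _paired_rows(records, measure, getter)
        if t0.size >= 2:
            if np.ptp(t0 - t8) == 0 and (t0 - t8)[0] == 0:
                tval, pval = 0.0, 1.0  # all-zero change: t defined as 0
            else:
                res = stats.ttest_rel(t0, t8)
                tval, pval = float(res.statistic), float(res.pvalue)
            rows.append({"measure": measure, "test": "paired_obese_T0_vs_T8",
                         "t": tval, "df": int(t0.size - 1),
                         "p": pval, "n": int(t0.size)})
        lean = [getter(r, "T0") for r in records if r.group == "lean"]
        obese = [getter(r, "T0") for r in records if r.group == "obese"]
        lean = np.asarray([v for v in lean if v is not None], dtype=float)
        obese = np.asarray([v for v in obese if v is not None], dtype=float)
        if lean.size >= 2 and obese.size >= 2:
            res = stats.ttest_ind(obese, lean)
            rows.append({"measure": measure, "test": "two_sample_obese_vs_lean_T0",
                         "t": float(res.statistic),
                         "df": int(lean.size + obese.size - 2),
                         "p": float(res.pvalue), "n": int(lean.size + obese.size)})
    return pd.DataFrame(rows)
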