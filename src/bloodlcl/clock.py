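"""Three-CpG DNA-methylation age prediction (pyrosequencing epigenetic clock).

The model is a published affine regression of chronological age on percent
methylation at one CpG in each of three age-associated promoters:

    predicted age = -20.372 + 0.830 * ELOVL2 (CpG5)
                           + 1.723 * KLF14  (CpG2)
                           + 0.715 * TRIM59 (CpG5)

Coefficients are fixed; this module never refits them. Evaluation follows the
convention used for blood vs lymphoblastoid-cell-line (LCL) comparisons: mean
absolute deviation (MAD, years) of predicted from chronological age, and the
Pearson correlation between the two, computed per tissue group. In blood the
clock tracks age closely; in LCLs immortalisation and passaging disrupt the
methylome, so predictions decorrelate from donor age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

AGE_INTERCEPT = -20.372
AGE_COEFFS = {
    "elovl2_cpg5": 0.830,
    "klf14_cpg2": 1.723,
    "trim59_cpg5": 0.715,
}
CPG_SITES = tuple(AGE_COEFFS)

TISSUES = ("blood", "LCL", "unknown")


@dataclass(frozen=True)
class MethylationProfile:
    """Per-sample percent methylation at the three clock CpGs plus donor age."""

    sample_id: str
    elovl2_cpg5: float
    klf14_cpg2: float
    trim59_cpg5: float
    chronological_age: float
    tissue: str = "unknown"

    def __post_init__(self) -> None:
        for site in CPG_SITES:
            v = getattr(self, site)
            if not np.isfinite(v) or not (0.0 <= v <= 100.0):
                raise ValueError(f"{site} must be a percentage in [0, 100], got {v}")
        if not np.isfinite(self.chronological_age) or self.chronological_age < 0:
            raise ValueError("chronological_age must be non-negative")
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}")

    @property
    def predicted_age(self) -> float:
        return predict_age(self.elovl2_cpg5, self.klf14_cpg2, self.trim59_cpg5)


def predict_age(elovl2_cpg5, klf14_cpg2, trim59_cpg5):
    """Predicted age (years) from percent methylation at the three clock CpGs.

    Accepts scalars or array-likes (broadcast elementwise). Values must lie in
    [0, 100]. Predictions are not clamped: the affine model can return
    negative ages or ages beyond the human range, and raw deviations are what
    the MAD evaluation consumes.
    """
    e = np.asarray(elovl2_cpg5, dtype=float)
    k = np.asarray(klf14_cpg2, dtype=float)
    t = np.asarray(trim59_cpg5, dtype=float)
    for name, v in (("elovl2_cpg5", e), ("klf14_cpg2", k), ("trim59_cpg5", t)):
        if not np.all(np.isfinite(v)) or np.any(v < 0) or np.any(v > 100):
            raise ValueError(f"{name} must be percentages in [0, 100]")
    out = (AGE_INTERCEPT
           + AGE_COEFFS["elovl2_cpg5"] * e
           + AGE_COEFFS["klf14_cpg2"] * k
           + AGE_COEFFS["trim59_cpg5"] * t)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class AgeEval:
    """Age-prediction performance for one tissue group.

    ``pearson_r`` is None when fewer than two samples are available or when
    either variable is constant (the correlation is then undefined).
    """

    tissue: str
    n: int
    mad: float
    pearson_r: float | None


def evaluate_predictions(profiles: list[MethylationProfile]) -> dict[str, AgeEval]:
    """MAD and Pearson R of predicted vs chronological age, per tissue group.

    MAD is the mean absolute deviation of the prediction from the
    chronological age in years (not the median-based robust statistic).
    """
    groups: dict[str, list[MethylationProfile]] = {}
    for p in profiles:
        groups.setdefault(p.tissue, []).append(p)
    out: dict[str, AgeEval] = {}
    for tissue, members in groups.items():
        pred = np.array([m.predicted_age for m in members])
        chron = np.array([m.chronological_age for m in members])
        mad = float(np.mean(np.abs(pred - chron)))
        r: float | None = None
        if len(members) >= 2 and np.ptp(pred) > 0 and np.ptp(chron) > 0:
            r = float(stats.pearsonr(pred, chron).statistic)
        out[tissue] = AgeEval(tissue=tissue, n=len(members), mad=mad, pearson_r=r)
    return out


def scatter_table(profiles: list[MethylationProfile]) -> pd.DataFrame:
    """Predicted-vs-chronological table (one row per sample) for plotting."""
    return pd.DataFrame(
        {
            "sample_id": [p.sample_id for p in profiles],
            "tissue": [p.tissue for p in profiles],
            "chronological_age": [p.chronological_age for p in profiles],
            "predicted_age": [p.predicted_age for p in profiles],
        }
    )
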