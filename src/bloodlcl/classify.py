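"""Tissue-of-origin classification from the three-assay qPCR panel.

A sample's panel holds the GAPDH, EBV and rearranged-TCRgamma Ct values and
the TCRbeta melting peaks. GAPDH (a single-copy housekeeping gene) normalises
for DNA input: the decision statistics are the Ct(GAPDH)/Ct(target) ratios,
conventionally reported x100. Each assay gives a three-way label with an
abstention ("uncertain") band:

* EBV: LCLs carry 2-500 episomal EBV genome copies per diploid genome, blood
  essentially none. No amplification is imputed at Ct 40, so blood ratios
  cluster near 100*Ct_GAPDH/40 (~60-70), far below the lower threshold of 91;
  LCL ratios exceed 110. Between the thresholds the call is "uncertain".
* TCRgamma: V(D)J-rearranged TCRgamma templates exist only in blood T cells;
  no amplification is imputed at Ct 45. The rule mirrors EBV: high ratio ->
  blood, low -> LCL.
* TCRbeta: the multiplexed rearrangement PCR yields primer dimers in any
  sample, so Ct is uninformative; instead the highest melting temperature is
  thresholded at 89.5 degC - specific products above it occur only in blood.

Per-assay labels are combined by voting: at least two blood votes -> blood,
else at least two LCL votes -> LCL, otherwise uncertain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

BLOOD = "blood"
LCL = "LCL"
UNCERTAIN = "uncertain"
LABELS = (BLOOD, LCL, UNCERTAIN)

#: fixed Ct assigned when an assay shows no amplification
EBV_IMPUTED_CT = 40.0
TCRG_IMPUTED_CT = 45.0


@dataclass(frozen=True)
class AssayPanel:
    """One sample's called assay values.

    ``ct_ebv`` / ``ct_tcrg`` carry the imputed values 40 / 45 when the assay
    did not amplify, with the corresponding flag set. A sample whose GAPDH
    assay failed is not classifiable and cannot be represented here.
    """

    sample_id: str
    ct_gapdh: float
    ct_ebv: float
    ct_tcrg: float
    tcrb_max_tm: float | None  # None == no melting peak at all
    ebv_imputed: bool = False
    tcrg_imputed: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.ct_gapdh) or self.ct_gapdh <= 0:
            raise ValueError(
                f"sample {self.sample_id!r}: ct_gapdh must be positive and finite "
                "(a sample failing the GAPDH control is not classifiable)")
        for name in ("ct_ebv", "ct_tcrg"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"sample {self.sample_id!r}: {name} must be positive and finite")
        if self.tcrb_max_tm is not None and not np.isfinite(self.tcrb_max_tm):
            raise ValueError(f"sample {self.sample_id!r}: tcrb_max_tm must be finite or None")


@dataclass(frozen=True)
class ThresholdConfig:
    """Decision thresholds for the three assays.

    EBV thresholds (91 / 110 on the x100 ratio scale) and the TCRbeta Tm
    cutoff (89.5 degC) are the published values. TCRgamma thresholds were
    never published; the defaults are calibrated on the synthetic generator
    and can be refit with :func:`calibrate_tcrg_thresholds`.
    """

    ebv_lower: float = 91.0
    ebv_upper: float = 110.0
    tcrg_lower: float = 70.0
    tcrg_upper: float = 80.0
    tcrb_tm_cutoff: float = 89.5
    ratio_scale: float = 100.0

    def __post_init__(self) -> None:
        for lo, hi, name in ((self.ebv_lower, self.ebv_upper, "ebv"),
                             (self.tcrg_lower, self.tcrg_upper, "tcrg")):
            if not (np.isfinite(lo) and np.isfinite(hi)) or lo <= 0 or hi <= 0:
                raise ValueError(f"{name} thresholds must be positive and finite")
            if not lo < hi:
                raise ValueError(f"{name}_lower must be below {name}_upper")
        if self.tcrb_tm_cutoff <= 0 or self.ratio_scale <= 0:
            raise ValueError("tcrb_tm_cutoff and ratio_scale must be positive")


@dataclass(frozen=True)
class OriginCall:
    """Per-assay and combined three-way origin labels for one sample."""

    sample_id: str
    ebv_ratio: float
    tcrg_ratio: float
    tcrb_max_tm: float | None
    label_ebv: str
    label_tcrg: str
    label_tcrb: str
    combined: str
    votes_blood: int
    votes_lcl: int


def ebv_ratio(panel: AssayPanel, scale: float = 100.0) -> float:
    """Normalised EBV load statistic: scale * Ct_GAPDH / Ct_EBV.

    GAPDH sits in the numerator: abundant EBV templates lower Ct_EBV and
    raise the ratio, so LCLs score high and blood (imputed Ct 40) low.
    """
    if panel.ct_ebv == 0:
        raise ValueError("ct_ebv must be non-zero")
    return scale * panel.ct_gapdh / panel.ct_ebv


def tcrg_ratio(panel: AssayPanel, scale: float = 100.0) -> float:
    """Normalised rearranged-TCRgamma statistic: scale * Ct_GAPDH / Ct_TCRgamma."""
    if panel.ct_tcrg == 0:
        raise ValueError("ct_tcrg must be non-zero")
    return scale * panel.ct_gapdh / panel.ct_tcrg


def classify_ebv(ratio: float, cfg: ThresholdConfig = ThresholdConfig()) -> str:
    """Three-way EBV call: below 91 -> blood, above 110 -> LCL, between
    (inclusive boundaries) -> uncertain."""
    if not np.isfinite(ratio):
        raise ValueError("ratio must be finite")
    if ratio < cfg.ebv_lower:
        return BLOOD
    if ratio > cfg.ebv_upper:
        return LCL
    return UNCERTAIN


def classify_tcrg(ratio: float, cfg: ThresholdConfig = ThresholdConfig()) -> str:
    """Three-way TCRgamma call — the mirror of the EBV rule.

    Rearranged TCRgamma amplifies in blood, lowering Ct_TCRgamma and raising
    the ratio: above ``tcrg_upper`` -> blood, below ``tcrg_lower`` -> LCL,
    between (inclusive) -> uncertain.
    """
    if not np.isfinite(ratio):
        raise ValueError("ratio must be finite")
    if ratio > cfg.tcrg_upper:
        return BLOOD
    if ratio < cfg.tcrg_lower:
        return LCL
    return UNCERTAIN


def classify_tcrb(max_tm: float | None, cfg: ThresholdConfig = ThresholdConfig()) -> str:
    """TCRbeta call from the highest melting peak.

    Strictly above the 89.5 degC cutoff -> blood (a specific rearrangement
    product); at or below, or no peak at all -> LCL (primer dimers and
    non-specific products only).
    """
    if max_tm is None:
        return LCL
    if max_tm > cfg.tcrb_tm_cutoff:
        return BLOOD
    return LCL


def combine(labels: tuple[str, str, str]) -> tuple[str, int, int]:
    """Two-of-three vote: >=2 blood -> blood; else >=2 LCL -> LCL; else uncertain.

    Returns (combined label, blood votes, LCL votes). The blood rule is the
    published one; the symmetric LCL rule makes the combined outcome
    three-way, with discordant singleton patterns abstaining.
    """
    if len(labels) != 3:
        raise ValueError("combine expects exactly three per-assay labels")
    for lab in labels:
        if lab not in LABELS:
            raise ValueError(f"unknown label {lab!r}")
    votes_blood = sum(lab == BLOOD for lab in labels)
    votes_lcl = sum(lab == LCL for lab in labels)
    if votes_blood >= 2:
        return BLOOD, votes_blood, votes_lcl
    if votes_lcl >= 2:
        return LCL, votes_blood, votes_lcl
    return UNCERTAIN, votes_blood, votes_lcl


def classify_panel(panel: AssayPanel, cfg: ThresholdConfig = ThresholdConfig()) -> OriginCall:
    """Full per-sample classification: ratios, three per-assay labels, vote."""
    r_ebv = ebv_ratio(panel, cfg.ratio_scale)
    r_tcrg = tcrg_ratio(panel, cfg.ratio_scale)
    lab_ebv = classify_ebv(r_ebv, cfg)
    lab_tcrg = classify_tcrg(r_tcrg, cfg)
    lab_tcrb = classify_tcrb(panel.tcrb_max_tm, cfg)
    combined, vb, vl = combine((lab_ebv, lab_tcrg, lab_tcrb))
    return OriginCall(
        sample_id=panel.sample_id,
        ebv_ratio=r_ebv,
        tcrg_ratio=r_tcrg,
        tcrb_max_tm=panel.tcrb_max_tm,
        label_ebv=lab_ebv,
        label_tcrg=lab_tcrg,
        label_tcrb=lab_tcrb,
        combined=combined,
        votes_blood=vb,
        votes_lcl=vl,
    )


def classify_cohort(panels: list[AssayPanel],
                    cfg: ThresholdConfig = ThresholdConfig()) -> list[OriginCall]:
    """Classify every panel; a failing panel is logged by sample id and
    skipped, the rest are still processed."""
    calls: list[OriginCall] = []
    for panel in panels:
        try:
            calls.append(classify_panel(panel, cfg))
        except ValueError as exc:
            logger.warning("sample %s not classifiable: %s", panel.sample_id, exc)
    return calls


def calibrate_tcrg_thresholds(ratios, labels, min_band: float = 1.0) -> tuple[float, float]:
    """Fit the two TCRgamma thresholds from a labelled calibration cohort.

    Scans all cut points between adjacent sorted ratios and keeps those
    maximising accuracy of the single-cut rule (ratio above the cut -> blood).
    The returned (lower, upper) pair spans the set of equally optimal cuts —
    the region where the calibration data cannot adjudicate — so ratios
    falling inside it are labelled uncertain. A degenerate band is widened to
    ``min_band`` around the optimum.
    """
    r = np.asarray(ratios, dtype=float)
    y = np.asarray(labels)
    if r.shape != y.shape or r.ndim != 1 or len(r) < 2:
        raise ValueError("need matched 1-D ratios and labels with at least 2 samples")
    bad = set(y) - {BLOOD, LCL}
    if bad:
        raise ValueError(f"calibration labels must be blood/LCL, got {sorted(bad)}")
    order = np.argsort(r)
    r_sorted, y_sorted = r[order], y[order]
    cuts = 0.5 * (r_sorted[:-1] + r_sorted[1:])
    is_blood = (y_sorted == BLOOD)
    # accuracy of "ratio > cut -> blood" for each candidate cut
    acc = np.array([np.mean((r_sorted > c) == is_blood) for c in cuts])
    best = np.flatnonzero(acc == acc.max())
    lower, upper = float(cuts[best[0]]), float(cuts[best[-1]])
    if upper - lower < min_band:
        mid = 0.5 * (lower + upper)
        lower, upper = mid - min_band / 2, mid + min_band / 2
    return lower, upper
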