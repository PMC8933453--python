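"""Stage composition: raw curves -> assay panels -> origin calls -> reports.

The panel-assembly step applies the published no-amplification imputation
(Ct 40 for the EBV assay, Ct 45 for TCRgamma) so that normalised ratios are
defined for every sample; a sample whose GAPDH control fails is reported as
unclassifiable rather than silently dropped from counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .classify import (
    EBV_IMPUTED_CT,
    TCRG_IMPUTED_CT,
    AssayPanel,
    OriginCall,
    ThresholdConfig,
    classify_cohort,
)
from .qpcr import AmplificationCurve, MeltCurve, call_ct, extract_tm_peaks
from .synthetic import CohortSample

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignalConfig:
    """Signal-processing parameters for Ct calling and melt-peak extraction."""

    min_amplitude: float = 0.5
    min_prominence: float = 0.5
    ct_window: int = 7
    ct_polyorder: int = 4
    tm_window: int = 9
    tm_polyorder: int = 3
    ct_refine: str = "logistic_fit"


@dataclass
class PanelResult:
    """Panels for classifiable samples plus ids that failed the GAPDH control."""

    panels: list[AssayPanel] = field(default_factory=list)
    unclassifiable: list[str] = field(default_factory=list)


def build_panel(
    sample_id: str,
    amplification: dict[str, AmplificationCurve],
    melt: MeltCurve | None,
    signal: SignalConfig = SignalConfig(),
) -> AssayPanel | None:
    """Call Cts and melting peaks for one sample and assemble its panel.

    Returns None (and logs) when the GAPDH control is missing or does not
    amplify. EBV / TCRgamma assays that are missing or do not amplify get
    the fixed imputed Cts 40 / 45; a missing melt acquisition counts as no
    peak (the most conservative TCRbeta outcome, an LCL call).
    """
    gapdh = amplification.get("GAPDH")
    if gapdh is None:
        logger.warning("sample %s: no GAPDH curve; unclassifiable", sample_id)
        return None
    ct_gapdh = call_ct(gapdh, signal.min_amplitude, window=signal.ct_window,
                       polyorder=signal.ct_polyorder, refine=signal.ct_refine)
    if ct_gapdh.ct is None:
        logger.warning("sample %s: GAPDH did not amplify; unclassifiable", sample_id)
        return None

    def target_ct(assay: str, imputed_value: float) -> tuple[float, bool]:
        curve = amplification.get(assay)
        if curve is None:
            return imputed_value, True
        res = call_ct(curve, signal.min_amplitude, window=signal.ct_window,
                      polyorder=signal.ct_polyorder, refine=signal.ct_refine)
        if res.ct is None:
            return imputed_value, True
        return res.ct, False

    ct_ebv, ebv_imp = target_ct("EBV", EBV_IMPUTED_CT)
    ct_tcrg, tcrg_imp = target_ct("TCRG", TCRG_IMPUTED_CT)

    max_tm = None
    if melt is not None:
        max_tm = extract_tm_peaks(melt, signal.min_prominence,
                                  window=signal.tm_window,
                                  polyorder=signal.tm_polyorder).max_tm

    return AssayPanel(
        sample_id=sample_id, ct_gapdh=ct_gapdh.ct,
        ct_ebv=ct_ebv, ct_tcrg=ct_tcrg, tcrb_max_tm=max_tm,
        ebv_imputed=ebv_imp, tcrg_imputed=tcrg_imp,
    )


def build_panels(samples: list[CohortSample],
                 signal: SignalConfig = SignalConfig()) -> PanelResult:
    """Assemble panels for a generated cohort."""
    result = PanelResult()
    for s in samples:
        panel = build_panel(s.truth.sample_id, s.amplification, s.melt, signal)
        if panel is None:
            result.unclassifiable.append(s.truth.sample_id)
        else:
            result.panels.append(panel)
    return result


def panels_from_curves(
    amplification: list[AmplificationCurve],
    melts: list[MeltCurve],
    signal: SignalConfig = SignalConfig(),
) -> PanelResult:
    """Assemble panels from flat curve lists (as read from curve tables)."""
    by_sample: dict[str, dict[str, AmplificationCurve]] = {}
    for c in amplification:
        by_sample.setdefault(c.sample_id, {})[c.assay] = c
    melt_by_sample: dict[str, MeltCurve] = {m.sample_id: m for m in melts}
    result = PanelResult()
    for sid in sorted(set(by_sample) | set(melt_by_sample)):
        panel = build_panel(sid, by_sample.get(sid, {}), melt_by_sample.get(sid), signal)
        if panel is None:
            result.unclassifiable.append(sid)
        else:
            result.panels.append(panel)
    return result


def classify_samples(
    samples: list[CohortSample],
    thresholds: ThresholdConfig = ThresholdConfig(),
    signal: SignalConfig = SignalConfig(),
) -> tuple[list[OriginCall], PanelResult]:
    """Generated cohort -> origin calls (plus the panel intermediates)."""
    panels = build_panels(samples, signal)
    return classify_cohort(panels.panels, thresholds), panels
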