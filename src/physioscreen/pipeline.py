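"""End-to-end pipeline: recordings → 43 features → tables → screening."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import eda as eda_mod
from . import ppg as ppg_mod
from . import temperature as temp_mod
from .dataset import FEATURE_NAMES, FeatureTable, assemble_dataset, minmax_normalize
from .preprocessing import FilterSpec, apply_filters, make_windows, ppg_filter_spec
from .recording import ChannelRecording
from .screening import ScreeningConfig, ScreeningReport, run_screening
from .synthetic import CohortConfig, CohortRecording, EffectSpec, simulate_cohort

logger = logging.getLogger(__name__)


def extract_phase_features(
    ppg: ChannelRecording,
    eda: ChannelRecording,
    temperature: ChannelRecording,
    apply_acquisition_filters: bool = True,
    window_s: float = 10.0,
) -> dict:
    """All 43 catalogue features for one phase's three channels.

    Features that cannot be computed (e.g. no SCR peaks, trend too short
    for spectral HRV) come back as NaN; the dict always has 43 keys.
    """
    out: dict[str, float] = {name: float("nan") for name in FEATURE_NAMES}
    if apply_acquisition_filters:
        common = FilterSpec()
        ppg = apply_filters(ppg, ppg_filter_spec())
        eda = apply_filters(eda, common)
        temperature = apply_filters(temperature, common)

    try:
        beats = ppg_mod.detect_beats(ppg)
        windows = make_windows(ppg, width_s=window_s)
        out.update(ppg_mod.ppg_shape_features(beats, windows))
        trend = ppg_mod.bpm_trend(beats)
        out.update(ppg_mod.hr_hrv_features(beats, trend))
    except ValueError as err:
        logger.warning("PPG features missing: %s", err)

    try:
        decomp = eda_mod.decompose_eda(eda)
        out.update(eda_mod.scl_features(decomp.tonic, decomp.fs))
        out.update(eda_mod.scr_features(decomp))
    except (ValueError, RuntimeError) as err:
        logger.warning("EDA features missing: %s", err)

    try:
        out.update(temp_mod.temperature_features(temperature, "raw"))
        deriv = temp_mod.estimate_derivative(temperature)
        out.update(temp_mod.temperature_features(deriv, "derivative"))
    except ValueError as err:
        logger.warning("temperature features missing: %s", err)

    return {k: out[k] for k in FEATURE_NAMES}


def extract_cohort_features(cohort: CohortRecording) -> pd.DataFrame:
    """Long feature frame (subject, test, phase, feature, value) for a cohort.

    Phases are generated lazily and released after extraction, so a
    default-sized cohort streams through bounded memory.
    """
    rows = []
    for key in cohort.phase_keys():
        phase = cohort.get_phase(*key)
        feats = extract_phase_features(phase.ppg, phase.eda, phase.temperature)
        for name, value in feats.items():
            rows.append({"subject": phase.subject, "test": phase.test,
                         "phase": phase.phase, "feature": name, "value": value})
    return pd.DataFrame(rows)


def build_feature_tables(features: pd.DataFrame, labels: pd.DataFrame,
                         normalize: bool = True) -> dict[str, FeatureTable]:
    """Assemble per-test tables and (optionally) max–min normalize them."""
    tables = assemble_dataset(features, labels)
    if normalize:
        tables = {t: minmax_normalize(tab) for t, tab in tables.items()}
    return tables


def run_pipeline(
    config: CohortConfig | None = None,
    effect: EffectSpec | None = None,
    screening: ScreeningConfig | None = None,
):
    """Simulate a cohort, extract + normalize features, screen every test.

    Returns ``(tables, reports)``: dicts keyed by test name.
    """
    config = config or CohortConfig()
    cohort = simulate_cohort(config, effect)
    features = extract_cohort_features(cohort)
    tables = build_feature_tables(features, cohort.labels)
    screening = screening or ScreeningConfig()
    reports: dict[str, ScreeningReport] = {
        t: run_screening(tab, screening) for t, tab in tables.items()
    }
    return tables, reports
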