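"""Feature catalogue, labelled table assembly and per-subject normalization.

Each test dataset is a long table of
(subject, test, phase, class, feature, value, normalized) rows whose count
obeys the design identity

    n_data = n_participants × n_phases × n_features

(4816 for the default 28 × 4 × 43 design).  Missing feature values are
kept as explicitly flagged rows so the identity always holds.

Normalization is max–min per subject and per feature, within one test
dataset: v' = (v − min) / (max − min) over that subject's phases.  A
subject-constant feature maps to 0 and is flagged degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

#: The 43-entry feature catalogue, grouped by signal.  The PPG/HR/HRV,
#: SCL/SCR and temperature groups follow the study's feature list; RMSSD
#: and SDNN are the catalogue's two classical IBI-domain HRV entries.
FEATURE_CATALOGUE: dict[str, tuple] = {
    "ppg_shape": (
        "ppg_amplitude_mean", "ppg_amplitude_std", "ppg_amplitude_median",
        "ppg_duration_mean", "ppg_duration_std", "ppg_duration_median",
        "ppg_rise_time_mean", "ppg_rise_time_std", "ppg_rise_time_median",
    ),
    "hr": ("bpm_mean", "bpm_std", "bpm_median"),
    "hrv": (
        "pnn50",
        "plf_mean", "plf_std", "phf_mean", "phf_std",
        "lf_hf_ratio_mean", "lf_hf_ratio_std",
        "rmssd", "sdnn",
    ),
    "scl": ("scl_mean", "scl_std", "scl_slope"),
    "scr": (
        "scr_amplitude_mean", "scr_amplitude_std",
        "scr_rise_time_mean", "scr_rise_time_std",
        "scr_peak_count",
    ),
    "temperature": (
        "temp_initial", "temp_final", "temp_delta", "temp_mean",
        "temp_std", "temp_variation", "temp_variation_slope",
    ),
    "temperature_derivative": (
        "temp_deriv_initial", "temp_deriv_final", "temp_deriv_delta",
        "temp_deriv_mean", "temp_deriv_std", "temp_deriv_variation",
        "temp_deriv_variation_slope",
    ),
}

FEATURE_NAMES: tuple = tuple(n for group in FEATURE_CATALOGUE.values() for n in group)

N_FEATURES = len(FEATURE_NAMES)


def feature_group(name: str) -> str:
    for group, names in FEATURE_CATALOGUE.items():
        if name in names:
            return group
    raise KeyError(f"unknown feature: {name}")


@dataclass
class FeatureTable:
    """Labelled long feature table for ONE test dataset."""

    test: str
    data: pd.DataFrame  # subject, phase, class, feature, value, normalized, missing, degenerate
    n_participants: int
    n_phases: int
    n_features: int = N_FEATURES
    meta: dict = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def validate(self) -> None:
        expected = self.n_participants * self.n_phases * self.n_features
        if self.n_rows != expected:
            raise ValueError(
                f"row-count identity violated for test {self.test!r}: "
                f"{self.n_rows} rows != {self.n_participants} x {self.n_phases} "
                f"x {self.n_features} = {expected}"
            )
        rest = self.data[self.data["class"] == 0]
        per_subject = rest.groupby("subject")["phase"].nunique()
        if not (per_subject == 1).all():
            raise ValueError("each subject must have exactly one class-0 (Rest) phase")
        if "normalized" in self.data:
            norm = self.data["normalized"].dropna()
            if len(norm) and ((norm < -1e-9) | (norm > 1 + 1e-9)).any():
                raise ValueError("normalized values must lie in [0, 1]")

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)
        with open(str(path) + ".yaml", "w") as fh:
            yaml.safe_dump(
                {"test": self.test, "n_participants": self.n_participants,
                 "n_phases": self.n_phases, "n_features": self.n_features}, fh)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        data = pd.read_csv(path)
        with open(str(path) + ".yaml") as fh:
            meta = yaml.safe_load(fh)
        return cls(test=meta["test"], data=data,
                   n_participants=meta["n_participants"],
                   n_phases=meta["n_phases"], n_features=meta["n_features"])


def assemble_dataset(features: pd.DataFrame, labels: pd.DataFrame,
                     feature_names=FEATURE_NAMES) -> dict[str, FeatureTable]:
    """Join long feature rows with class labels into per-test tables.

    ``features`` needs columns (subject, test, phase, feature, value);
    ``labels`` needs (subject, test, phase, class).  Every (subject, test,
    phase) must be labelled, the Rest phase (phase 0) with class 0.
    Missing (subject, phase, feature) combinations become flagged NaN rows
    so per-test row counts always equal
    n_participants × n_phases × n_features.
    """
    feature_names = tuple(feature_names)
    dup = features.duplicated(subset=["subject", "test", "phase", "feature"])
    if dup.any():
        first = features[dup].iloc[0]
        raise ValueError(
            "duplicate feature row for "
            f"(subject={first.subject}, test={first.test}, "
            f"phase={first.phase}, feature={first.feature})"
        )
    unknown = set(features["feature"]) - set(feature_names)
    if unknown:
        raise ValueError(f"features outside the catalogue: {sorted(unknown)}")
    label_map = labels.set_index(["subject", "test", "phase"])["class"]
    if label_map.index.duplicated().any():
        raise ValueError("duplicate label rows")

    tables: dict[str, FeatureTable] = {}
    for test, sub in features.groupby("test", sort=False):
        subjects = sorted(labels.loc[labels.test == test, "subject"].unique())
        phases = sorted(labels.loc[labels.test == test, "phase"].unique())
        for s in sorted(sub["subject"].unique()):
            for p in sorted(sub.loc[sub.subject == s, "phase"].unique()):
                if (s, test, p) not in label_map.index:
                    raise KeyError(f"missing class label for (subject={s}, test={test}, phase={p})")
        grid = pd.MultiIndex.from_product(
            [subjects, phases, feature_names], names=["subject", "phase", "feature"]
        )
        wide = (
            sub.set_index(["subject", "phase", "feature"])["value"]
            .reindex(grid)
            .reset_index()
        )
        wide["missing"] = wide["value"].isna()
        wide["class"] = [
            int(label_map[(s, test, p)]) for s, p in zip(wide["subject"], wide["phase"])
        ]
        wide.insert(1, "test", test)
        table = FeatureTable(
            test=test,
            data=wide[["subject", "test", "phase", "class", "feature", "value", "missing"]],
            n_participants=len(subjects),
            n_phases=len(phases),
            n_features=len(feature_names),
        )
        table.validate()
        tables[test] = table
    return tables


def minmax_normalize(table: FeatureTable) -> FeatureTable:
    """Max–min normalization per (subject, feature) within the test.

    Adds ``normalized`` and ``degenerate`` columns; constant (or
    single-valued) features map to 0 and are flagged degenerate.  Missing
    raw values stay missing.
    """
    out = table.data.copy()
    grp = out.groupby(["subject", "feature"], sort=False)["value"]
    lo = grp.transform("min")
    rng = grp.transform("max") - lo
    degenerate = ~np.isfinite(rng) | (rng == 0)
    normalized = np.where(
        degenerate, np.where(out["value"].notna(), 0.0, np.nan),
        (out["value"] - lo) / rng.where(rng != 0),
    )
    out["normalized"] = normalized
    out["degenerate"] = degenerate.to_numpy()
    result = FeatureTable(
        test=table.test, data=out, n_participants=table.n_participants,
        n_phases=table.n_phases, n_features=table.n_features, meta=dict(table.meta),
    )
    result.validate()
    return result
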