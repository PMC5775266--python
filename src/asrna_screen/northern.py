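"""5S-normalised northern-blot quantification and rnc-response calling.

Band intensities from a developmental time course (vegetative mycelium at
24 h, aerial mycelium at 48 h, spores at 72 h) are divided by the same
lane's 5S rRNA signal to correct loading. Each antisense feature is then
classified by how its level responds to deletion of RNase III (the *rnc*
strain relative to wild type): a geometric-mean rnc/wt ratio across shared
time points of at least ``ratio_threshold`` calls ``increased_in_rnc``, at
most its reciprocal ``decreased_in_rnc``, otherwise ``unchanged``; profiles
below the detection floor in both strains are ``not_detected``. A pseudo
floor in both numerator and denominator keeps ratios finite for empty lanes.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple, Union

import pandas as pd

from .exceptions import InsufficientDataError, TableParseError, ZeroControlError

STRAINS = ("wt", "rnc")
TIME_POINTS_H = (24, 48, 72)


class Response(enum.Enum):
    INCREASED_IN_RNC = "increased_in_rnc"
    DECREASED_IN_RNC = "decreased_in_rnc"
    UNCHANGED = "unchanged"
    NOT_DETECTED = "not_detected"


@dataclass(frozen=True)
class NorthernMeasurement:
    """One lane: a band signal and its 5S loading control."""

    feature_id: str
    strain: str
    time_point_h: int
    band_signal: float
    control_signal: float

    def __post_init__(self) -> None:
        if self.strain not in STRAINS:
            raise TableParseError(f"strain must be one of {STRAINS}, got {self.strain!r}")
        if self.band_signal < 0:
            raise TableParseError(
                f"{self.feature_id} {self.strain} {self.time_point_h}h: band signal < 0"
            )
        if not self.control_signal > 0:
            raise ZeroControlError(
                f"lane {self.feature_id}/{self.strain}/{self.time_point_h}h: "
                f"5S control signal must be > 0, got {self.control_signal!r}"
            )

    @property
    def normalized(self) -> float:
        return self.band_signal / self.control_signal


@dataclass
class NorthernProfile:
    """All normalised values of one feature, plus its response call."""

    feature_id: str
    values: Dict[Tuple[str, int], float]
    response: Response | None = None
    ratio_summary: Dict[int, float] = field(default_factory=dict)


def read_northern_table(path: Union[str, Path]) -> List[NorthernMeasurement]:
    """Read a northern TSV (feature, strain, time_h, band, control)."""
    df = pd.read_csv(path, sep="\t", comment="#", encoding="utf-8")
    required = {"feature", "strain", "time_h", "band", "control"}
    missing = required - set(df.columns)
    if missing:
        raise TableParseError(f"{path}: northern table lacks columns {sorted(missing)}")
    return [
        NorthernMeasurement(
            str(row["feature"]),
            str(row["strain"]),
            int(row["time_h"]),
            float(row["band"]),
            float(row["control"]),
        )
        for _, row in df.iterrows()
    ]


def normalize_measurements(measurements: Sequence[NorthernMeasurement]) -> pd.DataFrame:
    """Normalised (band / 5S control) intensity table, one row per lane."""
    return pd.DataFrame(
        [
            {
                "feature": m.feature_id,
                "strain": m.strain,
                "time_h": m.time_point_h,
                "normalized": m.normalized,
            }
            for m in measurements
        ],
        columns=["feature", "strain", "time_h", "normalized"],
    )


def build_profiles(measurements: Sequence[NorthernMeasurement]) -> List[NorthernProfile]:
    """Group lane measurements into per-feature profiles (no response call yet)."""
    values: Dict[str, Dict[Tuple[str, int], float]] = {}
    for m in measurements:
        values.setdefault(m.feature_id, {})[(m.strain, m.time_point_h)] = m.normalized
    return [NorthernProfile(fid, vals) for fid, vals in sorted(values.items())]


def classify_rnc_response(
    profile: NorthernProfile,
    ratio_threshold: float = 2.0,
    detection_floor: float = 0.01,
) -> Response:
    """Call how a feature's level responds to RNase III deletion.

    Per shared time point t the ratio r_t = (rnc_t + floor) / (wt_t + floor)
    is formed; the geometric mean G of the r_t decides the call. The floor is
    both a pseudocount and the detection limit: a profile entirely below it
    in both strains is ``not_detected``. The call is filled into
    ``profile.response`` and the per-time-point ratios into
    ``profile.ratio_summary`` so single-time-point readings stay inspectable.
    """
    if ratio_threshold < 1:
        raise ValueError("ratio_threshold must be >= 1")
    wt = {t: v for (strain, t), v in profile.values.items() if strain == "wt"}
    rnc = {t: v for (strain, t), v in profile.values.items() if strain == "rnc"}
    shared = sorted(set(wt) & set(rnc))
    if not shared:
        raise InsufficientDataError(
            f"{profile.feature_id}: no time point measured in both strains"
        )
    ratios = {t: (rnc[t] + detection_floor) / (wt[t] + detection_floor) for t in shared}
    profile.ratio_summary = ratios
    all_values = [wt[t] for t in wt] + [rnc[t] for t in rnc]
    if all(v < detection_floor for v in all_values):
        profile.response = Response.NOT_DETECTED
        return profile.response
    log_mean = sum(math.log(r) for r in ratios.values()) / len(ratios)
    geometric_mean = math.exp(log_mean)
    if geometric_mean >= ratio_threshold:
        profile.response = Response.INCREASED_IN_RNC
    elif geometric_mean <= 1.0 / ratio_threshold:
        profile.response = Response.DECREASED_IN_RNC
    else:
        profile.response = Response.UNCHANGED
    return profile.response


def profiles_to_table(profiles: Iterable[NorthernProfile]) -> pd.DataFrame:
    """Flat per-feature export: normalised values, per-time ratios, response."""
    rows = []
    for p in profiles:
        row: Dict[str, object] = {"feature": p.feature_id}
        for (strain, t), v in sorted(p.values.items()):
            row[f"{strain}_{t}h"] = v
        for t, r in sorted(p.ratio_summary.items()):
            row[f"ratio_{t}h"] = r
        row["response"] = p.response.value if p.response is not None else ""
        rows.append(row)
    return pd.DataFrame(rows)


def plot_profile(profile: NorthernProfile, ax=None):
    """Bar chart of one feature's normalised time course (needs matplotlib)."""
    import matplotlib.pyplot as plt  # deferred: plotting is optional

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    times = sorted({t for _, t in profile.values})
    width = 0.35
    for i, strain in enumerate(STRAINS):
        heights = [profile.values.get((strain, t), 0.0) for t in times]
        ax.bar([x + (i - 0.5) * width for x in range(len(times))], heights, width, label=strain)
    ax.set_xticks(range(len(times)), [f"{t} h" for t in times])
    ax.set_ylabel("band / 5S")
    ax.set_title(profile.feature_id)
    ax.legend()
    return ax
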