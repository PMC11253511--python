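"""Blot densitometry: Southern MAT-switching repair fractions and western
relative protein levels.

Quantification follows the two-step normalization used for gene-conversion
repair kinetics: every band is first divided by its lane's ACT1 loading
signal, then each MATalpha (repair product) band is divided by the
ACT1-normalized HO-cut band of the reference lane (1 h of endonuclease
action), so the series reads "fraction of cut DNA repaired by homologous
recombination".  Western levels are housekeeping-normalized and expressed
relative to mock; checkpoint activation is summarized as the ratio of hyper-
to hypo-phosphorylated Rad53.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "normalize_lane",
    "lanes_to_wide",
    "switch_fraction_series",
    "western_relative",
    "rad53_ratio",
]

DEFAULT_REFERENCE_TIME = 60.0


def normalize_lane(bands: Mapping[str, float], ref_band: str) -> dict[str, float]:
    """Divide every band in a lane by the lane's reference band intensity."""
    if ref_band not in bands:
        raise ValueError(f"reference band {ref_band!r} missing from lane")
    ref = bands[ref_band]
    if ref <= 0:
        raise ValueError(f"reference band {ref_band!r} must be positive")
    if any(v < 0 for v in bands.values()):
        raise ValueError("band intensities must be non-negative")
    return {name: v / ref for name, v in bands.items()}


def lanes_to_wide(lanes: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long lane table (lane_id, time_min, band, intensity) to wide."""
    required = {"lane_id", "time_min", "band", "intensity"}
    if not required.issubset(lanes.columns):
        raise ValueError(f"lane table needs columns {sorted(required)}")
    wide = lanes.pivot_table(
        index=["lane_id", "time_min"], columns="band", values="intensity"
    ).reset_index()
    wide.columns.name = None
    return wide


def switch_fraction_series(
    lanes: pd.DataFrame,
    reference_time: float = DEFAULT_REFERENCE_TIME,
    product_band: str = "MATalpha",
    cut_band: str = "HOcut",
    loading_band: str = "ACT1",
) -> pd.DataFrame:
    """MATalpha product fraction over time, per the two-step normalization.

    ``lanes`` is a long table with one row per band per lane.  Returns a
    frame ``time_min, switch_fraction`` where ``switch_fraction(t)`` is the
    loading-normalized product band at ``t`` divided by the
    loading-normalized HO-cut band of the ``reference_time`` lane.
    """
    wide = lanes_to_wide(lanes)
    for band in (product_band, cut_band, loading_band):
        if band not in wide.columns:
            raise ValueError(f"band {band!r} missing from lane table")
    ref_rows = wide[wide["time_min"] == reference_time]
    if ref_rows.empty:
        raise ValueError(
            f"no lane at the reference time ({reference_time:g} min): "
            "HO-cut reference undefined"
        )
    ref = ref_rows.iloc[0]
    ref_cut = ref[cut_band] / ref[loading_band]
    if ref_cut <= 0:
        raise ValueError("reference HO-cut band is zero: cannot normalize")

    out_rows = []
    for _, lane in wide.iterrows():
        norm = normalize_lane(
            {b: lane[b] for b in wide.columns if b not in ("lane_id", "time_min")},
            loading_band,
        )
        out_rows.append(
            {
                "time_min": lane["time_min"],
                "switch_fraction": norm[product_band] / ref_cut,
            }
        )
    return pd.DataFrame(out_rows).sort_values("time_min", ignore_index=True)


def western_relative(
    target: float,
    housekeeping: float,
    target_mock: float,
    housekeeping_mock: float,
) -> float:
    """Housekeeping-normalized target level as a fold over mock."""
    for name, v in (
        ("target", target),
        ("housekeeping", housekeeping),
        ("target_mock", target_mock),
        ("housekeeping_mock", housekeeping_mock),
    ):
        if v < 0:
            raise ValueError(f"{name} intensity must be non-negative")
    if housekeeping <= 0 or housekeeping_mock <= 0 or target_mock <= 0:
        raise ValueError("denominator intensities must be positive")
    return (target / housekeeping) / (target_mock / housekeeping_mock)


def rad53_ratio(hyper: float | Sequence[float], hypo: float) -> float:
    """Hyper- to hypo-phosphorylated Rad53 band ratio (checkpoint readout).

    Multiple slow-migrating hyperphosphorylated bands may be passed as a
    sequence; they are summed before the ratio.  A zero hypo band means the
    hypo form is undetectable (saturated hyperphosphorylation) and the ratio
    is undefined.
    """
    hyper_total = float(np.sum(np.asarray(hyper, dtype=float)))
    if hyper_total < 0:
        raise ValueError("hyper intensity must be non-negative")
    if hypo <= 0:
        raise ValueError(
            "hypo band must be positive: ratio undefined when Rad53 is fully "
            "shifted (saturated hyperphosphorylation) or absent"
        )
    return hyper_total / hypo
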