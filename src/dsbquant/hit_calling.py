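"""Condition-intersection hit calling across the four volcano comparisons.

The headline selection asks which proteins respond to DNA double-strand
breaks specifically in late mitosis: enriched after both damage types (HO
endonuclease and phleomycin) in late-M, and not enriched after either damage
type in the G2/M comparison stage.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["HitReport", "enriched_set", "stage_specific_hits"]


def enriched_set(result: pd.DataFrame) -> set[str]:
    """Protein ids called enriched (significant with positive log2 fold change)."""
    return set(result.index[result["direction"] == "enriched"])


@dataclass
class HitReport:
    """Per-stage enriched sets, their intersections, and the stage-specific hits.

    ``stage_specific`` holds proteins enriched by both damage types in late-M
    and absent from the G2/M enriched sets (the union of the two G2/M sets in
    strict mode, their intersection in lenient mode).
    """

    enriched: dict[str, dict[str, set[str]]]  # stage -> treatment -> ids
    both: dict[str, set[str]]                 # stage -> ids enriched by both damages
    stage_specific: set[str]
    mode: str = "strict"
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "enriched": {
                stage: {trt: sorted(ids) for trt, ids in by_trt.items()}
                for stage, by_trt in self.enriched.items()
            },
            "both": {stage: sorted(ids) for stage, ids in self.both.items()},
            "stage_specific": sorted(self.stage_specific),
            "mode": self.mode,
            "provenance": self.provenance,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def stage_specific_hits(
    lateM_ho: pd.DataFrame,
    lateM_phleo: pd.DataFrame,
    g2m_ho: pd.DataFrame,
    g2m_phleo: pd.DataFrame,
    mode: str = "strict",
    provenance: dict | None = None,
) -> HitReport:
    """Intersect the four damage-vs-mock comparisons into late-M-specific hits.

    ``stage_specific = (enriched(lateM_HO) & enriched(lateM_phleo))
    - excluded(G2/M)`` where the excluded set is the union of the two G2/M
    enriched sets in ``"strict"`` mode (a protein enriched after either
    damage type in G2/M is not stage-specific) or their intersection in
    ``"lenient"`` mode.  The set algebra is taken over the enriched sets as
    given: a protein filtered out of a G2/M comparison (e.g. never quantified
    in that stage) is simply not enriched there, which is exactly what makes
    presence/absence candidates stage-specific.  Differing protein universes
    therefore only trigger a warning.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError("mode must be 'strict' or 'lenient'")
    frames = {
        "lateM_HO": lateM_ho,
        "lateM_phleo": lateM_phleo,
        "G2M_HO": g2m_ho,
        "G2M_phleo": g2m_phleo,
    }
    universes = {name: set(df.index) for name, df in frames.items()}
    if len(set(map(frozenset, universes.values()))) > 1:
        warnings.warn(
            "comparisons cover different protein universes; "
            "absence from a comparison counts as not enriched there",
            stacklevel=2,
        )

    e = {name: enriched_set(df) for name, df in frames.items()}
    both_late = e["lateM_HO"] & e["lateM_phleo"]
    both_g2m = e["G2M_HO"] & e["G2M_phleo"]
    excluded = (
        e["G2M_HO"] | e["G2M_phleo"] if mode == "strict" else both_g2m
    )
    return HitReport(
        enriched={
            "lateM": {"HO": e["lateM_HO"], "phleo": e["lateM_phleo"]},
            "G2M": {"HO": e["G2M_HO"], "phleo": e["G2M_phleo"]},
        },
        both={"lateM": both_late, "G2M": both_g2m},
        stage_specific=both_late - excluded,
        mode=mode,
        provenance=provenance or {},
    )
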