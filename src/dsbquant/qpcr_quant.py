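"""qPCR estimators for the HO cut fraction, resection fraction and
reference-gene-controlled expression.

The resection assay reads single-stranded DNA by restriction protection:
genomic DNA is split into a mock and a restriction-digested aliquot, and a
locus survives digestion only where 5'->3' resection has already converted
it to ssDNA.  With per-cycle primer efficiencies E and quantification cycles
Cq, the estimators are

    f          = 1 - E_HOcs^dCq_HOcs(t0-t) / E_ref^dCq_ref(t0-t)
    f_resected = 2 / ((E_RS^dCq_RS(digest-mock) / E_ref^dCq_ref(digest-mock)
                       + 1) * f)

where ``dCq(a-b) = Cq(a) - Cq(b)`` (sign conventions follow the printed
superscripts).  ``f`` is the fraction of molecules cut by the HO
endonuclease — the cut-site amplicon loses template as cutting proceeds —
and ``f_resected`` is the fraction of cut molecules whose resection has
passed the restriction site.  Under the strand-accounting model (intact
duplex = 2 template units, resected locus = 1 protected strand) the
estimators invert the forward model exactly.

Expression changes use the efficiency-corrected two-gene ratio
``E_target^dCq_target / E_ref^dCq_ref`` with ``dCq = Cq(mock) -
Cq(treated)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "cut_fraction",
    "resected_fraction",
    "relative_expression",
    "estimate_resection",
]


def _check_efficiency(E: float, name: str) -> None:
    if not 1 < E <= 2:
        raise ValueError(f"{name} must lie in (1, 2], got {E}")


def cut_fraction(
    E_hocs: float, E_ref: float, dCq_hocs: float, dCq_ref: float
) -> float:
    """Fraction of molecules cut at the HO site.

    ``dCq_hocs`` and ``dCq_ref`` are ``Cq(t0) - Cq(t)`` for the cut-site and
    reference amplicons.  The estimate is reported even when outside [0, 1]
    (measurement noise can push it out); callers flag, never clamp.
    """
    _check_efficiency(E_hocs, "E_hocs")
    _check_efficiency(E_ref, "E_ref")
    if not (math.isfinite(dCq_hocs) and math.isfinite(dCq_ref)):
        raise ValueError("dCq values must be finite")
    return 1.0 - (E_hocs**dCq_hocs) / (E_ref**dCq_ref)


def resected_fraction(
    E_rs: float,
    E_ref: float,
    dCq_rs: float,
    dCq_ref: float,
    f: float,
) -> float:
    """Fraction of cut molecules resected past a restriction site.

    ``dCq_rs`` and ``dCq_ref`` are ``Cq(digest) - Cq(mock)``.  A
    non-amplifying digested well (max-Cq sentinel upstream) corresponds to
    ``dCq_rs = +inf``: no protected strand, so the resected fraction is 0.
    Undefined when ``f = 0`` (no cut molecules to classify).
    """
    _check_efficiency(E_rs, "E_rs")
    _check_efficiency(E_ref, "E_ref")
    if f <= 0:
        raise ValueError("f must be > 0: f_resected is undefined without cutting")
    if not math.isfinite(dCq_ref):
        raise ValueError("dCq_ref must be finite")
    if math.isinf(dCq_rs) and dCq_rs > 0:
        return 0.0
    if not math.isfinite(dCq_rs):
        raise ValueError("dCq_rs must be finite or +inf (sentinel)")
    ratio = (E_rs**dCq_rs) / (E_ref**dCq_ref)
    return 2.0 / ((ratio + 1.0) * f)


def relative_expression(
    E_target: float,
    E_ref: float,
    dCq_target: float,
    dCq_ref: float,
) -> float:
    """Efficiency-corrected expression fold change over mock.

    ``dCq = Cq(mock) - Cq(treated)`` per gene; the reference gene (e.g. a
    housekeeping transcript) cancels loading differences.
    """
    _check_efficiency(E_target, "E_target")
    _check_efficiency(E_ref, "E_ref")
    if not (math.isfinite(dCq_target) and math.isfinite(dCq_ref)):
        raise ValueError("dCq values must be finite")
    return (E_target**dCq_target) / (E_ref**dCq_ref)


@dataclass
class ResectionEstimate:
    """Per-time cut fraction and per-(amplicon, time) resected fractions.

    ``f`` and ``f_resected`` are pandas objects; ``out_of_range`` mirrors
    them with True wherever an estimate fell outside [0, 1] (flagged, never
    clamped).
    """

    f: pd.Series
    f_resected: pd.DataFrame

    @property
    def out_of_range(self) -> dict:
        return {
            "f": ((self.f < 0) | (self.f > 1)),
            "f_resected": (
                (self.f_resected["f_resected"] < 0)
                | (self.f_resected["f_resected"] > 1)
            ),
        }


def _mean_cq(group: pd.DataFrame, max_cq: float | None) -> float:
    """Average replicate Cq; all-sentinel wells stay sentinel, mixed wells
    average the amplifying replicates."""
    cq = group["cq"].to_numpy(dtype=float)
    if max_cq is not None:
        amplifying = cq < max_cq
        if not amplifying.any():
            return math.inf  # no amplification at all
        cq = cq[amplifying]
    return float(cq.mean())


def estimate_resection(
    cq_table: pd.DataFrame,
    ref_amplicon: str = "ADH1",
    hocs_amplicon: str = "HOcs",
    t0: float = 0.0,
    max_cq: float | None = None,
    mode: str = "mean_cq",
) -> ResectionEstimate:
    """Run both estimators over a long Cq table.

    The table needs columns ``amplicon, aliquot, time_min, replicate, cq,
    efficiency``.  Replicates are combined according to ``mode``:
    ``"mean_cq"`` (default) averages Cq within (amplicon, aliquot, time)
    before estimating; ``"mean_estimate"`` estimates per replicate and
    averages the estimates.  ``max_cq`` marks the no-amplification sentinel;
    such wells are treated as zero signal.  The reference amplicon's
    digest-mock dCq defaults to 0 when the digested reference aliquot was
    not measured.
    """
    if mode not in ("mean_cq", "mean_estimate"):
        raise ValueError("mode must be 'mean_cq' or 'mean_estimate'")
    required = {"amplicon", "aliquot", "time_min", "replicate", "cq", "efficiency"}
    if not required.issubset(cq_table.columns):
        raise ValueError(f"Cq table needs columns {sorted(required)}")

    eff = cq_table.groupby("amplicon")["efficiency"].first().to_dict()
    times = sorted(cq_table["time_min"].unique())
    if t0 not in times:
        raise ValueError(f"anchor time t0={t0} not present in the table")

    if mode == "mean_estimate":
        reps = sorted(cq_table["replicate"].unique())
        per_rep = [
            estimate_resection(
                cq_table[cq_table["replicate"] == r],
                ref_amplicon=ref_amplicon,
                hocs_amplicon=hocs_amplicon,
                t0=t0,
                max_cq=max_cq,
                mode="mean_cq",
            )
            for r in reps
        ]
        f = pd.concat([e.f for e in per_rep], axis=1).mean(axis=1)
        f.name = "f"
        fr = pd.concat([e.f_resected["f_resected"] for e in per_rep], axis=1).mean(
            axis=1
        )
        f_res = per_rep[0].f_resected.copy()
        f_res["f_resected"] = fr.to_numpy()
        return ResectionEstimate(f=f, f_resected=f_res)

    def cq_at(amplicon, aliquot, time):
        sel = cq_table[
            (cq_table["amplicon"] == amplicon)
            & (cq_table["aliquot"] == aliquot)
            & (cq_table["time_min"] == time)
        ]
        if sel.empty:
            return None
        return _mean_cq(sel, max_cq)

    # cut fraction per time, anchored at t0
    ref_t0 = cq_at(ref_amplicon, "mock", t0)
    hocs_t0 = cq_at(hocs_amplicon, "mock", t0)
    if ref_t0 is None or hocs_t0 is None:
        raise ValueError("reference or HO-cut-site amplicon missing at t0")
    f_by_time = {}
    for t in times:
        ref_t = cq_at(ref_amplicon, "mock", t)
        hocs_t = cq_at(hocs_amplicon, "mock", t)
        if ref_t is None or hocs_t is None:
            continue
        if math.isinf(hocs_t):
            f_by_time[t] = 1.0  # cut-site amplicon fully lost
            continue
        f_by_time[t] = cut_fraction(
            eff[hocs_amplicon], eff[ref_amplicon], hocs_t0 - hocs_t, ref_t0 - ref_t
        )
    f = pd.Series(f_by_time, name="f").sort_index()
    f.index.name = "time_min"

    # resected fraction per (restriction-site amplicon, time)
    rs_amplicons = sorted(
        set(cq_table["amplicon"]) - {ref_amplicon, hocs_amplicon}
    )
    rows = []
    for amp in rs_amplicons:
        for t in times:
            mock = cq_at(amp, "mock", t)
            dig = cq_at(amp, "digest", t)
            if mock is None or dig is None or t not in f.index:
                continue
            ref_mock = cq_at(ref_amplicon, "mock", t)
            ref_dig = cq_at(ref_amplicon, "digest", t)
            dCq_ref = 0.0 if (ref_dig is None or ref_mock is None) else ref_dig - ref_mock
            dCq_rs = math.inf if math.isinf(dig) else dig - mock
            f_t = f.loc[t]
            if f_t <= 0:
                continue  # nothing cut: resection undefined at this time
            rows.append(
                {
                    "amplicon": amp,
                    "time_min": t,
                    "f_resected": resected_fraction(
                        eff[amp], eff[ref_amplicon], dCq_rs, dCq_ref, f_t
                    ),
                }
            )
    f_res = pd.DataFrame(rows, columns=["amplicon", "time_min", "f_resected"])
    return ResectionEstimate(f=f, f_resected=f_res)
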