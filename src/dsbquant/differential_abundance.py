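"""Label-free differential abundance with left-censored imputation and a
curved volcano significance threshold.

The procedure mirrors the standard LFQ workflow for detecting proteins whose
abundance responds to a treatment: intensities are log2 transformed; missing
values — which in LFQ data arise preferentially at low abundance (missing not
at random) — are imputed per replicate column from a compressed beta
distribution confined to the extreme low tail of that column's measured
values (between its 0.001 and 0.015 empirical percentiles); each protein is
tested with a two-sample Welch t-test; and a protein is called significant
when it clears a curved threshold in the volcano plane,

    |log2FC| > s   and   -log10(p) >= -log10(p0) + c / (|log2FC| - s),

a hyperbola with vertical asymptote at the minimum fold change ``s``,
horizontal asymptote at the significance floor ``-log10(p0)``, and curvature
``c``.  Defaults are p0 = 0.05, s = 1, c = 0.5.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .proteomics_io import Comparison, ProteinGroupsTable, SampleDesign
from .stats_core import welch_t_arrays

__all__ = [
    "ImputationParams",
    "CurveParams",
    "log2_transform",
    "impute_replicate",
    "significance_curve",
    "compare",
]


@dataclass(frozen=True)
class ImputationParams:
    """Low-tail beta imputation settings.

    Missing entries of a replicate column are drawn as
    ``lo + (hi - lo) * Beta(beta_a, beta_b)`` where ``lo``/``hi`` are the
    ``q_low``/``q_high`` empirical percentiles of the column's measured log2
    intensities.  Beta(2, 2) is symmetric and compressed relative to a
    uniform draw over the same band.
    """

    q_low: float = 0.001
    q_high: float = 0.015
    beta_a: float = 2.0
    beta_b: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.q_low < self.q_high <= 1:
            raise ValueError("need 0 <= q_low < q_high <= 1")
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ValueError("beta shapes must be positive")


@dataclass(frozen=True)
class CurveParams:
    """Curved volcano threshold: significance floor p0, fold-change offset s
    (log2 units), curvature c."""

    p0: float = 0.05
    s: float = 1.0
    c: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.p0 < 1:
            raise ValueError("p0 must lie in (0, 1)")
        if self.s < 0 or self.c < 0:
            raise ValueError("s and c must be non-negative")


def log2_transform(table: ProteinGroupsTable) -> ProteinGroupsTable:
    """Replace measured intensities by their log2; missing stays missing."""
    vals = table.lfq.to_numpy(dtype=float)
    if np.any(vals[np.isfinite(vals)] <= 0):
        raise ValueError("cannot log2-transform non-positive intensities")
    out = table.copy()
    out.lfq = np.log2(table.lfq)
    return out


def _column_band(measured: np.ndarray, params: ImputationParams) -> tuple[float, float]:
    # linear-interpolation empirical quantiles, fixed convention
    lo, hi = np.quantile(measured, [params.q_low, params.q_high])
    return float(lo), float(hi)


def impute_replicate(
    values, params: ImputationParams, rng: np.random.Generator
) -> np.ndarray:
    """Impute one sample column (log2 scale) from its own low tail.

    ``values`` holds the column across all proteins with NaN for missing.
    Requires at least two measured values to anchor the percentile band.
    Measured entries are returned untouched.
    """
    values = np.asarray(values, dtype=float)
    missing = ~np.isfinite(values)
    if not missing.any():
        return values.copy()
    measured = values[~missing]
    if measured.size < 2:
        raise ValueError("imputation needs >= 2 measured values in the column")
    lo, hi = _column_band(measured, params)
    out = values.copy()
    draws = rng.beta(params.beta_a, params.beta_b, size=int(missing.sum()))
    out[missing] = lo + (hi - lo) * draws
    return out


def _column_rng(seed: int, sample_id: str) -> np.random.Generator:
    # deterministic per-column substream from (seed, sample id)
    return np.random.default_rng([seed, zlib.crc32(sample_id.encode())])


def significance_curve(log2fc, p_value, cp: CurveParams | None = None):
    """Boolean volcano call; accepts scalars or arrays."""
    cp = cp or CurveParams()
    log2fc = np.asarray(log2fc, dtype=float)
    p_value = np.asarray(p_value, dtype=float)
    afc = np.abs(log2fc)
    with np.errstate(divide="ignore", invalid="ignore"):
        neg_log_p = -np.log10(p_value)
        cutoff = -np.log10(cp.p0) + cp.c / (afc - cp.s)
    passed = (afc > cp.s) & (neg_log_p >= cutoff)
    if passed.ndim == 0:
        return bool(passed)
    return passed


def compare(
    table: ProteinGroupsTable,
    design: SampleDesign,
    comparison: Comparison,
    imputation: ImputationParams | None = None,
    curve: CurveParams | None = None,
) -> pd.DataFrame:
    """Run one damage-vs-mock comparison on a filtered log2-scale table.

    Per protein: impute each replicate column independently, compute group
    means and the log2 fold change (test minus reference), Welch-test the
    imputed vectors, and apply the curved threshold.  Returns one row per
    protein with columns ``gene_name, log2fc, t_stat, df, p_value,
    neg_log10_p, significant, direction, n_imputed_test, n_imputed_ref,
    q_value``.  The Benjamini-Hochberg ``q_value`` is informational only;
    calls come from the curve.
    """
    ip = imputation or ImputationParams()
    cp = curve or CurveParams()
    test = comparison.test_samples(design)
    ref = comparison.ref_samples(design)
    absent = [s for s in test + ref if s not in table.lfq.columns]
    if absent:
        raise ValueError(f"design samples absent from table: {absent}")

    imputed: dict[str, np.ndarray] = {}
    for sample in test + ref:
        col = table.lfq[sample].to_numpy(dtype=float)
        imputed[sample] = impute_replicate(col, ip, _column_rng(ip.seed, sample))

    xs = np.column_stack([imputed[s] for s in test])
    ys = np.column_stack([imputed[s] for s in ref])
    mx, my = xs.mean(axis=1), ys.mean(axis=1)
    vx, vy = xs.var(axis=1, ddof=1), ys.var(axis=1, ddof=1)
    t, df, p = welch_t_arrays(mx, vx, xs.shape[1], my, vy, ys.shape[1])
    log2fc = mx - my

    sig = significance_curve(log2fc, p, cp)
    direction = np.where(sig & (log2fc > 0), "enriched",
                         np.where(sig & (log2fc < 0), "depleted", "none"))
    # BH over the finite p-values (degenerate zero-variance rows included as-is)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]

    with np.errstate(divide="ignore"):
        neg_log10_p = -np.log10(p)

    return pd.DataFrame(
        {
            "gene_name": table.gene_names.to_numpy(),
            "log2fc": log2fc,
            "t_stat": t,
            "df": df,
            "p_value": p,
            "neg_log10_p": neg_log10_p,
            "significant": sig,
            "direction": direction,
            "n_imputed_test": table.lfq[test].isna().sum(axis=1).to_numpy(),
            "n_imputed_ref": table.lfq[ref].isna().sum(axis=1).to_numpy(),
            "q_value": q,
        },
        index=table.ids.copy(),
    )
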