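"""Forward simulators for every input the pipeline consumes, with ground truth.

Four generators emulate the assays of a DSB-response study in budding yeast
so each analysis stage can be validated against a known truth:

* ``gen_lfq_table`` — label-free proteomics intensities in a 2-stage
  (G2/M vs late mitosis) x 3-treatment (mock, HO endonuclease, phleomycin)
  x n-replicate design, with planted enrichments in chosen stage x treatment
  cells, log-normal abundance, and left-censored missing-not-at-random
  dropout (the probability a value goes missing follows a logistic curve
  decreasing in log2 intensity).
* ``gen_resection_cq`` — qPCR quantification cycles from a restriction-
  protection template model of DSB end resection: an undamaged or unresected
  locus is double-stranded (2 template strands, both cut by the restriction
  enzyme), a resected locus retains 1 protected single strand; mock and
  enzyme-digested aliquots are read per amplicon.
* ``gen_repair_blot`` — Southern-blot lane intensities from a planted
  mating-type switching (gene-conversion repair) trajectory, with per-lane
  multiplicative loading noise that the ACT1 normalization must cancel.
* ``gen_foci_counts`` — multinomial per-cell focus-category counts.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .proteomics_io import (
    G2M,
    HO,
    LATE_M,
    MOCK,
    PHLEO,
    ProteinGroupsTable,
    SampleDesign,
    build_design,
)

__all__ = [
    "SpikeDesign",
    "ResectionTruth",
    "RepairTruth",
    "gen_lfq_table",
    "gen_resection_cq",
    "gen_repair_blot",
    "gen_foci_counts",
    "planted_hit_scenario",
    "protein_id",
    "write_truth",
]

Cell = tuple[str, str]  # (stage, treatment)


@dataclass
class SpikeDesign:
    """Parameters of the spike-in LFQ simulation.

    Protein log2 abundances are ``base_mean_log2 + N(0, between_protein_sd)``
    per protein, plus ``N(0, between_replicate_sd)`` per measurement, plus
    ``spike_log2fc`` for spiked proteins in the designated stage x treatment
    cells.  Each measurement is independently censored with probability
    ``logistic((dropout_midpoint - log2 intensity) * dropout_slope)``, the
    left-censoring that motivates low-tail imputation downstream.

    ``spike_map`` (protein id -> cells) overrides the uniform
    ``spike_ids`` x ``spike_cells`` assignment when planted effects must
    differ between proteins.
    """

    n_proteins: int = 3000
    groups: SampleDesign = field(default_factory=build_design)
    spike_ids: tuple[str, ...] = ()
    spike_cells: tuple[Cell, ...] = ((LATE_M, HO), (LATE_M, PHLEO))
    spike_map: Mapping[str, Sequence[Cell]] | None = None
    spike_log2fc: float = 2.0
    base_mean_log2: float = 25.0
    between_protein_sd: float = 2.0
    between_replicate_sd: float = 0.3
    dropout_midpoint: float = 21.5
    dropout_slope: float = 3.0
    decoy_rows: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not np.isfinite(self.spike_log2fc):
            raise ValueError("spike_log2fc must be finite")
        if self.between_replicate_sd <= 0 or self.between_protein_sd < 0:
            raise ValueError("replicate sd must be > 0, protein sd >= 0")
        if self.dropout_slope <= 0:
            raise ValueError("dropout_slope must be > 0")
        if self.decoy_rows < 0:
            raise ValueError("decoy_rows must be >= 0")

    def resolved_spike_map(self) -> dict[str, tuple[Cell, ...]]:
        if self.spike_map is not None:
            return {pid: tuple(cells) for pid, cells in self.spike_map.items()}
        return {pid: self.spike_cells for pid in self.spike_ids}


def protein_id(i: int) -> str:
    return f"P{i:05d}"


def planted_hit_scenario(
    n_proteins: int = 300,
    n_stage_specific: int = 5,
    n_shared: int = 3,
    n_g2m_only: int = 2,
    spike_log2fc: float = 6.0,
    seed: int = 0,
    **kwargs,
) -> tuple[SpikeDesign, dict[str, set[str]]]:
    """Spike design for the four-comparison intersection benchmark.

    Plants three classes of enrichment: late-M-specific (both damage types in
    late mitosis only), shared (all four stage x damage cells), and G2/M-only.
    Returns the design and the truth sets keyed ``stage_specific``,
    ``shared``, ``g2m_only``.  Planted effects are strong (6 log2 units by
    default, the presence/absence regime of an induced protein) so the
    intersection logic, not test power, is what the scenario probes: even a
    planted protein whose baseline draws into the left-censored tail stays
    well above the imputation band.
    """
    ids = [protein_id(i) for i in range(n_stage_specific + n_shared + n_g2m_only)]
    late = ((LATE_M, HO), (LATE_M, PHLEO))
    g2m = ((G2M, HO), (G2M, PHLEO))
    spike_map: dict[str, tuple[Cell, ...]] = {}
    truth = {
        "stage_specific": set(ids[:n_stage_specific]),
        "shared": set(ids[n_stage_specific:n_stage_specific + n_shared]),
        "g2m_only": set(ids[n_stage_specific + n_shared:]),
    }
    for pid in truth["stage_specific"]:
        spike_map[pid] = late
    for pid in truth["shared"]:
        spike_map[pid] = late + g2m
    for pid in truth["g2m_only"]:
        spike_map[pid] = g2m
    design = SpikeDesign(
        n_proteins=n_proteins,
        spike_map=spike_map,
        spike_log2fc=spike_log2fc,
        seed=seed,
        **kwargs,
    )
    return design, truth


def gen_lfq_table(design: SpikeDesign) -> tuple[ProteinGroupsTable, dict]:
    """Simulate a protein-groups table; returns ``(table, truth)``.

    The truth record carries the spiked protein ids, their cells, the planted
    log2 fold change and the generator parameters, and is JSON-serialisable.
    """
    rng = np.random.default_rng(design.seed)
    samples = design.groups.samples
    sample_cells = [
        (design.groups.frame.loc[s, "stage"], design.groups.frame.loc[s, "treatment"])
        for s in samples
    ]
    n, m = design.n_proteins, len(samples)

    ids = [protein_id(i) for i in range(n)]
    spike_map = design.resolved_spike_map()
    unknown = set(spike_map) - set(ids)
    if unknown:
        raise ValueError(f"spike ids not among generated proteins: {sorted(unknown)}")

    protein_means = design.base_mean_log2 + rng.normal(
        0.0, design.between_protein_sd, size=n
    )
    shift = np.zeros((n, m))
    for pid, cells in spike_map.items():
        i = ids.index(pid)
        for j, cell in enumerate(sample_cells):
            if cell in set(map(tuple, cells)):
                shift[i, j] = design.spike_log2fc

    log2_vals = (
        protein_means[:, None]
        + shift
        + rng.normal(0.0, design.between_replicate_sd, size=(n, m))
    )
    p_missing = expit((design.dropout_midpoint - log2_vals) * design.dropout_slope)
    missing = rng.random(size=(n, m)) < p_missing

    linear = np.exp2(log2_vals)
    linear[missing] = np.nan

    # decoy rows: contaminants / reverse hits / only-by-site, cycling
    decoy_ids, decoy_vals, flag_rows = [], [], []
    flag_names = ["contaminant", "reverse", "only_by_site"]
    for k in range(design.decoy_rows):
        which = flag_names[k % 3]
        prefix = {"contaminant": "CON__", "reverse": "REV__", "only_by_site": "SITE__"}
        decoy_ids.append(f"{prefix[which]}D{k:03d}")
        decoy_vals.append(
            np.exp2(design.base_mean_log2 + rng.normal(0.0, 1.0, size=m))
        )
        flag_rows.append({name: name == which for name in flag_names})

    all_ids = pd.Index(ids + decoy_ids, name="protein_group_id")
    lfq = pd.DataFrame(
        np.vstack([linear] + ([np.array(decoy_vals)] if decoy_vals else [])),
        index=all_ids,
        columns=samples,
    )
    flags = pd.DataFrame(
        [{name: False for name in flag_names}] * n + flag_rows, index=all_ids
    )
    genes = pd.Series(
        [f"GENE{i}" for i in range(n)] + ["" for _ in decoy_ids],
        index=all_ids,
        name="gene_name",
    )
    table = ProteinGroupsTable(lfq=lfq, gene_names=genes, flags=flags)

    truth = {
        "spiked": {pid: [list(c) for c in cells] for pid, cells in spike_map.items()},
        "spike_log2fc": design.spike_log2fc,
        "n_proteins": n,
        "decoy_rows": design.decoy_rows,
        "seed": design.seed,
        "base_mean_log2": design.base_mean_log2,
        "between_protein_sd": design.between_protein_sd,
        "between_replicate_sd": design.between_replicate_sd,
        "dropout_midpoint": design.dropout_midpoint,
        "dropout_slope": design.dropout_slope,
    }
    return table, truth


# ---------------------------------------------------------------------------
# qPCR resection assay
# ---------------------------------------------------------------------------

REF_AMPLICON = "ADH1"
HOCS_AMPLICON = "HOcs"


@dataclass
class ResectionTruth:
    """Ground truth for the restriction-protection resection simulation.

    ``f_by_time`` is the fraction of molecules cut by the HO endonuclease at
    each sampling time (time 0 must be present; it anchors the cut-fraction
    estimator).  ``r_by_amplicon_time`` maps ``(amplicon, time)`` to the
    fraction of cut molecules resected past that amplicon's restriction site.
    ``efficiency`` maps every amplicon (including the reference and the
    HO-cut-site amplicon) to its per-cycle primer efficiency E in (1, 2].

    Template units per locus: intact duplex contributes 2 strand equivalents,
    a resected (single-stranded, digestion-protected) locus contributes 1.
    ``Cq = reference_cq - log_E(signal) + N(0, cq_noise_sd)``; a zero signal
    is reported as the ``max_cq`` sentinel ("no amplification").
    """

    f_by_time: Mapping[float, float] = field(
        default_factory=lambda: {0: 0.0, 120: 0.8, 240: 0.9}
    )
    r_by_amplicon_time: Mapping[tuple[str, float], float] = field(default_factory=dict)
    efficiency: Mapping[str, float] = field(
        default_factory=lambda: {REF_AMPLICON: 2.0, HOCS_AMPLICON: 2.0}
    )
    reference_cq: float = 20.0
    cq_noise_sd: float = 0.0
    n_replicates: int = 3
    max_cq: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if 0 not in self.f_by_time and 0.0 not in self.f_by_time:
            raise ValueError("f_by_time must include time 0 (pre-induction anchor)")
        for t, f in self.f_by_time.items():
            if not 0 <= f <= 1:
                raise ValueError(f"cut fraction out of [0,1] at t={t}")
        for key, r in self.r_by_amplicon_time.items():
            if not 0 <= r <= 1:
                raise ValueError(f"resected fraction out of [0,1] at {key}")
        for amp, e in self.efficiency.items():
            if not 1 < e <= 2:
                raise ValueError(f"efficiency of {amp} must lie in (1, 2]")
        if self.cq_noise_sd < 0:
            raise ValueError("cq_noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def _cq_from_signal(signal, E, reference_cq, max_cq):
    if signal <= 0:
        return None  # sentinel marker
    return reference_cq - np.log(signal) / np.log(E)


def gen_resection_cq(truth: ResectionTruth) -> pd.DataFrame:
    """Simulate the two-aliquot qPCR readout of the resection assay.

    Per time point each genomic DNA sample is split into a mock aliquot and
    a restriction-digested aliquot.  Signals in template strand units:

    * reference amplicon (no restriction site): 2 in both aliquots;
    * HO-cut-site amplicon (mock aliquot): ``2 * (1 - f)`` — cut molecules
      no longer amplify across the break;
    * restriction-site amplicon, mock: ``2 - f*r`` (resection converts one
      of the two strands to ssDNA); digest: ``f*r`` (only the protected
      single strand survives digestion).

    Returns a long table ``amplicon, aliquot, time_min, replicate, cq,
    efficiency``.  Wells with zero signal carry the ``max_cq`` sentinel.
    """
    rng = np.random.default_rng(truth.seed)
    times = sorted(truth.f_by_time)
    rows = []

    def emit(amplicon, aliquot, time, signal):
        E = truth.efficiency[amplicon]
        base = _cq_from_signal(signal, E, truth.reference_cq, truth.max_cq)
        for rep in range(1, truth.n_replicates + 1):
            if base is None:
                cq = truth.max_cq
            else:
                cq = base + rng.normal(0.0, truth.cq_noise_sd)
                if cq >= truth.max_cq:
                    cq = truth.max_cq
            rows.append(
                {
                    "amplicon": amplicon,
                    "aliquot": aliquot,
                    "time_min": time,
                    "replicate": rep,
                    "cq": cq,
                    "efficiency": E,
                }
            )

    rs_amplicons = sorted({amp for amp, _ in truth.r_by_amplicon_time})
    for t in times:
        f = truth.f_by_time[t]
        emit(REF_AMPLICON, "mock", t, 2.0)
        emit(REF_AMPLICON, "digest", t, 2.0)
        emit(HOCS_AMPLICON, "mock", t, 2.0 * (1.0 - f))
        for amp in rs_amplicons:
            if (amp, t) not in truth.r_by_amplicon_time:
                continue
            r = truth.r_by_amplicon_time[(amp, t)]
            emit(amp, "mock", t, 2.0 - f * r)
            emit(amp, "digest", t, f * r)

    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Southern-blot repair (MAT switching) lanes
# ---------------------------------------------------------------------------


@dataclass
class RepairTruth:
    """Planted gene-conversion repair trajectory for blot simulation.

    ``switch_fraction_by_time`` maps minutes after HO induction to the
    fraction of cut molecules repaired into the MATalpha product.
    ``cut_fraction`` is the fraction of MATa loci cut at the reference time
    (1 in the ideal assay).  Lane loading varies by ``exp(N(0,
    lane_scale_sd))`` and each band additionally carries multiplicative
    noise with coefficient of variation ``band_noise_cv``.
    """

    switch_fraction_by_time: Mapping[float, float] = field(
        default_factory=lambda: {60: 0.0, 90: 0.4, 120: 0.8}
    )
    cut_fraction: float = 1.0
    reference_time: float = 60.0
    lane_scale_sd: float = 0.1
    band_noise_cv: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for t, s in self.switch_fraction_by_time.items():
            if not 0 <= s <= 1:
                raise ValueError(f"switch fraction out of [0,1] at t={t}")
        if not 0 <= self.cut_fraction <= 1:
            raise ValueError("cut_fraction must lie in [0,1]")
        if self.reference_time not in self.switch_fraction_by_time:
            raise ValueError(
                "reference time point missing: HO-cut reference band undefined"
            )
        if self.lane_scale_sd < 0 or self.band_noise_cv < 0:
            raise ValueError("noise parameters must be >= 0")


def gen_repair_blot(truth: RepairTruth) -> pd.DataFrame:
    """Simulate Southern lanes: MATa, MATalpha, HOcut and ACT1 bands per time.

    Band means (before lane scaling): ACT1 = 1, MATalpha = s(t) * cut,
    HOcut = (1 - s(t)) * cut, MATa = 1 - cut.  Returns a long table
    ``lane_id, time_min, band, intensity``.
    """
    rng = np.random.default_rng(truth.seed)
    rows = []
    for t in sorted(truth.switch_fraction_by_time):
        s = truth.switch_fraction_by_time[t]
        cut = truth.cut_fraction
        means = {
            "ACT1": 1.0,
            "MATa": 1.0 - cut,
            "MATalpha": s * cut,
            "HOcut": (1.0 - s) * cut,
        }
        lane_scale = np.exp(rng.normal(0.0, truth.lane_scale_sd))
        for band, mean in means.items():
            noise = 1.0 + rng.normal(0.0, truth.band_noise_cv)
            intensity = max(mean * lane_scale * noise, 0.0)
            rows.append(
                {
                    "lane_id": f"t{t:g}",
                    "time_min": t,
                    "band": band,
                    "intensity": intensity,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Focus-category counts
# ---------------------------------------------------------------------------


def gen_foci_counts(
    proportions: Mapping[str, float],
    n_cells: int,
    n_replicates: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Multinomial counts of cells per focus category, one row per replicate.

    Categories follow the usual scoring of repair-factor foci: e.g.
    ``no_focus`` (diffuse nuclear signal), ``focus`` (one spot), ``foci``
    (more than one).  ``proportions`` must be non-negative and sum to 1;
    each replicate's counts sum exactly to ``n_cells``.
    """
    cats = list(proportions)
    p = np.array([proportions[c] for c in cats], dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("proportions must sum to 1")
    if n_cells < 1 or n_replicates < 1:
        raise ValueError("n_cells and n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_cells, p / p.sum(), size=n_replicates)
    out = pd.DataFrame(counts, columns=cats)
    out.insert(0, "replicate", np.arange(1, n_replicates + 1))
    return out


def write_truth(truth: dict, path) -> None:
    """Write a generator truth record as a JSON sidecar."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True, default=float)
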