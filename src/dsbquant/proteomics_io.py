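"""Protein-groups I/O in the MaxQuant dialect, sample design binding, row filters.

A MaxQuant ``proteinGroups.txt`` is a tab-separated table with one row per
protein group, ``LFQ intensity <sample>`` columns holding label-free
quantification values (``0`` meaning "not quantified"), and ``+``-flag columns
marking contaminants, reverse (decoy) hits and groups identified only by a
modification site.  This module parses that dialect into an in-memory table
with explicit missingness (NaN), binds sample columns to an experimental
design (cell-cycle stage x treatment x replicate), and applies the standard
row filters that precede differential-abundance analysis: decoy removal and a
minimum number of quantification events per comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "G2M",
    "LATE_M",
    "MOCK",
    "HO",
    "PHLEO",
    "STAGES",
    "TREATMENTS",
    "ProteinGroupsTable",
    "SampleDesign",
    "Comparison",
    "read_protein_groups",
    "write_protein_groups",
    "filter_decoys",
    "filter_min_valid",
]

# Canonical stage / treatment labels.  Parsers accept the common spellings
# ("G2/M", "late-M", "Phleo", ...) and map them onto these.
G2M = "G2M"
LATE_M = "lateM"
STAGES = (G2M, LATE_M)

MOCK = "mock"
HO = "HO"
PHLEO = "phleo"
TREATMENTS = (MOCK, HO, PHLEO)

_STAGE_ALIASES = {
    "g2m": G2M,
    "g2/m": G2M,
    "g2-m": G2M,
    "latem": LATE_M,
    "late-m": LATE_M,
    "late_m": LATE_M,
    "late m": LATE_M,
    "telophase": LATE_M,
}
_TREATMENT_ALIASES = {
    "mock": MOCK,
    "ho": HO,
    "phleo": PHLEO,
    "phleomycin": PHLEO,
    "phle": PHLEO,
}

logger = logging.getLogger(__name__)

LFQ_PREFIX = "LFQ intensity "
ID_COLUMN = "Protein IDs"
MAJORITY_ID_COLUMN = "Majority protein IDs"
GENE_COLUMN = "Gene names"
FLAG_COLUMNS = {
    "contaminant": "Potential contaminant",
    "reverse": "Reverse",
    "only_by_site": "Only identified by site",
}


def parse_stage(label: str) -> str:
    try:
        return _STAGE_ALIASES[str(label).strip().lower()]
    except KeyError:
        raise ValueError(f"unknown cell-cycle stage label: {label!r}") from None


def parse_treatment(label: str) -> str:
    try:
        return _TREATMENT_ALIASES[str(label).strip().lower()]
    except KeyError:
        raise ValueError(f"unknown treatment label: {label!r}") from None


@dataclass
class ProteinGroupsTable:
    """Protein groups x samples LFQ matrix with decoy/contaminant flags.

    Attributes
    ----------
    lfq : pandas.DataFrame
        Linear-scale intensities, indexed by protein-group id, one column per
        sample.  Missing values are NaN (a zero on disk means "missing").
    gene_names : pandas.Series
        Gene name per protein group (may be empty strings), aligned to
        ``lfq.index``.
    flags : pandas.DataFrame
        Boolean columns ``contaminant``, ``reverse``, ``only_by_site``,
        aligned to ``lfq.index``.
    """

    lfq: pd.DataFrame
    gene_names: pd.Series
    flags: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.lfq.index.is_unique:
            dupes = self.lfq.index[self.lfq.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein group ids: {dupes}")
        if not self.lfq.columns.is_unique:
            raise ValueError("duplicate sample names in LFQ columns")
        self.gene_names = self.gene_names.reindex(self.lfq.index).fillna("")
        missing_flags = [c for c in FLAG_COLUMNS if c not in self.flags.columns]
        if missing_flags:
            raise ValueError(f"flag columns missing: {missing_flags}")
        self.flags = self.flags.reindex(self.lfq.index).fillna(False).astype(bool)

    @property
    def ids(self) -> pd.Index:
        return self.lfq.index

    @property
    def samples(self) -> list[str]:
        return list(self.lfq.columns)

    @property
    def n_proteins(self) -> int:
        return len(self.lfq)

    def select(self, mask) -> "ProteinGroupsTable":
        """Return a new table with the rows where ``mask`` is True (order kept)."""
        mask = np.asarray(mask, dtype=bool)
        return ProteinGroupsTable(
            lfq=self.lfq.loc[mask].copy(),
            gene_names=self.gene_names.loc[mask].copy(),
            flags=self.flags.loc[mask].copy(),
        )

    def copy(self) -> "ProteinGroupsTable":
        return ProteinGroupsTable(
            self.lfq.copy(), self.gene_names.copy(), self.flags.copy()
        )


@dataclass
class SampleDesign:
    """Maps each sample id to (stage, treatment, replicate).

    ``frame`` is indexed by sample id with columns ``stage``, ``treatment``,
    ``replicate``; the (stage, treatment, replicate) triple must be unique.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        required = {"stage", "treatment", "replicate"}
        if not required.issubset(df.columns):
            raise ValueError(f"design needs columns {sorted(required)}")
        df["stage"] = df["stage"].map(parse_stage)
        df["treatment"] = df["treatment"].map(parse_treatment)
        df["replicate"] = df["replicate"].astype(int)
        if (df["replicate"] < 1).any():
            raise ValueError("replicate indices must be positive")
        if not df.index.is_unique:
            raise ValueError("duplicate sample ids in design")
        key = df[["stage", "treatment", "replicate"]]
        if key.duplicated().any():
            raise ValueError("(stage, treatment, replicate) must be unique")
        self.frame = df

    @classmethod
    def read(cls, path) -> "SampleDesign":
        df = pd.read_csv(path, sep=None, engine="python")
        if "sample" not in df.columns:
            raise ValueError("design file needs a 'sample' column")
        return cls(df.set_index("sample"))

    def write(self, path) -> None:
        out = self.frame.reset_index(names="sample")
        out.to_csv(path, sep="\t", index=False)

    @property
    def samples(self) -> list[str]:
        return list(self.frame.index)

    def samples_for(self, stage: str, treatment: str) -> list[str]:
        """Sample ids in one (stage, treatment) cell, ordered by replicate."""
        stage = parse_stage(stage)
        treatment = parse_treatment(treatment)
        cell = self.frame[
            (self.frame["stage"] == stage) & (self.frame["treatment"] == treatment)
        ]
        return list(cell.sort_values("replicate").index)


def build_design(n_replicates: int = 4) -> SampleDesign:
    """The full 2-stage x 3-treatment x n-replicate layout used throughout.

    Sample ids follow ``{stage}_{treatment}_r{k}``.
    """
    rows = []
    for stage in STAGES:
        for treatment in TREATMENTS:
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample": f"{stage}_{treatment}_r{rep}",
                        "stage": stage,
                        "treatment": treatment,
                        "replicate": rep,
                    }
                )
    return SampleDesign(pd.DataFrame(rows).set_index("sample"))


@dataclass(frozen=True)
class Comparison:
    """One pairwise damage-vs-mock comparison within a cell-cycle stage."""

    stage: str
    treatment_test: str
    treatment_ref: str = MOCK

    def __post_init__(self) -> None:
        object.__setattr__(self, "stage", parse_stage(self.stage))
        object.__setattr__(self, "treatment_test", parse_treatment(self.treatment_test))
        object.__setattr__(self, "treatment_ref", parse_treatment(self.treatment_ref))
        if self.treatment_test == self.treatment_ref:
            raise ValueError("test and reference treatments must differ")

    @property
    def name(self) -> str:
        return f"{self.stage}_{self.treatment_test}_vs_{self.treatment_ref}"

    def test_samples(self, design: SampleDesign) -> list[str]:
        s = design.samples_for(self.stage, self.treatment_test)
        if not s:
            raise ValueError(f"no samples for ({self.stage}, {self.treatment_test})")
        return s

    def ref_samples(self, design: SampleDesign) -> list[str]:
        s = design.samples_for(self.stage, self.treatment_ref)
        if not s:
            raise ValueError(f"no samples for ({self.stage}, {self.treatment_ref})")
        return s


def read_protein_groups(path) -> ProteinGroupsTable:
    """Parse a proteinGroups-style TSV.

    ``LFQ intensity <sample>`` columns become the intensity matrix with zeros
    and blanks mapped to NaN; ``+`` in the contaminant/reverse/only-by-site
    columns becomes a boolean flag.  The protein group id is taken from
    ``Protein IDs`` and falls back to ``Majority protein IDs``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns.size == 0:
        raise ValueError("empty file: no header row")
    lfq_cols = [c for c in df.columns if c.startswith(LFQ_PREFIX)]
    if not lfq_cols:
        raise ValueError(f"no '{LFQ_PREFIX}<sample>' columns found")
    samples = [c[len(LFQ_PREFIX):] for c in lfq_cols]
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample names among LFQ columns")

    id_col = ID_COLUMN if ID_COLUMN in df.columns else MAJORITY_ID_COLUMN
    if id_col not in df.columns:
        raise ValueError(
            f"need an id column ({ID_COLUMN!r} or {MAJORITY_ID_COLUMN!r})"
        )
    ids = pd.Index(df[id_col].astype(str), name="protein_group_id")

    lfq = df[lfq_cols].replace("", "0").astype(float)
    lfq.columns = samples
    lfq.index = ids
    lfq = lfq.mask(lfq == 0.0)  # MaxQuant writes 0 for "not quantified"
    if (lfq.to_numpy() < 0).any():
        raise ValueError("negative LFQ intensities are not valid")

    flags = pd.DataFrame(index=ids)
    for name, col in FLAG_COLUMNS.items():
        if col in df.columns:
            flags[name] = (df[col].str.strip() == "+").to_numpy()
        else:
            flags[name] = False

    if GENE_COLUMN in df.columns:
        genes = pd.Series(df[GENE_COLUMN].to_numpy(), index=ids, name="gene_name")
    else:
        genes = pd.Series("", index=ids, name="gene_name")

    return ProteinGroupsTable(lfq=lfq, gene_names=genes, flags=flags)


def write_protein_groups(table: ProteinGroupsTable, path) -> None:
    """Write the table back in the same dialect (NaN -> 0, flags -> '+')."""
    out = pd.DataFrame(index=table.ids)
    out[ID_COLUMN] = table.ids
    out[GENE_COLUMN] = table.gene_names
    for name, col in FLAG_COLUMNS.items():
        out[col] = np.where(table.flags[name], "+", "")
    for sample in table.samples:
        out[LFQ_PREFIX + sample] = table.lfq[sample].fillna(0.0)
    out.to_csv(path, sep="\t", index=False)


def filter_decoys(table: ProteinGroupsTable) -> ProteinGroupsTable:
    """Drop contaminants, reverse hits and only-by-site identifications."""
    keep = ~table.flags.any(axis=1)
    return table.select(keep.to_numpy())


def filter_min_valid(
    table: ProteinGroupsTable,
    design: SampleDesign,
    comparison: Comparison,
    min_events: int = 2,
    mode: str = "any",
) -> ProteinGroupsTable:
    """Require a minimum number of quantification events for a comparison.

    ``mode="any"`` (default) keeps a protein when at least one of the two
    comparison groups has >= ``min_events`` measured values, so that clean
    presence/absence candidates survive into imputation.  ``mode="both"``
    is the stricter reading requiring >= ``min_events`` in each group.
    """
    if mode not in ("any", "both"):
        raise ValueError("mode must be 'any' or 'both'")
    test = comparison.test_samples(design)
    ref = comparison.ref_samples(design)
    missing_cols = [s for s in test + ref if s not in table.lfq.columns]
    if missing_cols:
        raise ValueError(f"design samples absent from table: {missing_cols}")
    if mode == "any" and min_events > max(len(test), len(ref)):
        raise ValueError("min_events exceeds both group sizes")
    if mode == "both" and min_events > min(len(test), len(ref)):
        raise ValueError("min_events exceeds a group size")

    n_test = table.lfq[test].notna().sum(axis=1)
    n_ref = table.lfq[ref].notna().sum(axis=1)
    if mode == "any":
        keep = (n_test >= min_events) | (n_ref >= min_events)
    else:
        keep = (n_test >= min_events) & (n_ref >= min_events)
    logger.info(
        "%s: kept %d/%d protein groups (min %d events, mode=%s)",
        comparison.name, int(keep.sum()), len(keep), min_events, mode,
    )
    return table.select(keep.to_numpy())
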