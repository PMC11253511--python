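# dsbquant

Quantitative analysis of DNA double-strand-break (DSB) response experiments
in budding yeast, built around four assay families:

- **Label-free proteomics differential abundance** — MaxQuant-style
  protein-groups tables (`LFQ intensity <sample>` columns) are filtered
  (contaminant / reverse / only-by-site decoys, minimum quantification
  events), log2-transformed, completed by per-replicate low-tail beta
  imputation of the left-censored missing values, tested protein-by-protein
  with a Welch t-test, and called against a curved volcano threshold
  `|log2FC| > s` and `−log10 p ≥ −log10 p0 + c/(|log2FC| − s)`
  (defaults p0 = 0.05, s = 1, c = 0.5).
- **Hit calling** — intersection of the four damage-vs-mock comparisons
  (G2/M and late-mitotic arrest × HO endonuclease and phleomycin) into the
  set of proteins enriched specifically in late mitosis after both damage
  types.
- **qPCR estimators** — the HO cut fraction
  `f = 1 − E_HOcs^ΔCq(t0−t) / E_ref^ΔCq(t0−t)` and the resection fraction
  `f_resected = 2 / ((E_RS^ΔCq(digest−mock) / E_ref^ΔCq(digest−mock) + 1)·f)`
  from the StyI-protection assay (ssDNA produced by 5′→3′ resection resists
  restriction digestion), plus efficiency-corrected relative expression.
- **Blot densitometry** — MAT-switching repair kinetics (ACT1-normalized
  MATα over the 1-h HO-cut reference band), housekeeping-normalized western
  levels, and the Rad53 hyper:hypo phosphorylation ratio.

Each stage has a seeded forward simulator (`dsbquant.synthetic_data`) that
generates its inputs with known ground truth — spike-in LFQ tables with
missing-not-at-random dropout, restriction-protection Cq tables, Southern
lane intensities, focus-category counts — so the whole pipeline is testable
end to end without any external download.  See `docs/methods.md` for the
models and conventions.

## Worked example

Simulate a 500-protein experiment with 10 proteins spiked 4-fold (+2 log2)
in the late-mitotic damage cells, then run one damage-vs-mock comparison:

```python
import dsbquant as dq
from dsbquant.synthetic_data import SpikeDesign, gen_lfq_table, protein_id

spikes = tuple(protein_id(i) for i in range(10))
design = SpikeDesign(n_proteins=500, spike_ids=spikes, spike_log2fc=2.0, seed=7)
table, truth = gen_lfq_table(design)

comp = dq.Comparison("lateM", "phleo")
filtered = dq.filter_min_valid(dq.filter_decoys(table), design.groups, comp)
result = dq.compare(
    dq.log2_transform(filtered), design.groups, comp,
    dq.ImputationParams(seed=7),
)
hits = result[result["direction"] == "enriched"]
print(f"{len(result)} proteins tested, {len(hits)} called enriched")
print(hits[["log2fc", "p_value", "n_imputed_ref"]].round(3).to_string())
```

```
488 proteins tested, 10 called enriched
                  log2fc  p_value  n_imputed_ref
protein_group_id
P00000             1.811    0.000              0
P00001             2.162    0.000              0
P00002             2.036    0.000              0
P00003             2.308    0.000              0
P00004             2.308    0.000              0
P00005             1.772    0.000              0
P00006             2.410    0.000              0
P00007             1.962    0.000              0
P00008             1.759    0.001              0
P00009             2.315    0.000              0
```

All ten called proteins are exactly the planted spikes, with estimated fold
changes scattered around the true +2 log2 units, and no false positives
among the 478 null proteins.

The qPCR side, with 0.1-cycle Cq noise on a sample that is 90% cut and
resected 80% past a near (0.7 kb) and 20% past a far (10 kb) restriction
site:

```python
from dsbquant.synthetic_data import ResectionTruth, gen_resection_cq
from dsbquant.qpcr_quant import estimate_resection

truth = ResectionTruth(
    f_by_time={0: 0.0, 120: 0.9},
    r_by_amplicon_time={("RS_0.7kb", 120): 0.8, ("RS_10kb", 120): 0.2},
    efficiency={"ADH1": 2.0, "HOcs": 2.0, "RS_0.7kb": 2.0, "RS_10kb": 1.9},
    cq_noise_sd=0.1, n_replicates=3, seed=3,
)
est = estimate_resection(gen_resection_cq(truth), max_cq=truth.max_cq)
print(est.f.round(3).to_string())
print(est.f_resected.round(3).to_string(index=False))
```

```
time_min
0      0.000
120    0.899
amplicon  time_min  f_resected
RS_0.7kb       120       0.731
 RS_10kb       120       0.186
```

The cut fraction is recovered almost exactly (0.899 vs 0.9) and the
resected fractions land close to the planted 0.8 / 0.2 despite the Cq
noise; with noiseless input the estimators invert the forward model to
1e-9.

The same stages are exposed as a CLI: `dsbquant simulate lfq|resection|
blot|foci`, `dsbquant volcano`, `dsbquant hits`, `dsbquant resection`,
`dsbquant switch`, `dsbquant western`, `dsbquant test`.  Run any of them
with `--help` for options.

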