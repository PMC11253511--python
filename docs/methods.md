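# Methods

`dsbquant` quantifies four kinds of readout from DNA double-strand-break
(DSB) response experiments in budding yeast: label-free proteomics
differential abundance, condition-intersection hit selection, qPCR-based cut
and resection fractions, and blot densitometry for repair kinetics.  Every
stage has a matching forward simulator with known ground truth, so the whole
pipeline is validated end-to-end without any external data.

## Differential abundance (volcano analysis)

**Model.**  Protein-level LFQ intensities from a 2-stage (G2/M arrest vs
late-mitotic arrest) × 3-treatment (mock, HO endonuclease, phleomycin) ×
4-replicate design are compared damage-vs-mock within each stage.  The
processing chain per comparison:

1. Remove contaminants, reverse (decoy) hits and only-by-site
   identifications (rows with a `+` flag).
2. Keep proteins with ≥ 2 quantification events in at least one of the two
   comparison groups (`min_events=2`, `mode="any"`).  The lenient "at least
   one group" reading keeps presence/absence candidates — proteins
   quantified after damage and never in mock — alive into imputation; the
   strict "both groups" reading is available as `mode="both"`.
3. log2-transform; zeros on disk are missingness, not measurements.
4. Impute each replicate column independently: missing entries are drawn as
   `lo + (hi − lo)·Beta(2, 2)` where `lo`, `hi` are the 0.001 and 0.015
   empirical percentiles (linear-interpolation convention) of that column's
   measured log2 values.  This places imputed values in the extreme low tail
   of the observed distribution — the standard treatment for left-censored,
   missing-not-at-random (MNAR) LFQ dropout — while Beta(2, 2) compresses
   them symmetrically inside the band instead of spreading them uniformly.
5. Welch two-sample t-test (unequal variances, Welch–Satterthwaite df) on
   the completed 4 v 4 vectors; log2 fold change is the difference of
   post-imputation group means, so the plotted effect is the tested effect.
6. Curved significance threshold in the volcano plane: a protein is called
   when

   `|log2FC| > s`  and  `−log10 p ≥ −log10 p0 + c / (|log2FC| − s)`

   with defaults `p0 = 0.05`, `s = 1` (minimum 2-fold change), `c = 0.5`.
   The hyperbola has a vertical asymptote at `|log2FC| = s` and approaches
   the flat `−log10 p0` floor at large fold change; it is the standard
   curved-volcano construction for these three parameters.  No
   multiple-testing correction gates the calls; a Benjamini–Hochberg
   `q_value` column is emitted for information only.

**Numerical choices.**  The per-column imputation RNG substream is derived
deterministically from `(seed, crc32(sample_id))`, so results are
reproducible and independent of column order.  Degenerate Welch rows (zero
variance in both groups) get p = 1 when means agree and the limiting p = 0
otherwise, with a warning.  Welch calibration at these sample sizes is
conservative: the true type-I rate of the 4 v 4 test at nominal 0.05 is
≈ 0.041 because the Satterthwaite df is random and ≤ 6.

## Hit calling

The headline selection intersects the four comparisons:
`stage_specific = (enriched(lateM, HO) ∩ enriched(lateM, phleo)) \
(enriched(G2M, HO) ∪ enriched(G2M, phleo))` in the default strict mode
(lenient mode subtracts the G2/M intersection instead).  The set algebra is
taken over the enriched sets as produced: a protein filtered out of a G2/M
comparison — typically because it was never quantified in that stage — is
simply not enriched there.  This is deliberate: such presence/absence
proteins are exactly the biologically interesting stage-specific candidates,
and restricting to a common protein universe would delete them.

## qPCR estimators

**Cut fraction.**  With per-cycle primer efficiencies `E ∈ (1, 2]` and
`ΔCq(t0−t) = Cq(t0) − Cq(t)`,

`f = 1 − E_HOcs^ΔCq(t0−t) / E_ref^ΔCq(t0−t)`.

The cut-site amplicon spans the endonuclease recognition site, so cutting
removes template; the reference amplicon (ADH1) controls for input amount.

**Resected fraction.**  Resection converts one strand of the locus into
ssDNA, which resists restriction digestion.  Each sample is split into mock
and digested aliquots; with `ΔCq(digest−mock) = Cq(digest) − Cq(mock)`,

`f_resected = 2 / ((E_RS^ΔCq(digest−mock) / E_ref^ΔCq(digest−mock) + 1) · f)`.

The estimator is exact under duplex/ssDNA strand accounting: an intact or
cut-but-unresected locus contributes 2 template strands, a resected locus 1
protected strand, so mock signal ∝ 2 − f·r and digest signal ∝ f·r.  This
is the unique accounting under which the printed equation inverts the
forward model identically, which the round-trip tests verify to 1e-9 on the
full (f, r) grid.  Sign conventions follow the superscripts as written;
flipping either sign breaks the exact round trip, which pins them down.

**Conventions.**  Replicates are averaged as Cq before estimation
(estimator-of-mean; `mode="mean_estimate"` gives the alternative).
Non-amplifying wells carry a `max_cq` sentinel and are treated as zero
signal: an all-sentinel digested well yields `f_resected = 0`, an
all-sentinel cut-site well yields `f = 1`.  Estimates outside [0, 1]
(possible under noise) are reported and flagged, never clamped.  The
reference amplicon's digest−mock ΔCq is used when measured and defaults to
0 when the digested reference was not run.  Expression changes use the
efficiency-corrected two-gene ratio
`E_target^ΔCq_target / E_ref^ΔCq_ref` with `ΔCq = Cq(mock) − Cq(treated)`.

## Densitometry

Southern MAT-switching lanes are normalized in two steps: every band by its
lane's ACT1 signal (cancelling loading/transfer differences exactly — a
multiplicative lane factor provably drops out), then each MATα product band
by the ACT1-normalized HO-cut band of the 60-min reference lane, so the
series reads "fraction of cut DNA repaired by homologous recombination".
The reference time is configurable.  Western levels are
housekeeping-normalized (PGK1 by default at the CLI) and expressed relative
to mock; checkpoint activation is the hyper:hypo-phosphorylated Rad53 band
ratio, with multiple slow-migrating hyper bands summed first.  Inputs are
assumed background-corrected band intensities from gel-analysis software;
image analysis is out of scope.  A zero hypo band raises an error rather
than returning infinity, since saturated hyperphosphorylation needs manual
judgement.

## Inferential utilities

Two-sided throughout.  Mann–Whitney U uses the exact null distribution when
the sample-size product is ≤ 400 and the pooled data are tie-free, else the
normal approximation with midranks and tie-corrected variance; the exact
branch is verified against full rank enumeration for every size pair up to
5 v 5.  SEM is the n−1 sample SD over √n.  Star labels: * p<0.05,
** p<0.01, *** p<0.001, **** p<0.0001.

## Synthetic data: what it emulates and what it does not

**LFQ generator.**  Per-protein log2 means are `25 ± 2` (between-protein
SD), replicate noise SD 0.3, planted enrichments added in designated
stage × treatment cells, dropout probability
`logistic((21.5 − log2 intensity) · 3)`.  The midpoint sits ≈ 1.75 protein
SDs below the mean and the slope of 3 per log2 unit confines missingness to
the low-abundance tail (≈ 5% of values overall, near-zero for
well-quantified proteins), emulating left-censored MNAR dropout in
match-between-runs LFQ data.  The default scale of 3,000 proteins matches a
typical single-run yeast proteome depth.  Not emulated: correlated dropout
within replicates, peptide-level variation, between-run normalization
artefacts, heavy-tailed replicate noise, and batch structure — so passing
spike-in benchmarks demonstrates correctness of the statistical machinery
under the stated noise model, not performance on any real dataset.

**Benchmark scenarios.**  The spike-in benchmark plants 50 of 3,000
proteins at +2 log2 units (4-fold) in both late-M damage cells.  The
hit-calling benchmark plants 5 late-M-specific, 3 shared and 2 G2/M-only
enrichments among 300 proteins at +6 log2 units — the presence/absence
regime of a strongly induced protein — because that scenario probes the
intersection logic rather than test power; with mid-sized effects a planted
protein whose baseline falls in the censored tail can have its apparent
fold change compressed toward the imputation band, which is a property of
low-tail imputation itself, not of the set algebra under test.

**qPCR generator.**  Inverts to the estimators exactly when noiseless (the
estimators are the closed-form inverse of its strand accounting); Gaussian
Cq noise (default 0, benchmark 0.1 cycles) and a 40-cycle no-amplification
sentinel.  Replicate count defaults to 3.

**Blot generator.**  Per-lane multiplicative loading factor
`exp(N(0, 0.1))` and per-band multiplicative noise with 1% CV around a
planted switching trajectory; ACT1 band mean 1, MATα and HO-cut bands split
the cut fraction.  Band intensities are clipped at 0.

**Foci generator.**  Multinomial counts per replicate (categories like
no-focus / one focus / multiple foci), 100 cells and 3 replicates by
default, matching typical per-timepoint scoring depth.

All generators are bit-reproducible given their seed.

## Problem sizes used in validation

Round trips use the full 10 × 10 (f, r) grid; noise robustness 1,000
simulations; Welch calibration 400,000 null 4 v 4 draws (large enough that
the measured rate reflects calibration, not Monte-Carlo noise, given the
true rate ≈ 0.041); spike-in one 3,000-protein table; hit recovery 20
independent seeds; imputation 100,000 draws.

## Known limitations

- The curved-threshold functional form is a documented convention choice;
  analyses that used a different curve with the same (p0, s, c) labels will
  call borderline proteins differently.
- Imputation assumes every sample column has enough measured values to
  anchor its low-tail percentiles; tiny tables (a handful of proteins) are
  outside the intended regime, though columns with no missing values pass
  through untouched.
- The resected-fraction estimator is undefined at f = 0 and increasingly
  noise-sensitive as f → 0; callers should gate on f before interpreting
  f_resected at early time points.
- `filter_min_valid` in the default per-comparison mode yields different
  protein universes per comparison by design; consumers combining
  comparisons must treat absence as "not enriched", as `hit_calling` does.
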