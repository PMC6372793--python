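# Methods

Statistical and numerical design of `zerogrowth`, with the reasoning behind
every non-obvious default. Module order follows the analysis flow.

## 1. Synthetic data generator (`syndata`)

### Count model

Counts are negative binomial (NB) in the moment parameterization. For gene
*i* (length *L_i* nt, category *cat_i*) in sample *j* (library depth *N_j*
fragments, treatment activity factor *a_j*):

```
mu_ij = (L_i / 1000) * (N_j / 1e6) * b_i * a_j^gamma(cat_i)
Var   = mu + phi * mu^2
```

so that a gene's *expected FPKM against whole-library depth* is
`b_i * a_j^gamma`. `b_i` is log-normal (`baseline_log_mean = -3`,
`baseline_log_sd = 1` on the natural-log scale), putting typical
control-condition FPKMs in the 0.01–0.3 range — realistic for a population
that is ~0.006 % of the community. At `phi = 0` the generator draws Poisson
counts exactly (not NB with a tiny size parameter), so the Poisson limit is
available for oracle tests.

### Activity coupling `gamma`

`gamma(cat)` couples each functional category to the treatment activity
factor: 1.0 for energy/activity categories (`ribosomal`, `central_energy`,
`sulfate_reduction`, `stress`, and the bulk `other` category) and 0.0 for
growth categories (`growth_replication`, `growth_division`,
`growth_envelope`, `sporulation`, `phage_response`).

- **`other` gets gamma = 1.** The empirical phenomenon being modeled is a
  *genome-wide* transcription surge: total mRNA rises ~100-fold while only
  replication/division genes stay flat. If the bulk of the genome were
  uncoupled, total mRNA could not surge and the screen's reference signal
  (total mRNA) would not exist.
- **`activity_replicate_sd = 0.5`** adds log-normal sample-to-sample noise
  to `a_j`. Without it, replicates within a treatment have identical
  activity and the Spearman screen degenerates (within-group rank ties carry
  all the signal). 0.5 on the natural-log scale (~65 % CV) reflects the
  replicate scatter typical of anaerobic soil microcosms.

### Design, library sizes, qPCR

`default_design()` is the full factorial: 6 substrate amendments
(`none`, `formate`, `acetate`, `propionate`, `lactate`, `butyrate`) ×
(`plusS`/`minusS` sulfate) × 3 replicate microcosms × sampling days. Library
depths are log-uniform over 2.7e7–1.88e8 fragments, the realistic span of
per-sample metatranscriptome sizes. Activity factors plateau at day 36 and
ramp before it (day 0 → 1, day 8 → √a).

`simulate_qpcr` draws log-normal 16S copy numbers around a constant mean
(optionally scaled by a per-condition fold map), modelling a population that
does not grow.

### Determinism

All randomness flows from one `numpy.random.SeedSequence`, spawned into
independent child streams per component, so adding genes or samples does not
perturb unrelated draws and every result is bit-reproducible from the seed.

## 2. Quantification (`quantify`)

- **FPKM against whole-library depth.** `compute_fpkm` divides by the *total
  metatranscriptome* fragment count, not by fragments mapped to the focal
  genome. For a rare population the focal-mapped denominator would erase the
  very signal of interest (a genome-wide surge inflates the focal
  denominator and cancels itself). The focal denominator is still available
  via the `total_fragments` argument for within-genome composition
  questions.
- **Size factors** are DESeq-style median-of-ratios. When no gene is
  nonzero in all samples (common at rare-population depths), the geometric
  pseudo-reference falls back to `counts + 1` and a warning is logged.
- **Variance stabilization** is `log2(K_ij / s_j + pseudocount)` — a shifted
  log, not a fitted mean–dispersion VST. At the low counts this package
  targets the two are nearly indistinguishable, and the shifted log is
  exactly reproducible without a fitted curve.
- **Scaling** is per-row min–max to [0, 1]; constant rows map to 0.
- **Fold change vs control** compares per-treatment mean total mRNA to the
  no-substrate control at the same day and sulfate level.

## 3. Activity screen (`activity`)

- **Spearman rho** uses midranks for ties. P-values: exact enumeration of
  all n! permutations for n < 10 (two-sided, counting |rho| ≥ observed);
  the t-distribution approximation with df = n − 2 for n ≥ 10. Both agree
  with `scipy.stats.spearmanr` where comparable (tested to 1e-9).
- **Benjamini–Hochberg** is the standard step-up with the cumulative-minimum
  formulation; all-NaN/all-zero genes are excluded from the family *before*
  correction (they carry no evidence and would only dilute the ranks).
- **Screen.** Each gene's FPKM profile is correlated with the per-sample
  total mRNA; the per-category summary reports mean/sd of rho and counts of
  BH-significant genes. Category means in the state call use **all** genes
  (`significant_only=False`): growth categories at gamma = 0 rarely reach
  significance — precisely when the screen works — so a significant-only
  mean would be NaN exactly in the case of interest.
- **State call** (`classify_population_state`):
  - `growth` if the 95 % CI of the log10-copies-vs-day OLS slope lies
    above 0;
  - `active_zero_growth` if the CI contains 0 **and** the strongest
    treatment's total-mRNA fold change ≥ `fold_min` (default 10) **and**
    the activity-minus-growth mean-rho gap ≥ `gap_min` (default 0.2);
  - `baseline` otherwise.

  `fold_min = 10` separates a genuine surge from replicate noise (observed
  control-to-control folds are < 2); `gap_min = 0.2` is half the gap the
  generator produces under the weakest passing coupling, leaving margin for
  sampling noise without admitting a flat profile.

## 4. Differential expression and clustering (`de_cluster`)

### NB moment/Wald test

For two groups A and B with size-factor-normalized counts:

1. Group means `m_A`, `m_B`; `LFC = log2((m_B + 0.5) / (m_A + 0.5))`.
2. A **pooled moment dispersion** per gene:
   `phi = max((v - m) / m^2, floor)` with pooled normalized mean m and
   variance v, `floor = 0.05` by default.
3. Delta-method SE of the LFC with the NB variance plugged in at the
   **pseudocounted** means:
   `Var(m_A) = ((m_A + 0.5) + phi (m_A + 0.5)^2) / n_A` (likewise B),
   `SE = sqrt(Var_A / (m_A+0.5)^2 + Var_B / (m_B+0.5)^2) / ln 2`.
4. Two-sided normal p-value on `LFC / SE`; BH across tested genes
   (all-zero genes are dropped before testing).

Two choices deserve justification because the naive estimator
(`floor → 0`, variance at the raw means) is **anticonservative** — measured
false-discovery proportions of 0.19–0.24 on realistic low-count data:

- **Dispersion floor 0.05.** A per-gene moment dispersion from 3 + 3
  observations is extremely noisy and collapses to ~0 for a large fraction
  of genes by chance, producing near-zero SEs. 0.05 corresponds to a ~22 %
  biological CV — a weak lower bound for between-replicate variability in
  environmental samples. Passing `dispersion_floor=1e-8` recovers the raw
  moment estimator.
- **Variance plug-in at pseudocounted means.** A group with all-zero counts
  has raw moment variance 0, sending the Wald z to infinity; evaluating the
  NB variance at `m + 0.5` keeps the SE consistent with the statistic whose
  uncertainty it describes (the pseudocounted LFC) and bounded away from 0.

Alternatives measured and rejected: a t reference distribution with
df = n_A + n_B − 2 (or Satterthwaite df) controls FDR but destroys power
(0.13–0.57 vs 0.93 at a 4-fold effect, 3 vs 3, phi = 0.05); a grand-mean
dispersion yields zero discoveries; empirical-Bayes shrinkage is out of
scope for a moment-based test.

**Measured calibration** (20-seed averages, BH at alpha = 0.05, 3 vs 3):
false-discovery proportion 0.035 with power 0.93 at phi = 0.05 and moderate
counts; 0.051 at the generator defaults (phi = 0.1, low counts).
**Known limitation:** when the true dispersion exceeds the floor *and*
counts are high (phi = 0.1, mean counts in the hundreds), the plug-in SE is
still slightly too small and the realized FDP rises to ~0.15 at nominal
0.05. For high-count, high-dispersion data, raise `dispersion_floor` toward
the believed squared CV or use a shrinkage-based package.

### Clustering

Distance is `1 − Pearson r` between variance-stabilized profiles (constant
profiles are rejected — their correlation is undefined). Agglomerative
average or complete linkage is implemented directly on the distance matrix
with deterministic tie-breaking (lowest index pair), guaranteeing
reproducible trees; heights are non-decreasing (both linkages are monotone).
Trees cut by cluster count k or by height; Newick export preserves heights
as branch lengths.

## 5. Energetics (`energetics`)

Maintenance Gibbs-energy demand follows the species-independent Arrhenius
correlation for maintenance requirements:

```
m_G(T) = m_ref * exp(-(Ea/R) * (1/T - 1/T_ref))
```

with literature defaults `m_ref = 4.5 kJ (C-mol biomass)^-1 h^-1` at
298.15 K and `Ea = 69 kJ mol^-1` (Tijhuis et al. 1993; Harder 1997), giving
1.549 kJ C-mol⁻¹ h⁻¹ at the 14 °C (287.15 K) incubation temperature. A cell
of 6.5e-15 C-mol carbon (~0.16 pg C, a typical small soil bacterium)
respiring lactate incompletely to acetate with sulfate
(ΔG = −160 kJ per mol sulfate) must then reduce

```
1.549 kJ C-mol^-1 h^-1 * 24 h * 6.5e-15 C-mol / 160 kJ mol^-1
  = 1.510 fmol sulfate cell^-1 day^-1
```

to pay its maintenance bill (`per_cell_acceptor_demand`). `herbert_pirt_qs`
gives the general `q_s = mu / Y_max + m_s`, which collapses to `q_s = m_s`
at zero growth. `demand_vs_measured_ratio` classifies a measured
cell-specific rate as `below_maintenance` (< 0.1× demand),
`maintenance_consistent` (0.1–10×), or `above_maintenance` (> 10×) — a
band of one order of magnitude on either side, matching the precision of
the inputs (cell carbon, ΔG, and the maintenance correlation are each only
good to a factor of a few).

## 6. Genome-recovery support (`genome_support`)

- **GC-coverage transform** for SIP differential-coverage binning:
  `coverage / gc^9 * 1e15`, with `gc` on the **percent** scale (42.6, not
  0.426). The ninth power mimics how density-gradient fractionation skews
  coverage with G+C content; 1e15 rescales `42.6^9 ≈ 4.6e14` back to
  order-1 values so native and transformed coverages can share an axis. The
  exponent and scale are configurable.
- **Bin gating** is a rectangle in (native coverage, transformed SIP
  coverage); the summary reports scaffold count, total bp, and mean GC.
- **Homology calls** use inclusive thresholds on (percent identity, percent
  query coverage, evidence tier): ≥ 40 % / ≥ 80 % with curated-tier
  evidence → `true_homolog`; ≥ 25 % / ≥ 80 % → `putative_homolog`;
  otherwise `no_call`. A synteny flag promotes `putative` to `true`. The
  threshold table is versioned so calls can be reproduced later.
- **rrn correction** converts 16S qPCR copies to cells by dividing by the
  genus rrn operon count (default 9.3) and optionally reports relative
  abundance against a total community size.

## 7. Pipeline and reproducibility

`run_pipeline(PipelineConfig)` executes simulate → quantify → activity
screen → state call → maintenance budget, writing TSV/JSON outputs plus a
`manifest.json` with SHA-256 checksums of every file. The same config and
seed produce byte-identical outputs (verified by test). `validate_config`
rejects unknown fields and out-of-range values with messages naming the
offending field.

## 8. Limitations

- The DE test is a two-group moment/Wald test: no multi-factor designs, no
  dispersion shrinkage, and the FDR caveat above at high counts with
  under-floored dispersion.
- The VST is a shifted log, adequate at low counts but not a fitted
  mean–dispersion transform.
- The state call uses an OLS slope on log10 qPCR copies; it assumes
  independent errors across days and at least three time points.
- Energetics defaults are literature-scale values; all are dataclass fields
  meant to be overridden with system-specific measurements.
- The generator's activity model (single per-treatment factor with a fixed
  day ramp) is deliberately simple; it is a testbed for the statistics, not
  a mechanistic transcriptome model.
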