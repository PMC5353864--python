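# pancmetab

Tissue-metabolomics analysis pipeline for 1D ¹H HRMAS NMR spectra of intact
pancreatic tissue, built for the question of whether the tissue metabolome
separates healthy pancreatic parenchyma (PP) from pancreatic adenocarcinoma
(PA) and predicts long-term survival after resection. It is aimed at
metabolomics analysts who have bucketed 1D spectra (or quantified
concentration tables) plus a sample-metadata sheet, and want the full chain
— absolute quantification, class discrimination, network-level direction
calls, and single-metabolite biomarker evaluation — in reproducible,
scriptable form.

## What it computes

1. **Bucketing** — each spectrum is integrated over 0.01-ppm buckets on
   7.50–0.70 ppm (680 buckets) and divided by tissue weight, producing the
   multivariate data matrix.
2. **PULCON absolute quantification** — the designated quantification peak
   of each of 18 metabolites is window-integrated (local linear baseline
   subtracted) and referenced to an external 3 µmol lactate standard scanned
   under the same conditions:

   `amount = ref_nmol · (area/n_H) / (area_ref/n_H,ref)`,

   corrected by proton count, with glucose summed over its α/β anomer peaks;
   concentrations are reported in nmol per mg of wet tissue.
3. **OPLS-DA** — orthogonal projections to latent structures discriminant
   analysis: class-orthogonal variation is filtered out, one predictive
   component is fitted, and quality is summarized by R²Y and 7-fold
   cross-validated Q² (R²Y > 0.7 with Q² > 0.5 read as a good model).
4. **Univariate tables** — per-metabolite mean ± SD with two-sided
   Mann-Whitney U tests (exact for the small contrasts), uncorrected, in the
   layout of the published group-comparison tables.
5. **Network direction analysis** — pathway-related metabolite groups are
   scored jointly by a k-nearest-neighbor mutual-information estimate
   I(group; condition) with a permutation null; each metabolite in a
   significant group is called increase / decrease / stable between the two
   conditions.
6. **Survival biomarker** — ROC/AUC with the Youden-optimal threshold
   (sensitivity, specificity, predictive values), Kaplan-Meier curves for
   the threshold-defined strata, and the log-rank test; the motivating
   biomarker is tissue ethanolamine, whose high concentration marks
   short-term survivors.

Because the study's patient spectra were never deposited, the package ships
a synthetic-cohort generator whose defaults reproduce the study conditions:
group sizes (PP 9/8, PA 44/62, survivors 8/9), per-metabolite concentration
means ± SD transcribed from the published tables, Lorentzian spectra at the
published chemical shifts, and exponential survival for the outcome groups.

## Worked example

```sh
panc-metab reproduce-synthetic --seed 1 --out-dir run --points 65536
```

runs the whole chain on synthetic cohorts and prints

```
pipeline complete: R2Y = 0.972, Q2 = 0.595, ethanolamine AUC = 0.667 -> run
```

meaning: on the bucketed synthetic tissue cohort (9 PP vs 44 PA spectra) the
OPLS-DA model explains 97 % of the class variance in training and predicts
59 % of it under 7-fold cross-validation — past the R²Y > 0.7 / Q² > 0.5
quality gate — and on the 17-sample survivor cohort, ethanolamine alone
separates long- from short-term survivors with AUC 0.667. The output
directory holds the bucket matrix, the quantified concentration table
(`quant_table.csv`, nmol/mg, recovered from the rendered spectra via the
lactate reference), Mann-Whitney comparison tables, the OPLS summary, the
network direction map (e.g. `glucose  decrease  1` — glucose predicted to
decrease in long-term survivors via one significant group), the biomarker
report (Youden threshold 0.888 nmol/mg, specificity 1.00, log-rank
p = 0.0007 between the strata), and a manifest with the seed, config hash,
and per-file checksums; reruns with the same seed are byte-identical.

The same stages are available separately (`simulate`, `quantify`,
`compare`, `opls`, `adema`, `biomarker`) and as library functions
(`pancmetab.pulcon_quantify`, `fit_opls_da`, `predict_directions`,
`evaluate_biomarker`, ...).

## Data files

The packaged assignment table (`src/pancmetab/data/assignments.csv`, 31
identified metabolites, 18 with designated quantification peaks), the
metabolic network with its 12 pathway group comparisons (`network.txt`),
and the four cohort design tables (`design_table*.csv`) are plain text and
can be replaced by user versions via the corresponding reader functions.
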