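# thrombogen

Plasma-composition-driven modeling of thrombin generation, with a protein C
(PC) pathway module and pedigree-aware group statistics.

The package implements an end-to-end analysis for family cohorts with
measured coagulation-factor panels:

1. **Reaction network as data** (`thrombogen.model`) — the tissue-factor
   initiated extrinsic cascade plus a PC pathway module (thrombomodulin
   binding to thrombin/meizothrombin, PC activation by those complexes, AT
   inhibition of Tm-bound thrombin, APC inactivation of the fVa/fVIIIa
   cofactors) is parsed from plain-text TSV tables shipped under
   `src/thrombogen/data/`, with stoichiometric, unit/molecularity and
   moiety-conservation validation. The PC module can be switched off
   (`select_submodel`) to contrast thrombin generation with and without the
   PC pathway.
2. **Stiff ODE engine** (`thrombogen.kinetics`) — initial conditions are
   built from an individual's fII, fV, fVII, fVIII, fIX, fX, AT, TFPI and PC
   levels (nanomolar internally), triggered with 5 pM tissue factor and 1 nM
   thrombomodulin by default, and integrated over 20 minutes with an
   LSODA solver and an analytic Jacobian generated from the reaction list.
   Total active thrombin ([IIa] + 1.2·[mIIa], configurable) is reported at
   1 s intervals; moiety conservation is audited to <0.1% drift.
3. **Thrombogram parameters** (`thrombogen.metrics`) — MaxL, TMaxL, MaxR,
   TMaxR, AUC and clot time (first crossing of 10 nM thrombin), plus
   per-parameter "exceeds control" flags.
4. **Cohort pipeline** (`thrombogen.cohort`) — CSV input (molar or
   percent-of-mean dialect), the six-category inclusion filter, per-subject
   simulation under both pathway settings, group summary tables (overall and
   by sex) and mean ± SD envelope curves.
5. **Synthetic cohorts** (`thrombogen.synthetic`) — truncated-normal factor
   panels whose truncated moments match the published per-group means/SDs,
   printed group sizes and sex splits (364 subjects; 81/283 PC-mutation
   carriers/non-carriers, 43/292 prothrombin-variant, 13/351 thrombosis
   history), an optional 514-row raw roster carrying the printed exclusion
   counts, multi-generation pedigrees and a generative polygenic trait model.
6. **Variance-component statistics** (`thrombogen.stats`) — recursive
   kinship (with a Monte-Carlo gene-dropping cross-check), ML fit of
   `y ~ N(Xb, 2*Phi*sigma2_g + I*sigma2_e)` via eigen-rotation and a 1-D
   heritability profile, and likelihood-ratio tests for group effects
   adjusted for age and sex.

## CLI

```sh
thrombogen validate-model                  # transcription checks + conservation audit
thrombogen simulate --out tc.tsv           # mean physiologic control -> time-course TSV
thrombogen simulate --composition cohort.csv --subject S0001 --no-pc-pathway --out tc.tsv
thrombogen synth --out cohort.csv --pedigree-out ped.csv --raw-roster --seed 1
thrombogen cohort --in cohort.csv --out-dir results/   # metrics.csv, summaries.csv, envelopes.tsv
thrombogen stats --metrics results/metrics.csv --cohort cohort.csv \
                 --pedigree ped.csv --out results/stats.csv
```

A custom reaction network can be supplied with `--reactions/--rates/--species`
(TSV, same layout as `src/thrombogen/data/`); `--config` points at a flat
`key = value` file mirroring `SimulationConfig`.

## Layout

```
src/thrombogen/
  model.py       reaction-network parsing/validation, stoichiometry, submodels
  kinetics.py    compositions, simulation config, stiff mass-action integration
  metrics.py     thrombogram parameters
  cohort.py      filters, unit conversion, cohort orchestration, summaries
  synthetic.py   synthetic cohorts, pedigrees, polygenic traits
  stats.py       kinship, polygenic ML fit, likelihood-ratio tests
  data/*.tsv     the model transcription (species, reactions, rate constants)
tests/           pytest suite incl. test_acceptance.py
scripts/acceptance.py
```
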