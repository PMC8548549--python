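# panelgauge

Tools for evaluating gene-targeted sequencing panels as estimators of
tumor mutational burden (TMB).

TMB — the number of somatic mutations per megabase of interrogated
coding sequence — is an FDA-recognised biomarker for immune checkpoint
blockade therapy (threshold 10 mutations/Mb). Whole-exome sequencing
(WES) is the gold standard, but clinical practice estimates TMB from
gene-targeted panels covering ~0.2–1.5 Mb. `panelgauge` answers the
question *"how good is this panel?"* with two measurements computed over
a cohort of patients with paired panel-based TMB `x_i` and WES-based
TMB `y_i`:

* **R²** of the least-squares fit `y = a·x + b`, the mainstream
  concordance measure:

      a = Σ(xᵢ−x̄)(yᵢ−ȳ) / Σ(xᵢ−x̄)²,   b = ȳ − a·x̄
      R² = 1 − Σ(yᵢ − a·xᵢ − b)² / Σ(yᵢ − ȳ)²

  Because each patient enters through its squared residual, a patient at
  k× the TMB of another with the same relative bias contributes ≈ k²
  times as much — R² is dominated by the cohort's hypermutated tail and
  systematically overestimates panel performance on long-tailed cohorts.

* **Angular distance**, a per-patient estimation-bias measure that
  weights every patient equally:

      θᵢ = |π/4 − arctan(yᵢ / xᵢ)|  ∈ [0, π/4],    θ̄ = Σθᵢ / n

  θᵢ is 0 when the panel is exact, π/4 when it detects nothing, and is
  invariant to rescaling (x, y) → (kx, ky). A relative bias of 20%
  corresponds to θ = 0.1107; 10% to θ = 0.0526.

The package reads standard MAF mutation tables and CCDS-style gene
models, computes panel/WES TMB under total-point (F1CDx-style) or
nonsynonymous (MSK-IMPACT-style) counting, splits cohorts at the
hypermutation cutoff (WES total-point TMB > 50 mutations/Mb), runs
randomized in-silico panel simulations, and generates realistic
long-tailed synthetic cohorts so the whole pipeline is testable without
external downloads.

## Worked example

Generate a 500-patient synthetic cohort on a 300-gene universe, then
evaluate a small (40-gene) and a larger (150-gene) panel against
WES-based TMB:

```sh
panelgauge synth --n-patients 500 --n-genes 300 --seed 7 --out demo
# cohort: 500 patients, mean TMB 10.05, median 3.72, 18 hypermutated

python - <<'EOF'
import panelgauge as pg
models = pg.read_gene_models("demo/universe.ccds.txt")
open("demo/panel_small.txt", "w").write("\n".join(sorted(models)[:40]) + "\n")
open("demo/panel_large.txt", "w").write("\n".join(sorted(models)[:150]) + "\n")
EOF

panelgauge evaluate --maf demo/cohort.maf --ccds demo/universe.ccds.txt \
    --panel demo/panel_small.txt --panel demo/panel_large.txt \
    --out demo/eval --no-plots
```

Output:

```
      panel          dataset_label   n    slope  intercept  r_squared  mean_theta  accuracy
panel_small hypermutation_included 405 0.787854   2.000963   0.737237    0.609721     0.625
panel_small      non_hypermutation 387 0.400656   3.446620   0.374593    0.628675     0.625
panel_large hypermutation_included 405 0.931132   0.564041   0.965552    0.289763     0.625
panel_large      non_hypermutation 387 0.867124   0.824098   0.836693    0.299870     0.625
```

Reading the numbers: the larger panel is better by both measures (higher
R², lower θ̄). But note how R² changes when the 18 hypermutated patients
are dropped — 0.74 → 0.37 for the small panel, 0.97 → 0.84 for the large
one — while the mean angular distance moves by less than 0.02. R² was
being propped up by a handful of extreme-TMB patients; θ̄ reports the
typical patient's estimation bias either way. The `accuracy` column is
the fraction of patients with WES TMB in [9, 11] mutations/Mb that the
panel classifies on the correct side of the 10 mutations/Mb threshold —
near coin-flip for panels this small.

The same library surface is available in Python (`pg.read_maf`,
`pg.pair_tmb`, `pg.evaluate_panel`, `pg.run_simulation`, …), and
`panelgauge simulate` runs the randomized panel-size experiment
(`--n-panels 10000 --max-genes 3000` reproduces the full-scale design on
a real MAF + CCDS pair).

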