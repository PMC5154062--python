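# ifnstab

Association screening and split-half stability analysis for composite
peripheral-blood interferon (IFN) scores in rheumatoid arthritis (RA)
cohorts.

About half of RA patients show an *IFN signature*: coordinately elevated
expression of type I interferon response genes (IRGs) in whole blood. A
natural question for any such signature is whether it tracks anything
clinical — disease activity, autoantibodies, damage, treatment. `ifnstab`
packages the full analysis pipeline for that question:

1. **quantify** — qPCR standard-curve relative quantification: Ct values
   are mapped through per-gene calibration lines
   Ct = a + b·log10(quantity), normalized to a reference gene (GAPDH) and
   log2-transformed. Pre-computed log2 expression can be supplied
   directly instead.
2. **score** — the IFN score of patient *j* over an IRG panel *G*:

   score_j = (1/|G|) Σ_{g∈G} log2(rel. expr._gj)

   plus a panel-coherence QC (fraction of gene pairs with Pearson
   r ≥ 0.7, p ≤ 0.002) that warns when averaging is poorly justified.
3. **screen** — per variable: Spearman's ρ (continuous) or Mann-Whitney U
   (dichotomous) against the score on pairwise-complete cases, then
   Benjamini-Hochberg adjustment across the variable list. Both the
   standard monotone step-up and the "plain" q = p·m/rank dialect used by
   some statistics packages are provided, with family size *m* allowed to
   exceed the number of reported p values.
4. **stability** — internal cross-validation: the cohort is randomly
   bipartitioned into equal halves 1000 times, every test is run on both
   halves, and the report counts iterations significant in both / one /
   neither half with per-set median p. Under an iid null the disjoint
   halves are independent, so the both-halves rate calibrates to ≈ α².
5. **synthetic** — a cohort generator (equicorrelated factor-model
   expression, realistic established-RA clinical marginals, additive
   per-agent treatment suppression with recorded ground truth) so the
   whole pipeline is testable without patient data.
6. **report** — fuses screen and stability into one table with a
   provenance block; `run_pipeline` drives everything from a YAML config.

## Worked example

Simulate a 182-patient cohort in which hydroxychloroquine (HCQ),
prednisone and sulfasalazine (SSZ) suppress the score by 0.6 / 0.3 / 0.3
score-SD per agent, then run the full pipeline:

```python
from ifnstab import SyntheticCohortConfig, generate_cohort, run_pipeline
from ifnstab.quantify import write_expression

cfg = SyntheticCohortConfig(
    seed=17,
    suppression_delta={"prednisone_use": 0.3, "hcq_use": 0.6, "ssz_use": 0.3},
)
expr, cohort, truth = generate_cohort(cfg)
write_expression(expr, "expr.csv")
cohort.data.to_csv("cohort.csv", na_rep="NA")

artifacts = run_pipeline(
    {
        "expression": "expr.csv",
        "cohort": "cohort.csv",
        "stability": {"n_iter": 1000, "alpha": 0.05, "seed": 42},
        "bh": {"mode": "plain"},
    },
    out_prefix="demo_",
)
print(artifacts["report"].rows)
```

Selected rows of the printed report:

```
      variable         test   n   statistic        p        q  both  one  neither  median_p_set1  median_p_set2
         das28     spearman 182   -0.017777 0.811734 1.000000     3    8      989       0.626714       0.614473
    acpa_titer     spearman 172   -0.000462 0.995198 0.995198     7    6      987       0.583801       0.598522
prednisone_use mann_whitney 182 2563.000000 0.010990 0.091585     1  785      214       0.077584       0.068424
       hcq_use mann_whitney 182 1847.000000 0.001252 0.015655   370  630        0       0.025729       0.021493
       ssz_use mann_whitney 182 1331.000000 0.018903 0.118143     0  618      382       0.095163       0.096602
any_suppressor mann_whitney 182 2507.000000 0.000005 0.000124   961   39        0       0.001434       0.001145
```

Reading it: the injected treatment effects surface exactly where they
should. The combined any-suppressor flag replicates in both halves in
961/1000 bipartitions; the single-agent HCQ effect is significant on the
full cohort (q = 0.016 after plain-BH over 25 tests) but replicates in
both halves only 370 times — a textbook illustration of why the stability
columns matter. Variables with no injected effect (DAS28, ACPA titer, and
the other 19 rows not shown) sit near their null behavior: `both` counts
of a few per thousand, median half-set p around 0.6. The `n` column shows
pairwise-complete sizes (ACPA titer is missing for ~7/182 patients by
design), and the QC reported `171 pairs: 100.0% with r >= 0.7` for the
ρ = 0.8 factor-model panel.

The same run is available from the shell:

```bash
ifnstab simulate --seed 17 --out-prefix syn_
ifnstab score --expr syn_expr.csv --qc-report qc.tsv --out scores.csv
ifnstab screen --scores scores.csv --cohort syn_cohort.csv --replicate-published-bh --out screen.tsv
ifnstab stability --scores scores.csv --cohort syn_cohort.csv --iters 1000 --seed 42 --out stab.tsv
ifnstab run --config run.yaml        # everything at once
```

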