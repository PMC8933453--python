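# bloodlcl

Real-time PCR tissue-of-origin testing for DNA biobanks: distinguishing
blood-derived from lymphoblastoid-cell-line (LCL)-derived DNA, plus a
three-CpG DNA-methylation age model.

## The problem

Large DNA collections assembled over decades hold samples extracted either
from whole blood or from EBV-immortalised lymphoblastoid cell lines, and the
recorded tissue of origin is often dated, uncertain or missing. The
distinction matters: LCL methylomes and transcriptomes drift during
immortalisation and culture, so blood DNA should be preferred for epigenomic
work whenever it exists. This package implements, end to end, a qPCR-based
quality-control test that resolves the origin of a DNA sample from three
genetic features, together with the downstream evaluation machinery and a
synthetic cohort generator for testing:

* **EBV relative load** — LCLs carry 2–500 episomal EBV genome copies per
  diploid genome equivalent; healthy blood carries essentially none.
* **Rearranged TCRγ** — V(D)J-rearranged T-cell-receptor-γ templates exist
  only in the T-cell fraction of blood; LCLs are B-cell derived.
* **TCRβ melting temperature** — the multiplexed TCRβ rearrangement PCR
  produces primer dimers in every sample, so its Ct is uninformative;
  instead the highest melting peak Tm is thresholded at 89.5 °C, above which
  only specific blood-derived products melt.

## The method

Cts are called from raw amplification curves by the second-derivative-maximum
method (the Ct is the cycle at which the curvature of the fluorescence trace
peaks); melting peaks are maxima of −dF/dT. Assays that do not amplify are
imputed at Ct 40 (EBV) and Ct 45 (TCRγ). With GAPDH as single-copy input
control, the decision statistics are

    r_EBV  = 100 · Ct_GAPDH / Ct_EBV      r_TCRγ = 100 · Ct_GAPDH / Ct_TCRγ

Each assay yields a three-way label with an abstention band:
r_EBV < 91 → blood, r_EBV > 110 → LCL, between → uncertain; the TCRγ rule
mirrors it (high ratio → blood); TCRβ max-Tm > 89.5 °C → blood, else LCL.
The combined call is a two-of-three vote: ≥ 2 blood votes → blood, else
≥ 2 LCL votes → LCL, else uncertain. Diagnostic metrics follow the
convention that a blood call is the positive outcome and LCL or uncertain
calls are negative:

    sens = TP/(TP+FN)   spec = TN/(TN+FP)   PPV = TP/(TP+FP)
    NPV  = TN/(TN+FN)   accuracy = (TP+TN)/n

The epigenetic clock is the published affine model on percent methylation at
three CpGs,

    predicted age = −20.372 + 0.830·ELOVL2(CpG5) + 1.723·KLF14(CpG2) + 0.715·TRIM59(CpG5),

evaluated per tissue group by the mean absolute deviation (MAD, years) from
chronological age and the Pearson correlation R.

## Worked example

```python
from bloodlcl import (CohortConfig, generate_cohort, classify_samples,
                      evaluate_binary, evaluate_predictions, predict_age)

cohort = generate_cohort(CohortConfig(n_blood=50, n_lcl=50, seed=7))
calls, panels = classify_samples(cohort)
truth = {s.truth.sample_id: s.truth.tissue for s in cohort}
ev = evaluate_binary([c.combined for c in calls], [truth[c.sample_id] for c in calls])
print(ev.summary("combined"))

c = calls[0]
print(f"{c.sample_id}: EBV ratio {c.ebv_ratio:.1f} ({c.label_ebv}), "
      f"TCRg ratio {c.tcrg_ratio:.1f} ({c.label_tcrg}), "
      f"max Tm {c.tcrb_max_tm:.1f} C ({c.label_tcrb}) -> {c.combined}")

for tissue, e in evaluate_predictions([s.methylation for s in cohort]).items():
    print(f"age model [{tissue}]: n={e.n} MAD={e.mad:.1f} y, Pearson R={e.pearson_r:.2f}")

print(f"predicted age at (60, 20, 40)% methylation: {predict_age(60, 20, 40):.3f} y")
```

prints

```
combined: sensitivity 100.0% | specificity 100.0% | PPV 100.0% | NPV 100.0% | accuracy 1.000 (tp=50 fp=0 tn=50 fn=0)
B0001: EBV ratio 63.2 (blood), TCRg ratio 90.8 (blood), max Tm 90.8 C (blood) -> blood
age model [blood]: n=50 MAD=4.6 y, Pearson R=0.95
age model [LCL]: n=50 MAD=24.3 y, Pearson R=-0.21
predicted age at (60, 20, 40)% methylation: 92.488 y
```

The first line scores the combined two-of-three call on a default synthetic
cohort of 50 blood + 50 LCL samples: every sample is recovered, so all five
metrics are at their ceiling. The per-sample line shows the three decision
statistics behind one blood call: an EBV ratio of 63.2 (no EBV
amplification, Ct imputed at 40), a TCRγ ratio of 90.8 (rearranged TCRγ
amplified), and a melting peak above 89.5 °C — three blood votes. The age
model tracks chronological age closely in blood (MAD 4.6 years, R 0.95) but
not in LCLs (MAD 24.3 years, R −0.21), the signature of methylation
disruption in immortalised lines.

The same pipeline is available from the shell:

```sh
bloodlcl run-all --n-blood 50 --n-lcl 50 --seed 7 --out-dir out/
bloodlcl simulate --n-blood 20 --n-lcl 20 --seed 1 --out-dir cohort/
bloodlcl call --curves cohort/curves.csv --out cohort/panels.csv
bloodlcl classify --panels cohort/panels.csv --out cohort/calls.csv
bloodlcl evaluate --calls cohort/calls.csv --truth cohort/truth.csv --out-prefix cohort/eval
bloodlcl age --methylation cohort/methylation.csv --out-prefix cohort/age
```

Every output table carries a versioned schema header, a resolved copy of the
configuration is written next to the outputs, and a fixed seed makes the
whole run byte-identical.

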