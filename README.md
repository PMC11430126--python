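# recombrisk

Quantitative prediction of excess relative cancer risk (ERR) from two
cellular assays on skin fibroblasts: the rate of DNA hyper-recombination
(H, pTPSN plasmid assay) and the degree of G2/M checkpoint escape after a
2 Gy X-ray challenge (G, flow cytometry). Fibroblast lines from eight
hereditary cancer syndromes span ERR values from 0.4 (BRCA1) to 9 (ataxia
telangiectasia); healthy controls anchor ERR = 0.

The package is aimed at radiobiology/biostatistics groups who want to run
the full analysis on their own assay tables — or on synthetic panels when
raw data are unavailable — rather than re-derive it from figure captions.

## The models

Hyper-recombination follows a constrained cubic in ERR, the solution of a
growth law with a quadratic "brake" from nuclear ATM monomers:

```
dH/dERR = k0 − k1·ERR·(ERRmax − ERR),   H(0) = 0,   k0 = k1·ERRmax²/4
H(ERR)  = (k1/3)·ERR³ − (k1·ERRmax/2)·ERR² + (k1·ERRmax²/4)·ERR
```

G2/M escape follows a logistic law bounded between Gmin and Gmax:

```
dG/dERR = c0·G·(1 − G/Gmax),   G(0) = Gmin
G(ERR)  = Gmax / (1 + (Gmax/Gmin − 1)·e^(−c0·ERR))
```

Calibrated defaults: k1 = 0.9, ERRmax = 10.28 (hence k0 = 23.78);
c0 = 0.5473, Gmax = 10.98, Gmin = 0.8655. The composite H×G (percent
convention: percent×percent/100) is approximately linear in ERR
(y = −0.3 + 0.623·x) and is inverted — exactly through the monotone
composite, or through the linear calibration — to predict ERR per line.
See `docs/methods.md` for assumptions, fitting details and limitations.

## Worked example

Generate a synthetic nine-syndrome panel (3 replicates/assay, SEM-scale
noise, seed 11) and run the pipeline:

```
$ recombrisk simulate --seed 11 --out demo_panel.csv
$ recombrisk run demo_panel.csv --out demo_report
   line_id syndrome  hg_percent  predicted_err  reference_err note
      1BR3  CONTROL    0.006312       0.030386            0.0
    202CLB    BRCA1    0.094127       0.404700            0.4
    201CLB    BRCA2    0.305035       1.083782            1.0
   GM00369     FANC    0.444033       1.439584            1.4
   GM02520      BLM    0.979224       2.511047            2.4
   GM02718       RB    1.427090       3.245976            3.2
Rackham 37      NF1    1.659828       3.606613            3.6
   GM07166      NBS    3.496914       6.629921            7.0
     AT4BI       AT    5.861688       8.994975            9.0
```

`hg_percent` is the measured composite for each line; `predicted_err`
inverts the mechanistic composite and lands within ~0.4 ERR units of the
reference for every syndrome at this noise level. `demo_report/report.json`
also carries the fitted models — for this panel the constrained cubic
recovers k1 = 0.855, ERRmax = 10.55 (truth 0.9, 10.28), the logistic
recovers (c0, Gmax, Gmin) = (0.554, 10.65, 0.862), and the composite
calibration line is y = −0.351 + 0.623·x with r = 0.984 — plus the
correlation screens (FDR vs ERR: not significant, as expected from its
scatter-dominated weak trend).

The same works in Python:

```python
from recombrisk import GeneratorConfig, make_panel, run_pipeline, compare_to_reference

records, truth = make_panel(GeneratorConfig(seed=11))
report = run_pipeline(records)
print(compare_to_reference(report, truth).r)   # 0.9992
```

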