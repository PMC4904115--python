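# uhrconvert

Psychometric machinery for the ultra-high-risk (UHR) psychosis
diagnostic interview: rule engines for the **CAARMS 12/2006** and
**SIPS 5.0** criteria, individual-case **conversion** between the two
instruments, the **agreement statistics** used to compare them, and
**equipercentile linking** of their severity/frequency scales.

Clinical services and research consortia identify people at risk of
psychosis with one of two semi-structured interviews whose criteria
(attenuated psychotic symptoms, brief limited intermittent psychotic
symptoms, genetic risk and deterioration, and the psychosis threshold
itself) are similar but operationalized differently: the CAARMS caps
brief psychotic episodes at 7 days where the SIPS allows 3 months, the
SIPS rules any seriously disorganizing or dangerous psychotic symptom
over threshold (urgency), the functioning-decline gate exists only in
the CAARMS, the comorbidity exclusion only in the SIPS, and perceptual
abnormalities at severity 5 are psychotic under one and attenuated
under the other. `uhrconvert` makes both rule sets executable,
converts cases across them, and quantifies their agreement — for
psychometricians harmonizing multi-site UHR cohorts and for services
switching or comparing instruments.

## The statistics at the core

For two instruments rated on the same N subjects, cross-tabulated into
a k×k table with observed diagonal proportion P_o and chance agreement
P_e = Σ p_i·p_·i:

- Cohen's kappa  κ = (P_o − P_e)/(1 − P_e), with the null-SE Z test and
  CI  κ ± 1.96·SE₀, and weighted variants  κ_w with weights
  w_ij = 1 − |s_i − s_j|/range(s);
- PABAK = (k·P_o − 1)/(k − 1), correcting for prevalence and bias;
- McNemar–Bowker symmetry  χ² = Σ_{i<j} (n_ij − n_ji)²/(n_ij + n_ji);
- adjusted residuals  r_ij = (n_ij − e_ij)/√(e_ij(1−p_i·)(1−p_·j)),
  significant beyond ±3.29;
- conversion accuracy: sensitivity, specificity, ROC area
  (sens + spec)/2;
- equipercentile linking  e(x) = Q_Y(P_X(x)) with the ±0.5
  uniform-kernel continuization of discrete score distributions.

## Worked example

Recompute the agreement between the two instruments from a published
3×3 diagnostic crosstab (rows CAARMS, columns SIPS; N = 212):

```python
from uhrconvert import ContingencyTable, cohen_kappa, bowker_test, adjusted_residuals

table = ContingencyTable(
    ("UHR-", "UHR+", "Psychosis"),
    [[51, 0, 0], [5, 92, 14], [1, 9, 40]],
)
print(cohen_kappa(table).summary())
chi2, df, p = bowker_test(table)
print(f"Bowker chi2          {chi2:.3f} (df={df}, p={p:.3f})")
print(f"min expected count   {adjusted_residuals(table).min_expected:.2f}")
```

prints

```
observed agreement   86.32%
chance agreement     37.42%
kappa                0.781
SE0 (null)           0.0494
Z                    15.83
p                    2e-56
95% CI               0.685 to 0.878
PABAK                0.795
Bowker chi2          7.087 (df=3, p=0.069)
min expected count   12.74
```

The two instruments agree on 86% of subjects — far above the 37%
expected by chance — for a substantial κ of 0.781; the Bowker test
finds no significant marginal asymmetry (p = 0.069), and the smallest
independence-model expected count (12.74) licenses the chi-square
approximations.

The same works end to end from the shell, on a synthetic dual-rated
cohort with study-like discordance mechanisms injected:

```sh
uhrconvert simulate --n 212 --seed 1 --preset table3 --out cohort.csv
uhrconvert agree cohort.csv
uhrconvert validate cohort.csv --direction caarms2sips
```

```
observed agreement   83.96%
chance agreement     38.26%
kappa                0.740
...
sensitivity          100.00%
specificity          100.00%
roc_area             1.000
```

Here `agree` rates every subject with both rule engines and
cross-tabulates the outcomes (κ = 0.74 under the injected discordance
prevalences), while `validate` checks the conversion engine's
predictions against the direct target-instrument classification —
conversion is exact because every rule difference between the
instruments is carried by the crosswalk. Per-subject classification
(`classify`), conversion tables (`convert`) and equipercentile linking
tables (`link`) are also available; see `uhrconvert --help`.

```python
from uhrconvert import classify_caarms, classify_sips, caarms_to_sips
result = classify_caarms(subject)        # DiagnosticResult with rule trace
print(result.primary_outcome, result.subgroups_met)
print(caarms_to_sips(subject).predicted.fine_label)
```

## Layout

- `src/uhrconvert/instruments.py` — domain types, validation,
  functioning criteria
- `src/uhrconvert/caarms.py`, `sips.py` — the two diagnostic rule
  engines
- `src/uhrconvert/convert.py` — cross-instrument conversion
- `src/uhrconvert/agreement.py` — kappa family, Bowker, residuals,
  accuracy
- `src/uhrconvert/linking.py` — equipercentile linking
- `src/uhrconvert/simulate.py` — synthetic dual-instrument cohorts
- `src/uhrconvert/io.py`, `cli.py` — cohort CSV schema and the
  `uhrconvert` command

See `docs/methods.md` for the operationalization choices and their
rationale.
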