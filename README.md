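# qstrtox

Quantitative structure–toxicity relationship (QSTR) modeling of carbamate
pesticides: a reusable pipeline for computing the molecular descriptors of a
published ten-variable acute-toxicity model, fitting and validating
multi-linear regression models, and delimiting the model's applicability
domain.

Carbamates (the O–C(=O)–N ester/amide family of carbamic acid) are
broad-spectrum insecticides whose acute toxicity stems from carbamylation of
acetylcholinesterase. The modeled endpoint is oral-rat acute toxicity:
LD₅₀ values in mg/kg are converted to the molar-scale response

```
log(1/C) = -log10( LD50[mg/kg] / MW[g/mol] )        (C in mmol/kg)
```

and regressed on ten descriptors:

```
log(1/C) = b0 + b1·EA + b2·qC + b3·LOC + b4·SpPosA_RG + b5·H4m
              + b6·nCt + b7·nROCON + b8·B05[C-N] + b9·B05[N-O] + b10·DLS_05
```

| family | descriptors |
|---|---|
| electronic (ingested from external DFT output) | EA (electron affinity, eV), qC (Hirshfeld charge of the carbamate carbonyl carbon, e) |
| topological | LOC (lopping centric index), nCt (tertiary sp³ carbons), B05[C-N] / B05[N-O] (element pair at exactly five bonds), nROCON (aliphatic substituent on the carbamate sp³ oxygen) |
| geometric (need 3D input) | SpPosA_RG (normalised positive spectral sum of the reciprocal squared geometry matrix), H4m (GETAWAY lag-4 H autocorrelation, mass-weighted) |
| drug-likeness | DLS_05 (two-rule score from the heteroatom ratio nNO/nC3 and the unsaturation ratio Unsat-p) |

The published coefficients are bundled as the frozen constant
`qstrtox.PUBLISHED_MODEL`. Validation follows standard QSAR practice:
R², leave-one-out Q² (acceptable when Q²_LOO > 0.5), five-fold
cross-validation, and a leverage applicability domain with cutoff
h\* = 3(p+1)/n visualised as a Williams plot. Descriptor subsets are
selected with a genetic algorithm after a correlation pre-filter
(|r| > 0.90).

Conceptual-DFT indices (ionisation potential, electron affinity, chemical
potential μ, hardness η, electrophilicity ω) are derived from frontier
orbital energies by the Koopmans approximation; the quantum-chemical
calculations themselves are external and ingested as CSV data.

## Worked example

Predict the toxicity of the bundled worked-example compounds with the
published model:

```python
import numpy as np
from qstrtox import PUBLISHED_MODEL, predict, gen_table1_fixture

table, y, labels = gen_table1_fixture()   # 11 compounds, 10 descriptors
pred = predict(PUBLISHED_MODEL, table)
print(np.sqrt(np.mean((y - pred) ** 2)))
```

or from the shell (`qstr predict --published --descriptors table1.csv`):

```
RMSE vs experimental: 0.3406 over 11 compounds
        id  predicted_log_inv_c  log_inv_c  residual
0000126523            -0.626512   -0.29657  0.329942
0000886748            -0.798173   -0.48124  0.316933
...
0053380237            -0.282907   -0.29370 -0.010793
```

A predicted log(1/C) of −0.63 for compound 0000126523 means a lethal dose of
about 4.2 mmol/kg; the residual RMSE of 0.34 log units is well inside the
model's error band. Fitting a fresh model on a simulated study-sized data
set (`qstr simulate --preset paper-regime --seed 1` followed by `qstr fit`)
prints the full coefficient table with standardized coefficients, 95%
confidence half-widths and p-values:

```
n = 152   R2 = 0.6650   Q2_LOO = 0.6158   RMSE = 0.4668   MAE = 0.3661
variable           coeff   std coeff   conf int 95     p-value
EA                0.2396      0.3164        0.0986   3.881e-06
...
5-fold CV: R2 0.6032  RMSE 0.4983  MAE 0.3927
```

Q²_LOO = 0.616 > 0.5, so the fitted model passes the internal-validation
acceptability rule. `qstr ad` writes the Williams-plot table (leverage,
standardized residual, in-domain and outlier flags per compound).

## Layout

- `qstrtox.molecule_io` — SMILES/SDF parsing, hydrogen-depleted graphs, log(1/C)
- `qstrtox.descriptors` — the eight structural/topological/geometric descriptors
- `qstrtox.electronic` — conceptual-DFT indices, electronic-data ingestion
- `qstrtox.modeling` — prefilter, OLS, Q²_LOO, k-fold CV, GA selection, leverage/Williams
- `qstrtox.synthetic_data` — simulator, hand-authored molecule fixtures, worked-example table
- `qstrtox.cli` — the `qstr` command

See `docs/methods.md` for modeling conventions, parameter choices and
limitations.
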