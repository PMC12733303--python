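# cytoqsar

Quantitative prediction of cell-line cytotoxicity (pIC50 / pGI50) from
chemical structure, for preclinical toxicology and drug-candidate triage.
The package covers the full workflow a modeller needs when building
per-cell-line QSAR panels from public bioactivity data:

1. **Structure curation** — parse SMILES/MOL records; remove mixtures,
   net-charged species, inorganics, and compounds above 1250 Da; derive a
   canonical structure identity for duplicate detection.
2. **Activity curation** — convert IC50/GI50 concentrations to the p-scale
   (p = −log10 of the molar concentration, so 10 µM → 5), consolidate
   replicate measurements by the median, and keep a cell line only when it
   has more than 100 unique curated compounds.
3. **Descriptors** — multilevel atom-neighborhood strings (canonical
   recursive encodings of each atom's bonded environment), quantitative
   atom-neighborhood values (per-atom (P, Q) pairs from tabulated ionization
   potentials and electron affinities propagated through exp(−C/2) of the
   adjacency matrix), and ten whole-molecule properties.
4. **Model engine** — self-consistent-regression variable selection (ridge
   + backward elimination scored by closed-form leave-one-out Q²) feeding a
   Gaussian radial-basis-function network.
5. **Consensus + applicability domain** — an ensemble of (by default) 320
   configuration variants; models with R², Q², and internal leave-many-out
   R² all above 0.5 are averaged into a consensus. Every prediction carries
   a three-method applicability-domain verdict (similarity ≥ 0.70 Tanimoto
   to a training compound, leverage below 3(p+1)/n, and nearest-3-neighbor
   deviation within the model's cross-validated RMSE); one "out" flags the
   whole prediction.
6. **Validation** — R² = 1 − Σ(y_exp−y_pred)²/Σ(y_exp−ȳ)² and
   RMSE = √(Σ(y_exp−y_pred)²/n), leave-one-out Q², and 5-fold
   cross-validation with full per-fold pipeline refits; final models must
   pass R²_5-fold > 0.5 and RMSE_5-fold < 1.
7. **Panel profiling** — per-cell-line predictions for a query compound,
   non-tumor vs tumor group means, and the therapeutic index
   TI = 10^(mean_tumor − mean_non-tumor).

A synthetic-data module generates structure–activity sets with known
additive fragment contributions, so the whole pipeline is testable without
downloading anything.

## Worked example

The bundled reference panel holds per-cell-line predictions for three
anticancer drugs over 11 non-tumor and 11 tumor cell-line models:

```python
from cytoqsar.reference import example_panel_report
from cytoqsar.panel import classify_ti

report = example_panel_report("paclitaxel")
delta, ti = report.therapeutic_index
print(f"non-tumor mean {report.mean_non_tumor:.3f}")
print(f"tumor mean     {report.mean_tumor:.3f}")
print(f"delta {delta:.3f} log units -> TI {ti:.1f} ({classify_ti(ti)})")
```

prints

```
non-tumor mean 6.889
tumor mean     7.503
delta 0.613 log units -> TI 4.1 (intermediate)
```

Paclitaxel is on average ~4× more cytotoxic to the tumor panel than to the
non-tumor panel — a modest therapeutic window. The same computation gives
TI 4.3 for trametinib and 6.2 for dabrafenib (the latter crossing the
TI > 5 "drug-candidate" advisory cutoff).

An end-to-end run on synthetic data:

```bash
cytoqsar synth --n 300 --sigma 0.2 --seed 1 --out work/data
cytoqsar train work/data/activity.csv --min-compounds 100 \
         --n-variants 16 --seed 1 --out work/bundle
cytoqsar validate work/data/activity.csv --min-compounds 100 \
         --n-variants 16 --seed 1 --out work/val --bundle work/bundle
cytoqsar predict work/bundle --smiles "Oc1ccc(Cl)cn1" --out work/pred
```

`validate` writes a summary CSV with the pooled 5-fold R²/RMSE and whether
the model passes the final acceptance filter; `predict` writes a CSV with
columns `cell_line, type, value, AD` plus the per-method domain flags.

## Layout

| module | role |
| --- | --- |
| `cytoqsar.chem` | structure parsing, curation filters, canonical identity |
| `cytoqsar.activity` | p-scale conversion, median consolidation, training sets |
| `cytoqsar.descriptors` | descriptor families and matrix assembly |
| `cytoqsar.engine` | variable selection + RBF regression, one model |
| `cytoqsar.consensus` | variant ensemble, selection, consensus, AD |
| `cytoqsar.validation` | metrics, LOO/LMO/k-fold protocols, acceptance filter |
| `cytoqsar.panel` | multi-cell-line profiles and therapeutic index |
| `cytoqsar.synth` | synthetic structure–activity generator |
| `cytoqsar.bundle` | JSON model-bundle serialization |
| `cytoqsar.cli` | `cytoqsar` command-line interface |

See `docs/methods.md` for the modelling details and design choices.
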