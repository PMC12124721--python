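# fluoroqspr

Measurement reduction and descriptor-regression modeling of lipophilicity
(logD at pH 7.4) and basicity (conjugate-acid pKa) for a library of 22
2-(thio/sulfonyl-fluoroalkyl)pyridines.

The package implements the full computational chain:

1. **compound_library** — the 22 compounds as a packaged CSV fixture
   (SMILES, series, sulfur oxidation state, experimental logD/pKa where
   measured), structure parsing (RDKit), fluorine counting (`#F`) and
   constitutional descriptors including a fragment-contribution TPSA
   restricted to the library's atom environments.
2. **nmr_reduction** — shake-flask ¹⁹F NMR logD from per-phase
   analyte/internal-standard integral ratios (double-ratio formula),
   HPLC-UV logD from aqueous-phase depletion with volume correction, and
   pKa from (pH, chemical-shift) titrations via a Henderson–Hasselbalch
   sigmoid fit plus a model-free second-derivative estimate.
3. **descriptor_engine** — descriptor-table assembly (constitutional +
   ingested DFT CSV columns), transform expansion {1/x, x², 1/x², log x}
   applied only where valid for every compound, and min–max scaling to
   [0, 1] with stored (min, max) for prediction-time reuse.
4. **model_search** — exhaustive enumeration of all 1- and 2-descriptor
   OLS models (d + d(d−1)/2 fits), in-sample R²/MAE/RMSE, ranking and
   tie-broken best-model selection, prediction with extrapolation
   flagging, and Pearson correlation utilities.
5. **synthetic_data** — seeded generators for descriptor tables with
   planted linear laws, partition integrals and titration series, so every
   stage is testable offline with known ground truth.

## CLI

```bash
fluoroqspr describe --out descriptors.csv
fluoroqspr descriptors --dft si_descriptors.csv --scale --out table.csv
fluoroqspr logd-nmr --partitions p.csv --standards s.csv --out logd.csv
fluoroqspr pka-fit --titrations t.csv --method sigmoid
fluoroqspr model-search --table table.csv --response response --best-out best.json
fluoroqspr predict --model best.json --table table.csv --ids 21,22
fluoroqspr simulate descriptors --seed 1 --out sim/
```

Input CSV dialects: header row, compound id in the first column, `.`
decimal separator. Partition CSV columns:
`compound_id,replicate,phase,analyte_integral,standard_integral` (phase is
`oct` or `aq`) plus a standards CSV `standard_name,logd`. Titration CSV:
`compound_id,pH,shift_ppm,nucleus`.

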