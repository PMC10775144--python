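# capsidms

A Python toolkit for HILIC-FLR-MS analysis of AAV (adeno-associated virus)
capsid proteins: rapid serotype identity testing, VP stoichiometry, and
post-translational modification (PTM) monitoring at both the intact-protein
and peptide level.

## What it does

- **Component libraries** (`capsidms.capsid_model`): define a serotype by its
  VP1 sequence plus VP2/VP3/variant start positions, derive chain sequences
  with N-terminal Met excision + acetylation rules, and build proteoform
  target lists with theoretical average masses and retention-time windows
  (±1.00 min for VP3-class chains, ±0.60 min for VP1/VP2). Theoretical masses
  can be pinned per VP from a curated mass table.
- **Mass arithmetic** (`capsidms.masscalc`): average/monoisotopic chain
  masses, PTM deltas, N-terminal truncations, ppm mass errors.
- **Spectrum processing** (`capsidms.spectra`): MS1 input as minimal mzML or a
  plain CSV spectrum-table dialect (`rt_min,mz,intensity`), greedy
  charge-ladder deconvolution to neutral masses (10 ppm merge tolerance,
  13.00–28.50 min window, ≥10 supporting measurements by default), XIC
  extraction, and valley-to-valley chromatographic peak integration.
- **Identity testing** (`capsidms.identity`, `capsidms.workflows`): match
  deconvolved features to the component library by RT window and mass
  tolerance (the most intense in-window feature wins), form triplicate
  consensus (present in all runs with score ≥60), and call the serotype —
  requiring its full unmodified VP1/VP2/VP3 set and flagging any
  cross-serotype matches.
- **Stoichiometry** (`capsidms.stoichiometry`): VP copies (of 60) and ratios
  (of 12) from FLR peak areas or per-VP summed proteoform XIC areas, with
  replicate averaging and CV%.
- **Peptide PTM quantitation** (`capsidms.ptm_quant`): confidence/area/ppm
  filtering, site-level relative abundance with replicate mean ± SD,
  mobile-proton classification, sequence coverage.
- **Synthetic data** (`capsidms.synth`): seeded, fully deterministic
  HILIC-FLR-MS run and peptide-table simulators with closed-form ground
  truth, so the entire pipeline is testable without instrument data.

## CLI

```bash
# build a component library from serotype definitions
capsidms library build --definitions defs.yaml --specs specs.yaml \
    --rt-calibration cal.yaml --out lib.yaml

# simulate a synthetic run (CSV or mzML)
capsidms simulate --config sim.yaml --out-dir run1/

# rapid identity testing over replicate injections
capsidms identify --runs r1.csv --runs r2.csv --runs r3.csv \
    --library lib.yaml --out report.json

# serotype-specific PTM monitoring over the same runs
capsidms ptm-monitor --runs r1.csv --runs r2.csv --runs r3.csv \
    --library lib.yaml --serotype AAV2 --out ptm.json

# VP stoichiometry from a peaks table (replicate,label,area)
capsidms stoich --method flr --peaks peaks.csv --out stoich.json

# peptide-level PTM quantitation
capsidms ptm-quant --records records.csv --sequence vp1.fasta --out ptm.csv
```

All reports are deterministic JSON (stable key order) embedding the full
parameter snapshot and tool version.

## Layout

```
src/capsidms/
  capsid_model.py   serotype definitions, VP derivation, component libraries
  masscalc.py       residue/PTM mass arithmetic and ppm errors
  spectra.py        MS1 + chromatogram I/O, deconvolution, XIC, peaks
  identity.py       component matching, replicate consensus, serotype calls
  stoichiometry.py  VP copies/ratios from FLR or MS areas
  ptm_quant.py      peptide filtering and site-level PTM abundance
  synth.py          seeded synthetic runs and peptide tables
  workflows.py      identity / PTM-monitor orchestration and reports
  cli.py            click-based command line
tests/              pytest suite (unit, property-based, acceptance)
scripts/acceptance.py
```
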