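# cysexpose

Quantification of cysteine solvent exposure by differential isotopic
alkylation and mass spectrometry, with the surrounding analysis stack:
peptide/label mass arithmetic, XIC-based exposure fractions, a comparative
cysteine survey, plate-reader enzyme kinetics, and a four-pool
active/deactive/alkylation state model. Every pipeline input can be
generated synthetically with known ground truth, so the full workflow is
testable offline.

## Modules

| Module | What it does |
| --- | --- |
| `cysexpose.peptide_chem` | Elemental compositions, isotope-coded thiol labels (light/heavy IAM, NEM/d5-NEM, TPP-IAM/d15-TPP-IAM, MMTS), tryptic digestion, precursor/fragment m/z, MRM transition lists |
| `cysexpose.exposure_quant` | XIC integration, channel proportions, labeling-scheme resolution (two-label, MMTS block-and-replace, three-label gel scheme), standard curves |
| `cysexpose.cys_survey` | Conservation mapping from alignments, tryptic-peptide detectability rules, Shrake–Rupley gamma-S SASA with a 5 Å² exposed/occluded cutoff, survey summary statistics |
| `cysexpose.kinetics` | NADH/dQ rates (ε340−380 = 4.81 mM⁻¹cm⁻¹), rotenone-sensitive fractions, reactivation lags, citrate synthase (ε412), Amplex Red H₂O₂ with standard curve (ε240), GSH–IAM labeling kinetics |
| `cysexpose.ad_analysis` | Exact-exponential simulator of the A/D/alkylated pools, activity mapping, activity–exposure regression with confidence band, binary-model deviation |
| `cysexpose.synthetic_data` | Seeded, byte-reproducible generators for peak tables, chromatograms, absorbance plates, toy complexes (FASTA + alignments + PDB pairs), GSH and Amplex time courses |

Conventions worth knowing:

* m/z is `(M + z × 1.00728)/z` from an embedded monoisotopic mass table.
  The TPP adduct is treated as a neutral composition delta and protonated
  like any other label (this reproduces reference tables; the strict
  cation convention does not).
* "Exposed" in the survey means SASA strictly greater than the cutoff;
  residues unmodeled in the deactive structure count as exposed
  (disordered-loop convention).
* Rates are reported positive in the assay direction (consumption for
  NADH, production for TNB²⁻/resorufin).

## CLI

All functionality is exposed through the `cysexpose` entry point:

```bash
cysexpose masses --sequence TSPYECGFDPMGSAR --labels IAM-light,IAM-heavy --charge 2,3
cysexpose digest --fasta proteins.fasta --missed-cleavages 1
cysexpose transitions --sequence ANPYECGFDPTSSAR --fragment y:13:2
cysexpose xic chromatogram.csv --mz 836.357 --tol-ppm 10
cysexpose exposure peak_areas.csv --scheme two-label
cysexpose survey --reference-fasta ref.fasta --alignment A=aln_A.fasta \
    --reference-species sp0 --structures active=6g2j.pdb,deactive=6g72.pdb \
    --annotations annotations.csv --summary-out summary.json
cysexpose rates plate.csv --assay nadh-dq --window 10
cysexpose simulate-ad --protocol protocol.json --k-d 0.1 --k-a 0.3
cysexpose simulate --what complex --seed 7 --outdir synthetic/
```

Peak-area CSVs need columns `species_id, channel, replicate, area`;
chromatograms `rt_min, mz, intensity`; plates `condition, time_s, a340,
a380[, path_cm, replicate]`.

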