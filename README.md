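# psnstrat

Patient stratification from symptom-coded inpatient EMR records:

1. **curation** — normalize free-text-derived terms against a dictionary,
   roll up ICD codes, and apply inclusion/exclusion rules (complete
   records only; one most-complete admission per patient).
2. **psn** — build a shared-symptom patient similarity network: Jaccard
   similarity on chief-complaint symptoms thresholded at 0.8, intersected
   with the general-symptom network whose similarities become the edge
   weights.
3. **communities** — detect patient subgroups by greedy weighted-modularity
   maximization (Louvain, implemented here) or an overlapping
   cluster-affiliation cover (BigClam-style likelihood ascent, implemented
   here).
4. **enrichment** — characterize each subgroup by relative-risk enrichment
   of symptoms, tongue/pulse findings, diagnoses, and herbs, screened by a
   Pearson chi-square test (RR > 1, p < 0.05).
5. **efficacy** — rank per-subgroup symptom resolution between admission
   and discharge, and bundle it with the significant features into module
   profiles.
6. **synthetic** — generate cohorts with planted subgroups, herb
   signatures, resolution probabilities, synonym noise, duplicate
   admissions, and missing records, plus ground-truth labels for recovery
   experiments.

## CLI

```bash
# generate a synthetic cohort (records.csv, dictionary.tsv, truth_labels.tsv)
psnstrat simulate --seed 7 --n-patients 1000 --out data/

# stage by stage
psnstrat curate    --records data/records.csv --dictionary data/dictionary.tsv --out run/
psnstrat build-psn --records data/records.csv --dictionary data/dictionary.tsv --out run/
psnstrat detect    --edgelist run/psn_edgelist.txt --seed 7 --out run/
psnstrat enrich    --records data/records.csv --dictionary data/dictionary.tsv \
                   --edgelist run/psn_edgelist.txt --partition run/partition.tsv --out run/
psnstrat efficacy  --records data/records.csv --dictionary data/dictionary.tsv \
                   --edgelist run/psn_edgelist.txt --partition run/partition.tsv --out run/
psnstrat profile   --records data/records.csv --dictionary data/dictionary.tsv \
                   --edgelist run/psn_edgelist.txt --partition run/partition.tsv \
                   --module 0 --out run/profile_m0.json

# or everything at once from a YAML config
psnstrat run-all --config config.yaml --seed 7
```

A minimal config:

```yaml
seed: 7
output_dir: run
input:
  simulate:          # or: records: path.csv / dictionary: path.tsv
    n_patients: 1000
psn:
  main_threshold: 0.8
enrichment:
  alpha: 0.05
profiles:
  top_modules: 3
```

`run-all` writes every artifact as plain text (CSV/TSV/JSON/GraphML) plus
a `manifest.json` with the config snapshot, per-stage timings, and SHA-256
digests; identical config + seed reproduces identical digests.

## File formats

- records: CSV with `|`-joined list fields, or JSON lines with arrays;
  columns `patient_id, admission_id, admission_date, age, sex,
  main_symptoms, general_symptoms, tongue_features, pulse_features,
  tcm_diagnoses, icd_codes, herbs, discharge_symptoms, outcome`.
- term dictionary: TSV `raw_term<TAB>canonical_term<TAB>feature_class`
  with feature classes `symptom|tongue|pulse|diagnosis|herb`.
- networks: GraphML and a 3-column `u v weight` edge list.
- partitions and truth labels: 2-column TSV.
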