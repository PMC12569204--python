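# methcal

Two quantitative assay pipelines with matching synthetic-data generators:

1. **Methylation-fraction estimation** from methylation-sensitive
   restriction-digestion qPCR. Parallel digests (methylation-sensitive
   enzyme, methylation-insensitive isoschizomer, carrier enzyme only) are
   compared by relative amplification `R = E^-(Ct_digest - Ct_control)`;
   `R` is calibrated against a least-squares standard curve of known
   methylation fractions and inverted, with a digestion-completeness QC on
   the insensitive digest. A comparative-Ct (ΔΔCt) helper for expression
   data is included.
2. **Calcium-transient detection** on ROI fluorescence time series:
   ΔF/F₀ normalization against the lower 5th-percentile baseline, candidate
   detection on a three-difference pattern (positive, non-positive,
   negative), a dynamic threshold `max(2 × MAD, 0.1)`, de-duplication of
   candidates not separated by a sub-threshold dip, and per-cell activity
   rates (events/min; silent cells flagged excluded).

The `synthetic` module simulates both assays with known ground truth
(allele-dosage Ct tables; Poisson-onset transient traces), so the full
pipelines are testable end to end with no external data.

## CLI

```bash
# simulate an assay (spec is a small YAML file; see tests/test_cli.py)
methcal --seed 1 simulate --arm meth    --spec spec.yaml --out out/
methcal --seed 1 simulate --arm calcium --spec spec.yaml --out out/

# methylation fractions from Ct tables (CSV: sample_id,condition,replicate,ct;
# calibration additionally has known_fraction; empty ct = no amplification)
methcal methfrac --calibration out/calibration.csv --samples out/samples.csv --out est/

# transient detection on a trace matrix (first column time, one ROI per column)
methcal calcium --traces out/traces.csv --interval 1.0 --out act/ [--plot]
```

Every run writes its result CSVs plus a `report.json` echoing the full
parameter set, package version and seed. Sample indices in outputs are
0-based.

## Library

```python
from methcal.synthetic import AlleleConfig, DigestionSimSpec, CalciumSimSpec
from methcal.workflows import simulate_and_estimate, session_detection_scores
from methcal.calcium import detect_events, DetectionParams
```

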