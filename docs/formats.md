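# File formats

## AEP record XML dialect

One file holds an ordered collection of evoked-potential records:

```xml
<?xml version="1.0" encoding="utf-8"?>
<aep_records>
  <record id="p0001-left-abr" patient="p0001" ear="left"
          subtype="ABR" fs_hz="30000.0">
    <stimulus type="click" rate_hz="22.0" intensity_db_nhl="80.0"
              highpass_hz="33.0" lowpass_hz="1500.0"/>
    <samples unit="uV">0.0123 -0.0456 0.0789 ...</samples>
  </record>
  ...
</aep_records>
```

* `id`, `patient` — opaque identifiers; `id` must be unique per file.
* `ear` — `left` | `right`; `subtype` — `ABR` | `AMLR`.
* `fs_hz` — sampling rate in Hz; the stimulus occurs at sample index 0 and
  the latency of sample *k* is `k / fs_hz × 1000` ms.
* `<stimulus>` is optional; when absent, the subtype's protocol defaults
  are applied on read with a logged notice (ABR: click, 22/s, 80 dB nHL,
  33–1500 Hz band; AMLR: 2 kHz tone burst, 6.1/s, 70 dB nHL, 10–1500 Hz).
* `<samples>` holds whitespace-separated voltages in µV, written as
  shortest-round-trip decimals so that reading reproduces the float64
  series bit-exactly.  Reading performs no resampling, filtering, or
  scaling.

## AEP record CSV

Long format, one row per sample:

```
record_id,patient_id,ear,subtype,fs_hz,sample_index,value_uv
```

`sample_index` runs 0..n−1 without gaps per record.  The CSV schema has no
stimulus columns; subtype defaults are applied on read (logged).

## Wave metric table CSV

One row per (record, wave, metric):

```
record_id,patient_id,ear,subtype,wave,metric,value,found
```

`metric` is `latency` (ms) or `amplitude` (µV, signed); a wave that was
not detected has `found = False` and an empty `value` — never a zero.

## Clinical table CSV

One row per patient, indexed by `patient_id`: the 33 covariate columns
(after ear aggregation), written with a JSON sidecar
(`clinical_features.schema.json`) typing each column as `numeric` or
`categorical`.  Categorical variables are integer-coded; the level maps
are documented in `aepkit.synth.CLINICAL_SCHEMA`.

## Scattering feature matrix CSV

Rows = records, columns = scattering path labels `m:l1[:l2]` where `m` is
the order and `l1`, `l2` are wavelet centre frequencies in Hz; values are
scale-averaged log scattering coefficients.

## Run manifest JSON

`manifest.json` in a run directory records the full configuration echo,
library versions, per-stage status, and SHA-256 hashes of every data
artifact (plots are excluded from hashing).  Identical configuration and
seed reproduce identical hashes.
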