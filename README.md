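# qpcrmap

Harmonize raw qPCR fluorescence exports with Darwin-Core-aligned sample
metadata, compute threshold-cycle (Ct) values, classify detection intensity,
and export geographically clustered, filterable detection maps.

qpcrmap is aimed at eDNA / molecular-biosurveillance groups who accumulate
raw quantitative PCR runs from heterogeneous instruments (MIC cyclers,
Biomeme handhelds, ...) and need them in one standardized, mappable table.
Each qPCR well is one record: the well name (`run_location`) is the primary
key joining the instrument's cycle-by-cycle fluorescence readings to a
metadata row carrying nine required fields (`run_location`, `run_platform`,
`threshold`, `organismScope`, `eventDate`, `decimalLatitude`,
`decimalLongitude`, `taxonID`, `species`) plus any extra Darwin Core columns.

## The model

For a well with readings $F_1, F_2, \dots$ at cycles $1, 2, \dots$ and a
user-supplied fluorescence threshold $T > 0$, the threshold cycle is the
first crossing, located by linear interpolation between the flanking cycles:

$$\mathrm{Ct} = c_{j-1} + \frac{T - F_{j-1}}{F_j - F_{j-1}},
  \qquad j = \min\{\,j : F_j \ge T\,\}$$

(the first cycle if $F_1 \ge T$, and the sentinel `NO_CROSSING` if no
reading reaches $T$). Detections are binned by Ct into ordinal intensity
levels; the defaults are Ct < 40 for a positive detection, with
very strong [0, 10), strong [10, 20), moderate [20, 30), weak [30, 40),
and "none detected" at Ct ≥ 40 or no crossing. Records whose coordinates
differ by no more than 0.005° in both latitude and longitude are collapsed
into one cluster (single linkage), and cluster members are "spiderfied"
onto a small circle so each replicate stays visible on the map.

## Worked example

```sh
qpcrmap simulate --wells 16 --seed 7 --out-dir fixtures
# simulated 16 wells into fixtures
qpcrmap prepare --platform mic --fluor fixtures/mic_run.csv \
                --meta fixtures/metadata.csv --out merged.csv
# merged 16 records -> merged.csv
qpcrmap map --in merged.csv --out detections.geojson
# mapped 16 records in 3 clusters -> detections.geojson
```

`simulate` writes a synthetic plate (sigmoidal amplification curves with
known crossing cycles) in every supported instrument dialect plus matching
metadata and a ground-truth table. `prepare` parses the raw export, validates
the metadata, joins them on the well name, computes Ct per well against that
well's threshold, and writes the standardized merged table — all metadata
columns, then one `fluorescence` column holding the `;`-joined readings, then
`ct`:

```
run_location,run_platform,threshold,...,species,...,fluorescence,ct
A1,mic,2.0,...,Dreissena polymorpha,...,0.5146...;0.4021...;...,29.328331090054167
```

`map` filters (species / organism scope / date range), clusters coordinates,
classifies each record, and writes GeoJSON (or a self-contained HTML map when
`--out` ends in `.html`). Each record becomes a Point feature at its display
coordinate, with the information-bubble content as properties:

```json
{
  "species": "Dreissena polymorpha",
  "taxonID": "45954",
  "taxonomy_url": "https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?mode=Info&id=45954",
  "ct": 29.328331090054167,
  "intensity_label": "moderate",
  "color": "#007BA7",
  "run_platform": "mic",
  "eventDate": "2020-07-20",
  "decimalLatitude": 45.323018,
  "decimalLongitude": -78.62498,
  "recordedBy": "K. Osei",
  "vernacularName": "zebra mussel"
}
```

This well amplified late-ish (Ct ≈ 29.3, between bin bounds 20 and 30), so it
is a "moderate" detection and drawn cerulean; the 16 records collapse into 3
coordinate clusters, and the document holds 16 detection features + 3 cluster
summary features. `qpcrmap combine` concatenates merged tables from separate
runs (namespacing colliding well names), and `qpcrmap classify` annotates a
merged table with `intensity_label`/`color` columns. Custom schemes:
`--ct-cutoff 35 --bins 0,5,15,25`; custom instruments: `--descriptor my.json`
with a documented platform-descriptor file (orientation, cycle field, well
pattern, rows to skip).

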