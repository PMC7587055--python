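# Methods

## Pipeline model

qpcrmap treats one qPCR well as the unit of observation. A record is the
join, on the well name `run_location`, of (a) the instrument's raw
fluorescence readings for that well and (b) one metadata row describing the
assay and the sampling event. The join is strictly 1:1: duplicate keys in
the metadata are an error, and unmatched wells or metadata rows are
collected into an orphan report (optionally escalated to an error in strict
mode) rather than silently dropped. Merged rows are sorted by
`run_location`, so the merge is deterministic regardless of input order.

### Ct calling

The threshold cycle is the first point at which the piecewise-linear
interpolant of the readings reaches the per-well threshold: with
`j = min{j : F_j >= T}`, Ct is the linear interpolation of the crossing
between cycles `j-1` and `j` (the first cycle if the curve starts at or
above threshold; `NO_CROSSING` if it never reaches it). Choices worth
stating:

- **Two-point linear interpolation**, i.e. a local linear fit through the
  flanking cycles. It is deterministic, parameter-free, and exact whenever a
  reading touches the threshold. Local polynomial refinements exist but add
  tuning surface for sub-0.05-cycle gains, below run-to-run variability of
  real instruments (replicate Ct can differ by cycles, not hundredths).
- **No baseline subtraction.** The user supplies the threshold per well and
  it is compared to raw readings; `ct_from_curve` exposes a
  `baseline_corrector` hook for plugging a corrector in front.
- **First crossing wins** when noise makes the curve cross more than once.
- The per-well `threshold` field means thresholds can differ within one run;
  each record's Ct uses its own threshold.

### Intensity classification

An `IntensityScheme` holds a positivity cutoff (default Ct 40), ascending
bin lower bounds (default 0/10/20/30) and ordered labels (very strong,
strong, moderate, weak) with a fixed color per label (light green, light
yellow, cerulean, light magenta-pink, tawny mapped to #90EE90, #FFFFE0,
#007BA7, #FF66B3, #CD5700 — the conventional names pinned to concrete hex
values). Bins are half-open at the top, `[lower_i, lower_{i+1})`, the last
bin ending at the cutoff, so Ct = 40.0 exactly is "none detected" and every
finite Ct ≥ 0 maps to exactly one label (with defaults: four positive
levels + "none detected" = five levels total). A Ct below the first bound
of a custom scheme falls into the strongest bin. Negative or non-finite Ct
values are rejected.

### Geospatial collapse and spiderfy

Two records are directly linked when both |Δlat| ≤ tol and |Δlon| ≤ tol
(default 0.005°; a box rule, not a Euclidean disk — the tolerance is stated
per axis). Clusters are the connected components of this link graph
(single linkage, union-find), so a chain of points each within tolerance of
the next collapses into one cluster even if its endpoints are farther
apart; grid snapping was rejected because replicates straddling a grid edge
would split. The sweep is O(n·k) after sorting by latitude. At tol = 0 only
exactly coincident points merge; the partition is invariant under input
permutation, and cluster order is fixed by sorting on (centroid lat, lon).
Members of a multi-point cluster get display offsets at equal angles
2πk/n on a circle of radius 0.0008° (a display constant, roughly tens of
metres) around the centroid; singletons stay put. Offsets sum to zero, so
the fan is centred on the centroid.

### Map export

GeoJSON (RFC 7946) with one Point feature per record at its display
coordinate — coordinates in (lon, lat) order, true sampling coordinates
preserved in the properties — plus one summary feature per multi-member
cluster. Properties carry the information-bubble content: species, taxonID
and its NCBI Taxonomy URL (numeric IDs only; user-created higher-taxon
tokens get no link), Ct (or `"none"`), intensity label and color, platform,
date, and collector/common name when present. Serialization sorts keys and
rounds coordinates to 8 decimals, so identical inputs give byte-identical
output. The HTML export is a dependency-free static page: an inline SVG
scatter in an equirectangular projection of the feature bounding box plus
the legend (levels strongest-first, then "none detected"). It intentionally
does not provide tiles, zooming, or click-to-spiderfy interactivity.

## File formats

- **Platform dialects.** Real vendor layouts are proprietary and variable,
  so parsing is descriptor-driven: orientation (wells as columns vs rows),
  the cycle-axis label, a well-name regex, banner rows to skip, and an
  optional workbook sheet. Three documented canonical dialects ship
  built in (`mic`: wells-as-columns CSV with a `Cycle` column; `biomeme2`
  and `biomeme3`: wells-as-rows with cycle numbers in the header, the
  latter with one banner row); real exports are mapped by writing a JSON
  descriptor, not code. Labels failing the well pattern are reported on the
  parse result, never silently dropped. Cycle numbering is 1-based and must
  be strictly increasing.
- **Merged table.** CSV with all metadata columns in canonical order
  (the nine required fields, the higher-taxon flag, then extra columns
  sorted), a `fluorescence` column holding the readings joined with `;`
  (shortest round-trip decimal formatting, so write→read is bit-exact), and
  `ct` (empty cell = `NO_CROSSING`). Curves are reconstructed from the
  string with contiguous 1-based cycles; a curve that did not start at
  cycle 1 would lose its offset on round trip (all shipped dialects start
  at 1). `combine` requires identical schemas and keeps `run_location`
  unique by suffixing colliding keys with `#<table-index>`.
- **Metadata.** CSV or XLSX. Dates must be ISO 8601 (`YYYY-MM-DD`); other
  formats are rejected with a message rather than guessed at, since silent
  coercion corrupts temporal filtering. Latitude/longitude are range
  checked; `threshold` must be positive; `species` must contain a space
  ("Genus species") unless `is_higher_taxon` is set, which covers assays
  that amplify a whole higher taxon under a user-created identifier. The
  alias spelling `decimalLongtitude` is accepted on input. Validation is
  total (every row ends up valid or in the problem list) and idempotent.

## Synthetic data generator

`simulate` emulates a plate read once per cycle. Amplifying wells follow a
four-parameter logistic
`F(c) = baseline + plateau / (1 + exp(-(c - c_half)/k))` — flat background,
exponential rise, saturation — which is the canonical amplification-curve
shape and analytically invertible, so the exact threshold crossing
`c* = c_half - k ln(plateau/(T - baseline) - 1)` is recorded as ground
truth. Negative wells are baseline only. Gaussian reading noise is scaled
by the plateau.

Defaults, chosen once as a plausible eDNA plate: 96 wells, 45 cycles,
plateau 10 fluorescence units over baseline 0.5, logistic width k = 1.5
cycles (an exponential phase spanning a handful of cycles), threshold 2.0
(15% of the amplitude above background — above baseline noise, inside the
exponential phase), noise 1% of plateau, 15% negative wells, midpoints
uniform over cycles 18–32 so crossings sit well inside the run. Metadata
rows draw species/taxonID/common name, collectors, and dates from small
fixed pools, and coordinates from six stations (three within the collapse
tolerance of each other, three apart) with ±0.002° jitter, so clustering
and filtering are exercised. All randomness comes from one seed;
fixture files are byte-identical across repeated calls.

What the generator does **not** emulate: instrument-specific noise spectra
and drift, baseline slopes, probe-chemistry artifacts, plateau variation
between wells, or the vendors' true proprietary file layouts. Passing tests
therefore demonstrate the pipeline's arithmetic and plumbing on idealized
curves, not robustness to every real-world export.

## Numerical behavior and verification sizes

With 1-cycle sampling, linear interpolation of a logistic with k = 1.5
carries a discretization error of up to ~0.03 cycles against the continuous
curve's analytic crossing (bounded by ≈0.048/k); the implementation is
checked both against a dense-grid (1e-4-cycle) root scan of the sampled
curve (agreement ≤ 0.01 cycles, in practice ≤ 1e-4) and against analytic
ground truth (median error < 0.05 at zero noise; ≥95% of wells within 0.5
cycles at 1% noise). Recovery experiments use 200-well plates; oracle
equivalence uses 10,000 random Ct values and 500 random points; round
trips use 100-record tables. These sizes make the whole suite run in
seconds while keeping every check statistically comfortable.

## Known limitations

- No absolute quantification, standard curves, amplification-efficiency
  estimation, or multiplex (multi-dye) support.
- No live NCBI taxonomy verification; the link is constructed, not checked.
- Clustering is a fixed degree-box rule at export time, not zoom-dependent
  re-clustering; degrees are not metres, so the box's ground size varies
  with latitude.
- No relational/SQL persistence; merged CSVs are the interchange format.
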