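"""Synthetic qPCR runs with known ground truth.

Amplifying wells follow a four-parameter logistic,

    F(c) = baseline + plateau / (1 + exp(-(c - c_half) / k)),

the canonical amplification-curve shape: flat background, exponential rise,
saturation. It is analytically invertible, so the exact cycle at which the
noiseless curve reaches the detection threshold,

    c* = c_half - k * ln(plateau / (threshold - baseline) - 1),

serves as ground truth for every downstream Ct estimate. Negative wells
(no target DNA) are baseline + noise only. Gaussian reading noise is
expressed as a fraction of the plateau.

Defaults sketch a plausible eDNA plate: 96 wells read once per cycle for 45
cycles, amplitude 10 fluorescence units over a 0.5-unit background, logistic
width k = 1.5 cycles (exponential phase spanning a handful of cycles),
threshold at 15% of the amplitude above background (above baseline noise,
inside the exponential phase), 1% reading noise, and 15% of wells negative.
Midpoints are drawn uniformly over cycles 18-32 so every true crossing lies
well inside the run.

``simulate_run`` writes one raw-export file per shipped dialect plus a
metadata CSV and a ground-truth table, all deterministic under the seed.
"""

from __future__ import annotations

import math
import string
import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import NO_CROSSING
from .platform_io import BUILTIN_DESCRIPTORS

#: Species pool (binomial, NCBI-style taxonID, common name, organism scope) —
#: synthetic assay targets typical of freshwater eDNA surveillance.
SPECIES_POOL: tuple[tuple[str, int, str, str], ...] = (
    ("Salmo salar", 8030, "Atlantic salmon", "multicellular organism"),
    ("Esox lucius", 8010, "northern pike", "multicellular organism"),
    ("Petromyzon marinus", 7757, "sea lamprey", "multicellular organism"),
    ("Dreissena polymorpha", 45954, "zebra mussel", "multicellular organism"),
    ("Frog virus 3", 10493, "ranavirus FV3", "virus"),
)

#: Sampling sites (lat, lon): three lake stations within the collapse
#: tolerance of each other plus three well-separated river stations.
SITE_POOL: tuple[tuple[float, float], ...] = (
    (45.3211, -78.6247),
    (45.3234, -78.6260),
    (45.3228, -78.6239),
    (45.4102, -78.5120),
    (45.5237, -78.8414),
    (45.2591, -78.3088),
)

RECORDED_BY_POOL: tuple[str, ...] = (
    "A. Rivera", "K. Osei", "M. Tremblay", "J. Park",
)

_DATE_START = date(2019, 6, 1)
_DATE_SPAN_DAYS = 480


@dataclass(frozen=True)
class SimParams:
    """Generator settings; the seed fixes all randomness."""

    n_wells: int = 96
    plateau: float = 10.0          # amplitude above baseline, fluorescence units
    baseline: float = 0.5
    slope_k: float = 1.5           # logistic width, cycles
    noise_sd: float = 0.01         # Gaussian sd as a fraction of plateau
    n_cycles: int = 45
    threshold: float = 2.0         # baseline + 0.15 * plateau
    fraction_negative: float = 0.15
    midpoint_range: tuple[float, float] = (18.0, 32.0)
    seed: int = 0

    def __post_init__(self):
        if not self.plateau > self.baseline >= 0:
            raise ValueError("need plateau > baseline >= 0")
        if self.slope_k <= 0:
            raise ValueError("slope_k must be > 0")
        if not 0.0 <= self.fraction_negative <= 1.0:
            raise ValueError("fraction_negative must be in [0, 1]")
        if self.n_wells < 1 or self.n_cycles < 2:
            raise ValueError("need n_wells >= 1 and n_cycles >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def well_names(n: int) -> list[str]:
    """Plate-style names A1..A12, B1.., then AA1.. after row Z."""
    letters = list(string.ascii_uppercase)
    rows = letters + [a + b for a in letters for b in letters]
    names = []
    for i in range(n):
        names.append(f"{rows[i // 12]}{i % 12 + 1}")
    return names


def logistic_readings(
    cycles: np.ndarray, baseline: float, plateau: float, c_half: float, k: float
) -> np.ndarray:
    return baseline + plateau / (1.0 + np.exp(-(cycles - c_half) / k))


def analytic_crossing(params: SimParams, c_half: float) -> float | object:
    """Exact cycle where the noiseless logistic reaches the threshold."""
    rise = params.threshold - params.baseline
    if rise <= 0:
        # threshold at/below background: the curve starts above it
        return 1.0
    if rise >= params.plateau:
        return NO_CROSSING
    c = c_half - params.slope_k * math.log(params.plateau / rise - 1.0)
    if c > params.n_cycles:
        return NO_CROSSING
    return max(c, 1.0)


@dataclass
class SimulatedRun:
    """In-memory ground truth for one synthetic plate."""

    params: SimParams
    well_ids: list[str]
    cycles: np.ndarray                      # shape (n_cycles,)
    matrix: np.ndarray                      # shape (n_wells, n_cycles)
    midpoints: np.ndarray                   # c_half per well (nan for negatives)
    is_negative: np.ndarray                 # bool per well
    ground_truth: dict[str, float | object] # well -> crossing cycle or NO_CROSSING
    metadata: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)


def simulate_wells(params: SimParams) -> SimulatedRun:
    """Draw the plate: curves, per-well ground truth, and metadata rows."""
    if params.threshold >= params.baseline + params.plateau:
        warnings.warn(
            "threshold at or above baseline + plateau: every well is negative",
            stacklevel=2,
        )
    rng = np.random.default_rng(params.seed)
    wells = well_names(params.n_wells)
    cycles = np.arange(1, params.n_cycles + 1, dtype=float)

    is_negative = rng.random(params.n_wells) < params.fraction_negative
    midpoints = rng.uniform(*params.midpoint_range, size=params.n_wells)
    midpoints[is_negative] = np.nan

    matrix = np.empty((params.n_wells, params.n_cycles))
    truth: dict[str, float | object] = {}
    for i, well in enumerate(wells):
        if is_negative[i]:
            matrix[i] = params.baseline
            truth[well] = NO_CROSSING
        else:
            matrix[i] = logistic_readings(
                cycles, params.baseline, params.plateau, midpoints[i], params.slope_k
            )
            truth[well] = analytic_crossing(params, midpoints[i])
    if params.noise_sd > 0:
        matrix += rng.normal(
            0.0, params.noise_sd * params.plateau, size=matrix.shape
        )

    metadata = _metadata_frame(params, wells, rng)
    return SimulatedRun(
        params=params,
        well_ids=wells,
        cycles=cycles,
        matrix=matrix,
        midpoints=midpoints,
        is_negative=is_negative,
        ground_truth=truth,
        metadata=metadata,
    )


def _metadata_frame(
    params: SimParams, wells: list[str], rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    for well in wells:
        sp, taxon, common, scope = SPECIES_POOL[rng.integers(len(SPECIES_POOL))]
        site_lat, site_lon = SITE_POOL[rng.integers(len(SITE_POOL))]
        lat = site_lat + rng.uniform(-0.002, 0.002)
        lon = site_lon + rng.uniform(-0.002, 0.002)
        when = _DATE_START + timedelta(days=int(rng.integers(_DATE_SPAN_DAYS)))
        rows.append(
            {
                "run_location": well,
                "run_platform": "mic",
                "threshold": repr(float(params.threshold)),
                "organismScope": scope,
                "eventDate": when.isoformat(),
                "decimalLatitude": repr(round(lat, 6)),
                "decimalLongitude": repr(round(lon, 6)),
                "taxonID": str(taxon),
                "species": sp,
                "recordedBy": RECORDED_BY_POOL[rng.integers(len(RECORDED_BY_POOL))],
                "vernacularName": common,
            }
        )
    return pd.DataFrame(rows)


def _fmt(x: float) -> str:
    return repr(float(x))


def _write_mic(sim: SimulatedRun, path: Path) -> None:
    lines = ["Cycle," + ",".join(sim.well_ids)]
    for j, c in enumerate(sim.cycles):
        lines.append(
            f"{int(c)}," + ",".join(_fmt(sim.matrix[i, j]) for i in range(len(sim.well_ids)))
        )
    path.write_text("\n".join(lines) + "\n")


def _write_biomeme(sim: SimulatedRun, path: Path, banner: str | None) -> None:
    lines = []
    if banner is not None:
        lines.append(banner)
    lines.append("Well," + ",".join(str(int(c)) for c in sim.cycles))
    for i, well in enumerate(sim.well_ids):
        lines.append(f"{well}," + ",".join(_fmt(v) for v in sim.matrix[i]))
    path.write_text("\n".join(lines) + "\n")


def write_fixture_files(
    sim: SimulatedRun, out_dir: str | Path, platforms: list[str] | None = None
) -> dict[str, Path]:
    """Write the raw export for each requested dialect + metadata + truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    platforms = platforms or sorted(BUILTIN_DESCRIPTORS)
    paths: dict[str, Path] = {}
    for platform in platforms:
        p = out_dir / f"{platform}_run.csv"
        if platform == "mic":
            _write_mic(sim, p)
        elif platform == "biomeme2":
            _write_biomeme(sim, p, banner=None)
        elif platform == "biomeme3":
            _write_biomeme(sim, p, banner="Biomeme three9 raw fluorescence export")
        else:
            raise KeyError(f"no writer for platform {platform!r}")
        paths[platform] = p

    meta_path = out_dir / "metadata.csv"
    sim.metadata.to_csv(meta_path, index=False)
    paths["metadata"] = meta_path

    truth_path = out_dir / "ground_truth.csv"
    truth_lines = ["run_location,true_crossing_cycle"]
    for well in sim.well_ids:
        c = sim.ground_truth[well]
        truth_lines.append(f"{well}," + ("" if c is NO_CROSSING else _fmt(c)))
    truth_path.write_text("\n".join(truth_lines) + "\n")
    paths["ground_truth"] = truth_path
    return paths


def simulate_run(
    params: SimParams, out_dir: str | Path, platforms: list[str] | None = None
) -> SimulatedRun:
    """Simulate a plate and write all fixture files; returns the ground truth."""
    sim = simulate_wells(params)
    sim.paths = write_fixture_files(sim, out_dir, platforms)
    return sim


def read_ground_truth(path: str | Path) -> Mapping[str, float | object]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return {
        r["run_location"]: (
            NO_CROSSING
            if r["true_crossing_cycle"] == ""
            else float(r["true_crossing_cycle"])
        )
        for r in df.to_dict(orient="records")
    }
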