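from __future__ import annotations

import random
from datetime import date, timedelta

import pytest

from qpcrmap import (
    FluorescenceCurve,
    MergedRecord,
    MetadataRecord,
    SimParams,
    simulate_run,
)
from qpcrmap.core import NO_CROSSING


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A 24-well noisy plate written in every dialect, with ground truth."""
    out = tmp_path_factory.mktemp("sim24")
    return simulate_run(SimParams(n_wells=24, seed=11), out)


@pytest.fixture(scope="session")
def noiseless_sim(tmp_path_factory):
    out = tmp_path_factory.mktemp("sim_clean")
    return simulate_run(SimParams(n_wells=24, noise_sd=0.0, seed=11), out)


def make_metadata(
    well="A1",
    species="Salmo salar",
    taxon=8030,
    lat=45.0,
    lon=-78.0,
    when=date(2020, 7, 1),
    scope="multicellular organism",
    threshold=2.0,
    **extras,
) -> MetadataRecord:
    return MetadataRecord(
        run_location=well,
        run_platform="mic",
        threshold=threshold,
        organismScope=scope,
        eventDate=when,
        decimalLatitude=lat,
        decimalLongitude=lon,
        taxonID=taxon,
        species=species,
        extras=dict(extras),
    )


def make_record(well="A1", ct=25.0, readings=(1.0, 2.0, 3.0), **meta_kwargs):
    curve = FluorescenceCurve(
        well, tuple(range(1, len(readings) + 1)), tuple(float(r) for r in readings)
    )
    return MergedRecord(
        metadata=make_metadata(well=well, **meta_kwargs), curve=curve, ct=ct
    )


def random_record(rng: random.Random, well: str) -> MergedRecord:
    n = rng.randint(2, 45)
    readings = tuple(round(rng.uniform(0.0, 12.0), 6) for _ in range(n))
    ct = NO_CROSSING if rng.random() < 0.2 else round(rng.uniform(0.0, 45.0), 4)
    extras = {}
    if rng.random() < 0.5:
        extras["recordedBy"] = rng.choice(["A. Rivera", "K. Osei"])
    return make_record(
        well=well,
        ct=ct,
        readings=readings,
        species=rng.choice(["Salmo salar", "Esox lucius", "Frog virus 3"]),
        taxon=rng.choice([8030, 8010, "GenusX-complex"]),
        lat=round(rng.uniform(-89.0, 89.0), 6),
        lon=round(rng.uniform(-179.0, 179.0), 6),
        when=date(2019, 1, 1) + timedelta(days=rng.randint(0, 700)),
        **extras,
    )
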