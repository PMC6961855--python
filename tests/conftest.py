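"""Shared fixtures: study-scale and desk-scale synthetic landscapes."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from invstab.regions import GenomicInterval
from invstab.scanner import QueryMotif
from invstab.simulate import (
    PlantSpec,
    SyntheticLandscapeSpec,
    generate_haplotype_set,
    generate_master,
)

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=list(HealthCheck)
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_spec() -> SyntheticLandscapeSpec:
    """The study-condition recipe: 1 Mb, 90 plants in Table-1-like classes."""
    return SyntheticLandscapeSpec(seed=20)


@pytest.fixture(scope="session")
def default_master(default_spec):
    return generate_master(default_spec)


@pytest.fixture(scope="session")
def default_hapset(default_spec):
    """Five haplotypes sharing the master plant set with 21 haplotype-specific absences."""
    return generate_haplotype_set(default_spec, n_haplotypes=5, absence_count=21)


def small_plants():
    return [
        PlantSpec(distance=1_366, m=2, gapped=True, anchor=True),
        PlantSpec(distance=None, m=3),
        PlantSpec(distance=None, m=4),
        PlantSpec(distance=None, m=4),
        PlantSpec(distance=None, m=5),
        PlantSpec(distance=None, m=5),
        PlantSpec(distance=None, m=6),
        PlantSpec(distance=None, m=6),
        PlantSpec(distance=None, m=6),
    ]


@pytest.fixture(scope="session")
def small_spec() -> SyntheticLandscapeSpec:
    """A desk-scale 80 kb landscape with 9 plants for fast unit tests."""
    return SyntheticLandscapeSpec(
        seed=7, length=80_001, plants=small_plants(), min_distance=3_000
    )


@pytest.fixture(scope="session")
def small_master(small_spec):
    return generate_master(small_spec)


@pytest.fixture(scope="session")
def small_query(small_spec) -> QueryMotif:
    return QueryMotif(small_spec.query, small_spec.query_interval)


@pytest.fixture(scope="session")
def default_query(default_spec) -> QueryMotif:
    return QueryMotif(default_spec.query, default_spec.query_interval)


@pytest.fixture()
def interval():
    def make(start: int, end: int, chrom: str = "chr7") -> GenomicInterval:
        return GenomicInterval(chrom, start, end)

    return make
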