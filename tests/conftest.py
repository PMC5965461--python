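"""Shared fixtures: small synthetic archives generated once per session."""

from __future__ import annotations

import pytest
from hypothesis import settings

from tagmaps.archive import StorageVersion, load_archive
from tagmaps.synth import ArchiveSpec, generate_archive, generate_sql_fixture

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

#: compact geometry for fast tests; the full-size scenario has its own fixture
SMALL = dict(
    image_shape=(64, 64),
    mvct_shape=(32, 32),
    target_width=96,
    couch_height_px=8,
    n_projections=24,
    delivery_channels=48,
    dose_shape=(8, 8, 8),
    n_ct_slices=2,
)


@pytest.fixture(scope="session")
def small_spec() -> ArchiveSpec:
    return ArchiveSpec(n_patients=2, n_fractions=2, seed=11, broken_link_fraction=0.5, **SMALL)


@pytest.fixture(scope="session")
def small_archive_dir(small_spec, tmp_path_factory):
    root = tmp_path_factory.mktemp("small_archive")
    manifest = generate_archive(small_spec, root)
    return root, manifest


@pytest.fixture()
def archive(small_archive_dir):
    root, _ = small_archive_dir
    return load_archive(root)


@pytest.fixture(scope="session")
def manifest(small_archive_dir):
    return small_archive_dir[1]


@pytest.fixture(scope="session")
def sql_fixture_text(small_spec, manifest) -> str:
    return generate_sql_fixture(small_spec, manifest)


@pytest.fixture(scope="session")
def v3_archive_dir(tmp_path_factory):
    root = tmp_path_factory.mktemp("v3_archive")
    spec = ArchiveSpec(
        n_patients=1, n_fractions=1, seed=5, version=StorageVersion.V3, **SMALL
    )
    manifest = generate_archive(spec, root)
    return root, manifest


@pytest.fixture(scope="session")
def fullsize_archive_dir(tmp_path_factory):
    """One patient at the clinical plan-CT geometry: 256x256 acquired, couch
    insertion to 384 columns + 28 rows, so the stored slice is 284x384."""
    root = tmp_path_factory.mktemp("fullsize_archive")
    spec = ArchiveSpec(
        n_patients=1,
        n_fractions=1,
        seed=3,
        couch_scenario="both",
        n_ct_slices=1,
        mvct_shape=(64, 64),
        n_projections=40,
        delivery_channels=64,
        dose_shape=(8, 16, 16),
    )
    manifest = generate_archive(spec, root)
    return root, manifest
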