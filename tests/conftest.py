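"""Shared fixtures: a tiny fast dataset for unit tests and the full default
dataset (generated once per session) for end-to-end checks."""

from __future__ import annotations

import pytest

from lbd_atlas import cr_catalog, clustering, lbd_extract
from lbd_atlas.synthetic_data import FamilySpec, SynthConfig, generate


def tiny_config(seed: int = 0) -> SynthConfig:
    """Small, fast study: 16 species, three families, all three extraction
    strategies exercised."""
    return SynthConfig(
        n_species=16,
        seed=seed,
        broad_fraction=0.5,
        phyto_fraction=0.125,
        symb_fraction=0.25,
        cr_mean_pab=4.0,
        cr_mean_non_pab=2.0,
        cr_mean_phyto=5.0,
        families=(
            FamilySpec("TINY0", "dCache_1", 5, 90, 0.15, 1.0, "clade", "inter_tm"),
            FamilySpec("TINY1", "unknown", 5, 70, 0.15, 0.6, "scattered", "n_terminal"),
            FamilySpec("TINY2", "PAS_3", 4, 60, 0.15, 0.0, "scattered", "domain_based"),
        ),
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    return generate(tiny_config())


@pytest.fixture(scope="session")
def dataset():
    """The default study conditions (96 species, twelve planted families)."""
    return generate(SynthConfig(seed=1))


def run_pipeline(ds):
    crs = cr_catalog.identify_crs(
        ds.hits, ds.sequences, ds.species_map, 25.0, ds.tm_segments
    )
    lbds = lbd_extract.extract_all(crs)
    clusters = clustering.greedy_cluster(lbds)
    return crs, lbds, clusters


@pytest.fixture(scope="session")
def pipeline(dataset):
    crs, lbds, clusters = run_pipeline(dataset)
    return {"crs": crs, "lbds": lbds, "clusters": clusters}


@pytest.fixture(scope="session")
def tiny_pipeline(tiny_dataset):
    crs, lbds, clusters = run_pipeline(tiny_dataset)
    return {"crs": crs, "lbds": lbds, "clusters": clusters}
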