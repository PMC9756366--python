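import numpy as np
import pandas as pd
import pytest

from polarconverge.io_formats import StrainRecord
from polarconverge.synthetic_data import SimConfig, simulate_panel, simulate_stations


def make_strain(
    strain_id,
    group="diatoms",
    habitat="Other",
    library_type="genome",
    water="marine",
    photosynthetic=True,
    busco=90.0,
    gene_count=1000,
):
    return StrainRecord(
        strain_id=strain_id,
        taxonomic_group=group,
        habitat=habitat,
        library_type=library_type,
        water=water,
        photosynthetic=photosynthetic,
        busco_complete_pct=busco,
        gene_count=gene_count,
    )


@pytest.fixture(scope="session")
def small_config():
    # scaled-down study for fast end-to-end tests
    return SimConfig(seed=11, n_pfams=300, n_planted_enriched=10, n_planted_expanded=10)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return simulate_panel(small_config)


@pytest.fixture(scope="session")
def small_stations(small_config):
    return simulate_stations(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


def random_strain_panel(rng, n=12):
    """A panel with randomised eligibility fields for filter-rule fuzzing."""
    groups = ("diatoms", "haptophytes", "chlorophytes", "dinoflagellates")
    habitats = ("Arctic", "Antarctic", "Other")
    return [
        make_strain(
            f"s{i:02d}",
            group=groups[rng.integers(len(groups))],
            habitat=habitats[rng.integers(len(habitats))],
            library_type=("genome", "transcriptome")[rng.integers(2)],
            water=("marine", "nonmarine")[int(rng.integers(4) == 0)],
            photosynthetic=bool(rng.integers(4) > 0),
            busco=float(rng.uniform(50, 100)),
        )
        for i in range(n)
    ]
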