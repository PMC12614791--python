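import numpy as np
import pytest

from fossilbias.coverage import IncidenceFrequencyTable
from fossilbias.occurrences import OccurrenceRecord


def make_occ(
    occurrence_id="O1",
    identified_name="Genus1 species1",
    clade_path=("Mammalia", "Order1", "Family1", "Genus1"),
    max_ma=10.0,
    min_ma=5.0,
    lat=40.0,
    lon=-100.0,
    collection_id="C1",
    reference_id="R1",
    ref_pubyr=1950,
    **kwargs,
):
    return OccurrenceRecord(
        occurrence_id=occurrence_id,
        identified_name=identified_name,
        clade_path=tuple(clade_path),
        max_ma=max_ma,
        min_ma=min_ma,
        lat=lat,
        lon=lon,
        collection_id=collection_id,
        reference_id=reference_id,
        ref_pubyr=ref_pubyr,
        **kwargs,
    )


def random_incidence_matrix(rng, n_species=None, T=None, density=0.35):
    """Random species-by-unit incidence matrix with no empty species/units."""
    n_species = n_species or int(rng.integers(4, 12))
    T = T or int(rng.integers(4, 13))
    while True:
        m = rng.random((n_species, T)) < density
        if m.any(axis=1).all() and m.any(axis=0).all():
            return m


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_table():
    # Y = [3, 2, 2, 1, 1], T = 5
    m = np.array(
        [
            [1, 1, 1, 0, 0],
            [1, 1, 0, 0, 0],
            [0, 0, 1, 1, 0],
            [0, 0, 0, 1, 0],
            [0, 0, 0, 0, 1],
        ],
        dtype=bool,
    )
    return IncidenceFrequencyTable.from_matrix(m)
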