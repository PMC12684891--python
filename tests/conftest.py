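import pandas as pd
import pytest

from plastrisk import (
    CategoryLoad,
    CauseOfDeath,
    NecropsyDataset,
    NecropsyRecord,
    PlasticCategory,
    SpeciesReference,
    Taxon,
)


def make_record(
    rid="r1",
    taxon=Taxon.SEA_TURTLE,
    cause=CauseOfDeath.KND,
    attributed=(),
    loads=None,
    body_length=50.0,
    species="Chelonia mydas",
    **kw,
):
    """Terse record builder: loads as {category: (pieces, volume, length)}."""
    load_map = {}
    for cat, spec in (loads or {}).items():
        pieces, vol, length = (spec + (None, None))[:3] if isinstance(spec, tuple) else (spec, None, None)
        load_map[cat] = CategoryLoad(cat, pieces, vol, length)
    return NecropsyRecord(
        id=rid,
        source_id="test",
        taxon=taxon,
        species=species,
        cause_of_death=cause,
        death_attributed_categories=frozenset(attributed),
        loads=load_map,
        body_length_cm=body_length,
        **kw,
    )


@pytest.fixture
def toy_dataset():
    """3 turtles + 1 seabird: one KD (rubber), one KND ingester, one clean KND, one IND."""
    H, R = PlasticCategory.HARD, PlasticCategory.RUBBER
    return NecropsyDataset(
        [
            make_record("t1", cause=CauseOfDeath.KD, attributed=[R],
                        loads={R: (3, 0.9), H: (1, 0.2)}),
            make_record("t2", cause=CauseOfDeath.KND, loads={H: (4, 1.0)}),
            make_record("t3", cause=CauseOfDeath.KND),
            make_record("t4", cause=CauseOfDeath.IND, loads={H: (2, 0.4)}),
            make_record("b1", taxon=Taxon.SEABIRD, cause=CauseOfDeath.KND,
                        loads={H: (1, 0.05)}, body_length=30.0),
        ]
    )


@pytest.fixture
def species_reference():
    return SpeciesReference(
        pd.DataFrame(
            {
                "species": ["Chelonia mydas"] * 3 + ["Caretta caretta"],
                "age_class": ["posthatchling", "juvenile", "adult", "adult"],
                "mean_length_cm": [5.2, 25.0, 90.0, 120.0],
                "min_length_cm": [3.0, 10.0, 35.0, 70.0],
                "max_length_cm": [10.0, 35.0, 150.0, 180.0],
            }
        )
    )
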