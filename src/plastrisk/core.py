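"""Shared enumerations for taxa, plastic categories, cause-of-death codes and load metrics."""

from __future__ import annotations

import enum


class PlasticCategory(str, enum.Enum):
    """Macroplastic material categories distinguished at necropsy."""

    HARD = "hard"
    SOFT = "soft"
    FISHING_DEBRIS = "fishing_debris"
    RUBBER = "rubber"
    FOAM = "foam"
    CLOTH = "cloth"
    OTHER = "other"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class CauseOfDeath(str, enum.Enum):
    """Cause-of-death coding for necropsied individuals.

    KND: known not debris; KD: known debris death; PD: probable debris death;
    IND: indeterminate cause.
    """

    KND = "KND"
    KD = "KD"
    PD = "PD"
    IND = "IND"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Taxon(str, enum.Enum):
    SEABIRD = "seabird"
    MARINE_MAMMAL = "marine_mammal"
    SEA_TURTLE = "sea_turtle"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class LoadMetric(str, enum.Enum):
    """How the gastrointestinal plastic load is quantified.

    PIECE_COUNT: number of pieces >= 5 mm.
    VOLUME_PER_LENGTH: total volume (cm^3) divided by body length (cm).
    LENGTH_PER_LENGTH: total debris length (cm) divided by body length (cm);
        meaningful for fishing debris (line, rope, net) only.
    """

    PIECE_COUNT = "piece_count"
    VOLUME_PER_LENGTH = "volume_per_length"
    LENGTH_PER_LENGTH = "length_per_length"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Cause codes treated as debris-death events in the survival model.
EVENT_CAUSES = frozenset({CauseOfDeath.KD, CauseOfDeath.PD})
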