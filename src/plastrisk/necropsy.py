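"""Per-individual necropsy records: data model, CSV reader/writer and ingest filters.

The unit of observation is one necropsied animal with its per-category
gastrointestinal macroplastic loads (pieces >= 5 mm, volume in cm^3, and for
fishing debris total length in cm), its cause-of-death code and, when plastic
killed it, which material categories were responsible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .aft import AFTModelSpec, LoadObservation
from .core import EVENT_CAUSES, CauseOfDeath, LoadMetric, PlasticCategory, Taxon

logger = logging.getLogger(__name__)

__all__ = [
    "CategoryLoad",
    "NecropsyRecord",
    "NecropsyDataset",
    "SpeciesReference",
    "VolumeEstimate",
    "load_necropsy_table",
    "write_necropsy_table",
    "filter_detection_limit",
    "impute_body_size",
    "estimate_piece_volume",
    "derive_load_observations",
]


@dataclass(frozen=True)
class CategoryLoad:
    """Aggregate load of one plastic category in one animal's GI tract."""

    category: PlasticCategory
    piece_count: int = 0
    total_volume_cm3: float | None = None
    total_length_cm: float | None = None  # fishing debris only
    piece_max_dims_mm: tuple[float, ...] | None = None  # per-piece largest dimension, if reported

    def __post_init__(self) -> None:
        if self.piece_count < 0:
            raise ValueError(f"{self.category}: piece_count must be nonnegative")
        if self.total_volume_cm3 is not None and self.total_volume_cm3 < 0:
            raise ValueError(f"{self.category}: volume must be nonnegative")
        if self.piece_count == 0 and self.total_volume_cm3 not in (None, 0, 0.0):
            raise ValueError(f"{self.category}: zero pieces but nonzero volume")
        if self.total_length_cm is not None:
            if self.category is not PlasticCategory.FISHING_DEBRIS:
                raise ValueError("total_length_cm applies to fishing debris only")
            if self.total_length_cm < 0:
                raise ValueError("total_length_cm must be nonnegative")


@dataclass(frozen=True)
class NecropsyRecord:
    """One necropsied individual."""

    id: str
    source_id: str
    taxon: Taxon
    species: str
    cause_of_death: CauseOfDeath
    family: str | None = None
    age_class: str | None = None
    sex: str | None = None
    body_length_cm: float | None = None
    species_mean_length_cm: float | None = None
    location: str | None = None
    death_attributed_categories: frozenset[PlasticCategory] = frozenset()
    loads: dict[PlasticCategory, CategoryLoad] = field(default_factory=dict)
    detection_limit_mm: float | None = None
    imputed: bool = False

    def __post_init__(self) -> None:
        attributed = self.death_attributed_categories
        if self.cause_of_death in EVENT_CAUSES and not attributed:
            raise ValueError(
                f"record {self.id}: cause {self.cause_of_death.value} requires "
                "at least one attributed plastic category"
            )
        if self.cause_of_death not in EVENT_CAUSES and attributed:
            raise ValueError(
                f"record {self.id}: attributed categories only valid for KD/PD"
            )
        for cat in attributed:
            load = self.loads.get(cat)
            if load is None or load.piece_count <= 0:
                raise ValueError(
                    f"record {self.id}: attributed category {cat.value} has no pieces"
                )
        if self.body_length_cm is not None and self.body_length_cm <= 0:
            raise ValueError(f"record {self.id}: body_length_cm must be positive")
        if self.species_mean_length_cm is not None and self.species_mean_length_cm <= 0:
            raise ValueError(f"record {self.id}: species_mean_length_cm must be positive")
        if self.detection_limit_mm is not None and self.detection_limit_mm <= 0:
            raise ValueError(f"record {self.id}: detection_limit_mm must be positive")

    def load_for(self, category: PlasticCategory) -> CategoryLoad:
        return self.loads.get(category, CategoryLoad(category))

    def total_pieces(self, categories: frozenset[PlasticCategory] | None = None) -> int:
        cats = categories if categories is not None else set(PlasticCategory)
        return sum(self.load_for(c).piece_count for c in cats)


@dataclass
class NecropsyDataset:
    """Ordered collection of necropsy records with provenance metadata."""

    records: list[NecropsyRecord]
    provenance: str = ""
    diagnostics: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, taxon: Taxon) -> "NecropsyDataset":
        return NecropsyDataset(
            [r for r in self.records if r.taxon is taxon],
            provenance=self.provenance,
        )


class SpeciesReference:
    """Mean and range of body length per (species, age class).

    Used both to fill a missing body length from the species/age-class mean
    and to assign an age class from a known length.  Age-class intervals are
    checked in ascending order of mean length with inclusive bounds, so a
    length on a shared boundary is assigned to the younger (smaller) class.
    """

    COLUMNS = ["species", "age_class", "mean_length_cm", "min_length_cm", "max_length_cm"]

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"species reference missing columns: {sorted(missing)}")
        t = table[self.COLUMNS].copy()
        bad = ~((t.min_length_cm <= t.mean_length_cm) & (t.mean_length_cm <= t.max_length_cm))
        if bad.any():
            raise ValueError("species reference requires min <= mean <= max")
        if t.duplicated(["species", "age_class"]).any():
            raise ValueError("duplicate (species, age_class) rows in reference")
        self.table = t.sort_values(["species", "mean_length_cm"]).reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "SpeciesReference":
        return cls(pd.read_csv(path))

    def mean_length(self, species: str, age_class: str) -> float | None:
        rows = self.table[
            (self.table.species == species) & (self.table.age_class == age_class)
        ]
        return None if rows.empty else float(rows.mean_length_cm.iloc[0])

    def age_class_for_length(self, species: str, length_cm: float) -> str | None:
        rows = self.table[self.table.species == species]
        for _, row in rows.iterrows():  # ascending mean length: boundary -> younger
            if row.min_length_cm <= length_cm <= row.max_length_cm:
                return str(row.age_class)
        return None


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

_BASE_COLUMNS = [
    "id", "source", "taxon", "species", "family", "age_class", "sex",
    "body_length_cm", "species_mean_length_cm", "cause_of_death",
    "attributed_categories",
]
_TAIL_COLUMNS = ["fishing_debris_length_cm", "detection_limit_mm"]


def _csv_columns(include_piece_sizes: bool = False) -> list[str]:
    cols = list(_BASE_COLUMNS)
    for cat in PlasticCategory:
        cols += [f"{cat.value}_pieces", f"{cat.value}_volume_cm3"]
        if include_piece_sizes:
            cols.append(f"{cat.value}_piece_sizes_mm")
    return cols + _TAIL_COLUMNS


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return float(v)


def _opt_str(v) -> str | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return str(v)


def _record_from_row(row: pd.Series) -> NecropsyRecord:
    loads: dict[PlasticCategory, CategoryLoad] = {}
    for cat in PlasticCategory:
        pieces = row.get(f"{cat.value}_pieces")
        pieces = 0 if pieces is None or (isinstance(pieces, float) and np.isnan(pieces)) else int(pieces)
        vol = _opt_float(row.get(f"{cat.value}_volume_cm3"))
        length = (
            _opt_float(row.get("fishing_debris_length_cm"))
            if cat is PlasticCategory.FISHING_DEBRIS
            else None
        )
        sizes_raw = _opt_str(row.get(f"{cat.value}_piece_sizes_mm"))
        sizes = (
            tuple(float(s) for s in sizes_raw.split(";") if s != "")
            if sizes_raw
            else None
        )
        if pieces or vol is not None or length is not None or sizes is not None:
            loads[cat] = CategoryLoad(cat, pieces, vol, length, sizes)
    attributed_raw = _opt_str(row.get("attributed_categories"))
    attributed = frozenset(
        PlasticCategory(token.strip())
        for token in attributed_raw.split(";")
        if token.strip()
    ) if attributed_raw else frozenset()
    return NecropsyRecord(
        id=str(row["id"]),
        source_id=str(row.get("source", "")),
        taxon=Taxon(row["taxon"]),
        species=str(row["species"]),
        family=_opt_str(row.get("family")),
        age_class=_opt_str(row.get("age_class")),
        sex=_opt_str(row.get("sex")),
        body_length_cm=_opt_float(row.get("body_length_cm")),
        species_mean_length_cm=_opt_float(row.get("species_mean_length_cm")),
        location=_opt_str(row.get("location")),
        cause_of_death=CauseOfDeath(row["cause_of_death"]),
        death_attributed_categories=attributed,
        loads=loads,
        detection_limit_mm=_opt_float(row.get("detection_limit_mm")),
    )


def load_necropsy_table(path, schema_config: dict[str, str] | None = None) -> NecropsyDataset:
    """Read the delimited necropsy table; invalid rows are rejected with diagnostics.

    ``schema_config`` optionally maps this package's canonical column names to
    the names used in the file.  Missing numeric cells stay missing — they are
    never coerced to zero.  Rejected rows are reported in
    ``dataset.diagnostics`` (one entry per row, with the reason).
    """
    df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    if schema_config:
        df = df.rename(columns={v: k for k, v in schema_config.items()})
    if "id" not in df.columns:
        raise ValueError("necropsy table must contain an 'id' column")
    records: list[NecropsyRecord] = []
    diagnostics: list[str] = []
    for i, row in df.iterrows():
        try:
            records.append(_record_from_row(row))
        except (ValueError, KeyError) as exc:
            diagnostics.append(f"row {i} (id={row.get('id')!r}) rejected: {exc}")
    ds = NecropsyDataset(records, provenance=f"loaded from {path}")
    ds.diagnostics = diagnostics
    for msg in diagnostics:
        logger.warning(msg)
    return ds


def write_necropsy_table(dataset: NecropsyDataset, path) -> None:
    """Write the dataset in the same CSV dialect the reader consumes."""
    any_sizes = any(
        load.piece_max_dims_mm is not None
        for r in dataset.records
        for load in r.loads.values()
    )
    rows = []
    for r in dataset.records:
        row: dict = {
            "id": r.id,
            "source": r.source_id,
            "taxon": r.taxon.value,
            "species": r.species,
            "family": r.family,
            "age_class": r.age_class,
            "sex": r.sex,
            "body_length_cm": r.body_length_cm,
            "species_mean_length_cm": r.species_mean_length_cm,
            "location": r.location,
            "cause_of_death": r.cause_of_death.value,
            "attributed_categories": ";".join(
                sorted(c.value for c in r.death_attributed_categories)
            ),
            "detection_limit_mm": r.detection_limit_mm,
        }
        for cat in PlasticCategory:
            load = r.load_for(cat)
            row[f"{cat.value}_pieces"] = load.piece_count
            row[f"{cat.value}_volume_cm3"] = load.total_volume_cm3
            if cat is PlasticCategory.FISHING_DEBRIS:
                row["fishing_debris_length_cm"] = load.total_length_cm
            if any_sizes:
                row[f"{cat.value}_piece_sizes_mm"] = (
                    ";".join(f"{s:g}" for s in load.piece_max_dims_mm)
                    if load.piece_max_dims_mm is not None
                    else None
                )
        rows.append(row)
    cols = _csv_columns(include_piece_sizes=any_sizes) + ["location"]
    # %.17g round-trips float64 exactly: writer . reader is the identity
    pd.DataFrame(rows).reindex(columns=cols).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Ingest filters
# ---------------------------------------------------------------------------


def filter_detection_limit(dataset: NecropsyDataset, min_size_mm: float = 5.0) -> NecropsyDataset:
    """Harmonize loads to pieces >= ``min_size_mm`` in their largest dimension.

    Records whose source reported no detection limit are passed through
    unchanged (the source is assumed to have captured all macroplastics).
    Records whose limit already meets ``min_size_mm`` cannot contain smaller
    pieces and also pass through.  Otherwise per-piece sizes are used to drop
    sub-threshold pieces; category volume is scaled by the retained piece
    fraction.  Idempotent: the output carries a limit of ``min_size_mm``.
    """
    if min_size_mm < 0:
        raise ValueError("min_size_mm must be nonnegative")
    out: list[NecropsyRecord] = []
    for r in dataset.records:
        limit = r.detection_limit_mm
        if limit is None or limit >= min_size_mm:
            out.append(r)
            continue
        new_loads: dict[PlasticCategory, CategoryLoad] = {}
        for cat, load in r.loads.items():
            if load.piece_count == 0 or load.piece_max_dims_mm is None:
                if load.piece_count > 0:
                    logger.warning(
                        "record %s: detection limit %.3g mm < %.3g mm but no "
                        "piece sizes for %s; passing through",
                        r.id, limit, min_size_mm, cat.value,
                    )
                new_loads[cat] = load
                continue
            kept = tuple(s for s in load.piece_max_dims_mm if s >= min_size_mm)
            frac = len(kept) / load.piece_count if load.piece_count else 0.0
            vol = None if load.total_volume_cm3 is None else load.total_volume_cm3 * frac
            if len(kept) == 0:
                vol = None if load.total_volume_cm3 is None else 0.0
            length = load.total_length_cm
            if length is not None:
                length = length * frac
            new_loads[cat] = CategoryLoad(cat, len(kept), vol, length, kept or None)
        attributed = frozenset(
            c for c in r.death_attributed_categories if new_loads.get(c, CategoryLoad(c)).piece_count > 0
        )
        cause = r.cause_of_death
        if cause in EVENT_CAUSES and not attributed:
            # attribution lost with the filtered pieces; cause becomes indeterminate
            cause = CauseOfDeath.IND
            logger.warning("record %s: all attributed pieces below %.3g mm; recoded IND", r.id, min_size_mm)
        out.append(
            replace(
                r,
                loads=new_loads,
                death_attributed_categories=attributed,
                cause_of_death=cause,
                detection_limit_mm=min_size_mm,
            )
        )
    return NecropsyDataset(out, provenance=dataset.provenance)


def impute_body_size(record: NecropsyRecord, reference: SpeciesReference) -> NecropsyRecord:
    """Fill a missing body length from the species/age-class mean, or a missing
    age class from the species length ranges.  Lookups that miss return the
    record unchanged with a warning."""
    if record.body_length_cm is None and record.age_class is not None:
        mean = reference.mean_length(record.species, record.age_class)
        if mean is None:
            warnings.warn(
                f"record {record.id}: ({record.species}, {record.age_class}) "
                "not in species reference; body length left missing",
                stacklevel=2,
            )
            return record
        return replace(record, body_length_cm=mean, imputed=True)
    if record.age_class is None and record.body_length_cm is not None:
        age = reference.age_class_for_length(record.species, record.body_length_cm)
        if age is None:
            warnings.warn(
                f"record {record.id}: no age-class range covers length "
                f"{record.body_length_cm} cm for {record.species}",
                stacklevel=2,
            )
            return record
        return replace(record, age_class=age, imputed=True)
    return record


@dataclass(frozen=True)
class VolumeEstimate:
    volume_cm3: float
    method: str  # "measured" | geometry name | "category_mean"


_GEOMETRY = {
    # dims in cm: (length, width, height); missing trailing dims unusable
    "box": lambda d: d[0] * d[1] * d[2],
    "ellipsoid": lambda d: (np.pi / 6.0) * d[0] * d[1] * d[2],
    "cylinder": lambda d: (np.pi / 4.0) * d[1] * d[1] * d[0],  # length x diameter
}


def estimate_piece_volume(
    piece_dimensions: dict,
    category: PlasticCategory,
    strategy_config: dict | None = None,
) -> VolumeEstimate:
    """Deterministic volume cascade: measured volume, else a geometric formula
    from linear dimensions, else the configured per-category mean piece volume.

    ``piece_dimensions`` may carry ``measured_volume_cm3`` and/or
    ``dims_cm`` (a length-3 sequence).  ``strategy_config`` keys:
    ``geometry`` (default "box") and ``category_mean_cm3`` (mapping).
    """
    cfg = dict(strategy_config or {})
    measured = piece_dimensions.get("measured_volume_cm3")
    if measured is not None:
        if measured < 0:
            raise ValueError("measured volume must be nonnegative")
        return VolumeEstimate(float(measured), "measured")
    dims = piece_dimensions.get("dims_cm")
    geometry = cfg.get("geometry", "box")
    if dims is not None and len(dims) == 3 and all(d is not None for d in dims):
        if geometry not in _GEOMETRY:
            raise ValueError(f"unknown geometry {geometry!r}")
        return VolumeEstimate(float(_GEOMETRY[geometry](list(dims))), geometry)
    means = cfg.get("category_mean_cm3", {})
    mean = means.get(category)
    if mean is None:
        raise ValueError(
            f"no volume strategy applicable for {category.value}: "
            "no measured volume, no full dimensions, no category mean configured"
        )
    return VolumeEstimate(float(mean), "category_mean")


# ---------------------------------------------------------------------------
# Model-ready observations
# ---------------------------------------------------------------------------


def _metric_load(record: NecropsyRecord, spec: AFTModelSpec) -> float | None:
    """Load in the spec's metric over its category subset; None when the
    required volume/length or body length is missing."""
    cats = (
        list(spec.categories)
        if spec.categories is not None
        else list(PlasticCategory)
    )
    if spec.metric is LoadMetric.PIECE_COUNT:
        return float(sum(record.load_for(c).piece_count for c in cats))
    if record.body_length_cm is None:
        return None
    if spec.metric is LoadMetric.VOLUME_PER_LENGTH:
        total = 0.0
        for c in cats:
            load = record.load_for(c)
            if load.piece_count == 0:
                continue
            if load.total_volume_cm3 is None:
                return None  # volume provenance required; never imputed silently
            total += load.total_volume_cm3
        return total / record.body_length_cm
    if spec.metric is LoadMetric.LENGTH_PER_LENGTH:
        load = record.load_for(PlasticCategory.FISHING_DEBRIS)
        if spec.categories is not None and spec.categories != frozenset(
            {PlasticCategory.FISHING_DEBRIS}
        ):
            raise ValueError("length-per-length metric applies to fishing debris only")
        if load.piece_count == 0:
            return 0.0
        if load.total_length_cm is None:
            return None
        return load.total_length_cm / record.body_length_cm
    raise ValueError(f"unknown metric {spec.metric}")  # pragma: no cover


_COVARIATE_GETTERS = {
    "individual_length": lambda r: r.body_length_cm,
    "species_mean_length": lambda r: r.species_mean_length_cm,
}


def derive_load_observations(
    dataset: NecropsyDataset, spec: AFTModelSpec
) -> list[LoadObservation]:
    """Turn records into (load, event, covariates) observations for one model.

    KD/PD deaths are events when the model is TOTAL or when a modeled
    category was attributed; a KD death attributed only to categories outside
    the model is right-censored at its in-model load (that load demonstrably
    did not kill it).  IND records are excluded.  Records missing a required
    volume/length, body length or covariate are skipped and logged.
    """
    observations: list[LoadObservation] = []
    n_ind = n_other_taxon = n_skipped = 0
    for r in dataset.records:
        if r.taxon is not spec.taxon:
            n_other_taxon += 1
            continue
        if r.cause_of_death is CauseOfDeath.IND:
            n_ind += 1
            continue
        event = int(
            r.cause_of_death in EVENT_CAUSES
            and (
                spec.categories is None
                or bool(spec.categories & r.death_attributed_categories)
            )
        )
        p = _metric_load(r, spec)
        if p is None:
            n_skipped += 1
            logger.info("record %s skipped: missing data for metric %s", r.id, spec.metric.value)
            continue
        x = []
        missing_cov = False
        for name in spec.covariates:
            v = _COVARIATE_GETTERS[name](r)
            if v is None:
                missing_cov = True
                break
            x.append(float(v))
        if missing_cov:
            n_skipped += 1
            logger.info("record %s skipped: missing covariate", r.id)
            continue
        if event and p <= 0:
            n_skipped += 1
            logger.info("record %s skipped: event with zero in-metric load", r.id)
            continue
        observations.append(LoadObservation(p=p, event=event, x=tuple(x), record_id=r.id))
    logger.info(
        "derive_load_observations[%s]: %d kept (%d events), %d IND, "
        "%d other taxon, %d skipped",
        spec.label, len(observations),
        sum(o.event for o in observations), n_ind, n_other_taxon, n_skipped,
    )
    if not observations:
        raise ValueError(f"no usable observations for spec {spec.label}")
    return observations
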