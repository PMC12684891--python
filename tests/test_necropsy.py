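"""Record invariants, CSV round trip, ingest filters and observation coding."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from plastrisk import (
    AFTModelSpec,
    CategoryLoad,
    CauseOfDeath,
    LoadMetric,
    NecropsyDataset,
    NecropsyRecord,
    PlasticCategory,
    Taxon,
    derive_load_observations,
    estimate_piece_volume,
    filter_detection_limit,
    impute_body_size,
    load_necropsy_table,
    write_necropsy_table,
)
from conftest import make_record

H, S, R, FD = (
    PlasticCategory.HARD,
    PlasticCategory.SOFT,
    PlasticCategory.RUBBER,
    PlasticCategory.FISHING_DEBRIS,
)


class TestRecordInvariants:
    def test_kd_without_attribution_rejected(self):
        with pytest.raises(ValueError, match="attributed"):
            make_record(cause=CauseOfDeath.KD, loads={R: (2, 0.5)})

    def test_attributed_category_needs_pieces(self):
        with pytest.raises(ValueError, match="no pieces"):
            make_record(cause=CauseOfDeath.KD, attributed=[R], loads={H: (2, 0.5)})

    def test_knd_with_attribution_rejected(self):
        with pytest.raises(ValueError):
            make_record(cause=CauseOfDeath.KND, attributed=[R], loads={R: (1, 0.1)})

    def test_zero_pieces_nonzero_volume_rejected(self):
        with pytest.raises(ValueError, match="zero pieces"):
            CategoryLoad(H, 0, 1.5)

    def test_length_only_for_fishing_debris(self):
        with pytest.raises(ValueError, match="fishing debris"):
            CategoryLoad(H, 2, 0.5, 10.0)
        CategoryLoad(FD, 2, 0.5, 10.0)  # fine

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            NecropsyDataset([make_record("a"), make_record("a")])


class TestCsvRoundTrip:
    def test_toy_round_trip(self, toy_dataset, tmp_path):
        path = tmp_path / "toy.csv"
        write_necropsy_table(toy_dataset, path)
        reloaded = load_necropsy_table(path)
        assert reloaded.records == toy_dataset.records
        assert not reloaded.diagnostics
        kd = [r for r in reloaded.records if r.cause_of_death is CauseOfDeath.KD]
        assert len(kd) == 1 and kd[0].death_attributed_categories == frozenset({R})

    def test_invalid_row_rejected_with_diagnostic(self, toy_dataset, tmp_path):
        path = tmp_path / "bad.csv"
        write_necropsy_table(toy_dataset, path)
        df = pd.read_csv(path)
        df.loc[df.id == "t1", "attributed_categories"] = ""  # KD without attribution
        df.to_csv(path, index=False)
        ds = load_necropsy_table(path)
        assert len(ds) == len(toy_dataset) - 1
        assert any("t1" in d and "attributed" in d for d in ds.diagnostics)

    def test_missing_numeric_cells_stay_missing(self, tmp_path):
        ds = NecropsyDataset([make_record("x", body_length=None, loads={H: (2, None)})])
        path = tmp_path / "m.csv"
        write_necropsy_table(ds, path)
        rec = load_necropsy_table(path).records[0]
        assert rec.body_length_cm is None
        assert rec.load_for(H).total_volume_cm3 is None


class TestDetectionLimitFilter:
    def _record_with_sizes(self, limit):
        return dataclasses.replace(
            make_record(
                "d1",
                loads={H: (2, 1.0)},
            ),
            loads={H: CategoryLoad(H, 2, 1.0, None, (3.0, 7.0))},
            detection_limit_mm=limit,
        )

    def test_subthreshold_pieces_dropped(self):
        ds = NecropsyDataset([self._record_with_sizes(1.0)])
        out = filter_detection_limit(ds, 5.0)
        load = out.records[0].load_for(H)
        assert load.piece_count == 1
        assert load.total_volume_cm3 == pytest.approx(0.5)  # proportional share retained

    def test_missing_limit_passes_through(self):
        rec = make_record("d2", loads={H: (3, 0.3)})
        out = filter_detection_limit(NecropsyDataset([rec]), 5.0)
        assert out.records[0] == rec

    def test_all_pieces_large_is_identity(self):
        rec = dataclasses.replace(
            make_record("d3"),
            loads={H: CategoryLoad(H, 2, 1.0, None, (6.0, 9.0))},
            detection_limit_mm=1.0,
        )
        out = filter_detection_limit(NecropsyDataset([rec]), 5.0)
        assert out.records[0].load_for(H).piece_count == 2
        assert out.records[0].load_for(H).total_volume_cm3 == pytest.approx(1.0)

    def test_idempotent(self):
        ds = NecropsyDataset([self._record_with_sizes(1.0)])
        once = filter_detection_limit(ds, 5.0)
        twice = filter_detection_limit(once, 5.0)
        assert once.records == twice.records

    def test_counts_never_increase(self):
        ds = NecropsyDataset([self._record_with_sizes(1.0)])
        out = filter_detection_limit(ds, 5.0)
        for before, after in zip(ds.records, out.records):
            for cat in PlasticCategory:
                assert after.load_for(cat).piece_count <= before.load_for(cat).piece_count

    def test_negative_threshold_rejected(self, toy_dataset):
        with pytest.raises(ValueError):
            filter_detection_limit(toy_dataset, -1.0)


class TestBodySizeImputation:
    def test_mean_fill(self, species_reference):
        rec = make_record("i1", body_length=None, age_class="adult")
        out = impute_body_size(rec, species_reference)
        assert out.body_length_cm == 90.0 and out.imputed

    def test_age_from_length(self, species_reference):
        rec = make_record("i2", body_length=30.0)
        out = impute_body_size(rec, species_reference)
        assert out.age_class == "juvenile" and out.imputed

    def test_boundary_assigns_younger_class(self, species_reference):
        rec = make_record("i3", body_length=35.0)  # juvenile max == adult min
        assert impute_body_size(rec, species_reference).age_class == "juvenile"

    def test_unknown_species_warns_and_passes_through(self, species_reference):
        rec = make_record("i4", species="Mola mola", body_length=None, age_class="adult")
        with pytest.warns(UserWarning, match="not in species reference"):
            out = impute_body_size(rec, species_reference)
        assert out == rec


class TestVolumeEstimation:
    def test_measured_wins(self):
        est = estimate_piece_volume({"measured_volume_cm3": 0.5, "dims_cm": (1, 2, 3)}, H, {})
        assert est.volume_cm3 == 0.5 and est.method == "measured"

    def test_box_formula(self):
        est = estimate_piece_volume({"dims_cm": (1.0, 2.0, 0.25)}, H, {"geometry": "box"})
        assert est.volume_cm3 == pytest.approx(0.5) and est.method == "box"

    def test_category_mean_fallback(self):
        est = estimate_piece_volume({}, H, {"category_mean_cm3": {H: 0.046}})
        assert est.volume_cm3 == pytest.approx(0.046) and est.method == "category_mean"

    def test_no_strategy_errors(self):
        with pytest.raises(ValueError, match="no volume strategy"):
            estimate_piece_volume({}, H, {})


class TestDeriveLoadObservations:
    def test_event_and_censoring_coding(self, toy_dataset):
        spec = AFTModelSpec(Taxon.SEA_TURTLE, None, LoadMetric.PIECE_COUNT)
        obs = {o.record_id: o for o in derive_load_observations(toy_dataset, spec)}
        assert obs["t1"].event == 1 and obs["t1"].p == 4  # KD, total pieces
        assert obs["t2"].event == 0 and obs["t2"].p == 4  # KND censored
        assert obs["t3"].event == 0 and obs["t3"].p == 0  # zero-load censored retained
        assert "t4" not in obs  # IND excluded
        assert "b1" not in obs  # other taxon

    def test_cross_category_death_is_censored(self, toy_dataset):
        # t1 died of rubber; in a hard-plastic model it is censored at its hard load
        spec = AFTModelSpec(Taxon.SEA_TURTLE, frozenset({H}), LoadMetric.PIECE_COUNT)
        obs = {o.record_id: o for o in derive_load_observations(toy_dataset, spec)}
        assert obs["t1"].event == 0 and obs["t1"].p == 1

    def test_category_event(self, toy_dataset):
        spec = AFTModelSpec(Taxon.SEA_TURTLE, frozenset({R}), LoadMetric.PIECE_COUNT)
        obs = {o.record_id: o for o in derive_load_observations(toy_dataset, spec)}
        assert obs["t1"].event == 1 and obs["t1"].p == 3

    def test_volume_metric_skips_missing_body_length(self):
        ds = NecropsyDataset(
            [
                make_record("v1", loads={H: (2, 1.0)}, body_length=None),
                make_record("v2", loads={H: (2, 1.0)}, body_length=50.0),
            ]
        )
        spec = AFTModelSpec(Taxon.SEA_TURTLE, None, LoadMetric.VOLUME_PER_LENGTH)
        obs = derive_load_observations(ds, spec)
        assert [o.record_id for o in obs] == ["v2"]
        assert obs[0].p == pytest.approx(1.0 / 50.0)

    def test_partition_invariant(self, toy_dataset):
        spec = AFTModelSpec(Taxon.SEA_TURTLE, None, LoadMetric.PIECE_COUNT)
        obs = derive_load_observations(toy_dataset, spec)
        n_ind = sum(r.cause_of_death is CauseOfDeath.IND for r in toy_dataset.records)
        n_other = sum(r.taxon is not Taxon.SEA_TURTLE for r in toy_dataset.records)
        assert len(obs) + n_ind + n_other == len(toy_dataset)

    def test_covariates_populated(self, toy_dataset):
        spec = AFTModelSpec(
            Taxon.SEA_TURTLE, None, LoadMetric.PIECE_COUNT, ("individual_length",)
        )
        obs = derive_load_observations(toy_dataset, spec)
        assert all(o.x == (50.0,) for o in obs)

    def test_all_loads_nonnegative(self, toy_dataset):
        spec = AFTModelSpec(Taxon.SEA_TURTLE, None, LoadMetric.PIECE_COUNT)
        assert all(o.p >= 0 for o in derive_load_observations(toy_dataset, spec))
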