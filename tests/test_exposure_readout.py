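"""Blank filtering, noise floor, parent grouping and ontology summaries."""

import numpy as np
import pandas as pd
import pytest

from drugtrace import (
    DrugLibrary,
    DrugLibraryEntry,
    FeatureTable,
    PharmMetadata,
    Spectrum,
    blank_filter,
    demographic_normalize,
    exclude_nonmedical,
    group_by_parent,
    noise_floor,
    summarize_ontology,
)


def _table(areas: dict, blanks=("B1",)):
    feature_ids = list(next(iter(areas.values())).keys()) if areas else []
    sample_ids = list(areas.keys())
    frame = pd.DataFrame(areas).T[feature_ids].T if False else pd.DataFrame(
        {s: [areas[s][f] for f in feature_ids] for s in sample_ids},
        index=feature_ids,
    )
    features = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "mz": np.linspace(100, 200, len(feature_ids)),
            "rt": np.linspace(1, 5, len(feature_ids)),
            "ms2_spectrum_id": [f"sp_{f}" for f in feature_ids],
        }
    )
    samples = pd.DataFrame(
        {
            "is_blank": [s in blanks for s in sample_ids],
            "group": ["g"] * len(sample_ids),
            "age": [35] * len(sample_ids),
            "sex": ["female"] * len(sample_ids),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return FeatureTable(features=features, areas=frame, samples=samples)


class TestBlankFilter:
    def test_fold_rule_on_feature_means_and_cells(self):
        table = _table(
            {
                "S1": {"keep": 1.2e5, "drop": 2.0e4, "edge": 9.0e4},
                "S2": {"keep": 0.8e5, "drop": 2.0e4, "edge": 2.5e4},
                "B1": {"keep": 1.0e4, "drop": 1.0e4, "edge": 1.0e4},
            }
        )
        out = blank_filter(table, fold=3.0)
        kept = set(out.areas.index)
        assert kept == {"keep", "edge"}  # drop: 2e4 < 3 x 1e4
        # cell-level: 2.5e4 < 3 x 1e4 -> zeroed (not detected)
        assert out.areas.loc["edge", "S2"] == 0.0
        assert out.areas.loc["edge", "S1"] == 9.0e4

    def test_requires_blanks(self):
        table = _table({"S1": {"f": 1.0}}, blanks=())
        with pytest.raises(ValueError, match="no-blank-filter"):
            blank_filter(table)


def test_noise_floor_zeroes_small_areas():
    table = _table({"S1": {"a": 5e3, "b": 2e4}, "B1": {"a": 0.0, "b": 0.0}})
    out = noise_floor(table, floor=1e4)
    assert out.areas.loc["a", "S1"] == 0.0
    assert out.areas.loc["b", "S1"] == 2e4
    identity = noise_floor(table, floor=0.0)
    assert identity.areas.equals(table.areas)


def _library():
    def entry(entry_id, annotation_type, parent, sources=("medical",), cls="statin"):
        return DrugLibraryEntry(
            entry_id=entry_id,
            compound_name=entry_id if annotation_type == "drug" else f"x {entry_id}",
            parent_drug=parent,
            annotation_type=annotation_type,
            spectrum=Spectrum(entry_id, 300.0, [(100.0, 1.0)]),
            metadata=PharmMetadata(
                exposure_sources=frozenset(sources),
                pharmacologic_class=cls,
                therapeutic_area="area",
                therapeutic_indication="ind",
                mechanism_of_action="moa",
            ),
            mass_offset=14.0 if annotation_type == "analog" else None,
        )

    return DrugLibrary(
        [
            entry("venlafaxine", "drug", "venlafaxine", cls="SNRI"),
            entry("venlafaxine_m1", "metabolite", "venlafaxine", cls="SNRI"),
            entry("venlafaxine_m2", "metabolite", "venlafaxine", cls="SNRI"),
            entry("darunavir", "drug", "darunavir", cls="antiretroviral"),
            entry("darunavir_an", "analog", "darunavir", cls="antiretroviral"),
            entry("deoxycholic", "drug", "deoxycholic",
                  sources=("medical", "endogenous"), cls="bile acid"),
            entry("simva", "drug", "simva", cls="statin"),
            entry("prava", "drug", "prava", cls="statin"),
        ]
    )


@pytest.fixture()
def grouped():
    library = _library()
    table = _table(
        {
            "S1": {"f_v": 3e5, "f_m1": 1e5, "f_m2": 2e5, "f_da": 0.0,
                   "f_dx": 4e5, "f_s": 2e5, "f_p": 1e5},
            "S2": {"f_v": 0.0, "f_m1": 0.0, "f_m2": 0.0, "f_da": 5e5,
                   "f_dx": 0.0, "f_s": 0.0, "f_p": 0.0},
            "B1": {"f_v": 0.0, "f_m1": 0.0, "f_m2": 0.0, "f_da": 0.0,
                   "f_dx": 0.0, "f_s": 0.0, "f_p": 0.0},
        }
    )
    annotations = pd.DataFrame(
        {
            "feature_id": ["f_v", "f_m1", "f_m2", "f_da", "f_dx", "f_s", "f_p"],
            "entry_id": [
                "venlafaxine", "venlafaxine_m1", "venlafaxine_m2",
                "darunavir_an", "deoxycholic", "simva", "prava",
            ],
        }
    )
    return group_by_parent(annotations, table, library), library


def test_group_by_parent_sums_members_and_detects_analog_only(grouped):
    exposure, _ = grouped
    # venlafaxine + two metabolites collapse into one column
    assert exposure.areas.loc["S1", "venlafaxine"] == pytest.approx(6e5)
    # analog-only detection still flags the parent drug
    assert bool(exposure.detected.loc["S2", "darunavir"])
    assert exposure.areas.loc["S2", "darunavir"] == pytest.approx(5e5)
    assert not bool(exposure.detected.loc["S1", "darunavir"])


def test_exclude_nonmedical_drops_endogenous_columns(grouped):
    exposure, _ = grouped
    reduced, removed = exclude_nonmedical(exposure)
    assert removed == ["deoxycholic"]
    assert "deoxycholic" not in reduced.parent_drugs
    assert "darunavir" in reduced.parent_drugs
    # conservation: every parent is either kept or reported removed
    assert set(exposure.parent_drugs) == set(reduced.parent_drugs) | set(removed)


def test_summarize_ontology_counts_class_once_per_sample(grouped):
    exposure, _ = grouped
    classes = summarize_ontology(exposure, level="pharmacologic_class")
    # two detected statins in S1 -> the class is True, once
    assert bool(classes.loc["S1", "statin"])
    assert not bool(classes.loc["S2", "statin"])
    drugs = summarize_ontology(exposure, level="drug")
    assert drugs.equals(exposure.detected)
    with pytest.raises(ValueError):
        summarize_ontology(exposure, level="constellation")


def test_demographic_normalize_rates():
    summary = pd.DataFrame(
        {"statin": [True] * 5 + [False] * 15},
        index=[f"S{i}" for i in range(20)],
    )
    samples = pd.DataFrame(
        {
            "age": [34] * 20,
            "sex": ["female"] * 20,
            "is_blank": [False] * 20,
        },
        index=summary.index,
    )
    rates = demographic_normalize(summary, samples)
    bin_row = rates[
        (rates["age_bin"] == "30-40") & (rates["level_value"] == "statin")
    ].iloc[0]
    assert bin_row["rate"] == pytest.approx(0.25)
    assert bin_row["group_size"] == 20
    empty_bins = rates[(rates["age_bin"] == "80-90")]
    assert empty_bins["rate"].isna().all()
    assert rates.attrs["excluded"] == []


def test_filter_order_commutes_on_detection_when_floor_below_blank_fold():
    areas = {
        "S1": {"a": 5e4, "b": 8e3, "c": 2.0e5},
        "S2": {"a": 6e4, "b": 9e3, "c": 1.8e5},
        "B1": {"a": 1e4, "b": 1e3, "c": 2e3},
    }
    table = _table(areas)
    fold, floor = 3.0, 1e4  # floor <= fold x blank mean for feature a, c
    one = noise_floor(blank_filter(table, fold), floor)
    two = blank_filter(noise_floor(table, floor), fold)
    assert (one.areas.loc["a"] > 0).equals(two.areas.loc["a"] > 0)
    assert (one.areas.loc["c"] > 0).equals(two.areas.loc["c"] > 0)
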