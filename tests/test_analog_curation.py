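"""The four curation filters, their commutativity, dedup, co-occurrence."""

import itertools

import numpy as np
import pytest

from drugtrace import (
    AnalogCandidate,
    DrugLibrary,
    DrugLibraryEntry,
    MassOffsetEntry,
    MatchResult,
    PharmMetadata,
    Spectrum,
    cooccurrence_fraction,
    dedup_analogs,
    frequency_filter,
    library_match_filter,
    mass_offset_filter,
    run_curation,
    source_filter,
)
from drugtrace.chem_mass import load_mass_offsets


def _drug(name, sources=("medical",), mz=300.0, peaks=None):
    peaks = peaks or [(100.0, 50.0), (150.0, 80.0), (200.0, 20.0),
                      (230.0, 100.0), (260.0, 60.0), (270.0, 10.0)]
    return DrugLibraryEntry(
        entry_id=name, compound_name=name, parent_drug=name,
        annotation_type="drug",
        spectrum=Spectrum(name, mz, peaks),
        metadata=PharmMetadata(exposure_sources=frozenset(sources)),
    )


def _candidate(analog_id, parent, offset, peaks=None, parent_mz=300.0):
    peaks = peaks or [(100.0, 50.0), (150.0, 80.0), (200.0 + offset, 20.0),
                      (230.0 + offset, 100.0), (260.0, 60.0), (270.0, 10.0)]
    spectrum = Spectrum(analog_id, parent_mz + offset, peaks)
    match = MatchResult(
        query_id=parent, target_id=analog_id, score=0.95,
        matched_peaks=6, mass_offset=offset,
    )
    return AnalogCandidate(match=match, parent_drug=parent,
                           analog_spectrum=spectrum)


@pytest.fixture()
def library():
    return DrugLibrary(
        [
            _drug("darunavir"),
            _drug("testosterone", sources=("medical", "endogenous"), mz=289.2),
            _drug("caffeine", sources=("food",), mz=195.1),
        ]
    )


def test_source_filter_drops_endogenous_and_food_parents(library):
    candidates = [
        _candidate("a1", "darunavir", 14.01565),
        _candidate("a2", "testosterone", 14.01565, parent_mz=289.2),
        _candidate("a3", "caffeine", 14.01565, parent_mz=195.1),
    ]
    retained = source_filter(candidates, library)
    assert [c.analog_id for c in retained] == ["a1"]
    assert source_filter([], library) == []
    with pytest.raises(KeyError, match="x"):
        source_filter([_candidate("x", "ghost", 1.0)], library)


def test_mass_offset_filter_tolerance_governs():
    packaged = load_mass_offsets()
    methylated = _candidate("m", "d", 14.0157)
    unexplained = _candidate("u", "d", 100.123)
    assert mass_offset_filter([methylated, unexplained], packaged) == [methylated]
    # a table storing the rounded 14.02 at tiny tolerance rejects +14.0157
    rounded = [MassOffsetEntry(14.02, "methylation", "metabolism")]
    assert mass_offset_filter([methylated], rounded, tol=1e-5) == []
    assert mass_offset_filter([methylated], rounded, tol=0.01) == [methylated]
    with pytest.raises(ValueError):
        mass_offset_filter([methylated], packaged, tol=0.0)


def test_library_match_filter_removes_known_spectra(library):
    ramipril = library["darunavir"]  # stands in for a same-class sibling
    # analog spectrum identical to a library entry -> removed
    twin = AnalogCandidate(
        match=MatchResult("q", "twin", 0.9, 6, 14.0),
        parent_drug="darunavir",
        analog_spectrum=Spectrum("twin", ramipril.spectrum.precursor_mz,
                                 ramipril.spectrum.peaks),
    )
    novel = _candidate("novel", "darunavir", 57.02146,
                       peaks=[(88.0, 10.0), (99.0, 20.0), (111.0, 30.0)])
    retained = library_match_filter([twin, novel], library)
    assert [c.analog_id for c in retained] == ["novel"]
    with pytest.raises(ValueError):
        library_match_filter([novel], DrugLibrary())


def test_frequency_filter_thresholds():
    analog = _candidate("a", "d", 14.01565)
    high = {"fecal_1": {"a": 0.6}}
    low = {"fecal_1": {"a": 0.1}, "plasma_1": {"a": 0.4}}
    assert frequency_filter([analog], high, max_frequency=0.5) == []
    assert frequency_filter([analog], low, max_frequency=0.5) == [analog]
    assert frequency_filter([analog], high, max_frequency=1.0) == [analog]
    with pytest.raises(ValueError):
        frequency_filter([analog], {"x": {"a": 1.2}})


def test_filters_commute_and_conserve(library, rng):
    """Any order of the four filters yields the same retained set."""
    offsets = load_mass_offsets()
    detections = {"ds1": {}}
    pool = []
    parents = ["darunavir", "testosterone", "caffeine"]
    parent_mz = {"darunavir": 300.0, "testosterone": 289.2, "caffeine": 195.1}
    for i in range(30):
        parent = parents[int(rng.integers(0, 3))]
        offset = float(rng.choice([14.01565, 15.994915, -18.010565, 77.7, 123.4]))
        candidate = _candidate(f"c{i:02d}", parent, offset,
                               parent_mz=parent_mz[parent])
        detections["ds1"][candidate.analog_id] = float(rng.random())
        pool.append(candidate)

    filters = [
        lambda cs: source_filter(cs, library),
        lambda cs: mass_offset_filter(cs, offsets),
        lambda cs: library_match_filter(cs, library),
        lambda cs: frequency_filter(cs, detections),
    ]
    reference = None
    for order in itertools.permutations(range(4)):
        current = list(pool)
        for index in order:
            current = filters[index](current)
        ids = {c.analog_id for c in current}
        if reference is None:
            reference = ids
        assert ids == reference
    # subset property and report conservation
    retained, report = run_curation(
        pool, library, offsets, full_library=library, test_detections=detections
    )
    assert {c.analog_id for c in retained} <= {c.analog_id for c in pool}
    assert report.check_conservation()
    assert report.input_count == 30


def test_dedup_collapses_near_identical_spectra():
    a = _candidate("a", "d", 14.01565)
    b = _candidate("b", "d", 14.01565)  # byte-identical peaks
    far = _candidate("far", "d", 24.01565)  # 10 Da away in precursor
    representatives = dedup_analogs([a, b, far], precursor_tol=0.02)
    assert len(representatives) == 2
    assert {c.analog_id for c in representatives} == {"b", "far"} or {
        c.analog_id for c in representatives
    } == {"a", "far"}


def test_dedup_recovers_planted_group_count(rng):
    groups = 4
    candidates = []
    for g in range(groups):
        base_mz = 200.0 + 30.0 * g
        peaks = [(50.0 + 20 * i + g, float(rng.uniform(10, 100))) for i in range(6)]
        for member in range(3):
            candidates.append(
                AnalogCandidate(
                    match=MatchResult("q", f"g{g}m{member}", 0.9, 6, 10.0),
                    parent_drug="d",
                    analog_spectrum=Spectrum(f"g{g}m{member}", base_mz, peaks),
                )
            )
    assert len(dedup_analogs(candidates)) == groups


def test_cooccurrence_fraction_definition():
    detections = {
        "A": {"analog", "parent"},
        "B": {"analog", "parent"},
        "C": {"analog"},
        "D": {"parent"},
    }
    assert cooccurrence_fraction("analog", "parent", detections) == pytest.approx(2 / 3)
    everywhere = {"A": {"analog", "parent"}, "B": {"analog", "parent"}}
    assert cooccurrence_fraction("analog", "parent", everywhere) == 1.0
    assert cooccurrence_fraction("never", "parent", detections) is None
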