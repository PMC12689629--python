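"""Preprocessing, modified cosine (with exhaustive assignment oracle),
analog search and two-tier library search."""

import numpy as np
import pytest

from drugtrace import (
    Spectrum,
    analog_search,
    library_search,
    modified_cosine,
    preprocess_spectrum,
)
from conftest import brute_force_modified_cosine, random_spectrum_pair


class TestPreprocess:
    def test_removes_fragments_near_precursor(self):
        s = Spectrum("s", 346.122, [(340.0, 50.0), (200.0, 10.0)])
        out = preprocess_spectrum(s)
        assert [m for m, _ in out.peaks] == [200.0]

    def test_keeps_top_six_within_window(self):
        peaks = [(100.0 + i, float(i + 1)) for i in range(8)]  # all in one window
        out = preprocess_spectrum(Spectrum("s", 400.0, peaks))
        assert len(out.peaks) == 6
        assert {i for _, i in out.peaks} == {3.0, 4.0, 5.0, 6.0, 7.0, 8.0}

    def test_empty_spectrum_allowed(self):
        out = preprocess_spectrum(Spectrum("s", 400.0, []))
        assert out.peaks == ()


class TestModifiedCosine:
    def test_identical_spectra_score_one(self):
        s = Spectrum("s", 300.0, [(100, 50), (120, 80), (150, 20), (200, 100), (250, 60)])
        r = modified_cosine(s, s)
        assert r.score == pytest.approx(1.0, abs=1e-12)
        assert r.matched_peaks == 5
        assert r.shifted_pairs == 0
        assert r.mass_offset == 0.0

    def test_precursor_shifted_fragments_still_score_one(self):
        delta = 14.0157
        a = Spectrum("a", 300.0, [(100, 50), (120, 80), (150, 20), (200, 100), (250, 60)])
        b = Spectrum(
            "b", 300.0 + delta,
            [(100, 50), (120, 80), (150 + delta, 20), (200 + delta, 100), (250, 60)],
        )
        r = modified_cosine(a, b)
        assert r.score == pytest.approx(1.0, abs=1e-9)
        assert r.shifted_pairs == 2
        assert r.mass_offset == pytest.approx(delta)

    def test_symmetry_and_empty_input(self, rng):
        for _ in range(50):
            a, b = random_spectrum_pair(rng)
            assert modified_cosine(a, b).score == pytest.approx(
                modified_cosine(b, a).score, abs=1e-9
            )
        empty = Spectrum("e", 100.0, [])
        r = modified_cosine(empty, empty)
        assert r.score == 0.0 and r.matched_peaks == 0

    def test_greedy_equals_exhaustive_assignment_on_small_spectra(self, rng):
        """The greedy one-to-one pairing attains the exhaustive maximum-weight
        assignment on randomized analog pairs with <= 8 peaks per spectrum."""
        for _ in range(200):
            a, b = random_spectrum_pair(rng, n_max=8)
            got = modified_cosine(a, b).score
            want = brute_force_modified_cosine(a, b)
            assert got == pytest.approx(want, abs=1e-9)

    def test_matchms_agrees_on_plain_pairs(self, rng):
        """Independent cross-check against the community modified cosine."""
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import ModifiedCosine

        similarity = ModifiedCosine(tolerance=0.02)
        for _ in range(25):
            a, b = random_spectrum_pair(rng, ambiguity=False)
            # matchms scores raw intensities (no sqrt scaling)
            ours = modified_cosine(a, b, scaling="none")
            sa = matchms.Spectrum(
                mz=a.mz, intensities=a.intensity,
                metadata={"precursor_mz": a.precursor_mz},
                metadata_harmonization=False,
            )
            sb = matchms.Spectrum(
                mz=b.mz, intensities=b.intensity,
                metadata={"precursor_mz": b.precursor_mz},
                metadata_harmonization=False,
            )
            theirs = similarity.pair(sa, sb)
            assert ours.score == pytest.approx(float(theirs["score"]), abs=1e-6)
            assert ours.matched_peaks == int(theirs["matches"])


class TestAnalogSearch:
    def _query(self):
        return Spectrum(
            "q", 346.0, [(100, 50), (140, 80), (180, 20), (220, 100), (260, 60), (300, 30)]
        )

    def test_query_against_itself(self):
        q = self._query()
        hits = analog_search(q, [q])
        assert len(hits) == 1
        assert hits[0].score == pytest.approx(1.0)
        assert hits[0].mass_offset == 0.0

    def test_window_excludes_far_precursors(self):
        q = self._query()
        far = Spectrum("far", q.precursor_mz + 250.0, list(q.peaks))
        assert analog_search(q, [far]) == []

    def test_planted_metabolites_recovered_exactly(self, small_library):
        library, truth = small_library
        drugs = [e for e in library if e.annotation_type == "drug"]
        corpus = [e.spectrum for e in library]
        for drug in drugs:
            hits = analog_search(drug.spectrum, corpus, min_peaks=5)
            hit_ids = {h.target_id for h in hits} - {drug.spectrum.spectrum_id}
            expected = {
                met_id
                for met_id, record in truth.metabolites.items()
                if record["parent_drug"] == drug.compound_name
            }
            assert expected <= hit_ids

    def test_threshold_monotonicity(self, rng):
        q = self._query()
        corpus = []
        for i in range(30):
            a, b = random_spectrum_pair(rng)
            corpus.append(b)
        loose = {h.target_id for h in analog_search(q, corpus, min_score=0.2, min_peaks=1)}
        tight = {h.target_id for h in analog_search(q, corpus, min_score=0.6, min_peaks=3)}
        assert tight <= loose


class TestLibrarySearch:
    def test_two_tier_acceptance(self, small_library):
        library, _ = small_library
        entry = library.entries[0]
        exact = entry.spectrum.with_peaks(entry.spectrum.peaks)
        result = library_search([exact], library)
        best = result[result["best"]]
        assert len(best) == 1
        assert best.iloc[0]["entry_id"] == entry.entry_id
        assert best.iloc[0]["score"] == pytest.approx(1.0)
        assert bool(best.iloc[0]["accepted"])

    def test_candidate_below_acceptance_stays_stage_one(self, small_library):
        library, _ = small_library
        entry = library.entries[0]
        # keep enough common peaks for stage 1 but corrupt the rest
        peaks = list(entry.spectrum.peaks)
        corrupted = [
            (mz, inten) if i < 3 else (mz + 0.5, inten * 5)
            for i, (mz, inten) in enumerate(peaks)
        ]
        query = Spectrum("q", entry.spectrum.precursor_mz, corrupted)
        result = library_search([query], library)
        rows = result[result["entry_id"] == entry.entry_id]
        if len(rows):
            row = rows.iloc[0]
            assert row["score"] < 0.9 or row["matched_peaks"] < 5
            assert not row["accepted"]

    def test_empty_library_rejected(self):
        from drugtrace import DrugLibrary

        with pytest.raises(ValueError):
            library_search([Spectrum("q", 100.0, [(50, 1)])], DrugLibrary())
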