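"""Modified-cosine spectral similarity with precursor-shift-aware peak
pairing, plus spectrum preprocessing, analog search, and two-tier library
search.

The modified cosine aligns fragment peaks of two MS/MS spectra where a pair
may match either directly (|mz_a - mz_b| <= tol) or shifted by the precursor
mass difference (|mz_a - mz_b - dPrecursor| <= tol).  Pairs are assigned
one-to-one greedily by descending intensity product on square-root-scaled
intensities, and the score is the normalized dot product of the assigned
pairs — 1.0 for a spectrum against itself, and still 1.0 for a metabolite
whose fragments all shift with the precursor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .drug_library import DrugLibrary
from .spectra_io import Spectrum

__all__ = [
    "MatchResult",
    "preprocess_spectrum",
    "modified_cosine",
    "analog_search",
    "library_search",
]


@dataclass(frozen=True)
class MatchResult:
    """Outcome of aligning a query spectrum to a target spectrum."""

    query_id: str
    target_id: str
    score: float
    matched_peaks: int
    mass_offset: float  # target precursor - query precursor
    shifted_pairs: int = 0
    matched_intensity_fraction: float = 0.0  # of query total, for review flags

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0 + 1e-9:
            raise ValueError(f"score out of [0, 1]: {self.score}")
        if not self.matched_peaks >= self.shifted_pairs >= 0:
            raise ValueError("matched_peaks >= shifted_pairs >= 0 violated")


def preprocess_spectrum(
    s: Spectrum,
    precursor_exclusion: float = 17.0,
    window: float = 50.0,
    top_k: int = 6,
) -> Spectrum:
    """GNPS-style fragment cleanup before matching.

    Removes fragments within ``±precursor_exclusion`` of the precursor m/z
    (residual precursor and neutral-loss satellites), then keeps a peak only
    if it ranks among the ``top_k`` most intense within ``±window`` Da of
    itself.  An empty result is allowed.
    """
    if s.ms_level != 2:
        raise ValueError("preprocessing applies to MS2 spectra")
    peaks = [
        (mz, inten)
        for mz, inten in s.peaks
        if abs(mz - s.precursor_mz) > precursor_exclusion
    ]
    kept = []
    for mz, inten in peaks:
        neighbours = sorted(
            (i2 for m2, i2 in peaks if abs(m2 - mz) <= window), reverse=True
        )
        rank = neighbours.index(inten)
        # ties: a peak survives if any copy of its intensity is inside top_k
        if rank < top_k:
            kept.append((mz, inten))
    return s.with_peaks(kept)


def modified_cosine(
    a: Spectrum, b: Spectrum, frag_tol: float = 0.02, scaling: str = "sqrt"
) -> MatchResult:
    """Precursor-shift-aware cosine similarity between two MS/MS spectra.

    Greedy one-to-one assignment over the eligibility graph: pairs sorted by
    descending intensity product (ties broken by smaller residual |dmz|), each
    peak used at most once across the direct and shifted channels.  Scaling
    is applied to intensities before normalization (``"sqrt"`` by default,
    ``"none"`` for raw intensities).  Symmetric to 1e-9 by construction.
    """
    if frag_tol <= 0:
        raise ValueError("frag_tol must be positive")
    if scaling not in ("sqrt", "none"):
        raise ValueError("scaling must be 'sqrt' or 'none'")
    offset = b.precursor_mz - a.precursor_mz
    if not a.peaks or not b.peaks:
        return MatchResult(a.spectrum_id, b.spectrum_id, 0.0, 0, offset, 0)

    ia = a.intensity
    ib = b.intensity
    if scaling == "sqrt":
        ia, ib = np.sqrt(ia), np.sqrt(ib)
    norm = float(np.linalg.norm(ia) * np.linalg.norm(ib))
    if norm == 0.0:
        return MatchResult(a.spectrum_id, b.spectrum_id, 0.0, 0, offset, 0)

    pairs = []
    for i, mza in enumerate(a.mz):
        for j, mzb in enumerate(b.mz):
            direct = abs(mza - mzb)
            shifted = abs(mzb - mza - offset)
            if direct <= frag_tol or shifted <= frag_tol:
                pairs.append(
                    (float(ia[i] * ib[j]), min(direct, shifted),
                     direct > frag_tol, i, j)
                )
    pairs.sort(key=lambda p: (-p[0], p[1], p[3], p[4]))

    used_a: set[int] = set()
    used_b: set[int] = set()
    total = 0.0
    matched = 0
    shifted_count = 0
    matched_query_intensity = 0.0
    for product, _, is_shifted, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        total += product
        matched += 1
        shifted_count += int(is_shifted)
        matched_query_intensity += a.intensity[i]
    score = min(total / norm, 1.0)
    frac = matched_query_intensity / a.total_intensity if a.total_intensity else 0.0
    return MatchResult(
        a.spectrum_id, b.spectrum_id, score, matched, offset, shifted_count, frac
    )


def analog_search(
    query: Spectrum,
    corpus: list[Spectrum],
    precursor_window: float = 200.0,
    min_score: float = 0.8,
    min_peaks: int = 6,
    frag_tol: float = 0.02,
) -> list[MatchResult]:
    """Find candidate analogs of a drug spectrum in a spectrum corpus.

    A corpus spectrum is a hit when its precursor lies within
    ``±precursor_window`` of the query precursor and the modified cosine
    reaches ``min_score`` with at least ``min_peaks`` matched ions.  Hits are
    sorted by descending score, ties by |mass offset| then target id.
    """
    if not corpus:
        raise ValueError("analog search needs a non-empty corpus")
    hits = []
    for target in corpus:
        if abs(target.precursor_mz - query.precursor_mz) > precursor_window:
            continue
        result = modified_cosine(query, target, frag_tol=frag_tol)
        if result.score >= min_score and result.matched_peaks >= min_peaks:
            hits.append(result)
    hits.sort(key=lambda r: (-r.score, abs(r.mass_offset), r.target_id))
    return hits


def library_search(
    dataset: list[Spectrum],
    library: DrugLibrary,
    precursor_tol: float = 0.02,
    frag_tol: float = 0.02,
    search_min_score: float = 0.7,
    search_min_peaks: int = 2,
    accept_min_score: float = 0.9,
    accept_min_peaks: int = 5,
    preprocess: bool = False,
) -> pd.DataFrame:
    """Two-tier spectral library annotation of a dataset.

    Stage 1 collects candidates at permissive search thresholds with the
    precursor within ``±precursor_tol`` of a library entry; stage 2 accepts
    only candidates reaching the stricter acceptance thresholds.  Each
    dataset spectrum keeps its best accepted entry (higher score, then more
    matched peaks, then lexicographic entry id); both tiers are reported in
    the returned annotation table.
    """
    if len(library) == 0:
        raise ValueError("library search needs a non-empty library")
    entries = library.entries
    rows = []
    for spectrum in dataset:
        query = preprocess_spectrum(spectrum) if preprocess else spectrum
        candidates = []
        for entry in entries:
            if abs(entry.spectrum.precursor_mz - query.precursor_mz) > precursor_tol:
                continue
            result = modified_cosine(query, entry.spectrum, frag_tol=frag_tol)
            if (
                result.score >= search_min_score
                and result.matched_peaks >= search_min_peaks
            ):
                candidates.append((entry, result))
        accepted = [
            (entry, r)
            for entry, r in candidates
            if r.score >= accept_min_score and r.matched_peaks >= accept_min_peaks
        ]
        accepted.sort(key=lambda er: (-er[1].score, -er[1].matched_peaks, er[0].entry_id))
        best_id = accepted[0][0].entry_id if accepted else None
        for entry, r in candidates:
            is_accepted = (
                r.score >= accept_min_score and r.matched_peaks >= accept_min_peaks
            )
            rows.append(
                {
                    "spectrum_id": spectrum.spectrum_id,
                    "entry_id": entry.entry_id,
                    "compound_name": entry.compound_name,
                    "parent_drug": entry.parent_drug,
                    "annotation_type": entry.annotation_type,
                    "score": r.score,
                    "matched_peaks": r.matched_peaks,
                    "mass_offset": r.mass_offset,
                    "accepted": is_accepted,
                    "best": entry.entry_id == best_id,
                }
            )
    columns = [
        "spectrum_id", "entry_id", "compound_name", "parent_drug",
        "annotation_type", "score", "matched_peaks", "mass_offset",
        "accepted", "best",
    ]
    return pd.DataFrame(rows, columns=columns)
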