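"""Four-stage curation of raw analog matches into a drug analog library.

The filters remove analog candidates that cannot be confidently tied to a
drug exposure:

1. source filter   — drop analogs of drugs with endogenous or dietary
                     sources (the source of such molecules is ambiguous);
2. mass-offset filter — keep only precursor mass offsets explainable by a
                     curated table of drug-metabolism deltas and adduct or
                     isotope spacings;
3. library-match filter — drop analog spectra that already match a reference
                     library entry (often a sibling drug of the same class);
4. frequency filter — drop analogs detected in an implausibly large fraction
                     of any test dataset.

The filters are pure set operations on the input matches, so they commute:
any application order yields the same retained set.  A greedy single-linkage
dedup collapses near-identical analog spectra, and a per-file co-occurrence
fraction quantifies how often an analog appears together with its parent
drug.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .chem_mass import MassOffsetEntry
from .drug_library import DrugLibrary
from .spectra_io import Spectrum
from .spectral_match import MatchResult, modified_cosine

__all__ = [
    "AnalogCandidate",
    "CurationReport",
    "source_filter",
    "mass_offset_filter",
    "library_match_filter",
    "frequency_filter",
    "run_curation",
    "dedup_analogs",
    "cooccurrence_fraction",
]


@dataclass(frozen=True)
class AnalogCandidate:
    """A raw analog hit: a drug's reference spectrum aligned to an unknown
    spectrum with a nonzero precursor mass offset."""

    match: MatchResult
    parent_drug: str
    analog_spectrum: Spectrum

    @property
    def analog_id(self) -> str:
        return self.match.target_id

    @property
    def mass_offset(self) -> float:
        return self.match.mass_offset


@dataclass
class CurationReport:
    input_count: int = 0
    removed_by_source: int = 0
    removed_by_offset: int = 0
    removed_by_library_match: int = 0
    removed_by_frequency: int = 0
    removed_as_duplicates: int = 0
    retained_count: int = 0
    labels: dict[str, str] = field(default_factory=dict)  # analog_id -> filter label

    def check_conservation(self) -> bool:
        return self.input_count == (
            self.retained_count
            + self.removed_by_source
            + self.removed_by_offset
            + self.removed_by_library_match
            + self.removed_by_frequency
            + self.removed_as_duplicates
        )

    def to_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "removed_by_source": self.removed_by_source,
            "removed_by_offset": self.removed_by_offset,
            "removed_by_library_match": self.removed_by_library_match,
            "removed_by_frequency": self.removed_by_frequency,
            "removed_as_duplicates": self.removed_as_duplicates,
            "retained_count": self.retained_count,
        }


def source_filter(
    candidates: list[AnalogCandidate], library: DrugLibrary
) -> list[AnalogCandidate]:
    """Drop analogs whose parent drug has endogenous or food sources."""
    unresolved = []
    retained = []
    for c in candidates:
        parent = library.parent_entry(c.parent_drug)
        if parent is None:
            unresolved.append(c.analog_id)
            continue
        if not parent.metadata.is_nonmedical:
            retained.append(c)
    if unresolved:
        raise KeyError(f"parent drugs unresolvable in library for: {unresolved}")
    return retained


def mass_offset_filter(
    candidates: list[AnalogCandidate],
    offsets: list[MassOffsetEntry],
    tol: float = 0.01,
) -> list[AnalogCandidate]:
    """Keep a candidate iff its precursor mass offset sits within ``tol`` of
    a curated offset entry (signed; gains and losses are distinct)."""
    if tol <= 0:
        raise ValueError("offset tolerance must be positive")
    if not offsets:
        raise ValueError("offset table must be non-empty")
    deltas = [o.delta_mass for o in offsets]
    return [
        c
        for c in candidates
        if any(abs(c.mass_offset - d) <= tol for d in deltas)
    ]


def library_match_filter(
    candidates: list[AnalogCandidate],
    full_library: DrugLibrary,
    score_thr: float = 0.7,
    peaks_thr: int = 6,
    precursor_tol: float = 0.02,
    frag_tol: float = 0.02,
) -> list[AnalogCandidate]:
    """Drop analog spectra that spectral-match an entry of the full
    reference library at precursor-level tolerance — these are usually known
    compounds (e.g. a same-class sibling drug), not true unknowns."""
    if len(full_library) == 0:
        raise ValueError("library-match filter needs a non-empty library")
    retained = []
    for c in candidates:
        is_known = False
        for entry in full_library:
            if (
                abs(entry.spectrum.precursor_mz - c.analog_spectrum.precursor_mz)
                > precursor_tol
            ):
                continue
            r = modified_cosine(c.analog_spectrum, entry.spectrum, frag_tol=frag_tol)
            if r.score >= score_thr and r.matched_peaks >= peaks_thr:
                is_known = True
                break
        if not is_known:
            retained.append(c)
    return retained


def frequency_filter(
    candidates: list[AnalogCandidate],
    test_detections: dict[str, dict[str, float]],
    max_frequency: float = 0.5,
) -> list[AnalogCandidate]:
    """Drop analogs detected above ``max_frequency`` in any test dataset.

    ``test_detections`` maps dataset id -> {analog_id -> detection fraction}.
    """
    for dataset_id, fractions in test_detections.items():
        for analog_id, fraction in fractions.items():
            if not 0.0 <= fraction <= 1.0:
                raise ValueError(
                    f"detection fraction out of [0,1] for {analog_id!r} "
                    f"in {dataset_id!r}: {fraction}"
                )
    retained = []
    for c in candidates:
        offending = [
            dataset_id
            for dataset_id, fractions in test_detections.items()
            if fractions.get(c.analog_id, 0.0) > max_frequency
        ]
        if not offending:
            retained.append(c)
    return retained


def run_curation(
    candidates: list[AnalogCandidate],
    library: DrugLibrary,
    offsets: list[MassOffsetEntry],
    full_library: DrugLibrary | None = None,
    test_detections: dict[str, dict[str, float]] | None = None,
    offset_tol: float = 0.01,
    library_score_thr: float = 0.7,
    library_peaks_thr: int = 6,
    max_frequency: float = 0.5,
    dedup_precursor_tol: float = 0.02,
    dedup_min_score: float = 0.95,
) -> tuple[list[AnalogCandidate], CurationReport]:
    """Apply the four filters in order, then dedup, with a conservation-
    checked report.  Each removed candidate is labeled with the first filter
    that rejected it (the filters commute, so the label is bookkeeping, not
    semantics)."""
    report = CurationReport(input_count=len(candidates))

    after_source = source_filter(candidates, library)
    removed = {c.analog_id for c in candidates} - {c.analog_id for c in after_source}
    report.removed_by_source = len(candidates) - len(after_source)
    report.labels.update({a: "source" for a in removed})

    after_offset = mass_offset_filter(after_source, offsets, tol=offset_tol)
    removed = {c.analog_id for c in after_source} - {c.analog_id for c in after_offset}
    report.removed_by_offset = len(after_source) - len(after_offset)
    report.labels.update({a: "mass_offset" for a in removed})

    after_library = after_offset
    if full_library is not None and len(full_library):
        after_library = library_match_filter(
            after_offset, full_library,
            score_thr=library_score_thr, peaks_thr=library_peaks_thr,
        )
        removed = {c.analog_id for c in after_offset} - {
            c.analog_id for c in after_library
        }
        report.removed_by_library_match = len(after_offset) - len(after_library)
        report.labels.update({a: "library_match" for a in removed})

    after_frequency = after_library
    if test_detections:
        after_frequency = frequency_filter(
            after_library, test_detections, max_frequency=max_frequency
        )
        removed = {c.analog_id for c in after_library} - {
            c.analog_id for c in after_frequency
        }
        report.removed_by_frequency = len(after_library) - len(after_frequency)
        report.labels.update({a: "frequency" for a in removed})

    deduped = dedup_analogs(
        after_frequency, precursor_tol=dedup_precursor_tol,
        min_score=dedup_min_score,
    )
    removed = {c.analog_id for c in after_frequency} - {
        c.analog_id for c in deduped
    }
    report.removed_as_duplicates = len(after_frequency) - len(deduped)
    report.labels.update({a: "duplicate" for a in removed})

    report.retained_count = len(deduped)
    report.labels.update({c.analog_id: "retained" for c in deduped})
    assert report.check_conservation()
    return deduped, report


def dedup_analogs(
    candidates: list[AnalogCandidate],
    precursor_tol: float = 0.02,
    min_score: float = 0.95,
    frag_tol: float = 0.02,
) -> list[AnalogCandidate]:
    """Collapse near-identical analog spectra by greedy single linkage.

    Two analogs join one group when their precursors agree within
    ``precursor_tol`` and their plain cosine (modified cosine at offset zero)
    reaches ``min_score``.  The highest-total-intensity spectrum represents
    each group.
    """
    n = len(candidates)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = candidates[i].analog_spectrum, candidates[j].analog_spectrum
            if abs(a.precursor_mz - b.precursor_mz) > precursor_tol:
                continue
            # offset-zero comparison: force equal precursors for the scorer
            b_zero = replace(b, precursor_mz=a.precursor_mz)
            r = modified_cosine(a, b_zero, frag_tol=frag_tol)
            if r.score >= min_score:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    representatives = []
    for members in groups.values():
        best = max(
            members,
            key=lambda i: (
                candidates[i].analog_spectrum.total_intensity,
                candidates[i].analog_id,
            ),
        )
        representatives.append(candidates[best])
    representatives.sort(key=lambda c: c.analog_id)
    return representatives


def cooccurrence_fraction(
    analog_id: str,
    parent_drug: str,
    detections: dict[str, set[str]],
) -> float | None:
    """Fraction of data files containing the analog that also contain its
    parent drug.  ``detections`` maps file id -> set of detected ids (analog
    ids and parent drug names share the namespace of the caller).  Returns
    ``None`` when the analog is never detected."""
    analog_files = {f for f, ids in detections.items() if analog_id in ids}
    if not analog_files:
        return None
    both = sum(1 for f in analog_files if parent_drug in detections[f])
    return both / len(analog_files)
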