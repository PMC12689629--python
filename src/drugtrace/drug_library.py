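"""Drug library data model: entries with controlled-vocabulary pharmacologic
metadata, identifier/name matching, and parent-metadata inheritance.

An entry is a reference MS/MS spectrum bound to a drug, drug-metabolite, or
propagated-analog record.  Metabolite and analog entries inherit the
pharmacologic metadata of their parent drug verbatim, so that exposure
summaries can collapse everything onto the administered compound.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import pandas as pd

from .spectra_io import Spectrum, read_mgf, write_mgf

__all__ = [
    "EXPOSURE_SOURCES",
    "ANNOTATION_TYPES",
    "PharmMetadata",
    "DrugLibraryEntry",
    "DrugLibrary",
    "UnresolvedParentError",
    "match_identifier",
    "partial_name_match",
    "inherit_metadata",
]

#: Controlled vocabulary of exposure sources.
EXPOSURE_SOURCES = frozenset(
    {"medical", "endogenous", "food", "personal care", "industrial"}
)
ANNOTATION_TYPES = frozenset({"drug", "metabolite", "analog"})

#: Sources that disqualify a drug from exposure reasoning: a detection cannot
#: be attributed to medication when the compound is endogenous or dietary.
NONMEDICAL_SOURCES = frozenset({"endogenous", "food"})

_INCHIKEY = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")


class UnresolvedParentError(KeyError):
    """A metabolite/analog entry references a parent drug not in the library."""


@dataclass(frozen=True)
class PharmMetadata:
    """Controlled-vocabulary pharmacologic annotations of one drug."""

    exposure_sources: frozenset[str] = frozenset()
    therapeutic_area: str = ""
    pharmacologic_class: str = ""
    therapeutic_indication: str = ""
    mechanism_of_action: str = ""
    clinical_phase: str | None = None

    def __post_init__(self) -> None:
        sources = frozenset(self.exposure_sources)
        unknown = sources - EXPOSURE_SOURCES
        if unknown:
            raise ValueError(
                f"unknown exposure sources {sorted(unknown)}; "
                f"vocabulary: {sorted(EXPOSURE_SOURCES)}"
            )
        object.__setattr__(self, "exposure_sources", sources)

    @property
    def is_empty(self) -> bool:
        return not (
            self.exposure_sources
            or self.therapeutic_area
            or self.pharmacologic_class
            or self.therapeutic_indication
            or self.mechanism_of_action
        )

    @property
    def is_nonmedical(self) -> bool:
        return bool(self.exposure_sources & NONMEDICAL_SOURCES)


@dataclass(frozen=True)
class DrugLibraryEntry:
    entry_id: str
    compound_name: str
    parent_drug: str
    annotation_type: str
    spectrum: Spectrum
    metadata: PharmMetadata = field(default_factory=PharmMetadata)
    smiles: str | None = None
    inchikey: str | None = None
    mass_offset: float | None = None  # analog entries: precursor - parent precursor

    def __post_init__(self) -> None:
        if self.annotation_type not in ANNOTATION_TYPES:
            raise ValueError(f"annotation_type must be one of {sorted(ANNOTATION_TYPES)}")
        if self.annotation_type == "drug" and self.parent_drug != self.compound_name:
            raise ValueError(
                f"{self.entry_id}: a drug entry is its own parent "
                f"({self.parent_drug!r} != {self.compound_name!r})"
            )
        if self.annotation_type == "analog" and self.mass_offset is None:
            raise ValueError(f"{self.entry_id}: analog entries carry a mass_offset")
        if self.inchikey is not None and not _INCHIKEY.match(self.inchikey):
            raise ValueError(f"{self.entry_id}: malformed InChIKey {self.inchikey!r}")


def normalize_name(name: str) -> str:
    """Lower-case, trim, collapse internal whitespace.  No stemming."""
    return " ".join(name.strip().lower().split())


def match_identifier(query: str, registry: pd.DataFrame) -> list[dict]:
    """Match a compound identifier against a registry table.

    ``registry`` rows carry an ``inchikey`` column and a ``synonyms`` column
    (list of names or ``;``-separated string).  Hits are ranked: exact
    full-InChIKey, then first-block (stereochemistry-stripped) InChIKey, then
    case-insensitive synonym.  Each hit records its match kind and whether it
    is exact.
    """
    if not query or not query.strip():
        raise ValueError("empty identifier query")
    query = query.strip()
    looks_like_key = bool(_INCHIKEY.match(query)) or bool(
        re.match(r"^[A-Z]{14}$", query)
    )
    hits: list[dict] = []
    for idx, row in registry.iterrows():
        key = row.get("inchikey") or ""
        synonyms = row.get("synonyms") or []
        if isinstance(synonyms, str):
            synonyms = [s for s in synonyms.split(";") if s]
        if looks_like_key and key:
            if query == key:
                hits.append({"row": idx, "kind": "inchikey", "exact": True, "rank": 0})
                continue
            if query.split("-")[0] == key.split("-")[0]:
                hits.append(
                    {"row": idx, "kind": "inchikey_first_block", "exact": False,
                     "rank": 1}
                )
                continue
        if not looks_like_key:
            names = {normalize_name(s) for s in synonyms}
            if normalize_name(query) in names:
                hits.append({"row": idx, "kind": "synonym", "exact": False, "rank": 2})
    hits.sort(key=lambda h: (h["rank"], str(h["row"])))
    return hits


def partial_name_match(drug_name: str, candidate_names: list[str]) -> list[str]:
    """Candidates whose name contains the full drug name as a substring
    (case-insensitive), excluding the exact name itself.

    This is how metabolite records are attached to a parent drug by name:
    searching "venlafaxine" returns "N-desmethylvenlafaxine" and the like.
    """
    if not drug_name:
        raise ValueError("empty drug name")
    needle = normalize_name(drug_name)
    return [
        c
        for c in candidate_names
        if needle in normalize_name(c) and normalize_name(c) != needle
    ]


class DrugLibrary:
    """An ordered collection of :class:`DrugLibraryEntry`, keyed by entry_id."""

    def __init__(self, entries: list[DrugLibraryEntry] = ()):  # type: ignore[assignment]
        self._entries: dict[str, DrugLibraryEntry] = {}
        for entry in entries:
            self.add(entry)

    def add(self, entry: DrugLibraryEntry) -> None:
        if entry.entry_id in self._entries:
            raise ValueError(f"duplicate entry_id {entry.entry_id!r}")
        self._entries[entry.entry_id] = entry

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def __contains__(self, entry_id: str) -> bool:
        return entry_id in self._entries

    def __getitem__(self, entry_id: str) -> DrugLibraryEntry:
        return self._entries[entry_id]

    def get(self, entry_id: str) -> DrugLibraryEntry | None:
        return self._entries.get(entry_id)

    @property
    def entries(self) -> list[DrugLibraryEntry]:
        return list(self._entries.values())

    def parent_entry(self, parent_drug: str) -> DrugLibraryEntry | None:
        """The drug-type entry for a parent compound name, if present."""
        for entry in self._entries.values():
            if entry.annotation_type == "drug" and entry.compound_name == parent_drug:
                return entry
        return None

    def spectra(self) -> list[Spectrum]:
        return [e.spectrum for e in self._entries.values()]

    def missing_metadata_report(self) -> list[str]:
        """Entry ids with empty pharmacologic metadata (e.g. withdrawn or
        never-marketed drugs); every entry must be here or carry metadata."""
        return [e.entry_id for e in self._entries.values() if e.metadata.is_empty]

    # ---- disk round-trip: MGF spectra + CSV metadata keyed by entry_id ----

    _CSV_COLUMNS = [
        "entry_id", "compound_name", "parent_drug", "annotation_type",
        "exposure_sources", "therapeutic_area", "pharmacologic_class",
        "therapeutic_indication", "mechanism_of_action", "clinical_phase",
        "smiles", "inchikey", "mass_offset",
    ]

    def write(self, mgf_path: str, csv_path: str) -> None:
        spectra = []
        rows = []
        for e in self._entries.values():
            spectra.append(replace(e.spectrum, spectrum_id=e.entry_id))
            rows.append(
                {
                    "entry_id": e.entry_id,
                    "compound_name": e.compound_name,
                    "parent_drug": e.parent_drug,
                    "annotation_type": e.annotation_type,
                    "exposure_sources": ";".join(sorted(e.metadata.exposure_sources)),
                    "therapeutic_area": e.metadata.therapeutic_area,
                    "pharmacologic_class": e.metadata.pharmacologic_class,
                    "therapeutic_indication": e.metadata.therapeutic_indication,
                    "mechanism_of_action": e.metadata.mechanism_of_action,
                    "clinical_phase": e.metadata.clinical_phase or "",
                    "smiles": e.smiles or "",
                    "inchikey": e.inchikey or "",
                    "mass_offset": "" if e.mass_offset is None else e.mass_offset,
                }
            )
        write_mgf(spectra, mgf_path)
        pd.DataFrame(rows, columns=self._CSV_COLUMNS).to_csv(csv_path, index=False)

    @classmethod
    def read(cls, mgf_path: str, csv_path: str) -> "DrugLibrary":
        spectra = {s.spectrum_id: s for s in read_mgf(mgf_path)}
        meta = pd.read_csv(csv_path, keep_default_na=False)
        library = cls()
        for _, row in meta.iterrows():
            entry_id = str(row["entry_id"])
            if entry_id not in spectra:
                raise ValueError(f"{csv_path}: no spectrum for entry {entry_id!r}")
            sources = frozenset(
                s for s in str(row["exposure_sources"]).split(";") if s
            )
            offset = row.get("mass_offset", "")
            library.add(
                DrugLibraryEntry(
                    entry_id=entry_id,
                    compound_name=row["compound_name"],
                    parent_drug=row["parent_drug"],
                    annotation_type=row["annotation_type"],
                    spectrum=spectra[entry_id],
                    metadata=PharmMetadata(
                        exposure_sources=sources,
                        therapeutic_area=row.get("therapeutic_area", ""),
                        pharmacologic_class=row.get("pharmacologic_class", ""),
                        therapeutic_indication=row.get("therapeutic_indication", ""),
                        mechanism_of_action=row.get("mechanism_of_action", ""),
                        clinical_phase=row.get("clinical_phase") or None,
                    ),
                    smiles=row.get("smiles") or None,
                    inchikey=row.get("inchikey") or None,
                    mass_offset=float(offset) if offset != "" else None,
                )
            )
        return library


def inherit_metadata(
    entry: DrugLibraryEntry, parents: DrugLibrary
) -> DrugLibraryEntry:
    """Copy the parent drug's pharmacologic metadata onto a metabolite or
    analog entry, verbatim.  Idempotent; the parent is never modified."""
    if entry.annotation_type == "drug":
        return entry
    parent = parents.parent_entry(entry.parent_drug)
    if parent is None:
        raise UnresolvedParentError(
            f"entry {entry.entry_id!r}: parent drug {entry.parent_drug!r} "
            "not found in library"
        )
    return replace(entry, metadata=parent.metadata)
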