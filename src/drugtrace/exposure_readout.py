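"""Turn an annotated feature table into per-sample drug-exposure records and
ontology-level summaries.

Pipeline: blank filtering (features must exceed a fold-change over
laboratory blanks) and a noise floor on peak areas, then grouping of drug /
metabolite / analog annotations onto parent drugs, removal of parents with
endogenous or dietary sources, summarization at a chosen ontology level
(drug, pharmacologic class, therapeutic area, indication, mechanism), and
demographic normalization by 10-year age bin and sex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .drug_library import DrugLibrary
from .spectra_io import FeatureTable

__all__ = [
    "ExposureTable",
    "blank_filter",
    "noise_floor",
    "group_by_parent",
    "exclude_nonmedical",
    "summarize_ontology",
    "demographic_normalize",
    "AGE_BINS",
]

ONTOLOGY_LEVELS = {
    "drug": None,
    "pharmacologic_class": "pharmacologic_class",
    "therapeutic_area": "therapeutic_area",
    "indication": "therapeutic_indication",
    "mechanism": "mechanism_of_action",
}

#: 10-year age intervals covering 0-90.
AGE_BINS = [(lo, lo + 10) for lo in range(0, 90, 10)]


@dataclass
class ExposureTable:
    """Samples x parent drugs: detection flags and summed peak areas.

    ``areas`` and ``detected`` are DataFrames indexed by sample id with one
    column per parent drug; ``drug_metadata`` maps parent drug -> metadata
    fields; ``samples`` carries demographics.
    """

    areas: pd.DataFrame
    detected: pd.DataFrame
    drug_metadata: pd.DataFrame
    samples: pd.DataFrame
    long: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if (self.areas.to_numpy() < 0).any():
            raise ValueError("negative summed areas")
        bad = self.detected.to_numpy() & ~(self.areas.to_numpy() > 0)
        if bad.any():
            raise ValueError("detected cells must have positive summed area")

    @property
    def parent_drugs(self) -> list[str]:
        return list(self.areas.columns)


def blank_filter(ft: FeatureTable, fold: float = 3.0) -> FeatureTable:
    """Remove features not exceeding ``fold`` x the mean blank area, and mark
    cells as detected only above that same threshold.

    A feature survives when its mean area across (non-blank) samples is at
    least ``fold`` times its mean area across blanks.  In surviving features,
    a cell below ``fold`` x blank mean is zeroed (not detected).
    """
    blanks = ft.blank_ids
    if not blanks:
        raise ValueError(
            "blank_filter needs at least one blank sample; "
            "use --no-blank-filter to skip blank subtraction"
        )
    samples = ft.sample_ids
    blank_mean = ft.areas[blanks].mean(axis=1)
    sample_mean = ft.areas[samples].mean(axis=1)
    keep = sample_mean >= fold * blank_mean
    out = ft.copy()
    out.features = out.features[keep.values].reset_index(drop=True)
    out.areas = out.areas.loc[keep]
    threshold = fold * blank_mean.loc[keep]
    zeroed = out.areas[samples].where(
        out.areas[samples].gt(threshold, axis=0), 0.0
    )
    out.areas = pd.concat([zeroed, out.areas[blanks]], axis=1)[ft.areas.columns]
    return out


def noise_floor(ft: FeatureTable, floor: float = 1e4) -> FeatureTable:
    """Replace peak areas below ``floor`` with zero (instrument noise)."""
    if floor < 0:
        raise ValueError("noise floor must be non-negative")
    out = ft.copy()
    out.areas = ft.areas.where(ft.areas >= floor, 0.0)
    return out


def group_by_parent(
    annotations: pd.DataFrame, ft: FeatureTable, library: DrugLibrary
) -> ExposureTable:
    """Collapse drug/metabolite/analog annotations onto parent drugs.

    ``annotations`` is the accepted tier of a library search joined to
    features: columns feature_id, entry_id.  Per sample and parent drug the
    summed area runs over every annotated member feature; the drug counts as
    detected when any member has area > 0 — an analog-only detection still
    marks the parent drug as detected.
    """
    samples = ft.sample_ids
    sample_meta = ft.samples.loc[samples]
    rows = []
    for _, ann in annotations.iterrows():
        entry = library.get(str(ann["entry_id"]))
        if entry is None:
            raise KeyError(f"annotation references unknown entry {ann['entry_id']!r}")
        feature_id = str(ann["feature_id"])
        if feature_id not in ft.areas.index:
            raise KeyError(f"annotation references unknown feature {feature_id!r}")
        rows.append(
            {
                "feature_id": feature_id,
                "entry_id": entry.entry_id,
                "parent_drug": entry.parent_drug,
                "annotation_type": entry.annotation_type,
            }
        )
    long = pd.DataFrame(
        rows, columns=["feature_id", "entry_id", "parent_drug", "annotation_type"]
    )
    parents = sorted(long["parent_drug"].unique()) if len(long) else []
    areas = pd.DataFrame(0.0, index=samples, columns=parents)
    for parent, members in long.groupby("parent_drug"):
        member_areas = ft.areas.loc[members["feature_id"].unique(), samples]
        areas[parent] = member_areas.sum(axis=0).values
    detected = areas > 0
    meta_rows = {}
    for parent in parents:
        entry = library.parent_entry(parent)
        md = entry.metadata if entry is not None else None
        meta_rows[parent] = {
            "exposure_sources": ";".join(sorted(md.exposure_sources)) if md else "",
            "pharmacologic_class": md.pharmacologic_class if md else "",
            "therapeutic_area": md.therapeutic_area if md else "",
            "therapeutic_indication": md.therapeutic_indication if md else "",
            "mechanism_of_action": md.mechanism_of_action if md else "",
            "nonmedical": md.is_nonmedical if md else False,
        }
    drug_metadata = pd.DataFrame.from_dict(meta_rows, orient="index")
    return ExposureTable(
        areas=areas, detected=detected, drug_metadata=drug_metadata,
        samples=sample_meta, long=long,
    )


def exclude_nonmedical(et: ExposureTable) -> tuple[ExposureTable, list[str]]:
    """Drop parent-drug columns with endogenous or food exposure sources.

    Such detections cannot be attributed to medication.  Returns the reduced
    table and the list of removed drugs.
    """
    removed = [
        drug
        for drug in et.parent_drugs
        if bool(et.drug_metadata.loc[drug, "nonmedical"])
    ]
    kept = [d for d in et.parent_drugs if d not in removed]
    long = et.long[~et.long["parent_drug"].isin(removed)] if len(et.long) else et.long
    reduced = ExposureTable(
        areas=et.areas[kept],
        detected=et.detected[kept],
        drug_metadata=et.drug_metadata.loc[kept],
        samples=et.samples,
        long=long,
    )
    return reduced, removed


def summarize_ontology(et: ExposureTable, level: str = "drug") -> pd.DataFrame:
    """Per-sample detection matrix at an ontology level.

    At ``level="drug"`` this is the detection matrix itself.  At coarser
    levels each value (e.g. a pharmacologic class) is counted at most once
    per sample regardless of how many member drugs were detected; drugs with
    missing metadata at that level go to an ``"unclassified"`` bucket with a
    warning.
    """
    if level not in ONTOLOGY_LEVELS:
        raise ValueError(f"level must be one of {sorted(ONTOLOGY_LEVELS)}")
    if level == "drug":
        return et.detected.copy()
    column = ONTOLOGY_LEVELS[level]
    values = {}
    unclassified = []
    for drug in et.parent_drugs:
        value = str(et.drug_metadata.loc[drug, column]) if column else drug
        if not value or value == "nan":
            unclassified.append(drug)
            value = "unclassified"
        values[drug] = value
    if unclassified:
        warnings.warn(
            f"no {level} metadata for {sorted(unclassified)}; "
            "routed to 'unclassified'"
        )
    buckets = sorted(set(values.values()))
    summary = pd.DataFrame(False, index=et.detected.index, columns=buckets)
    for drug, value in values.items():
        summary[value] |= et.detected[drug]
    return summary


def demographic_normalize(
    summary: pd.DataFrame, samples: pd.DataFrame
) -> pd.DataFrame:
    """Detection rates per (age bin, sex) group.

    Returns a long table: age_bin, sex, level value, n_detected, group_size,
    rate = detections / group size.  Samples with missing age/sex or age
    outside 0-90 are excluded (their ids are reported in the ``excluded``
    attribute of the result).
    """
    meta = samples.loc[summary.index]
    age = pd.to_numeric(meta.get("age"), errors="coerce")
    sex = meta.get("sex")
    valid = age.notna() & sex.notna() & (age >= 0) & (age < 90)
    excluded = list(summary.index[~valid])
    rows = []
    for (lo, hi) in AGE_BINS:
        in_bin = valid & (age >= lo) & (age < hi)
        for sex_value in sorted(sex[valid].dropna().unique()):
            members = summary.index[in_bin & (sex == sex_value)]
            group_size = len(members)
            for value in summary.columns:
                n_detected = int(summary.loc[members, value].sum()) if group_size else 0
                rows.append(
                    {
                        "age_bin": f"{lo}-{hi}",
                        "sex": sex_value,
                        "level_value": value,
                        "n_detected": n_detected,
                        "group_size": group_size,
                        "rate": n_detected / group_size if group_size else np.nan,
                    }
                )
    result = pd.DataFrame(rows)
    result.attrs["excluded"] = excluded
    return result
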