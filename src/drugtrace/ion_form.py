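"""Classify curated analogs as isotopes, adducts, in-source fragments, or
candidate drug derivatives.

Three-stage decision procedure per analog-drug pair:

1. mass-offset rule — isotope spacings (+1.003355 / +2.006710 Da) and the
   sodium/calcium/potassium adduct spacings are assigned directly;
2. peak-shape correlation — for pairs co-occurring in at least one run, the
   maximum squared Pearson correlation between the two extracted-ion
   chromatograms (10 consecutive MS1 scans centered on the apex) decides:
   R² above the threshold means a co-eluting analytical artifact (adduct for
   a positive offset, in-source fragment for a negative one), otherwise a
   drug derivative with an independent elution apex;
3. fragment evidence — for pairs never observed together, an analog whose
   fragment hits the drug's precursor m/z is an adduct; an analog whose
   precursor hits a drug fragment m/z is an in-source fragment.

Anything left is a candidate derivative by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spectra_io import Spectrum

__all__ = [
    "XICTrace",
    "IonFormLabel",
    "ISOTOPE_OFFSETS",
    "ADDUCT_OFFSETS",
    "classify_by_mass_offset",
    "peak_shape_correlation",
    "fragment_evidence",
    "classify_ion_form",
]

ISOTOPE_OFFSETS = {"+1.00": 1.003355, "+2.00": 2.006710}
ADDUCT_OFFSETS = {
    "adduct_Na": 21.981945,  # Na - H
    "adduct_Ca": 37.946941,  # Ca - 2H
    "adduct_K": 37.955882,   # K - H
}

LABELS = frozenset({"isotope", "adduct", "in_source_fragment", "derivative"})
EVIDENCE = frozenset({"mass_offset", "peak_shape", "fragment_match", "default"})


@dataclass(frozen=True)
class XICTrace:
    """Extracted-ion-chromatogram intensities across consecutive MS1 scans,
    nominally 10 scans centered on the chromatographic apex."""

    target_mz: float
    points: tuple[tuple[int, float], ...]  # (scan_index, intensity)

    def __post_init__(self) -> None:
        points = tuple((int(s), float(i)) for s, i in self.points)
        indices = [s for s, _ in points]
        if any(i < 0 for _, i in points):
            raise ValueError("negative trace intensity")
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValueError("scan indices must be strictly increasing")
        object.__setattr__(self, "points", points)

    @property
    def intensities(self) -> np.ndarray:
        return np.array([i for _, i in self.points])

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class IonFormLabel:
    label: str
    evidence: str
    detail: str = ""

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {sorted(LABELS)}")
        if self.evidence not in EVIDENCE:
            raise ValueError(f"evidence must be one of {sorted(EVIDENCE)}")
        if self.label == "isotope" and self.evidence != "mass_offset":
            raise ValueError("isotopes are assigned by mass offset only")
        if self.label == "in_source_fragment" and self.evidence == "mass_offset":
            raise ValueError("in-source fragments are never assigned by mass offset")


def classify_by_mass_offset(delta: float, tol: float = 0.01) -> str:
    """Stage 1: named isotope/adduct spacing nearest ``delta`` within
    ``tol``, else ``"none"``.  Returns one of
    {isotope, adduct_Na, adduct_Ca, adduct_K, none}."""
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    named = [("isotope", v) for v in ISOTOPE_OFFSETS.values()]
    named += list(ADDUCT_OFFSETS.items())
    best = min(named, key=lambda nv: abs(delta - nv[1]))
    return best[0] if abs(delta - best[1]) <= tol else "none"


def peak_shape_correlation(
    trace_drug: XICTrace, trace_analog: XICTrace
) -> float | None:
    """Stage 2 statistic: squared Pearson correlation of the two XIC
    intensity profiles.  Returns ``None`` (with a warning) when either trace
    is constant, where the correlation is undefined."""
    if len(trace_drug) != len(trace_analog):
        raise ValueError("traces must cover the same scans")
    if len(trace_drug) < 3:
        raise ValueError("need at least 3 scans for a peak-shape correlation")
    x = trace_drug.intensities
    y = trace_analog.intensities
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant XIC trace; peak-shape correlation undefined")
        return None
    r, _ = stats.pearsonr(x, y)
    return float(r * r)


def fragment_evidence(
    drug: Spectrum, analog: Spectrum, tol: float = 0.02
) -> str:
    """Stage 3: MS/MS cross-evidence for non-co-occurring pairs.

    No intensity filtering is applied.  Returns one of
    {adduct, in_source_fragment, none}.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if analog.precursor_mz > drug.precursor_mz:
        if any(abs(mz - drug.precursor_mz) <= tol for mz, _ in analog.peaks):
            return "adduct"
    elif analog.precursor_mz < drug.precursor_mz:
        if any(abs(analog.precursor_mz - mz) <= tol for mz, _ in drug.peaks):
            return "in_source_fragment"
    return "none"


def classify_ion_form(
    mass_offset: float,
    drug_spectrum: Spectrum,
    analog_spectrum: Spectrum,
    cooccurring_traces: list[tuple[XICTrace, XICTrace]] = (),  # type: ignore[assignment]
    r2_threshold: float = 0.9,
    offset_tol: float = 0.01,
    frag_tol: float = 0.02,
) -> IonFormLabel:
    """Full three-stage decision for one analog-drug pair.

    ``cooccurring_traces`` holds one ``(drug_trace, analog_trace)`` pair per
    file in which both were observed; the maximum R² across files is used.
    R² exactly at the threshold counts as a derivative (the artifact call
    requires strictly greater).
    """
    stage1 = classify_by_mass_offset(mass_offset, tol=offset_tol)
    if stage1 == "isotope":
        return IonFormLabel("isotope", "mass_offset", f"{mass_offset:+.2f}")
    if stage1.startswith("adduct_"):
        return IonFormLabel("adduct", "mass_offset", stage1.removeprefix("adduct_"))

    r2_values = []
    for trace_drug, trace_analog in cooccurring_traces:
        r2 = peak_shape_correlation(trace_drug, trace_analog)
        if r2 is not None:
            r2_values.append(r2)
    if r2_values:
        max_r2 = max(r2_values)
        detail = f"max R2={max_r2:.3f}"
        if max_r2 > r2_threshold:
            label = "adduct" if mass_offset > 0 else "in_source_fragment"
            return IonFormLabel(label, "peak_shape", detail)
        return IonFormLabel("derivative", "peak_shape", detail)

    verdict = fragment_evidence(drug_spectrum, analog_spectrum, tol=frag_tol)
    if verdict != "none":
        return IonFormLabel(verdict, "fragment_match")
    return IonFormLabel("derivative", "default")
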