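"""Mitochondrial disease criteria (MDC) score for children.

Three sections — clinical signs and symptoms, metabolic abnormalities and
neuroimaging, histologic anomalies — each contribute up to 4 points; the
total (0-12) bins the likelihood of mitochondrial disease and assigns the
patient group used for cohort stratification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

SECTION_MAX = 4

#: total -> likelihood bin; 0 maps to "unlikely" (extension of the published
#: 1/2-4/5-7/8-12 boundaries to cover the degenerate no-points case).
BINS = (
    (0, 1, "unlikely"),
    (2, 4, "possible"),
    (5, 7, "probable"),
    (8, 12, "definite"),
)


@dataclass(frozen=True)
class MDCScore:
    clinical: int
    metabolic_imaging: int
    histology: int
    total: int
    bin: str
    group: int


def score_mdc(
    clinical: int, metabolic_imaging: int, histology: int, *, group_threshold: int = 5
) -> MDCScore:
    """Compute the MDC total, likelihood bin and patient group.

    Sections above 4 points are capped with a warning; group is 1 when the
    total reaches ``group_threshold`` (default 5, i.e. probable or definite
    mitochondrial disease), else 2.
    """
    sections = []
    for name, value in (
        ("clinical", clinical),
        ("metabolic_imaging", metabolic_imaging),
        ("histology", histology),
    ):
        if value < 0:
            raise ValueError(f"MDC section {name} is negative: {value}")
        if value > SECTION_MAX:
            warnings.warn(f"MDC section {name}={value} capped at {SECTION_MAX}", stacklevel=2)
            value = SECTION_MAX
        sections.append(value)
    total = sum(sections)
    for lo, hi, label in BINS:
        if lo <= total <= hi:
            bin_label = label
            break
    return MDCScore(
        clinical=sections[0],
        metabolic_imaging=sections[1],
        histology=sections[2],
        total=total,
        bin=bin_label,
        group=1 if total >= group_threshold else 2,
    )
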