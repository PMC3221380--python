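"""Packaged diagnostic-accuracy contingency counts from the reference
smartphone reading study.

Each row gives one reader x finding cell: true/false positives and
negatives of the handheld reading against the workstation ground truth,
together with the sensitivity / specificity / accuracy percentages as
printed (printed values are truncated, not rounded, to the shown
decimals). Interrater kappa was perfect (1.0) for hemorrhage and for CTA
vessel occlusion, where both readers made identical calls including the
same single missed vertebral-artery (V4) occlusion.
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class StudyRow:
    reader: int
    finding: str
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: str   # printed percentage, e.g. "94.11"
    specificity: str
    accuracy: str


STUDY_ROWS: tuple[StudyRow, ...] = (
    StudyRow(1, "hemorrhage",          7, 0, 105, 0, "100",   "100",  "100"),
    StudyRow(1, "parenchymal_change", 32, 0,  71, 2, "94.11", "100",  "98.09"),
    StudyRow(1, "dense_vessel",       18, 4,  83, 0, "100",   "95.4", "96.19"),
    StudyRow(1, "cta_occlusion",      17, 0,  47, 1, "94.4",  "100",  "98.46"),
    StudyRow(2, "hemorrhage",          7, 0, 105, 0, "100",   "100",  "100"),
    StudyRow(2, "parenchymal_change", 33, 0,  71, 1, "97.05", "100",  "99.04"),
    StudyRow(2, "dense_vessel",       13, 0,  87, 5, "72.2",  "100",  "95.23"),
    StudyRow(2, "cta_occlusion",      17, 0,  47, 1, "94.4",  "100",  "98.46"),
)

#: CTA occlusion reading: 18 occluded cases (both readers called 17, both
#: missing the same V4 occlusion), 47 patent cases all called negative.
CTA_POSITIVES = 18
CTA_NEGATIVES = 47
CTA_SHARED_MISSES = 1
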