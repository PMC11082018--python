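"""Questionnaire metadata for the 21-node symptom network.

The node set covers four patient-reported outcome instruments: the Checklist
Individual Strength (CIS; four subscales), the CES-D depression sum score,
the MOS cognitive-functioning sum score, seven BN-20 brain-tumor symptom
subscales, and eight SF-36 health-related quality-of-life subscales (the
energy/fatigue subscale is omitted as redundant with the CIS).
"""

from __future__ import annotations

#: Canonical node order used everywhere (CSV columns, network labels).
NODE_LABELS_21: tuple[str, ...] = (
    "FA-Fs", "FA-con", "FA-Mot", "FA-Act",   # CIS
    "Depr",                                   # CES-D sum
    "Cogni",                                  # MOS-Cog sum
    "FutU", "Visual", "Motor", "CommD", "HA", "Seiz", "Drow",  # BN-20
    "PhF", "SocF", "RolePh", "RoleE", "EmotWB", "Pain", "HealthP", "ChangeH",  # SF-36
)

#: CIS subscales, excluded when stratifying on fatigue status.
CIS_NODES: tuple[str, ...] = ("FA-Fs", "FA-con", "FA-Mot", "FA-Act")

#: 17-node set used for the fatigue-status networks.
NODE_LABELS_17: tuple[str, ...] = tuple(
    lab for lab in NODE_LABELS_21 if lab not in CIS_NODES
)

#: Node whose raw score carries the fatigue-severity cut-off.
FATIGUE_NODE = "FA-Fs"

#: Raw CIS fatigue-severity score at or above which an assessment counts
#: as fatigued.
FATIGUE_CUTOFF = 27

#: (lower bound, upper bound, number of discrete levels) per node.
#: CIS subscales use their raw Likert sum ranges (items scored 1-7);
#: CES-D is 0-60; MOS-Cog and the EORTC/SF-36 subscales use the 0-100
#: transformed-score convention on a 21-point grid.
SCORE_SCALES: dict[str, tuple[float, float, int]] = {
    "FA-Fs": (8, 56, 49),
    "FA-con": (5, 35, 31),
    "FA-Mot": (4, 28, 25),
    "FA-Act": (3, 21, 19),
    "Depr": (0, 60, 61),
    **{lab: (0, 100, 21) for lab in NODE_LABELS_21[5:]},
}

DISEASE_STATUSES: tuple[str, ...] = (
    "preoperative", "active_treatment", "stable", "progression",
)
POSTOPERATIVE_STATUSES: tuple[str, ...] = ("active_treatment", "stable")
TUMOR_GRADES: tuple[str, ...] = ("II", "III", "IV")

#: Non-score columns of the long-format assessment table, in order.
META_COLUMNS: tuple[str, ...] = (
    "patient_id", "assessment_id", "timepoint", "disease_status", "tumor_grade",
)
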