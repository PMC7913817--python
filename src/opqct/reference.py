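"""Reference cohort parameters and published discrimination results.

The synthetic cohort generator defaults to the group-level summary statistics
of the matched case-control study this package models: 17 patients with an
incident osteoporotic vertebral fracture on follow-up routine contrast-enhanced
MDCT and 17 age-, sex- and follow-up-matched controls.  Values are baseline
trabecular BMD (mg/cm3) per vertebral level Th5-L5 and SAT/VAT volumes (cm3)
over the L4/5 window, as group mean and SD (group 0 = controls, group 1 =
incident fracture).  The reported AUCs serve as sanity anchors for
simulation-based coverage checks; they are never fed back into any
computation.
"""

from __future__ import annotations

from .synth.specs import CohortParams, GroupStats

#: (control mean, control SD, fracture mean, fracture SD) per BMD level, mg/cm3
REFERENCE_BMD: dict[str, tuple[float, float, float, float]] = {
    "Th5": (176.4, 33.1, 142.2, 17.9),
    "Th6": (165.3, 39.7, 132.8, 32.5),
    "Th7": (166.3, 22.3, 128.4, 32.5),
    "Th8": (151.4, 30.4, 123.4, 27.6),
    "Th9": (158.9, 20.9, 124.1, 27.5),
    "Th10": (162.2, 29.7, 135.7, 27.4),
    "Th11": (154.0, 25.5, 129.4, 20.5),
    "Th12": (141.7, 26.9, 116.3, 16.0),
    "L1": (136.8, 32.4, 115.1, 25.1),
    "L2": (137.4, 32.6, 113.3, 21.7),
    "L3": (127.1, 30.3, 111.9, 19.7),
    "L4": (128.8, 31.7, 113.6, 25.6),
    "L5": (133.3, 47.9, 117.9, 40.1),
}

#: QCT-standard mean over L1-L3, as reported (used for direct simulation only;
#: generated cohorts recompute the per-subject mean from L1, L2, L3).
REFERENCE_L1_L3: tuple[float, float, float, float] = (133.8, 29.4, 112.6, 19.5)

#: Adipose compartments at L4/5, cm3.
REFERENCE_VAT: tuple[float, float, float, float] = (266.3, 262.7, 245.0, 260.2)
REFERENCE_SAT: tuple[float, float, float, float] = (519.3, 339.8, 514.0, 347.5)

#: Reported AUC (and its SE) per predictor from the reference study's ROC
#: analysis of incident-fracture discrimination.
REPORTED_AUC: dict[str, tuple[float, float]] = {
    "Th5": (0.781, 0.090),
    "Th6": (0.722, 0.097),
    "Th7": (0.877, 0.066),
    "Th8": (0.738, 0.099),
    "Th9": (0.818, 0.089),
    "Th10": (0.754, 0.100),
    "Th11": (0.754, 0.094),
    "Th12": (0.749, 0.096),
    "L1": (0.668, 0.106),
    "L2": (0.658, 0.104),
    "L3": (0.663, 0.104),
    "L4": (0.604, 0.111),
    "L5": (0.481, 0.115),
    "L1-L3": (0.684, 0.104),
    "VAT": (0.578, 0.112),
    "SAT": (0.497, 0.116),
    "VAT/SAT": (0.519, 0.118),
}

#: Reproducibility error band (%CV) reported for the ROI re-measurement
#: technique; used as a sanity band, never as a hard gate.
REPRODUCIBILITY_CV_RANGE: tuple[float, float] = (2.09, 7.70)


def reference_cohort_params(n_per_group: int = 17, rho: float = 0.7) -> CohortParams:
    """CohortParams populated with the reference study's group parameters."""
    bmd = {
        lv: (GroupStats(cm, cs), GroupStats(fm, fs))
        for lv, (cm, cs, fm, fs) in REFERENCE_BMD.items()
    }
    return CohortParams(
        bmd=bmd,
        vat=(GroupStats(*REFERENCE_VAT[:2]), GroupStats(*REFERENCE_VAT[2:])),
        sat=(GroupStats(*REFERENCE_SAT[:2]), GroupStats(*REFERENCE_SAT[2:])),
        n_per_group=n_per_group,
        rho=rho,
    )
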