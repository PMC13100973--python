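"""Automated Anatomical Labeling (AAL) parcellation labels.

The 116-region AAL atlas is the parcellation used for both the regional
gray-matter-volume tables and the ROI-to-ROI connectivity matrices. The
list below follows the canonical AAL ordering: 45 bilateral cerebral pairs,
9 bilateral cerebellar pairs, and 8 vermis subdivisions.
"""

from __future__ import annotations

_CEREBRAL = [
    "Precentral", "Frontal_Sup", "Frontal_Sup_Orb", "Frontal_Mid",
    "Frontal_Mid_Orb", "Frontal_Inf_Oper", "Frontal_Inf_Tri", "Frontal_Inf_Orb",
    "Rolandic_Oper", "Supp_Motor_Area", "Olfactory", "Frontal_Sup_Medial",
    "Frontal_Med_Orb", "Rectus", "Insula", "Cingulum_Ant", "Cingulum_Mid",
    "Cingulum_Post", "Hippocampus", "ParaHippocampal", "Amygdala", "Calcarine",
    "Cuneus", "Lingual", "Occipital_Sup", "Occipital_Mid", "Occipital_Inf",
    "Fusiform", "Postcentral", "Parietal_Sup", "Parietal_Inf", "SupraMarginal",
    "Angular", "Precuneus", "Paracentral_Lobule", "Caudate", "Putamen",
    "Pallidum", "Thalamus", "Heschl", "Temporal_Sup", "Temporal_Pole_Sup",
    "Temporal_Mid", "Temporal_Pole_Mid", "Temporal_Inf",
]

_CEREBELLAR = [
    "Cerebelum_Crus1", "Cerebelum_Crus2", "Cerebelum_3", "Cerebelum_4_5",
    "Cerebelum_6", "Cerebelum_7b", "Cerebelum_8", "Cerebelum_9", "Cerebelum_10",
]

_VERMIS = [
    "Vermis_1_2", "Vermis_3", "Vermis_4_5", "Vermis_6", "Vermis_7",
    "Vermis_8", "Vermis_9", "Vermis_10",
]

#: The 116 AAL region names in canonical atlas order (L before R per pair).
AAL116: tuple[str, ...] = tuple(
    f"{name}_{side}" for name in _CEREBRAL + _CEREBELLAR for side in ("L", "R")
) + tuple(_VERMIS)

assert len(AAL116) == 116


def region_labels(n_regions: int = 116) -> list[str]:
    """Return the first ``n_regions`` AAL labels, or synthetic ``ROI_###``
    labels beyond the atlas size (useful for large simulated parcellations)."""
    if n_regions <= 116:
        return list(AAL116[:n_regions])
    return list(AAL116) + [f"ROI_{i:03d}" for i in range(117, n_regions + 1)]
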