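"""Atlas specifications for the two ROI feature spaces.

Two parcellation layouts are provided: a 116-region AAL-style atlas (90
cerebral regions as 45 left/right pairs plus 26 cerebellar regions) used for
the voxel-based gray-matter *density* features, and a 68-parcel
Desikan-Killiany-style atlas (34 parcels per hemisphere, cortex only) used
for the surface-based *cortical thickness* features.

Each atlas is a list of ``RoiSpec(name, lobe, hemisphere)`` entries with
``lobe`` in {frontal, temporal, parietal, occipital, subcortical, cerebellar}
and ``hemisphere`` in {L, R, mid}.  The lobe/hemisphere tags drive the
construction of subtype atrophy templates; the names follow the conventions
of the corresponding atlases so generated tables read like real exports.
"""

from __future__ import annotations

from typing import NamedTuple

LOBES = frozenset(
    {"frontal", "temporal", "parietal", "occipital", "subcortical", "cerebellar"}
)
HEMISPHERES = frozenset({"L", "R", "mid"})


class RoiSpec(NamedTuple):
    """One region of interest: its column name and anatomical tags."""

    name: str
    lobe: str
    hemisphere: str


# 45 paired cerebral regions of the AAL parcellation with a coarse lobe tag.
# Cingulate regions are folded into frontal/parietal; insula and the medial
# temporal cortex into temporal; the deep gray nuclei are tagged subcortical.
_AAL_CEREBRUM: list[tuple[str, str]] = [
    ("Precentral", "frontal"),
    ("Frontal_Sup", "frontal"),
    ("Frontal_Sup_Orb", "frontal"),
    ("Frontal_Mid", "frontal"),
    ("Frontal_Mid_Orb", "frontal"),
    ("Frontal_Inf_Oper", "frontal"),
    ("Frontal_Inf_Tri", "frontal"),
    ("Frontal_Inf_Orb", "frontal"),
    ("Rolandic_Oper", "frontal"),
    ("Supp_Motor_Area", "frontal"),
    ("Olfactory", "frontal"),
    ("Frontal_Sup_Medial", "frontal"),
    ("Frontal_Med_Orb", "frontal"),
    ("Rectus", "frontal"),
    ("Paracentral_Lobule", "frontal"),
    ("Cingulum_Ant", "frontal"),
    ("Cingulum_Mid", "frontal"),
    ("Cingulum_Post", "parietal"),
    ("Hippocampus", "subcortical"),
    ("Amygdala", "subcortical"),
    ("Caudate", "subcortical"),
    ("Putamen", "subcortical"),
    ("Pallidum", "subcortical"),
    ("Thalamus", "subcortical"),
    ("Insula", "temporal"),
    ("ParaHippocampal", "temporal"),
    ("Fusiform", "temporal"),
    ("Heschl", "temporal"),
    ("Temporal_Sup", "temporal"),
    ("Temporal_Pole_Sup", "temporal"),
    ("Temporal_Mid", "temporal"),
    ("Temporal_Pole_Mid", "temporal"),
    ("Temporal_Inf", "temporal"),
    ("Calcarine", "occipital"),
    ("Cuneus", "occipital"),
    ("Lingual", "occipital"),
    ("Occipital_Sup", "occipital"),
    ("Occipital_Mid", "occipital"),
    ("Occipital_Inf", "occipital"),
    ("Postcentral", "parietal"),
    ("Parietal_Sup", "parietal"),
    ("Parietal_Inf", "parietal"),
    ("SupraMarginal", "parietal"),
    ("Angular", "parietal"),
    ("Precuneus", "parietal"),
]

_AAL_CEREBELLUM_PAIRED = [
    "Cerebelum_Crus1",
    "Cerebelum_Crus2",
    "Cerebelum_3",
    "Cerebelum_4_5",
    "Cerebelum_6",
    "Cerebelum_7b",
    "Cerebelum_8",
    "Cerebelum_9",
    "Cerebelum_10",
]

_AAL_VERMIS = [
    "Vermis_1_2",
    "Vermis_3",
    "Vermis_4_5",
    "Vermis_6",
    "Vermis_7",
    "Vermis_8",
    "Vermis_9",
    "Vermis_10",
]

# 34 Desikan-Killiany parcels per hemisphere with a coarse lobe tag
# (cingulate parcels split between frontal and parietal, insula -> temporal).
_DK_PARCELS: list[tuple[str, str]] = [
    ("bankssts", "temporal"),
    ("caudalanteriorcingulate", "frontal"),
    ("caudalmiddlefrontal", "frontal"),
    ("cuneus", "occipital"),
    ("entorhinal", "temporal"),
    ("frontalpole", "frontal"),
    ("fusiform", "temporal"),
    ("inferiorparietal", "parietal"),
    ("inferiortemporal", "temporal"),
    ("insula", "temporal"),
    ("isthmuscingulate", "parietal"),
    ("lateraloccipital", "occipital"),
    ("lateralorbitofrontal", "frontal"),
    ("lingual", "occipital"),
    ("medialorbitofrontal", "frontal"),
    ("middletemporal", "temporal"),
    ("paracentral", "frontal"),
    ("parahippocampal", "temporal"),
    ("parsopercularis", "frontal"),
    ("parsorbitalis", "frontal"),
    ("parstriangularis", "frontal"),
    ("pericalcarine", "occipital"),
    ("postcentral", "parietal"),
    ("posteriorcingulate", "parietal"),
    ("precentral", "frontal"),
    ("precuneus", "parietal"),
    ("rostralanteriorcingulate", "frontal"),
    ("rostralmiddlefrontal", "frontal"),
    ("superiorfrontal", "frontal"),
    ("superiorparietal", "parietal"),
    ("superiortemporal", "temporal"),
    ("supramarginal", "parietal"),
    ("temporalpole", "temporal"),
    ("transversetemporal", "temporal"),
]


def aal116_atlas() -> list[RoiSpec]:
    """116-region AAL-style atlas for gray-matter density features.

    Returns 45 left/right cerebral pairs (90 regions), 9 cerebellar pairs
    (18) and 8 midline vermis regions, in a fixed deterministic order.
    """
    rois: list[RoiSpec] = []
    for base, lobe in _AAL_CEREBRUM:
        rois.append(RoiSpec(f"{base}_L", lobe, "L"))
        rois.append(RoiSpec(f"{base}_R", lobe, "R"))
    for base in _AAL_CEREBELLUM_PAIRED:
        rois.append(RoiSpec(f"{base}_L", "cerebellar", "L"))
        rois.append(RoiSpec(f"{base}_R", "cerebellar", "R"))
    for base in _AAL_VERMIS:
        rois.append(RoiSpec(base, "cerebellar", "mid"))
    assert len(rois) == 116
    return rois


def dk68_atlas() -> list[RoiSpec]:
    """68-parcel Desikan-Killiany-style atlas for cortical thickness."""
    rois: list[RoiSpec] = []
    for hemi, prefix in (("L", "lh"), ("R", "rh")):
        for base, lobe in _DK_PARCELS:
            rois.append(RoiSpec(f"{prefix}_{base}_thickness", lobe, hemi))
    assert len(rois) == 68
    return rois


def validate_atlas(atlas: list[RoiSpec]) -> None:
    """Check tags and name uniqueness of an atlas specification."""
    names = [r.name for r in atlas]
    if len(set(names)) != len(names):
        raise ValueError("atlas ROI names are not unique")
    for roi in atlas:
        if roi.lobe not in LOBES:
            raise ValueError(f"unknown lobe tag {roi.lobe!r} for ROI {roi.name!r}")
        if roi.hemisphere not in HEMISPHERES:
            raise ValueError(
                f"unknown hemisphere tag {roi.hemisphere!r} for ROI {roi.name!r}"
            )
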