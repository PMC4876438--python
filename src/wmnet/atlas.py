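"""Default node parcellation: the 90-region automated anatomical
labelling (AAL) cortical/subcortical atlas, 45 regions per hemisphere,
in the conventional interleaved left/right numbering (1-based regions
1..90; stored 0-based internally)."""

from __future__ import annotations

# Left/right pairs in standard AAL order; suffixes appended below.
_AAL90_STEMS = [
    "Precentral",
    "Frontal_Sup",
    "Frontal_Sup_Orb",
    "Frontal_Mid",
    "Frontal_Mid_Orb",
    "Frontal_Inf_Oper",
    "Frontal_Inf_Tri",
    "Frontal_Inf_Orb",
    "Rolandic_Oper",
    "Supp_Motor_Area",
    "Olfactory",
    "Frontal_Sup_Medial",
    "Frontal_Med_Orb",
    "Rectus",
    "Insula",
    "Cingulum_Ant",
    "Cingulum_Mid",
    "Cingulum_Post",
    "Hippocampus",
    "ParaHippocampal",
    "Amygdala",
    "Calcarine",
    "Cuneus",
    "Lingual",
    "Occipital_Sup",
    "Occipital_Mid",
    "Occipital_Inf",
    "Fusiform",
    "Postcentral",
    "Parietal_Sup",
    "Parietal_Inf",
    "SupraMarginal",
    "Angular",
    "Precuneus",
    "Paracentral_Lobule",
    "Caudate",
    "Putamen",
    "Pallidum",
    "Thalamus",
    "Heschl",
    "Temporal_Sup",
    "Temporal_Pole_Sup",
    "Temporal_Mid",
    "Temporal_Pole_Mid",
    "Temporal_Inf",
]


def aal90_labels() -> tuple[str, ...]:
    """Return the 90 AAL region names, odd indices left / even right."""
    out: list[str] = []
    for stem in _AAL90_STEMS:
        out.append(stem + "_L")
        out.append(stem + "_R")
    return tuple(out)


def aal90_index(label: str) -> int:
    """0-based index of an AAL-90 region name (e.g. ``Parietal_Inf_R``)."""
    labels = aal90_labels()
    try:
        return labels.index(label)
    except ValueError:
        raise KeyError(f"unknown AAL-90 region name: {label!r}") from None
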