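"""Desikan-Killiany cortical parcellation labels.

The 68-region bilateral parcellation (34 parcels per hemisphere) is the
node set of every covariance network in this package. Labels follow the
FreeSurfer convention ``lh_<parcel>`` / ``rh_<parcel>``.
"""

from __future__ import annotations

DESIKAN_KILLIANY_PARCELS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
)

#: Vertices on the medial wall carry this label and are excluded from
#: regional aggregation.
UNKNOWN_LABEL = "unknown"


def desikan_killiany_labels() -> list[str]:
    """Return the 68 bilateral region labels (left hemisphere first)."""
    return [f"{hemi}_{parcel}" for hemi in ("lh", "rh")
            for parcel in DESIKAN_KILLIANY_PARCELS]


def normalize_region_label(label: str) -> str:
    """Map a region name onto the canonical ``lh_<parcel>`` form.

    Handles case differences and the ``lh.parcel`` / ``lh-parcel``
    separators produced by various FreeSurfer table exporters.
    """
    return label.strip().lower().replace(".", "_").replace("-", "_")
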