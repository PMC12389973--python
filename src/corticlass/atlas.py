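"""Desikan-Killiany cortical parcellation labels.

The atlas defines 34 regions per hemisphere; ROI lists used throughout the
package mirror the left-hemisphere names to both hemispheres (68 labels).
"""

from __future__ import annotations

DK_LEFT_REGIONS: tuple[str, ...] = (
    "Banks of superior temporal sulcus",
    "Caudal anterior cingulate",
    "Caudal middle frontal",
    "Cuneus",
    "Entorhinal",
    "Fusiform",
    "Inferior parietal",
    "Inferior temporal",
    "Isthmus cingulate",
    "Lateral occipital",
    "Lateral orbitofrontal",
    "Lingual",
    "Medial orbitofrontal",
    "Middle temporal",
    "Parahippocampal",
    "Paracentral",
    "Pars opercularis",
    "Pars orbitalis",
    "Pars triangularis",
    "Pericalcarine",
    "Postcentral",
    "Posterior cingulate",
    "Precentral",
    "Precuneus",
    "Rostral anterior cingulate",
    "Rostral middle frontal",
    "Superior frontal",
    "Superior parietal",
    "Superior temporal",
    "Supramarginal",
    "Frontal pole",
    "Temporal pole",
    "Transverse temporal",
    "Insula",
)


def roi_labels() -> list[str]:
    """Return the 68 bilateral ROI labels (left names suffixed -lh / -rh)."""
    return [f"{name}-lh" for name in DK_LEFT_REGIONS] + [
        f"{name}-rh" for name in DK_LEFT_REGIONS
    ]
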