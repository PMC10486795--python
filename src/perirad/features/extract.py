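"""Assemble the 45 retained radiomic indices per VOI.

Key layout: ``<Phase>_<VOI>_<Name>`` where ``Name`` carries its family prefix
for matrix/shape indices (``GLCM_Correlation``, ``Shape_Sphericity``, ...) and
is bare for the grey-level descriptors and first-order moments (``HUmin``,
``Skewness``, ...), matching the naming used in clinical radiomics reports.

The retained set has exactly 45 indices per VOI: 7 grey-level descriptors,
4 first-order, 3 shape, 6 GLCM, 11 GLRLM, 3 NGLDM and 11 GLZLM.  The GLCM
family internally computes both log2 and log10 entropies, but the retained
vector keeps only the log2 variant: the two are exact scalar multiples of
each other (perfectly correlated), so the second would be removed by any
redundancy screen and carries no information.
"""

from __future__ import annotations

import pandas as pd

from ..voi import ImageVolume, VoiPair
from ._discretize import DiscretizationScheme
from .firstorder import grey_level_descriptors, histogram_features
from .shape import shape_features
from .texture import glcm_features, glrlm_features, glzlm_features, ngldm_features

#: the 45 retained index names (per phase and VOI)
RETAINED_INDICES: tuple[str, ...] = (
    "HUmin", "HUmean", "HUstd", "HUmax", "HUQ1", "HUQ2", "HUQ3",
    "Skewness", "Kurtosis", "Histogram_Energy", "Histogram_Entropy",
    "Shape_Volume_mL", "Shape_Sphericity", "Shape_Compacity",
    "GLCM_Homogeneity", "GLCM_Energy", "GLCM_Contrast", "GLCM_Correlation",
    "GLCM_Entropy_log2", "GLCM_Dissimilarity",
    "GLRLM_SRE", "GLRLM_LRE", "GLRLM_LGRE", "GLRLM_HGRE", "GLRLM_SRLGE",
    "GLRLM_SRHGE", "GLRLM_LRLGE", "GLRLM_LRHGE", "GLRLM_GLNU", "GLRLM_RLNU",
    "GLRLM_RP",
    "NGLDM_Coarseness", "NGLDM_Contrast", "NGLDM_Busyness",
    "GLZLM_SZE", "GLZLM_LZE", "GLZLM_LGZE", "GLZLM_HGZE", "GLZLM_SZLGE",
    "GLZLM_SZHGE", "GLZLM_LZLGE", "GLZLM_LZHGE", "GLZLM_GLNU", "GLZLM_ZLNU",
    "GLZLM_ZP",
)

assert len(RETAINED_INDICES) == 45


def extract_voi(
    volume: ImageVolume,
    mask,
    scheme: DiscretizationScheme | None = None,
) -> dict[str, float]:
    """The 45 indices for a single VOI, keyed by bare index name."""
    scheme = scheme or DiscretizationScheme()
    values = volume.values
    out: dict[str, float] = {}
    out.update(grey_level_descriptors(values, mask))
    out.update(histogram_features(values, mask, scheme))
    out.update(shape_features(mask, volume.spacing_mm))
    out.update(glcm_features(values, mask, scheme))
    out.update(glrlm_features(values, mask, scheme))
    out.update(ngldm_features(values, mask, scheme))
    out.update(glzlm_features(values, mask, scheme))
    vec = {name: out[name] for name in RETAINED_INDICES}
    return vec


def extract_all(
    volume: ImageVolume,
    voi_pair: VoiPair,
    scheme: DiscretizationScheme | None = None,
    phase_label: str = "Portal",
) -> dict[str, float]:
    """Extract tumor and margin feature vectors, namespaced
    ``<Phase>_<Tumor|Margin>_<Name>`` (90 keys in total)."""
    out: dict[str, float] = {}
    for voi_label, mask in (("Tumor", voi_pair.tumor), ("Margin", voi_pair.margin)):
        vec = extract_voi(volume, mask, scheme)
        out.update({f"{phase_label}_{voi_label}_{k}": v for k, v in vec.items()})
    return out


def features_to_frame(rows: list[dict[str, float]], patient_ids=None) -> pd.DataFrame:
    """Stack per-patient feature dicts into a table (one row per patient)."""
    frame = pd.DataFrame(rows)
    if patient_ids is not None:
        frame.insert(0, "patient_id", list(patient_ids))
    return frame
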