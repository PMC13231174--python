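"""Region volumes and the T2/FLAIR Heterogeneity Index (TFHI).

TFHI = V_nCET / V_edema, the fraction of the total peritumoral edema volume
occupied by the putative nCET subregion. The denominator is the *total* edema
(nCET + vasogenic), so cleanup-reassigned voxels stay in it and TFHI is
always in [0, 1]. The conventional CET/edema volume ratio is computed
alongside as a comparator biomarker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging_io import AnatomyLabelMap
from .postprocess import EdemaSplit


@dataclass
class BiomarkerRecord:
    v_ncet_mm3: float
    v_edema_mm3: float
    v_cet_mm3: float
    tfhi: float
    cet_edema_ratio: float

    def to_dict(self) -> dict:
        return {
            "v_ncet_mm3": self.v_ncet_mm3,
            "v_edema_mm3": self.v_edema_mm3,
            "v_cet_mm3": self.v_cet_mm3,
            "tfhi": self.tfhi,
            "cet_edema_ratio": self.cet_edema_ratio,
        }


def volume_mm3(mask: np.ndarray, spacing) -> float:
    """Voxel count times voxel volume, in mm^3."""
    spacing = np.asarray(spacing, dtype=np.float64)
    if np.any(spacing <= 0):
        raise ValueError("non-positive spacing")
    return float(np.count_nonzero(np.asarray(mask, dtype=bool)) * np.prod(spacing))


def compute_tfhi(split: EdemaSplit, anatomy: AnatomyLabelMap, spacing=None) -> BiomarkerRecord:
    """TFHI and comparator CET/edema ratio for one case."""
    spacing = anatomy.spacing if spacing is None else np.asarray(spacing, dtype=np.float64)
    edema = anatomy.edema_mask
    if not edema.any():
        raise ValueError("empty edema label (upstream contract violation)")
    split.check_partition(edema)
    v_ncet = volume_mm3(split.ncet_mask, spacing)
    v_edema = volume_mm3(edema, spacing)
    v_cet = volume_mm3(anatomy.cet_mask, spacing)
    return BiomarkerRecord(
        v_ncet_mm3=v_ncet,
        v_edema_mm3=v_edema,
        v_cet_mm3=v_cet,
        tfhi=v_ncet / v_edema,
        cet_edema_ratio=v_cet / v_edema,
    )
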