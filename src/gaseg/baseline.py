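"""Classical sub-RPE slab-threshold segmentation baseline.

En face projection of the slab just below the RPE band is the traditional,
non-learned readout of hypertransmission (commercial en face RPE-analysis
tools work on the same principle). It serves three roles here:

* an independent check that the synthetic segmentation task is well-posed
  (a trivial method must already recover the lesion on clean volumes);
* a fast fixed "model" for longitudinal analyses in tests and examples;
* a sanity reference the learned network should beat on noisy data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .synthetic import sub_rpe_slab_projection
from .types import EnFaceMask, OCTVolume

__all__ = ["SlabThresholdSegmenter"]


@dataclass
class SlabThresholdSegmenter:
    """Threshold the smoothed sub-RPE slab projection.

    The threshold is Otsu's, guarded from below by ``min_contrast`` times
    the median slab brightness so a lesion-free projection (unimodal) does
    not get split into spurious foreground.
    """

    smooth_sigma_px: float = 1.0
    min_contrast: float = 1.35

    def predict(self, vol: OCTVolume, nir=None) -> EnFaceMask:
        proj = sub_rpe_slab_projection(vol)
        if self.smooth_sigma_px > 0:
            proj = ndimage.gaussian_filter(proj, self.smooth_sigma_px)
        med = float(np.median(proj))
        try:
            thr = float(threshold_otsu(proj))
        except ValueError:  # constant image
            thr = np.inf
        thr = max(thr, self.min_contrast * med)
        grid = (proj > thr).astype(np.uint8)
        dx, dy = vol.spacing_mm[1], vol.spacing_mm[2]
        return EnFaceMask(grid=grid, pixel_area_mm2=dx * dy, binary=True)
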