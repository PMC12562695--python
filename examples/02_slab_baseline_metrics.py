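"""Segment one synthetic scan with the classical sub-RPE slab baseline and
score it against ground truth.

Shows the agreement metrics on a single case: Dice similarity, lesion areas
in mm^2, and the multifocal coalescence diagnostic (connected-component
counts). No training involved — this is the non-learned reference method.
"""

from gaseg import (SPECTRALIS_SMALL, EnFaceMask, add_speckle, apply_atrophy,
                   area_mm2, coalescence_diagnostic, dsc, make_background,
                   sample_lesion_mask)
from gaseg.baseline import SlabThresholdSegmenter

profile = SPECTRALIS_SMALL
background = make_background(profile, seed=3)
truth = sample_lesion_mask(profile, n_foci=3, radius_range_mm=(0.4, 1.0), seed=11)
volume = add_speckle(apply_atrophy(background, truth, profile), 0.15, seed=5)

pred = SlabThresholdSegmenter().predict(volume)
truth_mask = EnFaceMask(truth.grid, pixel_area_mm2=truth.pixel_area_mm2)

print(f"DSC vs ground truth:     {dsc(pred, truth_mask):.3f}")
print(f"area, manual (truth):    {area_mm2(truth_mask):.2f} mm^2")
print(f"area, automated (slab):  {area_mm2(pred):.2f} mm^2")
n_auto, n_manual = coalescence_diagnostic(pred, truth_mask)
print(f"lesion foci, auto/manual: {n_auto} / {n_manual}"
      " (fewer auto foci = coalescence of neighbouring lesions)")
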