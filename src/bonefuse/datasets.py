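"""Bundled reference data: a two-reader bone-metastasis confidence table.

Reader-1 four-point confidence counts over 1746 skeletal lesions with
abnormal tracer uptake (744 metastatic, 1002 benign) assessed under three
display conditions: planar whole-body scintigraphy plus SPECT, conventional
2D SPECT/CT fusion, and 3D SPECT/CT surface-projection fusion.  The counts
serve as a worked example and regression fixture for the evaluation
arithmetic (confusion metrics, ordinal ROC/AUC, equivocal rates).
"""
from __future__ import annotations

from .reader_stats import OrdinalCounts

#: Display-condition keys, in increasing anatomic-information order.
MODALITIES = ("wb_spect", "fusion_2d", "fusion_3d")

#: Reader-1 score counts (index 0 = "definitely benign" ... 3 = "definitely
#: malignant") per display condition.
READER1_COUNTS: dict = {
    "wb_spect": OrdinalCounts(malignant=[23, 140, 401, 180],
                              benign=[245, 527, 182, 48]),
    "fusion_2d": OrdinalCounts(malignant=[15, 52, 198, 479],
                               benign=[914, 74, 12, 2]),
    "fusion_3d": OrdinalCounts(malignant=[13, 52, 194, 485],
                               benign=[906, 78, 16, 2]),
}
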