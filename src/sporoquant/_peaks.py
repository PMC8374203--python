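"""Prominence-filtered local maxima via morphological reconstruction.

Shared by the adjustable watershed (maxima of the distance map) and the
semi-automatic maxima finder (maxima of intensity). The reconstruction-by-
dilation of ``f - h`` under ``f`` levels every peak that rises less than
``h`` above its connecting saddle; the regional maxima of the
reconstruction are therefore the peaks with dynamics (prominence) above
``h``, *as connected regions*: equal-height twin maxima whose mutual
saddle is within ``h`` collapse into a single plateau instead of staying
split — the behaviour a merge tolerance is supposed to have.
"""

from __future__ import annotations

import numpy as np
from skimage import morphology


def prominent_max_regions(f: np.ndarray, h: float) -> np.ndarray:
    """Boolean mask of maxima regions with prominence above ``h``.

    ``h <= 0`` degenerates to plain regional maxima. For integer-valued
    images pass ``h - 0.5`` to realise an inclusive (>= h) criterion, since
    integer dynamics cannot fall strictly between ``h - 1`` and ``h``.
    """
    f = np.asarray(f, dtype=float)
    if h <= 0:
        return morphology.local_maxima(f, connectivity=2)
    rec = morphology.reconstruction(f - h, f, method="dilation")
    return morphology.local_maxima(rec, connectivity=2)
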