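"""Package-wide constants and logging setup.

Coordinates follow the common mouse reference-atlas convention: axis 0 is
anterior-posterior, axis 1 is dorsal-ventral, axis 2 is medial-lateral, all in
micrometers.  The mediolateral midline (used to mirror centroids when
computing cross-hemisphere distances) defaults to half the 11.4 mm
mediolateral extent of the adult mouse reference volume.
"""

from __future__ import annotations

import logging

#: Index of the mediolateral axis in (x, y, z) centroid triples.
MIRROR_AXIS: int = 2

#: Mediolateral midline position in micrometers (half of 11400 um).
MIDLINE_UM: float = 5700.0

#: Two weighted path lengths closer than this are treated as equal (a tie).
PATH_TIE_TOL: float = 1e-9

#: Number of histogram bins used by the Otsu auto-threshold.
OTSU_BINS: int = 256

#: Hemisphere labels used throughout.
LEFT = "left"
RIGHT = "right"
HEMISPHERES = (LEFT, RIGHT)

#: Side-relative labels (relative to the injection hemisphere).
IPSI = "ipsi"
CONTRA = "contra"

#: The four projection measures carried by every experiment record.
MEASURES = ("density", "intensity", "energy", "volume")

logger = logging.getLogger("tracenet")
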