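"""Reference prediction counts from the Hs68 fibroblast RNase-R experiment.

These are the published per-caller counts for the human fibroblast (Hs68)
total-RNA library SRR444655 evaluated against its RNase-R-treated counterpart
SRR444974, after the >= 2 junction-read filter.  They serve as worked-example
inputs for the evaluation arithmetic; this package does not download or
re-process the underlying libraries.
"""

from __future__ import annotations

__all__ = ["PUBLISHED_COUNTS", "THREE_WAY_OVERLAP"]

# caller -> (n_predicted from total RNA, overlap with RNase-R set, n_true with E > 0)
# CIRI2.0's overlap count was not reported; None marks the gap.
PUBLISHED_COUNTS: dict[str, tuple[int, int | None, int]] = {
    "CIRI1.2": (3488, 2531, 1362),
    "CIRI2.0": (2207, None, 1096),
    "KNIFE": (2854, None, 1689),
}

# Junctions called by all three algorithms on the total-RNA library.
THREE_WAY_OVERLAP = 1152
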