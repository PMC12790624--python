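"""Shared test helpers."""

import numpy as np

from driverfusion.io import AlignedView


def make_view(pairs, n, scores=None, modality="PPI"):
    """Build an AlignedView from integer pairs (i < j enforced by sorting)."""
    arr = np.asarray(sorted(pairs), dtype=np.intp).reshape(-1, 2).T
    s = (
        np.asarray(scores, dtype=np.float64)
        if scores is not None
        else np.full(arr.shape[1], 0.9)
    )
    return AlignedView(modality=modality, edge_index=arr, scores=s, threshold=0.0)
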