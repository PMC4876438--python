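"""Hub identification from group-mean nodal-strength AUC.

A node is a hub for a group when its across-subject mean strength AUC
exceeds the across-node mean by more than one across-node sample SD
(ddof=1, strict inequality).  The threshold is computed within each
group; the displayed "normalized" AUC divides by the group maximum and
is used only for presentation, never for the flag.  Hub sets are
invariant to multiplying all AUCs by a positive constant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["identify_hubs"]


def identify_hubs(strength_auc: pd.DataFrame, groups: pd.Series) -> dict[str, pd.DataFrame]:
    """Flag hub nodes per group.

    Parameters
    ----------
    strength_auc
        Subjects x nodes frame of nodal-strength AUC values (columns
        are node labels, index subject ids).
    groups
        Group label per subject, indexed like ``strength_auc``.

    Returns
    -------
    dict mapping group label to a frame with columns node, mean_auc,
    normalized_auc, threshold, is_hub, sorted in node order.
    """
    if strength_auc.shape[1] < 2:
        raise ValueError("hub detection needs at least two nodes")
    groups = groups.reindex(strength_auc.index)
    out: dict[str, pd.DataFrame] = {}
    for g in sorted(groups.unique()):
        mean_auc = strength_auc.loc[groups == g].mean(axis=0)
        thr = float(mean_auc.mean() + mean_auc.std(ddof=1))
        out[g] = pd.DataFrame({
            "node": mean_auc.index,
            "mean_auc": mean_auc.to_numpy(),
            "normalized_auc": mean_auc.to_numpy() / mean_auc.max(),
            "threshold": thr,
            "is_hub": mean_auc.to_numpy() > thr,
        }).reset_index(drop=True)
    return out
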