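"""Published reference cross-tabulations from the Ndlovu HIV cohort analysis.

Each panel cross-tabulates the D:A:D 2010 risk category (rows: low < 10%,
moderate 10-20%, high > 20%) against one comparator model (columns, same
order) for the 735 eligible participants. These printed counts serve as
fixed inputs for regression tests of the agreement statistics; totals are
always recomputed from cells (the D:A:D 2016 panel's printed margins are
internally inconsistent by 10 participants, so its cells are taken as
authoritative).
"""

from __future__ import annotations

import numpy as np

from .agreement import CrossTab

__all__ = ["NDLOVU_PANELS", "ndlovu_crosstab"]

NDLOVU_PANELS: dict[str, list[list[int]]] = {
    "FHS_CVD": [[621, 19, 1], [30, 36, 5], [4, 4, 15]],
    "FHS_CHD": [[631, 10, 0], [50, 21, 0], [4, 15, 4]],
    "ASCVD": [[637, 3, 1], [57, 13, 1], [2, 18, 3]],
    "DAD_2016": [[568, 63, 2], [4, 42, 25], [0, 0, 21]],
}


def ndlovu_crosstab(model_id: str) -> CrossTab:
    """Reference panel: D:A:D 2010 (rows) vs ``model_id`` (columns)."""
    return CrossTab("DAD_2010", model_id, np.array(NDLOVU_PANELS[model_id]))
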