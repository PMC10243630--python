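"""Forest-style tabular reports of trial-level and pooled estimates.

Figures in this kind of analysis show, per drug class and indication, the
trial-level interaction estimates (circles) and the meta-analysed estimate
(diamond) with 95% intervals.  The canonical machine-checkable surface here
is the equivalent table: trial rows followed by a pooled row per group, with
the scale (MCID multiples or ratio) and effects model recorded.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .meta import MetaResult
from .stage1 import CoefficientExport

__all__ = ["forest_table", "RATIO_FOOTNOTE"]

RATIO_FOOTNOTE = (
    "Ratio per one-unit increase in the covariate; estimates above one "
    "indicate worse outcomes in the intervention arm."
)


def _trial_rows(
    exports: Sequence[CoefficientExport], result: MetaResult, label: str
) -> list[dict]:
    rows = []
    for e in exports:
        if (e.indication, e.comparison) != (result.indication, result.comparison):
            continue
        if label not in e.labels:
            continue
        if result.analysis and e.spec.family != result.analysis:
            continue
        est, se = e.coef(label), e.coef_se(label)
        lo, hi = est - 1.96 * se, est + 1.96 * se
        if result.scale == "ratio":
            est, lo, hi = np.exp(est), np.exp(lo), np.exp(hi)
        rows.append(
            {
                "indication": result.indication,
                "comparison": result.comparison,
                "coefficient": label,
                "row": "trial",
                "trial_id": e.trial_id,
                "estimate": est,
                "lower95": lo,
                "upper95": hi,
                "scale": result.scale,
                "effects_model": "",
                "degenerate": bool(hi - lo <= 0),
            }
        )
    return rows


def forest_table(
    results: Sequence[MetaResult],
    exports: Sequence[CoefficientExport] = (),
    footnote_slot: bool = False,
) -> pd.DataFrame:
    """Build the forest table: trial rows then a pooled row per group.

    Groups containing a single trial are rendered without a pooled row (the
    trial estimate is the evidence).  Zero-width intervals are flagged in the
    ``degenerate`` column rather than silently printed.
    """
    if len(results) == 0:
        raise ValueError("forest_table requires at least one result")
    rows: list[dict] = []
    for res in results:
        for j, label in enumerate(res.labels):
            rows.extend(_trial_rows(exports, res, label))
            if res.k_trials < 2:
                continue
            lo, hi = float(res.lower[j]), float(res.upper[j])
            rows.append(
                {
                    "indication": res.indication,
                    "comparison": res.comparison,
                    "coefficient": label,
                    "row": "pooled",
                    "trial_id": "",
                    "estimate": float(res.mean[j]),
                    "lower95": lo,
                    "upper95": hi,
                    "scale": res.scale,
                    "effects_model": res.effects_model,
                    "degenerate": bool(hi - lo <= 0),
                }
            )
    columns = [
        "indication", "comparison", "coefficient", "row", "trial_id",
        "estimate", "lower95", "upper95", "scale", "effects_model", "degenerate",
    ]
    table = pd.DataFrame(rows, columns=columns)
    if footnote_slot:
        table.attrs["footnote"] = RATIO_FOOTNOTE if any(
            r.scale == "ratio" for r in results
        ) else ""
    return table
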