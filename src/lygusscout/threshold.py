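"""Economic-threshold agreement between quadrant- and field-scale calls.

The action thresholds are 8 adults+nymphs per 100-sweep unit (squaring) and
2.5 per 1.5 row-m drop-cloth unit (bloom). Each quadrant's density estimate
and its field's mean estimate are classified against the threshold ("at or
above" counts as above, the conservative treat-on-tie convention), the 2x2
quadrant-call x field-call table is tested for independence by a plain
chi-square test, and the single-quadrant inadequacy is the share of
below-threshold quadrants inside fields that are at or above threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .records import units_to_frame


@dataclass(frozen=True)
class AgreementSummary:
    method: str
    threshold: float
    pct_below_both: float
    pct_above_both: float
    pct_disagree: float
    p_single_quadrant_inadequate: float
    inadequacy_defined: bool
    chi2: float
    p_value: float
    n_quadrants: int

    def __post_init__(self) -> None:
        total = self.pct_below_both + self.pct_above_both + self.pct_disagree
        if abs(total - 100.0) > 1e-6:
            raise ValueError("agreement percentages must sum to 100")


def agreement_analysis(records, threshold: float,
                       field_scale: str = "quadrant_mean") -> AgreementSummary:
    """Cross-classify quadrant and field threshold calls.

    Quadrant estimates are mean counts per sampling unit within the
    quadrant; the field estimate is either the mean of its quadrant
    estimates (``"quadrant_mean"``, default) or the mean over all raw units
    (``"unit_mean"``) - identical for balanced designs.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    units = units_to_frame(records)
    if units.empty:
        raise ValueError("records must be non-empty")
    methods = units["method"].unique()
    method = methods[0] if len(methods) == 1 else "mixed"

    quad = (units.groupby(["field_id", "quadrant"])["total"].mean()
            .reset_index(name="density"))
    counts_per_field = quad.groupby("field_id").size()
    if (counts_per_field < 2).all():
        raise ValueError("need at least one field with >= 2 quadrants")
    if field_scale == "quadrant_mean":
        field = quad.groupby("field_id")["density"].mean()
    elif field_scale == "unit_mean":
        field = units.groupby("field_id")["total"].mean()
    else:
        raise ValueError("field_scale must be 'quadrant_mean' or 'unit_mean'")

    quad = quad.assign(
        q_above=quad["density"] >= threshold,
        f_above=quad["field_id"].map(field >= threshold),
    )
    n = len(quad)
    below_both = (~quad["q_above"] & ~quad["f_above"]).sum()
    above_both = (quad["q_above"] & quad["f_above"]).sum()
    disagree = n - below_both - above_both

    table = pd.crosstab(quad["q_above"], quad["f_above"]) \
        .reindex(index=[False, True], columns=[False, True], fill_value=0)
    if (table.to_numpy().sum(axis=0) == 0).any() or \
            (table.to_numpy().sum(axis=1) == 0).any():
        chi2, p = 0.0, 1.0
    else:
        chi2, p, *_ = stats.chi2_contingency(table.to_numpy(), correction=False)

    hot = quad[quad["f_above"]]
    if len(hot):
        inadequacy = 100.0 * (~hot["q_above"]).mean()
        defined = True
    else:
        inadequacy, defined = 0.0, False

    return AgreementSummary(
        method=method,
        threshold=float(threshold),
        pct_below_both=100.0 * below_both / n,
        pct_above_both=100.0 * above_both / n,
        pct_disagree=100.0 * disagree / n,
        p_single_quadrant_inadequate=float(inadequacy),
        inadequacy_defined=defined,
        chi2=float(chi2),
        p_value=float(p),
        n_quadrants=int(n),
    )
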