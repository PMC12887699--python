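"""Cohort-level enrichment statistics between two response groups.

Per-sample cell-type proportions with two-sided rank-sum comparisons
(exact by enumeration for small cohorts), and pooled-cell 2x2 odds ratios
per subtype between the two groups (Haldane-Anscombe correction when a
zero cell occurs, Woolf 95% CI, two-sided Fisher exact p).  Odds ratios on
pooled cells are the convention for subtype-abundance heatmaps; per-sample
proportions are reported alongside so pseudoreplication stays visible.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import ranksum_p
from .core import GroupDesign

log = logging.getLogger("stnichekit")

__all__ = ["proportions", "proportion_test", "subtype_or"]


def proportions(labels, design: GroupDesign, within=None) -> pd.DataFrame:
    """Per-sample cell-type proportions, optionally within a parent compartment.

    ``labels`` maps obs_id -> cell type; ``within`` restricts the denominator
    to cells of the listed parent types (e.g. a macrophage subtype within the
    myeloid compartment).  Samples with zero cells in the compartment are
    omitted with a warning.  Types absent from a sample appear with
    proportion 0 so group comparisons see every sample.
    """
    labels = pd.Series(labels).astype(str)
    unmapped = labels.index.difference(design.obs_to_sample.index)
    if len(unmapped):
        raise ValueError(f"labeled observations missing from design: {list(unmapped[:5])}")
    df = pd.DataFrame(
        {
            "cell_type": labels,
            "sample_id": design.obs_to_sample.loc[labels.index],
        }
    )
    if within is not None:
        within = {str(w) for w in (within if not isinstance(within, str) else [within])}
        df = df[df["cell_type"].isin(within)]
    all_samples = design.sample_to_group.index
    counts = (
        df.groupby(["sample_id", "cell_type"], observed=True).size().unstack(fill_value=0)
    )
    empty = all_samples.difference(counts.index)
    if len(empty):
        log.warning("proportions: samples with 0 cells in compartment omitted: %s", list(empty))
    table = counts.stack().rename("n_cells").reset_index()
    totals = counts.sum(axis=1)
    table["proportion"] = table.apply(
        lambda r: r["n_cells"] / totals[r["sample_id"]], axis=1
    )
    table["group"] = table["sample_id"].map(design.sample_to_group)
    return table[["sample_id", "group", "cell_type", "n_cells", "proportion"]].sort_values(
        ["sample_id", "cell_type"], kind="stable"
    ).reset_index(drop=True)


def proportion_test(pt: pd.DataFrame, cell_type: str, exact_max_n: int = 20) -> float:
    """Two-sided rank-sum p comparing a type's per-sample proportions between
    the two groups: exact by enumeration for pooled n <= exact_max_n, else
    the tie-corrected normal approximation.  Returns NaN (with a warning)
    when either group has fewer than 2 samples."""
    sub = pt[pt["cell_type"] == str(cell_type)]
    groups = sorted(sub["group"].unique())
    if len(groups) != 2:
        log.warning("proportion_test(%s): need 2 groups, have %s", cell_type, groups)
        return float("nan")
    x = sub.loc[sub["group"] == groups[0], "proportion"].to_numpy()
    y = sub.loc[sub["group"] == groups[1], "proportion"].to_numpy()
    if len(x) < 2 or len(y) < 2:
        log.warning("proportion_test(%s): a group has <2 samples; skipped", cell_type)
        return float("nan")
    return ranksum_p(x, y, exact_max_n=exact_max_n)


OR_COLUMNS = [
    "cell_type",
    "group_a_count",
    "group_a_other",
    "group_b_count",
    "group_b_other",
    "odds_ratio",
    "ci_low",
    "ci_high",
    "p_value",
]


def subtype_or(labels, design: GroupDesign) -> pd.DataFrame:
    """Pooled-cell odds ratio of each subtype between the two groups.

    Groups are taken in sorted order (a, b); OR > 1 means the type is
    relatively more abundant in group a.  A zero cell anywhere in the 2x2
    table triggers the Haldane-Anscombe +0.5 correction for the OR and its
    Woolf CI; the Fisher exact p always uses the uncorrected counts.
    """
    labels = pd.Series(labels).astype(str)
    obs_group = design.obs_groups().loc[labels.index]
    group_a, group_b = design.groups
    in_a = (obs_group == group_a).to_numpy()
    n_a, n_b = int(in_a.sum()), int((~in_a).sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must contain cells")

    rows = []
    for ct in sorted(labels.unique()):
        is_ct = (labels == ct).to_numpy()
        a = int((is_ct & in_a).sum())       # type, group a
        b = n_a - a                          # other, group a
        c = int((is_ct & ~in_a).sum())      # type, group b
        d = n_b - c                          # other, group b
        if min(a, b, c, d) == 0:
            aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        else:
            aa, bb, cc, dd = a, b, c, d
        or_ = (aa * dd) / (bb * cc)
        se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
        ci_low, ci_high = np.exp(np.log(or_) - 1.96 * se), np.exp(np.log(or_) + 1.96 * se)
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((ct, a, b, c, d, float(or_), float(ci_low), float(ci_high), float(p)))
    out = pd.DataFrame(rows, columns=OR_COLUMNS)
    out.attrs["group_a"], out.attrs["group_b"] = group_a, group_b
    return out
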