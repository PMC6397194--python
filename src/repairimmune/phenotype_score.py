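"""Immunophenotype groups and the combined DNA-repair/TGFB1/WNT2 score.

Tumors are placed in a 2×2 scheme crossing DNA-repair variant status
with activated-T-cell infiltration:

* group I   — variant absent, not infiltrated
* group II  — variant present, not infiltrated
* group III — variant absent, infiltrated
* group IV  — variant present, infiltrated

The combined score gives one point each for a TGFB1 z-score above the
cohort median, a WNT2 z-score above the median, and the absence of any
DNA-repair gene variant; scores ≤ 1 are "low" and predict activated
T-cell infiltration.  Panel-level comparisons (ANOVA + Tukey, t-test
volcano tables with Storey q, two-proportion subtype associations)
delegate to :mod:`repairimmune.stats_core`.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_io import ExpressionMatrix
from .stats_core import anova_tukey, storey_q, t_test, two_proportion_z

__all__ = [
    "activated_t_flag",
    "assign_group",
    "combined_score",
    "assemble_phenotypes",
    "panel_comparison",
    "signature_table",
    "subtype_association",
]

GROUPS = ("I", "II", "III", "IV")

ACT_CD4 = "Act_CD4"
ACT_CD8 = "Act_CD8"


def activated_t_flag(
    calls: pd.DataFrame,
    convention: str = "either",
    cd4: str = ACT_CD4,
    cd8: str = ACT_CD8,
) -> pd.Series:
    """Per-sample activated-T-cell infiltration flag.

    ``convention`` is "either" (CD4 or CD8, the default), "both", "cd4"
    or "cd8".  ``calls`` is the long-format infiltration table.
    """
    wide = calls.pivot(index="sample_id", columns="cell_type", values="infiltrated")
    for ct in (cd4, cd8):
        if ct not in wide.columns:
            raise ValueError(f"cell type {ct!r} missing from infiltration calls")
    cd4_flag = wide[cd4].astype(bool)
    cd8_flag = wide[cd8].astype(bool)
    if convention == "either":
        return cd4_flag | cd8_flag
    if convention == "both":
        return cd4_flag & cd8_flag
    if convention == "cd4":
        return cd4_flag
    if convention == "cd8":
        return cd8_flag
    raise ValueError(f"unknown activated-T convention {convention!r}")


def assign_group(repair_variant: bool, act_t_infiltrated: bool) -> str:
    """Map (repair variant, activated-T infiltration) to group I–IV."""
    if not repair_variant and not act_t_infiltrated:
        return "I"
    if repair_variant and not act_t_infiltrated:
        return "II"
    if not repair_variant and act_t_infiltrated:
        return "III"
    return "IV"


def combined_score(
    zscores: pd.DataFrame,
    repair_variant: Mapping[str, bool] | pd.Series,
    tgfb1: str = "TGFB1",
    wnt2: str = "WNT2",
    score_cut: int = 1,
) -> pd.DataFrame:
    """Combined DNA-repair/TGFB1/WNT2 score per sample.

    One point each for a TGFB1 z-score strictly greater than the cohort
    median, a WNT2 z-score strictly greater than the median, and absence
    of any DNA-repair gene variant.  ``score_class`` is "low" when the
    score is ≤ ``score_cut`` (default 1), else "high"; low scores
    predict activated T-cell infiltration.
    """
    for gene in (tgfb1, wnt2):
        if gene not in zscores.index:
            raise ValueError(f"gene {gene!r} absent from the expression matrix")
    repair = pd.Series(dict(repair_variant)).astype(bool)
    samples = [s for s in zscores.columns if s in repair.index]
    if not samples:
        raise ValueError("no overlap between expression samples and repair statuses")
    z_t = zscores.loc[tgfb1, samples]
    z_w = zscores.loc[wnt2, samples]
    med_t = float(z_t.median())
    med_w = float(z_w.median())
    score = (z_t > med_t).astype(int) + (z_w > med_w).astype(int) + (~repair[samples]).astype(int)
    return pd.DataFrame(
        {
            "combined_score": score,
            "score_class": np.where(score <= score_cut, "low", "high"),
        },
        index=pd.Index(samples, name="sample_id"),
    )


def assemble_phenotypes(
    repair_variant: Mapping[str, bool] | pd.Series,
    act_t_infiltrated: Mapping[str, bool] | pd.Series,
    zscores: pd.DataFrame,
    score_cut: int = 1,
) -> pd.DataFrame:
    """Per-sample phenotype table: flags, group I–IV, combined score."""
    repair = pd.Series(dict(repair_variant)).astype(bool)
    act = pd.Series(dict(act_t_infiltrated)).astype(bool)
    samples = repair.index.intersection(act.index)
    if samples.empty:
        raise ValueError("no samples with both repair status and infiltration flag")
    score = combined_score(zscores, repair[samples], score_cut=score_cut)
    frame = pd.DataFrame(
        {
            "repair_variant": repair[samples],
            "act_t_infiltrated": act[samples],
            "group": [assign_group(r, a) for r, a in zip(repair[samples], act[samples])],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return frame.join(score)


def panel_comparison(
    groups: pd.Series,
    matrix: ExpressionMatrix,
    panel: Sequence[str],
    min_group_size: int = 2,
) -> pd.DataFrame:
    """Per-gene one-way ANOVA with Tukey pairwise comparisons.

    ``groups`` maps sample → group label.  Output is a long table with
    one row per gene × pairwise comparison plus the gene-level F and p;
    genes or groupings too degenerate to test get a missing entry with a
    reason.
    """
    groups = pd.Series(groups)
    usable = {}
    for label, members in groups.groupby(groups):
        cols = [s for s in members.index if s in matrix.values.columns]
        if len(cols) >= min_group_size:
            usable[label] = cols
    rows = []
    for gene in panel:
        if gene not in matrix.values.index:
            rows.append({"gene": gene, "comparison": None, "p_adj": np.nan, "f": np.nan,
                         "p_anova": np.nan, "reason": "gene absent"})
            continue
        if len(usable) < 2:
            rows.append({"gene": gene, "comparison": None, "p_adj": np.nan, "f": np.nan,
                         "p_anova": np.nan, "reason": "fewer than 2 usable groups"})
            continue
        data = {label: matrix.values.loc[gene, cols].to_numpy() for label, cols in usable.items()}
        try:
            res = anova_tukey(data)
        except ValueError as exc:
            rows.append({"gene": gene, "comparison": None, "p_adj": np.nan, "f": np.nan,
                         "p_anova": np.nan, "reason": str(exc)})
            continue
        for pair in res.pairwise.itertuples(index=False):
            rows.append(
                {
                    "gene": gene,
                    "comparison": f"{pair.group_a} vs {pair.group_b}",
                    "p_adj": pair.p_adj,
                    "f": res.f,
                    "p_anova": res.p,
                    "reason": "",
                }
            )
    return pd.DataFrame(rows)


def signature_table(
    labels: pd.Series,
    matrix: ExpressionMatrix,
    panel: Sequence[str],
    welch: bool = False,
) -> pd.DataFrame:
    """Two-group differential expression over a gene panel.

    Student's t-test per gene between the two label levels with Storey
    q-value adjustment across the panel — the volcano-plot table for
    high- vs low-burden comparisons.
    """
    labels = pd.Series(labels)
    levels = pd.unique(labels)
    if len(levels) != 2:
        raise ValueError(f"signature_table needs a binary split, got {len(levels)} levels")
    a_cols = [s for s in labels.index[labels == levels[0]] if s in matrix.values.columns]
    b_cols = [s for s in labels.index[labels == levels[1]] if s in matrix.values.columns]
    rows = []
    for gene in panel:
        if gene not in matrix.values.index:
            rows.append({"gene": gene, "t": np.nan, "p": np.nan, "mean_diff": np.nan})
            continue
        a = matrix.values.loc[gene, a_cols].to_numpy()
        b = matrix.values.loc[gene, b_cols].to_numpy()
        res = t_test(a, b, welch=welch)
        rows.append({"gene": gene, "t": res.statistic, "p": res.p, "mean_diff": res.estimate})
    out = pd.DataFrame(rows)
    tested = out["p"].notna()
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = storey_q(out.loc[tested, "p"].to_numpy())
    return out


def subtype_association(
    flags: pd.Series,
    labels: pd.Series,
) -> pd.DataFrame:
    """Association of a binary flag with each level of a categorical label.

    For each level, the proportion of flagged samples inside the level
    is compared with the proportion outside it by the pooled
    two-proportion z-test; p-values are Storey-adjusted across levels.
    """
    flags = pd.Series(flags).astype(bool)
    labels = pd.Series(labels)
    common = flags.index.intersection(labels.index)
    flags, labels = flags[common], labels[common]
    levels = [lvl for lvl in pd.unique(labels) if pd.notna(lvl)]
    if len(levels) < 2:
        raise ValueError("subtype association needs >= 2 label levels")
    rows = []
    for level in levels:
        inside = labels == level
        n_in, n_out = int(inside.sum()), int((~inside).sum())
        if n_in == 0 or n_out == 0:
            continue
        res = two_proportion_z(int(flags[inside].sum()), n_in, int(flags[~inside].sum()), n_out)
        rows.append(
            {
                "level": level,
                "prop_in": flags[inside].mean(),
                "prop_out": flags[~inside].mean(),
                "z": res.statistic,
                "p": res.p,
            }
        )
    out = pd.DataFrame(rows)
    tested = out["p"].notna()
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = storey_q(out.loc[tested, "p"].to_numpy())
    return out
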