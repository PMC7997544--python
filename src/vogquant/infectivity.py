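"""Flow-cytometry gating, %GFP-positive, rank tests and luciferase summaries.

Infection readouts follow the standard flow workflow: remove doublets by
height-vs-width scatter gating, set a GFP gate from a non-infected control,
and report the percent of gated events above the gate.  Group comparisons
use the Kruskal-Wallis rank test with Dunn's pairwise post-hoc z-tests.
Luciferase (RLU) readouts are background-subtracted and normalized to p24
input as a proxy for viral dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "InfectionResult",
    "RankTestResult",
    "gate_singlets",
    "percent_positive",
    "kruskal_wallis",
    "dunn_test",
    "rlu_normalize",
]


@dataclass
class InfectionResult:
    """Percent GFP-positive singlets for one condition against a control."""

    condition: str
    n_singlets: int
    percent_positive: float  # 0..100
    gate_value: float
    control_condition: str
    gate_quantile: float


@dataclass
class RankTestResult:
    """Kruskal-Wallis omnibus plus Dunn's pairwise comparisons."""

    H: float
    p_value: float
    pairwise: pd.DataFrame  # group1, group2, z, p_raw, p_adj
    correction: str
    meta: dict = field(default_factory=dict)


_RATIO_PAIRS = (("FSC-W", "FSC-H"), ("SSC-W", "SSC-H"))


def gate_singlets(events: pd.DataFrame, tolerance: float = 3.0) -> pd.DataFrame:
    """Retain singlet events by robust width-to-height scatter ratios.

    For each of FSC-W/FSC-H and SSC-W/SSC-H the band is
    ``median +/- tolerance * 1.4826 * MAD``; the gate is iterated to a fixed
    point (re-fit on the retained events until nothing more is removed), so
    gating an already-gated table changes nothing.
    """
    if len(events) == 0:
        raise ValueError("empty event table")
    df = events
    for _ in range(20):
        keep = np.ones(len(df), dtype=bool)
        for wcol, hcol in _RATIO_PAIRS:
            ratio = df[wcol].to_numpy() / df[hcol].to_numpy()
            med = np.median(ratio)
            mad = np.median(np.abs(ratio - med))
            band = tolerance * 1.4826 * mad
            keep &= np.abs(ratio - med) <= band
        if keep.all():
            break
        df = df[keep]
        if len(df) == 0:
            raise ValueError("singlet gate rejected every event")
    return df.reset_index(drop=True)


def percent_positive(
    events: pd.DataFrame,
    control_events: pd.DataFrame,
    quantile: float = 0.999,
    fluor_column: str = "fluor",
) -> InfectionResult:
    """Percent of events above a GFP gate anchored on the control.

    The gate is the given quantile of the control's fluorescence (so by
    construction roughly ``100 * (1 - quantile)`` percent of control events
    exceed it); both tables should already be singlet-gated.
    """
    if len(control_events) == 0:
        raise ValueError("control table is empty")
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    gate = float(np.quantile(control_events[fluor_column].to_numpy(), quantile))
    frac = float(np.mean(events[fluor_column].to_numpy() > gate))
    condition = str(events["condition"].iloc[0]) if "condition" in events else "sample"
    control = (
        str(control_events["condition"].iloc[0]) if "condition" in control_events else "control"
    )
    return InfectionResult(
        condition=condition,
        n_singlets=len(events),
        percent_positive=100.0 * frac,
        gate_value=gate,
        control_condition=control,
        gate_quantile=quantile,
    )


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with a chi-square p (k-1 df).

    All values identical across all groups yields ``(0.0, 1.0)``.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = stats.kruskal(*arrays)
    return float(H), float(p)


def dunn_test(
    groups: list[np.ndarray],
    correction: str = "holm",
    labels: list[str] | None = None,
) -> RankTestResult:
    """Dunn's pairwise post-hoc comparisons on pooled ranks.

    z for groups i, j is the mean-rank difference over
    ``sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j))`` with the tie correction
    ``T = sum(t^3 - t) / (12 (N - 1))``; two-sided normal p-values are
    adjusted by the configured method (statsmodels ``multipletests``).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("groups must be non-empty")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    H, p_omni = kruskal_wallis(arrays)

    pooled = np.concatenate(arrays)
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    splits = np.cumsum([a.size for a in arrays])[:-1]
    group_ranks = np.split(ranks, splits)
    mean_ranks = [r.mean() for r in group_ranks]

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for i, j in combinations(range(len(arrays)), 2):
        var = base_var * (1.0 / arrays[i].size + 1.0 / arrays[j].size)
        z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var) if var > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group1": labels[i], "group2": labels[j], "z": float(z), "p_raw": min(p_raw, 1.0)})
    pairwise = pd.DataFrame(rows)
    if len(pairwise):
        _, p_adj, _, _ = multipletests(pairwise["p_raw"].to_numpy(), method=correction)
        pairwise["p_adj"] = np.maximum(p_adj, pairwise["p_raw"])
    else:
        pairwise["p_adj"] = []
    return RankTestResult(H=H, p_value=p_omni, pairwise=pairwise, correction=correction)


def rlu_normalize(
    rlu_table: pd.DataFrame,
    p24_table: pd.DataFrame,
    background_conditions: list[str] | None = None,
) -> pd.DataFrame:
    """Background-subtracted RLU per unit p24 input, per condition.

    ``rlu_table`` needs columns (condition, rlu); ``p24_table`` needs
    (condition, p24_ng).  Background is the mean RLU of the
    ``background_conditions`` wells (uninfected / integration-blocked);
    omitted, no subtraction is applied.  Every non-background condition must
    have a positive p24 entry.
    """
    p24 = p24_table.set_index("condition")["p24_ng"]
    background = 0.0
    if background_conditions:
        bg_rows = rlu_table[rlu_table["condition"].isin(background_conditions)]
        if len(bg_rows) == 0:
            raise ValueError("no rows match the background conditions")
        background = float(bg_rows["rlu"].mean())

    rows = []
    for cond, grp in rlu_table.groupby("condition", sort=False):
        if cond not in p24.index:
            raise ValueError(f"condition {cond!r} has no p24 entry")
        p24_val = float(p24.loc[cond])
        if p24_val <= 0:
            raise ValueError(f"condition {cond!r} has non-positive p24 input")
        norm = (grp["rlu"].to_numpy() - background) / p24_val
        rows.append(
            {
                "condition": cond,
                "n_replicates": len(grp),
                "mean_norm_rlu": float(norm.mean()),
                "sd_norm_rlu": float(norm.std(ddof=1)) if len(grp) > 1 else 0.0,
                "p24_ng": p24_val,
                "background_rlu": background,
            }
        )
    return pd.DataFrame(rows)
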