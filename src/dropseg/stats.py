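"""Strain-comparison statistics.

Fields are averaged into one data point per strain per experiment, and
strains are compared by a one-way ANOVA with the experiment treated as
a block ("linked" / repeated-measures design): the two-way additive
decomposition SS_total = SS_strain + SS_block + SS_residual, with
F = MS_strain / MS_residual on (s-1, (s-1)(b-1)) degrees of freedom.

Pairwise comparisons on preselected strain pairs use t statistics with
the pooled residual mean square on the residual degrees of freedom, and
the Holm-Sidak step-down adjustment: sort raw p ascending and set
adjusted p_(k) = 1 - (1 - p_(k))^(m-k+1), enforcing monotonicity by a
running maximum.  Significance stars follow the usual convention
(* p<0.05, ** p<0.01, *** p<0.001).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quant import FieldSummary

__all__ = [
    "AnovaResult",
    "PairwiseResult",
    "build_experiment_table",
    "linked_anova",
    "holm_sidak",
    "significance_stars",
    "report",
]


@dataclass
class AnovaResult:
    F: float
    p_value: float
    df_strain: int
    df_block: int
    df_residual: int
    ss_strain: float
    ss_block: float
    ss_residual: float
    ms_residual: float
    n_blocks: int
    strain_means: dict[str, float]


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    mean_difference: float
    t: float
    p_raw: float
    p_adjusted: float
    stars: str


def build_experiment_table(
    field_summaries: Iterable[FieldSummary] | pd.DataFrame,
    metric: str = "mean_ld_per_cell",
) -> pd.DataFrame:
    """One row per strain x experiment: the unweighted mean over fields.

    Accepts FieldSummary objects or a fields DataFrame with columns
    ``strain``, ``experiment_id`` and the metric.  Raises on an
    incomplete design (a strain missing from some experiment).
    """
    if isinstance(field_summaries, pd.DataFrame):
        fields = field_summaries
    else:
        fields = pd.DataFrame([f.row() for f in field_summaries])
    if metric not in fields.columns:
        raise ValueError(f"unknown metric {metric!r}")
    if fields.empty:
        raise ValueError("no field summaries supplied")
    table = (
        fields.groupby(["strain", "experiment_id"], sort=True)[metric]
        .mean()
        .reset_index()
        .rename(columns={metric: "value"})
    )
    strains = sorted(table["strain"].unique())
    experiments = sorted(table["experiment_id"].unique())
    missing = [
        (s, e)
        for s in strains
        for e in experiments
        if not ((table["strain"] == s) & (table["experiment_id"] == e)).any()
    ]
    if missing:
        raise ValueError(f"incomplete design; missing strain/experiment cells: {missing}")
    return table


def linked_anova(table: pd.DataFrame) -> AnovaResult:
    """Blocked (experiment-linked) one-way ANOVA on an experiment table."""
    pivot = table.pivot(index="strain", columns="experiment_id", values="value")
    if pivot.isna().any().any():
        raise ValueError("incomplete design")
    y = pivot.to_numpy(dtype=float)
    s, b = y.shape
    if s < 2 or b < 2:
        raise ValueError("need at least 2 strains and 2 experiments (blocks)")
    grand = y.mean()
    strain_means = y.mean(axis=1)
    block_means = y.mean(axis=0)
    ss_strain = b * float(((strain_means - grand) ** 2).sum())
    ss_block = s * float(((block_means - grand) ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_res = ss_total - ss_strain - ss_block
    ss_res = max(ss_res, 0.0)
    df_strain, df_block = s - 1, b - 1
    df_res = df_strain * df_block
    if df_res < 1:
        raise ValueError("zero residual degrees of freedom")
    ms_strain = ss_strain / df_strain
    ms_res = ss_res / df_res
    if ms_res == 0:
        F = np.inf if ms_strain > 0 else 0.0
        p = 0.0 if ms_strain > 0 else 1.0
    else:
        F = ms_strain / ms_res
        p = float(sps.f.sf(F, df_strain, df_res))
    return AnovaResult(
        F=float(F),
        p_value=p,
        df_strain=df_strain,
        df_block=df_block,
        df_residual=df_res,
        ss_strain=ss_strain,
        ss_block=ss_block,
        ss_residual=ss_res,
        ms_residual=ms_res,
        n_blocks=b,
        strain_means={str(k): float(v) for k, v in zip(pivot.index, strain_means)},
    )


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def _step_down_adjust(p_raw: np.ndarray, method: str) -> np.ndarray:
    """Step-down multiplicity adjustment (Sidak or Holm-Bonferroni)."""
    m = len(p_raw)
    order = np.argsort(p_raw, kind="stable")
    adj = np.empty(m, dtype=float)
    running = 0.0
    for k, idx in enumerate(order):  # k = 0 .. m-1, rank k+1
        remaining = m - k
        if method == "sidak":
            a = 1.0 - (1.0 - p_raw[idx]) ** remaining
        elif method == "holm":
            a = remaining * p_raw[idx]
        else:
            raise ValueError(f"unknown adjustment method {method!r}")
        running = max(running, min(a, 1.0))
        adj[idx] = running
    return adj


def holm_sidak(
    pairs: Sequence[tuple[str, str]],
    table: pd.DataFrame,
    anova: AnovaResult,
    alpha: float = 0.05,
    method: str = "sidak",
) -> list[PairwiseResult]:
    """Pairwise strain comparisons with step-down adjustment.

    ``pairs`` are the preselected strain pairs (they must be chosen
    before looking at the data; m enters the adjustment).  Each t uses
    the pooled residual mean square from the blocked ANOVA:
    t = (mean_i - mean_j) / sqrt(2 * MS_res / b) on df_residual.
    """
    known = set(anova.strain_means)
    for pair in pairs:
        for strain in pair:
            if strain not in known:
                raise ValueError(f"pair references unknown strain {strain!r}")
    diffs, traws = [], []
    se = np.sqrt(2.0 * anova.ms_residual / anova.n_blocks)
    for i, j in pairs:
        d = anova.strain_means[i] - anova.strain_means[j]
        if se == 0:
            t = np.inf if d != 0 else 0.0
            p = 0.0 if d != 0 else 1.0
        else:
            t = d / se
            p = 2.0 * float(sps.t.sf(abs(t), anova.df_residual))
        diffs.append(d)
        traws.append((t, min(p, 1.0)))
    p_raw = np.array([p for _, p in traws])
    p_adj = _step_down_adjust(p_raw, method)
    return [
        PairwiseResult(
            pair=tuple(pair),
            mean_difference=diffs[k],
            t=traws[k][0],
            p_raw=float(p_raw[k]),
            p_adjusted=float(p_adj[k]),
            stars=significance_stars(float(p_adj[k])),
        )
        for k, pair in enumerate(pairs)
    ]


def report(
    results: Sequence[PairwiseResult],
    out_path: str | Path,
    anova: AnovaResult | None = None,
) -> pd.DataFrame:
    """Write pairwise results as CSV plus a readable text summary."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(
        [
            {
                "strain_a": r.pair[0],
                "strain_b": r.pair[1],
                "mean_difference": r.mean_difference,
                "t": r.t,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "stars": r.stars,
            }
            for r in results
        ],
        columns=[
            "strain_a",
            "strain_b",
            "mean_difference",
            "t",
            "p_raw",
            "p_adjusted",
            "stars",
        ],
    )
    frame.to_csv(out_path, index=False)
    lines = []
    if anova is not None:
        lines.append(
            f"Blocked one-way ANOVA: F({anova.df_strain}, {anova.df_residual}) = "
            f"{anova.F:.4g}, p = {anova.p_value:.4g}"
        )
    for r in results:
        lines.append(
            f"{r.pair[0]} vs {r.pair[1]}: diff = {r.mean_difference:.4g}, "
            f"t = {r.t:.4g}, adj. p = {r.p_adjusted:.4g} [{r.stars}]"
        )
    out_path.with_suffix(".txt").write_text("\n".join(lines) + "\n")
    return frame
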