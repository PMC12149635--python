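"""Group statistics and run report.

One-way (single-factor) ANOVA with Tukey–Kramer post hoc pairwise
comparisons, as is standard for comparing vascular parameters (diameter,
tortuosity, counts) across the three transverse layers.  Summaries are
reported as mean ± SEM (sample standard deviation with the n−1 denominator,
divided by √n).  Significance is flagged at p < .05; all raw p values are
emitted.
"""

from __future__ import annotations

from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps


def _as_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, dict):
        items = groups.items()
    else:
        items = ((f"group{i}", g) for i, g in enumerate(groups))
    out = {str(k): np.asarray(v, dtype=float).ravel() for k, v in items}
    if len(out) < 2:
        raise ValueError("need at least two groups")
    for name, vals in out.items():
        if vals.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    return out


def mean_sem(values) -> tuple[float, float]:
    """Mean and standard error of the mean (ddof=1)."""
    v = np.asarray(values, dtype=float).ravel()
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))


def anova_oneway(groups) -> tuple[float, float]:
    """Classical one-way ANOVA: returns (F, p).

    F is the ratio of between-group to within-group mean squares; p comes
    from the F(k−1, N−k) distribution.  If every observation is identical
    (zero within- and between-group variance) F is defined as 0 and p as 1.
    """
    g = _as_groups(groups)
    values = list(g.values())
    k = len(values)
    ns = np.array([v.size for v in values])
    N = int(ns.sum())
    grand = np.concatenate(values).mean()
    ss_between = float(sum(n * (v.mean() - grand) ** 2 for n, v in zip(ns, values)))
    ss_within = float(sum(((v - v.mean()) ** 2).sum() for v in values))
    df_b, df_w = k - 1, N - k
    ms_between = ss_between / df_b
    ms_within = ss_within / df_w
    if ms_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    F = ms_between / ms_within
    p = float(sps.f.sf(F, df_b, df_w))
    return float(F), p


def tukey_kramer(groups, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey–Kramer pairwise comparisons after one-way ANOVA.

    For groups a, b with means m, sizes n and pooled within-group mean square
    MSW, the studentized-range statistic is

        q = |m_a − m_b| / sqrt( MSW/2 · (1/n_a + 1/n_b) )

    with the Kramer harmonic correction handling unequal sizes (for equal
    sizes this reduces to the plain Tukey HSD).  Adjusted p values come from
    the studentized-range distribution with k groups and N−k error df.

    Returns a DataFrame with one row per unordered pair.
    """
    g = _as_groups(groups)
    names = list(g)
    k = len(names)
    ns = {n: g[n].size for n in names}
    N = sum(ns.values())
    df_w = N - k
    msw = sum(((g[n] - g[n].mean()) ** 2).sum() for n in names) / df_w

    rows = []
    qs = []
    for a, b in combinations(names, 2):
        diff = g[a].mean() - g[b].mean()
        if msw > 0:
            se = np.sqrt(msw / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            q = abs(diff) / se
        else:
            q = 0.0 if diff == 0 else float("inf")
        qs.append(q)
        rows.append({"group_a": a, "group_b": b, "mean_diff": diff, "q": q})
    q_arr = np.array(qs)
    finite = np.isfinite(q_arr)
    p_adj = np.ones_like(q_arr)
    if finite.any():
        p_adj[finite] = sps.studentized_range.sf(q_arr[finite], k, df_w)
    p_adj[~finite] = 0.0
    p_adj = np.clip(p_adj, 0.0, 1.0)
    for row, p in zip(rows, p_adj):
        row["p_adj"] = float(p)
        row["significant"] = bool(p < alpha)
    return pd.DataFrame(rows)


def compare_layers(per_segment: pd.DataFrame, value: str, unit: str = "segment",
                   alpha: float = 0.05) -> dict:
    """ANOVA + Tukey–Kramer of a per-segment column across transverse layers.

    ``unit`` declares the sampling unit: ``"segment"`` treats each vessel
    segment as an observation; ``"specimen"`` expects a ``specimen`` column
    and compares per-specimen means.
    """
    df = per_segment.dropna(subset=[value, "layer"])
    if unit == "specimen":
        df = df.groupby(["layer", "specimen"], as_index=False)[value].mean()
    groups = {name: sub[value].to_numpy() for name, sub in df.groupby("layer")}
    groups = {k: v for k, v in groups.items() if v.size >= 2}
    if len(groups) < 2:
        return {"F": np.nan, "p": np.nan, "pairwise": pd.DataFrame()}
    F, p = anova_oneway(groups)
    pairwise = tukey_kramer(groups, alpha=alpha)
    return {"F": F, "p": p, "pairwise": pairwise}


def render_report(
    out_path: str | Path,
    contributions: dict[str, pd.DataFrame],
    layer_stats: pd.DataFrame,
    histogram: pd.DataFrame | None = None,
    comparisons: dict[str, dict] | None = None,
    title: str = "Meniscal vasculature run report",
) -> Path:
    """Write a Markdown run report aggregating all result tables."""
    out_path = Path(out_path)
    lines = [f"# {title}", ""]
    lines += ["## Per-layer vessel statistics (mean ± SEM)", "",
              layer_stats.to_markdown(index=False), ""]
    for axis, table in contributions.items():
        lines += [f"## Vascular contributions — {axis} zones", "",
                  table.to_markdown(index=False), ""]
    if histogram is not None:
        lines += ["## Segment diameter distribution (counts per bin)", "",
                  histogram.to_markdown(), ""]
    if comparisons:
        for name, res in comparisons.items():
            lines += [f"## Layer comparison — {name}", "",
                      f"One-way ANOVA: F = {res['F']:.4g}, p = {res['p']:.4g}", ""]
            if len(res["pairwise"]):
                lines += [res["pairwise"].to_markdown(index=False), ""]
    out_path.write_text("\n".join(lines))
    return out_path
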