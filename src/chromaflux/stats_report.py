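"""Group-comparison statistics and report generation.

The classification stage yields per-cell fractions (scattered, 1-2
nucleosomes, >= 3 nucleosomes) under several treatment conditions.  These
are compared by one-way ANOVA followed by Dunnett's many-to-one test
against the control group.  The Dunnett adjustment uses the equicoordinate
distribution of the maximum absolute correlated t statistic, evaluated by
seeded Monte Carlo so that arbitrary unbalanced designs are handled with a
quantifiable Monte-Carlo standard error.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
from scipy import stats as sps

from .config import PipelineConfig


@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_means: dict[str, float]


@dataclass
class DunnettResult:
    control: str
    comparisons: pd.DataFrame  # group, t, p_adjusted, mc_se
    n_draws: int
    seed: int


def _validate_groups(table: pd.DataFrame) -> dict[str, np.ndarray]:
    if not {"group", "value"}.issubset(table.columns):
        raise ValueError("group table needs 'group' and 'value' columns")
    groups = {g: sub["value"].to_numpy(float) for g, sub in table.groupby("group", sort=False)}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has {len(v)} row(s); ANOVA needs >= 2")
    return groups


def one_way_anova(table: pd.DataFrame) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA on a group/value table.

    F is the ratio of the between-group to the within-group mean square;
    the p-value comes from the F distribution with (k - 1, N - k) degrees
    of freedom.
    """
    groups = _validate_groups(table)
    values = np.concatenate(list(groups.values()))
    grand = values.mean()
    n_total = len(values)
    k = len(groups)
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_b, df_w = k - 1, n_total - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        f = 0.0 if ms_b == 0 else float("inf")
    else:
        f = ms_b / ms_w
    p = float(sps.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    return AnovaResult(float(f), df_b, df_w, p, {g: float(v.mean()) for g, v in groups.items()})


def dunnett(
    table: pd.DataFrame,
    control: str,
    n_draws: int = 100_000,
    seed: int = 0,
) -> DunnettResult:
    """Dunnett's two-sided many-to-one comparisons against a control group.

    Test statistics use the pooled within-group variance.  The adjusted
    p-value for comparison j is P(max_i |T_i| >= |t_j|) under the joint
    null, where (T_1 ... T_k) are the correlated many-to-one t statistics;
    the joint distribution is sampled by Monte Carlo (``n_draws`` draws of
    the group means and the pooled chi-squared variance).  The per-p
    Monte-Carlo standard error sqrt(p(1-p)/n_draws) is reported.
    """
    groups = _validate_groups(table)
    if control not in groups:
        raise ValueError(f"control group {control!r} not present")
    others = [g for g in groups if g != control]
    vc = groups[control]
    nc = len(vc)
    nu = sum(len(v) for v in groups.values()) - len(groups)
    s2 = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / nu

    t_obs = np.array(
        [
            (groups[g].mean() - vc.mean()) / np.sqrt(s2 * (1 / len(groups[g]) + 1 / nc))
            for g in others
        ]
    )

    rng = np.random.default_rng(seed)
    z0 = rng.standard_normal(n_draws)
    w = rng.chisquare(nu, size=n_draws)
    scale = np.sqrt(w / nu)
    max_abs_t = np.zeros(n_draws)
    for g in others:
        ng = len(groups[g])
        zg = rng.standard_normal(n_draws)
        t = (zg / np.sqrt(ng) - z0 / np.sqrt(nc)) / (np.sqrt(1 / ng + 1 / nc) * scale)
        np.maximum(max_abs_t, np.abs(t), out=max_abs_t)

    p_adj = np.array([float(np.mean(max_abs_t >= abs(t))) for t in t_obs])
    mc_se = np.sqrt(p_adj * (1 - p_adj) / n_draws)
    comparisons = pd.DataFrame(
        {"group": others, "t": t_obs, "p_adjusted": p_adj, "mc_se": mc_se}
    )
    return DunnettResult(control, comparisons, n_draws, seed)


def build_report(
    out_dir: str | Path,
    fiber_summary: dict | None = None,
    nucleosome_hist: dict | None = None,
    classifications: list | None = None,
    anova_results: dict[str, AnovaResult] | None = None,
    dunnett_results: dict[str, DunnettResult] | None = None,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> Path:
    """Write the analysis summary tables and a run manifest.

    Produces (when the corresponding input is given) ``fiber_lengths.csv``,
    ``segments.csv``, ``nucleosome_diameters.csv``, ``regions.csv`` and
    ``stats.csv`` plus ``manifest.json`` recording the configuration, seed
    and library versions.  Output is deterministic for fixed inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if fiber_summary is not None:
        fiber_summary["lengths"].to_csv(out / "fiber_lengths.csv", index=False,
                                        float_format="%.6g", lineterminator="\n")
        fiber_summary["segments"].to_csv(out / "segments.csv", index=False,
                                         float_format="%.6g", lineterminator="\n")
    if nucleosome_hist is not None and len(nucleosome_hist.get("counts", [])):
        edges = nucleosome_hist["edges"]
        pd.DataFrame(
            {
                "bin_lo_nm": edges[:-1],
                "bin_hi_nm": edges[1:],
                "count": nucleosome_hist["counts"],
            }
        ).to_csv(out / "nucleosome_diameters.csv", index=False,
                 float_format="%.6g", lineterminator="\n")
    if classifications:
        pd.DataFrame(
            {
                "region_id": [c.region_id for c in classifications],
                "n_locs": [c.n_locs for c in classifications],
                "fraction_scattered": [c.fraction_scattered for c in classifications],
                "fraction_1_2": [c.fraction_1_2 for c in classifications],
                "fraction_3plus": [c.fraction_3plus for c in classifications],
            }
        ).to_csv(out / "regions.csv", index=False, float_format="%.6g",
                 lineterminator="\n")

    rows = []
    for name, res in (anova_results or {}).items():
        rows.append(
            {
                "metric": name,
                "test": "anova",
                "comparison": "",
                "statistic": res.f_statistic,
                "df_between": res.df_between,
                "df_within": res.df_within,
                "p": res.p_value,
            }
        )
        dr = (dunnett_results or {}).get(name)
        if dr is not None:
            for _, row in dr.comparisons.iterrows():
                rows.append(
                    {
                        "metric": name,
                        "test": "dunnett",
                        "comparison": f"{dr.control} vs {row['group']}",
                        "statistic": row["t"],
                        "df_between": "",
                        "df_within": "",
                        "p": row["p_adjusted"],
                    }
                )
    if rows:
        pd.DataFrame(rows).to_csv(out / "stats.csv", index=False,
                                  float_format="%.6g", lineterminator="\n")

    manifest = {
        "config": (config or PipelineConfig()).to_dict(),
        "seed": seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
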