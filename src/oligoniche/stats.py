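"""Per-animal summarization and the study's named group-comparison tests.

The animal is the experimental unit: per-FOV measurements are averaged
over 5 fields of view across at least three sections before any group
test.  ``compare_groups`` encodes which named test applies to which
pipeline output (see ``DEFAULT_TESTS``): Welch's t for per-animal counts
and densities, Mann-Whitney U for ultrastructure and bootstrap volumes,
two-way ANOVA + Holm-Sidak for core/edge cell counts over time,
Chi-square comparison of binned distributions for post-stroke
myelination, Kruskal-Wallis + Benjamini-Hochberg FDR for conditioned
media panels, a one-sample t against zero expression, and an ordinal
shift Chi-square for ordinal severity scores.  The tests themselves
delegate to scipy/statsmodels; this module's contribution is the
dispatch, averaging, and adjustment conventions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["per_animal_summary", "compare_groups", "DEFAULT_TESTS"]

ALPHA = 0.05

# Which named test each upstream artifact gets by default.
DEFAULT_TESTS = {
    "cells_per_mm": "welch_t",
    "opc_fraction": "welch_t",
    "vessel_density": "welch_t",
    "gratio": "mann_whitney_u",
    "ultrastructure": "mann_whitney_u",
    "lesion_volume": "mann_whitney_u",
    "cell_counts_core_edge": "anova2_holm_sidak",
    "myelination_profile": "chi2_distributions",
    "conditioned_media": "kruskal_fdr",
    "vessel_segment_fraction": "one_sample_t",
    "ordinal_severity": "ordinal_shift_chi2",
}

_METHODS = (
    "welch_t",
    "mann_whitney_u",
    "anova2_holm_sidak",
    "chi2_distributions",
    "kruskal_fdr",
    "one_sample_t",
    "ordinal_shift_chi2",
)


def per_animal_summary(
    records: pd.DataFrame,
    value: str = "value",
    animal: str = "animal",
    section: str = "section",
    fov: str = "fov",
    group: str = "group",
) -> pd.DataFrame:
    """Collapse per-FOV records to one value per animal (plain mean).

    Requires animal/section/FOV tags on every record.  Section and FOV
    counts are reported for audit; unbalanced designs are averaged as-is
    (the counts make the imbalance visible).
    """
    missing = [c for c in (value, animal, section, fov) if c not in records.columns]
    if missing:
        raise ValueError(f"records are missing required tags: {missing}")
    keys = [animal] if group not in records.columns else [group, animal]
    out = (
        records.groupby(keys, sort=True)
        .agg(
            value=(value, "mean"),
            n_fov=(fov, "count"),
            n_sections=(section, "nunique"),
        )
        .reset_index()
    )
    return out


def _two_sample(data: pd.DataFrame, value: str, group: str):
    levels = sorted(data[group].unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, found {levels}")
    x = data.loc[data[group] == levels[0], value].to_numpy(dtype=float)
    y = data.loc[data[group] == levels[1], value].to_numpy(dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    return levels, x, y


def _holm_sidak(pvals: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvals, method="holm-sidak")[1]


def _bh(pvals: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvals, method="fdr_bh")[1]


def compare_groups(
    data,
    method: str,
    value: str = "value",
    group: str = "group",
    alpha: float = ALPHA,
    **options,
) -> dict:
    """Run one named group-comparison test on tidy per-animal data.

    ``data`` is a tidy DataFrame (or, for ``chi2_distributions``, either
    tidy counts with ``group``/``bin``/``count`` columns or a 2D count
    array, groups in rows).  Returns statistic, p, adjusted p where the
    method defines one, per-group n, and the alpha = 0.05 decision.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {_METHODS}")
    out: dict = {"method": method, "alpha": alpha, "adj_p": None}

    if method == "welch_t":
        levels, x, y = _two_sample(data, value, group)
        t, p = sps.ttest_ind(x, y, equal_var=False)
        out.update(statistic=float(t), p=float(p), n={levels[0]: len(x), levels[1]: len(y)})

    elif method == "mann_whitney_u":
        levels, x, y = _two_sample(data, value, group)
        u, p = sps.mannwhitneyu(x, y, alternative="two-sided")
        out.update(statistic=float(u), p=float(p), n={levels[0]: len(x), levels[1]: len(y)})

    elif method == "one_sample_t":
        vals = np.asarray(data[value] if isinstance(data, pd.DataFrame) else data, dtype=float)
        if len(vals) < 2:
            raise ValueError("one-sample t needs at least 2 observations")
        popmean = options.get("popmean", 0.0)
        t, p = sps.ttest_1samp(vals, popmean)
        out.update(statistic=float(t), p=float(p), n={"all": len(vals)}, popmean=popmean)

    elif method == "anova2_holm_sidak":
        factor2 = options.get("factor2", "region")
        if factor2 not in data.columns:
            raise ValueError(f"two-way ANOVA needs a second factor column {factor2!r}")
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        df = data.rename(columns={value: "_y", group: "_g", factor2: "_f"})
        model = smf.ols("_y ~ C(_g) * C(_f)", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
        # post hoc: group contrast within each level of the second factor
        ph = []
        for lev, sub in df.groupby("_f", sort=True):
            glev = sorted(sub["_g"].unique())
            if len(glev) != 2:
                continue
            a = sub.loc[sub["_g"] == glev[0], "_y"]
            b = sub.loc[sub["_g"] == glev[1], "_y"]
            t, p = sps.ttest_ind(a, b, equal_var=False)
            ph.append({"level": lev, "t": float(t), "p": float(p)})
        posthoc = pd.DataFrame(ph)
        if len(posthoc):
            posthoc["adj_p"] = _holm_sidak(posthoc["p"].to_numpy())
        p_group = float(table.loc["C(_g)", "PR(>F)"])
        out.update(
            statistic=float(table.loc["C(_g)", "F"]),
            p=p_group,
            anova_table=table,
            posthoc=posthoc,
            n=data.groupby(group)[value].count().to_dict(),
        )

    elif method == "chi2_distributions":
        if isinstance(data, pd.DataFrame) and {"group", "bin", "count"} <= set(data.columns):
            counts = data.pivot_table(index="group", columns="bin", values="count",
                                      aggfunc="sum", fill_value=0).to_numpy()
        else:
            counts = np.asarray(data, dtype=float)
        if counts.ndim != 2 or counts.shape[0] < 2:
            raise ValueError("need a (groups x bins) count table with ≥ 2 groups")
        chi2, p, dof, _ = sps.chi2_contingency(counts, correction=False)
        out.update(statistic=float(chi2), p=float(p), dof=int(dof),
                   n={f"group{i}": int(c) for i, c in enumerate(counts.sum(axis=1))})

    elif method == "kruskal_fdr":
        feature = options.get("feature")
        if feature is not None and feature in data.columns:
            recs = []
            for feat, sub in data.groupby(feature, sort=True):
                samples = [g[value].to_numpy(dtype=float) for _, g in sub.groupby(group)]
                h, p = sps.kruskal(*samples)
                recs.append({"feature": feat, "H": float(h), "p": float(p)})
            tab = pd.DataFrame(recs)
            tab["adj_p"] = _bh(tab["p"].to_numpy())
            out.update(statistic=float(tab["H"].iloc[0]), p=float(tab["p"].iloc[0]),
                       adj_p=float(tab["adj_p"].iloc[0]), per_feature=tab,
                       n=data.groupby(group)[value].count().to_dict())
        else:
            samples = [g[value].to_numpy(dtype=float) for _, g in data.groupby(group)]
            if len(samples) < 2:
                raise ValueError("Kruskal-Wallis needs ≥ 2 groups")
            h, p = sps.kruskal(*samples)
            out.update(statistic=float(h), p=float(p), adj_p=float(p),
                       n=data.groupby(group)[value].count().to_dict())

    elif method == "ordinal_shift_chi2":
        scores = np.asarray(data[value], dtype=float)
        if not np.allclose(scores, np.round(scores)):
            raise ValueError("ordinal shift test requires integer-coded ordinal scores")
        cats = np.unique(scores)
        levels = sorted(data[group].unique())
        if len(levels) < 2 or len(cats) < 2:
            raise ValueError("need ≥ 2 groups and ≥ 2 ordinal categories")
        counts = np.array(
            [[np.sum((data[group] == g) & (scores == c)) for c in cats] for g in levels]
        )
        if options.get("trend", False):
            # linear-by-linear association (test of trend), df = 1
            gnum = pd.Categorical(data[group], categories=levels).codes.astype(float)
            r = np.corrcoef(gnum, scores)[0, 1]
            m2 = (len(scores) - 1) * r**2
            out.update(statistic=float(m2), p=float(sps.chi2.sf(m2, df=1)), dof=1)
        else:
            chi2, p, dof, _ = sps.chi2_contingency(counts, correction=False)
            out.update(statistic=float(chi2), p=float(p), dof=int(dof))
        out["n"] = {g: int(n) for g, n in zip(levels, counts.sum(axis=1))}

    out["reject"] = bool(out["p"] < alpha)
    return out


def results_table(results: list[dict]) -> pd.DataFrame:
    """Tidy results table (one test per row) for CSV export."""
    rows = []
    for r in results:
        rows.append(
            {
                "method": r["method"],
                "statistic": r["statistic"],
                "p": r["p"],
                "adj_p": r.get("adj_p"),
                "n": ";".join(f"{k}={v}" for k, v in r.get("n", {}).items()),
                "alpha": r["alpha"],
                "reject": r["reject"],
            }
        )
    return pd.DataFrame(rows)
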