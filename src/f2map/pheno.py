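"""Phenotype-level statistics for replicated mutant/wild-type designs.

Covers broad-sense heritability from replicated lines, vernalization
sensitivity as log2 flowering-time ratios, knockout/knockdown
classification by relative expression, trait correlations, paired
mutant-vs-wild-type contrasts with multiplicity control, qPCR
relative-expression quantification (ddCt), and growth-trajectory
analysis of projected rosette area.

Phenotype tables are tidy DataFrames with one row per measurement:
``line``, ``genotype_class`` (wildtype/mutant), ``treatment`` (none /
vernalized), ``replicate`` and trait columns (DTF, RLN, CLN, TLN,
``flc_expression`` ...).  Growth tables have ``line``, ``replicate``,
``day``, ``area_px``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def broad_sense_heritability(table: pd.DataFrame, trait: str, line_col: str = "line") -> float:
    """Broad-sense heritability H2 from replicated lines.

    One-way random-effects variance components by the method of moments:
    H2 = sigma2_line / (sigma2_line + sigma2_error), with
    sigma2_line = (MSB - MSW) / k0 and the unbalanced-design effective
    replicate number k0 = (N - sum(n_i^2)/N) / (g - 1).  The estimate is
    clipped to [0, 1].
    """
    df = table[[line_col, trait]].dropna()
    groups = df.groupby(line_col)[trait]
    sizes = groups.size()
    if (sizes >= 2).sum() < 2 or len(sizes) < 2:
        raise ValueError("need >= 2 lines with >= 2 replicates")
    N = sizes.sum()
    g = len(sizes)
    grand = df[trait].mean()
    means = groups.mean()
    ssb = float((sizes * (means - grand) ** 2).sum())
    ssw = float(((df[trait] - df[line_col].map(means)) ** 2).sum())
    msb = ssb / (g - 1)
    msw = ssw / (N - g)
    k0 = (N - (sizes**2).sum() / N) / (g - 1)
    sigma_line = (msb - msw) / k0
    h2 = sigma_line / (sigma_line + msw)
    return float(np.clip(h2, 0.0, 1.0))


def vernalization_sensitivity(table: pd.DataFrame, trait: str, line_col: str = "line") -> pd.Series:
    """Per-line log2(mean without vernalization / mean with vernalization).

    Vernalized measurements are expected to already have the cold period
    (60 days under the standard protocol) subtracted on ingestion.  Lines
    missing either treatment arm are skipped with a log entry.
    """
    out = {}
    for line, sub in table.groupby(line_col):
        arms = sub.groupby("treatment")[trait].mean()
        if "none" not in arms or "vernalized" not in arms or arms.isna().any():
            logger.info("line %s missing a treatment arm; skipped", line)
            continue
        out[line] = float(np.log2(arms["none"] / arms["vernalized"]))
    return pd.Series(out, name=f"vern_sensitivity_{trait}")


KO_KD_CUTOFF = 5.0  # relative expression (a.u.) dividing knockouts from knockdowns


def classify_ko_kd(table: pd.DataFrame, cutoff: float = KO_KD_CUTOFF,
                   expression_col: str = "flc_expression", line_col: str = "line") -> pd.Series:
    """Label mutant lines knockout (KO) or knockdown (KD) by expression.

    Line mean relative expression below ``cutoff`` (5 a.u.) is KO;
    at or above is KD.  Wild-type rows are rejected: the classification
    applies to mutants only.
    """
    if "genotype_class" in table.columns and (table["genotype_class"] == "wildtype").any():
        raise ValueError("classification applies to mutant lines only")
    means = table.groupby(line_col)[expression_col].mean()
    return pd.Series(np.where(means < cutoff, "KO", "KD"), index=means.index, name="class")


def trait_correlations(table: pd.DataFrame, traits: list[str], line_col: str = "line") -> pd.DataFrame:
    """Pairwise Pearson correlations of per-line trait means.

    Returns a tidy table with r, two-sided p and df = n - 2 per pair;
    pairs with fewer than 3 complete lines yield NaN with a warning.
    """
    means = table.groupby(line_col)[traits].mean()
    rows = []
    for i, t1 in enumerate(traits):
        for t2 in traits[i:]:
            sub = means[[t1, t2]].dropna()
            n = len(sub)
            if n < 3:
                warnings.warn(f"fewer than 3 lines for {t1} vs {t2}")
                r, p = np.nan, np.nan
            elif t1 == t2:
                r, p = 1.0, 0.0
            else:
                r, p = stats.pearsonr(sub[t1], sub[t2])
            rows.append({"trait1": t1, "trait2": t2, "r": float(r), "p": float(p), "df": n - 2})
    return pd.DataFrame(rows)


def _degenerate_t_p(a: np.ndarray, b: np.ndarray) -> float | None:
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return 1.0
        warnings.warn("zero-variance groups with unequal means: p = 0")
        return 0.0
    return None


def pairwise_contrasts(
    data: pd.DataFrame,
    pairs: list[tuple[str, str]],
    value_col: str,
    group_col: str = "line",
    test: str = "t_two_sided",
    correction: str = "benjamini_hochberg",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mutant-vs-wild-type contrasts with multiple-testing correction.

    ``pairs`` lists (mutant, wildtype) group labels.  ``test`` is
    ``t_two_sided`` (Student's t) or ``mann_whitney`` (rank test with
    mid-rank tie handling; exact for small samples, normal approximation
    with continuity correction otherwise).  ``correction`` is
    ``benjamini_hochberg``, ``bonferroni`` or ``none``.
    """
    rows = []
    for mutant, wildtype in pairs:
        a = data.loc[data[group_col] == mutant, value_col].dropna().to_numpy()
        b = data.loc[data[group_col] == wildtype, value_col].dropna().to_numpy()
        if test == "t_two_sided":
            if len(a) < 2 or len(b) < 2:
                raise ValueError(f"t test needs >= 2 values per side ({mutant} vs {wildtype})")
            p_deg = _degenerate_t_p(a, b)
            if p_deg is not None:
                stat, p = np.nan, p_deg
            else:
                stat, p = stats.ttest_ind(a, b)
        elif test == "mann_whitney":
            if len(a) < 1 or len(b) < 1:
                raise ValueError("rank test needs >= 1 value per side")
            method = "exact" if max(len(a), len(b)) <= 8 and not _has_ties(a, b) else "asymptotic"
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append(
            {
                "mutant": mutant,
                "wildtype": wildtype,
                "statistic": float(stat),
                "p_raw": float(p),
                "direction": "up" if a.mean() > b.mean() else ("down" if a.mean() < b.mean() else "none"),
            }
        )
    out = pd.DataFrame(rows)
    if correction == "benjamini_hochberg":
        out["p_adj"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    elif correction == "bonferroni":
        out["p_adj"] = np.minimum(out["p_raw"] * len(out), 1.0)
    elif correction == "none":
        out["p_adj"] = out["p_raw"]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    out["significant"] = out["p_adj"] < alpha
    return out


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return len(np.unique(pooled)) < len(pooled)


def delta_delta_ct(
    ct: pd.DataFrame,
    target_col: str = "ct_target",
    reference_col: str = "ct_reference",
    calibrator: str | tuple | None = None,
    sample_col: str = "sample",
) -> pd.Series:
    """Relative expression 2^(-ddCt) against a reference gene and calibrator.

    dCt = Ct_target - Ct_reference per sample; ddCt subtracts the
    calibrator's dCt (by convention biological replicate 1 of the
    reference accession, e.g., Col-0 rep1).  Samples with a missing
    reference Ct are skipped.
    """
    df = ct.copy()
    ok = df[[target_col, reference_col]].notna().all(axis=1)
    skipped = (~ok).sum()
    if skipped:
        logger.info("ddCt: %d samples skipped for missing Ct", skipped)
    df = df[ok]
    dct = df[target_col] - df[reference_col]
    if calibrator is None:
        calibrator = df[sample_col].iloc[0]
    cal_mask = df[sample_col] == calibrator
    if not cal_mask.any():
        raise ValueError(f"calibrator {calibrator!r} not found")
    ddct = dct - dct[cal_mask].iloc[0]
    out = pd.Series(np.power(2.0, -ddct.to_numpy()), index=df[sample_col], name="relative_expression")
    return out


# ---------------------------------------------------------------------------
# growth trajectories


@dataclass
class GrowthAnalysisResult:
    rgr: pd.DataFrame  # line, replicate, rgr
    daily_contrasts: pd.DataFrame  # per mutant per day, p_raw/p_adj
    trajectories: pd.DataFrame  # mutants x days, daily log2(mutant/wildtype)
    clusters: pd.Series  # mutant -> cluster label 1..k
    excluded: pd.DataFrame  # line, replicate, reason


def growth_analysis(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]],
    rgr_days: tuple[int, int] = (11, 18),
    n_clusters: int = 3,
    min_any_px: float = 500.0,
    min_late_px: float = 5000.0,
    test: str = "mann_whitney",
    correction: str = "benjamini_hochberg",
    alpha: float = 0.05,
) -> GrowthAnalysisResult:
    """Relative growth rate, per-day contrasts and trajectory clustering.

    Plants below ``min_any_px`` on any measured day, or below
    ``min_late_px`` in the late stage (the final third of measured days),
    are excluded (likely empty pots or dying plants).  RGR is the log-area
    slope between the two ``rgr_days`` endpoints: (ln A_d2 - ln A_d1) /
    (d2 - d1), NaN when either day is missing.  Per-mutant trajectory
    vectors of daily log2(mutant mean / wildtype mean) are clustered by
    Ward linkage on Euclidean distance into ``n_clusters`` groups;
    interior missing days are linearly interpolated, ends are not
    extrapolated.
    """
    if (table["area_px"] <= 0).any():
        raise ValueError("areas must be positive")
    days = np.sort(table["day"].unique())
    late_days = days[len(days) - max(len(days) // 3, 1):]

    excluded_rows = []
    keep_keys = []
    for (line, rep), sub in table.groupby(["line", "replicate"]):
        if (sub["area_px"] < min_any_px).any():
            excluded_rows.append({"line": line, "replicate": rep, "reason": f"< {min_any_px} px on a day"})
        elif (sub.loc[sub["day"].isin(late_days), "area_px"] < min_late_px).any():
            excluded_rows.append({"line": line, "replicate": rep, "reason": f"< {min_late_px} px late stage"})
        else:
            keep_keys.append((line, rep))
    kept = table.set_index(["line", "replicate"]).loc[keep_keys].reset_index()

    d1, d2 = rgr_days
    rgr_rows = []
    for (line, rep), sub in kept.groupby(["line", "replicate"]):
        by_day = sub.set_index("day")["area_px"]
        if d1 in by_day.index and d2 in by_day.index:
            rgr = (np.log(by_day[d2]) - np.log(by_day[d1])) / (d2 - d1)
        else:
            rgr = np.nan
        rgr_rows.append({"line": line, "replicate": rep, "rgr": rgr})
    rgr_df = pd.DataFrame(rgr_rows)

    contrast_frames = []
    for day in days:
        sub = kept[kept["day"] == day]
        day_pairs = [
            (m, w) for m, w in pairs
            if (sub["line"] == m).any() and (sub["line"] == w).any()
        ]
        if not day_pairs:
            continue
        res = pairwise_contrasts(sub, day_pairs, "area_px", group_col="line",
                                 test=test, correction=correction, alpha=alpha)
        res.insert(0, "day", day)
        contrast_frames.append(res)
    daily = pd.concat(contrast_frames, ignore_index=True) if contrast_frames else pd.DataFrame()

    means = kept.groupby(["line", "day"])["area_px"].mean()
    traj_rows = {}
    for mutant, wildtype in pairs:
        vec = []
        for day in days:
            m = means.get((mutant, day), np.nan)
            w = means.get((wildtype, day), np.nan)
            vec.append(np.log2(m / w) if np.isfinite(m) and np.isfinite(w) else np.nan)
        traj_rows[mutant] = vec
    traj = pd.DataFrame.from_dict(traj_rows, orient="index", columns=days)
    traj = traj.apply(lambda row: row.interpolate(limit_area="inside"), axis=1)

    complete = traj.dropna(axis=1, how="any")
    if len(traj) >= max(n_clusters, 2) and complete.shape[1] >= 1:
        Z = linkage(complete.to_numpy(), method="ward", metric="euclidean")
        labels = fcluster(Z, t=n_clusters, criterion="maxclust")
        clusters = pd.Series(labels, index=traj.index, name="cluster")
    else:
        clusters = pd.Series(np.ones(len(traj), dtype=int), index=traj.index, name="cluster")
    return GrowthAnalysisResult(rgr_df, daily, traj, clusters, pd.DataFrame(excluded_rows))
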