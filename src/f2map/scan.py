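"""Genome scans and multiple-QTL model selection for F2 crosses.

The scan regresses the phenotype on conditional genotype probabilities
(Haley-Knott regression): at each marker and pseudomarker, probabilities
of AA/AB/BB given the flanking marker genotypes provide an additive
predictor (P(BB) - P(AA)) and a dominance predictor (P(AB));
LOD = (n/2) * log10(RSS0/RSS1) against the intercept-only null.
Genome-wide significance comes from permuting the phenotype vector against
the intact genotype matrix.  Multiple-QTL models are selected by a
forward/backward search maximizing the penalized LOD
pLOD = LOD - penalty * (number of QTL) over additive models, and each QTL
is summarized by its 95% Bayes interval (normalized 10^LOD mass), signed
additive effect and explained variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cross import CrossObject
from .genome import haldane_r
from .hmm import f2_transition

logger = logging.getLogger(__name__)

F2_PRIOR = np.array([0.25, 0.5, 0.25])
_RSS_FLOOR_FRAC = 1e-12


# ---------------------------------------------------------------------------
# conditional genotype probabilities


@dataclass
class GenoProb:
    """Conditional genotype probabilities on the marker + pseudomarker grid."""

    positions: pd.DataFrame  # chrom, pos_cm, pos_bp, is_marker
    probs: np.ndarray  # (n_individuals, n_positions, 3)
    individuals: list[str]


def calc_genoprob(cross: CrossObject, step_cm: float = 2.0, error_prob: float = 1e-4) -> GenoProb:
    """Genotype probabilities at markers and a ``step_cm`` pseudomarker grid.

    A forward-backward pass per chromosome treats observed marker codes as
    emissions with genotyping-error probability ``error_prob``; missing
    genotypes emit uniformly (they are summed over with prior weights);
    transitions follow the F2 matrix at Haldane recombination fractions
    from the cM gaps.  Pseudomarkers are unobserved positions inserted
    every ``step_cm``.
    """
    g = cross.numeric_genotypes()
    n_ind = len(g)
    with np.errstate(divide="ignore"):
        log_hit = np.log(1.0 - error_prob)
        log_miss = np.log(error_prob / 2.0)
        log_init = np.log(F2_PRIOR)

    pos_frames = []
    prob_blocks = []
    for chrom, sub in cross.markers.groupby("chrom", sort=False):
        m_cm = sub["pos_cm"].to_numpy(dtype=float)
        m_bp = sub["pos_bp"].to_numpy(dtype=float)
        # strictly increasing support for interpolation
        eps = 1e-9 * np.arange(len(m_cm))
        m_cm_u = np.maximum.accumulate(m_cm) + eps
        grid = np.arange(m_cm_u[0], m_cm_u[-1], step_cm) if len(m_cm_u) > 1 else np.array([])
        all_cm = np.unique(np.concatenate([m_cm_u, grid]))
        is_marker = np.isin(all_cm, m_cm_u)
        marker_idx = np.searchsorted(m_cm_u, all_cm[is_marker])
        bp = np.interp(all_cm, m_cm_u, m_bp)

        n_pos = len(all_cm)
        log_emis = np.zeros((n_ind, n_pos, 3))
        marker_cols = cross.markers.index.get_indexer(sub.index)
        obs = g[:, marker_cols]  # (n_ind, n_markers)
        pos_of_marker = np.flatnonzero(is_marker)
        for j, p in enumerate(pos_of_marker):
            oj = obs[:, marker_idx[j]]
            called = oj >= 0
            emis = np.full((n_ind, 3), log_miss)
            emis[np.arange(n_ind), np.clip(oj, 0, 2)] = log_hit
            emis[~called] = 0.0
            log_emis[:, p, :] = emis

        gaps = np.diff(all_cm)
        log_trans = np.empty((n_pos - 1, 3, 3))
        for t, d in enumerate(gaps):
            with np.errstate(divide="ignore"):
                log_trans[t] = np.log(f2_transition(haldane_r(d)))

        post = _forward_backward_probs(log_emis, log_trans, log_init)
        prob_blocks.append(post)
        pos_frames.append(
            pd.DataFrame({"chrom": chrom, "pos_cm": all_cm, "pos_bp": bp, "is_marker": is_marker})
        )

    positions = pd.concat(pos_frames, ignore_index=True)
    probs = np.concatenate(prob_blocks, axis=1)
    return GenoProb(positions, probs, list(cross.genotypes.index))


def _forward_backward_probs(log_emis, log_trans, log_init):
    from scipy.special import logsumexp

    S, N, _ = log_emis.shape
    la = np.empty((S, N, 3))
    la[:, 0] = log_init[None, :] + log_emis[:, 0]
    for t in range(1, N):
        la[:, t] = logsumexp(la[:, t - 1][:, :, None] + log_trans[t - 1][None], axis=1) + log_emis[:, t]
    lb = np.zeros((S, N, 3))
    for t in range(N - 2, -1, -1):
        lb[:, t] = logsumexp(log_trans[t][None] + (log_emis[:, t + 1] + lb[:, t + 1])[:, None, :], axis=2)
    ll = logsumexp(la[:, -1], axis=1)
    return np.exp(la + lb - ll[:, None, None])


# ---------------------------------------------------------------------------
# LOD machinery


def _design(probs_pos: np.ndarray) -> np.ndarray:
    """Haley-Knott design at one position: intercept, additive, dominance."""
    return np.column_stack(
        [np.ones(len(probs_pos)), probs_pos[:, 2] - probs_pos[:, 0], probs_pos[:, 1]]
    )


def _orthonormal_basis(X: np.ndarray) -> np.ndarray:
    """SVD-based orthonormal basis of the column space (rank-safe)."""
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if len(s) else 0
    return u[:, :rank]

def _stack_bases(probs: np.ndarray) -> np.ndarray:
    """Per-position orthonormal bases stacked to (n_pos, n, 3) (zero-padded)."""
    n, n_pos = probs.shape[0], probs.shape[1]
    out = np.zeros((n_pos, n, 3))
    for p in range(n_pos):
        q = _orthonormal_basis(_design(probs[:, p, :]))
        out[p, :, : q.shape[1]] = q
    return out


def lod_matrix(bases: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """LOD for every position x phenotype column.

    ``bases``: (n_pos, n, r) orthonormal design bases; ``Y``: (n, k)
    centered-or-not phenotype columns.  Returns (n_pos, k).
    """
    n_pos, n, r = bases.shape
    k = Y.shape[1]
    tss = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    B = np.transpose(bases, (0, 2, 1)).reshape(n_pos * r, n)
    P = (B @ Y).reshape(n_pos, r, k)
    # bases span the intercept, so RSS1 = sum(Y^2) - sum(projections^2)
    rss1 = (Y**2).sum(axis=0)[None, :] - (P**2).sum(axis=1)
    rss1 = np.maximum(rss1, _RSS_FLOOR_FRAC * np.maximum(tss[None, :], 1e-300))
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = (n / 2.0) * np.log10(tss[None, :] / rss1)
    return np.where(tss[None, :] > 0, lod, 0.0)


# ---------------------------------------------------------------------------
# single-QTL scan


@dataclass
class ScanResult:
    """LOD profile of a single-trait genome scan."""

    trait: str
    positions: pd.DataFrame  # chrom, pos_cm, pos_bp, is_marker
    lod: np.ndarray
    n: int
    threshold: float | None = None
    perm_max_lods: np.ndarray | None = None

    def max_lod(self) -> float:
        return float(self.lod.max())

    def peak(self, chrom: str | None = None) -> pd.Series:
        df = self.positions.assign(lod=self.lod)
        if chrom is not None:
            df = df[df["chrom"] == chrom]
        return df.loc[df["lod"].idxmax()]

    def summary(self) -> pd.DataFrame:
        """Per-chromosome peak table, flagged against the threshold if set."""
        rows = []
        for chrom, sub in self.positions.assign(lod=self.lod).groupby("chrom", sort=False):
            peak = sub.loc[sub["lod"].idxmax()]
            rows.append(
                {
                    "trait": self.trait,
                    "chrom": chrom,
                    "peak_cm": peak["pos_cm"],
                    "peak_bp": peak["pos_bp"],
                    "lod": peak["lod"],
                    "significant": (peak["lod"] > self.threshold) if self.threshold is not None else None,
                }
            )
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        return self.positions.assign(lod=self.lod, trait=self.trait)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        offset = 0.0
        for chrom, sub in self.to_frame().groupby("chrom", sort=False):
            ax.plot(sub["pos_cm"] + offset, sub["lod"], label=chrom)
            offset += sub["pos_cm"].max() + 10
        if self.threshold is not None:
            ax.axhline(self.threshold, ls="--", color="grey")
        ax.set_xlabel("position (cM, chromosomes concatenated)")
        ax.set_ylabel("LOD")
        return ax


class HKScan:
    """Haley-Knott single-QTL genome scan for one trait.

    Parameters
    ----------
    cross
        Assembled and QC'd cross.
    trait
        Phenotype column to scan; individuals with missing values are
        dropped (at least 30 are required).
    step_cm, error_prob
        Pseudomarker spacing and assumed genotyping-error rate for the
        conditional-probability computation.
    """

    def __init__(
        self,
        cross: CrossObject,
        trait: str,
        step_cm: float = 2.0,
        error_prob: float = 1e-4,
        min_individuals: int = 30,
    ):
        if trait not in cross.phenotypes.columns:
            raise KeyError(f"trait {trait!r} not in phenotypes")
        y_all = cross.phenotypes[trait].to_numpy(dtype=float)
        keep = ~np.isnan(y_all)
        if keep.sum() < min_individuals:
            raise ValueError(f"need at least {min_individuals} phenotyped individuals")
        self.cross = cross
        self.trait = trait
        self._keep = keep
        self.y = y_all[keep]
        gp = calc_genoprob(cross, step_cm=step_cm, error_prob=error_prob)
        self.genoprob = GenoProb(gp.positions, gp.probs[keep], [i for i, k in zip(gp.individuals, keep) if k])
        self._bases = _stack_bases(self.genoprob.probs)

    def fit(self) -> ScanResult:
        y = self.y
        if np.ptp(y) == 0:
            warnings.warn("constant phenotype: LOD is zero everywhere")
            lod = np.zeros(self._bases.shape[0])
        else:
            lod = lod_matrix(self._bases, y[:, None])[:, 0]
        return ScanResult(self.trait, self.genoprob.positions.copy(), lod, len(y))

    def permutation_threshold(
        self, n_perm: int = 1000, alpha: float = 0.05, seed: int = 0
    ) -> tuple[float, np.ndarray]:
        """Genome-wide LOD threshold from phenotype permutations.

        The phenotype vector is permuted jointly against the whole
        genotype matrix (marker correlation preserved); the threshold is
        the empirical (1 - alpha) quantile of per-permutation maximum LOD.
        """
        rng = np.random.default_rng(seed)
        Y = np.column_stack([rng.permutation(self.y) for _ in range(n_perm)])
        max_lods = lod_matrix(self._bases, Y).max(axis=0)
        return float(np.quantile(max_lods, 1.0 - alpha)), max_lods


def hk_scan(cross: CrossObject, trait: str, step_cm: float = 2.0, error_prob: float = 1e-4) -> ScanResult:
    """Functional wrapper around :class:`HKScan`."""
    return HKScan(cross, trait, step_cm=step_cm, error_prob=error_prob).fit()


def permutation_threshold(
    cross: CrossObject, trait: str, n_perm: int = 1000, alpha: float = 0.05, seed: int = 0, step_cm: float = 2.0
) -> float:
    thr, _ = HKScan(cross, trait, step_cm=step_cm).permutation_threshold(n_perm, alpha, seed)
    return thr


# ---------------------------------------------------------------------------
# two-QTL scan


@dataclass
class TwoScanResult:
    positions: pd.DataFrame
    lod_full: np.ndarray  # (P, P), upper triangle
    lod_add: np.ndarray
    lod_int: np.ndarray
    threshold_int: float | None
    threshold_full: float | None
    interactions: pd.DataFrame = field(default_factory=pd.DataFrame)


def _thin_positions(positions: pd.DataFrame, min_gap_cm: float) -> np.ndarray:
    keep = []
    for _, sub in positions.groupby("chrom", sort=False):
        last = -np.inf
        for idx, row in sub.iterrows():
            if row["pos_cm"] - last >= min_gap_cm:
                keep.append(idx)
                last = row["pos_cm"]
    return np.array(keep)


def scan_two(
    cross: CrossObject,
    trait: str,
    step_cm: float = 10.0,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> TwoScanResult:
    """Two-QTL scan: full (with epistasis) vs additive model per pair.

    For every pair of distinct grid positions the full model adds the four
    interaction products of the additive/dominance predictors; the
    interaction LOD is LOD_full - LOD_add.  Significance of the maximum
    interaction (and full) LOD is assessed by phenotype permutation.
    """
    model = HKScan(cross, trait, step_cm=step_cm)
    y = model.y
    take = _thin_positions(model.genoprob.positions, step_cm * 0.999)
    probs = model.genoprob.probs[:, take, :]
    positions = model.genoprob.positions.loc[take].reset_index(drop=True)
    P = len(positions)
    n = len(y)
    tss = float(((y - y.mean()) ** 2).sum())

    rng = np.random.default_rng(seed)
    Y = np.column_stack([y] + [rng.permutation(y) for _ in range(n_perm)])
    Yc2 = (Y - Y.mean(axis=0)) ** 2
    tss_all = Yc2.sum(axis=0)

    lod_full = np.zeros((P, P))
    lod_add = np.zeros((P, P))
    max_int = np.zeros(n_perm + 1)
    max_full = np.zeros(n_perm + 1)
    ones = np.ones(n)
    for i in range(P):
        ai, di = probs[:, i, 2] - probs[:, i, 0], probs[:, i, 1]
        for j in range(i + 1, P):
            aj, dj = probs[:, j, 2] - probs[:, j, 0], probs[:, j, 1]
            Xa = np.column_stack([ones, ai, di, aj, dj])
            Xf = np.column_stack([Xa, ai * aj, ai * dj, di * aj, di * dj])
            lod_a = _lod_cols(Xa, Y, tss_all, n)
            lod_f = _lod_cols(Xf, Y, tss_all, n)
            lod_int_pair = np.maximum(lod_f - lod_a, 0.0)
            lod_full[i, j] = lod_f[0]
            lod_add[i, j] = lod_a[0]
            max_int = np.maximum(max_int, lod_int_pair)
            max_full = np.maximum(max_full, lod_f)

    thr_int = float(np.quantile(max_int[1:], 1 - alpha)) if n_perm else None
    thr_full = float(np.quantile(max_full[1:], 1 - alpha)) if n_perm else None
    lod_int = np.maximum(lod_full - lod_add, 0.0)
    inter_rows = []
    if thr_int is not None:
        for i, j in zip(*np.nonzero(np.triu(lod_int > thr_int, k=1))):
            inter_rows.append(
                {
                    "chrom1": positions.loc[i, "chrom"], "pos1_cm": positions.loc[i, "pos_cm"],
                    "chrom2": positions.loc[j, "chrom"], "pos2_cm": positions.loc[j, "pos_cm"],
                    "lod_int": lod_int[i, j],
                }
            )
    return TwoScanResult(positions, lod_full, lod_add, lod_int, thr_int, thr_full, pd.DataFrame(inter_rows))


def _lod_cols(X: np.ndarray, Y: np.ndarray, tss_all: np.ndarray, n: int) -> np.ndarray:
    """LOD of the model X (which contains the intercept) for each Y column."""
    q = _orthonormal_basis(X)
    rss1 = (Y**2).sum(axis=0) - ((q.T @ Y) ** 2).sum(axis=0)
    rss1 = np.maximum(rss1, _RSS_FLOOR_FRAC * np.maximum(tss_all, 1e-300))
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = (n / 2.0) * np.log10(tss_all / rss1)
    return np.where(tss_all > 0, lod, 0.0)


# ---------------------------------------------------------------------------
# stepwise additive multiple-QTL model


@dataclass
class QTLModelResults:
    """Selected additive multiple-QTL model and its per-QTL summaries."""

    trait: str
    qtl: pd.DataFrame  # chrom, pos_cm, pos_bp per selected QTL
    model_lod: float
    plod: float
    penalty: float
    n: int
    effects: pd.DataFrame | None = None  # effect_add, effect_dom, pev per QTL
    model_pev: float | None = None
    intervals: pd.DataFrame | None = None  # bayes_lo_bp, bayes_hi_bp per QTL

    @property
    def n_qtl(self) -> int:
        return len(self.qtl)

    def summary(self) -> pd.DataFrame:
        """Flat per-QTL table in deposited-QTL-table style."""
        out = self.qtl.copy()
        out["trait"] = self.trait
        out["model_lod"] = self.model_lod
        out["plod"] = self.plod
        if self.effects is not None:
            out = out.join(self.effects)
        if self.intervals is not None:
            out = out.join(self.intervals)
        return out


def stepwise_additive(
    cross: CrossObject,
    trait: str,
    penalty: float,
    max_qtl: int = 8,
    step_cm: float = 2.0,
    error_prob: float = 1e-4,
) -> QTLModelResults:
    """Forward/backward search maximizing the penalized LOD.

    Forward steps add the grid position that maximizes the additive model
    LOD; backward elimination then drops QTL while the penalized LOD
    improves.  The returned model maximizes pLOD = LOD - penalty * n_QTL
    over everything visited (the empty model, pLOD = 0, is a valid
    winner).  The model space is additive only: each QTL contributes an
    additive and a dominance predictor, no interactions.
    """
    model = HKScan(cross, trait, step_cm=step_cm, error_prob=error_prob, min_individuals=2)
    y = model.y
    n = len(y)
    probs = model.genoprob.probs
    positions = model.genoprob.positions
    P = probs.shape[1]
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        res = QTLModelResults(
            trait, positions.iloc[:0][["chrom", "pos_cm", "pos_bp"]].copy(), 0.0, 0.0, penalty, n
        )
        res._sel_probs = probs[:, [], :]
        res._y = y
        return res

    def model_lod(sel: list[int]) -> float:
        X = _additive_design(probs, sel, n)
        q = _orthonormal_basis(X)
        rss = float((y**2).sum() - ((q.T @ y) ** 2).sum())
        rss = max(rss, _RSS_FLOOR_FRAC * tss)
        return (n / 2.0) * np.log10(tss / rss)

    visited: list[tuple[tuple[int, ...], float]] = [((), 0.0)]
    selected: list[int] = []
    for _ in range(min(max_qtl, P)):
        best_p, best_lod = -1, -np.inf
        Xb = _additive_design(probs, selected, n)
        qb = _orthonormal_basis(Xb)
        y_res = y - qb @ (qb.T @ y)
        rss_cur = float((y_res**2).sum())
        for p in range(P):
            if p in selected:
                continue
            C = np.column_stack([probs[:, p, 2] - probs[:, p, 0], probs[:, p, 1]])
            C_res = C - qb @ (qb.T @ C)
            qc = _orthonormal_basis(C_res) if np.abs(C_res).max() > 1e-12 else np.zeros((n, 0))
            extra = float(((qc.T @ y_res) ** 2).sum()) if qc.shape[1] else 0.0
            rss_new = max(rss_cur - extra, _RSS_FLOOR_FRAC * tss)
            lod = (n / 2.0) * np.log10(tss / rss_new)
            if lod > best_lod:
                best_lod, best_p = lod, p
        if best_p < 0:
            break
        selected.append(best_p)
        visited.append((tuple(selected), best_lod))

    # backward elimination from the full forward model
    current = list(selected)
    while len(current) > 1:
        best_drop, best_lod = None, -np.inf
        for q_pos in current:
            sub = [p for p in current if p != q_pos]
            lod = model_lod(sub)
            if lod > best_lod:
                best_lod, best_drop = lod, q_pos
        current = [p for p in current if p != best_drop]
        visited.append((tuple(current), best_lod))

    best_sel, best_lod, best_plod = (), 0.0, 0.0
    for sel, lod in visited:
        plod = lod - penalty * len(sel)
        if plod > best_plod + 1e-12 or (abs(plod - best_plod) <= 1e-12 and len(sel) < len(best_sel)):
            best_sel, best_lod, best_plod = sel, lod, plod

    qtl = positions.iloc[list(best_sel)].copy().reset_index(drop=True)
    qtl.index.name = "qtl"
    res = QTLModelResults(trait, qtl[["chrom", "pos_cm", "pos_bp"]], float(best_lod), float(best_plod), penalty, n)
    res._sel_probs = probs[:, list(best_sel), :]  # cached for effect computation
    res._y = y
    return res


def _additive_design(probs: np.ndarray, sel: list[int], n: int) -> np.ndarray:
    cols = [np.ones(n)]
    for p in sel:
        cols.append(probs[:, p, 2] - probs[:, p, 0])
        cols.append(probs[:, p, 1])
    return np.column_stack(cols)


def qtl_effects(
    cross: CrossObject,
    results: QTLModelResults,
    early_parent: str = "A",
) -> QTLModelResults:
    """Signed additive effects and explained variance for a fitted model.

    The additive effect is half the fitted difference between homozygote
    means, signed so that a positive effect means the early parent's
    allele promotes flowering (reduces the trait).  Per-QTL explained
    variance (PEV) is the drop-one residual-sum-of-squares share of the
    total; model PEV is 100 * (1 - RSS_full / TSS).
    """
    if early_parent not in ("A", "B"):
        raise ValueError("early_parent must be 'A' (parent1) or 'B' (parent2)")
    if not hasattr(results, "_sel_probs"):
        raise ValueError("results lack cached design; refit with stepwise_additive")
    probs = results._sel_probs
    y = results._y
    n = len(y)
    k = probs.shape[1]
    tss = float(((y - y.mean()) ** 2).sum())
    if k == 0 or tss == 0:
        results.effects = pd.DataFrame(columns=["effect_add", "effect_dom", "pev"])
        results.model_pev = 0.0
        return results

    def design(drop: int | None = None) -> np.ndarray:
        cols = [np.ones(n)]
        for j in range(k):
            if j == drop:
                continue
            cols.append(probs[:, j, 2] - probs[:, j, 0])
            cols.append(probs[:, j, 1])
        return np.column_stack(cols)

    X = design()
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss_full = float(((y - X @ beta) ** 2).sum())
    sign = 1.0 if early_parent == "A" else -1.0
    rows = []
    for j in range(k):
        a_raw = float(beta[1 + 2 * j])  # (mean BB - mean AA) / 2
        d = float(beta[2 + 2 * j])
        Xd = design(drop=j)
        bd, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        rss_d = float(((y - Xd @ bd) ** 2).sum())
        rows.append(
            {
                "effect_add": sign * a_raw,
                "effect_dom": d,
                "pev": 100.0 * max(rss_d - rss_full, 0.0) / tss,
            }
        )
    results.effects = pd.DataFrame(rows, index=results.qtl.index)
    results.model_pev = 100.0 * (1.0 - rss_full / tss)
    return results


# ---------------------------------------------------------------------------
# Bayes credible interval and window summaries


def bayes_interval(scan: ScanResult, chrom: str, coverage: float = 0.95) -> tuple[float, float]:
    """Smallest contiguous grid run holding ``coverage`` of the 10^LOD mass.

    The normalized 10^LOD profile over the chromosome's evaluation
    positions is scanned for the shortest contiguous window containing at
    least the requested mass; the window is then expanded outward to the
    flanking marker positions and reported in bp.
    """
    sub = scan.positions.assign(lod=scan.lod)
    sub = sub[sub["chrom"] == chrom].reset_index(drop=True)
    if len(sub) < 2:
        raise ValueError(f"need >= 2 positions on {chrom}")
    dens = np.power(10.0, sub["lod"].to_numpy() - sub["lod"].max())
    # integrate over genetic distance: the grid is irregular (markers
    # cluster near crossovers), so each position carries a trapezoidal
    # spacing weight or the mass would concentrate where sampling is dense
    cm = sub["pos_cm"].to_numpy()
    spacing = np.zeros(len(cm))
    spacing[1:-1] = (cm[2:] - cm[:-2]) / 2.0
    spacing[0] = cm[1] - cm[0]
    spacing[-1] = cm[-1] - cm[-2]
    w = dens * np.maximum(spacing, 1e-12)
    w = w / w.sum()
    if np.allclose(dens, dens[0]):
        warnings.warn(f"flat LOD profile on {chrom}; interval spans the chromosome")
        return float(sub["pos_bp"].iloc[0]), float(sub["pos_bp"].iloc[-1])

    n = len(w)
    best = (n, np.inf, 0, n - 1)  # (#positions, bp span, i, j)
    j = 0
    total = 0.0
    for i in range(n):
        if j < i:
            j, total = i, 0.0
        while j < n and total < coverage:
            total += w[j]
            j += 1
        if total >= coverage:
            span = sub["pos_bp"].iloc[j - 1] - sub["pos_bp"].iloc[i]
            cand = (j - i, span, i, j - 1)
            if cand < best:
                best = cand
        total -= w[i]
    _, _, i, jj = best

    # each selected position represents its half-spacing cell in cM; the
    # interval edge is the cell edge, snapped outward to the flanking
    # marker positions and reported in bp
    bp = sub["pos_bp"].to_numpy()
    lo_cm = cm[i] - spacing[i] / 2.0
    hi_cm = cm[jj] + spacing[jj] / 2.0
    lo_edge = float(np.interp(lo_cm, cm, bp))
    hi_edge = float(np.interp(hi_cm, cm, bp))
    markers = sub[sub["is_marker"]]
    lo_mk = markers[markers["pos_bp"] <= lo_edge]
    hi_mk = markers[markers["pos_bp"] >= hi_edge]
    lo = float(lo_mk["pos_bp"].iloc[-1]) if len(lo_mk) else lo_edge
    hi = float(hi_mk["pos_bp"].iloc[0]) if len(hi_mk) else hi_edge
    return lo, hi


def window_lod_summary(scans: list[ScanResult], window_bp: int = 100_000, genome=None) -> pd.DataFrame:
    """Sum LOD over non-overlapping windows, reported at window centers.

    All scans' evaluation positions falling in a window contribute; the
    total over windows equals the total over positions (a partition).
    """
    frames = [s.to_frame() for s in scans]
    allpos = pd.concat(frames, ignore_index=True)
    rows = []
    for chrom, sub in allpos.groupby("chrom", sort=False):
        max_bp = genome.length(chrom) if genome is not None else float(sub["pos_bp"].max()) + 1
        edges = np.arange(0, max_bp + window_bp, window_bp)
        idx = np.clip(np.searchsorted(edges, sub["pos_bp"].to_numpy(), side="right") - 1, 0, len(edges) - 2)
        sums = np.zeros(len(edges) - 1)
        np.add.at(sums, idx, sub["lod"].to_numpy())
        for k in range(len(sums)):
            rows.append(
                {
                    "chrom": chrom,
                    "window_start": edges[k],
                    "window_end": edges[k + 1],
                    "center_bp": edges[k] + window_bp / 2,
                    "summed_lod": sums[k],
                }
            )
    return pd.DataFrame(rows)
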