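"""Two-tier quality filtering of parental SNP markers.

A biparental cross needs a set of SNPs that reliably distinguish the two
parents.  Filtering happens in two tiers: a hard "soft filter" on the
standard GATK-style annotations (QD, FS, MQ, MQRankSum, ReadPosRankSum),
then an automated "corrected" filter that fits Gaussians to the annotation
distributions of the surviving records and keeps only the dominant mode,
additionally excluding variants in centromeres, telomeres and
transposable-element regions and requiring MQ >= 50.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import Region

logger = logging.getLogger(__name__)

ANNOTATIONS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum")

#: Hard thresholds; a record fails when any strict comparison is true.
SOFT_FILTER = {
    "QD": ("<", 5.0),
    "FS": (">", 60.0),
    "MQ": ("<", 50.0),
    "MQRankSum": ("<", -12.5),
    "ReadPosRankSum": ("<", -8.0),
}

PASS = "pass"
SOFT_FAIL = "soft_fail"
CORRECTED_FAIL = "corrected_fail"
REGION_FAIL = "region_fail"
NON_BIALLELIC = "non_biallelic"


@dataclass
class ParentalVariantSet:
    """Biallelic SNP markers distinguishing the two cross parents.

    ``variants`` is a DataFrame with columns ``chrom``, ``pos`` (1-based),
    ``ref``, ``alt``, the five annotation columns (NaN when missing), and
    ``filter_status``.  A synthetic set additionally carries a ``label``
    column recording which mixture component generated each record.
    """

    variants: pd.DataFrame
    source_parent: str = "parent1"
    n_non_biallelic: int = 0

    def __post_init__(self) -> None:
        df = self.variants
        required = {"chrom", "pos", "ref", "alt"}
        if not required.issubset(df.columns):
            raise ValueError(f"variant table missing columns {required - set(df.columns)}")
        if "filter_status" not in df.columns:
            df = df.assign(filter_status=PASS)
            self.variants = df
        dup = df.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise ValueError("duplicate variant positions")
        if (df["ref"] == df["alt"]).any():
            raise ValueError("REF must differ from ALT")

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def passing(self) -> pd.DataFrame:
        return self.variants[self.variants["filter_status"] == PASS]

    def status_counts(self) -> pd.Series:
        return self.variants["filter_status"].value_counts()

    def audit_table(self) -> pd.DataFrame:
        """Per-record removal audit: chrom, pos, stage/reason."""
        df = self.variants
        out = df.loc[df["filter_status"] != PASS, ["chrom", "pos", "filter_status"]]
        return out.rename(columns={"filter_status": "reason"}).reset_index(drop=True)


@dataclass(frozen=True)
class GaussianFitResult:
    """A (possibly one-component) Gaussian fit and its retention interval."""

    means: tuple[float, ...]
    sds: tuple[float, ...]
    weights: tuple[float, ...]
    dominant: int
    k_sd: float
    interval: tuple[float, float] = field(default=(0.0, 0.0))

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.weights), 1.0):
            raise ValueError("component weights must sum to 1")
        if any(s <= 0 for s in self.sds):
            raise ValueError("component SDs must be positive")
        lo = self.means[self.dominant] - self.k_sd * self.sds[self.dominant]
        hi = self.means[self.dominant] + self.k_sd * self.sds[self.dominant]
        object.__setattr__(self, "interval", (lo, hi))

    def contains(self, values: np.ndarray) -> np.ndarray:
        lo, hi = self.interval
        return (values >= lo) & (values <= hi)


def apply_soft_filter(variant_set: ParentalVariantSet) -> ParentalVariantSet:
    """Flag records failing the hard annotation filter.

    Comparisons are strict; a missing (NaN) annotation never triggers its
    clause.  Records already failed at an earlier stage are untouched.
    """
    df = variant_set.variants.copy()
    fail = np.zeros(len(df), dtype=bool)
    for ann, (op, thr) in SOFT_FILTER.items():
        if ann not in df.columns:
            continue
        vals = pd.to_numeric(df[ann], errors="coerce").to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            clause = vals < thr if op == "<" else vals > thr
        clause &= ~np.isnan(vals)
        fail |= clause
    mask = fail & (df["filter_status"] == PASS).to_numpy()
    df.loc[mask, "filter_status"] = SOFT_FAIL
    logger.info("soft filter flagged %d of %d records", int(mask.sum()), len(df))
    return replace(variant_set, variants=df)


_SD_FLOOR = 1e-6


def fit_dominant_gaussian(
    values,
    n_components: int = 2,
    k_sd: float = 2.5,
    seed: int = 0,
) -> GaussianFitResult:
    """Fit a 1- or 2-component Gaussian and return the dominant-peak interval.

    The two-component fit uses expectation-maximization (k-means
    initialisation, 100 iterations max, tolerance 1e-6); the one-component
    fit uses moment estimates.  Degenerate (zero-variance) components get an
    SD floor of 1e-6 so the retention interval stays defined.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) < 10:
        raise ValueError("need at least 10 finite values to fit")
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")

    if n_components == 1 or np.ptp(vals) == 0.0:
        mean = float(vals.mean())
        sd = max(float(vals.std()), _SD_FLOOR)
        if np.ptp(vals) == 0.0 and n_components != 1:
            logger.warning("degenerate data for %d-component fit; using single component", n_components)
        return GaussianFitResult((mean,), (sd,), (1.0,), 0, k_sd)
    if n_components != 2:
        raise ValueError("n_components must be 1 or 2")

    import warnings

    from sklearn.exceptions import ConvergenceWarning
    from sklearn.mixture import GaussianMixture

    with warnings.catch_warnings():
        # the 100-iteration cap is deliberate; a non-converged EM at tol
        # 1e-6 is still far tighter than the 2.5-SD retention interval
        warnings.simplefilter("ignore", ConvergenceWarning)
        gm = GaussianMixture(
            n_components=2,
            covariance_type="full",
            max_iter=100,
            tol=1e-6,
            init_params="kmeans",
            random_state=seed,
        ).fit(vals.reshape(-1, 1))
    means = tuple(float(m) for m in gm.means_.ravel())
    sds = tuple(max(float(np.sqrt(c)), _SD_FLOOR) for c in gm.covariances_.ravel())
    weights = tuple(float(w) for w in gm.weights_)
    # effectively unimodal data: EM splits the single peak into two
    # overlapping halves with understated SDs; collapse to moments then
    if abs(means[0] - means[1]) < min(sds):
        logger.info("mixture components unseparated; collapsing to a single Gaussian")
        return fit_dominant_gaussian(vals, n_components=1, k_sd=k_sd, seed=seed)
    dominant = int(np.argmax(weights))
    return GaussianFitResult(means, sds, weights, dominant, k_sd)


def _in_regions(df: pd.DataFrame, regions: list[Region] | tuple[Region, ...]) -> np.ndarray:
    """True where a 1-based variant position falls in a 0-based half-open region."""
    mask = np.zeros(len(df), dtype=bool)
    by_chrom: dict[str, list[Region]] = {}
    for reg in regions:
        by_chrom.setdefault(reg.chrom, []).append(reg)
    for chrom, regs in by_chrom.items():
        sel = (df["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        pos0 = df.loc[sel, "pos"].to_numpy(dtype=np.int64) - 1  # to 0-based
        hit = np.zeros(sel.sum(), dtype=bool)
        for reg in regs:
            hit |= (pos0 >= reg.start) & (pos0 < reg.end)
        mask[sel] = hit
    return mask


def corrected_filter(
    variant_set: ParentalVariantSet,
    exclusion_regions=(),
    k_qd: float = 2.5,
    k_fs: float = 2.5,
    k_mqrs: float = 4.0,
    mq_min: float = 50.0,
    seed: int = 0,
    fits: dict[str, GaussianFitResult] | None = None,
) -> tuple[ParentalVariantSet, dict[str, GaussianFitResult]]:
    """Automated dominant-peak filter on the soft-filter survivors.

    Region exclusion is applied first (a variant in a centromere, telomere
    or TE region fails regardless of its annotations); the Gaussian
    intervals are then fitted on the remaining passing records: QD against
    the dominant peak of a two-component fit +- ``k_qd`` SD, FS and
    MQRankSum against single-Gaussian fits (+- ``k_fs`` / ``k_mqrs`` SD),
    and MQ against the fixed threshold ``mq_min``.  A missing annotation
    cannot be tested and is retained for that metric.

    Pass ``fits`` to reapply previously fitted intervals (the filter with
    fixed intervals is idempotent; refitting on its own output is not,
    because truncation shrinks the estimated SDs).
    """
    df = variant_set.variants.copy()
    passing = (df["filter_status"] == PASS).to_numpy()
    if passing.sum() == 0:
        logger.warning("corrected filter received no passing records")
        return replace(variant_set, variants=df), dict(fits or {})

    region_hit = _in_regions(df, tuple(exclusion_regions)) & passing
    df.loc[region_hit, "filter_status"] = REGION_FAIL
    candidates = (df["filter_status"] == PASS).to_numpy()

    plan = {"QD": (2, k_qd), "FS": (1, k_fs), "MQRankSum": (1, k_mqrs)}
    if fits is None:
        fits = {}
        for ann, (ncomp, k) in plan.items():
            vals = df.loc[candidates, ann].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if len(vals) >= 10:
                fits[ann] = fit_dominant_gaussian(vals, n_components=ncomp, k_sd=k, seed=seed)
            else:
                logger.warning("too few %s values to fit; metric skipped", ann)

    fail = np.zeros(len(df), dtype=bool)
    for ann, fit in fits.items():
        vals = df[ann].to_numpy(dtype=float)
        ok = np.isnan(vals) | fit.contains(vals)
        fail |= ~ok
    mq = df["MQ"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        fail |= ~np.isnan(mq) & (mq < mq_min)

    mask = fail & candidates
    df.loc[mask, "filter_status"] = CORRECTED_FAIL
    logger.info(
        "corrected filter: %d region_fail, %d corrected_fail of %d candidates",
        int(region_hit.sum()), int(mask.sum()), int(passing.sum()),
    )
    return replace(variant_set, variants=df), fits


def _read_biallelic_snps(vcf_path: str) -> tuple[pd.DataFrame, int]:
    """Read a VCF, keeping biallelic SNP records; returns (table, n_excluded)."""
    from cyvcf2 import VCF

    rows = []
    excluded = 0
    for rec in VCF(str(vcf_path)):
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            excluded += 1
            continue
        row = {"chrom": rec.CHROM, "pos": rec.POS, "ref": rec.REF, "alt": rec.ALT[0]}
        for ann in ANNOTATIONS:
            val = rec.INFO.get(ann)
            row[ann] = float(val) if val is not None else np.nan
        rows.append(row)
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", *ANNOTATIONS])
    return df, excluded


def select_biallelic_and_alt_parent(
    vcf_parent1: str, vcf_parent2: str
) -> ParentalVariantSet:
    """Choose the ALT-source parent and return its biallelic SNPs.

    The parent contributing more biallelic SNPs supplies the alternative
    (ALT) alleles for downstream genotyping; a tie is broken to parent1.
    Indels and multiallelic records are excluded and counted.
    """
    df1, ex1 = _read_biallelic_snps(vcf_parent1)
    df2, ex2 = _read_biallelic_snps(vcf_parent2)
    if len(df2) > len(df1):
        chosen, name, excluded = df2, "parent2", ex2
    else:
        if len(df2) == len(df1):
            logger.info("equal variant counts; ALT source tie broken to parent1")
        chosen, name, excluded = df1, "parent1", ex1
    chosen = chosen.assign(source_parent=name, filter_status=PASS)
    return ParentalVariantSet(chosen, source_parent=name, n_non_biallelic=excluded)


def write_filtered_vcf(variant_set: ParentalVariantSet, path: str, contigs=None) -> None:
    """Write the passing records as a minimal VCF v4.2 text file."""
    from .simulate import write_vcf  # shared fixed-schema writer

    write_vcf(variant_set, path, contigs=contigs, passing_only=True)
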