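"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates a biparental F2 mapping experiment on a
five-chromosome, Arabidopsis-like genome: parental SNP markers with
GATK-style quality annotations drawn from an inlier/outlier mixture,
F2 meioses with Poisson crossovers along the genetic map (Haldane, no
interference), shallow-coverage allele counts (Poisson depth, binomial
allele sampling with per-read error), additive QTL phenotypes, and
replicated-line phenotype/growth tables with a vernalization arm.

Truth (segment states, crossover positions, QTL effects, line means) is
retained on every object so downstream reconstruction and mapping can be
scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genome import GenomeSpec
from .hmm import AlleleCountTable
from .variants import ANNOTATIONS, PASS, ParentalVariantSet

STATES = ("AA", "AB", "BB")  # 0, 1, 2 copies of the ALT-parent allele


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class TrueF2Genome:
    """Ground-truth mosaic of one F2 individual.

    ``segments`` maps chromosome name to an ordered list of
    ``(start_bp, end_bp, state)`` tuples tiling [0, length) without gaps;
    adjacent segments differ in state.  ``crossover_positions`` lists the
    (chrom, bp) breakpoints, one per state change.
    """

    individual_id: str
    segments: dict[str, list[tuple[int, int, int]]]
    crossover_positions: list[tuple[str, int]]

    def state_at(self, chrom: str, pos: int) -> int:
        for start, end, state in self.segments[chrom]:
            if start <= pos < end:
                return state
        raise ValueError(f"{chrom}:{pos} outside all segments of {self.individual_id}")

    def states_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        segs = self.segments[chrom]
        ends = np.array([e for _, e, _ in segs])
        states = np.array([s for _, _, s in segs])
        idx = np.searchsorted(ends, positions, side="right")
        if idx.size and idx.max() >= len(segs):
            raise ValueError("position outside chromosome segments")
        return states[idx]

    @property
    def n_crossovers(self) -> int:
        return len(self.crossover_positions)


@dataclass(frozen=True)
class QTL:
    chrom: str
    pos: int
    additive: float  # a: half the difference between homozygote means
    dominance: float = 0.0  # d: heterozygote deviation from the midpoint


@dataclass(frozen=True)
class QTLSpec:
    """Planted trait architecture: QTL plus residual and line-level noise."""

    qtl: tuple[QTL, ...]
    residual_sd: float = 1.0
    line_sd: float = 0.0
    baseline: float = 30.0

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")

    def genetic_value(self, states: np.ndarray, which: int) -> np.ndarray:
        """Contribution of QTL ``which`` given genotype states (0/1/2)."""
        q = self.qtl[which]
        contrib = np.array([-q.additive, q.dominance, q.additive])
        return contrib[states]


@dataclass(frozen=True)
class ComponentParams:
    """Per-annotation sampling parameters for one mixture component."""

    qd: tuple[float, float] = (25.0, 3.0)  # normal (mean, sd)
    fs_scale: float = 5.0  # half-normal scale
    mq: tuple[float, float] = (60.0, 0.0)  # normal; sd 0 = point mass
    mqranksum: tuple[float, float] = (0.0, 1.5)
    readposranksum: tuple[float, float] = (0.0, 1.5)


@dataclass(frozen=True)
class AnnotationModel:
    """Inlier/outlier mixture for variant-quality annotations.

    Defaults give the corrected filter a well-separated dominant peak:
    inlier QD ~ N(25, 3) vs outlier QD ~ N(3, 1); outliers also show
    inflated strand bias, degraded mapping quality and shifted rank sums.
    """

    inlier: ComponentParams = field(default_factory=ComponentParams)
    outlier: ComponentParams = field(
        default_factory=lambda: ComponentParams(
            qd=(3.0, 1.0),
            fs_scale=40.0,
            mq=(45.0, 5.0),
            mqranksum=(-6.0, 2.0),
            readposranksum=(-4.0, 2.0),
        )
    )

    def draw(self, rng: np.random.Generator, n: int, component: ComponentParams) -> dict:
        return {
            "QD": rng.normal(*component.qd, size=n),
            "FS": np.abs(rng.normal(0.0, component.fs_scale, size=n)),
            "MQ": rng.normal(*component.mq, size=n) if component.mq[1] > 0 else np.full(n, component.mq[0]),
            "MQRankSum": rng.normal(*component.mqranksum, size=n),
            "ReadPosRankSum": rng.normal(*component.readposranksum, size=n),
        }


# ---------------------------------------------------------------------------
# generators

_BASES = np.array(list("ACGT"))


def simulate_parents(
    genome: GenomeSpec,
    n_variants: int,
    annotation_model: AnnotationModel | None = None,
    outlier_fraction: float = 0.0,
    seed: int = 0,
) -> ParentalVariantSet:
    """Parental biallelic SNPs with quality annotations and truth labels.

    Positions are unique and sorted within chromosomes, allocated
    proportionally to chromosome length.  Each variant's annotations are
    drawn from the inlier or outlier component; the generating component
    is recorded in the ``label`` column.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if not 0.0 <= outlier_fraction < 1.0:
        raise ValueError("outlier_fraction must be in [0, 1)")
    model = annotation_model or AnnotationModel()
    rng = np.random.default_rng(seed)

    total = genome.total_bp()
    chroms, counts = [], []
    remaining = n_variants
    for i, (name, length) in enumerate(genome.chromosomes):
        k = round(n_variants * length / total) if i < len(genome.chromosomes) - 1 else remaining
        k = min(k, remaining)
        chroms.append(name)
        counts.append(k)
        remaining -= k
    if remaining > 0:
        counts[-1] += remaining

    frames = []
    for name, k in zip(chroms, counts):
        if k == 0:
            continue
        length = genome.length(name)
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=min(k, length), replace=False))
        frames.append(pd.DataFrame({"chrom": name, "pos": pos}))
    df = pd.concat(frames, ignore_index=True)

    n = len(df)
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    df["ref"] = _BASES[ref_idx]
    df["alt"] = _BASES[alt_idx]

    is_outlier = rng.random(n) < outlier_fraction
    ann = {k: np.empty(n) for k in ANNOTATIONS}
    for mask, comp in ((~is_outlier, model.inlier), (is_outlier, model.outlier)):
        if mask.any():
            drawn = model.draw(rng, int(mask.sum()), comp)
            for k in ANNOTATIONS:
                ann[k][mask] = drawn[k]
    for k in ANNOTATIONS:
        df[k] = ann[k]
    df["label"] = np.where(is_outlier, "outlier", "inlier")
    df["filter_status"] = PASS
    df["source_parent"] = "parent2"
    return ParentalVariantSet(df, source_parent="parent2")


def _simulate_gamete(genome: GenomeSpec, rng: np.random.Generator) -> dict[str, tuple[int, list[int]]]:
    """One gamete: per chromosome a starting allele and crossover positions."""
    gamete = {}
    for name, length in genome.chromosomes:
        morgans = genome.genetic_length_cm(name) / 100.0
        n_co = rng.poisson(morgans)
        # constant cM/Mb: uniform in genetic distance == uniform in bp
        positions = sorted(int(p) for p in rng.integers(1, length, size=n_co)) if n_co else []
        start_allele = int(rng.integers(0, 2))
        gamete[name] = (start_allele, positions)
    return gamete


def simulate_f2(genome: GenomeSpec, n_individuals: int, seed: int = 0) -> list[TrueF2Genome]:
    """F2 individuals as fusions of two independent gametes.

    Crossovers per gamete per chromosome are Poisson with mean equal to the
    genetic length in Morgans (no interference), placed uniformly; state
    frequencies at any locus approach 1:2:1 across many individuals.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_individuals):
        g1, g2 = _simulate_gamete(genome, rng), _simulate_gamete(genome, rng)
        segments: dict[str, list[tuple[int, int, int]]] = {}
        crossovers: list[tuple[str, int]] = []
        for name, length in genome.chromosomes:
            a1, pos1 = g1[name]
            a2, pos2 = g2[name]
            breaks = sorted(set(pos1) | set(pos2))
            bounds = [0, *breaks, length]
            segs = []
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                if hi <= lo:
                    continue
                mid = (lo + hi) // 2
                s1 = a1 + (np.searchsorted(pos1, mid, side="right") % 2 if pos1 else 0)
                s2 = a2 + (np.searchsorted(pos2, mid, side="right") % 2 if pos2 else 0)
                state = (s1 % 2) + (s2 % 2)
                if segs and segs[-1][2] == state:  # coincident breakpoints cancel
                    segs[-1] = (segs[-1][0], hi, state)
                else:
                    segs.append((lo, hi, state))
            segments[name] = segs
            crossovers.extend((name, seg[0]) for seg in segs[1:])
        out.append(TrueF2Genome(f"F2_{i:04d}", segments, crossovers))
    return out


def _allele_states(truth: TrueF2Genome, variants: pd.DataFrame) -> np.ndarray:
    states = np.empty(len(variants), dtype=np.int64)
    for chrom, sub in variants.groupby("chrom", sort=False):
        # variant pos is 1-based; segments are 0-based half-open
        states[sub.index] = truth.states_at(chrom, sub["pos"].to_numpy() - 1)
    return states


def simulate_allele_counts(
    truth: list[TrueF2Genome],
    variants: ParentalVariantSet,
    mean_coverage: float = 0.2,
    error_rate: float = 0.01,
    seed: int = 0,
) -> list[AlleleCountTable]:
    """Shallow-sequencing REF/ALT read counts per individual per site.

    Depth is Poisson(mean_coverage) independently per site; ALT reads are
    binomial with success probability ``error_rate``, 0.5 or
    ``1 - error_rate`` for states AA, AB, BB.
    """
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be positive")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    var_df = variants.passing.reset_index(drop=True)
    p_alt = np.array([error_rate, 0.5, 1.0 - error_rate])

    tables = []
    for indiv in truth:
        states = _allele_states(indiv, var_df)
        depth = rng.poisson(mean_coverage, size=len(var_df))
        alt = rng.binomial(depth, p_alt[states])
        sites = pd.DataFrame(
            {
                "chrom": var_df["chrom"],
                "pos": var_df["pos"],
                "ref_count": depth - alt,
                "alt_count": alt,
            }
        )
        tables.append(AlleleCountTable(indiv.individual_id, sites))
    return tables


def simulate_phenotypes(
    truth: list[TrueF2Genome],
    qtl: QTLSpec,
    seed: int = 0,
    trait: str = "DTF",
) -> pd.DataFrame:
    """Additive-QTL phenotypes for F2 individuals.

    phenotype = baseline + sum over QTL of (-a, d, +a) for (AA, AB, BB)
    plus Normal(0, residual_sd) noise.  Genotype states count copies of
    the ALT-parent (B) allele, so positive ``a`` means the A (parent1)
    allele reduces the trait.
    """
    rng = np.random.default_rng(seed)
    n = len(truth)
    values = np.full(n, qtl.baseline, dtype=float)
    for which, q in enumerate(qtl.qtl):
        states = np.array([indiv.state_at(q.chrom, q.pos) for indiv in truth])
        values += qtl.genetic_value(states, which)
    values += rng.normal(0.0, qtl.residual_sd, size=n)
    return pd.DataFrame({"individual": [t.individual_id for t in truth], trait: values})


def censor_dtf(values: pd.Series | np.ndarray, limit: float = 125.0, code: float = 130.0):
    """Recode flowering later than ``limit`` days (or never) as ``code``."""
    arr = np.asarray(values, dtype=float)
    out = np.where(np.isnan(arr) | (arr > limit), code, arr)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


@dataclass
class ReplicatedLines:
    """Replicated-design phenotypes with stored truth."""

    pheno: pd.DataFrame  # line, replicate, treatment, DTF, RLN, flc_expression
    growth: pd.DataFrame  # line, replicate, day, area_px
    true_line_means: pd.Series
    vernalization_shift: float


def simulate_replicated_lines(
    n_lines: int = 60,
    reps_per_line: int = 12,
    line_sd: float = 3.0,
    residual_sd: float = 1.0,
    vernalization_shift: float = 0.5,
    baseline: float = 30.0,
    seed: int = 0,
    days: tuple[int, int] = (8, 20),
    growth_rate: float = 0.18,
    growth_rate_sd: float = 0.02,
    growth_noise_sd: float = 0.05,
) -> ReplicatedLines:
    """Replicated phenotype and growth tables for heritability-style designs.

    Each line has a true mean ``baseline + N(0, line_sd)``; replicates add
    Normal(0, residual_sd) noise.  The vernalized arm multiplies the line's
    true mean by ``vernalization_shift`` (0.5 halves flowering time, giving
    a log2 sensitivity of 1).  Projected rosette areas grow log-linearly
    with a per-line relative growth rate.
    """
    if reps_per_line < 2:
        raise ValueError("need >= 2 replicates per line")
    rng = np.random.default_rng(seed)
    line_ids = [f"line_{i:03d}" for i in range(n_lines)]
    line_means = baseline + rng.normal(0.0, line_sd, size=n_lines)

    rows = []
    for i, line in enumerate(line_ids):
        expr = float(rng.lognormal(mean=1.0, sigma=1.0))
        for treatment, mean in (("none", line_means[i]), ("vernalized", line_means[i] * vernalization_shift)):
            vals = mean + rng.normal(0.0, residual_sd, size=reps_per_line)
            for rep, v in enumerate(vals):
                rows.append(
                    {
                        "line": line,
                        "genotype_class": "mutant",
                        "replicate": rep,
                        "treatment": treatment,
                        "DTF": v,
                        "RLN": 0.5 * v + rng.normal(0.0, 0.5 * residual_sd),
                        "flc_expression": expr,
                    }
                )
    pheno = pd.DataFrame(rows)

    day_lo, day_hi = days
    growth_rows = []
    for i, line in enumerate(line_ids):
        rate = rng.normal(growth_rate, growth_rate_sd)
        for rep in range(reps_per_line):
            log_a0 = rng.normal(np.log(800.0), 0.2)
            for day in range(day_lo, day_hi + 1):
                log_area = log_a0 + rate * day + rng.normal(0.0, growth_noise_sd)
                growth_rows.append(
                    {
                        "line": line,
                        "genotype_class": "mutant",
                        "replicate": rep,
                        "day": day,
                        "area_px": float(np.exp(log_area)),
                    }
                )
    growth = pd.DataFrame(growth_rows)
    return ReplicatedLines(pheno, growth, pd.Series(line_means, index=line_ids), vernalization_shift)


# ---------------------------------------------------------------------------
# writers (plain-text external formats)


def write_vcf(variant_set: ParentalVariantSet, path: str, contigs=None, passing_only: bool = False) -> None:
    """Write variants as VCF v4.2 with QD/FS/MQ/MQRankSum/ReadPosRankSum INFO keys."""
    df = variant_set.passing if passing_only else variant_set.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contigs:
            for name, length in contigs:
                fh.write(f"##contig=<ID={name},length={length}>\n")
        for ann in ANNOTATIONS:
            fh.write(f'##INFO=<ID={ann},Number=1,Type=Float,Description="{ann}">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in df.itertuples(index=False):
            info = ";".join(
                f"{ann}={getattr(row, ann):.4f}"
                for ann in ANNOTATIONS
                if np.isfinite(getattr(row, ann))
            )
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t{info or '.'}\n")


def write_counts_tsv(table: AlleleCountTable, path: str) -> None:
    out = table.sites.rename(
        columns={"chrom": "CONTIG", "pos": "POSITION", "ref_count": "REF_COUNT", "alt_count": "ALT_COUNT"}
    )
    out.to_csv(path, sep="\t", index=False)


def write_bed(genome: GenomeSpec, path: str) -> None:
    """Exclusion regions as 0-based half-open BED."""
    with open(path, "w") as fh:
        for reg in genome.excluded_regions:
            fh.write(f"{reg.chrom}\t{reg.start}\t{reg.end}\t{reg.region_class}\n")


def write_truth_json(truth: list[TrueF2Genome], qtl: QTLSpec | None, path: str) -> None:
    payload = {
        "individuals": [
            {
                "id": t.individual_id,
                "segments": {c: [[int(a), int(b), STATES[s]] for a, b, s in segs] for c, segs in t.segments.items()},
                "crossovers": [[c, int(p)] for c, p in t.crossover_positions],
            }
            for t in truth
        ],
        "qtl": asdict(qtl) if qtl is not None else None,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def simulate_bundle(config: dict, outdir: str) -> dict:
    """Run the generators from a ``simulate:`` YAML/dict block and write files.

    Recognised keys: seed, n_variants, n_individuals, mean_coverage,
    error_rate, outlier_fraction, qtl (list of {chrom, pos, additive,
    dominance}), residual_sd, baseline.  Returns the paths written.
    """
    import os

    from .genome import default_genome

    cfg = dict(config.get("simulate", config))
    seed = int(cfg.get("seed", 0))
    genome = default_genome()
    os.makedirs(outdir, exist_ok=True)

    parents = simulate_parents(
        genome,
        n_variants=int(cfg.get("n_variants", 10_000)),
        outlier_fraction=float(cfg.get("outlier_fraction", 0.1)),
        seed=seed,
    )
    truth = simulate_f2(genome, int(cfg.get("n_individuals", 100)), seed=seed + 1)
    counts = simulate_allele_counts(
        truth,
        parents,
        mean_coverage=float(cfg.get("mean_coverage", 0.2)),
        error_rate=float(cfg.get("error_rate", 0.01)),
        seed=seed + 2,
    )
    qtl_spec = QTLSpec(
        qtl=tuple(
            QTL(q["chrom"], int(q["pos"]), float(q.get("additive", 1.0)), float(q.get("dominance", 0.0)))
            for q in cfg.get("qtl", [])
        ),
        residual_sd=float(cfg.get("residual_sd", 1.0)),
        baseline=float(cfg.get("baseline", 30.0)),
    )
    pheno = simulate_phenotypes(truth, qtl_spec, seed=seed + 3)

    paths = {"vcf": os.path.join(outdir, "parents.vcf"), "bed": os.path.join(outdir, "excluded.bed")}
    write_vcf(parents, paths["vcf"], contigs=genome.chromosomes)
    write_bed(genome, paths["bed"])
    counts_dir = os.path.join(outdir, "counts")
    os.makedirs(counts_dir, exist_ok=True)
    for table in counts:
        write_counts_tsv(table, os.path.join(counts_dir, f"{table.sample_id}.tsv"))
    paths["counts_dir"] = counts_dir
    paths["pheno"] = os.path.join(outdir, "phenotypes.csv")
    pheno.to_csv(paths["pheno"], index=False)
    paths["truth"] = os.path.join(outdir, "truth.json")
    write_truth_json(truth, qtl_spec, paths["truth"])
    return paths
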