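"""Population-level marker matrix built from per-individual crossovers.

Every crossover breakpoint observed in any individual splits the genome;
the resulting intervals become markers (placed at interval midpoints), and
each individual's genotype at a marker is the state of its reconstructed
segment there.  A QC cascade then removes poorly covered or duplicated
individuals, individuals with implausibly many crossovers, and markers
with excessive missingness or strong segregation distortion, before the
genetic map is (re-)estimated from adjacent-marker recombination
fractions and the cross is written in the rotated ("csvr") CSV dialect
used by standard mapping software.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import chisquare

from .genome import GenomeSpec, haldane_cm
from .hmm import GenotypeReconstruction

logger = logging.getLogger(__name__)

CODES = ("A", "H", "B")
MISSING = "-"


@dataclass
class CrossObject:
    """Individuals x markers genotype matrix with positions and phenotypes.

    ``genotypes``: DataFrame indexed by individual id, columns marker ids,
    values 'A'/'H'/'B' or NaN.  ``markers``: DataFrame indexed by marker
    id with chrom, pos_bp, pos_cm (non-decreasing within chromosome).
    ``phenotypes``: DataFrame indexed by individual id.
    """

    genotypes: pd.DataFrame
    markers: pd.DataFrame
    phenotypes: pd.DataFrame
    n_crossovers: pd.Series | None = None
    qc_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if list(self.genotypes.columns) != list(self.markers.index):
            raise ValueError("genotype columns do not match marker table")
        for chrom, sub in self.markers.groupby("chrom", sort=False):
            if not sub["pos_cm"].is_monotonic_increasing:
                raise ValueError(f"genetic positions decrease on {chrom}")

    @property
    def n_individuals(self) -> int:
        return len(self.genotypes)

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def numeric_genotypes(self) -> np.ndarray:
        """Matrix of 0/1/2 with -1 for missing."""
        mapping = {c: i for i, c in enumerate(CODES)}
        return (
            self.genotypes.map(lambda v: mapping.get(v, -1) if isinstance(v, str) else -1)
            .to_numpy(dtype=np.int8)
        )

    def log(self, stage: str, removed: list, reason: str) -> None:
        self.qc_log.append({"stage": stage, "removed": list(removed), "reason": reason})

    def removed_counts(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"stage": e["stage"], "n_removed": len(e["removed"]), "reason": e["reason"]} for e in self.qc_log]
        )


# ---------------------------------------------------------------------------
# marker construction


def _segment_lookup(segments, confidences, positions):
    """(state, confidence) of the segment containing each query position."""
    ends = np.array([e for _, e, _ in segments])
    states = np.array([s for _, _, s in segments])
    idx = np.searchsorted(ends, positions, side="right")
    idx = np.clip(idx, 0, len(segments) - 1)
    conf = np.asarray(confidences)[idx]
    return states[idx], conf


def _reconstruction_confidences(path: GenotypeReconstruction, chrom: str) -> list[float]:
    mask = (path.sites["chrom"] == chrom).to_numpy()
    states = path.states[mask]
    post = path.posteriors[mask]
    confs = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            confs.append(float(post[start:i, states[start]].mean()))
            start = i
    return confs


def build_markers(
    paths: list[GenotypeReconstruction],
    genome: GenomeSpec,
    phenotypes: pd.DataFrame | None = None,
    conf_threshold: float = 0.95,
) -> CrossObject:
    """Assemble the cross from reconstructed genotype paths.

    The union of crossover midpoints across all individuals partitions
    each chromosome; each interval is one marker at its midpoint.  An
    individual's genotype at a marker is its segment state there, set to
    missing when the segment's mean posterior is below ``conf_threshold``.
    """
    if len(paths) < 2:
        raise ValueError("need at least 2 individuals")
    events = [p.crossovers() for p in paths]
    breakpoints: dict[str, set[int]] = {c: set() for c in genome.names}
    for ev in events:
        for chrom, sub in ev.groupby("chrom"):
            breakpoints[chrom].update(int(x) for x in sub["mid_bp"])

    marker_rows = []
    for chrom in genome.names:
        bks = sorted(breakpoints[chrom])
        if not bks:
            logger.warning("no crossovers on %s; single marker for the chromosome", chrom)
        bounds = [0, *bks, genome.length(chrom)]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            mid = (lo + hi) // 2
            marker_rows.append({"id": f"{chrom}_{mid}", "chrom": chrom, "pos_bp": mid})
    markers = pd.DataFrame(marker_rows).set_index("id")
    markers["pos_cm"] = [genome.bp_to_cm(bp) for bp in markers["pos_bp"]]

    geno = {}
    for path in paths:
        row = np.empty(len(markers), dtype=object)
        col = 0
        for chrom in genome.names:
            sub = markers[markers["chrom"] == chrom]
            confs = _reconstruction_confidences(path, chrom) if path.posteriors is not None else [1.0] * len(path.segments[chrom])
            states, conf = _segment_lookup(path.segments[chrom], confs, sub["pos_bp"].to_numpy())
            vals = np.array(CODES, dtype=object)[states]
            vals[conf < conf_threshold] = np.nan
            row[col: col + len(sub)] = vals
            col += len(sub)
        geno[path.sample_id] = row
    genotypes = pd.DataFrame.from_dict(geno, orient="index", columns=markers.index)
    n_co = pd.Series({p.sample_id: p.n_crossovers for p in paths})

    pheno = phenotypes if phenotypes is not None else pd.DataFrame(index=genotypes.index)
    pheno = pheno.reindex(genotypes.index)
    return CrossObject(genotypes, markers, pheno, n_crossovers=n_co)


def cross_from_truth(truth, genome: GenomeSpec, phenotypes: pd.DataFrame | None = None) -> CrossObject:
    """Build an error-free cross directly from simulated true genomes."""
    breakpoints: dict[str, set[int]] = {c: set() for c in genome.names}
    for indiv in truth:
        for chrom, bp in indiv.crossover_positions:
            breakpoints[chrom].add(int(bp))

    marker_rows = []
    for chrom in genome.names:
        bounds = [0, *sorted(breakpoints[chrom]), genome.length(chrom)]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if hi <= lo:
                continue
            mid = (lo + hi) // 2
            marker_rows.append({"id": f"{chrom}_{mid}", "chrom": chrom, "pos_bp": mid})
    markers = pd.DataFrame(marker_rows).set_index("id")
    markers["pos_cm"] = [genome.bp_to_cm(bp) for bp in markers["pos_bp"]]

    geno = {}
    for indiv in truth:
        row = np.empty(len(markers), dtype=object)
        col = 0
        for chrom in genome.names:
            sub = markers[markers["chrom"] == chrom]
            states = indiv.states_at(chrom, sub["pos_bp"].to_numpy())
            row[col: col + len(sub)] = np.array(CODES, dtype=object)[states]
            col += len(sub)
        geno[indiv.individual_id] = row
    genotypes = pd.DataFrame.from_dict(geno, orient="index", columns=markers.index)
    n_co = pd.Series({t.individual_id: t.n_crossovers for t in truth})
    pheno = phenotypes if phenotypes is not None else pd.DataFrame(index=genotypes.index)
    pheno = pheno.reindex(genotypes.index)
    return CrossObject(genotypes, markers, pheno, n_crossovers=n_co)


# ---------------------------------------------------------------------------
# QC cascade


def qc_individuals(
    cross: CrossObject,
    min_marker_frac: float | None = None,
    similarity_cutoff: float = 0.9,
    max_crossovers: int = 25,
) -> CrossObject:
    """Remove low-call, duplicated and crossover-inflated individuals.

    Stages run in order: (1) individuals called at too few markers (below
    ``min_marker_frac`` of markers, or below half the population median
    called count when unset); (2) of every pair with genotype identity >=
    ``similarity_cutoff`` over shared called markers, the member with
    fewer called markers (ties to the later sample id); (3) individuals
    with more than ``max_crossovers`` genome-wide crossovers.
    """
    g = cross.numeric_genotypes()
    ids = np.array(cross.genotypes.index)
    called = (g >= 0).sum(axis=1)

    if min_marker_frac is not None:
        min_called = min_marker_frac * cross.n_markers
    else:
        min_called = 0.5 * float(np.median(called))
    low = called < min_called
    removed_low = list(ids[low])

    keep = ~low
    kept_idx = np.flatnonzero(keep)
    gk = g[kept_idx]
    valid = (gk >= 0).astype(np.float64)
    shared = valid @ valid.T
    equal = np.zeros_like(shared)
    for s in range(3):
        ind = (gk == s).astype(np.float64)
        equal += ind @ ind.T
    with np.errstate(invalid="ignore", divide="ignore"):
        identity = np.where(shared > 0, equal / shared, 0.0)
    np.fill_diagonal(identity, 0.0)

    removed_sim: list[str] = []
    active = set(range(len(kept_idx)))
    pairs = np.argwhere(np.triu(identity >= similarity_cutoff, k=1))
    for i, j in pairs:
        if i not in active or j not in active:
            continue
        ci, cj = called[kept_idx[i]], called[kept_idx[j]]
        if ci < cj:
            drop = i
        elif cj < ci:
            drop = j
        else:  # tie: later sample id
            drop = i if ids[kept_idx[i]] > ids[kept_idx[j]] else j
        active.discard(drop)
        removed_sim.append(ids[kept_idx[drop]])

    surviving = [ids[kept_idx[i]] for i in sorted(active)]
    removed_co: list[str] = []
    if cross.n_crossovers is not None:
        co = cross.n_crossovers
        removed_co = [i for i in surviving if co.get(i, 0) > max_crossovers]
        surviving = [i for i in surviving if i not in set(removed_co)]

    if not surviving:
        raise ValueError(f"individual QC removed everything: low={removed_low}, similar={removed_sim}, crossovers={removed_co}")

    out = replace(
        cross,
        genotypes=cross.genotypes.loc[surviving],
        phenotypes=cross.phenotypes.loc[surviving],
        n_crossovers=cross.n_crossovers.loc[surviving] if cross.n_crossovers is not None else None,
        qc_log=list(cross.qc_log),
    )
    out.log("individual_low_call", removed_low, f"called markers < {min_called:.1f}")
    out.log("individual_similarity", removed_sim, f"genotype identity >= {similarity_cutoff}")
    out.log("individual_crossovers", removed_co, f"> {max_crossovers} crossovers")
    return out


def segregation_chi2(n_a: int, n_h: int, n_b: int) -> tuple[float, float]:
    """Chi-square goodness of fit (df=2) of genotype counts against 1:2:1."""
    n = n_a + n_h + n_b
    stat, p = chisquare([n_a, n_h, n_b], f_exp=[n / 4, n / 2, n / 4])
    return float(stat), float(p)


def qc_markers(
    cross: CrossObject,
    max_missing_frac: float = 0.1,
    distortion_p: float = 1e-7,
) -> CrossObject:
    """Remove markers with excess missingness or segregation distortion.

    Distortion is tested per marker by a 1:2:1 chi-square (df=2, no
    continuity correction) on called genotypes only; markers with
    p < ``distortion_p`` are removed.
    """
    g = cross.numeric_genotypes()
    n = cross.n_individuals
    missing_frac = (g < 0).mean(axis=0)
    cols = np.array(cross.genotypes.columns)
    removed_missing = list(cols[missing_frac > max_missing_frac])

    keep = missing_frac <= max_missing_frac
    removed_distorted = []
    for k in np.flatnonzero(keep):
        counts = [(g[:, k] == s).sum() for s in range(3)]
        if sum(counts) == 0:
            continue
        _, p = segregation_chi2(*counts)
        if p < distortion_p:
            keep[k] = False
            removed_distorted.append(cols[k])

    kept_cols = list(cols[keep])
    out = replace(
        cross,
        genotypes=cross.genotypes[kept_cols],
        markers=cross.markers.loc[kept_cols],
        qc_log=list(cross.qc_log),
    )
    out.log("marker_missingness", removed_missing, f"missing fraction > {max_missing_frac}")
    out.log("marker_distortion", removed_distorted, f"1:2:1 chi-square p < {distortion_p}")
    return out


# ---------------------------------------------------------------------------
# genetic map


def _expected_recombinants(r: float) -> tuple[np.ndarray, np.ndarray]:
    """Joint probability and E[recombinant gametes] for the 9 two-locus classes."""
    probs = np.zeros((3, 3))
    exp_rec = np.zeros((3, 3))
    gametes = [(x, y) for x in (0, 1) for y in (0, 1)]
    for x1, y1 in gametes:
        p1 = (1 - r) / 2 if x1 == y1 else r / 2
        rec1 = 0 if x1 == y1 else 1
        for x2, y2 in gametes:
            p2 = (1 - r) / 2 if x2 == y2 else r / 2
            rec2 = 0 if x2 == y2 else 1
            g1, g2 = x1 + x2, y1 + y2
            probs[g1, g2] += p1 * p2
            exp_rec[g1, g2] += p1 * p2 * (rec1 + rec2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = np.where(probs > 0, exp_rec / probs, 0.0)
    return probs, cond


def estimate_rf(g1: np.ndarray, g2: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> float:
    """EM estimate of the F2 recombination fraction between two markers.

    ``g1``/``g2`` are 0/1/2 genotype codes with -1 for missing; only
    individuals called at both markers contribute.  The heterozygous double
    class mixes parental and double-recombinant gamete pairs, which is what
    the EM resolves.  The estimate is capped at 0.49.
    """
    ok = (g1 >= 0) & (g2 >= 0)
    a, b = g1[ok], g2[ok]
    n = len(a)
    if n == 0:
        return 0.49
    counts = np.zeros((3, 3))
    np.add.at(counts, (a, b), 1)
    r = 0.25
    for _ in range(max_iter):
        _, cond = _expected_recombinants(r)
        r_new = float((counts * cond).sum() / (2 * n))
        if abs(r_new - r) < tol:
            r = r_new
            break
        r = r_new
    return min(max(r, 0.0), 0.49)


def estimate_genetic_map(cross: CrossObject) -> CrossObject:
    """Re-estimate cM positions from adjacent-marker recombination fractions.

    Recombination fractions come from the two-locus EM above and are
    converted to map distances with the Haldane inverse; positions are
    cumulative within each chromosome starting at 0.
    """
    g = cross.numeric_genotypes()
    markers = cross.markers.copy()
    cols = {m: i for i, m in enumerate(cross.genotypes.columns)}
    new_cm = np.empty(len(markers))
    for chrom, sub in markers.groupby("chrom", sort=False):
        if not sub["pos_bp"].is_monotonic_increasing:
            raise ValueError(f"markers on {chrom} not sorted by physical position")
        idx = [cols[m] for m in sub.index]
        cm = [0.0]
        for i in range(len(idx) - 1):
            r = estimate_rf(g[:, idx[i]], g[:, idx[i + 1]])
            cm.append(cm[-1] + haldane_cm(r))
        new_cm[[markers.index.get_loc(m) for m in sub.index]] = cm
    markers["pos_cm"] = new_cm
    return replace(cross, markers=markers, qc_log=list(cross.qc_log))


# ---------------------------------------------------------------------------
# rotated-CSV ("csvr") round trip


def write_cross(cross: CrossObject, path: str) -> None:
    """Write the cross in the rotated CSV dialect.

    First an ``id`` row, then one row per phenotype (name,,,values), then
    one row per marker (id, chrom, cM, A/H/B codes with '-' for missing).
    """
    pheno = cross.phenotypes
    for colname in pheno.columns:
        if pheno[colname].isna().all():
            raise ValueError(f"phenotype column {colname!r} is entirely empty")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "", "", *cross.genotypes.index])
        for colname in pheno.columns:
            w.writerow([colname, "", "", *[("" if pd.isna(v) else repr(float(v))) for v in pheno[colname]]])
        for marker in cross.genotypes.columns:
            row = cross.markers.loc[marker]
            codes = [v if isinstance(v, str) else MISSING for v in cross.genotypes[marker]]
            w.writerow([marker, row["chrom"], f"{row['pos_cm']:.8f}", *codes])


def read_cross(path: str) -> CrossObject:
    """Read a cross written by :func:`write_cross`."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or rows[0][0] != "id":
        raise ValueError("malformed cross file: missing id row")
    ids = rows[0][3:]
    pheno_data: dict[str, list[float]] = {}
    marker_rows = []
    for row in rows[1:]:
        if row[1] == "":  # phenotype row
            pheno_data[row[0]] = [float(v) if v != "" else np.nan for v in row[3:]]
        else:
            marker_rows.append(row)
    markers = []
    geno_cols = {}
    for row in marker_rows:
        # physical position is carried in the marker id ("<chrom>_<bp>")
        try:
            bp = int(row[0].rsplit("_", 1)[1])
        except (IndexError, ValueError):
            bp = -1
        markers.append({"id": row[0], "chrom": row[1], "pos_bp": bp, "pos_cm": float(row[2])})
        geno_cols[row[0]] = [v if v in CODES else np.nan for v in row[3:]]
    markers_df = pd.DataFrame(markers).set_index("id")
    genotypes = pd.DataFrame(geno_cols, index=ids)
    phenotypes = pd.DataFrame(pheno_data, index=ids)
    return CrossObject(genotypes, markers_df, phenotypes)


def write_qc_report(cross: CrossObject, path: str) -> None:
    import json

    with open(path, "w") as fh:
        json.dump(cross.qc_log, fh, indent=2, default=str)
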