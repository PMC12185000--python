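"""F2 genotype reconstruction from sparse allele counts.

At ~0.1-0.2x coverage most marker sites see zero or one read, so genotypes
cannot be called per site.  A three-state hidden Markov model (states AA,
AB, BB = 0, 1, 2 copies of the ALT-parent allele) pools information along
each chromosome: ALT-read counts are binomial emissions with success
probability epsilon, 0.5 or 1 - epsilon; transitions between adjacent
sites follow the F2 two-locus matrix at the Haldane recombination fraction
implied by the physical gap.  Viterbi gives the segment mosaic, the
forward-backward pass gives per-site posteriors, and crossovers are called
at state changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom

from .genome import GenomeSpec

logger = logging.getLogger(__name__)

F2_INIT = np.array([0.25, 0.5, 0.25])


@dataclass
class AlleleCountTable:
    """Per-sample REF/ALT read counts at marker sites.

    ``sites`` columns: chrom, pos (1-based), ref_count, alt_count; sorted
    by (chrom, pos).  Depth is ref_count + alt_count.
    """

    sample_id: str
    sites: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.sites
        if (df[["ref_count", "alt_count"]].to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> np.ndarray:
        return (self.sites["ref_count"] + self.sites["alt_count"]).to_numpy()

    @property
    def n_informative(self) -> int:
        """Sites with at least one read."""
        return int((self.depth > 0).sum())


def read_counts_tsv(path: str, sample_id: str | None = None) -> AlleleCountTable:
    """Read a CONTIG/POSITION/REF_COUNT/ALT_COUNT table (header tolerated)."""
    import os

    first = open(path).readline()
    header = 0 if first.upper().startswith("CONTIG") else None
    df = pd.read_csv(path, sep="\t", header=header)
    if header is None:
        df.columns = ["CONTIG", "POSITION", "REF_COUNT", "ALT_COUNT"][: len(df.columns)]
    df = df.rename(
        columns={"CONTIG": "chrom", "POSITION": "pos", "REF_COUNT": "ref_count", "ALT_COUNT": "alt_count"}
    )
    sid = sample_id or os.path.splitext(os.path.basename(path))[0]
    return AlleleCountTable(sid, df)


@dataclass
class CountsFilterResult:
    table: AlleleCountTable | None
    rejected: bool
    reason: str | None
    n_organellar_removed: int
    n_depth_removed: int
    n_informative: int


def filter_counts(
    table: AlleleCountTable,
    organellar_contigs: tuple[str, ...] = ("ChrM", "ChrC", "mitochondria", "chloroplast"),
    sd_mult: float = 5.0,
    min_sites: int = 7000,
) -> CountsFilterResult:
    """Coverage and sample-level QC on an allele-count table.

    Organellar contigs are dropped; sites whose depth deviates from the
    per-sample mean by more than ``sd_mult`` standard deviations (moments
    over all retained sites, zero-depth included — at shallow coverage the
    zero class anchors the scale so that rare pile-ups stand out) are
    removed; samples left with fewer than ``min_sites`` informative sites
    are rejected, not crashed.  With zero depth variance the SD interval
    degenerates to a point and the rule is skipped.
    """
    if table.sites.empty:
        return CountsFilterResult(None, True, "empty table", 0, 0, 0)
    df = table.sites
    org = df["chrom"].isin(organellar_contigs)
    df = df[~org].reset_index(drop=True)

    depth = (df["ref_count"] + df["alt_count"]).to_numpy()
    n_depth_removed = 0
    if len(depth):
        mu = depth.mean()
        sd = depth.std()
        if sd > 0:
            bad = (depth < mu - sd_mult * sd) | (depth > mu + sd_mult * sd)
            n_depth_removed = int(bad.sum())
            df = df[~bad].reset_index(drop=True)
        else:
            logger.warning("%s: zero depth variance, SD rule skipped", table.sample_id)

    filtered = AlleleCountTable(table.sample_id, df)
    n_inf = filtered.n_informative
    if n_inf < min_sites:
        logger.info("%s rejected: %d informative sites < %d", table.sample_id, n_inf, min_sites)
        return CountsFilterResult(None, True, f"{n_inf} informative sites < {min_sites}", int(org.sum()), n_depth_removed, n_inf)
    return CountsFilterResult(filtered, False, None, int(org.sum()), n_depth_removed, n_inf)


# ---------------------------------------------------------------------------
# HMM core


def f2_transition(r: float) -> np.ndarray:
    """Two-locus F2 genotype transition matrix at recombination fraction r."""
    s = 1.0 - r
    return np.array(
        [
            [s * s, 2 * r * s, r * r],
            [r * s, s * s + r * r, r * s],
            [r * r, 2 * r * s, s * s],
        ]
    )


def _log_transitions(gaps_bp: np.ndarray, cm_per_mb: float) -> np.ndarray:
    d_cm = gaps_bp / 1e6 * cm_per_mb
    r = 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))
    out = np.empty((len(r), 3, 3))
    for i, ri in enumerate(r):
        out[i] = f2_transition(ri)
    with np.errstate(divide="ignore"):
        return np.log(out)


def _log_emissions(depth: np.ndarray, alt: np.ndarray, error_rate: float, depth_cap: int) -> np.ndarray:
    """Binomial log-emissions, shape (n_sites, 3); zero-depth sites emit uniformly."""
    depth = depth.astype(np.int64).copy()
    alt = alt.astype(np.int64).copy()
    over = depth > depth_cap
    if over.any():  # overdispersion guard: rescale to the cap
        alt[over] = np.round(alt[over] * depth_cap / depth[over]).astype(np.int64)
        depth[over] = depth_cap
    p = np.array([error_rate, 0.5, 1.0 - error_rate])
    le = binom.logpmf(alt[:, None], depth[:, None], p[None, :])
    le[depth == 0] = 0.0
    return le


def _viterbi(log_emis: np.ndarray, log_trans: np.ndarray, log_init: np.ndarray) -> np.ndarray:
    """Viterbi paths for stacked samples.

    ``log_emis``: (S, N, 3); ``log_trans``: (N-1, 3, 3) shared across
    samples; returns states (S, N).  Ties are broken toward staying in the
    current state, which favors paths with fewer crossovers.
    """
    S, N, _ = log_emis.shape
    delta = log_init[None, :] + log_emis[:, 0, :]
    ptr = np.empty((N, S, 3), dtype=np.int8)
    stay = np.arange(3)
    for t in range(1, N):
        M = delta[:, :, None] + log_trans[t - 1][None, :, :]  # (S, i, j)
        best = M.max(axis=1)
        arg = M.argmax(axis=1)
        diag = np.diagonal(M, axis1=1, axis2=2)
        arg = np.where(diag == best, stay[None, :], arg)
        ptr[t] = arg
        delta = best + log_emis[:, t, :]
    states = np.empty((S, N), dtype=np.int8)
    states[:, -1] = delta.argmax(axis=1)
    for t in range(N - 1, 0, -1):
        states[:, t - 1] = ptr[t][np.arange(S), states[:, t]]
    return states


def _forward_backward(
    log_emis: np.ndarray, log_trans: np.ndarray, log_init: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Log-domain forward-backward for stacked samples.

    Returns (posteriors (S, N, 3), forward logliks (S,), backward logliks
    (S,)); the two likelihood computations are independent recursions and
    must agree.
    """
    S, N, _ = log_emis.shape
    la = np.empty((S, N, 3))
    la[:, 0] = log_init[None, :] + log_emis[:, 0]
    for t in range(1, N):
        la[:, t] = logsumexp(la[:, t - 1][:, :, None] + log_trans[t - 1][None], axis=1) + log_emis[:, t]
    lb = np.empty((S, N, 3))
    lb[:, -1] = 0.0
    for t in range(N - 2, -1, -1):
        lb[:, t] = logsumexp(log_trans[t][None] + (log_emis[:, t + 1] + lb[:, t + 1])[:, None, :], axis=2)
    ll_fwd = logsumexp(la[:, -1], axis=1)
    ll_bwd = logsumexp(log_init[None, :] + log_emis[:, 0] + lb[:, 0], axis=1)
    post = np.exp(la + lb - ll_fwd[:, None, None])
    return post, ll_fwd, ll_bwd


# ---------------------------------------------------------------------------
# model / results objects


@dataclass
class GenotypeReconstruction:
    """Fitted genotype path for one individual.

    ``sites`` carries chrom/pos/depth; ``posteriors`` (n_sites, 3) and
    ``states`` align with it.  ``segments`` maps chromosome to
    (start_bp, end_bp, state) tuples tiling [0, length); breakpoints sit at
    the midpoint between the sites flanking each state change.
    """

    sample_id: str
    sites: pd.DataFrame
    posteriors: np.ndarray
    states: np.ndarray
    loglik_forward: float
    loglik_backward: float
    segments: dict[str, list[tuple[int, int, int]]] = field(default_factory=dict)

    @property
    def n_crossovers(self) -> int:
        return sum(len(segs) - 1 for segs in self.segments.values())

    def crossovers(self) -> pd.DataFrame:
        return call_crossovers(self)

    def summary(self) -> pd.DataFrame:
        rows = []
        for chrom, segs in self.segments.items():
            rows.append(
                {
                    "chrom": chrom,
                    "n_sites": int((self.sites["chrom"] == chrom).sum()),
                    "n_segments": len(segs),
                    "n_crossovers": len(segs) - 1,
                }
            )
        return pd.DataFrame(rows)


class GenotypeHMM:
    """Three-state genotype HMM for shallow-coverage F2 individuals.

    Parameters
    ----------
    genome
        Coordinate frame; supplies chromosome lengths and the cM/Mb rate
        used to turn physical gaps into recombination fractions.
    error_rate
        Per-read probability that a read reports the wrong allele
        (must be in [0, 0.5)).
    depth_cap
        Sites deeper than this are rescaled to the cap before the binomial
        emission, guarding against overdispersed pileups.
    init
        Initial state distribution; the F2 prior (1/4, 1/2, 1/4) by default.
    """

    def __init__(
        self,
        genome: GenomeSpec,
        error_rate: float = 0.01,
        depth_cap: int = 50,
        init: tuple[float, float, float] = (0.25, 0.5, 0.25),
    ) -> None:
        if not 0.0 <= error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        self.genome = genome
        self.error_rate = error_rate
        self.depth_cap = depth_cap
        with np.errstate(divide="ignore"):
            self.log_init = np.log(np.asarray(init, dtype=float))

    def fit(self, table: AlleleCountTable) -> GenotypeReconstruction:
        """Reconstruct one individual's genotype path."""
        return self.fit_population([table])[0]

    def fit_population(self, tables: list[AlleleCountTable]) -> list[GenotypeReconstruction]:
        """Reconstruct many individuals sharing one marker-site grid.

        When all tables list the same (chrom, pos) sites in the same order
        (the usual case: counts collected against one parental marker set)
        the recursions run vectorized across samples; otherwise each
        sample is fitted on its own grid.
        """
        if not tables:
            return []
        ref = tables[0].sites[["chrom", "pos"]]
        shared = all(
            len(t.sites) == len(ref) and ref.equals(t.sites[["chrom", "pos"]].reset_index(drop=True))
            for t in tables[1:]
        )
        if not shared:
            return [self.fit_population([t])[0] for t in tables]
        n_samples = len(tables)

        chrom_order = [c for c in self.genome.names if (ref["chrom"] == c).any()]
        missing = set(ref["chrom"].unique()) - set(self.genome.names)
        if missing:
            raise ValueError(f"sites on contigs absent from genome: {sorted(missing)}")

        results_states: list[list[np.ndarray]] = [[] for _ in range(n_samples)]
        results_post: list[list[np.ndarray]] = [[] for _ in range(n_samples)]
        ll_fwd = np.zeros(n_samples)
        ll_bwd = np.zeros(n_samples)
        segments: list[dict[str, list[tuple[int, int, int]]]] = [dict() for _ in range(n_samples)]
        site_frames = []

        for chrom in chrom_order:
            mask = (ref["chrom"] == chrom).to_numpy()
            pos = ref.loc[mask, "pos"].to_numpy(dtype=np.int64)
            if not np.all(np.diff(pos) >= 0):
                raise ValueError(f"sites on {chrom} are not position-sorted")
            log_emis = np.stack(
                [
                    _log_emissions(
                        (t.sites.loc[mask, "ref_count"] + t.sites.loc[mask, "alt_count"]).to_numpy(),
                        t.sites.loc[mask, "alt_count"].to_numpy(),
                        self.error_rate,
                        self.depth_cap,
                    )
                    for t in tables
                ]
            )
            log_trans = _log_transitions(np.diff(pos), self.genome.cm_per_mb)
            states = _viterbi(log_emis, log_trans, self.log_init)
            post, lf, lb = _forward_backward(log_emis, log_trans, self.log_init)
            ll_fwd += lf
            ll_bwd += lb
            length = self.genome.length(chrom)
            for s in range(n_samples):
                results_states[s].append(states[s])
                results_post[s].append(post[s])
                segments[s][chrom] = _states_to_segments(states[s], pos, length)
            site_frames.append(pd.DataFrame({"chrom": chrom, "pos": pos}))

        sites_out_base = pd.concat(site_frames, ignore_index=True)
        out = []
        for s, table in enumerate(tables):
            st = np.concatenate(results_states[s])
            po = np.concatenate(results_post[s])
            sites_out = sites_out_base.copy()
            order = pd.concat(
                [table.sites[(table.sites["chrom"] == c)] for c in chrom_order], ignore_index=True
            )
            sites_out["depth"] = (order["ref_count"] + order["alt_count"]).to_numpy()
            out.append(
                GenotypeReconstruction(
                    table.sample_id, sites_out, po, st, float(ll_fwd[s]), float(ll_bwd[s]), segments[s]
                )
            )
        return out


def _states_to_segments(states: np.ndarray, pos: np.ndarray, chrom_length: int) -> list[tuple[int, int, int]]:
    """Run-length encode a state path into bp segments tiling [0, length)."""
    changes = np.flatnonzero(np.diff(states)) + 1
    bounds = [0]
    for c in changes:
        bounds.append(int((pos[c - 1] + pos[c]) // 2))
    bounds.append(chrom_length)
    starts_idx = np.concatenate([[0], changes])
    return [
        (bounds[i], bounds[i + 1], int(states[starts_idx[i]]))
        for i in range(len(starts_idx))
    ]


def call_crossovers(path: GenotypeReconstruction) -> pd.DataFrame:
    """One crossover event per state change in the fitted path.

    The breakpoint interval is bracketed by the nearest informative
    (nonzero-depth) sites on either side of the change; the reported
    position is the interval midpoint.  Confidence is the smaller of the
    two flanking segments' mean posterior mass for their called state.
    An AA<->BB change (a collapsed double crossover) is flagged
    non-canonical.
    """
    events = []
    sites = path.sites
    for chrom, segs in path.segments.items():
        mask = (sites["chrom"] == chrom).to_numpy()
        pos = sites.loc[mask, "pos"].to_numpy()
        depth = sites.loc[mask, "depth"].to_numpy()
        states = path.states[mask]
        post = path.posteriors[mask]
        changes = np.flatnonzero(np.diff(states)) + 1
        informative = depth > 0
        for c in changes:
            left_candidates = np.flatnonzero(informative[:c])
            right_candidates = np.flatnonzero(informative[c:]) + c
            li = left_candidates[-1] if len(left_candidates) else c - 1
            ri = right_candidates[0] if len(right_candidates) else c
            # confidence: mean posterior of each flanking segment's called state
            conf_left = float(post[_run_start(states, c - 1): c, states[c - 1]].mean())
            conf_right = float(post[c:_run_end(states, c) + 1, states[c]].mean())
            events.append(
                {
                    "sample_id": path.sample_id,
                    "chrom": chrom,
                    "left_bp": int(pos[li]),
                    "right_bp": int(pos[ri]),
                    "mid_bp": int((pos[li] + pos[ri]) // 2),
                    "from_state": int(states[c - 1]),
                    "to_state": int(states[c]),
                    "confidence": min(conf_left, conf_right),
                    "non_canonical": abs(int(states[c]) - int(states[c - 1])) == 2,
                }
            )
    return pd.DataFrame(
        events,
        columns=[
            "sample_id", "chrom", "left_bp", "right_bp", "mid_bp",
            "from_state", "to_state", "confidence", "non_canonical",
        ],
    )


def _run_start(states: np.ndarray, idx: int) -> int:
    i = idx
    while i > 0 and states[i - 1] == states[idx]:
        i -= 1
    return i


def _run_end(states: np.ndarray, idx: int) -> int:
    i = idx
    while i + 1 < len(states) and states[i + 1] == states[idx]:
        i += 1
    return i


def write_segments_tsv(path: GenotypeReconstruction, out_path: str) -> None:
    rows = [
        {"chrom": chrom, "start": a, "end": b, "state": ("AA", "AB", "BB")[s]}
        for chrom, segs in path.segments.items()
        for a, b, s in segs
    ]
    pd.DataFrame(rows).to_csv(out_path, sep="\t", index=False)
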