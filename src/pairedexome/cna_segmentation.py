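"""Copy-number alteration calling from paired binned coverage.

The metastasis-versus-primary copy profile is the per-bin
log2(met/primary) coverage ratio after library-size normalization.
Profiles are smoothed with circular binary segmentation (CBS):
recursively find the circular arc (i, j) maximizing a two-sample
t-like statistic between the arc and its complement, accept the split
if its permutation p-value is below ``alpha``, and recurse.  Each
sample's copy-neutral baseline ("zero level") is the most frequent
smoothed value, estimated as a bin-count-weighted histogram mode.
States are then called by fixed offsets from that zero: +/-0.15 for
gain/deletion, +/-2 for high-level amplification / homozygous
deletion, with "above"/"below" read strictly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STATES = ("neutral", "gain", "deletion", "amplification", "homozygous_deletion")
GAIN_OFFSET = 0.15
AMP_OFFSET = 2.0
DEPTH_FLOOR = 10  # bins with primary depth below this are masked


@dataclass
class Segment:
    """A maximal run of bins sharing one smoothed log2-ratio value."""

    chrom: str
    start_bin: int  # inclusive bin indices within the chromosome
    end_bin: int
    smoothed_value: float
    n_bins: int
    state: str = "neutral"


def log_ratio(
    primary: pd.DataFrame,
    met: pd.DataFrame,
    depth_floor: float = DEPTH_FLOOR,
    normalize: bool = True,
) -> pd.DataFrame:
    """Per-bin log2 coverage ratio of metastasis over primary.

    Both tables must share the same (chrom, start, end) grid.  With
    ``normalize`` each sample's bin depths are first divided by that
    sample's total depth, so global sequencing-yield differences cancel.
    Bins with primary depth below ``depth_floor`` (un-normalized reads)
    or zero metastasis depth are masked as NaN.
    """
    for col in ("chrom", "start", "end"):
        if not primary[col].reset_index(drop=True).equals(met[col].reset_index(drop=True)):
            raise ValueError("primary and metastasis coverage use different bin grids")
    p = primary["depth"].to_numpy(float)
    m = met["depth"].to_numpy(float)
    if normalize:
        pn = p / p.sum() if p.sum() > 0 else p
        mn = m / m.sum() if m.sum() > 0 else m
    else:
        pn, mn = p, m
    mask = (p < depth_floor) | (m <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lr = np.log2(mn / pn)
    lr[mask] = np.nan
    out = primary[["chrom", "start", "end"]].reset_index(drop=True).copy()
    out["log2_ratio"] = lr
    return out


def max_arc_stat(
    values: np.ndarray, min_width: int = 3
) -> tuple[float, int, int]:
    """Maximal circular-arc two-sample statistic over a value vector.

    Considers every arc ``values[i:j]`` with both the arc and its
    complement at least ``min_width`` long, scoring
    ``|mean(arc) - mean(complement)| / pooled SE``.  Returns
    ``(t_max, i, j)``; ties resolve to the lexicographically first
    (i, j).  Returns ``(0.0, -1, -1)`` when no admissible arc exists or
    the vector is constant.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2 * min_width:
        return 0.0, -1, -1
    c = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))
    total, total2 = c[-1], c2[-1]

    i_idx = np.arange(n + 1)
    k = i_idx[None, :] - i_idx[:, None]  # arc length j - i
    arc_sum = c[None, :] - c[:, None]
    arc_sq = c2[None, :] - c2[:, None]
    valid = (k >= min_width) & (n - k >= min_width)

    with np.errstate(divide="ignore", invalid="ignore"):
        comp = n - k
        mean_diff = arc_sum / k - (total - arc_sum) / comp
        ss = (arc_sq - arc_sum**2 / k) + (
            (total2 - arc_sq) - (total - arc_sum) ** 2 / comp
        )
        sp2 = ss / (n - 2)
        se = np.sqrt(sp2 * (1.0 / k + 1.0 / comp))
        t = np.abs(mean_diff) / se
    # se == 0 with a real mean difference is a perfect (noise-free) split
    # and scores +inf; se == 0 with no difference (constant data) is no split.
    t[np.isnan(t)] = -np.inf
    t[~valid] = -np.inf

    flat = int(np.argmax(t))  # row-major: first (i, j) among ties
    i, j = divmod(flat, n + 1)
    t_max = t[i, j]
    if t_max == -np.inf:
        return 0.0, -1, -1
    return float(t_max), int(i), int(j)


def _split_significant(
    x: np.ndarray,
    alpha: float,
    n_perm: int,
    rng: np.random.Generator,
    min_width: int,
) -> tuple[int, int] | None:
    """Permutation-test the best arc split of ``x``; return (i, j) if accepted."""
    t_obs, i, j = max_arc_stat(x, min_width)
    if i < 0 or t_obs <= 0:
        return None
    # Once exceedances guarantee p >= alpha the split is rejected; stopping
    # there changes nothing about the accept/reject outcome.
    reject_at = int(np.ceil(alpha * (1 + n_perm)))
    exceed = 0
    for _ in range(n_perm):
        t_perm, _, _ = max_arc_stat(rng.permutation(x), min_width)
        if t_perm >= t_obs:
            exceed += 1
            if exceed >= reject_at:
                return None
    p = (1 + exceed) / (1 + n_perm)
    return (i, j) if p < alpha else None


def _refine_boundaries(
    x: np.ndarray, segments: list[tuple[int, int]], min_width: int, window: int = 5
) -> list[tuple[int, int]]:
    """Locally re-optimize each internal boundary by within-segment RSS.

    The arc search locates both edges of a split jointly, so a noisy
    edge can sit a few bins off its optimum; one sweep of local
    likelihood maximization over a +/-window neighborhood (keeping both
    neighbors >= min_width) fixes that.  Ties prefer the smaller move,
    then the smaller index.
    """
    out = [list(s) for s in sorted(segments)]
    for k in range(len(out) - 1):
        lo, b, hi = out[k][0], out[k][1], out[k + 1][1]
        lo_b = max(lo + min_width, b - window)
        hi_b = min(hi - min_width, b + window)
        if lo_b > hi_b:
            continue

        def rss(bb: int) -> float:
            a, c = x[lo:bb], x[bb:hi]
            return float(((a - a.mean()) ** 2).sum() + ((c - c.mean()) ** 2).sum())

        best = min(range(lo_b, hi_b + 1), key=lambda bb: (rss(bb), abs(bb - b), bb))
        out[k][1] = out[k + 1][0] = best
    return [tuple(s) for s in out]


def cbs_segment(
    values: np.ndarray,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int | None = None,
    min_width: int = 3,
) -> list[tuple[int, int]]:
    """Segment a vector of per-bin log ratios by recursive CBS.

    Returns ``(start, end)`` half-open index intervals partitioning
    ``range(len(values))``; NaNs must be removed by the caller.
    Deterministic for a fixed seed (permutations and recursion order
    are both seeded / fixed).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        return []
    if not np.all(np.isfinite(x)):
        raise ValueError("cbs_segment requires finite values; mask NaNs upstream")
    rng = np.random.default_rng(seed)

    segments: list[tuple[int, int]] = []
    stack = [(0, x.size)]  # LIFO; children pushed right-first so left pops first
    while stack:
        lo, hi = stack.pop()
        split = _split_significant(x[lo:hi], alpha, n_perm, rng, min_width)
        if split is None:
            segments.append((lo, hi))
            continue
        i, j = split
        pieces = [(lo, lo + i), (lo + i, lo + j), (lo + j, hi)]
        for piece in reversed(pieces):
            if piece[1] > piece[0]:
                stack.append(piece)
    segments.sort()
    if len(segments) > 1:
        segments = _refine_boundaries(x, segments, min_width)
    return segments


def segment_chromosomes(
    ratios: pd.DataFrame,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int | None = None,
    min_width: int = 3,
) -> list[Segment]:
    """Run CBS per chromosome on a ``log_ratio`` output table.

    Masked (NaN) bins are dropped before segmentation; segment bounds
    refer to the original bin indices of the first and last unmasked
    member bins.  An all-masked chromosome yields no segments (warned).
    """
    segments: list[Segment] = []
    for chrom, grp in ratios.groupby("chrom", sort=False):
        vals = grp["log2_ratio"].to_numpy()
        finite = np.isfinite(vals)
        if not finite.any():
            logger.warning("chromosome %s fully masked; no segments", chrom)
            continue
        kept = np.flatnonzero(finite)
        x = vals[kept]
        for lo, hi in cbs_segment(x, alpha, n_perm, seed, min_width):
            member = kept[lo:hi]
            segments.append(
                Segment(
                    chrom=str(chrom),
                    start_bin=int(member[0]),
                    end_bin=int(member[-1]),
                    smoothed_value=float(x[lo:hi].mean()),
                    n_bins=int(hi - lo),
                )
            )
    return segments


def zero_level(segments: list[Segment], bandwidth: float = 0.05) -> float:
    """Copy-neutral baseline: the most frequent smoothed segment value.

    "Most frequent" for continuous values is estimated as the mode of a
    Gaussian kernel density over smoothed values, weighted by each
    segment's bin count, with ``bandwidth`` kept well below the 0.15
    call offset.  The density is evaluated at the segment values
    themselves, so the estimate is exactly translation-equivariant and
    pools neutral segments whose means differ by a fraction of the
    bandwidth (a fixed-edge histogram can split that mass across bins).
    Near-ties pick the candidate nearest zero.
    """
    if not segments:
        raise ValueError("zero_level requires at least one segment")
    vals = np.array([s.smoothed_value for s in segments])
    weights = np.array([s.n_bins for s in segments], dtype=float)
    z = (vals[:, None] - vals[None, :]) / bandwidth
    density = (weights[None, :] * np.exp(-0.5 * z * z)).sum(axis=1)
    best = density.max()
    candidates = sorted(float(v) for v in vals[density >= best * (1 - 1e-9)])
    if len(candidates) > 1:
        logger.warning("zero level tie among %s; choosing value nearest 0", candidates)
    return min(candidates, key=lambda v: (abs(v), v))


def call_states(
    segments: list[Segment],
    zero: float,
    gain_offset: float = GAIN_OFFSET,
    amp_offset: float = AMP_OFFSET,
) -> list[Segment]:
    """Assign a CNA state to each segment relative to the zero level.

    A segment strictly above zero + 2 is an amplification, strictly
    above zero + 0.15 a gain; symmetric below for homozygous deletion
    and deletion; the most extreme applicable label wins.  Values at
    exactly an offset stay in the milder class.
    """
    out = []
    for s in segments:
        d = s.smoothed_value - zero
        if d > amp_offset:
            state = "amplification"
        elif d > gain_offset:
            state = "gain"
        elif d < -amp_offset:
            state = "homozygous_deletion"
        elif d < -gain_offset:
            state = "deletion"
        else:
            state = "neutral"
        out.append(Segment(s.chrom, s.start_bin, s.end_bin, s.smoothed_value, s.n_bins, state))
    return out


def states_per_bin(ratios: pd.DataFrame, segments: list[Segment]) -> pd.DataFrame:
    """Expand segment state calls back onto the bin grid."""
    out = ratios[["chrom", "start", "end"]].copy()
    out["state"] = "neutral"
    bin_index = out.groupby("chrom").cumcount()
    for s in segments:
        sel = (out["chrom"] == s.chrom) & (bin_index >= s.start_bin) & (bin_index <= s.end_bin)
        out.loc[sel, "state"] = s.state
    return out


def recurrent_regions(
    state_tables: dict[str, pd.DataFrame], min_patients: int
) -> pd.DataFrame:
    """Regions gained (or deleted) in at least ``min_patients`` patients.

    ``state_tables`` maps patient id to a per-bin state table (output of
    :func:`states_per_bin`); all patients must share one bin grid.
    Gains include amplifications; deletions include homozygous
    deletions.  Returns maximal runs of bins with recurrence count
    >= min_patients, as chrom/start/end/direction/n_patients rows.
    """
    if len(state_tables) < 2:
        raise ValueError("recurrent_regions requires at least 2 patients")
    tables = list(state_tables.values())
    grid = tables[0][["chrom", "start", "end"]].reset_index(drop=True)
    for t in tables[1:]:
        if not grid.equals(t[["chrom", "start", "end"]].reset_index(drop=True)):
            raise ValueError("patients use inconsistent bin grids")
    gain_like = {"gain", "amplification"}
    del_like = {"deletion", "homozygous_deletion"}
    n_gain = sum(t["state"].isin(gain_like).to_numpy(int) for t in tables)
    n_del = sum(t["state"].isin(del_like).to_numpy(int) for t in tables)

    rows = []
    for direction, counts in (("gain", n_gain), ("deletion", n_del)):
        hot = counts >= min_patients
        for chrom, grp in grid.groupby("chrom", sort=False):
            idx = grp.index.to_numpy()
            h = hot[idx]
            start = None
            for pos, flag in enumerate(np.append(h, False)):
                if flag and start is None:
                    start = pos
                elif not flag and start is not None:
                    block = grp.iloc[start:pos]
                    rows.append(
                        {
                            "chrom": str(chrom),
                            "start": int(block["start"].iloc[0]),
                            "end": int(block["end"].iloc[-1]),
                            "direction": direction,
                            "n_patients": int(counts[idx[start:pos]].min()),
                        }
                    )
                    start = None
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "direction", "n_patients"])


def segments_to_frame(segments: list[Segment], sample: str) -> pd.DataFrame:
    """SEG-style table of segment calls for one sample."""
    return pd.DataFrame(
        [
            {
                "sample": sample,
                "chrom": s.chrom,
                "start_bin": s.start_bin,
                "end_bin": s.end_bin,
                "n_bins": s.n_bins,
                "smoothed_value": s.smoothed_value,
                "state": s.state,
            }
            for s in segments
        ],
        columns=["sample", "chrom", "start_bin", "end_bin", "n_bins", "smoothed_value", "state"],
    )
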