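"""Piecewise-constant fitting (PCF) of per-sample copy-number profiles.

Each sample's log2-ratio profile is segmented per chromosome by minimising

    sum of within-segment squared deviations  +  gamma * (number of breakpoints)

over all segmentations whose segments contain at least ``kmin`` probes.  The
optimum is found by exact dynamic programming over breakpoints, O(n^2) per
chromosome.  Every probe then inherits its segment's mean value (the "PCF
value"), which is what aberration calling and the cis model operate on.

Ties are broken deterministically: among equal-cost segmentations, the one
with fewest segments wins, then the one with lexicographically earliest
breakpoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import GenomicMatrix

logger = logging.getLogger("ipac.segmentation")

#: Cost comparisons use a tiny absolute slack so float summation order cannot
#: flip a genuine tie; distinct optima differ by far more in practice.
_COST_TOL = 1e-9


@dataclass(frozen=True)
class PcfParams:
    """Penalty per breakpoint (gamma) and minimum probes per segment (kmin).

    gamma trades sensitivity for specificity: larger values suppress short,
    shallow segments caused by local trends (GC waves etc.).  Defaults are
    deliberately conservative for noisy aCGH data.
    """

    gamma: float = 40.0
    kmin: int = 5

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.kmin < 1:
            raise ValueError("kmin must be >= 1")


@dataclass(frozen=True)
class Segment:
    """One constant piece of a (sample, chromosome) profile.

    Probe indices are 0-based inclusive into the (non-missing) probe vector
    that was segmented; positions are 1-based basepairs.  ``mean_value`` is
    the PCF value inherited by every probe in the segment.
    """

    sample_id: str
    chromosome: str
    start_index: int
    end_index: int
    start_pos: int
    end_pos: int
    n_probes: int
    mean_value: float

    def __post_init__(self) -> None:
        if self.end_index < self.start_index:
            raise ValueError("end_index < start_index")
        if self.n_probes != self.end_index - self.start_index + 1:
            raise ValueError("n_probes inconsistent with index range")


def _segment_boundaries_multi(V: np.ndarray, gamma: float,
                              kmin: int) -> list[list[int]]:
    """Optimal segment end indices (0-based inclusive) for each column of V.

    Exact suffix DP, vectorised over the columns (profiles sharing one probe
    grid): best[i] = optimal cost of segmenting V[i:]; the first segment
    V[i..e] must have >= kmin probes and leave an empty or segmentable
    remainder.  Among equal-cost choices the DP prefers fewer segments, then
    the earliest end, which yields the lexicographically earliest breakpoint
    sequence overall.
    """
    n, m = V.shape
    if n < kmin:
        return [[n - 1]] * m

    # prefix sums for O(1) segment SSE over V[i..e] inclusive
    cs = np.zeros((n + 1, m))
    cs2 = np.zeros((n + 1, m))
    np.cumsum(V, axis=0, out=cs[1:])
    np.cumsum(V * V, axis=0, out=cs2[1:])

    cost = np.full((n + 1, m), np.inf)
    nseg = np.zeros((n + 1, m), dtype=np.int32)
    first_end = np.full((n + 1, m), -1, dtype=np.int32)
    cost[n] = 0.0
    cols = np.arange(m)
    for i in range(n - kmin, -1, -1):
        ends = np.arange(i + kmin - 1, n)
        ends = ends[(ends <= n - 1 - kmin) | (ends == n - 1)]
        length = (ends + 1 - i).astype(float)[:, None]
        c = (cs2[ends + 1] - cs2[i]) - (cs[ends + 1] - cs[i]) ** 2 / length
        tot = c + cost[ends + 1]
        tot[ends + 1 < n] += gamma
        segs = 1 + nseg[ends + 1]
        # lexicographic min per column: cost (within tol), then fewest
        # segments, then earliest end (argmin picks the first among equals)
        key = np.where(tot <= tot.min(axis=0) + _COST_TOL, segs, n + 2)
        b = key.argmin(axis=0)
        cost[i] = tot[b, cols]
        nseg[i] = segs[b, cols]
        first_end[i] = ends[b]

    out = []
    for j in range(m):
        ends_j = []
        i = 0
        while i < n:
            e = int(first_end[i, j])
            ends_j.append(e)
            i = e + 1
        out.append(ends_j)
    return out


def _segment_boundaries(values: np.ndarray, gamma: float, kmin: int) -> list[int]:
    """Single-profile wrapper around :func:`_segment_boundaries_multi`."""
    return _segment_boundaries_multi(np.asarray(values, float)[:, None],
                                     gamma, kmin)[0]


def segment_profile(values: np.ndarray, params: PcfParams,
                    sample_id: str = "", chromosome: str = "",
                    positions: np.ndarray | None = None) -> list[Segment]:
    """Segment one finite-valued profile; returns segments tiling the probes.

    A vector shorter than kmin yields a single segment with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) == 0:
        raise ValueError("values must be a non-empty 1-D vector")
    if not np.isfinite(values).all():
        raise ValueError("values must be finite; drop missing probes upstream")
    if positions is None:
        positions = np.arange(1, len(values) + 1)
    if len(values) < params.kmin:
        logger.warning("profile %s/%s shorter than kmin=%d: single segment",
                       sample_id, chromosome, params.kmin)

    ends = _segment_boundaries(values, params.gamma, params.kmin)
    segments = []
    start = 0
    for end in ends:
        seg_vals = values[start:end + 1]
        segments.append(Segment(
            sample_id=sample_id, chromosome=chromosome,
            start_index=start, end_index=end,
            start_pos=int(positions[start]), end_pos=int(positions[end]),
            n_probes=end - start + 1, mean_value=float(seg_vals.mean())))
        start = end + 1
    return segments


def segmentation_cost(values: np.ndarray, segments: list[Segment],
                      gamma: float) -> float:
    """Total cost (SSE + gamma * breakpoints) of a segmentation; for tests."""
    values = np.asarray(values, dtype=float)
    sse = sum(float(((values[s.start_index:s.end_index + 1]
                      - values[s.start_index:s.end_index + 1].mean()) ** 2).sum())
              for s in segments)
    return sse + gamma * (len(segments) - 1)


def pcf_values(segments: list[Segment], n_probes: int) -> np.ndarray:
    """Expand segments back to a per-probe vector of PCF values.

    Segments must tile [0, n_probes) without gaps or overlaps.
    """
    out = np.full(n_probes, np.nan)
    expected_start = 0
    for seg in sorted(segments, key=lambda s: s.start_index):
        if seg.start_index != expected_start:
            raise ValueError("segments do not tile the probe list")
        out[seg.start_index:seg.end_index + 1] = seg.mean_value
        expected_start = seg.end_index + 1
    if expected_start != n_probes:
        raise ValueError("segments do not tile the probe list")
    return out


def segment_matrix(cn: GenomicMatrix, params: PcfParams | None = None
                   ) -> tuple[GenomicMatrix, pd.DataFrame]:
    """Segment every (sample, chromosome) profile of a copy-number matrix.

    Missing probe values are dropped before segmentation; their PCF value is
    taken from the segment covering their genomic position (NaN only if the
    whole chromosome is missing for that sample).

    Returns the probe-level PCF-value matrix (same shape and annotation as
    the input) and a SEG-like table (sample, chromosome, start, end,
    n_probes, seg_mean) sorted deterministically.
    """
    if params is None:
        params = PcfParams()
    pcf = np.full(cn.values.shape, np.nan)
    seg_rows = []
    ann = cn.annotations
    values = cn.values.to_numpy()
    samples = cn.samples
    # probe order within chromosome: by position, stable
    for chrom, idx in ann.groupby("chromosome", sort=True).groups.items():
        chrom = str(chrom)
        rows = np.asarray([cn.values.index.get_loc(i) for i in idx])
        order = np.argsort(ann.loc[idx, "position"].to_numpy(), kind="mergesort")
        rows = rows[order]
        pos = ann.loc[idx, "position"].to_numpy()[order]
        Vc = values[rows]
        finite = np.isfinite(Vc)
        # samples sharing a missingness pattern share one vectorised DP
        groups: dict[bytes, list[int]] = {}
        for si in range(Vc.shape[1]):
            groups.setdefault(finite[:, si].tobytes(), []).append(si)
        for cols in groups.values():
            keep = finite[:, cols[0]]
            n_kept = int(keep.sum())
            if n_kept == 0:
                for si in cols:
                    logger.warning("sample %s chromosome %s: all values "
                                   "missing", samples[si], chrom)
                continue
            if n_kept < params.kmin:
                logger.warning("%d profiles on chromosome %s shorter than "
                               "kmin=%d: single segment", len(cols), chrom,
                               params.kmin)
            sub = Vc[keep][:, cols]
            kpos = pos[keep]
            ends_lists = _segment_boundaries_multi(sub, params.gamma,
                                                   params.kmin)
            kept_rows = rows[keep]
            for j, si in enumerate(cols):
                segs = []
                start = 0
                for end in ends_lists[j]:
                    vals = sub[start:end + 1, j]
                    segs.append(Segment(
                        sample_id=samples[si], chromosome=chrom,
                        start_index=start, end_index=end,
                        start_pos=int(kpos[start]), end_pos=int(kpos[end]),
                        n_probes=end - start + 1,
                        mean_value=float(vals.mean())))
                    start = end + 1
                pcf[kept_rows, si] = pcf_values(segs, n_kept)
                # missing probes inherit the covering segment's mean
                if n_kept < len(keep):
                    bounds = np.array([s.end_pos for s in segs])
                    miss_pos = pos[~keep]
                    seg_idx = np.clip(np.searchsorted(bounds, miss_pos),
                                      0, len(segs) - 1)
                    pcf[rows[~keep], si] = [segs[k].mean_value
                                            for k in seg_idx]
                for s in segs:
                    seg_rows.append((samples[si], chrom, s.start_pos,
                                     s.end_pos, s.n_probes, s.mean_value))
    seg_table = pd.DataFrame(seg_rows, columns=["sample", "chromosome", "start",
                                                "end", "n_probes", "seg_mean"])
    seg_table = seg_table.sort_values(["sample", "chromosome", "start"],
                                      kind="mergesort").reset_index(drop=True)
    out = GenomicMatrix(values=pd.DataFrame(pcf, index=cn.values.index,
                                            columns=cn.values.columns),
                        annotations=cn.annotations.copy(), kind="copy_number")
    return out, seg_table
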