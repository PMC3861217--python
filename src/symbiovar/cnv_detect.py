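"""Copy-number variation from binned read depth, plus structural-variant
candidate filtering.

Segmentation follows the mean-shift idea used for read-depth CNV calling:
each bin's depth is iteratively moved toward a depth-weighted local mean
(Gaussian kernel over bin index, Gaussian depth window at the Poisson scale)
until convergence; contiguous bins converging to the same mode form segments,
and adjacent segments with nearly equal means are merged. Copy number is the
segment mean over the median of background bins; significance is a Welch t
test of segment bins against background with Bonferroni correction across
segments.

Split-read SV candidates enter as a support matrix and are filtered by the
max-support / zero-support rule, then checked against a strain tree for
monophyly of the carrier set (a true variant should have arisen once).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .seq import revcomp
from .synthgen import DepthProfile


@dataclass
class Segment:
    start_bp: int  # 1-based inclusive, bin-aligned
    end_bp: int
    start_bin: int  # 0-based bin indices, inclusive
    end_bin: int
    mean_depth: float
    copy_number: float | None = None
    p_value: float | None = None
    p_bonferroni: float | None = None

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin + 1


@dataclass
class RepeatPair:
    left: tuple[int, int]  # 1-based inclusive genome intervals
    right: tuple[int, int]
    length: int
    orientation: str  # 'direct' or 'inverted'
    identity: float = 1.0


# --------------------------------------------------------------------------
# binning and segmentation
# --------------------------------------------------------------------------


def bin_depth(per_base_depth: np.ndarray, bin_width: int, strain_id: str = "strain") -> DepthProfile:
    """Sum per-base depth over consecutive bins; a trailing partial bin is dropped."""
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    depth = np.asarray(per_base_depth, dtype=float)
    n_bins = len(depth) // bin_width
    if n_bins == 0:
        raise ValueError("bin_width larger than the depth vector")
    sums = depth[: n_bins * bin_width].reshape(n_bins, bin_width).sum(axis=1)
    return DepthProfile(strain_id, bin_width, sums)


def _mean_shift(
    counts: np.ndarray,
    bandwidth: float,
    depth_bandwidth: float | None,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, bool]:
    """Iteratively shift each bin's value toward the depth-weighted local mean.

    The kernel is Gaussian in bin index (sd = bandwidth, truncated at 3 sd)
    and Gaussian in current value (sd = depth_bandwidth, defaulting to the
    Poisson scale sqrt(mean depth)). Returns the converged values and whether
    convergence was reached.
    """
    v = counts.astype(float).copy()
    n = len(v)
    if depth_bandwidth is None:
        depth_bandwidth = max(np.sqrt(max(v.mean(), 1.0)), 1.0)
    half = max(1, int(np.ceil(3 * bandwidth)))
    offsets = np.arange(-half, half + 1)
    w_idx = np.exp(-0.5 * (offsets / bandwidth) ** 2)
    tol_abs = tol * max(v.mean(), 1.0)

    idx = np.arange(n)
    neighbour = np.clip(idx[:, None] + offsets[None, :], 0, n - 1)
    valid = (idx[:, None] + offsets[None, :] >= 0) & (idx[:, None] + offsets[None, :] < n)
    for _ in range(max_iter):
        vj = v[neighbour]
        w = w_idx[None, :] * np.exp(-0.5 * ((vj - v[:, None]) / depth_bandwidth) ** 2)
        w = np.where(valid, w, 0.0)
        new = (w * vj).sum(axis=1) / w.sum(axis=1)
        delta = np.abs(new - v).max()
        v = new
        if delta < tol_abs:
            return v, True
    warnings.warn("mean shift did not converge; using the current partition", stacklevel=2)
    return v, False


def segment_profile(
    profile: DepthProfile,
    bandwidth: float = 8.0,
    merge_threshold: float = 0.25,
    depth_bandwidth: float | None = None,
    tol: float = 1e-3,
    max_iter: int = 200,
    min_segment_bins: int = 3,
) -> list[Segment]:
    """Piecewise-constant partition of a binned depth profile.

    Bins whose converged mode values are close (relative to the Poisson scale)
    join one segment; runs shorter than ``min_segment_bins`` (isolated Poisson
    outliers) are absorbed into the nearer-mean neighbour; adjacent segments
    whose raw means differ by less than ``merge_threshold`` (relative) are
    merged. Segments tile the binned genome and breakpoints sit at bin
    boundaries.
    """
    counts = np.asarray(profile.counts, dtype=float)
    if len(counts) < 10:
        raise ValueError("need at least 10 bins to segment")
    modes, _converged = _mean_shift(counts, bandwidth, depth_bandwidth, tol, max_iter)

    scale = max(np.sqrt(max(counts.mean(), 1.0)), 1.0)
    breaks = np.flatnonzero(np.abs(np.diff(modes)) > 0.5 * scale) + 1
    bounds = [0, *breaks.tolist(), len(counts)]
    segments = [(bounds[i], bounds[i + 1] - 1) for i in range(len(bounds) - 1)]

    def seg_mean(seg: tuple[int, int]) -> float:
        return float(counts[seg[0] : seg[1] + 1].mean())

    # absorb sub-minimum runs into the neighbour with the closer mean
    changed = True
    while changed and len(segments) > 1:
        changed = False
        sizes = [e - s + 1 for s, e in segments]
        k = int(np.argmin(sizes))
        if sizes[k] < min_segment_bins:
            mean_k = seg_mean(segments[k])
            left_gap = abs(mean_k - seg_mean(segments[k - 1])) if k > 0 else np.inf
            right_gap = (
                abs(mean_k - seg_mean(segments[k + 1])) if k + 1 < len(segments) else np.inf
            )
            j = k - 1 if left_gap <= right_gap else k + 1
            lo, hi = min(j, k), max(j, k)
            segments[lo] = (segments[lo][0], segments[hi][1])
            del segments[hi]
            changed = True

    # iterative merge of the most similar adjacent pair under the threshold

    merged = True
    while merged and len(segments) > 1:
        merged = False
        means = [seg_mean(s) for s in segments]
        rel = [
            abs(means[i] - means[i + 1]) / max(means[i], means[i + 1], 1e-12)
            for i in range(len(segments) - 1)
        ]
        k = int(np.argmin(rel))
        if rel[k] < merge_threshold:
            segments[k] = (segments[k][0], segments[k + 1][1])
            del segments[k + 1]
            merged = True

    w = profile.bin_width
    return [
        Segment(
            start_bp=s * w + 1,
            end_bp=(e + 1) * w,
            start_bin=s,
            end_bin=e,
            mean_depth=seg_mean((s, e)),
        )
        for s, e in segments
    ]


def copy_number(segment: Segment, background_bins: np.ndarray) -> float:
    """Fold estimate: segment mean depth over the median background bin depth."""
    background_bins = np.asarray(background_bins, dtype=float)
    if background_bins.size == 0:
        raise ValueError("empty background")
    med = float(np.median(background_bins))
    if med <= 0:
        raise ValueError("background median depth is zero")
    return segment.mean_depth / med


def segment_significance(
    segment: Segment, profile: DepthProfile, background_bins: np.ndarray
) -> float:
    """Two-sided Welch t test of segment bins versus background bins."""
    seg_bins = profile.counts[segment.start_bin : segment.end_bin + 1]
    background_bins = np.asarray(background_bins, dtype=float)
    if len(seg_bins) < 2 or len(background_bins) < 2:
        raise ValueError("need >= 2 bins in both groups")
    if np.all(seg_bins == seg_bins[0]) and np.all(background_bins == seg_bins[0]):
        return 1.0
    res = stats.ttest_ind(seg_bins, background_bins, equal_var=False)
    return float(res.pvalue)


def call_cnv(
    profile: DepthProfile,
    bandwidth: float = 8.0,
    merge_threshold: float = 0.25,
    background_tolerance: float = 0.25,
) -> list[Segment]:
    """Segment a profile, estimate copy numbers and Bonferroni-corrected p values.

    Background bins are those in segments whose mean lies within
    ``background_tolerance`` (relative) of the genome-wide median bin depth.
    """
    segments = segment_profile(profile, bandwidth=bandwidth, merge_threshold=merge_threshold)
    counts = np.asarray(profile.counts, dtype=float)
    global_med = float(np.median(counts))
    is_background = [
        abs(s.mean_depth - global_med) / max(global_med, 1e-12) <= background_tolerance
        for s in segments
    ]
    if not any(is_background):
        raise ValueError("no background segment found")
    background = np.concatenate(
        [counts[s.start_bin : s.end_bin + 1] for s, bg in zip(segments, is_background) if bg]
    )
    candidates = [s for s, bg in zip(segments, is_background) if not bg]
    n_tests = max(len(candidates), 1)
    for s, bg in zip(segments, is_background):
        s.copy_number = copy_number(s, background)
        if not bg:
            if s.n_bins < 2:  # a single-bin candidate supports no t test
                s.p_value = float("nan")
                s.p_bonferroni = float("nan")
            else:
                s.p_value = segment_significance(s, profile, background)
                s.p_bonferroni = min(1.0, s.p_value * n_tests)
    return segments


def segments_to_bed(segments: list[Segment], chrom: str = "reference") -> pd.DataFrame:
    """Segments as 0-based half-open BED rows with CN and p in extra columns."""
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": [s.start_bp - 1 for s in segments],
            "end": [s.end_bp for s in segments],
            "mean_depth": [s.mean_depth for s in segments],
            "copy_number": [s.copy_number for s in segments],
            "p_value": [s.p_value for s in segments],
            "p_bonferroni": [s.p_bonferroni for s in segments],
        }
    )


# --------------------------------------------------------------------------
# split-read SV candidate filtering and monophyly
# --------------------------------------------------------------------------


def filter_sv_candidates(
    candidates: pd.DataFrame,
    strain_columns: list[str] | None = None,
    min_support: int = 10,
    require_zero: bool = True,
) -> pd.DataFrame:
    """Retain candidates with >= min_support reads in some strain and (by
    default) zero supporting reads in at least one strain."""
    if strain_columns is None:
        strain_columns = [
            c for c in candidates.columns if c not in ("id", "type", "position")
        ]
    if not strain_columns:
        raise ValueError("no strain support columns")
    support = candidates[strain_columns].to_numpy()
    if (support < 0).any():
        raise ValueError("support counts must be non-negative")
    keep = support.max(axis=1) >= min_support
    if require_zero:
        keep &= support.min(axis=1) == 0
    return candidates[keep].reset_index(drop=True)


def monophyly_check(presence: dict[str, bool], tree: dendropy.Tree) -> bool:
    """True iff the carrier set is exactly the leaf set of one clade.

    A single leaf counts as (trivially) monophyletic; an empty carrier set is
    defined false. Strains missing from the tree raise.
    """
    tree.is_rooted = True  # newick input is read as rooted-as-written
    leaves = {t.label for t in tree.taxon_namespace}
    unknown = set(presence) - leaves
    if unknown:
        raise ValueError(f"strains absent from the tree: {sorted(unknown)}")
    carriers = {s for s, p in presence.items() if p}
    if not carriers:
        return False
    if len(carriers) == 1:
        return True
    taxa = [t for t in tree.taxon_namespace if t.label in carriers]
    mrca = tree.mrca(taxa=taxa)
    clade_leaves = {lf.taxon.label for lf in mrca.leaf_iter()}
    return clade_leaves == carriers


def monophyly_fraction(
    candidates: pd.DataFrame,
    tree: dendropy.Tree,
    strain_columns: list[str] | None = None,
) -> float:
    """Fraction of candidates whose carrier set (support > 0) is monophyletic."""
    if strain_columns is None:
        strain_columns = [
            c for c in candidates.columns if c not in ("id", "type", "position")
        ]
    if len(candidates) == 0:
        raise ValueError("no candidates")
    ok = 0
    for _, row in candidates.iterrows():
        presence = {s: row[s] > 0 for s in strain_columns}
        ok += monophyly_check(presence, tree)
    return ok / len(candidates)


# --------------------------------------------------------------------------
# flanking direct repeats
# --------------------------------------------------------------------------


def _maximal_exact_matches(a: str, b: str, min_length: int) -> list[tuple[int, int, int]]:
    """Maximal exact matches >= min_length between two strings.

    Returns (start_a, start_b, length) triples, 0-based. Seed-and-extend with
    k-mer anchors (k = min(min_length, 24)), deduplicated by diagonal.
    """
    k = min(min_length, 24)
    if len(a) < k or len(b) < k:
        return []
    anchors: dict[str, list[int]] = {}
    for i in range(len(a) - k + 1):
        anchors.setdefault(a[i : i + k], []).append(i)
    seen: set[tuple[int, int, int]] = set()
    out = []
    for j in range(len(b) - k + 1):
        kmer = b[j : j + k]
        for i in anchors.get(kmer, ()):  # extend the seed to a maximal match
            s_a, s_b = i, j
            while s_a > 0 and s_b > 0 and a[s_a - 1] == b[s_b - 1]:
                s_a -= 1
                s_b -= 1
            e_a, e_b = i + k, j + k
            while e_a < len(a) and e_b < len(b) and a[e_a] == b[e_b]:
                e_a += 1
                e_b += 1
            length = e_a - s_a
            key = (s_a, s_b, length)
            if length >= min_length and key not in seen:
                seen.add(key)
                out.append(key)
    return out


def flanking_repeats(
    genome: str,
    interval: tuple[int, int],
    min_length: int = 500,
    orientation: str = "direct",
    window: int | None = None,
) -> list[RepeatPair]:
    """Same-orientation exact repeats flanking an interval.

    Windows of ``window`` bp (default: the interval length) immediately
    upstream and downstream of the interval are scanned for maximal exact
    matches >= min_length. ``orientation`` is 'direct', 'inverted' or 'both'.
    """
    start, end = interval
    if start < 1 or end > len(genome) or end < start:
        raise ValueError("interval outside the genome")
    if orientation not in ("direct", "inverted", "both"):
        raise ValueError("orientation must be direct, inverted or both")
    w = window if window is not None else (end - start + 1)
    up_start = max(1, start - w)
    up = genome[up_start - 1 : start - 1]
    down = genome[end : min(len(genome), end + w)]
    pairs: list[RepeatPair] = []
    if orientation in ("direct", "both"):
        for s_a, s_b, length in _maximal_exact_matches(up, down, min_length):
            pairs.append(
                RepeatPair(
                    left=(up_start + s_a, up_start + s_a + length - 1),
                    right=(end + 1 + s_b, end + s_b + length),
                    length=length,
                    orientation="direct",
                )
            )
    if orientation in ("inverted", "both"):
        down_rc = revcomp(down)
        for s_a, s_b, length in _maximal_exact_matches(up, down_rc, min_length):
            r_end = end + len(down) - s_b
            pairs.append(
                RepeatPair(
                    left=(up_start + s_a, up_start + s_a + length - 1),
                    right=(r_end - length + 1, r_end),
                    length=length,
                    orientation="inverted",
                )
            )
    pairs.sort(key=lambda p: (-p.length, p.left))
    return pairs
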