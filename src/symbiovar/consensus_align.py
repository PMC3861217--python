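"""Reference-based consensus calling and alignment masking.

Per-strain consensus sequences are called from pileup columns under read-depth
bounds (default 10-100): positions outside the bounds become ``N``, positions
with a clear plurality base get that base, and near-ties get the two-base
IUPAC ambiguity code. Because every consensus has reference length, "merging"
consensus genomes into a multiple alignment is positional; columns containing
an ``N`` in any strain (fully ambiguous call or deletion relative to the
reference) are then removed, with a map back to reference coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seq import BASES, iupac_code

MIN_DEPTH_DEFAULT = 10
MAX_DEPTH_DEFAULT = 100
PLURALITY_DEFAULT = 0.8

_BASE_ORDER = "ACGTN"


@dataclass
class ConsensusGenome:
    strain_id: str
    sequence: str  # over {A,C,G,T,N, two-base IUPAC codes}; reference length


@dataclass
class MaskedAlignment:
    """Alignment columns surviving the N mask, with reference coordinates.

    ``column_map[k]`` is the 1-based reference position of alignment column k;
    it is strictly increasing. No retained column contains N in any strain.
    """

    strain_ids: list[str]
    columns: np.ndarray  # (n_strains, n_columns) array of single characters
    column_map: np.ndarray  # 1-based reference positions

    @property
    def n_columns(self) -> int:
        return self.columns.shape[1]

    def sequence(self, strain_id: str) -> str:
        i = self.strain_ids.index(strain_id)
        return "".join(self.columns[i])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.columns.T, columns=self.strain_ids)
        df.insert(0, "position", self.column_map)
        return df


def call_consensus_base(
    base_counts: dict[str, int] | pd.Series,
    min_depth: int = MIN_DEPTH_DEFAULT,
    max_depth: int = MAX_DEPTH_DEFAULT,
    plurality_fraction: float = PLURALITY_DEFAULT,
) -> str:
    """Depth-bounded plurality call for one pileup column.

    N when total depth is outside [min_depth, max_depth]; the plurality base
    when its fraction reaches ``plurality_fraction``; otherwise the IUPAC code
    of the two most frequent bases.
    """
    if min_depth > max_depth:
        raise ValueError("min_depth must be <= max_depth")
    if not 0.5 <= plurality_fraction <= 1.0:
        raise ValueError("plurality_fraction must be in [0.5, 1]")
    counts = {b: int(base_counts.get(b, 0)) for b in _BASE_ORDER}
    depth = sum(counts.values())
    if depth < min_depth or depth > max_depth:
        return "N"
    acgt = [(counts[b], b) for b in BASES]
    acgt.sort(key=lambda t: (-t[0], t[1]))
    top_n, top_b = acgt[0]
    if top_n == 0:  # covered only by N reads
        return "N"
    if top_n / depth >= plurality_fraction:
        return top_b
    second_b = acgt[1][1]
    return iupac_code((top_b, second_b))


def build_consensus(
    pileup: pd.DataFrame,
    reference_length: int,
    strain_id: str = "strain",
    min_depth: int = MIN_DEPTH_DEFAULT,
    max_depth: int = MAX_DEPTH_DEFAULT,
    plurality_fraction: float = PLURALITY_DEFAULT,
) -> ConsensusGenome:
    """Vectorized consensus over a pileup table (columns pos, A, C, G, T, N).

    Positions absent from the pileup are N. Duplicate positions are an error.
    """
    if min_depth > max_depth:
        raise ValueError("min_depth must be <= max_depth")
    if not 0.5 <= plurality_fraction <= 1.0:
        raise ValueError("plurality_fraction must be in [0.5, 1]")
    seq = np.full(reference_length, "N", dtype="<U1")
    if len(pileup) == 0:
        return ConsensusGenome(strain_id, "".join(seq))
    pos = pileup["pos"].to_numpy(dtype=np.int64)
    if np.unique(pos).size != pos.size:
        raise ValueError("duplicate positions in pileup")
    if pos.min() < 1 or pos.max() > reference_length:
        raise ValueError("pileup positions outside the reference")

    counts = pileup[list(_BASE_ORDER)].to_numpy(dtype=np.int64)
    depth = counts.sum(axis=1)
    acgt = counts[:, :4]
    # ranked base indices; ties broken alphabetically via stable sort on (-count)
    order = np.argsort(-acgt, axis=1, kind="stable")
    top = order[:, 0]
    second = order[:, 1]
    top_n = np.take_along_axis(acgt, top[:, None], axis=1)[:, 0]

    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, top_n / np.maximum(depth, 1), 0.0)
    in_bounds = (depth >= min_depth) & (depth <= max_depth) & (top_n > 0)
    plural = in_bounds & (frac >= plurality_fraction)
    ambig = in_bounds & ~plural

    base_arr = np.array(list(BASES))
    calls = np.full(len(pileup), "N", dtype="<U1")
    calls[plural] = base_arr[top[plural]]
    for i in np.flatnonzero(ambig):
        calls[i] = iupac_code((BASES[top[i]], BASES[second[i]]))
    seq[pos - 1] = calls
    return ConsensusGenome(strain_id, "".join(seq))


def mask_ambiguous_columns(genomes: list[ConsensusGenome]) -> MaskedAlignment:
    """Drop every alignment column holding an N in at least one strain.

    Non-N IUPAC ambiguity codes are retained. Idempotent and invariant to the
    order of strains (up to row order).
    """
    if not genomes:
        raise ValueError("no genomes given")
    lengths = {len(g.sequence) for g in genomes}
    if len(lengths) != 1:
        raise ValueError("consensus genomes differ in length")
    mat = np.array([list(g.sequence) for g in genomes], dtype="<U1")
    keep = ~(mat == "N").any(axis=0)
    column_map = np.flatnonzero(keep) + 1  # 1-based reference positions
    return MaskedAlignment(
        strain_ids=[g.strain_id for g in genomes],
        columns=mat[:, keep],
        column_map=column_map,
    )
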