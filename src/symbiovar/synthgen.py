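"""Synthetic data generator for the endosymbiont clade-comparison pipeline.

Emulates the statistical structure the downstream analyses assume: two clades
of near-identical reference-based genome assemblies separated by planted fixed
differences, a strain carrying a tandem-amplified cassette flanked by identical
direct repeats, Poisson read depth proportional to copy number, qPCR cycle
thresholds under an amplification-efficiency model, clustered survival times
under proportional hazards, and titre time courses under linear or exponential
growth. Every planted event is recorded in a ``Truth`` sidecar so downstream
stages can be scored against it.

Genomes are reference-based and length-preserving: substitutions and IUPAC
ambiguities replace single bases, deletions are marked ``-`` (zero read depth,
hence ``N`` in any consensus). Insertions are not modelled.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .seq import BASES, GeneFeature, iupac_code, revcomp, write_fasta, write_gff3

BACTERIAL_TABLE = 11


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass
class QpcrConfig:
    """Ct-generation parameters: per-gene efficiency in (1, 2], cycle noise."""

    efficiency: float = 2.0
    ct_noise_sd: float = 0.2
    n_techreps: int = 3
    baseline_ct: float = 25.0

    def __post_init__(self) -> None:
        if not 1.0 < self.efficiency <= 2.0:
            raise ValueError("amplification efficiency must be in (1, 2]")


@dataclass
class SurvivalConfig:
    baseline_hazard: float = 0.05  # deaths per fly-day
    group_lnhr: dict[str, float] = field(default_factory=dict)
    n_vials: int = 10
    flies_per_vial: int = 10
    n_experiments: int = 1
    frailty_sd: float = 0.0  # sd of log-normal vial frailty; 0 = pure fixed effects
    horizon: int = 60  # censoring horizon, days

    def __post_init__(self) -> None:
        if self.baseline_hazard < 0:
            raise ValueError("baseline hazard must be non-negative")
        if self.flies_per_vial < 1:
            raise ValueError("flies_per_vial must be >= 1")


@dataclass
class GrowthConfig:
    model: str = "linear"  # 'linear' or 'exponential'
    params: dict[str, tuple[float, float]] = field(default_factory=dict)  # strain -> (a, b)
    noise_sd: float = 0.1
    timepoints: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0)
    n_replicates: int = 5

    def __post_init__(self) -> None:
        if self.model not in ("linear", "exponential"):
            raise ValueError("growth model must be 'linear' or 'exponential'")


@dataclass
class SimConfig:
    """All knobs of the generator; a fixed seed makes outputs byte-identical."""

    seed: int = 0
    genome_length: int = 100_000
    n_genes: int = 40
    # amplified cassette: interval, gene content, flanking direct repeats
    cassette_start: int = 60_000
    cassette_span: int = 21_000
    cassette_n_genes: int = 8
    cassette_repeat_length: int = 1912
    cassette_copy_number: int = 7
    clade_sizes: tuple[int, int] = (4, 5)
    clade_a_names: tuple[str, ...] | None = None
    clade_b_names: tuple[str, ...] | None = None
    n_fixed_diffs: int = 108
    # optional (n_nonsynonymous, n_synonymous, n_intergenic) split of fixed diffs
    fixed_diff_composition: tuple[int, int, int] | None = None
    private_snp_rate: float = 0.0
    ambiguous_rate: float = 0.0
    n_indels: int = 7
    max_indel_length: int = 30
    # exact planted counts for the cassette-carrier strain (wMelPop analogue)
    carrier_unique_snps: int = 0
    carrier_ambiguous_sites: int = 0
    coverage_lambda: float = 30.0
    bin_width: int = 200
    error_rate: float = 0.0
    circular: bool = False
    qpcr: QpcrConfig = field(default_factory=QpcrConfig)
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    growth: GrowthConfig = field(default_factory=GrowthConfig)

    def __post_init__(self) -> None:
        if self.cassette_copy_number < 1:
            raise ValueError("cassette copy number must be >= 1")
        span_with_repeats = self.cassette_span + 2 * self.cassette_repeat_length
        if (
            self.cassette_start - self.cassette_repeat_length < 1
            or self.cassette_start + self.cassette_span + self.cassette_repeat_length - 1
            > self.genome_length
        ):
            raise ValueError("cassette plus flanking repeats must fit inside the genome")
        if span_with_repeats * 2 > self.genome_length:
            raise ValueError("genome too small relative to the cassette")
        for rate in (self.private_snp_rate, self.ambiguous_rate):
            if not 0 <= rate < 1:
                raise ValueError("per-bp event rates must be in [0, 1)")
        if sum(self.clade_sizes) < 2:
            raise ValueError("need at least two strains")
        if self.fixed_diff_composition is not None and sum(
            self.fixed_diff_composition
        ) != self.n_fixed_diffs:
            raise ValueError("fixed_diff_composition must sum to n_fixed_diffs")

    @property
    def strain_names(self) -> list[str]:
        n_a, n_b = self.clade_sizes
        a = list(self.clade_a_names or (f"A{i + 1}" for i in range(n_a)))
        b = list(self.clade_b_names or (f"B{i + 1}" for i in range(n_b)))
        if len(a) != n_a or len(b) != n_b:
            raise ValueError("clade name lists must match clade_sizes")
        return a + b

    @property
    def clade_a(self) -> list[str]:
        return self.strain_names[: self.clade_sizes[0]]

    @property
    def clade_b(self) -> list[str]:
        return self.strain_names[self.clade_sizes[0] :]

    @property
    def cassette_carrier(self) -> str:
        # the over-replicating strain sits in clade B, like wMelPop in the CS clade
        return self.clade_b[-1]

    @property
    def cassette_interval(self) -> tuple[int, int]:
        return self.cassette_start, self.cassette_start + self.cassette_span - 1

    @property
    def repeat_intervals(self) -> tuple[tuple[int, int], tuple[int, int]]:
        s, e = self.cassette_interval
        rl = self.cassette_repeat_length
        return (s - rl, s - 1), (e + 1, e + rl)


# --------------------------------------------------------------------------
# truth sidecar
# --------------------------------------------------------------------------


@dataclass
class Truth:
    """Planted events behind one synthetic dataset, serializable to JSON."""

    fixed_diffs: list[dict] = field(default_factory=list)
    private_snps: dict[str, list[dict]] = field(default_factory=dict)
    ambiguous_sites: dict[str, list[dict]] = field(default_factory=dict)
    indels: dict[str, list[dict]] = field(default_factory=dict)
    cassette: dict = field(default_factory=dict)
    qpcr_quantities: dict = field(default_factory=dict)
    survival_lnhr: dict[str, float] = field(default_factory=dict)
    growth: dict = field(default_factory=dict)

    def fixed_positions(self) -> list[int]:
        return sorted(d["position"] for d in self.fixed_diffs)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "Truth":
        return cls(**json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------
# reference genome and annotation
# --------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)


def _to_str(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def _place_genes(
    rng: np.random.Generator, intervals: list[tuple[int, int]], lengths: list[int]
) -> list[tuple[int, int]]:
    """Place non-overlapping genes of the given lengths inside free intervals.

    Greedy round-robin fill with random gaps; raises if packing is infeasible.
    """
    placements: list[tuple[int, int]] = []
    capacity = [e - s + 1 for s, e in intervals]
    if sum(lengths) + len(lengths) > sum(capacity):
        raise ValueError("infeasible gene packing: genes do not fit in the genome")
    # assign genes to intervals greedily, largest remaining capacity first
    cursors = [s for s, _ in intervals]
    order = sorted(range(len(lengths)), key=lambda i: -lengths[i])
    for gi in order:
        length = lengths[gi]
        placed = False
        for k in np.argsort([-(intervals[j][1] - cursors[j]) for j in range(len(intervals))]):
            start_min = cursors[k]
            start_max = intervals[k][1] - length + 1
            if start_max >= start_min:
                slack = start_max - start_min
                start = start_min + int(rng.integers(0, min(slack, 200) + 1))
                placements.append((start, start + length - 1))
                cursors[k] = start + length + 1  # keep >=1 bp intergenic gap
                placed = True
                break
        if not placed:
            raise ValueError("infeasible gene packing: genes do not fit in the genome")
    return sorted(placements)


def make_reference(config: SimConfig) -> tuple[str, list[GeneFeature]]:
    """Reference genome plus annotation.

    The cassette interval is flanked by two identical, same-orientation direct
    repeats; ``cassette_n_genes`` CDS features sit inside the cassette, the rest
    in the remainder of the genome on either strand.
    """
    rng = np.random.default_rng(config.seed)
    codes = _random_seq(rng, config.genome_length)
    (r1s, r1e), (r2s, r2e) = config.repeat_intervals
    repeat = _random_seq(rng, config.cassette_repeat_length)
    codes[r1s - 1 : r1e] = repeat
    codes[r2s - 1 : r2e] = repeat

    cs, ce = config.cassette_interval
    n_outside = config.n_genes - config.cassette_n_genes
    if n_outside < 0:
        raise ValueError("cassette_n_genes exceeds n_genes")
    gene_lengths = [int(x) * 3 for x in rng.integers(100, 301, size=config.n_genes)]
    inside = _place_genes(rng, [(cs, ce)], gene_lengths[: config.cassette_n_genes]) if config.cassette_n_genes else []
    free = [(1, r1s - 2), (r2e + 2, config.genome_length)]
    free = [(s, e) for s, e in free if e - s + 1 > 0]
    outside = _place_genes(rng, free, gene_lengths[config.cassette_n_genes :]) if n_outside else []

    features = []
    pseudo_picks = set(rng.choice(config.n_genes, size=max(1, config.n_genes // 20), replace=False)) if config.n_genes else set()
    for i, (s, e) in enumerate(sorted(inside + outside)):
        strand = "+" if rng.random() < 0.5 else "-"
        features.append(
            GeneFeature(
                gene_id=f"g{i + 1:04d}",
                start=s,
                end=e,
                strand=strand,
                feature_type="CDS",
                pseudo=i in pseudo_picks,
            )
        )
    return _to_str(codes), features


# --------------------------------------------------------------------------
# clade genomes with planted variation
# --------------------------------------------------------------------------


def _coding_context(reference: str, feature: GeneFeature, position: int) -> tuple[int, int, str]:
    """(codon_index, offset_in_codon, ref_codon) for a genome position in a CDS."""
    if feature.strand == "+":
        offset = position - feature.start
    else:
        offset = feature.end - position
    codon_idx = offset // 3
    within = offset % 3
    if feature.strand == "+":
        codon_start = feature.start + codon_idx * 3
        codon = reference[codon_start - 1 : codon_start + 2]
    else:
        codon_end = feature.end - codon_idx * 3
        codon = revcomp(reference[codon_end - 3 : codon_end])
    return codon_idx, within, codon


def _translate(codon: str) -> str:
    return str(Seq(codon).translate(table=BACTERIAL_TABLE))


def _pick_coding_substitution(
    rng: np.random.Generator,
    reference: str,
    features: list[GeneFeature],
    used: set[int],
    want_synonymous: bool,
    max_tries: int = 2000,
) -> tuple[int, str] | None:
    """A (position, genome-strand alt allele) whose coding effect matches the request."""
    cds = [f for f in features if f.feature_type == "CDS" and not f.pseudo]
    for _ in range(max_tries):
        f = cds[int(rng.integers(0, len(cds)))]
        pos = int(rng.integers(f.start, f.end + 1))
        if pos in used:
            continue
        _, within, codon = _coding_context(reference, f, pos)
        ref_aa = _translate(codon)
        coding_ref = codon[within]
        for alt_coding in rng.permutation([b for b in BASES if b != coding_ref]):
            mutated = codon[:within] + alt_coding + codon[within + 1 :]
            alt_aa = _translate(mutated)
            if (alt_aa == ref_aa) == want_synonymous:
                alt_genome = alt_coding if f.strand == "+" else revcomp(alt_coding)
                return pos, alt_genome
    return None


def make_clades(
    reference: str, features: list[GeneFeature], config: SimConfig
) -> tuple[dict[str, str], Truth]:
    """Per-strain genomes with planted fixed differences, private SNPs,
    ambiguous sites and deletions; the cassette carrier is flagged in Truth.

    Clade A carries the reference allele at every fixed-difference site (the
    reference genome comes from clade A, as AE017196 comes from the wMel
    clade); clade B carries the alternative allele.
    """
    rng = np.random.default_rng(config.seed + 1)
    length = config.genome_length
    (r1s, r1e), (r2s, r2e) = config.repeat_intervals
    in_repeat = np.zeros(length + 1, dtype=bool)
    in_repeat[r1s : r1e + 1] = True
    in_repeat[r2s : r2e + 1] = True  # keep flank repeats identical: no events inside

    in_cds = np.zeros(length + 1, dtype=bool)
    for f in features:
        in_cds[f.start : f.end + 1] = True

    used: set[int] = set()
    truth = Truth()

    def _free(mask: np.ndarray) -> np.ndarray:
        ok = mask.copy()
        ok[0] = False
        ok[list(used)] = False
        ok &= ~in_repeat
        return np.flatnonzero(ok)

    # --- fixed inter-clade differences
    fixed: list[tuple[int, str, str, str]] = []  # pos, ref allele, alt allele, category
    if config.fixed_diff_composition is not None:
        n_nonsyn, n_syn, n_inter = config.fixed_diff_composition
        for want_syn, n, label in ((False, n_nonsyn, "non-synonymous"), (True, n_syn, "synonymous")):
            for _ in range(n):
                pick = _pick_coding_substitution(rng, reference, features, used, want_syn)
                if pick is None:
                    raise ValueError("could not plant requested coding substitutions")
                pos, alt = pick
                used.add(pos)
                fixed.append((pos, reference[pos - 1], alt, label))
        candidates = _free(~in_cds)
        if len(candidates) < n_inter:
            raise ValueError("not enough intergenic sites for requested fixed differences")
        for pos in rng.choice(candidates, size=n_inter, replace=False):
            pos = int(pos)
            used.add(pos)
            ref_b = reference[pos - 1]
            alt = str(rng.choice([b for b in BASES if b != ref_b]))
            fixed.append((pos, ref_b, alt, "intergenic"))
    else:
        candidates = _free(np.ones(length + 1, dtype=bool))
        if len(candidates) < config.n_fixed_diffs:
            raise ValueError("n_fixed_diffs exceeds the number of eligible sites")
        for pos in rng.choice(candidates, size=config.n_fixed_diffs, replace=False):
            pos = int(pos)
            used.add(pos)
            ref_b = reference[pos - 1]
            alt = str(rng.choice([b for b in BASES if b != ref_b]))
            fixed.append((pos, ref_b, alt, "unclassified"))
    fixed.sort()
    truth.fixed_diffs = [
        {"position": p, "allele_a": ra, "allele_b": aa, "category": cat}
        for p, ra, aa, cat in fixed
    ]

    # --- per-strain genomes
    genomes: dict[str, list[str]] = {s: list(reference) for s in config.strain_names}
    for pos, _ra, alt, _cat in fixed:
        for s in config.clade_b:
            genomes[s][pos - 1] = alt

    expected_events = length * max(config.private_snp_rate, config.ambiguous_rate)
    if expected_events > 0.5 * length:
        raise ValueError("event rates imply more than one event per site")

    for strain in config.strain_names:
        truth.private_snps[strain] = []
        truth.ambiguous_sites[strain] = []
        truth.indels[strain] = []
        if config.private_snp_rate > 0:
            n = rng.binomial(length, config.private_snp_rate)
            candidates = _free(np.ones(length + 1, dtype=bool))
            for pos in rng.choice(candidates, size=min(n, len(candidates)), replace=False):
                pos = int(pos)
                used.add(pos)
                cur = genomes[strain][pos - 1]
                alt = str(rng.choice([b for b in BASES if b != cur]))
                genomes[strain][pos - 1] = alt
                truth.private_snps[strain].append({"position": pos, "allele": alt})
        if config.ambiguous_rate > 0:
            n = rng.binomial(length, config.ambiguous_rate)
            candidates = _free(np.ones(length + 1, dtype=bool))
            for pos in rng.choice(candidates, size=min(n, len(candidates)), replace=False):
                pos = int(pos)
                used.add(pos)
                cur = genomes[strain][pos - 1]
                other = str(rng.choice([b for b in BASES if b != cur]))
                code = iupac_code((cur, other))
                genomes[strain][pos - 1] = code
                truth.ambiguous_sites[strain].append({"position": pos, "code": code})

    # --- exact planted events in the cassette carrier (the wMelPop analogue)
    carrier = config.cassette_carrier
    candidates = _free(np.ones(length + 1, dtype=bool))
    picks = rng.choice(
        candidates, size=config.carrier_unique_snps + config.carrier_ambiguous_sites, replace=False
    )
    for i, pos in enumerate(picks):
        pos = int(pos)
        used.add(pos)
        cur = genomes[carrier][pos - 1]
        other = str(rng.choice([b for b in BASES if b != cur]))
        if i < config.carrier_unique_snps:
            genomes[carrier][pos - 1] = other
            truth.private_snps[carrier].append({"position": pos, "allele": other})
        else:
            code = iupac_code((cur, other))
            genomes[carrier][pos - 1] = code
            truth.ambiguous_sites[carrier].append({"position": pos, "code": code})

    # --- clade-fixed deletions (shared by all clade-B strains)
    for _ in range(config.n_indels):
        dlen = int(rng.integers(1, config.max_indel_length + 1))
        for _try in range(200):
            start = int(rng.integers(1, length - dlen + 1))
            span = range(start, start + dlen)
            if all(p not in used and not in_repeat[p] for p in span):
                break
        else:
            raise ValueError("could not place requested indels")
        used.update(span)
        for s in config.clade_b:
            for p in span:
                genomes[s][p - 1] = "-"
            truth.indels[s].append({"start": start, "end": start + dlen - 1, "type": "deletion"})

    cs, ce = config.cassette_interval
    cassette_genes = [f.gene_id for f in features if f.start >= cs and f.end <= ce]
    truth.cassette = {
        "carrier": carrier,
        "start": cs,
        "end": ce,
        "copy_number": config.cassette_copy_number,
        "repeat_intervals": [list(config.repeat_intervals[0]), list(config.repeat_intervals[1])],
        "genes": cassette_genes,
    }
    return {s: "".join(g) for s, g in genomes.items()}, truth


def make_tree(config: SimConfig) -> str:
    """Newick strain tree: two clades matching the planted grouping, ladderized."""

    def ladder(names: Sequence[str]) -> str:
        if len(names) == 1:
            return names[0]
        return f"({names[0]},{ladder(names[1:])})"

    return f"({ladder(config.clade_a)},{ladder(config.clade_b)});"


def copy_number_track(config: SimConfig, strain: str) -> np.ndarray:
    """Per-base true copy number (1.0 everywhere except the carrier's cassette)."""
    track = np.ones(config.genome_length)
    if strain == config.cassette_carrier:
        cs, ce = config.cassette_interval
        track[cs - 1 : ce] = config.cassette_copy_number
    return track


# --------------------------------------------------------------------------
# pileups and binned depth
# --------------------------------------------------------------------------


def simulate_pileup(
    genome: str,
    coverage_lambda: float,
    rng: np.random.Generator,
    error_rate: float = 0.0,
) -> pd.DataFrame:
    """Per-position depth and base counts.

    Depth ~ Poisson(coverage_lambda); deleted positions (``-``) get zero depth.
    Reads carry the strain's true base; at an IUPAC-ambiguous position reads
    split 50/50 between the two underlying bases. An optional uniform
    substitution error rate redistributes reads to the other three bases.
    """
    if coverage_lambda <= 0:
        raise ValueError("coverage_lambda must be positive")
    length = len(genome)
    depth = rng.poisson(coverage_lambda, size=length)
    arr = np.frombuffer(genome.encode(), dtype="S1")
    depth[arr == b"-"] = 0

    counts = np.zeros((length, 5), dtype=np.int64)  # A C G T N
    col = {b: i for i, b in enumerate("ACGTN")}
    for base in "ACGT":
        mask = arr == base.encode()
        counts[mask, col[base]] = depth[mask]
    from .seq import IUPAC2_INV

    for code, pair in IUPAC2_INV.items():
        mask = arr == code.encode()
        if mask.any():
            idx = np.flatnonzero(mask)
            b1, b2 = sorted(pair)
            n1 = rng.binomial(depth[idx], 0.5)
            counts[idx, col[b1]] = n1
            counts[idx, col[b2]] = depth[idx] - n1
    mask_n = arr == b"N"
    counts[mask_n, col["N"]] = depth[mask_n]

    if error_rate > 0:
        for b in "ACGT":
            src = col[b]
            here = counts[:, src].copy()
            n_err = rng.binomial(here, error_rate)
            counts[:, src] -= n_err
            others = [col[x] for x in "ACGT" if x != b]
            alloc = np.zeros((length, 3), dtype=np.int64)
            nonzero = np.flatnonzero(n_err)
            for i in nonzero:
                alloc[i] = rng.multinomial(n_err[i], [1 / 3] * 3)
            for j, dst in enumerate(others):
                counts[:, dst] += alloc[:, j]

    out = pd.DataFrame(counts, columns=list("ACGTN"))
    out.insert(0, "depth", depth)
    out.insert(0, "pos", np.arange(1, length + 1))
    return out


@dataclass
class DepthProfile:
    """Binned read counts over consecutive non-overlapping windows."""

    strain_id: str
    bin_width: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        if (self.counts < 0).any():
            raise ValueError("bin counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def bin_interval(self, i: int) -> tuple[int, int]:
        """1-based inclusive genome coordinates of bin i (0-based index)."""
        return i * self.bin_width + 1, (i + 1) * self.bin_width


def simulate_depth_bins(
    cn_track: np.ndarray,
    coverage_lambda: float,
    bin_width: int,
    rng: np.random.Generator,
    strain_id: str = "strain",
) -> DepthProfile:
    """Bin counts ~ Poisson(copy_number x coverage_lambda x bin_width)."""
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    n_bins = max(1, len(cn_track) // bin_width) if bin_width >= len(cn_track) else len(cn_track) // bin_width
    if bin_width >= len(cn_track):
        lam = coverage_lambda * cn_track.sum()
        return DepthProfile(strain_id, bin_width, rng.poisson(lam, size=1))
    trimmed = cn_track[: n_bins * bin_width].reshape(n_bins, bin_width)
    lam = coverage_lambda * trimmed.sum(axis=1)
    return DepthProfile(strain_id, bin_width, rng.poisson(lam))


# --------------------------------------------------------------------------
# qPCR, survival, growth
# --------------------------------------------------------------------------


def simulate_ct(
    quantities: pd.DataFrame,
    efficiencies: Mapping[str, float] | float,
    ct_noise_sd: float,
    n_techreps: int,
    rng: np.random.Generator,
    baseline_ct: Mapping[str, float] | float = 25.0,
) -> pd.DataFrame:
    """Invert the efficiency model: Ct = c0_gene - log_E(quantity) + noise.

    ``quantities`` columns: sample, replicate, gene, quantity. Non-positive
    quantities become below-detection wells (ct = NaN, below_detection = True).
    """
    rows = []
    for rec in quantities.itertuples(index=False):
        eff = efficiencies[rec.gene] if isinstance(efficiencies, Mapping) else efficiencies
        if not 1.0 < eff <= 2.0:
            raise ValueError(f"efficiency for {rec.gene} must be in (1, 2]")
        c0 = baseline_ct[rec.gene] if isinstance(baseline_ct, Mapping) else baseline_ct
        for tr in range(1, n_techreps + 1):
            if rec.quantity <= 0:
                ct, nd = np.nan, True
            else:
                ct = c0 - np.log(rec.quantity) / np.log(eff) + rng.normal(0.0, ct_noise_sd)
                nd = False
            rows.append(
                {
                    "sample": rec.sample,
                    "replicate": rec.replicate,
                    "gene": rec.gene,
                    "techrep": tr,
                    "ct": ct,
                    "below_detection": nd,
                }
            )
    return pd.DataFrame(rows)


def simulate_survival(
    config: SurvivalConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Exponential event times under proportional hazards with vial structure.

    hazard = baseline x exp(lnHR_line + vial frailty); observation at daily
    resolution (time = ceil of the event time), censored at the horizon.
    Columns: line, vial, experiment, day, event (1 = died, 0 = censored).
    """
    if config.baseline_hazard < 0:
        raise ValueError("baseline hazard must be non-negative")
    rows = []
    for line, lnhr in config.group_lnhr.items():
        for exp_id in range(1, config.n_experiments + 1):
            for v in range(1, config.n_vials + 1):
                frailty = rng.normal(0.0, config.frailty_sd) if config.frailty_sd > 0 else 0.0
                rate = config.baseline_hazard * np.exp(lnhr + frailty)
                vial_id = f"{line}.e{exp_id}.v{v}"
                for _ in range(config.flies_per_vial):
                    if rate <= 0:
                        day, event = config.horizon, 0
                    else:
                        t = rng.exponential(1.0 / rate)
                        day = int(np.ceil(t))  # daily checks; >= 1
                        event = 1 if day <= config.horizon else 0
                        if not event:
                            day = config.horizon
                    rows.append(
                        {
                            "line": line,
                            "vial": vial_id,
                            "experiment": exp_id,
                            "day": day,
                            "event": event,
                        }
                    )
    return pd.DataFrame(rows)


def simulate_growth(config: GrowthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Titre time courses: a + b*t + e (linear) or exp(a + b*t + e) (exponential)."""
    rows = []
    for strain, (a, b) in config.params.items():
        for t in config.timepoints:
            for _ in range(config.n_replicates):
                eps = rng.normal(0.0, config.noise_sd)
                if config.model == "linear":
                    titre = a + b * t + eps
                else:
                    titre = float(np.exp(a + b * t + eps))
                rows.append({"strain": strain, "day": float(t), "titre": titre})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# whole-dataset driver
# --------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    config: SimConfig
    reference: str
    features: list[GeneFeature]
    genomes: dict[str, str]
    truth: Truth
    tree_newick: str
    pileups: dict[str, pd.DataFrame]
    depth_profiles: dict[str, DepthProfile]

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(out / "reference.fasta", {"reference": self.reference})
        write_gff3(out / "annotation.gff3", self.features, seqid="reference")
        write_fasta(out / "strains.fasta", {s: g.replace("-", "N") for s, g in self.genomes.items()})
        (out / "tree.nwk").write_text(self.tree_newick + "\n")
        self.truth.to_json(out / "truth.json")
        pdir = out / "pileups"
        pdir.mkdir(exist_ok=True)
        for strain, df in self.pileups.items():
            df.to_csv(pdir / f"{strain}.pileup.tsv", sep="\t", index=False)
        bins = pd.DataFrame({s: p.counts for s, p in self.depth_profiles.items()})
        bins.insert(0, "bin", np.arange(len(bins)))
        bins.to_csv(out / "depth_bins.tsv", sep="\t", index=False)


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Run the full generator under one seed; all stages draw from one stream."""
    reference, features = make_reference(config)
    genomes, truth = make_clades(reference, features, config)
    rng = np.random.default_rng(config.seed + 2)
    pileups = {
        s: simulate_pileup(genomes[s], config.coverage_lambda, rng, config.error_rate)
        for s in config.strain_names
    }
    profiles = {
        s: simulate_depth_bins(
            copy_number_track(config, s), config.coverage_lambda, config.bin_width, rng, s
        )
        for s in config.strain_names
    }
    return SyntheticDataset(
        config=config,
        reference=reference,
        features=features,
        genomes=genomes,
        truth=truth,
        tree_newick=make_tree(config),
        pileups=pileups,
        depth_profiles=profiles,
    )
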