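"""Clade-discriminating variants and their coding effects.

From a masked multiple alignment this module extracts polymorphic sites,
identifies fixed differences between two named clades (sites where all members
of one clade share one allele and all members of the other clade a different
one), maps sites onto a CDS annotation, and classifies coding consequences
under the bacterial genetic code (translation table 11).

Ambiguity policy: under the default ``shared-ambiguous-allowed`` policy a
common IUPAC ambiguity code within one clade counts as that clade's allele and
flags the site; ``strict`` restricts group alleles to A/C/G/T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .consensus_align import MaskedAlignment
from .seq import BASES, GeneFeature, is_ambiguous, revcomp

BACTERIAL_TABLE = 11

EFFECT_CLASSES = (
    "synonymous",
    "non-synonymous",
    "nonsense",
    "stop-loss",
    "intergenic",
    "ambiguous",
)


@dataclass(frozen=True)
class FixedDifference:
    position: int  # 1-based reference coordinate
    allele_a: str
    allele_b: str
    ambiguity_flag: bool  # a clade's shared call is an IUPAC ambiguity code


@dataclass(frozen=True)
class EffectCall:
    gene_id: str
    strand: str
    codon_index: int  # 0-based codon within the CDS
    aa_position: int  # 1-based amino-acid position
    ref_aa: str
    alt_aa: str
    effect_class: str


# --------------------------------------------------------------------------
# variant extraction
# --------------------------------------------------------------------------


def extract_variants(alignment: MaskedAlignment, reference: str) -> pd.DataFrame:
    """Columns with >= 2 distinct alleles across strains plus the reference.

    Returns a frame with ``position`` (1-based reference coordinate), ``ref``
    and one allele column per strain; positions strictly increasing.
    """
    ref_arr = np.array(list(reference), dtype="<U1")[alignment.column_map - 1]
    stacked = np.vstack([ref_arr, alignment.columns])
    poly = np.array([len(set(stacked[:, j])) > 1 for j in range(stacked.shape[1])])
    df = pd.DataFrame(
        alignment.columns[:, poly].T, columns=alignment.strain_ids
    )
    df.insert(0, "ref", ref_arr[poly])
    df.insert(0, "position", alignment.column_map[poly])
    return df


def fixed_differences(
    table: pd.DataFrame,
    clade_a: list[str],
    clade_b: list[str],
    ambiguity_policy: str = "shared-ambiguous-allowed",
) -> list[FixedDifference]:
    """Sites at which the two clades carry different, within-clade-shared alleles."""
    if ambiguity_policy not in ("shared-ambiguous-allowed", "strict"):
        raise ValueError(f"unknown ambiguity policy {ambiguity_policy!r}")
    set_a, set_b = set(clade_a), set(clade_b)
    if not set_a or not set_b:
        raise ValueError("clades must be non-empty")
    if set_a & set_b:
        raise ValueError("clades overlap")
    missing = (set_a | set_b) - set(table.columns)
    if missing:
        raise ValueError(f"strains not in the variant table: {sorted(missing)}")

    out: list[FixedDifference] = []
    a_cols = table[clade_a].to_numpy(dtype="<U1")
    b_cols = table[clade_b].to_numpy(dtype="<U1")
    positions = table["position"].to_numpy()
    for i in range(len(table)):
        alleles_a = set(a_cols[i])
        alleles_b = set(b_cols[i])
        if len(alleles_a) != 1 or len(alleles_b) != 1:
            continue
        a, b = next(iter(alleles_a)), next(iter(alleles_b))
        if a == b:
            continue
        flag = is_ambiguous(a) or is_ambiguous(b)
        if flag and ambiguity_policy == "strict":
            continue
        out.append(FixedDifference(int(positions[i]), a, b, flag))
    return out


def strain_unique_variants(
    table: pd.DataFrame, strain: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sites where the focal strain differs from all other (agreeing) strains.

    Returns (unambiguous, ambiguous): rows where the focal allele is a plain
    base are ``unambiguous``; rows where it is an IUPAC code are listed
    separately, mirroring how ambiguous calls are reported apart.
    """
    strains = [c for c in table.columns if c not in ("position", "ref")]
    if len(strains) < 3:
        raise ValueError("need at least three strains")
    if strain not in strains:
        raise ValueError(f"strain {strain!r} not in table")
    others = [s for s in strains if s != strain]
    focal = table[strain].to_numpy(dtype="<U1")
    rest = table[others].to_numpy(dtype="<U1")
    rest_uniform = np.array([len(set(rest[i])) == 1 for i in range(len(table))])
    differs = np.array([focal[i] not in set(rest[i]) for i in range(len(table))])
    hit = rest_uniform & differs
    focal_ambig = np.array([is_ambiguous(a) for a in focal])
    unamb = table[hit & ~focal_ambig].reset_index(drop=True)
    amb = table[hit & focal_ambig].reset_index(drop=True)
    return unamb, amb


# --------------------------------------------------------------------------
# annotation mapping and effect classification
# --------------------------------------------------------------------------


def annotate_sites(
    positions: list[int], features: list[GeneFeature]
) -> pd.DataFrame:
    """Partition sites into genic and intergenic (1-based inclusive intervals).

    A site overlapping several features yields one row per feature.
    """
    rows = []
    for pos in positions:
        hits = [f for f in features if f.contains(pos)]
        if not hits:
            rows.append({"position": pos, "gene_id": None, "genic": False, "pseudo": False})
        for f in hits:
            rows.append(
                {"position": pos, "gene_id": f.gene_id, "genic": True, "pseudo": f.pseudo}
            )
    return pd.DataFrame(rows, columns=["position", "gene_id", "genic", "pseudo"])


def classify_effect(
    position: int,
    ref_allele: str,
    alt_allele: str,
    feature: GeneFeature,
    reference: str,
) -> EffectCall:
    """Coding consequence of substituting ``alt_allele`` at ``position``.

    The allele is placed into its codon (reverse-complemented for minus-strand
    genes) and translated with the bacterial genetic code. A CDS whose length
    is not a multiple of 3 is classified up to the last full codon.
    """
    if not feature.contains(position):
        raise ValueError("site outside the feature")
    if is_ambiguous(alt_allele) or is_ambiguous(ref_allele):
        return EffectCall(feature.gene_id, feature.strand, -1, -1, "?", "?", "ambiguous")

    if feature.strand == "+":
        offset = position - feature.start
    else:
        offset = feature.end - position
    codon_idx = offset // 3
    within = offset % 3
    n_full_codons = feature.length // 3
    if codon_idx >= n_full_codons:
        # trailing partial codon of a CDS not divisible by 3
        import warnings

        warnings.warn(
            f"CDS {feature.gene_id} length {feature.length} not divisible by 3; "
            "site falls in the trailing partial codon",
            stacklevel=2,
        )
        return EffectCall(feature.gene_id, feature.strand, codon_idx, codon_idx + 1, "?", "?", "ambiguous")

    if feature.strand == "+":
        codon_start = feature.start + codon_idx * 3
        codon = reference[codon_start - 1 : codon_start + 2]
        coding_ref = ref_allele
        coding_alt = alt_allele
    else:
        codon_end = feature.end - codon_idx * 3
        codon = revcomp(reference[codon_end - 3 : codon_end])
        coding_ref = revcomp(ref_allele)
        coding_alt = revcomp(alt_allele)
    if codon[within] != coding_ref:
        raise ValueError(
            f"reference allele {ref_allele} does not match the reference codon at {position}"
        )
    mutated = codon[:within] + coding_alt + codon[within + 1 :]
    ref_aa = str(Seq(codon).translate(table=BACTERIAL_TABLE))
    alt_aa = str(Seq(mutated).translate(table=BACTERIAL_TABLE))
    if ref_aa == alt_aa:
        klass = "synonymous"
    elif alt_aa == "*":
        klass = "nonsense"
    elif ref_aa == "*":
        klass = "stop-loss"
    else:
        klass = "non-synonymous"
    return EffectCall(
        gene_id=feature.gene_id,
        strand=feature.strand,
        codon_index=codon_idx,
        aa_position=codon_idx + 1,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        effect_class=klass,
    )


def classify_fixed_differences(
    diffs: list[FixedDifference],
    features: list[GeneFeature],
    reference: str,
    include_pseudogenes: bool = False,
) -> pd.DataFrame:
    """One row per (fixed difference, overlapping CDS); intergenic sites get
    gene_id None and class 'intergenic'. Pseudogenes count as genic for the
    mapping but are excluded from effect classification unless requested.
    """
    rows = []
    for d in diffs:
        hits = [f for f in features if f.contains(d.position)]
        if not hits:
            rows.append(
                {
                    "position": d.position,
                    "allele_a": d.allele_a,
                    "allele_b": d.allele_b,
                    "ambiguity_flag": d.ambiguity_flag,
                    "gene_id": None,
                    "pseudo": False,
                    "aa_position": None,
                    "ref_aa": None,
                    "alt_aa": None,
                    "effect_class": "intergenic",
                }
            )
            continue
        for f in hits:
            if f.pseudo and not include_pseudogenes:
                effect = None
            else:
                effect = classify_effect(d.position, d.allele_a, d.allele_b, f, reference)
            rows.append(
                {
                    "position": d.position,
                    "allele_a": d.allele_a,
                    "allele_b": d.allele_b,
                    "ambiguity_flag": d.ambiguity_flag,
                    "gene_id": f.gene_id,
                    "pseudo": f.pseudo,
                    "aa_position": effect.aa_position if effect else None,
                    "ref_aa": effect.ref_aa if effect else None,
                    "alt_aa": effect.alt_aa if effect else None,
                    "effect_class": effect.effect_class if effect else "pseudogene",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "position",
            "allele_a",
            "allele_b",
            "ambiguity_flag",
            "gene_id",
            "pseudo",
            "aa_position",
            "ref_aa",
            "alt_aa",
            "effect_class",
        ],
    )


def summarize_differences(effects: pd.DataFrame, n_indels: int = 0) -> dict:
    """Bookkeeping counts over a classified fixed-difference table.

    total / genic / non-synonymous SNP counts, distinct genes hit by
    non-synonymous changes, and the indel count passed through.
    """
    if len(effects) == 0:
        return {
            "total_snps": 0,
            "genic_snps": 0,
            "intergenic_snps": 0,
            "non_synonymous": 0,
            "genes_with_nonsyn": 0,
            "indels": n_indels,
        }
    per_site = effects.groupby("position")
    genic = per_site["gene_id"].apply(lambda g: g.notna().any())
    nonsyn = effects[effects["effect_class"].isin(["non-synonymous", "nonsense", "stop-loss"])]
    return {
        "total_snps": int(effects["position"].nunique()),
        "genic_snps": int(genic.sum()),
        "intergenic_snps": int((~genic).sum()),
        "non_synonymous": int(nonsyn["position"].nunique()),
        "genes_with_nonsyn": int(nonsyn["gene_id"].nunique()),
        "indels": n_indels,
    }
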