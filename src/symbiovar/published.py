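"""Access to bundled published tables.

The package ships the published table of non-synonymous SNPs fixed between the
wMel-like and wMelCS-like *Wolbachia* clades (coordinates on the AE017196
reference). Counting its rows and distinct genes is the bookkeeping check the
summary stage reproduces.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_nonsyn_clade_snps() -> pd.DataFrame:
    """The published non-synonymous clade-discriminating SNP table."""
    path = resources.files("symbiovar.data").joinpath("nonsyn_clade_snps.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", comment="#", dtype={"aa_pos": "Int64"})
    return df


def nonsyn_bookkeeping() -> dict[str, int]:
    """Row and distinct-gene counts of the published non-synonymous SNP set."""
    df = load_nonsyn_clade_snps()
    return {
        "non_synonymous_snps": int(len(df)),
        "distinct_genes": int(df["gene"].nunique()),
    }
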