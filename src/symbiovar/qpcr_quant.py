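"""Efficiency-corrected relative quantification of qPCR panels.

Technical replicates are averaged on the Ct scale with a QC flag for noisy
wells; relative quantities use the efficiency-corrected ratio

    ratio = E_target^(Ct_target,calibrator - Ct_target,sample)
          / E_ref^(Ct_ref,calibrator - Ct_ref,sample)

which reduces to 2^-ddCt when both efficiencies are 2. Below-detection wells
propagate a censored marker; they are never silently imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

CENSORED = "below_detection"


@dataclass
class CtSummary:
    sample: str
    replicate: object
    gene: str
    mean_ct: float  # NaN when censored
    sd_ct: float
    n: int
    censored: bool
    flagged: bool


def summarize_ct(panel: pd.DataFrame, max_sd: float = 0.5) -> pd.DataFrame:
    """Mean Ct per (sample, replicate, gene) well group with QC flags.

    A group is flagged when the replicate SD exceeds ``max_sd`` cycles or any
    replicate is below detection; a group with every replicate below detection
    has a censored (NaN) mean.
    """
    required = {"sample", "replicate", "gene", "ct"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"panel missing columns: {sorted(missing)}")
    nd = panel["below_detection"] if "below_detection" in panel else panel["ct"].isna()
    work = panel.assign(_nd=nd.astype(bool))
    rows = []
    for (sample, rep, gene), grp in work.groupby(["sample", "replicate", "gene"], sort=False):
        vals = grp.loc[~grp["_nd"], "ct"].to_numpy(dtype=float)
        censored = len(vals) == 0
        any_nd = bool(grp["_nd"].any())
        mean = float(np.mean(vals)) if not censored else float("nan")
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rows.append(
            {
                "sample": sample,
                "replicate": rep,
                "gene": gene,
                "mean_ct": mean,
                "sd_ct": sd,
                "n": len(vals),
                "censored": censored,
                "flagged": bool(any_nd or sd > max_sd),
            }
        )
    return pd.DataFrame(rows)


def pfaffl_ratio(
    ct_target_sample: float,
    ct_target_calibrator: float,
    ct_ref_sample: float,
    ct_ref_calibrator: float,
    e_target: float = 2.0,
    e_ref: float = 2.0,
) -> float | str:
    """Efficiency-corrected relative quantity of the sample vs the calibrator.

    Any censored (NaN) Ct yields the string marker ``'below_detection'``.
    """
    for e in (e_target, e_ref):
        if not 1.0 < e <= 2.0:
            raise ValueError("amplification efficiencies must be in (1, 2]")
    cts = (ct_target_sample, ct_target_calibrator, ct_ref_sample, ct_ref_calibrator)
    if any(c is None or (isinstance(c, float) and math.isnan(c)) for c in cts):
        return CENSORED
    return (
        e_target ** (ct_target_calibrator - ct_target_sample)
        / e_ref ** (ct_ref_calibrator - ct_ref_sample)
    )


def relative_quantities(
    panel: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    calibrator_sample: str,
    efficiencies: dict[str, float] | None = None,
    max_sd: float = 0.5,
) -> pd.DataFrame:
    """Per-biological-replicate relative quantity of one target gene.

    Calibrator Ct values are the medians over the calibrator sample's
    biological replicates (on the Ct scale).
    """
    eff = efficiencies or {}
    e_t = eff.get(target_gene, 2.0)
    e_r = eff.get(reference_gene, 2.0)
    summary = summarize_ct(panel, max_sd=max_sd)
    if calibrator_sample not in set(summary["sample"]):
        raise ValueError(f"calibrator sample {calibrator_sample!r} absent from panel")

    def _mean_ct(sample: str, gene: str) -> pd.DataFrame:
        return summary[(summary["sample"] == sample) & (summary["gene"] == gene)]

    cal_t = _mean_ct(calibrator_sample, target_gene)["mean_ct"].median()
    cal_r = _mean_ct(calibrator_sample, reference_gene)["mean_ct"].median()
    rows = []
    for sample in summary["sample"].unique():
        t = _mean_ct(sample, target_gene).set_index("replicate")["mean_ct"]
        r = _mean_ct(sample, reference_gene).set_index("replicate")["mean_ct"]
        for rep in t.index:
            if rep not in r.index:
                raise ValueError(
                    f"reference gene {reference_gene!r} missing for {sample}/{rep}"
                )
            ratio = pfaffl_ratio(t[rep], cal_t, r[rep], cal_r, e_t, e_r)
            rows.append(
                {
                    "sample": sample,
                    "replicate": rep,
                    "target": target_gene,
                    "reference": reference_gene,
                    "calibrator": calibrator_sample,
                    "ratio": ratio if ratio != CENSORED else float("nan"),
                    "censored": ratio == CENSORED,
                }
            )
    return pd.DataFrame(rows)


def relative_copy_number(
    panel: pd.DataFrame,
    target_genes: list[str],
    reference_gene: str,
    calibrator_sample: str,
    efficiencies: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Relative genomic copy number for a set of target genes.

    Applies the efficiency-corrected ratio per gene per biological replicate
    against the calibrator; returns the per-replicate table and per
    (sample, gene) medians (censored replicates excluded from medians).
    """
    tables = []
    for gene in target_genes:
        tables.append(
            relative_quantities(
                panel, gene, reference_gene, calibrator_sample, efficiencies
            )
        )
    table = pd.concat(tables, ignore_index=True)
    medians = (
        table[~table["censored"]]
        .groupby(["sample", "target"])["ratio"]
        .median()
        .rename("median_ratio")
    )
    return table, medians
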