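"""Relative qPCR quantification by the comparative-Ct (2^-ddCt) method.

Each sample's target Ct is normalized against the arithmetic mean of its
reference-gene Cts (equivalent to the geometric mean of reference
quantities), then against the mean dCt of the calibrator group:

    dCt   = Ct_target - mean(Ct_references)          per sample
    ddCt  = dCt - mean(dCt of calibrator group)
    RQ    = 2 ** (-ddCt)

Amplification efficiency is fixed at 2 (no efficiency correction); technical
replicates are averaged per (sample, gene) before anything else.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["QpcrPlate", "relative_quantification"]

DEFAULT_REFERENCES = ("GAPDH", "YWHAZ")


@dataclass(frozen=True)
class QpcrPlate:
    """Long-format Ct records: columns sample, group, gene, ct."""

    records: pd.DataFrame
    reference_genes: tuple[str, ...] = DEFAULT_REFERENCES
    calibrator_group: str = ""

    def __post_init__(self) -> None:
        required = {"sample", "group", "gene", "ct"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"plate missing columns: {sorted(missing)}")
        if not self.calibrator_group:
            raise ValueError("calibrator_group must be set")
        if self.calibrator_group not in set(self.records["group"]):
            raise ValueError(f"calibrator group not on plate: {self.calibrator_group!r}")

    def mean_ct(self) -> pd.DataFrame:
        """Replicate-averaged Ct per (sample, group, gene)."""
        return (
            self.records.groupby(["sample", "group", "gene"], as_index=False)["ct"]
            .mean()
        )


def relative_quantification(plate: QpcrPlate, target: str) -> dict:
    """Per-sample and per-group RQ of ``target`` relative to the calibrator.

    Returns ``{"per_sample": DataFrame, "per_group": DataFrame}``; per-sample
    rows carry dCt, ddCt and RQ, per-group rows the RQ mean and SD.
    """
    ct = plate.mean_ct()
    samples = ct[["sample", "group"]].drop_duplicates().set_index("sample")

    wide = ct.pivot(index="sample", columns="gene", values="ct")
    for ref in plate.reference_genes:
        if ref not in wide.columns:
            raise ValueError(f"reference gene missing from plate: {ref!r}")
        bad = wide.index[wide[ref].isna()]
        if len(bad):
            raise ValueError(f"missing {ref} Ct for sample(s): {list(bad)}")
    if target not in wide.columns:
        raise ValueError(f"target not measured: {target!r}")
    bad = wide.index[wide[target].isna()]
    if len(bad):
        raise ValueError(f"missing {target} Ct for sample(s): {list(bad)}")

    ref_mean = wide[list(plate.reference_genes)].mean(axis=1)
    dct = wide[target] - ref_mean
    groups = samples.loc[dct.index, "group"]
    cal_mask = groups == plate.calibrator_group
    if not cal_mask.any():
        raise ValueError("calibrator group has no samples with target measurements")
    ddct = dct - dct[cal_mask].mean()
    rq = 2.0 ** (-ddct)

    per_sample = pd.DataFrame(
        {
            "sample": dct.index,
            "group": groups.values,
            "dct": dct.values,
            "ddct": ddct.values,
            "rq": rq.values,
        }
    ).sort_values(["group", "sample"], kind="mergesort", ignore_index=True)
    per_group = (
        per_sample.groupby("group", as_index=False)["rq"]
        .agg(rq_mean="mean", rq_sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0)
        .sort_values("group", ignore_index=True)
    )
    return {"per_sample": per_sample, "per_group": per_group}
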