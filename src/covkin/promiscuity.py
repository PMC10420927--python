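"""Promiscuity-degree (multi-kinase activity) profiling.

The promiscuity degree (PD) of an inhibitor is the number of distinct
kinases it has qualifying curated activity against.  Profiles are
binned as PD 1, PD 2-4, PD 5-9 and PD >= 10.  Reported proportions
reflect the activity records available, not exhaustive kinome profiling;
most inhibitors have only been tested against one or two kinases, and
no correction for this incompleteness is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

BIN_LABELS = ("PD1", "PD2_4", "PD5_9", "PD10plus")


def pd_bin(pd_value: int) -> str:
    if pd_value < 1:
        raise ValueError("pd must be >= 1")
    if pd_value == 1:
        return "PD1"
    if pd_value <= 4:
        return "PD2_4"
    if pd_value <= 9:
        return "PD5_9"
    return "PD10plus"


@dataclass(frozen=True)
class PromiscuityProfile:
    standard_smiles: str
    pd: int
    bin: str


def compute_pd(curated: pd.DataFrame) -> list[PromiscuityProfile]:
    """One profile per distinct compound; PD counts distinct kinase ids."""
    counts = curated.groupby("standard_smiles")["target_id"].nunique()
    return [
        PromiscuityProfile(standard_smiles=smi, pd=int(n), bin=pd_bin(int(n)))
        for smi, n in sorted(counts.items())
    ]


def pd_distribution(
    profiles: list[PromiscuityProfile], subset=None
) -> pd.DataFrame:
    """Counts and proportions per PD bin, optionally within a subset.

    Returns a frame indexed by bin label with columns count, proportion;
    proportions sum to 1 (within 1e-9).
    """
    if subset is not None:
        subset = set(subset)
        profiles = [p for p in profiles if p.standard_smiles in subset]
    if not profiles:
        raise ValueError("empty_subset")
    counts = {b: 0 for b in BIN_LABELS}
    for p in profiles:
        counts[p.bin] += 1
    total = len(profiles)
    return pd.DataFrame(
        {
            "count": [counts[b] for b in BIN_LABELS],
            "proportion": [counts[b] / total for b in BIN_LABELS],
        },
        index=list(BIN_LABELS),
    )


class PromiscuityProfiler(BaseEstimator, TransformerMixin):
    """Transformer mapping a curated activity table to PD profiles."""

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        profiles = compute_pd(X)
        return pd.DataFrame(
            {
                "standard_smiles": [p.standard_smiles for p in profiles],
                "pd": [p.pd for p in profiles],
                "bin": [p.bin for p in profiles],
            }
        )
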