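"""High-confidence activity curation.

Raw compound-kinase activity records (ChEMBL/BindingDB-style rows) are
standardized, filtered through a fixed cascade of confidence criteria,
grouped per (standard_smiles, target_id) across sources, and aggregated
into one pPotency value per pair.

Filter cascade (the reason code names the first failed filter, in this
order):

1.  ``malformed_record`` - a mandatory field is missing/empty
2.  ``units``            - a units column is present and is not nM
3.  ``relation``         - activity relation is not "="
4.  ``relationship_type``- (ChEMBL only) assay relationship type is not "D"
5.  ``potency_cutoff``   - value above 10,000 nM
6.  ``measurement_type`` - not one of Ki / Kd / IC50
7.  ``assay_kinase_count``- assay covers more than one kinase
8.  ``assay_confidence`` - (ChEMBL only) confidence score is not 9
9.  ``comment``          - flagged phrases ("uncertain", "potential
    transcription error", "outside typical range") or contradictory
    active/inactive tags in the activity comment

Records surviving the cascade are averaged on the log scale per
compound-target pair; Ki/Kd measurements take priority over IC50; a
pair whose replicate standard deviation reaches 1 log unit is dropped
(``sd_exceeds``).
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .standardize import standardize_smiles

MEASUREMENT_TYPES = ("Ki", "Kd", "IC50")

FLAGGED_PHRASES = (
    "uncertain",
    "potential transcription error",
    "outside typical range",
)

MANDATORY_FIELDS = (
    "compound_smiles",
    "target_id",
    "measurement_type",
    "relation",
    "value_nM",
    "source",
)

#: Columns of the raw activity-record table.
RECORD_COLUMNS = [
    "compound_smiles",
    "target_id",
    "measurement_type",
    "relation",
    "value_nM",
    "relationship_type",
    "assay_confidence",
    "assay_kinase_count",
    "activity_comment",
    "source",
]


@dataclass
class CurationConfig:
    """Thresholds of the curation filter cascade.

    Defaults are the standard high-confidence settings: a 10 uM potency
    ceiling, ChEMBL assay-confidence score 9, single-kinase assays and a
    1-log-unit replicate-consistency limit.
    """

    potency_cutoff_nM: float = 10_000.0
    sd_limit_log: float = 1.0
    required_confidence: int = 9
    flagged_phrases: tuple = FLAGGED_PHRASES
    required_units: str = "nM"


def to_pPotency(value_nM: float) -> float:
    """Negative decadic logarithm of the molar potency.

    10,000 nM -> 5.0; 1 nM -> 9.0.
    """
    if value_nM is None or not np.isfinite(value_nM) or value_nM <= 0:
        raise ValueError("nonpositive_potency")
    return -math.log10(value_nM * 1e-9)


def _is_missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    if isinstance(v, str) and not v.strip():
        return True
    return False


def _comment_flagged(comment: str, phrases) -> bool:
    c = comment.lower()
    if any(p in c for p in phrases):
        return True
    # contradictory active/inactive tags in the same comment
    tags = {t for t in ("inactive", "active") if t in c}
    if "inactive" in tags:
        # "inactive" contains "active" as a substring; require a separate
        # occurrence of "active" not part of "inactive"
        stripped = c.replace("inactive", "")
        tags = {"inactive"} | ({"active"} if "active" in stripped else set())
    return tags == {"active", "inactive"}


def filter_record(record: dict, config: CurationConfig | None = None) -> tuple[bool, str]:
    """Apply the filter cascade to one raw record.

    Returns ``(keep, reason)``; ``reason`` is "" when kept, otherwise
    the code of the first failed filter.
    """
    config = config or CurationConfig()
    for f in MANDATORY_FIELDS:
        if _is_missing(record.get(f)):
            return False, "malformed_record"
    units = record.get("units")
    if units is not None and not _is_missing(units) and str(units) != config.required_units:
        return False, "units"
    if str(record["relation"]).strip() != "=":
        return False, "relation"
    source = str(record["source"]).strip().lower()
    if source == "chembl":
        if str(record.get("relationship_type", "")).strip() != "D":
            return False, "relationship_type"
    try:
        value = float(record["value_nM"])
    except (TypeError, ValueError):
        return False, "malformed_record"
    if not np.isfinite(value) or value <= 0:
        return False, "malformed_record"
    if value > config.potency_cutoff_nM:
        return False, "potency_cutoff"
    if str(record["measurement_type"]) not in MEASUREMENT_TYPES:
        return False, "measurement_type"
    try:
        kc = int(record.get("assay_kinase_count", 1))
    except (TypeError, ValueError):
        return False, "malformed_record"
    if kc != 1:
        return False, "assay_kinase_count"
    if source == "chembl":
        conf = record.get("assay_confidence")
        if _is_missing(conf) or int(conf) != config.required_confidence:
            return False, "assay_confidence"
    comment = record.get("activity_comment", "")
    if not _is_missing(comment) and _comment_flagged(str(comment), config.flagged_phrases):
        return False, "comment"
    return True, ""


@dataclass
class CuratedActivity:
    """One aggregated compound-kinase potency."""

    standard_smiles: str
    target_id: str
    pPotency: float
    measurement_class: str  # "KiKd" or "IC50"
    n_measurements: int
    sd_log: float


def aggregate_measurements(records: list[dict], sd_limit_log: float = 1.0) -> CuratedActivity | None:
    """Aggregate passing records of one (standard_smiles, target_id) pair.

    Ki/Kd records take priority over IC50; the mean and sample standard
    deviation are taken on the pPotency (log) scale; the pair is dropped
    (returns None) when sd_log >= 1.
    """
    if not records:
        raise ValueError("no_records")
    kikd = [r for r in records if r["measurement_type"] in ("Ki", "Kd")]
    used = kikd if kikd else records
    mclass = "KiKd" if kikd else "IC50"
    p = np.array([to_pPotency(float(r["value_nM"])) for r in used])
    sd = float(np.std(p, ddof=1)) if len(p) > 1 else 0.0
    if sd >= sd_limit_log:
        return None
    return CuratedActivity(
        standard_smiles=records[0]["standard_smiles"],
        target_id=records[0]["target_id"],
        pPotency=float(np.mean(p)),
        measurement_class=mclass,
        n_measurements=len(used),
        sd_log=sd,
    )


@dataclass
class CurationReport:
    """Per-reason rejection counts plus conservation bookkeeping."""

    n_input: int = 0
    n_kept_records: int = 0
    rejected: Counter = field(default_factory=Counter)
    n_pairs: int = 0
    n_pairs_dropped_sd: int = 0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept_records": self.n_kept_records,
            "rejected": dict(self.rejected),
            "n_pairs": self.n_pairs,
            "n_pairs_dropped_sd": self.n_pairs_dropped_sd,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def curate(
    records, config: CurationConfig | None = None
) -> tuple[pd.DataFrame, CurationReport]:
    """Run the full curation: standardize, filter, group, aggregate.

    ``records`` is a DataFrame or list of dicts with the raw-record
    columns.  Returns the curated table (one row per compound-target
    pair) and a report whose counts satisfy
    kept_records + sum(rejected) == n_input.
    """
    config = config or CurationConfig()
    if isinstance(records, pd.DataFrame):
        records = records.to_dict("records")
    report = CurationReport(n_input=len(records))
    groups: dict[tuple[str, str], list[dict]] = {}
    for rec in records:
        keep, reason = filter_record(rec, config)
        if not keep:
            report.rejected[reason] += 1
            continue
        std = standardize_smiles(str(rec["compound_smiles"]))
        if not std.valid:
            report.rejected["standardize_" + std.rejection_reason] += 1
            continue
        rec = dict(rec)
        rec["standard_smiles"] = std.standard_smiles
        groups.setdefault((std.standard_smiles, str(rec["target_id"])), []).append(rec)

    rows = []
    for (_, _), grp in sorted(groups.items()):
        agg = aggregate_measurements(grp, config.sd_limit_log)
        if agg is None:
            report.n_pairs_dropped_sd += 1
            report.rejected["sd_exceeds"] += len(grp)
            continue
        report.n_kept_records += len(grp)
        rows.append(agg)
    report.n_pairs = len(rows)
    curated = pd.DataFrame(
        {
            "standard_smiles": [r.standard_smiles for r in rows],
            "target_id": [r.target_id for r in rows],
            "pPotency": [r.pPotency for r in rows],
            "measurement_class": [r.measurement_class for r in rows],
            "n_measurements": [r.n_measurements for r in rows],
            "sd_log": [r.sd_log for r in rows],
        }
    )
    return curated, report


class ActivityCurator(BaseEstimator, TransformerMixin):
    """sklearn-style transformer wrapping :func:`curate`.

    Parameters mirror :class:`CurationConfig`; after ``transform`` the
    report of the last run is available as ``report_``.
    """

    def __init__(
        self,
        potency_cutoff_nM: float = 10_000.0,
        sd_limit_log: float = 1.0,
        required_confidence: int = 9,
    ):
        self.potency_cutoff_nM = potency_cutoff_nM
        self.sd_limit_log = sd_limit_log
        self.required_confidence = required_confidence

    def _config(self) -> CurationConfig:
        return CurationConfig(
            potency_cutoff_nM=self.potency_cutoff_nM,
            sd_limit_log=self.sd_limit_log,
            required_confidence=self.required_confidence,
        )

    def fit(self, X, y=None):
        self.n_features_in_ = len(RECORD_COLUMNS)
        return self

    def transform(self, X) -> pd.DataFrame:
        curated, report = curate(X, self._config())
        self.report_ = report
        return curated
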