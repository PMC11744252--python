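"""Participant-level inclusion rules applied before any analysis.

Two rules operate at the participant level:

* **minimum completed assessments** — a participant must have completed at
  least ``min_required`` of the ``total`` scheduled occasions, where an
  occasion counts as completed if at least one item rating at that
  ``assessment_index`` is non-missing;
* **data-quality checks** — participants who failed more than
  ``max_failures`` of the (two attention + one honesty) checks are excluded.
  Check outcomes arrive as an auxiliary per-participant table of failure
  counts; scoring the free-text answers is outside this package.

Both rules are idempotent and commute, so the combined report does not
depend on application order; participants caught by both rules are
attributed to the minimum-assessments rule first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .synthetic import ConfigError


@dataclass
class QcReport:
    """Exclusion accounting for one QC pass."""

    n_input: int = 0
    n_excluded_min_assessments: int = 0
    n_excluded_quality: int = 0
    n_retained: int = 0
    per_participant: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_excluded_min_assessments": self.n_excluded_min_assessments,
            "n_excluded_quality": self.n_excluded_quality,
            "n_retained": self.n_retained,
            "per_participant": self.per_participant.to_dict(orient="records"),
        }


def completed_assessments(records: pd.DataFrame) -> pd.Series:
    """Number of occasions with >= 1 non-missing item rating, per participant."""
    obs = records.dropna(subset=["rating"])
    counts = obs.groupby("participant_id")["assessment_index"].nunique()
    all_ids = records["participant_id"].unique()
    return counts.reindex(all_ids, fill_value=0).astype(int)


def apply_min_assessments(
    records: pd.DataFrame, min_required: int = 3, total: int = 6
) -> tuple[pd.DataFrame, QcReport]:
    """Drop participants who completed fewer than ``min_required`` occasions.

    The boundary is inclusive: exactly ``min_required`` completed occasions
    is retained.
    """
    if min_required > total:
        raise ConfigError(
            f"min_required ({min_required}) cannot exceed total ({total})"
        )
    counts = completed_assessments(records)
    keep_ids = counts.index[counts >= min_required]
    kept = records[records["participant_id"].isin(keep_ids)].reset_index(drop=True)
    report = QcReport(
        n_input=counts.size,
        n_excluded_min_assessments=int((counts < min_required).sum()),
        n_retained=len(keep_ids),
        per_participant=pd.DataFrame(
            {"participant_id": counts.index, "completed_assessments": counts.values}
        ),
    )
    return kept, report


def apply_quality_checks(
    checks: pd.DataFrame, max_failures: int = 1
) -> tuple[pd.Index, QcReport]:
    """Keep participants with at most ``max_failures`` failed checks.

    ``checks`` has columns ``participant_id`` and ``failed_checks``.
    Returns the kept participant ids and a partial report.
    """
    failures = checks.set_index("participant_id")["failed_checks"].astype(int)
    if (failures < 0).any():
        raise ValueError("failed_checks counts must be non-negative")
    keep = failures.index[failures <= max_failures]
    report = QcReport(
        n_input=failures.size,
        n_excluded_quality=int((failures > max_failures).sum()),
        n_retained=len(keep),
        per_participant=pd.DataFrame(
            {"participant_id": failures.index, "failed_checks": failures.values}
        ),
    )
    return keep, report


def apply_qc(
    records: pd.DataFrame,
    checks: pd.DataFrame | None = None,
    min_required: int = 3,
    total: int = 6,
    max_failures: int = 1,
) -> tuple[pd.DataFrame, QcReport]:
    """Apply both inclusion rules and return retained records plus a report.

    Participants missing from ``checks`` are assumed to have zero failures.
    A participant failing both rules is counted under the
    minimum-assessments rule.
    """
    all_ids = pd.Index(records["participant_id"].unique())
    counts = completed_assessments(records)

    if checks is not None:
        failures = (
            checks.set_index("participant_id")["failed_checks"]
            .astype(int)
            .reindex(all_ids, fill_value=0)
        )
        if (failures < 0).any():
            raise ValueError("failed_checks counts must be non-negative")
    else:
        failures = pd.Series(0, index=all_ids)

    fail_min = counts < min_required
    if min_required > total:
        raise ConfigError(
            f"min_required ({min_required}) cannot exceed total ({total})"
        )
    fail_quality = failures > max_failures
    keep_ids = all_ids[~(fail_min | fail_quality).to_numpy()]
    kept = records[records["participant_id"].isin(keep_ids)].reset_index(drop=True)

    report = QcReport(
        n_input=len(all_ids),
        n_excluded_min_assessments=int(fail_min.sum()),
        n_excluded_quality=int((fail_quality & ~fail_min).sum()),
        n_retained=len(keep_ids),
        per_participant=pd.DataFrame(
            {
                "participant_id": all_ids,
                "completed_assessments": counts.reindex(all_ids).to_numpy(),
                "failed_checks": failures.to_numpy(),
            }
        ),
    )
    return kept, report
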