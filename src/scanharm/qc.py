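"""Subject-level exclusion pipeline.

Stages, in the order the full pipeline applies them: age window,
quality-probability cutoffs, missing-data exclusion, per-scanner
iterative outlier removal on relative volumes, and the minimum
scanner-size filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import CohortTable

logger = logging.getLogger(__name__)


@dataclass
class QcReport:
    """Accounting of one or several exclusion stages.

    Counts partition the input: ``n_input == n_retained + sum(n_excluded.values())``.
    Each excluded subject appears once, with its primary reason.
    """

    n_input: int
    n_retained: int
    n_excluded: dict[str, int] = field(default_factory=dict)
    excluded_ids: list[tuple[str, str]] = field(default_factory=list)
    outlier_iterations: dict[str, int] = field(default_factory=dict)

    def check(self) -> None:
        if self.n_input != self.n_retained + sum(self.n_excluded.values()):
            raise AssertionError("QcReport counts do not partition n_input")
        if len(self.excluded_ids) != sum(self.n_excluded.values()):
            raise AssertionError("excluded_ids inconsistent with counts")

    @staticmethod
    def chain(reports: list["QcReport"]) -> "QcReport":
        """Combine sequential stage reports into one conserved partition."""
        if not reports:
            raise ValueError("no reports to chain")
        merged = QcReport(n_input=reports[0].n_input, n_retained=reports[-1].n_retained)
        for r in reports:
            for reason, cnt in r.n_excluded.items():
                merged.n_excluded[reason] = merged.n_excluded.get(reason, 0) + cnt
            merged.excluded_ids.extend(r.excluded_ids)
            merged.outlier_iterations.update(r.outlier_iterations)
        merged.check()
        return merged


def _report(table: CohortTable, keep: pd.Series, reason: str) -> tuple[CohortTable, QcReport]:
    keep = keep.to_numpy() if isinstance(keep, pd.Series) else np.asarray(keep)
    excluded = table.data.loc[~keep, "subject_id"].tolist()
    report = QcReport(
        n_input=len(table),
        n_retained=int(keep.sum()),
        n_excluded={reason: len(excluded)} if excluded else {},
        excluded_ids=[(sid, reason) for sid in excluded],
    )
    report.check()
    return table.subset(keep), report


def filter_age_range(
    table: CohortTable, min_age: float = 18.0, max_age: float = 70.0
) -> tuple[CohortTable, QcReport]:
    """Retain subjects with ``min_age <= age <= max_age`` (inclusive bounds:
    exclusion targets subjects strictly younger / older)."""
    if min_age > max_age:
        raise ValueError(f"min_age ({min_age}) > max_age ({max_age})")
    age = table.data["age"]
    keep = (age >= min_age) & (age <= max_age)
    out, report = _report(table, keep, "age")
    if out.n == 0:
        logger.warning("age filter removed every subject")
    return out, report


def filter_quality(
    table: CohortTable, threshold: float = 0.5
) -> tuple[CohortTable, QcReport]:
    """Drop subjects whose unusable-probability is strictly above ``threshold``.

    Applied to every quality-probability column present (image-level and
    segmentation-level). No-op with a warning when neither is present.
    """
    cols = [c for c in ("qc_prob_image", "qc_prob_seg") if c in table.data.columns]
    if not cols:
        logger.warning("no quality-probability columns present; quality filter skipped")
        return table.copy(), QcReport(n_input=len(table), n_retained=len(table))
    keep = pd.Series(True, index=table.data.index)
    for c in cols:
        vals = table.data[c]
        present = vals.notna()
        if ((vals < 0) | (vals > 1)).any():
            bad = vals[(vals < 0) | (vals > 1)].iloc[0]
            raise ValueError(f"{c}: probability {bad} outside [0, 1]")
        keep &= ~(present & (vals > threshold))
    return _report(table, keep, "quality")


def filter_missing(table: CohortTable) -> tuple[CohortTable, QcReport]:
    """Exclude subjects with any missing ROI or IQM value (no imputation)."""
    cols = list(table.roi_cols) + list(table.iqm_cols)
    keep = table.data[cols].notna().all(axis=1) if cols else pd.Series(True, index=table.data.index)
    return _report(table, keep, "missing")


def compute_relative_volumes(table: CohortTable) -> CohortTable:
    """relative_volume[g] = roi_volume[g] / tiv, per subject."""
    tiv = table.data["tiv"]
    if (tiv <= 0).any():
        sid = table.data.loc[tiv <= 0, "subject_id"].iloc[0]
        raise ValueError(f"non-positive TIV for subject {sid!r}")
    out = table.copy()
    for roi in table.roi_cols:
        out.data[table.rel_col(roi)] = out.data[roi] / tiv
    return out


def iterative_outlier_filter(
    table: CohortTable,
    z_cut: float = 2.5,
    min_rois: int | None = 10,
    min_roi_fraction: float | None = None,
) -> tuple[CohortTable, QcReport]:
    """Remove per-scanner outliers on relative volumes until a fixed point.

    Within each scanner, compute per-ROI mean and sample SD over the
    currently retained subjects; a subject is flagged when
    ``|v - mu| > z_cut * sigma`` on at least ``min_rois`` ROIs (or the
    equivalent fraction of the feature space when ``min_roi_fraction``
    is given). All flagged subjects are removed together, moments are
    recomputed, and the pass repeats until no subject is flagged.
    """
    if not table.has_relative:
        raise ValueError("relative volumes required; run compute_relative_volumes first")
    if min_roi_fraction is not None:
        min_rois = max(1, int(round(min_roi_fraction * len(table.roi_cols))))
    if min_rois is None:
        raise ValueError("one of min_rois / min_roi_fraction required")

    rel = table.data[list(table.rel_cols)].to_numpy(float)
    scanner = table.data["scanner"].to_numpy()
    removed = np.zeros(len(table), dtype=bool)
    iterations: dict[str, int] = {}

    for s in np.unique(scanner):
        idx = np.flatnonzero(scanner == s)
        if len(idx) < 2:
            logger.warning("scanner %s has < 2 subjects; outlier pass skipped", s)
            iterations[str(s)] = 0
            continue
        active = idx.copy()
        n_iter = 0
        while True:
            n_iter += 1
            vals = rel[active]
            mu = vals.mean(axis=0)
            sigma = vals.std(axis=0, ddof=1)
            with np.errstate(invalid="ignore"):
                flags = np.abs(vals - mu) > z_cut * sigma
            n_flagged_rois = flags.sum(axis=1)
            out_mask = n_flagged_rois >= min_rois
            if not out_mask.any() or out_mask.all():
                break
            removed[active[out_mask]] = True
            active = active[~out_mask]
            if len(active) < 2:
                break
        iterations[str(s)] = n_iter
    out, report = _report(table, ~removed, "outlier")
    report.outlier_iterations = iterations
    return out, report


def filter_min_scanner_size(
    table: CohortTable, min_n: int = 5
) -> tuple[CohortTable, QcReport]:
    """Drop every subject of a scanner with fewer than ``min_n`` retained subjects."""
    sizes = table.data["scanner"].map(table.scanner_sizes())
    keep = sizes >= min_n
    return _report(table, keep, "small_scanner")


def run_qc(
    table: CohortTable,
    min_age: float = 18.0,
    max_age: float = 70.0,
    qc_threshold: float = 0.5,
    z_cut: float = 2.5,
    min_rois: int | None = 10,
    min_roi_fraction: float | None = None,
    min_scanner_n: int = 5,
) -> tuple[CohortTable, QcReport]:
    """Full pipeline: age -> quality -> missing -> relative volumes ->
    per-scanner outliers -> scanner size."""
    reports = []
    table, r = filter_age_range(table, min_age, max_age)
    reports.append(r)
    table, r = filter_quality(table, qc_threshold)
    reports.append(r)
    table, r = filter_missing(table)
    reports.append(r)
    table = compute_relative_volumes(table)
    table, r = iterative_outlier_filter(table, z_cut, min_rois, min_roi_fraction)
    reports.append(r)
    table, r = filter_min_scanner_size(table, min_scanner_n)
    reports.append(r)
    return table, QcReport.chain(reports)
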