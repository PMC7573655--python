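"""Scanner-bias quantification.

Pairwise two-sample Kolmogorov-Smirnov matrices over scanner pairs and
ROIs (no multiplicity correction, by design: type-II errors are the
concern), correction-strength summaries (correction ratio, CV, QCV),
and the per-covariate decomposition of total correction magnitude.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .combat import CorrectionTable
from .tables import CohortTable

logger = logging.getLogger(__name__)


def ks_two_sample(
    x: np.ndarray, y: np.ndarray, mode: str = "asymp"
) -> tuple[float, float]:
    """Two-sided two-sample K-S test.

    ``mode='asymp'`` (default) uses the asymptotic Kolmogorov
    distribution with effective size nx*ny/(nx+ny); ``'exact'`` uses the
    exact null distribution of D; ``'permutation'`` enumerates every
    split when feasible (combined n <= 30) and falls back to exact
    otherwise. Returns ``(D, p)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample must contain at least 2 observations")
    if mode in ("asymp", "exact"):
        res = stats.ks_2samp(x, y, method=mode)
        return float(res.statistic), float(res.pvalue)
    if mode == "permutation":
        if len(x) + len(y) > 30:
            logger.warning("combined n > 30; permutation mode falling back to exact")
            res = stats.ks_2samp(x, y, method="exact")
            return float(res.statistic), float(res.pvalue)
        return _ks_permutation(x, y)
    raise ValueError(f"unknown mode {mode!r}")


def _ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """sup |ECDF_x - ECDF_y| by direct evaluation at every data point."""
    pts = np.concatenate([x, y])
    cdf_x = np.searchsorted(np.sort(x), pts, side="right") / len(x)
    cdf_y = np.searchsorted(np.sort(y), pts, side="right") / len(y)
    return float(np.abs(cdf_x - cdf_y).max())


def _ks_permutation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exhaustive permutation distribution of D over all label splits."""
    d_obs = _ks_statistic(x, y)
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    count = total = 0
    for comb in itertools.combinations(range(n), nx):
        mask = np.zeros(n, dtype=bool)
        mask[list(comb)] = True
        d = _ks_statistic(pooled[mask], pooled[~mask])
        count += d >= d_obs - 1e-12
        total += 1
    return d_obs, count / total


@dataclass
class KsMatrix:
    """Pairwise K-S results: one row per unordered scanner pair x ROI."""

    table: pd.DataFrame            # columns: scanner_a, scanner_b, roi, d, p
    condition: str = ""

    def min_p_per_pair(self) -> pd.Series:
        return self.table.groupby(["scanner_a", "scanner_b"])["p"].min()

    def pair(self, a: str, b: str) -> pd.DataFrame:
        a, b = sorted((a, b))
        t = self.table
        return t[(t["scanner_a"] == a) & (t["scanner_b"] == b)]


def ks_pair_matrix(
    table: CohortTable,
    condition: str = "",
    mode: str = "asymp",
    min_pair_size: int = 2,
    values: pd.DataFrame | None = None,
) -> KsMatrix:
    """K-S test for every unordered scanner pair on every ROI.

    ``values`` overrides the relative volumes (subject-indexed frame);
    pairs where either scanner has fewer than ``min_pair_size`` subjects
    are skipped.
    """
    if values is None:
        values = table.relative_volumes()
    scanners = table.data.set_index("subject_id")["scanner"].loc[values.index]
    groups = {s: values.loc[scanners[scanners == s].index] for s in scanners.unique()}
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("at least 2 scanners required")
    rows = []
    for a, b in itertools.combinations(names, 2):
        ga, gb = groups[a], groups[b]
        if len(ga) < min_pair_size or len(gb) < min_pair_size:
            continue
        for roi in values.columns:
            d, p = ks_two_sample(ga[roi].to_numpy(), gb[roi].to_numpy(), mode=mode)
            rows.append((a, b, roi, d, p))
    return KsMatrix(
        pd.DataFrame(rows, columns=["scanner_a", "scanner_b", "roi", "d", "p"]),
        condition=condition,
    )


def aggregate_tissue(
    table: CohortTable,
    roi_groups: dict[str, str],
    values: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-subject summed relative volume per tissue class.

    ``roi_groups`` maps ROI name -> class (e.g. ``'GM'``/``'WM'``); ROIs
    absent from the map fall into ``'neither'`` with a warning. A
    ``'whole'`` column sums every ROI. Empty classes listed in the map
    raise.
    """
    if values is None:
        values = table.relative_volumes()
    unmapped = [r for r in values.columns if r not in roi_groups]
    if unmapped:
        logger.warning("%d ROI(s) not in tissue map; grouped as 'neither'", len(unmapped))
    mapped = {r: roi_groups.get(r, "neither") for r in values.columns}
    classes = sorted(set(roi_groups.values()))
    out = pd.DataFrame(index=values.index)
    for cls in classes:
        members = [r for r, c in mapped.items() if c == cls]
        if not members:
            raise ValueError(f"tissue class {cls!r} has no member ROIs")
        out[cls] = values[members].sum(axis=1)
    if unmapped:
        out["neither"] = values[unmapped].sum(axis=1)
    out["whole"] = values.sum(axis=1)
    return out


def correction_strength(
    raw_values: pd.DataFrame, corrections: pd.DataFrame
) -> pd.DataFrame:
    """Per-ROI dispersion and correction-magnitude summary.

    Columns: median_volume, median_abs_correction, correction_ratio
    (median |v| / median |c|), correction_percent (its reciprocal x
    100), CV = 100*sd/mean and QCV = 100*(Q3-Q1)/Q2 of the raw values
    (quartiles by linear interpolation, sample SD).
    """
    rois = list(raw_values.columns)
    corrections = corrections[rois]
    med_v = raw_values.abs().median(axis=0)
    med_c = corrections.abs().median(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(med_c > 0, med_v / med_c, np.inf)
        percent = np.where(med_c > 0, 100.0 * med_c / med_v, 0.0)
    mean = raw_values.mean(axis=0)
    sd = raw_values.std(axis=0, ddof=1)
    q1 = raw_values.quantile(0.25, interpolation="linear")
    q2 = raw_values.quantile(0.50, interpolation="linear")
    q3 = raw_values.quantile(0.75, interpolation="linear")
    out = pd.DataFrame(
        {
            "median_volume": med_v,
            "median_abs_correction": med_c,
            "correction_ratio": ratio,
            "correction_percent": percent,
            "cv": 100.0 * sd / mean,
            "qcv": 100.0 * (q3 - q1) / q2,
        },
        index=rois,
    )
    undefined = med_v == 0
    if undefined.any():
        logger.warning("%d ROI(s) with zero median volume flagged", int(undefined.sum()))
        out.loc[undefined, ["correction_ratio", "correction_percent"]] = np.nan
    return out


def covariate_contributions(
    corrections: CorrectionTable,
    scanners: pd.Series,
    median_over: str = "subjects",
) -> pd.DataFrame:
    """Per-scanner share of total correction magnitude per step covariate.

    For scanner s and step k: raw_k(s) = sum over ROIs of the median
    (over the scanner's subjects) of |c_k|; the normalized share divides
    by the sum over steps, so shares sum to 1 per scanner.
    ``median_over='rois'`` swaps the order (median over ROIs per
    subject, summed over subjects).
    """
    steps = list(corrections.steps)
    if not steps:
        raise ValueError("no step corrections present")
    rows = {}
    for s in sorted(scanners.unique()):
        ids = scanners[scanners == s].index
        raw = {}
        for k in steps:
            c = corrections.steps[k].loc[ids].abs()
            if median_over == "subjects":
                raw[k] = float(c.median(axis=0).sum())
            elif median_over == "rois":
                raw[k] = float(c.median(axis=1).sum())
            else:
                raise ValueError(f"unknown median_over {median_over!r}")
        rows[s] = raw
    out = pd.DataFrame(rows).T[steps]
    total = out.sum(axis=1)
    if (total == 0).any():
        logger.warning("scanner(s) with zero total correction; shares undefined (NaN)")
    shares = out.div(total, axis=0)
    shares.columns = [f"share_{k}" for k in steps]
    return pd.concat([out, shares], axis=1)
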