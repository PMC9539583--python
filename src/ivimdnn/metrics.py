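"""Robust accuracy/precision metrics and method comparison.

All error metrics are relative to ground truth, per voxel:

* MdAE — median of |est - true| / true (accuracy).
* MdB  — median of (est - true) / true (signed bias).
* RCV  — 1.4826 * MAD / median of the estimates inside a homogeneous ROI
  (precision/repeatability; 1.4826 makes the MAD a consistent sigma
  estimator under Gaussian spread).
* FR   — fraction of voxels whose relative absolute error exceeds 50%.

Method medians are compared with a Kruskal–Wallis omnibus test followed by
Tukey-HSD-corrected pairwise comparisons on the pooled ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "mdae",
    "mdb",
    "rcv",
    "failure_rate",
    "compare_methods",
    "build_report",
    "MAD_SCALE",
    "PARAMS",
]

#: consistency constant: MAD * 1.4826 estimates sigma for Gaussian data.
MAD_SCALE = 1.4826

PARAMS = ("D", "f", "Dstar")


def _rel_errors(est, true):
    est = np.asarray(est, dtype=float).ravel()
    true = np.asarray(true, dtype=float).ravel()
    if est.shape != true.shape:
        raise ValueError("est and true must have the same length")
    keep = true != 0
    return (est[keep] - true[keep]) / true[keep], int((~keep).sum())


def mdae(est, true) -> float:
    """Relative median absolute error: median(|est - true| / true)."""
    rel, _ = _rel_errors(est, true)
    if rel.size == 0:
        raise ValueError("no voxels with non-zero ground truth")
    return float(np.median(np.abs(rel)))


def mdb(est, true) -> float:
    """Relative median bias: median((est - true) / true), sign preserved."""
    rel, _ = _rel_errors(est, true)
    if rel.size == 0:
        raise ValueError("no voxels with non-zero ground truth")
    return float(np.median(rel))


def mad(x) -> float:
    """Median absolute deviation (unscaled)."""
    x = np.asarray(x, dtype=float)
    return float(np.median(np.abs(x - np.median(x))))


def rcv(est_within_roi) -> float:
    """Robust coefficient of variation of estimates in one homogeneous ROI."""
    x = np.asarray(est_within_roi, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty ROI sample")
    med = np.median(x)
    if med == 0:
        raise ValueError("zero median: RCV undefined")
    return float(MAD_SCALE * mad(x) / med)


def failure_rate(est, true, threshold: float = 0.5) -> float:
    """Fraction of voxels whose relative absolute error exceeds ``threshold``."""
    rel, _ = _rel_errors(est, true)
    if rel.size == 0:
        raise ValueError("no voxels with non-zero ground truth")
    return float(np.mean(np.abs(rel) > threshold))


@dataclass(frozen=True)
class MethodComparison:
    """Omnibus Kruskal–Wallis p-value plus Tukey-corrected pairwise table."""

    statistic: float
    p_value: float
    pairwise: pd.DataFrame
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def compare_methods(samples: dict[str, np.ndarray],
                    alpha: float = 0.05) -> MethodComparison:
    """Compare per-voxel metric samples across methods.

    Kruskal–Wallis on the raw samples; pairwise comparisons via Tukey's HSD
    applied to the pooled ranks (the standard follow-up to a rank-based
    omnibus test).  Requires at least two groups of at least two samples.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if len(samples) < 2:
        raise ValueError("need at least two methods to compare")
    groups = {k: np.asarray(v, dtype=float).ravel() for k, v in samples.items()}
    for name, g in groups.items():
        if g.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 samples")
    stat, p = stats.kruskal(*groups.values())
    pooled = np.concatenate(list(groups.values()))
    labels = np.concatenate([[name] * g.size for name, g in groups.items()])
    ranks = stats.rankdata(pooled)
    tukey = pairwise_tukeyhsd(ranks, labels, alpha=alpha)
    pairwise = pd.DataFrame(tukey.summary().data[1:],
                            columns=tukey.summary().data[0])
    return MethodComparison(statistic=float(stat), p_value=float(p),
                            pairwise=pairwise, alpha=alpha)


def _roi_rcvs(est_map: np.ndarray, labels: np.ndarray) -> list[float]:
    out = []
    for label in np.unique(labels[labels > 0]):
        out.append(rcv(est_map[labels == label]))
    return out


def build_report(records, snr_aggregate: str = "median") -> pd.DataFrame:
    """Long-form metrics table over (method, parameter, SNR) plus summaries.

    ``records`` is an iterable of dicts with keys ``method``, ``snr``,
    ``est`` (3, ...) estimated maps ordered (D, f, Dstar), ``truth`` (3, ...)
    ground-truth maps, and ``roi_labels``.  Background (label 0) voxels are
    excluded.  MdAE/MdB/FR pool voxels over all phantoms of a (method, snr)
    cell; RCV is computed per ROI per phantom and aggregated by median.

    Summary rows (``snr == "all"``) aggregate the per-SNR values across SNR
    levels as median +/- MAD (``snr_aggregate="mean"`` switches the central
    value to the mean).
    """
    if snr_aggregate not in ("median", "mean"):
        raise ValueError("snr_aggregate must be 'median' or 'mean'")
    cells: dict[tuple, dict] = {}
    for rec in records:
        est = np.asarray(rec["est"], dtype=float)
        truth = np.asarray(rec["truth"], dtype=float)
        labels = np.asarray(rec["roi_labels"])
        if est.shape != truth.shape or est.shape[1:] != labels.shape:
            raise ValueError("est/truth/roi_labels shapes disagree")
        fg = labels > 0
        for pi, pname in enumerate(PARAMS):
            key = (rec["method"], pname, float(rec["snr"]))
            cell = cells.setdefault(key, {"est": [], "true": [], "rcvs": []})
            cell["est"].append(est[pi][fg])
            cell["true"].append(truth[pi][fg])
            cell["rcvs"].extend(_roi_rcvs(est[pi], labels))

    rows = []
    for (method, pname, snr), cell in sorted(cells.items()):
        e = np.concatenate(cell["est"])
        t = np.concatenate(cell["true"])
        rows.append({
            "method": method, "parameter": pname, "snr": snr,
            "MdAE": mdae(e, t), "MdB": mdb(e, t),
            "RCV": float(np.median(cell["rcvs"])),
            "FR": failure_rate(e, t), "n_voxels": int(e.size),
        })
    table = pd.DataFrame(rows)

    summaries = []
    for (method, pname), sub in table.groupby(["method", "parameter"], sort=True):
        row = {"method": method, "parameter": pname, "snr": "all",
               "n_voxels": int(sub["n_voxels"].sum())}
        for col in ("MdAE", "MdB", "RCV", "FR"):
            vals = sub[col].to_numpy()
            center = np.median(vals) if snr_aggregate == "median" else np.mean(vals)
            row[col] = float(center)
            row[f"{col}_mad"] = mad(vals)
        summaries.append(row)
    return pd.concat([table, pd.DataFrame(summaries)], ignore_index=True)
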