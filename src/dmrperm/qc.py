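"""Probe/sample quality filters and the beta <-> M-value transform.

Two filtering dialects are provided, matching common practice on the two
Illumina Infinium platforms:

* 450K: a probe is excluded when its bead count is < 3 in **at least 5%** of
  samples, or its detection p value exceeds 0.001 in at least 5% of samples,
  or it appears on a user-supplied blacklist (cross-hybridising or
  SNP-proximal probes).
* EPIC: strict ``> 10%`` sample fractions, detection threshold 0.01.

Detection p values are intensity-based quantities computed upstream by the
scanning software; here they are inputs, never recomputed.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .datatypes import QCReport

__all__ = [
    "beta_to_m",
    "m_to_beta",
    "clip_betas",
    "filter_probes_450k",
    "filter_probes_epic",
    "filter_samples",
    "apply_qc",
]

_LN2 = np.log(2.0)


def beta_to_m(beta):
    """M = log2(beta / (1 - beta)). Input must lie strictly inside (0, 1)."""
    arr = np.asarray(beta, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise ValueError("beta values must lie strictly in (0, 1); clip first")
    out = logit(arr) / _LN2
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(out, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(out, index=beta.index)
    return out


def m_to_beta(m):
    """Inverse transform, beta = 2^M / (1 + 2^M), numerically stable."""
    arr = np.asarray(m, dtype=float)
    out = expit(arr * _LN2)
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(out, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(out, index=m.index)
    return out


def clip_betas(beta, eps: float = 1e-6):
    """Clip betas into [eps, 1 - eps] so that the logit stays finite."""
    if not 0 < eps < 0.5:
        raise ValueError("eps must lie in (0, 0.5)")
    if isinstance(beta, (pd.DataFrame, pd.Series)):
        return beta.clip(eps, 1.0 - eps)
    return np.clip(np.asarray(beta, dtype=float), eps, 1.0 - eps)


def _check_aligned(det_p: pd.DataFrame, beads: pd.DataFrame) -> None:
    if det_p.shape != beads.shape or not det_p.index.equals(beads.index) \
            or not det_p.columns.equals(beads.columns):
        raise ValueError("detection-p and bead-count matrices must share probe/sample indexing")
    if det_p.shape[1] == 0:
        raise ValueError("matrices have no samples")


def _build_report(det_p, bead_fail, det_fail, blacklist) -> QCReport:
    exclusions: dict[str, str] = {}
    blacklist = set(map(str, blacklist))
    for probe in det_p.index:
        if bead_fail.loc[probe]:
            exclusions[probe] = "bead"
        elif det_fail.loc[probe]:
            exclusions[probe] = "detection"
        elif probe in blacklist:
            exclusions[probe] = "blacklist"
    kept = [p for p in det_p.index if p not in exclusions]
    return QCReport(kept_probes=kept, exclusions=exclusions)


def filter_probes_450k(det_p: pd.DataFrame, beads: pd.DataFrame,
                       blacklist: Iterable[str] = ()) -> QCReport:
    """450K probe exclusion: bead < 3 or detection p > 0.001 in >= 5% of samples.

    The bead rule takes precedence in the reported reason, then detection,
    then the blacklist.
    """
    _check_aligned(det_p, beads)
    n = det_p.shape[1]
    bead_fail = (beads < 3).sum(axis=1) / n >= 0.05
    det_fail = (det_p > 0.001).sum(axis=1) / n >= 0.05
    return _build_report(det_p, bead_fail, det_fail, blacklist)


def filter_probes_epic(det_p: pd.DataFrame, beads: pd.DataFrame) -> QCReport:
    """EPIC probe exclusion: detection p > 0.01 or bead < 3 for > 10% of samples."""
    _check_aligned(det_p, beads)
    n = det_p.shape[1]
    bead_fail = (beads < 3).sum(axis=1) / n > 0.10
    det_fail = (det_p > 0.01).sum(axis=1) / n > 0.10
    return _build_report(det_p, bead_fail, det_fail, ())


def filter_samples(det_p: pd.DataFrame, threshold: float = 0.001,
                   max_failed_fraction: float = 0.01) -> list[str]:
    """Samples whose fraction of failed probes (det p > threshold) *exceeds*
    ``max_failed_fraction``. A sample at exactly the limit is kept."""
    if det_p.size == 0:
        raise ValueError("empty detection-p matrix")
    if not (0 < threshold < 1) or not (0 < max_failed_fraction < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    frac = (det_p > threshold).sum(axis=0) / det_p.shape[0]
    return list(det_p.columns[frac > max_failed_fraction])


def apply_qc(betas: pd.DataFrame, det_p: pd.DataFrame, beads: pd.DataFrame,
             platform: str = "450k", blacklist: Iterable[str] = (),
             sample_det_threshold: float | None = None,
             max_failed_fraction: float = 0.01) -> tuple[pd.DataFrame, QCReport]:
    """Run the platform's probe filter plus the sample filter; return the
    filtered beta matrix and the combined report."""
    if platform == "450k":
        report = filter_probes_450k(det_p, beads, blacklist)
        det_thr = 0.001 if sample_det_threshold is None else sample_det_threshold
    elif platform == "epic":
        report = filter_probes_epic(det_p, beads)
        det_thr = 0.01 if sample_det_threshold is None else sample_det_threshold
    else:
        raise ValueError("platform must be '450k' or 'epic'")
    failed = filter_samples(det_p, det_thr, max_failed_fraction)
    report.failed_samples.extend(failed)
    keep_cols = [c for c in betas.columns if c not in set(failed)]
    filtered = betas.loc[[p for p in betas.index if p in set(report.kept_probes)], keep_cols]
    return filtered, report
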