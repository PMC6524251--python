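"""DMR calling: seed runs of nominally significant CpGs combined with a
Stouffer region statistic.

A candidate region is a maximal run of consecutive map probes that all pass
the per-CpG seed threshold, with inter-probe gaps no larger than ``max_gap``
and at least ``min_cpgs`` probes. The region statistic is the equal-weight
Stouffer combination S = sum(z_i)/sqrt(k) of the per-CpG signed z scores,
referred to a two-sided normal tail; regions with p_region below the nominal
region threshold (default 0.01) are reported. Inter-CpG correlation is
deliberately ignored here: region-wise significance is recalibrated
empirically by the permutation module against same-size CpG windows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datatypes import CpGMap, DMR

__all__ = ["DMRCaller", "call_dmrs", "enumerate_windows", "stouffer", "dmrs_to_frame"]


def stouffer(z: np.ndarray) -> float:
    """Equal-weight Stouffer statistic S = sum(z)/sqrt(k)."""
    z = np.asarray(z, dtype=float)
    return float(z.sum() / np.sqrt(z.size))


def _aligned_columns(assoc: pd.DataFrame, cpg_map: CpGMap):
    """z, p, delta_beta arrays in map order; errors on missing probes."""
    missing = set(cpg_map.probe_ids) - set(assoc.index)
    if missing:
        raise ValueError(f"association table lacks {len(missing)} map probes")
    sub = assoc.loc[cpg_map.probe_ids]
    return (sub["z"].to_numpy(dtype=float), sub["p"].to_numpy(dtype=float),
            sub["delta_beta"].to_numpy(dtype=float))


class DMRCaller(BaseEstimator):
    """Seed-run-Stouffer DMR caller.

    Parameters
    ----------
    alpha_cpg : per-CpG seed threshold (p < alpha_cpg).
    max_gap : maximum inter-probe gap (bp) within a run.
    min_cpgs : minimum probes per reported region.
    alpha_dmr : nominal region-level threshold on the Stouffer tail p.

    After ``fit(assoc, cpg_map)``, ``dmrs_`` holds the regions sorted by
    chromosome then start.
    """

    def __init__(self, alpha_cpg: float = 0.05, max_gap: int = 1000,
                 min_cpgs: int = 2, alpha_dmr: float = 0.01):
        self.alpha_cpg = alpha_cpg
        self.max_gap = max_gap
        self.min_cpgs = min_cpgs
        self.alpha_dmr = alpha_dmr

    def fit(self, assoc: pd.DataFrame, cpg_map: CpGMap):
        if not (0 < self.alpha_cpg <= 1 and 0 < self.alpha_dmr <= 1):
            raise ValueError("alpha thresholds must lie in (0, 1]")
        if self.max_gap <= 0 or self.min_cpgs < 1:
            raise ValueError("max_gap and min_cpgs must be positive")
        z, p, db = _aligned_columns(assoc, cpg_map)
        table = cpg_map.table
        pos = table["pos"].to_numpy()
        probes = table["probe_id"].to_numpy()
        seed = p < self.alpha_cpg

        dmrs: list[DMR] = []
        for chrom in cpg_map.chromosomes:
            sl = cpg_map.chrom_slice(chrom)
            i = sl.start
            while i < sl.stop:
                if not seed[i]:
                    i += 1
                    continue
                j = i
                while (j + 1 < sl.stop and seed[j + 1]
                       and pos[j + 1] - pos[j] <= self.max_gap):
                    j += 1
                k = j - i + 1
                if k >= self.min_cpgs:
                    S = stouffer(z[i:j + 1])
                    p_region = 2.0 * stats.norm.sf(abs(S))
                    if p_region < self.alpha_dmr:
                        mean_db = float(db[i:j + 1].mean())
                        dmrs.append(DMR(
                            chrom=chrom, start=int(pos[i]) - 1, end=int(pos[j]),
                            probe_ids=tuple(probes[i:j + 1]), stat=S,
                            p_region=float(p_region), mean_delta_beta=mean_db,
                            direction="hypo" if mean_db < 0 else "hyper"))
                i = j + 1
        self.dmrs_ = dmrs
        return self


def call_dmrs(assoc: pd.DataFrame, cpg_map: CpGMap, alpha_cpg: float = 0.05,
              max_gap: int = 1000, min_cpgs: int = 2,
              alpha_dmr: float = 0.01) -> list[DMR]:
    """Functional wrapper over :class:`DMRCaller`."""
    caller = DMRCaller(alpha_cpg=alpha_cpg, max_gap=max_gap,
                       min_cpgs=min_cpgs, alpha_dmr=alpha_dmr)
    return caller.fit(assoc, cpg_map).dmrs_


def enumerate_windows(cpg_map: CpGMap, k: int) -> pd.DataFrame:
    """All contiguous k-CpG windows genome-wide: for every chromosome with
    m >= k probes, its m - k + 1 windows of k consecutive probes.

    Returns a DataFrame with columns ``chrom``, ``i0`` (global index of the
    first probe), ``start``/``end`` (0-based half-open base span). This is
    the sole null universe used by the permutation module.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    table = cpg_map.table
    pos = table["pos"].to_numpy()
    rows = []
    for chrom in cpg_map.chromosomes:
        sl = cpg_map.chrom_slice(chrom)
        m = sl.stop - sl.start
        if m < k:
            continue
        first = np.arange(sl.start, sl.stop - k + 1)
        rows.append(pd.DataFrame({
            "chrom": chrom,
            "i0": first,
            "start": pos[first] - 1,
            "end": pos[first + k - 1],
        }))
    if not rows:
        return pd.DataFrame(columns=["chrom", "i0", "start", "end"])
    return pd.concat(rows, ignore_index=True)


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    """Tabular view of a DMR list (1-based inclusive coordinates)."""
    rows = []
    for d in dmrs:
        s1, e1 = d.span_1based()
        rows.append({
            "chrom": d.chrom, "start": s1, "end": e1, "n_cpgs": d.n_cpgs,
            "stat": d.stat, "p_region": d.p_region,
            "mean_delta_beta": d.mean_delta_beta, "direction": d.direction,
            "probes": ";".join(d.probe_ids),
        })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_cpgs", "stat",
                                       "p_region", "mean_delta_beta", "direction",
                                       "probes"])
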