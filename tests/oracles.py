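"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a pipeline quantity by direct enumeration or explicit
per-unit algebra, sharing no code path with the implementation it checks.
"""

from itertools import product

import numpy as np
from scipy import stats

from dmrperm.datatypes import DMR


def brute_force_dmrs(assoc, cpg_map, alpha_cpg=0.05, max_gap=1000,
                     min_cpgs=2, alpha_dmr=0.01):
    """Test every contiguous probe interval directly for the DMR conditions:
    all probes seeded, internal gaps within max_gap, maximal on both sides,
    length and region-p thresholds."""
    sub = assoc.loc[cpg_map.probe_ids]
    z = sub["z"].to_numpy(float)
    p = sub["p"].to_numpy(float)
    db = sub["delta_beta"].to_numpy(float)
    pos = cpg_map.table["pos"].to_numpy()
    probes = cpg_map.table["probe_id"].to_numpy()
    seed = p < alpha_cpg
    out = []
    for chrom in cpg_map.chromosomes:
        sl = cpg_map.chrom_slice(chrom)
        for i in range(sl.start, sl.stop):
            if not seed[i]:
                continue
            for j in range(i, sl.stop):
                if not seed[j] or (j > i and pos[j] - pos[j - 1] > max_gap):
                    break
                left_max = (i == sl.start or not seed[i - 1]
                            or pos[i] - pos[i - 1] > max_gap)
                right_max = (j == sl.stop - 1 or not seed[j + 1]
                             or pos[j + 1] - pos[j] > max_gap)
                k = j - i + 1
                if left_max and right_max and k >= min_cpgs:
                    S = z[i:j + 1].sum() / np.sqrt(k)
                    p_region = 2.0 * stats.norm.sf(abs(S))
                    if p_region < alpha_dmr:
                        mdb = float(db[i:j + 1].mean())
                        out.append(DMR(chrom=chrom, start=int(pos[i]) - 1,
                                       end=int(pos[j]),
                                       probe_ids=tuple(probes[i:j + 1]),
                                       stat=float(S), p_region=float(p_region),
                                       mean_delta_beta=mdb,
                                       direction="hypo" if mdb < 0 else "hyper"))
    return out


def wilcoxon_two_sided_by_enumeration(d):
    """Exact two-sided signed-rank p by enumerating all 2^n sign vectors.

    Zero differences dropped; tied |d| get average ranks. The two-sided rule
    is p = min(1, 2*min(P(W <= w), P(W >= w))) over the enumeration.
    """
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks2 = np.round(2 * stats.rankdata(np.abs(d))).astype(int)
    w_obs = int(ranks2[d > 0].sum())
    ws = [sum(r for r, s in zip(ranks2, signs) if s)
          for signs in product((0, 1), repeat=n)]
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs)
    p_ge = np.mean(ws >= w_obs)
    return min(1.0, 2.0 * min(p_le, p_ge))


def ols_t_by_normal_equations(X, y, j):
    """t statistic of coefficient j by explicit normal-equations algebra."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(sigma2 * np.linalg.inv(XtX)[j, j])
    return beta[j] / se


def simplex_grid_proportions(R, b, step=0.02):
    """Brute-force 3-type deconvolution: exhaustive simplex grid search."""
    best, best_r = None, np.inf
    ticks = np.arange(0.0, 1.0 + step / 2, step)
    for w1 in ticks:
        for w2 in ticks:
            w3 = 1.0 - w1 - w2
            if w3 < -1e-12:
                continue
            w = np.array([w1, w2, max(w3, 0.0)])
            r = float(np.sum((R @ w - b) ** 2))
            if r < best_r:
                best, best_r = w, r
    return best, best_r


def exact_overlap_probability(cpg_map, k_a, k_b, concordant=True,
                              dir_a="hypo", dir_b="hypo"):
    """Probability that two independently, uniformly placed windows (of k_a
    and k_b CpGs) overlap by >= 1 bp, by enumerating every placement pair."""
    from dmrperm.dmr import enumerate_windows

    wa = enumerate_windows(cpg_map, k_a)
    wb = enumerate_windows(cpg_map, k_b)
    if concordant and dir_a != dir_b:
        return 0.0
    hits = 0
    for _, ra in wa.iterrows():
        for _, rb in wb.iterrows():
            if ra["chrom"] == rb["chrom"] and ra["start"] < rb["end"] \
                    and rb["start"] < ra["end"]:
                hits += 1
    return hits / (len(wa) * len(wb))
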