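"""Per-CpG association testing for the two arms.

* cohort arm: mass-univariate ordinary least squares of M values on the
  exposure plus adjustment covariates, two-sided t test on the exposure
  coefficient;
* paired arm: exact Wilcoxon signed-rank test on within-donor M differences
  (full enumeration of the signed-rank distribution for up to 25 informative
  pairs, normal approximation with continuity and tie correction above).

Both produce an **association table** (``AssocTable``): a DataFrame indexed
by probe with columns ``effect`` (exposure coefficient or median paired
difference, M scale), ``delta_beta`` (exposed/deprived minus control mean
beta), ``z`` (signed probit of p/2), ``p`` (two-sided) and ``direction``
('hypo' iff delta_beta < 0).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datatypes import CpGMap
from .qc import m_to_beta

__all__ = [
    "MassUnivariateOLS",
    "PairedWilcoxon",
    "fit_cpg_regression",
    "paired_wilcoxon",
    "nominal_loci",
    "inflation_lambda",
    "qq_points",
    "make_design",
]

_P_FLOOR = 1e-300


def _signed_z(effect: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Signed normal-scale statistic: z = sign(effect) * Phi^-1(1 - p/2)."""
    z = stats.norm.isf(np.clip(p, _P_FLOOR, 1.0) / 2.0)
    return np.where(effect < 0, -z, z)


def make_design(cov_table: pd.DataFrame, drop_cell: str | None = "last",
                cell_columns: list[str] | None = None) -> pd.DataFrame:
    """Regression design from a covariate table.

    One cell-proportion column is dropped (default: the last, conventionally
    the dominant granulocyte fraction) because the proportions sum to one and
    would otherwise be collinear with the intercept.
    """
    design = cov_table.copy()
    if cell_columns is None:
        cell_columns = [c for c in design.columns
                        if c not in ("exposure", "age", "sex", "smoking_score")
                        and not c.startswith("PC")]
    if drop_cell is not None and cell_columns:
        col = cell_columns[-1] if drop_cell == "last" else drop_cell
        design = design.drop(columns=[col])
    return design


class MassUnivariateOLS(BaseEstimator):
    """Vectorised per-probe OLS with a t test on the exposure coefficient.

    ``fit(X, Y)`` takes the design ``X`` (samples x covariates, an intercept
    is added internally) and the response ``Y`` (samples x probes, M scale).
    An optional beta matrix provides the group-mean delta_beta; otherwise
    betas are recovered from ``Y`` via the inverse M transform.

    Fitted attributes: ``results_`` (the association table), ``dof_``,
    ``coef_`` (exposure coefficients).
    """

    def __init__(self, exposure_col: str = "exposure"):
        self.exposure_col = exposure_col

    def fit(self, X: pd.DataFrame, Y: pd.DataFrame, betas: pd.DataFrame | None = None):
        if self.exposure_col not in X.columns:
            raise ValueError(f"design lacks an {self.exposure_col!r} column")
        if not X.index.equals(Y.index):
            raise ValueError("design and response must share sample indexing")
        expo = X[self.exposure_col].to_numpy(dtype=float)
        if np.ptp(expo) == 0:
            raise ValueError("exposure column is constant: no contrast to test")
        Xm = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
        n, p = Xm.shape
        if n <= p:
            raise ValueError("need more samples than design columns")
        if np.linalg.matrix_rank(Xm) < p:
            raise ValueError("rank-deficient design (collinear covariates?)")
        j = 1 + list(X.columns).index(self.exposure_col)

        Ym = Y.to_numpy(dtype=float).T  # probes x samples
        XtX_inv = np.linalg.inv(Xm.T @ Xm)
        coefs = Ym @ (Xm @ XtX_inv)  # probes x p
        resid = Ym - coefs @ Xm.T
        dof = n - p
        sigma2 = np.einsum("ij,ij->i", resid, resid) / dof
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(sigma2 * XtX_inv[j, j])
            t = coefs[:, j] / se
        pvals = 2.0 * stats.t.sf(np.abs(t), dof)
        pvals = np.clip(pvals, _P_FLOOR, 1.0)

        constant = Ym.std(axis=1) == 0
        perfect = (~constant) & (sigma2 == 0)
        pvals[perfect] = _P_FLOOR
        effect = coefs[:, j].copy()
        effect[constant] = 0.0
        pvals[constant] = 1.0

        if betas is None:
            B = m_to_beta(Ym)
        else:
            if not betas.index.equals(Y.index):
                raise ValueError("beta matrix must share the sample index of Y")
            B = betas.to_numpy(dtype=float).T
        grp1 = expo > 0
        delta_beta = B[:, grp1].mean(axis=1) - B[:, ~grp1].mean(axis=1)

        res = pd.DataFrame({
            "effect": effect,
            "delta_beta": delta_beta,
            "z": _signed_z(effect, pvals),
            "p": pvals,
            "direction": np.where(delta_beta < 0, "hypo", "hyper"),
            "flag": np.where(constant, "constant", ""),
        }, index=pd.Index(Y.columns, name="probe_id"))
        res.loc[constant, "z"] = 0.0
        self.results_ = res
        self.dof_ = dof
        self.coef_ = effect
        self.t_ = t
        return self


# ---------------------------------------------------------------------------
# exact Wilcoxon signed-rank machinery


@lru_cache(maxsize=64)
def _signed_rank_cdf_untied(n: int) -> np.ndarray:
    """CDF of 2*W+ for n untied pairs (support 0..n(n+1)), by convolution."""
    total = n * (n + 1)  # sum of doubled ranks 2,4,...,2n
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r2 in range(2, 2 * n + 1, 2):
        shifted = np.zeros_like(counts)
        shifted[r2:] = counts[: total + 1 - r2]
        counts = counts + shifted
    cdf = np.cumsum(counts) / counts.sum()
    return cdf


def _signed_rank_cdf(ranks2: np.ndarray) -> np.ndarray:
    """CDF of 2*W+ for the given doubled (possibly tied/half-integer) ranks."""
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r2 in ranks2:
        r2 = int(r2)
        shifted = np.zeros_like(counts)
        shifted[r2:] = counts[: total + 1 - r2]
        counts = counts + shifted
    return np.cumsum(counts) / counts.sum()


def _two_sided_from_cdf(cdf: np.ndarray, w2: int) -> float:
    p_le = cdf[w2]
    p_ge = 1.0 - (cdf[w2 - 1] if w2 > 0 else 0.0)
    return min(1.0, 2.0 * min(p_le, p_ge))


def _wilcoxon_exact_p(d: np.ndarray, exact_max_n: int = 25) -> tuple[float, bool]:
    """Two-sided signed-rank p for one probe's paired differences.

    Returns (p, degenerate) where degenerate marks an all-zero difference
    vector. Zero differences are dropped; ties get average ranks.
    """
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0, True
    ranks = stats.rankdata(np.abs(d))
    w2 = int(round(2.0 * ranks[d > 0].sum()))
    if n <= exact_max_n:
        r2 = np.round(2.0 * ranks).astype(int)
        if np.array_equal(np.sort(r2), np.arange(2, 2 * n + 1, 2)):
            cdf = _signed_rank_cdf_untied(n)
        else:
            cdf = _signed_rank_cdf(r2)
        return _two_sided_from_cdf(cdf, w2), False
    # normal approximation with tie correction and continuity correction
    w = w2 / 2.0
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    z = (w - mu - 0.5 * np.sign(w - mu)) / np.sqrt(var)
    return min(1.0, 2.0 * stats.norm.sf(abs(z))), False


class PairedWilcoxon(BaseEstimator):
    """Exact paired signed-rank testing, one test per probe.

    ``fit(X_normal, X_deprived)`` takes two donors x probes M-value matrices
    with identical row (donor) and column (probe) indexing. The effect is the
    median within-donor difference; delta_beta is the mean within-donor beta
    difference (deprived minus normal).
    """

    def __init__(self, exact_max_n: int = 25):
        self.exact_max_n = exact_max_n

    def fit(self, X_normal: pd.DataFrame, X_deprived: pd.DataFrame):
        if not X_normal.index.equals(X_deprived.index) or \
                not X_normal.columns.equals(X_deprived.columns):
            raise ValueError("paired matrices must share donor and probe indexing")
        if X_normal.shape[0] < 2:
            raise ValueError("need at least 2 pairs")
        D = (X_deprived.to_numpy(dtype=float) - X_normal.to_numpy(dtype=float)).T
        G, n = D.shape
        pvals = np.empty(G)
        degenerate = np.zeros(G, dtype=bool)

        # fast path: untied, zero-free rows share one exact distribution
        has_zero = np.any(D == 0, axis=1)
        sorted_abs = np.sort(np.abs(D), axis=1)
        has_tie = np.any(np.diff(sorted_abs, axis=1) == 0, axis=1)
        fast = (~has_zero) & (~has_tie) & (n <= self.exact_max_n)
        if fast.any():
            cdf = _signed_rank_cdf_untied(n)
            ranks = stats.rankdata(np.abs(D[fast]), axis=1)
            w2 = np.round(2.0 * np.where(D[fast] > 0, ranks, 0.0).sum(axis=1)).astype(int)
            p_le = cdf[w2]
            p_ge = 1.0 - np.where(w2 > 0, cdf[np.maximum(w2 - 1, 0)], 0.0)
            pvals[fast] = np.minimum(1.0, 2.0 * np.minimum(p_le, p_ge))
        for i in np.flatnonzero(~fast):
            pvals[i], degenerate[i] = _wilcoxon_exact_p(D[i], self.exact_max_n)

        effect = np.median(D, axis=1)
        B_dep = m_to_beta(X_deprived.to_numpy(dtype=float)).T
        B_norm = m_to_beta(X_normal.to_numpy(dtype=float)).T
        delta_beta = (B_dep - B_norm).mean(axis=1)
        res = pd.DataFrame({
            "effect": effect,
            "delta_beta": delta_beta,
            "z": _signed_z(effect, pvals),
            "p": pvals,
            "direction": np.where(delta_beta < 0, "hypo", "hyper"),
            "flag": np.where(degenerate, "all_zero", ""),
        }, index=pd.Index(X_normal.columns, name="probe_id"))
        res.loc[degenerate, "z"] = 0.0
        self.results_ = res
        self.n_pairs_ = n
        return self


# ---------------------------------------------------------------------------
# function wrappers (probes x samples orientation) and diagnostics


def _attach_coords(res: pd.DataFrame, cpg_map: CpGMap | None) -> pd.DataFrame:
    if cpg_map is None:
        return res
    coords = cpg_map.table.set_index("probe_id")[["chrom", "pos"]]
    out = coords.join(res, how="inner")
    out.index.name = "probe_id"
    return out


def fit_cpg_regression(M: pd.DataFrame, design: pd.DataFrame,
                       betas: pd.DataFrame | None = None,
                       cpg_map: CpGMap | None = None,
                       exposure_col: str = "exposure") -> pd.DataFrame:
    """Cohort-arm association table from a probes x samples M matrix and a
    samples x covariates design (must include the exposure column)."""
    est = MassUnivariateOLS(exposure_col=exposure_col)
    est.fit(design, M.T, betas=None if betas is None else betas.T)
    return _attach_coords(est.results_, cpg_map)


def paired_wilcoxon(M_normal: pd.DataFrame, M_deprived: pd.DataFrame,
                    pairing: dict[str, str] | None = None,
                    cpg_map: CpGMap | None = None) -> pd.DataFrame:
    """Paired-arm association table from probes x samples M matrices.

    ``pairing`` maps normal-column -> deprived-column; by default columns are
    paired positionally.
    """
    if pairing is not None:
        norm_cols = list(pairing.keys())
        dep_cols = [pairing[c] for c in norm_cols]
        missing = (set(norm_cols) - set(M_normal.columns)) | (set(dep_cols) - set(M_deprived.columns))
        if missing:
            raise ValueError(f"unpaired columns: {sorted(missing)}")
        M_normal = M_normal[norm_cols]
        M_deprived = M_deprived[dep_cols]
    if M_normal.shape[1] != M_deprived.shape[1]:
        raise ValueError("conditions must have the same number of columns")
    Xn = M_normal.T
    Xd = M_deprived.T
    Xd.index = Xn.index  # donors align positionally once paired
    est = PairedWilcoxon().fit(Xn, Xd)
    return _attach_coords(est.results_, cpg_map)


def nominal_loci(assoc: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Rows of the association table with p < alpha (direction retained)."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    return assoc[assoc["p"] < alpha]


def inflation_lambda(assoc: pd.DataFrame) -> float:
    """Genomic inflation: median observed chi2(1) quantile over its expected
    value under uniform p (0.4549...)."""
    p = assoc["p"].to_numpy(dtype=float)
    if p.size < 10:
        raise ValueError("need at least 10 probes for a stable lambda")
    observed = stats.chi2.isf(np.clip(p, _P_FLOOR, 1.0), df=1)
    return float(np.median(observed) / stats.chi2.isf(0.5, df=1))


def qq_points(assoc: pd.DataFrame) -> pd.DataFrame:
    """Ordered (expected, observed) -log10 p pairs for a QQ plot."""
    p = np.sort(assoc["p"].to_numpy(dtype=float))
    n = p.size
    expected = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame({
        "expected": -np.log10(expected),
        "observed": -np.log10(np.clip(p, _P_FLOOR, 1.0)),
    })


def plot_qq(assoc: pd.DataFrame, ax=None):  # pragma: no cover - thin plotting shim
    """QQ plot of the association p values (requires matplotlib)."""
    import matplotlib.pyplot as plt

    pts = qq_points(assoc)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(pts["expected"], pts["observed"], s=4)
    lim = pts["expected"].max()
    ax.plot([0, lim], [0, lim], color="grey", lw=1)
    ax.set_xlabel("expected $-\\log_{10} p$")
    ax.set_ylabel("observed $-\\log_{10} p$")
    ax.set_title(f"lambda = {inflation_lambda(assoc):.3f}")
    return ax
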