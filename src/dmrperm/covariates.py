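"""Adjustment covariates for the cohort regression.

Three methylation-derived covariates are inferred from the beta matrix:

* **cell-type proportions** by constrained projection onto reference
  profiles (non-negative weights summing to one, least squares), the
  standard reference-based deconvolution of whole-blood methylomes;
* **ancestry principal components** from the probes near common SNPs,
  where genotype leaks into apparent methylation;
* a **smoking proxy score**, a weighted sum of M values over CpGs known to
  respond to smoking (weights supplied by the caller).

Estimators follow scikit-learn conventions and take ``X`` as samples x
probes; the module-level functions accept the package's native probes x
samples orientation.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import CellReference
from .qc import beta_to_m

__all__ = [
    "CellTypeDeconvolver",
    "AncestryPCA",
    "estimate_cell_proportions",
    "ancestry_pcs",
    "smoking_score",
    "build_covariate_table",
]


def _constrained_ls(R: np.ndarray, b: np.ndarray) -> np.ndarray:
    """min ||R w - b||^2  s.t.  w >= 0, sum(w) = 1 (simplex-constrained LS)."""
    k = R.shape[1]
    RtR = R.T @ R
    Rtb = R.T @ b

    def obj(w):
        r = RtR @ w - Rtb
        return 0.5 * float(w @ RtR @ w) - float(Rtb @ w), RtR @ w - Rtb

    res = minimize(obj, np.full(k, 1.0 / k), jac=True, method="SLSQP",
                   bounds=[(0.0, 1.0)] * k,
                   constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                                 "jac": lambda w: np.ones(k)}],
                   options={"maxiter": 500, "ftol": 1e-14})
    w = np.clip(res.x, 0.0, None)
    return w / w.sum()


class CellTypeDeconvolver(BaseEstimator, TransformerMixin):
    """Reference-based cell-mixture deconvolution.

    Parameters
    ----------
    reference : CellReference
        Beta-scale profiles (probes x cell types).

    After :meth:`fit`, ``probe_ids_`` holds the reference probes found in the
    data and ``reference_matrix_`` the matching profile matrix. ``transform``
    returns one simplex weight vector per sample.
    """

    def __init__(self, reference: CellReference):
        self.reference = reference

    def fit(self, X: pd.DataFrame, y=None):
        probes = [p for p in self.reference.probe_ids if p in set(X.columns)]
        k = len(self.reference.cell_names)
        if len(probes) < k:
            raise ValueError("need at least as many reference probes as cell types")
        R = self.reference.profiles.loc[probes].to_numpy()
        if np.linalg.matrix_rank(R) < k:
            raise ValueError("rank-deficient reference: profiles are not distinguishable")
        self.probe_ids_ = probes
        self.reference_matrix_ = R
        self.cell_names_ = list(self.reference.cell_names)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        B = X.loc[:, self.probe_ids_].to_numpy()
        W = np.vstack([_constrained_ls(self.reference_matrix_, b) for b in B])
        return pd.DataFrame(W, index=X.index, columns=self.cell_names_)


class AncestryPCA(BaseEstimator, TransformerMixin):
    """Principal components of methylation at SNP-proximal probes.

    Betas at the listed probes are centred per probe and decomposed by SVD;
    the first ``n_components`` sample scores act as ancestry indicators.
    Each component's sign is fixed so that its largest-magnitude probe
    loading is positive.
    """

    def __init__(self, probe_ids: Sequence[str], n_components: int = 2):
        self.probe_ids = probe_ids
        self.n_components = n_components

    def fit(self, X: pd.DataFrame, y=None):
        if len(self.probe_ids) == 0:
            raise ValueError("empty SNP-proximal probe list")
        present = [p for p in self.probe_ids if p in set(X.columns)]
        k = self.n_components
        if len(present) < max(k, 1):
            raise ValueError("fewer listed probes present than components requested")
        if X.shape[0] < k + 1:
            raise ValueError("need at least n_components + 1 samples")
        self.probes_ = present
        sub = X.loc[:, present].to_numpy(dtype=float)
        self.mean_ = sub.mean(axis=0)
        if k == 0:
            self.components_ = np.empty((0, len(present)))
            self.singular_values_ = np.empty(0)
            return self
        U, s, Vt = np.linalg.svd(sub - self.mean_, full_matrices=False)
        comps = Vt[:k]
        signs = np.sign(comps[np.arange(k), np.argmax(np.abs(comps), axis=1)])
        signs[signs == 0] = 1.0
        self.components_ = comps * signs[:, None]
        self.singular_values_ = s[:k]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        sub = X.loc[:, self.probes_].to_numpy(dtype=float) - self.mean_
        scores = sub @ self.components_.T
        cols = [f"PC{i + 1}" for i in range(self.components_.shape[0])]
        return pd.DataFrame(scores, index=X.index, columns=cols)


def estimate_cell_proportions(betas: pd.DataFrame, reference: CellReference) -> pd.DataFrame:
    """Per-sample cell proportions from a probes x samples beta matrix."""
    est = CellTypeDeconvolver(reference).fit(betas.T)
    return est.transform(betas.T)


def ancestry_pcs(betas: pd.DataFrame, snp_proximal_ids: Iterable[str],
                 k: int = 2) -> pd.DataFrame:
    """First ``k`` ancestry PC scores from a probes x samples beta matrix."""
    est = AncestryPCA(list(snp_proximal_ids), n_components=k).fit(betas.T)
    return est.transform(betas.T)


def smoking_score(betas: pd.DataFrame, weights: pd.Series) -> pd.Series:
    """Weighted sum of M values over the weighted probes, one score per sample.

    Probes absent from the data are dropped with a warning; an empty
    intersection is an error.
    """
    present = [p for p in weights.index if p in set(betas.index)]
    if not present:
        raise ValueError("none of the weighted probes are present in the data")
    if len(present) < len(weights):
        warnings.warn(f"{len(weights) - len(present)} weighted probes missing; dropped",
                      stacklevel=2)
    M = beta_to_m(betas.loc[present])
    score = M.T.to_numpy() @ weights.loc[present].to_numpy()
    return pd.Series(score, index=betas.columns, name="smoking_score")


def build_covariate_table(betas: pd.DataFrame, sample_sheet: pd.DataFrame,
                          reference: CellReference, smoking_weights: pd.Series,
                          ancestry_probe_ids: Iterable[str], n_pcs: int = 2) -> pd.DataFrame:
    """Assemble the full per-sample covariate table for the cohort regression:
    pass-through exposure/age/sex, estimated cell proportions, the first
    ``n_pcs`` ancestry PCs, and the smoking score."""
    props = estimate_cell_proportions(betas, reference)
    pcs = ancestry_pcs(betas, ancestry_probe_ids, k=n_pcs)
    score = smoking_score(betas, smoking_weights)
    table = sample_sheet.loc[betas.columns, ["exposure", "age", "sex"]].copy()
    for c in props.columns:
        table[c] = props[c]
    for c in pcs.columns:
        table[c] = pcs[c]
    table["smoking_score"] = score
    return table
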