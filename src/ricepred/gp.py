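"""Whole-genome prediction of scalar traits from biallelic marker codes.

Four methods: ridge regression (RR) and LASSO on marker effects with the
penalty tuned by seeded internal k-fold CV; GBLUP, a mixed model on the
additive genomic relationship matrix with variance components estimated by
spectral REML; and RKHS, Gaussian-kernel ridge with a median-heuristic
bandwidth.  Genotypes are coded +1 / −1 for the two parental homozygotes
and 0 for heterozygotes, the natural additive coding for a biparental RIL
population.  Narrow-sense heritability is the GBLUP variance-component
ratio σ²_g / (σ²_g + σ²_e).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.linear_model import Lasso, LassoCV, Ridge
from sklearn.model_selection import KFold

METHODS = ("rr", "lasso", "gblup", "rkhs")


@dataclass
class MarkerMatrix:
    """Lines × markers genotype matrix with map metadata.

    codes: +1 (parent-A homozygote), −1 (parent-B homozygote), 0 (het);
    fractional values arise from mean imputation of missing cells.
    """

    line_ids: list[str]
    marker_ids: list[str]
    chromosome: np.ndarray
    position: np.ndarray  # genetic position, cM
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.line_ids = list(self.line_ids)
        self.marker_ids = list(self.marker_ids)
        self.codes = np.asarray(self.codes, dtype=float)
        self.chromosome = np.asarray(self.chromosome)
        self.position = np.asarray(self.position, dtype=float)
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("duplicate line ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")
        if self.codes.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError("codes shape does not match ids")
        if np.any(np.abs(self.codes) > 1 + 1e-9):
            raise ValueError("codes must lie in [-1, +1]")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def subset(self, line_ids: list[str]) -> "MarkerMatrix":
        lookup = {l: i for i, l in enumerate(self.line_ids)}
        missing = [l for l in line_ids if l not in lookup]
        if missing:
            raise KeyError(f"unknown line ids: {missing[:5]}")
        idx = [lookup[l] for l in line_ids]
        return MarkerMatrix(list(line_ids), self.marker_ids,
                            self.chromosome, self.position, self.codes[idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.codes, index=self.line_ids,
                          columns=self.marker_ids)
        df.index.name = "line"
        return df


def additive_relationship(markers: MarkerMatrix,
                          return_parts: bool = False):
    """VanRaden-style additive genomic relationship matrix.

    Columns are centered; zero-variance markers are dropped with a warning;
    A = X_c X_cᵀ / (trace(X_c X_cᵀ)/n), so the mean diagonal is exactly 1
    and σ²_g from the GBLUP mixed model is on the phenotypic-variance scale.
    """
    if markers.n_lines < 2:
        raise ValueError("need >= 2 lines")
    codes = markers.codes
    var = codes.var(axis=0)
    keep = var > 0
    if not keep.any():
        raise ValueError("no informative markers (all zero-variance)")
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} zero-variance marker(s)")
    x = codes[:, keep]
    xc = x - x.mean(axis=0)
    g = xc @ xc.T
    normalizer = np.trace(g) / markers.n_lines
    a = g / normalizer
    if return_parts:
        return a, x.mean(axis=0), normalizer, keep
    return a


@dataclass
class FittedGPModel:
    """A fitted genomic-prediction model for one trait."""

    method: str
    intercept: float
    line_ids: list[str]
    marker_ids: list[str]
    marker_effects: Optional[np.ndarray] = None   # rr / lasso
    penalty: Optional[float] = None
    # kernel methods
    train_codes: Optional[np.ndarray] = None
    col_means: Optional[np.ndarray] = None
    keep_mask: Optional[np.ndarray] = None
    normalizer: Optional[float] = None
    bandwidth: Optional[float] = None
    dual_coef: Optional[np.ndarray] = None
    sigma2_g: Optional[float] = None
    sigma2_e: Optional[float] = None
    fitted_values: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        out = {"method": self.method, "intercept": self.intercept,
               "penalty": self.penalty, "sigma2_g": self.sigma2_g,
               "sigma2_e": self.sigma2_e, "bandwidth": self.bandwidth}
        if self.marker_effects is not None:
            out["marker_effects"] = dict(zip(self.marker_ids,
                                             self.marker_effects.tolist()))
        return out


def _cv_penalty(x: np.ndarray, y: np.ndarray, alphas: np.ndarray,
                model_cls, folds: int, seed: int) -> float:
    """Plain minimum-MSE penalty over a grid by seeded k-fold CV."""
    kf = KFold(n_splits=min(folds, len(y)), shuffle=True, random_state=seed)
    mse = np.zeros(len(alphas))
    for tr, te in kf.split(x):
        for j, a in enumerate(alphas):
            m = model_cls(alpha=a, max_iter=50000)
            m.fit(x[tr], y[tr])
            mse[j] += np.mean((m.predict(x[te]) - y[te]) ** 2)
    return float(alphas[int(np.argmin(mse))])


def _reml_gblup(a: np.ndarray, y: np.ndarray) -> tuple[float, float, float,
                                                       np.ndarray]:
    """Spectral REML for y = 1μ + g + e, g ~ N(0, σ²_g A), e ~ N(0, σ²_e I).

    Profile restricted likelihood over δ = σ²_g/σ²_e using one
    eigendecomposition of A.  Returns (μ, σ²_g, σ²_e, BLUP ĝ).
    """
    n = len(y)
    d, u = np.linalg.eigh(a)
    d = np.clip(d, 0.0, None)
    yt = u.T @ y
    xt = u.T @ np.ones(n)

    def neg_reml(log10_delta: float) -> float:
        delta = 10.0 ** log10_delta
        w = delta * d + 1.0
        xvx = np.sum(xt ** 2 / w)
        beta = np.sum(xt * yt / w) / xvx
        r = yt - xt * beta
        rss = np.sum(r ** 2 / w)
        s2e = rss / (n - 1)
        return 0.5 * ((n - 1) * np.log(s2e) + np.sum(np.log(w))
                      + np.log(xvx))

    res = minimize_scalar(neg_reml, bounds=(-6.0, 6.0), method="bounded",
                          options={"xatol": 1e-8})
    if not res.success:
        raise RuntimeError(f"REML optimization failed: {res}")
    delta = 10.0 ** res.x
    w = delta * d + 1.0
    xvx = np.sum(xt ** 2 / w)
    mu = float(np.sum(xt * yt / w) / xvx)
    r = yt - xt * mu
    s2e = float(np.sum(r ** 2 / w) / (n - 1))
    s2g = float(delta * s2e)
    # BLUP: ĝ = δ A V0⁻¹ (y − μ) with V0 = δA + I
    ghat = u @ (delta * d * (r / w))
    return mu, s2g, s2e, ghat


def fit_gp(markers: MarkerMatrix, y, method: str = "lasso",
           cv_folds: int = 5, seed: int = 0,
           penalty: float | None = None) -> FittedGPModel:
    """Fit a genomic-prediction model for one trait.

    Missing phenotypes are dropped pairwise.  For RR/LASSO the penalty is
    chosen by seeded internal CV minimizing MSE unless ``penalty`` is given
    explicitly (used by tests and for reproducing closed-form limits).
    """
    method = method.lower()
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < 10:
        raise ValueError("need >= 10 non-missing phenotypes")
    sub = markers.subset([l for l, m in zip(markers.line_ids, ok) if m])
    y = y[ok]

    if np.ptp(y) == 0:
        warnings.warn("constant phenotype: returning intercept-only model")
        return FittedGPModel(method, float(y[0]), sub.line_ids,
                             sub.marker_ids,
                             marker_effects=np.zeros(sub.n_markers),
                             col_means=sub.codes.mean(axis=0),
                             fitted_values=np.full(len(y), y[0]))

    if method == "lasso":
        x = sub.codes
        if penalty is None:
            kf = KFold(n_splits=min(cv_folds, len(y)), shuffle=True,
                       random_state=seed)
            m = LassoCV(alphas=40, cv=kf, max_iter=50000, precompute=True)
            m.fit(x, y)
            penalty = float(m.alpha_)
        else:
            m = Lasso(alpha=penalty, max_iter=50000)
            m.fit(x, y)
        return FittedGPModel(method, float(m.intercept_), sub.line_ids,
                             sub.marker_ids, marker_effects=m.coef_.copy(),
                             penalty=float(penalty),
                             fitted_values=m.predict(x))

    if method == "rr":
        x = sub.codes
        if penalty is None:
            penalty = _cv_penalty(x, y, np.logspace(-3, 5, 40), Ridge,
                                  cv_folds, seed)
        m = Ridge(alpha=penalty)
        m.fit(x, y)
        return FittedGPModel(method, float(m.intercept_), sub.line_ids,
                             sub.marker_ids, marker_effects=m.coef_.copy(),
                             penalty=float(penalty),
                             fitted_values=m.predict(x))

    if method == "gblup":
        a, col_means, normalizer, keep = additive_relationship(
            sub, return_parts=True)
        mu, s2g, s2e, ghat = _reml_gblup(a, y)
        delta = s2g / s2e if s2e > 0 else np.inf
        d, u = np.linalg.eigh(a)
        w = delta * np.clip(d, 0, None) + 1.0
        dual = u @ ((u.T @ (y - mu)) / w) * delta  # δ V0⁻¹ (y−μ)
        return FittedGPModel(method, mu, sub.line_ids, sub.marker_ids,
                             train_codes=sub.codes[:, keep],
                             col_means=col_means, keep_mask=keep,
                             normalizer=normalizer, dual_coef=dual,
                             sigma2_g=s2g, sigma2_e=s2e,
                             fitted_values=mu + ghat)

    # rkhs: Gaussian-kernel ridge, median-heuristic bandwidth
    x = sub.codes
    sq = _sq_dists(x, x)
    off = sq[np.triu_indices_from(sq, k=1)]
    bandwidth = float(np.median(off[off > 0])) if np.any(off > 0) else 1.0
    k = np.exp(-sq / bandwidth)
    if penalty is None:
        grid = np.logspace(-4, 2, 30)
        penalty = _cv_kernel_penalty(k, y, grid, cv_folds, seed)
    yc = y - y.mean()
    dual = np.linalg.solve(k + penalty * np.eye(len(y)), yc)
    return FittedGPModel("rkhs", float(y.mean()), sub.line_ids,
                         sub.marker_ids, train_codes=x,
                         bandwidth=bandwidth, dual_coef=dual,
                         penalty=float(penalty),
                         fitted_values=float(y.mean()) + k @ dual)


def _sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.maximum(
        (a ** 2).sum(1)[:, None] + (b ** 2).sum(1)[None, :] - 2 * a @ b.T,
        0.0)


def _cv_kernel_penalty(k: np.ndarray, y: np.ndarray, grid: np.ndarray,
                       folds: int, seed: int) -> float:
    kf = KFold(n_splits=min(folds, len(y)), shuffle=True, random_state=seed)
    mse = np.zeros(len(grid))
    for tr, te in kf.split(y):
        ktr = k[np.ix_(tr, tr)]
        kte = k[np.ix_(te, tr)]
        yc = y[tr] - y[tr].mean()
        for j, lam in enumerate(grid):
            dual = np.linalg.solve(ktr + lam * np.eye(len(tr)), yc)
            pred = y[tr].mean() + kte @ dual
            mse[j] += np.mean((pred - y[te]) ** 2)
    return float(grid[int(np.argmin(mse))])


def predict_gp(model: FittedGPModel, markers_new: MarkerMatrix) -> np.ndarray:
    """Predict the trait for new lines; marker sets must match training."""
    if list(markers_new.marker_ids) != list(model.marker_ids):
        missing = set(model.marker_ids) - set(markers_new.marker_ids)
        raise ValueError(f"marker mismatch; missing from new set: "
                         f"{sorted(missing)[:5]}")
    x = markers_new.codes
    if model.method in ("rr", "lasso"):
        return model.intercept + x @ model.marker_effects
    if model.method == "gblup":
        if model.dual_coef is None:  # intercept-only fallback
            return np.full(markers_new.n_lines, model.intercept)
        xc_new = x[:, model.keep_mask] - model.col_means
        xc_tr = model.train_codes - model.col_means
        a_cross = xc_new @ xc_tr.T / model.normalizer
        return model.intercept + a_cross @ model.dual_coef
    if model.method == "rkhs":
        if model.dual_coef is None:
            return np.full(markers_new.n_lines, model.intercept)
        k_cross = np.exp(-_sq_dists(x, model.train_codes) / model.bandwidth)
        return model.intercept + k_cross @ model.dual_coef
    raise ValueError(model.method)


def estimate_h2(markers: MarkerMatrix, y) -> float:
    """Narrow-sense heritability from the GBLUP REML variance components.

    h² = σ²_g / (σ²_g + σ²_e), clamped to [0, 1].  With the mean-diagonal-1
    relationship scaling, σ²_g is directly the additive variance on the
    phenotypic scale.
    """
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < 10:
        raise ValueError("need >= 10 non-missing phenotypes")
    sub = markers.subset([l for l, m in zip(markers.line_ids, ok) if m])
    a = additive_relationship(sub)
    _, s2g, s2e, _ = _reml_gblup(a, y[ok])
    if s2g + s2e <= 0:
        return 0.0
    return float(np.clip(s2g / (s2g + s2e), 0.0, 1.0))
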