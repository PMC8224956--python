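"""Kinship-corrected semidominant association scan.

Model
-----
Phenotype is coded 0 (wild type), 1 (heterozygous mutant), 2 (homozygous
mutant) and regressed on marker dosage under the linear mixed model

    y = 1*mu + g*beta + u + e,    u ~ N(0, sigma_g^2 K),  e ~ N(0, sigma_e^2 I)

where K is the VanRaden genomic relationship matrix built from the same
filtered marker set.  Variance components are estimated once by REML
under the null (no marker term) via eigendecomposition of K and a 1-D
search over the variance ratio lambda = sigma_g^2/sigma_e^2; every marker
is then tested by generalized least squares in the whitened coordinates
with lambda held fixed (the P3D / EMMAX approximation), giving a Wald
t-test on the dosage coefficient.  With lambda = 0 the scan reduces
exactly to ordinary least squares.

Multiple testing uses the effective number of independent tests
M_eff = (sum_i sqrt(lambda_i))^2 / sum_i lambda_i over the eigenvalues of
the marker correlation matrix (Galwey), and the family-wise threshold is
alpha / M_eff.  A Pearson chi-square segregation test against Mendelian
class ratios is included for pedigree sanity checks.

Missing dosages are mean-imputed per marker throughout (kinship,
correlation, and scan); negative eigenvalues from floating point are
clipped at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

__all__ = [
    "VarianceComponents", "compute_kinship", "fit_null_variance_components",
    "association_scan", "effective_tests", "fwer_threshold", "segregation_test",
    "mean_impute",
]

_P_FLOOR = 5e-324  # smallest positive double; keeps p in (0, 1]


def mean_impute(dosage: np.ndarray) -> np.ndarray:
    """Replace NaN dosages with their marker mean (columns all-NaN -> 0)."""
    g = np.array(dosage, float)
    mean = np.nanmean(np.where(np.isnan(g).all(axis=0), 0.0, g), axis=0)
    idx = np.where(np.isnan(g))
    g[idx] = mean[idx[1]]
    return g


def compute_kinship(dosage: np.ndarray) -> np.ndarray:
    """VanRaden genomic relationship matrix.

    Dosages (individuals x markers, NaN = missing) are mean-imputed,
    centred by twice the allele frequency, and cross-multiplied:
    K = W W' / (2 * sum_j p_j (1 - p_j)).  Monomorphic markers contribute
    nothing and trigger a warning.
    """
    g = np.asarray(dosage, float)
    if g.ndim != 2 or g.shape[0] < 2:
        raise ValueError("need a 2-D dosage matrix with at least 2 individuals")
    g = mean_impute(g)
    p = g.mean(axis=0) / 2.0
    poly = np.ptp(g, axis=0) > 0  # zero variance after imputation -> skip
    if not poly.any():
        raise ValueError("all markers monomorphic; kinship undefined")
    if not poly.all():
        warnings.warn(f"{int((~poly).sum())} monomorphic markers skipped in kinship")
    w = g[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    k = (w @ w.T) / denom
    return (k + k.T) / 2.0


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float

    @property
    def lam(self) -> float:
        return self.sigma_g2 / self.sigma_e2 if self.sigma_e2 > 0 else np.inf


def _reml_neg_loglik(log_lam: float, s: np.ndarray, yr: np.ndarray,
                     xr: np.ndarray) -> float:
    lam = 10.0 ** log_lam
    d = lam * s + 1.0
    n, p = xr.shape
    xtd = xr.T / d
    xtx = xtd @ xr
    beta = np.linalg.solve(xtx, xtd @ yr)
    r = yr - xr @ beta
    rss = float(np.sum(r * r / d))
    sigma2 = rss / (n - p)
    ll = -0.5 * ((n - p) * np.log(2 * np.pi * sigma2) + np.sum(np.log(d))
                 + np.linalg.slogdet(xtx)[1] + (n - p))
    return -ll


def fit_null_variance_components(
    y: np.ndarray, K: np.ndarray, bounds: tuple[float, float] = (1e-5, 1e5)
) -> tuple[VarianceComponents, dict]:
    """REML estimate of the variance ratio under the null (intercept-only).

    The profile REML log-likelihood is maximised over log10(lambda) on a
    grid spanning ``bounds``, refined by bounded scalar minimisation.
    Returns the components and the eigendecomposition context reused by
    the scan (P3D).
    """
    y = np.asarray(y, float)
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant; variance components undefined")
    K = np.asarray(K, float)
    n = len(y)
    if K.shape != (n, n):
        raise ValueError("kinship dimension mismatch")
    s, u = np.linalg.eigh((K + K.T) / 2.0)
    if s.min() < -1e-6 * max(1.0, s.max()):
        raise ValueError("kinship matrix is not PSD")
    s = np.clip(s, 0.0, None)
    yr = u.T @ y
    xr = u.T @ np.ones((n, 1))
    lo, hi = np.log10(bounds[0]), np.log10(bounds[1])
    grid = np.linspace(lo, hi, 61)
    vals = [_reml_neg_loglik(g, s, yr, xr) for g in grid]
    i = int(np.argmin(vals))
    a, b = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    opt = minimize_scalar(_reml_neg_loglik, bounds=(a, b), args=(s, yr, xr),
                          method="bounded")
    log_lam = float(opt.x) if opt.fun <= vals[i] else float(grid[i])
    lam = 10.0 ** log_lam
    d = lam * s + 1.0
    xtd = xr.T / d
    beta = np.linalg.solve(xtd @ xr, xtd @ yr)
    r = yr - xr @ beta
    sigma_e2 = float(np.sum(r * r / d)) / (n - xr.shape[1])
    vc = VarianceComponents(sigma_g2=lam * sigma_e2, sigma_e2=sigma_e2)
    return vc, {"s": s, "u": u, "lam": lam}


def association_scan(
    y: np.ndarray,
    dosage: np.ndarray,
    K: np.ndarray,
    marker_meta: pd.DataFrame | None = None,
    lam: float | None = None,
) -> pd.DataFrame:
    """Per-marker GLS scan with variance components fixed under the null.

    ``dosage`` is individuals x markers with NaN for missing (mean-imputed
    before testing).  ``lam`` overrides the REML variance ratio (0 forces
    the ordinary-least-squares scan).  Returns a DataFrame with beta, se,
    t, p per marker; markers monomorphic after imputation are reported
    with ``tested=False`` and NaN statistics.
    """
    y = np.asarray(y, float)
    g = np.asarray(dosage, float)
    n = len(y)
    if g.ndim != 2 or g.shape[0] != n or K.shape != (n, n):
        raise ValueError("dimension mismatch between phenotype, dosage, kinship")
    if lam is None:
        _, ctx = fit_null_variance_components(y, K)
    else:
        s, u = np.linalg.eigh((np.asarray(K, float) + np.asarray(K, float).T) / 2.0)
        ctx = {"s": np.clip(s, 0.0, None), "u": u, "lam": float(lam)}
    s, u, lam_hat = ctx["s"], ctx["u"], ctx["lam"]
    w = 1.0 / np.sqrt(lam_hat * s + 1.0)
    yt = w * (u.T @ y)
    ones_t = w * (u.T @ np.ones(n))
    g = mean_impute(g)
    tested = np.ptp(g, axis=0) > 0
    gt = (u.T @ g) * w[:, None]

    # closed-form 2-predictor GLS per marker: X = [whitened 1, whitened g]
    saa = ones_t @ ones_t
    sag = ones_t @ gt
    sgg = np.einsum("ij,ij->j", gt, gt)
    say = ones_t @ yt
    sgy = gt.T @ yt
    syy = yt @ yt
    det = saa * sgg - sag ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (saa * sgy - sag * say) / det
        alpha = (say - sag * beta) / saa
        rss = syy - alpha * say - beta * sgy
        rss = np.clip(rss, 0.0, None)
        dof = n - 2
        sigma2 = rss / dof
        se = np.sqrt(sigma2 * saa / det)
        tstat = beta / se
        p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    p = np.clip(p, _P_FLOOR, 1.0)
    out = pd.DataFrame({
        "beta": np.where(tested, beta, np.nan),
        "se": np.where(tested, se, np.nan),
        "t": np.where(tested, tstat, np.nan),
        "p": np.where(tested, p, np.nan),
        "tested": tested,
    })
    if marker_meta is not None:
        out = pd.concat([marker_meta.reset_index(drop=True), out], axis=1)
    return out


def effective_tests(dosage: np.ndarray) -> float:
    """Effective number of independent tests (Galwey).

    Eigenvalues lambda_i of the marker-marker correlation matrix of
    mean-imputed dosages (negatives clipped at 0) give
    M_eff = (sum sqrt(lambda_i))^2 / sum lambda_i, with 1 <= M_eff <= M.
    """
    g = mean_impute(np.asarray(dosage, float))
    g = g[:, np.ptp(g, axis=0) > 0]
    if g.shape[1] < 2:
        raise ValueError("need at least 2 polymorphic markers")
    c = np.corrcoef(g, rowvar=False)
    ev = np.clip(np.linalg.eigvalsh(c), 0.0, None)
    ev[ev < 1e-10 * ev.max()] = 0.0  # rank-deficiency noise
    return float(np.sum(np.sqrt(ev)) ** 2 / np.sum(ev))


def fwer_threshold(alpha: float, m_eff: float) -> float:
    """Per-marker p-value threshold controlling the family-wise error rate:
    alpha divided by the effective number of tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m_eff < 1:
        raise ValueError("effective number of tests must be >= 1")
    return alpha / m_eff


def segregation_test(observed, expected_ratio) -> tuple[float, float]:
    """Pearson chi-square test of class counts against a Mendelian ratio
    (e.g. 1:1 backcross, 1:2:1 intercross); df = classes - 1."""
    obs = np.asarray(observed, float)
    ratio = np.asarray(expected_ratio, float)
    if obs.shape != ratio.shape:
        raise ValueError("ratio length must match class count")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    if obs.sum() == 0:
        raise ValueError("all counts are zero")
    expected = obs.sum() * ratio / ratio.sum()
    chi2, p = stats.chisquare(obs, expected)
    return float(chi2), float(p)
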