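"""Per-CpG beta-binomial differential methylation with dispersion shrinkage.

The test compares one exposed group against the reference group at each
united locus. Methylated counts X_ij ~ BetaBin(N_ij, p_g, phi): phi is the
extra-binomial dispersion across biological replicates, estimated per
locus by a Williams-type method of moments and moderated toward the
genome-wide log-dispersion mean (empirical-Bayes shrinkage with d0 prior
pseudo-observations). Group proportions are compared with a Wald
statistic; p-values are two-sided normal and BH-FDR adjusted.

An optional sequencing-lane covariate path fits an arcsine-root
variance-stabilised weighted linear model (intercept + group + lane
dummies) and takes the Wald statistic of the group coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .meth_io import UnitedMatrix

__all__ = [
    "ShrinkagePrior",
    "estimate_site_dispersion",
    "fit_shrinkage_prior",
    "shrink",
    "dml_test",
    "adjust_bh",
]

logger = logging.getLogger(__name__)

EPS = 1e-4
DEFAULT_D0 = 20.0
PHI_MAX = 0.99


@dataclass
class ShrinkagePrior:
    """Log-scale dispersion prior: mean ``mu_logphi`` with weight ``d0``
    pseudo-observations."""

    mu_logphi: float
    d0: float = DEFAULT_D0

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ValueError("d0 must be > 0")


def estimate_site_dispersion(
    n_meth: np.ndarray, n_total: np.ndarray, groups: np.ndarray
) -> float:
    """Williams-type method-of-moments dispersion at a single locus.

    chi2 = sum_g sum_j (X_ij - N_ij p_g)^2 / (N_ij p_g (1 - p_g)) with
    continuity-stabilised group proportions p_g = (SX+0.5)/(SN+1);
    phi_raw = clamp((chi2 - (m - K)) / sum_j (N_ij - 1), 0, 0.99).
    """
    X = np.asarray(n_meth, dtype=float)
    N = np.asarray(n_total, dtype=float)
    groups = np.asarray(groups)
    ok = np.isfinite(N) & (N >= 1)
    X, N, groups = X[ok], N[ok], groups[ok]
    if len(X) < 2:
        raise ValueError("dispersion needs >= 2 samples with coverage")
    labels = pd.unique(groups)
    chi2 = 0.0
    for g in labels:
        sel = groups == g
        p = (X[sel].sum() + 0.5) / (N[sel].sum() + 1.0)
        chi2 += float(((X[sel] - N[sel] * p) ** 2 / (N[sel] * p * (1 - p))).sum())
    m, K = len(X), len(labels)
    denom = float((N - 1).sum())
    if denom <= 0 or m - K <= 0:  # no replication information
        return 0.0
    return float(np.clip((chi2 - (m - K)) / denom, 0.0, PHI_MAX))


def fit_shrinkage_prior(
    phi_raw: np.ndarray, d0: float = DEFAULT_D0, fallback_mu: float = np.log(0.05)
) -> ShrinkagePrior:
    """Empirical log-dispersion prior: mu = log(mean(phi_raw) + eps).

    The prior is centered on the arithmetic mean of the raw method-of-
    moments dispersions: many loci clamp at phi_raw = 0 (boundary
    proportions carry no dispersion information), so a geometric-mean
    center would collapse toward zero and anti-conservatively understate
    replicate variance. Falls back to ``fallback_mu`` when fewer than 100
    loci are available.
    """
    phi_raw = np.asarray(phi_raw, dtype=float)
    phi_raw = phi_raw[np.isfinite(phi_raw)]
    if len(phi_raw) < 100:
        return ShrinkagePrior(mu_logphi=float(fallback_mu), d0=d0)
    return ShrinkagePrior(mu_logphi=float(np.log(np.mean(phi_raw) + EPS)), d0=d0)


def shrink(phi_raw: np.ndarray, df: np.ndarray, prior: ShrinkagePrior) -> np.ndarray:
    """Moderate raw dispersions toward the prior on the log scale.

    log(phi + eps) is replaced by the precision-weighted average of the
    prior mean (weight d0) and the raw value (weight df = m - K).
    """
    phi_raw = np.asarray(phi_raw, dtype=float)
    df = np.maximum(np.asarray(df, dtype=float), 0.0)
    logphi = (prior.d0 * prior.mu_logphi + df * np.log(phi_raw + EPS)) / (prior.d0 + df)
    return np.clip(np.exp(logphi) - EPS, 0.0, PHI_MAX)


def _dispersion_vectorized(
    X1: np.ndarray, N1: np.ndarray, X2: np.ndarray, N2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """phi_raw and df for every locus (NaN-aware, vectorised)."""

    def group_chi2(X, N):
        ok = np.isfinite(N) & (N >= 1)
        Xs = np.where(ok, X, 0.0)
        Ns = np.where(ok, N, 0.0)
        p = (Xs.sum(axis=1) + 0.5) / (Ns.sum(axis=1) + 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            contrib = (Xs - Ns * p[:, None]) ** 2 / (Ns * (p * (1 - p))[:, None])
        contrib = np.where(ok, contrib, 0.0)
        return contrib.sum(axis=1), ok.sum(axis=1), np.where(ok, Ns - 1, 0.0).sum(axis=1)

    c1, m1, d1 = group_chi2(X1, N1)
    c2, m2, d2 = group_chi2(X2, N2)
    m = m1 + m2
    denom = d1 + d2
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = (c1 + c2 - (m - 2)) / denom
    phi = np.where((denom > 0) & (m - 2 > 0), phi, 0.0)
    return np.clip(phi, 0.0, PHI_MAX), np.maximum(m - 2, 0.0)


def dml_test(
    matrix: UnitedMatrix,
    exposed_group: str,
    reference_group: str,
    covariate: str | None = None,
    d0: float = DEFAULT_D0,
    prior: ShrinkagePrior | None = None,
) -> pd.DataFrame:
    """Differential methylation at every locus, exposed minus reference.

    Returns a DataFrame with columns chrom, pos, p1, p2, diff, phi, wald,
    pvalue, qvalue. Loci with a group entirely missing are skipped (count
    logged). ``covariate='lane'`` switches to the arcsine-root weighted
    regression path.
    """
    idx1 = matrix.group_index(exposed_group)
    idx2 = matrix.group_index(reference_group)
    X1, N1 = matrix.n_meth[:, idx1], matrix.n_total[:, idx1]
    X2, N2 = matrix.n_meth[:, idx2], matrix.n_total[:, idx2]

    has1 = np.isfinite(N1).any(axis=1)
    has2 = np.isfinite(N2).any(axis=1)
    keep = has1 & has2
    skipped = int((~keep).sum())
    if skipped:
        logger.info("dml_test: skipped %d loci with a group entirely missing", skipped)
    X1, N1, X2, N2 = X1[keep], N1[keep], X2[keep], N2[keep]
    loci = matrix.loci.loc[keep].reset_index(drop=True)

    phi_raw, df = _dispersion_vectorized(X1, N1, X2, N2)
    if prior is None:
        prior = fit_shrinkage_prior(phi_raw, d0=d0)
    phi = shrink(phi_raw, df, prior)

    S1x, S1n = np.nansum(X1, axis=1), np.nansum(N1, axis=1)
    S2x, S2n = np.nansum(X2, axis=1), np.nansum(N2, axis=1)
    p1 = S1x / S1n
    p2 = S2x / S2n
    diff = p1 - p2

    if covariate is None:
        v1 = _wald_var(X1, N1, phi)
        v2 = _wald_var(X2, N2, phi)
        with np.errstate(invalid="ignore", divide="ignore"):
            wald = diff / np.sqrt(v1 + v2)
        wald = np.where(diff == 0, 0.0, wald)
    elif covariate == "lane":
        wald = _lane_covariate_wald(matrix, keep, idx1, idx2, phi)
    else:
        raise ValueError(f"unknown covariate {covariate!r}")

    pvalue = 2.0 * stats.norm.sf(np.abs(wald))
    out = pd.DataFrame(
        {
            "chrom": loci["chrom"],
            "pos": loci["pos"],
            "p1": p1,
            "p2": p2,
            "diff": diff,
            "phi": phi,
            "wald": wald,
            "pvalue": pvalue,
        }
    )
    out["qvalue"] = adjust_bh(out["pvalue"].to_numpy())
    return out


def _wald_var(X: np.ndarray, N: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Beta-binomial variance of the pooled group proportion.

    Var(p_hat) = ptilde (1-ptilde) sum_j N_j [1 + (N_j - 1) phi] / (sum N)^2
    with ptilde continuity-stabilised so the variance never vanishes at
    boundary proportions.
    """
    ok = np.isfinite(N)
    Xs = np.where(ok, X, 0.0)
    Ns = np.where(ok, N, 0.0)
    Sn = Ns.sum(axis=1)
    ptilde = (Xs.sum(axis=1) + 0.5) / (Sn + 1.0)
    w = (Ns * (1.0 + (Ns - 1.0) * phi[:, None]) * ok).sum(axis=1)
    return ptilde * (1 - ptilde) * w / Sn**2


def _lane_covariate_wald(
    matrix: UnitedMatrix,
    keep: np.ndarray,
    idx1: np.ndarray,
    idx2: np.ndarray,
    phi: np.ndarray,
) -> np.ndarray:
    """Wald statistic of the group coefficient in an arcsine-root weighted
    linear model with lane dummies.

    Response arcsin(2*ptilde_ij - 1) has approximate variance
    (1 + (N-1)phi) / (4N); weights are its inverse, and Var(beta) uses the
    known variance rather than a residual estimate.
    """
    cols = np.concatenate([idx1, idx2])
    X = matrix.n_meth[np.ix_(keep, cols)]
    N = matrix.n_total[np.ix_(keep, cols)]
    lanes = matrix.samples["lane"].to_numpy()[cols]
    group = np.concatenate([np.ones(len(idx1)), np.zeros(len(idx2))])
    uniq = np.unique(lanes)
    design = [np.ones(len(cols)), group]
    for l in uniq[1:]:
        design.append((lanes == l).astype(float))
    D = np.column_stack(design)

    n_loci = X.shape[0]
    wald = np.zeros(n_loci)
    with np.errstate(invalid="ignore", divide="ignore"):
        ptilde = (X + 0.5) / (N + 1.0)
        y = np.arcsin(2.0 * ptilde - 1.0)
    for i in range(n_loci):
        ok = np.isfinite(N[i]) & (N[i] >= 1)
        if ok.sum() <= D.shape[1]:
            continue
        Ni = N[i, ok]
        w = 4.0 * Ni / (1.0 + (Ni - 1.0) * phi[i])
        Di = D[:, [True] + [True] + [bool((lanes[ok] == l).any()) for l in uniq[1:]]][ok]
        XtWX = Di.T @ (w[:, None] * Di)
        try:
            cov = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError:
            continue
        beta = cov @ (Di.T @ (w * y[i, ok]))
        se = np.sqrt(cov[1, 1])
        wald[i] = beta[1] / se if se > 0 else 0.0
    return wald


def adjust_bh(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if not np.isfinite(p).all():
        raise ValueError("p-values must be finite")
    return multipletests(p, method="fdr_bh")[1]
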