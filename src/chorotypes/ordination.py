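"""Redundancy analysis (RDA) of the species table on environmental variables.

RDA is a PCA of the fitted values of a multivariate linear regression of the
(column-centered) sites × species response on the (column-centered)
constraining variables.  Total inertia is the total variance of the centered
response; constrained eigenvalues partition the variance of the fitted
values, unconstrained eigenvalues that of the residuals, and the explained
fraction of each axis is its eigenvalue over the total inertia.

Per-axis significance comes from a permutation test: each canonical axis is
represented by its fixed site-score direction, prior axes are partialled out
as conditioning covariates, and site rows of the response are freely
permuted.  The pseudo-F for axis i is its constrained variance over the
residual variance of the model holding axes 1..i, on the matching residual
degrees of freedom.  An alternative ``forward`` scheme re-estimates the
leading constrained eigenvalue from each permuted data set (the behaviour of
current constrained-ordination toolkits) instead of projecting on the fixed
direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import EnvironmentTable, PresenceAbsenceTable

__all__ = ["RDAResult", "AxisTestResult", "rda_fit", "rda_axis_test"]

_EIG_TOL = 1e-9  # relative cutoff below which a constrained axis is noise


@dataclass(frozen=True)
class RDAResult:
    """Eigenvalues, variance fractions and scores of a fitted RDA."""

    eigenvalues: np.ndarray            #: constrained axes, descending
    residual_eigenvalues: np.ndarray   #: unconstrained (residual) axes
    total_inertia: float
    site_scores: pd.DataFrame          #: constrained (fitted) site scores
    species_scores: pd.DataFrame
    biplot_scores: pd.DataFrame        #: env-variable correlations with axes
    variables: tuple[str, ...]

    @property
    def proportion_explained(self) -> np.ndarray:
        return self.eigenvalues / self.total_inertia

    @property
    def constrained_fraction(self) -> float:
        """Multivariate R²: total variance explained by all constraints."""
        return float(self.eigenvalues.sum() / self.total_inertia)

    def summary(self) -> dict:
        return {
            "total_inertia": self.total_inertia,
            "constrained_eigenvalues": self.eigenvalues.tolist(),
            "residual_eigenvalues": self.residual_eigenvalues.tolist(),
            "proportion_explained": self.proportion_explained.tolist(),
            "constrained_fraction": self.constrained_fraction,
            "variables": list(self.variables),
        }


@dataclass(frozen=True)
class AxisTestResult:
    """Per-axis pseudo-F statistics and permutation p-values."""

    pseudo_f: np.ndarray
    p_values: np.ndarray
    n_permutations: int
    seed: int
    scheme: str = "sequential"

    def __post_init__(self) -> None:
        lo = 1.0 / (self.n_permutations + 1)
        if ((self.p_values < lo - 1e-12) | (self.p_values > 1 + 1e-12)).any():
            raise ValueError("permutation p-values must lie in [1/(N+1), 1]")


def _design_matrices(pa: PresenceAbsenceTable, env: EnvironmentTable,
                     standardize_species: bool = False):
    env = env.aligned_to(pa.unit_labels)
    Y = pa.cells.T.astype(float)            # sites x species
    Y = Y - Y.mean(axis=0)
    if standardize_species:
        sd = Y.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError("cannot standardize a constant species column")
        Y = Y / sd
    X = env.values - env.values.mean(axis=0)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via QR pivoting on the correlation scale
        r = np.abs(np.diag(np.linalg.qr(X / np.linalg.norm(X, axis=0), mode="r")))
        bad = [env.variables[i] for i in np.flatnonzero(r < 1e-10)]
        raise ValueError(f"environment matrix is rank deficient; collinear columns: {bad}")
    return Y, X, env


def rda_fit(pa: PresenceAbsenceTable, env: EnvironmentTable,
            standardize_species: bool = False) -> RDAResult:
    """Fit the RDA of species composition on the environmental variables.

    Species columns are centered (optionally standardized — off by default
    for presence–absence responses); environment columns are centered.
    Scores use symmetric scaling: site and species scores are each multiplied
    by the fourth root of their axis' eigenvalue share.
    """
    Y, X, env = _design_matrices(pa, env, standardize_species)
    n = Y.shape[0]
    denom = n - 1
    Q, _ = np.linalg.qr(X)
    Yhat = Q @ (Q.T @ Y)
    U, sv, Vt = np.linalg.svd(Yhat, full_matrices=False)
    eig = sv**2 / denom
    keep = eig > _EIG_TOL * max(eig[0], 1e-300)
    eig = eig[keep]
    U, sv, Vt = U[:, keep], sv[keep], Vt[keep]
    resid_sv = np.linalg.svd(Y - Yhat, compute_uv=False)
    resid_eig = resid_sv**2 / denom
    resid_eig = resid_eig[resid_eig > _EIG_TOL * max(eig[0], 1e-300)]
    total = float((Y**2).sum() / denom)

    axes = [f"RDA{i + 1}" for i in range(len(eig))]
    scale = (eig / eig.sum()) ** 0.25
    site = pd.DataFrame(U * sv / np.sqrt(denom) * scale, index=list(pa.unit_labels),
                        columns=axes)
    species = pd.DataFrame(Vt.T * scale, index=list(pa.species_labels), columns=axes)
    # biplot arrows: correlations of env columns with the site (LC) axes
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(np.hstack([X, U]), rowvar=False)[: X.shape[1], X.shape[1]:]
    biplot = pd.DataFrame(corr, index=list(env.variables), columns=axes)
    return RDAResult(
        eigenvalues=eig, residual_eigenvalues=resid_eig, total_inertia=total,
        site_scores=site, species_scores=species, biplot_scores=biplot,
        variables=env.variables,
    )


def rda_axis_test(pa: PresenceAbsenceTable, env: EnvironmentTable,
                  n_permutations: int = 9999, seed: int = 0,
                  scheme: str = "sequential",
                  standardize_species: bool = False) -> AxisTestResult:
    """Permutation test of each constrained axis.

    ``sequential`` (default): axis i is its fixed canonical direction; axes
    1..i−1 are conditioned out of permuted responses, site rows are freely
    permuted, and pseudo-F uses the residual of the (i+1)-parameter model.
    ``forward``: the statistic is re-estimated as the leading constrained
    eigenvalue of the conditioned, permuted response over the remaining
    constraint space, with reduced-model permutation — this reproduces the
    current vegan ``anova(..., by="axis")`` behaviour.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if scheme not in ("sequential", "forward"):
        raise ValueError(f"unknown permutation scheme: {scheme!r}")
    Y, X, env = _design_matrices(pa, env, standardize_species)
    n = Y.shape[0]
    q = np.linalg.matrix_rank(X)
    Qx = np.linalg.qr(X)[0][:, :q]
    Yhat = Qx @ (Qx.T @ Y)
    U, sv, _ = np.linalg.svd(Yhat, full_matrices=False)
    ev = sv**2
    k = int((ev > _EIG_TOL * ev[0]).sum())
    rng = np.random.default_rng(seed)
    fs = np.empty(k)
    ps = np.empty(k)
    total_ss = (Y**2).sum()
    resid_full = total_ss - ev[:k].sum()
    for i in range(k):
        Z = U[:, :i]
        u = U[:, i]
        if scheme == "sequential":
            df = n - 1 - (i + 1)
            num = ev[i]
            res = total_ss - ((Z.T @ Y) ** 2).sum() - num
            f_obs = num / (res / df)
            exceed = 0
            for _ in range(n_permutations):
                Yp = Y[rng.permutation(n)]
                cond = ((Z.T @ Yp) ** 2).sum() if i else 0.0
                Er = Yp - Z @ (Z.T @ Yp) if i else Yp
                nm = ((u @ Er) ** 2).sum()
                rs = (Yp**2).sum() - cond - nm
                if nm / (rs / df) >= f_obs - 1e-12:
                    exceed += 1
        else:  # forward
            df = n - 1 - q
            f_obs = ev[i] / (resid_full / df)
            E = Y - Z @ (Z.T @ Y) if i else Y
            Xc = X - Z @ (Z.T @ X) if i else X
            Qc = np.linalg.qr(Xc)[0][:, : q - i]
            exceed = 0
            for _ in range(n_permutations):
                Ep = E[rng.permutation(n)]
                cond = ((Z.T @ Ep) ** 2).sum() if i else 0.0
                proj = Qc.T @ (Ep - Z @ (Z.T @ Ep)) if i else Qc.T @ Ep
                lam = np.linalg.svd(proj, compute_uv=False)[0] ** 2
                rs = (Ep**2).sum() - cond - (proj**2).sum()
                if lam / (rs / df) >= f_obs - 1e-12:
                    exceed += 1
        fs[i] = f_obs
        ps[i] = (1 + exceed) / (1 + n_permutations)
    return AxisTestResult(pseudo_f=fs, p_values=ps, n_permutations=n_permutations,
                          seed=seed, scheme=scheme)
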