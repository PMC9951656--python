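"""Quasi-Poisson generalized linear models (log link) via IRLS.

The quasi-Poisson family keeps the Poisson mean structure
``E[y] = exp(X beta + offset)`` but lets the variance be ``phi * mu``.
Point estimates therefore coincide with Poisson maximum likelihood;
only the standard errors are scaled by ``sqrt(phi)``, where ``phi`` is the
Pearson-statistic estimate of dispersion.  Wald tests use Student's t with
``n - p`` degrees of freedom, the convention of the R ``glm`` ecosystem in
which overdispersed count models of age-at-death are usually reported.

This module is deliberately self-contained (numpy + scipy only); an
established GLM implementation is used in the test-suite as an independent
oracle, never as the engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .records import DeathRecord, cause_class

logger = logging.getLogger(__name__)

__all__ = [
    "QuasiPoissonGLM",
    "QuasiPoissonResults",
    "fit_quasipoisson",
    "fit_age_inbreeding",
]


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    # QR-based detection so the error can name the collinear columns.
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = X.shape[0] * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = [names[j] for j in range(len(diag)) if diag[j] <= tol]
    if bad:
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear column(s): {', '.join(bad)}"
        )


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


class QuasiPoissonGLM:
    """Quasi-Poisson regression model with log link.

    Parameters
    ----------
    endog : array-like
        Non-negative count response.
    exog : array-like, (n, p)
        Design matrix; supply the intercept column explicitly.
    exog_names : sequence of str, optional
    offset : array-like, optional
        Added to the linear predictor (e.g. log exposure).
    """

    def __init__(self, endog, exog, exog_names=None, offset=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError(
                f"endog has {self.endog.shape[0]} rows but exog has {self.exog.shape[0]}"
            )
        if np.any(self.endog < 0):
            raise ValueError("endog must be non-negative")
        self.offset = (
            np.zeros_like(self.endog) if offset is None else np.asarray(offset, float)
        )
        n, p = self.exog.shape
        if exog_names is None:
            exog_names = ["const"] + [f"x{j}" for j in range(1, p)]
        if len(exog_names) != p:
            raise ValueError("exog_names length does not match exog columns")
        self.exog_names = list(exog_names)
        _check_rank(self.exog, self.exog_names)

    @classmethod
    def from_records(
        cls,
        records: Sequence[DeathRecord],
        interaction_with_cause: bool = False,
        drop_unknown_sex: bool = False,
    ) -> "QuasiPoissonGLM":
        """Build the age-at-death ~ heterozygosity design from records.

        With ``interaction_with_cause`` the design is
        ``age ~ ihet * cause2`` where ``cause2`` is the traffic/non-traffic
        dichotomy (traffic coded 1); records with unknown cause are dropped.
        Records with missing heterozygosity are always dropped (count logged).
        """
        kept = [r for r in records if r.heterozygosity is not None]
        n_missing = len(records) - len(kept)
        if n_missing:
            logger.info("dropping %d records with missing heterozygosity", n_missing)
        if drop_unknown_sex:
            before = len(kept)
            kept = [r for r in kept if r.sex.value != "unknown"]
            logger.info("dropping %d records of unknown sex", before - len(kept))
        if interaction_with_cause:
            before = len(kept)
            kept = [r for r in kept if cause_class(r) is not None]
            if before - len(kept):
                logger.info(
                    "dropping %d records with unknown cause", before - len(kept)
                )
        if len(kept) < 2:
            raise ValueError("fewer than 2 records with the required covariates")
        y = np.array([r.age_years for r in kept], dtype=float)
        ihet = np.array([r.heterozygosity for r in kept], dtype=float)
        cols = [np.ones_like(y), ihet]
        names = ["const", "ihet"]
        if interaction_with_cause:
            traffic = np.array(
                [1.0 if cause_class(r) == "traffic" else 0.0 for r in kept]
            )
            cols += [traffic, ihet * traffic]
            names += ["traffic", "ihet:traffic"]
        return cls(y, np.column_stack(cols), exog_names=names)

    def fit(
        self,
        max_iter: int = 100,
        tol: float = 1e-10,
        scale: float | str = "pearson",
        use_t: bool = True,
    ) -> "QuasiPoissonResults":
        """Fit by iteratively reweighted least squares.

        ``scale='pearson'`` gives the quasi-Poisson fit; ``scale=1.0`` gives
        plain Poisson standard errors (with ``use_t=False`` for normal
        p-values).  Non-convergence is flagged, never silent.
        """
        y, X, offset = self.endog, self.exog, self.offset
        n, p = X.shape
        mu = y + 0.5  # guards zeros under the log link
        eta = np.log(mu)
        beta = np.zeros(p)
        deviance = _poisson_deviance(y, mu)
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            w = np.sqrt(mu)
            z = eta - offset + (y - mu) / mu
            beta, *_ = np.linalg.lstsq(X * w[:, None], z * w, rcond=None)
            eta = X @ beta + offset
            mu = np.exp(eta)
            new_dev = _poisson_deviance(y, mu)
            if abs(new_dev - deviance) <= tol * (abs(deviance) + 0.1):
                deviance = new_dev
                converged = True
                break
            deviance = new_dev
        if not converged:
            logger.warning("IRLS did not converge in %d iterations", max_iter)

        df_resid = n - p
        pearson = float(np.sum((y - mu) ** 2 / mu))
        if scale == "pearson":
            dispersion = pearson / df_resid if df_resid > 0 else np.nan
        else:
            dispersion = float(scale)
        XtWX = (X * mu[:, None]).T @ X
        cov_unscaled = np.linalg.inv(XtWX)
        bse = np.sqrt(dispersion * np.diag(cov_unscaled))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvalues = np.where(bse > 0, beta / bse, np.nan)
        if use_t:
            pvalues = 2.0 * stats.t.sf(np.abs(tvalues), df_resid)
        else:
            pvalues = 2.0 * stats.norm.sf(np.abs(tvalues))
        return QuasiPoissonResults(
            model=self,
            params=beta,
            bse=bse,
            tvalues=tvalues,
            pvalues=pvalues,
            dispersion=float(dispersion),
            pearson_chi2=pearson,
            df_resid=df_resid,
            deviance=deviance,
            fittedvalues=mu,
            converged=converged,
            n_iter=n_iter,
            use_t=use_t,
        )


@dataclass
class QuasiPoissonResults:
    """Fitted quasi-Poisson GLM: estimates, scaled uncertainty, diagnostics."""

    model: QuasiPoissonGLM
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    dispersion: float
    pearson_chi2: float
    df_resid: int
    deviance: float
    fittedvalues: np.ndarray
    converged: bool
    n_iter: int
    use_t: bool = True

    @property
    def exog_names(self) -> list[str]:
        return self.model.exog_names

    def summary(self) -> str:
        stat = "t" if self.use_t else "z"
        lines = [
            "Quasi-Poisson GLM (log link)",
            f"  n = {self.model.endog.shape[0]}, residual df = {self.df_resid}, "
            f"dispersion (Pearson) = {self.dispersion:.4f}",
            f"  deviance = {self.deviance:.4f}, converged = {self.converged} "
            f"({self.n_iter} IRLS iterations)",
            "",
            f"  {'term':<14}{'estimate':>12}{'std err':>12}{stat:>9}{'P>|' + stat + '|':>10}",
        ]
        for name, b, se, t, pv in zip(
            self.exog_names, self.params, self.bse, self.tvalues, self.pvalues
        ):
            lines.append(f"  {name:<14}{b:>12.4f}{se:>12.4f}{t:>9.3f}{pv:>10.4f}")
        return "\n".join(lines)


def fit_quasipoisson(
    y,
    X,
    max_iter: int = 100,
    tol: float = 1e-10,
    exog_names=None,
    offset=None,
    scale: float | str = "pearson",
    use_t: bool = True,
) -> QuasiPoissonResults:
    """Convenience wrapper: build a :class:`QuasiPoissonGLM` and fit it."""
    return QuasiPoissonGLM(y, X, exog_names=exog_names, offset=offset).fit(
        max_iter=max_iter, tol=tol, scale=scale, use_t=use_t
    )


def fit_age_inbreeding(
    records: Sequence[DeathRecord],
    interaction_with_cause: bool = False,
    drop_unknown_sex: bool = False,
    **fit_kwargs,
) -> QuasiPoissonResults:
    """Fit age-at-death against individual heterozygosity (optionally with
    a traffic/non-traffic interaction) on the records that carry iH_O."""
    model = QuasiPoissonGLM.from_records(
        records,
        interaction_with_cause=interaction_with_cause,
        drop_unknown_sex=drop_unknown_sex,
    )
    return model.fit(**fit_kwargs)
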