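"""Beta-uniform mixture (BUM) modelling of p-value distributions.

A collection of differential-expression p-values is modelled as a two
component mixture: null p-values are Uniform(0,1), signal p-values follow
a Beta(a, 1) density with shape ``0 < a < 1``, mixed with weight
``lambda_mix`` on the uniform component:

    f(x | a, lambda) = lambda + (1 - lambda) * a * x**(a - 1)

From a maximum-likelihood fit we derive

* ``pi_hat = lambda + (1 - lambda) * a`` — an upper bound on the fraction
  of p-values attributable to the null hypothesis;
* ``tau`` — the p-value threshold at which the estimated upper bound of
  the false discovery rate equals a target ``alpha``;
* the additive per-gene activity score
  ``S(x) = (a - 1) * (log x - log tau)`` (natural log), which is zero at
  ``x = tau``, positive for smaller p-values and negative above.

These scores are the node weights that the module search optimises.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "MIN_PVALUE",
    "BumFit",
    "ScoringScheme",
    "clamp_pvalues",
    "read_pvalues",
    "bum_pdf",
    "bum_log_likelihood",
    "fit_bum",
    "compute_pi_hat",
    "compute_tau",
    "node_score",
    "plot_fit",
]

logger = logging.getLogger(__name__)

#: Smallest p-value accepted after clamping; the mixture density diverges
#: at zero, so exact zeros are pulled up to this floor before fitting.
MIN_PVALUE = 1e-300

_BOX = (1e-6, 1.0 - 1e-6)


@dataclass(frozen=True)
class BumFit:
    """Maximum-likelihood parameters of the beta-uniform mixture.

    Attributes
    ----------
    a : float
        Beta shape parameter, in (0, 1).
    lambda_mix : float
        Mixture weight of the uniform (null) component, in (0, 1).
    log_likelihood : float
        Log-likelihood of the fitted parameters on the input p-values.
    n : int
        Number of p-values used in the fit.
    """

    a: float
    lambda_mix: float
    log_likelihood: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ScoringScheme:
    """Everything needed to turn a p-value into an additive node score."""

    a: float
    tau: float
    fdr_alpha: float
    pi_hat: float

    @classmethod
    def from_fit(cls, fit: BumFit, fdr_alpha: float) -> "ScoringScheme":
        return cls(
            a=fit.a,
            tau=compute_tau(fit, fdr_alpha),
            fdr_alpha=fdr_alpha,
            pi_hat=compute_pi_hat(fit),
        )

    def to_dict(self) -> dict:
        return asdict(self)


def clamp_pvalues(pvals, min_pvalue: float = MIN_PVALUE) -> np.ndarray:
    """Validate p-values and clamp exact zeros up to ``min_pvalue``.

    Values must lie in [0, 1]; zeros are replaced by ``min_pvalue`` because
    the mixture density is unbounded at the origin.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and lie in [0, 1]")
    return np.clip(p, min_pvalue, 1.0)


def read_pvalues(path) -> pd.Series:
    """Read a two-column TSV ``gene_id<TAB>pvalue`` into a Series.

    The header row is required; gene ids must be unique. Zeros are clamped
    (see :func:`clamp_pvalues`).
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns gene_id<TAB>pvalue")
    genes = df.iloc[:, 0].astype(str)
    if genes.duplicated().any():
        dups = genes[genes.duplicated()].tolist()[:5]
        raise ValueError(f"{path}: duplicate gene ids, e.g. {dups}")
    vals = clamp_pvalues(df.iloc[:, 1].to_numpy(dtype=float))
    return pd.Series(vals, index=pd.Index(genes, name="gene_id"), name="pvalue")


def _check_domain(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or np.any(x > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return x


def bum_pdf(x, fit: BumFit):
    """Mixture density ``lambda + (1 - lambda) * a * x**(a - 1)`` on (0, 1]."""
    x = _check_domain(x)
    a, lam = fit.a, fit.lambda_mix
    out = lam + (1.0 - lam) * a * np.power(x, a - 1.0)
    return out if out.shape else float(out)


def bum_log_likelihood(pvals, a: float, lambda_mix: float) -> float:
    """Sum of log mixture densities over ``pvals`` at fixed parameters."""
    x = _check_domain(pvals)
    logx = np.log(x)
    dens = lambda_mix + (1.0 - lambda_mix) * a * np.exp((a - 1.0) * logx)
    return float(np.sum(np.log(dens)))


def _neg_log_likelihood(theta: np.ndarray, logx: np.ndarray) -> float:
    a, lam = theta
    dens = lam + (1.0 - lam) * a * np.exp((a - 1.0) * logx)
    return -float(np.sum(np.log(dens)))


def fit_bum(pvals, min_pvalue: float = MIN_PVALUE) -> BumFit:
    """Fit the beta-uniform mixture by maximum likelihood.

    Bounded L-BFGS-B on the open box (0, 1)^2, restarted from the five best
    points of a coarse grid; the restart with the highest likelihood wins.
    At least ten p-values are required for a meaningful fit.

    The mixture is not identifiable at the uniform limit: ``a -> 1`` with
    any ``lambda`` and ``lambda -> 1`` with any ``a`` describe the same
    flat density. When restarts tie in likelihood (within 1e-4), the fit
    with the larger ``lambda_mix`` is preferred — the conservative
    reading that attributes the flat component to the null.

    Parameters
    ----------
    pvals : array-like or mapping gene -> p-value
        P-values in (0, 1]; exact zeros are clamped up to ``min_pvalue``.
    """
    if isinstance(pvals, (dict, pd.Series)):
        pvals = pd.Series(pvals).to_numpy(dtype=float)
    x = clamp_pvalues(pvals, min_pvalue)
    if x.size < 10:
        raise ValueError(f"need at least 10 p-values to fit, got {x.size}")
    if np.unique(x).size == 1:
        logger.warning("all p-values identical; BUM fit is degenerate")
        warnings.warn("all p-values identical; BUM fit is degenerate")
    logx = np.log(x)

    grid = np.linspace(0.05, 0.95, 10)
    cand = [(a0, l0) for a0 in grid for l0 in grid]
    cand.sort(key=lambda th: _neg_log_likelihood(np.array(th), logx))
    # five best grid points plus one high-lambda start so the null-heavy
    # ridge is always explored
    starts = cand[:5] + [(0.5, _BOX[1])]

    results = []
    for a0, l0 in starts:
        res = minimize(
            _neg_log_likelihood,
            x0=np.array([a0, l0]),
            args=(logx,),
            method="L-BFGS-B",
            bounds=[_BOX, _BOX],
            options={"ftol": 1e-8, "gtol": 1e-10, "maxiter": 500},
        )
        results.append(res)
    best_fun = min(r.fun for r in results)
    # on likelihood ties prefer the larger mixture weight (more null)
    best = max(
        (r for r in results if r.fun <= best_fun + 1e-4), key=lambda r: r.x[1]
    )
    a_hat, lam_hat = best.x
    return BumFit(
        a=float(a_hat),
        lambda_mix=float(lam_hat),
        log_likelihood=-float(best.fun),
        n=int(x.size),
    )


def compute_pi_hat(fit: BumFit) -> float:
    """Upper bound on the null proportion: ``lambda + (1 - lambda) * a``."""
    return fit.lambda_mix + (1.0 - fit.lambda_mix) * fit.a


def compute_tau(fit: BumFit, fdr_alpha: float) -> float:
    """Significance threshold controlling the FDR upper bound at ``fdr_alpha``.

    tau = ((pi_hat - alpha*lambda) / (alpha*(1 - lambda))) ** (1 / (a - 1))

    P-values below tau receive positive scores. When the base of the power
    falls below one the formula yields tau > 1 (every p-value significant);
    the result is clipped to 1 with a warning.
    """
    if not 0.0 < fdr_alpha < 1.0:
        raise ValueError(f"fdr_alpha must lie in (0, 1), got {fdr_alpha}")
    a, lam = fit.a, fit.lambda_mix
    pi_hat = compute_pi_hat(fit)
    if fdr_alpha * lam >= pi_hat:
        raise ValueError(
            f"alpha*lambda = {fdr_alpha * lam:.3g} must be < pi_hat = "
            f"{pi_hat:.3g}; the FDR bound cannot be attained at this alpha"
        )
    base = (pi_hat - fdr_alpha * lam) / (fdr_alpha * (1.0 - lam))
    if base < 1.0:
        warnings.warn(
            f"FDR level {fdr_alpha} is lenient enough that tau exceeds 1; "
            "clipping to 1 (all p-values deemed significant)"
        )
        return 1.0
    return float(base ** (1.0 / (a - 1.0)))


def node_score(x, scheme: ScoringScheme):
    """Additive activity score ``(a - 1) * (log x - log tau)``.

    Natural logarithm; zero at ``x == tau``, positive iff ``x < tau`` and
    strictly decreasing in x (since a < 1).
    """
    x = _check_domain(x)
    out = (scheme.a - 1.0) * (np.log(x) - np.log(scheme.tau))
    return out if out.shape else float(out)


def write_fit_report(path, fit: BumFit, scheme: ScoringScheme) -> None:
    """Dump the fit and derived scoring parameters as JSON."""
    report = {
        "a": fit.a,
        "lambda": fit.lambda_mix,
        "pi_hat": scheme.pi_hat,
        "tau": scheme.tau,
        "loglik": fit.log_likelihood,
        "n": fit.n,
        "alpha": scheme.fdr_alpha,
    }
    Path(path).write_text(json.dumps(report, indent=2) + "\n")


def plot_fit(pvals, fit: BumFit, path) -> None:
    """Diagnostic plot: p-value histogram with the fitted mixture, plus a
    Q-Q plot of fitted versus empirical quantiles."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = clamp_pvalues(pvals)
    a, lam = fit.a, fit.lambda_mix
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))

    ax1.hist(x, bins=50, density=True, color="0.8", edgecolor="0.5")
    grid = np.linspace(1e-4, 1, 500)
    ax1.plot(grid, bum_pdf(grid, fit), "r-", label="mixture")
    ax1.axhline(lam, color="b", ls="--", label="uniform component")
    ax1.set_xlabel("p-value")
    ax1.set_ylabel("density")
    ax1.set_ylim(0, min(ax1.get_ylim()[1], 20))
    ax1.legend()

    # model CDF: lam*x + (1-lam)*x^a, inverted numerically for Q-Q
    emp = np.sort(x)
    probs = (np.arange(emp.size) + 0.5) / emp.size
    fine = np.linspace(1e-12, 1, 4096)
    cdf = lam * fine + (1 - lam) * fine**a
    theo = np.interp(probs, cdf, fine)
    ax2.plot(theo, emp, ".", ms=2)
    ax2.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax2.set_xlabel("fitted quantiles")
    ax2.set_ylabel("empirical quantiles")

    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
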