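"""Partial redundancy analysis of genotypes against decline status.

Individual dosage genotypes are the response matrix; a binary decline
indicator (1 = individual belongs to a significantly declining
population) is the single constraint; geography (latitude) is partialled
out.  With one binary constraint the constrained ordination has exactly
one axis, obtained here directly: genotypes and indicator are both
residualized on [intercept, conditioning covariates] by least squares,
the residualized genotypes are regressed on the residualized indicator,
and the SVD of the fitted matrix gives locus scores (right singular
vector scaled by the singular value) and individual site scores.

Decline-associated loci are the score outliers: more than ``k`` standard
deviations (default 3) from the mean locus score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


@dataclass
class RdaResult:
    """Constrained-axis scores and the outlier calls derived from them."""

    loci: list[str]
    locus_scores: np.ndarray          # on the single constrained axis
    site_scores: np.ndarray           # per individual
    constrained_fraction: float       # share of conditioned variance explained
    outlier: np.ndarray               # bool per locus
    sd_multiplier: float
    conditioning: list[str]
    scaled: bool

    def outlier_loci(self) -> list[str]:
        return [l for l, o in zip(self.loci, self.outlier) if o]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus": self.loci,
                "rda1_score": self.locus_scores,
                "outlier": self.outlier,
            }
        )


def _residualize(M: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of each column of M on the column space of Z (least squares)."""
    coef, *_ = np.linalg.lstsq(Z, M, rcond=None)
    return M - Z @ coef


def run_partial_rda(
    G: GenotypeMatrix,
    decline_indicator: np.ndarray,
    conditioning: dict[str, np.ndarray] | None = None,
    *,
    sd_multiplier: float = 3.0,
    scale_loci: bool = False,
    collinearity_tol: float = 1e-8,
) -> RdaResult:
    """Single-constraint partial RDA of dosages on a decline indicator.

    ``decline_indicator`` is per-individual 0/1 (constant within
    population); ``conditioning`` maps covariate name -> per-individual
    values (default: none beyond the intercept).  Genotypes must be
    complete (impute first).  ``scale_loci`` divides each centered locus
    by its SD (correlation-based RDA); default is covariance-based.
    """
    if (G.dosage == MISSING).any():
        raise ValueError("genotypes contain missing calls; impute first")
    y = np.asarray(decline_indicator, dtype=float)
    if y.shape != (G.n_samples,):
        raise ValueError("indicator length does not match sample count")
    conditioning = conditioning or {}
    Z = np.column_stack(
        [np.ones(G.n_samples)] + [np.asarray(v, float) for v in conditioning.values()]
    )

    X = G.dosage.astype(float)
    X = X - X.mean(axis=0)
    if scale_loci:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = X / sd
    X_res = _residualize(X, Z)
    y_res = _residualize(y[:, None], Z)[:, 0]

    y_norm2 = float(y_res @ y_res)
    if y_norm2 <= collinearity_tol * max(1.0, float(y @ y)):
        raise ValueError(
            "decline indicator is collinear with the conditioning covariates "
            f"(residual sum of squares {y_norm2:.3e})"
        )

    # fitted matrix of the constrained regression: rank one by construction
    b = (y_res @ X_res) / y_norm2          # per-locus slopes
    fitted = np.outer(y_res, b)
    U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 0
    assert rank <= 1, "single binary constraint must give exactly one axis"
    if rank == 0:
        locus_scores = np.zeros(G.n_loci)
        site = np.zeros(G.n_samples)
        frac = 0.0
    else:
        locus_scores = Vt[0] * s[0]
        site = U[:, 0]
        total = float((X_res**2).sum())
        frac = float(s[0] ** 2 / total) if total > 0 else 0.0
        # sign convention: declining individuals sit on the positive side
        if site[y == 1].size and site[y == 1].mean() < 0:
            site = -site
            locus_scores = -locus_scores

    outlier = flag_outlier_loci(locus_scores, sd_multiplier)
    return RdaResult(
        loci=list(G.loci),
        locus_scores=locus_scores,
        site_scores=site,
        constrained_fraction=frac,
        outlier=outlier,
        sd_multiplier=sd_multiplier,
        conditioning=list(conditioning),
        scaled=scale_loci,
    )


def flag_outlier_loci(scores: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Loci more than ``k`` SD from the mean score (population SD, divisor n)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 10:
        raise ValueError("outlier rule needs at least 10 loci")
    sd = scores.std()
    if sd == 0:
        warnings.warn("zero score variance: no outliers flagged", stacklevel=2)
        return np.zeros(scores.size, dtype=bool)
    return np.abs(scores - scores.mean()) > k * sd


def indicator_from_meta(G: GenotypeMatrix, declining_pops: set[str]) -> np.ndarray:
    """Per-individual 0/1 decline indicator from population labels."""
    return np.array(
        [1.0 if G.population_of[s] in declining_pops else 0.0 for s in G.samples]
    )
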