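"""Weighted polygenic risk-of-decline scores and their repeatability.

Decline-associated loci (RDA outliers) are distance-thinned — the single
highest-|score| outlier per 1-Mbp window survives — and capped at the
top 100 by |score|.  A multivariate logistic regression of the
individual-level decline label on the selected dosages provides
per-locus weights beta (log-odds units); an individual's risk score is
the weighted dosage sum ``sum_j beta_j g_ij`` (the intercept is a shared
shift and is excluded).  With ~100 predictors on a few hundred
individuals the unpenalized likelihood often separates; in that case the
fit falls back to a small ridge penalty (smallest power of ten that
converges), which is recorded on the model.

Repeatability is assessed leave-one-population-out: the weights are
refitted without population P, P's individuals are scored under the full
and the reduced model, and the two score vectors are compared with a
two-sided Mann-Whitney test at a Bonferroni-adjusted alpha
(0.05 / number of populations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import mannwhitneyu

from .genotypes import MISSING, GenotypeMatrix, LinkageMap, impute_most_frequent

MBP = 1_000_000


@dataclass
class RiskModel:
    loci: list[str]
    beta: np.ndarray          # log-odds weights, aligned with loci
    intercept: float
    converged: bool
    penalty: float            # ridge lambda actually used (0 = unpenalized)


@dataclass
class RiskScoreTable:
    samples: list[str]
    population_of: dict[str, str]
    scores: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.samples,
                "population": [self.population_of[s] for s in self.samples],
                "score": self.scores,
            }
        )

    def population_summary(self) -> pd.DataFrame:
        df = self.to_frame()
        return (
            df.groupby("population")["score"]
            .agg(
                mean="mean",
                median="median",
                q1=lambda s: s.quantile(0.25),
                q3=lambda s: s.quantile(0.75),
                n="count",
            )
            .reset_index()
        )


def select_score_loci(
    outlier_loci: list[str],
    scores: dict[str, float],
    lmap: LinkageMap,
    n: int = 100,
    thin_bp: int = MBP,
) -> list[str]:
    """Distance-thin outliers (best per 1-Mbp window), then take top-n by |score|.

    Ties break by locus id so selection is deterministic.
    """
    if not outlier_loci:
        raise ValueError("empty outlier set: nothing to select")
    best: dict[tuple[str, int], str] = {}
    for l in outlier_loci:
        ch = str(lmap.table.at[l, "chrom"])
        win = int((int(lmap.table.at[l, "bp"]) - 1) // thin_bp)
        key = (ch, win)
        cur = best.get(key)
        if (
            cur is None
            or abs(scores[l]) > abs(scores[cur])
            or (abs(scores[l]) == abs(scores[cur]) and l < cur)
        ):
            best[key] = l
    thinned = list(best.values())
    thinned.sort(key=lambda l: (-abs(scores[l]), l))
    return thinned[:n]


def _neg_loglik(params: np.ndarray, X: np.ndarray, y: np.ndarray, lam: float):
    """Ridge-penalized logistic negative log-likelihood and gradient."""
    b0, b = params[0], params[1:]
    eta = b0 + X @ b
    # log(1 + exp(eta)) computed stably
    nll = np.sum(np.logaddexp(0.0, eta) - y * eta) + 0.5 * lam * b @ b
    p = 1.0 / (1.0 + np.exp(-eta))
    grad = np.empty_like(params)
    grad[0] = np.sum(p - y)
    grad[1:] = X.T @ (p - y) + lam * b
    return nll, grad


def _fit_logistic(X: np.ndarray, y: np.ndarray, lam: float):
    x0 = np.zeros(X.shape[1] + 1)
    res = minimize(
        _neg_loglik,
        x0,
        args=(X, y, lam),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-8},
    )
    return res


def fit_risk_model(
    G: GenotypeMatrix,
    labels: np.ndarray,
    loci: list[str] | None = None,
    *,
    max_abs_beta: float = 10.0,
) -> RiskModel:
    """Joint logistic regression of the decline label on selected dosages.

    ``labels`` are per-individual 0/1 (constant within population).
    Separation (detected as optimizer failure or implausibly large
    weights, |beta| >= ``max_abs_beta``) triggers a ridge refit with the
    smallest power-of-ten penalty that converges to finite, moderate
    weights; the penalty used is recorded.
    """
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both decline classes must be present")
    use = loci if loci is not None else list(G.loci)
    sub = G.subset_loci(use)
    if (sub.dosage == MISSING).any():
        raise ValueError("missing dosages at model loci; impute first")
    X = sub.dosage.astype(float)

    res = _fit_logistic(X, y, lam=0.0)
    beta = res.x[1:]
    ok = res.success and np.all(np.abs(beta) < max_abs_beta)
    lam_used = 0.0
    if not ok:
        for exp in range(-4, 3):
            lam_used = 10.0**exp
            res = _fit_logistic(X, y, lam_used)
            beta = res.x[1:]
            if res.success and np.all(np.abs(beta) < max_abs_beta):
                ok = True
                break
    return RiskModel(
        loci=list(use),
        beta=res.x[1:].copy(),
        intercept=float(res.x[0]),
        converged=bool(ok),
        penalty=lam_used,
    )


def compute_scores(
    G: GenotypeMatrix, model: RiskModel, *, impute: bool = True
) -> RiskScoreTable:
    """Per-individual weighted dosage sum over the model loci."""
    missing_loci = [l for l in model.loci if l not in G.loci]
    if missing_loci:
        raise ValueError(f"model loci absent from panel: {missing_loci[:5]}")
    sub = G.subset_loci(model.loci)
    if (sub.dosage == MISSING).any():
        if not impute:
            raise ValueError("missing dosages at model loci")
        sub = impute_most_frequent(sub)
    scores = sub.dosage.astype(float) @ model.beta
    return RiskScoreTable(
        samples=list(G.samples),
        population_of=dict(G.population_of),
        scores=scores,
    )


def _mwu(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney; exact for small tie-free samples, else
    normal approximation with tie correction."""
    exact = len(a) <= 20 and len(b) <= 20 and np.unique(np.concatenate([a, b])).size == len(a) + len(b)
    res = mannwhitneyu(a, b, alternative="two-sided", method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)


@dataclass
class LopoRow:
    population: str
    U: float
    p: float
    alpha: float
    significant: bool
    skipped: bool = False
    reason: str = ""


def lopo_repeatability(
    G: GenotypeMatrix,
    labels: np.ndarray,
    loci: list[str],
    *,
    min_individuals: int = 3,
) -> pd.DataFrame:
    """Leave-one-population-out repeatability of the risk scores.

    For each population P: refit the weights without P's individuals,
    score P under the full and reduced models, Mann-Whitney the two score
    vectors, and call significance at alpha = 0.05 / n_populations.
    """
    pops = []
    seen = set()
    for s in G.samples:
        p = G.population_of[s]
        if p not in seen:
            seen.add(p)
            pops.append(p)
    if len(pops) < 3:
        raise ValueError("leave-one-population-out needs at least 3 populations")
    alpha = 0.05 / len(pops)
    y = np.asarray(labels, dtype=float)
    full = fit_risk_model(G, y, loci)
    poplab = G.population_labels()

    rows: list[LopoRow] = []
    for p in pops:
        mask = poplab == p
        if mask.sum() < min_individuals:
            rows.append(LopoRow(p, np.nan, np.nan, alpha, False, True, "too few individuals"))
            continue
        keep = [s for s, m in zip(G.samples, mask) if not m]
        G_rest = G.subset_samples(keep)
        y_rest = y[~mask]
        if len(np.unique(y_rest)) < 2:
            rows.append(LopoRow(p, np.nan, np.nan, alpha, False, True, "single class without population"))
            continue
        reduced = fit_risk_model(G_rest, y_rest, loci)
        G_p = G.subset_samples([s for s, m in zip(G.samples, mask) if m])
        s_full = compute_scores(G_p, full).scores
        s_red = compute_scores(G_p, reduced).scores
        if np.allclose(s_full, s_red):
            rows.append(LopoRow(p, len(s_full) ** 2 / 2.0, 1.0, alpha, False))
            continue
        U, pval = _mwu(s_full, s_red)
        rows.append(LopoRow(p, U, pval, alpha, bool(pval < alpha)))
    return pd.DataFrame([r.__dict__ for r in rows])
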