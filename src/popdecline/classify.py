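"""Calling a population "significantly declining" from its Ne trajectory.

The rule compares the trajectory bins nearest to two anchor years
(1975 and 2005 under the default 5-year generation time and 2010 start
year).  A population is declining when either

(a) the recent point estimate is lower and the 95% CIs do not overlap
    (CI_low at the deep bin exceeds CI_high at the recent bin), or
(b) the deep bin's CI is unbounded (infinite upper limit, including any
    negative-bound artifact of the 1/Ne transform) while the recent bin's
    CI is fully bounded — the population has gone from "too large to
    resolve" to measurably small.

Everything else — no significant change, or a significant increase — is
non-declining.  A two-sample variant applies the same CI rules to
single-time-point estimates from a historical and a recent sample of the
same population (unlinked pairs only), which is how the single-sample
trajectory calls can be validated when temporal samples exist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, LinkageMap
from .ldne import LdNeSettings, NeTrajectory, PairBin, reconstruct_trajectory

#: reporting value substituted for unbounded/negative Ne estimates in plots
REPORTING_CAP = 10_000.0


@dataclass
class DeclineCall:
    """Outcome of the decline rule for one population."""

    population: str
    ne_deep: float
    ci_deep: tuple[float, float]
    year_deep: float
    ne_recent: float
    ci_recent: tuple[float, float]
    year_recent: float
    status: str            # declining | non-declining | unclassifiable
    branch: str            # CI-nonoverlap | unbounded-to-bounded | none
    reason: str = ""


def _normalize_ci(ci: tuple[float, float]) -> tuple[float, float]:
    """Map negative/unbounded artifacts to +inf on the Ne scale.

    A negative CI bound signals an unbounded estimate (it arose from a
    negative value on the 1/Ne scale), so it is normalised to +inf before
    the rule is evaluated.
    """
    lo, hi = ci
    if hi < 0 or np.isinf(hi):
        hi = float("inf")
    if lo < 0:
        lo = float("inf")
    return lo, hi


def nearest_bin(traj: NeTrajectory, target_year: float) -> PairBin | None:
    """Bin whose calendar year is closest to ``target_year``.

    Ties break toward the more recent bin.
    """
    best = None
    best_key = None
    for b in traj.bins:
        key = (abs(b.year - target_year), -b.year)
        if best_key is None or key < best_key:
            best, best_key = b, key
    return best


def classify(
    traj: NeTrajectory,
    deep_year: float = 1975.0,
    recent_year: float = 2005.0,
) -> DeclineCall:
    """Apply the decline rule to the bins nearest the two anchor years."""
    deep = nearest_bin(traj, deep_year)
    recent = nearest_bin(traj, recent_year)
    if deep is None or recent is None or deep is recent:
        return DeclineCall(
            population=traj.population,
            ne_deep=float("nan"), ci_deep=(float("nan"), float("nan")),
            year_deep=float("nan"),
            ne_recent=float("nan"), ci_recent=(float("nan"), float("nan")),
            year_recent=float("nan"),
            status="unclassifiable", branch="none",
            reason="missing target bin",
        )
    return _classify_bins(traj.population, deep, recent)


def _classify_bins(pop: str, deep: PairBin, recent: PairBin) -> DeclineCall:
    ci_deep = _normalize_ci((deep.ci_low, deep.ci_high))
    ci_recent = _normalize_ci((recent.ci_low, recent.ci_high))
    deep_unbounded = np.isinf(ci_deep[1])
    recent_bounded = np.isfinite(ci_recent[0]) and np.isfinite(ci_recent[1])

    # branch (b) first: an unbounded deep estimate can coexist with
    # non-overlapping intervals, and the audit trail should name the
    # unbounded-to-bounded transition in that case
    status, branch = "non-declining", "none"
    if deep_unbounded and recent_bounded:
        status, branch = "declining", "unbounded-to-bounded"
    elif (
        recent.ne_hat < deep.ne_hat
        and np.isfinite(ci_deep[0])
        and ci_deep[0] > ci_recent[1]
    ):
        status, branch = "declining", "CI-nonoverlap"
    return DeclineCall(
        population=pop,
        ne_deep=deep.ne_hat, ci_deep=ci_deep, year_deep=deep.year,
        ne_recent=recent.ne_hat, ci_recent=ci_recent, year_recent=recent.year,
        status=status, branch=branch,
    )


def clamp_for_reporting(ne_hat: float, cap: float = REPORTING_CAP) -> float:
    """Plot-friendly Ne: unbounded or negative estimates become ``cap``.

    Used only for figures and summary tables, never for classification.
    """
    if not np.isfinite(ne_hat) or ne_hat < 0:
        return cap
    return float(ne_hat)


def _single_point_estimate(
    G: GenotypeMatrix, lmap: LinkageMap, settings: LdNeSettings, label: str
) -> PairBin:
    """Unlinked-bin-only Ne estimate for a single sample (two-sample check)."""
    traj = reconstruct_trajectory(G, lmap, settings, population=label)
    unlinked = [b for b in traj.bins if b.unlinked]
    if not unlinked:
        raise ValueError(f"no unlinked pairs in sample {label}")
    return unlinked[0]


def two_sample_check(
    G_historical: GenotypeMatrix,
    G_recent: GenotypeMatrix,
    lmap: LinkageMap,
    settings: LdNeSettings | None = None,
    population: str = "two-sample",
) -> DeclineCall:
    """Decline call from separate historical and recent samples.

    Each sample gets a single-time-point Ne from unlinked pairs only
    (c = 0.5 closed form) with a jackknife CI; the same CI rules as
    :func:`classify` are applied with (historical, recent) in place of
    the (1975, 2005) bins.
    """
    settings = settings or LdNeSettings()
    hist = _single_point_estimate(G_historical, lmap, settings, "historical")
    rec = _single_point_estimate(G_recent, lmap, settings, "recent")
    return _classify_bins(population, hist, rec)


def calls_to_frame(calls: list[DeclineCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "population": c.population,
                "ne_1975": c.ne_deep,
                "ci_1975_low": c.ci_deep[0],
                "ci_1975_high": c.ci_deep[1],
                "ne_2005": c.ne_recent,
                "ci_2005_low": c.ci_recent[0],
                "ci_2005_high": c.ci_recent[1],
                "status": c.status,
                "branch": c.branch,
            }
        )
    return pd.DataFrame(rows)
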