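"""Welch's unequal-variance t-test and the exudation-call rubric.

A target species is called an exuder when its leaf [Mn] is significantly
higher than the site's negative reference (two-sided Welch test plus a
direction check); it additionally has *strong capacity* when its mean leaf
[Mn] is at or above the positive-reference mean, or significantly above it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from statistics import fmean
from typing import Sequence

import numpy as np
from scipy import stats

from .io import LeafSample, Role
from .references import ReferenceSet, resolve_references

logger = logging.getLogger("mnminer")


class InsufficientReplicationError(ValueError):
    """Fewer than two replicates in a sample to be tested."""


@dataclass(frozen=True)
class WelchResult:
    """Welch's t-test summary for two independent samples."""

    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    degenerate: bool = False  # both variances zero with unequal means


@dataclass(frozen=True)
class ExudationCall:
    """Per species x site exudation classification."""

    species: str
    site_id: str
    vs_negative: WelchResult
    vs_positive: WelchResult
    category: str           # "exudes" | "no_evidence"
    strong_capacity: bool
    alpha: float


def welch_t(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance t-test, two-sided.

    t = (mean_x - mean_y) / sqrt(s2_x/n_x + s2_y/n_y), with the
    Welch-Satterthwaite degrees of freedom and a two-sided Student-t p-value.

    Degenerate corners follow explicit conventions: both variances zero and
    means equal gives t = 0, p = 1; both variances zero with unequal means
    gives an infinite t, p = 0, flagged and logged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_x, n_y = len(x), len(y)
    if n_x < 2 or n_y < 2:
        raise InsufficientReplicationError(
            f"welch_t needs >= 2 observations per sample (got {n_x}, {n_y})"
        )
    mean_x, mean_y = float(x.mean()), float(y.mean())
    var_x = float(x.var(ddof=1))
    var_y = float(y.var(ddof=1))
    if var_x == 0.0 and var_y == 0.0:
        if mean_x == mean_y:
            return WelchResult(0.0, float(n_x + n_y - 2), 1.0,
                               mean_x, mean_y, n_x, n_y)
        logger.warning(
            "welch_t: both samples have zero variance with unequal means; "
            "reporting infinite t, p = 0"
        )
        t = math.inf if mean_x > mean_y else -math.inf
        return WelchResult(t, float(n_x + n_y - 2), 0.0,
                           mean_x, mean_y, n_x, n_y, degenerate=True)
    se2 = var_x / n_x + var_y / n_y
    t = (mean_x - mean_y) / math.sqrt(se2)
    df = se2 ** 2 / (
        (var_x / n_x) ** 2 / (n_x - 1) + (var_y / n_y) ** 2 / (n_y - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(t, df, float(p), mean_x, mean_y, n_x, n_y)


def classify_species(
    target: Sequence[LeafSample],
    refset: ReferenceSet,
    alpha: float = 0.05,
    one_sided: bool = False,
) -> ExudationCall:
    """Classify one target species at one site against its references.

    ``category`` is ``"exudes"`` iff the target's Mn is significantly higher
    than the negative reference (the test is two-sided by default, paired
    with a direction check; ``one_sided`` halves the p-value for positive
    differences instead). ``strong_capacity`` is true when the target mean is
    at or above the positive-reference mean, or significantly above it.
    """
    if len(target) < 2:
        raise InsufficientReplicationError(
            f"need >= 2 target replicates, got {len(target)}"
        )
    species = target[0].species
    site = target[0].site_id
    mn = [s.mn for s in target]
    vs_neg = welch_t(mn, refset.negative_mn)
    vs_pos = welch_t(mn, refset.positive_mn)

    def significant_higher(res: WelchResult) -> bool:
        p = res.p
        if one_sided:
            p = res.p / 2.0 if res.t > 0 else 1.0 - res.p / 2.0
        return p < alpha and res.mean_a > res.mean_b

    exudes = significant_higher(vs_neg)
    strong = vs_pos.mean_a >= vs_pos.mean_b or significant_higher(vs_pos)
    return ExudationCall(
        species=species,
        site_id=site,
        vs_negative=vs_neg,
        vs_positive=vs_pos,
        category="exudes" if exudes else "no_evidence",
        strong_capacity=strong,
        alpha=alpha,
    )


def classify_survey(
    samples: Sequence[LeafSample],
    alpha: float = 0.05,
    one_sided: bool = False,
    holm: bool = False,
) -> list[ExudationCall]:
    """Run the classifier over every target species x site in a survey.

    With ``holm=True`` the per-site vs-negative p-values are Holm-adjusted
    across all calls before categories are assigned (off by default).
    """
    sites = sorted({s.site_id for s in samples})
    calls: list[ExudationCall] = []
    for site in sites:
        refset = resolve_references(samples, site)
        by_species: dict[str, list[LeafSample]] = {}
        for s in samples:
            if s.site_id == site and s.role == Role.TARGET:
                by_species.setdefault(s.species, []).append(s)
        for species in sorted(by_species):
            reps = by_species[species]
            if len(reps) < 2:
                logger.warning(
                    "skipping %s at %s: only %d replicate(s)",
                    species, site, len(reps),
                )
                continue
            calls.append(
                classify_species(reps, refset, alpha=alpha, one_sided=one_sided)
            )
    if holm and calls:
        order = np.argsort([c.vs_negative.p for c in calls])
        m = len(calls)
        adjusted = [0.0] * m
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * calls[idx].vs_negative.p)
            adjusted[idx] = min(1.0, running)
        calls = [
            ExudationCall(
                species=c.species, site_id=c.site_id,
                vs_negative=c.vs_negative, vs_positive=c.vs_positive,
                category=(
                    "exudes"
                    if adjusted[i] < c.alpha
                    and c.vs_negative.mean_a > c.vs_negative.mean_b
                    else "no_evidence"
                ),
                strong_capacity=c.strong_capacity, alpha=c.alpha,
            )
            for i, c in enumerate(calls)
        ]
    return calls


def classification_table(calls: Sequence[ExudationCall]):
    """Per-genus summary: species counts, exuder counts and percentages.

    A species sampled at several sites is counted once, as an exuder if any
    of its site-level calls is positive (and likewise for strong capacity).
    Returns a pandas DataFrame (one row per genus plus a total row).
    """
    import pandas as pd

    per_species: dict[str, dict] = {}
    for c in calls:
        genus = c.species.split()[0]
        rec = per_species.setdefault(
            c.species, {"genus": genus, "exudes": False, "strong": False}
        )
        rec["exudes"] = rec["exudes"] or c.category == "exudes"
        rec["strong"] = rec["strong"] or c.strong_capacity
    rows = []
    genera = sorted({r["genus"] for r in per_species.values()})
    for genus in genera:
        specs = [s for s, r in per_species.items() if r["genus"] == genus]
        n = len(specs)
        n_ex = sum(per_species[s]["exudes"] for s in specs)
        n_strong = sum(per_species[s]["strong"] for s in specs)
        rows.append({
            "genus": genus, "n_species": n, "n_exudes": n_ex,
            "n_strong_capacity": n_strong,
            "pct_exudes": 100.0 * n_ex / n if n else float("nan"),
            "pct_strong_capacity": 100.0 * n_strong / n if n else float("nan"),
        })
    n = len(per_species)
    n_ex = sum(r["exudes"] for r in per_species.values())
    n_strong = sum(r["strong"] for r in per_species.values())
    if n:
        rows.append({
            "genus": "<all>", "n_species": n, "n_exudes": n_ex,
            "n_strong_capacity": n_strong,
            "pct_exudes": 100.0 * n_ex / n,
            "pct_strong_capacity": 100.0 * n_strong / n,
        })
    return pd.DataFrame(rows)


def calls_to_frame(calls: Sequence[ExudationCall]):
    """Flatten calls to a tidy DataFrame (one row per species x site)."""
    import pandas as pd

    return pd.DataFrame([
        {
            "site_id": c.site_id, "species": c.species,
            "mean_mn": c.vs_negative.mean_a,
            "t_vs_negative": c.vs_negative.t, "p_vs_negative": c.vs_negative.p,
            "t_vs_positive": c.vs_positive.t, "p_vs_positive": c.vs_positive.p,
            "category": c.category, "strong_capacity": c.strong_capacity,
            "alpha": c.alpha,
        }
        for c in calls
    ])
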