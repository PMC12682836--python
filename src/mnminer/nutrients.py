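"""Site/species-level nutrient statistics.

Covers the leaf N:P phosphorus-limitation flag, maximum-likelihood
group-means GLS under candidate variance structures with AICc selection,
post-hoc pairwise comparisons with a compact letter display, PCA with
sampling-adequacy diagnostics (KMO, Bartlett's sphericity), and log-scale
Pearson correlation matrices.

The group-means model is saturated (one mean per group), so the GLS fitted
means equal the group sample means under any variance structure that is
constant within a group; maximum likelihood therefore reduces to the
variance parameters given the residuals, and the power-of-mean structure to
a one-dimensional profile optimisation over its exponent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger("mnminer")

VARIANCE_STRUCTURES = ("constant", "per_group", "power_of_mean")


# ---------------------------------------------------------------------------
# N:P limitation
# ---------------------------------------------------------------------------

def np_ratio(leaf_n: float, leaf_p: float, threshold: float = 20.0):
    """Leaf N:P mass ratio and a P-limitation flag (ratio strictly > threshold).

    Ratios above ~20 are broadly taken to indicate phosphorus limitation of
    plant growth.
    """
    if leaf_p <= 0:
        raise ValueError(f"leaf P must be > 0 for an N:P ratio (got {leaf_p})")
    ratio = leaf_n / leaf_p
    return ratio, ratio > threshold


# ---------------------------------------------------------------------------
# Heteroscedastic group-means GLS with AICc selection
# ---------------------------------------------------------------------------

def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError(f"AICc needs n > k + 1 (n={n}, k={k})")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class GroupMeansGLSResults:
    """Fitted group-means GLS under one variance structure."""

    model: "GroupMeansGLS"
    variance_structure: str
    coefficients: dict[str, float]       # group -> fitted mean
    group_variances: dict[str, float]    # group -> ML residual variance
    params: dict[str, float]             # variance-function parameters
    log_likelihood: float
    k: int
    n: int

    @property
    def aicc(self) -> float:
        return aicc(self.log_likelihood, self.k, self.n)

    def summary(self) -> str:
        lines = [
            f"Group-means GLS ({self.variance_structure} variance)",
            f"  n = {self.n}, k = {self.k}, "
            f"logLik = {self.log_likelihood:.3f}, AICc = {self.aicc:.3f}",
            "  group means:",
        ]
        for g, m in self.coefficients.items():
            lines.append(
                f"    {g}: mean = {m:.4g}, var = {self.group_variances[g]:.4g}"
            )
        if self.params:
            lines.append(
                "  variance parameters: "
                + ", ".join(f"{k} = {v:.4g}" for k, v in self.params.items())
            )
        return "\n".join(lines)


class GroupMeansGLS:
    """One-way group-means model fitted by ML under a variance structure.

    Structures: ``constant`` (one sigma^2), ``per_group`` (sigma^2_g per
    group), ``power_of_mean`` (Var = sigma^2 * |mu_g|^(2*delta)).

    Use :meth:`fit` for one structure, :meth:`fit_select` for AICc selection
    over a candidate set (ties broken toward fewer parameters).
    """

    def __init__(self, response: Sequence[float], group: Sequence):
        y = np.asarray(response, dtype=float)
        g = np.asarray(group)
        if y.shape != g.shape:
            raise ValueError("response and group must have equal length")
        self.groups = [str(v) for v in pd.unique(g)]
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        self.y_by_group = {
            lab: y[np.asarray([str(v) == lab for v in g])] for lab in self.groups
        }
        for lab, yy in self.y_by_group.items():
            if len(yy) < 2:
                raise ValueError(f"group {lab!r} has fewer than 2 observations")
        self.n = len(y)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str, group: str):
        sub = data[[response, group]].dropna()
        return cls(sub[response].to_numpy(), sub[group].to_numpy())

    # -- internals ---------------------------------------------------------

    def _moments(self):
        means = {g: float(y.mean()) for g, y in self.y_by_group.items()}
        rss = {g: float(((y - means[g]) ** 2).sum()) for g, y in self.y_by_group.items()}
        ns = {g: len(y) for g, y in self.y_by_group.items()}
        return means, rss, ns

    def fit(self, variance_structure: str = "constant") -> GroupMeansGLSResults:
        means, rss, ns = self._moments()
        n, g = self.n, len(self.groups)
        c = -0.5 * n * math.log(2.0 * math.pi)
        if variance_structure == "constant":
            sigma2 = sum(rss.values()) / n
            if sigma2 <= 0:
                raise ValueError("zero residual variance; model degenerate")
            ll = c - 0.5 * n * math.log(sigma2) - 0.5 * n
            gvar = {lab: sigma2 for lab in self.groups}
            params = {"sigma2": sigma2}
            k = g + 1
        elif variance_structure == "per_group":
            gvar = {}
            ll = c
            for lab in self.groups:
                s2 = rss[lab] / ns[lab]
                if s2 <= 0:
                    raise ValueError(f"zero residual variance in group {lab!r}")
                gvar[lab] = s2
                ll += -0.5 * ns[lab] * math.log(s2) - 0.5 * ns[lab]
            params = {f"sigma2[{lab}]": gvar[lab] for lab in self.groups}
            k = 2 * g
        elif variance_structure == "power_of_mean":
            mu = np.array([abs(means[lab]) for lab in self.groups])
            if np.any(mu == 0):
                raise ValueError("power_of_mean undefined for a zero group mean")
            log_mu = np.log(mu)
            rss_v = np.array([rss[lab] for lab in self.groups])
            ns_v = np.array([ns[lab] for lab in self.groups], dtype=float)

            def profile_nll(delta: float) -> float:
                w = np.exp(-2.0 * delta * log_mu)  # |mu|^(-2 delta)
                sigma2 = float((rss_v * w).sum()) / n
                if sigma2 <= 0:
                    return math.inf
                return 0.5 * n * math.log(sigma2) + delta * float(
                    (2.0 * ns_v * log_mu).sum()
                ) * 0.5 + 0.5 * n

            res = optimize.minimize_scalar(
                profile_nll, bounds=(-10.0, 10.0), method="bounded",
                options={"xatol": 1e-10},
            )
            delta = float(res.x)
            w = np.exp(-2.0 * delta * log_mu)
            sigma2 = float((rss_v * w).sum()) / n
            ll = c - profile_nll(delta)
            gvar = {
                lab: sigma2 * abs(means[lab]) ** (2.0 * delta)
                for lab in self.groups
            }
            params = {"sigma2": sigma2, "delta": delta}
            k = g + 2
        else:
            raise ValueError(f"unknown variance structure {variance_structure!r}")
        if self.n <= k + 1:
            raise ValueError(
                f"n={self.n} too small for {variance_structure} (k={k})"
            )
        return GroupMeansGLSResults(
            model=self, variance_structure=variance_structure,
            coefficients=means, group_variances=gvar, params=params,
            log_likelihood=ll, k=k, n=n,
        )

    def fit_select(
        self,
        structures: Sequence[str] = VARIANCE_STRUCTURES,
        parsimony_margin: float = 2.0,
    ) -> tuple[GroupMeansGLSResults, pd.DataFrame]:
        """Fit every candidate structure; select by lowest AICc with the
        conventional parsimony band: among candidates within
        ``parsimony_margin`` AICc units of the minimum (models that the AICc
        scale regards as effectively equivalent), the one with the fewest
        parameters wins. ``parsimony_margin=0`` gives strict lowest-AICc.
        Returns the selected fit and the full candidate table."""
        fits = []
        for s in structures:
            try:
                fits.append(self.fit(s))
            except ValueError as exc:
                logger.warning("skipping structure %s: %s", s, exc)
        if not fits:
            raise ValueError("no variance structure could be fitted")
        table = pd.DataFrame([
            {
                "variance_structure": f.variance_structure, "k": f.k,
                "log_likelihood": f.log_likelihood, "aicc": f.aicc,
            }
            for f in fits
        ]).sort_values("aicc", kind="stable").reset_index(drop=True)
        best_aicc = min(f.aicc for f in fits)
        contenders = [f for f in fits if f.aicc <= best_aicc + parsimony_margin]
        best = min(contenders, key=lambda f: (f.k, f.aicc))
        return best, table


def fit_gls_aicc(
    response: Sequence[float],
    group: Sequence,
    structures: Sequence[str] = VARIANCE_STRUCTURES,
) -> tuple[GroupMeansGLSResults, pd.DataFrame]:
    """Functional wrapper: build :class:`GroupMeansGLS` and select by AICc."""
    return GroupMeansGLS(response, group).fit_select(structures)


# ---------------------------------------------------------------------------
# Post-hoc pairwise comparisons + compact letter display
# ---------------------------------------------------------------------------

def _letters_from_nondiff(groups: list[str], same: dict[tuple[str, str], bool]):
    """Insert-and-absorb compact letter display."""
    letter_sets: list[set[str]] = []
    for gi in groups:
        placed = False
        for ls in letter_sets:
            if all(same[tuple(sorted((gi, gj)))] for gj in ls if gj != gi):
                ls.add(gi)
                placed = True
        if not placed:
            letter_sets.append({gi})
    # absorb subsets
    letter_sets = [
        ls for i, ls in enumerate(letter_sets)
        if not any(ls < other for j, other in enumerate(letter_sets) if i != j)
    ]
    # ensure every significantly-different pair is separated
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {}
    for gi in groups:
        out[gi] = "".join(
            alphabet[k % 26] for k, ls in enumerate(letter_sets) if gi in ls
        )
    return out


def posthoc_groups(fit: GroupMeansGLSResults, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise group contrasts under the studentized-range criterion.

    Under the constant variance structure this is classical Tukey HSD; under
    per-group or power-of-mean variances, standard errors use the fitted
    group variances with Welch-style degrees of freedom (Games-Howell).
    Adds a compact letter display: groups sharing a letter do not differ at
    ``alpha``.
    """
    groups = fit.model.groups
    if len(groups) < 2:
        raise ValueError("post hoc needs >= 2 groups")
    k = len(groups)
    means = fit.coefficients
    ns = {g: len(fit.model.y_by_group[g]) for g in groups}
    # sample variances for Welch df; fitted variances for SEs
    s2 = {g: float(fit.model.y_by_group[g].var(ddof=1)) for g in groups}
    rows = []
    same: dict[tuple[str, str], bool] = {}
    constant = fit.variance_structure == "constant"
    if constant:
        df_resid = fit.n - k
        mse = sum(
            float(((fit.model.y_by_group[g] - means[g]) ** 2).sum()) for g in groups
        ) / df_resid
    for i, gi in enumerate(groups):
        for gj in groups[i + 1:]:
            diff = means[gi] - means[gj]
            if constant:
                se = math.sqrt(mse / 2.0 * (1.0 / ns[gi] + 1.0 / ns[gj]))
                df = df_resid
            else:
                vi, vj = fit.group_variances[gi] / ns[gi], fit.group_variances[gj] / ns[gj]
                se = math.sqrt((vi + vj) / 2.0)
                # Welch-Satterthwaite on the sample variances
                wi, wj = s2[gi] / ns[gi], s2[gj] / ns[gj]
                df = (wi + wj) ** 2 / (
                    wi ** 2 / (ns[gi] - 1) + wj ** 2 / (ns[gj] - 1)
                )
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df))
            rows.append({
                "group_a": gi, "group_b": gj, "diff": diff, "se": se,
                "q": q, "df": df, "p": p, "significant": p < alpha,
            })
            same[tuple(sorted((gi, gj)))] = not (p < alpha)
    table = pd.DataFrame(rows)
    letters = _letters_from_nondiff(list(groups), same)
    table.attrs["letters"] = letters
    table.attrs["letters_table"] = pd.DataFrame(
        {"group": list(letters), "letters": list(letters.values()),
         "mean": [means[g] for g in letters]}
    )
    return table


# ---------------------------------------------------------------------------
# PCA with KMO / Bartlett diagnostics
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_fractions: np.ndarray
    kmo: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    n_obs: int
    n_dropped: int


def pca_diagnostics(matrix: pd.DataFrame) -> PcaResult:
    """PCA on the correlation matrix with KMO and Bartlett diagnostics.

    Rows with any missing value are dropped (listwise deletion, counted).
    KMO > 0.6 and Bartlett p < 0.05 are the conventional adequacy gates;
    both statistics are returned, not enforced. A singular correlation
    matrix leaves KMO as NaN with a warning (the PCA itself is still valid).
    """
    if not isinstance(matrix, pd.DataFrame):
        matrix = pd.DataFrame(np.asarray(matrix, dtype=float))
    clean = matrix.dropna()
    n_dropped = len(matrix) - len(clean)
    if n_dropped:
        logger.info("pca_diagnostics: dropped %d incomplete row(s)", n_dropped)
    n, v = clean.shape
    if v < 3:
        raise ValueError("PCA diagnostics need >= 3 variables")
    if n <= v:
        raise ValueError(f"need more observations ({n}) than variables ({v})")
    sd = clean.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant column(s): {', '.join(map(str, constant))}")

    z = (clean - clean.mean()) / sd
    r = np.corrcoef(z.to_numpy(), rowvar=False)
    evals, evecs = np.linalg.eigh(r)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    frac = evals / evals.sum()
    comp_names = [f"PC{i+1}" for i in range(v)]
    loadings = pd.DataFrame(evecs, index=clean.columns, columns=comp_names)
    scores = pd.DataFrame(
        z.to_numpy() @ evecs, index=clean.index, columns=comp_names
    )

    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        logger.warning("correlation matrix numerically singular; det <= 0")
        logdet = -math.inf
    chi2 = -(n - 1 - (2 * v + 5) / 6.0) * logdet
    df = v * (v - 1) // 2
    bartlett_p = float(stats.chi2.sf(chi2, df)) if math.isfinite(chi2) else 0.0

    try:
        prec = np.linalg.inv(r)
        d = np.sqrt(np.outer(np.diag(prec), np.diag(prec)))
        partial = -prec / d
        off = ~np.eye(v, dtype=bool)
        kmo = float((r[off] ** 2).sum() / ((r[off] ** 2).sum() + (partial[off] ** 2).sum()))
    except np.linalg.LinAlgError:
        logger.warning("singular correlation matrix; KMO undefined")
        kmo = float("nan")

    return PcaResult(
        scores=scores, loadings=loadings, explained_variance_fractions=frac,
        kmo=kmo, bartlett_chi2=float(chi2), bartlett_df=df,
        bartlett_p=bartlett_p, n_obs=n, n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# Log-scale Pearson correlation matrix
# ---------------------------------------------------------------------------

def correlation_matrix(
    data: pd.DataFrame,
    variables: Sequence[str],
    transform: str = "log",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with two-sided t-test p-values.

    ``transform="log"`` applies a natural-log transform first (concentrations
    are positive and right-skewed); non-positive values raise with the row
    and variable named. Returns (r matrix, p matrix); r is symmetric with a
    unit diagonal.
    """
    variables = list(variables)
    sub = data[variables].astype(float)
    if transform == "log":
        bad = sub <= 0
        if bad.any().any():
            rows = sub.index[bad.any(axis=1)].tolist()[:5]
            cols = [c for c in variables if bad[c].any()]
            raise ValueError(
                f"non-positive values under log transform in {cols} "
                f"(e.g. rows {rows})"
            )
        sub = np.log(sub)
    elif transform not in (None, "none"):
        raise ValueError(f"unknown transform {transform!r}")
    v = len(variables)
    r = pd.DataFrame(np.eye(v), index=variables, columns=variables)
    p = pd.DataFrame(np.zeros((v, v)), index=variables, columns=variables)
    for i, a in enumerate(variables):
        for b in variables[i + 1:]:
            pair = sub[[a, b]].dropna()
            if len(pair) < 3:
                raise ValueError(f"fewer than 3 complete pairs for ({a}, {b})")
            rr, pp = stats.pearsonr(pair[a], pair[b])
            r.loc[a, b] = r.loc[b, a] = float(rr)
            p.loc[a, b] = p.loc[b, a] = float(pp)
    return r, p
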