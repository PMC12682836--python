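"""Phylogenetic comparative methods under Brownian motion.

Everything here is built on the tree-implied covariance matrix V, whose
(i, j) entry is the shared root-to-MRCA path length of tips i and j: the
phylogenetic mean and Blomberg's K variance-ratio statistic with a
randomisation test, maximum-likelihood ancestral states for continuous
traits, phylogenetic generalised least squares (PGLS), and Spearman/PGLS
tests of speciation tip rates against traits. Brownian motion is the only
correlation model; K = 1 is the Brownian expectation, K < 1 weaker signal.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import Phylogeny

logger = logging.getLogger("mnminer")


class ConstantTraitError(ValueError):
    """Trait has zero variance; signal statistics undefined."""


@dataclass(frozen=True)
class TraitVector:
    """Continuous trait values keyed by tip label, optionally log-scale.

    ``transform="log"`` records that ``values`` already hold natural-log
    trait values (use :meth:`from_raw` to build one from raw positive data).
    """

    values: Mapping[str, float]
    name: str = "trait"
    transform: str = "none"

    @classmethod
    def from_raw(cls, values: Mapping[str, float], name: str = "trait",
                 log: bool = True) -> "TraitVector":
        if log:
            bad = [k for k, v in values.items() if not v > 0]
            if bad:
                raise ValueError(f"log transform needs positive values; bad tips: {bad}")
            return cls({k: math.log(v) for k, v in values.items()}, name, "log")
        return cls(dict(values), name, "none")

    def aligned(self, labels: Sequence[str]) -> np.ndarray:
        missing = [l for l in labels if l not in self.values]
        if missing:
            raise KeyError(
                f"trait {self.name!r} missing tip value(s): {missing} "
                "(complete data required; no imputation)"
            )
        return np.array([self.values[l] for l in labels], dtype=float)


@dataclass(frozen=True)
class SignalResult:
    """Blomberg's K with its randomisation-test p-value."""

    k: float
    p: float
    n_perm: int
    seed: int
    observed_msr: float   # MSE0 / MSE variance ratio
    expected_msr: float   # Brownian expectation of the ratio
    n_tips: int


# ---------------------------------------------------------------------------
# Tree covariance
# ---------------------------------------------------------------------------

def phylo_vcv(phy: Phylogeny) -> pd.DataFrame:
    """Brownian covariance matrix V: shared root-to-MRCA path lengths.

    Diagonal entries are root-to-tip depths; V is symmetric positive
    semidefinite by construction. Tips are ordered alphabetically.
    """
    if not phy.rooted:
        raise ValueError("phylo_vcv requires a rooted tree")
    labels = sorted(phy.tip_labels)
    index = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    v = np.zeros((n, n))
    # postorder: cross pairs first meet at the current node, at depth d
    for node in phy.tree.preorder_node_iter():
        parent_depth = 0.0 if node.parent_node is None else node.parent_node._d
        node._d = parent_depth + (node.edge.length or 0.0)
    for node in phy.tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            node._tips = [i]
            v[i, i] = node._d
        else:
            groups = [ch._tips for ch in node.child_nodes()]
            for a, b in itertools.combinations(groups, 2):
                for i in a:
                    v[i, b] = node._d
                    v[b, i] = node._d
            node._tips = [i for grp in groups for i in grp]
    return pd.DataFrame(v, index=labels, columns=labels)


def _stable_inverse(v: np.ndarray, tree_depth: float):
    """Cholesky-based inverse; singular V gets a tiny logged jitter."""
    try:
        c = np.linalg.cholesky(v)
    except np.linalg.LinAlgError:
        eps = 1e-12 * max(tree_depth, 1.0)
        logger.warning("V singular; adding %.3g jitter to the diagonal", eps)
        c = np.linalg.cholesky(v + eps * np.eye(len(v)))
    ci = np.linalg.inv(c)
    return ci.T @ ci, 2.0 * float(np.log(np.diag(c)).sum())


def _phylo_mean(vinv: np.ndarray, y: np.ndarray) -> float:
    one = np.ones(len(y))
    return float(one @ vinv @ y) / float(one @ vinv @ one)


# ---------------------------------------------------------------------------
# Blomberg's K
# ---------------------------------------------------------------------------

def blomberg_k(
    phy: Phylogeny,
    trait: TraitVector,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> SignalResult:
    """Blomberg's K with a permutation test for phylogenetic signal.

    With a^ the phylogenetic (GLS root) mean,

        MSE0 = (y - a^)'(y - a^) / (n - 1)
        MSE  = (y - a^)' V^-1 (y - a^) / (n - 1)
        K    = (MSE0/MSE) / { [tr(V) - n / (1'V^-1 1)] / (n - 1) }

    The p-value shuffles trait values across tips ``n_perm`` times and is
    the upper-tail frequency of variance ratios at least as large as the
    observed one, with the +1 correction; it is exactly reproducible given
    ``seed``.
    """
    v_df = phylo_vcv(phy)
    labels = list(v_df.index)
    v = v_df.to_numpy()
    n = len(labels)
    if n < 4:
        raise ValueError("blomberg_k needs >= 4 tips")
    y = trait.aligned(labels)
    if np.ptp(y) == 0:
        raise ConstantTraitError(f"trait {trait.name!r} is constant across tips")
    depth = float(np.max(np.diag(v)))
    vinv, _ = _stable_inverse(v, depth)
    one = np.ones(n)
    denom_sum = float(one @ vinv @ one)
    expected_msr = (float(np.trace(v)) - n / denom_sum) / (n - 1)

    def msr(col: np.ndarray) -> np.ndarray:
        """Vectorised MSE0/MSE for columns of trait permutations."""
        a = (one @ vinv @ col) / denom_sum
        r = col - np.outer(one, np.atleast_1d(a))
        mse0 = (r * r).sum(axis=0)
        mse = (r * (vinv @ r)).sum(axis=0)
        return mse0 / mse

    observed = float(msr(y[:, None])[0])
    k = observed / expected_msr

    rng = np.random.default_rng(seed)
    perms = np.empty((n, n_perm))
    for j in range(n_perm):
        perms[:, j] = rng.permutation(y)
    ratios = msr(perms)
    p = (1.0 + int((ratios >= observed).sum())) / (n_perm + 1.0)
    return SignalResult(
        k=k, p=p, n_perm=n_perm, seed=-1 if seed is None else int(seed),
        observed_msr=observed, expected_msr=expected_msr, n_tips=n,
    )


# ---------------------------------------------------------------------------
# ML ancestral states
# ---------------------------------------------------------------------------

def asr_ml(phy: Phylogeny, trait: TraitVector) -> dict:
    """Maximum-likelihood Brownian ancestral states for internal nodes.

    States are GLS conditional expectations given the tips: the root state
    equals the phylogenetic mean a^, and node i gets
    a^ + Cov(node_i, tips) V^-1 (y - a^). Returns ``{"nodes": DataFrame
    (node_id, state, depth), "root": float, "interpolate": callable}``;
    ``interpolate(parent_state, child_state, f)`` is the linear Brownian
    conditional expectation at fraction ``f`` along a branch. Zero-length
    cherries with conflicting values are handled in the (jittered) limit
    with a warning.
    """
    v_df = phylo_vcv(phy)
    labels = list(v_df.index)
    index = {l: i for i, l in enumerate(labels)}
    v = v_df.to_numpy()
    n = len(labels)
    y = trait.aligned(labels)
    depth = float(np.max(np.diag(v)))
    vinv, _ = _stable_inverse(v, depth)
    ahat = _phylo_mean(vinv, y)
    resid = y - ahat

    # Cov(internal node, tip j) = depth of MRCA(node, tip) = node depth if
    # tip descends from node, else depth of their deepest common ancestor.
    for node in phy.tree.preorder_node_iter():
        parent_depth = 0.0 if node.parent_node is None else node.parent_node._d
        node._d = parent_depth + (node.edge.length or 0.0)
    rows = []
    node_ids = []
    internal = [nd for nd in phy.tree.preorder_node_iter() if not nd.is_leaf()]
    for k, node in enumerate(internal):
        node._asr_id = k
    for node in internal:
        desc = {index[lf.taxon.label] for lf in node.leaf_iter()}
        cov = np.empty(n)
        for j in range(n):
            if j in desc:
                cov[j] = node._d
            else:
                # walk up until tip j is among descendants
                anc = node.parent_node
                while anc is not None:
                    if labels[j] in {lf.taxon.label for lf in anc.leaf_iter()}:
                        break
                    anc = anc.parent_node
                cov[j] = 0.0 if anc is None else anc._d
        state = ahat + float(cov @ vinv @ resid)
        node_ids.append(node._asr_id)
        rows.append({"node_id": node._asr_id, "state": state, "depth": node._d})
    nodes = pd.DataFrame(rows).set_index("node_id")

    def interpolate(parent_state: float, child_state: float, f: float) -> float:
        return parent_state + f * (child_state - parent_state)

    return {"nodes": nodes, "root": float(nodes.loc[0, "state"]),
            "interpolate": interpolate, "phylo_mean": ahat}


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------

@dataclass
class PGLSResults:
    """PGLS estimates: slope/intercept, SEs, t, p, Brownian residual rate."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    sigma2: float
    df_resid: int
    n: int
    correlation_model: str = "brownian"

    @property
    def slope(self) -> float:
        return float(self.params["slope"])

    @property
    def intercept(self) -> float:
        return float(self.params["intercept"])

    def summary(self) -> str:
        lines = [
            f"PGLS ({self.correlation_model} correlation), n = {self.n}, "
            f"df_resid = {self.df_resid}, sigma2 = {self.sigma2:.4g}",
            f"{'':>10} {'coef':>12} {'se':>12} {'t':>10} {'p':>10}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:>10} {self.params[name]:>12.6g} {self.bse[name]:>12.6g} "
                f"{self.tvalues[name]:>10.4g} {self.pvalues[name]:>10.4g}"
            )
        return "\n".join(lines)


class PGLS:
    """Phylogenetic GLS regression of one trait on another.

    The error covariance is sigma^2 V with V the Brownian tree covariance;
    estimates are beta^ = (X'V^-1X)^-1 X'V^-1 y with an intercept column,
    sigma^2 from the V-weighted residual sum of squares on n - 2 df.
    """

    def __init__(self, phy: Phylogeny, y: TraitVector, x: TraitVector):
        v_df = phylo_vcv(phy)
        self.labels = list(v_df.index)
        if len(self.labels) < 3:
            raise ValueError("pgls needs >= 3 tips (n - 2 residual df)")
        self.v = v_df.to_numpy()
        self.yv = y.aligned(self.labels)
        self.xv = x.aligned(self.labels)
        self.y_name, self.x_name = y.name, x.name

    def fit(self) -> PGLSResults:
        n = len(self.labels)
        x_design = np.column_stack([np.ones(n), self.xv])
        if np.ptp(self.xv) == 0:
            raise ValueError("collinear design: predictor is constant")
        depth = float(np.max(np.diag(self.v)))
        vinv, _ = _stable_inverse(self.v, depth)
        xtvi = x_design.T @ vinv
        xtvix = xtvi @ x_design
        beta = np.linalg.solve(xtvix, xtvi @ self.yv)
        resid = self.yv - x_design @ beta
        df_resid = n - 2
        sigma2 = float(resid @ vinv @ resid) / df_resid
        cov_beta = sigma2 * np.linalg.inv(xtvix)
        se = np.sqrt(np.diag(cov_beta))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
        names = ["intercept", "slope"]
        return PGLSResults(
            params=pd.Series(beta, index=names),
            bse=pd.Series(se, index=names),
            tvalues=pd.Series(tvals, index=names),
            pvalues=pd.Series(pvals, index=names),
            sigma2=sigma2, df_resid=df_resid, n=n,
        )


def pgls(phy: Phylogeny, y: TraitVector, x: TraitVector) -> PGLSResults:
    """Functional wrapper over :class:`PGLS`."""
    return PGLS(phy, y, x).fit()


# ---------------------------------------------------------------------------
# Tip-rate correlations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TipRateVector:
    """Per-tip speciation rates (events per Myr), e.g. from an external
    macroevolutionary analysis or the package's simulator."""

    values: Mapping[str, float]
    source: str = "external"

    def __post_init__(self) -> None:
        bad = [k for k, v in self.values.items() if not v > 0]
        if bad:
            raise ValueError(f"speciation rates must be > 0; bad tips: {bad}")


def _spearman_exact_p(rho_obs: float, x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided permutation p for Spearman's rho (small n)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        r = np.corrcoef(rx, perm)[0, 1]
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def tip_rate_tests(
    rates: TipRateVector,
    traits: Sequence[TraitVector],
    phy: Phylogeny,
    exact_threshold: int = 9,
) -> pd.DataFrame:
    """Spearman and PGLS tests of log tip speciation rate against traits.

    Rates are natural-log transformed (rank-invariant for Spearman, but the
    PGLS arm uses the log scale). The Spearman p-value is an exact
    permutation p for n <= ``exact_threshold`` and the t-approximation
    otherwise. One row per trait.
    """
    labels = sorted(set(phy.tip_labels) & set(rates.values))
    rows = []
    log_rates = TraitVector(
        {l: math.log(rates.values[l]) for l in labels}, name="log_tip_rate",
        transform="log",
    )
    for trait in traits:
        shared = [l for l in labels if l in trait.values]
        if len(shared) < 4:
            raise ValueError(
                f"trait {trait.name!r} shares only {len(shared)} tips with rates"
            )
        x = trait.aligned(shared)
        r = np.array([rates.values[l] for l in shared])
        if np.ptp(r) == 0:
            raise ValueError("all tip rates tied; Spearman rho undefined")
        rho, p_asym = stats.spearmanr(r, x)
        if len(shared) <= exact_threshold:
            p_s = _spearman_exact_p(float(rho), r, x)
            p_kind = "exact"
        else:
            p_s, p_kind = float(p_asym), "asymptotic"
        sub = prune_shared(phy, shared)
        fit = PGLS(sub, log_rates, trait).fit()
        rows.append({
            "trait": trait.name, "n": len(shared),
            "spearman_rho": float(rho), "spearman_p": p_s,
            "spearman_p_kind": p_kind,
            "pgls_slope": fit.slope, "pgls_p": float(fit.pvalues["slope"]),
        })
    return pd.DataFrame(rows)


def prune_shared(phy: Phylogeny, labels: Sequence[str]) -> Phylogeny:
    from .io import prune_to_taxa

    if set(labels) == set(phy.tip_labels):
        return phy
    return prune_to_taxa(phy, labels)
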