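"""Synthetic surveys, trees, traits and tip rates with known ground truth.

The survey generator emulates the sampling design the pipeline targets:
18 acidic low-P sites across a few regions, one positive and one negative
reference species per site (with designated sites missing one so the
cross-site average-reference fallback is exercised), a handful of target
species per site with 5 replicates each, lognormal within-species element
variation with a shared multiplicative site-fertility effect, and leaf N/P
drawn jointly on the log scale with correlation 0.8 so stoichiometry and
correlation stages have structure. Default Mn levels follow field
magnitudes: negative references ~40, positive references ~300, strong
exuders ~1000 mg kg^-1.

Trees are pure-birth (Yule); traits evolve by Brownian motion accumulated
root-to-tip; log tip speciation rates are a linear function of the trait
plus noise, giving the rate-trait tests recoverable signal.

Each artifact (survey, tree, traits, rates) consumes its own RNG stream
spawned from the master seed, so adding a stage never perturbs earlier
outputs; the same seed yields byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .io import Phylogeny, read_newick
from .phylo import TipRateVector, TraitVector


@dataclass(frozen=True)
class SurveyConfig:
    """Design parameters of a synthetic leaf/soil survey."""

    n_sites: int = 18
    min_species_per_site: int = 1
    max_species_per_site: int = 6
    replicates: int = 5
    exuder_fraction: float = 0.8
    mn_neg_meanlog: float = math.log(40.0)     # mg kg^-1 scale
    mn_pos_meanlog: float = math.log(300.0)
    mn_exuder_meanlog: float = math.log(1000.0)
    sdlog: float = 0.25                         # within-species lognormal sd
    site_effect_sd: float = 0.15                # multiplicative site fertility
    missing_pos_ref_sites: int = 2
    missing_neg_ref_sites: int = 2
    n_species_pool: int = 34
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        if not 0.0 <= self.exuder_fraction <= 1.0:
            raise ValueError("exuder_fraction must be in [0, 1]")
        if self.missing_pos_ref_sites + 1 > self.n_sites:
            raise ValueError("cannot remove positive references from every site")


@dataclass
class GroundTruth:
    """What the generator actually did, keyed to its outputs."""

    exuder: dict[str, bool] = field(default_factory=dict)
    site_has_pos_ref: dict[str, bool] = field(default_factory=dict)
    site_has_neg_ref: dict[str, bool] = field(default_factory=dict)
    bm_sigma2: float | None = None
    rate_slope: float | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


_REGIONS = ("Highlands", "Coastal", "Inland")


def gen_survey(config: SurveyConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (leaf table, soil table, ground truth) for one survey.

    The leaf table parses cleanly through :func:`mnminer.read_leaf_table`;
    element units are the canonical ones (N, P mg g^-1; trace mg kg^-1).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    truth = GroundTruth()
    pool = [f"Genus{chr(65 + i % 4)} species{i:02d}" for i in range(config.n_species_pool)]
    exuder_flags = rng.random(config.n_species_pool) < config.exuder_fraction
    truth.exuder = {sp: bool(f) for sp, f in zip(pool, exuder_flags)}

    sites = [f"S{i+1:02d}" for i in range(config.n_sites)]
    site_effect = rng.normal(0.0, config.site_effect_sd, size=config.n_sites)
    # site fertility also shifts N and P jointly
    no_pos = set(rng.choice(config.n_sites, config.missing_pos_ref_sites, replace=False))
    remaining = [i for i in range(config.n_sites) if i not in no_pos]
    no_neg = set(rng.choice(remaining, min(config.missing_neg_ref_sites, len(remaining) - 1),
                            replace=False))

    leaf_rows = []
    soil_rows = []

    def lognormal(meanlog: float, size: int) -> np.ndarray:
        return np.exp(rng.normal(meanlog, config.sdlog, size=size))

    def emit(site_i, species, genus, role, mn_meanlog, leaf_age="mature"):
        site = sites[site_i]
        mn = np.exp(
            rng.normal(mn_meanlog + site_effect[site_i], config.sdlog,
                       size=config.replicates)
        )
        # leaf N and P: bivariate lognormal, corr 0.8 on the log scale, plus
        # the site fertility effect
        cov = np.array([[0.09, 0.8 * 0.3 * 0.25], [0.8 * 0.3 * 0.25, 0.0625]])
        ln_np = rng.multivariate_normal(
            [math.log(10.6) + site_effect[site_i], math.log(0.4) + site_effect[site_i]],
            cov, size=config.replicates,
        )
        n_vals, p_vals = np.exp(ln_np[:, 0]), np.exp(ln_np[:, 1])
        other = {
            "K": lognormal(math.log(5000.0), config.replicates),
            "Ca": lognormal(math.log(4000.0), config.replicates),
            "Cu": lognormal(math.log(4.0), config.replicates),
            "Zn": lognormal(math.log(15.0), config.replicates),
            "Fe": lognormal(math.log(50.0), config.replicates),
            "Mg": lognormal(math.log(2000.0), config.replicates),
        }
        for rep in range(config.replicates):
            leaf_rows.append({
                "site_id": site,
                "region": _REGIONS[site_i % len(_REGIONS)],
                "species": species, "genus": genus, "role": role,
                "replicate": rep + 1, "leaf_age": leaf_age,
                "N": round(n_vals[rep], 4), "P": round(p_vals[rep], 4),
                "K": round(other["K"][rep], 2), "Ca": round(other["Ca"][rep], 2),
                "Cu": round(other["Cu"][rep], 3), "Zn": round(other["Zn"][rep], 3),
                "Mn": round(mn[rep], 3), "Fe": round(other["Fe"][rep], 3),
                "Mg": round(other["Mg"][rep], 2),
            })

    for i, site in enumerate(sites):
        n_targets = int(rng.integers(config.min_species_per_site,
                                     config.max_species_per_site + 1))
        chosen = rng.choice(config.n_species_pool, n_targets, replace=False)
        truth.site_has_pos_ref[site] = i not in no_pos
        truth.site_has_neg_ref[site] = i not in no_neg
        if i not in no_pos:
            emit(i, "Posref clusterroot", "Posref", "positive_ref",
                 config.mn_pos_meanlog)
        if i not in no_neg:
            emit(i, "Negref grasstree", "Negref", "negative_ref",
                 config.mn_neg_meanlog)
        for sp_idx in chosen:
            sp = pool[sp_idx]
            meanlog = (
                config.mn_exuder_meanlog if exuder_flags[sp_idx]
                else config.mn_neg_meanlog
            )
            emit(i, sp, sp.split()[0], "target", meanlog)
        # acidic, low-P topsoil; one record per sampling location
        for loc in range(3):
            ph_w = float(rng.uniform(3.9, 5.4))
            soil_rows.append({
                "site_id": site, "location": loc + 1,
                "pH_water": round(ph_w, 2),
                "pH_cacl2": round(float(rng.uniform(3.4, 4.9)), 2),
                "ec": round(float(rng.uniform(20.0, 120.0)), 1),
                "olsen_p": round(float(rng.gamma(2.0, 1.2)), 2),
                "water_p": round(float(rng.gamma(1.5, 0.8)), 2),
                "total_P": round(float(rng.gamma(3.0, 18.0)), 1),
                "total_Mn": round(float(rng.gamma(2.0, 12.0)), 1),
                "total_Fe": round(float(rng.gamma(3.0, 900.0)), 0),
                "total_Ca": round(float(rng.gamma(2.5, 150.0)), 1),
            })

    leaf = pd.DataFrame(leaf_rows)
    soil = pd.DataFrame(soil_rows)
    return leaf, soil, truth


# ---------------------------------------------------------------------------
# Trees, traits, rates
# ---------------------------------------------------------------------------

def _yule_tree(n_tips: int, birth_rate: float, rng: np.random.Generator) -> Phylogeny:
    """Pure-birth tree grown by exponential waiting times, returned rooted.

    Implemented directly (rather than via an external simulator) so the
    stream of random draws is fully controlled by ``rng``.
    """
    # lineage id -> (parent id, birth time); grow until n_tips lineages
    t = 0.0
    next_id = 2
    active = {0: (None, 0.0), 1: (None, 0.0)}  # root bifurcates at time 0
    events: list[tuple[int, int, int, float]] = []  # (parent, child_a, child_b, time)
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        split = int(rng.choice(sorted(active)))
        a, b = next_id, next_id + 1
        next_id += 2
        events.append((split, a, b, t))
        birth = active.pop(split)
        active[a] = (split, t)
        active[b] = (split, t)
    t_end = t + rng.exponential(1.0 / (birth_rate * len(active)))

    # assemble newick bottom-up
    birth_time = {0: 0.0, 1: 0.0}
    children: dict[int, tuple[int, int, float]] = {}
    for parent, a, b, when in events:
        children[parent] = (a, b, when)
        birth_time[a] = when
        birth_time[b] = when

    tip_counter = iter(range(1, n_tips + 1))

    def render(node: int) -> str:
        if node in children:
            a, b, when = children[node]
            length = when - birth_time[node]
            return f"({render(a)},{render(b)}):{length:.10f}"
        length = t_end - birth_time[node]
        return f"t{next(tip_counter)}:{length:.10f}"

    newick = f"({render(0)},{render(1)});"
    return read_newick(newick)


def _simulate_bm(phy: Phylogeny, sigma2: float, rng: np.random.Generator) -> dict[str, float]:
    """Brownian trait accumulated root-to-tip along each branch."""
    values: dict[str, float] = {}
    for node in phy.tree.preorder_node_iter():
        parent_val = 0.0 if node.parent_node is None else node.parent_node._bm
        bl = node.edge.length or 0.0
        node._bm = parent_val + (
            rng.normal(0.0, math.sqrt(sigma2 * bl)) if bl > 0 else 0.0
        )
        if node.is_leaf():
            values[node.taxon.label] = float(node._bm)
    return values


def gen_tree_traits_rates(
    n_tips: int = 50,
    birth_rate: float = 1.0,
    bm_sigma2: float = 1.0,
    rate_slope: float = -1.0,
    rate_noise_sd: float = 0.1,
    rate_intercept: float = -1.0,
    seed: int = 0,
) -> tuple[Phylogeny, TraitVector, TipRateVector, GroundTruth]:
    """Yule tree + Brownian trait + trait-linked log tip speciation rates.

    log(rate) = rate_intercept + rate_slope * trait + Normal(0, rate_noise_sd),
    standing in for externally estimated macroevolutionary tip rates.
    ``bm_sigma2 = 0`` produces a constant trait (useful for degenerate-input
    contracts downstream).
    """
    if n_tips < 4:
        raise ValueError("n_tips must be >= 4")
    streams = np.random.SeedSequence(seed).spawn(3)
    tree_rng = np.random.default_rng(streams[0])
    trait_rng = np.random.default_rng(streams[1])
    rate_rng = np.random.default_rng(streams[2])

    phy = _yule_tree(n_tips, birth_rate, tree_rng)
    trait_vals = _simulate_bm(phy, bm_sigma2, trait_rng)
    trait = TraitVector(trait_vals, name="trait")
    rates = {
        tip: math.exp(
            rate_intercept + rate_slope * trait_vals[tip]
            + rate_rng.normal(0.0, rate_noise_sd)
        )
        for tip in sorted(trait_vals)
    }
    truth = GroundTruth(bm_sigma2=bm_sigma2, rate_slope=rate_slope)
    return phy, trait, TipRateVector(rates, source="simulated"), truth


def write_survey(out_dir: str | Path, config: SurveyConfig,
                 tree_kwargs: dict | None = None) -> dict[str, Path]:
    """Write leaf.csv, soil.csv, tree.nwk, traits.csv, rates.csv, truth.json."""
    from .io import write_newick

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    leaf, soil, truth = gen_survey(config)
    phy, trait, rates, tree_truth = gen_tree_traits_rates(
        seed=config.seed + 1, **(tree_kwargs or {})
    )
    truth.bm_sigma2 = tree_truth.bm_sigma2
    truth.rate_slope = tree_truth.rate_slope
    paths = {
        "leaf": out / "leaf.csv", "soil": out / "soil.csv",
        "tree": out / "tree.nwk", "traits": out / "traits.csv",
        "rates": out / "rates.csv", "truth": out / "truth.json",
    }
    leaf.to_csv(paths["leaf"], index=False)
    soil.to_csv(paths["soil"], index=False)
    paths["tree"].write_text(write_newick(phy) + "\n")
    pd.DataFrame(
        {"tip": list(trait.values), "trait": list(trait.values.values())}
    ).to_csv(paths["traits"], index=False)
    pd.DataFrame(
        {"tip": list(rates.values), "rate": list(rates.values.values())}
    ).to_csv(paths["rates"], index=False)
    paths["truth"].write_text(truth.to_json() + "\n")
    return paths
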