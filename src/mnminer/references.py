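"""Per-site reference resolution and reference-normalised leaf-Mn scores.

Each site needs a positive reference (a known carboxylate exuder, typically
a cluster-rooted Proteaceae such as *Banksia*) and a negative reference
(a non-exuder such as *Xanthorrhoea*, or young leaves where nothing better
grows). Sites missing a reference fall back to the cross-site average
reference (APR / ANR), with one pseudo-replicate per contributing site so
downstream Welch tests stay defined. The relative leaf [Mn] score places a
target species on a 0-100 % scale between its site's negative and positive
reference means:

    relative [Mn] (%) = 100 * (target - neg) / (pos - neg)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from statistics import fmean
from typing import Sequence

from .io import LeafSample, LeafAge, Role

logger = logging.getLogger("mnminer")

#: relative tolerance below which pos and neg reference means are considered
#: indistinguishable and the relative score undefined (numerical guard only)
DEGENERATE_RTOL = 1e-9


class RefProvenance(str, Enum):
    OBSERVED = "observed"
    GROUPED = "grouped"         # >1 reference species at the site, pooled
    SITE_AVERAGE = "site_average"  # APR / ANR cross-site fallback
    YOUNG_LEAF = "young_leaf"


class DegenerateReferenceError(ValueError):
    """Positive and negative reference means coincide; score undefined."""


class UnresolvableReferenceError(ValueError):
    """No reference of the required polarity observed at any site."""


@dataclass(frozen=True)
class ReferenceSet:
    """Resolved positive/negative reference samples for one site."""

    site_id: str
    positive: tuple[LeafSample, ...]
    negative: tuple[LeafSample, ...]
    pos_provenance: RefProvenance
    neg_provenance: RefProvenance

    @property
    def positive_mn(self) -> list[float]:
        return [s.mn for s in self.positive]

    @property
    def negative_mn(self) -> list[float]:
        return [s.mn for s in self.negative]

    @property
    def positive_mean(self) -> float:
        return fmean(self.positive_mn)

    @property
    def negative_mean(self) -> float:
        return fmean(self.negative_mn)


@dataclass(frozen=True)
class MnScore:
    """Reference-normalised Mn summary for one target species at one site."""

    species: str
    site_id: str
    target_mean_mn: float
    diff_vs_negative: float
    diff_vs_positive: float
    relative_mn: float
    pos_provenance: RefProvenance
    neg_provenance: RefProvenance


def _site_role_samples(
    samples: Sequence[LeafSample], site_id: str, role: Role
) -> list[LeafSample]:
    return [s for s in samples if s.site_id == site_id and s.role == role]


def _pseudo_replicates(
    samples: Sequence[LeafSample], site_id: str, role: Role
) -> list[LeafSample]:
    """One pseudo-replicate per other site: that site's reference mean.

    Supports the cross-site average-reference (APR/ANR) fallback; flagged by
    provenance so users can exclude such sites.
    """
    by_site: dict[str, list[float]] = {}
    for s in samples:
        if s.role == role and s.site_id != site_id:
            by_site.setdefault(s.site_id, []).append(s.mn)
    if not by_site:
        raise UnresolvableReferenceError(
            f"no {role.value} samples observed at any site; cannot resolve "
            f"references for site {site_id!r}"
        )
    pseudo = []
    for k, (other_site, values) in enumerate(sorted(by_site.items()), start=1):
        pseudo.append(
            LeafSample(
                site_id=site_id,
                region="",
                species=f"<{role.value} site mean: {other_site}>",
                genus="",
                role=role,
                replicate=k,
                conc={"Mn": fmean(values)},
            )
        )
    return pseudo


def resolve_references(
    samples: Sequence[LeafSample], site_id: str
) -> ReferenceSet:
    """Resolve the positive and negative reference sample sets for one site.

    Observed references at the site are used directly (pooled across species
    and flagged ``grouped`` when more than one reference species was sampled).
    A site with no observed reference receives the cross-site site-mean
    pseudo-replicates (``site_average``). A negative reference consisting of
    young leaves is flagged ``young_leaf``.

    Resolution is deterministic: row order of ``samples`` never matters.
    """
    ordered = sorted(samples, key=lambda s: (s.site_id, s.species, s.replicate))

    def resolve(role: Role) -> tuple[tuple[LeafSample, ...], RefProvenance]:
        observed = _site_role_samples(ordered, site_id, role)
        if observed:
            species = {s.species for s in observed}
            if role == Role.NEGATIVE_REF and all(
                s.leaf_age == LeafAge.YOUNG for s in observed
            ):
                prov = RefProvenance.YOUNG_LEAF
            elif len(species) > 1:
                prov = RefProvenance.GROUPED
            else:
                prov = RefProvenance.OBSERVED
            return tuple(observed), prov
        return tuple(_pseudo_replicates(ordered, site_id, role)), RefProvenance.SITE_AVERAGE

    positive, pos_prov = resolve(Role.POSITIVE_REF)
    negative, neg_prov = resolve(Role.NEGATIVE_REF)
    if pos_prov == RefProvenance.SITE_AVERAGE:
        logger.info("site %s: using average positive reference (APR)", site_id)
    if neg_prov == RefProvenance.SITE_AVERAGE:
        logger.info("site %s: using average negative reference (ANR)", site_id)
    return ReferenceSet(
        site_id=site_id,
        positive=positive,
        negative=negative,
        pos_provenance=pos_prov,
        neg_provenance=neg_prov,
    )


def relative_mn(target_mean: float, neg_mean: float, pos_mean: float) -> float:
    """Relative leaf [Mn] in percent: 100*(target - neg)/(pos - neg).

    0 % at the negative reference mean, 100 % at the positive; linear in the
    target, so values below 0 or above 100 are meaningful (e.g. targets far
    exceeding the positive reference).

    Raises
    ------
    DegenerateReferenceError
        When the reference means are numerically indistinguishable.
    """
    span = pos_mean - neg_mean
    scale = max(abs(pos_mean), abs(neg_mean), 1.0)
    if abs(span) < DEGENERATE_RTOL * scale:
        raise DegenerateReferenceError(
            f"positive ({pos_mean}) and negative ({neg_mean}) reference means "
            "coincide; relative [Mn] undefined"
        )
    return 100.0 * (target_mean - neg_mean) / span


def mn_scores(
    samples: Sequence[LeafSample], refset: ReferenceSet
) -> list[MnScore]:
    """One :class:`MnScore` per target species at the reference set's site.

    Uses species-mean Mn for targets and the resolved reference means.
    Degenerate references raise rather than silently dropping the site.
    """
    site = refset.site_id
    targets = _site_role_samples(samples, site, Role.TARGET)
    if not targets:
        return []
    pos_mean = refset.positive_mean
    neg_mean = refset.negative_mean
    by_species: dict[str, list[float]] = {}
    for s in targets:
        by_species.setdefault(s.species, []).append(s.mn)
    scores = []
    for species in sorted(by_species):
        tmean = fmean(by_species[species])
        scores.append(
            MnScore(
                species=species,
                site_id=site,
                target_mean_mn=tmean,
                diff_vs_negative=tmean - neg_mean,
                diff_vs_positive=tmean - pos_mean,
                relative_mn=relative_mn(tmean, neg_mean, pos_mean),
                pos_provenance=refset.pos_provenance,
                neg_provenance=refset.neg_provenance,
            )
        )
    return scores
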