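"""Tabular and tree IO with validation into domain types.

Leaf and soil tables are RFC-4180 CSV with a header; a column-map config can
bridge arbitrary layouts and declare units (concentrations are stored as
N, P in mg g^-1 and K, Ca, Cu, Zn, Mn, Fe, Mg in mg kg^-1). Trees are Newick,
parsed with dendropy and wrapped in a thin :class:`Phylogeny`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("mnminer")

#: canonical element order; N and P in mg g^-1, the rest in mg kg^-1
ELEMENTS = ("N", "P", "K", "Ca", "Cu", "Zn", "Mn", "Fe", "Mg")


class FormatError(ValueError):
    """Input file does not have the required structure."""


class ValidationError(ValueError):
    """A row violates a domain invariant; message names row and field."""


class Role(str, Enum):
    TARGET = "target"
    POSITIVE_REF = "positive_ref"
    NEGATIVE_REF = "negative_ref"


class LeafAge(str, Enum):
    MATURE = "mature"
    YOUNG = "young"


@dataclass(frozen=True)
class LeafSample:
    """One measured individual: site, taxon, role and element concentrations."""

    site_id: str
    region: str
    species: str
    genus: str
    role: Role
    replicate: int
    conc: Mapping[str, float]
    leaf_age: LeafAge = LeafAge.MATURE

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")
        for elem, value in self.conc.items():
            if value is not None and not math.isnan(value) and value < 0:
                raise ValidationError(
                    f"negative concentration {elem}={value} for "
                    f"{self.species} at {self.site_id}"
                )

    @property
    def mn(self) -> float:
        return self.conc["Mn"]


@dataclass(frozen=True)
class SoilRecord:
    """Per-location topsoil chemistry (one or more locations per site)."""

    site_id: str
    pH_water: float
    pH_cacl2: float
    ec: float
    total: Mapping[str, float]
    olsen_p: float
    water_p: float

    def __post_init__(self) -> None:
        for name, ph in (("pH_water", self.pH_water), ("pH_cacl2", self.pH_cacl2)):
            if not (0.0 < ph < 14.0):
                raise ValidationError(f"{name}={ph} outside (0, 14) at {self.site_id}")
        if self.olsen_p < 0:
            raise ValidationError(f"olsen_p={self.olsen_p} < 0 at {self.site_id}")


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

@dataclass
class Phylogeny:
    """Rooted tree with branch lengths, backed by a dendropy tree.

    Ultrametricity is reported (``is_ultrametric``), never enforced; trees
    are used as given with no re-dating.
    """

    tree: dendropy.Tree
    rooted: bool = True

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def tip_depths(self) -> dict[str, float]:
        depths: dict[str, float] = {}
        for node in self.tree.preorder_node_iter():
            parent_depth = 0.0 if node.parent_node is None else node.parent_node._depth
            node._depth = parent_depth + (node.edge.length or 0.0)
            if node.is_leaf():
                depths[node.taxon.label] = node._depth
        return depths

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        depths = list(self.tip_depths().values())
        span = max(depths) - min(depths)
        scale = max(max(depths), 1e-30)
        return span <= rel_tol * scale

    def distance_matrix(self) -> pd.DataFrame:
        """Pairwise tip-to-tip patristic distances."""
        pdm = self.tree.phylogenetic_distance_matrix()
        labels = sorted(self.tip_labels)
        taxa = {t.label: t for t in self.tree.taxon_namespace if t.label in set(labels)}
        n = len(labels)
        d = np.zeros((n, n))
        for i, a in enumerate(labels):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pdm.patristic_distance(taxa[a], taxa[labels[j]])
        return pd.DataFrame(d, index=labels, columns=labels)


def _normalise_label(label: str) -> str:
    """Exact matching after whitespace/underscore normalisation (no fuzziness)."""
    return " ".join(label.replace("_", " ").split())


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a rooted :class:`Phylogeny`.

    Raises
    ------
    FormatError
        On malformed Newick or duplicate tip labels.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"could not parse Newick: {exc}") from exc
    labels = [_normalise_label(lf.taxon.label) for lf in tree.leaf_node_iter()]
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise FormatError(f"duplicate tip labels: {', '.join(dupes)}")
    for lf in tree.leaf_node_iter():
        lf.taxon.label = _normalise_label(lf.taxon.label)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise FormatError(f"negative branch length {edge.length}")
    tree.is_rooted = True
    return Phylogeny(tree=tree, rooted=True)


def write_newick(phy: Phylogeny) -> str:
    return phy.tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def prune_to_taxa(phy: Phylogeny, keep: Iterable[str]) -> Phylogeny:
    """Prune to the given tips, collapsing degree-2 nodes by summing lengths.

    Path lengths between kept tips are preserved exactly.
    """
    keep_norm = {_normalise_label(k) for k in keep}
    if len(keep_norm) < 2:
        raise ValueError("need at least 2 tips to keep")
    present = set(phy.tip_labels)
    missing = sorted(keep_norm - present)
    if missing:
        raise KeyError(f"tip labels not in tree: {', '.join(missing)}")
    sub = phy.tree.extract_tree(
        node_filter_fn=lambda nd: (not nd.is_leaf()) or nd.taxon.label in keep_norm,
        suppress_unifurcations=True,
    )
    # give the subtree its own namespace so the source tree is untouched
    sub.migrate_taxon_namespace(dendropy.TaxonNamespace())
    sub.is_rooted = True
    return Phylogeny(tree=sub, rooted=True)


# ---------------------------------------------------------------------------
# Tabular readers
# ---------------------------------------------------------------------------

_DEFAULT_COLUMNS = {
    "site_id": "site_id",
    "region": "region",
    "species": "species",
    "genus": "genus",
    "role": "role",
    "replicate": "replicate",
    "leaf_age": "leaf_age",
}

_MANDATORY = ("site_id", "species", "genus", "role")


def read_leaf_table(
    path: str | Path,
    config: Mapping | None = None,
) -> list[LeafSample]:
    """Read a leaf-chemistry CSV into validated :class:`LeafSample` records.

    ``config`` may carry a ``columns`` mapping (logical name -> header name),
    an ``elements`` mapping (element symbol -> header name), a ``units``
    mapping (element -> ``mg_g`` or ``mg_kg``) for conversion into the
    canonical units, and an ``aliases`` mapping for taxon-name synonyms.

    Rows failing invariants are rejected with row-numbered diagnostics.
    """
    config = dict(config or {})
    colmap = {**_DEFAULT_COLUMNS, **config.get("columns", {})}
    elem_map = {e: e for e in ELEMENTS}
    elem_map.update(config.get("elements", {}))
    units = config.get("units", {})
    aliases = {
        _normalise_label(k): v for k, v in config.get("aliases", {}).items()
    }

    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]

    missing = [colmap[k] for k in _MANDATORY if colmap[k] not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
    elem_cols = {e: c for e, c in elem_map.items() if c in df.columns}
    if "Mn" not in elem_cols:
        raise FormatError("missing mandatory element column: Mn")

    canonical_unit = {e: ("mg_g" if e in ("N", "P") else "mg_kg") for e in ELEMENTS}
    factor = {}
    for e in elem_cols:
        declared = units.get(e, canonical_unit[e])
        if declared == canonical_unit[e]:
            factor[e] = 1.0
        elif declared == "mg_kg" and canonical_unit[e] == "mg_g":
            factor[e] = 1e-3
        elif declared == "mg_g" and canonical_unit[e] == "mg_kg":
            factor[e] = 1e3
        else:
            raise FormatError(f"unknown unit {declared!r} for element {e}")

    samples: list[LeafSample] = []
    errors: list[str] = []
    seen: dict[tuple, int] = {}
    rep_counters: dict[tuple, int] = {}
    for idx, row in df.iterrows():
        rownum = idx + 2  # header is line 1
        try:
            role = Role(str(row[colmap["role"]]).strip().lower())
        except ValueError:
            errors.append(f"row {rownum}: unknown role {row[colmap['role']]!r}")
            continue
        species = _normalise_label(str(row[colmap["species"]]))
        species = aliases.get(species, species)
        site = str(row[colmap["site_id"]]).strip()
        if colmap["replicate"] in df.columns and not pd.isna(row[colmap["replicate"]]):
            replicate = int(row[colmap["replicate"]])
        else:
            key = (site, species)
            rep_counters[key] = rep_counters.get(key, 0) + 1
            replicate = rep_counters[key]
        conc = {}
        row_ok = True
        for e, c in elem_cols.items():
            raw = row[c]
            if pd.isna(raw):
                conc[e] = float("nan")
                continue
            try:
                val = float(raw)
            except (TypeError, ValueError):
                errors.append(f"row {rownum}: non-numeric {e}={raw!r}")
                row_ok = False
                break
            if val < 0:
                errors.append(f"row {rownum}: negative concentration {e}={val}")
                row_ok = False
                break
            conc[e] = val * factor[e]
        if not row_ok:
            continue
        if math.isnan(conc.get("Mn", float("nan"))):
            errors.append(f"row {rownum}: missing Mn value")
            continue
        age = LeafAge.MATURE
        if colmap["leaf_age"] in df.columns and not pd.isna(row[colmap["leaf_age"]]):
            age = LeafAge(str(row[colmap["leaf_age"]]).strip().lower())
        key = (site, species, replicate)
        if key in seen:
            errors.append(
                f"row {rownum}: duplicate (site, species, replicate)={key} "
                f"first seen at row {seen[key]}"
            )
            continue
        seen[key] = rownum
        region = (
            str(row[colmap["region"]]).strip()
            if colmap["region"] in df.columns and not pd.isna(row[colmap["region"]])
            else ""
        )
        genus = _normalise_label(str(row[colmap["genus"]]))
        samples.append(
            LeafSample(
                site_id=site, region=region, species=species, genus=genus,
                role=role, replicate=replicate, conc=conc, leaf_age=age,
            )
        )
    if errors:
        raise ValidationError(
            f"{len(errors)} invalid row(s):\n" + "\n".join(errors)
        )
    return samples


_SOIL_COLUMNS = {
    "site_id": "site_id",
    "pH_water": "pH_water",
    "pH_cacl2": "pH_cacl2",
    "ec": "ec",
    "olsen_p": "olsen_p",
    "water_p": "water_p",
}


def read_soil_table(path: str | Path, config: Mapping | None = None) -> list[SoilRecord]:
    """Read a soil-chemistry CSV into :class:`SoilRecord` rows.

    Total-element columns are recognised as ``total_<Element>``.
    """
    config = dict(config or {})
    colmap = {**_SOIL_COLUMNS, **config.get("columns", {})}
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    missing = [v for k, v in colmap.items() if v not in df.columns]
    if missing:
        raise FormatError(f"missing soil column(s): {', '.join(missing)}")
    total_cols = {
        c.split("_", 1)[1]: c for c in df.columns if c.startswith("total_")
    }
    records = []
    for idx, row in df.iterrows():
        records.append(
            SoilRecord(
                site_id=str(row[colmap["site_id"]]).strip(),
                pH_water=float(row[colmap["pH_water"]]),
                pH_cacl2=float(row[colmap["pH_cacl2"]]),
                ec=float(row[colmap["ec"]]),
                total={e: float(row[c]) for e, c in total_cols.items()},
                olsen_p=float(row[colmap["olsen_p"]]),
                water_p=float(row[colmap["water_p"]]),
            )
        )
    return records


def samples_to_frame(samples: Sequence[LeafSample]) -> pd.DataFrame:
    """Flatten samples to a tidy DataFrame (one row per individual)."""
    rows = []
    for s in samples:
        row = {
            "site_id": s.site_id, "region": s.region, "species": s.species,
            "genus": s.genus, "role": s.role.value, "replicate": s.replicate,
            "leaf_age": s.leaf_age.value,
        }
        row.update({e: s.conc.get(e, float("nan")) for e in ELEMENTS})
        rows.append(row)
    return pd.DataFrame(rows)
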