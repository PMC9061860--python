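"""Readers and writers for inventory, seed-trap, crop-count, trait and tree data.

All tabular formats are comma-separated UTF-8 text with '.' decimal and
integer ISO years.  The inventory is long format, one row per (tree, year).
Coordinates are stand-local Cartesian meters; distances are Euclidean.
Phylogenies are Newick with branch lengths, read and written with dendropy.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TreeRecord",
    "TrapRecord",
    "CropCountRecord",
    "SpeciesTraits",
    "SchemaError",
    "ValidationError",
    "read_inventory",
    "write_inventory",
    "read_traps",
    "write_traps",
    "read_crop_counts",
    "write_crop_counts",
    "read_traits",
    "write_traits",
    "read_phylogeny",
    "write_phylogeny",
    "terrain_vector",
    "basal_area",
    "interpolate_diameters",
    "write_manifest",
]

SHADE_CLASSES = {1, 2, 3, 4, 5}


class SchemaError(ValueError):
    """A mandatory column is missing or has the wrong type."""


class ValidationError(ValueError):
    """A row violates a domain invariant; the message carries the line."""


@dataclass
class TreeRecord:
    """One tree: identity, location, and its per-year diameter/shade series.

    Diameters are cm at breast height; basal area in m² follows as
    π(d/200)².  Shade class is the FIA/NEON ordinal, 1 (fully exposed)
    to 5 (fully shaded).  ``plot_area`` (ha) is needed only for
    community-level summaries.
    """

    tree_id: str
    species: str
    genus: str
    stand_id: str
    x: float
    y: float
    diameter_by_year: dict[int, float] = field(default_factory=dict)
    shade_by_year: dict[int, int] = field(default_factory=dict)
    order: str | None = None
    plot_area: float | None = None
    first_observed_mature_year: int | None = None

    def __post_init__(self) -> None:
        for year, d in self.diameter_by_year.items():
            if not d > 0:
                raise ValidationError(
                    f"tree {self.tree_id}: diameter {d} in year {year} not positive"
                )
        for year, sh in self.shade_by_year.items():
            if sh not in SHADE_CLASSES:
                raise ValidationError(
                    f"tree {self.tree_id}: shade class {sh} in year {year} "
                    f"not in {sorted(SHADE_CLASSES)}"
                )

    @property
    def years(self) -> list[int]:
        return sorted(self.diameter_by_year)

    def basal_area(self, year: int) -> float:
        return basal_area(self.diameter_by_year[year])


def basal_area(diameter_cm: float) -> float:
    """Stem cross-section in m² from diameter in cm: π(d/200)²."""
    return math.pi * (diameter_cm / 200.0) ** 2


@dataclass
class TrapRecord:
    """A mapped seed trap and its annual counts.

    ``counts_by_year`` maps (year, taxon, taxon_level) to a nonnegative
    integer seed count; ``taxon_level`` is ``"species"`` or ``"genus"``
    (seeds are often identifiable only to genus).
    """

    trap_id: str
    stand_id: str
    x: float
    y: float
    collection_area: float  # m²
    counts_by_year: dict[tuple[int, str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.collection_area > 0:
            raise ValidationError(
                f"trap {self.trap_id}: collection area must be positive"
            )
        for (year, taxon, level), n in self.counts_by_year.items():
            if level not in ("species", "genus"):
                raise ValidationError(
                    f"trap {self.trap_id}: taxon_level {level!r} invalid"
                )
            if n < 0 or n != int(n):
                raise ValidationError(
                    f"trap {self.trap_id}: count {n} for {taxon} in {year} "
                    "not a nonnegative integer"
                )


@dataclass
class CropCountRecord:
    """A count of reproductive structures on one tree in one year,
    with the observer's estimate of the fraction of the crop seen."""

    tree_id: str
    year: int
    structures_counted: int
    crop_fraction_estimate: float

    def __post_init__(self) -> None:
        if self.structures_counted < 0:
            raise ValidationError(
                f"tree {self.tree_id} year {self.year}: negative structure count"
            )
        if not (0.0 < self.crop_fraction_estimate <= 1.0):
            raise ValidationError(
                f"tree {self.tree_id} year {self.year}: crop fraction "
                f"{self.crop_fraction_estimate} outside (0, 1]"
            )


@dataclass
class SpeciesTraits:
    """Species-level traits: seed mass (g, with provenance so that
    species-level-only sensitivity reruns are possible), foliar N and P
    (mg/g), leaf habit, fruit type, and optional wood density (g/cm³)."""

    species: str
    seed_mass: float
    seed_mass_provenance: str = "species"
    foliar_N: float | None = None
    foliar_P: float | None = None
    leaf_habit: str | None = None
    fruit_type: str | None = None
    wood_density: float | None = None

    def __post_init__(self) -> None:
        if not self.seed_mass > 0:
            raise ValidationError(f"{self.species}: seed mass must be positive")
        if self.seed_mass_provenance not in ("species", "genus", "family"):
            raise ValidationError(
                f"{self.species}: seed_mass_provenance "
                f"{self.seed_mass_provenance!r} invalid"
            )
        if self.leaf_habit is not None and self.leaf_habit not in (
            "BD",
            "BE",
            "NE",
            "SE",
        ):
            raise ValidationError(
                f"{self.species}: leaf habit {self.leaf_habit!r} invalid"
            )


# ---------------------------------------------------------------------------
# tabular I/O


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing mandatory column(s) {missing}")


_INVENTORY_COLS = [
    "tree_id",
    "species",
    "genus",
    "stand_id",
    "x",
    "y",
    "year",
    "diameter_cm",
    "shade",
]


def read_inventory(path: str | Path) -> list[TreeRecord]:
    """Read a long-format inventory (one row per tree-year) into TreeRecords.

    Optional columns: ``order``, ``plot_area_ha``,
    ``first_observed_mature_year``.
    """
    df = pd.read_csv(path)
    _require_columns(df, _INVENTORY_COLS, "inventory")
    records: dict[str, TreeRecord] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        tid = str(row["tree_id"])
        try:
            d = float(row["diameter_cm"])
        except (TypeError, ValueError):
            raise ValidationError(
                f"inventory line {line}: non-numeric diameter "
                f"{row['diameter_cm']!r}"
            ) from None
        year = int(row["year"])
        shade = int(row["shade"])
        if tid not in records:
            fom = row.get("first_observed_mature_year")
            records[tid] = TreeRecord(
                tree_id=tid,
                species=str(row["species"]),
                genus=str(row["genus"]),
                stand_id=str(row["stand_id"]),
                x=float(row["x"]),
                y=float(row["y"]),
                order=(str(row["order"]) if "order" in df.columns and pd.notna(row.get("order")) else None),
                plot_area=(
                    float(row["plot_area_ha"])
                    if "plot_area_ha" in df.columns and pd.notna(row.get("plot_area_ha"))
                    else None
                ),
                first_observed_mature_year=(int(fom) if fom is not None and pd.notna(fom) else None),
            )
        rec = records[tid]
        if not d > 0:
            raise ValidationError(
                f"inventory line {line}: diameter {d} not positive"
            )
        if shade not in SHADE_CLASSES:
            raise ValidationError(
                f"inventory line {line}: shade class {shade} not in 1..5"
            )
        rec.diameter_by_year[year] = d
        rec.shade_by_year[year] = shade
    return list(records.values())


def write_inventory(trees: list[TreeRecord], path: str | Path) -> None:
    rows = []
    for t in trees:
        for year in t.years:
            rows.append(
                {
                    "tree_id": t.tree_id,
                    "species": t.species,
                    "genus": t.genus,
                    "order": t.order,
                    "stand_id": t.stand_id,
                    "x": t.x,
                    "y": t.y,
                    "plot_area_ha": t.plot_area,
                    "year": year,
                    "diameter_cm": t.diameter_by_year[year],
                    "shade": t.shade_by_year.get(year, 3),
                    "first_observed_mature_year": t.first_observed_mature_year,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


_TRAP_COLS = [
    "trap_id",
    "stand_id",
    "x",
    "y",
    "collection_area_m2",
    "year",
    "taxon",
    "taxon_level",
    "count",
]


def read_traps(path: str | Path) -> list[TrapRecord]:
    """Read long-format seed-trap counts; duplicate (trap, year, taxon)
    rows are an error."""
    df = pd.read_csv(path)
    _require_columns(df, _TRAP_COLS, "traps")
    dup = df.duplicated(subset=["trap_id", "year", "taxon"], keep=False)
    if dup.any():
        lines = (df.index[dup] + 2).tolist()
        raise ValidationError(f"traps: duplicate (trap, year, taxon) rows at lines {lines}")
    traps: dict[str, TrapRecord] = {}
    for idx, row in df.iterrows():
        tid = str(row["trap_id"])
        if tid not in traps:
            traps[tid] = TrapRecord(
                trap_id=tid,
                stand_id=str(row["stand_id"]),
                x=float(row["x"]),
                y=float(row["y"]),
                collection_area=float(row["collection_area_m2"]),
            )
        key = (int(row["year"]), str(row["taxon"]), str(row["taxon_level"]))
        n = int(row["count"])
        if n < 0:
            raise ValidationError(f"traps line {idx + 2}: negative count")
        traps[tid].counts_by_year[key] = n
        # re-run record validation for the new entry
        traps[tid].__post_init__()
    return list(traps.values())


def write_traps(traps: list[TrapRecord], path: str | Path) -> None:
    rows = []
    for tr in traps:
        for (year, taxon, level), n in sorted(tr.counts_by_year.items()):
            rows.append(
                {
                    "trap_id": tr.trap_id,
                    "stand_id": tr.stand_id,
                    "x": tr.x,
                    "y": tr.y,
                    "collection_area_m2": tr.collection_area,
                    "year": year,
                    "taxon": taxon,
                    "taxon_level": level,
                    "count": n,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_crop_counts(path: str | Path) -> list[CropCountRecord]:
    df = pd.read_csv(path)
    _require_columns(
        df,
        ["tree_id", "year", "structures_counted", "crop_fraction_estimate"],
        "crop counts",
    )
    return [
        CropCountRecord(
            tree_id=str(r["tree_id"]),
            year=int(r["year"]),
            structures_counted=int(r["structures_counted"]),
            crop_fraction_estimate=float(r["crop_fraction_estimate"]),
        )
        for _, r in df.iterrows()
    ]


def write_crop_counts(counts: list[CropCountRecord], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(c) for c in counts]).to_csv(path, index=False)


def read_traits(path: str | Path) -> list[SpeciesTraits]:
    df = pd.read_csv(path)
    _require_columns(df, ["species", "seed_mass_g"], "traits")

    def opt(r, col, cast=float):
        return cast(r[col]) if col in df.columns and pd.notna(r.get(col)) else None

    return [
        SpeciesTraits(
            species=str(r["species"]),
            seed_mass=float(r["seed_mass_g"]),
            seed_mass_provenance=(
                str(r["seed_mass_provenance"])
                if "seed_mass_provenance" in df.columns
                and pd.notna(r.get("seed_mass_provenance"))
                else "species"
            ),
            foliar_N=opt(r, "foliar_n_mg_g"),
            foliar_P=opt(r, "foliar_p_mg_g"),
            leaf_habit=opt(r, "leaf_habit", str),
            fruit_type=opt(r, "fruit_type", str),
            wood_density=opt(r, "wood_density_g_cm3"),
        )
        for _, r in df.iterrows()
    ]


def write_traits(traits: list[SpeciesTraits], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "species": t.species,
                "seed_mass_g": t.seed_mass,
                "seed_mass_provenance": t.seed_mass_provenance,
                "foliar_n_mg_g": t.foliar_N,
                "foliar_p_mg_g": t.foliar_P,
                "leaf_habit": t.leaf_habit,
                "fruit_type": t.fruit_type,
                "wood_density_g_cm3": t.wood_density,
            }
            for t in traits
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# phylogeny I/O


def read_phylogeny(
    path: str | Path,
    species: list[str] | None = None,
    require_positive_lengths: bool = True,
) -> dendropy.Tree:
    """Read a Newick tree with branch lengths.

    If ``species`` is given, tips are matched case-insensitively against
    it and unmatched tips are reported on the returned tree's
    ``unmatched_tips`` attribute (never silently dropped).  Zero or
    negative branch lengths are an error when
    ``require_positive_lengths`` (the λ transform is undefined there).
    """
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    if require_positive_lengths:
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None or edge.length <= 0:
                raise ValidationError(
                    f"phylogeny: edge above {edge.head_node} has "
                    f"non-positive or missing branch length {edge.length}"
                )
    tree.unmatched_tips = []
    if species is not None:
        lookup = {s.lower(): s for s in species}
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label
            if label.lower() in lookup:
                leaf.taxon.label = lookup[label.lower()]
            else:
                tree.unmatched_tips.append(label)
    return tree


def write_phylogeny(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


# ---------------------------------------------------------------------------
# terrain


def terrain_vector(slope_deg: float, aspect_deg: float) -> tuple[float, float, float]:
    """Terrain vector (u1, u2, u3) from slope and aspect in degrees.

    u1 = sin(slope), u2 = sin(slope)sin(aspect), u3 = sin(slope)cos(aspect);
    aspect is degrees clockwise from north.  The identity u1² = u2² + u3²
    holds exactly.
    """
    if not (0.0 <= slope_deg <= 90.0):
        raise ValueError(f"slope {slope_deg} outside [0, 90] degrees")
    if not (0.0 <= aspect_deg < 360.0):
        raise ValueError(f"aspect {aspect_deg} outside [0, 360) degrees")
    s = math.radians(slope_deg)
    a = math.radians(aspect_deg)
    return (math.sin(s), math.sin(s) * math.sin(a), math.sin(s) * math.cos(a))


def interpolate_diameters(tree: TreeRecord) -> tuple[TreeRecord, list[int]]:
    """Fill missing diameter years inside a tree's observed window by
    linear interpolation; never extrapolates.  Returns the filled record
    and the list of interpolated years."""
    years = tree.years
    if len(years) < 2:
        return tree, []
    full = list(range(years[0], years[-1] + 1))
    missing = [y for y in full if y not in tree.diameter_by_year]
    if not missing:
        return tree, []
    known_y = np.array(years, dtype=float)
    known_d = np.array([tree.diameter_by_year[y] for y in years])
    filled = dict(tree.diameter_by_year)
    shade = dict(tree.shade_by_year)
    for y in missing:
        filled[y] = float(np.interp(y, known_y, known_d))
        # nearest observed shade class
        nearest = min(years, key=lambda k: abs(k - y))
        shade[y] = tree.shade_by_year.get(nearest, 3)
    out = dataclasses.replace(tree, diameter_by_year=filled, shade_by_year=shade)
    return out, missing


# ---------------------------------------------------------------------------
# run manifests


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    config: Mapping,
    seed: int,
    data_files: list[str | Path] | None = None,
    extra: Mapping | None = None,
) -> dict:
    """Write a JSON manifest (config hash, seed, data checksums) sufficient
    to reproduce deterministic outputs bit-identically."""
    cfg_json = json.dumps(dict(config), sort_keys=True, default=str)
    manifest = {
        "seed": int(seed),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": json.loads(cfg_json),
        "data_sha256": {
            str(p): _sha256(Path(p)) for p in (data_files or [])
        },
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
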