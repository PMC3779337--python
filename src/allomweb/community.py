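"""Community descriptions: species tables plus directed trophic links.

A community is a list of species — each with a body mass (kg), an observed
average population density (individuals per cubic metre) and a metabolic
category — together with a set of directed resource -> consumer links.
Species order in the node table defines the index order used by every
downstream rate vector and biomass vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PRODUCER = "producer"
INVERTEBRATE = "invertebrate"
VERTEBRATE = "vertebrate_ectotherm"
CATEGORIES = (PRODUCER, INVERTEBRATE, VERTEBRATE)

NODE_COLUMNS = ("id", "name", "category", "mass_kg", "n_per_m3")
LINK_COLUMNS = ("resource_id", "consumer_id")


class CommunitySchemaError(ValueError):
    """A node or link file is missing required columns."""


class CommunityValidationError(ValueError):
    """A community description violates an invariant."""


@dataclass(frozen=True)
class Species:
    """One population: identity, body mass M (kg), observed density N (m^-3)."""

    id: str
    name: str
    body_mass: float
    observed_density: float
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise CommunityValidationError(
                f"species {self.id!r}: unknown category {self.category!r}; "
                f"expected one of {CATEGORIES}"
            )
        if not (self.body_mass > 0):
            raise CommunityValidationError(
                f"species {self.id!r}: body_mass must be > 0, got {self.body_mass}"
            )
        if not (self.observed_density > 0):
            raise CommunityValidationError(
                f"species {self.id!r}: observed_density must be > 0, "
                f"got {self.observed_density}"
            )


@dataclass(frozen=True)
class Community:
    """An ordered species list plus directed (resource_id, consumer_id) links.

    Self-links (cannibalism) are permitted.  Producers must not consume
    anything; validation enforces this.  Whether every consumer has at least
    one resource is checked by :meth:`validate` so that preprocessing
    (removal of unconsumed producers) can be expressed on valid objects.
    """

    label: str
    species: tuple[Species, ...]
    links: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = [sp.id for sp in self.species]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CommunityValidationError(f"duplicate species ids: {dupes}")
        known = set(ids)
        for res, con in self.links:
            if res not in known:
                raise CommunityValidationError(f"link resource {res!r} is not a species")
            if con not in known:
                raise CommunityValidationError(f"link consumer {con!r} is not a species")
        cat = {sp.id: sp.category for sp in self.species}
        for res, con in self.links:
            if cat[con] == PRODUCER:
                raise CommunityValidationError(
                    f"producer {con!r} appears as a consumer in link ({res!r}, {con!r})"
                )

    # -- index helpers -----------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(sp.id for sp in self.species)

    def index_of(self, species_id: str) -> int:
        return self.ids.index(species_id)

    @property
    def masses(self) -> np.ndarray:
        return np.array([sp.body_mass for sp in self.species], dtype=float)

    @property
    def observed_densities(self) -> np.ndarray:
        return np.array([sp.observed_density for sp in self.species], dtype=float)

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(sp.category for sp in self.species)

    def category_mask(self, category: str) -> np.ndarray:
        return np.array([sp.category == category for sp in self.species])

    @property
    def producer_mask(self) -> np.ndarray:
        return self.category_mask(PRODUCER)

    def link_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(resource_index, consumer_index) arrays in a stable sorted order."""
        idx = {sid: i for i, sid in enumerate(self.ids)}
        pairs = sorted((idx[r], idx[c]) for r, c in self.links)
        if not pairs:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        res, con = zip(*pairs)
        return np.array(res, dtype=int), np.array(con, dtype=int)

    def resources_of(self, species_id: str) -> set[str]:
        return {r for r, c in self.links if c == species_id}

    def consumers_of(self, species_id: str) -> set[str]:
        return {c for r, c in self.links if r == species_id}

    def validate(self) -> list[str]:
        """Return a list of problems; empty means simulation-ready."""
        problems = []
        for sp in self.species:
            if sp.category != PRODUCER and not self.resources_of(sp.id):
                problems.append(f"consumer {sp.id!r} has no resources")
        return problems


def community_from_frames(
    label: str, nodes: pd.DataFrame, links: pd.DataFrame
) -> Community:
    for col in NODE_COLUMNS:
        if col not in nodes.columns:
            raise CommunitySchemaError(f"node table is missing column {col!r}")
    for col in LINK_COLUMNS:
        if col not in links.columns:
            raise CommunitySchemaError(f"link table is missing column {col!r}")
    species = tuple(
        Species(
            id=str(row["id"]),
            name=str(row["name"]),
            body_mass=float(row["mass_kg"]),
            observed_density=float(row["n_per_m3"]),
            category=str(row["category"]),
        )
        for _, row in nodes.iterrows()
    )
    link_set = frozenset(
        (str(row["resource_id"]), str(row["consumer_id"])) for _, row in links.iterrows()
    )
    return Community(label=label, species=species, links=link_set)


def read_community(nodes_path, links_path, label: str | None = None) -> Community:
    """Read a community from node and link CSV files (UTF-8, header row)."""
    nodes_path, links_path = Path(nodes_path), Path(links_path)
    nodes = pd.read_csv(nodes_path, dtype={"id": str, "name": str, "category": str},
                        float_precision="round_trip")
    links = pd.read_csv(links_path, dtype=str)
    if links.empty and set(LINK_COLUMNS) - set(links.columns):
        # an empty file with the right header parses fine; a truly headerless
        # empty file is a schema error handled in community_from_frames
        pass
    return community_from_frames(label or nodes_path.stem, nodes, links)


def write_community(c: Community, nodes_path, links_path) -> None:
    """Write node and link CSVs such that read_community round-trips exactly."""
    nodes = pd.DataFrame(
        {
            "id": [sp.id for sp in c.species],
            "name": [sp.name for sp in c.species],
            "category": [sp.category for sp in c.species],
            "mass_kg": [repr(sp.body_mass) for sp in c.species],
            "n_per_m3": [repr(sp.observed_density) for sp in c.species],
        }
    )
    links = pd.DataFrame(sorted(c.links), columns=list(LINK_COLUMNS))
    nodes.to_csv(nodes_path, index=False)
    links.to_csv(links_path, index=False)


def remove_unconsumed_producers(c: Community) -> tuple[Community, list[str]]:
    """Drop producers that nothing eats; return (community, removed ids).

    Applied once: removing a producer can never create a newly unconsumed
    producer, because producers do not consume.  Idempotent.
    """
    consumed = {r for r, _ in c.links}
    removed = [
        sp.id for sp in c.species if sp.category == PRODUCER and sp.id not in consumed
    ]
    if not removed:
        return c, []
    removed_set = set(removed)
    species = tuple(sp for sp in c.species if sp.id not in removed_set)
    links = frozenset(
        (r, con) for r, con in c.links if r not in removed_set and con not in removed_set
    )
    return Community(label=c.label, species=species, links=links), removed
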