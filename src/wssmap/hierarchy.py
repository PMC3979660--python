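"""Administrative hierarchies, adjacency graphs and population tables.

The analysis operates on a three-level nesting: survey sites sit inside
second-level administrative areas (admin2, "districts"), which sit inside
first-level areas (admin1, "provinces"), which sit inside countries.
Spatial smoothing acts on a within-country adjacency graph over admin2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["AdminHierarchy", "PopulationTable"]


@dataclass
class AdminHierarchy:
    """Countries → admin1 → admin2 with a within-country admin2 adjacency graph.

    Parameters
    ----------
    countries
        Country identifiers.
    admin1_of
        Map admin1 id → country id.
    admin2_of
        Map admin2 id → admin1 id.
    adjacency
        Unordered admin2 pairs, each within a single country. Stored as a
        set of sorted 2-tuples.
    """

    countries: list[str]
    admin1_of: dict[str, str]
    admin2_of: dict[str, str]
    adjacency: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.adjacency = {tuple(sorted(e)) for e in self.adjacency}
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        for a1, c in self.admin1_of.items():
            if c not in self.countries:
                raise ValueError(f"admin1 {a1!r} maps to unknown country {c!r}")
        for a2, a1 in self.admin2_of.items():
            if a1 not in self.admin1_of:
                raise ValueError(f"admin2 {a2!r} maps to unknown admin1 {a1!r}")
        for i, j in self.adjacency:
            if i == j:
                raise ValueError(f"self-loop on {i!r}")
            if i not in self.admin2_of or j not in self.admin2_of:
                raise ValueError(f"adjacency edge ({i!r}, {j!r}) not in hierarchy")
            if self.country_of_admin2(i) != self.country_of_admin2(j):
                raise ValueError(f"edge ({i!r}, {j!r}) crosses a country boundary")

    # -- lookups ----------------------------------------------------------
    @property
    def admin1_ids(self) -> list[str]:
        return sorted(self.admin1_of)

    @property
    def admin2_ids(self) -> list[str]:
        return sorted(self.admin2_of)

    def country_of_admin2(self, admin2: str) -> str:
        return self.admin1_of[self.admin2_of[admin2]]

    def admin2_in_admin1(self, admin1: str) -> list[str]:
        return sorted(a2 for a2, a1 in self.admin2_of.items() if a1 == admin1)

    def admin2_in_country(self, country: str) -> list[str]:
        return sorted(
            a2 for a2 in self.admin2_of if self.country_of_admin2(a2) == country
        )

    def neighbours(self, admin2: str) -> list[str]:
        out = []
        for i, j in self.adjacency:
            if i == admin2:
                out.append(j)
            elif j == admin2:
                out.append(i)
        return sorted(out)

    @property
    def islands(self) -> set[str]:
        """Admin2 with no neighbours."""
        touched = {n for e in self.adjacency for n in e}
        return {a2 for a2 in self.admin2_of if a2 not in touched}

    # -- graph views ------------------------------------------------------
    def graph(self, country: str | None = None, nodes: Iterable[str] | None = None) -> nx.Graph:
        """Adjacency as a networkx graph, optionally restricted.

        ``nodes`` restricts to the induced subgraph on those admin2; isolated
        admin2 are included as degree-0 nodes.
        """
        g = nx.Graph()
        if nodes is not None:
            keep = set(nodes)
        elif country is not None:
            keep = set(self.admin2_in_country(country))
        else:
            keep = set(self.admin2_of)
        g.add_nodes_from(sorted(keep))
        g.add_edges_from((i, j) for i, j in self.adjacency if i in keep and j in keep)
        return g

    def components(self, country: str) -> list[set[str]]:
        """Connected components of a country's admin2 graph (islands are
        singleton components)."""
        return [set(c) for c in nx.connected_components(self.graph(country))]

    # -- I/O --------------------------------------------------------------
    def write_adjacency(self, path: str | Path) -> None:
        """Two-column whitespace edge list, one edge per line."""
        with open(path, "w") as fh:
            for i, j in sorted(self.adjacency):
                fh.write(f"{i}\t{j}\n")

    @staticmethod
    def read_adjacency(path: str | Path) -> set[tuple[str, str]]:
        edges: set[tuple[str, str]] = set()
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if len(parts) != 2:
                    raise ValueError(f"bad adjacency line: {line!r}")
                edges.add(tuple(sorted(parts)))  # type: ignore[arg-type]
        return edges

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "admin2": a2,
                "admin1": a1,
                "country": self.admin1_of[a1],
            }
            for a2, a1 in sorted(self.admin2_of.items())
        ]
        return pd.DataFrame(rows)


@dataclass
class PopulationTable:
    """Urban and rural person counts per admin2."""

    p_urban: dict[str, float]
    p_rural: dict[str, float]

    def __post_init__(self) -> None:
        for d in (self.p_urban, self.p_rural):
            for a2, p in d.items():
                if p < 0:
                    raise ValueError(f"negative population for {a2!r}")

    def total(self, admin2: str) -> float:
        return self.p_urban.get(admin2, 0.0) + self.p_rural.get(admin2, 0.0)

    def urban_share(self, admin2: str) -> float:
        tot = self.total(admin2)
        return self.p_urban.get(admin2, 0.0) / tot if tot > 0 else 0.0

    def to_frame(self) -> pd.DataFrame:
        admin2 = sorted(set(self.p_urban) | set(self.p_rural))
        return pd.DataFrame(
            {
                "admin2": admin2,
                "P_urban": [self.p_urban.get(a, 0.0) for a in admin2],
                "P_rural": [self.p_rural.get(a, 0.0) for a in admin2],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "PopulationTable":
        df = pd.read_csv(path)
        return cls(
            p_urban=dict(zip(df["admin2"].astype(str), df["P_urban"].astype(float))),
            p_rural=dict(zip(df["admin2"].astype(str), df["P_rural"].astype(float))),
        )


def laplacian(graph: nx.Graph, nodes: list[str]) -> np.ndarray:
    """Dense graph Laplacian ordered by ``nodes``."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    lap = np.zeros((n, n))
    for i, j in graph.edges():
        a, b = idx[i], idx[j]
        lap[a, a] += 1.0
        lap[b, b] += 1.0
        lap[a, b] -= 1.0
        lap[b, a] -= 1.0
    return lap
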