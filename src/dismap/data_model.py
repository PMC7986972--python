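"""Domain types and file I/O for county-level stratified incidence data.

A study region bundles five pieces: age-stratified case counts per
(county, race, age-group) cell, populations at risk per (county, race), a
standard-population age weight vector, county-level deprivation covariates,
and a border-sharing adjacency graph. Counties are referenced by name in
files and mapped to 0-based indices internally so the five inputs cannot be
silently misaligned.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from ._nm_adjacency import NM_BORDER_EDGES, NM_COUNTIES

__all__ = [
    "AGE_LABELS_15",
    "AdjacencyStructure",
    "IncidenceDataset",
    "SchemaError",
    "StructureError",
    "NormalizationError",
    "load_dataset",
    "write_dataset",
    "validate_cohort_totals",
    "nm_adjacency_fixture",
]

#: 5-year age intervals from 15-19 up to the open-ended 85+ group.
AGE_LABELS_15 = [f"{a}-{a + 4}" for a in range(15, 85, 5)] + ["85+"]


class SchemaError(ValueError):
    """An input table violates the documented column/cell schema."""


class StructureError(ValueError):
    """The adjacency graph violates a structural invariant."""


class NormalizationError(ValueError):
    """Standard-population weights do not sum to one."""


@dataclass(frozen=True)
class AdjacencyStructure:
    """Symmetric border-sharing graph over the study counties.

    Parameters
    ----------
    counties
        County names in index order; node i is ``counties[i]``.
    edges
        Undirected edges as (i, j) index pairs with i < j, no duplicates.
    """

    counties: tuple[str, ...]
    edges: tuple[tuple[int, int], ...]
    neighbors: tuple[tuple[int, ...], ...] = field(init=False, repr=False)
    component_labels: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = len(self.counties)
        if len(set(self.counties)) != n:
            raise StructureError("duplicate county names in adjacency")
        nbrs: list[set[int]] = [set() for _ in range(n)]
        for i, j in self.edges:
            if i == j:
                raise StructureError(f"self-loop at county {self.counties[i]!r}")
            if not (0 <= i < n and 0 <= j < n):
                raise StructureError(f"edge ({i}, {j}) out of range")
            nbrs[i].add(j)
            nbrs[j].add(i)
        object.__setattr__(
            self, "neighbors", tuple(tuple(sorted(s)) for s in nbrs)
        )
        g = self.to_graph()
        labels = np.empty(n, dtype=int)
        for k, comp in enumerate(nx.connected_components(g)):
            for node in comp:
                labels[node] = k
        labels.setflags(write=False)
        object.__setattr__(self, "component_labels", labels)

    @classmethod
    def from_named_edges(
        cls, counties: list[str] | tuple[str, ...], named_edges
    ) -> "AdjacencyStructure":
        index = {c: i for i, c in enumerate(counties)}
        seen = set()
        edges = []
        for a, b in named_edges:
            if a not in index or b not in index:
                missing = a if a not in index else b
                raise StructureError(f"edge references unknown county {missing!r}")
            i, j = index[a], index[b]
            if i == j:
                raise StructureError(f"self-loop at county {a!r}")
            key = (min(i, j), max(i, j))
            if key not in seen:
                seen.add(key)
                edges.append(key)
        return cls(tuple(counties), tuple(sorted(edges)))

    @property
    def n_counties(self) -> int:
        return len(self.counties)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_components(self) -> int:
        return int(self.component_labels.max()) + 1 if self.counties else 0

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.counties)))
        g.add_edges_from(self.edges)
        return g

    def laplacian(self) -> np.ndarray:
        """Dense graph Laplacian D - W (degree minus adjacency)."""
        n = self.n_counties
        lap = np.zeros((n, n))
        for i, j in self.edges:
            lap[i, i] += 1.0
            lap[j, j] += 1.0
            lap[i, j] -= 1.0
            lap[j, i] -= 1.0
        return lap


@dataclass(frozen=True)
class IncidenceDataset:
    """Validated bundle of counts, denominators, covariates and adjacency.

    Arrays are indexed ``[county, race, age]`` (counts), ``[county, race]``
    (at-risk), ``[age]`` (standard weights) and ``[county]`` (covariates).
    ``races`` is ``(0, 1)`` for a two-group study (race 1 = focal group) or
    ``(0,)`` for a single-group reduced dataset.
    """

    counties: tuple[str, ...]
    races: tuple[int, ...]
    age_labels: tuple[str, ...]
    counts: np.ndarray          # (I, R, A) non-negative ints
    at_risk: np.ndarray         # (I, R) positive ints
    std_weights: np.ndarray     # (A,) sums to 1
    adi_score: np.ndarray       # (I,)
    x2: np.ndarray              # (I,) binary deprivation indicator
    adjacency: AdjacencyStructure
    extra_covariates: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        I, R, A = len(self.counties), len(self.races), len(self.age_labels)
        for name, arr, shape in [
            ("counts", self.counts, (I, R, A)),
            ("at_risk", self.at_risk, (I, R)),
            ("std_weights", self.std_weights, (A,)),
            ("adi_score", self.adi_score, (I,)),
            ("x2", self.x2, (I,)),
        ]:
            if np.asarray(arr).shape != shape:
                raise SchemaError(f"{name} has shape {np.asarray(arr).shape}, expected {shape}")
        if tuple(self.races) not in {(0,), (0, 1)}:
            raise SchemaError(f"race levels must be (0,) or (0, 1), got {self.races}")
        if np.any(self.counts < 0):
            raise SchemaError("negative case count")
        if np.any(self.at_risk < 1):
            i, r = np.argwhere(self.at_risk < 1)[0]
            raise SchemaError(
                f"at-risk population must be >= 1; county {self.counties[i]!r}, "
                f"race {self.races[r]} has n = {self.at_risk[i, r]}"
            )
        s = float(np.sum(self.std_weights))
        if abs(s - 1.0) > 1e-9:
            raise NormalizationError(
                f"standard-population weights sum to {s:.6g}, expected 1"
            )
        if not np.isin(self.x2, (0, 1)).all():
            raise SchemaError("x2 must be binary")
        if self.adjacency.counties != tuple(self.counties):
            raise SchemaError("adjacency county set differs from count tables")

    @property
    def n_counties(self) -> int:
        return len(self.counties)

    @property
    def n_races(self) -> int:
        return len(self.races)

    @property
    def n_age_groups(self) -> int:
        return len(self.age_labels)

    def race_indicator(self) -> np.ndarray:
        """x1 per (county, race) cell: 1 for the focal group."""
        return np.broadcast_to(
            np.asarray(self.races, dtype=float), (self.n_counties, self.n_races)
        )


def _require_columns(frame: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what} file is missing columns {missing}")


def _read_adjacency_file(path) -> list[tuple[str, str]]:
    """Edge list, one undirected edge per line.

    County names may contain spaces, so a tab separates the two names when
    present; otherwise the line is split on whitespace into exactly two
    tokens.
    """
    edges = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split("\t") if p.strip()] if "\t" in line \
            else line.split()
        if len(parts) != 2:
            raise SchemaError(f"adjacency line {raw!r} does not name two counties")
        edges.append((parts[0], parts[1]))
    return edges


def load_dataset(
    counts_path,
    at_risk_path,
    std_pop_path,
    covariates_path,
    adjacency_path,
) -> IncidenceDataset:
    """Read and cross-validate the five input files.

    Every (county, race, age) cell must be present exactly once; the
    adjacency edge list must contain each undirected border in both
    directions (asymmetry is treated as a data-entry error, not repaired);
    weights must sum to one. The deprivation indicator x2 is taken from an
    ``x2`` column when the covariates file carries one, otherwise derived by
    the lower-20th-percentile classification of the ADI scores.
    """
    counts = pd.read_csv(counts_path)
    at_risk = pd.read_csv(at_risk_path)
    std_pop = pd.read_csv(std_pop_path)
    covariates = pd.read_csv(covariates_path)
    _require_columns(counts, ["county", "race", "age_group", "count"], "counts")
    _require_columns(at_risk, ["county", "race", "n"], "at_risk")
    _require_columns(std_pop, ["age_group", "weight"], "std_pop")
    _require_columns(covariates, ["county", "adi_score"], "covariates")

    counties = list(dict.fromkeys(covariates["county"].astype(str)))
    if covariates["county"].duplicated().any():
        raise SchemaError("covariates file repeats a county")
    races = sorted(int(r) for r in counts["race"].unique())
    age_labels = list(dict.fromkeys(std_pop["age_group"].astype(str)))

    count_ages = set(counts["age_group"].astype(str))
    if count_ages != set(age_labels):
        raise SchemaError(
            "age-group sets of counts and standard population differ: "
            f"{sorted(count_ages ^ set(age_labels))}"
        )

    cidx = {c: i for i, c in enumerate(counties)}
    ridx = {r: k for k, r in enumerate(races)}
    aidx = {a: k for k, a in enumerate(age_labels)}

    I, R, A = len(counties), len(races), len(age_labels)
    count_arr = np.full((I, R, A), -1, dtype=float)
    for row in counts.itertuples(index=False):
        county = str(row.county)
        if county not in cidx:
            raise SchemaError(f"counts file names unknown county {county!r}")
        i, r, a = cidx[county], ridx[int(row.race)], aidx[str(row.age_group)]
        if count_arr[i, r, a] >= 0:
            raise SchemaError(
                f"duplicate cell (county={county!r}, race={row.race}, "
                f"age_group={row.age_group!r})"
            )
        count_arr[i, r, a] = row.count
    if np.any(count_arr < 0):
        i, r, a = np.argwhere(count_arr < 0)[0]
        raise SchemaError(
            f"missing cell (county={counties[i]!r}, race={races[r]}, "
            f"age_group={age_labels[a]!r})"
        )

    n_arr = np.zeros((I, R), dtype=int)
    seen = np.zeros((I, R), dtype=bool)
    for row in at_risk.itertuples(index=False):
        county = str(row.county)
        if county not in cidx:
            raise SchemaError(f"at_risk file names unknown county {county!r}")
        i, r = cidx[county], ridx[int(row.race)]
        n_arr[i, r] = row.n
        seen[i, r] = True
    if not seen.all():
        i, r = np.argwhere(~seen)[0]
        raise SchemaError(
            f"missing at-risk row (county={counties[i]!r}, race={races[r]})"
        )

    weights = np.array(
        [float(std_pop.set_index(std_pop["age_group"].astype(str))["weight"][a])
         for a in age_labels]
    )

    named_edges = _read_adjacency_file(adjacency_path)
    directed = set()
    for a, b in named_edges:
        for name in (a, b):
            if name not in cidx:
                raise StructureError(f"adjacency names unknown county {name!r}")
        directed.add((cidx[a], cidx[b]))
    for i, j in directed:
        if (j, i) not in directed:
            raise StructureError(
                f"adjacency asymmetric: edge ({counties[i]!r}, {counties[j]!r}) "
                "lacks its reverse"
            )
    undirected = sorted({(min(i, j), max(i, j)) for i, j in directed})
    adjacency = AdjacencyStructure(tuple(counties), tuple(undirected))

    scores = covariates.set_index(covariates["county"].astype(str))
    adi = np.array([float(scores["adi_score"][c]) for c in counties])
    if "x2" in covariates.columns:
        x2 = np.array([int(scores["x2"][c]) for c in counties])
    else:
        from .standardization import classify_adi

        x2 = classify_adi(adi).x2
    extra = {
        col: np.array([int(scores[col][c]) for c in counties])
        for col in covariates.columns
        if col not in {"county", "adi_score", "x2"}
    }

    return IncidenceDataset(
        counties=tuple(counties),
        races=tuple(races),
        age_labels=tuple(age_labels),
        counts=count_arr.astype(int)
        if np.allclose(count_arr, np.round(count_arr))
        else count_arr,
        at_risk=n_arr,
        std_weights=weights,
        adi_score=adi,
        x2=x2,
        adjacency=adjacency,
        extra_covariates=extra,
    )


def write_dataset(dataset: IncidenceDataset, out_dir) -> dict[str, Path]:
    """Write the five CSV/edge-list inputs; inverse of :func:`load_dataset`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.csv",
        "at_risk": out / "at_risk.csv",
        "std_pop": out / "std_pop.csv",
        "covariates": out / "covariates.csv",
        "adjacency": out / "adjacency.txt",
    }
    rows = [
        (c, r, a, dataset.counts[i, k, m])
        for (i, c), (k, r), (m, a) in itertools.product(
            enumerate(dataset.counties),
            enumerate(dataset.races),
            enumerate(dataset.age_labels),
        )
    ]
    pd.DataFrame(rows, columns=["county", "race", "age_group", "count"]).to_csv(
        paths["counts"], index=False
    )
    rows = [
        (c, r, dataset.at_risk[i, k])
        for (i, c), (k, r) in itertools.product(
            enumerate(dataset.counties), enumerate(dataset.races)
        )
    ]
    pd.DataFrame(rows, columns=["county", "race", "n"]).to_csv(
        paths["at_risk"], index=False
    )
    pd.DataFrame(
        {"age_group": dataset.age_labels, "weight": dataset.std_weights}
    ).to_csv(paths["std_pop"], index=False)
    cov = pd.DataFrame(
        {
            "county": dataset.counties,
            "adi_score": dataset.adi_score,
            "x2": dataset.x2,
        }
    )
    for name, values in dataset.extra_covariates.items():
        cov[name] = values
    cov.to_csv(paths["covariates"], index=False)
    lines = []
    for i, j in dataset.adjacency.edges:
        lines.append(f"{dataset.counties[i]}\t{dataset.counties[j]}")
        lines.append(f"{dataset.counties[j]}\t{dataset.counties[i]}")
    paths["adjacency"].write_text("\n".join(lines) + "\n")
    return paths


def validate_cohort_totals(dataset: IncidenceDataset) -> dict:
    """Aggregate counts and denominators into a cohort totals report.

    Returns cases per race, the grand case total, at-risk women per race,
    the grand at-risk total and the percentage of at-risk women in the
    focal group (race 1), when present.
    """
    cases_by_race = {
        r: int(dataset.counts[:, k, :].sum()) for k, r in enumerate(dataset.races)
    }
    at_risk_by_race = {
        r: int(dataset.at_risk[:, k].sum()) for k, r in enumerate(dataset.races)
    }
    report = {
        "cases_by_race": cases_by_race,
        "total_cases": int(sum(cases_by_race.values())),
        "at_risk_by_race": at_risk_by_race,
        "total_at_risk": int(sum(at_risk_by_race.values())),
    }
    if 1 in at_risk_by_race:
        report["focal_at_risk_pct"] = (
            100.0 * at_risk_by_race[1] / report["total_at_risk"]
        )
    return report


def nm_adjacency_fixture() -> AdjacencyStructure:
    """The packaged New Mexico 33-county border-sharing graph."""
    return AdjacencyStructure.from_named_edges(NM_COUNTIES, NM_BORDER_EDGES)
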