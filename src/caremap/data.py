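"""Core data model and file I/O.

Two containers drive the whole pipeline:

* :class:`StratifiedAreaTable` — per-area observed event counts and
  populations cross-classified by sex and age band, plus area-level
  covariates.  This is the input to indirect standardization and to the
  spatial Poisson model.
* :class:`Adjacency` — a symmetric binary contiguity structure over the same
  areas (areas as nodes, shared borders as edges), read from / written to the
  GAL neighbor-list text format.

Area order is defined by the area table; an adjacency read from file is
re-indexed to that order.  Contiguity is supplied as a file rather than
derived from polygons: how neighborhood is defined (rook vs queen, island
handling) materially changes spatial smoothing, so that decision is left
explicit to the user.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import SchemaError, ValidationError

SEXES = ("male", "female")
AGE_BANDS = (
    "under20",
    "21-30",
    "31-40",
    "41-50",
    "51-60",
    "61-70",
    "71-80",
    "over80",
)
#: The default 16 strata: {male, female} x 8 age bands.
DEFAULT_STRATA = tuple(f"{sex}_{band}" for sex in SEXES for band in AGE_BANDS)


def default_schema(covariates: tuple[str, ...] | list[str] = ()) -> dict:
    """Column-name schema for the default 16-stratum layout.

    Observed counts live in columns ``O_<stratum>`` and populations in
    ``n_<stratum>``; pass ``covariates`` to name additional area-level
    columns.
    """
    return {
        "area_id": "area_id",
        "strata": list(DEFAULT_STRATA),
        "observed": {s: f"O_{s}" for s in DEFAULT_STRATA},
        "population": {s: f"n_{s}" for s in DEFAULT_STRATA},
        "covariates": list(covariates),
    }


@dataclass(frozen=True)
class StratifiedAreaTable:
    """Observed counts and populations by area and sex-age stratum.

    Attributes
    ----------
    area_ids : tuple of str
        Unique, opaque area labels; their order defines area order
        everywhere downstream.
    strata : tuple of str
        Stratum labels, by default the 16-fold sex x age cross.
    observed, population : ndarray of int, shape (n_areas, n_strata)
        Event counts ``O[i, s]`` and person counts ``n[i, s]``.
    covariates : DataFrame, shape (n_areas, n_covariates)
        Area-level covariates, indexed like ``area_ids``.
    """

    area_ids: tuple[str, ...]
    strata: tuple[str, ...]
    observed: np.ndarray
    population: np.ndarray
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        n, k = len(self.area_ids), len(self.strata)
        if self.observed.shape != (n, k) or self.population.shape != (n, k):
            raise ValidationError(
                f"count arrays must have shape ({n}, {k}); got "
                f"O{self.observed.shape}, n{self.population.shape}"
            )
        if len(set(self.area_ids)) != n:
            dupes = pd.Index(self.area_ids)
            dupes = sorted(set(dupes[dupes.duplicated()]))
            raise ValidationError(f"duplicate area ids: {dupes}")
        for name, arr in (("O", self.observed), ("n", self.population)):
            bad = np.argwhere(arr < 0)
            if bad.size:
                i, s = bad[0]
                raise ValidationError(
                    f"negative {name} for area {self.area_ids[i]!r}, "
                    f"stratum {self.strata[s]!r}"
                )
        bad = np.argwhere(self.observed > self.population)
        if bad.size:
            i, s = bad[0]
            raise ValidationError(
                f"observed exceeds population for area {self.area_ids[i]!r}, "
                f"stratum {self.strata[s]!r} "
                f"(O={self.observed[i, s]}, n={self.population[i, s]})"
            )

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_strata(self) -> int:
        return len(self.strata)

    @property
    def observed_totals(self) -> np.ndarray:
        """Per-area totals ``O[i] = sum_s O[i, s]``."""
        return self.observed.sum(axis=1)

    def covariate_matrix(self, names: list[str] | None = None) -> np.ndarray:
        names = list(self.covariates.columns) if names is None else names
        missing = [c for c in names if c not in self.covariates.columns]
        if missing:
            raise SchemaError(f"unknown covariate column(s): {missing}")
        return self.covariates[names].to_numpy(dtype=float)


@dataclass(frozen=True)
class Adjacency:
    """Symmetric binary contiguity over an ordered set of areas."""

    area_ids: tuple[str, ...]
    neighbors: tuple[tuple[int, ...], ...]  # sorted neighbor indices per area
    warnings: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        n = len(self.area_ids)
        for i, nbrs in enumerate(self.neighbors):
            for j in nbrs:
                if not 0 <= j < n:
                    raise ValidationError(f"neighbor index {j} out of range")
                if j == i:
                    raise ValidationError(
                        f"self-neighbor for area {self.area_ids[i]!r}"
                    )
                if i not in self.neighbors[j]:
                    raise ValidationError(
                        f"asymmetric adjacency between "
                        f"{self.area_ids[i]!r} and {self.area_ids[j]!r}"
                    )

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors], dtype=int)

    @property
    def isolated(self) -> np.ndarray:
        """Boolean mask of areas with no neighbors (islands)."""
        return self.degrees == 0

    @property
    def n_edges(self) -> int:
        return int(self.degrees.sum()) // 2

    def matrix(self) -> sp.csr_array:
        """Binary contiguity matrix W as a sparse CSR array."""
        rows, cols = [], []
        for i, nbrs in enumerate(self.neighbors):
            rows.extend([i] * len(nbrs))
            cols.extend(nbrs)
        data = np.ones(len(rows))
        return sp.csr_array(
            (data, (rows, cols)), shape=(self.n_areas, self.n_areas)
        )

    @classmethod
    def from_edges(
        cls,
        area_ids: tuple[str, ...] | list[str],
        edges: list[tuple[int, int]] | np.ndarray,
        warnings: tuple[str, ...] = (),
    ) -> "Adjacency":
        """Build from an undirected edge list of area indices."""
        n = len(area_ids)
        nbrs: list[set[int]] = [set() for _ in range(n)]
        for i, j in edges:
            if i == j:
                continue
            nbrs[int(i)].add(int(j))
            nbrs[int(j)].add(int(i))
        return cls(
            area_ids=tuple(area_ids),
            neighbors=tuple(tuple(sorted(s)) for s in nbrs),
            warnings=tuple(warnings),
        )

    def subset(self, keep: np.ndarray) -> "Adjacency":
        """Induced subgraph on the kept area indices (order preserved)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        new_pos = {int(i): k for k, i in enumerate(keep)}
        ids = tuple(self.area_ids[int(i)] for i in keep)
        edges = [
            (new_pos[i], new_pos[j])
            for i in new_pos
            for j in self.neighbors[i]
            if i < j and j in new_pos
        ]
        return Adjacency.from_edges(ids, edges, self.warnings)

    def reindex(self, area_ids: tuple[str, ...] | list[str]) -> "Adjacency":
        """Reorder to a new area-id order (same set of areas)."""
        if set(area_ids) != set(self.area_ids):
            raise ValidationError("reindex requires the same set of area ids")
        old_pos = {a: i for i, a in enumerate(self.area_ids)}
        new_pos = {a: i for i, a in enumerate(area_ids)}
        edges = [
            (new_pos[self.area_ids[i]], new_pos[self.area_ids[j]])
            for i, nbrs in enumerate(self.neighbors)
            for j in nbrs
            if i < j
        ]
        del old_pos
        return Adjacency.from_edges(tuple(area_ids), edges, self.warnings)


def read_area_table(
    path,
    schema: dict | None = None,
    *,
    require_default_strata: bool = True,
) -> StratifiedAreaTable:
    """Read and validate a stratified area table from CSV.

    Parameters
    ----------
    path : path-like
        UTF-8 CSV with a header row.
    schema : dict, optional
        Mapping with keys ``area_id``, ``strata``, ``observed``,
        ``population``, ``covariates`` (see :func:`default_schema`).  By
        default the 16-stratum naming convention is assumed and every
        non-count column except the id is treated as a covariate.
    require_default_strata : bool
        When True (default), the stratum set must be exactly the
        {male, female} x 8-age-band cross; pass False to accept any
        stratification the schema describes.
    """
    df = pd.read_csv(path, dtype={schema["area_id"] if schema else "area_id": str})
    if schema is None:
        count_cols = [f"{p}_{s}" for s in DEFAULT_STRATA for p in ("O", "n")]
        covs = [
            c for c in df.columns if c != "area_id" and c not in count_cols
        ]
        schema = default_schema(covs)
    for key in ("area_id", "strata", "observed", "population"):
        if key not in schema:
            raise SchemaError(f"schema is missing the {key!r} entry")
    strata = tuple(schema["strata"])
    if require_default_strata and set(strata) != set(DEFAULT_STRATA):
        raise SchemaError(
            "strata must be the 16-fold sex x age cross "
            "(pass require_default_strata=False for custom strata)"
        )
    needed = (
        [schema["area_id"]]
        + [schema["observed"][s] for s in strata]
        + [schema["population"][s] for s in strata]
        + list(schema.get("covariates", []))
    )
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {missing}")

    area_ids = tuple(df[schema["area_id"]].astype(str))
    o_cols = [schema["observed"][s] for s in strata]
    n_cols = [schema["population"][s] for s in strata]
    for col in o_cols + n_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise ValidationError(f"non-numeric or missing value in column {col!r}")
        if not np.allclose(vals, np.round(vals)):
            raise ValidationError(f"non-integer count in column {col!r}")
    observed = df[o_cols].to_numpy(dtype=np.int64)
    population = df[n_cols].to_numpy(dtype=np.int64)
    covariates = df[list(schema.get("covariates", []))].astype(float)
    covariates.index = pd.Index(area_ids, name="area_id")
    return StratifiedAreaTable(
        area_ids=area_ids,
        strata=strata,
        observed=observed,
        population=population,
        covariates=covariates,
    )


def write_area_table(table: StratifiedAreaTable, path) -> None:
    """Write a table back to CSV using the default column convention."""
    data = {"area_id": list(table.area_ids)}
    for s_idx, s in enumerate(table.strata):
        data[f"O_{s}"] = table.observed[:, s_idx]
        data[f"n_{s}"] = table.population[:, s_idx]
    for c in table.covariates.columns:
        data[c] = table.covariates[c].to_numpy()
    pd.DataFrame(data).to_csv(path, index=False)


def read_gal(path, area_ids: tuple[str, ...] | list[str]) -> Adjacency:
    """Read a GAL neighbor-list file and re-index it to ``area_ids``.

    GAL dialect: a header line whose last token is the number of areas,
    then for each area a line ``<id> <k>`` followed by a line of its ``k``
    neighbor ids.  Asymmetric listings (A names B but not vice versa) are
    symmetrized by union, with a warning recorded on the result.
    """
    area_ids = tuple(str(a) for a in area_ids)
    pos = {a: i for i, a in enumerate(area_ids)}
    with open(path, encoding="utf-8") as fh:
        tokens_per_line = [ln.split() for ln in fh if ln.strip()]
    if not tokens_per_line:
        raise SchemaError("empty GAL file")
    header = tokens_per_line[0]
    try:
        n_declared = int(header[-1])
    except (ValueError, IndexError) as exc:
        raise SchemaError(f"malformed GAL header: {' '.join(header)!r}") from exc

    directed: list[tuple[int, int]] = []
    lines = tokens_per_line[1:]
    li = 0
    n_seen = 0
    while li < len(lines):
        head = lines[li]
        if len(head) != 2:
            raise SchemaError(f"malformed GAL record header: {' '.join(head)!r}")
        aid, k_str = head
        try:
            k = int(k_str)
        except ValueError as exc:
            raise SchemaError(
                f"malformed neighbor count for area {aid!r}"
            ) from exc
        if aid not in pos:
            raise ValidationError(f"GAL area id {aid!r} not in the area table")
        li += 1
        nbrs: list[str] = []
        while len(nbrs) < k:
            if li >= len(lines):
                raise SchemaError(f"truncated neighbor list for area {aid!r}")
            nbrs.extend(lines[li])
            li += 1
        if len(nbrs) > k:
            raise SchemaError(f"too many neighbors listed for area {aid!r}")
        for b in nbrs:
            if b not in pos:
                raise ValidationError(
                    f"neighbor id {b!r} of area {aid!r} not in the area table"
                )
            directed.append((pos[aid], pos[b]))
        n_seen += 1
    if n_seen != n_declared:
        raise SchemaError(
            f"GAL header declares {n_declared} areas but {n_seen} records found"
        )
    pairs = set(directed)
    warnings = []
    if any((j, i) not in pairs for i, j in pairs):
        warnings.append("asymmetric GAL neighbor lists symmetrized by union")
    edges = sorted({(min(i, j), max(i, j)) for i, j in pairs})
    return Adjacency.from_edges(area_ids, edges, tuple(warnings))


def write_gal(adj: Adjacency, path) -> None:
    """Write an adjacency as a GAL neighbor-list file (lossless)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{adj.n_areas}\n")
        for i, aid in enumerate(adj.area_ids):
            nbrs = adj.neighbors[i]
            fh.write(f"{aid} {len(nbrs)}\n")
            if nbrs:
                fh.write(" ".join(adj.area_ids[j] for j in nbrs) + "\n")


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def write_results(results: dict, path) -> None:
    """Write fit summaries / diagnostics to JSON at full precision."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonify(results), fh, indent=2, allow_nan=False)
        fh.write("\n")


def read_results(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
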