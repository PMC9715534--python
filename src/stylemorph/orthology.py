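"""Orthogroup tables, one-to-one ortholog maps, and cross-species DEG overlap.

Orthogroup tables follow the tab-separated dialect with a header row
naming species and comma-space separated gene lists per cell (empty cell:
species absent from the orthogroup). One-to-one ortholog maps come either
from two-column TSVs or from reciprocal-best-hit reduction of a pairwise
score table.

The comparative step tags an orthogroup for a species when the orthogroup
contains at least one of that species' DEGs for the stratum under study
(organ class x regulation direction), then partitions tagged orthogroups
into the seven Venn cells over three species. Direction concordance
within a stratum is enforced by construction: each stratum is analyzed
separately.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import pandas as pd

ORGAN_CLASSES = ("female", "male")
DIRECTIONS = ("up", "down")


@dataclass
class OrthogroupTable:
    """Orthogroup id -> {species -> gene id tuple}; genes belong to <= 1 orthogroup."""

    groups: dict[str, dict[str, tuple[str, ...]]]
    species: tuple[str, ...]
    _gene_to_og: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        gene_to_og: dict[str, str] = {}
        for og_id, members in self.groups.items():
            unknown = set(members) - set(self.species)
            if unknown:
                raise ValueError(f"orthogroup {og_id} names unknown species {sorted(unknown)}")
            for sp, genes in members.items():
                for g in genes:
                    if g in gene_to_og:
                        raise ValueError(
                            f"gene {g!r} assigned to both {gene_to_og[g]} and {og_id}"
                        )
                    gene_to_og[g] = og_id
        self._gene_to_og = gene_to_og

    def orthogroup_of(self, gene: str) -> str | None:
        return self._gene_to_og.get(gene)

    def genes(self, og_id: str, species: str | None = None) -> tuple[str, ...]:
        members = self.groups[og_id]
        if species is not None:
            return members.get(species, ())
        return tuple(g for sp in sorted(members) for g in members[sp])

    def __len__(self) -> int:
        return len(self.groups)


def parse_orthogroups(path) -> OrthogroupTable:
    """Read the tab-separated orthogroup dialect (header: Orthogroup, species...)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    id_col = df.columns[0]
    species = tuple(df.columns[1:])
    if df[id_col].duplicated().any():
        dups = df[id_col][df[id_col].duplicated()].tolist()
        raise ValueError(f"duplicate orthogroup ids: {dups[:5]}")
    groups: dict[str, dict[str, tuple[str, ...]]] = {}
    for _, row in df.iterrows():
        members = {}
        for sp in species:
            cell = row[sp].strip()
            if cell:
                members[sp] = tuple(g.strip() for g in cell.split(",") if g.strip())
        groups[row[id_col]] = members
    return OrthogroupTable(groups, species)


def write_orthogroups(table: OrthogroupTable, path) -> None:
    rows = []
    for og_id in sorted(table.groups):
        row = {"Orthogroup": og_id}
        for sp in table.species:
            row[sp] = ", ".join(table.groups[og_id].get(sp, ()))
        rows.append(row)
    pd.DataFrame(rows, columns=["Orthogroup", *table.species]).to_csv(
        path, sep="\t", index=False
    )


def reciprocal_best_hits(scores: pd.DataFrame) -> dict[str, str]:
    """One-to-one map from a (query, target, score) table; higher score is better.

    A pair (a, b) survives iff b is a's unique best target AND a is b's
    unique best query. A tie for best (equal top scores) removes the tied
    gene from the map entirely. An empty table yields an empty map.
    """
    required = {"query", "target", "score"}
    if not required.issubset(scores.columns):
        raise ValueError(f"score table needs columns {sorted(required)}")
    if len(scores) == 0:
        return {}

    def unique_best(df: pd.DataFrame, key: str, value: str) -> dict[str, str]:
        best: dict[str, str] = {}
        for k, grp in df.groupby(key, sort=False):
            top = grp["score"].max()
            hits = grp.loc[grp["score"] == top, value].unique()
            if len(hits) == 1:
                best[k] = hits[0]
        return best

    best_fwd = unique_best(scores, "query", "target")
    best_rev = unique_best(scores, "target", "query")
    return {
        q: t for q, t in best_fwd.items() if best_rev.get(t) == q
    }


def read_ortholog_map(path) -> dict[str, str]:
    """Two-column TSV (species gene, outgroup gene); must be one-to-one."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None,
                     names=["gene", "ortholog"], comment="#")
    if df["gene"].duplicated().any() or df["ortholog"].duplicated().any():
        raise ValueError("ortholog map is not one-to-one")
    return dict(zip(df["gene"], df["ortholog"]))


def write_ortholog_map(mapping: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(mapping):
            fh.write(f"{g}\t{mapping[g]}\n")


@dataclass
class StratifiedDEGSets:
    """Per species -> organ class -> direction -> DEG id set.

    Within one species and organ class, the up and down sets must be
    disjoint (a gene cannot be both up- and down-regulated in the same
    stratified analysis).
    """

    sets: dict[str, dict[str, dict[str, set[str]]]]

    def __post_init__(self) -> None:
        for sp, organs in self.sets.items():
            for organ, directions in organs.items():
                if organ not in ORGAN_CLASSES:
                    raise ValueError(f"unknown organ class {organ!r}")
                up = directions.get("up", set())
                down = directions.get("down", set())
                overlap = up & down
                if overlap:
                    raise ValueError(
                        f"{sp}/{organ}: genes in both up and down sets: "
                        f"{sorted(overlap)[:5]}"
                    )

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted(self.sets))

    def get(self, species: str, organ: str, direction: str) -> set[str]:
        return self.sets.get(species, {}).get(organ, {}).get(direction, set())

    def add(self, species: str, organ: str, direction: str, genes: Iterable[str]) -> None:
        if organ not in ORGAN_CLASSES or direction not in DIRECTIONS:
            raise ValueError(f"bad stratum {organ!r}/{direction!r}")
        node = self.sets.setdefault(species, {}).setdefault(organ, {})
        node[direction] = node.get(direction, set()) | set(genes)
        self.__post_init__()


@dataclass(frozen=True)
class SharedOrthogroupReport:
    """Venn partition of tagged orthogroups for one stratum.

    ``cells`` maps a sorted species tuple (the exact tagging set) to the
    ascending-sorted orthogroup ids tagged by exactly those species;
    ``members`` maps orthogroup id -> {species -> sorted stratum DEGs in
    that orthogroup}; ``unassigned`` lists stratum DEGs found in no
    orthogroup, per species.
    """

    stratum: tuple[str, str]
    species: tuple[str, ...]
    cells: dict[tuple[str, ...], tuple[str, ...]]
    members: dict[str, dict[str, tuple[str, ...]]]
    unassigned: dict[str, tuple[str, ...]]

    def cell(self, *species: str) -> tuple[str, ...]:
        return self.cells.get(tuple(sorted(species)), ())

    @property
    def triple_intersection(self) -> tuple[str, ...]:
        return self.cells.get(tuple(sorted(self.species)), ())


def shared_orthogroups(table: OrthogroupTable, degs: StratifiedDEGSets,
                       organ: str, direction: str,
                       species: Iterable[str] | None = None) -> SharedOrthogroupReport:
    """Venn partition of orthogroups containing stratum DEGs per species."""
    if organ not in ORGAN_CLASSES or direction not in DIRECTIONS:
        raise ValueError(f"bad stratum {organ!r}/{direction!r}")
    roster = tuple(sorted(species if species is not None else degs.species))
    unknown = set(roster) - set(table.species)
    if unknown:
        raise ValueError(f"species not in the orthogroup table: {sorted(unknown)}")
    tags: dict[str, set[str]] = defaultdict(set)
    members: dict[str, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    unassigned: dict[str, list[str]] = {sp: [] for sp in roster}
    for sp in roster:
        for gene in sorted(degs.get(sp, organ, direction)):
            og = table.orthogroup_of(gene)
            if og is None:
                unassigned[sp].append(gene)
                continue
            tags[og].add(sp)
            members[og][sp].add(gene)
    cells: dict[tuple[str, ...], list[str]] = {
        combo: []
        for r in range(1, len(roster) + 1)
        for combo in combinations(roster, r)
    }
    for og in sorted(tags):
        cells[tuple(sorted(tags[og]))].append(og)
    return SharedOrthogroupReport(
        stratum=(organ, direction),
        species=roster,
        cells={k: tuple(v) for k, v in cells.items()},
        members={
            og: {sp: tuple(sorted(gs)) for sp, gs in sorted(spmap.items())}
            for og, spmap in sorted(members.items())
        },
        unassigned={sp: tuple(v) for sp, v in unassigned.items()},
    )


def report_to_frame(report: SharedOrthogroupReport) -> pd.DataFrame:
    """Flatten a Venn report to one row per tagged orthogroup."""
    rows = []
    for combo, ogs in sorted(report.cells.items()):
        for og in ogs:
            rows.append({
                "organ": report.stratum[0],
                "direction": report.stratum[1],
                "venn_cell": "&".join(combo),
                "n_species": len(combo),
                "orthogroup": og,
                "degs": "; ".join(
                    f"{sp}:{','.join(genes)}"
                    for sp, genes in report.members[og].items()
                ),
            })
    return pd.DataFrame(
        rows, columns=["organ", "direction", "venn_cell", "n_species",
                       "orthogroup", "degs"]
    )
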