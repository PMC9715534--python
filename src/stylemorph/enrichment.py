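"""Exact 2x2 contingency testing and gene-set over-representation.

The central primitive is Fisher's exact test computed from hypergeometric
log-probabilities (log-factorials via gammaln). The two-sided p-value uses
the minimum-likelihood rule — the sum of probabilities of all tables with
the observed margins whose point probability does not exceed the observed
one, with a small relative tolerance for floating-point ties. One-sided
tails are plain cumulative sums over the support.

On top of it sit Benjamini-Hochberg adjustment, contingency-table
construction from gene sets, a generic over-representation scan across
flat gene-set terms, and the cross-species PIF-regulation scan in which
each species' analysis universe is its set of genes carrying a one-to-one
ortholog in the label-bearing outgroup species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

TIE_RELATIVE_TOLERANCE = 1e-7

_SIDES = ("two-sided", "greater", "less")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: a = DEG & in-set, b = DEG & not, c = non-DEG & in-set, d = rest."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError(f"contingency cells must be non-negative integers: {cells}")
        if sum(cells) < 1:
            raise ValueError("contingency table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def odds_ratio(self) -> float:
        """Sample (cross-product) odds ratio; inf/NaN when a margin cell is 0."""
        if self.b * self.c == 0:
            return float("inf") if self.a * self.d > 0 else float("nan")
        return (self.a * self.d) / (self.b * self.c)

    @property
    def direction(self) -> str:
        """'enriched' if the DEG row has the higher in-set rate, else 'depleted'/'none'."""
        r1, r2 = self.a + self.b, self.c + self.d
        if r1 == 0 or r2 == 0:
            return "none"
        lhs, rhs = self.a * r2, self.c * r1  # cross-multiplied rates
        if lhs > rhs:
            return "enriched"
        if lhs < rhs:
            return "depleted"
        return "none"


@dataclass(frozen=True)
class EnrichmentResult:
    table: ContingencyTable
    pvalue: float
    odds_ratio: float
    direction: str
    significant: bool


def _support_logpmf(row1: int, col1: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Hypergeometric support and log-pmf for fixed margins (row1, col1, n)."""
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    a = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(row1 + 1) - gammaln(a + 1) - gammaln(row1 - a + 1)
        + gammaln(n - row1 + 1) - gammaln(col1 - a + 1) - gammaln(n - row1 - (col1 - a) + 1)
        - (gammaln(n + 1) - gammaln(col1 + 1) - gammaln(n - col1 + 1))
    )
    return a, logpmf


def fisher_exact(table: ContingencyTable, sided: str = "two-sided") -> float:
    """Exact p-value for a 2x2 table under fixed margins.

    ``sided``: "two-sided" (minimum-likelihood rule), "greater" (enrichment
    of cell a), or "less".
    """
    if sided not in _SIDES:
        raise ValueError(f"sided must be one of {_SIDES}")
    row1 = table.a + table.b
    col1 = table.a + table.c
    support, logpmf = _support_logpmf(row1, col1, table.n)
    pmf = np.exp(logpmf - logpmf.max())
    pmf /= pmf.sum()
    idx = table.a - support[0]
    if sided == "greater":
        p = pmf[idx:].sum()
    elif sided == "less":
        p = pmf[: idx + 1].sum()
    else:
        p = pmf[pmf <= pmf[idx] * (1.0 + TIE_RELATIVE_TOLERANCE)].sum()
    return float(min(1.0, max(0.0, p)))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    p_(i) * m / i with a cumulative minimum from the largest p down, capped
    at 1.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    monotone = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.empty(m, dtype=float)
    adjusted[order] = np.minimum(monotone, 1.0)
    return adjusted


def build_set_contingency(deg_set: Iterable[str], universe: Iterable[str],
                          label_set: Iterable[str]) -> ContingencyTable:
    """Cross-classify the analysis universe by DEG status and set membership.

    The universe is the analysis universe (for ortholog-based labels, the
    genes carrying an ortholog), never the whole genome. DEGs outside the
    universe are an integrity error.
    """
    universe = set(universe)
    deg = set(deg_set)
    label = set(label_set) & universe
    outside = deg - universe
    if outside:
        raise ValueError(
            f"{len(outside)} DEG(s) outside the universe, e.g. {sorted(outside)[:5]}"
        )
    a = len(deg & label)
    b = len(deg) - a
    c = len(label) - a
    d = len(universe) - len(deg) - c
    return ContingencyTable(a, b, c, d)


def test_enrichment(table: ContingencyTable, sided: str = "two-sided",
                    alpha: float = 0.05) -> EnrichmentResult:
    p = fisher_exact(table, sided=sided)
    return EnrichmentResult(
        table=table,
        pvalue=p,
        odds_ratio=table.odds_ratio,
        direction=table.direction,
        significant=bool(p <= alpha),
    )


def term_enrichment(deg_set: Iterable[str], universe: Iterable[str],
                    term_map: Mapping[str, Iterable[str]], alpha: float = 0.05,
                    ) -> pd.DataFrame:
    """One-sided (greater) over-representation per term with BH across terms.

    Terms with no member inside the universe are skipped. Returns one row
    per tested term: cell counts, raw p, BH-adjusted p, significance at
    ``alpha`` on the adjusted p.
    """
    deg = set(deg_set)
    if not deg:
        raise ValueError("empty DEG set")
    universe = set(universe)
    rows = []
    for term in sorted(term_map):
        members = set(term_map[term]) & universe
        if not members:
            continue
        t = build_set_contingency(deg, universe, members)
        rows.append({
            "term": term, "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "odds_ratio": t.odds_ratio,
            "pvalue": fisher_exact(t, sided="greater"),
        })
    out = pd.DataFrame(rows, columns=["term", "a", "b", "c", "d", "odds_ratio", "pvalue"])
    if len(out) > 0:
        out["padj"] = bh_adjust(out["pvalue"])
        out["significant"] = out["padj"] <= alpha
    else:
        out["padj"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out


def pif_scan(samples: Sequence[tuple[str, str, Iterable[str]]],
             ortholog_maps: Mapping[str, Mapping[str, str]],
             label_list: Iterable[str], alpha: float = 0.05,
             sided: str = "greater") -> pd.DataFrame:
    """Gene-set enrichment among DEGs via orthology-transferred labels.

    Parameters
    ----------
    samples
        Sequence of ``(sample_name, species, deg_gene_ids)``; report rows
        keep this order.
    ortholog_maps
        Per species, a one-to-one map {species gene -> outgroup gene}. The
        species' analysis universe is the keys of its map.
    label_list
        Outgroup gene ids carrying the label (e.g. PIF-regulated).
    sided
        Tail of the exact test; the published analysis this mirrors is
        reproduced by the one-sided enrichment tail.

    A species gene is labelled iff its outgroup ortholog is in
    ``label_list``. DEGs without an ortholog are dropped from the table
    (they are outside the universe); a sample whose orthologed DEG row is
    empty is flagged untestable with p = NaN.
    """
    label = set(label_list)
    rows = []
    for name, species, deg in samples:
        if species not in ortholog_maps:
            raise ValueError(f"no ortholog map for species {species!r}")
        omap = ortholog_maps[species]
        universe = set(omap)
        labelled = {g for g, og in omap.items() if og in label}
        deg_in = set(deg) & universe
        t = build_set_contingency(deg_in, universe, labelled)
        if t.a + t.b == 0:
            rows.append({
                "sample": name, "species": species,
                "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                "pvalue": float("nan"), "odds_ratio": float("nan"),
                "significant": False, "testable": False,
            })
            continue
        res = test_enrichment(t, sided=sided, alpha=alpha)
        rows.append({
            "sample": name, "species": species,
            "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "pvalue": res.pvalue, "odds_ratio": res.odds_ratio,
            "significant": res.significant, "testable": True,
        })
    return pd.DataFrame(rows)


def read_gene_list(path) -> list[str]:
    """One gene id per line; '#' comments and blank lines ignored."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.append(line)
    return genes


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
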