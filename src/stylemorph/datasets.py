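"""Small published example datasets bundled with the package.

Currently: the ten published PIF-regulation contingency tables from the
three-species distyly comparison (DEG vs non-DEG crossed with
PIF-regulated vs not, per floral tissue sample), useful for exercising
the exact-test machinery on real numbers without any download.
"""

from __future__ import annotations

import pandas as pd

from .enrichment import ContingencyTable

# (species, tissue sample, a=DEG&PIF, b=DEG&non-PIF, c=nonDEG&PIF, d=nonDEG&non-PIF)
_PIF_TABLES = [
    ("Primula veris", "style", 12, 83, 513, 10262),
    ("Primula veris", "corolla tube", 6, 34, 520, 10312),
    ("Primula vulgaris", "whole flower", 3, 79, 523, 10262),
    ("Fagopyrum esculentum", "mature carpel", 25, 174, 418, 9041),
    ("Fagopyrum esculentum", "young carpel", 10, 134, 434, 9082),
    ("Fagopyrum esculentum", "stamen filament", 43, 338, 401, 8874),
    ("Turnera subulata", "mature pistil", 45, 169, 417, 8491),
    ("Turnera subulata", "mature stamen", 9, 99, 453, 8561),
    ("Turnera subulata", "young pistil", 14, 64, 448, 8596),
    ("Turnera subulata", "young stamen", 9, 103, 453, 8557),
]


def pif_enrichment_tables() -> pd.DataFrame:
    """Published PIF-regulation 2x2 tables, one row per floral tissue sample.

    Columns a..d follow the package's contingency convention: a = DEG and
    PIF-regulated, b = DEG and not, c = non-DEG and PIF-regulated, d =
    remainder. The analysis universe per sample (a+b+c+d) is the species'
    gene set with one-to-one A. thaliana orthologs.
    """
    return pd.DataFrame(
        _PIF_TABLES, columns=["species", "sample", "a", "b", "c", "d"]
    )


def pif_contingency(species: str, sample: str) -> ContingencyTable:
    """The published table for one (species, tissue sample) pair."""
    for sp, ts, a, b, c, d in _PIF_TABLES:
        if sp == species and ts == sample:
            return ContingencyTable(a, b, c, d)
    raise KeyError(f"no published table for {species!r} / {sample!r}")
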