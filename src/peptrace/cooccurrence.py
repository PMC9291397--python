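"""Presence/absence of the four peptidases and co-occurrence enrichment.

Builds the species x family boolean presence matrix from the homolog table
and asks, with an exact conditional (Fisher-type) test, whether pairs of
peptidases co-occur more or less often in AMP-resistant bacteria than in
the other bacteria of a clade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

FAMILIES = ("MPP", "OOP", "PreP", "SPP")


def build_presence(homologs: pd.DataFrame, taxonomy: pd.DataFrame,
                   families: Sequence[str] = FAMILIES) -> pd.DataFrame:
    """Species x family boolean matrix with clade/resistance row metadata.

    A cell is True when the species has at least one homolog of the family;
    species without any homolog keep an all-False row.  Raises when a
    homolog references a species absent from the taxonomy.
    """
    known = set(taxonomy["species_id"])
    unknown = set(homologs["species_id"]) - known
    if unknown:
        raise KeyError(f"species in homolog table but not taxonomy: {sorted(unknown)}")
    mat = pd.DataFrame(False, index=sorted(known), columns=list(families))
    for _, row in homologs.iterrows():
        if row["family"] in mat.columns:
            mat.loc[row["species_id"], row["family"]] = True
    meta = taxonomy.set_index("species_id")
    mat.insert(0, "clade", meta.loc[mat.index, "clade"].to_numpy())
    mat.insert(1, "domain_of_life", meta.loc[mat.index, "domain_of_life"].to_numpy())
    mat.insert(2, "resistant", meta.loc[mat.index, "resistant"].astype(int).to_numpy())
    mat.index.name = "species_id"
    return mat


def pair_counts(matrix: pd.DataFrame, family_a: str, family_b: str,
                species: Sequence[str] | None = None) -> tuple[int, int, int, int]:
    """(both, only_a, only_b, neither) counts over a species subset."""
    if family_a == family_b:
        raise ValueError("pair must name two distinct families")
    sub = matrix if species is None else matrix.loc[sorted(set(species))]
    a = sub[family_a].to_numpy(bool)
    b = sub[family_b].to_numpy(bool)
    return (int((a & b).sum()), int((a & ~b).sum()),
            int((~a & b).sum()), int((~a & ~b).sum()))


@dataclass
class EnrichmentReport:
    family_a: str
    family_b: str
    clade: str | None
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float  # NaN when a margin is degenerate
    p_value: float
    direction: str  # "enriched", "depleted" or "none"
    n_resistant: int
    n_other: int
    alternative: str
    test: str = "fisher_exact_conditional"


def exact_cooccurrence_test(table, alternative: str = "two-sided"
                            ) -> tuple[float, float]:
    """Exact conditional test on a 2x2 table: (odds ratio, p-value).

    Degenerate margins give p = 1 and an undefined (NaN) odds ratio.
    """
    t = np.asarray(table, dtype=int)
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        return float("nan"), 1.0
    odds, p = stats.fisher_exact(t, alternative=alternative)
    return float(odds), float(p)


def cooccurrence_enrichment(matrix: pd.DataFrame, family_a: str, family_b: str,
                            clade: str | None = None,
                            alternative: str = "two-sided") -> EnrichmentReport:
    """Exact test of pair co-occurrence, resistant vs. non-resistant.

    The 2x2 table crosses "species carries both peptidases" with
    "species is AMP-resistant", within ``clade`` when given (otherwise all
    bacteria).  Resistant species are compared against the *other* species
    of the group (the exclusive contrast).  A degenerate margin yields
    p = 1 with an undefined (NaN) odds ratio.
    """
    sub = matrix[matrix["domain_of_life"] == "Bacteria"] \
        if "domain_of_life" in matrix.columns else matrix
    if clade is not None:
        sub = sub[sub["clade"] == clade]
    res = sub[sub["resistant"] == 1]
    other = sub[sub["resistant"] == 0]
    both_res = int((res[family_a] & res[family_b]).sum())
    both_other = int((other[family_a] & other[family_b]).sum())
    table = np.array([[both_res, len(res) - both_res],
                      [both_other, len(other) - both_other]])
    odds, p = exact_cooccurrence_test(table, alternative=alternative)
    if math.isnan(odds):
        return EnrichmentReport(family_a, family_b, clade,
                                tuple(map(tuple, table)), odds, p,
                                "none", len(res), len(other), alternative)
    f_res = both_res / len(res)
    f_other = both_other / len(other)
    direction = "enriched" if f_res > f_other else \
        ("depleted" if f_res < f_other else "none")
    return EnrichmentReport(family_a, family_b, clade, tuple(map(tuple, table)),
                            float(odds), float(p), direction,
                            len(res), len(other), alternative)


def enrichment_report(matrix: pd.DataFrame,
                      clades: Sequence[str | None] = (None,),
                      families: Sequence[str] = FAMILIES,
                      alternative: str = "two-sided") -> pd.DataFrame:
    """All family pairs x clades, raw p-values (no multiplicity correction)."""
    rows = []
    for clade in clades:
        for fa, fb in combinations(families, 2):
            r = cooccurrence_enrichment(matrix, fa, fb, clade=clade,
                                        alternative=alternative)
            rows.append({"clade": "all" if clade is None else clade,
                         "family_a": fa, "family_b": fb,
                         "both_resistant": r.table[0][0],
                         "not_both_resistant": r.table[0][1],
                         "both_other": r.table[1][0],
                         "not_both_other": r.table[1][1],
                         "odds_ratio": r.odds_ratio, "p_value": r.p_value,
                         "direction": r.direction, "test": r.test,
                         "alternative": r.alternative})
    return pd.DataFrame(rows)
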