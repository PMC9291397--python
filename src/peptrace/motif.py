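"""Sequence-logo statistics and the catalytic zinc-binding motif scanner.

The logo statistics follow the usual information-theoretic convention: a
column's information content is log2(20) minus the Shannon entropy of its
non-gap residue distribution (uniform background over the 20 amino acids),
each residue's stack height is its frequency times the column information,
and the stack width shrinks with the gap fraction.  The catalytic scanner
locates the metallopeptidase zinc-binding pattern HxxEH followed, 76
positions later, by the third catalytic glutamate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
MAX_BITS = math.log2(20.0)
GAP = "-"


@dataclass
class ColumnStats:
    """Per-column logo statistics (1-based position)."""

    position: int
    frequencies: dict[str, float]
    gap_fraction: float
    information: float  # bits

    @property
    def heights(self) -> dict[str, float]:
        return {aa: f * self.information for aa, f in self.frequencies.items()}

    @property
    def width(self) -> float:
        return 1.0 - self.gap_fraction


def logo_stats(rows: Sequence[str], small_sample_correction: bool = False
               ) -> list[ColumnStats]:
    """Compute per-column residue frequencies, gap fraction and information.

    ``-`` and ``.`` count as gaps; ``X`` counts as missing data and is
    excluded from both the frequencies and the gap fraction denominator's
    non-gap side.  An all-gap column has zero information and zero width.
    The optional small-sample correction subtracts the standard
    ``(|A|-1) / (2 ln2 n)`` term (floored at zero information).
    """
    if not rows:
        return []
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError("rows have unequal lengths")
    mat = np.array([list(r.upper().replace(".", GAP)) for r in rows])
    out = []
    for j in range(ncol):
        col = mat[:, j]
        gaps = int((col == GAP).sum())
        residues = col[(col != GAP) & (col != "X")]
        n = len(residues)
        freqs: dict[str, float] = {}
        if n == 0:
            info = 0.0
            gap_fraction = 1.0
        else:
            vals, counts = np.unique(residues, return_counts=True)
            p = counts / n
            freqs = dict(zip(vals.tolist(), p.tolist()))
            entropy = float(-(p * np.log2(p)).sum())
            info = MAX_BITS - entropy
            if small_sample_correction:
                info = max(0.0, info - (len(AMINO_ACIDS) - 1) / (2.0 * math.log(2) * n))
            gap_fraction = gaps / len(col)
        out.append(ColumnStats(j + 1, freqs, gap_fraction, info))
    return out


def find_catalytic_motif(sequence: str, spacing: int = 76, tolerance: int = 0
                         ) -> list[int]:
    """All 1-based positions i of the zinc-binding pattern HxxEH...E.

    A match requires H at i, E at i+3, H at i+4 and an E at offset
    i+4+s+1 for some spacer length s with ``|s - spacing| <= tolerance``.
    Sequences shorter than the motif span yield no match.
    """
    seq = sequence.upper()
    n = len(seq)
    matches = []
    for i in range(n):
        if i + 4 >= n:
            break
        if seq[i] != "H" or seq[i + 3] != "E" or seq[i + 4] != "H":
            continue
        for s in range(max(0, spacing - tolerance), spacing + tolerance + 1):
            j = i + 4 + s + 1
            if j < n and seq[j] == "E":
                matches.append(i + 1)
                break
    return matches


@dataclass
class LogoComparison:
    positions: pd.DataFrame
    agreement_fraction: float


def compare_logos(stats_a: Sequence[ColumnStats], stats_b: Sequence[ColumnStats]
                  ) -> LogoComparison:
    """Column-by-column comparison of two logos over the same coordinates.

    Reports each set's most frequent residue, whether they agree, and the
    information difference (a minus b); the summary is the fraction of
    columns whose top residues agree (columns where either set is all-gap
    are skipped in the summary).
    """
    if len(stats_a) != len(stats_b):
        raise ValueError("logos have different column counts")
    rows = []
    agree, considered = 0, 0
    for a, b in zip(stats_a, stats_b):
        top_a = max(a.frequencies, key=lambda k: (a.frequencies[k], k)) \
            if a.frequencies else None
        top_b = max(b.frequencies, key=lambda k: (b.frequencies[k], k)) \
            if b.frequencies else None
        match = top_a is not None and top_a == top_b
        if top_a is not None and top_b is not None:
            considered += 1
            agree += int(match)
        rows.append({"position": a.position, "top_a": top_a, "top_b": top_b,
                     "agree": match, "delta_information": a.information - b.information})
    frac = agree / considered if considered else float("nan")
    return LogoComparison(pd.DataFrame(rows), frac)


def stats_table(stats: Sequence[ColumnStats]) -> pd.DataFrame:
    """Flatten ColumnStats into the TSV-friendly per-column table."""
    rows = []
    for s in stats:
        top = max(s.frequencies, key=lambda k: (s.frequencies[k], k)) \
            if s.frequencies else None
        rows.append({"position": s.position, "information": s.information,
                     "gap_fraction": s.gap_fraction, "width": s.width,
                     "top_residue": top,
                     "top_frequency": s.frequencies.get(top, 0.0) if top else 0.0})
    return pd.DataFrame(rows, columns=["position", "information", "gap_fraction",
                                       "width", "top_residue", "top_frequency"])
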