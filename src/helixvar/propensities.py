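"""Amino-acid propensity statistics for helix subclasses.

Propensities are Chou–Fasman-style ratios: the relative frequency of an
amino acid within a subclass (overall, or at a fixed position) divided by
its background relative frequency.  A value above 1 means the residue is
preferred in that context.  Positions are named N1..N4 (first four helix
residues), C4..C1 (last four, C1 being the final residue) and, for helices
longer than 12 residues, M1..M4 (residues 5..8, immediately after N4, so
the M and C blocks never overlap).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .assembly import HelixSegment

__all__ = [
    "AMINO_ACIDS",
    "N_POSITIONS",
    "C_POSITIONS",
    "M_POSITIONS",
    "PropensityTable",
    "PositionalPropensityTable",
    "group_segments",
    "pooled_background",
    "overall_propensity",
    "positional_propensity",
    "rank_preferred",
    "length_distribution",
]

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
N_POSITIONS = ("N1", "N2", "N3", "N4")
C_POSITIONS = ("C4", "C3", "C2", "C1")
M_POSITIONS = ("M1", "M2", "M3", "M4")
MIDDLE_MIN_LENGTH = 13  # M positions defined only for length > 12


@dataclass
class PropensityTable:
    """Overall propensities: rows = amino acids, columns = subclasses."""

    values: pd.DataFrame
    counts: pd.DataFrame
    background: pd.Series


@dataclass
class PositionalPropensityTable:
    """Positional propensities with a (subclass, position) column MultiIndex.

    Positions with zero contributing segments hold NaN values and are listed
    in ``undefined``.
    """

    values: pd.DataFrame
    counts: pd.DataFrame
    background: pd.Series
    undefined: list


def group_segments(segments: Iterable[HelixSegment]) -> dict[str, list[str]]:
    """Group pure segments' sequences by their subclass label."""
    out: dict[str, list[str]] = {}
    for seg in segments:
        if seg.is_pure:
            out.setdefault(str(seg.purity_label), []).append(seg.sequence)
    return out


def _count_residues(sequences: Iterable[str]) -> pd.Series:
    counts = pd.Series(0, index=list(AMINO_ACIDS), dtype=int)
    for seq in sequences:
        for a in seq:
            if a in counts.index:
                counts[a] += 1
    return counts


def pooled_background(groups: Mapping[str, Sequence[str]]) -> pd.Series:
    """Amino-acid composition pooled over every subclass's sequences."""
    total = _count_residues(s for seqs in groups.values() for s in seqs)
    if total.sum() == 0:
        raise ValueError("no residues to pool a background from")
    return total / total.sum()


def _check_background(background: pd.Series, used: pd.Series) -> None:
    missing = [a for a in used.index if used[a] > 0 and
               (a not in background.index or background[a] <= 0)]
    if missing:
        raise ValueError(
            f"background lacks positive frequency for observed residues {missing}"
        )


def overall_propensity(
    groups: Mapping[str, Sequence[str]],
    background: pd.Series | None = None,
    pseudocount: float = 0.0,
) -> PropensityTable:
    """Overall propensity per (subclass, amino acid).

    value(s, a) = (count of a in s / residues in s) / background frequency
    of a.  The background defaults to the pooled composition over all
    groups.  Zero counts give propensity 0 unless a pseudocount is used.
    """
    if background is None:
        background = pooled_background(groups)
    counts = pd.DataFrame({s: _count_residues(seqs) for s, seqs in groups.items()})
    for s in counts.columns:
        if counts[s].sum() == 0:
            raise ValueError(f"subclass {s!r} has no residues")
        _check_background(background, counts[s])
    adj = counts + pseudocount
    freq = adj / adj.sum(axis=0)
    values = freq.div(background.reindex(freq.index), axis=0)
    return PropensityTable(values=values, counts=counts, background=background)


def _position_residue(seq: str, pos: str) -> str | None:
    """Residue at a named position, or None when the position is undefined."""
    n = len(seq)
    if pos in N_POSITIONS:
        return seq[N_POSITIONS.index(pos)]
    if pos in C_POSITIONS:
        return seq[n - 4 + C_POSITIONS.index(pos)]
    if pos in M_POSITIONS:
        if n < MIDDLE_MIN_LENGTH:
            return None
        return seq[4 + M_POSITIONS.index(pos)]
    raise KeyError(pos)


def positional_propensity(
    groups: Mapping[str, Sequence[str]],
    background: pd.Series | None = None,
    pseudocount: float = 0.0,
) -> PositionalPropensityTable:
    """Position-specific propensities at N1..N4, C4..C1 and M1..M4.

    value(s, p, a) = frequency of a at position p within subclass s divided
    by the background frequency of a.  M positions draw only on segments
    longer than 12 residues; per (subclass, position) the counts sum to the
    number of contributing segments.
    """
    if background is None:
        background = pooled_background(groups)
    positions = N_POSITIONS + C_POSITIONS + M_POSITIONS
    cols = pd.MultiIndex.from_product([list(groups), positions],
                                      names=["subclass", "position"])
    counts = pd.DataFrame(0, index=list(AMINO_ACIDS), columns=cols, dtype=int)
    for s, seqs in groups.items():
        for seq in seqs:
            for pos in positions:
                a = _position_residue(seq, pos)
                if a is not None and a in counts.index:
                    counts.loc[a, (s, pos)] += 1
    undefined = [c for c in cols if counts[c].sum() == 0]
    adj = counts + pseudocount
    totals = adj.sum(axis=0).replace(0, np.nan)
    freq = adj / totals
    values = freq.div(background.reindex(freq.index), axis=0)
    for c in undefined:
        values[c] = np.nan
    for s in groups:
        _check_background(background, counts[s].sum(axis=1))
    return PositionalPropensityTable(values=values, counts=counts,
                                     background=background, undefined=undefined)


def rank_preferred(
    table: PropensityTable | PositionalPropensityTable,
    subclass: str,
    position: str | None = None,
    threshold: float = 1.2,
) -> list[str]:
    """Amino acids with propensity above ``threshold``, best first.

    Ties are broken alphabetically.  ``position=None`` ranks the overall
    table; a position name ranks that column of the positional table.
    """
    col = table.values[subclass] if position is None else table.values[(subclass, position)]
    col = col.dropna()
    order = sorted(col.index, key=lambda a: (-col[a], a))
    return [a for a in order if col[a] > threshold]


def length_distribution(
    groups: Mapping[str, Sequence[int]] | Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Fraction of helices per subclass with l == 8, 8 < l <= 15, l > 15.

    Accepts sequences or integer lengths per subclass; empty subclasses are
    excluded.  Rows sum to 1.
    """
    rows = {}
    for s, items in groups.items():
        lengths = [len(x) if isinstance(x, str) else int(x) for x in items]
        if not lengths:
            continue
        arr = np.asarray(lengths)
        n = len(arr)
        rows[s] = {
            "l=8": float(np.sum(arr == 8)) / n,
            "8<l<=15": float(np.sum((arr > 8) & (arr <= 15))) / n,
            "l>15": float(np.sum(arr > 15)) / n,
        }
    return pd.DataFrame(rows).T[["l=8", "8<l<=15", "l>15"]]
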