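"""Set-level analytics over DE results: DEG sets, exclusive intersections,
tissue-specificity fractions, fold-change concordance and top-gene selection.

"Exclusive intersections" follow UpSet semantics: the count for a membership
pattern is the number of genes belonging to exactly that combination of sets
and no others, so the counts over all nonempty patterns partition the union.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import Thresholds, call_direction, UP, DOWN, UNCHANGED

logger = logging.getLogger(__name__)


@dataclass
class DEGSet:
    """A labelled set of differentially expressed genes with its Up/Down split."""

    label: str
    genes: frozenset
    n_up: int
    n_down: int


@dataclass
class IntersectionSummary:
    """Count of genes belonging to exactly the sets flagged in the pattern."""

    membership_pattern: tuple[bool, ...]
    exclusive_count: int


def _directions(de: pd.DataFrame, contrast: str, th: Thresholds) -> pd.Series:
    sub = de[de["contrast"] == contrast]
    if len(sub) == 0:
        raise ValueError(f"contrast {contrast!r} not present in DE table")
    return pd.Series(
        [call_direction(fc, pa, th) for fc, pa in zip(sub["log2fc"], sub["padj"])],
        index=sub["gene_id"].to_numpy(),
    )


def deg_sets(
    de_tables: dict[str, pd.DataFrame],
    contrast: str,
    th: Thresholds = Thresholds(),
) -> list[DEGSet]:
    """Per label (tissue or condition), the DEG set for one contrast with Up/Down split."""
    out = []
    for label, de in de_tables.items():
        dirs = _directions(de, contrast, th)
        sig = dirs[dirs != UNCHANGED]
        out.append(
            DEGSet(
                label=label,
                genes=frozenset(sig.index),
                n_up=int((sig == UP).sum()),
                n_down=int((sig == DOWN).sum()),
            )
        )
    return out


def exclusive_intersections(sets: list[DEGSet]) -> list[IntersectionSummary]:
    """UpSet-style exclusive intersection counts over a family of DEG sets.

    One summary per nonempty membership pattern that actually occurs;
    exclusive counts sum to the cardinality of the union.
    """
    if not 1 <= len(sets) <= 12:
        raise ValueError("between 1 and 12 sets supported")
    tally: dict[tuple[bool, ...], int] = {}
    universe = set().union(*(s.genes for s in sets))
    for g in universe:
        pattern = tuple(g in s.genes for s in sets)
        tally[pattern] = tally.get(pattern, 0) + 1
    return [
        IntersectionSummary(membership_pattern=p, exclusive_count=c)
        for p, c in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def specificity_fraction(
    summary: list[IntersectionSummary], sets: list[DEGSet], label: str
) -> float:
    """Fraction of a set's genes found in that set only (tissue specificity)."""
    labels = [s.label for s in sets]
    if label not in labels:
        raise ValueError(f"unknown label: {label!r}")
    i = labels.index(label)
    total = len(sets[i].genes)
    if total == 0:
        return float("nan")
    singleton = tuple(j == i for j in range(len(sets)))
    only = sum(s.exclusive_count for s in summary if s.membership_pattern == singleton)
    return only / total


def concordance_r2(
    de: pd.DataFrame,
    subset: str = "AB_degs",
    th: Thresholds = Thresholds(),
) -> tuple[float, int]:
    """Squared Pearson correlation of the two single-exposure log2FCs.

    The correlation is computed over a stated gene subset: ``AB_degs``
    (genes differentially expressed under the combined exposure) or
    ``A_or_B_degs`` (the union of the single-exposure DEG sets).  Returns
    (r2, n).
    """
    if subset not in ("AB_degs", "A_or_B_degs"):
        raise ValueError(f"unknown subset: {subset!r}")
    dir_AB = _directions(de, "AB", th)
    dir_A = _directions(de, "A", th)
    dir_B = _directions(de, "B", th)
    if subset == "AB_degs":
        genes = dir_AB.index[dir_AB != UNCHANGED]
    else:
        genes = dir_A.index[(dir_A != UNCHANGED) | (dir_B != UNCHANGED)]
    if len(genes) < 3:
        raise ValueError("subset too small: fewer than 3 genes")
    fc = de.pivot(index="gene_id", columns="contrast", values="log2fc").loc[genes]
    r = np.corrcoef(fc["A"], fc["B"])[0, 1]
    return float(r**2), int(len(genes))


def top_genes(
    de: pd.DataFrame,
    contrast: str,
    direction: str,
    k: int = 30,
    th: Thresholds = Thresholds(),
) -> list[str]:
    """The k genes most strongly regulated in one direction for a contrast.

    Ranking is by |log2FC| descending among genes called in the requested
    direction; ties break by smaller adjusted p, then gene id.  If fewer
    than k genes qualify, all are returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if direction not in (UP, DOWN):
        raise ValueError("direction must be Up or Down")
    sub = de[de["contrast"] == contrast].copy()
    if len(sub) == 0:
        raise ValueError(f"contrast {contrast!r} not present in DE table")
    calls = [call_direction(fc, pa, th) for fc, pa in zip(sub["log2fc"], sub["padj"])]
    sub = sub[np.asarray(calls) == direction]
    if len(sub) < k:
        logger.info("only %d genes qualify for top-%d selection", len(sub), k)
    sub = sub.assign(absfc=sub["log2fc"].abs()).sort_values(
        ["absfc", "padj", "gene_id"], ascending=[False, True, True], kind="stable"
    )
    return list(sub["gene_id"].head(k))
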