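"""Classification of transcriptional interactions under dual stimuli.

Given per-gene results for the four contrasts — the two single exposures
(A: cold, B: diet), their combination (AB) and the statistical interaction
(INT) — each gene significant in at least one contrast is assigned:

* a direction call (Up / Down / Unchanged) per contrast, using a dual
  threshold: BH-adjusted p below ``alpha`` AND |log2FC| at or above
  ``min_abs_l2fc`` (default 0.585 = log2(1.5));
* a *mode*: cooperative when the two single exposures agree (both Up, both
  Down, or both Unchanged), competitive when they differ;
* a *regulation category*: co-dependent, concordant, discordant,
  A-/B-dominant, A-/B-/mutually masked, or unclassified;
* an *expected additive effect*  log2FC_A + log2FC_B, the null prediction
  for the combined exposure on the log scale;
* a *synergy score*  log2 |log2FC_AB / expected|, undefined when the
  expectation is approximately zero (or the observed combined effect is
  exactly zero);
* a *synergy class*: additive when the interaction term is not significant,
  otherwise synergistic (score > 0) or antagonistic (score < 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

UP, DOWN, UNCHANGED = "Up", "Down", "Unchanged"
DIRECTIONS = (UP, DOWN, UNCHANGED)

CATEGORIES = (
    "co_dependent",
    "concordant",
    "discordant",
    "A_dominant",
    "B_dominant",
    "A_masked",
    "B_masked",
    "mutually_masked",
    "unclassified",
)


@dataclass(frozen=True)
class Thresholds:
    """Dual significance threshold for direction calls.

    ``min_abs_l2fc`` defaults to log2(1.5) rounded to 0.585, i.e. a 1.5-fold
    change; the boundary is inclusive.
    """

    alpha: float = 0.05
    min_abs_l2fc: float = 0.585

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_abs_l2fc < 0:
            raise ValueError("min_abs_l2fc must be nonnegative")


def call_direction(log2fc: float, padj: float, th: Thresholds = Thresholds()) -> str:
    """Up/Down/Unchanged call for one contrast; missing padj is Unchanged."""
    if padj is None or np.isnan(padj) or np.isnan(log2fc):
        return UNCHANGED
    if padj < th.alpha and log2fc >= th.min_abs_l2fc:
        return UP
    if padj < th.alpha and log2fc <= -th.min_abs_l2fc:
        return DOWN
    return UNCHANGED


def include_gene(dir_A: str, dir_B: str, dir_AB: str, dir_INT: str) -> bool:
    """A gene enters classification iff significant in at least one contrast."""
    return any(d != UNCHANGED for d in (dir_A, dir_B, dir_AB, dir_INT))


def _opposite(d: str) -> str:
    return {UP: DOWN, DOWN: UP}.get(d, UNCHANGED)


def classify_gene(dir_A: str, dir_B: str, dir_AB: str) -> tuple[str, str]:
    """(mode, category) from the three direction calls.

    Mode: cooperative iff the single exposures agree exactly (both Up, both
    Down, or both Unchanged); any mismatch — including one significant, one
    not — is competitive.

    Category decision tree:
      * combined significant, neither single significant  -> co_dependent
      * singles agree and combined follows them           -> concordant
      * singles agree and combined flips direction        -> discordant
      * singles differ, combined follows A (resp. B)      -> A_dominant (B_dominant)
      * combined not significant, one or both singles are -> A_masked / B_masked /
                                                             mutually_masked
      * anything else (e.g. combined opposite to the only
        significant single, or interaction-only genes)    -> unclassified

    The tree is total: every direction triple receives exactly one category.
    """
    for d in (dir_A, dir_B, dir_AB):
        if d not in DIRECTIONS:
            raise ValueError(f"invalid direction: {d!r}")
    mode = "cooperative" if dir_A == dir_B else "competitive"

    if dir_AB != UNCHANGED and dir_A == UNCHANGED and dir_B == UNCHANGED:
        return mode, "co_dependent"
    if dir_A == dir_B != UNCHANGED:
        if dir_AB == dir_A:
            return mode, "concordant"
        if dir_AB == _opposite(dir_A):
            return mode, "discordant"
        return mode, "mutually_masked"  # both singles significant, AB lost
    if mode == "competitive" and dir_AB != UNCHANGED:
        if dir_AB == dir_A != UNCHANGED:
            return mode, "A_dominant"
        if dir_AB == dir_B != UNCHANGED:
            return mode, "B_dominant"
        return mode, "unclassified"
    if dir_AB == UNCHANGED:
        a_sig, b_sig = dir_A != UNCHANGED, dir_B != UNCHANGED
        if a_sig and not b_sig:
            return mode, "A_masked"
        if b_sig and not a_sig:
            return mode, "B_masked"
        if a_sig and b_sig:
            return mode, "mutually_masked"
    return mode, "unclassified"


def synergy_score(l2fc_A: float, l2fc_B: float, l2fc_AB: float, zero_tol: float = 0.01):
    """log2 of |observed combined effect / expected additive effect|.

    The expected additive effect is l2fc_A + l2fc_B.  Returns NaN
    (undefined) when |expected| < ``zero_tol`` or the observed combined
    effect is exactly zero.
    """
    expected = l2fc_A + l2fc_B
    if abs(expected) < zero_tol or l2fc_AB == 0:
        return float("nan")
    return float(np.log2(abs(l2fc_AB / expected)))


def synergy_class(score: float, dir_INT: str) -> str:
    """additive / synergistic / antagonistic / undefined.

    Genes without a significant interaction term are additive regardless of
    score.  With a significant interaction, the sign of the synergy score
    decides; an exactly zero score means the observed combined effect equals
    the additive expectation, hence additive.
    """
    if dir_INT == UNCHANGED:
        return "additive"
    if score is None or np.isnan(score):
        return "undefined"
    if score > 0:
        return "synergistic"
    if score < 0:
        return "antagonistic"
    return "additive"


def classify_table(
    de: pd.DataFrame,
    th: Thresholds = Thresholds(),
    zero_tol: float = 0.01,
) -> pd.DataFrame:
    """Classify every included gene of a tidy DE table.

    ``de`` must contain all four contrasts (A, B, AB, INT) for each gene,
    with columns ``gene_id, contrast, log2fc, padj``.  Returns one row per
    included gene with direction calls, mode, category, expected additive
    effect, synergy score (NaN if undefined) and synergy class.  Genes with
    no significant contrast are omitted.
    """
    if len(de) == 0:
        return _empty_regulation_table()
    contrasts = ["A", "B", "AB", "INT"]
    present = de.assign(_one=1.0).pivot(index="gene_id", columns="contrast", values="_one")
    present = present.reindex(columns=contrasts)
    incomplete = present.isna().any(axis=1)
    if incomplete.any():
        gid = present.index[incomplete][0]
        raise ValueError(f"gene {gid} is missing a contrast")
    # NaN *values* in present rows (e.g. unconverged fits) are tolerated:
    # their direction calls are Unchanged, so fully failed genes drop out
    wide_fc = de.pivot(index="gene_id", columns="contrast", values="log2fc")[contrasts]
    wide_p = de.pivot(index="gene_id", columns="contrast", values="padj")[contrasts]

    rows = []
    for gid in wide_fc.index:
        fc = wide_fc.loc[gid]
        pa = wide_p.loc[gid]
        dirs = {c: call_direction(fc[c], pa[c], th) for c in ("A", "B", "AB", "INT")}
        if not include_gene(dirs["A"], dirs["B"], dirs["AB"], dirs["INT"]):
            continue
        mode, category = classify_gene(dirs["A"], dirs["B"], dirs["AB"])
        score = synergy_score(fc["A"], fc["B"], fc["AB"], zero_tol=zero_tol)
        rows.append(
            {
                "gene_id": gid,
                "dir_A": dirs["A"],
                "dir_B": dirs["B"],
                "dir_AB": dirs["AB"],
                "dir_INT": dirs["INT"],
                "mode": mode,
                "category": category,
                "expected_l2fc": float(fc["A"] + fc["B"]),
                "synergy_score": score,
                "synergy_class": synergy_class(score, dirs["INT"]),
            }
        )
    if not rows:
        return _empty_regulation_table()
    return pd.DataFrame(rows)


def _empty_regulation_table() -> pd.DataFrame:
    cols = [
        "gene_id",
        "dir_A",
        "dir_B",
        "dir_AB",
        "dir_INT",
        "mode",
        "category",
        "expected_l2fc",
        "synergy_score",
        "synergy_class",
    ]
    return pd.DataFrame(columns=cols)


def summarize_regulation(reg: pd.DataFrame) -> dict:
    """Category and synergy-class counts, split by combined-exposure direction.

    Mirrors stacked-fraction summaries of regulation modes: for each AB
    direction (Up / Down / Unchanged) the number of genes per category and
    per synergy class.
    """
    out: dict = {"n_genes": int(len(reg)), "by_AB_direction": {}}
    for d in DIRECTIONS:
        sub = reg[reg["dir_AB"] == d]
        out["by_AB_direction"][d] = {
            "n": int(len(sub)),
            "category": {k: int(v) for k, v in sub["category"].value_counts().items()},
            "synergy_class": {k: int(v) for k, v in sub["synergy_class"].value_counts().items()},
        }
    out["category"] = {k: int(v) for k, v in reg["category"].value_counts().items()}
    out["synergy_class"] = {k: int(v) for k, v in reg["synergy_class"].value_counts().items()}
    return out
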