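"""Cross-platform subfield comparisons and subfield-specific gene calling.

For each ordered region pair the two platforms' result tables are joined
gene-wise: a gene is *mutual* if detected on both platforms, *significant*
if BH-adjusted p < alpha on both, and *concordant* if additionally the two
platforms agree on the (nonzero) fold-change sign.  A gene is called
specific to region R when it is significant and direction-consistent
against BOTH other regions on BOTH platforms; its reported effect size is
the average of its two pairwise log2 fold changes, averaged within
platform first so each platform contributes equally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import REGIONS, PipelineError
from .behavior import pearson_r


@dataclass
class PairwiseConcordance:
    """Per-gene cross-platform flags for one region pair, plus counts."""

    region_pair: tuple[str, str]
    table: pd.DataFrame  # gene_id, log2fc_A, log2fc_B, adj_p_A, adj_p_B,
    #                      mutual, both_significant, concordant
    n_mutual: int
    n_both_significant: int
    n_concordant: int

    @property
    def n_discordant(self) -> int:
        return self.n_both_significant - self.n_concordant


def pairwise_concordance(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    region_pair: tuple[str, str],
    alpha: float = 0.05,
) -> PairwiseConcordance:
    """Join the two platforms' result tables for one region pair and count
    mutual / significant-both / concordant / discordant genes."""
    merged = results_a.merge(
        results_b, on="gene_id", how="outer", suffixes=("_A", "_B")
    )
    for col in ("detected_A", "detected_B"):
        merged[col] = merged[col].fillna(False).astype(bool)
    mutual = merged["detected_A"] & merged["detected_B"]
    both_sig = (
        mutual
        & (merged["p_adj_A"] < alpha).fillna(False)
        & (merged["p_adj_B"] < alpha).fillna(False)
    )
    concordant = (
        both_sig
        & (merged["log2fc_A"] * merged["log2fc_B"] > 0).fillna(False)
    )
    table = pd.DataFrame(
        {
            "gene_id": merged["gene_id"],
            "log2fc_A": merged["log2fc_A"],
            "log2fc_B": merged["log2fc_B"],
            "adj_p_A": merged["p_adj_A"],
            "adj_p_B": merged["p_adj_B"],
            "mutual": mutual,
            "both_significant": both_sig,
            "concordant": concordant,
        }
    )
    return PairwiseConcordance(
        region_pair=tuple(region_pair),
        table=table,
        n_mutual=int(mutual.sum()),
        n_both_significant=int(both_sig.sum()),
        n_concordant=int(concordant.sum()),
    )


def fc_cross_platform_r(
    results_a: pd.DataFrame, results_b: pd.DataFrame
) -> float:
    """Pearson correlation of log2 fold changes across platforms over
    mutually detected genes."""
    merged = results_a.merge(
        results_b, on="gene_id", how="inner", suffixes=("_A", "_B")
    )
    merged = merged[
        merged["detected_A"]
        & merged["detected_B"]
        & merged["log2fc_A"].notna()
        & merged["log2fc_B"].notna()
    ]
    if len(merged) < 3:
        raise PipelineError("cross-platform correlation needs >= 3 mutual genes")
    return pearson_r(merged["log2fc_A"], merged["log2fc_B"])


def call_subfield_specific(
    concordances: dict[tuple[str, str], PairwiseConcordance],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Subfield-specific gene calls from the three pairwise comparisons.

    For region R and gene g, the call requires BH-adjusted p < alpha in
    both comparisons involving R on both platforms, with all four fold
    changes placing R on the same side of both other regions.  Direction
    ``over``/``under`` means higher/lower in R; mixed directions yield no
    call.  A gene satisfying the criterion in two regions (e.g. highest in
    one and lowest in another with the third intermediate) is called in
    both and flagged ``multi_region``.

    The fold change reported per comparison is oriented *toward R* (sign
    flipped where R is the pair's reference level), and ``avg_log2fc``
    averages the two comparisons within each platform before averaging the
    two platforms.
    """
    if set(concordances) != {("CA1", "CA3"), ("CA1", "DG"), ("CA3", "DG")}:
        raise PipelineError("need all three region-pair concordance sets")
    indexed = {
        pair: pc.table.set_index("gene_id") for pair, pc in concordances.items()
    }
    rows = []
    for region in REGIONS:
        pairs = [p for p in indexed if region in p]
        t1, t2 = (indexed[p] for p in pairs)
        # orient log2fc so positive = higher in `region`
        sgn = [1.0 if p[1] == region else -1.0 for p in pairs]
        joined = t1.join(t2, how="inner", lsuffix="_p1", rsuffix="_p2")
        sig = np.ones(len(joined), dtype=bool)
        for suffix, s in (("_p1", sgn[0]), ("_p2", sgn[1])):
            sig &= (
                (joined[f"adj_p_A{suffix}"] < alpha)
                & (joined[f"adj_p_B{suffix}"] < alpha)
            ).fillna(False).to_numpy()
        fcs = {
            (platform, suffix): s * joined[f"log2fc_{platform}{suffix}"]
            for platform in ("A", "B")
            for suffix, s in (("_p1", sgn[0]), ("_p2", sgn[1]))
        }
        signs = np.stack([np.sign(v.to_numpy()) for v in fcs.values()])
        consistent = (np.abs(signs.sum(axis=0)) == 4) & sig
        avg_a = (fcs[("A", "_p1")] + fcs[("A", "_p2")]) / 2.0
        avg_b = (fcs[("B", "_p1")] + fcs[("B", "_p2")]) / 2.0
        avg = ((avg_a + avg_b) / 2.0).to_numpy()
        for gene, ok, fc in zip(joined.index, consistent, avg):
            if ok:
                rows.append(
                    (gene, region, "over" if fc > 0 else "under", float(fc))
                )
    calls = pd.DataFrame(
        rows, columns=["gene_id", "region", "direction", "avg_log2fc"]
    )
    calls["multi_region"] = calls["gene_id"].duplicated(keep=False)
    return calls.sort_values(["region", "gene_id"], kind="stable").reset_index(
        drop=True
    )


def fc_filter(calls: pd.DataFrame, threshold: float = 0.50) -> pd.DataFrame:
    """Keep calls with |avg_log2fc| strictly above ``threshold`` (the
    filter applied before over-representation analysis)."""
    return calls[calls["avg_log2fc"].abs() > threshold].reset_index(drop=True)
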