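"""Gene-set over-representation analysis against local GMT collections.

A hypergeometric (one-sided Fisher) test of a study gene list against a
background universe, replacing web-portal enrichment queries with a local,
reproducible equivalent.  The universe should be the genes actually
assayed (detected on both platforms for the relevant contrast), not a
whole-genome annotation.  Both Bonferroni and Benjamini-Hochberg adjusted
p-values are reported, matching the two correction styles in common use
by the ToppGene and DAVID portals respectively.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .core import ParseError, PipelineError
from .de import bh_adjust

RESULT_COLUMNS = ("set_name", "k", "K", "n", "N", "p", "p_bonf", "p_bh")


@dataclass
class GeneSet:
    name: str
    description: str
    genes: frozenset


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file (tab-separated: name, description, genes...).

    Gene identifiers are uppercased for case-insensitive matching.
    """
    sets: list[GeneSet] = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, description = parts[0], parts[1]
            if name in seen:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            seen.add(name)
            genes = frozenset(g.upper() for g in parts[2:] if g)
            if not genes:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets.append(GeneSet(name, description, genes))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.genes)]) + "\n")


def ora(study, universe, sets: list[GeneSet]) -> pd.DataFrame:
    """Over-representation of ``study`` genes in each gene set.

    With N = |universe|, K = |set ∩ universe|, n = |study| and k the
    observed overlap, p = P(X >= k) for X ~ Hypergeometric(N, K, n).
    Returns one row per set, sorted by p, with Bonferroni (over the tested
    sets) and BH adjustments.
    """
    study = {str(g).upper() for g in study}
    universe = {str(g).upper() for g in universe}
    if not study <= universe:
        extra = sorted(study - universe)
        raise PipelineError(
            f"study genes absent from universe: {extra[:5]}"
            + ("..." if len(extra) > 5 else "")
        )
    n_sets = len(sets)
    rows = []
    for gs in sets:
        members = {str(g).upper() for g in gs.genes} & universe
        k = len(study & members)
        K = len(members)
        n = len(study)
        N = len(universe)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((gs.name, k, K, n, N, min(p, 1.0)))
    result = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "p"])
    result["p_bonf"] = (result["p"] * n_sets).clip(upper=1.0)
    result["p_bh"] = bh_adjust(result["p"].to_numpy()) if n_sets else []
    return result.sort_values(["p", "set_name"], kind="stable").reset_index(drop=True)
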