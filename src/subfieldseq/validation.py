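"""Staged two-platform discovery/validation and the empirical FDR.

Discovery (platform A) produces a *seed list* of genes with two-tailed
p < seed_alpha; each seed gene fixes a fold-change direction.  Validation
(platform B) retests each seed gene one-tailed in that direction at
validate_alpha.  Under independent nulls the joint per-gene level is
seed_alpha * validate_alpha / 2 * 2 = seed_alpha * validate_alpha
(the halving of the one-tailed threshold cancels against the coin-flip
direction match), 0.0005 at the defaults.  The empirical FDR of a
validated list is n_seed * combined_alpha / n_validated — the expected
number of jointly-null survivors over the number actually validated.

The independence assumption is approximate when both platforms sequence
the same RNA; the formula is implemented as stated and the caveat is
documented rather than corrected for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PipelineError
from .de import one_tailed_p


@dataclass
class ValidationReport:
    """Outcome of one contrast's discovery/validation staging."""

    contrast_name: str
    n_seed: int
    n_validated: int
    validated: pd.DataFrame  # gene_id, log2fc_A, log2fc_B, p_one_B
    fdr: float | None
    combined_alpha: float

    def summary_line(self) -> str:
        fdr = "NA" if self.fdr is None else f"{self.fdr:.2g}"
        return (
            f"{self.contrast_name}\tn_seed={self.n_seed}\t"
            f"n_validated={self.n_validated}\tfdr={fdr}"
        )


def build_seed_list(results_a: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Seed list from the discovery platform: detected genes with
    two-tailed p < alpha and a nonzero fold change (which fixes the
    direction to be confirmed).  May be empty."""
    if not 0 < alpha < 1:
        raise PipelineError("seed alpha must be in (0, 1)")
    keep = (
        results_a["detected"]
        & results_a["p_two"].notna()
        & (results_a["p_two"] < alpha)
        & (results_a["log2fc"] != 0)
    )
    seed = results_a.loc[keep, ["gene_id", "log2fc", "p_two"]].reset_index(drop=True)
    return seed


def validate_seed(
    seed: pd.DataFrame,
    results_b: pd.DataFrame,
    alpha: float = 0.05,
    combined_alpha: float = 0.0005,
    contrast_name: str = "",
) -> ValidationReport:
    """Directional confirmation of a seed list on the validation platform.

    A seed gene validates iff it is detected on platform B and its
    one-tailed p-value in the seed-specified direction is below ``alpha``;
    seed genes undetected on B stay in ``n_seed`` but fail validation.
    """
    b = results_b.set_index("gene_id")
    rows = []
    for gene, lfc_a, _ in seed.itertuples(index=False):
        if gene not in b.index:
            continue
        rec = b.loc[gene]
        if not rec["detected"] or pd.isna(rec["p_two"]):
            continue
        p_one = one_tailed_p(rec["p_two"], rec["log2fc"], int(np.sign(lfc_a)))
        if p_one < alpha:
            rows.append((gene, lfc_a, rec["log2fc"], p_one))
    validated = pd.DataFrame(
        rows, columns=["gene_id", "log2fc_A", "log2fc_B", "p_one_B"]
    )
    n_seed = len(seed)
    n_validated = len(validated)
    fdr = (
        empirical_fdr(n_seed, n_validated, combined_alpha) if n_validated else None
    )
    return ValidationReport(
        contrast_name=contrast_name,
        n_seed=n_seed,
        n_validated=n_validated,
        validated=validated,
        fdr=fdr,
        combined_alpha=combined_alpha,
    )


def empirical_fdr(
    n_seed: int, n_validated: int, combined_alpha: float = 0.0005
) -> float:
    """Empirical false discovery rate of a validated list:
    n_seed * combined_alpha / n_validated."""
    if n_validated < 0 or n_seed < n_validated:
        raise PipelineError("need 0 <= n_validated <= n_seed")
    if n_validated == 0:
        raise PipelineError(
            "empirical FDR not computable with zero validated genes"
        )
    return n_seed * combined_alpha / n_validated


def null_calibration(
    n_genes: int,
    rng_seed: int,
    seed_alpha: float = 0.01,
    validate_alpha: float = 0.05,
) -> float:
    """Empirical joint pass rate of the staging under the global null.

    Simulates two independent null platforms — uniform two-sided p-values
    and independent random fold-change signs on each — applies the seed
    filter on A and the direction-matched one-tailed filter on B, and
    returns the fraction of genes surviving both stages.  At the defaults
    the analytic rate is seed_alpha * validate_alpha = 0.0005.
    """
    if n_genes <= 0:
        raise PipelineError("n_genes must be positive")
    rng = np.random.default_rng(rng_seed)
    p_a = rng.random(n_genes)
    sign_a = rng.choice((-1.0, 1.0), size=n_genes)
    p_b = rng.random(n_genes)
    sign_b = rng.choice((-1.0, 1.0), size=n_genes)

    seeded = p_a < seed_alpha
    # vectorised one_tailed_p on platform B in the A-specified direction
    p_one = np.where(sign_b == sign_a, p_b / 2.0, 1.0 - p_b / 2.0)
    passed = seeded & (p_one < validate_alpha)
    return passed.sum() / n_genes
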