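"""Synthetic two-platform study generator.

Emulates the study design downstream of alignment: one cohort of animals
(young, aged-unimpaired, aged-impaired), three dissected hippocampal
regions per animal, and the same underlying expression measured by two
sequencing platforms that differ in library size, extra technical
dispersion, and platform-specific detection dropout.  Counts are drawn
gene-wise from a negative binomial with mean

    mu_gs = s_sample * q_gene * 2 ** (sum of planted log2 effects)

and variance mu + alpha * mu**2.  Planted truth classes are disjoint:

* region-specific genes are shifted in one region in all animals,
* age genes are shifted in aged animals of every region, scaled by
  per-region weights (largest in DG by default) and predominantly
  up-regulated,
* cognition genes are shifted in aged-impaired animals of one region
  (CA1 by default).

Matching behavioral records are generated per animal: path lengths that
shorten over training blocks (more slowly for aged animals) and
probe-trial quadrant percentages drawn from a Dirichlet whose goal bias
depends on the animal's generative cognitive class, so that expected
discrimination indices order young ≈ AU > AI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import REGIONS, CountMatrix, PipelineError, validate_samplesheet
from .io import BEHAVIOR_COLUMNS


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated design: 10 young and 24 aged animals
    (split 12 unimpaired / 12 impaired), ~20k genes with log-normal
    baseline means and dispersions typical of bulk tissue RNA-seq, a
    1-log2-unit planted effect size, and a validation platform with ~70%
    of the discovery platform's depth plus extra technical dispersion.
    """

    n_genes: int = 20_000
    n_young: int = 10
    n_aged_unimpaired: int = 12
    n_aged_impaired: int = 12
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.5
    dispersion_log_mean: float = -2.5
    dispersion_log_sd: float = 0.6
    frac_region_specific: float = 0.10
    frac_age_de: float = 0.05
    frac_cognition_de: float = 0.05
    effect_size_log2: float = 1.0
    age_region_weights: dict = field(
        default_factory=lambda: {"CA1": 0.5, "CA3": 0.5, "DG": 1.0}
    )
    age_up_prob: float = 0.8
    cognition_region: str = "CA1"
    libsize_log_sd: float = 0.2
    platform_b_libsize_factor: float = 0.7
    platform_b_extra_dispersion: float = 0.05
    dropout_rate: float = 0.02
    sites: tuple = ("AZ", "FL")
    # behavior
    path_baseline: float = 9.0
    path_floor: float = 2.0
    path_noise_log_sd: float = 0.15
    learn_rate_young: float = 0.7
    learn_rate_aged: float = 0.35
    probe_conc_unimpaired: tuple = (20.0, 8.0, 8.0, 7.0)
    probe_conc_impaired: tuple = (12.0, 11.0, 11.0, 11.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.frac_region_specific,
            self.frac_age_de,
            self.frac_cognition_de,
        )
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1:
            raise PipelineError(
                "truth-class fractions must lie in [0,1] and sum to <= 1"
            )
        if self.platform_b_extra_dispersion < 0 or self.dropout_rate < 0:
            raise PipelineError("dispersion and dropout parameters must be >= 0")
        for name in ("n_young", "n_aged_unimpaired", "n_aged_impaired"):
            if getattr(self, name) < 2:
                raise PipelineError(
                    f"degenerate design: {name} must be >= 2 for contrasts"
                )
        if self.cognition_region not in REGIONS:
            raise PipelineError(f"unknown cognition_region {self.cognition_region!r}")


def _animal_table(config: SimConfig) -> pd.DataFrame:
    rows = []
    groups = (
        ("Y", "young", "young", config.n_young),
        ("AU", "aged", "AU", config.n_aged_unimpaired),
        ("AI", "aged", "AI", config.n_aged_impaired),
    )
    i = 0
    for prefix, age, klass, n in groups:
        for k in range(1, n + 1):
            rows.append(
                (f"{prefix}{k:02d}", age, klass, config.sites[i % len(config.sites)])
            )
            i += 1
    return pd.DataFrame(
        rows, columns=["animal_id", "age_group", "cognitive_class", "site"]
    )


def _truth_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_genes
    gene_ids = [f"gene{k:05d}" for k in range(1, n + 1)]
    n_rs = int(round(config.frac_region_specific * n))
    n_age = int(round(config.frac_age_de * n))
    n_cog = int(round(config.frac_cognition_de * n))
    klass = np.array(["null"] * n, dtype=object)
    order = rng.permutation(n)
    rs_idx = order[:n_rs]
    age_idx = order[n_rs : n_rs + n_age]
    cog_idx = order[n_rs + n_age : n_rs + n_age + n_cog]
    klass[rs_idx] = "region_specific"
    klass[age_idx] = "age_de"
    klass[cog_idx] = "cognition_de"

    region = np.array([""] * n, dtype=object)
    region[rs_idx] = rng.choice(REGIONS, size=n_rs)
    region[cog_idx] = config.cognition_region

    direction = np.zeros(n)
    direction[rs_idx] = rng.choice((-1.0, 1.0), size=n_rs)
    direction[age_idx] = np.where(
        rng.random(n_age) < config.age_up_prob, 1.0, -1.0
    )
    direction[cog_idx] = rng.choice((-1.0, 1.0), size=n_cog)

    delta = config.effect_size_log2
    truth = pd.DataFrame({"gene_id": gene_ids, "class": klass})
    truth["target_region"] = region
    truth["direction"] = direction
    for r in REGIONS:
        lfc_age = np.zeros(n)
        lfc_age[age_idx] = (
            direction[age_idx] * delta * config.age_region_weights[r]
        )
        truth[f"true_lfc_age_{r}"] = lfc_age
        lfc_cog = np.zeros(n)
        if r == config.cognition_region:
            lfc_cog[cog_idx] = direction[cog_idx] * delta
        truth[f"true_lfc_cognition_{r}"] = lfc_cog
        lfc_region = np.zeros(n)
        lfc_region[rs_idx] = np.where(
            region[rs_idx] == r, direction[rs_idx] * delta, 0.0
        )
        truth[f"true_lfc_region_{r}"] = lfc_region
    return truth


def simulate_counts(
    config: SimConfig,
) -> tuple[CountMatrix, CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Draw the two platforms' count matrices, the sample sheet, and the
    ground-truth table.  Fully reproducible under ``config.rng_seed``."""
    rng = np.random.default_rng(config.rng_seed)
    animals = _animal_table(config)
    truth = _truth_table(config, rng)
    n = config.n_genes

    q = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n))
    alpha = np.exp(
        rng.normal(config.dispersion_log_mean, config.dispersion_log_sd, size=n)
    )

    samples = animals.merge(pd.DataFrame({"region": REGIONS}), how="cross")
    delta = config.effect_size_log2
    direction = truth["direction"].to_numpy()
    is_rs = (truth["class"] == "region_specific").to_numpy()
    is_age = (truth["class"] == "age_de").to_numpy()
    is_cog = (truth["class"] == "cognition_de").to_numpy()
    target = truth["target_region"].to_numpy()

    # genes x samples matrix of planted log2 effects
    effects = np.zeros((n, len(samples)))
    for j, row in samples.iterrows():
        e = np.zeros(n)
        e += np.where(is_rs & (target == row.region), direction * delta, 0.0)
        if row.age_group == "aged":
            e += np.where(
                is_age,
                direction * delta * config.age_region_weights[row.region],
                0.0,
            )
        if row.cognitive_class == "AI" and row.region == config.cognition_region:
            e += np.where(is_cog, direction * delta, 0.0)
        effects[:, j] = e
    base_mu = q[:, None] * np.exp2(effects)

    dropout_platform = np.array(["none"] * n, dtype=object)
    drop = rng.random(n) < config.dropout_rate
    dropout_platform[drop] = rng.choice(("A", "B"), size=int(drop.sum()))
    truth["dropout_platform"] = dropout_platform

    matrices = {}
    sheets = []
    for platform in ("A", "B"):
        libsize = np.exp(rng.normal(0.0, config.libsize_log_sd, size=len(samples)))
        if platform == "B":
            libsize = libsize * config.platform_b_libsize_factor
        disp = alpha + (
            config.platform_b_extra_dispersion if platform == "B" else 0.0
        )
        mu = base_mu * libsize[None, :]
        counts = _nb_draw(rng, mu, disp[:, None])
        counts[dropout_platform == platform, :] = 0
        sample_ids = [
            f"{a}_{r}_{platform}"
            for a, r in zip(samples["animal_id"], samples["region"])
        ]
        matrices[platform] = CountMatrix(
            pd.DataFrame(
                counts,
                index=pd.Index(truth["gene_id"], name="gene_id"),
                columns=sample_ids,
            ),
            platform,
        )
        sheet = samples.copy()
        sheet.insert(0, "sample_id", sample_ids)
        sheet["platform"] = platform
        sheets.append(sheet)
    sheet = pd.concat(sheets, ignore_index=True)[
        [
            "sample_id",
            "animal_id",
            "region",
            "age_group",
            "cognitive_class",
            "platform",
            "site",
        ]
    ]
    return matrices["A"], matrices["B"], validate_samplesheet(sheet), truth


def _nb_draw(
    rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray
) -> np.ndarray:
    """NB(mu, alpha) draws with variance mu + alpha mu^2; alpha -> 0 is
    the Poisson limit (used directly below 1e-12 for numerical safety)."""
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    poisson = alpha < 1e-12
    if poisson.any():
        out[poisson] = rng.poisson(mu[poisson])
    nb = ~poisson
    if nb.any():
        size = 1.0 / alpha[nb]
        p = size / (size + mu[nb])
        out[nb] = rng.negative_binomial(size, p)
    return out


def simulate_behavior(config: SimConfig, sheet: pd.DataFrame) -> pd.DataFrame:
    """Per-animal water-maze records matching the cohort in ``sheet``.

    Path lengths decay exponentially over the five training blocks toward
    a floor, with aged animals learning more slowly; probe-trial quadrant
    percentages (goal, left, right, opposite) are Dirichlet draws whose
    goal concentration depends on the generative cognitive class, so the
    expected DI of impaired animals falls below the young minimum.

    A distinct stream of the configured seed is used, so behavior is
    reproducible independently of whether counts were drawn first.
    """
    animals = (
        sheet[["animal_id", "age_group", "cognitive_class"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    if not (animals["age_group"] == "young").any():
        raise PipelineError("sheet contains no young animals")
    rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed).spawn(1)[0])
    rows = []
    blocks = np.arange(5)
    for _, a in animals.iterrows():
        rate = (
            config.learn_rate_young
            if a.age_group == "young"
            else config.learn_rate_aged
        )
        record = [a.animal_id, a.age_group]
        for _task in ("cue", "spatial"):
            mean_path = config.path_floor + (
                config.path_baseline - config.path_floor
            ) * np.exp(-rate * blocks)
            noise = np.exp(rng.normal(0.0, config.path_noise_log_sd, size=5))
            record.extend(np.round(mean_path * noise, 3))
        conc = (
            config.probe_conc_impaired
            if a.cognitive_class == "AI"
            else config.probe_conc_unimpaired
        )
        quadrants = rng.dirichlet(conc) * 100.0
        record.extend(np.round((quadrants[0], quadrants[3]), 3))
        rows.append(record)
    return pd.DataFrame(rows, columns=BEHAVIOR_COLUMNS)
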