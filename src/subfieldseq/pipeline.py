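"""Stage orchestration: simulate -> behavior -> de -> validate ->
subfields -> enrich.

Each stage reads its inputs from the run directory (or from the paths in
the config) and writes fixed-column TSV outputs there, so stages can be
run individually from the command line or chained with ``run_all``.
Every source of randomness derives from ``RunConfig.rng_seed``, making a
full run byte-reproducible.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import pandas as pd

from .behavior import classify_animals, mean_split
from .core import REGION_PAIRS, REGIONS, Contrast, CountMatrix, PipelineError
from .de import nb_wald_test
from .enrichment import ora, read_gmt
from .io import (
    RunConfig,
    read_behavior,
    read_counts,
    read_samplesheet,
    read_table,
    write_behavior,
    write_counts,
    write_samplesheet,
    write_table,
)
from .simulate import SimConfig, simulate_behavior, simulate_counts
from .subfields import (
    call_subfield_specific,
    fc_cross_platform_r,
    fc_filter,
    pairwise_concordance,
)
from .validation import build_seed_list, validate_seed

logger = logging.getLogger(__name__)


def _timed(stage):
    def wrap(fn):
        def inner(self, *args, **kwargs):
            t0 = time.perf_counter()
            out = fn(self, *args, **kwargs)
            logger.info("stage %s finished in %.2fs", stage, time.perf_counter() - t0)
            return out

        return inner

    return wrap


def region_pair_contrast(r1: str, r2: str) -> Contrast:
    """Subfield contrast oriented r2 vs r1 (positive log2FC = higher in r2)."""
    return Contrast("region", r1, r2)


def age_contrast(region: str) -> Contrast:
    return Contrast("age_group", "young", "aged", subset={"region": region})


def cognition_contrast(region: str) -> Contrast:
    return Contrast(
        "cognitive_class", "AU", "AI", subset={"region": region, "age_group": "aged"}
    )


def cue_split_contrast(region: str) -> Contrast:
    return Contrast(
        "cue_split", "good", "poor", subset={"region": region, "age_group": "aged"}
    )


class Pipeline:
    """Runs the staged analysis for one :class:`RunConfig`."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)

    # ---------------- input resolution -----------------

    def _path(self, configured: str | None, default_name: str) -> Path:
        if configured:
            return Path(configured)
        return self.outdir / default_name

    def _load_counts(self, platform: str) -> CountMatrix:
        configured = self.config.counts_a if platform == "A" else self.config.counts_b
        path = self._path(configured, f"counts_{platform}.tsv")
        if not path.exists():
            raise PipelineError(
                f"counts for platform {platform} not found at {path}; "
                "run `simulate` or point the config at real counts"
            )
        return read_counts(path, platform)

    def _load_sheet(self, classified: bool = True) -> pd.DataFrame:
        """Sample sheet, preferring the behavior-classified version when the
        behavior stage has run."""
        classified_path = self.outdir / "samplesheet_classified.csv"
        if classified and classified_path.exists():
            return read_samplesheet(classified_path)
        path = self._path(self.config.samplesheet, "samplesheet.csv")
        if not path.exists():
            raise PipelineError(f"sample sheet not found at {path}")
        return read_samplesheet(path)

    def _load_behavior(self) -> pd.DataFrame:
        path = self._path(self.config.behavior, "behavior.csv")
        if not path.exists():
            raise PipelineError(f"behavior records not found at {path}")
        return read_behavior(path)

    # ---------------- stages -----------------

    @_timed("simulate")
    def simulate(self) -> None:
        sim = SimConfig(**{"rng_seed": self.config.rng_seed, **self.config.simulate})
        counts_a, counts_b, sheet, truth = simulate_counts(sim)
        behavior = simulate_behavior(sim, sheet)
        write_counts(counts_a, self.outdir / "counts_A.tsv")
        write_counts(counts_b, self.outdir / "counts_B.tsv")
        write_samplesheet(sheet, self.outdir / "samplesheet.csv")
        write_table(truth, self.outdir / "truth.tsv")
        write_behavior(behavior, self.outdir / "behavior.csv")
        logger.info(
            "simulated %d genes x %d samples per platform, %d animals",
            counts_a.shape[0],
            counts_a.shape[1],
            behavior.shape[0],
        )

    @_timed("behavior")
    def behavior(self) -> None:
        records = self._load_behavior()
        classification = classify_animals(records)
        write_table(classification, self.outdir / "classification.tsv")

        # carry the observed classes (and the cue-task mean split among aged
        # animals) onto the sample sheet used by the DE contrasts
        sheet = self._load_sheet(classified=False)
        observed = classification.set_index("animal_id")["cognitive_class"]
        sheet = sheet.copy()
        sheet["cognitive_class"] = (
            sheet["animal_id"].map(observed).fillna("unassigned")
        )
        aged = records[records["age_group"] == "aged"].set_index("animal_id")
        if len(aged) >= 2:
            split = mean_split(aged["cue_block5"])
            sheet["cue_split"] = sheet["animal_id"].map(split).fillna("")
        else:
            sheet["cue_split"] = ""
        write_samplesheet(sheet, self.outdir / "samplesheet_classified.csv")
        n_ai = int((classification["cognitive_class"] == "AI").sum())
        n_au = int((classification["cognitive_class"] == "AU").sum())
        logger.info(
            "classified %d animals (cutoff %.3f): %d AI, %d AU",
            len(classification),
            classification["cutoff"].iloc[0],
            n_ai,
            n_au,
        )

    def _contrasts(self, sheet: pd.DataFrame) -> list[Contrast]:
        contrasts = [region_pair_contrast(r1, r2) for r1, r2 in REGION_PAIRS]
        contrasts += [age_contrast(r) for r in REGIONS]
        if {"AU", "AI"} <= set(sheet["cognitive_class"]):
            contrasts += [cognition_contrast(r) for r in REGIONS]
        if "cue_split" in sheet.columns and {"good", "poor"} <= set(
            sheet["cue_split"]
        ):
            contrasts += [cue_split_contrast(r) for r in REGIONS]
        return contrasts

    @_timed("de")
    def de(self) -> None:
        sheet = self._load_sheet()
        counts = {p: self._load_counts(p) for p in ("A", "B")}
        for contrast in self._contrasts(sheet):
            for platform, cm in counts.items():
                result = nb_wald_test(
                    cm, sheet, contrast, self.config.min_detect_samples
                )
                write_table(
                    result,
                    self.outdir / f"de_{contrast.name}_{platform}.tsv",
                    comment=(
                        f"contrast {contrast.factor}: {contrast.level2} vs "
                        f"{contrast.level1}; positive log2fc = higher in "
                        f"{contrast.level2}; platform {platform}"
                    ),
                )
                logger.info(
                    "DE %s platform %s: %d genes, %d detected",
                    contrast.name,
                    platform,
                    len(result),
                    int(result["detected"].sum()),
                )

    def _de_table(self, contrast: Contrast, platform: str) -> pd.DataFrame:
        path = self.outdir / f"de_{contrast.name}_{platform}.tsv"
        if not path.exists():
            raise PipelineError(f"missing DE table {path}; run the `de` stage first")
        return read_table(path)

    @_timed("validate")
    def validate(self) -> list:
        sheet = self._load_sheet()
        staged = [c for c in self._contrasts(sheet) if c.factor != "region"]
        reports = []
        for contrast in staged:
            seed = build_seed_list(
                self._de_table(contrast, "A"), self.config.seed_alpha
            )
            report = validate_seed(
                seed,
                self._de_table(contrast, "B"),
                self.config.validate_alpha,
                self.config.combined_alpha,
                contrast_name=contrast.name,
            )
            write_table(
                report.validated, self.outdir / f"validated_{contrast.name}.tsv"
            )
            reports.append(report)
            logger.info(report.summary_line())
        summary = pd.DataFrame(
            {
                "contrast": [r.contrast_name for r in reports],
                "n_seed": [r.n_seed for r in reports],
                "n_validated": [r.n_validated for r in reports],
                "fdr": [r.fdr for r in reports],
            }
        )
        write_table(summary, self.outdir / "validation_summary.tsv")
        return reports

    @_timed("subfields")
    def subfields(self) -> pd.DataFrame:
        concordances = {}
        summary_rows = []
        for r1, r2 in REGION_PAIRS:
            contrast = region_pair_contrast(r1, r2)
            results_a = self._de_table(contrast, "A")
            results_b = self._de_table(contrast, "B")
            pc = pairwise_concordance(
                results_a, results_b, (r1, r2), self.config.subfield_alpha
            )
            concordances[(r1, r2)] = pc
            r = fc_cross_platform_r(results_a, results_b)
            summary_rows.append(
                (
                    f"{r1}_vs_{r2}",
                    pc.n_mutual,
                    pc.n_both_significant,
                    pc.n_concordant,
                    pc.n_discordant,
                    r,
                )
            )
        summary = pd.DataFrame(
            summary_rows,
            columns=[
                "region_pair",
                "n_mutual",
                "n_both_significant",
                "n_concordant",
                "n_discordant",
                "fc_pearson_r",
            ],
        )
        write_table(summary, self.outdir / "pairwise_summary.tsv")
        calls = call_subfield_specific(concordances, self.config.subfield_alpha)
        write_table(calls, self.outdir / "subfield_calls.tsv")
        filtered = fc_filter(calls, self.config.fc_filter)
        write_table(filtered, self.outdir / "subfield_calls_fc_filtered.tsv")
        for region in REGIONS:
            logger.info(
                "subfield %s: %d specific genes (%d past |log2FC| > %.2f)",
                region,
                int((calls["region"] == region).sum()),
                int((filtered["region"] == region).sum()),
                self.config.fc_filter,
            )
        self._concordances = concordances
        return calls

    @_timed("enrich")
    def enrich(self) -> None:
        if not self.config.gmt:
            raise PipelineError("enrichment requested but no GMT file configured")
        gmt_path = Path(self.config.gmt)
        if not gmt_path.exists():
            raise PipelineError(f"GMT file not found: {gmt_path}")
        sets = read_gmt(gmt_path)

        calls_path = self.outdir / "subfield_calls_fc_filtered.tsv"
        if not calls_path.exists():
            raise PipelineError(
                "enrichment needs subfield calls; run the `subfields` stage first"
            )
        calls = read_table(calls_path)
        universe = self._mutual_universe()
        for region in REGIONS:
            study = set(calls.loc[calls["region"] == region, "gene_id"])
            study &= universe
            if not study:
                logger.info("enrichment %s: empty study list, skipped", region)
                continue
            result = ora(study, universe, sets)
            write_table(result, self.outdir / f"enrichment_{region}.tsv")
            n_sig = int((result["p_bonf"] < 0.05).sum())
            logger.info(
                "enrichment %s: %d/%d sets Bonferroni-significant",
                region,
                n_sig,
                len(result),
            )

    def _mutual_universe(self) -> set:
        """Genes detected on both platforms in every pairwise subfield
        comparison — the assayed background for enrichment."""
        universe: set | None = None
        for r1, r2 in REGION_PAIRS:
            contrast = region_pair_contrast(r1, r2)
            merged = self._de_table(contrast, "A").merge(
                self._de_table(contrast, "B"), on="gene_id", suffixes=("_A", "_B")
            )
            mutual = set(
                merged.loc[merged["detected_A"] & merged["detected_B"], "gene_id"]
            )
            universe = mutual if universe is None else universe & mutual
        return universe or set()


def run_all(config: RunConfig, simulate: bool = True) -> Pipeline:
    """Run every stage in order; with ``simulate=False`` the configured
    input paths must point at existing counts/sheet/behavior files."""
    pipe = Pipeline(config)
    if simulate:
        pipe.simulate()
    pipe.behavior()
    pipe.de()
    pipe.validate()
    pipe.subfields()
    if config.gmt:
        pipe.enrich()
    return pipe
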