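"""End-to-end orchestration of the barcode-evaluation workflow.

curate -> annotate/excise -> pairwise distances -> divergence summaries
(+ paired locus comparison) -> identification reports.

Runs are driven by a declarative :class:`PipelineConfig`, write every
intermediate as TSV/FASTA under an output directory, and record a
manifest with a hash of the resolved configuration; re-running with the
same config and seed reproduces all outputs byte-identically.

In BOTH mode the full-length ITS locus and the excised ITS2 minibarcode
are analysed side by side on the matched record set, reproducing the
two-locus contrast.  The "ITS" locus is taken as everything up to the
start of the 28S flank placement (the leading 18S tail, when present, is
conserved and is not trimmed; only the 5.8S placement delimits regions).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from . import __version__
from .annotation import (
    AnnotationStatus,
    MotifProfile,
    _revcomp,
    annotate_corpus,
    default_profiles,
    write_annotation_table,
)
from .distance import DistanceMatrix, DistanceModel, distance_matrices
from .divergence import (
    DivergenceSummary,
    MeanSD,
    PairClass,
    WilcoxonResult,
    compare_loci,
    divergence_summary,
)
from .identification import (
    Criterion,
    IdentificationReport,
    Rank,
    identify_corpus,
    local_score_matrix,
    per_genus_report,
    write_outcomes_tsv,
    write_reports_tsv,
)
from .seq_model import Corpus, Region, curate, read_corpus, write_corpus
from .synthetic import SimulationConfig, simulate_corpus

__all__ = [
    "RegionMode",
    "PipelineConfig",
    "PipelineError",
    "LocusResult",
    "RunResult",
    "run_pipeline",
    "compare_regions_report",
]

logger = logging.getLogger("its2barcode")


class RegionMode(str, Enum):
    FULL_ITS = "FULL_ITS"
    ITS2 = "ITS2"
    BOTH = "BOTH"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative description of one evaluation run."""

    out_dir: str
    # either a simulation config or FASTA + taxonomy paths
    simulation: SimulationConfig | None = None
    input_fasta: str | None = None
    input_taxonomy: str | None = None
    input_region: Region = Region.ITS_FULL
    region_mode: RegionMode = RegionMode.BOTH
    min_length_bp: int = 100
    distance_model: DistanceModel = DistanceModel.K2P
    criteria: tuple[Criterion, ...] = (
        Criterion.BEST_HIT,
        Criterion.BEST_MATCH,
        Criterion.BEST_CLOSE_MATCH,
    )
    threshold: float = 0.03
    per_genus_min_species: int = 20
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")
        if self.simulation is None and not (
            self.input_fasta and self.input_taxonomy
        ):
            raise ValueError(
                "config needs either a simulation block or input paths"
            )
        if (
            self.region_mode in (RegionMode.BOTH, RegionMode.FULL_ITS)
            and self.simulation is None
            and self.input_region is Region.ITS2
        ):
            raise ValueError(
                f"{self.region_mode.value} mode requires full-length input"
            )

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, val in list(d.items()):
            if isinstance(val, Enum):
                d[key] = val.value
        d["criteria"] = [c.value for c in self.criteria]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            sim = dict(d["simulation"])
            for key in ("species_per_genus", "samples_per_species",
                        "len_its1", "len_5_8s", "len_its2", "len_flank"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            d["simulation"] = SimulationConfig(**sim)
        if "input_region" in d:
            d["input_region"] = Region(d["input_region"])
        if "region_mode" in d:
            d["region_mode"] = RegionMode(d["region_mode"])
        if "distance_model" in d:
            d["distance_model"] = DistanceModel(d["distance_model"])
        if "criteria" in d:
            d["criteria"] = tuple(Criterion(c) for c in d["criteria"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        """Hash of the scientific configuration.

        Output location and log level do not affect results and are
        excluded, so runs into different directories compare equal.
        """
        d = self.to_dict()
        d.pop("out_dir")
        d.pop("log_level")
        canon = json.dumps(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class LocusResult:
    """Everything computed for one locus (region) run."""

    region: str
    corpus: Corpus
    dm: DistanceMatrix
    dm_ident: DistanceMatrix
    divergence: DivergenceSummary
    reports: list[IdentificationReport]
    per_genus: list[dict]


@dataclass
class RunResult:
    config: PipelineConfig
    manifest: dict
    loci: dict[str, LocusResult]
    wilcoxon: dict[PairClass, WilcoxonResult] = field(default_factory=dict)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@_stage("identify")
def _identify_locus(
    config: PipelineConfig, region: str, corpus: Corpus,
    dm_ident: DistanceMatrix, out: Path,
) -> tuple[list[IdentificationReport], list[dict]]:
    reports: list[IdentificationReport] = []
    species_outcomes = None
    scores = (
        local_score_matrix(corpus)
        if Criterion.BEST_HIT in config.criteria else None
    )
    for criterion in config.criteria:
        for rank in (Rank.SPECIES, Rank.GENUS):
            report, outcomes = identify_corpus(
                corpus, criterion, rank,
                dm=dm_ident, scores=scores, threshold=config.threshold,
            )
            reports.append(report)
            write_outcomes_tsv(
                outcomes,
                out / f"outcomes_{criterion.value}_{rank.value}.tsv",
            )
            logger.info(
                "%s %s/%s: correct %.2f%%, ambiguous %.2f%%, "
                "incorrect %.2f%%, no-match %.2f%% (n=%d)",
                region, criterion.value, rank.value,
                report.pct_correct, report.pct_ambiguous,
                report.pct_incorrect, report.pct_no_match, report.n_queries,
            )
            if (criterion, rank) == (config.criteria[0], Rank.SPECIES):
                species_outcomes = outcomes
    write_reports_tsv(reports, out / "identification_reports.tsv")
    if species_outcomes is None:
        return reports, []
    genus_rows = per_genus_report(
        species_outcomes, corpus, config.per_genus_min_species
    )
    with open(out / "per_genus.tsv", "w") as fh:
        fh.write("genus\tn_species\tn_samples\tpct_unidentified\n")
        for row in genus_rows:
            fh.write(
                f"{row['genus']}\t{row['n_species']}\t{row['n_samples']}\t"
                f"{row['pct_unidentified']:.2f}\n"
            )
    return reports, genus_rows


def _run_locus(
    config: PipelineConfig, region: str, corpus: Corpus, out_dir: Path
) -> LocusResult:
    out = out_dir / region
    out.mkdir(parents=True, exist_ok=True)
    write_corpus(corpus, out / "corpus.fasta", out / "taxonomy.tsv")

    logger.info("[%s] computing %s distance matrix over %d records",
                region, config.distance_model.value, len(corpus))
    models = {config.distance_model, DistanceModel.P_DIST}
    dms = _stage("distances")(distance_matrices)(corpus, sorted(models))
    dm = dms[config.distance_model]
    dm_ident = dms[DistanceModel.P_DIST]
    for model, matrix in sorted(dms.items()):
        matrix.write_tsv(out / f"distances_{model.value}.tsv")
    if dm.n_nan:
        logger.info("[%s] %d undefined distances excluded", region, dm.n_nan)

    div = _stage("divergence")(divergence_summary)(dm, corpus)
    div.write_tsv(out / "divergence.tsv")
    logger.info("[%s] avg_intra_avg=%.4f avg_interbyG_avg=%.4f",
                region, div.avg_intra_avg.mean, div.avg_interbyG_avg.mean)

    reports, genus_rows = _identify_locus(config, region, corpus, dm_ident, out)
    return LocusResult(region, corpus, dm, dm_ident, div, reports, genus_rows)


def run_pipeline(
    config: PipelineConfig,
    profiles: tuple[MotifProfile, MotifProfile] | None = None,
) -> RunResult:
    """Execute the full workflow described by ``config``."""
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "resolved_config.json").write_text(
        json.dumps(config.to_dict(), sort_keys=True, indent=2) + "\n"
    )
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
        "complete": False,
    }

    # -- input ---------------------------------------------------------------
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        corpus, truth = _stage("simulate")(simulate_corpus)(sim)
        write_corpus(corpus, out_dir / "corpus.fasta", out_dir / "taxonomy.tsv")
        truth.write_tsv(out_dir / "truth.tsv")
    else:
        corpus = _stage("read")(read_corpus)(
            config.input_fasta, config.input_taxonomy, config.input_region
        )
    manifest["stages"]["input"] = {"n_records": len(corpus)}
    logger.info("input: %d records, %d species, %d genera",
                len(corpus), corpus.n_species, corpus.n_genera)

    # -- curation ------------------------------------------------------------
    corpus, report = _stage("curate")(curate)(corpus, config.min_length_bp)
    (out_dir / "curation_report.tsv").write_text(report.to_tsv())
    manifest["stages"]["curate"] = {
        "n_kept": report.n_kept,
        "n_removed_short": report.n_removed_short,
        "n_removed_unlabelled": report.n_removed_unlabelled,
    }
    logger.info("curation: kept %d / %d", report.n_kept, report.n_input)

    # -- annotation / excision -----------------------------------------------
    need_annotation = config.region_mode in (RegionMode.BOTH, RegionMode.ITS2)
    input_is_full = (
        config.simulation is not None
        or config.input_region is not Region.ITS2
    )
    its2_corpus = None
    if input_is_full:
        if profiles is None:
            profiles = default_profiles()
        its2_corpus, annotations = _stage("annotate")(annotate_corpus)(
            corpus, *profiles
        )
        write_annotation_table(annotations, out_dir / "annotation.tsv")
        n_fail = sum(
            a.status in (AnnotationStatus.NO_5_8S, AnnotationStatus.NO_FLANK)
            for a in annotations
        )
        manifest["stages"]["annotate"] = {
            "n_in": len(corpus), "n_excised": len(its2_corpus),
            "n_failed": n_fail,
        }
        logger.info("annotation: excised ITS2 for %d / %d records",
                    len(its2_corpus), len(corpus))
        if len(its2_corpus) == 0:
            raise PipelineError(
                "stage 'annotate' failed: no record carries the 5.8S motif "
                "— input may already be excised ITS2 or reversed; "
                "check the annotation table"
            )
        # the "ITS" locus: strip the trailing 28S flank where it was found
        by_id = {a.record_id: a for a in annotations}

        def trim_full(rec):
            ann = by_id[rec.record_id]
            if ann.its2 is None:
                return rec.sequence
            seq = rec.sequence
            if ann.flipped:
                seq = _revcomp(seq)
            return seq[: ann.its2[1]]

        full_corpus = corpus.subset(its2_corpus.record_ids).map_sequences(
            trim_full, region=Region.ITS_FULL
        )
    else:
        its2_corpus = corpus
        full_corpus = None

    # -- per-locus analyses ----------------------------------------------------
    loci: dict[str, LocusResult] = {}
    if config.region_mode in (RegionMode.BOTH, RegionMode.FULL_ITS):
        loci["ITS"] = _run_locus(config, "ITS", full_corpus, out_dir)
    if need_annotation:
        loci["ITS2"] = _run_locus(config, "ITS2", its2_corpus, out_dir)

    # -- locus comparison ------------------------------------------------------
    wilcoxon: dict[PairClass, WilcoxonResult] = {}
    if config.region_mode is RegionMode.BOTH:
        wilcoxon = _stage("compare")(compare_loci)(
            loci["ITS"].dm, loci["ITS2"].dm, loci["ITS2"].corpus
        )
        with open(out_dir / "wilcoxon.tsv", "w") as fh:
            fh.write("divergence\tw_plus\tw_minus\tn\tp_value\tresult\n")
            for kind, res in wilcoxon.items():
                verdict = {
                    "B_GT_A": "ITS2 > ITS",
                    "A_GT_B": "ITS > ITS2",
                    "NONE": "no difference",
                }[res.direction.value]
                fh.write(
                    f"{kind.value}\t{res.w_plus}\t{res.w_minus}\t{res.n}\t"
                    f"{res.p_value:.6g}\t{verdict}\n"
                )
        (out_dir / "comparison.tsv").write_text(
            compare_regions_report(loci["ITS"], loci["ITS2"], wilcoxon)
        )

    manifest["complete"] = True
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2) + "\n"
    )
    return RunResult(config, manifest, loci, wilcoxon)


def compare_regions_report(
    full_its: LocusResult,
    its2: LocusResult,
    wilcoxon: dict[PairClass, WilcoxonResult],
) -> str:
    """One table juxtaposing the two loci, mirroring the published layout."""
    if set(full_its.corpus.record_ids) != set(its2.corpus.record_ids):
        raise ValueError("locus runs cover different record sets")
    lines = ["section\tparameter\tITS\tITS2"]
    for name in DivergenceSummary.ROW_ORDER:
        a: MeanSD = getattr(full_its.divergence, name)
        b = getattr(its2.divergence, name)
        lines.append(f"divergence\t{name}\t{a}\t{b}")
    for kind, res in wilcoxon.items():
        verdict = {
            "B_GT_A": "ITS2 > ITS",
            "A_GT_B": "ITS > ITS2",
            "NONE": "no difference",
        }[res.direction.value]
        lines.append(
            f"wilcoxon\t{kind.value.lower()}\t"
            f"W+={res.w_plus:.1f}, W-={res.w_minus:.1f}, "
            f"n={res.n}, P={res.p_value:.3g}\t{verdict}"
        )
    its2_by_key = {(r.criterion, r.rank): r for r in its2.reports}
    for r in full_its.reports:
        other = its2_by_key.get((r.criterion, r.rank))
        if other is None:
            continue
        lines.append(
            f"identification\t{r.criterion.value}_{r.rank.value}"
            f"_pct_correct\t{r.pct_correct:.2f}\t{other.pct_correct:.2f}"
        )
    return "\n".join(lines) + "\n"
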