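"""End-to-end orchestration: counts -> guide stats -> gene stats -> hits + QC.

The pipeline is deterministic for fixed inputs and configuration; every
run writes the output tables, a text log, and a JSON manifest recording
the configuration, a config hash, input checksums and package version, so
a run is reproducible from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .library import GuideLibrary, count_spacers, read_counts, read_library, write_counts
from .qc import format_qc_summary, qc_table, representation_stats
from .rsa import HitThresholds, build_gene_stats, call_hits, write_gene_stats
from .scoring import guide_stats, write_guide_stats
from .simulate import ScreenSim, SimConfig, benchmark_recovery, simulate_screen

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Configuration of one screen-analysis run (one contrast)."""

    library: str
    counts: str | None = None
    fastqs: dict[str, str] = field(default_factory=dict)  # sample_id -> path
    control: str = "dmso"
    treatment: str = "drug"
    baseline: str | None = None  # accepted but unused by the contrast
    pseudocount: float = 1.0
    mad_mode: str = "median_abs_dev"
    thresholds: HitThresholds = field(default_factory=HitThresholds)
    fold_band: float = 5.0
    sort_direction: str = "down"
    search_revcomp: bool = False
    outdir: str = "poolscreen_run"

    def __post_init__(self) -> None:
        if self.counts is None and not self.fastqs:
            raise ValueError("provide either a counts table or FASTQ paths")
        if self.control == self.treatment:
            logger.warning("treatment and control are the same sample")
        if self.sort_direction not in ("down", "up"):
            raise ValueError("sort_direction must be 'down' or 'up'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        if "thresholds" in raw and isinstance(raw["thresholds"], dict):
            raw["thresholds"] = HitThresholds(**raw["thresholds"])
        return cls(**raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out


def _sha256(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def analyze_counts(
    counts: pd.DataFrame,
    library: GuideLibrary,
    treatment: str,
    control: str,
    pseudocount: float = 1.0,
    mad_mode: str = "median_abs_dev",
    thresholds: HitThresholds = HitThresholds(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts -> (guide-stats table, gene-stats table with hit calls).

    The in-memory core of :func:`run_screen_analysis`, also used directly
    on simulated screens.
    """
    try:
        guides = guide_stats(
            counts, library, treatment, control,
            pseudocount=pseudocount, mad_mode=mad_mode,
        )
    except ValueError as err:
        if "degenerate" not in str(err):
            raise
        # a spread-free contrast (e.g. treatment == control) carries no
        # signal; score it as all-zero z rather than failing the run
        logger.warning("fold-change distribution has zero spread; all z set to 0")
        from .scoring import log2_fold_change, size_factors

        guides = log2_fold_change(
            counts, size_factors(counts), treatment, control, pseudocount, library
        )
        guides["z"] = 0.0
    genes = call_hits(build_gene_stats(guides), thresholds)
    return guides, genes


def analyze_sim(
    sim: ScreenSim,
    thresholds: HitThresholds = HitThresholds(),
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the standard drug-vs-DMSO contrast on a simulated screen."""
    return analyze_counts(
        sim.counts, sim.library, "drug", "dmso", thresholds=thresholds, **kwargs
    )


def run_screen_analysis(config: RunConfig) -> dict:
    """Execute a full configured run and write all artifacts to outdir.

    Returns a dict with the guide table, gene table, QC table and the
    manifest. Stage failures abort with the stage named in the exception.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _attach_file_log(outdir / "run.log")

    inputs = {"library": config.library}
    stage = "read library"
    try:
        library = read_library(config.library)
        if config.counts is not None:
            stage = "read counts"
            inputs["counts"] = config.counts
            counts = read_counts(config.counts, library)
        else:
            stage = "count spacers"
            columns = []
            for sample_id, fastq in config.fastqs.items():
                inputs[f"fastq:{sample_id}"] = fastq
                column, summary = count_spacers(
                    fastq, library, sample_id, search_revcomp=config.search_revcomp
                )
                logger.info(
                    "sample %s: %d reads, %d assigned, %d ambiguous, %d unassigned",
                    sample_id, summary.total_reads, summary.assigned,
                    summary.ambiguous, summary.unassigned,
                )
                columns.append(column)
            counts = pd.concat(columns, axis=1)
            write_counts(counts, outdir / "counts.tsv")

        stage = "guide scoring"
        guides, genes = analyze_counts(
            counts,
            library,
            config.treatment,
            config.control,
            pseudocount=config.pseudocount,
            mad_mode=config.mad_mode,
            thresholds=config.thresholds,
        )
        stage = "qc"
        qc = qc_table(counts, k=config.fold_band)
        for sample in counts.columns:
            logger.info(format_qc_summary(representation_stats(counts[sample],
                                                               k=config.fold_band)))
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    genes = genes.sort_values(
        f"logp_{config.sort_direction}", kind="mergesort"
    )
    write_guide_stats(guides, outdir / "guide_stats.tsv")
    write_gene_stats(genes, outdir / "gene_stats.tsv")
    qc.to_csv(outdir / "qc.tsv", sep="\t")

    config_dict = config.to_dict()
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "poolscreen_version": __version__,
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "input_sha256": {name: _sha256(path) for name, path in inputs.items()},
        "outputs": ["guide_stats.tsv", "gene_stats.tsv", "qc.tsv"],
        "n_guides": int(len(guides)),
        "n_genes": int(len(genes)),
    }
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2)
    logger.info(
        "run complete: %d guides, %d genes, %d stringent hits",
        len(guides), len(genes),
        int(genes["hit_class"].str.endswith("stringent").sum()),
    )
    return {"guides": guides, "genes": genes, "qc": qc, "manifest": manifest}


def run_simulate(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate a screen and write library/counts/truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simulate_screen(config)
    paths = {
        "library": outdir / "library.tsv",
        "counts": outdir / "counts.tsv",
        "truth": outdir / "truth.tsv",
    }
    sim.library.frame.to_csv(paths["library"], sep="\t", index=False)
    write_counts(sim.counts, paths["counts"])
    sim.truth.to_csv(paths["truth"], sep="\t")
    with open(outdir / "sim_config.json", "w") as handle:
        json.dump(dataclasses.asdict(config), handle, indent=2)
    return paths


def run_benchmark(
    gene_stats: pd.DataFrame, truth: pd.DataFrame, out: str | Path | None = None
) -> pd.DataFrame:
    """Score hit calls against planted truth; optionally write metrics TSV."""
    metrics = benchmark_recovery(gene_stats, truth)
    if out is not None:
        metrics.to_csv(out, sep="\t", index=False)
    return metrics


def _attach_file_log(path: Path) -> None:
    root = logging.getLogger("poolscreen")
    if any(
        isinstance(h, logging.FileHandler)
        and Path(getattr(h, "baseFilename", "")) == path.resolve()
        for h in root.handlers
    ):
        return
    handler = logging.FileHandler(path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root.addHandler(handler)
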