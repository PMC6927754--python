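"""Synthetic pooled CRISPR screen generator with known ground truth.

Emulates the design of a genome-scale drug-modifier screen: a library of
G genes x 5 guides with lognormal plasmid representation, a finite-cell
transduction bottleneck (the count-level consequence of infecting at low
MOI with ~1000 cells per guide), a vehicle (DMSO) arm and a drug arm in
which planted sensitizer genes drop out (negative log2FC shift) and
planted resistance genes enrich (positive shift), guide-efficiency
heterogeneity (each guide of a planted gene is active only with
probability ``p_active``), and negative-binomial sequencing noise at a
target depth of ~1000 reads per guide.

The generative model per guide i:

1. plasmid abundance  a_i ~ Lognormal(0, baseline_sigma * ln 2)
   (i.e. 2**Normal(0, baseline_sigma));
2. cell bottleneck: multinomial resampling of a_i at depth
   bottleneck_cells_per_guide * N cells;
3. DMSO abundance = a_i * 2**eps_i,           eps ~ Normal(0, neutral_sigma);
4. drug abundance = a_i * 2**(e_i + eps'_i),  e_i the planted guide effect
   (0 for neutral genes and inactive guides);
5. observed counts ~ NegativeBinomial(mean scaled so each arm totals
   reads_per_guide * N, variance mu + alpha*mu^2); alpha = 0 is Poisson.

All draws flow from a single integer seed, so a configuration reproduces
bit-identical counts and truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .library import GuideLibrary

GENE_CLASSES = ("neutral", "sensitizer", "resistance")

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Screen-simulation parameters (defaults: test scale, 2000 genes)."""

    n_genes: int = 2000
    guides_per_gene: int = 5
    reads_per_guide: float = 1000.0
    baseline_sigma: float = 0.5  # lognormal spread of plasmid pool, log2 scale
    nb_dispersion: float = 0.05  # alpha in var = mu + alpha*mu^2; 0 = Poisson
    n_sensitizers: int = 40
    n_resistance: int = 40
    effect_mu_sens: float = -3.0  # mean per-guide log2FC shift, sensitizers
    effect_mu_res: float = 3.0
    effect_sigma: float = 0.5  # between-guide effect spread
    p_active_guide: float = 0.8  # guide-efficiency heterogeneity
    neutral_sigma: float = 0.15  # residual log2FC noise of neutral guides
    bottleneck_cells_per_guide: float | None = 1000.0
    seed: int = 0

    def validate_library(self) -> None:
        if self.n_genes < 1 or self.guides_per_gene < 1:
            raise ValueError("library dimensions must be positive")

    def validate(self) -> None:
        self.validate_library()
        if self.reads_per_guide <= 0:
            raise ValueError("reads_per_guide must be positive")
        if self.baseline_sigma < 0 or self.effect_sigma < 0 or self.neutral_sigma < 0:
            raise ValueError("spread parameters must be non-negative")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not 0 <= self.p_active_guide <= 1:
            raise ValueError("p_active_guide must lie in [0, 1]")
        if self.n_sensitizers < 0 or self.n_resistance < 0:
            raise ValueError("planted gene counts must be non-negative")
        if self.n_sensitizers + self.n_resistance > self.n_genes:
            raise ValueError("planted gene sets exceed the gene universe")
        if self.bottleneck_cells_per_guide is not None and (
            self.bottleneck_cells_per_guide <= 0
        ):
            raise ValueError("bottleneck_cells_per_guide must be positive or None")

    @property
    def n_guides(self) -> int:
        return self.n_genes * self.guides_per_gene


@dataclass
class ScreenSim:
    """One simulated screen: library, counts and planted ground truth."""

    config: SimConfig
    library: GuideLibrary
    counts: pd.DataFrame  # columns baseline, dmso, drug
    truth: pd.DataFrame  # per guide: gene, gene_class, effect, active


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, stream])))


def _random_spacers(n: int, length: int, rng: np.random.Generator) -> list[str]:
    spacers: set[str] = set()
    out: list[str] = []
    while len(out) < n:  # collisions vanishingly rare at 20 nt, but guarded
        block = _BASES[rng.integers(0, 4, size=(n - len(out), length))]
        for row in block:
            s = "".join(row)
            if s not in spacers:
                spacers.add(s)
                out.append(s)
    return out


def simulate_library(config: SimConfig, spacer_length: int = 20) -> GuideLibrary:
    """Deterministic random library of n_genes x guides_per_gene guides."""
    config.validate_library()
    rng = _rng(config.seed, 0)
    width = len(str(config.n_genes))
    genes = [f"G{i + 1:0{width}d}" for i in range(config.n_genes)]
    records = pd.DataFrame(
        {
            "guide_id": [
                f"{g}_g{j + 1}" for g in genes for j in range(config.guides_per_gene)
            ],
            "gene": np.repeat(genes, config.guides_per_gene),
            "spacer": _random_spacers(config.n_guides, spacer_length, rng),
        }
    )
    return GuideLibrary(records)


def _plant_effects(config: SimConfig, genes: Sequence[str], rng) -> pd.DataFrame:
    """Assign gene classes and realized per-guide log2FC effects."""
    gene_class = pd.Series("neutral", index=pd.Index(genes, name="gene"))
    n_planted = config.n_sensitizers + config.n_resistance
    planted = rng.choice(len(genes), size=n_planted, replace=False)
    gene_class.iloc[planted[: config.n_sensitizers]] = "sensitizer"
    gene_class.iloc[planted[config.n_sensitizers :]] = "resistance"

    per_guide = gene_class.reindex(
        np.repeat(genes, config.guides_per_gene)
    ).reset_index()
    per_guide.columns = ["gene", "gene_class"]
    is_planted = per_guide["gene_class"] != "neutral"
    active = np.zeros(len(per_guide), dtype=bool)
    active[is_planted] = rng.random(int(is_planted.sum())) < config.p_active_guide

    mu = np.where(per_guide["gene_class"] == "sensitizer",
                  config.effect_mu_sens, config.effect_mu_res)
    effect = np.zeros(len(per_guide))
    effect[active] = rng.normal(mu[active], config.effect_sigma)
    per_guide["effect"] = effect
    per_guide["active"] = active
    return per_guide


def _nb_counts(mean: np.ndarray, alpha: float, rng) -> np.ndarray:
    """Negative-binomial draws with variance mu + alpha*mu^2 (gamma-Poisson)."""
    mean = np.clip(mean, 0.0, None)
    if alpha == 0:
        return rng.poisson(mean)
    lam = np.zeros_like(mean)
    positive = mean > 0
    lam[positive] = rng.gamma(1.0 / alpha, alpha * mean[positive])
    return rng.poisson(lam)


def simulate_screen(config: SimConfig) -> ScreenSim:
    """Generate counts for baseline, DMSO and drug arms plus ground truth."""
    config.validate()
    library = simulate_library(config)
    rng = _rng(config.seed, 1)
    genes = library.frame["gene"].unique()
    truth = _plant_effects(config, genes, rng)
    truth.insert(0, "guide_id", library.frame["guide_id"].to_numpy())
    truth = truth.set_index("guide_id")

    n = config.n_guides
    ln2 = np.log(2.0)
    abundance = rng.lognormal(0.0, config.baseline_sigma * ln2, size=n)

    if config.bottleneck_cells_per_guide is not None:
        cells = int(round(config.bottleneck_cells_per_guide * n))
        abundance = rng.multinomial(cells, abundance / abundance.sum()).astype(float)

    dmso = abundance * np.exp2(rng.normal(0.0, config.neutral_sigma, size=n))
    drug = abundance * np.exp2(
        truth["effect"].to_numpy() + rng.normal(0.0, config.neutral_sigma, size=n)
    )

    depth = config.reads_per_guide * n
    columns = {}
    for name, arm in (("baseline", abundance), ("dmso", dmso), ("drug", drug)):
        total = arm.sum()
        if total == 0:
            raise ValueError(f"arm {name!r} lost all abundance")
        columns[name] = _nb_counts(arm / total * depth, config.nb_dispersion, rng)
    counts = pd.DataFrame(columns, index=library.guide_ids, dtype=np.int64)
    counts.index.name = "guide_id"
    return ScreenSim(config=config, library=library, counts=counts, truth=truth)


def truth_gene_classes(truth: pd.DataFrame) -> pd.Series:
    """Collapse the per-guide truth table to one class per gene."""
    return truth.groupby("gene")["gene_class"].first()


def benchmark_recovery(genes: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Precision/recall of hit calls against planted gene classes.

    ``genes`` must carry a filled ``hit_class`` column. Lenient rows score
    the union of stringent and lenient calls (the stringent set is a
    subset of the lenient set by construction). Precision is NaN when no
    call was made.
    """
    true_class = truth_gene_classes(truth)
    if not genes.index.intersection(true_class.index).size:
        raise ValueError("hit table and truth share no genes")
    if not genes.index.difference(true_class.index).empty:
        raise ValueError("hit table contains genes absent from the truth")
    true_class = true_class.reindex(genes.index)

    rows = []
    for cls, prefix in (("sensitizer", "sensitizer"), ("resistance", "resistance")):
        actual = true_class == cls
        for tier in ("stringent", "lenient"):
            if tier == "stringent":
                called = genes["hit_class"] == f"{prefix}_stringent"
            else:
                called = genes["hit_class"].isin(
                    [f"{prefix}_stringent", f"{prefix}_lenient"]
                )
            tp = int((called & actual).sum())
            fp = int((called & ~actual).sum())
            fn = int((~called & actual).sum())
            rows.append(
                {
                    "gene_class": cls,
                    "tier": tier,
                    "tp": tp,
                    "fp": fp,
                    "fn": fn,
                    "precision": tp / (tp + fp) if tp + fp else float("nan"),
                    "recall": tp / (tp + fn) if tp + fn else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def null_config(config: SimConfig) -> SimConfig:
    """Same screen conditions with zero planted genes."""
    return replace(config, n_sensitizers=0, n_resistance=0)
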