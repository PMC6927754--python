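"""Per-sgRNA scoring: normalization, log2 fold change, robust z.

Counts are normalized with median-of-ratios size factors (the classic
RNA-seq convention: each sample is scaled by the median, over guides
detected in every sample, of its ratio to the per-guide geometric mean).
The per-guide statistic is a pseudocounted log2 fold change between the
treatment and control arms, standardized into a robust z-score across the
whole library using the median and a robust scale:

    z_i = (lfc_i - median(lfc)) / s

where by default s = 1.4826 * MAD (median absolute deviation, scaled to be
consistent with the standard deviation under normality). A literal
mean-absolute-deviation mode is available as an alternative reading.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .library import GuideLibrary

#: Consistency constant making the MAD estimate sigma under normality.
MAD_SCALE = 1.4826

MAD_MODES = ("median_abs_dev", "mean_abs_dev")


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one per sample.

    Reference guides are those with strictly positive counts in every
    sample; each sample's factor is the median over reference guides of
    count / geometric-mean-across-samples. Factors are reported as
    computed, without rescaling to unit product.

    Raises
    ------
    ValueError
        With fewer than 2 samples, or when no guide is detected in all
        samples (consider pseudocount normalization in that regime).
    """
    if matrix.shape[1] < 2:
        raise ValueError("size factors need at least 2 samples")
    values = matrix.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no guide has positive counts in every sample; median-of-ratios "
            "is undefined — fall back to pseudocount normalization"
        )
    ref = values[positive]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=matrix.columns, name="size_factor")


def normalize(matrix: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    return matrix.div(factors, axis=1)


def log2_fold_change(
    matrix: pd.DataFrame,
    factors: pd.Series,
    treatment: str,
    control: str,
    pseudocount: float = 1.0,
    library: GuideLibrary | None = None,
) -> pd.DataFrame:
    """Per-guide log2 fold change of normalized counts, treatment vs control.

    lfc_i = log2((count[i,T]/sf_T + pc) / (count[i,C]/sf_C + pc))

    Returns a guide-stats table (index guide_id) with columns
    ``norm_control``, ``norm_treatment``, ``lfc`` — plus ``gene`` when a
    library is supplied.
    """
    for sample in (treatment, control):
        if sample not in matrix.columns:
            raise ValueError(f"unknown sample id {sample!r}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    samples = [control] if control == treatment else [control, treatment]
    norm = normalize(matrix[samples], factors[samples])
    lfc = np.log2((norm[treatment] + pseudocount) / (norm[control] + pseudocount))
    stats = pd.DataFrame(
        {
            "norm_control": norm[control],
            "norm_treatment": norm[treatment],
            "lfc": lfc,
        },
        index=matrix.index,
    )
    if library is not None:
        stats.insert(0, "gene", library.guide_to_gene.reindex(stats.index))
    return stats


def robust_z(lfc, mad_mode: str = "median_abs_dev") -> np.ndarray:
    """Robust z-scores of fold changes across the whole library.

    ``median_abs_dev`` (default): scale = 1.4826 x median |lfc - median|.
    ``mean_abs_dev``: scale = mean |lfc - median|, unscaled — the literal
    reading of "mean absolute deviation".
    """
    if mad_mode not in MAD_MODES:
        raise ValueError(f"mad_mode must be one of {MAD_MODES}")
    values = np.asarray(lfc, dtype=float)
    if values.size < 2:
        raise ValueError("robust z needs at least 2 guides")
    if not np.isfinite(values).all():
        raise ValueError("non-finite fold changes")
    center = np.median(values)
    deviations = np.abs(values - center)
    if mad_mode == "median_abs_dev":
        scale = MAD_SCALE * np.median(deviations)
    else:
        scale = deviations.mean()
    if scale == 0:
        raise ValueError("degenerate fold-change distribution (zero spread)")
    return (values - center) / scale


def guide_stats(
    matrix: pd.DataFrame,
    library: GuideLibrary,
    treatment: str,
    control: str,
    pseudocount: float = 1.0,
    mad_mode: str = "median_abs_dev",
) -> pd.DataFrame:
    """Full per-guide table: gene, normalized counts, lfc, robust z."""
    stats = log2_fold_change(
        matrix, size_factors(matrix), treatment, control, pseudocount, library
    )
    stats["z"] = robust_z(stats["lfc"].to_numpy(), mad_mode=mad_mode)
    return stats


def write_guide_stats(stats: pd.DataFrame, path, sep: str = "\t") -> None:
    stats.to_csv(path, sep=sep, index_label="guide_id")


def read_guide_stats(path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, index_col="guide_id")
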