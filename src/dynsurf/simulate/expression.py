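"""Synthetic two-color expression matrices with planted differential
expression.

Each gene gets a log-normal baseline intensity shared by both channels.
For a configured fraction of genes, the sample channel in one or more
randomly chosen conditions is multiplied by a fold factor drawn from the
configured range, up- or down-regulated with equal probability.  Channel
noise is multiplicative log-normal, so the per-spot log-ratio of a null
gene is exactly normal and the replicate t-test is calibrated.  An
optional smooth intensity-dependent bias (a function of mean log
intensity) can be injected to exercise the lowess correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import ConfigError, SimulationConfig
from ..expression import ExpressionMatrix

__all__ = ["gen_expression", "planted_truth"]


def _bias(a: np.ndarray, amplitude: float) -> np.ndarray:
    """Smooth log2-ratio bias as a function of mean log2 intensity."""
    center = a.mean()
    span = max(a.std(), 1e-9)
    return amplitude * np.sin((a - center) / span)


def gen_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate a gene-by-array two-channel matrix plus its ground truth.

    Returns ``(matrix, truth)`` where ``truth`` has one row per gene and
    columns ``condition`` (label or missing for null genes) and ``fold``
    (the planted sample/reference fold in that condition; 1.0 for null
    genes).  Array ids are ``<condition>_r<replicate>``.
    """
    if not 0.0 <= config.de_fraction <= 1.0:
        raise ConfigError("de_fraction must be in [0, 1]")
    rng = config.rng("expression")
    n_genes = config.n_genes
    genes = pd.Index([f"gene{i:05d}" for i in range(n_genes)], name="gene")
    conditions = list(config.conditions)
    arrays = [f"{c}_r{r + 1}" for c in conditions for r in range(config.n_replicates)]
    sheet = pd.DataFrame(
        {
            "condition": [c for c in conditions for _ in range(config.n_replicates)],
            "replicate": [r + 1 for _ in conditions for r in range(config.n_replicates)],
        },
        index=pd.Index(arrays, name="array"),
    )
    # log-normal baseline intensity per gene (log2 scale mean 10, sd 1.5)
    base_log2 = rng.normal(10.0, 1.5, size=n_genes)
    base = 2.0**base_log2

    n_de = int(round(config.de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    lo, hi = config.de_fold_range
    fold_mag = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_de))
    down = rng.random(n_de) < 0.5
    planted_fold = np.where(down, 1.0 / fold_mag, fold_mag)
    planted_cond = rng.choice(len(conditions), size=n_de)

    fold_matrix = np.ones((n_genes, len(conditions)))
    fold_matrix[de_idx, planted_cond] = planted_fold

    sd_s = config.noise_levels.get("sample", 0.15)
    sd_r = config.noise_levels.get("reference", 0.15)
    sample = np.empty((n_genes, len(arrays)))
    reference = np.empty((n_genes, len(arrays)))
    for j, arr in enumerate(arrays):
        ci = conditions.index(sheet.loc[arr, "condition"])
        s = base * fold_matrix[:, ci] * np.exp(rng.normal(0.0, sd_s, size=n_genes))
        r = base * np.exp(rng.normal(0.0, sd_r, size=n_genes))
        if config.intensity_bias != 0.0:
            a = 0.5 * np.log2(s * r)
            s = s * 2.0 ** _bias(a, config.intensity_bias)
        sample[:, j] = s
        reference[:, j] = r

    matrix = ExpressionMatrix(
        sample=pd.DataFrame(sample, index=genes, columns=arrays),
        reference=pd.DataFrame(reference, index=genes, columns=arrays),
        samples=sheet,
    )
    truth = pd.DataFrame({"condition": pd.NA, "fold": 1.0}, index=genes)
    truth["condition"] = truth["condition"].astype(object)
    truth.iloc[de_idx, truth.columns.get_loc("condition")] = [
        conditions[c] for c in planted_cond
    ]
    truth.iloc[de_idx, truth.columns.get_loc("fold")] = planted_fold
    return matrix, truth


def planted_truth(truth: pd.DataFrame) -> pd.Index:
    """Genes with a planted (non-unit) fold."""
    return truth.index[truth["fold"] != 1.0]
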