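"""Monoallelic-expression (MAE) enrichment among de-repressed genes.

Genes up-regulated at least three-fold upon loss of their repressor are
ranked and tested for enrichment of random monoallelic expression against a
background gene set, using MAE annotations compiled across cell lines and
tissues.  Two criteria:

* standard — monoallelic in at least three of five B cell lines AND in at
  least five other tissues;
* stringent — monoallelic in at least ten other tissues.

The annotation table is a local TSV snapshot with columns ``gene``,
``fold_change``, ``mae_status`` (measured_monoallelic / predicted_monoallelic
/ biallelic / unknown), ``n_b_cell_lines_mae`` and ``n_tissues_mae``.
``mae_status`` carries the measured/predicted/biallelic split; the criterion
fractions are computed from the line/tissue counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from kfac.stats import BiasTable, bias_table

MAE_COLUMNS = ["gene", "fold_change", "mae_status", "n_b_cell_lines_mae", "n_tissues_mae"]
MAE_STATUSES = ("measured_monoallelic", "predicted_monoallelic", "biallelic", "unknown")


def load_mae_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(MAE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"MAE table missing columns {sorted(missing)}")
    return df


def select_upregulated(records: pd.DataFrame, min_fold: float = 3.0) -> pd.DataFrame:
    """Genes with fold change >= ``min_fold``, ranked by descending fold
    (ties broken by gene id for determinism)."""
    if (records["fold_change"] <= 0).any():
        raise ValueError("fold changes must be positive")
    kept = records[records["fold_change"] >= min_fold]
    return kept.sort_values(["fold_change", "gene"],
                            ascending=[False, True]).reset_index(drop=True)


def is_mae(records: pd.DataFrame, criterion: str = "standard") -> pd.Series:
    """Boolean MAE call per gene under the given criterion."""
    if criterion == "standard":
        return (records["n_b_cell_lines_mae"] >= 3) & (records["n_tissues_mae"] >= 5)
    if criterion == "stringent":
        return records["n_tissues_mae"] >= 10
    raise ValueError(f"unknown criterion {criterion!r}")


def status_fractions(records: pd.DataFrame, include_predicted: bool = False) -> dict[str, float]:
    """Fraction of genes per annotation status among assessable genes.

    ``predicted_monoallelic`` is kept distinct from the measured-MAE fraction
    unless ``include_predicted``.
    """
    assessable = records[records["mae_status"] != "unknown"]
    n = len(assessable)
    if n == 0:
        raise ValueError("no assessable genes")
    counts = assessable["mae_status"].value_counts()
    out = {s: counts.get(s, 0) / n for s in MAE_STATUSES if s != "unknown"}
    if include_predicted:
        out["monoallelic_total"] = out["measured_monoallelic"] + out["predicted_monoallelic"]
    return out


def mae_fractions(genes: pd.DataFrame, background: pd.DataFrame,
                  criterion: str = "standard") -> dict:
    """MAE fraction of a focal gene set vs background, with Fisher's exact test."""
    if background.empty:
        raise ValueError("empty background set")
    if genes.empty:
        raise ValueError("empty focal set")
    a = int(is_mae(genes, criterion).sum())
    b = int(is_mae(background, criterion).sum())
    table = bias_table(a, len(genes), b, len(background))
    return {"criterion": criterion,
            "focal_fraction": table.focal_fraction,
            "background_fraction": table.comparison_fraction,
            "table": table}


def simulate_mae_table(n_focal: int, n_background: int, enrichment_odds: float = 1.0,
                       background_rate: float = 0.2, rng=None,
                       seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic focal/background MAE annotation tables with a planted
    enrichment odds ratio under the standard criterion."""
    if rng is None:
        rng = np.random.default_rng(seed)
    p0 = background_rate
    odds_focal = enrichment_odds * p0 / (1 - p0)
    p_focal = odds_focal / (1 + odds_focal)

    def build(n, p, prefix):
        mae = rng.random(n) < p
        lines = np.where(mae, rng.integers(3, 6, n), rng.integers(0, 3, n))
        tissues = np.where(mae, rng.integers(5, 21, n), rng.integers(0, 5, n))
        return pd.DataFrame({
            "gene": [f"{prefix}{i:05d}" for i in range(n)],
            "fold_change": np.round(rng.uniform(3.0, 30.0, n), 2),
            "mae_status": np.where(mae, "measured_monoallelic", "biallelic"),
            "n_b_cell_lines_mae": lines,
            "n_tissues_mae": tissues,
        })

    return build(n_focal, p_focal, "focal"), build(n_background, p0, "bg")
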