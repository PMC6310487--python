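"""Expression-bias statistics relative to CTCF sites and E2A-bound promoters.

Expression events are (cell, segment) pairs — a gene expressed in many cells
counts once per cell.  Three analyses:

* a signed distance profile of expressed V-kappas around their nearest CTCF
  site (genes 5' of the site at negative distances, 3' positive), compared to
  the exact expectation under uniformly random expression over all V-kappas;
* orientation bias: the fraction of away-from-CTCF-oriented V-kappa
  opportunities expressed versus the into-CTCF fraction and the
  orientation-blind fraction, with two-sided Fisher's exact tests
  (away vs into, and away vs all);
* E2A bias: expressed fraction of E2A-preloaded V-kappa promoters versus all
  V-kappas; the Fisher test runs on the disjoint E2A vs non-E2A partition so
  that its null is exact and its odds ratio estimates the per-opportunity
  expression odds (testing a focal class against a pool containing it is
  conservative and compresses the odds ratio).

Opportunity totals are class size x number of cells, so fractions are
per-cell expression frequencies pooled over the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from kfac.locus_model import LocusModel, signed_distance_and_orientation
from kfac.stats import BiasTable, bias_table


@dataclass
class OrientationBiasResult:
    from_fraction: float
    into_fraction: float
    all_fraction: float
    from_vs_into: BiasTable
    from_vs_all: BiasTable
    n_cells: int


def _segment_distances(model: LocusModel, mode: str) -> dict[str, int]:
    """Signed distance of each V-kappa TSS to its nearest CTCF site.

    ``signed``: sign is genomic (5' negative / 3' positive).  ``oriented``:
    sign encodes orientation (positive = transcribing away from the site).
    """
    out = {}
    for seg in model.vk_segments:
        site = model.nearest_ctcf(seg)
        distance, orient = signed_distance_and_orientation(seg, site)
        if mode == "signed":
            out[seg.id] = distance
        elif mode == "oriented":
            out[seg.id] = abs(distance) if orient == "away" else -abs(distance)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return out


def distance_profile(events: list[tuple[str, str]], model: LocusModel,
                     bin_width: int = 10_000, mode: str = "signed") -> pd.DataFrame:
    """Observed vs expected expression frequency by distance from CTCF sites.

    The expected profile replaces every event with an exact uniform draw over
    all V-kappa segments (weight 1/N each); it depends only on the locus.
    Both columns are normalised to sum to 1.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    distances = _segment_distances(model, mode)
    max_abs = max(abs(d) for d in distances.values())
    n_side = int(np.ceil((max_abs + 1) / bin_width))
    edges = np.arange(-n_side, n_side + 1) * bin_width

    obs_d = np.array([distances[seg] for _, seg in events], dtype=float)
    exp_d = np.array(list(distances.values()), dtype=float)
    observed, _ = np.histogram(obs_d, bins=edges)
    expected, _ = np.histogram(exp_d, bins=edges)
    observed = observed / observed.sum() if observed.sum() else observed.astype(float)
    expected = expected / expected.sum()
    return pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:],
                         "observed": observed, "expected": expected})


def orientation_bias_test(events: list[tuple[str, str]], model: LocusModel) -> OrientationBiasResult:
    """Away-from vs into-CTCF expression fractions with Fisher's exact tests."""
    away = {s.id for s in model.vk_segments if model.orientation_class(s) == "away"}
    toward = {s.id for s in model.vk_segments if model.orientation_class(s) == "toward"}
    n_cells = len({cell for cell, _ in events})
    if not away or not toward or n_cells == 0:
        raise ValueError("empty orientation class or no cells")
    a = sum(1 for _, seg in events if seg in away)
    b = sum(1 for _, seg in events if seg in toward)
    A = len(away) * n_cells
    B = len(toward) * n_cells
    from_vs_into = bias_table(a, A, b, B)
    from_vs_all = bias_table(a, A, a + b, A + B)
    return OrientationBiasResult(
        from_fraction=a / A, into_fraction=b / B, all_fraction=(a + b) / (A + B),
        from_vs_into=from_vs_into, from_vs_all=from_vs_all, n_cells=n_cells)


def e2a_bias_test(events: list[tuple[str, str]], model: LocusModel) -> BiasTable:
    """Expression enrichment at E2A-preloaded V-kappa promoters (Fisher).

    The test partitions expression opportunities into E2A-flagged versus
    unflagged V-kappas, so the 2x2 table is disjoint: its odds ratio estimates
    the per-opportunity expression odds favouring E2A promoters, and the null
    p-value is exact.  The figure-style "all V-kappa" fraction is the pooled
    (a + b) / (A + B); see :func:`e2a_fractions`.
    """
    e2a = {s.id for s in model.vk_segments if s.e2a_bound}
    if not e2a:
        raise ValueError("no E2A-flagged segments in model")
    other = {s.id for s in model.vk_segments} - e2a
    n_cells = len({cell for cell, _ in events})
    if n_cells == 0:
        raise ValueError("no events")
    a = sum(1 for _, seg in events if seg in e2a)
    b = sum(1 for _, seg in events if seg in other)
    return bias_table(a, len(e2a) * n_cells, b, len(other) * n_cells)


def e2a_fractions(table: BiasTable) -> dict[str, float]:
    """Display fractions for the E2A test: E2A-associated vs all V-kappa."""
    return {"e2a_fraction": table.focal_fraction,
            "all_fraction": (table.a + table.b) / (table.A + table.B)}
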