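"""Spike-in-normalized abundance and two-condition fold-change comparison.

norm_rpkm = raw_count * 1e9 / (substrate_length_nt * spike_count): reads per
kilobase of substrate per spike-in-defined library-size unit. The constant
makes the quantity scale-invariant under joint rescaling of substrate and
spike-in reads, which is the property the normalization exists to provide.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cpseq.mapping import CategoryAlignment

DEFAULT_MIN_COUNT = 10
LOG2_BIN_WIDTH = 0.25


def count_spike_in(assignments: list[CategoryAlignment]) -> int:
    n = sum(1 for a in assignments if a.category == "spike_in")
    if n == 0:
        warnings.warn("no spike-in reads detected; normalization disabled")
    return n


def substrate_counts(
    assignments: list[CategoryAlignment], category: str = "mRNA"
) -> pd.Series:
    """Raw read count per reference for one category."""
    ids = [a.ref_id for a in assignments if a.category == category]
    return pd.Series(ids, dtype=object).value_counts().sort_index()


def normalized_rpkm(
    counts: pd.Series, lengths: dict[str, int], spike_count: int, sample_id: str = "sample"
) -> pd.DataFrame:
    """Spike-in-scaled per-substrate abundance table."""
    if spike_count <= 0:
        raise ValueError("spike_count must be > 0 for normalization")
    rows = []
    for ref_id, raw in counts.items():
        length = lengths[ref_id]
        if length <= 0:
            raise ValueError(f"substrate {ref_id} has non-positive length")
        rows.append(
            {
                "sample_id": sample_id,
                "substrate_id": ref_id,
                "raw_count": int(raw),
                "substrate_length_nt": int(length),
                "spike_count": int(spike_count),
                "norm_rpkm": raw * 1e9 / (length * spike_count),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "substrate_id",
            "raw_count",
            "substrate_length_nt",
            "spike_count",
            "norm_rpkm",
        ],
    )


def replicate_aggregate(samples: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-substrate mean and dispersion of norm_rpkm across replicate samples.

    Standard deviation (ddof=1) is reported when n >= 2, else NaN.
    """
    if not samples:
        raise ValueError("at least one sample required")
    stacked = pd.concat(samples, ignore_index=True)
    grouped = stacked.groupby("substrate_id")["norm_rpkm"]
    out = grouped.agg(
        mean_norm_rpkm="mean",
        sd_norm_rpkm=lambda v: v.std(ddof=1) if len(v) >= 2 else np.nan,
        n_samples="count",
    ).reset_index()
    raw = stacked.groupby("substrate_id")["raw_count"].sum().rename("total_raw_count")
    return out.merge(raw, on="substrate_id").sort_values("substrate_id", ignore_index=True)


@dataclass
class FoldChangeSummary:
    table: pd.DataFrame
    modal_log2_fc_cp: float | None
    modal_log2_fc_mrna: float | None
    n_dropped: int


def _modal_bin_center_2d(
    x: np.ndarray, y: np.ndarray, width: float = LOG2_BIN_WIDTH
) -> tuple[float | None, float | None]:
    """Center of the densest (x, y) bin of a fixed-width 2-D histogram."""
    if x.size == 0:
        return None, None
    bx = np.floor(x / width).astype(int)
    by = np.floor(y / width).astype(int)
    pairs, counts = np.unique(np.column_stack([bx, by]), axis=0, return_counts=True)
    best = pairs[np.argmax(counts)]
    return float((best[0] + 0.5) * width), float((best[1] + 0.5) * width)


def fold_change_table(
    norm_cond1: pd.DataFrame,
    norm_cond2: pd.DataFrame,
    mrna_cond1: pd.Series,
    mrna_cond2: pd.Series,
    min_count: int = DEFAULT_MIN_COUNT,
) -> FoldChangeSummary:
    """Per-substrate fold changes (condition 2 / condition 1) for cP-RNA and
    substrate mRNA abundance, plus the modal (log2 fc_mrna, log2 fc_cp) found
    by fixed-width histogram binning.

    norm_cond* are replicate-aggregated tables (mean_norm_rpkm,
    total_raw_count per substrate); mrna_cond* are substrate-indexed RPKM
    series from an external mRNA-seq table. Substrates below min_count raw
    reads in either condition, or with zero denominators, are dropped and
    counted.
    """
    c1 = norm_cond1.set_index("substrate_id")
    c2 = norm_cond2.set_index("substrate_id")
    shared = c1.index.intersection(c2.index)
    rows = []
    dropped = 0
    for sid in shared:
        if (
            c1.loc[sid, "total_raw_count"] < min_count
            or c2.loc[sid, "total_raw_count"] < min_count
        ):
            dropped += 1
            continue
        base_cp = c1.loc[sid, "mean_norm_rpkm"]
        base_m = mrna_cond1.get(sid, np.nan)
        m2 = mrna_cond2.get(sid, np.nan)
        if base_cp <= 0 or not base_m > 0 or not m2 > 0:
            dropped += 1
            continue
        fc_cp = c2.loc[sid, "mean_norm_rpkm"] / base_cp
        fc_mrna = m2 / base_m
        if fc_cp <= 0:
            dropped += 1
            continue
        rows.append(
            {
                "substrate_id": sid,
                "fc_cp": fc_cp,
                "fc_mrna": fc_mrna,
                "log2_fc_cp": math.log2(fc_cp),
                "log2_fc_mrna": math.log2(fc_mrna),
            }
        )
    dropped += len(c1.index.symmetric_difference(c2.index))
    table = pd.DataFrame(
        rows, columns=["substrate_id", "fc_cp", "fc_mrna", "log2_fc_cp", "log2_fc_mrna"]
    )
    modal_mrna, modal_cp = _modal_bin_center_2d(
        table["log2_fc_mrna"].to_numpy(), table["log2_fc_cp"].to_numpy()
    )
    return FoldChangeSummary(
        table=table,
        modal_log2_fc_cp=modal_cp,
        modal_log2_fc_mrna=modal_mrna,
        n_dropped=dropped,
    )
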