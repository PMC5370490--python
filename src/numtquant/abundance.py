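"""The relative NUMT-abundance metric and its tumor/normal fold-change.

Per sample and genomic interval *i*, NUMT abundance is the proportion

    P_ij = N_ij / M_ij

of chimeric pairs N over mapped reads M, for genome type j in {t, h}
(tumor, matched blood-derived healthy).  The paired contrast is

    dP_i = P_it - P_ih            (difference)
    R_i  = P_it / P_ih            (fold-ratio, asymmetric around 1)
    S_i  = sign(dP_i)             (direction; 0 when dP_i = 0)
    R'_i = R_i ** S_i * S_i       (rescaled fold-change)

R' maps a ratio of 2 to +2, a ratio of 0.5 to -2, and collapses no-change
(R = 1) to 0; |R'| >= 1 or R' = 0, and swapping tumor with healthy flips
its sign.  For short intervals where a matched healthy sample may have no
NUMTs at all, the matched P_ih is replaced by the plate-pooled healthy
baseline (mean healthy proportion over samples sharing a plate barcode)
and tumor samples are pooled before normalization.
"""

from __future__ import annotations

import logging
import numbers

import numpy as np
import pandas as pd

from .genome_model import GenomeBuild, IntervalPartition

logger = logging.getLogger(__name__)


class UndefinedRatioError(ZeroDivisionError):
    """Healthy proportion is zero; the fold-ratio is undefined."""


class InconsistentCountsError(ValueError):
    """NUMT pairs reported in an interval with zero mapped reads."""


RATIO_COLUMNS = [
    "interval_id",
    "p_t",
    "p_h",
    "delta_p",
    "ratio",
    "direction",
    "rescaled",
    "baseline_kind",
]


def numt_proportion(numt_count, mapped_count):
    """P = N / M.  NaN where M = 0 and N = 0; error where M = 0 but N > 0
    (pairs imply mapped reads).  Accepts scalars or arrays."""
    n = np.asarray(numt_count, dtype=float)
    m = np.asarray(mapped_count, dtype=float)
    if np.any((m == 0) & (n > 0)):
        raise InconsistentCountsError(
            "numt_count > 0 with mapped_count == 0"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(m > 0, n / np.where(m > 0, m, 1.0), np.nan)
    if np.isscalar(numt_count) and np.isscalar(mapped_count):
        return float(p)
    return p


def fold_ratio(p_t: float, p_h: float) -> float:
    """R = P_t / P_h; raises when the healthy proportion is zero."""
    if p_h == 0:
        raise UndefinedRatioError(
            "p_h == 0: use a pooled baseline or exclude the interval"
        )
    return p_t / p_h


def direction_indicator(delta_p) -> int | np.ndarray:
    """S = sign(dP): +1, -1, or 0 at exactly no change."""
    s = np.sign(delta_p)
    if isinstance(delta_p, numbers.Number):
        return int(s)
    return s.astype(int)


def rescale_ratio(ratio, direction):
    """R' = R**S * S: +R when tumor is up, -(1/R) when down, 0 at no change.

    Vectorized; requires ratio > 0 wherever direction != 0.
    """
    r = np.asarray(ratio, dtype=float)
    s = np.asarray(direction, dtype=float)
    if np.any((s != 0) & ~(r > 0)):
        raise ValueError("rescale requires ratio > 0 where direction != 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(s == 0, 0.0, np.where(s > 0, r, -1.0 / np.where(r > 0, r, 1.0)))
    if np.isscalar(ratio):
        return float(out)
    return out


def rescaled_fold_change(p_t, p_h):
    """Convenience: dP, S and R' straight from two positive proportions."""
    delta = np.asarray(p_t, dtype=float) - np.asarray(p_h, dtype=float)
    s = np.sign(delta)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(np.asarray(p_h, dtype=float) > 0,
                     np.asarray(p_t, dtype=float) / np.asarray(p_h, dtype=float),
                     np.nan)
    rp = np.where(s == 0, 0.0, np.where(s > 0, r, -1.0 / r))
    if np.isscalar(p_t) and np.isscalar(p_h):
        return float(delta), int(s), float(rp)
    return delta, s.astype(int), rp


# ---------------------------------------------------------------------------
# pooled baselines


def pooled_healthy_baseline(
    healthy_records: pd.DataFrame,
    metadata: pd.DataFrame,
    interval_id: str | None = None,
) -> pd.DataFrame:
    """Plate-pooled healthy baselines P-bar_ih.

    ``healthy_records`` holds per-sample healthy proportions (columns
    sample_id, interval_id, proportion); ``metadata`` maps sample_id to a
    plate barcode.  Returns one row per (plate, interval) with the
    arithmetic mean proportion (zeros included) and member count.  When
    metadata has no plate column every sample joins a single global pool.
    """
    df = healthy_records.copy()
    if interval_id is not None:
        df = df[df["interval_id"] == interval_id]
    if "plate" in metadata.columns:
        plate_map = metadata.set_index("sample_id")["plate"]
    else:
        logger.warning("no plate column in metadata; using a single global pool")
        plate_map = pd.Series("all", index=metadata["sample_id"].values)
    df = df.assign(plate=df["sample_id"].map(plate_map))
    if df["plate"].isna().any():
        missing = df.loc[df["plate"].isna(), "sample_id"].unique()
        raise KeyError(f"samples missing from metadata: {list(missing)[:5]}")
    out = (
        df.groupby(["plate", "interval_id"], sort=False)["proportion"]
        .agg(mean_healthy_proportion="mean", n_samples="size")
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# ratio tables


def proportions_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Add a ``proportion`` column to a (sample, interval) counts table."""
    out = counts.copy()
    out["proportion"] = numt_proportion(
        out["numt_count"].to_numpy(), out["mapped_count"].to_numpy()
    )
    return out


def _finalize(df: pd.DataFrame, baseline_kind: str) -> pd.DataFrame:
    delta = df["p_t"] - df["p_h"]
    s = np.sign(delta).astype(int)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(df["p_h"] > 0, df["p_t"] / df["p_h"], np.nan)
        rescaled = np.where(
            s == 0, 0.0, np.where(s > 0, ratio, -1.0 / ratio)
        )
    out = df.assign(
        delta_p=delta, ratio=ratio, direction=s, rescaled=rescaled,
        baseline_kind=baseline_kind,
    )
    # exactly one side zero: the fold-ratio (or its reciprocal) is undefined,
    # so the interval is omitted and logged; both-zero intervals stay with
    # dP = S = R' = 0 and a NaN ratio
    undef = ((df["p_h"] == 0) & (df["p_t"] > 0)) | (
        (df["p_t"] == 0) & (df["p_h"] > 0)
    )
    if undef.any():
        logger.info(
            "omitting %d intervals where exactly one proportion is zero",
            int(undef.sum()),
        )
    return out[~undef].reset_index(drop=True)


def ratio_table(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    mode: str = "matched",
) -> pd.DataFrame:
    """Per-interval RatioRecords (P_t, P_h, dP, R, S, R').

    ``counts`` is a long table (sample_id, genome_type, interval_id,
    numt_count, mapped_count) covering one partition level; ``metadata``
    supplies participant and plate per sample_id.

    mode="matched": one record per (participant, interval), healthy
    baseline from the same individual's blood-derived sample.  Intervals
    where P_h = 0 while P_t > 0 are omitted and logged; both-zero
    intervals are kept with dP = S = R' = 0 and an undefined (NaN) ratio.

    mode="pooled": one record per (plate, interval); the tumor proportion
    pools counts before normalization (sum N / sum M over the plate's
    tumor samples) and the baseline is the plate-mean healthy proportion.
    """
    props = proportions_table(counts)
    meta = metadata.set_index("sample_id")
    if mode == "matched":
        if "participant" not in metadata.columns:
            raise KeyError("matched mode requires a participant column")
        props = props.assign(participant=props["sample_id"].map(meta["participant"]))
        wide = props.pivot_table(
            index=["participant", "interval_id"],
            columns="genome_type",
            values="proportion",
            aggfunc="first",
        ).reset_index()
        if "t" not in wide.columns or "h" not in wide.columns:
            raise ValueError("matched mode needs both tumor and healthy samples")
        wide = wide.rename(columns={"t": "p_t", "h": "p_h"})
        wide = wide.dropna(subset=["p_t", "p_h"])
        out = _finalize(wide[["participant", "interval_id", "p_t", "p_h"]], "matched")
        return out
    if mode == "pooled":
        if "plate" in metadata.columns:
            props = props.assign(plate=props["sample_id"].map(meta["plate"]))
        else:
            logger.warning("no plate column in metadata; using a single global pool")
            props = props.assign(plate="all")
        tumor = props[props["genome_type"] == "t"]
        healthy = props[props["genome_type"] == "h"]
        if healthy.empty:
            raise ValueError("pooled mode requires healthy samples for baselines")
        pooled_t = (
            tumor.groupby(["plate", "interval_id"], sort=False)[
                ["numt_count", "mapped_count"]
            ]
            .sum()
            .reset_index()
        )
        pooled_t["p_t"] = numt_proportion(
            pooled_t["numt_count"].to_numpy(), pooled_t["mapped_count"].to_numpy()
        )
        baseline = (
            healthy.groupby(["plate", "interval_id"], sort=False)["proportion"]
            .mean()
            .rename("p_h")
            .reset_index()
        )
        wide = pooled_t.merge(baseline, on=["plate", "interval_id"], how="left")
        no_base = wide["p_h"].isna()
        if no_base.any():
            logger.info(
                "omitting %d intervals without a plate healthy baseline",
                int(no_base.sum()),
            )
            wide = wide[~no_base]
        wide = wide.dropna(subset=["p_t"])
        return _finalize(wide[["plate", "interval_id", "p_t", "p_h"]], "pooled")
    raise ValueError(f"unknown mode {mode!r}")


def genome_fold_changes(
    counts_gen: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Per-participant genome-level fold change R_gen (matched mode)."""
    tab = ratio_table(counts_gen, metadata, mode="matched")
    return tab.rename(columns={"ratio": "fold_change"})[
        ["participant", "p_t", "p_h", "fold_change", "rescaled"]
    ]


def write_ratio_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="")
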