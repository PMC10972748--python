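"""Arrayed-screen well aggregation, three-anchor plate normalization, hit calling.

Raw well intensities are mapped per plate through the control anchors —
cGAS-targeting siRNA wells at -1, negative-control siRNA wells at 0 and
epoxomicin wells at +1 — by a continuous piecewise-linear transform (distinct
slopes below and above the negative anchor, since three anchor points are not
in general collinear).  Wells whose score deviates from the negative-control
mean by more than ``k_sd`` standard deviations are hits; the s.d. is a
hit-resistant estimate from the sample-well score distribution (see
``call_hits``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

CONTROL_ROLES = ("negative", "cgas", "epoxomicin")


def aggregate_wells(
    cells: pd.DataFrame,
    layout: pd.DataFrame,
    mfi_col: str = "cgas_gfp_mfi_corrected",
    integrated_col: str = "cgas_gfp_integrated",
    min_cells: int = 50,
) -> pd.DataFrame:
    """Aggregate per-cell features to per-well means.

    ``cells`` must carry ``plate_id``/``well_id`` columns mapping each cell to
    a layout well.  Per well the mean nuclear corrected MFI and mean
    integrated intensity are recorded along with the cell count; wells below
    ``min_cells`` are flagged ``low_count`` (kept in reports, excluded from
    s.d. estimation downstream).  Layout wells with no cells raise.
    """
    keys = ["plate_id", "well_id"]
    unknown = cells.merge(layout[keys], on=keys, how="left", indicator=True)
    if (unknown["_merge"] == "left_only").any():
        bad = cells.loc[(unknown["_merge"] == "left_only").to_numpy(), keys].iloc[0]
        raise ValueError(f"cell maps to a well absent from the layout: {tuple(bad)}")
    agg = (
        cells.groupby(keys)
        .agg(
            raw_mfi=(mfi_col, "mean"),
            raw_integrated=(integrated_col, "mean"),
            n_cells=(mfi_col, "size"),
        )
        .reset_index()
    )
    out = layout.merge(agg, on=keys, how="left")
    if out["n_cells"].isna().any():
        empty = out.loc[out["n_cells"].isna(), keys].iloc[0]
        raise ValueError(f"well with no cells: {tuple(empty)}")
    out["n_cells"] = out["n_cells"].astype(int)
    out["low_count"] = out["n_cells"] < min_cells
    return out


def anchor_normalize(
    wells: pd.DataFrame,
    value_cols: tuple[str, ...] = ("raw_mfi", "raw_integrated"),
    score_names: tuple[str, ...] = ("score_mfi", "score_integrated"),
) -> pd.DataFrame:
    """Per-plate three-anchor normalization of raw well intensities.

    With plate control means c- (cgas), c0 (negative), c+ (epoxomicin):

        score(x) = (x - c0) / (c0 - c-)   if x < c0
                   (x - c0) / (c+ - c0)   otherwise

    which maps the control means to exactly -1, 0, +1, is continuous at 0 and
    strictly increasing whenever c- < c0 < c+.  Plates violating that anchor
    ordering are flagged ``plate_invalid`` and their scores set to NaN.
    """
    out = wells.copy()
    for s in score_names:
        out[s] = np.nan
    out["plate_invalid"] = False
    for plate, idx in out.groupby("plate_id").groups.items():
        sub = out.loc[idx]
        for raw_col, score_col in zip(value_cols, score_names):
            anchors = {
                role: sub.loc[sub["role"] == role, raw_col].mean()
                for role in CONTROL_ROLES
            }
            missing = [r for r, v in anchors.items() if not np.isfinite(v)]
            if missing:
                raise ValueError(f"plate {plate} lacks control role(s): {missing}")
            c_minus, c0, c_plus = anchors["cgas"], anchors["negative"], anchors["epoxomicin"]
            if not (c_minus < c0 < c_plus):
                out.loc[idx, "plate_invalid"] = True
                continue
            x = sub[raw_col].to_numpy(float)
            score = np.where(x < c0, (x - c0) / (c0 - c_minus), (x - c0) / (c_plus - c0))
            out.loc[idx, score_col] = score
    return out


def _hit_scale(sample_scores: np.ndarray, trim_mads: float = 3.5) -> float:
    """Hit-resistant s.d. of sample-well scores.

    Standard deviation after excluding wells more than ``trim_mads``
    normal-scaled MADs from the median.  True hits (a small minority of
    extreme wells) are excluded while the near-Gaussian bulk keeps its scale,
    so the 3-s.d. rule stays calibrated to the null distribution.
    """
    med = np.median(sample_scores)
    madn = median_abs_deviation(sample_scores, scale="normal")
    if madn == 0:
        raise ValueError("degenerate screen: zero spread among sample scores")
    keep = np.abs(sample_scores - med) <= trim_mads * madn
    return float(sample_scores[keep].std(ddof=1))


def call_hits(
    wells: pd.DataFrame,
    k_sd: float = 3.0,
    score_col: str = "score_mfi",
    sd_method: str = "samples",
    hits_required: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag hit wells and aggregate to a gene-level call table.

    A well is a hit iff ``|score - mean(negative-control scores)| >
    k_sd * s.d.`` (strict).  ``sd_method``:

    * ``"samples"`` (default): hit-resistant s.d. of the sample-well scores
      (trimmed std, see ``_hit_scale``) — calibrated so a null screen yields
      the Gaussian two-sided rate 2*Phi(-k_sd);
    * ``"negatives"``: s.d. of the pooled negative-control well scores.  With
      two negative wells per plate this understates the sample-score spread
      (the per-plate anchors are estimated from those same wells), so the
      realized false-positive rate is well above the Gaussian rate; it is
      kept for comparison with the literal screen convention.

    Low-count and invalid-plate wells are excluded from the estimates and
    never called.  A gene is a hit when at least ``hits_required`` of its
    siRNA wells are hits in a consistent direction.
    """
    need_neg = wells.loc[wells["role"] == "negative", score_col].dropna()
    if len(need_neg) < 4:
        raise ValueError("need at least 4 negative-control wells")
    usable = ~wells.get("low_count", pd.Series(False, index=wells.index)) & ~wells.get(
        "plate_invalid", pd.Series(False, index=wells.index)
    )
    neg = wells.loc[(wells["role"] == "negative") & usable, score_col].to_numpy(float)
    samp = wells.loc[(wells["role"] == "sample") & usable, score_col].to_numpy(float)
    center = float(neg.mean())
    if sd_method == "samples":
        sd = _hit_scale(samp)
    elif sd_method == "negatives":
        sd = float(neg.std(ddof=1))
        if sd == 0:
            raise ValueError("degenerate screen: zero negative-control spread")
    else:
        raise ValueError(f"unknown sd_method {sd_method!r}")

    out = wells.copy()
    dev = out[score_col] - center
    is_hit = usable & (out["role"] == "sample") & (dev.abs() > k_sd * sd)
    out["hit"] = is_hit.fillna(False)
    out["direction"] = np.where(~out["hit"], "none", np.where(dev > 0, "up", "down"))
    out.attrs["hit_center"] = center
    out.attrs["hit_sd"] = sd

    sample = out[out["role"] == "sample"]
    genes = (
        sample.groupby("gene")
        .agg(
            n_wells=("hit", "size"),
            n_hits=("hit", "sum"),
            n_up=("direction", lambda d: int((d == "up").sum())),
            n_down=("direction", lambda d: int((d == "down").sum())),
            mean_score=(score_col, "mean"),
        )
        .reset_index()
    )
    genes["hit"] = (genes[["n_up", "n_down"]].max(axis=1) >= hits_required)
    genes["direction"] = np.where(
        ~genes["hit"], "none", np.where(genes["n_up"] >= genes["n_down"], "up", "down")
    )
    return out, genes


def screen_report(wells: pd.DataFrame, score_col: str = "score_mfi") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scatter table (score_mfi vs score_integrated) and ranked gene list.

    Genes are ranked by mean score across their siRNA wells, largest first.
    """
    cols = [c for c in ("plate_id", "well_id", "role", "gene", "sirna_id",
                        "score_mfi", "score_integrated", "hit", "direction") if c in wells]
    scatter = wells[cols].copy()
    sample = wells[wells["role"] == "sample"]
    ranked = (
        sample.groupby("gene")[score_col]
        .mean()
        .sort_values(ascending=False)
        .rename("mean_score")
        .reset_index()
    )
    ranked.insert(0, "rank", np.arange(1, len(ranked) + 1))
    return scatter, ranked
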