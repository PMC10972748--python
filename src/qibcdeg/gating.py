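"""Cell-cycle gating from DAPI/EdU intensities and per-phase summaries (QIBC).

DNA content is read from integrated DAPI intensity: a two-component Gaussian
mixture on log DNA places the 2N (G1) and 4N (G2/M) peaks.  S phase is gated
first on EdU mean intensity (incorporation marks active replication, so an
early-S cell still near 2N is called S), then the DNA windows assign G1 and
G2/M, and mitotic cells are split out of the 4N window by their elevated DAPI
MFI (condensed chromatin) or, when available, H3pS10 positivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu
from sklearn.mixture import GaussianMixture

PHASE_LABELS = ("G1", "S", "G2", "M", "unclassified")


@dataclass
class PhaseGates:
    """Fitted gate parameters mapping per-cell features to phases."""

    g1_peak: float
    g2_peak: float
    g1_window: tuple[float, float]
    g2_window: tuple[float, float]
    edu_threshold: float = np.nan
    m_dapi_mfi_threshold: float = np.inf
    quality: str = "ok"  # "ok" or "degraded"

    @property
    def peak_ratio(self) -> float:
        return self.g2_peak / self.g1_peak


def fit_dna_gates(
    dna_values, n_sigma: float = 2.5, seed: int = 0, max_iter: int = 500
) -> PhaseGates:
    """Fit 2N/4N peaks to DNA content (integrated DAPI) values.

    A two-component Gaussian mixture is fit by EM on log DNA; the smaller mode
    is the G1 (2N) peak and the larger the G2/M (4N) peak, with phase windows
    at mode +/- ``n_sigma`` component standard deviations (in log space).  If
    EM does not converge the peaks fall back to the two highest KDE modes.
    The fit is flagged ``degraded`` when the peak ratio leaves [1.7, 2.3] —
    e.g. a single-mode population, for which the single peak is duplicated.
    """
    x = np.asarray(dna_values, float)
    x = x[np.isfinite(x) & (x > 0)]
    if x.size < 50:
        raise ValueError("need at least 50 cells to fit DNA gates")
    logx = np.log(x)[:, None]
    q25, q75 = np.percentile(logx, [25, 75])
    gm = GaussianMixture(
        n_components=2,
        means_init=[[q25], [q75]],
        random_state=seed,
        max_iter=max_iter,
        n_init=1,
    ).fit(logx)
    if gm.converged_:
        mu = gm.means_.ravel()
        sd = np.sqrt(gm.covariances_.ravel())
        order = np.argsort(mu)
        mu, sd = mu[order], sd[order]
    else:  # fall back to KDE modes
        kde = stats.gaussian_kde(logx.ravel())
        grid = np.linspace(logx.min(), logx.max(), 512)
        dens = kde(grid)
        peaks = grid[(np.r_[True, dens[1:] > dens[:-1]] & np.r_[dens[:-1] > dens[1:], True])]
        peaks = np.sort(peaks)
        if peaks.size >= 2:
            mu = np.array([peaks[0], peaks[-1]])
        else:
            mu = np.array([peaks[0], peaks[0]])
        sd = np.full(2, logx.std() / 2)

    g1, g2 = float(np.exp(mu[0])), float(np.exp(mu[1]))
    quality = "ok"
    ratio = g2 / g1
    if not (1.7 <= ratio <= 2.3):
        quality = "degraded"
        if ratio < 1.2:  # effectively single-mode: duplicate the peak
            g2 = g1
            sd = np.array([sd.mean(), sd.mean()])
    return PhaseGates(
        g1_peak=g1,
        g2_peak=g2,
        g1_window=(float(np.exp(mu[0] - n_sigma * sd[0])), float(np.exp(mu[0] + n_sigma * sd[0]))),
        g2_window=(float(np.exp(mu[1] - n_sigma * sd[1])), float(np.exp(mu[1] + n_sigma * sd[1]))),
        quality=quality,
    )


def fit_gates(
    records: pd.DataFrame,
    dapi_integrated_col: str = "dapi_integrated",
    edu_col: str = "edu_mfi",
    dapi_mfi_col: str = "dapi_mfi",
    n_sigma: float = 2.5,
    seed: int = 0,
    m_separation: float = 1.5,
) -> PhaseGates:
    """Fit the full gate set from a per-cell feature table.

    The EdU threshold (Otsu on log EdU) is fit first and the DNA mixture is
    then fit on EdU-negative cells only, so the S-phase continuum between 2N
    and 4N does not distort the 2N/4N peaks.  The mitosis gate is an Otsu
    threshold on DAPI MFI restricted to the 4N window; it is only armed when
    the split is bimodal enough (upper/lower mean ratio > ``m_separation``),
    otherwise no cell is called M.
    """
    edu = records[edu_col].to_numpy(float)
    edu_thr = float(np.exp(threshold_otsu(np.log(np.maximum(edu, 1e-6)))))
    non_s = records.loc[edu <= edu_thr, dapi_integrated_col]
    gates = fit_dna_gates(non_s, n_sigma=n_sigma, seed=seed)
    gates.edu_threshold = edu_thr

    in_4n = records[dapi_integrated_col].between(*gates.g2_window) & (edu <= edu_thr)
    mfi_4n = records.loc[in_4n, dapi_mfi_col].to_numpy(float)
    if mfi_4n.size >= 20 and np.ptp(mfi_4n) > 0:
        thr = float(threshold_otsu(mfi_4n))
        lo, hi = mfi_4n[mfi_4n <= thr], mfi_4n[mfi_4n > thr]
        if lo.size and hi.size and hi.mean() / max(lo.mean(), 1e-12) > m_separation:
            gates.m_dapi_mfi_threshold = thr
    return gates


def call_phases(
    records: pd.DataFrame,
    gates: PhaseGates,
    dapi_integrated_col: str = "dapi_integrated",
    edu_col: str = "edu_mfi",
    dapi_mfi_col: str = "dapi_mfi",
    h3ps10_col: str | None = None,
    h3ps10_threshold: float | None = None,
) -> pd.Series:
    """Assign one of G1/S/G2/M/unclassified to every cell.

    Rule order: S if EdU above threshold; else G1 if DNA in the 2N window;
    else, within the 4N window, M if DAPI MFI exceeds the mitosis threshold
    (or the cell is H3pS10-positive when that channel is given), otherwise
    G2; anything else is unclassified.
    """
    for col in (dapi_integrated_col, edu_col, dapi_mfi_col):
        if col not in records:
            raise KeyError(f"required channel column missing: {col!r}")
    dna = records[dapi_integrated_col].to_numpy(float)
    edu = records[edu_col].to_numpy(float)
    dmfi = records[dapi_mfi_col].to_numpy(float)

    out = np.full(len(records), "unclassified", dtype=object)
    in_2n = (dna >= gates.g1_window[0]) & (dna <= gates.g1_window[1])
    in_4n = (dna >= gates.g2_window[0]) & (dna <= gates.g2_window[1])
    if h3ps10_col is not None:
        h3 = records[h3ps10_col].to_numpy(float)
        thr = h3ps10_threshold if h3ps10_threshold is not None else float(threshold_otsu(h3))
        mitotic = h3 > thr
    else:
        mitotic = dmfi > gates.m_dapi_mfi_threshold
    out[in_4n] = "G2"
    out[in_4n & mitotic] = "M"
    out[in_2n & ~(in_4n)] = "G1"
    out[edu > gates.edu_threshold] = "S"
    return pd.Series(out, index=records.index, name="phase")


def phase_summaries(
    records: pd.DataFrame,
    phases: pd.Series,
    channel: str,
    reference: str = "G1",
) -> pd.DataFrame:
    """Per-phase mean/sd of a channel with relative MFI versus a reference phase.

    Unclassified cells are excluded.  Phases with zero cells are kept as rows
    with ``n_cells = 0`` and NaN statistics.
    """
    values = records[channel]
    ref_vals = values[phases == reference]
    if len(ref_vals) == 0:
        raise ValueError(f"reference phase {reference!r} has no cells")
    ref_mean = float(ref_vals.mean())
    rows = []
    for ph in ("G1", "S", "G2", "M"):
        v = values[phases == ph]
        rows.append(
            {
                "phase": ph,
                "n_cells": int(len(v)),
                "mean_mfi": float(v.mean()) if len(v) else np.nan,
                "sd_mfi": float(v.std(ddof=1)) if len(v) > 1 else np.nan,
                "relative_mfi": float(v.mean()) / ref_mean if len(v) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def condition_contrast(
    groups: dict[str, tuple[pd.DataFrame, pd.Series]],
    channel: str,
    reference: str,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-phase condition contrasts with bootstrap CIs and Sidak-adjusted p values.

    ``groups`` maps condition label -> (records, phases).  For each phase the
    one-way ANOVA across all conditions is computed, then each non-reference
    condition is contrasted against the reference: ratio of means, seeded 95%
    bootstrap CI of the ratio, and a two-sided Welch t-test whose p value is
    Sidak-adjusted for the number of pairwise contrasts in that phase.
    """
    if reference not in groups:
        raise KeyError(f"reference condition {reference!r} not in groups")
    rng = np.random.default_rng(seed)
    others = [c for c in groups if c != reference]
    ref_rec, ref_ph = groups[reference]
    rows = []
    shared_phases = 0
    for ph in ("G1", "S", "G2", "M"):
        samples = {
            c: rec.loc[phs == ph, channel].to_numpy(float) for c, (rec, phs) in groups.items()
        }
        if any(len(v) < 2 for v in samples.values()):
            continue
        shared_phases += 1
        anova_p = float(stats.f_oneway(*samples.values()).pvalue)
        m = len(others)
        a = samples[reference]
        for cond in others:
            b = samples[cond]
            ratio = b.mean() / a.mean()
            boots = np.empty(n_boot)
            for i in range(n_boot):
                boots[i] = (
                    rng.choice(b, b.size).mean() / rng.choice(a, a.size).mean()
                )
            lo, hi = np.percentile(boots, [2.5, 97.5])
            p = float(stats.ttest_ind(b, a, equal_var=False).pvalue)
            rows.append(
                {
                    "phase": ph,
                    "condition": cond,
                    "reference": reference,
                    "ratio": float(ratio),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "anova_p": anova_p,
                    "p_adj_sidak": float(min(1.0, 1.0 - (1.0 - p) ** m)),
                }
            )
    if shared_phases == 0:
        raise ValueError("no phase has cells in every condition")
    return pd.DataFrame(rows)
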