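"""Global 1:1 Langmuir fitting of BLI sensorgrams.

All concentrations are fitted jointly with shared kon, koff and Rmax:

    association:  R(t) = Req(C) (1 - e^(-(kon C + koff) t)),
                  Req(C) = Rmax C / (C + Kd),  Kd = koff / kon
    dissociation: R(t) = R(t_split) e^(-koff (t - t_split))

Parameters are optimized in log space (positivity by construction) with a
multi-start grid over kon/koff initial guesses; the best residual sum of
squares wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np
import pandas as pd


@dataclass
class BindingFit:
    """Fitted 1:1 binding parameters; kd = koff/kon by construction."""

    kon: float   # 1/(M s)
    koff: float  # 1/s
    rmax: float  # response units
    kd: float    # M
    rss: float
    req: dict[float, float]  # per-concentration fitted plateau
    kon_reliable: bool = True


def kd_from_rates(kon: float, koff: float) -> float:
    """Equilibrium dissociation constant Kd = koff / kon (koff = 0 is the covalent limit)."""
    if kon <= 0:
        raise ValueError("kon must be positive")
    return koff / kon


def _model_response(t, conc, t_split, kon, koff, rmax):
    kd = koff / kon
    req = rmax * conc / (conc + kd)
    kobs = kon * conc + koff
    r_split = req * (1.0 - np.exp(-kobs * t_split))
    assoc = req * (1.0 - np.exp(-kobs * t))
    dissoc = r_split * np.exp(-koff * (t - t_split))
    return np.where(t <= t_split, assoc, dissoc)


def fit_1to1(
    sensorgrams: pd.DataFrame,
    t_split: float | None = None,
    baseline_correct: bool = False,
    n_starts: int = 3,
) -> BindingFit:
    """Globally fit the 1:1 Langmuir model across a concentration series.

    ``sensorgrams`` is long format with columns ``time_s``, ``response``,
    ``conc_M`` and either a ``phase`` column ('assoc'/'dissoc') or an explicit
    ``t_split``.  ``baseline_correct`` subtracts each curve's pre-association
    baseline (response at t <= 0).  With dissociation-only data, koff is
    fitted from the single-exponential decay and kon is flagged unreliable.
    """
    df = sensorgrams.copy()
    if t_split is None:
        if "phase" in df:
            assoc = df[df["phase"] == "assoc"]
            t_split = float(assoc["time_s"].max()) if len(assoc) else 0.0
        else:
            raise ValueError("provide t_split or a 'phase' column")
    if baseline_correct:
        for conc, idx in df.groupby("conc_M").groups.items():
            pre = df.loc[idx].query("time_s <= 0")["response"]
            if len(pre):
                df.loc[idx, "response"] -= pre.mean()

    concs = np.sort(df["conc_M"].unique())
    if len(df[df["time_s"] <= t_split]) == 0:  # dissociation-only
        return _fit_dissociation_only(df, t_split)

    t = df["time_s"].to_numpy(float)
    r = df["response"].to_numpy(float)
    c = df["conc_M"].to_numpy(float)
    rmax0 = max(r.max(), 1e-9)
    # initial-guess grids bracket the observable kinetics: koff spanning
    # decades around 1/t_split, kon tied to the concentration scale
    koff_grid = np.geomspace(0.1 / t_split, 10.0 / t_split, n_starts)
    c_scale = np.median(concs[concs > 0]) if np.any(concs > 0) else 1e-6
    kon_grid = np.geomspace(0.1, 10.0, n_starts) / (c_scale * t_split)

    def residual(params):
        kon = np.exp(params["log_kon"].value)
        koff = np.exp(params["log_koff"].value)
        rmax = np.exp(params["log_rmax"].value)
        return _model_response(t, c, t_split, kon, koff, rmax) - r

    best = None
    for kon0 in kon_grid:
        for koff0 in koff_grid:
            params = lmfit.Parameters()
            params.add("log_kon", value=np.log(kon0), min=np.log(1e-2), max=np.log(1e12))
            params.add("log_koff", value=np.log(koff0), min=np.log(1e-9), max=np.log(1e3))
            params.add("log_rmax", value=np.log(rmax0), min=np.log(rmax0 * 1e-3),
                       max=np.log(rmax0 * 1e3))
            try:
                res = lmfit.minimize(residual, params, method="leastsq")
            except Exception:
                continue
            rss = float(np.sum(res.residual**2))
            if best is None or rss < best[0]:
                best = (rss, res)
    if best is None:
        raise RuntimeError("1:1 fit failed to converge from every start")
    rss, res = best
    kon = float(np.exp(res.params["log_kon"].value))
    koff = float(np.exp(res.params["log_koff"].value))
    rmax = float(np.exp(res.params["log_rmax"].value))
    kd = kd_from_rates(kon, koff)
    return BindingFit(
        kon=kon,
        koff=koff,
        rmax=rmax,
        kd=kd,
        rss=rss,
        req={float(cc): rmax * cc / (cc + kd) for cc in concs},
    )


def _fit_dissociation_only(df: pd.DataFrame, t_split: float) -> BindingFit:
    """koff from log-linear decay of the dissociation phase; kon unreliable."""
    rates = []
    r0 = []
    for conc, sub in df.groupby("conc_M"):
        sub = sub[sub["response"] > 0]
        if len(sub) < 3:
            continue
        slope, intercept = np.polyfit(sub["time_s"] - t_split, np.log(sub["response"]), 1)
        rates.append(-slope)
        r0.append(np.exp(intercept))
    if not rates:
        raise ValueError("no usable dissociation data")
    koff = float(np.mean(rates))
    return BindingFit(
        kon=np.nan,
        koff=koff,
        rmax=float(np.max(r0)),
        kd=np.nan,
        rss=np.nan,
        req={},
        kon_reliable=False,
    )


def fitted_traces(fit: BindingFit, sensorgrams: pd.DataFrame, t_split: float) -> pd.DataFrame:
    """Model-predicted response at the observed time points, per concentration."""
    out = sensorgrams.copy()
    out["fitted"] = _model_response(
        out["time_s"].to_numpy(float),
        out["conc_M"].to_numpy(float),
        t_split,
        fit.kon,
        fit.koff,
        fit.rmax,
    )
    return out
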