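"""Deterministic calculations for the in-vitro validation assays: bacterial
growth rate from OD600 curves, percent bile-acid conversion from LC-MS peak
areas, and relative gene expression by the 2^-ddCt method."""

from __future__ import annotations

import numpy as np
import pandas as pd


def growth_rate(time_h, od600, window: int = 4) -> float:
    """Maximum specific growth rate mu (per hour) from an OD600 curve.

    mu = ln(X/X0)/T on the linear portion of growth, operationalized as the
    maximum over sliding windows of ``window`` points of the least-squares
    slope of ln(OD) against time.  Invariant to uniform scaling of the ODs.
    """
    t = np.asarray(time_h, dtype=float)
    x = np.asarray(od600, dtype=float)
    if t.size != x.size or t.size < 3:
        raise ValueError("need at least 3 (time, OD) points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time points must be strictly increasing")
    if np.any(x <= 0):
        raise ValueError("optical densities must be positive")
    window = min(max(window, 2), t.size)
    ln_x = np.log(x)
    best = -np.inf
    for i in range(t.size - window + 1):
        ts = t[i : i + window]
        ys = ln_x[i : i + window]
        slope = np.polyfit(ts, ys, 1)[0]
        best = max(best, slope)
    return float(best)


def percent_conversion(
    substrate_t0: float,
    substrate_end: float | None = None,
    product_end: float | None = None,
    mode: str = "disappearance",
) -> float:
    """Percent bile acid converted over an incubation.

    ``disappearance`` (e.g. deconjugation of TCA/GCDCA):
    100 * (1 - substrate_end / substrate_t0).
    ``appearance`` (e.g. 7a-oxidation of CA/CDCA to 7-keto products):
    100 * product_end / substrate_t0.
    """
    if substrate_t0 <= 0:
        raise ValueError("initial substrate area must be positive")
    if mode == "disappearance":
        if substrate_end is None or substrate_end < 0:
            raise ValueError("disappearance mode needs a non-negative substrate_end")
        return 100.0 * (1.0 - substrate_end / substrate_t0)
    if mode == "appearance":
        if product_end is None or product_end < 0:
            raise ValueError("appearance mode needs a non-negative product_end")
        return 100.0 * product_end / substrate_t0
    raise ValueError(f"unknown mode {mode!r}")


def growth_rates_from_csv(path, window: int = 4) -> pd.Series:
    """Per-replicate growth rates from a CSV with columns
    time_h, od600, replicate."""
    df = pd.read_csv(path)
    out = {
        rep: growth_rate(sub["time_h"].to_numpy(), sub["od600"].to_numpy(), window)
        for rep, sub in df.groupby("replicate")
    }
    return pd.Series(out, name="mu_per_h")


def conversions_from_csv(path) -> pd.DataFrame:
    """Percent conversion per assay row from a CSV with columns
    species, substrate, product, area_t0, area_t24, reaction
    (reaction in {deconjugation, oxidation}: deconjugation is measured as
    substrate disappearance, oxidation as product appearance)."""
    df = pd.read_csv(path)
    percents = []
    for _, r in df.iterrows():
        if r["reaction"] == "deconjugation":
            percents.append(percent_conversion(r["area_t0"], substrate_end=r["area_t24"]))
        else:
            percents.append(
                percent_conversion(r["area_t0"], product_end=r["area_t24"], mode="appearance")
            )
    out = df.copy()
    out["percent_converted"] = percents
    return out


def relative_expression(
    ct_target_test: float,
    ct_reference_test: float,
    ct_target_control: float,
    ct_reference_control: float,
) -> float:
    """Fold change by 2^-ddCt, with dCt = Ct_target - Ct_reference per
    condition and ddCt = dCt_test - dCt_control (reference gene normalized)."""
    for ct in (ct_target_test, ct_reference_test, ct_target_control, ct_reference_control):
        if not np.isfinite(ct) or ct <= 0:
            raise ValueError("Ct values must be positive and finite")
    ddct = (ct_target_test - ct_reference_test) - (ct_target_control - ct_reference_control)
    return float(2.0 ** (-ddct))
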