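"""qPCR relative abundance and the time-of-death (diurnal) confound check.

Transcript abundance relative to a reference gene (GAPDH) follows the
ΔCt convention: ``2 ** -(Ct_target - Ct_reference)``.  Because autopsy
samples are collected at arbitrary times of day, a diurnal rhythm could
masquerade as a group difference; the check fits a single-harmonic (24 h)
cosinor to log2 abundance against time of death and tests the two harmonic
coefficients jointly.  The cosinor is a formal stand-in for inspecting the
abundance-vs-time plot.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "relative_abundance",
    "abundance_table",
    "CosinorModel",
    "CosinorResults",
    "diurnal_test",
    "diurnal_report",
]


def relative_abundance(ct_target, ct_reference):
    """Linear abundance relative to the reference: 2^-(Ct_t - Ct_ref).
    One extra target cycle halves the abundance."""
    ct_target = np.asarray(ct_target, dtype=float)
    ct_reference = np.asarray(ct_reference, dtype=float)
    if not (np.all(np.isfinite(ct_target)) and np.all(np.isfinite(ct_reference))):
        raise ValueError("Ct values must be finite")
    out = np.exp2(-(ct_target - ct_reference))
    return float(out) if out.ndim == 0 else out


def abundance_table(qpcr: pd.DataFrame, reference: str = "GAPDH") -> pd.DataFrame:
    """Tidy per-sample, per-target relative abundances from a Ct table
    with columns (sample, gene, Ct, tod, group)."""
    ref = qpcr[qpcr["gene"] == reference].set_index("sample")["Ct"]
    targets = qpcr[qpcr["gene"] != reference]
    missing = set(targets["sample"]) - set(ref.index)
    if missing:
        raise ValueError(f"reference gene {reference!r} missing for samples {sorted(missing)}")
    out = targets.copy()
    out["abundance"] = relative_abundance(out["Ct"].to_numpy(),
                                          ref.loc[out["sample"]].to_numpy())
    return out[["sample", "gene", "tod", "group", "abundance"]].reset_index(drop=True)


class CosinorResults:
    """Fitted 24 h cosinor: mesor + amplitude * cos(2*pi*(t - phase)/24)."""

    def __init__(self, mesor, amplitude, phase, pvalue, params, ols_results):
        self.mesor = mesor
        self.amplitude = amplitude
        self.phase = phase          # hours of peak, in [0, 24)
        self.pvalue = pvalue        # joint F-test of the two harmonic terms
        self.params = params
        self._ols = ols_results

    def summary(self) -> str:
        return "\n".join([
            "24 h cosinor fit of log2 abundance on time of death",
            f"  mesor     : {self.mesor:.4g} log2 units",
            f"  amplitude : {self.amplitude:.4g} log2 units",
            f"  peak hour : {self.phase:.2f}",
            f"  rhythm p  : {self.pvalue:.4g}  (joint F-test, cos & sin terms)",
        ])


class CosinorModel:
    """Least-squares single-harmonic fit of log2 abundance vs hours."""

    def __init__(self, tod_hours, log2_abundance):
        t = np.asarray(tod_hours, dtype=float)
        y = np.asarray(log2_abundance, dtype=float)
        if len(t) != len(y):
            raise ValueError("tod and abundance lengths differ")
        if len(t) < 6:
            raise ValueError("need at least 6 samples for the diurnal check")
        if np.unique(np.mod(t, 24.0)).size < 3:
            raise ValueError("times of death are (nearly) all equal; "
                             "the harmonic fit is unidentifiable")
        self.t = t
        self.y = y

    def fit(self) -> CosinorResults:
        w = 2.0 * np.pi * self.t / 24.0
        X = np.column_stack([np.ones_like(self.t), np.cos(w), np.sin(w)])
        res = sm.OLS(self.y, X).fit()
        b0, bc, bs = res.params
        amplitude = float(np.hypot(bc, bs))
        phase = float(np.mod(np.arctan2(bs, bc) * 24.0 / (2.0 * np.pi), 24.0))
        if res.ssr <= 1e-24:            # exact fit: F ratio undefined, rhythm certain
            pvalue = 0.0 if amplitude > 1e-12 else 1.0
        else:
            ftest = res.f_test(np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]))
            pvalue = float(ftest.pvalue)
        return CosinorResults(mesor=float(b0), amplitude=amplitude, phase=phase,
                              pvalue=pvalue, params=res.params, ols_results=res)


def diurnal_test(abundances, tods):
    """(amplitude, phase, p) of the 24 h harmonic in linear abundances.

    Abundances are log2-transformed internally; invariant to shifting all
    times by 24 h.
    """
    y = np.log2(np.asarray(abundances, dtype=float))
    res = CosinorModel(np.mod(np.asarray(tods, dtype=float), 24.0), y).fit()
    return res.amplitude, res.phase, res.pvalue


def diurnal_report(qpcr: pd.DataFrame, reference: str = "GAPDH") -> pd.DataFrame:
    """Per-target cosinor summary (amplitude, peak hour, p) from a Ct table."""
    ab = abundance_table(qpcr, reference=reference)
    rows = []
    for gene, sub in ab.groupby("gene"):
        amplitude, phase, p = diurnal_test(sub["abundance"], sub["tod"])
        rows.append({"gene": gene, "amplitude": amplitude,
                     "peak_hour": phase, "p": p})
    return pd.DataFrame(rows)
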