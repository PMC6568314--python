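"""Quantification of primed adaptation from qPCR data.

The readout is the *adaptation score*: the percentage of cells whose CRISPR
array acquired a given hotspot spacer, obtained by inverting a calibration
curve built from defined mixtures of expanded- and unexpanded-array cells.
Relative hotspot signal is standard efficiency-based relative
quantification, ``E ** -(Cq_hotspot - Cq_reference)`` against the
single-copy chromosomal gyrA gene; a censored (non-amplifying) hotspot
reaction scores zero, like the water/mock control.

Hotspot assays differ in efficiency, so scores from HS2/HS3 are put on the
HS1 scale through a shared reference PAM (CAA)::

    normalized_HSi(PAM) = score_HSi(PAM) * score_HS1(CAA) / score_HSi(CAA)

and then averaged over hotspots and measurements.  A changed-context PAM set
(AGN*) measured without the CAA reference is bridged onto the common scale
through the one PAM present in both sets (AGC)::

    rescaled(AGN*) = <score_AGN*> * <score_AGC> / <score_AGC*>
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .pams import BRIDGE_PAM, REFERENCE_PAM


class CalibrationError(ValueError):
    pass


def relative_signal(
    cq_target: float, cq_reference: float, efficiency: float = 2.0
) -> float:
    """Relative quantity of the target amplicon vs the reference gene.

    A censored target Cq (NaN) means no amplification and returns 0; a
    censored reference invalidates the sample.
    """
    if not math.isfinite(cq_reference):
        raise CalibrationError("censored reference-gene Cq: sample invalid")
    if not math.isfinite(cq_target):
        return 0.0
    if efficiency <= 1.0:
        raise CalibrationError("amplification efficiency must exceed 1")
    return float(efficiency ** -(cq_target - cq_reference))


class QpcrCalibration(BaseEstimator, RegressorMixin):
    """Least-squares calibration of log10(signal) against log10(percent).

    Fit from defined mixtures of cells with and without the extra spacer;
    the fitted line is inverted to map a sample's relative signal to its
    adaptation score (percent of cells with the expanded array).

    Attributes
    ----------
    slope_, intercept_ : float
        Parameters of ``log10(signal) = intercept + slope * log10(percent)``.
    r2_, residual_sd_ : float
        Fit diagnostics in log10-signal space.
    percent_range_ : tuple[float, float]
        Valid (interpolation) range of the curve.
    """

    def __init__(self, min_points: int = 2):
        self.min_points = min_points

    def fit(self, percent, signal):
        percent = np.asarray(percent, dtype=float)
        signal = np.asarray(signal, dtype=float)
        if percent.shape != signal.shape or percent.ndim != 1:
            raise CalibrationError("percent and signal must be equal-length 1-D")
        ok = (percent > 0) & (signal > 0) & np.isfinite(signal)
        percent, signal = percent[ok], signal[ok]
        if len(np.unique(percent)) < max(2, self.min_points):
            raise CalibrationError(
                "calibration needs at least two distinct mixture levels"
            )
        span = percent.max() / percent.min()
        if span < 10:
            warnings.warn(
                f"calibration mixtures span only {span:.1f}x (< 1 order of "
                "magnitude); inverse predictions will extrapolate poorly",
                stacklevel=2,
            )
        x, y = np.log10(percent), np.log10(signal)
        res = stats.linregress(x, y)
        if res.slope <= 0:
            warnings.warn(
                "calibration is non-increasing in the expanded fraction; "
                f"slope={res.slope:.3f}, r={res.rvalue:.3f}",
                stacklevel=2,
            )
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r2_ = float(res.rvalue**2)
        self.stderr_slope_ = float(res.stderr)
        n = len(x)
        resid = y - (self.intercept_ + self.slope_ * x)
        self.residual_sd_ = float(
            np.sqrt((resid**2).sum() / (n - 2)) if n > 2 else 0.0
        )
        self.n_points_ = n
        self.x_mean_ = float(x.mean())
        self.sxx_ = float(((x - x.mean()) ** 2).sum())
        self.percent_range_ = (float(percent.min()), float(percent.max()))
        return self

    def signal_at(self, percent) -> np.ndarray:
        """Noiseless predicted relative signal for a given percent."""
        return 10 ** (self.intercept_ + self.slope_ * np.log10(percent))

    def predict(self, signal) -> np.ndarray:
        """Invert the calibration: relative signal -> percent of cells.

        Signals at or below zero (censored reactions) map to 0.
        """
        signal = np.atleast_1d(np.asarray(signal, dtype=float))
        out = np.zeros_like(signal)
        pos = signal > 0
        out[pos] = 10 ** ((np.log10(signal[pos]) - self.intercept_) / self.slope_)
        return out

    def prediction_interval(
        self, signal: float, level: float = 0.95
    ) -> tuple[float, float]:
        """Confidence interval for the percent behind one observed signal.

        Delta-method inverse prediction: the uncertainty of a new
        observation around the fitted line (residual scatter plus parameter
        uncertainty) is propagated through the inverse slope.
        """
        if signal <= 0:
            return (0.0, 0.0)
        x_hat = (math.log10(signal) - self.intercept_) / self.slope_
        n = self.n_points_
        se_y = self.residual_sd_ * math.sqrt(
            1 + 1 / n + (x_hat - self.x_mean_) ** 2 / self.sxx_
        )
        tq = stats.t.ppf(0.5 + level / 2, max(n - 2, 1))
        half = tq * se_y / abs(self.slope_)
        return (10 ** (x_hat - half), 10 ** (x_hat + half))


def fit_calibration(
    calibration: pd.DataFrame,
    efficiency: float = 2.0,
    assay: str = "HS1",
    reference_assay: str = "gyrA",
) -> QpcrCalibration:
    """Fit a :class:`QpcrCalibration` from a tidy calibration-mixture table.

    Expects columns ``sample, assay, replicate, cq, percent_expanded`` with
    one target and one reference row per (sample, replicate).
    """
    needed = {"sample", "assay", "replicate", "cq", "percent_expanded"}
    if not needed.issubset(calibration.columns):
        raise CalibrationError(f"calibration table needs columns {sorted(needed)}")
    percents, signals = [], []
    for (_, _), grp in calibration.groupby(["sample", "replicate"]):
        target = grp[grp["assay"] == assay]
        ref = grp[grp["assay"] == reference_assay]
        if len(target) != 1 or len(ref) != 1:
            raise CalibrationError(
                "each (sample, replicate) needs exactly one target and one "
                "reference reaction"
            )
        percents.append(float(target["percent_expanded"].iloc[0]))
        signals.append(
            relative_signal(
                float(target["cq"].iloc[0]), float(ref["cq"].iloc[0]), efficiency
            )
        )
    return QpcrCalibration().fit(percents, signals)


def adaptation_score(
    signal: float, curve: QpcrCalibration
) -> tuple[float, str]:
    """Map one relative signal to (percent of cells, flag).

    Signals below the curve's lower validity bound clamp to 0
    (``"below_range"``); values above the upper bound are reported but
    flagged ``"above_range"``; zero signal is ``"censored"``.
    """
    if signal <= 0:
        return 0.0, "censored"
    value = float(curve.predict([signal])[0])
    lo, hi = curve.percent_range_
    if value < lo:
        return 0.0, "below_range"
    if value > hi:
        return value, "above_range"
    return value, "ok"


def scores_from_cq(
    cq_table: pd.DataFrame,
    curve: QpcrCalibration,
    efficiency: float = 2.0,
    hotspots: tuple[str, ...] = ("HS1", "HS2", "HS3"),
    reference_assay: str = "gyrA",
) -> pd.DataFrame:
    """Raw adaptation scores per (sample, hotspot, replicate).

    ``cq_table`` is tidy with columns ``sample, assay, replicate, cq``.
    Returns a frame with columns ``pam, hotspot, replicate, score, flag``.
    """
    rows = []
    for (sample, rep), grp in cq_table.groupby(["sample", "replicate"]):
        ref = grp[grp["assay"] == reference_assay]
        if len(ref) != 1:
            raise CalibrationError(
                f"sample {sample!r} rep {rep}: need one {reference_assay} reaction"
            )
        cq_ref = float(ref["cq"].iloc[0])
        for hs in hotspots:
            row = grp[grp["assay"] == hs]
            if row.empty:
                continue
            sig = relative_signal(float(row["cq"].iloc[0]), cq_ref, efficiency)
            score, flag = adaptation_score(sig, curve)
            rows.append(
                {
                    "pam": sample,
                    "hotspot": hs,
                    "replicate": rep,
                    "score": score,
                    "flag": flag,
                }
            )
    return pd.DataFrame(rows)


def normalize_hotspot_scores(
    scores: pd.DataFrame, reference_pam: str = REFERENCE_PAM
) -> pd.DataFrame:
    """Rescale HS2/HS3 scores onto the HS1 scale via the reference PAM.

    The reference ratio uses the replicate-mean score of ``reference_pam``
    per hotspot.  HS1 scores pass through unchanged.  Adds a
    ``normalized_score`` column.
    """
    if reference_pam not in set(scores["pam"]):
        raise CalibrationError(f"reference PAM {reference_pam!r} not measured")
    ref = (
        scores[scores["pam"] == reference_pam]
        .groupby("hotspot")["score"]
        .mean()
    )
    hotspots = sorted(set(scores["hotspot"]))
    base_hs = hotspots[0]
    if base_hs not in ref.index:
        raise CalibrationError(f"reference PAM not measured on {base_hs}")
    factors = {}
    for hs in hotspots:
        if hs == base_hs:
            factors[hs] = 1.0
            continue
        if hs not in ref.index or ref[hs] == 0:
            raise CalibrationError(
                f"zero/missing reference score on {hs}: cannot normalize"
            )
        factors[hs] = ref[base_hs] / ref[hs]
    out = scores.copy()
    out["normalized_score"] = out["score"] * out["hotspot"].map(factors)
    return out


def average_scores(normalized: pd.DataFrame) -> pd.Series:
    """Mean normalized score per PAM over hotspots and measurements."""
    col = "normalized_score" if "normalized_score" in normalized else "score"
    return normalized.groupby("pam")[col].mean().rename("score")


def rescale_special_set(
    special_avg: pd.Series,
    general_avg: pd.Series,
    bridge_pam: str = BRIDGE_PAM,
) -> pd.Series:
    """Bring changed-context (starred) averaged scores onto the general scale.

    Every special-set score is multiplied by the ratio of the bridge PAM's
    averaged score in the general set to its score in the special set.
    Special entries may be named with a trailing ``*``.
    """
    special_key = (
        bridge_pam + "*" if bridge_pam + "*" in special_avg.index else bridge_pam
    )
    if special_key not in special_avg.index:
        raise CalibrationError(f"bridge PAM {bridge_pam!r} missing from special set")
    if bridge_pam not in general_avg.index:
        raise CalibrationError(f"bridge PAM {bridge_pam!r} missing from general set")
    denom = float(special_avg[special_key])
    if denom == 0:
        raise CalibrationError("bridge PAM score is zero in the special set")
    ratio = float(general_avg[bridge_pam]) / denom
    return (special_avg * ratio).rename("rescaled_score")
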