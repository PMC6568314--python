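"""Frequency normalization and the compositional depletion correction.

In a pooled loss assay, frequencies are compositional: once interfering PAM
plasmids are destroyed, the surviving variants' *relative* frequencies
inflate even though the number of cells carrying them is unchanged.  The
empirical correction identifies "depleted" PAMs — those whose frequency has
fallen below half of the uniform library share, ``0.5/64 = 1/128`` — and
rescales the sample by one minus the depleted mass.

Two conventions for the rescaling are supported (``mode="multiply"``,
the default, deflates the survivors; ``mode="divide"`` is the reciprocal)
and the depleted mass ``S`` can be summed either over the sample's own
frequencies or over a reference (CRISPR OFF control) row.  In the ON/OFF
pipeline the reference-summed multiply correction is used: the control
frequencies of the ON-depleted PAMs estimate the plasmid mass actually
lost, which is what survivor inflation must be deflated by.  Summing the
depleted PAMs' own residual frequencies measures only what is *left* of
them, which approaches zero exactly when the inflation is strongest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: A PAM counts as depleted when its frequency falls below half the uniform
#: library share.
DEPLETION_THRESHOLD = 0.5 / 64

#: Continuity correction (in reads) used for the OFF- and t0-normalized
#: ratio series, keeping log2 finite for fully depleted PAMs.
PSEUDOCOUNT = 0.5


class NormalizationError(ValueError):
    pass


@dataclass
class DepletionReport:
    """Per-sample record of the applied compositional correction."""

    sample: object
    depleted: tuple[str, ...]
    depleted_mass: float
    factor: float
    mode: str


def to_frequencies(counts: pd.DataFrame, pseudocount: float = 0.0) -> pd.DataFrame:
    """Row-normalize a count table to frequencies.

    Raises :class:`NormalizationError` for a zero-total sample (unless a
    pseudocount is supplied).
    """
    work = counts.astype(float) + pseudocount
    totals = work.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise NormalizationError(f"zero-total sample(s): {bad}")
    return work.div(totals, axis=0)


def find_depleted(
    f_sample: pd.Series, threshold: float = DEPLETION_THRESHOLD
) -> tuple[str, ...]:
    """PAMs whose frequency is strictly below the depletion threshold."""
    return tuple(f_sample.index[f_sample.to_numpy() < threshold])


def correct_frequencies(
    f_sample: pd.Series,
    mode: str = "multiply",
    threshold: float = DEPLETION_THRESHOLD,
    reference: pd.Series | None = None,
) -> tuple[pd.Series, DepletionReport]:
    """Apply the depleted-mass correction to one frequency row.

    The depleted set is found in ``f_sample``; its mass ``S`` is summed in
    ``reference`` when given (the paired control row), else in ``f_sample``
    itself.  ``mode="multiply"`` scales by ``1 - S``; ``mode="divide"``
    scales by ``1 / (1 - S)``.
    """
    if mode not in ("multiply", "divide"):
        raise NormalizationError(f"unknown mode {mode!r}")
    depleted = find_depleted(f_sample, threshold)
    source = f_sample if reference is None else reference
    mass = float(source[list(depleted)].sum()) if depleted else 0.0
    if mass >= 1.0:
        raise NormalizationError(
            f"depleted mass {mass:.3f} >= 1 for sample {f_sample.name!r}"
        )
    factor = (1.0 - mass) if mode == "multiply" else 1.0 / (1.0 - mass)
    corrected = f_sample * factor
    report = DepletionReport(
        sample=f_sample.name,
        depleted=depleted,
        depleted_mass=mass,
        factor=factor,
        mode=mode,
    )
    return corrected, report


def _require_paired(on: pd.DataFrame, off: pd.DataFrame) -> None:
    missing = on.index.difference(off.index)
    if len(missing):
        raise NormalizationError(
            f"missing OFF partner for sample(s): {missing.tolist()}"
        )


def correct_on_frequencies(
    f_on: pd.DataFrame,
    f_off: pd.DataFrame,
    mode: str = "multiply",
    threshold: float = DEPLETION_THRESHOLD,
) -> tuple[pd.DataFrame, list[DepletionReport]]:
    """Correct every CRISPR ON row against its paired OFF control row.

    ``f_on`` / ``f_off`` are indexed by (replicate, time) with 64 PAM
    columns.  The depleted set comes from the ON row, the depleted mass from
    the OFF row.
    """
    _require_paired(f_on, f_off)
    rows, reports = [], []
    for key in f_on.index:
        corrected, report = correct_frequencies(
            f_on.loc[key], mode=mode, threshold=threshold, reference=f_off.loc[key]
        )
        rows.append(corrected)
        reports.append(report)
    out = pd.DataFrame(rows)
    out.index = f_on.index
    return out, reports


def adjust_counts(
    on_counts: pd.DataFrame,
    off_counts: pd.DataFrame,
    corrected_f: pd.DataFrame,
    raw_f: pd.DataFrame,
) -> pd.DataFrame:
    """Put ON counts on the OFF scale and undo survivor inflation.

    ON sample totals are first matched to the paired OFF totals, then each
    PAM count is multiplied by the ratio of corrected to raw frequency.
    Zero-raw-frequency PAMs stay exactly zero.
    """
    _require_paired(on_counts, off_counts)
    totals_on = on_counts.sum(axis=1).astype(float)
    totals_off = off_counts.loc[on_counts.index].sum(axis=1).astype(float)
    scaled = on_counts.mul(totals_off / totals_on, axis=0)
    raw = raw_f.loc[on_counts.index]
    ratio = corrected_f.loc[on_counts.index] / raw.where(raw > 0)
    return (scaled * ratio.fillna(0.0)).where(raw > 0, 0.0)


def normalize_time_series(
    on_counts: pd.DataFrame,
    off_counts: pd.DataFrame,
    mode: str = "multiply",
    threshold: float = DEPLETION_THRESHOLD,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-PAM ratio series normalized to the OFF control and to t0.

    For every replicate and time ``t``::

        r(t) = [f_ON(t) / f_OFF(t)] / [f_ON(t0) / f_OFF(t0)]

    using depletion-corrected, pseudocounted ON frequencies.  ``r(t0) = 1``
    by construction.  Input frames are indexed by (replicate, time).  PAMs
    with a zero OFF frequency (possible only at ``pseudocount = 0``) come
    out NaN — flagged unquantifiable at that time.

    Returns a frame indexed by (replicate, time) with 64 PAM columns.
    """
    _require_paired(on_counts, off_counts)
    f_on = to_frequencies(on_counts, pseudocount=pseudocount)
    f_off = to_frequencies(off_counts, pseudocount=pseudocount)
    f_on_corr, _ = correct_on_frequencies(f_on, f_off, mode=mode, threshold=threshold)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = f_on_corr / f_off.loc[f_on_corr.index].replace(0.0, np.nan)
    replicates = ratio.index.get_level_values("replicate")
    times = ratio.index.get_level_values("time")
    t0 = times.min()
    out = []
    for rep in sorted(set(replicates)):
        block = ratio.loc[ratio.index[replicates == rep]]
        base = block.xs(t0, level="time")
        if base.shape[0] != 1:
            raise NormalizationError(f"replicate {rep}: need exactly one t0 sample")
        out.append(block / base.iloc[0])
    return pd.concat(out).sort_index()


@dataclass
class FrequencySet:
    """Raw and corrected frequency tables for one condition pair, plus the
    per-sample correction reports."""

    raw_on: pd.DataFrame
    raw_off: pd.DataFrame
    corrected_on: pd.DataFrame
    reports: list[DepletionReport] = field(default_factory=list)


def build_frequency_set(
    counts: pd.DataFrame,
    mode: str = "multiply",
    threshold: float = DEPLETION_THRESHOLD,
) -> FrequencySet:
    """Split a (condition, replicate, time)-indexed count table into ON/OFF
    frequency tables and apply the pipeline correction to the ON side."""
    for cond in ("ON", "OFF"):
        if cond not in counts.index.get_level_values("condition"):
            raise NormalizationError(f"missing condition {cond!r} in counts")
    on = counts.xs("ON", level="condition")
    off = counts.xs("OFF", level="condition")
    raw_on = to_frequencies(on)
    raw_off = to_frequencies(off)
    corrected, reports = correct_on_frequencies(
        raw_on, raw_off, mode=mode, threshold=threshold
    )
    return FrequencySet(
        raw_on=raw_on, raw_off=raw_off, corrected_on=corrected, reports=reports
    )
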