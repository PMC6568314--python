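"""End-to-end orchestration of the screen analysis stages.

Composes simulation, counting, normalization, classification and adaptation
scoring into reproducible runs with tabular outputs.  Every written table
carries header comments recording the package version, seed and
normalization mode, so a run can be reproduced from its outputs alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .adaptation import (
    average_scores,
    fit_calibration,
    normalize_hotspot_scores,
    rescale_special_set,
    scores_from_cq,
)
from .counting import count_pams
from .kinetics import (
    KineticClusterer,
    assign_groups,
    cluster_derivatives,
    kinetic_features,
)
from .normalize import FrequencySet, build_frequency_set, normalize_time_series
from .pams import group_sizes
from .simulate import (
    AcquisitionSimConfig,
    QpcrSimConfig,
    SimulationConfig,
    default_config,
    emit_fastq,
    fractions_from_kinetics,
    make_default_plasmid,
    simulate_acquisition,
    simulate_frequencies,
    simulate_qpcr,
)


def write_table(path: Path, df: pd.DataFrame, meta: dict) -> None:
    """Write a TSV with ``# key: value`` header comments."""
    with open(path, "w") as fh:
        fh.write(f"# pamscreen {__version__}\n")
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t")


@dataclass
class SimulationBundle:
    manifest: pd.DataFrame
    truth_counts: pd.DataFrame
    cq_table: pd.DataFrame
    calibration: pd.DataFrame
    spacers: list[str]
    plasmid: str
    truth: dict


def run_simulate(
    outdir: str | Path,
    seed: int = 0,
    config: SimulationConfig | None = None,
    qpcr_config: QpcrSimConfig | None = None,
    acquisition_config: AcquisitionSimConfig | None = None,
    write_files: bool = True,
) -> SimulationBundle:
    """Generate the full synthetic input bundle (FASTQ set, Cq CSVs, spacer
    FASTA) plus ``truth.json`` with every planted parameter."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config if config is not None else default_config(seed=seed)
    freqs = simulate_frequencies(cfg)
    manifest, truth_counts = emit_fastq(freqs, cfg, outdir / "fastq")
    fractions = fractions_from_kinetics(cfg)
    qcfg = qpcr_config
    if qcfg is None:
        measured = {
            p: f for p, f in fractions.items() if cfg.pam_groups[p] != "stable"
        }
        measured["CCG"] = 0.0  # stable negative control
        qcfg = QpcrSimConfig(true_fraction_expanded=measured, seed=seed)
    cq_table, calibration = simulate_qpcr(qcfg)
    plasmid, acfg = make_default_plasmid()
    if acquisition_config is not None:
        acfg = acquisition_config
        plasmid = acfg.plasmid
    else:
        acfg.seed = seed
    spacers, _ = simulate_acquisition(acfg)
    truth = {
        "seed": seed,
        "groups": cfg.pam_groups,
        "group_sizes": group_sizes(cfg.pam_groups),
        "decay_rates": cfg.decay_rates,
        "rate_overrides": cfg.rate_overrides,
        "induction_lag": cfg.induction_lag,
        "time_points": list(cfg.time_points),
        "reads_per_sample": cfg.reads_per_sample,
        "seq_error_rate": cfg.seq_error_rate,
        "protospacer": cfg.protospacer,
        "expanded_fractions": fractions,
        "hotspots": [list(h) for h in acfg.hotspots],
    }
    if write_files:
        manifest.to_csv(outdir / "manifest.csv", index=False)
        cq_table.to_csv(outdir / "cq.csv", index=False)
        calibration.to_csv(outdir / "calibration.csv", index=False)
        with open(outdir / "spacers.fasta", "w") as fh:
            for i, sp in enumerate(spacers):
                fh.write(f">spacer_{i}\n{sp}\n")
        with open(outdir / "plasmid.fasta", "w") as fh:
            fh.write(f">plasmid\n{plasmid}\n")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)
    return SimulationBundle(
        manifest=manifest,
        truth_counts=truth_counts,
        cq_table=cq_table,
        calibration=calibration,
        spacers=spacers,
        plasmid=plasmid,
        truth=truth,
    )


@dataclass
class InterferenceResult:
    counts: pd.DataFrame
    qc: pd.DataFrame
    freqs: FrequencySet
    ratio: pd.DataFrame
    log2fold: pd.DataFrame
    derivatives: pd.DataFrame
    clusterer: KineticClusterer
    groups: pd.DataFrame


def classify_counts(
    counts: pd.DataFrame,
    mode: str = "multiply",
    n_boot: int = 2000,
    seed: int = 0,
    metric: str = "euclidean",
) -> tuple[FrequencySet, pd.DataFrame, pd.DataFrame, pd.DataFrame, KineticClusterer, pd.DataFrame]:
    """Normalization through group assignment, starting from a
    (condition, replicate, time)-indexed count table."""
    freqs = build_frequency_set(counts, mode=mode)
    on = counts.xs("ON", level="condition")
    off = counts.xs("OFF", level="condition")
    ratio = normalize_time_series(on, off, mode=mode)
    lf, deriv = kinetic_features(ratio)
    clusterer = cluster_derivatives(deriv, n_boot=n_boot, seed=seed, metric=metric)
    groups = assign_groups(clusterer)
    return freqs, ratio, lf, deriv, clusterer, groups


def run_interference(
    manifest: pd.DataFrame,
    protospacer: str,
    outdir: str | Path | None = None,
    min_mean_quality: int = 32,
    min_length: int = 30,
    max_mismatches: int = 0,
    mode: str = "multiply",
    n_boot: int = 2000,
    seed: int = 0,
) -> InterferenceResult:
    """The full interference arm: count -> normalize -> features -> cluster.

    Writes counts.tsv, frequencies.tsv, logfold.tsv, derivatives.tsv,
    groups.tsv and qc.json when ``outdir`` is given.
    """
    counts, qc = count_pams(
        manifest,
        protospacer,
        min_mean_quality=min_mean_quality,
        min_length=min_length,
        max_mismatches=max_mismatches,
    )
    freqs, ratio, lf, deriv, clusterer, groups = classify_counts(
        counts, mode=mode, n_boot=n_boot, seed=seed
    )
    result = InterferenceResult(
        counts=counts,
        qc=qc,
        freqs=freqs,
        ratio=ratio,
        log2fold=lf,
        derivatives=deriv,
        clusterer=clusterer,
        groups=groups,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = {"seed": seed, "normalization_mode": mode, "n_boot": n_boot}
        write_table(outdir / "counts.tsv", counts, meta)
        raw = pd.concat(
            {"ON_raw": freqs.raw_on, "OFF_raw": freqs.raw_off, "ON_corrected": freqs.corrected_on},
            names=["table"],
        )
        write_table(outdir / "frequencies.tsv", raw, meta)
        write_table(outdir / "logfold.tsv", lf, meta)
        write_table(outdir / "derivatives.tsv", deriv, meta)
        write_table(outdir / "groups.tsv", groups, meta)
        with open(outdir / "qc.json", "w") as fh:
            json.dump(
                {
                    "samples": {
                        str(k): v for k, v in qc.to_dict(orient="index").items()
                    },
                    "group_sizes": groups["group"].value_counts().to_dict(),
                },
                fh,
                indent=1,
            )
    return result


def run_adaptation(
    cq_table: pd.DataFrame,
    calibration: pd.DataFrame,
    outdir: str | Path | None = None,
    efficiency: float = 2.0,
    special_cq_table: pd.DataFrame | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """The adaptation arm: calibrate, score, normalize, average (and bridge a
    changed-context set when supplied).  Returns the per-PAM score table."""
    curve = fit_calibration(calibration, efficiency=efficiency)
    scores = scores_from_cq(cq_table, curve, efficiency=efficiency)
    normalized = normalize_hotspot_scores(scores)
    averaged = average_scores(normalized).to_frame()
    averaged["source"] = "general"
    if special_cq_table is not None:
        s_scores = scores_from_cq(special_cq_table, curve, efficiency=efficiency)
        s_avg = s_scores.groupby("pam")["score"].mean()
        rescaled = rescale_special_set(s_avg, averaged["score"])
        extra = rescaled.to_frame(name="score")
        extra["source"] = "special_rescaled"
        averaged = pd.concat([averaged, extra])
    averaged = averaged.rename_axis("pam")
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = {
            "seed": seed,
            "efficiency": efficiency,
            "calibration_slope": f"{curve.slope_:.6g}",
            "calibration_r2": f"{curve.r2_:.4f}",
        }
        write_table(outdir / "scores_raw.tsv", normalized, meta)
        write_table(outdir / "scores.tsv", averaged, meta)
    return averaged
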