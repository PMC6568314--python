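"""Synthetic-data generation for the PAM screen pipeline.

Generates all three input kinds the analysis consumes, with known ground
truth so every downstream stage can be validated by parameter recovery:

* paired CRISPR ON / CRISPR OFF amplicon FASTQ time courses in which each
  read carries a fixed protospacer preceded by a variable trinucleotide PAM
  (:func:`simulate_frequencies`, :func:`emit_fastq`);
* qPCR quantification-cycle tables for hotspot-spacer and reference-gene
  assays plus calibration mixtures (:func:`simulate_qpcr`);
* acquired-spacer sequence sets drawn from a hotspot-weighted profile on a
  circular plasmid (:func:`simulate_acquisition`).

The interference model is a lagged single exponential per PAM: after an
induction lag ``L`` hours, the plasmid pool carrying PAM ``p`` decays at a
per-hour rate ``lambda(p)``, so its unnormalized abundance at time ``t`` is
``f0(p) * exp(-lambda(p) * max(0, t - L))``.  Observed frequencies are these
weights renormalized to sum to one (the compositional distortion the
normalization stage must undo), and sequencing is multinomial sampling with
per-base substitution errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pams import ALL_PAMS, GROUP_NAMES, reference_groups, revcomp

# ---------------------------------------------------------------------------
# default scenario constants
# ---------------------------------------------------------------------------

#: Sampling times in hours post-induction (T1..T6).
DEFAULT_TIME_POINTS = (0.0, 0.5, 1.0, 3.0, 6.0, 24.0)

#: Hours between induction and the onset of plasmid loss.
DEFAULT_LAG_H = 1.0

#: Per-hour decay rate of the rapidly interfered group.  Chosen so that an
#: interfering PAM is essentially exhausted two hours after the lag.
DEFAULT_INTERFERING_RATE = 4.0

#: Per-PAM decay rates for the intermediate group span this range (per hour),
#: log-spaced: attenuated interference is visibly heterogeneous, with the
#: fastest members approaching interfering-like depletion only late in the
#: time course and the slowest retaining ~10% of their plasmid at 24 h.
INTERMEDIATE_RATE_RANGE = (0.1, 0.3)

#: Rapidly interfered PAMs also differ somewhat in depletion speed; their
#: per-PAM rates are log-spaced over this range around the group default.
INTERFERING_RATE_RANGE = (3.0, 6.0)

#: A fixed 33-nt protospacer (synthetic stand-in for the G8 target sequence,
#: which is not printed in text form).
DEFAULT_PROTOSPACER = "TGGATTGATAATGGCTACGGCGACAGCCGGAAT"

#: Constant amplicon context.  The 5' flank ends in "AA" so that, as in the
#: screened library, AGN PAMs sit next to an off-register AAG trinucleotide.
DEFAULT_FLANK5 = "GGTCTGACGCTCAGTGGA" + "AA"
DEFAULT_FLANK3 = "CATCGTGGTGTCACGCTCGTCGTTTGGTATGGCTTCATTCAG"

#: Printed hotspot spacer sequences (33 nt each).
HOTSPOT_SEQUENCES = {
    "HS1": "GCTTTCCCTATAGTGAGTCGTATTAGAGCTTGG",
    "HS2": "GAGTATGAGCCATATTCAACGGGAAACGTCTTG",
    "HS3": "GAGTTGGTAGCTCTTGATCCGGCAAACAAACCA",
}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


# ---------------------------------------------------------------------------
# interference time-course simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Scenario definition for the pooled plasmid-loss experiment.

    Parameters
    ----------
    pam_groups
        Mapping PAM -> kinetic group; must cover all 64 trinucleotides.
    decay_rates
        Per-group decay rate in 1/h. ``stable`` must be 0 and
        ``interfering`` > ``intermediate`` > 0.
    rate_overrides
        Optional per-PAM rates that take precedence over the group rate
        (used to give intermediate members heterogeneous kinetics).
    induction_lag
        Hours before decay starts.
    time_points
        Strictly increasing sampling times, first element 0.
    reads_per_sample
        Sequencing depth per (condition, replicate, time) sample.
    n_replicates
        Technical replicate cultures.
    seq_error_rate
        Per-base substitution probability.
    f0_concentration
        Dirichlet concentration per PAM for the initial library composition;
        ``None`` gives a perfectly uniform library.
    quality_score
        Constant Phred score written for every base.
    """

    pam_groups: dict[str, str] = field(default_factory=reference_groups)
    decay_rates: dict[str, float] = field(
        default_factory=lambda: {
            "stable": 0.0,
            "interfering": DEFAULT_INTERFERING_RATE,
            "intermediate": float(np.sqrt(np.prod(INTERMEDIATE_RATE_RANGE))),
        }
    )
    rate_overrides: dict[str, float] = field(default_factory=dict)
    induction_lag: float = DEFAULT_LAG_H
    time_points: tuple[float, ...] = DEFAULT_TIME_POINTS
    reads_per_sample: int = 100_000
    n_replicates: int = 3
    seq_error_rate: float = 0.001
    protospacer: str = DEFAULT_PROTOSPACER
    flank5: str = DEFAULT_FLANK5
    flank3: str = DEFAULT_FLANK3
    f0_concentration: float | None = 100.0
    quality_score: int = 37
    seed: int = 0

    def validate(self) -> None:
        missing = set(ALL_PAMS) - set(self.pam_groups)
        if missing:
            raise ConfigurationError(f"pam_groups misses {len(missing)} PAMs")
        bad = {g for g in self.pam_groups.values() if g not in GROUP_NAMES}
        if bad:
            raise ConfigurationError(f"unknown groups: {sorted(bad)}")
        if self.decay_rates.get("stable", 0.0) != 0.0:
            raise ConfigurationError("stable decay rate must be 0")
        if not (
            self.decay_rates["interfering"] > self.decay_rates["intermediate"] > 0
        ):
            raise ConfigurationError(
                "need rate(interfering) > rate(intermediate) > 0"
            )
        tp = self.time_points
        if len(tp) < 2 or tp[0] != 0 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ConfigurationError(
                "time_points must be strictly increasing and start at 0"
            )
        if self.reads_per_sample <= 0:
            raise ConfigurationError("reads_per_sample must be positive")
        if not 0 <= self.seq_error_rate < 1:
            raise ConfigurationError("seq_error_rate must be in [0, 1)")
        if not 20 <= len(self.protospacer) <= 40:
            raise ConfigurationError("protospacer must be 20-40 nt")

    def rate(self, pam: str) -> float:
        if pam in self.rate_overrides:
            return float(self.rate_overrides[pam])
        return float(self.decay_rates[self.pam_groups[pam]])


def default_config(seed: int = 0, **kwargs) -> SimulationConfig:
    """The reference study scenario: published group structure, 6 time points,
    1e5 reads/sample, 3 replicates, heterogeneous intermediate kinetics."""
    cfg = SimulationConfig(seed=seed, **kwargs)
    overrides = {}
    for group, (lo, hi) in (
        ("intermediate", INTERMEDIATE_RATE_RANGE),
        ("interfering", INTERFERING_RATE_RANGE),
    ):
        members = sorted(p for p, g in cfg.pam_groups.items() if g == group)
        rates = np.geomspace(lo, hi, num=len(members))
        overrides.update(zip(members, rates.tolist()))
    overrides.update(cfg.rate_overrides)  # explicit overrides win
    cfg.rate_overrides = overrides
    return cfg


def _sample_rng(cfg: SimulationConfig, *key: int) -> np.random.Generator:
    """Deterministic per-sample generator derived from the scenario seed."""
    return np.random.default_rng([int(cfg.seed) & 0x7FFFFFFF, *key])


def simulate_frequencies(cfg: SimulationConfig) -> dict[str, pd.DataFrame]:
    """True per-sample PAM frequency trajectories.

    Returns ``{"ON": df, "OFF": df}`` with times as rows and the 64 PAMs as
    columns; every row sums to one.  OFF frequencies are constant at the
    initial composition ``f0``; ON frequencies are the lagged-exponential
    weights renormalized per time point.
    """
    cfg.validate()
    rng = _sample_rng(cfg, 0)
    if cfg.f0_concentration is None:
        f0 = np.full(64, 1.0 / 64)
    else:
        f0 = rng.dirichlet(np.full(64, float(cfg.f0_concentration)))
    rates = np.array([cfg.rate(p) for p in ALL_PAMS])
    times = np.asarray(cfg.time_points)
    active = np.clip(times[:, None] - cfg.induction_lag, 0.0, None)
    weights = f0[None, :] * np.exp(-rates[None, :] * active)
    on = weights / weights.sum(axis=1, keepdims=True)
    off = np.tile(f0, (len(times), 1))
    idx = pd.Index(times, name="time")
    return {
        "ON": pd.DataFrame(on, index=idx, columns=list(ALL_PAMS)),
        "OFF": pd.DataFrame(off, index=idx, columns=list(ALL_PAMS)),
    }


_BASE_LUT = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_LUT[_b] = _i
_IDX2BASE = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP_LUT = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP_LUT[_a] = _b


def _mutate(matrix: np.ndarray, error_rate: float, rng: np.random.Generator) -> None:
    """Apply uniform substitution errors in place to a byte matrix of reads."""
    if error_rate <= 0:
        return
    mask = rng.random(matrix.shape) < error_rate
    n = int(mask.sum())
    if n == 0:
        return
    idx = _BASE_LUT[matrix[mask]]
    shift = rng.integers(1, 4, size=n)
    matrix[mask] = _IDX2BASE[(idx + shift) % 4]


def _sample_reads(
    counts: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Byte matrix of reads (one row per read) for a per-PAM count vector."""
    amplicons = [
        (cfg.flank5 + pam + cfg.protospacer + cfg.flank3).encode()
        for pam in ALL_PAMS
    ]
    length = len(amplicons[0])
    total = int(counts.sum())
    matrix = np.empty((total, length), dtype=np.uint8)
    pos = 0
    for template, c in zip(amplicons, counts):
        c = int(c)
        if c:
            matrix[pos : pos + c] = np.frombuffer(template, dtype=np.uint8)
            pos += c
    _mutate(matrix, cfg.seq_error_rate, rng)
    # amplicons are sequenced from both ends: emit ~half the reads on the
    # reverse strand
    flip = rng.random(total) < 0.5
    matrix[flip] = _COMP_LUT[matrix[flip]][:, ::-1]
    return matrix


def write_fastq(path: Path, names: list[str], matrix: np.ndarray, qual_char: str) -> None:
    """Write a byte matrix of equal-length reads as Phred+33 FASTQ."""
    qual = qual_char * matrix.shape[1]
    reads = matrix.view(f"S{matrix.shape[1]}").ravel()
    with open(path, "w") as fh:
        fh.write(
            "".join(
                f"@{name}\n{seq.decode()}\n+\n{qual}\n"
                for name, seq in zip(names, reads)
            )
        )


def emit_fastq(
    freqs: dict[str, pd.DataFrame], cfg: SimulationConfig, outdir: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw multinomial reads per sample and write one FASTQ per
    (condition, replicate, time point).

    Returns ``(manifest, truth_counts)``: the manifest maps each sample to its
    FASTQ path; ``truth_counts`` holds the planted per-PAM multinomial draws
    (before sequencing errors), indexed by (condition, replicate, time).
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    qual_char = chr(cfg.quality_score + 33)
    manifest_rows = []
    truth_rows = []
    for ci, (condition, table) in enumerate(sorted(freqs.items())):
        for rep in range(1, cfg.n_replicates + 1):
            for ti, time in enumerate(table.index):
                rng = _sample_rng(cfg, 1, ci, rep, ti)
                probs = table.loc[time].to_numpy()
                counts = rng.multinomial(cfg.reads_per_sample, probs)
                matrix = _sample_reads(counts, cfg, rng)
                stem = f"{condition}_rep{rep}_t{_fmt_time(time)}"
                path = outdir / f"{stem}.fastq"
                names = [f"{stem}.{i}" for i in range(matrix.shape[0])]
                write_fastq(path, names, matrix, qual_char)
                manifest_rows.append(
                    {
                        "condition": condition,
                        "replicate": rep,
                        "time": float(time),
                        "path": str(path),
                    }
                )
                truth_rows.append(
                    pd.Series(
                        counts,
                        index=list(ALL_PAMS),
                        name=(condition, rep, float(time)),
                    )
                )
    manifest = pd.DataFrame(manifest_rows)
    truth = pd.DataFrame(truth_rows)
    truth.index = pd.MultiIndex.from_tuples(
        truth.index, names=["condition", "replicate", "time"]
    )
    return manifest, truth


def _fmt_time(t: float) -> str:
    return f"{float(t):g}".replace(".", "p")


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------


@dataclass
class QpcrSimConfig:
    """Generative model for hotspot-spacer qPCR assays.

    Quantification cycles follow the standard log-linear model
    ``Cq = intercept + slope * log10(percent expanded) + N(0, sd)``; the
    single-copy reference gene (gyrA) sits at a fixed baseline cycle.  A
    sample with no expanded arrays never amplifies and is reported censored
    (NaN), mirroring a water/mock control.
    """

    curve_slope: float = -3.32
    curve_intercept: float = 24.0  # Cq at 1% expanded arrays
    cq_noise_sd: float = 0.15
    reference_cq: float = 16.0
    true_fraction_expanded: dict[str, float] = field(default_factory=dict)
    n_replicates: int = 3
    calibration_percents: tuple[float, ...] = (0.1, 0.5, 2.0, 10.0, 50.0)
    hotspots: tuple[str, ...] = ("HS1", "HS2", "HS3")
    #: multiplicative hotspot-to-hotspot assay biases (HS1 fixed at 1); these
    #: are what the CAA-reference normalization must remove.
    hotspot_bias: dict[str, float] = field(default_factory=lambda: {"HS2": 1.6, "HS3": 0.7})
    seed: int = 0

    def validate(self) -> None:
        if self.cq_noise_sd < 0:
            raise ConfigurationError("cq_noise_sd must be >= 0")
        for k, v in self.true_fraction_expanded.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"fraction for {k!r} outside [0, 1]")
        if self.curve_slope >= 0:
            raise ConfigurationError("curve_slope must be negative")
        if len(self.calibration_percents) < 2:
            raise ConfigurationError("need >= 2 calibration mixtures")


def simulate_qpcr(qcfg: QpcrSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate sample and calibration Cq tables.

    Returns ``(cq_table, calibration_table)``.  Both are tidy frames with
    columns ``sample, assay, replicate, cq`` (the calibration table adds
    ``percent_expanded``); censored reactions carry ``cq = NaN``.
    """
    qcfg.validate()
    rng = np.random.default_rng([int(qcfg.seed) & 0x7FFFFFFF, 7])

    def cq_of(percent: float, bias: float) -> float:
        if percent <= 0:
            return math.nan
        cq = qcfg.curve_intercept + qcfg.curve_slope * math.log10(percent * bias)
        if qcfg.cq_noise_sd > 0:
            cq += rng.normal(0.0, qcfg.cq_noise_sd)
        return cq

    rows = []
    for sample, fraction in qcfg.true_fraction_expanded.items():
        for rep in range(1, qcfg.n_replicates + 1):
            for hs in qcfg.hotspots:
                bias = qcfg.hotspot_bias.get(hs, 1.0)
                rows.append(
                    {
                        "sample": sample,
                        "assay": hs,
                        "replicate": rep,
                        "cq": cq_of(fraction * 100.0, bias),
                    }
                )
            ref_cq = qcfg.reference_cq + (
                rng.normal(0.0, qcfg.cq_noise_sd) if qcfg.cq_noise_sd > 0 else 0.0
            )
            rows.append(
                {"sample": sample, "assay": "gyrA", "replicate": rep, "cq": ref_cq}
            )
    cq_table = pd.DataFrame(rows)

    cal_rows = []
    for percent in qcfg.calibration_percents:
        for rep in range(1, qcfg.n_replicates + 1):
            cal_rows.append(
                {
                    "sample": f"mix_{percent:g}",
                    "assay": "HS1",
                    "replicate": rep,
                    "cq": cq_of(percent, 1.0),
                    "percent_expanded": percent,
                }
            )
            ref_cq = qcfg.reference_cq + (
                rng.normal(0.0, qcfg.cq_noise_sd) if qcfg.cq_noise_sd > 0 else 0.0
            )
            cal_rows.append(
                {
                    "sample": f"mix_{percent:g}",
                    "assay": "gyrA",
                    "replicate": rep,
                    "cq": ref_cq,
                    "percent_expanded": percent,
                }
            )
    calibration = pd.DataFrame(cal_rows)
    return cq_table, calibration


def fractions_from_kinetics(
    cfg: SimulationConfig, horizon: float = 24.0, f_max: float = 0.25
) -> dict[str, float]:
    """Planted expanded-array fractions coupled to interference kinetics.

    Implements the kinetic (interference-driven) model of priming: the
    adaptation yield grows with the time window during which degradation
    products exist.  A PAM's plasmid persists until it is ~99.5% depleted
    (``lag + ln(200)/rate`` hours); acquisition accumulates toward a ceiling
    ``f_max`` with that persistence time, ``f_max * (1 - exp(-persist /
    horizon))``, so slowly interfered PAMs adapt most but the yield
    saturates rather than growing without bound.  Stable PAMs never
    generate degradation products and score zero.
    """
    fractions = {}
    for pam in ALL_PAMS:
        group = cfg.pam_groups[pam]
        if group == "stable":
            fractions[pam] = 0.0
            continue
        rate = cfg.rate(pam)
        persist = cfg.induction_lag + math.log(200.0) / rate
        fractions[pam] = f_max * (1.0 - math.exp(-persist / horizon))
    return fractions


# ---------------------------------------------------------------------------
# spacer-acquisition simulation
# ---------------------------------------------------------------------------


@dataclass
class AcquisitionSimConfig:
    """Generative model for primed spacer acquisition from a circular plasmid.

    Spacer start positions are drawn from a profile that mixes a uniform
    background with localized hotspots; each hotspot fixes a strand, the
    background picks strands at random.
    """

    plasmid: str = ""
    #: (plus-strand start position, strand '+'/'-', probability mass)
    hotspots: tuple[tuple[int, str, float], ...] = ()
    spacer_length: int = 33
    n_spacers: int = 10_000
    #: extra probability mass spread over positions whose 5'-adjacent
    #: trinucleotide is AAG (off-register consensus preference)
    pam_bias: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.plasmid:
            raise ConfigurationError("plasmid sequence required")
        if self.spacer_length > len(self.plasmid):
            raise ConfigurationError("spacer longer than plasmid")
        for pos, strand, w in self.hotspots:
            if strand not in "+-":
                raise ConfigurationError(f"bad strand {strand!r}")
            if w < 0:
                raise ConfigurationError("hotspot weights must be >= 0")
            if not 0 <= pos < len(self.plasmid):
                raise ConfigurationError("hotspot position outside plasmid")
        if sum(w for _, _, w in self.hotspots) > 1.0 + 1e-9:
            raise ConfigurationError("hotspot weights exceed 1")
        if not 0.0 <= self.pam_bias <= 1.0:
            raise ConfigurationError("pam_bias must be in [0, 1]")


def extract_window(plasmid: str, start: int, length: int, strand: str) -> str:
    """Excise ``length`` nt starting at plus-strand ``start`` with circular
    wrap-around; minus-strand windows are reverse complemented."""
    n = len(plasmid)
    start %= n
    window = (plasmid * 2)[start : start + length]
    return revcomp(window) if strand == "-" else window


def make_default_plasmid(length: int = 3300, seed: int = 7) -> tuple[str, AcquisitionSimConfig]:
    """A synthetic circular plasmid with the three printed hotspot spacers
    implanted, plus a matching acquisition scenario (hotspot shares 6/7/8%)."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    hs_positions = {"HS1": 500, "HS2": 1500, "HS3": 2500}
    chars = list(seq)
    for name, pos in hs_positions.items():
        hs = HOTSPOT_SEQUENCES[name]
        chars[pos : pos + len(hs)] = list(hs)
    plasmid = "".join(chars)
    cfg = AcquisitionSimConfig(
        plasmid=plasmid,
        hotspots=(
            (hs_positions["HS1"], "+", 0.06),
            (hs_positions["HS2"], "+", 0.07),
            (hs_positions["HS3"], "+", 0.08),
        ),
        seed=seed,
    )
    return plasmid, cfg


def simulate_acquisition(
    acfg: AcquisitionSimConfig,
) -> tuple[list[str], pd.DataFrame]:
    """Draw a multiset of acquired spacer sequences.

    Returns ``(spacers, truth)`` where ``truth`` records the planted
    (position, strand) of every draw.
    """
    acfg.validate()
    rng = np.random.default_rng([int(acfg.seed) & 0x7FFFFFFF, 11])
    n = len(acfg.plasmid)
    # probability over (strand, position): rows 0='+', 1='-'
    probs = np.zeros((2, n))
    hotspot_mass = sum(w for _, _, w in acfg.hotspots)
    background = max(0.0, 1.0 - hotspot_mass - acfg.pam_bias)
    probs += background / (2 * n)
    if acfg.pam_bias > 0:
        targets = []
        for strand_i, strand in enumerate("+-"):
            for pos in range(n):
                if strand == "+":
                    pam = extract_window(acfg.plasmid, pos - 3, 3, "+")
                else:
                    pam = extract_window(acfg.plasmid, pos + acfg.spacer_length, 3, "-")
                if pam == "AAG":
                    targets.append((strand_i, pos))
        if not targets:
            raise ConfigurationError("pam_bias > 0 but no AAG-adjacent position")
        for strand_i, pos in targets:
            probs[strand_i, pos] += acfg.pam_bias / len(targets)
    for pos, strand, w in acfg.hotspots:
        probs["+-".index(strand), pos] += w
    probs /= probs.sum()
    draws = rng.choice(2 * n, size=acfg.n_spacers, p=probs.ravel())
    strands = np.where(draws < n, "+", "-")
    positions = draws % n
    spacers = [
        extract_window(acfg.plasmid, int(p), acfg.spacer_length, s)
        for p, s in zip(positions, strands)
    ]
    truth = pd.DataFrame({"position": positions, "strand": strands})
    return spacers, truth
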