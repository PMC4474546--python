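"""Deterministic generator of synthetic RDML documents.

Every other module is testable without external files because this module
fabricates complete, valid documents of all three format versions: a
dilution series of standards with a known true amplification efficiency,
unknown samples, one no-template control, simulated sigmoid amplification
curves, melt curves, and the full metadata (experimenter, dye, cycling
program) a clean validation requires.

The fluorescence model is a logistic sigmoid

    F(c) = Fb + Fmax / (1 + exp(-(c - cMid) / k))

with baseline Fb = 0.05, plateau Fmax = 1.0 and slope parameter k = 1.2
cycles; cMid is placed so the threshold Fthr = 0.1 is crossed exactly at the
reaction's true Cq.  True Cq values follow the dilution law

    trueCq(input) = cqAtUnitInput - log10(input) / log10(E)

so a 10-fold dilution step shifts Cq by 1/log10(E) cycles (~3.32 for E = 2).
Additive Gaussian noise (SD ``noiseSd``) perturbs the fluorescence readings
and Gaussian Cq jitter (SD ``cqNoiseSd``) the dilution law.  The recorded Cq
is the threshold crossing of the simulated curve, interpolated on the logit
scale (exact for the noise-free sigmoid).  No-template controls carry flat
noise-only traces and no Cq.

One pseudo-random stream, seeded per document and consumed in a fixed
order (reactions by position; per reaction: Cq jitter, amplification noise,
melt noise), makes generation reproducible byte-for-byte through the writer.

These curves emulate the shape qPCR analysis software expects, not
amplification kinetics: there is no reagent depletion chemistry, no
per-reaction plateau variation and no dye crosstalk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from . import model as m
from .migrate import format_to_plate_type, plate_type_to_format

FLUOR_BASELINE = 0.05
FLUOR_MAX = 1.0
SIGMOID_K = 1.2  # cycles
FLUOR_THRESHOLD = 0.1
MELT_WIDTH = 1.5  # degC


@dataclass
class SyntheticTarget:
    id: str = "tgt1"
    #: fold-change per cycle, in (1, 2]
    trueEfficiency: float = 1.9
    #: Cq of a reaction with one unit of input (log10 input = 0)
    cqAtUnitInput: float = 35.0
    meltTm: float = 85.0  # degC


@dataclass
class DilutionSeries:
    topLog10Input: float = 5.0
    steps: int = 5
    foldPerStep: float = 10.0
    replicates: int = 2


@dataclass
class SyntheticRunSpec:
    version: str = "1.2"
    #: explicit geometry, or a version-1.0 plate-type token such as "96-well"
    plate: Union[m.PcrFormat, str] = field(
        default_factory=lambda: m.PcrFormat(rows=8, columns=12))
    targets: list[SyntheticTarget] = field(
        default_factory=lambda: [SyntheticTarget()])
    dilutionSeries: DilutionSeries = field(default_factory=DilutionSeries)
    unknowns: int = 2
    unknownLog10Input: float = 3.0
    cycles: int = 40
    noiseSd: float = 0.002  # fluorescence units
    cqNoiseSd: float = 0.05  # cycles
    #: tag each sample with a group annotation (1.2 documents only)
    annotateSamples: bool = True
    includeMelt: bool = True
    seed: int = 42


def _check_spec(spec: SyntheticRunSpec) -> None:
    if spec.version not in m.SUPPORTED_VERSIONS:
        raise m.InvalidSpecError(f"unsupported version {spec.version!r}")
    for t in spec.targets:
        if not (1.0 < t.trueEfficiency <= 2.0):
            raise m.InvalidSpecError(
                f"trueEfficiency {t.trueEfficiency} outside (1, 2]")
    if spec.dilutionSeries.steps < 1:
        raise m.InvalidSpecError("dilution series needs >= 1 step")
    if spec.cycles < 10:
        raise m.InvalidSpecError("need >= 10 cycles")
    if not spec.targets:
        raise m.InvalidSpecError("need >= 1 target")


def true_cq(log10_input: float, efficiency: float, cq_at_unit: float) -> float:
    """Dilution law: Cq at a given log10 input for a target."""
    return cq_at_unit - log10_input / math.log10(efficiency)


def _sigmoid_midpoint(cq: float) -> float:
    # F(trueCq) = Fthr  =>  cMid = trueCq + k * ln((Fmax/(Fthr-Fb)) - 1)
    return cq + SIGMOID_K * math.log(
        FLUOR_MAX / (FLUOR_THRESHOLD - FLUOR_BASELINE) - 1.0)


def simulate_amplification(
    true_cq_value: float, cycles: int, noise_sd: float,
    rng: np.random.Generator,
) -> list[float]:
    """Fluorescence per cycle (1..cycles) of one amplification reaction."""
    if not (0 < true_cq_value < cycles):
        raise m.InvalidSpecError(
            f"trueCq {true_cq_value} outside (0, {cycles})")
    c = np.arange(1, cycles + 1, dtype=float)
    mid = _sigmoid_midpoint(true_cq_value)
    f = FLUOR_BASELINE + FLUOR_MAX / (1.0 + np.exp(-(c - mid) / SIGMOID_K))
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=f.shape)
    return [float(v) for v in f]


def simulate_flat(cycles: int, noise_sd: float,
                  rng: np.random.Generator) -> list[float]:
    """Baseline-only trace for a no-template control."""
    f = np.full(cycles, FLUOR_BASELINE)
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=f.shape)
    return [float(v) for v in f]


def simulate_melt(
    tm: float,
    temp_range: tuple[float, float] = (60.0, 95.0),
    step: float = 0.5,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> list[tuple[float, float]]:
    """(temperature, fluorescence) pairs of a product melt curve.

    A decreasing sigmoid centred at *tm* (width 1.5 degC): in the noise-free
    case the negative first difference peaks within one step of tm.
    """
    lo, hi = temp_range
    if not (lo < tm < hi):
        raise m.InvalidSpecError(f"tm {tm} outside range {temp_range}")
    t = np.arange(lo, hi + step / 2, step)
    f = FLUOR_BASELINE + FLUOR_MAX / (1.0 + np.exp((t - tm) / MELT_WIDTH))
    if noise_sd > 0 and rng is not None:
        f = f + rng.normal(0.0, noise_sd, size=f.shape)
    return [(float(a), float(b)) for a, b in zip(t, f)]


def cq_from_curve(
    fluorescence: Sequence[float],
    threshold: float = FLUOR_THRESHOLD,
    baseline: float = FLUOR_BASELINE,
    fmax: float = FLUOR_MAX,
) -> Optional[float]:
    """Fractional cycle at which the trace first crosses *threshold*.

    Interpolation is linear on the logit of the baseline-corrected,
    plateau-normalized signal, which inverts the generator's sigmoid exactly
    in the noise-free case; None when the trace never crosses.
    """
    f = np.asarray(fluorescence, dtype=float)
    above = f >= threshold
    if not above.any() or above[0]:
        return None
    i = int(np.argmax(above))  # first crossing; cycles are 1-based
    eps = 1e-12

    def logit(v: float) -> float:
        p = min(max((v - baseline) / fmax, eps), 1.0 - eps)
        return math.log(p / (1.0 - p))

    z0, z1, zt = logit(f[i - 1]), logit(f[i]), logit(threshold)
    if z1 == z0:
        return float(i + 1)
    return float(i + (zt - z0) / (z1 - z0))


def generate_document(spec: Optional[SyntheticRunSpec] = None) -> m.RdmlDocument:
    """Build a complete document per *spec* (defaults: 1.2, 96-well, one
    target at E = 1.9, 5x10-fold series in duplicate, 2 unknowns, 1 NTC)."""
    spec = spec or SyntheticRunSpec()
    _check_spec(spec)
    rng = np.random.default_rng(spec.seed)

    doc = m.RdmlDocument(version=spec.version, dateMade="2014-10-01T12:00:00")
    doc.experimenters.append(m.Experimenter(
        id="exp1", firstName="Synth", lastName="Operator",
        email="synth.operator@example.org"))
    doc.documentations.append(m.Documentation(
        id="doc1", text="synthetic dataset generated by rdmlkit"))
    doc.dyes.append(m.Dye(id="SYBR", description="intercalating dye"))
    v12 = spec.version == "1.2"

    for t in spec.targets:
        doc.targets.append(m.Target(
            id=t.id, targetType="target-of-interest", dyeRef="SYBR",
            sequences=m.TargetSequences(
                forwardPrimer="ACGTACGTACGTACGTACGT",
                reversePrimer="TGCATGCATGCATGCATGCA"),
        ))
    doc.thermalCyclingConditions.append(m.CyclingProgram(
        id="cyc1", description="2-step qPCR",
        steps=[
            m.CyclingStep(temperature=95.0, duration=600.0),
            m.CyclingStep(temperature=95.0, duration=15.0),
            m.CyclingStep(temperature=60.0, duration=60.0, acquire=True),
        ]))

    series = spec.dilutionSeries

    def add_annotation(sample: m.Sample, group: str) -> None:
        if v12 and spec.annotateSamples:
            sample.annotations.append(
                m.Annotation(property="sample-group", value=group))

    # samples: standards with known quantity, unknowns, one NTC
    standard_log10: dict[str, float] = {}
    for i in range(series.steps):
        log10_input = series.topLog10Input - i * math.log10(series.foldPerStep)
        sid = f"std_{i + 1}"
        sample = m.Sample(
            id=sid, sampleType="standard",
            description=f"dilution step {i + 1}",
            quantity=m.Quantity(value=10.0 ** log10_input, unit="copies"),
            material="dna")
        add_annotation(sample, "standard")
        doc.samples.append(sample)
        standard_log10[sid] = log10_input
    for i in range(spec.unknowns):
        sample = m.Sample(id=f"unk_{i + 1}", sampleType="unknown")
        add_annotation(sample, "unknown")
        doc.samples.append(sample)
    ntc = m.Sample(id="ntc_1", sampleType="no-template-control")
    add_annotation(ntc, "control")
    doc.samples.append(ntc)

    # plate geometry
    if isinstance(spec.plate, str):
        plate_token: Optional[str] = spec.plate
        fmt = plate_type_to_format(spec.plate)
    else:
        fmt = m.PcrFormat(rows=spec.plate.rows, columns=spec.plate.columns)
        plate_token = (format_to_plate_type(fmt)
                       if spec.version == "1.0" else None)
    run = m.Run(
        id="run1", description="synthetic run", pcrFormat=fmt,
        plateType=plate_token if spec.version == "1.0" else None)

    # reaction layout: standards (each replicated), unknowns, NTC
    layout: list[tuple[str, Optional[float]]] = []
    for i in range(series.steps):
        for _ in range(series.replicates):
            sid = f"std_{i + 1}"
            layout.append((sid, standard_log10[sid]))
    for i in range(spec.unknowns):
        layout.append((f"unk_{i + 1}", spec.unknownLog10Input))
    layout.append(("ntc_1", None))
    if len(layout) > fmt.size:
        raise m.InvalidSpecError(
            f"{len(layout)} reactions do not fit a "
            f"{fmt.rows}x{fmt.columns} plate")

    for position, (sample_id, log10_input) in enumerate(layout, start=1):
        react = m.Reaction(position=position, sampleRef=sample_id)
        for t in spec.targets:
            data = m.ReactionData(
                targetRef=t.id,
                baseline=FLUOR_BASELINE,
                quantificationThreshold=FLUOR_THRESHOLD)
            if log10_input is None:  # no-template control
                data.amplificationPoints = [
                    (float(c), f) for c, f in zip(
                        range(1, spec.cycles + 1),
                        simulate_flat(spec.cycles, spec.noiseSd, rng))]
                data.cq = None
            else:
                cq = true_cq(log10_input, t.trueEfficiency, t.cqAtUnitInput)
                if spec.cqNoiseSd > 0:
                    cq += float(rng.normal(0.0, spec.cqNoiseSd))
                trace = simulate_amplification(
                    cq, spec.cycles, spec.noiseSd, rng)
                data.amplificationPoints = [
                    (float(c), f) for c, f in
                    zip(range(1, spec.cycles + 1), trace)]
                data.cq = cq_from_curve(trace)
                if spec.includeMelt:
                    data.meltingPoints = simulate_melt(
                        t.meltTm, noise_sd=spec.noiseSd, rng=rng)
            react.data.append(data)
        run.reactions.append(react)

    doc.experiments.append(m.Experiment(
        id="exp_run", description="synthetic experiment", runs=[run]))
    return doc
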