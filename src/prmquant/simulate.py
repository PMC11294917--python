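"""Synthetic LC-MS acquisition generator for PRM, DDA and MRM modes.

The simulator emulates a targeted small-molecule experiment well enough to
exercise every downstream stage: Gaussian chromatographic peaks on a fixed
duty-cycle scan grid, inclusion-list PRM scheduling (precursor intensity
threshold, per-cycle candidate cap, retention-time windows), DDA top-N
selection with dynamic exclusion, MRM transition traces on a uniform dwell
grid, multiplicative log-normal intensity noise, and in-source cleavage of
glycosides into their aglycones.

In-source fragmentation is modelled as a logistic function of the source
desolvation temperature T:

    f(T) = 1 / (1 + exp(−(T − 450)/40))

so that half of a glycoside's signal is lost at 450 °C and the loss grows
monotonically with temperature.  The intact-precursor signal of a glycoside
is attenuated by (1 − f) in every mode, and the cleaved fraction f is
deposited as an aglycone ion in MS1 scans.  The functional form and its
midpoint/scale are simulator configuration, not claims about any
instrument.

Every simulation returns a truth table (true concentrations, closed-form
Gaussian MS1 peak areas, emitted MS2 scan ids, applied in-source fractions)
so extraction and quantitation can be verified against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .extract import compute_adduct_mz, select_top_fragments
from .msdata import InclusionEntry, ReferenceSpectrum, Run, Spectrum, TransitionTrace

__all__ = [
    "SimTarget",
    "AcquisitionConfig",
    "TargetTruth",
    "TruthTable",
    "insource_fraction",
    "simulate_prm_run",
    "simulate_dda_run",
    "simulate_mrm_traces",
    "simulate_calibration_series",
    "default_panel",
    "inclusion_list_from_targets",
    "reference_spectra_from_targets",
]

# monoisotopic masses (Da) used for the default panel
_H = 1.0078250319
_C = 12.0
_O = 15.9949146221
_D = 2.0141017780
_HEXOSE_LOSS = 162.052824  # anhydroglucose, typical glycosidic-bond cleavage


@dataclass(frozen=True)
class SimTarget:
    """One simulated analyte: chromatography, response and fragmentation."""

    target_id: str
    neutral_mass: float
    adduct: str
    rt_apex: float  # minutes
    peak_sigma: float  # minutes
    response_factor: float  # cps per (ng/mL)
    concentration: float  # ng/mL
    fragments: tuple[tuple[float, float], ...]  # (m/z, relative intensity)
    is_glycoside: bool = False
    aglycone_target_id: str | None = None

    def __post_init__(self) -> None:
        if not self.peak_sigma > 0:
            raise ValueError(f"{self.target_id}: peak_sigma must be > 0")
        if not self.response_factor > 0:
            raise ValueError(f"{self.target_id}: response_factor must be > 0")
        if self.concentration < 0:
            raise ValueError(f"{self.target_id}: concentration must be >= 0")

    @property
    def precursor_mz(self) -> float:
        return compute_adduct_mz(self.neutral_mass, self.adduct)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Instrument-level settings for a simulated acquisition.

    Defaults are the PRM settings of the emulated platform: a 1.1001 s duty
    cycle holding one 250 ms MS1 scan plus up to eight 100 ms MS2 events,
    a 50 cps precursor scheduling threshold and 1 min retention-time
    windows over a 12 min gradient.  ``for_dda`` returns the corresponding
    DDA settings (700 ms cycle, top-4 selection, 30 s dynamic exclusion
    after 3 acquisitions).
    """

    cycle_time: float = 1.1001  # s
    ms1_accumulation: float = 250.0  # ms
    ms2_accumulation: float = 100.0  # ms
    max_candidates_per_cycle: int = 8
    precursor_threshold: float = 50.0  # cps
    rt_window: float = 1.0  # minutes, full width
    gradient_length: float = 12.0  # minutes
    desolvation_temperature: float = 550.0  # deg C
    noise_cv: float = 0.0  # fractional multiplicative noise
    baseline_counts: float = 0.0  # additive background, cps
    mz_tol_ppm: float = 25.0  # instrument m/z matching tolerance
    dda_exclusion_after: int = 3  # MS2 acquisitions before exclusion
    dda_exclusion_s: float = 30.0  # s
    mrm_dwell: float = 0.5  # s between MRM trace points
    seed: int = 0

    def __post_init__(self) -> None:
        budget = self.ms1_accumulation + self.max_candidates_per_cycle * self.ms2_accumulation
        if self.cycle_time * 1000.0 < budget:
            raise ValueError(
                f"cycle_time {self.cycle_time:.4f} s cannot hold "
                f"{self.ms1_accumulation:.0f} ms MS1 + "
                f"{self.max_candidates_per_cycle} x {self.ms2_accumulation:.0f} ms MS2"
            )
        if self.precursor_threshold < 0 or self.baseline_counts < 0:
            raise ValueError("count thresholds must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    @classmethod
    def for_dda(cls, **overrides) -> "AcquisitionConfig":
        defaults = dict(cycle_time=0.7, max_candidates_per_cycle=4)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class TargetTruth:
    """Ground truth for one target in one simulated run."""

    target_id: str
    concentration: float
    ms1_area: float  # closed-form Gaussian area of the intact precursor, counts*min
    insource_fraction: float
    ms2_scan_ids: list[str] = field(default_factory=list)


@dataclass
class TruthTable:
    targets: dict[str, TargetTruth]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for truth in self.targets.values():
            for sid in truth.ms2_scan_ids:
                if sid in seen:
                    raise ValueError(f"MS2 scan id {sid!r} emitted twice")
                seen.add(sid)


def insource_fraction(temperature: float, midpoint: float = 450.0, scale: float = 40.0) -> float:
    """Fraction of a glycoside cleaved in the source at a given temperature."""
    return 1.0 / (1.0 + math.exp(-(temperature - midpoint) / scale))


def _noise_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Mean-1 multiplicative log-normal factors with the requested CV."""
    if cv <= 0:
        return np.ones(n)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=n))


def _gauss(t: float, apex: float, sigma: float) -> float:
    z = (t - apex) / sigma
    return math.exp(-0.5 * z * z) if abs(z) < 8.0 else 0.0


def _intact_fraction(target: SimTarget, temperature: float) -> float:
    return 1.0 - insource_fraction(temperature) if target.is_glycoside else 1.0


def _aglycone_mz(target: SimTarget, by_id: dict[str, SimTarget]) -> float:
    partner = by_id.get(target.aglycone_target_id) if target.aglycone_target_id else None
    if partner is not None:
        return partner.precursor_mz
    return target.precursor_mz - _HEXOSE_LOSS


def _truth_for(targets: list[SimTarget], temperature: float) -> dict[str, TargetTruth]:
    out = {}
    for t in targets:
        f = insource_fraction(temperature) if t.is_glycoside else 0.0
        area = t.response_factor * t.concentration * (1.0 - f) * t.peak_sigma * math.sqrt(2 * math.pi)
        out[t.target_id] = TargetTruth(t.target_id, t.concentration, area, f)
    return out


def _ms1_sticks(
    targets: list[SimTarget],
    by_id: dict[str, SimTarget],
    t: float,
    temperature: float,
    noise: np.ndarray,
    baseline: float,
) -> tuple[np.ndarray, np.ndarray]:
    """All MS1 centroids at time t: intact precursors plus aglycone deposits."""
    mzs: list[float] = []
    intens: list[float] = []
    for i, tgt in enumerate(targets):
        g = tgt.response_factor * tgt.concentration * _gauss(t, tgt.rt_apex, tgt.peak_sigma)
        if g <= 0 and baseline <= 0:
            continue
        intact = g * _intact_fraction(tgt, temperature) * noise[2 * i] + baseline
        if intact > 0:
            mzs.append(tgt.precursor_mz)
            intens.append(intact)
        if tgt.is_glycoside:
            shed = g * insource_fraction(temperature) * noise[2 * i + 1]
            if shed > 0:
                mzs.append(_aglycone_mz(tgt, by_id))
                intens.append(shed)
    mz = np.asarray(mzs, dtype=float)
    inten = np.asarray(intens, dtype=float)
    order = np.argsort(mz, kind="stable")
    return mz[order], inten[order]


def _measured_at(mz: np.ndarray, inten: np.ndarray, query: float, tol_ppm: float) -> float:
    tol = query * tol_ppm * 1e-6
    lo = np.searchsorted(mz, query - tol, side="left")
    hi = np.searchsorted(mz, query + tol, side="right")
    return float(inten[lo:hi].sum()) if hi > lo else 0.0


def simulate_prm_run(
    targets: list[SimTarget],
    inclusion: list[InclusionEntry],
    config: AcquisitionConfig,
    sample_id: str = "sim_prm",
) -> tuple[Run, TruthTable]:
    """Simulate a PRM acquisition driven by an inclusion list.

    Per cycle: one MS1 scan of all species, then MS2 events for inclusion
    entries whose measured MS1 intensity strictly exceeds the scheduling
    threshold and whose event time falls inside their retention-time
    window, ranked by MS1 intensity (ties toward lower m/z) and capped at
    the per-cycle candidate maximum.
    """
    rng = np.random.default_rng(config.seed)
    by_id = {t.target_id: t for t in targets}
    truth = _truth_for(targets, config.desolvation_temperature)
    cycle_min = config.cycle_time / 60.0
    n_cycles = int(math.floor(config.gradient_length * 60.0 / config.cycle_time))
    spectra: list[Spectrum] = []
    for k in range(n_cycles):
        t0 = k * cycle_min
        noise = _noise_factors(rng, 2 * len(targets), config.noise_cv)
        mz, inten = _ms1_sticks(
            targets, by_id, t0, config.desolvation_temperature, noise, config.baseline_counts
        )
        spectra.append(Spectrum(f"cycle{k}_ms1", 1, t0, mz, inten))
        measured = [
            (_measured_at(mz, inten, e.precursor_mz, config.mz_tol_ppm), e) for e in inclusion
        ]
        ranked = sorted(
            (m for m in measured if m[0] > config.precursor_threshold),
            key=lambda pair: (-pair[0], pair[1].precursor_mz),
        )
        slot = 0
        for intensity, entry in ranked:
            if slot >= config.max_candidates_per_cycle:
                break
            t_event = t0 + (config.ms1_accumulation + slot * config.ms2_accumulation) / 60000.0
            if abs(t_event - entry.rt_center) > entry.rt_window / 2.0:
                continue
            scan_id = f"cycle{k}_ms2_{entry.target_id}"
            tgt = by_id.get(entry.target_id)
            if tgt is not None:
                base = (
                    tgt.response_factor
                    * tgt.concentration
                    * _gauss(t_event, tgt.rt_apex, tgt.peak_sigma)
                    * _intact_fraction(tgt, config.desolvation_temperature)
                )
                fnoise = _noise_factors(rng, len(tgt.fragments), config.noise_cv)
                fmz = np.array([f[0] for f in tgt.fragments])
                finten = np.array([f[1] for f in tgt.fragments]) * base * fnoise
                keep = finten > 0
                fmz, finten = fmz[keep], finten[keep]
            else:  # decoy entry: matched signal but no known fragments
                fmz = np.empty(0)
                finten = np.empty(0)
            spectra.append(
                Spectrum(
                    scan_id,
                    2,
                    t_event,
                    fmz,
                    finten,
                    precursor_mz=entry.precursor_mz,
                    collision_energy=35.0,
                )
            )
            if entry.target_id in truth:
                truth[entry.target_id].ms2_scan_ids.append(scan_id)
            slot += 1
    run = Run(sample_id=sample_id, spectra=spectra, metadata={"mode": "prm"})
    return run, TruthTable(truth)


def simulate_dda_run(
    targets: list[SimTarget],
    config: AcquisitionConfig,
    sample_id: str = "sim_dda",
) -> tuple[Run, TruthTable]:
    """Simulate a DDA acquisition: per cycle, fragment the most intense
    precursors above threshold (top ``max_candidates_per_cycle``), with each
    precursor dynamically excluded for ``dda_exclusion_s`` seconds after
    ``dda_exclusion_after`` MS2 acquisitions."""
    rng = np.random.default_rng(config.seed)
    by_id = {t.target_id: t for t in targets}
    truth = _truth_for(targets, config.desolvation_temperature)
    cycle_min = config.cycle_time / 60.0
    n_cycles = int(math.floor(config.gradient_length * 60.0 / config.cycle_time))
    spectra: list[Spectrum] = []
    acq_count: dict[str, int] = {}
    excluded_until: dict[str, float] = {}
    for k in range(n_cycles):
        t0 = k * cycle_min
        t0_s = t0 * 60.0
        noise = _noise_factors(rng, 2 * len(targets), config.noise_cv)
        mz, inten = _ms1_sticks(
            targets, by_id, t0, config.desolvation_temperature, noise, config.baseline_counts
        )
        spectra.append(Spectrum(f"cycle{k}_ms1", 1, t0, mz, inten))
        candidates = []
        for tgt in targets:
            m = _measured_at(mz, inten, tgt.precursor_mz, config.mz_tol_ppm)
            if m > config.precursor_threshold and t0_s >= excluded_until.get(tgt.target_id, -1.0):
                candidates.append((m, tgt))
        candidates.sort(key=lambda pair: (-pair[0], pair[1].precursor_mz))
        for slot, (m, tgt) in enumerate(candidates[: config.max_candidates_per_cycle]):
            t_event = t0 + (config.ms1_accumulation + slot * config.ms2_accumulation) / 60000.0
            base = (
                tgt.response_factor
                * tgt.concentration
                * _gauss(t_event, tgt.rt_apex, tgt.peak_sigma)
                * _intact_fraction(tgt, config.desolvation_temperature)
            )
            fnoise = _noise_factors(rng, len(tgt.fragments), config.noise_cv)
            fmz = np.array([f[0] for f in tgt.fragments])
            finten = np.array([f[1] for f in tgt.fragments]) * base * fnoise
            keep = finten > 0
            scan_id = f"cycle{k}_ms2_{tgt.target_id}"
            spectra.append(
                Spectrum(
                    scan_id,
                    2,
                    t_event,
                    fmz[keep],
                    finten[keep],
                    precursor_mz=tgt.precursor_mz,
                    collision_energy=35.0,
                )
            )
            truth[tgt.target_id].ms2_scan_ids.append(scan_id)
            n = acq_count.get(tgt.target_id, 0) + 1
            if n >= config.dda_exclusion_after:
                excluded_until[tgt.target_id] = t0_s + config.dda_exclusion_s
                acq_count[tgt.target_id] = 0
            else:
                acq_count[tgt.target_id] = n
    run = Run(sample_id=sample_id, spectra=spectra, metadata={"mode": "dda"})
    return run, TruthTable(truth)


def simulate_mrm_traces(
    targets: list[SimTarget],
    config: AcquisitionConfig,
) -> list[TransitionTrace]:
    """Simulate MRM transition traces on a uniform dwell grid.

    Each target's most intense fragment defines the monitored transition;
    a glycoside's sensitivity is attenuated by its intact fraction
    (1 − f(T)), reproducing the depressed response of steroidal saponins at
    harsh source temperatures."""
    rng = np.random.default_rng(config.seed)
    dwell_min = config.mrm_dwell / 60.0
    n_points = int(math.floor(config.gradient_length / dwell_min)) + 1
    grid = np.arange(n_points) * dwell_min
    traces = []
    for tgt in targets:
        if not tgt.fragments:
            raise ValueError(f"{tgt.target_id}: MRM simulation needs >= 1 fragment")
        product = min(tgt.fragments, key=lambda f: (-f[1], f[0]))[0]
        z = (grid - tgt.rt_apex) / tgt.peak_sigma
        signal = (
            tgt.response_factor
            * tgt.concentration
            * np.exp(-0.5 * z * z)
            * _intact_fraction(tgt, config.desolvation_temperature)
        )
        noise = _noise_factors(rng, n_points, config.noise_cv)
        traces.append(
            TransitionTrace(
                target_id=tgt.target_id,
                precursor_mz=tgt.precursor_mz,
                product_mz=product,
                rt=grid,
                intensity=signal * noise + config.baseline_counts,
            )
        )
    return traces


def simulate_calibration_series(
    targets: list[SimTarget],
    levels: list[float],
    replicates: int,
    config: AcquisitionConfig,
    mode: str = "prm",
    internal_standard_id: str | None = None,
):
    """One simulated acquisition per level x replicate, plus the design table.

    Analyte concentrations are set to the level; the internal standard (if
    named) keeps its fixed panel concentration in every run.  Returns
    ``(acquisitions, design)`` where each acquisition is
    ``(sample_id, run_or_traces, truth_or_None)`` and the design is the CSV
    table consumed by the calibration stage.
    """
    if any(lvl <= 0 for lvl in levels):
        raise ValueError("calibration levels must be > 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if mode not in ("prm", "dda", "mrm"):
        raise ValueError(f"unknown mode {mode!r}")
    acquisitions = []
    design_rows = []
    run_index = 0
    for level in levels:
        for rep in range(1, replicates + 1):
            adjusted = [
                t if t.target_id == internal_standard_id else replace(t, concentration=level)
                for t in targets
            ]
            sub = replace(config, seed=(config.seed + 7919 * run_index) % (2**31))
            run_index += 1
            sample_id = f"cal_{mode}_{level:g}_r{rep}"
            if mode == "prm":
                run, truth = simulate_prm_run(
                    adjusted, inclusion_list_from_targets(adjusted, sub.rt_window), sub, sample_id
                )
                acquisitions.append((sample_id, run, truth))
            elif mode == "dda":
                run, truth = simulate_dda_run(adjusted, sub, sample_id)
                acquisitions.append((sample_id, run, truth))
            else:
                acquisitions.append((sample_id, simulate_mrm_traces(adjusted, sub), None))
            for t in adjusted:
                design_rows.append(
                    {
                        "sample_id": sample_id,
                        "target_id": t.target_id,
                        "concentration_ng_ml": t.concentration,
                        "replicate": rep,
                    }
                )
    return acquisitions, pd.DataFrame(design_rows)


def inclusion_list_from_targets(
    targets: list[SimTarget], rt_window: float = 1.0
) -> list[InclusionEntry]:
    return [
        InclusionEntry(t.target_id, t.precursor_mz, t.rt_apex, rt_window, 1) for t in targets
    ]


def reference_spectra_from_targets(targets: list[SimTarget]) -> dict[str, ReferenceSpectrum]:
    return {
        t.target_id: ReferenceSpectrum(t.target_id, tuple(t.fragments)) for t in targets
    }


def glycone_aglycone_surface(
    temperatures,
    capillary_voltages,
) -> pd.DataFrame:
    """Glycone/aglycone signal-ratio summary over source conditions.

    For each (desolvation temperature, capillary voltage) condition the
    intact-glycoside and aglycone signals are proportional to (1 − f(T)) and
    f(T), so the diagnostic ratio is (1 − f)/f.  Only the temperature axis is
    modelled; the voltage is carried through as a condition label.  The table
    summarises where the source is gentle (high ratio) versus harsh (low
    ratio); it deliberately does not pick an operating point.
    """
    from .calibrate import glycone_aglycone_ratio

    rows = []
    for temp in temperatures:
        f = insource_fraction(temp)
        for volt in capillary_voltages:
            rows.append(
                {
                    "desolvation_temperature": float(temp),
                    "capillary_voltage": float(volt),
                    "insource_fraction": f,
                    "glycone_aglycone_ratio": glycone_aglycone_ratio(1.0 - f, f),
                }
            )
    return pd.DataFrame(rows)


def default_panel(concentration: float = 1000.0, is_concentration: float = 1000.0) -> list[SimTarget]:
    """The seven-withanolide panel plus the digoxin-d3 internal standard.

    Neutral monoisotopic masses are computed from elemental formulas;
    retention times, peak widths, response factors and fragment patterns are
    plausible values for a 12-min phenyl-column gradient, not measured ones.
    The two withanosides (steroidal saponins) are flagged as glycosides.
    """

    def mass(c: int, h: int, o: int, d: int = 0) -> float:
        return c * _C + h * _H + o * _O + d * (_D - _H)

    def frags(*pairs) -> tuple[tuple[float, float], ...]:
        return tuple(pairs)

    m_wfa = mass(28, 38, 6)  # withaferin A / withanolide A / withanone, C28H38O6
    return [
        SimTarget(
            "withanoside_iv", mass(40, 62, 15), "M+NH4", 3.2, 0.05, 120.0, concentration,
            frags((783.4164, 1.0), (621.3636, 0.55), (459.3105, 0.35), (283.2050, 0.2)),
            is_glycoside=True,
        ),
        SimTarget(
            "withanoside_v", mass(40, 62, 14), "M+NH4", 3.9, 0.05, 110.0, concentration,
            frags((767.4215, 1.0), (605.3687, 0.5), (443.3156, 0.3)),
            is_glycoside=True,
        ),
        SimTarget(
            "withaferin_a", m_wfa, "M+H", 4.6, 0.05, 200.0, concentration,
            frags((281.1900, 1.0), (263.1794, 0.6), (109.0648, 0.3)),
        ),
        SimTarget(
            "deoxywithastramonolide", m_wfa, "M+H", 5.1, 0.05, 90.0, concentration,
            frags((453.2641, 1.0), (435.2535, 0.45), (417.2430, 0.25)),
        ),
        SimTarget(
            "withanolide_a", m_wfa, "M+H", 5.6, 0.05, 150.0, concentration,
            frags((453.2641, 1.0), (281.1900, 0.7), (253.1951, 0.4)),
        ),
        SimTarget(
            "withanone", m_wfa, "M+H", 6.1, 0.05, 140.0, concentration,
            frags((453.2641, 1.0), (325.2162, 0.5), (155.0703, 0.2)),
        ),
        SimTarget(
            "withanolide_b", mass(28, 38, 5), "M+H", 6.8, 0.05, 130.0, concentration,
            frags((437.2692, 1.0), (419.2586, 0.5), (281.1900, 0.3)),
        ),
        SimTarget(
            "digoxin_d3", mass(41, 64, 14, d=3), "M+H", 7.4, 0.05, 80.0, is_concentration,
            frags((653.3900, 1.0), (523.3200, 0.4), (393.2500, 0.25)),
        ),
    ]
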