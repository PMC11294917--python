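"""Targeted extraction and integration for PRM, DDA MS1 and MRM acquisitions.

PRM quantitation proceeds in four steps sharing one contract with the other
two modes:

1. MS2 scans are matched to an inclusion-list target by precursor m/z (ppm
   tolerance) and retention-time window.
2. The top fragment ions are chosen from the target's reference MS2 spectrum.
3. A fragment-ion chromatogram is assembled per fragment (per-scan sum of
   centroid intensities inside the ppm window; one point per matched scan).
4. The summed trace is integrated by the trapezoid rule over the window,
   giving a single area (counts·minutes) per target per sample.  By linearity
   this equals the sum of per-fragment trapezoidal areas.

No smoothing, baseline subtraction, or peak modelling is applied: the window
bounds define the integral.  DDA quantitation integrates the precursor's MS1
extracted-ion chromatogram the same way; MRM quantitation integrates the
recorded transition trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .msdata import (
    InclusionEntry,
    ReferenceSpectrum,
    Run,
    Spectrum,
    TransitionTrace,
)

__all__ = [
    "FragmentTrace",
    "TargetArea",
    "ADDUCT_OFFSETS",
    "compute_adduct_mz",
    "match_ms2_scans",
    "assign_ms2_scans",
    "select_top_fragments",
    "extract_fragment_traces",
    "integrate_target",
    "extract_ms1_area",
    "integrate_transition",
    "quantify_prm",
    "quantify_dda_ms1",
]

DEFAULT_MZ_TOL_PPM = 25.0
DEFAULT_N_FRAGMENTS = 3


@dataclass
class FragmentTrace:
    """Extracted MS2 fragment-ion chromatogram for one target fragment."""

    target_id: str
    fragment_mz: float
    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.shape != self.intensity.shape or self.rt.ndim != 1:
            raise ValueError("rt and intensity must be 1-D arrays of equal length")
        if np.any(np.diff(self.rt) < 0):
            raise ValueError("trace points must be sorted by rt")


@dataclass
class TargetArea:
    """The single integrated area for one target in one sample."""

    target_id: str
    sample_id: str
    mode: str  # prm | dda_ms1 | mrm
    area: float
    n_scans: int
    fragments_used: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.mode not in ("prm", "dda_ms1", "mrm"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.area < 0 or self.n_scans < 0:
            raise ValueError("area and n_scans must be non-negative")


# singly-charged positive-mode adduct mass offsets (Th); proton 1.007276,
# NH4+ 18.033823, Na+ 22.989218, water loss 18.010565
ADDUCT_OFFSETS = {
    "M+H": 1.007276,
    "M+NH4": 18.033823,
    "M+Na": 22.989218,
    "M-H2O+H": 1.007276 - 18.010565,
}


def compute_adduct_mz(neutral_monoisotopic_mass: float, adduct: str) -> float:
    """m/z of a singly charged positive-mode adduct of a neutral mass."""
    if not neutral_monoisotopic_mass > 0:
        raise ValueError("neutral mass must be positive")
    key = adduct.replace("−", "-").replace("[", "").replace("]", "").replace(" ", "")
    if key.endswith("+"):
        key = key[:-1]
    if key not in ADDUCT_OFFSETS:
        raise ValueError(f"unknown adduct {adduct!r}; known: {sorted(ADDUCT_OFFSETS)}")
    return neutral_monoisotopic_mass + ADDUCT_OFFSETS[key]


def _ppm_distance(mz: float, ref_mz: float) -> float:
    return abs(mz - ref_mz) / ref_mz * 1e6


def match_ms2_scans(
    run: Run, entry: InclusionEntry, mz_tol_ppm: float = DEFAULT_MZ_TOL_PPM
) -> list[Spectrum]:
    """MS2 scans whose precursor matches the entry within ppm tolerance and
    whose retention time lies inside the entry's window, ordered by rt."""
    if not mz_tol_ppm > 0:
        raise ValueError("mz_tol_ppm must be > 0")
    half = entry.rt_window / 2.0
    out = [
        s
        for s in run.spectra
        if s.ms_level == 2
        and _ppm_distance(s.precursor_mz, entry.precursor_mz) <= mz_tol_ppm
        and abs(s.rt - entry.rt_center) <= half
    ]
    out.sort(key=lambda s: s.rt)
    return out


def assign_ms2_scans(
    run: Run, entries: list[InclusionEntry], mz_tol_ppm: float = DEFAULT_MZ_TOL_PPM
) -> dict[str, list[Spectrum]]:
    """Exclusive MS2-to-target assignment across a whole inclusion list.

    A scan matching several entries is assigned to the entry with the smaller
    ppm distance, ties broken by smaller |rt − rt_center|.  Every scan
    contributes to at most one target.
    """
    assigned: dict[str, list[Spectrum]] = {e.target_id: [] for e in entries}
    for scan in run.spectra:
        if scan.ms_level != 2:
            continue
        best = None
        best_key = None
        for entry in entries:
            ppm = _ppm_distance(scan.precursor_mz, entry.precursor_mz)
            drt = abs(scan.rt - entry.rt_center)
            if ppm <= mz_tol_ppm and drt <= entry.rt_window / 2.0:
                key = (ppm, drt)
                if best_key is None or key < best_key:
                    best, best_key = entry, key
        if best is not None:
            assigned[best.target_id].append(scan)
    for scans in assigned.values():
        scans.sort(key=lambda s: s.rt)
    return assigned


def select_top_fragments(ref: ReferenceSpectrum, n_fragments: int = DEFAULT_N_FRAGMENTS) -> list[float]:
    """The ``n_fragments`` most intense reference fragments, most intense
    first; intensity ties broken toward lower m/z."""
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    ranked = sorted(ref.fragments, key=lambda f: (-f[1], f[0]))
    return [mz for mz, _ in ranked[:n_fragments]]


def _window_sum(spec: Spectrum, mz: float, tol_mz: float) -> float:
    lo = np.searchsorted(spec.mz, mz - tol_mz, side="left")
    hi = np.searchsorted(spec.mz, mz + tol_mz, side="right")
    if hi <= lo:
        return 0.0
    return float(spec.intensity[lo:hi].sum())


def extract_fragment_traces(
    scans: list[Spectrum],
    fragment_mzs: list[float],
    mz_tol_ppm: float = DEFAULT_MZ_TOL_PPM,
    target_id: str = "",
) -> list[FragmentTrace]:
    """One chromatogram per fragment m/z over the given scans.

    Each trace has exactly one point per scan: the sum of centroid
    intensities within the ppm tolerance of the fragment m/z (0 if none).
    """
    rts = np.array([s.rt for s in scans], dtype=float)
    traces = []
    for frag in fragment_mzs:
        tol = frag * mz_tol_ppm * 1e-6
        intens = np.array([_window_sum(s, frag, tol) for s in scans], dtype=float)
        traces.append(FragmentTrace(target_id, frag, rts, intens))
    return traces


def integrate_target(
    traces: list[FragmentTrace], sample_id: str = "", mode: str = "prm"
) -> TargetArea:
    """Sum fragment traces over a shared rt grid and trapezoid-integrate.

    Fewer than two grid points cannot be integrated: the area is reported as
    zero with a warning, so batch processing survives dropouts.
    """
    if not traces:
        return TargetArea("", sample_id, mode, 0.0, 0, ())
    grid = traces[0].rt
    for t in traces[1:]:
        if t.rt.shape != grid.shape or not np.array_equal(t.rt, grid):
            raise ValueError("fragment traces have mismatched rt grids")
    target_id = traces[0].target_id
    frags = tuple(t.fragment_mz for t in traces)
    n = grid.size
    if n < 2:
        warnings.warn(
            f"{target_id or 'target'}: {n} scan(s) in window; area set to 0",
            stacklevel=2,
        )
        return TargetArea(target_id, sample_id, mode, 0.0, n, frags)
    summed = np.sum([t.intensity for t in traces], axis=0)
    area = float(np.trapezoid(summed, grid))
    return TargetArea(target_id, sample_id, mode, max(area, 0.0), n, frags)


def extract_ms1_area(
    run: Run,
    mz: float,
    rt_center: float,
    rt_window: float,
    mz_tol_ppm: float = DEFAULT_MZ_TOL_PPM,
    target_id: str = "",
) -> TargetArea:
    """DDA-style precursor quantitation: trapezoidal area of the MS1
    extracted-ion chromatogram over ``rt_center ± rt_window/2``."""
    half = rt_window / 2.0
    scans = [
        s for s in run.ms1_spectra() if rt_center - half <= s.rt <= rt_center + half
    ]
    if not scans:
        warnings.warn(
            f"{target_id or mz}: no MS1 scans in window "
            f"[{rt_center - half:.3f}, {rt_center + half:.3f}] min",
            stacklevel=2,
        )
        return TargetArea(target_id, run.sample_id, "dda_ms1", 0.0, 0, ())
    tol = mz * mz_tol_ppm * 1e-6
    rts = np.array([s.rt for s in scans], dtype=float)
    intens = np.array([_window_sum(s, mz, tol) for s in scans], dtype=float)
    if rts.size < 2:
        warnings.warn(f"{target_id or mz}: single MS1 scan in window; area 0", stacklevel=2)
        return TargetArea(target_id, run.sample_id, "dda_ms1", 0.0, int(rts.size), ())
    area = float(np.trapezoid(intens, rts))
    return TargetArea(target_id, run.sample_id, "dda_ms1", max(area, 0.0), int(rts.size), ())


def integrate_transition(
    trace: TransitionTrace, rt_center: float, rt_window: float
) -> TargetArea:
    """Trapezoidal area of an MRM transition trace inside the window."""
    if trace.rt.size == 0:
        raise ValueError(f"{trace.target_id}: empty transition trace")
    half = rt_window / 2.0
    mask = (trace.rt >= rt_center - half) & (trace.rt <= rt_center + half)
    rts = trace.rt[mask]
    intens = trace.intensity[mask]
    if rts.size < 2:
        return TargetArea(trace.target_id, "", "mrm", 0.0, int(rts.size), (trace.product_mz,))
    area = float(np.trapezoid(intens, rts))
    return TargetArea(
        trace.target_id, "", "mrm", max(area, 0.0), int(rts.size), (trace.product_mz,)
    )


def quantify_prm(
    run: Run,
    entries: list[InclusionEntry],
    reference_spectra: dict[str, ReferenceSpectrum],
    mz_tol_ppm: float = DEFAULT_MZ_TOL_PPM,
    n_fragments: int = DEFAULT_N_FRAGMENTS,
) -> list[TargetArea]:
    """Full PRM quantitation of one run: one area per inclusion-list target.

    Scans are assigned exclusively across the inclusion list; targets without
    a reference spectrum raise KeyError.
    """
    assigned = assign_ms2_scans(run, entries, mz_tol_ppm)
    areas = []
    for entry in entries:
        ref = reference_spectra.get(entry.target_id)
        if ref is None:
            raise KeyError(f"no reference spectrum for target {entry.target_id!r}")
        frags = select_top_fragments(ref, n_fragments)
        scans = assigned[entry.target_id]
        traces = extract_fragment_traces(scans, frags, mz_tol_ppm, entry.target_id)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            area = integrate_target(traces, sample_id=run.sample_id, mode="prm")
        area.target_id = entry.target_id
        areas.append(area)
    return areas


def quantify_dda_ms1(
    run: Run,
    entries: list[InclusionEntry],
    mz_tol_ppm: float = DEFAULT_MZ_TOL_PPM,
) -> list[TargetArea]:
    """MS1 precursor quantitation of one run for each listed target."""
    areas = []
    for entry in entries:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            areas.append(
                extract_ms1_area(
                    run,
                    entry.precursor_mz,
                    entry.rt_center,
                    entry.rt_window,
                    mz_tol_ppm,
                    target_id=entry.target_id,
                )
            )
    return areas
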