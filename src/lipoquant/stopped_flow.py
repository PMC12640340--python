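"""Stopped-flow light-scattering kinetics and osmotic permeability.

Vesicles mixed rapidly with a hyperosmotic solution shrink as water flows
out; the scattered intensity rises toward a plateau as they do. The workflow
here mirrors the standard analysis chain: average repeated shots, normalize
to the observation window, fit a double exponential to extract a shrinkage
rate constant K, correct against the empty-liposome control, convert to the
membrane osmotic permeability P_f and finally to a per-channel permeability
p_f using the reconstitution stoichiometry.

Unit conventions: time in seconds, rates in s^-1, vesicle diameters in nm,
osmotic gradients in osmol/L, molar volume of water in cm^3/mol, P_f in
µm/s and p_f in cm^3/s.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "ShrinkageTrace",
    "DoubleExpFit",
    "PermeabilityRecord",
    "read_trace_csv",
    "write_trace_csv",
    "average_and_normalize",
    "fit_double_exponential",
    "corrected_rate_ratios",
    "osmotic_permeability",
    "channels_per_vesicle",
    "single_channel_permeability",
    "analyze_permeability",
]

# Ledger-documented default constants for the permeability chain. The osmotic
# gradient follows from 1:1 mixing with 0.5 M NaCl (0.25 M across the
# membrane, van 't Hoff factor 2); the molecular weights and lipid headgroup
# area are standard soy-PC / AqpZ-tetramer values consistent with the molar
# lipid-to-protein ratios of the preparation protocol.
DEFAULT_DELTA_OSM = 0.5         # osmol/L
DEFAULT_V_W = 18.0              # cm^3/mol, partial molar volume of water
DEFAULT_LIPID_MW = 776.0        # g/mol (soy PC average)
DEFAULT_TETRAMER_MW = 97_000.0  # g/mol (AqpZ homotetramer)
DEFAULT_AREA_PER_LIPID = 0.7    # nm^2
PORES_PER_TETRAMER = 4          # four independently conducting monomer pores


@dataclass
class ShrinkageTrace:
    """One stopped-flow shot, or an averaged set of shots.

    ``dead_time`` is the instrument mixing dead time: points earlier than it
    do not reflect the osmotic response and are excluded from fitting.
    """

    t: np.ndarray
    y: np.ndarray
    dead_time: float = 0.01
    label: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape or self.t.ndim != 1:
            raise ValueError("t and y must be 1-D arrays of identical length")
        if self.t.size < 2:
            raise ValueError("a trace needs at least two points")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time points must be strictly increasing")
        if self.dead_time < 0:
            raise ValueError("dead_time must be non-negative")


@dataclass
class DoubleExpFit:
    """Result of a biphasic-exponential fit y(t) = y_inf - A1 e^-k1 t - A2 e^-k2 t.

    ``K`` is the amplitude-weighted mean rate (A1 k1 + A2 k2)/(A1 + A2), the
    reported shrinkage rate constant. ``collapsed`` flags fits that
    degenerated to a single exponential (vanishing second amplitude or
    indistinguishable rates).
    """

    A1: float
    A2: float
    k1: float
    k2: float
    y_inf: float
    K: float
    rms: float
    collapsed: bool = False


def read_trace_csv(path, dead_time: float = 0.01, label: str | None = None) -> ShrinkageTrace:
    """Read a 2-column (t [s], intensity) CSV; '#' lines are comments."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            parts = body.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            try:
                rows.append([float(parts[0]), float(parts[1])])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    if not rows:
        raise ValueError(f"{path}: no data rows found")
    arr = np.asarray(rows, dtype=float)
    return ShrinkageTrace(arr[:, 0], arr[:, 1], dead_time=dead_time,
                          label=label if label is not None else str(path))


def write_trace_csv(path, trace: ShrinkageTrace) -> None:
    with open(path, "w") as fh:
        fh.write(f"# label: {trace.label}\n# dead_time: {trace.dead_time}\n")
        fh.write("# t[s],intensity\n")
        for ti, yi in zip(trace.t, trace.y):
            fh.write(f"{ti:.9g},{yi:.9g}\n")


# --------------------------------------------------------------------------
# Averaging and normalization
# --------------------------------------------------------------------------

def average_and_normalize(traces, window: float = 0.4) -> ShrinkageTrace:
    """Average repeated shots and min–max normalize over the window.

    Shots are averaged pointwise (resampled onto the first shot's grid if
    grids differ), then rescaled affinely so the signal spans [0, 1] over
    t in [0, window]. Traces that decay (inverted detector sign) are flipped
    so the output rises toward its plateau; rates fitted downstream are
    invariant under any such affine re-orientation.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("cannot average an empty collection of traces")
    ref = traces[0]
    ys = []
    for tr in traces:
        if tr.t.shape == ref.t.shape and np.allclose(tr.t, ref.t):
            ys.append(tr.y)
        else:
            ys.append(np.interp(ref.t, tr.t, tr.y))
    y = np.mean(ys, axis=0)

    m = (ref.t >= 0) & (ref.t <= window)
    if not np.any(m):
        raise ValueError("normalization window contains no points")
    # orient rising: compare means of the first and last deciles of the window
    n = max(1, int(0.1 * m.sum()))
    yw = y[m]
    if yw[:n].mean() > yw[-n:].mean():
        y = -y
        yw = y[m]
    lo, hi = yw.min(), yw.max()
    span = hi - lo
    if span <= 0:
        raise ValueError("trace is constant over the window; cannot normalize")
    return ShrinkageTrace(ref.t.copy(), (y - lo) / span,
                          dead_time=ref.dead_time,
                          label=ref.label, normalized=True)


# --------------------------------------------------------------------------
# Double-exponential fitting
# --------------------------------------------------------------------------

def _model(t, y_inf, a1, a2, k1, k2):
    return y_inf - a1 * np.exp(-k1 * t) - a2 * np.exp(-k2 * t)


def fit_double_exponential(trace: ShrinkageTrace, min_points: int = 20) -> DoubleExpFit:
    """Least-squares biphasic fit of a shrinkage trace on t >= dead_time.

    Several deterministic starting points (built from a half-rise-time rate
    estimate) are refined by bounded least squares; the best chi-square wins.
    If the two phases are degenerate — second amplitude below 1e-3 of the
    first, or rates equal to within 0.1% — the fit collapses to a single
    exponential, flagged via ``collapsed`` with A2 = 0.

    The reported rate constant is the amplitude-weighted mean
    K = (A1 k1 + A2 k2) / (A1 + A2), which lies between the two rates.
    """
    mask = trace.t >= trace.dead_time
    t = trace.t[mask]
    y = trace.y[mask]
    if t.size < min_points:
        raise ValueError(
            f"only {t.size} points at t >= dead_time; need at least {min_points}"
        )

    # auto-orientation: fit expects a rising trace
    flipped = False
    n10 = max(1, t.size // 10)
    if y[:n10].mean() > y[-n10:].mean():
        y = -y
        flipped = True

    y_inf0 = y[-n10:].mean()
    amp0 = max(y_inf0 - y[0], 1e-12)
    half = y[0] + 0.5 * (y_inf0 - y[0])
    above = np.nonzero(y >= half)[0]
    t_half = t[above[0]] - t[0] if above.size else (t[-1] - t[0]) / 2
    k0 = math.log(2.0) / max(t_half, (t[1] - t[0]))

    span = max(t[-1] - t[0], 1e-9)
    k_lo, k_hi = 1e-3 / span, 1e4 * k0 + 1.0 / span
    bounds = ([-np.inf, 0.0, 0.0, k_lo, k_lo],
              [np.inf, np.inf, np.inf, k_hi, k_hi])
    starts = [
        (y_inf0, 0.5 * amp0, 0.5 * amp0, 3.0 * k0, 0.5 * k0),
        (y_inf0, 0.7 * amp0, 0.3 * amp0, 5.0 * k0, 1.0 * k0),
        (y_inf0, 0.9 * amp0, 0.1 * amp0, 1.0 * k0, 0.1 * k0),
    ]
    best = None
    for p0 in starts:
        p0 = np.clip(p0, bounds[0], bounds[1])
        res = optimize.least_squares(
            lambda p: _model(t, *p) - y, p0, bounds=bounds, method="trf",
            x_scale="jac",
        )
        if best is None or res.cost < best.cost:
            best = res
    y_inf, a1, a2, k1, k2 = best.x
    # order phases fast-first
    if k2 > k1:
        a1, a2, k1, k2 = a2, a1, k2, k1

    collapsed = False
    a_big, a_small = max(a1, a2), min(a1, a2)
    if (a_big > 0 and a_small / a_big < 1e-3) or abs(k1 - k2) / max(k1, k2) < 1e-3:
        res1 = optimize.least_squares(
            lambda p: (p[0] - p[1] * np.exp(-p[2] * t)) - y,
            np.array([y_inf0, amp0, k0]),
            bounds=([-np.inf, 0.0, k_lo], [np.inf, np.inf, k_hi]),
            method="trf", x_scale="jac",
        )
        y_inf, a1, k1 = res1.x
        a2, k2 = 0.0, k1
        collapsed = True
        rms = math.sqrt(2.0 * res1.cost / t.size)
    else:
        rms = math.sqrt(2.0 * best.cost / t.size)

    total = a1 + a2
    K = (a1 * k1 + a2 * k2) / total if total > 0 else k1
    return DoubleExpFit(A1=a1, A2=a2, k1=k1, k2=k2, y_inf=y_inf, K=K,
                        rms=rms, collapsed=collapsed)


# --------------------------------------------------------------------------
# Control correction and the permeability chain
# --------------------------------------------------------------------------

def corrected_rate_ratios(K_samples, K_empty: float, reference: int = 0) -> np.ndarray:
    """Empty-control-corrected rate ratios, normalized to a reference sample.

    ratio_i = (K_i - K_empty) / (K_ref - K_empty); the reference entry is 1
    exactly. Samples at or below the control rate have no resolvable protein
    activity — their ratios are non-positive and flagged with a warning.
    """
    k = np.asarray(K_samples, dtype=float)
    denom = k[reference] - K_empty
    if denom <= 0:
        raise ValueError("reference rate must exceed the empty-liposome control")
    ratios = (k - K_empty) / denom
    if np.any(k <= K_empty):
        bad = np.nonzero(k <= K_empty)[0].tolist()
        warnings.warn(f"samples {bad} show no activity above the control "
                      "(non-positive corrected rate)")
    return ratios


def osmotic_permeability(K: float, vesicle_diameter: float,
                         delta_osm: float = DEFAULT_DELTA_OSM,
                         V_w: float = DEFAULT_V_W,
                         formula=None) -> float:
    """Membrane osmotic permeability P_f [µm/s] from the shrinkage rate.

    Default formula (surface-to-volume ratio of a sphere, S/V0 = 3/r):

        P_f = K / ((S/V0) * V_w * delta_osm) = K * r / (3 * V_w * delta_osm)

    Parameters
    ----------
    K : float
        Shrinkage rate constant [s^-1] (raw or control-corrected; the
        conversion is linear, so correction commutes with it).
    vesicle_diameter : float
        Hydrodynamic diameter [nm] (post-extrusion Z-average).
    delta_osm : float
        Osmotic gradient [osmol/L].
    V_w : float
        Partial molar volume of water [cm^3/mol].
    formula : callable, optional
        Drop-in replacement with the same signature (K, vesicle_diameter,
        delta_osm, V_w) -> P_f [µm/s], for instrument- or protocol-specific
        variants of the conversion.
    """
    if K < 0:
        raise ValueError("rate constant K must be non-negative")
    if vesicle_diameter <= 0 or delta_osm <= 0 or V_w <= 0:
        raise ValueError("vesicle diameter, osmotic gradient and V_w must be positive")
    if formula is not None:
        return formula(K, vesicle_diameter, delta_osm, V_w)
    r_m = 0.5 * vesicle_diameter * 1e-9           # nm -> m
    vw_m3 = V_w * 1e-6                            # cm^3/mol -> m^3/mol
    osm_m3 = delta_osm * 1e3                      # osmol/L -> mol/m^3
    p_f_m_s = K * r_m / (3.0 * vw_m3 * osm_m3)
    return p_f_m_s * 1e6                          # m/s -> µm/s


def channels_per_vesicle(lipid_conc: float, protein_conc: float,
                         vesicle_diameter: float,
                         lipid_MW: float = DEFAULT_LIPID_MW,
                         tetramer_MW: float = DEFAULT_TETRAMER_MW,
                         area_per_lipid: float = DEFAULT_AREA_PER_LIPID) -> float:
    """Expected conducting pores per vesicle from the reconstitution mixture.

    Lipids per vesicle cover both leaflets of the sphere surface,
    2*(4 pi r^2)/area_per_lipid; tetramers follow from the molar
    lipid-to-protein ratio of the bulk mixture, and each tetramer carries
    four independently conducting pores. Zero protein gives zero channels
    (flagged), not an error, so control samples pass through the chain.
    """
    if lipid_conc <= 0 or vesicle_diameter <= 0:
        raise ValueError("lipid concentration and vesicle diameter must be positive")
    if lipid_MW <= 0 or tetramer_MW <= 0 or area_per_lipid <= 0:
        raise ValueError("molecular weights and area per lipid must be positive")
    if protein_conc < 0:
        raise ValueError("protein concentration must be non-negative")
    if protein_conc == 0:
        warnings.warn("zero protein concentration: infinite lipid-to-protein "
                      "ratio, zero channels per vesicle")
        return 0.0
    lpr = (lipid_conc / lipid_MW) / (protein_conc / tetramer_MW)
    r_nm = 0.5 * vesicle_diameter
    lipids = 2.0 * 4.0 * math.pi * r_nm**2 / area_per_lipid
    tetramers = lipids / lpr
    return PORES_PER_TETRAMER * tetramers


def single_channel_permeability(P_f: float, vesicle_diameter: float,
                                channels: float) -> float:
    """Per-channel permeability p_f [cm^3/s] from the protein-attributable P_f.

    p_f = P_f * (4 pi r^2) / N, i.e. the corrected volume flux of one vesicle
    divided equally among its N conducting pores.
    """
    if channels <= 0:
        raise ValueError("channels must be positive (per-channel quantity undefined)")
    if vesicle_diameter <= 0:
        raise ValueError("vesicle diameter must be positive")
    if P_f < 0:
        raise ValueError("P_f must be non-negative")
    r_cm = 0.5 * vesicle_diameter * 1e-7          # nm -> cm
    area_cm2 = 4.0 * math.pi * r_cm**2
    p_f_cm_s = P_f * 1e-4                         # µm/s -> cm/s
    return p_f_cm_s * area_cm2 / channels


@dataclass
class PermeabilityRecord:
    """Full permeability bookkeeping for one sample."""

    K: float
    K_empty: float
    vesicle_diameter: float
    delta_osm: float
    V_w: float
    P_f: float                      # control-corrected, µm/s
    p_f: float | None               # cm^3/s; None when no channels
    channels_per_vesicle: float
    label: str = ""


def analyze_permeability(K: float, K_empty: float, vesicle_diameter: float,
                         protein_conc: float, lipid_conc: float = 7.5,
                         delta_osm: float = DEFAULT_DELTA_OSM,
                         V_w: float = DEFAULT_V_W,
                         lipid_MW: float = DEFAULT_LIPID_MW,
                         tetramer_MW: float = DEFAULT_TETRAMER_MW,
                         area_per_lipid: float = DEFAULT_AREA_PER_LIPID,
                         label: str = "",
                         pf_formula=None) -> PermeabilityRecord:
    """Run the full chain K -> corrected P_f -> p_f for one sample."""
    k_corr = max(K - K_empty, 0.0)
    p_f_membrane = osmotic_permeability(k_corr, vesicle_diameter, delta_osm,
                                        V_w, formula=pf_formula)
    n_channels = channels_per_vesicle(lipid_conc, protein_conc, vesicle_diameter,
                                      lipid_MW, tetramer_MW, area_per_lipid) \
        if protein_conc > 0 else 0.0
    p_f_single = single_channel_permeability(p_f_membrane, vesicle_diameter,
                                             n_channels) if n_channels > 0 else None
    return PermeabilityRecord(
        K=K, K_empty=K_empty, vesicle_diameter=vesicle_diameter,
        delta_osm=delta_osm, V_w=V_w, P_f=p_f_membrane, p_f=p_f_single,
        channels_per_vesicle=n_channels, label=label,
    )
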