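"""Forward X-ray scattering model of protein-loaded liposome bilayers.

The bilayer is described as a symmetric two-slab scattering-length-density
(SLD) profile: a hydrophobic core of half-thickness ``L_t`` (the lipid alkyl
tails) flanked by hydrophilic headgroup layers of thickness ``L_h``. Membrane
protein embedded in the hydrophobic core is represented by a volume fraction
``x``: the core SLD is an x-weighted mix of tail and protein SLDs, while the
headgroup layer mixes head and solvent SLDs (the space above and below an
embedded protein is taken to be occupied by solvent).

Residual lipid aggregates are modelled as spherical core–shell micelles that
inherit the bilayer's geometry and SLDs (tail core, headgroup shell). The
measurable curve combines both contributions with Gaussian interface-roughness
damping and a flat background:

    I(q) = C1 * I_lam(q) * exp(-R^2 q^2) + C2 * I_mc(q) * exp(-R^2 q^2) + B
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "R_ELECTRON",
    "SLDSet",
    "EffectiveContrasts",
    "BilayerModel",
    "effective_slds",
    "lamellar_intensity",
    "micelle_intensity",
    "combined_intensity",
    "sld_from_sequence",
    "RESIDUE_VOLUMES",
    "RESIDUE_ELECTRONS",
    "AQPZ_HIS_SEQUENCE",
]

#: Classical electron radius [Å], converting electron density to X-ray SLD.
R_ELECTRON = 2.818e-5


# --------------------------------------------------------------------------
# Parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SLDSet:
    """The four fixed X-ray scattering length densities [Å^-2].

    Defaults are literature values for a soy-PC bilayer in PBS with an
    embedded aquaporin: solvent 9.46e-6, alkyl tails 8.7e-6, PC headgroups
    11.8e-6 and protein 11.7e-6 Å^-2.
    """

    rho_s: float = 9.46e-6
    rho_t: float = 8.7e-6
    rho_h: float = 11.8e-6
    rho_p: float = 11.7e-6

    def __post_init__(self) -> None:
        for name in ("rho_s", "rho_t", "rho_h", "rho_p"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v!r}")


@dataclass(frozen=True)
class EffectiveContrasts:
    """Effective SLDs of the mixed bilayer layers and their solvent contrasts."""

    rho_i: float  #: inner (hydrophobic) effective SLD [Å^-2]
    rho_o: float  #: outer (hydrophilic) effective SLD [Å^-2]
    drho_i: float  #: rho_i - rho_s [Å^-2]
    drho_o: float  #: rho_o - rho_s [Å^-2]


@dataclass
class BilayerModel:
    """Geometry, composition and nuisance parameters of one sample's model.

    Parameters
    ----------
    L_t, L_h:
        Tail (hydrophobic half-layer) and headgroup lengths [Å].
    x:
        Protein volume fraction in the hydrophobic core, in [0, 1].
    R:
        Gaussian interface roughness [Å], applied as exp(-R^2 q^2) damping.
    C1, C2:
        Scales of the lamellar and micellar contributions (arbitrary units).
    B:
        Flat background, same units as the intensity.
    """

    L_t: float = 14.3
    L_h: float = 6.65
    x: float = 0.0
    R: float = 0.0
    C1: float = 1.0
    C2: float = 0.0
    B: float = 0.0
    slds: SLDSet = field(default_factory=SLDSet)

    def __post_init__(self) -> None:
        if self.L_t <= 0 or self.L_h <= 0:
            raise ValueError("layer lengths L_t and L_h must be positive")
        if not 0.0 <= self.x <= 1.0:
            raise ValueError(f"protein fraction x must lie in [0, 1], got {self.x}")
        if self.R < 0:
            raise ValueError("roughness R must be non-negative")
        if self.C1 < 0 or self.C2 < 0:
            raise ValueError("scales C1 and C2 must be non-negative")

    def with_(self, **kwargs) -> "BilayerModel":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


# --------------------------------------------------------------------------
# Effective SLD mixing
# --------------------------------------------------------------------------

def effective_slds(x: float, slds: SLDSet) -> EffectiveContrasts:
    """Mix protein into the bilayer slabs at volume fraction ``x``.

    The hydrophobic core mixes tail and protein, the hydrophilic layer mixes
    headgroup and solvent (protein displaces headgroups towards solvent):

        rho_i = x*rho_p + (1-x)*rho_t
        rho_o = x*rho_s + (1-x)*rho_h

    Both are affine in x; x=0 recovers the pure lipid bilayer and x=1 full
    replacement.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"protein fraction x must lie in [0, 1], got {x}")
    rho_i = x * slds.rho_p + (1.0 - x) * slds.rho_t
    rho_o = x * slds.rho_s + (1.0 - x) * slds.rho_h
    return EffectiveContrasts(
        rho_i=rho_i,
        rho_o=rho_o,
        drho_i=rho_i - slds.rho_s,
        drho_o=rho_o - slds.rho_s,
    )


# --------------------------------------------------------------------------
# Lamellar (flat-sheet) intensity
# --------------------------------------------------------------------------

def lamellar_intensity(q, model: BilayerModel):
    """Thin-sheet intensity of the two-slab bilayer profile.

    Evaluates, with d = L_h + L_t and contrasts from :func:`effective_slds`,

        I_lam(q) = 4*pi / (q^4 d) *
                   (drho_o*(sin(q d) - sin(q L_t)) + drho_i*sin(q L_t))^2

    This is the per-unit-area intensity of an isolated flat bilayer; it
    carries no vesicle-size information (the q^-2 low-q divergence of a thin
    sheet instead of a closed-shell form factor), which is the appropriate
    limit when the vesicle radius is far above 2*pi/q_min.

    Parameters
    ----------
    q : array_like
        Momentum transfer [Å^-1]; every value must be strictly positive
        (the q^-4 prefactor is singular at q = 0).
    model : BilayerModel

    Returns
    -------
    numpy.ndarray or float
        Non-negative intensity, same shape as ``q``.
    """
    q_arr = np.asarray(q, dtype=float)
    if np.any(q_arr <= 0):
        raise ValueError("q must be strictly positive (q^-4 prefactor is singular)")
    c = effective_slds(model.x, model.slds)
    d = model.L_h + model.L_t
    amp = c.drho_o * (np.sin(q_arr * d) - np.sin(q_arr * model.L_t)) \
        + c.drho_i * np.sin(q_arr * model.L_t)
    out = 4.0 * np.pi / (q_arr**4 * d) * amp**2
    return out if out.ndim else float(out)


# --------------------------------------------------------------------------
# Core-shell micelle intensity
# --------------------------------------------------------------------------

def _sphere_amplitude(u):
    """Normalized sphere amplitude F(u) = 3(sin u - u cos u)/u^3, F(0) = 1.

    Below u = 1e-4 the direct expression suffers catastrophic cancellation,
    so the two-term Taylor series 1 - u^2/10 is used instead.
    """
    u = np.asarray(u, dtype=float)
    small = np.abs(u) < 1e-4
    u_safe = np.where(small, 1.0, u)
    direct = 3.0 * (np.sin(u_safe) - u_safe * np.cos(u_safe)) / u_safe**3
    series = 1.0 - u**2 / 10.0
    return np.where(small, series, direct)


def micelle_intensity(q, core_radius: float, shell_thickness: float,
                      rho_core: float, rho_shell: float, rho_s: float):
    """Spherical core–shell form-factor intensity.

    I(q) = [ (rho_core - rho_shell) V_c F(q R_c)
             + (rho_shell - rho_s) V_tot F(q R_tot) ]^2

    with F the normalized sphere amplitude, V the sphere volumes and
    R_tot = core_radius + shell_thickness. With rho_core == rho_shell this
    reduces exactly to the homogeneous sphere of radius R_tot.
    """
    if core_radius <= 0:
        raise ValueError("core_radius must be positive")
    if shell_thickness < 0:
        raise ValueError("shell_thickness must be non-negative")
    q_arr = np.asarray(q, dtype=float)
    r_tot = core_radius + shell_thickness
    v_core = 4.0 / 3.0 * np.pi * core_radius**3
    v_tot = 4.0 / 3.0 * np.pi * r_tot**3
    amp = (rho_core - rho_shell) * v_core * _sphere_amplitude(q_arr * core_radius) \
        + (rho_shell - rho_s) * v_tot * _sphere_amplitude(q_arr * r_tot)
    out = amp**2
    return out if out.ndim else float(out)


def micelle_intensity_from_model(q, model: BilayerModel):
    """Micelle term with geometry and SLDs inherited from the bilayer.

    The lipid aggregates are lipid-only: the micelle core is the tail region
    (radius L_t, SLD rho_t) and the corona the headgroups (thickness L_h,
    SLD rho_h); no protein enters the micelles.
    """
    s = model.slds
    return micelle_intensity(q, model.L_t, model.L_h, s.rho_t, s.rho_h, s.rho_s)


# --------------------------------------------------------------------------
# Combined measurable curve
# --------------------------------------------------------------------------

def combined_intensity(q, model: BilayerModel):
    """Full model curve: damped lamellar + damped micelle + background.

    ``q`` must be strictly positive and strictly increasing. With R = 0,
    C2 = 0 and B = 0 the result equals ``C1 * lamellar_intensity(q, model)``
    exactly.
    """
    q_arr = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any(q_arr <= 0):
        raise ValueError("q must be strictly positive")
    if q_arr.size > 1 and np.any(np.diff(q_arr) <= 0):
        raise ValueError("q must be strictly increasing")
    damp = np.exp(-(model.R**2) * q_arr**2)
    i_lam = lamellar_intensity(q_arr, model)
    i_mc = micelle_intensity_from_model(q_arr, model)
    out = model.C1 * i_lam * damp + model.C2 * i_mc * damp + model.B
    return out if np.ndim(q) else float(out[0])


# --------------------------------------------------------------------------
# Protein SLD from sequence
# --------------------------------------------------------------------------

#: Per-residue volumes [Å^3] (crystallographic consensus values, Chothia-type
#: partial volumes). Overridable via the ``volumes`` argument of
#: :func:`sld_from_sequence`.
RESIDUE_VOLUMES: dict[str, float] = {
    "G": 60.1, "A": 88.6, "S": 89.0, "C": 108.5, "D": 111.1,
    "P": 112.7, "N": 114.1, "T": 116.1, "E": 138.4, "V": 140.0,
    "Q": 143.8, "H": 153.2, "M": 162.9, "I": 166.7, "L": 166.7,
    "K": 168.6, "R": 173.4, "F": 189.9, "Y": 193.6, "W": 227.8,
}

#: Electrons per residue (amino acid minus one water), from the residue
#: molecular formulae with neutral side chains.
RESIDUE_ELECTRONS: dict[str, int] = {
    "G": 30, "A": 38, "S": 46, "C": 54, "D": 60,
    "P": 52, "N": 60, "T": 54, "E": 68, "V": 54,
    "Q": 68, "H": 72, "M": 70, "I": 62, "L": 62,
    "K": 70, "R": 84, "F": 78, "Y": 86, "W": 98,
}

_WATER_ELECTRONS = 10
_WATER_VOLUME = 29.9  # Å^3

#: E. coli aquaporin-Z (UniProt P60844) with an N-terminal His6 tag, used as
#: a representative default for the His-tagged AqpZ construct; exact
#: expression constructs vary by a few residues, which moves the SLD well
#: under a percent.
AQPZ_HIS_SEQUENCE = (
    "MHHHHHH"
    "MFRKLAAECFGTFWLVFGGCGSAVLAAGFPELGIGFAGVALAFGLTVLTMAFAVGHISGGHFNPAVTIGLWA"
    "GGRFPAKEVVGYVIAQVVGGIVAAALLYLIASGKTGFDAAASGFASNGYGEHSPGGYSMLSALVVELVLSAG"
    "FLLVIHGATDKFAPAGFAPIAIGLALTLIHLISIPVTNTSVNPARSTAVAIFQGGWALEQLWFFWVVPIVGG"
    "IIGGLIYRTLLEKRD"
)


def sld_from_sequence(sequence: str,
                      volumes: dict[str, float] | None = None,
                      electrons: dict[str, int] | None = None,
                      include_terminal_water: bool = True) -> float:
    """X-ray SLD of a protein from its amino-acid sequence [Å^-2].

    SLD = (total electrons * r_e) / (total residue volume), with one water
    added for the chain termini by default. The volume table is a published
    per-residue set shipped with the package; pass ``volumes`` to substitute
    another convention.

    Raises
    ------
    ValueError
        If the sequence is empty or contains a character outside the 20
        standard one-letter residue codes (the error names the offending
        character and its position).
    """
    if not sequence:
        raise ValueError("empty sequence: cannot compute an SLD")
    vol_table = RESIDUE_VOLUMES if volumes is None else volumes
    e_table = RESIDUE_ELECTRONS if electrons is None else electrons
    n_electrons = 0.0
    volume = 0.0
    for pos, aa in enumerate(sequence.upper()):
        if aa not in vol_table or aa not in e_table:
            raise ValueError(
                f"unknown residue code {aa!r} at position {pos} in sequence"
            )
        n_electrons += e_table[aa]
        volume += vol_table[aa]
    if include_terminal_water:
        n_electrons += _WATER_ELECTRONS
        volume += _WATER_VOLUME
    return n_electrons * R_ELECTRON / volume
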