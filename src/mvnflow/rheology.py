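"""Empirical blood rheology: effective viscosity, Fahraeus effect, phase separation.

Blood in microvessels is a suspension of red blood cells (RBCs) in plasma.
Three empirical in vitro laws (the Pries parameterizations) capture its
non-continuum behaviour at the vessel scale:

* the *relative effective viscosity* ``mu_rel(D, Hd)`` — apparent viscosity
  of blood relative to plasma as a function of tube diameter D (µm) and
  discharge hematocrit Hd, minimal near D ≈ 7 µm (Fahraeus–Lindqvist);
* the *Fahraeus effect* — RBCs travel faster than bulk flow, so the
  in-tube (tube) hematocrit Ht is lower than the discharge hematocrit Hd
  of the blood flowing through; vf = Hd/Ht is the RBC velocity factor;
* *phase separation* — at a divergent bifurcation the RBC flux divides
  disproportionately to the bulk flow, favouring the higher-flow daughter.

All coefficients live in :class:`RheologyParams` so variants of the laws
can be swapped via configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

__all__ = [
    "RheologyParams",
    "RoutingRegimeError",
    "relative_effective_viscosity",
    "tube_hematocrit",
    "discharge_hematocrit",
    "velocity_factor",
    "phase_separation_split",
]


class RoutingRegimeError(ValueError):
    """Phase-separation law called outside its diameter regime."""


@dataclass(frozen=True)
class RheologyParams:
    """Coefficients of the empirical laws.

    plasma_viscosity_mPas : dynamic plasma viscosity µ (mPa·s).
    reference_hct : discharge hematocrit at which the viscosity law's
        diameter-dependent amplitude ``eta_star`` is defined (0.45).
    single_file_threshold_um : parent diameter below which RBC routing at
        divergent bifurcations is single-file (pressure-force rule) rather
        than governed by the phase-separation law.
    fahraeus_* : coefficients of Ht/Hd = Hd + (1-Hd)(1 + c1 e^{-c2 D} - c3 e^{-c4 D}).
    ps_a, ps_b, ps_x0 : coefficients of the logit phase-separation law
        (A = -ps_a * (Da^2-Db^2)/(Da^2+Db^2) * (1-Hd)/Df, etc.).
    """

    plasma_viscosity_mPas: float = 1.2
    reference_hct: float = 0.45
    single_file_threshold_um: float = 10.0
    fahraeus_c1: float = 1.7
    fahraeus_c2: float = 0.415
    fahraeus_c3: float = 0.6
    fahraeus_c4: float = 0.011
    ps_a: float = 13.29
    ps_b: float = 6.98
    ps_x0: float = 0.964

    def with_(self, **kw) -> "RheologyParams":
        return replace(self, **kw)


DEFAULT_RHEOLOGY = RheologyParams()


# ----------------------------------------------------------------------
# Relative effective viscosity (in vitro law)


def _eta_star_45(d: float) -> float:
    # relative apparent viscosity at Hd = 0.45 as a function of diameter (µm)
    return 220.0 * math.exp(-1.3 * d) + 3.2 - 2.44 * math.exp(-0.06 * d**0.645)


def _shape_exponent(d: float) -> float:
    # hematocrit-dependence exponent C(D) of the in vitro law
    frac = 1.0 / (1.0 + 1e-11 * d**12)
    return (0.8 + math.exp(-0.075 * d)) * (-1.0 + frac) + frac


def relative_effective_viscosity(d_um: float, hd: float, params: RheologyParams = DEFAULT_RHEOLOGY) -> float:
    """Relative effective (apparent) viscosity of blood in a tube.

    Parameters
    ----------
    d_um : tube diameter in µm (> 0).
    hd : discharge hematocrit in [0, 1).

    Returns the dimensionless factor ``mu_rel >= 1`` multiplying the plasma
    viscosity. Equals 1 exactly in the plasma-only limit ``hd = 0``.
    """
    if d_um <= 0:
        raise ValueError(f"diameter must be positive, got {d_um}")
    if not 0.0 <= hd < 1.0:
        raise ValueError(f"discharge hematocrit must be in [0, 1), got {hd}")
    c = _shape_exponent(d_um)
    eta45 = _eta_star_45(d_um)
    href = params.reference_hct
    num = (1.0 - hd) ** c - 1.0
    den = (1.0 - href) ** c - 1.0
    mu = 1.0 + (eta45 - 1.0) * num / den
    return max(mu, 1.0)


# ----------------------------------------------------------------------
# Fahraeus effect: tube vs discharge hematocrit


def _fahraeus_x(d_um: float, p: RheologyParams) -> float:
    return 1.0 + p.fahraeus_c1 * math.exp(-p.fahraeus_c2 * d_um) - p.fahraeus_c3 * math.exp(-p.fahraeus_c4 * d_um)


def tube_hematocrit(d_um: float, hd: float, params: RheologyParams = DEFAULT_RHEOLOGY) -> float:
    """Tube hematocrit Ht for a given discharge hematocrit Hd (forward law).

    Ht/Hd = Hd + (1 - Hd) * X(D). Clamped to Ht <= Hd so the RBC velocity
    factor never drops below 1 (the empirical fit can overshoot for
    diameters below the RBC diameter, outside its intended range).
    """
    if d_um <= 0:
        raise ValueError(f"diameter must be positive, got {d_um}")
    if not 0.0 <= hd < 1.0:
        raise ValueError(f"discharge hematocrit must be in [0, 1), got {hd}")
    x = _fahraeus_x(d_um, params)
    ht = hd * (hd + (1.0 - hd) * x)
    return min(ht, hd)


def discharge_hematocrit(d_um: float, ht: float, params: RheologyParams = DEFAULT_RHEOLOGY) -> float:
    """Discharge hematocrit Hd for a given tube hematocrit Ht (inverse law).

    Inverts the quadratic Ht = (1-X) Hd^2 + X Hd analytically. Hd >= Ht
    always (Fahraeus effect); Hd -> Ht in the large-diameter limit.
    """
    if d_um <= 0:
        raise ValueError(f"diameter must be positive, got {d_um}")
    if not 0.0 <= ht < 1.0:
        raise ValueError(f"tube hematocrit must be in [0, 1), got {ht}")
    if ht == 0.0:
        return 0.0
    x = _fahraeus_x(d_um, params)
    a = 1.0 - x
    if abs(a) < 1e-12:
        hd = ht / x
    else:
        disc = x * x + 4.0 * a * ht
        hd = (-x + math.sqrt(max(disc, 0.0))) / (2.0 * a)
    return min(max(hd, ht), 0.999999)


def velocity_factor(d_um: float, ht: float, params: RheologyParams = DEFAULT_RHEOLOGY) -> float:
    """RBC velocity factor vf = Hd/Ht (>= 1); defined as 1 when Ht = 0."""
    if ht == 0.0:
        return 1.0
    return discharge_hematocrit(d_um, ht, params) / ht


# ----------------------------------------------------------------------
# Phase separation at divergent bifurcations


def _logit(x: float) -> float:
    return math.log(x / (1.0 - x))


def _pair_split(hd: float, d_parent: float, fqb: float, d_alpha: float, d_beta: float, p: RheologyParams) -> float:
    """Fractional RBC flux to daughter alpha given its fractional blood flow."""
    x0 = p.ps_x0 * (1.0 - hd) / d_parent
    if fqb <= x0:
        return 0.0
    if fqb >= 1.0 - x0:
        return 1.0
    ratio2 = (d_alpha**2 - d_beta**2) / (d_alpha**2 + d_beta**2)
    a = -p.ps_a * ratio2 * (1.0 - hd) / d_parent
    b = 1.0 + p.ps_b * (1.0 - hd) / d_parent
    arg = (fqb - x0) / (1.0 - 2.0 * x0)
    logit_fqe = a + b * _logit(arg)
    return 1.0 / (1.0 + math.exp(-logit_fqe))


def phase_separation_split(
    parent_hd: float,
    parent_d_um: float,
    flow_fractions: Sequence[float],
    daughter_d_um: Sequence[float],
    params: RheologyParams = DEFAULT_RHEOLOGY,
) -> list[float]:
    """RBC flux fractions to the daughters of a divergent bifurcation.

    Applies the empirical logit law pairwise; with more than two daughters
    (trifurcation) the split is sequentialized: daughter 0 against the
    merged remainder (area-equivalent diameter), then recursively on the
    remainder with flow fractions renormalized.

    Only valid above the single-file threshold; callers in the single-file
    regime must use the pressure-force routing rule instead.
    """
    if parent_d_um <= params.single_file_threshold_um:
        raise RoutingRegimeError(
            f"parent diameter {parent_d_um} µm is in the single-file regime "
            f"(<= {params.single_file_threshold_um} µm); use pressure-force routing"
        )
    if len(flow_fractions) != len(daughter_d_um):
        raise ValueError("flow_fractions and daughter_d_um must align")
    if any(f < 0 for f in flow_fractions):
        raise ValueError("flow fractions must be non-negative")
    total = sum(flow_fractions)
    if not math.isclose(total, 1.0, rel_tol=1e-9, abs_tol=1e-9):
        raise ValueError(f"flow fractions must sum to 1, got {total}")
    n = len(flow_fractions)
    if n == 1:
        return [1.0]
    if n == 2:
        f0, f1 = flow_fractions
        if f0 == 0.0:
            return [0.0, 1.0]
        if f1 == 0.0:
            return [1.0, 0.0]
        e0 = _pair_split(parent_hd, parent_d_um, f0, daughter_d_um[0], daughter_d_um[1], params)
        return [e0, 1.0 - e0]
    # trifurcation and beyond: daughter 0 vs merged rest, then recurse
    f0 = flow_fractions[0]
    rest_f = total - f0
    d_rest = math.sqrt(sum(d * d for d in daughter_d_um[1:]))
    if f0 == 0.0:
        e0 = 0.0
    elif rest_f == 0.0:
        e0 = 1.0
    else:
        e0 = _pair_split(parent_hd, parent_d_um, f0, daughter_d_um[0], d_rest, params)
    if rest_f > 0.0:
        sub = phase_separation_split(
            parent_hd, parent_d_um, [f / rest_f for f in flow_fractions[1:]], daughter_d_um[1:], params
        )
    else:
        sub = [1.0 / (n - 1)] * (n - 1)
    return [e0] + [(1.0 - e0) * s for s in sub]
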