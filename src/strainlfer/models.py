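"""Linear free-energy models linking strain release and delocalization to barriers.

The core picture is Marcus theory: breaking and forming bonds are intersecting
parabolas of constant curvature, giving

    dE_act = dE_int * (1 + dE_r / (4 * dE_int))**2

where ``dE_r`` is the reaction driving force (negative = exothermic, all
energies kcal/mol) and ``dE_int`` the intrinsic barrier at zero driving force.
Truncating at first order recovers the Bell-Evans-Polanyi (BEP) principle
``dE_act = c0 + alpha * dE_r``. Letting bond delocalization chi lower the
intrinsic barrier linearly (``beta < 0``) yields the combined model

    dE_act = c0 + alpha * dE_r + beta * chi

and, with chi = n3 (three-membered rings fused to the breaking bond) and the
round empirical values alpha = 0.5, beta = -10 kcal/mol per ring, the rule of
thumb for relative barriers between two substrates:

    ddH_act(a vs b) = 0.5 * (SRE_a - SRE_b) - 10 * (n3_a - n3_b)

Sign convention throughout: exothermic driving forces / strain-release
energies are negative; a lower (more negative) ddH_act means faster.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "GAS_CONSTANT_KCAL",
    "LFERParameters",
    "BarrierDecomposition",
    "NegativeBarrierWarning",
    "UnphysicalParameterWarning",
    "marcus_barrier",
    "bep_barrier",
    "strain_deloc_barrier",
    "rule_of_thumb",
    "rate_ratio",
    "decompose",
]

#: Molar gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.98720425e-3

#: Quoted temperature for relative-rate estimates (K).
DEFAULT_TEMPERATURE = 298.0

#: Rule-of-thumb sensitivities: alpha (dimensionless) and beta (kcal/mol per
#: fused three-membered ring), rounded from the radical and anionic fits.
RULE_OF_THUMB_ALPHA = 0.5
RULE_OF_THUMB_BETA = -10.0


class NegativeBarrierWarning(UserWarning):
    """A model returned a negative absolute barrier (unphysical extrapolation)."""


class UnphysicalParameterWarning(UserWarning):
    """Fitted parameters fall outside their physically expected range."""


@dataclass(frozen=True)
class LFERParameters:
    """Sensitivities of one reaction class.

    alpha
        Fraction of the driving-force change transmitted to the barrier;
        expected in (0, 1) for a Marcus-like surface.
    beta
        Barrier change per unit of the delocalization descriptor
        (kcal/mol per electron for chi_NBO, per ring for n3); negative when
        delocalization is barrier-lowering. ``None`` for a pure BEP model.
    intercept
        Reference intrinsic barrier at zero driving force and zero
        delocalization (kcal/mol); negative values are unphysical.
    """

    alpha: float
    beta: float | None = None
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.intercept < 0.0:
            warnings.warn(
                f"negative reference intrinsic barrier ({self.intercept:.3g} kcal/mol) "
                "is unphysical",
                UnphysicalParameterWarning,
                stacklevel=3,
            )
        if not 0.0 < self.alpha < 1.0:
            warnings.warn(
                f"alpha = {self.alpha:.3g} outside the expected (0, 1) range",
                UnphysicalParameterWarning,
                stacklevel=3,
            )


@dataclass(frozen=True)
class BarrierDecomposition:
    """Split of a relative barrier into strain and delocalization parts.

    ``total = strain_term + deloc_term`` holds exactly by construction:
    strain_term = alpha * ddE_r, deloc_term = beta * d_chi, both relative to
    the compound named by ``reference_id``.
    """

    strain_term: float
    deloc_term: float
    total: float
    reference_id: str = ""
    compound_id: str = ""


def marcus_barrier(dE_r: float, dE_int: float) -> float:
    """Marcus barrier dE_int * (1 + dE_r / (4 dE_int))**2 (kcal/mol).

    Valid on |dE_r| <= 4*dE_int (the normal region); the barrier vanishes at
    dE_r = -4*dE_int and equals dE_int at zero driving force. Inverted-region
    inputs are rejected rather than extrapolated.
    """
    if dE_int <= 0.0:
        raise ValueError(f"intrinsic barrier must be positive, got {dE_int}")
    bound = 4.0 * dE_int
    if abs(dE_r) > bound:
        raise ValueError(
            f"|dE_r| = {abs(dE_r):.4g} exceeds the normal-region bound "
            f"4*dE_int = {bound:.4g} kcal/mol (inverted region not modeled)"
        )
    x = 1.0 + dE_r / bound
    return dE_int * x * x


def bep_barrier(dE_r: float, params: LFERParameters) -> float:
    """BEP barrier: intercept + alpha * dE_r (beta ignored)."""
    return params.intercept + params.alpha * dE_r


def strain_deloc_barrier(dE_r: float, chi: float, params: LFERParameters) -> float:
    """Combined model: intercept + alpha * dE_r + beta * chi.

    Reduces to the BEP barrier at chi = 0. Negative predictions are returned
    but flagged with :class:`NegativeBarrierWarning`.
    """
    if chi < 0.0:
        raise ValueError(f"delocalization descriptor must be nonnegative, got {chi}")
    beta = params.beta if params.beta is not None else 0.0
    value = params.intercept + params.alpha * dE_r + beta * chi
    if value < 0.0:
        warnings.warn(
            f"predicted barrier {value:.3g} kcal/mol is negative "
            "(model extrapolated beyond its physical range)",
            NegativeBarrierWarning,
            stacklevel=2,
        )
    return value


def rule_of_thumb(
    sre_a: float,
    sre_b: float,
    n3_a: int,
    n3_b: int,
    alpha: float = RULE_OF_THUMB_ALPHA,
    beta: float = RULE_OF_THUMB_BETA,
) -> float:
    """Relative barrier of substrate a vs b from SREs and fused-ring counts.

    ddH_act = alpha * (sre_a - sre_b) + beta * (n3_a - n3_b), with strain
    release energies given as signed driving forces (negative = exothermic
    release). Defaults alpha = 0.5, beta = -10 kcal/mol per ring; override
    beta for reaction classes with other fitted sensitivities (e.g. -114
    kcal/mol/e when chi_NBO replaces n3 in cycloadditions).
    """
    return alpha * (sre_a - sre_b) + beta * (n3_a - n3_b)


def rate_ratio(ddH_act: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Relative rate constant k_a / k_b = exp(-ddH_act / RT).

    A barrier difference of -10 kcal/mol at 298 K corresponds to a ~1e7-fold
    rate increase.
    """
    if temperature <= 0.0:
        raise ValueError(f"temperature must be positive, got {temperature} K")
    return math.exp(-ddH_act / (GAS_CONSTANT_KCAL * temperature))


def decompose(
    dd_Er: float,
    d_chi: float,
    params: LFERParameters,
    reference_id: str = "",
    compound_id: str = "",
) -> BarrierDecomposition:
    """Split ddH_act = alpha*ddE_r + beta*d_chi into its two contributions."""
    beta = params.beta if params.beta is not None else 0.0
    strain = params.alpha * dd_Er
    deloc = beta * d_chi
    return BarrierDecomposition(
        strain_term=strain,
        deloc_term=deloc,
        total=strain + deloc,
        reference_id=reference_id,
        compound_id=compound_id,
    )
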