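"""Core ODE model of Shh signal transduction and its reduced variants.

The model tracks the intracellular response of a cell to an extracellular
Sonic hedgehog (Shh) input: *ptch1* transcription and maturation of the
Ptch1 receptor, production of full-length Gli (GliFL) and its processing
into activator (GliA) and repressor (GliR) isoforms, an intermediary
Gli-induced transcription factor X that feeds back on *gli* transcription,
and a Gli-reporter transgene (*gfp*).  Unliganded active Ptch1 inhibits the
GliFL -> GliA conversion; Shh removes active Ptch1 by mass-action binding.
Smoothened is deliberately not represented: Ptch1 acts directly on Gli
processing.

Transcription of every target gene is described by a thermodynamic
promoter-occupancy function in which activator and repressor isoforms
compete for the same binding sites and modulate polymerase recruitment
(see :func:`regulation_activity`).

Three reduced variants isolate one adaptation mechanism each by disabling
the alternatives: differential Gli-isoform stability, Ptch1 transcriptional
feedback, or Gli transcriptional downregulation via X.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, fields, replace
from importlib import resources
from itertools import product
from typing import Callable, Mapping

import numpy as np

__all__ = [
    "ModelVariant",
    "ParameterSet",
    "SPECIES",
    "regulation_activity",
    "regulation_activity_enumerated",
    "basal_activity",
    "make_rhs",
    "rhs",
    "load_fig7_parameters",
]

#: State-vector layout shared by all variants.  Variants without the
#: intermediary factor X keep the x_mRNA / X slots frozen at zero.
SPECIES: tuple[str, ...] = (
    "ptc_mRNA",
    "Ptc_inactive",
    "Ptc_active",
    "gliFL_mRNA",
    "GliFL",
    "GliA",
    "GliR",
    "x_mRNA",
    "X",
    "gfp_mRNA",
)

SPECIES_INDEX: dict[str, int] = {name: i for i, name in enumerate(SPECIES)}


class ModelVariant(str, enum.Enum):
    """Wiring variants of the pathway model.

    FULL
        All couplings active: Gli regulates *ptch1*, *x* and *gfp*; X
        regulates *gli*; Gli isoform degradation rates are independent.
    GLI_STABILITY
        Differential isoform stability is the only adaptive mechanism:
        X is removed, *ptch1* and *gli* transcription are constant (basal
        polymerase occupancy), the three Gli degradation rates stay free.
    PTCH1_FEEDBACK
        Ptch1 upregulation is the only adaptive mechanism: X is removed,
        *gli* transcription is constant, and GliFL/GliA/GliR share one
        degradation rate.
    GLI_TRANSCRIPTION
        Transcriptional downregulation of *gli* by X is the only adaptive
        mechanism: *ptch1* transcription is constant (decoupled from Gli)
        and the Gli degradation rates are shared.
    """

    FULL = "full"
    GLI_STABILITY = "gli_stability"
    PTCH1_FEEDBACK = "ptch1_feedback"
    GLI_TRANSCRIPTION = "gli_transcription"

    @property
    def has_x(self) -> bool:
        return self in (ModelVariant.FULL, ModelVariant.GLI_TRANSCRIPTION)

    @property
    def ptc_regulated(self) -> bool:
        return self in (ModelVariant.FULL, ModelVariant.PTCH1_FEEDBACK)

    @property
    def shared_gli_degradation(self) -> bool:
        return self in (ModelVariant.PTCH1_FEEDBACK, ModelVariant.GLI_TRANSCRIPTION)


@dataclass(frozen=True)
class ParameterSet:
    """Kinetic and regulatory rates of the pathway model.

    Units: transcription rates ``tr_*`` in conc/h, translation ``tl_*``,
    degradation ``deg_*``, conversion ``conv_*`` and activation ``act_*``
    rates in 1/h, the Shh binding rate ``k_ShhPtc`` in 1/(conc*h),
    ``Km_Ptch1`` and ``Pol`` in conc, binding affinities ``K_*`` in 1/conc,
    cooperativity factors ``c_*`` dimensionless.  Concentration units are
    arbitrary (Shh inputs are normalized).
    """

    # transcription (conc/h)
    tr_ptc: float
    tr_gliFL: float
    tr_x: float
    # translation (1/h)
    tl_Ptc: float
    tl_GliFL: float
    tl_X: float
    # mRNA degradation (1/h)
    deg_ptc: float
    deg_gliFL: float
    deg_x: float
    # protein degradation (1/h)
    deg_Ptc: float
    deg_GliFL: float
    deg_GliA: float
    deg_GliR: float
    deg_X: float
    # isoform conversion (1/h)
    conv_GliA: float
    conv_GliR: float
    # Ptch1 maturation and Shh binding
    act_Ptc: float
    k_ShhPtc: float
    Km_Ptch1: float
    # thermodynamic regulation
    Pol: float
    K_Pol_ptc: float
    K_Pol_gli: float
    K_Pol_x: float
    K_Gli_ptc: float
    K_Gli_x: float
    K_X_gli: float
    c_GliA: float
    c_X: float
    c_GliR: float = 0.0
    # reporter transgene; default to the ptch1 promoter values when unset
    tr_gfp: float | None = None
    deg_gfp: float | None = None
    K_Gli_gfp: float | None = None
    K_Pol_gfp: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "tr_gfp", self.tr_ptc if self.tr_gfp is None else self.tr_gfp
        )
        object.__setattr__(
            self, "deg_gfp", self.deg_ptc if self.deg_gfp is None else self.deg_gfp
        )
        object.__setattr__(
            self,
            "K_Gli_gfp",
            self.K_Gli_ptc if self.K_Gli_gfp is None else self.K_Gli_gfp,
        )
        object.__setattr__(
            self,
            "K_Pol_gfp",
            self.K_Pol_ptc if self.K_Pol_gfp is None else self.K_Pol_gfp,
        )
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"parameter {f.name}={v} must be finite and >= 0")
        if self.c_GliR != 0.0:
            raise ValueError("c_GliR must be 0 (GliR always acts as a repressor)")

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ParameterSet":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    @classmethod
    def from_json(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def replace(self, **kwargs: float) -> "ParameterSet":
        return replace(self, **kwargs)

    def for_variant(self, variant: ModelVariant) -> "ParameterSet":
        """Apply the variant's parameter-tying constraints.

        Variants without X zero its production; variants with shared Gli
        stability copy ``deg_GliFL`` onto GliA and GliR.
        """
        out = self
        if not variant.has_x:
            out = out.replace(tr_x=0.0, tl_X=0.0)
        if variant.shared_gli_degradation:
            out = out.replace(deg_GliA=out.deg_GliFL, deg_GliR=out.deg_GliFL)
        return out


def load_fig7_parameters() -> ParameterSet:
    """The published NIH3T3-contrast parameter set shipped with the package."""
    ref = resources.files("shhadapt").joinpath("data/fig7_parameters.json")
    return ParameterSet.from_dict(json.loads(ref.read_text()))


def regulation_activity(
    activator_conc: float,
    repressor_conc: float,
    K_tf: float,
    c_act: float,
    K_pol: float,
    pol: float,
    n_sites: int,
) -> float:
    """Thermodynamic promoter occupancy: fraction of time polymerase is bound.

    The promoter carries ``n_sites`` identical transcription-factor sites at
    which activator (concentration ``activator_conc``, affinity ``K_tf``) and
    repressor (``repressor_conc``, same affinity) compete, plus one polymerase
    site (affinity ``K_pol``, polymerase concentration ``pol``).  A bound
    activator multiplies the polymerase-bound statistical weight by the
    cooperativity ``c_act``; a bound repressor sets it to zero (strong
    repression, cooperativity 0).  Summing Boltzmann weights over all
    microstates gives

        Z_off = (1 + K_tf*A + K_tf*R)**n
        Z_on  = K_pol*pol * (1 + c_act*K_tf*A)**n
        f     = Z_on / (Z_off + Z_on)

    and the transcription rate of gene g is ``tr_g * f``.
    """
    if n_sites not in (1, 2):
        raise ValueError(f"n_sites must be 1 or 2, got {n_sites}")
    for name, v in (
        ("activator_conc", activator_conc),
        ("repressor_conc", repressor_conc),
        ("K_tf", K_tf),
        ("c_act", c_act),
        ("K_pol", K_pol),
        ("pol", pol),
    ):
        if v < 0 or not math.isfinite(v):
            raise ValueError(f"{name}={v} must be finite and >= 0")
    z_off = (1.0 + K_tf * activator_conc + K_tf * repressor_conc) ** n_sites
    z_on = K_pol * pol * (1.0 + c_act * K_tf * activator_conc) ** n_sites
    return z_on / (z_off + z_on)


def regulation_activity_enumerated(
    activator_conc: float,
    repressor_conc: float,
    K_tf: float,
    c_act: float,
    K_pol: float,
    pol: float,
    n_sites: int,
    c_rep: float = 0.0,
) -> float:
    """Brute-force microstate enumeration of the promoter partition function.

    Every site is empty / activator-bound / repressor-bound and polymerase is
    bound or not; each microstate's weight is the product of its binding
    factors, times the cooperativity factor of every bound TF when polymerase
    is present.  Exists as an independent cross-check of
    :func:`regulation_activity`; do not use in the ODE right-hand side.
    """
    site_states = ("empty", "act", "rep")
    z_on = 0.0
    z_off = 0.0
    for occupancy in product(site_states, repeat=n_sites):
        w_bind = 1.0
        w_coop = 1.0
        for s in occupancy:
            if s == "act":
                w_bind *= K_tf * activator_conc
                w_coop *= c_act
            elif s == "rep":
                w_bind *= K_tf * repressor_conc
                w_coop *= c_rep
        z_off += w_bind
        z_on += w_bind * w_coop * K_pol * pol
    return z_on / (z_off + z_on)


def basal_activity(K_pol: float, pol: float) -> float:
    """Promoter occupancy with no transcription factors bound (constant rate)."""
    z_on = K_pol * pol
    return z_on / (1.0 + z_on)


def make_rhs(
    params: ParameterSet,
    variant: ModelVariant,
    shh: Callable[[float], float],
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Build a fast ``f(t, y)`` closure for the given variant.

    The closure evaluates the ten-species right-hand side with all variant
    decoupling resolved ahead of time; ``shh`` is the exogenous ligand
    time course (non-depleted: binding removes active Ptch1 but the ligand
    pool is prescribed, not consumed).
    """
    if not isinstance(variant, ModelVariant):
        variant = ModelVariant(variant)
    p = params.for_variant(variant)

    pol = p.Pol
    # constant (basal) occupancies where the variant decouples regulation
    f_ptc_const = None if variant.ptc_regulated else basal_activity(p.K_Pol_ptc, pol)
    f_gli_const = None if variant.has_x else basal_activity(p.K_Pol_gli, pol)

    tr_ptc, tr_gli, tr_x, tr_gfp = p.tr_ptc, p.tr_gliFL, p.tr_x, p.tr_gfp
    tl_Ptc, tl_GliFL, tl_X = p.tl_Ptc, p.tl_GliFL, p.tl_X
    deg_ptc, deg_gli, deg_x, deg_gfp = p.deg_ptc, p.deg_gliFL, p.deg_x, p.deg_gfp
    deg_Ptc, deg_GliFL, deg_GliA, deg_GliR, deg_X = (
        p.deg_Ptc,
        p.deg_GliFL,
        p.deg_GliA,
        p.deg_GliR,
        p.deg_X,
    )
    conv_A, conv_R = p.conv_GliA, p.conv_GliR
    act_Ptc, k_bind, Km = p.act_Ptc, p.k_ShhPtc, p.Km_Ptch1
    K_Gli_ptc, K_Gli_x, K_Gli_gfp, K_X_gli = (
        p.K_Gli_ptc,
        p.K_Gli_x,
        p.K_Gli_gfp,
        p.K_X_gli,
    )
    KP_ptc = p.K_Pol_ptc * pol
    KP_gli = p.K_Pol_gli * pol
    KP_x = p.K_Pol_x * pol
    KP_gfp = p.K_Pol_gfp * pol
    c_A, c_X = p.c_GliA, p.c_X
    has_x = variant.has_x

    def f(t: float, y: np.ndarray) -> np.ndarray:
        ptc, ptc_i, ptc_a, gli, glifl, glia, glir, x_m, x_p, gfp = y
        if not (glia == glia and glir == glir):  # NaN guard, cheap
            raise FloatingPointError("NaN in state vector")

        if f_ptc_const is None:
            z_off = (1.0 + K_Gli_ptc * (glia + glir)) ** 2
            z_on = KP_ptc * (1.0 + c_A * K_Gli_ptc * glia) ** 2
            f_ptc = z_on / (z_off + z_on)
        else:
            f_ptc = f_ptc_const

        if f_gli_const is None:
            z_off = 1.0 + K_X_gli * x_p
            z_on = KP_gli * (1.0 + c_X * K_X_gli * x_p)
            f_gli = z_on / (z_off + z_on)
        else:
            f_gli = f_gli_const

        z_off = (1.0 + K_Gli_gfp * (glia + glir)) ** 2
        z_on = KP_gfp * (1.0 + c_A * K_Gli_gfp * glia) ** 2
        f_gfp = z_on / (z_off + z_on)

        hill = Km / (Km + ptc_a)  # Ptch1 inhibition of GliFL -> GliA
        to_glia = conv_A * glifl * hill
        to_glir = conv_R * glifl

        dy = np.empty(10)
        dy[0] = tr_ptc * f_ptc - deg_ptc * ptc
        dy[1] = tl_Ptc * ptc - act_Ptc * ptc_i - deg_Ptc * ptc_i
        dy[2] = act_Ptc * ptc_i - deg_Ptc * ptc_a - k_bind * shh(t) * ptc_a
        dy[3] = tr_gli * f_gli - deg_gli * gli
        dy[4] = tl_GliFL * gli - to_glia - to_glir - deg_GliFL * glifl
        dy[5] = to_glia - deg_GliA * glia
        dy[6] = to_glir - deg_GliR * glir
        if has_x:
            z_off = (1.0 + K_Gli_x * (glia + glir)) ** 2
            z_on = KP_x * (1.0 + c_A * K_Gli_x * glia) ** 2
            f_x = z_on / (z_off + z_on)
            dy[7] = tr_x * f_x - deg_x * x_m
            dy[8] = tl_X * x_m - deg_X * x_p
        else:
            dy[7] = -deg_x * x_m
            dy[8] = -deg_X * x_p
        dy[9] = tr_gfp * f_gfp - deg_gfp * gfp
        return dy

    return f


def rhs(
    state: np.ndarray,
    t: float,
    params: ParameterSet,
    variant: ModelVariant,
    shh: Callable[[float], float],
) -> np.ndarray:
    """Time derivative of the state vector (convenience, rebuilds the closure).

    For repeated evaluation (integration) use :func:`make_rhs` once.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (len(SPECIES),):
        raise ValueError(f"state must have shape ({len(SPECIES)},)")
    if np.isnan(state).any():
        raise ValueError("NaN in state")
    return make_rhs(params, variant, shh)(t, state)
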