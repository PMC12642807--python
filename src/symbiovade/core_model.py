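"""Consumer-resource model of coupled host-symbiont communities.

Two host populations (native ``p_n`` and invasive ``p_i``, e.g. plants) and
their associated microbial symbiont communities (``m_n``, ``m_i``, e.g.
mycorrhizal fungi) exchange resources: symbionts supply hosts (``alpha``
coefficients, e.g. phosphorus/nitrogen) and hosts supply symbionts (``beta``
coefficients, e.g. fixed carbon).  Hosts are facultative mutualists with an
intrinsic growth rate; symbionts are obligate and cannot grow without a host.
Exchange fluxes saturate with the partner of lower biomass, so benefits and
costs are density dependent rather than fixed per-capita coefficients.

The net effect of one host-symbiont pair on each partner collapses into two
signed coefficients ``Q_p`` (net effect on the host) and ``Q_m`` (net effect
on the symbiont), which place every association on a continuum from mutualism
(both positive) to parasitism (one negative).  Cross-pair associations between
native and invasive species define seven canonical invasion scenarios.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields as dc_fields
from typing import Iterable, NamedTuple

import numpy as np

__all__ = [
    "ModelParams",
    "ReducedParams",
    "SystemState",
    "QPair",
    "InteractionRegime",
    "FluxSet",
    "CrossRegimes",
    "exchange_fluxes",
    "full_rhs",
    "reduced_rhs",
    "compute_Q",
    "classify_regime",
    "cross_pair_regimes",
    "edge_regimes",
    "pair_params",
    "reduced_from_full",
    "scenario_id",
    "swap_communities",
    "Q_SIGN_TOL",
]

#: absolute tolerance below which a Q coefficient is treated as exactly zero
#: (commensal boundary); the regime boundaries are measure-zero lines and
#: float noise must not flip labels across them.
Q_SIGN_TOL = 1e-12


@dataclass(frozen=True)
class ModelParams:
    """All rates and coefficients of the four-compartment system.

    Subscript convention for the exchange coefficients: *first index =
    supplying species, second index = receiving species* (``n`` native,
    ``i`` invasive).  So ``alpha_in`` is supply from invasive symbionts to
    native hosts, and ``beta_ni`` is supply from native hosts to invasive
    symbionts.  Competition coefficients are named by the pair appearing in
    the loss term: ``c_p_in`` multiplies ``p_n * p_i`` in the *native* host
    equation (harming ``p_n``), ``c_p_ni`` the same product in the invasive
    host equation.

    All parameters are nonnegative; ``d`` (the biomass-adjustment factor in
    the flux denominators, shared by all pairs) must be positive, and the
    self-limitation rates ``mu_*`` must be positive for bounded dynamics.
    """

    # intrinsic host growth rates (per time); symbionts are obligate: none
    r_pn: float = 0.5
    r_pi: float = 0.5
    # symbiont -> host supply coefficients (dimensionless exchange capacity)
    alpha_nn: float = 1.0
    alpha_ni: float = 0.0
    alpha_in: float = 0.0
    alpha_ii: float = 1.0
    # host -> symbiont supply coefficients
    beta_nn: float = 1.0
    beta_ni: float = 0.0
    beta_in: float = 0.0
    beta_ii: float = 1.0
    # host conversion efficiencies (h = benefit, c = cost side)
    q_hpn: float = 2.0
    q_cpn: float = 1.0
    q_hpi: float = 2.0
    q_cpi: float = 1.0
    # symbiont conversion efficiencies (c = benefit, h = cost side)
    q_cmn: float = 2.0
    q_hmn: float = 1.0
    q_cmi: float = 2.0
    q_hmi: float = 1.0
    # interspecific competition (per biomass per time)
    c_p_in: float = 0.5
    c_p_ni: float = 0.5
    c_m_in: float = 0.5
    c_m_ni: float = 0.5
    # self-limitation / maintenance (per biomass per time)
    mu_pn: float = 1.0
    mu_mn: float = 1.0
    mu_pi: float = 1.0
    mu_mi: float = 1.0
    # biomass-adjustment factor in flux denominators (dimensionless, global)
    d: float = 1.0

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {f.name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"parameter {f.name} must be >= 0, got {v!r}")
        if self.d <= 0:
            raise ValueError(f"parameter d must be > 0, got {self.d!r}")
        for name in ("mu_pn", "mu_mn", "mu_pi", "mu_mi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be > 0 for bounded dynamics")

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dc_fields(cls))

    @classmethod
    def from_dict(cls, mapping: dict) -> "ModelParams":
        known = set(cls.field_names())
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    def to_dict(self) -> dict:
        return {f.name: float(getattr(self, f.name)) for f in dc_fields(self)}

    def replace(self, **changes) -> "ModelParams":
        d = self.to_dict()
        d.update(changes)
        return ModelParams.from_dict(d)


class SystemState(NamedTuple):
    """Biomass densities of the four compartments (arbitrary biomass units)."""

    p_n: float
    m_n: float
    p_i: float
    m_i: float

    def as_array(self) -> np.ndarray:
        return np.asarray(self, dtype=float)

    @property
    def total(self) -> float:
        return float(sum(self))


STATE_NAMES = ("p_n", "m_n", "p_i", "m_i")


@dataclass(frozen=True)
class ReducedParams:
    """One-host / one-symbiont analogue of :class:`ModelParams`."""

    r_p: float
    q_hp: float
    q_cp: float
    q_cm: float
    q_hm: float
    alpha: float
    beta: float
    mu_p: float
    mu_m: float
    d: float = 1.0

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {f.name} must be finite and >= 0, got {v!r}")
        if self.d <= 0:
            raise ValueError("parameter d must be > 0")


class QPair(NamedTuple):
    """Signed net-interaction coefficients (per time) of one host-symbiont pair."""

    Q_p: float
    Q_m: float


class InteractionRegime(str, enum.Enum):
    """Position of a host-symbiont association on the mutualism-parasitism continuum."""

    MUTUALISTIC = "mutualistic"
    PARASITIC_FOR_HOST = "parasitic_for_host"
    PARASITIC_FOR_SYMBIONT = "parasitic_for_symbiont"
    COMMENSAL_HOST = "commensal_host"
    COMMENSAL_SYMBIONT = "commensal_symbiont"
    NEUTRAL = "neutral"
    #: both Q negative: both partners lose from the exchange.  Not part of the
    #: model's taxonomy (with all conversion efficiencies positive it requires
    #: both benefit streams to vanish); flagged, never silently classified.
    INVALID_EXCHANGE = "invalid_exchange"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class FluxSet:
    """Aggregate exchange fluxes and their per-pair kernels (all per time).

    ``gain_*`` / ``cost_*`` are the two terms of each compartment's net flux
    function.  ``kernel_alpha[j, k]`` is the symbiont-j -> host-k kernel
    ``alpha_jk * m_j * p_k / D_alpha`` and ``kernel_beta[j, k]`` the
    host-j -> symbiont-k kernel ``beta_jk * p_j * m_k / D_beta``, with the
    shared denominators ``D_alpha = (p_n + p_i)/d + m_n + m_i`` and
    ``D_beta = p_n + p_i + d*(m_n + m_i)`` (index 0 = native, 1 = invasive).
    Each aggregate flux is its q-coefficient times the sum of its kernels, so
    per-pair conservation holds structurally: the host-j cost attributable to
    ``beta_jk`` divided by ``q_cp_j`` equals the symbiont-k gain attributable
    to ``beta_jk`` divided by ``q_cm_k`` (and mirrored for alpha kernels).
    """

    gain_p_n: float
    cost_p_n: float
    gain_m_n: float
    cost_m_n: float
    gain_p_i: float
    cost_p_i: float
    gain_m_i: float
    cost_m_i: float
    kernel_alpha: np.ndarray  # (2, 2), [supplier, receiver]
    kernel_beta: np.ndarray  # (2, 2), [supplier, receiver]

    @property
    def net(self) -> np.ndarray:
        """Net flux into each compartment, ordered (p_n, m_n, p_i, m_i)."""
        return np.array(
            [
                self.gain_p_n - self.cost_p_n,
                self.gain_m_n - self.cost_m_n,
                self.gain_p_i - self.cost_p_i,
                self.gain_m_i - self.cost_m_i,
            ]
        )


def _check_state(state: Iterable[float], n: int) -> np.ndarray:
    arr = np.asarray(tuple(state), dtype=float)
    if arr.shape != (n,):
        raise ValueError(f"state must have {n} components, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"state must be finite, got {arr}")
    if np.any(arr < 0):
        raise ValueError(f"state components must be nonnegative, got {arr}")
    return arr


def exchange_fluxes(state, params: ModelParams) -> FluxSet:
    """Evaluate all resource-exchange fluxes at ``state``.

    Flux ratios are defined as 0 whenever their denominator is 0, which (with
    d > 0) happens only at the all-zero state; extinction is an equilibrium.
    """
    p_n, m_n, p_i, m_i = _check_state(state, 4)
    pr = params
    D_a = (p_n + p_i) / pr.d + m_n + m_i
    D_b = p_n + p_i + pr.d * (m_n + m_i)

    if D_a <= 0.0 or D_b <= 0.0:
        zero = np.zeros((2, 2))
        return FluxSet(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, zero, zero)

    m = np.array([m_n, m_i])
    p = np.array([p_n, p_i])
    alpha = np.array([[pr.alpha_nn, pr.alpha_ni], [pr.alpha_in, pr.alpha_ii]])
    beta = np.array([[pr.beta_nn, pr.beta_ni], [pr.beta_in, pr.beta_ii]])
    kernel_alpha = alpha * np.outer(m, p) / D_a
    kernel_beta = beta * np.outer(p, m) / D_b

    return FluxSet(
        gain_p_n=pr.q_hpn * kernel_alpha[:, 0].sum(),
        cost_p_n=pr.q_cpn * kernel_beta[0, :].sum(),
        gain_m_n=pr.q_cmn * kernel_beta[:, 0].sum(),
        cost_m_n=pr.q_hmn * kernel_alpha[0, :].sum(),
        gain_p_i=pr.q_hpi * kernel_alpha[:, 1].sum(),
        cost_p_i=pr.q_cpi * kernel_beta[1, :].sum(),
        gain_m_i=pr.q_cmi * kernel_beta[:, 1].sum(),
        cost_m_i=pr.q_hmi * kernel_alpha[1, :].sum(),
        kernel_alpha=kernel_alpha,
        kernel_beta=kernel_beta,
    )


def full_rhs(state, params: ModelParams) -> np.ndarray:
    """Time derivative (dp_n, dm_n, dp_i, dm_i) of the four-compartment system.

    Each compartment follows growth (hosts only) + net exchange flux −
    interspecific competition − quadratic self-limitation.  The system is
    autonomous.
    """
    p_n, m_n, p_i, m_i = _check_state(state, 4)
    fl = exchange_fluxes(state, params)
    pr = params
    return np.array(
        [
            pr.r_pn * p_n + fl.gain_p_n - fl.cost_p_n - pr.c_p_in * p_n * p_i - pr.mu_pn * p_n**2,
            fl.gain_m_n - fl.cost_m_n - pr.c_m_in * m_n * m_i - pr.mu_mn * m_n**2,
            pr.r_pi * p_i + fl.gain_p_i - fl.cost_p_i - pr.c_p_ni * p_n * p_i - pr.mu_pi * p_i**2,
            fl.gain_m_i - fl.cost_m_i - pr.c_m_ni * m_n * m_i - pr.mu_mi * m_i**2,
        ]
    )


def reduced_rhs(state2, rp: ReducedParams) -> np.ndarray:
    """Time derivative of the one-host/one-symbiont system.

    dp/dt = r_p*p + s*Q_p − mu_p*p**2  and  dm/dt = s*Q_m − mu_m*m**2, where
    s = p*m / (p/d + m) is the shared saturating interaction term (0 at the
    origin by convention) and (Q_p, Q_m) are the net-interaction coefficients
    of :func:`compute_Q`.
    """
    p, m = _check_state(state2, 2)
    denom = p / rp.d + m
    s = p * m / denom if denom > 0 else 0.0
    Q_p, Q_m = compute_Q(rp)
    return np.array(
        [
            rp.r_p * p + s * Q_p - rp.mu_p * p**2,
            s * Q_m - rp.mu_m * m**2,
        ]
    )


def compute_Q(rp: ReducedParams) -> QPair:
    """Net-interaction coefficients of a host-symbiont pair.

    ``Q_p = q_hp*alpha/d − q_cp*beta`` (net effect of the symbiont on the
    host) and ``Q_m = q_cm*beta − q_hm*alpha/d`` (net effect of the host on
    the symbiont).
    """
    return QPair(
        Q_p=rp.q_hp * rp.alpha / rp.d - rp.q_cp * rp.beta,
        Q_m=rp.q_cm * rp.beta - rp.q_hm * rp.alpha / rp.d,
    )


def classify_regime(q: QPair, tol: float = Q_SIGN_TOL) -> InteractionRegime:
    """Map the signs of (Q_p, Q_m) to an interaction regime.

    (+,+) mutualistic; (−,+) parasitic for the host; (+,−) parasitic for the
    symbiont; a Q within ``tol`` of zero is a commensal boundary; (0,0) is
    neutral.  The double-negative pattern is reported as
    :attr:`InteractionRegime.INVALID_EXCHANGE` rather than silently placed on
    the continuum.  Boundary patterns (0,−) and (−,0) are classified by the
    harmed partner (parasitic_for_symbiont / parasitic_for_host).
    """
    Q_p, Q_m = q
    if not (np.isfinite(Q_p) and np.isfinite(Q_m)):
        raise ValueError(f"Q values must be finite, got {q}")
    zp = abs(Q_p) < tol
    zm = abs(Q_m) < tol
    if zp and zm:
        return InteractionRegime.NEUTRAL
    if zp:
        return (
            InteractionRegime.COMMENSAL_HOST if Q_m > 0 else InteractionRegime.PARASITIC_FOR_SYMBIONT
        )
    if zm:
        return (
            InteractionRegime.COMMENSAL_SYMBIONT if Q_p > 0 else InteractionRegime.PARASITIC_FOR_HOST
        )
    if Q_p > 0 and Q_m > 0:
        return InteractionRegime.MUTUALISTIC
    if Q_p < 0 and Q_m > 0:
        return InteractionRegime.PARASITIC_FOR_HOST
    if Q_p > 0 and Q_m < 0:
        return InteractionRegime.PARASITIC_FOR_SYMBIONT
    return InteractionRegime.INVALID_EXCHANGE


# the four host-symbiont edges of the interaction network, as
# (host tag, symbiont tag) with the parameter fields they draw on
_EDGES = {
    "pn_mn": dict(alpha="alpha_nn", beta="beta_nn", q_hp="q_hpn", q_cp="q_cpn",
                  q_cm="q_cmn", q_hm="q_hmn", r_p="r_pn", mu_p="mu_pn", mu_m="mu_mn"),
    "pi_mi": dict(alpha="alpha_ii", beta="beta_ii", q_hp="q_hpi", q_cp="q_cpi",
                  q_cm="q_cmi", q_hm="q_hmi", r_p="r_pi", mu_p="mu_pi", mu_m="mu_mi"),
    # native host <- invasive symbionts (alpha_in) / -> invasive symbionts (beta_ni)
    "pn_mi": dict(alpha="alpha_in", beta="beta_ni", q_hp="q_hpn", q_cp="q_cpn",
                  q_cm="q_cmi", q_hm="q_hmi", r_p="r_pn", mu_p="mu_pn", mu_m="mu_mi"),
    # invasive host <- native symbionts (alpha_ni) / -> native symbionts (beta_in)
    "pi_mn": dict(alpha="alpha_ni", beta="beta_in", q_hp="q_hpi", q_cp="q_cpi",
                  q_cm="q_cmn", q_hm="q_hmn", r_p="r_pi", mu_p="mu_pi", mu_m="mu_mn"),
}


def pair_params(params: ModelParams, edge: str) -> ReducedParams:
    """Pairwise :class:`ReducedParams` of one host-symbiont edge.

    ``edge`` is one of ``pn_mn``, ``pi_mi``, ``pn_mi``, ``pi_mn``; the
    coefficients are taken verbatim from the full parameter set (no
    rescaling), matching the regime-boundary inequalities in (alpha, beta)
    space.
    """
    try:
        spec = _EDGES[edge]
    except KeyError:
        raise ValueError(f"unknown edge {edge!r}; expected one of {sorted(_EDGES)}") from None
    return ReducedParams(d=params.d, **{k: getattr(params, v) for k, v in spec.items()})


class CrossRegimes(NamedTuple):
    """Regimes of the two cross-community edges."""

    pn_mi: InteractionRegime  # native host <-> invasive symbionts
    pi_mn: InteractionRegime  # invasive host <-> native symbionts


def cross_pair_regimes(params: ModelParams) -> CrossRegimes:
    """Interaction regimes of the two novel (cross-community) associations."""
    return CrossRegimes(
        pn_mi=classify_regime(compute_Q(pair_params(params, "pn_mi"))),
        pi_mn=classify_regime(compute_Q(pair_params(params, "pi_mn"))),
    )


def edge_regimes(params: ModelParams) -> dict[str, InteractionRegime]:
    """Regime of each of the four host-symbiont edges."""
    return {
        edge: classify_regime(compute_Q(pair_params(params, edge))) for edge in _EDGES
    }


def reduced_from_full(params: ModelParams, community: str = "native") -> ReducedParams:
    """Reduced parameters whose dynamics exactly equal the full system
    restricted to one resident pair (other community and cross terms zero).

    Because the reduced system groups both flux terms over the single
    saturating factor p*m/(p/d + m), its (alpha, beta) are the full-model
    coefficients rescaled by the biomass-adjustment factor: alpha -> d*alpha,
    beta -> beta/d (identity at d = 1).  Use :func:`pair_params` instead when
    classifying regimes in raw (alpha, beta) space.
    """
    edge = {"native": "pn_mn", "invasive": "pi_mi"}[community]
    rp = pair_params(params, edge)
    return ReducedParams(
        r_p=rp.r_p, q_hp=rp.q_hp, q_cp=rp.q_cp, q_cm=rp.q_cm, q_hm=rp.q_hm,
        alpha=rp.alpha * params.d, beta=rp.beta / params.d,
        mu_p=rp.mu_p, mu_m=rp.mu_m, d=params.d,
    )


# per-edge scenario digits for a single active cross edge
_SCENARIO_PI_MN = {
    InteractionRegime.MUTUALISTIC: "2",
    InteractionRegime.PARASITIC_FOR_HOST: "4",  # native symbionts exploit invasive hosts
    InteractionRegime.PARASITIC_FOR_SYMBIONT: "5",  # invasive hosts exploit native symbionts
}
_SCENARIO_PN_MI = {
    InteractionRegime.MUTUALISTIC: "3",
    InteractionRegime.PARASITIC_FOR_HOST: "6",  # invasive symbionts exploit native hosts
    InteractionRegime.PARASITIC_FOR_SYMBIONT: "7",  # native hosts exploit invasive symbionts
}


def scenario_id(params: ModelParams) -> str:
    """Canonical invasion-scenario label from the two cross-edge regimes.

    "1" when neither community shares partners (both cross edges neutral);
    "2"-"7" when exactly one cross edge is active; an ordered combined label
    like "(2,6)" when both edges are active simultaneously.  Commensal or
    invalid edges (boundary cases outside the seven-region taxonomy) are
    labelled by their regime name.
    """
    cross = cross_pair_regimes(params)

    def one(edge_regime: InteractionRegime, table: dict, tag: str) -> str:
        return table.get(edge_regime, f"{tag}:{edge_regime.value}")

    pn_mi_active = cross.pn_mi is not InteractionRegime.NEUTRAL
    pi_mn_active = cross.pi_mn is not InteractionRegime.NEUTRAL
    if not pn_mi_active and not pi_mn_active:
        return "1"
    if pi_mn_active and not pn_mi_active:
        return one(cross.pi_mn, _SCENARIO_PI_MN, "pi_mn")
    if pn_mi_active and not pi_mn_active:
        return one(cross.pn_mi, _SCENARIO_PN_MI, "pn_mi")
    return f"({one(cross.pi_mn, _SCENARIO_PI_MN, 'pi_mn')},{one(cross.pn_mi, _SCENARIO_PN_MI, 'pn_mi')})"


_SWAP = {
    "r_pn": "r_pi",
    "alpha_nn": "alpha_ii", "alpha_ni": "alpha_in",
    "beta_nn": "beta_ii", "beta_ni": "beta_in",
    "q_hpn": "q_hpi", "q_cpn": "q_cpi", "q_cmn": "q_cmi", "q_hmn": "q_hmi",
    "c_p_in": "c_p_ni", "c_m_in": "c_m_ni",
    "mu_pn": "mu_pi", "mu_mn": "mu_mi",
}
_SWAP.update({v: k for k, v in _SWAP.items()})


def swap_communities(params: ModelParams) -> ModelParams:
    """Relabel native <-> invasive throughout the parameter set."""
    src = params.to_dict()
    return ModelParams.from_dict({k: src[_SWAP.get(k, k)] for k in src})


def swap_state(state) -> np.ndarray:
    """Relabel native <-> invasive in a state 4-vector."""
    p_n, m_n, p_i, m_i = np.asarray(tuple(state), dtype=float)
    return np.array([p_i, m_i, p_n, m_n])
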