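"""Parameter-space exploration: regime-region maps over (alpha, beta) and
invasion-outcome phase diagrams over arbitrary parameter axes.

Region maps are pure algebra (per-cell sign evaluation of the two
net-interaction coefficients) and carry the analytic boundary lines; phase
diagrams run a full invasion experiment per cell.  Cells are evaluated
independently, so the order of evaluation cannot affect results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .core_model import (
    InteractionRegime,
    ModelParams,
    classify_regime,
    compute_Q,
    pair_params,
)
from .experiments import PropaguleSpec, invasion_experiment

__all__ = [
    "RegionMap",
    "SamplingError",
    "regime_region_map",
    "outcome_phase_diagram",
    "sample_params",
    "EDGE_COEFFS",
]

#: cross-edge name -> (alpha field, beta field) swept by a region map
EDGE_COEFFS = {
    "pn_mi": ("alpha_in", "beta_ni"),
    "pi_mn": ("alpha_ni", "beta_in"),
}


class SamplingError(RuntimeError):
    """Rejection sampling failed to satisfy the regime constraints."""


@dataclass
class RegionMap:
    """Labelled grid over two parameter axes.

    ``labels[i, j]`` is the label at ``(axis1_values[i], axis2_values[j])``.
    For regime maps, ``lines`` holds the analytic boundary coefficients: the
    host-commensal line alpha = ``alpha_over_beta`` * beta (Q_p = 0) and the
    symbiont-commensal line beta = ``beta_over_alpha`` * alpha (Q_m = 0).
    """

    axis1_name: str
    axis2_name: str
    axis1_values: np.ndarray
    axis2_values: np.ndarray
    labels: np.ndarray  # dtype=object, shape (n1, n2)
    lines: dict = field(default_factory=dict)
    base_params: Optional[ModelParams] = None
    meta: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        a1, a2 = np.meshgrid(self.axis1_values, self.axis2_values, indexing="ij")
        return pd.DataFrame(
            {
                self.axis1_name: a1.ravel(),
                self.axis2_name: a2.ravel(),
                "label": [str(v) for v in self.labels.ravel()],
            }
        )

    def header(self) -> dict:
        return {
            "axis1": {"name": self.axis1_name,
                      "min": float(self.axis1_values.min()),
                      "max": float(self.axis1_values.max()),
                      "n": int(len(self.axis1_values))},
            "axis2": {"name": self.axis2_name,
                      "min": float(self.axis2_values.min()),
                      "max": float(self.axis2_values.max()),
                      "n": int(len(self.axis2_values))},
            "lines": {k: float(v) for k, v in self.lines.items()},
            "base_params": self.base_params.to_dict() if self.base_params else None,
            **self.meta,
        }


def regime_region_map(
    params: ModelParams,
    edge: str = "pn_mi",
    alpha_range: tuple[float, float] = (0.02, 2.0),
    beta_range: tuple[float, float] = (0.02, 2.0),
    grid: int = 101,
) -> RegionMap:
    """Interaction regime of one cross edge over an (alpha, beta) grid.

    Each cell substitutes its (alpha, beta) into the edge's exchange
    coefficients and classifies the resulting pair.  The analytic boundary
    lines are ``alpha = (q_cp/q_hp)*d * beta`` (host commensal, Q_p = 0) and
    ``beta = (q_hm/q_cm)/d * alpha`` (symbiont commensal, Q_m = 0); the
    mutualism wedge lies between them when it is nonempty.
    """
    if edge not in EDGE_COEFFS:
        raise ValueError(f"edge must be one of {sorted(EDGE_COEFFS)}, got {edge!r}")
    if grid < 2:
        raise ValueError("grid must be >= 2 per axis")
    if alpha_range[0] <= 0 or beta_range[0] <= 0:
        raise ValueError("ranges must be positive")
    a_field, b_field = EDGE_COEFFS[edge]
    alphas = np.linspace(alpha_range[0], alpha_range[1], grid)
    betas = np.linspace(beta_range[0], beta_range[1], grid)
    labels = np.empty((grid, grid), dtype=object)
    rp0 = pair_params(params, edge)
    for i, a in enumerate(alphas):
        for j, b in enumerate(betas):
            rp = pair_params(
                params.replace(**{a_field: float(a), b_field: float(b)}), edge
            )
            labels[i, j] = classify_regime(compute_Q(rp))
    lines = {
        "alpha_over_beta": rp0.q_cp / rp0.q_hp * params.d if rp0.q_hp > 0 else np.inf,
        "beta_over_alpha": rp0.q_hm / rp0.q_cm / params.d if rp0.q_cm > 0 else np.inf,
    }
    return RegionMap(
        axis1_name=a_field, axis2_name=b_field,
        axis1_values=alphas, axis2_values=betas,
        labels=labels, lines=lines, base_params=params,
        meta={"edge": edge, "kind": "regime"},
    )


def outcome_phase_diagram(
    base_params: ModelParams,
    axis1: str,
    axis2: str,
    grid: int | tuple[int, int] = 21,
    propagule: PropaguleSpec = PropaguleSpec(),
    axis1_range: tuple[float, float] = (0.02, 2.0),
    axis2_range: tuple[float, float] = (0.02, 2.0),
    t_cap: float = 1e5,
) -> RegionMap:
    """Invasion-outcome label for every cell of a 2-parameter grid.

    Cells whose dynamics do not converge are labelled ``non_converged``
    (with a ``limit_cycle:`` prefix when oscillation was detected); per-cell
    failures are recorded as ``error:...`` labels, never raised.
    """
    names = ModelParams.field_names()
    for ax in (axis1, axis2):
        if ax not in names:
            raise ValueError(f"{ax!r} is not a ModelParams field")
    n1, n2 = (grid, grid) if isinstance(grid, int) else grid
    v1 = np.linspace(axis1_range[0], axis1_range[1], n1) if n1 > 1 else np.array([axis1_range[0]])
    v2 = np.linspace(axis2_range[0], axis2_range[1], n2) if n2 > 1 else np.array([axis2_range[0]])
    labels = np.empty((len(v1), len(v2)), dtype=object)
    for i, a in enumerate(v1):
        for j, b in enumerate(v2):
            try:
                p = base_params.replace(**{axis1: float(a), axis2: float(b)})
                result = invasion_experiment(p, propagule, t_cap=t_cap)
                out = result.outcome
                if out.limit_cycle:
                    labels[i, j] = f"limit_cycle:{out.label}"
                elif not out.converged:
                    labels[i, j] = "non_converged"
                else:
                    labels[i, j] = out.label
            except Exception as exc:  # per-cell errors stay in the map
                labels[i, j] = f"error:{type(exc).__name__}"
    return RegionMap(
        axis1_name=axis1, axis2_name=axis2,
        axis1_values=v1, axis2_values=v2,
        labels=labels, base_params=base_params,
        meta={"kind": "outcome", "propagule_fraction": propagule.fraction},
    )


# edges whose regime can be constrained during sampling
_CONSTRAINABLE = ("pn_mn", "pi_mi", "pn_mi", "pi_mn")
_EDGE_FIELDS = {
    "pn_mn": ("alpha_nn", "beta_nn"),
    "pi_mi": ("alpha_ii", "beta_ii"),
    "pn_mi": ("alpha_in", "beta_ni"),
    "pi_mn": ("alpha_ni", "beta_in"),
}
#: log-uniform draw range for free rate/coefficient parameters
DRAW_RANGE = (1e-2, 1e1)


def sample_params(
    constraints: dict[str, InteractionRegime | str] | None = None,
    seed: int | np.random.Generator = 0,
    max_draws: int = 10_000,
    d: float = 1.0,
) -> ModelParams:
    """Rejection-sample a parameter set satisfying per-edge regime constraints.

    ``constraints`` maps edge names (``pn_mn``, ``pi_mi``, ``pn_mi``,
    ``pi_mn``) to required :class:`InteractionRegime` values.  Exchange,
    conversion, growth, competition and maintenance parameters are drawn
    log-uniformly over [1e-2, 1e1]; ``d`` is held fixed (default 1).  A
    ``neutral`` constraint forces that edge's exchange coefficients to zero
    exactly.  Deterministic under a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    constraints = {
        k: InteractionRegime(v) for k, v in (constraints or {}).items()
    }
    unknown = set(constraints) - set(_CONSTRAINABLE)
    if unknown:
        raise ValueError(f"unknown edges in constraints: {sorted(unknown)}")

    lo, hi = np.log(DRAW_RANGE[0]), np.log(DRAW_RANGE[1])

    def draw() -> ModelParams:
        vals = {}
        for name in ModelParams.field_names():
            if name == "d":
                vals[name] = d
            else:
                vals[name] = float(np.exp(rng.uniform(lo, hi)))
        # neutral edges: no exchange on that edge at all
        for edge, regime in constraints.items():
            if regime is InteractionRegime.NEUTRAL:
                a_f, b_f = _EDGE_FIELDS[edge]
                vals[a_f] = 0.0
                vals[b_f] = 0.0
        # unconstrained cross edges default to inactive (no shared partners)
        for edge in ("pn_mi", "pi_mn"):
            if edge not in constraints:
                a_f, b_f = _EDGE_FIELDS[edge]
                vals[a_f] = 0.0
                vals[b_f] = 0.0
        return ModelParams.from_dict(vals)

    from .core_model import edge_regimes

    for _ in range(max_draws):
        cand = draw()
        regimes = edge_regimes(cand)
        if all(regimes[e] is r for e, r in constraints.items()):
            return cand
    raise SamplingError(
        f"no parameter set satisfying {constraints} found in {max_draws} draws"
    )
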