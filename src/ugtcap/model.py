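"""Sigmoid conjugation-capacity model for UGT1A1 variants.

The capacity of a variant enzyme for a substrate l is modelled as

    P_c = sigma * kappa * [ 1 / (1 + exp(-gamma_l (S_DH/S_DT - mu_l))) ]^beta_l + epsilon

where S_DH/S_DT is the fraction of docking poses with the substrate hydroxyl
oriented toward the coenzyme, beta_l = S_DT / S_DH(wild) anchors the exponent
to the wild-type enzyme, sigma is a substrate-specific scale, gamma_l and
mu_l are the sigmoid slope and midpoint, kappa scales for the *28 promoter
genotype, and epsilon is an in-vivo environment offset fixed at 0 for
in vitro work.

Relative capacity (percent of wild type) divides out sigma; with epsilon = 0
it reduces to ``100 * kappa * S(mutant) / S(wild)``.

The free constants (sigma, gamma, mu, and optionally epsilon) are estimated
by minimising the sum of squared errors against in vitro capacities over the
fit set M: the variants with a known capacity and at least one correct
coenzyme binding mode. Variants with no correct coenzyme binding are outside
the model's domain and are predicted as zero capacity with an explicit flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError

__all__ = [
    "GENOTYPES",
    "VMAX_BY_GENOTYPE",
    "KAPPA_TABLE",
    "kappa",
    "DockingSummary",
    "VariantRecord",
    "Panel",
    "ModelParams",
    "CapacityPrediction",
    "FitResult",
    "compute_beta",
    "sigmoid_term",
    "substrate_contribution",
    "predict",
    "predict_absolute",
    "predict_relative",
    "fit_parameters",
]

GENOTYPES = ("wild/wild", "wild/*28", "*28/*28")

#: Reported Vmax (nmol/min/mg) by TA-repeat promoter genotype.
VMAX_BY_GENOTYPE = {
    "wild/wild": 16.2,
    "wild/*28": 12.0,
    "*28/*28": 3.4,
}

#: Promoter-genotype scale factors (Vmax ratios rounded to two decimals).
KAPPA_TABLE = {
    "wild/wild": 1.0,
    "wild/*28": 0.74,
    "*28/*28": 0.21,
}


def kappa(genotype: str, mode: str = "table") -> float:
    """Promoter-genotype factor.

    ``mode='table'`` returns the two-decimal convention values;
    ``mode='vmax'`` recomputes the exact Vmax ratio (e.g. 12.0/16.2).
    """
    if genotype not in KAPPA_TABLE:
        raise ValueError(
            f"unknown genotype {genotype!r}; expected one of {GENOTYPES}"
        )
    if mode == "table":
        return KAPPA_TABLE[genotype]
    if mode == "vmax":
        return VMAX_BY_GENOTYPE[genotype] / VMAX_BY_GENOTYPE["wild/wild"]
    raise ValueError(f"unknown kappa mode {mode!r}")


@dataclass
class DockingSummary:
    """Per (variant, ligand) docking counts."""

    variant: str
    ligand: str
    S_DT: int
    S_DH: int
    udpga_correct_count: int = 1

    def __post_init__(self) -> None:
        if self.S_DT <= 0:
            raise ValueError("S_DT must be positive")
        if not 0 <= self.S_DH <= self.S_DT:
            raise ValueError("S_DH must satisfy 0 <= S_DH <= S_DT")
        if self.udpga_correct_count < 0:
            raise ValueError("udpga_correct_count must be non-negative")

    @property
    def fraction(self) -> float:
        return self.S_DH / self.S_DT


@dataclass
class VariantRecord:
    """In vitro capacity of a variant; ``v_c is None`` encodes ND."""

    variant: str
    genotype: str = "wild/wild"
    v_c: float | None = None

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.v_c is not None and self.v_c < 0:
            raise ValueError("capacity must be non-negative when present")

    @property
    def is_nd(self) -> bool:
        return self.v_c is None


@dataclass
class Panel:
    """One substrate's variant panel: wild-type docking summary plus
    (docking summary, in vitro record) pairs for each variant."""

    ligand: str
    wild_summary: DockingSummary
    members: list[tuple[DockingSummary, VariantRecord]]

    def __post_init__(self) -> None:
        if self.wild_summary.S_DH <= 0:
            raise ValueError(
                "wild-type substrate has no oriented poses; beta undefined"
            )
        for summary, record in self.members:
            if summary.variant != record.variant:
                raise ValueError(
                    f"member mismatch: {summary.variant!r} vs {record.variant!r}"
                )

    @property
    def fit_set(self) -> list[tuple[DockingSummary, VariantRecord]]:
        """Set M: members with a known capacity and a correct coenzyme
        binding mode."""
        return [
            (s, r)
            for s, r in self.members
            if not r.is_nd and s.udpga_correct_count > 0
        ]

    def without(self, variant: str) -> "Panel":
        return Panel(
            ligand=self.ligand,
            wild_summary=self.wild_summary,
            members=[(s, r) for s, r in self.members if s.variant != variant],
        )


@dataclass
class ModelParams:
    """Fitted or assumed model constants for one substrate."""

    sigma: float
    gamma: float
    mu: float
    epsilon: float = 0.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


@dataclass
class CapacityPrediction:
    """Decomposed prediction for one variant."""

    variant: str
    S_term: float
    kappa: float
    P_c_absolute: float
    P_c_relative: float | None = None
    C_term: float = 1.0
    no_correct_binding: bool = False


def compute_beta(S_DT: int, S_DH_wild: int) -> float:
    """Sigmoid exponent beta_l = S_DT / S_DH(wild)."""
    if S_DH_wild <= 0:
        raise FitError(
            "wild-type substrate has no oriented poses; beta undefined"
        )
    return S_DT / S_DH_wild


def sigmoid_term(f: float, gamma: float, mu: float) -> float:
    """Inner logistic ``1 / (1 + exp(-gamma (f - mu)))``; increasing in f."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return float(1.0 / (1.0 + np.exp(-gamma * (np.asarray(f, float) - mu))))


def substrate_contribution(summary: DockingSummary, params: ModelParams) -> float:
    """S term: the logistic of the oriented fraction raised to beta."""
    return sigmoid_term(summary.fraction, params.gamma, params.mu) ** params.beta


def predict(
    summary: DockingSummary,
    genotype: str,
    params: ModelParams,
    wild_summary: DockingSummary | None = None,
    kappa_mode: str = "table",
) -> CapacityPrediction:
    """Full prediction for one variant.

    A variant with no correct coenzyme binding mode is predicted as zero
    capacity and flagged (``no_correct_binding``): the sigmoid is not
    evaluated for it, as such variants fall outside the model's fit set.
    When ``wild_summary`` is given the relative capacity (percent of wild
    type) is also computed.
    """
    k = kappa(genotype, kappa_mode)
    if summary.udpga_correct_count == 0:
        return CapacityPrediction(
            variant=summary.variant,
            S_term=0.0,
            kappa=k,
            P_c_absolute=0.0,
            P_c_relative=0.0 if wild_summary is not None else None,
            no_correct_binding=True,
        )
    s_term = substrate_contribution(summary, params)
    absolute = params.sigma * k * s_term + params.epsilon
    relative = None
    if wild_summary is not None:
        s_wild = substrate_contribution(wild_summary, params)
        wild_abs = params.sigma * s_wild + params.epsilon
        if wild_abs == 0:
            raise FitError("wild-type S term is zero; relative capacity undefined")
        if params.epsilon == 0:
            relative = 100.0 * k * s_term / s_wild
        else:
            relative = 100.0 * absolute / wild_abs
    return CapacityPrediction(
        variant=summary.variant,
        S_term=s_term,
        kappa=k,
        P_c_absolute=absolute,
        P_c_relative=relative,
    )


def predict_absolute(
    summary: DockingSummary, genotype: str, params: ModelParams
) -> float:
    """Absolute capacity ``sigma * kappa * S + epsilon`` (capacity units)."""
    return predict(summary, genotype, params).P_c_absolute


def predict_relative(
    summary: DockingSummary,
    genotype: str,
    params: ModelParams,
    wild_summary: DockingSummary,
) -> float:
    """Capacity as percent of wild type.

    With epsilon = 0 this is ``100 * kappa * S(mutant) / S(wild)``; with a
    free epsilon the full ratio of offset absolute capacities is used.
    """
    pred = predict(summary, genotype, params, wild_summary=wild_summary)
    assert pred.P_c_relative is not None
    return pred.P_c_relative


@dataclass
class FitResult:
    params: ModelParams
    sse: float
    diagnostics: list[dict] = field(default_factory=list)


def _panel_beta(panel: Panel) -> float:
    return compute_beta(panel.wild_summary.S_DT, panel.wild_summary.S_DH)


def fit_parameters(
    panel: Panel,
    free_epsilon: bool = False,
    n_restarts: int = 20,
    seed: int = 0,
    gamma_bounds: tuple[float, float] = (1e-6, 100.0),
    kappa_mode: str = "table",
) -> FitResult:
    """Estimate (sigma, gamma, mu[, epsilon]) by SSE minimisation over set M.

    Bounded trust-region least squares from ``n_restarts`` seeded random
    starts (mu uniform on [0, 1], gamma log-uniform on [0.5, 50], sigma
    scaled to the data range); the best-SSE solution wins, ties broken by
    restart order, so identical panel and seed give identical constants.

    Raises
    ------
    FitError
        If set M has fewer usable members than free constants, or all
        observed capacities are identical (model unidentifiable).
    """
    members = panel.fit_set
    n_free = 4 if free_epsilon else 3
    if len(members) < n_free:
        raise FitError(
            f"fit set M has {len(members)} usable members; at least "
            f"{n_free} needed for {n_free} free constants"
        )
    v_obs = np.array([r.v_c for _, r in members], dtype=float)
    if np.allclose(v_obs, v_obs[0]):
        raise FitError("model unidentifiable: all observed capacities identical")
    fractions = np.array([s.fraction for s, _ in members])
    kappas = np.array([kappa(r.genotype, kappa_mode) for _, r in members])
    beta = _panel_beta(panel)
    v_max = float(np.max(v_obs))

    def residuals(theta: np.ndarray) -> np.ndarray:
        sigma, gamma, mu = theta[0], theta[1], theta[2]
        eps = theta[3] if free_epsilon else 0.0
        s = (1.0 / (1.0 + np.exp(-gamma * (fractions - mu)))) ** beta
        return sigma * kappas * s + eps - v_obs

    lo = [1e-9, gamma_bounds[0], 0.0]
    hi = [np.inf, gamma_bounds[1], 1.0]
    if free_epsilon:
        lo.append(-v_max)
        hi.append(v_max)

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray] | None = None
    diagnostics: list[dict] = []
    for k in range(n_restarts):
        mu0 = rng.uniform(0.0, 1.0)
        gamma0 = float(np.exp(rng.uniform(np.log(0.5), np.log(50.0))))
        sigma0 = v_max * rng.uniform(0.5, 2.0)
        x0 = [sigma0, gamma0, mu0] + ([0.0] if free_epsilon else [])
        sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf")
        sse = float(np.sum(sol.fun**2))
        diagnostics.append(
            {
                "restart": k,
                "x0": list(map(float, x0)),
                "sse": sse,
                "success": bool(sol.success),
                "nfev": int(sol.nfev),
            }
        )
        if sol.success and (best is None or sse < best[0] - 0.0):
            if best is None or sse < best[0]:
                best = (sse, sol.x.copy())
    if best is None:
        raise FitError("no optimizer restart converged")
    sse, theta = best
    params = ModelParams(
        sigma=float(theta[0]),
        gamma=float(theta[1]),
        mu=float(np.clip(theta[2], 0.0, 1.0)),
        epsilon=float(theta[3]) if free_epsilon else 0.0,
        beta=beta,
    )
    return FitResult(params=params, sse=sse, diagnostics=diagnostics)
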