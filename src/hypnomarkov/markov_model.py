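"""Panel-likelihood fitting of continuous-time Markov chains to hypnograms.

The vigilance process is modelled as a time-homogeneous continuous-time
Markov chain (CTMC) with generator matrix ``Q``: off-diagonal entries
``q_rs`` are instantaneous transition intensities (1/s) and each diagonal is
minus the row's off-diagonal sum.  Hypnograms observe the chain only at
epoch boundaries (panel data), so the likelihood of a consecutive epoch pair
``(s_t, s_{t+dt})`` is the matrix-exponential transition probability
``P(dt) = expm(Q dt)`` evaluated at the sampling interval.

Group effects enter log-linearly per transition (proportional intensities):

    q_rs(g) = q0_rs * exp(beta_rs_g),        beta_rs_reference = 0,

so ``exp(beta_rs_g)`` is the hazard ratio of group ``g`` versus the
reference, reported here as the *normalized transition rate* (NTR).  The
expected residence time of state ``r`` between two jumps — its *sojourn
time* — is the reciprocal of the total exit intensity,
``S_r(g) = 1 / sum_{s != r} q_rs(g)``.

All free parameters ``(log q0, beta)`` are unconstrained; the likelihood is
maximised by quasi-Newton ascent with an analytic gradient (Frechet
derivatives of the matrix exponential).  Confidence intervals are Wald
intervals on the log scale, with standard errors from the inverse observed
information; significance is declared purely from the CIs (an NTR is
significant versus the reference when its 95% CI excludes 1, and two
estimates differ significantly when their CIs are disjoint).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.linalg import expm, expm_frechet
from scipy.optimize import minimize
from statsmodels.tools.numdiff import approx_fprime

from .hypnogram_io import Hypnogram

__all__ = [
    "ModelSpec",
    "GeneratorMatrix",
    "FitResult",
    "SojournEstimate",
    "NTREstimate",
    "ConvergenceWarning",
    "crude_generator",
    "transition_matrix",
    "panel_log_likelihood",
    "fit_ctmc",
    "sojourn_times",
    "normalized_transition_rates",
    "compare_estimates",
]

_RATE_FLOOR = 1e-6  # 1/s, floor for unobserved transitions in crude rates
_PROB_FLOOR = 1e-300  # guard before taking logs of transition probabilities
_Z95 = 1.959963984540054  # two-sided 95% normal quantile


class ConvergenceWarning(UserWarning):
    """Emitted when the optimizer stops without meeting the gradient tolerance."""


@dataclass(frozen=True)
class ModelSpec:
    """State space, covariate structure and sampling interval of a CTMC fit.

    ``covariate_groups`` are the non-reference group labels; each gets one
    free ``beta`` per allowed transition.  ``delta`` is the panel sampling
    interval (the scoring epoch length).
    """

    states: tuple[str, ...]
    reference_group: str
    covariate_groups: tuple[str, ...] = ()
    allowed_transitions: tuple[tuple[str, str], ...] | None = None
    delta: float = 4.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "covariate_groups", tuple(self.covariate_groups))
        if len(self.states) < 2:
            raise ValueError("a CTMC needs at least two states")
        if len(set(self.states)) != len(self.states):
            raise ValueError("duplicate state labels")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.reference_group in self.covariate_groups:
            raise ValueError("reference_group must not appear in covariate_groups")
        if self.allowed_transitions is None:
            allowed = tuple(
                (r, s) for r in self.states for s in self.states if r != s
            )
        else:
            allowed = tuple((r, s) for r, s in self.allowed_transitions)
            for r, s in allowed:
                if r == s or r not in self.states or s not in self.states:
                    raise ValueError(f"invalid transition {(r, s)!r}")
        object.__setattr__(self, "allowed_transitions", allowed)

    @property
    def groups(self) -> tuple[str, ...]:
        return (self.reference_group, *self.covariate_groups)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_free_parameters(self) -> int:
        """log q0 per transition plus one beta per (transition, covariate group)."""
        return len(self.allowed_transitions) * (1 + len(self.covariate_groups))

    @property
    def descriptive_parameter_count(self) -> int:
        """Transition rates plus sojourn times describing one group's chain.

        A two-state chain needs 4 (2 rates + 2 sojourns), a full three-state
        chain 9 (6 rates + 3 sojourns).
        """
        return len(self.allowed_transitions) + self.n_states

    def state_index(self, state: str) -> int:
        return self.states.index(state)


@dataclass(frozen=True)
class GeneratorMatrix:
    """A single group's CTMC generator: intensities in 1/s, rows sum to zero."""

    states: tuple[str, ...]
    matrix: np.ndarray
    group: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        q = np.asarray(self.matrix, dtype=float)
        n = len(self.states)
        if q.shape != (n, n):
            raise ValueError(f"matrix shape {q.shape} does not match {n} states")
        off = q[~np.eye(n, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal intensities must be non-negative")
        if np.any(np.abs(q.sum(axis=1)) > 1e-12 * max(1.0, np.abs(q).max())):
            raise ValueError("generator rows must sum to zero")
        q.setflags(write=False)
        object.__setattr__(self, "matrix", q)

    @classmethod
    def from_rates(
        cls,
        states: Sequence[str],
        rates: Mapping[tuple[str, str], float],
        group: str | None = None,
    ) -> "GeneratorMatrix":
        """Build a generator from a ``(from, to) -> intensity`` mapping."""
        states = tuple(states)
        q = np.zeros((len(states), len(states)))
        for (r, s), v in rates.items():
            if r == s:
                raise ValueError("rates must be off-diagonal")
            q[states.index(r), states.index(s)] = v
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return cls(states=states, matrix=q, group=group)

    def exit_rates(self) -> np.ndarray:
        return -np.diag(self.matrix)

    def sojourns(self) -> dict[str, float]:
        """Expected residence time per state, ``1 / exit rate`` (seconds)."""
        with np.errstate(divide="ignore"):
            s = 1.0 / self.exit_rates()
        return dict(zip(self.states, s))

    def rate(self, r: str, s: str) -> float:
        return float(self.matrix[self.states.index(r), self.states.index(s)])


@dataclass(frozen=True)
class SojournEstimate:
    state: str
    group: str
    sojourn: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class NTREstimate:
    from_state: str
    to_state: str
    group: str
    ntr: float
    ci_low: float | None
    ci_high: float | None
    significant_vs_reference: bool


# ---------------------------------------------------------------------------
# counting and parameter layout


def _group_counts(
    data: Iterable[Hypnogram], spec: ModelSpec
) -> dict[str, np.ndarray]:
    """Per-group matrices of consecutive-epoch pair counts.

    Each hypnogram (or hypnogram segment) contributes only within-sequence
    pairs, so no contribution ever crosses a segment boundary.
    """
    index = {s: i for i, s in enumerate(spec.states)}
    counts = {g: np.zeros((spec.n_states, spec.n_states)) for g in spec.groups}
    for h in data:
        if h.group not in counts:
            raise ValueError(
                f"subject {h.subject_id!r} has group {h.group!r}, which is not "
                f"in the model spec groups {spec.groups}"
            )
        try:
            idx = np.array([index[s] for s in h.stages])
        except KeyError as exc:
            raise ValueError(
                f"subject {h.subject_id!r} uses stage {exc.args[0]!r}, not a "
                f"model state; collapse the hypnogram first"
            ) from None
        if len(idx) >= 2:
            np.add.at(counts[h.group], (idx[:-1], idx[1:]), 1)
    return counts


def _check_states_visited(counts: Mapping[str, np.ndarray], spec: ModelSpec) -> None:
    pooled = sum(counts.values())
    occupancy = pooled.sum(axis=0) + pooled.sum(axis=1)
    for i, state in enumerate(spec.states):
        if occupancy[i] == 0:
            raise ValueError(
                f"state {state!r} is never visited in the data; drop it from "
                f"the state space (e.g. merge into a two-state model)"
            )


def _build_q(params: np.ndarray, spec: ModelSpec, group: str) -> np.ndarray:
    """Generator of *group* from the free-parameter vector.

    Layout: ``params[:T]`` are ``log q0`` per allowed transition (in
    ``spec.allowed_transitions`` order); then one block of ``T`` betas per
    covariate group, in ``spec.covariate_groups`` order.
    """
    T = len(spec.allowed_transitions)
    logq = np.array(params[:T], dtype=float)
    if group != spec.reference_group:
        gi = spec.covariate_groups.index(group)
        logq = logq + params[T * (1 + gi) : T * (2 + gi)]
    q = np.zeros((spec.n_states, spec.n_states))
    for t, (r, s) in enumerate(spec.allowed_transitions):
        q[spec.state_index(r), spec.state_index(s)] = np.exp(logq[t])
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def _param_names(spec: ModelSpec) -> list[str]:
    names = [f"log_q0[{r}->{s}]" for r, s in spec.allowed_transitions]
    for g in spec.covariate_groups:
        names += [f"beta[{r}->{s},{g}]" for r, s in spec.allowed_transitions]
    return names


# ---------------------------------------------------------------------------
# operations


def crude_generator(data: Iterable[Hypnogram], spec: ModelSpec) -> GeneratorMatrix:
    """Pooled crude-rate generator: ``q_rs = N_rs / T_r``.

    ``N_rs`` counts consecutive-epoch ``r -> s`` pairs over all sequences and
    groups; ``T_r`` is ``delta`` times the number of pairs starting in ``r``.
    Zero-count transitions are floored at 1e-6 1/s.  Used as the optimizer
    start value.
    """
    counts = _group_counts(data, spec)
    _check_states_visited(counts, spec)
    pooled = sum(counts.values())
    holding = spec.delta * pooled.sum(axis=1)
    rates: dict[tuple[str, str], float] = {}
    for r, s in spec.allowed_transitions:
        i, j = spec.state_index(r), spec.state_index(s)
        if holding[i] > 0 and pooled[i, j] > 0:
            rates[(r, s)] = pooled[i, j] / holding[i]
        else:
            rates[(r, s)] = _RATE_FLOOR
    return GeneratorMatrix.from_rates(spec.states, rates)


def transition_matrix(gen: GeneratorMatrix, t: float) -> np.ndarray:
    """Panel transition probabilities ``P(t) = expm(Q t)``."""
    if t < 0:
        raise ValueError("t must be non-negative")
    return expm(gen.matrix * t)


def _loglik_from_counts(
    params: np.ndarray,
    counts: Mapping[str, np.ndarray],
    spec: ModelSpec,
    floor_hits: list[int] | None = None,
) -> float:
    ll = 0.0
    for g, c in counts.items():
        q = _build_q(params, spec, g)
        p = expm(q * spec.delta)
        mask = c > 0
        if floor_hits is not None:
            floor_hits.append(int(np.sum(mask & (p < _PROB_FLOOR))))
        ll += float(np.sum(c[mask] * np.log(np.maximum(p[mask], _PROB_FLOOR))))
    return ll


def _loglik_and_grad(
    params: np.ndarray, counts: Mapping[str, np.ndarray], spec: ModelSpec
) -> tuple[float, np.ndarray]:
    T = len(spec.allowed_transitions)
    ll = 0.0
    grad = np.zeros_like(params, dtype=float)
    for g, c in counts.items():
        q = _build_q(params, spec, g)
        a = q * spec.delta
        p = expm(a)
        mask = c > 0
        pc = np.maximum(p, _PROB_FLOOR)
        ll += float(np.sum(c[mask] * np.log(pc[mask])))
        w = np.where(mask, c / pc, 0.0)
        # parameter indices whose perturbation changes this group's Q
        if g == spec.reference_group:
            param_idx = list(range(T))
        else:
            gi = spec.covariate_groups.index(g)
            param_idx = list(range(T)) + list(range(T * (1 + gi), T * (2 + gi)))
        for k in param_idx:
            t = k % T
            r, s = spec.allowed_transitions[t]
            i, j = spec.state_index(r), spec.state_index(s)
            e = np.zeros_like(q)
            e[i, j] = q[i, j]
            e[i, i] = -q[i, j]
            dp = expm_frechet(a, e * spec.delta, compute_expm=False)
            grad[k] += float(np.sum(w * dp))
    return ll, grad


def panel_log_likelihood(
    params: np.ndarray, data: Iterable[Hypnogram], spec: ModelSpec
) -> float:
    """Log-likelihood of the panel-observed CTMC at the given parameters.

    Sums ``log P(delta)[s_t, s_{t+1}]`` over all consecutive epoch pairs of
    all subjects, each subject using its group's generator.  Probabilities
    are floored at 1e-300 before the log.
    """
    counts = _group_counts(list(data), spec)
    return _loglik_from_counts(np.asarray(params, dtype=float), counts, spec)


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood CTMC fit with covariate effects.

    ``params`` holds the free parameters (``log q0`` then per-group betas;
    see ``param_names``); ``cov`` is the inverse observed information.
    """

    spec: ModelSpec
    params: np.ndarray
    param_names: tuple[str, ...]
    cov: np.ndarray
    loglik: float
    converged: bool
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_parameters(self) -> int:
        return len(self.params)

    def generator(self, group: str) -> GeneratorMatrix:
        if group not in self.spec.groups:
            raise ValueError(f"unknown group {group!r}")
        return GeneratorMatrix(
            states=self.spec.states,
            matrix=_build_q(self.params, self.spec, group),
            group=group,
        )

    def beta(self, group: str, transition: tuple[str, str]) -> float:
        name = f"beta[{transition[0]}->{transition[1]},{group}]"
        return float(self.params[self.param_names.index(name)])

    def summary(self) -> dict:
        """JSON-serializable account of the fit."""
        return {
            "states": list(self.spec.states),
            "groups": list(self.spec.groups),
            "delta_s": self.spec.delta,
            "n_free_parameters": self.n_parameters,
            "descriptive_parameters_per_group": self.spec.descriptive_parameter_count,
            "log_likelihood": self.loglik,
            "converged": self.converged,
            "parameters": dict(zip(self.param_names, map(float, self.params))),
            "covariance": [[float(v) for v in row] for row in self.cov],
            "diagnostics": {
                k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                for k, v in self.diagnostics.items()
            },
        }


def fit_ctmc(
    data: Sequence[Hypnogram],
    spec: ModelSpec,
    *,
    start: np.ndarray | None = None,
    gtol: float = 1e-5,
    maxiter: int = 1000,
) -> FitResult:
    """Fit the covariate CTMC by maximum likelihood in a single run.

    Starts from the pooled crude-rate generator with all betas at zero and
    maximises the panel likelihood by BFGS on the unconstrained
    ``(log q0, beta)`` scale with an analytic gradient.  The covariance is
    the inverse observed information, obtained by centred finite differences
    of the analytic gradient at the optimum.  Non-convergence yields a
    warning and a flagged result, never an exception.
    """
    data = list(data)
    present = {h.group for h in data}
    missing = [g for g in spec.groups if g not in present]
    if missing:
        raise ValueError(f"groups {missing} have no subjects in the data")
    counts = _group_counts(data, spec)
    _check_states_visited(counts, spec)

    T = len(spec.allowed_transitions)
    if start is None:
        q0 = crude_generator(data, spec)
        start = np.concatenate(
            [
                np.log([max(q0.rate(r, s), _RATE_FLOOR) for r, s in spec.allowed_transitions]),
                np.zeros(T * len(spec.covariate_groups)),
            ]
        )
    start = np.asarray(start, dtype=float)
    if start.shape != (spec.n_free_parameters,):
        raise ValueError("start vector has the wrong length")

    def neg(params: np.ndarray) -> tuple[float, np.ndarray]:
        ll, g = _loglik_and_grad(params, counts, spec)
        return -ll, -g

    res = minimize(
        neg,
        start,
        jac=True,
        method="BFGS",
        options={"gtol": gtol, "maxiter": maxiter},
    )
    ll_opt, grad_opt = _loglik_and_grad(res.x, counts, spec)
    grad_norm = float(np.max(np.abs(grad_opt)))
    # The gradient scales with the number of observed pairs, so the absolute
    # tolerance is relaxed proportionally once rounding noise dominates.
    total_pairs = float(sum(c.sum() for c in counts.values()))
    converged = bool(grad_norm < max(gtol, 1e-8 * total_pairs))
    if not converged:
        warnings.warn(
            f"CTMC fit did not meet the gradient tolerance "
            f"(|grad|_inf = {grad_norm:.3g}); estimates returned anyway",
            ConvergenceWarning,
            stacklevel=2,
        )

    # observed information = -Hessian of loglik; differentiate the gradient
    def grad_only(p: np.ndarray) -> np.ndarray:
        return _loglik_and_grad(p, counts, spec)[1]

    hess = approx_fprime(res.x, grad_only, centered=True)
    info = -0.5 * (hess + hess.T)
    evals, evecs = np.linalg.eigh(info)
    inv = np.where(evals > 1e-12 * max(1.0, evals.max()), 1.0 / np.maximum(evals, 1e-300), 0.0)
    cov = evecs @ np.diag(inv) @ evecs.T
    cov = 0.5 * (cov + cov.T)

    floor_hits: list[int] = []
    _loglik_from_counts(res.x, counts, spec, floor_hits)
    diagnostics = {
        "grad_max_norm": grad_norm,
        "optimizer_status": res.message,
        "n_iterations": int(res.nit),
        "start_loglik": _loglik_from_counts(start, counts, spec),
        "log_floor_hits": int(sum(floor_hits)),
    }
    return FitResult(
        spec=spec,
        params=res.x,
        param_names=tuple(_param_names(spec)),
        cov=cov,
        loglik=float(ll_opt),
        converged=converged,
        diagnostics=diagnostics,
    )


def _sojourn_gradient(
    fit: FitResult, group: str, state: str
) -> tuple[float, np.ndarray]:
    """Sojourn time of (state, group) and gradient of its log w.r.t. params."""
    spec = fit.spec
    T = len(spec.allowed_transitions)
    q = _build_q(fit.params, spec, group)
    i = spec.state_index(state)
    exits = [
        (t, (r, s)) for t, (r, s) in enumerate(spec.allowed_transitions) if r == state
    ]
    rate = sum(q[i, spec.state_index(s)] for _, (_, s) in exits)
    grad = np.zeros_like(fit.params, dtype=float)
    for t, (_, s) in exits:
        dq = q[i, spec.state_index(s)] / rate  # d log S / d log q_t = -q_t/E
        grad[t] -= dq
        if group != spec.reference_group:
            gi = spec.covariate_groups.index(group)
            grad[T * (1 + gi) + t] -= dq
    return 1.0 / rate, grad


def sojourn_times(fit: FitResult) -> list[SojournEstimate]:
    """Sojourn times per state and group with delta-method 95% CIs.

    The CI is computed on the log scale, ``S * exp(+/- 1.96 SE_logS)``, so it
    is always positive and contains the point estimate.
    """
    if not fit.converged:
        warnings.warn(
            "sojourn times requested from a non-converged fit",
            ConvergenceWarning,
            stacklevel=2,
        )
    out: list[SojournEstimate] = []
    for group in fit.spec.groups:
        for state in fit.spec.states:
            if not any(r == state for r, _ in fit.spec.allowed_transitions):
                continue  # absorbing state: no finite sojourn
            s, grad = _sojourn_gradient(fit, group, state)
            se = float(np.sqrt(max(grad @ fit.cov @ grad, 0.0)))
            out.append(
                SojournEstimate(
                    state=state,
                    group=group,
                    sojourn=s,
                    ci_low=s * np.exp(-_Z95 * se),
                    ci_high=s * np.exp(_Z95 * se),
                )
            )
    return out


def normalized_transition_rates(fit: FitResult) -> list[NTREstimate]:
    """NTRs (hazard ratios vs the reference group) with 95% CIs.

    Reference-group rows are exactly 1 with no CI.  A non-reference NTR is
    flagged significant when its CI excludes 1 (the p < 0.05 rule).
    """
    if not fit.spec.covariate_groups:
        raise ValueError("the fit has no covariate groups, so no NTRs exist")
    T = len(fit.spec.allowed_transitions)
    out: list[NTREstimate] = []
    for r, s in fit.spec.allowed_transitions:
        out.append(
            NTREstimate(
                from_state=r,
                to_state=s,
                group=fit.spec.reference_group,
                ntr=1.0,
                ci_low=None,
                ci_high=None,
                significant_vs_reference=False,
            )
        )
    for gi, g in enumerate(fit.spec.covariate_groups):
        for t, (r, s) in enumerate(fit.spec.allowed_transitions):
            k = T * (1 + gi) + t
            beta = float(fit.params[k])
            se = float(np.sqrt(max(fit.cov[k, k], 0.0)))
            with np.errstate(over="ignore"):  # an unidentified beta -> inf CI
                lo, hi = np.exp(beta - _Z95 * se), np.exp(beta + _Z95 * se)
            out.append(
                NTREstimate(
                    from_state=r,
                    to_state=s,
                    group=g,
                    ntr=float(np.exp(beta)),
                    ci_low=float(lo),
                    ci_high=float(hi),
                    significant_vs_reference=bool(not (lo <= 1.0 <= hi)),
                )
            )
    return out


def compare_estimates(a, b) -> bool:
    """True iff the closed 95% CIs of two estimates are disjoint.

    This is the CI-overlap significance rule: two groups differ at p < 0.05
    when their intervals do not overlap.  Exact endpoint contact counts as
    overlap (conservative).
    """
    for e in (a, b):
        if getattr(e, "ci_low", None) is None or getattr(e, "ci_high", None) is None:
            raise ValueError("both estimates need confidence intervals")
    return bool(a.ci_high < b.ci_low or b.ci_high < a.ci_low)
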