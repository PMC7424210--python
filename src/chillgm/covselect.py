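"""Covariance selection: constrained MLE and NFI-guided backward elimination.

Dempster's covariance selection estimates a population correlation matrix
under the constraint that a chosen set of partial correlations is exactly
zero.  The fitted matrix PI_hat is the unique positive-definite matrix that

* agrees with the sample correlation matrix R on the diagonal and on every
  unconstrained ("free") entry, and
* has exact zeros in its inverse at every constrained entry.

It is computed here by iterative proportional scaling (IPS): cycling over
the constrained pairs, each visit adjusts the single entry sigma_ij so that
the corresponding precision entry becomes zero while everything else is
held fixed.  With K the current inverse, the exact single-pair update is

    sigma_ij  <-  sigma_ij + k_ij / (k_ii k_jj - k_ij^2),

which zeroes k_ij in closed form; cycling these updates converges to the
constrained MLE because each step is a coordinate ascent of the Gaussian
log-likelihood.

Model fit is summarized by the deviance against the saturated (full) model,

    Dev(RM) = n * log( det(PI_hat) / det(R) ),

and by the normed fit index

    NFI = 1 - Dev(RM) / Dev(NM),

where the null model NM constrains every pair (PI_hat = I, Dev(NM) =
-n log det R).  NFI is 1 when the reduced model fits as well as the full
model and 0 when it fits as poorly as total independence.

Backward elimination removes edges whose fitted partial correlation falls
below a threshold (0.1, then 0.2), smallest first, refitting after every
removal, and stops a threshold pass as soon as NFI would drop below 0.9.
The scan is organised by the three-tier layer structure (cause ->
intermediate -> effect); see :func:`backward_eliminate`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .correlation import correlation_matrix, partial_correlation
from .datasets import LayeredDataset, VariableSpec

__all__ = [
    "GraphModel",
    "FittedModel",
    "SelectionStep",
    "SelectionTrace",
    "ConvergenceError",
    "canonical_pair",
    "all_pairs",
    "fit_constrained_mle",
    "deviance",
    "nfi",
    "backward_eliminate",
    "LAYER_POLICIES",
]

LAYER_POLICIES = ("layered", "unrestricted", "batch")

DEFAULT_TOLERANCE = 1e-10
DEFAULT_MAX_ITERATIONS = 10_000


class ConvergenceError(RuntimeError):
    """IPS failed to reach the requested tolerance; carries the final residual."""

    def __init__(self, residual: float, iterations: int):
        super().__init__(
            f"iterative proportional scaling did not converge in {iterations} sweeps "
            f"(final max update {residual:.3e})"
        )
        self.residual = residual
        self.iterations = iterations


def canonical_pair(a, b) -> tuple:
    """Unordered pair in canonical (sorted) order."""
    if a == b:
        raise ValueError(f"a pair must join two distinct variables, got ({a!r}, {b!r})")
    return (a, b) if a < b else (b, a)


def all_pairs(names: Sequence) -> list:
    return [canonical_pair(names[i], names[j])
            for i in range(len(names)) for j in range(i + 1, len(names))]


@dataclass(frozen=True)
class GraphModel:
    """An undirected dependence structure: which pairs are constrained to zero.

    ``zero_set`` holds the pairs whose partial correlation is forced to
    zero; ``edges`` is its complement among all p(p-1)/2 pairs.  The full
    model FM has an empty zero set, the null model NM constrains every pair.
    """

    variables: tuple
    zero_set: frozenset

    def __post_init__(self):
        names = self.variable_names
        valid = set(all_pairs(names))
        bad = set(self.zero_set) - valid
        if bad:
            raise ValueError(f"zero_set contains unknown or non-canonical pairs: {sorted(bad)}")

    @classmethod
    def full(cls, variables) -> "GraphModel":
        return cls(tuple(variables), frozenset())

    @classmethod
    def null(cls, variables) -> "GraphModel":
        variables = tuple(variables)
        names = [v.name if isinstance(v, VariableSpec) else v for v in variables]
        return cls(variables, frozenset(all_pairs(names)))

    @property
    def variable_names(self) -> list:
        return [v.name if isinstance(v, VariableSpec) else v for v in self.variables]

    @property
    def edges(self) -> frozenset:
        return frozenset(all_pairs(self.variable_names)) - self.zero_set


@dataclass
class FittedModel:
    """Constrained MLE PI_hat with its deviance and NFI against the sample R."""

    pi_hat: pd.DataFrame
    deviance: float
    nfi: float
    zero_set: frozenset
    converged: bool = True
    sweeps: int = 0

    @property
    def variable_names(self) -> list:
        return list(self.pi_hat.columns)

    def partial_matrix(self) -> pd.DataFrame:
        """Partial correlations implied by the fitted matrix (NaN diagonal)."""
        _, partial = partial_correlation(self.pi_hat)
        return partial


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, pd.DataFrame):
        return matrix
    matrix = np.asarray(matrix, dtype=float)
    names = [f"X{i + 1}" for i in range(matrix.shape[0])]
    return pd.DataFrame(matrix, index=names, columns=names)


def _logdet(matrix: np.ndarray) -> float:
    sign, value = np.linalg.slogdet(matrix)
    if sign <= 0:
        raise ValueError("matrix must be positive definite")
    return value


def deviance(pi_hat, sample_correlation, n: int) -> float:
    """Dev = n log(det PI_hat / det R); zero for the full model, else positive."""
    pi = np.asarray(pi_hat, dtype=float)
    R = np.asarray(sample_correlation, dtype=float)
    return float(n * (_logdet(pi) - _logdet(R)))


def nfi(deviance_rm: float, deviance_nm: float) -> float:
    """Normed fit index 1 - Dev(RM)/Dev(NM)."""
    if deviance_nm <= 0.0:
        raise ValueError(
            "null-model deviance must be positive; a diagonal sample correlation "
            "matrix leaves the NFI undefined"
        )
    if deviance_rm < 0.0:
        raise ValueError("reduced-model deviance cannot be negative")
    return 1.0 - deviance_rm / deviance_nm


def fit_constrained_mle(
    sample_correlation,
    zero_set: Iterable,
    n: int,
    tolerance: float = DEFAULT_TOLERANCE,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
) -> FittedModel:
    """Dempster covariance selection via iterative proportional scaling.

    Parameters
    ----------
    sample_correlation
        Symmetric positive-definite sample correlation matrix (DataFrame
        with variable labels, or a plain array labelled X1..Xp).
    zero_set
        Unordered variable pairs whose partial correlation is constrained
        to zero.
    n
        Sample count, entering the deviance as n log(det PI_hat / det R).
    tolerance
        Convergence criterion: maximum absolute entry update in one sweep.
    max_iterations
        Sweep budget; exceeding it raises :class:`ConvergenceError`.
    """
    frame = _as_frame(sample_correlation)
    names = list(frame.columns)
    R = frame.to_numpy(dtype=float)
    if not np.allclose(R, R.T, atol=1e-12):
        raise ValueError("sample correlation must be symmetric")
    try:
        np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        raise ValueError("sample correlation must be positive definite") from None

    index = {name: i for i, name in enumerate(names)}
    pairs = sorted(canonical_pair(*pair) for pair in zero_set)
    idx_pairs = []
    for a, b in pairs:
        if a not in index or b not in index:
            raise ValueError(f"zero_set pair ({a!r}, {b!r}) references unknown variables")
        idx_pairs.append((index[a], index[b]))

    dev_nm = -n * _logdet(R)
    sigma = R.copy()
    sweeps = 0
    if idx_pairs:
        for sweeps in range(1, max_iterations + 1):
            max_update = 0.0
            for i, j in idx_pairs:
                K = np.linalg.inv(sigma)
                delta = K[i, j] / (K[i, i] * K[j, j] - K[i, j] ** 2)
                sigma[i, j] += delta
                sigma[j, i] = sigma[i, j]
                max_update = max(max_update, abs(delta))
            if max_update < tolerance:
                break
        else:
            raise ConvergenceError(max_update, max_iterations)

    dev = max(deviance(sigma, R, n), 0.0)
    fit_nfi = 1.0 if dev_nm == 0.0 and dev == 0.0 else nfi(dev, dev_nm)
    return FittedModel(
        pi_hat=pd.DataFrame(sigma, index=names, columns=names),
        deviance=dev,
        nfi=fit_nfi,
        zero_set=frozenset(pairs),
        converged=True,
        sweeps=sweeps,
    )


@dataclass(frozen=True)
class SelectionStep:
    """One elimination attempt in the backward-selection trace."""

    pair: tuple
    partial_r: float      # fitted partial correlation at the moment of removal
    threshold: float      # |partial r| threshold in force
    deviance: float       # deviance of the model with the pair constrained
    nfi: float            # NFI of the model with the pair constrained
    decision: str         # "removed" or "restored"


@dataclass
class SelectionTrace:
    """Ordered elimination log plus the final model and its fit."""

    steps: list
    final_model: GraphModel
    final_fit: FittedModel
    pcor_thresholds: tuple
    nfi_threshold: float
    layer_policy: str

    @property
    def removed_pairs(self) -> list:
        return [s.pair for s in self.steps if s.decision == "removed"]

    def to_dict(self) -> dict:
        return {
            "config": {
                "pcor_thresholds": list(self.pcor_thresholds),
                "nfi_threshold": self.nfi_threshold,
                "layer_policy": self.layer_policy,
            },
            "steps": [
                {
                    "pair": list(s.pair),
                    "partial_r": s.partial_r,
                    "threshold": s.threshold,
                    "deviance": s.deviance,
                    "nfi": s.nfi,
                    "decision": s.decision,
                }
                for s in self.steps
            ],
            "final": {
                "zero_set": sorted(map(list, self.final_model.zero_set)),
                "edges": sorted(map(list, self.final_model.edges)),
                "deviance": self.final_fit.deviance,
                "nfi": self.final_fit.nfi,
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _layer_stages(variables, policy: str) -> list:
    """Pair-eligibility stages scanned within each threshold pass.

    ``layered``: three stages; stage k holds the pairs whose deeper endpoint
    sits in layer k, so elimination sweeps the structure from the cause
    layer down to the effect layer.  ``unrestricted`` and ``batch``: a
    single stage containing every pair.
    """
    names = [v.name for v in variables]
    if policy in ("unrestricted", "batch"):
        return [set(all_pairs(names))]
    rank = {v.name: v.rank for v in variables}
    if any(rank[name] is None for name in names):
        raise ValueError(
            "the layered policy needs a layer label on every variable; "
            "use layer_policy='unrestricted' for unlayered data"
        )
    stages = []
    for depth in (1, 2, 3):
        stages.append({
            pair for pair in all_pairs(names)
            if max(rank[pair[0]], rank[pair[1]]) == depth
        })
    return stages


def backward_eliminate(
    dataset: LayeredDataset,
    pcor_thresholds: Sequence[float] = (0.1, 0.2),
    nfi_threshold: float = 0.9,
    layer_policy: str = "layered",
    tolerance: float = DEFAULT_TOLERANCE,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
) -> SelectionTrace:
    """Threshold-escalating backward edge elimination under an NFI guard.

    For each threshold in ``pcor_thresholds`` (default 0.1 then 0.2), and
    within it for each eligibility stage of the layer policy, the procedure
    repeatedly fits the current model, recomputes the FITTED partial
    correlations, and removes the still-connected eligible pair with the
    smallest |partial r| below the threshold (ties broken alphabetically).
    A removal that would push NFI below ``nfi_threshold`` is undone and ends
    the current threshold pass, so the returned model always satisfies
    NFI >= ``nfi_threshold``.

    ``layer_policy``:

    * ``"layered"`` (default) - scan pairs by the layer of their deeper
      endpoint: cause, then intermediate, then effect.
    * ``"unrestricted"`` - all pairs eligible at once.
    * ``"batch"`` - rank candidates once per threshold from the current fit
      and remove them in that fixed ascending order without re-ranking.
    """
    if layer_policy not in LAYER_POLICIES:
        raise ValueError(f"unknown layer policy {layer_policy!r}; choose from {LAYER_POLICIES}")
    thresholds = tuple(pcor_thresholds)
    if any(not (0.0 < t < 1.0) for t in thresholds):
        raise ValueError("partial-correlation thresholds must lie in (0, 1)")
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be non-decreasing")
    if not (0.0 < nfi_threshold <= 1.0):
        raise ValueError("NFI threshold must lie in (0, 1]")

    R = correlation_matrix(dataset)
    n = dataset.n
    dev_nm = -n * _logdet(R.to_numpy())
    if dev_nm <= 0.0:
        raise ValueError("null-model deviance is zero; NFI-guided selection undefined")

    def fit(zero):
        return fit_constrained_mle(R, zero, n, tolerance=tolerance, max_iterations=max_iterations)

    zero: set = set()
    steps: list = []

    for threshold in thresholds:
        stages = _layer_stages(dataset.variables, layer_policy)
        pass_aborted = False
        for stage_pairs in stages:
            if pass_aborted:
                break
            if layer_policy == "batch":
                pass_aborted = _run_batch_stage(
                    fit, stage_pairs, zero, threshold, nfi_threshold, steps)
            else:
                pass_aborted = _run_stepwise_stage(
                    fit, stage_pairs, zero, threshold, nfi_threshold, steps)

    final_fit = fit(zero)
    model = GraphModel(tuple(dataset.variables), frozenset(zero))
    return SelectionTrace(
        steps=steps,
        final_model=model,
        final_fit=final_fit,
        pcor_thresholds=thresholds,
        nfi_threshold=nfi_threshold,
        layer_policy=layer_policy,
    )


def _attempt_removal(fit, zero, pair, pcor_value, threshold, nfi_threshold, steps) -> bool:
    """Constrain one pair; undo if NFI falls below the guard.  True if kept."""
    zero.add(pair)
    trial = fit(zero)
    if trial.nfi >= nfi_threshold:
        steps.append(SelectionStep(pair, pcor_value, threshold,
                                   trial.deviance, trial.nfi, "removed"))
        return True
    steps.append(SelectionStep(pair, pcor_value, threshold,
                               trial.deviance, trial.nfi, "restored"))
    zero.discard(pair)
    return False


def _run_stepwise_stage(fit, stage_pairs, zero, threshold, nfi_threshold, steps) -> bool:
    """Remove-smallest-and-refit loop.  Returns True if the pass must abort."""
    while True:
        current = fit(zero)
        partial = current.partial_matrix()
        candidates = []
        for pair in stage_pairs:
            if pair in zero:
                continue
            value = float(partial.loc[pair[0], pair[1]])
            if abs(value) < threshold:
                candidates.append((abs(value), pair, value))
        if not candidates:
            return False
        candidates.sort(key=lambda c: (c[0], c[1]))
        _, pair, value = candidates[0]
        if not _attempt_removal(fit, zero, pair, value, threshold, nfi_threshold, steps):
            return True


def _run_batch_stage(fit, stage_pairs, zero, threshold, nfi_threshold, steps) -> bool:
    """Rank once from the current fit, then remove in that fixed order."""
    current = fit(zero)
    partial = current.partial_matrix()
    candidates = []
    for pair in stage_pairs:
        if pair in zero:
            continue
        value = float(partial.loc[pair[0], pair[1]])
        if abs(value) < threshold:
            candidates.append((abs(value), pair, value))
    candidates.sort(key=lambda c: (c[0], c[1]))
    for _, pair, value in candidates:
        if not _attempt_removal(fit, zero, pair, value, threshold, nfi_threshold, steps):
            return True
    return False
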