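"""Synthetic binary-classification benchmarks with known informative features.

Observations are Gaussian feature vectors; the class label is Bernoulli with
success probability given by a logistic model ``rho_i = expit(beta0 + x_i' beta)``.
Features carrying a nonzero coefficient are "informative"; the rest are
null-effect noise columns.  Three families of study conditions are bundled
as presets:

* ``s1`` — classical regime: n = 2000, three informative features with
  effects (3, -2, 0.5) and 22 independent noise features, balanced classes.
* ``s2_*`` — high-dimensional regime: n = 100, three informative features
  and 197 noise features, crossing class balance (intercept 0/0.5 vs
  -2.65/-2.75) with strong vs weak separation (Table-style effect vectors).
* ``s3_*`` — multicollinearity regime: n = 2000, ten groups of ten features
  with block-diagonal correlation (constant ``alpha_max`` or exponentially
  decaying ``alpha_ij = alpha_max * exp(-w (|i-j| - 1))``), the first
  feature of groups 1-5 and 10 informative with effect 1.5, group 10 left
  uncorrelated (identity block).

All features have unit variance.  In the decaying design ``w`` is set to
``log(alpha_max / c) / (s_g - 2)`` so that the correlation between the first
and last feature of a group equals the floor ``c`` exactly.

Every generated condition produces an independent train/validation pair of
the same size, and generation is reproducible from an integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit

from .datasets import LabeledDataset

__all__ = ["BlockStructure", "ScenarioSpec", "GeneratedData",
           "build_block_sigma", "generate_dataset", "scenario_preset",
           "PRESET_NAMES"]


@dataclass(frozen=True)
class BlockStructure:
    """Block-diagonal correlation layout for the feature covariance."""

    n_groups: int
    group_size: int
    correlation_kind: str           # "constant" | "decaying"
    alpha_max: float
    c: float | None = None          # min within-group correlation (decaying)
    independent_groups: tuple[int, ...] = ()   # 0-based group indices left at identity

    def __post_init__(self):
        if self.correlation_kind not in ("constant", "decaying"):
            raise ValueError(f"unknown correlation kind {self.correlation_kind!r}")
        if not 0 < self.alpha_max < 1:
            raise ValueError("alpha_max must lie in (0, 1)")
        if self.correlation_kind == "decaying":
            if self.c is None or not 0 < self.c < self.alpha_max:
                raise ValueError("decaying blocks need 0 < c < alpha_max")

    @property
    def w(self) -> float:
        """Decay rate making the first-to-last in-group correlation equal c."""
        if self.correlation_kind != "decaying":
            raise ValueError("w is defined only for decaying correlation")
        return float(np.log(self.alpha_max / self.c) / (self.group_size - 2))


@dataclass(frozen=True)
class ScenarioSpec:
    """Full parameterization of one simulated study condition.

    ``beta`` has one entry per feature (zeros on the null features);
    ``beta0`` is the intercept.  Feature indices are 0-based.
    """

    name: str
    n: int
    beta0: float
    beta: tuple[float, ...]
    block: BlockStructure | None = None

    def __post_init__(self):
        if self.n < 4:
            raise ValueError("n too small to split into classes")
        if self.block is not None:
            if self.block.n_groups * self.block.group_size != len(self.beta):
                raise ValueError("block layout does not cover all features")

    @property
    def p_total(self) -> int:
        return len(self.beta)

    @property
    def informative_idx(self) -> tuple[int, ...]:
        return tuple(j for j, b in enumerate(self.beta) if b != 0.0)

    @property
    def full_beta(self) -> np.ndarray:
        """Intercept-prepended coefficient vector."""
        return np.concatenate(([self.beta0], self.beta))


@dataclass(frozen=True)
class GeneratedData:
    train: LabeledDataset
    valid: LabeledDataset
    truth: tuple[int, ...]          # informative feature indices (0-based)


def build_block_sigma(spec: ScenarioSpec) -> np.ndarray:
    """Block-diagonal feature correlation matrix for a blocked scenario.

    Constant blocks have ``alpha_max`` off the diagonal; decaying blocks have
    ``alpha_ij = alpha_max * exp(-w (|i - j| - 1))``; independent groups get
    the identity.  The result is validated to be positive definite.
    """
    if spec.block is None:
        raise ValueError("spec has no block structure")
    b = spec.block
    p = spec.p_total
    sigma = np.eye(p)
    for g in range(b.n_groups):
        if g in b.independent_groups:
            continue
        sl = slice(g * b.group_size, (g + 1) * b.group_size)
        if b.correlation_kind == "constant":
            blk = np.full((b.group_size, b.group_size), b.alpha_max)
        else:
            dist = np.abs(np.subtract.outer(np.arange(b.group_size),
                                            np.arange(b.group_size))).astype(float)
            blk = b.alpha_max * np.exp(-b.w * (dist - 1.0))
        np.fill_diagonal(blk, 1.0)
        try:
            np.linalg.cholesky(blk)
        except np.linalg.LinAlgError:
            raise ValueError(f"correlation block for group {g + 1} is not positive definite")
        sigma[sl, sl] = blk
    return sigma


def generate_dataset(spec: ScenarioSpec, seed: int) -> GeneratedData:
    """Draw an independent train/validation pair from one study condition.

    A draw that lands all observations in one class (possible under strong
    imbalance at small n) is rejected and redrawn, up to 100 times.
    """
    rng = np.random.default_rng(seed)
    chol = None
    if spec.block is not None:
        chol = np.linalg.cholesky(build_block_sigma(spec))
    beta = np.asarray(spec.beta)

    def draw() -> LabeledDataset:
        for attempt in range(100):
            X = rng.standard_normal((spec.n, spec.p_total))
            if chol is not None:
                X = X @ chol.T
            rho = expit(spec.beta0 + X @ beta)
            y = (rng.random(spec.n) < rho).astype(int)
            if 2 <= y.sum() <= spec.n - 2:
                # labels 1 (control, Y=0) and 2 (case, Y=1)
                return LabeledDataset(X, y + 1, class_names=(0, 1))
            warnings.warn(f"degenerate single-class draw for {spec.name}; redrawing")
        raise RuntimeError(f"could not draw a two-class sample for {spec.name} in 100 attempts")

    train = draw()
    valid = draw()
    return GeneratedData(train=train, valid=valid, truth=spec.informative_idx)


def _logistic_spec(name: str, n: int, beta0: float, effects: Sequence[float],
                   p_prime: int) -> ScenarioSpec:
    return ScenarioSpec(name=name, n=n, beta0=beta0,
                        beta=tuple(effects) + (0.0,) * p_prime)


def _s3_spec(name: str, kind: str, alpha_max: float, c: float | None) -> ScenarioSpec:
    beta = [0.0] * 100
    for j in (0, 10, 20, 30, 40, 90):      # first feature of groups 1-5 and 10
        beta[j] = 1.5
    block = BlockStructure(n_groups=10, group_size=10, correlation_kind=kind,
                           alpha_max=alpha_max, c=c, independent_groups=(9,))
    return ScenarioSpec(name=name, n=2000, beta0=0.0, beta=tuple(beta), block=block)


_PRESETS = {
    "s1": lambda: _logistic_spec("s1", 2000, 0.0, (3.0, -2.0, 0.5), 22),
    "s2_unbal_strong": lambda: _logistic_spec("s2_unbal_strong", 100, -2.65, (3.6, -2.2, -1.0), 197),
    "s2_bal_strong": lambda: _logistic_spec("s2_bal_strong", 100, 0.0, (3.6, -4.0, -1.0), 197),
    "s2_unbal_weak": lambda: _logistic_spec("s2_unbal_weak", 100, -2.75, (0.6, -2.5, -1.0), 197),
    "s2_bal_weak": lambda: _logistic_spec("s2_bal_weak", 100, 0.5, (0.6, -2.5, -1.0), 197),
    "s3_const_09": lambda: _s3_spec("s3_const_09", "constant", 0.9, None),
    "s3_const_06": lambda: _s3_spec("s3_const_06", "constant", 0.6, None),
    "s3_const_03": lambda: _s3_spec("s3_const_03", "constant", 0.3, None),
    "s3_decay_09": lambda: _s3_spec("s3_decay_09", "decaying", 0.9, 0.35),
    "s3_decay_06": lambda: _s3_spec("s3_decay_06", "decaying", 0.6, 0.25),
    "s3_decay_03": lambda: _s3_spec("s3_decay_03", "decaying", 0.3, 0.1),
}

PRESET_NAMES = tuple(_PRESETS)


def scenario_preset(name: str) -> ScenarioSpec:
    """Published parameterization of a named study condition."""
    try:
        return _PRESETS[name]()
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; valid names: {', '.join(PRESET_NAMES)}")
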