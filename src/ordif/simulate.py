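"""Synthetic graded-response data with known, injectable DIF.

Responses are drawn from the graded response model: for person with latent
trait ``theta`` and item with discrimination ``a`` and ascending thresholds
``b_1 < ... < b_{m-1}``,

    P(Y >= k+1 | theta) = expit(a * (theta - b_k)),   k = 1..m-1,

so category probabilities are differences of adjacent cumulative curves.
Two kinds of group-specific distortion can be injected per item:

* **uniform DIF** — all thresholds of the focal group shift by ``+delta``,
  lowering (for ``delta > 0``) the focal group's expected score at every
  trait level;
* **nonuniform DIF** — the focal group's discrimination is multiplied by
  ``rho``, so the two groups' item response curves cross.

A group difference in the trait distribution itself ("impact") is a
separate, legitimate group difference and is controlled independently of
DIF through the per-group trait means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "generate",
    "marginal_category_probs",
    "default_item_bank",
    "default_fixture_spec",
]


@dataclass
class SyntheticSpec:
    """Generating conditions for a two-group graded-response dataset.

    ``dif_spec`` lists ``(item_index, kind, magnitude)`` triples with
    0-based item indices; ``kind`` is ``"uniform"`` (threshold shift
    ``delta``) or ``"nonuniform"`` (discrimination ratio ``rho > 0``).
    ``impact`` is the pair of group trait means (reference, focal) in units
    of the common trait SD.
    """

    n_per_group: tuple[int, int]
    discrimination: np.ndarray  # (J,)
    thresholds: np.ndarray  # (J, m-1), strictly ascending per row
    impact: tuple[float, float] = (0.0, 0.0)
    trait_sd: float = 1.0
    dif_spec: list[tuple[int, str, float]] = field(default_factory=list)
    group_labels: tuple[str, str] = ("ref", "focal")

    @property
    def n_items(self) -> int:
        return len(self.discrimination)

    @property
    def n_categories(self) -> int:
        return self.thresholds.shape[1] + 1

    def validate(self) -> None:
        a = np.asarray(self.discrimination, dtype=float)
        b = np.asarray(self.thresholds, dtype=float)
        if a.ndim != 1 or b.ndim != 2 or b.shape[0] != a.shape[0]:
            raise ValueError("discrimination and thresholds shapes disagree")
        if np.any(a <= 0):
            raise ValueError("discriminations must be positive")
        if np.any(np.diff(b, axis=1) <= 0):
            raise ValueError("thresholds must be strictly ascending per item")
        if self.trait_sd < 0:
            raise ValueError("trait_sd must be non-negative")
        for j, kind, mag in self.dif_spec:
            if not 0 <= j < self.n_items:
                raise ValueError(f"dif_spec item index {j} out of range")
            if kind not in ("uniform", "nonuniform"):
                raise ValueError(f"unknown DIF kind {kind!r}")
            if kind == "nonuniform" and mag <= 0:
                raise ValueError("nonuniform magnitude rho must be positive")

    def group_params(self) -> tuple[dict, dict]:
        """Per-group (discrimination, thresholds) after DIF injection."""
        self.validate()
        a = np.asarray(self.discrimination, dtype=float)
        b = np.asarray(self.thresholds, dtype=float)
        ref = {"a": a.copy(), "b": b.copy()}
        foc = {"a": a.copy(), "b": b.copy()}
        for j, kind, mag in self.dif_spec:
            if kind == "uniform":
                foc["b"][j] = foc["b"][j] + mag
            else:
                foc["a"][j] = foc["a"][j] * mag
        if np.any(np.diff(foc["b"], axis=1) <= 0):
            raise ValueError("thresholds non-ascending after DIF injection")
        return ref, foc


@dataclass
class SyntheticTruth:
    """Generating parameters and true DIF labels for recovery tests."""

    theta: np.ndarray
    group: np.ndarray  # 0 = reference, 1 = focal
    params_by_group: dict  # label -> {"a": (J,), "b": (J, m-1)}
    dif_labels: list[str]  # per item: "none" | "uniform" | "nonuniform"


def _category_probs(theta, a, b):
    """Graded-model category probabilities, (n, m) for one item."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    cum = expit(a * (theta[:, None] - b[None, :]))  # P(Y >= k+1)
    n = theta.shape[0]
    cp = np.hstack([np.ones((n, 1)), cum])
    return np.hstack([cp[:, :-1] - cp[:, 1:], cp[:, -1:]])


def expected_item_score(theta, a, b):
    """E[Y | theta] on the 1..m scale for one item."""
    p = _category_probs(theta, a, b)
    return p @ np.arange(1, p.shape[1] + 1)


def generate(
    spec: SyntheticSpec, seed: int | np.random.Generator | None = None
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw a two-group response table from the graded model.

    Returns a wide data frame (one row per person: item columns coded
    ``1..m`` plus a ``group`` column) and the :class:`SyntheticTruth`
    holding the generating traits, per-group parameters and DIF labels.
    Identical ``spec`` and ``seed`` give identical output.
    """
    spec.validate()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n0, n1 = spec.n_per_group
    mu0, mu1 = spec.impact
    theta = np.concatenate(
        [
            rng.normal(mu0, spec.trait_sd, n0),
            rng.normal(mu1, spec.trait_sd, n1),
        ]
    )
    group = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    ref, foc = spec.group_params()
    J = spec.n_items
    n = n0 + n1
    Y = np.empty((n, J), dtype=int)
    u = rng.random((n, J))
    for j in range(J):
        probs = np.where(
            group[:, None] == 0,
            _category_probs(theta, ref["a"][j], ref["b"][j]),
            _category_probs(theta, foc["a"][j], foc["b"][j]),
        )
        Y[:, j] = (u[:, j : j + 1] < np.cumsum(probs, axis=1)).argmax(axis=1) + 1

    labels = ["none"] * J
    for j, kind, mag in spec.dif_spec:
        noop = (kind == "uniform" and mag == 0.0) or (kind == "nonuniform" and mag == 1.0)
        if not noop:
            labels[j] = kind
    item_ids = [f"item{j + 1:02d}" for j in range(J)]
    df = pd.DataFrame(Y, columns=item_ids)
    df["group"] = np.asarray(spec.group_labels)[group]
    truth = SyntheticTruth(
        theta=theta,
        group=group,
        params_by_group={spec.group_labels[0]: ref, spec.group_labels[1]: foc},
        dif_labels=labels,
    )
    return df, truth


def marginal_category_probs(
    a: float,
    b: np.ndarray,
    trait_mean: float = 0.0,
    trait_sd: float = 1.0,
    n_quadrature: int = 61,
) -> np.ndarray:
    """Category probabilities marginalised over a normal trait distribution.

    Computed by fixed Gauss-Hermite-style quadrature on an equally spaced
    grid over +/- 6 SD (point mass at ``trait_mean`` when ``trait_sd`` is
    zero).  Used as the independent oracle for the generator's empirical
    category frequencies.
    """
    b = np.asarray(b, dtype=float)
    if a <= 0 or np.any(np.diff(b) <= 0):
        raise ValueError("invalid item parameters")
    if trait_sd == 0:
        return _category_probs(np.array([trait_mean]), a, b)[0]
    grid = np.linspace(trait_mean - 6 * trait_sd, trait_mean + 6 * trait_sd, n_quadrature)
    w = np.exp(-0.5 * ((grid - trait_mean) / trait_sd) ** 2)
    w /= w.sum()
    p = _category_probs(grid, a, b)
    return w @ p


def default_item_bank(
    n_items: int, n_categories: int = 5, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """A reproducible bank of realistic graded-item parameters.

    Discriminations are spaced in [0.9, 2.2]; thresholds per item are an
    ascending ladder centred near zero with unit-ish spread, the usual
    desk-simulation regime for 5-point Likert items.
    """
    rng = np.random.default_rng(seed if seed is not None else 20240501)
    a = np.linspace(0.9, 2.2, n_items)
    rng.shuffle(a)
    centres = rng.uniform(-0.8, 0.8, n_items)
    base = np.linspace(-1.5, 1.5, n_categories - 1)
    jitter = rng.uniform(-0.15, 0.15, (n_items, n_categories - 1))
    b = centres[:, None] + base[None, :] + jitter
    b.sort(axis=1)
    return a, b


def default_fixture_spec(
    n_per_group: int = 500,
    impact: float = 0.0,
    uniform_delta: float = 0.5,
    nonuniform_rho: float = 2.0,
) -> SyntheticSpec:
    """The desk-scale test scenario: J=20, m=5, two uniform-DIF items
    (indices 2, 7) and two nonuniform-DIF items (indices 4, 12)."""
    a, b = default_item_bank(20)
    return SyntheticSpec(
        n_per_group=(n_per_group, n_per_group),
        discrimination=a,
        thresholds=b,
        impact=(0.0, impact),
        dif_spec=[
            (2, "uniform", uniform_delta),
            (7, "uniform", uniform_delta),
            (4, "nonuniform", nonuniform_rho),
            (12, "nonuniform", nonuniform_rho),
        ],
    )
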