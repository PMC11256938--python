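"""Splat-style synthetic scRNA-seq count generator.

The generative pathway mirrors the parts of the splat model the evaluation
needs: lognormal gene base means, per-group lognormal differential-
expression factors on a random gene subset, optional per-batch
multiplicative factors, lognormal per-cell library sizes, Gamma-Poisson
(negative binomial) sampling of true counts, and an experiment-wide
logistic dropout that zeroes an entry with probability
``sigmoid(shape * (log mean - mid))`` - with the default ``shape = -1``
a larger ``dropout_mid`` means more dropout.

The ``dropout_mid`` axis is calibrated so the sweep -1.5 -> 0.5 yields
empirical capture-loss rates of roughly 5% -> 25% (the fraction of
originally non-zero entries zeroed by dropout); the affine calibration
constants are frozen in :data:`DROPOUT_MID_OFFSET` / :data:`DROPOUT_MID_SLOPE`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit

from .data import CountDataset

# frozen generator constants (see docs/methods.md)
# base means log-moment-matched to the splat Gamma(shape 0.6, rate 0.3)
BASE_MEAN_LOGLOC = -0.56  # lognormal location of gene base means
BASE_MEAN_LOGSCALE = 1.73  # lognormal scale of gene base means
DE_PROB = 0.1  # fraction of genes differentially expressed per group
BATCH_FAC_LOC = 0.1  # log-scale location of batch factors
BATCH_FAC_SCALE = 0.1  # log-scale scale of batch factors
LIB_LOGLOC = 11.0  # lognormal location of library sizes (splat default)
LIB_LOGSCALE = 0.2
NB_SHAPE = 100.0  # Gamma shape of the Gamma-Poisson mixing (BCV ~ 0.1)

# the nominal dropout_mid axis indexes expected capture loss linearly:
# mid = -1.5 -> 5%, mid = 0.5 -> 25% (the design's stated range); the
# logistic midpoint that realizes the target rate is solved per dataset
DROPOUT_RATE_AT_LOW = 0.05
DROPOUT_RATE_SLOPE = 0.10  # per unit of dropout_mid
DROPOUT_MID_LOW = -1.5


@dataclass
class SimulationScenario:
    """Full parameterization of one synthetic experiment."""

    n_groups: int
    n_cells: int = 2500
    n_genes: int = 2500
    group_ratio: float = 1.0  # geometric group-size ratio; 1.0 = balanced
    de_fac_scale: float = 0.2
    de_fac_loc: float = 0.5
    dropout_mid: float = -0.5
    dropout_shape: float = -1.0
    n_batches: int = 1
    batch_ratio: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.group_ratio <= 1.0):
            raise ValueError("group_ratio must lie in (0, 1]")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if self.n_groups > self.n_cells:
            raise ValueError("more groups than cells")

    def to_dict(self) -> dict:
        return asdict(self)


def geometric_sizes(total: int, k: int, ratio: float) -> np.ndarray:
    """Integer sizes following a geometric sequence with the given ratio,
    summing exactly to ``total`` (largest-remainder rounding)."""
    raw = np.array([ratio**i for i in range(k)], dtype=np.float64)
    raw = raw / raw.sum() * total
    sizes = np.floor(raw).astype(np.int64)
    rem = total - sizes.sum()
    order = np.argsort(-(raw - sizes))
    sizes[order[:rem]] += 1
    if np.any(sizes < 1):
        raise ValueError("a group received fewer than 1 cell; lower k or raise ratio")
    return sizes


@dataclass
class SimulationTruth:
    """Side products of one simulation run for calibration and testing."""

    mean_matrix: np.ndarray  # per-cell-per-gene NB means
    pre_dropout: np.ndarray  # counts before dropout
    dropout_mask: np.ndarray  # True where dropout zeroed the entry
    group_de_factors: np.ndarray  # (n_groups, n_genes)

    def capture_loss_rate(self) -> float:
        """Fraction of originally non-zero entries zeroed by dropout."""
        nz = self.pre_dropout > 0
        return float((self.dropout_mask & nz).sum() / max(nz.sum(), 1))


def simulate(
    scenario: SimulationScenario, return_truth: bool = False
) -> CountDataset | tuple[CountDataset, SimulationTruth]:
    rng = np.random.default_rng(scenario.seed)
    n, g, k = scenario.n_cells, scenario.n_genes, scenario.n_groups

    base = rng.lognormal(BASE_MEAN_LOGLOC, BASE_MEAN_LOGSCALE, size=g)

    de_factors = np.ones((k, g))
    for grp in range(k):
        mask = rng.random(g) < DE_PROB
        fac = rng.lognormal(scenario.de_fac_loc, scenario.de_fac_scale, size=g)
        down = rng.random(g) < 0.5
        fac = np.where(down, 1.0 / fac, fac)
        de_factors[grp, mask] = fac[mask]

    group_sizes = geometric_sizes(n, k, scenario.group_ratio)
    groups = np.repeat(np.arange(k), group_sizes)
    groups = groups[rng.permutation(n)]

    if scenario.n_batches > 1:
        batch_sizes = geometric_sizes(n, scenario.n_batches, scenario.batch_ratio)
        batches = np.repeat(np.arange(scenario.n_batches), batch_sizes)
        batches = batches[rng.permutation(n)]
        batch_factors = rng.lognormal(
            BATCH_FAC_LOC, BATCH_FAC_SCALE, size=(scenario.n_batches, g)
        )
    else:
        batches = np.zeros(n, dtype=np.int64)
        batch_factors = np.ones((1, g))

    lib = rng.lognormal(LIB_LOGLOC, LIB_LOGSCALE, size=n)

    prog = base[None, :] * de_factors[groups] * batch_factors[batches]
    prop = prog / prog.sum(axis=1, keepdims=True)
    mean = lib[:, None] * prop  # (n, g) NB means

    lam = rng.gamma(NB_SHAPE, mean / NB_SHAPE)
    y = rng.poisson(lam)

    log_mean = np.log(mean)
    nonzero = y > 0
    target = DROPOUT_RATE_AT_LOW + DROPOUT_RATE_SLOPE * (
        scenario.dropout_mid - DROPOUT_MID_LOW
    )
    target = float(np.clip(target, 1e-9, 0.95))
    mid_eff = _solve_dropout_midpoint(
        log_mean, nonzero, scenario.dropout_shape, target
    )
    p_drop = expit(scenario.dropout_shape * (log_mean - mid_eff))
    h = rng.random((n, g)) < p_drop
    x = np.where(h, 0, y)

    dataset = CountDataset(
        counts=x,
        batch=np.array([f"batch{b}" for b in batches]),
        true_labels=np.array([f"group{t}" for t in groups]),
        cell_names=np.array([f"cell{i}" for i in range(n)]),
        gene_names=np.array([f"g{i}" for i in range(g)]),
    )
    if not return_truth:
        return dataset
    truth = SimulationTruth(
        mean_matrix=mean,
        pre_dropout=y,
        dropout_mask=h,
        group_de_factors=de_factors,
    )
    return dataset, truth


def _solve_dropout_midpoint(log_mean, nonzero, shape, target) -> float:
    """Logistic midpoint whose expected capture loss among would-be
    non-zero entries equals ``target`` (monotone bisection)."""
    weights = nonzero.ravel()
    lm = log_mean.ravel()[weights]

    def rate(mid):
        return expit(shape * (lm - mid)).mean()

    lo, hi = lm.min() - 60.0, lm.max() + 60.0
    # rate is monotone in mid (increasing for shape < 0)
    increasing = rate(hi) > rate(lo)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if (rate(mid) < target) == increasing:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


_DROPOUT_SWEEP = (-1.5, -1.0, -0.5, 0.0, 0.5)
_BALANCED_GROUPS = (3, 4, 5, 6, 7)
_IMBALANCED_RATIOS = (0.6, 0.7, 0.8, 0.9, 1.0)


def scenario_grid(
    kind: str,
    n_seeds: int = 10,
    n_cells: int = 2500,
    n_genes: int = 2500,
    groups: tuple[int, ...] | None = None,
    dropout_mids: tuple[float, ...] | None = None,
    ratios: tuple[float, ...] | None = None,
    base_seed: int = 0,
) -> list[SimulationScenario]:
    """Scenario templates for the four simulation studies.

    ``balanced``: group counts 3..7 crossed with the dropout sweep;
    ``imbalanced``: 5 groups, geometric size ratios 0.6..1.0 crossed with
    the dropout sweep; the ``batch_*`` variants add 3 batches whose sizes
    follow a geometric sequence with ratio 0.7.  Each grid cell is
    replicated over ``n_seeds`` seeds.
    """
    mids = dropout_mids if dropout_mids is not None else _DROPOUT_SWEEP
    n_batches = 3 if kind.startswith("batch_") else 1
    core = kind.removeprefix("batch_")
    cells: list[tuple[int, float]] = []
    if core == "balanced":
        for grp in groups if groups is not None else _BALANCED_GROUPS:
            for mid in mids:
                cells.append((grp, 1.0, mid))
    elif core == "imbalanced":
        for r in ratios if ratios is not None else _IMBALANCED_RATIOS:
            for mid in mids:
                cells.append((5, r, mid))
    else:
        raise ValueError(f"unknown scenario kind {kind!r}")
    out = []
    for grp, r, mid in cells:
        for s in range(n_seeds):
            out.append(
                SimulationScenario(
                    n_groups=grp,
                    n_cells=n_cells,
                    n_genes=n_genes,
                    group_ratio=r,
                    dropout_mid=mid,
                    n_batches=n_batches,
                    seed=base_seed + s,
                )
            )
    return out
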