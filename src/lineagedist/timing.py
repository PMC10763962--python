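"""Timing statistics: correlations, shuffle nulls, and clock-slope estimation.

Two observations motivate this module.  First, a cell's *birth time* is the
sum of its ancestors' cycle times, and sums of random variables suppress
variation — so birth-time correlations between embryos are spuriously
inflated even when the underlying cycle times are completely uncorrelated.
The within-embryo shuffle null here demonstrates that directly.  Second, two
embryos can be near-perfectly correlated yet run on different global clocks;
the systematic rate difference is the *slope* of the paired cycle-time cloud,
estimated via the principal axis (total least squares) rather than ordinary
regression because neither embryo is a privileged independent variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import Lineage, Sublineage, birth_time, cells_of
from .metrics import align_by_name


@dataclass
class SlopeEstimate:
    """Clock-slope estimate between two embryos.

    m is dimensionless (minutes per minute): m < 1 means the x-axis embryo's
    cells cycle systematically longer (it develops slower).
    """

    m: float
    r2: float
    n: int


@dataclass
class ShuffleConfig:
    seed: int
    scope: str = "within_embryo"  # or "same_name_across_embryos"


def shuffle_cycle_times(lineage: Lineage, seed: int, derangement: bool = False) -> Lineage:
    """Permute the cycle times uniformly at random over the cells of one embryo.

    Topology and the multiset of cycle times are preserved exactly; only the
    assignment of times to cells is destroyed.  A plain permutation may fix a
    cell's own value; pass ``derangement=True`` to forbid fixed points.
    """
    names = sorted(lineage.cells)
    values = np.array([lineage.cells[n] for n in names])
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(names))
    if derangement and len(names) > 1:
        while np.any(perm == np.arange(len(names))):
            perm = rng.permutation(len(names))
    shuffled = {n: float(values[perm[i]]) for i, n in enumerate(names)}
    meta = dict(lineage.meta)
    meta["shuffle_seed"] = seed
    meta["shuffle_scope"] = "within_embryo"
    return Lineage(embryo_id=lineage.embryo_id, cells=shuffled, meta=meta)


def _shared_values(X, Y, value: str) -> tuple[np.ndarray, np.ndarray]:
    pairs = align_by_name(X, Y)
    if value == "cycle":
        return pairs.arrays()
    if value == "birth":
        keys = [k for k, _, _ in pairs.entries]
        bx = np.array([birth_time(X, k) for k in keys])
        by = np.array([birth_time(Y, k) for k in keys])
        return bx, by
    raise ValueError(f"value must be 'cycle' or 'birth', got {value!r}")


def correlation_r2(X, Y, value: str = "cycle") -> SlopeEstimate:
    """Squared Pearson correlation of the chosen per-cell value over shared cells.

    For a simple linear fit with intercept, R² and the squared linear
    correlation coefficient coincide, so one quantity serves both framings.
    The slope field is left as NaN; use :func:`pca_slope` for the clock.
    """
    x, y = _shared_values(X, Y, value)
    if len(x) < 2:
        raise ValueError(f"need >= 2 shared cells, have {len(x)}")
    r = stats.pearsonr(x, y).statistic
    return SlopeEstimate(m=float("nan"), r2=float(r * r), n=len(x))


def pca_slope(X, Y, value: str = "cycle") -> SlopeEstimate:
    """Principal-axis (total least squares) slope of Y's times against X's.

    The shared cycle-time pairs are mean-centered and the eigenvector of the
    2x2 covariance matrix with the largest eigenvalue is taken as the best
    fit line; m is its rise over run, oriented so run > 0.  Symmetric in the
    sense that pca_slope(X, Y).m * pca_slope(Y, X).m == 1.
    """
    x, y = _shared_values(X, Y, value)
    if len(x) < 3:
        raise ValueError(f"need >= 3 shared cells, have {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance on one axis; slope undefined")
    cov = np.cov(np.vstack([x - x.mean(), y - y.mean()]))
    eigvals, eigvecs = np.linalg.eigh(cov)
    v = eigvecs[:, int(np.argmax(eigvals))]
    if v[0] < 0:
        v = -v
    if v[0] == 0:
        raise ValueError("principal axis is vertical; slope undefined")
    r = stats.pearsonr(x, y).statistic
    return SlopeEstimate(m=float(v[1] / v[0]), r2=float(r * r), n=len(x))


def fraction_faster(A, B) -> float:
    """Fraction of shared cells that cycle strictly faster in A than in B.

    Ties do not count as faster, so fraction_faster(A, B) +
    fraction_faster(B, A) <= 1 with equality iff there are no ties.  A
    majority (> half the shared cells) is the usual "faster lineage" call.
    """
    pairs = align_by_name(A, B)
    if pairs.n_shared == 0:
        raise ValueError("no shared cells; fraction undefined")
    ta, tb = pairs.arrays()
    return float(np.mean(ta < tb))
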