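"""Pan/core genome growth over genome subsets and growth-law fitting.

Every non-empty subset of the panel's haplomes contributes one point:
the subset's *pan* size is the number of orthogroups present in at
least one member and its *core* size the number present in all members.
Pangenome growth is modelled with the power law ``y = A * x**B + C``
and core-genome decay with the exponential ``y = A * exp(B * x) + C``,
both fitted by Levenberg-Marquardt nonlinear least squares from
multiple documented starts (best residual sum of squares wins).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .datatypes import HaplomePanel, OrthogroupMatrix

Model = Literal["power_law", "exponential"]


@dataclass(frozen=True)
class SubsetPoint:
    """Pan and core orthogroup counts for one haplome subset."""

    k: int
    members: frozenset[str]
    pan_size: int
    core_size: int


def enumerate_subsets(
    matrix: OrthogroupMatrix,
    panel: HaplomePanel,
    max_haplomes: int = 20,
) -> list[SubsetPoint]:
    """Exact pan/core sizes for all 2**N - 1 non-empty haplome subsets.

    Uses bitset column logic: each orthogroup's presence row is packed
    into an integer, so a subset's pan count is the number of rows
    intersecting the subset mask and its core count the number of rows
    containing it.
    """
    matrix.validate_against(panel)
    n = panel.n_haplomes
    if n > max_haplomes:
        raise ValueError(
            f"{n} haplomes would require {2**n - 1} subsets; exact enumeration is "
            f"guarded at {max_haplomes} (pass max_haplomes to raise the guard)"
        )
    presence = matrix.presence.to_numpy()
    bits = presence @ (1 << np.arange(n, dtype=np.int64))
    haps = np.array(panel.haplome_ids, dtype=object)
    points: list[SubsetPoint] = []
    for mask in range(1, 2**n):
        hit = bits & mask
        pan = int(np.count_nonzero(hit))
        core = int(np.count_nonzero(hit == mask))
        members = frozenset(haps[[i for i in range(n) if mask >> i & 1]])
        points.append(SubsetPoint(len(members), members, pan, core))
    return points


def mean_sizes(points: Sequence[SubsetPoint]) -> pd.DataFrame:
    """Mean pan and core size per subset size k."""
    df = pd.DataFrame(
        {"k": [p.k for p in points], "pan": [p.pan_size for p in points],
         "core": [p.core_size for p in points]}
    )
    out = df.groupby("k", as_index=False).mean().rename(
        columns={"pan": "mean_pan", "core": "mean_core"}
    )
    return out


def growth_increments(points: Sequence[SubsetPoint]) -> pd.DataFrame:
    """Per-k change in mean pan/core size when adding the k-th genome.

    ``delta_pan(k)`` is the mean pan size over size-k subsets minus the
    mean over size-(k-1) subsets, for k = 2..N; ``delta_core``
    analogously.  Means are taken over all subsets of each size, not a
    single addition order.
    """
    means = mean_sizes(points)
    ks = means["k"].tolist()
    if ks != list(range(1, max(ks) + 1)):
        raise ValueError(f"subset sizes must cover 1..N without gaps, got {ks}")
    out = pd.DataFrame(
        {
            "k": means["k"].iloc[1:].to_numpy(),
            "delta_pan": np.diff(means["mean_pan"].to_numpy()),
            "delta_core": np.diff(means["mean_core"].to_numpy()),
        }
    )
    return out


@dataclass
class CurveFitResult:
    """Fitted growth-law parameters and goodness of fit."""

    model: Model
    A: float
    B: float
    C: float
    rss: float
    converged: bool

    def predict(self, k: np.ndarray | float) -> np.ndarray | float:
        k = np.asarray(k, dtype=float)
        if self.model == "power_law":
            return self.A * k**self.B + self.C
        return self.A * np.exp(self.B * k) + self.C

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "A": self.A,
            "B": self.B,
            "C": self.C,
            "rss": self.rss,
            "converged": self.converged,
        }


def _starts(model: Model, x: np.ndarray, y: np.ndarray) -> list[tuple[float, float, float]]:
    ymin, ymax = float(y.min()), float(y.max())
    y1 = float(y[x == x.min()].mean())
    yN = float(y[x == x.max()].mean())
    dy_dk = (ymax - ymin) / max(float(x.max() - x.min()), 1.0)
    if model == "power_law":
        starts = [(ymax - ymin, 0.3, ymin), (y1, 0.5, 0.0), (dy_dk, 1.0, ymin)]
    else:
        starts = [(y1 - yN, -0.3, yN), (y1, -0.5, 0.0), (ymax, -1.0, ymin)]
    # a zero amplitude start would freeze B; nudge it
    return [(a if a != 0 else 1.0, b, c) for a, b, c in starts]


def fit_growth(
    points: Sequence[SubsetPoint],
    model: Model,
    response: Literal["pan", "core"] | None = None,
    xtol: float = 1e-8,
    max_nfev: int = 10_000,
) -> CurveFitResult:
    """Least-squares fit of a growth law to subset points.

    ``response`` defaults to ``"pan"`` for the power law and ``"core"``
    for the exponential, the conventional pairing.  All points enter the
    regression (no per-k averaging).  Three documented starts are tried
    and the best residual sum of squares wins; ``converged`` is False if
    every start fails.
    """
    if model not in ("power_law", "exponential"):
        raise ValueError(f"unknown model {model!r}")
    if response is None:
        response = "pan" if model == "power_law" else "core"
    x = np.array([p.k for p in points], dtype=float)
    y = np.array(
        [p.pan_size if response == "pan" else p.core_size for p in points], dtype=float
    )
    if len(x) < 4 or len(np.unique(x)) < 3:
        raise ValueError("need >= 4 points spanning >= 3 distinct subset sizes")
    if not np.isfinite(y).all():
        raise ValueError("non-finite response values")

    if model == "power_law":
        f: Callable[[np.ndarray, np.ndarray], np.ndarray] = lambda p, xx: p[0] * xx ** p[1] + p[2]
    else:
        f = lambda p, xx: p[0] * np.exp(p[1] * xx) + p[2]

    best: CurveFitResult | None = None
    for start in _starts(model, x, y):
        try:
            sol = least_squares(
                lambda p: f(p, x) - y,
                x0=np.array(start, dtype=float),
                method="lm",
                xtol=xtol,
                max_nfev=max_nfev,
            )
        except Exception:
            continue
        if not np.isfinite(sol.x).all():
            continue
        rss = float(np.sum((f(sol.x, x) - y) ** 2))
        cand = CurveFitResult(model, *map(float, sol.x), rss=rss, converged=bool(sol.success))
        if best is None or rss < best.rss:
            best = cand
    if best is None:
        return CurveFitResult(model, np.nan, np.nan, np.nan, rss=np.inf, converged=False)
    return best


def subsets_frame(points: Sequence[SubsetPoint]) -> pd.DataFrame:
    """Subset table (k, comma-joined members, pan, core) for writing."""
    return pd.DataFrame(
        {
            "k": [p.k for p in points],
            "members": [",".join(sorted(p.members)) for p in points],
            "pan_size": [p.pan_size for p in points],
            "core_size": [p.core_size for p in points],
        }
    )
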