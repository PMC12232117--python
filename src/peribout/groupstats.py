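"""Group-level statistics for the behavioral and in vitro comparisons.

Implements, from first principles, the within-subjects toolkit used on
lick-behavior and multispout data — one- and two-way repeated-measures
ANOVA with Greenhouse–Geisser sphericity correction, Holm step-down
adjustment, planned paired comparisons — plus Welch's heteroscedastic
ANOVA with a Monte-Carlo Dunnett many-to-one post hoc and the +/-2 SD
outlier screen used for in vitro cell samples.

The repeated-measures decomposition works in contrast space: for a
within-subject effect with orthonormal contrast matrix C (q x cells),
Z = Y C' gives per-subject contrast scores, F = (n * ||z_bar||^2 / q) /
(SS_resid / (q (n-1))), and the Greenhouse–Geisser epsilon is
tr(S)^2 / (q * tr(S^2)) with S the sample covariance of Z — equal to 1
exactly under sphericity and bounded below by 1/q.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    IncompleteDesignError,
    InvalidDesignError,
    InvalidInputError,
)

__all__ = [
    "WithinSubjectsTable",
    "AnovaResult",
    "PairedComparison",
    "WelchDunnettResult",
    "rm_anova",
    "holm_correct",
    "planned_paired_comparisons",
    "welch_anova_dunnett",
    "outlier_filter",
]


@dataclass
class WithinSubjectsTable:
    """Complete subjects x cells response table for 1 or 2 within factors.

    ``factors`` maps factor name -> ordered level labels; cells are laid
    out with the first factor varying slowest.  ``data`` has one row per
    subject and one column per factor-level combination.
    """

    subjects: list[str]
    factors: dict[str, list]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n_cells = int(np.prod([len(v) for v in self.factors.values()]))
        if len(self.factors) not in (1, 2):
            raise InvalidDesignError("only 1 or 2 within-subject factors supported")
        if any(len(v) < 2 for v in self.factors.values()):
            raise InvalidDesignError("every factor needs >= 2 levels")
        if self.data.shape != (len(self.subjects), n_cells):
            raise IncompleteDesignError(
                f"expected shape {(len(self.subjects), n_cells)}, got {self.data.shape}"
            )
        if len(self.subjects) < 2:
            raise InvalidDesignError("need >= 2 subjects")
        if not np.all(np.isfinite(self.data)):
            raise IncompleteDesignError("table contains missing/non-finite cells")

    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        subject: str,
        factors: list[str],
        value: str,
    ) -> "WithinSubjectsTable":
        """Build from a long-format frame, averaging duplicate cell rows."""
        subjects = sorted(df[subject].unique().tolist())
        levels = {f: sorted(df[f].unique().tolist()) for f in factors}
        cells = list(itertools.product(*levels.values()))
        grouped = df.groupby([subject, *factors])[value].mean()
        data = np.full((len(subjects), len(cells)), np.nan)
        for i, s in enumerate(subjects):
            for j, cell in enumerate(cells):
                key = (s, *cell)
                if key in grouped.index:
                    data[i, j] = grouped.loc[key]
        if np.any(np.isnan(data)):
            raise IncompleteDesignError("long-format table has missing cells")
        return cls(subjects=subjects, factors=levels, data=data)

    def cell_labels(self) -> list[tuple]:
        return list(itertools.product(*self.factors.values()))


@dataclass(frozen=True)
class AnovaResult:
    """One within-subjects effect with uncorrected and GG-corrected p."""

    effect: str
    F: float
    df1: float
    df2: float
    p: float
    gg_epsilon: float
    p_gg: float

    @property
    def gg_applied(self) -> bool:
        """Whether the recommended p uses the GG correction (epsilon < 0.75)."""
        return self.gg_epsilon < 0.75

    @property
    def p_selected(self) -> float:
        return self.p_gg if self.gg_applied else self.p


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal basis of the contrast (mean-zero) subspace."""
    centered = np.eye(k) - 1.0 / k
    u, s, vt = np.linalg.svd(centered)
    return vt[s > 1e-10]


def _effect_f(z: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """Univariate RM-ANOVA F and GG epsilon from subject contrast scores."""
    n, q = z.shape
    zbar = z.mean(axis=0)
    ss_eff = n * float(zbar @ zbar)
    resid = z - zbar
    ss_err = float((resid * resid).sum())
    df1, df2 = float(q), float(q * (n - 1))
    F = (ss_eff / df1) / (ss_err / df2) if ss_err > 0 else np.inf
    if q == 1:
        eps = 1.0
    else:
        S = np.cov(z, rowvar=False, ddof=1)
        tr = float(np.trace(S))
        tr2 = float(np.trace(S @ S))
        eps = 1.0 if tr2 <= 0 else min(1.0, (tr * tr) / (q * tr2))
        eps = max(eps, 1.0 / q)
    p = float(stats.f.sf(F, df1, df2))
    p_gg = float(stats.f.sf(F, eps * df1, eps * df2))
    return F, df1, df2, p, eps, p_gg


def rm_anova(table: WithinSubjectsTable) -> list[AnovaResult]:
    """Main effects (and interaction for 2 factors) of a within design.

    Returns one :class:`AnovaResult` per effect with F, uncorrected df and
    p, the Greenhouse–Geisser epsilon estimated from the covariance of the
    within-subject contrasts, and the corrected p.
    """
    names = list(table.factors)
    sizes = [len(table.factors[f]) for f in names]
    contrasts = {f: _orthonormal_contrasts(k) for f, k in zip(names, sizes)}
    results = []
    if len(names) == 1:
        effects = {names[0]: contrasts[names[0]]}
    else:
        a, b = names
        ua = np.full((1, sizes[0]), 1 / np.sqrt(sizes[0]))
        ub = np.full((1, sizes[1]), 1 / np.sqrt(sizes[1]))
        effects = {
            a: np.kron(contrasts[a], ub),
            b: np.kron(ua, contrasts[b]),
            f"{a}:{b}": np.kron(contrasts[a], contrasts[b]),
        }
    for effect, M in effects.items():
        z = table.data @ M.T
        F, df1, df2, p, eps, p_gg = _effect_f(z)
        results.append(
            AnovaResult(effect=effect, F=F, df1=df1, df2=df2, p=p, gg_epsilon=eps, p_gg=p_gg)
        )
    return results


def holm_correct(pvals) -> list[float]:
    """Holm step-down adjusted p-values, order-preserving, capped at 1."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidInputError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


@dataclass(frozen=True)
class PairedComparison:
    level_a: object
    level_b: object
    at: object  # level of the other factor, or None
    t: float
    df: int
    p: float
    degenerate: bool = False


def planned_paired_comparisons(
    table: WithinSubjectsTable,
    factor: str,
    pairs: list[tuple],
    within: str | None = None,
) -> list[PairedComparison]:
    """Paired t-tests between levels of ``factor`` (no multiplicity correction).

    With a two-factor table and ``within`` given, each pair is tested
    separately at every level of the other factor (e.g. vehicle vs drug at
    each sucrose concentration); otherwise cell values are averaged over
    any other factor first.  A zero-variance difference is flagged
    degenerate with t and p set to NaN.
    """
    if factor not in table.factors:
        raise InvalidInputError(f"unknown factor {factor!r}")
    names = list(table.factors)
    cells = table.cell_labels()
    other = [f for f in names if f != factor]
    if within is not None and within not in other:
        raise InvalidInputError(f"'within' must name the other factor, got {within!r}")
    at_levels = table.factors[within] if within else [None]

    def cell_cols(level, at):
        cols = []
        for j, cell in enumerate(cells):
            d = dict(zip(names, cell))
            if d[factor] != level:
                continue
            if at is not None and d[within] != at:
                continue
            cols.append(j)
        return cols

    out = []
    for at in at_levels:
        for la, lb in pairs:
            for lvl in (la, lb):
                if lvl not in table.factors[factor]:
                    raise InvalidInputError(f"unknown level {lvl!r} of factor {factor!r}")
            xa = table.data[:, cell_cols(la, at)].mean(axis=1)
            xb = table.data[:, cell_cols(lb, at)].mean(axis=1)
            d = xa - xb
            n = d.size
            sd = float(np.std(d, ddof=1))
            if sd == 0:
                if np.allclose(d, 0):
                    out.append(PairedComparison(la, lb, at, 0.0, n - 1, 1.0))
                else:
                    out.append(
                        PairedComparison(la, lb, at, float("nan"), n - 1, float("nan"), True)
                    )
                continue
            t = float(np.mean(d) / (sd / np.sqrt(n)))
            p = float(2 * stats.t.sf(abs(t), n - 1))
            out.append(PairedComparison(la, lb, at, t, n - 1, p))
    return out


@dataclass
class WelchDunnettResult:
    F: float
    df1: float
    df2: float
    p: float
    dunnett_p: list[float | None] = field(default_factory=list)  # None at control


def welch_anova_dunnett(
    groups: list[np.ndarray],
    control_index: int = 0,
    n_mc: int = 100_000,
    seed: int = 0,
) -> WelchDunnettResult:
    """Welch's heteroscedastic ANOVA plus Dunnett many-to-one comparisons.

    The Dunnett family-wise p-values come from a seeded Monte-Carlo
    evaluation of the max-|t| null: each replicate redraws every group from
    a normal with its observed variance, recomputes the unpooled
    many-to-one t statistics against the control, and the p for comparison
    i is the fraction of replicates whose max |t| reaches |t_i|.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise InvalidInputError("need >= 2 groups")
    if any(g.size < 2 for g in groups):
        raise InvalidInputError("every group needs n >= 2")
    ns = np.array([g.size for g in groups])
    means = np.array([g.mean() for g in groups])
    vars_ = np.array([g.var(ddof=1) for g in groups])

    w = ns / np.maximum(vars_, 1e-300)
    W = w.sum()
    xw = float((w * means).sum() / W)
    A = float((w * (means - xw) ** 2).sum() / (k - 1))
    h = float((((1 - w / W) ** 2) / (ns - 1)).sum())
    B = 1 + 2 * (k - 2) / (k * k - 1) * h
    F = A / B if B > 0 else np.inf
    df1 = float(k - 1)
    df2 = float((k * k - 1) / (3 * h)) if h > 0 else np.inf
    p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    if A == 0:
        F, p = 0.0, 1.0

    # observed many-to-one statistics
    c = control_index
    comp = [i for i in range(k) if i != c]
    se = np.sqrt(vars_ / ns + vars_[c] / ns[c])
    t_obs = (means - means[c]) / np.where(se > 0, se, np.inf)

    rng = np.random.default_rng(seed)
    sim_means = np.empty((n_mc, k))
    sim_vars = np.empty((n_mc, k))
    for i, g in enumerate(groups):
        draws = rng.normal(0.0, np.sqrt(vars_[i]) if vars_[i] > 0 else 0.0, size=(n_mc, g.size))
        sim_means[:, i] = draws.mean(axis=1)
        sim_vars[:, i] = draws.var(axis=1, ddof=1)
    sim_se = np.sqrt(
        sim_vars[:, comp] / ns[comp] + sim_vars[:, [c]] / ns[c]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        sim_t = (sim_means[:, comp] - sim_means[:, [c]]) / sim_se
    sim_t = np.nan_to_num(sim_t)
    max_abs = np.abs(sim_t).max(axis=1)

    dunnett: list[float | None] = [None] * k
    for i in comp:
        if not np.isfinite(t_obs[i]):
            dunnett[i] = 0.0 if se[i] == 0 and means[i] != means[c] else 1.0
        else:
            # add-one Monte-Carlo convention: never exactly 0
            dunnett[i] = float((np.sum(max_abs >= abs(t_obs[i])) + 1) / (n_mc + 1))
    # identical samples everywhere -> all t_obs are 0 -> p = 1 by convention
    for i in comp:
        if t_obs[i] == 0:
            dunnett[i] = 1.0
    return WelchDunnettResult(F=F, df1=df1, df2=df2, p=p, dunnett_p=dunnett)


def outlier_filter(values, k: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass removal of values beyond k sample SDs of the full-input mean.

    Mean and SD (n-1 denominator) are computed once from the complete
    input; values with ``|v - mean| > k * sd`` (strict) are removed.
    Returns (kept values, removed indices).  Order-independent and
    deterministic; with zero SD nothing is removed.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise InvalidInputError("need >= 3 values for the outlier screen")
    mu = v.mean()
    sd = v.std(ddof=1)
    removed = np.nonzero(np.abs(v - mu) > k * sd)[0]
    kept = np.delete(v, removed)
    return kept, removed
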