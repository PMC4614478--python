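"""Monte Carlo harness: vulnerability sweeps, risk estimation, regression.

Risk at one grid point is the mean harm indicator over independent
simulated entries with fresh random targets.  Every (design, v) cell runs
on its own RNG substream derived by hashing the master seed with the cell
coordinates, so tables are bit-reproducible and independent of evaluation
order.  Per-design ordinary least squares of risk on vulnerability
summarises each design as a line; the coefficient of determination
measures the linearity of the risk/vulnerability relation.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
import math
import random
from dataclasses import dataclass, field, replace
from decimal import Decimal
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .codec import (
    INVALID,
    TargetDistribution,
    TargetNumber,
    TargetSource,
    value_of,
)
from .designs import DESIGN_IDS, check_design, presser_for
from .operator import ErrorModel, OperatorParams, _Compiled, _run_trial

log = logging.getLogger(__name__)


def derive_seed(*parts) -> int:
    """Deterministic 31-bit substream seed from arbitrary coordinates."""
    text = "|".join(str(p) for p in parts)
    digest = hashlib.sha256(text.encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# Harm metrics


@dataclass(frozen=True)
class HarmMetric:
    """How a finally accepted value is scored against the intended one.

    ``exact``: harm iff the values differ (an unreadable INVALID final
    state counts as harm).  ``out_by_factor``: harm iff the ratio of the
    two values reaches ``factor`` (or exactly one of them is zero).
    ``overdose_only``: harm iff the entered value exceeds the intended one
    (an INVALID reading is not an overdose).  Trials that exhaust the
    attempt cap count as harm under every metric and are reported in the
    ``n_capped`` column.
    """

    kind: str = "exact"
    factor: Optional[Decimal] = None

    def __post_init__(self):
        if self.kind not in ("exact", "out_by_factor", "overdose_only"):
            raise ValueError(f"unknown harm metric {self.kind!r}")
        if (self.kind == "out_by_factor") != (self.factor is not None):
            raise ValueError("factor is required exactly for out_by_factor")
        if self.factor is not None and self.factor <= 1:
            raise ValueError("factor must exceed 1")

    def harm(self, stored: Optional[str], target: TargetNumber) -> int:
        if stored is None:  # attempt cap exhausted, nothing accepted
            return 1
        if stored == target.canonical:
            return 0
        val = value_of(stored)
        if self.kind == "exact":
            return 0 if val == target.value else 1
        if val is INVALID:
            return 0 if self.kind == "overdose_only" else 1
        n = target.value
        if self.kind == "overdose_only":
            return 1 if val > n else 0
        if (val == 0) != (n == 0):
            return 1
        if val == 0:
            return 0
        lo, hi = (val, n) if val < n else (n, val)
        return 1 if hi >= self.factor * lo else 0


EXACT_MISMATCH = HarmMetric("exact")
OVERDOSE_ONLY = HarmMetric("overdose_only")


def OUT_BY_FACTOR(f: Union[int, str, Decimal]) -> HarmMetric:
    return HarmMetric("out_by_factor", Decimal(f))


# ---------------------------------------------------------------------------
# Configuration


def default_v_grid(n: int = 100) -> tuple[float, ...]:
    """The default vulnerability grid: n evenly spaced values up to 1."""
    return tuple(round((i + 1) / n, 10) for i in range(n))


@dataclass(frozen=True)
class ExperimentConfig:
    designs: tuple[str, ...] = DESIGN_IDS
    v_grid: tuple[float, ...] = field(default_factory=default_v_grid)
    trials_per_point: int = 10_000
    operator: ErrorModel = field(default_factory=ErrorModel)
    targets: TargetSource = field(default_factory=TargetDistribution)
    seed: int = 0
    harm_metric: HarmMetric = EXACT_MISMATCH

    def __post_init__(self):
        for d in self.designs:
            check_design(d)
        vg = self.v_grid
        if not vg or any(not 0.0 <= v <= 1.0 for v in vg):
            raise ValueError("v_grid values must lie in [0, 1]")
        if any(b <= a for a, b in zip(vg, vg[1:])):
            raise ValueError("v_grid must be strictly increasing")
        if self.trials_per_point < 1:
            raise ValueError("trials_per_point must be >= 1")

    def operator_at(self, v: float) -> OperatorParams:
        return OperatorParams(
            per_class_error_prob=self.operator.per_class_error_prob,
            class_probs=self.operator.class_probs,
            substitution_alphabet=self.operator.substitution_alphabet,
            insertion_alphabet=self.operator.insertion_alphabet,
            max_attempts=self.operator.max_attempts,
            vulnerability=v,
        )


# ---------------------------------------------------------------------------
# Risk estimation


@dataclass(frozen=True)
class RiskPoint:
    """Estimated risk at one (design, vulnerability) grid point."""

    design: str
    v: float
    trials: int
    risk: float
    se: float
    risk_ratio: Optional[float]  # undefined at v = 0
    n_capped: int = 0


def estimate_risk(
    design: str,
    v: float,
    config: ExperimentConfig,
    rng: Optional[random.Random] = None,
) -> RiskPoint:
    """Mean harm over ``trials_per_point`` fresh-target simulated entries."""
    check_design(design)
    if rng is None:
        rng = random.Random(
            derive_seed(config.seed, design, v, config.trials_per_point)
        )
    trials = config.trials_per_point
    cp = _Compiled(config.operator_at(v))
    press = presser_for(design)
    draw = config.targets.draw_canonical
    metric = config.harm_metric
    fast_exact = metric.kind == "exact"
    harms = 0
    capped = 0
    for _ in range(trials):
        canonical = draw(rng)
        target = TargetNumber(canonical)
        stored, _ = _run_trial(press, design, canonical, target, cp, rng)
        if stored is None:
            capped += 1
            harms += 1
        elif fast_exact:
            if stored != canonical and value_of(stored) != target.value:
                harms += 1
        else:
            harms += metric.harm(stored, target)
    risk = harms / trials
    se = math.sqrt(risk * (1.0 - risk) / trials)
    return RiskPoint(
        design, v, trials, risk, se, (risk / v if v > 0 else None), capped
    )


def sweep(config: ExperimentConfig) -> pd.DataFrame:
    """One :class:`RiskPoint` per (design, v) cell, as a tidy table."""
    rows = []
    for design in config.designs:
        log.info("sweeping design %s (%d v-points, %d trials each)",
                 design, len(config.v_grid), config.trials_per_point)
        for v in config.v_grid:
            pt = estimate_risk(design, v, config)
            log.debug("design %s v=%.4g risk=%.5g", design, v, pt.risk)
            rows.append(pt)
    return points_frame(rows)


def points_frame(points: Iterable[RiskPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "design": p.design,
                "v": p.v,
                "trials": p.trials,
                "risk": p.risk,
                "se": p.se,
                "risk_ratio": p.risk_ratio,
                "n_capped": p.n_capped,
            }
            for p in points
        ]
    )


# ---------------------------------------------------------------------------
# Regression


@dataclass(frozen=True)
class RegressionSummary:
    design: str
    slope: float
    intercept: float
    r_squared: float


def fit_line(
    points: Union[pd.DataFrame, Sequence[RiskPoint]], weighted: bool = False
) -> RegressionSummary:
    """Least squares of risk on vulnerability for one design's points.

    Unweighted OLS by default; ``weighted=True`` uses inverse-variance WLS
    as a sensitivity variant.  A zero-variance (constant-risk) fit returns
    slope 0 and, by convention, R-squared 0.
    """
    df = points if isinstance(points, pd.DataFrame) else points_frame(points)
    designs = df["design"].unique()
    if len(designs) != 1:
        raise ValueError("fit_line expects the points of exactly one design")
    if df["v"].nunique() < 3:
        raise ValueError("need at least 3 distinct vulnerability values")
    y = df["risk"].to_numpy(float)
    x = sm.add_constant(df["v"].to_numpy(float))
    if np.ptp(y) == 0.0:
        return RegressionSummary(designs[0], 0.0, float(y[0]), 0.0)
    if weighted:
        var = df["se"].to_numpy(float) ** 2
        floor = 0.25 / df["trials"].to_numpy(float) ** 2
        res = sm.WLS(y, x, weights=1.0 / np.maximum(var, floor)).fit()
    else:
        res = sm.OLS(y, x).fit()
    r2 = float(res.rsquared)
    if math.isnan(r2):
        r2 = 0.0
    return RegressionSummary(
        designs[0], float(res.params[1]), float(res.params[0]), r2
    )


def fit_all(sweep_df: pd.DataFrame, weighted: bool = False) -> pd.DataFrame:
    rows = []
    for design, grp in sweep_df.groupby("design", sort=False):
        s = fit_line(grp, weighted=weighted)
        rows.append(
            {
                "design": design,
                "slope": s.slope,
                "intercept": s.intercept,
                "r_squared": s.r_squared,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Design comparison


#: partial order the simulation is expected to reproduce: (safer, riskier)
EXPECTED_ORDER = (
    ("C", "A"),
    ("C", "B"),
    ("N", "C"),
    ("D", "C"),
    ("E", "C"),
    ("G", "C"),
    ("F", "E"),
)


@dataclass
class ComparisonReport:
    """Pairwise dominance, fitted-line crossings and a safety ranking."""

    ranking: list[str]
    dominance: pd.DataFrame
    crossings: list[tuple[str, str, float]]
    violations: list[str]

    def to_text(self) -> str:
        lines = ["ranking (safest first): " + " <= ".join(self.ranking), ""]
        lines.append("dominance matrix (row dominates column):")
        lines.append(self.dominance.to_string())
        lines.append("")
        if self.crossings:
            for a, b, vstar in self.crossings:
                lines.append(f"fitted lines of {a} and {b} cross at v={vstar:.3f}")
        else:
            lines.append("no statistically resolvable fitted-line crossings on (0,1]")
        for v in self.violations:
            lines.append("ORDER VIOLATION: " + v)
        if not self.violations:
            lines.append("expected safety ordering holds everywhere (within 3 SE)")
        return "\n".join(lines) + "\n"


def _pair_tables(sweep_df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    tables = {}
    grids = set()
    for design, grp in sweep_df.groupby("design", sort=False):
        g = grp.sort_values("v").reset_index(drop=True)
        grids.add(tuple(g["v"]))
        tables[design] = g
    if len(grids) != 1:
        raise ValueError("designs were swept on different vulnerability grids")
    return tables


def compare_designs(
    sweep_df: pd.DataFrame, fits: Optional[pd.DataFrame] = None
) -> ComparisonReport:
    """Rank designs and check dominance / non-intersection of fitted lines.

    Dominance of X over Y requires X's risk to be at most Y's at *every*
    grid vulnerability within 3 pooled binomial standard errors, and
    strictly below at some point.  A fitted-line crossing is reported only
    when it is statistically resolvable at this sweep's trial counts: the
    two lines must separate by more than 3 pooled SEs with opposite signs
    at the two ends of the grid (statistically coincident lines do not
    count as crossing).
    """
    tables = _pair_tables(sweep_df)
    designs = list(tables)
    if fits is None:
        fits = fit_all(sweep_df)
    fit_by = {r.design: r for r in fits.itertuples()}

    dom = pd.DataFrame(False, index=designs, columns=designs)
    for x, y in itertools.permutations(designs, 2):
        rx, ry = tables[x]["risk"].to_numpy(), tables[y]["risk"].to_numpy()
        tol = 3.0 * np.hypot(tables[x]["se"].to_numpy(), tables[y]["se"].to_numpy())
        dom.loc[x, y] = bool(
            np.all(rx <= ry + tol) and np.any(rx < ry - tol)
        )

    crossings = []
    for x, y in itertools.combinations(designs, 2):
        fx, fy = fit_by[x], fit_by[y]
        v_lo, v_hi = tables[x]["v"].iloc[0], tables[x]["v"].iloc[-1]
        d_lo = (fx.intercept + fx.slope * v_lo) - (fy.intercept + fy.slope * v_lo)
        d_hi = (fx.intercept + fx.slope * v_hi) - (fy.intercept + fy.slope * v_hi)
        tol_lo = 3.0 * math.hypot(tables[x]["se"].iloc[0], tables[y]["se"].iloc[0])
        tol_hi = 3.0 * math.hypot(tables[x]["se"].iloc[-1], tables[y]["se"].iloc[-1])
        if d_lo * d_hi < 0 and abs(d_lo) > tol_lo and abs(d_hi) > tol_hi:
            vstar = (fy.intercept - fx.intercept) / (fx.slope - fy.slope)
            if 0.0 < vstar <= 1.0:
                crossings.append((x, y, float(vstar)))

    violations = []
    for safer, riskier in EXPECTED_ORDER:
        if safer not in tables or riskier not in tables:
            continue
        rs, rr = tables[safer]["risk"].to_numpy(), tables[riskier]["risk"].to_numpy()
        tol = 3.0 * np.hypot(
            tables[safer]["se"].to_numpy(), tables[riskier]["se"].to_numpy()
        )
        bad = rs > rr + tol
        if bad.any():
            vs = tables[safer]["v"].to_numpy()[bad]
            violations.append(
                f"{safer} exceeds {riskier} beyond 3 SE at v={vs.round(4).tolist()}"
            )

    ranking = sorted(designs, key=lambda d: tables[d]["risk"].mean())
    return ComparisonReport(ranking, dom, crossings, violations)


# ---------------------------------------------------------------------------
# Coupled-stream comparisons


def coupled_harms(
    designs: Sequence[str],
    trials: int,
    params: OperatorParams,
    targets: TargetSource,
    seed: int,
) -> dict[str, np.ndarray]:
    """Per-trial harm indicators with trial-level RNG coupling.

    Every design replays trial *i* from an identical RNG state (same
    target, same error and noticing draws), so per-trial differences are
    attributable to the designs alone.
    """
    for d in designs:
        check_design(d)
    cp = _Compiled(params)
    out = {d: np.zeros(trials, dtype=np.uint8) for d in designs}
    pressers = {d: presser_for(d) for d in designs}
    for i in range(trials):
        s = derive_seed(seed, "trial", i)
        for d in designs:
            rng = random.Random(s)
            canonical = targets.draw_canonical(rng)
            target = TargetNumber(canonical)
            stored, _ = _run_trial(pressers[d], d, canonical, target, cp, rng)
            if stored is None or (
                stored != canonical and value_of(stored) != target.value
            ):
                out[d][i] = 1
    return out


# ---------------------------------------------------------------------------
# Scaled-down linearity experiment with noise escalation


def linearity_experiment(
    seed: int,
    designs: Sequence[str] = DESIGN_IDS,
    v_grid: Sequence[float] = tuple(round(0.05 * i, 10) for i in range(1, 21)),
    base_trials: int = 10_000,
    escalated_trials: int = 100_000,
    r2_threshold: float = 0.9906,
    operator: Optional[ErrorModel] = None,
    targets: Optional[TargetSource] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Per-design risk/vulnerability linearity at desk scale.

    Sweeps every design at ``base_trials`` per grid point, then re-runs any
    design whose R-squared falls below ``r2_threshold`` at
    ``escalated_trials`` per point, where Monte Carlo noise no longer
    limits the fit for the low-risk designs.  Returns the final sweep
    table, the per-design fits, and the list of escalated designs.
    """
    operator = operator or ErrorModel()
    targets = targets or TargetDistribution()
    config = ExperimentConfig(
        designs=tuple(designs),
        v_grid=tuple(v_grid),
        trials_per_point=base_trials,
        operator=operator,
        targets=targets,
        seed=seed,
    )
    table = sweep(config)
    fits = fit_all(table)
    weak = fits.loc[fits["r_squared"] < r2_threshold, "design"].tolist()
    if weak:
        log.info("escalating %s to %d trials/point", weak, escalated_trials)
        big = replace(
            config, designs=tuple(weak), trials_per_point=escalated_trials
        )
        big_table = sweep(big)
        table = pd.concat(
            [table[~table["design"].isin(weak)], big_table], ignore_index=True
        )
        table["design"] = pd.Categorical(
            table["design"], categories=list(designs), ordered=True
        )
        table = table.sort_values(["design", "v"]).reset_index(drop=True)
        table["design"] = table["design"].astype(str)
        fits = fit_all(table)
    return table, fits, weak
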