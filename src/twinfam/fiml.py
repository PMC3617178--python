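"""Full-information maximum likelihood for nuclear twin family tables.

Each family contributes the multivariate-normal log-density of its observed
trait values under the model-implied joint moments for its configuration
(which members are present, their sexes, zygosity), with missing entries
marginalised out by row/column deletion — the raw-data (FIML) likelihood.
Families are grouped by (configuration, missingness pattern) so each
covariance factorisation is computed once per group; the result is
independent of the grouping.

Model comparison uses the likelihood-ratio chi-square for nested variants
and AIC (= -2lnL + 2k) across the non-nested mating models.  Boundary
effects at zero variance paths are ignored in the chi-square reference, as
is conventional for this design; the naive tail is mildly conservative for
variance components.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import LinAlgError, cholesky, solve_triangular
from scipy.stats import chi2 as _chi2

from .model import (
    EquilibriumState,
    FamilyConfiguration,
    InadmissibleParameterError,
    ModelError,
    NTFModel,
    family_moments,
    solve_equilibrium,
)

logger = logging.getLogger(__name__)

_LN2PI = float(np.log(2.0 * np.pi))
# graded penalty base for inadmissible points: large enough to dominate any
# plausible -2lnL, finite and mildly sloped so line searches can backtrack
_BIG = 1e9

TABLE_COLUMNS = ["family_id", "role", "sex", "zygosity", "age", "sample",
                 "trait1", "trait2"]

_ROLE_ORDER = {"father": 0, "mother": 1, "twin1": 2, "twin2": 3}


def _role_rank(role: str) -> tuple:
    return (_ROLE_ORDER.get(role, 4), role)


def read_family_table(path) -> pd.DataFrame:
    """Read a delimited family table (tab or comma separated, NA missing)."""
    df = pd.read_csv(path, sep=None, engine="python", na_values=["NA"])
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing - {"age", "sample"}:
        raise ModelError(f"family table lacks columns {sorted(missing)}")
    df["sex"] = df["sex"].astype(str).str.lower().str[0]
    df["zygosity"] = df["zygosity"].fillna("").astype(str).str.upper().replace(
        {"NONE": "", "NAN": ""})
    return df


def write_family_table(df: pd.DataFrame, path) -> None:
    cols = [c for c in TABLE_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", na_rep="NA", index=False, columns=cols)


class FamilyData:
    """Family table prepared for repeated likelihood evaluation.

    Families are keyed by configuration and observed-entry pattern; the
    trait values of each group are stacked into one matrix.  Families with
    no observed trait value at all are dropped (count logged).
    """

    def __init__(self, table: pd.DataFrame):
        self.groups: dict = {}
        self.n_families = 0
        self.n_dropped = 0
        sub = table[["family_id", "role", "sex", "zygosity",
                     "trait1", "trait2"]].copy()
        sub["zygosity"] = sub["zygosity"].fillna("").replace({"none": ""})
        for fam_id, fam in sub.groupby("family_id", sort=True):
            order = sorted(range(len(fam)),
                           key=lambda i: _role_rank(fam["role"].iat[i]))
            fam = fam.iloc[order]
            members = tuple((r, s) for r, s in zip(fam["role"], fam["sex"]))
            zyg = ""
            if {"twin1", "twin2"} <= set(fam["role"]):
                z = [z for z in fam["zygosity"] if z in ("MZ", "DZ")]
                zyg = z[0] if z else ""
            vals = fam[["trait1", "trait2"]].to_numpy(float).ravel()
            mask = tuple(~np.isnan(vals))
            if not any(mask):
                self.n_dropped += 1
                continue
            config = FamilyConfiguration(members=members, zygosity=zyg)
            key = (config, mask)
            self.groups.setdefault(key, []).append(vals[list(mask)])
            self.n_families += 1
        if self.n_dropped:
            logger.info("dropped %d families with no observed values",
                        self.n_dropped)
        if self.n_families == 0:
            raise ModelError("no families with observed data")
        self.groups = {key: np.vstack(rows) for key, rows in self.groups.items()}
        self.configs = sorted({cfg for cfg, _ in self.groups},
                              key=lambda c: (len(c.members), c.zygosity,
                                             str(c.members)))

    @property
    def n_observations(self) -> int:
        return int(sum(x.size for x in self.groups.values()))


def _as_data(data) -> FamilyData:
    return data if isinstance(data, FamilyData) else FamilyData(data)


def negloglik(model: NTFModel, data, eq: EquilibriumState | None = None) -> float:
    """-2 log likelihood of the family table under the model.

    Sum over families of ``k ln(2 pi) + ln|S| + (x-m)' S^-1 (x-m)`` where S
    and m are the family-configuration moments restricted to observed
    entries.  Raises :class:`InadmissibleParameterError` on a singular
    observed covariance (parameters outside the admissible region).
    """
    data = _as_data(data)
    if eq is None:
        eq = solve_equilibrium(model)
    moments: dict = {}
    total = 0.0
    for (config, mask), x in data.groups.items():
        if config not in moments:
            moments[config] = family_moments(model, eq, config,
                                             validate=False)
        mean, cov = moments[config]
        idx = np.flatnonzero(mask)
        sub = cov[np.ix_(idx, idx)]
        try:
            chol = cholesky(sub, lower=True)
        except LinAlgError as err:
            raise InadmissibleParameterError(
                f"singular observed covariance for {config}") from err
        resid = x - mean[idx]
        y = solve_triangular(chol, resid.T, lower=True)
        logdet = 2.0 * float(np.log(np.diag(chol)).sum())
        total += len(x) * (len(idx) * _LN2PI + logdet) + float((y * y).sum())
    return total


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Maximum-likelihood solution of one model variant."""

    estimates: NTFModel
    equilibrium: EquilibriumState
    minus2lnL: float
    k: int
    converged: bool
    n_evaluations: int
    best_of_starts: int
    start_values: list = field(default_factory=list, repr=False)

    @property
    def aic(self) -> float:
        return self.minus2lnL + 2.0 * self.k

    def to_dict(self) -> dict:
        est = {lbl: val for lbl, val in
               zip(self.estimates.free_labels(), self.estimates.get_free())}
        return {
            "mode": self.estimates.mode,
            "minus2lnL": self.minus2lnL,
            "k": self.k,
            "aic": self.aic,
            "converged": self.converged,
            "n_evaluations": self.n_evaluations,
            "best_of_starts": self.best_of_starts,
            "estimates": est,
            "q": self.equilibrium.q.tolist(),
        }


class FitError(RuntimeError):
    """All optimisation starts failed."""


def fit(model: NTFModel, data, n_starts: int = 5, seed: int = 0,
        jitter: float = 0.10, maxiter: int = 500, tol: float = 1e-9,
        eq_tol: float = 1e-12) -> FitResult:
    """Minimise the FIML -2lnL over the model's free parameters.

    Box constraints come from the parameter registry (nonnegative path
    diagonals, correlations in [-1, 1]).  Start 0 uses the model's stored
    values; further starts jitter them.  Inadmissible points (non-convergent
    or non-PSD equilibria) are treated as infinite cost, never clamped.
    """
    data = _as_data(data)
    work = model.copy()
    x0 = work.get_free()
    bounds = work.bounds()
    n_eval = [0]
    # work on the per-family deviance scale: O(1) gradients condition the
    # quasi-Newton steps far better than raw -2lnL
    scale = 1.0 / max(1, data.n_families)
    # quadratic penalty enforcing nonlinear constraints on the stationary
    # moments (e.g. zero q off-diagonal); stiff enough that the residual
    # violation perturbs -2lnL by far less than any reportable chi-square
    constrain_q = "q_offdiag_zero" in work.constraints
    penalty_w = 1e7

    def objective(x):
        n_eval[0] += 1
        work.set_free(x)
        # undamped iteration is ~2x faster where it converges; fall back to
        # the damped solve before declaring the point inadmissible
        try:
            try:
                eq = solve_equilibrium(work, tol=eq_tol, max_iter=2000,
                                       damping=1.0)
            except InadmissibleParameterError:
                eq = solve_equilibrium(work, tol=eq_tol, max_iter=2000)
            val = negloglik(work, data, eq)
            if constrain_q:
                val += penalty_w * eq.q[0, 1] ** 2
            return scale * val
        except (InadmissibleParameterError, ModelError, FloatingPointError):
            return scale * _BIG * (1.0 + 1e-3 * float(np.dot(x, x)))

    # forward-difference gradient with a single-point cache; scipy's own
    # bounded finite differences mis-step on this objective
    cache = {"x": None, "f": None}
    fd_step = 1e-6
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def cached_objective(x):
        if cache["x"] is not None and np.array_equal(x, cache["x"]):
            return cache["f"]
        f = objective(x)
        cache["x"], cache["f"] = x.copy(), f
        return f

    def gradient(x):
        f0 = cached_objective(x)
        g = np.empty(len(x))
        for i in range(len(x)):
            xp = x.copy()
            step = fd_step if x[i] + fd_step <= hi[i] else -fd_step
            xp[i] += step
            g[i] = (objective(xp) - f0) / step
        return g

    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(max(0, n_starts - 1)):
        xs = x0 + jitter * rng.standard_normal(len(x0))
        starts.append(np.clip(xs, lo + 1e-6, hi - 1e-6))

    best = None
    best_i = -1
    diagnostics = []
    n_stall_retries = 0
    i = 0
    while i < len(starts):
        res = optimize.minimize(
            cached_objective, starts[i], jac=gradient, method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-4})
        diagnostics.append((i, res.fun / scale, res.status, res.message))
        if res.fun / scale < _BIG and (best is None or res.fun < best.fun):
            best = res
            best_i = i
        # a line search that dies within a few iterations is a stall, not an
        # optimum: retry from a jittered start (at most twice)
        if res.nit <= 3 and i == len(starts) - 1 and n_stall_retries < 2 \
                and (best is None or best.nit <= 3):
            starts.append(np.clip(
                starts[i] + 0.05 * rng.standard_normal(len(x0)),
                lo + 1e-6, hi - 1e-6))
            n_stall_retries += 1
        i += 1
    if best is None:
        raise FitError(f"all {len(starts)} starts failed: {diagnostics}")
    work.set_free(best.x)
    eq = solve_equilibrium(work, tol=eq_tol)
    return FitResult(
        estimates=work.copy(),
        equilibrium=eq,
        minus2lnL=float(negloglik(work, data, eq)),
        k=work.n_free,
        converged=bool(best.success),
        n_evaluations=n_eval[0],
        best_of_starts=best_i,
        start_values=[float(f) for _, f, _, _ in diagnostics],
    )


# ---------------------------------------------------------------------------
# Tests and criteria
# ---------------------------------------------------------------------------

def chi2_sf(x: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution."""
    if x < 0:
        raise ValueError("chi-square statistic must be nonnegative")
    if df < 1 or int(df) != df:
        raise ValueError("df must be a positive integer")
    return float(_chi2.sf(x, df))


@dataclass
class TestResult:
    """Likelihood-ratio test between nested fits.

    ``retained`` flags whether the tested parameters are kept (the reduction
    significantly worsens fit at the configured threshold).
    """

    chi2: float
    df: int
    p: float
    retained: bool
    clamped: bool = False

    def to_dict(self) -> dict:
        return {"chi2": self.chi2, "df": self.df, "p": self.p,
                "retained": self.retained, "clamped": self.clamped}


def lrt(full: FitResult, reduced: FitResult,
        threshold: float = 0.10) -> TestResult:
    """Chi-square difference test of a reduced model against the full one."""
    df = full.k - reduced.k
    if df < 1:
        raise ModelError("reduced model must have fewer free parameters")
    stat = reduced.minus2lnL - full.minus2lnL
    clamped = False
    if stat < 0:
        # quasi-Newton optima are reproducible to ~1e-3 on the -2lnL scale;
        # tiny inversions are numerical, not evidence of non-nesting
        if stat > -1e-2:
            stat, clamped = 0.0, True
            logger.warning("negative chi2 within tolerance clamped to 0")
        else:
            raise ModelError(
                f"reduced model fits better by {-stat:.3g}; the full model "
                "is not at its optimum (non-nested inputs or unconverged)")
    p = chi2_sf(stat, df)
    return TestResult(chi2=float(stat), df=int(df), p=p,
                      retained=bool(p < threshold), clamped=clamped)


def aic(result, k: int | None = None) -> float:
    """Akaike information criterion, -2lnL + 2k (lower is better)."""
    if isinstance(result, FitResult):
        return result.aic
    if k is None:
        raise ValueError("pass a FitResult or (minus2lnL, k)")
    return float(result) + 2.0 * k


def submodel(model, drop=(), fix=None, equate=(), constraints=()) -> NTFModel:
    """Reduced variant of a (possibly fitted) model.

    ``drop`` zeroes whole matrices; ``fix`` pins single cells (e.g.
    ``{'r_S': 1.0}``); ``equate`` merges free cells into one parameter;
    ``constraints`` adds equilibrium-level constraints such as
    ``'q_offdiag_zero'``.  Current values are kept as start values.
    """
    if isinstance(model, FitResult):
        model = model.estimates
    out = model.copy()
    for name in drop:
        out.drop(name)
    for ref, val in (fix or {}).items():
        out.fix(ref, val)
    for grp in equate:
        out.equate(list(grp))
    for c in constraints:
        if c not in ("q_offdiag_zero",):
            raise ModelError(f"unknown constraint {c!r}")
        out.constraints.add(c)
    return out


def format_report(obj) -> str:
    """Key-value text rendering of a FitResult or TestResult."""
    d = obj.to_dict()
    buf = io.StringIO()
    for key, val in d.items():
        if isinstance(val, dict):
            for k2, v2 in val.items():
                buf.write(f"{key}.{k2}\t{v2:.6g}\n")
        else:
            buf.write(f"{key}\t{val}\n")
    return buf.getvalue()
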