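"""Bivariate nuclear twin family (NTF) structural model.

Two standardized traits (trait1 = IQ-like, trait2 = height-like) are modelled
per individual as sums of latent components, each entering through a 2x2
lower-triangular path matrix (a Cholesky factorisation of that component's
contribution):

    P = a_x A + b B (males) + d_x D + s_x S + t_x T + e_x E
        (+ F in the vertical-transmission variant, + c_x C under homogamy)

with A additive-genetic, B male-specific additive-genetic, D dominance,
S sibling environment, T twin environment, E unique environment, F the
environment transmitted from parental phenotypes, and C the family
environment that produces spousal similarity under social homogamy.

Assortative mating is modelled as primary phenotypic assortment via a 2x2
copath matrix ``mu`` linking husband and wife phenotypes.  The copath tracing
rule — for any X on the husband's side and Y on the wife's side,
cov(X, Y) = cov(X, P_h) mu cov(P_w, Y) — induces spousal covariance between
every pair of latent variables, and hence, through inheritance, an
equilibrium inflation of the additive-genetic covariance matrix ``q``
(gametic phase disequilibrium).  Under random mating q is the identity.

Conventions
-----------
* Trait order is fixed: index 0 = trait1 (IQ), index 1 = trait2 (height).
* ``mu`` rows index the husband's traits, columns the wife's traits, so
  mu[0, 1] is the (male IQ) x (female height) copath.  A single transpose
  switches the convention.
* Sexes are 'm' and 'f'.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import numpy as np

I2 = np.eye(2)
Z2 = np.zeros((2, 2))

MODES = ("ABDSTE", "ABDFTE", "ABDCTE")

#: matrices active in each model variant (beyond the shared core)
_CORE = ("a_m", "a_f", "b", "d_m", "d_f", "t_m", "t_f", "e_m", "e_f")
_MODE_MATRICES = {
    "ABDSTE": _CORE + ("s_m", "s_f", "mu"),
    "ABDFTE": _CORE + ("v_fs", "v_fd", "v_ms", "v_md", "mu"),
    "ABDCTE": _CORE + ("c_m", "c_f"),
}
_MODE_SCALARS = {
    "ABDSTE": ("r_D", "r_S", "r_T"),
    "ABDFTE": ("r_D", "r_T"),
    "ABDCTE": ("r_D", "r_T"),
}
#: matrices whose diagonal is sign-fixed at >= 0 (Cholesky identification);
#: vertical-transmission paths may legitimately be negative.
_NONNEG_DIAG = {"a_m", "a_f", "b", "d_m", "d_f", "s_m", "s_f",
                "t_m", "t_f", "e_m", "e_f", "c_m", "c_f"}

_DEFAULTS = {
    "a_m": np.array([[0.6, 0.0], [0.05, 0.6]]),
    "a_f": np.array([[0.6, 0.0], [0.05, 0.6]]),
    "b": np.array([[0.2, 0.0], [0.0, 0.2]]),
    "d_m": np.array([[0.4, 0.0], [0.0, 0.4]]),
    "d_f": np.array([[0.4, 0.0], [0.0, 0.4]]),
    "s_m": np.array([[0.3, 0.0], [0.0, 0.2]]),
    "s_f": np.array([[0.3, 0.0], [0.0, 0.2]]),
    "t_m": np.array([[0.2, 0.0], [0.0, 0.2]]),
    "t_f": np.array([[0.2, 0.0], [0.0, 0.2]]),
    "e_m": np.array([[0.5, 0.0], [0.0, 0.5]]),
    "e_f": np.array([[0.5, 0.0], [0.0, 0.5]]),
    "c_m": np.array([[0.3, 0.0], [0.0, 0.3]]),
    "c_f": np.array([[0.3, 0.0], [0.0, 0.3]]),
    "v_fs": np.array([[0.1, 0.0], [0.0, 0.1]]),
    "v_fd": np.array([[0.1, 0.0], [0.0, 0.1]]),
    "v_ms": np.array([[0.1, 0.0], [0.0, 0.1]]),
    "v_md": np.array([[0.1, 0.0], [0.0, 0.1]]),
    "mu": np.array([[0.1, 0.02], [0.02, 0.1]]),
}
_DEFAULT_SCALARS = {"r_D": 0.9, "r_S": 0.9, "r_T": 0.9}

_PATH_DIAG_BOUNDS = (0.0, 3.0)
_PATH_OFF_BOUNDS = (-3.0, 3.0)
_V_BOUNDS = (-2.0, 2.0)
_MU_BOUNDS = (-0.9, 0.9)
_R_BOUNDS = (-1.0, 1.0)
_MEAN_BOUNDS = (-3.0, 3.0)


class ModelError(ValueError):
    """Invalid model specification or edit."""


class InadmissibleParameterError(RuntimeError):
    """Parameters imply a non-PSD or non-convergent equilibrium."""


@dataclass
class Parameter:
    """One free cell of the model, with box bounds and an equality group."""

    target: str          # matrix name, scalar name, or 'mean_m'/'mean_f'
    index: tuple | None  # (i, j) for matrices, (i,) for means, None scalar
    lo: float
    hi: float
    group: int

    @property
    def label(self) -> str:
        if self.index is None:
            return self.target
        if len(self.index) == 1:
            return f"{self.target}[{self.index[0]}]"
        return f"{self.target}[{self.index[0]},{self.index[1]}]"


def parse_ref(ref: str):
    """Parse a cell reference like ``'a_m[1,0]'``, ``'mean_f[0]'`` or ``'r_S'``."""
    ref = ref.strip()
    if "[" not in ref:
        return ref, None
    name, rest = ref.split("[", 1)
    idx = tuple(int(t) for t in rest.rstrip("]").split(","))
    return name.strip(), idx


class NTFModel:
    """Full parameter set of one NTF variant plus its free-parameter registry.

    The registry maps a flat vector of free values (one per equality group)
    onto cells of the path matrices, copath matrix, cross-sex correlations
    and means; fixed cells keep their stored value.
    """

    def __init__(self, mode: str):
        if mode not in MODES:
            raise ModelError(f"unknown mode {mode!r}; expected one of {MODES}")
        self.mode = mode
        self.matrices: dict[str, np.ndarray] = {}
        for name in _MODE_MATRICES[mode]:
            self.matrices[name] = _DEFAULTS[name].copy()
        self.scalars: dict[str, float] = {
            name: _DEFAULT_SCALARS[name] for name in _MODE_SCALARS[mode]
        }
        self.means: dict[str, np.ndarray] = {"m": np.zeros(2), "f": np.zeros(2)}
        self.params: list[Parameter] = []
        self.constraints: set[str] = set()

    # -- registry ----------------------------------------------------------

    def _build_registry(self, free_means: bool) -> None:
        self.params = []
        g = 0
        for name, mat in self.matrices.items():
            if name == "mu":
                cells = [(0, 0), (0, 1), (1, 0), (1, 1)]
                lo, hi = _MU_BOUNDS
                for ij in cells:
                    self.params.append(Parameter("mu", ij, lo, hi, g))
                    g += 1
                continue
            for i, j in [(0, 0), (1, 0), (1, 1)]:
                if i == j and name in _NONNEG_DIAG:
                    lo, hi = _PATH_DIAG_BOUNDS
                elif name.startswith("v"):
                    lo, hi = _V_BOUNDS
                else:
                    lo, hi = _PATH_OFF_BOUNDS
                self.params.append(Parameter(name, (i, j), lo, hi, g))
                g += 1
        for name in self.scalars:
            self.params.append(Parameter(name, None, *_R_BOUNDS, g))
            g += 1
        if free_means:
            for sex in ("m", "f"):
                for i in (0, 1):
                    self.params.append(
                        Parameter(f"mean_{sex}", (i,), *_MEAN_BOUNDS, g))
                    g += 1

    @property
    def n_free(self) -> int:
        """Number of free parameters, counting each equality group once,
        minus one per binding equilibrium constraint."""
        groups = {p.group for p in self.params}
        return len(groups) - len(self.constraints)

    def _groups(self) -> list[int]:
        seen: list[int] = []
        for p in self.params:
            if p.group not in seen:
                seen.append(p.group)
        return seen

    def get_free(self) -> np.ndarray:
        out = []
        done = set()
        for p in self.params:
            if p.group in done:
                continue
            done.add(p.group)
            out.append(self._get_cell(p))
        return np.asarray(out, dtype=float)

    def set_free(self, vec: np.ndarray) -> None:
        vals = {g: v for g, v in zip(self._groups(), np.asarray(vec, float))}
        for p in self.params:
            self._set_cell(p, vals[p.group])

    def bounds(self) -> list[tuple[float, float]]:
        out = []
        done = set()
        for p in self.params:
            if p.group in done:
                continue
            done.add(p.group)
            out.append((p.lo, p.hi))
        return out

    def free_labels(self) -> list[str]:
        out = []
        done = set()
        for p in self.params:
            if p.group in done:
                continue
            done.add(p.group)
            out.append(p.label)
        return out

    def _get_cell(self, p: Parameter) -> float:
        if p.target.startswith("mean_"):
            return float(self.means[p.target[-1]][p.index[0]])
        if p.index is None:
            return float(self.scalars[p.target])
        return float(self.matrices[p.target][p.index])

    def _set_cell(self, p: Parameter, val: float) -> None:
        if p.target.startswith("mean_"):
            self.means[p.target[-1]][p.index[0]] = val
        elif p.index is None:
            self.scalars[p.target] = float(val)
        else:
            self.matrices[p.target][p.index] = val

    # -- edits -------------------------------------------------------------

    def drop(self, name: str) -> None:
        """Fix an entire matrix (or scalar) to zero and remove it from the
        free set — the 'all-or-none' matrix drop used in model reduction."""
        if name in self.matrices:
            self.matrices[name][:] = 0.0
        elif name in self.scalars:
            self.scalars[name] = 0.0
        else:
            raise ModelError(f"cannot drop unknown matrix {name!r}")
        self.params = [p for p in self.params if p.target != name]

    def fix(self, ref: str, value: float) -> None:
        name, idx = parse_ref(ref)
        if name.startswith("mean_"):
            self.means[name[-1]][idx[0]] = value
        elif name in self.scalars and idx is None:
            self.scalars[name] = value
        elif name in self.matrices:
            if idx is None:
                self.matrices[name][:] = value
            else:
                if idx[0] == idx[1] and name in _NONNEG_DIAG and value < 0:
                    raise ModelError(f"diagonal of {name} fixed negative")
                self.matrices[name][idx] = value
        else:
            raise ModelError(f"unknown parameter reference {ref!r}")
        if name in self.matrices and idx is None:
            self.params = [p for p in self.params if p.target != name]
        else:
            self.params = [p for p in self.params
                           if not (p.target == name and p.index == idx)]

    def equate(self, refs: list[str]) -> None:
        """Constrain a group of cells to share one free value."""
        keys = [parse_ref(r) for r in refs]
        groups = []
        for name, idx in keys:
            match = [p for p in self.params
                     if p.target == name and p.index == idx]
            if not match:
                raise ModelError(f"reference {name}{idx} is not free")
            groups.append(match[0].group)
        lead = groups[0]
        val = self._get_cell([p for p in self.params if p.group == lead][0])
        for p in self.params:
            if p.group in groups[1:]:
                p.group = lead
                self._set_cell(p, val)

    def copy(self) -> "NTFModel":
        return _copy.deepcopy(self)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"NTFModel(mode={self.mode}, k={self.n_free}, "
                f"constraints={sorted(self.constraints)})")


def build_model(mode: str, drop=(), fix=None, equate=(), free_means=True,
                constraints=()) -> NTFModel:
    """Construct a fully specified model variant.

    Parameters
    ----------
    mode : {'ABDSTE', 'ABDFTE', 'ABDCTE'}
        ABDSTE/ABDFTE are primary phenotypic assortment variants with sibling
        environment (S) or parental vertical transmission (F) respectively —
        the two are not jointly identified.  ABDCTE is the social-homogamy
        variant: spousal similarity arises from a family environment C shared
        by every member, and the copath matrix is inactive (zero).
    drop : iterable of matrix/scalar names fixed wholly to zero.
    fix : mapping of cell references (``'a_m[1,0]'``, ``'r_S'``) to values.
    equate : iterable of groups of cell references sharing one free value.
    constraints : e.g. ``('q_offdiag_zero',)`` — a nonlinear constraint on
        the parameters requiring the *stationary* q to have zero
        off-diagonal (no gametic phase disequilibrium between the traits).
        Enforced during fitting; each constraint reduces the free-parameter
        count by 1.  Imposing it as a fixed-point projection instead would
        leave the model free to reroute the genetic cross-covariance
        through the Cholesky cross paths, making the constraint vacuous.
    """
    model = NTFModel(mode)
    model._build_registry(free_means)
    requested = set(drop)
    if {"s_m", "s_f"} & set(model.matrices) and {"v_fs"} & requested:
        pass  # nothing: v not active in ABDSTE anyway
    for name in drop:
        if name not in model.matrices and name not in model.scalars:
            raise ModelError(f"cannot drop {name!r}: not active in {mode}")
        model.drop(name)
    active_s = any(np.any(model.matrices.get(n, Z2)) for n in ("s_m", "s_f"))
    active_v = any(np.any(model.matrices.get(n, Z2))
                   for n in ("v_fs", "v_fd", "v_ms", "v_md"))
    if active_s and active_v:
        raise ModelError("S and F (vertical transmission) are not jointly "
                         "identified; activate at most one")
    for ref, val in (fix or {}).items():
        model.fix(ref, val)
    for grp in equate:
        model.equate(list(grp))
    for c in constraints:
        if c not in ("q_offdiag_zero",):
            raise ModelError(f"unknown constraint {c!r}")
        model.constraints.add(c)
    return model


# ---------------------------------------------------------------------------
# Equilibrium
# ---------------------------------------------------------------------------

@dataclass
class EquilibriumState:
    """Stationary moments implied by a parameter set.

    ``q`` is the equilibrium additive-genetic covariance (identity under
    random mating), ``gamma`` the father-mother cross-covariance of latent
    additive values, ``q_b`` the analogue for the male-specific factor,
    ``f_var_*``/``w_*`` the vertical-transmission latent variance and its
    covariance with A per offspring sex, and ``vp_*`` the model-implied
    phenotypic covariance per sex.
    """

    q: np.ndarray
    gamma: np.ndarray
    q_b: np.ndarray
    f_var_m: np.ndarray
    f_var_f: np.ndarray
    w_m: np.ndarray
    w_f: np.ndarray
    vp_m: np.ndarray
    vp_f: np.ndarray
    converged: bool
    n_iter: int
    residual: float
    cache: dict = field(default_factory=dict, repr=False)


def _alpha(model: NTFModel, sex: str) -> np.ndarray:
    """Loading of the phenotype on the stacked latents (A, B, F); 2x6."""
    a = model.matrices[f"a_{sex}"]
    b = model.matrices["b"] if sex == "m" else Z2
    return np.hstack([a, b, I2])


def _u_var(model: NTFModel, sex: str) -> np.ndarray:
    """Variance of the non-transmissible phenotype residual (D,S,T,E,C)."""
    u = Z2.copy()
    for base in ("d", "s", "t", "e", "c"):
        name = f"{base}_{sex}"
        if name in model.matrices:
            m = model.matrices[name]
            u = u + m @ m.T
    return u


def _mu(model: NTFModel) -> np.ndarray:
    return model.matrices.get("mu", Z2)


def _m_map(model: NTFModel, sex: str) -> np.ndarray:
    """Linear map from parental (L_fa, u_fa, L_mo, u_mo) [16] to offspring
    latents (A, B, F) [6]; segregation noise handled separately."""
    M = np.zeros((6, 16))
    # A_o = 1/2 A_fa + 1/2 A_mo (+ xi)
    M[0:2, 0:2] = 0.5 * I2
    M[0:2, 8:10] = 0.5 * I2
    # B_o likewise
    M[2:4, 2:4] = 0.5 * I2
    M[2:4, 10:12] = 0.5 * I2
    # F_o = v_{father,sex} P_fa + v_{mother,sex} P_mo, P = alpha L + u
    tag = "s" if sex == "m" else "d"
    if f"v_f{tag}" in model.matrices:
        vf = model.matrices[f"v_f{tag}"]
        vm = model.matrices[f"v_m{tag}"]
        M[4:6, 0:6] = vf @ _alpha(model, "m")
        M[4:6, 6:8] = vf
        M[4:6, 8:14] = vm @ _alpha(model, "f")
        M[4:6, 14:16] = vm
    return M


def _sigma_z(omega_m, omega_f, u_m, u_f, c_m_lat, c_f_lat, mu):
    """Joint covariance of (L_fa, u_fa, L_mo, u_mo) for an equilibrium mated
    pair under the copath rule; 16x16."""
    S = np.zeros((16, 16))
    S[0:6, 0:6] = omega_m
    S[6:8, 6:8] = u_m
    S[8:14, 8:14] = omega_f
    S[14:16, 14:16] = u_f
    # cross-spousal blocks via the copath tracing rule
    S[0:6, 8:14] = c_m_lat @ mu @ c_f_lat.T
    S[0:6, 14:16] = c_m_lat @ mu @ u_f
    S[6:8, 8:14] = u_m @ mu @ c_f_lat.T
    S[6:8, 14:16] = u_m @ mu @ u_f
    S[8:16, 0:8] = S[0:8, 8:16].T
    return S


def _check_psd(mat: np.ndarray, what: str, tol: float = 1e-8) -> None:
    w = np.linalg.eigvalsh(0.5 * (mat + mat.T))
    if w.min() < -tol:
        raise InadmissibleParameterError(
            f"{what} lost positive semi-definiteness (min eigenvalue "
            f"{w.min():.3e}); parameters are outside the admissible region")


def solve_equilibrium(model: NTFModel, tol: float = 1e-12,
                      max_iter: int = 10000,
                      damping: float = 0.5) -> EquilibriumState:
    """Solve the stationarity fixed point of the mating/inheritance system.

    Starting from identity latent variances, iterate the one-generation
    moment recursion — spousal cross-moments from the copath rule, offspring
    latent moments from Mendelian averaging plus segregation variance 0.5 I
    and the vertical-transmission construction — with damping, until the
    latent covariance matrices are stationary.  Under random mating
    (mu = 0) the fixed point is exact after one step: q = I, gamma = 0.

    Raises
    ------
    InadmissibleParameterError
        If the iteration does not converge within ``max_iter`` (assortment
        too strong) or the equilibrium q/vp are not positive semi-definite.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    alpha_m, alpha_f = _alpha(model, "m"), _alpha(model, "f")
    u_m, u_f = _u_var(model, "m"), _u_var(model, "f")
    mu = _mu(model)
    seg = np.zeros((6, 6))
    seg[0:2, 0:2] = 0.5 * I2
    seg[2:4, 2:4] = 0.5 * I2
    omega0 = np.zeros((6, 6))
    omega0[0:4, 0:4] = np.eye(4)
    omega_m, omega_f = omega0.copy(), omega0.copy()
    Mm, Mf = _m_map(model, "m"), _m_map(model, "f")
    has_f = np.any(Mm[4:6]) or np.any(Mf[4:6])

    residual = np.inf
    converged = False
    n_iter = 0
    with np.errstate(over="ignore", invalid="ignore"):
        for n_iter in range(1, max_iter + 1):
            c_m_lat = omega_m @ alpha_m.T      # cov(L, P) per sex, 6x2
            c_f_lat = omega_f @ alpha_f.T
            Sz = _sigma_z(omega_m, omega_f, u_m, u_f, c_m_lat, c_f_lat, mu)
            new_m = Mm @ Sz @ Mm.T + seg
            new_f = (Mf @ Sz @ Mf.T + seg) if has_f else new_m
            residual = max(np.abs(new_m - omega_m).max(),
                           np.abs(new_f - omega_f).max())
            omega_m = (1 - damping) * omega_m + damping * new_m
            omega_f = (1 - damping) * omega_f + damping * new_f
            if residual < tol:
                converged = True
                break
            if not np.all(np.isfinite(omega_m)):
                raise InadmissibleParameterError(
                    "equilibrium iteration diverged (assortment too strong)")
    if not converged:
        raise InadmissibleParameterError(
            f"equilibrium not converged after {max_iter} iterations "
            f"(residual {residual:.2e}); assortment too strong or "
            "parameters inadmissible")

    c_m_lat = omega_m @ alpha_m.T
    c_f_lat = omega_f @ alpha_f.T
    vp_m = alpha_m @ c_m_lat + u_m
    vp_f = alpha_f @ c_f_lat + u_f
    gamma_lat = c_m_lat @ mu @ c_f_lat.T
    q = 0.5 * (omega_m[0:2, 0:2] + omega_m[0:2, 0:2].T)
    _check_psd(q, "equilibrium q")
    _check_psd(vp_m, "male phenotypic covariance")
    _check_psd(vp_f, "female phenotypic covariance")

    Sz = _sigma_z(omega_m, omega_f, u_m, u_f, c_m_lat, c_f_lat, mu)
    cache = {
        "alpha_m": alpha_m, "alpha_f": alpha_f,
        "u_m": u_m, "u_f": u_f, "mu": mu,
        "omega_m": omega_m, "omega_f": omega_f,
        "c_m_lat": c_m_lat, "c_f_lat": c_f_lat,
        "sigma_z": Sz, "M_m": Mm, "M_f": Mf,
    }
    return EquilibriumState(
        q=q,
        gamma=gamma_lat[0:2, 0:2],
        q_b=omega_m[2:4, 2:4].copy(),
        f_var_m=omega_m[4:6, 4:6].copy(),
        f_var_f=omega_f[4:6, 4:6].copy(),
        w_m=omega_m[0:2, 4:6].copy(),
        w_f=omega_f[0:2, 4:6].copy(),
        vp_m=0.5 * (vp_m + vp_m.T),
        vp_f=0.5 * (vp_f + vp_f.T),
        converged=True,
        n_iter=n_iter,
        residual=residual,
        cache=cache,
    )


# ---------------------------------------------------------------------------
# Pair covariances and family moments
# ---------------------------------------------------------------------------

RELATIONSHIPS = ("self", "spouse", "MZ", "DZ", "sib", "parent_offspring")


def _shared_c(model: NTFModel, sex1: str, sex2: str) -> np.ndarray:
    """Family-environment covariance shared by all members under homogamy."""
    if model.mode != "ABDCTE":
        return Z2
    c1 = model.matrices[f"c_{sex1}"]
    c2 = model.matrices[f"c_{sex2}"]
    return c1 @ c2.T


def _cross_r(model: NTFModel, which: str, sex1: str, sex2: str) -> float:
    if sex1 == sex2:
        return 1.0
    return float(model.scalars.get(which, 1.0))


def _sib_block(model, eq, sex1, sex2, twins: bool) -> np.ndarray:
    """Cross-covariance between two (non-MZ) full siblings; ``twins`` marks
    co-twins of the same pair, who additionally share T."""
    cache = eq.cache
    M1 = cache[f"M_{sex1}"]
    M2 = cache[f"M_{sex2}"]
    lam = M1 @ cache["sigma_z"] @ M2.T   # shared parents; independent xi
    block = cache[f"alpha_{sex1}"] @ lam @ cache[f"alpha_{sex2}"].T
    d1, d2 = model.matrices[f"d_{sex1}"], model.matrices[f"d_{sex2}"]
    block = block + 0.25 * _cross_r(model, "r_D", sex1, sex2) * (d1 @ d2.T)
    if "s_m" in model.matrices:
        s1, s2 = model.matrices[f"s_{sex1}"], model.matrices[f"s_{sex2}"]
        block = block + _cross_r(model, "r_S", sex1, sex2) * (s1 @ s2.T)
    if twins:
        t1, t2 = model.matrices[f"t_{sex1}"], model.matrices[f"t_{sex2}"]
        block = block + _cross_r(model, "r_T", sex1, sex2) * (t1 @ t2.T)
    return block + _shared_c(model, sex1, sex2)


def _parent_offspring_block(model, eq, parent_sex, offspring_sex):
    """cov(P_parent [rows], P_offspring [cols])."""
    cache = eq.cache
    vp_m, vp_f = eq.vp_m, eq.vp_f
    mu = cache["mu"]
    c_m_lat, c_f_lat = cache["c_m_lat"], cache["c_f_lat"]
    u_m, u_f = cache["u_m"], cache["u_f"]
    if parent_sex == "m":
        # cov(Z, P_fa): mother's side routed through the co-parent copath
        cov_z_p = np.vstack([
            c_m_lat,                      # cov(L_fa, P_fa)
            u_m,                          # cov(u_fa, P_fa)
            c_f_lat @ mu.T @ vp_m,        # cov(L_mo, P_fa)
            u_f @ mu.T @ vp_m,            # cov(u_mo, P_fa)
        ])
    else:
        cov_z_p = np.vstack([
            c_m_lat @ mu @ vp_f,
            u_m @ mu @ vp_f,
            c_f_lat,
            u_f,
        ])
    M_o = cache[f"M_{offspring_sex}"]
    alpha_o = cache[f"alpha_{offspring_sex}"]
    block_op = alpha_o @ (M_o @ cov_z_p)      # cov(P_off, P_parent)
    block_op = block_op + _shared_c(model, offspring_sex, parent_sex)
    return block_op.T


def pair_covariance(model: NTFModel, eq: EquilibriumState, relationship: str,
                    sex1: str, sex2: str) -> np.ndarray:
    """Model-implied 2x2 cross-covariance between two family members.

    Rows index individual 1's traits, columns individual 2's.  Relationships:
    ``self``; ``spouse`` (sexes must differ); ``MZ`` co-twins; ``DZ``
    co-twins of one pair (share twin environment); ``sib`` any other pair of
    full siblings (twin-sib or sib-sib; no shared T); ``parent_offspring``
    with sex1 the parent's sex.
    """
    if relationship not in RELATIONSHIPS:
        raise ModelError(f"unknown relationship {relationship!r}")
    if not eq.converged:
        raise ModelError("equilibrium not converged")
    memo = eq.cache.setdefault("_blocks", {})
    key = (relationship, sex1, sex2)
    if key in memo:
        return memo[key]
    block = _pair_covariance(model, eq, relationship, sex1, sex2)
    memo[key] = block
    return block


def _pair_covariance(model, eq, relationship, sex1, sex2):
    cache = eq.cache
    if relationship == "self":
        return eq.vp_m if sex1 == "m" else eq.vp_f
    if relationship == "spouse":
        if sex1 == sex2:
            raise ModelError("spouse pair requires opposite sexes")
        block = eq.vp_m @ cache["mu"] @ eq.vp_f + _shared_c(model, "m", "f")
        return block if sex1 == "m" else block.T
    if relationship == "MZ":
        if sex1 != sex2:
            raise ModelError("MZ co-twins have the same sex")
        x = sex1
        alpha = cache[f"alpha_{x}"]
        block = alpha @ cache[f"omega_{x}"] @ alpha.T
        for base in ("d", "s", "t"):
            name = f"{base}_{x}"
            if name in model.matrices:
                m = model.matrices[name]
                block = block + m @ m.T
        return block + _shared_c(model, x, x)
    if relationship == "DZ":
        return _sib_block(model, eq, sex1, sex2, twins=True)
    if relationship == "sib":
        return _sib_block(model, eq, sex1, sex2, twins=False)
    return _parent_offspring_block(model, eq, sex1, sex2)


PARENT_ROLES = ("father", "mother")


@dataclass(frozen=True)
class FamilyConfiguration:
    """Roles present in one family, their sexes, and the twin pair zygosity.

    ``members`` is an ordered tuple of (role, sex) pairs; roles are unique,
    drawn from father/mother/twin1/twin2/sib1/sib2/...; zygosity is 'MZ',
    'DZ' or '' when no complete twin pair is present.
    """

    members: tuple
    zygosity: str = ""

    def __post_init__(self):
        roles = [r for r, _ in self.members]
        if not roles:
            raise ModelError("family configuration needs at least one member")
        if len(set(roles)) != len(roles):
            raise ModelError(f"duplicate roles in configuration: {roles}")
        sexes = dict(self.members)
        if self.zygosity == "MZ" and {"twin1", "twin2"} <= set(roles):
            if sexes["twin1"] != sexes["twin2"]:
                raise ModelError("MZ co-twins must have the same sex")
        for r, s in self.members:
            if s not in ("m", "f"):
                raise ModelError(f"sex must be 'm' or 'f', got {s!r}")
            if r == "father" and s != "m" or r == "mother" and s != "f":
                raise ModelError(f"role {r} has inconsistent sex {s}")


def _relationship(role1: str, role2: str, zygosity: str):
    """Relationship label (and orientation) between two distinct roles."""
    p1, p2 = role1 in PARENT_ROLES, role2 in PARENT_ROLES
    if p1 and p2:
        return "spouse", False
    if p1 != p2:
        return "parent_offspring", not p1   # flip so sex1 is the parent
    both_twins = {role1, role2} == {"twin1", "twin2"}
    if both_twins:
        return ("MZ" if zygosity == "MZ" else "DZ"), False
    return "sib", False


def family_moments(model: NTFModel, eq: EquilibriumState,
                   config: FamilyConfiguration, validate: bool = True):
    """Joint mean vector and covariance matrix for one family configuration.

    Members are laid out in ``config.members`` order, two traits per member
    (trait-fastest), giving a 2m vector and 2m x 2m matrix assembled from
    ``pair_covariance`` blocks and the per-sex means model.
    """
    m = len(config.members)
    mean = np.zeros(2 * m)
    cov = np.zeros((2 * m, 2 * m))
    for i, (role_i, sex_i) in enumerate(config.members):
        mean[2 * i:2 * i + 2] = model.means[sex_i]
        cov[2 * i:2 * i + 2, 2 * i:2 * i + 2] = pair_covariance(
            model, eq, "self", sex_i, sex_i)
        for j in range(i + 1, m):
            role_j, sex_j = config.members[j]
            rel, flip = _relationship(role_i, role_j, config.zygosity)
            if flip:
                block = pair_covariance(model, eq, rel, sex_j, sex_i).T
            else:
                block = pair_covariance(model, eq, rel, sex_i, sex_j)
            cov[2 * i:2 * i + 2, 2 * j:2 * j + 2] = block
            cov[2 * j:2 * j + 2, 2 * i:2 * i + 2] = block.T
    if validate:
        _check_psd(cov, "family covariance matrix", tol=1e-7)
    return mean, cov


# ---------------------------------------------------------------------------
# Variance components
# ---------------------------------------------------------------------------

@dataclass
class ComponentReport:
    """Per-sex variance components and derived summaries.

    All component matrices are 2x2 on the trait scale.  ``inflation_*`` are
    percentage increases of additive-genetic (co)variances over the
    random-mating (q = I) counterfactual — the footprint of gametic phase
    disequilibrium.
    """

    components: dict            # sex -> {name -> 2x2}
    vp: dict                    # sex -> 2x2
    narrow_h2: dict             # sex -> (2,) V_A / V_P
    broad_h2: dict              # sex -> (2,) (V_A + V_D) / V_P
    r_A: dict                   # sex -> scalar additive genetic correlation
    inflation: dict             # sex -> {'trait1': %, 'trait2': %, 'cross': %}
    cov_shares: dict            # sex -> {name -> share of cross-trait cov}


def inflation_percent(observed: float, counterfactual: float) -> float:
    """Percentage by which an observed (co)variance exceeds its random-mating
    counterfactual: 100 (obs - cf) / cf."""
    if counterfactual == 0:
        return float("nan")
    return 100.0 * (observed - counterfactual) / counterfactual


def variance_components(model: NTFModel, eq: EquilibriumState) -> ComponentReport:
    """Decompose each sex's phenotypic (co)variance into model components."""
    components, vp, narrow, broad, r_a, infl, shares = {}, {}, {}, {}, {}, {}, {}
    for sex in ("m", "f"):
        a = model.matrices[f"a_{sex}"]
        comp: dict[str, np.ndarray] = {}
        va = a @ eq.q @ a.T
        if sex == "m":
            bmat = model.matrices["b"]
            va = va + bmat @ eq.q_b @ bmat.T
        comp["A"] = va
        for base, label in (("d", "D"), ("s", "S"), ("t", "T"),
                            ("e", "E"), ("c", "C")):
            name = f"{base}_{sex}"
            if name in model.matrices:
                mm = model.matrices[name]
                comp[label] = mm @ mm.T
        fv = eq.f_var_m if sex == "m" else eq.f_var_f
        w = eq.w_m if sex == "m" else eq.w_f
        if np.any(fv) or np.any(w):
            comp["F"] = fv
            comp["AF"] = a @ w + (a @ w).T   # A-F covariance contribution
        v_p = eq.vp_m if sex == "m" else eq.vp_f
        if not np.all(np.diag(v_p) > 0):
            raise InadmissibleParameterError("zero phenotypic variance")
        components[sex] = comp
        vp[sex] = v_p
        narrow[sex] = np.diag(va) / np.diag(v_p)
        broad[sex] = np.diag(va + comp.get("D", Z2)) / np.diag(v_p)
        denom = np.sqrt(va[0, 0] * va[1, 1])
        r_a[sex] = va[0, 1] / denom if denom > 0 else float("nan")
        # random-mating counterfactual: q (and q_b) replaced by identity
        va0 = a @ a.T
        if sex == "m":
            va0 = va0 + bmat @ bmat.T
        infl[sex] = {
            "trait1": inflation_percent(va[0, 0], va0[0, 0]),
            "trait2": inflation_percent(va[1, 1], va0[1, 1]),
            "cross": inflation_percent(va[0, 1], va0[0, 1]),
        }
        cross = v_p[0, 1]
        shares[sex] = {name: (mat[0, 1] / cross if cross != 0 else np.nan)
                       for name, mat in comp.items()}
    return ComponentReport(components=components, vp=vp, narrow_h2=narrow,
                           broad_h2=broad, r_A=r_a, inflation=infl,
                           cov_shares=shares)


def univariate_q_closed_form(a2: float, mu: float) -> float:
    """Closed-form equilibrium additive-genetic variance for one trait.

    With heritable path variance a^2 and copath mu, stationarity gives
    q = 1 + a^2 mu q^2, whose admissible (smaller) root is
    (1 - sqrt(1 - 4 a^2 mu)) / (2 a^2 mu); requires 4 a^2 mu < 1.
    """
    c = a2 * mu
    disc = 1.0 - 4.0 * c
    if disc < 0:
        raise InadmissibleParameterError(
            "no real equilibrium: assortment too strong (4 a^2 mu >= 1)")
    # rationalized root, stable as c -> 0
    return 2.0 / (1.0 + np.sqrt(disc))
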