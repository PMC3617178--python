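"""Generational simulator for nuclear twin family data.

The simulator is the brute-force counterpart of the analytic moments in
:mod:`twinfam.model`: it uses the *same* structural equations as update
rules — infinitesimal-model latent transmission (offspring additive value is
the parental midpoint plus segregation noise of variance 0.5 I), phenotype
construction through the path matrices, and phenotype-based mate matching
that reproduces the copath-implied spousal covariance — so simulated moments
must agree with the analytic ones up to Monte-Carlo error.

Mate matching is done by a Gaussian-copula coupling: husband and wife pools
are whitened, rotated to canonical coordinates, and paired by a bucketed
two-dimensional rank sort against simulated spouse scores, with a few
iterative refinements of the working cross-correlation until the achieved
spousal covariance hits the copath target ``vp_m @ mu @ vp_f``.  Under
social homogamy there is no phenotypic matching; spousal similarity arises
from a family environment C drawn at family formation and shared by every
member.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular

from .model import (
    NTFModel,
    build_model,
    solve_equilibrium,
    family_moments,
    FamilyConfiguration,
)

LATENT_COLS = [f"{c}{t}" for c in "ABDSTEFC" for t in (1, 2)]


class MatchingError(RuntimeError):
    """Requested spousal covariance structure is not attainable."""


# ---------------------------------------------------------------------------
# Truth parameter sets and family designs
# ---------------------------------------------------------------------------

def default_truth(sex_equal: bool = False, pleiotropy_only: bool = False,
                  assortment_only: bool = False) -> NTFModel:
    """Paper-patterned ABDSTE truth for the bundled synthetic fixture.

    Calibrated once against the analytic moments so that the implied
    relative correlations fall in the ranges reported for the combined
    height/IQ samples: MZ within-trait ~ .80-.89, DZ/sib ~ .35-.54, spousal
    .35 (trait1) / .20 (trait2), cross-trait spousal ~ .11-.18, and a
    within-person cross-trait correlation ~ .1-.2.  Structure mirrors the
    best-fitting reduced model: no twin-specific environment, no
    male-specific additive factor, cross-sex correlations at 1, sibling
    environment acting mostly on trait1.
    """
    truth = build_model(
        "ABDSTE",
        drop=("t_m", "t_f", "b"),
        fix={"r_D": 1.0, "r_S": 1.0, "r_T": 0.0},
        free_means=False,
    )
    truth.matrices["a_m"][:] = [[0.74, 0.00], [0.10, 0.76]]
    truth.matrices["a_f"][:] = [[0.76, 0.00], [0.14, 0.82]]
    truth.matrices["d_m"][:] = [[0.42, 0.00], [0.04, 0.44]]
    truth.matrices["d_f"][:] = [[0.36, 0.00], [0.00, 0.26]]
    truth.matrices["s_m"][:] = [[0.27, 0.00], [0.00, 0.05]]
    truth.matrices["s_f"][:] = [[0.32, 0.00], [0.00, 0.05]]
    truth.matrices["e_m"][:] = [[0.44, 0.00], [0.02, 0.40]]
    truth.matrices["e_f"][:] = [[0.40, 0.00], [0.00, 0.40]]
    # copath matrix solved once so the implied spousal correlations hit the
    # targets [[.35, .11], [.18, .20]] (husband traits in rows)
    truth.matrices["mu"][:] = [[0.283, 0.017], [0.087, 0.162]]
    if sex_equal:
        # harness variant without quantitative sex limitation: average the
        # two sexes' paths
        for base in ("a", "d", "s", "e"):
            mean = 0.5 * (truth.matrices[f"{base}_m"]
                          + truth.matrices[f"{base}_f"])
            truth.matrices[f"{base}_m"][:] = mean
            truth.matrices[f"{base}_f"][:] = mean
    if pleiotropy_only:
        # cross-trait genetic covariance from shared genes only.  Zeroing
        # the copath off-diagonals is not enough: within-trait assortment
        # acting on phenotypes that are cross-correlated (via pleiotropy)
        # still builds up cross-trait gametic phase disequilibrium.  Solve
        # for the common copath off-diagonal that cancels it, so the
        # stationary q is exactly diagonal.
        from scipy.optimize import brentq

        def q_offdiag(delta):
            truth.matrices["mu"][0, 1] = delta
            truth.matrices["mu"][1, 0] = delta
            return solve_equilibrium(truth).q[0, 1]

        delta_star = brentq(q_offdiag, -0.15, 0.05, xtol=1e-12)
        truth.matrices["mu"][0, 1] = delta_star
        truth.matrices["mu"][1, 0] = delta_star
    if assortment_only:
        # cross-trait genetic covariance from gametic phase disequilibrium
        # only: no pleiotropic cross paths
        for name in ("a_m", "a_f", "d_m", "d_f", "e_m", "e_f"):
            truth.matrices[name][1, 0] = 0.0
    return truth


def homogamy_truth(sex_equal: bool = False) -> NTFModel:
    """Social-homogamy (ABDCTE) counterpart of :func:`default_truth`:
    spousal similarity from a fully shared family environment C rather than
    phenotype-based mate choice; additive paths at the same magnitudes
    (no gametic-phase-disequilibrium inflation: q = I)."""
    truth = build_model(
        "ABDCTE",
        drop=("t_m", "t_f", "b"),
        fix={"r_D": 1.0, "r_T": 0.0},
        free_means=False,
    )
    truth.matrices["a_m"][:] = [[0.74, 0.00], [0.10, 0.76]]
    truth.matrices["a_f"][:] = [[0.76, 0.00], [0.14, 0.82]]
    truth.matrices["d_m"][:] = [[0.42, 0.00], [0.04, 0.44]]
    truth.matrices["d_f"][:] = [[0.36, 0.00], [0.00, 0.26]]
    truth.matrices["c_m"][:] = [[0.52, 0.00], [0.08, 0.42]]
    truth.matrices["c_f"][:] = [[0.54, 0.00], [0.10, 0.44]]
    truth.matrices["e_m"][:] = [[0.44, 0.00], [0.02, 0.40]]
    truth.matrices["e_f"][:] = [[0.40, 0.00], [0.00, 0.40]]
    if sex_equal:
        for base in ("a", "d", "c", "e"):
            mean = 0.5 * (truth.matrices[f"{base}_m"]
                          + truth.matrices[f"{base}_f"])
            truth.matrices[f"{base}_m"][:] = mean
            truth.matrices[f"{base}_f"][:] = mean
    return truth


def parent_rich_design(n_families: int = 800) -> list[FamilyTemplate]:
    """Design with parents present in every family (the configuration that
    carries most of the information separating mating models); used by the
    scaled-down selection-consistency studies."""
    share = n_families / 10
    return [
        FamilyTemplate("LTS", round(2 * share), "MZ", "mm", (), True),
        FamilyTemplate("LTS", round(2 * share), "MZ", "ff", (), True),
        FamilyTemplate("LTS", round(1.5 * share), "DZ", "mm", (), True),
        FamilyTemplate("LTS", round(1.5 * share), "DZ", "ff", (), True),
        FamilyTemplate("LTS", round(1.5 * share), "DZ", "mf", (), True),
        FamilyTemplate("LTS", round(1.5 * share), "DZ", "mf", ("m",), True),
    ]


@dataclass(frozen=True)
class FamilyTemplate:
    """One family layout replicated ``n`` times in a design."""

    sample: str
    n: int
    zygosity: str = ""          # 'MZ', 'DZ' or '' (no twin pair)
    twin_sexes: str = ""        # 'mm', 'ff', 'mf' or ''
    sib_sexes: tuple = ()       # sexes of non-twin siblings
    parents: bool = True

    def config(self) -> FamilyConfiguration:
        members = []
        if self.parents:
            members += [("father", "m"), ("mother", "f")]
        if self.twin_sexes:
            members += [("twin1", self.twin_sexes[0]),
                        ("twin2", self.twin_sexes[1])]
        members += [(f"sib{i + 1}", s) for i, s in enumerate(self.sib_sexes)]
        return FamilyConfiguration(members=tuple(members),
                                   zygosity=self.zygosity)


def _twin_sample(sample, parents, counts, sib_frac, scale):
    """Expand per-zygosity pair counts into templates, giving a fraction of
    families one extra non-twin sibling of alternating sex."""
    out = []
    sib_cycle = ("m", "f")
    for i, (zyg, sexes, n) in enumerate(counts):
        n = max(1, round(n * scale))
        n_sib = round(n * sib_frac)
        if n - n_sib > 0:
            out.append(FamilyTemplate(sample, n - n_sib, zyg, sexes, (),
                                      parents))
        if n_sib > 0:
            out.append(FamilyTemplate(sample, n_sib, zyg, sexes,
                                      (sib_cycle[i % 2],), parents))
    return out


def table2_design(scale: float = 1.0) -> list[FamilyTemplate]:
    """Four-sample family design patterned on the study's Table-1 layout:
    twins+sibs+parents (LTS-like), two twins+sibs samples without parental
    rows (CTS/QIMR-like), and a sibs+parents sample without twins
    (FAM-like).  ``scale`` shrinks every count proportionally."""
    design: list[FamilyTemplate] = []
    design += _twin_sample("LTS", True, [
        ("MZ", "mm", 102), ("MZ", "ff", 112), ("DZ", "mm", 91),
        ("DZ", "ff", 97), ("DZ", "mf", 75)], 0.40, scale)
    design += _twin_sample("CTS", False, [
        ("MZ", "mm", 205), ("MZ", "ff", 259), ("DZ", "mm", 180),
        ("DZ", "ff", 185), ("DZ", "mf", 176)], 0.40, scale)
    design += _twin_sample("QIMR", False, [
        ("MZ", "mm", 183), ("MZ", "ff", 201), ("DZ", "mm", 190),
        ("DZ", "ff", 210), ("DZ", "mf", 194)], 0.25, scale)
    for sexes, n in [(("m", "m"), 220), (("m", "f"), 130), (("f", "f"), 51)]:
        n = max(1, round(n * scale))
        design.append(FamilyTemplate("FAM", n, "", "", sexes, True))
    return design


#: per-sample raw scales patterned on the study's descriptive table:
#: (mean, sd) for trait1 (IQ-like, instrument-dependent scale) and trait2
#: (height-like, cm).
RAW_SCALES = {
    "LTS": ((102.0, 12.0), (171.0, 9.0)),
    "CTS": ((10.4, 2.4), (172.0, 9.0)),
    "QIMR": ((112.0, 12.6), (170.0, 8.5)),
    "FAM": ((10.7, 2.4), (169.0, 10.0)),
}

#: uniform age ranges per role class, in years
AGE_RANGES = {"twin": (12, 28), "sib": (10, 35), "parent": (29, 78)}


@dataclass
class SimConfig:
    """Complete stated world for one synthetic dataset.

    Defaults encode the fixture conditions: 15 generations of phenotypic
    assortment in a 20 000-pairs-per-generation population, the four-sample
    family design, sex/age/age^2 covariate effects on the raw scales, a
    small rate of gross (>4 SD) outliers, and 2% random item missingness.
    """

    truth: NTFModel = field(default_factory=default_truth)
    generations: int = 15
    n_pop: int = 20000
    design: list = field(default_factory=table2_design)
    #: per-trait covariate coefficients on the standardized scale
    sex_effect: tuple = (0.12, 1.55)       # male minus female shift
    age_effect: tuple = (0.012, 0.010)     # per year, centred at 25
    age2_effect: tuple = (-0.0006, -0.0009)
    outlier_rate: float = 0.0005
    missing_rate: float = 0.02
    seed: int = 0


# ---------------------------------------------------------------------------
# Mate matching
# ---------------------------------------------------------------------------

def _hier_order(x: np.ndarray) -> np.ndarray:
    """Bucketed 2-d sort: order by ~sqrt(n) quantile buckets of the first
    coordinate, then by the second coordinate within bucket."""
    n = len(x)
    nb = max(1, int(np.sqrt(n)))
    r0 = np.empty(n, dtype=np.int64)
    r0[np.argsort(x[:, 0], kind="stable")] = np.arange(n)
    bucket = r0 * nb // n
    return np.lexsort((x[:, 1], bucket))


def mate_match(p_males: np.ndarray, p_females: np.ndarray,
               target_cross: np.ndarray, rng: np.random.Generator,
               n_refine: int = 6) -> np.ndarray:
    """Pair males with females so the empirical spousal cross-covariance
    matches ``target_cross`` (husband traits in rows).

    Returns ``perm`` with female ``perm[i]`` mated to male ``i``.
    """
    n = len(p_males)
    sm = np.cov(p_males.T)
    sf = np.cov(p_females.T)
    lm = cholesky(sm, lower=True)
    lf = cholesky(sf, lower=True)
    zh = solve_triangular(lm, (p_males - p_males.mean(0)).T, lower=True).T
    zw = solve_triangular(lf, (p_females - p_females.mean(0)).T, lower=True).T
    k = solve_triangular(lm, target_cross, lower=True)
    k = solve_triangular(lf, k.T, lower=True).T
    u, lam, vt = np.linalg.svd(k)
    if lam.max() > 1.0 + 1e-9:
        raise MatchingError(
            "requested spousal structure not attainable: joint spousal "
            f"covariance not PSD (canonical correlation {lam.max():.3f} > 1)")
    lam = np.clip(lam, 0.0, 0.999)
    ch = zh @ u
    cw = zw @ vt.T
    target = np.diag(lam)
    g = target.copy()
    perm = np.arange(n)
    for _ in range(n_refine):
        resid = np.eye(2) - g @ g.T
        w_res, v_res = np.linalg.eigh(0.5 * (resid + resid.T))
        lr = v_res @ np.diag(np.sqrt(np.clip(w_res, 0.0, None)))
        t = ch @ g.T + rng.standard_normal((n, 2)) @ lr.T
        om = _hier_order(t)
        ow = _hier_order(cw)
        perm = np.empty(n, dtype=np.int64)
        perm[om] = ow
        emp = ch.T @ cw[perm] / n
        g = g + 0.6 * (target - emp).T
    return perm


# ---------------------------------------------------------------------------
# Equilibrium population
# ---------------------------------------------------------------------------

@dataclass
class Population:
    """Mated parental pairs at (approximate) equilibrium.

    ``males``/``females`` hold aligned latent arrays (row i of each sex is
    one mated pair): 'A', 'B', 'F' (n x 2 each) and the phenotype 'P'
    (which under homogamy excludes the family-environment term, assigned at
    family formation).  ``trajectory`` records the male latent additive
    covariance per generation.
    """

    model: NTFModel
    males: dict
    females: dict
    trajectory: list
    spousal_cov: np.ndarray


def _draw_phenotype(model: NTFModel, sex: str, lat: dict,
                    rng: np.random.Generator) -> np.ndarray:
    """Phenotype of unrelated pool individuals; D/S/T/E drawn i.i.d. here
    (sibship structure matters only within simulated families)."""
    n = len(lat["A"])
    a = model.matrices[f"a_{sex}"]
    p = lat["A"] @ a.T + lat["F"]
    if sex == "m":
        p = p + lat["B"] @ model.matrices["b"].T
    for base in ("d", "s", "t", "e"):
        name = f"{base}_{sex}"
        if name in model.matrices:
            p = p + rng.standard_normal((n, 2)) @ model.matrices[name].T
    return p


def simulate_equilibrium_population(truth: NTFModel, n: int, generations: int,
                                    seed: int) -> Population:
    """Iterate assortative mating and reproduction to a stationary pool.

    Each generation draws fresh non-transmissible latents, forms phenotypes,
    mate-matches to the copath-implied spousal covariance target (computed
    from the empirical phenotypic covariances of the current pools), and
    produces one son and one daughter per pair.  Under social homogamy
    (mode ABDCTE) mating is random and a single generation suffices.
    """
    if n < 2:
        raise ValueError("population size must be >= 2")
    rng = np.random.default_rng(seed)
    mu = truth.matrices.get("mu", np.zeros((2, 2)))
    assorting = truth.mode != "ABDCTE" and np.any(mu)
    has_f = any(np.any(truth.matrices.get(v, np.zeros((2, 2))))
                for v in ("v_fs", "v_fd", "v_ms", "v_md"))

    lat = {sex: {"A": rng.standard_normal((n, 2)),
                 "B": rng.standard_normal((n, 2)),
                 "F": np.zeros((n, 2))} for sex in ("m", "f")}
    trajectory = []
    pm = pf = None
    perm = np.arange(n)
    for gen in range(generations):
        pm = _draw_phenotype(truth, "m", lat["m"], rng)
        pf = _draw_phenotype(truth, "f", lat["f"], rng)
        trajectory.append(np.cov(lat["m"]["A"].T))
        if assorting:
            target = np.cov(pm.T) @ mu @ np.cov(pf.T)
            perm = mate_match(pm, pf, target, rng)
        else:
            perm = rng.permutation(n)
        if gen == generations - 1:
            break
        # reproduce: one son and one daughter per mated pair
        new = {}
        a_mid = 0.5 * (lat["m"]["A"] + lat["f"]["A"][perm])
        b_mid = 0.5 * (lat["m"]["B"] + lat["f"]["B"][perm])
        for sex in ("m", "f"):
            child = {
                "A": a_mid + np.sqrt(0.5) * rng.standard_normal((n, 2)),
                "B": b_mid + np.sqrt(0.5) * rng.standard_normal((n, 2)),
                "F": np.zeros((n, 2)),
            }
            if has_f:
                tag = "s" if sex == "m" else "d"
                vf = truth.matrices[f"v_f{tag}"]
                vm = truth.matrices[f"v_m{tag}"]
                child["F"] = pm @ vf.T + pf[perm] @ vm.T
            new[sex] = child
        lat = new
    females = {key: val[perm] for key, val in lat["f"].items()}
    females["P"] = pf[perm]
    males = dict(lat["m"])
    males["P"] = pm
    cross = (males["P"] - males["P"].mean(0)).T @ (
        females["P"] - females["P"].mean(0)) / n
    return Population(model=truth, males=males, females=females,
                      trajectory=trajectory, spousal_cov=cross)


# ---------------------------------------------------------------------------
# Family generation
# ---------------------------------------------------------------------------

def _cross_sex_pair(base: np.ndarray, r: float,
                    rng: np.random.Generator) -> tuple:
    """Male and female versions of a shared latent with cross-sex
    correlation r (per trait component)."""
    other = r * base + np.sqrt(max(0.0, 1.0 - r * r)) * \
        rng.standard_normal(base.shape)
    return base, other


def simulate_families(pop: Population, design: list[FamilyTemplate],
                      seed: int, keep_truth: bool = False):
    """Generate a FamilyTable (long format) from the mated parental pool.

    Families are sampled from the pool with replacement.  Within a family,
    offspring additive values are parental midpoints plus independent
    segregation noise (identical for MZ co-twins); dominance is shared at
    coefficient 1/4 between siblings (1 for MZ); sibling environment S and
    vertical transmission F are shared at coefficient 1; twin environment T
    is shared by co-twins only; E is individual.  Opposite-sex pairs share
    sex-specific versions of D/S/T correlated at r_D/r_S/r_T.

    Returns ``(table, truth_records)``; ``truth_records`` is None unless
    ``keep_truth`` — then it holds every latent score per individual.
    """
    model = pop.model
    if len(pop.males["A"]) == 0:
        raise ValueError("empty parent pool")
    rng = np.random.default_rng(seed)
    homogamy = model.mode == "ABDCTE"
    r_d = float(model.scalars.get("r_D", 1.0))
    r_s = float(model.scalars.get("r_S", 1.0))
    r_t = float(model.scalars.get("r_T", 1.0))
    # non-twin siblings carry the twin-environment variance unshared
    has_t = any(np.any(model.matrices.get(f"t_{s}", 0.0)) for s in "mf")
    n_pool = len(pop.males["A"])
    rows = []
    truth_rows = [] if keep_truth else None
    fam_id = 0

    for tmpl in design:
        nf = tmpl.n
        idx = rng.integers(0, n_pool, nf)
        fa = {key: val[idx] for key, val in pop.males.items()}
        mo = {key: val[idx] for key, val in pop.females.items()}
        c_fam = rng.standard_normal((nf, 2)) if homogamy else None
        a_mid = 0.5 * (fa["A"] + mo["A"])
        b_mid = 0.5 * (fa["B"] + mo["B"])
        d_base = rng.standard_normal((nf, 2))
        d_m_sh, d_f_sh = _cross_sex_pair(d_base, r_d, rng)
        s_sh = {}
        if "s_m" in model.matrices:
            s_base = rng.standard_normal((nf, 2))
            s_sh["m"], s_sh["f"] = _cross_sex_pair(s_base, r_s, rng)
        t_sh = {}
        if tmpl.twin_sexes:
            t_base = rng.standard_normal((nf, 2))
            t_sh["m"], t_sh["f"] = _cross_sex_pair(t_base, r_t, rng)

        children = []
        if tmpl.twin_sexes:
            children += [("twin1", tmpl.twin_sexes[0], True),
                         ("twin2", tmpl.twin_sexes[1], True)]
        children += [(f"sib{i + 1}", s, False)
                     for i, s in enumerate(tmpl.sib_sexes)]

        mz_shared = None
        fam_ids = np.arange(fam_id, fam_id + nf)
        fam_id += nf

        def emit(role, sex, lat, pheno):
            frame = {
                "family_id": fam_ids, "role": role, "sex": sex,
                "zygosity": tmpl.zygosity, "sample": tmpl.sample,
                "trait1": pheno[:, 0], "trait2": pheno[:, 1],
            }
            rows.append(pd.DataFrame(frame))
            if keep_truth:
                rec = {"family_id": fam_ids, "role": role}
                for comp in "ABDSTEFC":
                    arr = lat.get(comp, np.zeros((nf, 2)))
                    rec[f"{comp}1"], rec[f"{comp}2"] = arr[:, 0], arr[:, 1]
                truth_rows.append(pd.DataFrame(rec))

        if tmpl.parents:
            for sex, par in (("m", fa), ("f", mo)):
                pheno = par["P"].copy()
                lat = {"A": par["A"], "B": par["B"], "F": par["F"]}
                if homogamy:
                    c_x = model.matrices[f"c_{sex}"]
                    pheno = pheno + c_fam @ c_x.T
                    lat["C"] = c_fam
                emit("father" if sex == "m" else "mother", sex, lat, pheno)

        for role, sex, is_twin in children:
            is_mz = is_twin and tmpl.zygosity == "MZ"
            if is_mz and mz_shared is not None:
                shared = mz_shared
            else:
                shared = {
                    "xi_a": np.sqrt(0.5) * rng.standard_normal((nf, 2)),
                    "xi_b": np.sqrt(0.5) * rng.standard_normal((nf, 2)),
                    "d_ind": rng.standard_normal((nf, 2)),
                    "e": None,
                }
                if is_mz:
                    mz_shared = shared
            lat = {
                "A": a_mid + shared["xi_a"],
                "B": b_mid + shared["xi_b"],
                "D": 0.5 * (d_m_sh if sex == "m" else d_f_sh)
                + np.sqrt(0.75) * shared["d_ind"],
                "E": rng.standard_normal((nf, 2)),
                "F": np.zeros((nf, 2)),
            }
            if s_sh:
                lat["S"] = s_sh[sex]
            if is_twin and t_sh:
                lat["T"] = t_sh[sex]
            elif has_t:
                lat["T"] = rng.standard_normal((nf, 2))
            if homogamy:
                lat["C"] = c_fam
            tag = "s" if sex == "m" else "d"
            if f"v_f{tag}" in model.matrices:
                lat["F"] = (fa["P"] @ model.matrices[f"v_f{tag}"].T
                            + mo["P"] @ model.matrices[f"v_m{tag}"].T)
            pheno = lat["A"] @ model.matrices[f"a_{sex}"].T + lat["F"]
            if sex == "m":
                pheno = pheno + lat["B"] @ model.matrices["b"].T
            for base, comp in (("d", "D"), ("s", "S"), ("t", "T"),
                               ("e", "E"), ("c", "C")):
                name = f"{base}_{sex}"
                if name in model.matrices and comp in lat:
                    pheno = pheno + lat[comp] @ model.matrices[name].T
            emit(role, sex, lat, pheno)

    table = pd.concat(rows, ignore_index=True)
    table = table.sort_values(["family_id", "role"], kind="stable",
                              ignore_index=True)
    table["age"] = np.nan
    truth_df = None
    if keep_truth:
        truth_df = pd.concat(truth_rows, ignore_index=True).sort_values(
            ["family_id", "role"], kind="stable", ignore_index=True)
    return table, truth_df


# ---------------------------------------------------------------------------
# Observation model
# ---------------------------------------------------------------------------

def _role_class(role: str) -> str:
    if role in ("father", "mother"):
        return "parent"
    if role.startswith("twin"):
        return "twin"
    return "sib"


def apply_observation_model(table: pd.DataFrame, config: SimConfig,
                            seed: int,
                            outlier_counts: dict | None = None) -> pd.DataFrame:
    """Dress standardized traits up as raw scores.

    Adds uniform ages per role class, sex/age/age^2 effects, per-sample raw
    scales (IQ-like and cm-like), random item missingness, and gross
    outliers displaced at least 4 SD from the mean.  ``outlier_counts`` may
    pin exact counts per trait and sign, e.g. ``{"trait2": (8, 2)}`` for
    8 low and 2 high — otherwise ``config.outlier_rate`` applies.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    role_class = out["role"].map(_role_class)
    lo = role_class.map(lambda c: AGE_RANGES[c][0]).to_numpy(float)
    hi = role_class.map(lambda c: AGE_RANGES[c][1]).to_numpy(float)
    out["age"] = np.round(lo + (hi - lo) * rng.random(len(out)), 1)
    male = (out["sex"] == "m").to_numpy(float)
    age_c = out["age"].to_numpy(float) - 25.0
    for t, trait in enumerate(("trait1", "trait2")):
        z = out[trait].to_numpy(float)
        z = (z + config.sex_effect[t] * male
             + config.age_effect[t] * age_c
             + config.age2_effect[t] * age_c ** 2)
        raw = np.empty_like(z)
        for sample, scales in RAW_SCALES.items():
            mask = (out["sample"] == sample).to_numpy()
            mean, sd = scales[t]
            raw[mask] = mean + sd * z[mask]
        out[trait] = raw
    # gross outliers, guaranteed > 4 SD from the post-hoc mean
    for t, trait in enumerate(("trait1", "trait2")):
        vals = out[trait].to_numpy(float)
        if outlier_counts and trait in outlier_counts:
            n_low, n_high = outlier_counts[trait]
        else:
            n_out = rng.binomial(len(out), config.outlier_rate)
            n_low = rng.binomial(n_out, 0.5)
            n_high = n_out - n_low
        if n_low + n_high:
            pick = rng.choice(len(out), size=n_low + n_high, replace=False)
            for sample, scales in RAW_SCALES.items():
                mask = out["sample"].to_numpy() == sample
                mean, sd = scales[t]
                sign = np.where(np.arange(len(pick)) < n_low, -1.0, 1.0)
                offs = sd * (4.8 + 1.5 * rng.random(len(pick))) * sign
                sel = pick[mask[pick]]
                vals[sel] = mean + offs[mask[pick]]
            out[trait] = vals
    if config.missing_rate > 0:
        for trait in ("trait1", "trait2"):
            drop = rng.random(len(out)) < config.missing_rate
            out.loc[drop, trait] = np.nan
    return out


def generate_dataset(config: SimConfig, keep_truth: bool = False,
                     raw: bool = True):
    """End-to-end synthetic dataset: equilibrium pool -> families ->
    observation model.  Seeds are derived deterministically from
    ``config.seed``."""
    pop = simulate_equilibrium_population(
        config.truth, config.n_pop, config.generations, config.seed)
    table, truth = simulate_families(pop, config.design, config.seed + 1,
                                     keep_truth=keep_truth)
    if raw:
        table = apply_observation_model(table, config, config.seed + 2)
    return table, truth, pop


# ---------------------------------------------------------------------------
# Moment oracle harness
# ---------------------------------------------------------------------------

def moment_check(table: pd.DataFrame, model: NTFModel,
                 config: FamilyConfiguration, n_se: float = 4.0,
                 min_n: int = 10000) -> pd.DataFrame:
    """Compare empirical family moments against the analytic predictions.

    ``table`` must hold standardized traits (no observation model) for
    families all of configuration ``config``.  Returns one row per entry of
    the joint covariance matrix with the empirical value, analytic value,
    Monte-Carlo standard error and a pass flag at ``n_se`` standard errors.
    """
    eq = solve_equilibrium(model)
    mean, cov = family_moments(model, eq, config)
    wide = table.pivot(index="family_id", columns="role",
                       values=["trait1", "trait2"])
    roles = [r for r, _ in config.members]
    cols = []
    for role in roles:
        cols += [("trait1", role), ("trait2", role)]
    x = wide[cols].to_numpy(float)
    x = x[~np.isnan(x).any(axis=1)]
    n = len(x)
    if n < min_n:
        raise ValueError(f"need >= {min_n} complete families, got {n}")
    emp = np.cov(x.T)
    labels = [f"{role}:{t}" for role in roles for t in ("t1", "t2")]
    recs = []
    for i in range(len(labels)):
        for j in range(i, len(labels)):
            se = np.sqrt((emp[i, i] * emp[j, j] + emp[i, j] ** 2) / n)
            z = (emp[i, j] - cov[i, j]) / se
            recs.append({"entry": f"{labels[i]} x {labels[j]}",
                         "empirical": emp[i, j], "analytic": cov[i, j],
                         "mc_se": se, "z": z, "ok": abs(z) <= n_se})
    return pd.DataFrame(recs)
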