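"""The motility analysis ladder.

Comparisons of two T-cell populations are run at increasing levels of
statistical control:

1. pooled two-sample t-test on step observations;
2. Mann-Whitney U test (exact U distribution for small tie-free samples,
   Conover-Iman rank-transform route otherwise);
3. factorial ANOVA with population, dye and population x dye fixed effects,
   controlling the confounding effect of the labelling dyes;
4. mixed-model ANOVA adding a per-cell random intercept, so repeated steps of
   one cell no longer masquerade as independent observations;
5. fully nested ANOVA adding random intercepts for every experimental block
   (date, mouse, lymph node, field) above the cell.

Each parametric analysis has a rank-transformed variant giving the
nonparametric analogue.  Fixed effects use sum-to-zero coding, so a factor's
effects sum to zero and the reported per-level offsets match the signed
"effect size" convention; per-population estimates are population marginal
means (equal-weight average over dye levels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .io import UID_COLUMNS, HierarchyReport
from .lmm import LMMFit, NestedLMM

__all__ = [
    "ModelSpec",
    "FitResult",
    "TestResult",
    "LadderRow",
    "IdentifiabilityError",
    "MotilityANOVA",
    "rank_transform",
    "t_test",
    "mann_whitney",
    "fit_model",
    "analysis_ladder",
    "LADDER_LABELS",
]

logger = logging.getLogger(__name__)

#: canonical random-effect levels from top to bottom of the hierarchy
RANDOM_LEVELS = ("date", "mouse", "lymph_node", "field", "cell")
_RANDOM_UID = {
    "date": "uid_date",
    "mouse": "uid_mouse",
    "lymph_node": "uid_lymph_node",
    "field": "uid_field",
    "cell": "uid_track",
}
FIXED_TERMS = ("population", "dye", "interaction")


class IdentifiabilityError(ValueError):
    """The requested model is not identifiable on the given data."""


@dataclass(frozen=True)
class ModelSpec:
    """Which analysis of the ladder to run."""

    response: str = "speed"
    unit: str = "step"
    fixed: tuple = FIXED_TERMS
    random_chain: tuple = ()
    rank_transform: bool = False
    drop_aliased: bool = True
    df_method: str = "satterthwaite"

    def __post_init__(self):
        unknown = set(self.fixed) - set(FIXED_TERMS)
        if unknown:
            raise ValueError(f"unknown fixed terms: {sorted(unknown)}")
        order = [RANDOM_LEVELS.index(r) for r in self.random_chain]
        if sorted(order) != order or len(set(order)) != len(order):
            raise ValueError(
                f"random_chain must follow the nesting order {RANDOM_LEVELS}"
            )
        if "cell" in self.random_chain and self.unit != "step":
            raise ValueError("a cell random effect requires step-level data")


@dataclass
class TestResult:
    """Two-group test outcome."""

    group_estimates: dict
    p_value: float
    statistic: float
    method: str
    flags: list = field(default_factory=list)


@dataclass
class FitResult:
    """Fitted model summary in response units."""

    grand_mean: float
    population_effects: dict
    dye_effects: dict
    interaction_effects: dict
    variance_components: dict
    population_estimates: dict
    p_population: float
    df_method: str
    df_population: float
    n_obs: int
    n_cells: int
    p_dye: float | None = None
    p_interaction: float | None = None
    rank_transform: bool = False
    dropped_terms: list = field(default_factory=list)
    dropped_random: list = field(default_factory=list)
    boundary: dict = field(default_factory=dict)
    method: str = "ols"


@dataclass
class LadderRow:
    label: str
    result: object = None
    skipped: bool = False
    reason: str | None = None


# ---------------------------------------------------------------------------
# elementary operations


def rank_transform(values) -> np.ndarray:
    """Average ranks 1..n of the non-missing values; NaN stays NaN."""
    v = np.asarray(values, float)
    out = np.full(v.shape, np.nan)
    m = ~np.isnan(v)
    if not m.any():
        raise ValueError("all values missing")
    out[m] = sps.rankdata(v[m], method="average")
    return out


def t_test(group1, group2, labels=("group1", "group2")) -> TestResult:
    """Pooled-variance two-sample t-test; estimates are group means."""
    g1 = np.asarray(group1, float)
    g2 = np.asarray(group2, float)
    g1, g2 = g1[~np.isnan(g1)], g2[~np.isnan(g2)]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 observations")
    flags = []
    if np.ptp(g1) == 0 and np.ptp(g2) == 0:
        if g1[0] == g2[0]:
            flags.append("degenerate: both groups constant and equal")
            stat, p = 0.0, 1.0
        else:
            flags.append("degenerate: zero within-group variance")
            stat, p = np.inf if g1.mean() > g2.mean() else -np.inf, 0.0
    else:
        stat, p = sps.ttest_ind(g1, g2, equal_var=True)
    return TestResult(
        group_estimates={labels[0]: float(g1.mean()), labels[1]: float(g2.mean())},
        p_value=float(p), statistic=float(stat), method="t-test", flags=flags,
    )


def _rank_route_p(g1, g2):
    """Conover-Iman: pooled t-test on the jointly ranked data."""
    ranks = rank_transform(np.concatenate([g1, g2]))
    r1, r2 = ranks[: len(g1)], ranks[len(g1):]
    if np.ptp(ranks) == 0:
        return 1.0
    stat, p = sps.ttest_ind(r1, r2, equal_var=True)
    return float(p)


def mann_whitney(group1, group2, labels=("group1", "group2"),
                 small_n: int = 25) -> TestResult:
    """Mann-Whitney U test; estimates are group medians.

    Small tie-free samples get the exact U-distribution p-value; larger or
    tied samples use the Conover-Iman rank-transform route, whose p-value
    agrees with the tie-corrected normal approximation for moderate n.
    """
    g1 = np.asarray(group1, float)
    g2 = np.asarray(group2, float)
    g1, g2 = g1[~np.isnan(g1)], g2[~np.isnan(g2)]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([g1, g2])
    has_ties = len(np.unique(pooled)) < len(pooled)
    u1 = float(sps.mannwhitneyu(g1, g2, alternative="two-sided",
                                method="asymptotic").statistic)
    if not has_ties and max(len(g1), len(g2)) <= small_n:
        p = float(sps.mannwhitneyu(g1, g2, alternative="two-sided",
                                   method="exact").pvalue)
        method = "Mann-Whitney U (exact)"
    else:
        p = _rank_route_p(g1, g2)
        method = "Mann-Whitney U (rank-transform route)"
    return TestResult(
        group_estimates={labels[0]: float(np.median(g1)),
                         labels[1]: float(np.median(g2))},
        p_value=p, statistic=u1, method=method,
    )


# ---------------------------------------------------------------------------
# design-matrix construction (sum-to-zero coding)


def _sum_code(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """n x (L-1) sum-to-zero contrast columns; last level codes as -1."""
    C = np.zeros((len(codes), n_levels - 1))
    for k in range(n_levels - 1):
        C[codes == k, k] = 1.0
    C[codes == n_levels - 1, :] = -1.0
    return C


def _expand_main(coefs: np.ndarray, levels) -> dict:
    eff = np.append(coefs, -coefs.sum())
    return {lev: float(e) for lev, e in zip(levels, eff)}


def _expand_interaction(coefs: np.ndarray, plevels, dlevels) -> dict:
    Lp, Ld = len(plevels), len(dlevels)
    M = np.zeros((Lp, Ld))
    M[: Lp - 1, : Ld - 1] = coefs.reshape(Lp - 1, Ld - 1)
    M[Lp - 1, : Ld - 1] = -M[: Lp - 1, : Ld - 1].sum(axis=0)
    M[:, Ld - 1] = -M[:, : Ld - 1].sum(axis=1)
    return {(p, d): float(M[i, j]) for i, p in enumerate(plevels)
            for j, d in enumerate(dlevels)}


# ---------------------------------------------------------------------------
# the estimator


class MotilityANOVA(BaseEstimator):
    """Sum-to-zero factorial / mixed / nested ANOVA of a motility response.

    Parameters
    ----------
    response : column of the step or cell table to analyse ("speed"/"angle").
    fixed : subset of ("population", "dye", "interaction").
    random_effects : ordered subset of ("date", "mouse", "lymph_node",
        "field", "cell"); empty for ordinary least squares.
    rank : fit on pooled average ranks and back-map estimates to response
        units through the inverse empirical quantile function.
    df_method : "satterthwaite" (default) or "residual" denominator df for
        the population test in mixed models.
    drop_aliased : drop random levels perfectly confounded with their child
        level before fitting (logged).

    After ``fit`` the estimates are available both as fitted attributes
    (``population_estimates_``, ``p_population_``, ...) and bundled in
    ``result_`` (a :class:`FitResult`).
    """

    def __init__(self, response="speed", fixed=FIXED_TERMS, random_effects=(),
                 rank=False, df_method="satterthwaite", drop_aliased=True):
        self.response = response
        self.fixed = fixed
        self.random_effects = random_effects
        self.rank = rank
        self.df_method = df_method
        self.drop_aliased = drop_aliased

    # -- helpers -------------------------------------------------------------

    def _aliased(self, df: pd.DataFrame) -> list:
        counts = {lev: df[_RANDOM_UID[lev]].nunique() for lev in RANDOM_LEVELS}
        out = []
        for parent, child in zip(RANDOM_LEVELS[:-1], RANDOM_LEVELS[1:]):
            if counts[parent] == counts[child]:
                out.append(parent)
        return out

    def fit(self, X: pd.DataFrame, y=None):
        if self.df_method not in ("satterthwaite", "residual"):
            raise ValueError(f"unknown df method {self.df_method!r}")
        df = X.loc[X[self.response].notna()].reset_index(drop=True)
        if not len(df):
            raise ValueError(f"no non-missing values of {self.response!r}")
        y_raw = df[self.response].to_numpy(float)

        if self.rank:
            y_fit = rank_transform(y_raw)
            order = np.argsort(y_raw, kind="mergesort")
            self._qmap_x = np.sort(y_fit)
            self._qmap_v = y_raw[order]
        else:
            y_fit = y_raw
            self._qmap_x = self._qmap_v = None

        pop_levels = sorted(df["population"].unique())
        if len(pop_levels) < 2:
            raise IdentifiabilityError("comparison requires two populations")
        dye_levels = sorted(df["dye"].unique())

        fixed = list(self.fixed)
        dropped_terms = []
        if len(dye_levels) < 2:
            for term in ("dye", "interaction"):
                if term in fixed:
                    fixed.remove(term)
                    dropped_terms.append(term)
            if dropped_terms:
                logger.info("single dye level %r: dropped terms %s",
                            dye_levels[0], dropped_terms)
        if "interaction" in fixed and "dye" not in fixed:
            raise ValueError("interaction requires the dye main effect")

        pcodes = pd.Categorical(df["population"], categories=pop_levels).codes
        cols = [np.ones((len(df), 1))]
        slices = {"intercept": slice(0, 1)}
        off = 1
        Cp = _sum_code(pcodes, len(pop_levels))
        cols.append(Cp)
        slices["population"] = slice(off, off + Cp.shape[1])
        off += Cp.shape[1]
        if "dye" in fixed:
            dcodes = pd.Categorical(df["dye"], categories=dye_levels).codes
            Cd = _sum_code(dcodes, len(dye_levels))
            cols.append(Cd)
            slices["dye"] = slice(off, off + Cd.shape[1])
            off += Cd.shape[1]
            if "interaction" in fixed:
                inter = np.einsum("ni,nj->nij", Cp, Cd).reshape(len(df), -1)
                cols.append(inter)
                slices["interaction"] = slice(off, off + inter.shape[1])
                off += inter.shape[1]
        Xmat = np.hstack(cols)
        if np.linalg.matrix_rank(Xmat) < Xmat.shape[1]:
            raise IdentifiabilityError(
                "fixed-effects design is rank deficient (e.g. a dye observed "
                "in only one population makes the interaction unidentifiable)"
            )

        chain = list(self.random_effects)
        dropped_random = []
        if chain:
            aliased = set(self._aliased(df))
            for lev in list(chain):
                n_groups = df[_RANDOM_UID[lev]].nunique()
                if self.drop_aliased and lev in aliased and lev != "cell":
                    chain.remove(lev)
                    dropped_random.append(lev)
                    logger.info(
                        "random level %r is aliased with its child level; "
                        "dropped from the nesting chain", lev)
                elif n_groups < 2:
                    chain.remove(lev)
                    dropped_random.append(lev)
                    logger.info("random level %r has a single group; dropped", lev)

        if chain:
            groups = [
                (lev, pd.factorize(df[_RANDOM_UID[lev]])[0]) for lev in chain
            ]
            model = NestedLMM(Xmat, groups, y_fit)
            lfit = model.fit()
            beta, cov = lfit.beta, lfit.cov_beta
            sigma2 = lfit.sigma2
            vc = dict(lfit.variance_components)
            method = "reml"
        else:
            model, lfit = None, None
            beta, *_ = np.linalg.lstsq(Xmat, y_fit, rcond=None)
            resid = y_fit - Xmat @ beta
            dof = len(df) - Xmat.shape[1]
            sigma2 = float(resid @ resid / dof)
            cov = sigma2 * np.linalg.inv(Xmat.T @ Xmat)
            vc = {}
            method = "ols"
        vc["residual"] = float(sigma2)

        def term_p(term):
            if term not in slices:
                return None, None
            sl = slices[term]
            k = sl.stop - sl.start
            if k == 1:
                c = np.zeros(Xmat.shape[1])
                c[sl.start] = 1.0
                se = float(np.sqrt(max(c @ cov @ c, 0.0)))
                if se == 0.0:  # zero-noise degenerate data
                    dof = len(df) - Xmat.shape[1]
                    return (1.0 if beta[sl.start] == 0.0 else 0.0), float(dof)
                tstat = float(beta[sl.start] / se)
                if method == "reml" and self.df_method == "satterthwaite":
                    dof = model.satterthwaite_df(lfit, c)
                else:
                    dof = len(df) - Xmat.shape[1]
                return 2.0 * float(sps.t.sf(abs(tstat), dof)), float(dof)
            # multi-level factor: Wald F with residual denominator df
            b = beta[sl]
            Vb = cov[sl, sl]
            F = float(b @ np.linalg.solve(Vb, b) / k)
            dof = len(df) - Xmat.shape[1]
            return float(sps.f.sf(F, k, dof)), float(dof)

        p_pop, df_pop = term_p("population")
        p_dye, _ = term_p("dye")
        p_int, _ = term_p("interaction")

        mu = float(beta[0])
        alpha = _expand_main(beta[slices["population"]], pop_levels)
        betas = (_expand_main(beta[slices["dye"]], dye_levels)
                 if "dye" in slices else {})
        inter = (_expand_interaction(beta[slices["interaction"]],
                                     pop_levels, dye_levels)
                 if "interaction" in slices else {})

        qmap = self._backmap
        pop_est = {p: qmap(mu + alpha[p]) for p in pop_levels}
        if self.rank:
            grand = qmap(mu)
            alpha_r = {p: qmap(mu + alpha[p]) - grand for p in pop_levels}
            betas_r = {d: qmap(mu + betas[d]) - grand for d in betas}
            inter_r = {
                (p, d): qmap(mu + alpha[p] + betas[d] + inter[(p, d)])
                - qmap(mu + alpha[p] + betas[d])
                for (p, d) in inter
            }
        else:
            grand, alpha_r, betas_r, inter_r = mu, alpha, betas, inter

        self.model_ = model
        self.lmm_fit_ = lfit
        self.term_slices_ = slices
        self.df_residual_ = len(df) - Xmat.shape[1]
        self.coef_ = beta
        self.cov_coef_ = cov
        self.population_levels_ = pop_levels
        self.dye_levels_ = dye_levels
        self.result_ = FitResult(
            grand_mean=grand,
            population_effects=alpha_r,
            dye_effects=betas_r,
            interaction_effects=inter_r,
            variance_components=vc,
            population_estimates=pop_est,
            p_population=p_pop,
            df_method=(self.df_method if method == "reml" else "residual"),
            df_population=df_pop,
            n_obs=len(df),
            n_cells=int(df["uid_track"].nunique()) if "uid_track" in df else len(df),
            p_dye=p_dye,
            p_interaction=p_int,
            rank_transform=self.rank,
            dropped_terms=dropped_terms,
            dropped_random=dropped_random,
            boundary=(dict(lfit.boundary) if lfit is not None else {}),
            method=method,
        )
        for name in ("grand_mean", "population_effects", "dye_effects",
                     "interaction_effects", "variance_components",
                     "population_estimates", "p_population"):
            setattr(self, name + "_", getattr(self.result_, name))
        return self

    def _backmap(self, value: float) -> float:
        if self._qmap_x is None:
            return float(value)
        return float(np.interp(value, self._qmap_x, self._qmap_v))


def fit_model(table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit one analysis of the ladder described by ``spec``."""
    est = MotilityANOVA(
        response=spec.response, fixed=spec.fixed,
        random_effects=spec.random_chain, rank=spec.rank_transform,
        df_method=spec.df_method, drop_aliased=spec.drop_aliased,
    )
    est.fit(table)
    return est.result_


# ---------------------------------------------------------------------------
# the ladder

LADDER_LABELS = (
    "t-test",
    "Mann-Whitney U test",
    "Factorial ANOVA",
    "Factorial ANOVA, rank-transformed data",
    "Mixed model ANOVA controlling for cell IDs",
    "Mixed model ANOVA, rank-transformed data",
    "Nested ANOVA controlling for all experimental blocks",
    "Nested ANOVA, rank-transformed data",
)

_NESTED_CHAIN = ("date", "mouse", "lymph_node", "field", "cell")


def analysis_ladder(steps: pd.DataFrame, hierarchy: HierarchyReport | None = None,
                    response: str = "speed",
                    df_method: str = "satterthwaite",
                    drop_aliased: bool = True) -> list[LadderRow]:
    """Run all eight analyses of the ladder on a step table.

    Returns one :class:`LadderRow` per analysis; rows that cannot run on the
    given data (e.g. a single population) are marked skipped with a reason.
    """
    work = steps.loc[steps[response].notna()]
    pops = sorted(work["population"].unique()) if len(work) else []
    rows: list[LadderRow] = []

    if len(pops) != 2:
        reason = (f"comparison requires two populations, found {len(pops)}")
        return [LadderRow(lab, skipped=True, reason=reason)
                for lab in LADDER_LABELS]

    g1 = work.loc[work["population"] == pops[0], response].to_numpy(float)
    g2 = work.loc[work["population"] == pops[1], response].to_numpy(float)

    def add(label, fn):
        try:
            rows.append(LadderRow(label, result=fn()))
        except (IdentifiabilityError, ValueError) as err:
            rows.append(LadderRow(label, skipped=True, reason=str(err)))

    add(LADDER_LABELS[0], lambda: t_test(g1, g2, labels=tuple(pops)))
    add(LADDER_LABELS[1], lambda: mann_whitney(g1, g2, labels=tuple(pops)))

    model_rows = (
        (LADDER_LABELS[2], (), False),
        (LADDER_LABELS[3], (), True),
        (LADDER_LABELS[4], ("cell",), False),
        (LADDER_LABELS[5], ("cell",), True),
        (LADDER_LABELS[6], _NESTED_CHAIN, False),
        (LADDER_LABELS[7], _NESTED_CHAIN, True),
    )
    for label, chain, rank in model_rows:
        spec = ModelSpec(response=response, random_chain=chain,
                         rank_transform=rank, drop_aliased=drop_aliased,
                         df_method=df_method)
        add(label, lambda spec=spec: fit_model(steps, spec))
    return rows
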