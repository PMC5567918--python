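"""Dyadic response table and multimodel inference on association predictors.

Builds one Bernoulli observation per dyad per calendar day at sea together
(associated / not associated), fits the candidate set of binomial GLMMs with
crossed random effects (bird identities nested within dyad), ranks them by
AICc, forms the 0.95 cumulative-weight confidence set, and produces
model-averaged coefficients with unconditional standard errors and relative
variable importance.  Also provides the Gaussian mixed-model colony
comparison of per-trip association counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._laplace import GlmmControl, LaplaceFit, fit_laplace_glmm
from .io_formats import condition_index, haversine_m

TERM_LOGT = "logT"
TERM_SEX = "sexPair"
TERM_NEST = "nestDist"
TERM_COND = "dCond"
TERM_INTERACTION = "logT:sexPair"
MAIN_TERMS = (TERM_LOGT, TERM_SEX, TERM_NEST, TERM_COND)

DAY_SECONDS = 86400

DYAD_COLUMNS = ["bird_a", "bird_b", "day", "associated",
                "log_dt_depart", "sex_pair", "nest_dist", "d_condition"]


@dataclass(frozen=True)
class ModelSpec:
    """A candidate fixed-effect structure (terms beyond the intercept)."""

    terms: frozenset = frozenset()

    def __post_init__(self):
        unknown = self.terms - {*MAIN_TERMS, TERM_INTERACTION}
        if unknown:
            raise ValueError(f"unknown terms {sorted(unknown)}")
        if TERM_INTERACTION in self.terms and not (
            TERM_LOGT in self.terms and TERM_SEX in self.terms
        ):
            raise ValueError("interaction requires both logT and sexPair")

    def formula(self) -> str:
        if not self.terms:
            return "1"
        order = [*MAIN_TERMS, TERM_INTERACTION]
        return " + ".join(t for t in order if t in self.terms)


@dataclass
class FitResult:
    """Per-model likelihood summary plus coefficient estimates."""

    spec: ModelSpec
    beta: pd.Series
    se: pd.Series
    sigma_dyad: float
    sigma_bird: float
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool


def build_dyad_table(
    trips: pd.DataFrame,
    events: pd.DataFrame,
    deployments: pd.DataFrame,
    log_offset: float = 1.0,
    unit: str = "dyad_day",
) -> pd.DataFrame:
    """One response row per unordered pair per calendar day at sea together.

    A (pair, day) row exists when the two birds have trips that overlap each
    other and the day; ``associated`` is 1 iff any association event of the
    pair intersects that day.  Predictors: ln(departure gap in minutes +
    ``log_offset``), same/different sex pairing, nest distance (m, from nest
    coordinates) and |delta BCI| (g/mm).

    ``unit="dyad"`` collapses days to one row per pair (association on any
    shared day; mean of the daily departure-gap covariate).
    """
    known = set(deployments["bird_id"])
    in_events = set(events["bird_a"]) | set(events["bird_b"]) if len(events) else set()
    orphans = in_events - known
    if orphans:
        raise ValueError(f"birds in events but not deployments: {sorted(orphans)}")

    dep = deployments.set_index("bird_id")
    bci = condition_index(dep["mass"].to_numpy(), dep["flipper"].to_numpy())
    bci = pd.Series(bci, index=dep.index)

    rows = []
    birds = sorted(trips["bird_id"].unique())
    trips_by_bird = {b: trips[trips["bird_id"] == b] for b in birds}
    for a, b in itertools.combinations(birds, 2):
        pair_events = events[
            (events["bird_a"] == min(a, b)) & (events["bird_b"] == max(a, b))
        ] if len(events) else events
        for _, ta in trips_by_bird[a].iterrows():
            for _, tb in trips_by_bird[b].iterrows():
                lo = max(ta["t_start"], tb["t_start"])
                hi = min(ta["t_end"], tb["t_end"])
                if lo > hi:
                    continue
                for day in range(int(lo // DAY_SECONDS), int(hi // DAY_SECONDS) + 1):
                    d0, d1 = day * DAY_SECONDS, (day + 1) * DAY_SECONDS
                    if min(hi, d1 - 1) < max(lo, d0):
                        continue
                    assoc = 0
                    if len(pair_events):
                        assoc = int(((pair_events["t_start"] < d1) &
                                     (pair_events["t_end"] >= d0)).any())
                    gap_min = abs(ta["departure_time"] - tb["departure_time"]) / 60.0
                    rows.append({
                        "bird_a": min(a, b), "bird_b": max(a, b), "day": day,
                        "associated": assoc,
                        "gap_minutes": gap_min,
                        "log_dt_depart": float(np.log(gap_min + log_offset)),
                        "sex_pair": ("same" if dep.loc[a, "sex"] == dep.loc[b, "sex"]
                                     else "different"),
                        "nest_dist": haversine_m(
                            dep.loc[a, "nest_lat"], dep.loc[a, "nest_lon"],
                            dep.loc[b, "nest_lat"], dep.loc[b, "nest_lon"]),
                        "d_condition": abs(float(bci[a] - bci[b])),
                    })
    table = pd.DataFrame(rows)
    if len(table):
        table = table.drop_duplicates(subset=["bird_a", "bird_b", "day"])
    if unit == "dyad" and len(table):
        table = (
            table.groupby(["bird_a", "bird_b"], as_index=False)
            .agg(associated=("associated", "max"),
                 gap_minutes=("gap_minutes", "mean"),
                 sex_pair=("sex_pair", "first"),
                 nest_dist=("nest_dist", "first"),
                 d_condition=("d_condition", "first"))
        )
        table["log_dt_depart"] = np.log(table["gap_minutes"] + log_offset)
        table["day"] = -1
    elif unit != "dyad_day":
        raise ValueError(f"unknown observation unit {unit!r}")
    return table.reset_index(drop=True)


def enumerate_models() -> list[ModelSpec]:
    """All marginality-respecting subsets of the candidate terms (20 specs)."""
    specs = []
    for r in range(len(MAIN_TERMS) + 1):
        for combo in itertools.combinations(MAIN_TERMS, r):
            specs.append(ModelSpec(frozenset(combo)))
            if TERM_LOGT in combo and TERM_SEX in combo:
                specs.append(ModelSpec(frozenset(combo) | {TERM_INTERACTION}))
    return specs


def design_matrix(table: pd.DataFrame, spec: ModelSpec):
    """Fixed-effect design for a spec; returns (X, column names).

    Sex pairing is coded as an indicator for a same-sex pair.
    """
    cols = {"(Intercept)": np.ones(len(table))}
    same = (table["sex_pair"] == "same").to_numpy(dtype=float)
    if TERM_LOGT in spec.terms:
        cols[TERM_LOGT] = table["log_dt_depart"].to_numpy(dtype=float)
    if TERM_SEX in spec.terms:
        cols[TERM_SEX] = same
    if TERM_NEST in spec.terms:
        cols[TERM_NEST] = table["nest_dist"].to_numpy(dtype=float)
    if TERM_COND in spec.terms:
        cols[TERM_COND] = table["d_condition"].to_numpy(dtype=float)
    if TERM_INTERACTION in spec.terms:
        cols[TERM_INTERACTION] = cols[TERM_LOGT] * same
    names = list(cols)
    return np.column_stack([cols[c] for c in names]), names


def _index_groups(table: pd.DataFrame):
    pair_key = list(zip(table["bird_a"], table["bird_b"]))
    dyads = {p: i for i, p in enumerate(sorted(set(pair_key)))}
    birds = sorted(set(table["bird_a"]) | set(table["bird_b"]))
    bird_ix = {b: i for i, b in enumerate(birds)}
    dyad_idx = np.array([dyads[p] for p in pair_key])
    a_idx = np.array([bird_ix[a] for a in table["bird_a"]])
    b_idx = np.array([bird_ix[b] for b in table["bird_b"]])
    return dyad_idx, a_idx, b_idx


def fit_glmm(
    table: pd.DataFrame,
    spec: ModelSpec,
    control: GlmmControl | None = None,
) -> FitResult:
    """Fit one candidate logit GLMM by Laplace-approximate ML.

    k counts fixed effects plus the two variance components.
    """
    X, names = design_matrix(table, spec)
    y = table["associated"].to_numpy(dtype=float)
    dyad_idx, a_idx, b_idx = _index_groups(table)
    fit = fit_laplace_glmm(y, X, dyad_idx, a_idx, b_idx, control=control)
    k = X.shape[1] + 2
    n = len(table)
    return FitResult(
        spec=spec,
        beta=pd.Series(fit.beta, index=names),
        se=pd.Series(fit.se, index=names),
        sigma_dyad=fit.sigma_dyad,
        sigma_bird=fit.sigma_bird,
        loglik=fit.loglik,
        k=k,
        n=n,
        aicc=aicc(fit.loglik, k, n),
        converged=fit.converged,
    )


def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 logL + 2k + 2k(k+1)/(n - k - 1); requires n > k + 1."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """exp(-delta/2), normalised to sum to one."""
    a = np.asarray(aicc_values, dtype=float)
    if len(a) == 0 or not np.isfinite(a).any():
        raise ValueError("need at least one finite AICc value")
    delta = a - np.nanmin(a)
    w = np.exp(-0.5 * delta)
    w[~np.isfinite(w)] = 0.0
    return w / w.sum()


def rank_models(
    table: pd.DataFrame,
    specs: list[ModelSpec] | None = None,
    control: GlmmControl | None = None,
) -> tuple[list[FitResult], pd.DataFrame]:
    """Fit and AICc-rank the candidate set; non-converged fits are excluded.

    Returns the converged fits sorted by AICc and a summary table with the
    usual columns (formula, df, logLik, AICc, delta, weight).
    """
    specs = specs if specs is not None else enumerate_models()
    fits = [fit_glmm(table, s, control) for s in specs]
    ok = [f for f in fits if f.converged]
    ok.sort(key=lambda f: f.aicc)
    w = akaike_weights([f.aicc for f in ok])
    summary = pd.DataFrame(
        {
            "model": [f.spec.formula() for f in ok],
            "df": [f.k for f in ok],
            "logLik": [f.loglik for f in ok],
            "AICc": [f.aicc for f in ok],
            "dAICc": [f.aicc - ok[0].aicc for f in ok],
            "weight": w,
        }
    )
    return ok, summary


def confidence_set(weights, threshold: float = 0.95) -> int:
    """Size of the smallest AICc-ordered prefix with cumulative weight >=
    ``threshold``.  ``weights`` must be sorted by ascending AICc."""
    w = np.asarray(weights, dtype=float)
    if len(w) == 0:
        return 0
    cum = np.cumsum(w)
    return int(np.searchsorted(cum, threshold - 1e-12) + 1)


def model_average(
    fits: list[FitResult], weights, threshold: float = 0.95,
    mode: str = "conditional",
) -> pd.DataFrame:
    """Model-averaged coefficients over the confidence set.

    Fits must be AICc-sorted with matching ``weights``.  Weights are
    renormalised within the confidence set.  Conditional (subset) averaging
    averages each term over the models that contain it; ``mode="full"``
    substitutes zero in models lacking the term.  The unconditional SE is
    sum_i w_i * sqrt(se_i^2 + (beta_i - beta_bar)^2).
    """
    if not fits:
        raise ValueError("no fits to average")
    m = confidence_set(weights, threshold)
    sel = fits[:m]
    w = np.asarray(weights[:m], dtype=float)
    w = w / w.sum()
    terms: list[str] = []
    for f in sel:
        for name in f.beta.index:
            if name not in terms:
                terms.append(name)
    rows = []
    for term in terms:
        has = np.array([term in f.beta.index for f in sel])
        betas = np.array([f.beta.get(term, 0.0) for f in sel])
        ses = np.array([f.se.get(term, 0.0) for f in sel])
        if mode == "conditional":
            wt = w[has] / w[has].sum()
            bb, ss = betas[has], ses[has]
        elif mode == "full":
            wt, bb, ss = w, betas, ses
        else:
            raise ValueError(f"unknown averaging mode {mode!r}")
        beta_bar = float(wt @ bb)
        se_u = float(wt @ np.sqrt(ss**2 + (bb - beta_bar) ** 2))
        z = abs(beta_bar) / se_u if se_u > 0 else np.inf
        rows.append({
            "term": term,
            "estimate": beta_bar,
            "unconditional_se": se_u,
            "z": z,
            "p": 2.0 * stats.norm.sf(z),
            "ci_lower": beta_bar - 1.96 * se_u,
            "ci_upper": beta_bar + 1.96 * se_u,
            "importance": float(w[has].sum()),
            "n_models": int(has.sum()),
        })
    return pd.DataFrame(rows)


def predict_probability(
    averaged: pd.DataFrame, dt_depart_minutes, log_offset: float = 1.0,
) -> pd.DataFrame:
    """Predicted association probability vs departure-time gap, with 95% band.

    Uses the averaged intercept and logT coefficient; the band propagates
    the unconditional SEs on the linear-predictor scale (covariances between
    averaged terms are not available and are taken as zero).
    """
    dt = np.asarray(dt_depart_minutes, dtype=float)
    if (dt < 0).any():
        raise ValueError("departure gaps must be non-negative")
    av = averaged.set_index("term")
    b0 = float(av.loc["(Intercept)", "estimate"])
    b1 = float(av.loc[TERM_LOGT, "estimate"])
    s0 = float(av.loc["(Intercept)", "unconditional_se"])
    s1 = float(av.loc[TERM_LOGT, "unconditional_se"])
    x = np.log(dt + log_offset)
    lin = b0 + b1 * x
    sd = np.sqrt(s0**2 + (x * s1) ** 2)
    expit = lambda v: 1.0 / (1.0 + np.exp(-v))
    return pd.DataFrame({
        "dt_minutes": dt,
        "probability": expit(lin),
        "ci_lower": expit(lin - 1.96 * sd),
        "ci_upper": expit(lin + 1.96 * sd),
    })


def fit_lmm_colony(per_trip_counts: pd.DataFrame):
    """Gaussian LMM of per-trip association counts on colony.

    ``per_trip_counts`` needs columns ``n_partners``, ``colony_id`` and
    ``bird_id``; the model has a colony fixed effect and a bird random
    intercept (fitted by ML through statsmodels, exact for the Gaussian
    case).  Returns (contrast, se, F, p) where the contrast is the mean
    effect of the lexicographically second colony relative to the first and
    F is the 1-numerator-df Wald statistic.
    """
    colonies = sorted(per_trip_counts["colony_id"].unique())
    if len(colonies) < 2:
        raise ValueError("colony comparison needs two colonies")
    if len(colonies) > 2:
        raise ValueError("two-category predictor expected")
    import statsmodels.api as sm

    df = per_trip_counts.copy()
    df["is_second"] = (df["colony_id"] == colonies[1]).astype(float)
    exog = sm.add_constant(df[["is_second"]])
    model = sm.MixedLM(df["n_partners"].astype(float), exog, groups=df["bird_id"])
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=False)
        contrast = float(res.params["is_second"])
        se = float(res.bse["is_second"])
    except Exception:
        # fall back to OLS when the random-intercept variance hits zero
        res = sm.OLS(df["n_partners"].astype(float), exog).fit()
        contrast = float(res.params["is_second"])
        se = float(res.bse["is_second"])
    F = (contrast / se) ** 2
    p = float(stats.chi2.sf(F, 1))
    return contrast, se, float(F), p
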