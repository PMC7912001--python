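"""Behavioural-test data model and the statistical comparison layer.

Latency-based tests (tonic immobility, open-field, emergence) are
censored at the 300-s test maximum; censored values enter the models
as 300 s.  Responses are transformed as the protocol dictates (log10
for latencies, square root for counts and feather scores, logit for
fractions) and compared with restricted-maximum-likelihood linear
mixed models: rearing treatment, ranging and their interaction as
fixed effects, birds nested within pen and pen nested within the
treatment combinations as random effects.  Nonsignificant interactions
are removed and the model refitted.  Post-hoc pairwise t-tests on
least-squares means carry a Bonferroni correction only when there are
more than 3 comparisons.  Alpha is 0.05 throughout.

The mixed-model engine is statsmodels' MixedLM; this stage is glue by
design, the package's contribution being the data model around it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import patsy
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

ALPHA = 0.05
CENSOR_S = 300.0
TESTS = ("TI", "OFT_move", "OFT_vocalise", "OFT_step", "ET_step_out", "ET_emerge")
TRANSFORMS = ("log10", "sqrt", "logit", "none")


# ---------------------------------------------------------------- censoring

def censor_latency(raw_s: float, max_s: float = CENSOR_S) -> tuple[float, bool]:
    """Clip a raw latency at the test maximum; flag censoring."""
    if raw_s < 0:
        raise ValueError(f"negative latency {raw_s}")
    return (max_s, True) if raw_s >= max_s else (float(raw_s), False)


def censor_latencies(raw_s, max_s: float = CENSOR_S) -> pd.DataFrame:
    """Vectorised censoring: columns ``latency_s, censored``."""
    arr = np.asarray(raw_s, dtype=float)
    if (arr < 0).any():
        bad = int(np.flatnonzero(arr < 0)[0])
        raise ValueError(f"negative latency at position {bad}")
    return pd.DataFrame(
        {"latency_s": np.minimum(arr, max_s), "censored": arr >= max_s}
    )


def ti_induction(attempt_durations, min_hold_s: float = 10.0,
                 max_attempts: int = 5) -> tuple[int, float]:
    """Resolve a tonic-immobility induction sequence.

    Attempts proceed until the bird stays immobile for at least
    ``min_hold_s`` or ``max_attempts`` is reached; the recorded
    duration is that of the final attempt.  Returns
    ``(attempts_used, duration_s)``.
    """
    durations = list(attempt_durations)
    if not durations:
        raise ValueError("at least one attempt required")
    for i, d in enumerate(durations[:max_attempts], start=1):
        if d >= min_hold_s:
            return i, float(d)
    n = min(len(durations), max_attempts)
    return n, float(durations[n - 1])


# -------------------------------------------------------------- transforms

def transform(values, kind: str, offset: float = 0.0) -> np.ndarray:
    """Elementwise response transformation.

    ``offset`` is added before log10 (the documented handling of zero
    latencies).  Out-of-domain values abort, naming the offending row.
    """
    if kind not in TRANSFORMS:
        raise ValueError(f"unknown transform {kind!r}; choose from {TRANSFORMS}")
    arr = np.asarray(values, dtype=float)
    if kind == "none":
        return arr
    if kind == "log10":
        shifted = arr + offset
        if (shifted <= 0).any():
            bad = int(np.flatnonzero(shifted <= 0)[0])
            raise ValueError(
                f"log10 undefined for value {arr[bad]} (+offset {offset}) at row {bad}"
            )
        return np.log10(shifted)
    if kind == "sqrt":
        if (arr < 0).any():
            bad = int(np.flatnonzero(arr < 0)[0])
            raise ValueError(f"sqrt undefined for value {arr[bad]} at row {bad}")
        return np.sqrt(arr)
    # logit
    if ((arr <= 0) | (arr >= 1)).any():
        bad = int(np.flatnonzero((arr <= 0) | (arr >= 1))[0])
        raise ValueError(f"logit needs values in (0, 1); got {arr[bad]} at row {bad}")
    return np.log(arr / (1 - arr))


def inverse_transform(values, kind: str, offset: float = 0.0) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if kind == "none":
        return arr
    if kind == "log10":
        return 10.0 ** arr - offset
    if kind == "sqrt":
        return arr ** 2
    if kind == "logit":
        return 1.0 / (1.0 + np.exp(-arr))
    raise ValueError(f"unknown transform {kind!r}")


# ------------------------------------------------------------ mixed models

@dataclass(frozen=True)
class ModelSpec:
    """One GLMM: response, transformation, fixed and random structure."""

    response: str
    transform: str = "none"
    fixed: tuple = ("rearing", "ranging", "rearing:ranging")
    group: str = "pen"          # grouping random effect
    bird: str | None = None     # extra variance component for repeated measures
    alpha: float = ALPHA
    drop_ns_interactions: bool = True
    log_offset: float = 0.0

    def __post_init__(self):
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass
class MixedModelFit:
    """Fitted mixed model plus per-term F-tests and LS-mean machinery."""

    spec: ModelSpec
    result: object = field(repr=False)
    data: pd.DataFrame = field(repr=False)
    terms: tuple = ()
    anova: pd.DataFrame = field(default=None, repr=False)
    dropped_terms: tuple = ()
    singular: bool = False

    def term_pvalue(self, term: str) -> float:
        row = self.anova[self.anova["term"] == term]
        if row.empty:
            raise KeyError(f"term {term!r} not in the final model")
        return float(row["p"].iloc[0])

    # -- least-squares means -------------------------------------------
    def _design_rows(self, factors: list[str]) -> tuple[list[tuple], np.ndarray]:
        """Population-averaged design row per factor-level combination."""
        design_info = self.result.model.data.design_info
        level_sets = [sorted(self.data[f].unique()) for f in factors]

        def combos(sets):
            if len(sets) == 1:
                return [(v,) for v in sets[0]]
            out = []
            for v in sets[0]:
                for rest in combos(sets[1:]):
                    out.append((v,) + rest)
            return out

        rows = []
        for combo in combos(level_sets):
            df = self.data.copy()
            for f, v in zip(factors, combo):
                df[f] = v
            (X,) = patsy.build_design_matrices([design_info], df)
            rows.append(np.asarray(X).mean(axis=0))
        return combos(level_sets), np.vstack(rows)

    def lsmeans(self, factor: str | list[str]) -> pd.DataFrame:
        """Model-adjusted cell means +/- SE on the transformed scale."""
        factors = [factor] if isinstance(factor, str) else list(factor)
        combos, X = self._design_rows(factors)
        beta = np.asarray(self.result.fe_params)
        cov = np.asarray(self.result.cov_params())[: len(beta), : len(beta)]
        est = X @ beta
        se = np.sqrt(np.einsum("ij,jk,ik->i", X, cov, X))
        out = pd.DataFrame(combos, columns=factors)
        out["lsmean"] = est
        out["se"] = se
        return out

    @property
    def df_resid(self) -> float:
        return float(self.result.model.nobs - len(self.result.fe_params))


def _wald_term_tests(result, alpha: float) -> pd.DataFrame:
    """Per-term Wald F-tests on the fixed effects (residual df)."""
    design_info = result.model.data.design_info
    beta = np.asarray(result.fe_params)
    cov = np.asarray(result.cov_params())[: len(beta), : len(beta)]
    df_den = result.model.nobs - len(beta)
    rows = []
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = np.arange(len(beta))[sl]
        b = beta[idx]
        V = cov[np.ix_(idx, idx)]
        q = len(idx)
        try:
            stat = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            stat = np.nan
        F = stat / q
        p = float(sps.f.sf(F, q, df_den)) if np.isfinite(F) else np.nan
        rows.append(
            {"term": term, "F": F, "df_num": q, "df_den": df_den,
             "p": p, "significant": bool(p < alpha) if np.isfinite(p) else False}
        )
    return pd.DataFrame(rows)


def fit_mixed_model(table: pd.DataFrame, spec: ModelSpec) -> MixedModelFit:
    """Fit the specified mixed model by REML.

    The response is transformed per ``spec.transform``; fixed-effect
    terms get Wald F-tests with residual denominator df (approximate);
    nonsignificant interaction terms are removed and the model refitted
    when ``spec.drop_ns_interactions`` is set.  Singular or
    non-converged fits are reported via the ``singular`` flag, never
    hidden.
    """
    df = table.copy().reset_index(drop=True)
    df["_y"] = transform(df[spec.response], spec.transform, offset=spec.log_offset)

    def _fit(terms: tuple):
        formula = "_y ~ " + " + ".join(terms)
        vc = {"bird": f"0 + C({spec.bird})"} if spec.bird else None
        singular = False
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model = smf.mixedlm(
                formula, df, groups=df[spec.group], re_formula="1", vc_formula=vc
            )
            result = model.fit(reml=True)
            for w in caught:
                if issubclass(w.category, sm.tools.sm_exceptions.ConvergenceWarning):
                    singular = True
        # a boundary (zero) group variance is also a singular fit
        if np.asarray(result.cov_re).size and np.min(np.diag(result.cov_re)) < 1e-10:
            singular = True
        return result, singular

    terms = tuple(spec.fixed)
    result, singular = _fit(terms)
    anova = _wald_term_tests(result, spec.alpha)
    dropped: list[str] = []
    if spec.drop_ns_interactions:
        keep = []
        for t in terms:
            if ":" in t:
                match = anova[anova["term"].str.replace(" ", "") == t.replace(" ", "")]
                p = float(match["p"].iloc[0]) if not match.empty else np.nan
                if not (np.isfinite(p) and p < spec.alpha):
                    dropped.append(t)
                    continue
            keep.append(t)
        if dropped and keep:
            terms = tuple(keep)
            result, singular = _fit(terms)
            anova = _wald_term_tests(result, spec.alpha)
    return MixedModelFit(
        spec=spec, result=result, data=df, terms=terms, anova=anova,
        dropped_terms=tuple(dropped), singular=singular,
    )


def posthoc_pairwise(fit: MixedModelFit, factor: str | list[str]) -> pd.DataFrame:
    """All pairwise t-comparisons of LS-means for a (combination of) factor(s).

    The Bonferroni multiplier applies only when there are more than 3
    comparisons, per the analysis protocol.
    """
    factors = [factor] if isinstance(factor, str) else list(factor)
    combos, X = fit._design_rows(factors)
    beta = np.asarray(fit.result.fe_params)
    cov = np.asarray(fit.result.cov_params())[: len(beta), : len(beta)]
    df_den = fit.df_resid
    pairs = list(combinations(range(len(combos)), 2))
    n_comp = len(pairs)
    bonf = n_comp if n_comp > 3 else 1
    rows = []
    for i, j in pairs:
        L = X[i] - X[j]
        est = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        t = est / se if se > 0 else np.nan
        p_raw = 2 * float(sps.t.sf(abs(t), df_den)) if np.isfinite(t) else np.nan
        rows.append(
            {
                "level_a": combos[i] if len(factors) > 1 else combos[i][0],
                "level_b": combos[j] if len(factors) > 1 else combos[j][0],
                "estimate": est,
                "se": se,
                "t": t,
                "df": df_den,
                "p_raw": p_raw,
                "p_adj": min(1.0, p_raw * bonf) if np.isfinite(p_raw) else np.nan,
                "bonferroni_m": bonf,
            }
        )
    return pd.DataFrame(rows)


# -------------------------------------------------- correlation/regression

def correlate(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation on the given (transformed) scales."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass(frozen=True)
class FeatherRegression:
    slope: float
    intercept: float
    r: float
    r_squared: float
    F: float
    p: float
    n: int


def feather_regression(step_latency_s, feather_total,
                       log_offset: float = 0.0) -> FeatherRegression:
    """Plumage coverage against open-field step latency.

    Simple linear model of square-root-transformed feather totals on
    log10-transformed latencies; increasing fearfulness (longer step
    latency) appearing as a negative slope.
    """
    lat = np.asarray(step_latency_s, dtype=float)
    fea = np.asarray(feather_total, dtype=float)
    if lat.size != fea.size:
        raise ValueError("latency and feather tables must pair per hen")
    if lat.size < 3:
        raise ValueError("need at least 3 hens")
    x = transform(lat, "log10", offset=log_offset)
    y = transform(fea, "sqrt")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    slope = float(res.params[1])
    r2 = float(res.rsquared)
    return FeatherRegression(
        slope=slope,
        intercept=float(res.params[0]),
        r=float(np.sign(slope) * np.sqrt(r2)),
        r_squared=r2,
        F=float(res.fvalue),
        p=float(res.f_pvalue),
        n=int(lat.size),
    )


# ------------------------------------------------------------ feather model

FEATHER_PARTS = ("neck", "chest", "back", "wing", "vent", "tail")


def feather_total(scores: dict) -> int:
    """Total a six-part plumage record (each part scored 1-4, total 6-24)."""
    missing = set(FEATHER_PARTS) - set(scores)
    if missing:
        raise ValueError(f"missing feather parts: {sorted(missing)}")
    for part in FEATHER_PARTS:
        s = scores[part]
        if not (1 <= s <= 4) or int(s) != s:
            raise ValueError(f"{part} score {s} outside the integer range 1-4")
    return int(sum(scores[p] for p in FEATHER_PARTS))
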