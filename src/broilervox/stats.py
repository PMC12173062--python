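"""Statistical stage: treatment/time-of-day models, Tukey HSD, and THI.

Per-type hourly vocalization durations, averaged into diurnal bins, are
analyzed with a linear model with treatment (pen enrichment and, in the
finisher phase, heat stress) and time-of-day bin as fixed effects and pen
and compartment as random intercepts; the pen is the experimental unit
(microphones are nested within pens).  The treatment x time interaction is
dropped from the final model when not significant at alpha = 0.05.
Significant factors get Tukey-HSD-corrected pairwise comparisons and a
compact letter display (levels sharing a letter do not differ at alpha).

Estimation is REML via statsmodels MixedLM.  Omnibus F statistics use
containment (split-plot) denominator degrees of freedom: effects that vary
within pens are tested against the within-pen residual stratum, effects
constant within pens against the between-pen stratum.  These tests are
exact for the balanced designs the simulators generate.  A singular or
non-converging random-effects fit falls back to ordinary least squares with
a logged warning.

The temperature-humidity index (THI) combines dry-bulb temperature and
relative humidity; the cited poultry formula is not printed in the source
material, so the default here is the two-temperature stand-in
``THI = 0.85 T_db + 0.15 T_wb`` (wet bulb from Stull's 2011 approximation),
behind a registry so other formulas can be swapped in.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "EffectsReport",
    "fit_duration_model",
    "tukey_hsd",
    "compact_letters",
    "compute_thi",
    "wet_bulb_stull",
    "THI_FORMULAS",
    "anova_thi",
    "simulate_observation_table",
    "simulate_climate_records",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class EffectsReport:
    """Fitted effects, omnibus tests, pairwise letters, diagnostics."""

    model_type: str
    anova: pd.DataFrame  # term, F, df_num, df_den, p
    emmeans: dict[str, pd.Series] = field(default_factory=dict)
    pairwise: dict[str, pd.DataFrame] = field(default_factory=dict)
    letters: dict[str, dict[str, str]] = field(default_factory=dict)
    interaction_retained: bool = False
    interaction_p: float = float("nan")
    diagnostics: dict = field(default_factory=dict)

    def term_p(self, name: str) -> float:
        row = self.anova.loc[self.anova["term"] == name]
        if row.empty:
            raise KeyError(name)
        return float(row["p"].iloc[0])

    def to_dict(self) -> dict:
        return {
            "model_type": self.model_type,
            "anova": self.anova.to_dict(orient="records"),
            "emmeans": {f: s.to_dict() for f, s in self.emmeans.items()},
            "letters": self.letters,
            "interaction_retained": self.interaction_retained,
            "interaction_p": self.interaction_p,
            "diagnostics": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.diagnostics.items()
            },
        }


# ---------------------------------------------------------------------------
# compact letter display


def compact_letters(
    levels: Sequence[str], pvalues: pd.DataFrame, alpha: float = ALPHA
) -> dict[str, str]:
    """Insert-and-absorb compact letter display from a pairwise p matrix.

    Levels that are *not* significantly different share at least one letter;
    the display is reconstructible from (and consistent with) the matrix.
    """
    groups: list[set[str]] = [set(levels)]
    for i, a in enumerate(levels):
        for b in list(levels)[i + 1 :]:
            if float(pvalues.loc[a, b]) < alpha:
                new = []
                for g in groups:
                    if a in g and b in g:
                        new.extend([g - {a}, g - {b}])
                    else:
                        new.append(g)
                # absorb subsets
                groups = [
                    g
                    for g in new
                    if g and not any(g < h for h in new if h is not g)
                ]
                # deduplicate
                uniq = []
                for g in groups:
                    if g not in uniq:
                        uniq.append(g)
                groups = uniq
    groups.sort(key=lambda g: min(list(levels).index(x) for x in g))
    out = {lv: "" for lv in levels}
    for letter, g in zip("abcdefghijklmnopqrstuvwxyz", groups):
        for lv in g:
            out[lv] += letter
    return {lv: "".join(sorted(s)) for lv, s in out.items()}


def tukey_hsd(groups: Mapping[str, Sequence[float]], alpha: float = ALPHA):
    """Tukey HSD over independent groups: pairwise p-values and letters.

    Uses the studentized-range distribution (for two groups the statistic
    reduces to q = sqrt(2) |t| of the pooled-variance t test).
    """
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for n, a in zip(names, arrays):
        if a.size < 2:
            raise ValueError(f"group {n!r} has fewer than 2 observations")
    res = sps.tukey_hsd(*arrays)
    p = pd.DataFrame(res.pvalue, index=names, columns=names)
    letters = compact_letters(names, p, alpha)
    return p, letters


# ---------------------------------------------------------------------------
# duration model

_BRACKET = re.compile(r"\[[^\]]*\]")


def _term_of(col: str) -> str:
    """Collapse a design-column name to its term, e.g.
    'C(bin)[T.evening]' -> 'C(bin)', interactions keep the ':'."""
    return _BRACKET.sub("", col)


def _term_columns(exog_names: Sequence[str]) -> dict[str, list[int]]:
    terms: dict[str, list[int]] = {}
    for i, name in enumerate(exog_names):
        terms.setdefault(_term_of(name), []).append(i)
    return terms


def _containment_ddf(
    df: pd.DataFrame, exog: np.ndarray, exog_names: Sequence[str], group: str
) -> tuple[dict[str, float], dict[str, bool]]:
    """Containment denominator df per term: between-pen terms are tested in
    the between-pen stratum, within-pen terms in the residual stratum."""
    terms = _term_columns(exog_names)
    G = df[group].nunique()
    N = len(df)
    rank = np.linalg.matrix_rank(exog)
    codes = df[group].astype("category").cat.codes.to_numpy()
    between_cols = 0
    is_between: dict[str, bool] = {}
    for term, cols in terms.items():
        const = all(
            all(np.ptp(exog[codes == g, c]) < 1e-12 for g in range(G)) for c in cols
        )
        is_between[term] = const
        if const:
            between_cols += len(cols)
    ddf = {}
    for term, cols in terms.items():
        if is_between[term]:
            ddf[term] = max(G - between_cols, 1)
        else:
            ddf[term] = max(N - rank - (G - 1), 1)
    return ddf, is_between


def _wald_f(beta: pd.Series, cov: pd.DataFrame, cols: list[int], ddf: float):
    b = beta.to_numpy()[cols]
    V = cov.to_numpy()[np.ix_(cols, cols)]
    q = len(cols)
    # pinv handles degenerate (zero-variance) fits: b = 0 there, so F = 0
    stat = float(b @ np.linalg.pinv(V) @ b) / q
    p = float(sps.f.sf(stat, q, ddf))
    return stat, q, p


def _build_formula(dv: str, treatments: Sequence[str], time: str, interaction: bool) -> str:
    rhs = [f"C({t})" for t in treatments] + [f"C({time})"]
    if interaction:
        rhs += [f"C({t}):C({time})" for t in treatments]
    return f"{dv} ~ " + " + ".join(rhs)


def _fit_once(formula: str, data: pd.DataFrame, group: str, compartment_re: bool):
    """REML mixed fit with pen intercept (+ compartment variance component);
    falls back to OLS on convergence failure or a singular fit."""
    vc = None
    if compartment_re and data["compartment"].nunique() > 1:
        vc = {"compartment": "0 + C(compartment)"}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm(formula, data, groups=data[group], re_formula="1", vc_formula=vc)
            res = md.fit(reml=True, method="lbfgs", maxiter=200)
        if not np.all(np.isfinite(res.fe_params)) or not np.all(
            np.isfinite(np.asarray(res.cov_params()))
        ):
            raise np.linalg.LinAlgError("non-finite mixed fit")
        return res, "mixed"
    except Exception as exc:  # singular / non-convergent random effects
        logger.warning("mixed fit failed (%s); falling back to OLS", exc)
        res = smf.ols(formula, data).fit()
        return res, "ols"


def _emm_contrasts(res, data: pd.DataFrame, factors: Sequence[str], factor: str):
    """Estimated-marginal-mean contrast vectors for each level of ``factor``
    (averaging the design over the other factors' levels)."""
    levels = {f: sorted(data[f].astype(str).unique()) for f in factors}
    grid = pd.MultiIndex.from_product(
        [levels[f] for f in factors], names=list(factors)
    ).to_frame(index=False)
    design_info = res.model.data.design_info
    from patsy import build_design_matrices

    X = np.asarray(build_design_matrices([design_info], grid)[0])
    out = {}
    for lv in levels[factor]:
        mask = (grid[factor] == lv).to_numpy()
        out[lv] = X[mask].mean(axis=0)
    return out


def fit_duration_model(
    table: pd.DataFrame,
    sound_type: str | None = None,
    treatments: Sequence[str] = ("enrichment",),
    time: str = "bin",
    dv: str = "mean_s_per_min",
    alpha: float = ALPHA,
    compartment_re: bool = True,
    aggregate_microphones: bool = False,
) -> EffectsReport:
    """Fit the duration model for one sound type and report effects.

    Fixed effects: the treatment factor(s), the time-of-day bin, and their
    interactions; random intercepts for pen (the experimental unit) and
    compartment.  If no treatment x time interaction reaches ``alpha`` the
    model is refit without interactions (pruning).  Significant factors get
    Tukey-corrected pairwise comparisons and compact letters.  With
    ``aggregate_microphones`` the two microphones per pen are averaged to
    pen level before fitting (the alternative reading of the nesting).
    """
    data = table.copy()
    if sound_type is not None and "type" in data.columns:
        data = data.loc[data["type"] == str(sound_type)].copy()
    if data.empty:
        raise ValueError("no observations to fit")
    factors = list(treatments) + [time]
    for f in factors:
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels")
    if aggregate_microphones and "microphone" in data.columns:
        keys = [c for c in ("pen", "compartment", *factors) if c in data.columns]
        data = data.groupby(keys, as_index=False)[dv].mean()
    if "compartment" not in data.columns:
        data["compartment"] = "c0"

    if float(np.std(data[dv].to_numpy())) < 1e-12:
        return _degenerate_report(data, factors, treatments, time, dv)

    full = _build_formula(dv, treatments, time, interaction=True)
    res, kind = _fit_once(full, data, "pen", compartment_re)
    beta = res.fe_params if kind == "mixed" else res.params
    k = len(beta)
    cov = pd.DataFrame(
        np.asarray(res.cov_params())[:k, :k], index=beta.index, columns=beta.index
    )
    exog = np.asarray(res.model.exog)
    names = list(beta.index)
    if kind == "mixed":
        ddf_map, _ = _containment_ddf(data, exog, names, "pen")
    else:
        ddf_map = {t: res.df_resid for t in _term_columns(names)}

    terms = _term_columns(names)
    inter_terms = [t for t in terms if ":" in t]
    inter_p = []
    for t in inter_terms:
        _, _, p = _wald_f(beta, cov, terms[t], ddf_map[t])
        inter_p.append(p)
    interaction_p = float(min(inter_p)) if inter_p else float("nan")
    retain = bool(inter_p) and any(p < alpha for p in inter_p)

    if not retain:
        reduced = _build_formula(dv, treatments, time, interaction=False)
        res, kind = _fit_once(reduced, data, "pen", compartment_re)
        beta = res.fe_params if kind == "mixed" else res.params
        k = len(beta)
        cov = pd.DataFrame(
            np.asarray(res.cov_params())[:k, :k], index=beta.index, columns=beta.index
        )
        exog = np.asarray(res.model.exog)
        names = list(beta.index)
        if kind == "mixed":
            ddf_map, _ = _containment_ddf(data, exog, names, "pen")
        else:
            ddf_map = {t: res.df_resid for t in _term_columns(names)}
        terms = _term_columns(names)

    rows = []
    for t, cols in terms.items():
        if t == "Intercept":
            continue
        F, q, p = _wald_f(beta, cov, cols, ddf_map[t])
        rows.append({"term": t, "F": F, "df_num": q, "df_den": ddf_map[t], "p": p})
    anova = pd.DataFrame(rows)

    emmeans: dict[str, pd.Series] = {}
    pairwise: dict[str, pd.DataFrame] = {}
    letters: dict[str, dict[str, str]] = {}
    bvec = beta.to_numpy()
    Vmat = cov.to_numpy()
    for f in factors:
        term_name = f"C({f})"
        contrasts = _emm_contrasts(res, data, factors, f)
        means = pd.Series({lv: float(c @ bvec) for lv, c in contrasts.items()}, name=f)
        emmeans[f] = means
        lvls = list(contrasts)
        k = len(lvls)
        ddf = ddf_map.get(term_name, res.df_resid if kind == "ols" else 1)
        pm = pd.DataFrame(1.0, index=lvls, columns=lvls)
        for i, a in enumerate(lvls):
            for b in lvls[i + 1 :]:
                d = contrasts[a] - contrasts[b]
                se = float(np.sqrt(d @ Vmat @ d))
                qstat = np.sqrt(2.0) * abs(float(d @ bvec)) / max(se, 1e-12)
                p = float(sps.studentized_range.sf(qstat, k, ddf))
                pm.loc[a, b] = pm.loc[b, a] = p
        pairwise[f] = pm
        omnibus_p = (
            float(anova.loc[anova["term"] == term_name, "p"].iloc[0])
            if (anova["term"] == term_name).any()
            else 1.0
        )
        # letters reflect pairwise tests only when the omnibus is significant
        letters[f] = (
            compact_letters(lvls, pm, alpha)
            if omnibus_p < alpha
            else {lv: "a" for lv in lvls}
        )

    resid = np.asarray(res.resid, dtype=float)
    sd = resid.std(ddof=1) if resid.size > 1 else 0.0
    stud = resid / sd if sd > 0 else resid
    shapiro_p = float(sps.shapiro(resid).pvalue) if 3 <= resid.size <= 5000 else float("nan")
    report = EffectsReport(
        model_type=kind,
        anova=anova,
        emmeans=emmeans,
        pairwise=pairwise,
        letters=letters,
        interaction_retained=retain,
        interaction_p=interaction_p,
        diagnostics={
            "n_obs": int(len(data)),
            "outlier_rows": np.flatnonzero(np.abs(stud) > 3.0),
            "shapiro_p": shapiro_p,
        },
    )
    return report


def _degenerate_report(
    data: pd.DataFrame, factors: Sequence[str], treatments: Sequence[str], time: str, dv: str
) -> EffectsReport:
    """Zero-variance response: no effect can be significant by definition."""
    terms = [f"C({f})" for f in factors] + [f"C({t}):C({time})" for t in treatments]
    anova = pd.DataFrame(
        [{"term": t, "F": 0.0, "df_num": np.nan, "df_den": np.nan, "p": 1.0} for t in terms]
    )
    const = float(data[dv].iloc[0])
    emmeans, letters = {}, {}
    for f in factors:
        lvls = sorted(data[f].astype(str).unique())
        emmeans[f] = pd.Series({lv: const for lv in lvls}, name=f)
        letters[f] = {lv: "a" for lv in lvls}
    return EffectsReport(
        model_type="degenerate",
        anova=anova,
        emmeans=emmeans,
        letters=letters,
        interaction_retained=False,
        interaction_p=1.0,
        diagnostics={"n_obs": int(len(data)), "outlier_rows": np.zeros(0, int), "shapiro_p": float("nan")},
    )


# ---------------------------------------------------------------------------
# THI


def wet_bulb_stull(temp_c: float, rh: float) -> float:
    """Stull (2011) wet-bulb approximation from dry bulb (degC) and RH (%)."""
    T, H = float(temp_c), float(rh)
    return (
        T * np.arctan(0.151977 * np.sqrt(H + 8.313659))
        + np.arctan(T + H)
        - np.arctan(H - 1.676331)
        + 0.00391838 * H**1.5 * np.arctan(0.023101 * H)
        - 4.686035
    )


def _thi_two_temperature(temp_c: float, rh: float) -> float:
    return 0.85 * temp_c + 0.15 * wet_bulb_stull(temp_c, rh)


def _thi_tao_xin(temp_c: float, rh: float) -> float:
    return 0.6 * temp_c + 0.4 * wet_bulb_stull(temp_c, rh)


#: Registry of THI formulas (all degC in, monotone increasing in temperature).
THI_FORMULAS = {
    "two_temperature": _thi_two_temperature,
    "tao_xin": _thi_tao_xin,
}


def compute_thi(temp_c: float, rh: float, formula: str = "two_temperature") -> float:
    """Temperature-humidity index from dry-bulb temperature and RH."""
    if not (-10.0 < temp_c < 50.0):
        raise ValueError(f"temperature {temp_c} degC outside plausible range")
    if not (0.0 <= rh <= 100.0):
        raise ValueError(f"relative humidity {rh}% outside [0, 100]")
    try:
        fn = THI_FORMULAS[formula]
    except KeyError:
        raise ValueError(f"unknown THI formula {formula!r}") from None
    return float(fn(temp_c, rh))


def anova_thi(
    records: pd.DataFrame,
    dv: str = "thi",
    factors: Sequence[str] = ("treatment", "round", "time"),
    alpha: float = ALPHA,
) -> EffectsReport:
    """Full-factorial ANOVA of THI on treatment, round, and time of day.

    All interactions are included; a rank-deficient design raises an error
    naming the aliased columns.  Significant factors get Tukey HSD post-hoc
    comparisons on the raw groups.
    """
    data = records.copy()
    if dv not in data.columns:
        data[dv] = [
            compute_thi(t, h) for t, h in zip(data["dry_bulb_temp"], data["relative_humidity"])
        ]
    for f in factors:
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels")
    if float(np.std(data[dv].to_numpy())) < 1e-12:
        terms = []
        for f in factors:
            terms.append(f"C({f})")
        anova = pd.DataFrame(
            [{"term": t, "F": 0.0, "df_num": np.nan, "df_den": np.nan, "p": 1.0} for t in terms]
        )
        letters = {
            f: {str(lv): "a" for lv in sorted(data[f].unique(), key=str)} for f in factors
        }
        return EffectsReport(model_type="degenerate", anova=anova, letters=letters,
                             diagnostics={"n_obs": int(len(data))})
    formula = f"{dv} ~ " + " * ".join(f"C({f})" for f in factors)
    model = smf.ols(formula, data)
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        _, _, piv = sp_qr(exog)
        aliased = [model.exog_names[i] for i in piv[rank:]]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    res = model.fit()
    table = sm.stats.anova_lm(res, typ=2)
    rows = []
    for term, row in table.iterrows():
        if term == "Residual":
            continue
        rows.append(
            {
                "term": term,
                "F": float(row["F"]),
                "df_num": float(row["df"]),
                "df_den": float(table.loc["Residual", "df"]),
                "p": float(row["PR(>F)"]),
            }
        )
    anova = pd.DataFrame(rows)
    pairwise: dict[str, pd.DataFrame] = {}
    letters: dict[str, dict[str, str]] = {}
    emmeans: dict[str, pd.Series] = {}
    for f in factors:
        groups = {str(lv): data.loc[data[f] == lv, dv].to_numpy() for lv in sorted(data[f].unique(), key=str)}
        emmeans[f] = pd.Series({lv: float(np.mean(v)) for lv, v in groups.items()}, name=f)
        omnibus = anova.loc[anova["term"] == f"C({f})", "p"]
        if not omnibus.empty and float(omnibus.iloc[0]) < alpha and all(len(v) >= 2 for v in groups.values()):
            pm, lt = tukey_hsd(groups, alpha)
            pairwise[f], letters[f] = pm, lt
        else:
            letters[f] = {lv: "a" for lv in groups}
    return EffectsReport(
        model_type="ols",
        anova=anova,
        emmeans=emmeans,
        pairwise=pairwise,
        letters=letters,
        diagnostics={"n_obs": int(len(data))},
    )


def sp_qr(a: np.ndarray):
    from scipy.linalg import qr

    return qr(a, pivoting=True)


# ---------------------------------------------------------------------------
# simulators for calibration studies


def simulate_observation_table(
    n_pens: int = 8,
    mics_per_pen: int = 2,
    base: float = 10.0,
    bin_effects: Mapping[str, float] | None = None,
    treatment_effect: float = 0.0,
    interaction_effects: Mapping[tuple[str, str], float] | None = None,
    pen_sd: float = 1.0,
    compartment_sd: float = 0.0,
    resid_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Balanced synthetic observation table for model calibration.

    Pens are split over two compartments; enrichment (MP/NMP) alternates
    within compartment; each pen contributes ``mics_per_pen`` observations
    per diurnal bin.  The response is Gaussian around
    ``base + bin effect + treatment effect (MP) + interaction`` with pen,
    compartment, and residual noise components.
    """
    rng = np.random.default_rng(seed)
    bins = ["night", "morning", "midday", "evening"]
    bin_effects = dict(bin_effects or {})
    interaction_effects = dict(interaction_effects or {})
    pen_re = rng.normal(0.0, pen_sd, n_pens)
    comp_re = rng.normal(0.0, compartment_sd, 2)
    rows = []
    for p in range(n_pens):
        comp = p % 2
        enrich = "MP" if (p // 2) % 2 == 0 else "NMP"
        for mic in range(mics_per_pen):
            for b in bins:
                mu = (
                    base
                    + bin_effects.get(b, 0.0)
                    + (treatment_effect if enrich == "MP" else 0.0)
                    + interaction_effects.get((enrich, b), 0.0)
                    + pen_re[p]
                    + comp_re[comp]
                )
                rows.append(
                    {
                        "pen": f"pen{p:02d}",
                        "compartment": f"comp{comp}",
                        "microphone": f"pen{p:02d}_m{mic}",
                        "round": 1,
                        "phase": "starter",
                        "bin": b,
                        "enrichment": enrich,
                        "temperature_treatment": "TN",
                        "type": "SP",
                        "mean_s_per_min": mu + rng.normal(0.0, resid_sd),
                    }
                )
    return pd.DataFrame(rows)


def simulate_climate_records(
    treatment_means: Mapping[str, float] = None,
    sd: float = 1.0,
    n_days: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Hourly-style climate records for the THI ANOVA (balanced 2x3x3)."""
    rng = np.random.default_rng(seed)
    means = dict(treatment_means or {"HS": 29.0, "TN": 22.0})
    rows = []
    for treat, mu in means.items():
        for rnd in (1, 2, 3):
            for hour in (10, 12, 14):
                for d in range(n_days):
                    t = mu + 0.5 * (rnd - 2) + rng.normal(0.0, sd)
                    rh = float(np.clip(55.0 + rng.normal(0.0, 8.0), 20.0, 95.0))
                    rows.append(
                        {
                            "treatment": treat,
                            "round": rnd,
                            "time": f"{hour:02d}:00",
                            "day": d,
                            "dry_bulb_temp": float(np.clip(t, -5.0, 45.0)),
                            "relative_humidity": rh,
                        }
                    )
    return pd.DataFrame(rows)
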