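"""Environmental covariate models of daily abundance, statsmodels-style.

:class:`AdditiveCountModel` wraps the penalized-spline count fitter behind a
``Model.fit() -> Results`` surface; around it sit the selection procedure
used for survey covariates — a combined forward/backward AIC search, an
importance ranking, and a correlation-redundancy pruning step with
ecological exceptions (seasonal temperature terms are kept even though
mutually correlated, and the SST anomaly is never dropped because local
thermal anomalies carry signal beyond season) — plus the effect-shape
classification used to annotate fitted terms (+, -, single interior peak
'p', other non-monotone 'q').
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gam import AdditiveFit, FactorCoding, SplineBasis, TermSpec, fit_penalized_glm

__all__ = [
    "AdditiveCountModel",
    "AdditiveCountResults",
    "stepwise_select",
    "redundancy_prune",
    "classify_effect_shape",
    "select_smoothing",
    "DEFAULT_EXCEPTION_GROUPS",
    "NEVER_DROP",
]

#: Smoothing-weight grid searched by :func:`select_smoothing`.
ALPHA_GRID = (0.1, 1.0, 10.0, 100.0, 1e3, 1e4, 1e5)

#: Covariate sets exempt from redundancy pruning against each other.
DEFAULT_EXCEPTION_GROUPS = [frozenset({"month", "sst", "air_temp"})]
#: Covariates never dropped by pruning regardless of correlations.
NEVER_DROP = frozenset({"sst_anomaly"})

#: Effective degrees of freedom at or below which a smooth is reported as linear.
LINEARIZE_EDF = 1.2


class AdditiveCountModel:
    """Additive count model of daily abundance: log E[count] = a + sum f_j(x_j).

    Smooth terms are penalized cubic splines, factors unpenalized dummies.
    Construct from arrays or with :meth:`from_dataframe`; :meth:`fit`
    returns an :class:`AdditiveCountResults`.
    """

    def __init__(self, endog, exog: pd.DataFrame, terms: list[TermSpec],
                 family: str = "auto", nb_alpha: float | None = None):
        self.endog = np.asarray(endog)
        self.exog = exog
        self.terms = list(terms)
        self.family = family
        self.nb_alpha = nb_alpha

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str,
                       smooth: list[str] = (), linear: list[str] = (),
                       factor: list[str] = (), k: int = 6,
                       alpha: float | dict = 1.0, family: str = "auto",
                       nb_alpha: float | None = None) -> "AdditiveCountModel":
        """Build the model from named columns; ``alpha`` may be one smoothing
        weight for all smooth terms or a per-term mapping (see
        :func:`select_smoothing`)."""
        def get_alpha(c):
            return alpha.get(c, 1.0) if isinstance(alpha, dict) else alpha
        terms = ([TermSpec(c, "smooth", k=k, alpha=float(get_alpha(c)))
                  for c in smooth]
                 + [TermSpec(c, "linear") for c in linear]
                 + [TermSpec(c, "factor") for c in factor])
        missing = [t.name for t in terms if t.name not in data.columns]
        if missing:
            raise KeyError(f"covariates not in data: {missing}")
        if data[[t.name for t in terms]].isna().any().any():
            raise ValueError("missing covariate values in term specification")
        return cls(data[response], data, terms, family=family, nb_alpha=nb_alpha)

    def fit(self, tol: float = 1e-8) -> "AdditiveCountResults":
        fit = fit_penalized_glm(self.endog, self.exog, self.terms,
                                family=self.family, tol=tol,
                                nb_alpha=self.nb_alpha)
        return AdditiveCountResults(self, fit)


@dataclass
class AdditiveCountResults:
    """Fitted additive count model: estimates, EDFs, AIC, curves, summary."""

    model: AdditiveCountModel
    fit: AdditiveFit

    @property
    def aic(self) -> float:
        return self.fit.aic

    @property
    def deviance(self) -> float:
        return self.fit.deviance

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.fit.mu

    def term_names(self) -> list[str]:
        return [t.name for t in self.model.terms]

    def partial_effect(self, term: str, x: np.ndarray | None = None,
                       n_points: int = 100) -> tuple[np.ndarray, np.ndarray]:
        """Centred partial effect f_hat(x) of one term on the linear-predictor scale."""
        sl, basis = self._block(term)
        beta = self.fit.coef[sl]
        if isinstance(basis, SplineBasis):
            if x is None:
                x = np.linspace(basis.lo, basis.hi, n_points)
            return np.asarray(x, float), basis.design(np.asarray(x, float)) @ beta
        if isinstance(basis, tuple) and basis[0] == "linear":
            xv = np.asarray(self.model.exog[term], dtype=float)
            if x is None:
                x = np.linspace(xv.min(), xv.max(), n_points)
            return np.asarray(x, float), (np.asarray(x, float) - basis[1]) * beta[0]
        raise ValueError(f"term {term!r} has no 1-D partial effect")

    def _block(self, term: str):
        if term not in self.fit.blocks:
            raise KeyError(f"term {term!r} not in the fitted model")
        return self.fit.blocks[term]

    def mean_anchored_curve(self, term: str, n_points: int = 100
                            ) -> tuple[np.ndarray, np.ndarray]:
        """Predicted mean count as `term` varies over its observed range,
        all other covariates fixed at their means (factors at their mode)."""
        sl, basis = self._block(term)
        exog = self.model.exog
        eta0 = float(self.fit.coef[0])
        for name, (bsl, b) in self.fit.blocks.items():
            if name in ("(intercept)", term):
                continue
            beta = self.fit.coef[bsl]
            if isinstance(b, SplineBasis):
                xm = np.array([float(np.mean(exog[name]))])
                eta0 += float((b.design(xm) @ beta)[0])
            elif isinstance(b, tuple) and b[0] == "linear":
                eta0 += float((np.mean(exog[name]) - b[1]) * beta[0])
            elif isinstance(b, FactorCoding):
                mode = exog[name].mode().iloc[0] if hasattr(exog[name], "mode") \
                    else max(set(exog[name]), key=list(exog[name]).count)
                eta0 += float((b.design([mode]) @ beta)[0])
        xg, f = self.partial_effect(term, n_points=n_points)
        return xg, np.exp(eta0 + f)

    def effect_shapes(self, n_points: int = 100) -> dict[str, str]:
        """Shape label per 1-D term of the fitted partial effects."""
        out = {}
        for t in self.model.terms:
            if t.kind == "factor":
                continue
            xg, f = self.partial_effect(t.name, n_points=n_points)
            out[t.name] = classify_effect_shape(xg, f,
                                                response_scale=float(np.ptp(np.log1p(self.fit.mu))) or 1.0)
        return out

    def importance(self) -> pd.DataFrame:
        """Drop-one importance: increase in deviance when a term is removed.

        Refits use the same family (and, for negative binomial, the same
        dispersion) as this fit so the deviances are on one scale."""
        rows = []
        for t in self.model.terms:
            reduced = [u for u in self.model.terms if u.name != t.name]
            refit = fit_penalized_glm(self.model.endog, self.model.exog, reduced,
                                      family=self.fit.family,
                                      nb_alpha=self.fit.nb_alpha or None)
            rows.append({"term": t.name,
                         "importance": refit.deviance - self.fit.deviance})
        return (pd.DataFrame(rows)
                .sort_values("importance", ascending=False)
                .reset_index(drop=True))

    def summary(self) -> str:
        """Plain-text fit summary: family, deviance, AIC, per-term EDF and shape."""
        shapes = self.effect_shapes()
        lines = [
            "Additive count model of daily abundance",
            f"  family: {self.fit.family}"
            + (f" (alpha={self.fit.nb_alpha:.3f})" if self.fit.family == "negbin" else ""),
            f"  n = {self.fit.n_obs}, deviance = {self.fit.deviance:.2f}, "
            f"EDF = {self.fit.edf:.2f}, AIC = {self.fit.aic:.2f}",
            f"  Pearson dispersion = {self.fit.pearson_dispersion:.2f}",
            "  term            kind     edf   reported  shape",
        ]
        for t in self.model.terms:
            edf = self.fit.term_edf.get(t.name, float("nan"))
            reported = t.kind
            if t.kind == "smooth" and edf <= LINEARIZE_EDF:
                reported = "linear"
            shape = shapes.get(t.name, "")
            lines.append(f"  {t.name:<15} {t.kind:<8} {edf:5.2f}  {reported:<9} {shape}")
        return "\n".join(lines)


def classify_effect_shape(x: np.ndarray, f: np.ndarray, tol_frac: float = 0.02,
                          response_scale: float | None = None) -> str:
    """Label a partial-effect curve: '+', '-', 'p' (single interior peak),
    'q' (other non-monotone), or '0' (flat).

    Monotonicity is judged with a tolerance of ``tol_frac`` of the curve's
    range, so spline wiggle below 2% of the signal does not flip a label; a
    curve whose whole range is below that fraction of the response scale is
    flat.  Invariant to affine rescaling of the covariate axis.
    """
    f = np.asarray(f, dtype=float)
    if len(f) < 50:
        raise ValueError("evaluate the curve on at least 50 grid points")
    rng = float(np.ptp(f))
    scale = response_scale if response_scale is not None else rng
    if rng < tol_frac * (scale if scale > 0 else 1.0):
        return "0"
    eps = tol_frac * rng
    drawdown = float(np.max(np.maximum.accumulate(f) - f))   # largest fall
    runup = float(np.max(f - np.minimum.accumulate(f)))      # largest rise
    if drawdown <= eps:
        return "+"
    if runup <= eps:
        return "-"
    peak = int(np.argmax(f))
    if 0 < peak < len(f) - 1:
        rise_ok = np.max(np.maximum.accumulate(f[:peak + 1]) - f[:peak + 1]) <= eps
        fall_ok = np.max(f[peak:] - np.minimum.accumulate(f[peak:])) <= eps
        if rise_ok and fall_ok:
            return "p"
    return "q"


def select_smoothing(data: pd.DataFrame, response: str, smooth: list[str],
                     k: int = 6, grid=ALPHA_GRID, criterion: str = "bic",
                     family: str = "auto") -> dict[str, float]:
    """Per-term smoothing weights chosen by univariate grid search.

    Each smooth term is fitted alone against the response over ``grid`` and
    scored by BIC (deviance + log(n) * EDF) by default, or AIC with
    ``criterion='aic'``.  BIC's stronger complexity penalty suppresses the
    boundary wiggle that a weak fixed penalty leaves in genuinely monotone
    effects, which matters when fitted curves are classified by shape.
    """
    n = len(data)
    mult = np.log(n) if criterion == "bic" else 2.0
    out = {}
    for term in smooth:
        best = None
        for a in grid:
            fit = fit_penalized_glm(data[response], data,
                                    [TermSpec(term, alpha=a, k=k)], family=family)
            score = fit.deviance + mult * fit.edf
            if best is None or score < best[0]:
                best = (score, a)
        out[term] = best[1]
    return out


def stepwise_select(data: pd.DataFrame, response: str, candidates: list[str],
                    forced: list[str] = (), factor: list[str] = (),
                    k: int = 6, alpha: float = 1.0, family: str = "auto",
                    threshold: float = 2.0) -> dict:
    """Combined forward/backward greedy AIC search over candidate smooth terms.

    At each iteration every single-term addition and deletion is scored; the
    best move is accepted if it improves AIC by more than ``threshold``
    (default 2), and the search stops when no move does.  ``forced`` terms
    (and ``factor`` terms, e.g. beach identity) are always included and
    never dropped.  Deterministic given the data and candidate order.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    selected: list[str] = []
    forced = list(forced)

    # Fix the family (and NB dispersion) once, from the full candidate model,
    # so AIC stays comparable across every move of the search.
    try:
        probe = AdditiveCountModel.from_dataframe(
            data, response, smooth=forced + list(candidates), factor=list(factor),
            k=k, alpha=alpha, family=family).fit()
        fixed_family, fixed_nb = probe.fit.family, probe.fit.nb_alpha or None
    except (ValueError, np.linalg.LinAlgError):
        fixed_family, fixed_nb = ("poisson", None) if family == "auto" else (family, None)

    def fit_aic(names: list[str]) -> float:
        model = AdditiveCountModel.from_dataframe(
            data, response, smooth=forced + names, factor=list(factor),
            k=k, alpha=alpha, family=fixed_family, nb_alpha=fixed_nb)
        return model.fit().aic

    current_aic = fit_aic(selected)
    trace = [(tuple(selected), current_aic)]
    while True:
        moves: list[tuple[float, str, str]] = []
        for c in candidates:
            if c in selected or c in forced:
                continue
            try:
                moves.append((fit_aic(selected + [c]), "add", c))
            except (ValueError, np.linalg.LinAlgError):
                continue
        for c in selected:
            rest = [s for s in selected if s != c]
            moves.append((fit_aic(rest), "drop", c))
        if not moves:
            break
        best_aic, op, name = min(moves, key=lambda m: (m[0], m[1], m[2]))
        if current_aic - best_aic <= threshold:
            break
        if op == "add":
            selected.append(name)
        else:
            selected.remove(name)
        current_aic = best_aic
        trace.append((tuple(selected), current_aic))
    return {"selected": forced + selected, "aic": current_aic, "trace": trace}


def redundancy_prune(data: pd.DataFrame, response: str, selected: list[str],
                     factor: list[str] = (), k: int = 6, alpha: float = 1.0,
                     family: str = "auto",
                     exception_groups=None, never_drop=None,
                     r_threshold: float = 0.7, p_threshold: float = 0.05) -> dict:
    """Drop the less important member of strongly correlated covariate pairs.

    Importance is the drop-one increase in deviance from the selected model.
    A pair is redundant when its Pearson correlation is significant
    (p < ``p_threshold``) and |r| > ``r_threshold``; the lower-importance
    member is dropped unless both sit in a common exception group (by
    default month/SST/air-temperature, which are correlated through season
    but ecologically distinct) or the term is in ``never_drop`` (by default
    the SST anomaly).
    """
    exception_groups = (DEFAULT_EXCEPTION_GROUPS if exception_groups is None
                        else exception_groups)
    never_drop = NEVER_DROP if never_drop is None else frozenset(never_drop)
    selected = list(selected)
    if not selected:
        return {"final": [], "importance": pd.DataFrame(columns=["term", "importance"]),
                "dropped": []}
    model = AdditiveCountModel.from_dataframe(data, response, smooth=selected,
                                              factor=list(factor), k=k, alpha=alpha,
                                              family=family)
    imp = model.fit().importance()
    scores = dict(zip(imp["term"], imp["importance"]))

    def exempt(a: str, b: str) -> bool:
        return any(a in g and b in g for g in exception_groups)

    pairs = []
    for i, a in enumerate(selected):
        for b in selected[i + 1:]:
            r, p = sps.pearsonr(np.asarray(data[a], float), np.asarray(data[b], float))
            if abs(r) > r_threshold and p < p_threshold:
                pairs.append((abs(r), a, b))
    dropped: list[str] = []
    for _, a, b in sorted(pairs, reverse=True):
        if a in dropped or b in dropped or exempt(a, b):
            continue
        loser, winner = (a, b) if scores.get(a, 0) < scores.get(b, 0) else (b, a)
        if loser in never_drop:
            loser, winner = winner, loser
        if loser in never_drop:
            continue
        dropped.append(loser)
    final = [s for s in selected if s not in dropped]
    return {"final": final, "importance": imp, "dropped": dropped}
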