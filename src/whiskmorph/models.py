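"""Regression machinery for whisker-array morphometrics.

Every morphological response (basepoint coordinates, 2D shape, emergence
angles) is modelled as a low-order polynomial in a small set of predictors
(row/column identity or the basepoint angles theta_bp, phi_bp). Models are
built per animal by forward selection — a term enters only if its
coefficient is significant (p <= 0.05), and model order is escalated to
quadratic only when the higher-order AIC is more than two points lower —
and then combined across animals: a term enters the consensus model only if
it was selected in at least ``min_support`` of the individual animals, and
the consensus order never exceeds the supported order.

Fitted or transcribed equations are stored as :class:`ModelEquation` /
:class:`CoefficientSet` and can be evaluated on arbitrary predictor grids.
Ordinary least squares is delegated to statsmodels.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .shape2d import UpperBoundCurve

__all__ = [
    "ModelEquation",
    "CoefficientSet",
    "remove_outliers",
    "forward_select",
    "consensus_model",
    "evaluate",
    "diagnostics",
    "load_coefficient_set",
]

ALPHA = 0.05
DELTA_AIC = 2.0

#: term vocabulary; squared terms escalate their base term
_BASE_OF_SQUARE = {"theta_bp^2": "theta_bp", "phi_bp^2": "phi_bp",
                   "row^2": "row", "col^2": "col"}


def _term_values(term: str, predictors: Mapping[str, np.ndarray]) -> np.ndarray:
    if term == "1":
        ref = next(iter(predictors.values()))
        return np.ones_like(np.asarray(ref, float))
    if term.endswith("^2"):
        return np.asarray(predictors[term[:-2]], float) ** 2
    return np.asarray(predictors[term], float)


@dataclass
class ModelEquation:
    """One fitted or transcribed regression equation.

    ``terms`` maps term names (``1``, ``row``, ``col``, ``theta_bp``,
    ``phi_bp`` and their ``^2`` forms) to coefficients. ``log_response``
    marks equations fitted to the natural log of the response, which
    :func:`evaluate` back-transforms — this is how the exponential
    arclength model S = S0 * exp(k * theta_bp) is represented.
    """

    response: str
    terms: dict[str, float]
    log_response: bool = False
    r2: float = float("nan")
    aic: float = float("nan")
    n: int = 0

    @property
    def order(self) -> int:
        return 2 if any(t.endswith("^2") for t in self.terms) else 1

    @property
    def predictor_terms(self) -> list[str]:
        return [t for t in self.terms if t != "1"]

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "log_response": self.log_response,
            "terms": dict(self.terms),
            "r2": self.r2,
            "aic": self.aic,
            "n": self.n,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelEquation":
        return cls(
            response=d["response"],
            terms={k: float(v) for k, v in d["terms"].items()},
            log_response=bool(d.get("log_response", False)),
            r2=float(d.get("r2", float("nan"))),
            aic=float(d.get("aic", float("nan"))),
            n=int(d.get("n", 0)),
        )


def evaluate(
    eq: ModelEquation, predictors: Mapping[str, np.ndarray | float]
) -> np.ndarray | float:
    """Evaluate an equation on predictor values (inverse-transforming logs)."""
    preds = {k: np.asarray(v, float) for k, v in predictors.items()}
    if not preds:
        preds = {"_": np.asarray(0.0)}
    out = None
    for term, coef in eq.terms.items():
        val = coef * _term_values(term, preds)
        out = val if out is None else out + val
    assert out is not None
    if eq.log_response:
        out = np.exp(out)
    return float(out) if np.ndim(out) == 0 else out


def remove_outliers(
    table: pd.DataFrame, response: str, k: float = 2.0
) -> tuple[pd.DataFrame, dict]:
    """Single-pass grouped outlier removal for one response column.

    Whiskers are grouped by (row, col) identity pooled across animals; in
    groups of three or more values, entries farther than ``k`` sample
    standard deviations from the group mean are set to NaN. Smaller groups
    pass through untouched. Repeated application could remove more values;
    only one pass is ever applied.
    """
    out = table.copy()
    values = out[response]
    n_before = int(values.notna().sum())
    drop = pd.Series(False, index=out.index)
    for _, grp in out.groupby(["row", "col"]):
        vals = grp[response].dropna()
        if len(vals) < 3:
            continue
        mean, sd = vals.mean(), vals.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            continue
        bad = vals.index[np.abs(vals - mean) > k * sd]
        drop.loc[bad] = True
    out.loc[drop, response] = np.nan
    n_removed = int(drop.sum())
    report = {
        "response": response,
        "n_before": n_before,
        "n_removed": n_removed,
        "pct_removed": 100.0 * n_removed / n_before if n_before else 0.0,
        "n_after": n_before - n_removed,
    }
    return out, report


def _fit_ols(
    y: np.ndarray, preds: Mapping[str, np.ndarray], terms: Sequence[str]
) -> sm.regression.linear_model.RegressionResultsWrapper:
    X = np.column_stack([_term_values(t, preds) for t in terms])
    return sm.OLS(y, X).fit()


def _design_terms(terms: Iterable[str]) -> list[str]:
    return ["1"] + [t for t in terms if t != "1"]


def _select_terms(
    y: np.ndarray,
    preds: Mapping[str, np.ndarray],
    candidates: Sequence[str],
    allow_squares: Mapping[str, bool],
    alpha: float = ALPHA,
    delta_aic: float = DELTA_AIC,
) -> list[str]:
    """Staged forward selection over first-order then squared terms.

    ``candidates`` are first-order terms; ``allow_squares[c]`` says whether
    the squared escalation of candidate ``c`` may be considered at all
    (used by the consensus stage to cap order).
    """
    # stage 1: univariate screens
    admitted: list[str] = []
    for c in candidates:
        fit = _fit_ols(y, preds, _design_terms([c]))
        if fit.pvalues[1] <= alpha:
            admitted.append(c)
    # stage 2: joint first-order model; prune until all significant
    current = list(admitted)
    while current:
        fit = _fit_ols(y, preds, _design_terms(current))
        pvals = dict(zip(current, fit.pvalues[1:]))
        worst = max(current, key=lambda t: pvals[t])
        if pvals[worst] <= alpha:
            break
        current.remove(worst)
    # stage 3: escalate to squares, gated by significance AND delta-AIC
    for c in list(current):
        sq = f"{c}^2"
        if not allow_squares.get(c, True):
            continue
        base_fit = _fit_ols(y, preds, _design_terms(current))
        trial = current + [sq]
        trial_fit = _fit_ols(y, preds, _design_terms(trial))
        if (
            np.all(trial_fit.pvalues[1:] <= alpha)
            and trial_fit.aic < base_fit.aic - delta_aic
        ):
            current = trial
    return current


def forward_select(
    table: pd.DataFrame,
    response: str,
    candidates: Sequence[str] = ("theta_bp", "phi_bp"),
    allow_log: bool = False,
    alpha: float = ALPHA,
    delta_aic: float = DELTA_AIC,
) -> ModelEquation | dict[str, ModelEquation]:
    """Forward-selection regression for one animal's observations.

    Starts with univariate first-order fits in each candidate, admits terms
    at p <= ``alpha``, escalates to squared terms only when the quadratic
    coefficient is significant and AIC drops by more than ``delta_aic``,
    and never exceeds order two. With ``allow_log`` both the raw-response
    and log-response branches are fitted and returned (``{"raw": ...,
    "log": ...}``) so that the consensus stage can choose between them.
    """
    data = table.dropna(subset=[response, *candidates])
    if len(data) < 10:
        raise ValueError(f"need at least 10 observations, got {len(data)}")
    preds = {c: data[c].to_numpy(float) for c in candidates}
    y_raw = data[response].to_numpy(float)

    def fit_branch(y: np.ndarray, log_flag: bool) -> ModelEquation:
        terms = _select_terms(
            y, preds, candidates, {c: True for c in candidates}, alpha, delta_aic
        )
        fit = _fit_ols(y, preds, _design_terms(terms))
        coefs = dict(zip(_design_terms(terms), fit.params))
        return ModelEquation(
            response=response,
            terms=coefs,
            log_response=log_flag,
            r2=float(fit.rsquared) if terms else 0.0,
            aic=float(fit.aic),
            n=len(y),
        )

    raw_eq = fit_branch(y_raw, False)
    if not allow_log:
        return raw_eq
    if np.any(y_raw <= 0):
        raise ValueError("log branch requires strictly positive responses")
    log_eq = fit_branch(np.log(y_raw), True)
    return {"raw": raw_eq, "log": log_eq}


def _branch_support(models: Sequence[ModelEquation]) -> dict[str, int]:
    support: dict[str, int] = {}
    for m in models:
        for t in m.predictor_terms:
            support[t] = support.get(t, 0) + 1
    return support


def _consensus_one_branch(
    models: Sequence[ModelEquation],
    pooled: pd.DataFrame,
    response: str,
    min_support: int,
    log_flag: bool,
    alpha: float,
    delta_aic: float,
) -> ModelEquation:
    support = _branch_support(models)
    supported = {t for t, c in support.items() if c >= min_support}
    first_order = sorted(t for t in supported if not t.endswith("^2"))
    allow_squares = {
        base: (f"{base}^2" in supported) for base in first_order
    }
    data = pooled.dropna(subset=[response])
    needed = {t[:-2] if t.endswith("^2") else t for t in supported} or {"theta_bp"}
    data = data.dropna(subset=sorted(needed & set(pooled.columns)))
    preds = {
        c: data[c].to_numpy(float)
        for c in pooled.columns
        if c in ("theta_bp", "phi_bp", "row", "col")
    }
    y = data[response].to_numpy(float)
    if log_flag:
        mask = y > 0
        y, preds = np.log(y[mask]), {k: v[mask] for k, v in preds.items()}
    terms = _select_terms(y, preds, first_order, allow_squares, alpha, delta_aic)
    fit = _fit_ols(y, preds, _design_terms(terms))
    eq = ModelEquation(
        response=response,
        terms=dict(zip(_design_terms(terms), fit.params)),
        log_response=log_flag,
        r2=float(fit.rsquared) if terms else 0.0,
        aic=float(fit.aic),
        n=len(y),
    )
    if log_flag:
        # Jacobian-corrected AIC so branches are comparable on the raw scale
        eq.aic = eq.aic + 2.0 * float(np.sum(np.log(np.exp(y))))
    return eq


def consensus_model(
    per_animal_models: Sequence[ModelEquation | dict[str, ModelEquation]],
    pooled_table: pd.DataFrame,
    response: str,
    min_support: int = 6,
    alpha: float = ALPHA,
    delta_aic: float = DELTA_AIC,
) -> ModelEquation:
    """Cross-animal consensus equation.

    A term is a candidate only if it was selected in at least
    ``min_support`` of the individual-animal models, and squared terms are
    considered only when themselves supported, capping the consensus order
    at the supported order. Candidates are then re-selected on the pooled
    data with the same significance and AIC gates. When the per-animal
    models carry raw and log branches, both consensus branches are fitted
    and the one with the lower (Jacobian-corrected) AIC is returned.
    """
    if per_animal_models and isinstance(per_animal_models[0], dict):
        raw_models = [m["raw"] for m in per_animal_models]  # type: ignore[index]
        log_models = [m["log"] for m in per_animal_models]  # type: ignore[index]
        raw_eq = _consensus_one_branch(
            raw_models, pooled_table, response, min_support, False, alpha, delta_aic
        )
        log_eq = _consensus_one_branch(
            log_models, pooled_table, response, min_support, True, alpha, delta_aic
        )
        return log_eq if log_eq.aic < raw_eq.aic else raw_eq
    return _consensus_one_branch(
        list(per_animal_models), pooled_table, response, min_support,  # type: ignore[arg-type]
        False, alpha, delta_aic,
    )


def diagnostics(eq: ModelEquation, table: pd.DataFrame) -> dict:
    """Observed-vs-predicted summary for an equation on a table.

    Returns R^2 (1 - SSE/SST on the raw response scale), the residual
    table and an identity-line scatter frame ready for export.
    """
    needed = sorted({t[:-2] if t.endswith("^2") else t for t in eq.predictor_terms})
    data = table.dropna(subset=[eq.response, *needed])
    preds = {c: data[c].to_numpy(float) for c in needed} or {"_": np.zeros(len(data))}
    predicted = evaluate(eq, preds)
    observed = data[eq.response].to_numpy(float)
    predicted = np.broadcast_to(np.asarray(predicted, float), observed.shape)
    resid = observed - predicted
    sst = float(np.sum((observed - observed.mean()) ** 2))
    sse = float(np.sum(resid**2))
    scatter = pd.DataFrame(
        {"observed": observed, "predicted": predicted, "residual": resid}
    )
    return {
        "r2": 1.0 - sse / sst if sst > 0 else float("nan"),
        "n": len(observed),
        "rmse": float(np.sqrt(np.mean(resid**2))) if len(resid) else float("nan"),
        "scatter": scatter,
    }


# ---------------------------------------------------------------------------
# coefficient sets


def _equations_checksum(equations: dict, upper_bound: dict) -> str:
    payload = json.dumps(
        {"equations": equations, "upper_bound": upper_bound},
        sort_keys=True, separators=(",", ":"),
    )
    return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class CoefficientSet:
    """A species' complete equation set plus array layout and provenance.

    ``array_layout`` maps row letter to the largest column present for that
    row; identities outside the layout are absent from the species, not
    extrapolated. ``zeta_reduced_excludes`` lists identities excluded from
    the reduced twist-angle model (the A row and each row's rostral-most
    column), for which generation falls back to the full model.
    """

    species: str
    equations: dict[str, ModelEquation]
    upper_bound: UpperBoundCurve
    array_layout: dict[str, int]
    provenance: dict = field(default_factory=dict)

    REQUIRED_MOUSE = (
        "theta_bp_from_col",
        "phi_bp_from_row",
        "r_bp_from_row_col",
        "r_bp_from_angles",
        "s_from_theta_bp",
        "a_from_theta_bp",
        "theta_w_full",
        "theta_w_reduced",
        "phi_w_from_phi_bp",
        "zeta_w_full",
        "zeta_w_reduced",
    )

    def equation(self, name: str) -> ModelEquation:
        return self.equations[name]

    def identities(self) -> list[tuple[int, int]]:
        """(row, col) pairs present in this species' array layout."""
        rows = "ABCDE"
        out = []
        for letter, max_col in self.array_layout.items():
            row = rows.index(letter) + 1
            out.extend((row, col) for col in range(1, int(max_col) + 1))
        return sorted(out)

    def zeta_is_low_confidence(self, row: int, col: int) -> bool:
        """Whether the reduced twist model excludes this identity."""
        letter = "ABCDE"[row - 1]
        return letter == "A" or col == int(self.array_layout[letter])

    def to_dict(self) -> dict:
        eqs = {k: v.to_dict() for k, v in self.equations.items()}
        ub = {
            "c0": self.upper_bound.c0,
            "c1": self.upper_bound.c1,
            "window": self.upper_bound.window,
        }
        return {
            "species": self.species,
            "provenance": self.provenance,
            "array_layout": self.array_layout,
            "upper_bound": ub,
            "equations": eqs,
            "checksum": _equations_checksum(eqs, ub),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CoefficientSet":
        eqs_raw = d["equations"]
        ub_raw = d["upper_bound"]
        stored = d.get("checksum")
        if stored is not None and stored != _equations_checksum(eqs_raw, ub_raw):
            raise ValueError("coefficient-set checksum mismatch; file corrupted")
        return cls(
            species=d["species"],
            equations={k: ModelEquation.from_dict(v) for k, v in eqs_raw.items()},
            upper_bound=UpperBoundCurve(
                c0=float(ub_raw["c0"]), c1=float(ub_raw["c1"]),
                window=float(ub_raw.get("window", 4.0)),
            ),
            array_layout={k: int(v) for k, v in d["array_layout"].items()},
            provenance=d.get("provenance", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def load_coefficient_set(source: str | Path) -> CoefficientSet:
    """Load a coefficient set by species name ('mouse', 'rat') or file path."""
    if str(source) in ("mouse", "rat"):
        ref = resources.files("whiskmorph.data") / f"{source}_synthetic.json"
        text = ref.read_text()
    else:
        text = Path(source).read_text()
    return CoefficientSet.from_dict(json.loads(text))
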