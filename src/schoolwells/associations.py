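"""Disparity estimators: stratified fixed-effects logistic and Mantel-Haenszel.

The primary estimator mirrors the study design: bivariable logistic regression
of the school characteristic (outcome, e.g. predominantly non-Hispanic White)
on buffer exposure with one intercept per stratum (state or county) and no
grand intercept,

    logit P(y=1) = alpha_stratum + beta * exposed,   OR = exp(beta),

fit by Newton-Raphson on counts collapsed to (stratum, exposure) binomial
cells. Strata with an invariant outcome carry no likelihood information about
beta and would force their intercept to +/-inf, so they are dropped before the
fit and reported. The Mantel-Haenszel pooled odds ratio with the
Robins-Breslow-Greenland variance serves as an independent verification
oracle over the same stratified 2x2 tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

Z95 = 1.959963984540054  # two-sided 95% normal quantile

TOP_PRODUCING_STATES = ("AK", "CO", "LA", "ND", "NM", "OK", "PA", "TX", "WV")


class TwoByTwo(NamedTuple):
    """Exposure x outcome cell counts within one stratum."""

    a: int  # exposed, outcome present
    b: int  # exposed, outcome absent
    c: int  # unexposed, outcome present
    d: int  # unexposed, outcome absent

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


class SeparationError(RuntimeError):
    pass


@dataclass
class AssociationResult:
    odds_ratio: float
    log_or: float
    se_log_or: float
    ci95_low: float
    ci95_high: float
    n_outcome_yes: int
    n_outcome_no: int
    n_strata_used: int
    n_strata_dropped: int
    method: str
    buffer_m: float | None = None
    characteristic: str | None = None
    subset: str | None = None
    threshold: float | None = None
    estimable: bool = True
    note: str = ""

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def tabulate(outcome_flags, exposure_flags, strata_labels) -> dict:
    """Cross-tabulate outcome x exposure within each stratum."""
    y = np.asarray(outcome_flags, dtype=bool)
    e = np.asarray(exposure_flags, dtype=bool)
    s = np.asarray(strata_labels, dtype=object)
    if not (len(y) == len(e) == len(s)):
        raise ValueError("outcome, exposure, and strata vectors must be equal length")
    tables: dict = {}
    for label in pd.unique(s):
        m = s == label
        tables[label] = TwoByTwo(
            a=int((y & e & m).sum()),
            b=int((~y & e & m).sum()),
            c=int((y & ~e & m).sum()),
            d=int((~y & ~e & m).sum()),
        )
    return tables


def mh_odds_ratio(tables: Mapping[object, TwoByTwo]) -> AssociationResult:
    """Mantel-Haenszel pooled OR with Robins-Breslow-Greenland 95% CI.

    Strata contributing nothing to either MH sum (no exposure or no outcome
    variation) are dropped and counted. No continuity correction: if the
    pooled numerator or denominator is zero the result is flagged
    inestimable.
    """
    R = S = 0.0
    sum_PR = sum_PSQR = sum_QS = 0.0
    used = dropped = 0
    n_yes = n_no = 0
    informative = []
    for t in tables.values():
        n = t.n
        if n == 0:
            dropped += 1
            continue
        Ri = t.a * t.d / n
        Si = t.b * t.c / n
        if Ri + Si == 0:
            dropped += 1
            continue
        informative.append((t, Ri, Si))
        used += 1
        n_yes += t.a + t.c
        n_no += t.b + t.d
        R += Ri
        S += Si
    if used == 0:
        raise ValueError("no informative stratum for Mantel-Haenszel pooling")
    if R == 0 or S == 0:
        return AssociationResult(np.nan, np.nan, np.nan, np.nan, np.nan,
                                 n_yes, n_no, used, dropped, "mantel_haenszel",
                                 estimable=False, note="zero pooled MH numerator or denominator")
    for t, Ri, Si in informative:
        Pi = (t.a + t.d) / t.n
        Qi = (t.b + t.c) / t.n
        sum_PR += Pi * Ri
        sum_PSQR += Pi * Si + Qi * Ri
        sum_QS += Qi * Si
    var = sum_PR / (2 * R * R) + sum_PSQR / (2 * R * S) + sum_QS / (2 * S * S)
    log_or = float(np.log(R / S))
    se = float(np.sqrt(var))
    return AssociationResult(
        odds_ratio=float(np.exp(log_or)), log_or=log_or, se_log_or=se,
        ci95_low=float(np.exp(log_or - Z95 * se)), ci95_high=float(np.exp(log_or + Z95 * se)),
        n_outcome_yes=n_yes, n_outcome_no=n_no,
        n_strata_used=used, n_strata_dropped=dropped, method="mantel_haenszel")


def _collapse(outcome_flags, exposure_flags, strata_labels) -> pd.DataFrame:
    df = pd.DataFrame({
        "y": np.asarray(outcome_flags, dtype=bool).astype(int),
        "e": np.asarray(exposure_flags, dtype=bool).astype(int),
        "s": np.asarray(strata_labels, dtype=object),
    })
    if not (len(df["y"]) == len(df["e"]) == len(df["s"])):
        raise ValueError("outcome, exposure, and strata vectors must be equal length")
    g = df.groupby(["s", "e"], sort=True).agg(trials=("y", "size"), successes=("y", "sum"))
    return g.reset_index()


def fe_logistic(outcome_flags, exposure_flags, strata_labels,
                max_iter: int = 100, tol_score: float = 1e-8,
                tol_ll: float = 1e-10) -> AssociationResult:
    """Bivariable logistic regression with stratum fixed effects.

    Newton-Raphson (with step-halving) on the binomial log-likelihood over
    counts collapsed by (stratum, exposure). Convergence when the maximum
    absolute score is below ``tol_score`` or the relative log-likelihood
    change falls below ``tol_ll``.
    """
    cells = _collapse(outcome_flags, exposure_flags, strata_labels)

    totals = cells.groupby("s").agg(trials=("trials", "sum"), successes=("successes", "sum"))
    invariant = totals[(totals["successes"] == 0) | (totals["successes"] == totals["trials"])]
    dropped = len(invariant)
    cells = cells[~cells["s"].isin(invariant.index)]
    if len(cells) == 0:
        raise ValueError("no stratum with outcome variation; fixed-effects model inestimable")
    if not ((cells.groupby("s")["e"].nunique() > 1).any()):
        raise SeparationError("exposure constant within every informative stratum")

    strata = pd.unique(cells["s"])
    s_index = {lab: i for i, lab in enumerate(strata)}
    S = len(strata)
    e = cells["e"].to_numpy(dtype=float)
    n = cells["trials"].to_numpy(dtype=float)
    y = cells["successes"].to_numpy(dtype=float)
    srow = np.array([s_index[lab] for lab in cells["s"]])

    # design: column 0 = exposure, columns 1..S = stratum dummies
    X = np.zeros((len(cells), S + 1))
    X[:, 0] = e
    X[np.arange(len(cells)), srow + 1] = 1.0

    def loglik(theta):
        eta = X @ theta
        # binomial ll up to constants: y*eta - n*log(1+exp(eta))
        return float(y @ eta - n @ np.logaddexp(0.0, eta))

    theta = np.zeros(S + 1)
    # reasonable intercept start: empirical stratum log-odds (bounded)
    marg = totals.drop(index=invariant.index)
    p0 = np.clip(marg["successes"] / marg["trials"], 1e-3, 1 - 1e-3)
    start = np.log(p0 / (1 - p0))
    theta[1:] = np.array([start.loc[lab] for lab in strata])

    ll = loglik(theta)
    trace = [ll]
    for it in range(max_iter):
        eta = X @ theta
        p = expit(eta)
        score = X.T @ (y - n * p)
        if np.max(np.abs(score)) < tol_score:
            break
        w = n * p * (1 - p)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from exc
        new_theta = theta + step
        new_ll = loglik(new_theta)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step /= 2.0
            new_theta = theta + step
            new_ll = loglik(new_theta)
            halvings += 1
        rel_change = abs(new_ll - ll) / (abs(ll) + 1e-12)
        theta, ll = new_theta, new_ll
        trace.append(ll)
        if abs(theta[0]) > 30:
            raise SeparationError("exposure effect diverging; data separated after stratum dropping")
        if rel_change < tol_ll:
            break
    else:
        raise ConvergenceError(f"Newton-Raphson did not converge in {max_iter} iterations", trace)

    eta = X @ theta
    p = expit(eta)
    score = X.T @ (y - n * p)
    if np.max(np.abs(score)) > 1e-4:
        raise ConvergenceError("Newton-Raphson stalled away from the optimum", trace)
    w = n * p * (1 - p)
    H = X.T @ (X * w[:, None])
    cov = np.linalg.inv(H)
    beta = float(theta[0])
    se = float(np.sqrt(cov[0, 0]))
    with np.errstate(over="ignore"):  # huge SE in sparse cells -> CI bound inf
        ci_low, ci_high = float(np.exp(beta - Z95 * se)), float(np.exp(beta + Z95 * se))
    return AssociationResult(
        odds_ratio=float(np.exp(beta)), log_or=beta, se_log_or=se,
        ci95_low=ci_low, ci95_high=ci_high,
        n_outcome_yes=int(y.sum()), n_outcome_no=int((n - y).sum()),
        n_strata_used=S, n_strata_dropped=dropped, method="fe_logistic")


@dataclass
class AssociationSpec:
    """Layout of the association suite (Tables 2/3-style grid)."""

    buffers: Sequence[float] = (800.0, 1600.0, 10000.0)
    characteristics: Sequence[str] = ("nh_white", "hispanic", "frl")
    fixed_effect_level: str = "state"  # or "county"
    predominance_threshold: float = 0.5
    subsets: Sequence[str] = ("all",)  # of {all, per-urbanicity, per-state, top_producing_states}

    def __post_init__(self) -> None:
        if self.fixed_effect_level not in ("state", "county"):
            raise ValueError("fixed_effect_level must be 'state' or 'county'")
        if self.predominance_threshold not in (0.4, 0.5, 0.6):
            raise ValueError("predominance_threshold must be one of 0.4/0.5/0.6")
        bad = set(self.subsets) - {"all", "per-urbanicity", "per-state", "top_producing_states"}
        if bad:
            raise ValueError(f"unknown subsets: {sorted(bad)}")


def _fit_cell(frame: pd.DataFrame, outcome_col: str, exposure_col: str,
              strata_col: str | None, method: str = "fe_logistic") -> AssociationResult:
    if len(frame) == 0:
        return AssociationResult(np.nan, np.nan, np.nan, np.nan, np.nan, 0, 0, 0, 0,
                                 method, estimable=False, note="empty subset cell")
    strata = frame[strata_col] if strata_col else np.repeat("pooled", len(frame))
    try:
        if method == "mantel_haenszel":
            return mh_odds_ratio(tabulate(frame[outcome_col], frame[exposure_col], strata))
        return fe_logistic(frame[outcome_col], frame[exposure_col], strata)
    except (ValueError, SeparationError, ConvergenceError) as exc:
        return AssociationResult(np.nan, np.nan, np.nan, np.nan, np.nan,
                                 int(frame[outcome_col].sum()),
                                 int((~frame[outcome_col].astype(bool)).sum()),
                                 0, 0, method, estimable=False, note=str(exc))


def run_association_suite(exposure_profiles: pd.DataFrame, school_profiles: pd.DataFrame,
                          spec: AssociationSpec = AssociationSpec()) -> pd.DataFrame:
    """Fit one association per (buffer x characteristic x subset) cell.

    Pooled and top-producing-state fits use stratum fixed effects at
    ``spec.fixed_effect_level``; per-urbanicity fits are state-FE models
    within each urbanicity class; per-state fits are unadjusted within-state
    bivariable models.
    """
    frame = school_profiles.merge(exposure_profiles, on="school_id", validate="one_to_one")
    strata_col = "state_code" if spec.fixed_effect_level == "state" else "county_fips"
    pct = int(round(spec.predominance_threshold * 100))

    cells: list[tuple[str, pd.DataFrame, str | None]] = []
    for subset in spec.subsets:
        if subset == "all":
            cells.append(("all", frame, strata_col))
        elif subset == "per-urbanicity":
            for urb in ("Rural", "Micropolitan", "Metropolitan"):
                cells.append((f"urbanicity:{urb}", frame[frame["urbanicity"] == urb], strata_col))
        elif subset == "per-state":
            for st, g in frame.groupby("state_code"):
                cells.append((f"state:{st}", g, None))
        elif subset == "top_producing_states":
            sub = frame[frame["state_code"].isin(TOP_PRODUCING_STATES)]
            cells.append(("top_producing_states", sub, strata_col))

    results = []
    for label, sub, scol in cells:
        for char in spec.characteristics:
            outcome_col = f"predominant_{char}_{pct}"
            for r in spec.buffers:
                res = _fit_cell(sub, outcome_col, f"exposed_{int(r)}m", scol)
                res.buffer_m = float(r)
                res.characteristic = char
                res.subset = label
                res.threshold = spec.predominance_threshold
                results.append(res.as_dict())
    return pd.DataFrame(results)


EXPOSURE_CLASS_ORDER = ("exposed_800m", "exposed_1600m", "exposed_10000m", "unexposed_beyond_10000m")


def descriptive_table(exposure_profiles: pd.DataFrame, school_profiles: pd.DataFrame,
                      radii: Sequence[float] = (800.0, 1600.0, 10000.0),
                      characteristics: Sequence[str] = ("nh_white", "hispanic", "black", "asian_pi", "frl"),
                      ) -> pd.DataFrame:
    """Mean / median / IQR of student-body percentages by exposure class.

    Classes are "exposed within r" for each radius (nested, not mutually
    exclusive) plus "unexposed beyond the largest radius". Quantiles use
    linear interpolation between order statistics at rank 1+(n-1)p.
    """
    frame = school_profiles.merge(exposure_profiles, on="school_id", validate="one_to_one")
    classes = [(f"exposed_{int(r)}m", frame[frame[f"exposed_{int(r)}m"]]) for r in radii]
    largest = int(max(radii))
    classes.append((f"unexposed_beyond_{largest}m", frame[~frame[f"exposed_{largest}m"]]))

    rows = []
    for label, g in classes:
        for char in characteristics:
            vals = (g[f"prop_{char}"] * 100.0).to_numpy(dtype=float)
            if len(vals) == 0:
                rows.append({"exposure_class": label, "characteristic": char, "n_schools": 0,
                             "mean": np.nan, "median": np.nan, "iqr_low": np.nan,
                             "iqr_high": np.nan, "empty": True})
                continue
            rows.append({
                "exposure_class": label, "characteristic": char, "n_schools": len(vals),
                "mean": float(np.mean(vals)),
                "median": float(np.percentile(vals, 50, method="linear")),
                "iqr_low": float(np.percentile(vals, 25, method="linear")),
                "iqr_high": float(np.percentile(vals, 75, method="linear")),
                "empty": False,
            })
    return pd.DataFrame(rows)
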