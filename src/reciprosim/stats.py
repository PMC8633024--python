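"""Nonparametric contrasts, correlations, and random-intercept models.

Every test emits a :class:`StatResult` carrying a standard-normal-scale
statistic ``z`` plus the effect sizes r = z / sqrt(N) and eta² = z² / N,
with N the total number of observations entering the test.  All p values
are two-tailed.  Wilcoxon statistics use exact enumeration below n = 10
and the tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

__all__ = [
    "StatResult",
    "ModelSpec",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "spearman",
    "fit_random_intercept_model",
    "bonferroni",
    "MODEL_TERM_SCHEMA",
]

_EXACT_N_MAX = 10


@dataclass
class StatResult:
    name: str
    estimate: float
    z: float
    p: float
    r: float
    eta_sq: float
    n: int
    note: str = ""

    @classmethod
    def from_z(cls, name: str, estimate: float, z: float, p: float, n: int, note: str = "") -> "StatResult":
        r = abs(z) / np.sqrt(n) if n > 0 else np.nan
        return cls(
            name=name,
            estimate=float(estimate),
            z=float(z),
            p=float(p),
            r=float(r),
            eta_sq=float(r**2),
            n=int(n),
            note=note,
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "estimate": self.estimate,
            "z": self.z,
            "p": self.p,
            "r": self.r,
            "eta_sq": self.eta_sq,
            "n": self.n,
            "note": self.note,
        }


def _signed_rank_normal(diffs: np.ndarray) -> tuple[float, float]:
    """Tie-corrected normal approximation of the signed-rank W+ statistic."""
    n = diffs.size
    ranks = sps.rankdata(np.abs(diffs))
    w_plus = ranks[diffs > 0].sum()
    mu = n * (n + 1) / 4.0
    tie_counts = np.unique(ranks, return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
    z = (w_plus - mu) / np.sqrt(var)
    return float(z), float(2 * sps.norm.sf(abs(z)))


def wilcoxon_signed_rank(
    x, y=None, mu: float = 0.0, name: str = "wilcoxon_signed_rank"
) -> StatResult:
    """Two-tailed one-sample / paired signed-rank test.

    With ``y`` given the test is on the pairwise differences, otherwise
    on ``x - mu``.  N for the effect sizes is the number of observations
    before zero-difference removal.
    """
    x = np.asarray(x, dtype=float)
    diffs = x - (np.asarray(y, dtype=float) if y is not None else mu)
    n_total = diffs.size
    nonzero = diffs[diffs != 0]
    note = ""
    if nonzero.size < 5:
        if nonzero.size == 0:
            return StatResult.from_z(name, 0.0, 0.0, 1.0, n_total, note="degenerate: all zero differences")
        raise ValueError("signed-rank test needs >= 5 non-zero differences")
    has_ties = np.unique(np.abs(nonzero)).size < nonzero.size
    if nonzero.size < _EXACT_N_MAX and not has_ties:
        res = sps.wilcoxon(nonzero, alternative="two-sided", method="exact")
        p = float(res.pvalue)
        z_from_norm, _ = _signed_rank_normal(nonzero)
        z = float(np.sign(z_from_norm) * sps.norm.isf(min(p, 1.0) / 2)) if p < 1 else 0.0
        note = "exact"
    else:
        z, p = _signed_rank_normal(nonzero)
        note = "normal approximation, tie-corrected"
    return StatResult.from_z(name, float(np.median(diffs)), z, p, n_total, note=note)


def wilcoxon_rank_sum(x, y, name: str = "wilcoxon_rank_sum") -> StatResult:
    """Two-tailed two-sample rank-sum test; N = n1 + n2 for effect sizes."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    tie_counts = np.unique(ranks, return_counts=True)[1]
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return StatResult.from_z(name, 0.0, 0.0, 1.0, n, note="degenerate: zero variance")
    z = (r1 - mu) / np.sqrt(var)
    has_ties = np.unique(pooled).size < n
    if min(n1, n2) < _EXACT_N_MAX and not has_ties:
        p = float(sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
        z = float(np.sign(z) * sps.norm.isf(min(p, 1.0) / 2)) if 0 < p < 1 else float(z)
        note = "exact"
    else:
        p = float(2 * sps.norm.sf(abs(z)))
        note = "normal approximation, tie-corrected"
    return StatResult.from_z(name, float(np.median(x) - np.median(y)), z, p, n, note=note)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties), two-tailed p.

    For n <= 7 without ties the p value comes from full permutation
    enumeration; larger samples use the t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("spearman needs n >= 4")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("spearman undefined for constant input")
    rho = float(sps.spearmanr(x, y).statistic)
    has_ties = np.unique(x).size < n or np.unique(y).size < n
    if n <= 7 and not has_ties:
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    return rho, float(p)


def bonferroni(p_values, m: int, alpha: float = 0.05) -> list[bool]:
    """Significance decisions at the Bonferroni-corrected threshold alpha/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return [p < alpha / m for p in np.asarray(p_values, dtype=float)]


@dataclass
class ModelSpec:
    """Formula-level description of one random-intercept model."""

    model_id: int
    response: str
    formula: str
    groups: str = "participant_id"
    description: str = ""


#: Frozen term schemas for the six analysis models so report diffs stay
#: meaningful across versions.  The runner relabels patsy terms to these.
MODEL_TERM_SCHEMA: dict[int, list[str]] = {
    1: [
        "Intercept[Computer]",
        "Robot-Computer",
        "distance[Computer]",
        "distance[Robot]",
        "distance:Robot-Computer",
    ],
    2: ["Intercept", "partner_influence"],
    3: [
        "Intercept[Computer,Baseline]",
        "Susceptible-Baseline[Computer]",
        "Unsusceptible-Baseline[Computer]",
        "Susceptible-Baseline[Robot]",
        "Unsusceptible-Baseline[Robot]",
        "Susceptible-Baseline,Robot-Computer",
        "Unsusceptible-Baseline,Robot-Computer",
    ],
    4: [
        "Intercept[Computer,Baseline]",
        "Susceptible-Baseline[Computer]",
        "Unsusceptible-Baseline[Computer]",
        "Susceptible-Baseline[Robot]",
        "Unsusceptible-Baseline[Robot]",
        "Susceptible-Baseline,Robot-Computer",
        "Unsusceptible-Baseline,Robot-Computer",
    ],
    5: [
        "Intercept[Computer,Baseline]",
        "Susceptible-Baseline[Computer]",
        "Unsusceptible-Baseline[Computer]",
        "Susceptible-Baseline[Robot]",
        "Unsusceptible-Baseline[Robot]",
        "Susceptible-Baseline,Robot-Computer",
        "Unsusceptible-Baseline,Robot-Computer",
        "Susceptible-Unsusceptible[Computer]",
        "Susceptible-Unsusceptible[Robot]",
        "Susceptible-Unsusceptible,Robot-Computer",
    ],
    6: [
        "Final-Preceding[Computer]",
        "Final-Preceding[Robot]",
        "Final-Preceding,Robot-Computer",
    ],
}


def _fit_mixedlm(formula: str, data: pd.DataFrame, groups: str):
    model = smf.mixedlm(formula, data=data, groups=data[groups])
    last_err: Exception | str | None = None
    for method in ("lbfgs", "powell", "cg"):
        try:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = model.fit(reml=False, method=method)
                if np.all(np.isfinite(fit.bse_fe)) and np.all(fit.bse_fe > 0):
                    return fit
                last_err = f"non-finite standard errors with method {method}"
        except (np.linalg.LinAlgError, ValueError) as exc:
            last_err = exc
    raise RuntimeError(
        f"mixed model fit failed for formula {formula!r}: {last_err}"
    ) from (last_err if isinstance(last_err, Exception) else None)


def fit_random_intercept_model(
    data: pd.DataFrame, spec: ModelSpec
) -> list[StatResult]:
    """Fit a linear model with a participant-level random intercept.

    Coefficients are reported with Wald z statistics and normal-based
    two-tailed p values.  Singular or non-converged fits raise with
    diagnostics rather than returning silently wrong numbers.
    """
    missing = {spec.response, spec.groups} - set(data.columns)
    if missing:
        raise ValueError(f"model {spec.model_id}: missing columns {sorted(missing)}")
    if data[spec.groups].nunique() < 2:
        raise ValueError("random-intercept model needs >= 2 participants")
    fit = _fit_mixedlm(spec.formula, data, spec.groups)
    n = len(data)
    results = []
    for term in fit.fe_params.index:
        b = float(fit.fe_params[term])
        se = float(fit.bse_fe[term])
        if not np.isfinite(se) or se == 0:
            raise RuntimeError(
                f"model {spec.model_id}: singular fit, term {term!r} has "
                f"standard error {se}; converged={fit.converged}"
            )
        z = b / se
        p = float(2 * sps.norm.sf(abs(z)))
        results.append(
            StatResult.from_z(f"model{spec.model_id}:{term}", b, z, p, n)
        )
    return results
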